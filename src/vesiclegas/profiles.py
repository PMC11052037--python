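"""Spherical-shell mass density profiles.

Each selected atom's mass is accumulated into the concentric shell
containing its distance from the vesicle centre; shell mass divided by
shell volume gives a local density in kg/m^3, averaged over frames.  This
is the spherical analogue of a planar bilayer z-profile and is how the
radial organisation of lipids, solvent and gas around a liposome is
normally displayed.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks

from .frame import Frame, MASS_DENSITY_FACTOR
from .geometry import vesicle_center

__all__ = ["RadialProfile", "radial_density", "interlayer_minimum"]


@dataclass
class RadialProfile:
    """Binned radial mass densities for one or more named selections."""

    bin_edges: np.ndarray               # (n_bins + 1,) nm
    density: dict[str, np.ndarray]      # kg/m^3 per bin
    overflow_mass: dict[str, float]     # frame-averaged mass (u) beyond r_max
    frames_used: list[float]            # timestamps (ns)
    center: str                         # description of the reference point

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def shell_volumes(self) -> np.ndarray:
        """Shell volumes (nm^3): (4 pi / 3) ((r+dr)^3 - r^3)."""
        return 4.0 * np.pi / 3.0 * np.diff(self.bin_edges ** 3)

    def bin_mass(self, selection: str) -> np.ndarray:
        """Frame-averaged mass (u) per shell, inverse of the density scaling."""
        return self.density[selection] * self.shell_volumes / MASS_DENSITY_FACTOR


def radial_density(frames: Sequence[Frame] | Frame,
                   selections: Mapping[str, np.ndarray] | np.ndarray,
                   bin_width: float = 0.2, r_max: float = 20.0,
                   center: str | np.ndarray = "lipid_com",
                   lipid_resname: str = "DOPC") -> RadialProfile:
    """Mass-density profile in spherical shells of ``bin_width`` nm.

    ``selections`` maps names to boolean atom masks (a bare mask is treated
    as one selection named "selection").  ``center`` is either the string
    ``"lipid_com"`` (centre of mass of all lipid atoms, recomputed each
    frame), ``"box_center"``, or a fixed coordinate.  Atoms beyond ``r_max``
    go to a per-selection overflow tally; the vesicle itself is expected to
    stay whole inside ``r_max``, so a lipid atom landing in the overflow is
    an error.
    """
    if isinstance(frames, Frame):
        frames = [frames]
    if len(frames) == 0:
        raise ValueError("no frames supplied")
    if isinstance(selections, np.ndarray):
        selections = {"selection": selections}
    if not selections:
        raise ValueError("no selections supplied")
    for name, mask in selections.items():
        if not np.asarray(mask).any():
            raise ValueError(f"selection {name!r} is empty")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")

    half_box = float(min(fr.box.min() for fr in frames)) / 2.0
    if r_max > half_box + 1e-9:
        raise ValueError(
            f"r_max = {r_max} nm exceeds half the smallest box edge "
            f"({half_box:.3f} nm); shells would cross the periodic boundary")

    n_bins = int(np.ceil(r_max / bin_width - 1e-9))
    edges = np.arange(n_bins + 1) * bin_width
    mass_sum = {name: np.zeros(n_bins) for name in selections}
    overflow = {name: 0.0 for name in selections}
    times = []

    for fr in frames:
        if isinstance(center, str):
            if center == "lipid_com":
                c = vesicle_center(fr, lipid_resname)
            elif center == "box_center":
                c = fr.box / 2.0
            else:
                raise ValueError(f"unknown center definition {center!r}")
        else:
            c = np.asarray(center, dtype=float)
        r_all = np.linalg.norm(fr.coordinates - c, axis=1)
        lipid_mask = fr.resname_mask(lipid_resname)
        if lipid_mask.any() and r_all[lipid_mask].max() >= r_max:
            raise ValueError(
                "a lipid atom lies beyond r_max; the vesicle must stay whole "
                "within the profiled range")
        for name, mask in selections.items():
            r = r_all[mask]
            m = fr.masses[mask]
            inside = r < edges[-1]
            hist, _ = np.histogram(r[inside], bins=edges, weights=m[inside])
            mass_sum[name] += hist
            overflow[name] += float(m[~inside].sum())
        times.append(fr.time)

    nf = len(frames)
    shell_vol = 4.0 * np.pi / 3.0 * np.diff(edges ** 3)
    density = {name: mass_sum[name] / nf * MASS_DENSITY_FACTOR / shell_vol
               for name in selections}
    center_desc = center if isinstance(center, str) else "fixed point"
    return RadialProfile(edges, density,
                         {k: v / nf for k, v in overflow.items()},
                         times, center_desc)


def interlayer_minimum(profile: RadialProfile, selection: str | None = None,
                       search_window: tuple[float, float] | None = None) -> float:
    """Radius (nm) of the density minimum between the two headgroup peaks.

    The headgroup spheres are the radially extreme lipid layers, so the
    bracketing peaks are the innermost and outermost prominent local maxima
    (prominence at least 5% of the density range).  Ties in the minimum
    break toward the smaller radius.  A profile without two bracketing
    peaks (e.g. monotone) is an error.
    """
    if selection is None:
        if len(profile.density) != 1:
            raise ValueError("profile has several selections; name one")
        selection = next(iter(profile.density))
    dens = profile.density[selection]
    centers = profile.bin_centers
    thresh = 0.05 * (dens.max() - dens.min())
    peaks, props = find_peaks(dens, prominence=thresh)
    if len(peaks) < 2:
        raise ValueError(
            "no pair of monolayer peaks brackets an interlayer minimum")
    lo, hi = int(peaks[0]), int(peaks[-1])
    if search_window is not None:
        wlo = np.searchsorted(centers, search_window[0])
        whi = np.searchsorted(centers, search_window[1], side="right")
        lo, hi = max(lo, wlo), min(hi, whi - 1)
        if hi <= lo:
            raise ValueError("search window excludes the inter-peak region")
    segment = dens[lo:hi + 1]
    return float(centers[lo + int(np.argmin(segment))])
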