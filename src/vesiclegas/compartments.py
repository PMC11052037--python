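"""Five-domain gas compartment classification and percolation time series.

Each gas atom is assigned per frame to one of five spatial domains of the
vesicle system -- external bulk solvent, outer lipid monolayer, interlayer
gap (referenced by the terminal acyl carbons of both monolayers), inner
lipid monolayer, or confined (enclosed) solvent -- by an effective-contact
rule: the atom belongs to the domain of its nearest reference heavy atom
within a cutoff (default 1.0 nm).  An atom with no reference within the
cutoff falls back to a radial-zone assignment.  Counting these assignments
at a fixed sampling interval yields the gas percolation dynamics.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .frame import Frame
from .geometry import (leaflet_resids_by_threshold, phosphorus_radii,
                       radial_distances, vesicle_center)

__all__ = ["DOMAINS", "CompartmentModel", "CompartmentSeries",
           "split_water", "classify_gas", "percolation_series"]

# canonical reporting order
DOMAINS = ("bulk", "outer", "gap", "inner", "confined")
# tie priority for equal nearest-reference distances (most local wins)
_PRIORITY = ("gap", "inner", "outer", "confined", "bulk")
GAS_RESNAMES = ("HE", "NE", "AR", "XE")


def _terminal_names(frame: Frame, lipid_resname: str) -> list[str]:
    """Names of the last carbon of each acyl chain, found from the naming."""
    lipid = frame.resname_mask(lipid_resname)
    names = set(map(str, frame.atom_names[lipid]))
    out = []
    for suffix in ("A", "B"):
        ks = [int(n[1:-1]) for n in names
              if n.startswith("C") and n.endswith(suffix) and n[1:-1].isdigit()]
        if ks:
            out.append(f"C{max(ks)}{suffix}")
    if not out:
        raise ValueError("could not identify terminal chain carbons by name")
    return out


def split_water(frame: Frame, lipid_resname: str = "DOPC",
                water_resname: str = "SOL",
                boundary: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Split waters into (external, confined) atom masks.

    A water is confined when its oxygen lies closer to the vesicle centre
    than the mean inner-monolayer headgroup radius (or an explicit
    ``boundary``); assignment covers the whole residue and is recomputed
    per frame.
    """
    center = vesicle_center(frame, lipid_resname)
    if boundary is None:
        resids, radii = phosphorus_radii(frame, center, lipid_resname)
        split = 0.5 * (radii.min() + radii.max())
        inner_r = radii[radii < split]
        if (len(inner_r) == 0 or len(inner_r) == len(radii)
                or radii.max() - radii.min() < 0.5):
            raise ValueError("degenerate vesicle: cannot locate an inner "
                             "headgroup sphere to split the solvent")
        boundary = float(inner_r.mean())
    water = frame.resname_mask(water_resname)
    if not water.any():
        return water.copy(), water.copy()
    ox = water & frame.name_mask("OW")
    r_ox = radial_distances(frame, center, ox)
    confined_resids = frame.residue_ids[ox][r_ox < boundary]
    confined = water & np.isin(frame.residue_ids, confined_resids)
    external = water & ~confined
    return external, confined


@dataclass
class CompartmentModel:
    """Reference atom sets and geometry for the five-domain classifier."""

    references: dict[str, np.ndarray]   # domain -> (m, 3) coordinates (nm)
    cutoff: float                        # nm
    center: np.ndarray
    zone_radii: dict[str, float]         # fallback annuli boundaries (nm)
    box: np.ndarray | None = None        # periodic box for distances

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        unknown = set(self.references) - set(DOMAINS)
        if unknown:
            raise ValueError(f"unknown domains {unknown}")

    @classmethod
    def from_frame(cls, frame: Frame, cutoff: float = 1.0,
                   lipid_resname: str = "DOPC", water_resname: str = "SOL",
                   ) -> "CompartmentModel":
        """Resolve the five disjoint reference sets on one frame.

        bulk / confined: external and enclosed water oxygens; outer / inner:
        lipid heavy atoms of each monolayer minus their terminal carbons;
        gap: the terminal carbons of both monolayers.
        """
        center = vesicle_center(frame, lipid_resname)
        resids, pradii = phosphorus_radii(frame, center, lipid_resname)
        split = 0.5 * (pradii.min() + pradii.max())
        outer_res, inner_res = leaflet_resids_by_threshold(resids, pradii, split)
        if len(outer_res) == 0 or len(inner_res) == 0:
            raise ValueError("degenerate vesicle: one monolayer is empty")
        r_head_out = float(pradii[np.isin(resids, outer_res)].mean())
        r_head_in = float(pradii[np.isin(resids, inner_res)].mean())

        lipid = frame.resname_mask(lipid_resname)
        heavy = lipid & (frame.masses > 2.0)
        term = heavy & frame.name_mask(*_terminal_names(frame, lipid_resname))
        in_outer = np.isin(frame.residue_ids, outer_res)
        in_inner = np.isin(frame.residue_ids, inner_res)

        ext_w, conf_w = split_water(frame, lipid_resname, water_resname,
                                    boundary=r_head_in)
        ext_ox = ext_w & frame.name_mask("OW")
        conf_ox = conf_w & frame.name_mask("OW")

        xyz = frame.coordinates
        refs = {
            "bulk": xyz[ext_ox],
            "outer": xyz[heavy & in_outer & ~term],
            "gap": xyz[term],
            "inner": xyz[heavy & in_inner & ~term],
            "confined": xyz[conf_ox],
        }
        term_r = radial_distances(frame, center, term)
        term_out = term_r[np.isin(frame.residue_ids[term], outer_res)]
        term_in = term_r[np.isin(frame.residue_ids[term], inner_res)]
        zone_radii = {
            "head_outer": r_head_out,
            "term_outer": float(term_out.mean()) if len(term_out) else r_head_out,
            "term_inner": float(term_in.mean()) if len(term_in) else r_head_in,
            "head_inner": r_head_in,
        }
        return cls(refs, cutoff, center, zone_radii, frame.box.copy())

    def fallback_domain(self, radii: np.ndarray) -> np.ndarray:
        """Radial-zone assignment for atoms with no reference in range."""
        z = self.zone_radii
        out = np.full(len(radii), "bulk", dtype=object)
        out[radii <= z["head_outer"]] = "outer"
        out[radii <= z["term_outer"]] = "gap"
        out[radii <= z["term_inner"]] = "inner"
        out[radii <= z["head_inner"]] = "confined"
        return out


def _wrap(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    w = np.mod(coords, box)
    return np.where(w >= box, 0.0, w)  # guard the float edge of np.mod


def classify_gas(frame: Frame, model: CompartmentModel,
                 gas_mask: np.ndarray | None = None) -> np.ndarray:
    """Domain label for each gas atom (array of strings).

    Nearest reference atom within the cutoff wins; exact distance ties break
    by the fixed priority gap > inner > outer > confined > bulk.  Distances
    use the minimum-image convention in the orthorhombic box.
    """
    if gas_mask is None:
        gas_mask = frame.resname_mask(*GAS_RESNAMES)
    gas_xyz = frame.coordinates[gas_mask]
    n = len(gas_xyz)
    if n == 0:
        return np.empty(0, dtype=object)
    box = model.box if model.box is not None else frame.box
    q = _wrap(gas_xyz, box)
    dists = np.full((len(_PRIORITY), n), np.inf)
    for i, dom in enumerate(_PRIORITY):
        ref = model.references.get(dom)
        if ref is None or len(ref) == 0:
            continue
        tree = cKDTree(_wrap(ref, box), boxsize=box)
        dists[i], _ = tree.query(q, k=1)
    best = np.argmin(dists, axis=0)           # first minimum = highest priority
    dmin = dists[best, np.arange(n)]
    labels = np.array([_PRIORITY[b] for b in best], dtype=object)
    far = dmin > model.cutoff
    if far.any():
        radii = np.linalg.norm(gas_xyz[far] - model.center, axis=1)
        labels[far] = model.fallback_domain(radii)
    return labels


@dataclass
class CompartmentSeries:
    """Per-frame gas counts and fractions in the five domains."""

    times: np.ndarray                   # ns
    counts: np.ndarray                  # (n_frames, 5) int, DOMAINS order
    species: str = ""

    @property
    def fractions(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.counts / totals, 0.0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(DOMAINS))
        df.insert(0, "time_ns", self.times)
        return df


def percolation_series(frames: Sequence[Frame], model: CompartmentModel | None = None,
                       sampling: float = 1.0, cutoff: float = 1.0,
                       species: str = "", gas_resname: str | None = None,
                       lipid_resname: str = "DOPC") -> CompartmentSeries:
    """Count gas atoms per domain at every ``sampling`` ns.

    When no static ``model`` is given, the reference sets are re-resolved on
    each sampled frame (atoms move).  Counts always sum to the gas total.
    """
    if len(frames) == 0:
        raise ValueError("empty trajectory")
    times, rows = [], []
    next_t = frames[0].time
    for fr in frames:
        if fr.time + 1e-9 < next_t:
            continue
        next_t = fr.time + sampling
        m = model if model is not None else CompartmentModel.from_frame(
            fr, cutoff=cutoff, lipid_resname=lipid_resname)
        mask = (fr.resname_mask(gas_resname) if gas_resname
                else fr.resname_mask(*GAS_RESNAMES))
        labels = classify_gas(fr, m, gas_mask=mask)
        rows.append([int((labels == d).sum()) for d in DOMAINS])
        times.append(fr.time)
    return CompartmentSeries(np.asarray(times), np.asarray(rows, dtype=int),
                             species=species or (gas_resname or ""))
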