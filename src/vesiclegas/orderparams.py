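"""Prochiral deuterium order parameters for united-atom acyl chains.

United-atom force fields carry no explicit aliphatic hydrogens, so the two
methylene hydrogen positions are reconstructed from the carbon skeleton:
for an sp3 carbon C_i the pair lies in the plane perpendicular to the
C_{i-1}->C_{i+1} axis through C_i, at half the tetrahedral H-C-H angle on
either side of the in-plane bisector.  The two positions are prochiral --
swapping them requires a mirror image -- and are disambiguated into Pro-S
and Pro-R by the sign of the scalar triple product
det[C_{i-1}-C_i, C_{i+1}-C_i, H-C_i]: positive for Pro-S under the
convention used here (mirror-imaging a chain therefore swaps the labels,
consistent with CIP chirality).  The sp2 carbons of a cis double bond carry
a single in-plane hydrogen along the C-C-C bisector, used for both
channels; they are detected geometrically by their shortened bond.

The order parameter of carbon k is S = <(3 cos^2 theta - 1)/2> over lipids
and frames, theta being the angle between the reconstructed C-H unit vector
and a director: the laboratory z axis (``lab_z``), or the lipid's
instantaneous radial unit vector (``radial``), which is the
curvature-aware choice for a spherical monolayer.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .frame import Frame
from .geometry import (leaflet_resids_by_threshold, phosphorus_radii,
                       vesicle_center)
from . import profiles

__all__ = ["PseudoHydrogen", "OrderProfile", "reconstruct_hydrogens",
           "reconstruct_ch_vectors", "leaflet_split", "order_profile"]

log = logging.getLogger(__name__)

TETRA_HALF = np.deg2rad(109.471 / 2.0)   # half the H-C-H tetrahedral angle
SP2_BOND_NM = 0.143                       # bond shorter than this marks sp2


def reconstruct_ch_vectors(coords: np.ndarray, sp2_mask: np.ndarray | None = None,
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """C-H unit vectors for a batch of chains.

    ``coords`` has shape (..., k, 3).  Returns ``(h_proS, h_proR, valid)``
    with the same leading shape; terminal carbons and carbons with collinear
    neighbours are invalid (vectors NaN).
    """
    coords = np.asarray(coords, dtype=float)
    k = coords.shape[-2]
    lead = coords.shape[:-2]
    hS = np.full(lead + (k, 3), np.nan)
    hR = np.full(lead + (k, 3), np.nan)
    valid = np.zeros(lead + (k,), dtype=bool)
    if sp2_mask is None:
        sp2_mask = np.zeros(k, dtype=bool)

    prev = coords[..., :-2, :]
    cur = coords[..., 1:-1, :]
    nxt = coords[..., 2:, :]
    d1 = prev - cur
    d2 = nxt - cur
    d1 /= np.linalg.norm(d1, axis=-1, keepdims=True)
    d2 /= np.linalg.norm(d2, axis=-1, keepdims=True)
    bis = -(d1 + d2)
    nrm_b = np.linalg.norm(bis, axis=-1, keepdims=True)
    perp = np.cross(d1, d2)
    nrm_p = np.linalg.norm(perp, axis=-1, keepdims=True)
    ok = (nrm_p[..., 0] > 1e-8) & (nrm_b[..., 0] > 1e-8)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = bis / nrm_b
        v = perp / nrm_p
    h_plus = u * np.cos(TETRA_HALF) + v * np.sin(TETRA_HALF)
    h_minus = u * np.cos(TETRA_HALF) - v * np.sin(TETRA_HALF)
    # det[d1, d2, h+] = |d1 x d2| (v . h+) > 0, so h+ is the Pro-S hydrogen
    mid = slice(1, k - 1)
    hS[..., mid, :] = h_plus
    hR[..., mid, :] = h_minus
    sp2_mid = sp2_mask[1:k - 1]
    if sp2_mid.any():
        hS[..., mid, :][..., sp2_mid, :] = u[..., sp2_mid, :]
        hR[..., mid, :][..., sp2_mid, :] = u[..., sp2_mid, :]
    valid[..., mid] = ok
    bad = ~np.isfinite(hS).all(axis=-1)
    valid &= ~bad
    return hS, hR, valid


@dataclass
class PseudoHydrogen:
    """Reconstructed hydrogen directions at one chain carbon."""

    carbon: int                 # 1-based chain index
    h_proS: np.ndarray          # unit vector
    h_proR: np.ndarray
    sp2: bool


def reconstruct_hydrogens(chain_coords: np.ndarray,
                          sp2_carbons: Sequence[int] = ()) -> list[PseudoHydrogen]:
    """Hydrogen list for a single chain of shape (k, 3); 1-based sp2 indices.

    Raises ``ValueError`` when any interior carbon has collinear neighbours.
    """
    coords = np.asarray(chain_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 3:
        raise ValueError("a chain needs at least three consecutive carbons")
    k = coords.shape[0]
    sp2_mask = np.zeros(k, dtype=bool)
    for c in sp2_carbons:
        sp2_mask[c - 1] = True
    hS, hR, valid = reconstruct_ch_vectors(coords, sp2_mask)
    if not valid[1:-1].all():
        raise ValueError("collinear chain neighbours; hydrogens are undefined")
    return [PseudoHydrogen(i + 1, hS[i], hR[i], bool(sp2_mask[i]))
            for i in range(1, k - 1)]


def leaflet_split(frame: Frame, boundary_radius: float | None = None,
                  lipid_resname: str = "DOPC") -> tuple[np.ndarray, np.ndarray]:
    """(outer, inner) lipid resids, split by headgroup phosphorus radius.

    The boundary defaults to the interlayer minimum of the lipid radial
    density profile; a lipid exactly on the boundary counts as outer.
    """
    center = vesicle_center(frame, lipid_resname)
    if boundary_radius is None:
        r_max = float(frame.box.min()) / 2.0
        prof = profiles.radial_density(
            frame, {"lipid": frame.resname_mask(lipid_resname)},
            bin_width=0.2, r_max=r_max, lipid_resname=lipid_resname)
        boundary_radius = profiles.interlayer_minimum(prof, "lipid")
    resids, radii = phosphorus_radii(frame, center, lipid_resname)
    return leaflet_resids_by_threshold(resids, radii, boundary_radius)


@dataclass
class OrderProfile:
    """Per-carbon prochiral order parameters for one chain and leaflet."""

    chain: str                  # "sn1" | "sn2"
    leaflet: str                # "outer" | "inner"
    carbons: np.ndarray         # chain carbon indices (C2 .. C_{n-1})
    S_proS: np.ndarray
    S_proR: np.ndarray
    director_mode: str          # "lab_z" | "radial"
    window: tuple[float, float]  # ns
    n_samples: np.ndarray       # (lipid, frame) samples per carbon


def _chain_index_matrix(frame: Frame, resids: np.ndarray, chain: str,
                        lipid_resname: str) -> tuple[np.ndarray, int]:
    """(L, k) atom-index matrix for one chain across the given lipids."""
    suffix = {"sn1": "A", "sn2": "B"}[chain]
    lipid = frame.resname_mask(lipid_resname)
    names = frame.atom_names
    ks = [int(str(n)[1:-1]) for n in set(names[lipid])
          if str(n).startswith("C") and str(n).endswith(suffix)
          and str(n)[1:-1].isdigit()]
    if not ks:
        raise ValueError(f"no chain {chain} carbons found")
    k = max(ks)
    lookup: dict[tuple[int, str], int] = {}
    for i in np.flatnonzero(lipid):
        lookup[(int(frame.residue_ids[i]), str(names[i]))] = i
    idx = np.empty((len(resids), k), dtype=int)
    for li, rid in enumerate(resids):
        for c in range(1, k + 1):
            idx[li, c - 1] = lookup[(int(rid), f"C{c}{suffix}")]
    return idx, k


def order_profile(frames: Sequence[Frame], leaflet: str, chain: str,
                  director_mode: str = "lab_z",
                  window: tuple[float, float] | None = None,
                  boundary_radius: float | None = None,
                  lipid_resname: str = "DOPC") -> OrderProfile:
    """S_CD(k) per chain carbon, Pro-S and Pro-R channels accumulated
    separately over the lipids of one leaflet and the frames of a window.

    ``window`` defaults to the last 20 ns of the trajectory.  Lipids with a
    collinear chain segment in a frame are skipped for that frame (logged).
    """
    if len(frames) == 0:
        raise ValueError("empty trajectory")
    if director_mode not in ("lab_z", "radial"):
        raise ValueError(f"unknown director mode {director_mode!r}")
    if leaflet not in ("outer", "inner"):
        raise ValueError(f"unknown leaflet {leaflet!r}")
    times = np.array([fr.time for fr in frames])
    if window is None:
        window = (max(times[-1] - 20.0, times[0]), times[-1])
    sel = (times >= window[0] - 1e-9) & (times <= window[1] + 1e-9)
    if not sel.any():
        raise ValueError(f"window {window} lies outside the trajectory span "
                         f"({times[0]}, {times[-1]}) ns")
    used = [frames[i] for i in np.flatnonzero(sel)]

    first = used[0]
    out0, in0 = leaflet_split(first, boundary_radius, lipid_resname)
    resids0 = out0 if leaflet == "outer" else in0
    if len(resids0) == 0:
        raise ValueError(f"{leaflet} leaflet is empty")
    idx, k = _chain_index_matrix(first, resids0, chain, lipid_resname)
    # sp2 carbons from the shortened double bond, measured on the first frame
    chain0 = first.coordinates[idx]
    bonds = np.linalg.norm(np.diff(chain0, axis=1), axis=-1).mean(axis=0)
    sp2_mask = np.zeros(k, dtype=bool)
    short = bonds < SP2_BOND_NM
    sp2_mask[:-1] |= short
    sp2_mask[1:] |= short

    p_idx = {}
    lipid = first.resname_mask(lipid_resname) & first.name_mask("P")
    for i in np.flatnonzero(lipid):
        p_idx[int(first.residue_ids[i])] = i

    sumS = np.zeros(k)
    sumR = np.zeros(k)
    nsamp = np.zeros(k)
    skipped = 0
    for fr in used:
        out_r, in_r = leaflet_split(fr, boundary_radius, lipid_resname)
        resids = out_r if leaflet == "outer" else in_r
        if not np.array_equal(resids, resids0):
            idx_f, _ = _chain_index_matrix(fr, resids, chain, lipid_resname)
        else:
            idx_f = idx
        coords = fr.coordinates[idx_f]                  # (L, k, 3)
        hS, hR, valid = reconstruct_ch_vectors(coords, sp2_mask)
        if director_mode == "lab_z":
            director = np.array([0.0, 0.0, 1.0])[None, None, :]
        else:
            center = vesicle_center(fr, lipid_resname)
            p_pos = np.array([fr.coordinates[p_idx[int(r)]] for r in resids])
            rad = p_pos - center
            rad /= np.linalg.norm(rad, axis=1, keepdims=True)
            director = rad[:, None, :]
        cS = np.einsum("lkd,lkd->lk", np.nan_to_num(hS),
                       np.broadcast_to(director, hS.shape))
        cR = np.einsum("lkd,lkd->lk", np.nan_to_num(hR),
                       np.broadcast_to(director, hR.shape))
        w = valid.astype(float)
        skipped += int((~valid[:, 1:-1]).sum())
        sumS += ((1.5 * cS ** 2 - 0.5) * w).sum(axis=0)
        sumR += ((1.5 * cR ** 2 - 0.5) * w).sum(axis=0)
        nsamp += w.sum(axis=0)
    if skipped:
        log.warning("skipped %d collinear chain segments", skipped)

    mid = slice(1, k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        S_proS = np.where(nsamp[mid] > 0, sumS[mid] / nsamp[mid], np.nan)
        S_proR = np.where(nsamp[mid] > 0, sumR[mid] / nsamp[mid], np.nan)
    return OrderProfile(chain, leaflet, np.arange(2, k), S_proS, S_proR,
                        director_mode, window, nsamp[mid])
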