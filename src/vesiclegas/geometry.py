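"""Shared vesicle geometry helpers: centres, radial coordinates, leaflet
bookkeeping used by several analysis stages."""
from __future__ import annotations

import numpy as np

from .frame import Frame

__all__ = ["vesicle_center", "radial_distances", "phosphorus_radii",
           "leaflet_resids_by_threshold"]


def vesicle_center(frame: Frame, lipid_resname: str = "DOPC") -> np.ndarray:
    """Centre of mass of all lipid atoms (recomputed per frame)."""
    mask = frame.resname_mask(lipid_resname)
    if not mask.any():
        raise ValueError(f"no {lipid_resname!r} atoms in frame")
    return frame.center_of_mass(mask)


def radial_distances(frame: Frame, center: np.ndarray,
                     mask: np.ndarray | None = None) -> np.ndarray:
    xyz = frame.coordinates if mask is None else frame.coordinates[mask]
    return np.linalg.norm(xyz - center, axis=1)


def phosphorus_radii(frame: Frame, center: np.ndarray,
                     lipid_resname: str = "DOPC",
                     p_name: str = "P") -> tuple[np.ndarray, np.ndarray]:
    """(resids, radii) of the lipid phosphorus atoms, one per lipid."""
    mask = frame.resname_mask(lipid_resname) & frame.name_mask(p_name)
    if not mask.any():
        raise ValueError("no lipid phosphorus atoms found")
    resids = frame.residue_ids[mask]
    radii = radial_distances(frame, center, mask)
    return resids, radii


def leaflet_resids_by_threshold(resids: np.ndarray, radii: np.ndarray,
                                boundary: float) -> tuple[np.ndarray, np.ndarray]:
    """Split lipids into (outer, inner) by headgroup radius.

    A lipid exactly on the boundary is assigned to the outer leaflet.
    """
    outer = resids[radii >= boundary]
    inner = resids[radii < boundary]
    return np.sort(outer), np.sort(inner)
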