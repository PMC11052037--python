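"""Core trajectory container.

A :class:`Frame` holds one snapshot of a molecular system: positions in
nanometres, per-atom names, residue assignment, masses in unified atomic
mass units and an orthorhombic box.  A trajectory is simply a list of
frames with a constant atom count.  All analysis modules operate on these
plain numpy-backed objects; file formats are handled in :mod:`vesiclegas.io`.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["Frame", "validate_trajectory"]

# 1 u / nm^3 expressed in kg / m^3
MASS_DENSITY_FACTOR = 1.66053906660


@dataclass
class Frame:
    """One snapshot: coordinates in nm, masses in u, orthorhombic box in nm."""

    coordinates: np.ndarray          # (n, 3) float64, nm
    atom_names: np.ndarray           # (n,) str
    residue_names: np.ndarray        # (n,) str
    residue_ids: np.ndarray          # (n,) int
    masses: np.ndarray               # (n,) float64, u
    box: np.ndarray                  # (3,) float64, nm
    time: float = 0.0                # ns

    def __post_init__(self) -> None:
        self.coordinates = np.ascontiguousarray(self.coordinates, dtype=np.float64)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.residue_names = np.asarray(self.residue_names, dtype=object)
        self.residue_ids = np.asarray(self.residue_ids, dtype=np.int64)
        self.masses = np.asarray(self.masses, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        n = len(self.coordinates)
        for name, arr in (("atom_names", self.atom_names),
                          ("residue_names", self.residue_names),
                          ("residue_ids", self.residue_ids),
                          ("masses", self.masses)):
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")
        if self.box.shape != (3,):
            raise ValueError("box must be three orthorhombic edge lengths")
        if not np.all(self.box > 0):
            raise ValueError("box lengths must be positive")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")

    @property
    def n_atoms(self) -> int:
        return len(self.coordinates)

    def resname_mask(self, *resnames: str) -> np.ndarray:
        """Boolean mask selecting atoms whose residue name is in ``resnames``."""
        return np.isin(np.asarray(self.residue_names, dtype="U8"),
                       np.asarray(resnames, dtype="U8"))

    def name_mask(self, *names: str) -> np.ndarray:
        return np.isin(np.asarray(self.atom_names, dtype="U8"),
                       np.asarray(names, dtype="U8"))

    def center_of_mass(self, mask: np.ndarray | None = None) -> np.ndarray:
        if mask is None:
            xyz, m = self.coordinates, self.masses
        else:
            xyz, m = self.coordinates[mask], self.masses[mask]
        if len(xyz) == 0:
            raise ValueError("center of mass of an empty selection")
        return (xyz * m[:, None]).sum(axis=0) / m.sum()

    def subset(self, mask: np.ndarray) -> "Frame":
        return Frame(self.coordinates[mask], self.atom_names[mask],
                     self.residue_names[mask], self.residue_ids[mask],
                     self.masses[mask], self.box.copy(), self.time)

    def translated(self, shift: np.ndarray) -> "Frame":
        return replace(self, coordinates=self.coordinates + np.asarray(shift, float))

    def copy(self) -> "Frame":
        return Frame(self.coordinates.copy(), self.atom_names.copy(),
                     self.residue_names.copy(), self.residue_ids.copy(),
                     self.masses.copy(), self.box.copy(), self.time)


def validate_trajectory(frames: Sequence[Frame]) -> None:
    """Check the constant-atom-count invariant across a trajectory."""
    if len(frames) == 0:
        raise ValueError("empty trajectory")
    n = frames[0].n_atoms
    for i, fr in enumerate(frames):
        if fr.n_atoms != n:
            raise ValueError(f"frame {i} has {fr.n_atoms} atoms, expected {n}")


def concat_frames(parts: Sequence[Frame]) -> Frame:
    """Concatenate atom sets that share a box into a single frame."""
    if not parts:
        raise ValueError("nothing to concatenate")
    box = parts[0].box
    return Frame(
        np.concatenate([p.coordinates for p in parts]),
        np.concatenate([p.atom_names for p in parts]),
        np.concatenate([p.residue_names for p in parts]),
        np.concatenate([p.residue_ids for p in parts]),
        np.concatenate([p.masses for p in parts]),
        box.copy(),
        parts[0].time,
    )
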