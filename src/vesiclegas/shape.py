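"""Grid/probe molecular volumetrics: solvent-excluded volume, surface area,
sphericity index and effective radius.

The solvent-excluded envelope is built by the roll-back construction in two
passes.  First the probe-accessible boundary is located exactly: the field
F(x) = max_i (r_i + r_probe - |x - a_i|) is the signed distance to the union
of probe-inflated atom spheres wherever a single sphere dominates, and its
zero level set -- extracted sub-voxel by marching cubes -- is the surface on
which the probe centre rolls.  Second, every grid point closer than one
probe radius to that surface is rolled away: the excluded envelope is the
level set ``distance-to-accessible-surface = r_probe`` inside the inflated
union, triangulated by a second marching-cubes pass.  The mesh gives both
the enclosed volume and the surface area with sub-voxel accuracy, which the
plain voxel-counting estimate lacks.

All shape quantities are reported in angstroms, the customary unit of
molecular volume servers.  Sphericity is pi^(1/3) (6V)^(2/3) / A (1 for a
perfect sphere); the effective radius is 3V/A (the radius of the sphere
with the same volume-to-surface ratio).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes, mesh_surface_area

__all__ = ["ShapeReport", "probe_volume_area", "sphericity",
           "effective_radius", "shape_report", "normalize_report"]

DEFAULT_PROBE_A = 1.4     # water-sized probe, angstroms
DEFAULT_SPACING_A = 0.5   # grid spacing, angstroms
MAX_VOXELS = 6.0e7

_CHUNK = 2_000_000


def _inflated_field(positions: np.ndarray, radii: np.ndarray, inflate: float,
                    origin: np.ndarray, shape: tuple[int, int, int],
                    h: float) -> np.ndarray:
    """F(x) = max_i (r_i + inflate - |x - a_i|) on the voxel grid (float32)."""
    nx, ny, nz = shape
    field = np.full(nx * ny * nz, -np.inf, dtype=np.float32)
    trees = [(float(r), cKDTree(positions[radii == r]))
             for r in np.unique(radii)]
    zz = origin[2] + (np.arange(nz) + 0.5) * h
    yy = origin[1] + (np.arange(ny) + 0.5) * h
    rows_per_chunk = max(1, _CHUNK // (ny * nz))
    for x0 in range(0, nx, rows_per_chunk):
        x1 = min(x0 + rows_per_chunk, nx)
        xs = origin[0] + (np.arange(x0, x1) + 0.5) * h
        pts = np.stack(np.meshgrid(xs, yy, zz, indexing="ij"),
                       axis=-1).reshape(-1, 3)
        best = np.full(len(pts), -np.inf, dtype=np.float32)
        for r, tree in trees:
            d, _ = tree.query(pts, k=1)
            np.maximum(best, (r + inflate - d).astype(np.float32), out=best)
        field[x0 * ny * nz:x1 * ny * nz] = best
    return field.reshape(shape)


def probe_volume_area(positions: np.ndarray, radii: np.ndarray | float,
                      probe_radius: float = DEFAULT_PROBE_A,
                      grid_spacing: float = DEFAULT_SPACING_A,
                      max_voxels: float = MAX_VOXELS) -> tuple[float, float]:
    """Solvent-excluded volume (A^3) and surface area (A^2) of an atom set.

    ``positions`` (n, 3) and ``radii`` are in angstroms.  ``grid_spacing``
    must not exceed the probe radius, or the roll-back cannot be resolved;
    a grid exceeding ``max_voxels`` raises ``MemoryError`` rather than
    thrashing (coarsen the spacing for very large inputs).
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.shape[0] < 1:
        raise ValueError("need at least one atom")
    radii = np.ascontiguousarray(
        np.broadcast_to(np.asarray(radii, dtype=float), positions.shape[0]))
    if np.any(radii <= 0):
        raise ValueError("atom radii must be positive")
    if probe_radius < 0:
        raise ValueError("probe radius must be non-negative")
    if probe_radius > 0 and grid_spacing > probe_radius:
        raise ValueError(
            f"grid spacing {grid_spacing} A is coarser than the probe radius "
            f"{probe_radius} A; the roll-back cannot be resolved")
    h = float(grid_spacing)
    pad = float(radii.max()) + probe_radius + 2.0 * h
    origin = positions.min(axis=0) - pad
    top = positions.max(axis=0) + pad
    shape = tuple(int(np.ceil((top[d] - origin[d]) / h)) + 1 for d in range(3))
    n_vox = float(np.prod(shape))
    if n_vox > max_voxels:
        raise MemoryError(
            f"grid of {shape} = {n_vox:.2e} voxels exceeds the guard of "
            f"{max_voxels:.0e}; coarsen the spacing or shrink the input")

    F = _inflated_field(positions, radii, probe_radius, origin, shape, h)
    if probe_radius == 0.0:
        field, level = F, 0.0
    else:
        # accessible boundary, sub-voxel: zero level set of the exact field
        sas_verts, _, _, _ = marching_cubes(F, level=0.0, spacing=(h, h, h))
        stree = cKDTree(sas_verts)
        nx, ny, nz = shape
        dist = np.empty(nx * ny * nz, dtype=np.float32)
        zz = (np.arange(nz) + 0.5) * h
        yy = (np.arange(ny) + 0.5) * h
        rows = max(1, _CHUNK // (ny * nz))
        for x0 in range(0, nx, rows):
            x1 = min(x0 + rows, nx)
            xs = (np.arange(x0, x1) + 0.5) * h
            pts = np.stack(np.meshgrid(xs, yy, zz, indexing="ij"),
                           axis=-1).reshape(-1, 3)
            d, _ = stree.query(pts, k=1)
            dist[x0 * ny * nz:x1 * ny * nz] = d
        dist = dist.reshape(shape)
        field = np.where(F >= 0, dist, -dist)
        level = probe_radius
    if field.max() <= level:
        return 0.0, 0.0   # the probe rolls everywhere; nothing is excluded
    verts, faces, _, _ = marching_cubes(field, level=level, spacing=(h, h, h))
    area = float(mesh_surface_area(verts, faces))
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    volume = float(abs(mesh.volume))
    return volume, area


def sphericity(volume: float, area: float) -> float:
    """Sphericity index pi^(1/3) (6 V)^(2/3) / A (dimensionless, 1 = sphere)."""
    if volume <= 0 or area <= 0:
        raise ValueError("volume and area must be positive")
    return float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area)


def effective_radius(volume: float, area: float) -> float:
    """Effective radius 3 V / A; equals R for a sphere of radius R."""
    if volume <= 0 or area <= 0:
        raise ValueError("volume and area must be positive")
    return float(3.0 * volume / area)


@dataclass
class ShapeReport:
    """Volume/area/sphericity/effective-radius bundle (angstrom units)."""

    volume: float               # A^3
    area: float                 # A^2
    sphericity: float
    effective_radius: float     # A
    probe_radius: float         # A
    grid_spacing: float         # A
    normalized: tuple[float, float, float, float] | None = None

    @classmethod
    def from_volume_area(cls, volume: float, area: float, probe_radius: float,
                         grid_spacing: float) -> "ShapeReport":
        return cls(volume, area, sphericity(volume, area),
                   effective_radius(volume, area), probe_radius, grid_spacing)


def shape_report(positions: np.ndarray, radii: np.ndarray | float,
                 probe_radius: float = DEFAULT_PROBE_A,
                 grid_spacing: float = DEFAULT_SPACING_A,
                 max_voxels: float = MAX_VOXELS) -> ShapeReport:
    """Full probe-based shape report for an atom set (angstrom inputs)."""
    v, a = probe_volume_area(positions, radii, probe_radius, grid_spacing,
                             max_voxels)
    return ShapeReport.from_volume_area(v, a, probe_radius, grid_spacing)


def normalize_report(report: ShapeReport, control: ShapeReport) -> ShapeReport:
    """Report each quantity as a dimensionless score relative to a control.

    The division uses unrounded values; the control must have been computed
    with the same probe radius and grid spacing.
    """
    if not np.isclose(report.probe_radius, control.probe_radius) or \
       not np.isclose(report.grid_spacing, control.grid_spacing):
        raise ValueError("control was computed with different probe/grid "
                         "settings; normalisation would not be meaningful")
    normalized = (report.volume / control.volume,
                  report.area / control.area,
                  report.sphericity / control.sphericity,
                  report.effective_radius / control.effective_radius)
    return replace(report, normalized=normalized)
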