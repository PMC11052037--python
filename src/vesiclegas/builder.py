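"""Spherical liposome construction.

Lipids are placed on two concentric spheres: the outer monolayer heads-out,
the inner monolayer heads-in, each lipid oriented along its local radial
vector.  Headgroup anchor points are distributed with a deterministic
spherical Fibonacci lattice, which gives quasi-uniform surface coverage
without any force relaxation; downstream analysis needs geometry, not
minimised packing.  The headgroup-sphere radii follow from the prescribed
area per lipid a at a surface carrying N lipids: 4*pi*R^2 = N*a.

Solvation places SPC-geometry waters on a jittered cubic lattice that
excludes the lipid-occupied shell; dissolved gas is introduced by replacing
a random subset of waters with single Lennard-Jones atoms, mirroring how
saturated-gas systems are prepared for simulation.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .frame import Frame, concat_frames
from .params import GasSpec, UA_MASSES
from .template import LipidTemplate, dopc_template

__all__ = [
    "VesicleSpec", "PackingError", "build_vesicle", "solvate_and_insert_gas",
    "SolvationResult", "area_per_lipid_at", "gas_count", "fibonacci_sphere",
]

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


class PackingError(RuntimeError):
    """Raised when the requested vesicle cannot be packed without clashes."""


@dataclass(frozen=True)
class VesicleSpec:
    """Construction parameters for a two-monolayer spherical vesicle.

    ``apl_outer`` is the area per lipid at the outer surface of the external
    monolayer, ``apl_inner`` at the inner surface of the internal monolayer
    (both are headgroup spheres).  The reciprocal of each is the surface
    number density n = N/S of that monolayer.
    """

    n_outer: int
    n_inner: int
    apl_outer: float = 0.95   # nm^2
    apl_inner: float = 0.50   # nm^2
    template: LipidTemplate = field(default_factory=dopc_template)

    def __post_init__(self) -> None:
        if self.n_outer <= 0 or self.n_inner <= 0:
            raise ValueError("monolayer lipid counts must be positive")
        if not (self.apl_outer >= self.apl_inner > 0):
            raise ValueError("need apl_outer >= apl_inner > 0")
        r_out, r_in = self.headgroup_radii()
        if not (r_out > r_in > 0):
            raise ValueError("derived radii must satisfy R_outer > R_inner > 0")

    def headgroup_radii(self) -> tuple[float, float]:
        """Radii (nm) of the outer and inner headgroup spheres."""
        r_out = np.sqrt(self.n_outer * self.apl_outer / (4.0 * np.pi))
        r_in = np.sqrt(self.n_inner * self.apl_inner / (4.0 * np.pi))
        return float(r_out), float(r_in)

    @property
    def reference_density_outer(self) -> float:
        """Lipids per nm^2 on the outer headgroup sphere (n = N/S)."""
        return 1.0 / self.apl_outer

    @property
    def reference_density_inner(self) -> float:
        return 1.0 / self.apl_inner

    @classmethod
    def from_reference_density(cls, density: float, n_outer: int, n_inner: int,
                               template: LipidTemplate | None = None) -> "VesicleSpec":
        """Spec with the same surface number density n on both headgroup spheres."""
        apl = 1.0 / density
        kwargs = {} if template is None else {"template": template}
        return cls(n_outer, n_inner, apl, apl, **kwargs)


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors on the sphere (deterministic)."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = i * GOLDEN_ANGLE
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _rotation_to(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +z onto ``direction`` (unit vector)."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, direction))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(z, direction)
    s = np.linalg.norm(axis)
    axis = axis / s
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def _rot_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _place_monolayer(tpl: LipidTemplate, n: int, radius: float, heads_out: bool,
                     center: np.ndarray, first_resid: int,
                     chain_tilt: float = 0.0,
                     anchor_jitter: float = 0.0,
                     rng: np.random.Generator | None = None) -> Frame:
    """Place ``n`` template copies on a sphere of the given headgroup radius.

    Each lipid is rotated so its head-to-tail axis lies along the local
    radial vector (outward for ``heads_out``, inward otherwise), spun about
    its own axis by an equally spaced deterministic angle, and optionally
    tilted by ``chain_tilt`` radians away from the radial before placement.
    """
    dirs = fibonacci_sphere(n)
    spins = 2.0 * np.pi * np.arange(n) / n
    # alternating tilt sign cancels the lateral centre-of-mass bias pairwise;
    # the order parameter is even in the tilt angle, so the statistics of the
    # planted tilt are unchanged
    tilts = (_rot_y(chain_tilt), _rot_y(-chain_tilt))
    coords = np.empty((n * tpl.n_atoms, 3))
    offsets = tpl.offsets
    for i in range(n):
        u = dirs[i] if heads_out else -dirs[i]
        R = _rotation_to(u) @ tilts[i % 2] @ _rot_z(spins[i])
        anchor = center + radius * dirs[i]
        if anchor_jitter > 0.0 and rng is not None:
            t = rng.normal(size=3)
            t -= np.dot(t, dirs[i]) * dirs[i]
            norm = np.linalg.norm(t)
            if norm > 0:
                anchor = anchor + anchor_jitter * t / norm
        coords[i * tpl.n_atoms:(i + 1) * tpl.n_atoms] = offsets @ R.T + anchor
    names = np.tile(np.asarray(tpl.names, dtype=object), n)
    resnames = np.repeat(np.asarray([tpl.resname], dtype=object), n * tpl.n_atoms)
    resids = np.repeat(np.arange(first_resid, first_resid + n), tpl.n_atoms)
    masses = np.tile(tpl.masses, n)
    return Frame(coords, names, resnames, resids, masses,
                 box=np.array([1.0, 1.0, 1.0]))  # box set by caller


def build_vesicle(spec: VesicleSpec, box: float | np.ndarray, seed: int = 0,
                  clash_tolerance: float = 0.25, anchor_jitter: float = 0.0,
                  chain_tilt: float = 0.0) -> Frame:
    """Construct the two-monolayer vesicle, centred in the box.

    Raises :class:`PackingError` naming the offending monolayer pair when any
    two heavy atoms of different lipids come closer than ``clash_tolerance``
    nm, and ``ValueError`` when the vesicle cannot fit in the box.
    ``chain_tilt`` (radians) is a synthetic-data hook that tilts every lipid
    away from its radial axis.
    """
    box = np.asarray(box, dtype=float) * np.ones(3)
    tpl = spec.template
    r_out, r_in = spec.headgroup_radii()
    if r_out + tpl.head_extent >= float(box.min()) / 2.0:
        raise ValueError(
            f"box too small: outer radius {r_out:.2f} nm + headgroup extent "
            f"{tpl.head_extent:.2f} nm must fit inside half the box "
            f"({box.min() / 2:.2f} nm)")
    center = box / 2.0
    rng = np.random.default_rng(seed)
    outer = _place_monolayer(tpl, spec.n_outer, r_out, True, center, 1,
                             chain_tilt, anchor_jitter, rng)
    inner = _place_monolayer(tpl, spec.n_inner, r_in, False, center,
                             spec.n_outer + 1, chain_tilt, anchor_jitter, rng)
    frame = concat_frames([outer, inner])
    frame.box[:] = box

    tree = cKDTree(frame.coordinates)
    pairs = tree.query_pairs(r=clash_tolerance, output_type="ndarray")
    if len(pairs):
        rid = frame.residue_ids
        cross = pairs[rid[pairs[:, 0]] != rid[pairs[:, 1]]]
        if len(cross):
            which = np.where(rid[cross] <= spec.n_outer, "outer", "inner")
            kinds = {f"{a}-{b}" for a, b in zip(which[:, 0], which[:, 1])}
            raise PackingError(
                f"{len(cross)} inter-lipid contacts closer than "
                f"{clash_tolerance} nm involving monolayer pairs: "
                f"{sorted(kinds)}")
    return frame


def area_per_lipid_at(spec: VesicleSpec, monolayer: str, r: float) -> float:
    """Area per lipid 4*pi*r^2 / N of the given monolayer at radius ``r`` (nm)."""
    if r <= 0:
        raise ValueError("radius must be positive")
    if monolayer == "outer":
        n = spec.n_outer
    elif monolayer == "inner":
        n = spec.n_inner
    else:
        raise ValueError(f"unknown monolayer {monolayer!r}; use 'outer' or 'inner'")
    return float(4.0 * np.pi * r * r / n)


def gas_count(molar_fraction: float, n_molecules: int,
              n_atoms: int | None = None) -> int:
    """Number of waters to replace by gas.

    The default rule rounds ``molar_fraction`` times the total molecule count
    (solvent + gas; replacement keeps that total constant).  An explicit
    ``n_atoms`` bypasses the rule, because a stated molar fraction and a
    stated replacement count need not be mutually consistent.
    """
    if n_atoms is not None:
        return int(n_atoms)
    return int(np.floor(molar_fraction * n_molecules + 0.5))


def water_lattice_sites(box: np.ndarray, exclude_coords: np.ndarray | None,
                        spacing: float, exclusion_radius: float = 0.30,
                        radial_band: tuple[np.ndarray, float, float] | None = None,
                        ) -> np.ndarray:
    """Cubic-lattice candidate solvent sites, excluding occupied regions.

    Sites within ``exclusion_radius`` of any atom in ``exclude_coords`` are
    dropped, as are sites whose radius from ``radial_band[0]`` lies inside
    ``(radial_band[1], radial_band[2])`` -- used to keep solvent out of the
    lipid shell, including its interstices.
    """
    box = np.asarray(box, dtype=float)
    counts = np.maximum((box / spacing).astype(int), 1)
    axes = [(np.arange(c) + 0.5) * (box[d] / c) for d, c in enumerate(counts)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    keep = np.ones(len(grid), dtype=bool)
    if radial_band is not None:
        center, r_lo, r_hi = radial_band
        rad = np.linalg.norm(grid - center, axis=1)
        keep &= ~((rad > r_lo) & (rad < r_hi))
    if exclude_coords is not None and len(exclude_coords):
        tree = cKDTree(exclude_coords)
        d, _ = tree.query(grid[keep], k=1, distance_upper_bound=exclusion_radius)
        sub = keep.nonzero()[0]
        keep[sub[np.isfinite(d) & (d < exclusion_radius)]] = False
    return grid[keep]


# SPC water geometry: O-H 0.1 nm, H-O-H 109.47 degrees
_SPC_OFFSETS = np.array([
    [0.0, 0.0, 0.0],
    [0.1 * np.sin(np.deg2rad(54.735)), 0.0, 0.1 * np.cos(np.deg2rad(54.735))],
    [-0.1 * np.sin(np.deg2rad(54.735)), 0.0, 0.1 * np.cos(np.deg2rad(54.735))],
])
_WATER_NAMES = np.array(["OW", "HW1", "HW2"], dtype=object)
_WATER_MASSES = np.array([UA_MASSES["OW"], UA_MASSES["HW"], UA_MASSES["HW"]])


def water_frame(sites: np.ndarray, box: np.ndarray, first_resid: int,
                jitter: float = 0.0, rng: np.random.Generator | None = None,
                ) -> Frame:
    """SPC waters at the given oxygen sites (one residue per site)."""
    n = len(sites)
    if jitter > 0.0 and rng is not None:
        sites = sites + rng.uniform(-jitter, jitter, size=sites.shape)
    coords = (sites[:, None, :] + _SPC_OFFSETS[None, :, :]).reshape(-1, 3)
    names = np.tile(_WATER_NAMES, n)
    resnames = np.repeat(np.asarray(["SOL"], dtype=object), 3 * n)
    resids = np.repeat(np.arange(first_resid, first_resid + n), 3)
    masses = np.tile(_WATER_MASSES, n)
    return Frame(coords, names, resnames, resids, masses, box)


@dataclass
class SolvationResult:
    """Solvated frame plus the provenance of the gas replacement."""

    frame: Frame
    replaced_site_indices: np.ndarray   # indices into the accepted water sites
    n_waters: int
    n_gas: int


def solvate_and_insert_gas(frame: Frame, water_count: int, gas: GasSpec,
                           seed: int = 0, water_spacing: float | None = None,
                           shell_margin: float = 0.25) -> SolvationResult:
    """Solvate a vesicle frame and replace random waters by gas atoms.

    Waters go on a jittered cubic lattice that avoids the lipid-occupied
    spherical shell; ``n_gas = round(molar_fraction * water_count)`` waters
    (or ``gas.n_atoms`` if set) are then replaced by single gas atoms chosen
    uniformly at random.  The total molecule count is preserved.
    """
    rng = np.random.default_rng(seed)
    box = frame.box
    lipid_mask = frame.resname_mask("DOPC")
    lipid_xyz = frame.coordinates[lipid_mask]
    if len(lipid_xyz):
        center = frame.center_of_mass(lipid_mask)
        rad = np.linalg.norm(lipid_xyz - center, axis=1)
        band = (center, float(rad.min() - shell_margin),
                float(rad.max() + shell_margin))
    else:
        center, band = box / 2.0, None

    if water_spacing is None:
        vol = float(np.prod(box))
        if band is not None:
            vol -= 4.0 / 3.0 * np.pi * (band[2] ** 3 - max(band[1], 0.0) ** 3)
        water_spacing = (max(vol, 1e-6) / (1.3 * max(water_count, 1))) ** (1.0 / 3.0)

    sites = water_lattice_sites(box, lipid_xyz if len(lipid_xyz) else None,
                                water_spacing, radial_band=band)
    if len(sites) < water_count:
        sites = water_lattice_sites(box, lipid_xyz if len(lipid_xyz) else None,
                                    water_spacing * 0.85, radial_band=band)
    if len(sites) < water_count:
        raise ValueError(
            f"only {len(sites)} solvent sites available for {water_count} waters")
    chosen = np.sort(rng.choice(len(sites), size=water_count, replace=False))
    sites = sites[chosen]

    n_gas = gas_count(gas.molar_fraction, water_count, gas.n_atoms)
    if n_gas > water_count:
        raise ValueError(f"gas count {n_gas} exceeds available waters {water_count}")
    replaced = np.sort(rng.choice(water_count, size=n_gas, replace=False)) \
        if n_gas else np.empty(0, dtype=int)
    water_sel = np.ones(water_count, dtype=bool)
    water_sel[replaced] = False

    first_resid = int(frame.residue_ids.max()) + 1 if frame.n_atoms else 1
    waters = water_frame(sites[water_sel], box, first_resid,
                         jitter=0.12 * water_spacing, rng=rng)
    parts = [frame, waters]
    if n_gas:
        gas_sites = sites[replaced]
        gfirst = first_resid + int(water_sel.sum())
        gas_part = Frame(gas_sites,
                         np.repeat(np.asarray([gas.resname], dtype=object), n_gas),
                         np.repeat(np.asarray([gas.resname], dtype=object), n_gas),
                         np.arange(gfirst, gfirst + n_gas),
                         np.full(n_gas, gas.mass), box)
        parts.append(gas_part)
    out = concat_frames(parts)
    out.time = frame.time
    return SolvationResult(out, replaced, int(water_sel.sum()), n_gas)
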