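"""Synthetic vesicle trajectories with planted, recorded ground truth.

The generator emulates the study system at reduced scale: a two-monolayer
spherical vesicle built by :mod:`vesiclegas.builder`, lattice solvent inside
and outside, and a dissolved gas population whose compartment occupancies
follow a prescribed piecewise-linear schedule.  Ground truth (per-frame
compartment counts, analytic bubble volumes, closed-form order parameters,
the applied shape deformation) is recorded before any positional noise, so
every analysis stage can be validated against what was actually planted.

There is no physics here: atoms are resampled independently per frame, so
the trajectories carry realistic geometry and occupancy statistics but no
dynamics, forces or correlations.

Compartment zones are sampled with margins wide enough (relative to the
1.0 nm contact cutoff) that the nearest-reference classifier recovers every
planted label by construction; bubble lattices are packed at 1.05 sigma so
single-linkage clustering at the default 1.5 sigma cutoff finds each
planted bubble as one cluster.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import ellipeinc, ellipkinc

from .builder import VesicleSpec, build_vesicle, water_frame, water_lattice_sites
from .compartments import DOMAINS
from .frame import Frame, concat_frames
from .orderparams import reconstruct_ch_vectors
from .params import GAS_REGISTRY, vdw_radius_A
from .template import dopc_template

__all__ = ["Scenario", "BubblePlan", "GroundTruth", "generate", "degrade",
           "default_vesicle_spec", "ellipsoid_area", "hcp_ball"]


def default_vesicle_spec() -> VesicleSpec:
    """Reduced-scale vesicle used by the synthetic scenarios.

    450/187 lipids with short (6-carbon, all-trans) tails: large enough that
    the five compartments are geometrically well separated relative to the
    1.0 nm contact cutoff, small enough for fast test runs.
    """
    return VesicleSpec(n_outer=450, n_inner=188, apl_outer=0.95,
                       apl_inner=0.50,
                       template=dopc_template(n_chain=6, cis_bond=False))


@dataclass(frozen=True)
class BubblePlan:
    """A planted condensed-gas droplet."""

    compartment: str
    radius: float               # nm (lattice extent)
    species: str = "argon"
    center: tuple[float, float, float] | None = None


@dataclass
class Scenario:
    """Full specification of a synthetic trajectory."""

    vesicle: VesicleSpec = field(default_factory=default_vesicle_spec)
    box: float = 18.0           # nm
    n_frames: int = 5
    dt: float = 1.0             # ns
    n_gas: int = 60
    species: str = "argon"
    # waypoints (time_ns, {domain: fraction}); fractions interpolate linearly
    gas_plan: list[tuple[float, dict[str, float]]] = field(
        default_factory=lambda: [(0.0, {"bulk": 1.0})])
    bubbles: list[BubblePlan] = field(default_factory=list)
    deformation: tuple[float, float, float] = (1.0, 1.0, 1.0)
    chain_tilt: float = 0.0     # degrees from the radial director
    noise_sigma: float = 0.0    # nm
    water_spacing: float = 0.62  # nm
    margin: float = 1.0         # nm; compartment sampling margin (= cutoff)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if not (0.0 <= self.chain_tilt <= 90.0):
            raise ValueError("chain_tilt must lie in [0, 90] degrees")
        if any(s <= 0 for s in self.deformation):
            raise ValueError("deformation scale factors must be positive")
        for t, fr in self.gas_plan:
            unknown = set(fr) - set(DOMAINS)
            if unknown:
                raise ValueError(f"unknown domains in gas plan: {unknown}")
            if any(v < 0 for v in fr.values()):
                raise ValueError("gas plan fractions must be non-negative")
            if abs(sum(fr.values()) - 1.0) > 1e-9:
                raise ValueError(
                    f"gas plan fractions at t={t} sum to {sum(fr.values())}, "
                    "expected 1")


@dataclass
class BubbleTruth:
    compartment: str
    species: str
    center: np.ndarray
    radius: float                 # nm, planted lattice extent
    n_atoms: int
    atom_slice: slice             # position in every frame
    analytic_volume_nm3: float    # (4/3) pi r^3 of the planted sphere
    inflated_volume_A3: float     # expected probe volume: n_atoms s^3 / sqrt(2)


@dataclass
class GroundTruth:
    """Everything the generator planted, recorded before noise."""

    domain_order: tuple[str, ...]
    compartment_counts: np.ndarray        # (n_frames, 5) dispersed gas
    gas_labels: list[np.ndarray]          # per-frame planted labels
    gas_slice: slice                      # dispersed gas atoms in each frame
    bubbles: list[BubbleTruth]
    species: str
    chain_tilt_deg: float
    order_S_true: dict[str, np.ndarray]   # radial-mode S per carbon (C2..)
    order_carbons: np.ndarray
    applied_sphericity: float
    n_external_water: int
    n_confined_water: int
    zone_bounds: dict[str, tuple[float, float]]


def _p2(c: float) -> float:
    return 0.5 * (3.0 * c * c - 1.0)


def ellipsoid_area(a: float, b: float, c: float) -> float:
    """Exact surface area of an ellipsoid with semi-axes a, b, c."""
    axes = np.sort([a, b, c])[::-1]
    a, b, c = map(float, axes)
    if a - c < 1e-12 * a:
        return 4.0 * np.pi * a * a
    phi = np.arccos(c / a)
    m = (a * a * (b * b - c * c)) / (b * b * (a * a - c * c))
    F = ellipkinc(phi, m)
    E = ellipeinc(phi, m)
    s = np.sin(phi)
    return float(2.0 * np.pi * c * c
                 + 2.0 * np.pi * a * b / s * (E * s * s + F * np.cos(phi) ** 2))


def hcp_ball(radius: float, spacing: float) -> np.ndarray:
    """Hexagonal close-packing points within ``radius`` of the origin."""
    if radius <= 0 or spacing <= 0:
        raise ValueError("radius and spacing must be positive")
    n = int(np.ceil(radius / spacing)) + 1
    pts = []
    dz = spacing * np.sqrt(6.0) / 3.0
    dy = spacing * np.sqrt(3.0) / 2.0
    for k in range(-n, n + 1):
        for j in range(-n, n + 1):
            y = dy * (j + (k % 2) / 3.0)
            for i in range(-n, n + 1):
                x = spacing * (i + 0.5 * ((j + k) % 2))
                p = (x, y, dz * k)
                if x * x + y * y + (dz * k) ** 2 <= radius * radius:
                    pts.append(p)
    if not pts:
        pts = [(0.0, 0.0, 0.0)]
    return np.asarray(pts, dtype=float)


def _largest_remainder(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer counts summing to ``total`` with fractions as close as allowed."""
    raw = fractions * total
    counts = np.floor(raw).astype(int)
    rem = total - counts.sum()
    if rem > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:rem]] += 1
    return counts


def _plan_fractions(plan: list[tuple[float, dict[str, float]]],
                    t: float) -> np.ndarray:
    times = np.array([p[0] for p in plan])
    mats = np.array([[p[1].get(d, 0.0) for d in DOMAINS] for p in plan])
    if t <= times[0]:
        return mats[0]
    if t >= times[-1]:
        return mats[-1]
    i = int(np.searchsorted(times, t, side="right")) - 1
    w = (t - times[i]) / (times[i + 1] - times[i])
    return (1.0 - w) * mats[i] + w * mats[i + 1]


def _sample_annulus(rng: np.random.Generator, n: int, r_lo: float, r_hi: float,
                    center: np.ndarray) -> np.ndarray:
    u = rng.random(n)
    r = (u * (r_hi ** 3 - r_lo ** 3) + r_lo ** 3) ** (1.0 / 3.0)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return center + r[:, None] * v


def _order_truth(spec: VesicleSpec, tilt_deg: float,
                 ) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Closed-form radial-mode order parameters for the planted tilt.

    With the lipid spun uniformly about its own axis before tilting, the
    spherical-harmonic addition theorem gives S(k) = P2(cos tilt) *
    P2(cos gamma_k), gamma_k being the template angle between the C-H vector
    and the molecular axis (90 degrees exactly for an all-trans chain).
    """
    tpl = spec.template
    k = tpl.n_chain
    suffix_idx = [tpl.names.index(f"C{c}A") for c in range(1, k + 1)]
    chain = tpl.offsets[suffix_idx]
    sp2 = np.zeros(k, dtype=bool)
    for c in tpl.sp2_carbons:
        sp2[c - 1] = True
    hS, hR, valid = reconstruct_ch_vectors(chain, sp2)
    p2_tilt = _p2(np.cos(np.deg2rad(tilt_deg)))
    out = {}
    for name, h in (("proS", hS), ("proR", hR)):
        cos_gamma = h[1:-1, 2]          # template molecular axis is +z
        out[name] = p2_tilt * np.array([_p2(c) for c in cos_gamma])
    return out, np.arange(2, k)


def generate(scenario: Scenario) -> tuple[list[Frame], GroundTruth]:
    """Emit the synthetic trajectory and its ground truth."""
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    box = np.asarray([sc.box, sc.box, sc.box], dtype=float)
    center = box / 2.0
    spec = sc.vesicle
    tpl = spec.template
    gas = GAS_REGISTRY[sc.species]

    # clash checking is disabled: planted tilts and deformations are
    # geometric constructions, not packings that must be feasible
    lipids = build_vesicle(spec, box, seed=sc.seed,
                           chain_tilt=np.deg2rad(sc.chain_tilt),
                           clash_tolerance=0.0)
    lipid_xyz = lipids.coordinates
    r_head_out, r_head_in = spec.headgroup_radii()
    term = lipids.name_mask(*tpl.terminal_names)
    term_r = np.linalg.norm(lipid_xyz[term] - center, axis=1)
    outer_lipid = lipids.residue_ids <= spec.n_outer
    r_term_out = float(term_r[outer_lipid[term]].mean())
    r_term_in = float(term_r[~outer_lipid[term]].mean())
    head_ext = tpl.head_extent
    half = float(box.min()) / 2.0

    r_mid = 0.5 * (r_term_in + r_term_out)
    gap_half = min(0.08, 0.45 * (r_term_out - r_term_in))
    zones = {
        "bulk": (r_head_out + head_ext + sc.margin, half - 0.8),
        "outer": (r_term_out + 0.2, r_head_out - 0.2),
        "gap": (r_mid - gap_half, r_mid + gap_half),
        "inner": (r_head_in + 0.2, r_term_in - 0.2),
        "confined": (0.0, r_head_in - head_ext - sc.margin),
    }
    needed = set()
    for _, fr in sc.gas_plan:
        needed |= {d for d, v in fr.items() if v > 0}
    for b in sc.bubbles:
        needed.add(b.compartment)
    for d in needed:
        lo, hi = zones[d]
        if hi <= lo:
            raise ValueError(
                f"scenario geometry cannot host domain {d!r}: empty sampling "
                f"zone ({lo:.2f}, {hi:.2f}) nm")

    # --- bubbles (static across frames) -------------------------------
    if sc.bubbles:
        dirs = np.array([[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0],
                         [0.0, 1.0, 0.0], [0.0, -1.0, 0.0],
                         [0.0, 0.0, 1.0], [0.0, 0.0, -1.0]])
    bubble_coords: list[np.ndarray] = []
    bubble_meta: list[dict] = []
    for i, plan in enumerate(sc.bubbles):
        bgas = GAS_REGISTRY[plan.species]
        if plan.center is not None:
            bc = np.asarray(plan.center, dtype=float)
        else:
            lo, hi = zones[plan.compartment]
            r_c = float(np.clip(lo + plan.radius + 0.2, lo, 0.5 * (lo + hi)))
            bc = center + r_c * dirs[i % len(dirs)]
        spacing = 1.05 * bgas.sigma
        pts = bc + hcp_ball(plan.radius, spacing)
        bubble_coords.append(pts)
        # expected probe-envelope volume of a close-packed droplet: the
        # space-filling volume of its lattice cells (the envelope tracks the
        # packing mid-surface), in A^3
        inflated = len(pts) * (10.0 * spacing) ** 3 / np.sqrt(2.0)
        bubble_meta.append(dict(
            compartment=plan.compartment, species=plan.species, center=bc,
            radius=plan.radius, n_atoms=len(pts),
            analytic=4.0 / 3.0 * np.pi * plan.radius ** 3, inflated=inflated))
    for i in range(len(sc.bubbles)):
        for j in range(i + 1, len(sc.bubbles)):
            d = np.linalg.norm(bubble_meta[i]["center"] - bubble_meta[j]["center"])
            if d < sc.bubbles[i].radius + sc.bubbles[j].radius + 0.2:
                raise ValueError(
                    f"planted bubbles {i} and {j} overlap; a droplet spanning "
                    "compartments has no unambiguous ground truth")

    # --- solvent lattice (sites fixed, jitter per frame) ----------------
    rad_lip = np.linalg.norm(lipid_xyz - center, axis=1)
    band = (center, float(rad_lip.min() - 0.25), float(rad_lip.max() + 0.25))
    sites = water_lattice_sites(box, lipid_xyz, sc.water_spacing,
                                radial_band=band)
    if bubble_coords:
        from scipy.spatial import cKDTree
        all_b = np.vstack(bubble_coords)
        d, _ = cKDTree(all_b).query(sites, k=1)
        sites = sites[d > 0.35]
    site_r = np.linalg.norm(sites - center, axis=1)
    n_confined_w = int((site_r < r_head_in).sum())
    n_external_w = len(sites) - n_confined_w

    # --- per-frame assembly --------------------------------------------
    n_lipid_atoms = lipids.n_atoms
    n_water_atoms = 3 * len(sites)
    gas_lo = n_lipid_atoms + n_water_atoms
    gas_slice = slice(gas_lo, gas_lo + sc.n_gas)
    bubble_truths = []
    off = gas_lo + sc.n_gas
    for meta in bubble_meta:
        bubble_truths.append(BubbleTruth(
            meta["compartment"], meta["species"], meta["center"],
            meta["radius"], meta["n_atoms"],
            slice(off, off + meta["n_atoms"]),
            meta["analytic"], meta["inflated"]))
        off += meta["n_atoms"]

    # deformation of the vesicle about its centre
    scales = np.asarray(sc.deformation, dtype=float)
    lipid_deformed = center + (lipid_xyz - center) * scales
    lipids_frame = replace_coords(lipids, lipid_deformed)

    frames: list[Frame] = []
    counts_truth = np.zeros((sc.n_frames, len(DOMAINS)), dtype=int)
    labels_truth: list[np.ndarray] = []
    for fi in range(sc.n_frames):
        t = fi * sc.dt
        fracs = _plan_fractions(sc.gas_plan, t)
        counts = _largest_remainder(fracs, sc.n_gas)
        counts_truth[fi] = counts
        gxyz = np.empty((sc.n_gas, 3))
        labels = np.empty(sc.n_gas, dtype=object)
        pos = 0
        for d, c in zip(DOMAINS, counts):
            if c == 0:
                continue
            lo, hi = zones[d]
            gxyz[pos:pos + c] = _sample_annulus(rng, c, lo, hi, center)
            labels[pos:pos + c] = d
            pos += c
        labels_truth.append(labels)

        waters = water_frame(sites, box, spec.n_outer + spec.n_inner + 1,
                             jitter=0.12 * sc.water_spacing, rng=rng)
        first_gas_resid = int(waters.residue_ids.max()) + 1 if len(sites) \
            else spec.n_outer + spec.n_inner + 1
        parts = [lipids_frame, waters]
        parts.append(_gas_part(gxyz, gas.resname, gas.mass,
                               first_gas_resid, box))
        rid = first_gas_resid + sc.n_gas
        for bc, meta in zip(bubble_coords, bubble_meta):
            bgas = GAS_REGISTRY[meta["species"]]
            parts.append(_gas_part(bc, bgas.resname, bgas.mass, rid, box))
            rid += len(bc)
        fr = concat_frames(parts)
        fr.time = t
        if sc.noise_sigma > 0:
            fr.coordinates = fr.coordinates + rng.normal(
                scale=sc.noise_sigma, size=fr.coordinates.shape)
        frames.append(fr)

    order_truth, carbons = _order_truth(spec, sc.chain_tilt)
    v_norm = float(np.prod(scales))
    a_norm = ellipsoid_area(*scales) / (4.0 * np.pi)
    applied_sph = float((v_norm ** (2.0 / 3.0)) / a_norm)

    truth = GroundTruth(
        domain_order=DOMAINS, compartment_counts=counts_truth,
        gas_labels=labels_truth, gas_slice=gas_slice, bubbles=bubble_truths,
        species=sc.species, chain_tilt_deg=sc.chain_tilt,
        order_S_true=order_truth, order_carbons=carbons,
        applied_sphericity=applied_sph,
        n_external_water=n_external_w, n_confined_water=n_confined_w,
        zone_bounds=zones)
    return frames, truth


def replace_coords(frame: Frame, coords: np.ndarray) -> Frame:
    out = frame.copy()
    out.coordinates = np.asarray(coords, dtype=float)
    return out


def _gas_part(xyz: np.ndarray, resname: str, mass: float, first_resid: int,
              box: np.ndarray) -> Frame:
    n = len(xyz)
    names = np.repeat(np.asarray([resname], dtype=object), n)
    return Frame(xyz, names, names.copy(),
                 np.arange(first_resid, first_resid + n),
                 np.full(n, mass), box)


def degrade(frames: list[Frame], drop_fraction: float, seed: int = 0,
            water_resname: str = "SOL") -> list[Frame]:
    """Randomly delete solvent molecules (never lipids or gas).

    The same residues are removed from every frame, preserving the
    constant-atom-count invariant while creating solvent density
    inhomogeneity for robustness tests.
    """
    if not (0.0 <= drop_fraction < 1.0):
        raise ValueError("drop_fraction must lie in [0, 1)")
    if drop_fraction == 0.0:
        return [fr.copy() for fr in frames]
    rng = np.random.default_rng(seed)
    first = frames[0]
    water = first.resname_mask(water_resname)
    resids = np.unique(first.residue_ids[water])
    n_drop = int(np.floor(drop_fraction * len(resids) + 0.5))
    dropped = rng.choice(resids, size=n_drop, replace=False)
    out = []
    for fr in frames:
        keep = ~(fr.resname_mask(water_resname)
                 & np.isin(fr.residue_ids, dropped))
        out.append(fr.subset(keep))
    return out
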