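"""File formats, selections, configuration and the pipeline driver.

Coordinate I/O goes through MDAnalysis (GRO, PDB, XTC/TRR); coordinates are
nm internally regardless of the source format (PDB angstroms are converted
on read).  Masses are resolved from the bundled united-atom table by
residue/atom name, since coordinate formats carry none.  Tabular outputs
are TSV with units in the headers; every pipeline run writes a provenance
record (config hash, seeds, package versions).
"""
from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .frame import Frame, validate_trajectory
from .params import GAS_REGISTRY, UA_MASSES, VDW_RADII_A

log = logging.getLogger(__name__)

__all__ = ["read_structure", "read_trajectory", "write_structure",
           "write_trajectory", "resolve_site_types", "RunConfig",
           "run_pipeline", "StageError"]

_HEAD_TYPES = {
    "CN1": "CH3", "CN2": "CH3", "CN3": "CH3", "NTM": "N",
    "CA": "CH2", "CB": "CH2", "OA": "O", "P": "P", "OB": "O", "OC": "O",
    "OD": "O", "GC1": "CH2", "GC2": "CH", "GC3": "CH2",
    "OE1": "O", "OE2": "O", "OF1": "O", "OF2": "O",
}
_GAS_RESNAMES = {g.resname for g in GAS_REGISTRY.values()}


def _chain_carbon(name: str) -> tuple[int, str] | None:
    if len(name) >= 3 and name[0] == "C" and name[-1] in "AB" \
            and name[1:-1].isdigit():
        return int(name[1:-1]), name[-1]
    return None


def resolve_site_types(frame: Frame) -> np.ndarray:
    """United-atom site type per atom, resolved from residue/atom names.

    Chain carbons are typed from residue context: C1 is the ester carbonyl,
    the highest-numbered carbon the terminal methyl, and C9/C10 of long
    (>= 14 carbon) tails the sp2 pair of the cis double bond.  Unknown atoms
    fall back to bare carbon with a logged warning.
    """
    names = frame.atom_names
    resnames = frame.residue_names
    rid = frame.residue_ids
    types = np.empty(frame.n_atoms, dtype=object)
    max_k: dict[tuple[int, str], int] = {}
    for i in range(frame.n_atoms):
        cc = _chain_carbon(str(names[i]))
        if cc:
            key = (int(rid[i]), cc[1])
            max_k[key] = max(max_k.get(key, 0), cc[0])
    warned = set()
    for i in range(frame.n_atoms):
        name = str(names[i])
        res = str(resnames[i])
        if res == "SOL":
            types[i] = "OW" if name.startswith("O") else "HW"
        elif res in _GAS_RESNAMES:
            types[i] = res
        elif name in _HEAD_TYPES:
            types[i] = _HEAD_TYPES[name]
        else:
            cc = _chain_carbon(name)
            if cc:
                k, suffix = cc
                kmax = max_k[(int(rid[i]), suffix)]
                if k == 1:
                    types[i] = "C"
                elif k == kmax:
                    types[i] = "CH3"
                elif k in (9, 10) and kmax >= 14:
                    types[i] = "CH"
                else:
                    types[i] = "CH2"
            else:
                if name not in warned:
                    log.warning("unknown atom name %r (%s); treating as bare "
                                "carbon", name, res)
                    warned.add(name)
                types[i] = "C"
    return types


def _masses_from_types(types: np.ndarray) -> np.ndarray:
    return np.array([UA_MASSES[t] for t in types])


def vdw_radii(frame: Frame) -> np.ndarray:
    """Van-der-Waals radii (angstroms) per atom for the probe volumetrics."""
    return np.array([VDW_RADII_A[t] for t in resolve_site_types(frame)])


def _cryst1_box(path: Path) -> np.ndarray | None:
    """Box lengths (angstroms) from a PDB CRYST1 record, if present."""
    if path.suffix.lower() != ".pdb":
        return None
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                return np.array([float(line[6:15]), float(line[15:24]),
                                 float(line[24:33])])
            if line.startswith("ATOM"):
                break
    return None


def _frame_from_ts(u, time_ns: float, box_A: np.ndarray | None = None) -> Frame:
    ag = u.atoms
    if u.dimensions is not None:
        box_A = np.asarray(u.dimensions[:3], dtype=np.float64)
    if box_A is None:
        raise IOError("no box information in input; a CRYST1 record or GRO "
                      "box line is required")
    fr = Frame(ag.positions.astype(np.float64) * 0.1,   # A -> nm
               np.asarray(ag.names, dtype=object),
               np.asarray(ag.resnames, dtype=object),
               np.asarray(ag.resids, dtype=np.int64),
               np.ones(len(ag)),
               box_A * 0.1,
               time_ns)
    fr.masses = _masses_from_types(resolve_site_types(fr))
    return fr


def read_structure(path: str | Path) -> Frame:
    """Read a single-frame GRO or PDB file into a Frame (nm units)."""
    import MDAnalysis as mda
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        u = mda.Universe(str(path))
    except Exception as exc:
        raise IOError(f"cannot parse {path}: {exc}") from exc
    return _frame_from_ts(u, 0.0, _cryst1_box(path))


def read_trajectory(topology: str | Path, trajectory: str | Path | None = None,
                    dt: float | None = None) -> list[Frame]:
    """Read a trajectory (multi-model PDB, or topology + XTC/TRR).

    ``dt`` (ns) overrides per-frame timestamps when the format carries none.
    A truncated trajectory raises an error naming the last good frame.
    """
    import MDAnalysis as mda
    args = [str(topology)] + ([str(trajectory)] if trajectory else [])
    try:
        u = mda.Universe(*args)
    except Exception as exc:
        raise IOError(f"cannot open trajectory {args}: {exc}") from exc
    box_A = _cryst1_box(Path(topology))
    frames: list[Frame] = []
    it = iter(u.trajectory)
    i = 0
    while True:
        try:
            ts = next(it)
        except StopIteration:
            break
        except Exception as exc:
            raise IOError(
                f"trajectory truncated or malformed after frame {i - 1} "
                f"(t = {frames[-1].time if frames else 'n/a'} ns): {exc}"
            ) from exc
        t = i * dt if dt is not None else float(ts.time) / 1000.0
        frames.append(_frame_from_ts(u, t, box_A))
        i += 1
    if not frames:
        raise IOError(f"no frames in {args}")
    validate_trajectory(frames)
    return frames


def _universe_from_frame(frame: Frame):
    import MDAnalysis as mda
    resids, res_index = np.unique(frame.residue_ids, return_inverse=True)
    # np.unique sorts; keep the original residue order of appearance
    _, first_pos = np.unique(frame.residue_ids, return_index=True)
    order = np.argsort(first_pos)
    remap = np.empty_like(order)
    remap[order] = np.arange(len(order))
    res_index = remap[res_index]
    n_res = len(resids)
    u = mda.Universe.empty(frame.n_atoms, n_residues=n_res,
                           atom_resindex=res_index, trajectory=True)
    u.add_TopologyAttr("names", [str(n) for n in frame.atom_names])
    u.add_TopologyAttr("masses", frame.masses)
    res_names = [""] * n_res
    res_ids = [0] * n_res
    for i in range(frame.n_atoms):
        res_names[res_index[i]] = str(frame.residue_names[i])
        res_ids[res_index[i]] = int(frame.residue_ids[i])
    u.add_TopologyAttr("resnames", res_names)
    u.add_TopologyAttr("resids", res_ids)
    u.dimensions = np.array([*(frame.box * 10.0), 90.0, 90.0, 90.0])
    u.atoms.positions = frame.coordinates * 10.0
    return u


def write_structure(frame: Frame, path: str | Path) -> Path:
    """Write one frame to GRO (nm, fixed columns) or PDB (angstroms)."""
    path = Path(path)
    u = _universe_from_frame(frame)
    u.atoms.write(str(path))
    return path


def write_trajectory(frames: Sequence[Frame], path: str | Path) -> Path:
    """Write a multi-frame trajectory (multi-model PDB, or XTC)."""
    import MDAnalysis as mda
    validate_trajectory(frames)
    path = Path(path)
    u = _universe_from_frame(frames[0])
    with mda.Writer(str(path), n_atoms=frames[0].n_atoms,
                    multiframe=path.suffix.lower() == ".pdb") as w:
        for fr in frames:
            u.atoms.positions = fr.coordinates * 10.0
            u.trajectory.ts.time = fr.time * 1000.0
            w.write(u.atoms)
    return path


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


STAGE_ORDER = ("density", "compartments", "shape", "bubbles", "order")


@dataclass
class RunConfig:
    """Pipeline configuration (normally loaded from YAML)."""

    outdir: str
    topology: str | None = None
    trajectory: str | None = None
    stages: list[str] = field(default_factory=list)
    seed: int = 0
    dt: float | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for key in ("topology", "trajectory"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{key} file {p} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        blob = yaml.safe_dump({
            "outdir": self.outdir, "topology": self.topology,
            "trajectory": self.trajectory, "stages": list(self.stages),
            "seed": self.seed, "dt": self.dt, "params": self.params,
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


def _gas_resnames_present(frame: Frame) -> list[str]:
    present = set(map(str, np.unique(np.asarray(frame.residue_names, dtype="U8"))))
    return [r for r in sorted(_GAS_RESNAMES) if r in present]


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the requested stages in dependency order.

    Outputs are TSV/JSON files under ``config.outdir`` plus a provenance
    record; a stage failure aborts with the stage named, keeping whatever
    was already written.
    """
    from . import bubbles as bubbles_mod
    from . import compartments as comp_mod
    from . import orderparams as order_mod
    from . import profiles as prof_mod
    from . import shape as shape_mod

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    frames: list[Frame] = []
    if config.topology:
        frames = read_trajectory(config.topology, config.trajectory,
                                 dt=config.dt)
    elif config.stages:
        raise ValueError("stages requested but no input topology given")

    stages = [s for s in STAGE_ORDER if s in config.stages]
    for stage in stages:
        p = dict(config.params.get(stage, {}))
        t0 = _time.perf_counter()
        try:
            if stage == "density":
                first = frames[0]
                half = float(min(fr.box.min() for fr in frames)) / 2.0
                r_max = p.pop("r_max", min(20.0, half))
                sels = {"DOPC": first.resname_mask("DOPC")}
                if first.resname_mask("SOL").any():
                    sels["water"] = first.resname_mask("SOL")
                for g in _gas_resnames_present(first):
                    sels[g] = first.resname_mask(g)
                prof = prof_mod.radial_density(frames, sels, r_max=r_max, **p)
                df = pd.DataFrame({"bin_center_nm": prof.bin_centers})
                for name, dens in prof.density.items():
                    df[f"{name}_kg_m3"] = dens
                path = outdir / "radial_density.tsv"
                df.to_csv(path, sep="\t", index=False)
                outputs[stage] = path
            elif stage == "compartments":
                rows = []
                for g in _gas_resnames_present(frames[0]):
                    series = comp_mod.percolation_series(
                        frames, gas_resname=g, **p)
                    df = series.to_frame()
                    df.insert(0, "species", g)
                    rows.append(df)
                path = outdir / "compartments.tsv"
                pd.concat(rows).to_csv(path, sep="\t", index=False)
                outputs[stage] = path
            elif stage == "shape":
                fr = frames[-1]
                mask = fr.resname_mask("DOPC")
                rad = vdw_radii(fr)[mask]
                rep = shape_mod.shape_report(
                    fr.coordinates[mask] * 10.0, rad,
                    probe_radius=p.pop("probe", 1.4),
                    grid_spacing=p.pop("spacing", 1.0))
                path = outdir / "shape.json"
                path.write_text(json.dumps({
                    "volume_A3": rep.volume, "area_A2": rep.area,
                    "sphericity": rep.sphericity,
                    "effective_radius_A": rep.effective_radius,
                    "probe_radius_A": rep.probe_radius,
                    "grid_spacing_A": rep.grid_spacing}, indent=2))
                outputs[stage] = path
            elif stage == "bubbles":
                fr = frames[-1]
                model = comp_mod.CompartmentModel.from_frame(fr)
                tables = []
                for g in _gas_resnames_present(fr):
                    species = next(s for s, gg in GAS_REGISTRY.items()
                                   if gg.resname == g)
                    clusters = bubbles_mod.cluster_gas(fr, species)
                    _, table = bubbles_mod.condensed_volumes(
                        fr, clusters, model, species,
                        grid_spacing=p.get("spacing", 0.5),
                        min_size=p.get("min_size", 2))
                    table.insert(0, "species", species)
                    tables.append(table)
                path = outdir / "bubbles.tsv"
                pd.concat(tables).to_csv(path, sep="\t")
                outputs[stage] = path
            elif stage == "order":
                rows = []
                for leaflet in ("outer", "inner"):
                    for chain in ("sn1", "sn2"):
                        prof = order_mod.order_profile(
                            frames, leaflet, chain,
                            director_mode=p.get("director", "lab_z"),
                            window=p.get("window"))
                        rows.append(pd.DataFrame({
                            "leaflet": leaflet, "chain": chain,
                            "carbon": prof.carbons,
                            "S_proS": prof.S_proS, "S_proR": prof.S_proR}))
                path = outdir / "order_parameters.tsv"
                pd.concat(rows).to_csv(path, sep="\t", index=False)
                outputs[stage] = path
        except Exception as exc:
            raise StageError(stage, exc) from exc
        log.info("stage %s: %d frames in, %.2f s", stage, len(frames),
                 _time.perf_counter() - t0)

    prov = {
        "config_sha256": config.digest(),
        "seed": config.seed,
        "package_version": _pkg_version,
        "numpy_version": np.__version__,
        "stages_completed": [s for s in stages if s in outputs],
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    prov_path = outdir / "provenance.json"
    prov_path.write_text(json.dumps(prov, indent=2))
    outputs["provenance"] = prov_path
    return outputs
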