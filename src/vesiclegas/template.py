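"""Idealised united-atom phosphatidylcholine template.

The template places one lipid with its phosphorus at the origin and the
headgroup pointing along +z.  The two acyl chains run along -z as planar
zig-zags with a constant 0.153 nm C-C bond; the axial rise per carbon is a
parameter so that long chains can be built at the shorter effective length
of fluid-phase tails (an all-trans 18-carbon chain would be too long to fit
two opposing monolayers inside a vesicle of realistic radius).  A cis double
bond between chain carbons 9 and 10 is modelled as a shortened 0.133 nm
bond; it marks those carbons as sp2 for the order-parameter machinery,
which detects them geometrically by bond length.

Atom naming: headgroup CN1-CN3/NTM/CA/CB (choline), OA/P/OB/OC/OD
(phosphate), GC1-GC3 (glycerol), OE1/OE2 (ester oxygens), OF1/OF2 (carbonyl
oxygens) and chain carbons C1A..CnA (sn-1) / C1B..CnB (sn-2), where C1 is
the ester carbonyl carbon and Cn the terminal methyl.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import UA_MASSES

__all__ = ["LipidTemplate", "dopc_template"]

BOND_CC = 0.153      # nm
BOND_CC_SP2 = 0.133  # nm
TETRAHEDRAL_RISE = BOND_CC * np.cos(np.deg2rad(35.264))  # all-trans rise per carbon


@dataclass(frozen=True)
class LipidTemplate:
    resname: str
    names: tuple[str, ...]
    types: tuple[str, ...]
    offsets: np.ndarray          # (n, 3) nm, phosphorus at origin, head along +z
    n_chain: int
    sp2_carbons: tuple[int, ...]  # chain carbon indices that are sp2 (both chains)
    terminal_names: tuple[str, ...]
    phosphorus_name: str = "P"

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def masses(self) -> np.ndarray:
        return np.array([UA_MASSES[t] for t in self.types])

    @property
    def head_extent(self) -> float:
        """Extent of the headgroup above the phosphorus anchor (nm)."""
        return float(self.offsets[:, 2].max())

    @property
    def tail_extent(self) -> float:
        """Extent of the tails below the phosphorus anchor (nm)."""
        return float(-self.offsets[:, 2].min())

    def chain_names(self, chain: str) -> list[str]:
        suffix = {"sn1": "A", "sn2": "B"}[chain]
        return [f"C{k}{suffix}" for k in range(1, self.n_chain + 1)]

    def anchor_index(self) -> int:
        return self.names.index(self.phosphorus_name)


def _zigzag_chain(start: np.ndarray, n: int, rise: float,
                  sp2_bond: int | None) -> np.ndarray:
    """Planar zig-zag along -z starting at ``start`` (carbon 1).

    ``sp2_bond`` is the 1-based index k such that the bond C_k -> C_{k+1}
    is the shortened cis double bond.
    """
    amp = np.sqrt(BOND_CC**2 - rise**2) / 2.0
    pos = np.empty((n, 3))
    pos[0] = start
    y_sign = 1.0
    for k in range(1, n):
        step = np.array([0.0, y_sign * 2.0 * amp, -rise])
        if sp2_bond is not None and k == sp2_bond:
            step *= BOND_CC_SP2 / BOND_CC
        pos[k] = pos[k - 1] + step
        y_sign = -y_sign
    return pos


def dopc_template(n_chain: int = 18, cis_bond: bool | None = None,
                  rise: float | None = None) -> LipidTemplate:
    """Build a united-atom PC lipid with two ``n_chain``-carbon tails.

    ``cis_bond`` defaults to True for chains long enough to carry the C9=C10
    double bond of an oleoyl tail.  ``rise`` is the axial advance per chain
    carbon; the default (0.095 nm for long chains, the all-trans value for
    short ones) keeps an 18-carbon monolayer near its fluid-phase thickness.
    """
    if n_chain < 3:
        raise ValueError("chains need at least 3 carbons")
    if cis_bond is None:
        cis_bond = n_chain >= 14
    if cis_bond and n_chain < 11:
        raise ValueError("cis C9=C10 bond requires at least 11 chain carbons")
    if rise is None:
        rise = 0.095 if n_chain >= 14 else float(TETRAHEDRAL_RISE)
    if not (0.05 < rise < BOND_CC):
        raise ValueError("rise must lie between 0.05 nm and the bond length")

    names: list[str] = []
    types: list[str] = []
    offsets: list[np.ndarray] = []

    def add(name: str, typ: str, xyz: tuple[float, float, float]) -> None:
        names.append(name)
        types.append(typ)
        offsets.append(np.array(xyz))

    # choline + phosphate, compact stack above the phosphorus anchor
    add("CN1", "CH3", (0.07, 0.07, 0.62))
    add("CN2", "CH3", (-0.10, 0.02, 0.62))
    add("CN3", "CH3", (0.03, -0.10, 0.62))
    add("NTM", "N", (0.00, 0.00, 0.52))
    add("CA", "CH2", (0.00, 0.05, 0.39))
    add("CB", "CH2", (0.00, -0.02, 0.26))
    add("OA", "O", (0.00, 0.05, 0.13))
    add("P", "P", (0.00, 0.00, 0.00))
    add("OB", "O", (0.13, 0.00, 0.06))
    add("OC", "O", (-0.13, 0.00, 0.06))
    add("OD", "O", (0.00, 0.00, -0.13))
    # glycerol backbone and ester linkage
    add("GC1", "CH2", (0.02, 0.00, -0.26))
    add("GC2", "CH", (0.00, 0.05, -0.39))
    add("GC3", "CH2", (0.12, 0.00, -0.50))
    add("OE1", "O", (-0.11, 0.00, -0.47))
    add("OE2", "O", (0.22, 0.00, -0.60))
    add("OF1", "O", (-0.17, 0.03, -0.58))
    add("OF2", "O", (0.22, 0.06, -0.69))

    sp2_bond = 9 if cis_bond else None
    sp2 = (9, 10) if cis_bond else ()
    chain_a = _zigzag_chain(np.array([-0.125, 0.0, -0.55]), n_chain, rise, sp2_bond)
    chain_b = _zigzag_chain(np.array([0.125, 0.0, -0.65]), n_chain, rise, sp2_bond)
    for suffix, chain in (("A", chain_a), ("B", chain_b)):
        for k in range(n_chain):
            idx = k + 1
            if idx == 1:
                typ = "C"            # ester carbonyl carbon
            elif idx == n_chain:
                typ = "CH3"          # terminal methyl
            elif idx in sp2:
                typ = "CH"           # sp2 CH at the double bond
            else:
                typ = "CH2"
            add(f"C{idx}{suffix}", typ, tuple(chain[k]))

    return LipidTemplate(
        resname="DOPC",
        names=tuple(names),
        types=tuple(types),
        offsets=np.array(offsets),
        n_chain=n_chain,
        sp2_carbons=sp2,
        terminal_names=(f"C{n_chain}A", f"C{n_chain}B"),
    )
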