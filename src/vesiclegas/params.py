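"""Physical parameter registry: gas Lennard-Jones sites, united-atom masses
and van-der-Waals radii used by the volumetric probe."""
from __future__ import annotations

from dataclasses import dataclass

__all__ = ["GasSpec", "GAS_REGISTRY", "UA_MASSES", "VDW_RADII_A", "vdw_radius_A"]


@dataclass(frozen=True)
class GasSpec:
    """A noble-gas species modelled as a single Lennard-Jones site.

    epsilon in kJ/mol, sigma in nm.  ``molar_fraction`` is the dissolved gas
    fraction of the total solvent+gas molecule count; ``n_atoms`` overrides
    the derived count when set (the two conventions in circulation do not
    always agree, so both are constructible).
    """

    species: str
    epsilon: float
    sigma: float
    molar_fraction: float = 0.015
    n_atoms: int | None = None

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.sigma <= 0:
            raise ValueError("epsilon and sigma must be positive")
        if not (0.0 <= self.molar_fraction < 1.0):
            raise ValueError("molar_fraction must be in [0, 1)")
        if self.n_atoms is not None and self.n_atoms < 0:
            raise ValueError("n_atoms must be non-negative")

    @property
    def resname(self) -> str:
        return self.species[:2].upper()

    @property
    def mass(self) -> float:
        return GAS_MASSES[self.species]

    def with_fraction(self, molar_fraction: float | None = None,
                      n_atoms: int | None = None) -> "GasSpec":
        return GasSpec(self.species, self.epsilon, self.sigma,
                       self.molar_fraction if molar_fraction is None else molar_fraction,
                       n_atoms)


# LJ parameters for the four noble gases (kJ/mol, nm)
GAS_REGISTRY: dict[str, GasSpec] = {
    "helium": GasSpec("helium", 0.084, 0.256),
    "neon": GasSpec("neon", 0.289, 0.278),
    "argon": GasSpec("argon", 0.979, 0.340),
    "xenon": GasSpec("xenon", 1.900, 0.406),
}

GAS_MASSES = {"helium": 4.0026, "neon": 20.1797, "argon": 39.948, "xenon": 131.293}

# united-atom masses (u) keyed by site type
UA_MASSES = {
    "CH3": 15.0350,
    "CH2": 14.0270,
    "CH": 13.0190,
    "C": 12.0110,
    "N": 14.0067,
    "P": 30.9738,
    "O": 15.9994,
    "OW": 15.9994,
    "HW": 1.0080,
    "HE": GAS_MASSES["helium"],
    "NE": GAS_MASSES["neon"],
    "AR": GAS_MASSES["argon"],
    "XE": GAS_MASSES["xenon"],
}

# van-der-Waals radii in angstroms for the probe volumetrics
# (united-atom carbon sites share the bare-carbon radius; gases use sigma/2)
VDW_RADII_A = {
    "C": 1.880, "CH": 1.880, "CH2": 1.880, "CH3": 1.880,
    "N": 1.625, "O": 1.480, "P": 1.871,
    "OW": 1.480, "HW": 0.000,
    "HE": GAS_REGISTRY["helium"].sigma * 5.0,   # sigma/2 in nm -> A
    "NE": GAS_REGISTRY["neon"].sigma * 5.0,
    "AR": GAS_REGISTRY["argon"].sigma * 5.0,
    "XE": GAS_REGISTRY["xenon"].sigma * 5.0,
}


def vdw_radius_A(site_type: str) -> float:
    """Radius in angstroms for a united-atom site type."""
    try:
        return VDW_RADII_A[site_type]
    except KeyError:
        raise KeyError(f"no van-der-Waals radius for site type {site_type!r}") from None
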