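"""Vesicle construction: radii, packing, orientation, gas insertion."""
import numpy as np
import pytest

import vesiclegas as vg
from vesiclegas.builder import gas_count
from vesiclegas.template import dopc_template


class TestVesicleSpec:
    def test_headgroup_radii_from_area_per_lipid(self, full_scale_spec):
        # closed-form sphere-area inversion: R = sqrt(N a / 4 pi)
        r_out, r_in = full_scale_spec.headgroup_radii()
        assert r_out == pytest.approx(9.477, abs=5e-4)
        assert r_in == pytest.approx(4.438, abs=5e-4)

    def test_equal_density_radius_ratio(self):
        # n = N/S equal on both headgroup spheres -> R ratio sqrt(1188/495)
        spec = vg.VesicleSpec.from_reference_density(1.0, 1188, 495)
        r_out, r_in = spec.headgroup_radii()
        assert r_out / r_in == pytest.approx(np.sqrt(1188 / 495), rel=1e-12)

    @pytest.mark.parametrize("kwargs", [
        dict(n_outer=0, n_inner=10),
        dict(n_outer=10, n_inner=-1),
        dict(n_outer=10, n_inner=10, apl_outer=0.4, apl_inner=0.5),
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            vg.VesicleSpec(**kwargs)


class TestAreaPerLipid:
    @pytest.mark.parametrize("monolayer,r,expected", [
        ("outer", 9.476873661010604, 0.95),
        ("inner", 4.437952704527398, 0.50),
    ])
    def test_reconstructs_spec_apl_at_headgroup_radius(
            self, full_scale_spec, monolayer, r, expected):
        apl = vg.area_per_lipid_at(full_scale_spec, monolayer, r)
        assert apl == pytest.approx(expected, rel=1e-3)

    def test_unit_area_single_lipid(self):
        spec = vg.VesicleSpec(1, 1, 1.0, 0.2,
                              template=dopc_template(n_chain=6, cis_bond=False))
        r = 1.0 / np.sqrt(4.0 * np.pi)
        assert vg.area_per_lipid_at(spec, "outer", r) == pytest.approx(1.0)

    def test_unknown_monolayer_rejected(self, full_scale_spec):
        with pytest.raises(ValueError, match="monolayer"):
            vg.area_per_lipid_at(full_scale_spec, "middle", 5.0)


class TestBuildVesicle:
    def test_reconstruction_consistency(self, reduced_spec, reduced_vesicle):
        # area_per_lipid_at evaluated at the built headgroup radii must
        # reproduce the spec values to < 0.1%
        center = reduced_vesicle.center_of_mass(
            reduced_vesicle.resname_mask("DOPC"))
        p = reduced_vesicle.name_mask("P")
        radii = np.linalg.norm(reduced_vesicle.coordinates[p] - center, axis=1)
        outer = reduced_vesicle.residue_ids[p] <= reduced_spec.n_outer
        r_out, r_in = radii[outer].mean(), radii[~outer].mean()
        assert vg.area_per_lipid_at(reduced_spec, "outer", r_out) == \
            pytest.approx(reduced_spec.apl_outer, rel=1e-3)
        assert vg.area_per_lipid_at(reduced_spec, "inner", r_in) == \
            pytest.approx(reduced_spec.apl_inner, rel=1e-3)

    def test_determinism(self, reduced_spec):
        a = vg.build_vesicle(reduced_spec, 18.0, seed=42, anchor_jitter=0.02)
        b = vg.build_vesicle(reduced_spec, 18.0, seed=42, anchor_jitter=0.02)
        assert np.array_equal(a.coordinates, b.coordinates)

    def test_lipids_oriented_radially(self, reduced_spec, reduced_vesicle):
        # head-to-tail axis of every lipid along +- its radial unit vector
        fr = reduced_vesicle
        center = fr.box / 2.0
        tpl = reduced_spec.template
        n_at = tpl.n_atoms
        coords = fr.coordinates.reshape(-1, n_at, 3)
        p_i = tpl.anchor_index()
        cn = tpl.names.index("CN1")
        tail = tpl.names.index(tpl.terminal_names[0])
        axis = coords[:, cn] - coords[:, tail]
        axis /= np.linalg.norm(axis, axis=1, keepdims=True)
        rad = coords[:, p_i] - center
        rad /= np.linalg.norm(rad, axis=1, keepdims=True)
        # template head atoms are slightly off-axis, hence the 0.99 bound
        assert np.abs((axis * rad).sum(axis=1)).min() > 0.99

    def test_single_lipid_per_monolayer(self):
        tpl = dopc_template(n_chain=6, cis_bond=False)
        spec = vg.VesicleSpec(1, 1, 300.0, 6.0, template=tpl)
        fr = vg.build_vesicle(spec, 16.0, seed=0)
        assert fr.n_atoms == 2 * tpl.n_atoms

    def test_full_scale_packs_without_clashes(self, full_scale_vesicle):
        assert full_scale_vesicle.n_atoms == (1188 + 495) * 54

    def test_infeasible_packing_names_monolayer(self):
        tpl = dopc_template(n_chain=6, cis_bond=False)
        spec = vg.VesicleSpec(400, 100, 0.30, 0.30, template=tpl)
        with pytest.raises(vg.PackingError, match="outer"):
            vg.build_vesicle(spec, 18.0, seed=0)

    def test_box_too_small_rejected(self, full_scale_spec):
        with pytest.raises(ValueError, match="box"):
            vg.build_vesicle(full_scale_spec, 12.0, seed=0)


class TestGasInsertion:
    def test_count_rule_and_override(self):
        # round(fraction x molecules), or the explicit override
        assert gas_count(0.015, 352_928) == 5294
        assert gas_count(0.015, 352_928, n_atoms=5513) == 5513
        assert gas_count(0.5, 10) == 5
        assert gas_count(0.0, 1000) == 0

    def test_zero_fraction_inserts_no_gas(self, reduced_vesicle):
        gas = vg.GAS_REGISTRY["argon"].with_fraction(0.0)
        res = vg.solvate_and_insert_gas(reduced_vesicle, 500, gas, seed=0)
        assert res.n_gas == 0
        assert res.n_waters == 500
        assert not res.frame.resname_mask("AR").any()

    def test_total_molecule_count_preserved(self, reduced_vesicle):
        gas = vg.GAS_REGISTRY["neon"].with_fraction(0.10)
        res = vg.solvate_and_insert_gas(reduced_vesicle, 800, gas, seed=3)
        assert res.n_waters + res.n_gas == 800
        assert res.frame.resname_mask("NE").sum() == res.n_gas
        assert len(res.replaced_site_indices) == res.n_gas

    def test_gas_exceeding_waters_rejected(self, reduced_vesicle):
        gas = vg.GAS_REGISTRY["argon"].with_fraction(0.0).with_fraction(
            n_atoms=50)
        with pytest.raises(ValueError, match="exceeds"):
            vg.solvate_and_insert_gas(reduced_vesicle, 20, gas, seed=0)

    def test_insertion_deterministic(self, reduced_vesicle):
        gas = vg.GAS_REGISTRY["xenon"].with_fraction(0.05)
        a = vg.solvate_and_insert_gas(reduced_vesicle, 400, gas, seed=9)
        b = vg.solvate_and_insert_gas(reduced_vesicle, 400, gas, seed=9)
        assert np.array_equal(a.frame.coordinates, b.frame.coordinates)
        assert np.array_equal(a.replaced_site_indices, b.replaced_site_indices)


class TestGasRegistry:
    def test_lennard_jones_parameters(self):
        # epsilon kJ/mol, sigma nm for the four species
        expected = {"helium": (0.084, 0.256), "neon": (0.289, 0.278),
                    "argon": (0.979, 0.340), "xenon": (1.900, 0.406)}
        for species, (eps, sig) in expected.items():
            g = vg.GAS_REGISTRY[species]
            assert (g.epsilon, g.sigma) == (eps, sig)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            vg.GasSpec("argon", 0.979, 0.340, molar_fraction=1.5)
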