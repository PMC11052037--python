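"""Prochiral hydrogen reconstruction and order-parameter estimation."""
import numpy as np
import pytest

import vesiclegas as vg
from vesiclegas.orderparams import reconstruct_ch_vectors
from vesiclegas.template import dopc_template


def _random_chain(rng, k=10):
    """Random non-collinear chain with 0.153 nm bonds."""
    pos = [np.zeros(3)]
    d = np.array([0.0, 0.0, -1.0])
    for _ in range(k - 1):
        step = d + rng.normal(scale=0.6, size=3)
        step /= np.linalg.norm(step)
        pos.append(pos[-1] + 0.153 * step)
    return np.asarray(pos)


class TestReconstructHydrogens:
    def test_all_trans_hydrogens_perpendicular_to_axis(self):
        tpl = dopc_template(n_chain=8, cis_bond=False)
        idx = [tpl.names.index(n) for n in tpl.chain_names("sn1")]
        chain = tpl.offsets[idx]
        hs = vg.reconstruct_hydrogens(chain)
        for ph in hs:
            assert abs(ph.h_proS[2]) < 1e-10
            assert abs(ph.h_proR[2]) < 1e-10

    def test_hch_angle_is_tetrahedral(self):
        # property over random valid chains: H-C-H = 109.47 +- 0.01 deg
        rng = np.random.default_rng(5)
        for _ in range(50):
            chain = _random_chain(rng)
            for ph in vg.reconstruct_hydrogens(chain):
                ang = np.degrees(np.arccos(np.dot(ph.h_proS, ph.h_proR)))
                assert ang == pytest.approx(109.471, abs=0.01)
                assert np.linalg.norm(ph.h_proS) == pytest.approx(1.0)
                assert np.linalg.norm(ph.h_proR) == pytest.approx(1.0)

    def test_hydrogens_consistent_with_tetrahedral_backbone(self):
        # on an ideal tetrahedral chain the H-C-C angles are tetrahedral too
        tpl = dopc_template(n_chain=8, cis_bond=False)
        idx = [tpl.names.index(n) for n in tpl.chain_names("sn2")]
        chain = tpl.offsets[idx]
        hs = vg.reconstruct_hydrogens(chain)
        for ph in hs:
            i = ph.carbon - 1
            for j in (i - 1, i + 1):
                b = chain[j] - chain[i]
                b /= np.linalg.norm(b)
                ang = np.degrees(np.arccos(np.clip(np.dot(ph.h_proS, b),
                                                   -1, 1)))
                assert ang == pytest.approx(109.47, abs=0.5)

    def test_mirror_image_swaps_prochiral_labels(self):
        rng = np.random.default_rng(8)
        chain = _random_chain(rng)
        mirrored = chain * np.array([1.0, 1.0, -1.0])
        hs = vg.reconstruct_hydrogens(chain)
        hs_m = vg.reconstruct_hydrogens(mirrored)
        flip = np.array([1.0, 1.0, -1.0])
        for a, b in zip(hs, hs_m):
            assert np.allclose(a.h_proS * flip, b.h_proR, atol=1e-12)
            assert np.allclose(a.h_proR * flip, b.h_proS, atol=1e-12)

    def test_sp2_carbons_get_single_inplane_hydrogen(self):
        tpl = dopc_template(n_chain=18, cis_bond=True)
        idx = [tpl.names.index(n) for n in tpl.chain_names("sn1")]
        chain = tpl.offsets[idx]
        hs = vg.reconstruct_hydrogens(chain, sp2_carbons=tpl.sp2_carbons)
        by_carbon = {ph.carbon: ph for ph in hs}
        for c in (9, 10):
            ph = by_carbon[c]
            assert ph.sp2
            assert np.allclose(ph.h_proS, ph.h_proR)
            # in-plane: perpendicular to the local C-C-C plane normal
            d1 = chain[c - 2] - chain[c - 1]
            d2 = chain[c] - chain[c - 1]
            normal = np.cross(d1, d2)
            normal /= np.linalg.norm(normal)
            assert abs(np.dot(ph.h_proS, normal)) < 1e-10

    def test_collinear_chain_rejected(self):
        chain = np.array([[0, 0, 0], [0, 0, -0.153], [0, 0, -0.306]])
        with pytest.raises(ValueError, match="collinear"):
            vg.reconstruct_hydrogens(chain)

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError, match="three"):
            vg.reconstruct_hydrogens(np.zeros((2, 3)))


class TestOrderProfile:
    def test_parallel_and_perpendicular_limits(self):
        # S = 1 when C-H is parallel to the director, -0.5 when perpendicular
        hS = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        z = np.array([0.0, 0.0, 1.0])
        s = 1.5 * (hS @ z) ** 2 - 0.5
        assert s[0] == pytest.approx(1.0)
        assert s[1] == pytest.approx(-0.5)

    def test_planted_tilt_recovered_in_radial_mode(self, tilted_scenario_run):
        _, frames, truth = tilted_scenario_run
        for leaflet in ("outer", "inner"):
            for chain in ("sn1", "sn2"):
                prof = vg.order_profile(frames, leaflet, chain,
                                        director_mode="radial")
                assert prof.S_proS == pytest.approx(
                    truth.order_S_true["proS"], abs=0.005)
                assert prof.S_proR == pytest.approx(
                    truth.order_S_true["proR"], abs=0.005)

    def test_magic_angle_tilt_gives_zero(self):
        sc = vg.Scenario(n_frames=1, n_gas=5, chain_tilt=54.7356, seed=2)
        frames, truth = vg.generate(sc)
        assert np.abs(truth.order_S_true["proS"]).max() < 1e-6
        prof = vg.order_profile(frames, "outer", "sn1",
                                director_mode="radial")
        assert np.abs(prof.S_proS).max() < 0.005

    def test_bounds_respected(self, tilted_scenario_run):
        _, frames, _ = tilted_scenario_run
        for mode in ("lab_z", "radial"):
            prof = vg.order_profile(frames, "outer", "sn1",
                                    director_mode=mode)
            assert (prof.S_proS >= -0.5 - 1e-9).all()
            assert (prof.S_proS <= 1.0 + 1e-9).all()

    def test_isotropic_chains_give_null_lab_signal(self):
        # uniformly oriented radial chains on a sphere average to ~0 in the
        # laboratory frame while the radial mode stays strongly negative
        sc = vg.Scenario(n_frames=1, n_gas=5, seed=4)
        frames, _ = vg.generate(sc)
        lab = vg.order_profile(frames, "outer", "sn1", director_mode="lab_z")
        rad = vg.order_profile(frames, "outer", "sn1", director_mode="radial")
        assert np.abs(lab.S_proS).max() < 0.05
        assert np.abs(lab.S_proS).max() < np.abs(rad.S_proS).min()
        assert rad.S_proS == pytest.approx(-0.5, abs=1e-6)

    def test_window_selection_and_errors(self, tilted_scenario_run):
        _, frames, _ = tilted_scenario_run
        prof = vg.order_profile(frames, "outer", "sn1",
                                window=(0.0, frames[-1].time))
        assert prof.window == (0.0, frames[-1].time)
        with pytest.raises(ValueError, match="window"):
            vg.order_profile(frames, "outer", "sn1", window=(100.0, 120.0))

    def test_carbonyl_excluded_terminal_unreported(self, tilted_scenario_run):
        sc, frames, _ = tilted_scenario_run
        k = sc.vesicle.template.n_chain
        prof = vg.order_profile(frames, "outer", "sn1")
        assert prof.carbons[0] == 2
        assert prof.carbons[-1] == k - 1


class TestLeafletSplit:
    def test_built_vesicle_splits_exactly(self, full_scale_vesicle):
        outer, inner = vg.leaflet_split(full_scale_vesicle)
        assert (len(outer), len(inner)) == (1188, 495)

    def test_boundary_tie_goes_outer(self, reduced_vesicle):
        from vesiclegas.geometry import leaflet_resids_by_threshold
        resids = np.array([1, 2, 3])
        radii = np.array([5.0, 3.0, 4.0])
        outer, inner = leaflet_resids_by_threshold(resids, radii, 4.0)
        assert 3 in outer and 2 in inner

    def test_flipped_lipid_follows_its_headgroup(self, reduced_spec,
                                                 reduced_vesicle):
        # plant one outer lipid with its phosphorus moved inside the inner
        # headgroup sphere: the split must follow the headgroup, not the tail
        fr = reduced_vesicle.copy()
        tpl = reduced_spec.template
        center = fr.box / 2
        p_mask = (fr.residue_ids == 1) & fr.name_mask("P")
        i = int(np.flatnonzero(p_mask)[0])
        direction = fr.coordinates[i] - center
        direction /= np.linalg.norm(direction)
        _, r_in = reduced_spec.headgroup_radii()
        fr.coordinates[i] = center + direction * (r_in - 0.4)
        outer, inner = vg.leaflet_split(fr)
        assert 1 in inner
        assert len(inner) == reduced_spec.n_inner + 1
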