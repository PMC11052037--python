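"""Five-domain gas classification: oracle equivalence, conservation,
water splitting and percolation series."""
import numpy as np
import pytest
from scipy.spatial import distance_matrix

import vesiclegas as vg
from vesiclegas.compartments import (DOMAINS, CompartmentModel, classify_gas,
                                     percolation_series, split_water)
from vesiclegas.frame import Frame

_PRIORITY = ("gap", "inner", "outer", "confined", "bulk")


def brute_force_classify(gas_xyz, model):
    """Exhaustive all-pairs nearest-reference classifier (the oracle).

    Every gas-reference distance is evaluated explicitly with the
    minimum-image formula; no spatial data structure is involved.
    """
    box = model.box
    n = len(gas_xyz)
    best_d = np.full(n, np.inf)
    best_dom = np.empty(n, dtype=object)
    for dom in _PRIORITY:              # first strict win = tie priority
        ref = model.references.get(dom)
        if ref is None or len(ref) == 0:
            continue
        delta = np.abs(gas_xyz[:, None, :] - ref[None, :, :])
        delta = np.minimum(delta, box - delta)       # minimum image
        d = np.sqrt((delta ** 2).sum(axis=2)).min(axis=1)
        better = d < best_d - 1e-15
        best_d[better] = d[better]
        best_dom[better] = dom
    labels = best_dom.copy()
    far = best_d > model.cutoff
    if far.any():
        r = np.linalg.norm(gas_xyz[far] - model.center, axis=1)
        labels[far] = model.fallback_domain(r)
    return labels


def _random_model_and_gas(rng, n_gas=200):
    box = np.array([12.0, 12.0, 12.0])
    refs = {}
    sizes = rng.integers(5, 40, size=5)
    for dom, m in zip(DOMAINS, sizes):
        refs[dom] = rng.random((m, 3)) * box
    model = CompartmentModel(refs, cutoff=1.0, center=box / 2.0,
                             zone_radii={"head_outer": 4.0, "term_outer": 3.0,
                                         "term_inner": 2.0, "head_inner": 1.0},
                             box=box)
    gas = rng.random((n_gas, 3)) * box
    return model, gas


def _gas_frame(gas_xyz, box):
    n = len(gas_xyz)
    names = np.repeat(np.asarray(["AR"], dtype=object), n)
    return Frame(gas_xyz, names, names.copy(), np.arange(1, n + 1),
                 np.full(n, 39.948), box)


class TestClassifyOracle:
    def test_matches_brute_force_on_many_random_frames(self):
        # cell-list/KD-tree classifier vs exhaustive all-pairs, 1000 frames
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            model, gas = _random_model_and_gas(rng, n_gas=200)
            fr = _gas_frame(gas, model.box)
            fast = classify_gas(fr, model)
            slow = brute_force_classify(gas, model)
            assert np.array_equal(fast, slow)

    def test_gap_contact_wins_over_distant_references(self):
        box = np.array([10.0, 10.0, 10.0])
        refs = {"gap": np.array([[5.0, 5.0, 5.3]]),
                "bulk": np.array([[5.0, 5.0, 6.9]])}
        model = CompartmentModel(refs, 1.0, box / 2,
                                 {"head_outer": 4.0, "term_outer": 3.0,
                                  "term_inner": 2.0, "head_inner": 1.0}, box)
        fr = _gas_frame(np.array([[5.0, 5.0, 5.0]]), box)
        assert classify_gas(fr, model)[0] == "gap"

    def test_tie_breaks_by_domain_priority(self):
        box = np.array([10.0, 10.0, 10.0])
        # equidistant gap and bulk references: gap is the more local call
        refs = {"bulk": np.array([[5.0, 5.0, 5.5]]),
                "gap": np.array([[5.0, 5.0, 4.5]])}
        model = CompartmentModel(refs, 1.0, box / 2,
                                 {"head_outer": 4.0, "term_outer": 3.0,
                                  "term_inner": 2.0, "head_inner": 1.0}, box)
        fr = _gas_frame(np.array([[5.0, 5.0, 5.0]]), box)
        assert classify_gas(fr, model)[0] == "gap"

    def test_fallback_radial_zones_are_total(self):
        box = np.array([20.0, 20.0, 20.0])
        refs = {d: np.empty((0, 3)) for d in DOMAINS}
        refs["bulk"] = np.array([[1.0, 1.0, 1.0]])
        model = CompartmentModel(refs, 1.0, box / 2,
                                 {"head_outer": 6.0, "term_outer": 4.5,
                                  "term_inner": 3.5, "head_inner": 2.0}, box)
        radii = np.array([0.5, 3.0, 4.0, 5.0, 8.0])
        gas = box / 2 + np.column_stack([radii, np.zeros(5), np.zeros(5)])
        labels = classify_gas(_gas_frame(gas, box), model)
        assert list(labels) == ["confined", "inner", "gap", "outer", "bulk"]

    def test_minimum_image_distances(self):
        box = np.array([10.0, 10.0, 10.0])
        refs = {"bulk": np.array([[9.9, 5.0, 5.0]])}
        model = CompartmentModel(refs, 1.0, box / 2,
                                 {"head_outer": 1.0, "term_outer": 0.8,
                                  "term_inner": 0.5, "head_inner": 0.2}, box)
        # neighbour across the periodic boundary, 0.2 nm away
        fr = _gas_frame(np.array([[0.1, 5.0, 5.0]]), box)
        assert classify_gas(fr, model)[0] == "bulk"

    def test_enlarging_cutoff_never_flips_lipid_domain_to_bulk(
            self, schedule_scenario_run):
        # on a vesicle with isolated reference shells, a wider contact
        # cutoff must not reassign lipid-referenced gas to the bulk
        _, frames, truth = schedule_scenario_run
        fr = frames[-1]
        mask = np.zeros(fr.n_atoms, dtype=bool)
        mask[truth.gas_slice] = True
        base_model = CompartmentModel.from_frame(fr, cutoff=1.0)
        base = classify_gas(fr, base_model, mask)
        for cutoff in (1.5, 2.0, 3.0):
            wider = CompartmentModel(base_model.references, cutoff,
                                     base_model.center, base_model.zone_radii,
                                     base_model.box)
            new = classify_gas(fr, wider, mask)
            flipped = (np.isin(base, ("outer", "gap", "inner"))
                       & (new == "bulk"))
            assert not flipped.any()


class TestSplitWater:
    def test_planted_interior_waters_all_confined(self, schedule_scenario_run):
        _, frames, truth = schedule_scenario_run
        fr = frames[0]
        external, confined = split_water(fr)
        n_conf = len(np.unique(fr.residue_ids[confined]))
        n_ext = len(np.unique(fr.residue_ids[external]))
        assert n_conf == truth.n_confined_water
        assert n_ext == truth.n_external_water

    def test_center_confined_corner_external(self, schedule_scenario_run):
        _, frames, _ = schedule_scenario_run
        fr = frames[0]
        external, confined = split_water(fr)
        center = fr.box / 2
        r = np.linalg.norm(fr.coordinates - center, axis=1)
        assert r[confined].max() < r[external].min() + 1e-9

    def test_degenerate_vesicle_rejected(self, reduced_spec, reduced_vesicle):
        # a single spherical monolayer has no inner headgroup sphere
        outer_only = reduced_vesicle.subset(
            reduced_vesicle.residue_ids <= reduced_spec.n_outer)
        with pytest.raises(ValueError, match="degenerate"):
            split_water(outer_only)


class TestPercolationSeries:
    def test_planted_schedule_recovered_exactly(self, schedule_scenario_run):
        _, frames, truth = schedule_scenario_run
        series = percolation_series(frames, gas_resname="AR", sampling=1.0)
        assert np.abs(series.counts - truth.compartment_counts).max() <= 1

    def test_counts_conserved_every_frame(self, schedule_scenario_run):
        sc, frames, _ = schedule_scenario_run
        series = percolation_series(frames, gas_resname="AR")
        assert (series.counts.sum(axis=1) == sc.n_gas).all()
        assert series.fractions.sum(axis=1) == pytest.approx(1.0)

    def test_static_trajectory_constant_series(self, bubble_scenario_run):
        _, frames, _ = bubble_scenario_run
        series = percolation_series(frames * 3, gas_resname="AR")
        assert (series.counts == series.counts[0]).all()

    def test_planted_labels_match_classifier(self, schedule_scenario_run):
        # every emitted gas atom, re-classified, carries its planted label
        _, frames, truth = schedule_scenario_run
        for fr, planted in zip(frames, truth.gas_labels):
            mask = np.zeros(fr.n_atoms, dtype=bool)
            mask[truth.gas_slice] = True
            model = CompartmentModel.from_frame(fr)
            assert np.array_equal(classify_gas(fr, model, mask), planted)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            percolation_series([])
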