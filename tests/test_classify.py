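"""SVM state classification: features, cross-validation, significance."""

import numpy as np
import pytest

from gcflow.classify import (
    FeatureSet,
    GcCollection,
    accuracy_table,
    build_features,
    pool_loc_conditions,
    region_pairs,
    run_region_pair,
    shuffle_labels,
    significance,
    significance_vs_shuffled,
    train_eval_pair,
)


def _collection(rng, layout, state="awake", n_samples=6, n_boot=10, offset=0.0):
    """Random GC collection; ``layout`` maps region -> electrode count."""
    region_of, channels = {}, []
    for reg, n in layout.items():
        for i in range(n):
            ch = f"{reg}{i}"
            channels.append(ch)
            region_of[ch] = reg
    dirpairs = [(a, b) for a in channels for b in channels
                if a != b and region_of[a] != region_of[b]]
    freqs = np.arange(6.0, 101.0, 2.0)
    gc = rng.gamma(2.0, 0.01, size=(n_samples, n_boot, len(dirpairs), 48)) + offset
    return GcCollection(gc=gc, dirpairs=dirpairs, freqs=freqs,
                        state=state, region_of=region_of)


def test_region_pair_enumeration_counts():
    assert len(region_pairs([f"r{i}" for i in range(8)])) == 28
    assert len(region_pairs([f"r{i}" for i in range(7)])) == 21


def test_feature_length_for_5_by_6_electrode_regions(rng):
    gc = _collection(rng, {"A": 5, "B": 6})
    fs = build_features(gc, "A", "B")
    assert fs.features[0].shape == (10, 2 * 5 * 6 * 48)
    # deterministic ordering: dirpair-major, frequency ascending within
    assert fs.columns[0][:2] < fs.columns[48][:2] or fs.columns[0][:2] != fs.columns[48][:2]
    assert [c[2] for c in fs.columns[:48]] == list(np.arange(6.0, 101.0, 2.0))


def test_same_region_or_empty_region_rejected(rng):
    gc = _collection(rng, {"A": 2, "B": 2})
    with pytest.raises(ValueError):
        build_features(gc, "A", "A")
    with pytest.raises(ValueError):
        build_features(gc, "A", "C")


def test_36_classifiers_and_separated_clusters_score_high(rng):
    a = _collection(rng, {"A": 2, "B": 2}, "awake")
    b = _collection(rng, {"A": 2, "B": 2}, "unconscious", offset=0.5)  # ~10 SD apart
    fa = build_features(a, "A", "B")
    fb = build_features(b, "A", "B")
    W, acc = run_region_pair(fa, fb)
    assert acc.shape == (36,) and W.shape[0] == 36
    assert acc.mean() > 0.95


def test_fast_path_matches_reference_classifier(rng):
    a = _collection(rng, {"A": 2, "B": 1}, "awake")
    b = _collection(rng, {"A": 2, "B": 1}, "unconscious", offset=0.02)
    fa, fb = build_features(a, "A", "B"), build_features(b, "A", "B")
    W, acc = run_region_pair(fa, fb)
    for i, j in [(0, 0), (3, 4), (5, 5)]:
        w_ref, acc_ref = train_eval_pair(fa, fb, i, j)
        assert np.allclose(W[i * 6 + j], w_ref)
        assert acc[i * 6 + j] == pytest.approx(acc_ref, abs=1e-12)


def test_shuffled_labels_center_on_chance(rng):
    a = _collection(rng, {"A": 2, "B": 2}, "awake")
    b = _collection(rng, {"A": 2, "B": 2}, "unconscious")  # same distribution
    fa, fb = build_features(a, "A", "B"), build_features(b, "A", "B")
    accs = []
    for s in range(3):
        fa_s, fb_s = shuffle_labels(fa, fb, seed=s)
        accs.append(run_region_pair(fa_s, fb_s)[1])
    assert abs(np.mean(accs) - 0.5) < 0.05


def test_degenerate_single_class_training_raises(rng):
    gc = _collection(rng, {"A": 1, "B": 1})
    fs = build_features(gc, "A", "B")
    empty = FeatureSet([np.empty((0, fs.features[0].shape[1]))] * 6,
                       fs.columns, "unconscious", ("A", "B"))
    with pytest.raises(ValueError):
        train_eval_pair(fs, empty, 0, 0)


class TestSignificance:
    def test_maximal_separation_is_significant(self):
        p = significance(np.ones(36), np.full(36, 0.5))
        assert p < 0.001

    def test_identical_constant_inputs_give_p_one(self):
        assert significance(np.full(36, 0.7), np.full(36, 0.7)) == 1.0

    def test_non_significant_pair_reported_at_chance(self, rng):
        same = rng.uniform(0.4, 0.6, 36)
        table = accuracy_table({("A", "B"): (same, same.copy())})
        assert not table["significant"].iloc[0]
        assert table["accuracy_reported"].iloc[0] == 0.5

    def test_studentized_shuffle_test_behaviour(self, rng):
        assert significance_vs_shuffled(np.ones(36), rng.normal(0.5, 0.01, 10)) < 1e-6
        null_p = significance_vs_shuffled(rng.normal(0.5, 0.01, 36),
                                          rng.normal(0.5, 0.01, 10))
        assert 0.01 < null_p
        with pytest.raises(ValueError):
            significance_vs_shuffled(np.ones(36), np.array([0.5, 0.5]))

    def test_missing_pairs_are_absent_not_chance(self, rng):
        table = accuracy_table({("A", "B"): (rng.uniform(0.9, 1.0, 36),
                                             rng.uniform(0.45, 0.55, 36))})
        assert len(table) == 1
        assert set(zip(table["region_a"], table["region_b"])) == {("A", "B")}


class TestPooling:
    def test_three_experiments_merge_to_awake_and_loc(self, rng):
        exps = []
        for _ in range(3):
            a = _collection(rng, {"A": 2, "B": 2}, "awake")
            u = _collection(rng, {"A": 2, "B": 2}, "unconscious")
            exps.append((a, u))
        awake, loc = pool_loc_conditions(exps)
        assert awake.n_samples == 18 and loc.n_samples == 18
        assert loc.state == "loc" and awake.state == "awake"
        assert awake.dirpairs == exps[0][0].dirpairs

    def test_single_experiment_passes_through(self, rng):
        a = _collection(rng, {"A": 2, "B": 2}, "awake")
        u = _collection(rng, {"A": 2, "B": 2}, "unconscious")
        awake, loc = pool_loc_conditions([(a, u)])
        assert np.array_equal(awake.gc, a.gc)
        assert np.array_equal(loc.gc, u.gc)

    def test_pooled_classifier_finds_shared_unconscious_couplings(self, rng):
        """Experiments whose unconscious conditions share planted feature
        offsets stay decodable after pooling into one LOC condition."""
        from gcflow.pipeline import RunConfig, classify_stage

        exps = []
        for _ in range(3):
            a = _collection(rng, {"A": 2, "B": 2, "C": 1}, "awake", n_samples=2)
            u = _collection(rng, {"A": 2, "B": 2, "C": 1}, "unconscious",
                            n_samples=2, offset=0.05)
            exps.append((a, u))
        awake, loc = pool_loc_conditions(exps)
        cfg = RunConfig(seed=0, n_shuffles=5)
        table, _ = classify_stage(awake, loc, cfg)
        assert len(table) == 3
        assert table["significant"].all()
        assert (table["accuracy_reported"] > 0.95).all()

    def test_layout_mismatch_raises(self, rng):
        a = _collection(rng, {"A": 2, "B": 2}, "awake")
        u = _collection(rng, {"A": 2, "B": 2}, "unconscious")
        a2 = _collection(rng, {"A": 3, "B": 2}, "awake")
        u2 = _collection(rng, {"A": 3, "B": 2}, "unconscious")
        with pytest.raises(ValueError):
            pool_loc_conditions([(a, u), (a2, u2)])
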