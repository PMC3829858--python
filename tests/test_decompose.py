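"""Non-negative PARAFAC, core consistency, and component summaries."""

import numpy as np
import pandas as pd
import pytest

from gcflow.decompose import (
    core_consistency,
    directional_difference,
    electrode_flow,
    frequency_peak,
    individual_consistency,
    match_components,
    parafac_fit,
    region_scores,
    select_components,
    spatial_frequency_correlation,
    state_dominance,
    tucker_congruence,
)
from gcflow.synth import make_component_tensor
from gcflow.tensorize import Axis3Entry


class TestParafac:
    def test_rank1_noiseless_fit_exact(self):
        x, _ = make_component_tensor(1, (10, 12, 14), 0.0, seed=1)
        comp = parafac_fit(x, 1, seed=0)
        assert comp.fit_pct >= 99.9
        assert all(f.min() >= 0 for f in comp.factors)

    def test_deterministic_under_fixed_seed(self):
        x, _ = make_component_tensor(2, (8, 9, 10), 0.05, seed=2)
        a = parafac_fit(x, 2, seed=5)
        b = parafac_fit(x, 2, seed=5)
        assert all(np.array_equal(f, g) for f, g in zip(a.factors, b.factors))

    def test_noisy_rank4_factors_recovered(self):
        x, true = make_component_tensor(4, (36, 48, 200), noise_sd=0.1, seed=3)
        comp = parafac_fit(x, 4, seed=0)
        _, cong = match_components(true, comp.factors)
        assert np.all(cong > 0.95)

    def test_components_ordered_by_explained_variation(self):
        x, _ = make_component_tensor(3, (20, 20, 20), 0.05, seed=4)
        comp = parafac_fit(x, 3, seed=0)
        strength = [np.linalg.norm(comp.factors[0][:, r])
                    * np.linalg.norm(comp.factors[1][:, r])
                    * np.linalg.norm(comp.factors[2][:, r]) for r in range(3)]
        assert strength == sorted(strength, reverse=True)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            parafac_fit(np.zeros((3, 3, 3)), 1)
        with pytest.raises(ValueError):
            parafac_fit(np.random.default_rng(0).random((3, 3)), 1)


class TestCoreConsistency:
    def test_exact_trilinear_data_scores_100(self):
        x, _ = make_component_tensor(4, (20, 24, 30), 0.0, seed=5)
        comp = parafac_fit(x, 4, seed=0)
        assert core_consistency(x, comp) == pytest.approx(100.0, abs=0.5)

    def test_overfactoring_rank1_degrades_ccd(self):
        x, _ = make_component_tensor(1, (12, 14, 16), 0.02, seed=6)
        c1 = parafac_fit(x, 1, seed=0)
        c2 = parafac_fit(x, 2, seed=0)
        assert core_consistency(x, c2) < core_consistency(x, c1)

    def test_selection_recovers_planted_rank(self):
        x, _ = make_component_tensor(4, (30, 40, 60), noise_sd=0.05, seed=7)
        k_star, table, models = select_components(x, k_max=5, seed=0, n_restarts=3)
        assert k_star == 4
        assert list(table["k"]) == [1, 2, 3, 4, 5]
        assert models[4].ccd_pct > 40.0
        # explained variation never decreases with k up to the true rank
        fits = list(table["fit_pct"][:4])
        assert fits == sorted(fits)


class TestSummaries:
    AXIS3 = [
        Axis3Entry("m1", "a0", "b0", "awake"),
        Axis3Entry("m1", "b0", "a0", "unconscious"),
    ]
    REGION_OF = {"a0": "A", "b0": "B"}

    def test_frequency_peak_examples(self):
        freqs = np.arange(6.0, 101.0, 2.0)
        scores = np.zeros(48)
        scores[np.where(freqs == 44.0)[0][0]] = 1.0
        assert frequency_peak(scores, freqs) == 44.0
        with pytest.raises(ValueError):
            frequency_peak(np.ones(48), freqs)

    def test_region_scores_single_pair(self):
        out = region_scores(np.array([2.5, 0.0]), self.AXIS3, self.REGION_OF, ["A", "B"])
        m = out[("m1", "awake")]
        assert m.loc["A", "B"] == 2.5
        assert m.to_numpy().sum() == 2.5

    def test_directional_difference_antisymmetric_and_zero_for_symmetric(self):
        m = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["A", "B"], columns=["A", "B"])
        assert np.all(directional_difference(m).to_numpy() == 0)
        m2 = pd.DataFrame([[0.0, 2.0], [0.5, 0.0]], index=["A", "B"], columns=["A", "B"])
        d = directional_difference(m2)
        assert np.allclose(d.to_numpy(), -d.to_numpy().T)

    def test_electrode_flow_conservation(self):
        out = electrode_flow(np.array([3.0, 1.0]), self.AXIS3)
        f_awake = out[("m1", "awake")]
        assert f_awake.loc["a0", "total"] == 3.0 and f_awake.loc["b0", "total"] == 3.0
        assert f_awake.loc["a0", "net"] == 3.0 and f_awake.loc["b0", "net"] == -3.0
        for df in out.values():
            assert df["net"].sum() == pytest.approx(0.0, abs=1e-12)

    def test_state_dominance(self):
        state, frac = state_dominance(np.array([3.0, 1.0]), self.AXIS3)
        assert state == "awake" and frac == pytest.approx(0.75)


class TestSpatialFrequencyCorrelation:
    def test_self_similarity_is_one(self, rng):
        f = rng.random(48)
        s = rng.random(200)
        assert spatial_frequency_correlation(f, s, f, s) == pytest.approx(1.0)

    def test_rank_invariance_under_monotone_transform(self, rng):
        f = rng.random(48)
        s = rng.random(200)
        assert spatial_frequency_correlation(f, s, f**2 + 1, np.exp(s)) == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self, rng):
        vals = [abs(spatial_frequency_correlation(
            rng.random(48), rng.random(1000), rng.random(48), rng.random(1000)))
            for _ in range(1000)]
        assert np.mean(np.array(vals) < 0.1) >= 0.95

    def test_zero_variance_raises(self, rng):
        with pytest.raises(ValueError):
            spatial_frequency_correlation(np.ones(48), rng.random(10),
                                          rng.random(48), rng.random(10))


class TestIndividualConsistency:
    @staticmethod
    def _mats(rng, n_datasets=4, identical=False):
        base = rng.random((8, 8))
        out = {}
        for d in range(n_datasets):
            m = base if identical else rng.random((8, 8))
            out[f"m{d}"] = {(c, s): pd.DataFrame(m if identical else rng.random((8, 8)))
                            for c in range(4) for s in ("awake", "unconscious")}
        return out

    def test_four_datasets_give_six_pairs_per_test(self, rng):
        ratio, table = individual_consistency(self._mats(rng))
        assert len(table) == 4 * 2 * 6
        assert set(table.columns) >= {"rho", "p_value", "p_adjusted", "significant"}

    def test_identical_matrices_fully_consistent(self, rng):
        ratio, _ = individual_consistency(self._mats(rng, identical=True))
        assert ratio == 1.0

    def test_independent_matrices_controlled_at_alpha(self):
        ratios = []
        for rep in range(100):
            rng = np.random.default_rng(rep)
            ratio, _ = individual_consistency(self._mats(rng))
            ratios.append(ratio)
        assert np.mean(ratios) <= 0.05

    def test_requires_two_datasets(self, rng):
        with pytest.raises(ValueError):
            individual_consistency({"m0": {}})


def test_tucker_congruence_is_scale_free(rng):
    v = rng.random(30)
    assert tucker_congruence(v, 7.3 * v) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        tucker_congruence(v, np.zeros(30))
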