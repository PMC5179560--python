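"""Filter rule, log-CPM transform, precision weights, weighted fits,
empirical-Bayes moderation, and direction calls."""

import numpy as np
import pandas as pd
import pytest

from sexmir.differential_expression import (
    AnalysisThresholds,
    ContrastSpec,
    classify_direction,
    default_contrasts,
    filter_low_counts,
    fit_contrasts,
    group_design_matrix,
    log_cpm,
    moderate_and_test,
    run_differential_expression,
    voom_weights,
)
from sexmir.io_formats import CountMatrix

from conftest import gaussian_logcpm, make_design


def _matrix_with_row(design, row, fill=0):
    counts = np.full((3, 12), fill, dtype=int)
    counts[0] = row
    counts[1] = 100  # keep the filter result non-empty
    counts[2] = 50
    return CountMatrix(["target", "keep1", "keep2"], design.sample_ids, counts, "mRNA")


class TestFilter:
    def test_expressed_in_one_full_cell_kept(self, design12):
        # male/control cell is columns 0..2: (6,6,6) there, zero elsewhere
        row = [6, 6, 6] + [0] * 9
        cm = _matrix_with_row(design12, row)
        kept = filter_low_counts(cm, design12)
        assert "target" in kept.feature_ids

    def test_uniformly_low_dropped(self, design12):
        cm = _matrix_with_row(design12, [5] * 12)  # never strictly > 5
        kept = filter_low_counts(cm, design12)
        assert "target" not in kept.feature_ids

    def test_two_of_three_in_cell_fails_eighty_percent(self, design12):
        row = [6, 6, 0] + [0] * 9  # 2/3 = 0.667 < 0.8 in the only nonzero cell
        cm = _matrix_with_row(design12, row)
        kept = filter_low_counts(cm, design12)
        assert "target" not in kept.feature_ids

    def test_empty_result_is_an_error(self, design12):
        counts = np.zeros((2, 12), dtype=int)
        cm = CountMatrix(["a", "b"], design12.sample_ids, counts, "mRNA")
        with pytest.raises(ValueError, match="no features pass filter"):
            filter_low_counts(cm, design12)

    def test_order_preserved(self, design12):
        counts = np.full((4, 12), 100, dtype=int)
        cm = CountMatrix(["d", "a", "c", "b"], design12.sample_ids, counts, "mRNA")
        assert filter_low_counts(cm, design12).feature_ids == ["d", "a", "c", "b"]


class TestLogCpm:
    def test_closed_form_values(self, design12):
        counts = np.zeros((2, 12), dtype=int)
        counts[0, 0] = 100
        counts[1, :] = 0
        # make column totals 1e6 via a filler feature
        filler = 1_000_000 - counts.sum(axis=0)
        counts = np.vstack([counts, filler])
        cm = CountMatrix(["a", "b", "fill"], design12.sample_ids, counts, "mRNA")
        lc = log_cpm(cm)
        assert lc.iloc[0, 0] == pytest.approx(6.6511, abs=1e-4)
        assert lc.iloc[1, 0] == pytest.approx(-1.0000, abs=1e-4)

    def test_scale_invariance_limit(self, design12):
        rng = np.random.default_rng(0)
        counts = rng.integers(20_000, 100_000, (50, 12))
        cm1 = CountMatrix([f"g{i}" for i in range(50)], design12.sample_ids, counts, "mRNA")
        cm2 = CountMatrix([f"g{i}" for i in range(50)], design12.sample_ids, counts * 2, "mRNA")
        diff = np.abs(log_cpm(cm1).to_numpy() - log_cpm(cm2).to_numpy())
        assert diff.max() < 1e-4

    def test_zero_total_sample_rejected(self, design12):
        counts = np.ones((2, 12), dtype=int)
        counts[:, 3] = 0
        cm = CountMatrix(["a", "b"], design12.sample_ids, counts, "mRNA")
        with pytest.raises(ValueError, match="zero total"):
            log_cpm(cm)


class TestVoomWeights:
    def _base_counts(self, design, n_low=200, n_high=200):
        counts = np.vstack(
            [np.full((n_low, 12), 10), np.full((n_high, 12), 1000)]
        ).astype(int)
        ids = [f"f{i}" for i in range(n_low + n_high)]
        return CountMatrix(ids, design.sample_ids, counts, "mRNA")

    def test_homoscedastic_fixture_gives_flat_weights(self, design12):
        rng = np.random.default_rng(42)
        cm = self._base_counts(design12)
        lc = log_cpm(cm) + rng.normal(0, 0.8, (400, 12))
        X = group_design_matrix(design12).loc[lc.columns]
        w = voom_weights(lc, cm, X)
        assert w.values.max() / w.values.min() < 1.5

    def test_two_tier_fixture_recovers_variance_ratio(self, design12):
        rng = np.random.default_rng(42)
        cm = self._base_counts(design12)
        noise = np.vstack(
            [rng.normal(0, 1.0, (200, 12)), rng.normal(0, 0.5, (200, 12))]
        )
        lc = log_cpm(cm) + noise
        X = group_design_matrix(design12).loc[lc.columns]
        w = voom_weights(lc, cm, X)
        ratio = w.iloc[200:].to_numpy().mean() / w.iloc[:200].to_numpy().mean()
        assert ratio == pytest.approx((1.0 / 0.5) ** 2, rel=0.30)

    def test_weights_strictly_positive_and_finite(self, design12, small_experiment):
        _, (_, mrna, design, _, _) = small_experiment
        filtered = filter_low_counts(mrna, design)
        lc = log_cpm(filtered)
        X = group_design_matrix(design).loc[lc.columns]
        w = voom_weights(lc, filtered, X)
        assert np.all(np.isfinite(w.to_numpy())) and np.all(w.to_numpy() > 0)

    def test_underdetermined_design_rejected(self, design12):
        cm = self._base_counts(design12)
        lc = log_cpm(cm)
        X = group_design_matrix(design12).loc[lc.columns].iloc[:3]
        with pytest.raises(ValueError):
            voom_weights(lc.iloc[:, :3], cm, X)


class TestFitContrasts:
    def test_equal_weights_reproduce_ols_group_differences(self, design12):
        Y = gaussian_logcpm(design12, 100, 1.0, 1)
        W = pd.DataFrame(3.7, index=Y.index, columns=Y.columns)
        f_unw = fit_contrasts(Y, None, design12)
        f_w = fit_contrasts(Y, W, design12)
        for c in ("stress_in_males", "stress_in_females"):
            np.testing.assert_allclose(
                f_unw[f"beta_{c}"], f_w[f"beta_{c}"], atol=1e-10
            )
        labels = design12.group_labels()
        g = Y.T.groupby(labels).mean().T
        np.testing.assert_allclose(
            f_unw["beta_stress_in_males"],
            (g["male.stress"] - g["male.control"]).to_numpy(),
            atol=1e-10,
        )

    def test_exact_group_means_fixture(self, design12):
        Y = pd.DataFrame(0.0, index=["g"], columns=design12.sample_ids)
        stress_males = design12.samples_in_cell("male", "stress")
        Y.loc["g", stress_males] = 1.0
        f = fit_contrasts(Y, None, design12)
        assert f["beta_stress_in_males"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert f["beta_stress_in_females"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_normal_equations(self, design12):
        """Independent oracle: solve the weighted normal equations gene by gene
        with explicit matrix algebra."""
        rng = np.random.default_rng(7)
        Y = gaussian_logcpm(design12, 30, 1.0, 2)
        W = pd.DataFrame(
            rng.uniform(0.2, 5.0, Y.shape), index=Y.index, columns=Y.columns
        )
        f = fit_contrasts(Y, W, design12)
        X = group_design_matrix(design12).loc[Y.columns].to_numpy()
        for c in default_contrasts():
            for gi in range(len(Y)):
                w = np.diag(W.iloc[gi].to_numpy())
                beta = np.linalg.solve(X.T @ w @ X, X.T @ w @ Y.iloc[gi].to_numpy())
                expect = c.vector @ beta
                assert f[f"beta_{c.name}"].iloc[gi] == pytest.approx(expect, abs=1e-10)

    def test_contrast_must_sum_to_zero(self):
        with pytest.raises(ValueError, match="sum to zero"):
            ContrastSpec("bad", np.array([1.0, 0.0, 0.0, 0.0]))


class TestModeration:
    def test_identical_variances_are_a_fixed_point(self, design12):
        Y = gaussian_logcpm(design12, 50, 1.0, 3)
        f = fit_contrasts(Y, None, design12)
        f["s_g"] = 0.9
        out = moderate_and_test(f)
        np.testing.assert_allclose(out["s_moderated"], 0.9, atol=1e-8)

    def test_posterior_variance_between_sample_and_prior(self, design12):
        Y = gaussian_logcpm(design12, 500, 1.0, 4)
        f = fit_contrasts(Y, None, design12)
        out = moderate_and_test(f)
        s2, s2p, s0 = f["s_g"] ** 2, out["s_moderated"] ** 2, out["s0_sq"].iloc[0]
        lo = np.minimum(s2, s0) - 1e-12
        hi = np.maximum(s2, s0) + 1e-12
        assert ((s2p >= lo) & (s2p <= hi)).all()

    def test_gaussian_null_calibration(self, design12):
        Y = gaussian_logcpm(design12, 5000, 1.0, 42)
        out = moderate_and_test(fit_contrasts(Y, None, design12))
        for c in ("stress_in_males", "stress_in_females"):
            frac = (out[f"p_{c}"] < 0.05).mean()
            assert 0.04 <= frac <= 0.06

    def test_degenerate_variances_rejected(self, design12):
        Y = gaussian_logcpm(design12, 10, 1.0, 5)
        f = fit_contrasts(Y, None, design12)
        f["s_g"] = 0.0
        with pytest.raises(ValueError, match="degenerate"):
            moderate_and_test(f)


class TestDirectionCalls:
    @pytest.mark.parametrize(
        "lfc,p,expect",
        [
            (0.40, 0.03, "up"),        # 2^0.40 = 1.32 > 1.3
            (0.20, 0.001, "neutral"),  # fold change below threshold
            (-0.50, 0.04, "down"),
            (0.40, 0.06, "neutral"),   # p above threshold
            (np.log2(1.3), 0.049, "up"),  # boundary fold change counts
        ],
    )
    def test_threshold_rule(self, lfc, p, expect):
        assert classify_direction(lfc, p) == expect

    def test_thresholds_validated(self):
        with pytest.raises(ValueError):
            AnalysisThresholds(p_cut=1.5)
        with pytest.raises(ValueError):
            AnalysisThresholds(fc_cut=0.9)


class TestEndToEnd:
    def test_sex_separation(self):
        """Effects planted only in females leave the male contrast at the
        null call rate."""
        from sexmir.synthetic_data import SimulationConfig, simulate_experiment

        cfg = SimulationConfig(
            n_genes=2500,
            n_mirs=60,
            frac_effect_genes={"male": 0.0, "female": 0.08},
            frac_effect_mirs={"male": 0.0, "female": 0.0},
            coupling_prob=0.0,
            seed=21,
        )
        _, mrna, design, _, truth = simulate_experiment(cfg)
        de = run_differential_expression(mrna, design)
        male_calls = de.table["dir_stress_in_males"] != "neutral"
        female_calls = de.table["dir_stress_in_females"] != "neutral"
        assert male_calls.mean() < 0.07  # null-rate calls only
        assert female_calls.sum() > 2 * male_calls.sum()
        # planted female genes are recovered in the female contrast
        called_f = set(de.table.loc[female_calls, "feature_id"])
        planted = truth.genes_up["female"] | truth.genes_down["female"]
        assert len(called_f & planted) / len(planted) > 0.5
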