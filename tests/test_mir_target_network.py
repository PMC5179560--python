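"""Dual-source intersection, chi-squared direction enrichment, BH selection,
association classification, and network summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sexmir.differential_expression import AnalysisThresholds, DEResult
from sexmir.io_formats import TargetPredictionTable
from sexmir.mir_target_network import (
    ChiSqEnrichment,
    MiRGeneNetwork,
    background_frequencies,
    bh_adjust,
    chi_squared_target_enrichment,
    classify_associations,
    intersect_target_sources,
    select_surviving,
    summarize_network,
)


def make_de(directions: dict[str, str], contrast: str = "stress_in_males") -> DEResult:
    """DEResult stub with prescribed per-gene direction calls."""
    lfc = {"up": 1.0, "down": -1.0, "neutral": 0.0}
    p = {"up": 0.01, "down": 0.01, "neutral": 0.5}
    table = pd.DataFrame(
        {
            "feature_id": list(directions),
            "ave_expr": 5.0,
            f"logFC_{contrast}": [lfc[d] for d in directions.values()],
            f"p_{contrast}": [p[d] for d in directions.values()],
            f"dir_{contrast}": list(directions.values()),
        }
    )
    return DEResult(table, [contrast], AnalysisThresholds())


class TestIntersectSources:
    def _table(self, rows):
        return TargetPredictionTable(
            pd.DataFrame(rows, columns=["mir_id", "gene_id", "source"])
        )

    def test_edge_in_both_sources_kept(self):
        t = self._table([("m1", "g1", "A"), ("m1", "g1", "B")])
        assert intersect_target_sources(t, ["A", "B"]) == {"m1": {"g1"}}

    def test_edge_in_one_source_dropped(self):
        t = self._table([("m1", "g1", "A"), ("m1", "g2", "A"), ("m1", "g2", "B")])
        assert intersect_target_sources(t, ["A", "B"]) == {"m1": {"g2"}}

    def test_missing_required_source_named(self):
        t = self._table([("m1", "g1", "A")])
        with pytest.raises(ValueError, match="'B'"):
            intersect_target_sources(t, ["A", "B"])

    def test_universe_restriction(self):
        t = self._table([("m1", "g1", "A"), ("m1", "g1", "B"), ("m1", "g2", "A"), ("m1", "g2", "B")])
        assert intersect_target_sources(t, ["A", "B"], universe={"g2"}) == {"m1": {"g2"}}

    def test_matches_brute_force_set_intersection(self):
        rng = np.random.default_rng(8)
        rows = []
        for src in "ABC":
            for _ in range(300):
                rows.append((f"m{rng.integers(10)}", f"g{rng.integers(40)}", src))
        t = self._table(rows)
        result = intersect_target_sources(t, ["A", "B", "C"])
        # brute force from the raw records
        by = {src: {} for src in "ABC"}
        for m, g, s in set(rows):
            by[s].setdefault(m, set()).add(g)
        expected = {}
        for m in set(by["A"]) & set(by["B"]) & set(by["C"]):
            inter = by["A"][m] & by["B"][m] & by["C"][m]
            if inter:
                expected[m] = inter
        assert result == expected


class TestBackgroundFrequencies:
    def test_counting(self):
        de = make_de({f"g{i}": d for i, d in enumerate(["up"] * 10 + ["down"] * 20 + ["neutral"] * 70)})
        assert background_frequencies(de, "stress_in_males") == (10, 20, 70)

    def test_nothing_significant(self):
        de = make_de({f"g{i}": "neutral" for i in range(50)})
        assert background_frequencies(de, "stress_in_males") == (0, 0, 50)

    def test_equals_recount_oracle(self):
        rng = np.random.default_rng(3)
        dirs = {f"g{i}": rng.choice(["up", "down", "neutral"]) for i in range(200)}
        de = make_de(dirs)
        up, down, neu = background_frequencies(de, "stress_in_males")
        vals = list(dirs.values())
        assert (up, down, neu) == (vals.count("up"), vals.count("down"), vals.count("neutral"))


class TestChiSquared:
    def _setup(self, bg=(100, 200, 700), obs=(10, 10, 30)):
        dirs = {}
        i = 0
        for d, n in zip(("up", "down", "neutral"), bg):
            for _ in range(n):
                dirs[f"g{i}"] = d
                i += 1
        de = make_de(dirs)
        # build a target set realizing obs
        targets = set()
        taken = {"up": 0, "down": 0, "neutral": 0}
        want = dict(zip(("up", "down", "neutral"), obs))
        for g, d in dirs.items():
            if taken[d] < want[d]:
                targets.add(g)
                taken[d] += 1
        return de, {"mir1": targets}

    def test_background_proportional_targets_give_p_one(self):
        de, targets = self._setup(bg=(100, 200, 700), obs=(5, 10, 35))
        res = chi_squared_target_enrichment(
            targets, de, "stress_in_males", pd.Series({"mir1": "up"})
        )
        assert res[0].chi2 == pytest.approx(0.0, abs=1e-12)
        assert res[0].p_value == pytest.approx(1.0)

    def test_df2_closed_form_example(self):
        """Expected (5,10,35) vs observed (10,10,30): chi2 = 5.714 and the
        df-2 survival function is exp(-chi2/2)."""
        de, targets = self._setup()
        res = chi_squared_target_enrichment(
            targets, de, "stress_in_males", pd.Series({"mir1": "up"})
        )
        assert res[0].expected == pytest.approx((5, 10, 35))
        assert res[0].chi2 == pytest.approx(5.714, abs=1e-3)
        assert res[0].p_value == pytest.approx(np.exp(-res[0].chi2 / 2), rel=1e-10)
        assert res[0].p_value == pytest.approx(0.0574, abs=2e-4)

    def test_p_matches_distribution_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            bg = tuple(rng.integers(50, 500, 3))
            obs = tuple(rng.integers(3, 30, 3))
            de, targets = self._setup(bg=bg, obs=obs)
            res = chi_squared_target_enrichment(
                targets, de, "stress_in_males", pd.Series({"mir1": "down"})
            )[0]
            exp = np.array(bg) / sum(bg) * sum(obs)
            chi2 = (((np.array(obs) - exp) ** 2) / exp).sum()
            assert res.p_value == pytest.approx(
                float(stats.chi2.sf(chi2, 2)), abs=1e-10
            )

    def test_neutral_mirs_not_tested_and_small_sets_skipped(self):
        de, targets = self._setup()
        targets["tiny"] = set(list(targets["mir1"])[:3])
        res = chi_squared_target_enrichment(
            targets,
            de,
            "stress_in_males",
            pd.Series({"mir1": "up", "tiny": "up", "neut": "neutral"}),
        )
        assert [r.mir_id for r in res] == ["mir1"]

    def test_zero_universe_targets_warns_not_errors(self):
        de, targets = self._setup()
        with pytest.warns(UserWarning, match="no targets"):
            res = chi_squared_target_enrichment(
                {"mirX": {"not_in_universe"}},
                de,
                "stress_in_males",
                pd.Series({"mirX": "up"}),
            )
        assert res == []

    def test_low_expected_cells_flagged(self):
        de, targets = self._setup(bg=(2, 3, 995), obs=(1, 1, 48))
        res = chi_squared_target_enrichment(
            targets, de, "stress_in_males", pd.Series({"mir1": "up"})
        )[0]
        assert res.low_expected

    def test_contingency_mode_matches_scipy(self):
        de, targets = self._setup()
        res = chi_squared_target_enrichment(
            targets, de, "stress_in_males", pd.Series({"mir1": "up"}), mode="contingency"
        )[0]
        obs = np.array([10, 10, 30])
        rest = np.array([100, 200, 700]) - obs
        chi2, p, _, _ = stats.chi2_contingency(np.vstack([obs, rest]), correction=False)
        assert res.p_value == pytest.approx(p, rel=1e-12)

    def test_null_pvalues_uniform(self):
        """Targets drawn at random from the universe: the goodness-of-fit
        p-values are uniform (KS)."""
        rng = np.random.default_rng(99)
        bg = (2000, 3000, 5000)
        dirs = {}
        i = 0
        for d, n in zip(("up", "down", "neutral"), bg):
            for _ in range(n):
                dirs[f"g{i}"] = d
                i += 1
        de = make_de(dirs)
        genes = np.array(list(dirs))
        pvals = []
        for _ in range(1000):
            tset = set(rng.choice(genes, 200, replace=False))
            res = chi_squared_target_enrichment(
                {"m": tset}, de, "stress_in_males", pd.Series({"m": "up"})
            )
            pvals.append(res[0].p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        adj, rej = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])
        assert rej.all()

    def test_single_p_unchanged(self):
        adj, _ = bh_adjust([0.3])
        assert adj[0] == pytest.approx(0.3)

    def test_empty_input(self):
        adj, rej = bh_adjust([])
        assert len(adj) == 0 and len(rej) == 0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_sorted_order_and_capped(self, ps):
        adj, rej = bh_adjust(ps)
        order = np.argsort(ps, kind="stable")
        sorted_adj = adj[order]
        assert all(a <= b + 1e-15 for a, b in zip(sorted_adj, sorted_adj[1:]))
        assert (adj <= 1.0).all() and (adj >= np.asarray(ps) - 1e-15).all()

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_bh_rejections_superset_of_bonferroni(self, ps):
        p = np.asarray(ps)
        _, bh = bh_adjust(p, alpha=0.05)
        bonf = p * len(p) < 0.05
        assert not np.any(bonf & ~bh)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.uniform(size=40)
        adj, rej = bh_adjust(p)
        sm_rej, sm_adj, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_allclose(adj, sm_adj, atol=1e-12)
        assert np.array_equal(rej, sm_rej)


def _surv(mir, direction, p=0.001):
    e = ChiSqEnrichment(mir, direction, (1, 1, 1), (1, 1, 1), 9.0, p, False)
    e.survives = True
    return e


class TestAssociationsAndSummary:
    def test_direction_rule(self):
        de = make_de({"g_up": "up", "g_down": "down", "g_neu": "neutral"})
        net = classify_associations(
            [_surv("m_up", "up")],
            {"m_up": {"g_up", "g_down", "g_neu"}},
            de,
            "stress_in_males",
        )
        assoc = {(m, g): a for m, g, a in net.edges}
        assert assoc[("m_up", "g_down")] == "negative"
        assert assoc[("m_up", "g_up")] == "positive"
        assert ("m_up", "g_neu") not in assoc
        net.validate()

    def test_no_neutral_nodes_ever(self):
        de = make_de({"g1": "neutral", "g2": "down"})
        net = classify_associations(
            [_surv("m", "down")], {"m": {"g1", "g2"}}, de, "stress_in_males"
        )
        dirs = [d for d, _ in net.gene_nodes.values()] + [
            d for d, _ in net.mir_nodes.values()
        ]
        assert "neutral" not in dirs
        net.validate()

    def test_inconsistent_edge_rejected_by_validate(self):
        net = MiRGeneNetwork(
            {"m": ("up", 1.0)}, {"g": ("up", 1.0)}, [("m", "g", "negative")]
        )
        with pytest.raises(ValueError, match="inconsistent"):
            net.validate()

    def test_empty_network_summary_is_all_zeros(self):
        de = make_de({"g1": "neutral"})
        s = summarize_network(MiRGeneNetwork(), de, "stress_in_males", [], n_de_mirs=0)
        assert s.n_genes_targeted == 0 and s.fraction_genes_targeted == 0.0
        assert s.fraction_mirs_surviving == 0.0

    def test_toy_sharing_count(self):
        """2 miRs sharing 1 target plus 1 private target each: one gene hit by
        2+ miRs, two genes hit by exactly one."""
        de = make_de({"shared": "down", "priv1": "down", "priv2": "up"})
        targets = {"mA": {"shared", "priv1"}, "mB": {"shared", "priv2"}}
        net = classify_associations(
            [_surv("mA", "up"), _surv("mB", "up")], targets, de, "stress_in_males"
        )
        s = summarize_network(net, de, "stress_in_males", [_surv("mA", "up"), _surv("mB", "up")], n_de_mirs=4)
        assert s.genes_by_multiple_mirs == 1
        assert s.genes_by_one_mir == 2
        assert s.genes_negative_only == 2  # shared, priv1 (down vs up miRs)
        assert s.genes_positive_only == 1  # priv2 up with up miR
        assert s.n_mirs_surviving == 2 and s.fraction_mirs_surviving == 0.5

    def test_partitions_sum_on_random_fixtures(self):
        rng = np.random.default_rng(17)
        genes = {f"g{i}": rng.choice(["up", "down", "neutral"]) for i in range(60)}
        de = make_de(genes)
        surviving = [_surv(f"m{i}", rng.choice(["up", "down"])) for i in range(6)]
        targets = {
            s.mir_id: set(rng.choice(list(genes), rng.integers(3, 20), replace=False))
            for s in surviving
        }
        net = classify_associations(surviving, targets, de, "stress_in_males")
        net.validate()
        s = summarize_network(net, de, "stress_in_males", surviving, n_de_mirs=10)
        s.validate()  # partition identities assert internally


class TestSelection:
    def test_select_surviving_annotates_and_filters(self):
        es = [
            ChiSqEnrichment("m1", "up", (1, 1, 1), (1, 1, 1), 20.0, 1e-6, False),
            ChiSqEnrichment("m2", "up", (1, 1, 1), (1, 1, 1), 0.1, 0.9, False),
        ]
        surv = select_surviving(es, alpha=0.05)
        assert [e.mir_id for e in surv] == ["m1"]
        assert es[0].p_adjusted == pytest.approx(2e-6)
        assert not es[1].survives
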