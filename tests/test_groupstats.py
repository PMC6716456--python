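"""Selection-framework checks: ANCOVA, FDR, trend logic, hypothesis sets."""

import numpy as np
import pandas as pd
import pytest
from bruteforce import brute_bh
from scipy import stats

from ecnet import groupstats as gs


def make_manifest(rng, n_per_group=15):
    rows = []
    for g in gs.GROUPS:
        for _ in range(n_per_group):
            rows.append({
                "group": g,
                "age": float(rng.normal(32, 6)),
                "education": float(rng.normal(14, 2)),
                "race": str(rng.choice(["a", "b", "c"], p=[0.5, 0.3, 0.2])),
                "motion": float(rng.lognormal(-2.3, 0.4)),
            })
    return pd.DataFrame(rows)


class TestCountComparisons:
    @pytest.mark.parametrize("k,expected", [
        (2, (2, 2, 8)),
        (20, (20, 380, 800)),
    ])
    def test_budget_arithmetic(self, k, expected):
        assert gs.count_comparisons(k) == expected

    def test_tiny_k_rejected(self):
        with pytest.raises(ValueError):
            gs.count_comparisons(1)


class TestAncovaPair:
    def test_relabeled_identical_data_is_null(self, rng):
        y = np.tile(rng.normal(size=20), 2)
        groups = np.array(["control"] * 20 + ["ptsd"] * 20)
        p, adj, coef = gs.ancova_pair(y, groups, None, ("control", "ptsd"))
        assert p > 0.9 and abs(coef) < 1e-10

    def test_planted_shift_detected_reliably(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.r_[rng.normal(0, 1, 20), rng.normal(3, 1, 20)]
            groups = np.array(["control"] * 20 + ["ptsd"] * 20)
            p, _, coef = gs.ancova_pair(y, groups, None, ("control", "ptsd"))
            hits += (p < 0.001) and (coef > 0)
        assert hits >= 19

    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        manifest = make_manifest(rng)
        y = rng.normal(size=len(manifest))
        cov = gs._covariate_design(manifest, ("age", "education", "race", "motion"))
        pair = ("control", "pcs_ptsd")
        p, adj, coef = gs.ancova_pair(y, manifest["group"].to_numpy(), cov, pair)
        X, mask, _ = gs._pair_design(manifest["group"].to_numpy(), cov, pair)
        res = sm.OLS(y[mask], X).fit()
        assert p == pytest.approx(float(res.pvalues[1]), abs=1e-10)
        assert coef == pytest.approx(float(res.params[1]), abs=1e-12)

    def test_covariate_only_effect_yields_uniform_p(self):
        # feature driven purely by age; group p-values should be U[0,1]
        ps = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            manifest = make_manifest(rng, n_per_group=20)
            y = 2.0 * manifest["age"].to_numpy() + rng.normal(size=len(manifest))
            cov = gs._covariate_design(manifest, ("age",))
            p, _, _ = gs.ancova_pair(y, manifest["group"].to_numpy(), cov,
                                     ("control", "ptsd"))
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_tiny_groups_rejected(self, rng):
        y = rng.normal(size=5)
        groups = np.array(["control", "control", "ptsd", "ptsd", "ptsd"])
        with pytest.raises(ValueError, match="n >= 3"):
            gs.ancova_pair(y, groups, None, ("control", "ptsd"))

    def test_collinear_covariates_rejected(self, rng):
        manifest = make_manifest(rng)
        cov = gs._covariate_design(manifest, ("age",))
        cov["age_copy"] = cov["age"]
        with pytest.raises(ValueError, match="collinear"):
            gs.ancova_pair(rng.normal(size=len(manifest)), manifest["group"].to_numpy(),
                           cov, ("control", "ptsd"))


class TestFdrBH:
    def test_single_small_p_significant(self):
        mask, q = gs.fdr_bh(np.array([0.01]), q=0.05)
        assert mask[0]

    def test_all_ones_none_significant(self):
        mask, _ = gs.fdr_bh(np.ones(50), q=0.05)
        assert not mask.any()

    def test_matches_naive_oracle_on_random_draws(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            m = int(rng.integers(5, 60))
            p = rng.uniform(size=m) ** rng.uniform(0.5, 3)
            mask, _ = gs.fdr_bh(p, q=0.05)
            assert np.array_equal(mask, brute_bh(p, q=0.05))


class TestTrendFilter:
    def pair_means(self, c, p, cp):
        return {"control|ptsd": (c, p), "control|pcs_ptsd": (c, cp),
                "ptsd|pcs_ptsd": (p, cp)}

    def test_decreasing_variance_is_rigidity(self):
        ok, label = gs.trend_filter(self.pair_means(10, 7, 4), "var", 2)
        assert ok and label == "rigidity"

    def test_non_monotone_fails(self):
        ok, _ = gs.trend_filter(self.pair_means(10, 4, 7), "var", 2)
        assert not ok
        ok, _ = gs.trend_filter(self.pair_means(10, 4, 7), "static", 2)
        assert not ok

    def test_increasing_strength_is_inflation(self):
        ok, label = gs.trend_filter(self.pair_means(4, 7, 10), "static", 2)
        assert ok and label == "inflation"

    def test_ties_break_conformance(self):
        ok, _ = gs.trend_filter(self.pair_means(10, 7, 7), "static", 2)
        assert not ok

    def test_h1_needs_only_control_displacement(self):
        ok, label = gs.trend_filter(self.pair_means(10, 6, 7), "static", 1)
        assert ok and label == "deflation"


class TestIntersectLocal:
    def test_disjoint_and_identical(self):
        assert gs.intersect_local({"a"}, {"b"}) == set()
        assert gs.intersect_local({"a", "b"}, {"a", "b"}) == {"a", "b"}

    def test_random_sets_match_membership_check(self, rng):
        universe = [f"n{i}" for i in range(30)]
        a = {u for u in universe if rng.random() < 0.4}
        b = {u for u in universe if rng.random() < 0.4}
        expected = {u for u in universe if u in a and u in b}
        assert gs.intersect_local(a, b) == expected


def synthetic_table(patterns):
    """Build a comparison table from {(measure, scope): (sig6, means3)} specs.

    ``sig6`` is a dict of (flavor, pair) -> bool; ``means3`` maps flavor ->
    (control, ptsd, pcs) adjusted means.
    """
    rows = []
    for (measure, scope), (sig, means) in patterns.items():
        for flavor in ("static", "var"):
            c, p, cp = means[flavor]
            for pair, (ma, mb) in {"control|ptsd": (c, p), "control|pcs_ptsd": (c, cp),
                                   "ptsd|pcs_ptsd": (p, cp)}.items():
                rows.append({
                    "measure": measure, "flavor": flavor, "scope": scope,
                    "pair": pair, "p": 0.001, "q_value": 0.01,
                    "significant": bool(sig[(flavor, pair)]),
                    "mean_a": ma, "mean_b": mb, "direction": mb - ma,
                })
    return pd.DataFrame(rows)


ALL_SIG = {(f, pr): True for f in ("static", "var")
           for pr in ("control|ptsd", "control|pcs_ptsd", "ptsd|pcs_ptsd")}
H1_SIG = {**ALL_SIG, ("static", "ptsd|pcs_ptsd"): False, ("var", "ptsd|pcs_ptsd"): False}
H2_MEANS = {"static": (10.0, 7.0, 4.0), "var": (9.0, 6.0, 3.0)}
H1_MEANS = {"static": (10.0, 6.0, 6.2), "var": (9.0, 5.0, 5.1)}


class TestApplyHypotheses:
    def test_fully_significant_monotone_feature_is_h2(self):
        patterns = {}
        for m in ("spl", "eb", "ec"):
            patterns[(m, "edge:A>B")] = (ALL_SIG, H2_MEANS)
        res = gs.apply_hypotheses(synthetic_table(patterns))
        assert res.h2_edges == {"edge:A>B"}
        assert res.gated_h2_edges == {"edge:A>B"}
        assert res.h1_edges == set()

    def test_control_only_significance_is_h1(self):
        patterns = {}
        for m in ("spl", "eb", "ec"):
            patterns[(m, "edge:A>B")] = (H1_SIG, H1_MEANS)
        res = gs.apply_hypotheses(synthetic_table(patterns))
        assert res.h1_edges == {"edge:A>B"}
        assert res.gated_h1_edges == {"edge:A>B"}
        assert res.h2_edges == set()

    def test_h1_h2_membership_is_exclusive(self):
        patterns = {("spl", "edge:A>B"): (ALL_SIG, H2_MEANS),
                    ("eb", "edge:A>B"): (ALL_SIG, H2_MEANS),
                    ("ec", "edge:A>B"): (ALL_SIG, H2_MEANS),
                    ("spl", "edge:C>D"): (H1_SIG, H1_MEANS),
                    ("eb", "edge:C>D"): (H1_SIG, H1_MEANS),
                    ("ec", "edge:C>D"): (H1_SIG, H1_MEANS)}
        res = gs.apply_hypotheses(synthetic_table(patterns))
        assert res.h1_edges & res.h2_edges == set()
        assert res.gated_edges <= res.h1_edges | res.h2_edges

    def test_local_measure_intersection_required(self):
        # spl hits but eb null -> no edge selection
        null_sig = {k: False for k in ALL_SIG}
        patterns = {("spl", "edge:A>B"): (ALL_SIG, H2_MEANS),
                    ("eb", "edge:A>B"): (null_sig, H2_MEANS),
                    ("ec", "edge:A>B"): (ALL_SIG, H2_MEANS)}
        res = gs.apply_hypotheses(synthetic_table(patterns))
        assert res.h2_edges == set()

    def test_connectivity_gate_drops_raw_null_edges(self):
        null_sig = {k: False for k in ALL_SIG}
        patterns = {("spl", "edge:A>B"): (ALL_SIG, H2_MEANS),
                    ("eb", "edge:A>B"): (ALL_SIG, H2_MEANS),
                    ("ec", "edge:A>B"): (null_sig, H2_MEANS)}
        table = synthetic_table(patterns)
        res = gs.apply_hypotheses(table)
        assert res.h2_edges == {"edge:A>B"}          # metric-level selection
        assert res.gated_h2_edges == set()           # but the raw-EC gate drops it
        assert gs.connectivity_gate(set(), table, 2) == set()

    def test_node_selection_intersects_cc_and_effloc(self):
        patterns = {("cc", "node:X"): (ALL_SIG, H2_MEANS),
                    ("effloc", "node:X"): (ALL_SIG, H2_MEANS),
                    ("cc", "node:Y"): (ALL_SIG, H2_MEANS)}
        res = gs.apply_hypotheses(synthetic_table(patterns))
        assert res.h2_nodes == {"node:X"}

    def test_nonconforming_trend_blocks_selection(self):
        bad_means = {"static": (10.0, 7.0, 4.0), "var": (3.0, 6.0, 9.0)}  # variance rises
        patterns = {(m, "edge:A>B"): (ALL_SIG, bad_means) for m in ("spl", "eb", "ec")}
        res = gs.apply_hypotheses(synthetic_table(patterns))
        assert res.h2_edges == set()


class TestCompareFeatures:
    def make_inputs(self, rng, n=12):
        manifest = make_manifest(rng, n_per_group=n)
        g = manifest["group"].to_numpy()
        shift = np.where(g == "control", 0.0, np.where(g == "ptsd", 1.5, 3.0))
        features = pd.DataFrame({
            "ec.static.edge:A>B": shift + rng.normal(size=len(g)) * 0.5,
            "ec.var.edge:A>B": -shift + rng.normal(size=len(g)) * 0.5,
            "cc.static.node:X": rng.normal(size=len(g)),
            "cc.var.node:X": rng.normal(size=len(g)),
        })
        return features, manifest

    def test_planted_shift_is_detected_and_null_is_not(self, rng):
        features, manifest = self.make_inputs(rng)
        table = gs.compare_features(features, manifest)
        planted = table[(table.scope == "edge:A>B") & (table.flavor == "static")]
        assert planted["significant"].all()
        null = table[table.scope == "node:X"]
        assert null["p"].min() > 0.001

    def test_selection_invariant_to_row_and_column_order(self, rng):
        features, manifest = self.make_inputs(rng)
        t1 = gs.compare_features(features, manifest)
        perm_cols = features[list(reversed(features.columns))]
        perm = rng.permutation(len(features))
        t2 = gs.compare_features(perm_cols.iloc[perm].reset_index(drop=True),
                                 manifest.iloc[perm].reset_index(drop=True))
        key = ["measure", "flavor", "scope", "pair"]
        m1 = t1.set_index(key).sort_index()
        m2 = t2.set_index(key).sort_index()
        assert np.allclose(m1["p"], m2["p"])
        assert (m1["significant"] == m2["significant"]).all()
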