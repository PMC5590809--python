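import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radiomod.modules import (
    Module,
    coherence_r,
    deduplicate,
    discover_and_validate,
    fdr_adjust,
    isa_bicluster,
    module_overlap,
    module_size,
    permutation_validate,
)


def _matrix(arr, rows=None, cols=None):
    arr = np.asarray(arr, dtype=float)
    rows = rows or [f"f{i}" for i in range(arr.shape[0])]
    cols = cols or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=rows, columns=cols)


class TestIsaBicluster:
    def test_all_zero_matrix_yields_no_modules(self):
        m = _matrix(np.zeros((20, 10)))
        assert isa_bicluster(m, n_seeds=20, seed=0) == []

    def test_planted_block_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((100, 80))
        a[:10, :8] += 5.0
        m = _matrix(a)
        cands = isa_bicluster(m, n_seeds=60, seed=1)
        best = 0.0
        planted_r = {f"f{i}" for i in range(10)}
        planted_c = {f"s{j}" for j in range(8)}
        for c in cands:
            jr = len(set(c.feature_ids) & planted_r) / len(set(c.feature_ids) | planted_r)
            jc = len(set(c.pathway_ids) & planted_c) / len(set(c.pathway_ids) | planted_c)
            best = max(best, min(jr, jc))
        assert best >= 0.9

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((40, 30))
        a[:5, :4] += 4.0
        m = _matrix(a)
        c1 = isa_bicluster(m, n_seeds=30, seed=7)
        c2 = isa_bicluster(m, n_seeds=30, seed=7)
        assert [(x.feature_ids, x.pathway_ids) for x in c1] == [
            (x.feature_ids, x.pathway_ids) for x in c2
        ]

    def test_incomplete_matrix_rejected(self):
        a = np.zeros((5, 5))
        m = _matrix(a)
        m.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            isa_bicluster(m)


class TestCoherence:
    def test_identical_columns_give_r_two(self):
        rng = np.random.default_rng(3)
        col = rng.standard_normal(50)
        feats = pd.DataFrame({"a": col, "b": col})
        scores = pd.DataFrame({"x": col * 2, "y": col * 2})
        mod = Module(("a", "b"), ("x", "y"))
        assert coherence_r(mod, feats, scores) == pytest.approx(2.0)

    def test_hand_constructed_mixed_correlations(self):
        # two features with rho 0.5, two pathway columns with rho -0.5
        rng = np.random.default_rng(4)
        n = 4000
        z = rng.standard_normal((n, 3))
        f1 = z[:, 0]
        f2 = 0.5 * stats.norm.ppf(stats.rankdata(f1) / (n + 1)) + np.sqrt(0.75) * z[:, 1]
        feats = pd.DataFrame({"a": f1, "b": f2})
        p1 = z[:, 2]
        p2 = -0.5 * stats.norm.ppf(stats.rankdata(p1) / (n + 1)) + np.sqrt(0.75) * rng.standard_normal(n)
        scores = pd.DataFrame({"x": p1, "y": p2})
        mod = Module(("a", "b"), ("x", "y"))
        r = coherence_r(mod, feats, scores)
        assert r == pytest.approx(0.0, abs=0.1)

    def test_null_columns_keep_r_small(self):
        rng = np.random.default_rng(5)
        flagged = 0
        for rep in range(20):
            feats = pd.DataFrame(
                rng.standard_normal((200, 3)), columns=["a", "b", "c"]
            )
            scores = pd.DataFrame(
                rng.standard_normal((200, 3)), columns=["x", "y", "z"]
            )
            mod = Module(("a", "b", "c"), ("x", "y", "z"))
            if abs(coherence_r(mod, feats, scores)) > 0.3:
                flagged += 1
        assert flagged <= 2

    def test_singleton_sides_use_unit_convention(self):
        rng = np.random.default_rng(6)
        feats = pd.DataFrame({"a": rng.standard_normal(30)})
        scores = pd.DataFrame({"x": rng.standard_normal(30)})
        mod = Module(("a",), ("x",))
        assert coherence_r(mod, feats, scores) == pytest.approx(2.0)

    def test_missing_columns_rejected(self):
        feats = pd.DataFrame({"a": np.arange(5.0)})
        scores = pd.DataFrame({"x": np.arange(5.0)})
        with pytest.raises(KeyError):
            coherence_r(Module(("zz",), ("x",)), feats, scores)


class TestDeduplicate:
    def test_identical_candidates_collapse(self):
        a = Module(("f1", "f2"), ("s1",), r_stat=1.0)
        b = Module(("f1", "f2"), ("s1",), r_stat=0.9)
        out = deduplicate([a, b], feature_universe=["f1", "f2", "f3"], pathway_universe=["s1", "s2"])
        assert len(out) == 1

    def test_disjoint_candidates_both_retained(self):
        a = Module(("f1",), ("s1",), r_stat=1.0)
        b = Module(("f2",), ("s2",), r_stat=0.5)
        out = deduplicate([a, b], feature_universe=["f1", "f2"], pathway_universe=["s1", "s2"])
        assert len(out) == 2

    def test_hand_computed_membership_correlations(self):
        universe_f = [f"f{i}" for i in range(10)]
        universe_p = [f"s{i}" for i in range(10)]
        m1 = Module(tuple(universe_f[:5]), tuple(universe_p[:5]), r_stat=2.0)
        m2 = Module(tuple(universe_f[:5]), (universe_p[0], *universe_p[1:4], "s5"), r_stat=1.5)
        m3 = Module((universe_f[9],), (universe_p[9],), r_stat=1.0)
        # m2 shares 9/10 members with m1 (corr ~0.9); m3 is disjoint
        out = deduplicate([m1, m2, m3], feature_universe=universe_f, pathway_universe=universe_p)
        assert m1 in out and m3 in out and m2 not in out

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        universe_f = [f"f{i}" for i in range(20)]
        universe_p = [f"s{i}" for i in range(10)]
        cands = []
        for k in range(12):
            fs = tuple(rng.choice(universe_f, size=4, replace=False))
            ps = tuple(rng.choice(universe_p, size=3, replace=False))
            cands.append(Module(fs, ps, r_stat=float(rng.random())))
        once = deduplicate(cands, feature_universe=universe_f, pathway_universe=universe_p)
        twice = deduplicate(once, feature_universe=universe_f, pathway_universe=universe_p)
        assert [(m.feature_ids, m.pathway_ids) for m in once] == [
            (m.feature_ids, m.pathway_ids) for m in twice
        ]

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            deduplicate([], max_corr=0.0)


class TestPermutationValidation:
    def test_planted_module_validates(self):
        rng = np.random.default_rng(8)
        n = 150
        factor = rng.standard_normal(n)
        feats = pd.DataFrame(
            {f"f{i}": 0.8 * factor + 0.6 * rng.standard_normal(n) for i in range(3)}
        )
        for i in range(12):
            feats[f"n{i}"] = rng.standard_normal(n)
        scores = pd.DataFrame(
            {f"s{i}": 0.8 * factor + 0.6 * rng.standard_normal(n) for i in range(2)}
        )
        for i in range(10):
            scores[f"m{i}"] = rng.standard_normal(n)
        mod = Module(("f0", "f1", "f2"), ("s0", "s1"))
        p = permutation_validate(mod, feats, scores, n_perm=500, seed=0)
        assert p <= 0.01

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(9)
        pvals = []
        for rep in range(60):
            feats = pd.DataFrame(
                rng.standard_normal((60, 10)), columns=[f"f{i}" for i in range(10)]
            )
            scores = pd.DataFrame(
                rng.standard_normal((60, 8)), columns=[f"s{i}" for i in range(8)]
            )
            mod = Module(("f0", "f1", "f2"), ("s0", "s1"))
            pvals.append(permutation_validate(mod, feats, scores, n_perm=200, seed=rep))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_minimal_observed_statistic_gives_p_one(self):
        # a module far below every null draw under the plus-one convention
        rng = np.random.default_rng(10)
        n = 100
        feats = pd.DataFrame(rng.standard_normal((n, 6)), columns=[f"f{i}" for i in range(6)])
        feats["anti1"] = np.arange(n, dtype=float)
        feats["anti2"] = -np.arange(n, dtype=float) + 0.001 * rng.standard_normal(n)
        scores = pd.DataFrame(rng.standard_normal((n, 5)), columns=[f"s{i}" for i in range(5)])
        mod = Module(("anti1", "anti2"), ("s0",))
        p = permutation_validate(mod, feats, scores, n_perm=300, seed=1)
        assert p > 0.95

    def test_insufficient_columns_rejected(self):
        feats = pd.DataFrame({"a": np.arange(5.0)})
        scores = pd.DataFrame({"x": np.arange(5.0)})
        mod = Module(("a",), ("x",))
        with pytest.raises(ValueError):
            permutation_validate(
                Module(("a", "a2"), ("x",)), feats, scores, n_perm=10
            )


class TestFdrAndSummaries:
    def test_bh_step_up_by_hand(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_passthrough(self):
        assert fdr_adjust([0.037])[0] == pytest.approx(0.037)

    def test_q_dominates_p_and_monotone(self):
        rng = np.random.default_rng(11)
        p = rng.random(50)
        q = fdr_adjust(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_module_size_worked_example(self):
        mod = Module(tuple(f"f{i}" for i in range(6)), tuple(f"s{i}" for i in range(7)))
        assert module_size(mod, 636, 511) == pytest.approx(6 / 636 + 7 / 511)
        assert module_size(mod, 636, 511) == pytest.approx(0.0231, abs=1e-4)

    def test_overlap_conventions(self):
        a = Module(("wavelet_HHH_firstorder_entropy",), ("s1",))
        b = Module(("original_firstorder_entropy",), ("s2",))
        assert module_overlap(a, b) == 1.0  # same base name after collapse
        c = Module(("original_shape_volume",), ("s3",))
        assert module_overlap(a, c) == 0.0
        assert module_overlap(a, a) == 1.0


class TestEndToEnd:
    def test_planted_block_discovered_and_validated(self):
        # direct NES-like matrix with a strong block, plus matching
        # patient-level data: the full chain flags the planted module
        rng = np.random.default_rng(12)
        a = rng.standard_normal((30, 20))
        a[:5, :4] += 4.0
        assoc = _matrix(a)
        n = 120
        factor = rng.standard_normal(n)
        d_feats = {}
        for i in range(30):
            d_feats[f"f{i}"] = (
                0.8 * factor + 0.6 * rng.standard_normal(n)
                if i < 5
                else rng.standard_normal(n)
            )
        d_scores = {}
        for j in range(20):
            d_scores[f"s{j}"] = (
                0.8 * factor + 0.6 * rng.standard_normal(n)
                if j < 4
                else rng.standard_normal(n)
            )
        d1f = pd.DataFrame(d_feats)
        d1s = pd.DataFrame(d_scores)
        # independent validation cohort with the same planted structure
        factor2 = rng.standard_normal(n)
        d2f = d1f.copy()
        d2s = d1s.copy()
        for i in range(5):
            d2f[f"f{i}"] = 0.8 * factor2 + 0.6 * rng.standard_normal(n)
        for i in range(5, 30):
            d2f[f"f{i}"] = rng.standard_normal(n)
        for j in range(4):
            d2s[f"s{j}"] = 0.8 * factor2 + 0.6 * rng.standard_normal(n)
        for j in range(4, 20):
            d2s[f"s{j}"] = rng.standard_normal(n)
        mods = discover_and_validate(
            assoc, d1f, d1s, d2f, d2s, n_seeds=40, n_perm=300, seed=3
        )
        validated = [m for m in mods if m.q_fdr < 0.05]
        assert any(
            len(set(m.feature_ids) & {f"f{i}" for i in range(5)}) >= 3
            and len(set(m.pathway_ids) & {f"s{j}" for j in range(4)}) >= 2
            for m in validated
        )
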