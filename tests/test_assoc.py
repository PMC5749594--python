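import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from radiogenomap import (
    AssociationMap,
    SemanticFeatureTable,
    binary_association,
    filter_features,
    group_difference_test,
    ordinal_association,
    simulate_features,
)


def _binary_table(n_ones, n, fid="f"):
    vals = [1.0] * n_ones + [0.0] * (n - n_ones)
    return SemanticFeatureTable(
        data=pd.DataFrame({fid: vals}, index=[f"p{i}" for i in range(n)]),
        codebook={fid: {"type": "binary", "levels": None}},
    )


class TestOccurrenceFilter:
    @pytest.mark.parametrize(
        "n_ones,kept", [(5, False), (15, True), (95, False), (10, False), (11, True)],
        ids=["5pct-removed", "15pct-kept", "95pct-minor-class-removed",
             "exactly-10pct-removed", "11pct-kept"],
    )
    def test_binary_minor_class_rule(self, n_ones, kept):
        out, removed = filter_features(_binary_table(n_ones, 100))
        assert ("f" in out.feature_ids) == kept
        # independent frequency count
        minor = min(n_ones, 100 - n_ones) / 100
        assert kept == (minor > 0.10)

    def test_ordinal_non_modal_rule(self):
        vals = [0.0] * 92 + [1.0, 2.0, 3.0, 4.0] * 2  # 8% outside mode -> removed
        t = SemanticFeatureTable(
            data=pd.DataFrame({"m": vals}, index=[f"p{i}" for i in range(100)]),
            codebook={"m": {"type": "ordinal", "levels": list("abcde")}},
        )
        out, removed = filter_features(t)
        assert "m" in removed
        vals2 = [0.0] * 85 + [1.0, 2.0, 3.0] * 5  # 15% outside mode -> kept
        t2 = SemanticFeatureTable(
            data=pd.DataFrame({"m": vals2}, index=[f"p{i}" for i in range(100)]),
            codebook={"m": {"type": "ordinal", "levels": list("abcde")}},
        )
        out2, _ = filter_features(t2)
        assert "m" in out2.feature_ids

    def test_all_missing_removed_with_warning(self):
        t = SemanticFeatureTable(
            data=pd.DataFrame({"f": [np.nan] * 10}, index=[f"p{i}" for i in range(10)]),
            codebook={"f": {"type": "binary", "levels": None}},
        )
        with pytest.warns(UserWarning, match="missing"):
            out, removed = filter_features(t)
        assert removed["f"] == "all values missing"


class TestBinaryAssociation:
    def test_hand_example(self):
        # groups (4,5,6) vs (1,2,3): pooled t = 3/sqrt(2/3), p ~ 0.0214
        scores = np.array([4, 5, 6, 1, 2, 3], dtype=float)
        feat = np.array([1, 1, 1, 0, 0, 0], dtype=float)
        t, p = binary_association(scores, feat)
        assert t == pytest.approx(3 / np.sqrt(2 / 3), abs=1e-9)
        assert p == pytest.approx(_t_two_sided_oracle(t, df=4), abs=1e-9)
        assert p == pytest.approx(0.0214, abs=5e-4)

    def test_identical_groups_t_zero(self):
        scores = np.array([1, 2, 3, 1, 2, 3], dtype=float)
        feat = np.array([1, 1, 1, 0, 0, 0], dtype=float)
        t, p = binary_association(scores, feat)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_label_swap_antisymmetry(self, rng):
        scores = rng.standard_normal(40)
        feat = (rng.random(40) < 0.5).astype(float)
        t1, p1 = binary_association(scores, feat)
        t2, p2 = binary_association(scores, 1 - feat)
        assert t2 == pytest.approx(-t1, abs=1e-12)
        assert p2 == pytest.approx(p1, abs=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="<2"):
            binary_association(np.arange(5.0), np.array([1, 0, 0, 0, 0.0]))


def _t_two_sided_oracle(t, df):
    """Two-sided t tail via the incomplete-beta continued fraction (hand-rolled)."""
    x = df / (df + t * t)
    # I_x(df/2, 1/2) with Lentz continued fraction
    a, b = df / 2.0, 0.5

    def betacf(a, b, x):
        qab, qap, qam = a + b, a + 1.0, a - 1.0
        c, d = 1.0, 1.0 - qab * x / qap
        d = 1.0 / d
        h = d
        for m in range(1, 200):
            m2 = 2 * m
            aa = m * (b - m) * x / ((qam + m2) * (a + m2))
            d = 1.0 + aa * d
            c = 1.0 + aa / c
            d = 1.0 / d
            h *= d * c
            aa = -(a + m) * (qab + m) * x / ((a + m2) * (qap + m2))
            d = 1.0 + aa * d
            c = 1.0 + aa / c
            d = 1.0 / d
            delta = d * c
            h *= delta
            if abs(delta - 1.0) < 1e-14:
                break
        return h

    from math import lgamma, exp, log

    ln_front = lgamma(a + b) - lgamma(a) - lgamma(b) + a * log(x) + b * log(1 - x)
    if x < (a + 1) / (a + b + 2):
        ib = exp(ln_front) * betacf(a, b, x) / a
    else:
        ib = 1 - exp(
            lgamma(a + b) - lgamma(b) - lgamma(a) + b * log(1 - x) + a * log(x)
        ) * betacf(b, a, 1 - x) / b
    return ib


class TestOrdinalAssociation:
    def test_monotone_limits(self):
        scores = np.array([1.2, 3.4, 5.0, 7.1, 9.9])
        levels = np.array([0, 1, 2, 3, 4], dtype=float)
        rho, p = ordinal_association(scores, levels)
        assert rho == pytest.approx(1.0) and p == 0.0
        rho2, p2 = ordinal_association(scores, levels[::-1].copy())
        assert rho2 == pytest.approx(-1.0) and p2 == 0.0

    def test_tied_data_matches_rank_oracle(self, rng):
        """Average-rank Spearman equals Pearson of hand-computed mid-ranks."""
        for _ in range(10):
            n = int(rng.integers(4, 9))
            scores = rng.standard_normal(n).round(1)  # force ties
            levels = rng.integers(0, 3, n).astype(float)
            if len(np.unique(levels)) < 2:
                continue
            rho, _ = ordinal_association(scores, levels)
            assert rho == pytest.approx(
                _rank_pearson_oracle(scores, levels), abs=1e-12
            )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match=">=3"):
            ordinal_association([1.0, 2.0], [0.0, 1.0])
        with pytest.raises(ValueError, match="constant"):
            ordinal_association([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])


def _rank_pearson_oracle(x, y):
    def midranks(v):
        out = np.empty(len(v))
        for i, vi in enumerate(v):
            less = sum(1 for u in v if u < vi)
            equal = sum(1 for u in v if u == vi)
            out[i] = less + (equal + 1) / 2
        return out

    rx, ry = midranks(x), midranks(y)
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


class TestGroupDifference:
    def test_exact_enumeration_example(self):
        # (1,2,3) vs (4,5,6): 2/20 rank splits are as extreme -> p = 0.1
        stat, p = group_difference_test(
            np.array([1, 2, 3, 4, 5, 6.0]), np.array([1, 1, 1, 0, 0, 0])
        )
        assert p == pytest.approx(0.1, abs=1e-12)
        assert p == pytest.approx(_ranksum_enumeration_oracle([1, 2, 3], [4, 5, 6]), abs=1e-12)

    def test_null_rarely_rejects(self, rng):
        hits, reps = 0, 200
        for _ in range(reps):
            v = rng.standard_normal(30)
            g = np.zeros(30)
            g[rng.choice(30, 15, replace=False)] = 1
            _, p = group_difference_test(v, g)
            hits += p < 0.05
        assert hits / reps <= 0.095  # 3-sigma above nominal 5%

    def test_exact_and_approximate_branches_agree(self, rng):
        """At n1=n2=6 the exact enumeration and the normal approximation give
        p values within 0.02 of each other."""
        from scipy.stats import mannwhitneyu

        for _ in range(5):
            v = rng.standard_normal(12)
            g = np.array([1] * 6 + [0] * 6)
            _, p_exact = group_difference_test(v, g)  # exact branch (n<=12, no ties)
            _, p_asym = mannwhitneyu(v[g == 1], v[g == 0], alternative="two-sided",
                                     method="asymptotic")
            assert abs(p_exact - p_asym) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_difference_test([1.0, 2.0], [1, 1])


def _ranksum_enumeration_oracle(a, b):
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in a)
    n = len(a)
    all_ws = [
        sum(ranks[pooled[i]] for i in idx)
        for idx in itertools.combinations(range(len(pooled)), n)
    ]
    mean_w = np.mean(all_ws)
    extreme = sum(1 for w in all_ws if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12)
    return extreme / comb(len(pooled), n)


class TestAssociationMapModel:
    def _scores(self, n_metagenes, n_patients, seed):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.standard_normal((n_metagenes, n_patients)),
            index=[f"m{i+1}" for i in range(n_metagenes)],
            columns=[f"p{i:03d}" for i in range(n_patients)],
        )

    def _planted_fit(self, seed):
        scores = self._scores(10, 150, seed)
        pairs = [(f"pf{i}", f"m{i+1}", 2.0) for i in range(6)]
        table, truth = simulate_features(
            scores, pairs, n_null_features=29, seed=seed + 1,
            null_frequencies=[0.3],
        )
        res = AssociationMap(scores, table).fit()
        return res, {(f, m) for f, m, _ in truth.planted_pairs}

    def test_planted_pairs_recovered_single_seed(self):
        res, planted = self._planted_fit(101)
        sig = set(zip(res.significant()["feature_id"], res.significant()["metagene_id"]))
        assert sig == planted
        assert res.n_significant == 6

    def test_single_pair_fdr_equals_p(self):
        scores = self._scores(1, 60, 5)
        table = _binary_table(30, 60)
        table.data.index = scores.columns
        res = AssociationMap(scores, table).fit()
        row = res.records.iloc[0]
        assert row["fdr"] == pytest.approx(row["p"], abs=1e-12)

    def test_dual_threshold_straddled(self):
        """P<.05 alone does not make a pair significant; FDR<0.01 is also required."""
        rng = np.random.default_rng(42)
        # find a null draw with 0.01 < p < 0.05: significant by p, not by fdr
        for s in range(200):
            scores = self._scores(1, 80, 1000 + s)
            feat = (np.random.default_rng(s).random(80) < 0.5).astype(float)
            table = SemanticFeatureTable(
                data=pd.DataFrame({"f": feat}, index=scores.columns),
                codebook={"f": {"type": "binary", "levels": None}},
            )
            res = AssociationMap(scores, table).fit()
            p = res.records["p"].iloc[0]
            if 0.011 < p < 0.05:
                assert not res.records["significant"].iloc[0]
                break
        else:
            pytest.fail("no draw in the straddling band")

    def test_fdr_family_counts(self):
        res, _ = self._planted_fit(7)
        assert len(res.records) == 35 * 10
        assert res.n_tested == res.records["tested"].sum()
        assert res.records.loc[res.records["tested"], "fdr"].notna().all()

    def test_patient_permutation_invariance(self):
        scores = self._scores(3, 60, 9)
        table, _ = simulate_features(scores, [("f0", "m1", 1.5)], 5, seed=10)
        res1 = AssociationMap(scores, table).fit()
        perm = np.random.default_rng(0).permutation(60)
        scores2 = scores.iloc[:, perm]
        table2 = SemanticFeatureTable(
            data=table.data.iloc[perm], codebook=table.codebook
        )
        res2 = AssociationMap(scores2, table2).fit()
        merged = res1.records.merge(
            res2.records, on=["feature_id", "metagene_id"], suffixes=("_a", "_b")
        )
        np.testing.assert_allclose(
            merged["statistic_a"], merged["statistic_b"], atol=1e-10
        )

    def test_empty_intersection_rejected(self):
        scores = self._scores(2, 20, 3)
        t = _binary_table(10, 20)  # patient ids p0.. don't match p000..
        with pytest.raises(ValueError, match="patients"):
            AssociationMap(scores, t)


class TestOrderMap:
    def _result_with_p(self, P):
        """Build a fitted map whose p matrix is exactly P (features x metagenes)."""
        from radiogenomap.assoc import AssociationMapResults

        feats = [f"f{i}" for i in range(P.shape[0])]
        mets = [f"m{j}" for j in range(P.shape[1])]
        records = pd.DataFrame(
            [
                {"feature_id": f, "metagene_id": m, "stat_type": "t",
                 "statistic": 1.0, "p": P[i, j], "tested": True,
                 "fdr": P[i, j], "significant": False, "direction": 1.0}
                for i, f in enumerate(feats)
                for j, m in enumerate(mets)
            ]
        )
        return AssociationMapResults(
            records, feats, mets, {}, 0.05, 0.01, n_patients=50
        )

    def test_identical_rows_adjacent(self):
        rng = np.random.default_rng(2)
        P = rng.random((6, 4))
        P[3] = P[0]
        res = self._result_with_p(P).order_map()
        i0, i3 = res.row_order.index("f0"), res.row_order.index("f3")
        assert abs(i0 - i3) == 1

    def test_block_structure_contiguous(self):
        P = np.full((8, 4), 0.5)
        P[:4, :2] = 1e-6  # one tight block of strong associations
        res = self._result_with_p(P).order_map()
        block = {res.row_order.index(f"f{i}") for i in range(4)}
        assert max(block) - min(block) == 3  # contiguous leaves

    def test_orders_are_permutations(self):
        rng = np.random.default_rng(3)
        res = self._result_with_p(rng.random((7, 5))).order_map()
        assert sorted(res.row_order) == sorted(f"f{i}" for i in range(7))
        assert sorted(res.col_order) == sorted(f"m{j}" for j in range(5))

    def test_single_row_identity(self):
        res = self._result_with_p(np.array([[0.1, 0.2]])).order_map()
        assert res.row_order == ["f0"]
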