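"""Univariate screen, projections, VIP, correlations and clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from isotrace.enrichment_metrics import SampleTable
from isotrace.stats_suite import (
    anova_fdr_lsd,
    cluster_order,
    pca_scores,
    plsda_vip,
    spearman_profile,
)


def make_table(x: np.ndarray, groups: list[str], prefix: str = "m") -> SampleTable:
    pools = pd.DataFrame(
        2.0 ** x,  # anova_fdr_lsd log2-transforms; generate on the log scale
        index=[f"s{i}" for i in range(x.shape[0])],
        columns=[f"{prefix}{j}" for j in range(x.shape[1])],
    )
    return SampleTable(pools, pd.Series(groups, index=pools.index))


class TestAnova:
    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 1))
        table = make_table(x, ["A"] * 3 + ["B"] * 3)
        res = anova_fdr_lsd(table)[0]
        t, _ = sps.ttest_ind(x[:3, 0], x[3:, 0])
        assert res.f_statistic == pytest.approx(t**2, rel=1e-9)

    def test_degenerate_variance_flagged_p_one(self):
        x = np.zeros((6, 1))
        table = make_table(x, ["A"] * 3 + ["B"] * 3)
        res = anova_fdr_lsd(table)[0]
        assert res.degenerate and res.p_value == 1.0

    def test_bh_q_monotone_in_p_rank(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(9, 25))
        x[:3, :4] += 2.0
        res = anova_fdr_lsd(make_table(x, ["A", "A", "A", "B", "B", "B", "C", "C", "C"]))
        by_p = sorted(res, key=lambda r: r.p_value)
        qs = [r.q_value for r in by_p]
        assert all(q1 <= q2 + 1e-12 for q1, q2 in zip(qs, qs[1:]))
        assert all(r.q_value >= r.p_value - 1e-12 for r in res)

    def test_lsd_gated_on_omnibus(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(9, 10), scale=0.2)
        x[3:6, 0] += 5.0  # one strong effect in group B
        res = anova_fdr_lsd(make_table(x, ["A"] * 3 + ["B"] * 3 + ["C"] * 3))
        hit = next(r for r in res if r.metabolite == "m0")
        assert hit.q_value <= 0.05 and len(hit.lsd_pairs) == 3
        flags = {(a, b): sig for a, b, sig in hit.lsd_pairs}
        assert flags[("A", "B")] and flags[("B", "C")] and not flags[("A", "C")]
        null = [r for r in res if r.metabolite != "m0" and r.q_value > 0.05]
        assert all(r.lsd_pairs == () for r in null)

    def test_null_rejection_rate_near_alpha(self):
        """Raw per-metabolite p-values are uniform: rejections at ~5%."""
        rng = np.random.default_rng(3)
        rejections = total = 0
        for _ in range(60):
            x = rng.normal(size=(9, 20))
            res = anova_fdr_lsd(make_table(x, ["A"] * 3 + ["B"] * 3 + ["C"] * 3))
            rejections += sum(r.p_value <= 0.05 for r in res)
            total += len(res)
        rate = rejections / total
        assert 0.02 < rate < 0.08  # binomial CI around 0.05 at n=1200


class TestPCA:
    def test_two_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(10, 8), scale=0.1)
        x[5:, 0] += 4.0
        table = make_table(x, ["A"] * 5 + ["B"] * 5)
        proj = pca_scores(table, scale=False)
        pc1 = proj.scores["PC1"]
        assert proj.explained_variance[0] > 0.5
        assert pc1.iloc[:5].max() < pc1.iloc[5:].min() or pc1.iloc[:5].min() > pc1.iloc[5:].max()

    def test_rotation_invariance_of_explained_variance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(8, 5)) @ np.diag([3, 2, 1, 0.5, 0.1])
        q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        t1 = make_table(x, ["A"] * 4 + ["B"] * 4)
        t2 = make_table(x @ q, ["A"] * 4 + ["B"] * 4)
        v1 = pca_scores(t1, scale=False).explained_variance
        v2 = pca_scores(t2, scale=False).explained_variance
        np.testing.assert_allclose(v1, v2, atol=1e-9)

    def test_duplicated_sample_coincident_scores(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(5, 4))
        x[4] = x[0]
        proj = pca_scores(make_table(x, ["A"] * 5), scale=False)
        np.testing.assert_allclose(proj.scores.iloc[4], proj.scores.iloc[0], atol=1e-9)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pca_scores(make_table(np.zeros((4, 3)), ["A", "A", "B", "B"]))


class TestPLSDA:
    def test_vip_mean_square_is_one(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(12, 30))
        x[6:, 2] += 2.0
        vip, _ = plsda_vip(make_table(x, ["A"] * 6 + ["B"] * 6))
        assert np.mean(vip.scores.to_numpy() ** 2) == pytest.approx(1.0, abs=1e-8)

    def test_informative_feature_ranks_first(self):
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(25):
            x = rng.normal(size=(20, 50))
            x[10:, 17] += 3.0
            vip, _ = plsda_vip(make_table(x, ["A"] * 10 + ["B"] * 10))
            if vip.scores.idxmax() == "m17":
                hits += 1
            assert vip.scores["m17"] > 1.0
        assert hits >= 24

    def test_permuted_labels_break_ranking(self):
        rng = np.random.default_rng(9)
        ranks = []
        for _ in range(20):
            x = rng.normal(size=(20, 50))
            x[10:, 17] += 3.0
            labels = list(rng.permutation(["A"] * 10 + ["B"] * 10))
            vip, _ = plsda_vip(make_table(x, labels))
            ranks.append(int(vip.scores.rank(ascending=False)["m17"]))
        assert np.median(ranks) > 5  # informative feature no longer privileged

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            plsda_vip(make_table(np.random.default_rng(0).normal(size=(4, 3)), ["A"] * 4))

    def test_multiclass_supported(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(9, 6))
        vip, proj = plsda_vip(make_table(x, ["A"] * 3 + ["B"] * 3 + ["C"] * 3))
        assert np.mean(vip.scores**2) == pytest.approx(1.0, abs=1e-8)
        assert proj.scores.shape == (9, 2)


class TestSpearman:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(11)
        table = make_table(rng.normal(size=(12, 4)), ["A"] * 6 + ["B"] * 6)
        prof = spearman_profile(table, "m0")
        assert prof.rho["m0"] == pytest.approx(1.0)

    def test_monotone_decreasing_transform_is_minus_one(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(10, 1))
        pools = pd.DataFrame(
            {"m0": 2.0 ** x[:, 0], "m1": np.exp(-(2.0 ** x[:, 0]))},
            index=[f"s{i}" for i in range(10)],
        )
        table = SampleTable(pools, pd.Series(["A"] * 10, index=pools.index))
        assert spearman_profile(table, "m0").rho["m1"] == pytest.approx(-1.0)

    def test_independent_noise_stays_small(self):
        rng = np.random.default_rng(13)
        big = 0
        for _ in range(40):
            table = make_table(rng.normal(size=(30, 2)), ["A"] * 30)
            if abs(spearman_profile(table, "m0").rho["m1"]) >= 0.5:
                big += 1
        assert big <= 2

    def test_constant_reference_rejected(self):
        pools = pd.DataFrame({"m0": [1.0] * 4, "m1": [1, 2, 3, 4.0]}, index=list("abcd"))
        table = SampleTable(pools, pd.Series(["A"] * 4, index=pools.index))
        with pytest.raises(ValueError, match="constant"):
            spearman_profile(table, "m0")


class TestClusterOrder:
    def test_duplicated_rows_merge_first(self):
        rng = np.random.default_rng(14)
        df = pd.DataFrame(rng.normal(size=(4, 6)), index=["w", "x", "y", "z"])
        df.loc["z"] = df.loc["w"]
        order, link = cluster_order(df)
        first = sorted(link[0, :2].astype(int))
        labels = sorted(df.index)
        assert {labels[first[0]], labels[first[1]]} == {"w", "z"}
        assert link[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_rows_merge_last(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        df = pd.DataFrame([base, base * 1.01 + 0.3, -base], index=["r0", "r1", "r2"])
        _, link = cluster_order(df)
        assert link[-1, 2] > 1.5  # last merge joins the anticorrelated row

    def test_row_scaling_does_not_change_order(self):
        rng = np.random.default_rng(15)
        df = pd.DataFrame(rng.normal(size=(5, 8)), index=[f"r{i}" for i in range(5)])
        order1, _ = cluster_order(df)
        scaled = df.mul(pd.Series([2.0, 5.0, 0.1, 7.0, 1.0], index=df.index), axis=0)
        order2, _ = cluster_order(scaled)
        assert order1 == order2

    def test_zero_variance_row_warns(self):
        df = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [3.0, 1.0, 2.0]], index=["flat", "r1", "r2"]
        )
        with pytest.warns(UserWarning, match="flat"):
            cluster_order(df)
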