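import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from amrsid import choose_test, one_way_compare, significance_report, two_way_compare
from amrsid.errors import DesignError, InsufficientDataError
from amrsid.group_stats import dunn_posthoc


def anova_f_oracle(groups):
    """Textbook between/within sum-of-squares one-way ANOVA F."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((g - np.mean(g)) ** 2).sum() for g in groups)
    dfb, dfw = len(groups) - 1, len(all_vals) - len(groups)
    return (ssb / dfb) / (ssw / dfw)


def kruskal_h_oracle(groups):
    """Rank-sum Kruskal-Wallis H with midranks and tie correction."""
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
    _, t = np.unique(pooled, return_counts=True)
    correction = 1.0 - (t**3 - t).sum() / (N**3 - N)
    return h / correction


class TestChooseTest:
    def test_small_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            choose_test({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0, 4.0]})

    def test_single_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            choose_test({"a": [1.0, 2.0, 3.0]})

    def test_gaussian_groups_mostly_parametric(self):
        rng = np.random.default_rng(21)
        picks = []
        for _ in range(100):
            groups = {k: rng.normal(0, 1, 16) for k in "abc"}
            picks.append(choose_test(groups))
        assert np.mean([p == "one_way_anova" for p in picks]) >= 0.80

    def test_heavy_tailed_group_flips_to_ranks(self):
        rng = np.random.default_rng(22)
        flips = []
        for _ in range(100):
            groups = {
                "a": rng.normal(0, 1, 16),
                "b": rng.normal(0, 1, 16),
                "c": rng.standard_cauchy(16),
            }
            flips.append(choose_test(groups) == "kruskal_wallis_dunn")
        # selection probability tracks Shapiro-Wilk's power against Cauchy
        assert np.mean(flips) > 0.8


class TestOneWayCompare:
    def test_hand_anova_example(self):
        res = one_way_compare(
            {"a": [1, 2, 3], "b": [2, 3, 4], "c": [3, 4, 5]}, test_name="one_way_anova"
        )
        assert res.statistic == pytest.approx(3.0, abs=1e-12)
        assert res.p_value == pytest.approx(0.125, abs=0.01)

    def test_identical_groups_give_f_zero(self):
        res = one_way_compare(
            {"a": [1, 2, 3], "b": [1, 2, 3]}, test_name="one_way_anova"
        )
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_constant_data(self):
        res = one_way_compare({"a": [2, 2, 2], "b": [2, 2, 2]}, test_name="one_way_anova")
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_f_matches_oracle_on_random_data(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            groups = {
                k: rng.normal(rng.uniform(-1, 1), 1.0, rng.integers(3, 10))
                for k in "abc"
            }
            res = one_way_compare(groups, test_name="one_way_anova")
            assert res.statistic == pytest.approx(
                anova_f_oracle(list(groups.values())), abs=1e-10
            )

    def test_kruskal_matches_rank_oracle(self):
        rng = np.random.default_rng(32)
        for _ in range(50):
            groups = {
                k: np.round(rng.normal(0, 2, rng.integers(3, 10)), 1)  # force ties
                for k in "abc"
            }
            res = one_way_compare(groups, test_name="kruskal_wallis_dunn")
            assert res.statistic == pytest.approx(
                kruskal_h_oracle(list(groups.values())), abs=1e-10
            )

    def test_separated_groups_trigger_dunn_posthoc(self):
        res = one_way_compare(
            {"a": [1.0, 2, 3, 4], "b": [10.0, 11, 12, 13], "c": [20.0, 21, 22, 23]},
            test_name="kruskal_wallis_dunn",
        )
        assert res.p_value < 0.05
        assert len(res.posthoc) == 3
        pairs = {frozenset(p) for p, _ in res.posthoc}
        assert frozenset(("a", "c")) in pairs


class TestDunnPosthoc:
    def test_z_matches_brute_force(self):
        rng = np.random.default_rng(33)
        groups = {k: rng.normal(i, 1, 8) for i, k in enumerate("abc")}
        got = dict((frozenset(p), v) for p, v in dunn_posthoc(groups))
        pooled = np.concatenate(list(groups.values()))
        ranks = stats.rankdata(pooled)
        N = len(pooled)
        _, t = np.unique(pooled, return_counts=True)
        var = N * (N + 1) / 12 - (t**3 - t).sum() / (12 * (N - 1))
        start, mean_rank = 0, {}
        for k, g in groups.items():
            mean_rank[k] = ranks[start : start + len(g)].mean()
            start += len(g)
        for a, b in itertools.combinations(groups, 2):
            z = (mean_rank[a] - mean_rank[b]) / np.sqrt(var * (1 / 8 + 1 / 8))
            assert got[frozenset((a, b))] == pytest.approx(
                2 * stats.norm.sf(abs(z)), abs=1e-12
            )


def _two_way_frame(rng, shift_sev=0.0, shift_path=0.0, n=16):
    rows = []
    for path in ("scoliosis", "spondylolisthesis"):
        for sev in ("low", "high"):
            mu = (sev == "high") * shift_sev + (path == "scoliosis") * shift_path
            for v in rng.normal(mu, 1.0, n):
                rows.append(dict(value=v, pathology=path, severity=sev))
    return pd.DataFrame(rows)


class TestTwoWayCompare:
    def test_severity_shift_detected_not_pathology(self):
        rng = np.random.default_rng(41)
        hits_sev, hits_path = 0, 0
        reps = 40
        for _ in range(reps):
            df = _two_way_frame(rng, shift_sev=2.0)
            res = two_way_compare(df)
            hits_sev += res.effects["severity"][1] < 0.05
            hits_path += res.effects["pathology"][1] < 0.05
        assert hits_sev / reps >= 0.95
        assert hits_path / reps < 0.3

    def test_identical_cells_give_zero_f(self):
        df = _two_way_frame(np.random.default_rng(0), 0, 0, n=4)
        df["value"] = 1.0
        res = two_way_compare(df)
        assert all(f == 0.0 for f, _ in res.effects.values())

    def test_rank_branch_idempotent_on_rank_data(self):
        # untied data equal to their own ranks: ranking is the identity
        rng = np.random.default_rng(42)
        df = _two_way_frame(rng, shift_sev=1.0, n=8)
        df["value"] = stats.rankdata(df["value"])
        param = two_way_compare(df.copy(), test_name="two_way_anova")
        ranked = two_way_compare(df.copy(), test_name="rank_two_way_anova")
        for key in param.effects:
            assert param.effects[key][0] == pytest.approx(ranked.effects[key][0], abs=1e-10)

    def test_empty_cell_rejected(self):
        df = _two_way_frame(np.random.default_rng(1), n=4)
        df = df[~((df.pathology == "scoliosis") & (df.severity == "high"))]
        with pytest.raises((DesignError, InsufficientDataError)):
            two_way_compare(df)


class TestSignificanceReport:
    @staticmethod
    def _cohort(rng, effect=0.0, n=12):
        rows = []
        sid = 0
        for group, sev_levels in (
            ("control", ("none",)),
            ("scoliosis", ("low", "high")),
            ("spondylolisthesis", ("low", "high")),
        ):
            for sev in sev_levels:
                for _ in range(n):
                    mu = effect if group != "control" else 0.0
                    rows.append(
                        dict(
                            subject_id=f"S{sid}",
                            group=group,
                            severity=sev,
                            region="AF",
                            normalization="CSF",
                            index="std",
                            value=rng.normal(mu, 1.0),
                        )
                    )
                    sid += 1
        return pd.DataFrame(rows)

    def test_empty_cohort(self):
        assert significance_report(pd.DataFrame()).empty

    def test_strong_effect_is_flagged(self):
        rng = np.random.default_rng(51)
        grid = significance_report(self._cohort(rng, effect=2.0))
        row = grid.loc[("control/scoliosis", "CSF", "AF")]
        assert row["std"] in ("*", "**")

    def test_null_cohort_mostly_unflagged(self):
        rng = np.random.default_rng(52)
        flagged = 0
        reps = 40
        for _ in range(reps):
            grid = significance_report(self._cohort(rng))
            pairwise = grid.loc[
                grid.index.get_level_values("comparison") != "severity low/high", "std"
            ]
            flagged += (pairwise != "").any()
        # an omnibus gate precedes pairwise stars, so false flags stay near alpha
        assert flagged / reps < 0.20

    def test_grid_has_four_comparison_blocks(self):
        rng = np.random.default_rng(53)
        grid = significance_report(self._cohort(rng))
        comparisons = set(grid.index.get_level_values("comparison"))
        assert comparisons == {
            "control/scoliosis",
            "control/spondylolisthesis",
            "scoliosis/spondylolisthesis",
            "severity low/high",
        }
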