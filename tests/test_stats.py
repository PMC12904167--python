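"""Group-comparison statistics against an independent brute-force oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

from myoseries.stats import compare_groups, two_way_anova, two_way_rm_anova


def _fit_rss(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r), int(np.linalg.matrix_rank(X))


def oracle_two_way_type2(df):
    """Type II F statistics from first principles: compare residual sums of
    squares of nested least-squares fits built from raw indicator matrices."""
    y = df["value"].to_numpy(float)
    A = pd.get_dummies(df["a"], drop_first=True).to_numpy(float)
    B = pd.get_dummies(df["b"], drop_first=True).to_numpy(float)
    AB = np.column_stack(
        [A[:, i] * B[:, j] for i in range(A.shape[1]) for j in range(B.shape[1])]
    )
    one = np.ones((len(y), 1))
    rss_full, rank_full = _fit_rss(np.column_stack([one, A, B, AB]), y)
    df_resid = len(y) - rank_full
    mse = rss_full / df_resid
    out = {}
    rss_ab, rank_ab = _fit_rss(np.column_stack([one, A, B]), y)
    rss_b, rank_b = _fit_rss(np.column_stack([one, B]), y)
    rss_a, rank_a = _fit_rss(np.column_stack([one, A]), y)
    out["a"] = ((rss_b - rss_ab) / (rank_ab - rank_b)) / mse
    out["b"] = ((rss_a - rss_ab) / (rank_ab - rank_a)) / mse
    out["ab"] = ((rss_ab - rss_full) / (rank_full - rank_ab)) / mse
    return out


def _random_layout(rng, balanced=False):
    na, nb = int(rng.integers(2, 4)), int(rng.integers(2, 4))
    rows = []
    for a, b in itertools.product(range(na), range(nb)):
        n = 5 if balanced else int(rng.integers(3, 8))
        for v in rng.normal(0.5 * a + 0.2 * b + 0.1 * a * b, 1.0, n):
            rows.append({"a": f"a{a}", "b": f"b{b}", "value": float(v)})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    @pytest.mark.parametrize("trial", range(8))
    def test_f_statistics_match_projection_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        df = _random_layout(rng)
        res = two_way_anova(df, "value", "a", "b")
        orc = oracle_two_way_type2(df)
        assert res.effects["a"]["F"] == pytest.approx(orc["a"], abs=1e-8)
        assert res.effects["b"]["F"] == pytest.approx(orc["b"], abs=1e-8)
        assert res.effects["a:b"]["F"] == pytest.approx(orc["ab"], abs=1e-8)

    def test_balanced_sum_of_squares_decomposition(self):
        """SS_total = SS_A + SS_B + SS_AB + SS_error on a balanced design."""
        rng = np.random.default_rng(5)
        df = _random_layout(rng, balanced=True)
        y = df["value"].to_numpy()
        ss_total = float(((y - y.mean()) ** 2).sum())
        one = np.ones((len(y), 1))
        A = pd.get_dummies(df["a"], drop_first=True).to_numpy(float)
        B = pd.get_dummies(df["b"], drop_first=True).to_numpy(float)
        AB = np.column_stack(
            [A[:, i] * B[:, j] for i in range(A.shape[1]) for j in range(B.shape[1])]
        )
        rss_full, _ = _fit_rss(np.column_stack([one, A, B, AB]), y)
        rss_b, _ = _fit_rss(np.column_stack([one, B]), y)
        rss_a, _ = _fit_rss(np.column_stack([one, A]), y)
        rss_ab, _ = _fit_rss(np.column_stack([one, A, B]), y)
        ss_a = rss_b - rss_ab
        ss_b = rss_a - rss_ab
        ss_inter = rss_ab - rss_full
        rss_null, _ = _fit_rss(one, y)
        assert ss_total == pytest.approx(rss_null)
        assert ss_a + ss_b + ss_inter + rss_full == pytest.approx(
            ss_total, abs=1e-10 * max(1.0, ss_total)
        )

    def test_fisher_lsd_posthocs_present_for_both_factors(self):
        rng = np.random.default_rng(7)
        df = _random_layout(rng)
        res = two_way_anova(df, "value", "a", "b")
        methods = {p["method"] for p in res.posthoc}
        assert methods == {"fisher_lsd"}
        assert any("within a=" in p["comparison"] for p in res.posthoc)
        assert any("within b=" in p["comparison"] for p in res.posthoc)


class TestSimpleDesigns:
    def test_identical_groups_give_t_zero_p_one(self):
        d = pd.DataFrame({"group": ["x"] * 3 + ["y"] * 3, "value": [1, 2, 3, 1, 2, 3]})
        res = compare_groups("t", d)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_paired_differences_plus_minus_one(self):
        d = pd.DataFrame(
            {"group": ["x", "x", "y", "y"], "value": [0.0, 0.0, 1.0, -1.0]}
        )
        res = compare_groups("paired_t", d)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_within_group_variance_raises(self):
        d = pd.DataFrame({"group": ["x"] * 3 + ["y"] * 3, "value": [1.0] * 3 + [2.0] * 3})
        with pytest.raises(ValueError, match="zero within-group variance"):
            compare_groups("t", d)

    def test_one_way_anova_with_tukey(self):
        rng = np.random.default_rng(2)
        d = pd.DataFrame(
            {
                "group": np.repeat(["a", "b", "c"], 8),
                "value": np.concatenate(
                    [rng.normal(m, 1.0, 8) for m in (0.0, 0.5, 2.0)]
                ),
            }
        )
        res = compare_groups("anova1", d)
        assert res.test == "anova1"
        assert len(res.posthoc) == 3
        from scipy.stats import f_oneway

        groups = [g["value"].to_numpy() for _, g in d.groupby("group")]
        assert res.statistic == pytest.approx(f_oneway(*groups).statistic)

    def test_rm_anova_requires_complete_pairs(self):
        d = pd.DataFrame(
            {
                "subject": ["s1", "s1", "s2"],
                "roi_class": ["normal", "disarrayed", "normal"],
                "value": [1.0, 2.0, 1.5],
            }
        )
        with pytest.raises(ValueError, match="complete"):
            two_way_rm_anova(d, "value", "subject", "roi_class")

    def test_rm_anova_detects_within_effect(self):
        rng = np.random.default_rng(4)
        rows = []
        for s in range(8):
            base = rng.normal(0, 1)
            rows.append({"subject": f"s{s}", "roi_class": "normal", "value": base})
            rows.append(
                {"subject": f"s{s}", "roi_class": "disarrayed", "value": base + 2.0 + rng.normal(0, 0.3)}
            )
        res = two_way_rm_anova(pd.DataFrame(rows), "value", "subject", "roi_class")
        assert res.p_value < 0.001
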