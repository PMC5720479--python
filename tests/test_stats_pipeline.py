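"""Inferential battery: t-tests, RM/mixed ANOVA, sphericity, post-hocs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from driftbias.stats_pipeline import (mixed_anova, one_sample_t_vs_zero,
                                      posthoc, results_to_frame, rm_anova,
                                      weekly_means)


class TestOneSampleT:
    def test_all_zeros_is_degenerate(self):
        res = one_sample_t_vs_zero([0.0, 0.0, 0.0])
        assert res.degenerate and np.isnan(res.statistic)

    def test_mean_zero_pair(self):
        res = one_sample_t_vs_zero([1.0, -1.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_matches_scipy(self):
        x = np.random.default_rng(0).normal(0.3, 1, 15)
        res = one_sample_t_vs_zero(x)
        t, p = sps.ttest_1samp(x, 0.0)
        assert res.statistic == pytest.approx(float(t))
        assert res.p == pytest.approx(float(p))

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            one_sample_t_vs_zero([1.0])


def _long(Y, subjects=None, groups=None, factors=("session", "tone")):
    """(N, p[, q]) array -> tidy frame."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 2:
        Y = Y[:, :, None]
    n, p, q = Y.shape
    rows = []
    for s in range(n):
        for i in range(p):
            for j in range(q):
                row = {"subject": f"s{s:02d}", factors[0]: f"l{i}",
                       factors[1]: f"m{j}", "y": Y[s, i, j]}
                if groups is not None:
                    row["group"] = groups[s]
                rows.append(row)
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_constant_within_subject_gives_zero_f(self):
        Y = np.tile(np.arange(6)[:, None], (1, 4)).astype(float)
        res = rm_anova(_long(Y), "y", "session", "subject")
        assert res[0].statistic == pytest.approx(0.0)

    def test_two_levels_have_trivial_sphericity(self):
        rng = np.random.default_rng(5)
        res = rm_anova(_long(rng.normal(size=(8, 2))), "y", "session", "subject")
        assert res[0].epsilon == 1.0
        assert res[0].correction == "none"

    def test_agrees_with_pingouin_glm(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        Y = rng.normal(size=(6, 3)) + rng.normal(size=(6, 1))
        df = _long(Y)
        mine = rm_anova(df, "y", "session", "subject", hf_policy="never")[0]
        ref = pg.rm_anova(data=df, dv="y", within="session", subject="subject")
        assert mine.statistic == pytest.approx(float(ref["F"].iloc[0]), abs=1e-6)
        wide = df.pivot(index="subject", columns="session", values="y")
        assert mine.epsilon == pytest.approx(
            float(pg.epsilon(wide, correction="hf")), abs=1e-9)
        sph = pg.sphericity(df, dv="y", within="session", subject="subject")
        assert mine.sphericity_w == pytest.approx(float(sph.W), abs=1e-9)

    def test_two_way_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(10, 3, 3)) + rng.normal(size=(10, 1, 1))
        df = _long(Y)
        mine = rm_anova(df, "y", ["session", "tone"], "subject",
                        hf_policy="never")
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = pg.rm_anova(data=df, dv="y", within=["session", "tone"],
                              subject="subject")
        for r, (_, row) in zip(mine, ref.iterrows()):
            assert r.statistic == pytest.approx(float(row["F"]), abs=1e-6)

    def test_incomplete_table_rejected(self):
        df = _long(np.random.default_rng(0).normal(size=(5, 3))).iloc[:-1]
        with pytest.raises(ValueError, match="complete"):
            rm_anova(df, "y", "session", "subject")

    def test_hf_correction_shrinks_df(self):
        # strongly non-spherical covariance triggers the HF-corrected df
        rng = np.random.default_rng(11)
        base = rng.normal(size=(12, 1))
        Y = np.hstack([base + rng.normal(0, 0.05, (12, 1)),
                       base + rng.normal(0, 0.05, (12, 1)),
                       rng.normal(0, 3.0, (12, 1)),
                       rng.normal(0, 3.0, (12, 1))])
        res = rm_anova(_long(Y), "y", "session", "subject", hf_policy="always")[0]
        assert res.epsilon < 1.0
        assert res.df[0] == pytest.approx(3 * res.epsilon)


class TestMixedAnova:
    def test_identical_groups_give_zero_group_f(self):
        rng = np.random.default_rng(2)
        Y_half = rng.normal(size=(5, 3))
        Y = np.vstack([Y_half, Y_half])
        groups = ["a"] * 5 + ["b"] * 5
        res = mixed_anova(_long(Y, groups=groups), "y", "session", "subject",
                          "group")
        by_name = {r.effect: r for r in res}
        assert by_name["group"].statistic == pytest.approx(0.0)

    def test_group_f_monotone_in_offset(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(12, 3))
        groups = ["a"] * 6 + ["b"] * 6
        fs = []
        for delta in (0.0, 0.5, 1.0, 2.0):
            Y = base.copy()
            Y[6:] += delta
            res = mixed_anova(_long(Y, groups=groups), "y", "session",
                              "subject", "group")
            fs.append({r.effect: r for r in res}["group"].statistic)
        assert all(b > a for a, b in zip(fs, fs[1:]))

    def test_agrees_with_pingouin_unbalanced(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        Y = rng.normal(size=(11, 3)) + rng.normal(size=(11, 1))
        groups = ["a"] * 6 + ["b"] * 5
        df = _long(Y, groups=groups)
        mine = {r.effect: r for r in mixed_anova(df, "y", "session", "subject",
                                                 "group", hf_policy="never")}
        ref = pg.mixed_anova(data=df, dv="y", within="session",
                             subject="subject", between="group")
        lookup = {"group": "group", "session": "session",
                  "Interaction": "session x group"}
        for _, row in ref.iterrows():
            assert mine[lookup[row["Source"]]].statistic == pytest.approx(
                float(row["F"]), abs=1e-6)

    def test_three_factor_matches_r_aov_oracle(self):
        # frozen F values from R: aov(y ~ grp*session*tone +
        # Error(subj/(session*tone))) on this exact table
        rng = np.random.default_rng(2024)
        rows = []
        for s in range(12):
            grp = "ctl" if s < 6 else "drug"
            b = rng.normal(0.4 if grp == "drug" else 0, 0.8)
            for i, sess in enumerate(["s1", "s2", "s3"]):
                for j, tone in enumerate(["high", "mid", "low"]):
                    rows.append({"subject": f"r{s:02d}", "group": grp,
                                 "session": sess, "tone": tone,
                                 "y": b + 0.3 * i - 0.25 * j + 0.15 * i * j
                                 + (0.2 * i if grp == "drug" else 0)
                                 + rng.normal(0, 0.6)})
        df = pd.DataFrame(rows)
        res = {r.effect: r.statistic
               for r in mixed_anova(df, "y", ["session", "tone"], "subject",
                                    "group", hf_policy="never")}
        expected = {"group": 0.027985, "session": 37.202413,
                    "session x group": 2.60672, "tone": 0.390624,
                    "tone x group": 0.123091, "session x tone": 0.872669,
                    "session x tone x group": 0.660567}
        for effect, f in expected.items():
            assert res[effect] == pytest.approx(f, abs=1e-4), effect

    def test_single_subject_group_rejected(self):
        Y = np.random.default_rng(1).normal(size=(4, 3))
        groups = ["a", "a", "a", "b"]
        with pytest.raises(ValueError, match="at least 2"):
            mixed_anova(_long(Y, groups=groups), "y", "session", "subject",
                        "group")


class TestPosthoc:
    def test_identical_paired_samples(self):
        res = posthoc([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], design="paired")
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        raw = float(sps.ttest_rel(x, y).pvalue)
        res = posthoc(x, y, design="paired", m_comparisons=3)
        assert res.p == pytest.approx(min(1.0, 3 * raw))

    def test_levene_routes_to_welch(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.5, np.sqrt(10), 30)  # 10x variance ratio
        res = posthoc(x, y, design="independent")
        assert "levene-adjusted" in res.correction
        welch = sps.ttest_ind(x, y, equal_var=False)
        assert res.statistic == pytest.approx(float(welch.statistic))

    def test_mismatched_pairs_rejected(self):
        with pytest.raises(ValueError):
            posthoc([1, 2, 3], [1, 2], design="paired")


class TestHelpers:
    def test_weekly_means_averages_session_pairs(self):
        df = pd.DataFrame({"subject": ["s1"] * 4, "session": [1, 2, 3, 4],
                           "cbi": [0.1, 0.3, -0.2, 0.4]})
        out = weekly_means(df, "cbi", "session", "subject")
        np.testing.assert_allclose(out["cbi"], [0.2, 0.1])

    def test_results_frame_columns(self):
        res = one_sample_t_vs_zero([0.1, 0.4, -0.2, 0.3])
        frame = results_to_frame([res])
        assert {"effect", "statistic", "p", "correction"} <= set(frame.columns)
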