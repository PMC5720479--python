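"""Inferential battery for judgement-bias metrics and diffusion parameters.

The battery mirrors a standard SPSS-style repeated-measures workflow:

* one-sample t-tests of change-from-baseline scores against zero,
* repeated-measures ANOVA with one or two within-subject factors
  (session, tone), with Huynh-Feldt correction of the degrees of freedom
  when Mauchly's test indicates a sphericity violation,
* mixed ANOVA adding a between-subjects group factor (split-plot design),
* paired / independent-samples post-hoc t-tests, the independent form
  gated by Levene's test (Welch correction under heteroscedasticity),
  with Bonferroni adjustment for multiple comparisons.

The ANOVA engine computes the classical sums of squares for complete,
balanced within-subject tables directly from cell means; sphericity
epsilons come from the orthonormal-contrast covariance of the
within-subject scores.  Incomplete tables are rejected outright rather
than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert

__all__ = [
    "StatResult",
    "one_sample_t_vs_zero",
    "rm_anova",
    "mixed_anova",
    "posthoc",
    "weekly_means",
    "results_to_frame",
    "ALPHA",
]

#: significance level used throughout the battery
ALPHA = 0.05


@dataclass
class StatResult:
    """One test's outcome: an F or t statistic with (possibly corrected) df."""

    effect: str
    statistic: float
    df: tuple[float, ...]
    p: float
    epsilon: float | None = None
    correction: str = "none"
    sphericity_w: float | None = None
    sphericity_p: float | None = None
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.p) and self.p < ALPHA)


def results_to_frame(results: Sequence[StatResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "effect": r.effect,
        "statistic": r.statistic,
        "df1": r.df[0] if len(r.df) > 0 else np.nan,
        "df2": r.df[1] if len(r.df) > 1 else np.nan,
        "epsilon": np.nan if r.epsilon is None else r.epsilon,
        "p": r.p,
        "correction": r.correction,
        "significant": r.significant,
    } for r in results])


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

def one_sample_t_vs_zero(deltas, effect: str = "delta vs 0") -> StatResult:
    """Two-sided one-sample t-test of change scores against zero."""
    x = np.asarray(deltas, dtype=float)
    if x.size < 2 or not np.isfinite(x).all():
        raise ValueError("need >= 2 finite values")
    if np.ptp(x) == 0.0:
        return StatResult(effect, float("nan"), (x.size - 1,), float("nan"),
                          degenerate=True)
    t, p = sps.ttest_1samp(x, 0.0)
    return StatResult(effect, float(t), (x.size - 1,), float(p))


def posthoc(x, y, design: str = "paired", m_comparisons: int = 1,
            effect: str = "posthoc") -> StatResult:
    """Post-hoc pairwise t-test with Bonferroni adjustment.

    ``design="paired"`` runs a dependent-samples t-test; ``"independent"``
    first applies Levene's test and switches to the Welch (unequal-variance)
    form when variances differ at alpha = 0.05.  The adjusted p-value is
    min(1, m * p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if m_comparisons < 1:
        raise ValueError("m_comparisons must be >= 1")
    correction = []
    if design == "paired":
        if x.size != y.size:
            raise ValueError("paired samples must have equal length")
        if np.ptp(x - y) == 0.0:
            p_adj = 1.0 if np.allclose(x, y) else 0.0
            return StatResult(effect, 0.0 if np.allclose(x, y) else float("inf"),
                              (x.size - 1,), p_adj, correction="bonferroni",
                              degenerate=True)
        t, p = sps.ttest_rel(x, y)
        df = x.size - 1.0
    elif design == "independent":
        lev_stat, lev_p = sps.levene(x, y)
        equal_var = lev_p >= ALPHA
        if not equal_var:
            correction.append("levene-adjusted")
        res = sps.ttest_ind(x, y, equal_var=equal_var)
        t, p = res.statistic, res.pvalue
        df = float(res.df)
    else:
        raise ValueError(f"design must be 'paired' or 'independent', got {design!r}")
    if m_comparisons > 1:
        correction.append("bonferroni")
    return StatResult(effect, float(t), (df,), min(1.0, m_comparisons * float(p)),
                      correction="+".join(correction) or "none")


# ---------------------------------------------------------------------------
# sphericity machinery
# ---------------------------------------------------------------------------

def _effect_scores(Y: np.ndarray, which: str) -> np.ndarray:
    """Orthonormal-contrast scores of one within effect, per subject.

    ``Y`` has shape (N, p, q); ``which`` is "A", "B" or "AB".
    """
    _, p, q = Y.shape
    if which == "A":
        m = Y.mean(axis=2)  # (N, p)
        return m @ helmert(p).T
    if which == "B":
        m = Y.mean(axis=1)
        return m @ helmert(q).T
    ca, cb = helmert(p), helmert(q)
    return np.einsum("ip,npq,jq->nij", ca, Y, cb).reshape(Y.shape[0], -1)


def _sphericity(Z: np.ndarray, group_codes: np.ndarray):
    """Greenhouse-Geisser and Huynh-Feldt epsilons plus Mauchly's test.

    ``Z``: (N, k) contrast scores; covariance pooled within groups with
    N - G error df.  Returns (eps_gg, eps_hf, mauchly_w, mauchly_p).
    """
    n, k = Z.shape
    if k <= 1:
        return 1.0, 1.0, 1.0, 1.0
    groups = np.unique(group_codes)
    n_err = n - groups.size
    Zc = Z.copy()
    for g in groups:
        Zc[group_codes == g] -= Z[group_codes == g].mean(axis=0)
    S = Zc.T @ Zc / n_err
    tr = np.trace(S)
    eps_gg = tr ** 2 / (k * float(np.sum(S * S)))
    num = (n_err + 1) * k * eps_gg - 2.0
    den = k * (n_err - k * eps_gg)
    eps_hf = min(1.0, num / den) if den > 0 else 1.0
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0 or n_err <= k:
        return eps_gg, eps_hf, 0.0, float("nan")
    log_w = logdet - k * np.log(tr / k)
    chi2 = -(n_err - (2 * k ** 2 + k + 2) / (6.0 * k)) * log_w
    df = k * (k + 1) // 2 - 1
    p = float(sps.chi2.sf(chi2, df))
    return eps_gg, eps_hf, float(np.exp(log_w)), p


# ---------------------------------------------------------------------------
# ANOVA engine for complete balanced within-subject tables
# ---------------------------------------------------------------------------

def _f_result(effect, ss, df1, ss_err, df2, eps_info, hf_policy) -> StatResult:
    ms = ss / df1
    ms_err = ss_err / df2 if df2 > 0 else float("nan")
    f = ms / ms_err if ms_err > 0 else 0.0
    eps_gg, eps_hf, w, w_p = eps_info
    apply_hf = hf_policy == "always" or (
        hf_policy == "auto" and np.isfinite(w_p) and w_p < ALPHA)
    if apply_hf and eps_hf < 1.0:
        d1, d2 = df1 * eps_hf, df2 * eps_hf
        correction = "HF"
    else:
        d1, d2 = float(df1), float(df2)
        correction = "none"
    p = float(sps.f.sf(f, d1, d2)) if d2 > 0 and np.isfinite(f) else float("nan")
    return StatResult(effect, float(f), (d1, d2), p, epsilon=eps_hf,
                      correction=correction, sphericity_w=w, sphericity_p=w_p)


def _anova_engine(Y: np.ndarray, group_codes: np.ndarray, names: dict,
                  hf_policy: str) -> list[StatResult]:
    """Classical split-plot sums of squares from cell means.

    ``Y``: (N, p, q) complete table; strata are subject (between), A x
    subject, B x subject and A x B x subject, each the error term for the
    effects it contains.
    """
    n, p, q = Y.shape
    groups, counts = np.unique(group_codes, return_counts=True)
    g_count = groups.size
    grand = Y.mean()
    subj = Y.mean(axis=(1, 2))
    g_m = np.array([Y[group_codes == g].mean() for g in groups])
    g_of = np.searchsorted(groups, group_codes)

    results: list[StatResult] = []

    if g_count > 1:
        ss_g = p * q * float(np.sum(counts * (g_m - grand) ** 2))
        ss_s = p * q * float(np.sum((subj - g_m[g_of]) ** 2))
        results.append(_f_result(names["G"], ss_g, g_count - 1, ss_s,
                                 n - g_count, (1.0, 1.0, 1.0, float("nan")),
                                 "never"))

    def one_within(name, sub_cells, mult, which):
        """Main effect, group interaction and error for one within stratum.

        ``sub_cells``: (N, k) per-subject scores whose k cells carry the
        effect (marginal means for A and B, double-centred residuals for
        A x B, where the effect deviation is the population mean itself).
        """
        df1 = sub_cells.shape[1] - 1 if which != "AB" else (p - 1) * (q - 1)
        pop = sub_cells.mean(axis=0)
        eff_dev = pop - grand if which != "AB" else pop
        ss_eff = n * mult * float(np.sum(eff_dev ** 2))
        g_cells = np.array([sub_cells[group_codes == g].mean(axis=0)
                            for g in groups])
        if which == "AB":
            g_dev = g_cells - pop[None, :]
            s_dev = sub_cells - g_cells[g_of]
        else:
            g_dev = g_cells - g_m[:, None] - pop[None, :] + grand
            s_dev = sub_cells - subj[:, None] - g_cells[g_of] + g_m[g_of, None]
        ss_int = mult * float(np.sum(counts[:, None] * g_dev ** 2))
        ss_err = mult * float(np.sum(s_dev ** 2))
        df_err = df1 * (n - g_count)
        eps_info = _sphericity(_effect_scores(Y, which), group_codes)
        results.append(_f_result(name, ss_eff, df1, ss_err, df_err,
                                 eps_info, hf_policy))
        if g_count > 1:
            results.append(_f_result(f"{name} x {names['G']}", ss_int,
                                     df1 * (g_count - 1), ss_err, df_err,
                                     eps_info, hf_policy))

    if p > 1:
        one_within(names["A"], Y.mean(axis=2), q, "A")
    if q > 1:
        one_within(names["B"], Y.mean(axis=1), p, "B")
    if p > 1 and q > 1:
        # double-centred within-subject residuals carry the A x B effect
        resid = (Y - Y.mean(axis=2, keepdims=True) - Y.mean(axis=1, keepdims=True)
                 + subj[:, None, None]).reshape(n, p * q)
        one_within(names["AB"], resid, 1, "AB")
    return results


def _pivot(data: pd.DataFrame, dv: str, within: list[str], subject: str):
    """Long table -> (N, p, q) array; rejects missing or duplicated cells."""
    cols = [subject] + within
    if data[cols + [dv]].isna().any().any():
        raise ValueError("missing values in the design columns or dv")
    dup = data.duplicated(subset=cols)
    if dup.any():
        raise ValueError("duplicated subject x within cells; aggregate first")
    wide = data.pivot(index=subject, columns=within, values=dv)
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(f"incomplete within-subject table for subjects {bad}; "
                         "the design must be complete and balanced")
    levels = [data[w].drop_duplicates().tolist() for w in within]
    shape = tuple(len(lv) for lv in levels)
    subjects = wide.index.to_numpy()
    Y = wide.to_numpy(dtype=float).reshape((len(subjects),) + shape)
    if len(within) == 1:
        Y = Y[:, :, None]
    return Y, subjects


def rm_anova(data: pd.DataFrame, dv: str, within, subject: str,
             hf_policy: str = "auto") -> list[StatResult]:
    """Repeated-measures ANOVA with one or two within-subject factors.

    ``hf_policy`` controls the Huynh-Feldt df correction: ``"auto"`` applies
    it when Mauchly's test rejects sphericity at alpha = 0.05, ``"always"``
    applies it unconditionally, ``"never"`` reports uncorrected df.  The HF
    epsilon and Mauchly statistics are recorded in every case.
    """
    within = [within] if isinstance(within, str) else list(within)
    if not 1 <= len(within) <= 2:
        raise ValueError("rm_anova supports 1 or 2 within factors")
    Y, subjects = _pivot(data, dv, within, subject)
    names = {"A": within[0], "B": within[1] if len(within) > 1 else "w2",
             "AB": None, "G": "group"}
    names["AB"] = f"{names['A']} x {names['B']}"
    return _anova_engine(Y, np.zeros(len(subjects), dtype=int), names, hf_policy)


def mixed_anova(data: pd.DataFrame, dv: str, within, subject: str,
                between: str, hf_policy: str = "auto") -> list[StatResult]:
    """Split-plot ANOVA: within factor(s) crossed with a between-subjects
    group factor; within effects use the HF policy of :func:`rm_anova`."""
    within = [within] if isinstance(within, str) else list(within)
    if not 1 <= len(within) <= 2:
        raise ValueError("mixed_anova supports 1 or 2 within factors")
    Y, subjects = _pivot(data, dv, within, subject)
    grp_of = data.drop_duplicates(subset=[subject]).set_index(subject)[between]
    if grp_of.index.duplicated().any() or (
            data.groupby(subject)[between].nunique() > 1).any():
        raise ValueError("each subject must belong to exactly one group")
    labels = grp_of.loc[subjects].to_numpy()
    _, codes, counts = np.unique(labels, return_inverse=True, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 subjects")
    names = {"A": within[0], "B": within[1] if len(within) > 1 else "w2",
             "AB": None, "G": between}
    names["AB"] = f"{names['A']} x {names['B']}"
    return _anova_engine(Y, codes, names, hf_policy)


# ---------------------------------------------------------------------------
# chronic-study helper
# ---------------------------------------------------------------------------

def weekly_means(data: pd.DataFrame, dv: str, session: str, subject: str,
                 sessions_per_week: int = 2) -> pd.DataFrame:
    """Average consecutive probe sessions into weekly scores per subject.

    Sessions are ordered by their column value within each subject and
    grouped into blocks of ``sessions_per_week`` (the twice-weekly probe
    design); the block mean becomes the weekly value.
    """
    out = data.sort_values([subject, session]).copy()
    out["week"] = out.groupby(subject).cumcount() // sessions_per_week + 1
    return (out.groupby([subject, "week"], as_index=False)[dv].mean())
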