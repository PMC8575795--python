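"""Univariate statistics and effect sizes for pre/post treatment designs.

Covers the quantitative layer of the analysis: two-tailed paired t tests
with 95% CIs and difference-score Cohen's d (d = t / sqrt(n)), one-way
repeated-measures ANOVA with partial eta-squared, Pearson correlation
tests, and the default JZS Bayes factor (Cauchy prior, scale sqrt(2)/2)
used to quantify evidence for null effects.

Sign convention: differences are pre - post, so a positive t statistic
means the score *decreased* — an improvement for symptom counts such as
depression severity or perseverative errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate
from scipy import stats as sps

__all__ = [
    "StatResult",
    "paired_t",
    "cohens_d_from_t",
    "rm_anova_oneway",
    "partial_eta_sq",
    "pearson_test",
    "bayes_factor_paired",
    "delta_scores",
]

DEFAULT_PRIOR_SCALE = float(np.sqrt(2.0) / 2.0)


@dataclass
class StatResult:
    statistic: float
    df: float | tuple[float, float]
    p: float
    effect_size: float | None = None
    effect_size_name: str = ""
    ci95: tuple[float, float] | None = None
    bf10: float | None = None
    n: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p outside [0, 1]")
        if self.ci95 is not None and self.ci95[0] > self.ci95[1]:
            raise ValueError("CI lower bound exceeds upper bound")

    def summary(self) -> dict:
        out = {"statistic": round(float(self.statistic), 4), "df": self.df,
               "p": float(self.p), "n": self.n}
        if self.effect_size is not None:
            out[self.effect_size_name or "effect_size"] = round(
                float(self.effect_size), 4)
        if self.ci95 is not None:
            out["ci95"] = [round(float(v), 4) for v in self.ci95]
        if self.bf10 is not None:
            out["bf10"] = round(float(self.bf10), 4)
        return out


def _aligned_pair(pre, post):
    pre = np.asarray(pre, dtype=float).ravel()
    post = np.asarray(post, dtype=float).ravel()
    if pre.size != post.size:
        raise ValueError("pre and post must be aligned pairs")
    ok = np.isfinite(pre) & np.isfinite(post)
    return pre[ok], post[ok]


def paired_t(pre, post) -> StatResult:
    """Two-tailed paired t test on differences d = pre - post.

    Reports df = n-1, the 95% CI of the mean difference, and the
    difference-score Cohen's d = t / sqrt(n).
    """
    pre, post = _aligned_pair(pre, post)
    n = pre.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = pre - post
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences")
    se = sd / np.sqrt(n)
    t = float(diff.mean() / se)
    df = n - 1
    p = float(2.0 * sps.t.sf(abs(t), df))
    crit = sps.t.ppf(0.975, df)
    ci = (float(diff.mean() - crit * se), float(diff.mean() + crit * se))
    return StatResult(statistic=t, df=df, p=p,
                      effect_size=cohens_d_from_t(t, n, rounded=False),
                      effect_size_name="cohens_d", ci95=ci, n=n)


def cohens_d_from_t(t: float, n: int, rounded: bool = True) -> float:
    """Difference-score Cohen's d for a paired design: d = t / sqrt(n)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    d = float(t) / np.sqrt(n)
    return float(round(d, 2)) if rounded else float(d)


def rm_anova_oneway(data: pd.DataFrame | np.ndarray) -> StatResult:
    """One-way repeated-measures ANOVA on a participants x conditions table.

    F = MS_condition / MS_(condition x participant), df = (k-1, (k-1)(n-1)),
    uncorrected (no sphericity adjustment), with partial eta-squared
    attached.  Rows with any missing condition are dropped listwise.
    """
    x = (data.to_numpy(dtype=float) if isinstance(data, pd.DataFrame)
         else np.asarray(data, dtype=float))
    x = x[np.all(np.isfinite(x), axis=1)]
    n, k = x.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    if n < 2:
        raise ValueError("need at least 2 complete cases")
    grand = x.mean()
    cond_means = x.mean(axis=0)
    subj_means = x.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    f = float(ms_cond / ms_err) if ms_err > 0 else (
        0.0 if ss_cond == 0 else np.inf)
    p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return StatResult(statistic=f, df=(df1, df2), p=p,
                      effect_size=partial_eta_sq(f, df1, df2),
                      effect_size_name="partial_eta_sq", n=n)


def partial_eta_sq(f: float, df1: int, df2: int) -> float:
    """Partial eta-squared from an F ratio: F*df1 / (F*df1 + df2)."""
    if f < 0 or df1 <= 0 or df2 <= 0:
        raise ValueError("need F >= 0 and positive dfs")
    if not np.isfinite(f):
        return 1.0
    return float(f * df1 / (f * df1 + df2))


def pearson_test(x, y) -> StatResult:
    """Pearson correlation with two-tailed p via t = r*sqrt(df/(1-r^2))."""
    x, y = _aligned_pair(x, y)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        p = float(np.finfo(float).tiny)
    else:
        t = r * np.sqrt(df / (1.0 - r ** 2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return StatResult(statistic=r, df=df, p=p, effect_size=r,
                      effect_size_name="r", n=n)


# ---------------------------------------------------------------------------
# JZS Bayes factor
# ---------------------------------------------------------------------------

def _jzs_bf10_from_t(t: float, n: int, prior_scale: float) -> float:
    """One-sample JZS Bayes factor by quadrature over the Cauchy mixture.

    BF10 = integral over g of the marginal likelihood under effect-size
    prior delta ~ Cauchy(0, r), expressed with g ~ InvGamma(1/2, r^2/2),
    divided by the point-null likelihood.
    """
    nu = n - 1

    def null_like() -> float:
        return (1.0 + t ** 2 / nu) ** (-(nu + 1) / 2.0)

    def integrand(g: float) -> float:
        m = (1.0 + n * g) ** (-0.5) * (
            1.0 + t ** 2 / ((1.0 + n * g) * nu)) ** (-(nu + 1) / 2.0)
        prior = sps.invgamma.pdf(g, 0.5, scale=prior_scale ** 2 / 2.0)
        return m * prior

    num, err = integrate.quad(integrand, 0, np.inf, limit=200)
    if not np.isfinite(num) or (num > 0 and err / num > 1e-4):
        raise RuntimeError(
            f"Bayes-factor quadrature failed (value={num}, abserr={err})")
    return float(num / null_like())


def bayes_factor_paired(pre, post,
                        prior_scale: float = DEFAULT_PRIOR_SCALE) -> float:
    """JZS BF10 for a paired contrast (one-sample test on differences).

    BF10 < 1 supports the null of no pre/post change.
    """
    res = paired_t(pre, post)
    return _jzs_bf10_from_t(res.statistic, res.n, prior_scale)


# ---------------------------------------------------------------------------
# change scores
# ---------------------------------------------------------------------------

def delta_scores(behavior: pd.DataFrame, from_timepoint: str,
                 to_timepoint: str, measure: str) -> pd.Series:
    """Per-participant change = from - to (decrease = improvement).

    Participants missing either timepoint are dropped listwise; the result
    is indexed by participant_id.
    """
    required = {"participant_id", "timepoint", measure}
    missing = required - set(behavior.columns)
    if missing:
        raise ValueError(f"behavior table missing columns: {sorted(missing)}")
    wide = behavior.pivot_table(index="participant_id", columns="timepoint",
                                values=measure, aggfunc="first")
    for tp in (from_timepoint, to_timepoint):
        if tp not in wide.columns:
            raise ValueError(f"timepoint {tp!r} absent from behavior table")
    delta = (wide[from_timepoint] - wide[to_timepoint]).dropna()
    delta.name = f"delta_{measure}_{from_timepoint}_{to_timepoint}"
    return delta
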