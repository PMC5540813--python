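"""Random-effects meta-analysis of per-site summary statistics.

Pools per-site effects (mean residualised-AI group differences, or per-year
age coefficients) by DerSimonian-Laird inverse-variance weighting, with
Cochran's Q, Higgins' I^2, Rosenberg's weighted fail-safe N, the per-group
inclusion filters, and the weighted meta-regression of age coefficients on
site median ages.

The DL estimator: with fixed-effect weights w_i = 1/se_i^2,

    Q    = sum w_i (y_i - ybar_w)^2
    tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))
    w*_i = 1 / (se_i^2 + tau2),  pooled = sum w* y / sum w*,
    se   = 1 / sqrt(sum w*),     z = pooled / se  (two-sided normal p).

When tau2 = 0 this reduces exactly to the fixed-effect analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "MetaResult",
    "RandomEffectsMeta",
    "random_effects_pool",
    "higgins_i2",
    "rosenberg_failsafe",
    "filter_datasets",
    "weighted_meta_regression",
    "bonferroni_alpha",
    "pool_summaries",
]


def higgins_i2(q: float, k: int) -> float:
    """Higgins' I^2 in percent: max(0, (Q - (k-1)) / Q) * 100.

    Zero whenever the heterogeneity statistic Q falls at or below its
    degrees of freedom k-1 (and by convention when Q = 0).
    """
    if q < 0:
        raise ValueError("Q must be non-negative")
    if k < 2:
        raise ValueError("need at least 2 studies")
    if q == 0.0:
        return 0.0
    return max(0.0, (q - (k - 1)) / q) * 100.0


def bonferroni_alpha(n_tests: int = 7, family_alpha: float = 0.05) -> float:
    """Bonferroni-adjusted per-test alpha (0.05/7 ~ 0.00714 for the seven
    structures, conventionally reported as 0.007)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return family_alpha / n_tests


@dataclass
class MetaResult:
    effect: float
    se: float
    z: float
    p: float
    tau2: float
    q: float
    q_df: int
    q_p: float
    i2: float
    k: int
    n_total: int = 0
    failsafe_n: int | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


class RandomEffectsMeta(BaseEstimator):
    """DerSimonian-Laird random-effects pooling as an estimator.

    Parameters
    ----------
    alpha : float
        Significance level used for the fail-safe N computation.
    compute_failsafe : bool
        Whether to attach Rosenberg's weighted fail-safe N after fitting.

    Attributes (after ``fit(y, se)``)
    ---------------------------------
    effect_, se_, z_, p_ : pooled effect and its normal-theory test
    tau2_ : between-study variance (DL moment estimator, floored at 0)
    q_, q_df_, q_p_ : Cochran's Q against chi^2 on k-1 df
    i2_ : Higgins' I^2 in percent
    weights_ : random-effects weights w*_i (normalized to sum 1)
    failsafe_n_ : Rosenberg fail-safe N (None unless requested)
    """

    def __init__(self, alpha: float = 0.007, compute_failsafe: bool = False):
        self.alpha = alpha
        self.compute_failsafe = compute_failsafe

    def fit(self, y, se, n=None):
        y = np.asarray(y, dtype=float)
        se = np.asarray(se, dtype=float)
        if y.shape != se.shape or y.ndim != 1:
            raise ValueError("y and se must be 1-d arrays of equal length")
        k = len(y)
        if k < 2:
            raise ValueError("need at least 2 studies to pool")
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(se)):
            raise ValueError("effects and standard errors must be finite")
        if np.any(se <= 0):
            raise ValueError("all standard errors must be positive")
        w = 1.0 / se**2
        ybar = np.sum(w * y) / np.sum(w)
        q = float(np.sum(w * (y - ybar) ** 2))
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
        wstar = 1.0 / (se**2 + tau2)
        self.k_ = k
        self.tau2_ = float(tau2)
        self.q_ = q
        self.q_df_ = k - 1
        self.q_p_ = float(stats.chi2.sf(q, k - 1))
        self.i2_ = higgins_i2(q, k)
        self.effect_ = float(np.sum(wstar * y) / np.sum(wstar))
        self.se_ = float(1.0 / math.sqrt(np.sum(wstar)))
        self.z_ = self.effect_ / self.se_
        self.p_ = float(2.0 * stats.norm.sf(abs(self.z_)))
        self.weights_ = wstar / np.sum(wstar)
        self.n_total_ = int(np.sum(n)) if n is not None else 0
        self.failsafe_n_ = (
            rosenberg_failsafe(y, se, alpha=self.alpha)
            if self.compute_failsafe else None
        )
        return self

    def result_(self) -> MetaResult:
        return MetaResult(
            effect=self.effect_, se=self.se_, z=self.z_, p=self.p_,
            tau2=self.tau2_, q=self.q_, q_df=self.q_df_, q_p=self.q_p_,
            i2=self.i2_, k=self.k_, n_total=self.n_total_,
            failsafe_n=self.failsafe_n_,
        )


def random_effects_pool(y, se, n=None, *, alpha: float = 0.007,
                        compute_failsafe: bool = True) -> MetaResult:
    """Functional wrapper around :class:`RandomEffectsMeta`."""
    est = RandomEffectsMeta(alpha=alpha, compute_failsafe=compute_failsafe)
    return est.fit(y, se, n=n).result_()


def rosenberg_failsafe(y, se, *, alpha: float = 0.007, max_n: int = 10**7) -> int:
    """Rosenberg's weighted fail-safe N.

    The smallest integer m of hypothetical null studies — each with effect 0
    and weight equal to the mean observed fixed-effect weight — whose
    addition drives the fixed-effect pooled two-sided p to alpha or above.
    Returns 0 when the observed pooled p is already >= alpha.

    With S = sum w_i y_i and W = sum w_i, adding m mean-weight (wbar) null
    studies gives z(m) = S / sqrt(W + m*wbar); the threshold solves
    z(m)^2 <= z_alpha^2 in closed form, then is verified by stepping, so the
    returned count always matches the incremental definition.
    """
    y = np.asarray(y, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / se**2
    s, wsum = float(np.sum(w * y)), float(np.sum(w))
    wbar = wsum / len(y)

    def pooled_p(m):
        z = s / math.sqrt(wsum + m * wbar)
        return 2.0 * stats.norm.sf(abs(z))

    if pooled_p(0) >= alpha:
        return 0
    zcrit = stats.norm.isf(alpha / 2.0)
    m = max(0, math.ceil((s**2 / zcrit**2 - wsum) / wbar))
    while m > 0 and pooled_p(m - 1) >= alpha:  # guard against ceil overshoot
        m -= 1
    while pooled_p(m) < alpha:
        m += 1
        if m > max_n:
            raise RuntimeError("fail-safe N search exceeded max_n")
    return m


def filter_datasets(df: pd.DataFrame, *, min_per_group: int = 15,
                    min_iqr_years: float | None = None) -> pd.DataFrame:
    """Apply the meta-analysis inclusion filters to summary rows.

    Keeps rows where every contrast group has at least ``min_per_group``
    observations (for one-group contrasts such as the age ANCOVA, both sex
    groups must pass, since the model adjusts for sex). When
    ``min_iqr_years`` is given (the age analyses), the site's age IQR width
    (Q3 - Q1) must also reach it. Raises if nothing survives.
    """
    def keep(row):
        if row["contrast"] in ("sex", "age"):
            if row["n_male"] < min_per_group or row["n_female"] < min_per_group:
                return False
        elif row["contrast"] == "handedness":
            if row["n_left"] < min_per_group or row["n_right"] < min_per_group:
                return False
        else:  # one-sample lateralization per sex
            if row["n_group1"] < min_per_group:
                return False
        if min_iqr_years is not None and row["age_iqr"] < min_iqr_years:
            return False
        return True

    out = df[df.apply(keep, axis=1)]
    if out.empty:
        raise ValueError(
            "no datasets survive the inclusion filters "
            f"(min_per_group={min_per_group}, min_iqr_years={min_iqr_years})"
        )
    return out


def weighted_meta_regression(coefs, median_ages, n):
    """Weighted least-squares regression of per-site age coefficients on
    site median ages, weighted by sqrt(sample size); returns
    (slope, se, p)."""
    import statsmodels.api as sm

    coefs = np.asarray(coefs, dtype=float)
    ages = np.asarray(median_ages, dtype=float)
    n = np.asarray(n, dtype=float)
    if len(coefs) < 3:
        raise ValueError("need at least 3 sites for meta-regression")
    if np.ptp(ages) == 0.0:
        raise ValueError("median ages are all equal; slope not identifiable")
    X = sm.add_constant(ages)
    fit = sm.WLS(coefs, X, weights=np.sqrt(n)).fit()
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])


@dataclass
class PoolingRules:
    """Which filters apply to each contrast."""
    min_per_group: int = 15
    min_iqr_years: float = 5.0
    alpha: float = 0.007
    use_ci_reconstruction: bool = True


def pool_summaries(summaries: pd.DataFrame, *, contrast: str,
                   rules: PoolingRules | None = None,
                   structures=None) -> pd.DataFrame:
    """Pool per-site summary rows into one MetaResult per structure.

    For the Welch-based contrasts (sex, handedness) the per-site SE is
    reconstructed from the 95% CI and Welch df — the form in which sites
    share their results — via ``se_from_ci``; the age contrast uses the
    ANCOVA SE directly. The age contrast additionally applies the
    minimum-age-IQR inclusion rule.
    """
    from .site import se_from_ci

    rules = rules or PoolingRules()
    rows = summaries[summaries["contrast"] == contrast]
    if rows.empty:
        raise ValueError(f"no summary rows for contrast {contrast!r}")
    iqr = rules.min_iqr_years if contrast == "age" else None
    rows = filter_datasets(rows, min_per_group=rules.min_per_group,
                           min_iqr_years=iqr)
    out = []
    for s in structures or rows["structure"].unique():
        sub = rows[rows["structure"] == s]
        if len(sub) < 2:
            continue
        if contrast in ("sex", "handedness") and rules.use_ci_reconstruction:
            se = np.array([
                se_from_ci(r.ci_low, r.ci_high, r.df)
                for r in sub.itertuples()
            ])
        else:
            se = sub["se"].to_numpy()
        n = (sub["n_group1"] + sub["n_group2"]).to_numpy()
        res = random_effects_pool(sub["effect"].to_numpy(), se, n,
                                  alpha=rules.alpha)
        out.append({"structure": s, "contrast": contrast, **res.to_dict()})
    return pd.DataFrame(out)
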