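"""Within-site stage: asymmetry indices, adaptive outlier exclusion,
covariate residualization and the per-site summary statistics that cross the
site-to-meta-analysis boundary.

Only the summary rows produced here leave a site; the meta-analysis stage
never sees subject-level data. That federation contract is why each
operation is careful to emit everything the pooling stage needs (effect,
CI + degrees of freedom, group counts, median age and age IQR width, and
the segmentation-software version label).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla, stats
from sklearn.base import BaseEstimator, TransformerMixin

from .structures import STRUCTURES

__all__ = [
    "compute_ai",
    "sd_threshold",
    "exclude_outliers",
    "residualize",
    "CovariateResidualizer",
    "welch_test",
    "ancova_age",
    "one_sample_lateralization",
    "se_from_ci",
    "summarize_site",
    "WelchResult",
]


def compute_ai(left, right):
    """Asymmetry index (L - R) / (L + R), elementwise.

    Positive values mean the left structure is larger. Defined only for
    non-negative volumes with a positive bilateral total; violations raise.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if np.any(left < 0) or np.any(right < 0):
        raise ValueError("volumes must be non-negative")
    total = left + right
    if np.any(total <= 0):
        raise ValueError("left + right must be positive to define an AI")
    return (left - right) / total


def sd_threshold(n: int) -> float:
    """Adaptive SD multiplier for outlier exclusion as a function of sample
    size: 2.5 below 150, 3.0 from 150 to 1000 inclusive, 3.5 above 1000."""
    if n < 1:
        raise ValueError("sample size must be >= 1")
    if n < 150:
        return 2.5
    if n <= 1000:
        return 3.0
    return 3.5


def exclude_outliers(values, threshold: float) -> np.ndarray:
    """Inclusion mask: True where |x - mean| <= threshold * SD.

    Mean and SD come from a single pass over all finite values (the rule is
    non-iterative). Non-finite entries are excluded. A zero-variance vector
    keeps every finite entry.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError("need at least 2 finite values")
    mu = x[finite].mean()
    sd = x[finite].std(ddof=1)
    if sd == 0.0:
        return finite
    return finite & (np.abs(x - mu) <= threshold * sd)


def _design(covariates, add_intercept=True):
    X = np.column_stack([np.asarray(c, dtype=float) for c in covariates])
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
    return X


def _check_full_rank(X, names):
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via pivoted QR
        _, r, piv = sla.qr(X, pivoting=True, mode="economic")
        diag = np.abs(np.diag(r))
        bad = [names[j] for j in piv[rank:]] if len(diag) else names
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def residualize(y, covariates, names=None):
    """OLS residuals of y on [1, covariates]; residual mean is 0 to machine
    precision. Raises naming the collinear columns on a rank-deficient
    design."""
    y = np.asarray(y, dtype=float)
    X = _design(covariates)
    names = ["intercept"] + list(
        names if names is not None else [f"x{i}" for i in range(X.shape[1] - 1)]
    )
    if len(y) != X.shape[0]:
        raise ValueError("y and covariates must have the same length")
    _check_full_rank(X, names)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


class CovariateResidualizer(TransformerMixin, BaseEstimator):
    """Transformer removing linear covariate effects from each column of X.

    ``fit(X, y=None, covariates=C)`` learns OLS coefficients of every column
    of X on [1, C]; ``transform`` subtracts the fitted values. Useful for
    residualizing AIs on age/ICV (and sex, for handedness contrasts) before
    group tests, matching the two-step residualize-then-test protocol.
    """

    def fit(self, X, y=None, *, covariates):
        X = np.atleast_2d(np.asarray(X, dtype=float).T).T
        C = _design(covariates)
        _check_full_rank(C, [f"c{i}" for i in range(C.shape[1])])
        self.coef_, *_ = np.linalg.lstsq(C, X, rcond=None)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, *, covariates):
        X = np.atleast_2d(np.asarray(X, dtype=float).T).T
        C = _design(covariates)
        return X - C @ self.coef_


@dataclass
class WelchResult:
    mean_diff: float
    se: float
    t: float
    df: float
    p: float
    ci_low: float
    ci_high: float


def welch_test(a, b, *, alpha: float = 0.05) -> WelchResult:
    """Welch two-sample t-test (unequal variances, Satterthwaite df) of
    mean(a) - mean(b), with the (1-alpha) CI from the t quantile at the
    Welch df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        raise ValueError("both groups have zero variance; Welch test undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    se = math.sqrt(va / len(a) + vb / len(b))
    diff = a.mean() - b.mean()
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, res.df)
    return WelchResult(
        mean_diff=diff,
        se=se,
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        ci_low=diff - tcrit * se,
        ci_high=diff + tcrit * se,
    )


def ancova_age(ai, age, sex, icv):
    """Per-year age coefficient on the AI from the linear model
    AI ~ 1 + age + sex + ICV; returns (coef, se, p)."""
    import statsmodels.api as sm

    age = np.asarray(age, dtype=float)
    if np.ptp(age) == 0.0:
        raise ValueError("age is constant; its coefficient is not identifiable")
    sex_num = _encode_sex(sex)
    X = sm.add_constant(
        np.column_stack([age, sex_num, np.asarray(icv, dtype=float)])
    )
    _check_full_rank(X, ["intercept", "age", "sex", "icv"])
    fit = sm.OLS(np.asarray(ai, dtype=float), X).fit()
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])


def _encode_sex(sex):
    sex = np.asarray(sex)
    if sex.dtype.kind in "OUS":
        return (sex == "M").astype(float)
    return sex.astype(float)


def one_sample_lateralization(ai):
    """One-sample t-test of the mean AI against zero (the point of
    volumetric symmetry); returns (mean, t, p)."""
    ai = np.asarray(ai, dtype=float)
    if len(ai) < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(ai) == 0.0:  # constant vector, robust to mean round-off
        raise ValueError("zero variance; t statistic undefined")
    res = stats.ttest_1samp(ai, 0.0)
    return float(ai.mean()), float(res.statistic), float(res.pvalue)


def se_from_ci(ci_low: float, ci_high: float, df: float) -> float:
    """Standard error reconstructed from a 95% CI and its degrees of
    freedom: (upper - lower) / (2 * t_{0.975, df})."""
    if ci_high <= ci_low:
        raise ValueError("CI upper bound must exceed lower bound")
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return (ci_high - ci_low) / (2.0 * stats.t.ppf(0.975, df))


# ---------------------------------------------------------------------------
# Site summary


def _structure_frame(table: pd.DataFrame, structure: str) -> pd.DataFrame:
    lcol, rcol = f"{structure}_L_mm3", f"{structure}_R_mm3"
    sub = table[["sex", "age_years", "handedness", "icv_mm3", lcol, rcol]].copy()
    sub = sub.dropna(subset=[lcol, rcol])
    sub = sub[(sub[lcol] + sub[rcol]) > 0]
    sub["ai"] = compute_ai(sub[lcol].to_numpy(), sub[rcol].to_numpy())
    return sub.rename(columns={lcol: "left", rcol: "right"})


def summarize_site(
    table: pd.DataFrame,
    *,
    site_id: str | None = None,
    freesurfer_version: str | None = None,
    structures=STRUCTURES,
) -> pd.DataFrame:
    """Compute the full per-site summary: one row per structure x contrast.

    Per structure, the pipeline is: compute AIs; apply the adaptive-SD
    exclusion jointly to the left volume, right volume and AI columns (a
    subject is dropped for that structure if any of the three flags it);
    then run the group contrasts on residualised AIs (sex contrast adjusts
    for age + ICV; handedness additionally for sex), the age ANCOVA
    (AI ~ age + sex + ICV) and per-sex one-sample lateralization tests on
    the raw AIs.

    Contrast rows: ``sex`` (male - female), ``handedness`` (left - right
    handers), ``age`` (per-year slope), ``lateralization_M`` /
    ``lateralization_F`` (mean AI vs zero). Columns effect/se/t/df/p/
    ci_low/ci_high plus group counts, median age, age IQR width and the
    version label — exactly the payload a site shares for pooling.
    """
    site_id = site_id or table.attrs.get("site_id", "site")
    version = freesurfer_version or table.attrs.get("freesurfer_version", "unknown")
    rows = []
    for s in structures:
        sub = _structure_frame(table, s)
        n0 = len(sub)
        if n0 < 4:
            continue
        thresh = sd_threshold(n0)
        mask = (
            exclude_outliers(sub["left"], thresh)
            & exclude_outliers(sub["right"], thresh)
            & exclude_outliers(sub["ai"], thresh)
        )
        sub = sub[mask]
        male = sub["sex"] == "M"
        left_h = sub["handedness"] == "L"
        right_h = sub["handedness"] == "R"
        median_age = float(sub["age_years"].median())
        q1, q3 = sub["age_years"].quantile([0.25, 0.75])
        iqr = float(q3 - q1)
        common = dict(
            site_id=site_id, structure=s, freesurfer_version=version,
            n_total=len(sub), n_excluded=n0 - len(sub),
            n_male=int(male.sum()), n_female=int((~male).sum()),
            n_left=int(left_h.sum()), n_right=int(right_h.sum()),
            median_age=median_age, age_iqr=iqr,
        )

        def add(contrast, n1, n2, **kw):
            rows.append({**common, "contrast": contrast,
                         "n_group1": n1, "n_group2": n2, **kw})

        ai = sub["ai"].to_numpy()
        age = sub["age_years"].to_numpy()
        icv = sub["icv_mm3"].to_numpy()
        sexn = male.to_numpy().astype(float)

        # sex contrast on AIs residualised for age + ICV
        if male.sum() >= 2 and (~male).sum() >= 2:
            try:
                resid = residualize(ai, [age, icv], names=["age", "icv"])
                w = welch_test(resid[male.to_numpy()], resid[~male.to_numpy()])
                add("sex", int(male.sum()), int((~male).sum()),
                    effect=w.mean_diff, se=w.se, t=w.t, df=w.df, p=w.p,
                    ci_low=w.ci_low, ci_high=w.ci_high)
            except ValueError:
                pass
        # handedness contrast, additionally residualised for sex
        if left_h.sum() >= 2 and right_h.sum() >= 2:
            try:
                resid = residualize(ai, [age, icv, sexn],
                                    names=["age", "icv", "sex"])
                w = welch_test(resid[left_h.to_numpy()], resid[right_h.to_numpy()])
                add("handedness", int(left_h.sum()), int(right_h.sum()),
                    effect=w.mean_diff, se=w.se, t=w.t, df=w.df, p=w.p,
                    ci_low=w.ci_low, ci_high=w.ci_high)
            except ValueError:
                pass
        # age ANCOVA
        if len(sub) >= 5 and np.ptp(age) > 0:
            coef, se, p = ancova_age(ai, age, sexn, icv)
            add("age", len(sub), 0, effect=coef, se=se, t=coef / se,
                df=len(sub) - 4, p=p, ci_low=np.nan, ci_high=np.nan)
        # per-sex lateralization on raw AIs
        for label, m in (("lateralization_M", male), ("lateralization_F", ~male)):
            g = ai[m.to_numpy()]
            if len(g) >= 2 and g.var(ddof=1) > 0:
                mean, t, p = one_sample_lateralization(g)
                se = g.std(ddof=1) / math.sqrt(len(g))
                add(label, len(g), 0, effect=mean, se=se, t=t,
                    df=len(g) - 1, p=p, ci_low=np.nan, ci_high=np.nan)
    return pd.DataFrame(rows)
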