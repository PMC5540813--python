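"""Between-dataset heterogeneity of asymmetry indices as eta-squared shares.

Each AI record carries a site label and a segmentation-software version
label; because every site ran exactly one software version the two factors
are confounded, so each is assessed as a separate one-way main effect
(SS_between / SS_total), never jointly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .site import compute_ai, exclude_outliers, sd_threshold
from .structures import STRUCTURES

__all__ = ["eta_squared", "heterogeneity_table", "pooled_ai_records"]


def eta_squared(values, labels) -> float:
    """One-way eta^2: proportion of total variance explained by the
    grouping factor, SS_between / SS_total, in [0, 1]."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) != len(labels):
        raise ValueError("values and labels must have the same length")
    groups = pd.Series(values).groupby(pd.Series(labels), observed=True)
    if groups.ngroups < 2:
        raise ValueError("need at least 2 groups")
    grand = values.mean()
    ss_total = float(np.sum((values - grand) ** 2))
    if ss_total == 0.0:
        raise ValueError("total variance is zero; eta^2 undefined")
    ss_between = float((groups.size() * (groups.mean() - grand) ** 2).sum())
    return ss_between / ss_total


def _within_mean_square(values, labels) -> float:
    """ANOVA within-group mean square: SS_within / (n - k)."""
    values = np.asarray(values, dtype=float)
    groups = pd.Series(values).groupby(pd.Series(np.asarray(labels)), observed=True)
    ss_within = float((groups.apply(lambda g: ((g - g.mean()) ** 2).sum())).sum())
    return ss_within / (len(values) - groups.ngroups)


def pooled_ai_records(tables, structures=STRUCTURES) -> pd.DataFrame:
    """Concatenate post-exclusion, non-residualised AI records across sites.

    Applies the same adaptive-SD exclusion as the site stage (joint over the
    left volume, right volume and AI) and returns tidy rows:
    structure, ai, site, version.
    """
    rows = []
    for table in tables:
        site = table.attrs.get("site_id", "site")
        version = table.attrs.get("freesurfer_version", "unknown")
        for s in structures:
            lcol, rcol = f"{s}_L_mm3", f"{s}_R_mm3"
            sub = table.dropna(subset=[lcol, rcol])
            sub = sub[(sub[lcol] + sub[rcol]) > 0]
            if len(sub) < 4:
                continue
            ai = compute_ai(sub[lcol].to_numpy(), sub[rcol].to_numpy())
            thresh = sd_threshold(len(sub))
            mask = (
                exclude_outliers(sub[lcol], thresh)
                & exclude_outliers(sub[rcol], thresh)
                & exclude_outliers(ai, thresh)
            )
            rows.append(pd.DataFrame({
                "structure": s,
                "ai": ai[mask],
                "site": site,
                "version": version,
            }))
    if not rows:
        raise ValueError("no AI records could be computed from the inputs")
    return pd.concat(rows, ignore_index=True)


def heterogeneity_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-structure heterogeneity summary.

    Columns: structure, mean_ai, sigma2_within (the within-site ANOVA mean
    square), n, eta2_dataset, eta2_version. ``eta2_version`` is NaN when
    only one software version is present.
    """
    out = []
    for s, grp in records.groupby("structure", observed=True, sort=False):
        ai = grp["ai"].to_numpy()
        row = {
            "structure": s,
            "mean_ai": float(ai.mean()),
            "sigma2_within": _within_mean_square(ai, grp["site"]),
            "n": len(ai),
            "eta2_dataset": eta_squared(ai, grp["site"]),
        }
        try:
            row["eta2_version"] = eta_squared(ai, grp["version"])
        except ValueError:
            row["eta2_version"] = float("nan")
        out.append(row)
    return pd.DataFrame(out)
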