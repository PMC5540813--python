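"""End-to-end orchestration of the two-level protocol.

Stage 1 runs independently per site and produces only summary statistics;
stage 2 pools those summaries (sex / handedness / age / lateralization
contrasts), partitions between-site AI variance, and optionally fits the
pedigree heritability models. Nothing but summaries crosses the
site-to-pooling boundary, mirroring a federation in which sites never share
subject-level data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import io as sio
from .heritability import fit_bivariate_vc, fit_univariate_vc, kinship_from_pedigree
from .meta import PoolingRules, pool_summaries, weighted_meta_regression
from .site import summarize_site
from .structures import STRUCTURES
from .variance import heterogeneity_table, pooled_ai_records

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    site_tables: list = field(default_factory=list)   # paths to site CSVs
    pedigree: str | None = None
    phenotypes: str | None = None
    structures: tuple = STRUCTURES
    contrasts: tuple = ("sex", "handedness", "age", "lateralization")
    min_per_group: int = 15
    min_iqr_years: float = 5.0
    alpha: float = 0.007
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        unknown = set(self.structures) - set(STRUCTURES)
        if unknown:
            raise ValueError(f"unknown structures: {sorted(unknown)}")
        for p in list(self.site_tables) + [self.pedigree, self.phenotypes]:
            if p is not None and not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")

    def manifest(self) -> dict:
        cfg = asdict(self)
        cfg["site_tables"] = [str(p) for p in cfg["site_tables"]]
        digest = hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest()
        return {"config": cfg, "config_sha256": digest, "seed": self.seed}


def _load_tables(config: RunConfig) -> list[pd.DataFrame]:
    return [sio.read_site_table(p) for p in config.site_tables]


def run_pipeline(config: RunConfig, *, tables=None, log=None) -> dict:
    """Run site summaries, pooling, variance partitioning and (when
    pedigree inputs are configured) the heritability stage.

    Returns a result bundle with keys ``summaries``, ``meta``,
    ``heterogeneity``, ``meta_regression``, ``heritability`` (optional),
    ``log`` and ``manifest``; writes them as CSV/JSON when
    ``config.output_dir`` is set. Any stage failure raises
    :class:`PipelineError` naming the failing site or structure.
    """
    config.validate()
    log = log if log is not None else []
    tables = tables if tables is not None else _load_tables(config)
    if not tables:
        raise PipelineError("no site tables to analyse")

    summaries = []
    for t in tables:
        site = t.attrs.get("site_id", "site")
        try:
            summ = summarize_site(t, structures=config.structures)
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            raise PipelineError(f"site stage failed for {site}: {exc}") from exc
        if not summ.empty:
            excl = summ.groupby("structure", observed=True)["n_excluded"].first()
            log.append({"site": site, "stage": "site_stats",
                        "outliers_excluded": excl.to_dict()})
        summaries.append(summ)
    summaries = pd.concat(summaries, ignore_index=True)

    rules = PoolingRules(min_per_group=config.min_per_group,
                         min_iqr_years=config.min_iqr_years,
                         alpha=config.alpha)
    meta_tables = {}
    wanted = set(config.contrasts)
    contrast_rows = {
        "sex": ["sex"],
        "handedness": ["handedness"],
        "age": ["age"],
        "lateralization": ["lateralization_M", "lateralization_F"],
    }
    for name, rows in contrast_rows.items():
        if name not in wanted:
            continue
        for contrast in rows:
            if contrast not in set(summaries["contrast"]):
                continue
            try:
                meta_tables[contrast] = pool_summaries(
                    summaries, contrast=contrast, rules=rules,
                    structures=config.structures)
            except ValueError as exc:
                raise PipelineError(
                    f"meta stage failed for contrast {contrast!r}: {exc}"
                ) from exc
    meta = (pd.concat(meta_tables.values(), ignore_index=True)
            if meta_tables else pd.DataFrame())

    records = pooled_ai_records(tables, structures=config.structures)
    heterogeneity = heterogeneity_table(records)

    meta_reg = None
    if "age" in wanted and "age" in meta_tables:
        age_rows = summaries[summaries["contrast"] == "age"]
        age_rows = age_rows[(age_rows["n_male"] >= config.min_per_group)
                            & (age_rows["n_female"] >= config.min_per_group)
                            & (age_rows["age_iqr"] >= config.min_iqr_years)]
        regs = []
        for s in config.structures:
            sub = age_rows[age_rows["structure"] == s]
            if len(sub) >= 3 and sub["median_age"].nunique() > 1:
                slope, se, p = weighted_meta_regression(
                    sub["effect"], sub["median_age"], sub["n_group1"])
                regs.append({"structure": s, "slope": slope, "se": se, "p": p})
        meta_reg = pd.DataFrame(regs)

    bundle = {
        "summaries": summaries,
        "meta": meta,
        "heterogeneity": heterogeneity,
        "meta_regression": meta_reg,
        "log": log,
        "manifest": config.manifest(),
    }

    if config.pedigree and config.phenotypes:
        bundle["heritability"] = _heritability_stage(config)

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        summaries.to_csv(out / "site_summaries.csv", index=False)
        meta.to_csv(out / "meta_results.csv", index=False)
        heterogeneity.to_csv(out / "heterogeneity.csv", index=False)
        if meta_reg is not None:
            meta_reg.to_csv(out / "age_meta_regression.csv", index=False)
        if "heritability" in bundle:
            bundle["heritability"].to_csv(out / "heritability.csv", index=False)
        (out / "run_manifest.json").write_text(
            json.dumps(bundle["manifest"], indent=2))
        (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return bundle


def _heritability_stage(config: RunConfig) -> pd.DataFrame:
    ped = sio.read_pedigree(config.pedigree)
    phen = sio.read_phenotypes(config.phenotypes)
    phen = phen.set_index("individual_id").loc[ped["individual_id"]].reset_index()
    K = kinship_from_pedigree(ped)
    import numpy as np

    X = np.column_stack([
        phen["age_years"].to_numpy(dtype=float),
        (phen["sex"] == "M").to_numpy(dtype=float),
        phen["icv_mm3"].to_numpy(dtype=float),
    ])
    rows = []
    trait_cols = [c for c in phen.columns if c.startswith("trait_")
                  or c.endswith("_ai")]
    for col in trait_cols:
        fit = fit_univariate_vc(phen[col].to_numpy(dtype=float), X, K)
        rows.append({"trait": col, "h2": fit.h2, "h2_se": fit.h2_se,
                     "p": fit.p_h2, "loglik": fit.loglik})
    lr_pairs = [
        (c, c.replace("_L_", "_R_"))
        for c in phen.columns if "_L_" in c and c.replace("_L_", "_R_") in phen.columns
    ]
    for lcol, rcol in lr_pairs:
        fit = fit_bivariate_vc(phen[lcol], phen[rcol], X, K)
        rows.append({"trait": f"{lcol}~{rcol}", "h2": fit.h2,
                     "rho_g": fit.rho_g, "rho_g_se": fit.rho_g_se,
                     "p_rho0": fit.p_rho0, "p_rho1": fit.p_rho1,
                     "rho_e": fit.rho_e, "rho_phen": fit.rho_phen,
                     "loglik": fit.loglik})
    return pd.DataFrame(rows)
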