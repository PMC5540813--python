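"""Parameter-recovery experiments at the consortium's study conditions.

Each function simulates data at the configured effect sizes, runs the full
relevant slice of the pipeline (generation -> site stage -> pooling, or
pedigree generation -> variance-component fit), and returns the estimates.
They are the package's reproduction surface: the same calls back both the
test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .heritability import (
    BivariateVarianceComponentModel,
    VarianceComponentModel,
    kinship_from_pedigree,
)
from .meta import PoolingRules, pool_summaries
from .site import summarize_site
from .structures import AGE_EFFECT, AI_VAR_WITHIN, MEAN_AI, SEX_EFFECT
from .synthetic import PedigreeSimConfig, SimConfig, generate_multisite, generate_pedigrees

__all__ = [
    "sex_contrast_recovery",
    "age_effect_recovery",
    "heritability_recovery",
    "genetic_correlation_recovery",
    "spawn_seeds",
]


def spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Derive n independent child seeds (< 2**31) from one master seed."""
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def _pooled_contrast(structure: str, contrast: str, n_sites: int, seed: int,
                     **sim_kw):
    cfg = SimConfig(n_sites=n_sites, n_per_site=(150, 400),
                    structures=(structure,), seed=seed, **sim_kw)
    tables = generate_multisite(cfg)
    summaries = pd.concat(
        [summarize_site(t, structures=(structure,)) for t in tables],
        ignore_index=True,
    )
    res = pool_summaries(summaries, contrast=contrast, rules=PoolingRules(),
                         structures=(structure,))
    return res.iloc[0]


def sex_contrast_recovery(structure: str = "putamen", n_sites: int = 41,
                          n_seeds: int = 20, seed: int = 0) -> dict:
    """End-to-end recovery of the male-female residualised-AI difference.

    Simulates ``n_sites`` sites per replicate with the configured sex effect
    for ``structure``, runs the site stage and DL pooling, and averages the
    pooled estimate over ``n_seeds`` replicates.
    """
    ests, ses, ks = [], [], []
    for s in spawn_seeds(seed, n_seeds):
        row = _pooled_contrast(structure, "sex", n_sites, int(s))
        ests.append(row["effect"])
        ses.append(row["se"])
        ks.append(row["k"])
    return {
        "true_effect": SEX_EFFECT[structure],
        "mean_estimate": float(np.mean(ests)),
        "mean_pooled_se": float(np.mean(ses)),
        "k": int(np.median(ks)),
        "estimates": np.asarray(ests),
    }


def age_effect_recovery(structure: str = "putamen", n_sites: int = 36,
                        n_seeds: int = 20, seed: int = 0) -> dict:
    """End-to-end recovery of the per-year age coefficient on the AI via
    per-site ANCOVA followed by DL pooling. Site age ranges are drawn wide
    enough that every site passes the minimum age-IQR inclusion rule."""
    ests, ses, ks = [], [], []
    for s in spawn_seeds(seed, n_seeds):
        row = _pooled_contrast(structure, "age", n_sites, int(s),
                               age_halfwidth_range=(10.0, 30.0))
        ests.append(row["effect"])
        ses.append(row["se"])
        ks.append(row["k"])
    return {
        "true_effect": AGE_EFFECT[structure],
        "mean_estimate": float(np.mean(ests)),
        "mean_pooled_se": float(np.mean(ses)),
        "k": int(np.median(ks)),
        "estimates": np.asarray(ests),
    }


def _ai_pedigree_config(structure: str, seed: int) -> PedigreeSimConfig:
    # AI-scale trait: configured heritability on the structure's AI
    # variance, with realistic covariate effects on the AI scale
    from .structures import AI_H2

    return PedigreeSimConfig(
        h2=(AI_H2[structure],),
        trait_sd=(float(np.sqrt(AI_VAR_WITHIN[structure])),),
        trait_mean=(MEAN_AI[structure],),
        beta_age=AGE_EFFECT[structure],
        beta_sex=SEX_EFFECT[structure],
        beta_icv=5e-4,
        seed=seed,
    )


def _covariates(phen: pd.DataFrame) -> np.ndarray:
    return np.column_stack([
        phen["age_years"].to_numpy(dtype=float),
        (phen["sex"] == "M").to_numpy(dtype=float),
        phen["icv_mm3"].to_numpy(dtype=float) / 1e5,
    ])


def heritability_recovery(structure: str = "putamen", n_reps: int = 10,
                          seed: int = 0) -> dict:
    """Univariate variance-component recovery of the AI heritability on
    extended pedigrees (~71 families, ~1200 individuals per replicate)."""
    from .structures import AI_H2

    ests = []
    for s in spawn_seeds(seed, n_reps):
        ped, phen = generate_pedigrees(_ai_pedigree_config(structure, int(s)))
        K = kinship_from_pedigree(ped)
        m = VarianceComponentModel().fit(
            phen["trait_0"].to_numpy(), _covariates(phen), kinship=K)
        ests.append(m.h2_)
    ests = np.asarray(ests)
    return {
        "true_h2": AI_H2[structure],
        "mean_estimate": float(ests.mean()),
        "mc_se": float(ests.std(ddof=1) / np.sqrt(len(ests))),
        "estimates": ests,
    }


def genetic_correlation_recovery(structure: str = "putamen", n_reps: int = 10,
                                 seed: int = 0) -> dict:
    """Bivariate variance-component recovery of the left-right volume
    genetic correlation.

    Per-side volume heritability is set so the implied phenotypic
    correlation h2*rho_g + (1-h2)*rho_e matches the configured left-right
    phenotypic correlation for the structure.
    """
    from .structures import LR_RHO_E, LR_RHO_G, LR_RHO_PHEN, MEAN_BILATERAL_VOLUME

    rho_g, rho_e = LR_RHO_G[structure], LR_RHO_E[structure]
    h2_side = (LR_RHO_PHEN[structure] - rho_e) / (rho_g - rho_e)
    half = MEAN_BILATERAL_VOLUME[structure] / 2.0
    ests = []
    for s in spawn_seeds(seed, n_reps):
        cfg = PedigreeSimConfig(
            h2=(h2_side, h2_side), rho_g=rho_g, rho_e=rho_e,
            trait_sd=(0.11 * half, 0.11 * half), trait_mean=(half, half),
            beta_age=-0.004 * half, beta_sex=0.06 * half, beta_icv=0.004 * half,
            seed=int(s),
        )
        ped, phen = generate_pedigrees(cfg)
        K = kinship_from_pedigree(ped)
        m = BivariateVarianceComponentModel().fit(
            phen[["trait_0", "trait_1"]].to_numpy(), _covariates(phen),
            kinship=K)
        ests.append(m.rho_g_)
    ests = np.asarray(ests)
    return {
        "true_rho_g": rho_g,
        "mean_estimate": float(ests.mean()),
        "mc_se": float(ests.std(ddof=1) / np.sqrt(len(ests))),
        "estimates": ests,
    }
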