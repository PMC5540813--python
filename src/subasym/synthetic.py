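"""Synthetic multi-site volumetric data and extended-pedigree generators.

Two generators back the test surface of the whole pipeline:

``generate_multisite``
    Emulates a consortium of independent imaging sites. Each subject has a
    per-structure asymmetry index (AI) composed of a population mean, a
    random site offset, a fixed segmentation-version offset (one software
    version per site), sex and age effects, and Gaussian within-subject
    noise. The bilateral volume total T is linear in intracranial volume
    (ICV) plus noise, and is split into left/right as
    L = T(1+AI)/2, R = T(1-AI)/2, so (L-R)/(L+R) recovers the drawn AI
    exactly.

``generate_pedigrees``
    Emulates a family study of extended pedigrees. Additive genetic values
    are drawn jointly with covariance sigma_g^2 * 2*Phi via a Cholesky
    factor of each family's expected relationship matrix; a second trait
    can share a genetic correlation rho_g and an environmental correlation
    rho_e with the first.

Both generators are deterministic given (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .structures import (
    AGE_EFFECT,
    AI_VAR_WITHIN,
    ETA2_DATASET,
    ETA2_VERSION,
    MEAN_AI,
    MEAN_BILATERAL_VOLUME,
    SEX_EFFECT,
    STRUCTURES,
    VERSION_LABELS,
    VERSION_PROBS,
    VERSION_SCORES,
)

__all__ = [
    "SimConfig",
    "PedigreeSimConfig",
    "generate_multisite",
    "generate_pedigrees",
]


def _default_site_ai_sd() -> dict:
    # Between-site offset SD calibrated so that the between-site share of
    # total AI variance matches the configured eta^2 targets:
    # sigma_b^2 = sigma_w^2 * eta2 / (1 - eta2), with the version component
    # carved out of the between-site total.
    out = {}
    for s in STRUCTURES:
        total_between = AI_VAR_WITHIN[s] * ETA2_DATASET[s] / (1.0 - ETA2_DATASET[s])
        version_part = AI_VAR_WITHIN[s] * ETA2_VERSION[s] / (1.0 - ETA2_VERSION[s])
        out[s] = math.sqrt(max(total_between - version_part, 0.0) or total_between * 0.1)
    return out


def _default_version_scale() -> dict:
    return {
        s: math.sqrt(AI_VAR_WITHIN[s] * ETA2_VERSION[s] / (1.0 - ETA2_VERSION[s]))
        for s in STRUCTURES
    }


@dataclass
class SimConfig:
    """Study conditions for the multi-site generator.

    Defaults emulate a 52-site consortium of roughly 16k healthy
    participants: per-structure mean AIs and within-subject AI variances,
    male-minus-female AI differences, per-year age slopes, and site/version
    heterogeneity calibrated to the between-dataset variance shares the
    analysis is designed to detect.
    """

    n_sites: int = 52
    n_per_site: tuple[int, int] = (25, 600)
    sex_ratio: float = 7524 / 15847  # male fraction
    age_center_range: tuple[float, float] = (20.0, 55.0)
    age_halfwidth_range: tuple[float, float] = (4.0, 30.0)
    icv_mean: float = 1.5e6
    icv_log_sd: float = 0.08
    # 1.0 keeps ICV independent of sex, so the configured sex effect on the
    # AI is exactly the estimand of the ICV-adjusted group contrast; set
    # >1 to study sex-ICV confounding
    male_icv_factor: float = 1.0
    mean_ai: dict = field(default_factory=lambda: dict(MEAN_AI))
    ai_sd_within: dict = field(
        default_factory=lambda: {s: math.sqrt(v) for s, v in AI_VAR_WITHIN.items()}
    )
    site_ai_sd: dict = field(default_factory=_default_site_ai_sd)
    version_labels: tuple[str, ...] = VERSION_LABELS
    version_probs: tuple[float, ...] = VERSION_PROBS
    version_ai_scale: dict = field(default_factory=_default_version_scale)
    sex_effect: dict = field(default_factory=lambda: dict(SEX_EFFECT))
    age_effect: dict = field(default_factory=lambda: dict(AGE_EFFECT))
    handedness_left_fraction: float = 0.1
    icv_volume_corr: float = 0.5
    volume_cv: float = 0.12
    structures: tuple[str, ...] = STRUCTURES
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        lo, hi = self.n_per_site
        if lo < 2 or hi < lo:
            raise ValueError("n_per_site range must satisfy 2 <= low <= high")
        if not 0.0 < self.sex_ratio < 1.0:
            raise ValueError("sex_ratio must lie in (0, 1)")
        if not 0.0 <= self.handedness_left_fraction <= 1.0:
            raise ValueError("handedness_left_fraction must lie in [0, 1]")
        unknown = set(self.structures) - set(STRUCTURES)
        if unknown:
            raise ValueError(f"unknown structures: {sorted(unknown)}")
        if abs(sum(self.version_probs) - 1.0) > 1e-9:
            raise ValueError("version_probs must sum to 1")
        for s in self.structures:
            mu = self.mean_ai[s]
            if not (np.isfinite(mu) and -1.0 < mu < 1.0):
                raise ValueError(f"mean AI for {s} must lie strictly in (-1, 1)")
            for d in (self.ai_sd_within, self.site_ai_sd, self.version_ai_scale):
                v = d[s]
                if not (np.isfinite(v) and 0.0 <= v < 1.0):
                    raise ValueError(f"AI scale for {s} must lie in [0, 1)")
        if not (np.isfinite(self.icv_mean) and self.icv_mean > 0):
            raise ValueError("icv_mean must be positive and finite")


def _with_seed(config, seed):
    return config if seed is None else replace(config, seed=seed)


def generate_multisite(config: SimConfig | None = None, *, seed: int | None = None
                       ) -> list[pd.DataFrame]:
    """Generate one subject table per site.

    Returns a list of DataFrames with columns ``subject_id``, ``sex`` (M/F),
    ``age_years``, ``handedness`` (L/R), ``icv_mm3``, then
    ``{structure}_L_mm3`` / ``{structure}_R_mm3`` for each requested
    structure, plus per-site attrs ``site_id`` and ``freesurfer_version``.

    The drawn AI for each subject/structure is
    ``mu + site_offset + version_offset + gamma_sex*(male - sex_ratio)
    + kappa_age*(age - site mean age) + eps``; the sex and age terms are
    centered so the per-site expected mean AI is exactly
    ``mu + site_offset + version_offset``.
    """
    config = _with_seed(config or SimConfig(), seed)
    config.validate()
    rng = np.random.default_rng(config.seed)
    tables: list[pd.DataFrame] = []
    version_idx = rng.choice(
        len(config.version_labels), size=config.n_sites, p=config.version_probs
    )
    site_offsets = {
        s: rng.normal(0.0, config.site_ai_sd[s], size=config.n_sites)
        for s in config.structures
    }
    for i in range(config.n_sites):
        n = int(rng.integers(config.n_per_site[0], config.n_per_site[1] + 1))
        version = config.version_labels[version_idx[i]]
        vscore = VERSION_SCORES[version]
        male = rng.random(n) < config.sex_ratio
        center = rng.uniform(*config.age_center_range)
        halfwidth = rng.uniform(*config.age_halfwidth_range)
        age = rng.uniform(center - halfwidth, center + halfwidth, size=n)
        age = np.clip(age, 8.0, None)
        icv = config.icv_mean * np.exp(
            rng.normal(0.0, config.icv_log_sd, size=n)
        )
        icv = np.where(male, icv * config.male_icv_factor,
                       icv / config.male_icv_factor)
        hand = np.where(
            rng.random(n) < config.handedness_left_fraction, "L", "R"
        )
        data = {
            "subject_id": [f"site{i:02d}_s{j:04d}" for j in range(n)],
            "sex": np.where(male, "M", "F"),
            "age_years": age,
            "handedness": hand,
            "icv_mm3": icv,
        }
        age_c = age - age.mean()
        sex_c = male.astype(float) - config.sex_ratio
        r = config.icv_volume_corr
        for s in config.structures:
            ai = (
                config.mean_ai[s]
                + site_offsets[s][i]
                + vscore * config.version_ai_scale[s]
                + config.sex_effect[s] * sex_c
                + config.age_effect[s] * age_c
                + rng.normal(0.0, config.ai_sd_within[s], size=n)
            )
            ai = np.clip(ai, -0.999, 0.999)
            m_vol = MEAN_BILATERAL_VOLUME[s]
            sd_vol = config.volume_cv * m_vol
            icv_sd = config.icv_mean * config.icv_log_sd  # approx lognormal sd
            slope = r * sd_vol / icv_sd
            total = (
                m_vol
                + slope * (icv - config.icv_mean)
                + rng.normal(0.0, sd_vol * math.sqrt(1 - r**2), size=n)
            )
            total = np.clip(total, 1.0, None)
            data[f"{s}_L_mm3"] = total * (1.0 + ai) / 2.0
            data[f"{s}_R_mm3"] = total * (1.0 - ai) / 2.0
        table = pd.DataFrame(data)
        table.attrs["site_id"] = f"site{i:02d}"
        table.attrs["freesurfer_version"] = version
        tables.append(table)
    return tables


# ---------------------------------------------------------------------------
# Pedigrees


@dataclass
class PedigreeSimConfig:
    """Study conditions for the extended-pedigree generator.

    The default template yields 71 three-generation families of 17
    individuals (two founders, three adult children married to founder
    spouses, three grandchildren per couple), about 1200 phenotyped
    individuals in total, emulating a large family study.

    ``h2`` gives the additive-genetic fraction of the unit residual trait
    variance per trait; ``rho_g``/``rho_e`` the genetic/environmental
    correlations between the two traits of a bivariate simulation.
    """

    n_pedigrees: int = 71
    n_children: int = 3
    n_grandchildren: int = 3
    h2: tuple[float, ...] = (0.27,)
    rho_g: float = 0.0
    rho_e: float = 0.0
    trait_sd: tuple[float, ...] = (1.0,)
    trait_mean: tuple[float, ...] = (0.0,)
    beta_age: float = 0.0   # per year, applied to (age - 40)
    beta_sex: float = 0.0   # male minus female
    beta_icv: float = 0.0   # per 1e5 mm^3 of (icv - icv_mean)
    icv_mean: float = 1.5e6
    icv_log_sd: float = 0.08
    seed: int = 0

    @property
    def n_traits(self) -> int:
        return len(self.h2)

    def validate(self) -> None:
        if self.n_pedigrees < 1 or self.n_children < 1 or self.n_grandchildren < 0:
            raise ValueError("pedigree shape counts out of range")
        if self.n_traits not in (1, 2):
            raise ValueError("only univariate or bivariate simulation supported")
        if len(self.trait_sd) != self.n_traits or len(self.trait_mean) != self.n_traits:
            raise ValueError("trait_sd/trait_mean must match the number of traits")
        for h in self.h2:
            if not 0.0 <= h <= 1.0:
                raise ValueError("h2 must lie in [0, 1]")
        for r in (self.rho_g, self.rho_e):
            if not -1.0 <= r <= 1.0:
                raise ValueError("correlations must lie in [-1, 1]")
        if self.n_traits == 2:
            # implied 2-trait phenotypic covariance must be PSD; with
            # |rho| <= 1 both G and E are PSD so their sum always is, but a
            # correlation requested for a trait with zero variance share is
            # infeasible.
            if self.rho_g != 0.0 and (self.h2[0] == 0.0 or self.h2[1] == 0.0):
                raise ValueError("rho_g != 0 requires h2 > 0 for both traits")
            if self.rho_e != 0.0 and (self.h2[0] == 1.0 or self.h2[1] == 1.0):
                raise ValueError("rho_e != 0 requires h2 < 1 for both traits")


def _template_pedigree(family: int, n_children: int, n_grandchildren: int,
                       rng: np.random.Generator) -> pd.DataFrame:
    """One three-generation family in long PED-like form."""
    fam = f"fam{family:03d}"
    rows = []

    def add(ind, father, mother, sex, generation):
        rows.append((fam, f"{fam}_{ind}", father and f"{fam}_{father}",
                     mother and f"{fam}_{mother}", sex, generation))

    add("p1", None, None, "M", 0)
    add("p2", None, None, "F", 0)
    for c in range(n_children):
        child_sex = "M" if rng.random() < 0.5 else "F"
        add(f"c{c}", "p1", "p2", child_sex, 1)
        spouse_sex = "F" if child_sex == "M" else "M"
        add(f"s{c}", None, None, spouse_sex, 1)
        father = f"c{c}" if child_sex == "M" else f"s{c}"
        mother = f"s{c}" if child_sex == "M" else f"c{c}"
        for g in range(n_grandchildren):
            add(f"g{c}{g}", father, mother, "M" if rng.random() < 0.5 else "F", 2)
    return pd.DataFrame(
        rows,
        columns=["family_id", "individual_id", "father_id", "mother_id",
                 "sex", "generation"],
    )


def generate_pedigrees(config: PedigreeSimConfig | None = None, *,
                       seed: int | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (pedigree, phenotype) tables.

    The pedigree table holds family_id, individual_id, father_id, mother_id
    (None for founders), sex and generation. The phenotype table is keyed by
    individual_id and carries age_years, sex, icv_mm3 and one column per
    trait (``trait_0`` [, ``trait_1``]).

    Genetic values per family are drawn as ``sigma_g * L z`` with
    ``L L' = 2*Phi`` (Cholesky of the expected relationship matrix); for two
    traits the n x 2 genetic matrix is ``L Z C_G'`` with ``C_G C_G' = G``,
    giving covariance ``G (x) 2Phi``. Environmental deviations are iid
    across individuals with covariance E.
    """
    from .heritability import kinship_from_pedigree  # local to avoid cycle

    config = _with_seed(config or PedigreeSimConfig(), seed)
    config.validate()
    rng = np.random.default_rng(config.seed)
    k = config.n_traits
    sd = np.asarray(config.trait_sd, dtype=float)
    h2 = np.asarray(config.h2, dtype=float)
    sg = sd * np.sqrt(h2)
    se = sd * np.sqrt(1.0 - h2)
    G = np.diag(sg) @ np.array([[1.0, config.rho_g], [config.rho_g, 1.0]])[:k, :k] @ np.diag(sg)
    E = np.diag(se) @ np.array([[1.0, config.rho_e], [config.rho_e, 1.0]])[:k, :k] @ np.diag(se)

    def psd_sqrt(M):
        w, V = np.linalg.eigh(M)
        return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))

    CG, CE = psd_sqrt(G), psd_sqrt(E)

    peds, phens = [], []
    for f in range(config.n_pedigrees):
        ped = _template_pedigree(f, config.n_children, config.n_grandchildren, rng)
        n = len(ped)
        K = kinship_from_pedigree(ped)
        Lk = np.linalg.cholesky(K + 1e-12 * np.eye(n))
        gvals = Lk @ rng.standard_normal((n, k)) @ CG.T
        evals = rng.standard_normal((n, k)) @ CE.T

        gen = ped["generation"].to_numpy()
        age = np.empty(n)
        for g, (lo, hi) in enumerate([(45.0, 80.0), (25.0, 60.0), (18.0, 45.0)]):
            mask = gen == g
            age[mask] = rng.uniform(lo, hi, size=mask.sum())
        male = (ped["sex"] == "M").to_numpy()
        icv = config.icv_mean * np.exp(rng.normal(0.0, config.icv_log_sd, size=n))
        icv = np.where(male, icv * 1.10, icv / 1.10)

        fixed = (
            config.beta_age * (age - 40.0)
            + config.beta_sex * (male.astype(float) - 0.5)
            + config.beta_icv * (icv - config.icv_mean) / 1e5
        )
        y = np.asarray(config.trait_mean) + fixed[:, None] + gvals + evals

        phen = pd.DataFrame({
            "individual_id": ped["individual_id"],
            "sex": ped["sex"],
            "age_years": age,
            "icv_mm3": icv,
        })
        for t in range(k):
            phen[f"trait_{t}"] = y[:, t]
        peds.append(ped)
        phens.append(phen)
    pedigree = pd.concat(peds, ignore_index=True)
    phenotypes = pd.concat(phens, ignore_index=True)
    return pedigree, phenotypes
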