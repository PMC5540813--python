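"""Canonical subcortical structures and their default population parameters.

The analysis targets the seven bilaterally paired subcortical structures
segmented by FreeSurfer. The per-structure defaults below parameterize the
synthetic multi-site generator: population mean asymmetry index (AI),
within-subject AI variance, sex and age effects on the AI, between-site
heterogeneity shares, narrow-sense AI heritability, and the left-right
volume genetic/environmental correlations. They are the study conditions
every downstream stage is exercised against.

AI convention: AI = (L - R) / (L + R), positive = leftward asymmetry.
"""

from __future__ import annotations

from types import MappingProxyType

#: Canonical structure names, fixed ordering used throughout.
STRUCTURES: tuple[str, ...] = (
    "accumbens",
    "amygdala",
    "caudate",
    "pallidum",
    "hippocampus",
    "putamen",
    "thalamus",
)

#: Population mean AI per structure (dimensionless).
MEAN_AI = MappingProxyType({
    "accumbens": -0.0072,
    "amygdala": -0.0205,
    "caudate": -0.0095,
    "pallidum": 0.0180,
    "hippocampus": -0.0066,
    "putamen": 0.0194,
    "thalamus": 0.0211,
})

#: Within-subject AI variance per structure (dimensionless, variance of AI
#: around the site mean).
AI_VAR_WITHIN = MappingProxyType({
    "accumbens": 0.0061,
    "amygdala": 0.0027,
    "caudate": 0.0006,
    "pallidum": 0.0027,
    "hippocampus": 0.0008,
    "putamen": 0.0008,
    "thalamus": 0.0009,
})

#: Sex effect on the AI, male minus female (dimensionless).
SEX_EFFECT = MappingProxyType({
    "accumbens": 0.002,
    "amygdala": 5.7e-5,
    "caudate": -1.3e-4,
    "pallidum": 0.004,
    "hippocampus": 0.001,
    "putamen": -0.002,
    "thalamus": -0.001,
})

#: Linear age effect on the AI (per year).
AGE_EFFECT = MappingProxyType({
    "accumbens": 2.1e-6,
    "amygdala": -1.8e-4,
    "caudate": 5.9e-5,
    "pallidum": -2.0e-4,
    "hippocampus": -1.0e-4,
    "putamen": 1.5e-4,
    "thalamus": 1.5e-4,
})

#: Share of total AI variance attributable to between-site mean differences;
#: used to calibrate the site-offset SD of the generator.
ETA2_DATASET = MappingProxyType({
    "accumbens": 0.180,
    "amygdala": 0.103,
    "caudate": 0.279,
    "pallidum": 0.171,
    "hippocampus": 0.070,
    "putamen": 0.065,
    "thalamus": 0.189,
})

#: Share of total AI variance attributable to segmentation-software version;
#: used to calibrate the fixed per-version offsets.
ETA2_VERSION = MappingProxyType({
    "accumbens": 0.130,
    "amygdala": 0.017,
    "caudate": 0.014,
    "pallidum": 0.142,
    "hippocampus": 0.010,
    "putamen": 0.006,
    "thalamus": 0.333,
})

#: Narrow-sense heritability of the AI per structure.
AI_H2 = MappingProxyType({
    "accumbens": 0.114,
    "amygdala": 0.040,
    "caudate": 0.096,
    "pallidum": 0.148,
    "hippocampus": 0.180,
    "putamen": 0.270,
    "thalamus": 0.228,
})

#: Genetic correlation between left and right volumes.
LR_RHO_G = MappingProxyType({
    "accumbens": 0.841,
    "amygdala": 0.995,
    "caudate": 0.974,
    "pallidum": 0.823,
    "hippocampus": 0.939,
    "putamen": 0.899,
    "thalamus": 0.824,
})

#: Environmental correlation between left and right volumes.
LR_RHO_E = MappingProxyType({
    "accumbens": 0.34,
    "amygdala": 0.39,
    "caudate": 0.56,
    "pallidum": 0.45,
    "hippocampus": 0.53,
    "putamen": 0.58,
    "thalamus": 0.56,
})

#: Phenotypic correlation between left and right volumes.
LR_RHO_PHEN = MappingProxyType({
    "accumbens": 0.54,
    "amygdala": 0.71,
    "caudate": 0.85,
    "pallidum": 0.57,
    "hippocampus": 0.78,
    "putamen": 0.78,
    "thalamus": 0.68,
})

#: Typical bilateral (L+R) volume per structure in mm^3, adult population.
MEAN_BILATERAL_VOLUME = MappingProxyType({
    "accumbens": 1200.0,
    "amygdala": 3200.0,
    "caudate": 7400.0,
    "pallidum": 3600.0,
    "hippocampus": 8600.0,
    "putamen": 11000.0,
    "thalamus": 15500.0,
})

#: Segmentation-software version labels with assignment probabilities across
#: sites (one version per site; the majority of sites used 5.3).
VERSION_LABELS: tuple[str, ...] = ("4.1", "5.0", "5.1", "5.3", "6.0")
VERSION_PROBS: tuple[float, ...] = (0.05, 0.05, 0.10, 0.75, 0.05)

def _standardized_version_scores() -> MappingProxyType:
    # Equally spaced raw scores, standardized to mean 0 / variance 1 under
    # the site-assignment probabilities, so that the across-site variance of
    # the version offset for structure s is (version scale of s)^2.
    raw = [-2.0, -1.0, 0.0, 1.0, 2.0]
    mean = sum(p * r for p, r in zip(VERSION_PROBS, raw))
    var = sum(p * (r - mean) ** 2 for p, r in zip(VERSION_PROBS, raw))
    sd = var ** 0.5
    return MappingProxyType(
        {lab: (r - mean) / sd for lab, r in zip(VERSION_LABELS, raw)}
    )


#: Version scores (mean 0, variance 1 under the assignment probabilities);
#: the per-structure version offset is this score times a structure scale.
VERSION_SCORES = _standardized_version_scores()
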