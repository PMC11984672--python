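"""Synthetic multi-omic cohort generator.

Emulates the statistical structure the downstream analysis assumes: four
groups (CR = long-term calorie restriction, EX = endurance exercise,
WD = sedentary Western-diet adults, yWD = young Western-diet reference),
six omic layers with family-appropriate marginals, an age gradient on a
configurable fraction of features, and planted intervention effects that
partially reverse that gradient (so that interventions look biologically
"younger" than WD, as the analysis is designed to detect).  Ground truth
(which features carry effects, which age) is returned alongside the data
so recovery can be scored.

All effects are planted on the latent (transformed) scale — log for
compositional/count/lognormal layers, logit for methylation — so that
``effect_size`` is a standardized mean difference after the conventional
variance-stabilizing transforms are applied downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .datasets import LAYER_ORDER, MultiOmicDataset
from .enrichment import PathwayAnnotation

GROUPS = ("CR", "EX", "WD", "yWD")

#: full-study group sizes (blood biomarkers measured on everyone)
DEFAULT_GROUP_SIZES = {"CR": 41, "EX": 41, "WD": 35, "yWD": 6}
#: subset that underwent comprehensive multi-omic profiling
MULTIOMIC_GROUP_SIZES = {"CR": 12, "EX": 11, "WD": 12, "yWD": 6}

DEFAULT_AGE_RANGES = {
    "CR": (34.0, 82.0),
    "EX": (42.0, 78.0),
    "WD": (37.0, 74.0),
    "yWD": (21.0, 27.0),
}

#: male proportions per group (full sample: 36/41, 35/41, 27/35, 4/6)
MALE_PROPORTION = {"CR": 36 / 41, "EX": 35 / 41, "WD": 27 / 35, "yWD": 4 / 6}

#: (mean, sd, low, high) of truncated normals per group
BMI_PARAMS = {
    "CR": (19.2, 1.4, 16.5, 22.8),
    "EX": (22.7, 2.4, 17.6, 28.4),
    "WD": (25.5, 3.5, 18.0, 31.5),
    "yWD": (25.7, 0.9, 24.4, 27.2),
}
BODY_FAT_PARAMS = {
    "CR": (9.5, 6.1, 0.2, 26.2),
    "EX": (14.8, 6.6, 1.5, 28.0),
    "WD": (25.9, 6.8, 15.0, 48.4),
    "yWD": (17.9, 8.2, 7.3, 29.3),
}

#: reference (young) age anchoring the age gradient, years
REFERENCE_AGE = 24.0

#: the nine blood biomarkers of the PhenoAge composite
PHENO_BIOMARKERS = (
    "albumin",
    "creatinine",
    "glucose",
    "log_crp",
    "lymphocyte_pct",
    "mcv",
    "rdw",
    "alkaline_phosphatase",
    "wbc",
)

#: latent-scale family and test-scale feature count per layer
_LAYER_DEFAULTS = {
    "microbiome": ("compositional-lognormal", 200),
    "dnam": ("logit-normal-beta", 2000),
    "mrna": ("negative-binomial-count", 1000),
    "metabolome": ("lognormal", 108),
    "hormones": ("lognormal", 14),
    "pheno": ("gaussian", 9),
}

#: feature counts matching the study's post-QC universes
FULL_SCALE_FEATURES = {
    "microbiome": 1321,
    "dnam": 346699,
    "mrna": 23562,
    "metabolome": 108,
    "hormones": 14,
    "pheno": 9,
}


@dataclass
class LayerSpec:
    """One omic layer: its name, dimensionality and distributional family."""

    name: str
    n_features: int | None = None
    family: str | None = None
    #: per-feature baseline spread on the latent scale
    base_sd: float = 2.0
    #: latent residual SD (effect_size is expressed in these units)
    noise_sd: float = 1.0
    #: fraction of features with an age trend; None -> the config-wide
    #: default, except pheno (1.0: the blood biomarkers were chosen for
    #: their age association) and hormones (0.7)
    aging_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.name not in _LAYER_DEFAULTS:
            raise ValueError(f"unknown layer {self.name!r}; expected one of {sorted(_LAYER_DEFAULTS)}")
        default_family, default_p = _LAYER_DEFAULTS[self.name]
        if self.family is None:
            self.family = default_family
        if self.n_features is None:
            self.n_features = default_p
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")


def default_layer_specs() -> list[LayerSpec]:
    return [LayerSpec(name) for name in LAYER_ORDER]


@dataclass
class CohortConfig:
    """Everything the generator needs; identical config + seed => identical data."""

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    layer_specs: list[LayerSpec] = field(default_factory=default_layer_specs)
    age_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AGE_RANGES)
    )
    effect_size: float = 1.0
    #: planted features per layer per intervention; None -> half of the
    #: layer's aging features (footprint scales with layer size)
    n_effect_features: int | None = None
    overlap_fraction: float = 0.3
    #: adult groups share (jittered) ages, emulating the matched design
    age_matching: bool = True
    age_match_jitter: float = 2.0
    aging_fraction: float = 0.3
    #: latent drift per year of (biological) age, in noise-SD units
    aging_slope: float = 0.045
    #: SD (years) of the per-sample latent biological-age offset
    bioage_offset_sd: float = 3.0
    #: couple BMI to group more strongly (confounding stress test); off by default
    confound_bmi: bool = False
    #: emit microbiome as multinomial counts instead of relative abundances
    microbiome_counts: bool = False
    microbiome_depth: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.group_sizes) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group names: {sorted(unknown)}")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs >= 2 samples, got {n}")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 <= self.aging_fraction <= 1.0:
            raise ValueError("aging_fraction must be in [0, 1]")

    @classmethod
    def multiomic_subset(cls, **kwargs) -> "CohortConfig":
        """Config at the study's multi-omic subset sizes (12/11/12/6)."""
        kwargs.setdefault("group_sizes", dict(MULTIOMIC_GROUP_SIZES))
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Planted structure: effect/aging feature sets per layer, latent age offsets."""

    cr_features: dict[str, list[str]]
    ex_features: dict[str, list[str]]
    shared_features: dict[str, list[str]]
    aging_features: dict[str, list[str]]
    bio_age_offset: pd.Series

    def effect_features(self, intervention: str, layer: str) -> list[str]:
        if intervention == "CR":
            return self.cr_features[layer]
        if intervention == "EX":
            return self.ex_features[layer]
        raise ValueError(f"unknown intervention {intervention!r}")


def _feature_names(layer: str, p: int) -> list[str]:
    prefix = {
        "microbiome": "OTU_{:05d}",
        "dnam": "cg{:08d}",
        "mrna": "G{:05d}",
        "metabolome": "M{:04d}",
        "hormones": "H{:02d}",
    }
    if layer == "pheno":
        if p <= len(PHENO_BIOMARKERS):
            return list(PHENO_BIOMARKERS[:p])
        extra = [f"pheno_{i:02d}" for i in range(p - len(PHENO_BIOMARKERS))]
        return list(PHENO_BIOMARKERS) + extra
    return [prefix[layer].format(i + 1) for i in range(p)]


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _simulate_metadata(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    # adult groups were recruited age- and sex-matched; with matching on,
    # EX/WD ages are jittered copies of the CR draws (clipped to each
    # group's observed range) instead of independent draws
    base_n = max(config.group_sizes.get(g, 0) for g in ("CR", "EX", "WD"))
    lo_cr, hi_cr = config.age_ranges["CR"]
    base_ages = rng.uniform(lo_cr, hi_cr, size=base_n)
    rows = []
    for group in GROUPS:
        n = config.group_sizes.get(group, 0)
        if n == 0:
            continue
        lo, hi = config.age_ranges[group]
        if group == "yWD" or not config.age_matching:
            ages = rng.uniform(lo, hi, size=n)
        elif group == "CR":
            ages = np.clip(base_ages[:n], lo, hi)
        else:
            jitter = rng.normal(0.0, config.age_match_jitter, size=n)
            ages = np.clip(base_ages[:n] + jitter, lo, hi)
        sexes = np.where(rng.random(n) < MALE_PROPORTION[group], "M", "F")
        bmi_mean, bmi_sd, bmi_lo, bmi_hi = BMI_PARAMS[group]
        if config.confound_bmi and group in ("CR", "EX"):
            bmi_mean -= 1.5
        bmis = _truncated_normal(rng, bmi_mean, bmi_sd, bmi_lo, bmi_hi, n)
        bf = _truncated_normal(rng, *BODY_FAT_PARAMS[group], n)
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{group}_{i + 1:03d}",
                    "group": group,
                    "age": round(float(ages[i]), 1),
                    "sex": sexes[i],
                    "bmi": round(float(bmis[i]), 2),
                    "body_fat": round(float(bf[i]), 2),
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


_LAYER_AGING_FRACTION = {"pheno": 1.0, "hormones": 0.7, "dnam": 0.15}


def _plant_feature_sets(
    rng: np.random.Generator, features: list[str], config: CohortConfig,
    aging_fraction: float,
) -> tuple[list[str], list[str], list[str], list[str], dict[str, float]]:
    """Choose aging, CR-effect and EX-effect features for one layer.

    Effect features are drawn from the aging set, so an intervention shift
    of -effect_size along the drift direction moves treated samples back
    toward the young reference; the CR and EX sets never spill outside the
    aging pool (spilling would push treated samples *away* from the
    reference on drift-free features).  The shared CR/EX subset has size
    round(overlap_fraction * n_effect).  With aging_fraction = 0 the
    effects fall back to arbitrary features with random signs (a pure
    discrimination problem with no age structure).
    """
    p = len(features)
    n_aging = int(round(aging_fraction * p))
    perm = rng.permutation(p)
    aging = [features[i] for i in perm[:n_aging]]

    pool = aging if n_aging > 0 else [features[i] for i in perm]
    # the CR/EX union (2*n_eff - n_shared features) must fit in the pool
    cap = int(len(pool) / (2.0 - config.overlap_fraction))
    if config.n_effect_features is None:
        n_eff = max(1, round(0.5 * n_aging)) if n_aging else max(1, round(0.05 * p))
    else:
        n_eff = config.n_effect_features
    n_eff = max(0, min(n_eff, cap))
    n_shared = int(round(config.overlap_fraction * n_eff))
    shared = pool[:n_shared]
    cr = shared + pool[n_shared:n_eff]
    ex = shared + pool[n_eff : 2 * n_eff - n_shared]

    # drift sign per aging feature; effect features reuse it (or a random
    # sign when planted outside the aging pool)
    sign_feats = list(dict.fromkeys(aging + pool))  # stable order for rng
    signs = {f: (1.0 if rng.random() < 0.5 else -1.0) for f in sign_feats}
    return aging, cr, ex, shared, signs


def _latent_to_observed(
    layer: str, family: str, Z: np.ndarray, rng: np.random.Generator, config: CohortConfig
) -> np.ndarray:
    if family == "compositional-lognormal":
        A = np.exp(Z)
        rel = A / A.sum(axis=1, keepdims=True)
        if config.microbiome_counts:
            counts = np.vstack(
                [rng.multinomial(config.microbiome_depth, row) for row in rel]
            ).astype(float)
            return counts
        return rel
    if family == "logit-normal-beta":
        return np.clip(expit(Z), 1e-12, 1.0 - 1e-12)
    if family == "negative-binomial-count":
        # Poisson on top of the lognormal latent mean: a Poisson-lognormal
        # mixture, i.e. overdispersed counts
        return rng.poisson(np.exp(Z)).astype(np.int64)
    if family == "lognormal":
        return np.exp(Z)
    if family == "gaussian":
        return Z
    raise ValueError(f"unknown family {family!r}")


def simulate_cohort(config: CohortConfig) -> tuple[MultiOmicDataset, GroundTruth]:
    """Generate a multi-omic cohort with planted, recoverable structure.

    Returns the dataset (layers + metadata) and the ground truth needed to
    score recovery: per-layer CR/EX/shared effect sets, aging feature sets,
    and each sample's latent biological-age offset in years.
    """
    root = np.random.SeedSequence(config.seed)
    meta_ss, *layer_ss = root.spawn(1 + len(config.layer_specs))
    rng_meta = np.random.default_rng(meta_ss)

    metadata = _simulate_metadata(config, rng_meta)
    n = len(metadata)
    age = metadata["age"].to_numpy()
    offset = rng_meta.normal(0.0, config.bioage_offset_sd, size=n)
    effective_age = age + offset
    is_cr = (metadata["group"] == "CR").to_numpy()
    is_ex = (metadata["group"] == "EX").to_numpy()

    layers: dict[str, pd.DataFrame] = {}
    cr_sets, ex_sets, shared_sets, aging_sets = {}, {}, {}, {}
    for spec, ss in zip(config.layer_specs, layer_ss):
        rng = np.random.default_rng(ss)
        p = spec.n_features
        features = _feature_names(spec.name, p)
        aging_fraction = spec.aging_fraction
        if aging_fraction is None:
            aging_fraction = _LAYER_AGING_FRACTION.get(spec.name, config.aging_fraction)
        if config.aging_fraction == 0.0:
            aging_fraction = 0.0
        aging, cr, ex, shared, signs = _plant_feature_sets(rng, features, config, aging_fraction)

        # pheno biomarkers live on their natural scale; others get a wide
        # latent baseline so observed marginals look like real assays
        base_loc = {"mrna": 4.0, "metabolome": 2.0, "hormones": 1.0}.get(spec.name, 0.0)
        base = rng.normal(base_loc, spec.base_sd, size=p)
        Z = base[None, :] + rng.normal(0.0, spec.noise_sd, size=(n, p))

        idx = {f: j for j, f in enumerate(features)}
        for f in aging:
            Z[:, idx[f]] += signs[f] * config.aging_slope * (effective_age - REFERENCE_AGE)
        for f in cr:
            Z[is_cr, idx[f]] -= signs[f] * config.effect_size
        for f in ex:
            Z[is_ex, idx[f]] -= signs[f] * config.effect_size

        obs = _latent_to_observed(spec.name, spec.family, Z, rng, config)
        layers[spec.name] = pd.DataFrame(obs, index=metadata.index, columns=features)
        cr_sets[spec.name] = cr
        ex_sets[spec.name] = ex
        shared_sets[spec.name] = shared
        aging_sets[spec.name] = aging

    truth = GroundTruth(
        cr_features=cr_sets,
        ex_features=ex_sets,
        shared_features=shared_sets,
        aging_features=aging_sets,
        bio_age_offset=pd.Series(offset, index=metadata.index, name="bio_age_offset"),
    )
    return MultiOmicDataset(layers=layers, metadata=metadata), truth


def simulate_annotations(
    config: CohortConfig,
    n_pathways: int = 50,
    planted_enriched: int = 3,
    truth: GroundTruth | None = None,
    dataset: MultiOmicDataset | None = None,
    intervention: str = "CR",
    effect_member_fraction: float = 0.9,
    genes_per_pathway: tuple[int, int] = (20, 40),
    metabolites_per_pathway: tuple[int, int] = (4, 8),
    otus_per_pathway: tuple[int, int] = (4, 12),
    disjoint: bool = False,
) -> PathwayAnnotation:
    """Build synthetic pathway annotations matched to a cohort config.

    Pathways are sets of gene symbols (shared namespace for mRNA and, via a
    CpG->gene map, DNAm), metabolite IDs, and OTUs (via an OTU->pathway
    map).  The first ``planted_enriched`` pathways draw
    ``effect_member_fraction`` of their members from the ground-truth
    effect features of ``intervention``, so overrepresentation methods
    have a known positive to recover.  With ``disjoint=True`` gene members
    are sampled without replacement across pathways, yielding a partition
    suitable for multivariate-hypergeometric nulls.
    """
    if not n_pathways >= planted_enriched >= 0:
        raise ValueError("need n_pathways >= planted_enriched >= 0")
    if truth is None or dataset is None:
        dataset, truth = simulate_cohort(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(64)[-1])

    genes = list(dataset.layers["mrna"].columns)
    cpgs = list(dataset.layers["dnam"].columns)
    metabolites = list(dataset.layers["metabolome"].columns)
    otus = list(dataset.layers["microbiome"].columns)

    # CpG -> gene: per-gene propensity is lognormal, so CpG-per-gene counts
    # are right-skewed (mimicking gene-length bias); ~10% of CpGs annotate
    # to a second gene
    weights = rng.lognormal(0.0, 1.0, size=len(genes))
    weights /= weights.sum()
    primary = rng.choice(len(genes), size=len(cpgs), p=weights)
    cpg_to_genes: dict[str, set[str]] = {}
    for c, gi in zip(cpgs, primary):
        members = {genes[gi]}
        if rng.random() < 0.10:
            members.add(genes[int(rng.integers(len(genes)))])
        cpg_to_genes[c] = members

    effect_cpgs = set(truth.effect_features(intervention, "dnam"))
    mrna_effect_genes = set(truth.effect_features(intervention, "mrna"))
    cpg_effect_genes = {g for c in effect_cpgs for g in cpg_to_genes[c]}
    effect_genes = mrna_effect_genes | cpg_effect_genes
    effect_mets = set(truth.effect_features(intervention, "metabolome"))
    effect_otus = set(truth.effect_features(intervention, "microbiome"))

    def _sample_members(universe, effect_pools, size, planted, available):
        # sorted: set iteration order is process-dependent, rng draws are not
        if not planted:
            # unplanted pathways sample the whole universe, so effect
            # features appear at their base rate
            pool = sorted(f for f in universe if f in available)
            size = min(size, len(pool))
            return set(rng.choice(pool, size=size, replace=False)) if size else set()
        flat_effect = set().union(*effect_pools)
        other = sorted(f for f in universe if f not in flat_effect and f in available)
        chosen: list[str] = []
        if planted:
            # split the effect quota evenly across the pools so every omic
            # layer reading this pathway sees planted members
            k_eff = int(round(effect_member_fraction * size))
            quota = [k_eff // len(effect_pools)] * len(effect_pools)
            quota[0] += k_eff - sum(quota)
            for q, pool_set in zip(quota, effect_pools):
                pool = sorted(f for f in pool_set if f in available and f not in chosen)
                q = min(q, len(pool))
                if q:
                    chosen += list(rng.choice(pool, size=q, replace=False))
        k_other = min(size - len(chosen), len(other))
        if k_other:
            chosen += list(rng.choice(other, size=k_other, replace=False))
        return set(chosen)

    gene_sets: dict[str, set[str]] = {}
    metabolite_sets: dict[str, set[str]] = {}
    otu_to_pathways: dict[str, set[str]] = {o: set() for o in otus}
    avail_genes = set(genes)
    avail_mets = set(metabolites)
    avail_otus = set(otus)
    for i in range(n_pathways):
        name = f"PW{i + 1:03d}"
        planted = i < planted_enriched
        gsize = int(rng.integers(*genes_per_pathway))
        msize = int(rng.integers(*metabolites_per_pathway))
        osize = int(rng.integers(*otus_per_pathway))
        gset = _sample_members(
            genes, [mrna_effect_genes, cpg_effect_genes], gsize, planted, avail_genes
        )
        mset = _sample_members(metabolites, [effect_mets], msize, planted, avail_mets)
        oset = _sample_members(otus, [effect_otus], osize, planted, avail_otus)
        if disjoint:
            avail_genes -= gset
            avail_mets -= mset
            avail_otus -= oset
        gene_sets[name] = gset
        metabolite_sets[name] = mset
        for o in oset:
            otu_to_pathways[o].add(name)

    return PathwayAnnotation(
        gene_sets=gene_sets,
        metabolite_sets=metabolite_sets,
        cpg_to_genes=cpg_to_genes,
        otu_to_pathways=otu_to_pathways,
        universes={
            "mrna": set(genes),
            "dnam": set(cpgs),
            "metabolome": set(metabolites),
            "microbiome": set(otus),
        },
    )
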