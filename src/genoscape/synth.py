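"""Synthetic case-control cohort generator.

Emulates the statistical structure the landscape analysis assumes:
Hardy-Weinberg genotypes in LD blocks, two latent disease subtypes driven
by disjoint causal-variant sets plus one strong shared risk locus (an
APOE4-like variant enriched in subtype 1), age/sex confounding (cases
older and more often female), subtype-2-specific depression of serum
albumin and hemoglobin, and one cis-eQTL variant-expression pair.

Case-control status is drawn from a logistic liability

    logit P(case) = b0 + b_age * age + b_sex * female + sum_g beta_g * g

over the subject's subtype-specific causal set plus the shared locus, and
exact case/control totals are met by retrospective (rejection) sampling:
candidate subjects are drawn from the generative model and accepted while
their quota is open.

Scale defaults follow the package's desk-scale study design: 2,000
subjects (941 cases / 1,059 controls, preserving the reference cohort's
case fraction) by 5,000 variants; :meth:`CohortConfig.discovery_scale`
and :meth:`CohortConfig.validation_scale` give the full cohort sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import (
    BIOMARKERS,
    CASE,
    CONTROL,
    FEMALE,
    MALE,
    GenotypeDataset,
    TruthLabels,
)

_QUOTA_CAP_MULTIPLIER = 100  # candidate cap = cap * (n_cases + n_controls)

# biomarker generative means/SDs (units as labelled)
_BIOMARKER_PARAMS = {
    "creatinine": (0.80, 0.20),  # mg/dL
    "cystatin_c": (1.00, 0.25),  # mg/L
    "egfr": (70.0, 15.0),        # mL/min/1.73m^2
    "albumin": (4.20, 0.35),     # g/dL
    "hemoglobin": (13.5, 1.50),  # g/dL
    "hba1c": (5.80, 0.60),       # %
}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generative model.

    Effect sizes are log-odds per alt allele. ``apoe_like_effect`` is the
    shared-locus effect for subtype-2 subjects; subtype-1 subjects get an
    additional ``log(apoe_like_subtype1_enrichment)`` on top, which is
    what enriches the allele among subtype-1 cases.
    """

    n_cases: int = 941
    n_controls: int = 1059
    n_variants: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 5
    ld_resample_prob: float = 0.15
    n_subtypes: int = 2
    causal_per_subtype: int = 12
    effect_size_range: tuple[float, float] = (1.5, 2.2)
    population_prevalence: float = 0.05
    loaded_fraction: float = 1.0
    subtype_separation: float = 0.75
    cluster_separation: float = 0.9
    clusters_per_subtype: int = 3
    cluster_profile_flip: float = 0.3
    apoe_like_effect: float = 1.1
    apoe_like_subtype1_enrichment: float = 2.0
    apoe_block_size: int = 4
    apoe_block_separation: float = 0.6
    age_mean_case: float = 79.1
    age_mean_control: float = 70.8
    age_sd: float = 6.1
    female_odds_case: float = 2.13
    female_odds_control: float = 1.19
    albumin_shift_sd: float = 0.5
    hemoglobin_shift_sd: float = 0.5
    missing_rate: float = 0.01
    seed: int = 0

    @classmethod
    def discovery_scale(cls, **overrides) -> "CohortConfig":
        """Full discovery-cohort sizes (1,947 cases / 2,192 controls)."""
        cfg = cls(n_cases=1947, n_controls=2192)
        return replace(cfg, **overrides)

    @classmethod
    def validation_scale(cls, **overrides) -> "CohortConfig":
        """Full validation-cohort sizes (847 cases / 2,298 controls)."""
        cfg = cls(n_cases=847, n_controls=2298, seed=1)
        return replace(cfg, **overrides)

    def validate(self) -> None:
        for name in ("n_cases", "n_controls", "n_variants", "ld_block_size",
                     "n_subtypes", "causal_per_subtype"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"config field {name!r} must be a positive integer, got {v!r}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"config field 'maf_range' must lie within (0, 0.5], got {self.maf_range!r}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"config field 'missing_rate' must be in [0, 1), got {self.missing_rate!r}")
        if not 0.0 <= self.ld_resample_prob <= 1.0:
            raise ValueError(f"config field 'ld_resample_prob' must be in [0, 1], got {self.ld_resample_prob!r}")
        if self.apoe_block_size < 1:
            raise ValueError(f"config field 'apoe_block_size' must be >= 1, got {self.apoe_block_size!r}")
        if self.apoe_block_separation < 0:
            raise ValueError(f"config field 'apoe_block_separation' must be non-negative, got {self.apoe_block_separation!r}")
        if (self.causal_per_subtype * self.n_subtypes + self.apoe_block_size
                > self.n_variants):
            raise ValueError(
                "config field 'causal_per_subtype': "
                f"{self.causal_per_subtype} x {self.n_subtypes} subtypes + "
                f"{self.apoe_block_size} shared loci exceeds n_variants={self.n_variants}"
            )
        el, eh = self.effect_size_range
        if el > eh:
            raise ValueError(f"config field 'effect_size_range' must be (low, high), got {self.effect_size_range!r}")
        if self.age_sd <= 0:
            raise ValueError(f"config field 'age_sd' must be positive, got {self.age_sd!r}")
        if self.female_odds_case <= 0 or self.female_odds_control <= 0:
            raise ValueError("config field 'female_odds_case'/'female_odds_control' must be positive")
        if not 0.0 < self.loaded_fraction <= 1.0:
            raise ValueError(f"config field 'loaded_fraction' must be in (0, 1], got {self.loaded_fraction!r}")
        if self.subtype_separation < 0:
            raise ValueError(f"config field 'subtype_separation' must be non-negative, got {self.subtype_separation!r}")
        if self.cluster_separation < 0:
            raise ValueError(f"config field 'cluster_separation' must be non-negative, got {self.cluster_separation!r}")
        if self.clusters_per_subtype < 1:
            raise ValueError(f"config field 'clusters_per_subtype' must be >= 1, got {self.clusters_per_subtype!r}")
        if not 0.0 <= self.cluster_profile_flip <= 1.0:
            raise ValueError(f"config field 'cluster_profile_flip' must be in [0, 1], got {self.cluster_profile_flip!r}")
        if not 0.0 < self.population_prevalence < 1.0:
            raise ValueError(f"config field 'population_prevalence' must be in (0, 1), got {self.population_prevalence!r}")
        if self.apoe_like_subtype1_enrichment <= 0:
            raise ValueError(f"config field 'apoe_like_subtype1_enrichment' must be positive, got {self.apoe_like_subtype1_enrichment!r}")


def _rng_streams(seed: int, n: int = 8) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _draw_genotype_batch(n: int, maf: np.ndarray, block: np.ndarray,
                         resample_prob: float, missing_rate: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` subjects from the block-copy-with-resampling LD model.

    Each block opens with an LD-independent seed variant (the causal
    candidates) followed by a chain in which variant j copies variant
    j-1 entry-wise, each entry independently redrawn from
    Binomial(2, maf) with the configured probability; pairwise r^2
    within the chain therefore decays geometrically with distance.
    """
    m = maf.shape[0]
    first_in_block = np.r_[True, block[1:] != block[:-1]]
    chain_start = np.r_[False, first_in_block[:-1]]  # variant after the seed
    out = rng.binomial(2, maf, size=(n, m)).astype(float)
    copies = ~(first_in_block | chain_start)
    # cascade the copy-with-resampling down each block's chain; the k-th
    # chain positions of all blocks are updated together
    offset = np.zeros(m, dtype=int)
    for j in range(1, m):
        offset[j] = 0 if first_in_block[j] else offset[j - 1] + 1
    for k in range(2, int(offset.max()) + 1):
        cols = np.flatnonzero(copies & (offset == k))
        if cols.size == 0:
            continue
        keep = rng.random((n, cols.size)) >= resample_prob
        out[:, cols] = np.where(keep, out[:, cols - 1], out[:, cols])
    if missing_rate > 0:
        out[rng.random((n, m)) < missing_rate] = np.nan
    return out


def simulate_genotypes(config: CohortConfig) -> GenotypeDataset:
    """Genotypes only; phenotype/age/sex left unassigned.

    The generating allele frequency and LD-block index of each variant are
    stored in ``variant_meta`` (columns ``maf_gen``, ``block``) so that
    further candidate subjects can be drawn from the identical model.
    """
    config.validate()
    rng = _rng_streams(config.seed)[0]
    m = config.n_variants
    n = config.n_cases + config.n_controls
    block = np.arange(m) // config.ld_block_size
    block_maf = rng.uniform(*config.maf_range, size=block.max() + 1)
    maf = block_maf[block]
    variant_meta = pd.DataFrame(
        {
            "chrom": "1",
            "pos": 5000 * (np.arange(m) + 1),
            "ref": "A",
            "alt": "G",
            "maf_gen": maf,
            "block": block,
        },
        index=[f"var{j:05d}" for j in range(m)],
    )
    model = _build_liability(variant_meta, config, rng)
    dosages, subtype, loaded = _draw_candidates(n, variant_meta, config, model, rng)
    subject_meta = pd.DataFrame(
        {"phenotype": np.nan, "age": np.nan, "sex": np.nan},
        index=[f"S{i:05d}" for i in range(n)],
    )
    return GenotypeDataset(dosages, variant_meta, subject_meta,
                           attrs={"config": config, "generative_model": model,
                                  "subtype_pool": subtype,
                                  "loaded_pool": loaded})


@dataclass
class _LiabilityModel:
    """Frozen generative parameters shared between paired cohorts."""

    causal: dict[int, list[tuple[str, float]]]
    shared_variants: list[str]
    shared_effect: float
    shared_enrichment: float
    b_age: float
    b_sex: float
    b0: float
    age_mean: float
    age_sd: float
    female_prob: float
    n_subtypes: int
    subtype_separation: float
    cluster_separation: float
    loaded_fraction: float
    causal_ids: list[str]        # causal sets then the shared risk block
    set_of: np.ndarray           # owning subtype per latent variant
    latent_sep: np.ndarray       # per-latent-variant subtype separation
    cluster_subtype: np.ndarray  # subtype of each latent genotype cluster
    cluster_w: np.ndarray        # (n_clusters, n_latent) profile vectors


def _pick_causal_sets(variant_meta: pd.DataFrame, config: CohortConfig,
                      rng: np.random.Generator) -> tuple[dict, list[str]]:
    """Choose disjoint causal sets (one variant per LD block, common
    alleles only) plus the shared APOE4-region-like block."""
    seeds_mask = np.arange(len(variant_meta)) % config.ld_block_size == 0
    eligible = variant_meta.index[seeds_mask & (variant_meta["maf_gen"] >= 0.2)]
    need = config.causal_per_subtype * config.n_subtypes + config.apoe_block_size
    if len(eligible) < need:
        raise ValueError(
            f"only {len(eligible)} common block-seed variants available for "
            f"{need} causal slots; increase n_variants or maf_range"
        )
    chosen = rng.choice(eligible, size=need, replace=False)
    causal = {}
    load = {}
    maf = variant_meta["maf_gen"]
    for s in range(config.n_subtypes):
        ids = chosen[s * config.causal_per_subtype:(s + 1) * config.causal_per_subtype]
        betas = rng.uniform(*config.effect_size_range, size=len(ids))
        v = 2 * maf[ids].to_numpy() * (1 - maf[ids].to_numpy())
        load[s + 1] = float(np.sum(betas**2 * v))
        causal[s + 1] = list(zip(ids.tolist(), betas.tolist()))
    # equalize the genetic liability load across subtypes so neither
    # subtype dominates the case quota
    ref = load[1]
    for s in range(2, config.n_subtypes + 1):
        if ref > 0 and load[s] > 0:
            scale = float(np.sqrt(ref / load[s]))
            causal[s] = [(vid, b * scale) for vid, b in causal[s]]
    shared = [str(v) for v in chosen[-config.apoe_block_size:]]
    return causal, shared


def _build_liability(variant_meta, config, rng) -> _LiabilityModel:
    causal, shared = _pick_causal_sets(variant_meta, config, rng)
    # latent layout: subtype causal sets first, then the shared risk block
    causal_ids = [vid for st in sorted(causal) for vid, _ in causal[st]] + shared
    set_of = np.concatenate([
        np.full(len(causal[st]), st) for st in sorted(causal)
    ] + [np.full(len(shared), 1)]).astype(int)  # shared block: subtype-1 enriched
    n_clusters = config.clusters_per_subtype * config.n_subtypes
    cluster_subtype = np.repeat(np.arange(1, config.n_subtypes + 1),
                                config.clusters_per_subtype)
    # hierarchical profiles: a subtype-level base profile (aligned +W for
    # subtype 1, -W for subtype 2) with independent per-cluster sign flips,
    # so each cluster pair separates along its own direction
    base_w = rng.choice([-1.0, 1.0], size=len(causal_ids))
    t_of_cluster = np.where(cluster_subtype == 1, 1.0, -1.0)
    flips = np.where(
        rng.random((n_clusters, len(causal_ids))) < config.cluster_profile_flip,
        -1.0, 1.0,
    )
    cluster_w = t_of_cluster[:, None] * base_w[None, :] * flips
    n_shared = len(shared)
    cluster_w[:, -n_shared:] = 0.0  # shared block: subtype factor only
    latent_sep = np.r_[np.full(len(causal_ids) - n_shared, config.subtype_separation),
                       np.full(n_shared, config.apoe_block_separation)]
    odds_mid = float(np.sqrt(config.female_odds_case * config.female_odds_control))
    return _LiabilityModel(
        causal=causal,
        shared_variants=shared,
        shared_effect=config.apoe_like_effect,
        shared_enrichment=config.apoe_like_subtype1_enrichment,
        b_age=(config.age_mean_case - config.age_mean_control) / config.age_sd**2,
        b_sex=float(np.log(config.female_odds_case / config.female_odds_control)),
        b0=0.0,  # calibrated against the first candidate pool
        age_mean=0.5 * (config.age_mean_case + config.age_mean_control),
        age_sd=config.age_sd,
        female_prob=odds_mid / (1.0 + odds_mid),
        n_subtypes=config.n_subtypes,
        subtype_separation=config.subtype_separation,
        cluster_separation=config.cluster_separation,
        loaded_fraction=config.loaded_fraction,
        causal_ids=causal_ids,
        set_of=set_of,
        latent_sep=latent_sep,
        cluster_subtype=cluster_subtype,
        cluster_w=cluster_w,
    )


def _dosage_of(dosages, variant_meta, vid):
    maf = variant_meta["maf_gen"]
    d = dosages[:, variant_meta.index.get_loc(vid)]
    return np.where(np.isnan(d), 2 * maf[vid], d)


def _set_burdens(dosages: np.ndarray, variant_meta: pd.DataFrame,
                 model: _LiabilityModel) -> np.ndarray:
    """Per-subject, per-subtype causal burden: sum of beta * centered
    dosage over that subtype's causal set (missing dosages at their HW
    mean)."""
    maf = variant_meta["maf_gen"]
    out = np.zeros((dosages.shape[0], model.n_subtypes))
    for s, pairs in model.causal.items():
        for vid, beta in pairs:
            out[:, s - 1] += beta * (_dosage_of(dosages, variant_meta, vid) - 2 * maf[vid])
    return out


def _draw_candidates(n: int, variant_meta: pd.DataFrame, config: CohortConfig,
                     model: "_LiabilityModel",
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw candidate subjects: latent subtype, disease path, genotypes.

    Every candidate carries a uniform latent subtype; a ``loaded_fraction``
    of candidates are on the genetically loaded disease path of their
    subtype, falling into one of ``clusters_per_subtype`` latent genotype
    clusters (haplotype-group-like). A loaded subtype-s subject's latent
    value at a variant of causal set s is

        x_j = m0  +  m1 * w_{c,j}  +  eps_j

    (m0 = ``subtype_separation``, m1 = ``cluster_separation``, w the
    cluster's +-1 profile, unit Gaussian noise); other-set variants and
    all background-path subjects have x_j = eps_j. The normal CDF maps
    latents to dosages, so the genetically unloaded background is exactly
    Hardy-Weinberg at each variant's generating allele frequency, while
    loaded subjects are enriched for the risk alleles of their own set —
    the enrichment the liability then sweeps into the case group.
    """
    from scipy.stats import norm as _norm

    maf = variant_meta["maf_gen"].to_numpy()
    block = variant_meta["block"].to_numpy()
    subtype = rng.integers(1, model.n_subtypes + 1, size=n)
    loaded = rng.random(n) < model.loaded_fraction
    n_clusters = len(model.cluster_subtype)
    per = n_clusters // model.n_subtypes
    cluster = rng.integers(0, per, size=n) + (subtype - 1) * per
    dosages = _draw_genotype_batch(
        n, maf, block, config.ld_resample_prob, config.missing_rate, rng
    )
    m1 = model.cluster_separation
    col = {v: j for j, v in enumerate(variant_meta.index)}
    gamma = model.loaded_fraction
    n_comp_w = np.r_[1.0 - gamma, np.full(n_clusters, gamma / n_clusters)]
    for jc, vid in enumerate(model.causal_ids):
        j = col[vid]
        m0 = model.latent_sep[jc]
        sign = np.where(subtype == model.set_of[jc], 1.0, -1.0)
        shift = np.where(
            loaded, m0 * sign + m1 * model.cluster_w[cluster, jc], 0.0
        )
        # exact pooled candidate-mixture CDF -> uniform -> HW dosage
        sign_c = np.where(model.cluster_subtype == model.set_of[jc], 1.0, -1.0)
        centers = np.r_[0.0, m0 * sign_c + m1 * model.cluster_w[:, jc]]
        x = shift + rng.normal(size=n)
        u = _norm.cdf(x[:, None] - centers[None, :]) @ n_comp_w
        p = maf[j]
        g = np.where(u < (1 - p) ** 2, 0.0,
                     np.where(u < (1 - p) ** 2 + 2 * p * (1 - p), 1.0, 2.0))
        missing = np.isnan(dosages[:, j])
        dosages[:, j] = np.where(missing, np.nan, g)
    return dosages, subtype, loaded


def _genetic_score(dosages: np.ndarray, variant_meta: pd.DataFrame,
                   subtype: np.ndarray, model: _LiabilityModel,
                   burdens: np.ndarray | None = None) -> np.ndarray:
    """Per-subject genetic liability over the subject's own causal set."""
    if burdens is None:
        burdens = _set_burdens(dosages, variant_meta, model)
    score = burdens[np.arange(len(subtype)), subtype - 1]
    eff = np.full(dosages.shape[0], model.shared_effect)
    eff[subtype == 1] += np.log(model.shared_enrichment)
    for vid in model.shared_variants:
        score = score + eff * _dosage_of(dosages, variant_meta, vid)
    return score


def simulate_phenotypes(
    geno: GenotypeDataset, config: CohortConfig
) -> tuple[GenotypeDataset, TruthLabels]:
    """Assign subtype, age, sex and case/control status.

    Candidates are the rows of ``geno`` first; once exhausted, further
    candidates are drawn from the identical generative model until the
    case and control quotas are both filled (cap: 100x the requested
    total, after which a RuntimeError is raised).
    """
    config.validate()
    streams = _rng_streams(config.seed)
    rng = streams[1]
    model = geno.attrs.get("generative_model")
    if model is None:
        model = _build_liability(geno.variant_meta, config, rng)
    return _fill_cohort(geno, config, model, rng, subject_prefix="")


def _fill_cohort(geno, config, model, rng, subject_prefix=""):
    n_target = config.n_cases + config.n_controls
    cap = _QUOTA_CAP_MULTIPLIER * n_target

    acc_rows, acc_age, acc_sex, acc_pheno, acc_subtype = [], [], [], [], []
    need_case, need_control = config.n_cases, config.n_controls
    drawn = 0
    b0 = None
    batch = max(1024, n_target)
    pool = geno.dosages
    pool_subtype = geno.attrs.get("subtype_pool")
    pool_loaded = geno.attrs.get("loaded_pool")
    if pool_subtype is None or len(pool_subtype) != pool.shape[0]:
        pool_subtype = rng.integers(1, model.n_subtypes + 1, size=pool.shape[0])
        pool_loaded = None
    if pool_loaded is None or len(pool_loaded) != pool.shape[0]:
        pool_loaded = np.zeros(pool.shape[0], dtype=bool)
    while need_case > 0 or need_control > 0:
        if pool is None:
            pool, pool_subtype, pool_loaded = _draw_candidates(
                batch, geno.variant_meta, config, model, rng
            )
        nb = pool.shape[0]
        drawn += nb
        subtype = np.asarray(pool_subtype)
        background = ~np.asarray(pool_loaded)
        burdens = _set_burdens(pool, geno.variant_meta, model)
        age = rng.normal(model.age_mean, model.age_sd, size=nb)
        female = (rng.random(nb) < model.female_prob).astype(float)
        lin = (
            model.b_age * age
            + model.b_sex * female
            + _genetic_score(pool, geno.variant_meta, subtype, model, burdens)
        )
        if b0 is None:
            # calibrate the intercept so the genetically unloaded
            # background attains the population prevalence
            target = config.population_prevalence
            ref = lin[background] if background.any() else lin
            b0 = float(np.log(target / (1 - target)) - ref.mean())
        p_case = 1.0 / (1.0 + np.exp(-(b0 + lin)))
        is_case = rng.random(nb) < p_case
        for i in range(nb):
            if is_case[i] and need_case > 0:
                need_case -= 1
            elif (not is_case[i]) and need_control > 0:
                need_control -= 1
            else:
                continue
            acc_rows.append(pool[i])
            acc_age.append(age[i])
            acc_sex.append(FEMALE if female[i] else MALE)
            acc_pheno.append(CASE if is_case[i] else CONTROL)
            acc_subtype.append(subtype[i])
            if need_case == 0 and need_control == 0:
                break
        pool = None
        if need_case > 0:
            batch = int(np.clip(
                1.5 * need_case / max(config.population_prevalence, 1e-3),
                1024, max(1, min(cap - drawn, 20_000)),
            ))
        if (need_case > 0 or need_control > 0) and drawn >= cap:
            raise RuntimeError(
                f"case/control quota unreachable after {drawn} candidates "
                f"(still need {need_case} cases, {need_control} controls); "
                "liability intercept or effects too extreme"
            )
    ids = [f"{subject_prefix}S{i:05d}" for i in range(n_target)]
    subject_meta = pd.DataFrame(
        {"phenotype": acc_pheno, "age": acc_age, "sex": acc_sex}, index=ids
    )
    out = GenotypeDataset(
        np.array(acc_rows), geno.variant_meta.copy(), subject_meta,
        attrs=dict(geno.attrs),
    )
    truth = TruthLabels(
        subtype=pd.Series(acc_subtype, index=ids, name="subtype"),
        causal_variants=model.causal,
        shared_risk_variants=list(model.shared_variants),
        shared_risk_effect=model.shared_effect,
    )
    truth.validate_against(out)
    return out, truth


def simulate_cohort(config: CohortConfig) -> tuple[GenotypeDataset, TruthLabels]:
    """Genotypes plus phenotypes in one call."""
    return simulate_phenotypes(simulate_genotypes(config), config)


def simulate_biomarkers(
    labels: TruthLabels, subject_meta: pd.DataFrame, config: CohortConfig
) -> pd.DataFrame:
    """Routine blood-test values per subject.

    Albumin and hemoglobin are depressed (by the configured number of
    generative SDs) in subtype-2 cases only; the other four markers carry
    no phenotype effect. All values are truncated to stay positive.
    """
    config.validate()
    rng = _rng_streams(config.seed)[2]
    n = len(subject_meta)
    is_case = subject_meta["phenotype"].to_numpy(dtype=float) == CASE
    sub2_case = is_case & (labels.subtype.reindex(subject_meta.index).to_numpy() == 2)
    out = {}
    shifts = {"albumin": config.albumin_shift_sd,
              "hemoglobin": config.hemoglobin_shift_sd}
    for marker in BIOMARKERS:
        mean, sd = _BIOMARKER_PARAMS[marker]
        x = rng.normal(mean, sd, size=n)
        if marker in shifts:
            x[sub2_case] -= shifts[marker] * sd
        out[marker] = np.maximum(x, 1e-3)
    return pd.DataFrame(out, index=subject_meta.index)


def simulate_expression(
    geno: GenotypeDataset,
    eqtl_variant: str,
    beta: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.Series:
    """Expression = intercept + beta * dosage + small age and sex nuisance
    terms + Gaussian noise. Missing dosages contribute their cohort mean."""
    if eqtl_variant not in geno.variant_meta.index:
        raise KeyError(f"unknown variant identifier {eqtl_variant!r}")
    rng = np.random.default_rng(seed)
    j = geno.variant_meta.index.get_loc(eqtl_variant)
    d = geno.dosages[:, j]
    d = np.where(np.isnan(d), np.nanmean(d), d)
    age = np.nan_to_num(geno.subject_meta["age"].to_numpy(dtype=float), nan=75.0)
    female = geno.subject_meta["sex"].to_numpy(dtype=float) == FEMALE
    expr = 5.0 + beta * d + 0.01 * (age - 75.0) + 0.1 * female
    expr = expr + rng.normal(0.0, noise_sd, size=len(expr))
    return pd.Series(expr, index=geno.subject_ids, name="expression")


@dataclass
class CohortPair:
    discovery: GenotypeDataset
    discovery_truth: TruthLabels
    validation: GenotypeDataset
    validation_truth: TruthLabels
    shared_variants: list[str]


def make_cohort_pair(
    config_discovery: CohortConfig,
    config_validation: CohortConfig,
    variant_overlap: float = 0.8,
) -> CohortPair:
    """Paired discovery/validation cohorts from one generative model.

    Both cohorts share the variant panel's generative parameters and the
    identical subtype-causal sets; exactly ``round(overlap * n_variants)``
    variant identifiers are shared (the remainder are relabelled
    validation-private). Causal variants and the shared risk locus always
    fall in the shared set. Subject identifiers are disjoint by
    construction (``D``/``V`` prefixes).
    """
    if not 0.0 < variant_overlap <= 1.0:
        raise ValueError(f"variant_overlap must be in (0, 1], got {variant_overlap!r}")
    if config_validation.n_variants != config_discovery.n_variants:
        raise ValueError("paired cohorts must use the same n_variants")
    config_discovery.validate()
    config_validation.validate()

    disc_geno = simulate_genotypes(config_discovery)
    streams = _rng_streams(config_discovery.seed)
    model = disc_geno.attrs["generative_model"]
    disc, disc_truth = _fill_cohort(disc_geno, config_discovery, model,
                                    streams[1], subject_prefix="D")

    val_rng = _rng_streams(config_validation.seed)[3]
    m = config_discovery.n_variants
    pool, pool_subtype, pool_loaded = _draw_candidates(
        config_validation.n_cases + config_validation.n_controls,
        disc_geno.variant_meta, config_validation, model, val_rng,
    )
    val_geno = GenotypeDataset(
        pool, disc_geno.variant_meta.copy(),
        pd.DataFrame({"phenotype": np.nan, "age": np.nan, "sex": np.nan},
                     index=[f"V{i:05d}" for i in range(pool.shape[0])]),
        attrs={"config": config_validation, "generative_model": model,
               "subtype_pool": pool_subtype, "loaded_pool": pool_loaded},
    )
    val, val_truth = _fill_cohort(val_geno, config_validation, model,
                                  val_rng, subject_prefix="V")

    n_shared = int(round(variant_overlap * m))
    must_share = {vid for pairs in model.causal.values() for vid, _ in pairs}
    must_share.update(model.shared_variants)
    others = [v for v in disc_geno.variant_ids if v not in must_share]
    n_extra = n_shared - len(must_share)
    if n_extra < 0:
        raise ValueError(
            f"overlap {variant_overlap} shares {n_shared} variants but the causal "
            f"model requires {len(must_share)} shared loci"
        )
    shared = set(list(must_share) + others[:n_extra])
    rename = {v: f"{v}_v" for v in disc_geno.variant_ids if v not in shared}
    val.variant_meta = val.variant_meta.rename(index=rename)
    shared_sorted = [v for v in disc.variant_ids if v in shared]
    return CohortPair(disc, disc_truth, val, val_truth, shared_sorted)
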