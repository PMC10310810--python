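"""PLINK-style marker and sample quality control and LD pruning.

Filter order is fixed and reported: variants (call rate, then minor
allele frequency, then Hardy-Weinberg exact test) and samples
(missingness, then heterozygosity-based inbreeding coefficient, then
pairwise relatedness via method-of-moments PI_HAT). LD pruning is the
greedy windowed procedure of ``--indep-pairwise``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datatypes import GenotypeDataset


@dataclass
class QcThresholds:
    """Cutoffs mirroring the corresponding PLINK flags."""

    geno_call_rate: float = 0.95   # --geno
    maf_min: float = 0.001         # --maf
    hwe_p_min: float = 0.001       # --hwe
    sample_missing_max: float = 0.05  # --mind
    het_f_max: float = 0.1         # --het
    pihat_max: float = 0.25        # --genome
    prune_window: int = 50         # --indep-pairwise W
    prune_step: int = 5            # --indep-pairwise S
    prune_r2: float = 0.1          # --indep-pairwise r2

    def validate(self) -> None:
        for name, lo, hi in [
            ("geno_call_rate", 0, 1), ("maf_min", 0, 0.5), ("hwe_p_min", 0, 1),
            ("sample_missing_max", 0, 1), ("het_f_max", 0, 1),
            ("pihat_max", 0, 1), ("prune_r2", 0, 1),
        ]:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"threshold {name!r}={v!r} outside [{lo}, {hi}]")
        if self.prune_step > self.prune_window:
            raise ValueError("prune_step must not exceed prune_window")
        if self.prune_window < 1 or self.prune_step < 1:
            raise ValueError("prune window/step must be positive")


@dataclass
class QcReport:
    """Cumulative record of removals; stages are applied in order."""

    stages: list[dict] = field(default_factory=list)

    def add(self, stage: str, removed: list[str], n_variants: int, n_subjects: int) -> None:
        self.stages.append(
            {
                "stage": stage,
                "removed": list(removed),
                "n_removed": len(removed),
                "n_variants_remaining": n_variants,
                "n_subjects_remaining": n_subjects,
            }
        )

    def removed_by(self, stage: str) -> list[str]:
        for s in self.stages:
            if s["stage"] == stage:
                return s["removed"]
        raise KeyError(stage)


class EmptyDatasetError(RuntimeError):
    """All rows/columns removed by a filter."""


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test p-value for one biallelic variant.

    Conditions on the observed allele counts and sums the exact
    probabilities of all heterozygote counts no more probable than the
    observed one (the standard SNP-HWE construction).
    """
    for v in (n_AA, n_Aa, n_aa):
        if v < 0 or int(v) != v:
            raise ValueError(f"genotype counts must be non-negative integers, got {v!r}")
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("total genotype count must be positive")
    rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)  # rarer allele count
    hets = np.arange(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    # log P(h | allele counts) up to a constant:
    #   P(h) propto n! 2^h / ( ((rare-h)/2)! h! ((2n-rare-h)/2)! )
    logp = (
        hets * math.log(2.0)
        - _lgamma_arr((rare - hets) // 2 + 1)
        - _lgamma_arr(hets + 1)
        - _lgamma_arr((2 * n - rare - hets) // 2 + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[hets == n_Aa]
    if p_obs.size == 0:  # parity mismatch cannot happen with valid counts
        raise ValueError("observed heterozygote count inconsistent with allele counts")
    return float(min(1.0, prob[prob <= p_obs[0] * (1 + 1e-12)].sum()))


def _lgamma_arr(x: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(np.asarray(x, dtype=float))


def genotype_counts(dosages_col: np.ndarray) -> tuple[int, int, int]:
    """(n_ref_hom, n_het, n_alt_hom) ignoring missing calls."""
    obs = dosages_col[~np.isnan(dosages_col)]
    return int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum())


def filter_variants(
    geno: GenotypeDataset,
    thr: QcThresholds | None = None,
    hwe_controls_only: bool = True,
) -> tuple[GenotypeDataset, QcReport]:
    """Remove variants failing call rate, then MAF, then HWE.

    The HWE exact test is computed in controls only when phenotypes are
    available (standard practice, so true case-only association signals
    are not discarded as genotyping failures); set
    ``hwe_controls_only=False`` to use all subjects.
    """
    thr = thr or QcThresholds()
    thr.validate()
    if geno.n_variants == 0 or geno.n_subjects == 0:
        raise EmptyDatasetError("empty dataset")
    report = QcReport()
    current = geno

    def drop(mask_bad: np.ndarray, stage: str) -> None:
        nonlocal current
        removed = list(current.variant_ids[mask_bad])
        current = current.subset(variants=~mask_bad)
        report.add(stage, removed, current.n_variants, current.n_subjects)

    drop(current.call_rate() < thr.geno_call_rate, "variant_call_rate")
    if current.n_variants:
        drop(current.minor_allele_freq() < thr.maf_min, "variant_maf")
    if current.n_variants:
        if hwe_controls_only and np.isfinite(
            current.subject_meta["phenotype"].to_numpy(dtype=float)
        ).any():
            rows = current.is_control
            sub = current.dosages[rows] if rows.any() else current.dosages
        else:
            sub = current.dosages
        pvals = np.array(
            [hwe_exact_test(*genotype_counts(sub[:, j])) if np.isfinite(sub[:, j]).any()
             else 1.0
             for j in range(current.n_variants)]
        )
        drop(pvals < thr.hwe_p_min, "variant_hwe")
    if current.n_variants == 0:
        raise EmptyDatasetError("all variants removed by QC filters")
    return current, report


def heterozygosity_f(geno: GenotypeDataset) -> np.ndarray:
    """Per-subject method-of-moments inbreeding coefficient.

    F = (E_het - O_het) / E_het with E_het the sum of 2p(1-p) over the
    subject's non-missing variants (equivalently PLINK's
    (O_hom - E_hom) / (N - E_hom))."""
    p = geno.allele_freq()
    exp_het_var = 2.0 * p * (1.0 - p)
    obs_mask = ~np.isnan(geno.dosages)
    e_het = obs_mask @ np.nan_to_num(exp_het_var)
    o_het = ((geno.dosages == 1) & obs_mask).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (e_het - o_het) / e_het
    return np.where(e_het > 0, f, 0.0)


def pi_hat_matrix(
    geno: GenotypeDataset, max_variants: int = 500
) -> np.ndarray:
    """Pairwise PI_HAT = P(IBD=1)/2 + P(IBD=2), method of moments on IBS.

    IBS sharing counts are compared with their Hardy-Weinberg
    expectations given allele frequencies. Variants with complete calls
    are preferred, thinned evenly to at most ``max_variants``.
    """
    complete = np.flatnonzero(~np.isnan(geno.dosages).any(axis=0))
    cand = complete if complete.size >= min(max_variants, geno.n_variants // 2) else np.arange(geno.n_variants)
    if cand.size > max_variants:
        cand = cand[np.linspace(0, cand.size - 1, max_variants).astype(int)]
    D = geno.dosages[:, cand]
    D = np.where(np.isnan(D), np.round(2 * np.nanmean(D, axis=0) / 2), D)  # rare; fill with rounded mean genotype
    p = D.mean(axis=0) / 2.0
    q = 1.0 - p
    # keep polymorphic variants only (monomorphic ones carry no IBD signal)
    poly = (p > 0.01) & (p < 0.99)
    D, p, q = D[:, poly], p[poly], q[poly]
    if D.shape[1] == 0:
        return np.zeros((geno.n_subjects, geno.n_subjects))
    G = [(D == k).astype(float) for k in (0.0, 1.0, 2.0)]
    ibs2 = G[0] @ G[0].T + G[1] @ G[1].T + G[2] @ G[2].T
    ibs0 = G[0] @ G[2].T + G[2] @ G[0].T
    m = D.shape[1]
    ibs1 = m - ibs2 - ibs0
    # HW expectations per variant summed over the panel, using unbiased
    # estimators of the allele-frequency monomials (falling factorials of
    # the observed allele counts) so finite samples do not inflate PI_HAT
    n2 = 2.0 * D.shape[0]        # total alleles per variant
    x = p * n2                   # alt allele count
    y = q * n2

    def mono(a: int, b: int) -> np.ndarray:
        """Unbiased estimate of p^a q^b per variant."""
        num = np.ones_like(x)
        for k in range(a):
            num = num * (x - k)
        for k in range(b):
            num = num * (y - k)
        den = np.prod([n2 - k for k in range(a + b)])
        return num / den

    e0_ibd0 = float(np.sum(2 * mono(2, 2)))
    e1_ibd0 = float(np.sum(4 * mono(3, 1) + 4 * mono(1, 3)))
    e2_ibd0 = m - e0_ibd0 - e1_ibd0
    e1_ibd1 = float(np.sum(2 * mono(2, 1) + 2 * mono(1, 2)))
    e2_ibd1 = m - e1_ibd1
    p0 = ibs0 / e0_ibd0
    p1 = (ibs1 - p0 * e1_ibd0) / e1_ibd1
    p2 = (ibs2 - p0 * e2_ibd0 - p1 * e2_ibd1) / m
    # the components are left unclipped so their sampling noise cancels in
    # the sum; only the final estimate is bounded
    pihat = np.clip(0.5 * p1 + p2, 0.0, 1.0)
    np.fill_diagonal(pihat, 0.0)
    return pihat


def filter_samples(
    geno: GenotypeDataset, thr: QcThresholds | None = None
) -> tuple[GenotypeDataset, QcReport]:
    """Remove subjects by missingness, |F| heterozygosity, and relatedness.

    Of each pair with PI_HAT above the threshold, the member with the
    higher missingness is dropped (ties: the later subject)."""
    thr = thr or QcThresholds()
    thr.validate()
    if geno.n_subjects == 0:
        raise EmptyDatasetError("empty dataset")
    report = QcReport()
    current = geno

    miss = current.sample_missingness()
    bad = miss > thr.sample_missing_max
    removed = list(current.subject_ids[bad])
    current = current.subset(subjects=~bad)
    report.add("sample_missingness", removed, current.n_variants, current.n_subjects)

    if current.n_subjects:
        f = heterozygosity_f(current)
        bad = np.abs(f) > thr.het_f_max
        removed = list(current.subject_ids[bad])
        current = current.subset(subjects=~bad)
        report.add("sample_het", removed, current.n_variants, current.n_subjects)

    if current.n_subjects >= 2:
        pihat = pi_hat_matrix(current)
        miss = current.sample_missingness()
        keep = np.ones(current.n_subjects, dtype=bool)
        pairs = np.argwhere(np.triu(pihat > thr.pihat_max, k=1))
        order = np.argsort(-pihat[pairs[:, 0], pairs[:, 1]]) if len(pairs) else []
        dropped = []
        for k in order:
            i, j = pairs[k]
            if not (keep[i] and keep[j]):
                continue
            victim = i if (miss[i], i) > (miss[j], j) else j
            keep[victim] = False
            dropped.append(current.subject_ids[victim])
        current = current.subset(subjects=keep)
        report.add("sample_relatedness", dropped, current.n_variants, current.n_subjects)

    if current.n_subjects < 2:
        raise EmptyDatasetError("fewer than 2 subjects remain after sample QC")
    return current, report


def _window_r2(D: np.ndarray) -> np.ndarray:
    """Pairwise squared dosage correlation over pairwise-complete subjects."""
    M = (~np.isnan(D)).astype(float)
    X = np.nan_to_num(D)
    n = M.T @ M
    S = X.T @ M          # S[a, b] = sum of x_a over subjects observed for both
    C = X.T @ X
    Q = (X * X).T @ M
    num = n * C - S * S.T
    den = (n * Q - S**2) * (n * Q.T - (S.T) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(den > 0, num**2 / den, 0.0)
    np.fill_diagonal(r2, 0.0)
    return r2


def ld_prune(
    geno: GenotypeDataset, thr: QcThresholds | None = None
) -> list[str]:
    """Greedy windowed LD pruning; returns kept variant identifiers.

    A window of ``prune_window`` variants slides in ``prune_step``
    increments along each chromosome; within a window the pair with the
    highest r^2 above the threshold repeatedly loses one member (the
    lower-MAF variant; ties broken toward the later position) until no
    pair exceeds the threshold."""
    thr = thr or QcThresholds()
    thr.validate()
    if geno.n_variants == 0:
        return []
    maf = geno.minor_allele_freq()
    pos = geno.variant_meta["pos"].to_numpy()
    keep = np.ones(geno.n_variants, dtype=bool)
    chroms = geno.variant_meta["chrom"].to_numpy()
    for chrom in dict.fromkeys(chroms):  # preserve order
        idx = np.flatnonzero(chroms == chrom)
        start = 0
        while start < len(idx):
            window = idx[start:start + thr.prune_window]
            active = window[keep[window]]
            if len(active) > 1:
                r2 = _window_r2(geno.dosages[:, active])
                while True:
                    a, b = np.unravel_index(np.argmax(r2), r2.shape)
                    if r2[a, b] <= thr.prune_r2:
                        break
                    va, vb = active[a], active[b]
                    # remove lower MAF; tie -> later position
                    if (maf[va], -pos[va]) < (maf[vb], -pos[vb]):
                        victim = a
                    else:
                        victim = b
                    keep[active[victim]] = False
                    r2[victim, :] = 0.0
                    r2[:, victim] = 0.0
            if start + thr.prune_window >= len(idx):
                break
            start += thr.prune_step
    return list(geno.variant_ids[keep])
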