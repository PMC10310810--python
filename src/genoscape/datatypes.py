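"""Core in-memory containers shared across the pipeline.

The universal input is a :class:`GenotypeDataset`: a subjects x variants
allele-dosage matrix (0/1/2, ``NaN`` for missing calls) together with
per-variant and per-subject metadata tables. Phenotype and sex use
PLINK-style integer coding (phenotype: 1 = control, 2 = case;
sex: 1 = male, 2 = female).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTROL = 1
CASE = 2
MALE = 1
FEMALE = 2

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt"]
SUBJECT_COLUMNS = ["phenotype", "age", "sex"]


class GenotypeError(ValueError):
    """Raised when a genotype container violates its invariants."""


@dataclass
class GenotypeDataset:
    """Subjects x variants dosage matrix with aligned metadata.

    Parameters
    ----------
    dosages
        Float array of shape ``(n_subjects, n_variants)`` with entries in
        ``{0, 1, 2}`` or ``NaN`` for missing calls.
    variant_meta
        DataFrame indexed by unique variant identifier with columns
        ``chrom``, ``pos``, ``ref``, ``alt`` (extra columns are preserved;
        the synthetic generator stores its generating allele frequencies
        there). Positions must be strictly increasing within a chromosome.
    subject_meta
        DataFrame indexed by unique subject identifier with columns
        ``phenotype`` (1=control, 2=case, NaN=unassigned), ``age`` (years)
        and ``sex`` (1=male, 2=female).
    """

    dosages: np.ndarray
    variant_meta: pd.DataFrame
    subject_meta: pd.DataFrame
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise GenotypeError("dosages must be a 2-D subjects x variants array")
        n_subj, n_var = self.dosages.shape
        if len(self.subject_meta) != n_subj:
            raise GenotypeError(
                f"subject_meta has {len(self.subject_meta)} rows, dosages has {n_subj}"
            )
        if len(self.variant_meta) != n_var:
            raise GenotypeError(
                f"variant_meta has {len(self.variant_meta)} rows, dosages has {n_var}"
            )
        if not self.subject_meta.index.is_unique:
            raise GenotypeError("subject identifiers are not unique")
        if not self.variant_meta.index.is_unique:
            raise GenotypeError("variant identifiers are not unique")
        observed = self.dosages[~np.isnan(self.dosages)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            bad = observed[~np.isin(observed, (0.0, 1.0, 2.0))][0]
            raise GenotypeError(f"dosage entries must be 0/1/2/missing, found {bad!r}")
        for col in VARIANT_COLUMNS:
            if col not in self.variant_meta.columns:
                raise GenotypeError(f"variant_meta lacks required column {col!r}")
        pos = self.variant_meta[["chrom", "pos"]]
        for chrom, grp in pos.groupby("chrom", sort=False):
            d = np.diff(grp["pos"].to_numpy())
            if d.size and not (d > 0).all():
                raise GenotypeError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )
        for col in SUBJECT_COLUMNS:
            if col not in self.subject_meta.columns:
                raise GenotypeError(f"subject_meta lacks required column {col!r}")

    # -- convenience accessors -------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> pd.Index:
        return self.variant_meta.index

    @property
    def subject_ids(self) -> pd.Index:
        return self.subject_meta.index

    @property
    def is_case(self) -> np.ndarray:
        return self.subject_meta["phenotype"].to_numpy(dtype=float) == CASE

    @property
    def is_control(self) -> np.ndarray:
        return self.subject_meta["phenotype"].to_numpy(dtype=float) == CONTROL

    def variant_indexer(self, variant_ids) -> np.ndarray:
        idx = self.variant_meta.index.get_indexer(variant_ids)
        if (idx < 0).any():
            missing = [v for v, i in zip(variant_ids, idx) if i < 0]
            raise KeyError(f"variants not in dataset: {missing}")
        return idx

    def subset(self, subjects=None, variants=None) -> "GenotypeDataset":
        """Return a copy restricted to the given subject/variant identifiers
        (or boolean/integer indexers)."""
        sub_idx = np.arange(self.n_subjects)
        var_idx = np.arange(self.n_variants)
        if subjects is not None:
            subjects = np.asarray(subjects)
            if subjects.dtype == bool:
                sub_idx = np.flatnonzero(subjects)
            elif np.issubdtype(subjects.dtype, np.integer):
                sub_idx = subjects
            else:
                sub_idx = self.subject_meta.index.get_indexer(subjects)
                if (sub_idx < 0).any():
                    raise KeyError("unknown subject identifiers in subset")
        if variants is not None:
            variants = np.asarray(variants)
            if variants.dtype == bool:
                var_idx = np.flatnonzero(variants)
            elif np.issubdtype(variants.dtype, np.integer):
                var_idx = variants
            else:
                var_idx = self.variant_indexer(variants)
        return GenotypeDataset(
            dosages=self.dosages[np.ix_(sub_idx, var_idx)].copy(),
            variant_meta=self.variant_meta.iloc[var_idx].copy(),
            subject_meta=self.subject_meta.iloc[sub_idx].copy(),
            attrs=dict(self.attrs),
        )

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per variant over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def minor_allele_freq(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        """Per-variant fraction of non-missing calls."""
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def sample_missingness(self) -> np.ndarray:
        """Per-subject fraction of missing calls."""
        return np.isnan(self.dosages).mean(axis=1)

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            np.array_equal(self.dosages, other.dosages, equal_nan=True)
            and self.variant_meta.index.equals(other.variant_meta.index)
            and self.subject_meta.index.equals(other.subject_meta.index)
            and self.variant_meta[VARIANT_COLUMNS].equals(
                other.variant_meta[VARIANT_COLUMNS]
            )
            and self.subject_meta[SUBJECT_COLUMNS].astype(float).equals(
                other.subject_meta[SUBJECT_COLUMNS].astype(float)
            )
        )


@dataclass
class TruthLabels:
    """Ground truth attached to a synthetic cohort.

    ``subtype`` holds the latent disease-subtype index (1-based) per
    subject; ``causal_variants`` maps each subtype to its driver variants
    and true log-odds effects; ``shared_risk_variants`` is the strong
    APOE4-region-like block carried by both subtypes (enriched in
    subtype 1).
    """

    subtype: pd.Series
    causal_variants: dict[int, list[tuple[str, float]]]
    shared_risk_variants: list[str]
    shared_risk_effect: float

    @property
    def shared_risk_variant(self) -> str:
        return self.shared_risk_variants[0]

    def validate_against(self, geno: GenotypeDataset) -> None:
        known = set(geno.variant_ids)
        for st, pairs in self.causal_variants.items():
            for vid, _ in pairs:
                if vid not in known:
                    raise GenotypeError(
                        f"causal variant {vid!r} of subtype {st} absent from dataset"
                    )
        for vid in self.shared_risk_variants:
            if vid not in known:
                raise GenotypeError(
                    f"shared risk variant {vid!r} absent from dataset"
                )


BIOMARKERS = ["creatinine", "cystatin_c", "egfr", "albumin", "hemoglobin", "hba1c"]
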