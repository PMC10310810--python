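"""End-to-end orchestration: QC -> GWAS -> landscape -> prediction.

``run_discovery`` takes a phenotyped cohort through marker/sample QC, LD
pruning, the covariate-adjusted logistic scan, coefficient-weighted PCA
with mean-threshold binarization, and the maximum-entropy landscape with
its two-group split. ``run_prediction`` trains the PC-score network on
the discovery cohort (restricted to variants present in the validation
panel) and scores node-based accuracy on both cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeDataset
from .gwas import logistic_gwas, select_signals
from .landscape import EnergyLandscape, WeightedPCABinarizer
from .predictor import NetConfig, PCScorePredictor, PredictionAssessment, assess, predict_states
from .qc import QcReport, QcThresholds, filter_samples, filter_variants, ld_prune


@dataclass
class DiscoveryResult:
    geno: GenotypeDataset
    variant_report: QcReport
    sample_report: QcReport
    pruned_variants: list[str]
    gwas: pd.DataFrame
    selected_variants: list[str]
    selected_betas: np.ndarray
    encoder: WeightedPCABinarizer
    states: np.ndarray
    landscape: EnergyLandscape
    assignments: pd.DataFrame  # index: subject id; state, basin, group

    def save(self, path) -> None:
        """Bundle (JSON) sufficient to re-map new subjects without refitting."""
        bundle = {
            "selected_variants": list(self.selected_variants),
            "selected_betas": list(map(float, self.selected_betas)),
            "encoder": self.encoder.to_dict(),
            "landscape": self.landscape.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(bundle, fh)


def load_bundle(path) -> tuple[list[str], WeightedPCABinarizer, EnergyLandscape]:
    with open(path) as fh:
        bundle = json.load(fh)
    return (
        bundle["selected_variants"],
        WeightedPCABinarizer.from_dict(bundle["encoder"]),
        EnergyLandscape.from_dict(bundle["landscape"]),
    )


def run_discovery(
    geno: GenotypeDataset,
    thresholds: QcThresholds | None = None,
    n_components: int = 7,
    p_threshold: float = 0.01,
    lr: float = 0.1,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    sample_qc: bool = True,
    prune: bool = True,
) -> DiscoveryResult:
    thresholds = thresholds or QcThresholds()
    geno_v, variant_report = filter_variants(geno, thresholds)
    if sample_qc:
        geno_qc, sample_report = filter_samples(geno_v, thresholds)
    else:
        geno_qc, sample_report = geno_v, QcReport()
    if prune:
        pruned = ld_prune(geno_qc, thresholds)
        geno_p = geno_qc.subset(variants=np.asarray(pruned))
    else:
        pruned = list(geno_qc.variant_ids)
        geno_p = geno_qc
    results = logistic_gwas(geno_p)
    selected, betas = select_signals(results, p_threshold)
    X = geno_p.dosages[:, geno_p.variant_indexer(selected)]
    encoder = WeightedPCABinarizer(n_components=n_components)
    states = encoder.fit_binarize(X, weights=betas, variant_ids=selected)
    scape = EnergyLandscape(lr=lr, tol=tol, max_iter=max_iter).fit(
        states, geno_p.is_case
    )
    assignments = scape.assign(states)
    assignments.index = geno_p.subject_ids
    return DiscoveryResult(
        geno=geno_p,
        variant_report=variant_report,
        sample_report=sample_report,
        pruned_variants=pruned,
        gwas=results,
        selected_variants=list(selected),
        selected_betas=betas,
        encoder=encoder,
        states=states,
        landscape=scape,
        assignments=assignments,
    )


def project_cohort(
    encoder: WeightedPCABinarizer,
    selected_variants: list[str],
    geno: GenotypeDataset,
) -> np.ndarray:
    """Direct (non-network) mapping of a cohort onto the landscape.

    Builds the dosage matrix over the encoder's training variants,
    filling variants absent from the cohort with missing values (imputed
    at the training means inside ``transform``), and binarizes with the
    stored thresholds."""
    n = geno.n_subjects
    X = np.full((n, len(selected_variants)), np.nan)
    present = [
        (k, v) for k, v in enumerate(selected_variants)
        if v in geno.variant_meta.index
    ]
    if present:
        cols = geno.variant_indexer([v for _, v in present])
        X[:, [k for k, _ in present]] = geno.dosages[:, cols]
    return encoder.binarize(encoder.transform(X))


@dataclass
class PredictionResult:
    predictor: PCScorePredictor
    input_variants: list[str]
    discovery_assessment: PredictionAssessment
    validation_assessment: PredictionAssessment
    validation_true_groups: np.ndarray


def run_prediction(
    disc: DiscoveryResult,
    validation: GenotypeDataset,
    net_config: NetConfig | None = None,
) -> PredictionResult:
    """Train the PC-score network and assess node accuracy on both cohorts.

    Network inputs are the association signals present in both panels.
    Validation subjects' "true group" is the landscape group of their
    directly binarized PCA projection (absent variants imputed at
    training means)."""
    input_variants = [
        v for v in disc.selected_variants if v in validation.variant_meta.index
    ]
    if not input_variants:
        raise ValueError("no selected variant is present in the validation panel")
    X = disc.geno.dosages[:, disc.geno.variant_indexer(input_variants)]
    predictor = PCScorePredictor(config=net_config)
    predictor.fit(
        X,
        disc.encoder.scores_,
        variant_ids=input_variants,
        landscape=disc.landscape,
        thresholds=disc.encoder.thresholds_,
        is_case=disc.geno.is_case,
        true_groups=disc.assignments["group"].to_numpy(),
    )
    disc_states = predict_states(predictor, disc.geno)
    disc_assess = assess(
        disc.landscape, disc_states, disc.geno.is_case,
        disc.assignments["group"].to_numpy(),
    )
    val_truth_states = project_cohort(
        disc.encoder, disc.selected_variants, validation
    )
    val_true_groups = disc.landscape.assign(val_truth_states)["group"].to_numpy()
    val_states = predict_states(predictor, validation)
    val_assess = assess(
        disc.landscape, val_states, validation.is_case, val_true_groups
    )
    return PredictionResult(
        predictor=predictor,
        input_variants=input_variants,
        discovery_assessment=disc_assess,
        validation_assessment=val_assess,
        validation_true_groups=val_true_groups,
    )


def case_subtype_ari(disc: DiscoveryResult, truth_subtype: pd.Series) -> float:
    """Adjusted Rand index between the landscape's two-group split and
    the latent subtype, over cases (the subtype is a disease subtype;
    control genotypes carry no subtype signal)."""
    from sklearn.metrics import adjusted_rand_score

    ids = disc.assignments.index
    is_case = disc.geno.is_case
    truth = truth_subtype.reindex(ids).to_numpy()
    pred = disc.assignments["group"].to_numpy()
    mask = is_case & np.isfinite(truth.astype(float))
    return float(adjusted_rand_score(truth[mask], pred[mask]))
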