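"""Covariate-adjusted logistic association scan.

Each variant is tested with the model

    logit P(case_i) = b0 + b1 * age_i + b2 * sex_i + b3 * dosage_i

fit by iteratively reweighted least squares on the subjects with a
non-missing call at that variant (complete-case, as PLINK does), and
summarized by the Wald statistic for b3. Sex (1=male, 2=female) enters
centered; age in years, uncentered — the intercept is not interpreted.

Rows where the fit degenerates (monomorphic dosage, perfect separation,
non-convergence) are flagged, never raised.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .datatypes import CASE, GenotypeDataset

FLAG_OK = ""
FLAG_MONOMORPHIC = "MONOMORPHIC"
FLAG_SEPARATION = "SEPARATION"
FLAG_NOCONV = "NOCONV"
FLAG_SINGULAR = "SINGULAR"

GWAS_COLUMNS = ["variant", "beta", "se", "or_", "l95", "u95", "p", "n_used", "flag"]


def _fit_logistic_irls(
    X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray | None, str]:
    """IRLS (Newton) fit; returns (beta, covariance, flag).

    Convergence: max absolute score < tol. Divergence of coefficients
    with fitted probabilities at the boundary is reported as separation.
    """
    beta = np.zeros(X.shape[1])
    flag = FLAG_NOCONV
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        p = expit(eta)
        score = X.T @ (y - p)
        if np.max(np.abs(score)) < tol:
            flag = FLAG_OK
            break
        w = np.clip(p * (1.0 - p), 1e-12, None)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            return beta, None, FLAG_SINGULAR
        # dampened Newton: halve overshooting steps for stability
        if np.max(np.abs(step)) > 10.0:
            step *= 10.0 / np.max(np.abs(step))
        beta = beta + step
        if np.max(np.abs(beta)) > 30.0:
            return beta, None, FLAG_SEPARATION
    eta = np.clip(X @ beta, -30.0, 30.0)
    p = expit(eta)
    w = np.clip(p * (1.0 - p), 1e-12, None)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return beta, None, FLAG_SINGULAR
    # a "converged" score with a diverged coefficient is separation too
    if np.max(np.abs(beta)) > 12.0:
        flag = FLAG_SEPARATION
    return beta, cov, flag


def logistic_gwas(
    geno: GenotypeDataset,
    covariates: bool = True,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> pd.DataFrame:
    """Per-variant logistic association; returns one row per variant with
    columns ``variant, beta, se, or_, l95, u95, p, n_used, flag``."""
    pheno = geno.subject_meta["phenotype"].to_numpy(dtype=float)
    age = geno.subject_meta["age"].to_numpy(dtype=float)
    sex = geno.subject_meta["sex"].to_numpy(dtype=float)
    base_ok = np.isfinite(pheno)
    if covariates:
        base_ok &= np.isfinite(age) & np.isfinite(sex)
    if base_ok.sum() < 4:
        raise ValueError("need at least 4 subjects with phenotype (and covariates)")
    y_all = (pheno == CASE).astype(float)
    if len(np.unique(y_all[base_ok])) < 2:
        raise ValueError("need both cases and controls")
    sex_c = sex - np.nanmean(sex[base_ok])

    rows = []
    for j, vid in enumerate(geno.variant_ids):
        d = geno.dosages[:, j]
        ok = base_ok & np.isfinite(d)
        n_used = int(ok.sum())
        rec = dict.fromkeys(GWAS_COLUMNS, np.nan)
        rec.update(variant=vid, n_used=n_used, flag=FLAG_OK)
        if n_used < 4 or np.nanstd(d[ok]) == 0 or len(np.unique(y_all[ok])) < 2:
            rec["flag"] = FLAG_MONOMORPHIC
            rows.append(rec)
            continue
        if covariates:
            X = np.column_stack(
                [np.ones(n_used), age[ok], sex_c[ok], d[ok]]
            )
        else:
            X = np.column_stack([np.ones(n_used), d[ok]])
        beta, cov, flag = _fit_logistic_irls(X, y_all[ok], tol=tol, max_iter=max_iter)
        rec["flag"] = flag
        if flag == FLAG_OK and cov is not None:
            b3 = beta[-1]
            se = float(np.sqrt(cov[-1, -1]))
            z = b3 / se if se > 0 else np.inf
            rec.update(
                beta=float(b3),
                se=se,
                or_=float(np.exp(b3)),
                l95=float(np.exp(b3 - 1.959963984540054 * se)),
                u95=float(np.exp(b3 + 1.959963984540054 * se)),
                p=float(2.0 * norm.sf(abs(z))),
            )
        rows.append(rec)
    return pd.DataFrame(rows, columns=GWAS_COLUMNS)


def select_signals(
    results: pd.DataFrame, p_threshold: float = 0.01
) -> tuple[list[str], np.ndarray]:
    """Variants with p below the threshold and their coefficients, in
    input (dataset) order; flagged rows are excluded."""
    if len(results) == 0:
        raise ValueError("empty association results")
    ok = (results["flag"] == FLAG_OK) & results["p"].notna()
    hits = results[ok & (results["p"] < p_threshold)]
    if len(hits) == 0:
        raise ValueError(
            f"no variants reach p < {p_threshold}; cannot build a landscape"
        )
    return list(hits["variant"]), hits["beta"].to_numpy(dtype=float)
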