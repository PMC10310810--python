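"""Group-level statistics downstream of the landscape split.

Covers: representative-cluster selection (nodes where case and control
frequencies differ by more than a cutoff), within-cluster logistic
association with Bonferroni correction, exact r x c contingency tests
(Fisher-Freeman-Halton) for allele-count tables, carrier percentages,
Kendall's tau across landscape nodes, Wilcoxon rank-sum biomarker
comparisons with Benjamini-Hochberg FDR, and the eQTL linear regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import kendalltau, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .datatypes import BIOMARKERS, GenotypeDataset
from .gwas import FLAG_OK, logistic_gwas

KIDNEY_MARKERS = ["creatinine", "cystatin_c", "egfr", "albumin", "hemoglobin"]


# --------------------------------------------------------------------------
# representative clusters and within-cluster association
# --------------------------------------------------------------------------

@dataclass
class ClusterSelection:
    """Landscape nodes of one group whose |case-control frequency
    difference| exceeds the selection threshold, with their basin
    subjects."""

    group: int
    minima: list[int]
    subject_ids: list[str]
    n_case: int
    n_control: int
    threshold: float


def select_representative(
    node_summary: pd.DataFrame,
    groups: dict[int, int],
    assignments: pd.DataFrame,
    is_case: pd.Series,
    threshold: float = 0.05,
) -> dict[int, ClusterSelection]:
    """Per group, the minima with |freq_diff| > threshold and the
    subjects in their basins. Empty selections are returned (with a
    warning) rather than raised."""
    import warnings

    out: dict[int, ClusterSelection] = {}
    for g in sorted(set(groups.values())):
        minima = [
            m for m, grp in groups.items()
            if grp == g and abs(node_summary.loc[m, "freq_diff"]) > threshold
        ]
        mask = assignments["basin"].isin(minima)
        ids = list(assignments.index[mask])
        case_mask = is_case.reindex(ids).to_numpy(dtype=bool)
        out[g] = ClusterSelection(
            group=g,
            minima=sorted(minima),
            subject_ids=ids,
            n_case=int(case_mask.sum()),
            n_control=int((~case_mask).sum()),
            threshold=threshold,
        )
        if not minima:
            warnings.warn(f"group {g}: no node exceeds |freq_diff| > {threshold}",
                          stacklevel=2)
    return out


def cluster_association(
    geno: GenotypeDataset,
    selection: ClusterSelection,
    alpha: float = 0.05,
    p_floor_monomorphic: bool = True,
) -> pd.DataFrame:
    """Age/sex-adjusted logistic scan restricted to the selection's
    subjects, Bonferroni-corrected over the variants actually tested
    (unflagged rows) within the selection."""
    if not selection.subject_ids:
        raise ValueError("empty cluster selection")
    sub = geno.subset(subjects=np.asarray(selection.subject_ids))
    res = logistic_gwas(sub)
    tested = res["flag"] == FLAG_OK
    m = int(tested.sum())
    res = res.copy()
    res["m_tests"] = m
    res["p_bonferroni"] = np.where(
        tested, np.minimum(1.0, res["p"] * m), np.nan
    )
    res["significant"] = res["p_bonferroni"] < alpha
    return res


def bonferroni(p: np.ndarray, m: int | None = None) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    m = m or p.size
    return np.minimum(1.0, m * p)


# --------------------------------------------------------------------------
# exact contingency tests
# --------------------------------------------------------------------------

def _log_choose(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_rxc(table) -> float:
    """Two-sided Fisher-Freeman-Halton exact test for an r x c table.

    Sums the conditional probabilities (margins fixed) of every table no
    more probable than the observed one. 2 x c tables are enumerated with
    a vectorized inner column; larger tables fall back to plain recursion
    and are only practical for small margins.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or (np.asarray(table) != t).any() or (t < 0).any():
        raise ValueError("table must be a 2-D array of non-negative integers")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise ValueError("all row and column margins must be positive")
    if t.shape[0] > t.shape[1]:
        t = t.T
    if t.shape[0] == 2:
        return _fisher_2xc(t)
    return _fisher_recursive(t)


def _fisher_2xc(t: np.ndarray) -> float:
    cols = t.sum(axis=0)
    r0 = int(t[0].sum())
    n = int(t.sum())
    log_denom = _log_choose(n, r0)
    # compare unnormalized numerators; divide by the common denominator at the end
    logp_obs = float(_log_choose(cols, t[0]).sum())
    total = [0.0]
    eps = 1e-7

    c = len(cols)

    def rec(j: int, remaining: int, logp: float) -> None:
        if j == c - 1:
            if 0 <= remaining <= cols[j]:
                lp = logp + float(_log_choose(cols[j], remaining))
                if lp <= logp_obs + eps:
                    total[0] += np.exp(lp - log_denom)
            return
        if j == c - 2:
            # vectorized final two columns
            lo = max(0, remaining - cols[j + 1])
            hi = min(cols[j], remaining)
            if lo > hi:
                return
            a = np.arange(lo, hi + 1)
            lp = (
                logp
                + _log_choose(cols[j], a)
                + _log_choose(cols[j + 1], remaining - a)
            )
            total[0] += float(
                np.exp(lp[lp <= logp_obs + eps] - log_denom).sum()
            )
            return
        for a in range(min(cols[j], remaining) + 1):
            rec(j + 1, remaining - a, logp + float(_log_choose(cols[j], a)))

    rec(0, r0, 0.0)
    return float(min(1.0, total[0]))


def _fisher_recursive(t: np.ndarray) -> float:
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = int(t.sum())
    log_const = float(gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
                      - gammaln(n + 1))

    def log_prob(tab: np.ndarray) -> float:
        return log_const - float(gammaln(np.asarray(tab) + 1).sum())

    logp_obs = log_prob(t)
    r, c = t.shape
    total = [0.0]
    eps = 1e-7
    work = np.zeros((r, c), dtype=int)

    def rec(i: int, j: int, row_left: np.ndarray, col_left: np.ndarray) -> None:
        if i == r - 1:
            work[i] = col_left
            if (col_left >= 0).all():
                lp = log_prob(work)
                if lp <= logp_obs + eps:
                    total[0] += np.exp(lp)
            return
        if j == c - 1:
            v = row_left[i]
            if 0 <= v <= col_left[j]:
                work[i, j] = v
                cl = col_left.copy()
                cl[j] -= v
                rec(i + 1, 0, row_left, cl)
            return
        for v in range(min(row_left[i], col_left[j]) + 1):
            work[i, j] = v
            rl = row_left.copy()
            rl[i] -= v
            cl = col_left.copy()
            cl[j] -= v
            rec(i, j + 1, rl, cl)

    rec(0, 0, rows.copy(), cols.copy())
    return float(min(1.0, total[0]))


def carrier_percentage(n0: int, n1: int, n2: int) -> float:
    """Percentage of subjects carrying at least one risk allele, to two
    decimals: 100 * (n1 + n2) / (n0 + n1 + n2)."""
    for v in (n0, n1, n2):
        if v < 0:
            raise ValueError("counts must be non-negative")
    total = n0 + n1 + n2
    if total == 0:
        raise ValueError("total count must be positive")
    return round(100.0 * (n1 + n2) / total, 2)


def kendall_tau_nodes(x, y) -> tuple[float, float]:
    """Kendall's tau-b with tie correction across landscape nodes."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("need >= 3 paired node values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("tau undefined: an input is constant (all tied)")
    res = kendalltau(x, y)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# biomarker comparisons
# --------------------------------------------------------------------------

def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value; exact enumeration when both
    samples are small (n <= 10) and tie-free, else the normal
    approximation with tie and continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    small = len(x) <= 10 and len(y) <= 10
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (small and no_ties) else "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def benjamini_hochberg(p) -> np.ndarray:
    """Step-up FDR q-values (monotone, order-invariant)."""
    p = np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_biomarkers(
    markers: pd.DataFrame,
    is_case: pd.Series,
    group_of_subject: pd.Series,
    fdr_family: list[str] = KIDNEY_MARKERS,
) -> pd.DataFrame:
    """Per landscape group, case-vs-control Wilcoxon rank-sum tests of
    each biomarker, with Benjamini-Hochberg q-values computed within the
    kidney-marker family of each group; markers outside the family
    (HbA1c) are reported uncorrected."""
    import warnings

    rows = []
    for g in sorted(group_of_subject.dropna().unique()):
        ids = group_of_subject.index[group_of_subject == g]
        ids = ids.intersection(markers.index)
        case_ids = [s for s in ids if bool(is_case.get(s))]
        ctrl_ids = [s for s in ids if not bool(is_case.get(s))]
        for marker in markers.columns:
            xc = markers.loc[case_ids, marker].dropna()
            xn = markers.loc[ctrl_ids, marker].dropna()
            if len(xc) < 2 or len(xn) < 2:
                warnings.warn(
                    f"group {g}, marker {marker}: a class has <2 subjects; skipped",
                    stacklevel=2,
                )
                continue
            rows.append(
                {
                    "group": int(g),
                    "marker": marker,
                    "n_case": len(xc),
                    "n_control": len(xn),
                    "wilcoxon_p": wilcoxon_rank_sum(xc, xn),
                    "fdr_q": np.nan,
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    for g in out["group"].unique():
        fam = out.index[(out["group"] == g) & out["marker"].isin(fdr_family)]
        if len(fam):
            out.loc[fam, "fdr_q"] = benjamini_hochberg(out.loc[fam, "wilcoxon_p"])
    return out


# --------------------------------------------------------------------------
# eQTL regression
# --------------------------------------------------------------------------

def eqtl_linear(expression, dosage, age, sex) -> tuple[float, float, float]:
    """OLS of expression on dosage adjusting for age and sex; returns
    (beta, se, p) for the dosage coefficient (two-sided t-test)."""
    import statsmodels.api as sm

    expression = np.asarray(expression, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    ok = np.isfinite(expression) & np.isfinite(dosage) & np.isfinite(age) & np.isfinite(sex)
    if ok.sum() < 4:
        raise ValueError("need at least 4 complete observations")
    if np.std(dosage[ok]) == 0:
        raise ValueError("degenerate predictor: dosage has zero variance")
    X = sm.add_constant(np.column_stack([dosage[ok], age[ok], sex[ok]]))
    fit = sm.OLS(expression[ok], X).fit()
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])
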