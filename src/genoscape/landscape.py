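"""Energy-landscape construction over binarized genotype PC scores.

The pipeline stage this module implements: dosages at the association
signals are weighted by their logistic coefficients and decomposed by
PCA; each subject's first ``N`` PC scores are binarized to a spin vector
``(sigma_1 .. sigma_N)`` in {-1, +1}^N at the across-subject mean of each
component; the empirical distribution of the ``2^N`` states is fit with
the pairwise maximum-entropy (Boltzmann/Ising) model

    P(V) = exp(-E(V)) / Z,   E(V) = - sum_i h_i sigma_i
                                    - sum_{i<j} J_ij sigma_i sigma_j;

local minima of E define the landscape's nodes, steepest single-flip
descent assigns every state to a basin, and a union-find sweep over
states in energy order yields the disconnectivity tree, whose root cut
splits the cohort into two groups.

State indexing: bit ``i`` of the state index set <=> ``sigma_{i+1} = +1``
(component 1 is the least significant bit). All tie-breaks (minima,
descent, state ordering) are lexicographic by (energy, state index).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "WeightedPCABinarizer",
    "PairwiseMaxEnt",
    "EnergyLandscape",
    "DisconnectivityTree",
    "ConvergenceError",
    "all_states",
    "state_index",
    "state_vector",
    "empirical_distribution",
    "find_local_minima",
    "descend",
    "basin_map",
    "build_disconnectivity",
    "summarize_nodes",
]


# --------------------------------------------------------------------------
# state indexing
# --------------------------------------------------------------------------

def all_states(n_spins: int) -> np.ndarray:
    """All 2^N spin vectors as a (2^N, N) array of -1/+1."""
    idx = np.arange(2**n_spins)
    bits = (idx[:, None] >> np.arange(n_spins)) & 1
    return (2 * bits - 1).astype(float)


def state_index(sigma: np.ndarray) -> np.ndarray:
    """Spin vector(s) -> integer state index (component 1 = LSB)."""
    sigma = np.asarray(sigma)
    bits = (sigma > 0).astype(int)
    weights = 1 << np.arange(sigma.shape[-1])
    return bits @ weights


def state_vector(index: int, n_spins: int) -> np.ndarray:
    bits = (index >> np.arange(n_spins)) & 1
    return (2 * bits - 1).astype(float)


def empirical_distribution(states: np.ndarray, n_spins: int | None = None) -> np.ndarray:
    """Relative frequency of each state index over subjects."""
    states = np.asarray(states)
    if states.ndim != 2 or states.shape[0] == 0:
        raise ValueError("states must be a non-empty (subjects x N) array")
    n = n_spins or states.shape[1]
    counts = np.bincount(state_index(states), minlength=2**n).astype(float)
    return counts / counts.sum()


# --------------------------------------------------------------------------
# weighted PCA + binarization
# --------------------------------------------------------------------------

class WeightedPCABinarizer(TransformerMixin, BaseEstimator):
    """Coefficient-weighted PCA of dosages with mean-threshold binarization.

    Dosage columns are mean-imputed, standardized (optional), multiplied
    by their association coefficients, and decomposed by SVD. PC scores
    are binarized at the per-component mean of the training scores; the
    thresholds, imputation means and scalings are stored so validation
    subjects can be mapped with the training-time rule.

    Attributes (after ``fit``)
    --------------------------
    loadings_ : (m, N) orthonormal component loadings (each column's
        largest-magnitude entry is positive).
    scores_ : (n, N) training PC scores.
    thresholds_ : per-component binarization cut.
    explained_variance_ : non-increasing across components.
    """

    def __init__(self, n_components: int = 7, standardize: bool = True):
        self.n_components = n_components
        self.standardize = standardize

    def fit(self, X, y=None, weights=None, variant_ids=None):
        Xw = self._prepare_fit(np.asarray(X, dtype=float), weights, variant_ids)
        n, m = Xw.shape
        if self.n_components > min(n, m):
            raise ValueError(
                f"n_components={self.n_components} exceeds matrix size {min(n, m)}"
            )
        U, S, Vt = np.linalg.svd(Xw, full_matrices=False)
        rank = int((S > S[0] * 1e-10).sum()) if S.size else 0
        if self.n_components > rank:
            raise ValueError(
                f"n_components={self.n_components} exceeds matrix rank {rank}"
            )
        V = Vt[: self.n_components].T
        # deterministic sign: largest-|.| entry of each loading positive
        flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(V.shape[1])])
        flip[flip == 0] = 1.0
        V = V * flip
        self.loadings_ = V
        self.singular_values_ = S[: self.n_components]
        self.explained_variance_ = S[: self.n_components] ** 2 / max(n - 1, 1)
        self.scores_ = Xw @ V
        self.thresholds_ = self.scores_.mean(axis=0)
        return self

    def _prepare_fit(self, X, weights, variant_ids):
        if X.ndim != 2:
            raise ValueError("X must be 2-D (subjects x variants)")
        m = X.shape[1]
        weights = np.ones(m) if weights is None else np.asarray(weights, dtype=float)
        if weights.shape != (m,):
            raise ValueError("weights must have one entry per variant")
        if np.all(weights == 0):
            raise ValueError("all-zero weights give a degenerate zero matrix")
        means = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
        means = np.where(np.isnan(means), 0.0, means)
        Xi = np.where(np.isnan(X), means[None, :], X)
        sds = Xi.std(axis=0)
        keep = sds > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance variant(s) from PCA",
                stacklevel=2,
            )
        if not keep.any():
            raise ValueError("all variants have zero variance after imputation")
        self.kept_mask_ = keep
        self.variant_ids_ = (
            list(np.asarray(variant_ids)[keep]) if variant_ids is not None else None
        )
        self.column_means_ = means[keep]
        self.column_sds_ = sds[keep] if self.standardize else np.ones(keep.sum())
        self.weights_ = weights[keep]
        Xc = (Xi[:, keep] - self.column_means_) / self.column_sds_
        return Xc * self.weights_

    def transform(self, X) -> np.ndarray:
        """PC scores for (possibly new) subjects using the stored
        imputation means, scalings, weights and loadings."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] == self.kept_mask_.size:
            X = X[:, self.kept_mask_]
        elif X.shape[1] != self.kept_mask_.sum():
            raise ValueError(
                f"X has {X.shape[1]} variants; expected {self.kept_mask_.size} "
                f"(pre-drop) or {int(self.kept_mask_.sum())} (post-drop)"
            )
        Xi = np.where(np.isnan(X), self.column_means_[None, :], X)
        Xc = (Xi - self.column_means_) / self.column_sds_
        return (Xc * self.weights_) @ self.loadings_

    def binarize(self, scores: np.ndarray) -> np.ndarray:
        """Scores -> spin vectors: +1 where score >= stored threshold."""
        return np.where(scores >= self.thresholds_, 1.0, -1.0)

    def fit_binarize(self, X, weights=None, variant_ids=None) -> np.ndarray:
        self.fit(X, weights=weights, variant_ids=variant_ids)
        return self.binarize(self.scores_)


# --------------------------------------------------------------------------
# pairwise maximum-entropy model
# --------------------------------------------------------------------------

class ConvergenceError(RuntimeError):
    def __init__(self, message: str, moment_gap: float):
        super().__init__(message)
        self.moment_gap = moment_gap


class PairwiseMaxEnt(BaseEstimator):
    """Pairwise maximum-entropy (Ising/Boltzmann) model over spin states.

    Fit by plain gradient ascent on the log-likelihood with exact model
    moments from full enumeration of the 2^N states (N <= 20):

        h_i  += lr * (<s_i>_emp    - <s_i>_model)
        J_ij += lr * (<s_i s_j>_emp - <s_i s_j>_model)

    stopping when every moment gap is below ``tol``. Empirical moments at
    exactly +-1 (a component constant in the data) are shrunk by
    ``moment_shrink`` so finite parameters exist.

    Attributes: ``h_`` (N,), ``J_`` (N x N symmetric, zero diagonal),
    ``energies_`` (2^N,), ``log_z_``, ``n_iter_``, ``moment_gap_``.
    """

    def __init__(self, lr: float = 0.1, tol: float = 1e-6,
                 max_iter: int = 100_000, moment_shrink: float = 1e-6):
        self.lr = lr
        self.tol = tol
        self.max_iter = max_iter
        self.moment_shrink = moment_shrink

    # -- fitting ---------------------------------------------------------
    def fit(self, X, y=None):
        """Fit from per-subject spin vectors (n_subjects x N array)."""
        X = np.asarray(X, dtype=float)
        return self.fit_from_probabilities(
            empirical_distribution(X), n_spins=X.shape[1]
        )

    def fit_from_probabilities(self, p_emp: np.ndarray, n_spins: int | None = None):
        p_emp = np.asarray(p_emp, dtype=float)
        if n_spins is None:
            n_spins = int(np.log2(len(p_emp)))
        if len(p_emp) != 2**n_spins:
            raise ValueError("p_emp length must be 2^N")
        if not np.isclose(p_emp.sum(), 1.0, atol=1e-8):
            raise ValueError("p_emp must sum to 1")
        if n_spins > 20:
            raise ValueError("exact enumeration limited to N <= 20")
        self.n_spins_ = n_spins
        S = all_states(n_spins)
        iu, ju = np.triu_indices(n_spins, k=1)
        P = S[:, iu] * S[:, ju]
        m1_emp = p_emp @ S
        m2_emp = p_emp @ P
        shrink = 1.0 - self.moment_shrink
        m1_emp = np.clip(m1_emp, -shrink, shrink)
        m2_emp = np.clip(m2_emp, -shrink, shrink)

        h = np.zeros(n_spins)
        jv = np.zeros(len(iu))
        gap = np.inf
        for it in range(self.max_iter):
            logits = S @ h + P @ jv          # = -E(V)
            logits -= logits.max()
            w = np.exp(logits)
            prob = w / w.sum()
            g1 = m1_emp - prob @ S
            g2 = m2_emp - prob @ P
            gap = max(np.abs(g1).max(), np.abs(g2).max() if g2.size else 0.0)
            if gap < self.tol:
                break
            h += self.lr * g1
            jv += self.lr * g2
        else:
            raise ConvergenceError(
                f"maximum-entropy fit did not converge in {self.max_iter} "
                f"iterations (moment gap {gap:.3g})",
                moment_gap=float(gap),
            )
        self.n_iter_ = it + 1
        self.moment_gap_ = float(gap)
        self.h_ = h
        J = np.zeros((n_spins, n_spins))
        J[iu, ju] = jv
        self.J_ = J + J.T
        self._finalize_energies(S, P, jv)
        return self

    def set_parameters(self, h: np.ndarray, J: np.ndarray):
        """Install given fields/couplings directly (for simulation)."""
        h = np.asarray(h, dtype=float)
        J = np.asarray(J, dtype=float)
        n = h.shape[0]
        if J.shape != (n, n) or not np.allclose(J, J.T) or np.any(np.diag(J) != 0):
            raise ValueError("J must be N x N symmetric with zero diagonal")
        self.n_spins_ = n
        self.h_ = h
        self.J_ = J
        iu, ju = np.triu_indices(n, k=1)
        S = all_states(n)
        P = S[:, iu] * S[:, ju]
        self._finalize_energies(S, P, J[iu, ju])
        self.n_iter_ = 0
        self.moment_gap_ = 0.0
        return self

    def _finalize_energies(self, S, P, jv):
        self.energies_ = -(S @ self.h_) - (P @ jv)
        m = -self.energies_.max()
        self.log_z_ = float(np.log(np.exp(-self.energies_ + m).sum()) - m)

    # -- queries ---------------------------------------------------------
    def energy(self, sigma: np.ndarray) -> float:
        """E(V) = -sum_i h_i s_i - sum_{i<j} J_ij s_i s_j."""
        sigma = np.asarray(sigma, dtype=float)
        if sigma.shape[-1] != self.n_spins_:
            raise ValueError(
                f"state has {sigma.shape[-1]} spins, model has {self.n_spins_}"
            )
        return float(-(self.h_ @ sigma) - 0.5 * sigma @ self.J_ @ sigma)

    def probabilities(self) -> np.ndarray:
        return np.exp(-self.energies_ - self.log_z_)

    def model_moments(self) -> tuple[np.ndarray, np.ndarray]:
        S = all_states(self.n_spins_)
        iu, ju = np.triu_indices(self.n_spins_, k=1)
        prob = self.probabilities()
        return prob @ S, prob @ (S[:, iu] * S[:, ju])

    def sample(self, n: int, random_state=None) -> np.ndarray:
        """Draw spin vectors i.i.d. from the exact state distribution."""
        rng = np.random.default_rng(random_state)
        idx = rng.choice(2**self.n_spins_, size=n, p=self.probabilities())
        return all_states(self.n_spins_)[idx]


# --------------------------------------------------------------------------
# minima, basins, disconnectivity
# --------------------------------------------------------------------------

def _neighbor_table(n_spins: int) -> np.ndarray:
    idx = np.arange(2**n_spins)
    return idx[:, None] ^ (1 << np.arange(n_spins))[None, :]


def find_local_minima(energies: np.ndarray, n_spins: int) -> np.ndarray:
    """States strictly below all single-flip neighbours; exact ties are
    resolved by granting the plateau's lowest state index the minimum."""
    E = np.asarray(energies, dtype=float)
    nb = _neighbor_table(n_spins)
    idx = np.arange(2**n_spins)
    later = (E[nb] > E[:, None]) | ((E[nb] == E[:, None]) & (nb > idx[:, None]))
    return idx[later.all(axis=1)]


def _descent_successor(E: np.ndarray, nb_row: np.ndarray, k: int) -> int | None:
    """Single steepest-descent step from state ``k`` (None at a minimum)."""
    e_nb = E[nb_row]
    best = e_nb.min()
    if best < E[k]:
        return int(nb_row[np.flatnonzero(e_nb == best)[0]])  # lowest flip index
    # plateau: move toward the lowest-indexed equal-energy earlier state
    cand = np.flatnonzero((e_nb == E[k]) & (nb_row < k))
    if cand.size:
        return int(nb_row[cand[0]])
    return None


def descend(energies: np.ndarray, n_spins: int, start: int) -> int:
    """Steepest single-flip descent to the local minimum of the basin."""
    E = np.asarray(energies, dtype=float)
    nb = _neighbor_table(n_spins)
    k = int(start)
    while True:
        nxt = _descent_successor(E, nb[k], k)
        if nxt is None:
            return k
        k = nxt


def basin_map(energies: np.ndarray, n_spins: int) -> np.ndarray:
    """Minimum index reached by steepest descent from every state."""
    E = np.asarray(energies, dtype=float)
    nb = _neighbor_table(n_spins)
    order = np.lexsort((np.arange(2**n_spins), E))
    basin = np.full(2**n_spins, -1, dtype=int)
    for k in order:
        nxt = _descent_successor(E, nb[k], k)
        basin[k] = k if nxt is None else basin[nxt]
    return basin


@dataclass
class TreeNode:
    node_id: int
    height: float
    children: tuple[int, ...] = ()
    leaf_state: int | None = None


@dataclass
class DisconnectivityTree:
    """Binary merge tree over local minima.

    Leaf heights are minima energies; internal-node heights are barrier
    energies (the minimal over paths of the maximal energy en route
    between the minima beneath)."""

    nodes: list[TreeNode]
    root: int
    leaf_of_state: dict[int, int] = field(default_factory=dict)

    @property
    def minima(self) -> list[int]:
        return sorted(self.leaf_of_state)

    def _parent_index(self) -> dict[int, int]:
        parent = {}
        for node in self.nodes:
            for c in node.children:
                parent[c] = node.node_id
        return parent

    def barrier(self, state_a: int, state_b: int) -> float:
        """Barrier energy between two minima = height of their lowest
        common ancestor."""
        if state_a == state_b:
            return self.nodes[self.leaf_of_state[state_a]].height
        parent = self._parent_index()
        path = set()
        k = self.leaf_of_state[state_a]
        while k is not None:
            path.add(k)
            k = parent.get(k)
        k = self.leaf_of_state[state_b]
        while k not in path:
            k = parent[k]
        return self.nodes[k].height

    def leaves_under(self, node_id: int) -> list[int]:
        node = self.nodes[node_id]
        if node.leaf_state is not None:
            return [node.leaf_state]
        out: list[int] = []
        for c in node.children:
            out.extend(self.leaves_under(c))
        return out

    def split_two_groups(self, energies: np.ndarray) -> dict[int, int]:
        """Cut at the root barrier; group 1 contains the global minimum."""
        root = self.nodes[self.root]
        if root.leaf_state is not None:
            raise ValueError("cannot split: landscape has a single minimum")
        sides = [self.leaves_under(c) for c in root.children]
        E = np.asarray(energies, dtype=float)
        key = [min((E[s], s) for s in side) for side in sides]
        first = 0 if key[0] <= key[1] else 1
        groups = {}
        for s in sides[first]:
            groups[s] = 1
        for s in sides[1 - first]:
            groups[s] = 2
        return groups

    def to_dict(self) -> dict:
        return {
            "root": self.root,
            "nodes": [
                {
                    "node_id": n.node_id,
                    "height": n.height,
                    "children": list(n.children),
                    "leaf_state": n.leaf_state,
                }
                for n in self.nodes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DisconnectivityTree":
        nodes = [
            TreeNode(n["node_id"], n["height"], tuple(n["children"]), n["leaf_state"])
            for n in d["nodes"]
        ]
        leaf_of_state = {
            n.leaf_state: n.node_id for n in nodes if n.leaf_state is not None
        }
        return cls(nodes=nodes, root=d["root"], leaf_of_state=leaf_of_state)


def build_disconnectivity(
    energies: np.ndarray, n_spins: int, minima: np.ndarray | None = None
) -> DisconnectivityTree:
    """Union-find sweep over states in (energy, index) order.

    States are inserted one by one into the single-flip adjacency graph;
    when an insertion first connects components containing two distinct
    minima, a merge node is recorded at the inserted state's energy."""
    E = np.asarray(energies, dtype=float)
    n_states = 2**n_spins
    if minima is None:
        minima = find_local_minima(E, n_spins)
    minima_set = set(int(m) for m in minima)
    nb = _neighbor_table(n_spins)
    parent = np.arange(n_states)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    nodes: list[TreeNode] = []
    leaf_of_state: dict[int, int] = {}
    comp_node: dict[int, int] = {}
    inserted = np.zeros(n_states, dtype=bool)
    order = np.lexsort((np.arange(n_states), E))
    for k in order:
        k = int(k)
        inserted[k] = True
        if k in minima_set:
            node = TreeNode(len(nodes), float(E[k]), leaf_state=k)
            nodes.append(node)
            leaf_of_state[k] = node.node_id
            comp_node[k] = node.node_id
        for r in {find(int(n)) for n in nb[k] if inserted[n]}:
            rk = find(k)
            if r == rk:
                continue
            na, nb_ = comp_node.pop(rk, None), comp_node.pop(r, None)
            parent[r] = rk
            new_root = find(rk)
            if na is not None and nb_ is not None:
                node = TreeNode(len(nodes), float(E[k]), children=(na, nb_))
                nodes.append(node)
                comp_node[new_root] = node.node_id
            elif na is not None or nb_ is not None:
                comp_node[new_root] = na if na is not None else nb_
    (root,) = set(comp_node.values())
    return DisconnectivityTree(nodes=nodes, root=root, leaf_of_state=leaf_of_state)


# --------------------------------------------------------------------------
# node summaries
# --------------------------------------------------------------------------

def summarize_nodes(
    basin: np.ndarray,
    minima: np.ndarray,
    subject_states: np.ndarray,
    is_case: np.ndarray,
) -> pd.DataFrame:
    """Per-minimum case/control occupancy.

    ``case_frequency`` is the fraction of all cases whose basin is that
    minimum (control analogously); ``freq_diff`` their difference; color
    red/green/gray by its sign."""
    idx = state_index(np.asarray(subject_states))
    if np.asarray(subject_states).shape[1] != int(np.log2(len(basin))):
        raise ValueError("subject state dimension does not match the landscape")
    node_of_subject = basin[idx]
    is_case = np.asarray(is_case, dtype=bool)
    n_cases = max(int(is_case.sum()), 1)
    n_controls = max(int((~is_case).sum()), 1)
    rows = []
    for m in minima:
        here = node_of_subject == m
        nc = int((here & is_case).sum())
        nn = int((here & ~is_case).sum())
        fd = nc / n_cases - nn / n_controls
        rows.append(
            {
                "minimum": int(m),
                "n_case": nc,
                "n_control": nn,
                "case_frequency": nc / n_cases,
                "control_frequency": nn / n_controls,
                "freq_diff": fd,
                "color": "red" if fd > 0 else ("green" if fd < 0 else "gray"),
            }
        )
    return pd.DataFrame(rows).set_index("minimum")


# --------------------------------------------------------------------------
# the fitted landscape
# --------------------------------------------------------------------------

class EnergyLandscape(BaseEstimator):
    """Fit the maximum-entropy landscape from per-subject spin states.

    ``fit(states, is_case)`` fits the pairwise model, finds local minima,
    basins and the disconnectivity tree, performs the two-group root cut,
    and summarizes case/control occupancy per node.

    Attributes: ``model_`` (:class:`PairwiseMaxEnt`), ``minima_``,
    ``basin_``, ``tree_``, ``groups_`` (minimum state -> 1/2; None when a
    single minimum exists), ``node_summary_``.
    """

    def __init__(self, lr: float = 0.1, tol: float = 1e-6,
                 max_iter: int = 100_000):
        self.lr = lr
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        states = np.asarray(X, dtype=float)
        self.n_spins_ = states.shape[1]
        self.model_ = PairwiseMaxEnt(
            lr=self.lr, tol=self.tol, max_iter=self.max_iter
        ).fit(states)
        E = self.model_.energies_
        self.minima_ = find_local_minima(E, self.n_spins_)
        self.basin_ = basin_map(E, self.n_spins_)
        self.tree_ = build_disconnectivity(E, self.n_spins_, self.minima_)
        if len(self.minima_) >= 2:
            self.groups_ = self.tree_.split_two_groups(E)
        else:
            self.groups_ = None
        if y is not None:
            self.node_summary_ = summarize_nodes(
                self.basin_, self.minima_, states, np.asarray(y, dtype=bool)
            )
        else:
            self.node_summary_ = None
        return self

    def assign(self, states: np.ndarray) -> pd.DataFrame:
        """Map spin states to (state index, basin minimum, group)."""
        states = np.asarray(states, dtype=float)
        if states.shape[1] != self.n_spins_:
            raise ValueError("state dimension mismatch")
        idx = state_index(states)
        node = self.basin_[idx]
        group = (
            np.array([self.groups_[int(m)] for m in node])
            if self.groups_ is not None
            else np.full(len(node), 1)
        )
        return pd.DataFrame({"state": idx, "basin": node, "group": group})

    def node_color(self, minimum: int) -> str:
        if self.node_summary_ is None:
            raise RuntimeError("landscape was fit without phenotypes")
        return str(self.node_summary_.loc[minimum, "color"])

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "n_spins": int(self.n_spins_),
            "h": self.model_.h_.tolist(),
            "J": self.model_.J_.tolist(),
            "minima": [int(m) for m in self.minima_],
            "basin": [int(b) for b in self.basin_],
            "tree": self.tree_.to_dict(),
            "groups": {str(k): v for k, v in (self.groups_ or {}).items()},
            "params": {"lr": self.lr, "tol": self.tol, "max_iter": self.max_iter},
        }
        if self.node_summary_ is not None:
            d["node_summary"] = self.node_summary_.reset_index().to_dict("records")
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EnergyLandscape":
        obj = cls(**d.get("params", {}))
        obj.n_spins_ = d["n_spins"]
        obj.model_ = PairwiseMaxEnt(
            lr=obj.lr, tol=obj.tol, max_iter=obj.max_iter
        ).set_parameters(np.asarray(d["h"]), np.asarray(d["J"]))
        obj.minima_ = np.asarray(d["minima"], dtype=int)
        obj.basin_ = np.asarray(d["basin"], dtype=int)
        obj.tree_ = DisconnectivityTree.from_dict(d["tree"])
        obj.groups_ = {int(k): v for k, v in d["groups"].items()} or None
        ns = d.get("node_summary")
        obj.node_summary_ = (
            pd.DataFrame(ns).set_index("minimum") if ns else None
        )
        return obj

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "EnergyLandscape":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# -- encoder serialization (appended to keep the class surface compact) ----

def _encoder_to_dict(enc: WeightedPCABinarizer) -> dict:
    return {
        "n_components": enc.n_components,
        "standardize": enc.standardize,
        "kept_mask": enc.kept_mask_.astype(int).tolist(),
        "variant_ids": enc.variant_ids_,
        "column_means": enc.column_means_.tolist(),
        "column_sds": enc.column_sds_.tolist(),
        "weights": enc.weights_.tolist(),
        "loadings": enc.loadings_.tolist(),
        "thresholds": enc.thresholds_.tolist(),
        "singular_values": enc.singular_values_.tolist(),
    }


def _encoder_from_dict(d: dict) -> WeightedPCABinarizer:
    enc = WeightedPCABinarizer(
        n_components=d["n_components"], standardize=d["standardize"]
    )
    enc.kept_mask_ = np.asarray(d["kept_mask"], dtype=bool)
    enc.variant_ids_ = d["variant_ids"]
    enc.column_means_ = np.asarray(d["column_means"])
    enc.column_sds_ = np.asarray(d["column_sds"])
    enc.weights_ = np.asarray(d["weights"])
    enc.loadings_ = np.asarray(d["loadings"])
    enc.thresholds_ = np.asarray(d["thresholds"])
    enc.singular_values_ = np.asarray(d["singular_values"])
    enc.explained_variance_ = enc.singular_values_**2
    return enc


WeightedPCABinarizer.to_dict = _encoder_to_dict
WeightedPCABinarizer.from_dict = staticmethod(_encoder_from_dict)
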