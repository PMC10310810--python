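"""Feed-forward PC-score predictor and node-based subtype assessment.

A fully connected network regresses each subject's PC scores on their
standardized dosages (mean-imputed). Hidden layers use the randomized
leaky rectifier (RReLU: negative slopes drawn uniformly from
[1/8, 1/3] during training, their mean at evaluation) with inverted
dropout; optimization is mini-batch Adam on the mean-squared error, with
checkpoints on a fixed epoch grid and the checkpoint with the best
discovery-cohort node accuracy retained.

Predicted PC scores are binarized with the landscape's stored thresholds
(never re-estimated on new data) and each subject is dropped onto the
fitted landscape; a case counts as correctly predicted when it lands in
a red (case-majority) basin of its true group, a control in a green one.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .datatypes import GenotypeDataset
from .landscape import EnergyLandscape


@dataclass
class NetConfig:
    """Network and training hyperparameters.

    Defaults mirror the reference architecture: six hidden layers of 512
    neurons, RReLU activation, 50% dropout, batch size 32, epoch grid
    100..1500 in steps of 100, seven outputs (one per landscape
    component). :meth:`small` gives a reduced architecture suited to
    desk-scale synthetic cohorts."""

    n_hidden_layers: int = 6
    width: int = 512
    dropout: float = 0.5
    batch_size: int = 32
    epoch_grid: tuple[int, ...] = tuple(range(100, 1501, 100))
    n_outputs: int = 7
    learning_rate: float = 1e-3
    rrelu_lower: float = 1.0 / 8.0
    rrelu_upper: float = 1.0 / 3.0
    seed: int = 0

    @classmethod
    def small(cls, **overrides) -> "NetConfig":
        cfg = cls(n_hidden_layers=2, width=64, epoch_grid=(20, 40, 60, 80, 100))
        return replace(cfg, **overrides)

    def validate(self) -> None:
        if self.n_hidden_layers < 1:
            raise ValueError("n_hidden_layers must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        grid = tuple(self.epoch_grid)
        if len(grid) == 0 or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("epoch_grid must be non-empty and strictly increasing")
        if self.batch_size < 1 or self.width < 1 or self.n_outputs < 1:
            raise ValueError("batch_size, width and n_outputs must be positive")
        if not 0.0 < self.rrelu_lower <= self.rrelu_upper < 1.0:
            raise ValueError("RReLU slopes must satisfy 0 < lower <= upper < 1")


class _MLP:
    """Minimal dense network with RReLU + inverted dropout, Adam/MSE."""

    def __init__(self, sizes: list[int], cfg: NetConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self._adam_t = 0
        self._m = [np.zeros_like(w) for w in self.W + self.b]
        self._v = [np.zeros_like(w) for w in self.W + self.b]

    @property
    def eval_slope(self) -> float:
        return 0.5 * (self.cfg.rrelu_lower + self.cfg.rrelu_upper)

    def forward(self, X: np.ndarray, train: bool):
        cache = []
        a = X
        n_hidden = len(self.W) - 1
        for layer in range(n_hidden):
            z = a @ self.W[layer] + self.b[layer]
            neg = z < 0
            if train:
                slope = self.rng.uniform(
                    self.cfg.rrelu_lower, self.cfg.rrelu_upper, size=z.shape
                )
            else:
                slope = self.eval_slope
            act = np.where(neg, z * slope, z)
            if train and self.cfg.dropout > 0:
                keep = (self.rng.random(z.shape) >= self.cfg.dropout) / (
                    1.0 - self.cfg.dropout
                )
                act = act * keep
            else:
                keep = None
            cache.append((a, neg, slope, keep))
            a = act
        out = a @ self.W[-1] + self.b[-1]
        return out, (cache, a)

    def train_batch(self, X: np.ndarray, Y: np.ndarray) -> float:
        out, (cache, last_a) = self.forward(X, train=True)
        n = X.shape[0]
        diff = out - Y
        loss = float((diff**2).mean())
        grad_out = 2.0 * diff / diff.size
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        gW[-1] = last_a.T @ grad_out
        gb[-1] = grad_out.sum(axis=0)
        g = grad_out @ self.W[-1].T
        for layer in range(len(self.W) - 2, -1, -1):
            a_in, neg, slope, keep = cache[layer]
            if keep is not None:
                g = g * keep
            g = np.where(neg, g * slope, g)
            gW[layer] = a_in.T @ g
            gb[layer] = g.sum(axis=0)
            if layer > 0:
                g = g @ self.W[layer].T
        self._adam_step(gW + gb)
        return loss

    def _adam_step(self, grads, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        params = self.W + self.b
        lr = self.cfg.learning_rate
        t = self._adam_t
        for k, (p, g) in enumerate(zip(params, grads)):
            self._m[k] = beta1 * self._m[k] + (1 - beta1) * g
            self._v[k] = beta2 * self._v[k] + (1 - beta2) * g * g
            mhat = self._m[k] / (1 - beta1**t)
            vhat = self._v[k] / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    def snapshot(self):
        return ([w.copy() for w in self.W], [b.copy() for b in self.b])

    def restore(self, snap):
        self.W = [w.copy() for w in snap[0]]
        self.b = [b.copy() for b in snap[1]]


@dataclass
class PredictionAssessment:
    """Node-based accuracy: correct = matching-color, matching-group basin."""

    n_correct: int
    n_total: int
    accuracy: float
    per_group: dict[int, tuple[int, int]] = field(default_factory=dict)


class PCScorePredictor(RegressorMixin, BaseEstimator):
    """Estimate PC scores from dosages with a feed-forward network.

    ``fit(X, Y, ...)`` standardizes inputs (mean-imputing missing calls)
    and targets, trains with mini-batch Adam, and at every epoch-grid
    point evaluates a checkpoint — by landscape node accuracy when a
    fitted landscape + phenotype are supplied, else by training MSE —
    keeping the best. Deterministic given the config seed.
    """

    def __init__(self, config: NetConfig | None = None):
        self.config = config

    def fit(
        self,
        X,
        Y,
        variant_ids=None,
        landscape: EnergyLandscape | None = None,
        thresholds: np.ndarray | None = None,
        is_case: np.ndarray | None = None,
        true_groups: np.ndarray | None = None,
    ):
        cfg = self.config or NetConfig()
        cfg.validate()
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if X.shape[0] != Y.shape[0]:
            raise ValueError(
                f"targets misaligned: X has {X.shape[0]} subjects, Y has {Y.shape[0]}"
            )
        cfg = replace(cfg, n_outputs=Y.shape[1])
        self.variant_ids_ = list(variant_ids) if variant_ids is not None else None
        self.input_means_ = np.nanmean(X, axis=0)
        self.input_means_ = np.where(
            np.isnan(self.input_means_), 0.0, self.input_means_
        )
        Xi = np.where(np.isnan(X), self.input_means_[None, :], X)
        sds = Xi.std(axis=0)
        self.input_sds_ = np.where(sds > 0, sds, 1.0)
        Xs = (Xi - self.input_means_) / self.input_sds_
        self.y_mean_ = Y.mean(axis=0)
        ysd = Y.std(axis=0)
        self.y_sd_ = np.where(ysd > 0, ysd, 1.0)
        Ys = (Y - self.y_mean_) / self.y_sd_

        self.thresholds_ = None if thresholds is None else np.asarray(thresholds)
        rng = np.random.default_rng(cfg.seed)
        sizes = [Xs.shape[1]] + [cfg.width] * cfg.n_hidden_layers + [cfg.n_outputs]
        net = _MLP(sizes, cfg, rng)
        n = Xs.shape[0]
        grid = set(cfg.epoch_grid)
        best = (-np.inf, None, None)
        history = []
        epoch_loss = np.nan
        for epoch in range(1, max(cfg.epoch_grid) + 1):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                batch = order[start:start + cfg.batch_size]
                losses.append(net.train_batch(Xs[batch], Ys[batch]))
            epoch_loss = float(np.mean(losses))
            if not np.isfinite(epoch_loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            if epoch in grid:
                metric = self._checkpoint_metric(
                    net, Xs, Y, landscape, is_case, true_groups
                )
                history.append(
                    {"epoch": epoch, "loss": epoch_loss, "metric": metric}
                )
                if metric > best[0]:
                    best = (metric, epoch, net.snapshot())
        self.history_ = pd.DataFrame(history)
        self.best_epoch_ = best[1]
        net.restore(best[2])
        self._net = net
        self._cfg = cfg
        return self

    def _checkpoint_metric(self, net, Xs, Y_raw, landscape, is_case, true_groups):
        out_s, _ = net.forward(Xs, train=False)
        out = out_s * self.y_sd_ + self.y_mean_
        if landscape is None or is_case is None or self.thresholds_ is None:
            return -float(((out - Y_raw) ** 2).mean())
        states = np.where(out >= self.thresholds_, 1.0, -1.0)
        return assess(landscape, states, is_case, true_groups).accuracy

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Xi = np.where(np.isnan(X), self.input_means_[None, :], X)
        Xs = (Xi - self.input_means_) / self.input_sds_
        out_s, _ = self._net.forward(Xs, train=False)
        return out_s * self.y_sd_ + self.y_mean_


def predict_states(
    model: PCScorePredictor, geno: GenotypeDataset,
    thresholds: np.ndarray | None = None,
) -> np.ndarray:
    """Map a cohort through the network and binarize with the stored
    landscape thresholds. Input variant order is enforced internally; any
    required variant absent from the cohort raises with its name."""
    if model.variant_ids_ is None:
        raise RuntimeError("predictor was fit without variant identifiers")
    missing = [v for v in model.variant_ids_ if v not in geno.variant_meta.index]
    if missing:
        raise KeyError(f"cohort lacks required variants: {missing[:10]}"
                       + ("..." if len(missing) > 10 else ""))
    X = geno.dosages[:, geno.variant_indexer(model.variant_ids_)]
    scores = model.predict(X)
    thr = thresholds if thresholds is not None else model.thresholds_
    if thr is None:
        raise RuntimeError("no binarization thresholds supplied or stored")
    return np.where(scores >= np.asarray(thr), 1.0, -1.0)


def assess(
    landscape: EnergyLandscape,
    states: np.ndarray,
    is_case: np.ndarray,
    true_groups: np.ndarray | None = None,
) -> PredictionAssessment:
    """Node-based accuracy of predicted states on a fitted landscape.

    Each predicted state descends to its basin; a case is correct iff
    the basin is red (and, when true groups are given, of the subject's
    true group), a control iff green with the same condition; gray basins
    never score."""
    states = np.asarray(states, dtype=float)
    is_case = np.asarray(is_case, dtype=bool)
    if states.shape[0] != is_case.shape[0]:
        raise ValueError("states and phenotype lengths differ")
    assign = landscape.assign(states)
    if landscape.node_summary_ is None:
        raise RuntimeError("landscape was fit without phenotypes (no node colors)")
    colors = landscape.node_summary_["color"]
    basin_color = assign["basin"].map(colors).to_numpy()
    group = assign["group"].to_numpy()
    color_ok = np.where(is_case, basin_color == "red", basin_color == "green")
    if true_groups is not None:
        ok = color_ok & (group == np.asarray(true_groups))
    else:
        ok = color_ok
    per_group = {}
    for g in sorted(np.unique(group)):
        mask = group == g
        per_group[int(g)] = (int(ok[mask].sum()), int(mask.sum()))
    n_total = int(len(ok))
    n_correct = int(ok.sum())
    return PredictionAssessment(
        n_correct=n_correct,
        n_total=n_total,
        accuracy=n_correct / n_total if n_total else 0.0,
        per_group=per_group,
    )
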