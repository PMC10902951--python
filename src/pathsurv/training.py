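"""Cluster initialization/updates, the multitask training loop, and CV.

Training is full-batch gradient descent with the Adam update and an L2 weight
penalty on all weights and biases.  Each epoch: forward with dropout ->
recompute the sharpened target distribution s from the current soft
assignments (s is treated as a constant within the epoch) -> total loss ->
backward/step -> one warm-started Lloyd update of the cluster centers on the
deterministic embeddings.  The cluster count k is chosen once, before
training, by silhouette score over k_range, and is not re-selected.

Ablation flags mirror the multitask decomposition: "-DR" drops the
reconstruction task (gamma=0), "-SS" drops the clustering task (beta=0),
"-DRSS" leaves the Cox prediction task alone.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.model_selection import StratifiedKFold

from . import objectives as obj
from .data_io import CohortDataset, DataError, PathwayMask
from .evaluation import concordance_index
from .network import (
    ModelState,
    NetworkConfig,
    backward,
    forward,
    init_model,
    make_dropout_masks,
    predict_risk,
)

logger = logging.getLogger("pathsurv")

ABLATIONS = ("none", "-DR", "-SS", "-DRSS")


class TrainingError(RuntimeError):
    pass


@dataclasses.dataclass
class TrainReport:
    loss_trace: pd.DataFrame  # columns: total, reconstruction, clustering, cox
    k: int | None
    silhouette_by_k: dict[int, float]
    seed: int
    ablation: str


@dataclasses.dataclass
class CVResult:
    records: pd.DataFrame  # columns: n_embedding, learning_rate, fold, c_index
    selected: dict
    fold_assignments: np.ndarray


# ---------------------------------------------------------------------------
# clustering state
# ---------------------------------------------------------------------------

def init_clusters(
    Z: np.ndarray, k_range: tuple[int, int], seed: int = 0
) -> tuple[int, np.ndarray, np.ndarray, dict[int, float]]:
    """k-means for each k in k_range; keep the k with the best silhouette."""
    Z = np.asarray(Z, dtype=np.float64)
    if np.allclose(Z, Z[0]):
        raise TrainingError("degenerate embeddings: all points identical")
    lo, hi = k_range
    if Z.shape[0] < hi + 1:
        raise TrainingError(f"need at least {hi + 1} samples for k_range {k_range}")
    scores: dict[int, float] = {}
    fits = {}
    for k in range(lo, hi + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(Z)
        if len(np.unique(km.labels_)) < 2:
            continue
        scores[k] = float(silhouette_score(Z, km.labels_))
        fits[k] = km
    if not scores:
        raise TrainingError("k-means produced a single cluster for every k")
    best = max(scores, key=lambda k: (scores[k], -k))
    km = fits[best]
    return best, km.labels_.copy(), km.cluster_centers_.copy(), scores


def update_clusters(
    state: ModelState, Z: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One warm-started Lloyd step: assign to current centers, repair any
    empty cluster by re-seeding it at the point farthest from its center,
    then recompute the means.  k never changes."""
    if state.centers is None:
        raise TrainingError("clusters not initialized")
    Z = np.asarray(Z, dtype=np.float64)
    centers = state.centers.copy()
    d2 = ((Z[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    for j in range(centers.shape[0]):
        if not np.any(labels == j):
            far = int(d2[np.arange(len(Z)), labels].argmax())
            labels[far] = j
    new_centers = np.vstack([Z[labels == j].mean(axis=0) for j in range(centers.shape[0])])
    return labels, new_centers


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class SGD:
    """Plain full-batch gradient descent (the default).

    On small cohorts with p >> n the slow, spectrum-ordered progress of plain
    gradient descent acts like ridge shrinkage (early-stopping
    regularization); adaptive per-coordinate scaling destroys that bias and
    measurably hurts held-out concordance here, so Adam is opt-in.
    """

    def __init__(self, lr: float):
        self.lr = lr

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        for k, g in grads.items():
            params[k] -= self.lr * g


class Adam:
    """Adaptive moment estimation; the L2 penalty enters through the gradient."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _effective_weights(config: NetworkConfig, ablation: str) -> tuple[float, float]:
    if ablation not in ABLATIONS:
        raise DataError(f"unknown ablation {ablation!r}; expected one of {ABLATIONS}")
    gamma = 0.0 if ablation in ("-DR", "-DRSS") else config.gamma
    beta = 0.0 if ablation in ("-SS", "-DRSS") else config.beta
    return gamma, beta


def train(
    cohort: CohortDataset,
    mask: PathwayMask,
    config: NetworkConfig,
    ablation: str = "none",
) -> tuple[ModelState, TrainReport]:
    """Fit the multitask network on one cohort.

    The cohort's expression columns must match the mask's gene list (use
    ``ExpressionMatrix.subset_genes(mask.gene_ids)`` after building the mask).
    """
    if cohort.expression.gene_ids != mask.gene_ids:
        raise DataError("cohort gene order does not match mask gene order")
    if cohort.survival.n_events == 0:
        raise DataError("cohort has no events; cannot train the risk head")
    gamma, beta = _effective_weights(config, ablation)

    X = cohort.expression.values
    n = X.shape[0]
    state = init_model(config, mask)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    optimizer = (
        Adam(state.params, lr=config.learning_rate)
        if config.optimizer == "adam"
        else SGD(lr=config.learning_rate)
    )

    sil: dict[int, float] = {}
    if beta > 0:
        z0 = forward(state, X).embedding
        state.k, state.labels, state.centers, sil = init_clusters(
            z0, config.k_range, seed=config.seed
        )
        logger.info("selected k=%d by silhouette %s", state.k, sil)

    trace = {"total": [], "reconstruction": [], "clustering": [], "cox": []}
    for epoch in range(config.max_epochs):
        masks = (
            make_dropout_masks(rng, config, n=n) if config.dropout_rate > 0 else None
        )
        out, cache = forward(state, X, dropout_masks=masks, return_cache=True)

        l_rec = obj.reconstruction_loss(X, out.reconstruction) if gamma > 0 else 0.0
        d_rec = gamma * obj.reconstruction_loss_grad(X, out.reconstruction) if gamma > 0 else None

        if beta > 0:
            t_soft = obj.soft_assignment(out.embedding, state.centers)
            s_target = obj.target_distribution(t_soft)  # constant within the epoch
            l_clu = obj.clustering_loss(s_target, t_soft)
            d_emb = beta * obj.clustering_loss_grad_embedding(
                out.embedding, state.centers, s_target
            )
        else:
            l_clu, d_emb = 0.0, None

        l_cox = obj.cox_loss(out.risk, cohort.survival)
        d_risk = obj.cox_loss_grad(out.risk, cohort.survival)

        total = obj.total_loss(l_rec, l_clu, l_cox, gamma=gamma, beta=beta)
        if not np.isfinite(total):
            raise TrainingError(
                f"non-finite loss at epoch {epoch}: "
                f"rec={l_rec:.4g} clu={l_clu:.4g} cox={l_cox:.4g}"
            )
        trace["total"].append(total)
        trace["reconstruction"].append(l_rec)
        trace["clustering"].append(l_clu)
        trace["cox"].append(l_cox)

        grads, _ = backward(
            state, cache, d_embedding=d_emb, d_reconstruction=d_rec, d_risk=d_risk
        )
        if config.weight_decay > 0:
            for k in grads:
                grads[k] = grads[k] + 2.0 * config.weight_decay * state.params[k]
        optimizer.step(state.params, grads)

        if beta > 0:
            z_eval = forward(state, X).embedding
            state.labels, state.centers = update_clusters(state, z_eval)

    report = TrainReport(
        loss_trace=pd.DataFrame(trace),
        k=state.k,
        silhouette_by_k=sil,
        seed=config.seed,
        ablation=ablation,
    )
    return state, report


# ---------------------------------------------------------------------------
# cross-validated hyperparameter selection
# ---------------------------------------------------------------------------

def cross_validate(
    cohort: CohortDataset,
    mask: PathwayMask,
    config: NetworkConfig,
    embedding_grid: tuple[int, ...] = (10, 20, 50),
    lr_grid: tuple[float, ...] = (1e-6, 1e-7, 1e-8),
    n_folds: int = 5,
    ablation: str = "none",
) -> CVResult:
    """Grid search (n_embedding x learning_rate) by event-stratified k-fold CV,
    scoring the validation C-index; selects the grid point with highest mean."""
    n = cohort.n_samples
    if n < n_folds:
        raise DataError(f"need at least {n_folds} samples for {n_folds}-fold CV")
    event = cohort.survival.event
    if event.sum() < n_folds:
        raise DataError("too few events to give every fold at least one event")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=config.seed)
    folds = list(skf.split(np.zeros(n), event))
    fold_of = np.empty(n, dtype=int)
    for f, (_, val) in enumerate(folds):
        fold_of[val] = f

    rows = []
    for d in embedding_grid:
        for lr in lr_grid:
            cfg = dataclasses.replace(config, n_embedding=d, learning_rate=lr)
            for f, (tr, val) in enumerate(folds):
                train_cohort = cohort.subset(tr)
                val_cohort = cohort.subset(val)
                state, _ = train(train_cohort, mask, cfg, ablation=ablation)
                risk = predict_risk(state, val_cohort.expression.values)
                ci = concordance_index(risk, val_cohort.survival)
                rows.append(
                    {"n_embedding": d, "learning_rate": lr, "fold": f, "c_index": ci}
                )
    records = pd.DataFrame(rows)
    means = records.groupby(["n_embedding", "learning_rate"])["c_index"].mean()
    best_d, best_lr = means.idxmax()
    selected = {
        "n_embedding": int(best_d),
        "learning_rate": float(best_lr),
        "mean_c_index": float(means.max()),
    }
    return CVResult(records=records, selected=selected, fold_assignments=fold_of)
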