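"""The pathway-masked multitask survival network.

Architecture: input genes -> sparse pathway layer (first-layer weights gated
elementwise by the binary pathway x gene biadjacency matrix, ReLU) -> two
dense hidden layers (ReLU) -> linear embedding Z.  Three heads share the
encoder: a mirrored decoder reconstructing the input (linear output), a
clustering head operating on Z via Student-t soft assignments, and a risk
head (single linear unit on Z) producing the Cox log-hazard score.

Everything runs in numpy with explicit forward caches and a hand-written
backward pass; gradients are verified against finite differences in the test
suite.  Masked sparse-layer weights receive identically zero gradient, so the
mask is a structural constraint, not a soft penalty.

Dropout is inverted (activations scaled by 1/(1-rate) when on), applied after
each dense hidden layer — never after the sparse layer — both during training
and during Monte-Carlo attribution passes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np

from .data_io import DataError, PathwayMask


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class NetworkConfig:
    """Hyperparameters; defaults follow the reference setting.

    gamma weights the reconstruction loss and beta the clustering loss in the
    total objective; learning-rate and embedding-size grids used for
    cross-validated selection are {1e-6, 1e-7, 1e-8} and {10, 20, 50}.
    """

    n_hidden1: int = 1000
    n_hidden2: int = 500
    n_embedding: int = 20
    learning_rate: float = 1e-6
    max_epochs: int = 2000
    gamma: float = 1.0
    beta: float = 10.0
    dropout_rate: float = 0.1
    weight_decay: float = 1e-4
    optimizer: str = "sgd"  # plain full-batch gradient descent, or "adam"
    k_range: tuple[int, int] = (2, 4)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_hidden1", "n_hidden2", "n_embedding", "max_epochs"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.gamma < 0 or self.beta < 0 or self.weight_decay < 0:
            raise ConfigError("gamma, beta, weight_decay must be nonnegative")
        if self.optimizer not in ("sgd", "adam"):
            raise ConfigError(f"unknown optimizer {self.optimizer!r}")
        self.k_range = tuple(self.k_range)
        if len(self.k_range) != 2 or self.k_range[0] < 2 or self.k_range[0] > self.k_range[1]:
            raise ConfigError("k_range must be (lo, hi) with 2 <= lo <= hi")


@dataclasses.dataclass
class ModelState:
    """All trainable weights plus the clustering state."""

    config: NetworkConfig
    mask: PathwayMask
    params: dict[str, np.ndarray]
    centers: np.ndarray | None = None  # (k, n_embedding)
    labels: np.ndarray | None = None  # (n_train,)
    k: int | None = None

    @property
    def mask_t(self) -> np.ndarray:
        return self.mask.matrix.T  # (p, q)


@dataclasses.dataclass
class ForwardOutputs:
    embedding: np.ndarray  # (n, d)
    reconstruction: np.ndarray  # (n, p)
    risk: np.ndarray  # (n,)


def init_model(config: NetworkConfig, mask: PathwayMask) -> ModelState:
    """Seeded initialization; layer sizes p -> q -> h1 -> h2 -> d.

    The sparse layer starts as a *soft pathway average*: each pathway unit's
    weights are 1/|pathway| with +-30% jitter, so at initialization the unit
    scores pathway activity (the standard starting point for pathway-informed
    models) and training refines which member genes matter.  Dense layers use
    uniform fan-in-scaled initialization.  The decoder mirrors the encoder
    (d -> h2 -> h1 -> p, linear output); the risk head is one linear unit on
    the embedding.
    """
    if config.n_embedding >= config.n_hidden2:
        raise ConfigError(
            f"n_embedding ({config.n_embedding}) must be smaller than "
            f"n_hidden2 ({config.n_hidden2}) for a compressing embedding"
        )
    q, p = mask.matrix.shape
    h1, h2, d = config.n_hidden1, config.n_hidden2, config.n_embedding
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))

    def u(fan_in: int | np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
        bound = 1.0 / np.sqrt(np.maximum(fan_in, 1))
        return rng.uniform(-1.0, 1.0, size=shape) * bound

    pathway_size = np.maximum(mask.matrix.sum(axis=1), 1.0)  # (q,)
    params = {
        # sparse layer: soft pathway-average with jitter
        "Ws": ((1.0 + 0.3 * rng.uniform(-1.0, 1.0, size=(p, q))) / pathway_size)
        * mask.matrix.T,
        "bs": np.zeros(q),
        "W1": u(q, (q, h1)), "b1": np.zeros(h1),
        "W2": u(h1, (h1, h2)), "b2": np.zeros(h2),
        "W3": u(h2, (h2, d)), "b3": np.zeros(d),
        "V1": u(d, (d, h2)), "c1": np.zeros(h2),
        "V2": u(h2, (h2, h1)), "c2": np.zeros(h1),
        "V3": u(h1, (h1, p)), "c3": np.zeros(p),
        "wr": u(d, (d,)), "br": np.zeros(1),
    }
    return ModelState(config=config, mask=mask, params=params)


def make_dropout_masks(
    rng: np.random.Generator,
    config: NetworkConfig,
    n: int | None = None,
    rate: float | None = None,
) -> dict[str, np.ndarray]:
    """Inverted-dropout masks for the four dense hidden layers.

    With ``n`` given, masks are per-sample (training); with ``n=None`` one
    unit-level mask is shared across all rows — a single thinned network, as
    used by each Monte-Carlo attribution run.
    """
    rate = config.dropout_rate if rate is None else rate
    keep = 1.0 - rate
    sizes = {"h1": config.n_hidden1, "h2": config.n_hidden2,
             "g1": config.n_hidden2, "g2": config.n_hidden1}
    masks = {}
    for key, size in sizes.items():
        shape = (size,) if n is None else (n, size)
        masks[key] = (rng.uniform(size=shape) < keep).astype(np.float64) / keep
    return masks


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def forward(
    state: ModelState,
    X: np.ndarray,
    dropout_masks: Mapping[str, np.ndarray] | None = None,
    return_cache: bool = False,
):
    """Run the network; ``dropout_masks=None`` is the deterministic pass."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != state.mask.n_genes:
        raise DataError(
            f"input has {X.shape[-1] if X.ndim == 2 else '?'} columns, "
            f"mask expects {state.mask.n_genes}"
        )
    P = state.params
    m = dropout_masks or {}
    one = 1.0

    pre_s = X @ (P["Ws"] * state.mask_t) + P["bs"]
    A = _relu(pre_s)
    pre1 = A @ P["W1"] + P["b1"]
    H1 = _relu(pre1)
    H1d = H1 * m.get("h1", one)
    pre2 = H1d @ P["W2"] + P["b2"]
    H2 = _relu(pre2)
    H2d = H2 * m.get("h2", one)
    Z = H2d @ P["W3"] + P["b3"]
    risk = Z @ P["wr"] + P["br"][0]

    pre_g1 = Z @ P["V1"] + P["c1"]
    G1 = _relu(pre_g1)
    G1d = G1 * m.get("g1", one)
    pre_g2 = G1d @ P["V2"] + P["c2"]
    G2 = _relu(pre_g2)
    G2d = G2 * m.get("g2", one)
    Xrec = G2d @ P["V3"] + P["c3"]

    out = ForwardOutputs(embedding=Z, reconstruction=Xrec, risk=risk)
    if not return_cache:
        return out
    cache = {
        "X": X, "pre_s": pre_s, "A": A, "pre1": pre1, "H1d": H1d,
        "pre2": pre2, "H2d": H2d, "Z": Z,
        "pre_g1": pre_g1, "G1d": G1d, "pre_g2": pre_g2, "G2d": G2d,
        "masks": m,
    }
    return out, cache


def backward(
    state: ModelState,
    cache: dict,
    d_embedding: np.ndarray | None = None,
    d_reconstruction: np.ndarray | None = None,
    d_risk: np.ndarray | None = None,
    want_input_grad: bool = False,
) -> tuple[dict[str, np.ndarray], np.ndarray | None]:
    """Backpropagate upstream gradients on the three outputs to all weights.

    Returns (grads, dX); dX is None unless ``want_input_grad``.  Gradients of
    masked sparse-layer weights are identically zero by construction.
    """
    P = state.params
    m = cache["masks"]
    one = 1.0
    n = cache["X"].shape[0]
    grads = {k: np.zeros_like(v) for k, v in P.items()}

    dZ = np.zeros_like(cache["Z"])
    if d_embedding is not None:
        dZ += d_embedding
    if d_risk is not None:
        d_risk = np.asarray(d_risk, dtype=np.float64)
        grads["wr"] += cache["Z"].T @ d_risk
        grads["br"] += d_risk.sum(keepdims=True)
        dZ += np.outer(d_risk, P["wr"])
    if d_reconstruction is not None:
        dXrec = np.asarray(d_reconstruction, dtype=np.float64)
        grads["V3"] += cache["G2d"].T @ dXrec
        grads["c3"] += dXrec.sum(axis=0)
        dG2 = (dXrec @ P["V3"].T) * m.get("g2", one)
        dpg2 = dG2 * (cache["pre_g2"] > 0)
        grads["V2"] += cache["G1d"].T @ dpg2
        grads["c2"] += dpg2.sum(axis=0)
        dG1 = (dpg2 @ P["V2"].T) * m.get("g1", one)
        dpg1 = dG1 * (cache["pre_g1"] > 0)
        grads["V1"] += cache["Z"].T @ dpg1
        grads["c1"] += dpg1.sum(axis=0)
        dZ += dpg1 @ P["V1"].T

    grads["W3"] += cache["H2d"].T @ dZ
    grads["b3"] += dZ.sum(axis=0)
    dH2 = (dZ @ P["W3"].T) * m.get("h2", one)
    dp2 = dH2 * (cache["pre2"] > 0)
    grads["W2"] += cache["H1d"].T @ dp2
    grads["b2"] += dp2.sum(axis=0)
    dH1 = (dp2 @ P["W2"].T) * m.get("h1", one)
    dp1 = dH1 * (cache["pre1"] > 0)
    grads["W1"] += cache["A"].T @ dp1
    grads["b1"] += dp1.sum(axis=0)
    dA = dp1 @ P["W1"].T
    dps = dA * (cache["pre_s"] > 0)
    grads["Ws"] += (cache["X"].T @ dps) * state.mask_t
    grads["bs"] += dps.sum(axis=0)

    dX = None
    if want_input_grad:
        dX = dps @ (P["Ws"] * state.mask_t).T
    return grads, dX


def predict_risk(state: ModelState, X: np.ndarray) -> np.ndarray:
    """Deterministic (dropout-off) risk scores."""
    return forward(state, X).risk


def risk_path_preactivations(
    state: ModelState,
    X: np.ndarray,
    dropout_masks: Mapping[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Concatenated ReLU preactivations (sparse, hidden1, hidden2) of the
    risk path, one row per input row.  Used to locate the switching points of
    the piecewise-linear risk function along an attribution path."""
    P = state.params
    m = dropout_masks or {}
    one = 1.0
    pre_s = X @ (P["Ws"] * state.mask_t) + P["bs"]
    pre1 = _relu(pre_s) @ P["W1"] + P["b1"]
    pre2 = (_relu(pre1) * m.get("h1", one)) @ P["W2"] + P["b2"]
    return np.concatenate([pre_s, pre1, pre2], axis=1)


def risk_input_gradient(
    state: ModelState,
    X: np.ndarray,
    dropout_masks: Mapping[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Per-sample gradient of the risk output with respect to the input genes."""
    _, cache = forward(state, X, dropout_masks=dropout_masks, return_cache=True)
    _, dX = backward(state, cache, d_risk=np.ones(X.shape[0]), want_input_grad=True)
    return dX


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

_CKPT_VERSION = 1


def save_checkpoint(state: ModelState, path: str | Path) -> None:
    """Serialize config, mask, weights and cluster state to one .npz file."""
    meta = {
        "version": _CKPT_VERSION,
        "config": dataclasses.asdict(state.config),
        "k": state.k,
    }
    arrays = {f"param_{k}": v for k, v in state.params.items()}
    arrays["mask_matrix"] = state.mask.matrix
    arrays["mask_pathways"] = np.array(state.mask.pathway_names)
    arrays["mask_genes"] = np.array(state.mask.gene_ids)
    arrays["meta_json"] = np.array(json.dumps(meta))
    if state.centers is not None:
        arrays["centers"] = state.centers
    if state.labels is not None:
        arrays["labels"] = state.labels
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> ModelState:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["meta_json"]))
        if meta["version"] != _CKPT_VERSION:
            raise DataError(f"unsupported checkpoint version {meta['version']}")
        cfg_dict = meta["config"]
        cfg_dict["k_range"] = tuple(cfg_dict["k_range"])
        config = NetworkConfig(**cfg_dict)
        mask = PathwayMask(
            npz["mask_matrix"],
            [str(s) for s in npz["mask_pathways"]],
            [str(s) for s in npz["mask_genes"]],
        )
        params = {k[6:]: npz[k] for k in npz.files if k.startswith("param_")}
        centers = npz["centers"] if "centers" in npz.files else None
        labels = npz["labels"] if "labels" in npz.files else None
    return ModelState(config=config, mask=mask, params=params,
                      centers=centers, labels=labels, k=meta["k"])
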