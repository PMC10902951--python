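"""The three task losses and their weighted combination.

* reconstruction: per-sample sum of squared errors over genes, averaged over
  the batch so the gamma weight is batch-size independent.
* deep-embedded clustering: Student-t soft assignments t (one degree of
  freedom), a sharpened target distribution s, and KL(S || T) with the target
  in the first argument, exactly as the objective is written.
* survival: negative Cox partial log-likelihood with Breslow-style handling
  of tied event times (tied subjects appear in each other's risk sets).

Each loss comes with its analytic gradient with respect to its direct input;
the training loop chains these through the network's backward pass.
"""

from __future__ import annotations

import numpy as np

from .data_io import DataError, SurvivalOutcome

_EPS = 1e-10  # guard inside the KL logs


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------

def reconstruction_loss(X: np.ndarray, X_rec: np.ndarray) -> float:
    """Mean over samples of the per-sample squared-error sum over genes."""
    X = np.asarray(X, dtype=np.float64)
    X_rec = np.asarray(X_rec, dtype=np.float64)
    if X.shape != X_rec.shape:
        raise DataError(f"shape mismatch {X.shape} vs {X_rec.shape}")
    return float(np.sum((X - X_rec) ** 2) / X.shape[0])


def reconstruction_loss_grad(X: np.ndarray, X_rec: np.ndarray) -> np.ndarray:
    """d loss / d X_rec."""
    return 2.0 * (np.asarray(X_rec) - np.asarray(X)) / X.shape[0]


# ---------------------------------------------------------------------------
# deep-embedded clustering
# ---------------------------------------------------------------------------

def soft_assignment(Z: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Student-t similarities (df=1): t_ij ∝ (1+||z_i-mu_j||^2)^-1, rows sum to 1."""
    Z = np.atleast_2d(np.asarray(Z, dtype=np.float64))
    centers = np.atleast_2d(np.asarray(centers, dtype=np.float64))
    if centers.shape[0] < 2:
        raise DataError("need at least 2 cluster centers")
    if not np.all(np.isfinite(centers)):
        raise DataError("non-finite cluster centers")
    d2 = ((Z[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    u = 1.0 / (1.0 + d2)
    return u / u.sum(axis=1, keepdims=True)


def target_distribution(t: np.ndarray) -> np.ndarray:
    """Sharpened target: s_ij ∝ t_ij^2 / sum_i t_ij, renormalized over j."""
    t = np.atleast_2d(np.asarray(t, dtype=np.float64))
    f = t.sum(axis=0)  # soft cluster frequencies
    s = t**2 / f
    return s / s.sum(axis=1, keepdims=True)


def clustering_loss(s: np.ndarray, t: np.ndarray) -> float:
    """KL(S || T) = sum_ij s_ij log(s_ij / t_ij), with 0 log 0 = 0."""
    s = np.atleast_2d(np.asarray(s, dtype=np.float64))
    t = np.atleast_2d(np.asarray(t, dtype=np.float64))
    if s.shape != t.shape:
        raise DataError(f"shape mismatch {s.shape} vs {t.shape}")
    terms = np.where(s > 0, s * (np.log(s + _EPS) - np.log(t + _EPS)), 0.0)
    return float(terms.sum())


def clustering_loss_grad_embedding(
    Z: np.ndarray, centers: np.ndarray, s: np.ndarray
) -> np.ndarray:
    """d KL(S||T) / d Z with the target s held constant.

    Chains through t = u / rowsum(u), u_ij = (1+||z_i-mu_j||^2)^-1:
    dL/dt = -s/t, dL/du_ij = (dL/dt_ij - sum_k dL/dt_ik t_ik) / rowsum(u)_i,
    du_ij/dz_i = -2 u_ij^2 (z_i - mu_j).
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=np.float64))
    centers = np.atleast_2d(np.asarray(centers, dtype=np.float64))
    diff = Z[:, None, :] - centers[None, :, :]  # (n, k, d)
    u = 1.0 / (1.0 + (diff**2).sum(axis=2))  # (n, k)
    r = u.sum(axis=1, keepdims=True)
    t = u / r
    dt = -s / np.maximum(t, _EPS)
    du = (dt - (dt * t).sum(axis=1, keepdims=True)) / r
    dz = (du * (-2.0 * u**2))[:, :, None] * diff
    return dz.sum(axis=1)


# ---------------------------------------------------------------------------
# Cox partial likelihood
# ---------------------------------------------------------------------------

def _risk_set_logsumexp(risk: np.ndarray, time: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """For each sample i: log sum_{j: T_j >= T_i} exp(h_j), via sorted suffix sums."""
    order = np.argsort(-time, kind="stable")  # descending time
    h = risk[order]
    shift = risk.max()
    cum = np.cumsum(np.exp(h - shift))
    # ties: all subjects with the same time share the full tied block
    t_sorted = time[order]
    # index of last occurrence of each time value in the descending sort
    last = np.zeros(len(h), dtype=int)
    i = 0
    while i < len(h):
        j = i
        while j + 1 < len(h) and t_sorted[j + 1] == t_sorted[i]:
            j += 1
        last[i:j + 1] = j
        i = j + 1
    lse_sorted = np.log(cum[last]) + shift
    lse = np.empty_like(lse_sorted)
    lse[order] = lse_sorted
    return lse, order


def cox_loss(risk: np.ndarray, survival: SurvivalOutcome) -> float:
    """Negative Cox partial log-likelihood, summed over events.

    L = -sum_{i: event} ( h_i - log sum_{j: T_j >= T_i} exp(h_j) ), with
    Breslow-style tie handling and a max-shift before exponentiation.
    """
    risk = np.asarray(risk, dtype=np.float64)
    if survival.n_events == 0:
        raise DataError("no events: Cox partial likelihood undefined")
    lse, _ = _risk_set_logsumexp(risk, survival.time)
    ev = survival.event == 1
    return float(-(risk[ev] - lse[ev]).sum())


def cox_loss_grad(risk: np.ndarray, survival: SurvivalOutcome) -> np.ndarray:
    """d loss / d h: -delta_j + sum_{events i: T_i <= T_j} exp(h_j) / S_i."""
    risk = np.asarray(risk, dtype=np.float64)
    if survival.n_events == 0:
        raise DataError("no events: Cox partial likelihood undefined")
    time, event = survival.time, survival.event
    lse, _ = _risk_set_logsumexp(risk, time)
    ev = event == 1
    # sum over events i with T_i <= T_j of 1/S_i, then scale by exp(h_j)
    shift = risk.max()
    ev_times = time[ev]
    # shift keeps both exponentials moderate; clip guards divergent risks
    inv_s = np.exp(np.minimum(shift - lse[ev], 700.0))
    o = np.argsort(ev_times, kind="stable")
    ev_times_sorted = ev_times[o]
    cum_inv = np.concatenate([[0.0], np.cumsum(inv_s[o])])
    counts = np.searchsorted(ev_times_sorted, time, side="right")
    grad = np.exp(risk - shift) * cum_inv[counts]
    grad[ev] -= 1.0
    return grad


def total_loss(l_reconstruction: float, l_clustering: float, l_cox: float,
               gamma: float = 1.0, beta: float = 10.0) -> float:
    """gamma * L_D + beta * L_C + L_P (defaults gamma=1, beta=10)."""
    return float(gamma * l_reconstruction + beta * l_clustering + l_cox)
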