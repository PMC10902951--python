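"""Synthetic cohorts with known ground truth.

Emulates the shape of public breast-cancer expression cohorts: n ~ 100-600
patients, p ~ 1000-5000 genes, censoring anywhere from ~12% to ~87%.  A small
set of planted prognostic genes carries a proportional-hazards signal; the
expression matrix has latent cluster structure so the clustering head has
something real to find.

Survival mechanism: event times are exponential with rate
``baseline_hazard * exp(r_i)`` where ``r_i = sum_planted effect_size * x_ig``
(an exponential-baseline proportional-hazards model, the model class the risk
head assumes).  Censoring times are Uniform(0, c_max), with c_max calibrated
by bisection so the realized censoring fraction lands within +-5 percentage
points of the target.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .data_io import (
    CohortDataset,
    ExpressionMatrix,
    PathwayCollection,
    SurvivalOutcome,
    write_expression,
    write_gmt,
    write_survival,
)


class SimulationError(ValueError):
    pass


@dataclasses.dataclass
class SyntheticSpec:
    """Parameters of one synthetic cohort.

    ``effect_size`` is the Cox log-hazard coefficient per planted gene (per
    unit of log-expression); ``baseline_hazard`` is the exponential event rate
    at risk score 0; ``target_censoring`` the desired censored fraction.
    """

    n_samples: int = 400
    n_genes: int = 1000
    n_pathways: int = 50
    pathway_size: int = 20
    planted_genes: int = 20
    effect_size: float = 0.5
    baseline_hazard: float = 0.1
    target_censoring: float = 0.6
    noise_sd: float = 1.0
    cluster_shift: float = 1.0
    n_clusters_true: int = 3
    weibull_shape: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_genes > self.n_genes:
            raise SimulationError("planted_genes exceeds n_genes")
        if not (0.0 <= self.target_censoring < 1.0):
            raise SimulationError("target_censoring must be in [0, 1)")
        if self.noise_sd <= 0 or self.baseline_hazard <= 0:
            raise SimulationError("noise_sd and baseline_hazard must be positive")
        if self.n_samples < 4 or self.n_genes < 1 or self.n_pathways < 1:
            raise SimulationError("degenerate cohort size")


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, stream]))


def simulate_pathways(spec: SyntheticSpec) -> PathwayCollection:
    """Partition the gene set into ``n_pathways`` sets with the planted
    prognostic genes grouped into a few "signal" pathways.

    Prognostic genes cluster in functional pathways rather than scattering
    uniformly — that alignment between prior structure and signal is the
    premise of the pathway-masked sparse layer.  The planted genes (the first
    ``planted_genes`` identifiers) are dealt into the smallest number of
    leading pathways that leaves each signal pathway about half planted and
    half background; all remaining genes are shuffled over the rest.
    """
    if spec.pathway_size * spec.n_pathways < spec.planted_genes:
        raise SimulationError("pathways too small to cover the planted genes")
    rng = _rng(spec, 1)
    genes = gene_names(spec.n_genes)
    members: list[list[str]] = [[] for _ in range(spec.n_pathways)]
    half = max(1, spec.pathway_size // 2)
    n_signal = min(spec.n_pathways, -(-spec.planted_genes // half))
    for j in range(spec.planted_genes):
        members[j % n_signal].append(genes[j])
    rest = rng.permutation(np.arange(spec.planted_genes, spec.n_genes))
    # fill signal pathways to full size with background genes, then deal the
    # remainder round-robin over the other pathways
    pos = 0
    for i in range(n_signal):
        take = min(max(0, spec.pathway_size - len(members[i])), len(rest) - pos)
        members[i].extend(genes[j] for j in rest[pos:pos + take])
        pos += take
    others = range(n_signal, spec.n_pathways) if n_signal < spec.n_pathways else range(spec.n_pathways)
    others = list(others)
    for k, j in enumerate(rest[pos:]):
        members[others[k % len(others)]].append(genes[j])
    members = [m for m in members if m]
    names = [f"PW{i + 1:03d}" for i in range(len(members))]
    return PathwayCollection(names, [sorted(m) for m in members])


def gene_names(p: int) -> list[str]:
    return [f"g{j + 1:04d}" for j in range(p)]


def simulate_cohort(spec: SyntheticSpec) -> tuple[CohortDataset, dict]:
    """Draw one cohort; returns (dataset, ground_truth).

    ground_truth holds the planted gene ids, the per-gene coefficients, the
    true per-sample risk score, the true cluster labels, and the realized
    censoring fraction.
    """
    rng = _rng(spec, 2)
    n, p = spec.n_samples, spec.n_genes
    genes = gene_names(p)
    samples = [f"s{i + 1:04d}" for i in range(n)]

    # cluster-structured expression: per-cluster mean shifts on a gene subset
    labels = rng.integers(spec.n_clusters_true, size=n)
    centers = np.zeros((spec.n_clusters_true, p))
    n_shift = max(1, p // 10)
    for c in range(spec.n_clusters_true):
        idx = rng.choice(p, size=n_shift, replace=False)
        centers[c, idx] = rng.normal(0.0, spec.cluster_shift, size=n_shift)
    X = centers[labels] + rng.normal(0.0, spec.noise_sd, size=(n, p))

    beta = np.zeros(p)
    beta[: spec.planted_genes] = spec.effect_size
    risk = X @ beta
    risk = risk - risk.mean()  # center so baseline_hazard sets the overall scale

    # Weibull(shape=k) proportional hazards; k=1 is the exponential default
    u = rng.uniform(size=n)
    rate = spec.baseline_hazard * np.exp(risk)
    event_time = (-np.log(u) / rate) ** (1.0 / spec.weibull_shape)

    if spec.target_censoring == 0.0:
        time, event = event_time, np.ones(n, dtype=int)
        realized = 0.0
    else:
        cu = rng.uniform(size=n)  # censor_time = cu * c_max, fixed draws
        c_max = _calibrate_cmax(event_time, cu, spec.target_censoring)
        censor_time = cu * c_max
        event = (event_time <= censor_time).astype(int)
        time = np.minimum(event_time, censor_time)
        realized = float(1.0 - event.mean())
    if event.sum() == 0:
        raise SimulationError("no events after censoring; lower target_censoring")

    cohort = CohortDataset(
        ExpressionMatrix(samples, genes, X),
        SurvivalOutcome(samples, time, event),
    )
    truth = {
        "planted_genes": genes[: spec.planted_genes],
        "beta": beta[: spec.planted_genes].tolist(),
        "true_risk": risk.tolist(),
        "true_clusters": labels.tolist(),
        "realized_censoring": realized,
    }
    return cohort, truth


def _calibrate_cmax(event_time: np.ndarray, cu: np.ndarray, target: float,
                    tol: float = 0.05, max_iter: int = 200) -> float:
    """Bisection on c_max: censored fraction mean(cu*c_max < T) falls as c_max grows."""

    def censored_frac(c_max: float) -> float:
        return float(np.mean(cu * c_max < event_time))

    lo, hi = 1e-12, float(event_time.max()) * 2.0 + 1e-12
    # expand hi until the censored fraction drops below target
    it = 0
    while censored_frac(hi) > target and it < 60:
        hi *= 2.0
        it += 1
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f = censored_frac(mid)
        if abs(f - target) <= tol * 0.5:
            return mid
        if f > target:
            lo = mid
        else:
            hi = mid
    f = censored_frac(0.5 * (lo + hi))
    if abs(f - target) <= tol:
        return 0.5 * (lo + hi)
    raise SimulationError(
        f"censoring calibration failed: target {target:.2f}, closest {f:.2f}"
    )


def write_cohort(cohort: CohortDataset, pathways: PathwayCollection,
                 out_dir: str | Path, truth: dict | None = None) -> dict[str, Path]:
    """Emit expression.tsv, survival.tsv, pathways.gmt (and truth.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "survival": out / "survival.tsv",
        "pathways": out / "pathways.gmt",
    }
    write_expression(cohort.expression, paths["expression"])
    write_survival(cohort.survival, paths["survival"])
    write_gmt(pathways, paths["pathways"])
    if truth is not None:
        paths["truth"] = out / "truth.json"
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=1)
    return paths
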