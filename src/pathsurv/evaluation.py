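"""Survival-prediction metrics and risk-group stratification.

Harrell's C is implemented in-package by vectorized pair counting so its
comparability and tie semantics are pinned: a pair is comparable when the
earlier time carries an event and the times differ; concordant when the
earlier-event patient has the higher predicted risk; tied risks earn half
credit.  The log-rank test comes from lifelines, the time-dependent AUC from
scikit-survival's IPCW cumulative/dynamic estimator, and Kaplan-Meier tables
from lifelines.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

from .data_io import DataError, SurvivalOutcome

_P_FLOOR = 1e-300  # keep |log10(p)| finite when the test statistic explodes


@dataclasses.dataclass
class EvaluationReport:
    c_index: float
    neglog10_p: float
    td_auc: float
    td_auc_by_time: pd.DataFrame
    group_sizes: tuple[int, int]
    km_table: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "c_index": self.c_index,
            "neglog10_p": self.neglog10_p,
            "td_auc": self.td_auc,
            "group_sizes": list(self.group_sizes),
        }


def concordance_index(risk: np.ndarray, survival: SurvivalOutcome) -> float:
    """Harrell's C: fraction of comparable pairs ordered correctly by risk."""
    risk = np.asarray(risk, dtype=np.float64)
    time, event = survival.time, survival.event
    n = len(time)
    if len(risk) != n:
        raise DataError("risk and survival lengths differ")
    # comparable (i, j): t_i < t_j and event_i == 1
    ti = time[:, None]
    comparable = (ti < time[None, :]) & (event[:, None] == 1)
    n_comp = comparable.sum()
    if n_comp == 0:
        raise DataError("no comparable pairs")
    ri = risk[:, None]
    concordant = (comparable & (ri > risk[None, :])).sum()
    tied = (comparable & (ri == risk[None, :])).sum()
    return float((concordant + 0.5 * tied) / n_comp)


def risk_group_split(risk: np.ndarray) -> np.ndarray:
    """Median split; returns 1 for the high-risk group (risk above median)."""
    risk = np.asarray(risk, dtype=np.float64)
    if len(risk) < 4:
        raise DataError("need at least 4 samples to split")
    if np.all(risk == risk[0]):
        raise DataError("degenerate split: all risk scores identical")
    return (risk > np.median(risk)).astype(int)


def logrank_neglog10p(groups: np.ndarray, survival: SurvivalOutcome) -> float:
    """|log10(p)| of the two-sample log-rank test between the risk groups."""
    groups = np.asarray(groups)
    g0, g1 = groups == 0, groups == 1
    if g0.sum() == 0 or g1.sum() == 0:
        raise DataError("both risk groups must be non-empty")
    if survival.n_events == 0:
        raise DataError("no events: log-rank test undefined")
    res = logrank_test(
        survival.time[g0], survival.time[g1],
        event_observed_A=survival.event[g0], event_observed_B=survival.event[g1],
    )
    return float(abs(np.log10(max(res.p_value, _P_FLOOR))))


def time_dependent_auc(
    risk: np.ndarray,
    survival: SurvivalOutcome,
    times: np.ndarray | None = None,
) -> tuple[pd.DataFrame, float]:
    """Cumulative/dynamic AUC with IPCW weights; headline value is the mean
    over the grid (default: interior deciles of the observed event times)."""
    risk = np.asarray(risk, dtype=np.float64)
    ev_times = survival.time[survival.event == 1]
    if len(ev_times) == 0:
        raise DataError("no events: time-dependent AUC undefined")
    if times is None:
        times = np.unique(np.quantile(ev_times, np.linspace(0.1, 0.9, 9)))
    times = np.asarray(times, dtype=np.float64)
    tmax = survival.time.max()
    keep = (times < tmax) & (times >= survival.time.min())
    keep &= times >= ev_times.min()  # need an event before each evaluated time
    if not np.all(keep):
        warnings.warn("dropping AUC grid times outside the evaluable range")
    times = times[keep]
    if len(times) == 0:
        raise DataError("no evaluable grid times")
    y = Surv.from_arrays(event=survival.event.astype(bool), time=survival.time)
    auc, _ = cumulative_dynamic_auc(y, y, risk, times)
    table = pd.DataFrame({"time": times, "auc": auc})
    return table, float(np.nanmean(auc))


def km_table(groups: np.ndarray, survival: SurvivalOutcome) -> pd.DataFrame:
    """Product-limit estimates per risk group at each distinct event time."""
    groups = np.asarray(groups)
    frames = []
    for g in np.unique(groups):
        sel = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(survival.time[sel], survival.event[sel])
        tab = kmf.event_table.reset_index().rename(columns={"event_at": "time"})
        surv = kmf.survival_function_.iloc[:, 0].to_numpy()
        frames.append(pd.DataFrame({
            "group": g,
            "time": tab["time"],
            "at_risk": tab["at_risk"].astype(int),
            "events": tab["observed"].astype(int),
            "survival": surv,
        }))
    return pd.concat(frames, ignore_index=True)


def evaluate(risk: np.ndarray, survival: SurvivalOutcome) -> EvaluationReport:
    """Full report: C-index, risk-group log-rank |log10(p)|, mean td-AUC, KM."""
    ci = concordance_index(risk, survival)
    groups = risk_group_split(risk)
    nlp = logrank_neglog10p(groups, survival)
    auc_table, mean_auc = time_dependent_auc(risk, survival)
    table = km_table(groups, survival)
    return EvaluationReport(
        c_index=ci,
        neglog10_p=nlp,
        td_auc=mean_auc,
        td_auc_by_time=auc_table,
        group_sizes=(int((groups == 0).sum()), int((groups == 1).sum())),
        km_table=table,
    )
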