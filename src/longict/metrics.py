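"""Survival evaluation: Harrell's C-index, one-year AUC, Youden-index cutoff
and risk groups, Kaplan-Meier curves, log-rank test and hazard ratios.

Scores follow the risk convention throughout: higher score = higher risk of
early death.  Confidence intervals are percentile bootstrap over patients
(2000 replicates, seeded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import concordance_index
from sklearn.metrics import roc_auc_score

from .data import POOR_OS_MONTHS

N_BOOTSTRAP = 2000


@dataclass(frozen=True)
class EstimateCI:
    value: float
    lo: float = np.nan
    hi: float = np.nan

    def __float__(self):
        return self.value


def _bootstrap_ci(stat, n: int, n_boot: int, seed: int) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            reps.append(stat(idx))
        except (ValueError, ZeroDivisionError):
            continue
    if not reps:
        return (np.nan, np.nan)
    return tuple(np.percentile(reps, [2.5, 97.5]))


def c_index(scores, os_months, events, n_boot: int = 0, seed: int = 0) -> EstimateCI:
    """Harrell's concordance of a risk score against censored survival:
    concordant pairs / comparable pairs, score ties counting one half."""
    scores = np.asarray(scores, dtype=float)
    os_months = np.asarray(os_months, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() == 0:
        raise ValueError("no comparable pairs: no events observed")
    value = float(concordance_index(os_months, -scores, events))
    lo = hi = np.nan
    if n_boot:
        lo, hi = _bootstrap_ci(
            lambda i: float(concordance_index(os_months[i], -scores[i], events[i])),
            len(scores), n_boot, seed)
    return EstimateCI(value, lo, hi)


def one_year_labels(os_months, events, horizon: float = POOR_OS_MONTHS
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Binary death-before-horizon labels; patients censored before the
    horizon are excluded (mask False)."""
    os_months = np.asarray(os_months, dtype=float)
    events = np.asarray(events, dtype=int)
    keep = (os_months >= horizon) | (events == 1)
    labels = ((os_months < horizon) & (events == 1)).astype(int)
    return labels, keep


def auc_one_year(scores, os_months, events, horizon: float = POOR_OS_MONTHS,
                 n_boot: int = 0, seed: int = 0) -> EstimateCI:
    """AUC of the risk score for death within one year versus survival
    beyond it, excluding patients censored before the horizon."""
    scores = np.asarray(scores, dtype=float)
    labels, keep = one_year_labels(os_months, events, horizon)
    y, s = labels[keep], scores[keep]
    if len(np.unique(y)) < 2:
        raise ValueError("one-year AUC undefined: a class is empty after exclusions")
    value = float(roc_auc_score(y, s))
    lo = hi = np.nan
    if n_boot:
        def stat(idx):
            yi, si = y[idx % len(y)], s[idx % len(y)]
            if len(np.unique(yi)) < 2:
                raise ValueError
            return float(roc_auc_score(yi, si))
        lo, hi = _bootstrap_ci(stat, len(y), n_boot, seed)
    return EstimateCI(value, lo, hi)


def youden_cutoff(scores, labels) -> float:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1 on the
    training cohort, scanned over midpoints of adjacent distinct scores;
    ties resolve to the lowest threshold.  Patients with score strictly
    above the cutoff form the high-risk group, and the training cutoff is
    frozen for all validation cohorts."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("Youden cutoff needs both classes")
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise ValueError("Youden cutoff undefined for a single distinct score")
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    pos, neg = labels.sum(), (1 - labels).sum()
    j = np.array([(labels[scores > c].sum() / pos)
                  + ((1 - labels[scores <= c]).sum() / neg) - 1.0
                  for c in cuts])
    return float(cuts[int(np.argmax(j))])   # argmax returns first (lowest) tie


@dataclass
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    censor_times: np.ndarray

    def at(self, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[i]) if i >= 0 else 1.0


def km_curve(os_months, events) -> KMCurve:
    """Product-limit (Kaplan-Meier) estimator with censoring marks."""
    os_months = np.asarray(os_months, dtype=float)
    events = np.asarray(events, dtype=int)
    km = KaplanMeierFitter()
    km.fit(os_months, events)
    sf = km.survival_function_
    return KMCurve(times=sf.index.to_numpy(dtype=float),
                   survival=sf.iloc[:, 0].to_numpy(dtype=float),
                   censor_times=np.sort(os_months[events == 0]))


def logrank(os_a, ev_a, os_b, ev_b) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, p-value)."""
    if len(os_a) == 0 or len(os_b) == 0:
        raise ValueError("log-rank test needs two non-empty groups")
    res = _ll_logrank(os_a, os_b, event_observed_A=ev_a, event_observed_B=ev_b)
    return float(res.test_statistic), float(res.p_value)


def hazard_ratio(groups, os_months, events) -> tuple[float, float]:
    """Univariate Cox fit of a binary risk-group indicator: (HR, p-value)."""
    df = pd.DataFrame({"group": np.asarray(groups, dtype=float),
                       "T": np.asarray(os_months, dtype=float),
                       "E": np.asarray(events, dtype=int)})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="T", event_col="E")
    return (float(np.exp(cph.params_["group"])),
            float(cph.summary.loc["group", "p"]))


@dataclass
class CohortResult:
    """Per-patient scores/groups plus the cohort-level survival metrics."""

    scores: pd.DataFrame
    c_index: EstimateCI
    auc_1yr: EstimateCI | None
    cutoff: float
    hr: float = np.nan
    hr_p: float = np.nan
    logrank_stat: float = np.nan
    logrank_p: float = np.nan
    km_curves: dict = field(default_factory=dict)


def evaluate_cohort(scores, os_months, events, cutoff: float | None = None,
                    patient_ids=None, n_boot: int = N_BOOTSTRAP,
                    seed: int = 0) -> CohortResult:
    """Full evaluation of one cohort's risk scores.

    ``cutoff`` must be the frozen training-cohort Youden cutoff when scoring
    a validation cohort; if None it is derived here from the one-year labels
    (training mode)."""
    scores = np.asarray(scores, dtype=float)
    os_months = np.asarray(os_months, dtype=float)
    events = np.asarray(events, dtype=int)
    if cutoff is None:
        labels, keep = one_year_labels(os_months, events)
        cutoff = youden_cutoff(scores[keep], labels[keep])
    group = (scores > cutoff).astype(int)
    ci = c_index(scores, os_months, events, n_boot=n_boot, seed=seed)
    try:
        auc = auc_one_year(scores, os_months, events, n_boot=n_boot, seed=seed)
    except ValueError:
        auc = None
    hr = hr_p = lr_stat = lr_p = np.nan
    curves = {}
    if 0 < group.sum() < len(group):
        hi, lo = group == 1, group == 0
        lr_stat, lr_p = logrank(os_months[hi], events[hi], os_months[lo], events[lo])
        if events[hi].sum() + events[lo].sum() > 0:
            try:
                hr, hr_p = hazard_ratio(group, os_months, events)
            except Exception:
                pass
        curves = {"high": km_curve(os_months[hi], events[hi]),
                  "low": km_curve(os_months[lo], events[lo])}
    df = pd.DataFrame({"score": scores, "risk_group": group})
    if patient_ids is not None:
        df.insert(0, "patient_id", list(patient_ids))
    return CohortResult(scores=df, c_index=ci, auc_1yr=auc, cutoff=float(cutoff),
                        hr=hr, hr_p=hr_p, logrank_stat=lr_stat, logrank_p=lr_p,
                        km_curves=curves)
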