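"""Survival evaluation stack: KM, log-rank, AUC, NRI, IDI, decision curves.

Implements the comparison battery for a risk model against a baseline on a
right-censored endpoint: bootstrap AUC at a fixed horizon, risk
stratification at the training-set median, Kaplan-Meier curves with a
log-rank test, continuous net reclassification improvement (NRI),
integrated discrimination improvement (IDI), and decision-curve analysis
(DCA).  The Kaplan-Meier estimator and log-rank test are delegated to
lifelines; everything is validated against closed-form oracles in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index
from sklearn.metrics import roc_auc_score


class EvaluationError(ValueError):
    pass


# --------------------------------------------------------------------------
# Kaplan-Meier and log-rank

@dataclass
class SurvivalCurve:
    """Product-limit estimate at the distinct observed event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self):
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.at_risk = np.asarray(self.at_risk, dtype=float)
        if not (self.event_times.size == self.survival.size == self.at_risk.size):
            raise EvaluationError("curve arrays must have equal length")
        if self.survival.size:
            if np.any(np.diff(self.event_times) <= 0):
                raise EvaluationError("event times must be strictly ascending")
            if np.any(np.diff(self.survival) > 1e-12):
                raise EvaluationError("survival must be non-increasing")
            if self.survival.min() < -1e-12 or self.survival.max() > 1 + 1e-12:
                raise EvaluationError("survival must lie in [0, 1]")


def km_curve(times: Sequence[float], events: Sequence[int]) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate, reported at event times only."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise EvaluationError("empty input")
    if times.shape != events.shape:
        raise EvaluationError("times and events must align")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tab = kmf.event_table
    has_event = tab["observed"] > 0
    t = tab.index.values[has_event]
    # survival immediately after each event time
    surv = kmf.survival_function_at_times(t).values
    at_risk = tab["at_risk"].values[has_event]
    return SurvivalCurve(t, surv, at_risk)


def logrank(times_a, events_a, times_b, events_b) -> Tuple[float, float]:
    """Two-group log-rank chi-square statistic (1 df) and p-value."""
    a_t, b_t = np.asarray(times_a, dtype=float), np.asarray(times_b, dtype=float)
    if a_t.size == 0 or b_t.size == 0:
        raise EvaluationError("both groups must be non-empty")
    res = logrank_test(a_t, b_t, event_observed_A=np.asarray(events_a),
                       event_observed_B=np.asarray(events_b))
    return float(res.test_statistic), float(res.p_value)


# --------------------------------------------------------------------------
# Risk stratification

@dataclass
class RiskGroups:
    threshold: float          # training-set median risk
    labels: np.ndarray        # 'high' / 'low' per subject


def risk_stratify(risks: Sequence[float], train_mask: Sequence[bool]) -> RiskGroups:
    """Label every subject high/low at the training-set median risk.

    A subject is 'high' iff its risk strictly exceeds the threshold, so a
    degenerate all-equal risk vector yields all-'low'.
    """
    risks = np.asarray(risks, dtype=float)
    train_mask = np.asarray(train_mask, dtype=bool)
    if not train_mask.any():
        raise EvaluationError("train_mask selects no subjects")
    thr = float(np.median(risks[train_mask]))
    labels = np.where(risks > thr, "high", "low")
    return RiskGroups(thr, labels)


# --------------------------------------------------------------------------
# Fixed-horizon binary outcome helpers

def horizon_labels(times, events, horizon: float) -> Tuple[np.ndarray, np.ndarray]:
    """Binary event-by-horizon labels and the kept-subject mask.

    Positive: event observed at or before the horizon.  Negative: followed
    beyond the horizon (event or not).  Subjects censored before the
    horizon carry no label and are excluded.
    """
    if horizon <= 0:
        raise EvaluationError("horizon must be > 0")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    pos = (events == 1) & (times <= horizon)
    keep = pos | (times >= horizon)
    return pos[keep].astype(int), keep


def _stratified_boot(rng: np.random.Generator, labels: np.ndarray):
    """Bootstrap indices resampled within each class (keeps both present)."""
    idx_pos = np.flatnonzero(labels == 1)
    idx_neg = np.flatnonzero(labels == 0)
    return np.concatenate([
        rng.choice(idx_pos, idx_pos.size, replace=True),
        rng.choice(idx_neg, idx_neg.size, replace=True),
    ])


def auc_ci(risks, times, events, horizon: float = 60.0,
           n_boot: int = 1000, seed: int = 0) -> Tuple[float, Tuple[float, float]]:
    """AUC for event-by-horizon status with a percentile bootstrap CI.

    The point estimate is the Mann-Whitney concordance of risks against the
    binary labels; the CI resamples subjects within each outcome class
    (default 1000 resamples, 2.5/97.5 percentiles).
    """
    risks = np.asarray(risks, dtype=float)
    labels, keep = horizon_labels(times, events, horizon)
    r = risks[keep]
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise EvaluationError(
            "AUC undefined: only one outcome class remains after excluding "
            "subjects censored before the horizon"
        )
    auc = float(roc_auc_score(labels, r))
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bi = _stratified_boot(rng, labels)
        boots[b] = roc_auc_score(labels[bi], r[bi])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return auc, (float(lo), float(hi))


# --------------------------------------------------------------------------
# NRI / IDI

def _check_two_class(labels) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise EvaluationError("labels contain a single class")
    return labels


def _nri_point(old: np.ndarray, new: np.ndarray, labels: np.ndarray) -> float:
    ev, ne = labels == 1, labels == 0
    up_ev = np.mean(new[ev] > old[ev]) - np.mean(new[ev] < old[ev])
    down_ne = np.mean(new[ne] < old[ne]) - np.mean(new[ne] > old[ne])
    return float(up_ev + down_ne)


def nri(risks_old, risks_new, labels, n_boot: int = 1000,
        seed: int = 0) -> Tuple[float, Tuple[float, float]]:
    """Continuous (category-free) net reclassification improvement.

    NRI = [P(up|event) - P(down|event)] + [P(down|non-event) - P(up|non-event)],
    range [-2, 2]; CI by stratified percentile bootstrap.
    """
    old = np.asarray(risks_old, dtype=float)
    new = np.asarray(risks_new, dtype=float)
    labels = _check_two_class(labels)
    if not (old.shape == new.shape == labels.shape):
        raise EvaluationError("risk vectors and labels must align")
    point = _nri_point(old, new, labels)
    rng = np.random.default_rng(seed)
    boots = [ _nri_point(old[bi], new[bi], labels[bi])
              for bi in (_stratified_boot(rng, labels) for _ in range(n_boot)) ]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return point, (float(lo), float(hi))


def _idi_point(old: np.ndarray, new: np.ndarray, labels: np.ndarray) -> float:
    ev, ne = labels == 1, labels == 0
    return float((new[ev].mean() - old[ev].mean()) - (new[ne].mean() - old[ne].mean()))


def idi(risks_old, risks_new, labels, n_boot: int = 1000,
        seed: int = 0) -> Tuple[float, Tuple[float, float]]:
    """Integrated discrimination improvement (difference of discrimination
    slopes).  Inputs must be probabilities in [0, 1]; map raw scores with
    :func:`rank_to_probability` first."""
    old = np.asarray(risks_old, dtype=float)
    new = np.asarray(risks_new, dtype=float)
    labels = _check_two_class(labels)
    for name, r in (("risks_old", old), ("risks_new", new)):
        if r.min() < 0 or r.max() > 1:
            raise EvaluationError(f"{name} must be probabilities in [0, 1]")
    point = _idi_point(old, new, labels)
    rng = np.random.default_rng(seed)
    boots = [ _idi_point(old[bi], new[bi], labels[bi])
              for bi in (_stratified_boot(rng, labels) for _ in range(n_boot)) ]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return point, (float(lo), float(hi))


def rank_to_probability(risks) -> np.ndarray:
    """Within-cohort rank scaling of raw scores to (0, 1): (rank - 0.5)/n."""
    risks = np.asarray(risks, dtype=float)
    order = np.argsort(np.argsort(risks, kind="stable"), kind="stable")
    return (order + 0.5) / risks.size


# --------------------------------------------------------------------------
# Decision curve analysis

@dataclass
class DecisionCurve:
    thresholds: np.ndarray
    net_benefit: np.ndarray      # model under evaluation
    net_benefit_all: np.ndarray  # treat-everyone reference
    net_benefit_none: np.ndarray  # treat-no-one reference (identically 0)


def dca(risk_probs, labels, thresholds=None) -> DecisionCurve:
    """Net benefit NB(p_t) = TP/n - (FP/n) * p_t/(1-p_t), treating risk >= p_t
    as positive, with treat-all and treat-none references."""
    p = np.asarray(risk_probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if p.min() < 0 or p.max() > 1:
        raise EvaluationError("risk_probs must lie in [0, 1]")
    if thresholds is None:
        thresholds = np.arange(0.05, 1.0, 0.05)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds <= 0) or np.any(thresholds >= 1):
        raise EvaluationError("thresholds must lie strictly inside (0, 1)")
    n = p.size
    prevalence = labels.mean()
    nb, nb_all = np.empty(thresholds.size), np.empty(thresholds.size)
    for k, pt in enumerate(thresholds):
        pos = p >= pt
        tp = np.sum(pos & (labels == 1)) / n
        fp = np.sum(pos & (labels == 0)) / n
        odds = pt / (1 - pt)
        nb[k] = tp - fp * odds
        nb_all[k] = prevalence - (1 - prevalence) * odds
    return DecisionCurve(thresholds, nb, nb_all, np.zeros(thresholds.size))


# --------------------------------------------------------------------------
# Full per-endpoint comparison report

@dataclass
class EvalReport:
    """All comparison statistics of a model (vs a baseline) on one endpoint."""

    endpoint: str
    auc: float
    auc_ci: Tuple[float, float]
    logrank_stat: float
    logrank_p: float
    median_threshold: float
    nri: Optional[float] = None
    nri_ci: Optional[Tuple[float, float]] = None
    idi: Optional[float] = None
    idi_ci: Optional[Tuple[float, float]] = None
    dca_thresholds: Optional[List[float]] = None
    dca_net_benefit: Optional[List[float]] = None
    dca_net_benefit_all: Optional[List[float]] = None
    n_evaluated: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_model(
    risks, times, events, train_mask, *,
    endpoint: str = "OS",
    baseline_risks=None,
    eval_mask=None,
    horizon: float = 60.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> EvalReport:
    """AUC/KM/log-rank for one risk vector, plus NRI/IDI/DCA vs a baseline.

    Stratification uses the training-median threshold; AUC, NRI, IDI and
    DCA are computed on ``eval_mask`` (default: all subjects) with
    event-by-horizon labels.
    """
    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = risk_stratify(risks, train_mask)
    if eval_mask is None:
        eval_mask = np.ones(risks.size, dtype=bool)
    eval_mask = np.asarray(eval_mask, dtype=bool)

    r, t, e = risks[eval_mask], times[eval_mask], events[eval_mask]
    lab = groups.labels[eval_mask]
    hi, lo = lab == "high", lab == "low"
    if hi.any() and lo.any():
        lr_stat, lr_p = logrank(t[hi], e[hi], t[lo], e[lo])
    else:
        lr_stat, lr_p = float("nan"), float("nan")

    auc, ci = auc_ci(r, t, e, horizon=horizon, n_boot=n_boot, seed=seed)
    report = EvalReport(endpoint, auc, ci, lr_stat, lr_p, groups.threshold,
                        n_evaluated=int(eval_mask.sum()))

    ylab, keep = horizon_labels(t, e, horizon)
    new_p = rank_to_probability(r[keep])
    report.dca_thresholds = list(np.round(np.arange(0.05, 1.0, 0.05), 10))
    curve = dca(new_p, ylab, report.dca_thresholds)
    report.dca_net_benefit = [float(x) for x in curve.net_benefit]
    report.dca_net_benefit_all = [float(x) for x in curve.net_benefit_all]

    if baseline_risks is not None:
        base = np.asarray(baseline_risks, dtype=float)[eval_mask][keep]
        old_p = rank_to_probability(base)
        report.nri, report.nri_ci = nri(base, r[keep], ylab, n_boot=n_boot, seed=seed + 1)
        report.idi, report.idi_ci = idi(old_p, new_p, ylab, n_boot=n_boot, seed=seed + 2)
    return report


def compare_models(
    model_risks: Dict[str, np.ndarray],
    times_by_endpoint: Dict[str, Tuple[np.ndarray, np.ndarray]],
    train_mask, *,
    baseline: str,
    eval_mask=None,
    horizon: float = 60.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> Dict[str, Dict[str, EvalReport]]:
    """Evaluate several aligned risk vectors on each endpoint.

    Every non-baseline model is additionally scored with NRI/IDI against
    ``baseline``.  Returns reports[model][endpoint].
    """
    if baseline not in model_risks:
        raise EvaluationError(f"baseline {baseline!r} not among models {sorted(model_risks)}")
    sizes = {np.asarray(v).size for v in model_risks.values()}
    if len(sizes) != 1:
        raise EvaluationError("model risk vectors are misaligned")
    reports: Dict[str, Dict[str, EvalReport]] = {}
    for name, risks in model_risks.items():
        reports[name] = {}
        for endpoint, (t, e) in times_by_endpoint.items():
            reports[name][endpoint] = evaluate_model(
                risks, t, e, train_mask,
                endpoint=endpoint,
                baseline_risks=None if name == baseline else model_risks[baseline],
                eval_mask=eval_mask, horizon=horizon, n_boot=n_boot, seed=seed,
            )
    return reports


def concordance(times, risks, events) -> float:
    """Harrell's c-index of a risk score (higher risk = earlier event)."""
    return float(concordance_index(times, -np.asarray(risks, dtype=float), events))
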