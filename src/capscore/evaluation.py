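"""Performance metrics and the leave-one-subject-out protocol.

Metrics follow the standard confusion-matrix definitions: accuracy,
sensitivity, specificity, positive and negative predictive value, the
diagnostic odds ratio DOR = (TP*TN)/(FN*FP) — equivalently, in its
prevalence-free form, [Sen/(1-Sen)]*[Spe/(1-Spe)] — and the ROC AUC as the
Mann-Whitney probability that a random positive outranks a random
negative (ties counted one half).

Aggregation convention: metrics are computed per held-out subject and then
averaged across subjects (not pooled counts), with a Student-t 95%
confidence interval over the per-subject means.  Undefined metrics (zero
denominators) are returned as NaN markers and excluded from averages with
a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np
from scipy import stats

from .errors import ProtocolViolationError
from .cap_cycles import CAP, score_cap_cycles
from .phase_post import correct_isolated_phases

logger = logging.getLogger(__name__)

METRIC_NAMES = ("Acc", "Sen", "Spe", "PPV", "NPV", "AUC", "DOR")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")
        if self.TP + self.TN + self.FP + self.FN == 0:
            raise ValueError("at least one compared epoch required")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricSet:
    """One value per metric; NaN marks an undefined (zero-denominator) entry."""

    Acc: float = np.nan
    Sen: float = np.nan
    Spe: float = np.nan
    PPV: float = np.nan
    NPV: float = np.nan
    AUC: float = np.nan
    DOR: float = np.nan

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class CIEntry:
    mean: float
    lower95: float
    upper95: float

    def __post_init__(self):
        if not (self.lower95 <= self.mean <= self.upper95):
            raise ValueError("CI bounds must bracket the mean")


def confusion(pred: np.ndarray, truth: np.ndarray,
              exclude: np.ndarray | None = None) -> ConfusionCounts:
    """Confusion counts of two aligned binary sequences (1 = positive).

    ``exclude`` marks epochs (e.g. flatline-flagged ones) removed before
    counting.
    """
    pred = np.asarray(pred).astype(bool).ravel()
    truth = np.asarray(truth).astype(bool).ravel()
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    if exclude is not None:
        keep = ~np.asarray(exclude, dtype=bool).ravel()
        if keep.shape != pred.shape:
            raise ValueError("exclude mask must align")
        pred, truth = pred[keep], truth[keep]
    return ConfusionCounts(
        TP=int(np.sum(pred & truth)),
        TN=int(np.sum(~pred & ~truth)),
        FP=int(np.sum(pred & ~truth)),
        FN=int(np.sum(~pred & truth)),
    )


def basic_metrics(c: ConfusionCounts) -> MetricSet:
    """Accuracy, sensitivity, specificity, PPV and NPV from counts.

    Zero-denominator entries come back as NaN rather than raising.
    """
    def ratio(num, den):
        return num / den if den > 0 else np.nan

    return MetricSet(
        Acc=ratio(c.TP + c.TN, c.total),
        Sen=ratio(c.TP, c.TP + c.FN),
        Spe=ratio(c.TN, c.TN + c.FP),
        PPV=ratio(c.TP, c.TP + c.FP),
        NPV=ratio(c.TN, c.TN + c.FN),
    )


def dor(sen: float, spe: float) -> float:
    """Diagnostic odds ratio from sensitivity and specificity.

    ``[Sen/(1-Sen)] * [Spe/(1-Spe)]`` — algebraically identical to
    ``(TP*TN)/(FN*FP)`` and independent of prevalence.  Boundary values
    (0 or 1) yield inf/NaN markers instead of raising.
    """
    sen = np.float64(sen)
    spe = np.float64(spe)
    with np.errstate(divide="ignore", invalid="ignore"):
        return float((sen / (1.0 - sen)) * (spe / (1.0 - spe)))


def dor_from_counts(c: ConfusionCounts) -> float:
    """DOR in its direct count form (TP*TN)/(FN*FP)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        return float(np.float64(c.TP) * c.TN / (np.float64(c.FN) * c.FP))


def auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """ROC AUC via the Mann-Whitney rank construction, ties counted 0.5."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    truth = np.asarray(truth).astype(bool).ravel()
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must align")
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[truth].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def ci95(values: np.ndarray) -> CIEntry:
    """Mean with Student-t 95% confidence interval; NaN entries are dropped."""
    values = np.asarray(values, dtype=np.float64).ravel()
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("confidence interval requires at least two finite values")
    mean = float(values.mean())
    half = float(stats.t.ppf(0.975, values.size - 1)
                 * values.std(ddof=1) / np.sqrt(values.size))
    return CIEntry(mean=mean, lower95=mean - half, upper95=mean + half)


def metrics_from_predictions(pred: np.ndarray, truth: np.ndarray,
                             scores: np.ndarray | None = None,
                             exclude: np.ndarray | None = None) -> MetricSet:
    """Full metric set for one subject's predictions."""
    c = confusion(pred, truth, exclude=exclude)
    m = basic_metrics(c)
    m.DOR = dor(m.Sen, m.Spe)
    if scores is not None:
        s = np.asarray(scores, dtype=np.float64).ravel()
        t = np.asarray(truth).astype(bool).ravel()
        if exclude is not None:
            keep = ~np.asarray(exclude, dtype=bool).ravel()
            s, t = s[keep], t[keep]
        if 0 < t.sum() < t.size:
            m.AUC = auc(s, t)
    return m


# ----------------------------------------------------------------------------
# Leave-one-subject-out protocol


@dataclass
class SubjectData:
    """One subject's preprocessed inputs and ground truth."""

    subject_id: str
    epochs: np.ndarray               # (n_epochs, 100)
    phase_labels: np.ndarray         # (n_epochs,) 1 = A
    cycle_truth: np.ndarray          # (n_epochs,) 1 = CAP
    error_flags: np.ndarray | None = None


@dataclass
class LOOResult:
    """Across-subject summary of a leave-one-subject-out run."""

    per_subject_phase: dict[str, MetricSet] = field(default_factory=dict)
    per_subject_cycle: dict[str, MetricSet] = field(default_factory=dict)
    phase_summary: dict[str, CIEntry] = field(default_factory=dict)
    cycle_summary: dict[str, CIEntry] = field(default_factory=dict)

    def summary_frame(self):
        """Report table with one row per metric and CI bounds, as a DataFrame."""
        import pandas as pd

        rows = []
        for stage, summary in (("phase", self.phase_summary),
                               ("cycle", self.cycle_summary)):
            for name, entry in summary.items():
                rows.append({"stage": stage, "metric": name,
                             "mean": entry.mean, "lower95": entry.lower95,
                             "upper95": entry.upper95})
        return pd.DataFrame(rows)


def _mean_metrics(metric_sets: list[MetricSet]) -> MetricSet:
    """Average metric-by-metric over repeats, skipping NaN markers."""
    out = MetricSet()
    for name in METRIC_NAMES:
        vals = np.array([getattr(m, name) for m in metric_sets], dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size < vals.size:
            logger.warning("metric %s undefined in %d/%d repeats; excluded",
                           name, vals.size - finite.size, vals.size)
        setattr(out, name, float(finite.mean()) if finite.size else np.nan)
    return out


def evaluate_subject(estimator, subject: SubjectData,
                     min_cycles_per_sequence: int = 2
                     ) -> tuple[MetricSet, MetricSet]:
    """Phase metrics (post-corrected) and cycle metrics (after the FSM)."""
    scores = estimator.score_phases(subject.epochs)
    corrected = correct_isolated_phases(scores.labels)
    phase_m = metrics_from_predictions(
        corrected, subject.phase_labels, scores=scores.proba,
        exclude=subject.error_flags)
    cycles = score_cap_cycles(corrected, min_cycles_per_sequence,
                              error_flags=subject.error_flags)
    cap_pred = cycles.flags == CAP
    cycle_m = metrics_from_predictions(
        cap_pred, np.asarray(subject.cycle_truth) == CAP,
        scores=cap_pred.astype(float),  # binary detector: rank-based AUC
        exclude=subject.error_flags)
    return phase_m, cycle_m


def loo_evaluate(dataset: list[SubjectData], estimator_factory,
                 n_repeats: int = 50, base_seed: int = 0,
                 min_cycles_per_sequence: int = 2) -> LOOResult:
    """Leave-one-subject-out evaluation over a dataset of recordings.

    For each held-out subject the estimator is trained on all remaining
    subjects ``n_repeats`` times with different seeds, the subject's
    metrics are averaged over the repeats, and the across-subject mean and
    Student-t 95% CI are reported for every metric — separately for the
    post-corrected phase predictions and for the CAP cycle vector produced
    by the rule engine.

    Parameters
    ----------
    dataset : list of SubjectData
        One entry per subject; each subject lies entirely on one side of
        every split (subject independence).
    estimator_factory : callable(seed) -> estimator
        Builds a fresh classifier for a given seed.
    n_repeats : int
        Training repetitions per held-out subject (50 mirrors the full
        protocol; small values suit desk-scale runs).
    """
    if len(dataset) < 2:
        raise ValueError("leave-one-subject-out requires at least 2 subjects")
    ids = [s.subject_id for s in dataset]
    if len(set(ids)) != len(ids):
        raise ProtocolViolationError(
            "duplicate subject ids would place a subject on both sides"
        )
    result = LOOResult()
    for k, held_out in enumerate(dataset):
        train = [s for s in dataset if s.subject_id != held_out.subject_id]
        x = np.concatenate([s.epochs for s in train])
        y = np.concatenate([s.phase_labels for s in train])
        rid = np.concatenate([np.full(s.phase_labels.size, i)
                              for i, s in enumerate(train)])
        phase_reps, cycle_reps = [], []
        for rep in range(n_repeats):
            est = estimator_factory(seed=base_seed + 1000 * k + rep)
            est.fit(x, y, recording_ids=rid)
            pm, cm = evaluate_subject(est, held_out, min_cycles_per_sequence)
            phase_reps.append(pm)
            cycle_reps.append(cm)
        result.per_subject_phase[held_out.subject_id] = _mean_metrics(phase_reps)
        result.per_subject_cycle[held_out.subject_id] = _mean_metrics(cycle_reps)

    for name in METRIC_NAMES:
        for summary, per_subject in (
                (result.phase_summary, result.per_subject_phase),
                (result.cycle_summary, result.per_subject_cycle)):
            vals = np.array([getattr(m, name) for m in per_subject.values()])
            if np.isfinite(vals).sum() >= 2:
                summary[name] = ci95(vals)
    return result
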