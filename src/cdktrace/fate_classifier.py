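"""Proliferation-vs-quiescence classification of CDK-activity traces.

Training: at every post-anaphase timepoint of the shared sampling grid, an
ROC curve is built over the observed DHB ratios (higher ratio means more
CDK activity, i.e. the proliferative class), the area under the curve is
recorded as the predictability of fate at that timepoint, and the
operating threshold is chosen to maximize the geometric mean of
sensitivity and specificity.

Prediction: each relevant timepoint of a trace votes independently
(proliferative iff its ratio is strictly above the trained threshold) and
the majority class wins.  For traces recorded beyond 60 min after
anaphase the relevant timepoints are all samples strictly after 60 min,
where prediction is near-perfect (AUC > 0.9); traces recorded 20-60 min
use their last three timepoints (AUC > 0.8, increasing with time).  Vote
ties are broken by the latest relevant timepoint, since prediction power
increases with time post-anaphase.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split as _sk_split

from .errors import (CoverageError, DegenerateLabelsError, InputError,
                     StratificationError, TrainingError)
from .traces import PROLIFERATIVE, QUIESCENT, CdkTrace, TraceSet

logger = logging.getLogger(__name__)

LONG_TRACE_CUTOFF_MIN = 60.0
SHORT_TRACE_MIN_MIN = 20.0
SHORT_TRACE_K = 3
AUC_FLOOR_LONG = 0.9
AUC_FLOOR_SHORT = 0.8


# ---------------------------------------------------------------------------
# per-timepoint ROC
# ---------------------------------------------------------------------------


@dataclass
class TimepointRoc:
    """ROC analysis of DHB ratios at one timepoint relative to anaphase.

    ``thresholds`` are the candidate cutoffs (-inf plus every distinct
    observed ratio); a ratio strictly greater than the cutoff predicts
    proliferative.  ``chosen_threshold`` maximizes the geometric mean
    sqrt(sensitivity x specificity); among ties the largest cutoff wins.
    """

    time_min: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    chosen_threshold: float
    chosen_gmean: float
    n_pos: int
    n_neg: int


def roc_at_timepoint(ratios, labels, time_min: float = 0.0) -> TimepointRoc:
    """Build the ROC curve for fate prediction from ratios at one timepoint.

    ``labels`` are fate strings; proliferative is the positive class and
    higher ratios score positive.  AUC is computed by trapezoidal
    integration of the (FPR, TPR) curve over all distinct observed ratios
    as thresholds plus the -inf endpoint, which handles ties the same way
    as the pair-counting (Mann-Whitney) definition.
    """
    ratios = np.asarray(ratios, dtype=float)
    labels = np.asarray(labels)
    if ratios.size == 0 or ratios.size != labels.size:
        raise InputError("ratios and labels must be nonempty and equal-length")
    pos = ratios[labels == PROLIFERATIVE]
    neg = ratios[labels == QUIESCENT]
    if pos.size == 0 or neg.size == 0:
        raise DegenerateLabelsError(
            f"t={time_min}: both fate classes are required "
            f"({pos.size} proliferative, {neg.size} quiescent)")

    thresholds = np.concatenate([[-np.inf], np.unique(ratios)])
    # predict proliferative iff ratio > threshold (strict)
    sens = np.array([(pos > c).mean() for c in thresholds])
    spec = np.array([(neg <= c).mean() for c in thresholds])
    # traverse the curve by descending threshold: (FPR, TPR) then runs
    # monotonically from (0, 0) to (1, 1), keeping tied points in path order
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))

    gmean = np.sqrt(sens * spec)
    best = gmean.max()
    # ties -> largest cutoff (most conservative toward quiescent)
    i = int(np.flatnonzero(gmean == best)[-1])
    return TimepointRoc(
        time_min=float(time_min), thresholds=thresholds, sensitivity=sens,
        specificity=spec, auc=auc, chosen_threshold=float(thresholds[i]),
        chosen_gmean=float(best), n_pos=int(pos.size), n_neg=int(neg.size))


# ---------------------------------------------------------------------------
# trace-level classifier
# ---------------------------------------------------------------------------


@dataclass
class TraceClassifier:
    """Per-timepoint thresholds plus the trace-level voting rules."""

    per_timepoint: dict[float, TimepointRoc]
    sample_interval_min: float
    positive_class: str = PROLIFERATIVE
    long_trace_cutoff_min: float = LONG_TRACE_CUTOFF_MIN
    short_trace_min_min: float = SHORT_TRACE_MIN_MIN
    short_trace_k: int = SHORT_TRACE_K
    auc_floor_long: float = AUC_FLOOR_LONG
    auc_floor_short: float = AUC_FLOOR_SHORT
    skipped_timepoints: list[float] = field(default_factory=list)

    @property
    def timepoints(self) -> np.ndarray:
        return np.array(sorted(self.per_timepoint), dtype=float)

    def to_json(self, path=None) -> str:
        payload = {
            "positive_class": self.positive_class,
            "sample_interval_min": self.sample_interval_min,
            "long_trace_cutoff_min": self.long_trace_cutoff_min,
            "short_trace_min_min": self.short_trace_min_min,
            "short_trace_k": self.short_trace_k,
            "auc_floor_long": self.auc_floor_long,
            "auc_floor_short": self.auc_floor_short,
            "skipped_timepoints": list(self.skipped_timepoints),
            "timepoints": [
                {"time_min": t, "threshold": r.chosen_threshold,
                 "gmean": r.chosen_gmean, "auc": r.auc,
                 "n_pos": r.n_pos, "n_neg": r.n_neg}
                for t, r in sorted(self.per_timepoint.items())
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "TraceClassifier":
        """Rebuild a classifier from its JSON summary (path or string).

        Full ROC curves are not stored; the reconstructed TimepointRoc
        objects carry only the chosen operating point and AUC.
        """
        try:
            payload = json.loads(source)
        except (json.JSONDecodeError, TypeError):
            with open(source) as fh:
                payload = json.load(fh)
        per = {}
        for tp in payload["timepoints"]:
            per[float(tp["time_min"])] = TimepointRoc(
                time_min=float(tp["time_min"]), thresholds=np.array([]),
                sensitivity=np.array([]), specificity=np.array([]),
                auc=float(tp["auc"]), chosen_threshold=float(tp["threshold"]),
                chosen_gmean=float(tp["gmean"]), n_pos=int(tp["n_pos"]),
                n_neg=int(tp["n_neg"]))
        return cls(
            per_timepoint=per,
            sample_interval_min=float(payload["sample_interval_min"]),
            positive_class=payload["positive_class"],
            long_trace_cutoff_min=float(payload["long_trace_cutoff_min"]),
            short_trace_min_min=float(payload["short_trace_min_min"]),
            short_trace_k=int(payload["short_trace_k"]),
            auc_floor_long=float(payload["auc_floor_long"]),
            auc_floor_short=float(payload["auc_floor_short"]),
            skipped_timepoints=[float(t) for t in payload.get("skipped_timepoints", [])],
        )


def fit_classifier(train: TraceSet, **rule_params) -> TraceClassifier:
    """Train per-timepoint thresholds on labeled traces.

    One :class:`TimepointRoc` is fitted at every post-anaphase grid
    timepoint where both fate classes are observed; single-class
    timepoints are omitted and logged.  Fitting is deterministic.
    """
    labeled = TraceSet([t for t in train if t.fate in (PROLIFERATIVE, QUIESCENT)])
    if len(labeled) == 0:
        raise TrainingError("no labeled traces in the training set")
    per: dict[float, TimepointRoc] = {}
    skipped: list[float] = []
    for t in labeled.time_grid(post_anaphase_only=True):
        vals, who = labeled.ratios_at(t)
        labels = np.array([w.fate for w in who])
        try:
            per[float(t)] = roc_at_timepoint(vals, labels, time_min=float(t))
        except DegenerateLabelsError:
            skipped.append(float(t))
    if skipped:
        logger.info("omitted %d single-class timepoint(s): %s",
                    len(skipped), skipped)
    if not per:
        raise TrainingError("no timepoint has both fate classes")
    return TraceClassifier(per_timepoint=per,
                           sample_interval_min=labeled.sampling_interval(),
                           skipped_timepoints=skipped, **rule_params)


@dataclass(frozen=True)
class Vote:
    """One relevant timepoint's independent classification."""

    time_min: float
    ratio: float
    trained_time_min: float
    threshold: float
    auc: float
    fate: str


def _relevant_samples(trace: CdkTrace, clf: TraceClassifier
                      ) -> tuple[np.ndarray, np.ndarray]:
    times, ratios = trace.post_anaphase()
    if times.size == 0 or times.max() < clf.short_trace_min_min:
        raise CoverageError(
            f"trace {trace.cell_id!r} ends {times.max() if times.size else 0:g} min "
            f"post-anaphase; need >= {clf.short_trace_min_min:g}")
    if times.max() > clf.long_trace_cutoff_min:
        sel = times > clf.long_trace_cutoff_min
        return times[sel], ratios[sel]
    if times.size < clf.short_trace_k:
        raise CoverageError(
            f"trace {trace.cell_id!r} has {times.size} post-anaphase samples; "
            f"need >= {clf.short_trace_k} for the last-{clf.short_trace_k} rule")
    return times[-clf.short_trace_k:], ratios[-clf.short_trace_k:]


def classify_trace(trace: CdkTrace, clf: TraceClassifier) -> tuple[str, list[Vote]]:
    """Majority-vote fate call for one trace.

    Relevant timepoints are all samples strictly after 60 min when the
    trace extends past 60 min, else the last three recorded post-anaphase
    samples.  Each votes proliferative iff its ratio strictly exceeds the
    threshold of the nearest trained timepoint (which must lie within one
    sampling interval); ties are broken by the latest relevant timepoint.
    """
    times, ratios = _relevant_samples(trace, clf)
    grid = clf.timepoints
    votes: list[Vote] = []
    for tm, r in zip(times, ratios):
        j = int(np.argmin(np.abs(grid - tm)))
        if abs(grid[j] - tm) > clf.sample_interval_min:
            raise CoverageError(
                f"trace {trace.cell_id!r}: no trained threshold within "
                f"{clf.sample_interval_min:g} min of t={tm:g}")
        roc = clf.per_timepoint[float(grid[j])]
        floor = (clf.auc_floor_long if tm > clf.long_trace_cutoff_min
                 else clf.auc_floor_short)
        if roc.auc < floor:
            logger.warning("voting timepoint t=%g has AUC %.3f below floor %.2f",
                           grid[j], roc.auc, floor)
        fate = PROLIFERATIVE if r > roc.chosen_threshold else QUIESCENT
        votes.append(Vote(time_min=float(tm), ratio=float(r),
                          trained_time_min=float(grid[j]),
                          threshold=roc.chosen_threshold, auc=roc.auc, fate=fate))
    n_pro = sum(v.fate == PROLIFERATIVE for v in votes)
    n_qui = len(votes) - n_pro
    if n_pro != n_qui:
        call = PROLIFERATIVE if n_pro > n_qui else QUIESCENT
    else:
        call = votes[-1].fate  # tie: latest relevant timepoint decides
    return call, votes


# ---------------------------------------------------------------------------
# splitting and evaluation
# ---------------------------------------------------------------------------


def train_test_split(traces: TraceSet, train_fraction: float = 0.75,
                     seed: int | None = None) -> tuple[TraceSet, TraceSet]:
    """Stratified whole-trace split into training and test sets."""
    if not (0.0 < train_fraction < 1.0):
        raise InputError("train_fraction must be strictly between 0 and 1")
    fates = traces.fates
    for cls_name in set(fates):
        if fates.count(cls_name) < 2:
            raise StratificationError(
                f"fate class {cls_name!r} has fewer than 2 traces")
    train, test = _sk_split(list(traces), train_size=train_fraction,
                            stratify=fates, random_state=seed, shuffle=True)
    return TraceSet(train), TraceSet(test)


@dataclass
class EvaluationReport:
    """Predicted-vs-actual fate bookkeeping over a test set."""

    n_traces: int
    n_correct: int
    confusion: dict[tuple[str, str], int]  # (actual, predicted) -> count
    per_trace: list[tuple[str, str, str, list[Vote]]]
    skipped: list[tuple[str, str]]  # (cell_id, reason)

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_traces if self.n_traces else float("nan")

    def to_dict(self) -> dict:
        return {
            "n_traces": self.n_traces,
            "n_correct": self.n_correct,
            "accuracy": self.accuracy,
            "confusion": {f"{a}|{p}": c for (a, p), c in sorted(self.confusion.items())},
            "n_skipped": len(self.skipped),
            "skipped": [{"cell_id": c, "reason": r} for c, r in self.skipped],
        }


def evaluate(clf: TraceClassifier, test: TraceSet) -> EvaluationReport:
    """Classify every labeled test trace and tabulate predicted vs actual.

    Traces that fail the classifier's coverage preconditions (too short,
    or no trained threshold near a voting timepoint) are reported as
    skipped and excluded from the accuracy denominator.
    """
    if len(test) == 0:
        raise InputError("empty test set")
    confusion: dict[tuple[str, str], int] = {}
    per_trace = []
    skipped = []
    n_correct = 0
    for t in test:
        try:
            pred, votes = classify_trace(t, clf)
        except CoverageError as exc:
            skipped.append((t.cell_id, str(exc)))
            continue
        confusion[(t.fate, pred)] = confusion.get((t.fate, pred), 0) + 1
        per_trace.append((t.cell_id, t.fate, pred, votes))
        if pred == t.fate:
            n_correct += 1
    return EvaluationReport(n_traces=len(per_trace), n_correct=n_correct,
                            confusion=confusion, per_trace=per_trace,
                            skipped=skipped)


def accuracy_vs_time(clf: TraceClassifier, test: TraceSet) -> pd.DataFrame:
    """Single-timepoint prediction accuracy (and test AUC) per trained time.

    For each trained timepoint, every test trace with a sample exactly at
    that time is classified by the timepoint's threshold alone.  Trained
    timepoints absent from all test traces are omitted (and logged); the
    test AUC is NaN when only one class is present at a timepoint.
    """
    rows = []
    for t in clf.timepoints:
        vals, who = test.ratios_at(float(t))
        labels = np.array([w.fate for w in who])
        usable = np.isin(labels, (PROLIFERATIVE, QUIESCENT))
        vals, labels = vals[usable], labels[usable]
        if vals.size == 0:
            logger.info("timepoint t=%g absent from all test traces; omitted", t)
            continue
        roc = clf.per_timepoint[float(t)]
        pred = np.where(vals > roc.chosen_threshold, PROLIFERATIVE, QUIESCENT)
        acc = float((pred == labels).mean())
        try:
            auc = roc_at_timepoint(vals, labels, time_min=float(t)).auc
        except DegenerateLabelsError:
            auc = float("nan")
        rows.append({"time_min": float(t), "n": int(vals.size),
                     "accuracy": acc, "auc": auc})
    return pd.DataFrame(rows, columns=["time_min", "n", "accuracy", "auc"])
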