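"""Behavioural measures of judgement bias.

The cognitive bias index (CBI) summarises responding to the ambiguous
midpoint tone as the proportion of responses on the high-reward lever minus
the proportion on the low-reward lever, giving a score in [-1, 1]: negative
values indicate a pessimistic bias, positive an optimistic one.  The
denominator counts lever responses only; omissions and premature responses
are excluded, so CBI reflects choice composition, not response rate.

Change-from-baseline variants subtract each subject's own vehicle/pre-drug
score so that a positive delta always means a more positive bias under the
manipulation, and the vehicle-centred variant subtracts the cohort's vehicle
mean from each subject's vehicle score so baseline sessions can enter
repeated-measures analyses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from driftbias.task_sim import Session, TONES

__all__ = [
    "BiasSummary",
    "UndefinedMetricError",
    "cbi",
    "change_from_baseline_cbi",
    "vehicle_centered_cbi",
    "behavioural_percentages",
    "reference_accuracy",
    "qc_filter",
    "QC_ACCURACY_THRESHOLD",
]

#: subjects must exceed this reference-tone accuracy in every session
QC_ACCURACY_THRESHOLD = 0.60


class UndefinedMetricError(ValueError):
    """A metric's denominator is empty (no qualifying responses)."""


@dataclass
class BiasSummary:
    """Per-session behavioural summary, per tone where applicable.

    Percentages are on the 0-100 scale; empty cells are NaN (undefined),
    never silently zero.
    """

    subject_id: str
    session_id: str
    condition_label: str
    cbi: float
    pct_positive: dict[str, float] = field(default_factory=dict)
    pct_omission: dict[str, float] = field(default_factory=dict)
    pct_premature: dict[str, float] = field(default_factory=dict)
    median_latency: dict[str, float] = field(default_factory=dict)
    mean_latency: dict[str, float] = field(default_factory=dict)
    n_responded: dict[str, int] = field(default_factory=dict)


def _lever_counts(session: Session, tone: str) -> tuple[int, int]:
    high = sum(1 for tr in session.trials
               if tr.tone == tone and tr.response == "high_lever")
    low = sum(1 for tr in session.trials
              if tr.tone == tone and tr.response == "low_lever")
    return high, low


def cbi(session: Session) -> float:
    """Cognitive bias index of a probe session.

    (high-lever - low-lever responses) / (lever responses), over midpoint
    trials only.  Raises :class:`UndefinedMetricError` when the subject made
    no lever response to the midpoint tone.
    """
    high, low = _lever_counts(session, "midpoint")
    total = high + low
    if total == 0:
        raise UndefinedMetricError(
            f"session {session.session_id!r}: no midpoint lever responses, CBI undefined")
    return (high - low) / total


def change_from_baseline_cbi(drug: BiasSummary | float,
                             baseline: BiasSummary | float) -> float:
    """Drug-session CBI minus baseline (vehicle or pre-drug) CBI.

    Positive deltas mean a more positive bias under the manipulation; the
    operation is antisymmetric in its arguments.
    """
    d = drug.cbi if isinstance(drug, BiasSummary) else float(drug)
    b = baseline.cbi if isinstance(baseline, BiasSummary) else float(baseline)
    if not (math.isfinite(d) and math.isfinite(b)):
        raise UndefinedMetricError("change from baseline undefined: CBI is NaN")
    return d - b


def vehicle_centered_cbi(vehicle_cbis) -> np.ndarray:
    """Per-subject vehicle CBI minus the cohort vehicle mean (sums to 0).

    Gives vehicle sessions a within-subject 'change' value on the same
    scale as change-from-baseline scores.  A single subject yields a
    degenerate all-zero result (with a warning).
    """
    values = np.asarray([c.cbi if isinstance(c, BiasSummary) else c
                         for c in vehicle_cbis], dtype=float)
    if values.size < 2:
        warnings.warn("vehicle-centred CBI is degenerate (all zero) for a "
                      "single subject", stacklevel=2)
    return values - values.mean()


def _median_or_nan(xs) -> float:
    return float(np.median(xs)) if xs else float("nan")


def behavioural_percentages(session: Session) -> BiasSummary:
    """Per-tone response percentages and latencies for one session.

    Percent positive is high-lever over lever responses; percent omission
    and premature are over scheduled trials of that tone; latency is
    summarised by the median (robust to the long 20 s tail), with the mean
    also reported.  CBI is NaN when undefined (e.g. baseline sessions).
    """
    try:
        score = cbi(session)
    except UndefinedMetricError:
        score = float("nan")
    out = BiasSummary(session.subject_id, session.session_id,
                      session.condition_label, cbi=score)
    for tone in TONES:
        trials = session.trials_of_tone(tone)
        if not trials:
            continue
        n_sched = len(trials)
        high, low = _lever_counts(session, tone)
        lever = high + low
        rts = [tr.rt for tr in trials if tr.rt is not None]
        out.pct_positive[tone] = 100.0 * high / lever if lever else float("nan")
        out.pct_omission[tone] = 100.0 * sum(
            1 for tr in trials if tr.response == "omission") / n_sched
        out.pct_premature[tone] = 100.0 * sum(
            1 for tr in trials if tr.response == "premature") / n_sched
        out.median_latency[tone] = _median_or_nan(rts)
        out.mean_latency[tone] = float(np.mean(rts)) if rts else float("nan")
        out.n_responded[tone] = lever
    return out


def reference_accuracy(session: Session) -> float:
    """Correct-lever proportion on reference tones (lever responses only)."""
    correct = wrong = 0
    for tr in session.trials:
        if tr.tone == "high":
            correct += tr.response == "high_lever"
            wrong += tr.response == "low_lever"
        elif tr.tone == "low":
            correct += tr.response == "low_lever"
            wrong += tr.response == "high_lever"
    total = correct + wrong
    if total == 0:
        raise UndefinedMetricError(
            f"session {session.session_id!r}: no reference-tone lever responses")
    return correct / total


def qc_filter(sessions, threshold: float = QC_ACCURACY_THRESHOLD):
    """Include/exclude decision from a subject's session history.

    Subjects are excluded if reference-tone accuracy fails to stay strictly
    above ``threshold`` in any session (accuracy exactly at threshold
    excludes).  Returns ``(include, reasons)`` where ``reasons`` lists the
    offending sessions.
    """
    reasons = []
    for s in sessions:
        try:
            acc = reference_accuracy(s)
        except UndefinedMetricError:
            reasons.append(f"{s.session_id}: no reference-tone lever responses")
            continue
        if acc <= threshold:
            reasons.append(
                f"{s.session_id}: reference accuracy {acc:.3f} <= {threshold:.2f}")
    return (len(reasons) == 0), reasons
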