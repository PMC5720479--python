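"""Synthetic session generator for the ambiguous-cue judgement-bias task.

A subject learns two reference tones, one predicting a high-value and one a
low-value reward, each earned by pressing the associated lever within a 20 s
response window.  Probe sessions add an ambiguous midpoint tone whose
outcome is assigned at random (50/50) to one of the two reference
contingencies, so no specific outcome can be learnt for it; the lever chosen
on midpoint trials indexes affective bias.

Sessions follow the study design: baseline sessions of 100 trials (50 high,
50 low, pseudorandom order) and probe sessions of 120 trials (40 high, 40
midpoint, 40 low).  Each simulated subject carries one set of diffusion
parameters per tone; choices and response times are drawn from the exact
first-passage sampler, with omissions modelled as an explicit per-tone
probability plus natural censoring at the response window, and premature
responses as a flat per-trial probability.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from driftbias.ddm_core import DDMParams, simulate_trials

__all__ = [
    "RESPONSE_WINDOW_S",
    "TONES",
    "TrialRecord",
    "Session",
    "SubjectSpec",
    "TrialLogError",
    "build_schedule",
    "generate_session",
    "generate_cohort",
    "default_subject_spec",
    "write_trial_log",
    "read_trial_log",
]

#: response window: a lever press counts only during the 20 s tone
RESPONSE_WINDOW_S = 20.0

#: longest permitted run of one tone in a pseudorandom schedule
MAX_TONE_RUN = 4

TONES = ("high", "midpoint", "low")
RESPONSES = ("high_lever", "low_lever", "omission", "premature")

BASELINE_COUNTS = {"high": 50, "low": 50}
PROBE_COUNTS = {"high": 40, "midpoint": 40, "low": 40}

SessionType = Literal["baseline", "probe"]


class TrialLogError(ValueError):
    """A trial log violates the task's structural invariants."""


@dataclass(frozen=True)
class TrialRecord:
    """One task trial."""

    subject_id: str
    session_id: str
    trial_index: int  # 1-based position in the session
    tone: str
    response: str
    rt: float | None  # seconds from tone onset; None unless a lever press
    reinforced_as: str  # outcome contingency in force: "high" or "low"

    def __post_init__(self) -> None:
        if self.tone not in TONES:
            raise TrialLogError(f"unknown tone {self.tone!r}")
        if self.response not in RESPONSES:
            raise TrialLogError(f"unknown response {self.response!r}")
        if self.reinforced_as not in ("high", "low"):
            raise TrialLogError(f"reinforced_as must be high/low, got {self.reinforced_as!r}")
        is_press = self.response in ("high_lever", "low_lever")
        if is_press:
            if self.rt is None or not (0.0 < self.rt <= RESPONSE_WINDOW_S):
                raise TrialLogError(
                    f"lever-press RT must lie in (0, {RESPONSE_WINDOW_S}] s, got {self.rt}")
        elif self.rt is not None:
            raise TrialLogError(f"{self.response} trials carry no RT, got {self.rt}")
        if self.tone != "midpoint" and self.reinforced_as != self.tone:
            raise TrialLogError(
                f"reference tone {self.tone!r} must be reinforced as itself")


@dataclass
class Session:
    """An ordered collection of trials of one subject under one condition."""

    subject_id: str
    session_id: str
    type: SessionType
    condition_label: str
    trials: list[TrialRecord] = field(default_factory=list)
    schedule_seed: int | None = None

    def validate(self) -> None:
        counts = {tone: 0 for tone in TONES}
        for tr in self.trials:
            counts[tr.tone] += 1
        expected = BASELINE_COUNTS if self.type == "baseline" else PROBE_COUNTS
        want = {t: expected.get(t, 0) for t in TONES}
        if counts != want:
            raise TrialLogError(
                f"session {self.session_id!r} ({self.type}): tone counts {counts} "
                f"do not match the {self.type} design {want}")

    def trials_of_tone(self, tone: str) -> list[TrialRecord]:
        return [tr for tr in self.trials if tr.tone == tone]


@dataclass(frozen=True)
class SubjectSpec:
    """Generative model of one subject: per-tone diffusion parameters plus
    omission and premature-response probabilities."""

    subject_id: str
    params: dict[str, DDMParams]  # keyed by tone
    omission_rate: dict[str, float] = field(
        default_factory=lambda: {t: 0.0 for t in TONES})
    premature_rate: float = 0.0

    def __post_init__(self) -> None:
        missing = [t for t in TONES if t not in self.params]
        if missing:
            raise ValueError(f"missing DDM parameters for tones {missing}")
        for t, r in self.omission_rate.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"omission_rate[{t}]={r} outside [0, 1]")
        if not 0.0 <= self.premature_rate <= 1.0:
            raise ValueError(f"premature_rate={self.premature_rate} outside [0, 1]")

    def shifted(self, field_name: str, delta: float,
                tones: Sequence[str] = ("midpoint",)) -> "SubjectSpec":
        """Copy with ``delta`` added to one diffusion parameter.

        ``zr`` shifts apply session-wide (all tones); drift shifts default to
        the midpoint tone only.
        """
        new = dict(self.params)
        for tone in tones:
            p = new[tone]
            new[tone] = p.replace(**{field_name: getattr(p, field_name) + delta})
        return replace(self, params=new)


# ---------------------------------------------------------------------------
# schedules and sessions
# ---------------------------------------------------------------------------

def build_schedule(type: SessionType, seed) -> list[str]:
    """Pseudorandom tone order with exact per-tone counts.

    Shuffles until no tone repeats more than ``MAX_TONE_RUN`` times in a row,
    mimicking the constrained orders used in operant schedules.
    """
    counts = BASELINE_COUNTS if type == "baseline" else PROBE_COUNTS
    if type not in ("baseline", "probe"):
        raise ValueError(f"unknown session type {type!r}")
    rng = np.random.default_rng(seed)
    tones = np.array([t for t, n in counts.items() for _ in range(n)])
    for _ in range(1000):
        order = rng.permutation(tones)
        if _max_run(order) <= MAX_TONE_RUN:
            return order.tolist()
    raise RuntimeError("could not build a run-constrained schedule")  # pragma: no cover


def _max_run(seq) -> int:
    longest = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        longest = max(longest, run)
    return longest


def generate_session(spec: SubjectSpec, type: SessionType, condition_label: str,
                     seed, session_id: str | None = None) -> Session:
    """Simulate one session of ``spec``'s subject.

    Per trial: a premature response fires with ``premature_rate`` (before
    tone processing, no RT); otherwise choice and RT are drawn from the
    tone's diffusion process, and the trial becomes an omission if an
    explicit omission draw fires or the RT exceeds the response window.
    Midpoint outcomes are randomly reinforced 50/50.
    """
    seed_seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    sched_seed, trial_seed = seed_seq.spawn(2)
    schedule = build_schedule(type, sched_seed)
    rng = np.random.default_rng(trial_seed)
    if session_id is None:
        session_id = f"{spec.subject_id}-{condition_label}-{type}"

    # draw all diffusion trials per tone in one vectorised call
    tone_draws: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for tone in TONES:
        n = sum(1 for t in schedule if t == tone)
        if n:
            tone_draws[tone] = simulate_trials(spec.params[tone], n, rng.spawn(1)[0])

    used = {t: 0 for t in TONES}
    trials = []
    for idx, tone in enumerate(schedule, start=1):
        reinforced = tone if tone != "midpoint" else ("high" if rng.random() < 0.5 else "low")
        if rng.random() < spec.premature_rate:
            response, rt_val = "premature", None
        else:
            upper, rts = tone_draws[tone]
            i = used[tone]
            used[tone] += 1
            if rng.random() < spec.omission_rate.get(tone, 0.0) or rts[i] > RESPONSE_WINDOW_S:
                response, rt_val = "omission", None
            else:
                response = "high_lever" if upper[i] else "low_lever"
                rt_val = float(rts[i])
        trials.append(TrialRecord(spec.subject_id, session_id, idx, tone,
                                  response, rt_val, reinforced))
    session = Session(spec.subject_id, session_id, type, condition_label,
                      trials, schedule_seed=None)
    session.validate()
    return session


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: population-level defaults for a well-trained subject: strong drifts toward
#: the correct lever on reference tones, a mildly negative drift at the
#: ambiguous midpoint (the innate negative bias seen in trained cohorts)
DEFAULT_POPULATION = {
    "a": (1.2, 0.10),       # boundary separation: mean, between-subject SD
    "zr": (0.47, 0.03),     # relative starting point
    "v_high": (2.2, 0.25),  # drift toward the high lever on the high tone
    "v_low": (-2.2, 0.25),
    "v_mid": (-0.8, 0.25),
    "t0": (0.30, 0.04),
    "omission_rate": 0.03,
    "premature_rate": 0.03,
}

PRESETS = ("vehicle", "v_shift", "zr_shift")


def default_subject_spec(subject_id: str, rng,
                         population: dict | None = None) -> SubjectSpec:
    """Draw one subject's generative parameters from the population model."""
    pop = dict(DEFAULT_POPULATION, **(population or {}))
    rng = np.random.default_rng(rng)

    def draw(key, lo=None, hi=None):
        m, s = pop[key]
        x = rng.normal(m, s)
        return float(np.clip(x, lo, hi)) if lo is not None else float(x)

    a = draw("a", 0.6, 3.0)
    zr = draw("zr", 0.2, 0.8)
    t0 = draw("t0", 0.1, 1.0)
    params = {
        "high": DDMParams(a=a, zr=zr, v=draw("v_high"), t0=t0),
        "midpoint": DDMParams(a=a, zr=zr, v=draw("v_mid"), t0=t0),
        "low": DDMParams(a=a, zr=zr, v=draw("v_low"), t0=t0),
    }
    return SubjectSpec(
        subject_id=subject_id,
        params=params,
        omission_rate={t: pop["omission_rate"] for t in TONES},
        premature_rate=pop["premature_rate"],
    )


def generate_cohort(n_subjects: int, preset: str, seed, delta: float = 0.0,
                    condition_label: str | None = None,
                    population: dict | None = None):
    """Paired vehicle/manipulation probe sessions for ``n_subjects``.

    Presets mimic pharmacological signatures: ``v_shift`` adds ``delta`` to
    the midpoint-tone drift rate (the rapid-antidepressant/psychostimulant
    signature), ``zr_shift`` adds ``delta`` to the session-wide starting
    point (the chronic-antidepressant signature), and ``vehicle`` applies no
    change (paired null sessions).

    Returns a list of ``(SubjectSpec, vehicle Session, drug Session)``.
    """
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    label = condition_label or (preset if preset == "vehicle" else f"{preset}({delta:+g})")
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    out = []
    for i in range(n_subjects):
        s_spec, s_veh, s_drug = root.spawn(3)
        sid = f"s{i + 1:02d}"
        spec = default_subject_spec(sid, s_spec, population)
        if preset == "v_shift":
            drug_spec = spec.shifted("v", delta, tones=("midpoint",))
        elif preset == "zr_shift":
            drug_spec = spec.shifted("zr", delta, tones=TONES)
        else:
            drug_spec = spec
        veh = generate_session(spec, "probe", "vehicle", s_veh,
                               session_id=f"{sid}-vehicle")
        drug = generate_session(drug_spec, "probe", label, s_drug,
                                session_id=f"{sid}-drug")
        out.append((spec, veh, drug))
    return out


# ---------------------------------------------------------------------------
# trial-log CSV I/O
# ---------------------------------------------------------------------------

CSV_COLUMNS = ["subject_id", "session_id", "session_type", "condition_label",
               "trial_index", "tone", "response", "rt", "reinforced_as"]


def write_trial_log(sessions: Iterable[Session], path) -> None:
    """Write sessions as a tidy CSV trial log.

    RTs are in seconds, printed with the shortest representation that
    round-trips exactly, so write -> read reproduces the sessions losslessly.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for s in sessions:
            for tr in s.trials:
                writer.writerow([
                    tr.subject_id, tr.session_id, s.type, s.condition_label,
                    tr.trial_index, tr.tone, tr.response,
                    "" if tr.rt is None else repr(tr.rt), tr.reinforced_as,
                ])


def read_trial_log(path) -> list[Session]:
    """Read and validate a CSV trial log; errors carry line numbers.

    Rejects unknown tone/response labels, RTs outside the response window,
    and sessions whose tone counts violate the baseline/probe design.
    """
    sessions: dict[str, Session] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(CSV_COLUMNS) - set(reader.fieldnames):
            raise TrialLogError(
                f"{path}: header must contain columns {CSV_COLUMNS}")
        for lineno, row in enumerate(reader, start=2):
            try:
                rt = float(row["rt"]) if row["rt"] not in ("", None) else None
                record = TrialRecord(
                    subject_id=row["subject_id"],
                    session_id=row["session_id"],
                    trial_index=int(row["trial_index"]),
                    tone=row["tone"],
                    response=row["response"],
                    rt=rt,
                    reinforced_as=row["reinforced_as"],
                )
            except (TrialLogError, ValueError, KeyError) as exc:
                raise TrialLogError(f"{path}:{lineno}: {exc}") from exc
            stype = row["session_type"]
            if stype not in ("baseline", "probe"):
                raise TrialLogError(f"{path}:{lineno}: unknown session type {stype!r}")
            key = record.session_id
            if key not in sessions:
                sessions[key] = Session(record.subject_id, key, stype,
                                        row["condition_label"])
            sessions[key].trials.append(record)
    for s in sessions.values():
        s.validate()
    return list(sessions.values())
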