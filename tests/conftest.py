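import numpy as np
import pytest
from hypothesis import settings

from driftbias.ddm_core import DDMParams
from driftbias.task_sim import (Session, TrialRecord, default_subject_spec,
                                generate_session)

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def simple_params():
    """Symmetric unit-boundary process with moderate drift."""
    return DDMParams(a=1.0, zr=0.5, v=1.0)


@pytest.fixture(scope="session")
def probe_session():
    """One simulated probe session from a default well-trained subject."""
    spec = default_subject_spec("s01", np.random.default_rng(7))
    return generate_session(spec, "probe", "vehicle", 42)


def make_probe_session(mid_high=40, mid_low=0, mid_omit=0, subject="s01",
                       session_id="constructed", ref_correct=40,
                       ref_wrong=0, rt=1.5):
    """Hand-constructed probe session: reference tones split into
    correct/wrong lever presses, midpoint trials into high/low/omitted."""
    trials = []
    idx = 1

    def add(tone, response, reinforced):
        nonlocal idx
        trials.append(TrialRecord(subject, session_id, idx, tone, response,
                                  rt if response.endswith("lever") else None,
                                  reinforced))
        idx += 1

    for tone, correct in (("high", "high_lever"), ("low", "low_lever")):
        wrong = "low_lever" if correct == "high_lever" else "high_lever"
        for _ in range(ref_correct):
            add(tone, correct, tone)
        for _ in range(ref_wrong):
            add(tone, wrong, tone)
        for _ in range(40 - ref_correct - ref_wrong):
            add(tone, "omission", tone)
    for i in range(mid_high):
        add("midpoint", "high_lever", "high" if i % 2 else "low")
    for i in range(mid_low):
        add("midpoint", "low_lever", "high" if i % 2 else "low")
    for _ in range(mid_omit):
        add("midpoint", "omission", "high")
    for _ in range(40 - mid_high - mid_low - mid_omit):
        add("midpoint", "premature", "high")
    return Session(subject, session_id, "probe", "constructed", trials)
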