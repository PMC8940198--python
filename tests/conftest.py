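import numpy as np
import pytest

from dyadstats import Modality, SessionRecord, SignalEvent


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def make_event(modality, onset, offset, dyad="d1", session="s1", behavior=None):
    default_behavior = {
        Modality.AUDITORY: "vocalization",
        Modality.TACTILE: "touch",
        Modality.VISUAL_MOTHER: "manipulating-object",
        Modality.VISUAL_CHILD_ATTEND: "attending",
    }
    return SignalEvent(
        dyad_id=dyad,
        session_id=session,
        modality=modality,
        behavior=behavior or default_behavior[modality],
        onset=onset,
        offset=offset,
    )


def make_session(events, duration=10.0, dyad="d1", age_point="8mo"):
    return SessionRecord(
        dyad_id=dyad, age_point=age_point, duration=duration, events=list(events)
    )


@pytest.fixture
def simple_log(tmp_path):
    """A well-formed 3-row event log for one session."""
    path = tmp_path / "log.csv"
    path.write_text(
        "dyad,session,behavior,onset,offset\n"
        "d1,s1,vocalization,0.0,2.0\n"
        "d1,s1,touch,1.0,3.0\n"
        "d1,s1,manipulating-object,2.5,4.0\n"
    )
    return path
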