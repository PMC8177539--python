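import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from facs_affect.events_io import AnnotationEvent, ClipRecord  # noqa: E402

EVENT_SORT_KEY = lambda e: (e.video_id, e.onset, e.offset, e.code)  # noqa: E731

CODES = ("AD38", "AU145", "EAD101", "EAD104", "AU25", "AD19", "AU5", "AD1")


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def random_events(rng, n, video="v1", codes=CODES, tmax=30.0, max_dur=3.0):
    """Uniform random event stream for one clip, onset-sorted."""
    events = []
    for _ in range(int(n)):
        onset = float(rng.uniform(0, tmax))
        dur = float(rng.uniform(0, max_dur))
        code = codes[int(rng.integers(len(codes)))]
        events.append(AnnotationEvent(video, code, onset, onset + dur))
    return sorted(events, key=EVENT_SORT_KEY)


def two_condition_clips(n_horses, clips_per_condition=1, group="PRI"):
    """Baseline + transportation clips for n_horses horses."""
    clips = []
    for h in range(n_horses):
        for cond in ("baseline", "transportation"):
            for rep in range(clips_per_condition):
                clips.append(
                    ClipRecord(
                        f"h{h:02d}_{cond}_{rep}", f"h{h:02d}", group, cond,
                        clip_start=150.0, clip_length=30.0,
                    )
                )
    return clips
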