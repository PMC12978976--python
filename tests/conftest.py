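import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from feedkin.channels import JOINT_CHANNELS
from feedkin.recording import MotionRecording
from feedkin.segmentation import detect_cycles, segment_phases
from feedkin.simulate import SimConfig, synth_trial


def recording_from_hand(hand, rate=120.0, mouth=(0.0, 0.0, 0.3),
                        bowl=(0.26, 0.0, 0.0), angles=None):
    """Wrap a hand-position series (n, 3) into a minimal valid recording."""
    hand = np.asarray(hand, dtype=float)
    n = len(hand)
    if angles is None:
        angles = {c: np.zeros(n) for c in JOINT_CHANNELS}
    return MotionRecording(
        participant_id="T00", sex="male", condition="chopsticks",
        sample_rate=rate, time=np.arange(n) / rate, angles=angles,
        hand_pos=hand,
        mouth_pos=np.tile(np.asarray(mouth, float), (n, 1)),
        bowl_pos=np.tile(np.asarray(bowl, float), (n, 1)),
    ).validate()


@pytest.fixture(scope="session")
def clean_trial():
    """One deterministic noise-free trial with ground truth."""
    cfg = SimConfig(seed=11).noise_free()
    return synth_trial(cfg, "chopsticks", "male")


@pytest.fixture(scope="session")
def segmented_trial(clean_trial):
    """(recording, truth, [CycleSegmentation]) for the clean trial."""
    rec, truth = clean_trial
    segs = [segment_phases(rec, c) for c in detect_cycles(rec)]
    return rec, truth, segs
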