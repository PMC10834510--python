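"""Shared fixtures: the fixed-seed synthetic recording and its encodings."""

import pytest
from hypothesis import settings

import cagedepth as cd

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

#: Seed of the packaged synthetic fixture recording.
FIXTURE_SEED = 1234

#: 10 s of 320x240 depth at 15 fps.
FIXTURE_FRAMES = 150
FIXTURE_FPS = 15.0


@pytest.fixture(scope="session")
def fixture_seq():
    """The fixed-seed fixture recording used across codec tests."""
    return cd.simulate_sequence(
        FIXTURE_FRAMES, seed=FIXTURE_SEED, frame_rate=FIXTURE_FPS
    )


@pytest.fixture(scope="session")
def small_seq():
    """A short low-resolution sequence for fast unit round trips."""
    scene = cd.CageScene(depth_dims=(160, 120))
    return cd.simulate_sequence(12, scene=scene, seed=FIXTURE_SEED, frame_rate=15.0)


@pytest.fixture(scope="session")
def encoded_ladder(fixture_seq, tmp_path_factory):
    """The fixture recording encoded at every LSB quality rung.

    Returns ``{rung: (EncodedRecording, QualityReport)}`` with pinned
    encoder settings and the fixed seed, shared across the session.
    """
    out = tmp_path_factory.mktemp("ladder")
    result = {}
    for rung in cd.QUALITY_LADDER:
        rec = cd.encode_sequence(
            fixture_seq,
            cd.EncoderSettings(lsb_quality=rung, frame_rate=FIXTURE_FPS),
            out,
            name=f"fixture_{rung}",
        )
        result[rung] = (rec, cd.verify_recording(fixture_seq, rec))
    return result
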