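import pytest

from flygait import synth, tracking


@pytest.fixture(scope="session")
def small_spec():
    """5-cycle alternating-tripod walk at 250 fps, 20 mm/s."""
    return synth.GaitSpec(period_ms=100.0, duty_factor=0.5, n_cycles=5,
                          fps=250.0, speed_mm_s=20.0)


@pytest.fixture(scope="session")
def small_video(small_spec):
    """Rendered small walk: (stack, truth, render config)."""
    return synth.synthesize(small_spec, seed=1, noise_sigma=0.03)


@pytest.fixture(scope="session")
def small_tracked(small_video):
    """Full tracking pass over the small video: (pattern, body, provenance)."""
    stack, truth, cfg = small_video
    pattern, body, prov = tracking.track_video(stack, n_pre_entry=cfg.n_pre_entry_frames)
    return pattern, body, prov
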