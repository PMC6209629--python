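import numpy as np
import pytest

from erplatency import (
    ComponentSpec,
    GroupAverages,
    LatencyConfig,
    generate_group,
    validate_and_fill,
)


def make_effective(w, **cfg_kwargs):
    """Effective config for a single bare waveform (identity time map)."""
    w = np.asarray(w, dtype=float)
    group = GroupAverages(data=w[None, None, :])
    cfg_kwargs.setdefault("sign", 1)
    return validate_and_fill(LatencyConfig(**cfg_kwargs), group)


@pytest.fixture
def gaussian_group():
    """Noiseless single-Gaussian group: μ=0.5 s, σ=0.05 s, amp 10, 500 Hz."""
    groups, truth = generate_group(
        n_subjects=4,
        components=[ComponentSpec("gaussian", center=0.5, width=0.05, amplitude=10.0)],
        noise_sd=0.0,
        jitter_sd=0.0,
        amplitude_jitter_sd=0.0,
        t_start=0.0,
        t_end=1.0,
        sfreq=500.0,
        n_channels=2,
        seed=11,
    )
    return groups["A"], truth


@pytest.fixture
def noisy_group():
    """Small noisy two-component group for end-to-end paths."""
    groups, truth = generate_group(
        n_subjects=6,
        components=[
            ComponentSpec("gaussian", center=0.17, width=0.02, amplitude=10.0),
            ComponentSpec("gaussian", center=0.60, width=0.12, amplitude=6.0),
        ],
        noise_sd=0.4,
        jitter_sd=0.02,
        t_start=-0.1,
        t_end=1.0,
        sfreq=250.0,
        n_channels=2,
        seed=23,
    )
    return groups["A"], truth
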