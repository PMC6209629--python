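"""Synthetic group data with known ground truth.

Emulates baseline-corrected evoked responses (ERP/ERF averages) composed of
a transient early component and a broad late component, with per-subject
latency jitter, amplitude variation, slow drift, and broadband noise — the
regimes in which the different latency measures succeed or fail.  Every
stage of the library is testable against the recorded truth without any
external recording.

The noise model is deliberately minimal: white Gaussian noise plus a single
half-cosine drift with random phase.  That reproduces the two classic
failure modes — high-frequency noise spikes corrupting peak latency, and
low-frequency drift detaching a late component from the pre-stimulus
baseline — while keeping analytic oracles tractable (no 1/f process).

All randomness flows through one master seed; per-subject substreams are
spawned deterministically from it, so the same seed always yields the same
group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import GroupAverages

__all__ = [
    "ComponentSpec",
    "ConditionSpec",
    "ScenarioPreset",
    "SyntheticTruth",
    "component_waveform",
    "generate_group",
    "scenario_presets",
]


@dataclass(frozen=True)
class ComponentSpec:
    """One evoked component.

    ``shape`` is ``'gaussian'`` (symmetric) or ``'gamma'`` (asymmetric,
    fast rise / slow decay, as real late components often are).  ``center``
    is the peak time, ``width`` the temporal scale (Gaussian σ, or the gamma
    scale parameter), both in seconds; ``amplitude`` is the peak amplitude
    in data units and ``polarity`` ±1.
    """

    shape: str = "gaussian"
    center: float = 0.5
    width: float = 0.05
    amplitude: float = 10.0
    polarity: int = 1

    def __post_init__(self) -> None:
        if self.shape not in ("gaussian", "gamma"):
            raise ValueError(f"shape must be 'gaussian' or 'gamma', got {self.shape!r}")
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.amplitude == 0:
            raise ValueError("amplitude must be non-zero")
        if self.polarity not in (1, -1):
            raise ValueError("polarity must be +1 or -1")


@dataclass(frozen=True)
class ConditionSpec:
    """Per-condition manipulation: a latency shift (s) and an amplitude scale."""

    latency_shift: float = 0.0
    amplitude_scale: float = 1.0


_GAMMA_K = 3.0  # shape parameter of the asymmetric component


def component_waveform(
    spec: ComponentSpec,
    times: np.ndarray,
    center_shift: float = 0.0,
    amplitude_scale: float = 1.0,
) -> np.ndarray:
    """Noise-free waveform of one component, peak-normalised to its amplitude."""
    t = np.asarray(times, dtype=float)
    c = spec.center + center_shift
    a = spec.amplitude * spec.polarity * amplitude_scale
    if spec.shape == "gaussian":
        return a * np.exp(-((t - c) ** 2) / (2.0 * spec.width**2))
    # gamma: mode at (k-1)*theta after onset; normalise so the peak equals a
    k, theta = _GAMMA_K, spec.width
    onset = c - (k - 1) * theta
    x = np.maximum(t - onset, 0.0) / theta
    g = x ** (k - 1) * np.exp(-x)
    g_peak = (k - 1) ** (k - 1) * np.exp(-(k - 1))
    return a * g / g_peak


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a generated group.

    ``centers[cond]`` is Subjects × Components: the true (jittered, shifted)
    peak times; ``amplitudes[cond]`` the true per-subject peak amplitudes.
    """

    seed: int
    components: tuple[ComponentSpec, ...]
    conditions: dict[str, ConditionSpec]
    noise_sd: float
    drift_amplitude: float
    jitter_sd: float
    amplitude_jitter_sd: float
    centers: dict[str, np.ndarray] = field(default_factory=dict)
    amplitudes: dict[str, np.ndarray] = field(default_factory=dict)
    subject_jitter: np.ndarray | None = None


def generate_group(
    n_subjects: int = 16,
    components: tuple[ComponentSpec, ...] | list[ComponentSpec] | None = None,
    conditions: dict[str, ConditionSpec] | None = None,
    *,
    noise_sd: float = 0.5,
    drift_amplitude: float = 0.0,
    jitter_sd: float = 0.03,
    amplitude_jitter_sd: float = 0.1,
    t_start: float = -0.1,
    t_end: float = 1.0,
    sfreq: float = 1000.0,
    n_channels: int = 2,
    seed: int = 0,
) -> tuple[dict[str, GroupAverages], SyntheticTruth]:
    """Generate one :class:`GroupAverages` per condition, plus the truth.

    Each subject's waveform is the sum of the components (with a per-subject
    center jitter ~ Normal(0, ``jitter_sd``), shared across conditions as in
    a within-subject design, and a per-subject amplitude scale
    ~ Normal(1, ``amplitude_jitter_sd``)), plus a half-cosine drift with
    random phase and white Gaussian noise, both drawn independently per
    condition.  The signal is identical across channels; noise is drawn per
    channel (channel averaging then buys the usual √n noise reduction).

    Deterministic for a given ``seed``: per-subject substreams are spawned
    from the master seed, so adding subjects never reshuffles earlier ones.
    """
    if components is None:
        components = (
            ComponentSpec("gaussian", center=0.17, width=0.02, amplitude=10.0),
            ComponentSpec("gaussian", center=0.60, width=0.12, amplitude=6.0),
        )
    components = tuple(components)
    if conditions is None:
        conditions = {"A": ConditionSpec()}

    n_times = int(round((t_end - t_start) * sfreq)) + 1
    times = t_start + np.arange(n_times) / sfreq

    substreams = np.random.SeedSequence(seed).spawn(n_subjects)
    rngs = [np.random.default_rng(ss) for ss in substreams]

    n_comp = len(components)
    jitter = np.array(
        [rng.normal(0.0, jitter_sd, size=n_comp) for rng in rngs]
    )  # subject × component, shared across conditions
    amp_scale = np.array(
        [rng.normal(1.0, amplitude_jitter_sd, size=n_comp) for rng in rngs]
    )

    duration = t_end - t_start
    groups: dict[str, GroupAverages] = {}
    truth = SyntheticTruth(
        seed=seed,
        components=components,
        conditions=dict(conditions),
        noise_sd=noise_sd,
        drift_amplitude=drift_amplitude,
        jitter_sd=jitter_sd,
        amplitude_jitter_sd=amplitude_jitter_sd,
        subject_jitter=jitter,
    )

    for cond_name, cond in conditions.items():
        data = np.empty((n_subjects, n_channels, n_times))
        centers = np.empty((n_subjects, n_comp))
        amps = np.empty((n_subjects, n_comp))
        for s, rng in enumerate(rngs):
            signal = np.zeros(n_times)
            for c, spec in enumerate(components):
                shift = jitter[s, c] + cond.latency_shift
                scale = amp_scale[s, c] * cond.amplitude_scale
                signal += component_waveform(spec, times, shift, scale)
                centers[s, c] = spec.center + shift
                amps[s, c] = spec.amplitude * spec.polarity * scale
            if drift_amplitude:
                phase = rng.uniform(0.0, 2.0 * np.pi)
                signal = signal + drift_amplitude * np.cos(
                    np.pi * (times - t_start) / duration + phase
                )
            noise = rng.normal(0.0, noise_sd, size=(n_channels, n_times))
            data[s] = signal[None, :] + (noise if noise_sd else 0.0)
        groups[cond_name] = GroupAverages(
            data=data,
            subject_ids=list(range(1, n_subjects + 1)),
            channel_names=[f"CH{i + 1}" for i in range(n_channels)],
            time_axis=times,
        )
        truth.centers[cond_name] = centers
        truth.amplitudes[cond_name] = amps

    return groups, truth


@dataclass(frozen=True)
class ScenarioPreset:
    """A named bundle of components and noise settings."""

    components: tuple[ComponentSpec, ...]
    noise_sd: float
    drift_amplitude: float
    jitter_sd: float
    description: str


def scenario_presets() -> dict[str, ScenarioPreset]:
    """Named scenarios covering the canonical latency-measure regimes.

    * ``transient_early`` — narrow component near 170 ms; peak latency works.
    * ``broad_late`` — wide component near 600 ms; peak latency is fragile,
      area latency is the robust choice.
    * ``overlapping_pair`` — both components with overlapping time support;
      a generous area window leaks activity from the neighbour unless the
      area is bounded by on/offsets.
    * ``drifting_baseline`` — broad late component riding on slow drift;
      zero-referenced thresholds and areas are biased unless a counter-peak
      anchor raises the baseline.
    """
    early = ComponentSpec("gaussian", center=0.17, width=0.02, amplitude=10.0)
    late = ComponentSpec("gaussian", center=0.60, width=0.12, amplitude=6.0)
    return {
        "transient_early": ScenarioPreset(
            components=(early,),
            noise_sd=0.5,
            drift_amplitude=0.0,
            jitter_sd=0.01,
            description="narrow ~170 ms component, favourable for peak latency",
        ),
        "broad_late": ScenarioPreset(
            components=(late,),
            noise_sd=0.5,
            drift_amplitude=0.0,
            jitter_sd=0.04,
            description="broad ~600 ms component, noise corrupts peak latency",
        ),
        "overlapping_pair": ScenarioPreset(
            components=(
                ComponentSpec("gaussian", center=0.20, width=0.03, amplitude=8.0),
                ComponentSpec("gaussian", center=0.45, width=0.12, amplitude=6.0),
            ),
            noise_sd=0.5,
            drift_amplitude=0.0,
            jitter_sd=0.02,
            description="adjacent components with overlapping support",
        ),
        "drifting_baseline": ScenarioPreset(
            components=(late,),
            noise_sd=0.5,
            drift_amplitude=2.0,
            jitter_sd=0.04,
            description="broad late component on slow half-cosine drift",
        ),
    }
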