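"""Synthetic paired HQ/LC EEG sessions with known ground truth.

The generator emulates a paired-recording comparison between a laboratory
("HQ") and a portable low-cost ("LC") 14-channel, 128 Hz EEG system.  Both
recordings share identical neural content: Gaussian-windowed evoked
components placed at every stimulus onset of a Go/NoGo (or single-condition)
trial schedule, an alpha-band oscillation whose amplitude envelope carries
tunable long-range temporal correlations, plus per-system 1/f and white
noise.  The LC system's event markers are written *early* relative to the
signal by a constant acquisition delay, reproducing the marker-to-signal
latency of wireless consumer headsets, so the delay is recoverable from the
data as ground truth.

Every generator is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .containers import CHANNELS_14, Recording

__all__ = [
    "TrialSchedule",
    "ErpComponent",
    "ERPTemplate",
    "SystemModel",
    "OscillationSpec",
    "generate_task_schedule",
    "constant_schedule",
    "gonogo_template",
    "semantic_template",
    "fractional_gaussian_noise",
    "lrtc_envelope",
    "generate_lrtc_oscillation",
    "generate_session",
    "generate_resting_session",
]

# ---------------------------------------------------------------------------
# Trial schedules
# ---------------------------------------------------------------------------


@dataclass
class TrialSchedule:
    """Stimulus onsets with condition labels and block membership."""

    onsets_s: np.ndarray
    conditions: np.ndarray
    blocks: np.ndarray
    stimulus_duration_s: float
    trial_duration_s: float

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        self.conditions = np.asarray(self.conditions, dtype=object)
        self.blocks = np.asarray(self.blocks, dtype=int)
        d = np.diff(self.onsets_s)
        if np.any(d <= 0):
            raise ValueError("onsets must be strictly increasing")
        if np.any(d < self.trial_duration_s - 1e-9):
            raise ValueError("consecutive onsets closer than trial_duration")

    @property
    def n_trials(self) -> int:
        return len(self.onsets_s)

    @property
    def end_s(self) -> float:
        return float(self.onsets_s[-1] + self.trial_duration_s)

    def counts(self) -> dict:
        labels, n = np.unique(self.conditions.astype(str), return_counts=True)
        return dict(zip(labels.tolist(), n.tolist()))


def generate_task_schedule(
    n_blocks: int,
    trials_per_block: int,
    p_go: float,
    trial_duration_s: float,
    seed: int,
    *,
    labels: tuple[str, str] = ("Go", "NoGo"),
    stimulus_duration_s: float = 0.2,
    lead_in_s: float = 5.0,
) -> TrialSchedule:
    """Go/NoGo schedule with exact per-block condition counts.

    Each block contains ``round(p_go * trials_per_block)`` trials of the
    first label, the remainder of the second, in an order randomized per
    block by ``seed``.  Trials are back-to-back at ``trial_duration_s``
    spacing, starting after ``lead_in_s`` of task-free signal.
    """
    if n_blocks < 1 or trials_per_block < 1:
        raise ValueError("n_blocks and trials_per_block must be >= 1")
    if not 0.0 < p_go < 1.0:
        raise ValueError(f"p_go must lie strictly in (0, 1), got {p_go}")
    rng = np.random.default_rng(seed)
    n_go = int(np.round(p_go * trials_per_block))
    conditions: list[str] = []
    blocks: list[int] = []
    for b in range(n_blocks):
        block = np.array([labels[0]] * n_go + [labels[1]] * (trials_per_block - n_go),
                         dtype=object)
        rng.shuffle(block)
        conditions.extend(block.tolist())
        blocks.extend([b] * trials_per_block)
    n_total = n_blocks * trials_per_block
    onsets = lead_in_s + np.arange(n_total) * trial_duration_s
    return TrialSchedule(onsets, np.array(conditions, dtype=object),
                         np.array(blocks), stimulus_duration_s, trial_duration_s)


def constant_schedule(
    n_trials: int,
    trial_duration_s: float,
    label: str = "Stim",
    *,
    n_blocks: int = 1,
    stimulus_duration_s: float = 0.8,
    lead_in_s: float = 5.0,
) -> TrialSchedule:
    """Single-condition schedule (e.g. the semantic-association task)."""
    if n_trials < 1 or n_trials % n_blocks:
        raise ValueError("n_trials must be a positive multiple of n_blocks")
    onsets = lead_in_s + np.arange(n_trials) * trial_duration_s
    blocks = np.repeat(np.arange(n_blocks), n_trials // n_blocks)
    return TrialSchedule(onsets, np.array([label] * n_trials, dtype=object),
                         blocks, stimulus_duration_s, trial_duration_s)


# ---------------------------------------------------------------------------
# Evoked templates
# ---------------------------------------------------------------------------

#: Frontal-dominant scalp weighting used for the visual/frontal components.
FRONTAL_WEIGHTS: Mapping[str, float] = {
    "F3": 1.0, "F4": 1.0, "AF3": 0.8, "AF4": 0.8,
    "FC5": 0.6, "FC6": 0.6, "F7": 0.5, "F8": 0.5,
}

#: Occipital-dominant weighting for the alpha source.
OCCIPITAL_WEIGHTS: Mapping[str, float] = {
    "O1": 1.0, "O2": 1.0, "P7": 0.5, "P8": 0.5, "T7": 0.2, "T8": 0.2,
}


@dataclass(frozen=True)
class ErpComponent:
    """One evoked component: a Gaussian-windowed half-wave.

    The waveform is ``polarity * amplitude_uV * exp(-(t - latency)^2 / (2 w^2))``
    scaled per channel by ``channel_weights``, so the ground-truth peak
    latency is exactly ``latency_ms``.
    """

    name: str
    polarity: int
    latency_ms: float
    amplitude_uV: float
    width_ms: float
    channel_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(FRONTAL_WEIGHTS))


@dataclass
class ERPTemplate:
    """A set of components plus per-condition amplitude multipliers."""

    components: tuple[ErpComponent, ...]
    condition_modulation: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    epoch_length_ms: float = 800.0

    def __post_init__(self) -> None:
        for c in self.components:
            if not 0 <= c.latency_ms < self.epoch_length_ms:
                raise ValueError(
                    f"component {c.name} latency {c.latency_ms} outside "
                    f"[0, {self.epoch_length_ms}) ms")

    def component(self, name: str) -> ErpComponent:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    def multiplier(self, condition: str, component: str) -> float:
        return float(self.condition_modulation.get(condition, {}).get(component, 1.0))

    def waveform(self, condition: str, times_ms: np.ndarray,
                 channel: str | None = None) -> np.ndarray:
        """Noise-free evoked time course for one condition.

        With ``channel=None`` the unit-weight (weight 1.0) time course is
        returned; otherwise the per-channel weighting is applied.
        """
        out = np.zeros_like(times_ms, dtype=float)
        for c in self.components:
            w = 1.0 if channel is None else float(c.channel_weights.get(channel, 0.0))
            m = self.multiplier(condition, c.name)
            out += (c.polarity * c.amplitude_uV * m * w
                    * np.exp(-((times_ms - c.latency_ms) ** 2) / (2 * c.width_ms ** 2)))
        return out


def gonogo_template(
    latencies_ms: tuple[float, float, float] = (109.0, 164.0, 256.0),
    *,
    n2_nogo_gain: float = 1.6,
) -> ERPTemplate:
    """Go/NoGo evoked template: N1, P1, and a NoGo-enhanced frontal N2.

    Default latencies are the HQ-system group means for this paradigm; the
    NoGo N2 amplitude multiplier models the response-inhibition effect.
    """
    n1, p1, n2 = latencies_ms
    comps = (
        ErpComponent("N1", -1, n1, 5.0, 15.0),
        ErpComponent("P1", +1, p1, 6.0, 18.0),
        ErpComponent("N2", -1, n2, 4.5, 30.0),
    )
    modulation = {"Go": {"N2": 1.0}, "NoGo": {"N2": n2_nogo_gain}}
    return ERPTemplate(comps, modulation)


def semantic_template(
    latencies_ms: tuple[float, float] = (132.0, 193.0),
) -> ERPTemplate:
    """Early visual N1/P1 template for the picture-association task."""
    n1, p1 = latencies_ms
    comps = (
        ErpComponent("N1", -1, n1, 5.0, 15.0),
        ErpComponent("P1", +1, p1, 6.0, 18.0),
    )
    return ERPTemplate(comps)


# ---------------------------------------------------------------------------
# Acquisition system models and oscillation specs
# ---------------------------------------------------------------------------


@dataclass
class SystemModel:
    """Noise and marker-timing model of one acquisition system.

    ``marker_delay_ms`` models the wireless acquisition latency: the event
    marker is written that many milliseconds *before* the corresponding
    neural response appears in the recorded stream, so epochs locked to the
    marker show the evoked components late by the same amount.

    ``clock_drift_ppm`` models the asynchrony between the stimulus
    computer's clock and the amplifier's sampling clock.  Stimulus-clock
    onset times are stretched by ``1 + drift*1e-6`` before being mapped to
    samples, so a schedule with an exactly periodic trial spacing still
    sweeps through every sampling phase over a session — as real
    asynchronous clocks do — instead of pinning every onset to one phase
    of the 7.8 ms sample grid.
    """

    name: str
    marker_delay_ms: float = 0.0
    noise_sd_uV: float = 15.0
    pink_sd_uV: float = 5.0
    jitter_sd_ms: float = 0.0
    clock_drift_ppm: float = 50.0
    acquisition_band_hz: tuple[float, float] | None = (0.5, 40.0)
    n_channels: int = 14
    fs_hz: float = 128.0

    def __post_init__(self) -> None:
        if self.marker_delay_ms < 0:
            raise ValueError("marker_delay_ms must be >= 0")
        if self.noise_sd_uV < 0 or self.pink_sd_uV < 0:
            raise ValueError("noise scales must be >= 0")
        if self.acquisition_band_hz is not None:
            lo, hi = self.acquisition_band_hz
            if not 0 < lo < hi < self.fs_hz / 2:
                raise ValueError(
                    f"acquisition band {self.acquisition_band_hz} invalid "
                    f"at fs={self.fs_hz}")


@dataclass
class OscillationSpec:
    """Band-limited oscillation with a long-range correlated envelope."""

    band_hz: tuple[float, float] = (8.0, 12.0)
    hurst: float = 0.75
    mean_amplitude_uV: float = 10.0
    duration_s: float = 300.0
    modulation_depth: float = 0.3
    channel_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(OCCIPITAL_WEIGHTS))

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not 0 < lo < hi:
            raise ValueError(f"invalid band {self.band_hz}")
        if not 0.5 <= self.hurst < 1.0:
            raise ValueError(f"hurst must lie in [0.5, 1.0), got {self.hurst}")
        if self.duration_s < 10.0:
            raise ValueError("duration must be >= 10 s")


# ---------------------------------------------------------------------------
# Noise and oscillation synthesis
# ---------------------------------------------------------------------------


def fractional_gaussian_noise(n: int, hurst: float,
                              rng: np.random.Generator) -> np.ndarray:
    """Unit-variance fGn by spectral synthesis.

    White Gaussian noise is shaped in the frequency domain with amplitude
    ``f ** (-(2H - 1) / 2)`` (power spectrum ``f ** (1 - 2H)``), which gives
    a stationary series whose detrended-fluctuation exponent equals the
    Hurst exponent ``H``.  The DC bin is zeroed.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-(2.0 * hurst - 1.0) / 2.0)
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def lrtc_envelope(spec: OscillationSpec, fs: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Positive amplitude envelope with the requested Hurst exponent.

    The envelope is an affine transform of fractional Gaussian noise,
    ``mean * (1 + depth * z)``, floored at 5% of the mean.  With the default
    depth of 0.3 the floor is hit only beyond -3.2 sd, so the correlation
    structure (and hence the scaling exponent) of the fGn is preserved.

    The fGn is low-passed at half the oscillation bandwidth before the
    transform: a band-limited oscillation physically cannot carry envelope
    fluctuations faster than its bandwidth, and unfiltered fGn would spread
    sideband power outside the band.  The smoothing acts well below the
    seconds-scale windows DFA analyses, so the scaling exponent at those
    scales is unchanged.
    """
    from scipy.signal import butter, sosfiltfilt

    n = int(round(spec.duration_s * fs))
    z = fractional_gaussian_noise(n, spec.hurst, rng)
    half_bw = (spec.band_hz[1] - spec.band_hz[0]) / 2.0
    sos = butter(4, half_bw, btype="lowpass", fs=fs, output="sos")
    z = sosfiltfilt(sos, z)
    sd = z.std()
    if sd > 0:
        z = z / sd
    env = spec.mean_amplitude_uV * (1.0 + spec.modulation_depth * z)
    return np.maximum(env, 0.05 * spec.mean_amplitude_uV)


def _unit_band_carrier(n: int, band_hz: tuple[float, float], fs: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Band-limited oscillation with wandering phase and unit envelope.

    White noise is restricted to the band in the frequency domain and then
    divided by its own Hilbert envelope, leaving a constant-amplitude
    oscillation whose instantaneous frequency drifts inside the band (as
    real alpha does — a fixed-frequency sinusoid would stay phase-locked
    to any periodic trial schedule and would not average out of ERPs).
    """
    from scipy.signal import hilbert

    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    out_of_band = (f < band_hz[0]) | (f > band_hz[1])
    spec[out_of_band] = 0.0
    x = np.fft.irfft(spec, n)
    # envelope normalisation re-broadens the spectrum slightly; alternating
    # normalise/band-limit a few times converges to a near-unit envelope
    # with ~98% of power inside the band
    for _ in range(3):
        amp = np.abs(hilbert(x))
        x = x / np.maximum(amp, 1e-12 * amp.max())
        s = np.fft.rfft(x)
        s[out_of_band] = 0.0
        x = np.fft.irfft(s, n)
    amp = np.abs(hilbert(x))
    return x / np.maximum(amp, 1e-12 * amp.max())


def generate_lrtc_oscillation(spec: OscillationSpec, fs: float,
                              seed: int | np.random.Generator) -> np.ndarray:
    """Amplitude-modulated alpha-band oscillation.

    A narrowband unit-envelope carrier (see :func:`_unit_band_carrier`) is
    multiplied by the long-range correlated envelope from
    :func:`lrtc_envelope`, so the Hilbert envelope of the output recovers
    (up to edge effects) an envelope whose DFA exponent equals
    ``spec.hurst``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo, hi = spec.band_hz
    if hi >= fs / 2:
        raise ValueError(f"band {spec.band_hz} exceeds Nyquist at fs={fs}")
    env = lrtc_envelope(spec, fs, rng)
    carrier = _unit_band_carrier(len(env), spec.band_hz, fs, rng)
    return env * carrier


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise by spectral shaping (power exponent 1)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** -0.5
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x / sd if sd > 0 else x


# ---------------------------------------------------------------------------
# Session assembly
# ---------------------------------------------------------------------------


def _evoked_matrix(onsets_s: np.ndarray, conditions: np.ndarray,
                   template: ERPTemplate, channels: Sequence[str], fs: float,
                   n: int) -> np.ndarray:
    """Sum of Gaussian components at every onset, per channel."""
    out = np.zeros((len(channels), n))
    weights = {
        c.name: np.array([c.channel_weights.get(ch, 0.0) for ch in channels])
        for c in template.components
    }
    for onset, cond in zip(onsets_s, conditions):
        onset_idx = onset * fs
        for c in template.components:
            m = template.multiplier(str(cond), c.name)
            w_samples = c.width_ms / 1000.0 * fs
            centre = onset_idx + c.latency_ms / 1000.0 * fs
            lo = max(0, int(np.floor(centre - 6 * w_samples)))
            hi = min(n, int(np.ceil(centre + 6 * w_samples)) + 1)
            if lo >= hi:
                continue
            k = np.arange(lo, hi)
            pulse = (c.polarity * c.amplitude_uV * m
                     * np.exp(-((k - centre) ** 2) / (2 * w_samples ** 2)))
            out[:, lo:hi] += weights[c.name][:, None] * pulse[None, :]
    return out


def _background(system: SystemModel, n: int, n_ch: int,
                rng: np.random.Generator) -> np.ndarray:
    noise = np.zeros((n_ch, n))
    for ch in range(n_ch):
        if system.pink_sd_uV > 0:
            noise[ch] += system.pink_sd_uV * pink_noise(n, rng)
        if system.noise_sd_uV > 0:
            noise[ch] += system.noise_sd_uV * rng.standard_normal(n)
    return noise


def _acquire(signal: np.ndarray, system: SystemModel) -> np.ndarray:
    """Apply the system's acquisition band-pass (zero-phase, order 4)."""
    if system.acquisition_band_hz is None:
        return signal
    from scipy.signal import butter, sosfiltfilt

    sos = butter(4, system.acquisition_band_hz, btype="bandpass",
                 fs=system.fs_hz, output="sos")
    return sosfiltfilt(sos, signal, axis=-1)


def _marker_samples(onsets_s: np.ndarray, system: SystemModel, fs: float,
                    rng: np.random.Generator) -> np.ndarray:
    delays_ms = np.full(len(onsets_s), system.marker_delay_ms)
    if system.jitter_sd_ms > 0:
        delays_ms = delays_ms + rng.normal(0.0, system.jitter_sd_ms,
                                           len(onsets_s))
    return np.round((onsets_s - delays_ms / 1000.0) * fs).astype(int)


def generate_session(
    schedule: TrialSchedule,
    template: ERPTemplate,
    oscillation: OscillationSpec | None,
    systems: Sequence[SystemModel],
    seed: int,
    *,
    duration_s: float | None = None,
    channels: Sequence[str] = CHANNELS_14,
) -> dict[str, Recording]:
    """Paired recordings of one task session.

    All systems share identical neural content (evoked responses + alpha
    oscillation); each system adds its own noise and applies its own marker
    delay.  Returns a mapping from system name to :class:`Recording`.
    """
    fs = float(systems[0].fs_hz)
    if any(s.fs_hz != fs for s in systems):
        raise ValueError("all systems must share one sampling rate")
    if duration_s is None:
        duration_s = (oscillation.duration_s if oscillation is not None
                      else schedule.end_s + 5.0)
    if duration_s < schedule.end_s:
        raise ValueError(
            f"schedule ends at {schedule.end_s:.1f} s but the recording is "
            f"only {duration_s:.1f} s long")
    n = int(round(duration_s * fs))

    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF])
    rng_shared, *rng_sys = [np.random.default_rng(s)
                            for s in ss.spawn(1 + len(systems))]

    # stimulus-clock onsets mapped into amplifier time: a constant relative
    # clock drift sweeps onsets across sampling phases over the session
    drift = 1.0 + systems[0].clock_drift_ppm * 1e-6
    onsets_eeg_s = schedule.onsets_s * drift

    neural = _evoked_matrix(onsets_eeg_s, schedule.conditions, template,
                            channels, fs, n)
    if oscillation is not None and oscillation.mean_amplitude_uV > 0:
        if oscillation.duration_s * fs < n:
            raise ValueError("oscillation shorter than the session")
        alpha = generate_lrtc_oscillation(oscillation, fs, rng_shared)[:n]
        w = np.array([oscillation.channel_weights.get(ch, 0.0) for ch in channels])
        neural = neural + w[:, None] * alpha[None, :]

    out: dict[str, Recording] = {}
    for system, rng in zip(systems, rng_sys):
        signal = _acquire(neural + _background(system, n, len(channels), rng),
                          system)
        markers = _marker_samples(onsets_eeg_s, system, fs, rng)
        if markers.min() < 0:
            raise ValueError(
                "marker delay pushes events before the recording start; "
                "increase the schedule lead-in")
        events = [(int(m), str(c)) for m, c in zip(markers, schedule.conditions)]
        out[system.name] = Recording(
            signal, fs, tuple(channels), events, reference="raw",
            meta={"system": system.name, "marker_delay_ms": system.marker_delay_ms,
                  "seed": int(seed)},
        )
    return out


def generate_resting_session(
    oscillation: OscillationSpec,
    systems: Sequence[SystemModel],
    seed: int,
    *,
    channels: Sequence[str] = CHANNELS_14,
) -> dict[str, Recording]:
    """Paired task-free recordings: shared alpha source plus per-system noise."""
    fs = float(systems[0].fs_hz)
    if any(s.fs_hz != fs for s in systems):
        raise ValueError("all systems must share one sampling rate")
    n = int(round(oscillation.duration_s * fs))
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF])
    rng_shared, *rng_sys = [np.random.default_rng(s)
                            for s in ss.spawn(1 + len(systems))]
    alpha = generate_lrtc_oscillation(oscillation, fs, rng_shared)
    w = np.array([oscillation.channel_weights.get(ch, 0.0) for ch in channels])
    neural = w[:, None] * alpha[None, :]
    out: dict[str, Recording] = {}
    for system, rng in zip(systems, rng_sys):
        signal = _acquire(neural + _background(system, n, len(channels), rng),
                          system)
        out[system.name] = Recording(
            signal, fs, tuple(channels), [], reference="raw",
            meta={"system": system.name, "condition": "resting", "seed": int(seed)})
    return out
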