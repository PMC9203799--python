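"""Spike, burst and power-spectrum quantification of simulated potentials.

The pipeline mirrors how seizure simulations are usually scored: threshold
crossings give spike trains, gap-based segmentation gives bursts, Welch's
method gives the power spectral density, and an ordinary least-squares fit of
log10 power against log10 frequency in a chosen band gives the power-law
exponent beta of a p ~ f^-beta spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

__all__ = [
    "ProbeTrace",
    "SpikeTrain",
    "Burst",
    "PowerLawFit",
    "count_spikes",
    "detect_bursts",
    "welch_psd",
    "default_segment_length",
    "fit_power_law",
    "synth_powerlaw_trace",
]

_UNIFORMITY_RTOL = 1e-9


@dataclass
class ProbeTrace:
    """A uniformly sampled potential time series at one probe.

    times are in ms, values in mV; `label` identifies the probe and the field
    (transmembrane v or extracellular u_e).
    """

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if len(self.times) < 2:
            raise ValueError("a trace needs at least two samples")
        dts = np.diff(self.times)
        if np.any(dts <= 0):
            raise ValueError("times must be strictly increasing")
        self._dt = float(np.mean(dts))
        if np.max(np.abs(dts - self._dt)) > _UNIFORMITY_RTOL * max(self._dt, 1.0):
            raise ValueError("trace is not uniformly sampled")

    @property
    def dt_ms(self) -> float:
        return self._dt

    @property
    def sample_rate(self) -> float:
        """Sampling rate in Hz."""
        return 1000.0 / self._dt

    def window(self, t0_ms: float, t1_ms: float) -> "ProbeTrace":
        """Sub-trace restricted to times in [t0_ms, t1_ms]."""
        m = (self.times >= t0_ms) & (self.times <= t1_ms)
        return ProbeTrace(self.times[m], self.values[m], self.label)


@dataclass
class SpikeTrain:
    spike_times: np.ndarray  # ms, strictly increasing
    threshold: float  # mV
    refractory: float  # ms

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if len(self.spike_times) > 1:
            gaps = np.diff(self.spike_times)
            if np.any(gaps <= 0):
                raise ValueError("spike times must be strictly increasing")
            if np.any(gaps < self.refractory):
                raise ValueError("spikes closer than the refractory period")

    def __len__(self) -> int:
        return len(self.spike_times)


@dataclass(frozen=True)
class Burst:
    onset: float  # ms, first spike
    offset: float  # ms, last spike
    n_spikes: int

    @property
    def duration(self) -> float:
        """Burst duration first-to-last spike, ms."""
        return self.offset - self.onset


@dataclass(frozen=True)
class PowerLawFit:
    """Descriptor of a fitted p ~ f^-beta spectrum over [f_min, f_max]."""

    beta: float  # positive for decaying spectra
    intercept: float  # log10 power extrapolated to 1 Hz
    f_min: float
    f_max: float
    r_squared: float


def count_spikes(
    trace: ProbeTrace, threshold: float = -20.0, refractory: float = 2.0
) -> SpikeTrain:
    """Detect spikes as upward threshold crossings with a refractory period.

    A spike occurs at sample i when value[i-1] < threshold <= value[i] and at
    least `refractory` ms have passed since the previous accepted spike.
    """
    if refractory < 0:
        raise ValueError("refractory must be nonnegative")
    v = trace.values
    idx = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold)) + 1
    times = trace.times[idx]
    accepted: list[float] = []
    last = -np.inf
    for t in times:
        if t - last >= refractory:
            accepted.append(t)
            last = t
    return SpikeTrain(np.array(accepted), threshold, refractory)


def adaptive_threshold(trace: ProbeTrace) -> float:
    """Midrange between the 1st and 99th percentile; for u_e-like traces with
    unknown baseline."""
    lo, hi = np.percentile(trace.values, [1.0, 99.0])
    return 0.5 * (lo + hi)


def detect_bursts(
    train: SpikeTrain, max_gap: float = 500.0, min_spikes: int = 10
) -> list[Burst]:
    """Segment a spike train into bursts.

    A burst is a maximal run of spikes whose consecutive gaps are all
    <= `max_gap` ms, containing at least `min_spikes` spikes.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    if min_spikes < 2:
        raise ValueError("min_spikes must be at least 2")
    st = train.spike_times
    if len(st) == 0:
        return []
    breaks = np.flatnonzero(np.diff(st) > max_gap)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(st) - 1]))
    return [
        Burst(onset=float(st[a]), offset=float(st[b]), n_spikes=int(b - a + 1))
        for a, b in zip(starts, ends)
        if b - a + 1 >= min_spikes
    ]


def default_segment_length(n_samples: int, cap: int = 2 ** 16) -> int:
    """Welch segment length: the largest power of two <= n_samples/4, capped."""
    target = max(n_samples // 4, 2)
    return min(2 ** int(np.floor(np.log2(target))), cap, n_samples)


def welch_psd(
    trace: ProbeTrace,
    segment_length: int | None = None,
    overlap_fraction: float = 0.5,
    window: str = "hann",
    detrend: str = "linear",
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch power spectral density of a probe trace.

    Returns (frequencies [Hz], power density [mV^2/Hz]); frequency grid runs
    from 0 to the Nyquist rate.
    """
    n = len(trace.values)
    if segment_length is None:
        segment_length = default_segment_length(n)
    if segment_length > n:
        raise ValueError("trace shorter than one Welch segment")
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")
    freqs, power = _signal.welch(
        trace.values,
        fs=trace.sample_rate,
        window=window,
        nperseg=segment_length,
        noverlap=int(round(overlap_fraction * segment_length)),
        detrend=detrend,
        return_onesided=True,
    )
    return freqs, power


def fit_power_law(
    frequencies: np.ndarray,
    power: np.ndarray,
    f_min: float,
    f_max: float,
) -> PowerLawFit:
    """OLS fit of log10(power) on log10(frequency) restricted to [f_min, f_max].

    beta is minus the slope, so beta > 0 describes a decaying spectrum.
    """
    if not f_min < f_max:
        raise ValueError("f_min must be below f_max")
    frequencies = np.asarray(frequencies, dtype=float)
    power = np.asarray(power, dtype=float)
    band = (frequencies >= f_min) & (frequencies <= f_max)
    if band.sum() < 5:
        raise ValueError("fewer than 5 frequency bins in the fit band")
    if np.any(power[band] <= 0):
        raise ValueError("nonpositive power inside the fit band")
    x = np.log10(frequencies[band])
    y = np.log10(power[band])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(
        beta=float(-slope),
        intercept=float(intercept),
        f_min=float(f_min),
        f_max=float(f_max),
        r_squared=r2,
    )


def synth_powerlaw_trace(
    beta: float,
    duration_ms: float,
    sample_rate: float,
    seed: int,
    label: str = "synthetic",
) -> ProbeTrace:
    """Gaussian random-phase signal with expected PSD proportional to f^-beta.

    Spectral synthesis: Fourier amplitudes drawn proportional to f^(-beta/2)
    with seeded random phases, then inverse-transformed to a real signal.
    Deterministic for a given seed.
    """
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    if duration_ms <= 0 or sample_rate <= 0:
        raise ValueError("duration and sample rate must be positive")
    n = int(round(duration_ms / 1000.0 * sample_rate))
    if n < 2:
        raise ValueError("duration too short for the sample rate")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    re = rng.standard_normal(len(freqs))
    im = rng.standard_normal(len(freqs))
    spectrum = amp * (re + 1j * im)
    spectrum[0] = 0.0
    values = np.fft.irfft(spectrum, n=n)
    values /= max(np.std(values), np.finfo(float).tiny)
    dt_ms = 1000.0 / sample_rate
    times = np.arange(n) * dt_ms
    return ProbeTrace(times, values, label=label)
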