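"""Spiking, calcium-indicator fluorescence, and linear mixing.

Neurons spike as independent Bernoulli processes at a configurable mean
rate; spike trains are convolved with a unit-peak GCaMP6f impulse response
(linear rise to ``t_peak`` = 0.14 s, exponential decay with half-life
``t_half`` = 0.32 s), simulated at 100 steps/s and block-averaged down to
the recording frame rate. Fiber signals are the static linear mixture
``Y = M X`` through the bundle's mixing matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from . import _kernels
from .bundle import MixingMatrix

__all__ = [
    "IndicatorKernel",
    "SpikeMatrix",
    "TraceMatrix",
    "gcamp_kernel",
    "simulate_spike_trains",
    "sample_spike_events",
    "convolve_and_frame",
    "frames_from_events",
    "mix_traces",
]

DT_DEFAULT = 0.01          # s, simulation time step (100 steps/s)
T_PEAK_DEFAULT = 0.14      # s, GCaMP6f rise time
T_HALF_DEFAULT = 0.32      # s, GCaMP6f decay half-life
RATE_DEFAULT = 0.4         # Hz, mean spiking rate
FRAME_RATE_DEFAULT = 20.0  # Hz, recording frame rate


@dataclass(frozen=True)
class IndicatorKernel:
    """Unit-peak fluorescence impulse response sampled at ``dt``."""

    t_peak: float
    t_half: float
    dt: float
    samples: np.ndarray

    def __len__(self) -> int:
        return self.samples.size

    def framed(self, frame_rate: float) -> np.ndarray:
        """Kernel block-averaged to ``frame_rate`` (phase-0 event)."""
        return framed_polyphase(self, frame_rate)[0]


@dataclass
class SpikeMatrix:
    """Binary spike indicator per source per ``dt`` bin."""

    values: np.ndarray  # (n_sources, n_bins) of {0, 1}
    rate: float
    duration: float
    dt: float
    seed: int

    @property
    def n_sources(self) -> int:
        return self.values.shape[0]


@dataclass
class TraceMatrix:
    """Time-sampled signals, one row per source or fiber."""

    values: np.ndarray  # (n_traces, n_frames)
    frame_rate: float
    role: str = ""      # "neural" (x_j), "fiber" (y_i), "deconvolved" (z_i),
                        # "separated"
    meta: dict = field(default_factory=dict)

    @property
    def n_traces(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


def gcamp_kernel(t_peak: float = T_PEAK_DEFAULT, t_half: float = T_HALF_DEFAULT,
                 dt: float = DT_DEFAULT, length: float = 3.0,
                 rise: str = "linear") -> IndicatorKernel:
    """Unit-peak indicator waveform.

    Linear ramp 0 -> 1 over [0, t_peak] (``rise="exp"`` substitutes a
    saturating-exponential ramp normalized to the same peak), then
    exponential decay with time constant t_half / ln 2.
    """
    if not 0 < dt <= t_peak:
        raise ValueError("need 0 < dt <= t_peak")
    if length <= t_peak:
        raise ValueError("kernel length must exceed t_peak")
    t = np.arange(0.0, length, dt)
    w = np.empty_like(t)
    rising = t <= t_peak
    if rise == "linear":
        w[rising] = t[rising] / t_peak
    elif rise == "exp":
        tau_r = t_peak / 3.0
        w[rising] = (1 - np.exp(-t[rising] / tau_r)) / (1 - math.exp(-t_peak / tau_r))
    else:
        raise ValueError("rise must be 'linear' or 'exp'")
    tau_d = t_half / math.log(2.0)
    w[~rising] = np.exp(-(t[~rising] - t_peak) / tau_d)
    return IndicatorKernel(t_peak=t_peak, t_half=t_half, dt=dt, samples=w)


def simulate_spike_trains(n_sources: int, rate: float, duration: float,
                          dt: float = DT_DEFAULT, seed: int = 0) -> SpikeMatrix:
    """Independent Bernoulli(rate*dt) spike trains, one row per source."""
    p = rate * dt
    if p > 1:
        raise ValueError(f"rate*dt = {p} exceeds 1; reduce rate or dt")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if rate < 0:
        raise ValueError("rate must be non-negative")
    n_bins = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    vals = (rng.random((n_sources, n_bins)) < p).astype(np.uint8)
    return SpikeMatrix(values=vals, rate=rate, duration=duration, dt=dt,
                       seed=int(seed))


def sample_spike_events(n_sources: int, rate: float, duration: float,
                        dt: float, rng: np.random.Generator
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Sparse, exact Bernoulli spike events for large populations.

    Returns (source_index, bin_index) arrays. Equivalent in distribution to
    ``simulate_spike_trains`` but sampled via geometric inter-success gaps
    over the flattened (source-major) trial sequence, so memory scales with
    the number of spikes, not sources x bins.
    """
    p = rate * dt
    if p > 1:
        raise ValueError(f"rate*dt = {p} exceeds 1; reduce rate or dt")
    n_bins = int(round(duration / dt))
    n_trials = n_sources * n_bins
    if p <= 0 or n_trials == 0:
        return (np.empty(0, dtype=np.int64),) * 2
    out = []
    pos = -1
    remaining = n_trials
    while remaining > 0:
        expect = max(16, int(remaining * p + 6 * math.sqrt(remaining * p) + 16))
        gaps = rng.geometric(p, size=expect)
        idx = pos + np.cumsum(gaps)
        take = idx[idx < n_trials]
        out.append(take)
        if idx.size and idx[-1] >= n_trials:
            break
        pos = int(idx[-1]) if idx.size else pos
        remaining = n_trials - 1 - pos
    flat = np.concatenate(out) if out else np.empty(0, dtype=np.int64)
    return flat // n_bins, flat % n_bins


def convolve_and_frame(spikes: SpikeMatrix, kernel: IndicatorKernel,
                       frame_rate: float = FRAME_RATE_DEFAULT) -> TraceMatrix:
    """Causal convolution with the indicator, then block-mean framing."""
    decim = _decimation(kernel.dt, frame_rate)
    x = sps.fftconvolve(spikes.values.astype(np.float64),
                        kernel.samples[None, :], axes=1)
    x = x[:, :spikes.values.shape[1]]
    n_frames = x.shape[1] // decim
    x = x[:, :n_frames * decim].reshape(x.shape[0], n_frames, decim).mean(axis=2)
    np.maximum(x, 0.0, out=x)  # clear convolution round-off
    return TraceMatrix(values=x, frame_rate=frame_rate, role="neural",
                       meta={"rate": spikes.rate, "seed": spikes.seed})


def _decimation(dt: float, frame_rate: float) -> int:
    steps_per_s = 1.0 / dt
    decim = steps_per_s / frame_rate
    if frame_rate > steps_per_s + 1e-9 or abs(decim - round(decim)) > 1e-9:
        raise ValueError(
            f"frame rate {frame_rate} Hz must evenly divide {steps_per_s} Hz")
    return int(round(decim))


def framed_polyphase(kernel: IndicatorKernel, frame_rate: float) -> np.ndarray:
    """Framed kernel for every sub-frame spike phase.

    Row ``ph`` is the block-mean-framed fluorescence of a unit spike landing
    ``ph`` simulation steps into its frame; adding row ``ph`` at the event's
    frame reproduces convolve-then-frame exactly.
    """
    decim = _decimation(kernel.dt, frame_rate)
    w = kernel.samples
    n_frames = (decim - 1 + w.size + decim - 1) // decim
    poly = np.zeros((decim, n_frames))
    for ph in range(decim):
        pad = np.zeros(n_frames * decim)
        pad[ph:ph + w.size] = w
        poly[ph] = pad.reshape(n_frames, decim).mean(axis=1)
    return poly


def frames_from_events(src_idx: np.ndarray, bin_idx: np.ndarray,
                       n_sources: int, n_bins: int,
                       kernel: IndicatorKernel,
                       frame_rate: float = FRAME_RATE_DEFAULT,
                       dtype=np.float64) -> TraceMatrix:
    """Framed fluorescence traces built directly from sparse spike events.

    Exactly equals ``convolve_and_frame`` of the dense spike matrix, at a
    cost proportional to the number of spikes.
    """
    decim = _decimation(kernel.dt, frame_rate)
    n_frames = n_bins // decim
    poly = framed_polyphase(kernel, frame_rate)
    out = np.zeros((n_sources, n_frames), dtype=np.float64)
    _kernels.add_framed_events(np.ascontiguousarray(src_idx, dtype=np.int64),
                               np.ascontiguousarray(bin_idx // decim,
                                                    dtype=np.int64),
                               np.ascontiguousarray(bin_idx % decim,
                                                    dtype=np.int64),
                               poly, out)
    return TraceMatrix(values=out.astype(dtype, copy=False),
                       frame_rate=frame_rate, role="neural")


def mix_traces(mixing, traces: TraceMatrix) -> TraceMatrix:
    """Fiber signals Y = M X (exact linear mixing; excitation is static)."""
    M = mixing.M if isinstance(mixing, MixingMatrix) else np.asarray(mixing)
    X = traces.values
    if M.shape[1] != X.shape[0]:
        raise ValueError(f"mixing matrix has {M.shape[1]} columns but "
                         f"{X.shape[0]} source traces were given")
    return TraceMatrix(values=M @ X, frame_rate=traces.frame_rate,
                       role="fiber", meta=dict(traces.meta))
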