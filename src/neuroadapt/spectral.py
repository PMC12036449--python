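"""Time–frequency decomposition and band-limited analytic amplitude.

Two complementary decompositions are provided:

* a complex Morlet transform over a 50-bin logarithmic frequency grid
  (4–150 Hz) with cycle counts increasing logarithmically from 4 at the
  lowest frequency to 9 at the highest — the full-spectrum view used for
  time–frequency statistic maps; and
* the Hilbert analytic amplitude (HAA) of a named band, obtained by
  splitting the band into eight logarithmically spaced sub-bands, filtering
  each with a unit-energy Gabor filter of fractional bandwidth 0.25, taking
  the analytic-signal magnitude, and averaging across sub-bands.  Averaging
  sub-band envelopes yields a stabler broadband power estimate than one wide
  filter because power is non-uniform across the band.

Event-locked epoching slices continuous decompositions into
time × frequency × trial (or time × trial) arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from mne.time_frequency import tfr_array_morlet
from scipy.signal import fftconvolve

__all__ = [
    "FreqGrid",
    "MorletSpec",
    "TFMap",
    "BandEnvelope",
    "BANDS",
    "log_freq_grid",
    "morlet_cycles",
    "morlet_tfr",
    "gabor_kernel",
    "gabor_haa",
    "epoch_signal",
    "epoch_envelope",
]

#: canonical analysis bands, Hz
BANDS = {"theta": (4.0, 9.0), "high_gamma": (70.0, 150.0)}


@dataclass(frozen=True)
class FreqGrid:
    """Logarithmically (geometrically) spaced frequency grid."""

    f_min: float = 4.0
    f_max: float = 150.0
    n_bins: int = 50
    values: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not (0 < self.f_min < self.f_max) or self.n_bins < 2:
            raise ValueError("need 0 < f_min < f_max and n_bins >= 2")
        object.__setattr__(
            self, "values", np.geomspace(self.f_min, self.f_max, self.n_bins)
        )

    @property
    def ratio(self) -> float:
        """Constant ratio between adjacent bins."""
        return (self.f_max / self.f_min) ** (1.0 / (self.n_bins - 1))

    def bin_widths_hz(self) -> np.ndarray:
        """Geometric local bin widths Δf_i = f_i (r^1/2 − r^−1/2)."""
        r = self.ratio
        return self.values * (np.sqrt(r) - 1.0 / np.sqrt(r))


def log_freq_grid(f_min: float = 4.0, f_max: float = 150.0, n_bins: int = 50) -> FreqGrid:
    """The standard analysis grid: f_i = f_min (f_max/f_min)^(i/(n-1))."""
    return FreqGrid(f_min, f_max, n_bins)


@dataclass(frozen=True)
class MorletSpec:
    """Morlet grid plus per-frequency cycle counts (log-spaced 4 → 9)."""

    grid: FreqGrid = field(default_factory=FreqGrid)
    cycles_min: float = 4.0
    cycles_max: float = 9.0

    @property
    def cycles(self) -> np.ndarray:
        return morlet_cycles(self.grid, self.cycles_min, self.cycles_max)


def morlet_cycles(grid: FreqGrid, c_min: float = 4.0, c_max: float = 9.0) -> np.ndarray:
    """Cycle counts increasing logarithmically with frequency.

    Geometric interpolation in log-frequency: exactly ``c_min`` at the lowest
    and ``c_max`` at the highest grid frequency.
    """
    logf = np.log(grid.values)
    frac = (logf - logf[0]) / (logf[-1] - logf[0])
    return c_min * (c_max / c_min) ** frac


@dataclass
class TFMap:
    """Epoched time–frequency data: (trials, freqs, times) power/phase."""

    power: np.ndarray            # (n_trials, n_freqs, n_times)
    phase: np.ndarray | None
    times: np.ndarray            # s relative to event
    grid: FreqGrid
    events: object = None        # per-trial metadata table

    @property
    def shape(self):
        return self.power.shape


@dataclass
class BandEnvelope:
    """Band-limited analytic amplitude: continuous trace or epochs."""

    amplitude: np.ndarray        # (n_times,) continuous or (n_trials, n_times)
    band: tuple
    fs: float
    times: np.ndarray | None = None
    events: object = None


def morlet_tfr(signal: np.ndarray, fs: float, spec: MorletSpec | None = None,
               output: str = "power_phase"):
    """Complex-Morlet decomposition of a continuous single-channel signal.

    Returns ``(power, phase)`` arrays of shape (n_freqs, n_times); power is
    the squared modulus of the analytic coefficient.
    """
    if spec is None:
        spec = MorletSpec()
    freqs = spec.grid.values
    if fs < 2 * freqs[-1]:
        raise ValueError(f"fs={fs} below Nyquist for f_max={freqs[-1]}")
    signal = np.asarray(signal, float)
    data = signal[np.newaxis, np.newaxis, :]
    tfr = tfr_array_morlet(
        data, sfreq=fs, freqs=freqs, n_cycles=spec.cycles,
        output="complex", zero_mean=True, verbose="error",
    )[0, 0]
    if tfr.ndim == 3:  # (n_tapers, n_freqs, n_times) in some versions
        tfr = tfr[0]
    power = np.abs(tfr) ** 2
    if output == "power":
        return power
    phase = np.angle(tfr)
    return power, phase


# ---------------------------------------------------------------------------
# Gabor filter bank / Hilbert analytic amplitude

def _gabor_s0(v0: float, fbw: float) -> float:
    """Duration parameter giving frequency-response FWHM = fbw * v0.

    The Fourier magnitude of exp(-s0 t^2) is proportional to
    exp(-pi^2 f^2 / s0); half-maximum at f = sqrt(s0 ln 2)/pi gives
    s0 = pi^2 (fbw v0)^2 / (4 ln 2).
    """
    return (np.pi * fbw * v0) ** 2 / (4.0 * np.log(2.0))


def gabor_kernel(v0: float, fs: float, fbw: float = 0.25, n_sigmas: float = 5.0):
    """Complex Gabor filter kernel, unit energy, centered at ``v0`` Hz.

    ``g(t) = A exp(-s0 t^2) exp(2 pi i v0 t)`` sampled at ``fs``; A is set so
    the discrete energy ``sum |g|^2 dt`` equals 1.  The Gaussian envelope's
    time/frequency standard deviations satisfy the Gabor limit
    sigma_t * sigma_f = 1/(4 pi).
    """
    if v0 <= 0 or v0 >= fs / 2:
        raise ValueError(f"center frequency {v0} outside (0, fs/2)")
    s0 = _gabor_s0(v0, fbw)
    sigma_t = 1.0 / np.sqrt(2.0 * s0)
    half = max(int(np.ceil(n_sigmas * sigma_t * fs)), 3)
    t = np.arange(-half, half + 1) / fs
    g = np.exp(-s0 * t**2) * np.exp(2j * np.pi * v0 * t)
    dt = 1.0 / fs
    g /= np.sqrt(np.sum(np.abs(g) ** 2) * dt)
    return g


def gabor_haa(signal: np.ndarray, fs: float, band: tuple,
              n_subbands: int = 8, fbw: float = 0.25) -> BandEnvelope:
    """Hilbert analytic amplitude of a band via an 8-sub-band Gabor bank.

    Center frequencies are log-spaced across ``band``; each sub-band's
    complex Gabor filter yields an analytic signal whose magnitude is the
    sub-band envelope, and the ``n_subbands`` envelopes are averaged.
    """
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"band {band} outside (0, fs/2)")
    centers = np.geomspace(lo, hi, n_subbands)
    if len(np.unique(np.round(centers * len(signal) / fs))) < n_subbands:
        raise ValueError("band too narrow for distinct sub-bands at this resolution")
    signal = np.asarray(signal, float)
    env = np.zeros(len(signal))
    for v0 in centers:
        analytic = fftconvolve(signal, gabor_kernel(v0, fs, fbw), mode="same")
        env += np.abs(analytic)
    env /= n_subbands
    return BandEnvelope(amplitude=env, band=(lo, hi), fs=fs)


# ---------------------------------------------------------------------------
# epoching

def _epoch_indices(event_times: np.ndarray, window: tuple, fs: float, n_samples: int):
    """Start indices and epoch length; drops trials overlapping the edges."""
    t_pre, t_post = window
    n_per = int(round(fs * (t_post - t_pre)))
    if n_per <= 0:
        raise ValueError(f"window {window} has non-positive length")
    starts = np.round((np.asarray(event_times) + t_pre) * fs).astype(int)
    keep = (starts >= 0) & (starts + n_per <= n_samples)
    return starts, keep, n_per


def epoch_signal(power: np.ndarray, event_times: np.ndarray, window: tuple,
                 fs: float, grid: FreqGrid | None = None,
                 phase: np.ndarray | None = None, events=None) -> TFMap:
    """Slice a continuous (n_freqs, n_times) decomposition into trials.

    ``window = (t_pre, t_post)`` is half-open, in seconds relative to the
    event: exactly ``fs * (t_post - t_pre)`` samples per trial, the event at
    index ``fs * |t_pre|``.  Trials too close to the recording edges are
    dropped (with their metadata rows).
    """
    event_times = np.asarray(event_times, float)
    if event_times.size == 0:
        raise ValueError("empty event table")
    starts, keep, n_per = _epoch_indices(event_times, window, fs, power.shape[-1])
    if not keep.all():
        import logging
        logging.getLogger(__name__).info("dropping %d edge trials", (~keep).sum())
    idx = np.where(keep)[0]
    pw = np.stack([power[:, s:s + n_per] for s in starts[idx]])
    ph = None if phase is None else np.stack([phase[:, s:s + n_per] for s in starts[idx]])
    times = window[0] + np.arange(n_per) / fs
    ev = None
    if events is not None:
        ev = events.iloc[idx].reset_index(drop=True)
    return TFMap(power=pw, phase=ph, times=times, grid=grid, events=ev)


def epoch_envelope(env: BandEnvelope, event_times: np.ndarray, window: tuple,
                   events=None) -> BandEnvelope:
    """Epoch a continuous band envelope into a (n_trials, n_times) array."""
    event_times = np.asarray(event_times, float)
    if event_times.size == 0:
        raise ValueError("empty event table")
    starts, keep, n_per = _epoch_indices(event_times, window, env.fs, len(env.amplitude))
    idx = np.where(keep)[0]
    amp = np.stack([env.amplitude[s:s + n_per] for s in starts[idx]])
    times = window[0] + np.arange(n_per) / env.fs
    ev = None
    if events is not None:
        ev = events.iloc[idx].reset_index(drop=True)
    return BandEnvelope(amplitude=amp, band=env.band, fs=env.fs, times=times, events=ev)
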