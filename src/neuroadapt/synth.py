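"""Synthetic two-region LFP with ground-truth injected effects.

The generator emulates clean, referenced intracranial recordings from two
prefrontal regions (dmPFC, dlPFC) at 500 Hz: 1/f background noise per
channel, plus injected effects whose parameters are recorded as ground
truth —

* band-limited oscillations whose trial-wise amplitude depends linearly on a
  behavioral regressor (reward, decision, PE, RV, RU),
* theta-phase → gamma-amplitude coupling of configurable depth between a
  phase-providing and an amplitude-providing region, and
* inter-regional band-envelope correlation at a configurable target r.

Effects are additive oscillations rather than multiplicative modulation of
the background, so their envelopes are analytically known and every
downstream detector can be validated against the truth block.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal.windows import tukey

from .bandit import BanditSession
from .models import LearnerTrajectory
from .spectral import BANDS

logger = logging.getLogger(__name__)

__all__ = [
    "Effect",
    "PACEffect",
    "AACEffect",
    "RecordingSpec",
    "PatientRecording",
    "SyntheticRecording",
    "gen_background",
    "inject_regressor_power",
    "inject_pac",
    "inject_shared_envelope",
    "events_from_behavior",
    "generate_dataset",
    "save_recording",
    "load_recording",
]

#: analysis windows in seconds relative to the stage's event
_STAGE_WINDOWS = {"post_feedback": (0.0, 2.0), "pre_selection": (-1.0, 0.0)}


def _band_edges(band) -> tuple:
    return BANDS[band] if isinstance(band, str) else tuple(band)


def _band_center(band) -> float:
    lo, hi = _band_edges(band)
    return float(np.sqrt(lo * hi))  # geometric center of a log band


@dataclass(frozen=True)
class Effect:
    """A regressor-modulated band oscillation in one region and stage."""

    region: str
    band: str
    regressor: str
    slope: float
    stage: str = "post_feedback"
    base_amplitude: float = 1.0


@dataclass(frozen=True)
class PACEffect:
    """Injected phase→amplitude coupling between two regions."""

    phase_region: str = "dlPFC"
    amp_region: str = "dmPFC"
    phase_freq: float = 8.0
    amp_freq: float = 110.0
    depth: float = 0.8
    stage: str = "pre_selection"
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError("PAC depth must lie in [0, 1]")
        if self.amp_freq <= self.phase_freq:
            raise ValueError("amp_freq must exceed phase_freq")


@dataclass(frozen=True)
class AACEffect:
    """Injected inter-regional shared band envelope."""

    region_a: str = "dlPFC"
    region_b: str = "dmPFC"
    band: str = "theta"
    target_r: float = 0.6
    stage: str = "post_feedback"
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if abs(self.target_r) > 1:
            raise ValueError("|target_r| must be <= 1")


@dataclass(frozen=True)
class RecordingSpec:
    """Configuration of the synthetic recording.

    Channel counts default to the real montage's dlPFC:dmPFC proportions
    scaled to desk size.  ``noise_exponent`` is the 1/f^alpha background
    exponent.
    """

    fs: float = 500.0
    channels_per_region: tuple = (("dmPFC", 4), ("dlPFC", 8))
    noise_exponent: float = 1.0
    noise_amplitude: float = 1.0
    effects: tuple = ()
    pac: PACEffect | None = None
    aac: AACEffect | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 2 * 150.0:
            raise ValueError("fs must exceed twice the highest oscillator frequency")

    @property
    def regions(self) -> dict:
        return dict(self.channels_per_region)


@dataclass
class PatientRecording:
    signals: dict          # region -> (n_channels, n_samples)
    events: pd.DataFrame   # one row per trial with regressors and codings
    fs: float


@dataclass
class SyntheticRecording:
    patients: dict         # patient id -> PatientRecording
    truth: dict            # generating effect parameters
    fs: float


# ---------------------------------------------------------------------------
# primitives

def gen_background(n_samples: int, fs: float, exponent: float = 1.0,
                   amplitude: float = 1.0, rng=None) -> np.ndarray:
    """Gaussian 1/f^alpha noise via spectral shaping, unit SD × amplitude."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if exponent < 0:
        raise ValueError("exponent must be nonnegative")
    if rng is None:
        rng = np.random.default_rng()
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0
    sig = np.fft.irfft(spec * shaping, n=n_samples)
    sd = sig.std()
    if sd > 0:
        sig = sig / sd
    return amplitude * sig


def _window_slice(event_time: float, window: tuple, fs: float, n_samples: int):
    start = int(round((event_time + window[0]) * fs))
    stop = start + int(round((window[1] - window[0]) * fs))
    if start < 0 or stop > n_samples:
        return None
    return slice(start, stop)


def inject_regressor_power(
    signal: np.ndarray,
    fs: float,
    event_times: np.ndarray,
    regressor: np.ndarray,
    band,
    slope: float,
    window: tuple,
    base_amplitude: float = 1.0,
    rng=None,
) -> np.ndarray:
    """Add a band oscillation whose amplitude tracks a trial regressor.

    Per trial the added component is
    ``base * (1 + clip(slope * z, ±0.95)) * taper(t) * cos(2 pi f_c t + phi)``
    with ``z`` the z-scored regressor, ``f_c`` the band's geometric center
    and a per-trial random phase.  Trials whose window falls outside the
    recording are skipped with a log entry.  Returns a new array.
    """
    if rng is None:
        rng = np.random.default_rng()
    out = np.array(signal, float, copy=True)
    reg = np.asarray(regressor, float)
    sd = reg.std()
    z = (reg - reg.mean()) / sd if sd > 0 else np.zeros_like(reg)
    fc = _band_center(band)
    for et, zt in zip(np.asarray(event_times, float), z):
        sl = _window_slice(et, window, fs, len(out))
        if sl is None:
            logger.info("inject_regressor_power: trial at %.3f s outside recording", et)
            continue
        n = sl.stop - sl.start
        t = np.arange(n) / fs
        amp = base_amplitude * (1.0 + np.clip(slope * zt, -0.95, 0.95))
        out[sl] += amp * tukey(n, 0.2) * np.cos(2 * np.pi * fc * t + rng.uniform(0, 2 * np.pi))
    return out


def _pac_components(n: int, fs: float, phase_freq: float, amp_freq: float,
                    depth: float, amplitude: float, phi0: float):
    """(slow wave, modulated fast wave) over n samples."""
    t = np.arange(n) / fs
    phi_slow = 2 * np.pi * phase_freq * t + phi0
    slow = amplitude * np.cos(phi_slow)
    fast = amplitude * (1.0 + depth * np.cos(phi_slow)) * np.cos(2 * np.pi * amp_freq * t)
    taper = tukey(n, 0.2)
    return slow * taper, fast * taper


def inject_pac(
    signal: np.ndarray,
    fs: float,
    event_times: np.ndarray,
    phase_freq: float,
    amp_freq: float,
    depth: float,
    window: tuple,
    amplitude: float = 1.0,
    rng=None,
) -> np.ndarray:
    """Add phase-coupled slow + fast oscillations within peri-event windows.

    The fast component is ``a0 (1 + d cos phi_slow(t)) cos phi_fast(t)``;
    the slow oscillation providing ``phi_slow`` is added as well.
    """
    if not 0.0 <= depth <= 1.0:
        raise ValueError("depth must lie in [0, 1]")
    if amp_freq <= phase_freq:
        raise ValueError("amp_freq must exceed phase_freq")
    if rng is None:
        rng = np.random.default_rng()
    out = np.array(signal, float, copy=True)
    for et in np.asarray(event_times, float):
        sl = _window_slice(et, window, fs, len(out))
        if sl is None:
            continue
        slow, fast = _pac_components(sl.stop - sl.start, fs, phase_freq, amp_freq,
                                     depth, amplitude, rng.uniform(0, 2 * np.pi))
        out[sl] += slow + fast
    return out


def _smooth_unit_noise(n: int, fs: float, rng, cutoff_hz: float = 1.0) -> np.ndarray:
    """Standardized slowly varying Gaussian process (envelope carrier)."""
    sigma = fs / (2 * np.pi * cutoff_hz)
    x = gaussian_filter1d(rng.standard_normal(n), sigma, mode="reflect")
    sd = x.std()
    return x / sd if sd > 0 else x


def inject_shared_envelope(
    signal_a: np.ndarray,
    signal_b: np.ndarray,
    fs: float,
    event_times: np.ndarray,
    band,
    target_r: float,
    window: tuple,
    amplitude: float = 1.0,
    rng=None,
):
    """Add band oscillations to two signals with correlated envelopes.

    Each region's envelope mixes a shared slow component (weight sqrt|r|)
    with an independent one, so the envelope correlation of the injected
    components approaches ``target_r``.  Returns the pair of new arrays.
    """
    if abs(target_r) > 1:
        raise ValueError("|target_r| must be <= 1")
    if rng is None:
        rng = np.random.default_rng()
    out_a = np.array(signal_a, float, copy=True)
    out_b = np.array(signal_b, float, copy=True)
    fc = _band_center(band)
    w_shared = np.sqrt(abs(target_r))
    w_indep = np.sqrt(1.0 - abs(target_r))
    sign = np.sign(target_r) if target_r != 0 else 1.0
    for et in np.asarray(event_times, float):
        sl = _window_slice(et, window, fs, len(out_a))
        if sl is None:
            continue
        n = sl.stop - sl.start
        t = np.arange(n) / fs
        shared = _smooth_unit_noise(n, fs, rng)
        xa = w_shared * shared + w_indep * _smooth_unit_noise(n, fs, rng)
        xb = sign * w_shared * shared + w_indep * _smooth_unit_noise(n, fs, rng)
        env_a = 1.0 + 0.45 * np.clip(xa, -2.0, 2.0)
        env_b = 1.0 + 0.45 * np.clip(xb, -2.0, 2.0)
        taper = tukey(n, 0.2)
        out_a[sl] += amplitude * env_a * taper * np.cos(2 * np.pi * fc * t + rng.uniform(0, 2 * np.pi))
        out_b[sl] += amplitude * env_b * taper * np.cos(2 * np.pi * fc * t + rng.uniform(0, 2 * np.pi))
    return out_a, out_b


# ---------------------------------------------------------------------------
# dataset assembly

def events_from_behavior(session: BanditSession, traj: LearnerTrajectory,
                         patient: int = 0) -> pd.DataFrame:
    """Trial event table joining timing, codings and model regressors.

    ``decision`` is the *next-trial* decision (stay = 1, switch = 0; NaN on
    the last trial); ``prev_reward`` is trial t-1's feedback (NaN on the
    first).  PE/RV/RU are the post-update values of the current trial, which
    hold until the next selection.
    """
    n = session.n_trials
    decision = np.full(n, np.nan)
    decision[:-1] = (session.choices[1:] == session.choices[:-1]).astype(float)
    prev_reward = np.full(n, np.nan)
    prev_reward[1:] = session.outcomes[:-1]
    return pd.DataFrame({
        "patient": patient,
        "trial": np.arange(n),
        "selection_time": session.selection_times,
        "feedback_time": session.feedback_times,
        "reward": session.outcomes.astype(float),
        "prev_reward": prev_reward,
        "decision": decision,
        "pe": traj.pe,
        "rv": traj.rv,
        "ru": traj.ru,
    })


def _stage_event_times(events: pd.DataFrame, stage: str) -> np.ndarray:
    col = "feedback_time" if stage == "post_feedback" else "selection_time"
    return events[col].to_numpy()


def generate_dataset(behavior: list, spec: RecordingSpec) -> SyntheticRecording:
    """Compose the full synthetic recording from behavioral ground truth.

    ``behavior`` is a list of ``(BanditSession, LearnerTrajectory)`` pairs,
    one per patient.  Background + injected effects are built per region and
    channel; the truth block echoes all generating parameters.
    """
    rng = np.random.default_rng(spec.seed)
    patients = {}
    for pid, (session, traj) in enumerate(behavior):
        events = events_from_behavior(session, traj, patient=pid)
        if traj.n_trials != session.n_trials:
            raise ValueError("behavioral session and trajectory lengths differ")
        duration = session.feedback_times[-1] + 3.0
        n_samples = int(np.ceil(duration * spec.fs))
        signals = {}
        for region, n_chan in spec.regions.items():
            chans = np.empty((n_chan, n_samples))
            for c in range(n_chan):
                sig = gen_background(n_samples, spec.fs, spec.noise_exponent,
                                     spec.noise_amplitude, rng)
                gain = rng.uniform(0.8, 1.2)  # per-channel effect-size jitter
                for eff in spec.effects:
                    if eff.region != region:
                        continue
                    sig = inject_regressor_power(
                        sig, spec.fs, _stage_event_times(events, eff.stage),
                        events[eff.regressor].fillna(0).to_numpy(),
                        eff.band, eff.slope, _STAGE_WINDOWS[eff.stage],
                        base_amplitude=gain * eff.base_amplitude, rng=rng,
                    )
                chans[c] = sig
            signals[region] = chans
        # cross-regional effects operate on per-channel pairs
        if spec.pac is not None:
            p = spec.pac
            times = _stage_event_times(events, p.stage)
            win = _STAGE_WINDOWS[p.stage]
            for c in range(signals[p.amp_region].shape[0]):
                phi_rng = np.random.default_rng(spec.seed + 7000 + 13 * pid + c)
                # coherent slow wave into the phase region, modulated fast wave
                # into the amplitude region
                amp_sig = signals[p.amp_region][c]
                cph = c % signals[p.phase_region].shape[0]
                phase_sig = signals[p.phase_region][cph]
                for et in times:
                    sl = _window_slice(et, win, spec.fs, len(amp_sig))
                    if sl is None:
                        continue
                    slow, fast = _pac_components(
                        sl.stop - sl.start, spec.fs, p.phase_freq, p.amp_freq,
                        p.depth, p.amplitude, phi_rng.uniform(0, 2 * np.pi))
                    phase_sig[sl] += slow
                    amp_sig[sl] += fast
        if spec.aac is not None:
            a = spec.aac
            times = _stage_event_times(events, a.stage)
            win = _STAGE_WINDOWS[a.stage]
            n_pairs = min(signals[a.region_a].shape[0], signals[a.region_b].shape[0])
            for c in range(n_pairs):
                sa, sb = inject_shared_envelope(
                    signals[a.region_a][c], signals[a.region_b][c], spec.fs,
                    times, a.band, a.target_r, win, amplitude=a.amplitude, rng=rng,
                )
                signals[a.region_a][c] = sa
                signals[a.region_b][c] = sb
        patients[pid] = PatientRecording(signals=signals, events=events, fs=spec.fs)
    truth = {
        "effects": [asdict(e) for e in spec.effects],
        "pac": None if spec.pac is None else asdict(spec.pac),
        "aac": None if spec.aac is None else asdict(spec.aac),
        "noise_exponent": spec.noise_exponent,
        "noise_amplitude": spec.noise_amplitude,
        "seed": spec.seed,
        "fs": spec.fs,
    }
    return SyntheticRecording(patients=patients, truth=truth, fs=spec.fs)


# ---------------------------------------------------------------------------
# HDF5 serialization

def save_recording(rec: SyntheticRecording, path) -> None:
    """Write /patients/<id>/regions/<name>/signals + events + /truth."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["truth"] = json.dumps(rec.truth)
        f.attrs["fs"] = rec.fs
        for pid, pr in rec.patients.items():
            g = f.create_group(f"patients/{pid}")
            for region, arr in pr.signals.items():
                g.create_dataset(f"regions/{region}/signals", data=arr)
            ev = g.create_group("events")
            for col in pr.events.columns:
                ev.create_dataset(col, data=pr.events[col].to_numpy(float))


def load_recording(path) -> SyntheticRecording:
    import h5py

    with h5py.File(path, "r") as f:
        truth = json.loads(f.attrs["truth"])
        fs = float(f.attrs["fs"])
        patients = {}
        for pid in f["patients"]:
            g = f[f"patients/{pid}"]
            signals = {r: g[f"regions/{r}/signals"][()] for r in g["regions"]}
            events = pd.DataFrame({c: g["events"][c][()] for c in g["events"]})
            patients[int(pid)] = PatientRecording(signals=signals, events=events, fs=fs)
    return SyntheticRecording(patients=patients, truth=truth, fs=fs)
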