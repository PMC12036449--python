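"""Cross-frequency and cross-regional coupling measures.

Phase–amplitude coupling (PAC) is quantified by the modulation index — the
modulus of the time-averaged amplitude-weighted unit phasor of the slower
oscillation's phase — standardized against a circular-shift permutation
null.  Amplitude–amplitude coupling (AAC) is the Pearson correlation between
two band envelopes over an analysis window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import FreqGrid

__all__ = [
    "PACResult",
    "PACGrid",
    "AACResult",
    "pac_mi",
    "pac_permutation_z",
    "pac_grid_search",
    "aac",
    "STAGE_WINDOWS",
]

#: analysis windows in seconds: post-feedback from outcome onset,
#: pre-selection from selection onset
STAGE_WINDOWS = {"post_feedback": (0.0, 2.0), "pre_selection": (-1.0, 0.0)}


@dataclass
class PACResult:
    mi: float
    z: float
    null_mean: float
    null_sd: float
    n_perm: int


@dataclass
class PACGrid:
    """PAC z-scores over a (phase frequency × amplitude frequency) grid."""

    phase_freqs: np.ndarray
    amp_freqs: np.ndarray
    z_matrix: np.ndarray     # (n_phase, n_amp)
    mi_matrix: np.ndarray

    @property
    def argmax_pair(self) -> tuple:
        i, j = np.unravel_index(np.argmax(self.z_matrix), self.z_matrix.shape)
        return float(self.phase_freqs[i]), float(self.amp_freqs[j])

    @property
    def mi_argmax_pair(self) -> tuple:
        """Raw modulation-index peak; less permutation noise than the z peak."""
        i, j = np.unravel_index(np.argmax(self.mi_matrix), self.mi_matrix.shape)
        return float(self.phase_freqs[i]), float(self.amp_freqs[j])


@dataclass
class AACResult:
    r: float
    band_pair: tuple
    stage: str


def pac_mi(amplitude: np.ndarray, phase: np.ndarray) -> float:
    """Modulation index: ``| n^-1 sum_t a_t exp(i phi_t) |``."""
    a = np.asarray(amplitude, float)
    phi = np.asarray(phase, float)
    if a.shape != phi.shape:
        raise ValueError("amplitude and phase must have equal lengths")
    if a.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.abs(np.mean(a * np.exp(1j * phi))))


def pac_permutation_z(
    amplitude: np.ndarray,
    phase: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
    min_shift_frac: float = 0.1,
) -> PACResult:
    """Permutation-standardized modulation index.

    The null circularly shifts the amplitude series by random offsets (at
    least ``min_shift_frac`` of the series length, to avoid near-identity
    shifts) while the phase series stays fixed; the observed MI is converted
    to a z-score against the null mean and SD.
    """
    a = np.asarray(amplitude, float)
    phi = np.asarray(phase, float)
    mi = pac_mi(a, phi)
    n = len(a)
    rng = np.random.default_rng(seed)
    min_shift = max(int(min_shift_frac * n), 1)
    shifts = rng.integers(min_shift, n - min_shift + 1, size=n_perm)
    phasor = np.exp(1j * phi)
    null = np.empty(n_perm)
    for i, s in enumerate(shifts):
        null[i] = np.abs(np.mean(np.roll(a, s) * phasor))
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    if null_sd == 0:
        raise ValueError("degenerate permutation null (zero variance)")
    return PACResult(mi=mi, z=(mi - null_mean) / null_sd,
                     null_mean=null_mean, null_sd=null_sd, n_perm=n_perm)


def pac_grid_search(
    phase_signal_tfr: tuple,
    amp_signal_tfr: tuple,
    grid: FreqGrid,
    n_perm: int = 1000,
    seed: int = 0,
    phase_cut: float = 15.0,
    amp_cut: float = 30.0,
) -> PACGrid:
    """Exploratory PAC over all (phase < 15 Hz, amplitude > 30 Hz) pairs.

    ``phase_signal_tfr`` is ``(power, phase)`` from the phase-providing
    region's Morlet decomposition, ``amp_signal_tfr`` likewise for the
    amplitude-providing region; the standard 50-bin grid yields an 18 × 22
    z-score matrix.
    """
    _, phase_all = phase_signal_tfr
    power_all, _ = amp_signal_tfr
    phase_idx = np.where(grid.values < phase_cut)[0]
    amp_idx = np.where(grid.values > amp_cut)[0]
    z = np.empty((len(phase_idx), len(amp_idx)))
    mi = np.empty_like(z)
    for i, pi in enumerate(phase_idx):
        for j, ai in enumerate(amp_idx):
            amp = np.sqrt(power_all[ai])  # analytic amplitude from power
            res = pac_permutation_z(
                amp, phase_all[pi], n_perm=n_perm,
                seed=seed + 1009 * i + j,
            )
            z[i, j] = res.z
            mi[i, j] = res.mi
    return PACGrid(
        phase_freqs=grid.values[phase_idx], amp_freqs=grid.values[amp_idx],
        z_matrix=z, mi_matrix=mi,
    )


def aac(envelope_a: np.ndarray, envelope_b: np.ndarray,
        band_pair: tuple = ("theta", "theta"), stage: str = "post_feedback") -> AACResult:
    """Amplitude–amplitude coupling: Pearson r between two envelopes.

    Returns ``nan`` if either envelope has zero variance over the window.
    """
    a = np.asarray(envelope_a, float)
    b = np.asarray(envelope_b, float)
    if a.shape != b.shape:
        raise ValueError("envelopes must have equal sample counts")
    if a.std() == 0 or b.std() == 0:
        return AACResult(r=float("nan"), band_pair=band_pair, stage=stage)
    r = float(np.corrcoef(a, b)[0, 1])
    return AACResult(r=r, band_pair=band_pair, stage=stage)
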