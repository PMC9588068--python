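"""Frequency-domain decomposition of f_o fluctuation.

Spontaneous pitch fluctuation in sustained vowels mixes a slow, centrally
controllable component (<= 5 Hz, the range of intonational drift and of the
compensatory response itself) with a fast component (6-30 Hz) dominated by
physiological microtremor.  This module separates the two with zero-phase
second-order Butterworth filters, and computes a half-octave filter-bank
modulation spectrum (28 band-pass filters, centers 0.4 * 2**(k/4) Hz for
k = 0..27, i.e. quarter-octave spacing up to ~43 Hz) whose per-band RMS
profiles the fluctuation amplitude as a function of modulation frequency.

Filtering operates on zero-mean, zero-filled sequences; standard deviations
over the analysis window use voiced samples only.  Slow/fast extraction runs
at the native 100-Hz rate; the filter-bank analysis runs on trajectories
up-sampled to 200 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import FoTrajectory

__all__ = [
    "ModulationSpectrum",
    "VariabilityIndex",
    "filter_bank_centers",
    "center_and_fill",
    "upsample_double",
    "extract_component",
    "modulation_spectrum",
    "variability_index",
    "variability_difference",
]

#: Slow-component low-pass cutoff, Hz.
SLOW_CUTOFF_HZ = 5.0
#: Fast-component band-pass edges, Hz.
FAST_BAND_HZ = (6.0, 30.0)
#: Filter-bank geometry: first center, top limit, quarter-octave spacing,
#: half-octave bandwidth.
BANK_MIN_HZ = 0.4
BANK_MAX_HZ = 50.0
BANK_STEP_OCT = 0.25
BANK_WIDTH_OCT = 0.5
#: Analysis window for variability indices, seconds after voice onset.
VARIABILITY_WINDOW = (0.10, 1.20)


@dataclass
class ModulationSpectrum:
    """Per-band RMS amplitude of an f_o contour's fluctuation."""

    center_frequencies: np.ndarray  # Hz, strictly increasing
    band_rms: np.ndarray  # cents, same length

    def __post_init__(self) -> None:
        self.center_frequencies = np.asarray(self.center_frequencies, float)
        self.band_rms = np.asarray(self.band_rms, float)
        if len(self.center_frequencies) != len(self.band_rms):
            raise ValueError("centers and band RMS must have equal length")
        if np.any(self.band_rms < 0):
            raise ValueError("band RMS must be nonnegative")

    @property
    def peak_frequency(self) -> float:
        return float(self.center_frequencies[int(np.argmax(self.band_rms))])


@dataclass
class VariabilityIndex:
    """Per-participant f_o variability (mean within-trial SD), in cents."""

    whole: float
    slow: float
    fast: float
    n_trials: int


def filter_bank_centers(
    min_hz: float = BANK_MIN_HZ,
    max_hz: float = BANK_MAX_HZ,
    step_oct: float = BANK_STEP_OCT,
) -> np.ndarray:
    """Quarter-octave-spaced band centers from ``min_hz`` up to ``max_hz``.

    A quarter-octave grid starting at 0.4 Hz cannot land on 50 Hz exactly;
    all centers <= ``max_hz`` are taken (28 bands with the defaults, the
    highest at ~43.1 Hz).
    """
    k = np.arange(int(np.floor(np.log2(max_hz / min_hz) / step_oct)) + 1)
    return min_hz * 2.0 ** (k * step_oct)


def center_and_fill(traj: FoTrajectory | np.ndarray) -> np.ndarray:
    """Zero-center on the voiced mean and replace missing samples by zero."""
    values = traj.values if isinstance(traj, FoTrajectory) else np.asarray(traj, float)
    voiced = ~np.isnan(values)
    if not voiced.any():
        raise ValueError("trajectory has no voiced samples")
    out = values - values[voiced].mean()
    out[~voiced] = 0.0
    return out


def upsample_double(seq: np.ndarray) -> np.ndarray:
    """Linear-interpolation up-sampling from 100 Hz to 200 Hz.

    Midpoints are inserted between consecutive samples and the final sample
    is held for one extra half-step (output length ``2 n``, so a 2-s input
    stays 2 s at 200 Hz).  Linear interpolation preserves in-band sinusoids
    up to the filter bank's top band within ~1% RMS.
    """
    seq = np.asarray(seq, float)
    if seq.ndim != 1 or len(seq) < 2:
        raise ValueError("need a 1-D sequence of length >= 2")
    out = np.empty(2 * len(seq))
    out[::2] = seq
    out[1:-1:2] = 0.5 * (seq[:-1] + seq[1:])
    out[-1] = seq[-1]
    return out


def _butter_sos(component: str, rate: float):
    if component == "slow":
        return signal.butter(2, SLOW_CUTOFF_HZ / (rate / 2), "lowpass", output="sos")
    if component == "fast":
        lo, hi = FAST_BAND_HZ
        return signal.butter(2, [lo / (rate / 2), hi / (rate / 2)], "bandpass", output="sos")
    raise ValueError(f"unknown component {component!r}")


def extract_component(seq: np.ndarray, rate: float, component: str) -> np.ndarray:
    """Zero-phase slow (<=5 Hz) or fast (6-30 Hz) component of ``seq``.

    Second-order Butterworth, applied forward and backward (``sosfiltfilt``)
    so there is no group delay.  ``seq`` may be 1-D or 2-D (filtering along
    the last axis).
    """
    seq = np.asarray(seq, float)
    sos = _butter_sos(component, rate)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if seq.shape[-1] <= padlen:
        raise ValueError(f"sequence too short to filter (need > {padlen} samples)")
    return signal.sosfiltfilt(sos, seq, axis=-1)


def band_sos(fc: float, rate: float, width_oct: float = BANK_WIDTH_OCT):
    """Second-order Butterworth band-pass for a half-octave band at ``fc``."""
    lo = fc * 2.0 ** (-width_oct / 2)
    hi = fc * 2.0 ** (width_oct / 2)
    return signal.butter(2, [lo / (rate / 2), hi / (rate / 2)], "bandpass", output="sos")


def modulation_spectrum(
    seq: np.ndarray,
    rate: float = 200.0,
    centers: np.ndarray | None = None,
) -> ModulationSpectrum:
    """Half-octave filter-bank modulation spectrum of a zero-mean sequence.

    For each band center the sequence is band-pass filtered (zero-phase) and
    the RMS of the output is the band amplitude.  The input must be at least
    2 s long so the 0.4-Hz band is minimally resolved.
    """
    seq = np.asarray(seq, float)
    if seq.shape[-1] / rate < 2.0:
        raise ValueError("need at least 2 s of signal for the 0.4-Hz band")
    if centers is None:
        centers = filter_bank_centers()
    rms = np.empty((len(centers),) + seq.shape[:-1])
    for i, fc in enumerate(centers):
        filtered = signal.sosfiltfilt(band_sos(fc, rate), seq, axis=-1)
        rms[i] = np.sqrt(np.mean(filtered**2, axis=-1))
    if seq.ndim == 1:
        return ModulationSpectrum(centers, rms)
    return ModulationSpectrum(centers, rms)  # (n_bands, n_trials)


def _windowed_sd(traj: FoTrajectory, filtered: np.ndarray | None, window) -> float:
    sl = traj.window_slice(window)
    voiced = traj.voiced[sl]
    if not voiced.any():
        return np.nan
    data = (traj.values if filtered is None else filtered)[sl][voiced]
    return float(np.std(data, ddof=0))


def trajectory_sds(traj: FoTrajectory, window=VARIABILITY_WINDOW) -> tuple[float, float, float]:
    """(whole, slow, fast) SD of one trajectory over the analysis window.

    The whole SD is taken on raw voiced samples; slow/fast are taken on the
    filtered zero-filled contour, again over voiced samples only.
    """
    rate = 1.0 / traj.sample_period
    centered = center_and_fill(traj)
    slow = extract_component(centered, rate, "slow")
    fast = extract_component(centered, rate, "fast")
    return (
        _windowed_sd(traj, None, window),
        _windowed_sd(traj, slow, window),
        _windowed_sd(traj, fast, window),
    )


def batch_trajectory_sds(
    trajs: list[FoTrajectory], window=VARIABILITY_WINDOW
) -> np.ndarray:
    """(n_trajs, 3) array of (whole, slow, fast) windowed SDs.

    Equivalent to calling :func:`trajectory_sds` per trajectory but with the
    zero-phase filtering batched into one call per component, which matters
    when analyzing thousands of trials.
    """
    if not trajs:
        return np.empty((0, 3))
    rate = 1.0 / trajs[0].sample_period
    max_len = max(len(t) for t in trajs)
    values = np.full((len(trajs), max_len), np.nan)
    for i, t in enumerate(trajs):
        values[i, : len(t)] = t.values
    voiced = ~np.isnan(values)
    if not voiced.any(axis=1).all():
        raise ValueError("trajectory has no voiced samples")
    means = np.nanmean(values, axis=1, keepdims=True)
    centered = np.where(voiced, values - means, 0.0)
    slow = extract_component(centered, rate, "slow")
    fast = extract_component(centered, rate, "fast")

    # Gather each trajectory's analysis window (start depends on its onset)
    # with fancy indexing; samples outside the trajectory count as missing.
    dt = trajs[0].sample_period
    i0 = int(round(window[0] / dt))
    i1 = int(round(window[1] / dt))
    onsets = np.array([t.onset_index for t in trajs])
    lengths = np.array([len(t) for t in trajs])
    cols = onsets[:, None] + np.arange(i0, i1)
    in_range = (cols >= 0) & (cols < lengths[:, None])
    rows = np.arange(len(trajs))[:, None]
    cols_c = np.clip(cols, 0, max_len - 1)
    out = np.empty((len(trajs), 3))
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows -> NaN
        for j, mat in enumerate((values, slow, fast)):
            win = mat[rows, cols_c]
            win[~in_range | ~voiced[rows, cols_c]] = np.nan
            out[:, j] = np.nanstd(win, axis=1)
    return out


def variability_index(
    trajs: list[FoTrajectory], window: tuple[float, float] = VARIABILITY_WINDOW
) -> VariabilityIndex:
    """Mean within-trial SD of whole/slow/fast components over ``trajs``.

    Callers are responsible for trial eligibility (first vocalizations,
    excluding trials that immediately followed a shifted trial).
    """
    if not trajs:
        raise ValueError("no eligible trials")
    sds = batch_trajectory_sds(trajs, window)
    sds = sds[~np.isnan(sds).any(axis=1)]
    if sds.size == 0:
        raise ValueError("no trials with voiced data in the analysis window")
    whole, slow, fast = sds.mean(axis=0)
    return VariabilityIndex(float(whole), float(slow), float(fast), len(sds))


def _component_sd(traj: FoTrajectory, component: str, window) -> float:
    rate = 1.0 / traj.sample_period
    if component == "whole":
        return _windowed_sd(traj, None, window)
    filtered = extract_component(center_and_fill(traj), rate, component)
    return _windowed_sd(traj, filtered, window)


def variability_difference(
    pairs: list[tuple[FoTrajectory, FoTrajectory]],
    component: str = "slow",
    window: tuple[float, float] = VARIABILITY_WINDOW,
):
    """Mean (second - first vocalization) variability over paired trials.

    ``component`` is 'whole', 'slow', 'fast', or 'subbands'; the subbands
    variant returns one difference per filter-bank band (computed on the
    200-Hz up-sampled contour).  Positive and negative shifts of the same
    magnitude should be pooled by the caller when emulating the design.
    """
    if not pairs:
        raise ValueError("no first/second vocalization pairs supplied")
    if component == "subbands":
        # Band RMS needs the full contour to resolve the lowest bands, so the
        # subband variant works on whole trajectories (up-sampled to 200 Hz)
        # rather than the SD analysis window.
        diffs = []
        for first, second in pairs:
            spec1 = modulation_spectrum(upsample_double(center_and_fill(first)))
            spec2 = modulation_spectrum(upsample_double(center_and_fill(second)))
            diffs.append(spec2.band_rms - spec1.band_rms)
        return np.mean(diffs, axis=0)
    diffs = [
        _component_sd(second, component, window) - _component_sd(first, component, window)
        for first, second in pairs
    ]
    return float(np.mean(diffs))
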