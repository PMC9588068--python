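"""Voice-amplitude analysis: A-weighted envelopes, background estimation,
onset/offset detection, and relative voice amplitude across a cohort.

The envelope is the RMS of the A-weighted waveform in a 40-ms Hann window
every 10 ms, in dB (20 log10).  Voice onset/offset are the first/last
frames exceeding the background level by 30 dB, with a 100-ms debounce so a
single noisy frame cannot set the onset.  Relative voice amplitude is each
participant's mean envelope level in the 100-1200 ms window, centered on
the cohort grand mean (so the cohort average is zero by construction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "AmplitudeEnvelope",
    "a_weight",
    "compute_envelope",
    "estimate_background",
    "detect_voice_bounds",
    "relative_voice_amplitude",
    "read_wav",
]

#: Envelope frame step, seconds.
ENVELOPE_STEP = 0.01
#: Envelope analysis window, seconds.
ENVELOPE_WINDOW = 0.04
#: Voice-detection margin above the background level, dB.
VOICE_MARGIN_DB = 30.0
#: Minimum continuous suprathreshold duration at the onset, seconds.
ONSET_DEBOUNCE = 0.10
#: Averaging window for the per-trial amplitude level, seconds after onset.
AMPLITUDE_WINDOW = (0.10, 1.20)

# IEC 61672 A-weighting analog prototype: corner frequencies in Hz.
_A_F1 = 20.598997
_A_F2 = 107.65265
_A_F3 = 737.86223
_A_F4 = 12194.217
# Normalization so that the analog gain at 1 kHz is exactly 0 dB (~+2.0 dB).
_A1000 = 1.9997


@dataclass
class AmplitudeEnvelope:
    """Frame-wise dB envelope of one recording.

    Frame k summarizes the window starting at ``k * sample_step``; its
    timestamp (``times``) is the window center.
    """

    values: np.ndarray  # dB per 10-ms frame
    sample_step: float = ENVELOPE_STEP
    background_level: float = float("nan")  # dB
    window: float = ENVELOPE_WINDOW

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.sample_step + self.window / 2


def a_weight(waveform: np.ndarray, rate: float) -> np.ndarray:
    """Apply the standard A-weighting filter (IEC 61672 analog prototype,
    discretized by the bilinear transform).

    Gain at 1 kHz is 0 dB within 0.2 dB; a 100-Hz tone is attenuated by
    about 19.1 dB.  Sampling rates below 8 kHz cannot represent the
    weighting poles and raise.
    """
    if rate < 8000:
        raise ValueError("A-weighting requires a sampling rate of at least 8 kHz")
    two_pi = 2 * np.pi
    zeros = [0.0] * 4
    poles = [
        -two_pi * _A_F1, -two_pi * _A_F1,
        -two_pi * _A_F2, -two_pi * _A_F3,
        -two_pi * _A_F4, -two_pi * _A_F4,
    ]
    k = (two_pi * _A_F4) ** 2 * 10 ** (_A1000 / 20.0)
    zd, pd_, kd = signal.bilinear_zpk(zeros, poles, k, fs=rate)
    sos = signal.zpk2sos(zd, pd_, kd)
    return signal.sosfilt(sos, np.asarray(waveform, float))


def compute_envelope(
    waveform: np.ndarray,
    rate: float,
    window: float = ENVELOPE_WINDOW,
    step: float = ENVELOPE_STEP,
    apply_a_weighting: bool = True,
) -> AmplitudeEnvelope:
    """Hann-windowed RMS per 10-ms step of the (A-weighted) waveform, in dB."""
    x = np.asarray(waveform, float)
    n_win = int(round(window * rate))
    n_step = int(round(step * rate))
    if x.size < n_win:
        raise ValueError("waveform shorter than one analysis window")
    if apply_a_weighting:
        x = a_weight(x, rate)
    w = np.hanning(n_win)
    wsum = w.sum()
    n_frames = 1 + (x.size - n_win) // n_step
    frames = np.lib.stride_tricks.sliding_window_view(x, n_win)[::n_step][:n_frames]
    rms = np.sqrt((frames**2 @ w) / wsum)
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(rms)
    return AmplitudeEnvelope(values=db, sample_step=step, window=window)


def estimate_background(envelope: AmplitudeEnvelope, silent_region: slice | tuple) -> float:
    """Mean dB level over a known-silent frame range."""
    if isinstance(silent_region, tuple):
        silent_region = slice(*silent_region)
    seg = envelope.values[silent_region]
    if seg.size == 0:
        raise ValueError("silent region outside the envelope")
    return float(seg.mean())


def detect_voice_bounds(
    envelope: AmplitudeEnvelope,
    margin: float = VOICE_MARGIN_DB,
    debounce: float = ONSET_DEBOUNCE,
) -> tuple[int, int]:
    """(onset, offset) frame indices of the vocalization.

    Onset is the first frame of the first run of at least ``debounce``
    seconds continuously above background + margin; offset is the last
    frame of the last such run.  Raises if no qualifying run exists.
    """
    if np.isnan(envelope.background_level):
        raise ValueError("background_level must be set before voice detection")
    above = envelope.values > envelope.background_level + margin
    min_run = max(int(round(debounce / envelope.sample_step)), 1)
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    runs = [(s, e) for s, e in zip(edges[::2], edges[1::2]) if e - s >= min_run]
    if not runs:
        raise ValueError("no voice found above background + margin")
    return int(runs[0][0]), int(runs[-1][1] - 1)


def relative_voice_amplitude(
    envelopes,
    window: tuple[float, float] = AMPLITUDE_WINDOW,
    margin: float = VOICE_MARGIN_DB,
) -> dict[str, float]:
    """Per-participant voice amplitude relative to the cohort mean, in dB.

    ``envelopes`` maps participant id -> list of per-trial
    :class:`AmplitudeEnvelope` (with background levels set).  Each trial
    contributes its mean dB in ``window`` after the detected onset; trial
    means are averaged per participant and the grand mean over participants
    is subtracted, so the outputs sum to zero.
    """
    per_participant: dict[str, float] = {}
    for pid, trials in envelopes.items():
        levels = []
        for env in trials:
            onset, _ = detect_voice_bounds(env, margin=margin)
            i0 = onset + int(round(window[0] / env.sample_step))
            i1 = onset + int(round(window[1] / env.sample_step))
            if i1 > len(env.values):
                warnings.warn(f"{pid}: amplitude window extends past envelope; trial skipped")
                continue
            levels.append(env.values[i0:i1].mean())
        if not levels:
            raise ValueError(f"{pid}: no usable trials for amplitude")
        per_participant[pid] = float(np.mean(levels))
    grand = np.mean(list(per_participant.values()))
    return {pid: float(v - grand) for pid, v in per_participant.items()}


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a mono WAV file as float samples in [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    return np.asarray(data, float), int(rate)
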