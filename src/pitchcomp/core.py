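"""Domain types, unit conversions and I/O for vocal-pitch trajectories.

The package works on fundamental-frequency (f_o) contours sampled on a fixed
10-ms grid (100 Hz).  Frequencies are carried in *cents* relative to a base
frequency (55 Hz by default; the choice only shifts contours by a constant and
cancels in every downstream statistic).  Unvoiced/missing samples are carried
explicitly as NaN so that gap filling, fragment removal and filtering can
treat them uniformly.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_BASE_HZ",
    "SAMPLE_PERIOD",
    "FoTrajectory",
    "PitchTrackParseError",
    "hz_to_cents",
    "cents_to_hz",
    "read_pitch_track",
    "write_pitch_track",
    "read_trial_design",
    "write_trial_design",
]

#: Base frequency for the cent scale, in Hz.
DEFAULT_BASE_HZ = 55.0

#: Grid step of pitch trajectories, in seconds (100-Hz frame rate).
SAMPLE_PERIOD = 0.01

#: Columns of a trial-design table.
DESIGN_COLUMNS = [
    "participant_id",
    "trial_index",
    "vowel",
    "condition",
    "shift_cents",
    "follows_shifted_trial",
]


class PitchTrackParseError(ValueError):
    """Raised when a pitch-track stream cannot be parsed."""


def hz_to_cents(frequency, base: float = DEFAULT_BASE_HZ):
    """Convert frequency in Hz to cents relative to ``base``.

    1200 cents = one octave: ``1200 * log2(frequency / base)``.
    NaN values pass through (missing samples stay missing).
    """
    frequency = np.asarray(frequency, dtype=float)
    if base <= 0:
        raise ValueError(f"base frequency must be positive, got {base}")
    with np.errstate(invalid="ignore"):
        if np.any(frequency[~np.isnan(frequency)] <= 0):
            raise ValueError("frequencies must be positive")
    out = 1200.0 * np.log2(frequency / base)
    return float(out) if out.ndim == 0 else out


def cents_to_hz(value, base: float = DEFAULT_BASE_HZ):
    """Inverse of :func:`hz_to_cents`: ``base * 2**(value / 1200)``."""
    if base <= 0:
        raise ValueError(f"base frequency must be positive, got {base}")
    value = np.asarray(value, dtype=float)
    out = base * np.exp2(value / 1200.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class FoTrajectory:
    """One vocalization's f_o contour in cents on the 10-ms grid.

    ``values`` holds cents relative to ``base_hz``; NaN marks unvoiced or
    removed samples.  ``onset_index``/``offset_index`` bound the vocalization
    (inclusive sample indices), normally set from the amplitude envelope and
    possibly refined by preprocessing.
    """

    values: np.ndarray
    sample_period: float = SAMPLE_PERIOD
    onset_index: int = 0
    offset_index: int | None = None
    participant_id: str = ""
    trial_index: int = 0
    vowel: str = "a"
    vocalization_index: int = 1
    shift_cents: float = 0.0
    base_hz: float = DEFAULT_BASE_HZ

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.sample_period <= 0:
            raise ValueError("sample_period must be positive")
        if self.offset_index is None:
            self.offset_index = len(self.values) - 1
        if not (0 <= self.onset_index <= self.offset_index < len(self.values)):
            raise ValueError(
                f"invalid onset/offset ({self.onset_index}, {self.offset_index}) "
                f"for {len(self.values)} samples"
            )
        finite = self.values[~np.isnan(self.values)]
        if finite.size and not np.all(np.isfinite(finite)):
            raise ValueError("non-missing values must be finite")
        if self.shift_cents != 0 and self.vocalization_index != 2:
            raise ValueError("only the second vocalization may carry a feedback shift")

    # -- convenience ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.sample_period

    @property
    def voiced(self) -> np.ndarray:
        """Boolean mask of voiced (non-missing) samples."""
        return ~np.isnan(self.values)

    @property
    def voiced_duration(self) -> float:
        return float(self.voiced.sum()) * self.sample_period

    def copy(self, **changes) -> "FoTrajectory":
        out = replace(self, **changes)
        if "values" not in changes:
            out.values = self.values.copy()
        return out

    def window_slice(self, window: tuple[float, float]) -> slice:
        """Half-open sample slice for ``window`` seconds after the onset."""
        i0 = self.onset_index + int(round(window[0] / self.sample_period))
        i1 = self.onset_index + int(round(window[1] / self.sample_period))
        return slice(max(i0, 0), min(i1, len(self.values)))


# ---------------------------------------------------------------------------
# Pitch-track I/O
# ---------------------------------------------------------------------------

def _as_text_stream(source) -> IO[str]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8")
    return source


def _parse_delimited(lines: list[str]) -> list[tuple[float, float]]:
    points = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = re.split(r"[,\t;]|\s+", line)
        fields = [f for f in fields if f]
        if len(fields) < 2:
            raise PitchTrackParseError(f"line {lineno}: expected two columns, got {line!r}")
        try:
            t, f = float(fields[0]), float(fields[1])
        except ValueError:
            if lineno == 1:  # optional header
                continue
            raise PitchTrackParseError(f"line {lineno}: non-numeric row {line!r}")
        points.append((t, f))
    return points


def _parse_pitchtier(lines: list[str]) -> list[tuple[float, float]]:
    """Parse a Praat PitchTier in either the 'full' or 'short' text layout."""
    body = [ln.rstrip("\n") for ln in lines]
    if not any("PitchTier" in ln for ln in body[:5]):
        raise PitchTrackParseError("line 2: not a PitchTier object")
    rest = body[2:]
    is_full = any("=" in ln for ln in rest)
    points: list[tuple[float, float]] = []
    if is_full:
        number = value = None
        for lineno, ln in enumerate(rest, start=3):
            m = re.match(r"\s*(number|value)\s*=\s*(\S+)", ln)
            if not m:
                continue
            try:
                x = float(m.group(2))
            except ValueError:
                raise PitchTrackParseError(f"line {lineno}: bad number {ln!r}")
            if m.group(1) == "number":
                number = x
            else:
                value = x
                if number is None:
                    raise PitchTrackParseError(f"line {lineno}: value before number")
                points.append((number, value))
                number = None
    else:
        numbers = []
        for lineno, ln in enumerate(rest, start=3):
            s = ln.strip()
            if not s:
                continue
            try:
                numbers.append(float(s))
            except ValueError:
                raise PitchTrackParseError(f"line {lineno}: bad number {s!r}")
        if len(numbers) < 3:
            raise PitchTrackParseError("short PitchTier truncated")
        size = int(numbers[2])
        pts = numbers[3:]
        if len(pts) < 2 * size:
            raise PitchTrackParseError("short PitchTier: fewer points than declared")
        points = [(pts[2 * i], pts[2 * i + 1]) for i in range(size)]
    return points


def read_pitch_track(
    source,
    dialect: str = "delimited",
    base_hz: float = DEFAULT_BASE_HZ,
    sample_period: float = SAMPLE_PERIOD,
    **metadata,
) -> FoTrajectory:
    """Read a pitch track and place it on the 10-ms grid in cents.

    Parameters
    ----------
    source : path or text stream
    dialect : {'delimited', 'praat_pitchtier'}
        ``delimited``: two columns (time s, f_o Hz), optional header.
        ``praat_pitchtier``: Praat "short" or "full" text format.
    metadata : passed through to :class:`FoTrajectory` (participant_id, ...).

    Non-voiced samples (f_o absent or <= 0) become NaN; points are assigned
    to the nearest 10-ms grid sample.
    """
    stream = _as_text_stream(source)
    try:
        lines = stream.readlines()
    finally:
        if isinstance(source, (str, Path)):
            stream.close()
    if dialect == "delimited":
        points = _parse_delimited(lines)
    elif dialect == "praat_pitchtier":
        points = _parse_pitchtier(lines)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not points:
        raise PitchTrackParseError("empty pitch track")
    t_max = max(t for t, _ in points)
    n = int(round(t_max / sample_period)) + 1
    values = np.full(n, np.nan)
    for t, f in points:
        idx = int(round(t / sample_period))
        if 0 <= idx < n and f > 0:
            values[idx] = hz_to_cents(f, base_hz)
    return FoTrajectory(values=values, sample_period=sample_period, base_hz=base_hz, **metadata)


def write_pitch_track(traj: FoTrajectory, sink) -> None:
    """Write a trajectory as delimited text (time_s, f0_hz; 0 Hz = missing).

    Formatting is fixed (10 significant digits) so output is byte-stable and
    the reader round-trips non-missing values to better than 1e-6 cents.
    """
    own = isinstance(sink, (str, Path))
    stream = open(sink, "w", encoding="utf-8") if own else sink
    try:
        stream.write("time_s,f0_hz\n")
        for i, v in enumerate(traj.values):
            t = i * traj.sample_period
            hz = 0.0 if np.isnan(v) else cents_to_hz(v, traj.base_hz)
            stream.write(f"{t:.4f},{hz:.10g}\n")
    finally:
        if own:
            stream.close()


# ---------------------------------------------------------------------------
# Trial-design tables
# ---------------------------------------------------------------------------

def validate_trial_design(design: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"trial design missing columns: {missing}")
    return design


def read_trial_design(source) -> pd.DataFrame:
    df = pd.read_csv(source)
    df["follows_shifted_trial"] = df["follows_shifted_trial"].astype(bool)
    return validate_trial_design(df)


def write_trial_design(design: pd.DataFrame, sink) -> None:
    validate_trial_design(design).to_csv(sink, index=False)
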