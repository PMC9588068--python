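"""Alignment-and-refinement rules for f_o trajectories.

Raw pitch tracks from an autocorrelation extractor carry characteristic
artifacts: brief voicing dropouts, isolated spurious fragments, harsh or
aperiodic glottal pulsation around the vocal onset/offset (seen as >100-cent
jumps), and octave-jump spikes mid-vocalization.  The refinement pipeline
repairs or detaches these in a fixed order:

1. fill gaps <= 40 ms by linear interpolation,
2. remove isolated voiced fragments <= 50 ms,
3. trim unrealistic (> 100 cent) jumps searched backward from 200 ms after
   the onset, redefining the onset as the start of stable vocalization,
4. the mirror rule searched forward from 300 ms before the offset,
5. repair > 100-cent jumps between 210 and 1500 ms after the onset by
   holding the pre-jump value until the contour returns within 100 cents.

All durations are converted to sample counts on the 100-Hz grid by rounding
to nearest; thresholds are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import FoTrajectory

__all__ = [
    "RefinementReport",
    "fill_gaps",
    "remove_fragments",
    "trim_onset_jumps",
    "trim_offset_jumps",
    "repair_mid_jumps",
    "refine_trajectory",
]

#: Minimum usable voiced duration after refinement, seconds.
MIN_USABLE_DURATION = 0.5


@dataclass
class RefinementReport:
    """Bookkeeping of what refinement changed, for audit."""

    samples_filled: int = 0
    fragments_removed: int = 0
    onset_shift: int = 0
    offset_shift: int = 0
    mid_jumps_repaired: int = 0
    usable: bool = True

    def __iadd__(self, other: "RefinementReport") -> "RefinementReport":
        self.samples_filled += other.samples_filled
        self.fragments_removed += other.fragments_removed
        self.onset_shift += other.onset_shift
        self.offset_shift += other.offset_shift
        self.mid_jumps_repaired += other.mid_jumps_repaired
        return self


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in ``mask`` as (start, stop) half-open pairs."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _samples(duration: float, dt: float) -> int:
    return int(round(duration / dt))


def fill_gaps(traj: FoTrajectory, max_gap: float = 0.04, _count=None) -> FoTrajectory:
    """Linearly interpolate missing runs of duration <= ``max_gap``.

    Only runs flanked by voiced samples on both sides are filled; leading or
    trailing missing runs, and longer gaps, are untouched.
    """
    values = traj.values.copy()
    limit = _samples(max_gap, traj.sample_period)
    filled = 0
    for start, stop in _runs(np.isnan(values)):
        if stop - start > limit or start == 0 or stop == len(values):
            continue
        left, right = values[start - 1], values[stop]
        if np.isnan(left) or np.isnan(right):
            continue
        k = stop - start
        values[start:stop] = left + (right - left) * np.arange(1, k + 1) / (k + 1)
        filled += k
    if _count is not None:
        _count.samples_filled += filled
    return traj.copy(values=values)


def remove_fragments(traj: FoTrajectory, min_len: float = 0.05, _count=None) -> FoTrajectory:
    """Detach isolated voiced islands of duration <= ``min_len``.

    A fragment is a maximal voiced run bounded by missing samples or the
    track edges.  Thresholds are inclusive (a 50-ms island is removed).
    """
    values = traj.values.copy()
    limit = _samples(min_len, traj.sample_period)
    removed = 0
    for start, stop in _runs(~np.isnan(values)):
        if stop - start <= limit:
            values[start:stop] = np.nan
            removed += 1
    if _count is not None:
        _count.fragments_removed += removed
    return traj.copy(values=values)


def _first_jump(values: np.ndarray, lo: int, hi: int, jump: float, backward: bool):
    """Index i of the first pair (i, i+1) with |diff| > jump, scanning pairs
    with i in [lo, hi); backward=True scans from hi-1 down to lo."""
    seg = values[lo : hi + 1]
    with np.errstate(invalid="ignore"):
        big = np.abs(np.diff(seg)) > jump
    idx = np.flatnonzero(big)
    if idx.size == 0:
        return None
    return lo + (idx[-1] if backward else idx[0])


def trim_onset_jumps(
    traj: FoTrajectory, search_from: float = 0.20, jump: float = 100.0
) -> FoTrajectory:
    """Remove unstable data at the vocal onset and redefine the onset.

    Scanning backward from ``onset + search_from`` toward the onset, the
    first consecutive-sample difference exceeding ``jump`` cents marks the
    end of unstable vocalization: that sample and everything before it are
    detached, and the onset is redefined to the first remaining voiced
    sample.  Because redefining the onset moves the search window, the scan
    is repeated until stable (this makes refinement idempotent).
    """
    values = traj.values.copy()
    n = len(values)
    span = _samples(search_from, traj.sample_period)
    onset = traj.onset_index
    for _ in range(n):
        hi = min(onset + span, n - 1)
        i = _first_jump(values, onset, hi, jump, backward=True)
        if i is None:
            break
        values[: i + 1] = np.nan
        voiced = np.flatnonzero(~np.isnan(values))
        if voiced.size == 0:
            onset = min(i + 1, n - 1)
            break
        onset = int(voiced[0])
    offset = max(traj.offset_index, onset)
    return traj.copy(values=values, onset_index=onset, offset_index=offset)


def trim_offset_jumps(
    traj: FoTrajectory, search_from: float = 0.30, jump: float = 100.0
) -> FoTrajectory:
    """Mirror of :func:`trim_onset_jumps` at the trajectory end.

    Searches forward from ``offset - search_from``; samples from the jump to
    the offset are detached and the offset redefined to the last remaining
    voiced sample.
    """
    values = traj.values.copy()
    n = len(values)
    span = _samples(search_from, traj.sample_period)
    offset = traj.offset_index
    for _ in range(n):
        lo = max(offset - span, 0)
        i = _first_jump(values, lo, offset, jump, backward=False)
        if i is None:
            break
        values[i + 1 :] = np.nan
        voiced = np.flatnonzero(~np.isnan(values))
        if voiced.size == 0:
            offset = i
            break
        offset = int(voiced[-1])
    onset = min(traj.onset_index, offset)
    return traj.copy(values=values, onset_index=onset, offset_index=offset)


def repair_mid_jumps(
    traj: FoTrajectory,
    window: tuple[float, float] = (0.21, 1.50),
    jump: float = 100.0,
    _count=None,
) -> FoTrajectory:
    """Repair > ``jump``-cent excursions in the middle of the vocalization.

    Within [onset + 0.21 s, onset + 1.50 s], a consecutive-sample difference
    exceeding the threshold triggers replacement of subsequent samples with
    the value immediately before the jump, until the original contour
    returns within ``jump`` cents of that value (or the window ends).
    """
    values = traj.values.copy()
    dt = traj.sample_period
    lo = traj.onset_index + _samples(window[0], dt)
    hi = min(traj.onset_index + _samples(window[1], dt), len(values) - 1)
    repaired = 0
    t = max(lo, 1)
    while t <= hi:
        prev, cur = values[t - 1], values[t]
        if np.isnan(prev) or np.isnan(cur) or abs(cur - prev) <= jump:
            t += 1
            continue
        ref = prev
        repaired += 1
        while t <= hi:
            orig = traj.values[t]
            if not np.isnan(orig) and abs(orig - ref) <= jump:
                break
            if not np.isnan(values[t]):
                values[t] = ref
            t += 1
    if _count is not None:
        _count.mid_jumps_repaired += repaired
    return traj.copy(values=values)


def refine_trajectory(
    traj: FoTrajectory,
    max_gap: float = 0.04,
    min_fragment: float = 0.05,
    jump: float = 100.0,
    onset_search: float = 0.20,
    offset_search: float = 0.30,
    repair_window: tuple[float, float] = (0.21, 1.50),
    max_passes: int = 5,
) -> tuple[FoTrajectory, RefinementReport]:
    """Full refinement: fill -> remove fragments -> trim edges -> repair.

    The composition is applied repeatedly until it is a no-op (at most
    ``max_passes`` times); removals and repairs are monotone so this
    converges, and it makes the whole refinement idempotent even when an
    edge trim exposes new material to a later rule.  Trajectories left with
    less than 0.5 s of voiced data are flagged unusable.
    """
    report = RefinementReport()
    # Fast path: a fully voiced contour with no super-threshold jumps is a
    # fixed point of every rule.
    values = traj.values
    if not np.isnan(values).any() and np.all(np.abs(np.diff(values)) <= jump):
        report.usable = traj.voiced_duration >= MIN_USABLE_DURATION
        return traj, report
    current = traj
    for _ in range(max_passes):
        before = current.values.copy()
        onset_before, offset_before = current.onset_index, current.offset_index
        step = fill_gaps(current, max_gap, _count=report)
        step = remove_fragments(step, min_fragment, _count=report)
        step = trim_onset_jumps(step, onset_search, jump)
        step = trim_offset_jumps(step, offset_search, jump)
        step = repair_mid_jumps(step, repair_window, jump, _count=report)
        report.onset_shift += step.onset_index - onset_before
        report.offset_shift += step.offset_index - offset_before
        same_values = np.array_equal(step.values, before, equal_nan=True)
        if same_values and step.onset_index == onset_before and step.offset_index == offset_before:
            current = step
            break
        current = step
    report.usable = current.voiced_duration >= MIN_USABLE_DURATION
    return current, report
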