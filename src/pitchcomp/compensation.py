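"""Quantification of compensatory responses to pitch-shifted feedback.

A participant hearing their own voice shifted in f_o typically responds by
moving vocal f_o in the opposite direction.  The per-participant summary is
the *compensation ratio*: the sign-inverted slope of an ordinary
least-squares line fitted to per-trial response plateaus as a function of
the induced shift (0, +/-25, +/-50, +/-100 cents).  A ratio of 1 would be
full cancellation; typical values are around 0.4 with wide individual
spread, and participants with a non-positive ratio (no compensation) are
excluded from cohort correlations.

Pipeline per participant and vowel: detrend (remove the pointwise grand
mean over all second-vocalization trials, which removes drift common to
every trial) -> baseline-align each trial on its 50-150 ms mean -> average
the 800-1200 ms plateau -> regress plateau on shift.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import FoTrajectory

__all__ = [
    "CompensationResult",
    "detrend_cohort",
    "baseline_align",
    "plateau_mean",
    "fit_compensation_ratio",
    "percent_compensation",
    "exclude_noncompensators",
]

logger = logging.getLogger(__name__)

#: Baseline window, seconds after onset (first 50 ms excluded as unstable).
BASELINE_WINDOW = (0.05, 0.15)
#: Plateau window, seconds after onset, where the response has stabilized.
PLATEAU_WINDOW = (0.80, 1.20)


@dataclass
class CompensationResult:
    """Fitted compensation ratio for one participant and vowel."""

    participant_id: str
    vowel: str
    per_trial: pd.DataFrame  # columns: shift_cents, plateau_mean
    ratio: float
    slope_se: float
    intercept: float = 0.0
    n_trials: int = 0

    @property
    def included(self) -> bool:
        """Participants must actually compensate (ratio > 0) to be analyzed."""
        return self.ratio > 0

    def summary(self) -> str:
        return (
            f"CompensationResult({self.participant_id}/{self.vowel}): "
            f"ratio={self.ratio:.3f} (se {self.slope_se:.3f}, "
            f"{self.n_trials} trials), included={self.included}"
        )


def detrend_cohort(trials: list[FoTrajectory]) -> list[FoTrajectory]:
    """Subtract the pointwise grand mean over all trials of one participant.

    Trials are compared at sample offsets relative to their onsets; at each
    offset the mean over trials voiced there is removed, so participant-
    specific drift common to every trial (e.g. a slow settling of f_o)
    cancels.  Shorter trials are unaffected beyond their own extent.
    """
    if len(trials) < 2:
        raise ValueError("detrending needs at least two trials")
    max_len = max(len(t.values) - t.onset_index for t in trials)
    stack = np.full((len(trials), max_len), np.nan)
    for i, t in enumerate(trials):
        seg = t.values[t.onset_index :]
        stack[i, : len(seg)] = seg
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        grand = np.nanmean(stack, axis=0)
    out = []
    for t in trials:
        values = t.values.copy()
        n = len(values) - t.onset_index
        values[t.onset_index :] = values[t.onset_index :] - grand[:n]
        out.append(t.copy(values=values))
    return out


def baseline_align(
    traj: FoTrajectory, window: tuple[float, float] = BASELINE_WINDOW
) -> FoTrajectory:
    """Zero the early-vocalization baseline (mean of 50-150 ms after onset)."""
    sl = traj.window_slice(window)
    seg = traj.values[sl]
    if seg.size == 0 or np.all(np.isnan(seg)):
        raise ValueError("baseline window fully missing; trial unusable")
    return traj.copy(values=traj.values - np.nanmean(seg))


def plateau_mean(
    traj: FoTrajectory,
    window: tuple[float, float] = PLATEAU_WINDOW,
    min_voiced_fraction: float = 0.5,
) -> float:
    """Mean of voiced samples over the late plateau (800-1200 ms).

    Requires at least ``min_voiced_fraction`` of the window to be voiced;
    returns NaN otherwise so callers can flag the trial.
    """
    sl = traj.window_slice(window)
    seg = traj.values[sl]
    expected = int(round((window[1] - window[0]) / traj.sample_period))
    voiced = ~np.isnan(seg)
    if seg.size == 0 or voiced.sum() < min_voiced_fraction * expected:
        return float("nan")
    return float(seg[voiced].mean())


def fit_compensation_ratio(
    per_trial: pd.DataFrame,
    participant_id: str = "",
    vowel: str = "",
) -> CompensationResult:
    """OLS of per-trial plateau means on the induced shift; ratio = -slope.

    ``per_trial`` needs columns ``shift_cents`` and ``plateau_mean``; rows
    with NaN plateau (unusable trials) are dropped.  The fit uses per-trial
    points rather than condition means -- with a balanced design OLS gives
    the same slope either way.
    """
    data = per_trial.dropna(subset=["plateau_mean"])
    shifts = data["shift_cents"].to_numpy(float)
    plateaus = data["plateau_mean"].to_numpy(float)
    if np.unique(shifts).size < 2:
        raise ValueError("need at least two distinct shift values to fit a slope")
    fit = sps.linregress(shifts, plateaus)
    se = float(fit.stderr) if np.isfinite(fit.stderr) else 0.0
    return CompensationResult(
        participant_id=participant_id,
        vowel=vowel,
        per_trial=data.reset_index(drop=True),
        ratio=float(-fit.slope),
        slope_se=se,
        intercept=float(fit.intercept),
        n_trials=len(data),
    )


def percent_compensation(per_trial: pd.DataFrame, magnitude: float) -> float:
    """Percent of a +/-``magnitude``-cent shift that is compensated.

    Responses to positive shifts are sign-inverted and pooled with the
    negative-shift responses, so compensation opposing the shift is always
    positive; the result is ``100 * mean(pooled) / magnitude``.
    """
    data = per_trial.dropna(subset=["plateau_mean"])
    mask = np.abs(data["shift_cents"]) == magnitude
    if not mask.any():
        raise ValueError(f"no trials at +/-{magnitude} cents")
    sel = data[mask]
    comp = -np.sign(sel["shift_cents"].to_numpy(float)) * sel["plateau_mean"].to_numpy(float)
    return float(100.0 * comp.mean() / magnitude)


def exclude_noncompensators(
    results: list[CompensationResult],
) -> list[CompensationResult]:
    """Retain participants with a positive compensation ratio.

    Exclusions are logged; an empty result triggers a warning.
    """
    kept = [r for r in results if r.included]
    for r in results:
        if not r.included:
            logger.info(
                "excluding non-compensator %s/%s (ratio %.3f)",
                r.participant_id, r.vowel, r.ratio,
            )
    if not kept:
        warnings.warn("all participants excluded as non-compensators")
    return kept
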