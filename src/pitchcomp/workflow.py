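"""Orchestration: run preprocessing, per-participant indices and cohort
statistics over a trial collection (in memory or from a dataset directory)
and emit the cohort report.

The central objects are the per-participant index table (compensation
ratio, whole/slow/fast variability, detection threshold and accuracy,
relative voice amplitude, gender) and the report of cohort statistics
computed from it: correlations of each variability component with the
compensation ratio, first-vs-second-vocalization variability comparisons,
the shift-magnitude ANOVA on percent compensation, perception and
amplitude correlations, and the stepwise regression over all candidate
predictors.  Figures are emitted as data tables, keeping the analysis
surface numeric.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import compensation as comp
from . import modulation as mod
from . import preprocess as prep
from . import psychometrics as psy
from . import stats as st
from .core import FoTrajectory, read_pitch_track, read_trial_design
from .synthetic import Cohort, TrialRecord

__all__ = [
    "AnalysisConfig",
    "participant_indices",
    "build_cohort_table",
    "cohort_statistics",
    "run_cohort_analysis",
    "cohort_recovery_experiment",
    "run_analysis",
]

logger = logging.getLogger(__name__)

SHIFT_MAGNITUDES = (25.0, 50.0, 100.0)


@dataclass
class AnalysisConfig:
    """Paths and constants for a dataset-directory analysis run."""

    data_dir: str = "."
    design_path: str = "design.csv"
    listening_path: str | None = None
    amplitude_path: str | None = None  # CSV: participant_id, trial_index, amp_db
    vowel: str = "a"
    refine: bool = True
    exclude_noncompensators: bool = True
    exclude_post_shift: bool = True
    full_report: bool = False  # include per-band analyses (slower)


def _refined(records: list[TrialRecord], enable: bool) -> list[TrialRecord]:
    if not enable:
        return records
    out = []
    for r in records:
        first, rep1 = prep.refine_trajectory(r.first)
        second, rep2 = prep.refine_trajectory(r.second)
        if not (rep1.usable and rep2.usable):
            logger.info("dropping unusable trial %s/%s", r.first.participant_id, r.trial_index)
            continue
        out.append(
            TrialRecord(r.trial_index, r.vowel, r.condition, r.shift_cents,
                        r.follows_shifted_trial, first, second, r.amp_db)
        )
    return out


def participant_indices(
    records: list[TrialRecord],
    vowel: str = "a",
    refine: bool = True,
    exclude_post_shift: bool = True,
    full: bool = False,
) -> dict:
    """All per-participant indices for one vowel.

    Returns a dict with the compensation result, variability indices,
    percent compensation by magnitude, per-magnitude slow/fast variability
    of first and second vocalizations (for the vocalization-comparison
    tests), and optionally per-band quantities.
    """
    records = [r for r in records if r.vowel == vowel]
    if not records:
        raise ValueError(f"no trials for vowel {vowel!r}")
    records = _refined(records, refine)
    pid = records[0].first.participant_id

    # Windowed (whole, slow, fast) SDs for every trajectory, batched once.
    firsts_sd = mod.batch_trajectory_sds([r.first for r in records])
    seconds_sd_all = mod.batch_trajectory_sds([r.second for r in records])

    # -- spontaneous variability: first vocalizations, no after-effects ----
    eligible_mask = np.array(
        [not (exclude_post_shift and r.follows_shifted_trial) for r in records]
    )
    eligible = [r.first for r, m in zip(records, eligible_mask) if m]
    sds = firsts_sd[eligible_mask]
    sds = sds[~np.isnan(sds).any(axis=1)]
    if sds.size == 0:
        raise ValueError("no eligible first vocalizations")
    variability = mod.VariabilityIndex(*(float(v) for v in sds.mean(axis=0)), len(sds))

    # -- compensation: second vocalizations of pitch/control conditions ----
    pitch_records = [r for r in records if not r.condition.startswith("timbre")]
    seconds = comp.detrend_cohort([r.second for r in pitch_records])
    plateau_rows = []
    aligned_seconds = []
    for r, traj in zip(pitch_records, seconds):
        try:
            aligned = comp.baseline_align(traj)
        except ValueError:
            logger.info("%s trial %s: baseline missing, skipped", pid, r.trial_index)
            continue
        aligned_seconds.append((r, aligned))
        plateau_rows.append({"shift_cents": r.shift_cents, "plateau_mean": comp.plateau_mean(aligned)})
    per_trial = pd.DataFrame(plateau_rows).dropna(subset=["plateau_mean"])
    result = comp.fit_compensation_ratio(per_trial, participant_id=pid, vowel=vowel)
    percent = {m: comp.percent_compensation(per_trial, m) for m in SHIFT_MAGNITUDES}

    # -- variability of 1st vs 2nd vocalization by shift magnitude ---------
    by_magnitude: dict[float, dict[str, float]] = {}
    shifts = np.array([abs(r.shift_cents) for r in records])
    for m in SHIFT_MAGNITUDES:
        mask = shifts == m
        if not mask.any():
            continue
        by_magnitude[m] = {
            "first_slow": float(np.nanmean(firsts_sd[mask, 1])),
            "first_fast": float(np.nanmean(firsts_sd[mask, 2])),
            "second_slow": float(np.nanmean(seconds_sd_all[mask, 1])),
            "second_fast": float(np.nanmean(seconds_sd_all[mask, 2])),
        }

    out = {
        "participant_id": pid,
        "vowel": vowel,
        "compensation": result,
        "variability": variability,
        "percent_compensation": percent,
        "variability_by_magnitude": by_magnitude,
        "amp_db": float(np.mean([r.amp_db for r in records])),
        "n_trials": len(records),
    }
    if full:
        spectra = [
            mod.modulation_spectrum(mod.upsample_double(mod.center_and_fill(t)))
            for t in eligible
        ]
        out["band_centers"] = spectra[0].center_frequencies
        out["band_rms"] = np.mean([s.band_rms for s in spectra], axis=0)
        pairs100 = [(r.first, r.second) for r in records if abs(r.shift_cents) == 100.0]
        out["band_diff_100"] = mod.variability_difference(pairs100, "subbands")
    return out


def build_cohort_table(
    cohort: Cohort,
    vowels: tuple[str, ...] = ("a",),
    refine: bool = True,
    full: bool = False,
    with_listening: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Per-participant index table for a simulated cohort.

    Returns (table, extras); the table has one row per participant with the
    columns the statistics stage consumes, extras carries the per-
    participant detail dicts keyed by (participant, vowel).
    """
    rows = []
    extras: dict = {}
    for i, subject in enumerate(cohort.subjects):
        records = cohort.trials(i, vowels=vowels)
        row: dict = {"participant_id": subject.participant_id, "gender": subject.gender}
        for vowel in vowels:
            idx = participant_indices(records, vowel=vowel, refine=refine, full=full)
            extras[(subject.participant_id, vowel)] = idx
            row[f"ratio_{vowel}"] = idx["compensation"].ratio
            if vowel == vowels[0]:
                v = idx["variability"]
                row.update(var_whole=v.whole, var_slow=v.slow, var_fast=v.fast)
                row["rel_amplitude_raw"] = idx["amp_db"]
        if with_listening:
            fit = psy.fit_detection_curve(psy.pool_detection_responses(cohort.listening(i)))
            row["threshold"] = fit.threshold
            row["accuracy"] = fit.accuracy
        rows.append(row)
    table = pd.DataFrame(rows)
    if "rel_amplitude_raw" in table:
        table["rel_amplitude"] = table["rel_amplitude_raw"] - table["rel_amplitude_raw"].mean()
        table = table.drop(columns=["rel_amplitude_raw"])
    return table, extras


def cohort_statistics(
    table: pd.DataFrame,
    extras: dict | None = None,
    vowel: str = "a",
    exclude: bool = True,
) -> dict:
    """Cohort statistics from the per-participant table.

    Participants with a non-positive compensation ratio for ``vowel`` are
    excluded from correlations (they did not compensate); the stepwise
    regression uses the same subset.
    """
    ratio_col = f"ratio_{vowel}"
    data = table.copy()
    excluded = data[data[ratio_col] <= 0]["participant_id"].tolist() if exclude else []
    if exclude:
        data = data[data[ratio_col] > 0]
    report: dict = {
        "vowel": vowel,
        "n_included": int(len(data)),
        "excluded_participants": excluded,
        "correlations": {},
    }
    ratio = data[ratio_col].to_numpy(float)
    for name in ("var_whole", "var_slow", "var_fast", "threshold", "accuracy", "rel_amplitude"):
        if name in data and data[name].notna().all():
            r, p, n = st.correlation_test(data[name].to_numpy(float), ratio)
            report["correlations"][name] = {"r": r, "p": p, "n": n}

    if extras is not None:
        keyed = {k[0]: v for k, v in extras.items() if k[1] == vowel}
        included = [pid for pid in data["participant_id"] if pid in keyed]
        # percent compensation by magnitude -> repeated-measures ANOVA
        pct = np.array(
            [[keyed[pid]["percent_compensation"][m] for m in SHIFT_MAGNITUDES] for pid in included]
        )
        if len(pct) >= 2:
            F, df1, df2, p = st.repeated_anova(pct)
            report["percent_compensation"] = {
                "means": dict(zip([str(int(m)) for m in SHIFT_MAGNITUDES], pct.mean(axis=0))),
                "anova": {"F": F, "df1": df1, "df2": df2, "p": p},
                "tukey": st.tukey_kramer(pct).to_dict("records"),
            }
        # 1st vs 2nd vocalization variability at +/-100 cents
        for component in ("slow", "fast"):
            firsts, seconds = [], []
            for pid in included:
                mag = keyed[pid]["variability_by_magnitude"].get(100.0)
                if mag:
                    firsts.append(mag[f"first_{component}"])
                    seconds.append(mag[f"second_{component}"])
            if len(firsts) >= 2:
                t, df, p = st.paired_t_test(np.array(seconds), np.array(firsts))
                report[f"second_vs_first_{component}_100"] = {
                    "t": t, "df": df, "p": p,
                    "mean_difference": float(np.mean(np.array(seconds) - np.array(firsts))),
                }

    # stepwise regression over the six candidate predictors
    predictor_cols = ["var_slow", "var_fast", "threshold", "accuracy", "rel_amplitude"]
    avail = [c for c in predictor_cols if c in data and data[c].notna().all()]
    if len(avail) == len(predictor_cols) and len(data) > 10:
        X = data[avail].copy()
        X["gender"] = (data["gender"] == "f").astype(float)
        sel = st.stepwise_select(ratio, X)
        report["stepwise"] = {
            "selected": sel.selected,
            "adj_r_squared": sel.adj_r_squared,
            "sse": sel.sse,
            "df_resid": sel.df_resid,
            "terms": sel.terms.reset_index(names="term").to_dict("records"),
        }
    report["power_r037_n38"] = st.correlation_power(38, 0.37, 0.05)
    return report


def run_cohort_analysis(
    cohort: Cohort,
    vowels: tuple[str, ...] = ("a",),
    refine: bool = True,
    full: bool = False,
) -> dict:
    """Full in-memory pipeline for a simulated cohort: table + statistics."""
    table, extras = build_cohort_table(cohort, vowels=vowels, refine=refine, full=full)
    report = cohort_statistics(table, extras, vowel=vowels[0])
    report["table"] = table.to_dict("records")
    return report


def cohort_recovery_experiment(
    n_cohorts: int = 100,
    coupling: float = 0.4,
    seed: int = 0,
    n_subjects: int = 40,
    refine: bool = True,
    with_listening: bool = False,
) -> dict:
    """Parameter recovery over repeated simulated cohorts.

    For each cohort, simulate /a/-vowel trials, run the full pipeline and
    correlate estimated slow variability with the estimated compensation
    ratio (non-compensators excluded).  Reports the mean recovered
    correlation, the rejection rate at alpha = 0.05, and exclusion counts.
    """
    from .synthetic import CohortConfig, simulate_cohort

    rs, ps, n_excluded = [], [], []
    root = np.random.SeedSequence(seed)
    cohort_seeds = root.generate_state(n_cohorts) % (2**31)
    for k in range(n_cohorts):
        cfg = CohortConfig(n_subjects=n_subjects, coupling=coupling, seed=int(cohort_seeds[k]))
        cohort = simulate_cohort(cfg)
        table, _ = build_cohort_table(
            cohort, vowels=("a",), refine=refine, with_listening=with_listening
        )
        kept = table[table["ratio_a"] > 0]
        n_excluded.append(len(table) - len(kept))
        r, p, _ = st.correlation_test(
            kept["var_slow"].to_numpy(float), kept["ratio_a"].to_numpy(float)
        )
        rs.append(r)
        ps.append(p)
    rs, ps = np.array(rs), np.array(ps)
    return {
        "n_cohorts": n_cohorts,
        "coupling": coupling,
        "mean_r": float(rs.mean()),
        "sd_r": float(rs.std(ddof=1)),
        "rejection_rate": float((ps < 0.05).mean()),
        "mean_excluded": float(np.mean(n_excluded)),
    }


# ---------------------------------------------------------------------------
# Disk-based analysis
# ---------------------------------------------------------------------------

def _load_records(config: AnalysisConfig) -> dict[str, list[TrialRecord]]:
    """Load pitch tracks for all participants listed in the design table.

    Expects files ``<participant>_t<trial>_v<1|2>.csv`` (delimited pitch
    tracks) under ``data_dir``.
    """
    data_dir = Path(config.data_dir)
    design = read_trial_design(Path(config.design_path))
    amp = None
    if config.amplitude_path:
        amp = pd.read_csv(config.amplitude_path).set_index(["participant_id", "trial_index"])
    by_participant: dict[str, list[TrialRecord]] = {}
    missing = []
    for _, row in design.iterrows():
        pid, trial = row["participant_id"], int(row["trial_index"])
        paths = [data_dir / f"{pid}_t{trial:03d}_v{v}.csv" for v in (1, 2)]
        if not all(p.exists() for p in paths):
            missing.append((pid, trial))
            continue
        first = read_pitch_track(paths[0], participant_id=pid, trial_index=trial,
                                 vowel=row["vowel"], vocalization_index=1)
        second = read_pitch_track(paths[1], participant_id=pid, trial_index=trial,
                                  vowel=row["vowel"], vocalization_index=2,
                                  shift_cents=float(row["shift_cents"]))
        amp_db = float(amp.loc[(pid, trial), "amp_db"]) if amp is not None else 0.0
        by_participant.setdefault(pid, []).append(
            TrialRecord(trial, row["vowel"], row["condition"], float(row["shift_cents"]),
                        bool(row["follows_shifted_trial"]), first, second, amp_db)
        )
    if missing:
        logger.warning("missing pitch tracks for %d trials (e.g. %s)", len(missing), missing[:3])
    if not by_participant:
        raise FileNotFoundError(f"no usable trials under {data_dir}")
    return by_participant


def run_analysis(config: AnalysisConfig) -> dict:
    """Analyze a dataset directory: per-participant indices + cohort stats."""
    by_participant = _load_records(config)
    listening = pd.read_csv(config.listening_path) if config.listening_path else None
    rows, extras = [], {}
    for pid in sorted(by_participant):
        idx = participant_indices(
            by_participant[pid], vowel=config.vowel, refine=config.refine,
            exclude_post_shift=config.exclude_post_shift, full=config.full_report,
        )
        extras[(pid, config.vowel)] = idx
        v = idx["variability"]
        row = {
            "participant_id": pid, "gender": "",
            f"ratio_{config.vowel}": idx["compensation"].ratio,
            "var_whole": v.whole, "var_slow": v.slow, "var_fast": v.fast,
            "rel_amplitude_raw": idx["amp_db"],
        }
        if listening is not None:
            resp = listening[listening["participant_id"] == pid]
            if len(resp):
                fit = psy.fit_detection_curve(psy.pool_detection_responses(resp))
                row["threshold"], row["accuracy"] = fit.threshold, fit.accuracy
        rows.append(row)
    table = pd.DataFrame(rows)
    table["rel_amplitude"] = table["rel_amplitude_raw"] - table["rel_amplitude_raw"].mean()
    table = table.drop(columns=["rel_amplitude_raw"])
    report = cohort_statistics(table, extras, vowel=config.vowel,
                               exclude=config.exclude_noncompensators)
    report["table"] = table.to_dict("records")
    return report


def write_report(report: dict, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = report.pop("table", None)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    if table is not None:
        pd.DataFrame(table).to_csv(out / "cohort_table.csv", index=False)
        report["table"] = table
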