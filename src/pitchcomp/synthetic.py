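"""Synthetic cohorts with the statistical structure the analysis assumes.

Each simulated participant owns a slow-fluctuation magnitude (SD of the
<= 5 Hz component, cents), a fast magnitude (6-30 Hz), a compensation gain
(the generative analog of the compensation ratio), detection parameters of
a cumulative-normal psychometric function, a base f_o and per-vowel voice
levels.  Across the cohort the gain is affine in the slow magnitude plus
independent noise, calibrated so that the gain mean/SD and the
slow-variability/gain correlation hit their targets -- the headline
structure (larger spontaneous slow variability <-> greater compensation)
that parameter-recovery tests must re-estimate.

A vocalization is simulated as

    f_o(t) [cents] = base + slow noise + fast noise + compensation term,

where the noises are white Gaussian sequences band-limited (brick-wall, via
FFT) to 0.3-3 Hz and 8-16 Hz and scaled per trial to the subject's
magnitudes -- the bands sit at the two modulation-spectrum peaks of real
sustained vowels (intonational drift at 2-3 Hz; microtremor around 10 Hz)
and comfortably inside the analysis filters' passbands, so the variability
indices recover the generating magnitudes -- and the compensation term
opposes the feedback shift with a smooth (raised-cosine) onset that starts
at 0.15 s and is complete by 0.5 s -- fully risen well before the 0.8-1.2 s
plateau, so a noise-free subject yields the generating gain exactly.

All randomness flows from one cohort seed through spawned per-subject and
per-trial seed sequences, so any single trial is reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .core import DEFAULT_BASE_HZ, SAMPLE_PERIOD, FoTrajectory, hz_to_cents

__all__ = [
    "SubjectParams",
    "CohortConfig",
    "ArtifactRates",
    "TrialRecord",
    "Cohort",
    "make_trial_design",
    "simulate_trajectory",
    "simulate_participant",
    "simulate_cohort",
    "simulate_listening_test",
    "inject_artifacts",
    "simulate_vowel_waveform",
]

#: Compensation-onset time and raised-cosine rise duration, seconds.
RESPONSE_ONSET_S = 0.15
RESPONSE_RISE_S = 0.35

#: Spectral support of the generated noise components, Hz.
SLOW_NOISE_BAND = (0.3, 3.0)
FAST_NOISE_BAND = (8.0, 16.0)

#: Pitch-shift conditions (cents) and timbre conditions (percent).
PITCH_SHIFTS = (0, 25, -25, 50, -50, 100, -100)
TIMBRE_SHIFTS = (3, -3, 6, -6, 12, -12)

#: Absolute shifts probed in the listening test, cents.
LISTENING_SHIFTS = (0, 25, 50, 100)


@dataclass
class SubjectParams:
    """Generating parameters of one simulated participant."""

    participant_id: str
    sigma_slow: float  # cents, SD of the slow (<=5 Hz) component
    sigma_fast: float  # cents, SD of the fast (6-30 Hz) component
    gain: float  # compensation-ratio analog, dimensionless
    gain_100: float | None = None  # optional reduced gain at |shift| = 100
    theta: float = 54.7  # detection threshold, cents
    s_det: float = 14.1  # detection scale (accuracy), cents
    base_fo: float = 150.0  # Hz
    amp_a: float = 0.0  # /a/ voice level relative to cohort, dB
    amp_u: float = -6.5  # /u/ voice level, dB
    gender: str = "f"

    def __post_init__(self) -> None:
        if self.sigma_slow < 0 or self.sigma_fast < 0:
            raise ValueError("noise magnitudes must be nonnegative")
        if self.s_det <= 0:
            raise ValueError("detection scale must be positive")
        if not (-0.5 <= self.gain <= 1.5):
            raise ValueError("gain outside plausible range")


@dataclass
class ArtifactRates:
    """Expected artifact counts per trajectory (Poisson) and probabilities."""

    dropout: float = 0.0  # missing runs of 10-80 ms
    fragment: float = 0.0  # isolated voiced islands cut out by gaps
    spike: float = 0.0  # octave-jump spikes (+/-1200 cents, 10-50 ms)
    onset_harsh: float = 0.0  # probability of a harsh, jumpy onset segment


@dataclass
class CohortConfig:
    """Study-design and population parameters of a simulated cohort.

    Defaults emulate the reference design: 40 participants (half female),
    10 trials per condition and vowel over 13 conditions (6 pitch-shifted,
    6 timbre-shifted -- f_o-neutral -- and 1 control), slow variability
    ~ N(13.07, 3.72) cents, gain mean/SD 0.39/0.21, and a target
    slow-variability/gain correlation of 0.4.
    """

    n_subjects: int = 40
    coupling: float = 0.4
    gain_mean: float = 0.39
    gain_sd: float = 0.21
    sigma_slow_mean: float = 13.07
    sigma_slow_sd: float = 3.72
    sigma_fast_mean: float = 3.50
    sigma_fast_sd: float = 1.2
    theta_mean: float = 54.71
    theta_sd: float = 16.69
    s_det_mean: float = 14.13
    s_det_sd: float = 11.48
    vowel_amp_diff: float = 6.5  # /a/ minus /u/ level, dB
    vowel_amp_diff_sd: float = 2.8
    amp_between_sd: float = 3.0  # between-subject /a/ level SD, dB
    gain100_factor: float = 0.85  # gain at |shift|=100 relative to gain
    trials_per_condition: int = 10
    include_timbre: bool = True
    seed: int = 0
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)

    def __post_init__(self) -> None:
        if not (-1 < self.coupling < 1):
            raise ValueError("|coupling| must be < 1")
        if self.gain_sd <= 0 or self.sigma_slow_sd <= 0:
            raise ValueError("population SDs must be positive")


@dataclass
class TrialRecord:
    """One simulated trial: design row plus its two vocalizations."""

    trial_index: int
    vowel: str
    condition: str
    shift_cents: float
    follows_shifted_trial: bool
    first: FoTrajectory
    second: FoTrajectory
    amp_db: float = 0.0


# ---------------------------------------------------------------------------
# Trial design
# ---------------------------------------------------------------------------

def make_trial_design(
    participant_id: str = "S00",
    trials_per_condition: int = 10,
    vowels: tuple[str, ...] = ("a", "u"),
    include_timbre: bool = True,
    seed=None,
) -> pd.DataFrame:
    """Pseudo-randomized trial order over all conditions and vowels.

    The timbre-shifted conditions do not move f_o and are excluded from the
    pitch analyses, but including them in the order matters: whether a trial
    *follows* an f_o-shifted trial (and is therefore excluded from the
    spontaneous-variability estimate) depends on the full 13-condition
    sequence.
    """
    rows = []
    for vowel in vowels:
        for shift in PITCH_SHIFTS:
            label = "control" if shift == 0 else f"pitch{shift:+d}"
            rows += [(vowel, label, float(shift))] * trials_per_condition
        if include_timbre:
            for pct in TIMBRE_SHIFTS:
                rows += [(vowel, f"timbre{pct:+d}", 0.0)] * trials_per_condition
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]
    design = pd.DataFrame(rows, columns=["vowel", "condition", "shift_cents"])
    design.insert(0, "participant_id", participant_id)
    design.insert(1, "trial_index", np.arange(len(design)))
    is_fo_shifted = design["condition"].str.startswith("pitch").to_numpy()
    follows = np.concatenate(([False], is_fo_shifted[:-1]))
    design["follows_shifted_trial"] = follows
    return design


# ---------------------------------------------------------------------------
# Trajectory synthesis
# ---------------------------------------------------------------------------

def _spawn_fixed(ss: np.random.SeedSequence, k: int) -> list[np.random.SeedSequence]:
    """Stateless version of ``SeedSequence.spawn``: the i-th child is always
    the same object regardless of how often this is called."""
    return [
        np.random.SeedSequence(entropy=ss.entropy, spawn_key=ss.spawn_key + (i,))
        for i in range(k)
    ]


def _response_ramp(times: np.ndarray) -> np.ndarray:
    """Raised-cosine onset: 0 before 0.15 s, 1 from 0.5 s on."""
    u = (times - RESPONSE_ONSET_S) / RESPONSE_RISE_S
    ramp = np.clip(u, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * ramp))


def _band_noise(white: np.ndarray, rate: float, band: tuple[float, float], sigma) -> np.ndarray:
    """Brick-wall band-limit white noise and scale each row to SD ``sigma``."""
    if np.all(np.asarray(sigma) == 0):
        return np.zeros_like(white)
    n = white.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    spectrum = np.fft.rfft(white, axis=-1)
    spectrum[..., (freqs < band[0]) | (freqs > band[1])] = 0.0
    shaped = np.fft.irfft(spectrum, n, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    scale = np.asarray(sigma, float)
    if white.ndim == 2:
        scale = scale.reshape(-1, 1)
    return shaped / sd * scale


def simulate_trajectory(
    subject: SubjectParams,
    shift: float = 0.0,
    vocalization_index: int = 1,
    duration: float = 2.0,
    seed=None,
    **metadata,
) -> FoTrajectory:
    """Simulate one vocalization's f_o contour (cents re 55 Hz).

    The first vocalization never carries a shift; the second responds to
    the feedback shift with the subject's gain (``gain_100`` at +/-100
    cents when set).  Same seed, same trajectory.
    """
    if vocalization_index == 1 and shift != 0:
        raise ValueError("first vocalization is always unshifted")
    n = int(round(duration / SAMPLE_PERIOD))
    rate = 1.0 / SAMPLE_PERIOD
    rng = np.random.default_rng(seed)
    white_slow = rng.standard_normal(n)
    white_fast = rng.standard_normal(n)
    slow = _band_noise(white_slow, rate, SLOW_NOISE_BAND, subject.sigma_slow)
    fast = _band_noise(white_fast, rate, FAST_NOISE_BAND, subject.sigma_fast)
    values = hz_to_cents(subject.base_fo) + slow + fast
    if vocalization_index == 2 and shift != 0:
        gain = subject.gain
        if abs(shift) == 100 and subject.gain_100 is not None:
            gain = subject.gain_100
        times = np.arange(n) * SAMPLE_PERIOD
        values = values - gain * shift * _response_ramp(times)
    return FoTrajectory(
        values=values,
        participant_id=subject.participant_id,
        vocalization_index=vocalization_index,
        shift_cents=shift if vocalization_index == 2 else 0.0,
        **metadata,
    )


def simulate_participant(
    subject: SubjectParams,
    design: pd.DataFrame,
    seed=None,
    vowels: tuple[str, ...] | None = None,
    duration: float = 2.0,
    artifact_rates: ArtifactRates | None = None,
) -> list[TrialRecord]:
    """Simulate all trials of one participant according to ``design``.

    Noise shaping is batched over trials for speed (one zero-phase filter
    call per band), which is numerically identical to per-trial calls; the
    per-trial seeds spawned from ``seed`` make any single trial
    reproducible with :func:`simulate_trajectory`.
    """
    rows = design if vowels is None else design[design["vowel"].isin(vowels)]
    n_rows = len(rows)
    n = int(round(duration / SAMPLE_PERIOD))
    rate = 1.0 / SAMPLE_PERIOD
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    # Seeds are indexed by the design's own trial_index so a trial gets the
    # same noise regardless of which vowel subset is simulated.
    n_total = int(design["trial_index"].max()) + 1
    children = _spawn_fixed(ss, 2 * n_total + 1)
    amp_rng = np.random.default_rng(children[-1])
    trial_children = [children[2 * int(r)] for r in rows["trial_index"]]
    trial_children2 = [children[2 * int(r) + 1] for r in rows["trial_index"]]

    white_slow = np.empty((2 * n_rows, n))
    white_fast = np.empty((2 * n_rows, n))
    for i in range(n_rows):
        for j, child in ((2 * i, trial_children[i]), (2 * i + 1, trial_children2[i])):
            rng = np.random.default_rng(child)
            white_slow[j] = rng.standard_normal(n)
            white_fast[j] = rng.standard_normal(n)
    slow = _band_noise(white_slow, rate, SLOW_NOISE_BAND, np.full(2 * n_rows, subject.sigma_slow))
    fast = _band_noise(white_fast, rate, FAST_NOISE_BAND, np.full(2 * n_rows, subject.sigma_fast))
    base = hz_to_cents(subject.base_fo)
    contours = base + slow + fast

    times = np.arange(n) * SAMPLE_PERIOD
    ramp = _response_ramp(times)
    records = []
    for i, row in enumerate(rows.to_dict("records")):
        shift = float(row["shift_cents"])
        first_vals = contours[2 * i]
        second_vals = contours[2 * i + 1].copy()
        if shift != 0:
            gain = subject.gain
            if abs(shift) == 100 and subject.gain_100 is not None:
                gain = subject.gain_100
            second_vals -= gain * shift * ramp
        meta = dict(
            participant_id=subject.participant_id,
            trial_index=int(row["trial_index"]),
            vowel=row["vowel"],
        )
        first = FoTrajectory(values=first_vals.copy(), vocalization_index=1, **meta)
        second = FoTrajectory(values=second_vals, vocalization_index=2,
                              shift_cents=shift, **meta)
        if artifact_rates is not None:
            first, _ = inject_artifacts(
                first, artifact_rates, seed=_spawn_fixed(trial_children[i], 1)[0]
            )
            second, _ = inject_artifacts(
                second, artifact_rates, seed=_spawn_fixed(trial_children2[i], 1)[0]
            )
        level = subject.amp_a if row["vowel"] == "a" else subject.amp_u
        records.append(
            TrialRecord(
                trial_index=int(row["trial_index"]),
                vowel=row["vowel"],
                condition=row["condition"],
                shift_cents=shift,
                follows_shifted_trial=bool(row["follows_shifted_trial"]),
                first=first,
                second=second,
                amp_db=level + amp_rng.normal(0.0, 1.5),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lower, size=None):
    x = rng.normal(mean, sd, size)
    bad = x <= lower
    while np.any(bad):
        x = np.where(bad, rng.normal(mean, sd, size), x)
        bad = x <= lower
    return x


@dataclass
class Cohort:
    """A simulated cohort: subjects, per-subject seeds, and the truth table."""

    config: CohortConfig
    subjects: list[SubjectParams]
    truth: pd.DataFrame
    # per subject: (design_ss, trials_ss, listening_ss), spawned once so that
    # repeated calls are reproducible
    _subject_seeds: list[tuple] = field(repr=False, default_factory=list)

    def design(self, index: int, vowels: tuple[str, ...] | None = None) -> pd.DataFrame:
        design_ss, _, _ = self._subject_seeds[index]
        d = make_trial_design(
            self.subjects[index].participant_id,
            self.config.trials_per_condition,
            include_timbre=self.config.include_timbre,
            seed=design_ss,
        )
        return d if vowels is None else d[d["vowel"].isin(vowels)].reset_index(drop=True)

    def trials(self, index: int, vowels: tuple[str, ...] | None = None) -> list[TrialRecord]:
        _, trials_ss, _ = self._subject_seeds[index]
        rates = self.config.artifact_rates
        use_rates = rates if any(
            (rates.dropout, rates.fragment, rates.spike, rates.onset_harsh)
        ) else None
        return simulate_participant(
            self.subjects[index], self.design(index), seed=trials_ss,
            vowels=vowels, artifact_rates=use_rates,
        )

    def listening(self, index: int, reps_per_abs_shift: int = 8) -> pd.DataFrame:
        _, _, listening_ss = self._subject_seeds[index]
        return simulate_listening_test(
            self.subjects[index], reps_per_abs_shift=reps_per_abs_shift, seed=listening_ss
        )


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Draw a cohort of subjects with the configured population structure.

    ``gain = a + b * sigma_slow + e`` with (a, b, var(e)) solved so the gain
    mean, SD and the sigma_slow/gain correlation match the config (moments
    are nominal, i.e. pre-truncation).  The truth table records every
    generating parameter for parameter-recovery checks.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_subjects + 1)
    rng = np.random.default_rng(children[0])
    subject_seeds = children[1:]

    resid_var = cfg.gain_sd**2 * (1 - cfg.coupling**2)
    b = cfg.coupling * cfg.gain_sd / cfg.sigma_slow_sd

    subjects = []
    rows = []
    for i in range(cfg.n_subjects):
        pid = f"S{i:02d}"
        gender = "f" if i < cfg.n_subjects / 2 else "m"
        sigma_slow = float(_truncated_normal(rng, cfg.sigma_slow_mean, cfg.sigma_slow_sd, 2.0))
        sigma_fast = float(_truncated_normal(rng, cfg.sigma_fast_mean, cfg.sigma_fast_sd, 0.5))
        gain = float(
            cfg.gain_mean + b * (sigma_slow - cfg.sigma_slow_mean)
            + rng.normal(0.0, math.sqrt(resid_var))
        )
        gain = float(np.clip(gain, -0.5, 1.5))
        theta = float(_truncated_normal(rng, cfg.theta_mean, cfg.theta_sd, 5.0))
        s_det = float(_truncated_normal(rng, cfg.s_det_mean, cfg.s_det_sd, 0.5))
        base_fo = float(rng.normal(220.0, 20.0) if gender == "f" else rng.normal(120.0, 15.0))
        amp_a = float(rng.normal(0.0, cfg.amp_between_sd))
        amp_u = amp_a - float(rng.normal(cfg.vowel_amp_diff, cfg.vowel_amp_diff_sd))
        subj = SubjectParams(
            participant_id=pid,
            sigma_slow=sigma_slow,
            sigma_fast=sigma_fast,
            gain=gain,
            gain_100=cfg.gain100_factor * gain if cfg.gain100_factor is not None else None,
            theta=theta,
            s_det=s_det,
            base_fo=max(base_fo, 75.0),
            amp_a=amp_a,
            amp_u=amp_u,
            gender=gender,
        )
        subjects.append(subj)
        rows.append(
            {
                "participant_id": pid, "gender": gender,
                "sigma_slow": sigma_slow, "sigma_fast": sigma_fast,
                "gain": gain, "gain_100": subj.gain_100,
                "theta": theta, "s_det": s_det,
                "base_fo": subj.base_fo, "amp_a": amp_a, "amp_u": amp_u,
            }
        )
    return Cohort(
        cfg, subjects, pd.DataFrame(rows), [tuple(_spawn_fixed(s, 3)) for s in subject_seeds]
    )


# ---------------------------------------------------------------------------
# Listening test
# ---------------------------------------------------------------------------

def simulate_listening_test(
    subject: SubjectParams, reps_per_abs_shift: int = 8, seed=None
) -> pd.DataFrame:
    """Bernoulli detection responses: P(yes) = Phi((|shift| - theta)/s).

    Repetitions cycle over the 2 directions x 2 vowels x 2 trials structure
    of the pooled design (direction is irrelevant to the detection model
    but recorded for pooling code to exercise).
    """
    from scipy.stats import norm

    rng = np.random.default_rng(seed)
    rows = []
    for abs_shift in LISTENING_SHIFTS:
        p = norm.cdf((abs_shift - subject.theta) / subject.s_det)
        for rep in range(reps_per_abs_shift):
            if abs_shift == 0:
                # no direction at zero shift: vowel x trial only
                sign, vowel, repetition = 1, ("a" if rep % 2 == 0 else "u"), rep // 2
            else:
                sign = -1 if rep % 2 else 1
                vowel = "a" if (rep // 2) % 2 == 0 else "u"
                repetition = rep // 4
            rows.append(
                {
                    "participant_id": subject.participant_id,
                    "shift_cents": sign * abs_shift,
                    "vowel": vowel,
                    "repetition": repetition,
                    "detected": int(rng.random() < p),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Artifacts and waveforms
# ---------------------------------------------------------------------------

def inject_artifacts(
    traj: FoTrajectory, rates: ArtifactRates, seed=None
) -> tuple[FoTrajectory, list[dict]]:
    """Insert tracking artifacts, returning the damaged trajectory and a log.

    Dropouts (10-80 ms missing runs), isolated fragments (a short voiced
    island cut out by fresh gaps), octave-jump spikes (+/-1200 cents,
    10-50 ms) in the repairable mid region, and a harsh onset segment with
    > 100-cent sample-to-sample jumps.
    """
    rng = np.random.default_rng(seed)
    values = traj.values.copy()
    n = len(values)
    log: list[dict] = []

    for _ in range(rng.poisson(rates.dropout)):
        length = rng.integers(1, 9)
        start = rng.integers(traj.onset_index + 25, max(n - 35, traj.onset_index + 26))
        values[start : start + length] = np.nan
        log.append({"type": "dropout", "start": int(start), "length": int(length)})

    for _ in range(rng.poisson(rates.spike)):
        length = rng.integers(1, 6)
        lo = traj.onset_index + 25
        hi = min(traj.onset_index + 145, n - 10)
        start = rng.integers(lo, hi)
        values[start : start + length] += 1200.0 * rng.choice([-1.0, 1.0])
        log.append({"type": "spike", "start": int(start), "length": int(length)})

    for _ in range(rng.poisson(rates.fragment)):
        island = rng.integers(1, 6)
        gap = rng.integers(5, 9)
        start = rng.integers(traj.onset_index + 30, max(n - 40, traj.onset_index + 31))
        values[start - gap : start] = np.nan
        values[start + island : start + island + gap] = np.nan
        log.append({"type": "fragment", "start": int(start), "length": int(island)})

    if rng.random() < rates.onset_harsh:
        length = int(rng.integers(3, 16))
        seg = slice(traj.onset_index, traj.onset_index + length)
        offsets = rng.uniform(150.0, 400.0, length) * rng.choice([-1.0, 1.0], length)
        values[seg] = values[seg] + offsets
        log.append({"type": "onset_harsh", "start": traj.onset_index, "length": length})

    return traj.copy(values=values), log


def simulate_vowel_waveform(
    traj: FoTrajectory,
    level: float = -20.0,
    rate: int = 16000,
    seed=None,
    lead_silence: float = 0.25,
    tail_silence: float = 0.25,
) -> tuple[np.ndarray, int]:
    """Render a minimal harmonic-tone waveform following the f_o contour.

    Five harmonics at fixed relative levels (0, -6, -12, -18, -24 dB), with
    the overall scale calibrated so the A-weighted level of the voiced part
    equals ``level`` dB (re full scale).  Silence (plus a faint noise floor
    for background estimation) surrounds the vocalization.
    """
    from .amplitude import a_weight
    from .core import cents_to_hz

    rng = np.random.default_rng(seed)
    cents = traj.values.copy()
    voiced = ~np.isnan(cents)
    if not voiced.any():
        raise ValueError("cannot synthesize an all-unvoiced trajectory")
    idx = np.arange(len(cents))
    cents = np.interp(idx, idx[voiced], cents[voiced])
    f0 = cents_to_hz(cents, traj.base_hz)

    t_traj = idx * traj.sample_period
    n_voice = int(round((t_traj[-1] + traj.sample_period) * rate))
    t_audio = np.arange(n_voice) / rate
    f0_audio = np.interp(t_audio, t_traj, f0)
    phase = 2 * np.pi * np.cumsum(f0_audio) / rate
    tone = np.zeros(n_voice)
    for h in range(1, 6):
        tone += 10 ** (-6.0 * (h - 1) / 20.0) * np.sin(h * phase)
    edge = int(round(0.01 * rate))
    envelope = np.ones(n_voice)
    fade = 0.5 * (1 - np.cos(np.pi * np.arange(edge) / edge))
    envelope[:edge] = fade
    envelope[-edge:] = fade[::-1]
    tone *= envelope

    weighted = a_weight(tone, rate)
    rms = np.sqrt(np.mean(weighted**2))
    tone *= 10 ** (level / 20.0) / rms

    n_lead = int(round(lead_silence * rate))
    n_tail = int(round(tail_silence * rate))
    out = np.concatenate([np.zeros(n_lead), tone, np.zeros(n_tail)])
    out += rng.normal(0.0, 10 ** (-80.0 / 20.0), out.size)  # -80 dB noise floor
    return out, rate
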