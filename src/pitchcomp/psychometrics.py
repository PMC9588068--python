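"""Pitch-shift detection: pooling listening-test responses and fitting a
cumulative-normal psychometric function.

Listeners judged whether the second voice in a replayed trial pair carried a
pitch modification.  Responses are pooled over shift direction and vowel
(8 repetitions per absolute shift in the complete design: 2 directions x
2 vowels x 2 trials), giving a detection rate per absolute shift (0, 25,
50, 100 cents).  A two-parameter cumulative normal

    rate(x) = Phi((x - threshold) / accuracy)

is fitted by unweighted least squares on the rates; ``threshold`` is the
50%-detection point and ``accuracy`` the sigmoid shallowness (both in
cents; despite the name, *larger* accuracy means a shallower curve).  No
lapse or guess parameters are used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

__all__ = ["PsychometricFit", "pool_detection_responses", "fit_detection_curve"]

#: A fitted scale below this fraction of the smallest gap between tested
#: levels means the data look like a perfect step: the scale is then only
#: bounded above, not identified.
_NEAR_DEGENERATE_FRACTION = 0.1


@dataclass
class PsychometricFit:
    """Cumulative-normal detection curve: location and scale in cents."""

    threshold: float
    accuracy: float
    rates: pd.DataFrame  # columns: abs_shift, k_detected, n, rate
    converged: bool
    near_degenerate: bool = False
    residual_rms: float = float("nan")

    def predict(self, abs_shift) -> np.ndarray:
        return norm.cdf((np.asarray(abs_shift, float) - self.threshold) / self.accuracy)

    def summary(self) -> str:
        flag = " (near-degenerate)" if self.near_degenerate else ""
        return (
            f"PsychometricFit: threshold={self.threshold:.2f} cents, "
            f"accuracy={self.accuracy:.2f} cents, converged={self.converged}{flag}"
        )


def pool_detection_responses(responses: pd.DataFrame) -> pd.DataFrame:
    """Pool yes/no responses over shift sign and vowel into rate rows.

    ``responses`` needs columns ``shift_cents``, ``vowel``, ``repetition``
    and ``detected`` (0/1).  Rows are grouped by ``|shift_cents|``; the
    number of repetitions actually present is recorded (no padding), and
    duplicate (shift, vowel, repetition) keys raise.
    """
    required = {"shift_cents", "vowel", "repetition", "detected"}
    missing = required - set(responses.columns)
    if missing:
        raise ValueError(f"response table missing columns: {sorted(missing)}")
    keys = responses[["shift_cents", "vowel", "repetition"]]
    if keys.duplicated().any():
        raise ValueError("duplicate trial keys in listening responses")
    pooled = (
        responses.assign(abs_shift=responses["shift_cents"].abs())
        .groupby("abs_shift", as_index=False)
        .agg(k_detected=("detected", "sum"), n=("detected", "size"))
    )
    pooled["rate"] = pooled["k_detected"] / pooled["n"]
    return pooled.sort_values("abs_shift", ignore_index=True)


def _initial_guess(x: np.ndarray, rate: np.ndarray) -> tuple[float, float]:
    # crude 50%-crossing by linear interpolation, scale from the x span
    order = np.argsort(x)
    xs, rs = x[order], rate[order]
    theta = float(np.interp(0.5, np.clip(rs, 0, 1), xs)) if rs.max() > 0.5 > rs.min() else float(xs.mean())
    scale = max((xs.max() - xs.min()) / 4.0, 1.0)
    return theta, scale


def fit_detection_curve(rates: pd.DataFrame) -> PsychometricFit:
    """Least-squares cumulative-normal fit to pooled detection rates.

    Requires at least two distinct absolute shifts with differing rates;
    otherwise the location is unidentifiable and ``converged`` is False.
    Step-like data drive the scale toward zero and are flagged
    ``near_degenerate``.
    """
    x = rates["abs_shift"].to_numpy(float)
    r = rates["rate"].to_numpy(float)
    if np.unique(x).size < 2 or np.allclose(r, r[0]):
        return PsychometricFit(float("nan"), float("nan"), rates, converged=False)

    def residuals(params):
        theta, scale = params
        return norm.cdf((x - theta) / scale) - r

    theta0, scale0 = _initial_guess(x, r)
    result = optimize.least_squares(
        residuals,
        x0=[theta0, scale0],
        bounds=([-np.inf, 1e-6], [np.inf, np.inf]),
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    theta, scale = result.x
    min_gap = float(np.min(np.diff(np.unique(x))))
    return PsychometricFit(
        threshold=float(theta),
        accuracy=float(scale),
        rates=rates,
        converged=bool(result.success),
        near_degenerate=bool(scale < _NEAR_DEGENERATE_FRACTION * min_gap),
        residual_rms=float(np.sqrt(np.mean(result.fun**2))),
    )
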