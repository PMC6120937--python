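"""Cosine tuning-curve fits and preferred-direction trial categorization.

Each unit's mean planning-period rate as a function of reach direction θ is
fit with F(θ) = a + b·cos(θ − φ) via its linear form a + c1·cosθ + c2·sinθ,
or with the doubled-frequency variant a + b·cos(2(θ − φ)) whose two peaks
define a preferred axis.  Significance comes from a direction-shuffle
bootstrap on the fitted amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PRO_ANTI_HALF_WIDTH_DEG = 22.5
PD_AXIS_MAX_DEG = 30.0


@dataclass
class TuningFit:
    """Fitted cosine-tuning parameters for one unit.

    ``b`` is non-negative by convention (the phase absorbs the sign);
    ``preferred_axis`` (φ mod π) is populated only for the doubled model.
    ``tunable`` is False for constant input, where φ is undefined and
    stored as 0.
    """

    a: float
    b: float
    phi: float
    model: str  # "single" | "doubled"
    significant: bool | None = None
    preferred_axis: float | None = None
    tunable: bool = True

    def predict(self, theta: np.ndarray | float) -> np.ndarray:
        k = 2.0 if self.model == "doubled" else 1.0
        return self.a + self.b * np.cos(k * (np.asarray(theta) - self.phi))


def _fit_harmonic(mean_rates: np.ndarray, directions: np.ndarray, k: float):
    X = np.column_stack(
        [np.ones_like(directions), np.cos(k * directions), np.sin(k * directions)]
    )
    coef, *_ = np.linalg.lstsq(X, mean_rates, rcond=None)
    a, c1, c2 = coef
    b = float(np.hypot(c1, c2))
    phi = float(np.arctan2(c2, c1) / k % (2.0 * np.pi / k))
    return float(a), b, phi


def _check_inputs(mean_rates, directions):
    mean_rates = np.asarray(mean_rates, dtype=float)
    directions = np.asarray(directions, dtype=float)
    if mean_rates.shape != directions.shape:
        raise ValueError("mean_rates and directions must have the same shape")
    if np.unique(np.round(directions, 9)).size < 3:
        raise ValueError("need at least 3 distinct directions to fit a cosine")
    return mean_rates, directions


def fit_cosine_tuning(mean_rates, directions) -> TuningFit:
    """Least-squares cosine fit of per-direction mean rates.

    Constant input yields b = 0 with φ stored as 0 and ``tunable=False``.
    """
    mean_rates, directions = _check_inputs(mean_rates, directions)
    a, b, phi = _fit_harmonic(mean_rates, directions, k=1.0)
    tunable = b > 1e-12
    return TuningFit(a=a, b=b, phi=phi if tunable else 0.0,
                     model="single", tunable=tunable)


def fit_doubled_cosine(mean_rates, directions) -> TuningFit:
    """Doubled-frequency cosine fit; its two peaks define the preferred axis."""
    mean_rates, directions = _check_inputs(mean_rates, directions)
    a, b, phi = _fit_harmonic(mean_rates, directions, k=2.0)
    tunable = b > 1e-12
    phi = phi if tunable else 0.0
    return TuningFit(a=a, b=b, phi=phi, model="doubled",
                     preferred_axis=phi % np.pi, tunable=tunable)


def bootstrap_tuning_significance(
    trial_rates,
    trial_directions,
    n_boot: int = 1000,
    alpha_quantile: float = 0.99,
    model: str = "single",
    seed: int = 0,
) -> bool:
    """Direction-shuffle test of tuning amplitude on per-trial activity.

    The unit is significantly tuned iff the amplitude fit to the true
    direction labels exceeds the ``alpha_quantile`` quantile of amplitudes
    refit after shuffling labels across trials.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    trial_rates = np.asarray(trial_rates, dtype=float)
    trial_directions = np.asarray(trial_directions, dtype=float)
    uniq, dir_idx = np.unique(trial_directions, return_inverse=True)
    if uniq.size < 3:
        raise ValueError("need at least 3 distinct directions")
    k = 2.0 if model == "doubled" else 1.0
    X = np.column_stack([np.ones_like(uniq), np.cos(k * uniq), np.sin(k * uniq)])
    P = np.linalg.pinv(X)  # fixed design: shuffles only permute group means
    counts = np.bincount(dir_idx, minlength=uniq.size)

    def amplitude(idx: np.ndarray) -> float:
        sums = np.bincount(idx, weights=trial_rates, minlength=uniq.size)
        coef = P @ (sums / counts)
        return float(np.hypot(coef[1], coef[2]))

    observed = amplitude(dir_idx)
    rng = np.random.default_rng(seed)
    null = np.empty(n_boot)
    for i in range(n_boot):
        null[i] = amplitude(rng.permutation(dir_idx))
    return bool(observed > np.quantile(null, alpha_quantile))


def angular_difference_deg(x_deg: float, y_deg: float, period_deg: float = 360.0) -> float:
    """Minimal absolute angular difference on a circle of the given period."""
    d = (x_deg - y_deg) % period_deg
    return float(min(d, period_deg - d))


def check_pd_axis_consistency(
    single: TuningFit, doubled: TuningFit, max_deg: float = PD_AXIS_MAX_DEG
) -> bool:
    """True iff the preferred direction and preferred axis agree within max_deg.

    The comparison is mod 180° since the axis is direction-agnostic.
    """
    pd_deg = np.degrees(single.phi)
    axis_deg = np.degrees(doubled.preferred_axis if doubled.preferred_axis is not None
                          else doubled.phi)
    return angular_difference_deg(pd_deg, axis_deg, period_deg=180.0) <= max_deg


def categorize_trial_responses(fit: TuningFit, trial_direction: float) -> str:
    """Label a trial pro/anti/orthogonal relative to the unit's PD.

    Pro if the reach direction is within 22.5° of the PD, anti if within
    22.5° of PD+180°, orthogonal if within 22.5° of either perpendicular,
    otherwise "none".  Boundaries are closed; an exact tie goes to the
    earlier category in the order pro < anti < orthogonal.
    """
    delta = angular_difference_deg(np.degrees(trial_direction), np.degrees(fit.phi))
    if delta <= PRO_ANTI_HALF_WIDTH_DEG:
        return "pro_pd"
    if abs(delta - 180.0) <= PRO_ANTI_HALF_WIDTH_DEG:
        return "anti_pd"
    if abs(delta - 90.0) <= PRO_ANTI_HALF_WIDTH_DEG:
        return "orthogonal_pd"
    return "none"
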