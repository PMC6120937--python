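"""Linking decoded reach plans to behavior.

Covers the behavioral analyses built on the ΔProximity read-out: target-axis
planning preferences on cued two-target trials, prediction of Free-Choice
reaches from Target Blank activity, reaction time from hand speed, the
RT-vs-plan-strength regression (per-direction slopes and a mixed model with
uncorrelated random intercept and slope per direction×session group), and
the three-way typing of error trials from decoded plans in the late-Blank,
late-Cue, and pre-Go windows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .preprocessing import RateMatrix, epoch_window
from .state_space import DirectionClusterSet, StateSpaceModel, proximity_matrix
from .synthetic_data import KinematicsTrace, TrialRecord, opposite_direction

logger = logging.getLogger(__name__)

DEAD_BAND = 0.05
"""|ΔProximity| below this is treated as "no plan" in sign-based read-outs."""

RT_SPEED_THRESHOLD_CM_S = 5.0


# ---------------------------------------------------------------------------
# ΔProximity traces


def delta_proximity_traces(
    model: StateSpaceModel,
    rates: RateMatrix,
    trials: Sequence[TrialRecord],
    clusters: DirectionClusterSet,
    toward: str = "presented",
    windows_ms: dict[int, list[tuple[float, float]]] | None = None,
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Per-trial (bin_times, ΔProximity) with the sign toward a reference.

    ``toward`` picks the positive direction: the presented target
    ("presented", i.e. the favored axis end on two-target trials), the cue
    ("cue"), or the eventual choice ("choice").  ``windows_ms`` optionally
    restricts the computation to the union of [start, end) windows per
    trial id (proximity evaluation is the expensive step).
    """
    out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for trial in trials:
        if toward == "cue":
            ref = trial.cue_direction
            if ref is None:
                continue
        elif toward == "choice":
            ref = trial.choice
        else:
            ref = trial.presented_direction
        t = rates.bin_times[trial.trial_id]
        mask = np.ones(t.size, dtype=bool)
        if windows_ms is not None:
            mask = np.zeros(t.size, dtype=bool)
            for start, end in windows_ms.get(trial.trial_id, []):
                mask |= (t >= start) & (t < end)
            if not mask.any():
                continue
        states = model.project(rates.values[trial.trial_id][:, mask].T)
        prox = proximity_matrix(states, clusters)
        dp = prox[:, ref] - prox[:, opposite_direction(ref)]
        out[trial.trial_id] = (t[mask], dp)
    return out


def _window_mean(
    trace: tuple[np.ndarray, np.ndarray], window: tuple[float, float]
) -> float:
    t, dp = trace
    mask = (t >= window[0]) & (t < window[1])
    return float(dp[mask].mean()) if mask.any() else np.nan


# ---------------------------------------------------------------------------
# axis preferences


@dataclass
class AxisPreference:
    """Fraction of Target Blank ΔProximity mass favoring each axis end.

    ``frac_first`` + ``frac_second`` = 1 over the bins outside the dead
    band; ``defined`` is False when every bin fell inside it.
    """

    axis: int
    frac_first: float
    frac_second: float
    n_bins_used: int
    n_bins_dead: int
    defined: bool = True


def decode_axis_preference(
    traces: dict[int, tuple[np.ndarray, np.ndarray]],
    trials: Sequence[TrialRecord],
    axis: int,
    dead_band: float = DEAD_BAND,
    by: str = "bins",
) -> AxisPreference:
    """Planning preference of one target axis from Target Blank ΔProximity.

    Counts Blank bins (or trials via their mean, ``by="trials"``) with
    positive vs negative ΔProximity toward the axis's first end; values
    within the dead band are excluded and counted separately.
    """
    values: list[float] = []
    for trial in trials:
        if trial.presented_direction % 4 != axis or trial.trial_id not in traces:
            continue
        win = epoch_window(trial, "blank")
        t, dp = traces[trial.trial_id]
        mask = (t >= win[0]) & (t < win[1])
        if by == "trials":
            if mask.any():
                values.append(float(dp[mask].mean()))
        else:
            values.extend(dp[mask].tolist())
    vals = np.asarray(values)
    dead = np.abs(vals) <= dead_band
    used = vals[~dead]
    if used.size == 0:
        logger.info("axis %d: preference undefined (all bins in dead band)", axis)
        return AxisPreference(axis, np.nan, np.nan, 0, int(dead.sum()), defined=False)
    frac = float(np.mean(used > 0))
    return AxisPreference(axis, frac, 1.0 - frac, int(used.size), int(dead.sum()))


# ---------------------------------------------------------------------------
# Free-Choice prediction


@dataclass
class FreeChoicePrediction:
    """Choice prediction from Target Blank ΔProximity on Free-Choice trials."""

    trial_ids: np.ndarray
    predicted: np.ndarray
    actual: np.ndarray
    accuracy: float
    accuracy_favored: float
    accuracy_nonfavored: float
    n_undecided: int
    preference_choice_correlation: float


def free_choice_prediction(
    traces: dict[int, tuple[np.ndarray, np.ndarray]],
    trials: Sequence[TrialRecord],
    cued_preferences: Sequence[AxisPreference] | None = None,
    dead_band: float = DEAD_BAND,
) -> FreeChoicePrediction:
    """Predict each Free-Choice reach from the sign of mean Blank ΔProximity.

    Traces must be signed toward the presented (favored) end.  Accuracy is
    reported overall and split by whether the decoded initial plan pointed
    to the favored or non-favored end.  When cued-trial preferences are
    supplied, the across-axes Pearson correlation between decoded
    preference and Free-Choice choice fraction is reported.
    """
    tids, preds, actuals, favored_flags = [], [], [], []
    undecided = 0
    fc = [t for t in trials if t.condition == "free_choice"]
    for trial in fc:
        if trial.trial_id not in traces:
            continue
        win = epoch_window(trial, "blank")
        m = _window_mean(traces[trial.trial_id], win)
        if np.isnan(m) or abs(m) <= dead_band:
            undecided += 1
            continue
        favored, unfavored = trial.axis_pair
        pred = favored if m > 0 else unfavored
        tids.append(trial.trial_id)
        preds.append(pred)
        actuals.append(trial.choice)
        favored_flags.append(pred == favored)
    preds_arr = np.asarray(preds)
    actual_arr = np.asarray(actuals)
    fav = np.asarray(favored_flags, dtype=bool)
    correct = preds_arr == actual_arr

    def _acc(mask: np.ndarray) -> float:
        return float(correct[mask].mean()) if mask.any() else np.nan

    corr = np.nan
    if cued_preferences:
        pref_by_axis = {p.axis: p.frac_first for p in cued_preferences if p.defined}
        xs, ys = [], []
        for axis, pref in pref_by_axis.items():
            axis_trials = [t for t in fc if t.presented_direction % 4 == axis]
            if axis_trials:
                choice_frac = float(
                    np.mean([t.choice == t.axis_pair[0] for t in axis_trials])
                )
                xs.append(pref)
                ys.append(choice_frac)
        if len(xs) >= 3 and np.ptp(xs) > 0 and np.ptp(ys) > 0:
            corr = float(stats.pearsonr(xs, ys)[0])

    return FreeChoicePrediction(
        trial_ids=np.asarray(tids),
        predicted=preds_arr,
        actual=actual_arr,
        accuracy=float(correct.mean()) if correct.size else np.nan,
        accuracy_favored=_acc(fav),
        accuracy_nonfavored=_acc(~fav),
        n_undecided=undecided,
        preference_choice_correlation=corr,
    )


# ---------------------------------------------------------------------------
# reaction time


def reaction_time(
    kin: KinematicsTrace,
    go_time_ms: float,
    threshold_cm_s: float = RT_SPEED_THRESHOLD_CM_S,
) -> float | None:
    """Time from Go to the hand speed first exceeding 5 cm/s, in ms.

    The crossing is linearly interpolated between samples.  Movement onset
    before Go yields a negative RT (anticipation, logged); a trace that
    never crosses returns None (logged).
    """
    speed = kin.speed_cm_s
    above = speed > threshold_cm_s
    if not above.any():
        logger.info("trial %d: no speed threshold crossing", kin.trial_id)
        return None
    k = int(np.argmax(above))
    if k == 0:
        t_cross = kin.t_ms[0]
    else:
        s0, s1 = speed[k - 1], speed[k]
        frac = (threshold_cm_s - s0) / (s1 - s0)
        t_cross = kin.t_ms[k - 1] + frac * (kin.t_ms[k] - kin.t_ms[k - 1])
    rt = float(t_cross - go_time_ms)
    if rt < 0:
        logger.info("trial %d: anticipatory movement (RT %.1f ms)", kin.trial_id, rt)
    return rt


# ---------------------------------------------------------------------------
# RT regression


@dataclass
class RTRegressionResult:
    """Per-group OLS slopes and the pooled mixed-model coefficient.

    The mixed model has reaction time as the response, ΔProximity as the
    fixed predictor, and uncorrelated random intercept and slope per group
    (direction × session).  With a single group it reduces exactly to OLS.
    """

    group_slopes: pd.DataFrame
    pooled_coefficient: float
    pooled_se: float
    pooled_pvalue: float
    converged: bool


def rt_plan_strength_regression(
    rt_ms: np.ndarray,
    dprox: np.ndarray,
    groups: np.ndarray,
) -> RTRegressionResult:
    """Regress reaction time on pre-Go ΔProximity toward the cued target.

    ``groups`` labels reach direction (separated by session).  Under a
    generator with positive RT gain the pooled coefficient is negative:
    stronger plans to the executed target shorten RT.
    """
    df = pd.DataFrame(
        {"rt": np.asarray(rt_ms, float), "dp": np.asarray(dprox, float),
         "g": np.asarray(groups)}
    ).dropna()
    if df.empty or df["dp"].nunique() < 2:
        raise ValueError("need varying ΔProximity values to regress on")

    slopes = []
    for g, sub in df.groupby("g"):
        if len(sub) >= 3 and sub["dp"].nunique() >= 2:
            res = sm.OLS(sub["rt"], sm.add_constant(sub["dp"])).fit()
            slopes.append({"group": g, "slope": res.params["dp"], "n": len(sub)})
    slopes_df = pd.DataFrame(slopes)

    if df["g"].nunique() == 1:
        # random effects are unidentifiable from one group: exact OLS
        res = sm.OLS(df["rt"], sm.add_constant(df["dp"])).fit()
        return RTRegressionResult(
            group_slopes=slopes_df,
            pooled_coefficient=float(res.params["dp"]),
            pooled_se=float(res.bse["dp"]),
            pooled_pvalue=float(res.pvalues["dp"]),
            converged=True,
        )
    mixed = smf.mixedlm(
        "rt ~ dp", df, groups=df["g"], re_formula="1", vc_formula={"dp": "0 + dp"}
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = mixed.fit(reml=True, method="lbfgs")
        if not fit.converged:
            fit = mixed.fit(reml=True, method="powell")
    return RTRegressionResult(
        group_slopes=slopes_df,
        pooled_coefficient=float(fit.params["dp"]),
        pooled_se=float(fit.bse["dp"]),
        pooled_pvalue=float(fit.pvalues["dp"]),
        converged=bool(fit.converged),
    )


# ---------------------------------------------------------------------------
# error typing


@dataclass
class ErrorTypeLabel:
    """Decoded error class of one incorrect cued trial.

    ``signs`` holds the decoded plan sign toward the cue in the late-Blank,
    late-Cue, and pre-Go windows (+1 toward cue, −1 away, 0 dead-band).
    """

    trial_id: int
    error_type: int  # 1, 2, 3 or 0 for "other"
    signs: tuple[int, int, int]


def classify_error_type(
    trace: tuple[np.ndarray, np.ndarray],
    trial: TrialRecord,
    dead_band: float = DEAD_BAND,
    window_ms: float = 100.0,
) -> ErrorTypeLabel:
    """Type an incorrect cued trial from its ΔProximity-toward-cue trace.

    The early read-out is the full Target Blank epoch and the late one the
    last 250 ms of the Cue epoch (its minimum duration) — both long enough
    to average over transient decode excursions; the final read-out is the
    [Go − window_ms, Go) window.  Type 1 planned against the cue throughout
    (wrong, wrong); type 2 switched to the cue then reverted before Go
    (wrong, correct, wrong); type 3 planned correctly and defected at the
    last moment (correct, correct, wrong).  Anything else — including
    dead-band windows — is "other" (type 0).
    """
    if trial.correct or trial.cue_direction is None:
        raise ValueError("error typing applies to incorrect cued trials")
    windows = [
        (trial.blank_on_ms, trial.cue_on_ms),
        (trial.cue_off_ms - 250.0, trial.cue_off_ms),
        (trial.go_ms - window_ms, trial.go_ms),
    ]
    signs = []
    for w in windows:
        m = _window_mean(trace, w)
        if np.isnan(m) or abs(m) <= dead_band:
            signs.append(0)
        else:
            signs.append(1 if m > 0 else -1)
    s_blank, s_cue, s_pre = signs
    if (s_blank, s_cue) == (-1, -1):
        etype = 1
    elif (s_blank, s_cue) == (-1, 1) and s_pre == -1:
        etype = 2
    elif (s_blank, s_cue) == (1, 1) and s_pre == -1:
        etype = 3
    else:
        etype = 0
    return ErrorTypeLabel(trial.trial_id, etype, (s_blank, s_cue, s_pre))


def classify_session_errors(
    model: StateSpaceModel,
    rates: RateMatrix,
    trials: Sequence[TrialRecord],
    clusters: DirectionClusterSet,
    dead_band: float = DEAD_BAND,
) -> list[ErrorTypeLabel]:
    """Error-type labels for every incorrect cued two-target trial."""
    errors = [
        t for t in trials if t.condition == "two_target_cued" and not t.correct
    ]
    windows = {
        t.trial_id: [
            (t.blank_on_ms, t.cue_on_ms),
            (t.cue_off_ms - 250.0, t.cue_off_ms),
            (t.go_ms - 100.0, t.go_ms),
        ]
        for t in errors
    }
    traces = delta_proximity_traces(
        model, rates, errors, clusters, toward="cue", windows_ms=windows
    )
    return [
        classify_error_type(traces[t.trial_id], t, dead_band)
        for t in errors
        if t.trial_id in traces
    ]
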