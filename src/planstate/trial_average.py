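"""Trial-averaged single-neuron analyses and the guessing-simulation control.

These are the analyses that, applied to trial-averaged activity, can
suggest simultaneous encoding of two reach plans.  Each unit's trials are
labeled pro-PD, anti-PD, or orthogonal-PD by the angle between the trial's
(labeled) direction and the unit's preferred direction; the fraction of
pro- and anti-PD planning bins exceeding the unit's median orthogonal-PD
activity summarizes apparent co-activation (mean 50% under a single
unbiased plan).

The guessing simulations relabel 1-Target trials to show the control's
failure mode: unbiased relabeling (half of each direction's trials get the
opposite label) leaves the exceedance mean at 50%, while biased relabeling
(first discarding four of the eight directions, counterclockwise from the
left target) pushes it far above 50% — a false dual-representation signal
from purely single-plan data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .preprocessing import RateMatrix, extract_epoch
from .synthetic_data import (
    DIRECTIONS_RAD,
    N_DIRECTIONS,
    TrialRecord,
    opposite_direction,
)
from .tuning import TuningFit, categorize_trial_responses

logger = logging.getLogger(__name__)

BIASED_DISCARD_DIRECTIONS = (4, 5, 6, 7)  # 180°, 225°, 270°, 315°: ccw from left


# ---------------------------------------------------------------------------
# categorization


def categorize_trials(
    fits: Sequence[TuningFit],
    trial_directions: dict[int, int],
) -> dict[int, dict[int, str]]:
    """Per-unit, per-trial pro/anti/orthogonal labels.

    ``trial_directions`` maps trial_id to the (possibly relabeled)
    direction index; the result maps unit index → {trial_id: category}.
    """
    out: dict[int, dict[int, str]] = {}
    for u, fit in enumerate(fits):
        out[u] = {
            tid: categorize_trial_responses(fit, DIRECTIONS_RAD[d])
            for tid, d in trial_directions.items()
        }
    return out


# ---------------------------------------------------------------------------
# averaged traces


@dataclass
class AveragedTraces:
    """Time-resolved pro-PD and anti-PD activity relative to orthogonal-PD.

    Traces are aligned to Target On on the 25 ms grid; confidence bands are
    bootstrap percentiles over (unit, trial) pairs.  ``bands_defined`` is
    False when n_boot < 2 (point estimate only).
    """

    times_ms: np.ndarray
    pro_minus_orth: np.ndarray
    anti_minus_orth: np.ndarray
    pro_band: np.ndarray | None
    anti_band: np.ndarray | None
    bands_defined: bool


def averaged_pd_traces(
    rates: RateMatrix,
    trials: Sequence[TrialRecord],
    categories: dict[int, dict[int, str]],
    n_boot: int = 1000,
    window_ms: tuple[float, float] = (-200.0, 1250.0),
    seed: int = 0,
) -> AveragedTraces:
    """Mean pro-PD and anti-PD traces minus the orthogonal-PD mean, with
    bootstrapped 95% bands.

    Activity is aligned to each trial's Target On; the window end is capped
    by the shortest trial.  The bootstrap resamples trials.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    trials = list(trials)
    offsets = np.arange(window_ms[0], window_ms[1], rates.bin_ms)
    # per (unit, trial) aligned traces by category
    per_cat: dict[str, list[np.ndarray]] = {"pro_pd": [], "anti_pd": [], "orthogonal_pd": []}
    cat_trial_idx: dict[str, list[int]] = {k: [] for k in per_cat}
    for ti, trial in enumerate(trials):
        t = rates.bin_times[trial.trial_id]
        want = trial.target_on_ms + offsets
        idx = np.searchsorted(t, want)
        ok = idx < t.size
        if not ok.all():
            idx = idx[ok]
        vals = rates.values[trial.trial_id][:, idx]  # units × window
        for u, cats in categories.items():
            cat = cats.get(trial.trial_id)
            if cat in per_cat:
                row = np.full(offsets.size, np.nan)
                row[: vals.shape[1]] = vals[u]
                per_cat[cat].append(row)
                cat_trial_idx[cat].append(ti)
    stacks = {k: np.vstack(v) if v else np.empty((0, offsets.size)) for k, v in per_cat.items()}

    def mean_diff(pro_rows, orth_rows):
        with np.errstate(invalid="ignore"):
            return np.nanmean(pro_rows, axis=0) - np.nanmean(orth_rows, axis=0)

    pro = mean_diff(stacks["pro_pd"], stacks["orthogonal_pd"])
    anti = mean_diff(stacks["anti_pd"], stacks["orthogonal_pd"])

    bands_defined = n_boot >= 2
    pro_band = anti_band = None
    if bands_defined:
        rng = np.random.default_rng(seed)
        boots_pro = np.empty((n_boot, offsets.size))
        boots_anti = np.empty((n_boot, offsets.size))
        n_trials = len(trials)
        cat_trial_arr = {k: np.asarray(v) for k, v in cat_trial_idx.items()}
        for b in range(n_boot):
            take = rng.integers(n_trials, size=n_trials)
            counts = np.bincount(take, minlength=n_trials).astype(float)
            sel = {
                k: np.repeat(
                    np.arange(stacks[k].shape[0]),
                    counts[cat_trial_arr[k]].astype(int),
                )
                if stacks[k].size
                else np.empty(0, int)
                for k in stacks
            }
            boots_pro[b] = mean_diff(
                stacks["pro_pd"][sel["pro_pd"]], stacks["orthogonal_pd"][sel["orthogonal_pd"]]
            )
            boots_anti[b] = mean_diff(
                stacks["anti_pd"][sel["anti_pd"]], stacks["orthogonal_pd"][sel["orthogonal_pd"]]
            )
        pro_band = np.nanpercentile(boots_pro, [2.5, 97.5], axis=0)
        anti_band = np.nanpercentile(boots_anti, [2.5, 97.5], axis=0)

    return AveragedTraces(
        times_ms=offsets,
        pro_minus_orth=pro,
        anti_minus_orth=anti,
        pro_band=pro_band,
        anti_band=anti_band,
        bands_defined=bands_defined,
    )


# ---------------------------------------------------------------------------
# orthogonal-median exceedance


@dataclass
class ExceedanceResult:
    """Per-unit percent of pro/anti planning bins above the orthogonal median.

    ``unit_percents`` holds one pooled pro+anti percentage per included
    unit; the one-sample t statistic tests the unit-wise mean against 50%.
    """

    unit_ids: np.ndarray
    unit_percents: np.ndarray
    mean_percent: float
    t_statistic: float
    p_value: float
    excluded_units: int


def orthogonal_median_exceedance(
    rates: RateMatrix,
    trials: Sequence[TrialRecord],
    categories: dict[int, dict[int, str]],
    include_units: np.ndarray | None = None,
) -> ExceedanceResult:
    """Percent of pro-PD and anti-PD planning activity exceeding each unit's
    median orthogonal-PD activity, tested against 50% across units.

    The orthogonal median is computed per unit over all orthogonal-PD
    planning bins pooled across trials.  Units missing any of the three
    categories are excluded and counted.  Exceedance is strict (>), so
    constant activity gives exactly 0%.
    """
    planning = extract_epoch(rates, trials, "planning_window")
    unit_ids, percents = [], []
    excluded = 0
    units = categories.keys() if include_units is None else np.flatnonzero(include_units)
    for u in units:
        cats = categories[u]
        pools: dict[str, list[np.ndarray]] = {"pro_pd": [], "anti_pd": [], "orthogonal_pd": []}
        for trial in trials:
            cat = cats.get(trial.trial_id)
            if cat in pools:
                vals = planning.X[planning.trial_ids == trial.trial_id, u]
                if vals.size:
                    pools[cat].append(vals)
        if not all(pools.values()):
            excluded += 1
            continue
        orth_median = np.median(np.concatenate(pools["orthogonal_pd"]))
        pooled = np.concatenate(pools["pro_pd"] + pools["anti_pd"])
        unit_ids.append(u)
        percents.append(100.0 * np.mean(pooled > orth_median))
    if excluded:
        logger.info(
            "exceedance: excluded %d units missing a trial category", excluded
        )
    percents_arr = np.asarray(percents)
    if percents_arr.size >= 2 and np.ptp(percents_arr) > 0:
        t_stat, p_val = stats.ttest_1samp(percents_arr, 50.0)
    else:
        t_stat, p_val = np.nan, np.nan
    return ExceedanceResult(
        unit_ids=np.asarray(unit_ids),
        unit_percents=percents_arr,
        mean_percent=float(percents_arr.mean()) if percents_arr.size else np.nan,
        t_statistic=float(t_stat),
        p_value=float(p_val),
        excluded_units=excluded,
    )


# ---------------------------------------------------------------------------
# guessing simulations


def relabel_guessing(
    trials: Sequence[TrialRecord],
    mode: str,
    seed: int = 0,
) -> dict[int, int]:
    """Relabeled direction per trial id for the guessing simulations.

    ``unbiased``: for every direction, a random half (floor(n/2)) of its
    trials are relabeled to the opposite direction.  ``biased``: trials to
    directions 180°/225°/270°/315° are discarded first (their ids are
    absent from the result), then half of the survivors are relabeled.
    The neural data are never touched — only the labels change.
    """
    if mode not in ("unbiased", "biased"):
        raise ValueError(f"mode must be 'unbiased' or 'biased', got {mode!r}")
    for t in trials:
        if t.condition != "one_target":
            raise ValueError("guessing relabeling applies to 1-Target trials only")
    rng = np.random.default_rng(seed)
    kept = [
        t
        for t in trials
        if mode == "unbiased" or t.presented_direction not in BIASED_DISCARD_DIRECTIONS
    ]
    labels = {t.trial_id: t.presented_direction for t in kept}
    for d in range(N_DIRECTIONS):
        ids = [t.trial_id for t in kept if t.presented_direction == d]
        flip = rng.choice(ids, size=len(ids) // 2, replace=False)
        for tid in flip:
            labels[tid] = opposite_direction(d)
    return labels
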