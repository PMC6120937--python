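"""Firing-rate estimation and epoch slicing.

Spike trains are converted to causal firing-rate estimates by binning at
40 Hz and convolving with a half-Gaussian kernel (s.d. 150 ms) that is zero
before the spike, then square-root transformed.  The transform stabilizes
Poisson variance so downstream state-space distances are not dominated by
high-rate units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .synthetic_data import BIN_MS, SpikeData, TrialRecord

logger = logging.getLogger(__name__)

EPOCHS = ("target_on", "blank", "cue", "go", "planning_window", "cluster_window")

PLANNING_OFFSET_MS = 500.0
"""Planning windows start this long after Target On (plan-formation delay)."""


def half_gaussian_kernel(
    sd_ms: float = 150.0, bin_ms: float = BIN_MS, truncate_sd: float = 4.0
) -> np.ndarray:
    """Causal half-Gaussian kernel weights on the bin grid, summing to 1.

    Weight j applies to the bin j steps in the past; the kernel is truncated
    at ``truncate_sd`` standard deviations and renormalized.
    """
    n = int(np.ceil(truncate_sd * sd_ms / bin_ms))
    lags = np.arange(n + 1) * bin_ms
    w = np.exp(-0.5 * (lags / sd_ms) ** 2)
    return w / w.sum()


@dataclass
class RateMatrix:
    """Causal firing-rate estimates per trial, units × 25 ms bins.

    ``values[trial_id]`` has shape (n_units, n_bins); entries are in
    sqrt(spikes/s) when ``sqrt_transformed`` (the pipeline default).
    ``bin_times[trial_id]`` holds right-edge timestamps in ms, so the value
    at a bin depends only on spikes at times ≤ its timestamp.
    """

    values: dict[int, np.ndarray]
    bin_times: dict[int, np.ndarray]
    unit_ids: np.ndarray
    sqrt_transformed: bool = True
    bin_ms: float = BIN_MS

    @property
    def n_units(self) -> int:
        return self.unit_ids.size

    def trial_ids(self) -> list[int]:
        return sorted(self.values)


def estimate_firing_rates(
    spikes: SpikeData,
    trials: Sequence[TrialRecord],
    kernel_sd_ms: float = 150.0,
    out_rate_hz: float = 40.0,
    sqrt_transform: bool = True,
) -> RateMatrix:
    """Estimate firing rates causally on the 25 ms grid, per trial.

    Each spike contributes a half-Gaussian bump that is exactly zero for
    bins whose right edge precedes the spike's bin.  The kernel integrates
    to one, so a homogeneous train of rate r plateaus near r.  Smoothing is
    per trial (no leakage across trial boundaries).
    """
    bin_ms = 1000.0 / out_rate_hz
    kernel = half_gaussian_kernel(kernel_sd_ms, bin_ms)
    values: dict[int, np.ndarray] = {}
    times: dict[int, np.ndarray] = {}
    for trial in trials:
        n_bins = int(round(trial.end_ms / bin_ms))
        edges = np.arange(n_bins + 1) * bin_ms
        per_trial = spikes.spikes[trial.trial_id]
        counts = np.zeros((spikes.n_units, n_bins))
        for u, ts in enumerate(per_trial):
            if ts.size:
                counts[u] = np.histogram(ts, bins=edges)[0]
        # causal FIR: rate[t] = sum_j kernel[j] * counts[t-j] / dt
        rate = lfilter(kernel, 1.0, counts, axis=1) / (bin_ms / 1000.0)
        if sqrt_transform:
            rate = np.sqrt(rate)
        values[trial.trial_id] = rate
        times[trial.trial_id] = edges[1:]
    return RateMatrix(
        values=values,
        bin_times=times,
        unit_ids=spikes.unit_ids.copy(),
        sqrt_transformed=sqrt_transform,
        bin_ms=bin_ms,
    )


@dataclass
class EpochActivity:
    """Rate bins pooled over trials for one epoch window.

    ``X`` stacks the selected bins as rows (n_bins_total × n_units);
    ``trial_ids`` / ``times_ms`` label each row; ``directions`` holds the
    per-row direction label (the trial's presented target by default).
    ``skipped_trials`` counts trials lacking the epoch.
    """

    X: np.ndarray
    trial_ids: np.ndarray
    times_ms: np.ndarray
    directions: np.ndarray
    epoch: str
    skipped_trials: int = 0

    def for_trial(self, trial_id: int) -> np.ndarray:
        return self.X[self.trial_ids == trial_id]


def epoch_window(
    trial: TrialRecord,
    epoch: str,
    offset_ms: float = 0.0,
    duration_ms: float | None = None,
) -> tuple[float, float] | None:
    """Half-open window [start, end) in ms for an epoch on one trial.

    ``offset_ms`` shifts the epoch start; ``duration_ms`` fixes the window
    length from the shifted start (e.g. epoch="go", offset=-100,
    duration=100 gives the 100 ms window preceding Go).  Returns None when
    the trial lacks the epoch (e.g. cue on Free-Choice).
    """
    if epoch == "target_on":
        start, end = trial.target_on_ms, trial.blank_on_ms
    elif epoch == "blank":
        start = trial.blank_on_ms
        end = trial.cue_on_ms if trial.cue_on_ms is not None else trial.go_ms
    elif epoch == "cue":
        if trial.cue_on_ms is None:
            return None
        start, end = trial.cue_on_ms, trial.cue_off_ms
    elif epoch == "go":
        start, end = trial.go_ms, trial.end_ms
    elif epoch == "planning_window":
        start = trial.target_on_ms + PLANNING_OFFSET_MS
        end = trial.cue_on_ms if trial.cue_on_ms is not None else trial.go_ms
    elif epoch == "cluster_window":
        start = trial.target_on_ms + PLANNING_OFFSET_MS
        end = trial.end_ms
    else:
        raise ValueError(f"unknown epoch {epoch!r}; expected one of {EPOCHS}")
    start += offset_ms
    end = start + duration_ms if duration_ms is not None else end + min(offset_ms, 0)
    if duration_ms is None:
        end = max(end, start)  # degenerate but well-formed
    return (start, end)


def extract_epoch(
    rates: RateMatrix,
    trials: Sequence[TrialRecord],
    epoch: str,
    offset_ms: float = 0.0,
    duration_ms: float | None = None,
    direction_label: str = "presented",
) -> EpochActivity:
    """Pool rate bins whose timestamps fall in [start, end) of an epoch.

    Bins are selected by their right-edge timestamp.  ``direction_label``
    chooses the per-row label: the presented target ("presented") or the
    eventual choice ("choice").  Trials lacking the epoch are skipped and
    counted.
    """
    rows, tids, ts, dirs = [], [], [], []
    skipped = 0
    for trial in trials:
        win = epoch_window(trial, epoch, offset_ms, duration_ms)
        if win is None:
            skipped += 1
            continue
        start, end = win
        t = rates.bin_times[trial.trial_id]
        mask = (t >= start) & (t < end)
        if not mask.any():
            skipped += 1
            continue
        rows.append(rates.values[trial.trial_id][:, mask].T)
        tids.append(np.full(mask.sum(), trial.trial_id))
        ts.append(t[mask])
        label = trial.choice if direction_label == "choice" else trial.presented_direction
        dirs.append(np.full(mask.sum(), label))
    if skipped:
        logger.info("extract_epoch(%s): skipped %d trials without the epoch",
                    epoch, skipped)
    if not rows:
        n_u = rates.n_units
        return EpochActivity(
            X=np.empty((0, n_u)), trial_ids=np.empty(0, int),
            times_ms=np.empty(0), directions=np.empty(0, int),
            epoch=epoch, skipped_trials=skipped,
        )
    return EpochActivity(
        X=np.vstack(rows),
        trial_ids=np.concatenate(tids).astype(int),
        times_ms=np.concatenate(ts),
        directions=np.concatenate(dirs).astype(int),
        epoch=epoch,
        skipped_trials=skipped,
    )
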