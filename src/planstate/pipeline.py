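"""End-to-end session analysis: one object wiring all pipeline stages.

``SessionAnalysis`` lazily computes and caches the standard chain —
firing-rate estimation, PCA state space, direction clusters, tuning fits,
ΔProximity traces — so CLI commands, tests, and reproduction scripts share
one code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from . import behavior, hypothesis_models, state_space, trial_average, tuning
from .preprocessing import (
    RateMatrix,
    epoch_window,
    estimate_firing_rates,
    extract_epoch,
)
from .state_space import DirectionClusterSet, StateSpaceModel
from .synthetic_data import DIRECTIONS_RAD, Session


@dataclass
class SessionAnalysis:
    """Cached analysis pipeline over one (synthetic) session."""

    session: Session
    shrinkage: float = 0.1
    density: str = "kde"
    significance_seed: int = 0
    n_boot: int = 1000

    @cached_property
    def rates(self) -> RateMatrix:
        return estimate_firing_rates(self.session.spikes, self.session.trials)

    @cached_property
    def state_space(self) -> StateSpaceModel:
        return state_space.fit_state_space(self.rates, self.session.trials)

    @cached_property
    def clusters(self) -> DirectionClusterSet:
        return state_space.build_direction_clusters(
            self.state_space,
            self.rates,
            self.session.trials,
            shrinkage=self.shrinkage,
            density=self.density,
        )

    @cached_property
    def one_target_trials(self):
        return self.session.trials_by_condition("one_target")

    @cached_property
    def tuning_fits(self) -> list[tuning.TuningFit]:
        """Single-cosine fits to 1-Target planning-window activity per unit."""
        planning = extract_epoch(self.rates, self.one_target_trials, "planning_window")
        fits = []
        for u in range(self.rates.n_units):
            means = np.array(
                [
                    planning.X[planning.directions == d, u].mean()
                    for d in range(DIRECTIONS_RAD.size)
                ]
            )
            fits.append(tuning.fit_cosine_tuning(means, DIRECTIONS_RAD))
        return fits

    @cached_property
    def tuning_significance(self) -> np.ndarray:
        """Direction-shuffle bootstrap significance per unit (trial means)."""
        planning = extract_epoch(self.rates, self.one_target_trials, "planning_window")
        direction_of = {
            t.trial_id: t.presented_direction for t in self.one_target_trials
        }
        trial_ids = sorted(direction_of)
        sig = np.zeros(self.rates.n_units, dtype=bool)
        for u in range(self.rates.n_units):
            trial_means = np.array(
                [
                    planning.X[planning.trial_ids == tid, u].mean()
                    for tid in trial_ids
                ]
            )
            dirs = np.array([DIRECTIONS_RAD[direction_of[tid]] for tid in trial_ids])
            sig[u] = tuning.bootstrap_tuning_significance(
                trial_means,
                dirs,
                n_boot=self.n_boot,
                seed=self.significance_seed + u,
            )
        return sig

    @cached_property
    def session_tuning(self) -> hypothesis_models.SessionTuning:
        return hypothesis_models.measure_session_tuning(
            self.rates, self.session.trials, significant=self.tuning_significance
        )

    def classify_one_target(self, leave_one_out: bool = True):
        return state_space.classify_one_target_trials(
            self.state_space,
            self.rates,
            self.session.trials,
            leave_one_out=leave_one_out,
            shrinkage=self.shrinkage,
            density=self.density,
        )

    def model_states(self) -> list[hypothesis_models.ModelResponse]:
        return hypothesis_models.simulate_all_models(
            self.session_tuning, self.state_space, self.clusters
        )

    def dri_fraction(self, condition: str, threshold: float = 0.2) -> float:
        """Fraction of Target Blank bins with DRI above threshold."""
        trials = self.session.trials_by_condition(condition)
        dri = state_space.dri_for_trials(
            self.state_space, self.rates, trials, self.clusters, "blank"
        )
        return state_space.dri_threshold_summary(dri, threshold)

    def guessing_exceedance(
        self, mode: str, seed: int = 0
    ) -> trial_average.ExceedanceResult:
        """Relabel 1-Target trials per the guessing simulation and run the
        orthogonal-median exceedance analysis on the relabeled dataset.

        The relabeled dataset plays the role of two-target data in the
        trial-averaged control: preferred directions come from the original
        (true-label) 1-Target cosine fits of significantly tuned units, and
        a doubled-frequency cosine is fit to the relabeled planning
        activity.  Units whose PD disagrees with the doubled-cosine
        preferred axis by more than 30° are discarded — but only when that
        axis is itself meaningful, i.e. when the doubled amplitude passes
        the direction-shuffle bootstrap on the relabeled data; a noise axis
        cannot disqualify a unit.
        """
        labels = trial_average.relabel_guessing(self.one_target_trials, mode, seed)
        kept = [t for t in self.one_target_trials if t.trial_id in labels]
        planning = extract_epoch(self.rates, kept, "planning_window")
        relabeled_dir = np.array([labels[tid] for tid in planning.trial_ids])
        kept_ids = sorted(labels)
        trial_means = {
            tid: planning.X[planning.trial_ids == tid].mean(axis=0)
            for tid in kept_ids
        }
        trial_dirs = np.array([DIRECTIONS_RAD[labels[tid]] for tid in kept_ids])
        consistent = np.zeros(self.rates.n_units, dtype=bool)
        for u in range(self.rates.n_units):
            means = np.array(
                [
                    planning.X[relabeled_dir == d, u].mean()
                    for d in range(DIRECTIONS_RAD.size)
                ]
            )
            doubled = tuning.fit_doubled_cosine(means, DIRECTIONS_RAD)
            per_trial = np.array([trial_means[tid][u] for tid in kept_ids])
            axis_meaningful = tuning.bootstrap_tuning_significance(
                per_trial,
                trial_dirs,
                n_boot=self.n_boot,
                model="doubled",
                seed=self.significance_seed + u,
            )
            consistent[u] = (not axis_meaningful) or tuning.check_pd_axis_consistency(
                self.tuning_fits[u], doubled
            )
        cats = trial_average.categorize_trials(self.tuning_fits, labels)
        include = self.tuning_significance & consistent
        return trial_average.orthogonal_median_exceedance(
            self.rates, kept, cats, include_units=include
        )

    def delta_traces(
        self, condition: str, toward: str = "presented", epoch: str | None = None
    ):
        """ΔProximity traces for one condition; ``epoch`` restricts the
        (expensive) proximity evaluation to that epoch's bins."""
        trials = self.session.trials_by_condition(condition)
        windows = None
        if epoch is not None:
            windows = {}
            for t in trials:
                win = epoch_window(t, epoch)
                if win is not None:
                    windows[t.trial_id] = [win]
        return behavior.delta_proximity_traces(
            self.state_space,
            self.rates,
            trials,
            self.clusters,
            toward=toward,
            windows_ms=windows,
        )
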