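"""Synthetic delayed-reach sessions with single-plan latent dynamics.

Emulates chronic-array recordings from dorsal premotor cortex during a
center-out "go-before-you-know" task: eight targets at 45° spacing, trials
mixing 1-Target, cued 2-Target, Free-Choice, and discarded no-cue types.
Each unit is cosine tuned to the currently planned reach direction and
spikes as an inhomogeneous Poisson process; the latent plan trace is the
generator's ground truth and never encodes two directions at once.  An
alternative encoding flag produces dual-representation firing (the mean of
the two single-plan rates) purely so downstream metrics can be shown to
detect it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.signal import lfilter

BIN_MS = 25.0
"""Width of the analysis time bin (40 Hz grid), in ms."""

N_DIRECTIONS = 8
DIRECTIONS_RAD = np.arange(N_DIRECTIONS) * (2.0 * np.pi / N_DIRECTIONS)
"""Direction index k maps to k*45°; 0 rad = rightward, counter-clockwise."""

NO_PLAN = -1
"""Latent-plan code for bins with no active reach plan."""

CONDITIONS = ("one_target", "two_target_cued", "free_choice", "one_target_no_cue")

# Minimum-jerk profile x(τ) = 10τ³ − 15τ⁴ + 6τ⁵ has peak speed 1.875·d/D.
MIN_JERK_PEAK_FACTOR = 1.875


def opposite_direction(d: int) -> int:
    return (d + 4) % N_DIRECTIONS


def snap_to_grid(t_ms: float) -> float:
    """Snap a timestamp to the 25 ms bin grid."""
    return float(np.round(t_ms / BIN_MS) * BIN_MS)


# ---------------------------------------------------------------------------
# population


@dataclass(frozen=True)
class PopulationSpec:
    """Parameters of the simulated cosine-tuned population.

    ``baseline_rate`` and ``tuning_depth`` are population means (spikes/s);
    per-unit offsets a and depths b are drawn around them, with b clipped to
    a so expected rates never go negative.

    Spiking is doubly stochastic.  Excess (super-Poisson) variability is
    injected additively in the square-root domain, where Poisson noise is
    variance-stabilized, so every component perturbs √rate symmetrically
    (amplitudes below are in √(spikes/s)): a per-unit within-trial
    Ornstein–Uhlenbeck process (``unit_gain_sd``, correlation time
    ``unit_gain_tau_ms``), a per-unit per-trial constant offset
    (``unit_gain_trial_sd``), a shared low-dimensional fluctuation — a
    random population pattern per trial with OU amplitude
    (``shared_noise_sd``, ``shared_noise_tau_ms``) — sweeping the state
    along directions unrelated to the direction code, as cortical noise
    correlations do, and a per-unit random walk across trials
    (``drift_step_sd``; electrode/excitability drift over the session).
    The whole population additionally carries a shared per-trial mean-1
    lognormal rate gain (``population_gain_sd``, log-sd; slow arousal-like
    fluctuations).  Set the sds to 0 for pure Poisson spiking.

    Tuning curves are sharpened cosines: the directional modulation is
    b·[cos(θ−φ) + κ_u·cos(2(θ−φ))] with per-unit κ_u drawn around
    ``tuning_second_harmonic`` with spread ``second_harmonic_sd``, giving
    the narrower-than-cosine peaks (and occasional secondary anti-direction
    bumps) seen in real premotor tuning.  κ = 0 recovers the pure cosine.

    After the Go cue each unit switches to a movement-execution pattern:
    tuning depth scaled by ``move_gain`` and preferred direction rotated by
    a per-unit angle ~ N(0, ``move_pd_rotation_sd``) rad, reflecting the
    distinct planning and execution population patterns of premotor cortex.
    Set move_gain = 1 and move_pd_rotation_sd = 0 to disable.
    """

    n_units: int = 120
    baseline_rate: float = 20.0
    tuning_depth: float = 12.0
    noise_model: str = "poisson"
    unit_gain_sd: float = 0.45
    unit_gain_tau_ms: float = 300.0
    unit_gain_trial_sd: float = 0.2
    population_gain_sd: float = 0.15
    drift_step_sd: float = 0.02
    shared_noise_sd: float = 0.7
    shared_noise_tau_ms: float = 300.0
    tuning_second_harmonic: float = 0.0
    second_harmonic_sd: float = 0.0
    move_gain: float = 1.4
    move_pd_rotation_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 2:
            raise ValueError("n_units must be >= 2")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.tuning_depth > self.baseline_rate:
            raise ValueError(
                "tuning_depth must not exceed baseline_rate "
                "(expected rates would go negative)"
            )
        if self.noise_model != "poisson":
            raise ValueError(f"unsupported noise model: {self.noise_model!r}")


@dataclass(frozen=True)
class PopulationModel:
    """Realized per-unit tuning parameters for planning and execution.

    Directional modulation is cosine in the square-root domain:
    rate(θ) = (c + d·cos(θ − φ))² with c = √a.  In rate terms this is a
    cosine with a sharpened peak and a shallow trough — the characteristic
    shape of premotor tuning — and in the analysis pipeline's
    variance-stabilized (√) space the modulation is exactly symmetric
    about the orthogonal-direction level.  ``a``/``b`` report the
    rate-space offset and first-harmonic depth for reference;
    c and d (``sqrt_base``, ``sqrt_depth``) generate the rates.
    """

    a: np.ndarray  # rate offset, spikes/s
    b: np.ndarray  # rate first-harmonic depth, spikes/s
    phi: np.ndarray  # planning preferred direction, rad in [0, 2π)
    kappa: np.ndarray  # extra second-harmonic weight (0 = standard shape)
    sqrt_base: np.ndarray  # c, sqrt(spikes/s)
    sqrt_depth: np.ndarray  # d, sqrt(spikes/s)
    sqrt_depth_move: np.ndarray  # execution-period d
    phi_move: np.ndarray  # execution preferred direction, rad
    spec: PopulationSpec

    @property
    def n_units(self) -> int:
        return self.a.size

    def _modulation(self, delta: np.ndarray) -> np.ndarray:
        return np.cos(delta) + self.kappa * np.cos(2.0 * delta)

    def rate(self, theta: float | np.ndarray, strength: float = 1.0) -> np.ndarray:
        """Expected planning rate of every unit for direction ``theta`` (rad)."""
        v = self.sqrt_base + strength * self.sqrt_depth * self._modulation(
            np.asarray(theta) - self.phi
        )
        return np.maximum(v, 0.0) ** 2

    def move_rate(self, theta: float | np.ndarray, strength: float = 1.0) -> np.ndarray:
        """Expected execution-period rate for reach direction ``theta`` (rad)."""
        v = self.sqrt_base + strength * self.sqrt_depth_move * self._modulation(
            np.asarray(theta) - self.phi_move
        )
        return np.maximum(v, 0.0) ** 2


def generate_population(spec: PopulationSpec) -> PopulationModel:
    """Draw a population of cosine-tuned units; deterministic given spec.seed.

    Preferred directions are stratified-uniform over [0, 2π) so every part of
    the circle is covered even for small populations.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_units
    a = spec.baseline_rate * rng.uniform(0.6, 1.4, size=n)
    b = spec.tuning_depth * rng.uniform(0.6, 1.4, size=n)
    b = np.minimum(b, a)  # keep expected rates non-negative
    phi = 2.0 * np.pi * (np.arange(n) + rng.uniform(0.0, 1.0, size=n)) / n
    rng.shuffle(phi)
    kappa = np.clip(
        rng.normal(spec.tuning_second_harmonic, spec.second_harmonic_sd, size=n),
        0.0,
        0.8,
    )
    sqrt_base = np.sqrt(a)
    # first-order match: (c + d cos)^2 has rate-space first harmonic ~ 2cd
    with np.errstate(divide="ignore", invalid="ignore"):
        sqrt_depth = np.where(sqrt_base > 0, b / (2.0 * sqrt_base), 0.0)
    sqrt_depth_move = np.minimum(spec.move_gain * sqrt_depth, sqrt_base)
    phi_move = (phi + rng.normal(0.0, spec.move_pd_rotation_sd, size=n)) % (
        2.0 * np.pi
    )
    return PopulationModel(
        a=a,
        b=b,
        phi=phi,
        kappa=kappa,
        sqrt_base=sqrt_base,
        sqrt_depth=sqrt_depth,
        sqrt_depth_move=sqrt_depth_move,
        phi_move=phi_move,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# task configuration and trials


@dataclass(frozen=True)
class TaskConfig:
    """Task statistics of the delayed-reach session.

    Epoch durations are drawn uniformly from the given (lo, hi) ranges in ms
    and snapped to the 25 ms grid.  ``axis_bias`` is the probability that the
    initial plan on a two-target trial points to the favored end of the axis
    (the end at angle < 180°).  ``error_rates`` gives the probability of
    each error template on cued 2-Target trials, conditional on the
    congruence the template requires: types 1 and 2 apply when the initial
    plan disagrees with the cue, type 3 when it agrees.  With the default
    0.75 axis bias and balanced cueing, roughly 14% of cued trials end in
    an error.  With
    probability ``late_switch_prob`` a correct trial with an incongruent
    initial plan defers its switch until after Go (the reach is still to
    the cued target, at the cost of a long reaction time).

    Plan vigor varies from trial to trial (clipped normal around 1).  On
    two-target trials — where the subject deliberates — strengths are broad
    and reach near zero (``plan_strength_sd``/``plan_strength_range``);
    on 1-Target trials the target is known from the outset and plans are
    consistently vigorous (``one_target_strength_*``).

    Within a trial the instantaneous strength is not constant: it follows
    an Ornstein–Uhlenbeck process around the trial's mean level (stationary
    sd ``strength_ou_sd``, correlation time ``strength_ou_tau_ms``), so
    plans wax and wane on a sub-second timescale and occasionally dip to
    near zero.  Set ``strength_ou_sd = 0`` for constant-strength trials.
    """

    target_radius_cm: float = 7.0
    center_radius_cm: float = 1.5
    hold_ms: float = 500.0
    target_on_range_ms: tuple[float, float] = (750.0, 1000.0)
    blank_range_ms: tuple[float, float] = (250.0, 500.0)
    cue_range_ms: tuple[float, float] = (250.0, 500.0)
    return_range_ms: tuple[float, float] = (450.0, 600.0)
    post_go_ms: float = 1800.0
    trial_mix: dict[str, float] = field(
        default_factory=lambda: {
            "two_target_cued": 0.40,
            "one_target": 0.40,
            "free_choice": 0.10,
            "one_target_no_cue": 0.10,
        }
    )
    axis_bias: float = 0.75
    plan_onset_latency_ms: float = 150.0
    switch_latency_ms: float = 150.0
    error_rates: dict[int, float] = field(
        default_factory=lambda: {1: 0.16, 2: 0.10, 3: 0.03}
    )
    fc_late_switch_rate: float = 0.0
    late_switch_prob: float = 0.15
    plan_strength_sd: float = 0.4
    plan_strength_range: tuple[float, float] = (0.3, 1.8)
    one_target_strength_sd: float = 0.25
    one_target_strength_range: tuple[float, float] = (0.5, 1.8)
    strength_ou_sd: float = 0.3
    strength_ou_tau_ms: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.trial_mix.values()) - 1.0) > 1e-9:
            raise ValueError("trial_mix must sum to 1")
        if not set(self.trial_mix) <= set(CONDITIONS):
            raise ValueError(f"unknown condition in trial_mix: {set(self.trial_mix)}")
        if not 0.5 <= self.axis_bias <= 1.0:
            raise ValueError("axis_bias must lie in [0.5, 1]")
        if not 0.0 <= sum(self.error_rates.values()) <= 1.0:
            raise ValueError("error_rates must sum to at most 1")
        for lo, hi in (
            self.target_on_range_ms,
            self.blank_range_ms,
            self.cue_range_ms,
            self.return_range_ms,
        ):
            if lo > hi or lo < 0:
                raise ValueError("epoch ranges must be 0 <= lo <= hi")


@dataclass
class TrialRecord:
    """One trial: condition, geometry, epoch boundaries, latent ground truth.

    ``latent_plan`` holds one direction index (or NO_PLAN) per 25 ms bin over
    [0, end_ms); it is the generator's ground truth and never encodes two
    simultaneous plans.  ``plan_strength`` is the trial's mean plan vigor;
    ``strength_profile`` (same length as ``latent_plan``) is the
    instantaneous vigor per bin, fluctuating around that mean.
    """

    trial_id: int
    condition: str
    target_pair: tuple[int, ...]
    cue_direction: int | None
    target_on_ms: float
    blank_on_ms: float
    cue_on_ms: float | None
    cue_off_ms: float | None
    go_ms: float
    end_ms: float
    latent_plan: np.ndarray
    choice: int
    correct: bool
    error_type: int = 0  # 0 = none; 1/2/3 = generated error template
    plan_strength: float = 1.0
    strength_profile: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.target_pair) == 2:
            d0, d1 = self.target_pair
            if opposite_direction(d0) != d1:
                raise ValueError("target_pair directions must be 180° apart")
        bounds = [self.target_on_ms, self.blank_on_ms]
        if self.cue_on_ms is not None:
            bounds += [self.cue_on_ms, self.cue_off_ms]
        bounds += [self.go_ms, self.end_ms]
        if not all(x < y for x, y in zip(bounds, bounds[1:])):
            raise ValueError("epoch boundaries must be strictly increasing")

    @property
    def presented_direction(self) -> int:
        """The (first) presented target direction."""
        return self.target_pair[0]

    @property
    def axis_pair(self) -> tuple[int, int]:
        """The two ends of the trial's target axis (presented, opposite)."""
        d = self.target_pair[0]
        return (d, opposite_direction(d))

    @property
    def n_bins(self) -> int:
        return self.latent_plan.size

    def bin_times(self) -> np.ndarray:
        """Right-edge timestamps (ms) of the trial's 25 ms bins."""
        return (np.arange(self.n_bins) + 1) * BIN_MS

    def plan_at(self, t_ms: float) -> int:
        """Latent plan in the bin containing time ``t_ms``."""
        idx = min(int(t_ms // BIN_MS), self.n_bins - 1)
        return int(self.latent_plan[idx])


def _draw_condition_sequence(
    rng: np.random.Generator, mix: dict[str, float], n: int, balanced: bool
) -> list[str]:
    names = list(mix)
    if not balanced:
        return list(rng.choice(names, size=n, p=[mix[c] for c in names]))
    counts = {c: int(round(mix[c] * n)) for c in names}
    while sum(counts.values()) < n:
        counts[names[0]] += 1
    while sum(counts.values()) > n:
        counts[max(counts, key=counts.get)] -= 1
    seq = [c for c in names for _ in range(counts[c])]
    rng.shuffle(seq)
    return seq


def generate_trials(
    config: TaskConfig, n_trials: int, balanced: bool = False
) -> list[TrialRecord]:
    """Generate trial records with latent single-plan dynamics.

    ``balanced=True`` fixes the condition counts to round(mix*n) and cycles
    directions/axes evenly (useful for sessions with an exact per-direction
    trial count); otherwise conditions and directions are drawn i.i.d.

    Error trials on the cued 2-Target condition follow three latent
    templates: type 1 keeps the initial (anti-cue) plan throughout; type 2
    switches to the cue but reverts 250 ms before Go; type 3 plans the cued
    target throughout and defects 250 ms before Go.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(config.seed)
    conditions = _draw_condition_sequence(rng, config.trial_mix, n_trials, balanced)

    # balanced round-robin counters, independent per condition
    rr_dir = {"one_target": 0, "one_target_no_cue": 0}
    rr_axis = {"two_target_cued": 0, "free_choice": 0}

    trials: list[TrialRecord] = []
    for tid, cond in enumerate(conditions):
        t_on = config.hold_ms
        blank_on = t_on + snap_to_grid(rng.uniform(*config.target_on_range_ms))
        blank_dur = snap_to_grid(rng.uniform(*config.blank_range_ms))
        if cond in ("one_target", "two_target_cued"):
            cue_on = blank_on + blank_dur
            cue_off = cue_on + snap_to_grid(rng.uniform(*config.cue_range_ms))
            go = cue_off + snap_to_grid(rng.uniform(*config.return_range_ms))
        else:  # Free-Choice and no-cue trials omit the Cue period entirely
            cue_on = cue_off = None
            go = blank_on + blank_dur
        end = go + config.post_go_ms

        n_bins = int(round(end / BIN_MS))
        plan = np.full(n_bins, NO_PLAN, dtype=np.int8)
        onset = t_on + rng.exponential(config.plan_onset_latency_ms)

        def set_plan(start_ms: float, stop_ms: float, d: int) -> None:
            i0 = max(0, int(np.ceil(start_ms / BIN_MS)))
            i1 = min(n_bins, int(np.ceil(stop_ms / BIN_MS)))
            plan[i0:i1] = d

        error_type = 0
        if cond in ("one_target", "one_target_no_cue"):
            if balanced:
                d = rr_dir[cond] % N_DIRECTIONS
                rr_dir[cond] += 1
            else:
                d = int(rng.integers(N_DIRECTIONS))
            pair = (d,)
            cue = d if cond == "one_target" else None
            set_plan(onset, end, d)
            choice, correct = d, True
        else:
            if balanced:
                axis = rr_axis[cond] % 4
                rr_axis[cond] += 1
            else:
                axis = int(rng.integers(4))
            favored, unfavored = axis, axis + 4
            pair = (favored, unfavored)
            initial = favored if rng.random() < config.axis_bias else unfavored

            if cond == "two_target_cued":
                cue = favored if rng.random() < 0.5 else unfavored
                # errors are failures to switch away from (or to stay with)
                # the initial plan, so they are conditional on whether that
                # plan agrees with the cue; the initial plan itself always
                # follows the axis bias
                error_type = 0
                u = rng.random()
                if initial != cue:
                    if u < config.error_rates.get(1, 0.0):
                        error_type = 1
                    elif u < config.error_rates.get(1, 0.0) + config.error_rates.get(
                        2, 0.0
                    ):
                        error_type = 2
                elif u < config.error_rates.get(3, 0.0):
                    error_type = 3
                set_plan(onset, end, initial)
                if error_type == 1:
                    pass  # never switches
                elif error_type == 2:
                    lat = min(
                        rng.exponential(config.switch_latency_ms),
                        (cue_off - cue_on) - 250.0,
                    )
                    switch = cue_on + max(lat, 0.0)
                    # the revert leads the pre-Go read-out window by more
                    # than the causal kernel's memory so the decoded plan
                    # can follow the latent one
                    revert = go - 350.0
                    set_plan(switch, revert, cue)
                elif error_type == 3:
                    set_plan(go - 350.0, end, opposite_direction(cue))
                elif initial != cue:
                    if rng.random() < config.late_switch_prob:
                        # holds the initial plan through Go, switching only
                        # during the reaction period (reach is still cued;
                        # the time cost shows up as a long reaction time)
                        set_plan(go + 100.0, end, cue)
                    else:
                        lat = min(
                            rng.exponential(config.switch_latency_ms),
                            (go - cue_on) - 250.0,
                        )
                        set_plan(cue_on + max(lat, 0.0), end, cue)
            else:  # free_choice
                cue = None
                set_plan(onset, end, initial)
                if rng.random() < config.fc_late_switch_rate:
                    switch = max(blank_on + BIN_MS, go - 125.0)
                    set_plan(switch, end, opposite_direction(initial))

            # the executed reach follows the final latent plan (which can
            # switch after Go on late-switch trials)
            choice = int(plan[-1]) if plan[-1] != NO_PLAN else int(
                rng.integers(N_DIRECTIONS)
            )
            correct = (choice == cue) if cue is not None else True

        if cond in ("one_target", "one_target_no_cue"):
            s_sd, s_range = (
                config.one_target_strength_sd,
                config.one_target_strength_range,
            )
        else:
            s_sd, s_range = config.plan_strength_sd, config.plan_strength_range
        strength = float(np.clip(rng.normal(1.0, s_sd), *s_range))
        if config.strength_ou_sd > 0:
            alpha = float(np.exp(-BIN_MS / config.strength_ou_tau_ms))
            innov_sd = config.strength_ou_sd * np.sqrt(1.0 - alpha**2)
            noise = rng.normal(0.0, innov_sd, size=n_bins)
            noise[0] = rng.normal(0.0, config.strength_ou_sd)
            ou = lfilter([1.0], [1.0, -alpha], noise)
            profile = np.clip(strength + ou, 0.02, 2.5)
        else:
            profile = np.full(n_bins, strength)
        trials.append(
            TrialRecord(
                trial_id=tid,
                condition=cond,
                target_pair=pair,
                cue_direction=cue,
                target_on_ms=t_on,
                blank_on_ms=blank_on,
                cue_on_ms=cue_on,
                cue_off_ms=cue_off,
                go_ms=go,
                end_ms=end,
                latent_plan=plan,
                choice=choice,
                correct=correct,
                error_type=error_type,
                plan_strength=strength,
                strength_profile=profile,
            )
        )
    return trials


# ---------------------------------------------------------------------------
# spikes


@dataclass
class SpikeData:
    """Spike timestamps (ms, relative to trial start) per unit and trial."""

    unit_ids: np.ndarray
    spikes: dict[int, list[np.ndarray]]  # trial_id -> [array per unit]

    @property
    def n_units(self) -> int:
        return self.unit_ids.size

    def trial_ids(self) -> list[int]:
        return sorted(self.spikes)


def trial_rate_profile(
    pop: PopulationModel,
    trial: TrialRecord,
    encoding: Literal["single", "dual"] = "single",
) -> np.ndarray:
    """Expected firing rate (units × bins, spikes/s) implied by the latent plan.

    ``single``: rate = (c + s(t)·d·cos(θ_plan − φ))² while a plan is
    active, c² = a otherwise, where s(t) is the trial's instantaneous plan
    strength.  From ~150 ms after the Go cue the population switches to
    its execution pattern (rotated PDs, scaled depth).  ``dual``: on
    two-target trials, bins before cue onset (before Go on Free-Choice)
    carry the mean of the two single-plan rates — a dual-representation
    code used only to test that the downstream metrics detect it.
    """
    n_bins = trial.n_bins
    prof = (
        trial.strength_profile
        if trial.strength_profile is not None
        else np.full(n_bins, trial.plan_strength)
    )
    active = trial.latent_plan != NO_PLAN

    def tuned(mod_vec: np.ndarray, cols: np.ndarray) -> np.ndarray:
        v = pop.sqrt_base[:, None] + np.outer(mod_vec, prof[cols])
        return np.maximum(v, 0.0) ** 2

    rates = np.tile(pop.a[:, None], (1, n_bins))
    for d in np.unique(trial.latent_plan[active]):
        cols = trial.latent_plan == d
        mod = pop.sqrt_depth * pop._modulation(DIRECTIONS_RAD[d] - pop.phi)
        rates[:, cols] = tuned(mod, cols)
    # execution-period pattern: movement command engages shortly after Go
    move_idx = int(np.ceil((trial.go_ms + 150.0) / BIN_MS))
    if move_idx < n_bins:
        cols = active.copy()
        cols[:move_idx] = False
        mod = pop.sqrt_depth_move * pop._modulation(
            DIRECTIONS_RAD[trial.choice] - pop.phi_move
        )
        rates[:, cols] = tuned(mod, cols)
    if encoding == "dual" and len(trial.target_pair) == 2:
        d0, d1 = trial.target_pair
        resolve_ms = trial.cue_on_ms if trial.cue_on_ms is not None else trial.go_ms
        resolve_idx = int(np.ceil(resolve_ms / BIN_MS))
        cols = active.copy()
        cols[resolve_idx:] = False
        mod0 = pop.sqrt_depth * pop._modulation(DIRECTIONS_RAD[d0] - pop.phi)
        mod1 = pop.sqrt_depth * pop._modulation(DIRECTIONS_RAD[d1] - pop.phi)
        rates[:, cols] = 0.5 * (tuned(mod0, cols) + tuned(mod1, cols))
    return rates


def generate_spikes(
    pop: PopulationModel,
    trials: Sequence[TrialRecord],
    seed: int = 0,
    encoding: Literal["single", "dual"] = "single",
) -> SpikeData:
    """Inhomogeneous-Poisson spikes from the latent plan, independent across units.

    The rate is piecewise constant on the 25 ms grid; counts are Poisson per
    bin with spike times uniform within the bin.  Per-trial multiplicative
    gains (see PopulationSpec) make the counts super-Poisson across trials.
    """
    rng = np.random.default_rng(seed)
    dt_s = BIN_MS / 1000.0
    spec = pop.spec
    drift = np.zeros(pop.n_units)  # random-walk excitability drift (√ units)

    def _ou(sd: float, tau_ms: float, shape: tuple[int, ...]) -> np.ndarray:
        alpha = np.exp(-BIN_MS / tau_ms)
        innov = rng.normal(0.0, sd * np.sqrt(1.0 - alpha**2), size=shape)
        innov[..., 0] = rng.normal(0.0, sd, size=shape[:-1])
        return lfilter([1.0], [1.0, -alpha], innov, axis=-1)

    out: dict[int, list[np.ndarray]] = {}
    for trial in trials:
        rates = trial_rate_profile(pop, trial, encoding)
        n_bins = rates.shape[1]
        # excess variability: additive, symmetric in the sqrt domain
        v = np.sqrt(rates)
        if spec.unit_gain_sd > 0:
            v += _ou(spec.unit_gain_sd, spec.unit_gain_tau_ms,
                     (pop.n_units, n_bins))
        if spec.unit_gain_trial_sd > 0:
            v += rng.normal(0.0, spec.unit_gain_trial_sd,
                            size=pop.n_units)[:, None]
        if spec.shared_noise_sd > 0:
            # shared fluctuation: random unit-space pattern, OU amplitude
            pattern = rng.normal(0.0, 1.0, size=pop.n_units)
            amp = _ou(spec.shared_noise_sd, spec.shared_noise_tau_ms, (n_bins,))
            v += np.outer(pattern, amp)
        if spec.drift_step_sd > 0:
            drift += rng.normal(0.0, spec.drift_step_sd, size=pop.n_units)
            v += drift[:, None]
        rates = np.maximum(v, 0.0) ** 2
        if spec.population_gain_sd > 0:
            s = spec.population_gain_sd
            rates = rates * rng.lognormal(-0.5 * s * s, s)
        counts = rng.poisson(rates * dt_s)  # units × bins
        per_unit: list[np.ndarray] = []
        for u in range(pop.n_units):
            c = counts[u]
            total = int(c.sum())
            if total == 0:
                per_unit.append(np.empty(0))
                continue
            bin_idx = np.repeat(np.arange(c.size), c)
            times = (bin_idx + rng.uniform(0.0, 1.0, size=total)) * BIN_MS
            times.sort()
            per_unit.append(times)
        out[trial.trial_id] = per_unit
    return SpikeData(unit_ids=np.arange(pop.n_units), spikes=out)


# ---------------------------------------------------------------------------
# kinematics


@dataclass(frozen=True)
class RTModel:
    """Reaction-time model: RT = base − gain·(plan strength at Go) + noise.

    Plan strength is the trial's latent strength scaled by the fraction of
    the 100 ms pre-Go window whose plan matches the eventual choice, so
    late plan switches lengthen RT.  Peak reach speed is log-normal around
    ``peak_speed_cm_s`` with log-sd ``peak_speed_log_sd``.
    """

    rt_base_ms: float = 320.0
    rt_gain_ms: float = 140.0
    rt_noise_sd_ms: float = 40.0
    rt_min_ms: float = 50.0
    rt_max_ms: float = 600.0
    peak_speed_cm_s: float = 23.9
    peak_speed_log_sd: float = 0.3


@dataclass
class KinematicsTrace:
    """Hand position and speed at 40 Hz for one trial.

    Speed is the finite-difference ‖Δposition‖/Δt (speed[0] = 0).  ``rt_ms``
    and ``move_end_ms`` are generator ground truth, not measurements.
    """

    trial_id: int
    t_ms: np.ndarray
    position_cm: np.ndarray  # n × 2
    speed_cm_s: np.ndarray
    rt_ms: float
    move_end_ms: float


def minimum_jerk_position(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk displacement profile on τ ∈ [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def generate_kinematics(
    trials: Sequence[TrialRecord],
    rt_model: RTModel | None = None,
    seed: int = 0,
    target_radius_cm: float = 7.0,
    sample_rate_hz: float = 40.0,
) -> dict[int, KinematicsTrace]:
    """Minimum-jerk reaches to the chosen target with RT tied to plan strength."""
    rt_model = rt_model or RTModel()
    rng = np.random.default_rng(seed)
    dt_ms = 1000.0 / sample_rate_hz
    out: dict[int, KinematicsTrace] = {}
    for trial in trials:
        # signed plan strength at Go: positive when the pre-Go plan already
        # points at the executed target, negative when the reach requires a
        # post-Go plan switch (switch time cost lengthens RT)
        pre_go = np.arange(
            int((trial.go_ms - 100.0) // BIN_MS), int(trial.go_ms // BIN_MS)
        )
        pre_go = pre_go[(pre_go >= 0) & (pre_go < trial.n_bins)]
        agree = (
            float(np.mean(trial.latent_plan[pre_go] == trial.choice))
            if pre_go.size
            else 0.0
        )
        strength = trial.plan_strength * (2.0 * agree - 1.0)
        rt = float(
            np.clip(
                rt_model.rt_base_ms
                - rt_model.rt_gain_ms * strength
                + rng.normal(0.0, rt_model.rt_noise_sd_ms),
                rt_model.rt_min_ms,
                rt_model.rt_max_ms,
            )
        )
        peak = rt_model.peak_speed_cm_s * np.exp(
            rng.normal(0.0, rt_model.peak_speed_log_sd)
        )
        move_dur_ms = 1000.0 * MIN_JERK_PEAK_FACTOR * target_radius_cm / peak
        onset = trial.go_ms + rt
        move_end = min(onset + move_dur_ms, trial.end_ms)

        t = np.arange(0.0, trial.end_ms, dt_ms)
        theta = DIRECTIONS_RAD[trial.choice]
        target = target_radius_cm * np.array([np.cos(theta), np.sin(theta)])
        tau = (t - onset) / move_dur_ms
        disp = minimum_jerk_position(tau)
        pos = disp[:, None] * target[None, :]
        speed = np.zeros_like(t)
        speed[1:] = np.linalg.norm(np.diff(pos, axis=0), axis=1) / (dt_ms / 1000.0)
        out[trial.trial_id] = KinematicsTrace(
            trial_id=trial.trial_id,
            t_ms=t,
            position_cm=pos,
            speed_cm_s=speed,
            rt_ms=rt,
            move_end_ms=move_end,
        )
    return out


# ---------------------------------------------------------------------------
# session bundle


@dataclass
class Session:
    """A complete synthetic session: population, trials, spikes, kinematics."""

    population: PopulationModel
    trials: list[TrialRecord]
    spikes: SpikeData
    kinematics: dict[int, KinematicsTrace]
    task_config: TaskConfig
    encoding: str = "single"

    def trials_by_condition(self, condition: str) -> list[TrialRecord]:
        return [t for t in self.trials if t.condition == condition]

    def get_trial(self, trial_id: int) -> TrialRecord:
        return self._index()[trial_id]

    def _index(self) -> dict[int, TrialRecord]:
        if not hasattr(self, "_trial_index"):
            self._trial_index = {t.trial_id: t for t in self.trials}
        return self._trial_index


def generate_session(
    n_trials: int = 400,
    seed: int = 0,
    pop_spec: PopulationSpec | None = None,
    task_config: TaskConfig | None = None,
    rt_model: RTModel | None = None,
    encoding: Literal["single", "dual"] = "single",
    balanced: bool = True,
) -> Session:
    """Generate a full session from one master seed.

    Independent RNG streams are derived per purpose (population, trials,
    spikes, kinematics) so e.g. adding trials does not perturb the population.
    Explicit seeds inside ``pop_spec``/``task_config`` override the derived
    streams when those objects are passed in.
    """
    child = np.random.SeedSequence(seed).spawn(4)
    derived = [int(c.generate_state(1)[0] % (2**31)) for c in child]
    if pop_spec is None:
        pop_spec = PopulationSpec(seed=derived[0])
    if task_config is None:
        task_config = TaskConfig(seed=derived[1])
    pop = generate_population(pop_spec)
    trials = generate_trials(task_config, n_trials, balanced=balanced)
    spikes = generate_spikes(pop, trials, seed=derived[2], encoding=encoding)
    kin = generate_kinematics(
        trials,
        rt_model,
        seed=derived[3],
        target_radius_cm=task_config.target_radius_cm,
    )
    return Session(
        population=pop,
        trials=trials,
        spikes=spikes,
        kinematics=kin,
        task_config=task_config,
        encoding=encoding,
    )
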