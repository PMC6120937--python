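"""Forward simulations of three candidate planning codes.

Given the per-unit tuning measured on 1-Target Target Blank activity, three
models predict the population response when two opposite targets are shown:

* ``dual_target`` — both targets encoded at once via an artificial bimodal
  tuning curve F_bi(θ) = 0.7·[a + b·cos(2(θ − φ))] built from each unit's
  fitted cosine parameters (the 0.7 matches the reported 1- vs 2-Target
  rate difference; changing it has no qualitative effect);
* ``averaged_plan`` — the mean of the two single-target responses,
  F_average(θ) = ½·(F_nonpar(θ) + F_nonpar(θ + π)), with F_nonpar the
  nonparametric per-direction mean activity;
* ``stay_or_switch`` — a single plan to one target, i.e. F_nonpar itself.

Responses are simulated without noise (one state per target pair, or per
target for stay-or-switch), projected into the session's 10-D state space
and scored with its clusters.  Dual-target and averaged-plan states land
near the proximity diagonal (high DRI); stay-or-switch states land on the
axes, indistinguishable from 1-Target planning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .preprocessing import RateMatrix, extract_epoch
from .state_space import (
    DirectionClusterSet,
    StateSpaceModel,
    dual_representation_index,
    proximity_matrix,
)
from .synthetic_data import (
    DIRECTIONS_RAD,
    N_DIRECTIONS,
    TrialRecord,
    opposite_direction,
)
from .tuning import TuningFit, fit_cosine_tuning

logger = logging.getLogger(__name__)

MODEL_NAMES = ("dual_target", "averaged_plan", "stay_or_switch")
DUAL_TARGET_SCALE = 0.7


@dataclass
class SessionTuning:
    """Per-unit tuning measured on 1-Target Target Blank activity.

    ``f_nonpar`` is the 8 × n_units matrix of per-direction mean activity
    (the nonparametric tuning curves); ``fits`` are the cosine fits to it.
    Values are in the same (square-root transformed) space as the rate
    pipeline unless the caller supplies pre-transform rates.
    """

    f_nonpar: np.ndarray
    fits: list[TuningFit]
    included: np.ndarray  # boolean per unit, False = not significantly tuned

    @property
    def n_units(self) -> int:
        return self.f_nonpar.shape[1]


def measure_session_tuning(
    rates: RateMatrix,
    trials: Sequence[TrialRecord],
    significant: np.ndarray | None = None,
) -> SessionTuning:
    """Nonparametric and cosine tuning from 1-Target Target Blank activity.

    ``significant`` (boolean per unit, e.g. from the bootstrap test) marks
    units whose modeled modulation is trusted; unmarked units are excluded
    from model-specific modulation and contribute their mean activity.
    """
    one_target = [t for t in trials if t.condition == "one_target"]
    blank = extract_epoch(rates, one_target, "blank")
    f_nonpar = np.vstack(
        [blank.X[blank.directions == d].mean(axis=0) for d in range(N_DIRECTIONS)]
    )
    fits = [
        fit_cosine_tuning(f_nonpar[:, u], DIRECTIONS_RAD)
        for u in range(f_nonpar.shape[1])
    ]
    if significant is None:
        included = np.ones(f_nonpar.shape[1], dtype=bool)
    else:
        included = np.asarray(significant, dtype=bool)
        if not included.all():
            logger.info(
                "hypothesis models: %d units without significant tuning "
                "contribute only their mean activity",
                int((~included).sum()),
            )
    return SessionTuning(f_nonpar=f_nonpar, fits=fits, included=included)


@dataclass
class ModelResponse:
    """One noiseless simulated population response, projected and scored."""

    model: str
    target_pair: tuple[int, int]
    rates: np.ndarray  # per-unit simulated Target Blank activity
    state: np.ndarray  # 10-D projection
    prox_a: float
    prox_b: float
    dri: float = field(init=False)

    def __post_init__(self) -> None:
        self.dri = float(dual_representation_index(self.prox_a, self.prox_b))


def _model_rates(
    model: str, tuning: SessionTuning, pair: tuple[int, int]
) -> np.ndarray:
    theta = DIRECTIONS_RAD[pair[0]]
    a = np.array([f.a for f in tuning.fits])
    b = np.array([f.b for f in tuning.fits])
    phi = np.array([f.phi for f in tuning.fits])
    if model == "dual_target":
        out = DUAL_TARGET_SCALE * (a + b * np.cos(2.0 * (theta - phi)))
    elif model == "averaged_plan":
        out = 0.5 * (tuning.f_nonpar[pair[0]] + tuning.f_nonpar[pair[1]])
    elif model == "stay_or_switch":
        out = tuning.f_nonpar[pair[0]]
    else:
        raise ValueError(f"unknown model {model!r}; expected one of {MODEL_NAMES}")
    # untuned units carry their direction-averaged activity instead
    mean_activity = tuning.f_nonpar.mean(axis=0)
    return np.where(tuning.included, out, mean_activity)


def simulate_model_states(
    model: Literal["dual_target", "averaged_plan", "stay_or_switch"],
    tuning: SessionTuning,
    pair: tuple[int, int],
    state_space: StateSpaceModel,
    clusters: DirectionClusterSet,
    transform: bool = False,
) -> ModelResponse:
    """Simulate one model response for a target pair and score it.

    ``tuning`` is normally measured on the pipeline's transformed activity,
    in which case the simulated rates are projected directly
    (``transform=False``).  If tuning was measured on pre-transform rates,
    set ``transform=True`` to square-root the simulated response first.
    """
    if opposite_direction(pair[0]) != pair[1]:
        raise ValueError("pair must be two directions 180° apart")
    r = _model_rates(model, tuning, pair)
    v = np.sqrt(np.maximum(r, 0.0)) if transform else r
    state = state_space.project(v[None, :])
    prox = proximity_matrix(state, clusters)[0]
    return ModelResponse(
        model=model,
        target_pair=pair,
        rates=r,
        state=state[0],
        prox_a=float(prox[pair[0]]),
        prox_b=float(prox[pair[1]]),
    )


def simulate_all_models(
    tuning: SessionTuning,
    state_space: StateSpaceModel,
    clusters: DirectionClusterSet,
    transform: bool = False,
) -> list[ModelResponse]:
    """All model responses for a session: 4 axes × dual/averaged plus the
    8 single-target stay-or-switch states."""
    out: list[ModelResponse] = []
    for axis in range(N_DIRECTIONS // 2):
        pair = (axis, opposite_direction(axis))
        for model in ("dual_target", "averaged_plan"):
            out.append(
                simulate_model_states(
                    model, tuning, pair, state_space, clusters, transform
                )
            )
    for d in range(N_DIRECTIONS):
        pair = (d, opposite_direction(d))
        out.append(
            simulate_model_states(
                "stay_or_switch", tuning, pair, state_space, clusters, transform
            )
        )
    return out
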