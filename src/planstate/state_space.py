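"""Low-dimensional neural state space, proximity decoding, and the DRI.

Population firing rates from 1-Target trials are reduced to a 10-D state by
PCA.  For each reach direction i the states visited from 500 ms after
Target On until trial completion form a reference cluster {C_i}.  The
proximity of a state S to direction i is a normalized likelihood ratio

    Proximity(S, {C_i}) = P(d | i) / sum_j P(d | j),   d = D_M(S, {C_i})

where D_M is the Mahalanobis distance to cluster i and P(d | j) is the
density of that same distance under the empirical distribution of
distances-to-cluster-i from states belonging to direction j.  The
normalization bounds the metric in [0, 1] and makes it conservative: a
state far from every cluster has near-zero proximity to all of them, so
the signed difference of proximities to the two ends of a target axis
(ΔProximity) reports plan strength, not mere relative nearness.  The dual
representation index (DRI) is high only when a state is simultaneously
close to both clusters of an axis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp
from sklearn.decomposition import PCA

from .preprocessing import RateMatrix, extract_epoch
from .synthetic_data import N_DIRECTIONS, TrialRecord

logger = logging.getLogger(__name__)

N_COMPONENTS = 10
DENSITY_FLOOR = 1e-12
DRI_THRESHOLD = 0.2
MIN_STATES_MARGIN = 5  # require at least n_dim + margin states per cluster

# Rates smoothed with a 150 ms causal kernel riding on ~300 ms latent
# fluctuations decorrelate over ~12 of the 25 ms bins; distance samples
# from consecutive bins count as 1/12 of an independent draw for KDE
# bandwidth selection.
STATE_DECORRELATION_BINS = 12

# A 1-D density needs no more samples than this; larger sample sets are
# strided down so proximity evaluation stays linear in session size.
MAX_DENSITY_SAMPLES = 2000


# ---------------------------------------------------------------------------
# state space


@dataclass
class StateSpaceModel:
    """Top-10 principal axes of the 1-Target population activity.

    ``components`` (10 × n_kept) and ``mean`` act on the units retained
    after dropping zero-variance units (``kept_units`` indexes the original
    unit order); ``project`` accepts full-width activity rows.
    """

    components: np.ndarray
    mean: np.ndarray
    kept_units: np.ndarray
    explained_variance: np.ndarray
    n_total_units: int

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def project(self, X: np.ndarray) -> np.ndarray:
        """Project activity rows (n × n_units) into the 10-D state space."""
        X = np.atleast_2d(X)
        return (X[:, self.kept_units] - self.mean) @ self.components.T


def fit_state_space(
    rates: RateMatrix,
    trials: Sequence[TrialRecord],
    n_components: int = N_COMPONENTS,
) -> StateSpaceModel:
    """PCA of the concatenated 1-Target firing rates M (units × all time bins).

    ``trials`` should be the 1-Target set; all of each trial's bins enter M.
    Units with zero variance across M are dropped with a warning.
    """
    one_target = [t for t in trials if t.condition == "one_target"]
    if not one_target:
        raise ValueError("no 1-Target trials to fit the state space on")
    X = np.hstack([rates.values[t.trial_id] for t in one_target]).T  # bins × units
    variances = X.var(axis=0)
    kept = np.flatnonzero(variances > 0)
    if kept.size < X.shape[1]:
        warnings.warn(
            f"dropping {X.shape[1] - kept.size} zero-variance units from PCA",
            stacklevel=2,
        )
    n_components = min(n_components, kept.size)
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X[:, kept])
    return StateSpaceModel(
        components=pca.components_,
        mean=pca.mean_,
        kept_units=kept,
        explained_variance=pca.explained_variance_,
        n_total_units=X.shape[1],
    )


# ---------------------------------------------------------------------------
# distance densities


@dataclass
class _Density1D:
    """Density estimate over a 1-D sample of Mahalanobis distances."""

    samples: np.ndarray
    kind: Literal["kde", "hist"] = "kde"
    bandwidth: float = 0.0
    hist_edges: np.ndarray | None = None
    hist_density: np.ndarray | None = None

    @classmethod
    def fit(
        cls, samples: np.ndarray, kind: str = "kde", n_eff: float | None = None
    ) -> "_Density1D":
        """Fit the estimator; ``n_eff`` overrides the sample count in
        Silverman's rule when samples are autocorrelated (consecutive
        smoothed time bins are not independent draws)."""
        samples = np.asarray(samples, dtype=float)
        if samples.size > MAX_DENSITY_SAMPLES:
            stride = int(np.ceil(samples.size / MAX_DENSITY_SAMPLES))
            samples = samples[::stride]
        if kind == "kde":
            n = n_eff if n_eff is not None else samples.size
            n = min(n, samples.size)
            sd = samples.std()
            iqr = np.subtract(*np.percentile(samples, [75, 25]))
            spread = min(sd, iqr / 1.34) if iqr > 0 else sd
            h = 0.9 * spread * n ** (-0.2) if spread > 0 else 1e-3
            return cls(samples=samples, kind="kde", bandwidth=max(h, 1e-6))
        if kind == "hist":
            dens, edges = np.histogram(samples, bins="auto", density=True)
            return cls(samples=samples, kind="hist",
                       hist_edges=edges, hist_density=dens)
        raise ValueError(f"unknown density estimator {kind!r}")

    def log_pdf(self, x: np.ndarray) -> np.ndarray:
        """Log density; evaluated in log space so the Gaussian-kernel tail
        never underflows and distance ordering is preserved arbitrarily far
        from the sample support."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if self.kind == "kde":
            norm = np.log(self.samples.size * self.bandwidth * np.sqrt(2.0 * np.pi))
            out = np.empty(x.size)
            for lo in range(0, x.size, 4096):  # bound the query × samples block
                z = (x[lo:lo + 4096, None] - self.samples[None, :]) / self.bandwidth
                out[lo:lo + 4096] = logsumexp(-0.5 * z**2, axis=1) - norm
        else:
            idx = np.searchsorted(self.hist_edges, x, side="right") - 1
            inside = (idx >= 0) & (idx < self.hist_density.size)
            dens = np.where(inside, self.hist_density[np.clip(idx, 0, None)], 0.0)
            out = np.log(np.maximum(dens, DENSITY_FLOOR))
        return out

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return np.exp(self.log_pdf(x))


# ---------------------------------------------------------------------------
# direction clusters


@dataclass
class DirectionClusterSet:
    """Per-direction reference state clouds and their distance distributions.

    ``states[i]`` holds the 10-D states of direction i over the cluster
    window; ``means``/``chol_factors`` give the regularized Gaussian summary
    used for Mahalanobis distances; ``densities[(j, i)]`` estimates the
    distribution of distances-to-cluster-i among states of direction j.
    """

    states: list[np.ndarray]
    state_trial_ids: list[np.ndarray]
    means: np.ndarray  # 8 × 10
    chol_factors: list[np.ndarray]  # lower Cholesky of regularized covariances
    densities: dict[tuple[int, int], _Density1D]
    shrinkage: float
    density_kind: str

    @property
    def n_directions(self) -> int:
        return self.means.shape[0]

    def mahalanobis(self, X: np.ndarray, direction: int) -> np.ndarray:
        """D_M of each row of X to cluster ``direction``."""
        return _mahalanobis(X, self.means[direction], self.chol_factors[direction])

    def proximity_matrix(self, X: np.ndarray) -> np.ndarray:
        return proximity_matrix(X, self)


def _regularized_cholesky(states: np.ndarray, shrinkage: float) -> np.ndarray:
    cov = np.cov(states, rowvar=False)
    dim = cov.shape[0]
    target = (np.trace(cov) / dim) * np.eye(dim)
    cov = (1.0 - shrinkage) * cov + shrinkage * target
    return np.linalg.cholesky(cov)


def _mahalanobis(X: np.ndarray, mean: np.ndarray, chol: np.ndarray) -> np.ndarray:
    z = solve_triangular(chol, (np.atleast_2d(X) - mean).T, lower=True)
    return np.sqrt(np.einsum("ij,ij->j", z, z))


def build_direction_clusters(
    model: StateSpaceModel,
    rates: RateMatrix,
    trials: Sequence[TrialRecord],
    shrinkage: float = 0.1,
    density: str = "kde",
    exclude_trials: Iterable[int] = (),
) -> DirectionClusterSet:
    """Build the eight reference clusters from 1-Target cluster-window states.

    ``exclude_trials`` removes those trials' states everywhere (cluster
    means, covariances, and distance distributions) — used for
    leave-one-trial-out scoring.  A direction with fewer than
    n_dim + margin states raises, naming the direction.
    """
    one_target = [t for t in trials if t.condition == "one_target"]
    epoch = extract_epoch(rates, one_target, "cluster_window")
    states = model.project(epoch.X)
    return clusters_from_states(
        states, epoch.directions, epoch.trial_ids,
        shrinkage=shrinkage, density=density, exclude_trials=exclude_trials,
    )


def clusters_from_states(
    states: np.ndarray,
    directions: np.ndarray,
    trial_ids: np.ndarray,
    shrinkage: float = 0.1,
    density: str = "kde",
    exclude_trials: Iterable[int] = (),
    n_directions: int = N_DIRECTIONS,
) -> DirectionClusterSet:
    """Assemble clusters and all ordered-pair distance densities from states."""
    excluded = set(exclude_trials)
    if excluded:
        keep = ~np.isin(trial_ids, list(excluded))
        states, directions, trial_ids = states[keep], directions[keep], trial_ids[keep]

    dim = states.shape[1]
    by_dir: list[np.ndarray] = []
    tids: list[np.ndarray] = []
    for i in range(n_directions):
        mask = directions == i
        if mask.sum() < dim + MIN_STATES_MARGIN:
            raise ValueError(
                f"direction {i}: only {int(mask.sum())} states; need at least "
                f"{dim + MIN_STATES_MARGIN} to estimate the cluster"
            )
        by_dir.append(states[mask])
        tids.append(trial_ids[mask])

    means = np.vstack([s.mean(axis=0) for s in by_dir])
    chols = [_regularized_cholesky(s, shrinkage) for s in by_dir]

    # Every state this set will ever score is outside the cluster it is
    # scored against, so all distance distributions must describe
    # out-of-sample distances.  Cross-direction samples (j != i) are
    # out-of-sample by construction; the within-direction samples are made
    # so by holding each contributing trial out of the cluster summary
    # before measuring its states' distances.
    densities: dict[tuple[int, int], _Density1D] = {}
    for i in range(n_directions):
        within = np.empty(by_dir[i].shape[0])
        for tid in np.unique(tids[i]):
            mask = tids[i] == tid
            rest = by_dir[i][~mask]
            mu = rest.mean(axis=0)
            chol = _regularized_cholesky(rest, shrinkage)
            within[mask] = _mahalanobis(by_dir[i][mask], mu, chol)
        densities[(i, i)] = _Density1D.fit(
            within, kind=density, n_eff=within.size / STATE_DECORRELATION_BINS
        )
        for j in range(n_directions):
            if j == i:
                continue
            d = _mahalanobis(by_dir[j], means[i], chols[i])
            densities[(j, i)] = _Density1D.fit(
                d, kind=density, n_eff=d.size / STATE_DECORRELATION_BINS
            )

    return DirectionClusterSet(
        states=by_dir,
        state_trial_ids=tids,
        means=means,
        chol_factors=chols,
        densities=densities,
        shrinkage=shrinkage,
        density_kind=density,
    )


def mahalanobis_distance(
    X: np.ndarray, clusters: DirectionClusterSet, direction: int
) -> np.ndarray:
    """Mahalanobis distance of each state row to one direction cluster."""
    return _mahalanobis(X, clusters.means[direction], clusters.chol_factors[direction])


def proximity_matrix(X: np.ndarray, clusters: DirectionClusterSet) -> np.ndarray:
    """Proximity of each state row to every direction; shape (n, 8), in [0, 1].

    For each direction i the distance d = D_M(S, {C_i}) is scored by the
    within-direction density (numerator) against the sum of the densities of
    the same d under every direction's distance-to-cluster-i distribution
    (denominator).  Densities are floored, so a state beyond all empirical
    supports degrades to the uniform ratio 1/8.
    """
    X = np.atleast_2d(X)
    n_dir = clusters.n_directions
    out = np.empty((X.shape[0], n_dir))
    tail_events = 0
    for i in range(n_dir):
        d = mahalanobis_distance(X, clusters, i)
        logs = np.stack(
            [clusters.densities[(j, i)].log_pdf(d) for j in range(n_dir)]
        )
        log_num = logs[i]
        log_den = logsumexp(logs, axis=0)
        tail_events += int(np.sum(log_num < np.log(DENSITY_FLOOR)))
        out[:, i] = np.clip(np.exp(log_num - log_den), 0.0, 1.0)
    if tail_events:
        logger.debug("proximity: %d distance evaluations beyond the empirical "
                     "support of the within-direction distances", tail_events)
    return out


def proximity(
    state: np.ndarray, clusters: DirectionClusterSet, direction: int
) -> float:
    """Proximity of a single 10-D state to one direction's cluster."""
    return float(proximity_matrix(np.atleast_2d(state), clusters)[0, direction])


def delta_proximity(
    states: np.ndarray, clusters: DirectionClusterSet, pair: tuple[int, int]
) -> np.ndarray:
    """Signed proximity difference toward the first direction of ``pair``.

    Positive values indicate a plan toward ``pair[0]``.  Swapping the pair
    flips the sign exactly.  States far from both clusters give values near
    zero regardless of their relative nearness (the conservative-decoder
    property).
    """
    prox = proximity_matrix(states, clusters)
    return prox[:, pair[0]] - prox[:, pair[1]]


def classify_direction(
    states: np.ndarray, clusters: DirectionClusterSet
) -> int:
    """8-way direction read-out: argmax of the mean proximity over the bins.

    Ties break deterministically toward the lowest direction index and are
    logged.
    """
    mean_prox = proximity_matrix(states, clusters).mean(axis=0)
    best = float(mean_prox.max())
    winners = np.flatnonzero(mean_prox == best)
    if winners.size > 1:
        logger.info("classify_direction: tie among directions %s", winners.tolist())
    return int(winners[0])


def classify_one_target_trials(
    model: StateSpaceModel,
    rates: RateMatrix,
    trials: Sequence[TrialRecord],
    epoch: str = "blank",
    leave_one_out: bool = True,
    shrinkage: float = 0.1,
    density: str = "kde",
) -> tuple[np.ndarray, np.ndarray, float]:
    """Classify each 1-Target trial's epoch states; returns (pred, true, accuracy).

    With ``leave_one_out`` the scored trial is excluded from cluster
    construction (means, covariances, and distance distributions), removing
    the optimistic bias of scoring a trial against clusters that contain it.
    """
    one_target = [t for t in trials if t.condition == "one_target"]
    cluster_epoch = extract_epoch(rates, one_target, "cluster_window")
    cluster_states = model.project(cluster_epoch.X)
    score_epoch = extract_epoch(rates, one_target, epoch)

    preds, truths = [], []
    full = None
    if not leave_one_out:
        full = clusters_from_states(
            cluster_states, cluster_epoch.directions, cluster_epoch.trial_ids,
            shrinkage=shrinkage, density=density,
        )
    for trial in one_target:
        X = model.project(score_epoch.for_trial(trial.trial_id))
        if X.size == 0:
            continue
        clusters = full if full is not None else clusters_from_states(
            cluster_states, cluster_epoch.directions, cluster_epoch.trial_ids,
            shrinkage=shrinkage, density=density,
            exclude_trials=[trial.trial_id],
        )
        preds.append(classify_direction(X, clusters))
        truths.append(trial.presented_direction)
    preds_arr = np.array(preds)
    truths_arr = np.array(truths)
    accuracy = float(np.mean(preds_arr == truths_arr))
    return preds_arr, truths_arr, accuracy


# ---------------------------------------------------------------------------
# dual representation index


@dataclass(frozen=True)
class DRIValue:
    """A dual-representation index with the two proximities that produced it."""

    prox_a: float
    prox_b: float

    @property
    def value(self) -> float:
        return float(dual_representation_index(self.prox_a, self.prox_b))


def dual_representation_index(prox_a, prox_b):
    """DRI = sqrt((pa² + pb²)/2) · ((pa + pb)/max(pa, pb) − 1).

    The first factor grows with distance from the origin of the proximity
    plane, the second with closeness to its diagonal; the product is
    approximately min(pa, pb), equals p on the diagonal (pa = pb = p), and
    vanishes whenever either proximity is zero.  Defined as 0 at (0, 0).
    """
    pa = np.asarray(prox_a, dtype=float)
    pb = np.asarray(prox_b, dtype=float)
    if np.any(pa < 0) or np.any(pb < 0) or np.any(pa > 1) or np.any(pb > 1):
        raise ValueError("proximities must lie in [0, 1]")
    rms = np.sqrt((pa**2 + pb**2) / 2.0)
    mx = np.maximum(pa, pb)
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.where(mx > 0, (pa + pb) / np.where(mx > 0, mx, 1.0) - 1.0, 0.0)
    out = rms * skew
    return out if out.shape else float(out)


def dri_threshold_summary(dri_values, threshold: float = DRI_THRESHOLD) -> float:
    """Fraction of DRI values strictly above the threshold."""
    dri_values = np.asarray(dri_values, dtype=float)
    if dri_values.size == 0:
        raise ValueError("no DRI values supplied")
    return float(np.mean(dri_values > threshold))


def dri_for_trials(
    model: StateSpaceModel,
    rates: RateMatrix,
    trials: Sequence[TrialRecord],
    clusters: DirectionClusterSet,
    epoch: str = "blank",
) -> np.ndarray:
    """DRI of every epoch bin of every trial, against the trial's target axis.

    For 1-Target trials the axis is (presented, opposite); for two-target
    trials it is the displayed pair.
    """
    epoch_act = extract_epoch(rates, trials, epoch)
    if epoch_act.X.shape[0] == 0:
        return np.empty(0)
    states = model.project(epoch_act.X)
    prox = proximity_matrix(states, clusters)
    trial_axis = {t.trial_id: t.axis_pair for t in trials}
    a_idx = np.array([trial_axis[tid][0] for tid in epoch_act.trial_ids])
    b_idx = np.array([trial_axis[tid][1] for tid in epoch_act.trial_ids])
    rows = np.arange(prox.shape[0])
    return dual_representation_index(prox[rows, a_idx], prox[rows, b_idx])
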