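"""State space, proximity metric, classification, and DRI."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import planstate as ps
from planstate import state_space as ss
from planstate.preprocessing import estimate_firing_rates


def _gaussian_clusters(
    rng, n_dir=8, dim=10, n_per=80, separation=8.0, trials_per_dir=4
):
    """Synthetic 10-D direction clusters on a ring, with trial labels."""
    states, dirs, tids = [], [], []
    for d in range(n_dir):
        angle = 2 * np.pi * d / n_dir
        mean = np.zeros(dim)
        mean[0], mean[1] = separation * np.cos(angle), separation * np.sin(angle)
        x = rng.normal(0, 1, size=(n_per, dim)) + mean
        states.append(x)
        dirs.append(np.full(n_per, d))
        tids.append(d * trials_per_dir + (np.arange(n_per) % trials_per_dir))
    return (
        np.vstack(states),
        np.concatenate(dirs),
        np.concatenate(tids),
    )


@pytest.fixture(scope="module")
def ring_clusters(request):
    rng = np.random.default_rng(42)
    states, dirs, tids = _gaussian_clusters(rng)
    return ss.clusters_from_states(states, dirs, tids)


class TestStateSpaceFit:
    def test_rank_deficient_data_has_empty_trailing_axes(self, medium_session):
        """Activity lying exactly in a 3-D subspace leaves axes 4-10 with
        zero explained variance."""
        rates = estimate_firing_rates(
            medium_session.spikes, medium_session.trials
        )
        # project every bin onto 3 fixed random directions in unit space
        rng = np.random.default_rng(0)
        basis = np.linalg.qr(rng.normal(size=(120, 3)))[0]
        flat = {
            tid: basis @ (basis.T @ v) for tid, v in rates.values.items()
        }
        rates3 = ps.RateMatrix(
            values=flat, bin_times=rates.bin_times, unit_ids=rates.unit_ids
        )
        model = ps.fit_state_space(rates3, medium_session.trials)
        assert model.explained_variance[:3].min() > 1e-6
        assert model.explained_variance[3:].max() < 1e-9

    def test_unit_permutation_invariance(self, medium_analysis, medium_session):
        rates = medium_analysis.rates
        rng = np.random.default_rng(1)
        perm = rng.permutation(rates.n_units)
        permuted = ps.RateMatrix(
            values={tid: v[perm] for tid, v in rates.values.items()},
            bin_times=rates.bin_times,
            unit_ids=rates.unit_ids,
        )
        m1 = medium_analysis.state_space
        m2 = ps.fit_state_space(permuted, medium_session.trials)
        tid = medium_session.trials[0].trial_id
        p1 = m1.project(rates.values[tid].T)
        p2 = m2.project(permuted.values[tid].T)
        # principal axes have arbitrary sign; compare up to per-axis sign
        signs = np.sign(np.sum(p1 * p2, axis=0))
        np.testing.assert_allclose(p1, p2 * signs, atol=1e-6)

    def test_reconstruction_error_identity(self, medium_analysis):
        """Total variance minus the top-10 eigenvalue sum equals the
        variance left out of the projection."""
        rates = medium_analysis.rates
        one_target = [
            t for t in medium_analysis.session.trials if t.condition == "one_target"
        ]
        X = np.hstack([rates.values[t.trial_id] for t in one_target]).T
        model = medium_analysis.state_space
        total_var = X.var(axis=0, ddof=1).sum()
        proj = model.project(X)
        recon = proj @ model.components + model.mean
        resid_var = (X - recon).var(axis=0, ddof=1).sum()
        expect = total_var - model.explained_variance.sum()
        assert resid_var == pytest.approx(expect, rel=1e-6)


class TestMahalanobis:
    def test_matches_bruteforce_inverse_on_3d_toys(self, rng):
        states = rng.normal(size=(60, 3)) @ np.diag([3.0, 1.0, 0.5])
        dirs = np.repeat(np.arange(4), 15)
        tids = np.arange(60) // 5
        cl = ss.clusters_from_states(
            states, dirs, tids, n_directions=4, shrinkage=0.1
        )
        query = rng.normal(size=(7, 3))
        for i in range(4):
            member = states[dirs == i]
            cov = np.cov(member, rowvar=False)
            cov = 0.9 * cov + 0.1 * (np.trace(cov) / 3) * np.eye(3)
            inv = np.linalg.inv(cov)
            mu = member.mean(axis=0)
            expect = np.sqrt(
                np.einsum("ij,jk,ik->i", query - mu, inv, query - mu)
            )
            np.testing.assert_allclose(
                cl.mahalanobis(query, i), expect, atol=1e-10
            )

    def test_within_distances_are_chi_distributed(self, rng):
        """Distances of Gaussian cluster members to their own cluster follow
        approximately a chi distribution with dim degrees of freedom."""
        states, dirs, tids = _gaussian_clusters(rng, n_per=400, trials_per_dir=20)
        cl = ss.clusters_from_states(states, dirs, tids, shrinkage=0.0)
        d = cl.mahalanobis(cl.states[0], 0)
        qs = np.linspace(0.05, 0.95, 19)
        sample_q = np.quantile(d, qs)
        chi_q = stats.chi.ppf(qs, df=10)
        assert np.abs(sample_q - chi_q).max() < 0.35

    def test_cluster_mean_has_near_zero_self_distance(self, ring_clusters):
        for i in range(8):
            d = ring_clusters.mahalanobis(
                ring_clusters.means[i][None, :], i
            )
            assert d[0] < 1e-9


class TestProximity:
    def test_state_at_cluster_mean_is_near_and_far(self, ring_clusters):
        for i in range(8):
            prox = ss.proximity_matrix(
                ring_clusters.means[i][None, :], ring_clusters
            )[0]
            assert prox[i] > 0.9
            assert prox[(i + 4) % 8] < 0.05

    def test_identical_clusters_give_uniform_proximity(self, rng):
        """With all eight clusters identical, any in-support state is
        equally proximal to each (ratio forced to ~1/8).  Far outliers are
        excluded: the out-of-sample within-densities are deliberately
        longer-tailed than the cross densities there."""
        base = rng.normal(size=(160, 10))
        states = np.vstack([base for _ in range(8)])
        dirs = np.repeat(np.arange(8), 160)
        tids = np.concatenate([np.arange(160) // 20 + 8 * d for d in range(8)])
        cl = ss.clusters_from_states(states, dirs, tids)
        prox = ss.proximity_matrix(base[:30], cl)
        np.testing.assert_allclose(prox, 1.0 / 8.0, atol=0.05)

    def test_identical_clusters_cross_distances_coincide(self, rng):
        """The two cross-direction distance samples between identical
        clusters are the same point set."""
        base = rng.normal(size=(160, 10))
        states = np.vstack([base, base])
        dirs = np.repeat([0, 1], 160)
        tids = np.concatenate([np.arange(160) // 20, np.arange(160) // 20 + 8])
        cl = ss.clusters_from_states(states, dirs, tids, n_directions=2)
        np.testing.assert_allclose(
            np.sort(cl.densities[(0, 1)].samples),
            np.sort(cl.densities[(1, 0)].samples),
            atol=1e-9,
        )

    def test_bounded_in_unit_interval(self, ring_clusters, rng):
        X = rng.normal(0, 20, size=(200, 10))
        prox = ss.proximity_matrix(X, ring_clusters)
        assert (prox >= 0).all() and (prox <= 1).all()

    def test_conservative_far_state_decay(self, ring_clusters):
        """Moving a state radially away from every cluster drives the
        absolute proximity difference toward zero."""
        direction = np.ones(10) / np.sqrt(10)
        radii = [30.0, 60.0, 120.0]
        gaps = []
        for r in radii:
            dp = ss.delta_proximity(
                (r * direction)[None, :], ring_clusters, (0, 4)
            )[0]
            gaps.append(abs(dp))
        assert gaps[0] < 0.05
        assert gaps[-1] <= gaps[0] + 1e-12

    def test_too_few_states_error_names_direction(self, rng):
        states, dirs, tids = _gaussian_clusters(rng, n_per=30)
        short = dirs != 3
        states2 = np.vstack([states[short], states[dirs == 3][:8]])
        dirs2 = np.concatenate([dirs[short], np.full(8, 3)])
        tids2 = np.concatenate([tids[short], np.full(8, 999)])
        with pytest.raises(ValueError, match="direction 3"):
            ss.clusters_from_states(states2, dirs2, tids2)


class TestDeltaProximityAndClassification:
    def test_pair_swap_flips_sign_exactly(self, ring_clusters, rng):
        X = rng.normal(size=(20, 10)) * 3
        d1 = ss.delta_proximity(X, ring_clusters, (2, 6))
        d2 = ss.delta_proximity(X, ring_clusters, (6, 2))
        np.testing.assert_allclose(d1, -d2, atol=1e-12)

    def test_states_near_a_cluster_classify_to_it(self, ring_clusters, rng):
        for i in range(8):
            X = ring_clusters.means[i] + rng.normal(0, 0.3, size=(12, 10))
            assert ss.classify_direction(X, ring_clusters) == i

    def test_equal_proximities_break_toward_lowest_index(self, rng):
        base = rng.normal(size=(160, 10))
        states = np.vstack([base for _ in range(8)])
        dirs = np.repeat(np.arange(8), 160)
        tids = np.concatenate([np.arange(160) // 20 + 8 * d for d in range(8)])
        cl = ss.clusters_from_states(states, dirs, tids)
        # all clusters identical: proximities tie, index 0 wins
        assert ss.classify_direction(np.zeros((1, 10)), cl) == 0


class TestDRI:
    def test_printed_formula_examples(self):
        assert ss.dual_representation_index(0.7, 0.0) == 0.0
        assert ss.dual_representation_index(1.0, 1.0) == pytest.approx(1.0)
        assert ss.dual_representation_index(0.8, 0.4) == pytest.approx(
            np.sqrt(0.4) * 0.5
        )
        assert ss.dual_representation_index(0.0, 0.0) == 0.0

    @given(
        p=st.floats(0.0, 1.0),
        q=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetry_bounds_and_diagonal(self, p, q):
        dri = ss.dual_representation_index(p, q)
        assert dri == pytest.approx(ss.dual_representation_index(q, p), abs=1e-12)
        assert 0.0 <= dri <= np.sqrt((p**2 + q**2) / 2) + 1e-12
        assert ss.dual_representation_index(p, p) == pytest.approx(p, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ss.dual_representation_index(1.2, 0.5)

    def test_threshold_summary(self):
        assert ss.dri_threshold_summary(np.zeros(50)) == 0.0
        assert ss.dri_threshold_summary([0.1, 0.3, 0.5]) == pytest.approx(2 / 3)
        with pytest.raises(ValueError):
            ss.dri_threshold_summary([])

    def test_dri_value_container(self):
        v = ss.DRIValue(prox_a=0.8, prox_b=0.4)
        assert v.value == pytest.approx(np.sqrt(0.4) * 0.5)


class TestSessionDecoding:
    def test_one_target_classification_without_cv_is_high(self, medium_analysis):
        """Scoring trials against clusters that contain them (the literal,
        optimistically biased protocol) classifies nearly all trials."""
        _, _, acc = medium_analysis.classify_one_target(leave_one_out=False)
        assert acc >= 0.95

    def test_single_plan_session_rarely_exceeds_dri_threshold(
        self, medium_analysis
    ):
        assert medium_analysis.dri_fraction("one_target") <= 0.05
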