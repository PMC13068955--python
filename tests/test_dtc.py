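"""Deep temporal clustering: equations, autoencoder, training, k selection."""

import numpy as np
import pytest

from fontanflow import dtc, phantom as ph
from fontanflow.flowquant import FlowCurve


def brute_force_soft_assign(z, mu):
    n, k = len(z), len(mu)
    q = np.zeros((n, k))
    for i in range(n):
        denom = 0.0
        for jp in range(k):
            denom += (1.0 + np.sum((z[i] - mu[jp]) ** 2)) ** -1
        for j in range(k):
            q[i, j] = (1.0 + np.sum((z[i] - mu[j]) ** 2)) ** -1 / denom
    return q


def brute_force_target(q):
    n, k = q.shape
    f = q.sum(axis=0)
    p = np.zeros_like(q)
    for i in range(n):
        denom = 0.0
        for jp in range(k):
            denom += q[i, jp] ** 2 / f[jp]
        for j in range(k):
            p[i, j] = (q[i, j] ** 2 / f[j]) / denom
    return p


class TestSoftAssign:
    def test_equidistant_point_gets_uniform_assignment(self):
        mu = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        q = dtc.soft_assign(np.zeros((1, 2)), mu)
        np.testing.assert_allclose(q, 0.25)

    def test_hand_computed_two_centroid_case(self):
        # ||z-mu1||^2 = 0, ||z-mu2||^2 = 1 -> q1 = 1/(1+0.5) = 2/3
        z = np.array([[0.0]])
        mu = np.array([[0.0], [1.0]])
        q = dtc.soft_assign(z, mu)
        np.testing.assert_allclose(q[0], [2.0 / 3.0, 1.0 / 3.0], rtol=1e-12)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(7, 5))
        mu = rng.normal(size=(3, 5))
        np.testing.assert_allclose(dtc.soft_assign(z, mu),
                                   brute_force_soft_assign(z, mu), atol=1e-12)

    def test_rows_sum_to_one_and_positive(self):
        rng = np.random.default_rng(1)
        q = dtc.soft_assign(rng.normal(size=(20, 4)), rng.normal(size=(5, 4)))
        np.testing.assert_allclose(q.sum(axis=1), 1.0, atol=1e-12)
        assert (q > 0).all()

    def test_single_centroid_rejected(self):
        with pytest.raises(ValueError):
            dtc.soft_assign(np.zeros((2, 2)), np.zeros((1, 2)))


class TestTargetDistribution:
    def test_one_hot_rows_are_fixed_point(self):
        q = np.eye(3)[[0, 1, 2, 0]]
        np.testing.assert_allclose(dtc.target_distribution(q), q, atol=1e-12)

    def test_uniform_rows_stay_uniform(self):
        q = np.full((6, 3), 1.0 / 3.0)
        np.testing.assert_allclose(dtc.target_distribution(q), q, atol=1e-12)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(2)
        q = rng.dirichlet(np.ones(3), size=5)
        np.testing.assert_allclose(dtc.target_distribution(q),
                                   brute_force_target(q), atol=1e-12)

    def test_sharpens_assignments_on_average(self):
        rng = np.random.default_rng(3)
        q = rng.dirichlet(np.ones(4) * 2, size=50)
        p = dtc.target_distribution(q)
        ent = lambda m: -(m * np.log(m + 1e-12)).sum(axis=1).mean()
        assert ent(p) <= ent(q)


class TestPrepCurves:
    def test_thirty_frame_input_is_identity_up_to_zscore(self):
        rng = np.random.default_rng(4)
        raw = rng.uniform(10, 60, size=(5, 30, 2))
        data = dtc.prep_curves(raw, np.ones(5))
        recovered = data.curves * data.norm_sd + data.norm_mean
        np.testing.assert_allclose(recovered, raw, atol=1e-9)

    def test_47_frame_input_resampled_to_30(self):
        rng = np.random.default_rng(5)
        raw = rng.uniform(0, 1, size=(3, 47, 2))
        data = dtc.prep_curves(raw, np.ones(3))
        assert data.curves.shape == (3, 30, 2)

    def test_constant_zero_dataset_rejected(self):
        with pytest.raises(ValueError, match="z-score"):
            dtc.prep_curves(np.zeros((4, 30, 2)), np.ones(4))

    def test_nonpositive_bsa_rejected(self):
        with pytest.raises(ValueError, match="BSA"):
            dtc.prep_curves(np.ones((2, 30, 2)), np.array([1.0, 0.0]))


def _curve(values, rr=900.0):
    values = np.asarray(values, float)
    t = np.arange(len(values)) * rr / len(values)
    return FlowCurve(flow=values, times=t, rr_interval=rr, vessel="Ao",
                     net_forward_volume=float(values.mean() * rr / 1000.0))


class TestExclusionFilter:
    def test_early_peak_kept(self):
        flow = np.zeros(30)
        flow[3] = 200.0
        flow += 50
        keep, reason = dtc.exclusion_filter(_curve(flow), bsa=1.5, rr=900.0)
        assert keep and reason is None

    def test_late_peak_dropped_as_pulse_gated(self):
        flow = np.zeros(30) + 50
        flow[20] = 200.0
        keep, reason = dtc.exclusion_filter(_curve(flow), bsa=1.5, rr=900.0)
        assert not keep and reason == "pulse-gated"

    def test_low_volume_dropped_as_non_physiological(self):
        flow = np.zeros(30)
        flow[2] = 30.0  # net volume ~0.9 mL < 10 mL
        keep, reason = dtc.exclusion_filter(_curve(flow), bsa=1.5, rr=900.0)
        assert not keep and reason == "non-physiological"

    def test_volume_just_below_threshold_dropped(self):
        flow = np.full(30, 11.0)
        fc = _curve(flow)
        fc.net_forward_volume = 9.9
        keep, reason = dtc.exclusion_filter(fc, bsa=1.5, rr=900.0)
        assert not keep and reason == "non-physiological"

    @pytest.mark.parametrize("bsa,rr,expected", [
        (None, 900.0, "missing BSA"),
        (float("nan"), 900.0, "missing BSA"),
        (1.5, None, "missing RR"),
    ])
    def test_missing_metadata_dropped(self, bsa, rr, expected):
        flow = np.zeros(30) + 40
        flow[3] = 200.0
        keep, reason = dtc.exclusion_filter(_curve(flow), bsa=bsa, rr=rr)
        assert not keep and reason == expected

    def test_missing_aortic_curve_dropped(self):
        keep, reason = dtc.exclusion_filter(None, bsa=1.5, rr=900.0)
        assert not keep


class TestAutoencoder:
    def test_latent_geometry_follows_layer_spec(self):
        # pool 3 on 30 frames -> 10 steps; bidirectional 1-unit -> 2 features
        cfg = dtc.TAEConfig()
        assert cfg.latent_length() == 10
        assert cfg.latent_dim() == 20
        model = dtc.TemporalAutoencoder(cfg)
        z = model.latent(np.zeros((3, 30, 2)))
        assert z.shape == (3, 20)

    def test_decoder_restores_input_shape(self):
        model = dtc.TemporalAutoencoder(dtc.TAEConfig())
        from fontanflow.nn import Tensor
        recon, z = model(Tensor(np.zeros((4, 30, 2), np.float32)))
        assert recon.shape == (4, 30, 2)

    def test_zero_epoch_pretrain_returns_initial_weights(self):
        cfg = dtc.TAEConfig(seed=6)
        spec = ph.CohortSpec(n_per_cluster=10, scan_probs=(1.0,), seed=6)
        curves, _, demo = ph.generate_flow_cohort(spec)
        data = dtc.prep_curves(curves, demo["BSA"].to_numpy())
        model = dtc.TemporalAutoencoder(cfg, 2, np.random.default_rng(6))
        before = [p.data.copy() for p in model.parameters()]
        dtc.pretrain_autoencoder(data, cfg, model=model, epochs=0)
        for b, p in zip(before, model.parameters()):
            np.testing.assert_array_equal(b, p.data)

    def test_pretraining_shrinks_reconstruction_error(self):
        spec = ph.CohortSpec(archetypes=ph.PA_ARCHETYPES[:2], n_per_cluster=30,
                             noise_sd=0.0, scan_probs=(1.0,), seed=7)
        curves, _, demo = ph.generate_flow_cohort(spec)
        data = dtc.prep_curves(curves, demo["BSA"].to_numpy())
        cfg = dtc.TAEConfig(seed=7, pretrain_epochs=100, batch_size=16)
        _, _, hist = dtc.pretrain_autoencoder(data, cfg)
        assert hist[-1] < 0.1 * hist[0]


class TestJointTraining:
    @pytest.fixture(scope="class")
    def fitted(self, small_cohort):
        spec, curves, labels, demo = small_cohort
        data = dtc.prep_curves(curves, demo["BSA"].to_numpy(), ("SVC", "IVC"))
        cfg = dtc.TAEConfig(pretrain_epochs=30, update_interval=25,
                            max_epochs=300, seed=1)
        res = dtc.train_dtc(data, k=4, config=cfg)
        return labels, res

    def test_recovers_true_partition(self, fitted):
        from sklearn.metrics import adjusted_rand_score
        labels, res = fitted
        assert adjusted_rand_score(labels, res.labels_) >= 0.9

    def test_converged_below_threshold(self, fitted):
        _, res = fitted
        assert res.state.converged
        assert res.state.fraction_changed[-1] < res.model.config.convergence_frac

    def test_assignments_row_stochastic(self, fitted):
        _, res = fitted
        for m in (res.state.q, res.state.p):
            np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-9)
            assert (m >= 0).all()

    def test_joint_training_does_not_hurt_silhouette(self, fitted):
        _, res = fitted
        initial = dtc.silhouette(res.model.initial_labels, res.state.z)
        assert res.silhouette() >= initial - 0.05

    def test_summary_mentions_convergence(self, fitted):
        _, res = fitted
        assert "converged: True" in res.summary()

    def test_non_convergence_flag_path(self, small_cohort):
        spec, curves, labels, demo = small_cohort
        data = dtc.prep_curves(curves, demo["BSA"].to_numpy())
        cfg = dtc.TAEConfig(pretrain_epochs=2, update_interval=5,
                            max_epochs=15, convergence_frac=0.0, seed=2)
        res = dtc.train_dtc(data, k=8, config=cfg)
        assert not res.state.converged
        assert res.state.epochs_run == 15

    def test_too_few_samples_rejected(self):
        data = dtc.DTCInput(curves=np.random.default_rng(0).normal(
            size=(15, 30, 2)))
        with pytest.raises(ValueError, match="10\\*k"):
            dtc.DeepTemporalClustering(data, k=2).fit()


class TestSilhouette:
    def test_two_distant_point_masses_approach_one(self):
        pts = np.vstack([np.zeros((10, 2)), np.full((10, 2), 100.0)])
        labels = np.repeat([0, 1], 10)
        assert dtc.silhouette(labels, pts) > 0.99

    def test_random_labels_on_noise_near_zero(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(500, 5))
        labels = rng.integers(0, 3, size=500)
        assert abs(dtc.silhouette(labels, pts)) < 0.1

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(12, 3))
        labels = rng.integers(0, 3, size=12)
        ref = _brute_silhouette(pts, labels)
        assert dtc.silhouette(labels, pts) == pytest.approx(ref, abs=1e-12)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            dtc.silhouette(np.zeros(5, int), np.zeros((5, 2)))


def _brute_silhouette(pts, labels):
    n = len(pts)
    scores = []
    for i in range(n):
        d = np.linalg.norm(pts - pts[i], axis=1)
        own = labels == labels[i]
        if own.sum() == 1:
            scores.append(0.0)
            continue
        a = d[own & (np.arange(n) != i)].mean()
        b = min(d[labels == other].mean()
                for other in np.unique(labels) if other != labels[i])
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


class TestKSensitivity:
    def test_table_structure_and_selection(self, small_cohort):
        spec, curves, labels, demo = small_cohort
        data = dtc.prep_curves(curves, demo["BSA"].to_numpy())
        cfg = dtc.TAEConfig(pretrain_epochs=15, update_interval=15,
                            max_epochs=150, seed=3)
        table = dtc.k_sensitivity(data, k_range=(3, 4, 5), config=cfg)
        assert list(table["k"]) == [3, 4, 5]
        assert table.attrs["selected_k"] in (3, 4, 5)

    def test_no_convergence_yields_empty_selection(self, small_cohort):
        spec, curves, labels, demo = small_cohort
        data = dtc.prep_curves(curves, demo["BSA"].to_numpy())
        cfg = dtc.TAEConfig(pretrain_epochs=1, update_interval=5,
                            max_epochs=10, convergence_frac=0.0, seed=4)
        table = dtc.k_sensitivity(data, k_range=(3, 4), config=cfg)
        assert table.attrs["selected_k"] is None
        assert not table["converged"].any()
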