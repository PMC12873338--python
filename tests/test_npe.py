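"""Neural posterior estimation: input encoding, network contracts, flow
properties, ensembles and diagnostics."""

import numpy as np
import pytest

from pillarwalk.autodiff import Tensor
from pillarwalk.nn import AffineCouplingFlow, TrajectorySummaryNet, VectorSummaryNet
from pillarwalk.npe import (
    NPEEnsemble,
    NPEPosterior,
    Standardizer,
    TrainConfig,
    build_input_tensor,
    misspecification_check,
    sbc,
    train_joint,
    train_posterior_mean,
)
from pillarwalk.params import BoxPrior
from pillarwalk.tracks import Track, TrackSet


def make_trackset(lengths, dt=30.0):
    tracks = []
    rng = np.random.default_rng(sum(lengths))
    for cid, n in enumerate(lengths, start=1):
        t = np.arange(n) * dt
        xy = rng.normal(size=(n, 2)).cumsum(axis=0)
        tracks.append(Track(cid, t, xy[:, 0], xy[:, 1]))
    return TrackSet(tracks, dt_obs=dt)


class TestBuildInputTensor:
    def test_indicator_row_sums_match_track_lengths(self):
        ts = make_trackset([3, 5])
        x = build_input_tensor(ts, t_max=5, n_cells_max=4)
        assert x.shape == (4, 5, 4)
        assert x[:, :, 3].sum(axis=1).tolist() == [3.0, 5.0, 0.0, 0.0]

    def test_full_length_tracks_all_ones(self):
        ts = make_trackset([4, 4])
        x = build_input_tensor(ts, t_max=4, n_cells_max=2)
        assert (x[:, :, 3] == 1).all()

    def test_empty_trackset_all_zeros(self):
        x = build_input_tensor(TrackSet([]), t_max=4, n_cells_max=3)
        assert (x == 0).all()

    def test_channels_zero_where_unobserved(self):
        ts = make_trackset([2])
        x = build_input_tensor(ts, t_max=6, n_cells_max=2)
        unobserved = x[:, :, 3] == 0
        assert (x[unobserved] == 0).all()

    def test_overlong_tracks_truncated(self):
        ts = make_trackset([9])
        x = build_input_tensor(ts, t_max=4, n_cells_max=1)
        assert x[0, :, 3].sum() == 4


class TestSummaryNetwork:
    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        net = TrajectorySummaryNet(summary_dim=6, rng=rng)
        x = rng.standard_normal((2, 5, 7, 4))
        ind = (rng.random((2, 5, 7)) < 0.8).astype(float)
        x[..., 3] = ind
        x[..., :3] *= ind[..., None]
        s = net(x).data
        perm = rng.permutation(5)
        s_perm = net(x[:, perm]).data
        assert np.abs(s - s_perm).max() < 1e-5

    def test_finite_output_on_empty_input(self):
        net = TrajectorySummaryNet(summary_dim=4)
        s = net(np.zeros((1, 3, 5, 4))).data
        assert np.isfinite(s).all()


class TestFlow:
    def test_roundtrip_invertibility(self):
        rng = np.random.default_rng(1)
        flow = AffineCouplingFlow(4, 6, n_layers=7, rng=rng)
        phi = rng.standard_normal((20, 4))
        ctx = rng.standard_normal((20, 6))
        z, _ = flow.forward(Tensor(phi), Tensor(ctx))
        back = flow.inverse(z.data, ctx)
        assert np.abs(back - phi).max() < 1e-5

    def test_identity_flow_passes_base_density_through(self):
        rng = np.random.default_rng(2)
        flow = AffineCouplingFlow(3, 2, n_layers=4, rng=rng)
        for cond in flow.conditioners:
            cond.layers[-1].W.data[:] = 0.0
            cond.layers[-1].b.data[:] = 0.0
        draws = flow.sample(100_000, np.zeros(2), np.random.default_rng(3))
        assert np.abs(draws.mean(axis=0)).max() < 0.02
        assert np.abs(np.cov(draws.T) - np.eye(3)).max() < 0.03

    def test_log_prob_integrates_to_one_on_grid(self):
        """Change of variables: the 1D slice density integrates to ~1."""
        rng = np.random.default_rng(3)
        flow = AffineCouplingFlow(1, 2, n_layers=4, rng=rng)
        ctx = np.tile(rng.standard_normal(2), (8001, 1))
        grid = np.linspace(-50, 50, 8001)[:, None]
        lp = flow.log_prob(Tensor(grid), Tensor(ctx)).data
        integral = np.trapezoid(np.exp(lp), grid[:, 0])
        assert integral == pytest.approx(1.0, abs=0.02)

    def test_sampling_deterministic_given_seed(self):
        flow = AffineCouplingFlow(2, 2, n_layers=4,
                                  rng=np.random.default_rng(0))
        a = flow.sample(10, np.zeros(2), np.random.default_rng(5))
        b = flow.sample(10, np.zeros(2), np.random.default_rng(5))
        assert np.array_equal(a, b)


class TestTraining:
    def _toy(self, n, rng):
        phi = rng.standard_normal((n, 1))
        x = phi + rng.standard_normal((n, 2))
        return x, phi

    def test_joint_training_beats_initial_loss(self):
        rng = np.random.default_rng(4)
        train = self._toy(1200, rng)
        val = self._toy(100, rng)
        cfg = TrainConfig(max_epochs=12, summary_dim=3, flow_layers=4,
                          patience=12)
        post = train_joint(train, val, cfg, rng)
        assert post.history.train_loss[-1] < post.history.train_loss[0]
        assert min(post.history.val_loss) <= post.history.val_loss[0]

    def test_posterior_mean_learns_identity_map(self):
        rng = np.random.default_rng(5)
        phi = rng.uniform(-1, 1, size=(1500, 2))
        x = phi.copy()  # the data IS the parameter
        cfg = TrainConfig(max_epochs=60, patience=60)
        pm = train_posterior_mean((x, phi), (x[:150], phi[:150]), cfg, rng)
        assert min(pm.history.val_loss) < 0.02
        pred = pm.predict(np.array([0.3, -0.6]))
        assert pred == pytest.approx([0.3, -0.6], abs=0.15)

    def test_sample_contracts(self):
        rng = np.random.default_rng(6)
        train = self._toy(600, rng)
        val = self._toy(80, rng)
        cfg = TrainConfig(max_epochs=4, summary_dim=3, flow_layers=4,
                          patience=4)
        post = train_joint(train, val, cfg, rng)
        assert post.sample(np.zeros(2), 0, rng).shape == (0, 1)
        a = post.sample(np.ones(2), 50, np.random.default_rng(9))
        b = post.sample(np.ones(2), 50, np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(8)
        train = self._toy(600, rng)
        val = self._toy(80, rng)
        cfg = TrainConfig(max_epochs=3, summary_dim=3, flow_layers=4, patience=3)
        post = train_joint(train, val, cfg, rng)
        post.save(tmp_path / "model")
        back = NPEPosterior.load(tmp_path / "model")
        x = np.ones(2)
        assert np.allclose(back.summarize(x), post.summarize(x))
        a = post.sample(x, 20, np.random.default_rng(0))
        b = back.sample(x, 20, np.random.default_rng(0))
        assert np.allclose(a, b)


class TestEnsemble:
    def _fixed_member(self, mean, sd):
        """NPE member whose posterior is exactly N(mean, sd^2) per dim."""
        flow = AffineCouplingFlow(2, 1, n_layers=2,
                                  rng=np.random.default_rng(0))
        for cond in flow.conditioners:
            cond.layers[-1].W.data[:] = 0.0
            cond.layers[-1].b.data[:] = 0.0
        std = Standardizer(np.zeros(1), np.ones(1),
                           np.full(2, mean), np.full(2, sd), "flat")
        net = VectorSummaryNet(1, 1, rng=np.random.default_rng(0))
        return NPEPosterior(net, flow, std)

    def test_share_rule(self):
        ens = NPEEnsemble([self._fixed_member(0, 1)] * 3)
        assert ens.member_counts(10) == [4, 3, 3]
        assert ens.member_counts(3) == [1, 1, 1]

    def test_identical_members_match_single_member(self):
        m = self._fixed_member(1.0, 0.5)
        ens = NPEEnsemble([m, m, m])
        draws = ens.sample(np.zeros(1), 30_000, np.random.default_rng(1))
        assert draws.mean() == pytest.approx(1.0, abs=0.02)
        assert draws.std() == pytest.approx(0.5, abs=0.02)

    def test_disjoint_modes_inflate_variance(self):
        ens = NPEEnsemble([self._fixed_member(-2.0, 0.3),
                           self._fixed_member(2.0, 0.3)])
        draws = ens.sample(np.zeros(1), 20_000, np.random.default_rng(2))
        assert draws.var(axis=0).min() > 0.3**2 * 1.5

    def test_too_few_members_rejected(self):
        with pytest.raises(ValueError):
            NPEEnsemble([self._fixed_member(0, 1)])


class TestDiagnostics:
    def test_sbc_null_ranks_are_uniform(self):
        """Posterior sampler == prior (self-consistent null) gives uniform
        ranks."""
        prior = BoxPrior(np.zeros(2), np.ones(2))
        rng = np.random.default_rng(3)

        def sampler(x, n, r):
            return prior.sample(n, r)

        ranks = sbc(sampler, lambda phi, seed: phi, prior, 200, 19, rng)
        from pillarwalk.evaluation import sbc_within_band
        ok, sup, band = sbc_within_band(ranks, 19, rng=np.random.default_rng(0))
        assert ok

    def test_sbc_detects_shifted_posterior(self):
        prior = BoxPrior(np.zeros(1), np.ones(1))
        rng = np.random.default_rng(4)

        def biased(x, n, r):
            return np.clip(prior.sample(n, r) + 0.4, 0, 1)

        ranks = sbc(biased, lambda phi, seed: phi, prior, 200, 19, rng)
        # the true parameter sits low in the biased posterior
        assert np.median(ranks) < 19 / 2 - 2

    def test_misspecification_scores(self):
        rng = np.random.default_rng(5)
        ref = rng.standard_normal((2000, 4))
        ok_flag, _ = misspecification_check(ref[0], ref)
        assert not ok_flag
        far_flag, score = misspecification_check(np.full(4, 10.0), ref)
        assert far_flag and score > 100

    def test_misspecification_false_positive_rate(self):
        rng = np.random.default_rng(6)
        ref = rng.standard_normal((3000, 3))
        held = rng.standard_normal((3000, 3))
        q = 0.99
        flags = [misspecification_check(h, ref, quantile=q)[0] for h in held]
        rate = np.mean(flags)
        assert rate == pytest.approx(1 - q, abs=0.01)
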