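"""Network architecture contracts and the autodiff engine behind them."""

import numpy as np
import pytest

from plantfill.networks import (
    CMLP,
    MSDDGModel,
    MultiResolutionEncoder,
    MultiScaleGenerator,
    NetConfig,
    SilhouetteDiscriminator,
    SpatialDiscriminator,
    desk_config,
)
from plantfill.nn import AdamW, Tensor, concat


DESK = desk_config(M=128, seed=0)


@pytest.fixture(scope="module")
def desk_model():
    return MSDDGModel(DESK)


class TestAutogradEngine:
    def test_numerical_gradient_of_composite_graph(self, rng):
        x0 = rng.normal(size=(3, 4))
        w = Tensor(rng.normal(size=(4, 5)))

        def f(x):
            h = (x @ w).relu().tanh()
            return (h.amax(axis=1) + h.amin(axis=0).mean()).sum()

        x = Tensor(x0.copy(), requires_grad=True)
        f(x).backward()
        eps = 1e-6
        num = np.zeros_like(x0)
        for i in np.ndindex(*x0.shape):
            xp, xm = x0.copy(), x0.copy()
            xp[i] += eps
            xm[i] -= eps
            num[i] = (f(Tensor(xp)).data - f(Tensor(xm)).data) / (2 * eps)
        np.testing.assert_allclose(x.grad, num, atol=1e-7)

    def test_broadcasting_gradients(self, rng):
        a = Tensor(rng.normal(size=(4, 1, 3)), requires_grad=True)
        b = Tensor(rng.normal(size=(1, 5, 3)), requires_grad=True)
        ((a - b).pow(2.0).sum()).backward()
        assert a.grad.shape == (4, 1, 3) and b.grad.shape == (1, 5, 3)

    def test_optimizer_reduces_quadratic(self):
        p = Tensor(np.array([5.0, -3.0]), requires_grad=True)
        opt = AdamW([p], lr=0.1, weight_decay=0.0)
        for _ in range(200):
            opt.zero_grad()
            (p * p).sum().backward()
            opt.step()
        assert np.abs(p.data).max() < 1e-2


class TestCMLP:
    def test_latent_dimension_from_default_widths(self, plant_2048):
        # full-size widths: pooled last four layers sum to 1920
        cfg = NetConfig(seed=0)
        net = CMLP(cfg, np.random.default_rng(0))
        net.eval()
        out = net(Tensor(plant_2048.points[None]))
        assert out.shape == (1, 1920)
        assert cfg.latent_dim == 1920

    def test_permutation_invariance(self, rng):
        net = CMLP(DESK, np.random.default_rng(0))
        net.eval()
        pts = rng.normal(size=(1, 64, 3))
        perm = pts[:, rng.permutation(64)]
        np.testing.assert_allclose(
            net(Tensor(pts)).data, net(Tensor(perm)).data, atol=1e-12
        )

    def test_duplication_invariance(self, rng):
        net = CMLP(DESK, np.random.default_rng(0))
        net.eval()
        pts = rng.normal(size=(1, 32, 3))
        doubled = np.concatenate([pts, pts], axis=1)
        np.testing.assert_allclose(
            net(Tensor(pts)).data, net(Tensor(doubled)).data, atol=1e-12
        )


class TestEncoder:
    def test_latent_shape_scales_with_config(self, desk_model, rng):
        lat = desk_model.encoder(rng.normal(size=(2, 128, 3)))
        assert lat.shape == (2, DESK.latent_dim)
        assert DESK.latent_dim == sum(DESK.cmlp_widths[-4:])

    def test_too_small_input_rejected(self, desk_model, rng):
        with pytest.raises(ValueError):
            desk_model.encoder(rng.normal(size=(1, 2, 3)))

    def test_nonfinite_input_rejected(self, desk_model):
        bad = np.full((1, 64, 3), np.nan)
        with pytest.raises(ValueError):
            desk_model.encoder(bad)

    def test_gradient_reaches_input_coordinates(self, rng):
        # eval mode: batch-statistic normalization at batch size one would
        # otherwise absorb the single sample into its own statistics
        enc = MultiResolutionEncoder(DESK, np.random.default_rng(0))
        enc.eval()
        x0 = rng.normal(size=(1, 32, 3))
        x = Tensor(x0.copy(), requires_grad=True)
        enc(x).sum().backward()
        assert x.grad is not None and np.abs(x.grad).max() > 0
        # finite-difference check on one coordinate
        eps = 1e-6
        xp, xm = x0.copy(), x0.copy()
        xp[0, 5, 1] += eps
        xm[0, 5, 1] -= eps
        num = (enc(Tensor(xp)).sum().data - enc(Tensor(xm)).sum().data) / (2 * eps)
        assert x.grad[0, 5, 1] == pytest.approx(float(num), abs=1e-5)


class TestGenerator:
    def test_default_config_sizes(self):
        cfg = NetConfig(seed=0)
        gen = MultiScaleGenerator(cfg, np.random.default_rng(0))
        gen.eval()
        pred = gen(Tensor(np.random.default_rng(1).normal(size=(1, cfg.latent_dim))))
        assert pred.primary.shape == (1, 128, 3)
        assert pred.secondary.shape == (1, 256, 3)
        assert pred.detail.shape == (1, 512, 3)

    def test_outputs_bounded(self, desk_model, rng):
        pred = desk_model.predict(rng.uniform(-1, 1, (2, 96, 3)))
        for t in (pred.primary, pred.secondary, pred.detail):
            assert np.all(np.abs(t.data) <= 1.0)

    def test_eval_forward_deterministic(self, desk_model, rng):
        desk_model.eval()
        vis = rng.uniform(-1, 1, (1, 128, 3))
        a = desk_model.predict(vis).detail.data
        b = desk_model.predict(vis).detail.data
        desk_model.train()
        np.testing.assert_array_equal(a, b)


class TestDiscriminators:
    def test_spatial_score_in_unit_interval(self, desk_model, rng):
        s = desk_model.spatial_disc(rng.uniform(-1, 1, (3, DESK.M, 3)))
        assert np.all((s.data > 0) & (s.data < 1))

    def test_spatial_permutation_invariance(self, desk_model, rng):
        desk_model.spatial_disc.eval()
        pts = rng.uniform(-1, 1, (1, DESK.M, 3))
        perm = pts[:, rng.permutation(DESK.M)]
        a = desk_model.spatial_disc(pts).data
        b = desk_model.spatial_disc(perm).data
        desk_model.spatial_disc.train()
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_spatial_wrong_size_rejected(self, desk_model, rng):
        with pytest.raises(ValueError):
            desk_model.spatial_disc(rng.normal(size=(1, DESK.M + 1, 3)))

    def test_silhouette_score_on_degenerate_rasters(self, desk_model):
        for img in (np.zeros((1, 64, 64)), np.ones((1, 64, 64))):
            s = desk_model.sil_disc(img)
            assert np.isfinite(s.data).all() and 0 < s.data < 1

    def test_silhouette_wrong_size_rejected(self, desk_model):
        with pytest.raises(ValueError):
            desk_model.sil_disc(np.zeros((1, 32, 32)))

    def test_spatial_separability_after_toy_training(self, rng):
        cfg = desk_config(M=64, seed=1)
        disc = SpatialDiscriminator(cfg, np.random.default_rng(1))
        opt = AdamW(disc.parameters(), lr=1e-3, weight_decay=0.0)
        from plantfill.losses import discriminator_loss

        for _ in range(200):
            sphere = rng.normal(size=(8, 64, 3))
            sphere /= np.linalg.norm(sphere, axis=2, keepdims=True)
            cube = rng.uniform(-1, 1, (8, 64, 3))
            opt.zero_grad()
            discriminator_loss(disc(sphere), disc(cube)).backward()
            opt.step()
        disc.eval()
        sphere = rng.normal(size=(16, 64, 3))
        sphere /= np.linalg.norm(sphere, axis=2, keepdims=True)
        cube = rng.uniform(-1, 1, (16, 64, 3))
        assert disc(sphere).data.mean() > disc(cube).data.mean()

    def test_silhouette_separability_after_toy_training(self, rng):
        cfg = NetConfig(
            cmlp_widths=(8, 16, 32, 64, 128),
            mspg_fc_dims=(64, 32, 16, 8),
            disc_channels=(8, 16, 32),
            M=64,
            sil_img=32,
            seed=2,
        )
        disc = SilhouetteDiscriminator(cfg, np.random.default_rng(2))
        opt = AdamW(disc.parameters(), lr=1e-3, weight_decay=0.0)
        from plantfill.losses import discriminator_loss

        yy, xx = np.mgrid[:32, :32]

        def disc_image(r_seed):
            r = np.random.default_rng(r_seed)
            cy, cx = r.uniform(10, 22, 2)
            return ((yy - cy) ** 2 + (xx - cx) ** 2 <= 8**2).astype(float)

        for step in range(200):
            real = np.stack([disc_image(step * 8 + i) for i in range(8)])[:, None]
            fake = (rng.uniform(size=(8, 1, 32, 32)) < 0.15).astype(float)
            opt.zero_grad()
            discriminator_loss(disc(Tensor(real)), disc(Tensor(fake))).backward()
            opt.step()
        disc.eval()
        real = np.stack([disc_image(10_000 + i) for i in range(16)])[:, None]
        fake = (rng.uniform(size=(16, 1, 32, 32)) < 0.15).astype(float)
        assert disc(Tensor(real)).data.mean() > disc(Tensor(fake)).data.mean()


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, rng):
        model = MSDDGModel(desk_config(M=64, seed=3))
        vis = rng.uniform(-1, 1, (1, 96, 3))
        model.eval()
        before = model.predict(vis).detail.data
        path = tmp_path / "ckpt.npz"
        model.save(path)
        loaded = MSDDGModel.load(path)
        loaded.eval()
        after = loaded.predict(vis).detail.data
        np.testing.assert_array_equal(before, after)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NetConfig(M=130)  # not divisible by 4
        with pytest.raises(ValueError):
            NetConfig(disc_channels=(64, 64, 128))
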