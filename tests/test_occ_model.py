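import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from x2br.autodiff import Tensor, concat, conv2d
from x2br.occ_model import (
    ModelConfig,
    OccupancyFieldModel,
    TrainConfig,
    TrainSample,
    bce_loss,
    decode_logits,
    elbo_loss,
    encode_image,
    infer_field,
    kl_gaussian_standard,
    load_checkpoint,
    occupancy_prob,
    save_checkpoint,
    train,
)

TINY = ModelConfig(image_size=32, encoding_dim=32, latent_dim=8, hidden_dim=16,
                   n_blocks=2, stem_width=4, seed=0)


@pytest.fixture()
def tiny_model():
    return OccupancyFieldModel(TINY)


def _toy_batch(rng, b=2, t=12, size=32):
    pts = rng.uniform(-0.5, 0.5, (b, t, 3))
    lab = rng.integers(0, 2, (b, t)).astype(float)
    ims = rng.uniform(0, 1, (b, size, size))
    return pts, lab, ims


class TestAutodiff:
    def test_broadcast_add_mul(self):
        a = Tensor(np.ones((2, 3)), requires_grad=True)
        b = Tensor(np.arange(3.0), requires_grad=True)
        out = (a * b + b).sum()
        out.backward()
        assert np.allclose(a.grad, np.tile(np.arange(3.0), (2, 1)))
        assert np.allclose(b.grad, [4, 4, 4])

    def test_matmul_grad(self, rng):
        a = Tensor(rng.normal(size=(4, 5)), requires_grad=True)
        b = Tensor(rng.normal(size=(5, 2)), requires_grad=True)
        (a @ b).sum().backward()
        assert np.allclose(a.grad, np.ones((4, 2)) @ b.data.T)

    def test_conv2d_matches_finite_difference(self, rng):
        x = Tensor(rng.normal(size=(1, 2, 6, 6)), requires_grad=True)
        w = Tensor(rng.normal(size=(3, 2, 3, 3)), requires_grad=True)
        b = Tensor(np.zeros(3), requires_grad=True)
        conv2d(x, w, b, stride=1, pad=1).sum().backward()
        h = 1e-6
        g_fd = np.zeros_like(w.data)
        for idx in [(0, 0, 0, 0), (2, 1, 2, 2), (1, 0, 1, 2)]:
            wp = w.data.copy(); wp[idx] += h
            wm = w.data.copy(); wm[idx] -= h
            fp = conv2d(Tensor(x.data), Tensor(wp), Tensor(np.zeros(3)),
                        stride=1, pad=1).data.sum()
            fm = conv2d(Tensor(x.data), Tensor(wm), Tensor(np.zeros(3)),
                        stride=1, pad=1).data.sum()
            assert w.grad[idx] == pytest.approx((fp - fm) / (2 * h), rel=1e-5)

    def test_elbo_gradient_check(self, tiny_model, rng):
        pts, lab, ims = _toy_batch(rng, b=2, t=10)

        def loss_value():
            loss, _ = elbo_loss(pts, lab, ims, tiny_model, np.random.default_rng(7))
            return loss

        loss = loss_value()
        for p in tiny_model.parameters():
            p.grad = None
        loss.backward()
        param = tiny_model.decoder.blocks[0].fc0.w
        h = 1e-6
        for idx in [(0, 0), (3, 5), (11, 2)]:
            orig = param.data[idx]
            param.data[idx] = orig + h
            up = loss_value().data
            param.data[idx] = orig - h
            down = loss_value().data
            param.data[idx] = orig
            fd = (up - down) / (2 * h)
            assert param.grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-10)

    def test_concat_grad(self):
        a = Tensor(np.ones((2, 2)), requires_grad=True)
        b = Tensor(np.ones((2, 3)), requires_grad=True)
        concat([a, b], axis=1).sum().backward()
        assert a.grad.shape == (2, 2) and b.grad.shape == (2, 3)


class TestEncodeImage:
    def test_deterministic(self, tiny_model, rng):
        img = rng.uniform(0, 1, (32, 32))
        assert np.array_equal(encode_image(img, tiny_model), encode_image(img, tiny_model))

    def test_distinct_inputs_distinct_codes(self, tiny_model, rng):
        a = encode_image(rng.uniform(0, 1, (32, 32)), tiny_model)
        b = encode_image(rng.uniform(0, 1, (32, 32)), tiny_model)
        assert not np.allclose(a, b)

    def test_zero_image_finite(self, tiny_model):
        c = encode_image(np.zeros((32, 32)), tiny_model)
        assert np.all(np.isfinite(c)) and c.shape == (32,)

    def test_size_mismatch(self, tiny_model):
        with pytest.raises(ValueError, match="size"):
            encode_image(np.zeros((64, 64)), tiny_model)


class TestDecodeLogits:
    def test_permutation_equivariance(self, tiny_model, rng):
        pts = rng.uniform(-0.5, 0.5, (20, 3))
        z = rng.normal(size=8)
        c = rng.normal(size=32)
        perm = rng.permutation(20)
        out = decode_logits(pts, z, c, tiny_model)
        out_perm = decode_logits(pts[perm], z, c, tiny_model)
        assert np.allclose(out[perm], out_perm, atol=1e-10)

    def test_batched_equals_single(self, tiny_model, rng):
        pts = rng.uniform(-0.5, 0.5, (8, 3))
        z = rng.normal(size=8)
        c = rng.normal(size=32)
        full = decode_logits(pts, z, c, tiny_model)
        singles = np.array([decode_logits(p[None], z, c, tiny_model)[0] for p in pts])
        assert np.allclose(full, singles, atol=1e-5)

    def test_nan_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="NaN"):
            decode_logits(np.full((2, 3), np.nan), np.zeros(8), np.zeros(32), tiny_model)


class TestOccupancyProb:
    def test_zero_logit_half(self):
        assert occupancy_prob(np.array([0.0]))[0] == 0.5

    def test_extreme_logits_clamped(self):
        out = occupancy_prob(np.array([1e4, -1e4]))
        assert out[0] == pytest.approx(1.0) and out[1] == pytest.approx(0.0)
        assert np.all(np.isfinite(out))

    @given(st.floats(-300, 300))
    @settings(max_examples=50, deadline=None)
    def test_sigmoid_symmetry(self, logit):
        p = occupancy_prob(np.array([logit, -logit]))
        assert p[0] + p[1] == pytest.approx(1.0, abs=1e-12)


class TestBceLoss:
    def test_closed_form_ln2(self):
        assert float(bce_loss(np.array([0.0]), np.array([1.0])).data) == pytest.approx(np.log(2))

    def test_stable_at_extreme_logits(self):
        val = float(bce_loss(np.array([-100.0]), np.array([0.0])).data)
        assert 0 <= val < 1e-10

    def test_matches_naive_formula(self, rng):
        logits = rng.uniform(-20, 20, size=200)
        labels = rng.integers(0, 2, size=200).astype(float)
        p = 1 / (1 + np.exp(-logits))
        naive = np.mean(-labels * np.log(p) - (1 - labels) * np.log(1 - p))
        assert float(bce_loss(logits, labels).data) == pytest.approx(naive, abs=1e-8)

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError, match="binary"):
            bce_loss(np.zeros(3), np.array([0.0, 0.5, 1.0]))


class TestElboLoss:
    def test_kl_matches_closed_form(self, rng):
        mu = rng.normal(size=(3, 8))
        logvar = rng.normal(scale=0.3, size=(3, 8))
        kl = kl_gaussian_standard(Tensor(mu), Tensor(logvar)).data
        expected = 0.5 * np.sum(mu ** 2 + np.exp(logvar) - 1 - logvar, axis=1)
        assert np.allclose(kl, expected, atol=1e-8)

    def test_kl_nonnegative_and_loss_bounded_below_by_bce(self, tiny_model, rng):
        pts, lab, ims = _toy_batch(rng)
        loss, diag = elbo_loss(pts, lab, ims, tiny_model, rng)
        assert diag["kl"] >= 0
        assert float(loss.data) >= diag["bce"] - 1e-12

    def test_prior_posterior_gives_pure_bce(self, tiny_model, rng):
        # zero-initialized posterior heads -> q = N(0, I) -> KL = 0
        pts, lab, ims = _toy_batch(rng)
        loss, diag = elbo_loss(pts, lab, ims, tiny_model, rng)
        assert diag["kl"] == pytest.approx(0.0, abs=1e-12)
        assert float(loss.data) == pytest.approx(diag["bce"], abs=1e-10)

    def test_empty_batch_rejected(self, tiny_model, rng):
        with pytest.raises(ValueError, match="empty"):
            elbo_loss(np.zeros((0, 5, 3)), np.zeros((0, 5)), np.zeros((0, 32, 32)),
                      tiny_model, rng)


def _tiny_dataset(n_phantoms=2, n_points=400, size=32, seed=0):
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n_phantoms):
        center = rng.uniform(-0.15, 0.15, size=3)
        radius = rng.uniform(0.15, 0.3)
        pts = rng.uniform(-0.5, 0.5, (n_points, 3))
        labels = (np.linalg.norm(pts - center, axis=1) < radius).astype(np.uint8)
        img = np.clip(rng.uniform(0, 0.1, (size, size)) + radius, 0, 1)
        samples.append(TrainSample(img, pts, labels, f"s{i}"))
    return samples


class TestTrain:
    def test_seeded_runs_identical(self):
        data = _tiny_dataset()
        cfg = TrainConfig(learning_rate=1e-3, batch_size=2, t_points=64, n_steps=8, seed=3)
        _, log_a = train(data, cfg, model=OccupancyFieldModel(TINY))
        _, log_b = train(data, cfg, model=OccupancyFieldModel(TINY))
        assert log_a["train_loss"] == log_b["train_loss"]

    def test_loss_decreases(self):
        data = _tiny_dataset()
        cfg = TrainConfig(learning_rate=1e-3, batch_size=2, t_points=128, n_steps=60, seed=1)
        _, log = train(data, cfg, model=OccupancyFieldModel(TINY))
        first = np.mean(log["train_loss"][:5])
        last = np.mean(log["train_loss"][-5:])
        assert last < first

    def test_validation_improves_after_training(self):
        data = _tiny_dataset(n_phantoms=8, n_points=600, seed=5)
        cfg = TrainConfig(learning_rate=1e-3, batch_size=4, t_points=128, n_steps=80,
                          seed=2, log_every=40)
        from x2br.occ_model import validate

        model = OccupancyFieldModel(TINY)
        before = validate(data[6:], model, cfg)
        model, _ = train(data[:6], cfg, model=model, val_dataset=data[6:])
        after = validate(data[6:], model, cfg)
        assert after < before

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], TrainConfig())


class TestInferField:
    def test_untrained_warns(self, tiny_model, rng):
        with pytest.warns(RuntimeWarning, match="untrained"):
            infer_field(rng.uniform(0, 1, (32, 32)), tiny_model)

    def test_deterministic_and_in_range(self, tiny_model, rng):
        tiny_model.trained = True
        field = infer_field(rng.uniform(0, 1, (32, 32)), tiny_model)
        pts = rng.uniform(-0.5, 0.5, (500, 3))
        a, b = field(pts), field(pts)
        assert np.array_equal(a, b)
        assert np.all((a > 0) & (a < 1))

    def test_batch_independent(self, tiny_model, rng):
        # the field is a pointwise function: value cannot depend on batching
        tiny_model.trained = True
        field = infer_field(rng.uniform(0, 1, (32, 32)), tiny_model)
        pts = rng.uniform(-0.5, 0.5, (64, 3))
        whole = field(pts)
        halves = np.concatenate([field(pts[:10]), field(pts[10:])])
        assert np.allclose(whole, halves, atol=1e-12)


class TestCheckpoint:
    def test_roundtrip_preserves_field(self, tiny_model, tmp_path, rng):
        data = _tiny_dataset()
        cfg = TrainConfig(learning_rate=1e-3, batch_size=2, t_points=64, n_steps=5, seed=0)
        model, _ = train(data, cfg, model=tiny_model)
        save_checkpoint(model, tmp_path / "ckpt")
        back = load_checkpoint(tmp_path / "ckpt")
        img = rng.uniform(0, 1, (32, 32))
        pts = rng.uniform(-0.5, 0.5, (100, 3))
        assert np.allclose(infer_field(img, model)(pts), infer_field(img, back)(pts),
                           atol=1e-12)
        assert back.trained
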