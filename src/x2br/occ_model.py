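"""Conditional occupancy-field network and its variational training loop.

A hierarchical convolutional encoder compresses the projection image into a
conditioning vector c; a decoder of dense residual blocks with
conditionally-modulated normalization maps (point, z, c) to an occupancy
logit; a permutation-invariant point-set encoder infers the Gaussian
posterior over the latent shape code z.  Training minimizes the negative
ELBO: KL(q || N(0, I)) plus mean binary cross-entropy over the sampled
points, with Adam.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat, conv2d
from .projection import ProjectionImage

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainSample",
    "OccupancyFieldModel",
    "encode_image",
    "decode_logits",
    "occupancy_prob",
    "bce_loss",
    "kl_gaussian_standard",
    "elbo_loss",
    "train",
    "infer_field",
    "save_checkpoint",
    "load_checkpoint",
]

logger = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    """Architecture hyperparameters; defaults follow the full-size model,
    tests shrink them."""

    image_size: int = 224
    encoding_dim: int = 1024
    latent_dim: int = 64
    hidden_dim: int = 256
    n_blocks: int = 5
    stem_width: int = 16
    seed: int = 0


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    batch_size: int = 8
    t_points: int = 2048
    n_steps: int = 1000
    seed: int = 0
    log_every: int = 50


# ----------------------------------------------------------------------
# parameter containers
# ----------------------------------------------------------------------

class _Module:
    def _children(self) -> list["_Module"]:
        out: list[_Module] = []
        for v in self.__dict__.values():
            if isinstance(v, _Module):
                out.append(v)
            elif isinstance(v, (list, tuple)):
                out.extend(item for item in v if isinstance(item, _Module))
        return out

    def parameters(self) -> list[Tensor]:
        out = [v for v in self.__dict__.values()
               if isinstance(v, Tensor) and v.requires_grad]
        for child in self._children():
            out.extend(child.parameters())
        return out

    def buffers(self) -> list[tuple["_Module", str]]:
        """Non-trainable state (e.g. running normalization statistics)."""
        out = [(self, name) for name in getattr(self, "_buffer_names", ())]
        for child in self._children():
            out.extend(child.buffers())
        return out

    def set_training(self, flag: bool) -> None:
        if hasattr(self, "training"):
            self.training = flag
        for child in self._children():
            child.set_training(flag)


class _Linear(_Module):
    def __init__(self, rng, n_in: int, n_out: int, zero_init: bool = False):
        scale = 0.0 if zero_init else np.sqrt(2.0 / n_in)
        self.w = Tensor(rng.normal(scale=scale or 1e-30, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class _Conv(_Module):
    def __init__(self, rng, c_in: int, c_out: int, k: int, stride: int = 1, pad: int = 0):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.w = Tensor(rng.normal(scale=scale, size=(c_out, c_in, k, k)), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride, self.pad = stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class _ConvBlock(_Module):
    """Residual inverted-bottleneck: x + 1x1(relu(3x3(x)))."""

    def __init__(self, rng, width: int):
        self.conv_spatial = _Conv(rng, width, width, 3, pad=1)
        self.conv_mix = _Conv(rng, width, width, 1)

    def __call__(self, x: Tensor) -> Tensor:
        return x + self.conv_mix(self.conv_spatial(x).relu())


class _Encoder(_Module):
    """4-stage hierarchical convolutional image encoder -> encoding_dim."""

    def __init__(self, rng, cfg: ModelConfig):
        w = cfg.stem_width
        self.stem = _Conv(rng, 1, w, 4, stride=4)
        self.stages = []
        self.downs = []
        widths = [w, 2 * w, 4 * w, 8 * w]
        for i, wi in enumerate(widths):
            self.stages.append(_ConvBlock(rng, wi))
            if i < 3:
                self.downs.append(_Conv(rng, wi, widths[i + 1], 2, stride=2))
        self.head = _Linear(rng, widths[-1], cfg.encoding_dim)

    def __call__(self, images: Tensor) -> Tensor:
        x = self.stem(images).relu()
        for i, stage in enumerate(self.stages):
            x = stage(x)
            if i < 3:
                x = self.downs[i](x).relu()
        pooled = x.mean(axis=(2, 3))  # global average pool -> (B, 8w)
        return self.head(pooled)


class _CBN(_Module):
    """Conditional batch normalization over (batch, points) per channel.

    Scale/shift are predicted linearly from the conditioning vector.
    Training normalizes with mini-batch statistics and updates running
    estimates; evaluation uses the running statistics, so an inferred field
    is a pure pointwise function independent of query batching.
    """

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, rng, width: int, cond_dim: int, momentum: float = 0.1):
        self.gamma = _Linear(rng, cond_dim, width, zero_init=True)
        self.beta = _Linear(rng, cond_dim, width, zero_init=True)
        self.running_mean = np.zeros(width)
        self.running_var = np.ones(width)
        self.momentum = momentum
        self.training = True

    def __call__(self, h: Tensor, cond: Tensor) -> Tensor:
        if self.training:
            mu = h.mean(axis=(0, 1), keepdims=True)
            var = ((h - mu) ** 2).mean(axis=(0, 1), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            norm = (h - mu) * (var + 1e-5) ** -0.5
        else:
            norm = (h - self.running_mean.reshape(1, 1, -1)) * (
                1.0 / np.sqrt(self.running_var + 1e-5)
            ).reshape(1, 1, -1)
        g = self.gamma(cond).reshape(cond.shape[0], 1, -1) + 1.0
        b = self.beta(cond).reshape(cond.shape[0], 1, -1)
        return norm * g + b


class _DecoderBlock(_Module):
    def __init__(self, rng, width: int, cond_dim: int):
        self.cbn0 = _CBN(rng, width, cond_dim)
        self.fc0 = _Linear(rng, width, width)
        self.cbn1 = _CBN(rng, width, cond_dim)
        self.fc1 = _Linear(rng, width, width)

    def __call__(self, h: Tensor, cond: Tensor) -> Tensor:
        dx = self.fc0(self.cbn0(h, cond).relu())
        dx = self.fc1(self.cbn1(dx, cond).relu())
        return h + dx


class _Decoder(_Module):
    def __init__(self, rng, cfg: ModelConfig):
        cond_dim = cfg.latent_dim + cfg.encoding_dim
        self.fc_p = _Linear(rng, 3, cfg.hidden_dim)
        self.blocks = [
            _DecoderBlock(rng, cfg.hidden_dim, cond_dim) for _ in range(cfg.n_blocks)
        ]
        self.cbn_out = _CBN(rng, cfg.hidden_dim, cond_dim)
        self.head = _Linear(rng, cfg.hidden_dim, 1)

    def __call__(self, points: Tensor, z: Tensor, c: Tensor) -> Tensor:
        cond = concat([z, c], axis=-1)
        h = self.fc_p(points)
        for block in self.blocks:
            h = block(h, cond)
        out = self.head(self.cbn_out(h, cond).relu())
        return out.reshape(points.shape[0], points.shape[1])


class _PosteriorEncoder(_Module):
    """Permutation-invariant q(z | points, labels, c): pointwise MLP,
    mean-pool over points, fuse with c, linear mean / log-variance heads."""

    def __init__(self, rng, cfg: ModelConfig):
        h = cfg.hidden_dim
        self.fc_in = _Linear(rng, 4, h)
        self.fc_mid = _Linear(rng, h, h)
        self.fc_fuse = _Linear(rng, h + cfg.encoding_dim, h)
        self.head_mean = _Linear(rng, h, cfg.latent_dim, zero_init=True)
        self.head_logvar = _Linear(rng, h, cfg.latent_dim, zero_init=True)

    def __call__(self, points: Tensor, labels: Tensor, c: Tensor):
        x = concat([points, labels.reshape(*labels.shape, 1)], axis=-1)
        h = self.fc_mid(self.fc_in(x).relu()).relu()
        pooled = h.mean(axis=1)
        fused = self.fc_fuse(concat([pooled, c], axis=-1)).relu()
        return self.head_mean(fused), self.head_logvar(fused)


class OccupancyFieldModel(_Module):
    """Encoder + variational posterior + conditioned decoder."""

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        rng = np.random.default_rng(self.config.seed)
        self.encoder = _Encoder(rng, self.config)
        self.decoder = _Decoder(rng, self.config)
        self.posterior = _PosteriorEncoder(rng, self.config)
        self.trained = False

    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.data for p in self.parameters()]
        arrays.extend(getattr(mod, name) for mod, name in self.buffers())
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        buffers = self.buffers()
        if len(params) + len(buffers) != len(arrays):
            raise ValueError("checkpoint does not match architecture")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch in checkpoint")
            p.data = np.asarray(a, dtype=np.float64)
        for (mod, name), a in zip(buffers, arrays[len(params):]):
            setattr(mod, name, np.asarray(a, dtype=np.float64))


# ----------------------------------------------------------------------
# functional pieces
# ----------------------------------------------------------------------

def _image_batch(images) -> Tensor:
    arr = np.stack([im.pixels if isinstance(im, ProjectionImage) else im for im in images])
    return Tensor(arr[:, None, :, :])  # (B, 1, H, W)


def encode_image(image, model: OccupancyFieldModel) -> np.ndarray:
    """Conditioning vector for one image; deterministic."""
    model.set_training(False)
    px = image.pixels if isinstance(image, ProjectionImage) else np.asarray(image)
    if px.shape[0] != model.config.image_size:
        raise ValueError(
            f"image size {px.shape[0]} does not match model config "
            f"{model.config.image_size}"
        )
    return model.encoder(_image_batch([px])).data[0]


def decode_logits(points: np.ndarray, z: np.ndarray, c: np.ndarray,
                  model: OccupancyFieldModel) -> np.ndarray:
    """Occupancy logits for (t, 3) points under one latent and encoding."""
    model.set_training(False)
    pts = np.asarray(points, dtype=float)
    if np.isnan(pts).any():
        raise ValueError("NaN in query points")
    out = model.decoder(
        Tensor(pts[None]), Tensor(np.asarray(z)[None]), Tensor(np.asarray(c)[None])
    )
    return out.data[0]


def occupancy_prob(logits: np.ndarray) -> np.ndarray:
    """Sigmoid with overflow-safe clamping."""
    x = np.clip(np.asarray(logits, dtype=float), -500, 500)
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)), np.exp(x) / (1.0 + np.exp(x)))


def bce_loss(logits: Tensor | np.ndarray, labels: np.ndarray) -> Tensor:
    """Mean binary cross-entropy in the stable logit form
    ``softplus(l) - l * o``."""
    lab = np.asarray(labels, dtype=float)
    if lab.size and not np.isin(lab, (0.0, 1.0)).all():
        raise ValueError("labels must be binary")
    lg = logits if isinstance(logits, Tensor) else Tensor(logits)
    return (lg.softplus() - lg * lab).mean()


def kl_gaussian_standard(mean: Tensor, logvar: Tensor) -> Tensor:
    """KL( N(mean, exp(logvar)) || N(0, I) ), summed over dims, per sample."""
    return ((mean ** 2 + logvar.exp() - logvar - 1.0) * 0.5).sum(axis=-1)


def elbo_loss(
    points: np.ndarray,
    labels: np.ndarray,
    images: np.ndarray,
    model: OccupancyFieldModel,
    rng: np.random.Generator,
    sample_posterior: bool = True,
):
    """Negative ELBO over a batch: mean_i [ KL_i + (1/T) sum_j BCE_ij ].

    ``points`` (B, T, 3), ``labels`` (B, T), ``images`` (B, H, W); one
    reparameterized z sample per batch element.  Returns (loss Tensor,
    diagnostics dict).
    """
    if len(points) == 0:
        raise ValueError("empty batch")
    c = model.encoder(_image_batch(images))
    pts_t = Tensor(np.asarray(points, dtype=float))
    mu, logvar = model.posterior(pts_t, Tensor(np.asarray(labels, dtype=float)), c)
    if sample_posterior:
        eps = rng.standard_normal(mu.shape)
        z = mu + (logvar * 0.5).exp() * eps
    else:
        z = mu
    logits = model.decoder(pts_t, z, c)
    lab = np.asarray(labels, dtype=float)
    bce = (logits.softplus() - logits * lab).mean(axis=1)  # (B,)
    kl = kl_gaussian_standard(mu, logvar)
    loss = (kl + bce).mean()
    diag = {"bce": float(bce.data.mean()), "kl": float(kl.data.mean())}
    return loss, diag


# ----------------------------------------------------------------------
# optimizer & training
# ----------------------------------------------------------------------

class Adam:
    def __init__(self, params: list[Tensor], cfg: TrainConfig):
        self.params = params
        self.cfg = cfg
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.cfg.beta1, self.cfg.beta2
        lr = self.cfg.learning_rate
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.cfg.eps)


@dataclass
class TrainSample:
    """One phantom's supervision: a projection image plus its labeled pool."""

    image: np.ndarray
    points: np.ndarray
    labels: np.ndarray
    source_id: str = ""


def train(
    dataset: list[TrainSample],
    config: TrainConfig,
    model: OccupancyFieldModel | None = None,
    val_dataset: list[TrainSample] | None = None,
):
    """Seeded Adam training; returns (model, run log).

    Each step draws ``batch_size`` samples (with replacement if the dataset
    is smaller) and ``t_points`` fresh pool points per sample.  Aborts on
    NaN loss with diagnostics.
    """
    if not dataset:
        raise ValueError("empty dataset")
    if model is None:
        size = dataset[0].image.shape[0]
        model = OccupancyFieldModel(ModelConfig(image_size=size, seed=config.seed))
    rng = np.random.default_rng(config.seed)
    model.set_training(True)
    opt = Adam(model.parameters(), config)
    log = {"train_loss": [], "val_loss": [], "config": config.__dict__.copy(),
           "seed": config.seed}

    for step in range(config.n_steps):
        replace = len(dataset) < config.batch_size
        idx = rng.choice(len(dataset), size=min(config.batch_size, len(dataset)),
                         replace=replace)
        pts, lab, ims = [], [], []
        for i in idx:
            s = dataset[i]
            take = rng.choice(len(s.points), size=min(config.t_points, len(s.points)),
                              replace=False)
            pts.append(s.points[take])
            lab.append(s.labels[take])
            ims.append(s.image)
        loss, diag = elbo_loss(np.stack(pts), np.stack(lab), np.stack(ims), model, rng)
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"training diverged at step {step}: loss={loss.data}, diag={diag}"
            )
        opt.zero_grad()
        loss.backward()
        opt.step()
        log["train_loss"].append(float(loss.data))
        if (step + 1) % config.log_every == 0:
            logger.info("step %d loss %.4f (bce %.4f kl %.4f)",
                        step + 1, loss.data, diag["bce"], diag["kl"])
            if val_dataset:
                log["val_loss"].append((step + 1, validate(val_dataset, model, config)))
                model.set_training(True)
    _calibrate_norm_statistics(dataset, model, config)
    model.trained = True
    model.set_training(False)
    return model, log


def _calibrate_norm_statistics(
    dataset: list[TrainSample],
    model: OccupancyFieldModel,
    config: TrainConfig,
    n_passes: int = 50,
) -> None:
    """Settle the running normalization statistics under inference
    conditions (latent code at the prior mean) — training batches see
    sampled codes, which shifts deep feature statistics."""
    model.set_training(True)
    rng = np.random.default_rng((config.seed, 0xCA1B))
    for _ in range(n_passes):
        idx = rng.choice(len(dataset), size=min(config.batch_size, len(dataset)),
                         replace=len(dataset) < config.batch_size)
        pts, ims = [], []
        for i in idx:
            s = dataset[i]
            take = rng.choice(len(s.points), size=min(config.t_points, len(s.points)),
                              replace=False)
            pts.append(s.points[take])
            ims.append(s.image)
        c = model.encoder(_image_batch(ims))
        z = Tensor(np.zeros((len(idx), model.config.latent_dim)))
        model.decoder(Tensor(np.stack(pts)), z, c)
    model.set_training(False)


def validate(dataset: list[TrainSample], model: OccupancyFieldModel,
             config: TrainConfig) -> float:
    model.set_training(False)
    rng = np.random.default_rng(config.seed + 1)
    losses = []
    for s in dataset:
        take = rng.choice(len(s.points), size=min(config.t_points, len(s.points)),
                          replace=False)
        loss, _ = elbo_loss(s.points[take][None], s.labels[take][None],
                            s.image[None], model, rng, sample_posterior=False)
        losses.append(float(loss.data))
    return float(np.mean(losses))


def infer_field(image, model: OccupancyFieldModel, batch: int = 8192):
    """Queryable occupancy field conditioned on one image.

    The latent code is fixed at the prior mean (zero), so the field is a
    pure function of the query points; safe for concurrent reads.
    """
    import warnings as _warnings

    if not model.trained:
        _warnings.warn("inferring from an untrained model", RuntimeWarning)
    c = encode_image(image, model)
    z = np.zeros(model.config.latent_dim)

    def field(points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.empty(len(pts))
        for s in range(0, len(pts), batch):
            out[s:s + batch] = occupancy_prob(decode_logits(pts[s:s + batch], z, c, model))
        return out

    return field


# ----------------------------------------------------------------------
# checkpointing: parameter arrays (npz) + JSON config snapshot
# ----------------------------------------------------------------------

def save_checkpoint(model: OccupancyFieldModel, path, extra: dict | None = None) -> None:
    path = Path(path)
    np.savez(path.with_suffix(".npz"), *model.state_arrays())
    snapshot = {"config": model.config.__dict__.copy(), "trained": model.trained}
    if extra:
        snapshot.update(extra)
    path.with_suffix(".json").write_text(json.dumps(snapshot, indent=2))


def load_checkpoint(path) -> OccupancyFieldModel:
    path = Path(path)
    snapshot = json.loads(path.with_suffix(".json").read_text())
    model = OccupancyFieldModel(ModelConfig(**snapshot["config"]))
    with np.load(path.with_suffix(".npz")) as archive:
        model.load_state_arrays([archive[f"arr_{i}"] for i in range(len(archive.files))])
    model.trained = bool(snapshot.get("trained", False))
    return model
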