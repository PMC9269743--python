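"""Per-patient 1-D convolutional GAN for single-day glucose sequences.

The generator maps standard-normal latent vectors through a dense layer
into 50 parallel low-resolution sequences, which are alternately upsampled
and convolutionally filtered until they form one 288-value day (a full day
of 5-minute CGM readings).  The tanh output is mapped affinely onto the
sensor support [40, 400] mg/dL.  The discriminator mirrors it: strided
convolutions with leaky-ReLU activations and a single sigmoid unit
emitting the probability that its input day is real (1) rather than
synthetic (0).  The two are trained adversarially with binary
cross-entropy in the usual minimax fashion — one model per patient, never
pooled, since the goal is to replicate an individual's glycemic
distribution.

Training can periodically run the statistical acceptance battery
(:mod:`glucosynth.evalgen`) against the training days and stop at the
first accepted checkpoint, acceptance being the model's validity
criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _nn
from .cgm_io import GLUCOSE_MAX, GLUCOSE_MIN, SAMPLES_PER_DAY, DayMatrix
from .evalgen import wilcoxon_acceptance

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "GANTrainConfig",
    "Generator",
    "Discriminator",
    "TrainedGAN",
    "build_generator",
    "build_discriminator",
    "train_gan",
    "generate_days",
    "save_checkpoint",
    "load_checkpoint",
]


def _to_norm(x: np.ndarray) -> np.ndarray:
    """mg/dL in [40, 400] -> [-1, 1] (the tanh support)."""
    return (x - GLUCOSE_MIN) / (GLUCOSE_MAX - GLUCOSE_MIN) * 2.0 - 1.0


def _from_norm(y: np.ndarray) -> np.ndarray:
    return (y + 1.0) / 2.0 * (GLUCOSE_MAX - GLUCOSE_MIN) + GLUCOSE_MIN


@dataclass(frozen=True)
class GeneratorSpec:
    """Architecture of the generator.

    The dense input layer produces ``low_res_channels`` copies of a
    ``low_res_length``-sample low-definition sequence; each upsample stage
    is ``(factor, kernel_size, channels)``.  The product of the factors
    must stretch ``low_res_length`` to ``output_length``.
    """

    latent_dim: int = 100
    low_res_channels: int = 50
    low_res_length: int = 72
    upsample_stages: tuple = ((2, 9, 32), (2, 9, 16))
    output_length: int = SAMPLES_PER_DAY
    output_kernel: int = 9
    output_activation: str = "tanh"

    def validate(self) -> None:
        stretch = self.low_res_length * math.prod(f for f, _, _ in self.upsample_stages)
        if stretch != self.output_length:
            raise ValueError(
                f"low_res_length x upsample factors = {stretch}, "
                f"must equal output_length = {self.output_length}")
        if self.output_activation != "tanh":
            raise ValueError("only tanh output is supported")
        if self.latent_dim < 1 or self.low_res_channels < 1:
            raise ValueError("latent_dim and low_res_channels must be positive")


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Architecture of the discriminator: ``(kernel, stride, channels)`` blocks."""

    conv_stages: tuple = ((9, 2, 16), (9, 2, 32), (9, 2, 64))
    leaky_slope: float = 0.2
    input_length: int = SAMPLES_PER_DAY

    def validate(self) -> None:
        if not self.conv_stages:
            raise ValueError("need at least one convolution stage")
        if not (0.0 <= self.leaky_slope < 1.0):
            raise ValueError("leaky_slope must be in [0, 1)")


@dataclass
class GANTrainConfig:
    epochs: int = 1500
    batch_size: int = 16
    gen_lr: float = 2e-4
    disc_lr: float = 2e-4
    beta1: float = 0.5
    seed: int = 0
    check_every: int = 25  # 0 disables acceptance-based selection/early exit
    alpha: float = 0.05
    stop_margin: float = 0.25  # stop once min p-value clears this comfortably
    real_label: float = 0.9  # one-sided label smoothing stabilizes the game
    synth_label: float = 0.0


class Generator:
    """Latent vectors -> normalized day sequences in [-1, 1]."""

    def __init__(self, spec: GeneratorSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        layers: list[_nn.Layer] = [
            _nn.Dense(spec.latent_dim, spec.low_res_channels * spec.low_res_length, rng),
            _nn.LeakyReLU(0.2),
            _nn.Reshape((spec.low_res_channels, spec.low_res_length)),
        ]
        self._post_dense = len(layers)  # index after the reshape
        c_prev = spec.low_res_channels
        for factor, kernel, channels in spec.upsample_stages:
            layers += [_nn.UpSample1D(factor),
                       _nn.Conv1D(c_prev, channels, kernel, rng),
                       _nn.LeakyReLU(0.2)]
            c_prev = channels
        layers += [_nn.Conv1D(c_prev, 1, spec.output_kernel, rng), _nn.Tanh()]
        self.net = _nn.Sequential(layers).astype(np.float32)

    def forward(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.shape[1] != self.spec.latent_dim:
            raise ValueError(f"latent vectors must have {self.spec.latent_dim} dims")
        return self.net.forward(z)[:, 0, :]  # (n, 288)

    def low_res_representation(self, z: np.ndarray) -> np.ndarray:
        """The (n, low_res_channels, low_res_length) tensor after the input dense layer."""
        z = np.atleast_2d(np.asarray(z, dtype=float))
        x = z
        for layer in self.net.layers[: self._post_dense]:
            x = layer.forward(x)
        return x


class Discriminator:
    """Day sequences (normalized, length 288) -> probability of being real."""

    def __init__(self, spec: DiscriminatorSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        layers: list[_nn.Layer] = []
        c_prev, length = 1, spec.input_length
        for kernel, stride, channels in spec.conv_stages:
            layers += [_nn.Conv1D(c_prev, channels, kernel, rng, stride=stride),
                       _nn.LeakyReLU(spec.leaky_slope)]
            c_prev = channels
            length = -(-length // stride)
        layers += [_nn.Flatten(), _nn.Dense(c_prev * length, 1, rng), _nn.Sigmoid()]
        self.net = _nn.Sequential(layers).astype(np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[-1] != self.spec.input_length:
            raise ValueError(f"input length must be {self.spec.input_length}")
        if x.ndim == 2:
            x = x[:, None, :]
        return self.net.forward(x)[:, 0]


def build_generator(spec: GeneratorSpec = GeneratorSpec(), seed: int = 0) -> Generator:
    return Generator(spec, seed=seed)


def build_discriminator(spec: DiscriminatorSpec = DiscriminatorSpec(),
                        seed: int = 0) -> Discriminator:
    return Discriminator(spec, seed=seed)


@dataclass
class TrainedGAN:
    generator: Generator
    discriminator: Discriminator
    cfg: GANTrainConfig
    patient_id: str = ""
    anchor_hour: int = 0
    history: pd.DataFrame = field(default_factory=pd.DataFrame)
    accepted_at_epoch: int | None = None

    def sample_latent(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.standard_normal((n, self.generator.spec.latent_dim))


def train_gan(days: DayMatrix, gspec: GeneratorSpec = GeneratorSpec(),
              dspec: DiscriminatorSpec = DiscriminatorSpec(),
              cfg: GANTrainConfig = GANTrainConfig(),
              checkpoint_dir: str | Path | None = None) -> TrainedGAN:
    """Adversarially train a per-patient GAN on complete day rows.

    Alternating 1:1 updates with binary cross-entropy: the discriminator is
    fit to label training days 1 and generated days 0; the generator is
    updated through the frozen discriminator to push its samples toward
    label 1.  All randomness (initialization, shuffling, latent draws)
    derives from ``cfg.seed``.  With ``cfg.check_every > 0`` the acceptance
    battery is evaluated periodically on the training days and training
    stops at the first accepted epoch.
    """
    if days.n_days == 0:
        raise ValueError("cannot train on an empty day matrix")
    if cfg.batch_size > days.n_days:
        raise ValueError(
            f"batch_size {cfg.batch_size} exceeds the {days.n_days} available days")

    gen = Generator(gspec, seed=cfg.seed)
    disc = Discriminator(dspec, seed=cfg.seed + 1)
    rng = np.random.default_rng(cfg.seed + 2)
    g_opt = _nn.Adam(gen.net.params(), lr=cfg.gen_lr, beta1=cfg.beta1)
    d_opt = _nn.Adam(disc.net.params(), lr=cfg.disc_lr, beta1=cfg.beta1)

    x_real = _to_norm(days.rows)
    n = len(x_real)
    history_rows = []
    best_min_p, best_epoch, best_weights = -1.0, None, None
    gan = TrainedGAN(gen, disc, cfg, patient_id=days.patient_id,
                     anchor_hour=days.anchor_hour)

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        d_losses, g_losses = [], []
        for start in range(0, n - cfg.batch_size + 1, cfg.batch_size):
            xb = x_real[order[start: start + cfg.batch_size]]
            bs = len(xb)

            # --- discriminator step: real batch then fake batch
            z = rng.standard_normal((bs, gspec.latent_dim))
            fake = gen.forward(z)
            d_opt.zero_grad()
            p_real = disc.net.forward(xb[:, None, :])[:, 0]
            loss_r, dp = _nn.bce_loss(p_real, np.full(bs, cfg.real_label))
            disc.net.backward(dp[:, None])
            p_fake = disc.net.forward(fake[:, None, :])[:, 0]
            loss_f, dp = _nn.bce_loss(p_fake, np.full(bs, cfg.synth_label))
            disc.net.backward(dp[:, None])
            d_opt.step()
            d_losses.append(0.5 * (loss_r + loss_f))

            # --- generator step through the frozen discriminator
            z = rng.standard_normal((bs, gspec.latent_dim))
            g_opt.zero_grad()
            fake = gen.net.forward(z)  # (bs, 1, 288)
            p = disc.net.forward(fake)[:, 0]
            loss_g, dp = _nn.bce_loss(p, np.full(bs, cfg.real_label))
            dfake = disc.net.backward(dp[:, None])
            gen.net.backward(dfake)
            g_opt.step()
            g_losses.append(loss_g)

        history_rows.append({"epoch": epoch + 1,
                             "d_loss": float(np.mean(d_losses)) if d_losses else np.nan,
                             "g_loss": float(np.mean(g_losses)) if g_losses else np.nan})

        if cfg.check_every and (epoch + 1) % cfg.check_every == 0:
            # worst case over a few evaluation draws, so the selected
            # snapshot is robust to the generation/subsampling seed
            min_p = 1.0
            for k in range(3):
                synth = generate_days(gan, n, seed=cfg.seed + 3 + 1000 * k)
                report = wilcoxon_acceptance(days, synth, alpha=cfg.alpha,
                                             seed=cfg.seed + 4 + 1000 * k)
                min_p = min(min_p, *report.p_values.values())
            history_rows[-1]["min_p"] = min_p
            if min_p > best_min_p:
                best_min_p = min_p
                best_epoch = epoch + 1
                best_weights = (gen.net.get_weights(), disc.net.get_weights())
            # adversarial training oscillates: keep the best-matching
            # snapshot and stop once the fit is comfortable
            if min_p >= cfg.stop_margin:
                break

    if best_weights is not None:
        gen.net.set_weights(best_weights[0])
        disc.net.set_weights(best_weights[1])
        if best_min_p >= cfg.alpha:
            gan.accepted_at_epoch = best_epoch
    gan.history = pd.DataFrame(history_rows,
                               columns=["epoch", "d_loss", "g_loss", "min_p"])
    if checkpoint_dir is not None:
        save_checkpoint(gan, checkpoint_dir)
    return gan


def generate_days(gan: TrainedGAN, n: int, seed: int = 0) -> DayMatrix:
    """Draw ``n`` synthetic days (mg/dL, clamped to [40, 400]) from the generator."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for start in range(0, n, 256):  # chunked to bound memory
        z = gan.sample_latent(min(256, n - start), rng)
        rows.append(_from_norm(gan.generator.forward(z)))
    rows = np.clip(np.vstack(rows), GLUCOSE_MIN, GLUCOSE_MAX)
    return DayMatrix(gan.patient_id, rows, anchor_hour=gan.anchor_hour,
                     day_dates=[f"synthetic-{i}" for i in range(n)],
                     provenance="synthetic")


# ---------------------------------------------------------------------------
# checkpoints: {patient_id}/generator.ckpt, discriminator.ckpt, config.yaml,
# loss_history.csv

def save_checkpoint(gan: TrainedGAN, directory: str | Path) -> Path:
    d = Path(directory) / (gan.patient_id or "patient")
    d.mkdir(parents=True, exist_ok=True)
    def _dump(net: _nn.Sequential, path: Path) -> None:
        np.savez(path, **{f"w{i:03d}": w for i, w in enumerate(net.get_weights())})

    _dump(gan.generator.net, d / "generator.ckpt")
    _dump(gan.discriminator.net, d / "discriminator.ckpt")
    config = {
        "patient_id": gan.patient_id,
        "anchor_hour": gan.anchor_hour,
        "generator_spec": _spec_dict(gan.generator.spec),
        "discriminator_spec": _spec_dict(gan.discriminator.spec),
        "train_config": asdict(gan.cfg),
        "accepted_at_epoch": gan.accepted_at_epoch,
    }
    (d / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=False))
    gan.history.to_csv(d / "loss_history.csv", index=False)
    return d


def _spec_dict(spec) -> dict:
    out = asdict(spec)
    for key, val in out.items():
        if isinstance(val, tuple):
            out[key] = [list(v) if isinstance(v, tuple) else v for v in val]
    return out


def _as_stages(raw) -> tuple:
    return tuple(tuple(s) for s in raw)


def load_checkpoint(directory: str | Path) -> TrainedGAN:
    d = Path(directory)
    config = yaml.safe_load((d / "config.yaml").read_text())
    gdict = config["generator_spec"]
    gdict["upsample_stages"] = _as_stages(gdict["upsample_stages"])
    ddict = config["discriminator_spec"]
    ddict["conv_stages"] = _as_stages(ddict["conv_stages"])
    gspec = GeneratorSpec(**gdict)
    dspec = DiscriminatorSpec(**ddict)
    cfg = GANTrainConfig(**config["train_config"])
    gen = Generator(gspec, seed=cfg.seed)
    disc = Discriminator(dspec, seed=cfg.seed + 1)

    def _load(net: _nn.Sequential, path: Path) -> None:
        with np.load(path) as data:
            net.set_weights([data[k] for k in sorted(data.files)])

    # numpy appends .npz when saving to a name without that suffix
    _load(gen.net, d / "generator.ckpt.npz" if (d / "generator.ckpt.npz").exists()
          else d / "generator.ckpt")
    _load(disc.net, d / "discriminator.ckpt.npz" if (d / "discriminator.ckpt.npz").exists()
          else d / "discriminator.ckpt")
    history_path = d / "loss_history.csv"
    history = pd.read_csv(history_path) if history_path.exists() else pd.DataFrame()
    return TrainedGAN(gen, disc, cfg, patient_id=config["patient_id"],
                      anchor_hour=config["anchor_hour"], history=history,
                      accepted_at_epoch=config.get("accepted_at_epoch"))
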