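"""2.5D adversarial slice segmenter.

A 2D encoder–decoder generator turns a CT slice into a binary psoas mask;
to inject through-plane context without the parameter cost of a full 3D
network, each input is the active slice concatenated with its neighbours
above and below (three channels — "2.5D"). A patch discriminator judges
(image, mask) pairs, and the generator objective is the adversarial term
plus a strongly weighted (x10) pixel-wise L1 term:

    L_GAN(G, D) = E_y[log D(x, y)] + E_x[log(1 - D(x, G(x)))]
    L_L1(G)     = E_{x,y}[ || y - G(x) ||_1 ]
    L           = lambda_GAN * L_GAN + lambda_L1 * L_L1

Training slices run from 2 to n-1 (1-based), since the first and last
slices lack one neighbour; at inference those edge slices are predicted by
replicating the nearest neighbour so every slice of the volume is covered.

The network itself is the hand-written numpy stack in :mod:`psoasseg.nn`;
training is single-device deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from skimage.transform import resize
from sklearn.base import BaseEstimator

from .nn import (Adam, Conv2d, InstanceNorm, LeakyReLU, Param, Sigmoid,
                 Upsample2x, bce_with_logits, sigmoid)
from .volume import BinaryMask, ImageVolume, MaskLabel

__all__ = [
    "GanConfig",
    "SliceSample",
    "Generator",
    "PatchDiscriminator",
    "build_slice_samples",
    "l1_loss",
    "gan_loss",
    "total_loss",
    "train",
    "predict_volume",
    "save_generator",
    "load_generator",
    "AdversarialSliceSegmenter",
]

#: Soft-tissue HU window used to normalize inputs to [-1, 1].
HU_WINDOW = (-200.0, 300.0)


@dataclass
class GanConfig:
    """Training configuration.

    Defaults are the reference conditions (256 px slices, 50 epochs,
    Adam with lr 2e-4 and momentum beta1 = 0.5, L1 weight 10); use
    :meth:`desk` for the scaled-down configuration suited to the phantom
    cohort on one CPU.
    """

    train_size: int = 256
    epochs: int = 50
    lr: float = 2e-4
    beta1: float = 0.5
    lambda_l1: float = 10.0
    lambda_gan: float = 1.0
    batch_size: int = 8
    base_channels: int = 16
    depth: int | None = None  # None -> log2(train_size) - 2 (4x4 bottleneck)
    gan_mode: str = "log"  # original saturating form; or "nonsaturating"
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        ts = self.train_size
        if ts < 32 or (ts & (ts - 1)) != 0:
            raise ValueError("train_size must be a power of two >= 32")
        if self.lambda_l1 <= 0 or self.lambda_gan <= 0:
            raise ValueError("loss weights must be > 0")
        if self.gan_mode not in ("log", "nonsaturating"):
            raise ValueError(f"unknown gan_mode {self.gan_mode!r}")
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must lie in (0, 1)")

    def resolved_depth(self) -> int:
        return self.depth if self.depth is not None else int(np.log2(self.train_size)) - 2

    @classmethod
    def desk(cls, **overrides) -> "GanConfig":
        """Scaled-down configuration: 64 px slices, narrow channels."""
        base = dict(train_size=64, epochs=12, batch_size=4, base_channels=8,
                    lr=1e-3)
        base.update(overrides)
        return cls(**base)


@dataclass
class SliceSample:
    """One 2.5D training sample.

    ``image`` is (3, S, S) float32 in [-1, 1], channels ordered
    below/active/above; ``label`` is (S, S) boolean; ``z`` is the 1-based
    slice number of the active slice in the source volume (2..n-1).
    """

    image: np.ndarray
    label: np.ndarray
    case_id: str
    z: int


def _normalize_hu(voxels: np.ndarray) -> np.ndarray:
    lo, hi = HU_WINDOW
    clipped = np.clip(voxels, lo, hi)
    return ((clipped - lo) / (hi - lo) * 2.0 - 1.0).astype(np.float32)


def _resize_image(sl: np.ndarray, size: int) -> np.ndarray:
    if sl.shape == (size, size):
        return sl.astype(np.float32)
    return resize(sl, (size, size), order=1, preserve_range=True,
                  anti_aliasing=sl.shape[0] > size).astype(np.float32)


def _resize_label(sl: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if sl.shape == shape:
        return sl.astype(bool)
    return resize(sl.astype(np.float32), shape, order=0, preserve_range=True,
                  anti_aliasing=False) > 0.5


def build_slice_samples(
    volume: ImageVolume, mask: BinaryMask, cfg: GanConfig
) -> list[SliceSample]:
    """Build the n-2 interior 2.5D samples of a volume.

    Slices 1 and n (1-based) are excluded: each has only one adjacent
    slice. Inputs are windowed, normalized and resized to the training
    size; labels are resized with nearest-neighbour so they stay binary.
    """
    mask.check_same_grid(volume)
    n = volume.n_slices
    if n < 3:
        raise ValueError("2.5D sampling needs at least 3 slices")
    norm = _normalize_hu(volume.voxels)
    samples = []
    for z in range(1, n - 1):
        chans = np.stack(
            [_resize_image(norm[z + dz], cfg.train_size) for dz in (-1, 0, 1)]
        )
        label = _resize_label(mask.voxels[z], (cfg.train_size, cfg.train_size))
        samples.append(SliceSample(chans, label, volume.case_id, z + 1))
    return samples


# ---------------------------------------------------------------------------
# losses


def _check_finite(name: str, arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")


def l1_loss(gen_out: np.ndarray, target: np.ndarray) -> float:
    """Mean absolute deviation E[||y - G(x)||_1] (zero iff G(x) = y)."""
    gen_out = np.asarray(gen_out, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if gen_out.shape != target.shape:
        raise ValueError("shape mismatch between generator output and target")
    _check_finite("gen_out", gen_out)
    _check_finite("target", target)
    return float(np.abs(target - gen_out).mean())


def gan_loss(d_real: np.ndarray, d_fake: np.ndarray) -> float:
    """Adversarial value E[log D(x,y)] + E[log(1 - D(x,G(x)))].

    Inputs are discriminator probabilities in (0, 1).
    """
    d_real = np.asarray(d_real, dtype=np.float64)
    d_fake = np.asarray(d_fake, dtype=np.float64)
    _check_finite("d_real", d_real)
    _check_finite("d_fake", d_fake)
    if np.any((d_real <= 0) | (d_real >= 1)) or np.any((d_fake <= 0) | (d_fake >= 1)):
        raise ValueError("discriminator outputs must lie strictly in (0, 1)")
    return float(np.log(d_real).mean() + np.log1p(-d_fake).mean())


def total_loss(l_gan: float, l_l1: float, cfg: GanConfig) -> float:
    """Weighted sum lambda_GAN * L_GAN + lambda_L1 * L_L1."""
    return cfg.lambda_gan * l_gan + cfg.lambda_l1 * l_l1


# ---------------------------------------------------------------------------
# networks


class Generator:
    """Encoder–decoder with skip connections (U-Net style), sigmoid output.

    Stride-2 convolutions halve resolution ``depth`` times down to a 4x4
    bottleneck at the default depth; the decoder mirrors with nearest-
    neighbour upsampling + convolution and concatenated skips.
    """

    def __init__(self, in_ch: int = 3, base: int = 16, depth: int = 4,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.depth = depth
        ch = [base * min(2**i, 4) for i in range(depth)]
        self.ch = ch
        self.enc = []
        c = in_ch
        for i in range(depth):
            norm = InstanceNorm(ch[i]) if i > 0 else None  # raw intensities first
            self.enc.append((Conv2d(c, ch[i], k=4, stride=2, pad=1, rng=rng),
                             norm, LeakyReLU(0.2)))
            c = ch[i]
        self.dec = []
        for j, i in enumerate(range(depth - 2, -1, -1)):
            self.dec.append((Upsample2x(), Conv2d(c + ch[i], ch[i], k=3, rng=rng),
                             InstanceNorm(ch[i]), LeakyReLU(0.0)))
            c = ch[i]
        self.final_up = Upsample2x()
        self.final_conv = Conv2d(c, 1, k=3, rng=rng)
        self.final_act = Sigmoid()

    def params(self) -> list[Param]:
        ps: list[Param] = []
        for conv, norm, _ in self.enc:
            ps += conv.params() + (norm.params() if norm else [])
        for _, conv, norm, _ in self.dec:
            ps += conv.params() + norm.params()
        return ps + self.final_conv.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        skips = []
        h = x.astype(np.float32)
        for conv, norm, act in self.enc:
            h = conv.forward(h)
            if norm:
                h = norm.forward(h)
            h = act.forward(h)
            skips.append(h)
        self._split = []
        for j, (up, conv, norm, act) in enumerate(self.dec):
            i = self.depth - 2 - j
            h = up.forward(h)
            self._split.append(h.shape[1])
            h = np.concatenate([h, skips[i]], axis=1)
            h = act.forward(norm.forward(conv.forward(h)))
        h = self.final_up.forward(h)
        return self.final_act.forward(self.final_conv.forward(h))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.final_act.backward(dy)
        dh = self.final_up.backward(self.final_conv.backward(dh))
        dskips: list[np.ndarray | None] = [None] * self.depth
        for j in range(len(self.dec) - 1, -1, -1):
            up, conv, norm, act = self.dec[j]
            i = self.depth - 2 - j
            d = conv.backward(norm.backward(act.backward(dh)))
            split = self._split[j]
            dskips[i] = d[:, split:]
            dh = up.backward(d[:, :split])
        for i in range(self.depth - 1, -1, -1):
            conv, norm, act = self.enc[i]
            if dskips[i] is not None:
                dh = dh + dskips[i]
            dh = act.backward(dh)
            if norm:
                dh = norm.backward(dh)
            dh = conv.backward(dh)
        return dh

    # -- state (for serialization) --
    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_state(self, arrays: list[np.ndarray]) -> None:
        for p, a in zip(self.params(), arrays, strict=True):
            p.value[...] = a


class PatchDiscriminator:
    """Three-layer patch classifier on concatenated (image, mask) channels.

    Output is a grid of patch logits; each logit sees a local receptive
    field, so realism is judged patch-wise rather than globally.
    """

    def __init__(self, in_ch: int = 4, base: int = 16,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.layers = [
            Conv2d(in_ch, base, k=4, stride=2, pad=1, rng=rng), LeakyReLU(0.2),
            Conv2d(base, 2 * base, k=4, stride=2, pad=1, rng=rng),
            InstanceNorm(2 * base), LeakyReLU(0.2),
            Conv2d(2 * base, 1, k=3, rng=rng),
        ]

    def params(self) -> list[Param]:
        ps: list[Param] = []
        for layer in self.layers:
            if isinstance(layer, (Conv2d, InstanceNorm)):
                ps += layer.params()
        return ps

    def forward(self, image: np.ndarray, mask: np.ndarray) -> np.ndarray:
        h = np.concatenate([image, mask], axis=1).astype(np.float32)
        for layer in self.layers:
            h = layer.forward(h)
        return h  # logits

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dh = dlogits
        for layer in reversed(self.layers):
            dh = layer.backward(dh)
        return dh  # grad wrt concatenated input channels


# ---------------------------------------------------------------------------
# training / inference


@dataclass
class TrainResult:
    generator: Generator
    discriminator: PatchDiscriminator
    config: GanConfig
    trace: list[dict] = field(default_factory=list)


def train(samples: list[SliceSample], cfg: GanConfig) -> TrainResult:
    """Alternating generator/discriminator training with Adam(lr, beta1).

    ``epochs == 0`` returns an untrained (randomly initialized) generator
    whose predictions are still valid masks. A non-finite loss aborts with
    a message naming the last completed epoch.
    """
    if not samples:
        raise ValueError("need at least one training sample")
    rng = np.random.default_rng(cfg.seed)
    X = np.stack([s.image for s in samples]).astype(np.float32)
    Y = np.stack([s.label for s in samples]).astype(np.float32)[:, None]
    G = Generator(3, cfg.base_channels, cfg.resolved_depth(), rng)
    D = PatchDiscriminator(4, cfg.base_channels, rng)
    opt_g = Adam(G.params(), cfg.lr, cfg.beta1)
    opt_d = Adam(D.params(), cfg.lr, cfg.beta1)
    result = TrainResult(G, D, cfg)

    n = len(samples)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_l1 = ep_gan = ep_d = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            x, y = X[idx], Y[idx]
            fake = G.forward(x)

            # -- discriminator: real up, fake down --
            opt_d.zero_grad()
            zr = D.forward(x, y)
            m = zr.size
            D.backward(0.5 * (sigmoid(zr) - 1.0) / m)
            zf = D.forward(x, fake)
            D.backward(0.5 * sigmoid(zf) / m)
            d_loss = 0.5 * (bce_with_logits(zr, 1.0) + bce_with_logits(zf, 0.0))
            opt_d.step()

            # -- generator: adversarial (through updated D) + weighted L1 --
            opt_g.zero_grad()
            zf2 = D.forward(x, fake)
            if cfg.gan_mode == "log":  # minimize log(1 - D(fake))
                dz = -sigmoid(zf2) / zf2.size
            else:  # non-saturating: minimize -log D(fake)
                dz = (sigmoid(zf2) - 1.0) / zf2.size
            d_in_grad = D.backward(cfg.lambda_gan * dz)
            opt_d.zero_grad()  # discard grads from the generator pass
            dfake = d_in_grad[:, 3:4] + cfg.lambda_l1 * np.sign(fake - y) / fake.size
            G.backward(dfake.astype(np.float32))
            opt_g.step()

            l1 = float(np.abs(y - fake).mean())
            adv = -(bce_with_logits(zr, 1.0) + bce_with_logits(zf, 0.0))
            if not np.isfinite(l1) or not np.isfinite(d_loss):
                raise RuntimeError(
                    f"training diverged (non-finite loss); last good state is "
                    f"the checkpoint after epoch {epoch}"
                )
            ep_l1 += l1
            ep_gan += adv
            ep_d += d_loss
            n_batches += 1
        result.trace.append(
            {
                "epoch": epoch + 1,
                "l1": ep_l1 / n_batches,
                "gan": ep_gan / n_batches,
                "total": cfg.lambda_gan * ep_gan / n_batches
                + cfg.lambda_l1 * ep_l1 / n_batches,
                "d_loss": ep_d / n_batches,
            }
        )
    return result


def _volume_to_batches(volume: ImageVolume, size: int) -> np.ndarray:
    """All-slices 2.5D input stack with replicated-neighbour edge padding."""
    norm = _normalize_hu(volume.voxels)
    n = volume.n_slices
    stacks = []
    for z in range(n):
        zs = (max(z - 1, 0), z, min(z + 1, n - 1))
        stacks.append(np.stack([_resize_image(norm[zz], size) for zz in zs]))
    return np.stack(stacks)


def predict_volume(
    volume: ImageVolume, generator: Generator | TrainResult, cfg: GanConfig
) -> BinaryMask:
    """Segment every slice of a volume; output grid equals the input grid.

    Edge slices (which lack one neighbour) use replicated-neighbour
    padding. The sigmoid output is thresholded at ``cfg.threshold`` and
    mapped back to native in-plane resolution with nearest-neighbour.
    """
    gen = generator.generator if isinstance(generator, TrainResult) else generator
    X = _volume_to_batches(volume, cfg.train_size)
    probs = np.concatenate(
        [gen.forward(X[i : i + 8]) for i in range(0, len(X), 8)], axis=0
    )[:, 0]
    binary = probs > cfg.threshold
    nz, ny, nx = volume.shape
    out = np.empty((nz, ny, nx), dtype=bool)
    for z in range(nz):
        out[z] = _resize_label(binary[z], (ny, nx))
    return BinaryMask(out, volume.spacing, origin=volume.origin,
                      case_id=volume.case_id, label=MaskLabel.BILATERAL)


def save_generator(result: TrainResult, path: str | Path) -> None:
    """Serialize generator weights (.npz) with a JSON config sidecar."""
    path = Path(path)
    arrays = {f"p{i}": a for i, a in enumerate(result.generator.get_state())}
    np.savez(path, **arrays)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(asdict(result.config), indent=2))


def load_generator(path: str | Path) -> TrainResult:
    path = Path(path)
    cfg = GanConfig(**json.loads(path.with_suffix(".json").read_text()))
    with np.load(path if path.suffix == ".npz" else f"{path}.npz") as data:
        arrays = [data[f"p{i}"] for i in range(len(data.files))]
    gen = Generator(3, cfg.base_channels, cfg.resolved_depth(),
                    np.random.default_rng(cfg.seed))
    gen.set_state(arrays)
    return TrainResult(gen, PatchDiscriminator(4, cfg.base_channels), cfg)


class AdversarialSliceSegmenter(BaseEstimator):
    """sklearn-style wrapper around the 2.5D adversarial segmenter.

    Defaults are the desk scale (64 px, narrow channels) so that fitting a
    small cohort stays within minutes on one CPU; pass the reference-scale
    values (train_size=256, epochs=50, base_channels=16, batch_size=8) to
    reproduce the full configuration.
    """

    def __init__(self, train_size: int = 64, epochs: int = 12, lr: float = 1e-3,
                 beta1: float = 0.5, lambda_l1: float = 10.0,
                 lambda_gan: float = 1.0, batch_size: int = 4,
                 base_channels: int = 8, depth: int | None = None,
                 gan_mode: str = "log", threshold: float = 0.5, seed: int = 0):
        self.train_size = train_size
        self.epochs = epochs
        self.lr = lr
        self.beta1 = beta1
        self.lambda_l1 = lambda_l1
        self.lambda_gan = lambda_gan
        self.batch_size = batch_size
        self.base_channels = base_channels
        self.depth = depth
        self.gan_mode = gan_mode
        self.threshold = threshold
        self.seed = seed

    def _config(self) -> GanConfig:
        return GanConfig(
            train_size=self.train_size, epochs=self.epochs, lr=self.lr,
            beta1=self.beta1, lambda_l1=self.lambda_l1,
            lambda_gan=self.lambda_gan, batch_size=self.batch_size,
            base_channels=self.base_channels, depth=self.depth,
            gan_mode=self.gan_mode, threshold=self.threshold, seed=self.seed,
        )

    def fit(self, volumes, masks):
        cfg = self._config()
        samples: list[SliceSample] = []
        for vol, mask in zip(volumes, masks, strict=True):
            samples.extend(build_slice_samples(vol, mask, cfg))
        result = train(samples, cfg)
        self.config_ = cfg
        self.result_ = result
        self.generator_ = result.generator
        self.trace_ = result.trace
        self.n_samples_ = len(samples)
        return self

    def predict(self, volume: ImageVolume) -> BinaryMask:
        return predict_volume(volume, self.generator_, self.config_)
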