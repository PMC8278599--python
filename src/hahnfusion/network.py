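"""Convolutional feature extraction, image reconstruction, losses, training.

The network is a small fully-convolutional autoencoder.  The extractor is
three stride-1 layers (64 kernels of 7×7, 5×5, 3×3 with padding 3, 2, 1) so
spatial resolution is never lost; the reconstructor is a 3×3 layer of 64
kernels followed by a 1×1 layer down to 3 output channels.  ReLU follows
every hidden layer; a final sigmoid squashes the output into (0, 1), which
the pixel-wise cross-entropy loss requires.  The block-wise fusion module
operates between extractor and reconstructor at inference time; training is
plain input-reconstruction (no fusion in the loop), since brain image fusion
has no ground-truth fused image to regress against.

Total loss = cross-entropy + (1 − MS-SSIM) + total-variation, unweighted by
default: the first drives per-pixel agreement, the second preserves
luminance/contrast/structure across scales, the third discourages noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, avg_pool2x2, conv2d

logger = logging.getLogger(__name__)

__all__ = [
    "ConvLayerSpec",
    "FusionNetwork",
    "TrainConfig",
    "EXTRACTOR_SPECS",
    "RECONSTRUCTOR_SPECS",
    "build_network",
    "extract_features",
    "reconstruct_image",
    "loss_cross_entropy",
    "loss_ms_ssim",
    "loss_tv",
    "loss_total",
    "ms_ssim",
    "train_autoencoder",
    "save_weights",
    "load_weights",
]


@dataclass(frozen=True)
class ConvLayerSpec:
    kernel_count: int
    kernel_size: int
    stride: int = 1
    padding: int = 0

    def __post_init__(self) -> None:
        if self.kernel_count < 1 or self.kernel_size < 1 or self.stride < 1:
            raise ValueError(f"invalid layer spec {self}")
        if self.padding < 0:
            raise ValueError(f"padding must be >= 0, got {self.padding}")


# CONV1-3: stride-1 with "same" padding so no spatial information is lost.
EXTRACTOR_SPECS = (
    ConvLayerSpec(64, 7, 1, 3),
    ConvLayerSpec(64, 5, 1, 2),
    ConvLayerSpec(64, 3, 1, 1),
)
# CONV4-5; the 1x1 output layer maps 64 feature channels to 3 color channels.
RECONSTRUCTOR_SPECS = (
    ConvLayerSpec(64, 3, 1, 1),
    ConvLayerSpec(3, 1, 1, 0),
)


@dataclass
class FusionNetwork:
    """Layer specs plus their weights (a flat list of (w, b) Tensor pairs)."""

    extractor: tuple[ConvLayerSpec, ...]
    reconstructor: tuple[ConvLayerSpec, ...]
    params: list[Tensor] = field(repr=False)
    seed: int | None = None

    def parameters(self) -> list[Tensor]:
        return self.params


def build_network(seed: int = 0) -> FusionNetwork:
    """Build the 5-layer network with seeded He-normal weights (float32)."""
    rng = np.random.default_rng(seed)
    params: list[Tensor] = []
    in_ch = 3
    for spec in EXTRACTOR_SPECS + RECONSTRUCTOR_SPECS:
        fan_in = in_ch * spec.kernel_size**2
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(spec.kernel_count, in_ch,
                             spec.kernel_size, spec.kernel_size))
        params.append(Tensor(w.astype(np.float32), requires_grad=True))
        params.append(Tensor(np.zeros(spec.kernel_count, dtype=np.float32),
                             requires_grad=True))
        in_ch = spec.kernel_count
    return FusionNetwork(extractor=EXTRACTOR_SPECS,
                         reconstructor=RECONSTRUCTOR_SPECS,
                         params=params, seed=seed)


def _forward_extract(net: FusionNetwork, x: Tensor) -> Tensor:
    for i, spec in enumerate(net.extractor):
        w, b = net.params[2 * i], net.params[2 * i + 1]
        x = conv2d(x, w, b, stride=spec.stride, padding=spec.padding,
                   ws=f"ext{i}").relu()
    return x


def _forward_reconstruct(net: FusionNetwork, x: Tensor) -> Tensor:
    n_ext = len(net.extractor)
    for i, spec in enumerate(net.reconstructor):
        w = net.params[2 * (n_ext + i)]
        b = net.params[2 * (n_ext + i) + 1]
        x = conv2d(x, w, b, stride=spec.stride, padding=spec.padding,
                   ws=f"rec{i}")
        x = x.relu() if i < len(net.reconstructor) - 1 else x.sigmoid()
    return x


def _to_batch(image: np.ndarray) -> np.ndarray:
    """(H, W, 3) image in [0,1] -> (1, 3, H, W) float32 batch."""
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(
            f"expected an (H, W, 3) image, got shape {img.shape}; replicate "
            "grayscale inputs with hahnfusion.image_io.to_network_input first")
    return img[None]


def extract_features(net: FusionNetwork, image: np.ndarray) -> np.ndarray:
    """Run the 3-layer extractor; (H, W, 3) -> (64, H, W) activations."""
    out = _forward_extract(net, Tensor(_to_batch(image)))
    return out.data[0].transpose(2, 0, 1)


def reconstruct_image(net: FusionNetwork, features: np.ndarray) -> np.ndarray:
    """Run the 2-layer reconstructor; (64, H, W) -> (H, W, 3) in (0, 1)."""
    feats = np.asarray(features, dtype=np.float32)
    if feats.ndim != 3 or feats.shape[0] != net.extractor[-1].kernel_count:
        raise ValueError(
            f"expected ({net.extractor[-1].kernel_count}, H, W) features, "
            f"got shape {feats.shape}")
    out = _forward_reconstruct(net, Tensor(feats.transpose(1, 2, 0)[None]))
    return out.data[0]


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

_EPS = 1e-7

#: standard 5-scale MS-SSIM exponents (renormalized when fewer scales fit)
_MSSSIM_WEIGHTS = np.array([0.0448, 0.2856, 0.3001, 0.2363, 0.1333])
_SSIM_K1, _SSIM_K2, _SSIM_SIGMA, _SSIM_WIN = 0.01, 0.03, 1.5, 11


def _prep_pair(I, O):
    """Coerce a pair of inputs to 4-D (B, C, H, W) Tensors of matching shape."""
    def prep(v):
        if isinstance(v, Tensor):
            if v.data.ndim != 4:
                raise ValueError("Tensor inputs must already be (B, C, H, W)")
            return v
        arr = np.asarray(v, dtype=float)
        if arr.ndim == 0:
            arr = arr.reshape(1, 1, 1, 1)
        elif arr.ndim == 2:
            arr = arr[None, ..., None]
        elif arr.ndim == 3:  # (H, W, C) image
            arr = arr[None]
        elif arr.ndim != 4:
            raise ValueError(f"unsupported input rank {arr.ndim}")
        return Tensor(arr)

    It, Ot = prep(I), prep(O)
    if It.shape != Ot.shape:
        raise ValueError(f"shape mismatch {It.shape} vs {Ot.shape}")
    return It, Ot


def _as_result(value: Tensor, *inputs) -> Tensor | float:
    """Return a float when every input was a plain array, else keep the graph."""
    if any(isinstance(v, Tensor) for v in inputs):
        return value
    return value.item()


def loss_cross_entropy(I, O, reduction: str = "mean"):
    """Pixel-wise binary cross-entropy −Σ I·log O + (1−I)·log(1−O).

    Both images are clamped to [ε, 1−ε] (ε = 1e−7).  Mean reduction by
    default; ``reduction="sum"`` gives the literal raw sum.
    """
    It, Ot = _prep_pair(I, O)
    Ic = It.clamp(_EPS, 1.0 - _EPS)
    Oc = Ot.clamp(_EPS, 1.0 - _EPS)
    per_px = -(Ic * Oc.log() + (1.0 - Ic) * (1.0 - Oc).log())
    out = per_px.mean() if reduction == "mean" else per_px.sum()
    return _as_result(out, I, O)


def _gaussian_kernel(dtype) -> np.ndarray:
    r = _SSIM_WIN // 2
    g = np.exp(-np.arange(-r, r + 1)**2 / (2 * _SSIM_SIGMA**2))
    g /= g.sum()
    return np.asarray(np.outer(g, g)[None, None], dtype=dtype)


def _ssim_terms(x: Tensor, y: Tensor):
    """Mean luminance and contrast-structure SSIM terms over valid windows."""
    B, H, W, C = x.shape
    k = Tensor(_gaussian_kernel(x.data.dtype))
    xf = x.transpose(0, 3, 1, 2).reshape(B * C, H, W, 1)
    yf = y.transpose(0, 3, 1, 2).reshape(B * C, H, W, 1)
    mu_x = conv2d(xf, k)
    mu_y = conv2d(yf, k)
    sxx = conv2d(xf * xf, k) - mu_x * mu_x
    syy = conv2d(yf * yf, k) - mu_y * mu_y
    sxy = conv2d(xf * yf, k) - mu_x * mu_y
    C1 = _SSIM_K1**2
    C2 = _SSIM_K2**2
    lum = (2.0 * mu_x * mu_y + C1) / (mu_x * mu_x + mu_y * mu_y + C1)
    cs = (2.0 * sxy + C2) / (sxx + syy + C2)
    return lum.mean(), cs.mean()


def _n_scales(H: int, W: int) -> int:
    """As many halvings as keep the smallest scale >= 16 px (max 5)."""
    n = 1
    while n < 5 and min(H, W) // 2**n >= 16:
        n += 1
    return n


def ms_ssim(X, Y) -> Tensor | float:
    """Multi-scale SSIM with the standard 5-scale exponents.

    Contrast-structure terms are taken at every scale, the luminance term
    only at the coarsest; small images use fewer scales (renormalized
    weights) with a logged notice.
    """
    Xt, Yt = _prep_pair(X, Y)
    H, W = Xt.shape[1], Xt.shape[2]
    levels = _n_scales(H, W)
    if levels < 5:
        logger.info("ms_ssim: %dx%d image supports %d of 5 scales", H, W,
                    levels)
    weights = _MSSSIM_WEIGHTS[:levels] / _MSSSIM_WEIGHTS[:levels].sum()
    out = None
    x, y = Xt, Yt
    for lvl in range(levels):
        lum, cs = _ssim_terms(x, y)
        term = (lum * cs) if lvl == levels - 1 else cs
        piece = term.clamp(1e-6, 1.0)**float(weights[lvl])
        out = piece if out is None else out * piece
        if lvl < levels - 1:
            x, y = avg_pool2x2(x), avg_pool2x2(y)
    return _as_result(out, X, Y)


def loss_ms_ssim(I, O):
    """1 − MS-SSIM(I, O); zero iff the images are structurally identical."""
    It, Ot = _prep_pair(I, O)
    out = 1.0 - ms_ssim(It, Ot)
    return _as_result(out, I, O)


def loss_tv(F, reduction: str = "mean"):
    """Total variation: summed squared horizontal and vertical differences."""
    if isinstance(F, Tensor):
        Ft = F
    else:
        Ft = Tensor(np.asarray(F, dtype=float))
        if Ft.data.ndim == 2:
            Ft = Tensor(Ft.data[None, ..., None])
        elif Ft.data.ndim == 3:
            Ft = Tensor(Ft.data[None])
    dh = Ft[:, :, 1:, :] - Ft[:, :, :-1, :]
    dv = Ft[:, 1:, :, :] - Ft[:, :-1, :, :]
    raw = (dh * dh).sum() + (dv * dv).sum()
    out = raw * (1.0 / Ft.data.size) if reduction == "mean" else raw
    return _as_result(out, F)


def loss_total(I, O, weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
               return_components: bool = False):
    """Composite loss: w1·CE + w2·(1−MS-SSIM) + w3·TV of the output."""
    It, Ot = _prep_pair(I, O)
    ce = loss_cross_entropy(It, Ot)
    ms = loss_ms_ssim(It, Ot)
    tv = loss_tv(Ot)
    total = weights[0] * ce + weights[1] * ms + weights[2] * tv
    if return_components:
        comps = (ce, ms, tv)
        if not any(isinstance(v, Tensor) for v in (I, O)):
            return total.item(), tuple(c.item() for c in comps)
        return total, comps
    return _as_result(total, I, O)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Desk-scale autoencoder training settings (Adam)."""

    epochs: int = 50
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0
    loss_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError(f"invalid training config {self}")


class _Adam:
    def __init__(self, params: list[Tensor], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                p.data.dtype)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def train_autoencoder(net: FusionNetwork, images,
                      config: TrainConfig | None = None):
    """Train extractor + reconstructor to reproduce the given images.

    Parameters
    ----------
    net
        Network to train (updated in place and returned).
    images
        Sequence of (H, W, 3) images in [0, 1] — all the same size.
    config
        Training hyperparameters.

    Returns
    -------
    (net, history) where history is the list of per-epoch mean total losses.
    """
    if config is None:
        config = TrainConfig()
    imgs = [np.asarray(im, dtype=np.float32) for im in images]
    if len(imgs) == 0:
        raise ValueError("training set is empty")
    if any(im.ndim != 3 or im.shape[-1] != 3 for im in imgs):
        raise ValueError("every training image must be (H, W, 3)")
    data = np.stack(imgs)  # (n, H, W, 3), NHWC

    rng = np.random.default_rng(config.seed)
    opt = _Adam(net.parameters(), lr=config.learning_rate)
    history: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(len(imgs))
        epoch_losses = []
        for start in range(0, len(imgs), config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = Tensor(data[idx])
            out = _forward_reconstruct(net, _forward_extract(net, batch))
            loss = loss_total(batch, out, weights=config.loss_weights)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        history.append(float(np.mean(epoch_losses)))
    return net, history


def save_weights(net: FusionNetwork, path) -> None:
    """Write all weights to a single .npz archive."""
    np.savez(path, **{f"p{i}": p.data for i, p in enumerate(net.params)})


def load_weights(path, seed: int = 0) -> FusionNetwork:
    """Rebuild a network from a saved .npz checkpoint."""
    net = build_network(seed)
    with np.load(path) as z:
        for i, p in enumerate(net.params):
            arr = z[f"p{i}"]
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"checkpoint parameter p{i} has shape {arr.shape}, "
                    f"expected {p.data.shape}")
            p.data = arr
    return net
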