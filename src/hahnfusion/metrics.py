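"""Fusion-quality metrics: Q_AB/F, SSIM, VIF, FMI, SF, CE.

The six scores cover five assessment families: edge-information transfer
(Q_AB/F, Xydeas–Petrović), structural similarity (SSIM, Wang et al.),
human-visual fidelity (pixel-domain VIF, Sheikh–Bovik), feature-level
information (FMI: mutual information between gradient-magnitude features),
image activity (spatial frequency SF), and histogram divergence (CE, in
bits; lower is better).  Color images are collapsed to ITU-R 601 luminance
before scoring; all images are float in [0, 1].

SSIM delegates to scikit-image (standard constants); the remaining metrics
are implemented here following their original references, with every
constant pinned below.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import correlate, sobel
from skimage.metrics import structural_similarity

from .image_io import to_luminance

__all__ = [
    "FusionTriplet",
    "ScoreReport",
    "metric_sf",
    "metric_ssim",
    "metric_ce",
    "metric_qabf",
    "metric_vif",
    "metric_fmi",
    "score_all",
    "write_scores_csv",
]

# Q_AB/F sigmoid constants (edge-strength and orientation channels)
_QABF_GAMMA_G, _QABF_KAPPA_G, _QABF_SIGMA_G = 0.9994, -15.0, 0.5
_QABF_GAMMA_A, _QABF_KAPPA_A, _QABF_SIGMA_A = 0.9879, -22.0, 0.8

_VIF_SIGMA_N_SQ = 2.0  # GSM noise variance, on the 0-255 intensity scale
_HIST_BINS = 256
_HIST_EPS = 1e-10


@dataclass(frozen=True)
class FusionTriplet:
    """Two source images and their fused result, all co-registered."""

    source_a: np.ndarray = field(repr=False)
    source_b: np.ndarray = field(repr=False)
    fused: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        a = to_luminance(self.source_a)
        b = to_luminance(self.source_b)
        f = to_luminance(self.fused)
        if not (a.shape == b.shape == f.shape):
            raise ValueError(
                f"spatial shapes differ: {a.shape}, {b.shape}, {f.shape}")
        object.__setattr__(self, "_lum", (a, b, f))

    @property
    def luminances(self):
        return self._lum


@dataclass(frozen=True)
class ScoreReport:
    qabf: float
    ssim: float
    vif: float
    fmi: float
    sf: float
    ce: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("qabf", "ssim", "vif", "fmi", "sf", "ce")}


def metric_sf(F: np.ndarray) -> float:
    """Spatial frequency: RMS of horizontal and vertical first differences."""
    img = to_luminance(F)
    if img.ndim != 2 or min(img.shape) < 2:
        raise ValueError(f"image must be at least 2x2, got shape {img.shape}")
    n = img.size
    rf = np.sum(np.diff(img, axis=1)**2) / n
    cf = np.sum(np.diff(img, axis=0)**2) / n
    return float(np.sqrt(rf + cf))


def metric_ssim(X: np.ndarray, Y: np.ndarray) -> float:
    """Mean local SSIM, 11×11 Gaussian window σ=1.5, K1=0.01, K2=0.03."""
    x, y = to_luminance(X), to_luminance(Y)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    return float(structural_similarity(
        x, y, data_range=1.0, gaussian_weights=True, sigma=1.5,
        win_size=11, use_sample_covariance=False))


def _gray_hist(img: np.ndarray) -> np.ndarray:
    h, _ = np.histogram(np.clip(img, 0, 1), bins=_HIST_BINS, range=(0, 1))
    p = h.astype(float) + _HIST_EPS
    return p / p.sum()


def _kl_bits(p: np.ndarray, q: np.ndarray) -> float:
    return float(np.sum(p * np.log2(p / q)))


def metric_ce(triplet: FusionTriplet) -> float:
    """Cross entropy: mean source→fused KL divergence of gray histograms."""
    a, b, f = triplet.luminances
    qf = _gray_hist(f)
    return 0.5 * (_kl_bits(_gray_hist(a), qf) + _kl_bits(_gray_hist(b), qf))


def _edges(img: np.ndarray):
    gx = sobel(img, axis=1, mode="nearest")
    gy = sobel(img, axis=0, mode="nearest")
    g = np.hypot(gx, gy)
    alpha = np.arctan2(gy, gx)
    # fold orientation into (-pi/2, pi/2]: edges are undirected
    alpha = np.where(alpha > np.pi / 2, alpha - np.pi, alpha)
    alpha = np.where(alpha <= -np.pi / 2, alpha + np.pi, alpha)
    return g, alpha


def _edge_preservation(gs, als, gf, alf):
    """Per-pixel Q^{SF} edge strength+orientation preservation."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(gs > gf, gf / gs, np.where(gf > 0, gs / gf, 0.0))
    ratio = np.nan_to_num(ratio)
    dalpha = 1.0 - np.abs(als - alf) / (np.pi / 2)
    qg = _QABF_GAMMA_G / (1 + np.exp(_QABF_KAPPA_G * (ratio - _QABF_SIGMA_G)))
    qa = _QABF_GAMMA_A / (1 + np.exp(_QABF_KAPPA_A * (dalpha - _QABF_SIGMA_A)))
    return qg * qa


def metric_qabf(triplet: FusionTriplet) -> float:
    """Edge-information transfer Q_AB/F in [0, 1].

    Sobel edge strength and orientation of the fused image are compared with
    each source; per-pixel preservation scores pass through the published
    sigmoids and are averaged with source edge strength as weight.
    """
    a, b, f = triplet.luminances
    ga, ala = _edges(a)
    gb, alb = _edges(b)
    gf, alf = _edges(f)
    qaf = _edge_preservation(ga, ala, gf, alf)
    qbf = _edge_preservation(gb, alb, gf, alf)
    wsum = np.sum(ga + gb)
    if wsum == 0:
        return 0.0
    return float(np.sum(qaf * ga + qbf * gb) / wsum)


def _gaussian2d(n: int, sd: float) -> np.ndarray:
    r = (n - 1) / 2
    ax = np.arange(n) - r
    g = np.exp(-ax**2 / (2 * sd**2))
    k = np.outer(g, g)
    return k / k.sum()


def metric_vif(X: np.ndarray, Y: np.ndarray) -> float:
    """Pixel-domain visual information fidelity of Y given reference X.

    Four scales; at each, the reference is modelled as a Gaussian scale
    mixture and the test image as a gain-plus-noise distortion of it, with
    noise variance σ_n² = 2 on the 0–255 intensity scale.
    """
    ref = to_luminance(X) * 255.0
    dist = to_luminance(Y) * 255.0
    if ref.shape != dist.shape:
        raise ValueError(f"shape mismatch {ref.shape} vs {dist.shape}")
    num = den = 0.0
    for scale in range(1, 5):
        n = 2**(4 - scale + 1) + 1
        win = _gaussian2d(n, n / 5.0)
        if scale > 1:
            ref = correlate(ref, win, mode="nearest")[::2, ::2]
            dist = correlate(dist, win, mode="nearest")[::2, ::2]
        mu1 = correlate(ref, win, mode="nearest")
        mu2 = correlate(dist, win, mode="nearest")
        s1 = correlate(ref * ref, win, mode="nearest") - mu1 * mu1
        s2 = correlate(dist * dist, win, mode="nearest") - mu2 * mu2
        s12 = correlate(ref * dist, win, mode="nearest") - mu1 * mu2
        s1 = np.maximum(s1, 0)
        s2 = np.maximum(s2, 0)
        g = s12 / (s1 + 1e-10)
        sv = s2 - g * s12
        g = np.where(s1 < 1e-10, 0.0, g)
        sv = np.where(s1 < 1e-10, s2, sv)
        s1 = np.where(s1 < 1e-10, 0.0, s1)
        sv = np.where(s2 < 1e-10, 0.0, sv)
        g = np.where(s2 < 1e-10, 0.0, g)
        sv = np.where(g < 0, s2, sv)
        g = np.maximum(g, 0.0)
        sv = np.maximum(sv, 1e-10)
        num += np.sum(np.log10(1 + g * g * s1 / (sv + _VIF_SIGMA_N_SQ)))
        den += np.sum(np.log10(1 + s1 / _VIF_SIGMA_N_SQ))
    if den == 0:
        return 0.0
    return float(num / den)


def _gradient_feature(img: np.ndarray) -> np.ndarray:
    g = np.hypot(sobel(img, axis=1, mode="nearest"),
                 sobel(img, axis=0, mode="nearest"))
    rng = g.max() - g.min()
    return (g - g.min()) / rng if rng > 0 else np.zeros_like(g)


def _nmi(x: np.ndarray, y: np.ndarray) -> float:
    joint, _, _ = np.histogram2d(x.ravel(), y.ravel(), bins=_HIST_BINS,
                                 range=[[0, 1], [0, 1]])
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nz = pxy > 0
    mi = np.sum(pxy[nz] * np.log2(pxy[nz] / np.outer(px, py)[nz]))
    hx = -np.sum(px[px > 0] * np.log2(px[px > 0]))
    hy = -np.sum(py[py > 0] * np.log2(py[py > 0]))
    if hx + hy == 0:
        return 0.0
    return float(2.0 * mi / (hx + hy))


def metric_fmi(triplet: FusionTriplet) -> float:
    """Feature mutual information: NMI between gradient-magnitude features
    of each source and the fused image, averaged over the two sources."""
    a, b, f = triplet.luminances
    ff = _gradient_feature(f)
    return 0.5 * (_nmi(_gradient_feature(a), ff)
                  + _nmi(_gradient_feature(b), ff))


def score_all(triplet: FusionTriplet) -> ScoreReport:
    """All six metrics; pairwise scores are averaged over the two sources."""
    a, b, f = triplet.luminances
    return ScoreReport(
        qabf=metric_qabf(triplet),
        ssim=0.5 * (metric_ssim(a, f) + metric_ssim(b, f)),
        vif=0.5 * (metric_vif(a, f) + metric_vif(b, f)),
        fmi=metric_fmi(triplet),
        sf=metric_sf(f),
        ce=metric_ce(triplet),
    )


def write_scores_csv(reports: dict[str, ScoreReport], path) -> None:
    """One CSV row per triplet: image id followed by the six scores."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "qabf", "ssim", "vif", "fmi", "sf", "ce"])
        for key, rep in reports.items():
            d = rep.as_dict()
            writer.writerow([key] + [f"{d[k]:.6f}" for k in
                                     ("qabf", "ssim", "vif", "fmi", "sf", "ce")])
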