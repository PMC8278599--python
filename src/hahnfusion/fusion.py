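"""Block-wise feature-map fusion driven by Hahn-moment energy and PCNN firing.

The fusion rule decides, block by block, which source's features survive:

1. collapse each source's feature stack to a single activity image (mean of
   absolute channel activations);
2. partition into D×D blocks (zero fill on the bottom/right edges);
3. per block, take 2-D Hahn moments and summarize them by their *potential
   energy* — the distance-weighted absolute deviation of every moment from
   the leading (DC-like) moment.  Dark, structure-free blocks (background)
   score ~0; bright and/or textured blocks score high, because every
   deviation term inherits the leading moment when the higher orders are
   empty;
4. feed the (jointly min–max normalized) PE maps as stimuli into one PCNN per
   source, one neuron per block, with saliency-derived link strengths;
5. per block, the source whose neuron fired most wins and its block is copied
   across all channels; exact ties take the element-wise maximum of the tied
   sources' blocks.

The competition generalizes unchanged to k ≥ 2 sources (tri-modal fusion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.filters import sobel
from skimage.filters.rank import entropy as rank_entropy
from skimage.morphology import footprint_rectangle

from .hahn import HahnBasis, HahnParams, hahn_basis, hahn_moments_2d
from .pcnn import PCNNConfig, pcnn_fire

__all__ = [
    "BlockGrid",
    "partition_blocks",
    "reassemble_blocks",
    "potential_energy",
    "cws_saliency",
    "block_link_strength",
    "fuse_feature_maps",
]


@dataclass(frozen=True)
class BlockGrid:
    """Zero-padded tiling of a 2-D map into D×D blocks.

    ``blocks[i, j]`` is the (i, j)-th D×D tile of the padded map;
    ``pad_rows``/``pad_cols`` record the zero fill so reassembly can strip it.
    """

    blocks: np.ndarray = field(repr=False)  # (gi, gj, D, D)
    D: int
    pad_rows: int
    pad_cols: int

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.blocks.shape[:2]


def partition_blocks(map2d: np.ndarray, D: int) -> BlockGrid:
    """Split a map into D×D blocks, zero-filling bottom/right to multiples of D."""
    if not (isinstance(D, (int, np.integer)) and D >= 2):
        raise ValueError(f"block side D must be an integer >= 2, got {D!r}")
    m = np.asarray(map2d, dtype=float)
    if m.ndim != 2:
        raise ValueError(f"expected a 2-D map, got ndim={m.ndim}")
    H, W = m.shape
    pad_rows = (-H) % D
    pad_cols = (-W) % D
    padded = np.pad(m, ((0, pad_rows), (0, pad_cols)))
    gi, gj = padded.shape[0] // D, padded.shape[1] // D
    blocks = padded.reshape(gi, D, gj, D).swapaxes(1, 2)
    return BlockGrid(blocks=blocks, D=D, pad_rows=pad_rows, pad_cols=pad_cols)


def reassemble_blocks(grid: BlockGrid) -> np.ndarray:
    """Invert :func:`partition_blocks`, stripping the recorded zero fill."""
    gi, gj = grid.grid_shape
    D = grid.D
    padded = grid.blocks.swapaxes(1, 2).reshape(gi * D, gj * D)
    H = gi * D - grid.pad_rows
    W = gj * D - grid.pad_cols
    return padded[:H, :W]


def potential_energy(moments: np.ndarray) -> float:
    """Distance-weighted deviation of Hahn moments from the leading moment.

    PE = Σ_{u,v} |H_uv − H_00| / √(u² + v²)  (0-based orders), with the
    singular leading term defined as 0 — it measures the deviation of the
    leading moment from itself at zero distance.
    """
    H = np.asarray(moments, dtype=float)
    if H.ndim != 2 or H.size == 0:
        raise ValueError("moments must be a non-empty 2-D matrix")
    u = np.arange(H.shape[0])[:, None]
    v = np.arange(H.shape[1])[None, :]
    dist = np.sqrt(u**2 + v**2, dtype=float)
    with np.errstate(divide="ignore"):
        inv = np.where(dist > 0, 1.0 / np.where(dist > 0, dist, 1.0), 0.0)
    return float(np.sum(np.abs(H - H[0, 0]) * inv))


def _block_potential_energies(grid: BlockGrid, basis: HahnBasis) -> np.ndarray:
    """PE of every block of a grid (vectorized over blocks)."""
    V = basis.values
    # H_ijmn = V f_ij V^T for every block (i, j)
    moments = np.einsum("mx,ijxy,ny->ijmn", V, grid.blocks, V, optimize=True)
    D = grid.D
    u = np.arange(D)[:, None]
    v = np.arange(D)[None, :]
    dist = np.sqrt(u**2 + v**2, dtype=float)
    inv = np.zeros_like(dist)
    inv[dist > 0] = 1.0 / dist[dist > 0]
    dev = np.abs(moments - moments[:, :, :1, :1])
    return np.einsum("ijmn,mn->ij", dev, inv)


def cws_saliency(image: np.ndarray, window: int = 7, bins: int = 32,
                 smooth_sigma: float = 2.0) -> np.ndarray:
    """Complexity-weighted saliency proxy in [0, 1].

    Saliency = min–max normalized product of local intensity entropy
    (``window``×``window`` neighbourhood histogram over ``bins`` gray levels)
    and Gaussian-smoothed gradient magnitude.  Textured, high-contrast
    regions score high; flat regions (including flat background) score ~0.
    A constant image has no structure anywhere and maps to uniform zero
    saliency.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3 and img.shape[-1] == 3:
        img = img @ np.array([0.299, 0.587, 0.114])
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty single-channel image")
    lo, hi = float(img.min()), float(img.max())
    span = hi - lo if hi > lo else 1.0
    quant = np.clip(((img - lo) / span * (bins - 1)).round(), 0, bins - 1)
    ent = rank_entropy(quant.astype(np.uint8),
                       footprint_rectangle((window, window)))
    grad = gaussian_filter(sobel(img), smooth_sigma)
    sal = ent * np.abs(grad)
    rng = sal.max() - sal.min()
    if rng > 0:
        sal = (sal - sal.min()) / rng
    else:
        sal = np.zeros_like(sal)
    return sal


def block_link_strength(saliency: np.ndarray, D: int) -> np.ndarray:
    """Downsample a pixel saliency field to per-block mean link strengths."""
    grid = partition_blocks(saliency, D)
    return grid.blocks.mean(axis=(2, 3))


def _joint_minmax(arrays: list[np.ndarray]) -> list[np.ndarray]:
    """Min–max normalize a family of arrays with one shared scale."""
    lo = min(float(a.min()) for a in arrays)
    hi = max(float(a.max()) for a in arrays)
    if hi > lo:
        return [(a - lo) / (hi - lo) for a in arrays]
    return [np.zeros_like(a) for a in arrays]


def fuse_feature_maps(maps: list[np.ndarray], D: int = 8,
                      hahn_params: HahnParams | None = None,
                      pcnn_config: PCNNConfig | None = None,
                      return_details: bool = False):
    """Fuse k ≥ 2 co-registered feature stacks block by block.

    Parameters
    ----------
    maps
        Feature stacks of identical shape (C, H, W).
    D
        Block side; one PCNN neuron per D×D block.
    hahn_params, pcnn_config
        Basis and dynamics parameters; defaults are the symmetric Hahn basis
        of size D and the standard simplified-PCNN settings.
    return_details
        Also return a dict with PE maps, link strengths, firing counts and
        the per-block winner map (ties marked -1).

    Returns
    -------
    Fused stack of shape (C, H, W); every block is a verbatim copy of one
    source's block, or the element-wise maximum of the sources tied for the
    highest firing count.
    """
    if len(maps) < 2:
        raise ValueError(f"need at least 2 sources, got {len(maps)}")
    stacks = [np.asarray(m, dtype=float) for m in maps]
    shape = stacks[0].shape
    if any(s.shape != shape for s in stacks):
        raise ValueError("all feature stacks must share one shape")
    if len(shape) != 3:
        raise ValueError(f"expected (C, H, W) stacks, got shape {shape}")
    if hahn_params is None:
        hahn_params = HahnParams(N=D)
    elif hahn_params.N != D:
        raise ValueError(f"hahn_params.N={hahn_params.N} must equal D={D}")
    basis = hahn_basis(hahn_params)
    if pcnn_config is None:
        pcnn_config = PCNNConfig()

    C, H, W = shape
    activities = [np.abs(s).mean(axis=0) for s in stacks]
    grids = [partition_blocks(act, D) for act in activities]
    pe_maps = [_block_potential_energies(g, basis) for g in grids]
    stimuli = _joint_minmax(pe_maps)

    act_norm = _joint_minmax(activities)
    betas = [block_link_strength(cws_saliency(a), D) for a in act_norm]

    counts = np.stack([
        pcnn_fire(stim, beta, pcnn_config).firing_counts
        for stim, beta in zip(stimuli, betas)
    ])  # (k, gi, gj)

    best = counts.max(axis=0)
    tied = counts == best  # (k, gi, gj)
    n_winners = tied.sum(axis=0)

    pad_r, pad_c = grids[0].pad_rows, grids[0].pad_cols
    padded = [np.pad(s, ((0, 0), (0, pad_r), (0, pad_c))) for s in stacks]
    ones = np.ones((D, D), dtype=bool)
    fused_padded = np.full_like(padded[0], -np.inf)
    for k, stack in enumerate(padded):
        mask = np.kron(tied[k], ones)  # block mask -> pixel mask
        fused_padded = np.where(mask, np.maximum(fused_padded, stack),
                                fused_padded)
    fused = fused_padded[:, :H, :W]

    if return_details:
        winner = np.where(n_winners == 1, counts.argmax(axis=0), -1)
        return fused, {
            "pe_maps": pe_maps,
            "stimuli": stimuli,
            "link_strengths": betas,
            "firing_counts": counts,
            "winner": winner,
        }
    return fused
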