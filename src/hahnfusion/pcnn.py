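"""Simplified pulse-coupled neural network (PCNN) firing dynamics.

One neuron per pixel of the stimulus map.  Each iteration n:

    F_ij      = S_ij                          (feeding = external stimulus)
    L_ij(n)   = Σ_kl W_kl · Y(n-1)            (8-neighbourhood linking)
    U_ij(n)   = F_ij · (1 + β_ij · L_ij(n))   (internal activity)
    θ_ij(n)   = exp(-α_T) · θ_ij(n-1) + V_T · Y_ij(n-1)
    Y_ij(n)   = 1  if U_ij(n) ≥ θ_ij(n) else 0

The threshold decays geometrically until the neuron fires, then jumps by V_T;
stronger stimuli fire earlier and more often, and linking lets firing spread
through neighbourhoods of similar activity.  The update is fully synchronous:
all of iteration n reads Y from iteration n-1, with Y(0) = 0 and θ(0) = θ0,
so the result is independent of traversal order.  The per-neuron cumulative
firing count over `n_iter` iterations is the "firing times" record used to
arbitrate between sources in fusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve

__all__ = ["PCNNConfig", "PCNNResult", "pcnn_fire", "NEVER_FIRED"]

#: sentinel in ``first_fire`` for neurons that never pulsed
NEVER_FIRED = -1

#: inverse-Euclidean-distance linking kernel over the 8-neighbourhood
_DEFAULT_W = np.array([
    [1 / np.sqrt(2), 1.0, 1 / np.sqrt(2)],
    [1.0, 0.0, 1.0],
    [1 / np.sqrt(2), 1.0, 1 / np.sqrt(2)],
])


def _default_w() -> np.ndarray:
    return _DEFAULT_W.copy()


@dataclass(frozen=True)
class PCNNConfig:
    """Threshold and linking parameters of the simplified PCNN.

    alpha_T : threshold decay exponent (decay factor exp(-alpha_T) per step)
    V_T     : threshold jump after a pulse; large values enforce a long
              refractory gap so each reset yields a single pulse
    theta0  : initial threshold, shared by all neurons
    n_iter  : number of synchronous iterations
    W       : 3x3 linking kernel, zero centre (a neuron does not link to
              itself)
    """

    alpha_T: float = 0.2
    V_T: float = 20.0
    theta0: float = 1.0
    n_iter: int = 200
    W: np.ndarray = field(default_factory=_default_w, repr=False)

    def __post_init__(self) -> None:
        for name in ("alpha_T", "V_T", "theta0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if not (isinstance(self.n_iter, (int, np.integer)) and self.n_iter >= 1):
            raise ValueError(f"n_iter must be a positive integer, got {self.n_iter!r}")
        W = np.asarray(self.W, dtype=float)
        if W.shape != (3, 3):
            raise ValueError(f"W must be 3x3, got shape {W.shape}")
        if W[1, 1] != 0:
            raise ValueError("W must have a zero centre (no self-linking)")
        object.__setattr__(self, "W", W)


@dataclass(frozen=True)
class PCNNResult:
    """Per-neuron firing record over the run."""

    firing_counts: np.ndarray
    first_fire: np.ndarray


def pcnn_fire(stimulus: np.ndarray, link_strength: np.ndarray | float,
              config: PCNNConfig | None = None) -> PCNNResult:
    """Run the simplified PCNN and return firing counts and first-fire times.

    Parameters
    ----------
    stimulus
        Non-negative feeding input S, typically normalized to [0, 1].
    link_strength
        Per-neuron linking coefficient β (scalar broadcasts).
    config
        Dynamics parameters; defaults per :class:`PCNNConfig`.
    """
    if config is None:
        config = PCNNConfig()
    S = np.asarray(stimulus, dtype=float)
    beta = np.broadcast_to(np.asarray(link_strength, dtype=float), S.shape)
    if np.asarray(link_strength).ndim and np.asarray(link_strength).shape != S.shape:
        raise ValueError(
            f"link_strength shape {np.asarray(link_strength).shape} "
            f"!= stimulus shape {S.shape}")
    if not np.all(np.isfinite(S)):
        raise ValueError("stimulus must be finite")
    if np.any(S < 0):
        raise ValueError("stimulus must be non-negative")

    decay = np.exp(-config.alpha_T)
    theta = np.full(S.shape, config.theta0, dtype=float)
    Y = np.zeros(S.shape, dtype=float)
    counts = np.zeros(S.shape, dtype=np.int64)
    first = np.full(S.shape, NEVER_FIRED, dtype=np.int64)

    for n in range(1, config.n_iter + 1):
        L = convolve(Y, config.W, mode="constant", cval=0.0)
        U = S * (1.0 + beta * L)
        theta = decay * theta + config.V_T * Y
        Y = (U >= theta).astype(float)
        fired = Y > 0
        counts[fired] += 1
        first[fired & (first == NEVER_FIRED)] = n

    return PCNNResult(firing_counts=counts, first_fire=first)
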