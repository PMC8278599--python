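"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive results by the most literal route
possible (explicit loops, per-iteration simulation) so the vectorized
production code is checked against something it shares no code with.
"""

from __future__ import annotations

import numpy as np
import pytest

import hahnfusion as hf
from hahnfusion.image_io import to_network_input

# ---------------------------------------------------------------------------
# oracle helpers
# ---------------------------------------------------------------------------


def pcnn_oracle(stimulus, beta, config):
    """Literal per-iteration simulation of the simplified PCNN dynamics.

    Scalar Python loops over neurons and iterations; zero-padded
    8-neighbourhood linking; synchronous update.
    """
    S = np.asarray(stimulus, dtype=float)
    B = np.broadcast_to(np.asarray(beta, dtype=float), S.shape)
    H, W = S.shape
    theta = np.full((H, W), config.theta0)
    Y = np.zeros((H, W))
    counts = np.zeros((H, W), dtype=int)
    first = np.full((H, W), hf.NEVER_FIRED, dtype=int)
    decay = np.exp(-config.alpha_T)
    for n in range(1, config.n_iter + 1):
        L = np.zeros((H, W))
        for i in range(H):
            for j in range(W):
                acc = 0.0
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ii, jj = i + di, j + dj
                        if (di or dj) and 0 <= ii < H and 0 <= jj < W:
                            acc += config.W[di + 1, dj + 1] * Y[ii, jj]
                L[i, j] = acc
        U = S * (1 + B * L)
        theta = decay * theta + config.V_T * Y
        Y = (U >= theta).astype(float)
        for i in range(H):
            for j in range(W):
                if Y[i, j]:
                    counts[i, j] += 1
                    if first[i, j] == hf.NEVER_FIRED:
                        first[i, j] = n
    return counts, first


def hahn_moments_bruteforce(block, basis):
    """Quadruple-loop evaluation of the 2-D Hahn moment sum."""
    N = basis.N
    V = basis.values
    H = np.zeros((N, N))
    for m in range(N):
        for n in range(N):
            s = 0.0
            for x in range(N):
                for y in range(N):
                    s += V[m, x] * V[n, y] * block[x, y]
            H[m, n] = s
    return H


def potential_energy_bruteforce(H):
    """Direct double-sum of the distance-weighted moment deviation."""
    total = 0.0
    for u in range(H.shape[0]):
        for v in range(H.shape[1]):
            if u == 0 and v == 0:
                continue
            total += abs(H[u, v] - H[0, 0]) / np.sqrt(u**2 + v**2)
    return total


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom_pair():
    return hf.make_pair(size=64, seed=11)


#: the desk-scale training task: 64 brain phantoms (32 structural grayscale
#: replicated to RGB + 32 functional color), 64x64 px, 50 epochs, seed 0
DESK_TRAIN_SEED = 0
DESK_DATA_SEED = 7
DESK_EPOCHS = 50
DESK_N_PAIRS = 32
DESK_SIZE = 64


def desk_training_images():
    pairs = hf.make_dataset(DESK_N_PAIRS, size=DESK_SIZE, seed=DESK_DATA_SEED)
    return ([to_network_input(p.structural) for p in pairs]
            + [p.functional for p in pairs])


@pytest.fixture(scope="session")
def desk_trained():
    """Train the autoencoder once per session at the desk-scale settings."""
    net = hf.build_network(DESK_TRAIN_SEED)
    net, history = hf.train_autoencoder(
        net, desk_training_images(),
        hf.TrainConfig(epochs=DESK_EPOCHS, batch_size=8,
                       seed=DESK_TRAIN_SEED))
    return net, history
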