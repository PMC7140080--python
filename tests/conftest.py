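"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np
import pytest

from scaffoldomics.synthetic import (CountsSpec, GlassLayerSpec, NetworkSpec,
                                     StackSpec, simulate_counts,
                                     simulate_networks, simulate_stack)


# ---------------------------------------------------------------------------
# Oracles (independent of the implementation paths they check)
# ---------------------------------------------------------------------------

def brute_force_otsu(values: np.ndarray) -> float:
    """Exhaustive between-class-variance maximization over 8-bit levels;
    ties resolved toward the lowest threshold; foreground = value > t."""
    v = np.asarray(values).ravel().astype(float)
    best_t, best_var = None, -1.0
    for t in range(255):
        bg = v[v <= t]
        fg = v[v > t]
        if bg.size == 0 or fg.size == 0:
            continue
        w0, w1 = bg.size / v.size, fg.size / v.size
        var = w0 * w1 * (bg.mean() - fg.mean()) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return float(best_t)


def flood_fill_label(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Brute-force BFS connected-component labeling of a 3D binary mask."""
    mask = np.asarray(mask).astype(bool)
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    if connectivity == 6:
        offsets = [o for o in offsets if sum(map(abs, o)) == 1]
    elif connectivity == 18:
        offsets = [o for o in offsets if sum(map(abs, o)) <= 2]
    labels = np.zeros(mask.shape, dtype=int)
    next_label = 0
    for idx in zip(*np.nonzero(mask)):
        if labels[idx]:
            continue
        next_label += 1
        queue = deque([idx])
        labels[idx] = next_label
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in offsets:
                nz, ny, nx_ = z + dz, y + dy, x + dx
                if (0 <= nz < mask.shape[0] and 0 <= ny < mask.shape[1]
                        and 0 <= nx_ < mask.shape[2]
                        and mask[nz, ny, nx_] and not labels[nz, ny, nx_]):
                    labels[nz, ny, nx_] = next_label
                    queue.append((nz, ny, nx_))
    return labels


def exact_hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by exact combinatorial enumeration (rational arithmetic)."""
    total = math.comb(N, n)
    hits = sum(math.comb(K, j) * math.comb(N - K, n - j)
               for j in range(k, min(K, n) + 1))
    return hits / total


def exact_ranksum_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p by enumerating every assignment of pooled
    ranks to group a (tie-free data only)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    assert np.unique(pooled).size == pooled.size, "oracle needs tie-free data"
    ranks = pooled.argsort().argsort() + 1.0
    na = a.size
    obs_u = ranks[:na].sum() - na * (na + 1) / 2
    us = np.array([
        ranks[list(c)].sum() - na * (na + 1) / 2
        for c in itertools.combinations(range(pooled.size), na)
    ])
    ge = np.mean(us >= obs_u)
    le = np.mean(us <= obs_u)
    return min(1.0, 2.0 * min(ge, le))


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def glass_stack():
    """Stack with a glass layer strictly above the brightest scaffold slice."""
    spec = StackSpec(seed=7, glass_layer=GlassLayerSpec())
    stack, truth = simulate_stack(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def clean_stack():
    """Noise-free stack of well-separated singletons only."""
    spec = StackSpec(seed=3, n_singletons=8, n_clusters=0, noise_sd=0.0,
                     background=0.0, glass_layer=None)
    stack, truth = simulate_stack(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def counts_fixture():
    spec = CountsSpec(seed=11, max_molecules_tail=0.05)
    adata, truth = simulate_counts(spec)
    return spec, adata, truth


@pytest.fixture(scope="session")
def network_fixture():
    spec = NetworkSpec(seed=5)
    edges, sets, degt, truth = simulate_networks(spec)
    return spec, edges, sets, degt, truth
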