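"""Degree-preserving null networks and small-world normalization.

Small-worldness is judged by comparing a network's clustering and path
length with those of an ensemble of matched random networks (default 100):

    gamma = Cp_real / <Cp_null>,  lambda = Lp_real / <Lp_null>,
    sigma = gamma / lambda

A small-world network keeps near-random path lengths while being far more
clustered, giving sigma > 1.  Nulls are built by Maslov-Sneppen double-edge
swaps with the weights travelling on the edges, so both the degree sequence
and the weight multiset of the source network are preserved exactly.

All randomness flows from a single master seed; per-null generators are
spawned with a counter scheme (``SeedSequence(master, null_index)``) so the
ensemble is reproducible and order-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .construction import WeightedNetwork
from .metrics import (
    GlobalMetrics,
    characteristic_path_length,
    clustering_coefficient,
    global_metrics,
    shortest_paths,
)

__all__ = ["NullEnsemble", "rewire", "small_worldness"]

DEFAULT_N_NULLS = 100
DEFAULT_SWAPS_PER_EDGE = 10


@dataclass
class NullEnsemble:
    """Cp and Lp of each degree-preserving null network."""

    cp_values: np.ndarray
    lp_values: np.ndarray
    seed: int
    n_nulls: int


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def rewire(
    net: WeightedNetwork,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
    seed: int | np.random.Generator | None = None,
) -> WeightedNetwork:
    """Randomize topology by double-edge swaps, carrying weights along.

    Repeatedly picks two edges (a, b) and (c, d) and replaces them with
    (a, d) and (c, b) unless that would create a self-loop or a duplicate
    edge.  Each edge keeps its weight through the swap, so the degree
    sequence and the multiset of edge weights are construction invariants.
    Attempts ``swaps_per_edge * n_edges`` successful swaps (with a bounded
    number of tries); a degenerate network where no legal swap exists is
    returned unchanged with a warning.
    """
    rng = _rng(seed)
    n = net.n_nodes
    iu, ju = np.nonzero(np.triu(net.weights, 1))
    m = iu.size
    if m < 2:
        raise ValueError("rewiring requires at least 2 edges")
    u = iu.copy()
    v = ju.copy()
    wts = net.weights[iu, ju].copy()
    present = set((int(a) * n + int(b)) for a, b in zip(u, v))

    target = swaps_per_edge * m
    max_tries = 20 * target
    done = 0
    tries = 0
    # draw candidate indices and orientation bits in blocks to keep the
    # per-attempt cost low
    block = 4096
    buf_e = rng.integers(0, m, size=(0, 2))
    buf_o = rng.integers(0, 2, size=0)
    ptr = block
    while done < target and tries < max_tries:
        if ptr >= buf_o.size:
            buf_e = rng.integers(0, m, size=(block, 2))
            buf_o = rng.integers(0, 2, size=block)
            ptr = 0
        e1, e2 = buf_e[ptr]
        flip = buf_o[ptr]
        ptr += 1
        tries += 1
        if e1 == e2:
            continue
        a, b = int(u[e1]), int(v[e1])
        c, d = int(u[e2]), int(v[e2])
        if flip:
            c, d = d, c
        # proposed replacement: (a, d) and (c, b)
        if a == d or c == b:
            continue
        p, q = (a, d) if a < d else (d, a)
        r, s = (c, b) if c < b else (b, c)
        k1, k2 = p * n + q, r * n + s
        if k1 == k2 or k1 in present or k2 in present:
            continue
        present.discard(min(a, b) * n + max(a, b))
        present.discard(min(c, d) * n + max(c, d))
        present.add(k1)
        present.add(k2)
        u[e1], v[e1] = p, q
        u[e2], v[e2] = r, s
        done += 1
    if done == 0:
        warnings.warn("no legal double-edge swap found; returning network unchanged", stacklevel=2)
        return net
    w = np.zeros((n, n))
    w[u, v] = wts
    w = w + w.T
    return WeightedNetwork(weights=w, atlas=net.atlas)


def null_ensemble(
    net: WeightedNetwork,
    n_nulls: int = DEFAULT_N_NULLS,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
    seed: int = 0,
) -> NullEnsemble:
    """Cp and Lp over ``n_nulls`` independent degree-preserving nulls."""
    if n_nulls < 1:
        raise ValueError("n_nulls must be >= 1")
    cps = np.empty(n_nulls)
    lps = np.empty(n_nulls)
    for k in range(n_nulls):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(k,)))
        null = rewire(net, swaps_per_edge=swaps_per_edge, seed=rng)
        cps[k] = clustering_coefficient(null)
        lps[k] = characteristic_path_length(shortest_paths(null))
    return NullEnsemble(cp_values=cps, lp_values=lps, seed=seed, n_nulls=n_nulls)


def small_worldness(
    net: WeightedNetwork,
    n_nulls: int = DEFAULT_N_NULLS,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
    seed: int = 0,
) -> GlobalMetrics:
    """Global metrics with the small-world ratios gamma, lambda, sigma filled.

    Deterministic for a fixed seed.  Raises if the null means degenerate to
    zero (ratio undefined).
    """
    gm = global_metrics(net)
    ens = null_ensemble(net, n_nulls=n_nulls, swaps_per_edge=swaps_per_edge, seed=seed)
    cp_rand = float(np.mean(ens.cp_values))
    lp_rand = float(np.mean(ens.lp_values))
    if cp_rand == 0 or lp_rand == 0 or not np.isfinite(lp_rand):
        raise ValueError(
            f"undefined small-world ratio: mean null Cp={cp_rand}, Lp={lp_rand}"
        )
    gm.gamma = gm.Cp / cp_rand
    gm.lambda_ = gm.Lp / lp_rand
    gm.sigma = gm.gamma / gm.lambda_
    return gm
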