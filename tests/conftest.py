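"""Shared fixtures and independent brute-force oracles.

The oracles re-derive path lengths, betweenness, clustering and efficiency
by exhaustive enumeration on small graphs, independently of the package's
scipy/networkx-based implementations, so metric tests compare two unrelated
routes to the same quantity.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from wmnet.atlas import RegionAtlas
from wmnet.construction import SubjectConnectivity, WeightedNetwork

REL_TIE_TOL = 1e-12


def small_atlas(n: int) -> RegionAtlas:
    return RegionAtlas(labels=tuple(f"N{i}" for i in range(n)))


def network_from_weights(w: np.ndarray) -> WeightedNetwork:
    w = np.asarray(w, dtype=float)
    return WeightedNetwork(weights=w, atlas=small_atlas(w.shape[0]))


def random_weighted_network(rng: np.random.Generator, n: int, p: float = 0.5) -> WeightedNetwork:
    """A random symmetric weighted graph with continuous weights."""
    mask = np.triu(rng.random((n, n)) < p, 1)
    w = np.where(mask, rng.uniform(0.2, 3.0, (n, n)), 0.0)
    w = np.triu(w, 1)
    return network_from_weights(w + w.T)


# ---------------------------------------------------------------- oracles


def enumerate_simple_paths(w: np.ndarray, s: int, t: int):
    """All simple s-t paths with their 1/weight lengths (exhaustive DFS)."""
    n = w.shape[0]
    out = []

    def dfs(node, visited, length, path):
        if node == t:
            out.append((length, tuple(path)))
            return
        for nxt in range(n):
            if w[node, nxt] > 0 and nxt not in visited:
                dfs(nxt, visited | {nxt}, length + 1.0 / w[node, nxt], path + [nxt])

    dfs(s, {s}, 0.0, [s])
    return out


def brute_force_path_matrix(w: np.ndarray) -> np.ndarray:
    """Shortest path lengths by exhaustive path enumeration."""
    n = w.shape[0]
    L = np.full((n, n), np.inf)
    np.fill_diagonal(L, 0.0)
    for s in range(n):
        for t in range(s + 1, n):
            paths = enumerate_simple_paths(w, s, t)
            if paths:
                best = min(p[0] for p in paths)
                L[s, t] = L[t, s] = best
    return L


def brute_force_betweenness(w: np.ndarray, tol: float = REL_TIE_TOL) -> np.ndarray:
    """Unnormalized betweenness over unordered pairs by path enumeration.

    Minimal paths are those within relative tolerance ``tol`` of the best
    length; each interior node of a minimal path gets 1/(number of minimal
    paths) per pair.
    """
    n = w.shape[0]
    b = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = enumerate_simple_paths(w, s, t)
            if not paths:
                continue
            best = min(p[0] for p in paths)
            minimal = [p for length, p in paths if length <= best * (1 + tol)]
            for path in minimal:
                for node in path[1:-1]:
                    b[node] += 1.0 / len(minimal)
    return b


def brute_force_clustering(w: np.ndarray) -> float:
    """Mean binary clustering by counting connected neighbor pairs."""
    a = w > 0
    n = w.shape[0]
    ccs = []
    for i in range(n):
        nb = np.nonzero(a[i])[0]
        d = len(nb)
        if d < 2:
            ccs.append(0.0)
            continue
        e = sum(1 for j, k in itertools.combinations(nb, 2) if a[j, k])
        ccs.append(e / (d * (d - 1) / 2))
    return float(np.mean(ccs))


def brute_force_global_efficiency(w: np.ndarray) -> float:
    L = brute_force_path_matrix(w)
    n = w.shape[0]
    inv = np.where(np.isfinite(L) & (L > 0), 1.0 / np.where(L > 0, L, 1.0), 0.0)
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def brute_force_local_efficiency(w: np.ndarray) -> float:
    n = w.shape[0]
    effs = []
    for i in range(n):
        nb = np.nonzero(w[i])[0]
        if len(nb) < 2:
            effs.append(0.0)
            continue
        effs.append(brute_force_global_efficiency(w[np.ix_(nb, nb)]))
    return float(np.mean(effs))


# --------------------------------------------------------------- fixtures


@pytest.fixture
def toy_subject() -> SubjectConnectivity:
    """A 4-region subject with hand-set FN/FA/volumes."""
    fn = np.array(
        [
            [0, 4, 2, 10],
            [4, 0, 5, 0],
            [2, 5, 0, 3],
            [10, 0, 3, 0],
        ],
        dtype=float,
    )
    fa = np.array(
        [
            [0, 0.5, 0.4, 0.6],
            [0.5, 0, 0.3, 0],
            [0.4, 0.3, 0, 0.45],
            [0.6, 0, 0.45, 0],
        ]
    )
    vols = np.array([2000.0, 3000.0, 2500.0, 1500.0])
    return SubjectConnectivity(
        subject_id="toy", group="NC", fn=fn, fa=fa, volumes=vols,
        age=60.0, sex="F", education=12.0,
        scores={"MMSE": 28.0, "MoCA": 26.0, "AVLT_I": 9.0, "AVLT_D": 10.0, "AVLT_R": 12.0},
        atlas=small_atlas(4),
    )


@pytest.fixture(scope="session")
def fast_cohort_spec():
    """A reduced synthetic cohort for pipeline-level tests."""
    from wmnet.cohort import CohortSpec

    return CohortSpec(
        n_per_group={"NC": 6, "SCD": 4, "aMCI": 6},
        master_seed=7,
    )
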