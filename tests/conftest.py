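"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from eegfc.recording import FrequencyBand, MultichannelRecording


@pytest.fixture
def high_alpha() -> FrequencyBand:
    return FrequencyBand("high_alpha", 9.0, 13.0)


@pytest.fixture
def low_alpha() -> FrequencyBand:
    return FrequencyBand("low_alpha", 6.0, 9.0)


def make_tone(freq: float, fs: float, duration: float, amplitude: float = 1.0,
              phase: float = 0.0, n_channels: int = 1) -> MultichannelRecording:
    t = np.arange(int(round(duration * fs))) / fs
    x = amplitude * np.cos(2 * np.pi * freq * t + phase)
    data = np.tile(x[:, None], (1, n_channels))
    return MultichannelRecording(data, fs, [str(i + 1) for i in range(n_channels)])


def fft_peak_amplitude(x: np.ndarray, fs: float, freq: float) -> float:
    """Amplitude of the component nearest ``freq`` via the rectangular-window FFT."""
    x = np.asarray(x, dtype=float)
    spec = np.abs(np.fft.rfft(x)) / len(x) * 2.0
    freqs = np.fft.rfftfreq(len(x), 1.0 / fs)
    return float(spec[np.argmin(np.abs(freqs - freq))])


# ---------------------------------------------------------------------------
# tree oracles (pure-python path enumeration; independent of networkx)

def random_tree_edges(n: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Uniform random labelled tree on n nodes via Pruefer-sequence decoding."""
    if n == 2:
        return [(0, 1)]
    prufer = list(rng.integers(0, n, size=n - 2))
    degree = [1] * n
    for v in prufer:
        degree[v] += 1
    edges = []
    leaves = sorted(i for i in range(n) if degree[i] == 1)
    for v in prufer:
        leaf = leaves.pop(0)
        edges.append((leaf, v))
        degree[v] -= 1
        if degree[v] == 1:
            # insert keeping the leaf pool sorted
            import bisect

            bisect.insort(leaves, v)
    edges.append((leaves[0], leaves[1]))
    return edges


def tree_paths(edges: list[tuple[int, int]], n: int) -> dict[tuple[int, int], list[int]]:
    """Unique node path for every unordered pair, by breadth-first search."""
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    paths = {}
    for src in range(n):
        parent = {src: None}
        queue = [src]
        while queue:
            v = queue.pop(0)
            for w in adj[v]:
                if w not in parent:
                    parent[w] = v
                    queue.append(w)
        for dst in range(src + 1, n):
            path = [dst]
            while path[-1] != src:
                path.append(parent[path[-1]])
            paths[(src, dst)] = path[::-1]
    return paths


def oracle_tree_metrics(edges: list[tuple[int, int]], n: int) -> dict:
    """All MST topology metrics from explicit path enumeration."""
    paths = tree_paths(edges, n)
    degree = np.zeros(n)
    for a, b in edges:
        degree[a] += 1
        degree[b] += 1
    ecc = np.zeros(n, dtype=int)
    for (a, b), path in paths.items():
        length = len(path) - 1
        ecc[a] = max(ecc[a], length)
        ecc[b] = max(ecc[b], length)
    raw_bc = np.zeros(n)
    for path in paths.values():
        for v in path[1:-1]:
            raw_bc[v] += 1
    norm = (n - 1) * (n - 2) / 2
    bc = raw_bc / norm
    leaves = int((degree == 1).sum())
    m = n - 1
    xs, ys = [], []
    for a, b in edges:
        xs.extend((degree[a], degree[b]))
        ys.extend((degree[b], degree[a]))
    xs, ys = np.array(xs), np.array(ys)
    if xs.std() == 0 or ys.std() == 0:
        degree_corr = float("nan")
    else:
        degree_corr = float(np.corrcoef(xs, ys)[0, 1])
    return {
        "leaf_fraction": leaves / n,
        "diameter": int(ecc.max()),
        "eccentricity": ecc,
        "eccentricity_mean": float(ecc.mean()),
        "betweenness": bc,
        "betweenness_mean": float(bc.mean()),
        "betweenness_max": float(bc.max()),
        "tree_hierarchy": leaves / (2 * m * bc.max()),
        "degree_correlation": degree_corr,
        "kappa": float((degree**2).mean() / degree.mean()),
        "raw_betweenness": raw_bc,
        "paths": paths,
    }


def oracle_best_spanning_tree_weight(values: np.ndarray) -> float:
    """Maximum total PLI over all spanning trees, by exhaustive enumeration."""
    n = values.shape[0]
    all_edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = -np.inf
    for subset in itertools.combinations(all_edges, n - 1):
        parent = list(range(n))

        def find(v):
            while parent[v] != v:
                parent[v] = parent[parent[v]]
                v = parent[v]
            return v

        acyclic = True
        for a, b in subset:
            ra, rb = find(a), find(b)
            if ra == rb:
                acyclic = False
                break
            parent[ra] = rb
        if acyclic:
            best = max(best, sum(values[a, b] for a, b in subset))
    return best
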