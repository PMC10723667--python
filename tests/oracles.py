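"""Independent brute-force oracles used only by the tests.

Pure-python set enumeration over row-sets and a plain dense eigensolver —
deliberately sharing no code with the package's vectorised implementations.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def rows_as_sets(flags, names) -> list[set[str]]:
    return [{names[j] for j in range(len(names)) if row[j]} for row in flags]


def carriers(rows: list[set[str]], disease: str) -> set[int]:
    return {i for i, r in enumerate(rows) if disease in r}


def prevalence(rows: list[set[str]], disease: str) -> float:
    return len(carriers(rows, disease)) / len(rows)


def exact_profile_edges(rows: list[set[str]]) -> dict[tuple[str, ...], dict]:
    """Unique exact profiles of size >= 2 with n_exact and n_all counts."""
    out: dict[tuple[str, ...], dict] = {}
    profiles = {tuple(sorted(r)) for r in rows if len(r) >= 2}
    for prof in profiles:
        members = set(prof)
        n_exact = sum(1 for r in rows if r == members)
        n_all = sum(1 for r in rows if members <= r)
        out[prof] = {"n_exact": n_exact, "n_all": n_all}
    return out


def overlap(rows: list[set[str]], members) -> float:
    """Generalised overlap coefficient by direct set arithmetic."""
    sets = [carriers(rows, m) for m in members]
    inter = set.intersection(*sets)
    return len(inter) / min(len(s) for s in sets)


def standardized_rate_slow(counts, ages, lowers, weights) -> float:
    """Direct standardisation with an explicit per-band loop."""
    lowers = list(lowers)
    bands = {}
    for c, a in zip(counts, ages):
        b = max(i for i, lo in enumerate(lowers) if a >= lo)
        bands.setdefault(b, []).append(c)
    wsum = sum(weights[b] for b in bands)
    return 100_000.0 * sum(
        weights[b] * (sum(cs) / len(cs)) for b, cs in bands.items()
    ) / wsum


def leading_eigenvector(A: np.ndarray) -> np.ndarray:
    """Max-normalised Perron vector via numpy's dense symmetric solver."""
    w, V = np.linalg.eigh(A)
    v = V[:, int(np.argmax(w))]
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    return v / v.max()


def random_toy_cohort(rng: np.random.Generator, max_persons=50, max_diseases=6):
    """Random small cohort guaranteed to contain >= 1 multimorbid person."""
    import morbigraph as mg

    while True:
        n = int(rng.integers(5, max_persons + 1))
        d = int(rng.integers(2, max_diseases + 1))
        names = tuple(chr(ord("A") + j) for j in range(d))
        flags = (rng.random((n, d)) < rng.uniform(0.15, 0.6)).astype(np.int8)
        if (flags.sum(axis=1) >= 2).any() and (flags.sum(axis=0) > 0).all():
            break
    ages = rng.integers(20, 95, size=n)
    outp = rng.poisson(2.0, size=n)
    inp = rng.poisson(0.5, size=n)
    cat = mg.DiseaseCatalogue(names)
    return mg.Cohort(flags, ages, outp, inp, cat), names


def random_weighted_hypergraph(rng: np.random.Generator, max_nodes=12, max_edges=30):
    """Random hypergraph with positive weights and a non-trivial dual."""
    import morbigraph as mg

    while True:
        d = int(rng.integers(3, max_nodes + 1))
        names = tuple(f"D{j:02d}" for j in range(d))
        n_edges = int(rng.integers(2, max_edges + 1))
        seen = set()
        for _ in range(5 * n_edges):
            size = int(rng.integers(2, min(d, 5) + 1))
            members = tuple(sorted(rng.choice(d, size=size, replace=False)))
            seen.add(members)
            if len(seen) == n_edges:
                break
        edges = tuple(mg.DiseaseSet(tuple(names[j] for j in m)) for m in sorted(seen))
        if len(edges) < 2:
            continue
        node_w = rng.uniform(0.05, 1.0, size=d)
        edge_w = rng.uniform(0.05, 1.0, size=len(edges))
        n_exact = np.ones(len(edges), dtype=np.int64)
        h = mg.WeightedHypergraph(mg.DiseaseCatalogue(names), edges, node_w,
                                  edge_w, n_exact, n_exact, "prevalence_overlap")
        # need a positive off-diagonal entry (some pair of edges sharing a node)
        try:
            mg.dual_adjacency(h)
        except ValueError:
            continue
        return h
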