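"""Independent oracles and random-fixture builders shared across tests.

The oracles are deliberately naive — explicit per-position loops and
all-pairs sorts — so they stay independent of the vectorized code paths
they check.
"""

from __future__ import annotations

import numpy as np

from mbsubtype import ExpressionMatrix, GeneSetCollection


def naive_enrichment_score(
    gene_order: list[str],
    rank_values: np.ndarray,
    gene_set,
    alpha: float,
    es_mode: str = "integrated",
) -> float:
    """Per-position running-sum enrichment score, one Python loop step per gene."""
    members = set(gene_set)
    flags = [g in members for g in gene_order]
    n_genes = len(flags)
    n_in = sum(flags)
    assert 0 < n_in < n_genes
    denom = sum(float(r) ** alpha for r, f in zip(rank_values, flags) if f)
    run_in = 0.0
    run_out = 0
    total = 0.0
    best = 0.0
    for i in range(n_genes):
        if flags[i]:
            run_in += float(rank_values[i]) ** alpha
        else:
            run_out += 1
        diff = run_in / denom - run_out / (n_genes - n_in)
        total += diff
        if abs(diff) > abs(best):
            best = diff
    return total if es_mode == "integrated" else best


def naive_rank_descending(values) -> list[float]:
    """Tie-averaged descending ranks via an explicit sort (rank 1 = largest)."""
    values = list(map(float, values))
    order = sorted(range(len(values)), key=lambda i: -values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def brute_knn_neighbors(
    test_vec: np.ndarray,
    rank_matrix: np.ndarray,
    sample_ids: list[str],
    k: int,
    metric: str = "euclidean",
) -> list[tuple[str, float]]:
    """All-pairs distance sort with (distance, sample_id) ordering."""
    dists = []
    for sid, row in zip(sample_ids, rank_matrix):
        diff = np.asarray(row, dtype=float) - np.asarray(test_vec, dtype=float)
        if metric == "euclidean":
            d = float(np.sqrt((diff ** 2).sum()))
        else:
            d = float(np.abs(diff).sum())
        dists.append((d, sid))
    dists.sort()
    return [(sid, d) for d, sid in dists[:k]]


def random_expression(
    rng: np.random.Generator, n_genes: int, n_samples: int
) -> ExpressionMatrix:
    genes = [f"g{i:04d}" for i in range(n_genes)]
    samples = [f"s{j:03d}" for j in range(n_samples)]
    return ExpressionMatrix(genes, samples, rng.normal(size=(n_genes, n_samples)))


def random_collection(
    rng: np.random.Generator,
    gene_pool: list[str],
    n_sets: int,
    min_size: int = 5,
    max_size: int = 30,
    species: str = "human",
) -> GeneSetCollection:
    sets = {}
    for i in range(n_sets):
        size = int(rng.integers(min_size, max_size + 1))
        members = list(rng.choice(gene_pool, size=min(size, len(gene_pool) - 1),
                                  replace=False))
        sets[f"SET{i:03d}"] = (f"random set {i}", members)
    return GeneSetCollection(species=species, sets=sets)
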