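"""Condition-specific GO–GO networks from a co-expressed interaction network.

A link between two GO biological-process terms is counted once for every
CEIN edge {g1, g2} and every ordered term combination (X, Y) with
X ∈ terms(g1), Y ∈ terms(g2); the pair key is unordered, so an edge whose
endpoints are each annotated to both terms contributes twice to {X, Y} and
a same-term edge contributes once to {X, X}. Significance uses the same
gene-name-shuffling permutation null as the temporal networks, but the
permutation universe is the CEIN's own node set (genes carrying at least
one co-expression link).
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .temporal import GoGoCount, PermutationResult
from .types import FirstDayLabeling, GoAnnotation, GoGoNetwork

__all__ = [
    "count_condition_gogo",
    "permute_condition_pvalues",
    "build_condition_network",
]


class _IndexedCein:
    """Integer-indexed CEIN edges with per-gene term tuples."""

    def __init__(
        self, cein_edges: Iterable[tuple[str, str]], annot: GoAnnotation
    ) -> None:
        edges = [tuple(sorted(e)) for e in cein_edges]
        self.genes = sorted({g for e in edges for g in e})
        index = {g: i for i, g in enumerate(self.genes)}
        self.terms: list[tuple[str, ...]] = [
            tuple(sorted(annot.terms(g))) for g in self.genes
        ]
        self.e0 = np.array([index[a] for a, _ in edges], dtype=np.int64)
        self.e1 = np.array([index[b] for _, b in edges], dtype=np.int64)
        self.n = len(self.genes)

    def count(self, perm: np.ndarray | None = None) -> dict[tuple[str, str], int]:
        g1 = self.e0 if perm is None else perm[self.e0]
        g2 = self.e1 if perm is None else perm[self.e1]
        counts: dict[tuple[str, str], int] = {}
        terms = self.terms
        for a, b in zip(g1, g2):
            for x in terms[a]:
                for y in terms[b]:
                    key = (x, y) if x <= y else (y, x)
                    counts[key] = counts.get(key, 0) + 1
        return counts


def count_condition_gogo(
    cein_edges: Iterable[tuple[str, str]], annot: GoAnnotation
) -> GoGoCount:
    """Count CEIN edges linking GO terms (undirected; self-pairs retained)."""
    indexed = _IndexedCein(cein_edges, annot)
    return GoGoCount(day_pair=None, counts=indexed.count())


def permute_condition_pvalues(
    cein_edges: Iterable[tuple[str, str]],
    annot: GoAnnotation,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> PermutationResult:
    """Permutation p-values for the observed condition GO–GO link counts.

    Each round shuffles gene names uniformly over the CEIN's node positions
    (topology fixed, annotations travelling with the names); one-sided
    p = (1 + r) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    indexed = _IndexedCein(cein_edges, annot)
    observed = indexed.count()
    exceed = {pair: 0 for pair in observed}
    rng = np.random.default_rng(seed)
    for _ in range(n_perm):
        perm = rng.permutation(indexed.n)
        counts = indexed.count(perm)
        for pair, obs in observed.items():
            if counts.get(pair, 0) >= obs:
                exceed[pair] += 1
    p_values = {pair: (1 + r) / (1 + n_perm) for pair, r in exceed.items()}
    return PermutationResult(
        n_perm=n_perm, p_values=p_values, seed=seed, observed=observed
    )


def build_condition_network(
    cein_edges: Iterable[tuple[str, str]],
    annot: GoAnnotation,
    labeling: FirstDayLabeling | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
    p_cutoff: float = 0.01,
    condition: str = "coexpr",
) -> GoGoNetwork:
    """Assemble the undirected GO–GO network for one condition's CEIN.

    Edges with p < ``p_cutoff`` are retained with ``link_count``,
    ``p_value``, ``neg_log10_p`` and the export style attribute ``coexpr``.
    With a labeling, nodes carry ``de_fraction`` over the CEIN's genes.
    """
    cein_edges = [tuple(sorted(e)) for e in cein_edges]
    graph = nx.Graph()
    if cein_edges:
        result = permute_condition_pvalues(
            cein_edges, annot, n_perm=n_perm, seed=seed
        )
        for pair in sorted(result.p_values):
            p = result.p_values[pair]
            if p < p_cutoff:
                x, y = pair
                graph.add_edge(
                    x,
                    y,
                    condition=condition,
                    link_count=result.observed[pair],
                    p_value=float(p),
                    neg_log10_p=-math.log10(p),
                )
    # node attributes over the CEIN's own gene universe
    cein_genes = {g for e in cein_edges for g in e}
    labeled = labeling.genes if labeling is not None else frozenset()
    for t in graph.nodes:
        members = {g for g in cein_genes if t in annot.terms(g)}
        graph.nodes[t]["gene_count"] = len(members)
        if labeling is not None and members:
            graph.nodes[t]["de_fraction"] = len(members & labeled) / len(members)
    term_names = {t: annot.term_names.get(t, t) for t in graph.nodes}
    return GoGoNetwork(graph=graph, kind="condition", term_names=term_names)
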