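"""Time-directed GO–GO networks from first-DE-day labels on an interactome.

For a consecutive day pair (d, d+1), a link X → Y between two GO terms is
counted once for every interactome edge {g1, g2} with g1 annotated to X and
first differentially expressed on d, and g2 annotated to Y and first
differentially expressed on d+1 (multi-annotated genes fan out over all
their terms). Significance of each observed link count is assessed by a
permutation null in which gene names are shuffled uniformly over the
network's node positions — topology is held fixed, each gene's annotation
and first-DE day travel with its name — and the one-sided empirical p-value
is (1 + r) / (1 + n_perm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .types import (
    ConsistencyError,
    FirstDayLabeling,
    GoAnnotation,
    GoGoNetwork,
)

__all__ = [
    "GoGoCount",
    "PermutationResult",
    "count_gogo_links",
    "permute_pvalues",
    "build_temporal_network",
    "de_fractions",
]


@dataclass
class GoGoCount:
    """Observed GO–GO link counts for one consecutive day pair.

    ``counts`` maps ordered term pairs (X, Y) — direction follows time —
    to the number of qualifying interactome edges; only pairs with count
    ≥ 1 are stored.
    """

    day_pair: tuple[int, int]
    counts: dict[tuple[str, str], int]


@dataclass
class PermutationResult:
    """Empirical one-sided p-values for the observed link counts."""

    n_perm: int
    p_values: dict[tuple[str, str], float]
    seed: int | None = None
    day_pair: tuple[int, int] | None = None
    observed: dict[tuple[str, str], int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# indexing helpers shared by counting and permutation
# ---------------------------------------------------------------------------


class _Indexed:
    """Integer-indexed view of (network, annotation, labeling).

    Position i in the network initially holds gene i; a permutation is an
    array ``perm`` with gene ``perm[i]`` sitting at position i.
    """

    def __init__(
        self,
        net: nx.Graph,
        annot: GoAnnotation,
        labeling: FirstDayLabeling,
    ) -> None:
        self.genes: list[str] = sorted(net.nodes)
        index = {g: i for i, g in enumerate(self.genes)}
        self.day = np.array(
            [labeling.gene_to_day.get(g, -1) for g in self.genes], dtype=np.int64
        )
        self.terms: list[tuple[str, ...]] = [
            tuple(sorted(annot.terms(g))) for g in self.genes
        ]
        if net.number_of_edges():
            self.e0 = np.fromiter(
                (index[a] for a, _ in net.edges()), dtype=np.int64
            )
            self.e1 = np.fromiter(
                (index[b] for _, b in net.edges()), dtype=np.int64
            )
        else:
            self.e0 = np.empty(0, dtype=np.int64)
            self.e1 = np.empty(0, dtype=np.int64)
        self.n = len(self.genes)

    def count_pair(
        self, day_pair: tuple[int, int], perm: np.ndarray | None = None
    ) -> dict[tuple[str, str], int]:
        """Link counts for one day pair under an optional gene permutation."""
        d, dn = day_pair
        g1 = self.e0 if perm is None else perm[self.e0]
        g2 = self.e1 if perm is None else perm[self.e1]
        d1 = self.day[g1]
        d2 = self.day[g2]
        counts: dict[tuple[str, str], int] = {}
        fwd = np.nonzero((d1 == d) & (d2 == dn))[0]
        bwd = np.nonzero((d1 == dn) & (d2 == d))[0]
        terms = self.terms
        for i in fwd:
            for x in terms[g1[i]]:
                for y in terms[g2[i]]:
                    key = (x, y)
                    counts[key] = counts.get(key, 0) + 1
        for i in bwd:
            for x in terms[g2[i]]:
                for y in terms[g1[i]]:
                    key = (x, y)
                    counts[key] = counts.get(key, 0) + 1
        return counts


def _check_day_pair(day_pair: tuple[int, int], days: Sequence[int] | None) -> None:
    d, dn = day_pair
    if d == dn:
        raise ConsistencyError(f"day pair {day_pair} is degenerate")
    if days is not None:
        order = sorted(int(x) for x in days)
        if d not in order or dn not in order or order.index(dn) != order.index(d) + 1:
            raise ConsistencyError(
                f"day pair {day_pair} is not consecutive in design days {order}"
            )


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def count_gogo_links(
    net: nx.Graph,
    annot: GoAnnotation,
    labeling: FirstDayLabeling,
    day_pair: tuple[int, int],
    days: Sequence[int] | None = None,
) -> GoGoCount:
    """Count interactome edges linking GO terms across one day pair.

    Genes without GO annotation contribute nothing; edges whose endpoints
    share the same first-DE day contribute nothing. A single gene–gene edge
    fans out over every (X, Y) in terms(g1) × terms(g2).
    """
    _check_day_pair(day_pair, days)
    indexed = _Indexed(net, annot, labeling)
    return GoGoCount(day_pair=tuple(day_pair), counts=indexed.count_pair(day_pair))


def permute_pvalues(
    net: nx.Graph,
    annot: GoAnnotation,
    labeling: FirstDayLabeling,
    day_pair: tuple[int, int],
    n_perm: int = 10_000,
    seed: int | None = None,
    days: Sequence[int] | None = None,
) -> PermutationResult:
    """Permutation p-values for all observed GO–GO links of one day pair.

    Each round draws one uniform random bijection of gene names onto node
    positions (shared across all term pairs, preserving the joint null);
    p(X, Y) = (1 + #{rounds with count ≥ observed}) / (1 + n_perm). Only
    pairs with observed count ≥ 1 are tested.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    _check_day_pair(day_pair, days)
    indexed = _Indexed(net, annot, labeling)
    observed = indexed.count_pair(day_pair)
    exceed = {pair: 0 for pair in observed}
    rng = np.random.default_rng(seed)
    for _ in range(n_perm):
        perm = rng.permutation(indexed.n)
        counts = indexed.count_pair(day_pair, perm)
        for pair, obs in observed.items():
            if counts.get(pair, 0) >= obs:
                exceed[pair] += 1
    p_values = {
        pair: (1 + r) / (1 + n_perm) for pair, r in exceed.items()
    }
    return PermutationResult(
        n_perm=n_perm,
        p_values=p_values,
        seed=seed,
        day_pair=tuple(day_pair),
        observed=observed,
    )


def de_fractions(
    net: nx.Graph,
    annot: GoAnnotation,
    labeling: FirstDayLabeling,
    terms: Sequence[str],
) -> dict[str, tuple[int, float | None]]:
    """Per term: (count of annotated genes in the network, fraction DE).

    The denominator is the term's annotated genes present in the network;
    the numerator those of them labeled with a first-DE day (any day).
    Fraction is ``None`` for terms with no annotated network gene.
    """
    net_nodes = set(net.nodes)
    labeled = labeling.genes
    out: dict[str, tuple[int, float | None]] = {}
    wanted = set(terms)
    members: dict[str, set[str]] = {t: set() for t in wanted}
    for gene, gene_terms in annot.gene_to_terms.items():
        if gene not in net_nodes:
            continue
        for t in gene_terms:
            if t in wanted:
                members[t].add(gene)
    for t in wanted:
        genes = members[t]
        if not genes:
            out[t] = (0, None)
        else:
            frac = len(genes & labeled) / len(genes)
            out[t] = (len(genes), frac)
    return out


def build_temporal_network(
    net: nx.Graph,
    annot: GoAnnotation,
    labeling: FirstDayLabeling,
    days: Sequence[int],
    n_perm: int = 10_000,
    seed: int | None = None,
    p_cutoff: float = 0.01,
    bh_correction: bool = False,
) -> GoGoNetwork:
    """Assemble the directed GO–GO network over all consecutive day pairs.

    Edges with p < ``p_cutoff`` (raw by default; Benjamini–Hochberg-adjusted
    with ``bh_correction``) are retained, annotated with ``link_count``,
    ``p_value`` and ``neg_log10_p``. Node attributes carry ``gene_count``
    and ``de_fraction``. Per-day-pair permutation streams are derived
    deterministically from ``seed``.
    """
    days = [int(d) for d in days]
    if len(days) < 2:
        raise ConsistencyError("need at least two days to build a temporal network")
    if sorted(set(days)) != days:
        raise ConsistencyError(f"days must be strictly increasing, got {days}")
    # parallel edges are real: the same X -> Y pair may be enriched in
    # several day pairs, and those are distinct temporal links
    graph = nx.MultiDiGraph()
    seed_seq = np.random.SeedSequence(seed)
    child_seeds = seed_seq.spawn(len(days) - 1)
    for k, (d, dn) in enumerate(zip(days[:-1], days[1:])):
        sub_seed = int(child_seeds[k].generate_state(1)[0] % (2**31))
        result = permute_pvalues(
            net, annot, labeling, (d, dn),
            n_perm=n_perm, seed=sub_seed, days=days,
        )
        p_items = sorted(result.p_values.items())
        if bh_correction and p_items:
            raw = np.array([p for _, p in p_items])
            adj = stats.false_discovery_control(raw, method="bh")
            p_map = {pair: float(q) for (pair, _), q in zip(p_items, adj)}
        else:
            p_map = dict(p_items)
        for pair, p in p_map.items():
            if p < p_cutoff:
                x, y = pair
                graph.add_edge(
                    x,
                    y,
                    key=f"t{d}->t{dn}",
                    day_pair=(d, dn),
                    link_count=result.observed[pair],
                    p_value=float(result.p_values[pair]),
                    neg_log10_p=-math.log10(result.p_values[pair]),
                )
    fracs = de_fractions(net, annot, labeling, list(graph.nodes))
    for t, (gene_count, frac) in fracs.items():
        graph.nodes[t]["gene_count"] = gene_count
        graph.nodes[t]["de_fraction"] = frac
    term_names = {t: annot.term_names.get(t, t) for t in graph.nodes}
    return GoGoNetwork(graph=graph, kind="temporal", term_names=term_names)
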