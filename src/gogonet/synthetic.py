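"""Self-contained synthetic fixtures with planted, recoverable structure.

Emulates the study design every other module expects: a scale-free gene
interactome, GO biological-process terms of varied size, a time-course DEG
table in which cascades propagate along planted interactome bridges between
consecutive first-DE days, and a 2-treatment × D-day × r-replicate
expression matrix with planted condition-specific or developmental
co-expressed pairs. All generators are deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io as gio
from .types import (
    CONTROL,
    TREATED,
    ConsistencyError,
    DegTable,
    ExpressionData,
    GoAnnotation,
)

__all__ = [
    "PlantedBridge",
    "PlantedCoexpr",
    "SyntheticConfig",
    "simulate_interactome",
    "simulate_annotation",
    "simulate_deg_cascade",
    "simulate_expression",
    "write_fixture",
]


@dataclass(frozen=True)
class PlantedBridge:
    """A dense GO:X(day d) → GO:Y(day d+1) bridge planted in the cascade."""

    term_x: str
    term_y: str
    day_pair: tuple[int, int]
    n_bridge_edges: int = 8
    term_size: int = 10


@dataclass(frozen=True)
class PlantedCoexpr:
    """Planted co-expressed gene pairs for one condition.

    ``condition`` is one of ``treated``, ``control``, ``developmental``.
    By default pairs are random interactome edges with disjoint endpoints.
    With ``term_x``/``term_y`` set, each term gets a dedicated set of
    ``n_pairs`` genes and pair i joins the i-th gene of X with the i-th gene
    of Y (edges added to the interactome if absent), so the planted signal
    concentrates between two GO terms and is recoverable in the
    condition-specific GO–GO network.
    """

    n_pairs: int
    condition: str
    target_correlation: float = 0.97
    term_x: str | None = None
    term_y: str | None = None


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic fixtures.

    Defaults emulate the modelled experiment: a two-arm design over days
    (2, 4, 6, 7) with 4 replicates per treatment × day cell (32 samples), a
    preferential-attachment interactome, and GO terms of varied size large
    enough that every gene carries 1–3 annotations.
    """

    n_genes: int = 1000
    n_terms: int = 80
    term_size_range: tuple[int, int] = (5, 30)
    m_attach: int = 3  # preferential-attachment edges per new node
    days: tuple[int, ...] = (2, 4, 6, 7)
    n_replicates: int = 4
    planted_temporal: tuple[PlantedBridge, ...] = ()
    planted_coexpr: tuple[PlantedCoexpr, ...] = ()
    background_de_prob: float = 0.3
    alpha: float = 0.01
    noise_sd: float = 1.0
    treat_shift: float = 3.0  # treated-arm mean shift (in noise-sd units) for planted pairs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < self.m_attach + 1:
            raise ConsistencyError("n_genes must exceed the attachment parameter")
        if tuple(sorted(self.days)) != tuple(self.days) or len(set(self.days)) != len(self.days):
            raise ConsistencyError("days must be strictly increasing")
        lo, hi = self.term_size_range
        if not 1 <= lo <= hi:
            raise ConsistencyError("invalid term_size_range")
        for pc in self.planted_coexpr:
            if not -1.0 < pc.target_correlation < 1.0:
                raise ConsistencyError("target_correlation must be in (-1, 1)")
            if pc.condition not in (TREATED, CONTROL, "developmental"):
                raise ConsistencyError(f"unknown planted condition {pc.condition!r}")
        for pb in self.planted_temporal:
            d, dn = pb.day_pair
            order = list(self.days)
            if d not in order or dn not in order or order.index(dn) != order.index(d) + 1:
                raise ConsistencyError(
                    f"planted day pair {pb.day_pair} not consecutive in {order}"
                )

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([stage, self.seed])

    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]


def simulate_interactome(cfg: SyntheticConfig) -> nx.Graph:
    """Preferential-attachment gene network with heavy-tailed degrees.

    The growth rule attaches each of the n − m incoming nodes to m existing
    nodes, so the edge count is exactly m·(n − m).
    """
    seed = int(cfg.rng(1).integers(2**31))
    g = nx.barabasi_albert_graph(cfg.n_genes, cfg.m_attach, seed=seed)
    names = cfg.gene_names()
    return nx.relabel_nodes(g, {i: names[i] for i in g.nodes})


def _planted_term_requirements(cfg: SyntheticConfig) -> dict[str, int]:
    """Term → dedicated gene-set size over all planted structures."""
    req: dict[str, int] = {}
    for pb in cfg.planted_temporal:
        for term in (pb.term_x, pb.term_y):
            req[term] = max(req.get(term, 0), pb.term_size)
    for pc in cfg.planted_coexpr:
        if pc.term_x is not None and pc.term_y is not None:
            for term in (pc.term_x, pc.term_y):
                req[term] = max(req.get(term, 0), pc.n_pairs)
    return req


def _planted_term_genes(
    cfg: SyntheticConfig, rng: np.random.Generator, genes: list[str]
) -> dict[str, list[str]]:
    """Disjoint dedicated gene sets for every planted term."""
    out: dict[str, list[str]] = {}
    pool = list(genes)
    rng.shuffle(pool)
    cursor = 0
    for term, size in _planted_term_requirements(cfg).items():
        take = pool[cursor : cursor + size]
        if len(take) < size:
            raise ConsistencyError("not enough genes for planted terms")
        out[term] = take
        cursor += size
    return out


def simulate_annotation(cfg: SyntheticConfig, net: nx.Graph) -> GoAnnotation:
    """Assign GO terms: dedicated sets for planted terms, 1–3 terms per gene.

    Background term sizes are drawn from ``term_size_range``; term slots are
    dealt so that every background gene receives at least one and at most
    three terms, keeping realised sizes within ±1 of their targets.
    """
    rng = cfg.rng(2)
    genes = sorted(net.nodes)
    planted = _planted_term_genes(cfg, rng, genes)
    planted_genes = {g for members in planted.values() for g in members}
    background = [g for g in genes if g not in planted_genes]

    lo, hi = cfg.term_size_range
    sizes = rng.integers(lo, hi + 1, size=cfg.n_terms)
    if sizes.sum() < len(background):
        raise ConsistencyError(
            "term-size budget cannot annotate every gene: increase n_terms "
            "or term_size_range"
        )
    terms = [f"GO:{i + 1:07d}" for i in range(cfg.n_terms)]
    slots: list[str] = []
    for t, s in zip(terms, sizes):
        slots.extend([t] * int(s))
    slots = [slots[i] for i in rng.permutation(len(slots))]

    gene_terms: dict[str, set[str]] = {g: set() for g in background}
    # first pass: one slot per gene, so every gene is annotated
    leftover: list[str] = []
    it = iter(slots)
    for g in background:
        t = next(it)
        gene_terms[g].add(t)
    leftover = list(it)
    # deal remaining slots to random genes with < 3 terms
    order = rng.permutation(len(background))
    capacity = [g for i in order for g in [background[i]]]
    for t in leftover:
        for _ in range(100):
            g = capacity[int(rng.integers(len(capacity)))]
            if len(gene_terms[g]) < 3 and t not in gene_terms[g]:
                gene_terms[g].add(t)
                break
        # slot dropped if no host found (rare; sizes stay within ±1)

    mapping = {g: frozenset(ts) for g, ts in gene_terms.items()}
    for term, members in planted.items():
        for g in members:
            mapping[g] = frozenset({term})
    return GoAnnotation(mapping)


def simulate_deg_cascade(
    cfg: SyntheticConfig, net: nx.Graph, annot: GoAnnotation
) -> DegTable:
    """Time-course adjusted p-values with planted first-DE-day cascades.

    Genes of each planted bridge's term X become first-DE on the earlier
    day, genes of term Y on the later day, and ``n_bridge_edges`` new
    interactome edges are added (in place) between them, emulating a
    perturbation propagating along network links. Background genes are DE
    on one uniformly chosen day with probability ``background_de_prob``.
    """
    rng = cfg.rng(3)
    days = list(cfg.days)
    sig_hi = cfg.alpha / 2.0
    rows: list[tuple[str, int, float]] = []
    planted_gene_day: dict[str, int] = {}
    for pb in cfg.planted_temporal:
        d, dn = pb.day_pair
        genes_x = sorted(annot.genes_of_term(pb.term_x))
        genes_y = sorted(annot.genes_of_term(pb.term_y))
        for g in genes_x:
            planted_gene_day[g] = d
        for g in genes_y:
            planted_gene_day[g] = dn
        # plant the bridge: new edges between X-genes and Y-genes
        candidates = [
            (a, b) for a in genes_x for b in genes_y if not net.has_edge(a, b)
        ]
        if len(candidates) < pb.n_bridge_edges:
            raise ConsistencyError("not enough free pairs for bridge edges")
        pick = rng.choice(len(candidates), size=pb.n_bridge_edges, replace=False)
        for i in pick:
            net.add_edge(*candidates[i])

    for g in sorted(net.nodes):
        if g in planted_gene_day:
            de_day = planted_gene_day[g]
        elif rng.random() < cfg.background_de_prob:
            de_day = days[int(rng.integers(len(days)))]
        else:
            de_day = None
        for day in days:
            if de_day is not None and day == de_day:
                p = float(rng.uniform(0.0, sig_hi))
            else:
                p = float(rng.uniform(0.05, 1.0))
            rows.append((g, day, p))
    return DegTable(pd.DataFrame(rows, columns=["gene", "day", "adj_p"]))


def _design_frame(cfg: SyntheticConfig) -> pd.DataFrame:
    rows = []
    for treatment in (TREATED, CONTROL):
        for day in cfg.days:
            for rep in range(1, cfg.n_replicates + 1):
                rows.append(
                    {
                        "sample": f"{treatment}_d{day}_r{rep}",
                        "treatment": treatment,
                        "day": day,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def planted_coexpr_pairs(
    cfg: SyntheticConfig, net: nx.Graph, annot: GoAnnotation | None = None
) -> list[tuple["PlantedCoexpr", list[tuple[str, str]]]]:
    """Deterministically choose the gene pairs carrying planted signal.

    Term-anchored plantings pair the i-th dedicated gene of term X with the
    i-th of term Y (adding the interactome edge if absent, in place); free
    plantings use existing network edges with endpoint sets disjoint across
    all planted pairs, so each planted gene belongs to exactly one pair.
    """
    rng = cfg.rng(4)
    edges = sorted(tuple(sorted(e)) for e in net.edges())
    order = rng.permutation(len(edges))
    used: set[str] = set()
    out: list[tuple[PlantedCoexpr, list[tuple[str, str]]]] = []
    for pc in cfg.planted_coexpr:
        if pc.term_x is not None and pc.term_y is not None:
            if annot is None:
                raise ConsistencyError(
                    "term-anchored planted pairs need the annotation"
                )
            genes_x = sorted(annot.genes_of_term(pc.term_x))[: pc.n_pairs]
            genes_y = sorted(annot.genes_of_term(pc.term_y))[: pc.n_pairs]
            if len(genes_x) < pc.n_pairs or len(genes_y) < pc.n_pairs:
                raise ConsistencyError(
                    f"terms {pc.term_x}/{pc.term_y} lack dedicated genes"
                )
            chosen = [tuple(sorted(p)) for p in zip(genes_x, genes_y)]
            for a, b in chosen:
                net.add_edge(a, b)
                used.update((a, b))
            out.append((pc, chosen))
    cursor = 0
    for pc in cfg.planted_coexpr:
        if pc.term_x is not None and pc.term_y is not None:
            continue
        chosen = []
        while len(chosen) < pc.n_pairs:
            if cursor >= len(edges):
                raise ConsistencyError("not enough disjoint edges to plant pairs")
            a, b = edges[order[cursor]]
            cursor += 1
            if a in used or b in used:
                continue
            used.update((a, b))
            chosen.append((a, b))
        out.append((pc, chosen))
    return out


def _standardised_profile(rng: np.random.Generator, values: np.ndarray) -> np.ndarray:
    """Centre/scale a per-sample profile to population sd 1."""
    v = values - values.mean()
    sd = v.std()
    if sd == 0:
        v = rng.normal(size=values.size)
        v -= v.mean()
        sd = v.std()
    return v / sd


def simulate_expression(
    cfg: SyntheticConfig, net: nx.Graph, annot: GoAnnotation | None = None
) -> ExpressionData:
    """Expression matrix with planted co-expressed pairs.

    Background genes are i.i.d. Gaussian noise around a per-gene baseline.
    A planted condition-specific pair shares a day-dependent profile (plus a
    treated-arm mean shift, so the treatment effect registers in the
    factorial ANOVA) in its condition only; a developmental pair shares a
    monotone day trend in both arms. Profiles are standardised so the
    planted correlation equals ``target_correlation`` in expectation.
    """
    rng = cfg.rng(5)
    genes = sorted(net.nodes)
    design = _design_frame(cfg)
    n_samples = len(design)
    day_of = design["day"].to_numpy()
    treat_mask = (design["treatment"] == TREATED).to_numpy()
    ctrl_mask = ~treat_mask

    baseline = rng.uniform(4.0, 12.0, size=len(genes))
    values = baseline[:, None] + rng.normal(
        0.0, cfg.noise_sd, size=(len(genes), n_samples)
    )
    index = {g: i for i, g in enumerate(genes)}

    plantings = planted_coexpr_pairs(cfg, net, annot)
    days = np.array(cfg.days)
    for pc, chosen in plantings:
        rho = pc.target_correlation
        s = cfg.noise_sd * np.sqrt(rho / (1.0 - rho))
        for a, b in chosen:
            ia, ib = index[a], index[b]
            if pc.condition == "developmental":
                trend = np.interp(day_of, days, np.linspace(-1.0, 1.0, len(days)))
                profile = _standardised_profile(rng, trend.astype(float))
                values[ia] += s * profile
                values[ib] += s * profile
            else:
                mask = treat_mask if pc.condition == TREATED else ctrl_mask
                z_day = rng.normal(size=len(days))
                per_sample = z_day[np.searchsorted(days, day_of[mask])]
                profile = _standardised_profile(rng, per_sample)
                signal = s * profile + cfg.treat_shift * cfg.noise_sd
                values[ia, mask] += signal
                values[ib, mask] += signal

    frame = pd.DataFrame(values, index=genes, columns=design["sample"].tolist())
    return ExpressionData(values=frame, design=design)


def write_fixture(cfg: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write all four inputs in the formats the readers accept."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net = simulate_interactome(cfg)
    annot = simulate_annotation(cfg, net)
    deg = simulate_deg_cascade(cfg, net, annot)  # adds bridge edges in place
    expr = simulate_expression(cfg, net, annot)  # adds term-anchored pair edges
    paths = {
        "network": out / "network.tsv",
        "annotation": out / "go_annotation.tsv",
        "deg_table": out / "deg_table.tsv",
        "expression": out / "expression.tsv",
        "design": out / "design.tsv",
    }
    gio.write_network(net, paths["network"])
    gio.write_go_annotation(annot, paths["annotation"])
    gio.write_deg_table(deg, paths["deg_table"])
    gio.write_expression(expr, paths["expression"], paths["design"])
    return paths
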