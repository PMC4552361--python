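"""Domain types shared across the package.

The central objects are thin, validated wrappers around the field's standard
containers: gene networks are :class:`networkx.Graph`, tabular data are
:class:`pandas.DataFrame`. Gene and GO-term identifiers are opaque strings;
no identifier mapping is performed anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "GogonetError",
    "ParseError",
    "ConsistencyError",
    "GoAnnotation",
    "DegTable",
    "FirstDayLabeling",
    "ExpressionData",
    "GoGoNetwork",
    "TREATED",
    "CONTROL",
]

#: canonical treatment levels used throughout (input aliases are normalised on read)
TREATED = "treated"
CONTROL = "control"


class GogonetError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(GogonetError):
    """A file could not be parsed; the message carries the line number."""


class ConsistencyError(GogonetError):
    """Inputs that must agree (e.g. matrix columns vs design rows) do not."""


# ---------------------------------------------------------------------------
# GO annotation
# ---------------------------------------------------------------------------


@dataclass
class GoAnnotation:
    """Gene → set of GO biological-process term IDs, plus term names.

    ``term_names`` maps every term appearing in ``gene_to_terms`` to a
    human-readable name; when no name is known the name equals the ID.
    """

    gene_to_terms: dict[str, frozenset[str]]
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for gene, terms in self.gene_to_terms.items():
            terms = frozenset(terms)
            if not terms:
                continue  # unannotated genes are simply absent
            clean[gene] = terms
        self.gene_to_terms = clean
        for terms in clean.values():
            for t in terms:
                self.term_names.setdefault(t, t)

    def terms(self, gene: str) -> frozenset[str]:
        return self.gene_to_terms.get(gene, frozenset())

    @property
    def all_terms(self) -> frozenset[str]:
        out: set[str] = set()
        for terms in self.gene_to_terms.values():
            out |= terms
        return frozenset(out)

    def genes_of_term(self, term: str) -> frozenset[str]:
        return frozenset(
            g for g, ts in self.gene_to_terms.items() if term in ts
        )


# ---------------------------------------------------------------------------
# Differential-expression table and first-DE-day labeling
# ---------------------------------------------------------------------------


@dataclass
class DegTable:
    """Per-gene, per-time-point adjusted p-values from an upstream DE test.

    ``records`` has columns ``gene``, ``day`` (ordinal time point) and
    ``adj_p`` (adjusted p-value in [0, 1]); at most one row per (gene, day).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records, columns=["gene", "day", "adj_p"]).copy()
        df["gene"] = df["gene"].astype(str)
        df["day"] = df["day"].astype(int)
        df["adj_p"] = df["adj_p"].astype(float)
        if ((df["adj_p"] < 0) | (df["adj_p"] > 1)).any():
            raise ConsistencyError("adjusted p-values must lie in [0, 1]")
        dup = df.duplicated(subset=["gene", "day"])
        if dup.any():
            offender = df.loc[dup, ["gene", "day"]].iloc[0]
            raise ConsistencyError(
                f"duplicate record for gene {offender['gene']!r} on day "
                f"{offender['day']}"
            )
        self.records = df.reset_index(drop=True)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.records["gene"])


@dataclass
class FirstDayLabeling:
    """Gene → earliest day on which it was differentially expressed.

    Only genes with at least one adjusted p-value strictly below ``alpha``
    carry a label; all other genes are absent from ``gene_to_day``.
    """

    gene_to_day: dict[str, int]
    alpha: float = 0.01

    def first_day(self, gene: str) -> int | None:
        return self.gene_to_day.get(gene)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.gene_to_day)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.gene_to_day.items()), columns=["gene", "first_day"]
        )


# ---------------------------------------------------------------------------
# Expression matrix with sample design
# ---------------------------------------------------------------------------

_TREATMENT_ALIASES = {
    "treated": TREATED,
    "treatment": TREATED,
    "vd3": TREATED,
    "control": CONTROL,
    "vehicle": CONTROL,
    "ethanol": CONTROL,
}


def normalise_treatment(value: str) -> str:
    """Map a treatment label from the design table onto {treated, control}."""
    key = str(value).strip().lower()
    if key not in _TREATMENT_ALIASES:
        raise ConsistencyError(
            f"unrecognised treatment level {value!r}; expected one of "
            f"{sorted(_TREATMENT_ALIASES)}"
        )
    return _TREATMENT_ALIASES[key]


@dataclass
class ExpressionData:
    """Normalised expression values (genes × samples) plus the sample design.

    ``design`` is indexed by sample name with columns ``treatment`` (one of
    ``treated``/``control``), ``day`` and ``replicate``; its rows are
    bijective with the columns of ``values``. Columns are stored in the
    canonical order sorted by (treatment, day, replicate) so that logically
    identical inputs compare equal regardless of file row order.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        design = self.design.copy()
        if design.index.name != "sample":
            if "sample" in design.columns:
                design = design.set_index("sample")
            else:
                raise ConsistencyError("design table needs a 'sample' column")
        design["treatment"] = [normalise_treatment(t) for t in design["treatment"]]
        design["day"] = design["day"].astype(int)
        design["replicate"] = design["replicate"].astype(int)

        mat_samples = set(map(str, self.values.columns))
        des_samples = set(map(str, design.index))
        if mat_samples != des_samples:
            missing = sorted(mat_samples - des_samples)
            extra = sorted(des_samples - mat_samples)
            raise ConsistencyError(
                "expression matrix and design disagree on samples: "
                f"matrix-only={missing}, design-only={extra}"
            )

        design = design.sort_values(["treatment", "day", "replicate"])
        self.design = design
        self.values = self.values[design.index.tolist()].copy()
        self.values.index = self.values.index.astype(str)

    @property
    def days(self) -> tuple[int, ...]:
        return tuple(sorted(self.design["day"].unique()))

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.values.index)

    def samples_of(self, treatment: str | None = None) -> list[str]:
        """Sample names for one treatment arm (or all samples if ``None``)."""
        if treatment is None:
            return list(self.design.index)
        return list(self.design.index[self.design["treatment"] == treatment])

    @property
    def balanced(self) -> bool:
        """True iff every treatment × day cell has the same replicate count ≥ 2."""
        counts = self.design.groupby(["treatment", "day"]).size()
        n_cells = self.design["treatment"].nunique() * self.design["day"].nunique()
        return (
            len(counts) == n_cells
            and counts.nunique() == 1
            and int(counts.iloc[0]) >= 2
        )

    @property
    def n_replicates(self) -> int:
        return int(self.design.groupby(["treatment", "day"]).size().iloc[0])


# ---------------------------------------------------------------------------
# GO–GO meta-network
# ---------------------------------------------------------------------------


@dataclass
class GoGoNetwork:
    """Directed (temporal) or undirected (condition) network over GO terms.

    Nodes carry ``gene_count`` (annotated genes present in the underlying
    gene network) and ``de_fraction`` (fraction of those genes differentially
    expressed on any day). Edges carry ``link_count``, ``p_value``,
    ``neg_log10_p`` and either ``day_pair`` (temporal) or ``condition``.
    """

    graph: nx.DiGraph | nx.Graph
    kind: str  # "temporal" | "condition"
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("temporal", "condition"):
            raise ValueError(f"unknown GoGoNetwork kind {self.kind!r}")
        directed = self.graph.is_directed()
        if self.kind == "temporal" and not directed:
            raise ValueError("temporal GO-GO networks are directed")
        if self.kind == "condition" and directed:
            raise ValueError("condition GO-GO networks are undirected")

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_records(self) -> pd.DataFrame:
        """All edges with attributes as a tidy frame (deterministic order)."""
        rows = []
        for u, v, data in self.graph.edges(data=True):
            if data.get("day_pair") is not None:
                d, dn = data["day_pair"]
                interaction = f"t{d}->t{dn}"
            else:
                interaction = data.get("condition", "coexpr")
            row = {"source": u, "target": v, "interaction": interaction}
            row.update(data)
            rows.append(row)
        cols = ["source", "target", "interaction", "link_count", "p_value", "neg_log10_p"]
        df = pd.DataFrame(rows, columns=cols)
        return df.sort_values(["source", "target"]).reset_index(drop=True)

    def node_records(self) -> pd.DataFrame:
        rows = []
        for n, data in self.graph.nodes(data=True):
            row = {
                "term": n,
                "name": self.term_names.get(n, n),
                "gene_count": data.get("gene_count"),
                "de_fraction": data.get("de_fraction"),
            }
            rows.append(row)
        df = pd.DataFrame(rows, columns=["term", "name", "gene_count", "de_fraction"])
        return df.sort_values("term").reset_index(drop=True)


def check_gene_network(graph: nx.Graph) -> nx.Graph:
    """Validate the invariants of an interactome graph (no self-loops)."""
    loops = list(nx.selfloop_edges(graph))
    if loops:
        raise ConsistencyError(f"gene network contains self-loops: {loops[:3]}")
    return graph


def union_terms(annot: GoAnnotation, genes: Iterable[str]) -> frozenset[str]:
    """All GO terms annotating any of ``genes``."""
    out: set[str] = set()
    for g in genes:
        out |= annot.terms(g)
    return frozenset(out)
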