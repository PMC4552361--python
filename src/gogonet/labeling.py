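"""First-DE-day labeling and the DEG vs non-DEG degree comparison.

A gene's label is the earliest time point at which its adjusted p-value
drops strictly below the significance cutoff; this label later gives GO–GO
edges their temporal direction. Genes never significant carry no label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .types import ConsistencyError, DegTable, FirstDayLabeling

__all__ = ["label_first_de_day", "degree_comparison", "DegreeComparison"]


def label_first_de_day(
    deg: DegTable,
    alpha: float = 0.01,
    days: Sequence[int] | None = None,
) -> FirstDayLabeling:
    """Label each gene with its earliest day of differential expression.

    Parameters
    ----------
    deg:
        Adjusted p-values per gene and day from the upstream DE test.
    alpha:
        Significance cutoff; a gene counts as differentially expressed on a
        day iff ``adj_p < alpha`` (strict — boundary values are not
        significant).
    days:
        The ordered set of days in the experimental design. Records on days
        outside this set are an error. Defaults to the days present in the
        table.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    df = deg.records
    if days is not None:
        day_set = set(int(d) for d in days)
        bad = sorted(set(df["day"]) - day_set)
        if bad:
            raise ConsistencyError(
                f"DEG table contains days {bad} outside the design days "
                f"{sorted(day_set)}"
            )
    sig = df[df["adj_p"] < alpha]
    gene_to_day = sig.groupby("gene")["day"].min().astype(int).to_dict()
    return FirstDayLabeling(gene_to_day=gene_to_day, alpha=alpha)


@dataclass
class DegreeComparison:
    """Mean interactome degree of DE vs non-DE genes with a one-way ANOVA p.

    For two groups the one-way ANOVA is equivalent to a pooled-variance
    two-sample t-test (F = t²). ``p_value`` is ``None`` when either group is
    empty or the pooled variance vanishes.
    """

    mean_degree_deg: float
    mean_degree_non: float
    n_deg: int
    n_non: int
    p_value: float | None

    @property
    def p_defined(self) -> bool:
        return self.p_value is not None


def degree_comparison(
    net: nx.Graph, labeling: FirstDayLabeling
) -> DegreeComparison:
    """Compare mean network degree between DE-labeled and unlabeled genes.

    The two groups partition the network's node set: DE = present in the
    labeling. Labeled genes absent from the network are ignored here (they
    have no degree).
    """
    if net.number_of_nodes() == 0:
        raise ConsistencyError("degree comparison requires a non-empty network")
    de_genes = labeling.genes
    deg_degrees = np.array(
        [d for n, d in net.degree() if n in de_genes], dtype=float
    )
    non_degrees = np.array(
        [d for n, d in net.degree() if n not in de_genes], dtype=float
    )
    mean_deg = float(deg_degrees.mean()) if deg_degrees.size else float("nan")
    mean_non = float(non_degrees.mean()) if non_degrees.size else float("nan")
    p: float | None = None
    if deg_degrees.size >= 2 and non_degrees.size >= 2:
        f, p_val = stats.f_oneway(deg_degrees, non_degrees)
        if np.isnan(p_val) and np.isfinite(f) and f <= 0:
            # exactly equal group means: F underflows to a tiny negative value
            p = 1.0
        else:
            p = None if np.isnan(p_val) else float(p_val)
    return DegreeComparison(
        mean_degree_deg=mean_deg,
        mean_degree_non=mean_non,
        n_deg=int(deg_degrees.size),
        n_non=int(non_degrees.size),
        p_value=p,
    )
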