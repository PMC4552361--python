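"""Condition-specific co-expressed interaction networks (CEINs).

Every interactome edge whose endpoint genes are both measured is scored by
(i) per-condition Pearson correlations — over treated samples, over control
samples, and over all samples — and (ii) a balanced 3-way factorial ANOVA
with factors treatment (2 levels), day (D levels) and gene (2 levels: which
member of the pair an observation came from). The pair is then classified:

* condition-specific (treatment- or control-related): one condition carries
  a strong correlation, the normalised difference between the two
  conditions' correlations is large, and at least one treatment-involving
  ANOVA effect (TREAT, TREAT×GENE, TREAT×DAY×GENE) is significant;
* developmental: strong correlation across all samples, a significant day
  effect, and no day×gene interaction (the two genes track development
  synchronously);
* none otherwise. Condition-specific rules take precedence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .types import CONTROL, TREATED, ConsistencyError, ExpressionData

__all__ = [
    "EFFECTS",
    "PairCorrelations",
    "PairAnova",
    "LinkThresholds",
    "CoexpressionLink",
    "CeinResult",
    "pcc",
    "pair_correlations",
    "pair_anova",
    "classify_link",
    "build_ceins",
    "links_to_frame",
    "write_cein",
    "read_cein_pairs",
    "LINK_TYPES",
]

#: the seven effects of the 2 (treatment) x D (day) x 2 (gene) factorial
EFFECTS = (
    "TREAT",
    "DAY",
    "GENE",
    "TREAT:DAY",
    "TREAT:GENE",
    "DAY:GENE",
    "TREAT:DAY:GENE",
)

LINK_TYPES = ("treatment_specific", "control_specific", "developmental", "none")


# ---------------------------------------------------------------------------
# Pearson correlation (per-condition)
# ---------------------------------------------------------------------------


def pcc(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation with (n-1) normalisation.

    r = 1/(n-1) * sum_i z(x_i) z(y_i) with z-scores built from the sample
    mean and sample standard deviation (ddof=1). Returns ``nan`` when either
    vector is constant (undefined correlation); raises on length mismatch or
    n < 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    zx = (x - x.mean()) / sx
    zy = (y - y.mean()) / sy
    r = float(np.dot(zx, zy) / (n - 1))
    # clip tiny floating excursions outside [-1, 1]
    return max(-1.0, min(1.0, r))


@dataclass
class PairCorrelations:
    """Per-condition Pearson correlations for one gene pair."""

    pcc_treat: float
    pcc_control: float
    pcc_all: float

    @property
    def defined(self) -> bool:
        return not (
            np.isnan(self.pcc_treat)
            or np.isnan(self.pcc_control)
            or np.isnan(self.pcc_all)
        )


def pair_correlations(
    expr: ExpressionData, pair: tuple[str, str]
) -> PairCorrelations:
    """Correlations of a gene pair over treated, control and all samples."""
    a, b = pair
    for g in (a, b):
        if g not in expr.values.index:
            raise ConsistencyError(f"gene {g!r} absent from the expression matrix")
    xa = expr.values.loc[a]
    xb = expr.values.loc[b]
    treat = expr.samples_of(TREATED)
    ctrl = expr.samples_of(CONTROL)
    return PairCorrelations(
        pcc_treat=pcc(xa[treat].to_numpy(), xb[treat].to_numpy()),
        pcc_control=pcc(xa[ctrl].to_numpy(), xb[ctrl].to_numpy()),
        pcc_all=pcc(xa.to_numpy(), xb.to_numpy()),
    )


# ---------------------------------------------------------------------------
# Balanced 3-way factorial ANOVA on a gene pair
# ---------------------------------------------------------------------------


@dataclass
class PairAnova:
    """Classical balanced-design ANOVA of a stacked gene pair.

    ``f_stats`` maps each of the seven effects to F = MS(effect)/MS(resid);
    ``df`` maps effect → (numerator df, denominator df); ``ss`` carries the
    sums of squares including ``"RESID"`` and ``"TOTAL"``.
    """

    f_stats: dict[str, float]
    df: dict[str, tuple[int, int]]
    residual_df: int
    ss: dict[str, float] = field(default_factory=dict)


def _pair_layout(expr: ExpressionData, pair: tuple[str, str]) -> np.ndarray:
    """Stack a pair's values into a (2, D, 2, r) treatment×day×gene×rep array."""
    if not expr.balanced:
        raise ConsistencyError(
            "factorial ANOVA needs a complete balanced design (equal "
            "replicate count >= 2 in every treatment x day cell); check "
            "ExpressionData.balanced"
        )
    a, b = pair
    days = expr.days
    r = expr.n_replicates
    design = expr.design
    y = np.empty((2, len(days), 2, r), dtype=float)
    for ti, treatment in enumerate((TREATED, CONTROL)):
        for di, day in enumerate(days):
            mask = (design["treatment"] == treatment) & (design["day"] == day)
            cols = design.index[mask][
                np.argsort(design.loc[mask, "replicate"].to_numpy(), kind="stable")
            ]
            y[ti, di, 0, :] = expr.values.loc[a, cols].to_numpy()
            y[ti, di, 1, :] = expr.values.loc[b, cols].to_numpy()
    return y


def pair_anova(expr: ExpressionData, pair: tuple[str, str]) -> PairAnova:
    """Seven-effect factorial ANOVA for one gene pair.

    The response stacks both genes' expression values; each observation is
    tagged with its sample's treatment and day and with which gene of the
    pair it came from. Sums of squares are the classical balanced-design
    decomposition; every F uses the full model's residual mean square.
    """
    return _anova_from_layout(_pair_layout(expr, pair))


def _anova_from_layout(y: np.ndarray) -> PairAnova:
    nt, nd, ng, r = y.shape
    n = y.size
    m = y.mean()

    m_t = y.mean(axis=(1, 2, 3))
    m_d = y.mean(axis=(0, 2, 3))
    m_g = y.mean(axis=(0, 1, 3))
    m_td = y.mean(axis=(2, 3))
    m_tg = y.mean(axis=(1, 3))
    m_dg = y.mean(axis=(0, 3))
    m_tdg = y.mean(axis=3)

    ss = {
        "TREAT": nd * ng * r * float(((m_t - m) ** 2).sum()),
        "DAY": nt * ng * r * float(((m_d - m) ** 2).sum()),
        "GENE": nt * nd * r * float(((m_g - m) ** 2).sum()),
        "TREAT:DAY": ng * r * float(
            ((m_td - m_t[:, None] - m_d[None, :] + m) ** 2).sum()
        ),
        "TREAT:GENE": nd * r * float(
            ((m_tg - m_t[:, None] - m_g[None, :] + m) ** 2).sum()
        ),
        "DAY:GENE": nt * r * float(
            ((m_dg - m_d[:, None] - m_g[None, :] + m) ** 2).sum()
        ),
    }
    inter3 = (
        m_tdg
        - m_td[:, :, None]
        - m_tg[:, None, :]
        - m_dg[None, :, :]
        + m_t[:, None, None]
        + m_d[None, :, None]
        + m_g[None, None, :]
        - m
    )
    ss["TREAT:DAY:GENE"] = r * float((inter3**2).sum())
    ss["RESID"] = float(((y - m_tdg[:, :, :, None]) ** 2).sum())
    ss["TOTAL"] = float(((y - m) ** 2).sum())

    df_num = {
        "TREAT": nt - 1,
        "DAY": nd - 1,
        "GENE": ng - 1,
        "TREAT:DAY": (nt - 1) * (nd - 1),
        "TREAT:GENE": (nt - 1) * (ng - 1),
        "DAY:GENE": (nd - 1) * (ng - 1),
        "TREAT:DAY:GENE": (nt - 1) * (nd - 1) * (ng - 1),
    }
    residual_df = nt * nd * ng * (r - 1)
    ms_resid = ss["RESID"] / residual_df
    f_stats = {}
    for eff in EFFECTS:
        ms = ss[eff] / df_num[eff]
        f_stats[eff] = float(ms / ms_resid) if ms_resid > 0 else float("inf")
    return PairAnova(
        f_stats=f_stats,
        df={eff: (df_num[eff], residual_df) for eff in EFFECTS},
        residual_df=residual_df,
        ss=ss,
    )


class _ExprArrays:
    """numpy view of an ExpressionData for tight per-edge loops.

    Produces bit-identical results to :func:`pair_correlations` /
    :func:`pair_anova` (same sample ordering, same reductions) without
    per-pair pandas indexing.
    """

    def __init__(self, expr: ExpressionData) -> None:
        self.index = {g: i for i, g in enumerate(expr.values.index)}
        self.X = expr.values.to_numpy(dtype=float)
        design = expr.design
        self.treat_mask = (design["treatment"] == TREATED).to_numpy()
        self.ctrl_mask = (design["treatment"] == CONTROL).to_numpy()
        days = expr.days
        self.balanced = expr.balanced
        self.cell_cols: list[list[np.ndarray]] | None = None
        if self.balanced:
            cols = []
            treatment_arr = design["treatment"].to_numpy()
            day_arr = design["day"].to_numpy()
            rep_arr = design["replicate"].to_numpy()
            for treatment in (TREATED, CONTROL):
                per_day = []
                for day in days:
                    idx = np.nonzero((treatment_arr == treatment) & (day_arr == day))[0]
                    per_day.append(idx[np.argsort(rep_arr[idx], kind="stable")])
                cols.append(per_day)
            self.cell_cols = cols
            self.n_days = len(days)
            self.n_reps = int(len(cols[0][0]))

    def correlations(self, ia: int, ib: int) -> PairCorrelations:
        xa, xb = self.X[ia], self.X[ib]
        return PairCorrelations(
            pcc_treat=pcc(xa[self.treat_mask], xb[self.treat_mask]),
            pcc_control=pcc(xa[self.ctrl_mask], xb[self.ctrl_mask]),
            pcc_all=pcc(xa, xb),
        )

    def anova(self, ia: int, ib: int) -> PairAnova:
        if self.cell_cols is None:
            raise ConsistencyError(
                "factorial ANOVA needs a complete balanced design (equal "
                "replicate count >= 2 in every treatment x day cell); check "
                "ExpressionData.balanced"
            )
        y = np.empty((2, self.n_days, 2, self.n_reps), dtype=float)
        for ti in range(2):
            for di in range(self.n_days):
                cols = self.cell_cols[ti][di]
                y[ti, di, 0, :] = self.X[ia, cols]
                y[ti, di, 1, :] = self.X[ib, cols]
        return _anova_from_layout(y)


# ---------------------------------------------------------------------------
# Link classification
# ---------------------------------------------------------------------------


@dataclass
class LinkThresholds:
    """Cutoffs governing link classification.

    ``min_pcc`` — minimum per-condition |PCC| for a condition-specific link;
    ``diff_pcc`` — minimum normalised PCC difference between conditions;
    ``full_pcc`` — minimum all-sample PCC for a developmental link;
    ``alpha_effect`` / ``alpha_sync`` — significance levels for the ANOVA
    gates. ``paper_df`` compares every F against quantiles with denominator
    df 19 (numerator 1 for treatment effects, D-1 for day effects) instead
    of the layout's actual residual df; ``abs_full_pcc`` applies the
    developmental correlation cutoff to |PCC_all| instead of the signed
    value.
    """

    min_pcc: float = 0.9
    diff_pcc: float = 0.6
    full_pcc: float = 0.9
    alpha_effect: float = 0.05
    alpha_sync: float = 0.2
    paper_df: bool = False
    abs_full_pcc: bool = False


def _f_crit(alpha: float, num_df: int, den_df: int) -> float:
    return float(stats.f.ppf(1.0 - alpha, num_df, den_df))


def classify_link(
    corr: PairCorrelations, anova: PairAnova | None, th: LinkThresholds
) -> str:
    """Assign a link type from correlations and ANOVA statistics.

    Pure function; the three predicates are mutually exclusive by the fixed
    precedence condition-specific > developmental > none. Undefined
    correlations yield ``none``.
    """
    if not corr.defined or anova is None:
        return "none"
    pt, pc = corr.pcc_treat, corr.pcc_control
    denom = max(abs(pt), abs(pc))

    if th.paper_df:
        # as printed: treatment-effect gate at (1, 19), day gates at (D-1, 19)
        crit_treat = _f_crit(th.alpha_effect, 1, 19)
        crit_day = _f_crit(th.alpha_effect, anova.df["DAY"][0], 19)
        crit_sync = _f_crit(th.alpha_sync, anova.df["DAY:GENE"][0], 19)
    else:
        crit_treat = None  # per-effect below
        crit_day = _f_crit(th.alpha_effect, *anova.df["DAY"])
        crit_sync = _f_crit(th.alpha_sync, *anova.df["DAY:GENE"])

    treat_effects = ("TREAT", "TREAT:GENE", "TREAT:DAY:GENE")
    if th.paper_df:
        treat_gate = any(anova.f_stats[e] > crit_treat for e in treat_effects)
    else:
        treat_gate = any(
            anova.f_stats[e] > _f_crit(th.alpha_effect, *anova.df[e])
            for e in treat_effects
        )

    if (
        denom > th.min_pcc
        and denom > 0
        and abs(pt - pc) / denom > th.diff_pcc
        and treat_gate
    ):
        if abs(pt) > abs(pc):
            return "treatment_specific"
        if abs(pc) > abs(pt):
            return "control_specific"
        # exact tie: no information on which condition carries the signal

    pcc_all = abs(corr.pcc_all) if th.abs_full_pcc else corr.pcc_all
    if (
        pcc_all > th.full_pcc
        and anova.f_stats["DAY"] > crit_day
        and anova.f_stats["DAY:GENE"] < crit_sync
    ):
        return "developmental"
    return "none"


# ---------------------------------------------------------------------------
# CEIN construction over the interactome
# ---------------------------------------------------------------------------


@dataclass
class CoexpressionLink:
    """One classified interactome edge."""

    pair: tuple[str, str]  # sorted
    link_type: str
    correlations: PairCorrelations
    anova: PairAnova | None


@dataclass
class CeinResult:
    """All classified links plus per-type summary statistics."""

    links: list[CoexpressionLink]
    summary: pd.DataFrame  # columns: link_type, n_genes, n_links

    def of_type(self, link_type: str) -> list[CoexpressionLink]:
        return [l for l in self.links if l.link_type == link_type]

    def edges_of_type(self, link_type: str) -> list[tuple[str, str]]:
        return [l.pair for l in self.of_type(link_type)]


def build_ceins(
    expr: ExpressionData,
    net: nx.Graph,
    th: LinkThresholds | None = None,
) -> CeinResult:
    """Classify every interactome edge whose both genes are measured.

    Returns all links (including type ``none``) plus a per-type summary:
    number of links and number of distinct endpoint genes.
    """
    th = th or LinkThresholds()
    measured = set(expr.values.index)
    shared = measured & set(net.nodes)
    if not shared:
        raise ConsistencyError(
            "interactome and expression matrix share no genes"
        )
    arrays = _ExprArrays(expr)
    links: list[CoexpressionLink] = []
    for a, b in sorted(tuple(sorted(e)) for e in net.edges()):
        if a not in measured or b not in measured:
            continue
        ia, ib = arrays.index[a], arrays.index[b]
        corr = arrays.correlations(ia, ib)
        anova = arrays.anova(ia, ib) if corr.defined else None
        link_type = classify_link(corr, anova, th)
        links.append(
            CoexpressionLink(
                pair=(a, b), link_type=link_type, correlations=corr, anova=anova
            )
        )
    rows = []
    for lt in LINK_TYPES:
        of_type = [l for l in links if l.link_type == lt]
        genes = set()
        for l in of_type:
            genes.update(l.pair)
        rows.append({"link_type": lt, "n_genes": len(genes), "n_links": len(of_type)})
    summary = pd.DataFrame(rows, columns=["link_type", "n_genes", "n_links"])
    return CeinResult(links=links, summary=summary)


# ---------------------------------------------------------------------------
# CEIN edge-list I/O
# ---------------------------------------------------------------------------


def links_to_frame(links: Iterable[CoexpressionLink]) -> pd.DataFrame:
    rows = []
    for l in links:
        row = {
            "geneA": l.pair[0],
            "geneB": l.pair[1],
            "link_type": l.link_type,
            "pcc_treat": l.correlations.pcc_treat,
            "pcc_control": l.correlations.pcc_control,
            "pcc_all": l.correlations.pcc_all,
        }
        for eff in EFFECTS:
            row[f"F_{eff.replace(':', 'x')}"] = (
                l.anova.f_stats[eff] if l.anova is not None else float("nan")
            )
        rows.append(row)
    cols = ["geneA", "geneB", "link_type", "pcc_treat", "pcc_control", "pcc_all"] + [
        f"F_{e.replace(':', 'x')}" for e in EFFECTS
    ]
    return pd.DataFrame(rows, columns=cols)


def write_cein(links: Iterable[CoexpressionLink], path) -> None:
    links_to_frame(links).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_cein_pairs(path, link_type: str | None = None) -> list[tuple[str, str]]:
    """Read gene pairs back from a CEIN edge TSV, optionally one type only."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"geneA": str, "geneB": str})
    if link_type is not None:
        df = df[df["link_type"] == link_type]
    return [tuple(sorted((a, b))) for a, b in zip(df["geneA"], df["geneB"])]
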