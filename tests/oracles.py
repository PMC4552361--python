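"""Independent reference implementations used only to check the package.

Everything here is deliberately naive — double loops, exhaustive
enumeration, textbook formulas — and shares no code with the implementation
under test.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def brute_temporal_counts(edges, terms_of, day_of, d, dn):
    """Double loop over edges and term pairs; direction follows time."""
    counts = {}
    for g1, g2 in edges:
        for a, b in ((g1, g2), (g2, g1)):
            if day_of.get(a) == d and day_of.get(b) == dn:
                for x in terms_of.get(a, ()):
                    for y in terms_of.get(b, ()):
                        counts[(x, y)] = counts.get((x, y), 0) + 1
    return counts


def brute_condition_counts(edges, terms_of):
    """Double loop over edges and ordered term combinations, unordered key."""
    counts = {}
    for g1, g2 in edges:
        for x in terms_of.get(g1, ()):
            for y in terms_of.get(g2, ()):
                key = tuple(sorted((x, y)))
                counts[key] = counts.get(key, 0) + 1
    return counts


def exact_temporal_pvalues(genes, edges, terms_of, day_of, d, dn):
    """Exact permutation p-values by enumerating every label bijection.

    p(pair) = #{bijections with count >= observed} / n!; the identity
    bijection is included in the enumeration.
    """
    genes = sorted(genes)
    observed = brute_temporal_counts(edges, terms_of, day_of, d, dn)
    exceed = {pair: 0 for pair in observed}
    total = 0
    for perm in permutations(genes):
        assign = dict(zip(genes, perm))  # position -> gene occupying it
        t_of = {pos: terms_of.get(g, ()) for pos, g in assign.items()}
        d_of = {pos: day_of[g] for pos, g in assign.items() if g in day_of}
        counts = brute_temporal_counts(edges, t_of, d_of, d, dn)
        for pair, obs in observed.items():
            if counts.get(pair, 0) >= obs:
                exceed[pair] += 1
        total += 1
    return {pair: exceed[pair] / total for pair in observed}, observed


def exact_condition_pvalues(genes, edges, terms_of):
    """Exact permutation p-values for the undirected condition counting."""
    genes = sorted(genes)
    observed = brute_condition_counts(edges, terms_of)
    exceed = {pair: 0 for pair in observed}
    total = 0
    for perm in permutations(genes):
        assign = dict(zip(genes, perm))
        t_of = {pos: terms_of.get(g, ()) for pos, g in assign.items()}
        counts = brute_condition_counts(edges, t_of)
        for pair, obs in observed.items():
            if counts.get(pair, 0) >= obs:
                exceed[pair] += 1
        total += 1
    return {pair: exceed[pair] / total for pair in observed}, observed


def pearson_closed_form(x, y):
    """Textbook covariance over product of standard deviations (ddof=1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = np.cov(x, y, ddof=1)[0, 1]
    return cov / (x.std(ddof=1) * y.std(ddof=1))


def anova_glm_reference(expr, pair):
    """Seven-effect factorial ANOVA via an independent OLS fit (statsmodels).

    Returns (f_stats, ss) keyed like the implementation's effect names.
    """
    import pandas as pd
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    rows = []
    for gene_idx, gene in enumerate(pair):
        vals = expr.values.loc[gene]
        for sample, v in vals.items():
            des = expr.design.loc[sample]
            rows.append(
                {
                    "y": v,
                    "treat": des["treatment"],
                    "day": str(des["day"]),
                    "gene": f"g{gene_idx}",
                }
            )
    df = pd.DataFrame(rows)
    fit = smf.ols(
        "y ~ C(treat, Sum) * C(day, Sum) * C(gene, Sum)", data=df
    ).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    mapping = {
        "C(treat, Sum)": "TREAT",
        "C(day, Sum)": "DAY",
        "C(gene, Sum)": "GENE",
        "C(treat, Sum):C(day, Sum)": "TREAT:DAY",
        "C(treat, Sum):C(gene, Sum)": "TREAT:GENE",
        "C(day, Sum):C(gene, Sum)": "DAY:GENE",
        "C(treat, Sum):C(day, Sum):C(gene, Sum)": "TREAT:DAY:GENE",
    }
    f_stats = {}
    ss = {}
    for row_name, eff in mapping.items():
        f_stats[eff] = float(table.loc[row_name, "F"])
        ss[eff] = float(table.loc[row_name, "sum_sq"])
    ss["RESID"] = float(table.loc["Residual", "sum_sq"])
    return f_stats, ss
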