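import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gogonet as gg
from gogonet.coexpression import EFFECTS, LinkThresholds, links_to_frame
from gogonet.types import TREATED, CONTROL, ConsistencyError, ExpressionData

from oracles import anova_glm_reference, pearson_closed_form


def make_expr(values, n_days=4, n_reps=4, seed=None):
    """ExpressionData from a genes × 32 matrix (or random if None)."""
    rows = []
    for treatment in (TREATED, CONTROL):
        for day in (2, 4, 6, 7)[:n_days]:
            for rep in range(1, n_reps + 1):
                rows.append((f"{treatment[0]}{day}r{rep}", treatment, day, rep))
    design = pd.DataFrame(rows, columns=["sample", "treatment", "day", "replicate"])
    if values is None:
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(2, len(design)))
    values = np.asarray(values, dtype=float)
    frame = pd.DataFrame(
        values, index=[f"g{i}" for i in range(values.shape[0])],
        columns=design["sample"],
    )
    return ExpressionData(values=frame, design=design)


class TestPcc:
    def test_self_and_anti_correlation(self):
        v = np.array([1.0, 2.0, 5.0, 3.0])
        assert gg.pcc(v, v) == pytest.approx(1.0, abs=1e-12)
        assert gg.pcc(v, -v) == pytest.approx(-1.0, abs=1e-12)

    def test_textbook_example(self):
        x, y = (1, 2, 3, 4), (1, 3, 2, 5)
        assert gg.pcc(x, y) == pytest.approx(pearson_closed_form(x, y), abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_closed_form_and_scipy(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 40))
        x, y = rng.normal(size=n), rng.normal(size=n)
        r = gg.pcc(x, y)
        assert r == pytest.approx(pearson_closed_form(x, y), abs=1e-12)
        assert r == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=15), rng.normal(size=15)
        r = gg.pcc(x, y)
        assert gg.pcc(3.5 * x + 2.0, y) == pytest.approx(r, abs=1e-12)
        assert gg.pcc(-2.0 * x + 1.0, y) == pytest.approx(-r, abs=1e-12)
        assert gg.pcc(y, x) == pytest.approx(r, abs=1e-12)

    def test_constant_vector_undefined(self):
        assert np.isnan(gg.pcc([1, 1, 1, 1], [1, 2, 3, 4]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gg.pcc([1, 2, 3], [1, 2])


class TestPairCorrelations:
    def test_identical_genes(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=32)
        expr = make_expr(np.vstack([x, x]))
        c = gg.pair_correlations(expr, ("g0", "g1"))
        assert c.pcc_treat == pytest.approx(1.0)
        assert c.pcc_control == pytest.approx(1.0)
        assert c.pcc_all == pytest.approx(1.0)

    def test_treated_only_correlation(self):
        """Copying only the treated half gives pcc_treat=1, small pcc_control."""
        rng = np.random.default_rng(1)
        abs_controls = []
        for _ in range(300):
            x = rng.normal(size=32)
            y = x.copy()
            y[16:] = rng.normal(size=16)  # control columns are independent
            expr = make_expr(np.vstack([x, y]))
            c = gg.pair_correlations(expr, ("g0", "g1"))
            assert c.pcc_treat == pytest.approx(1.0)
            abs_controls.append(abs(c.pcc_control))
        assert np.mean(abs_controls) < 0.3

    def test_constant_condition_flagged(self):
        x = np.concatenate([np.ones(16), np.random.default_rng(2).normal(size=16)])
        y = np.random.default_rng(3).normal(size=32)
        expr = make_expr(np.vstack([x, y]))
        c = gg.pair_correlations(expr, ("g0", "g1"))
        assert np.isnan(c.pcc_treat)
        assert not c.defined

    def test_missing_gene_named(self):
        expr = make_expr(None, seed=4)
        with pytest.raises(ConsistencyError, match="gX"):
            gg.pair_correlations(expr, ("g0", "gX"))


class TestPairAnova:
    def test_df_bookkeeping(self):
        expr = make_expr(None, seed=5)
        a = gg.pair_anova(expr, ("g0", "g1"))
        nums = [a.df[e][0] for e in EFFECTS]
        assert nums == [1, 3, 1, 3, 1, 3, 3]
        assert a.residual_df == 48
        assert all(a.df[e][1] == 48 for e in EFFECTS)

    def test_pure_treatment_contrast(self):
        """A treated-vs-control shift loads on F_TREAT far above other effects."""
        rng = np.random.default_rng(6)
        for _ in range(20):
            noise = rng.normal(0, 0.05, size=(2, 32))
            contrast = np.where(np.arange(32) < 16, 1.0, -1.0)
            expr = make_expr(noise + contrast)
            a = gg.pair_anova(expr, ("g0", "g1"))
            assert a.f_stats["TREAT"] == max(a.f_stats.values())
            others = [a.f_stats[e] for e in EFFECTS if e != "TREAT"]
            assert a.f_stats["TREAT"] > 100 * max(others)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_glm_reference(self, seed):
        expr = make_expr(None, seed=seed)
        a = gg.pair_anova(expr, ("g0", "g1"))
        ref_f, ref_ss = anova_glm_reference(expr, ("g0", "g1"))
        for eff in EFFECTS:
            assert a.f_stats[eff] == pytest.approx(ref_f[eff], rel=1e-8)
            assert a.ss[eff] == pytest.approx(ref_ss[eff], rel=1e-8)
        assert a.ss["RESID"] == pytest.approx(ref_ss["RESID"], rel=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_ss_decomposition_sums_to_total(self, seed):
        expr = make_expr(None, seed=100 + seed)
        a = gg.pair_anova(expr, ("g0", "g1"))
        total = sum(a.ss[e] for e in EFFECTS) + a.ss["RESID"]
        assert total == pytest.approx(a.ss["TOTAL"], rel=1e-10)

    def test_unbalanced_rejected(self):
        expr = make_expr(None, seed=8)
        drop = expr.design.index[0]  # removes one replicate from one cell
        unbalanced = ExpressionData(
            values=expr.values.drop(columns=[drop]),
            design=expr.design.drop(index=[drop]).reset_index(),
        )
        assert not unbalanced.balanced
        with pytest.raises(ConsistencyError, match="balanced"):
            gg.pair_anova(unbalanced, ("g0", "g1"))


def fake_anova(f_values, n_days=4, residual_df=48):
    from gogonet.coexpression import PairAnova

    nums = {"TREAT": 1, "DAY": n_days - 1, "GENE": 1, "TREAT:DAY": n_days - 1,
            "TREAT:GENE": 1, "DAY:GENE": n_days - 1, "TREAT:DAY:GENE": n_days - 1}
    f = {e: 0.0 for e in EFFECTS}
    f.update(f_values)
    return PairAnova(
        f_stats=f,
        df={e: (nums[e], residual_df) for e in EFFECTS},
        residual_df=residual_df,
    )


def corr(t, c, a):
    from gogonet.coexpression import PairCorrelations

    return PairCorrelations(pcc_treat=t, pcc_control=c, pcc_all=a)


class TestClassifyLink:
    th = LinkThresholds()

    def test_condition_specific_case(self):
        """0.95 vs 0.20 with a significant treatment effect: diff 0.789 > 0.6."""
        link = gg.classify_link(
            corr(0.95, 0.20, 0.5), fake_anova({"TREAT": 50.0}), self.th
        )
        assert link == "treatment_specific"

    def test_small_difference_not_condition_specific(self):
        """0.95 vs 0.80: normalised diff 0.158 < 0.6 falls through."""
        link = gg.classify_link(
            corr(0.95, 0.80, 0.5), fake_anova({"TREAT": 50.0}), self.th
        )
        assert link == "none"

    def test_developmental_case(self):
        crit_day = stats.f.ppf(0.95, 3, 48)
        crit_sync = stats.f.ppf(0.80, 3, 48)
        a = fake_anova({"DAY": crit_day + 1.0, "DAY:GENE": crit_sync - 0.1})
        assert gg.classify_link(corr(0.3, 0.2, 0.95), a, self.th) == "developmental"

    def test_developmental_needs_synchrony(self):
        crit_day = stats.f.ppf(0.95, 3, 48)
        crit_sync = stats.f.ppf(0.80, 3, 48)
        a = fake_anova({"DAY": crit_day + 1.0, "DAY:GENE": crit_sync + 1.0})
        assert gg.classify_link(corr(0.3, 0.2, 0.95), a, self.th) == "none"

    def test_control_specific_by_argmax(self):
        link = gg.classify_link(
            corr(0.10, -0.95, 0.2), fake_anova({"TREAT:GENE": 50.0}), self.th
        )
        assert link == "control_specific"

    def test_anova_gate_required(self):
        assert gg.classify_link(corr(0.95, 0.1, 0.3), fake_anova({}), self.th) == "none"

    def test_signed_full_pcc_as_default(self):
        crit_day = stats.f.ppf(0.95, 3, 48)
        a = fake_anova({"DAY": crit_day + 1.0})
        assert gg.classify_link(corr(0.3, 0.2, -0.95), a, self.th) == "none"
        th_abs = LinkThresholds(abs_full_pcc=True)
        assert gg.classify_link(corr(0.3, 0.2, -0.95), a, th_abs) == "developmental"

    def test_undefined_correlation_is_none(self):
        assert gg.classify_link(
            corr(float("nan"), 0.1, 0.2), fake_anova({"TREAT": 50.0}), self.th
        ) == "none"

    def test_exact_tie_not_condition_specific(self):
        link = gg.classify_link(
            corr(0.95, -0.95, 0.0), fake_anova({"TREAT": 50.0}), self.th
        )
        assert link == "none"

    def test_paper_df_changes_critical_value(self):
        """F(0.95;1,19)=4.381 vs F(0.95;1,48)=4.043: F=4.2 passes only actual df."""
        assert stats.f.ppf(0.95, 1, 19) == pytest.approx(4.3807, abs=1e-3)
        a = fake_anova({"TREAT": 4.2})
        c = corr(0.95, 0.1, 0.3)
        assert gg.classify_link(c, a, LinkThresholds()) == "treatment_specific"
        assert gg.classify_link(c, a, LinkThresholds(paper_df=True)) == "none"

    def test_pure_function(self):
        c, a = corr(0.95, 0.2, 0.5), fake_anova({"TREAT": 50.0})
        assert gg.classify_link(c, a, self.th) == gg.classify_link(c, a, self.th)


class TestBuildCeins:
    def test_zero_shared_genes_rejected(self):
        expr = make_expr(None, seed=9)
        net = nx.Graph()
        net.add_edge("x1", "x2")
        with pytest.raises(ConsistencyError, match="share"):
            gg.build_ceins(expr, net)

    def test_summary_counts_match_links(self, small_fixture):
        cfg, paths = small_fixture
        from gogonet import io as gio

        net = gio.read_network(paths["network"])
        expr = gio.read_expression(paths["expression"], paths["design"])
        result = gg.build_ceins(expr, net)
        for lt in ("treatment_specific", "control_specific", "developmental", "none"):
            links = result.of_type(lt)
            genes = {g for l in links for g in l.pair}
            row = result.summary[result.summary["link_type"] == lt].iloc[0]
            assert row["n_links"] == len(links)
            assert row["n_genes"] == len(genes)

    def test_null_expression_rarely_classified(self):
        """i.i.d. noise: well under 1% of edges get a non-none label."""
        rng = np.random.default_rng(11)
        n_genes = 120
        genes = [f"g{i}" for i in range(n_genes)]
        rows = []
        for treatment in (TREATED, CONTROL):
            for day in (2, 4, 6, 7):
                for rep in range(1, 5):
                    rows.append((f"{treatment[0]}{day}r{rep}", treatment, day, rep))
        design = pd.DataFrame(rows, columns=["sample", "treatment", "day", "replicate"])
        values = pd.DataFrame(
            rng.normal(size=(n_genes, 32)), index=genes, columns=design["sample"]
        )
        expr = ExpressionData(values=values, design=design)
        net = nx.random_regular_graph(4, n_genes, seed=13)
        net = nx.relabel_nodes(net, {i: genes[i] for i in net.nodes})
        result = gg.build_ceins(expr, net)
        n_assigned = sum(1 for l in result.links if l.link_type != "none")
        assert n_assigned / len(result.links) < 0.01

    def test_cein_tsv_roundtrip(self, tmp_path):
        expr = make_expr(None, seed=14)
        net = nx.Graph()
        net.add_edge("g0", "g1")
        result = gg.build_ceins(expr, net)
        path = tmp_path / "cein.tsv"
        from gogonet.coexpression import read_cein_pairs, write_cein

        write_cein(result.links, path)
        pairs = read_cein_pairs(path)
        assert pairs == [("g0", "g1")]
        frame = links_to_frame(result.links)
        assert set(frame.columns) >= {"geneA", "geneB", "link_type", "pcc_treat"}
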