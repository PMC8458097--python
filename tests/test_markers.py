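"""Wilcoxon marker rules, moderated differential expression, enrichment."""

import itertools
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from cryptomics.core import ValidationError
from cryptomics.markers import (
    bulk_regulated_sets,
    gene_set_enrichment,
    lineage_markers,
    moderated_de,
    state_markers,
    wilcoxon_z,
)
from .conftest import make_expression

DATA = Path(__file__).parent / "data"


def exact_rank_sum_p(x, y, z_obs):
    """Brute-force two-sided P of the rank-sum statistic by enumeration."""
    pooled = np.concatenate([x, y])
    n, N = len(x), len(pooled)
    ranks = st.rankdata(pooled)
    W_obs = ranks[:n].sum()
    mu = n * (N + 1) / 2.0
    ws = [sum(ranks[list(c)]) for c in itertools.combinations(range(N), n)]
    ws = np.array(ws)
    return float(np.mean(np.abs(ws - mu) >= abs(W_obs - mu) - 1e-12))


class TestWilcoxonZ:
    def test_separated_groups_closed_form(self):
        # W = 15, mu = 10.5, sigma^2 = 3*3*7/12 = 5.25
        z = wilcoxon_z([4, 5, 6], [1, 2, 3])
        assert z == pytest.approx(4.5 / np.sqrt(5.25), abs=1e-12)
        assert z == pytest.approx(1.964, abs=5e-4)

    def test_antisymmetric_under_group_swap(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=5)
        assert wilcoxon_z(x, y) == pytest.approx(-wilcoxon_z(y, x), abs=1e-12)

    def test_all_tied_gives_zero(self):
        assert wilcoxon_z([1, 1, 1], [1, 1, 1]) == 0.0

    def test_empty_group_error(self):
        with pytest.raises(ValidationError):
            wilcoxon_z([], [1.0])

    @pytest.mark.parametrize("n,m", [(3, 3), (4, 5), (6, 6), (2, 6)])
    def test_z_p_close_to_exact_enumeration(self, n, m, rng):
        """Normal-approximation P tracks the exact permutation P for small n."""
        for _ in range(5):
            x, y = rng.normal(size=n), rng.normal(1.0, 1.0, size=m)
            z = wilcoxon_z(x, y)
            p_normal = 2 * st.norm.sf(abs(z))
            p_exact = exact_rank_sum_p(x, y, z)
            # discreteness of the exact null dominates at these sizes
            assert abs(p_normal - p_exact) <= 0.24

    def test_matches_scipy_mannwhitney_with_ties(self, rng):
        x = rng.integers(0, 4, 30).astype(float)
        y = rng.integers(0, 4, 25).astype(float)
        z = wilcoxon_z(x, y)
        ref = st.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                              use_continuity=False)
        assert 2 * st.norm.sf(abs(z)) == pytest.approx(ref.pvalue, abs=1e-12)


def _three_state_expression(rng, per_state=30, n_genes=50):
    labels = pd.Series(
        ["A"] * per_state + ["B"] * per_state + ["C"] * per_state,
        index=[f"c{i}" for i in range(3 * per_state)],
    )
    values = rng.normal(0.0, 0.3, (3 * per_state, n_genes))
    return values, labels


class TestStateMarkers:
    def test_noiseless_construction(self, rng):
        values, labels = _three_state_expression(rng)
        values[:30, 0] += 5.0  # gene g0 high only in state A
        out = state_markers(make_expression(values), labels, z_min=5, top_n=10)
        a_markers = out.loc[out["state"] == "A", "gene"].tolist()
        assert "g0" in a_markers
        assert "g1" not in out["gene"].tolist()  # uniform gene never a marker

    def test_rule_requires_every_pairwise_test(self, rng):
        values, labels = _three_state_expression(rng)
        values[:60, 0] += 5.0  # g0 high in A and B: separates neither from the other
        out = state_markers(make_expression(values), labels, z_min=5, top_n=10)
        assert "g0" not in out["gene"].tolist()

    def test_infinite_threshold_empty(self, rng):
        values, labels = _three_state_expression(rng)
        out = state_markers(make_expression(values), labels, z_min=np.inf)
        assert len(out) == 0

    def test_cell_order_invariance(self, rng):
        values, labels = _three_state_expression(rng)
        values[:30, :3] += 4.0
        expr = make_expression(values)
        out1 = state_markers(expr, labels, z_min=4, top_n=10)
        perm = rng.permutation(len(labels))
        expr2 = make_expression(values[perm], cell_ids=[labels.index[i] for i in perm])
        out2 = state_markers(expr2, labels, z_min=4, top_n=10)
        pd.testing.assert_frame_equal(out1, out2)

    def test_small_state_excluded_with_warning(self, rng):
        values, labels = _three_state_expression(rng)
        labels.iloc[:28] = "A"
        labels.iloc[28:30] = "tiny"
        with pytest.warns(UserWarning, match="tiny"):
            state_markers(make_expression(values), labels, z_min=5)


class TestLineageMarkers:
    def _expr(self, rng):
        """A -> B lineage plus outgroup C; g0 shared by A and B, absent in C."""
        values, labels = _three_state_expression(rng)
        values[:60, 0] += 5.0
        return make_expression(values), labels

    def test_later_stage_excluded_from_tests(self, rng):
        expr, labels = self._expr(rng)
        out = lineage_markers(expr, labels, stage_order=[("A", "B")], z_min=5, top_n=10)
        a_markers = out.loc[out["state"] == "A", "gene"].tolist()
        assert "g0" in a_markers  # A tested only against C

    def test_empty_order_reduces_to_state_markers(self, rng):
        expr, labels = self._expr(rng)
        a = lineage_markers(expr, labels, stage_order=[], z_min=3, top_n=15)
        b = state_markers(expr, labels, z_min=3, top_n=15)
        pd.testing.assert_frame_equal(a, b)

    def test_cyclic_order_rejected(self, rng):
        expr, labels = self._expr(rng)
        with pytest.raises(ValidationError, match="cyclic"):
            lineage_markers(expr, labels, stage_order=[("A", "B"), ("B", "A")])

    def test_hand_enumerated_toy(self, rng):
        """Three populations, hand-worked expected marker sets."""
        per = 20
        labels = pd.Series(
            ["A"] * per + ["B"] * per + ["C"] * per,
            index=[f"c{i}" for i in range(3 * per)],
        )
        values = rng.normal(0, 0.2, (3 * per, 6))
        values[:per, 0] += 4.0          # g0: A only           -> state & lineage marker of A
        values[: 2 * per, 1] += 4.0     # g1: A and B          -> lineage marker of A only
        values[per : 2 * per, 2] += 4.0  # g2: B only          -> marker of B
        values[2 * per :, 3] += 4.0     # g3: C only           -> marker of C
        expr = make_expression(values)
        state = state_markers(expr, labels, z_min=5, top_n=3)
        lineage = lineage_markers(expr, labels, stage_order=[("A", "B")], z_min=5, top_n=3)

        def genes_of(table, s):
            return set(table.loc[table["state"] == s, "gene"])

        assert genes_of(state, "A") == {"g0"}
        assert genes_of(lineage, "A") == {"g0", "g1"}
        assert genes_of(state, "B") == genes_of(lineage, "B") == {"g2"}
        assert genes_of(state, "C") == genes_of(lineage, "C") == {"g3"}


@pytest.fixture(scope="module")
def limma_fixture():
    x = pd.read_csv(DATA / "limma_input.csv", index_col=0)
    expr = make_expression(x.values.T, cell_ids=x.columns.tolist(),
                           gene_ids=x.index.tolist())
    cond = pd.Series(["A"] * 6 + ["B"] * 6, index=x.columns)
    return expr, cond


class TestModeratedDE:
    def test_constant_prior_matches_limma_exactly(self, limma_fixture):
        expr, cond = limma_fixture
        mine = moderated_de(expr, cond, trend=False)
        oracle = pd.read_csv(DATA / "limma_oracle_trendF.csv")
        assert mine["d0"].iloc[0] == pytest.approx(oracle["d0"].iloc[0], abs=1e-9)
        for col in ("logFC", "t", "P"):
            assert np.allclose(mine[col].values, oracle[col].values, atol=1e-9)

    def test_trend_mode_close_to_limma(self, limma_fixture):
        """The trend smoother differs from limma's, so agreement is loose."""
        expr, cond = limma_fixture
        mine = moderated_de(expr, cond, trend=True)
        oracle = pd.read_csv(DATA / "limma_oracle_trendT.csv")
        assert np.allclose(mine["logFC"], oracle["logFC"], atol=1e-9)
        assert np.corrcoef(mine["t"], oracle["t"])[0, 1] > 0.999
        assert np.max(np.abs(mine["P"] - oracle["P"])) < 0.05

    def test_d0_zero_equals_ordinary_t(self, rng):
        values = rng.normal(size=(20, 40))
        expr = make_expression(values)
        cond = pd.Series(["X"] * 10 + ["Y"] * 10, index=expr.cell_ids)
        mine = moderated_de(expr, cond, d0_override=0.0)
        t_ref, p_ref = st.ttest_ind(values[10:], values[:10], axis=0, equal_var=True)
        assert np.allclose(mine["t"].values, t_ref, atol=1e-9)
        assert np.allclose(mine["P"].values, p_ref, atol=1e-9)

    def test_large_d0_shrinks_to_trend(self, rng):
        values = rng.normal(size=(30, 50))
        expr = make_expression(values)
        cond = pd.Series(["X"] * 15 + ["Y"] * 15, index=expr.cell_ids)
        out = moderated_de(expr, cond, d0_override=1e12, trend=False)
        assert out["s2_post"].std() / out["s2_post"].mean() < 1e-3

    def test_small_lfc_not_flagged_despite_tiny_fdr(self):
        """A shift below the logFC threshold is never called, however significant."""
        n = 40
        base = np.zeros((2 * n, 30))
        base[n:, 0] = 0.05  # real but tiny shift, zero noise elsewhere tiny
        rng = np.random.default_rng(0)
        base += rng.normal(0, 0.01, base.shape)
        expr = make_expression(base)
        cond = pd.Series(["X"] * n + ["Y"] * n, index=expr.cell_ids)
        out = moderated_de(expr, cond).set_index("gene")
        assert out.loc["g0", "FDR"] < 1e-6
        assert abs(out.loc["g0", "logFC"]) < 0.1
        assert not out.loc["g0", "flagged"]

    def test_bh_matches_brute_force_definition(self, rng):
        """BH on <= 20 P-values against the step-up definition."""
        p = rng.random(17)
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(p, method="fdr_bh")[1]
        m = len(p)
        order = np.argsort(p)
        brute = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            brute[i] = running
        assert np.allclose(adj, brute, atol=1e-12)

    def test_single_condition_stratum_skipped(self, rng):
        values = rng.normal(size=(12, 8))
        expr = make_expression(values)
        cond = pd.Series(["X"] * 6 + ["Y"] * 6, index=expr.cell_ids)
        strata = pd.Series(["s1"] * 6 + ["s2"] * 6, index=expr.cell_ids)
        with pytest.raises(ValidationError):
            with pytest.warns(UserWarning, match="single condition"):
                moderated_de(expr, cond, strata=strata)


class TestBulkRegulatedSets:
    def _bulk(self, mean_a, mean_b, rng, n_rep=3, noise=0.01):
        genes = [f"g{i}" for i in range(len(mean_a))]
        cols = [f"a{j}" for j in range(n_rep)] + [f"b{j}" for j in range(n_rep)]
        a = np.array(mean_a)[:, None] * np.exp(rng.normal(0, noise, (len(genes), n_rep)))
        b = np.array(mean_b)[:, None] * np.exp(rng.normal(0, noise, (len(genes), n_rep)))
        tab = pd.DataFrame(np.hstack([a, b]), index=genes, columns=cols)
        groups = pd.Series(["A"] * n_rep + ["B"] * n_rep, index=cols)
        return tab, groups

    def test_printed_rule_boundaries(self, rng):
        tab, groups = self._bulk(
            [10, 100, 100, 50], [20, 120, 200, 50.5], rng
        )
        out = bulk_regulated_sets(tab, groups).set_index("gene")
        assert not out.loc["g0", "regulated"]  # FC 2, but both means <= 32
        assert not out.loc["g1", "regulated"]  # FC 1.2 <= 1.3
        assert out.loc["g2", "regulated"]      # FC 2, P tiny, means > 32
        assert not out.loc["g3", "regulated"]  # FC ~1.01

    def test_too_few_replicates_error(self, rng):
        tab, groups = self._bulk([100], [200], rng, n_rep=1)
        with pytest.raises(ValidationError):
            bulk_regulated_sets(tab, groups)


class TestEnrichment:
    def test_fully_contained_query_hypergeometric_oracle(self):
        background = [f"g{i}" for i in range(100)]
        query = {g: 1.0 for g in background[:10]}
        sets = {"target": background[:10]}
        out = gene_set_enrichment(query, sets, background)
        # brute-force hypergeometric: P(overlap >= 10) with N=100, K=10, n=10
        from math import comb

        p_exact = sum(
            comb(10, k) * comb(90, 10 - k) for k in range(10, 11)
        ) / comb(100, 10)
        row = out.set_index("set").loc["target"]
        assert row["n_overlap"] == 10
        assert row["P"] == pytest.approx(p_exact, rel=1e-9)
        assert row["mean_abs_logFC"] == 1.0

    def test_two_sided_matches_scipy_fisher(self, rng):
        background = [f"g{i}" for i in range(60)]
        query = {g: rng.normal() for g in background[:20]}
        sets = {"s": background[10:35]}
        out = gene_set_enrichment(query, sets, background).set_index("set")
        a = len(set(background[10:35]) & set(query))
        table = [[a, 20 - a], [25 - a, 60 - 25 - (20 - a)]]
        assert out.loc["s", "P"] == pytest.approx(st.fisher_exact(table)[1], rel=1e-12)

    def test_disjoint_set_skipped_and_empty_query_error(self):
        background = ["a", "b", "c"]
        out = gene_set_enrichment({"a": 1.0}, {"gone": ["x", "y"]}, background)
        assert len(out) == 0
        with pytest.raises(ValidationError):
            gene_set_enrichment({}, {"s": ["a"]}, background)

    def test_null_query_rarely_significant(self, rng):
        background = [f"g{i}" for i in range(200)]
        sets = {f"s{k}": list(rng.choice(background, 20, replace=False)) for k in range(15)}
        n_sig = 0
        for rep in range(20):
            query = {g: 1.0 for g in rng.choice(background, 25, replace=False)}
            out = gene_set_enrichment(query, sets, background)
            n_sig += int((out["FDR"] < 0.05).sum())
        assert n_sig <= 3
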