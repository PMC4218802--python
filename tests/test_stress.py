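"""Stress-gene accumulation, the log fit, pruning, and the Spearman network."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from metaratio.stress import (
    StressAccumulationPoint,
    correlation_network,
    export_network,
    fit_log_curve,
    prune_matrix,
    read_edge_tsv,
    stress_accumulation,
)

from conftest import matrix_from_frame


# ---------------------------------------------------------------------------
# Independent oracles


def midranks(values):
    """Mid-rank assignment computed by explicit enumeration."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_spearman(x, y):
    """Rank both vectors by hand, then Pearson on the ranks, then the
    t-approximation p-value on n-2 degrees of freedom."""
    from scipy.stats import t as t_dist

    rx, ry = midranks(list(x)), midranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    rho = cov / math.sqrt(vx * vy)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    return rho, 2 * t_dist.sf(abs(t), n - 2)


def brute_bh(pvals):
    """Benjamini-Hochberg step-up by direct enumeration."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = min(prev, pvals[i] * m / rank_from_end)
        adj[i] = val
        prev = val
    return adj


def species_matrix(data, index):
    return matrix_from_frame(pd.DataFrame(data, index=index).astype("int64"))


# ---------------------------------------------------------------------------


class TestAccumulation:
    def test_set_union_of_stress_types(self, catalog):
        df = pd.DataFrame(
            {
                "RuBisCo": [1, 1, 0],
                "orange carotenoid protein": [2, 0, 1],
                "superoxide dismutase": [0, 3, 5],
            },
            index=["A sp.", "B sp.", "C sp."],
        )
        points = {p.function_label: p for p in stress_accumulation(matrix_from_frame(df), catalog)}
        rubisco = points["RuBisCo"]
        assert rubisco.richness == 2
        assert rubisco.n_stress_types == 2  # ocp from A, sod from B

    def test_absent_gene_scores_zero_zero(self, catalog):
        df = pd.DataFrame({"orange carotenoid protein": [1]}, index=["A sp."])
        points = {p.function_label: p for p in stress_accumulation(matrix_from_frame(df), catalog)}
        assert (points["amoA"].richness, points["amoA"].n_stress_types) == (0, 0)

    def test_invariant_zero_richness_implies_zero_stress(self):
        with pytest.raises(ValueError):
            StressAccumulationPoint("g", "DNA", 0, 2)

    @given(st.integers(min_value=0, max_value=30))
    def test_adding_a_species_never_decreases_s(self, catalog, extra_stress):
        base = pd.DataFrame(
            {"RuBisCo": [1, 1], "catalase": [1, 0]}, index=["A sp.", "B sp."]
        )
        grown = base.copy()
        grown.loc["C sp."] = [1, 1 if extra_stress % 2 else 0]
        s_base = {
            p.function_label: p.n_stress_types
            for p in stress_accumulation(matrix_from_frame(base), catalog)
        }
        s_grown = {
            p.function_label: p.n_stress_types
            for p in stress_accumulation(matrix_from_frame(grown), catalog)
        }
        assert all(s_grown[g] >= s_base[g] for g in s_base)


class TestLogFit:
    def pts(self, pairs):
        return [StressAccumulationPoint(f"g{i}", "DNA", r, s) for i, (r, s) in enumerate(pairs)]

    def test_exact_interpolation(self):
        # S = 2 ln R + 1 interpolated exactly through three points
        pts = [
            StressAccumulationPoint("a", "DNA", 1, 1),
            StressAccumulationPoint("b", "DNA", 10, 2 * math.log(10) + 1),
            StressAccumulationPoint("c", "DNA", 100, 2 * math.log(100) + 1),
        ]
        fit = fit_log_curve(pts)
        assert fit.a == pytest.approx(2.0, abs=1e-9)
        assert fit.b == pytest.approx(1.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_s_gives_zero_slope(self):
        fit = fit_log_curve(self.pts([(1, 4), (10, 4), (100, 4)]))
        assert fit.a == pytest.approx(0.0, abs=1e-12)
        assert fit.b == pytest.approx(4.0, abs=1e-12)

    def test_noisy_recovery_matches_closed_form_least_squares(self):
        rng = np.random.default_rng(23)
        r = rng.integers(1, 400, size=50)
        s = 3.0 * np.log(r) + 2.0 + rng.normal(0, 0.1, size=50)
        pts = [
            StressAccumulationPoint(f"g{i}", "DNA", int(ri), float(si))
            for i, (ri, si) in enumerate(zip(r, s))
        ]
        fit = fit_log_curve(pts)
        # independent closed-form least squares
        x = np.log(r.astype(float))
        a_hat = np.cov(x, s, ddof=0)[0, 1] / np.var(x)
        b_hat = s.mean() - a_hat * x.mean()
        assert fit.a == pytest.approx(a_hat, abs=1e-9)
        assert fit.b == pytest.approx(b_hat, abs=1e-9)
        assert 2.8 <= fit.a <= 3.2

    def test_zero_richness_points_excluded(self):
        fit = fit_log_curve(self.pts([(0, 0), (1, 1), (10, 3)]))
        assert fit.n_points == 2 and fit.n_excluded_zero_richness == 1

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_log_curve(self.pts([(5, 2)]))
        with pytest.raises(ValueError):
            fit_log_curve(self.pts([(5, 2), (5, 3)]))


class TestPruning:
    def test_single_gene_species_removed(self, catalog):
        df = pd.DataFrame(
            {
                "RuBisCo": [1, 1, 1],
                "nitrogenase": [0, 1, 1],
                "catalase": [5, 0, 1],
            },
            index=["X sp.", "Y sp.", "Z sp."],
        )
        pruned = prune_matrix(matrix_from_frame(df), catalog)
        assert "X sp." not in pruned.counts.index  # only one functional gene
        assert set(pruned.counts.index) == {"Y sp.", "Z sp."}

    def test_sequential_gene_removal_after_species_removal(self, catalog):
        # X carries only amoA; after X is dropped, amoA survives in only Y
        df = pd.DataFrame(
            {
                "amoA": [1, 1, 0],
                "RuBisCo": [0, 1, 1],
                "nitrogenase": [0, 1, 1],
            },
            index=["X sp.", "Y sp.", "Z sp."],
        )
        pruned = prune_matrix(matrix_from_frame(df), catalog)
        assert "X sp." not in pruned.counts.index
        assert "amoA" not in pruned.counts.columns

    def test_stress_genes_never_column_pruned(self, catalog):
        df = pd.DataFrame(
            {
                "RuBisCo": [1, 1],
                "nitrogenase": [1, 1],
                "catalase": [1, 0],  # present in one species only
            },
            index=["Y sp.", "Z sp."],
        )
        pruned = prune_matrix(matrix_from_frame(df), catalog)
        assert "catalase" in pruned.counts.columns

    def test_fixed_point_matrix_unchanged(self, catalog):
        df = pd.DataFrame(
            {"RuBisCo": [1, 2], "nitrogenase": [3, 1]}, index=["Y sp.", "Z sp."]
        )
        pruned = prune_matrix(matrix_from_frame(df), catalog)
        pd.testing.assert_frame_equal(pruned.counts, df.astype("int64"))


class TestNetwork:
    def test_perfect_monotone_pair_retained(self, catalog):
        df = pd.DataFrame(
            {
                "RuBisCo": [1, 2, 3, 4, 5],
                "nitrogenase": [2, 2, 3, 3, 4],
                "catalase": [2, 4, 6, 8, 10],
            },
            index=[f"t{i} sp." for i in range(5)],
        )
        net = correlation_network(matrix_from_frame(df), catalog, alpha=0.05)
        pairs = {(e.functional_gene, e.stress_gene): e for e in net.edges}
        assert ("RuBisCo", "catalase") in pairs
        assert pairs[("RuBisCo", "catalase")].rho == pytest.approx(1.0)

    def test_constant_vector_flagged_not_tested(self, catalog):
        df = pd.DataFrame(
            {"RuBisCo": [1, 2, 3], "nitrogenase": [2, 1, 3], "catalase": [4, 4, 4]},
            index=[f"t{i} sp." for i in range(3)],
        )
        net = correlation_network(matrix_from_frame(df), catalog)
        assert net.n_zero_variance == 2  # catalase against both functional genes
        assert all(e.stress_gene != "catalase" for e in net.edges)

    def test_rho_and_p_match_brute_force_to_1e12(self, catalog):
        rng = np.random.default_rng(29)
        for _ in range(8):
            n = int(rng.integers(4, 11))
            df = pd.DataFrame(
                {
                    "RuBisCo": rng.integers(0, 6, n),
                    "nitrogenase": rng.integers(0, 6, n),
                    "catalase": rng.integers(0, 6, n),
                    "photolyase": rng.integers(0, 6, n),
                },
                index=[f"t{i} sp." for i in range(n)],
            )
            net = correlation_network(matrix_from_frame(df), catalog, alpha=1.0)
            for e in net.edges:
                rho, p = brute_spearman(df[e.functional_gene], df[e.stress_gene])
                assert e.rho == pytest.approx(rho, abs=1e-12)
                assert e.p_raw == pytest.approx(p, abs=1e-12)

    def test_bh_adjustment_matches_brute_force(self, catalog):
        rng = np.random.default_rng(31)
        n = 12
        cols = {"RuBisCo": rng.integers(0, 9, n), "nitrogenase": rng.integers(0, 9, n),
                "amoA": rng.integers(0, 9, n)}
        cols.update({s: rng.integers(0, 9, n) for s in
                     ["catalase", "photolyase", "trehalose synthase"]})
        df = pd.DataFrame(cols, index=[f"t{i} sp." for i in range(n)])
        net = correlation_network(matrix_from_frame(df), catalog, alpha=1.0)
        pvals = [e.p_raw for e in net.edges]
        assert len(pvals) == net.n_pairs_tested  # alpha=1 retains all tested pairs w/ sharing
        adj = brute_bh(pvals)
        for e, expected in zip(net.edges, adj):
            assert e.p_adj == pytest.approx(expected, abs=1e-12)
            assert e.p_adj >= e.p_raw - 1e-15

    def test_edges_only_between_cooccurring_genes(self, catalog):
        rng = np.random.default_rng(37)
        n = 10
        df = pd.DataFrame(
            {
                "RuBisCo": rng.integers(0, 3, n),
                "nitrogenase": rng.integers(0, 3, n),
                "catalase": rng.integers(0, 3, n),
            },
            index=[f"t{i} sp." for i in range(n)],
        )
        net = correlation_network(matrix_from_frame(df), catalog, alpha=1.0)
        for e in net.edges:
            both = (df[e.functional_gene] > 0) & (df[e.stress_gene] > 0)
            assert e.shared_species == int(both.sum()) and e.shared_species >= 1

    def test_too_few_species_rejected(self, catalog):
        df = pd.DataFrame({"RuBisCo": [1, 2], "catalase": [2, 1]}, index=["a sp.", "b sp."])
        with pytest.raises(ValueError):
            correlation_network(matrix_from_frame(df), catalog)


class TestExports:
    def _net(self, catalog):
        df = pd.DataFrame(
            {
                "RuBisCo": [1, 2, 3, 4, 5],
                "nitrogenase": [5, 3, 4, 1, 2],
                "catalase": [2, 4, 6, 8, 10],
                "orange carotenoid protein": [1, 3, 2, 5, 4],
            },
            index=[f"t{i} sp." for i in range(5)],
        )
        return correlation_network(matrix_from_frame(df), catalog, alpha=1.0)

    def test_edge_tsv_round_trip(self, catalog, tmp_path):
        net = self._net(catalog)
        path = tmp_path / "edges.tsv"
        export_network(net, path, "edge_tsv")
        assert read_edge_tsv(path) == net.edges

    def test_empty_network_writes_header_only(self, catalog, tmp_path):
        from metaratio.stress import GeneNetwork

        path = tmp_path / "empty.tsv"
        export_network(GeneNetwork(), path, "edge_tsv")
        assert path.read_text().strip() == read_header(path)

    def test_graphml_preserves_node_attributes(self, catalog, tmp_path):
        import networkx as nx

        net = self._net(catalog)
        path = tmp_path / "net.graphml"
        export_network(net, path, "graphml")
        back = nx.read_graphml(path)
        assert set(back.nodes) == set(net.nodes)
        assert back.nodes["catalase"]["node_type"] == "stress"
        assert back.nodes["catalase"]["stress_category"] == "oxidative"
        assert back.nodes["orange carotenoid protein"]["stress_category"] == "UV"
        assert back.number_of_edges() == len(net.edges)

    def test_sif_uses_corr_interaction(self, catalog, tmp_path):
        net = self._net(catalog)
        path = tmp_path / "net.sif"
        export_network(net, path, "sif")
        lines = [l.split("\t") for l in path.read_text().splitlines() if "\t" in l]
        assert lines and all(parts[1] == "corr" for parts in lines)

    def test_unknown_format_rejected(self, catalog, tmp_path):
        with pytest.raises(ValueError):
            export_network(self._net(catalog), tmp_path / "x", "gexf")


def read_header(path):
    with open(path) as fh:
        return fh.readline().strip()
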