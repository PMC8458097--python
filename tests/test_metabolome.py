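"""Spectrum peak statistics, pathway topology, Ward clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch
import scipy.stats as st

from cryptomics.core import ValidationError
from cryptomics.metabolome import (
    annotate_masses,
    discriminative_masses,
    exclude_isotopes,
    pathway_enrichment,
    pick_peaks,
    ward_cluster,
)
from cryptomics.simulate import SpectrumSet, simulate_spectra


GRID = np.linspace(250.0, 350.0, 500001)  # 0.2 mDa spacing


def _single_peak_set(height, noise_sd, seed=0, n=4, width=0.01):
    return simulate_spectra(
        n // 2, GRID, [{"mz": 300.0, "heights": (height, height), "width": width,
                        "isotope": False}],
        noise_sd=noise_sd, seed=seed,
    )


class TestPickPeaks:
    def test_strong_peak_detected(self):
        ss = _single_peak_set(height=10.0, noise_sd=1.0)
        peaks = pick_peaks(ss)
        assert len(peaks) >= 1
        apex = peaks.iloc[(peaks["mz"] - 300.0).abs().argmin()]
        assert apex["mz"] == pytest.approx(300.0, abs=0.001)
        assert apex["snr"] >= 4

    def test_weak_peak_rejected(self):
        # mean-spectrum noise sigma is ~0.5, so a height-1 line sits far
        # below the SNR-4 threshold even after riding on noise maxima
        ss = _single_peak_set(height=1.0, noise_sd=1.0, width=0.0004)
        peaks = pick_peaks(ss)
        near = peaks.loc[(peaks["mz"] - 300.0).abs() < 0.01] if len(peaks) else peaks
        assert len(near) == 0

    def test_grid_coarser_than_min_width_error(self):
        coarse = np.linspace(100.0, 900.0, 1000)
        ss = SpectrumSet(coarse, np.ones((2, 1000)), ["a", "b"])
        with pytest.raises(ValidationError, match="coarser"):
            pick_peaks(ss)

    def test_rescaling_invariance(self):
        ss = _single_peak_set(height=12.0, noise_sd=1.0, seed=3)
        p1 = pick_peaks(ss)
        scaled = SpectrumSet(ss.mz, ss.intensities * 37.0, ss.groups)
        p2 = pick_peaks(scaled)
        assert np.allclose(p1["mz"].values, p2["mz"].values)

    def test_mz_shift_shifts_apexes(self):
        ss = _single_peak_set(height=12.0, noise_sd=1.0, seed=4)
        p1 = pick_peaks(ss)
        shifted = SpectrumSet(ss.mz + 5.0, ss.intensities, ss.groups)
        p2 = pick_peaks(shifted)
        assert np.allclose(p2["mz"].values, p1["mz"].values + 5.0)


def _peak_frame(rows):
    """rows: (mz, mean_intensity) -> minimal PeakTable."""
    df = pd.DataFrame(
        {
            "mz": [r[0] for r in rows],
            "height": [r[1] for r in rows],
            "intensity_0": [r[1] for r in rows],
            "intensity_1": [r[1] for r in rows],
            "isotope": False,
        }
    )
    return df


class TestExcludeIsotopes:
    def test_satellite_removed(self):
        peaks = _peak_frame([(300.0, 100.0), (301.00335, 30.0)])
        out = exclude_isotopes(peaks)
        assert out["mz"].tolist() == [300.0]
        assert out.attrs["n_isotopes_removed"] == 1

    def test_more_intense_companion_kept(self):
        peaks = _peak_frame([(300.0, 100.0), (301.00335, 150.0)])
        out = exclude_isotopes(peaks)
        assert len(out) == 2

    def test_cascade_removes_whole_chain(self):
        peaks = _peak_frame(
            [(300.0, 100.0), (301.00335, 30.0), (302.0067, 9.0)]
        )
        out = exclude_isotopes(peaks)
        assert out["mz"].tolist() == [300.0]


class TestDiscriminativeMasses:
    def _table(self, means_a, means_b, noise, rng, n=4):
        rows = {"mz": np.arange(len(means_a)) + 100.0}
        for j in range(n):
            grp = means_a if j < n // 2 else means_b
            rows[f"intensity_{j}"] = np.asarray(grp) * np.exp(rng.normal(0, noise, len(grp)))
        df = pd.DataFrame(rows)
        groups = ["CD"] * (n // 2) + ["HF"] * (n - n // 2)
        return df, groups

    def test_strong_fold_change_passes(self, rng):
        df, groups = self._table([10.0], [30.0], 0.01, rng)
        out = discriminative_masses(df, groups)
        assert bool(out["pass"].iloc[0])
        assert out["direction"].iloc[0] == "enriched"

    def test_fc_below_threshold_fails_regardless_of_p(self, rng):
        df, groups = self._table([10.0], [15.0], 0.001, rng)
        out = discriminative_masses(df, groups)
        assert out["P"].iloc[0] < 0.01  # highly significant...
        assert not bool(out["pass"].iloc[0])  # ...but FC 1.5 < 2

    def test_pass_counts_decompose(self, rng):
        df, groups = self._table(
            [10, 10, 30, 40, 5], [30, 11, 10, 41, 20], 0.01, rng
        )
        out = discriminative_masses(df, groups)
        assert out.attrs["n_pass"] == out.attrs["n_enriched"] + out.attrs["n_depleted"]
        assert out.attrs["n_enriched"] == 2 and out.attrs["n_depleted"] == 1

    def test_pooled_t_matches_scipy(self, rng):
        df, groups = self._table([20.0], [25.0], 0.2, rng, n=8)
        out = discriminative_masses(df, groups)
        cols = [c for c in df.columns if c.startswith("intensity_")]
        x = df[cols].values[0]
        ref = st.ttest_ind(x[:4], x[4:], equal_var=True)
        assert out["P"].iloc[0] == pytest.approx(ref.pvalue, rel=1e-12)

    def test_single_sample_group_error(self, rng):
        df, groups = self._table([10.0], [30.0], 0.01, rng, n=2)
        with pytest.raises(ValidationError):
            discriminative_masses(df, groups)


class TestAnnotateMasses:
    DB = pd.DataFrame(
        {"id": ["m1", "m2", "m3"], "name": ["x", "y", "z"],
         "exact_mass": [500.0015, 500.0025, 500.0010]}
    )

    def test_ppm_rule_and_sorting(self):
        peaks = _peak_frame([(500.0000, 10.0)])
        out = annotate_masses(peaks, self.DB, ppm_max=4.0)
        # 3.0 ppm and 2.0 ppm match (sorted by error), 5.0 ppm does not
        assert out["annotation"].iloc[0] == "m3:2.00;m1:3.00"

    def test_empty_db_error(self):
        with pytest.raises(ValidationError):
            annotate_masses(_peak_frame([(500.0, 1.0)]), pd.DataFrame(), 4.0)


def brute_force_betweenness(nodes, edges):
    """All-pairs shortest-path counting by explicit path enumeration."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    btw = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            frac = sum(1 for p in paths if v in p) / len(paths)
            btw[v] += frac
    return btw


class TestPathwayEnrichment:
    def test_path_graph_middle_node_impact_one(self):
        graph = {"pw": {"nodes": ["A", "B", "C"], "edges": [["A", "B"], ["B", "C"]]}}
        out = pathway_enrichment({"B"}, graph, {"A", "B", "C", "D", "E"})
        assert out["impact"].iloc[0] == pytest.approx(1.0)

    def test_full_hit_set_impact_one(self):
        graph = {"pw": {"nodes": ["A", "B", "C", "D"],
                        "edges": [["A", "B"], ["B", "C"], ["C", "D"], ["A", "C"]]}}
        out = pathway_enrichment({"A", "B", "C", "D"}, graph, {"A", "B", "C", "D", "X"})
        assert out["impact"].iloc[0] == pytest.approx(1.0)

    def test_hypergeometric_tail_vs_summation(self):
        from math import comb

        universe = {f"m{i}" for i in range(50)}
        nodes = [f"m{i}" for i in range(5)]
        hits = {f"m{i}" for i in range(2, 12)}  # 10 hits, overlap 3 with pathway
        graph = {"pw": {"nodes": nodes, "edges": []}}
        out = pathway_enrichment(hits, graph, universe)
        k = len(set(nodes) & hits)
        p_exact = sum(
            comb(5, j) * comb(45, 10 - j) for j in range(k, 6)
        ) / comb(50, 10)
        assert out["P"].iloc[0] == pytest.approx(p_exact, rel=1e-9)

    def test_impact_matches_brute_force_on_small_graphs(self, rng):
        nodes = list("abcdefgh")
        for trial in range(5):
            edges = [
                [a, b] for a, b in itertools.combinations(nodes, 2)
                if rng.random() < 0.3
            ]
            hits = {n for n in nodes if rng.random() < 0.4}
            graph = {"pw": {"nodes": nodes, "edges": edges}}
            out = pathway_enrichment(hits, graph, set(nodes) | {"zz"})
            btw = brute_force_betweenness(nodes, [tuple(e) for e in edges])
            total = sum(btw.values())
            expected = (
                sum(btw[n] for n in hits) / total if total > 0
                else len(hits) / len(nodes)
            )
            assert out["impact"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_singleton_pathway(self):
        graph = {"pw": {"nodes": ["A"], "edges": []}}
        hit = pathway_enrichment({"A"}, graph, {"A", "B"})
        miss = pathway_enrichment({"B"}, graph, {"A", "B"})
        assert hit["impact"].iloc[0] == 1.0
        assert miss["impact"].iloc[0] == 0.0

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ValidationError):
            pathway_enrichment({"Q"}, {"pw": {"nodes": ["A"], "edges": []}}, {"A"})


class TestWardCluster:
    def test_three_point_merge_order(self):
        Z = ward_cluster(np.array([[0.0], [1.0], [10.0]]))
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}  # closest pair first
        assert Z[0, 2] == pytest.approx(1.0)

    def test_duplicate_rows_merge_at_zero_first(self, rng):
        X = rng.normal(size=(5, 3))
        X[3] = X[1]
        Z = ward_cluster(X)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {1, 3}
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_heights_nondecreasing(self, rng):
        Z = ward_cluster(rng.normal(size=(12, 4)))
        assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_matches_scipy_reference_on_random_matrices(self, rng):
        for _ in range(5):
            X = rng.normal(size=(10, 4))
            Z_mine = ward_cluster(X)
            Z_ref = sch.linkage(X, method="ward")
            assert np.allclose(np.sort(Z_mine[:, 2]), np.sort(Z_ref[:, 2]), atol=1e-9)
            # identical tree structure: compare cophenetic distances
            c_mine = sch.cophenet(Z_mine)
            c_ref = sch.cophenet(Z_ref)
            assert np.allclose(np.sort(c_mine), np.sort(c_ref), atol=1e-9)

    def test_nan_rejected(self):
        with pytest.raises(ValidationError):
            ward_cluster(np.array([[0.0], [np.nan]]))
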