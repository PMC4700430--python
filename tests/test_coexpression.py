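"""Spearman edges, thresholds, networks, hubs and the normality screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bloodtx.coexpression import (build_network, compare_networks,
                                  count_significant, hubs, normality_screen,
                                  pair_correlations, rho_threshold,
                                  spearman_p, spearman_rho)
from bloodtx.datatypes import ProbeAnnotation
from bloodtx.preprocess import preprocess_pipeline
from bloodtx.simulate import SynthConfig, generate_dataset
from conftest import make_matrix, make_samples


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.array([1.0, 2.5, 3.0, 7.0, 9.0])
        assert spearman_rho(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman_rho(x, -(x ** 3)) == pytest.approx(-1.0)

    def test_ties_match_midrank_reference(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 5, 12).astype(float)  # many ties
            y = rng.integers(0, 5, 12).astype(float)
            ref = sps.spearmanr(x, y).statistic
            if np.isnan(ref):
                continue
            assert spearman_rho(x, y) == pytest.approx(ref, abs=1e-12)

    def test_constant_vector_is_missing(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(spearman_rho(np.ones(5), np.arange(5.0)))

    def test_p_formula_and_monotonicity(self):
        assert spearman_p(0.0, 14) == 1.0
        rhos = np.linspace(0.05, 0.99, 30)
        ps = [spearman_p(r, 14) for r in rhos]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        # symmetric in sign
        assert spearman_p(-0.8, 10) == spearman_p(0.8, 10)

    def test_p_against_brute_force_t_tail(self):
        rng = np.random.default_rng(1)
        for n in (8, 14, 20):
            for _ in range(10):
                x, y = rng.normal(size=(2, n))
                rho = spearman_rho(x, y)
                t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
                ref = 2 * sps.t.sf(abs(t), n - 2)
                assert spearman_p(rho, n) == pytest.approx(ref, rel=1e-10)

    def test_rho_097_at_n14_is_1e_minus_8(self):
        p = spearman_p(0.97, 14)
        assert p == pytest.approx(1e-8, rel=0.5)


class TestRhoThreshold:
    def test_reproduces_published_correspondence(self):
        assert round(rho_threshold(1e-8, 14), 2) == 0.97

    def test_bisection_contract(self):
        for p_target, n in ((1e-8, 14), (0.01, 14), (0.05, 30)):
            r = rho_threshold(p_target, n)
            assert spearman_p(r, n) <= p_target
            assert spearman_p(r - 1e-4, n) > p_target

    def test_threshold_vanishes_for_large_n(self):
        assert rho_threshold(0.05, 100000) < 0.01

    def test_unreachable_target(self):
        with pytest.raises(ValueError, match="unreachable"):
            rho_threshold(1e-320, 14)


class TestPairCorrelations:
    def test_pair_count_is_m_choose_2(self, small_dataset, small_filtered):
        filt, _ = small_filtered
        probes = small_dataset.truth.module_probes
        edges = pair_correlations(filt, probes, small_dataset.samples, "control")
        m = len(probes)
        assert len(edges) == m * (m - 1) // 2
        assert (edges["probe_i"] < edges["probe_j"]).all()

    def test_two_probes_one_edge(self, small_dataset, small_filtered):
        filt, _ = small_filtered
        probes = small_dataset.truth.module_probes[:2]
        edges = pair_correlations(filt, probes, small_dataset.samples, "case")
        assert len(edges) == 1

    def test_matches_scipy_double_loop(self, samples4):
        rng = np.random.default_rng(2)
        samples = make_samples(5)
        m = make_matrix(rng.normal(size=(10, 10)))
        edges = pair_correlations(m, m.probe_ids.tolist(), samples, "case")
        lookup = {(r.probe_i, r.probe_j): r for r in edges.itertuples()}
        case_ids = samples.case_ids
        probes = sorted(m.probe_ids)
        for i in range(10):
            for j in range(i + 1, 10):
                x = m.values.loc[probes[i], case_ids]
                y = m.values.loc[probes[j], case_ids]
                ref = sps.spearmanr(x, y)
                edge = lookup[(probes[i], probes[j])]
                assert edge.rho == pytest.approx(ref.statistic, abs=1e-10)
                assert edge.p == pytest.approx(ref.pvalue, rel=1e-8)

    def test_constant_probe_missing_and_counted(self):
        samples = make_samples(4)
        vals = np.random.default_rng(3).normal(size=(3, 8))
        vals[0] = 5.0
        m = make_matrix(vals)
        edges = pair_correlations(m, m.probe_ids.tolist(), samples, "case")
        assert edges.attrs["n_missing"] == 2
        assert edges["rho"].isna().sum() == 2

    def test_counts_monotone_in_alpha(self, small_dataset, small_filtered):
        filt, _ = small_filtered
        edges = pair_correlations(filt, small_dataset.truth.module_probes,
                                  small_dataset.samples, "control")
        counts = [count_significant(edges, a) for a in (1.0, 0.01, 0.001, 1e-8)]
        assert counts == sorted(counts, reverse=True)
        assert counts[0] == len(edges) - edges["rho"].isna().sum()

    def test_planted_disruption_control_exceeds_case(self, small_dataset,
                                                     small_filtered):
        filt, _ = small_filtered
        probes = small_dataset.truth.module_probes
        case = pair_correlations(filt, probes, small_dataset.samples, "case")
        ctrl = pair_correlations(filt, probes, small_dataset.samples, "control")
        assert count_significant(ctrl, 0.01) > 2 * count_significant(case, 0.01)


def _edges(rows):
    return pd.DataFrame(rows, columns=["probe_i", "probe_j", "rho", "p"])


class TestNetwork:
    def _ann(self, mapping):
        return ProbeAnnotation(pd.DataFrame(
            {"gene_symbol": list(mapping.values())},
            index=pd.Index(list(mapping.keys()), name="probe_id")))

    def test_threshold_below_all_gives_empty_graph(self):
        e = _edges([("a", "b", 0.9, 1e-3)])
        g = build_network(e, 1e-9, suppress_same_gene=False)
        assert g.number_of_nodes() == 0 and g.number_of_edges() == 0

    def test_same_gene_edge_suppression(self):
        e = _edges([("a", "b", 0.99, 1e-12), ("a", "c", 0.98, 1e-10)])
        ann = self._ann({"a": "G1", "b": "G1", "c": "G2"})
        g_on = build_network(e, 1e-8, ann, suppress_same_gene=True)
        assert set(map(tuple, map(sorted, g_on.edges))) == {("a", "c")}
        g_off = build_network(e, 1e-8, ann, suppress_same_gene=False)
        assert g_off.number_of_edges() == 2

    def test_gene_collapse_merges_probes(self):
        e = _edges([("a", "c", 0.99, 1e-12), ("b", "c", 0.98, 1e-10)])
        ann = self._ann({"a": "G1", "b": "G1", "c": "G2"})
        g = build_network(e, 1e-8, ann, suppress_same_gene=True,
                          collapse_genes=True)
        assert set(g.nodes) == {"G1", "G2"}
        assert g.number_of_edges() == 1

    def test_planted_module_recovered_in_controls(self, tight_module_dataset):
        ds, filt = tight_module_dataset
        probes = ds.truth.module_probes
        ctrl = pair_correlations(filt, probes, ds.samples, "control")
        g = build_network(ctrl, 1e-8, ds.annotation)
        # scaled-down planted recovery: most module probes should appear
        assert g.number_of_nodes() >= 0.8 * len(probes)

    def test_hubs_star_graph(self):
        rows = [("hub", f"x{i}", 0.99, 1e-12) for i in range(6)]
        g = build_network(_edges(rows), 1e-8, suppress_same_gene=False)
        assert hubs(g, 6) == ["hub"]
        assert hubs(g, 7) == []

    def test_empty_graph_no_hubs(self):
        import networkx as nx
        assert hubs(nx.Graph(), 1) == []


class TestCompare:
    def test_identical_groups_all_common(self):
        e = _edges([("a", "b", 0.99, 1e-12), ("b", "c", 0.9, 0.5)])
        comp = compare_networks(e, e.copy(), thresholds=(0.01,),
                                suppress_same_gene=False)
        assert comp.case_specific == set() and comp.control_specific == set()
        assert comp.common_edges == {("a", "b")}

    def test_disjoint_edge_sets(self):
        e1 = _edges([("a", "b", 0.99, 1e-12), ("b", "c", 0.1, 0.9)])
        e2 = _edges([("a", "b", 0.1, 0.9), ("b", "c", 0.99, 1e-12)])
        comp = compare_networks(e1, e2, suppress_same_gene=False)
        assert comp.common_edges == set()
        assert comp.case_specific == {("a", "b")}
        assert comp.control_specific == {("b", "c")}

    def test_mismatched_universe_rejected(self):
        e1 = _edges([("a", "b", 0.5, 0.5)])
        e2 = _edges([("a", "c", 0.5, 0.5)])
        with pytest.raises(ValueError, match="different pairs"):
            compare_networks(e1, e2)

    def test_planted_disruption_summary(self, tight_module_dataset):
        ds, filt = tight_module_dataset
        probes = ds.truth.module_probes
        case = pair_correlations(filt, probes, ds.samples, "case")
        ctrl = pair_correlations(filt, probes, ds.samples, "control")
        comp = compare_networks(case, ctrl, annotation=ds.annotation)
        counts = comp.counts
        assert (counts["control"] >= counts["case"]).all()
        assert len(comp.control_specific) > len(comp.case_specific)
        # hub recovery: the densely wired control module yields hub nodes
        assert comp.control_hubs and not comp.case_hubs


class TestNormalityScreen:
    def test_heavy_tailed_probes_flagged(self):
        rng = np.random.default_rng(9)
        samples = make_samples(14)
        gauss = rng.normal(size=(30, 28))
        heavy = rng.standard_cauchy(size=(10, 28)) * 5
        m = make_matrix(np.vstack([gauss, heavy]))
        count, table = normality_screen(m, m.probe_ids.tolist(), samples)
        heavy_ids = m.probe_ids[30:]
        assert table.loc[heavy_ids, "non_normal"].mean() >= 0.5
        false_flags = table.loc[m.probe_ids[:30], "non_normal"].mean()
        assert false_flags <= 0.25  # ~2 x 5% per-group tests

    def test_constant_probe_degenerate_not_counted(self):
        samples = make_samples(4)
        vals = np.random.default_rng(10).normal(size=(2, 8))
        vals[0] = 3.0
        m = make_matrix(vals)
        count, table = normality_screen(m, m.probe_ids.tolist(), samples)
        assert bool(table.iloc[0]["degenerate"]) is True
        assert not table.iloc[0]["non_normal"]

    def test_count_invariant_to_probe_order(self):
        rng = np.random.default_rng(11)
        samples = make_samples(5)
        m = make_matrix(rng.normal(size=(12, 10)))
        ids = m.probe_ids.tolist()
        c1, _ = normality_screen(m, ids, samples)
        c2, _ = normality_screen(m, ids[::-1], samples)
        assert c1 == c2
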