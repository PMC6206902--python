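"""CNC network: correlations, edge rules, degree selection, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cncnet.diffexpr import differential_expression
from cncnet.matrix import ExpressionMatrix
from cncnet.network import (build_cnc_network, cross_class_correlations,
                            pearson_r, select_mrnas_by_degree)
from cncnet.targets import TargetTable


def _corr_rows(rows):
    return pd.DataFrame(
        [{"gene_a": a, "gene_b": b, "class_a": ca, "class_b": cb,
          "r": r, "n_samples": 6} for a, b, ca, cb, r in rows])


def _de_rows(rows):
    return pd.DataFrame(
        [{"gene_id": g, "gene_class": c, "log2fc": 1.0 if d == "up" else -1.0,
          "t_stat": 0.0, "p_value": 0.01, "direction": d, "significant": True}
         for g, c, d in rows])


def _cand_rows(rows):
    return pd.DataFrame(
        [{"gene_id": g, "direction": d, "n_up_mirnas": 0, "n_down_mirnas": 1}
         for g, d in rows])


def _pairs(rows):
    return pd.DataFrame(
        [{"mirna_id": m, "target_id": t, "target_class": "mRNA",
          "best_score": 200.0, "best_energy": -30.0, "site_count": 1}
         for m, t in rows])


class TestPearsonR:
    def test_closed_forms(self):
        x = np.array([1.0, 2, 3, 4])
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)
        assert pearson_r(x, [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2], [3, 4])


class TestCrossClassCorrelations:
    def test_one_gene_per_class_gives_three_records(self, rng):
        vals = rng.normal(8, 1, size=(3, 6))
        genes = ["m1", "l1", "g1"]
        m = ExpressionMatrix(
            pd.DataFrame(np.exp2(vals), index=genes, columns=[f"s{i}" for i in range(6)]),
            gene_class=pd.Series(["miRNA", "lncRNA", "mRNA"], index=genes),
            groups=pd.Series(["control"] * 3 + ["induced"] * 3,
                             index=[f"s{i}" for i in range(6)]),
        )
        out = cross_class_correlations(m, {"miRNA": ["m1"], "lncRNA": ["l1"],
                                           "mRNA": ["g1"]})
        assert len(out) == 3
        assert (out["n_samples"] == 6).all()

    def test_within_class_pairs_skipped(self, small_bundle):
        m = small_bundle.matrix
        out = cross_class_correlations(
            m, {"miRNA": m.genes_of_class("miRNA")[:4], "lncRNA": [], "mRNA": []})
        assert out.empty

    def test_planted_pairs_strongly_anticorrelated(self, small_bundle):
        m = small_bundle.matrix
        truth = small_bundle.truth
        out = cross_class_correlations(
            m, {"miRNA": [p.mirna for p in truth.target_pairs],
                "mRNA": [p.gene for p in truth.target_pairs]})
        idx = out.set_index(["gene_a", "gene_b"])["r"]
        for p in truth.target_pairs:
            key = tuple(sorted([p.mirna, p.gene]))
            assert idx[key] < -0.9

    def test_constant_gene_excluded_with_warning(self, caplog, rng):
        vals = np.exp2(rng.normal(8, 1, size=(3, 6)))
        vals[0] = 7.0
        genes = ["m1", "l1", "g1"]
        m = ExpressionMatrix(
            pd.DataFrame(vals, index=genes, columns=[f"s{i}" for i in range(6)]),
            gene_class=pd.Series(["miRNA", "lncRNA", "mRNA"], index=genes),
            groups=pd.Series(["control"] * 3 + ["induced"] * 3,
                             index=[f"s{i}" for i in range(6)]),
        )
        with caplog.at_level("WARNING"):
            out = cross_class_correlations(m, {"miRNA": ["m1"], "lncRNA": ["l1"],
                                               "mRNA": ["g1"]})
        assert len(out) == 1  # only the l1-g1 pair survives
        assert "constant profile" in caplog.text

    def test_symmetric_in_gene_order(self, small_bundle):
        m = small_bundle.matrix
        t = small_bundle.truth
        a = cross_class_correlations(m, {"miRNA": [t.target_pairs[0].mirna],
                                         "mRNA": [t.target_pairs[0].gene]})
        b = cross_class_correlations(m, {"mRNA": [t.target_pairs[0].gene],
                                         "miRNA": [t.target_pairs[0].mirna]})
        pd.testing.assert_frame_equal(a, b)

    def test_null_high_correlation_rate_matches_analytic(self, rng):
        """At n=6 independent samples the fraction of |r| > 0.9 matches the
        exact null Pearson distribution within Monte-Carlo error."""
        n_pairs, n = 10_000, 6
        x = rng.normal(size=(n_pairs, n))
        y = rng.normal(size=(n_pairs, n))
        xc = x - x.mean(1, keepdims=True)
        yc = y - y.mean(1, keepdims=True)
        r = (xc * yc).sum(1) / np.sqrt((xc ** 2).sum(1) * (yc ** 2).sum(1))
        frac = float((np.abs(r) > 0.9).mean())
        t_crit = 0.9 * np.sqrt(n - 2) / np.sqrt(1 - 0.81)
        p0 = float(2 * stats.t.sf(t_crit, n - 2))
        se = np.sqrt(p0 * (1 - p0) / n_pairs)
        assert abs(frac - p0) < 4 * se


class TestBuildNetwork:
    TOY_CORRS = _corr_rows([
        ("lnc1", "mrna1", "lncRNA", "mRNA", +0.95),   # kept
        ("mir1", "mrna1", "miRNA", "mRNA", -0.95),    # kept (supported)
        ("mir1", "lnc1", "miRNA", "lncRNA", -0.92),   # kept
        ("lnc1", "mrna2", "lncRNA", "mRNA", +0.5),    # below threshold
        ("mir1", "mrna2", "miRNA", "mRNA", -0.91),    # no site support -> dropped
        ("mir2", "lnc1", "miRNA", "lncRNA", +0.93),   # wrong sign -> dropped
        ("lnc2", "mrna1", "lncRNA", "mRNA", -0.94),   # wrong sign -> dropped
    ])
    TOY_DE = _de_rows([("mir1", "miRNA", "down"), ("mir2", "miRNA", "down"),
                       ("lnc1", "lncRNA", "up"), ("lnc2", "lncRNA", "up")])
    TOY_CAND = _cand_rows([("mrna1", "up"), ("mrna2", "up")])
    TOY_TARGETS = TargetTable(pairs=_pairs([("mir1", "mrna1")]))

    def _build(self, threshold=0.9):
        return build_cnc_network(self.TOY_CORRS, self.TOY_TARGETS,
                                 self.TOY_DE, self.TOY_CAND, threshold=threshold)

    def test_toy_edge_set_by_rule_enumeration(self):
        net = self._build()
        edges = {frozenset(e) for e in net.graph.edges}
        assert edges == {frozenset({"lnc1", "mrna1"}),
                         frozenset({"mir1", "mrna1"}),
                         frozenset({"mir1", "lnc1"})}

    def test_threshold_one_gives_no_edges(self):
        assert self._build(threshold=1.0).graph.number_of_edges() == 0

    def test_empty_correlations_valid(self):
        net = build_cnc_network(pd.DataFrame(columns=self.TOY_CORRS.columns),
                                self.TOY_TARGETS, self.TOY_DE, self.TOY_CAND)
        assert net.graph.number_of_edges() == 0

    def test_edge_law_holds_exhaustively(self, small_bundle):
        from cncnet.targets import infer_candidate_directions, predict_targets

        de = differential_expression(small_bundle.matrix)
        mirnas = {g: small_bundle.mirna_seqs[g]
                  for g in de[(de.gene_class == "miRNA") & de.significant]["gene_id"]}
        targets = predict_targets(mirnas, small_bundle.utrs)
        cand = infer_candidate_directions(de[de.gene_class == "miRNA"], targets)
        corrs = cross_class_correlations(small_bundle.matrix, {
            "miRNA": sorted(de[(de.gene_class == "miRNA") & de.significant]["gene_id"]),
            "lncRNA": sorted(de[(de.gene_class == "lncRNA") & de.significant]["gene_id"]),
            "mRNA": sorted(cand["gene_id"]),
        })
        net = build_cnc_network(corrs, targets, de, cand)
        net.assert_edge_law(targets)  # raises on any violation
        assert net.graph.number_of_edges() > 0

    def test_handshake(self):
        net = self._build()
        degs = [net.graph.degree(n) for n in net.graph.nodes]
        assert sum(degs) == 2 * net.graph.number_of_edges()

    def test_direction_only_mrna_mode(self):
        """Without measured mRNA profiles, miRNA-mRNA edges come from the
        target table plus opposite predicted directions, with r absent."""
        corrs = _corr_rows([("mir1", "lnc1", "miRNA", "lncRNA", -0.92)])
        net = build_cnc_network(corrs, self.TOY_TARGETS, self.TOY_DE,
                                self.TOY_CAND, mrna_measured=False)
        assert frozenset({"mir1", "mrna1"}) in {frozenset(e) for e in net.graph.edges}
        assert np.isnan(net.graph.edges["mir1", "mrna1"]["r"])


class TestSelectByDegree:
    def test_hand_counted_degrees(self):
        corrs = _corr_rows([
            ("lnc1", "mrna1", "lncRNA", "mRNA", 0.95),
            ("lnc2", "mrna1", "lncRNA", "mRNA", 0.96),
            ("lnc1", "mrna2", "lncRNA", "mRNA", 0.93),
            ("lnc1", "mrna3", "lncRNA", "mRNA", 0.99),
        ])
        de = _de_rows([("lnc1", "lncRNA", "up"), ("lnc2", "lncRNA", "up")])
        cand = _cand_rows([("mrna1", "up"), ("mrna2", "up"), ("mrna3", "up"),
                           ("mrna4", "up")])
        net = build_cnc_network(corrs, TargetTable(), de, cand)
        out = select_mrnas_by_degree(net, min_degree=1)
        assert list(out["gene_id"]) == ["mrna1", "mrna2", "mrna3"]
        assert list(out["degree"]) == [2, 1, 1]
        # isolated mrna4 excluded at min_degree 1, included at 0
        out0 = select_mrnas_by_degree(net, min_degree=0)
        assert "mrna4" in set(out0["gene_id"])
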