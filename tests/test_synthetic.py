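"""Synthetic-data generator: planted structure, determinism, degenerate cases."""

from dataclasses import replace

import numpy as np
import pytest

from cncnet.synthetic import (SyntheticSpec, reverse_complement, simulate_all,
                              simulate_expression, simulate_genesets,
                              simulate_mirnas, simulate_reference, simulate_utrs)


class TestSpecValidation:
    @pytest.mark.parametrize("kw", [
        {"n_ctrl": 1},
        {"n_induced": 1},
        {"noise_sd": 0.0},
        {"planted_log2fc": -1.0},
        {"de_fraction_per_class": 1.5},
        {"utr_length": 10, "mirna_length": 22},
    ])
    def test_rejects_invalid(self, kw):
        with pytest.raises(ValueError):
            SyntheticSpec(**kw)


class TestSimulateExpression:
    def test_shape_and_labels(self, small_spec, small_bundle):
        m = small_bundle.matrix
        spec = small_spec
        assert m.values.shape == (spec.n_mirna + spec.n_lncrna + spec.n_mrna,
                                  spec.n_ctrl + spec.n_induced)
        assert len(m.genes_of_class("miRNA")) == spec.n_mirna
        assert len(m.samples_in("control")) == spec.n_ctrl

    def test_no_planted_structure_when_disabled(self):
        spec = SyntheticSpec(de_fraction_per_class=0.0, n_target_pairs=0, rng_seed=3)
        _, truth = simulate_expression(spec)
        assert truth.de_genes == {}
        assert truth.target_pairs == []

    def test_deterministic_under_fixed_seed(self, small_spec):
        m1, t1 = simulate_expression(small_spec)
        m2, t2 = simulate_expression(small_spec)
        assert m1.values.equals(m2.values)
        assert t1.de_genes == t2.de_genes

    def test_seed_changes_output(self, small_spec):
        m1, _ = simulate_expression(small_spec)
        m2, _ = simulate_expression(replace(small_spec, rng_seed=small_spec.rng_seed + 1))
        assert not m1.values.equals(m2.values)

    def test_planted_effect_recovers_log2fc(self, small_spec):
        """Monte-Carlo over re-simulations: the mean log2 group difference of
        planted genes matches the planted effect to within 0.05."""
        diffs = []
        for seed in range(200):
            spec = replace(small_spec, n_mirna=4, n_lncrna=4, n_mrna=12,
                           n_target_pairs=2, rng_seed=seed)
            matrix, truth = simulate_expression(spec)
            log2 = np.log2(matrix.values)
            ctrl = log2[matrix.samples_in("control")].mean(axis=1)
            ind = log2[matrix.samples_in("induced")].mean(axis=1)
            for gene, direction in truth.de_genes.items():
                d = ind[gene] - ctrl[gene]
                diffs.append(d if direction == "up" else -d)
        assert np.mean(diffs) == pytest.approx(2.0, abs=0.05)

    def test_direction_law_for_planted_pairs(self, small_bundle):
        truth = small_bundle.truth
        assert truth.target_pairs
        for pair in truth.target_pairs:
            assert truth.de_genes[pair.mirna] != truth.de_genes[pair.gene]

    def test_planted_pairs_anticorrelated(self, small_bundle):
        m = small_bundle.matrix
        log2 = np.log2(m.values)
        for pair in small_bundle.truth.target_pairs:
            r = np.corrcoef(log2.loc[pair.mirna], log2.loc[pair.gene])[0, 1]
            assert r < -0.9

    def test_truth_genes_exist_in_matrix(self, small_bundle):
        ids = set(small_bundle.matrix.gene_ids)
        t = small_bundle.truth
        assert set(t.de_genes) <= ids
        assert {p.mirna for p in t.target_pairs} <= ids
        assert {p.gene for p in t.target_pairs} <= ids


class TestSimulateUtrs:
    def test_planted_site_is_exact_reverse_complement(self, small_bundle):
        for pair in small_bundle.truth.target_pairs:
            utr = small_bundle.utrs[pair.gene]
            site = utr[pair.utr_site_start - 1:pair.utr_site_end]
            assert site == reverse_complement(small_bundle.mirna_seqs[pair.mirna])

    def test_known_reverse_complement(self):
        assert reverse_complement("UGAGGUAG") == "CUACCUCA"

    def test_one_utr_per_mrna_without_pairs(self):
        spec = SyntheticSpec(n_target_pairs=0, rng_seed=5)
        _, truth = simulate_expression(spec)
        utrs = simulate_utrs(spec, truth, simulate_mirnas(spec))
        assert len(utrs) == spec.n_mrna
        assert all(len(u) == spec.utr_length for u in utrs.values())

    def test_missing_mirna_sequence_rejected(self, small_spec):
        _, truth = simulate_expression(small_spec)
        if truth.target_pairs:
            with pytest.raises(ValueError):
                simulate_utrs(small_spec, truth, {})


class TestSimulateGenesets:
    def test_enriched_sets_subset_of_de_when_fraction_one(self, small_spec):
        spec = replace(small_spec, enriched_fraction=1.0, geneset_size=5)
        _, truth = simulate_expression(spec)
        coll = simulate_genesets(spec, truth)
        de = set(truth.de_genes)
        for sid in truth.enriched_sets:
            assert coll.members(sid) <= de

    def test_empty_collection_when_no_sets(self, small_spec):
        spec = replace(small_spec, n_genesets=0)
        _, truth = simulate_expression(spec)
        coll = simulate_genesets(spec, truth)
        assert len(coll) == 0

    def test_planted_set_detected_by_enrichment(self):
        """An enriched set at a representative design point (size 20, fraction 0.5,
        100 DE in 1000 background) comes out significant."""
        from cncnet.enrichment import enrich

        spec = SyntheticSpec(n_mirna=5, n_lncrna=5, n_mrna=1000,
                             de_fraction_per_class=0.1, n_target_pairs=0,
                             n_genesets=6, geneset_size=20,
                             enriched_fraction=0.5, rng_seed=9)
        _, truth = simulate_expression(spec)
        coll = simulate_genesets(spec, truth)
        query = truth.de_of_class("gene", "up")
        res = enrich(query, coll).set_index("set_id")
        planted_up = truth.enriched_sets[0]
        assert res.loc[planted_up, "p_value"] < 0.05

    def test_distinct_collections_per_prefix(self, small_spec):
        _, truth = simulate_expression(small_spec)
        go = simulate_genesets(small_spec, truth, prefix="GO")
        kegg = simulate_genesets(small_spec, truth, prefix="KEGG")
        assert set(go.sets) != set(kegg.sets)


class TestSimulateReference:
    def test_reference_covers_part_of_targets_and_decoys(self, small_bundle):
        truth = small_bundle.truth
        ref = set(small_bundle.reference)
        targets_upper = {g.upper() for g in truth.target_mrnas}
        hits = ref & targets_upper
        assert hits
        assert ref - targets_upper  # decoys present


class TestSimulateAll:
    def test_fully_deterministic(self, small_spec):
        b1 = simulate_all(small_spec)
        b2 = simulate_all(small_spec)
        assert b1.matrix.values.equals(b2.matrix.values)
        assert b1.utrs == b2.utrs
        assert b1.mirna_seqs == b2.mirna_seqs
        assert {k: v for k, v in b1.go_sets.sets.items()} == \
               {k: v for k, v in b2.go_sets.sets.items()}
        assert b1.reference == b2.reference
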