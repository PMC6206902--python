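"""Seeded Smith-Waterman aligner: worked examples, oracle equivalence, laws."""

import numpy as np
import pytest

from cncnet.alignment import (DuplexAlignment, ScoringScheme, normalize_sequence,
                              sw_align_seeded, alignment_has_seed_gap)
from tests._oracles import oracle_best_score, random_scheme


class TestNormalizeSequence:
    @pytest.mark.parametrize("raw, expected", [
        ("acgt", "ACGU"),
        ("UGAGGUAG", "UGAGGUAG"),
        ("  tTgG \n", "UUGG"),
    ])
    def test_normalizes(self, raw, expected):
        assert normalize_sequence(raw) == expected

    @pytest.mark.parametrize("bad", ["ACGN", "AC-G", "", "acxg"])
    def test_rejects_invalid(self, bad):
        with pytest.raises(ValueError):
            normalize_sequence(bad)


class TestScoringScheme:
    def test_defaults_valid(self):
        s = ScoringScheme()
        assert s.match_score > s.mismatch_score
        assert s.wobble_score > s.mismatch_score

    @pytest.mark.parametrize("kw", [
        {"match_score": -3.0, "mismatch_score": 5.0},
        {"wobble_score": -5.0},
        {"gap_open_penalty": 1.0},
        {"seed_start": 8, "seed_end": 2},
        {"seed_scale": 0.5},
    ])
    def test_rejects_invalid(self, kw):
        with pytest.raises(ValueError):
            ScoringScheme(**kw)


class TestWorkedExample:
    """Full 8-mer complement: 8 matches, site at UTR 3..10."""

    MIRNA = "UGAGGUAG"
    UTR = "AACUACCUCAAA"

    def test_unscaled_score_40(self):
        scheme = ScoringScheme(score_threshold=0, seed_scale=1)
        sites = sw_align_seeded(self.MIRNA, self.UTR, scheme)
        assert len(sites) == 1
        aln = sites[0]
        assert aln.score == 40.0
        assert (aln.utr_start, aln.utr_end) == (3, 10)
        assert aln.mirna_aln == "GAUGGAGU"  # 3'->5'
        assert aln.utr_aln == "CUACCUCA"

    def test_seed_scaled_score_145(self):
        # position 1 scores 5; positions 2-8 score 5 x 4 each
        scheme = ScoringScheme(score_threshold=0, seed_scale=4)
        sites = sw_align_seeded(self.MIRNA, self.UTR, scheme)
        assert len(sites) == 1
        assert sites[0].score == 145.0

    def test_mirna_longer_than_utr_yields_no_sites(self):
        scheme = ScoringScheme(score_threshold=0)
        assert sw_align_seeded("UGAGGUAGUA", "ACG", scheme) == []


class TestOracleEquivalence:
    def test_matches_exhaustive_enumeration(self, rng):
        """Best aligner score equals the memoized exhaustive recursion on
        200 random small instances with random schemes."""
        bases = np.array(list("ACGU"))
        checked = 0
        for _ in range(200):
            lm = int(rng.integers(2, 8))
            lu = int(rng.integers(4, 13))
            mirna = "".join(rng.choice(bases, lm))
            utr = "".join(rng.choice(bases, lu))
            scheme = random_scheme(rng, lm)
            sites = sw_align_seeded(mirna, utr, scheme)
            got = sites[0].score if sites else None
            want = oracle_best_score(mirna, utr, scheme)
            assert got == pytest.approx(want) if want is not None else got is None, (
                mirna, utr, scheme)
            checked += 1
        assert checked == 200

    def test_planted_complement_recovers_max_score(self, rng):
        """A full-complement site always aligns at the maximum possible score."""
        from cncnet.synthetic import reverse_complement

        bases = np.array(list("ACGU"))
        scheme = ScoringScheme(score_threshold=0)
        for _ in range(20):
            mirna = "".join(rng.choice(bases, 22))
            flank = "".join(rng.choice(bases, 30))
            utr = flank + reverse_complement(mirna) + flank
            sites = sw_align_seeded(mirna, utr, scheme)
            expected = 5.0 * (22 - 7) + 5.0 * 4 * 7
            assert sites and sites[0].score >= expected


class TestAlignmentLaws:
    def test_seed_law_no_gap_in_seed(self, rng):
        """No emitted alignment carries a gap touching the seed."""
        bases = np.array(list("ACGU"))
        scheme = ScoringScheme(score_threshold=10, seed_scale=2,
                               gap_open_penalty=-2, gap_extend_penalty=-1)
        found_with_gap = 0
        for _ in range(100):
            mirna = "".join(rng.choice(bases, int(rng.integers(8, 12))))
            utr = "".join(rng.choice(bases, 60))
            for aln in sw_align_seeded(mirna, utr, scheme):
                assert not alignment_has_seed_gap(aln, scheme)
                if "-" in aln.mirna_aln + aln.utr_aln:
                    found_with_gap += 1
        assert found_with_gap > 0  # the check above actually saw gapped sites

    def test_score_threshold_law(self, rng):
        bases = np.array(list("ACGU"))
        scheme = ScoringScheme(score_threshold=60)
        for _ in range(30):
            mirna = "".join(rng.choice(bases, 12))
            utr = "".join(rng.choice(bases, 80))
            for aln in sw_align_seeded(mirna, utr, scheme):
                assert aln.score >= scheme.score_threshold

    def test_monotone_under_complementary_flank_extension(self, rng):
        """Appending a complementary flank to both sequences never lowers
        the best score."""
        from cncnet.synthetic import reverse_complement

        bases = np.array(list("ACGU"))
        scheme = ScoringScheme(score_threshold=0, seed_start=2, seed_end=5)
        for _ in range(30):
            mirna = "".join(rng.choice(bases, 8))
            utr = reverse_complement(mirna)
            base_sites = sw_align_seeded(mirna, utr, scheme)
            flank = "".join(rng.choice(bases, 3))
            # extend miRNA 3' end and UTR 5' end with complementary bases
            mirna2 = mirna + flank
            utr2 = reverse_complement(flank) + utr
            new_sites = sw_align_seeded(mirna2, utr2, scheme)
            assert new_sites[0].score >= base_sites[0].score

    def test_non_overlapping_sites(self):
        """Two planted complements in one UTR give two disjoint sites."""
        from cncnet.synthetic import reverse_complement

        mirna = "UGAGGUAGUAGGUU"
        site = reverse_complement(mirna)
        utr = "AAAA" + site + "CCCCGGGGAAAA" + site + "AAAA"
        scheme = ScoringScheme(score_threshold=100)
        sites = sw_align_seeded(mirna, utr, scheme)
        assert len(sites) == 2
        spans = sorted((a.utr_start, a.utr_end) for a in sites)
        assert spans[0][1] < spans[1][0]
        assert sites[0].score == sites[1].score

    def test_deterministic(self, rng):
        bases = np.array(list("ACGU"))
        mirna = "".join(rng.choice(bases, 10))
        utr = "".join(rng.choice(bases, 50))
        scheme = ScoringScheme(score_threshold=20)
        a = sw_align_seeded(mirna, utr, scheme)
        b = sw_align_seeded(mirna, utr, scheme)
        assert [(x.score, x.utr_start, x.mirna_aln, x.utr_aln) for x in a] == \
               [(x.score, x.utr_start, x.mirna_aln, x.utr_aln) for x in b]
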