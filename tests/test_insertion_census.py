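"""Seed–chain–align detector: oracles, filters, coverage, histogram."""

import numpy as np
import pytest

from egtcensus import insertion_census as ic
from egtcensus import synthetic_data as sd
from egtcensus.formats_io import SequenceRecord, reverse_complement


def rec(seq, id="s", **kw):
    return SequenceRecord(id=id, seq=seq, kind="nucleotide", **kw)


def brute_force_anchors(nuclear, organelle, w):
    """All-pairs word-comparison oracle, forward and reverse complement."""
    out = set()
    rc = reverse_complement(organelle)
    L = len(organelle)
    for n in range(len(nuclear) - w + 1):
        word = nuclear[n : n + w]
        if "N" in word:
            continue
        for o in range(L - w + 1):
            if organelle[o : o + w] == word:
                out.add((n, o, "+"))
            if rc[L - w - o : L - o] == word:
                out.add((n, o, "-"))
    return out


class TestFindSeedMatches:
    @pytest.mark.parametrize("nuc,org,w", [
        ("ACGTACGTACGT", "ACGTACGTACGT", 8),
        ("ACGNACGTACGTAA", "ACGAACGTACGTAA", 8),
        ("AACCGGTTAACCGG", "TTGGCCAATTGGCC", 8),
    ])
    def test_matches_brute_force_oracle(self, nuc, org, w):
        got = {(a.n_pos, a.o_pos, a.strand)
               for a in ic.find_seed_matches(rec(nuc), rec(org, id="o"), word_size=w)}
        assert got == brute_force_anchors(nuc, org, w)

    def test_no_shared_word(self):
        assert ic.find_seed_matches(rec("AAAAAAAAAA"), rec("CCCCCCCCCC", id="o"),
                                    word_size=8) == []

    def test_words_with_n_never_match(self):
        anchors = ic.find_seed_matches(rec("ACGNACGTACGT"), rec("ACGNACGTACGT", id="o"),
                                       word_size=8)
        # every anchor word is N-free on both sides
        for a in anchors:
            assert "N" not in "ACGNACGTACGT"[a.n_pos : a.n_pos + 8]

    def test_word_size_longer_than_sequence_warns_empty(self):
        with pytest.warns(UserWarning):
            assert ic.find_seed_matches(rec("ACGTACGT"), rec("ACGTACGT", id="o"),
                                        word_size=50) == []

    def test_random_sequences_match_oracle(self, rng):
        for _ in range(5):
            nuc = "".join(rng.choice(list("ACGT"), size=60))
            org = "".join(rng.choice(list("ACGT"), size=40))
            got = {(a.n_pos, a.o_pos, a.strand)
                   for a in ic.find_seed_matches(rec(nuc), rec(org, id="o"), word_size=8)}
            assert got == brute_force_anchors(nuc, org, 8)


class TestChainAndAlign:
    def test_exact_implanted_copy_recovered(self, rng):
        org = "".join(rng.choice(list("ACGT"), size=500))
        fragment = org[50:170]
        nuc = "".join(rng.choice(list("ACGT"), size=200)) + fragment \
            + "".join(rng.choice(list("ACGT"), size=200))
        anchors = ic.find_seed_matches(rec(nuc), rec(org, id="o"), word_size=20)
        hits = ic.chain_and_align(anchors, rec(nuc), rec(org, id="o"), word_size=20)
        exact = [h for h in hits if h.o_start == 50 and h.o_end == 170]
        assert len(exact) == 1
        assert exact[0].identity_pct == 100.0
        assert exact[0].n_start == 200 and exact[0].n_end == 320

    def test_distant_anchor_runs_stay_separate(self, rng):
        org = "".join(rng.choice(list("ACGT"), size=400))
        filler = lambda n: "".join(rng.choice(list("ACGT"), size=n))
        nuc = filler(100) + org[0:60] + filler(500) + org[100:160] + filler(100)
        anchors = ic.find_seed_matches(rec(nuc), rec(org, id="o"), word_size=20)
        hits = ic.chain_and_align(anchors, rec(nuc), rec(org, id="o"), word_size=20)
        assert len(hits) == 2

    def test_identity_of_mutated_implant_matches_planted_truth(self):
        """Measured identity of a generator implant equals the value computed
        from the planted substitution positions inside the hit span."""
        nuc, org, truths = sd.gen_genome_with_implants(
            organelle_len=3000, nuclear_len=10000, n_implants=1,
            length_range=(200, 200), identity_range=(90, 90), seed=5)
        (t,) = truths
        assert t.planted_identity_pct == 90.0
        hits = ic.detect_insertions([nuc], org, word_size=50)
        assert len(hits) == 1
        span_subs = sum(1 for p in t.sub_positions
                        if (hits[0].o_start - t.o_start) <= p < (hits[0].o_end - t.o_start))
        expected = 100.0 * (1 - span_subs / hits[0].length)
        assert hits[0].identity_pct == pytest.approx(expected, abs=1e-9)

    def test_identity_of_evenly_scattered_substitutions(self, rng):
        """A 200 bp copy with substitutions every 20 bp yields one hit whose
        identity equals matched/total columns counted by hand."""
        org = "".join(rng.choice(list("ACGT"), size=600))
        fragment = list(org[100:300])
        positions = list(range(20, 180, 20))
        for p in positions:
            fragment[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[fragment[p]]
        filler = lambda n: "".join(rng.choice(list("ACGT"), size=n))
        nuc = filler(150) + "".join(fragment) + filler(150)
        anchors = ic.find_seed_matches(rec(nuc), rec(org, id="o"), word_size=16)
        hits = ic.chain_and_align(anchors, rec(nuc), rec(org, id="o"), word_size=16)
        hits = ic.filter_hits(hits, min_identity_pct=80, min_length=50)
        assert len(hits) == 1
        (h,) = hits
        in_span = sum(1 for p in positions if h.o_start <= 100 + p < h.o_end)
        assert h.identity_pct == pytest.approx(100.0 * (1 - in_span / h.length), abs=1e-9)

    def test_empty_anchor_list(self):
        assert ic.chain_and_align([], rec("ACGTACGT"), rec("ACGTACGT", id="o")) == []


class TestFilterHits:
    def make(self, identity, length):
        return ic.InsertionHit(organelle_id="o", o_start=0, o_end=length,
                               nuclear_id="n", n_start=0, n_end=length,
                               strand="+", identity_pct=identity)

    def test_identity_threshold_is_strict(self):
        assert ic.filter_hits([self.make(80.0, 100)]) == []
        assert len(ic.filter_hits([self.make(80.1, 50)])) == 1

    def test_min_length(self):
        assert ic.filter_hits([self.make(99.0, 49)]) == []
        assert len(ic.filter_hits([self.make(99.0, 50)])) == 1

    def test_order_preserved(self):
        hits = [self.make(90, 60), self.make(85, 70), self.make(95, 80)]
        assert ic.filter_hits(hits) == hits


class TestCoverageProfile:
    def org(self, n=100):
        return rec("A" * n, id="o")

    def hit(self, o_start, o_end):
        return ic.InsertionHit(organelle_id="o", o_start=o_start, o_end=o_end,
                               nuclear_id="n", n_start=0, n_end=o_end - o_start,
                               strand="+", identity_pct=99.0)

    def test_no_hits(self):
        prof = ic.coverage_profile([], self.org())
        assert prof.exchange_rate_pct == 0.0
        assert (prof.depth == 0).all()

    def test_three_stacked_hits(self):
        prof = ic.coverage_profile([self.hit(10, 60)] * 3, self.org())
        assert (prof.depth[10:60] == 3).all()
        assert prof.depth[9] == 0 and prof.depth[60] == 0
        assert prof.exchange_rate_pct == 50.00

    def test_interval_union(self):
        prof = ic.coverage_profile([self.hit(0, 50), self.hit(40, 100)], self.org())
        assert prof.exchange_rate_pct == 100.00
        assert prof.depth.max() == 2
        assert (prof.depth[40:50] == 2).all()

    def test_out_of_bounds_hit_rejected(self):
        with pytest.raises(ValueError, match="outside organelle"):
            ic.coverage_profile([self.hit(50, 150)], self.org())

    def test_matches_interval_stabbing_oracle(self, rng):
        intervals = [(int(a), int(a + b)) for a, b in
                     zip(rng.integers(0, 80, 20), rng.integers(1, 20, 20))]
        prof = ic.coverage_profile([self.hit(a, b) for a, b in intervals], self.org())
        oracle = np.array([sum(a <= i < b for a, b in intervals) for i in range(100)])
        assert (prof.depth == oracle).all()


class TestSizeHistogram:
    def hit_of_length(self, L):
        return ic.InsertionHit(organelle_id="o", o_start=0, o_end=L, nuclear_id="n",
                               n_start=0, n_end=L, strand="+", identity_pct=99.0)

    def test_bin_edges(self):
        hist = ic.size_histogram([self.hit_of_length(L) for L in (50, 99, 100, 999, 1000)])
        assert hist.counts == {"50–99": 2, "-199": 1, "-299": 0, "-399": 0,
                               "-499": 0, "-999": 1, "≥1000": 1}

    def test_open_top_bin(self):
        assert ic.size_histogram([self.hit_of_length(1_000_000)]).counts["≥1000"] == 1

    def test_empty(self):
        hist = ic.size_histogram([])
        assert hist.total == 0

    def test_sub_minimum_length_rejected(self):
        with pytest.raises(ValueError, match="filter hits first"):
            ic.size_histogram([self.hit_of_length(49)])

    def test_total_conserved(self, rng):
        lengths = rng.integers(50, 3000, size=40)
        hist = ic.size_histogram([self.hit_of_length(int(L)) for L in lengths])
        assert hist.total == 40


class TestStrandSymmetry:
    def test_reverse_complement_flips_strands_only(self):
        nuc, org, _ = sd.gen_genome_with_implants(
            organelle_len=5000, nuclear_len=40000, n_implants=5,
            length_range=(100, 600), identity_range=(90, 100), seed=9)
        hits_fwd = ic.detect_insertions([nuc], org)
        rc = SequenceRecord(id=nuc.id, seq=reverse_complement(nuc.seq),
                            kind="nucleotide", compartment="nuclear")
        hits_rev = ic.detect_insertions([rc], org)
        prof_f = ic.coverage_profile(hits_fwd, org)
        prof_r = ic.coverage_profile(hits_rev, org)
        assert prof_f.exchange_rate_pct == prof_r.exchange_rate_pct
        assert ic.size_histogram(hits_fwd).counts == ic.size_histogram(hits_rev).counts
        fwd = sorted((h.o_start, h.o_end, h.strand) for h in hits_fwd)
        rev = sorted((h.o_start, h.o_end, h.strand) for h in hits_rev)
        flip = {"+": "-", "-": "+"}
        assert [(a, b, flip[s]) for a, b, s in fwd] == rev


class TestCircularOption:
    def test_wraparound_pad_seeds_origin_crossing_hit(self, rng):
        org = "".join(rng.choice(list("ACGT"), size=300))
        crossing = org[260:] + org[:60]  # spans the origin of a circular genome
        nuc = "".join(rng.choice(list("ACGT"), size=150)) + crossing \
            + "".join(rng.choice(list("ACGT"), size=150))
        linear = ic.find_seed_matches(rec(nuc), rec(org, id="o"), word_size=30)
        circular = ic.find_seed_matches(rec(nuc), rec(org, id="o"), word_size=30,
                                        circular=True)
        assert len(circular) > len(linear)
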