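"""Seed-site scanning, duplex alignment and free energy against oracles."""

import numpy as np
import pytest

from mircover.duplex import (
    DuplexAlignment,
    align_duplex,
    duplex_free_energy,
    find_seed_sites,
    load_energy_params,
    report_sites,
)
from mircover.model import SequenceSet, reverse_complement

from oracles import dp_align_score, scan_seed_sites

ALPHA = np.array(list("ACGU"))


def random_seq(rng, n):
    return "".join(rng.choice(ALPHA, size=n))


class TestFindSeedSites:
    def test_no_complement_no_sites(self):
        mir = "UAGCAGCACGUAAAUAUUGGCG"
        assert find_seed_sites(mir, "A" * 50) == []

    def test_planted_8mer_recovered(self, rng):
        for _ in range(20):
            mir = random_seq(rng, 22)
            site = reverse_complement(mir[1:8]) + "A"
            utr = random_seq(rng, 10) + site + random_seq(rng, 10)
            sites = [s for s in find_seed_sites(mir, utr) if s.start == 10]
            assert len(sites) == 1
            assert sites[0].site_type == "8mer" and sites[0].end == 18

    def test_short_mirna_errors(self):
        with pytest.raises(ValueError, match="at least 8"):
            find_seed_sites("ACGUACG", "ACGU" * 20)

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(60):
            mir = random_seq(rng, 22)
            utr = random_seq(rng, 500)
            got = [(s.start, s.end, s.site_type) for s in find_seed_sites(mir, utr)]
            assert got == scan_seed_sites(mir, utr)


class TestAlignDuplex:
    def test_perfect_duplex(self):
        mir = "UAGCAGCACGUAAAUAUUGGCG"
        aln = align_duplex(mir, reverse_complement(mir))
        assert aln.bars == "|" * 22
        assert "-" not in aln.mirna_line + aln.utr_line
        assert aln.score == 22 * 5.0

    def test_single_base_window(self):
        mir = "UAGCAGCACGUAAAUAUUGGCG"
        aln = align_duplex(mir, "A")
        assert len(aln.mirna_line) == 22
        assert aln.utr_line.count("-") == 21

    def test_empty_window_errors(self):
        with pytest.raises(ValueError):
            align_duplex("UAGCAGCACGUAAAUAUUGGCG", "")

    def test_score_matches_dp_oracle(self, rng):
        for _ in range(40):
            mir = random_seq(rng, 22)
            window = random_seq(rng, int(rng.integers(6, 40)))
            aln = align_duplex(mir, window)
            assert aln.score == pytest.approx(dp_align_score(mir, window), abs=1e-9)

    def test_reproducible_bit_exact(self, rng):
        mir = random_seq(rng, 22)
        window = random_seq(rng, 30)
        a1 = align_duplex(mir, window)
        a2 = align_duplex(mir, window)
        assert (a1.mirna_line, a1.bars, a1.utr_line) == (a2.mirna_line, a2.bars, a2.utr_line)

    def test_bars_only_over_pairing_columns(self):
        with pytest.raises(ValueError, match="pairing bar"):
            DuplexAlignment("AA", "||", "AA", 0.0)


class TestFreeEnergy:
    def test_no_pairs_gives_initiation(self):
        p = load_energy_params()
        aln = DuplexAlignment("AAAA", "    ", "CCCC", 0.0)
        assert duplex_free_energy(aln) == p["initiation"]

    def test_hand_summed_helix(self):
        # miRNA 3'CGCG / UTR 5'GCGC: three stacks keyed GC, CG, GC
        p = load_energy_params()
        aln = DuplexAlignment("CGCG", "||||", "GCGC", 20.0)
        expected = p["initiation"] + p["GC"] + p["CG"] + p["GC"]
        assert duplex_free_energy(aln) == pytest.approx(expected, abs=1e-12)

    def test_extra_wc_stack_strictly_decreases(self):
        shorter = DuplexAlignment("CGCG", "||||", "GCGC", 0.0)
        longer = DuplexAlignment("CGCGC", "|||||", "GCGCG", 0.0)
        assert duplex_free_energy(longer) < duplex_free_energy(shorter)

    def test_two_stacked_wc_pairs_nonpositive(self):
        # weakest helix: two stacked A:U pairs
        aln = DuplexAlignment("UU", "||", "AA", 0.0)
        assert duplex_free_energy(aln) <= 0.0

    def test_loop_penalty_applied(self):
        p = load_energy_params()
        helix = DuplexAlignment("CGCG", "||||", "GCGC", 0.0)
        looped = DuplexAlignment("CG" + "AA" + "CG", "||  ||", "GC" + "UU" + "GC", 0.0)
        # two 2-pair helices (one GC stack each) + 4-nt internal loop
        expected = (
            p["initiation"] + p["GC"] + p["GC"] + p["loop_open"] + 4 * p["loop_per_nt"]
        )
        assert duplex_free_energy(looped) == pytest.approx(expected, abs=1e-12)
        assert duplex_free_energy(looped) > duplex_free_energy(helix)

    def test_translation_invariance(self, rng):
        """The same site embedded at different UTR offsets scores identically."""
        mir = "UAGCAGCACGUAAAUAUUGGCG"
        site = reverse_complement(mir[1:8]) + "A"
        energies = []
        for offset in (30, 120, 300):
            utr = ("C" * offset + site + "C" * (400 - offset)).replace("T", "U")
            utrs = SequenceSet({"u": utr}, role="utr")
            mirs = SequenceSet({"m": mir}, role="mirna")
            hits = report_sites(mirs, utrs, top_n=1)
            assert len(hits) == 1
            energies.append(hits[0].delta_g)
        assert energies[0] == energies[1] == energies[2]


class TestReportSites:
    def mirna_with_two_sites(self):
        mir = "UAGCAGCACGUAAAUAUUGGCG"
        strong = reverse_complement(mir) + "A"  # full complement ending at an A1-like A
        weak = reverse_complement(mir[1:8]) + "A"  # seed only
        utr = "CACA" * 5 + strong + "CACA" * 5 + weak + "CACA" * 5
        return mir, utr

    def test_stronger_site_ranked_first(self):
        mir, utr = self.mirna_with_two_sites()
        hits = report_sites(
            SequenceSet({"m": mir}, role="mirna"), SequenceSet({"u": utr}, role="utr"), top_n=5
        )
        assert len(hits) >= 2
        assert hits[0].delta_g < hits[-1].delta_g
        assert hits == sorted(hits, key=lambda h: (h.delta_g, h.utr_id, h.site.start))

    def test_top_n_zero_empty(self):
        mir, utr = self.mirna_with_two_sites()
        assert report_sites(
            SequenceSet({"m": mir}, role="mirna"), SequenceSet({"u": utr}, role="utr"), top_n=0
        ) == []

    def test_input_order_invariance(self, rng):
        mirs = {f"m{i}": random_seq(rng, 22) for i in range(3)}
        utrs = {f"u{i}": random_seq(rng, 300) for i in range(3)}
        fwd = report_sites(SequenceSet(mirs, "mirna"), SequenceSet(utrs, "utr"), top_n=3)
        rev = report_sites(
            SequenceSet(dict(reversed(list(mirs.items()))), "mirna"),
            SequenceSet(dict(reversed(list(utrs.items()))), "utr"),
            top_n=3,
        )
        assert fwd == rev
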