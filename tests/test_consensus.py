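"""Evidence tallies, scores and coverage ranking against brute-force recounts."""

import numpy as np
import pytest

from mircover.consensus import integrated_score, net_evidence, rank_mirnas, summarize_mirna
from mircover.model import GeneSet

from conftest import GENES6, make_table, random_rows
from oracles import brute_rank, recount_summary


def table_like_top_candidate(gene_set):
    """Evidence reproducing the strongest candidate's tallies: 16 validated
    records over 6 genes, one of them negative, plus one predicted record
    per gene."""
    rows = []
    genes = list(gene_set.genes)
    for k in range(16):
        g = genes[k % 6]
        rows.append(
            (
                "hsa-miR-16-5p", g, f"vsrc{k // 6}", "validated",
                "negative" if k == 0 else "positive", 1.0,
            )
        )
    for g in genes:
        rows.append(("hsa-miR-16-5p", g, "mirdip", "predicted", "positive", 0.9))
    return make_table(rows)


class TestSummarize:
    def test_top_candidate_tallies(self, gene_set):
        s = summarize_mirna(table_like_top_candidate(gene_set), gene_set, "hsa-miR-16-5p")
        assert (s.n_validated_genes, s.positive_evidence, s.negative_evidence) == (6, 15, 1)
        assert s.net_evidence == 14
        assert s.validated_score == 6 and s.predicted_score == 6

    def test_empty_table_all_zero(self, gene_set):
        s = summarize_mirna(make_table([]), gene_set, "hsa-miR-1")
        assert (s.coverage, s.net_evidence, s.integrated_score) == (0, 0, 0.0)

    def test_genes_outside_set_ignored(self, gene_set):
        rows = [("m1", "TP53", "s1", "validated", "positive", 1.0)]
        s = summarize_mirna(make_table(rows), gene_set, "m1")
        assert s.coverage == 0 and s.positive_evidence == 0

    def test_matches_brute_force_recount(self, gene_set, rng):
        rows = random_rows(rng, n_records=200)
        table = make_table(rows)
        for m in table.mirna_ids():
            s = summarize_mirna(table, gene_set, m)
            exp = recount_summary(rows, GENES6, m)
            for field, want in exp.items():
                got = getattr(s, field)
                assert got == pytest.approx(want, abs=1e-12), (m, field)

    def test_permutation_invariance(self, gene_set, rng):
        rows = random_rows(rng, n_records=80)
        shuffled = [rows[i] for i in rng.permutation(len(rows))]
        for m in {r[0] for r in rows}:
            assert summarize_mirna(make_table(rows), gene_set, m) == summarize_mirna(
                make_table(shuffled), gene_set, m
            )

    def test_monotonicity_of_added_records(self, gene_set, rng):
        rows = random_rows(rng, n_records=60)
        m = rows[0][0]
        before = summarize_mirna(make_table(rows), gene_set, m)
        uncovered = [g for g in GENES6 if g not in {
            r[1].upper() for r in rows if r[0].lower() == m.lower()}]
        if uncovered:
            plus = rows + [(m, uncovered[0], "newsrc", "validated", "positive", 1.0)]
            after = summarize_mirna(make_table(plus), gene_set, m)
            assert after.validated_score == before.validated_score + 1
        plus_neg = rows + [(m, GENES6[0], "negsrc", "validated", "negative", 1.0)]
        after_neg = summarize_mirna(make_table(plus_neg), gene_set, m)
        assert after_neg.net_evidence == before.net_evidence - 1

    def test_conservation_of_validated_counts(self, gene_set, rng):
        rows = random_rows(rng, n_records=150)
        for m in {r[0] for r in rows}:
            s = summarize_mirna(make_table(rows), gene_set, m)
            n_validated_records = sum(
                1 for r in rows
                if r[0].lower() == m.lower() and r[3] == "validated" and r[1].upper() in GENES6
            )
            assert s.positive_evidence + s.negative_evidence == n_validated_records


class TestNetEvidence:
    @pytest.mark.parametrize("pos,neg,want", [(7, 2, 5), (6, 2, 4), (15, 1, 14), (0, 0, 0)])
    def test_values(self, pos, neg, want):
        assert net_evidence(pos, neg) == want

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            net_evidence(-1, 0)


class TestIntegratedScore:
    def test_single_record(self, gene_set):
        t = make_table([("m1", "AR", "s1", "predicted", "positive", 1.0)])
        assert integrated_score(t, gene_set, "m1") == 1.0

    def test_max_rule_over_sources(self, gene_set):
        t = make_table(
            [
                ("m1", "AR", "s1", "predicted", "positive", 0.4),
                ("m1", "AR", "s2", "validated", "positive", 0.9),
            ]
        )
        assert integrated_score(t, gene_set, "m1") == 0.9

    def test_brute_force_double_loop(self, gene_set, rng):
        rows = random_rows(rng, n_records=120)
        table = make_table(rows)
        for m in table.mirna_ids():
            expected = 0.0
            for g in GENES6:
                confs = [r[5] for r in rows if r[0].lower() == m.lower() and r[1] == g]
                expected += max(confs) if confs else 0.0
            assert integrated_score(table, gene_set, m) == pytest.approx(expected, abs=1e-12)


class TestRanking:
    def test_distractor_excluded_candidates_kept(self, gene_set):
        rows = []
        # three multi-gene candidates with distinct validated coverage
        for i, (m, cov) in enumerate(
            [("hsa-miR-16-5p", 6), ("hsa-miR-124-3p", 6), ("hsa-miR-27a-3p", 5)]
        ):
            for g in list(gene_set.genes)[:cov]:
                rows.append((m, g, f"v{i}", "validated", "positive", 1.0))
        rows.append(("hsa-miR-x", "AR", "v9", "validated", "positive", 1.0))  # 1-gene distractor
        ranked = rank_mirnas(make_table(rows), gene_set, min_coverage=2, top_k=3)
        assert "hsa-miR-x" not in ranked.mirna_ids()
        assert set(ranked.mirna_ids()) == {"hsa-miR-16-5p", "hsa-miR-124-3p", "hsa-miR-27a-3p"}

    def test_ties_break_lexicographically(self, gene_set):
        rows = [
            ("mir-b", "AR", "s1", "validated", "positive", 1.0),
            ("mir-b", "MET", "s1", "validated", "positive", 1.0),
            ("mir-a", "AR", "s1", "validated", "positive", 1.0),
            ("mir-a", "MET", "s1", "validated", "positive", 1.0),
        ]
        ranked = rank_mirnas(make_table(rows), gene_set, min_coverage=2, top_k=2)
        assert ranked.mirna_ids() == ["mir-a", "mir-b"]

    def test_order_matches_brute_force_sort(self, gene_set, rng):
        for _ in range(20):
            rows = random_rows(rng, n_mirnas=50, n_records=250)
            got = rank_mirnas(make_table(rows), gene_set, min_coverage=2, top_k=50).mirna_ids()
            want = brute_rank(rows, GENES6, 2, 50)
            assert [g.lower() for g in got] == [w.lower() for w in want]

    def test_hubs_always_outrank_background(self, gene_set, rng):
        for trial in range(10):
            rows = random_rows(rng, n_mirnas=20, n_records=60)
            rows = [r for r in rows if not r[0].startswith("hub")]
            for h in ("hub-1", "hub-2"):
                for g in GENES6:
                    rows.append((h, g, "vh", "validated", "positive", 1.0))
            ranked = rank_mirnas(make_table(rows), gene_set, min_coverage=1, top_k=100)
            ids = ranked.mirna_ids()
            hub_pos = [ids.index(h) for h in ("hub-1", "hub-2")]
            others = [
                i for i, m in enumerate(ids)
                if m not in ("hub-1", "hub-2")
                and summarize_mirna(make_table(rows), gene_set, m).validated_score < 6
            ]
            assert all(h < o for h in hub_pos for o in others)

    def test_empty_after_filter(self, gene_set):
        rows = [("m1", "AR", "s1", "validated", "positive", 1.0)]
        ranked = rank_mirnas(make_table(rows), gene_set, min_coverage=3, top_k=5)
        assert len(ranked) == 0
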