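"""Protein alignment, hit filtering, pair calling, DNA PID, and PID bins."""

import itertools
import math

import pytest
from Bio.Align import substitution_matrices

from ohnopipe.genome_model import GenomicInterval, GeneLocus, HomeologBlockPair, TetrasomyRegistry
from ohnopipe.ohnolog_calling import (
    AlignmentHit,
    OhnologPair,
    SequenceRecord,
    align_protein,
    all_vs_all_hits,
    bin_pid,
    call_pairs,
    dna_pid,
    filter_hits,
    read_tabular_hits,
    _PROT_ALIGNER,
)

from conftest import locus

BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN, GAP_EXTEND = 11.0, 1.0


def brute_force_local_score(a: str, b: str) -> float:
    """Independent oracle: enumerate every local alignment of two short
    sequences as a monotone matching of residue subsets, scoring matched
    columns by BLOSUM62 and each internal unaligned run as an affine gap
    (open 11, extend 1, no end penalties)."""
    best = 0.0
    n, m = len(a), len(b)
    for k in range(1, min(n, m) + 1):
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.combinations(range(m), k):
                score = sum(
                    BLOSUM62[a[i], b[j]] for i, j in zip(rows, cols)
                )
                for t in range(k - 1):
                    gap_a = rows[t + 1] - rows[t] - 1
                    gap_b = cols[t + 1] - cols[t] - 1
                    for g in (gap_a, gap_b):
                        if g > 0:
                            score -= GAP_OPEN + GAP_EXTEND * (g - 1)
                best = max(best, score)
    return best


class TestAlignProtein:
    def test_self_alignment_is_perfect(self):
        rec = SequenceRecord("g", "MKLVINSGATT" * 9 + "M")  # 100 residues
        hit = align_protein(rec, rec)
        assert hit.percent_identity == pytest.approx(100.0)
        assert hit.query_coverage == pytest.approx(1.0)

    def test_ten_of_hundred_substitutions_give_ninety_percent(self):
        base = list("ACDEFGHIKL" * 10)
        mutated = base.copy()
        # substitutions chosen dissimilar enough that the optimal alignment
        # stays gap-free
        # interior positions only: a substituted terminal residue would be
        # trimmed by the local alignment
        for pos, res in zip(range(5, 100, 10), "WYWYWYWYWY"):
            mutated[pos] = res
        hit = align_protein(
            SequenceRecord("a", "".join(base)), SequenceRecord("b", "".join(mutated))
        )
        assert hit.alignment_length == 100
        assert hit.percent_identity == pytest.approx(90.0)

    def test_empty_and_invalid_sequences_are_rejected(self):
        good = SequenceRecord("g", "MKLV")
        with pytest.raises(ValueError, match="empty"):
            align_protein(SequenceRecord("e", ""), good)
        with pytest.raises(ValueError, match="'\\*'"):
            align_protein(SequenceRecord("s", "MK*V"), good)

    def test_no_positive_alignment_flags_no_hit(self):
        # W vs P scores -4 in BLOSUM62: nothing positive to extend
        hit = align_protein(SequenceRecord("a", "WWWWW"), SequenceRecord("b", "PPPPP"))
        assert not hit.is_hit
        assert hit.alignment_length == 0

    @pytest.mark.parametrize(
        "a,b",
        [
            ("MKLVIN", "MKLVIN"),
            ("MKLVIN", "MKVIN"),
            ("ACDEFG", "AXDEFG"),
            ("WPHAK", "KAHPW"),
            ("MKYWVLIN", "MKWVLN"),
            ("AAAA", "AARA"),
        ],
    )
    def test_optimal_score_matches_exhaustive_enumeration(self, a, b):
        expected = brute_force_local_score(a, b)
        got = _PROT_ALIGNER.align(a, b)
        score = float(got.score) if len(got) else 0.0
        assert max(score, 0.0) == pytest.approx(expected)


class TestFilterHits:
    def hit(self, pid, cov, qid="x", sid="y"):
        return AlignmentHit(qid, sid, pid, 100, cov, 50.0)

    def test_thresholds_are_inclusive_minima(self):
        kept = filter_hits(
            [self.hit(84.9, 0.9), self.hit(95.0, 0.49), self.hit(85.0, 0.50)]
        )
        assert [(h.percent_identity, h.query_coverage) for h in kept] == [(85.0, 0.50)]

    def test_self_hits_removed_and_empty_output_allowed(self):
        assert filter_hits([self.hit(99, 0.9, "g", "g")]) == []
        assert filter_hits([]) == []


def _toy_registry():
    return TetrasomyRegistry([
        HomeologBlockPair(
            GenomicInterval("c1", 0, 1000), GenomicInterval("c2", 0, 1000), True, "b1"
        ),
    ])


class TestCallPairs:
    def test_block_restriction_dominates_score(self):
        registry = _toy_registry()
        loci = {
            "X": locus("X", "c1", 10, 20),
            "Y": locus("Y", "c2", 10, 20),
            "Z": locus("Z", "c9", 10, 20),  # outside any block pairing with X
        }
        hits = [
            AlignmentHit("X", "Y", 95, 100, 0.9, 500.0),
            AlignmentHit("X", "Z", 99, 100, 0.9, 600.0),
        ]
        pairs = call_pairs(hits, loci, registry)
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("X", "Y")]

    def test_top_ranked_hit_wins_and_loser_stays_free(self):
        registry = _toy_registry()
        loci = {
            "X": locus("X", "c1", 10, 20),
            "Y": locus("Y", "c2", 10, 20),
            "W": locus("W", "c2", 110, 120),
            "V": locus("V", "c1", 110, 120),
        }
        hits = [
            AlignmentHit("X", "Y", 95, 100, 0.9, 700.0),
            AlignmentHit("X", "W", 94, 100, 0.9, 600.0),
            AlignmentHit("V", "W", 90, 100, 0.9, 500.0),
        ]
        pairs = call_pairs(hits, loci, registry)
        assert {(p.gene_a, p.gene_b) for p in pairs} == {("X", "Y"), ("V", "W")}

    def test_empty_hits_give_empty_pairs(self):
        assert call_pairs([], {}, _toy_registry()) == []

    def test_gene_without_locus_skipped_with_warning(self, caplog):
        registry = _toy_registry()
        loci = {"X": locus("X", "c1", 10, 20)}
        hits = [AlignmentHit("X", "Q", 95, 100, 0.9, 500.0)]
        import logging
        with caplog.at_level(logging.WARNING):
            assert call_pairs(hits, loci, registry) == []
        assert any("no locus" in r.message for r in caplog.records)

    def test_output_is_an_exact_matching_on_simulated_genome(self, recoverable_genome):
        g = recoverable_genome
        hits = filter_hits(all_vs_all_hits(g.sequences, g.loci, g.registry))
        pairs = call_pairs(hits, g.loci, g.registry, g.sequences)
        seen = [gid for p in pairs for gid in (p.gene_a, p.gene_b)]
        assert len(seen) == len(set(seen))

    def test_recovers_true_pairs_when_divergence_clears_the_filter(self, recoverable_genome):
        g = recoverable_genome
        hits = filter_hits(all_vs_all_hits(g.sequences, g.loci, g.registry))
        pairs = call_pairs(hits, g.loci, g.registry, g.sequences)
        truth = {(p.gene_a, p.gene_b) for p in g.truth_pairs}
        called = {(p.gene_a, p.gene_b) for p in pairs}
        assert len(truth & called) / len(truth) >= 0.99
        # modes recovered exactly
        mode_of = {(p.gene_a, p.gene_b): p.mode for p in g.truth_pairs}
        for p in pairs:
            assert p.mode is mode_of[(p.gene_a, p.gene_b)]


class TestDnaPid:
    def test_identical_cds_give_hundred(self):
        rec = SequenceRecord("a", "M", cds_seq="ATGGCTGCTAAA")
        assert dna_pid(rec, rec) == pytest.approx(100.0)

    def test_fifteen_substitutions_in_300bp_give_95(self, rng):
        bases = "ACGT"
        seq = "".join(bases[i] for i in rng.integers(0, 4, size=300))
        mutated = list(seq)
        positions = rng.choice(300, size=15, replace=False)
        for pos in positions:
            mutated[pos] = bases[(bases.index(mutated[pos]) + 2) % 4]
        pid = dna_pid(
            SequenceRecord("a", "M", cds_seq=seq),
            SequenceRecord("b", "M", cds_seq="".join(mutated)),
        )
        assert pid == pytest.approx(95.0)

    def test_missing_or_empty_cds_raises(self):
        with_cds = SequenceRecord("a", "M", cds_seq="ATG")
        without = SequenceRecord("b", "M")
        with pytest.raises(ValueError, match="protein-only"):
            dna_pid(with_cds, without)
        with pytest.raises(ValueError, match="empty"):
            dna_pid(with_cds, SequenceRecord("c", "M", cds_seq=""))

    def test_gap_columns_count_in_denominator(self):
        # 12 identical bases + 3-base deletion: 12 / 15 columns = 80%
        a = SequenceRecord("a", "M", cds_seq="ATGGCTGCTAAATTT")
        b = SequenceRecord("b", "M", cds_seq="ATGGCTGCTAAA")
        assert dna_pid(a, b) == pytest.approx(100.0 * 12 / 15)


class TestBinPid:
    @pytest.mark.parametrize(
        "pid,expected",
        [(96.2, ">95%"), (90.0, "90-95%"), (95.0, "90-95%"),
         (89.999, "<90%"), (0.0, "<90%"), (100.0, ">95%")],
    )
    def test_bin_boundaries(self, pid, expected):
        assert bin_pid(pid) == expected

    def test_out_of_range_rejected(self):
        for bad in (-0.1, 100.1, float("nan")):
            with pytest.raises(ValueError):
                bin_pid(bad)

    def test_bins_partition_any_pair_set(self, small_genome):
        pids = [p.pid for p in small_genome.truth_pairs]
        counts = {b: 0 for b in ("<90%", "90-95%", ">95%")}
        for pid in pids:
            counts[bin_pid(pid)] += 1
        assert sum(counts.values()) == len(pids)


class TestPairRecord:
    def test_gene_order_and_pid_range_enforced(self):
        from ohnopipe.genome_model import InheritanceMode
        with pytest.raises(ValueError):
            OhnologPair("b", "a", 90.0, InheritanceMode.DISOMIC)
        with pytest.raises(ValueError):
            OhnologPair("a", "b", 101.0, InheritanceMode.DISOMIC)


class TestTabularHits:
    def test_round_trip_fields_and_coverage(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("q1\ts1\t92.5\t80\t6\t0\t11\t90\t1\t80\t1e-30\t250\n")
        hits = read_tabular_hits(path, {"q1": 100})
        assert len(hits) == 1
        h = hits[0]
        assert h.percent_identity == 92.5
        assert h.query_coverage == pytest.approx(0.80)
        assert h.score == 250.0

    def test_unknown_query_and_short_lines_rejected(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("q9\ts1\t92.5\t80\t6\t0\t11\t90\t1\t80\t1e-30\t250\n")
        with pytest.raises(ValueError, match="unknown query"):
            read_tabular_hits(path, {"q1": 100})
        path.write_text("q1\ts1\t92.5\n")
        with pytest.raises(ValueError, match="12 columns"):
            read_tabular_hits(path, {"q1": 100})
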