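"""Mapping, annotation cascade, feature counting, and region clustering."""

import numpy as np
import pytest

from pollensnc.annotate import (Alignment, AnnotationIndex, GenomeIndex,
                                annotate_alignment, annotate_library,
                                build_index, class_totals, cluster_unannotated,
                                count_features, map_read, revcomp)
from pollensnc.preprocess import ReadLibrary, ReadRecord
from pollensnc.seqio import Feature


def _random_genome(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


class TestIndex:
    def test_kmer_found_at_all_positions(self):
        idx = build_index({"c": "ACGTACGT"}, k=8)
        # k=8 over an 8-mer: one window; use lookup of the full sequence
        assert idx.lookup("ACGTACGT") == [("c", 0, "+"), ("c", 0, "-")]

    def test_empty_genome_errors(self):
        with pytest.raises(ValueError, match="empty genome"):
            build_index({}, k=8)

    def test_k_range_enforced(self):
        with pytest.raises(ValueError):
            build_index({"c": "ACGTACGTACGT"}, k=4)

    def test_lookup_matches_naive_scan(self):
        """Index positions equal a brute-force scan over a random genome."""
        genome = _random_genome(1000, seed=3)
        k = 9
        idx = build_index({"c": genome}, k=k)
        rng = np.random.default_rng(4)
        for _ in range(25):
            start = rng.integers(0, len(genome) - k)
            kmer = genome[start : start + k]
            naive_fwd = [i for i in range(len(genome) - k + 1)
                         if genome[i : i + k] == kmer]
            naive_rev = [i for i in range(len(genome) - k + 1)
                         if genome[i : i + k] == revcomp(kmer)]
            hits = idx.lookup(kmer)
            assert [p for c, p, s in hits if s == "+"] == naive_fwd
            assert [p for c, p, s in hits if s == "-"] == naive_rev


class TestMapRead:
    def test_unique_substring_maps_exactly(self):
        genome = _random_genome(2000, seed=5)
        read = genome[500:522]
        idx = build_index({"c": genome}, k=12)
        alns = map_read(read, idx)
        assert len(alns) == 1
        a = alns[0]
        assert (a.start, a.end, a.strand, a.mismatches) == (500, 522, "+", 0)

    def test_exact_substrings_always_recovered(self):
        """Mapper recall is 1 for exact substrings at max_mismatch=0."""
        genome = _random_genome(3000, seed=6)
        idx = build_index({"c": genome}, k=12)
        rng = np.random.default_rng(7)
        for _ in range(50):
            start = int(rng.integers(0, 2960))
            n = int(rng.integers(16, 39))
            alns = map_read(genome[start : start + n], idx, max_mismatch=0)
            assert any(a.start == start and a.strand == "+" for a in alns)

    def test_reverse_strand_read(self):
        genome = _random_genome(2000, seed=8)
        read = revcomp(genome[700:724])
        alns = map_read(read, build_index({"c": genome}, k=12))
        assert alns[0].strand == "-" and alns[0].start == 700

    def test_two_copy_repeat_multiplicity(self):
        unit = _random_genome(30, seed=9)
        genome = _random_genome(200, seed=10) + unit + \
            _random_genome(200, seed=11) + unit + _random_genome(200, seed=12)
        alns = map_read(unit, build_index({"c": genome}, k=12))
        assert len(alns) == 2 and all(a.multiplicity == 2 for a in alns)

    def test_one_mismatch_agrees_with_exhaustive_hamming_scan(self):
        genome = _random_genome(800, seed=13)
        idx = build_index({"c": genome}, k=8)
        rng = np.random.default_rng(14)
        for _ in range(20):
            start = int(rng.integers(0, 770))
            read = list(genome[start : start + 24])
            pos = int(rng.integers(0, 24))
            read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
            read = "".join(read)
            # oracle: exhaustive Hamming scan on the forward strand
            def ham(a, b):
                return sum(x != y for x, y in zip(a, b))
            best = min(ham(read, genome[i : i + 24])
                       for i in range(len(genome) - 23))
            alns = map_read(read, idx, max_mismatch=1)
            if best <= 1:
                fwd = [a for a in alns if a.strand == "+"]
                assert fwd and min(a.mismatches for a in fwd) == best
            else:
                assert not [a for a in alns if a.strand == "+"
                            and a.mismatches == 0]


def _feature_set():
    return [
        Feature("c", "gene", 100, 520, "+", {"ID": "g1", "gene_id": "g1"}),
        Feature("c", "exon", 100, 250, "+", {"ID": "g1.e1", "gene_id": "g1"}),
        Feature("c", "intron", 250, 370, "+", {"ID": "g1.i1", "gene_id": "g1"}),
        Feature("c", "exon", 370, 520, "+", {"ID": "g1.e2", "gene_id": "g1"}),
        Feature("c", "tRNA", 200, 275, "+", {"ID": "t1", "amino_acid": "Asp"}),
        Feature("c", "snoRNA", 600, 710, "+", {"ID": "s1"}),
    ]


class TestCascade:
    def test_trna_beats_exon(self):
        # alignment inside the tRNA that also overlaps the exon
        ann = AnnotationIndex(_feature_set())
        v = annotate_alignment(Alignment("r", "c", 210, 232, "+", 0), ann)
        assert v.region_class == "ncRNA:tRNA" and v.feature_id == "t1"

    def test_exon_only_is_excluded_from_discovery(self):
        ann = AnnotationIndex(_feature_set())
        v = annotate_alignment(Alignment("r", "c", 110, 132, "+", 0), ann)
        assert v.region_class == "exonic" and v.excluded_from_discovery

    def test_intron_feeds_discovery(self):
        ann = AnnotationIndex(_feature_set())
        v = annotate_alignment(Alignment("r", "c", 300, 322, "+", 0), ann)
        assert v.region_class == "intronic" and not v.excluded_from_discovery

    def test_no_overlap_is_intergenic(self):
        ann = AnnotationIndex(_feature_set())
        v = annotate_alignment(Alignment("r", "c", 800, 822, "+", 0), ann)
        assert v.region_class == "intergenic" and v.feature_id is None

    def test_antisense_ncrna_counts_antisense_exon_does_not(self):
        ann = AnnotationIndex(_feature_set())
        v_trna = annotate_alignment(Alignment("r", "c", 210, 232, "-", 0), ann)
        assert v_trna.region_class == "ncRNA:tRNA" and v_trna.antisense
        v_exon = annotate_alignment(Alignment("r", "c", 110, 132, "-", 0), ann)
        assert v_exon.region_class == "intergenic"

    def test_half_overlap_rule(self):
        ann = AnnotationIndex(_feature_set())
        # 22-nt read with only 8 nt inside the snoRNA: below 50 %
        v = annotate_alignment(Alignment("r", "c", 586, 608, "+", 0), ann)
        assert v.region_class == "intergenic"

    def test_unknown_contig_warns_intergenic(self):
        ann = AnnotationIndex(_feature_set())
        v = annotate_alignment(Alignment("r", "zzz", 0, 22, "+", 0), ann)
        assert v.region_class == "intergenic"


class TestCounting:
    def test_copies_summed_per_feature_and_totals_conserve(self):
        genome = _random_genome(1000, seed=20)
        features = [Feature("c", "tRNA", 100, 175, "+", {"ID": "t1"})]
        lib = ReadLibrary("s1", "control", reads=[
            ReadRecord(genome[110:132], 10),   # tRNA read, 10 copies
            ReadRecord(genome[500:522], 3),    # intergenic
        ])
        idx = build_index({"c": genome}, k=12)
        annotated = annotate_library(lib, idx, AnnotationIndex(features))
        cm = count_features({"s1": annotated}, {"s1": "control"})
        assert cm.counts.loc["t1", "s1"] == 10
        totals = class_totals(annotated)
        classes = sum(totals.get(k, 0) for k in
                      ("ncRNA:tRNA", "intergenic", "intronic", "exonic",
                       "ncRNA:miRNA", "ncRNA:snoRNA", "ncRNA:rRNA"))
        assert classes == totals["mapped"]

    def test_multimapper_counted_once_at_priority_locus(self):
        # identical sequence inside a tRNA and in intergenic space
        unit = _random_genome(30, seed=21)
        genome = _random_genome(100, seed=22) + unit + \
            _random_genome(300, seed=23) + unit + _random_genome(100, seed=24)
        features = [Feature("c", "tRNA", 100, 130, "+", {"ID": "t1"})]
        lib = ReadLibrary("s1", "control", reads=[ReadRecord(unit[2:26], 7)])
        idx = build_index({"c": genome}, k=12)
        annotated = annotate_library(lib, idx, AnnotationIndex(features))
        cm = count_features({"s1": annotated}, {"s1": "control"})
        assert cm.counts.loc["t1", "s1"] == 7
        assert cm.counts["s1"].sum() == 7  # not double-counted


class TestClustering:
    def test_overlapping_reads_one_cluster(self):
        alns = [Alignment("a", "c", 100, 150, "+", 0),
                Alignment("b", "c", 140, 190, "+", 0)]
        assert len(cluster_unannotated(alns, min_gap=100)) == 1

    def test_distant_reads_split(self):
        alns = [Alignment("a", "c", 100, 150, "+", 0),
                Alignment("b", "c", 1150, 1200, "+", 0)]
        assert len(cluster_unannotated(alns, min_gap=100)) == 2

    def test_matches_brute_force_single_linkage(self):
        rng = np.random.default_rng(30)
        alns = [Alignment(f"r{i}", "c", int(s), int(s) + 50, "+", 0)
                for i, s in enumerate(rng.integers(0, 20_000, size=60))]
        min_gap = 200
        got = cluster_unannotated(alns, min_gap=min_gap)
        # oracle: transitive closure of the "gap < min_gap" relation
        parent = list(range(len(alns)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(len(alns)):
            for j in range(i + 1, len(alns)):
                a, b = alns[i], alns[j]
                gap = max(b.start - a.end, a.start - b.end, 0)
                if gap < min_gap:
                    parent[find(i)] = find(j)
        n_components = len({find(i) for i in range(len(alns))})
        assert len(got) == n_components
        assert sum(r[4] for r in got) == len(alns)
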