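"""Synthetic-data generator: determinism, planted truth, NB recovery."""

import numpy as np
import pytest

from pollensnc import seqio, synthetic
from pollensnc.discovery import check_plant_criteria, extract_duplex
from pollensnc.folding import fold
from pollensnc.preprocess import collapse_pcr_duplicates
from pollensnc.stats import size_factors
from pollensnc.synthetic import (CapacityError, SyntheticTruth, make_genome,
                                 simulate_count_matrix, simulate_mace_library,
                                 simulate_sncrna_library)


class TestMakeGenome:
    def test_seed_determinism_bytes(self, tmp_path):
        paths = []
        for run in (1, 2):
            genome, features, _ = make_genome(50_000, 20, 8, 3, 5, seed=1)
            fa = tmp_path / f"g{run}.fa"
            gff = tmp_path / f"a{run}.gff3"
            seqio.write_fasta(genome, fa)
            seqio.write_gff3(features, gff)
            paths.append((fa.read_bytes(), gff.read_bytes()))
        assert paths[0] == paths[1]

    def test_no_hairpins_requested(self):
        _, _, truth = make_genome(30_000, 5, 2, 1, 0, seed=2)
        assert truth.planted_hairpins == []

    def test_features_do_not_overlap(self):
        _, features, _ = make_genome(50_000, 20, 8, 3, 5, seed=3)
        spans = sorted((f.start, f.end) for f in features
                       if f.ftype != "gene")  # exons/introns tile their gene
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_capacity_error_when_too_small(self):
        with pytest.raises(CapacityError):
            make_genome(2_000, 20, 8, 3, 5, seed=4)

    def test_planted_hairpins_pass_plant_criteria(self):
        """Folding each planted precursor yields a duplex the checker accepts."""
        _, _, truth = make_genome(50_000, 20, 8, 3, 5, seed=1)
        genome_seq = truth.genome[synthetic.CONTIG]
        assert truth.planted_hairpins
        for h in truth.planted_hairpins:
            precursor = genome_seq[h.start:h.end]
            structure, mfe = fold(precursor)
            assert structure.count("(") >= 18
            d = extract_duplex(precursor, structure, 0, len(h.mature))
            assert check_plant_criteria(d).passed, h.feature_id

    def test_planted_de_ids_exist(self):
        _, _, truth = make_genome(50_000, 20, 8, 3, 5, seed=5)
        known = set(truth.expression)
        assert truth.planted_de and set(truth.planted_de) <= known

    def test_truth_json_round_trip_is_byte_stable(self):
        _, _, truth = make_genome(30_000, 5, 4, 2, 2, seed=6)
        text1 = truth.to_json()
        text2 = SyntheticTruth.from_json(text1).to_json()
        assert text1 == text2


class TestSncrnaLibrary:
    def test_seed_determinism(self):
        _, _, truth = make_genome(30_000, 5, 4, 2, 2, seed=7)
        a = simulate_sncrna_library(truth, "control", 1, 2_000)
        b = simulate_sncrna_library(truth, "control", 1, 2_000)
        assert [(r.read_id, r.sequence) for r in a] == \
            [(r.read_id, r.sequence) for r in b]

    def test_read_count_conservation(self):
        _, _, truth = make_genome(30_000, 5, 4, 2, 2, seed=8)
        depth, rate = 3_000, 0.25
        reads = simulate_sncrna_library(truth, "control", 1, depth,
                                        duplicate_rate=rate)
        assert len(reads) == depth + round(depth * rate)

    def test_zero_duplicate_rate_leaves_dedup_unchanged(self):
        _, _, truth = make_genome(30_000, 5, 4, 2, 2, seed=9)
        reads = simulate_sncrna_library(truth, "control", 1, 2_000,
                                        duplicate_rate=0.0)
        collapsed, _ = collapse_pcr_duplicates(reads)
        assert len(collapsed) == len(reads)

    def test_duplicate_rate_half_collapses_back(self):
        _, _, truth = make_genome(30_000, 5, 4, 2, 2, seed=10)
        reads = simulate_sncrna_library(truth, "control", 1, 1_000,
                                        duplicate_rate=0.5)
        assert len(reads) == 1_500
        collapsed, _ = collapse_pcr_duplicates(reads)
        assert len(collapsed) == 1_000

    def test_unknown_condition_rejected(self):
        _, _, truth = make_genome(30_000, 5, 4, 2, 2, seed=11)
        with pytest.raises(ValueError, match="unknown condition"):
            simulate_sncrna_library(truth, "drought", 1, 100)

    def test_length_histogram_peaks_at_22_and_24(self):
        _, _, truth = make_genome(30_000, 5, 4, 2, 0, seed=12)
        reads = simulate_sncrna_library(truth, "control", 1, 20_000,
                                        duplicate_rate=0.0)
        from pollensnc.preprocess import (build_library, length_histogram,
                                          trim_adapters)
        collapsed, _ = collapse_pcr_duplicates(reads)
        trimmed = trim_adapters(collapsed, truth.adapter3, truth.adapter5)
        hist = length_histogram(build_library(trimmed, "s", "control"))
        top2 = sorted(hist, key=hist.get, reverse=True)[:2]
        assert set(top2) == {22, 24}

    def test_planted_log2fc_recovered(self):
        """A +2 planted fold change is recovered within the NB noise band."""
        _, _, truth = make_genome(40_000, 10, 6, 2, 0, seed=13,
                                  planted_fraction=0.3, planted_log2fc=2.0)
        up = [fid for fid, lfc in truth.planted_de.items()
              if lfc > 0 and fid in truth.trna_loci]
        assert up
        from collections import Counter
        per_cond = {}
        for cond in ("control", "heat"):
            tot = Counter()
            for rep in (1, 2, 3):
                reads = simulate_sncrna_library(truth, cond, rep, 30_000,
                                                duplicate_rate=0.0)
                tot.update(r.comment.split("src:")[1] for r in reads)
            per_cond[cond] = tot
        for fid in up:
            lfc = np.log2(per_cond["heat"][fid] / per_cond["control"][fid])
            assert 1.5 <= lfc <= 2.5, fid

    def test_null_features_balanced_between_conditions(self):
        _, _, truth = make_genome(40_000, 10, 6, 2, 0, seed=14,
                                  planted_fraction=0.0)
        from collections import Counter
        tot = {c: Counter() for c in ("control", "heat")}
        for cond in tot:
            for rep in (1, 2, 3):
                reads = simulate_sncrna_library(truth, cond, rep, 30_000,
                                                duplicate_rate=0.0)
                tot[cond].update(r.comment.split("src:")[1] for r in reads)
        disp = 0.1
        for fid in truth.trna_loci:
            c, h = tot["control"][fid], tot["heat"][fid]
            if min(c, h) < 30:
                continue
            # 3 NB standard errors on the mean of 3 replicates
            se = np.sqrt((c + disp * (c / 3) ** 2 * 3) +
                         (h + disp * (h / 3) ** 2 * 3))
            assert abs(h - c) <= 3 * se, fid


class TestMaceLibrary:
    def test_zero_depth_empty(self):
        _, _, truth = make_genome(30_000, 5, 4, 2, 2, seed=15)
        assert simulate_mace_library(truth, "control", 1, 0) == []

    def test_tags_map_within_3prime_window(self):
        genome, features, truth = make_genome(30_000, 5, 4, 2, 0, seed=16)
        reads = simulate_mace_library(truth, "control", 1, 2_000,
                                      duplicate_rate=0.0)
        genes = {f.feature_id: f for f in features if f.ftype == "gene"}
        genome_seq = genome[synthetic.CONTIG]
        from pollensnc.annotate import revcomp
        for r in reads[:200]:
            gid = r.comment.split("src:")[1]
            g = genes[gid]
            gseq = genome_seq[g.start:g.end]
            if g.strand == "-":
                gseq = revcomp(gseq)
            insert = r.sequence[8:]
            assert insert in gseq[-250:], gid

    def test_exact_depth_before_duplicates(self):
        _, _, truth = make_genome(30_000, 5, 4, 2, 0, seed=17)
        reads = simulate_mace_library(truth, "control", 1, 1_234,
                                      duplicate_rate=0.0)
        assert len(reads) == 1_234


class TestSimulateCountMatrix:
    def test_shape_and_design(self):
        cm = simulate_count_matrix(100, seed=1)
        assert cm.counts.shape == (100, 6)
        assert sorted(set(cm.design.values())) == ["control", "heat"]

    def test_planted_shift_visible_in_means(self):
        cm = simulate_count_matrix(200, seed=2, planted={0: 2.0},
                                   min_mean=50)
        sf = size_factors(cm.counts)
        norm = cm.counts / sf
        c = norm[cm.samples_for("control")].mean(axis=1).iloc[0]
        h = norm[cm.samples_for("heat")].mean(axis=1).iloc[0]
        assert 1.0 < np.log2(h / c) < 3.0
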