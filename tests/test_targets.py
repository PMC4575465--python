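"""Seed-weighted target alignment, duplex energy, hit filtering."""

import numpy as np
import pandas as pd
import pytest

from pollensnc.annotate import revcomp
from pollensnc.targets import (GAP_EXTEND, GAP_OPEN, STACK_TABLE,
                               TargetHit, _pair_score, _seed_weight,
                               align_mirna_target, duplex_energy, hits_table,
                               integrate_expression, predict_targets)

MIRNA21 = "UGAACCUAGCUCGGAUCAGCG"  # 21 nt


def brute_force_best_score(q: str, t: str) -> float:
    """Exhaustive local-alignment oracle for tiny sequences.

    Enumerates every alignment path (pair, query gap, target gap) between
    every pair of start points by depth-first search, applying the same
    scoring constants; independent of the DP implementation.
    """
    q = q.upper().replace("T", "U")[::-1]
    t = t.upper().replace("T", "U")
    n, m = len(q), len(t)
    best = 0.0

    def walk(i, j, score, last):
        nonlocal best
        best = max(best, score)
        if i < n and j < m:
            w = _seed_weight(n, i)
            walk(i + 1, j + 1, score + w * _pair_score(q[i], t[j]), "M")
        if i < n:
            cost = GAP_EXTEND if last == "X" else GAP_OPEN
            walk(i + 1, j, score + cost, "X")
        if j < m:
            cost = GAP_EXTEND if last == "Y" else GAP_OPEN
            walk(i, j + 1, score + cost, "Y")

    for i0 in range(n):
        for j0 in range(m):
            walk(i0, j0, 0.0, "M")
    return best


class TestAlign:
    def test_perfect_complement_hand_score(self):
        # 21 paired positions: 15 at weight 1 (+5 each) and 6 seed
        # positions at weight 4 (+20 each) = 195
        target = revcomp(MIRNA21)
        assert align_mirna_target(MIRNA21, target).score == 195.0

    def test_no_complementarity_scores_zero(self):
        assert align_mirna_target("A" * 21, "C" * 30).score == 0.0

    def test_empty_sequence_scores_zero(self):
        assert align_mirna_target("", "ACGU").score == 0.0

    @pytest.mark.parametrize("q,t", [
        ("ACGUACGU", "ACGUACGU"), ("GGGCCC", "GGGCCC"), ("AUGCUA", "UAGCAU"),
        ("GUGUGU", "ACACAC"), ("ACG", "CGUACG"), ("UUUUAAC", "GUUAA"),
    ])
    def test_dp_equals_exhaustive_enumeration(self, q, t):
        assert align_mirna_target(q, t).score == \
            pytest.approx(brute_force_best_score(q, t))

    def test_extra_mismatch_never_increases_score(self):
        target = revcomp(MIRNA21)
        base = align_mirna_target(MIRNA21, target).score
        swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
        for pos in range(len(target)):
            mutated = list(target)
            mutated[pos] = swap[mutated[pos]]
            assert align_mirna_target(MIRNA21, "".join(mutated)).score <= base

    def test_score_symmetric_under_joint_reversal(self):
        # holds for the unweighted scorer; seed weighting deliberately
        # breaks it because reversal relocates the seed region
        rng = np.random.default_rng(3)
        for _ in range(10):
            q = "".join(rng.choice(list("ACGU"), size=12))
            t = "".join(rng.choice(list("ACGU"), size=25))
            a = align_mirna_target(q, t, seed_scale=1.0).score
            b = align_mirna_target(q[::-1], t[::-1], seed_scale=1.0).score
            assert a == pytest.approx(b)


class TestDuplexEnergy:
    def test_gc_duplex_more_stable_than_au(self):
        gc = align_mirna_target("G" * 10, "C" * 10)
        au_mir = "A" * 10
        au = align_mirna_target(au_mir, "U" * 10)
        assert duplex_energy(gc) < duplex_energy(au) < 0

    def test_energy_equals_table_lookup_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            mir = "".join(rng.choice(list("ACGU"), size=15))
            aln = align_mirna_target(mir, revcomp(mir))
            # oracle: walk the alignment strings, summing table entries
            pairs = []
            for qc, tc in zip(aln.mirna_aligned, aln.target_aligned):
                ok = (qc, tc) in {("A", "U"), ("U", "A"), ("G", "C"),
                                  ("C", "G"), ("G", "U"), ("U", "G")}
                pairs.append((tc, qc) if ok else None)
            expected = 0.0
            for p1, p2 in zip(pairs, pairs[1:]):
                if p1 and p2:
                    expected += STACK_TABLE[(p1[0] + p2[0], p1[1] + p2[1])]
            expected += 0.5 * sum(p is None for p in pairs)
            assert duplex_energy(aln) == pytest.approx(expected)

    def test_single_pair_has_no_stack(self):
        aln = align_mirna_target("G", "C")
        assert duplex_energy(aln) >= -1.0


def _transcripts_with_sites(mirna: str, n_sites: int, seed: int = 9):
    rng = np.random.default_rng(seed)
    site = revcomp(mirna)
    transcripts = {}
    for i in range(n_sites):
        flank1 = "".join(rng.choice(list("ACGT"), size=60))
        flank2 = "".join(rng.choice(list("ACGT"), size=60))
        transcripts[f"tx{i:02d}"] = flank1 + site + flank2
    for i in range(5):  # decoys without sites
        transcripts[f"decoy{i}"] = "".join(rng.choice(list("ACGT"), size=140))
    return transcripts


class TestPredictTargets:
    def test_planted_site_found_at_rank_one(self):
        transcripts = _transcripts_with_sites(MIRNA21, 1)
        hits = predict_targets({"mir1": MIRNA21}, transcripts)
        assert [h.target_id for h in hits] == ["tx00"]
        site = hits[0].site
        assert transcripts["tx00"][site[0]:site[1]] == revcomp(MIRNA21)

    def test_fifteen_sites_keep_ten_best(self):
        transcripts = _transcripts_with_sites(MIRNA21, 15)
        hits = predict_targets({"mir1": MIRNA21}, transcripts)
        assert len(hits) == 10
        # retained hits outrank every dropped one under the total order
        ranked = sorted(hits, key=lambda h: (-h.align_score, h.free_energy,
                                             h.target_id))
        assert [h.target_id for h in hits] == [h.target_id for h in ranked]

    def test_no_site_above_threshold_is_empty(self):
        rng = np.random.default_rng(10)
        transcripts = {"t": "".join(rng.choice(list("ACGT"), size=200))}
        assert predict_targets({"mir1": MIRNA21}, transcripts) == []

    def test_energy_filter_flag(self):
        transcripts = _transcripts_with_sites(MIRNA21, 1)
        strict = predict_targets({"m": MIRNA21}, transcripts,
                                 energy_max=-1000.0, energy_filter=True)
        relaxed = predict_targets({"m": MIRNA21}, transcripts,
                                  energy_max=-1000.0, energy_filter=False)
        assert strict == [] and len(relaxed) == 1


class TestIntegrateExpression:
    def _hit(self):
        aln = align_mirna_target(MIRNA21, revcomp(MIRNA21))
        return TargetHit("m1", "t1", aln.score, duplex_energy(aln),
                         (0, 21), aln)

    @pytest.mark.parametrize("m_lfc,t_lfc,expected", [
        (2.0, -1.0, True),   # up-regulated miRNA, down-regulated target
        (1.0, 1.0, False),
        (1.0, 0.0, False),
        (-1.5, 0.7, True),
    ])
    def test_anticorrelation_flag(self, m_lfc, t_lfc, expected):
        hits = integrate_expression(
            [self._hit()],
            pd.DataFrame({"id": ["m1"], "log2fc": [m_lfc]}),
            pd.DataFrame({"id": ["t1"], "log2fc": [t_lfc], "fdr": [0.5]}))
        assert hits[0].anticorrelated is expected

    def test_missing_target_flagged(self):
        hits = integrate_expression(
            [self._hit()],
            pd.DataFrame({"id": ["m1"], "log2fc": [1.0]}),
            pd.DataFrame({"id": ["other"], "log2fc": [0.0], "fdr": [1.0]}))
        assert hits[0].missing_expression and not hits[0].anticorrelated

    def test_hits_table_columns(self):
        df = hits_table([self._hit()])
        assert list(df.columns)[:4] == ["mirna_id", "target_id", "score", "FE"]
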