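"""miRNA target prediction by seed-weighted complementarity alignment.

A Smith-Waterman-style local alignment scores antiparallel complementarity
between a mature miRNA and a candidate transcript: Watson-Crick pairs +5,
G:U wobbles +1, mismatches -3, affine gaps (-9 open, -4 extend), with
contributions at miRNA positions 2-7 from the 5' end (the seed) scaled by
4.  Hit stability is a nearest-neighbor stack-energy sum over the aligned
duplex.  Hits are filtered on score and energy and capped at the ten best
per miRNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MATCH, WOBBLE_SCORE, MISMATCH = 5.0, 1.0, -3.0
GAP_OPEN, GAP_EXTEND = -9.0, -4.0
SEED_START, SEED_END, SEED_SCALE = 2, 7, 4.0  # 1-based miRNA positions
SCORE_MIN_DEFAULT = 140.0
ENERGY_MAX_DEFAULT = -20.0
TOP_N_DEFAULT = 10

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}

# Nearest-neighbor stack free energies (kcal/mol, 37 C) for consecutive base
# pairs; key is (top dinucleotide 5'->3', bottom dinucleotide 3'->5').
# Watson-Crick values are the standard nearest-neighbor set; stacks involving
# G:U wobbles use a coarse three-level model (see docs).
_WC_STACKS = {
    ("AA", "UU"): -0.93, ("AU", "UA"): -1.10, ("UA", "AU"): -1.33,
    ("CU", "GA"): -2.08, ("CA", "GU"): -2.11, ("GU", "CA"): -2.24,
    ("GA", "CU"): -2.35, ("CG", "GC"): -2.36, ("GG", "CC"): -3.26,
    ("GC", "CG"): -3.42,
}
LOOP_PENALTY = 0.5  # kcal/mol per unpaired position inside the duplex


def _build_stack_table() -> dict[tuple[str, str], float]:
    table: dict[tuple[str, str], float] = {}
    for (top, bottom), e in _WC_STACKS.items():
        table[(top, bottom)] = e
        # the same stack read from the other strand
        table[(bottom[::-1], top[::-1])] = e
    return table


STACK_TABLE = _build_stack_table()


def _is_pair(x: str, y: str) -> bool:
    return (x, y) in _PAIRS or (x, y) in _WOBBLE


def _wobble_stack_energy(p1: tuple[str, str], p2: tuple[str, str]) -> float:
    """Coarse stack model when at least one pair is a G:U wobble."""
    def strength(p):
        return 2 if p in (("G", "C"), ("C", "G")) else (
            1 if p in (("A", "U"), ("U", "A")) else 0)
    s = strength(p1) + strength(p2)
    return {4: -3.0, 3: -2.0, 2: -1.2, 1: -0.8, 0: -0.5}[s]


def stack_energy(p1: tuple[str, str], p2: tuple[str, str]) -> float:
    """Free energy of stacking pair p2 on pair p1 (5'->3' on the top strand)."""
    key = (p1[0] + p2[0], p1[1] + p2[1])
    if key in STACK_TABLE:
        return STACK_TABLE[key]
    if p1 in _WOBBLE or p2 in _WOBBLE:
        return _wobble_stack_energy(p1, p2)
    raise ValueError(f"not a stack of canonical pairs: {p1}, {p2}")


@dataclass
class AlignmentResult:
    score: float
    mirna_aligned: str   # miRNA 3'->5' (reversed), gapped
    match_line: str      # '|' pair, ':' wobble, ' ' otherwise
    target_aligned: str  # target 5'->3', gapped
    target_start: int    # site interval on the target, 0-based half-open
    target_end: int
    mirna_start: int     # aligned span on the reversed miRNA
    mirna_end: int


def _seed_weight(mirna_len: int, rev_index: int,
                 seed_scale: float = SEED_SCALE) -> float:
    """Seed scaling for position `rev_index` of the reversed miRNA."""
    pos_from_5p = mirna_len - rev_index  # 1-based position on the miRNA
    return seed_scale if SEED_START <= pos_from_5p <= SEED_END else 1.0


def _pair_score(q: str, t: str) -> float:
    if (q, t) in _PAIRS:
        return MATCH
    if (q, t) in _WOBBLE:
        return WOBBLE_SCORE
    return MISMATCH


def align_mirna_target(mirna_seq: str, target_seq: str,
                       seed_scale: float = SEED_SCALE) -> AlignmentResult:
    """Best local complementarity alignment of a miRNA against a target.

    The miRNA is reversed so it runs antiparallel (3'->5') against the
    target (5'->3'); each aligned column is scored by complementarity, with
    seed positions up-weighted.  Affine-gap Gotoh recurrences with a zero
    floor give the local optimum; traceback returns the alignment triple.
    """
    q = mirna_seq.upper().replace("T", "U")[::-1]
    t = target_seq.upper().replace("T", "U")
    n, m = len(q), len(t)
    if n == 0 or m == 0:
        return AlignmentResult(0.0, "", "", "", 0, 0, 0, 0)

    NEG = -1e9
    M = np.full((n + 1, m + 1), 0.0)
    X = np.full((n + 1, m + 1), NEG)   # gap in target (consumes q)
    Y = np.full((n + 1, m + 1), NEG)   # gap in query (consumes t)
    ptr = {}
    best, best_pos = 0.0, (0, 0, "M")

    for i in range(1, n + 1):
        w = _seed_weight(n, i - 1, seed_scale)
        for j in range(1, m + 1):
            s = w * _pair_score(q[i - 1], t[j - 1])
            cand = [(M[i - 1, j - 1] + s, "M"), (X[i - 1, j - 1] + s, "X"),
                    (Y[i - 1, j - 1] + s, "Y"), (0.0, "0")]
            M[i, j], src = max(cand)
            ptr[(i, j, "M")] = src
            xc = [(M[i - 1, j] + GAP_OPEN, "M"), (X[i - 1, j] + GAP_EXTEND, "X")]
            X[i, j], xsrc = max(xc)
            ptr[(i, j, "X")] = xsrc
            yc = [(M[i, j - 1] + GAP_OPEN, "M"), (Y[i, j - 1] + GAP_EXTEND, "Y")]
            Y[i, j], ysrc = max(yc)
            ptr[(i, j, "Y")] = ysrc
            if M[i, j] > best:
                best, best_pos = M[i, j], (i, j, "M")

    if best <= 0:
        return AlignmentResult(0.0, "", "", "", 0, 0, 0, 0)

    qa, ta, ml = [], [], []
    i, j, state = best_pos
    end_i, end_j = i, j
    while i > 0 and j > 0:
        src = ptr[(i, j, state)]
        if state == "M":
            qa.append(q[i - 1])
            ta.append(t[j - 1])
            pair = (q[i - 1], t[j - 1])
            ml.append("|" if pair in _PAIRS else (":" if pair in _WOBBLE else " "))
            i, j = i - 1, j - 1
        elif state == "X":
            qa.append(q[i - 1])
            ta.append("-")
            ml.append(" ")
            i -= 1
        else:
            qa.append("-")
            ta.append(t[j - 1])
            ml.append(" ")
            j -= 1
        if src == "0":
            break
        state = src
    return AlignmentResult(float(best), "".join(reversed(qa)),
                           "".join(reversed(ml)), "".join(reversed(ta)),
                           j, end_j, i, end_i)


def duplex_energy(alignment: AlignmentResult) -> float:
    """Stack-energy sum over the aligned duplex, kcal/mol.

    Consecutive aligned pairs contribute their nearest-neighbor stack energy;
    every unpaired or gapped column inside the duplex adds a fixed
    destabilizing loop penalty.  No pairs at all gives 0.
    """
    pairs: list[tuple[str, str] | None] = []
    for qc, tc in zip(alignment.mirna_aligned, alignment.target_aligned):
        if qc != "-" and tc != "-" and _is_pair(qc, tc):
            pairs.append((tc, qc))  # top strand = target 5'->3'
        else:
            pairs.append(None)
    if not any(pairs):
        return 0.0
    energy = 0.0
    prev: tuple[str, str] | None = None
    for p in pairs:
        if p is None:
            energy += LOOP_PENALTY
            prev = None
            continue
        if prev is not None:
            energy += stack_energy(prev, p)
        prev = p
    return energy


@dataclass
class TargetHit:
    mirna_id: str
    target_id: str
    align_score: float
    free_energy: float
    site: tuple[int, int]
    alignment: AlignmentResult
    tpm_n: float = np.nan
    tpm_h: float = np.nan
    log2fc: float = np.nan
    fdr: float = np.nan
    anticorrelated: bool = False
    missing_expression: bool = False


def predict_targets(mirnas: dict[str, str], transcripts: dict[str, str],
                    score_min: float = SCORE_MIN_DEFAULT,
                    energy_max: float = ENERGY_MAX_DEFAULT,
                    top_n: int = TOP_N_DEFAULT,
                    energy_filter: bool = True) -> list[TargetHit]:
    """Score every miRNA against every transcript and keep the best hits.

    A hit requires alignment score >= ``score_min`` and (when the energy
    filter is active) duplex energy <= ``energy_max``.  Hits are ordered by
    score (descending), energy (ascending), then target id, and capped at
    ``top_n`` per miRNA.
    """
    hits: list[TargetHit] = []
    for mid in sorted(mirnas):
        per_mirna: list[TargetHit] = []
        for tid in sorted(transcripts):
            aln = align_mirna_target(mirnas[mid], transcripts[tid])
            if aln.score < score_min:
                continue
            energy = duplex_energy(aln)
            if energy_filter and energy > energy_max:
                continue
            per_mirna.append(TargetHit(mid, tid, aln.score, energy,
                                       (aln.target_start, aln.target_end), aln))
        per_mirna.sort(key=lambda h: (-h.align_score, h.free_energy, h.target_id))
        hits.extend(per_mirna[:top_n])
    return hits


def integrate_expression(hits: list[TargetHit], mirna_de: pd.DataFrame,
                         target_de: pd.DataFrame,
                         target_tpm_n: pd.Series | None = None,
                         target_tpm_h: pd.Series | None = None
                         ) -> list[TargetHit]:
    """Attach expression statistics to hits and flag anticorrelation.

    A hit is anticorrelated when its miRNA and target log2 fold changes have
    strictly opposite signs.  Targets absent from the DE table get missing
    fields and a flag.
    """
    mirna_lfc = dict(zip(mirna_de["id"], mirna_de["log2fc"]))
    tgt = target_de.set_index("id")
    for h in hits:
        m_lfc = mirna_lfc.get(h.mirna_id, np.nan)
        if h.target_id not in tgt.index:
            h.missing_expression = True
            continue
        row = tgt.loc[h.target_id]
        h.log2fc = float(row["log2fc"])
        h.fdr = float(row["fdr"])
        if target_tpm_n is not None and h.target_id in target_tpm_n.index:
            h.tpm_n = float(target_tpm_n[h.target_id])
        if target_tpm_h is not None and h.target_id in target_tpm_h.index:
            h.tpm_h = float(target_tpm_h[h.target_id])
        h.anticorrelated = bool(
            np.isfinite(m_lfc) and not np.isnan(h.log2fc)
            and m_lfc != 0 and h.log2fc != 0
            and np.sign(m_lfc) == -np.sign(h.log2fc))
    return hits


def hits_table(hits: list[TargetHit]) -> pd.DataFrame:
    """Report table with the standard column layout (FE, tpm-N, tpm-H, log2, fdr)."""
    rows = [{
        "mirna_id": h.mirna_id, "target_id": h.target_id,
        "score": h.align_score, "FE": h.free_energy,
        "site_start": h.site[0], "site_end": h.site[1],
        "tpm_N": h.tpm_n, "tpm_H": h.tpm_h,
        "log2": h.log2fc, "fdr": h.fdr,
        "anticorrelated": h.anticorrelated,
    } for h in hits]
    return pd.DataFrame(rows, columns=["mirna_id", "target_id", "score", "FE",
                                       "site_start", "site_end", "tpm_N",
                                       "tpm_H", "log2", "fdr",
                                       "anticorrelated"])
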