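"""Novel plant miRNA discovery from the intron/intergenic read pool.

A 270-nt window is folded around each mapped read stack; the most abundant
stack is taken as the candidate mature miRNA, its pairing partner on the
opposite arm (shifted to leave the 2-nt 3' overhangs diagnostic of Dicer
cleavage) as the star.  Candidates must satisfy the plant criteria — mature
at least 21 nt, at most four unpaired mature bases in the duplex, asymmetric
bulges no larger than two bases and at most one of them, 2-nt 3' overhangs
on both ends — plus MFE significance against dinucleotide-shuffled nulls and
a read-signature check (reads pile onto mature, star, or loop).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .annotate import AnnotatedRead, revcomp
from .folding import MfeSignificance, fold, pair_table, score_precursor

logger = logging.getLogger(__name__)

WOBBLE = {("G", "U"), ("U", "G")}
WATSON_CRICK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


@dataclass
class Duplex:
    """Geometry of a miRNA/miRNA* duplex extracted from a folded hairpin."""

    mature_len: int
    n_mismatches: int           # unpaired mature bases within the duplex
    n_wobble: int               # G:U pairs (paired, reported separately)
    bulges: list[int] = field(default_factory=list)  # asymmetric bulge sizes
    overhang_mature: int = 2    # 3' overhang at the mature end
    overhang_star: int = 2      # 3' overhang at the star end
    star_interval: tuple[int, int] | None = None  # precursor coordinates
    error: str | None = None    # e.g. "loop-spanning"


@dataclass
class CriteriaVerdict:
    passed: bool
    reasons: list[str] = field(default_factory=list)


@dataclass
class HairpinCandidate:
    contig: str
    strand: str
    window: tuple[int, int]           # genome coordinates, 0-based half-open
    sequence: str                     # window sequence, 5'->3' on `strand`
    structure: str = ""
    mfe: float = 0.0
    mature: tuple[int, int, str] | None = None  # window-local start/end, seq
    star: tuple[int, int, str] | None = None
    duplex: Duplex | None = None
    verdict: CriteriaVerdict | None = None
    significance: MfeSignificance | None = None
    signature_ok: bool = False
    name: str = ""


def extract_duplex(sequence: str, structure: str,
                   mature_start: int, mature_end: int) -> Duplex:
    """Describe the mature/star duplex implied by a folded precursor.

    The mature interval (precursor-local, 0-based half-open) must lie on one
    arm; its last two bases are the Dicer 3' overhang and are excluded from
    pairing.  The star is the pairing partner region shifted to leave 2-nt 3'
    overhangs on both ends.  Unpaired mature bases inside the duplex count as
    mismatches; runs of unpaired bases on exactly one strand count as
    asymmetric bulges.
    """
    seq = sequence.upper().replace("T", "U")
    table = pair_table(structure)
    mature_len = mature_end - mature_start
    if mature_len < 1 or mature_end > len(seq):
        return Duplex(mature_len, 0, 0, error="bad-mature-interval")

    core = range(mature_start, mature_end - 2)  # excludes the 2-nt overhang
    partners = [table[i] for i in core]
    paired = [(i, j) for i, j in zip(core, partners) if j is not None]
    if not paired:
        return Duplex(mature_len, mature_len, 0, error="unpaired-mature")
    # partner falling inside the mature itself means the mature folds onto
    # itself across the terminal loop
    if any(mature_start <= j < mature_end for _, j in paired):
        return Duplex(mature_len, 0, 0, error="loop-spanning")

    # the star lies on the dominant opposite arm: pairs of an antiparallel
    # helix share i + j up to bulge shifts, so stray pairs against distant
    # regions (folding artifacts of the surrounding window) are recognized
    # by their deviant diagonal and demoted to mismatches
    diags = sorted(i + j for i, j in paired)
    med = diags[len(diags) // 2]
    kept = [(i, j) for i, j in paired if abs((i + j) - med) <= 30]
    n_stray = len(paired) - len(kept)
    paired = kept
    if not paired:
        return Duplex(mature_len, mature_len, 0, error="unpaired-mature")
    # arm consistency: partners must be monotone decreasing (single opposite arm)
    js = [j for _, j in paired]
    if any(b >= a for a, b in zip(js, js[1:])):
        return Duplex(mature_len, 0, 0, error="discontiguous-arm")

    n_mismatch = sum(1 for j in partners if j is None) + n_stray
    n_wobble = sum(1 for i, j in paired if (seq[i], seq[j]) in WOBBLE)

    bulges: list[int] = []
    for (i1, j1), (i2, j2) in zip(paired, paired[1:]):
        gap_m = i2 - i1 - 1
        gap_s = j1 - j2 - 1
        if gap_m > 0 and gap_s == 0:
            bulges.append(gap_m)
        elif gap_s > 0 and gap_m == 0:
            bulges.append(gap_s)
        # gaps on both strands form an internal loop; the mature-side gap is
        # already counted in n_mismatch

    # star interval with Dicer geometry: project the outermost paired mature
    # bases onto the opposite arm and restore 2-nt 3' overhangs at both ends
    first_i, first_j = paired[0]
    last_i, last_j = paired[-1]
    star_start = last_j - ((mature_end - 3) - last_i)
    star_end = first_j + (first_i - mature_start) + 2 + 1
    oh_star = 2
    oh_mature = 2
    if star_start < 0:
        star_start = 0
    if star_end > len(seq):
        oh_star -= star_end - len(seq)
        star_end = len(seq)
    return Duplex(mature_len, n_mismatch, n_wobble, bulges,
                  overhang_mature=oh_mature, overhang_star=max(oh_star, 0),
                  star_interval=(star_start, star_end))


def check_plant_criteria(duplex: Duplex, min_mature_len: int = 21,
                         max_mismatches: int = 4, max_bulge_size: int = 2,
                         max_bulge_count: int = 1) -> CriteriaVerdict:
    """Plant miRNA annotation criteria applied to an extracted duplex.

    Pass requires: mature >= 21 nt; <= 4 mismatched (unpaired) mature bases;
    every asymmetric bulge <= 2 nt; at most one asymmetric bulge; and 2-nt 3'
    overhangs on both duplex ends.  Failed clauses are enumerated as reason
    codes.  G:U wobbles count as paired.
    """
    reasons = []
    if duplex.error:
        reasons.append(duplex.error)
    if duplex.mature_len < min_mature_len:
        reasons.append("mature_length")
    if duplex.n_mismatches > max_mismatches:
        reasons.append("mismatches")
    if any(b > max_bulge_size for b in duplex.bulges):
        reasons.append("bulge_size")
    if len(duplex.bulges) > max_bulge_count:
        reasons.append("bulge_count")
    if duplex.overhang_mature != 2 or duplex.overhang_star != 2:
        reasons.append("overhangs")
    return CriteriaVerdict(passed=not reasons, reasons=reasons)


# ---------------------------------------------------------------------------
# Locus calling

def _merge_windows(windows: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(windows):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _signature_fraction(stacks, mature, star, window_len,
                        tolerance: int = 2) -> float:
    """Fraction of window read copies consistent with the hairpin layout.

    Consistent means the read lies within mature +/- tolerance, star +/-
    tolerance, or entirely between the two arms (the loop).
    """
    regions = []
    for start, end, _seq in (mature, star):
        regions.append((start - tolerance, end + tolerance))
    lo = min(mature[1], star[1])
    hi = max(mature[0], star[0])
    loop = (lo, hi) if lo < hi else None
    total = consistent = 0
    for start, end, copies in stacks:
        total += copies
        if any(start >= r0 and end <= r1 for r0, r1 in regions):
            consistent += copies
        elif loop and start >= loop[0] and end <= loop[1]:
            consistent += copies
    return consistent / total if total else 0.0


def call_novel_mirnas(pool: list[AnnotatedRead], genome: dict[str, str],
                      window_size: int = 270, min_read_len: int = 16,
                      min_stack_copies: int = 5,
                      min_stack_frac: float = 1e-3, n_shuffles: int = 100,
                      signature_min: float = 0.9, p_max: float = 0.05,
                      seed: int = 0) -> tuple[pd.DataFrame, list[HairpinCandidate]]:
    """Call novel miRNA loci from intron/intergenic-mapped reads.

    ``pool`` is the annotated read set; only reads with intronic/intergenic
    verdicts and length >= ``min_read_len`` seed windows.  Windows of
    ``window_size`` nt are centered on expressed read stacks, merged when
    overlapping, folded, and passed through duplex extraction, the plant
    criteria, MFE significance and the read-signature check.  A stack seeds
    a window when it carries both ``min_stack_copies`` copies and
    ``min_stack_frac`` of the eligible pool: an absolute floor alone does
    not scale with sequencing depth, since coincidental co-placements of
    unrelated reads grow linearly with the pool.  Returns the calls table
    and all evaluated candidates (including failures, with reasons).
    """
    eligible = [ar for ar in pool
                if ar.verdict is not None
                and not ar.verdict.excluded_from_discovery
                and len(ar.sequence) >= min_read_len
                and ar.alignment is not None]

    # read stacks: identical placements aggregated over reads
    stacks: dict[tuple[str, str, int, int], int] = defaultdict(int)
    for ar in eligible:
        a = ar.alignment
        stacks[(a.contig, a.strand, a.start, a.end)] += ar.copies
    total_eligible = sum(stacks.values())
    min_stack_copies = max(min_stack_copies,
                           int(min_stack_frac * total_eligible))

    # windows are merged across strands: a hairpin is a near-palindrome, so
    # antisense read stacks at the same locus describe the same precursor;
    # each merged window is evaluated on its better-supported strand
    windows: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for (contig, strand, start, end), copies in stacks.items():
        if copies < min_stack_copies:
            continue
        center = (start + end) // 2
        w0 = max(center - window_size // 2, 0)
        w1 = min(w0 + window_size, len(genome[contig]))
        windows[contig].append((w0, w1))

    candidates: list[HairpinCandidate] = []
    counter: dict[str, int] = defaultdict(int)
    for contig, wins in sorted(windows.items()):
        for w0, w1 in _merge_windows(wins):
            support = {"+": 0, "-": 0}
            for (c, s, a0, a1), copies in stacks.items():
                if c == contig and a0 >= w0 and a1 <= w1:
                    support[s] += copies
            strand = "+" if support["+"] >= support["-"] else "-"
            genome_seq = genome[contig][w0:w1]
            window_seq = genome_seq if strand == "+" else revcomp(genome_seq)
            cand = HairpinCandidate(contig, strand, (w0, w1), window_seq)

            # stacks inside the window, in window-local strand coordinates
            local = []
            for (c, s, a0, a1), copies in stacks.items():
                if c != contig or s != strand or a0 < w0 or a1 > w1:
                    continue
                if strand == "+":
                    local.append((a0 - w0, a1 - w0, copies))
                else:
                    local.append((w1 - a1, w1 - a0, copies))
            if not local:
                continue
            m0, m1, m_copies = max(local, key=lambda t: (t[2], -t[0]))
            if m_copies < min_stack_copies:
                continue

            cand.structure, cand.mfe = fold(window_seq)
            cand.mature = (m0, m1, window_seq[m0:m1].replace("T", "U"))
            duplex = extract_duplex(window_seq, cand.structure, m0, m1)
            cand.duplex = duplex
            cand.verdict = check_plant_criteria(duplex)
            if duplex.star_interval is not None:
                s0, s1 = duplex.star_interval
                cand.star = (s0, s1, window_seq[s0:s1].replace("T", "U"))
            candidates.append(cand)
            if not cand.verdict.passed:
                continue

            cand.significance = score_precursor(window_seq, n_shuffles,
                                                seed=seed + w0)
            if cand.significance.p_value > p_max:
                cand.verdict = CriteriaVerdict(False, ["mfe_significance"])
                continue
            frac = _signature_fraction(local, cand.mature, cand.star, len(window_seq))
            cand.signature_ok = frac >= signature_min
            if not cand.signature_ok:
                cand.verdict = CriteriaVerdict(False, ["read_signature"])
                continue
            counter[contig] += 1
            cand.name = f"{contig}_{counter[contig]}"

    rows = []
    for c in candidates:
        if not c.name:
            continue
        rows.append({
            "id": c.name, "contig": c.contig, "strand": c.strand,
            "window_start": c.window[0], "window_end": c.window[1],
            "mature_seq": c.mature[2], "star_seq": c.star[2] if c.star else "",
            "mfe": c.mfe, "p": c.significance.p_value,
            "score": c.significance.score, "verdict": "pass",
        })
    columns = ["id", "contig", "strand", "window_start", "window_end",
               "mature_seq", "star_seq", "mfe", "p", "score", "verdict"]
    return pd.DataFrame(rows, columns=columns), candidates
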