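"""Genome mapping and the annotation-priority cascade.

Reads are mapped with a k-mer seed index and full-length Hamming
verification on both strands.  Each alignment is assigned exactly one class
by priority: known ncRNA (miRNA > tRNA > snoRNA > rRNA) > exonic > intronic >
intergenic.  Exonic reads are excluded from novel-miRNA discovery; intronic
and intergenic reads feed it.  Per-feature counts (multimappers counted once,
at the highest-priority then leftmost locus) form the CountMatrix, and
unannotated 3'-tag alignments are clustered into consensus regions.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .preprocess import ReadLibrary
from .seqio import Feature
from .stats import CountMatrix

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")

# annotation cascade order; lower rank wins
NCRNA_CLASSES = ("miRNA", "tRNA", "snoRNA", "rRNA")
CLASS_PRIORITY = {
    "ncRNA:miRNA": 0, "ncRNA:tRNA": 1, "ncRNA:snoRNA": 2, "ncRNA:rRNA": 3,
    "exonic": 4, "intronic": 5, "intergenic": 6,
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Alignment:
    read_id: str
    contig: str
    start: int  # 0-based
    end: int    # half-open
    strand: str
    mismatches: int
    multiplicity: int = 1


@dataclass
class AnnotationVerdict:
    region_class: str
    feature_id: str | None = None
    antisense: bool = False

    @property
    def excluded_from_discovery(self) -> bool:
        return self.region_class not in ("intronic", "intergenic")

    @property
    def priority(self) -> int:
        return CLASS_PRIORITY[self.region_class]


# ---------------------------------------------------------------------------
# k-mer index + mapper

class GenomeIndex:
    """Exact k-mer position index over the forward strand of each contig."""

    def __init__(self, genome: dict[str, str], k: int = 12):
        if not (8 <= k <= 16):
            raise ValueError("k must lie in [8, 16]")
        if not genome or all(len(s) == 0 for s in genome.values()):
            raise ValueError("empty genome")
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.k = k
        self.kmers: dict[str, list[tuple[str, int]]] = defaultdict(list)
        ambiguous = 0
        for contig, seq in self.genome.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if set(kmer) - set("ACGT"):
                    ambiguous += 1
                    continue
                self.kmers[kmer].append((contig, i))
        if ambiguous:
            logger.warning("index: skipped %d k-mers with ambiguous bases",
                           ambiguous)

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        """All positions of ``kmer`` on either strand (contig, start, strand)."""
        hits = [(c, i, "+") for c, i in self.kmers.get(kmer, [])]
        hits += [(c, i, "-") for c, i in self.kmers.get(revcomp(kmer), [])]
        return hits


def build_index(genome: dict[str, str], k: int = 12) -> GenomeIndex:
    return GenomeIndex(genome, k)


def _hamming(a: str, b: str, limit: int) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


def map_read(seq: str, index: GenomeIndex, max_mismatch: int = 1,
             read_id: str = "") -> list[Alignment]:
    """All equally-best (fewest-mismatch) loci of a read on either strand.

    Seeds are non-overlapping k-mers of the read; candidate starts are
    verified by full-length Hamming comparison against the forward genome
    (the read is reverse-complemented for minus-strand candidates).
    """
    seq = seq.upper().replace("U", "T")
    k = index.k
    if len(seq) < k:
        return []
    offsets = list(range(0, len(seq) - k + 1, k))
    if offsets[-1] != len(seq) - k:
        offsets.append(len(seq) - k)

    candidates: set[tuple[str, int, str]] = set()
    rc = revcomp(seq)
    for off in offsets:
        for contig, pos in index.kmers.get(seq[off : off + k], []):
            candidates.add((contig, pos - off, "+"))
        # a read from the minus strand: its k-mer at offset `off` matches the
        # forward genome as the revcomp, which sits at rc-offset from the end
        for contig, pos in index.kmers.get(rc[off : off + k], []):
            candidates.add((contig, pos - off, "-"))

    hits: list[tuple[int, str, int, str]] = []
    for contig, start, strand in candidates:
        genome_seq = index.genome[contig]
        if start < 0 or start + len(seq) > len(genome_seq):
            continue
        query = seq if strand == "+" else rc
        mm = _hamming(query, genome_seq[start : start + len(seq)], max_mismatch)
        if mm <= max_mismatch:
            hits.append((mm, contig, start, strand))
    if not hits:
        return []
    best = min(h[0] for h in hits)
    best_hits = sorted(h for h in hits if h[0] == best)
    return [Alignment(read_id, contig, start, start + len(seq), strand, mm,
                      multiplicity=len(best_hits))
            for mm, contig, start, strand in best_hits]


# ---------------------------------------------------------------------------
# Annotation cascade

class AnnotationIndex:
    """Interval trees over features, split into ncRNA and gene-model layers."""

    def __init__(self, features: list[Feature]):
        self.ncrna: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self.genic: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self.contigs = {f.contig for f in features}
        for f in features:
            if len(f) == 0:
                continue
            if f.ftype in NCRNA_CLASSES:
                self.ncrna[f.contig][f.start:f.end] = f
            elif f.ftype in ("exon", "intron"):
                self.genic[f.contig][f.start:f.end] = f


def _overlap_frac(a: Alignment, f: Feature) -> float:
    inter = min(a.end, f.end) - max(a.start, f.start)
    return max(inter, 0) / (a.end - a.start)


def annotate_alignment(a: Alignment, ann: AnnotationIndex,
                       min_overlap_frac: float = 0.5) -> AnnotationVerdict:
    """Assign one region class to an alignment by the cascade priority.

    An alignment overlaps a feature when at least ``min_overlap_frac`` of the
    read lies inside the feature interval.  Antisense overlap counts only for
    ncRNA classes (flagged); gene-model features are strand-specific.
    """
    if a.contig not in ann.contigs:
        logger.warning("contig %s absent from annotation; calling intergenic",
                       a.contig)
        return AnnotationVerdict("intergenic")

    best: tuple[int, str, Feature, bool] | None = None
    for iv in ann.ncrna.get(a.contig, IntervalTree()).overlap(a.start, a.end):
        f: Feature = iv.data
        if _overlap_frac(a, f) < min_overlap_frac:
            continue
        rank = CLASS_PRIORITY[f"ncRNA:{f.ftype}"]
        if best is None or rank < best[0]:
            best = (rank, f"ncRNA:{f.ftype}", f, f.strand != a.strand)
    if best is not None:
        _, cls, f, anti = best
        return AnnotationVerdict(cls, f.feature_id, antisense=anti)

    for iv in ann.genic.get(a.contig, IntervalTree()).overlap(a.start, a.end):
        f = iv.data
        if f.strand != a.strand or _overlap_frac(a, f) < min_overlap_frac:
            continue
        rank = CLASS_PRIORITY["exonic" if f.ftype == "exon" else "intronic"]
        if best is None or rank < best[0]:
            best = (rank, "exonic" if f.ftype == "exon" else "intronic", f, False)
    if best is not None:
        _, cls, f, _ = best
        return AnnotationVerdict(cls, f.attributes.get("gene_id", f.feature_id))
    return AnnotationVerdict("intergenic")


@dataclass
class AnnotatedRead:
    sequence: str
    copies: int
    alignment: Alignment | None
    verdict: AnnotationVerdict | None


def annotate_library(library: ReadLibrary, index: GenomeIndex,
                     ann: AnnotationIndex, max_mismatch: int = 1,
                     min_overlap_frac: float = 0.5) -> list[AnnotatedRead]:
    """Map and classify every distinct read of a library.

    Multimapping reads are placed once, at the highest-priority (then
    leftmost) locus among their equally-best alignments.
    """
    out = []
    for rec in library.reads:
        alns = map_read(rec.sequence, index, max_mismatch=max_mismatch)
        if not alns:
            out.append(AnnotatedRead(rec.sequence, rec.copies, None, None))
            continue
        verdicts = [annotate_alignment(a, ann, min_overlap_frac) for a in alns]
        chosen = min(range(len(alns)),
                     key=lambda i: (verdicts[i].priority, alns[i].contig,
                                    alns[i].start))
        out.append(AnnotatedRead(rec.sequence, rec.copies, alns[chosen],
                                 verdicts[chosen]))
    return out


def class_totals(annotated: list[AnnotatedRead], copy_weighted: bool = True
                 ) -> pd.Series:
    """Read totals per region class plus mapped/unmapped conservation rows."""
    totals: dict[str, int] = defaultdict(int)
    for ar in annotated:
        w = ar.copies if copy_weighted else 1
        totals["total"] += w
        if ar.verdict is None:
            totals["unmapped"] += w
        else:
            totals["mapped"] += w
            totals[ar.verdict.region_class] += w
    return pd.Series(dict(totals), dtype=int)


def count_features(annotated_by_sample: dict[str, list[AnnotatedRead]],
                   design: dict[str, str]) -> CountMatrix:
    """Per-feature raw counts (read copies summed) per sample."""
    feature_ids: set[str] = set()
    per_sample: dict[str, dict[str, int]] = {}
    for sample, annotated in annotated_by_sample.items():
        counts: dict[str, int] = defaultdict(int)
        for ar in annotated:
            if ar.verdict is None or ar.verdict.feature_id is None:
                continue
            counts[ar.verdict.feature_id] += ar.copies
        per_sample[sample] = counts
        feature_ids.update(counts)
    index = sorted(feature_ids)
    df = pd.DataFrame({s: [per_sample[s].get(f, 0) for f in index]
                       for s in per_sample}, index=index)
    return CountMatrix(df, design)


# ---------------------------------------------------------------------------
# MACE cluster calling

def cluster_unannotated(alignments: list[Alignment], min_gap: int = 100,
                        weights: dict[str, int] | None = None
                        ) -> list[tuple[str, int, int, str, int]]:
    """Merge unannotated alignments separated by < min_gap into regions.

    Returns BED-style rows (contig, start, end, name, read_count), one per
    maximal single-linkage run of alignments.
    """
    rows = []
    by_contig: dict[str, list[Alignment]] = defaultdict(list)
    for a in alignments:
        by_contig[a.contig].append(a)
    for contig in sorted(by_contig):
        alns = sorted(by_contig[contig], key=lambda a: (a.start, a.end))
        cluster: list[Alignment] = []
        clusters: list[list[Alignment]] = []
        cur_end = None
        for a in alns:
            if cur_end is not None and a.start - cur_end >= min_gap:
                clusters.append(cluster)
                cluster = []
                cur_end = None
            cluster.append(a)
            cur_end = a.end if cur_end is None else max(cur_end, a.end)
        if cluster:
            clusters.append(cluster)
        for i, cl in enumerate(clusters, start=1):
            n = sum((weights or {}).get(a.read_id, 1) for a in cl)
            rows.append((contig, min(a.start for a in cl),
                         max(a.end for a in cl), f"{contig}_cluster{i}", n))
    return rows
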