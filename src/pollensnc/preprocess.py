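"""Raw-read preprocessing and the size/abundance read classification.

Small-RNA libraries carry an 8-nt molecular tag prefix used to collapse PCR
duplicates, plus ligation adapters at both ends.  After collapsing and
trimming, distinct read sequences are classified by length (22 nt, 24 nt,
"other" >= 20 nt, "short" < 20 nt) and by abundance (singleton = sequence
seen exactly once in the library vs non-singleton).
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .seqio import FastqRead

logger = logging.getLogger(__name__)

HIST_MIN, HIST_MAX = 13, 38  # reported length range


@dataclass
class ReadRecord:
    """A distinct read sequence with its post-dedup multiplicity."""

    sequence: str
    copies: int

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def size_class(self) -> str:
        n = self.length
        if n < 20:
            return "short"
        if n == 22:
            return "22"
        if n == 24:
            return "24"
        return "other"

    @property
    def singleton(self) -> bool:
        return self.copies == 1


@dataclass
class ReadLibrary:
    sample_id: str
    condition: str
    stage: str = ""
    reads: list[ReadRecord] = field(default_factory=list)
    total_raw: int = 0

    @property
    def total_dedup(self) -> int:
        return len(self.reads)

    @property
    def total_copies(self) -> int:
        return sum(r.copies for r in self.reads)


def collapse_pcr_duplicates(reads: list[FastqRead], tag_len: int = 8
                            ) -> tuple[list[FastqRead], int]:
    """Collapse exact PCR duplicates identified by the molecular-tag prefix.

    Reads sharing both the first ``tag_len`` nucleotides (the tag) and the
    remaining insert are retained once, with the tag stripped from the output.
    Reads shorter than the tag are dropped.  Returns (reads, n_dropped_short).
    """
    seen: set[tuple[str, str]] = set()
    out: list[FastqRead] = []
    dropped = 0
    for r in reads:
        if len(r.sequence) <= tag_len:
            dropped += 1
            continue
        tag, insert = r.sequence[:tag_len], r.sequence[tag_len:]
        key = (tag, insert)
        if key in seen:
            continue
        seen.add(key)
        out.append(FastqRead(r.read_id, insert, r.quality[tag_len:], r.comment))
    if dropped:
        logger.info("collapse_pcr_duplicates: dropped %d reads shorter than "
                    "the %d-nt tag", dropped, tag_len)
    return out, dropped


def _allowed_mm(overlap: int, max_mismatch: int) -> int:
    # short overlaps must match exactly; mismatches earn in at a 10% rate
    return min(max_mismatch, overlap // 10)


def _trim_3prime(seq: str, adapter: str, min_overlap: int, max_mismatch: int) -> str:
    """Remove the longest read suffix matching a prefix of the 3' adapter."""
    best = 0
    limit = min(len(seq), len(adapter))
    for n in range(min_overlap, limit + 1):
        suffix = seq[-n:]
        prefix = adapter[:n]
        mm = sum(a != b for a, b in zip(suffix, prefix))
        if mm <= _allowed_mm(n, max_mismatch):
            best = n
    return seq[: len(seq) - best] if best else seq


def _trim_5prime(seq: str, adapter: str, min_overlap: int, max_mismatch: int) -> str:
    """Remove the longest read prefix matching a suffix of the 5' adapter."""
    best = 0
    limit = min(len(seq), len(adapter))
    for n in range(min_overlap, limit + 1):
        prefix = seq[:n]
        suffix = adapter[-n:]
        mm = sum(a != b for a, b in zip(prefix, suffix))
        if mm <= _allowed_mm(n, max_mismatch):
            best = n
    return seq[best:] if best else seq


def trim_adapters(reads: list[FastqRead], adapter3: str, adapter5: str = "",
                  min_overlap: int = 5, max_mismatch: int = 1
                  ) -> list[FastqRead]:
    """Trim ligation adapters from both read ends.

    The longest read suffix matching a prefix of ``adapter3`` (and the
    longest prefix matching a suffix of ``adapter5``), at or above the
    minimum overlap, is removed.  Up to ``max_mismatch`` mismatches are
    tolerated, earned in at one per 10 nt of overlap so that short overlaps
    must match exactly.  Reads emptied by trimming are dropped; unmatched
    reads pass unchanged.
    """
    if not adapter3 and not adapter5:
        raise ValueError("at least one adapter must be non-empty")
    out = []
    cache: dict[str, str] = {}  # trimming is a pure function of the sequence
    for r in reads:
        seq = cache.get(r.sequence)
        if seq is None:
            seq = r.sequence
            if adapter3:
                seq = _trim_3prime(seq, adapter3, min_overlap, max_mismatch)
            if adapter5:
                seq = _trim_5prime(seq, adapter5, min_overlap, max_mismatch)
            cache[r.sequence] = seq
        if seq:
            out.append(FastqRead(r.read_id, seq, r.quality[: len(seq)], r.comment))
    return out


def build_library(reads: list[FastqRead], sample_id: str, condition: str,
                  stage: str = "") -> ReadLibrary:
    """Deduplicate sequences into ReadRecords with copy counts."""
    counts = Counter(r.sequence for r in reads)
    records = [ReadRecord(seq, n) for seq, n in sorted(counts.items())]
    return ReadLibrary(sample_id, condition, stage, records, total_raw=len(reads))


def classify_reads(library: ReadLibrary) -> pd.DataFrame:
    """Six-part size x abundance classification of reads of length >= 20 nt.

    Returns one row per (size_class, abundance_class) cell with counts of
    distinct sequences and of read copies, plus fractions of each.  Reads
    shorter than 20 nt are excluded from the split (they remain visible in
    the length histogram).
    """
    if not library.reads:
        warnings.warn(f"library {library.sample_id} is empty")
        return pd.DataFrame(columns=["library", "size_class", "abundance_class",
                                     "n_distinct", "n_copies",
                                     "fraction_distinct", "fraction_copies"])
    eligible = [r for r in library.reads if r.size_class != "short"]
    tot_distinct = len(eligible)
    tot_copies = sum(r.copies for r in eligible)
    rows = []
    for size_class in ("22", "24", "other"):
        for abundance in ("singleton", "non-singleton"):
            members = [r for r in eligible if r.size_class == size_class
                       and (r.singleton == (abundance == "singleton"))]
            nd = len(members)
            nc = sum(r.copies for r in members)
            rows.append({
                "library": library.sample_id,
                "size_class": size_class,
                "abundance_class": abundance,
                "n_distinct": nd,
                "n_copies": nc,
                "fraction_distinct": nd / tot_distinct if tot_distinct else 0.0,
                "fraction_copies": nc / tot_copies if tot_copies else 0.0,
            })
    return pd.DataFrame(rows)


def length_histogram(library: ReadLibrary, copy_weighted: bool = True
                     ) -> dict[int, float]:
    """Fraction of reads at each length in the 13-38 nt reporting range.

    Reads outside the range are excluded (and logged), so fractions sum to 1
    over the range.
    """
    weights: Counter[int] = Counter()
    excluded = 0
    for r in library.reads:
        w = r.copies if copy_weighted else 1
        if HIST_MIN <= r.length <= HIST_MAX:
            weights[r.length] += w
        else:
            excluded += w
    if excluded:
        logger.info("length_histogram: %d reads outside %d-%d nt excluded",
                    excluded, HIST_MIN, HIST_MAX)
    total = sum(weights.values())
    if total == 0:
        return {}
    return {length: n / total for length, n in sorted(weights.items())}
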