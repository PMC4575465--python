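"""Readers and writers for the plain-text formats used across the pipeline.

Internal coordinates are always 0-based half-open.  GFF3 (1-based inclusive)
and BED (0-based half-open) are converted at this boundary and nowhere else.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Malformed record in an input file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class Feature:
    """A stranded genomic interval with a feature class and attributes.

    ``start``/``end`` are 0-based half-open; GFF3 I/O converts.
    """

    contig: str
    ftype: str
    start: int
    end: int
    strand: str = "+"
    attributes: dict[str, str] = field(default_factory=dict)
    source: str = "pollensnc"

    @property
    def feature_id(self) -> str | None:
        return self.attributes.get("ID")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class FastqRead:
    read_id: str
    sequence: str
    quality: str
    comment: str = ""


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Load a FASTA file into an {id: sequence} mapping (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# FASTQ

def read_fastq(path: str | os.PathLike) -> list[FastqRead]:
    """Parse FASTQ; a truncated trailing record raises with its line number."""
    reads: list[FastqRead] = []
    with open(path) as fh:
        lines = [ln.rstrip("\r\n") for ln in fh]
    # drop trailing blank lines
    while lines and not lines[-1]:
        lines.pop()
    if len(lines) % 4 != 0:
        raise FormatError("truncated FASTQ record", line=(len(lines) // 4) * 4 + 1)
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i : i + 4]
        if not header.startswith("@"):
            raise FormatError("expected '@' header", line=i + 1)
        if not plus.startswith("+"):
            raise FormatError("expected '+' separator", line=i + 3)
        if len(seq) != len(qual):
            raise FormatError("sequence/quality length mismatch", line=i + 1)
        name, _, comment = header[1:].partition(" ")
        reads.append(FastqRead(name, seq.upper(), qual, comment))
    return reads


def write_fastq(reads: Iterable[FastqRead], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            header = f"@{r.read_id}"
            if r.comment:
                header += f" {r.comment}"
            fh.write(f"{header}\n{r.sequence}\n+\n{r.quality}\n")


# ---------------------------------------------------------------------------
# GFF3

def _format_attributes(attrs: dict[str, str]) -> str:
    if not attrs:
        return "."
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    if text in (".", ""):
        return attrs
    for part in text.strip().split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3(path: str | os.PathLike) -> list[Feature]:
    feats: list[Feature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"expected 9 columns, got {len(cols)}", line=lineno)
            contig, source, ftype, start1, end1, _score, strand, _frame, attrs = cols
            try:
                start = int(start1) - 1  # GFF3 is 1-based inclusive
                end = int(end1)
            except ValueError as exc:
                raise FormatError(f"non-integer coordinate: {exc}", line=lineno) from None
            if start < 0 or end < start:
                raise FormatError("invalid interval", line=lineno)
            feats.append(Feature(contig, ftype, start, end, strand,
                                 _parse_attributes(attrs), source))
    return feats


def write_gff3(features: Iterable[Feature], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write("\t".join([
                f.contig, f.source, f.ftype,
                str(f.start + 1), str(f.end), ".",
                f.strand, ".", _format_attributes(f.attributes),
            ]) + "\n")


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | os.PathLike) -> list[tuple[str, int, int, str, int]]:
    """Read BED as (contig, start, end, name, score) tuples (0-based half-open)."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError("BED needs >= 3 columns", line=lineno)
            name = cols[3] if len(cols) > 3 else "."
            score = int(cols[4]) if len(cols) > 4 else 0
            rows.append((cols[0], int(cols[1]), int(cols[2]), name, score))
    return rows


def write_bed(rows: Iterable[tuple[str, int, int, str, int]],
              path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for contig, start, end, name, score in rows:
            fh.write(f"{contig}\t{start}\t{end}\t{name}\t{score}\n")


# ---------------------------------------------------------------------------
# Provenance-stamped TSV

def write_tsv(df, path: str | os.PathLike, params: dict | None = None) -> None:
    """Write a DataFrame as TSV with a provenance comment header."""
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# pollensnc {__version__}\n")
        if params:
            rendered = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
            fh.write(f"# parameters: {rendered}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | os.PathLike):
    import pandas as pd

    return pd.read_csv(path, sep="\t", comment="#")
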