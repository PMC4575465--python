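"""Synthetic genomes, annotations, and read libraries with planted truth.

Emulates the study design of a pollen heat-stress small-RNA experiment:
three replicates per condition (control vs heat), negative-binomially
distributed feature counts with planted log2 fold changes, planted miRNA
hairpins with Dicer-consistent read stacks, tRNA loci labelled by amino
acid/anticodon, adapter-flanked reads with molecular-tagged PCR duplicates,
and a read-length mixture peaked at 22 and 24 nt over 13-38 nt.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .seqio import FastqRead, Feature

CONTIG = "SLsynth_ch01"
BASES = np.array(list("ACGT"))

# anticodon table used to label tRNA loci, cycled in order
TRNA_TABLE = [
    ("Asp", "GTC"), ("His", "GTG"), ("Ala", "AGC"), ("Glu", "CTC"),
    ("Gly", "CCC"), ("Lys", "CTT"), ("Val", "AAC"), ("Ser", "GCT"),
    ("Pro", "TGG"), ("Leu", "CAG"), ("Gln", "CTG"), ("Thr", "AGT"),
    ("Phe", "GAA"), ("Ile", "AAT"), ("Arg", "TCT"), ("Tyr", "GTA"),
]

SNORNA_FAMILIES = ["U1", "U3", "U4", "snoR101", "R24", "snoR31", "snoR32"]

# read-length mixture over 13-38 nt, peaked at 22 and 24
_LENGTHS = np.arange(13, 39)
_LEN_W = np.full(26, (1.0 - 0.72) / 22)
_LEN_W[_LENGTHS == 21] = 0.06
_LEN_W[_LENGTHS == 22] = 0.28
_LEN_W[_LENGTHS == 23] = 0.06
_LEN_W[_LENGTHS == 24] = 0.32
LENGTH_WEIGHTS = _LEN_W / _LEN_W.sum()

DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"


class CapacityError(ValueError):
    """Raised when features cannot be placed without overlap."""


@dataclass
class PlantedHairpin:
    contig: str
    start: int        # precursor start, 0-based
    end: int          # precursor end, half-open
    strand: str
    mature: str       # DNA alphabet, genome-strand orientation of the miRNA
    star: str
    feature_id: str

    @property
    def mature_interval(self) -> tuple[int, int]:
        return self.start, self.start + len(self.mature)


@dataclass
class SyntheticTruth:
    """Machine-readable ground truth for one synthetic study."""

    seed: int
    adapter3: str
    adapter5: str
    planted_hairpins: list[PlantedHairpin] = field(default_factory=list)
    planted_de: dict[str, float] = field(default_factory=dict)
    trna_loci: dict[str, tuple[str, str]] = field(default_factory=dict)
    known_mirnas: dict[str, str] = field(default_factory=dict)  # id -> mature
    expression: dict[str, float] = field(default_factory=dict)  # id -> weight
    genome: dict[str, str] = field(default_factory=dict)
    features: list[Feature] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "adapter3": self.adapter3,
            "adapter5": self.adapter5,
            "planted_hairpins": [vars(h) for h in self.planted_hairpins],
            "planted_de": self.planted_de,
            "trna_loci": {k: list(v) for k, v in self.trna_loci.items()},
            "known_mirnas": self.known_mirnas,
            "expression": self.expression,
            "genome": self.genome,
            "features": [{
                "contig": f.contig, "ftype": f.ftype, "start": f.start,
                "end": f.end, "strand": f.strand, "attributes": f.attributes,
            } for f in self.features],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            seed=d["seed"], adapter3=d["adapter3"], adapter5=d["adapter5"],
            planted_hairpins=[PlantedHairpin(**h) for h in d["planted_hairpins"]],
            planted_de=d["planted_de"],
            trna_loci={k: tuple(v) for k, v in d["trna_loci"].items()},
            known_mirnas=d["known_mirnas"],
            expression=d["expression"],
            genome=d["genome"],
            features=[Feature(**f) for f in d["features"]],
        )


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _make_precursor(rng: np.random.Generator, mature_len: int = 22,
                    loop_len: int = 12) -> tuple[str, str, str]:
    """Build a hairpin precursor with exact duplex geometry.

    The star pairs the first ``mature_len - 2`` mature bases, leaving the
    2-nt 3' overhangs of Dicer cleavage on both duplex ends.  Returns
    (precursor, mature, star) in DNA alphabet.
    """
    # GC-leaning mature so the stem dominates the fold against random flanks
    mature = "".join(rng.choice(BASES, size=mature_len,
                                p=[0.2, 0.3, 0.3, 0.2]))
    loop = _random_seq(rng, loop_len)
    star = _revcomp(mature[: mature_len - 2]) + _random_seq(rng, 2)
    return mature + loop + star, mature, star


def make_genome(length_bp: int, n_genes: int, n_trna: int, n_snorna: int,
                n_hairpins: int, seed: int, n_rrna: int = 1,
                n_known_mirna: int = 2, planted_fraction: float = 0.25,
                planted_log2fc: float = 2.0,
                ) -> tuple[dict[str, str], list[Feature], SyntheticTruth]:
    """Generate a random genome with non-overlapping annotated features.

    Genes carry exon-intron-exon models (the gene body feeds the 3'-tag
    simulator), tRNA loci are labelled with amino acid and anticodon,
    hairpin precursors are embedded in intergenic space and recorded only in
    the truth object (they stay unannotated, i.e. "novel").  A subset of
    features gets a planted heat-vs-control log2 fold change of
    ``+/- planted_log2fc``, alternating in sign.
    """
    rng = np.random.default_rng(seed)
    seq = list(_random_seq(rng, length_bp))

    placed: list[tuple[int, int]] = []

    def place(span: int, margin: int) -> int:
        lo, hi = margin, length_bp - span - margin
        if hi <= lo:
            raise CapacityError("genome too short for requested features")
        for _ in range(500):
            start = int(rng.integers(lo, hi))
            if all(start + span + margin <= s or start >= e + margin
                   for s, e in placed):
                placed.append((start, start + span))
                return start
        raise CapacityError(
            f"could not place a {span}-bp feature after bounded retries; "
            f"increase length_bp")

    features: list[Feature] = []
    truth = SyntheticTruth(seed=seed, adapter3=DEFAULT_ADAPTER3,
                           adapter5=DEFAULT_ADAPTER5)

    exon_len, intron_len = 150, 120
    for i in range(n_genes):
        gid = f"gene{i + 1:04d}"
        span = 2 * exon_len + intron_len
        start = place(span, margin=30)
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(Feature(CONTIG, "gene", start, start + span, strand,
                                {"ID": gid, "gene_id": gid}))
        features.append(Feature(CONTIG, "exon", start, start + exon_len,
                                strand, {"ID": f"{gid}.exon1", "gene_id": gid}))
        features.append(Feature(CONTIG, "intron", start + exon_len,
                                start + exon_len + intron_len, strand,
                                {"ID": f"{gid}.intron1", "gene_id": gid}))
        features.append(Feature(CONTIG, "exon", start + exon_len + intron_len,
                                start + span, strand,
                                {"ID": f"{gid}.exon2", "gene_id": gid}))
        truth.expression[gid] = float(rng.lognormal(mean=4.0, sigma=1.0))

    for i in range(n_trna):
        tid = f"trna{i + 1:04d}"
        aa, anticodon = TRNA_TABLE[i % len(TRNA_TABLE)]
        start = place(75, margin=25)
        features.append(Feature(CONTIG, "tRNA", start, start + 75, "+",
                                {"ID": tid, "amino_acid": aa,
                                 "anticodon": anticodon}))
        truth.trna_loci[tid] = (aa, anticodon)
        truth.expression[tid] = float(rng.lognormal(mean=5.0, sigma=0.8))

    for i in range(n_snorna):
        sid = f"sno{i + 1:04d}"
        start = place(110, margin=25)
        features.append(Feature(CONTIG, "snoRNA", start, start + 110, "+",
                                {"ID": sid,
                                 "family": SNORNA_FAMILIES[i % len(SNORNA_FAMILIES)]}))
        truth.expression[sid] = float(rng.lognormal(mean=4.5, sigma=0.8))

    for i in range(n_rrna):
        rid = f"rrna{i + 1:04d}"
        start = place(160, margin=25)
        features.append(Feature(CONTIG, "rRNA", start, start + 160, "+",
                                {"ID": rid}))
        truth.expression[rid] = float(rng.lognormal(mean=4.5, sigma=0.8))

    for i in range(n_known_mirna):
        mid = f"mir{i + 1:04d}"
        precursor, mature, _star = _make_precursor(rng)
        start = place(len(precursor), margin=40)
        seq[start : start + len(precursor)] = list(precursor)
        features.append(Feature(CONTIG, "miRNA", start, start + len(precursor),
                                "+", {"ID": mid}))
        truth.known_mirnas[mid] = mature
        truth.expression[mid] = float(rng.lognormal(mean=4.5, sigma=0.8))

    # novel hairpins live in intergenic space; the margin exceeds the 270-nt
    # discovery window so each planted locus yields its own unmerged window
    # with no annotated feature or sibling hairpin bleeding into it
    for i in range(n_hairpins):
        hid = f"hairpin{i + 1:04d}"
        precursor, mature, star = _make_precursor(rng)
        start = place(len(precursor), margin=300)
        seq[start : start + len(precursor)] = list(precursor)
        truth.planted_hairpins.append(
            PlantedHairpin(CONTIG, start, start + len(precursor), "+",
                           mature, star, hid))
        truth.expression[hid] = float(rng.lognormal(mean=5.0, sigma=0.5))

    # plant differential expression, alternating signs across feature ids
    countable = ([t for t in truth.trna_loci]
                 + [f"sno{i + 1:04d}" for i in range(n_snorna)]
                 + list(truth.known_mirnas)
                 + [h.feature_id for h in truth.planted_hairpins]
                 + [f"gene{i + 1:04d}" for i in range(n_genes)])
    n_planted = int(round(planted_fraction * len(countable)))
    chosen = rng.choice(len(countable), size=n_planted, replace=False)
    for rank, idx in enumerate(sorted(chosen)):
        sign = 1.0 if rank % 2 == 0 else -1.0
        truth.planted_de[countable[idx]] = sign * planted_log2fc

    genome = {CONTIG: "".join(seq)}
    truth.genome = genome
    truth.features = sorted(features, key=lambda f: (f.contig, f.start))
    return genome, truth.features, truth


# ---------------------------------------------------------------------------
# Read simulation

def _library_rng(truth: SyntheticTruth, condition: str, replicate: int,
                 stream: int) -> np.random.Generator:
    cond_code = {"control": 0, "heat": 1}.get(condition)
    if cond_code is None:
        raise ValueError(f"unknown condition {condition!r}")
    return np.random.default_rng([truth.seed, cond_code, replicate, stream])


def _nb_counts(rng: np.random.Generator, means: np.ndarray,
               dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(means)
    n = 1.0 / dispersion
    p = 1.0 / (1.0 + dispersion * means)
    return rng.negative_binomial(n, p)


def _sample_length(rng: np.random.Generator) -> int:
    return int(rng.choice(_LENGTHS, p=LENGTH_WEIGHTS))


def _fragment(rng: np.random.Generator, seq: str) -> str:
    n = min(_sample_length(rng), len(seq))
    start = int(rng.integers(0, len(seq) - n + 1))
    return seq[start : start + n]


def _feature_means(truth: SyntheticTruth, ids: list[str], condition: str,
                   total: float) -> np.ndarray:
    w = np.array([truth.expression[i] for i in ids])
    w = w / w.sum()
    means = w * total
    if condition == "heat":
        scale = np.array([2.0 ** truth.planted_de.get(i, 0.0) for i in ids])
        means = means * scale
    return means


def simulate_sncrna_library(truth: SyntheticTruth, condition: str,
                            replicate: int, depth: int,
                            duplicate_rate: float = 0.1,
                            background_fraction: float = 0.3,
                            dispersion: float = 0.1,
                            tag_len: int = 8) -> list[FastqRead]:
    """Simulate one small-RNA FASTQ library.

    Exactly ``depth`` reads are emitted before duplicate injection; PCR
    duplicates (exact copies sharing the molecular-tag prefix) add
    ``round(depth * duplicate_rate)`` more.  Feature reads are mature miRNA
    sequences, tRNA/snoRNA/rRNA fragments with the 22/24-nt-peaked length
    mixture, and hairpin mature/star stacks; the remainder is uniform
    intergenic background.  Heat scales each planted feature's expected count
    by 2^log2fc.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = _library_rng(truth, condition, replicate, stream=1)
    if depth == 0:
        return []

    genome_seq = truth.genome[CONTIG]
    feat_by_id = {f.feature_id: f for f in truth.features if f.feature_id}
    hairpins = {h.feature_id: h for h in truth.planted_hairpins}

    sncrna_ids = ([t for t in truth.trna_loci]
                  + [f.feature_id for f in truth.features
                     if f.ftype in ("snoRNA", "rRNA")]
                  + list(truth.known_mirnas)
                  + list(hairpins))
    means = _feature_means(truth, sncrna_ids, condition,
                           total=(1.0 - background_fraction) * depth)
    counts = _nb_counts(rng, means, dispersion)

    inserts: list[tuple[str, str]] = []  # (sequence, source id)
    for fid, n in zip(sncrna_ids, counts):
        if n == 0:
            continue
        if fid in truth.known_mirnas:
            for _ in range(int(n)):
                inserts.append((truth.known_mirnas[fid], fid))
        elif fid in hairpins:
            h = hairpins[fid]
            for _ in range(int(n)):
                if rng.random() < 0.85:
                    inserts.append((h.mature, fid))
                else:
                    inserts.append((h.star, fid))
        else:
            f = feat_by_id[fid]
            fseq = genome_seq[f.start:f.end]
            for _ in range(int(n)):
                inserts.append((_fragment(rng, fseq), fid))

    # uniform intergenic background fills the library to exactly `depth`
    n_background = depth - len(inserts)
    occupied = sorted((f.start, f.end) for f in truth.features)
    occupied += [(h.start, h.end) for h in truth.planted_hairpins]
    for _ in range(max(n_background, 0)):
        for _try in range(50):
            n = _sample_length(rng)
            start = int(rng.integers(0, len(genome_seq) - n))
            if all(start + n <= s or start >= e for s, e in occupied):
                break
        inserts.append((genome_seq[start : start + n], "background"))
    if n_background < 0:
        inserts = inserts[:depth]

    perm = rng.permutation(len(inserts))
    reads: list[FastqRead] = []
    used_tags: dict[str, set[str]] = {}
    for i, idx in enumerate(perm):
        insert, src = inserts[idx]
        # distinct molecules of the same insert carry distinct molecular tags
        seen = used_tags.setdefault(insert, set())
        for _ in range(50):
            tag = _random_seq(rng, tag_len)
            if tag not in seen:
                break
        seen.add(tag)
        seq = tag
        if rng.random() < 0.1:  # occasional 5' adapter carry-through
            k = int(rng.integers(5, min(len(truth.adapter5), 12) + 1))
            seq += truth.adapter5[-k:]
        seq += insert + truth.adapter3
        reads.append(FastqRead(
            f"{condition[0].upper()}{replicate}_{i + 1}", seq,
            "I" * len(seq), comment=f"mt:Z:{tag} src:{src}"))

    n_dup = int(round(depth * duplicate_rate))
    if n_dup:
        dup_idx = rng.integers(0, len(reads), size=n_dup)
        for j, idx in enumerate(dup_idx):
            src = reads[int(idx)]
            reads.append(FastqRead(f"{src.read_id}_dup{j + 1}", src.sequence,
                                   src.quality, src.comment))
    return reads


def simulate_count_matrix(n_features: int, seed: int, n_replicates: int = 3,
                          dispersion: float = 0.1,
                          mean_log: float = 4.5, mean_sigma: float = 1.0,
                          planted: dict[int, float] | None = None,
                          min_mean: float | None = None):
    """Simulate a features x samples NB count matrix directly.

    Per-feature means are lognormal; ``planted`` maps feature index to a
    log2 fold change applied to the heat condition; ``min_mean`` optionally
    floors the means (for power studies on well-expressed features).
    Returns a :class:`~pollensnc.stats.CountMatrix`.
    """
    import pandas as pd

    from .stats import CountMatrix

    rng = np.random.default_rng(seed)
    means = rng.lognormal(mean=mean_log, sigma=mean_sigma, size=n_features)
    if min_mean is not None:
        means = np.maximum(means, min_mean)
    heat_means = means.copy()
    for idx, lfc in (planted or {}).items():
        heat_means[idx] = means[idx] * 2.0 ** lfc
    cols, data, design = [], [], {}
    for cond, m in (("control", means), ("heat", heat_means)):
        for rep in range(1, n_replicates + 1):
            name = f"{cond}_{rep}"
            cols.append(name)
            design[name] = cond
            data.append(_nb_counts(rng, m, dispersion))
    df = pd.DataFrame(dict(zip(cols, data)),
                      index=[f"f{i:05d}" for i in range(n_features)])
    return CountMatrix(df, design)


def simulate_mace_library(truth: SyntheticTruth, condition: str,
                          replicate: int, depth: int,
                          duplicate_rate: float = 0.1,
                          dispersion: float = 0.1, tag_len: int = 8,
                          read_len: int = 50,
                          window: int = 250) -> list[FastqRead]:
    """Simulate one 3'-tag (MACE-like) FASTQ library.

    One tag per transcript molecule, drawn from the 3'-most ``window`` bp of
    each gene model on the sense strand; per-gene expected counts follow the
    same NB model as the small-RNA simulator.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = _library_rng(truth, condition, replicate, stream=2)
    if depth == 0:
        return []

    genome_seq = truth.genome[CONTIG]
    genes = [f for f in truth.features if f.ftype == "gene"]
    gene_ids = [g.feature_id for g in genes]
    means = _feature_means(truth, gene_ids, condition, total=float(depth))
    counts = _nb_counts(rng, means, dispersion)
    # rescale to exactly `depth` tags by multinomial resampling of the draw
    total = counts.sum()
    if total == 0:
        counts = rng.multinomial(depth, np.ones(len(genes)) / len(genes))
    else:
        counts = rng.multinomial(depth, counts / total)

    reads: list[FastqRead] = []
    i = 0
    for g, n in zip(genes, counts):
        gseq = genome_seq[g.start:g.end]
        if g.strand == "-":
            gseq = _revcomp(gseq)
        tail = gseq[-window:]
        span = max(len(tail) - read_len, 1)
        for _ in range(int(n)):
            start = int(rng.integers(0, span))
            insert = tail[start : start + read_len]
            tag = _random_seq(rng, tag_len)
            i += 1
            reads.append(FastqRead(
                f"M{condition[0].upper()}{replicate}_{i}", tag + insert,
                "I" * (tag_len + len(insert)),
                comment=f"mt:Z:{tag} src:{g.feature_id}"))
    rng.shuffle(reads)

    n_dup = int(round(depth * duplicate_rate))
    if n_dup:
        dup_idx = rng.integers(0, len(reads), size=n_dup)
        for j, idx in enumerate(dup_idx):
            src = reads[int(idx)]
            reads.append(FastqRead(f"{src.read_id}_dup{j + 1}", src.sequence,
                                   src.quality, src.comment))
    return reads
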