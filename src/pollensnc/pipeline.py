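"""End-to-end pipeline driver: config, stage orchestration, report bundle."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import seqio, synthetic
from .annotate import (AnnotationIndex, annotate_library, build_index,
                       class_totals, cluster_unannotated, count_features,
                       revcomp)
from .discovery import call_novel_mirnas
from .downstream import aggregate_trna_by_aa, de_report
from .preprocess import (build_library, classify_reads,
                         collapse_pcr_duplicates, length_histogram,
                         trim_adapters)
from .stats import CountMatrix, condition_tpm, nb_test
from .targets import hits_table, integrate_expression, predict_targets

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative configuration for one pipeline run."""

    out_dir: str = "pollensnc_out"
    seed: int = 1
    # synthetic-study design (used when simulate=True)
    simulate: bool = True
    genome_length: int = 50_000
    n_genes: int = 20
    n_trna: int = 8
    n_snorna: int = 3
    n_hairpins: int = 5
    replicates: int = 3
    sncrna_depth: int = 100_000
    mace_depth: int = 50_000
    # user-supplied inputs (used when simulate=False)
    genome_fasta: str | None = None
    annotation_gff3: str | None = None
    sncrna_fastq: dict[str, str] = field(default_factory=dict)  # sample->path
    design: dict[str, str] = field(default_factory=dict)        # sample->cond
    # stage parameters
    tag_len: int = 8
    adapter3: str = synthetic.DEFAULT_ADAPTER3
    adapter5: str = synthetic.DEFAULT_ADAPTER5
    k: int = 12
    max_mismatch: int = 1
    window: int = 270
    shuffles: int = 100
    score_min: float = 140.0
    energy_max: float = -20.0
    top_n: int = 10
    fdr: float = 0.05

    def validate(self) -> None:
        if not (8 <= self.k <= 16):
            raise ValueError("k must lie in [8, 16]")
        if not self.simulate:
            for name in ("genome_fasta", "annotation_gff3"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise ValueError(f"config field {name!r} missing or "
                                     f"nonexistent: {path}")
            for sample, path in self.sncrna_fastq.items():
                if not Path(path).exists():
                    raise ValueError(f"FASTQ for sample {sample!r} not found: "
                                     f"{path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Execute simulate -> preprocess -> annotate -> DE -> discover -> targets
    -> reports, writing a TSV bundle under ``config.out_dir``.

    Returns a summary dict with the key result tables.  Refuses to overwrite
    an existing bundle unless ``force`` is set.
    """
    config.validate()
    out = Path(config.out_dir)
    sentinel = out / "pipeline_done.json"
    if sentinel.exists() and not force:
        raise FileExistsError(f"output bundle already exists at {out}; "
                              "use force=True / --force to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    params = dataclasses.asdict(config)

    # -- inputs -------------------------------------------------------------
    if config.simulate:
        genome, features, truth = synthetic.make_genome(
            config.genome_length, config.n_genes, config.n_trna,
            config.n_snorna, config.n_hairpins, seed=config.seed)
        seqio.write_fasta(genome, out / "genome.fa")
        seqio.write_gff3(features, out / "annotation.gff3")
        (out / "truth.json").write_text(truth.to_json())
        raw = {}
        design = {}
        for cond in ("control", "heat"):
            for rep in range(1, config.replicates + 1):
                sample = f"{cond}_{rep}"
                raw[sample] = synthetic.simulate_sncrna_library(
                    truth, cond, rep, config.sncrna_depth)
                design[sample] = cond
        adapter3, adapter5 = truth.adapter3, truth.adapter5
    else:
        genome = seqio.read_fasta(config.genome_fasta)
        features = seqio.read_gff3(config.annotation_gff3)
        truth = None
        raw = {s: seqio.read_fastq(p) for s, p in config.sncrna_fastq.items()}
        design = dict(config.design)
        adapter3, adapter5 = config.adapter3, config.adapter5

    # -- preprocess ---------------------------------------------------------
    libraries = {}
    for sample, reads in raw.items():
        collapsed, _ = collapse_pcr_duplicates(reads, tag_len=config.tag_len)
        trimmed = trim_adapters(collapsed, adapter3, adapter5)
        lib = build_library(trimmed, sample, design[sample])
        libraries[sample] = lib
        seqio.write_tsv(classify_reads(lib), out / f"classes_{sample}.tsv",
                        params={"stage": "preprocess", "sample": sample})
    hist_rows = []
    for sample, lib in libraries.items():
        for length, frac in length_histogram(lib).items():
            hist_rows.append({"library": sample, "length": length,
                              "fraction": frac})
    seqio.write_tsv(pd.DataFrame(hist_rows), out / "length_histogram.tsv",
                    params={"stage": "preprocess"})

    # -- map + annotate -----------------------------------------------------
    index = build_index(genome, k=config.k)
    ann = AnnotationIndex(features)
    annotated = {s: annotate_library(lib, index, ann,
                                     max_mismatch=config.max_mismatch)
                 for s, lib in libraries.items()}
    totals = pd.DataFrame({s: class_totals(a) for s, a in annotated.items()}
                          ).fillna(0).astype(int)
    totals.insert(0, "category", totals.index)
    seqio.write_tsv(totals, out / "class_totals.tsv",
                    params={"stage": "annotate"})
    cm = count_features(annotated, design)
    counts_out = cm.counts.copy()
    counts_out.insert(0, "id", counts_out.index)
    seqio.write_tsv(counts_out, out / "counts.tsv",
                    params={"stage": "annotate"})

    # -- differential expression -------------------------------------------
    de = nb_test(cm)
    seqio.write_tsv(de, out / "diffexp.tsv",
                    params={"stage": "diffexp", "fdr": config.fdr})

    # -- novel miRNA discovery ---------------------------------------------
    pool = [ar for sample_reads in annotated.values() for ar in sample_reads]
    calls, _candidates = call_novel_mirnas(
        pool, genome, window_size=config.window, n_shuffles=config.shuffles,
        seed=config.seed)
    seqio.write_tsv(calls, out / "novel_mirnas.tsv",
                    params={"stage": "discover", "window": config.window})

    structures = out / "novel_mirna_structures.txt"
    with open(structures, "w") as fh:
        for c in _candidates:
            if c.name:
                fh.write(f">{c.name} mfe={c.mfe:.2f}\n{c.sequence}\n"
                         f"{c.structure}\n")

    # -- MACE 3'-tag quantification (synthetic runs only) -------------------
    mace_de = None
    mace_tpm = {}
    if config.simulate and config.mace_depth > 0:
        mace_counts = {}
        unannotated = []
        for cond in ("control", "heat"):
            for rep in range(1, config.replicates + 1):
                sample = f"{cond}_{rep}"
                tags = synthetic.simulate_mace_library(
                    truth, cond, rep, config.mace_depth)
                collapsed, _ = collapse_pcr_duplicates(tags,
                                                       tag_len=config.tag_len)
                lib = build_library(collapsed, sample, cond)
                annotated_tags = annotate_library(
                    lib, index, ann, max_mismatch=config.max_mismatch)
                counts = {}
                for ar in annotated_tags:
                    if ar.verdict is None:
                        continue
                    gid = ar.verdict.feature_id
                    if gid is None:
                        unannotated.append(ar.alignment)
                        continue
                    counts[gid] = counts.get(gid, 0) + ar.copies
                mace_counts[sample] = counts
        gene_ids = sorted({g for c in mace_counts.values() for g in c})
        mace_cm = CountMatrix(
            pd.DataFrame({s: [mace_counts[s].get(g, 0) for g in gene_ids]
                          for s in mace_counts}, index=gene_ids), design)
        mc_out = mace_cm.counts.copy()
        mc_out.insert(0, "id", mc_out.index)
        seqio.write_tsv(mc_out, out / "mace_counts.tsv",
                        params={"stage": "mace"})
        mace_de = nb_test(mace_cm)
        seqio.write_tsv(mace_de, out / "mace_diffexp.tsv",
                        params={"stage": "mace", "fdr": config.fdr})
        mace_tpm = {
            "control": condition_tpm(mace_cm, "control"),
            "heat": condition_tpm(mace_cm, "heat"),
        }
        seqio.write_bed(cluster_unannotated(unannotated, min_gap=100),
                        out / "mace_clusters.bed")

    # -- target prediction on gene 3' windows -------------------------------
    mirna_seqs = dict(zip(calls["id"], calls["mature_seq"]))
    transcripts = {}
    for f in features:
        if f.ftype != "gene" or f.feature_id is None:
            continue
        gseq = genome[f.contig][f.start:f.end]
        if f.strand == "-":
            gseq = revcomp(gseq)
        transcripts[f.feature_id] = gseq[-250:]
    hits = predict_targets(mirna_seqs, transcripts,
                           score_min=config.score_min,
                           energy_max=config.energy_max, top_n=config.top_n)
    if mace_de is not None and hits:
        # novel loci are unannotated, so their DE comes from a dedicated
        # count matrix of mature-sequence read copies per library
        mature_dna = {row["id"]: row["mature_seq"].replace("U", "T")
                      for _, row in calls.iterrows()}
        mirna_counts = pd.DataFrame(
            {s: [sum(r.copies for r in lib.reads if r.sequence == seq)
                 for seq in mature_dna.values()]
             for s, lib in libraries.items()},
            index=list(mature_dna))
        if (mirna_counts.sum(axis=1) > 0).any():
            mirna_de = nb_test(CountMatrix(mirna_counts, design))
        else:
            mirna_de = pd.DataFrame(columns=["id", "log2fc"])
        hits = integrate_expression(hits, mirna_de, mace_de,
                                    target_tpm_n=mace_tpm.get("control"),
                                    target_tpm_h=mace_tpm.get("heat"))
        seqio.write_tsv(mirna_de, out / "novel_mirna_diffexp.tsv",
                        params={"stage": "targets"})
    seqio.write_tsv(hits_table(hits), out / "targets.tsv",
                    params={"stage": "targets"})

    # -- downstream reports -------------------------------------------------
    trna_table = aggregate_trna_by_aa(cm, features)
    seqio.write_tsv(trna_table, out / "trna_clusters.tsv",
                    params={"stage": "report"})
    groups = {f.feature_id: f.attributes.get("amino_acid",
                                             f.attributes.get("family", ""))
              for f in features if f.feature_id}
    report = de_report(de, feature_group=groups, fdr_threshold=config.fdr)
    seqio.write_tsv(report, out / "de_report.tsv",
                    params={"stage": "report", "fdr": config.fdr})

    summary = {
        "n_samples": len(libraries),
        "n_features_counted": int(cm.counts.shape[0]),
        "n_significant": int((de["fdr"] < config.fdr).sum()),
        "n_novel_mirnas": int(len(calls)),
        "n_target_hits": len(hits),
    }
    sentinel.write_text(json.dumps(summary, indent=1, sort_keys=True))
    return {"summary": summary, "count_matrix": cm, "diffexp": de,
            "novel_mirnas": calls, "targets": hits,
            "trna_clusters": trna_table, "truth": truth}
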