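# pollensnc

Small non-coding RNA (sncRNA) analysis of pollen under heat stress, as a
tested, reusable Python pipeline. It covers the full path from raw
small-RNA-seq reads to biology-level reports:

- **Preprocessing** — molecular-tag PCR-duplicate collapse, 3'/5' adapter
  trimming, and the size/abundance read classification (22 nt, 24 nt,
  "other" ≥ 20 nt × singleton/non-singleton).
- **Mapping & annotation cascade** — k-mer seed mapping with Hamming
  verification on both strands; each alignment gets exactly one class by
  priority ncRNA (miRNA > tRNA > snoRNA > rRNA) > exonic > intronic >
  intergenic. Exonic reads are excluded from discovery; intronic and
  intergenic reads feed it.
- **Differential expression** — median-of-ratios size factors
  (s_j = median_i k_ij / (∏_v k_iv)^{1/m}), per-feature method-of-moments NB
  dispersion floored at a fitted α(q) = a₀ + a₁/q trend, and the two-sided
  exact negative-binomial test over all splits (a, b) of the per-condition
  count sums, with Benjamini–Hochberg FDR at 0.05.
- **Novel miRNA discovery** — 270-nt windows folded around expressed read
  stacks (ViennaRNA MFE model), miRNA/miRNA* duplex extraction with Dicer
  2-nt 3' overhang geometry, the plant annotation criteria (mature ≥ 21 nt,
  ≤ 4 mismatched mature bases, asymmetric bulges ≤ 2 nt and ≤ 1 in number),
  Gumbel-calibrated MFE significance against dinucleotide-preserving
  shuffles, and a read-signature check.
- **Target prediction** — Smith–Waterman-style local complementarity
  scoring (match +5, G:U +1, mismatch −3, gaps −9/−4) with miRNA seed
  positions 2–7 weighted ×4, nearest-neighbor stack free energies for the
  duplex, score ≥ 140 / energy ≤ −20 kcal/mol filters, ten best targets per
  miRNA, and anticorrelation flags against 3'-tag (MACE-style) expression.
- **Downstream reports** — amino-acid-clustered tRNA tpm tables with
  percent change 100·(H−C)/max(C,H), per-class DE reports, Venn-region
  summaries, and hypergeometric GO enrichment.
- **Synthetic data** — a generator that emits genomes, GFF3 annotations,
  FASTQ libraries and machine-readable planted truth (hairpins with
  Dicer-consistent read stacks, NB counts with planted log2 fold changes,
  tRNA loci labelled by amino acid), so the whole pipeline is testable
  without any external downloads.

## Worked example

```python
from pollensnc.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(out_dir="demo", seed=5, genome_length=30_000,
                        n_genes=8, n_trna=6, n_snorna=2, n_hairpins=2,
                        sncrna_depth=8_000, mace_depth=4_000, shuffles=40)
result = run_pipeline(config)
print(result["summary"])
```

prints

```
{'n_samples': 6, 'n_features_counted': 11, 'n_significant': 1,
 'n_novel_mirnas': 2, 'n_target_hits': 0}
```

i.e. six simulated libraries (three replicates × control/heat) were
preprocessed and counted over 11 annotated small-RNA features, one passed
FDR < 0.05 at this shallow 8k-read demo depth (the exact test needs deeper
counts for full power on the planted changes — the calibration in
`scripts/acceptance.py` runs at study scale), and both planted hairpins
were recovered as novel miRNA calls with zero false calls. `demo/` holds
the TSV bundle: per-library classification tables, the length histogram,
class totals, the count matrix, the DE table, novel miRNA calls with
dot-bracket structures, MACE 3'-tag counts and gene-level DE, target hits,
and the tRNA amino-acid cluster report.

The same stages are available from the shell:

```bash
pollensnc simulate --out synthetic --depth 20000 --seed 1
pollensnc preprocess synthetic/sncrna_control_1.fastq trimmed.fastq
pollensnc run --out bundle --seed 1
```

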