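# Methods

## Scope and model

`pollensnc` implements a small-RNA-seq analysis for a two-condition
(control vs heat), three-replicate study across pollen developmental
stages: read preprocessing, an annotation-priority cascade, exact
negative-binomial differential expression, plant-criteria novel miRNA
discovery, seed-weighted target prediction integrated with 3'-tag
expression, and tRNA/snoRNA/GO report statistics. All internal coordinates
are 0-based half-open; GFF3 (1-based inclusive) and BED are converted only
at I/O, so no off-by-one can accumulate inside the pipeline.

## Preprocessing

Reads carry an 8-nt molecular tag prefix; PCR duplicates are exact copies
sharing both tag and insert, and collapsing keeps one read per (tag,
insert) pair. Adapter trimming removes the longest read suffix matching a
prefix of the 3' adapter (and symmetrically at the 5' end) with minimum
overlap 5 nt. Mismatches are admitted at a 10% error rate — one mismatch
only from 10 nt of overlap — rather than a flat one-mismatch allowance:
with a flat allowance at 5-nt overlap, roughly 1.6% of all distinct read
5' ends match the adapter by chance, and because trimming is deterministic
per sequence this deletes entire read stacks rather than a random subset,
which is fatal for stack-based miRNA discovery.

The size/abundance classification covers reads ≥ 20 nt (classes 22 nt,
24 nt, "other"; singleton = sequence seen exactly once in the library,
post-collapse). Reads of 13–19 nt stay visible in the length histogram but
are excluded from the six-part split; the histogram covers 13–38 nt and
excludes (and logs) anything outside.

## Mapping and annotation cascade

The mapper indexes genome k-mers (default k = 12) and verifies candidate
placements by full-length Hamming comparison on both strands (default ≤ 1
mismatch; indels are not modeled — small-RNA reads are short and the
simulator introduces none). All equally-best placements are returned.
Annotation priority is ncRNA (miRNA > tRNA > snoRNA > rRNA) > exonic >
intronic > intergenic, with a ≥ 50% read-overlap rule. Antisense overlap
counts only for ncRNA classes (flagged); gene models are strand-specific.
Multimappers are counted once, at the highest-priority then leftmost
placement, so the count matrix never double-counts a read. Class totals
therefore partition mapped reads exactly.

## Differential expression

Size factors are median-of-ratios over features positive in all samples.
The per-feature dispersion is a method-of-moments estimate from pooled
within-condition variances of normalized counts, floored elementwise at a
parametric trend α(q) = a₀ + a₁/q fitted by least squares across features.
The two-parameter trend replaces a local-regression fit: it is the
standard parametric alternative, has no tuning parameters, and behaves
identically under reruns. The p-value is the exact two-sided tail over all
splits (a, b) with a + b equal to the observed sum of per-condition
counts, each side NB with mean/variance implied by the pooled mean, the
condition's size-factor sums, and the feature's dispersion; splits at
least as improbable as the observed one are summed and normalized by the
total. In the dispersion→0 limit this reduces to the conditional binomial
split test, which is the brute-force oracle used in the tests. log2 fold
changes come from mean normalized counts, unshrunken, so a condition that
is exactly zero renders as ±inf in report tables. Benjamini–Hochberg
controls FDR with the 0.05 decision threshold.

Calibration under the study design (2000 features, NB dispersion 0.1,
3 vs 3 replicates): type-I error at p < 0.05 sits near 0.04 (the floor at
the trend makes the test mildly conservative), BH at 0.05 yields
essentially no false discoveries, and features planted at |log2fc| = 2
with mean ≥ 50 are detected with power near 0.9.

## Novel miRNA discovery

Reads ≥ 16 nt with intronic or intergenic verdicts form the discovery
pool. Identical placements aggregate into stacks; a stack seeds a 270-nt
window centered on it when it carries at least max(5, 0.1% of the pool)
copies. The relative component is essential: an absolute floor does not
scale with depth, because coincidental co-placements of unrelated reads
grow linearly with the pool and would seed windows across the whole
genome at realistic depths. Overlapping windows are merged — including
across strands, since a hairpin is a near-palindrome and antisense stacks
at the same locus describe the same physical precursor; each merged
window is evaluated on the strand carrying more read support.

Each window is folded with the ViennaRNA MFE model (the package's duplex
and criteria layers are engine-agnostic: they consume only the dot-bracket
string). The most abundant stack is the candidate mature; its pairing
partners on the opposite arm, shifted to restore the 2-nt 3' overhangs of
Dicer cleavage, define the star. Unpaired mature bases inside the duplex
count as mismatches; G:U wobbles count as paired and are reported
separately (standard plant annotation practice). Maximal unpaired runs on
exactly one strand are asymmetric bulges. The plant criteria require:
mature ≥ 21 nt ("longer than 20 nt" read strictly), ≤ 4 mismatches, every
bulge ≤ 2 nt, at most one bulge, and 2-nt 3' overhangs on both ends; each
failed clause is enumerated as a reason code.

MFE significance: 100 dinucleotide-preserving shuffles (Altschul–Erickson
Eulerian-walk construction) are folded; a Gumbel distribution fitted by
moments to the negated shuffle MFEs gives the upper-tail probability of a
stability at least as extreme as observed (p ≤ 0.05 to call). Finally, a
read-signature check requires ≥ 90% of in-window read copies to sit
within mature ± 2 nt, star ± 2 nt, or the loop. The 90%/± 2 nt constants
operationalize the qualitative requirement that expressed hairpins show a
two-stack Dicer signature; both are configurable.

## Target prediction

The aligner runs Gotoh affine-gap local alignment of the reversed miRNA
(3'→5') against the target (5'→3'), scoring complementarity: Watson–Crick
+5, G:U +1, mismatch −3, gap open −9, extend −4, with contributions at
miRNA positions 2–7 from the 5' end scaled ×4. The defaults (score ≥ 140,
energy ≤ −20 kcal/mol, ten best per miRNA) are pinned explicitly and
configurable. Seed weighting deliberately breaks the joint-reversal score
symmetry of the unweighted scorer (the seed is position-specific);
`seed_scale=1` restores it.

Duplex free energy sums nearest-neighbor stack energies over consecutive
aligned pairs: Watson–Crick stacks use the standard 37 °C nearest-neighbor
set; stacks involving a G:U wobble use a coarse three-level model (−1.2
against G:C, −0.8 against A:U, −0.5 wobble-on-wobble) — a deliberate
simplification, adequate for ranking since wobbles are rare in hits that
clear the score filter. Every unpaired or gapped column inside the duplex
adds +0.5 kcal/mol. Hits are ordered by score (descending), energy
(ascending), then target id, and capped at ten per miRNA — a retained hit
always outranks every dropped one under that total order. Expression
integration flags a hit anticorrelated when miRNA and target log2 fold
changes have strictly opposite signs.

## Downstream statistics

tRNA clusters sum condition tpm (replicate mean of per-library tpm) over
the members of each amino acid; percent change is 100·(H−C)/max(C,H),
bounded in [−100, 100] (−100 attained exactly when the heat tpm is zero),
with |change| > 30% highlighted. DE reports filter to FDR < 0.05 and
render log2fc at two decimals, half-up, with ±inf spelled "inf"/"-inf".
Venn summaries count exclusive regions for every set combination. GO
enrichment is the hypergeometric upper tail of category membership among
targets against all annotated genes as background, BH-adjusted within
each target set; categories are taken as annotated, with no GO-DAG
ancestor propagation.

## Synthetic data: what it emulates and what it does not

The generator plants, on a random genome: exon–intron–exon gene models
(the 3'-most 250 bp feed the MACE-style tag simulator), tRNA loci
labelled with amino acid and anticodon, snoRNA/rRNA loci, annotated
("known") miRNA precursors, and unannotated hairpin precursors recorded
only in the truth object. Hairpins are built with exact duplex geometry —
star = reverse complement of all but the last two mature bases, plus a
free 2-nt star 3' overhang — with a GC-leaning 22-nt mature so the
planted stem dominates the fold against random flanks, and are placed
with a 300-bp margin so each planted locus yields its own unmerged,
feature-free discovery window (co-located precursors would make the
planted truth ambiguous). Matures of 22 nt keep the library length
histogram peaked at 22 and 24 nt as in the emulated study design.

Per-feature expected counts are lognormal weights scaled to
(1 − background) × depth, NB-sampled with dispersion 0.1 (typical
small-RNA-seq overdispersion; configurable), with heat means scaled by
2^(planted log2fc). A planted fraction of 25% of features at |log2fc| = 2,
alternating sign, defines the differential-expression truth. Exactly
`depth` reads are emitted (background fills the remainder, drawn
uniformly from unannotated space, default fraction 30%); duplicate
injection then adds round(depth × rate) exact copies. Distinct molecules
of the same insert always receive distinct molecular tags — that is what
molecular tagging is for — so a duplicate rate of zero collapses to
exactly the original count. Reads are tag + (occasional 5'-adapter
carry-through) + insert + full 3' adapter.

Not modeled: sequencing errors, quality-score realism, indels, spliced
reads, strand-specific library chemistry, and hairpins on the minus
strand. Passing tests therefore demonstrate the correctness of the
pipeline's logic and statistics under idealized reads, not robustness to
base-calling noise.

## Numerical choices

Report-table rounding is two decimals, half-up (matching printed report
conventions). The percent-change statistic is clamped to [−100, 100] to
absorb float roundoff at the boundary. The exact-test split enumeration
works in log space with a log-sum-exp normalization; a 1e-12 relative
slack on the "at least as improbable" comparison absorbs pmf roundoff.
Gumbel fitting uses the moments estimator (β = s√6/π, μ = mean − γβ).
Ties in the ten-best ordering break by target id, making reports
deterministic. All simulation randomness flows from explicit integer
seeds through `numpy.random.default_rng`; identical seeds give
byte-identical FASTA/GFF3/FASTQ/TSV outputs.

## Problem sizes

The default synthetic study used by the tests and the acceptance script:
50-kb genome, 20 genes, 8 tRNAs, 3 snoRNAs, 5 planted hairpins, depth
100,000 reads per library, three replicates per condition. NB calibration
runs on 2000 features (400 planted for the power estimate). These sizes
give stable stochastic estimates while keeping a full run in minutes;
every size is a parameter, and nothing in the implementation depends on
them.

## Known limitations

The exact NB test enumerates all splits of the per-condition count sum,
which is O(total) per feature; for very deep counts a saddlepoint or
normal approximation would be preferable. The wobble stack-energy model
is coarse (see above). The mapper's Hamming model cannot place reads over
indels. The discovery caller evaluates one candidate mature per merged
window (the most abundant stack), so two genuinely distinct precursors
closer than a window width would yield a single call.
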