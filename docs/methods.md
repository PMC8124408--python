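# Methods

This note documents the models, conventions and design choices behind
`oryzalnc`, in the order the pipeline runs. It states what each stage
computes and under which assumptions, what the synthetic data emulate and
what they do not, and where the design was genuinely open.

## Coordinates, lengths and formats

All genomic coordinates are 1-based inclusive (the GFF3 convention): an
interval `start..end` contains `end − start + 1` bases. This convention is
fixed by the package's reference worked example, where a single-exon
transcript printed as spanning 3,117,854–3,119,120 bp must measure 1267 nt.
BED export converts to 0-based half-open at the boundary and nowhere else.

Transcript *length* always means spliced length — the sum of exon lengths —
for lncRNAs and mRNAs alike, not genomic span. The two coincide for
single-exon transcripts; spliced length is the standard choice for lncRNA
length distributions.

GFF3 and GTF are both accepted; exons are grouped into transcripts by
`transcript_id`, falling back to `Parent`/`ID`. Records with `start > end`,
non-positive coordinates or unknown strands abort with the file line
number. The single repair the reader performs silently (with a logged
warning) is sorting and merging out-of-order or overlapping exons.

## Synthetic trio generator

The generator emulates the study design the pipeline was built for: a wild
progenitor and two cultivars, two tissues (panicle, seedling), one library
per genome × tissue. Its defaults are the study conditions:

| parameter | wild | cultivar A | cultivar B |
|---|---|---|---|
| lncRNA length median (nt) | 370 | 670 | 508 |
| single-exon fraction | 0.658 | 0.504 | 0.620 |
| mean exon count | 1.61 | 2.37 | 1.76 |
| mRNA length median (nt) | 1178 | 1425 | 912 |

* **Lengths** are log-normal with log-SD 0.6, truncated to [201, 10000] nt.
  The log-scale location is solved (Brent's method) so that the *truncated*
  median equals the target — naive truncation at 201 nt would inflate the
  wild median by ~12%. Sampling is by inverse CDF on the truncated range.
* **Exon counts** are 1 with the configured single-exon probability, else
  2 + Poisson(λ) with λ chosen so the overall mean matches the target.
* **Homolog families** derive all copies from one random consensus.
  The per-copy substitution budget is *half* the configured pairwise
  divergence, and within each of the k mutation strata (equal-length
  windows, one substitution per copy per stratum) copies mutate distinct
  positions whenever the stratum is wide enough. Consequences: realized
  pairwise identity equals the configured value exactly, and no long
  unmutated run survives — an 85%-identity decoy cannot contain any
  >100-column window above 90% identity, so decoys fail the screen by
  construction, not by chance. Substitution-only is the default mutation
  model (an indel mode was considered and dropped: exact identity control
  is what the recovery suites need).
* **Collinear blocks** place n (default 5) orthologous coding genes in
  identical order around a planted lncRNA in each participating genome;
  ortholog gene pairs derive from a shared ancestor at 95% identity and are
  emitted as a truth table (the generator knows orthology; the RBH module
  can recompute it). Each block is flanked on both sides by 12
  genome-specific "shield" coding genes plus wide margins. The shields
  guarantee two separations: the planted lncRNA's 5 nearest coding genes
  are exactly the block genes, and any lncRNA outside the block meets ≥ 12
  ortholog-free genes (more than the caller's default rank window of 10)
  before reaching a block gene. Planted positional truth is therefore
  recovered exactly, with zero spurious calls, independent of background
  gene density. Decoy blocks have the same geometry but non-orthologous
  genes. Shield and block genes are single-exon plumbing; background mRNA
  exon counts follow 2 + Poisson(4).
* **Expression** is negative-binomial (default mean 50 for lncRNAs, 200
  for mRNAs, dispersion 0.1). A configurable fraction of lncRNAs (default
  60%) is planted differentially expressed with a 4× tissue multiplier,
  85% of them panicle-up, reproducing the panicle-over-seedling bias
  direction. Planted silent transcripts get zero counts; planted short and
  coding-score decoys exercise the other cascade gates.
* **Coding-potential scores** are drawn from two normals separated by
  biotype (lncRNA −2.0 ± 0.4, coding +2.0 ± 0.4 per scorer). This is
  explicitly *not* a reimplementation of CPC or CNCI — scores are inputs
  to the pipeline, and the generator only needs the two populations to be
  separable with a realistic error rate.
* **Known/novel truth**: half of the reference genome's lncRNAs are copied
  into a reference annotation at their own coordinates.
* **Traits** are normal draws per line × trait parameterized by published
  summary statistics (mean, SD per mutant line), with n = 12 for plant and
  panicle architecture traits, n = 31 for grain traits and n = 9 for
  lesion lengths, satisfying the n > 10 / n > 30 / n > 8 design bounds.

All randomness flows from one integer seed through named `SeedSequence`
spawns; two runs of the same config are byte-identical, and every planted
element is recorded in emitted `truth_*.tsv` tables.

What the generator does **not** emulate: reads, mapping or assembly noise,
isoform structure shared between lncRNAs and mRNAs, sequence composition
biases, expression correlation along chromosomes, or indel divergence
between homologs. Passing the recovery suites therefore demonstrates that
the pipeline's decision rules are implemented correctly and are exact on
data satisfying their assumptions — not that the thresholds are optimal
for real libraries.

## Identification cascade

Gates run in a fixed order — annotated-coding, length, expression, coding
potential — so each rejected candidate carries the first gate it failed;
the retained *set* is provably order-independent (tested against an
unordered predicate oracle). Conventions:

* "longer than 200 nt" is strict: spliced length ≥ 201.
* The FPKM gate uses the **maximum** across the transcript's samples
  (a transcript observed at FPKM ≥ 0.1 in either tissue was expressed);
  one-sample, mean and other readings are possible, and the choice is
  surfaced as a threshold parameter.
* Both coding scores must be < 0 (conjunction of the two scorer
  conditions).
* *Known* requires only ≥ 1 nt of same-strand exonic overlap with a
  reference lncRNA — the most permissive defensible reading of aligning
  against annotated references; the overlap is configurable.

Percentages in summary tables are rounded half-up to two decimals, matching
how such tables are conventionally printed.

## Expression and differential expression

FPKM is computed exactly as c·10⁹/(L·N) with library sizes defaulting to
counts-column sums. The no-replicate DE contrast is the exact binomial
test of the panicle count against Binomial(c_p + c_s, N_p/(N_p+N_s))
(equivalent in spirit to Audic–Claverie), with a Fisher-exact variant
behind a flag; the upstream study's actual tool is unnamed, so both are
documented stand-ins. FDR is Benjamini–Hochberg; a call requires both
|FC| beyond 2 and q < 0.05. Fold changes use an ε = 0.01 FPKM pseudocount —
small enough to leave expressed transcripts unchanged, large enough to
avoid division by zero. Transcripts with zero counts in both samples are
excluded from testing and reported untested.

**Known limitation.** The exact binomial test models Poisson (technical)
count variation. Under biological overdispersion it is anticonservative:
on an all-null negative-binomial genome (mean 50, dispersion 0.1) it flags
~16% of transcripts at BH 0.05, and the test suite pins this behavior.
Calibration is therefore verified under the test's own sampling model — on
Poisson nulls the flagged fraction is ~0 — and sensitivity is verified on
a spike-in design (10% of transcripts planted at 10×, mean 50, dispersion
0.1; ≥ 90% recovered). The spike-in uses a null majority deliberately:
planting every transcript shifts the library size and cancels the fold
changes (composition effect). With replicated designs a dispersion-aware
test should replace this contrast entirely.

## Sequence-conservation screen

BLAST is replaced by exact Smith–Waterman with affine gaps, removing the
external binary and making scores reproducible. Scoring: match +1,
mismatch −2 (near megablast's defaults), a gap of length L costs 4 + L.
`N` scores as a mismatch against everything, itself included, and never
counts as an identity. Identity uses the BLAST-style denominator (all
alignment columns, gaps included). Both strands are searched;
reverse-strand hits report subject coordinates on the forward strand plus
a strand flag. The alignment engine is Biopython's `PairwiseAligner`
configured to these scores; the test suite checks its optima against an
independent exhaustive Gotoh dynamic program on hundreds of random pairs.
When co-optimal alignments exist the engine's first traceback is reported —
deterministic, though not necessarily the lowest-query-start optimum.

The screen's thresholds are strict inequalities: segment > 100 columns and
identity > 90%. Screening all-vs-all uses two cheap exact filters that
cannot discard a passing pair of the planted kind: (1) a pair is aligned
only if it shares ≥ 2 exact 11-mers in one diagonal band (width 50 nt) on
either strand; (2) traceback is skipped when the optimal score is below
100·(0.9·1 + 0.1·(−2)) = 70, a lower bound every passing segment must
exceed. Filter (1) is heuristic in principle — a worst-case segment at
90.x% identity with perfectly spaced mismatches has no 11-mer run — but
planted families at 96% always seed; the k-mer length and seed count are
parameters, and `seed_kmer=0` disables seeding for exhaustive screening.

Families are connected components of the undirected link graph (via
networkx, tested against a union-find oracle). How the original analysis
grouped its "matches" is not reconstructible — components are the
documented interpretation here. The three-way rule keeps families with at
least one member in every genome. TE-like flagging marks families with
≥ 5 copies in any genome (threshold configurable) and reports the
wild→cultivar contraction ratio (wild copies over the mean cultivar
copies).

## Positional conservation

The flanking context is the 5 nearest protein-coding genes by absolute
midpoint distance (ties: lower start), whatever the upstream/downstream
split turns out to be — a "nearest upstream and downstream … 4 of 5"
rule forces an odd, mixed-side window. Contexts with fewer than 5 genes on
the chromosome are excluded as incomplete. "Close" is operationalized as:
the context gene's ortholog lies in the partner lncRNA's own context, or
within W = 10 coding-gene ranks of the partner lncRNA on its chromosome.
W is a free parameter the source procedure never defines; 10 ranks
(~100 kb at typical rice gene density) is the documented default and is
recorded in output headers. Missing orthologs count as not-close, never as
errors. Calls are directional (wild→cultivar, cultivar-A→cultivar-B); a
reciprocal mode requires both directions. Orthology comes from a
reciprocal-best-hit screen over the same aligner (ties excluded as
ambiguous) or from a user/generator-supplied table. Triples are pairs
conserved along all three pairwise comparisons.

Genome-scale counts of positionally conserved lncRNAs from the original
study (78/123/60 pairwise, 8 triple) are not expected to be reproducible
from desk-scale data; the synthetic trio instead plants a known set —
including 8 triple-conserved blocks and more wild–cultivar-B than
wild–cultivar-A blocks, so the recovered counts must preserve that
order — plus shuffled-annotation and non-orthologous-block negative
controls that must yield zero calls.

## Trait statistics

Mutant-vs-wild-type comparisons use the pooled-variance Student's t test
(the test the source procedure names; Welch is a flag — note the
structural comparisons in `features` default to Welch instead, where group
variances plainly differ). Marks: \*\* for p < 0.01, \* for
0.01 ≤ p < 0.05, n.s. otherwise; arrows follow the sign of (mutant −
wild-type) mean and appear only when significant. Cells render as
`mean ± SD(mark arrow)` with two decimals and parse back losslessly.
Exact published t values are not reproducible because only summary
statistics and bounds on n are available; the statistics, decision logic
and table format are what this module reproduces.

## Problem sizes in the test and acceptance suites

Chosen once as the package's standard study conditions: the
distribution-calibration trio uses 2000 lncRNAs per genome (medians within
10% of targets are required at this n); the conservation-recovery trio
uses 200 background lncRNAs per genome plus the planted families
((41,1,3) and (21,1,2) at 96%/150 nt), decoys (85%/150 nt and 96%/90 nt)
and 21 collinear blocks; DE calibration uses 2000 transcripts × 20
replicate simulations and a 10%-spike-in sensitivity run; the aligner
oracle uses 500 random pairs ≤ 30 nt. All suites run at fixed seeds.

## Known limitations

* No indel model in planted homologs; the aligner supports gaps but the
  recovery suites never exercise them.
* The no-replicate DE test's anticonservativeness under overdispersion
  (above) — a property of the test class, not of this implementation.
* The k-mer seeding of the screen is heuristic at the identity boundary
  (90.x%); exhaustive mode exists but is quadratic.
* Coding-potential scoring is consumed, not computed; synthetic scores
  only emulate separability, and no claim is made about CPC/CNCI behavior.
* Collinearity calling assumes one-to-one orthologs; paralog-rich
  neighborhoods would need the reciprocal mode plus curated ortholog
  tables.
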