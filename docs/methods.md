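# Methods

This note documents the models, the numerical choices and the synthetic
study conditions behind `pbmgrn`, and what the passing tests do and do not
demonstrate about real data.

## PBM scoring

Probe normalization scales each replicate so its median matches the mean
of the replicate medians, then averages per-probe intensities on the log
scale (geometric mean). Probes below an intensity floor (default 10⁻³ of
the common median) are flagged, never dropped, so the probe universe —
which defines the background of every rank test — is preserved. The
platform-specific spatial and sequence-bias corrections applied by array
vendors are upstream of this package and are not reproduced.

The enrichment score is the rank-sum (Mann–Whitney) AUC statistic shifted
to [−½, +½]: ES = U/(|F||B|) − ½ with ties counted one half. It is
computed from midranks, which is algebraically identical to explicit pair
enumeration; the test suite verifies this to 10⁻¹² against brute force.
Reverse-complement words are identified everywhere (double-stranded
probes), so ES(w) = ES(revcomp(w)) exactly. Alternative ES variants based
on truncated foreground lists exist in the PBM literature; the rank-AUC
form shares their range and the 0.40/0.45 operating points and is used
throughout as the package's single scoring rule.

**Minimum foreground support.** Words matching fewer than `min_foreground`
probes (default 4) are left unscored. The rank statistic of a word seen
once or twice is dominated by the noise of those few spots — a word unique
to the single brightest probe always scores exactly +½ — so a small
support floor is required before an ES is meaningful. Universal "all
k-mer" array designs enforce such multiplicity by construction; the floor
plays the same role at desk scale.

**Word universe.** Patterns have 8 informative positions and at most one
contiguous gap of N's (default `max_gap` 1 in the pipeline config, up to 3
supported), never at the edges. There are 32,896 canonical ungapped
8-mers; the pipeline scores only words actually present in probes.

**Core words** (ungapped 6-mers and single-gap 7-mers) summarize the
significant 8-mers. Exact reproduction of a published core-word list is
not a goal; the selection here is a greedy cover: candidates are the
6/7-mer sub-words of the significant set, scored by their maximum per-TF
median ES over containing words, and selected—largest uncovered coverage
first, ties by score then lexicographic—until every significant word
contains a chosen core. This is deterministic and reproducible; it stands
in for the published combination of a "preferred k-mers" statistic with
manual curation, which is not algorithmically specified anywhere.

**PWMs** are built per TF from the top-N ungapped words (default 10),
aligned to the top-scoring seed with ≥ 6 overlapping positions in either
orientation, ES-weighted base counts per column, and a 0.01 pseudocount.
Columns outside the seed frame are discarded; the PWM is a display/summary
object, not the scanning engine (scanning is exact word matching).

## Clustering and fingerprints

The specificity matrix (significant words × TFs) is clustered
agglomeratively: 1 − Pearson between TF columns, Euclidean between word
rows, average linkage; both metrics and the linkage are configurable
because the original figures name only the plotting software. Missing
cells are imputed as ES 0 (absence of enrichment) for distance computation
only, and a constant profile under the correlation metric is an error
naming the offender. Flat labels come from cutting the tree at a requested
count. Fingerprints are Matlab-convention boxplot statistics
(linear-interpolation quartiles, whiskers at the last point within
1.5 IQR) of the ES values of significant words containing each core word.

## Promoters and scanning

A promoter is min(1000, upstream gap) bp upstream of the annotated gene
start (not a transcript TSS), reverse-complemented for − strand genes so
it always reads 5'→3' toward the gene. The truncating neighbor is the
nearest annotated gene boundary on either strand. Genes with zero gap
yield no promoter; promoters over 50% N are dropped; both are logged.
Coordinates are 1-based inclusive genomically, 0-based from the promoter
5' end in hit tables.

Scanning is strand-symmetric exact matching (pattern N matches any base,
sequence N matches nothing), reporting all overlapping hits. Seed sets use
a strict ES > 0.45; significance uses an inclusive ES ≥ 0.40. By default
gapped seed words scan alongside ungapped ones (configurable).
Palindromic double sites use the self-reverse-complementary pattern class
CGT‑N{7,8}‑ACG, scanned forward only (the class is its own reverse
complement); both spacer lengths are reported.

Binding-site redesign searches substitution neighborhoods of growing
radius for the minimal-edit variant whose best 8-mer-window ES reaches the
gain threshold for one TF (default ≥ 0.40) and stays at or below the loss
threshold for the other (default ≤ 0.30), ties broken lexicographically.
Distances are standard unit-cost Levenshtein.

## Co-expression filter

Each gene's cluster is its `top_n` neighbors by Pearson correlation on raw
expression values (a log2 option exists), ties broken by gene id,
zero-variance genes excluded. A P target is retained as P+COE if, in at
least one compendium (configurable to "majority"/"all" — the published
rule does not say how its 14 compendia were combined), the hypergeometric
upper tail of (cluster ∩ P) against the universe is below α = 0.05, raw
(no multiple-testing correction, matching the published rule; a BH option
is provided). The universe is the set of genes present in both the
annotation and the compendium. Exactness matters at small N, so the
p-value is an integer-arithmetic tail sum, verified against complete draw
enumeration for N ≤ 25.

## Phylogenetic footprinting

The published workflow used a dedicated promoter aligner; here the
pairwise step is an iterative masked Smith–Waterman block extractor
implementing the same contract — mutually consistent, non-overlapping,
gap-free local blocks. Defaults: match +1, mismatch −1, gap open −2,
extend −1, stop when the best local score falls below 20 (random 300–400
bp promoter pairs top out near 18, so null pairs almost always yield zero
blocks), keep the maximal-scoring (Kadane) sub-block of each gap-free
segment if it is ≥ 8 bp at ≥ 70% identity, mask consumed columns in both
sequences, repeat. The Kadane step prevents a conserved core from being
diluted by diverged flanks dragged along in the same alignment. Blocks
shorter than the stop threshold are undetectable by construction — the
conserved windows of interest (~40 bp) sit well above it.

Support profiles count distinct species covering each query position;
footprints are maximal runs at support ≥ c. Empirical significance
resamples, per query gene, `n_samples` non-orthologous promoter sets with
the true species composition (default 1000; the tests and the bundled
studies use 50–200 for runtime) and asks how often a random set contains a
run with at least the observed support and length; "similar or better
conservation" is operationalized exactly as (support ≥, length ≥), which
the source text leaves open. All observed footprints of a gene are scored
against the same null samples, making FDR non-increasing in support level
at fixed length. Both per-footprint FDR and the per-gene best-footprint
FDR are exposed, since the published description is ambiguous between
them. A motif hit is conserved only if fully contained in an FDR < 5%
footprint.

## Network and modules

The GRN takes one edge per (TF, gene) pair in P+COE, flagged when the
gene's motif instance is conserved. Module enrichment is the same
hypergeometric machinery at raw P < 0.05 (BH optional). Enriched modules'
GO terms are propagated to ancestors through a user-supplied parent map
(the package bundles no ontology snapshot), intersected with the GO-slim
vocabulary and mapped onto the fixed 10 functional categories; modules are
partitioned into those enriched for ≥ 5 TFs versus fewer. Curated-
interaction recovery divides by the curated pairs whose TF is actually in
the network. The perturbation analysis clusters the focal TF and its
candidate targets across selected conditions (Euclidean, average linkage)
and labels each target by the sign of its correlation with the focal
profile.

## Synthetic study conditions

The generators define the study conditions; every generator is a pure
function of (config, seed).

- **PBM**: 2000 probes of 36 bp covering all 4096 ungapped 6-mers (de
  Bruijn tiling) plus random padding; two replicates with independent
  multiplicative lognormal noise (σ = 0.2) and a deliberate 1.3× scale
  difference to exercise normalization. Intensity = 50 + 2000 × (best
  window probability ratio under the TF's planted core PWM, width 6,
  consensus probability 0.9). Each TF's 8-bp site word (core + fixed
  flanks) is additionally spiked into 12 random probes — the desk-scale
  counterpart of the word multiplicity a universal design guarantees — so
  the site has dependable foreground support. Defaults plant TTGCGT
  (site ATTGCGTA) and TTACTT (site GTTACTTC), mirroring the two most
  distinct specificity classes of the motivating TF family.
- **Genome**: 500 tandem + strand genes on one chromosome, intergenic gaps
  drawn from {300…1500} bp so the 1 kb truncation rule is exercised; each
  of 30 designated true targets per TF receives one site copy at a uniform
  promoter offset on a random strand.
- **Expression**: 2 compendia × 30 samples; per-TF latent activity;
  true-target expression = sign × 2.0 × activity + N(0,1); background
  N(0,1); DE sets are the true targets passing a |contrast| ≥ 1 threshold
  with N(0, 0.3) background contrasts. Signs are planted per gene and
  reused by the perturbation simulation.
- **Orthologs**: per species, true-target promoters are substituted at
  rate 0.5 outside — and 0.02 inside — a 40 bp conserved window centered
  on the planted site; background genes get independent random promoters.
  No indels are simulated; the block aligner tolerates them but the
  planted signal does not need them.
- **Modules**: per TF, 3 modules drawn 80% from that TF's true targets,
  the rest random; every module carries a leaf GO term whose parent is a
  slim term, exercising propagation and categorization end to end.

The bundled end-to-end studies run a scaled-down analogue: 250 genes,
top-30 co-expression clusters (preserving a usable cluster-to-genome
ratio; the published 100-of-27k proportion is far more dilute), 3 species
and 50 null resamples, chosen to keep a 20-seed study under a few minutes
on one CPU. Problem sizes are stated alongside every reported quantity.

What passing tests show: the statistics agree with exact oracles; planted
signal at realistic signal-to-noise is recovered; both resampling filters
are calibrated under their nulls; the evidence tiers nest and their DE
enrichment is monotone. What they do not show: behavior under array
spatial artifacts, probe sequence bias, indel-rich promoter evolution,
condition-dependent expression structure, or annotation errors — none of
which the generators emulate.

## Known limitations

- The ES is a single rank-AUC definition; published PBM pipelines differ
  in detail, so absolute ES values are comparable only within this
  package.
- The core-word selector is a deterministic surrogate for a partly manual
  published procedure.
- The block aligner is a functional stand-in for a dedicated promoter
  alignment tool; its stop threshold bounds the smallest detectable
  footprint (~20 bp at full identity).
- Promoters anchor at annotated gene starts; isoform-aware TSS selection
  and UTR modeling are out of scope.
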