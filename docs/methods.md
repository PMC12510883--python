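# Methods

This note documents the models, numerical choices and known limitations of
`sdrkit`'s processing stack and of the synthetic-data generator that the
test suite is built on.

## Backbone alignment and score filtering

A barcode read is matched against every concrete *backbone*: the
concatenation of its non-payload segments for one combination of
variable-segment lengths (with the default layout, four backbones per
modality, one per 14–17 bp linker₁ length). Barcode, sample-barcode and UMI
positions are `N` wildcards that match any base at the match score; linkers
contribute their fixed sequence. Alignment is semi-global — the backbone
aligns end to end, the read from its first base, and may continue past the
backbone into payload — under linear scoring (match +1, mismatch −1,
gap −1). The implementation is a numpy-vectorised dynamic program over read
batches with per-read traceback; reads whose fixed linker positions match a
backbone verbatim take a fast path, since their optimal score is the
maximum achievable and the DP is redundant (the outcome is provably
identical, and tests compare scores against an independent quadratic DP on
random pairs).

**Score normalisation.** Scores must be comparable across backbones of
different lengths so one adaptive threshold can govern them all. Dividing
the raw score by the backbone's own length does not achieve this: a read
with *k* edits scores 1 − 2k/L, which differs between the L = 63 and L = 66
backbone variants, and an adaptive threshold calibrated on the mixture can
fall *inside* the one-edit band, discarding one-edit reads on the shortest
backbone while keeping them on the longest. We therefore normalise the
score *deficit* by a single per-library constant: with m the match score
and L_ref the longest backbone length,

    normalized = m − (L·m − raw) / L_ref .

A perfect read scores exactly m on any backbone and a k-edit read scores
m − 2k/L_ref regardless of which backbone it followed. The winning backbone
maximises this score; ties prefer the shorter backbone, then the lower
backbone id (determinism).

**Threshold.** The pass threshold is mean − 2·sd (sample standard
deviation, n−1) of the normalised scores of the first 10,000 reads of a
library; filtering keeps scores ≥ threshold (inclusive boundary, so a
zero-variance library keeps everything). With the default error regime
(≈0.6 %/base total) this keeps reads with ≤ 1 edit in scored positions and
discards ≥ 2-edit reads — roughly a 2 % loss. At very low but non-zero
error rates the rule tightens toward the perfect score and is intentionally
aggressive; at exactly zero error the threshold equals the perfect score
and everything passes.

## Barcode correction

Cell barcodes (BC1, BC2) have known endpoints inside the segmented read and
correct to a whitelist entry when **exactly one** entry lies within
Levenshtein distance 1 (unique-within-1; an exact hit flanked by a
distance-1 neighbour is rejected as ambiguous — whitelists should be
designed with pairwise separation ≥ 3, which the simulator enforces).

The sample barcode is directly upstream of the random UMI, so an insertion
or deletion makes its endpoint unknowable. It is corrected under **free
divergence** — the minimum Levenshtein distance from a whitelist barcode to
any prefix of the observed window — computed with edlib's prefix-alignment
mode, which implements exactly this quantity (the test suite holds an
independent brute-force enumeration oracle). The observation window is the
sample-barcode segment plus the next two read bases (spilling into the
UMI), so that an insertion shifting the true barcode end rightward stays
recoverable. The margin rule accepts the best entry w at divergence d\* iff
d\* ≤ 1 and no other entry is within d\* + 1 — applied literally even at
d\* = 0. The simulator's sample whitelist uses pairwise Levenshtein ≥ 4 so
that two extension bases can never pull a foreign barcode inside the
margin.

## UMI deduplication

For each (cell, sample barcode, gene), observed UMIs form a directed graph:
A→B when free_divergence(A, B) = 1 (one edit, indels included) and
n_A ≥ 2·n_B − 1 reads. The metric is asymmetric, so both orientations of
each pair are tested and the count rule decides direction. Each node then
keeps at most one incoming parent edge — the highest-count parent, ties to
the lexicographically smallest sequence — to prevent artifactual chains
through singletons; the molecule count is the number of weakly connected
components. The count rule is applied against the immediate parent, not the
component root. Equivalence with a rule-by-rule brute-force oracle
(pairwise DP matrix, explicit edge and parent rules, union-find) is
asserted on a thousand random multisets.

Note that UMI counts are estimates even on error-free reads: two distinct
molecules can draw colliding or divergence-1 UMIs, and the count rule then
legitimately merges them. Truth comparisons in the tests therefore collapse
the *true* UMI multisets with the independent oracle rather than counting
molecules directly.

## Cell QC

**Cell calling.** Barcodes are ranked by total reads (gDNA + RNA); on the
log₁₀(rank) vs log₁₀(count) curve the knee is the point of maximum
perpendicular distance to the chord between the first and last points. The
threshold is then the count at the last point before the steepest
consecutive log-drop at or past the knee: with counting noise the
max-distance point sits a few ranks inside the high plateau's tail, and
extending to the cliff keeps the full cell population (exact recovery on
bimodal fixtures across seeds). Uniform counts raise an error directing
manual mode; a manual read-count threshold is always available and is what
the tests use on simulations without empty-droplet background.

**Demultiplexing and doublets.** A cell's sample is the majority sample
barcode among its RNA reads (gDNA reads carry no sample barcode); purity =
majority-sample reads / total RNA reads. Purity below 0.8 (configurable)
flags a doublet. Cells with zero RNA reads are unassignable and dropped.
RNA entries from minority sample barcodes of kept cells are removed as
contamination before the final matrix is collapsed to one row per cell;
the operation is idempotent and totals never increase.

## Genotype analytics

Pipeline order is fixed: ingest merged VCF → wild-type inclusion →
depth/quality filters → low-frequency variant removal; each stage is
idempotent. GT codes map 0/0→REF, x/y with one alt copy→HET, two→ALT,
missing otherwise; multi-allelic records split into one variant per alt
allele. Wild-type inclusion fills uncalled (cell, variant) entries with REF
when the covering amplicon has ≥ 10 reads in that cell (DP = amplicon
depth, no GQ); filters mask entries with DP < 10 or GQ < 30 (boundaries
keep; absent GQ passes the GQ test, absent DP fails). Low-frequency removal
drops variants whose non-REF fraction among non-missing entries is below
`min_frac` or whose non-REF cell count is below `min_cells`; both
thresholds are parameters because different study designs use different
cutoffs (per-mille-scale fractions for engineered samples, a few percent or
a minimum carrier count for primary samples).

**ADO.** At known-heterozygous loci, ado = 1 − (HET calls / non-missing
calls) per variant; the summary averages variants detected in > 80 % of
cells. **Noise.** At known homozygous-reference loci, noise = non-REF calls
/ non-missing calls, stratified by (reference base, variant class ∈
{substitution, insertion, deletion}); the class rates' weighted sum equals
the overall rate by construction. **Burden.** Per-cell count of HET + ALT
calls; top/bottom 20 % quantiles (by stable sort) define high/low strata;
an all-equal burden vector yields only "mid" with a warning.
**Differential abundance.** Per variant, a 2×2 carrier/non-carrier × state
table over non-missing cells, Pearson χ² without continuity correction
(scipy), Benjamini–Hochberg adjustment over tested variants (statsmodels),
significance at q < 0.05; delta is the carrier percentage difference in
percentage points. Variants with an empty margin are reported untested.

## The simulator

The generator emulates the assay's read structure and its dominant error
processes; its defaults are the study conditions of the test suite.

| Parameter | Default | Meaning |
| --- | --- | --- |
| n_cells / n_samples | 300 / 3 | droplets and sample-barcode groups |
| doublet_rate | 0 (tests: 0.05) | droplets hosting two cells |
| bc1/bc2 whitelists | 96 × 9 nt, pairwise Lev ≥ 3 | cell barcode halves |
| sample whitelist | 12 × 8 nt, pairwise Lev ≥ 4 | in-situ RT sample barcodes |
| umi_length | 8 nt | random molecular tag |
| n_gdna / n_rna targets | 8 / 8 | panel size (one SNP per amplicon) |
| mean_gdna_reads_per_amplicon | 20 | per cell, Poisson |
| mean_rna_molecules_per_gene | 4 | per cell, Poisson |
| mean_reads_per_molecule | 3 | PCR duplication (1 + Poisson) |
| sub / ins / del rates | 0 (noisy: 0.005 / 0.0005 / 0.0005) | per base |
| ambient_fraction | 0 (noisy: 0.01) | reads re-barcoded to a random droplet |
| ado_rate | 0 (noisy: 0.10) | per (cell, het locus): drop one allele |
| noise_rate | 0 (noisy: 0.001) | per (cell, ref locus): spurious alt allele |

Choices worth spelling out:

- **ADO model.** A dropout event drops exactly one (uniformly chosen)
  allele per (cell, heterozygous locus) at rate `ado_rate`, *before*
  amplification. Under this model the estimand 1 − het-call-rate equals the
  parameter, so the estimator's calibration can be checked directly. (Under
  independent per-allele Bernoulli dropout q, 1 − het-call-rate would be
  2q/(1+q) and both alleles could vanish; that variant conflates dropout
  with missingness and has no clean true parameter for this estimator.)
- **Noise model.** A noise event gives a truly homozygous-reference cell an
  amplifiable alt allele (allele pool REF+ALT, a PCR-jackpot-like artifact),
  producing a HET-level signal rather than scattered error reads; this is
  what a genotype-level noise rate measures.
- **Doublets** always merge constituents from two *distinct* samples, so
  sample-barcode demultiplexing can reveal every simulated doublet and
  truth comparisons are exact. Same-sample doublets are invisible to this
  assay class by construction and are not modelled.
- **Ambient reads** keep their own sample barcode and UMI but carry a
  uniformly drawn other droplet's cell barcode; cross-sample ambient
  molecules are exactly the ones contamination stripping can remove.
- Genomic amplicons (160 bp) sit on one synthetic chromosome; RNA
  references are transcript suffixes from the primer-binding site plus a
  20-A poly(A) stub. Variant positions are placed 30–89 bp into the
  amplicon so the payload read always covers them. Quality strings are a
  constant 'I' (unused by scoring).
- Expression is Poisson per (cell, gene) — deliberately simpler than real
  single-cell overdispersion. The generator also does not model
  polymerase error spectra, sequence-dependent PCR bias, deamination
  artifacts or droplet physics; passing tests therefore demonstrate
  correctness of the *processing rules* under controlled conditions, not
  performance on real libraries.

## The fixture genotype caller

Variant calling proper is outside this package (a merged VCF is the
interface). For closed-loop testing the simulator ships a naive
allele-count diploid caller: payload reads are projected onto their
amplicon reference (edlib prefix alignment, cigar walk to the variant
offset), ref/alt reads counted per (cell, variant), and a variant is
emitted when alt reads ≥ 3 **and** alt fraction ≥ 0.1 (HET below 0.9,
hom-ALT at or above). The three-read evidence floor keeps 0.5 %/base
sequencing errors (alt-read probability ≈ 1.7 × 10⁻³ per read) from
producing false HET calls at depth ~20, which would otherwise contaminate
genotype-noise estimation at the 10⁻³ level being measured. GQ is the
Phred-scaled gap between the best and second-best binomial genotype
likelihoods under a symmetric 2 % allele-error model, capped at 99 —
enough structure for the GQ < 30 filter to act on low-depth calls.
Homozygous-reference cells are deliberately *not* emitted; they enter the
matrix through wild-type inclusion, mirroring the real workflow.

## Problem sizes and numerics

The acceptance-style tests run the full stack at 300 cells, 3 samples and
8+8 targets (~80k reads), with smaller 40–60-cell runs for unit-level
round trips; these sizes exercise every code path while keeping the whole
suite fast. Alignment uses int32 scores; thresholds compare with inclusive
boundaries throughout (score filter, DP/GQ keep-side, manual cell calling);
all tie-breaks (backbone choice, UMI parent, sample argmax) are
deterministic and documented above; every stochastic step flows from a
single integer seed through named child generators, so identical configs
produce byte-identical FASTQs.
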