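# Methods

This note documents the models, statistics and generator design behind
`ocrdyn`, the choices made where several designs were defensible, and
what the synthetic benchmarks do and do not establish about real data.

All genomic coordinates throughout the package are 0-based, half-open.
Stage order is configurable and defaults to hiPSC < N-d30 < N-d41 with
two replicates per stage; count-matrix columns follow the
`<stage>_<replicate>` convention, from which the stage factor is parsed.

## Differential accessibility

**Normalization.** Peak counts are scaled to counts per million of
in-peak reads: `value = raw × 1e6 / column_total`. This is the plain
total-count normalization commonly applied to ATAC peak matrices; it is
exact when total accessibility is conserved across stages and biased
when it is not (see *Composition balance* below).

**Dispersion.** A common negative-binomial dispersion φ (Var = μ + φμ²)
is estimated by the method of moments: per peak and replicate group, on
depth-equalized counts with group mean m and sample variance v, the
moment ratio is (v − m)/m²; the common estimate is the median over peaks
of the group-averaged ratio, clipped at zero. With two replicates per
group this estimator is noisy and biased low (≈0.03 for a true 0.05 in
simulation). It is adequate for ranking and classification, but the
exact test becomes mildly liberal when the plugged-in φ is
underestimated; calibration analyses should use a known or externally
estimated dispersion. The default φ when none is given is the data
estimate; 0.05 is a typical ATAC replicate dispersion and is the
generator default.

**Exact conditional test.** For one peak and two conditions with n_A and
n_B replicates: counts are depth-equalized to the geometric-mean library
size (rounded to nearest integer) and summed per condition; the sum of n
i.i.d. NB(μ, φ) with common success probability is NB(nμ, φ/n).
Conditional on the grand total T, the probability of a split (a, T−a)
is proportional to C(a + r_A − 1, a) · C(T − a + r_B − 1, T − a) with
r = n/φ — the common success probability cancels, so the conditional law
needs no mean estimate. The two-sided p-value is the total conditional
mass of splits whose probability does not exceed the observed one
(minimum-likelihood definition), with 1e-12 relative slack on ties.
As φ → 0 the law converges to Binomial(T, n_A/(n_A + n_B)); the φ = 0
branch computes that limit directly and is verified against exhaustive
binomial enumeration for all totals ≤ 200.

**FDR and classes.** Benjamini–Hochberg step-up q-values are computed
over all transition tests pooled. Per transition a peak is up/down if
q < α (default 0.05) with the corresponding sign of the log2 fold change
of stage-mean CPM (pseudocount 0.5), else flat. The dynamic class is the
ordered pair of transition labels; all nine labels are reported, and the
six without a sign reversal (the classes a monotone differentiation
course is expected to occupy) are flagged as canonical.

**Stage-specific peak sets.** A stage's peak is stage-specific iff it
overlaps (≥1 bp) no peak called in any other stage. Overlap queries use
a sorted-start index with prefix-maximum ends (O(log n) per query),
fuzz-tested against an all-pairs oracle. Any-overlap is the chosen rule;
a minimum-overlap fraction would also be defensible but needs a
threshold the analysis otherwise never uses.

## Promoter–expression concordance

Genes map to at most one promoter-TSS peak: candidate peaks overlap the
strand-aware window (−1000, +100) around the TSS (on the − strand the
window is [TSS − 100, TSS + 1000)); the peak whose center is nearest the
TSS wins, ties to the smaller start. The (−1000, +100) default matches
common promoter annotation practice and is configurable.

Pearson correlation is computed on log2(x + 1)-transformed openness and
RPKM (the transform stabilizes variance of count-derived quantities; it
can be disabled). Fold changes use pseudocount 1, FC = (a+1)/(b+1), so
FC(a,b)·FC(b,a) = 1 and zeros are defined. The concordance test keeps
genes with FC > 2 or < 1/2 in either measure, tabulates up/down vs 1 in
both, and applies the shared two-sided Fisher implementation; genes with
FC exactly 1 cannot be oriented and are dropped; an empty selection is a
defined no-test result (NaN p), not an error.

Variable-gene selection takes |log2 FC| > log2(fold) (default 4) and
q < 0.005 from the same exact test applied to the two stages' expression
values (or a user-supplied q column).

## Footprinting

**Scanning.** PWMs are probability matrices (pseudocount 1 when built
from counts); log-odds are taken against genome-wide mononucleotide
frequencies. Every offset on both strands is scored; a window is a hit
at ≥ 0.8 × the maximum attainable score, ambiguous bases contributing 0
(background). Reverse-strand hits are reported on forward coordinates
with strand "−". Same-TF hits closer than half a motif width are merged
keeping the best score, so a motif instance is counted once. The scanner
is verified against brute-force rescoring of every window.

**Purity score.** For a hit and a stage,
`purity = clip(1 − core_mean/flank_mean, 0, 1)` with core = motif
interval and flanks = ±50 bp; no footprint is defined when the flank
mean falls below 0.2 insertions/bp (prevents purity-1 artifacts at
uncovered sites). The score is invariant to sequencing depth. Footprints
are called at purity ≥ 0.9. This is a deliberately transparent stand-in
for generative footprint posteriors (EM over insertion profiles); the
numeric 0.9 cutoff is reused on this scale, but the two scales are not
claimed equivalent — a posterior-like score and a depletion ratio answer
the same question with different units.

**Stage-specific TFs.** Footprint counts per TF per stage are compared
pairwise with the shared Fisher test on (TF count, stage total − TF
count); Bonferroni correction spans all TF × pair tests. A TF is
stage-specific iff its count in that stage exceeds every other stage by
more than the fold threshold (default 2) *and* every contrast is
significant; with three stages, a TF whose two later stages both beat
the first by the same rule, with neither beating the other, is shared.
The global "is the stage distribution of specific TFs non-random" check
is implemented as a chi-square test on the stage × specific/non-specific
table and labeled as an interpretation; other constructions exist.

**Lag test.** Binding peak = argmax stage of footprint counts;
expression peak = argmax stage of RPKM; ties resolve to the earliest
stage. The lag flag is expression strictly earlier than binding; k lags
among n TFs are tested against 0.5 with the exact two-sided binomial.

## Networks

Edges are TF → gene pairs supported by ≥1 footprint in the strand-aware
(−10 kb, +1 kb) window around the gene TSS. The window is a conservative
promoter-proximal default, configurable, and deliberately distinct from
the 100-kb span used for upstream-regulator queries (a stated analysis
choice, not a linking rule). Per-stage networks restrict TF nodes to
stage-specific (optionally shared) TFs with ≥1 supporting footprint at
purity ≥ 0.9 in that stage; node expression attributes are
log2(stage RPKM + 1) − log2(baseline RPKM + 1). The largest weakly
connected component is selected by node count, ties by edge count and
then the lexicographically smallest node set; master nodes are its top-k
TFs by out-degree (ties: total degree, then name; k defaults to 6).
Autoregulation is a self-edge; its reported distance is the strand-aware
signed offset of the supporting motif start from the TSS (upstream
negative), nearest first.

## Gene-set enrichment

Upper-tail hypergeometric overrepresentation with BH FDR across sets,
universe = annotation ∩ assayed genes; peaks are linked to genes by
nearest TSS to the peak center (ties to the smaller TSS coordinate).
Only overrepresentation is offered; depletion was not part of the
analysis this package supports.

## The synthetic experiment

The generator emulates the *statistical structure* the analysis assumes,
not sequencing itself (no reads, fragments, or nucleosomes; haploid
genome; chromosomes named chr1..chrN).

- **Genome/genes:** i.i.d. bases at the configured GC (default 0.41);
  genes placed with ≥2 kb TSS spacing, random strand, infeasible
  requests failing loudly.
- **Peaks:** one promoter peak centered on each gene's TSS plus distal
  peaks placed outside all promoter-proximal windows (so distal bound
  motifs can never create edges outside the planted truth); dynamic
  classes assigned by largest-remainder allocation (exact counts when
  proportions divide n) then shuffled.
- **Class multipliers:** each class keeps 4-fold effects per changing
  transition, and class base levels are chosen so the per-stage
  multiplier totals are equal under the uniform six-class mix
  (up-up (1,4,16), up-flat (4,16,16), flat-up (1,1,4), down-down
  (16,4,1), down-flat (4,1,1), flat-down (16,16,4); 42 per stage).
  *Composition balance matters:* with unbalanced totals, total-count
  normalization converts global shifts into spurious per-peak calls —
  in an unbalanced variant of this generator roughly a sixth of planted
  flat transitions are miscalled. Real experiments lacking this balance
  need a resistant normalization (trimmed-mean or median-ratio), which
  is out of scope here.
- **Counts:** per replicate, NB(mean_depth × multiplier × relative
  width, φ) signal (φ = 0.05 default; φ = 0 gives Poisson) plus Poisson
  background (0.05 insertions/bp). Peaks are "called" in a stage when
  the multiplier is ≥1.
- **Coverage:** per stage, the summed replicate count of each peak is
  distributed over its bases by a single multinomial draw whose weights
  are a raised-cosine bump (smooth, unimodal, integrates cleanly) plus
  the uniform background share — so base-level insertions inside a peak
  sum *exactly* to the reported counts. Outside peaks, Poisson
  background.
- **Footprints:** at a bound motif instance, in its bound stages, the
  core weight is multiplied by ρ (default 0.1) and the ±50 bp flank
  weight by `flank_boost` (default 2). The flank elevation reproduces
  the dip-between-two-flanking-peaks profile seen at occupied sites in
  real ATAC data, and it is what makes the planted signal decidable: a
  bare ρ = 0.1 core puts the expected purity exactly at the 0.9 call
  cutoff, where no finite-depth experiment can reach high sensitivity —
  with the boost the expected purity is ≈ 1 − ρ/2 ≈ 0.95. Peaks carrying
  bound instances are assigned the dynamic class most open in their
  bound stages (TFs bind open chromatin). ρ = 0 yields exactly zero core
  insertions; ρ = 1 yields no calls at the 0.9 cutoff.
- **Network plant:** the first PWMs become TF genes (renamed to the TF
  names); each TF gets `edges_per_tf` disjoint targets with its
  consensus written into their promoter peaks; consecutive TFs bound in
  the same stages share two targets so planted hubs form one connected
  component; one TF gets a self-promoter instance at −213 bp from its
  own TSS (strand-aware).
- **Expression:** per stage, log2(RPKM + 1) = β0 + β1·log2(openness + 1)
  + ε, with σ_ε solved in closed form from
  R = β1 σx / sqrt(β1² σx² + σ_ε²) at the target per-stage Pearson R
  (defaults 0.21 / 0.42 / 0.41), σx taken from the generated openness.
  The target must lie in the open interval (0, 1); forcing σ_ε = 0 gives
  an exactly deterministic link. RPKM is clipped at 0 (negligible at the
  default operating point).

Determinism: one config seed fans out to fixed per-step child seeds
(genome, planting, counts, expression), so identical configs produce
byte-identical artifacts, and each step is independently reproducible.

### What the benchmarks show — and don't

Passing recovery benchmarks on this generator shows the *pipeline logic*
is correct under its own assumptions: balanced totals, smooth unimodal
peak profiles, sharp consensus motifs, footprints with elevated flanks,
no Tn5 sequence bias, no GC effects, no overlapping peaks, no enhancer–
promoter ambiguity. Real data violate several of these (Tn5 insertion
bias alone can mimic or mask dips), so measured sensitivities and error
rates here are upper bounds on real-data performance, not estimates of
it.

## Benchmark problem sizes

The shipped tests and `scripts/acceptance.py` use desk-scale problems
chosen to exercise every code path with stable statistics: 2–8 Mb
genomes, 150–2000 peaks/genes, depth 200, 2000-peak null simulations,
20 × 2000-gene correlation runs, 200-TF specificity panels. All are
package choices; every size is a config parameter.

## Known limitations

- Total-count normalization only; no TMM/median-ratio alternative.
- Common dispersion only (no trended/tagwise), biased low at 2
  replicates; no GLM designs.
- The purity score ignores insertion strandedness and Tn5 bias; its 0.9
  cutoff is on a different scale than posterior-based footprint scores.
- Enrichment does no ontology-graph propagation; gene sets are flat.
- The expression link is log-linear with Gaussian noise; real
  mean–variance structure of RNA-seq is not modeled (RPKM is consumed
  as given, never recomputed).
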