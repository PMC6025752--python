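# ocrdyn

Stage-resolved open-chromatin analysis for ATAC-seq differentiation time
courses, built around the hiPSC → glutamatergic-neuron paradigm: induced
pluripotent stem cells (hiPSC), day-30 neural stem cells / early neurons
(N-d30), and day-41 maturing neurons (N-d41), each profiled with ATAC-seq
(two replicates) and RNA-seq.

The package answers four questions a chromatin time course poses:

1. **Which open-chromatin regions (OCRs) change, and how?** Peak read
   counts are normalized against each sample's total in-peak reads (CPM)
   and each consecutive transition is tested with an exact conditional
   negative-binomial test: replicate counts are depth-equalized to the
   geometric-mean library size and summed per condition; conditional on
   the grand total *T*, the split (a, T−a) follows a beta-negative-binomial
   law that depends only on the shape parameters n/φ, and the two-sided
   p-value is the mass of all splits no more probable than the observed
   one (at φ = 0 this is exactly the two-sided binomial test). After
   Benjamini–Hochberg FDR at 5%, each peak gets a *dynamic class* — the
   ordered pair of up/down/flat calls across the two transitions
   (up-up, up-flat, flat-up, down-down, down-flat, flat-down, …).

2. **Does promoter accessibility track expression?** Each gene is linked
   to the peak nearest its TSS within a strand-aware promoter window
   (−1000/+100 bp); per stage, Pearson's r is computed on
   log2(x+1)-transformed promoter openness vs RPKM, and directional
   concordance of fold-changes (genes with FC > 2 in either measure) is
   tested with the two-sided Fisher exact test.

3. **Which TFs occupy chromatin, and when?** PWMs are scanned genome-wide
   (log-odds vs genomic background, threshold 0.8 × max score) and every
   motif hit is scored per stage with the **purity score**
   `purity = clip(1 − core_mean / flank_mean, 0, 1)`, core = motif
   interval, flanks = ±50 bp, with a 0.2 insertions/bp flank floor.
   Footprints are called at purity ≥ 0.9. A TF is *stage-specific* when
   its footprint count in one stage exceeds every other stage by
   \>2-fold with each pairwise Fisher contrast significant after
   Bonferroni correction; a binomial lag test asks whether TF expression
   peaks a stage before TF binding.

4. **What does the regulatory network look like?** Footprints within
   −10 kb/+1 kb of a TSS become TF → gene edges; stage-specific TFs and
   their targets form a directed network whose largest connected
   component is summarized by its *master nodes* (top out-degree TFs).
   Upstream regulators are read from footprints within 100 kb upstream
   of a focal TSS, and promoter-proximal self-edges are flagged as
   autoregulation.

Because public ATAC-seq of this design is not bundled, the package ships
a first-class **synthetic-data generator** (`ocrdyn.simulate`) that
plants all of the above — dynamic classes, protected motif instances,
expression coupled to promoter openness at a chosen Pearson R, hub-and-
spoke regulatory edges including a self-edge at −213 bp — and emits
truth tables so every analysis stage can be scored against its plant.

## Worked example

```bash
python examples/05_tf_network.py
```

prints (abridged):

```
footprint counts per TF x stage:
     hiPSC  N-d30  N-d41
TF1      0      0     35
TF2      0      0     32
TF3     44      0      0
TF4      1     37      0
  TF1: N-d41-specific
  TF2: N-d41-specific
  TF3: hiPSC-specific
  TF4: N-d30-specific

N-d41 network: 18 nodes, 19 edges; most-connected component has 18
nodes; master nodes: ['TF2', 'TF1']
TF1 autoregulation: True, footprint at -213 bp from its own TSS
```

Four TFs were planted with bound motif instances in different stages;
footprint calling finds them only where they are bound, the Fisher/
Bonferroni rule recovers each TF's stage, the two N-d41 hubs come back
as the master nodes of the network's main component, and the planted
promoter-proximal self-edge is reported at its planted offset. The other
examples (`examples/01…06`) walk through simulation, dynamic classes,
promoter–expression concordance (recovered r of 0.216/0.412/0.456
against planted targets 0.21/0.42/0.41 at n = 600), footprint tag-density
dips, and gene-set enrichment.

There is also a thin CLI:

```bash
ocrdyn run --config demo.yaml --outdir out/   # full pipeline + summary.json
ocrdyn simulate | dynamics | concord | footprint | enrich ...
```

## Layout

- `src/ocrdyn/simulate.py` — synthetic experiment generator + truth tables
- `src/ocrdyn/io.py` — FASTA / BED / bedGraph / TSV / JASPAR / GMT / GraphML
- `src/ocrdyn/dynamics.py` — normalization, exact NB test, dynamic classes,
  stage-specific peak sets
- `src/ocrdyn/concordance.py` — promoter-peak assignment, correlations,
  FC concordance, variable-gene selection
- `src/ocrdyn/footprints.py` — PWM scanning, purity scoring, tag-density
  profiles, motif enrichment
- `src/ocrdyn/networks.py` — TF stage specificity, lag test, network
  assembly, master nodes, autoregulation
- `src/ocrdyn/enrich.py` — nearest gene, hypergeometric gene-set tests
- `src/ocrdyn/pipeline.py`, `cli.py` — end-to-end orchestration + CLI
- `docs/methods.md` — model, assumptions, parameter choices, limitations
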