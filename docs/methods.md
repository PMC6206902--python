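# Methods

This note documents the models behind `cncnet`, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and
the numerical conventions that make runs reproducible byte for byte.

## Differential expression

Intensities are mapped to log2 with a floor (`log2(max(x, floor))`,
default floor 1.0) so zeros are defined; an optional quantile mode forces
identical per-sample distributions. Each gene is tested with a two-sample
t-test between induced and control samples; `log2fc` is the difference of
group means on the log2 scale (up = higher in induced).

The default is the pooled-variance Student t rather than Welch. With two
or three replicates per group the Welch–Satterthwaite approximation is
noticeably conservative — on a 10,000-gene null matrix at n = 3 + 3 it
rejects ~3.3% at α = 0.05, versus ~4.7–5.3% for the pooled test, which is
exactly calibrated when group variances are equal (true under the
generator's model and a reasonable microarray approximation after
normalization). `test="welch"` selects the unequal-variance test, and the
standalone `welch_t` (statistic for mean(x) − mean(y), Satterthwaite df)
is available for ad-hoc comparisons.

Significance defaults to the raw *P* < α filter (α = 0.05), the convention
of the study design this pipeline emulates; Benjamini–Hochberg is a flag
(`correction="BH"`). Genes constant in both groups get t = 0, p = 1 and a
logged warning.

## Target prediction

### Alignment model

The scanner performs local alignment of the reversed miRNA (3'→5') over
the UTR (5'→3'), scoring columns by hybridisation: Watson–Crick pairs are
matches, G:U is the wobble (between match and mismatch), everything else a
mismatch. Gaps are affine; opening costs more than extending (the standard
convention; both penalties are configurable). The seed — miRNA positions
`seed_start..seed_end` from the 5' end, default 2–8 — is privileged three
ways:

* substitution scores inside the seed are multiplied by `seed_scale`
  (default 4);
* no gap may touch the seed: a seed base cannot sit opposite a gap and no
  insertion may fall between two seed bases;
* **every emitted site must cover the entire seed.** Without this rule,
  "all non-overlapping sites above threshold" is ill-defined at low
  thresholds (any single complementary base would qualify); with it, the
  8-mer worked example yields exactly one site. This is also how the
  original heuristic anchors sites.

Defaults are the canonical published set: match +5, mismatch −3, wobble
+2, gap open −9, gap extend −4, seed 2–8 ×4, score threshold 140, energy
threshold −20 kcal/mol. A full complement of a 22-mer scores
15·5 + 7·5·4 = 215.

The dynamic program is vectorised along the UTR (three affine states; the
insertion state is computed with a running-maximum scan), so a full scan
is a few numpy operations per miRNA base. Non-overlapping sites are
extracted best-first: report the optimum, mask its UTR footprint, rescan.
Determinism is pinned by explicit tie-breaks: maximum score, then leftmost
UTR end; in traceback, pairing is preferred over gap-in-UTR over
gap-in-miRNA; adjacent gap columns of opposite type are disallowed
(canonical alignments only). The test suite proves the DP equal to an
independent exhaustive enumeration on 200 random small instances.

### Duplex free energy

ΔG = +4.09 (initiation) + Σ nearest-neighbour stack terms over adjacent
paired columns + 0.8 per interior mismatch column + 2.0 per gap column
(kcal/mol). The shipped stack table uses the standard unified Watson–Crick
parameters and representative values for wobble-containing stacks
(wobble-on-wobble stacks are weak or slightly destabilising); it is
complete over all 36 pair-pair combinations and symmetric under strand
flip. There is no loop-entropy model — interior disruptions carry flat
penalties — which keeps the model exactly checkable by table arithmetic.
Every stack containing at least one Watson–Crick pair is negative, so
appending a Watson–Crick column never raises ΔG (a tested invariant).

A site is a hit only if score ≥ threshold **and** ΔG ≤ energy threshold.
The energy threshold is read as "at least this stable" (ΔG is negative).

### Chance hits

At the canonical defaults, chance hits are a real feature of the method,
not a bug of the implementation: a random 22-mer against a random 300-nt
UTR passes both thresholds with probability ≈ 0.5% (a near-perfect seed
plus a sufficiently stacked helix). A default synthetic run therefore
predicts roughly twice as many candidate pairs as were planted. Planted
full-complement sites always score the maximum attainable value and
dominate every chance hit — a tested invariant — and the downstream funnel
removes chance candidates. Consequences: occasionally a chance regulator
with the opposite direction ties a planted candidate's direction vote
(ties are dropped, with a warning), or contributes an extra core miRNA;
recovery of the planted funnel is exact at most seeds and ≥ 0.83 (Jaccard)
otherwise.

### Direction inference

A candidate mRNA's predicted direction is the opposite of the majority
direction of its *significant* regulating miRNAs; exact ties are dropped
with a warning. Candidates with no significant regulator are dropped.

## CNC network

Pearson r is computed over all samples pooled (both groups) for every
cross-class pair among significant DE miRNAs, significant DE lncRNAs and
candidate mRNAs; pooling maximises n at this assay scale (n = 6 by
default) and deliberately lets the group effect contribute to r — which is
what makes co-regulated DE genes correlate strongly, the premise of the
method. Genes with constant profiles are excluded with a warning.

Edge rule (all parts strict): |r| > threshold (default 0.9), r < 0 for
miRNA–mRNA (plus a predicted binding site) and miRNA–lncRNA, r > 0 for
lncRNA–mRNA. The rule is re-asserted exhaustively after construction.
When the mRNA side was never measured, `mrna_measured=False` takes
miRNA–mRNA edges from the target table with opposite predicted directions
and records r as missing; no lncRNA–mRNA edges are then possible.

Target mRNAs are selected by degree ≥ `min_degree` (default 1; the
original selection rule behind this step is not stated numerically
anywhere, so it is a knob).

## Enrichment

One-sided hypergeometric tail P(X ≥ k) for a query of n genes against a
set of m in a background of N (equivalently Fisher's exact
over-representation). The background is the annotation universe
intersected with the assayed mRNAs; when a GMT is read with an explicit
background, set members outside it are dropped (sets left empty are
removed with a warning). Reported per set: p, richness factor k/m, −LgP =
−log10 p, and the overlap genes. Up- and down-regulated queries run
independently; raw p < α defines significance by default, BH optional.

## Core-gene funnel

core = (genes of significant GO sets ∩ query) ∩ (genes of significant
KEGG sets ∩ query); sub-core = core ∩ reference list (ids matched
case-insensitively after whitespace stripping; no ortholog mapping); the
core network is the induced subgraph on sub-core mRNAs plus their
neighbours. Core lncRNAs are the lncRNAs adjacent to a sub-core mRNA
(`adjacency_mode="direct"`); `"shared_mirna"` additionally walks one step
through the core miRNAs, since how the original analyses identified their
lncRNAs is ambiguous.

## Synthetic data generator

The generator emulates a small two-colour-array-style study: two groups
(default 3 + 3 samples), per-gene baselines N(8, 1.5²) on the log2 scale,
within-group noise sd 0.25, intensities exponentiated so the pipeline's
log2 transform inverts the model exactly. Per class, a fraction (default
0.3) of genes is planted differentially expressed with group-mean shifts
of exactly ±2.0 log2 units, alternating up/down.

Planted regulations pair a DE miRNA with a DE mRNA of the opposite
direction (default 10 pairs, disjoint genes). The pair's residuals are
**mirrored**: both members share one per-sample residual stream with
opposite signs (sd = noise_sd) plus independent jitter of sd noise_sd/10.
Group means and within-group sd are untouched (full DE power), while the
pooled-sample correlation is pinned at |r| ≈ 0.999, so the |r| > 0.9 cut
recovers pairs essentially always at n = 6. An additive latent factor on
top of independent noise was considered and rejected: at n = 3 + 3 it
loses ~6% of pairs at the 0.9 cut and ~19% of DE power per paired gene.
Each planted pair's target UTR carries the exact reverse complement of the
full miRNA at a recorded position; background sequence is uniform over
A/C/G/U.

Gene sets (two collections, GO-like and KEGG-like, default 12 sets of 15
over the mRNA universe) include up to four planted enriched sets
alternating direction; an enriched set draws `enriched_fraction` (default
0.6) of its members from DE mRNAs of its direction, **starting with the
planted target-pair mRNAs** — the regulated program — so every realizable
candidate appears in at least one enriched set per collection, making the
funnel's expected output derivable from the truth table. The reference
list contains ~60% of the planted targets plus an equal number of decoy
mRNAs, upper-cased to exercise case-insensitive matching.

What it does **not** emulate: probe-level artifacts (background
correction, spatial effects, dye bias), heavy-tailed or
intensity-dependent noise, batch structure, realistic UTR base
composition or conserved seed families, and annotation incompleteness.
Passing recovery tests therefore demonstrates internal correctness of the
pipeline's logic under a clean generative model, not performance on real
arrays.

All randomness flows from one integer seed; each generator stage derives
its own fixed substream (string-prefix keys use CRC32, not Python's salted
hash), so outputs are reproducible byte for byte — writers use a fixed
`%.6g` float format, sorted orders, and explicit tie-breaks throughout.

## Default problem sizes

Defaults (40 miRNAs, 60 lncRNAs, 200 mRNAs, 300-nt UTRs, 3 + 3 samples)
make a full pipeline run take a few seconds and the complete validation
suite well under a minute, while keeping every planted-recovery statement
non-trivial (thousands of scanned miRNA–UTR pairs, tens of planted
structures). Calibration checks use 10,000 genes / 10,000 pairs.

## Known limitations

* The alignment scoring and energy tables are reduced models; absolute ΔG
  values are indicative, not thermodynamic predictions.
* Raw-p filtering at α = 0.05 with thousands of genes implies many false
  positives by construction; that is the emulated convention, and BH is
  available.
* Degree-based mRNA selection and the lncRNA adjacency mode are knobs
  because the underlying published choices are unstated.
* With predicted-only mRNAs (`mrna_measured=False`) the lncRNA–mRNA layer
  of the network is empty by necessity.
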