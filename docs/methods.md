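# Methods

`stromage` re-implements, as a tested pipeline over a synthetic cohort with
planted ground truth, the statistical workflow of a small-cohort multi-omics
aging study of dermal fibroblasts: 15 donors in three age bands (young
20–30, middle 40–50, old 60–70, five donors each), a label-free proteome,
a probe-level microarray transcriptome, and a miRNAome.

## Statistical procedures

**Quantifiability.** A protein enters analysis when it has at least 2 unique
peptides and was identified in at least 14 of 15 samples (both
configurable). Missing intensities are explicit NaN; zero is a legal
measured value. All protein statistics run on log10 intensities.

**Age-association screen.** Two tests are combined with AND logic at raw
p ≤ 0.05 each: classical one-way fixed-effects ANOVA across the three age
groups, and Pearson correlation of log10 intensity against calendar age
with no grouping (two-sided p via the t transform with n−2 df). Subset
analyses (e.g. an organelle-restricted screen) replace both alphas with a
single override, 0.1 by default. No multiple-testing correction is applied
in the primary screen — with ~1600 tests at α = 0.05 the expected false
calls are part of the emulated design — but BH q-values are emitted
alongside for transparency. Fold change is reported as the linear-scale
ratio of the extreme age-group means (always ≥ 1, with an up/down label
from the sign of the age correlation); the extreme-group convention is a
documented choice, since several defensible definitions exist.

**Stability (TOST).** A feature is *unchanged* when all three pairwise
age-group contrasts are equivalent: for each pair, the two one-sided
pooled-variance t tests against ±ε reject, and the TOST p (the max of the
two one-sided p-values) is ≤ 0.05. ε is fixed at 0.3 log10 units — about a
2-fold intensity ratio — rather than recomputed per run, because the
reference-SD provenance behind "3×SD" conventions is rarely reproducible; a
Welch variant is available by config. Degenerate zero-variance data yield
p = 0 when |Δ| < ε, 0.5 at the boundary, 1 otherwise (the limits of the
one-sided tests as the variance shrinks).

**Abundance classes.** Per-(feature, age-group) mean log10 intensities are
pooled, and four classes (I = highest) are cut either as equal-width
intervals over [min, max] (default — the dynamic-range reading of
"ranked into classes") or as quartiles (equal-count mode). Boundaries are
computed once and shared by all age groups, so a class shift between
groups is meaningful on a common scale. Boundary ties go to the
higher-abundance class.

**Cross-layer correlation.** Transcript recipe: log2 all probe
intensities, drop the lowest 25% of probes by across-sample median
(rank-based, so exactly ⌊q·n⌋ probes are dropped), drop probes without a
gene id, average remaining probes per gene, rescale the global max to
100%. Protein recipe: per-sample sum intensity divided by the unique
peptide count, log2, percent-of-max. The filter-before-average order is
pinned by a regression test because the alternative order gives different
gene values on multi-probe genes. Matched genes are correlated per donor
(Pearson, across genes) and averaged unweighted over donors.

**miRNA-target networks.** For each target gene (mRNA layer) or protein,
the model is

    minimize (1/2n)·‖y − Xβ‖² + λ·[α·Σ|βⱼ| + ((1−α)/2)·Σβⱼ²]   s.t. βⱼ ≤ 0,

where the columns of X are the standardized expressions of the candidate
miRNAs predicted (by the sequence prior) to target that gene, and y is the
centered log expression. Because the feasible set is separable, cyclic
coordinate descent with each update projected onto (−∞, 0] solves the
problem exactly; every fit is certified in the test suite against the
first-order conditions and an independent box-constrained smooth solver
(with β ≤ 0 the ℓ1 term is linear, so the objective is smooth on the
feasible set). The null threshold λ_max = maxⱼ max(0, −Xⱼᵀy/n)/α accounts
for the sign constraint: positively associated predictors can never enter.
λ is selected per target by 10-fold cross-validation (folds from a seeded
permutation; with n = 15 the folds have 1–2 samples, honoured literally),
on a 100-point log grid spanning 4 decades below λ_max. The selection rule
defaults to the one-standard-error rule with the SE computed from
per-observation squared-error deviations scaled by √(k−1) (the convention
of the reference cross-validation routines): at this sample size the
minimum rule selects a nonzero model on a fifth to a third of pure-noise
targets, which contradicts the intended behaviour of an all-zero model on
null data; the 1-SE rule reduces that to a few percent while keeping
recall of planted effects around 0.8–0.9. `lambda_rule="min"` remains
available. Strictly negative coefficients at the selected λ become edges;
no magnitude threshold is applied. An edge is annotated *anti-correlated*
when its miRNA's age direction opposes an age-associated target's
direction.

**Enrichment.** Two-sided hypergeometric p by the minimum-likelihood
convention (sum of point probabilities ≤ the observed one, with a 1e−9
relative tolerance at ties), exact against full-support enumeration for
all universes up to N = 25 in the test suite. Direction is
enriched/depleted around the expectation n·K/N. Sets are intersected with
the background (the quantified proteome), sets with ≤ 5 members discarded,
exact duplicate membership collapsed; significance is raw p ≤ 0.01 with BH
q reported for every tested set. Significant terms are grouped by connected
components of the Cohen-kappa ≥ 0.5 agreement graph over the background
universe. Ontology-level filters (GO depth, term fusion) require an
ontology graph and are out of scope.

## The synthetic cohort

All randomness flows from one seed through named `SeedSequence` child
streams (cohort, proteome, transcriptome, miRNAome, prior, gene sets), so
outputs are byte-identical under a fixed seed and any layer is
independently reproducible.

* **Design.** Five donors per band, ages uniform integers within the band.
* **Proteome.** 1600 proteins, baselines log10-uniform over 5 decades.
  47% are planted constant (noise SD 0.1 log10); 43/1607 ≈ 2.7% carry
  age-linear log10 trends with |slope| ~ U(0.08, 0.145) per decade and
  random sign (young→old fold changes ≈ 2.1–3.8). The lower slope bound is
  set so that a planted effect is reliably *outside* the ε = 0.3
  equivalence range even for unlucky age draws; smaller printed fold
  changes (down to 1.1) exist in real data but would be genuinely
  equivalent at this design size, making "age-associated" and "unchanged"
  ground truths contradictory. The residual pool gets heterogeneous
  inflated noise (SD 0.15–0.3 log10) and no trend. A five-protein block
  with a −0.9 log10 step in the old group emulates a coordinated
  class III → class IV shift. Unique-peptide counts are geometric
  (min 1, P(1) = 0.25); per-sample detection is Bernoulli with probability
  rising with abundance (0.6–0.995 over the bottom quintile, 0.995 above),
  so the peptide and presence filters exercise real paths.
* **Transcriptome.** Gene baselines are coupled to protein baselines by a
  bivariate Gaussian. The *latent* coupling is set by analytically
  inverting the attenuation that the measurement layers impose on the
  observed per-donor correlation: nuisance variance on both axes
  (peptide-count division; probe offsets/noise; gene noise) attenuates
  linearly, and two range restrictions (abundance-dependent
  quantifiability on the protein axis; the lowest-quartile probe filter on
  the mRNA axis, with expected gene loss computed by numeric integration)
  follow the classical selection formula. At the default target of 0.28
  the realized mean per-donor r is ≈ 0.26–0.33 across seeds; the inversion
  is exact in the noise-free limit. Genes get 1–3 probes (offset SD 0.6,
  probe noise SD 0.2 log2); 5% of probes lack a gene id; 2% of genes have
  no transcript; 1200 low-expressed background genes (log2 ~ N(5, 1))
  emulate the array content outside the proteome, so the lowest-quartile
  filter mostly removes background rather than matched genes.
* **miRNAome.** 120 miRNAs, 12 with age trends of ±0.15 log2/decade.
  Each age miRNA represses 15 planted target genes: the target's log2 mRNA
  value receives −0.4 per SD of the miRNA's realized expression; half of
  that effect propagates to the protein layer (translation buffering).
  Each age miRNA also gets 10 decoy prior-only targets drawn from
  planted-constant genes, so network precision is a meaningful quantity.
* **Gene sets.** One set per planted block (padded to ≥ 6 members), the
  planted age set, a deliberately 5-member set (exercises the size
  filter), and 30 random sets.

**What the generator does not emulate:** peptide-level signals, retention
time, missingness-not-at-random beyond abundance-dependent detection,
batch structure, shared-pathway co-regulation beyond the planted blocks,
and isoform/identifier ambiguity (the gene namespace is a clean 1:1 join).
Passing recovery tests therefore shows the statistics behave as designed
under their own assumptions, not that real data meet those assumptions.

## Numerical choices

Coordinate descent runs in Gram form (p ≤ ~15 predictors), tolerance 1e−9
on the max coefficient change, warm starts along the descending λ grid;
the grid head is pinned to λ_max exactly (a log-space round-trip would
otherwise sit one ulp below the null threshold and emit 1e−17-scale
coefficients). CV error curves break ties toward the larger λ.
Zero-variance predictors are dropped before standardization. Degenerate
inputs (all-equal ANOVA, zero-variance Pearson, empty designs, missing age
groups) return flagged results rather than raising, so a single bad
feature never aborts a run.

## Known limitations

* With ~1000 quantifiable features, small-but-real trends (notably
  buffered repression targets) can satisfy both the joint age calls and
  all-pairwise TOST equivalence; the unchanged ∩ age-associated overlap is
  reported by the pipeline and is small (~2% of quantified features) but
  not empty at the default design size.
* Cross-validated penalty selection at n = 15 retains a residual
  false-selection rate on null targets (~1% of prior targets with the 1-SE
  rule; a handful of edges network-wide). This is a property of the
  procedure, also exhibited by reference implementations, not of this
  solver.
* Fold changes, the abundance-class binning rule, and the probe-filter
  order follow documented conventions where several readings are
  defensible; each is pinned by a regression test.
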