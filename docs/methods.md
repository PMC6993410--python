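# Methods

## The model

The pipeline asks, for a case/control cohort with sample-matched TF
expression, gene expression and DNA-methylation profiles: *which
methylation sites change how a TF regulates a target gene?* Its unit of
inference is the **methylation-mediated transcriptional dysregulation
motif** — a triple (methylation site *m*, TF *t*, gene *g*) in which the
*t*–*g* expression correlation differs between case samples with low and
high methylation at *m*.

The procedure, stage by stage:

1. **Preprocessing.** Per matrix: features that are exactly 0 in every
   sample are dropped; remaining zeros are replaced by the global minimum
   *nonzero* value of the matrix (the literal global minimum would be 0
   and change nothing); values are log2-transformed. Probes mapping to one
   gene symbol are averaged. log2 is applied to methylation as well as
   expression by default; the stratification below is rank-based, so this
   choice cannot affect which motifs are found.
2. **Candidate screens.** A TF→gene catalog pair is retained when the
   Pearson correlation of its expression *over case samples only* exceeds
   0.25 in magnitude (strictly). A site is retained when the classical
   pooled-variance two-sample t test (case vs control) survives
   Benjamini–Hochberg at q < 0.05 (strictly), one global BH family over
   all testable sites. Degenerate rows (zero variance) are reported
   separately, never silently dropped.
3. **Stratified differential correlation.** For each retained site, case
   samples are ranked by methylation (ties broken by sample-ID
   lexicographic order) and split into the bottom and top
   floor(0.4·n_case) samples. For each retained pair, Pearson
   correlations r_low and r_high are computed inside the two strata;
   Δ = r_high − r_low. Combinations with |Δ| > 0.7 (strictly) are
   candidate motifs. With 30 case samples the strata have 12 samples each.
4. **Permutation test.** The null hypothesis is "methylation at *m* does
   not modulate the *t*–*g* correlation", so permutations shuffle the
   assignment between the site's methylation values and the case samples
   while keeping the TF–gene pairing intact, re-derive the strata and
   recompute |Δ|. The add-one estimator
   p = (1 + #{|Δ_perm| ≥ |Δ_obs|}) / (n_perm + 1) is never 0; n_perm
   defaults to 1000. Each motif's permutation stream is seeded by a stable
   SHA-256 hash of (master seed, site, tf, gene), so p-values do not
   depend on iteration order. Permutations that produce a zero-variance
   stratum are redrawn, capped at 10× n_perm draws.
5. **FDR.** BH runs across all candidate motifs in one family; q < 0.05
   (strictly) defines the significant motifs.
6. **Pattern classification.** The low-methylation stratum is the
   baseline: r_low < 0 reads as inhibition, r_low > 0 as activation, and
   r_high shows what methylation does to it — same sign with smaller
   magnitude = *relax*, larger magnitude = *intensify*, opposite sign =
   *reverse* (activation↔inhibition). A motif with |r_low| < τ = 0.25 has
   no callable baseline direction and is reported unclassifiable;
   |r_high| = |r_low| exactly resolves to the relax label. Summaries:
   per-label counts/fractions, shared pairs/sites between every two
   labels, and per-element distinct-label counts.
7. **Network.** One node per distinct site, one per distinct TF–gene
   pair, one edge per significant motif (bipartite, simple). Degrees are
   fit by OLS of log10(count of nodes with degree k) on log10(k) over
   degrees with nonzero counts — the era-typical scale-free check — and
   dense modules come from a from-scratch MCODE (below).
8. **Interpretation.** Enrichment is a one-sided Fisher exact test of the
   motif TF+gene universe against each GMT set within a configurable
   background (default: all features of the expression matrices), BH
   across tested sets, with strict per-library thresholds (0.01 GO-style,
   0.05 KEGG-style). The drug network restricts a drug→gene catalog to
   motif genes and ranks drugs by degree.

## MCODE

Node weight = k × density of the highest k-core of the node's closed
neighborhood (nodes under the degree cutoff, default 2, weigh 0). Modules
grow breadth-first from the highest-weighted unseen node, admitting unseen
neighbors whose weight ≥ seed weight × (1 − 0.2), to a depth of 100.
Modules lacking a 2-core are discarded; the haircut removes degree-1
nodes; module score = density × node count; ranking is by score with
lexicographic tie-breaks, so results are fully deterministic. The fluff
option is accepted but deliberately unimplemented. Density of a simple
graph is 2E/(N(N−1)), 0 for a single node.

A structural consequence worth knowing: in a *bipartite* graph every
closed neighborhood is a star, so node weights reduce to 2/(degree+1) and
seeded expansion only holds together when the dense region is a roughly
balanced biclique (pair side ≥ ~0.8 × site side). On small cohorts the
motif network is sparse and an empty module list is a legitimate outcome;
the dense-module machinery is exercised independently on general graphs
(planted dense blocks), where recovery is reliable.

## Synthetic data generator

The generator emulates the emulated-study design: 30 case + 18 control
samples by default, methylation on the beta [0,1] scale, expression as
2^latent intensities whose log2 restores the exact planted Gaussian
structure.

* A planted motif's site is bimodal in cases (equal-weight Beta(4,16) /
  Beta(16,4) mixture, modes ≈0.2/0.8). Case samples in the lower (upper)
  half of the site's values — median split — draw their (TF, gene) latent
  pair from a bivariate normal with correlation r_low (r_high). The
  analysis's 40% tails are strict subsets of these halves, so the planted
  contrast survives the stricter split.
* A *differential* site's control samples draw from Beta(36,4)
  (mean ≈0.9), a ≈0.4 mean shift against the bimodal case mean of ≈0.5 —
  large against the pooled spread, so planted sites clear the t-test
  screen essentially always.
* Null sites are N(μ, 0.05) noise (μ per site, uniform in [0.2, 0.8]),
  clipped to [0,1], identical in both groups; null expression rows are
  independent noise. Ground truth records every planted motif (with its
  geometric pattern label), the differential sites, and designated null
  pairs/sites for benchmarking.
* **Site groups** let several planted sites share one mixture-component
  assignment, hence (nearly) the same low/high split: every pair planted
  on a group member is then genuinely modulated by every member, creating
  a biclique in the motif network — the generative analogue of a dense
  core module.
* Planted motifs must use pairwise-disjoint TF, gene and site rows: one
  expression row cannot carry two different planted joint distributions.
  This is a generator constraint, not a claim about real data.

What the generator does **not** emulate: genomic coordinates or CpG-island
structure, array-probe chemistry, batch effects, correlated null features,
or realistic expression dynamic range. Tests passing on this generator
show the *procedure* is implemented correctly and calibrated under its own
null; they do not certify performance on real cohorts.

## Statistical properties measured on the benchmarks

* **Calibration.** On a fully null cohort (200 site–pair combinations,
  200 permutations) the permutation p-values are uniform (KS) and the
  BH-retained fraction is ~0.
* **Recovery.** At the benchmark design (50 symmetric reversals
  r_low = +0.8 / r_high = −0.8 among 450 nulls, 30 cases, 1000
  permutations, BH 0.05) sensitivity averages ≈0.99. The *empirical* false
  discovery proportion of the full procedure averages ≈0.2–0.25, not 0.05:
  thresholding |Δ| > 0.7 *before* testing the same statistic by
  permutation makes the candidate family selection-biased (a null
  candidate's p-value is conditionally ~U(0, 0.1)), so BH's nominal
  guarantee does not transfer to the two-stage procedure. Widening the BH
  family to all tested combinations restores FDR control (≈0.03) but costs
  sensitivity (≈0.75–0.85), because a planted motif's own permutation null
  is wide — the permuted data still contains the planted mixture. The
  package implements the two-stage procedure as specified and documents
  this bias rather than silently changing the method; treat the q-values
  as a ranking with an FDR-flavoured scale, not an exact guarantee.
* **Label fidelity.** Classification accuracy is measured on a 300-case
  cohort (strata of 120): at 12-sample strata the sampling sd of a stratum
  correlation is ≈0.3, which would swamp direction calls near the
  boundary — the fidelity bench measures the classifier, not stratum
  noise. Accuracy on detected motifs is ≥95% at magnitude margins ≥0.3 and
  |r_low| ≥ 0.4.
* **Pattern geometry.** An intensify motif needs |r_high| − |r_low| > 0.7
  to become a candidate, which forces |r_low| < 0.3 — intensify patterns
  are intrinsically rare under this detector (the default design plants
  them at |r_low| ≈ 0.27, just above τ), and symmetric reversals have
  case-wide correlation ≈ (r_low + r_high)/2 ≈ 0, so the 0.25 screen
  passes only asymmetric reversals. Both corners are properties of the
  method, mirrored by the dominance of reverse patterns in its outputs.

## Numerical and design choices

* "Student's t test" is the classical pooled-variance test
  (df = n₁+n₂−2); Welch is available behind a flag.
* Thresholds (0.25, 0.7, 0.05, 0.01) are strict inequalities throughout.
* The 40% split uses floor; at n_case = 30 the strata are exactly 12.
* Stratum ties, output orderings, and module rankings all break ties
  lexicographically; every output is byte-stable under reruns with the
  same seed.
* Elementary statistics are delegated to scipy/statsmodels and verified
  against definition-level brute-force oracles to 1e-12 in the test suite.
* Benchmarks generate expression directly on the log2 latent scale (the
  scale the planted correlations are defined on and that preprocessing
  restores); the worked end-to-end chain runs on the intensity scale
  through the real preprocessing step.
* Problem sizes in the worked analysis (14 planted motifs, 60 TFs, 100
  genes, 150 sites) keep a full run in seconds while leaving room for
  decoys and null structure; the benchmarks use the sizes stated above.

## Known limitations

* The empirical-FDR caveat above is the main statistical limitation.
* MCODE behaves conservatively on small bipartite networks (see above).
* The generator cannot plant two motifs sharing a TF or gene row.
* Enrichment replaces rank-combined web-service scores with a plain
  Fisher/BH test; background choice is the user's responsibility.
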