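# Methods

This note documents the models, calibrations and numerical choices behind
the package, and what the synthetic cohorts do and do not emulate.

## The cohort model

A panel of `n_strains` recombinant-inbred-backcross strains (default 49)
contributes `replicates_range` animals per strain and transgene group
(default 2–17, drawn uniformly — only the observed range of a real panel
is specified, not its distribution). All animals are 6-month-old females;
sex-by-age structure is deliberately out of scope.

**Genotypes.** Each strain × chromosome is an independent two-state Markov
chain over markers ordered by position: the first marker is Bernoulli(1/2)
and each subsequent marker switches allele with probability
`recomb_prob` (default 0.1). This is not a meiosis model; it is the
simplest process with geometric LD decay, which is all the downstream
statistics consume. On chromosome 1 a block of 10 markers inside
173,200,610–175,596,722 bp shares one strain-distribution pattern
(pairwise r² = 1 exactly); when `recomb_prob` > 0 the remaining markers of
that chromosome are re-drawn if they land in perfect LD (identical or
complementary) with the block, so the planted block has a well-defined
boundary. Monomorphic columns are resampled i.i.d. — a slight local
violation of the chain in exchange for every marker being testable.

**Phenotypes.** Ntg strain means are Gaussian (mean 50 %, SD 12 % time
freezing; within-strain SD 5 %). The AD strain mean is

    m_s = α + β·u_s + τ·d_s

with u_s the Ntg strain mean, τ = `trait_scale` (5 percentage points per
trait SD) and d_s the standardized deviation

    d_s = c′·x̃_s + b·L_s + ε_s,    L_s = a·x̃_s + η_s,    Var(d_s) = 1,

where x̃ is the standardized genotype at the planted block (oriented so
B/B carries the high-resilience allele), L the module latent, a =
`snp_module_effect` (0.9), b = `module_trait_effect` (0.75), c′ =
`snp_direct_effect` (0). The generator refuses configurations with
c′² + b² + 2abc′ > 1 (no non-negative residual variance exists).

Two calibrations make the dials mean what the analysis measures:

* `h2_strain` (default 0.26) is the **expected ANOVA SS fraction** of the
  trait, not the raw variance-component share. The within-strain variance
  (in trait-SD² units) is solved from
  E[SS_strain]/E[SS_total] = h² at the mean replicate count n̄:
  W = n̄ / (h²(n̄−1)/(1−h²) − 1). Targets below 1/n̄ are unreachable and
  raise. Because a ratio of noisy sums of squares is slightly biased
  downward relative to the ratio of expectations, finite panels recover
  the dial to within about one percentage point (measured: ≈ 70 % vs the
  71 % strain-mean target at 49 strains × 7 replicates).
* `baseline_r2` (default 0.38) is the **expected R² of the observed
  strain-mean regression**. The slope β is solved with the sampling
  variances of both groups' strain means (within-strain variance times
  the mean of 1/n over the replicate distribution) folded into the
  attenuation, so the finite cohort reproduces the dial instead of a
  shrunken value.

Per-animal CFM = strain mean + Gaussian noise, clipped to [0, 100]
(clipping affects < 0.5 % of draws at the defaults and is ignored in the
calibrations).

**Proteome.** Strain-level z-structures: eight module proteins
s_j·(√ρ·L + √(1−ρ)·e) with ρ = `module_rho` = 0.463 (population PC1
fraction (1+7ρ)/8 = 0.53) and one negative member; a ninth trait protein
with the same construction, negative loading, and its gene on chromosome
19 — its block pQTL is therefore trans; `n_null_proteins` (200)
independent proteins of which 20 get strong decoy cis effects (r = 0.8 to
a random marker); 26 transcription-factor tracks, two of which (Nr1d1- and
Dlx3-like) are planted to correlate with the trait at r = 0.55 and 0.39.
Per-animal log2 abundance = protein baseline (N(20, 2²)) + 0.7 × strain
z + N(0, 0.3²) measurement noise. Peptide level: 2–5 peptides per protein
(fixed log2 offsets, N(0, 0.2²) noise), batches of 14 samples + 2 pooled
references assigned round-robin over a strain-ordered list, batch k
shifted by k·`batch_shift` log2 units.

What the generator does **not** emulate: non-Gaussian freezing
distributions, missing-at-random structure tied to abundance, kinship
between strains (strains are exchangeable), shared-funnel pedigree
effects, genotype-specific TF wiring, and amyloid pathology itself.
Passing tests therefore certify the statistical machinery, not its
robustness to those real-data features.

## Analysis chain

* **Normalization**: log2, then per-sample median alignment to the global
  median of sample medians; per-feature batch regression (categorical
  one-hot ≡ subtracting batch means) with the grand mean added back so
  abundances stay interpretable — a constant offset relative to raw
  residuals that cannot change any regression or correlation downstream.
  The correction is exactly idempotent. Peptides are summed to protein
  groups in linear space (intensities are physically additive) and
  re-logged; protein ids claiming identical peptide sets merge into one
  node. Features missing in > 50 % of samples are flagged, not dropped.
* **Resilience**: weights 1/n_s make the individual-animal objective
  separate into a within-strain constant plus the strain-mean SSE, hence
  the exact equivalence with the strain-mean OLS (asserted at run time).
  z-scores use the sample SD (ddof 1). The n ≥ 2 filter applies to the
  heritability ANOVA only.
* **pQTL scan**: vectorized complete-case OLS per marker; markers
  monomorphic within a protein's observed strains are skipped and logged.
  BH FDR spans the full protein × marker matrix by default (per-protein
  universes by flag); q < 0.05. Peak = minimum-p marker per protein, ties
  broken by lowest chromosome then bp. Multiple animals per strain are
  averaged to strain level before scanning. No kinship/mixed-model
  correction — a deliberate non-goal.
* **cis/trans**: distance from the marker to the gene *interval* (not the
  TSS) ≤ 5 Mb on the same chromosome is cis.
* **Moderated t**: per-protein pooled variances s²_g with df d are
  modelled as s₀²·F(d, d₀); d₀ and s₀² come from moment matching on the
  first two moments of the observed s²_g (using the mean df when
  missingness makes df vary). Overly concentrated variances give d₀ = ∞
  (complete shrinkage; with equal variances the moderated t equals the
  ordinary t); the method-of-moments inversion yields d₀ > 4 whenever it
  is finite. `prior_df`/`ordinary` override the estimate.
* **Mediation**: complete-case strains (count reported) rather than
  full-information ML — FIML would import an estimation framework used
  nowhere else in the chain; the cost is a smaller n, which the report
  carries explicitly. PC1 is the only supported mediator (raw module
  proteins are collinear by construction). Bootstrap resamples strains
  within each genotype group (every replicate keeps the marker
  polymorphic), BCa intervals use the bootstrap bias estimate and a
  leave-one-strain-out jackknife acceleration; with zero bias and
  acceleration the interval is exactly the percentile interval. The
  two-sided bootstrap p for the indirect effect is floored at
  1/(n_boot+1). Degenerate bootstrap distributions fall back to the
  percentile interval with a warning. Measured coverage of the 95%
  interval over 500 synthetic 60-strain panels: 0.94 (BCa is second-order
  accurate; mild small-sample undercoverage is expected).
* **Motif intersection**: BED sites are 0-based half-open; markers are
  1-based bp, so a SNP at bp p hits [start, end) iff start ≤ p−1 < end.
  The tree-backed search is verified against exhaustive enumeration. TF
  correlations report raw p (BH q rides along as an extra column).

## Pipeline and seeds

`resilience-pqtl run` executes simulate → normalize → resilience → scan →
associate → mediate → motif. The resilience locus is found as the modal
peak marker among trait-associated proteins, expanded to its r² = 1 block;
the module is the trait-associated proteins whose peak lies in the block
*and* whose gene is local (cis) — which is exactly what separates the
eight locally encoded members from the trans-regulated ninth. One integer
seed fans out to per-stage substreams via
`numpy.random.SeedSequence(seed).spawn` in a fixed stage order; identical
config + seed gives a byte-identical report.

## Problem sizes

Defaults were chosen so that a full cohort (49 strains, ~1,000 markers,
~235 proteins) simulates and analyses in a few seconds: averages over
100–200 seeds for the calibration checks and the 500-panel bootstrap
coverage study all run on one CPU in well under the time of a coffee.
Qualitative-recovery tests (all nine trait proteins, full-mediation
pattern) use deliberately large planted effects (a = 0.95, b = 0.85,
ρ = 0.7, 17 replicates, h² = 0.5) — they certify that strong planted
signals are found with the right signs and ranks, not that study-scale
effects are always detectable in a single cohort; at the default effect
sizes a single 49-strain panel frequently lacks that power, which is the
realistic situation.

## Known limitations

Exchangeable strains (no kinship) make the pQTL p-values optimistic
relative to a mixed-model scan on a real panel. The moderated-t prior is
moment-matched rather than profile-likelihood fitted, which is slightly
less efficient for very small protein sets. The mediation model is a
single-mediator linear chain; multi-mediator structural models and latent
mediators are out of scope. TF-binding-site fixtures encode a consistent
synthetic geometry, not asserted genomic coordinates.
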