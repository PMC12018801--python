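# Methods

`dynaqtl` re-creates, as a tested pipeline, the analysis chain used to map
genetic variation in dynamic photosynthesis — non-photochemical quenching
(NPQ) kinetics and PSII operating efficiency — in a multiparent (MAGIC)
maize population, and provides a synthetic-data generator with recorded
ground truth so every stage can be validated without any external data.

## Fluorescence traits

A sample's record is the dark-adapted pair (Fo, Fm) followed by saturating
pulses under 1500 µmol m⁻² s⁻¹ actinic light at
20–600 s (12 pulses) and after light-off at 20–540 s (7 pulses), each pulse
yielding (F′, Fm′).  Derived series: Fv/Fm = (Fm−Fo)/Fm,
NPQ = (Fm−Fm′)/Fm′, ΦPSII = (Fm′−F′)/Fm′.  Samples with Fv/Fm < 0.70 are
removed (something other than genetics is limiting them); negative NPQ
(Fm′ > Fm) is retained but flagged, never clipped, because clipping would
bias the kinetic fits.

Kinetic models, fit by bounded trust-region least squares (start values
a₀ = series range, b₀ = ln2/60 s⁻¹, c₀ = series minimum; up to five
jittered restarts are attempted only if the first solve fails):

* NPQ induction (light): `NPQ(t) = a (1 − e^{−bt})`, with the definitional
  origin NPQ(0) = 0 included as a data point.
* NPQ relaxation (dark, clock re-zeroed at light-off):
  `NPQ(t) = a e^{−bt} + c`, b, c ≥ 0; c absorbs NPQ that does not relax.
* ΦPSII recovery (dark): `ΦPSII(t) = a (1 − e^{−bt}) + c`.  The last
  light-phase ΦPSII value is included as the t = 0 anchor: c is the
  light-off intercept by construction, and without the anchor the rate
  constant is weakly identified from seven dark pulses (its median error
  at 1% trace noise roughly halves with the anchor).

The 0–80 s induction slope is ordinary least squares of NPQ on time over
pulses with t ≤ 80 s plus the origin.  Summary traits are the NPQ maximum
over all pulses and the final dark-phase NPQ and ΦPSII.

The photoprotection index PI combines final ΦPSII, final NPQ and Fv/Fm.
The printed formula's grouping is typographically ambiguous, so both
defensible parenthesizations are implemented behind a `parse` switch and
the parse id is carried in the output.  With q = 1 − Fv/Fm and
s = 1/(1+NPQf), the default (`nested-ratio`) is
`PI = ΦPSIIf / ( [1 − q(Fv/Fm + q s)] / s )`, chosen because PI → ΦPSIIf in
the ideal limit Fv/Fm → 1, NPQf → 0; the alternative divides only the inner
bracket by s.  Both parses agree whenever NPQf = 0.

OJIP half-rise time t½ is the first time the fast fluorescence transient
reaches Fo + (Fj−Fo)/2, linearly interpolated between samples; 1/t½ is the
relative effective PSII antenna size.

## Trial model, BLUPs, heritability

Phenotypes follow a fully random-effects model with independent intercepts
for genotype, year, year:genotype, year:rep, year:rep:block, year:date and
year:silking-interval, plus a residual; date and silking interval enter as
categorical intercepts because no functional form is implied.  REML
estimates are obtained by maximizing the profiled restricted likelihood
over the variance ratios γ_k = σ²_k/σ²_e with σ²_e profiled out in closed
form.  The optimizer is L-BFGS-B on log γ with an analytic gradient: for
V₀ = I + Σ γ_k Z_k Z_kᵀ each per-term derivative needs tr(V₀⁻¹Z_kZ_kᵀ) —
one triangular solve of the stacked indicator matrix against the Cholesky
factor — and two quadratic forms that reduce to group sums.  Components
are bounded at zero (estimates below 10⁻⁵γ are snapped to the boundary);
aliased terms (identical record partitions) are rejected by name.  On
balanced single-factor designs the estimates agree with the closed-form
ANOVA estimators to machine precision, which the tests assert.

Genotype BLUPs are posterior means γ_g Z_gᵀV₀⁻¹(y − μ̂); predicted means
are μ̂ + BLUP and form the phenotype used for mapping.  Broad-sense
heritability defaults to the entry-mean basis,
H² = σ²_g / (σ²_g + σ²_g×y/n_y + σ²_e/(n_y n_r)), with the plot basis
(no divisors) available — the published analysis prints only "genotypic
over phenotypic variance", so the divisor convention is an explicit,
documented choice.

## Founder-haplotype HMM

RILs are treated as fully inbred single-haplotype mosaics; observed
heterozygous calls are treated as missing.  Hidden states are the founders;
transitions over a map interval of d Morgans follow the exchangeable model
with stay probability `e^{−λd} + (1−e^{−λd})/K` (λ default 2.0 per Morgan);
emissions are 1−ε for an allele match, ε for a mismatch (ε default 0.002,
a typical targeted-genotyping error scale) and 1 for missing.  Posteriors
come from forward-backward with per-position scaling — algebraically the
log-stabilized dynamic program — and are exact against exhaustive path
enumeration on small instances (asserted to 10⁻¹⁰).  The Viterbi path
(ties to the lowest founder index) supplies the mosaic BED output.  Genetic
positions missing from the anchored map are interpolated proportionally to
physical distance between flanking anchors, with terminal-rate
extrapolation outside them.

## Genome scan

Kinship is the founder-probability inner product over all markers *not* on
the focal chromosome (LOCO), scaled to mean diagonal 1.  Per chromosome
the null model y = μ + g + e with cov(g) ∝ K is solved on the kinship
eigenbasis; the polygenic share h² is estimated once by 1-D profiled REML
and fixed for the scan (the standard fast approximation).  Each marker is
scored by GLS regression of the whitened phenotype on the K−1 df
founder-probability design, `LOD = (n/2) log₁₀(RSS₀/RSS₁)`; with kinship
disabled this is exactly Haley–Knott regression, which the tests assert to
10⁻⁸.  Marker regressions are batched through normal equations with a
least-squares fallback for rank-deficient designs (a founder locally
absent).

Significance uses trait-specific permutations of the phenotype vector
(default 999, threshold the 95th percentile of per-permutation genome-wide
maxima); the null h² is re-estimated for every permutation.  One peak per
chromosome (ties to the smaller position).  The credible interval treats
10^LOD as an unnormalized posterior over marker positions, accumulates
mass outward from the peak adding the higher-posterior neighbour first
(ties toward lower bp) until 95%, then expands both endpoints to the
flanking marker positions.  Founder effects over the interval are
zero-sum-centred GLS coefficients on the full K probability columns;
founders never locally present above probability 0.01 are flagged
unreliable, and CML91 — a two-way-hybrid contributor carrying only a small
genome share — is excluded from downstream clustering.

## Candidate genes

Founder coefficient profiles across the interval (z-scaled per marker) are
clustered by k-means over k = 2 … K−1 with seeded restarts; k is chosen by
average silhouette, and a best silhouette below 0.5 declares "no
structure" and skips the expression test.  The silhouette criterion is a
documented stand-in — the clustering routine referenced by the original
analysis searches k without naming its criterion.  The divergent pair is
the clusters with the highest and lowest mean coefficient; founders in
intermediate clusters are dropped from the test factor.

Genes with models inside the credible interval (1-based inclusive
intersection) are tested only when the interval spans < 30 Mbp.  Counts
from founder replicates are compared between the divergent groups with a
negative-binomial log-link GLM (log library-size offset).  The dispersion
is estimated per gene from the Pearson-χ² moment equation and shared by
the null and group models, and the deviance difference is assessed with a
quasi-likelihood F test rather than a plain χ² LRT: with three replicates
per founder the LRT's far tail is anticonservative (about 3× at p = 10⁻³
in simulation), while the F version is calibrated — this matters because
Benjamini–Hochberg passes at FDR 0.1 across ~100 genes are decided in that
tail.  Candidates are BH-corrected within the interval and pass at
q ≤ 0.1.

## Local GWAS

Founder whole-genome SNPs (homozygous, biallelic, polymorphic) are
collapsed onto RIL haplotype posteriors: posteriors are interpolated
linearly in physical position between flanking markers and the expected
dosage is Σ_f P(f)·allele_f ∈ [0,1].  SNPs in the credible interval
extended by 250 kbp on each side are tested as 1-df covariates in the same
whitened model (LOCO kinship, null h²), with an F-test p-value and a
Bonferroni threshold α/m at α = 0.05 over the m SNPs tested; the top SNP
is reported only if it passes, along with gene models overlapping its
position.  The genotype QC filter drops loci and then individuals whose
missingness reaches 20% (strict "lower than" retention), in that order.

## Synthetic data

The generator emulates the study population and measurement design:

* **Founders** — 8 inbred founders (optionally CML91 as a low-share ninth,
  default 5%, reflecting its entry as a two-way hybrid); biallelic marker
  alleles with per-marker MAF drawn from feasible carrier counts in a
  configurable range (default 0.2–0.5).
* **RIL mosaics** — each chromosome is an exchangeable Markov walk:
  breakpoints arrive as a Poisson process at λ per Morgan (default 2.0, a
  rough effective density for a funnel plus selfing; the true pedigree's
  density is not published, so λ is a free parameter, not a claim) and
  every event switches to a uniformly chosen different founder, so the
  recorded breakpoint count is exactly Poisson(λ·L).  The Haldane map
  convention is used wherever cM↔recombination conversion is needed.
  Observed alleles are copied from the underlying founder, flipped with
  the genotyping-error probability and masked at the missing rate.
* **Planted QTL** — founder-specific additive effects (centred to zero
  mean), rescaled so the locus explains the requested share of total
  phenotypic variance on the entry-mean scale.
* **Phenotypes** — records as overall mean + genotype (planted value +
  polygenic draw) + draws for every trial-model term at stated variances,
  over a 2-year × 2-rep × 40-block design with categorical measurement
  dates and silking classes.
* **Traces** — NPQ and ΦPSII evaluated from the kinetic models at the
  protocol pulse times and converted by Fm′ = Fm/(1+NPQ),
  F′ = Fm′(1−ΦPSII), with multiplicative Gaussian noise on every
  fluorescence value.  Light-phase ΦPSII, which the kinetic models do not
  cover, declines exponentially to a steady state (~0.25 at 1500 µmol m⁻²
  s⁻¹) — a construction device only; trait derivation inverts the
  Fm′/F′ encoding exactly regardless.  Cohorts plant ~2% of samples with
  degraded Fv/Fm to exercise the quality filter.
* **Expression** — negative-binomial counts (gamma-Poisson, size
  parameter default 10) for founder replicates (default 3); non-causal
  genes share a gene-specific mean across founders; the causal gene's
  log-mean is baseline + slope × founder effect.
* **Founder SNPs** — random polymorphic biallelic patterns across
  founders.  When a causal SNP is planted, background patterns identical
  to the causal pattern (or its complement) are resampled: a duplicated
  pattern in tight linkage would be a second, indistinguishable causal
  SNP, and the recovery study is defined as one causal SNP among distinct
  background SNPs.

What the generator does **not** emulate: pedigree-exact funnel transition
probabilities, segregation distortion or selection, linkage-disequilibrium
decay within founder haplotypes, read-level data, spatial field trends
beyond the block effect, or expression correlation structure between
genes.  Passing recovery tests therefore demonstrate correctness of the
algorithms under the stated generative assumptions, not performance on
real field or sequencing data.

## Problem sizes and numerical choices

Simulation studies in the test suite and the acceptance script use scales
chosen to make Monte-Carlo error small relative to the asserted margins:
200–300 RILs, 2–3 chromosomes of 100–500 markers (~0.67 cM/Mbp, a
maize-like density), 200 permutations per replicate in calibration loops
(the pipeline default remains 999), 50–200 replicates per recovery or
calibration estimate in tests and 20–60 in the faster acceptance script.
Posterior normalization is exact to 10⁻⁹; LOD values are clipped at zero
(the marker model nests the null, so negative values can only be float
noise); the credible-interval posterior is normalized after subtracting
the peak LOD to avoid overflow; REML tolerances are ftol 10⁻¹³ / gtol 10⁻⁹
with a second start used only if the first fails.

## Known limitations

* The exchangeable transition model is shared between the simulator and
  the HMM; equivalence with a pedigree-exact MAGIC HMM is not claimed.
* The quasi-likelihood F test is a calibrated variant of, not identical
  to, a plain NB likelihood-ratio test.
* Year-specific BLUP models assume the single-year table still identifies
  the genotype term; unbalanced missingness is handled by REML without
  imputation.
* The "average peak position" style of merging peaks across timepoints is
  out of scope; one peak per chromosome per trait is reported.
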