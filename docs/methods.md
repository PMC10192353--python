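# Methods

## Breeding and genotype model

A pedigree descends from one G1 male heterozygous at every induced mutation
site. The implemented topology is G1 × wild-type → G2 daughters, each
backcrossed to the G1 sire. Consequences used throughout:

- a G2 dam is HET at a site with probability 1/2 and can never be VAR;
- a G3 pup receives a variant allele from the sire with probability 1/2 at
  every site, and from its dam with probability 1/2 only where she is HET;
- marginal G3 genotype probabilities per site are REF 3/8, HET 1/2,
  VAR 1/8; conditional on a HET dam the REF:HET:VAR ratio is 1:2:1.

Sites segregate independently (no recombination map) and are autosomal
only; X-linkage would break the three-state genotype model and is out of
scope. The default founder set size is 60 sites, read as the G1
founder's heterozygous mutation count; a G3 mouse then carries (HET or
VAR) a random ~5/8 subset of it. Default pedigree shape: 5 G2 dams × 8
pups ≈ 40 G3 mice, a typical screened-pedigree size; both knobs are free
parameters. Positions are drawn uniformly over the 19 mouse autosomes with
chromosome choice proportional to physical length; the four
predicted-effect classes default to (0.10, 0.25, 0.25, 0.40) for
(probably_null, probably_damaging, possibly_damaging, probably_benign),
reflecting that most ENU point mutations are missense of uncertain effect.

## Spot-count model

Per eye, expected spots are λ = baseline + g·effect + age_slope·age, with
g the susceptibility weight of the genotype at the causal site (recessive
0/0/1, additive 0/0.5/1, dominant 0/1/1). Counts are negative binomial
with mean λ and shape θ (variance λ + λ²/θ), split over the four quadrants
by an equal-probability multinomial; the two eyes are independent given
genotype. Defaults: baseline 1 spot/eye (healthy retinas are nearly
clear), effect 40 spots/eye (a severe, "reservoir-like" recessive
phenotype in which homozygotes score 7–8 while others score 0–2),
age_slope 0, θ = 10 (moderate overdispersion — biological counts are
rarely Poisson). G3 exam ages are uniform on 4–6 months, the screening
window. The generator emulates genotype-driven spot accumulation only: it
has no grader noise, no inter-eye correlation, no spatial clustering of
spots and no secondary phenotypes, so passing tests demonstrate the
mapping machinery under a clean generative model, not robustness to those
features of real images.

## Scoring scale

Per eye: 0 spots → 0; 1–10 spots → 1; above 10 spots the grade is driven by
quadrant coverage, operationalized as the number of quadrants holding at
least `quadrant_involvement_threshold` spots (default 3): ≤1 involved
quadrant → 2, two–three → 3, four → 4. The two eye grades sum to the 0–8
per-mouse score (nine achievable values). The >10-total rule plus the
involvement threshold is one consistent reading of "equivalent of one
fundus quadrant" — human graders judge coverage by eye, not by count — and
the threshold is deliberately exposed as a parameter. The scale is monotone
in every quadrant count (property-tested).

## Linkage scan

Continuous analysis: OLS of the 0–8 score on the encoded genotype
(recessive 0/0/1, semidominant 0/1/2, dominant 0/1/1), two-sided slope
t test with n−2 df. Semidominant 0/1/2 is equivalent to 0/0.5/1 up to
slope rescaling; p-values are identical. A zero-variance encoding or
phenotype is reported as degenerate (p unset), never silently set to 1;
degenerate fits are excluded from the per-site best-p minimization, so a
site with no VAR mice is still tested under dominant/semidominant.
Perfect-separation fits would give p = 0; p is floored at 1e-300 so
−log10 p stays finite.

Dichotomized analysis: affected = score ≥ cut (default 6); each encoding is
collapsed to susceptible (> 0) vs not and the 2×2 table of affected ×
susceptible is tested with the two-sided exact hypergeometric (Fisher)
test — a concrete choice for "binomial calculations" on ordinal traits.

Candidate criteria: (1) best p below α/(n_sites × n_models) with α = 0.05 —
counting models in the Bonferroni divisor is the conservative reading and
is configurable; (2) the lead peak exceeds the highest peak at any other
gene by ≥ 3 logs (+∞ margin for a single-gene scan, so the rule passes
vacuously). Sites of the same gene do not defeat each other's margin. At
most one candidate is called per scan.

## Power driver

`power_study` simulates replicate pedigrees end to end. A master seed fans
out per replicate through `SeedSequence([master, rep])`, so any replicate
is individually reproducible. With a causal site, the breeding is redrawn
until the site carries at least `min_var_carriers` (default 2) VAR G3 mice
— an informative pedigree in this design needs ≥ 2 homozygotes, and
unconditioned draws would fold a ~3% "no homozygotes bred" event into the
power estimate, conflating breeding luck with detection. Power is the
fraction of replicates in which the causal site itself is called
candidate; the family-wise false-candidate rate (null runs) is the
fraction with any candidate. `per_model_power` attributes each detection
to the model achieving the winning p-value.

### Small-sample behaviour of the null p-values

With ~40 mice, a discrete skewed 0–8 response and only ~5 expected VAR
carriers per site, the normal-theory t p-values of the *recessive*
encoding deviate measurably from uniform under the null (the regression
effectively compares a mean of ~5 observations against ~35 under a
non-normal response). The balanced semidominant encoding shows no such
deviation at 10,000 draws, and the family-wise false-candidate rate stays
far below 0.05 in all encodings because the 3-log margin rule is much
stricter than the threshold alone. Uniformity is therefore asserted on the
balanced encoding; the recessive deviation is a known small-sample
property of the design, not of the implementation.

Similarly, at n = 8 the normal-theory slope p and the exact permutation p
of the same data differ by a systematic O(1/n) finite-sample gap
(~0.02–0.04), which no number of Monte-Carlo permutations removes; the
test suite pins their agreement at a finite-sample band (|Δp| ≤ 0.06)
rather than at Monte-Carlo error.

## Characterization statistics

- IQR outliers: fences Q1 − 1.5·IQR and Q3 + 1.5·IQR, strict exclusion
  (only values strictly outside are removed); quartiles by linear
  interpolation between order statistics (the common type-7 convention),
  with Tukey hinges as an option; below n = 4 nothing is excluded and a
  notice is issued. Group comparisons report p both with all values and
  after per-group exclusion.
- Two-group comparison: pooled-variance two-tailed Student t
  (df = n₁ + n₂ − 2); Welch available but not default.
- Trend: simple OLS with R², F = R²/(1−R²)·(n−2), p from F(1, n−2); a
  constant response returns R² = 0, F = 0, p = 1.
- Percent change: 100·(alt − ref)/ref, negative = decrease; integer
  rounding is half-away-from-zero (so 14.32% → 14).
- Saturation: distinct genes with ≥ 1 probable-null/probable-damaging
  mutation and ≥ 2 homozygous mice screened, over an explicit gene-universe
  parameter (default 20,000 protein-coding genes — the true denominator of
  a screen's published saturation figure depends on its chosen universe).
- Lipid ratios: TAG/(TAG+DAG) and CE/(Chl+CE) are bounded in [0,1];
  TAG/DAG is reported as NaN with a notice when DAG = 0.

## Problem sizes used in the test suite

Simulation-based checks use 200 replicate pedigrees for the type-I and
parameter-recovery runs, 500 replicates per arm for the
continuous-vs-dichotomized sensitivity comparison, 10,000 G3 mice for the
Mendelian segregation checks, and 100,000 permutations (n = 8) for the
resampling oracle — sizes at which the binomial/KS tolerances quoted in
the tests are meaningful.

## Known limitations

No recombination or linkage between sites; no X chromosome; no missing
genotype handling (the design pre-genotypes every mouse); no grader-noise
or inter-grader agreement modelling; no multi-pedigree meta-analysis or
kinship correction; the saturation metric depends on an externally chosen
gene universe.
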