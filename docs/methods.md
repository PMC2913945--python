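# Methods

`pedlink` implements a single-position linkage-analysis pipeline for a
quantitative social-trait score (SRS-style raw totals) measured across
extended, multiplex pedigrees, together with a synthetic-data generator
that reproduces the statistical structure the analysis assumes. This
note records the models, the parameter choices that matter, and the
design decisions taken where the design was genuinely open.

## Phenotype model

Raw scores enter the analysis two ways.

*Qualitative*: published raw-score cutoffs partition scores into
`unaffected` [0, 54), `spectrum` [54, 87), and `affected` [87, ∞);
missing scores are `unknown`. The lower cutoff is inclusive so that the
three intervals partition the range ("below 54" / "87 or above" fixes
both boundary conventions). Scores produced by a rater who themselves
has an ASD are discarded entirely; scores from raters flagged as poor
reporters are excluded from quantitative use only, since under-reporting
is not expected to move a score across a category boundary.

*Quantitative*: the trait is the residual of `sqrt(raw)` after ordinary
least squares on age (years) and sex (0 = female, 1 = male, so the male
coefficient is positive when males score higher). A single regression is
fitted over all included individuals; child and adult instrument
versions are pooled on the raw scale with the version kept as metadata.
Spouse resemblance is summarised as the Pearson correlation of the
adjusted scores with a t-distribution p-value (n − 2 df).

## Marker quality control

Allele frequencies are counted over *all* genotyped individuals
(founders and non-founders alike), matching how the analysis engine
consumes them. QC stages run in the order: failed/monomorphic markers →
sliding-window LD pruning → MAF filter (markers with minor-allele
frequency strictly below 0.10 removed; exactly 0.10 kept) →
Hardy-Weinberg exact test. The HW test is the standard exact
conditional test (heterozygote-count enumeration at fixed allele
counts); it is computed on founders only by default because non-founders
violate the sampling assumptions, and the significance threshold
defaults to 1e-3 (a common linkage-QC choice; configurable — no
canonical value exists).

LD pruning uses the variance-inflation-factor rule: within a window of
50 markers, the marker whose VIF = 1/(1 − R²) against the remaining
window markers is largest is removed, repeatedly, until all VIFs fall
below 1.5 (equivalently multiple R² < 1/3); the window then advances by
5 markers. Ties remove the marker later in map order, making pruning
deterministic; window regressions use complete cases and allele-dosage
coding 0/1/2.

## Parametric linkage engine

The engine computes the exact probability of one marker's genotypes and
the phenotypes under a two-locus disease–marker model indexed by the
recombination fraction θ. An individual's latent state is the unordered
pair of two-locus haplotypes (disease allele × marker allele): 4
haplotypes, 10 diplotypes. Unordered diplotypes are sufficient because
the gamete distribution depends only on the haplotype multiset. Founder
states take Hardy-Weinberg × linkage-equilibrium priors; each meiosis
transmits a parental haplotype intact with probability (1 − θ)/2 each
or a recombinant with probability θ/2 each; phenotypes contribute
penetrance weights over the 0/1/2 risk-allele count.

Likelihoods are evaluated by sum-product variable elimination on the
pedigree's moralised transmission graph with greedy min-fill ordering —
the generalisation of classic nuclear-family peeling — which is exact on
loop-free pedigrees and yields three-variable cliques there. The
implementation batches families with identical transmission structure
into one vectorised elimination (this is what makes 2 × 10⁶ family
likelihoods in the calibration study feasible), with per-family
rescaling at every elimination step to prevent underflow. Looped
pedigrees (consanguinity) are rejected at load; loop-breaking is out of
scope because the target pedigrees have very low inbreeding.

The LOD score is log₁₀ L(θ) − log₁₀ L(1/2), evaluated on the grid
{0, 0.01, 0.05, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5}. Obligate recombinants
drive L(0) to zero; per-family LODs are floored at −99 to keep pooled
sums finite. The heterogeneity LOD maximises the Smith admixture
log-likelihood Σᵢ log₁₀[α·10^{lodᵢ(θ)} + (1 − α)] over θ and over α on a
0.01-step grid (estimates are conventionally reported to two decimals);
α = 0 is in the grid, so HLOD ≥ 0. Scans are per-marker
("single-position"); multipoint smoothing between markers is
deliberately out of scope — exactness and testability were preferred
over the MCMC multipoint machinery the original software family uses,
and the reported statistics (LOD, HLOD, NPL p) are the contract, not
the sampler.

### Disease models

Two qualitative models with two liability classes each:

| model     | allele freq | spectrum (g = 0,1,2) | affected (g = 0,1,2) |
|-----------|------------:|----------------------|----------------------|
| recessive | 0.05        | 0.01, 0.01, 0.5      | 0.0014, 0.0014, 0.8  |
| dominant  | 0.0025      | 0.01, 0.5, 0.5       | 0.0014, 0.8, 0.8     |

Penetrance vectors are relative weights — only ratios matter in a
likelihood ratio — and the engine is invariant to rescaling them (tested
end to end). No penetrance row is published for the unaffected
category; the default uses 1 − f_spectrum[g] ("not even spectrum" is the
complement of the broader threshold), with an option to treat
unaffected individuals as unknown instead. This choice is the largest
single modelling judgement in the qualitative analysis and is flagged
here deliberately.

The quantitative model assigns genotypes normal trait distributions
with means (−1.552, 1.184, 2.558) and SDs (2.238, 1.581, 1.356) on the
adjusted sqrt scale. For speed the density is discretized into 40
equal-width classes spanning mean₀ − 3·sd₀ = −8.266 to mean₂ + 3·sd₂ =
6.626 (width 0.3723); an individual's penetrance vector is the three
densities at the midpoint of the class containing their trait value.
Values outside the range clamp to the end classes (regression residuals
can exceed ±3 SD); class membership uses half-open intervals with the
last class closed. The quantitative likelihood needs a disease-allele
frequency for the genotype prior; none is published for this model, so
the recessive value 0.05 is the default, overridable in config.

### Nonparametric statistic

The NPL analog enumerates inheritance vectors (2 bits per non-founder,
default cap 18 bits; larger families are skipped with a count) and
computes the exact posterior of the vector given the marker data. The
per-family score S is the expected proportion of alleles shared
identical-by-descent over all affected pairs; it is standardised by the
mean and SD of S under the uniform (null) inheritance distribution —
the conservative convention, since the null SD of the *posterior mean*
is smaller than the null SD of S. Families combine with equal weights,
Z = Σ Zᵢ/√F, and the one-sided p comes from the normal tail. The
original software's internal NPL scoring function is not published;
this statistic is a documented analog and no numerical agreement with
the original reports is claimed. For the quantitative NPL analog,
individuals above the 0.75 quantile of the adjusted trait form the
"affected" set.

### p-values and thresholds

LOD and p interconvert through the one-sided 50:50 mixture chi-square:
p = 0.5·Pr[χ²₁ ≥ 2 ln(10)·LOD], so LOD 1.88 ↔ p ≈ 0.0016 (the
conventional suggestive benchmark rounds this to 0.0017) and LOD 3.30 ↔
p ≈ 4.8e-5. These thresholds drive peak calling: local maxima above
the suggestive threshold are merged when no intervening position drops
more than 1 LOD below the peak, and the 1-LOD support interval defines
the reported extent (a standard convention; no explicit rule is
published for the reported bp ranges). Testing five models inflates
the genome-wide error rate; under an independence assumption the
thresholds shift by log₁₀(5) ≈ 0.7 LOD units, reported alongside the
raw thresholds, which remain the default for peak calling.

## Synthetic data generator

The generator emulates: three pedigree size classes (large 6–9
generations, moderate 4–5, small 2–3; default counts 19/6/39), grown
top-down with a guaranteed "spine" lineage reaching the target depth,
sibships of 1 + Poisson(1.2) and a 0.2 branch probability (calibrated
so large families average roughly 15–25 members, inside the reported
5–50 range); gene dropping with founder alleles i.i.d. from the allele
frequencies and meioses following a Haldane Markov walk along the locus
order; a trait locus that segregates with the markers in a fraction
`alpha_sim` of families and independently in the rest; and two
phenotype mechanisms matching the two analysis families.

Under a quantitative spec the latent adjusted trait is drawn from the
genotype's normal distribution with a couple-shared environmental
component scaled to a spouse correlation of 0.33, then back-transformed:
sqrt-scale s = 10.0 + (−0.074)·age + 1.6·male + x, raw = max(s, 0)².
The intercept 10.0 was chosen so that typical zero-risk adults land in
the unaffected band while high-risk genotypes reach the affected band;
the floor at zero truncates a small fraction of elderly low-trait
records. Ages are uniform on 3–80 years. Because the trait mixes three
genotype distributions, the realised spouse correlation of the *trait*
is mildly attenuated below the environmental target (≈0.29 at the
default allele frequency); the recovery tests account for this.

The qualitative penetrance triples are relative weights, not a
probability distribution (0.5 + 0.8 > 1 at g = 2), so qualitative specs
draw categories from the coherent factorisation P(affected | g) =
f_affected[g], P(spectrum | g) = f_spectrum[g]·(1 − f_affected[g]),
remainder unaffected, which preserves the weight ratios that drive the
likelihood. Raw scores are then drawn uniformly inside the category's
band purely as synthetic placeholders.

Ascertainment (≥ 2 affected members, mirroring the multiplex sampling
rule) is on by default. For general pedigrees it is implemented by
re-drawing phenotypes given the dropped genotypes, which conditions on
the genotypes rather than re-drawing them jointly — adequate for
quantitative specs where affection is common. For nuclear-family study
designs, where rejection sampling is hopeless at a disease allele
frequency of 0.05, the generator provides an *exact*
ascertainment-conditioned sampler: parent genotype pairs are drawn from
their analytic posterior (Hardy-Weinberg prior × probability of ≥ 2
affected), the affected configuration from its exact conditional
distribution (members are independent given the parents), offspring
genotypes given their own affected status, and finally the
spectrum/unaffected split. The sampler is validated against rejection
sampling at a boosted allele frequency in the test suite. Marker
genotypes are then dropped conditionally on the transmitted disease
alleles (linked families) or independently (unlinked).

What the generator does *not* emulate: linkage disequilibrium between
markers (they are simulated in equilibrium, the state the analysis
assumes after pruning), genotyping-error models, residual shared-family
environmental trait correlation beyond couples, and assortative mating
at the genotype level. Passing recovery tests therefore demonstrate the
statistical machinery, not robustness to those real-data features.

## Calibration and recovery studies

*Type-I error*: 20,000 replicates of 100 ascertained nuclear families
(sibship 3, all members genotyped, recessive analysis model matching the
generating model family) with a single unlinked biallelic marker of MAF
0.3. The fraction of replicates whose pooled LOD, maximised over the θ
grid, reaches 1.88 is compared with the asymptotic
0.5·Pr[χ²₁ ≥ 2 ln(10)·1.88] ≈ 0.00163 by a binomial test at the 1%
level. Sibship 3 and full genotyping were fixed at design time as the
smallest informative multiplex configuration; the observed rate sits
slightly below the asymptotic value, consistent with the known
finite-sample conservatism of grid-maximised LODs on discrete marker
data.

*Locus recovery*: 60 ascertained nuclear families (sibship 2–4) all
linked (`alpha_sim` = 1), six markers 5 cM apart with the trait locus at
the third, plus four markers on an unlinked chromosome; 50 seeds. The
highest HLOD is required at or adjacent to the trait-locus marker in at
least 90% of seeds, with the mean admixture estimate at the trait
marker ≥ 0.8.

*Alpha recovery*: with half the families linked, the admixture estimate
at the trait marker centres near 0.5 (checked with a wide interval over
several seeds — α̂ on a 0.01 grid at 80 families is noisy by nature).

Problem sizes throughout (family counts, replicate counts, marker
counts) were chosen as the smallest designs that make the statistical
claims sharp; all simulations are seeded and reproducible.

## Known limitations

- Single-position scans only; between-marker information is unused, so
  power is lower than a multipoint analysis on sparse maps.
- The unaffected-category penetrance is a modelling choice (see above);
  results for phenotype configurations rich in unaffected individuals
  depend on it.
- The NPL analog's family combination uses equal weights; no claim of
  optimality, and large families are skipped beyond the bit cap rather
  than approximated.
- Looped pedigrees are rejected rather than broken.
- The exact ascertainment sampler covers nuclear families only; general
  pedigrees fall back to phenotype-only rejection.
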