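# Methods

## Model

Crossovers on a chromosome of genetic length L Morgans are modeled as
the superposition of two independent stationary point processes.

**Interference pathway.** Latent chiasmata follow a gamma renewal
process with shape ν > 0 and rate 2qν, q = 1 − p, so chiasma gaps have
mean 1/(2q). Each chiasma appears on the transmitted chromatid
independently with probability 1/2 (four-strand thinning). The observed
gap between adjacent interference-pathway crossovers therefore skips a
Geometric(1/2) number of chiasma gaps:

    f*(y) = Σ_{k=1..∞} (1/2)^k · Gamma(y; shape kν, rate 2qν),

with mean 1/q. The distance from the chromosome start (an arbitrary
point of the stationary process) to the first crossover has the
forward-recurrence density g*(y) = q·(1 − F*(y)), where F* is the cdf
of f*.

**Escape pathway.** A homogeneous Poisson process with rate p per
Morgan. Total crossover intensity is q + p = 1 per Morgan for every
(ν, p) — this is the model's core identifiability constraint and is
verified against simulation in the test suite.

**Likelihood.** For one chromosome of one meiosis with ordered
crossover positions u₁ < … < u_n, the likelihood sums over all 2ⁿ
assignments of events to the two pathways. An assignment placing k
events in the escape pathway contributes the Poisson factor
p^k·e^(−pL); the interference-pathway complement û₁ < … < û_m
contributes g*(û₁)·Π f*(ûⱼ − ûⱼ₋₁)·(1 − F*(L − û_m)), or 1 − G*(L)
when the complement is empty (G* the cdf of g*). Both censoring terms
and the zero-crossover case are included: chromosomes without
crossovers still carry information about both parameters. The dataset
log-likelihood is the sum over chromosome-meioses.

Edge cases: p = 1 removes the interference pathway (only the all-escape
assignment contributes, and 1 − G*(L) → 1); p = 0 keeps only the empty
escape set; q = 0 makes f*, g* undefined and the density functions
raise so callers must branch, which the likelihood does internally.

## Numerical choices

- **Series truncation.** All mixture series stop at K = 40 terms, where
  the remaining geometric weight Σ_{k>K} 2^−k < 1e−12 certifiably
  bounds the truncation error; the residual weight is folded into the
  survival function so tails stay proper.
- **G\* in closed form.** Rather than quadrature, G*(y) uses the exact
  identity ∫₀^y P(a, ru) du = y·P(a, ry) − (a/r)·P(a+1, ry) applied
  termwise, inheriting the same geometric truncation bound. Quadrature
  survives only as an independent oracle in the tests.
- **Vectorized subset sum.** A dataset is compiled once into flat
  arrays of all assignment terms (at most 2³ = 8 per meiosis after the
  three-crossover filter); one likelihood evaluation is then a handful
  of vectorized density calls plus a grouped log-sum-exp, making
  maximum-likelihood fits on 50,000 meioses take tens of seconds on one
  core. Duplicate (positions, L) meioses — in practice the
  zero-crossover ones — collapse into multiplicity weights.
- **Optimization.** Nelder–Mead on (log ν, logit p), p clipped at 1e−6
  from the boundary. The likelihood is screened on the grid
  ν ∈ {3, 7, 12} × p ∈ {0.01, 0.1} and the simplex starts from the best
  grid point; simplex tolerance 1e−6 by default (1e−4 for per-parent
  fits, whose sampling SEs are orders of magnitude larger). SEs come
  from a central-difference Hessian (step 1e−4 on the transformed
  scale) mapped back by the delta method; a non-invertible Hessian —
  typical when p̂ sits on the boundary — yields missing SEs, flagged
  rather than fabricated.
- **Impossible datasets** (zero likelihood under the tested parameters)
  return a large negative sentinel instead of −inf so the simplex can
  retreat.

## Crossover detection

Within a three-generation family the transmitted parental haplotype is
phased deterministically: at markers where the focal parent is
heterozygous, the transmitted allele follows from the offspring dosage
(homozygous offspring decide it outright; heterozygous offspring are
resolved by a homozygous mate when genotyped), and a homozygous
grandsire then identifies which parental haplotype carries it.
Crossovers are called at switches of grandparental origin between
consecutive informative markers, localized to the flanking pair, with
the genetic midpoint of the flanks as position (the within-interval
placement is unknowable at chip resolution).

Origin runs supported by a single informative marker and flanked by the
same origin on both sides are reverted before calling (configurable
`min_run`, default 1): at dense-chip spacing such double switches are
overwhelmingly genotyping errors, and a genuine double crossover inside
one informative interval is unobservable anyway. The collapse threshold
is exposed because it trades error robustness against rare genuine
events — error-free validation runs disable it. Markers with Mendelian
inconsistencies are set uninformative and counted; families exceeding
5% inconsistent markers are excluded. Meioses with more than three
crossovers on any single chromosome are removed entirely, so the
likelihood's subset sum never exceeds 2³ terms.

## Genetic maps

Per-interval recombination rate = observed crossovers / informative
meioses, used directly as genetic distance (cM = 100·rate; no
Haldane/Kosambi correction, matching the recombination-fraction
definition of the map). A crossover whose flanking pair spans several
marker intervals is allocated fractionally by physical length —
unbiased under a uniform within-interval position prior. Interval rates
above 0.5 are capped and logged. Maps are always built per sex;
crossover positions in Morgans are flank midpoints on the cumulative
map, and zero-crossover chromosomes keep their full length for the
censoring terms.

## Association scans

Per-parent phenotypes are the fitted ν̂ or p̂ (parents enter with
strictly more than 15 offspring for bulls, 3 for cows), or the mean
relative inter-crossover distance (RCO: gap in cM divided by
chromosome map length, averaged over autosomes then progeny). The scan
fits y = Xb + Za + e with a VanRaden genomic relationship matrix for
the polygenic effect and heteroscedastic residuals
Var(eᵢ) = SEᵢ²·σ²ₑ — the phenotype is itself an estimate, so its
squared fitting SE enters the residual, with a free scale σ²ₑ since
only relative weights are defensible. The variance ratio δ = σ²ₐ/σ²ₑ
is estimated once by REML on the null model through a single
eigendecomposition of the weighted GRM; each SNP is then a GLS fit
with the residual scale re-profiled, so with identity kinship and
equal weights the scan reduces exactly to per-SNP OLS. Wald p-values,
minor-allele-frequency filter 0.01, Bonferroni genome-wide threshold
α/#SNPs. The conditional scan appends the parent's mean recombination
rate as a fixed covariate; the two-cohort meta-analysis pools
individuals over the shared SNP set with cohort as a fixed covariate
(a pooled joint fit, not inverse-variance combination). Parents whose
boundary fits yield no SE receive the cohort-median residual variance
rather than being dropped.

## Maternal-age analysis

Meioses are split into K age quantile groups (default 8; boundary ages
go to the lower group). Because more crossovers mechanically mean
shorter gaps, interference estimates confound with recombination rate;
the subsampling removes this exactly: on a single chromosome, for each
crossover count x every group contributes n(x) = min over groups of
N_i(x) meioses drawn without replacement, so the count distribution is
*identical* across groups — an exact multiset property the tests assert
literally. The draw repeats 10 times by default; per-group estimates
are averaged over repeats, then ν̂ and p̂ are regressed on mean group
age by unweighted OLS (inverse-variance weighting optional), with
per-group 95% CIs as estimate ± 1.96·SE.

## Synthetic data

The generator emulates exactly what the analysis assumes: stationary
gamma-renewal chiasmata (first gap from the forward-recurrence law,
drawn as U·Gamma(ν+1, 2qν)) thinned by 1/2, escape events simulated
directly as Poisson crossovers (distributionally identical to thinning
a rate-2p chiasma process, and simpler), Mendelian trio transmission
over founder haplotypes in linkage equilibrium, symmetric dosage-flip
genotyping errors (default 0), and per-parent parameter rules — a
causal SNP adding β per alt allele to ν, and an arbitrary age → p rule
for the maternal-age harness.

Defaults are desk-scale study conditions: 600 parents × 30 offspring
for association power, five autosomes totaling 6 Morgans (a deliberate
scale-down of a ~25-Morgan livestock genome; per-parent ν̂ carries a
small-sample upward bias at this information level that disappears by
~10 Morgans × 30 offspring, which is why recovery checks that average
over parents use longer maps), allele frequencies uniform on
[0.05, 0.5], ages uniform on 24–120 months.

What the generator does *not* emulate — linkage disequilibrium,
realistic marker ascertainment, sex chromosomes, pedigree loops,
population structure beyond the GRM — bounds what passing tests show:
they validate the estimator and pipeline logic under the model's own
assumptions, not robustness to the ways real chip data violate them.

## Known limitations

- Phasing is family-local and deterministic; no population-scale
  statistical phasing or HMM origin inference, so sparse informative
  markers lose events near chromosome ends.
- The likelihood conditions on the built map being correct; map error
  propagates into (ν, p) without acknowledgment in the SEs.
- ν and p are weakly identified on short chromosomes with few double
  crossovers (boundary p̂ with missing SEs is the visible symptom), and
  at ν = 1 the pathway split is unidentifiable by construction.
- The fast-scan approximation (δ fixed from the null model) slightly
  misstates per-SNP tests when a SNP explains substantial variance.
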