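# xoinfer

Crossover-interference analysis for three-generation pedigree genotypes.

Meiotic crossovers are not placed independently along a chromosome: one
crossover suppresses others nearby (*crossover interference*), while a
minority of events appear to escape this control entirely. `xoinfer`
implements the full analysis chain used to quantify these effects in
dense-chip livestock pedigrees — detect crossovers by trio phasing,
build sex-specific genetic maps, fit the Housworth–Stahl
interference-escape model by maximum likelihood, scan SNPs for
association with per-parent interference phenotypes, and test
maternal-age trends with a count-matched subsampling design. Because
real pedigree chip data are rarely shareable, the package ships a
first-class synthetic-data generator with exactly the statistical
structure the analysis assumes, so every stage is testable end to end.

It is aimed at quantitative geneticists working with parent–offspring
genotype data (cattle conventions are the defaults: 29 autosomes,
chromosome X excluded).

## The model

The Housworth–Stahl model treats crossovers on a chromosome of genetic
length *L* Morgans as the superposition of two pathways:

- **Interference pathway.** Chiasmata follow a stationary gamma renewal
  process with shape ν and rate 2qν (mean chiasma spacing 1/(2q));
  each chiasma is transmitted to a given chromatid with probability 1/2.
  Thinning gives the inter-crossover gap density
  f\*(y) = Σ_{k≥1} (1/2)^k Gamma(y; kν, 2qν) and the stationary
  first-gap density g\*(y) = q·(1 − F\*(y)).
- **Escape pathway.** A homogeneous Poisson process with rate p per
  Morgan (ν = 1, no interference).

With q = 1 − p the total intensity is exactly 1 crossover per Morgan.
ν = 1 recovers a pure Poisson model; larger ν means stronger
interference. The likelihood of an observed meiosis with n crossovers
sums over all 2ⁿ assignments of events to the two pathways, with proper
censoring terms at both chromosome ends; (ν, p) are estimated by
Nelder–Mead on (log ν, logit p) with standard errors from the inverse
numerical Hessian.

Downstream, per-parent estimates become phenotypes in a linear mixed
model y = Xb + Za + e with a genomic relationship matrix for the
polygenic effect and the squared fitting SEs as per-individual residual
variances; maternal-age trends are tested after subsampling age groups
to identical crossover-count distributions, which removes the
recombination-rate confound by construction.

## Worked example

Simulate a small pedigree, detect crossovers, build the paternal map,
and fit the model:

```sh
xoinfer simulate --out sim --seed 3 --parents 10 --offspring 6 \
    --markers 80 --chromosomes "1:1.0,2:0.8"
# wrote 60 families to sim
xoinfer detect --genotypes sim/genotypes.tsv --pedigree sim/pedigree.tsv --out det
# 60 meioses kept, 85 crossovers
xoinfer map --crossovers det/crossovers.tsv --genotypes sim/genotypes.tsv \
    --pedigree sim/pedigree.tsv --sex male --out map
# male map total 141.7 cM over 2 chromosomes
xoinfer fit --intervals map/intervals.tsv --out fit/estimates.tsv
# genome: nu=4.923 p=0.0000 loglik=-73.81 n=120
```

The simulated truth here is 180 cM of genome per meiosis (ν = 7,
p = 0.05); with only 60 meioses the rebuilt map (141.7 cM) and the
interference estimate (ν̂ = 4.9, p̂ at its boundary) are noisy, as the
fitting SEs would show. At the scales the library is designed for the
estimates tighten: 50,000 single-Morgan meioses simulated at
(ν = 10, p = 0.05) refit to ν̂ = 9.81, p̂ = 0.0502 (seed 1).

The same stages are available as library calls (`simulate_population`,
`detect_all`, `build_map`, `fit_hs`, `gwas_scan`, `age_trend_pipeline`)
for anything beyond shell-scale use.

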