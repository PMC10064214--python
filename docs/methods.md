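# Methods

`beefgs` simulates a multi-breed beef-cattle breeding program forward in
time and compares two genetic-evaluation systems on the simulated data:
multi-breed pedigree BLUP with unknown-parent groups (UPG), and
single-step genomic BLUP with metafounders (ssGBLUP-MF).  The quantity of
interest throughout is the *prediction accuracy* of the final generation
of selection candidates: the Pearson correlation between true breeding
values (TBV, known in simulation) and estimated breeding values, pooled
over all candidates or restricted to a sex / no-record subset.

## 1. Population simulation

The simulation has four stages, each reproducibly driven by a child
stream of one master seed.

**Historical phase.**  A closed population of monoecious individuals mates
at random (two distinct parents per offspring, no selection) for
`n_gen_phase1` generations at constant size, then the size interpolates
linearly to `size_end` over `n_gen_phase2` generations.  Founders start
with independent Bernoulli(0.5) alleles at every locus of a candidate
pool laid out uniformly at random on the linkage map; recurrent
bidirectional mutation (default 2.5×10⁻⁵ per allele per meiosis) maintains
polymorphism.  The finite size builds linkage disequilibrium (LD) and
drifts allele frequencies, so the final generation provides a realistic
pool of segregating loci.

**Locus panel.**  Markers and QTL are drawn from loci with minor allele
frequency strictly above 0.1 in the final historical generation.  Markers
are "evenly spaced" in the only sense possible on a discrete set: the
nearest still-unused eligible locus to each of `n_markers` equidistant
genome positions (greedy, in target order).  QTL are drawn uniformly at
random from the remaining eligible loci; marker and QTL sets are disjoint.

**Expansion and breed formation.**  A founder sample (half of the final
historical generation at desk scale) is expanded by random mating; each
breeding dam leaves `offspring_per_dam` (5) offspring and the number of
breeding animals per sex is capped at a configurable ceiling (500), which
is the documented culling rule for this stage.  Five disjoint random
samples of 100 males + 100 females then found five reproductively
isolated breeds, randomly mated for 30 generations at 2 offspring per
dam.  Isolation plus drift differentiates breed allele frequencies; that
differentiation is exactly what the metafounder Γ matrix later measures.

**Selected breeding (the evaluated herd).**  Each breed enters the final
stage with its own founding counts of breeding sires and dams and runs
for 15 generations.  Every generation: each dam produces one offspring by
a randomly drawn sire of her breed; sexes are assigned exactly 50:50
within each breed×generation cohort (a random permutation of a balanced
vector — with a Bernoulli draw, the breed with the highest dam
replacement + growth demand would run out of female candidates with
appreciable probability); each animal receives a phenotype at birth.
Replacements are then selected on EBVs from a within-run UPG pedigree
BLUP fitted to all phenotypes recorded so far (true variance components,
PCG tolerance 10⁻⁶): a fraction `repl` of breeding animals exits (oldest
first — culling is strictly by age, with random tie-break within a birth
cohort), the breeding counts move to their growth target, and the vacant
slots are filled by the highest-EBV candidates of the newest cohort.
Breeding counts grow *linearly* in the founding counts,
`n_t = round(n₀(1 + g·t))`: this reproduces both the first-generation
counts and the final-cohort sizes of the program being modelled, which a
compounded reading overshoots by a factor of two.

Because the evaluated pedigree is truncated at this stage, its base
animals have unknown parents.  They are generated as offspring of random
within-breed matings of the last breed-formation generation (a bridging
generation that only supplies genotypes), and their missing parents are
mapped to one metafounder (or one UPG) per breed.

**Meiosis.**  Crossovers follow the Haldane model: Poisson crossover
counts per chromosome with mean equal to the genetic length in Morgans,
uniform positions, no interference.  The batched simulation path uses the
exactly equivalent Markov formulation — the parental phase switches
between adjacent loci with probability r = (1 − e^(−2d))/2 — which the
test suite checks against the explicit-crossover path.  Mutation events
in the batched path are placed by drawing the Binomial event count and
distinct uniform cells (exact, and much cheaper than per-cell draws at
realistic rates).

## 2. Trait model

One additive trait: TBV_k = Σ_j β_j q_kj over QTL dosages q ∈ {0,1,2}.
Effect magnitudes are Gamma(shape 0.4) — many small, few large effects —
with random symmetric signs, rescaled once so that the TBV variance of
the base cohort of the selected-breeding stage equals h²σ²_P = 0.3
(h² = 0.3, σ²_P = 1).  Phenotypes are y = μ + sex + TBV + ε with
ε ~ N(0, 0.7) and a ±0.25 sex effect (the magnitude is immaterial to
accuracy; it exists so the fixed-effect part of the model is estimable).
Breed fixed effects are not simulated: breed differences arise
genetically through drift and selection history.

## 3. Study design grid

All evaluations reuse one simulated herd per replicate (the design holds
the population fixed across cells).  The genotyping budget (5,000 at full
scale, 500 at desk scale — about 3% of the evaluated animals) is
allocated by scenario; genotyping is only allowed from generation 7
onward, and sampling is uniform within each stratum across the pooled
five-breed population:

| scenario | genotyped |
|---|---|
| RefSc | none (pedigree-only reference) |
| Sc1 | budget × male generation-15 candidates |
| Sc2 | 0.4 × ancestral sires with ≥ 10 progeny + 0.6 × male candidates |
| Sc3 | budget × candidates of both sexes (unrestricted draw) |
| Sc4 | 0.3 × ancestral sires + 0.3 × ancestral dams + 0.4 × both-sex candidates |

"Ancestral" means generations 7–14 and at least one progeny; the
10-progeny threshold applies only to Sc2's sire stratum.  Phenotyping
cases record an exact fraction (100/60/20%) of the animals of the allowed
sex(es) (both, male-limited, female-limited — nine cases), drawn without
replacement among generations 1–15; base animals carry no records.

## 4. Evaluators

Both evaluators solve the single-trait animal model
y = Xb + Zu + e at the true variance ratio λ = σ²_e/σ²_a = 7/3, with
fixed effects intercept + sex (the sex column is dropped when a case
records one sex only).  The solver is preconditioned conjugate gradients
(Jacobi preconditioner, relative residual 10⁻⁸, warm-started across cases
within a scenario) with a sparse-LU fallback.

**UPG pedigree BLUP.**  A⁻¹ is assembled by Henderson's rules with exact
inbreeding from the Meuwissen–Luo recursion; unknown parents are replaced
by their breed's group in the Quaas–Pollak transformed system, so animal
equations yield total EBVs u = Qs + a directly.  The group levels are
confounded with the intercept, so the last group's equation is removed
(its solution fixed at zero); correlations are invariant to that choice.

**ssGBLUP with metafounders.**  Γ = 8·Cov(P) where P holds each breed's
second-allele frequencies at the markers, computed from the base
generation of the selected-breeding stage (available exactly in
simulation).  Metafounders are pseudo-animals whose self- and
cross-relationships are Γ; for the purebred truncated pedigree, A^Γ obeys
A^Γ_ij = Γ[b_i,b_j] + δ(b_i=b_j)(1 − γ_b/2)·A_ij, and its sparse inverse
follows from generalized Henderson rules with Mendelian variances
(1 − γ_b/2)·d_i and Γ⁻¹ added to the metafounder block.  The genomic
matrix is G^Γ = WW′/s with W = dosage − 1 and s = n_markers/2 — no
allele-frequency centering, which the metafounder parameterisation
absorbs — and the combined inverse is
H^Γ⁻¹ = A^Γ⁻¹ + [0 0; 0 G^Γ⁻¹ − A22^Γ⁻¹], kept as a sparse pedigree part
plus a dense genotyped-block correction.  Γ is repaired by eigenvalue
clipping if a finite-marker estimate is indefinite (it is not, in
practice), and G^Γ is used raw unless numerically singular, in which case
it is blended 5% toward A22^Γ (logged).  Every animal, genotyped or not,
receives a GEBV; with an empty genotyped set the evaluator reduces
exactly to A^Γ pedigree BLUP.

A note on variances: calibrating the TBV variance in the (related) base
cohort means the metafounder model's nominally compatible genetic
variance would be σ²_a/(1 − γ̄/2) (≈1.4× at desk scale, where γ̄ ≈ 0.56).
Measured effect of this rescaling on candidate accuracy is below 0.005,
so both evaluators use the plain true variances; the subtlety is recorded
here rather than parameterised.

## 5. Presets and problem sizes

The `paper` preset carries the full-scale parameter set (29 chromosomes /
2,319 cM, 50K markers, 800 QTL, 2,020 historical generations, five breeds
with 740 sires / 5,200 dams initially, budget 5,000).  The `desk` preset
— used by the test suite and the acceptance script — scales the breeding
populations and budget to 1/10 (74 sires / 520 dams, budget 500) on a
5-chromosome 400 cM genome with 2,000 markers and 200 QTL and a
200-generation history (100 → 50 individuals).  A desk replicate
evaluates ~13–15k animals with ~1.4k final-generation candidates and
completes in well under a minute; ten replicates of the full 5×9 grid run
in a few minutes.  The `micro` preset is a seconds-scale variant for unit
tests.  Both sub-full-scale presets preserve the structure (five breeds,
replacement/growth rates, stratum shares, selection intensity) rather
than any single dimensionless quantity; the genotyped share of male
candidates (~70% in Sc1/Sc2) matches the full-scale design.

## 6. What the desk-scale results do and do not show

The simulated herd reproduces the qualitative behaviour expected of the
design: accuracy rises monotonically with the recorded fraction, every
genomic scenario beats the pedigree-only reference, male candidates are
predicted somewhat better than females in most cells, and genotyped
candidates gain the most (e.g. +0.10–0.12 under sparse recording).
Two quantitative caveats, analysed during development and deliberately
left visible in the acceptance output rather than calibrated away:

* The four genomic scenarios separate only weakly at desk scale.  With
  complete, deep pedigree recording, ancestors are evaluated almost
  exactly from progeny records alone, so genotyping them (Sc2/Sc4) adds
  little beyond genotyping candidates (Sc1/Sc3); the scenario averages
  are statistically tied at ~0.62–0.63.
* The absolute accuracy level is governed by an information bound: when
  candidates carry own records (as the 100% cases prescribe) accuracy
  cannot fall below ≈ √(σ²_a,15/(σ²_a,15+σ²_e)) ≈ 0.5 at the simulated
  generation-15 genetic variance (~0.26 after Bulmer reduction from
  0.30).  Reported reference levels far below this bound would require a
  ~70% erosion of genetic variance that neither drift nor selection can
  produce under these population sizes.

The generator emulates breed structure, selection-induced
disequilibrium, age-structured replacement and selective genotyping; it
does not emulate herd/contemporary-group environments, maternal effects,
genotype-by-breed interaction (the genetic correlation across breeds is
1 by construction), overlapping mating seasons, or pedigree errors —
passing tests therefore say nothing about robustness to those features
of real data.

## 7. Numerical choices, degenerate inputs, limitations

* All stochastic steps take explicit generators; a replicate is fully
  determined by (preset, seed); the master seed spawns independent child
  streams per stage so scenario sampling never perturbs the simulated
  population.
* Pedigrees are topologically ordered by construction and validated
  (a parent after its child raises).
* Accuracy of a degenerate subset (empty, or zero variance) is reported
  as missing (NaN), never silently zero.
* Exact-count sampling (rounding half away from fractional counts) makes
  stratum and phenotyping totals reproducible row sums.
* The CG solver falls back to a direct sparse solve if it fails to
  converge within 20,000 iterations; the fallback has not triggered in
  any shipped configuration.
* The full-scale `paper` preset is expressible and validated but not run
  by the test suite; its memory profile (50K markers × ~170k animals'
  haplotypes) would require a streaming haplotype store that this package
  does not implement.
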