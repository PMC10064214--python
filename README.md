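# beefgs

Simulation study of **selective genotyping for genomic selection in
multi-breed beef cattle**.

Beef-cattle breeding organisations typically cannot genotype every
animal: budgets cover a few percent of the population, phenotypes for
many traits are scarce or sex-limited, and evaluations pool several
breeds whose base populations differ genetically.  `beefgs` asks the
design question directly: *given a fixed genotyping budget, which animals
should get it?*  It simulates a five-breed beef population forward in
time — historical linkage-disequilibrium build-up, breed formation, then
15 generations of EBV-based selection with age-structured replacement —
and compares genotyping strategies by the prediction accuracy they buy
for the youngest selection candidates.

## Model

The trait is additive with heritability h² = 0.3 and phenotypic variance
1: TBV_k = Σ_j β_j q_kj over 0/1/2 QTL dosages, β gamma-distributed with
symmetric signs, y = μ + sex + TBV + ε.  Two evaluators are compared,
both solving the animal model y = Xb + Zu + e at the true variance ratio
λ = σ²_e/σ²_a:

* **Pedigree BLUP with unknown-parent groups** (the reference): u ~ N(0,
  A σ²_a) with one group per breed substituted for missing base parents
  (Quaas–Pollak form, so animal solutions are total EBVs u = Qs + a).
* **Single-step GBLUP with metafounders**: breed base populations become
  pseudo-animals with relationships Γ = 8·Cov(P) estimated from
  per-breed marker allele frequencies, and

  H^Γ⁻¹ = A^Γ⁻¹ + [0 0; 0 G^Γ⁻¹ − A22^Γ⁻¹],  G^Γ = WW′/(m/2),  W = M − 1,

  so genotyped and ungenotyped animals are evaluated jointly and every
  animal receives a GEBV.

Accuracy is the Pearson correlation between TBV and (G)EBV among
generation-15 candidates.  Four genotyping scenarios (male candidates
only; ancestral sires + male candidates; both-sex candidates; ancestral
sires + ancestral dams + both-sex candidates) are crossed with nine
phenotype-recording cases (100/60/20% of both sexes, males only, or
females only).  See `docs/methods.md` for the full model and design.

## Worked example

One desk-scale replicate (1/10-scale breeding populations, 2,000 markers,
genotyping budget 500) from the library:

```python
from beefgs import desk, run_replicate

res = run_replicate(desk(), seed=1)
print(res.n_animals, res.n_candidates)   # 15187 1426
print(res.grid.round(3))
```

```
       RefSc    Sc1    Sc2    Sc3    Sc4
100MF  0.688  0.706  0.716  0.726  0.723
60MF   0.595  0.622  0.638  0.642  0.642
20MF   0.454  0.482  0.510  0.499  0.536
100F   0.608  0.624  0.648  0.645  0.641
60F    0.533  0.535  0.587  0.571  0.571
20F    0.461  0.476  0.512  0.512  0.513
100M   0.587  0.608  0.620  0.619  0.642
60M    0.546  0.560  0.586  0.571  0.599
20M    0.444  0.459  0.499  0.485  0.509
```

Rows are phenotyping cases (fraction recorded × recorded sexes), columns
are genotyping scenarios.  Reading it: accuracy falls as records get
scarcer (0.69 → 0.45 down the reference column); every genomic scenario
beats the pedigree-only reference in every case (e.g. +0.08 at 20MF for
Sc4, where 80% of records are missing and genomic relationships
substitute for them); and sex-limited recording hurts the unrecorded sex
most — compare 100M male vs female accuracy in `res.by_sex`.

The same experiment from the shell:

```bash
beefgs run-grid --preset desk --seed 1 --replicates 10 --out runs/demo
beefgs summarize --run-dir runs/demo
```

which writes per-replicate CSVs plus `accuracy_mean.csv` /
`accuracy_sd.csv` (cases × scenarios, with a scenario-average row),
`accuracy_by_sex.csv` and `accuracy_no_record.csv`.  `beefgs simulate`
and `beefgs evaluate` split the pipeline when you want to keep a
simulated herd (pedigree CSV, map, HDF5 haplotypes) and re-use it.

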