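# Methods notes

## Prediction model

The engine is standard RR-BLUP: `y = µ1 + Xβ + e` with i.i.d. normal marker
effects and residuals. Dosages are stored on the VCF-native {0,1,2} scale
and centered per marker inside the engine (the fit keeps the centering
constants and applies them to any prediction matrix); markers are **not**
variance-standardized — equal prior variance per marker is the conventional
RR-BLUP coding and the choice matters only when allele frequencies are very
unequal.

Variance components come from REML on the single ratio λ = σ²ₑ/σ²ᵤ. The
intercept is projected out with a Helmert basis of 1⊥ (deterministic, no QR
randomness), the projected kernel `AᵀXXᵀA` is eigendecomposed once, and the
profiled restricted likelihood is minimized over log λ on [1e−6, 1e6] with a
bounded scalar search (tolerance 1e−8). Each λ evaluation is then O(t), so a
fit costs one t×t eigendecomposition plus a cheap 1-D search. µ̂ is the GLS
mean under V = XXᵀ + λI (not the raw mean; the difference is small but the
GLS form is the mixed-model definition). Marker effects use the kernel form
when m > t and the ridge form otherwise; the two are algebraically identical
and the tests assert agreement to 1e−8. Degenerate input (zero phenotypic
variance) yields a flagged fit with µ̂ = ȳ, β̂ = 0 rather than an error,
because cross-validation folds can legitimately be flat.

The genomic heritability reported from a fit is
`σ̂²ᵤ·mean(diag(XcXcᵀ)) / (σ̂²ᵤ·mean(diag(XcXcᵀ)) + σ̂²ₑ)`, i.e. genetic
variance referenced to the average centered marker sum of squares.

### λ search bounds

At t around 10 the restricted likelihood is often numerically flat near the
bounds (with t < m the kernel is full rank and a noise-free interpolating
solution competes with the noise-only solution). Optimizer-equivalence tests
therefore compare λ estimates with a combined relative/absolute tolerance
rather than in log scale, and treat bound-hitting fits as what they are:
boundary solutions, not estimation failures.

## Synthetic populations

The generator emulates the statistical structure the pipeline assumes, not
soybean biology in detail:

* **Founders** — ancestral allele frequencies ~ U(0.1, 0.9); subpopulation
  frequencies Beta-distributed around them (Balding–Nichols) with divergence
  parameter F; F = 0 short-circuits to identical frequencies. A Hudson-style
  two-population FST estimator on simulated founder pools recovers F.
* **RIL** — F1 of two homozygous parents followed by (default) 4 selfing
  generations by single-seed descent; crossovers are a Poisson process on
  the centimorgan map (Haldane, no interference — the simplest defensible
  meiosis model). Residual heterozygosity per locus is (1/2)⁴ ≈ 0.0625 and
  is tested against that closed form.
* **MULTIFAM** — several biparental families bred from a shared founder
  pool by the same RIL process; family labels ride in the genotype ids and
  are recoverable from the top principal components.
* **GERMPLASM** — individuals are two independent mosaics of founder
  haplotypes with geometric block lengths (mean `block_mean_cM`, default 20
  cM). Mosaic sampling gives tunable block LD without coalescent machinery
  and exact Hardy–Weinberg equilibrium within a subpopulation (the two
  mosaics are independent).
* **Phenotype** — `n_qtl` markers drawn uniformly act as QTL with N(0,1)
  allele-substitution effects; the residual SD is set from the sample
  variance of the breeding values so the realized variance ratio matches the
  target h² in expectation. h² = 1 and h² = 0 are exact special cases. QTL
  are markers (visible to the model) by default; a hidden-QTL flag reports
  their ids so callers can drop them and emulate incomplete LD.

What this does **not** emulate: multi-environment trials and across-
environment BLUP (the simulator emits one value per genotype, standing in
for a yield BLUP), dominance/epistasis, selection during line development,
genotyping error, and ascertainment bias of SNP arrays. Passing tests
therefore demonstrate that the machinery behaves as specified under a clean
additive world, not that any particular real population will show the same
prediction abilities.

## LD pruning

Greedy left-to-right scan per chromosome: a marker is dropped iff its
squared dosage correlation with an already-retained marker in the trailing
window exceeds the threshold (default 0.95). The window is 100 consecutive
SNPs by default, with a base-pair window available when physical positions
exist — simulated panels may carry only a genetic map, which is why the SNP
window is the default. Earlier markers win ties (deterministic and
order-stable); the pass is single (no fixed-point iteration across
windows), the common dialect among sliding-window pruners. Monomorphic
markers have undefined correlation; it is defined as 0 with a warning so
they never trigger removal. Every pruned output satisfies the audit: no
retained pair within a window with r² above threshold.

## Marker-selection strategies

The size schedule iterates `s ← floor(0.30·s)` from the pruned panel size
until the floor (default 48); `floor` is the only rounding that reproduces
the canonical 6072/1821/546/163/48 chain from 20,242 markers. Restriction
to a smaller panel keeps the sizes strictly below the available count.

* **NRE-MB** ranks once by |β̂| from a single full-panel fit (stable sort,
  earlier marker wins ties); subsets are nested by construction.
* **NRE-R** draws independent uniform subsets per size and replicate
  (replicates are *not* nested — the strategies differ in exactly this).
* **RE-MaB** refits on the current subset before each cut.
* **RE-MoB** draws many random candidate subsets *of the current entry set*
  per size, scores each, and keeps the argmax (ties: first encountered).
  The scorer is the open design point: here every candidate in a round is
  scored by mean prediction ability over **one fixed k-fold partition**
  (default k = 5), shared so scores are comparable and the evaluation cost
  is one CV per candidate. The candidate count is configurable (1000 for
  study-scale runs; tests and the acceptance script use 25–100, which is
  enough for the orderings to emerge at desk scale).

## Core selection

IBS distance `d(i,j) = mean |gᵢ − gⱼ|/2` on the dosage scale; the kinship
complement (1 − d) is computed but not consumed by the objectives. Core
sizes round `fraction·n` to the nearest integer with exact .5 ties rounded
**down** — the only convention consistent with all of 45, 55, 111, 113, 553
at the fractions and population sizes the drivers use.

EN (maximize mean entry-to-nearest-entry distance) and AN (minimize mean
accession-to-nearest-entry distance) are optimized by restarted steepest
single-swap local search: evaluate every (selected, unselected) swap with
incremental top-2/top-3 nearest-neighbor bookkeeping, apply the best
improving move, stop at a local optimum, keep the best of `n_restarts`
(default 10) seeded starts. This replaces a parallel-tempered metaheuristic
deliberately: it is deterministic under seed, fast at desk scale, and
matches exhaustive enumeration on every tested instance with n ≤ 12 and
core ≤ 4. Nearest-entry ties resolve to the smallest index. The reported
objective is always re-evaluated from scratch on the final subset.

## Validation conventions

* Repeated k-fold CV (default 20 × 10-fold): fold sizes differ by ≤ 1;
  aggregation is mean/min/max over **all k × repetitions fold-level r
  values**, not over repetition means (the difference is negligible; the
  convention is fixed here).
* Folds that cannot produce a correlation (zero variance in observations or
  predictions) are skipped with a warning and counted — never imputed as 0.
* Cores smaller than 3·k reduce k with a warning so every validation fold
  supports a correlation; below 6 genotypes CV is refused.
* `holdout_split` exists purely for split-size accounting of single-holdout
  designs (nearest-integer validation share, ties down); model evaluation
  always uses the k-fold machinery.
* In the joint marker × training-set grid, marker selection re-runs
  **inside each core**, so no information from excluded genotypes leaks
  into marker selection. This is the leakage-safe reading of an ambiguous
  design choice; the alternative (select once on the full population) would
  flatter small cores.
* One global seed expands into named substreams (simulation, folds, random
  panels, model-based selection, core optimizer, sweep, grid) so changing
  one stage's draws never shifts another's; pipeline reruns are
  bit-reproducible.

## Problem sizes

Tests and the acceptance script run the study design at desk scale:
populations of 120–400 genotypes, panels of 80–1000 markers, candidate
counts of 25–100 for model-based selection, 10–20 random replicates for the
Ra/Rmin/Rmax summaries, and 10 seeds for stochastic orderings. These sizes
were chosen so the stochastic properties under test (ordering of strategies,
heritability recovery within ±0.15) are comfortably resolved by the margins
observed, while a full run stays in the minutes range.

## Known limitations

* Mean imputation only; haplotype-aware imputation is out of scope, so
  heavily missing real panels will lose LD information before pruning.
* Biallelic SNPs only; multiallelic records are rejected, not split.
* The EN/AN optimizer guarantees a local optimum of the swap neighborhood,
  not a global one; at study scale (n ≈ 1000, fractions ≥ 0.5) more
  restarts may be warranted.
* NRE-R confidence summaries are empirical min/mean/max, not interval
  estimates.
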