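# gsalloc

Resource allocation for genomic selection: **selective genotyping** (how few
SNPs can a prediction model afford?) and **selective phenotyping** (how few
lines need field testing?) evaluated together on one pipeline, with
ridge-regression BLUP (RR-BLUP) as the prediction engine.

The package is aimed at plant-breeding quantitative geneticists who want to
benchmark low-density marker panels and optimized training sets before
committing genotyping or phenotyping budget. It ships a synthetic-population
generator emulating three soybean-style population archetypes — a biparental
recombinant-inbred-line (RIL) family, a multifamily breeding panel, and a
structured germplasm collection — so the whole workflow is testable without
any external data. Real data enter through VCF or dosage tables.

## The model

Phenotypes are regressed on all markers jointly with a common shrinkage:

```
y = µ·1 + Xβ + e,   β ~ N(0, σ²ᵤ I),   e ~ N(0, σ²ₑ I)
```

where `X` is the mean-centered genotype dosage matrix (t lines × m SNPs).
The ridge parameter λ = σ²ₑ/σ²ᵤ is estimated by REML via a single spectral
decomposition of the kernel `XXᵀ`; marker-effect BLUPs come from either the
kernel (t×t) or ridge (m×m) form of

```
β̂ = Xᵀ(XXᵀ + λI)⁻¹(y − µ̂·1) = (XᵀX + λI)⁻¹Xᵀ(y − µ̂·1)
```

Genomic estimated breeding values for new material are `µ̂ + X₁β̂`, and
**prediction ability** r is the Pearson correlation between observed
phenotypes and GEBVs, in cross-validation (r_cv) or on an external
population (r_ev).

Around the engine:

* **LD pruning** — greedy sliding-window removal of markers with pairwise
  r² > 0.95 against a retained neighbor;
* **marker-selection strategies** over a floor(30%) size schedule
  (e.g. 20,242 → 6072 → 1821 → 546 → 163 → 48 SNPs): rank-once by |β̂|
  (NRE-MB), rank-with-refitting (RE-MaB), random panels (NRE-R), and
  best-of-random-models selection scored by cross-validation (RE-MoB);
* **core selection** — identity-by-state distances feeding two
  single-objective core samplers: EN (maximize mean entry-to-nearest-entry
  distance, diversity) and AN (minimize mean accession-to-nearest-entry
  distance, representativeness), optimized by restarted steepest-swap local
  search at fractions such as 75/50/20/10/5%;
* **experiment drivers** for strategy comparison, training-set-size sweeps,
  and the joint marker × training-set reduction grid.

## Worked example

```bash
python examples/01_simulate_and_predict.py
```

prints (exact numbers are seed-dependent):

```
panel: 200 genotypes x 500 markers, realized h2 = 0.594
REML ridge parameter lambda = 110.04
genomic h2 estimate = 0.641 (simulated target 0.6)
training prediction ability r = 0.942
```

The generator hit the requested heritability (0.594 realized vs 0.6
target), REML recovered it from marker data alone (0.641), and the
training-set r of 0.94 illustrates why in-sample ability is never reported
as predictive performance — the other examples cross-validate. See
`examples/02_prune_and_select_markers.py` (marker reduction),
`examples/03_core_selection.py` (EN/AN cores vs random training sets) and
`examples/04_full_pipeline.py` (the end-to-end pipeline with its manifest).

A thin CLI mirrors the library for shell use:

```bash
gsalloc simulate --archetype MULTIFAM --n 200 --m 500 --outdir sim/
gsalloc prune --in sim/genotypes.csv --out kept.txt --r2 0.95
gsalloc select-core --geno sim/genotypes.csv --method an --fraction 0.2 --out core.json
gsalloc pipeline --config run.yaml --outdir results/
```

## Layout

```
src/gsalloc/      io, simulate, rrblup, pruning, markers, cores,
                  validation, pipeline, cli
examples/         one narrative script per capability
tests/            pytest suite (unit, property, acceptance)
docs/methods.md   modelling and design notes
```
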