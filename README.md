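# landgen

Landscape-genetics inference for individual-based microsatellite data:
from genotypes and environmental rasters to the environmental drivers of
dispersal and gene flow.

The package implements the isolation-by-resistance inference chain used to
ask questions like *"does terrain ruggedness or canopy height shape
short-range dispersal in a forest primate?"*:

1. **Genetic distances** — maximum-likelihood pairwise relatedness (over
   the Cotterman coefficients k₀, k₁, k₂ with r = k₂ + k₁/2), greedy
   removal of close kin (r̂ > 0.5), Rousset's â individual differentiation,
   and the proportion of shared alleles D_PS.
2. **Resistance surfaces** — terrain indices (TRI, TPI), kernel point
   densities, and the eight Monomolecular/Ricker transformation variants
   mapping a rescaled environmental raster onto resistance ∈ [1, max];
   categorical class-resistance assignments; additive composites.
3. **Circuit theory** — 8-neighbor conductance graphs, commute distances
   C(i,j) = vol(G)·(L⁺ᵢᵢ + L⁺ⱼⱼ − 2L⁺ᵢⱼ), and cumulative current maps.
4. **MLPE mixed models** — the pairwise regression
   y᷉ᵢⱼ = β₀ + βᵀxᵢⱼ + uᵢ + uⱼ + εᵢⱼ with node random effects accounting for
   the non-independence of dyads sharing an individual; ML/REML, AIC and
   AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1).
5. **Genetic-algorithm optimization** of transformation parameters
   maximizing the MLPE likelihood of genetic distance against commute
   distance, with ≥2 independent runs as a convergence check.
6. **Bootstrap model selection** — subsample individuals, refit all
   candidate surfaces, rank by AICc, and report average rank, mean Akaike
   weight ω̄, and the top-model frequency π̂.
7. **Gravity models** — singly-constrained mixed models of log D_PS on log
   distance (ω), within-site attraction covariates (υ) and between-site
   resistance distances (c), with a per-origin random intercept.

A first-class synthetic-data module generates autocorrelated landscapes,
genotypes whose differentiation tracks commute distance through a known
"true" resistance surface, and gravity networks with known coefficients, so
the whole chain is testable end to end with the generating truth in hand.

## Worked example

```python
import landgen as lg
from landgen.synthetic import (SyntheticTruth, make_landscape,
                               sample_locations, simulate_genotypes)
from landgen.optimizer import GAConfig, optimize_surface

truth = SyntheticTruth(lg.TransformSpec("Monomolecular", 3.0, 100.0), seed=0)
env = make_landscape("smooth", (40, 40), seed=0)
locs = sample_locations(env, 12, seed=1)
table = simulate_genotypes(truth, env, locs, n_per_site=4, decay=3.0, freq_sd=1.5)

rel = lg.estimate_relatedness(table)
kept = lg.filter_related(table, rel, threshold=0.5)
print(f"{table.n} individuals genotyped, {kept.n} retained")

ar = lg.rousset_ar(kept)
euclid = lg.euclidean_matrix(kept.ids, kept.xy)
print("IBD:", lg.ibd_regression(ar, euclid))

res = optimize_surface(env, ar, kept.xy,
                       cfg=GAConfig(population=20, max_generations=30,
                                    patience=10), seed=0)
s = res.best_spec
print(f"best transform: {s.family} (shape={s.shape:.2f}, max={s.maximum:.1f})")
print(f"logL={res.best_fit.logL:.3f}  AICc={res.best_fit.aicc:.3f}")
```

prints

```
48 individuals genotyped, 46 retained after kinship filtering
IBD: {'pearson_r': 0.3569508882233834, 'r_squared_pct': 12.741393660346235}
best transform: Inverse Ricker (shape=0.61, max=5000.0)
logL=893.456  AICc=-1777.937
```

Reading the output: two planted close-kin dyads were detected and one
member of each removed; straight-line distance alone explains ~13% of the
genetic structure (Pearson r ≈ 0.36); the GA then finds a resistance
transformation of the environmental raster whose commute distances fit the
genetic distances far better than distance alone.  With short GA budgets
the *labelled* family may differ from the generating one even when the
fitted resistance pattern matches — see `docs/methods.md` on transformation
aliasing.

The same workflow is scriptable from the shell:

```bash
landgen simulate --preset genetics --out data/ --seed 0
landgen distances --genotypes data/genotypes.csv --out dist/
landgen optimize --surface data/env.asc --genetic dist/rousset_ar.csv \
                 --locs data/coords.csv --seed 0 --out optimized.json
landgen run --config pipeline.yaml      # the whole chain
```

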