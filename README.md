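# forestprio

Spatial conservation prioritization of boreal forest landscapes from
inventory rasters — and a test bench for the question every planning agency
faces: **is open but coarse forest inventory data good enough to decide
where to protect, or do you need the detailed proprietary stand data?**

`forestprio` implements the full comparison pipeline:

1. **Conservation-value indices** — per tree-species group
   (pine/spruce/birch/other broadleaved), a sigmoidal benefit of mean stem
   diameter times growing-stock volume, `index_s = B_s(D_s)·V_s`, optionally
   split by the five Finnish site-fertility classes into 20 "forest type"
   features, with a [0, 1] condition layer discounting value where forestry
   operations are planned.
2. **Stand segmentation** — a directed-trees algorithm (minimum band-space
   gradient links + deterministic region merging) that recovers per-species
   mean diameters from coarse rasters carrying only one overall diameter.
3. **Greedy complementarity ranking** — Zonation-style iterative worst-cell
   removal in additive-benefit-function mode: marginal loss
   `δ_i = Σ_j w_j (p_j^z − (p_j − q_ij)^z)` with repeated range-size
   normalization (z = 0.25), feature weights, condition layers, and matrix
   connectivity (negative-exponential kernel, `α = 2/⟨dispersal distance⟩`,
   asymmetric feature-similarity multipliers).
4. **Comparison battery** — decile-interval Jaccard matrices between rank
   maps, priority-rank distributions inside validation masks (protected-area
   / woodland-key-habitat / acquisition analogues), and cross-loaded
   representation curves quantifying what a coarse-derived ranking loses.
5. **Synthetic landscapes** — seeded generators for a detailed inventory
   truth and its coarse degradation (disk-mean smoothing + noise, diameter
   collapse), with the statistical structure the analysis assumes, so the
   whole pipeline is testable without any proprietary data.

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

```python
import numpy as np
import forestprio as fp

cfg = fp.ExperimentConfig(
    landscape=fp.LandscapeConfig(grid_height=100, grid_width=100, seed=1,
        patch_specs=(fp.PatchSpec("pa_analogue", 5, 13.54, 0.5),
                     fp.PatchSpec("metso_analogue", 1, 5.36, 0.6),
                     fp.PatchSpec("wkh_analogue", 28, 0.61, 0.8))),
)
result = fp.run_experiment(cfg)          # the six-run grid, ~1 min

detail = result.runs["detailClass"]      # ranking from detailed data
coarse = result.runs["coarse"]           # ranking from coarse data
wkh = result.validation.masks["wkh_analogue"]

print(sorted(result.runs))
print(round(float(np.median(detail.rank[wkh])), 3),
      round(float(np.median(coarse.rank[wkh])), 3))

stack = result.stacks["detailClass"]
print(round(fp.cross_load_evaluation(detail, stack, 0.10)["mean"], 3),
      round(fp.cross_load_evaluation(coarse, stack, 0.10)["mean"], 3))
```

prints

```
['coarse', 'coarseClass', 'coarseClassCon', 'coarseCon', 'detailClass', 'detailClassCon']
0.942 0.674
0.438 0.335
```

Reading: the small (~0.6 ha) woodland-key-habitat analogues sit near the top
of the detailed-data ranking (median rank 0.94) but drop to 0.67 when only
coarse data is used — the degradation erases exactly the small high-value
features. And protecting the top 10% of the landscape covers 43.8% of the
detailed features' distributions under the native detailed ranking, but only
33.5% when the priority order is imported from the coarse-data run: the cost
of planning with coarser data.

A command-line interface mirrors the library
(`forestprio synth|index|segment|rank|evaluate|run`), e.g.

```bash
forestprio run --config experiment.yml --out results/
```

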