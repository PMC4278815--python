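# indets

Are all species necessary to see the large-scale pattern? Plot inventories
— tropical tree plots especially — are full of *indets*: morpho-species
with no valid species name. `indets` measures how much the standard
community-ecology toolkit actually changes when those unidentified
morpho-species are omitted, by comparing three views of one plot ×
morpho-species abundance table:

* **AMS** — all morpho-species,
* **IMS** — identified morpho-species only (AMS = IMS + UMS),
* **genus** — the higher-taxon shortcut (columns summed within genus),

across per-plot Fisher's alpha, Bray–Curtis / Jaccard / Sørensen
similarity, the frequency-dependent Raup–Crick null model, Mantel tests
against geographic distance, and 2-D NMDS ordinations. Every comparison is
a regression of the complete-view statistic *y* on the derived-view
statistic *x*; robustness means adjusted R² near 1 with the slope judged
against the *y = x* line (95% CI). A stratification experiment pushes
further, randomly discarding 50% or 75% of the identified species and
re-measuring the agreement. Because real inventories with per-species
identification status are rarely shareable, the package includes a
synthetic metacommunity generator (logseries regional pool, Gaussian
range kernels for distance decay, rarity-biased identification loss) so
every claim is testable end to end.

The core quantities, in standard notation: Fisher's alpha is the root of
`S = α·ln(1 + N/α)`; Bray–Curtis similarity is `1 − Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ)`;
Jaccard and Sørensen are `a/(a+b+c)` and `2a/(2a+b+c)` on shared (a) and
unique (b, c) species; `β_RC` is the probability, under frequency-dependent
random assembly at the observed richnesses, that the null shared-species
count exceeds the observed one (ties half-weighted); NMDS minimises Kruskal
stress-1. Details and design choices are in `docs/methods.md`.

## Worked example

```python
from indets import (AnalysisConfig, SyntheticConfig,
                    run_truncation_analysis, simulate_dataset)

cfg = SyntheticConfig(seed=1)   # 60 plots x 500 stems, alpha 35, 30% indets
table, geo = simulate_dataset(cfg)
report = run_truncation_analysis(table, geo, AnalysisConfig(seed=1))
print(report.to_frame()[["r2_adj", "slope", "slope_differs_from_1"]])
```

prints (seed 1):

```
              r2_adj     slope  slope_differs_from_1
row
alpha       0.986852  1.038892                  True
bray        0.999968  0.994061                  True
bray_genus  0.739565  1.561314                  True
jaccard     0.994539  0.942301                  True
sorensen    0.995506  0.970873                  True
raup_crick  0.968951  0.953156                  True
nmds1       0.999983  0.999231                 False
nmds2       0.999965  1.001448                 False
```

Reading: the identified-only view predicts the complete view almost
perfectly for every similarity statistic (adjusted R² ≥ 0.97) and for the
ordination axes, but the slopes sit slightly — and significantly — below 1
for the similarity indices (omitting species shifts similarities a little),
and slightly above 1 for Fisher's alpha (alpha is systematically
underestimated without the rare indets; the report's paired t-test makes
that explicit). The genus-level shortcut does clearly worse (R² ≈ 0.74)
than simply dropping the indets. The same run's stratification experiment
shows agreement degrading smoothly, not catastrophically, as 50% and then
75% of identified species are discarded.

The numbered scripts under `analysis/` walk the same pipeline step by step
(simulate → diversity → similarity/null model → ordination → stratification)
and write their tables under `results/`.

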