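# Methods

## The question

Large plot-inventory datasets (tropical tree plots in particular) always
contain *indets*: morpho-species that were delimited in the field or
herbarium but never matched to a valid Latin name. Analysts must either omit
them or spend heavily on identification. This package measures what omission
does to the pattern statistics ecologists actually use — per-plot diversity
(Fisher's alpha), pairwise compositional similarity, null-model (Raup–Crick)
structure, Mantel correlations with geographic distance, and NMDS
ordinations — by comparing three views of one community table:

* **AMS** — all morpho-species (the complete table);
* **IMS** — identified morpho-species only (unidentified columns removed);
* **genus** — columns aggregated to genus (the higher-taxon shortcut).

Each statistic is computed per view, and the complete-view value is
regressed on the derived-view value. Perfect robustness is the line
*y = x*: adjusted R² of 1 and a slope whose 95% CI contains 1.

## The synthetic metacommunity generator

No suitable inventory with per-species identification status is bundled, so
experiments run on synthetic metacommunities built to exhibit the three
statistical features that drive the question:

1. **Logseries regional abundance.** The regional pool has Fisher's alpha
   `pool_alpha` and `pool_stems` total stems. The species count is anchored
   at the logseries expectation `S = round(alpha·ln(1 + N/alpha))`,
   abundances are iid draws from the logseries pmf `p(n) ∝ xⁿ/n` with
   `x = N/(N+alpha)`, and the exact stem total is enforced by adjusting the
   most abundant species (never letting any abundance drop below 1).
   Anchoring S is deliberate: a fully emergent species count (drawing until
   the stem total is reached) leaves S with relative spread ≈ 1/√alpha
   (~17% at alpha 35), which would make `pool_alpha` a label rather than a
   recoverable parameter. With anchoring, re-estimating alpha from the
   realized (S, N) lands within ~2% at N ≥ 1e5 (tested to 10%).
2. **Distance decay.** Plots are uniform on a `landscape_size` km square;
   each species has a range center uniform on the landscape; plot
   composition is multinomial with weights ∝ regional abundance ×
   `exp(−d²/(2·range_sd²))`. A single isotropic Gaussian kernel per species
   is the minimal mechanism that produces spatial turnover; there are no
   forest-type strata, no environmental covariates, no demography.
3. **Rarity-biased identification loss.** Species are marked unidentified
   with probability ∝ `softmax(−unid_bias·ln(total abundance))`, rescaled so
   the *expected* unidentified species fraction equals `unid_species_frac`
   (probabilities above 1 are capped and the mass redistributed). Status is
   a species-level property — a morpho-species is unidentified everywhere
   or nowhere. `unid_bias = 0` gives abundance-independent loss; the default
   2 concentrates loss strongly in the rare tail, which is what empirical
   inventories show and what makes the question non-trivial (rare species
   carry Fisher's alpha; common species carry similarity structure).

Genera are assigned by sequential random aggregation (new genus with
probability `1/genus_mean_size`, else join a uniformly chosen existing
genus), giving the genus-level view something to aggregate.

Defaults — 60 plots × 500 stems, pool alpha 35, pool of 3·10⁵ stems,
300 km landscape with 75 km range kernels, 30% of species unidentified at
bias 2, ~3 species per genus — represent a single regional inventory of
one-hectare plots of trees ≥ 10 cm DBH; they are the conditions under which
all end-to-end claims are tested. Every draw flows from the single config
seed via named child streams, so identical configs give bit-identical
tables.

What the generator does **not** emulate: stem-level misidentification,
spatially clumped identification effort, multiple census dates, forest-type
mosaics, and the extreme dominance structure of real Guianan plots. Passing
tests therefore show that the analysis machinery reproduces the robustness
phenomenon under a clean logseries + distance-decay world, not that any
particular real inventory would behave identically.

## Statistics

* **Fisher's alpha** solves `S = α·ln(1 + N/α)` by bracketed Brent root
  finding (residual < 1e-8; the bracket expands upward until it straddles
  the root). `S = N` has no finite root and returns NaN as an explicit
  undefined flag; downstream regressions drop, never propagate, it.
* **Similarity indices**: Bray–Curtis `1 − Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ)` on counts;
  Jaccard `a/(a+b+c)` and Sørensen `2a/(2a+b+c)` on presence/absence.
  Plots emptied by truncation are flagged and excluded from all pairwise
  work (similarity to an empty plot is undefined).
* **Raup–Crick** (`β_RC`): for each pair, `n_reps` (default 999) random
  communities of the two observed richnesses are assembled by sequential
  draws without replacement, selection probability ∝ occurrence frequency
  (plots occupied) in the table at hand — AMS weights for AMS, IMS weights
  for IMS. `β_RC = [#(SS* > SS) + ½·#(SS* = SS)]/n_reps`; ties get half
  weight so the statistic is centered at 0.5 under its own null. A uniform
  pool is available as an option. Regressions use the similarity view
  `1 − β_RC` so all rows share orientation. The draw is vectorised with the
  Gumbel top-k trick in bounded-memory chunks.
* **Mantel**: Pearson correlation of strictly-lower-triangle entries;
  one-sided (greater) p with add-one correction over joint row/column
  permutations. The pipeline correlates *dissimilarity* with distance so
  distance decay appears as positive r with small p.
* **NMDS**: 2-D nonmetric SMACOF (scikit-learn backend), best of 20 random
  starts, max 200 iterations, stress-change tolerance 1e-6. Kruskal
  stress-1 is recomputed by isotonic regression of configuration distances
  on the dissimilarity order; scores are centered and rotated to principal
  axes (axis 1 carries maximal variance). Axis signs are arbitrary, so
  axis comparisons first flip the derived view's axis when negatively
  correlated with the reference axis.
* **Comparison regression**: closed-form simple OLS (slope, intercept,
  adjusted R², slope 95% CI from t theory, slope-vs-1 verdict) plus a
  permutation p from 5000 response-vector permutations (R² as the test
  statistic, add-one corrected). Closed form keeps the no-loss identity
  exact: when the derived view equals the complete view the report returns
  slope and R² of exactly 1.0.
* **Stratification**: heavier loss is simulated by retaining a uniformly
  random fraction (default 50% and 25%) of the IMS *species list*,
  recomputing each index's matrix, regressing against the baseline matrix,
  and averaging adjusted R² over 50 iterations. The baseline is the AMS
  matrix by default; the full-IMS baseline is an option, since either
  reading of "agreement with the complete analysis" is defensible.
  Degenerate draws (< 2 species or < 3 usable plots) are redrawn with a cap.

## Design choices where the design was open

* Genus aggregation *includes* unidentified morpho-species that carry a
  genus label (the higher-taxon view discards species-level identification,
  so genus-known indets are usable); a switch restricts it to identified
  species only. Species with no genus label are dropped, with the genus
  columns ordered lexicographically for deterministic output.
* Each analysis stage uses the *same* seed-derived stream for every view,
  so a table with zero unidentified species yields bit-identical AMS and
  IMS results — the end-to-end identity contract.
* Permutation significance permutes the response vector (not residuals);
  Mantel p is one-sided greater; both add-one corrected.
* The stratification experiment reads "the IMS pool" as the species list,
  not the stem list: omission operates on morpho-species, as identification
  does.

## Problem sizes

End-to-end checks run ten independent metacommunities at the default scale
(60 plots × 500 stems; ~240 species each) with 499 Raup–Crick replicates,
999 regression permutations and 10 NMDS starts per run; solver- and
null-model-level checks use small pools where exhaustive enumeration or
bisection serves as the independent oracle. The acceptance script runs one
full-resolution replicate (999 Raup–Crick replicates, 5000 permutations,
20 NMDS starts) in well under a minute.

## Known limitations

* Conclusions are about the *statistics*, not about ranges: omitting rare
  species still underestimates richness, Fisher's alpha (systematically —
  that is the point of the paired test) and species geographic ranges.
* The Raup–Crick null is presence/absence-based; identical plots can have
  nonzero dissimilarity and disjoint plots dissimilarity below one.
* NMDS is a local optimizer; the multi-start design makes the reported
  configuration reproducible under a fixed seed but not provably global.
* The generator's plots are equal-sized and equal-effort; unequal sampling
  effort, a major real-world nuisance, is out of scope.
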