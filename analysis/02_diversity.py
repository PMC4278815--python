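#!/usr/bin/env python
"""Per-plot diversity with and without the unidentified morpho-species.

Computes per-plot N, S, Fisher's alpha and singletons for the complete (AMS)
and identified-only (IMS) views, regresses alpha(AMS) on alpha(IMS), runs
the paired t-test, and writes the per-plot records and the dataset-level
rank-abundance curves under results/.
"""

from pathlib import Path

import pandas as pd

from indets import (
    linear_comparison,
    paired_alpha_test,
    plot_diversity,
    rank_abundance,
    read_community_table,
    subset_identified,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    table = read_community_table(ROOT / "data" / "community.csv",
                                 ROOT / "data" / "species_meta.csv")
    views = {"AMS": table, "IMS": subset_identified(table)}
    records = []
    for name, view in views.items():
        df = plot_diversity(view).assign(view=name)
        records.append(df)
        ra, singles = rank_abundance(view.drop_empty_plots())
        ra.assign(view=name).to_csv(ROOT / f"rank_abundance_{name}.csv",
                                    index=False)
        print(f"{name}: {view.n_species} species, "
              f"{singles} dataset singletons")
    div = pd.concat(records)
    div.to_csv(ROOT / "plot_diversity.csv")

    ams, ims = (plot_diversity(views[v]) for v in ("AMS", "IMS"))
    fit = linear_comparison(ims["fisher_alpha"].to_numpy(),
                            ams["fisher_alpha"].to_numpy(),
                            n_perm=5000, seed=SEED)
    t, dof, p = paired_alpha_test(ams, ims)
    print(f"alpha(AMS) on alpha(IMS): adj R2 = {fit.r2_adj:.3f}, "
          f"slope = {fit.slope:.3f} "
          f"(95% CI {fit.slope_ci95[0]:.3f}-{fit.slope_ci95[1]:.3f}), "
          f"perm p = {fit.perm_p:.2g}")
    print(f"paired t-test on alpha differences: t = {t:.2f}, df = {dof}, "
          f"p = {p:.2g}")
    print("omitting unidentified species depresses Fisher's alpha in every "
          "plot but leaves the cross-plot diversity pattern intact"
          if fit.r2_adj > 0.9 and t > 0 else "pattern NOT robust here")


if __name__ == "__main__":
    main()
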