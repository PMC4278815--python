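"""Per-plot diversity statistics and the paired AMS-vs-IMS comparison.

Fisher's alpha is the diversity parameter of the logseries species-abundance
model, defined implicitly by ``S = alpha * ln(1 + N/alpha)`` for ``S``
species among ``N`` individuals. It is nearly independent of sample size and
dominated by the rare tail, which is exactly why dropping unidentified
(mostly rare) morpho-species depresses it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .community import CommunityTable


@dataclass(frozen=True)
class DiversityRecord:
    plot_id: str
    n_stems: int
    n_species: int
    fisher_alpha: float  # NaN flags the undefined S == N (or empty) case
    n_singletons: int


def fishers_alpha(S: int, N: int) -> float:
    """Solve ``S = alpha * ln(1 + N/alpha)`` for alpha.

    The left side is strictly increasing in alpha with supremum ``N``, so a
    unique positive root exists whenever ``1 <= S < N``. ``S == N`` (every
    individual its own species) has no finite root and returns ``nan`` as an
    explicit undefined flag; downstream regressions drop it.

    Raises ``ValueError`` for ``S < 1`` or ``S > N``.
    """
    S, N = int(S), int(N)
    if S < 1 or S > N:
        raise ValueError(f"need 1 <= S <= N, got S={S}, N={N}")
    if S == N:
        return float("nan")

    def f(a: float) -> float:
        return a * np.log1p(N / a) - S

    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 10.0
        if hi > 1e12:  # unreachable for S < N
            raise RuntimeError("failed to bracket Fisher's alpha")
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16))


def plot_diversity(t: CommunityTable) -> pd.DataFrame:
    """Per-plot N, S, Fisher's alpha and singleton count.

    Empty plots (possible after truncation) get a flagged record with
    ``n_stems = 0`` and ``NaN`` alpha; they are excluded downstream.
    A singleton is a species with abundance exactly 1 *in that plot*.
    """
    rows = []
    for i, pid in enumerate(t.plot_ids):
        row = t.abundance[i]
        n = int(row.sum())
        s = int((row > 0).sum())
        singles = int((row == 1).sum())
        alpha = fishers_alpha(s, n) if n > 0 else float("nan")
        rows.append(
            {
                "plot_id": pid,
                "n_stems": n,
                "n_species": s,
                "fisher_alpha": alpha,
                "n_singletons": singles,
            }
        )
    return pd.DataFrame(rows).set_index("plot_id")


def paired_alpha_test(
    ams: pd.DataFrame, ims: pd.DataFrame
) -> tuple[float, int, float]:
    """Two-sided paired t-test on per-plot Fisher's alpha differences.

    ``ams`` and ``ims`` are :func:`plot_diversity` frames over the same
    plots. Pairs with an undefined alpha on either side are dropped; at
    least 3 usable pairs are required. Returns ``(t, df, p)``. Degenerate
    zero-variance differences return ``t = 0, p = 1`` (all-zero) or
    ``t = ±inf, p = 0`` (constant nonzero shift).
    """
    if set(ams.index) != set(ims.index):
        raise ValueError("AMS and IMS records cover different plot sets")
    d = (
        ams["fisher_alpha"] - ims.loc[ams.index, "fisher_alpha"]
    ).to_numpy(float)
    d = d[np.isfinite(d)]
    n = d.size
    if n < 3:
        raise ValueError(f"need >= 3 plot pairs with defined alpha, got {n}")
    mean = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, df, 1.0
        return float(np.copysign(np.inf, mean)), df, 0.0
    tstat = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(tstat), df)
    return float(tstat), df, float(p)


def rank_abundance(t: CommunityTable) -> tuple[pd.DataFrame, int]:
    """Dataset-level rank-abundance curve and singleton count.

    Species totals sorted descending, ties broken by species label so the
    order is deterministic. The singleton count here is the number of
    species with total abundance 1 over the whole dataset (the quantity the
    rank-abundance tail comparison is about).
    """
    totals = t.species_totals
    order = sorted(range(t.n_species), key=lambda j: (-totals[j], t.species_ids[j]))
    df = pd.DataFrame(
        {
            "rank": np.arange(1, t.n_species + 1),
            "species_id": [t.species_ids[j] for j in order],
            "abundance": totals[order],
        }
    )
    return df, int((totals == 1).sum())
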