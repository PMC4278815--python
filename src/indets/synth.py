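"""Synthetic spatially structured metacommunities.

The generator emulates the statistical structure of large tropical tree
inventories: a regional species pool with a Fisher logseries abundance
distribution, plots sampled multinomially from the pool with a Gaussian
spatial kernel per species (producing distance decay of similarity), a
rarity-biased identification-loss process that marks a target fraction of
species as unidentified (preferentially the rare ones), and a random
partition of species into genera.

Defaults correspond to a single study region of 60 one-hectare plots with
500 stems each, a regional pool of Fisher's alpha 35, 30% of morpho-species
unidentified with rarity bias 2, and about 3 species per genus.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .community import (
    STATUS_IDENTIFIED,
    STATUS_UNIDENTIFIED,
    CommunityTable,
    PlotGeo,
    ValidationError,
)
import pandas as pd


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the generator; every draw flows from ``seed``."""

    n_plots: int = 60
    stems_per_plot: int = 500
    pool_alpha: float = 35.0          # Fisher's alpha of the regional pool
    pool_stems: int = 300_000         # regional abundance total
    landscape_size: float = 300.0     # km, side of the square landscape
    range_sd: float = 75.0            # km, Gaussian range-kernel width
    unid_species_frac: float = 0.3    # target fraction of species unidentified
    unid_bias: float = 2.0            # rarity-bias strength (0 = unbiased)
    genus_mean_size: float = 3.0      # mean species per genus
    seed: int = 0

    def __post_init__(self):
        if self.n_plots < 1 or self.stems_per_plot < 1 or self.pool_stems < 1:
            raise ValidationError("counts must be positive")
        if self.pool_alpha <= 0 or self.landscape_size <= 0 or self.range_sd <= 0:
            raise ValidationError("pool_alpha, landscape_size, range_sd must be > 0")
        if not 0 <= self.unid_species_frac < 1:
            raise ValidationError("unid_species_frac must be in [0, 1)")
        if self.unid_bias < 0:
            raise ValidationError("unid_bias must be >= 0")
        if self.genus_mean_size < 1:
            raise ValidationError("genus_mean_size must be >= 1")


def _rng(seed, stream: int) -> np.random.Generator:
    # independent, reproducible stream per stage
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def sample_logseries_pool(
    pool_alpha: float, pool_stems: int, seed: int
) -> np.ndarray:
    """Draw regional species abundances from a Fisher logseries.

    The species count is set to the logseries expectation
    ``S = round(alpha * ln(1 + N/alpha))`` (capped at ``N``), abundances are
    drawn iid from the logseries pmf ``p(n) ∝ x**n / n`` with
    ``x = N/(N + alpha)``, and the exact stem total is then enforced by
    adjusting the most abundant species (topping it up, or walking the
    excess off the largest species while keeping every abundance >= 1).
    Anchoring S to its expectation keeps the generating alpha recoverable
    from the realized (S, N) — the property that makes ``pool_alpha`` a
    meaningful knob — which a fully emergent species count would not give
    (its relative spread is about ``1/sqrt(alpha)``).
    """
    if pool_alpha <= 0 or pool_stems < 1:
        raise ValidationError("pool_alpha > 0 and pool_stems >= 1 required")
    rng = _rng(seed, 1)
    n_stems = int(pool_stems)
    s_target = int(round(pool_alpha * np.log1p(n_stems / pool_alpha)))
    s_target = min(max(s_target, 1), n_stems)
    x = n_stems / (n_stems + pool_alpha)
    draws = np.asarray(
        stats.logser.rvs(x, size=s_target, random_state=rng), dtype=np.int64
    )
    draws = -np.sort(-draws)  # descending
    diff = n_stems - int(draws.sum())
    if diff > 0:
        draws[0] += diff
    else:
        j = 0
        while diff < 0:
            take = min(-diff, draws[j] - 1)
            draws[j] -= take
            diff += take
            j += 1
    return -np.sort(-draws)


def generate_landscape(cfg: SyntheticConfig) -> tuple[CommunityTable, PlotGeo]:
    """Place plots and species on the landscape and sample plot composition.

    Plots are uniform on the square ``[0, L]²``; each species has a range
    center uniform on the landscape; the ``stems_per_plot`` stems of each
    plot are multinomial with species weights proportional to regional
    abundance times the Gaussian kernel ``exp(-d² / (2·range_sd²))`` of the
    plot-to-center distance ``d``. Species never sampled anywhere are
    dropped. All species start with status ``identified`` and genus unknown
    pending :func:`assign_genera`.
    """
    pool = sample_logseries_pool(cfg.pool_alpha, cfg.pool_stems, cfg.seed)
    s_pool = len(pool)
    rng = _rng(cfg.seed, 2)
    L = cfg.landscape_size
    plot_xy = rng.uniform(0, L, size=(cfg.n_plots, 2))
    centers = rng.uniform(0, L, size=(s_pool, 2))
    d2 = ((plot_xy[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    weights = pool[None, :] * np.exp(-d2 / (2.0 * cfg.range_sd**2))
    # guard: a plot far from every range center still needs a valid multinomial
    weights = np.where(
        weights.sum(axis=1, keepdims=True) > 0, weights, pool[None, :].astype(float)
    )
    weights /= weights.sum(axis=1, keepdims=True)
    ab = np.stack(
        [rng.multinomial(cfg.stems_per_plot, w) for w in weights]
    ).astype(np.int64)
    present = ab.sum(axis=0) > 0
    ab = ab[:, present]
    species_ids = [f"sp{j:05d}" for j in np.flatnonzero(present)]
    plot_ids = [f"plot{i:03d}" for i in range(cfg.n_plots)]
    meta = pd.DataFrame(
        {"status": STATUS_IDENTIFIED, "genus": "unknown"},
        index=pd.Index(species_ids, name="species_id"),
    )
    t = CommunityTable(tuple(plot_ids), tuple(species_ids), ab, meta)
    geo = PlotGeo(tuple(plot_ids), "planar", plot_xy[:, 0], plot_xy[:, 1])
    return t, geo


def apply_identification_model(
    t: CommunityTable, unid_species_frac: float, unid_bias: float, seed: int
) -> CommunityTable:
    """Mark species unidentified, preferentially the rare ones.

    Per-species inclusion probabilities are proportional to
    ``softmax(-unid_bias · ln(total abundance))`` over species, scaled so the
    expected unidentified *species* fraction equals ``unid_species_frac``
    (probabilities above 1 are capped and the remainder redistributed).
    ``unid_bias = 0`` makes status independent of abundance. Status is a
    species-level property, consistent across plots.
    """
    if not 0 <= unid_species_frac < 1:
        raise ValidationError("unid_species_frac must be in [0, 1)")
    if np.any(t.statuses != STATUS_IDENTIFIED):
        raise ValidationError("table already carries unidentified species")
    if unid_species_frac == 0:
        return t
    totals = t.species_totals.astype(float)
    logw = -unid_bias * np.log(totals)
    logw -= logw.max()
    w = np.exp(logw)
    target = unid_species_frac * t.n_species
    p = target * w / w.sum()
    # water-fill: cap at 1 and rescale the rest to preserve the expected count
    for _ in range(t.n_species):
        over = p >= 1.0
        if not over.any() or over.all():
            break
        deficit = target - over.sum()
        free = ~over
        scale = deficit / p[free].sum() if p[free].sum() > 0 else 0.0
        newp = p.copy()
        newp[over] = 1.0
        newp[free] = p[free] * scale
        if np.allclose(newp, p):
            p = newp
            break
        p = newp
    p = np.clip(p, 0.0, 1.0)
    rng = _rng(seed, 3)
    unid = rng.random(t.n_species) < p
    meta = t.species_meta.copy()
    meta.loc[np.asarray(t.species_ids)[unid], "status"] = STATUS_UNIDENTIFIED
    return CommunityTable(t.plot_ids, t.species_ids, t.abundance, meta)


def assign_genera(
    t: CommunityTable, genus_mean_size: float, seed: int
) -> CommunityTable:
    """Partition species into genera by sequential random assignment.

    Each species founds a new genus with probability ``1/genus_mean_size``,
    otherwise joins a uniformly chosen existing genus, giving an expected
    genus size of ``genus_mean_size``. Every species receives a label.
    """
    if genus_mean_size < 1:
        raise ValidationError("genus_mean_size must be >= 1")
    rng = _rng(seed, 4)
    p_new = 1.0 / genus_mean_size
    labels = np.empty(t.n_species, dtype=object)
    n_genera = 0
    for j in range(t.n_species):
        if n_genera == 0 or rng.random() < p_new:
            labels[j] = f"gen{n_genera:04d}"
            n_genera += 1
        else:
            labels[j] = f"gen{rng.integers(n_genera):04d}"
    meta = t.species_meta.copy()
    meta.loc[list(t.species_ids), "genus"] = labels
    return CommunityTable(t.plot_ids, t.species_ids, t.abundance, meta)


def simulate_dataset(cfg: SyntheticConfig) -> tuple[CommunityTable, PlotGeo]:
    """Full generator: landscape → genera → identification statuses."""
    t, geo = generate_landscape(cfg)
    t = assign_genera(t, cfg.genus_mean_size, cfg.seed)
    t = apply_identification_model(
        t, cfg.unid_species_frac, cfg.unid_bias, cfg.seed
    )
    return t, geo
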