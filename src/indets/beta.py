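"""Pairwise similarity indices, the Raup–Crick null model, and distances.

Similarities: Bray–Curtis (abundance-based), Jaccard and Sørensen
(presence/absence). The Raup–Crick metric is a Monte-Carlo null model: for
each plot pair it asks how often randomly assembled communities of the two
observed richnesses share at least as many species as observed, drawing
species without replacement with probability proportional to their
occurrence frequency across plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .community import CommunityTable, PlotGeo

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class PairwiseMatrix:
    """Symmetric plot × plot matrix of similarity, dissimilarity or km."""

    labels: tuple
    values: np.ndarray
    kind: str  # "similarity" | "dissimilarity" | "distance_km"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if self.kind not in ("similarity", "dissimilarity", "distance_km"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "similarity":
            expected_diag = 1.0
        else:
            expected_diag = 0.0
        if not np.allclose(np.diag(v), expected_diag):
            raise ValueError(f"diagonal must be {expected_diag} for {self.kind}")
        if self.kind in ("similarity", "dissimilarity"):
            if v.min() < -1e-12 or v.max() > 1 + 1e-12:
                raise ValueError("similarity/dissimilarity values must be in [0,1]")
            v = np.clip(v, 0.0, 1.0)
        elif v.min() < 0:
            raise ValueError("distances must be >= 0")
        v = np.ascontiguousarray(v)
        v.setflags(write=False)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Strictly-lower-triangle entries in scipy condensed order."""
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels),
                            columns=list(self.labels))

    def to_similarity(self) -> "PairwiseMatrix":
        if self.kind == "similarity":
            return self
        if self.kind != "dissimilarity":
            raise ValueError("cannot convert distances to similarity")
        v = 1.0 - self.values
        np.fill_diagonal(v, 1.0)
        return PairwiseMatrix(self.labels, v, "similarity")

    def to_dissimilarity(self) -> "PairwiseMatrix":
        if self.kind == "dissimilarity":
            return self
        if self.kind != "similarity":
            raise ValueError("cannot convert distances to dissimilarity")
        v = 1.0 - self.values
        np.fill_diagonal(v, 0.0)
        return PairwiseMatrix(self.labels, v, "dissimilarity")


def write_pairwise(m: PairwiseMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kind: {m.kind}\n")
        m.to_frame().rename_axis("plot_id").to_csv(fh)


def read_pairwise(path) -> PairwiseMatrix:
    with open(path) as fh:
        header = fh.readline().strip()
        kind = header.split(":", 1)[1].strip() if header.startswith("# kind") else "similarity"
        df = pd.read_csv(fh, index_col=0)
    return PairwiseMatrix(tuple(df.index.astype(str)), df.to_numpy(), kind)


def _nonempty(t: CommunityTable) -> CommunityTable:
    t = t.drop_empty_plots()
    if t.n_plots < 2:
        raise ValueError("need at least two non-empty plots")
    return t


def bray_curtis(t: CommunityTable) -> PairwiseMatrix:
    """Bray–Curtis similarity, ``1 - Σ|x_i - y_i| / Σ(x_i + y_i)``."""
    t = _nonempty(t)
    sim = 1.0 - squareform(pdist(t.abundance.astype(float), metric="braycurtis"))
    np.fill_diagonal(sim, 1.0)
    return PairwiseMatrix(t.plot_ids, sim, "similarity")


def jaccard(t: CommunityTable) -> PairwiseMatrix:
    """Jaccard similarity ``a/(a+b+c)`` on presence/absence."""
    t = _nonempty(t)
    sim = 1.0 - squareform(pdist(t.presence(), metric="jaccard"))
    np.fill_diagonal(sim, 1.0)
    return PairwiseMatrix(t.plot_ids, sim, "similarity")


def sorensen(t: CommunityTable) -> PairwiseMatrix:
    """Sørensen similarity ``2a/(2a+b+c)``: shared species count double."""
    t = _nonempty(t)
    sim = 1.0 - squareform(pdist(t.presence(), metric="dice"))
    np.fill_diagonal(sim, 1.0)
    return PairwiseMatrix(t.plot_ids, sim, "similarity")


def raup_crick(
    t: CommunityTable,
    n_reps: int = 999,
    seed: int = 0,
    frequency_weighted: bool = True,
) -> PairwiseMatrix:
    """Raup–Crick dissimilarity under the frequency-dependent null model.

    For each pair of plots with observed richnesses ``a1, a2`` and observed
    shared species ``SS``, the null draws (``n_reps`` times) ``a1`` and
    ``a2`` species without replacement from the table's species pool with
    selection probability proportional to occurrence frequency (number of
    plots occupied, computed on ``t``; uniform when
    ``frequency_weighted=False``), counts the null shared ``SS*``, and
    scores ``beta_RC = [#(SS* > SS) + 0.5 · #(SS* = SS)] / n_reps``.
    Ties get half weight so beta_RC is centered at 0.5 under the null.

    The without-replacement weighted draw is vectorised with the Gumbel
    top-k trick: per replicate and plot, species are ranked by
    ``log w + Gumbel noise`` and the top ``a_i`` taken.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    t = _nonempty(t)
    pres = t.presence()
    P, S = pres.shape
    richness = pres.sum(axis=1)
    if np.any(richness > S):  # impossible by construction; guard anyway
        raise ValueError("plot richness exceeds pool size")
    obs_shared = (pres.astype(np.int64) @ pres.astype(np.int64).T).astype(np.float32)
    occ = pres.sum(axis=0).astype(float)
    logw = np.log(occ) if frequency_weighted else np.zeros(S)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 5]))
    gt = np.zeros((P, P), dtype=np.int64)
    eq = np.zeros((P, P), dtype=np.int64)
    chunk = max(1, min(n_reps, int(2**22 / (P * S + 1))))  # bounds working memory
    done = 0
    thresh = richness.astype(np.int64)[None, :, None]
    while done < n_reps:
        c = min(chunk, n_reps - done)
        keys = rng.gumbel(size=(c, P, S)) + logw[None, None, :]
        # rank of each species within its (rep, plot) row; top-a_i selected
        order = np.argsort(-keys, axis=2)
        ranks = np.empty_like(order)
        np.put_along_axis(
            ranks, order, np.broadcast_to(np.arange(S), (c, P, S)), axis=2
        )
        member = (ranks < thresh).astype(np.float32)
        ss_star = np.matmul(member, member.transpose(0, 2, 1))
        gt += (ss_star > obs_shared[None]).sum(axis=0)
        eq += (ss_star == obs_shared[None]).sum(axis=0)
        done += c
    beta = (gt + 0.5 * eq) / n_reps
    beta = 0.5 * (beta + beta.T)  # symmetric by construction; enforce exactly
    np.fill_diagonal(beta, 0.0)
    return PairwiseMatrix(t.plot_ids, beta, "dissimilarity")


def geographic_distance(g: PlotGeo) -> PairwiseMatrix:
    """Plot-to-plot distances in km.

    Geographic mode uses the haversine great-circle distance on a sphere of
    radius 6371 km; planar mode uses plain Euclidean distance on km
    coordinates.
    """
    if g.coord_mode == "planar":
        xy = np.column_stack([g.x, g.y])
        d = squareform(pdist(xy, metric="euclidean"))
    else:
        lon = np.radians(g.x)
        lat = np.radians(g.y)
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        h = (
            np.sin(dlat / 2) ** 2
            + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
        )
        d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
        np.fill_diagonal(d, 0.0)
        d = 0.5 * (d + d.T)
    return PairwiseMatrix(g.plot_ids, d, "distance_km")
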