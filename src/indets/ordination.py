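"""Mantel permutation test and 2-D nonmetric multidimensional scaling.

The Mantel statistic is the Pearson correlation between the strictly-lower
triangles of two matched plot × plot matrices, with significance from joint
row-and-column permutation of one matrix. NMDS embeds plots in the plane so
interpoint distances best preserve the rank order of the dissimilarities
(Kruskal stress-1); scores are centered at the origin and rotated to
principal axes so axis 1 carries the most variance, following the usual
metaMDS-style convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from .beta import PairwiseMatrix


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int


@dataclass(frozen=True)
class NMDSResult:
    labels: tuple
    scores: np.ndarray  # plots × 2, centered, principal-axis aligned
    stress: float       # Kruskal stress-1 of the best start
    n_starts: int
    best_start: int
    converged: bool


def mantel_test(
    A: PairwiseMatrix, B: PairwiseMatrix, n_perm: int = 999, seed: int = 0
) -> MantelResult:
    """One-sided (greater) Mantel test between two matched matrices.

    ``r`` is the Pearson correlation of the condensed lower triangles;
    ``p = (1 + #{r_perm >= r}) / (1 + n_perm)`` over joint row/column
    permutations of ``B``.
    """
    if A.labels != B.labels:
        raise ValueError("matrices must share labels in the same order")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a = A.condensed()
    r = float(pearsonr(a, B.condensed()).statistic)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 6]))
    n = A.n
    count = 0
    az = (a - a.mean()) / a.std()
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = B.values[np.ix_(perm, perm)]
        bvec = bp[np.tril_indices(n, k=-1)]
        rp = float(az @ ((bvec - bvec.mean()) / bvec.std()) / az.size)
        if rp >= r - 1e-12:
            count += 1
    return MantelResult(r=r, p=(1 + count) / (1 + n_perm), n_perm=n_perm)


def kruskal_stress1(dissim: np.ndarray, scores: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against dissimilarities.

    Disparities are the isotonic (monotone non-decreasing) regression of the
    configuration distances on the dissimilarity order;
    ``stress1 = sqrt(Σ(d - d̂)² / Σd²)``.
    """
    d = pdist(scores)
    order = np.argsort(dissim, kind="stable")
    iso = IsotonicRegression()
    dhat = np.empty_like(d)
    dhat[order] = iso.fit_transform(np.arange(d.size), d[order])
    return float(np.sqrt(((d - dhat) ** 2).sum() / (d**2).sum()))


def nmds(
    D: PairwiseMatrix,
    n_starts: int = 20,
    max_iter: int = 200,
    seed: int = 0,
    eps: float = 1e-6,
) -> NMDSResult:
    """2-D nonmetric MDS, best of ``n_starts`` random starts.

    Each start runs nonmetric SMACOF (convergence when the stress change
    drops below ``eps``); the winner is the configuration with the lowest
    Kruskal stress-1. Scores are centered (column means 0) and rotated to
    principal axes, so axis 1 has the larger variance.
    """
    if D.kind != "dissimilarity":
        raise ValueError("nmds expects a dissimilarity matrix")
    if D.n < 4:
        raise ValueError("need at least 4 plots for a 2-D ordination")
    ss = np.random.SeedSequence([int(seed), 7]).spawn(n_starts)
    dvec = D.condensed()
    best = None
    for k in range(n_starts):
        pos, _, n_iter = smacof(
            D.values,
            metric=False,
            n_components=2,
            init=None,
            n_init=1,
            max_iter=max_iter,
            eps=eps,
            random_state=int(ss[k].generate_state(1)[0]),
            normalized_stress=True,
            return_n_iter=True,
        )
        s1 = kruskal_stress1(dvec, pos)
        if best is None or s1 < best[0]:
            best = (s1, pos, k, n_iter)
    stress, pos, best_start, n_iter = best
    pos = pos - pos.mean(axis=0, keepdims=True)
    # principal-axis rotation (distances, hence stress, are preserved)
    _, _, vt = np.linalg.svd(pos, full_matrices=False)
    pos = pos @ vt.T
    pos = pos - pos.mean(axis=0, keepdims=True)
    return NMDSResult(
        labels=D.labels,
        scores=pos,
        stress=stress,
        n_starts=n_starts,
        best_start=best_start,
        converged=bool(n_iter < max_iter),
    )


def align_axis_sign(reference: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Flip ``other`` if negatively correlated with ``reference``.

    NMDS axes have an arbitrary sign; comparisons of axis scores are only
    meaningful after this alignment.
    """
    c = np.corrcoef(reference, other)[0, 1]
    return -other if c < 0 else other
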