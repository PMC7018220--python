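"""Assign individuals to resistant/susceptible haplotype groups per region.

For each region (or contig): a pairwise genetic distance between
individuals (count of differing dosage codes), classical multidimensional
scaling to two dimensions, k-means with k = 2, and the labelling rule that
the cluster containing less than half of the susceptible-population
individuals is the 'R' group.  An exact tie flags the whole region as
ambiguous rather than picking a side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tables import MISSING, GenotypeMatrix, PopulationPanel, Region

log = logging.getLogger(__name__)


def pairwise_diff(G: np.ndarray) -> np.ndarray:
    """Distance matrix: count of sites at which two individuals' dosage
    codes differ, over pairwise-complete sites.

    ``G`` is (n_sites, n_samples) with :data:`MISSING` for no-calls.  A
    pair sharing zero typed sites has no defined distance and raises.
    """
    X = np.asarray(G)
    if X.shape[0] < 1 or X.shape[1] < 2:
        raise ValueError("need >= 1 SNP and >= 2 individuals")
    valid = (X != MISSING).astype(np.int32)  # (m, n)
    shared = valid.T @ valid
    if np.any(shared == 0):
        raise ValueError("a pair of individuals shares no typed site")
    n = X.shape[1]
    D = np.zeros((n, n), dtype=float)
    # dosage equality over pairwise-complete sites, column-blocked
    for i in range(n):
        gi = X[:, i][:, None]
        both = (valid[:, i][:, None] & valid) > 0
        diff = (X != gi) & both
        D[i] = diff.sum(axis=0)
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def classical_mds(D: np.ndarray, k: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-centers the squared distances, eigendecomposes the Gram matrix
    and returns the top-``k`` axes scaled by the square roots of their
    (nonnegative) eigenvalues.  Negative eigenvalues — non-Euclidean
    distances — are discarded with a logged notice; if fewer than ``k``
    positive eigenvalues exist, a lower-dimensional embedding is returned
    with a warning.
    """
    D = np.asarray(D, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    n_neg = int(np.sum(w < -1e-10 * max(1.0, abs(w[0]))))
    if n_neg:
        log.info("classical_mds: %d negative eigenvalues discarded", n_neg)
    pos = w > 1e-12 * max(1.0, abs(w[0]))
    n_pos = int(pos.sum())
    if n_pos < k:
        import warnings

        warnings.warn(f"only {n_pos} positive eigenvalues; embedding in {max(n_pos, 1)}-D", stacklevel=2)
        k = max(n_pos, 1)
    return V[:, :k] * np.sqrt(np.clip(w[:k], 0.0, None))


def kmeans2(coords: np.ndarray, seed: int = 0, n_init: int = 20) -> np.ndarray:
    """Two-cluster k-means labels, best of ``n_init`` k-means++ restarts."""
    from sklearn.cluster import KMeans

    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    if coords.shape[0] < 2:
        raise ValueError("need >= 2 points")
    if np.allclose(coords, coords[0]):
        raise ValueError("all points identical; no separation to cluster")
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed)
    return km.fit_predict(coords)


@dataclass
class GroupAssignment:
    region_id: str
    groups: pd.Series  # per sample: 'R' | 'S' | 'ambiguous'
    r_proportion: pd.Series  # per population: fraction of individuals in R group
    coords: np.ndarray
    inertia_ratio: float  # within-cluster / total sum of squares
    ambiguous: bool = False


def assign_r_group(
    labels: np.ndarray,
    samples: list[str],
    populations: dict[str, str],
    panel: PopulationPanel,
    region_id: str = "",
    coords: np.ndarray | None = None,
) -> GroupAssignment:
    """Decide which k-means cluster is the resistant haplotype group.

    The cluster holding the minority of susceptible-population individuals
    is 'R'; an exact tie marks the region ambiguous (every individual
    labelled 'ambiguous').  Reports the per-population proportion of
    individuals carrying the R-group haplotype.
    """
    classes = panel.classes()
    if not classes:
        raise ValueError("panel lacks class labels")
    labels = np.asarray(labels)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    pops = np.array([populations[s] for s in samples], dtype=object)
    is_s = np.array([classes[p] == "S" for p in pops])
    s_in_0 = int(np.sum(is_s & (labels == 0)))
    s_in_1 = int(np.sum(is_s & (labels == 1)))
    if s_in_0 == s_in_1:
        group = pd.Series(["ambiguous"] * len(samples), index=samples)
        rprop = pd.Series(
            {p: float("nan") for p in panel.populations}, name="r_proportion"
        )
        return GroupAssignment(
            region_id=region_id,
            groups=group,
            r_proportion=rprop,
            coords=coords if coords is not None else np.zeros((len(samples), 0)),
            inertia_ratio=_inertia_ratio(coords, labels) if coords is not None else float("nan"),
            ambiguous=True,
        )
    r_cluster = 0 if s_in_0 < s_in_1 else 1
    group = pd.Series(np.where(labels == r_cluster, "R", "S"), index=samples)
    rprop = {}
    for p in panel.populations:
        mask = pops == p
        rprop[p] = float(np.mean(group[mask] == "R")) if mask.any() else float("nan")
    return GroupAssignment(
        region_id=region_id,
        groups=group,
        r_proportion=pd.Series(rprop, name="r_proportion"),
        coords=coords if coords is not None else np.zeros((len(samples), 0)),
        inertia_ratio=_inertia_ratio(coords, labels) if coords is not None else float("nan"),
    )


def _inertia_ratio(coords, labels) -> float:
    coords = np.asarray(coords, dtype=float)
    total = float(((coords - coords.mean(axis=0)) ** 2).sum())
    within = 0.0
    for lab in (0, 1):
        pts = coords[labels == lab]
        if len(pts):
            within += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return within / total if total > 0 else float("nan")


def haplotype_groups_for_region(
    gm: GenotypeMatrix,
    panel: PopulationPanel,
    region: Region,
    seed: int = 0,
) -> GroupAssignment:
    """End-to-end distance -> MDS -> k-means -> R/S labelling for a region."""
    in_r = np.flatnonzero(
        (gm.chrom == region.chrom) & (gm.pos >= region.start) & (gm.pos < region.end)
    )
    if in_r.size == 0:
        raise ValueError(f"no SNPs in region {region.region_id}")
    D = pairwise_diff(gm.G[in_r])
    coords = classical_mds(D, k=2)
    labels = kmeans2(coords, seed=seed)
    return assign_r_group(
        labels, gm.samples, gm.populations, panel, region_id=region.region_id, coords=coords
    )
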