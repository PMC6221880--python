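"""Marker-based genomic relationship matrices and kinship-based grouping.

The genomic relationship matrix here is the VanRaden matrix

    2K = W W' / (2 * sum_i p_i (1 - p_i)),

where ``W`` is the column-centred dosage matrix and ``p_i`` the frequency of
the second (counted) allele of marker ``i``.  On this scale ``A = 2K`` plays
the role of the additive numerator relationship matrix: the covariance of the
additive genetic effects is ``2K * sigma_a^2``.

For compressed BLUP, individuals are clustered on kinship (UPGMA by default)
and the relationship between two groups is the average relationship between
their members; a group's self-relationship averages the full within-group
block, diagonal included, so that ``g = n`` grouping returns the original
matrix unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "GenotypeMatrix",
    "KinshipMatrix",
    "GroupAssignment",
    "vanraden_kinship",
    "group_kinship",
    "cluster_individuals",
]


@dataclass
class GenotypeMatrix:
    """Dosage-coded biallelic genotypes with a marker map.

    Parameters
    ----------
    ids : list of str
        Individual identifiers, length ``n``.
    codes : ndarray of shape (n, m)
        Count of the second allele in {0, 1, 2}; ``NaN`` marks missing calls.
    marker_map : DataFrame
        One row per marker with columns ``marker``, ``chrom``, ``pos``
        (1-based bp).
    """

    ids: list
    codes: np.ndarray
    marker_map: pd.DataFrame

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=float)
        self.ids = list(self.ids)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D individuals x markers array")
        if len(self.ids) != self.codes.shape[0]:
            raise ValueError("number of ids does not match genotype rows")
        if len(self.ids) < 2:
            raise ValueError("need at least 2 individuals")
        if len(self.marker_map) != self.codes.shape[1]:
            raise ValueError("marker map length does not match genotype columns")
        ok = np.isnan(self.codes) | np.isin(self.codes, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosage codes must be 0/1/2 or missing")
        if self.marker_map["marker"].duplicated().any():
            raise ValueError("duplicated marker names")
        if (self.marker_map["pos"] <= 0).any():
            raise ValueError("marker positions must be positive")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def m(self) -> int:
        return self.codes.shape[1]

    def subset_individuals(self, ids) -> "GenotypeMatrix":
        pos = {v: i for i, v in enumerate(self.ids)}
        idx = np.array([pos[i] for i in ids], dtype=int)
        return GenotypeMatrix(list(ids), self.codes[idx], self.marker_map)


@dataclass
class KinshipMatrix:
    """Symmetric relationship matrix on the ``2K`` (VanRaden) scale."""

    ids: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.ids = list(self.ids)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship dimension does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("kinship matrix is not symmetric to 1e-8")
        if not np.isfinite(np.diag(self.values)).all():
            raise ValueError("non-finite kinship diagonal")
        # enforce exact symmetry for downstream eigendecompositions
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.ids)

    def reorder(self, ids) -> "KinshipMatrix":
        pos = {v: i for i, v in enumerate(self.ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise KeyError(f"ids absent from kinship matrix: {missing}")
        idx = np.array([pos[i] for i in ids], dtype=int)
        return KinshipMatrix(list(ids), self.values[np.ix_(idx, idx)])


@dataclass
class GroupAssignment:
    """Partition of individuals into ``g`` non-empty groups (indices 1..g)."""

    ids: list
    group_index: np.ndarray
    g: int

    def __post_init__(self):
        self.group_index = np.asarray(self.group_index, dtype=int)
        self.ids = list(self.ids)
        if len(self.ids) != self.group_index.size:
            raise ValueError("group_index length does not match ids")
        present = np.unique(self.group_index)
        if present.min() < 1 or present.max() > self.g or present.size != self.g:
            raise ValueError("group indices must cover 1..g with no empty group")

    @property
    def compression_level(self) -> float:
        """Average number of individuals per group, n/g."""
        return len(self.ids) / self.g

    @property
    def group_ids(self) -> list:
        return [f"grp{j}" for j in range(1, self.g + 1)]


def vanraden_kinship(G: GenotypeMatrix, subset=None) -> KinshipMatrix:
    """VanRaden genomic relationship 2K = WW'/(2 sum p_i(1-p_i)).

    ``p_i`` is half the mean dosage over non-missing calls of marker ``i``;
    missing dosages contribute 0 after centring (mean imputation).  The
    denominator sums over the marker ``subset`` (all markers by default), so
    monomorphic markers contribute nothing to either numerator or denominator.
    """
    codes = G.codes if subset is None else G.codes[:, np.asarray(subset, dtype=int)]
    if codes.shape[1] == 0:
        raise ValueError("zero denominator: empty marker subset")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        p = np.nanmean(codes, axis=0) / 2.0
    p = np.where(np.isfinite(p), p, 0.0)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("zero denominator: all markers monomorphic")
    W = codes - 2.0 * p
    W = np.where(np.isnan(W), 0.0, W)
    K2 = (W @ W.T) / denom
    return KinshipMatrix(G.ids, 0.5 * (K2 + K2.T))


def group_kinship(K: KinshipMatrix, groups: GroupAssignment) -> KinshipMatrix:
    """Block-average a relationship matrix over a group assignment.

    Off-diagonal (a, b) is the mean over all cross pairs of groups a and b;
    the diagonal (a, a) averages the full within-group block including the
    individual diagonal, which makes ``g = n`` an exact identity.
    """
    if list(groups.ids) != list(K.ids):
        groups_pos = {v: i for i, v in enumerate(groups.ids)}
        missing = [i for i in K.ids if i not in groups_pos]
        if missing:
            raise ValueError(f"group assignment does not cover ids: {missing}")
        idx = np.array([groups_pos[i] for i in K.ids], dtype=int)
        gidx = groups.group_index[idx]
    else:
        gidx = groups.group_index
    g = groups.g
    counts = np.bincount(gidx, minlength=g + 1)[1:]
    if (counts == 0).any():
        raise ValueError("empty group in assignment")
    # membership matrix scaled by group size: B = M' K M with M = P diag(1/n_a)
    M = np.zeros((len(K.ids), g))
    M[np.arange(len(K.ids)), gidx - 1] = 1.0 / counts[gidx - 1]
    B = M.T @ K.values @ M
    return KinshipMatrix(groups.group_ids, 0.5 * (B + B.T))


def cluster_individuals(K: KinshipMatrix, g: int, method: str = "average") -> GroupAssignment:
    """Cut a hierarchical clustering of individuals into exactly ``g`` groups.

    Distance is ``max(K) - K_ij`` (non-negative by construction); linkage is
    UPGMA by default (``complete`` and ``ward`` are accepted).  The result is
    deterministic for a given matrix; group labels follow first occurrence in
    individual order, so ties resolve toward the smallest individual index.
    """
    n = K.n
    if not 1 <= g <= n:
        raise ValueError(f"g must be in [1, {n}], got {g}")
    if g == n:
        return GroupAssignment(K.ids, np.arange(1, n + 1), n)
    if g == 1:
        return GroupAssignment(K.ids, np.ones(n, dtype=int), 1)
    D = np.max(K.values) - K.values
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method=method)
    raw = cut_tree(Z, n_clusters=g).ravel()
    # relabel 1..g in order of first occurrence
    relabel, nxt = {}, 1
    out = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = nxt
            nxt += 1
        out[i] = relabel[r]
    return GroupAssignment(K.ids, out, g)
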