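"""Compressed BLUP: groups of individuals as the random effects.

Individuals (reference and inference alike) are clustered on their kinship;
for a candidate number of groups g the individual relationship matrix is
replaced by the g x g block-averaged group relationship matrix, the incidence
matrix maps each phenotyped individual to its group, and the restricted
likelihood of the reference phenotypes selects g.  Plain gBLUP is the g = n
extreme, so the optimized fit can never be worse in likelihood than gBLUP
whenever n is in the grid.  Each individual inherits the BLUP of its group;
groups holding only unphenotyped individuals are predicted through their
kinship with the phenotyped groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import GroupAssignment, KinshipMatrix, cluster_individuals, group_kinship
from .mixedmodel import RemlFit, predict_unphenotyped, reml_fit

__all__ = [
    "CompressionFit",
    "default_g_grid",
    "optimize_compression",
    "cblup_predict",
]


@dataclass
class CompressionFit:
    best_g: int
    groups: GroupAssignment
    group_K: KinshipMatrix
    fit: RemlFit
    profile: pd.DataFrame


def default_g_grid(n: int, max_levels: int = 30) -> np.ndarray:
    """Geometric progression of group numbers from 2 to n (n always included)."""
    if n < 2:
        raise ValueError("need n >= 2")
    g = np.unique(np.round(np.geomspace(2, n, num=min(max_levels, n - 1))).astype(int))
    return g[(g >= 2) & (g <= n)]


def optimize_compression(
    y_ref,
    X_ref,
    ref_ids,
    K_full: KinshipMatrix,
    g_grid=None,
    method: str = "average",
) -> CompressionFit:
    """Choose the number of groups by restricted likelihood.

    Clustering uses the kinship of *all* individuals in ``K_full``; only the
    reference phenotypes enter the likelihood.  g = 1 is excluded (the single
    group's BLUP is confounded with the overall mean); ties in -2LL resolve
    toward larger g (less compression, closest to gBLUP).
    """
    n = K_full.n
    if g_grid is None:
        g_grid = default_g_grid(n)
    g_grid = np.unique(np.asarray(g_grid, dtype=int))
    if np.any(g_grid == 1):
        warnings.warn("g=1 excluded: the group BLUP is confounded with the overall mean")
        g_grid = g_grid[g_grid != 1]
    if g_grid.size == 0:
        raise ValueError("empty group-number grid after excluding g=1")
    if g_grid.min() < 2 or g_grid.max() > n:
        raise ValueError(f"g values must lie in [2, {n}]")

    pos = {v: i for i, v in enumerate(K_full.ids)}
    missing = [i for i in ref_ids if i not in pos]
    if missing:
        raise KeyError(f"reference ids absent from kinship matrix: {missing}")
    ref_pos = np.array([pos[i] for i in ref_ids], dtype=int)

    y_ref = np.asarray(y_ref, dtype=float).ravel()
    best = None  # (neg2LL, g, groups, gK, fit)
    rows = []
    for g in g_grid:
        groups = cluster_individuals(K_full, int(g), method=method)
        gK = group_kinship(K_full, groups)
        Z_levels = groups.group_index[ref_pos] - 1
        fit = reml_fit(y_ref, X_ref, gK.values, Z_levels=Z_levels, level_ids=gK.ids)
        rows.append(
            {"g": int(g), "compression_level": n / g, "neg2LL": fit.neg2LL}
        )
        if best is None or fit.neg2LL < best[0] - 1e-12 or (
            abs(fit.neg2LL - best[0]) <= 1e-12 and g > best[1]
        ):
            best = (fit.neg2LL, int(g), groups, gK, fit)
    _, best_g, groups, gK, fit = best
    return CompressionFit(
        best_g=best_g, groups=groups, group_K=gK, fit=fit, profile=pd.DataFrame(rows)
    )


def cblup_predict(compfit: CompressionFit, ref_ids=None, inf_ids=None) -> pd.Series:
    """Per-individual predictions: fixed-effect intercept part plus the BLUP
    of the individual's group (identical within a group)."""
    blup = predict_unphenotyped(compfit.fit, compfit.group_K, ref_ids=ref_ids, inf_ids=None)
    u_by_group = dict(zip(blup.levels, blup.u_hat))
    fixed = float(blup.beta_hat[0])  # intercept; covariates of inference unknown
    groups = compfit.groups
    if inf_ids is not None:
        missing = [i for i in inf_ids if i not in set(groups.ids)]
        if missing:
            raise KeyError(f"inference ids without group assignment: {missing}")
    preds = [
        fixed + u_by_group[f"grp{gi}"] for gi in groups.group_index
    ]
    return pd.Series(preds, index=pd.Index(groups.ids, name="id"), name="prediction")
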