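"""Cross-validated prediction accuracy and shrinkage diagnostics.

The protocol: individuals are randomly split into k folds; each fold in turn
is the inference set whose phenotypes are masked, the rest are the reference.
A model is fitted to the reference only and predicts everyone; the Pearson
correlation between predictions and the observed phenotypes of the inference
fold is recorded, the mean over the k folds is one replicate's accuracy, and
mean +/- standard error over replicates is reported.  When true breeding
values are known (simulated traits) their correlation with predictions and
the regression slope of predictions on true values (shrinkage/inflation,
expected below one for BLUP) are reported as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .compress import cblup_predict, optimize_compression
from .kinship import GenotypeMatrix, KinshipMatrix, vanraden_kinship
from .mixedmodel import predict_unphenotyped, reml_fit
from .superblup import gwas_scan, optimize_super, sblup_predict

__all__ = ["AccuracyReport", "kfold_split", "cross_validate", "inflation_slope"]


@dataclass
class AccuracyReport:
    """Per-replicate fold correlations and their summary for one method."""

    method: str
    fold_correlations: np.ndarray  # (n_reps, k), NaN where undefined
    replicate_means: np.ndarray
    mean_accuracy: float
    se: float
    k: int
    n_reps: int
    metadata: dict = field(default_factory=dict)
    bv_correlations: np.ndarray | None = None  # vs true breeding values
    inflation_slopes: np.ndarray | None = None
    n_flagged_folds: int = 0


def kfold_split(ids, k: int, seed: int = 0) -> list:
    """Random disjoint folds covering all ids, sizes differing by at most 1."""
    ids = list(ids)
    n = len(ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of individuals ({n})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [[ids[i] for i in chunk] for chunk in np.array_split(perm, k)]


def _pc_covariates(G: GenotypeMatrix, n_pcs: int) -> np.ndarray | None:
    if n_pcs <= 0:
        return None
    codes = np.where(np.isnan(G.codes), 0.0, G.codes)
    codes = codes - codes.mean(axis=0)
    _, _, Vt = np.linalg.svd(codes, full_matrices=False)
    return codes @ Vt[:n_pcs].T


def _design(n_ref: int, pcs: np.ndarray | None, ref_idx) -> np.ndarray:
    X = np.ones((n_ref, 1))
    if pcs is not None:
        X = np.column_stack([X, pcs[ref_idx]])
    return X


def _fold_predictions(method, G, K_full, y, ref_ids, inf_ids, pcs, options, caches):
    """Predictions (pd.Series over all ids) from one reference/inference split."""
    pos = {v: i for i, v in enumerate(K_full.ids)} if K_full is not None else {
        v: i for i, v in enumerate(G.ids)
    }
    ref_idx = np.array([pos[i] for i in ref_ids], dtype=int)
    y_ref = y.loc[list(ref_ids)].to_numpy(dtype=float)
    X_ref = _design(len(ref_ids), pcs, ref_idx)

    if method in ("gblup", "kinship"):
        K_ref = K_full.reorder(list(ref_ids))
        fit = reml_fit(y_ref, X_ref, K_ref)
        blup = predict_unphenotyped(fit, K_full, ref_ids=ref_ids, inf_ids=inf_ids)
        pred = pd.Series(
            float(blup.beta_hat[0]) + blup.u_hat, index=pd.Index(blup.levels, name="id")
        )
    elif method == "sblup":
        G_ref = G.subset_individuals(list(ref_ids))
        K_scan = vanraden_kinship(G_ref)
        scan = gwas_scan(y_ref, X_ref, K_scan, G_ref)
        superfit = optimize_super(
            y_ref, X_ref, G_ref, scan,
            s_grid=options.get("s_grid"), t_grid=options.get("t_grid"),
        )
        blup = sblup_predict(superfit, G, ref_ids, inf_ids)
        pred = pd.Series(
            float(blup.beta_hat[0]) + blup.u_hat, index=pd.Index(blup.levels, name="id")
        )
    elif method == "cblup":
        compfit = optimize_compression(
            y_ref, X_ref, ref_ids, K_full,
            g_grid=options.get("g_grid"), method=options.get("linkage", "average"),
        )
        pred = cblup_predict(compfit, ref_ids=ref_ids, inf_ids=inf_ids)
    else:
        raise ValueError(f"unknown method {method!r}")
    return pred


def cross_validate(
    method: str,
    G: GenotypeMatrix | None,
    y: pd.Series,
    k: int = 5,
    n_reps: int = 10,
    seed: int = 0,
    true_bv=None,
    K_full: KinshipMatrix | None = None,
    **method_options,
) -> AccuracyReport:
    """k-fold cross-validated accuracy of one prediction method.

    ``method`` is one of ``gblup``, ``sblup``, ``cblup`` or ``kinship`` (gBLUP
    machinery on a user-supplied ``K_full``, used to compare kinship sources).
    For sBLUP the scan and the (s, t) optimization are re-run on the reference
    of every fold.  Folds with zero-variance predictions or observations are
    recorded as missing and excluded from the replicate mean.
    """
    y = y.dropna()
    ids = list(y.index)
    if method in ("gblup", "cblup", "kinship") and K_full is None:
        if G is None:
            raise ValueError("need genotypes or a kinship matrix")
        K_full = vanraden_kinship(G)
    pcs = _pc_covariates(G, method_options.get("n_pcs", 0)) if G is not None else None

    all_ids = K_full.ids if K_full is not None else G.ids
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_reps)]

    corr = np.full((n_reps, k), np.nan)
    bv_corr = np.full(n_reps, np.nan) if true_bv is not None else None
    slopes = np.full(n_reps, np.nan) if true_bv is not None else None
    n_flagged = 0
    if true_bv is not None:
        true_bv = pd.Series(np.asarray(true_bv, dtype=float), index=all_ids)

    for rep in range(n_reps):
        folds = kfold_split(ids, k, seed=rep_seeds[rep])
        rep_pred = {}
        for j, fold in enumerate(folds):
            inf_ids = fold
            ref_ids = [i for i in ids if i not in set(fold)]
            try:
                pred = _fold_predictions(
                    method, G, K_full, y, ref_ids, inf_ids, pcs, method_options, None
                )
            except ValueError as e:
                if "unknown method" in str(e):
                    raise
                warnings.warn(f"fold {j}: fit failed ({e}); correlation recorded as missing")
                n_flagged += 1
                continue
            p_inf = pred.loc[inf_ids].to_numpy()
            o_inf = y.loc[inf_ids].to_numpy()
            if np.std(p_inf) == 0 or np.std(o_inf) == 0:
                warnings.warn(f"fold {j}: zero-variance predictions or observations")
                n_flagged += 1
            else:
                corr[rep, j] = stats.pearsonr(p_inf, o_inf)[0]
            rep_pred.update(dict(zip(inf_ids, p_inf)))
        if true_bv is not None:
            pv = np.array([rep_pred[i] for i in ids])
            bv = true_bv.loc[ids].to_numpy()
            if np.std(pv) > 0 and np.std(bv) > 0:
                bv_corr[rep] = stats.pearsonr(pv, bv)[0]
                slopes[rep] = inflation_slope(pv, bv)

    rep_means = np.array([np.nanmean(row) if np.any(np.isfinite(row)) else np.nan for row in corr])
    finite = rep_means[np.isfinite(rep_means)]
    mean_acc = float(np.mean(finite)) if finite.size else np.nan
    se = float(np.std(finite, ddof=1) / np.sqrt(finite.size)) if finite.size > 1 else np.nan
    return AccuracyReport(
        method=method,
        fold_correlations=corr,
        replicate_means=rep_means,
        mean_accuracy=mean_acc,
        se=se,
        k=k,
        n_reps=n_reps,
        metadata=dict(seed=seed, **method_options),
        bv_correlations=bv_corr,
        inflation_slopes=slopes,
        n_flagged_folds=n_flagged,
    )


def inflation_slope(predicted, true_bv) -> float:
    """OLS slope of predicted on true breeding values (intercept included).

    BLUP shrinkage makes this slope fall below one; the further below, the
    stronger the inflation of differences among true values relative to
    predictions.
    """
    predicted = np.asarray(predicted, dtype=float).ravel()
    true_bv = np.asarray(true_bv, dtype=float).ravel()
    if predicted.size != true_bv.size or predicted.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.std(true_bv) == 0:
        raise ValueError("true breeding values are constant")
    return float(stats.linregress(true_bv, predicted).slope)
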