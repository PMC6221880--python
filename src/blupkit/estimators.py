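"""scikit-learn style estimators for the BLUP alphabet.

All three estimators are regressors over dosage-coded genotype matrices
(individuals x markers, values 0/1/2, NaN allowed).  ``fit(X, y)`` accepts
NaN entries in ``y``: those rows are unphenotyped individuals that still
contribute to allele frequencies, kinship and (for compressed BLUP)
clustering, mirroring the reference/inference protocol in which genotypes of
the inference set are known while their phenotypes are masked.  ``predict``
returns predictions for rows that were present at fit time from the fitted
joint system, and handles genuinely new genotypes by rebuilding the joint
relationship matrix around the training set.

Fitted attributes follow sklearn conventions (trailing underscore), and the
estimators compose with ``sklearn.base.clone`` and ``get_params``/
``set_params``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .compress import cblup_predict, optimize_compression
from .kinship import GenotypeMatrix, vanraden_kinship
from .mixedmodel import estimate_h2, predict_unphenotyped, reml_fit
from .superblup import gwas_scan, optimize_super, sblup_predict

__all__ = ["GBLUP", "SuperBLUP", "CompressedBLUP"]


def _default_map(m: int) -> pd.DataFrame:
    return pd.DataFrame(
        {"marker": [f"m{j + 1:05d}" for j in range(m)], "chrom": "1", "pos": np.arange(1, m + 1)}
    )


class _BlupBase(RegressorMixin, BaseEstimator):
    def _validate(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be 2-D with one row per phenotype entry")
        obs = np.isfinite(y)
        if obs.sum() < 2:
            raise ValueError("need at least 2 observed phenotypes")
        return X, y, obs

    def _geno(self, X) -> GenotypeMatrix:
        ids = [f"i{j}" for j in range(X.shape[0])]
        mp = getattr(self, "_marker_map", None)
        if mp is None:
            mp = _default_map(X.shape[1])
        return GenotypeMatrix(ids, X, mp)

    def _design(self, n):
        return np.ones((n, 1))

    def _row_key(self, row) -> bytes:
        return np.ascontiguousarray(row).tobytes()

    def predict(self, X):
        check_is_fitted(self, "train_predictions_")
        X = np.asarray(X, dtype=float)
        seen = {self._row_key(r): i for i, r in enumerate(self._X_train)}
        out = np.empty(X.shape[0])
        new_rows = [i for i, r in enumerate(X) if self._row_key(r) not in seen]
        for i, r in enumerate(X):
            j = seen.get(self._row_key(r))
            if j is not None:
                out[i] = self.train_predictions_[j]
        if new_rows:
            out[new_rows] = self._predict_new(X[new_rows])
        return out


class GBLUP(_BlupBase):
    """Genomic BLUP: random individual effects with all-marker VanRaden kinship.

    Parameters
    ----------
    ridge : float
        Relative ridge added to near-singular relationship matrices.

    Attributes
    ----------
    reml_ : RemlFit with variance components and restricted log-likelihood.
    h2_ : estimated narrow-sense heritability 1/(1+delta).
    kinship_ : KinshipMatrix over the fit individuals.
    train_predictions_ : fixed part plus BLUP for every fit row.
    """

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    def fit(self, X, y):
        X, y, obs = self._validate(X, y)
        self._X_train, self._y_train, self._obs = X, y, obs
        G = self._geno(X)
        self.kinship_ = vanraden_kinship(G)
        ref_ids = [G.ids[i] for i in np.flatnonzero(obs)]
        K_ref = self.kinship_.reorder(ref_ids)
        self.reml_ = reml_fit(y[obs], self._design(obs.sum()), K_ref)
        self.h2_ = estimate_h2(self.reml_)
        blup = predict_unphenotyped(self.reml_, self.kinship_)
        self.beta_ = blup.beta_hat
        self.u_ = blup.u_hat
        self.train_predictions_ = float(blup.beta_hat[0]) + blup.u_hat
        return self

    def _predict_new(self, X_new):
        n0 = self._X_train.shape[0]
        joint = np.vstack([self._X_train, X_new])
        ids = [f"i{j}" for j in range(joint.shape[0])]
        K = vanraden_kinship(GenotypeMatrix(ids, joint, self._geno(self._X_train).marker_map))
        blup = predict_unphenotyped(self.reml_, K)
        return float(blup.beta_hat[0]) + blup.u_hat[n0:]


class SuperBLUP(_BlupBase):
    """SUPER BLUP: kinship from likelihood-selected pseudo-QTN markers.

    Parameters
    ----------
    chrom, pos : optional per-marker chromosome labels and bp positions
        (consecutive integers on one chromosome if omitted).
    s_grid, t_grid : candidate bin sizes (bp) and bin counts; defaults span
        Mendelian to polygenic architectures, t capped at m/10.

    Attributes
    ----------
    super_ : SuperFit (optimal BinSpec, grid table, pseudo-QTN kinship).
    pseudo_qtn_ : selected marker indices.
    scan_ : ScanResult of the P3D mixed-model association scan.
    """

    def __init__(self, chrom=None, pos=None, s_grid=None, t_grid=None):
        self.chrom = chrom
        self.pos = pos
        self.s_grid = s_grid
        self.t_grid = t_grid

    def fit(self, X, y):
        X, y, obs = self._validate(X, y)
        self._X_train, self._y_train, self._obs = X, y, obs
        m = X.shape[1]
        if self.pos is not None:
            self._marker_map = pd.DataFrame(
                {
                    "marker": [f"m{j + 1:05d}" for j in range(m)],
                    "chrom": np.asarray(self.chrom) if self.chrom is not None else "1",
                    "pos": np.asarray(self.pos),
                }
            )
        G = self._geno(X)
        ref_ids = [G.ids[i] for i in np.flatnonzero(obs)]
        G_ref = G.subset_individuals(ref_ids)
        Xd = self._design(obs.sum())
        self.scan_ = gwas_scan(y[obs], Xd, vanraden_kinship(G_ref), G_ref)
        self.super_ = optimize_super(
            y[obs], Xd, G_ref, self.scan_, s_grid=self.s_grid, t_grid=self.t_grid
        )
        self.pseudo_qtn_ = self.super_.pseudo_qtn
        self.h2_ = estimate_h2(self.super_.fit)
        inf_ids = [G.ids[i] for i in np.flatnonzero(~obs)]
        blup = sblup_predict(self.super_, G, ref_ids, inf_ids) if inf_ids else (
            predict_unphenotyped(self.super_.fit, self.super_.kinship)
        )
        pred_by_id = dict(zip(blup.levels, float(blup.beta_hat[0]) + blup.u_hat))
        self.beta_ = blup.beta_hat
        self.train_predictions_ = np.array([pred_by_id[i] for i in G.ids])
        return self

    def _predict_new(self, X_new):
        n0 = self._X_train.shape[0]
        joint = np.vstack([self._X_train, X_new])
        ids = [f"i{j}" for j in range(joint.shape[0])]
        G = GenotypeMatrix(ids, joint, self._geno(self._X_train).marker_map)
        ref_ids = [ids[i] for i in np.flatnonzero(self._obs)]
        inf_ids = ids[n0:]
        blup = sblup_predict(self.super_, G, ref_ids, inf_ids)
        pred_by_id = dict(zip(blup.levels, float(blup.beta_hat[0]) + blup.u_hat))
        return np.array([pred_by_id[i] for i in inf_ids])


class CompressedBLUP(_BlupBase):
    """Compressed BLUP: groups of kinship-clustered individuals as random
    effects, group number chosen by restricted likelihood.

    Parameters
    ----------
    g_grid : candidate group numbers (default: geometric from 2 to n, with n).
    linkage : hierarchical clustering linkage ('average', 'complete', 'ward').

    Attributes
    ----------
    compression_ : CompressionFit (best g, profile of -2LL over the grid).
    best_g_ : optimized number of groups.
    groups_ : GroupAssignment of all fit individuals.
    """

    def __init__(self, g_grid=None, linkage: str = "average"):
        self.g_grid = g_grid
        self.linkage = linkage

    def fit(self, X, y):
        X, y, obs = self._validate(X, y)
        self._X_train, self._y_train, self._obs = X, y, obs
        G = self._geno(X)
        self.kinship_ = vanraden_kinship(G)
        ref_ids = [G.ids[i] for i in np.flatnonzero(obs)]
        self.compression_ = optimize_compression(
            y[obs], self._design(obs.sum()), ref_ids, self.kinship_,
            g_grid=self.g_grid, method=self.linkage,
        )
        self.best_g_ = self.compression_.best_g
        self.groups_ = self.compression_.groups
        self.h2_ = estimate_h2(self.compression_.fit)
        pred = cblup_predict(self.compression_, ref_ids=ref_ids)
        self.train_predictions_ = pred.loc[G.ids].to_numpy()
        return self

    def _predict_new(self, X_new):
        # inductive path: re-cluster train + new jointly at the fitted g and
        # refit the variance ratio on the reference phenotypes (no leakage)
        n0 = self._X_train.shape[0]
        joint = np.vstack([self._X_train, X_new])
        ids = [f"i{j}" for j in range(joint.shape[0])]
        K = vanraden_kinship(GenotypeMatrix(ids, joint, self._geno(self._X_train).marker_map))
        ref_ids = [ids[i] for i in np.flatnonzero(self._obs)]
        compfit = optimize_compression(
            self._y_train[self._obs], self._design(int(self._obs.sum())), ref_ids, K,
            g_grid=[min(self.best_g_, len(ids))], method=self.linkage,
        )
        pred = cblup_predict(compfit, ref_ids=ref_ids)
        return pred.loc[ids[n0:]].to_numpy()
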