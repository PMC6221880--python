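"""SUPER BLUP: pseudo-QTN selection by binned GWAS and likelihood optimization.

A single-marker mixed-model scan is run once on the reference individuals with
the variance ratio fixed from the null model (P3D).  The genome is then split
per chromosome into half-open bins of ``s`` base pairs; each non-empty bin is
represented by its most significant marker, and the top ``t`` bins give the
pseudo-QTN set.  ``(s, t)`` is chosen to maximize the restricted likelihood of
the reference phenotypes under a kinship rebuilt from the pseudo-QTNs alone.
Unlike the SUPER GWAS procedure there is no LD-exclusion step: every selected
marker enters the kinship.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .kinship import GenotypeMatrix, KinshipMatrix, vanraden_kinship
from .mixedmodel import BlupResult, RemlFit, predict_unphenotyped, reml_fit

__all__ = [
    "ScanResult",
    "BinSpec",
    "SuperFit",
    "gwas_scan",
    "bin_and_select",
    "optimize_super",
    "sblup_predict",
    "default_s_grid",
    "default_t_grid",
]

DEFAULT_S_GRID = (50_000, 100_000, 500_000, 1_000_000, 5_000_000)
DEFAULT_T_GRID = (5, 10, 20, 50, 100, 200)


def default_s_grid() -> tuple:
    """Bin sizes (bp) spanning Mendelian to polygenic architectures."""
    return DEFAULT_S_GRID


def default_t_grid(m: int) -> tuple:
    """Bin counts {5,...,200} capped at m/10 markers."""
    cap = max(1, m // 10)
    grid = tuple(t for t in DEFAULT_T_GRID if t <= cap)
    return grid if grid else (cap,)


@dataclass
class ScanResult:
    stat: np.ndarray
    p: np.ndarray
    delta: float  # variance ratio fixed for all marker tests (P3D)
    n_collinear: int = 0

    def __post_init__(self):
        if self.stat.shape != self.p.shape:
            raise ValueError("stat/p length mismatch")
        if np.any((self.p <= 0) | (self.p > 1)):
            raise ValueError("p-values must lie in (0, 1]")


@dataclass
class BinSpec:
    s: int
    t: int

    def __post_init__(self):
        if self.s < 1 or self.t < 1:
            raise ValueError("bin size and count must be >= 1")


@dataclass
class SuperFit:
    best: BinSpec
    pseudo_qtn: np.ndarray
    kinship: KinshipMatrix
    logLik_restricted: float
    grid_table: pd.DataFrame
    fit: RemlFit = field(repr=False)


def gwas_scan(y, X, K: KinshipMatrix, G: GenotypeMatrix, null_fit: RemlFit | None = None) -> ScanResult:
    """Mixed-model association scan with P3D.

    delta is estimated once on the marker-free null model (or taken from
    ``null_fit``); each marker is then tested as a fixed effect by GLS with
    covariance sigma_a^2 (2K + delta I) held fixed.  Monomorphic markers and
    markers collinear with X get p = 1.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, q = X.shape
    if null_fit is None:
        null_fit = reml_fit(y, X, K)
    delta = null_fit.delta

    lam, U = np.linalg.eigh(K.values)
    d = np.sqrt(np.clip(lam, 0.0, None) + delta)
    # whiten: H^{-1/2} = D^{-1/2} U'
    yt = (U.T @ y) / d
    Xt = (U.T @ X) / d[:, None]
    Gt = (U.T @ np.where(np.isnan(G.codes), 0.0, G.codes)) / d[:, None]

    # project out fixed effects from response and every marker
    Q, _ = np.linalg.qr(Xt)
    yr = yt - Q @ (Q.T @ yt)
    Gr = Gt - Q @ (Q.T @ Gt)

    df = n - q - 1
    if df < 1:
        raise ValueError("not enough observations for marker tests")
    ww = np.sum(Gr * Gr, axis=0)
    mono = np.nanstd(G.codes, axis=0) == 0
    good = (~mono) & (ww > 1e-10 * max(float(ww.max(initial=0.0)), 1.0))
    n_collinear = int(np.sum(~good & ~mono))
    if n_collinear:
        warnings.warn(f"{n_collinear} markers collinear with fixed effects; p set to 1")

    beta = np.zeros(G.m)
    tstat = np.zeros(G.m)
    beta[good] = (Gr[:, good].T @ yr) / ww[good]
    rss = np.sum(yr * yr) - beta[good] * (Gr[:, good].T @ yr)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.maximum(rss, 0.0) / df / ww[good])
        tstat[good] = np.where(se > 0, beta[good] / se, 0.0)
    p = np.ones(G.m)
    p[good] = 2.0 * stats.t.sf(np.abs(tstat[good]), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return ScanResult(stat=tstat, p=p, delta=delta, n_collinear=n_collinear)


def bin_and_select(scan: ScanResult, marker_map: pd.DataFrame, binspec: BinSpec) -> np.ndarray:
    """Pseudo-QTN marker indices for a bin specification.

    Bins are half-open [k*s, (k+1)*s) per chromosome on 1-based positions;
    each bin's representative is its smallest-p marker (ties to the smaller
    position), representatives are ranked by p (ties to genome order) and the
    top t are returned sorted in genome order.
    """
    if len(marker_map) != scan.p.size:
        raise ValueError("marker map not aligned with scan")
    pos = marker_map["pos"].to_numpy()
    chrom = marker_map["chrom"].to_numpy().astype(str)
    order = np.lexsort((pos, chrom))  # genome order for deterministic ties
    genome_rank = np.empty(len(order), dtype=int)
    genome_rank[order] = np.arange(len(order))

    reps: dict = {}
    for j in range(scan.p.size):
        key = (chrom[j], pos[j] // binspec.s)
        best = reps.get(key)
        if (
            best is None
            or scan.p[j] < scan.p[best]
            or (scan.p[j] == scan.p[best] and pos[j] < pos[best])
        ):
            reps[key] = j
    rep_idx = np.array(sorted(reps.values(), key=lambda j: (scan.p[j], genome_rank[j])), dtype=int)
    chosen = rep_idx[: binspec.t]
    return chosen[np.argsort(genome_rank[chosen])]


def optimize_super(
    y,
    X,
    G: GenotypeMatrix,
    scan: ScanResult,
    s_grid=None,
    t_grid=None,
    marker_map: pd.DataFrame | None = None,
) -> SuperFit:
    """Maximize the restricted likelihood over the (s, t) grid.

    Each cell selects pseudo-QTNs, rebuilds a VanRaden kinship from them and
    runs a full REML fit (delta re-estimated per cell).  Ties go to the
    smaller t, then the smaller s.  Cells whose pseudo-QTNs are all
    monomorphic are skipped with a warning.
    """
    marker_map = G.marker_map if marker_map is None else marker_map
    s_grid = tuple(int(s) for s in (s_grid if s_grid is not None else default_s_grid()))
    t_grid = tuple(int(t) for t in (t_grid if t_grid is not None else default_t_grid(G.m)))
    if not s_grid or not t_grid:
        raise ValueError("empty (s, t) grid")

    rows = []
    best = None  # (ll, t, s, qtn, K, fit)
    cache: dict = {}
    for s in s_grid:
        for t in t_grid:
            qtn = bin_and_select(scan, marker_map, BinSpec(s, t))
            key = qtn.tobytes()
            if key in cache:
                K, fit = cache[key]
            else:
                try:
                    K = vanraden_kinship(G, subset=qtn)
                except ValueError:
                    warnings.warn(f"(s={s}, t={t}): pseudo-QTNs all monomorphic; skipped")
                    rows.append({"s": s, "t": t, "n_qtn": len(qtn), "logLik": np.nan})
                    continue
                fit = reml_fit(y, X, K)
                cache[key] = (K, fit)
            ll = fit.logLik_restricted
            rows.append({"s": s, "t": t, "n_qtn": len(qtn), "logLik": ll})
            if best is None or ll > best[0] + 1e-12 or (
                abs(ll - best[0]) <= 1e-12 and (t, s) < (best[1], best[2])
            ):
                best = (ll, t, s, qtn, K, fit)
    if best is None:
        raise ValueError("every (s, t) cell was skipped")
    ll, t, s, qtn, K, fit = best
    return SuperFit(
        best=BinSpec(s, t),
        pseudo_qtn=qtn,
        kinship=K,
        logLik_restricted=ll,
        grid_table=pd.DataFrame(rows),
        fit=fit,
    )


def sblup_predict(superfit: SuperFit, G_full: GenotypeMatrix, ref_ids, inf_ids) -> BlupResult:
    """Predict all individuals from a SUPER fit: the pseudo-QTN kinship is
    rebuilt over reference plus inference individuals, then the standard
    conditional BLUP applies."""
    all_ids = list(ref_ids) + [i for i in inf_ids if i not in set(ref_ids)]
    missing = [i for i in all_ids if i not in set(G_full.ids)]
    if missing:
        raise KeyError(f"ids absent from genotype matrix: {missing}")
    K_full = vanraden_kinship(G_full.subset_individuals(all_ids), subset=superfit.pseudo_qtn)
    return predict_unphenotyped(superfit.fit, K_full, ref_ids=ref_ids, inf_ids=inf_ids)
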