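"""Synthetic genotypes with full-sib family structure and simulated traits.

Genotypes: founder haplotypes are drawn at Hardy-Weinberg equilibrium with
per-marker allele frequencies sampled uniformly from a configurable range;
each family has two parents and produces full sibs by Mendelian transmission
with recombination between adjacent markers at a fixed per-interval rate.

Traits: a chosen number of QTNs is sampled uniformly without replacement from
the markers, QTN effects are standard normal, the breeding value of an
individual is the dosage-weighted sum of effects, and the residual variance is
set from the *observed* breeding-value variance so that the realized ratio of
genetic to total variance equals the requested heritability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import GenotypeMatrix

__all__ = [
    "SimConfig",
    "SimulatedTrait",
    "simulate_genotypes",
    "simulate_phenotype",
    "HERITABILITY_LEVELS",
    "QTN_LEVELS",
    "PRESETS",
]

#: heritability and QTN-count levels used throughout the evaluation scenarios
HERITABILITY_LEVELS = (0.1, 0.25, 0.5, 0.75)
QTN_LEVELS = (5, 10, 100, 500, 1000)

#: named genetic architectures: (n_qtn, h2)
PRESETS = {
    "mendelian": (5, 0.75),
    "oligogenic": (10, 0.5),
    "polygenic": (100, 0.5),
    "complex_low_h2": (500, 0.1),
}


@dataclass
class SimConfig:
    """Family-structured genotype simulation settings."""

    n_families: int = 80
    sibs_per_family: int = 5
    n_markers: int = 3000
    chrom_length: int = 100_000_000
    recomb_rate: float = 0.01  # switch probability per adjacent-marker interval
    freq_range: tuple = (0.1, 0.9)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_families, self.sibs_per_family, self.n_markers, self.chrom_length) < 1:
            raise ValueError("all counts must be positive")
        lo, hi = self.freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("freq_range must lie within (0, 1)")
        if not 0.0 <= self.recomb_rate <= 0.5:
            raise ValueError("recomb_rate must be in [0, 0.5]")


@dataclass
class SimulatedTrait:
    phenotype: pd.Series  # indexed by individual id
    breeding_values: np.ndarray
    qtn_indices: np.ndarray
    qtn_effects: np.ndarray
    h2_target: float
    residuals: np.ndarray

    def __post_init__(self):
        if len(self.qtn_indices) != len(self.qtn_effects):
            raise ValueError("qtn_indices and qtn_effects length mismatch")
        if not np.allclose(self.phenotype.to_numpy(), self.breeding_values + self.residuals):
            raise ValueError("phenotype must equal breeding values plus residuals")


def _gamete(parent_haps: np.ndarray, rng: np.random.Generator, r: float) -> np.ndarray:
    """One recombinant gamete from a (2, m) parent haplotype pair."""
    m = parent_haps.shape[1]
    start = rng.integers(0, 2)
    switches = rng.random(m - 1) < r
    strand = (start + np.concatenate([[0], np.cumsum(switches)])) % 2
    return parent_haps[strand, np.arange(m)]


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Simulate dosage genotypes for ``n_families x sibs_per_family``
    full sibs on one chromosome; deterministic given ``cfg.seed``."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_map, rng_founder, rng_meiosis = (np.random.default_rng(s) for s in ss.spawn(3))

    m = cfg.n_markers
    # unique, sorted 1-based positions (collisions negligible, retry to be safe)
    pos = np.unique(rng_map.integers(1, cfg.chrom_length + 1, size=2 * m))
    while pos.size < m:
        pos = np.unique(np.concatenate([pos, rng_map.integers(1, cfg.chrom_length + 1, size=m)]))
    pos = np.sort(rng_map.choice(pos, size=m, replace=False))
    freqs = rng_founder.uniform(*cfg.freq_range, size=m)

    rows, ids = [], []
    for fam in range(cfg.n_families):
        parents = (rng_founder.random((2, m)) < freqs).astype(np.int8), (
            rng_founder.random((2, m)) < freqs
        ).astype(np.int8)
        for sib in range(cfg.sibs_per_family):
            dose = _gamete(parents[0], rng_meiosis, cfg.recomb_rate) + _gamete(
                parents[1], rng_meiosis, cfg.recomb_rate
            )
            rows.append(dose)
            ids.append(f"F{fam + 1:03d}_S{sib + 1}")
    codes = np.asarray(rows, dtype=float)
    marker_map = pd.DataFrame(
        {"marker": [f"m{j + 1:05d}" for j in range(m)], "chrom": "1", "pos": pos}
    )
    return GenotypeMatrix(ids, codes, marker_map)


def simulate_phenotype(G: GenotypeMatrix, n_qtn: int, h2: float, seed: int = 0) -> SimulatedTrait:
    """Simulate one additive trait on an existing genotype matrix.

    Residual variance is ``var(g) * (1 - h2) / h2`` with ``var(g)`` the
    observed variance of breeding values, so realized heritability matches
    the target in expectation; ``h2 = 1`` gives identically zero residuals.
    """
    if not 1 <= n_qtn <= G.m:
        raise ValueError(f"n_qtn must be in [1, {G.m}]")
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must be in (0, 1]")
    ss = np.random.SeedSequence(seed)
    rng_qtn, rng_eff, rng_res = (np.random.default_rng(s) for s in ss.spawn(3))

    codes = np.where(np.isnan(G.codes), 0.0, G.codes)
    for _ in range(2):
        qtn = np.sort(rng_qtn.choice(G.m, size=n_qtn, replace=False))
        effects = rng_eff.standard_normal(n_qtn)
        g = codes[:, qtn] @ effects
        var_g = float(np.var(g, ddof=1))
        if var_g > 0:
            break
    else:
        raise ValueError("all sampled QTNs monomorphic; cannot scale residual variance")
    if h2 == 1.0:
        e = np.zeros(G.n)
    else:
        e = rng_res.normal(0.0, np.sqrt(var_g * (1.0 - h2) / h2), size=G.n)
    y = pd.Series(g + e, index=pd.Index(G.ids, name="id"), name="phenotype")
    return SimulatedTrait(
        phenotype=y,
        breeding_values=g,
        qtn_indices=qtn,
        qtn_effects=effects,
        h2_target=h2,
        residuals=e,
    )
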