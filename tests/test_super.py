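"""SUPER BLUP: association scan, binning, (s,t) optimization, prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import blupkit as bk


def scan_from_p(p):
    p = np.asarray(p, dtype=float)
    return bk.ScanResult(stat=np.zeros_like(p), p=p, delta=1.0)


def map_df(pos, chrom=None):
    pos = np.asarray(pos)
    return pd.DataFrame({
        "marker": [f"m{j}" for j in range(pos.size)],
        "chrom": chrom if chrom is not None else ["1"] * pos.size,
        "pos": pos,
    })


class TestBinAndSelect:
    def test_hand_binning(self):
        # bins [0,500) and [500,1000): marker at 150 wins its bin and ranks first
        scan = scan_from_p([1e-6, 1e-8, 1e-3])
        idx = bk.bin_and_select(scan, map_df([100, 150, 900]), bk.BinSpec(500, 1))
        assert list(idx) == [1]

    def test_saturation_one_marker_per_bin(self):
        scan = scan_from_p([1e-6, 1e-8, 1e-3, 1e-2])
        idx = bk.bin_and_select(scan, map_df([100, 150, 900, 1800]), bk.BinSpec(500, 99))
        assert len(idx) == 3  # bins 0, 1, 3 are non-empty

    def test_huge_bin_one_representative_per_chromosome(self):
        scan = scan_from_p([1e-3, 1e-5, 1e-4, 1e-2])
        mp = map_df([100, 900, 50, 700], chrom=["1", "1", "2", "2"])
        idx = bk.bin_and_select(scan, mp, bk.BinSpec(10**9, 99))
        assert sorted(idx) == [1, 2]  # best of chr1, best of chr2

    def test_tie_breaks_to_smaller_position(self):
        scan = scan_from_p([1e-4, 1e-4])
        idx = bk.bin_and_select(scan, map_df([300, 100]), bk.BinSpec(500, 1))
        assert list(idx) == [1]

    def test_output_in_genome_order(self):
        scan = scan_from_p([1e-2, 1e-8, 1e-5])
        idx = bk.bin_and_select(scan, map_df([100, 900, 1500]), bk.BinSpec(500, 3))
        pos = [100, 900, 1500]
        assert [pos[i] for i in idx] == sorted(pos[i] for i in idx)

    def test_storage_order_invariance(self):
        rng = np.random.default_rng(1)
        pos = rng.choice(10**6, size=60, replace=False) + 1
        p = rng.random(60)
        perm = rng.permutation(60)
        a = bk.bin_and_select(scan_from_p(p), map_df(pos), bk.BinSpec(50_000, 7))
        b = bk.bin_and_select(scan_from_p(p[perm]), map_df(pos[perm]), bk.BinSpec(50_000, 7))
        assert sorted(pos[a]) == sorted(pos[perm][b])

    @pytest.mark.parametrize("t", [3, 8])
    def test_nested_bin_sizes_only_merge(self, t):
        # for nested sizes s, 2s, 4s the non-empty bin count cannot grow
        rng = np.random.default_rng(2)
        pos = np.sort(rng.choice(10**6, size=80, replace=False)) + 1
        p = rng.random(80)
        counts = []
        for s in (25_000, 50_000, 100_000, 200_000):
            idx = bk.bin_and_select(scan_from_p(p), map_df(pos), bk.BinSpec(s, t))
            counts.append(len(np.unique(pos[idx] // s)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestGwasScan:
    def test_matches_per_marker_gls_oracle(self):
        cfg = bk.SimConfig(n_families=10, sibs_per_family=5, n_markers=60, seed=3)
        G = bk.simulate_genotypes(cfg)
        tr = bk.simulate_phenotype(G, 3, 0.6, seed=4)
        y = tr.phenotype.to_numpy()
        X = np.ones((G.n, 1))
        K = bk.vanraden_kinship(G)
        scan = bk.gwas_scan(y, X, K, G)
        Hi = np.linalg.inv(K.values + scan.delta * np.eye(G.n))
        Ch = np.linalg.cholesky(Hi)
        yt, Xt = Ch.T @ y, Ch.T @ X
        for j in [0, 7, 23, 59]:
            w = Ch.T @ G.codes[:, j]
            if np.std(G.codes[:, j]) == 0:
                continue
            D = np.column_stack([Xt, w])
            coef, res_, *_ = np.linalg.lstsq(D, yt, rcond=None)
            r = yt - D @ coef
            se = np.sqrt(r @ r / (G.n - 2) * np.linalg.inv(D.T @ D)[1, 1])
            np.testing.assert_allclose(scan.stat[j], coef[1] / se, atol=1e-8)

    def test_null_pvalues_uniform(self):
        cfg = bk.SimConfig(n_families=20, sibs_per_family=4, n_markers=500, seed=5)
        G = bk.simulate_genotypes(cfg)
        tr = bk.simulate_phenotype(G, 10, 0.5, seed=6)
        rng = np.random.default_rng(7)
        y = tr.phenotype.to_numpy()[rng.permutation(G.n)]  # break association
        scan = bk.gwas_scan(y, np.ones((G.n, 1)), bk.vanraden_kinship(G), G)
        poly = np.nanstd(G.codes, axis=0) > 0
        assert stats.kstest(scan.p[poly], "uniform").pvalue > 0.01

    def test_dominant_qtn_attains_min_p(self):
        cfg = bk.SimConfig(n_families=20, sibs_per_family=4, n_markers=300, seed=8)
        G = bk.simulate_genotypes(cfg)
        tr = bk.simulate_phenotype(G, 1, 0.9, seed=9)
        scan = bk.gwas_scan(tr.phenotype.to_numpy(), np.ones((G.n, 1)),
                            bk.vanraden_kinship(G), G)
        assert int(np.argmin(scan.p)) == int(tr.qtn_indices[0])

    def test_monomorphic_marker_p_one(self, small_genotypes, small_trait):
        G = small_genotypes
        codes = G.codes.copy()
        codes[:, 0] = 2.0
        Gm = bk.GenotypeMatrix(G.ids, codes, G.marker_map)
        scan = bk.gwas_scan(small_trait.phenotype.to_numpy(), np.ones((G.n, 1)),
                            bk.vanraden_kinship(Gm), Gm)
        assert scan.p[0] == 1.0


@pytest.fixture(scope="module")
def setup(small_genotypes, small_trait):
    G, tr = small_genotypes, small_trait
    y = tr.phenotype.to_numpy()
    X = np.ones((G.n, 1))
    scan = bk.gwas_scan(y, X, bk.vanraden_kinship(G), G)
    return G, y, X, scan


class TestOptimizeSuper:

    def test_singleton_grid(self, setup):
        G, y, X, scan = setup
        sf = bk.optimize_super(y, X, G, scan, s_grid=[10**6], t_grid=[4])
        assert (sf.best.s, sf.best.t) == (10**6, 4)
        qtn = bk.bin_and_select(scan, G.marker_map, bk.BinSpec(10**6, 4))
        assert list(sf.pseudo_qtn) == list(qtn)

    def test_exhaustive_grid_oracle(self, setup):
        G, y, X, scan = setup
        s_grid, t_grid = [5 * 10**5, 5 * 10**6], [2, 5, 10]
        sf = bk.optimize_super(y, X, G, scan, s_grid=s_grid, t_grid=t_grid)
        best = -np.inf
        for s in s_grid:
            for t in t_grid:
                qtn = bk.bin_and_select(scan, G.marker_map, bk.BinSpec(s, t))
                K = bk.vanraden_kinship(G, subset=qtn)
                best = max(best, bk.reml_fit(y, X, K).logLik_restricted)
        assert sf.logLik_restricted == pytest.approx(best, abs=1e-8)
        assert sf.logLik_restricted >= sf.grid_table["logLik"].max() - 1e-10

    def test_optimum_beats_any_single_cell(self, setup):
        G, y, X, scan = setup
        sf = bk.optimize_super(y, X, G, scan, s_grid=[5 * 10**5, 5 * 10**6], t_grid=[2, 5, 10])
        single = bk.optimize_super(y, X, G, scan, s_grid=[5 * 10**6], t_grid=[5])
        assert sf.logLik_restricted >= single.logLik_restricted - 1e-10

    def test_pseudo_qtns_near_true_qtns(self):
        # selected markers should tag the simulated QTNs
        hits, total = 0, 0
        for seed in range(3):
            cfg = bk.SimConfig(seed=20 + seed)  # 400 individuals, 3000 markers
            G = bk.simulate_genotypes(cfg)
            tr = bk.simulate_phenotype(G, 10, 0.75, seed=30 + seed)
            y, X = tr.phenotype.to_numpy(), np.ones((G.n, 1))
            scan = bk.gwas_scan(y, X, bk.vanraden_kinship(G), G)
            sf = bk.optimize_super(y, X, G, scan)
            s = sf.best.s
            pos = G.marker_map["pos"].to_numpy()
            near = {b for p in pos[tr.qtn_indices] for b in (p // s - 1, p // s, p // s + 1)}
            hits += sum(1 for p in pos[sf.pseudo_qtn] if p // s in near)
            total += len(sf.pseudo_qtn)
        assert hits / total >= 0.5


class TestSblupPredict:
    def test_all_marker_pseudo_qtns_reduce_to_gblup(self, small_genotypes, small_trait):
        G, tr = small_genotypes, small_trait
        ref, inf = G.ids[:40], G.ids[40:]
        y_ref = tr.phenotype.loc[ref].to_numpy()
        X = np.ones((len(ref), 1))
        K_ref = bk.vanraden_kinship(G.subset_individuals(ref))
        fit = bk.reml_fit(y_ref, X, K_ref)
        sf = bk.SuperFit(best=bk.BinSpec(1, G.m), pseudo_qtn=np.arange(G.m),
                         kinship=K_ref, logLik_restricted=fit.logLik_restricted,
                         grid_table=pd.DataFrame(), fit=fit)
        pred_s = bk.sblup_predict(sf, G, ref, inf)
        K_full = bk.vanraden_kinship(G.subset_individuals(list(ref) + list(inf)))
        pred_g = bk.predict_unphenotyped(fit, K_full, ref_ids=ref, inf_ids=inf)
        np.testing.assert_allclose(pred_s.u_hat, pred_g.u_hat, atol=1e-10)

    def test_deterministic(self, small_genotypes, small_trait):
        G, tr = small_genotypes, small_trait
        ref, inf = G.ids[:40], G.ids[40:]
        y_ref = tr.phenotype.loc[ref].to_numpy()
        X = np.ones((len(ref), 1))
        G_ref = G.subset_individuals(ref)
        out = []
        for _ in range(2):
            scan = bk.gwas_scan(y_ref, X, bk.vanraden_kinship(G_ref), G_ref)
            sf = bk.optimize_super(y_ref, X, G_ref, scan, s_grid=[10**6], t_grid=[3, 6])
            out.append(bk.sblup_predict(sf, G, ref, inf).u_hat)
        np.testing.assert_array_equal(out[0], out[1])


def test_reference_only_discipline(small_genotypes, small_trait):
    """Perturbing a masked inference phenotype never changes the SUPER fit."""
    G, tr = small_genotypes, small_trait
    ref = G.ids[:40]
    y_ref = tr.phenotype.loc[ref].to_numpy()
    X = np.ones((len(ref), 1))
    G_ref = G.subset_individuals(ref)
    scan = bk.gwas_scan(y_ref, X, bk.vanraden_kinship(G_ref), G_ref)
    sf1 = bk.optimize_super(y_ref, X, G_ref, scan, s_grid=[10**6], t_grid=[3])
    # mutate phenotypes outside the reference; the fit sees reference only
    y_mut = tr.phenotype.copy()
    y_mut.iloc[40:] += 100.0
    scan2 = bk.gwas_scan(y_mut.loc[ref].to_numpy(), X, bk.vanraden_kinship(G_ref), G_ref)
    sf2 = bk.optimize_super(y_mut.loc[ref].to_numpy(), X, G_ref, scan2,
                            s_grid=[10**6], t_grid=[3])
    assert list(sf1.pseudo_qtn) == list(sf2.pseudo_qtn)
    assert sf1.logLik_restricted == pytest.approx(sf2.logLik_restricted)


def test_default_t_grid_capped():
    assert max(bk.superblup.default_t_grid(3000)) <= 300
    assert bk.superblup.default_t_grid(40) == (4,)  # falls back to the cap m/10
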