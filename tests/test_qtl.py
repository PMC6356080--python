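"""Kinship, mixed-model scan, thresholds, pruning/clumping, conditional
LRT, and annotation enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from proteopop import qtl as q
from proteopop import simulate as sim
from proteopop.containers import GenotypeMatrix
from proteopop.statsutil import bh_threshold, hypergeom_logsf, hypergeom_sf


def toy_geno(dosages, lines=None, chrom="chr1"):
    dosages = np.asarray(dosages, dtype=float)
    snps = [f"s{i}" for i in range(dosages.shape[0])]
    lines = lines or [f"L{i}" for i in range(dosages.shape[1])]
    meta = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, dosages.shape[0] + 1) * 100,
            "ref": "A",
            "alt": "G",
        },
        index=pd.Index(snps, name="snp"),
    )
    return GenotypeMatrix(pd.DataFrame(dosages, index=snps, columns=lines), meta)


class TestKinship:
    def test_duplicate_lines_relatedness(self, small_panel):
        geno = small_panel["geno"]
        dup = geno.dosages.copy()
        dup["L000_dup"] = dup["L000"]
        meta = geno.snp_meta
        g2 = GenotypeMatrix(dup, meta)
        K = q.kinship_matrix(g2)
        assert K.loc["L000", "L000_dup"] == pytest.approx(K.loc["L000", "L000"], abs=1e-9)

    def test_structured_population_blocks(self, small_panel):
        geno = small_panel["geno"]
        labels = small_panel["truth"].subpop_labels
        K = q.kinship_matrix(geno)
        nss = labels.index[labels == "NSS"]
        tst = labels.index[labels == "TST"]
        within = K.loc[nss, nss].to_numpy()[np.triu_indices(len(nss), 1)].mean()
        between = K.loc[nss, tst].to_numpy().mean()
        assert within > between

    def test_snp_order_invariance(self, small_panel):
        geno = small_panel["geno"]
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(geno.snps))
        K1 = q.kinship_matrix(geno)
        K2 = q.kinship_matrix(geno.subset_snps(perm))
        assert np.allclose(K1, K2, atol=1e-9)

    def test_monomorphic_only_rejected(self):
        g = toy_geno(np.zeros((12, 10)))
        with pytest.raises(ValueError):
            q.kinship_matrix(g)


class TestMlmScan:
    def test_equals_ols_when_no_genetic_variance(self):
        rng = np.random.default_rng(1)
        n = 60
        geno = toy_geno(2 * (rng.random((30, n)) < 0.4))
        K0 = pd.DataFrame(np.zeros((n, n)), index=geno.lines, columns=geno.lines)
        y = pd.Series(rng.standard_normal(n), index=geno.lines)
        scan = q.mlm_scan(y, geno, K0, None)
        for s in scan.results.index:
            g = geno.dosages.loc[s].to_numpy()
            res = stats.linregress(g, y.to_numpy())
            assert scan.results.loc[s, "p"] == pytest.approx(res.pvalue, abs=1e-9)

    def test_null_calibration_structured(self):
        cfg = sim.PopulationConfig(n_lines=100, n_snps=600, fst=0.3, ld_block_size=1, seed=11)
        geno, truth = sim.simulate_genotypes(cfg)
        K = q.kinship_matrix(geno)
        Qcov = pd.get_dummies(truth.subpop_labels, dtype=float).iloc[:, 1:]
        scan_geno = geno.subset_snps(geno.snps[:100])
        L = np.linalg.cholesky(K.to_numpy() + 1e-6 * np.eye(100))
        rng = np.random.default_rng(5)
        cache = {}
        pvals = []
        for t in range(150):
            u = L @ rng.standard_normal(100)
            y = pd.Series(u + rng.standard_normal(100), index=geno.lines)
            scan = q.mlm_scan(y, scan_geno, K, Qcov, _eig_cache=cache)
            pvals.append(scan.results["p"].to_numpy())
        p = np.concatenate(pvals)
        lam = np.median(stats.chi2.isf(p, 1)) / stats.chi2.isf(0.5, 1)
        assert 0.9 <= lam <= 1.1
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_power_at_paper_scale_threshold(self):
        rng = np.random.default_rng(2)
        hits = 0
        n_sims = 100
        for s in range(n_sims):
            n = 100
            d = 2.0 * (rng.random(n) < 0.3)
            geno = toy_geno(d[None, :])
            y = pd.Series(1.0 * d + rng.standard_normal(n), index=geno.lines)
            K0 = pd.DataFrame(np.zeros((n, n)), index=geno.lines, columns=geno.lines)
            scan = q.mlm_scan(y, geno, K0, None, maf_min=0.05)
            hits += (scan.results["p"] < 1.98e-4).any()
        assert hits / n_sims >= 0.90

    def test_affine_trait_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        n = 50
        geno = toy_geno(2 * (rng.random((20, n)) < 0.3))
        K = q.kinship_matrix(geno)
        y = pd.Series(rng.standard_normal(n), index=geno.lines)
        p1 = q.mlm_scan(y, geno, K, None).results["p"]
        p2 = q.mlm_scan(3.7 * y + 11.0, geno, K, None).results["p"]
        assert np.allclose(p1, p2, atol=1e-8)

    def test_maf_filter_applied(self):
        rng = np.random.default_rng(4)
        n = 40
        d = 2 * (rng.random((10, n)) < 0.3)
        d[0] = 0.0
        d[0, 0] = 2.0  # MAF 1/40 < 0.05
        geno = toy_geno(d)
        K = q.kinship_matrix(geno)
        y = pd.Series(rng.standard_normal(n), index=geno.lines)
        scan = q.mlm_scan(y, geno, K, None, maf_min=0.05)
        assert "s0" not in scan.results.index


class TestThresholds:
    def test_bh_threshold_examples(self):
        thr, flags = bh_threshold(np.array([0.01, 0.02, 0.04]), alpha=0.05)
        assert thr == pytest.approx(0.04)
        assert flags.all()
        thr, flags = bh_threshold(np.ones(5), alpha=0.05)
        assert thr == 0.0 and not flags.any()

    def test_bh_false_rejection_rate_under_null(self):
        rng = np.random.default_rng(5)
        false_sims = 0
        for s in range(100):
            p = rng.uniform(0, 1, 10_000)
            _, flags = bh_threshold(p, alpha=0.05)
            false_sims += flags.any()
        assert false_sims / 100 <= 0.07

    def test_bonferroni_cutoff_values(self):
        assert q.bonferroni_cutoff(10, 1, 10) == 1.0
        assert q.bonferroni_cutoff(100, 100, 10) == pytest.approx(1e-3)
        with pytest.raises(ValueError):
            q.bonferroni_cutoff(0, 10)


class TestLdPrune:
    def test_duplicated_snp_one_survives(self):
        rng = np.random.default_rng(6)
        base = 2 * (rng.random(50) < 0.4)
        other = 2 * (rng.random(50) < 0.4)
        geno = toy_geno(np.vstack([base, base, other]))
        kept = q.ld_prune(geno)
        assert sum(s in kept for s in ("s0", "s1")) == 1
        assert "s2" in kept

    def test_independent_snps_all_survive(self):
        rng = np.random.default_rng(7)
        geno = toy_geno(2 * (rng.random((20, 500)) < 0.5))
        kept = q.ld_prune(geno)
        assert len(kept) == 20

    def test_postcondition_r2_bounded(self):
        rng = np.random.default_rng(8)
        for s in range(20):
            cfg = sim.PopulationConfig(
                n_lines=80, n_snps=60, fst=0.1, ld_block_size=4, seed=s
            )
            geno, _ = sim.simulate_genotypes(cfg)
            kept = q.ld_prune(geno, window=50, step=50, r2_max=0.1)
            sub = geno.subset_snps(kept)
            for chrom, meta in sub.snp_meta.groupby("chrom"):
                order = meta.sort_values("pos").index
                G = sub.dosages.loc[order].to_numpy()
                if len(order) < 2:
                    continue
                for start in range(0, len(order), 50):
                    win = G[start : start + 50]
                    win = win[win.std(axis=1) > 0]
                    if len(win) < 2:
                        continue
                    r2 = np.corrcoef(win) ** 2
                    off = ~np.eye(len(win), dtype=bool)
                    assert np.nanmax(r2[off]) <= 0.1 + 1e-9


class TestClumping:
    def test_perfect_ld_single_qtl(self):
        rng = np.random.default_rng(9)
        base = 2 * (rng.random(60) < 0.4)
        geno = toy_geno(np.vstack([base] * 5))
        res = pd.DataFrame(
            {
                "beta": 1.0,
                "se": 0.1,
                "p": [1e-8, 1e-7, 1e-6, 1e-5, 1e-4],
                "maf": 0.4,
                "chrom": "chr1",
                "pos": np.arange(5) * 100,
            },
            index=geno.snps,
        )
        scan = q.AssociationScan("g", "protein", res, "cis", 60)
        qtls = q.clump_qtls(scan, geno, threshold=1e-3)
        assert len(qtls) == 1
        assert qtls[0].lead_snp == "s0"
        assert set(qtls[0].clump) == set(geno.snps)

    def test_unlinked_snps_separate_qtls(self):
        rng = np.random.default_rng(10)
        g1 = 2 * (rng.random(200) < 0.4)
        g2 = 2 * (rng.random(200) < 0.4)
        geno = toy_geno(np.vstack([g1, g2]))
        res = pd.DataFrame(
            {"beta": 1.0, "se": 0.1, "p": [1e-8, 1e-7], "maf": 0.4,
             "chrom": "chr1", "pos": [100, 200]},
            index=geno.snps,
        )
        scan = q.AssociationScan("g", "protein", res, "cis", 200)
        qtls = q.clump_qtls(scan, geno, threshold=1e-3)
        assert len(qtls) == 2

    def test_planted_causal_snp_leads_clump(self):
        recovered = 0
        n_sims = 30
        for s in range(n_sims):
            rng = np.random.default_rng(100 + s)
            n = 200
            causal = 2.0 * (rng.random(n) < 0.4)
            proxies = []
            for _ in range(10):
                flip = rng.random(n) < 0.15
                proxies.append(np.where(flip, 2 - causal, causal))
            geno = toy_geno(np.vstack([causal] + proxies))
            y = pd.Series(0.5 * causal + rng.standard_normal(n), index=geno.lines)
            K0 = pd.DataFrame(np.zeros((n, n)), index=geno.lines, columns=geno.lines)
            scan = q.mlm_scan(y, geno, K0, None)
            qtls = q.clump_qtls(scan, geno, threshold=1e-3)
            if len(qtls) == 1 and qtls[0].lead_snp == "s0":
                recovered += 1
        assert recovered / n_sims >= 0.8


class TestConditionalLRT:
    def test_mediation_null_type_one(self):
        rng = np.random.default_rng(11)
        n = 100
        idx = pd.Index([f"L{i}" for i in range(n)])
        rej = 0
        n_sims = 500
        for _ in range(n_sims):
            x = pd.Series(2.0 * (rng.random(n) < 0.3), index=idx)
            m = pd.Series(0.5 * x + rng.standard_normal(n), index=idx)
            y = pd.Series(0.6 * m + rng.standard_normal(n), index=idx)
            rej += q.conditional_lrt(y, x, m).p < 0.05
        assert 0.02 <= rej / n_sims <= 0.09

    def test_power_for_direct_effect(self):
        rng = np.random.default_rng(12)
        n = 100
        idx = pd.Index([f"L{i}" for i in range(n)])
        rej = 0
        n_sims = 200
        for _ in range(n_sims):
            x = pd.Series(2.0 * (rng.random(n) < 0.3), index=idx)
            m = pd.Series(rng.standard_normal(n), index=idx)
            y = pd.Series(0.5 * x + rng.standard_normal(n), index=idx)
            rej += q.conditional_lrt(y, x, m).p < 0.05
        assert rej / n_sims >= 0.8

    def test_irrelevant_covariate_matches_marginal(self):
        rng = np.random.default_rng(13)
        n = 200
        idx = pd.Index([f"L{i}" for i in range(n)])
        diffs = []
        for _ in range(200):
            x = pd.Series(2.0 * (rng.random(n) < 0.3), index=idx)
            m = pd.Series(rng.standard_normal(n), index=idx)
            y = pd.Series(0.3 * x + rng.standard_normal(n), index=idx)
            p_cond = q.conditional_lrt(y, x, m).p
            res = stats.linregress(x, y)
            diffs.append(np.log10(max(p_cond, 1e-300)) - np.log10(max(res.pvalue, 1e-300)))
        assert abs(np.mean(diffs)) <= 0.2

    def test_constant_snp_rejected(self):
        idx = pd.Index([f"L{i}" for i in range(30)])
        x = pd.Series(2.0, index=idx)
        m = pd.Series(np.random.default_rng(14).standard_normal(30), index=idx)
        y = m.copy()
        with pytest.raises(ValueError, match="constant"):
            q.conditional_lrt(y, x, m)


class TestAnnotation:
    @pytest.fixture()
    def models(self, small_panel, tmp_path):
        from proteopop import io as ppio

        path = tmp_path / "genes.gff3"
        ppio.write_gff3(path, small_panel["gene_models"])
        return ppio.read_gene_models(path)

    def test_positions_classified_with_precedence(self, models, small_panel):
        gm = small_panel["gene_models"].loc["g0000"]
        probes = pd.DataFrame(
            {
                "chrom": gm["chrom"],
                "pos": [
                    gm["cds1_start"] + 5,   # CDS
                    gm["utr5_start"] + 5,   # 5'UTR
                    gm["utr3_end"] - 5,     # 3'UTR
                    gm["exon1_end"] + 100,  # intron
                    gm["start"] - 150_000,  # cis window, outside transcript
                ],
                "ref": "A",
                "alt": "G",
            },
            index=["p_cds", "p_u5", "p_u3", "p_int", "p_ext"],
        )
        ann = q.annotate_snps(probes, models, "g0000")
        assert ann["p_cds"] == "CDS"
        assert ann["p_u5"] == "5'UTR"
        assert ann["p_u3"] == "3'UTR"
        assert ann["p_int"] == "intronic"
        assert ann["p_ext"] == "extragenic"

    def test_outside_window_is_nan(self, models, small_panel):
        gm = small_panel["gene_models"].loc["g0000"]
        probes = pd.DataFrame(
            {"chrom": gm["chrom"], "pos": [gm["end"] + 250_000], "ref": "A", "alt": "G"},
            index=["far"],
        )
        ann = q.annotate_snps(probes, models, "g0000")
        assert pd.isna(ann["far"])


class TestHypergeometricEnrichment:
    def test_matches_exhaustive_tail_sum(self):
        rng = np.random.default_rng(15)
        for _ in range(300):
            N = int(rng.integers(5, 200))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(max(0, n + K - N), min(K, n) + 1))
            # log-sum-exp tail oracle
            logs = [
                stats.hypergeom.logpmf(j, N, K, n)
                for j in range(k, min(K, n) + 1)
            ]
            oracle = np.logaddexp.reduce(logs)
            ours = hypergeom_logsf(k, N, K, n)
            if np.isfinite(oracle):
                assert ours == pytest.approx(oracle, abs=1e-9)

    def test_invalid_table_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_sf(50, 100, 10, 20)
        with pytest.raises(ValueError):
            q.annotation_enrichment({"CDS": 50}, {"CDS": 10})

    def test_enrichment_frame_totals(self):
        res = q.annotation_enrichment(
            {"CDS": 5, "intronic": 1}, {"CDS": 50, "intronic": 100}
        )
        assert res.loc["CDS", "p"] == pytest.approx(
            hypergeom_sf(5, 150, 50, 6), rel=1e-12
        )
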