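"""Consensus clustering, signatures, NSC LOOCV, and subtype associations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from proteopop import subtypes as st
from proteopop.containers import ExpressionMatrix


def gaussian_clusters(seed, k=2, n_per=20, n_genes=100, sep=10.0):
    rng = np.random.default_rng(seed)
    centers = rng.standard_normal((k, n_genes)) * sep / np.sqrt(2)
    cols, labels = [], []
    for c in range(k):
        for _ in range(n_per):
            cols.append(centers[c] + rng.standard_normal(n_genes))
            labels.append(c)
    lines = [f"s{i}" for i in range(len(cols))]
    return (
        ExpressionMatrix(pd.DataFrame(np.array(cols).T, columns=lines)),
        pd.Series(labels, index=lines),
    )


class TestConsensusCluster:
    def test_separated_clusters_give_binary_consensus(self):
        m, truth = gaussian_clusters(0, k=2, sep=10.0)
        res = st.consensus_cluster(m, k_range=range(2, 5), reps=100, seed=1)
        cons = res.consensus[2].to_numpy()
        same = truth.to_numpy()[:, None] == truth.to_numpy()[None, :]
        off = ~np.eye(len(truth), dtype=bool)
        assert np.all(cons[same & off] >= 0.95)
        assert np.all(cons[~same] <= 0.05)

    def test_delta_area_selects_planted_k(self):
        hits = 0
        for seed in range(10):
            m, _ = gaussian_clusters(seed, k=3, sep=4.0, n_genes=200)
            res = st.consensus_cluster(m, k_range=range(2, 7), reps=100, seed=seed)
            hits += res.chosen_k == 3
        assert hits >= 9

    def test_single_full_rep_gives_binary_entries(self):
        m, _ = gaussian_clusters(2, k=2)
        res = st.consensus_cluster(m, k_range=range(2, 4), reps=1, p_item=1.0, p_feature=1.0, seed=3)
        vals = np.unique(res.consensus[2].to_numpy())
        assert set(np.round(vals, 9)) <= {0.0, 1.0}

    def test_consensus_symmetric_bounded(self):
        m, _ = gaussian_clusters(4, k=2, sep=1.0)
        res = st.consensus_cluster(m, k_range=range(2, 5), reps=50, seed=5)
        for k, cons in res.consensus.items():
            c = cons.to_numpy()
            assert np.allclose(c, c.T)
            assert c.min() >= 0 and c.max() <= 1
            assert np.allclose(np.diag(c), 1.0)


class TestSilhouetteCore:
    def test_separated_clusters_all_core(self):
        m, truth = gaussian_clusters(6, k=2, sep=10.0)
        d = 1.0 - np.corrcoef(m.values.to_numpy().T)
        np.fill_diagonal(d, 0.0)
        dist = pd.DataFrame(d, index=m.lines, columns=m.lines)
        widths, core = st.silhouette_core(truth, dist)
        assert (widths > 0).all() and core.all()

    def test_equidistant_sample_width_zero(self):
        # point 'x' exactly between two tight clusters
        dist = pd.DataFrame(
            [
                [0.0, 1.0, 5.0, 5.0, 3.0],
                [1.0, 0.0, 5.0, 5.0, 3.0],
                [5.0, 5.0, 0.0, 1.0, 3.0],
                [5.0, 5.0, 1.0, 0.0, 3.0],
                [3.0, 3.0, 3.0, 3.0, 0.0],
            ],
            index=list("abcdx"),
            columns=list("abcdx"),
        )
        labels = pd.Series([1, 1, 2, 2, 1], index=list("abcdx"))
        widths, core = st.silhouette_core(labels, dist)
        assert widths["x"] == pytest.approx(0.0)
        assert not core["x"]

    def test_matches_bruteforce_on_six_points(self):
        rng = np.random.default_rng(7)
        pts = rng.standard_normal((6, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        labels = pd.Series([1, 1, 1, 2, 2, 2], index=list("abcdef"))
        dist = pd.DataFrame(d, index=labels.index, columns=labels.index)
        widths, _ = st.silhouette_core(labels, dist)
        for i, s in enumerate(labels.index):
            own = [j for j in range(6) if labels.iloc[j] == labels.iloc[i] and j != i]
            other = [j for j in range(6) if labels.iloc[j] != labels.iloc[i]]
            a = np.mean([d[i, j] for j in own])
            b = np.mean([d[i, j] for j in other])
            assert widths[s] == pytest.approx((b - a) / max(a, b), abs=1e-12)


class TestSubtypeSignatures:
    def test_null_has_bonferroni_control(self):
        sig_counts = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vals = rng.standard_normal((100, 30))
            m = ExpressionMatrix(pd.DataFrame(vals, columns=[f"s{i}" for i in range(30)]))
            labels = pd.Series([1] * 15 + [2] * 15, index=m.lines)
            res = st.subtype_signatures(m, labels)
            sig_counts.append(res["significant"].sum() / 2)  # two one-vs-rest passes
        assert np.mean(sig_counts) <= 1.0

    def test_shifted_genes_detected(self):
        rng = np.random.default_rng(8)
        vals = rng.standard_normal((100, 60))
        vals[:, :30] += 2.0  # every gene shifted 2 SD in subtype 1
        m = ExpressionMatrix(pd.DataFrame(vals, columns=[f"s{i}" for i in range(60)]))
        labels = pd.Series([1] * 30 + [2] * 30, index=m.lines)
        res = st.subtype_signatures(m, labels)
        frac = res.xs(1, level="subtype")["significant"].mean()
        assert frac >= 0.95

    def test_label_exchange_flips_direction(self):
        rng = np.random.default_rng(9)
        vals = rng.standard_normal((20, 24))
        vals[:, :12] += 1.0
        m = ExpressionMatrix(pd.DataFrame(vals, columns=[f"s{i}" for i in range(24)]))
        labels = pd.Series([1] * 12 + [2] * 12, index=m.lines)
        flipped = labels.map({1: 2, 2: 1})
        r1 = st.subtype_signatures(m, labels)
        r2 = st.subtype_signatures(m, flipped)
        d1 = r1.xs(1, level="subtype")["direction"]
        d2 = r2.xs(2, level="subtype")["direction"]
        assert (d1 == d2).all()
        assert (r1.xs(1, level="subtype")["direction"]
                == -r1.xs(2, level="subtype")["direction"]).all()


class TestNSCLoocv:
    def test_separable_classes_zero_error(self):
        rng = np.random.default_rng(10)
        vals = rng.standard_normal((50, 30))
        vals[:10, :15] += 5.0  # 10 marker genes, 5 SD shift
        m = ExpressionMatrix(pd.DataFrame(vals, columns=[f"s{i}" for i in range(30)]))
        labels = pd.Series([1] * 15 + [2] * 15, index=m.lines)
        err, preds = st.nsc_loocv(m, labels)
        assert err == 0.0

    def test_permuted_labels_chance_level(self):
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed + 100)
            vals = rng.standard_normal((60, 24))
            m = ExpressionMatrix(pd.DataFrame(vals, columns=[f"s{i}" for i in range(24)]))
            labels = pd.Series(rng.permutation([1] * 12 + [2] * 12), index=m.lines)
            err, _ = st.nsc_loocv(m, labels)
            errs.append(err)
        assert np.mean(errs) == pytest.approx(0.5, abs=0.15)

    def test_infinite_shrinkage_predicts_majority(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((30, 40))
        y = np.array([1] * 20 + [2] * 10)
        clf = st.NearestShrunkenCentroid(delta=1e9).fit(X, y)
        assert (clf.predict(X) == 1).all()

    def test_invariant_to_gene_and_sample_order(self):
        rng = np.random.default_rng(12)
        vals = rng.standard_normal((40, 20))
        vals[:5, :10] += 2.0
        genes = [f"g{i}" for i in range(40)]
        lines = [f"s{i}" for i in range(20)]
        m = ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=lines))
        labels = pd.Series([1] * 10 + [2] * 10, index=lines)
        err1, _ = st.nsc_loocv(m, labels)
        gperm = list(rng.permutation(genes))
        m2 = ExpressionMatrix(m.values.loc[gperm], m.line_meta)
        err2, _ = st.nsc_loocv(m2, labels)
        assert err1 == err2


class TestSubtypeVsSubpopulation:
    def test_identical_partition_extreme_p(self):
        from scipy.special import comb

        lines = [f"s{i}" for i in range(60)]
        labels = pd.Series([1] * 30 + [2] * 30, index=lines)
        subpop = pd.Series(["X"] * 30 + ["Y"] * 30, index=lines)
        res = st.subtype_vs_subpopulation(labels, subpop)
        row = res[(res.subtype == 1) & (res.subpop == "X")].iloc[0]
        assert row["p"] == pytest.approx(2 / comb(60, 30, exact=True), rel=1e-6)
        assert row["enrichment"] == 1

    def test_type_one_error_random_labels(self):
        hits = 0
        n_sims = 200
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            lines = [f"s{i}" for i in range(40)]
            labels = pd.Series(rng.integers(1, 3, 40), index=lines)
            subpop = pd.Series(rng.choice(["X", "Y"], 40), index=lines)
            res = st.subtype_vs_subpopulation(labels, subpop)
            hits += (res["p"] < 0.05).any()
        # 4 tests per sim but highly dependent; generous familywise bound
        assert hits / n_sims <= 0.25

    def test_small_table_exact_value(self):
        # 2x2 table {{3,1},{1,3}}: two-sided Fisher p = 0.485714...
        _, p = stats.fisher_exact([[3, 1], [1, 3]], alternative="two-sided")
        lines = [f"s{i}" for i in range(8)]
        labels = pd.Series([1, 1, 1, 1, 2, 2, 2, 2], index=lines)
        subpop = pd.Series(["X", "X", "X", "Y", "X", "Y", "Y", "Y"], index=lines)
        res = st.subtype_vs_subpopulation(labels, subpop)
        row = res[(res.subtype == 1) & (res.subpop == "X")].iloc[0]
        assert row["p"] == pytest.approx(p)
        # enumeration oracle over all tables with the same margins
        total = 0.0
        from scipy.stats import hypergeom

        obs = hypergeom.pmf(3, 8, 4, 4)
        for k in range(0, 5):
            pk = hypergeom.pmf(k, 8, 4, 4)
            if pk <= obs * (1 + 1e-9):
                total += pk
        assert row["p"] == pytest.approx(total, rel=1e-9)
        assert row["p"] == pytest.approx(0.485714285714, rel=1e-6)


class TestExpressionVsGeneticDistance:
    def test_identical_matrices_r_one(self):
        rng = np.random.default_rng(13)
        pts = rng.standard_normal((10, 3))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(10)]
        dm = pd.DataFrame(d, index=ids, columns=ids)
        r, p = st.expression_vs_genetic_distance(dm, dm, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_type_one_error_uniform(self):
        hits = 0
        n_sims = 100
        for seed in range(n_sims):
            rng = np.random.default_rng(seed + 500)
            ids = [f"s{i}" for i in range(30)]
            mats = []
            for _ in range(2):
                pts = rng.standard_normal((30, 5))
                d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
                mats.append(pd.DataFrame(d, index=ids, columns=ids))
            _, p = st.expression_vs_genetic_distance(mats[0], mats[1], n_perm=199, seed=seed)
            hits += p < 0.05
        assert 0.0 <= hits / n_sims <= 0.10

    def test_orientation_of_planted_relation(self):
        rng = np.random.default_rng(14)
        ids = [f"s{i}" for i in range(25)]
        pts = rng.standard_normal((25, 4))
        gdist = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        noise = 0.1 * np.abs(rng.standard_normal(gdist.shape))
        edist = gdist + (noise + noise.T) / 2
        np.fill_diagonal(edist, 0.0)
        gdm = pd.DataFrame(gdist, index=ids, columns=ids)
        edm = pd.DataFrame(edist, index=ids, columns=ids)
        r_dist, _ = st.expression_vs_genetic_distance(edm, gdm, n_perm=99, seed=1)
        assert r_dist > 0
        # similarity orientation flips the sign
        sim_m = edm.max().max() - edm
        sim_df = pd.DataFrame(sim_m.to_numpy() - np.diag(np.diag(sim_m.to_numpy())), index=ids, columns=ids)
        corr = np.corrcoef(
            sim_df.to_numpy()[np.triu_indices(25, 1)], gdm.to_numpy()[np.triu_indices(25, 1)]
        )[0, 1]
        assert corr < 0

    def test_too_few_samples_rejected(self):
        ids = ["a", "b", "c"]
        d = pd.DataFrame(np.zeros((3, 3)), index=ids, columns=ids)
        with pytest.raises(ValueError):
            st.expression_vs_genetic_distance(d, d)
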