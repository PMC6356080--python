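"""Signed weighted coexpression networks, modules, and cross-network
module preservation.

The pipeline follows the weighted-network recipe: robust biweight
midcorrelation (bicor) between gene pairs, signed soft-thresholded
adjacency a_ij = ((1 + c_ij)/2)^beta, topological overlap similarity,
average-linkage clustering of 1 - TOM with a fixed-height branch cut,
module eigengenes (first principal component per module, sign-oriented),
iterative merging of highly correlated eigengenes, and module membership
(kME) with multi-assignment above a threshold. Preservation of modules in
a second dataset is quantified with a permutation Z-summary combining
density and connectivity statistics, and a rank-based medianRank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class NetworkConfig:
    soft_power: int = 9
    min_module_size: int = 30
    me_merge_cor: float = 0.85
    mm_threshold: float = 0.4
    # branch-cut height: None = automatic largest-gap rule; a float is
    # interpreted as a fraction of the dendrogram's maximum merge height
    cut_height_frac: float | None = None

    def __post_init__(self) -> None:
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if not (0 < self.me_merge_cor < 1):
            raise ValueError("me_merge_cor must be in (0, 1)")
        if not (0 < self.mm_threshold < 1):
            raise ValueError("mm_threshold must be in (0, 1)")


# ---------------------------------------------------------------------------
# population adjustment


def adjust_population(m: ExpressionMatrix, labels: pd.Series) -> ExpressionMatrix:
    """Regress out subpopulation means, then inverse-normal transform.

    Per gene: residuals of an OLS regression on subpopulation indicator
    covariates (groups with fewer than 2 lines are dropped from the
    covariates with a warning), then the residual ranks are mapped to
    N(0, 1) quantiles (Blom offsets). Missing cells stay missing.
    """
    lines = m.lines
    missing_label = [ln for ln in lines if ln not in labels.index]
    if missing_label:
        raise ValueError(f"lines without a subpopulation label: {missing_label[:5]}")
    lab = labels.loc[lines].astype(str)
    counts = lab.value_counts()
    small = counts[counts < 2].index.tolist()
    if small:
        log.warning("subpopulations with <2 lines dropped from covariates: %s", small)
    groups = [g for g in counts.index if g not in small]
    design = pd.get_dummies(lab.where(lab.isin(groups), other="_pooled_"), dtype=float)

    X = design.to_numpy()
    out = m.values.copy()
    vals = m.values.to_numpy()
    res = np.full_like(vals, np.nan)
    for i in range(vals.shape[0]):
        ok = np.isfinite(vals[i])
        if ok.sum() < 3:
            continue
        Xo = X[ok]
        beta, *_ = np.linalg.lstsq(Xo, vals[i, ok], rcond=None)
        res[i, ok] = vals[i, ok] - Xo @ beta
    out.loc[:, :] = _rank_inverse_normal(res)
    return ExpressionMatrix(out, m.line_meta)


def _rank_inverse_normal(res: np.ndarray, c: float = 3.0 / 8) -> np.ndarray:
    """Row-wise rank-based inverse normal transform with Blom offsets."""
    out = np.full_like(res, np.nan)
    for i in range(res.shape[0]):
        ok = np.isfinite(res[i])
        n = int(ok.sum())
        if n == 0:
            continue
        ranks = stats.rankdata(res[i, ok])
        out[i, ok] = stats.norm.ppf((ranks - c) / (n - 2 * c + 1))
    return out


# ---------------------------------------------------------------------------
# bicor


def _bicor_weights(x: np.ndarray) -> np.ndarray:
    """Tukey-biweight-normalized deviations; Pearson fallback at MAD=0."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        dev = x - np.mean(x)
        if np.all(dev == 0):
            raise ValueError("constant vector: correlation undefined")
        return dev
    u = (x - med) / (9.0 * mad)
    w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
    return (x - med) * w


def bicor(x, y) -> float:
    """Biweight midcorrelation of two paired vectors.

    Median/MAD standardization with Tukey biweights (zero weight beyond 9
    MADs); a vector whose MAD is zero falls back to Pearson centering.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need >= 3 complete pairs")
    a = _bicor_weights(x[ok])
    b = _bicor_weights(y[ok])
    return float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))


def bicor_matrix(X: np.ndarray) -> np.ndarray:
    """All-pairs bicor between rows of ``X`` (no missing values allowed)."""
    if not np.all(np.isfinite(X)):
        raise ValueError("bicor_matrix requires complete data; impute first")
    rows = np.empty_like(X, dtype=float)
    for i in range(X.shape[0]):
        rows[i] = _bicor_weights(X[i])
    norms = np.linalg.norm(rows, axis=1)
    C = (rows @ rows.T) / np.outer(norms, norms)
    np.clip(C, -1.0, 1.0, out=C)
    np.fill_diagonal(C, 1.0)
    return C


# ---------------------------------------------------------------------------
# adjacency and TOM


def signed_adjacency(corr: np.ndarray, beta: int = 9) -> np.ndarray:
    """Signed soft-thresholded adjacency a_ij = ((1 + c_ij)/2)^beta."""
    corr = np.asarray(corr, dtype=float)
    if np.any(np.abs(corr) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    adj = ((1.0 + corr) / 2.0) ** beta
    np.fill_diagonal(adj, 1.0)
    return adj


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    l_ij sums shared neighbourhood weights over u != i, j and
    k_i = sum_{u != i} a_iu. Diagonal is 1.
    """
    adj = np.asarray(adj, dtype=float)
    if not np.allclose(adj, adj.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if np.any((adj < -1e-12) | (adj > 1 + 1e-12)):
        raise ValueError("adjacency entries must lie in [0, 1]")
    A = adj.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    L = A @ A  # sum over u != i, j since diagonal is zeroed
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (L + A) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


# ---------------------------------------------------------------------------
# module detection


@dataclass
class ModuleSet:
    """Module assignments, eigengenes, and membership for one network."""

    primary: pd.Series  # gene -> module label ("M1", ..., "unassigned")
    eigengenes: pd.DataFrame  # lines x modules
    membership: pd.DataFrame  # genes x modules (kME correlations)
    multi: dict[str, list[str]] = field(default_factory=dict)  # gene -> modules via MM
    var_explained: dict[str, float] = field(default_factory=dict)

    @property
    def modules(self) -> list[str]:
        return list(self.eigengenes.columns)

    def genes_of(self, module: str) -> pd.Index:
        return self.primary.index[self.primary == module]

    def sizes(self) -> dict[str, int]:
        return {m: int((self.primary == m).sum()) for m in self.modules}


def impute_missing(m: ExpressionMatrix) -> tuple[pd.DataFrame, float]:
    """Per-gene mean imputation; returns (complete frame, imputed fraction)."""
    vals = m.values.copy()
    n_missing = int(vals.isna().sum().sum())
    frac = n_missing / vals.size if vals.size else 0.0
    if n_missing:
        means = vals.mean(axis=1, skipna=True)
        vals = vals.apply(lambda row: row.fillna(means[row.name]), axis=1)
        log.info("mean-imputed %.2f%% of cells before network construction", 100 * frac)
    return vals, frac


def _module_eigengene(sub: np.ndarray) -> tuple[np.ndarray, float]:
    """First-PC per-line score of a module block (genes x lines), oriented.

    Rows are z-scored; the eigengene is the first right-singular vector of
    the standardized block, sign-flipped to correlate positively with the
    module's mean profile. Returns (per-line score, variance explained).
    """
    Z = stats.zscore(sub, axis=1, ddof=1)
    Z = Z[np.isfinite(Z).all(axis=1)]
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    me = Vt[0]
    mean_profile = sub.mean(axis=0)
    if np.corrcoef(me, mean_profile)[0, 1] < 0:
        me = -me
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    return me, var_explained


def detect_modules(
    expr: ExpressionMatrix,
    cfg: NetworkConfig | None = None,
) -> ModuleSet:
    """Detect coexpression modules in one expression dataset.

    Average-linkage hierarchical clustering of 1 - TOM with a fixed-height
    branch cut. By default the height is placed in the widest gap of the
    upper half of the merge-height distribution, which separates the
    correlated blocks from the band of noise-gene merges regardless of the
    dendrogram's absolute scale; ``cut_height_frac`` instead cuts at that
    fraction of the maximum merge height. Clusters below
    ``min_module_size`` fall into the "unassigned" pool; modules whose
    eigengenes correlate above ``me_merge_cor`` are merged iteratively;
    final labels are ordered by size (M1 largest); genes join every module
    whose kME exceeds ``mm_threshold`` (multi-assignment).
    """
    cfg = cfg or NetworkConfig()
    if expr.n_genes < 2 * cfg.min_module_size:
        raise ValueError("need at least 2 x min_module_size genes")
    vals, _ = impute_missing(expr)
    genes = vals.index
    X = vals.to_numpy()
    corr = bicor_matrix(X)
    adj = signed_adjacency(corr, cfg.soft_power)
    tom = tom_similarity(adj)
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    Z = linkage(squareform(diss, checks=False), method="average")
    if cfg.cut_height_frac is None:
        cut = _gap_cut_height(Z)
    else:
        cut = cfg.cut_height_frac * Z[:, 2].max()
    raw = fcluster(Z, t=cut, criterion="distance")

    # drop undersized clusters to the unassigned pool
    labels = np.array([f"c{c}" for c in raw], dtype=object)
    sizes = pd.Series(labels).value_counts()
    for c, n in sizes.items():
        if n < cfg.min_module_size:
            labels[labels == c] = "unassigned"
    if (labels != "unassigned").sum() == 0:
        log.warning("no cluster reached min_module_size; all genes unassigned")
        return _empty_moduleset(genes, expr.lines)
    if len(set(labels[labels != "unassigned"])) == 1:
        log.warning("all assigned genes fall in a single module")

    labels = _merge_modules(X, labels, cfg)

    # order by size
    keep = pd.Series(labels[labels != "unassigned"]).value_counts()
    rename = {old: f"M{i + 1}" for i, old in enumerate(keep.index)}
    primary = pd.Series(
        [rename.get(l, "unassigned") for l in labels], index=genes, name="module"
    )

    me_cols, var_exp = {}, {}
    for mod in sorted(rename.values(), key=lambda s: int(s[1:])):
        idx = np.flatnonzero(primary.to_numpy() == mod)
        me, ve = _module_eigengene(X[idx])
        me_cols[mod] = me
        var_exp[mod] = ve
    eigengenes = pd.DataFrame(me_cols, index=expr.lines)

    membership = pd.DataFrame(
        {mod: [bicor(X[i], eigengenes[mod].to_numpy()) for i in range(len(genes))]
         for mod in eigengenes.columns},
        index=genes,
    )
    multi = {
        g: list(membership.columns[membership.loc[g] > cfg.mm_threshold])
        for g in genes
    }
    return ModuleSet(primary, eigengenes, membership, multi, var_exp)


def _empty_moduleset(genes: pd.Index, lines: pd.Index) -> ModuleSet:
    return ModuleSet(
        pd.Series("unassigned", index=genes, name="module"),
        pd.DataFrame(index=lines),
        pd.DataFrame(index=genes),
    )


def _merge_modules(X: np.ndarray, labels: np.ndarray, cfg: NetworkConfig) -> np.ndarray:
    """Iteratively merge modules whose eigengenes correlate > me_merge_cor."""
    labels = labels.copy()
    while True:
        mods = sorted(set(labels) - {"unassigned"})
        if len(mods) < 2:
            return labels
        mes = {}
        for mod in mods:
            idx = np.flatnonzero(labels == mod)
            mes[mod], _ = _module_eigengene(X[idx])
        best = None
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                r = np.corrcoef(mes[mods[i]], mes[mods[j]])[0, 1]
                if r > cfg.me_merge_cor and (best is None or r > best[0]):
                    best = (r, mods[i], mods[j])
        if best is None:
            return labels
        _, a, b = best
        labels[labels == b] = a


def _gap_cut_height(Z: np.ndarray) -> float:
    """Cut height at the widest gap in the upper half of merge heights."""
    h = np.sort(Z[:, 2])
    top = h[h >= np.quantile(h, 0.5)]
    if len(top) < 2:
        return float(h.max()) * 0.95
    gaps = np.diff(top)
    i = int(np.argmax(gaps))
    return float((top[i] + top[i + 1]) / 2)


# ---------------------------------------------------------------------------
# module overlap


def module_overlap(
    a: ModuleSet,
    b: ModuleSet,
    universe: pd.Index,
) -> pd.DataFrame:
    """Pairwise module overlap with upper-tail hypergeometric p-values.

    For modules of sizes n1, n2 in a universe of N genes with overlap k:
    expected = n1 n2 / N and p = P(X >= k); Bonferroni-adjusted across all
    module pairs.
    """
    from .statsutil import hypergeom_sf

    if len(universe) == 0:
        raise ValueError("empty gene universe")
    rows = []
    N = len(universe)
    for ma in a.modules:
        ga = set(a.genes_of(ma)) & set(universe)
        for mb in b.modules:
            gb = set(b.genes_of(mb)) & set(universe)
            k = len(ga & gb)
            p = hypergeom_sf(k, N, len(ga), len(gb)) if k > 0 else 1.0
            rows.append(
                {
                    "module_a": ma,
                    "module_b": mb,
                    "n_a": len(ga),
                    "n_b": len(gb),
                    "overlap": k,
                    "expected": len(ga) * len(gb) / N,
                    "p": p,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=["module_a", "module_b", "n_a", "n_b", "overlap",
                     "expected", "p", "p_bonferroni"]
        )
    df["p_bonferroni"] = np.minimum(df["p"] * len(df), 1.0)
    return df


# ---------------------------------------------------------------------------
# module preservation


DENSITY_STATS = ("mean_cor", "mean_adj", "prop_var_explained", "mean_kme")
CONNECTIVITY_STATS = ("cor_kim", "cor_adj", "cor_kme")


@dataclass
class PreservationResult:
    z_summary: pd.Series
    median_rank: pd.Series
    z_components: pd.DataFrame  # modules x statistics
    observed: pd.DataFrame
    n_permutations: int


def _density_stats(corr: np.ndarray, adj: np.ndarray, X: np.ndarray, idx: np.ndarray):
    sub_c = corr[np.ix_(idx, idx)]
    sub_a = adj[np.ix_(idx, idx)]
    off = ~np.eye(len(idx), dtype=bool)
    me, ve = _module_eigengene(X[idx])
    kme = np.array([np.corrcoef(X[i], me)[0, 1] for i in idx])
    return {
        "mean_cor": float(sub_c[off].mean()),
        "mean_adj": float(sub_a[off].mean()),
        "prop_var_explained": ve,
        "mean_kme": float(kme.mean()),
    }


def _kim(adj: np.ndarray, idx: np.ndarray) -> np.ndarray:
    sub = adj[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, 0.0)
    return sub.sum(axis=1)


def _connectivity_stats(
    ref_corr, ref_adj, ref_X, ref_idx, test_corr, test_adj, test_X, test_idx
):
    tri = np.triu_indices(len(ref_idx), k=1)
    ca = np.corrcoef(
        ref_adj[np.ix_(ref_idx, ref_idx)][tri], test_adj[np.ix_(test_idx, test_idx)][tri]
    )[0, 1]
    ck = np.corrcoef(_kim(ref_adj, ref_idx), _kim(test_adj, test_idx))[0, 1]
    me_r, _ = _module_eigengene(ref_X[ref_idx])
    me_t, _ = _module_eigengene(test_X[test_idx])
    kme_r = np.array([np.corrcoef(ref_X[i], me_r)[0, 1] for i in ref_idx])
    kme_t = np.array([np.corrcoef(test_X[i], me_t)[0, 1] for i in test_idx])
    cm = np.corrcoef(kme_r, kme_t)[0, 1]
    return {"cor_kim": float(ck), "cor_adj": float(ca), "cor_kme": float(cm)}


def module_preservation(
    ref_expr: ExpressionMatrix,
    test_expr: ExpressionMatrix,
    modules: ModuleSet,
    n_perm: int = 200,
    seed: int = 0,
    soft_power: int = 9,
) -> PreservationResult:
    """Permutation Z-summary / medianRank preservation of ref modules in test.

    Density statistics (mean within-module correlation and adjacency,
    eigengene variance explained, mean kME) and connectivity statistics
    (ref-vs-test correlation of intramodular connectivity, adjacency, and
    kME) are computed for each module in the test data; their permutation
    Z-scores (random same-size gene sets drawn within the test dataset)
    are summarized as Z-summary = (median density Z + median connectivity
    Z) / 2. medianRank ranks modules by observed statistics (higher =
    better preserved = rank 1).
    """
    shared = ref_expr.genes.intersection(test_expr.genes)
    ref_vals, _ = impute_missing(ref_expr.subset_genes(shared))
    test_vals, _ = impute_missing(test_expr.subset_genes(shared))
    Xr, Xt = ref_vals.to_numpy(), test_vals.to_numpy()
    pos = {g: i for i, g in enumerate(shared)}

    corr_r = bicor_matrix(Xr)
    corr_t = bicor_matrix(Xt)
    adj_r = signed_adjacency(corr_r, soft_power)
    adj_t = signed_adjacency(corr_t, soft_power)

    rng = np.random.default_rng(seed)
    n_genes = len(shared)
    all_stats = DENSITY_STATS + CONNECTIVITY_STATS

    obs_rows, z_rows, kept = {}, {}, []
    for mod in modules.modules:
        genes = [g for g in modules.genes_of(mod) if g in pos]
        if len(genes) < 3:
            log.warning("module %s has <3 shared genes; skipped", mod)
            continue
        kept.append(mod)
        idx = np.array([pos[g] for g in genes])
        obs = _density_stats(corr_t, adj_t, Xt, idx)
        obs.update(
            _connectivity_stats(corr_r, adj_r, Xr, idx, corr_t, adj_t, Xt, idx)
        )
        perm = {s: np.empty(n_perm) for s in all_stats}
        for b in range(n_perm):
            pidx = rng.choice(n_genes, size=len(idx), replace=False)
            d = _density_stats(corr_t, adj_t, Xt, pidx)
            c = _connectivity_stats(corr_r, adj_r, Xr, idx, corr_t, adj_t, Xt, pidx)
            for s in DENSITY_STATS:
                perm[s][b] = d[s]
            for s in CONNECTIVITY_STATS:
                perm[s][b] = c[s]
        z = {}
        for s in all_stats:
            sd = perm[s].std(ddof=1)
            z[s] = (obs[s] - perm[s].mean()) / sd if sd > 0 else 0.0
        obs_rows[mod] = obs
        z_rows[mod] = z

    observed = pd.DataFrame.from_dict(obs_rows, orient="index")
    zdf = pd.DataFrame.from_dict(z_rows, orient="index")
    z_density = zdf[list(DENSITY_STATS)].median(axis=1)
    z_conn = zdf[list(CONNECTIVITY_STATS)].median(axis=1)
    z_summary = (z_density + z_conn) / 2.0

    ranks = observed.rank(ascending=False, axis=0)
    median_rank = ranks.median(axis=1)

    return PreservationResult(
        z_summary=z_summary,
        median_rank=median_rank,
        z_components=zdf,
        observed=observed,
        n_permutations=n_perm,
    )
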