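"""Consensus-clustering subtype discovery and validation.

Subtypes of the line panel are found by resampled consensus clustering
(hierarchical average linkage on 1 - Pearson distance), with the number of
clusters chosen from the consensus-CDF delta-area curve. Core samples are
those with positive silhouette width; subtype signatures come from
two-sided Wilcoxon rank-sum tests with Bonferroni control; generalizability
is checked by leave-one-out cross-validation of a nearest shrunken
centroid classifier; and subtypes are compared with genomic
subpopulations via Fisher exact tests and a Mantel-style
expression-vs-genetic-distance correlation.
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


# ---------------------------------------------------------------------------
# consensus clustering


@dataclass
class ConsensusResult:
    consensus: dict[int, pd.DataFrame]  # k -> samples x samples co-clustering freq
    cdf_area: dict[int, float]
    delta_area: dict[int, float]
    chosen_k: int
    labels: pd.Series
    silhouette: pd.Series = field(default_factory=pd.Series)
    core: pd.Series = field(default_factory=pd.Series)


def _pearson_distance(X: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows of X."""
    d = 1.0 - np.corrcoef(X)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def _hclust_labels(dist: np.ndarray, k: int) -> np.ndarray:
    Z = linkage(squareform(dist, checks=False), method="average")
    return fcluster(Z, t=k, criterion="maxclust")


def consensus_cluster(
    m: ExpressionMatrix,
    k_range: range = range(2, 9),
    reps: int = 1000,
    p_item: float = 0.8,
    p_feature: float = 0.8,
    seed: int = 0,
    chosen_k: int | None = None,
    rel_delta_threshold: float = 0.1,
) -> ConsensusResult:
    """Resampled consensus clustering of the lines (columns) of ``m``.

    Each rep subsamples ``p_item`` of the samples and ``p_feature`` of the
    genes, clusters with average linkage on (1 - Pearson) distance, and
    the consensus matrix accumulates co-clustering frequency among
    co-sampled pairs. k is chosen as the largest k whose relative
    delta-area (area under the consensus CDF) exceeds
    ``rel_delta_threshold`` — an automated elbow standing in for visual
    inspection — unless ``chosen_k`` overrides it. Final labels cluster
    1 - consensus at the chosen k.
    """
    rng = np.random.default_rng(seed)
    vals = m.values.to_numpy()
    # genes x samples -> rows = samples for clustering
    data = np.nan_to_num(vals, nan=np.nanmean(vals)).T
    n = data.shape[0]
    ks = [k for k in k_range if k <= n - 2]
    if not ks:
        raise ValueError("k_range too large for the number of samples")

    n_sub = max(2, int(round(p_item * n)))
    n_feat = max(2, int(round(p_feature * data.shape[1])))

    draws = []
    for _ in range(reps):
        items = rng.choice(n, size=n_sub, replace=False)
        feats = rng.choice(data.shape[1], size=n_feat, replace=False)
        draws.append((items, _pearson_distance(data[np.ix_(items, feats)])))

    co_sampled = np.zeros((n, n))
    for items, _ in draws:
        co_sampled[np.ix_(items, items)] += 1
    if np.any(co_sampled + np.eye(n) * 1e9 == 0):
        log.warning("some sample pairs were never co-sampled; their consensus is 0")

    consensus: dict[int, pd.DataFrame] = {}
    areas: dict[int, float] = {}
    grid = np.linspace(0, 1, 101)
    for k in ks:
        co_clustered = np.zeros((n, n))
        for items, dist in draws:
            lab = _hclust_labels(dist, k)
            same = lab[:, None] == lab[None, :]
            co_clustered[np.ix_(items, items)] += same
        with np.errstate(invalid="ignore", divide="ignore"):
            cons = np.where(co_sampled > 0, co_clustered / np.maximum(co_sampled, 1), 0.0)
        np.fill_diagonal(cons, 1.0)
        consensus[k] = pd.DataFrame(cons, index=m.lines, columns=m.lines)
        tri = cons[np.triu_indices(n, k=1)]
        cdf = np.searchsorted(np.sort(tri), grid, side="right") / tri.size
        areas[k] = float(np.trapezoid(cdf, grid))

    delta: dict[int, float] = {}
    prev = None
    for k in ks:
        delta[k] = areas[k] if prev is None else areas[k] - areas[prev]
        prev = k
    if chosen_k is None:
        chosen_k = ks[0]
        for i, k in enumerate(ks[1:], start=1):
            rel = delta[k] / max(areas[ks[i - 1]], 1e-12)
            if rel >= rel_delta_threshold:
                chosen_k = k
    labels = pd.Series(
        _hclust_labels(1.0 - consensus[chosen_k].to_numpy(), chosen_k),
        index=m.lines,
        name="subtype",
    )
    dist = 1.0 - consensus[chosen_k].to_numpy()
    np.fill_diagonal(dist, 0.0)
    sil, core = silhouette_core(labels, pd.DataFrame(dist, index=m.lines, columns=m.lines))
    return ConsensusResult(consensus, areas, delta, chosen_k, labels, sil, core)


# ---------------------------------------------------------------------------
# silhouette / core samples


def silhouette_core(labels: pd.Series, dist: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Standard silhouette widths on a precomputed distance; core = width > 0.

    Samples in singleton clusters have undefined width and are marked
    non-core (width NaN).
    """
    from sklearn.metrics import silhouette_samples

    lab = labels.to_numpy()
    counts = pd.Series(lab).value_counts()
    widths = pd.Series(np.nan, index=labels.index, name="silhouette")
    multi = counts[counts >= 2].index
    if len(multi) >= 2:
        keep = np.isin(lab, multi)
        sub = dist.to_numpy()[np.ix_(keep, keep)]
        widths.loc[labels.index[keep]] = silhouette_samples(sub, lab[keep], metric="precomputed")
    core = widths > 0
    core.name = "core"
    return widths, core


# ---------------------------------------------------------------------------
# signatures


def subtype_signatures(m: ExpressionMatrix, labels: pd.Series) -> pd.DataFrame:
    """One-vs-rest two-sided Wilcoxon rank-sum per gene, Bonferroni-adjusted.

    Returns a frame indexed by (subtype, gene) with statistic, raw p,
    Bonferroni p, direction (+1 up in subtype), and significance at
    adjusted p < 0.05. Genes observed in fewer than 3 samples in either
    group are skipped.
    """
    rows = []
    for subtype in sorted(labels.unique()):
        in_lines = labels.index[labels == subtype]
        out_lines = labels.index[labels != subtype]
        sub_in = m.values[m.lines.intersection(in_lines)]
        sub_out = m.values[m.lines.intersection(out_lines)]
        for g in m.genes:
            x = sub_in.loc[g].dropna().to_numpy()
            y = sub_out.loc[g].dropna().to_numpy()
            if x.size < 3 or y.size < 3:
                continue
            stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
            rows.append(
                {
                    "subtype": subtype,
                    "gene": g,
                    "statistic": float(stat),
                    "p": float(p),
                    "direction": 1 if np.median(x) > np.median(y) else -1,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    n_tests = len(df)
    df["p_bonferroni"] = np.minimum(df["p"] * n_tests, 1.0)
    df["significant"] = df["p_bonferroni"] < 0.05
    return df.set_index(["subtype", "gene"])


# ---------------------------------------------------------------------------
# nearest shrunken centroid + LOOCV


class NearestShrunkenCentroid:
    """Soft-thresholded class centroids with pooled within-class SD.

    Per gene g and class k the standardized centroid deviation is
    d_kg = (xbar_kg - xbar_g) / (m_k (s_g + s0)) with
    m_k = sqrt(1/n_k - 1/n) and s0 the median pooled SD; shrinkage
    soft-thresholds d by Delta; classification minimizes the discriminant
    sum_g (x_g - xbar'_kg)^2 / (s_g + s0)^2 - 2 log pi_k.
    """

    def __init__(self, delta: float = 0.0):
        self.delta = delta

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NearestShrunkenCentroid":
        self.classes_ = np.unique(y)
        n, p = X.shape
        overall = X.mean(axis=0)
        k = len(self.classes_)
        cent = np.empty((k, p))
        nk = np.empty(k)
        ss = np.zeros(p)
        for i, c in enumerate(self.classes_):
            sub = X[y == c]
            nk[i] = len(sub)
            cent[i] = sub.mean(axis=0)
            ss += ((sub - cent[i]) ** 2).sum(axis=0)
        s = np.sqrt(ss / max(n - k, 1))
        s0 = np.median(s)
        mk = np.sqrt(1.0 / nk - 1.0 / n)
        d = (cent - overall) / (mk[:, None] * (s + s0))
        d_shrunk = np.sign(d) * np.maximum(np.abs(d) - self.delta, 0.0)
        self.centroids_ = overall + mk[:, None] * (s + s0) * d_shrunk
        self.scale_ = s + s0
        self.priors_ = nk / n
        self.max_delta_ = float(np.abs(d).max())
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = np.empty((X.shape[0], len(self.classes_)))
        for i in range(len(self.classes_)):
            scores[:, i] = (((X - self.centroids_[i]) / self.scale_) ** 2).sum(axis=1)
            scores[:, i] -= 2.0 * np.log(self.priors_[i])
        return self.classes_[np.argmin(scores, axis=1)]


def nsc_loocv(
    m: ExpressionMatrix,
    labels: pd.Series,
    n_deltas: int = 30,
) -> tuple[float, pd.Series]:
    """Leave-one-out error of a nearest shrunken centroid classifier.

    For each held-out line the classifier is trained on the rest; the
    shrinkage Delta is picked on the training fold by resubstitution error
    (ties resolved to the median tied value). Returns (error rate,
    per-line predictions).
    """
    lines = [ln for ln in m.lines if ln in labels.index]
    X_all = np.nan_to_num(
        m.values[lines].to_numpy().T,
        nan=float(np.nanmean(m.values.to_numpy())),
    )
    y_all = labels.loc[lines].to_numpy()
    preds = {}
    n_err = 0
    n_eval = 0
    for i, line in enumerate(lines):
        mask = np.ones(len(lines), dtype=bool)
        mask[i] = False
        X_tr, y_tr = X_all[mask], y_all[mask]
        if len(np.unique(y_tr)) < 2:
            log.warning("fold %s skipped: a class vanished in training", line)
            continue
        base = NearestShrunkenCentroid(0.0).fit(X_tr, y_tr)
        grid = np.linspace(0.0, base.max_delta_, n_deltas)
        errs = np.array(
            [
                float(np.mean(NearestShrunkenCentroid(d).fit(X_tr, y_tr).predict(X_tr) != y_tr))
                for d in grid
            ]
        )
        # ties resolved to the median tied delta: resubstitution error is flat
        # over wide shrinkage ranges, and the extremes are degenerate
        tied = np.flatnonzero(errs == errs.min())
        best_delta = float(grid[tied[len(tied) // 2]])
        clf = NearestShrunkenCentroid(best_delta).fit(X_tr, y_tr)
        pred = clf.predict(X_all[i : i + 1])[0]
        preds[line] = pred
        n_eval += 1
        n_err += int(pred != y_all[i])
    if n_eval == 0:
        raise ValueError("no evaluable folds")
    return n_err / n_eval, pd.Series(preds, name="prediction")


# ---------------------------------------------------------------------------
# subtype vs subpopulation


def subtype_vs_subpopulation(labels: pd.Series, subpops: pd.Series) -> pd.DataFrame:
    """Two-sided Fisher exact test of each (subtype, subpopulation) 2x2 table."""
    shared = labels.index.intersection(subpops.index)
    lab, sp = labels.loc[shared], subpops.loc[shared]
    rows = []
    for subtype in sorted(lab.unique()):
        for pop in sorted(sp.unique()):
            a = int(((lab == subtype) & (sp == pop)).sum())
            b = int(((lab == subtype) & (sp != pop)).sum())
            c = int(((lab != subtype) & (sp == pop)).sum())
            d = int(((lab != subtype) & (sp != pop)).sum())
            if min(a + b, c + d, a + c, b + d) == 0:
                log.warning("empty margin for subtype %s / subpop %s; p = 1", subtype, pop)
                p, odds = 1.0, np.nan
            else:
                odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            expected = (a + b) * (a + c) / max(len(shared), 1)
            rows.append(
                {
                    "subtype": subtype,
                    "subpop": pop,
                    "n_overlap": a,
                    "expected": expected,
                    "p": float(p),
                    "enrichment": 1 if a > expected else (-1 if a < expected else 0),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression vs genetic distance (Mantel)


def expression_vs_genetic_distance(
    expr_dist: pd.DataFrame,
    genetic_dist: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel correlation between two sample distance matrices.

    Pearson correlation over unordered sample pairs; significance from
    permuting sample identities of one matrix. Returns (r, p).
    """
    from skbio.stats.distance import DistanceMatrix, mantel

    shared = expr_dist.index.intersection(genetic_dist.index)
    if len(shared) < 4:
        raise ValueError("need at least 4 shared samples")
    a = expr_dist.loc[shared, shared].to_numpy().astype(float)
    b = genetic_dist.loc[shared, shared].to_numpy().astype(float)
    for x in (a, b):
        np.fill_diagonal(x, 0.0)
    a = (a + a.T) / 2
    b = (b + b.T) / 2
    r, p, _ = mantel(
        DistanceMatrix(a, ids=list(shared)),
        DistanceMatrix(b, ids=list(shared)),
        method="pearson",
        permutations=n_perm,
        seed=seed,
    )
    return float(r), float(p)
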