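"""Self-organizing-map integration of per-gene multi-omics summaries.

Each gene is described by six measurements — median mRNA and median
protein level within each of the three subpopulations — converted to
percentiles by each measurement's empirical CDF. Genes are placed on a
toroidal hexagonal SOM trained online with a linearly decaying learning
rate over many random restarts (keeping the restart with the smallest
mean quantization error), and the codebook vectors are grouped into
expression archetypes with affinity propagation on negative squared
distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .containers import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class SOMConfig:
    grid_x: int = 11
    grid_y: int = 8
    lr_start: float = 0.05
    lr_end: float = 0.01
    presentations: int = 100  # passes of the full dataset through the map
    restarts: int = 50
    ap_q: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_x * self.grid_y < 4:
            raise ValueError("grid must have at least 4 units")
        if not (0 < self.ap_q < 1):
            raise ValueError("ap_q must be in (0, 1)")


@dataclass
class SOMModel:
    codebook: np.ndarray  # units x n_dims
    bmu: pd.Series  # gene -> winning unit index
    quantization_error: float
    restart_errors: np.ndarray
    chosen_restart: int
    grid: tuple[int, int]
    unit_clusters: pd.Series = field(default_factory=pd.Series)  # unit -> cluster
    exemplars: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# percentiles


def to_percentiles(df: pd.DataFrame) -> pd.DataFrame:
    """Transform each column by its own ECDF, F(x) = rank(x)/n (average ranks).

    Output lies in (0, 1]; invariant to strictly monotone transforms of a
    column. Constant columns are rejected by name.
    """
    out = {}
    for col in df.columns:
        x = df[col].to_numpy(dtype=float)
        if np.unique(x[np.isfinite(x)]).size < 2:
            raise ValueError(f"column {col!r} is constant; ECDF undefined")
        out[col] = stats.rankdata(x) / len(x)
    return pd.DataFrame(out, index=df.index)


# ---------------------------------------------------------------------------
# per-gene subpopulation summaries


def subpopulation_gene_summary(
    mrna: ExpressionMatrix,
    protein: ExpressionMatrix,
    labels: pd.Series,
    subpops: tuple[str, ...] = ("NSS", "SS", "TST"),
) -> pd.DataFrame:
    """Six-column per-gene table: median mRNA and protein per subpopulation.

    Genes missing any of the six summaries are dropped (and counted in the
    log). Raises if a subpopulation has no labelled lines.
    """
    cols = {}
    for level, mat in (("mrna", mrna), ("protein", protein)):
        lab = labels.reindex(mat.lines)
        for sp in subpops:
            lines = mat.lines[(lab == sp).to_numpy()]
            if len(lines) == 0:
                raise ValueError(f"subpopulation {sp} absent from {level} matrix")
            cols[f"{level}_{sp}"] = mat.values[lines].median(axis=1, skipna=True)
    df = pd.DataFrame(cols)
    n_before = len(df)
    df = df.dropna()
    if n_before - len(df):
        log.info("dropped %d genes lacking one of the six summaries", n_before - len(df))
    return df


# ---------------------------------------------------------------------------
# toroidal hexagonal grid


def hex_unit_distances(grid_x: int, grid_y: int) -> np.ndarray:
    """Pairwise Euclidean distances between units on a toroidal hex lattice.

    Units live on an offset hexagonal grid (odd rows shifted by 0.5, row
    spacing sqrt(3)/2); toroidal distance is the minimum over the nine
    wrap-around translations of the plane.
    """
    xs = np.arange(grid_x)
    ys = np.arange(grid_y)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    px = gx + 0.5 * (gy % 2)
    py = gy * (np.sqrt(3) / 2)
    coords = np.column_stack([px.ravel(), py.ravel()])
    width = float(grid_x)
    height = grid_y * (np.sqrt(3) / 2)
    n = coords.shape[0]
    d = np.full((n, n), np.inf)
    for dx in (-width, 0.0, width):
        for dy in (-height, 0.0, height):
            shifted = coords + np.array([dx, dy])
            dd = np.sqrt(
                ((coords[:, None, :] - shifted[None, :, :]) ** 2).sum(axis=2)
            )
            d = np.minimum(d, dd)
    return d


@njit(cache=True)
def _som_train_loop(codebook, data, order, unit_dist, lrs, radii):  # pragma: no cover
    n_steps = order.shape[0]
    n_units, n_dim = codebook.shape
    for t in range(n_steps):
        x = data[order[t]]
        # best matching unit
        best, best_d = 0, 1e300
        for u in range(n_units):
            s = 0.0
            for j in range(n_dim):
                diff = codebook[u, j] - x[j]
                s += diff * diff
            if s < best_d:
                best_d, best = s, u
        r = radii[t]
        lr = lrs[t]
        for u in range(n_units):
            h = np.exp(-(unit_dist[best, u] ** 2) / (2.0 * r * r))
            if h < 1e-12:
                continue
            for j in range(n_dim):
                codebook[u, j] += lr * h * (x[j] - codebook[u, j])
    return codebook


def _quantization(codebook: np.ndarray, data: np.ndarray) -> tuple[np.ndarray, float]:
    d2 = ((data[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
    bmu = d2.argmin(axis=1)
    return bmu, float(np.sqrt(d2[np.arange(len(data)), bmu]).mean())


def train_som(data: pd.DataFrame, cfg: SOMConfig | None = None) -> SOMModel:
    """Train the SOM over multiple random restarts, keeping the best map.

    Online updates with a learning rate decaying linearly from
    ``lr_start`` to ``lr_end`` and a Gaussian neighbourhood whose radius
    shrinks from half the lattice diameter to 1. Across restarts the model
    minimizing the mean distance of data points to their winning codebook
    vectors is kept.
    """
    cfg = cfg or SOMConfig()
    X = data.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("SOM input must be finite")
    n_units = cfg.grid_x * cfg.grid_y
    if X.shape[0] < n_units:
        log.warning("fewer genes (%d) than SOM units (%d)", X.shape[0], n_units)
    unit_dist = hex_unit_distances(cfg.grid_x, cfg.grid_y)
    n_steps = cfg.presentations * X.shape[0]
    lrs = np.linspace(cfg.lr_start, cfg.lr_end, n_steps)
    radius0 = unit_dist.max() / 2.0
    radii = np.linspace(radius0, 1.0, n_steps)

    rng = np.random.default_rng(cfg.seed)
    best = None
    errors = np.empty(cfg.restarts)
    for r in range(cfg.restarts):
        codebook = rng.uniform(X.min(axis=0), X.max(axis=0), size=(n_units, X.shape[1]))
        order = np.concatenate(
            [rng.permutation(X.shape[0]) for _ in range(cfg.presentations)]
        )
        codebook = _som_train_loop(codebook, X, order, unit_dist, lrs, radii)
        bmu, err = _quantization(codebook, X)
        errors[r] = err
        if best is None or err < best[2]:
            best = (codebook, bmu, err, r)
    codebook, bmu, err, chosen = best
    return SOMModel(
        codebook=codebook,
        bmu=pd.Series(bmu, index=data.index, name="unit"),
        quantization_error=err,
        restart_errors=errors,
        chosen_restart=chosen,
        grid=(cfg.grid_x, cfg.grid_y),
    )


# ---------------------------------------------------------------------------
# affinity propagation on codebook vectors


def cluster_codebook(model: SOMModel, q: float = 0.1, damping: float = 0.9,
                     max_iter: int = 1000, seed: int = 0) -> SOMModel:
    """Affinity propagation over codebook vectors, preference = q-quantile.

    Similarity s(i, j) = -||c_i - c_j||^2; the preference is the
    ``q``-quantile of the off-diagonal similarities. Unit clusters (and by
    inheritance gene clusters through the BMU) are written back onto the
    model.
    """
    from sklearn.cluster import AffinityPropagation

    C = model.codebook
    d2 = ((C[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
    S = -d2
    off = S[~np.eye(len(C), dtype=bool)]
    if off.size == 0 or off.max() - off.min() < 1e-10:
        # all codebook vectors coincide: one cluster, exemplar unit 0
        model.unit_clusters = pd.Series(np.zeros(len(C), dtype=int), name="cluster")
        model.exemplars = [0]
        return model
    pref = float(np.quantile(off, q))
    ap = AffinityPropagation(
        affinity="precomputed",
        damping=damping,
        max_iter=max_iter,
        preference=pref,
        random_state=seed,
    )
    labels = ap.fit_predict(S)
    if len(ap.cluster_centers_indices_) == 0 or np.any(labels < 0):
        raise RuntimeError(
            "affinity propagation did not converge; increase damping or max_iter"
        )
    model.unit_clusters = pd.Series(labels, name="cluster")
    model.exemplars = list(ap.cluster_centers_indices_)
    return model


def gene_clusters(model: SOMModel) -> pd.Series:
    """Genes inherit the cluster of their winning unit."""
    if model.unit_clusters.empty:
        raise ValueError("run cluster_codebook first")
    return model.bmu.map(model.unit_clusters).rename("cluster")
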