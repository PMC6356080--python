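"""Mixed-model cis/trans QTL mapping with a conditional protein-specific test.

Associations between SNP dosages and protein or mRNA abundance are scanned
with a single-variance-component mixed model y = Xb + Qc + g + e,
g ~ (0, sg^2 K), e ~ (0, se^2 I), where K is a centered genomic
relationship matrix and Q carries population-structure covariates.
Variance components are estimated once per trait by REML on the
covariate-only model and reused for every SNP (the P3D approximation);
each SNP then gets a generalized-least-squares t-test. Multiple testing is
controlled by BH within level for cis scans and a Bonferroni-style
suggestive cutoff for trans scans; significant SNPs are clumped into QTLs
by LD (r^2 >= 0.1 with the lead SNP). A conditional likelihood-ratio test
comparing Y = aX + bP + gM + e against Y = bP + gM + e (M = mRNA level)
flags protein-specific QTLs whose effect is not mediated by transcription.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .containers import ExpressionMatrix, GenotypeMatrix
from .statsutil import bh_threshold, hypergeom_logsf, hypergeom_sf

log = logging.getLogger(__name__)

CIS_WINDOW = 200_000


# ---------------------------------------------------------------------------
# kinship


def kinship_matrix(geno: GenotypeMatrix) -> pd.DataFrame:
    """Centered genomic relationship matrix K = Z Z^T / m, Z standardized dosages."""
    if geno.n_lines < 2 or geno.n_snps < 10:
        raise ValueError("need >= 2 lines and >= 10 SNPs")
    D = geno.dosages.to_numpy()
    means = np.nanmean(D, axis=1, keepdims=True)
    sds = np.nanstd(D, axis=1, keepdims=True)
    poly = sds[:, 0] > 0
    if not poly.any():
        raise ValueError("all SNPs are monomorphic")
    Z = (D[poly] - means[poly]) / sds[poly]
    Z = np.nan_to_num(Z)
    K = Z.T @ Z / Z.shape[0]
    K = (K + K.T) / 2
    return pd.DataFrame(K, index=geno.lines, columns=geno.lines)


# ---------------------------------------------------------------------------
# REML (EMMA-style, eigendecomposition of K)


def _reml_delta(y: np.ndarray, Q: np.ndarray, s: np.ndarray, U: np.ndarray) -> float:
    """REML estimate of delta = se^2/sg^2 given eigenpairs (s, U) of K."""
    yt = U.T @ y
    Qt = U.T @ Q
    n, c = Q.shape

    def neg_rll(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = 1.0 / (s + delta)
        sw = np.sqrt(w)
        Qw = Qt * sw[:, None]
        yw = yt * sw
        beta, *_ = np.linalg.lstsq(Qw, yw, rcond=None)
        rss = float(np.sum((yw - Qw @ beta) ** 2))
        _, logdet_q = np.linalg.slogdet(Qw.T @ Qw)
        return 0.5 * (
            (n - c) * np.log(rss) - np.sum(np.log(w)) + logdet_q
        )

    res = minimize_scalar(neg_rll, bounds=(-10.0, 10.0), method="bounded")
    return float(np.exp(res.x))


@dataclass
class AssociationScan:
    """Per-SNP association results for one trait."""

    trait: str
    level: str  # "protein" | "mrna"
    results: pd.DataFrame  # snp-indexed: beta, se, p, maf
    scope: str  # "cis" | "genome"
    n_lines: int


def mlm_scan(
    trait: pd.Series,
    geno: GenotypeMatrix,
    K: pd.DataFrame,
    Q: pd.DataFrame | None = None,
    scope: str = "genome",
    maf_min: float = 0.05,
    trait_name: str = "trait",
    level: str = "protein",
    _eig_cache: dict | None = None,
) -> AssociationScan:
    """P3D mixed-model scan of one trait over the SNPs in ``geno``.

    Lines with missing trait values are dropped; SNPs failing the MAF
    filter within the used lines are excluded. If REML fails the scan
    falls back to OLS with a logged warning.
    """
    lines = [ln for ln in geno.lines if ln in trait.index and np.isfinite(trait[ln])]
    if len(lines) < 20:
        raise ValueError(f"need >= 20 lines with non-missing trait, got {len(lines)}")
    y = trait.loc[lines].to_numpy(dtype=float)
    Km = K.loc[lines, lines].to_numpy()
    if Q is None:
        Qm = np.ones((len(lines), 1))
    else:
        Qm = np.column_stack([np.ones(len(lines)), Q.loc[lines].to_numpy(dtype=float)])

    key = (tuple(lines),)
    if _eig_cache is not None and key in _eig_cache:
        s, U = _eig_cache[key]
    else:
        s, U = np.linalg.eigh(Km)
        s = np.clip(s, 0.0, None)
        if _eig_cache is not None:
            _eig_cache[key] = (s, U)

    if np.allclose(Km, 0.0):
        w = np.ones(len(lines))
    else:
        try:
            delta = _reml_delta(y, Qm, s, U)
            w = 1.0 / (s + delta)
        except np.linalg.LinAlgError:
            log.warning("REML failed for %s; falling back to OLS", trait_name)
            w = np.ones(len(lines))

    sw = np.sqrt(w)
    yt = (U.T @ y) * sw
    Qt = (U.T @ Qm) * sw[:, None]

    D = geno.dosages[lines].to_numpy()
    # per-SNP missing dosage cells are mean-imputed for the scan
    row_mean = np.nanmean(D, axis=1)
    nanmask = ~np.isfinite(D)
    if nanmask.any():
        D = np.where(nanmask, row_mean[:, None], D)
    freq = D.mean(axis=1) / 2.0
    maf = np.minimum(freq, 1 - freq)
    keep = maf >= maf_min
    snps = geno.snps[keep]
    G = D[keep]

    Gt = (G @ U) * sw[None, :]  # rotated, weighted dosages (snps x lines)

    # partition out covariates
    Qpinv = np.linalg.pinv(Qt)
    y_res = yt - Qt @ (Qpinv @ yt)
    G_res = Gt - (Gt @ Qpinv.T) @ Qt.T
    gg = np.einsum("ij,ij->i", G_res, G_res)
    gy = G_res @ y_res
    ok = gg > 1e-12
    beta = np.where(ok, gy / np.where(ok, gg, 1.0), np.nan)
    yy = float(y_res @ y_res)
    rss = yy - np.where(ok, beta**2 * gg, 0.0)
    df = len(lines) - Qt.shape[1] - 1
    sigma2 = rss / df
    se = np.sqrt(np.where(ok, sigma2 / np.where(ok, gg, 1.0), np.nan))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    p = np.where(ok, np.clip(p, np.finfo(float).tiny, 1.0), np.nan)

    res = pd.DataFrame(
        {"beta": beta, "se": se, "p": p, "maf": maf[keep]}, index=snps
    ).join(geno.snp_meta[["chrom", "pos"]])
    # SNPs collinear with the covariates have no testable effect
    res = res[np.isfinite(res["p"])]
    return AssociationScan(trait_name, level, res, scope, len(lines))


# ---------------------------------------------------------------------------
# thresholds


def bonferroni_cutoff(n_markers: int, n_traits: int, numerator: float = 10) -> float:
    """Suggestive genome-wide cutoff numerator / (n_markers * n_traits), capped at 1."""
    if n_markers <= 0 or n_traits <= 0:
        raise ValueError("marker and trait counts must be positive")
    return min(1.0, numerator / (n_markers * n_traits))


# ---------------------------------------------------------------------------
# LD pruning and clumping


def _r2_matrix(G: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between SNP dosage rows (complete pairs)."""
    with np.errstate(invalid="ignore"):
        c = np.atleast_2d(np.corrcoef(G))
    return np.nan_to_num(c**2)


def ld_prune(
    geno: GenotypeMatrix,
    window: int = 50,
    step: int = 50,
    r2_max: float = 0.1,
) -> pd.Index:
    """Greedy sliding-window LD pruning (plink indep-pairwise style).

    Within windows of ``window`` SNPs advanced by ``step`` (position-sorted
    per chromosome), pairs with r^2 > ``r2_max`` lose the member with the
    lower MAF (ties: the later position). Surviving SNPs have all
    within-window pairwise r^2 <= ``r2_max``.
    """
    maf = geno.maf()
    keep: set[str] = set()
    removed: set[str] = set()
    for chrom, meta in geno.snp_meta.groupby("chrom"):
        order = meta.sort_values("pos").index.to_list()
        start = 0
        while start < len(order):
            win = [s for s in order[start : start + window] if s not in removed]
            if len(win) > 1:
                G = geno.dosages.loc[win].to_numpy()
                G = np.where(np.isfinite(G), G, np.nanmean(G, axis=1, keepdims=True))
                r2 = _r2_matrix(G)
                active = list(range(len(win)))
                while True:
                    worst = None
                    for ii in range(len(active)):
                        for jj in range(ii + 1, len(active)):
                            a, b = active[ii], active[jj]
                            if r2[a, b] > r2_max:
                                worst = (a, b)
                                break
                        if worst:
                            break
                    if worst is None:
                        break
                    a, b = worst
                    sa, sb = win[a], win[b]
                    if maf[sa] < maf[sb]:
                        drop = a
                    elif maf[sb] < maf[sa]:
                        drop = b
                    else:  # tie -> later position
                        drop = a if meta.loc[sa, "pos"] > meta.loc[sb, "pos"] else b
                    removed.add(win[drop])
                    active.remove(drop)
            keep.update(s for s in win if s not in removed)
            start += step
    return pd.Index([s for s in geno.snps if s in keep and s not in removed])


@dataclass
class QTLRecord:
    gene: str
    level: str
    lead_snp: str
    p: float
    qtl_class: str  # "cis-pQTL" | "cis-eQTL" | "trans-pQTL" | ...
    clump: list[str]
    annotation: str | None = None
    conditional_p: float | None = None
    protein_specific: bool | None = None


def clump_qtls(
    scan: AssociationScan,
    geno: GenotypeMatrix,
    threshold: float,
    r2_min: float = 0.1,
    qtl_class: str | None = None,
) -> list[QTLRecord]:
    """Greedy LD clumping of significant SNPs into QTLs.

    Significant SNPs are visited by increasing p; each lead absorbs every
    remaining significant SNP with r^2 >= ``r2_min`` to it; every
    significant SNP ends up in exactly one clump, and the lead has the
    clump's minimum p.
    """
    sig = scan.results[scan.results["p"] <= threshold].sort_values("p")
    if sig.empty:
        return []
    G = geno.dosages.loc[sig.index].to_numpy()
    G = np.where(np.isfinite(G), G, np.nanmean(G, axis=1, keepdims=True))
    r2 = _r2_matrix(G)
    order = list(range(len(sig)))
    records = []
    cls = qtl_class or f"{scan.scope}-{'p' if scan.level == 'protein' else 'e'}QTL"
    remaining = set(order)
    for i in order:
        if i not in remaining:
            continue
        members = [j for j in remaining if r2[i, j] >= r2_min or j == i]
        remaining -= set(members)
        records.append(
            QTLRecord(
                gene=scan.trait,
                level=scan.level,
                lead_snp=str(sig.index[i]),
                p=float(sig["p"].iloc[i]),
                qtl_class=cls,
                clump=[str(sig.index[j]) for j in members],
            )
        )
    return records


# ---------------------------------------------------------------------------
# conditional LRT


@dataclass
class ConditionalModelFit:
    lrt: float
    df: int
    p: float
    alpha: float  # SNP effect in the full model
    n: int


def conditional_lrt(
    y: pd.Series,
    x: pd.Series,
    m: pd.Series,
    Q: pd.DataFrame | None = None,
) -> ConditionalModelFit:
    """LRT of the SNP term in Y = aX + bP + gM + e vs Y = bP + gM + e.

    Both models are plain linear models fit by maximum likelihood on the
    shared complete cases; the statistic is 2 (ll_full - ll_reduced) =
    n log(RSS_reduced / RSS_full) ~ chi2 with 1 df.
    """
    idx = y.index.intersection(x.index).intersection(m.index)
    sub = pd.DataFrame({"y": y.loc[idx], "x": x.loc[idx], "m": m.loc[idx]})
    if Q is not None:
        sub = sub.join(Q.loc[idx].add_prefix("q_"))
    sub = sub.dropna()
    n = len(sub)
    if n < 20:
        raise ValueError(f"need >= 20 complete cases, got {n}")
    xv = sub["x"].to_numpy()
    if np.std(xv) == 0:
        raise ValueError("SNP constant on complete cases; test skipped")
    covs = [np.ones(n), sub["m"].to_numpy()]
    covs += [sub[c].to_numpy() for c in sub.columns if c.startswith("q_")]
    X_red = np.column_stack(covs)
    X_full = np.column_stack([xv] + covs)

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, sub["y"].to_numpy(), rcond=None)
        r = sub["y"].to_numpy() - X @ beta
        return float(r @ r), beta

    rss_full, beta_full = rss(X_full)
    rss_red, _ = rss(X_red)
    lrt = max(0.0, n * np.log(rss_red / max(rss_full, 1e-300)))
    p = float(stats.chi2.sf(lrt, 1))
    return ConditionalModelFit(lrt=lrt, df=1, p=p, alpha=float(beta_full[0]), n=n)


def classify_protein_specific(
    qtls: list[QTLRecord],
    protein: ExpressionMatrix,
    mrna: ExpressionMatrix,
    geno: GenotypeMatrix,
    Q: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> list[QTLRecord]:
    """Run the conditional LRT on each QTL lead and flag protein-specific ones.

    The Bonferroni family is the set of tested lead SNP-gene pairs; a QTL
    is protein-specific when its adjusted conditional p is below ``alpha``.
    Records are updated in place (conditional_p holds the raw LRT p).
    """
    tested = []
    for rec in qtls:
        if rec.gene not in protein.genes or rec.gene not in mrna.genes:
            continue
        y = protein.values.loc[rec.gene]
        mvals = mrna.values.loc[rec.gene]
        x = geno.dosages.loc[rec.lead_snp]
        try:
            fit = conditional_lrt(y, x, mvals, Q)
        except ValueError:
            continue
        rec.conditional_p = fit.p
        tested.append(rec)
    n_tests = max(len(tested), 1)
    for rec in tested:
        rec.protein_specific = rec.conditional_p * n_tests < alpha
    return tested


# ---------------------------------------------------------------------------
# annotation


ANNOTATION_CATEGORIES = ("CDS", "5'UTR", "3'UTR", "intronic", "extragenic")


def _in_any(pos: int, intervals) -> bool:
    return any(s <= pos <= e for s, e in intervals)


def annotate_snps(
    snp_meta: pd.DataFrame,
    gene_models: dict,
    gene: str,
) -> pd.Series:
    """Classify SNPs relative to one gene's longest-CDS transcript.

    Precedence CDS > UTR > intronic within the transcript span; positions
    inside the +-200 kb cis window but outside the transcript are
    extragenic; positions outside the window get NaN. ``gene_models`` maps
    gene -> list of TranscriptModel.
    """
    txs = [t for t in gene_models.get(gene, []) if t.cds]
    if not txs:
        log.warning("gene %s has no transcript with CDS; skipped", gene)
        return pd.Series(np.nan, index=snp_meta.index, dtype=object)
    tx = max(txs, key=lambda t: t.cds_length)
    out = {}
    for snp, row in snp_meta.iterrows():
        if row["chrom"] != tx.chrom:
            out[snp] = np.nan
            continue
        pos = int(row["pos"])
        if not (tx.start - CIS_WINDOW <= pos <= tx.end + CIS_WINDOW):
            out[snp] = np.nan
        elif _in_any(pos, tx.cds):
            out[snp] = "CDS"
        elif _in_any(pos, tx.utr5):
            out[snp] = "5'UTR"
        elif _in_any(pos, tx.utr3):
            out[snp] = "3'UTR"
        elif tx.start <= pos <= tx.end:
            out[snp] = "intronic"
        else:
            out[snp] = "extragenic"
    return pd.Series(out, name="annotation")


def annotation_enrichment(
    qtl_counts: dict[str, int],
    background_counts: dict[str, int],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of QTL SNPs per annotation.

    Totals are the sums of the supplied counts: N background SNPs, K of
    them in the category, n QTL SNPs, k of those in the category;
    p = P(X >= k), computed in log space.
    """
    N = sum(background_counts.values())
    n = sum(qtl_counts.values())
    rows = []
    for cat, K in background_counts.items():
        k = qtl_counts.get(cat, 0)
        if k > min(K, n):
            raise ValueError(f"category {cat}: k={k} exceeds min(K={K}, n={n})")
        logp = hypergeom_logsf(k, N, K, n) if k > 0 else 0.0
        rows.append(
            {
                "annotation": cat,
                "qtl": k,
                "background": K,
                "p": float(np.exp(logp)),
                "log10_p": float(logp / np.log(10)),
            }
        )
    return pd.DataFrame(rows).set_index("annotation")


# ---------------------------------------------------------------------------
# cis scan convenience


def cis_snps(geno: GenotypeMatrix, gene_start: int, gene_end: int, chrom: str) -> pd.Index:
    meta = geno.snp_meta
    m = (
        (meta["chrom"] == chrom)
        & (meta["pos"] >= gene_start - CIS_WINDOW)
        & (meta["pos"] <= gene_end + CIS_WINDOW)
    )
    return meta.index[m]


__all__ = [
    "kinship_matrix",
    "mlm_scan",
    "AssociationScan",
    "bh_threshold",
    "bonferroni_cutoff",
    "ld_prune",
    "clump_qtls",
    "QTLRecord",
    "conditional_lrt",
    "ConditionalModelFit",
    "annotate_snps",
    "annotation_enrichment",
    "cis_snps",
    "hypergeom_sf",
]
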