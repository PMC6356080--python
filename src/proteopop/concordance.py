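"""Per-gene mRNA-protein concordance and category-level shifts.

The central quantity is the per-gene Pearson correlation between mRNA and
protein abundance across lines (pairwise-complete), BH-adjusted over all
tested genes. Functional-category shifts in the correlation landscape are
scored with a two-sample Kolmogorov-Smirnov test of member versus
non-member correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .statsutil import bh_adjust


@dataclass
class ConcordanceSummary:
    fraction_positive: float
    fraction_significant: float  # BH q < 0.05
    n_tested: int
    n_skipped: int


def gene_correlations(
    mrna: ExpressionMatrix,
    protein: ExpressionMatrix,
    min_pairs: int = 10,
) -> tuple[pd.DataFrame, ConcordanceSummary]:
    """Pearson r between mRNA and protein per gene on pairwise-complete lines.

    Genes and lines are intersected; genes with fewer than ``min_pairs``
    complete pairs are skipped and counted. Returns a frame (gene, r, n, p,
    q) and summary fractions.
    """
    genes = mrna.genes.intersection(protein.genes)
    lines = mrna.lines.intersection(protein.lines)
    mv = mrna.values.loc[genes, lines].to_numpy()
    pv = protein.values.loc[genes, lines].to_numpy()

    rows = []
    n_skipped = 0
    for i, g in enumerate(genes):
        ok = np.isfinite(mv[i]) & np.isfinite(pv[i])
        n = int(ok.sum())
        if n < min_pairs:
            n_skipped += 1
            continue
        x, y = mv[i, ok], pv[i, ok]
        if np.std(x) == 0 or np.std(y) == 0:
            n_skipped += 1
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"gene": g, "r": float(r), "n": n, "p": float(p)})
    if not rows:
        raise ValueError("no gene had enough complete mRNA/protein pairs")
    df = pd.DataFrame(rows).set_index("gene")
    df["q"] = bh_adjust(df["p"].to_numpy())
    summary = ConcordanceSummary(
        fraction_positive=float((df["r"] > 0).mean()),
        fraction_significant=float((df["q"] < 0.05).mean()),
        n_tested=len(df),
        n_skipped=n_skipped,
    )
    return df, summary


def mad_top_fraction(m: ExpressionMatrix, frac: float = 0.5) -> pd.Index:
    """The ceil(frac * n_genes) genes with the largest MAD across observed cells.

    MAD is median(|x - median(x)|) without the 1.4826 consistency constant
    (the ranking is scale-invariant). Ties break deterministically by gene
    ID.
    """
    if not (0 < frac <= 1):
        raise ValueError("frac must be in (0, 1]")
    vals = m.values
    med = vals.median(axis=1, skipna=True)
    mad = (vals.sub(med, axis=0)).abs().median(axis=1, skipna=True)
    k = int(np.ceil(frac * m.n_genes))
    ranked = sorted(mad.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.Index([g for g, _v in ranked[:k]])


def category_shift(
    corrs: pd.DataFrame,
    category_map: pd.DataFrame,
    min_members: int = 5,
) -> pd.DataFrame:
    """KS test of each category's member correlations vs non-members.

    ``corrs`` is the output of :func:`gene_correlations`; ``category_map``
    has columns ``gene_id`` and ``category``. Returns per-category D, p,
    BH q, and the direction (sign of member median r minus global median).
    """
    if category_map.empty:
        raise ValueError("empty category map")
    r = corrs["r"]
    global_median = float(r.median())
    rows = []
    for cat, sub in category_map.groupby("category"):
        members = r.index.intersection(pd.Index(sub["gene_id"].astype(str)))
        if len(members) < min_members:
            continue
        member_r = r.loc[members].to_numpy()
        other_r = r.drop(members).to_numpy()
        if other_r.size == 0:
            continue
        d, p = stats.ks_2samp(member_r, other_r)
        rows.append(
            {
                "category": cat,
                "n_members": len(members),
                "D": float(d),
                "p": float(p),
                "direction": int(np.sign(np.median(member_r) - global_median)),
            }
        )
    if not rows:
        return pd.DataFrame(columns=["category", "n_members", "D", "p", "direction", "q"])
    df = pd.DataFrame(rows).set_index("category")
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df
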