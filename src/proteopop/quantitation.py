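"""Peptide-to-protein quantitation and proteome-level QC.

Relative protein abundance per line is the median, over a gene's
gene-unique peptides, of the peptide-level ratios versus the common
reference line; shared (non-unique) peptides never contribute. Ratios are
aggregated on the linear scale and stored as log2. QC covers per-line
distribution summaries, detection-rate filtering, and a permutation test
that replicate line pairs correlate more strongly than non-replicate
pairs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

log = logging.getLogger(__name__)


def proteins_from_peptides(table: pd.DataFrame) -> ExpressionMatrix:
    """Collapse a peptide ratio table to a gene-level log2 matrix.

    ``table`` columns: ``peptide``, ``gene_id``, ``unique`` (bool), then one
    ratio column per line (positive reals, NaN = unobserved). Only unique
    peptides are used; the per-line cell is log2 of the median of observed
    unique-peptide ratios; genes without unique peptides are dropped.
    """
    if table.empty:
        raise ValueError("peptide table is empty")
    line_cols = [c for c in table.columns if c not in ("peptide", "gene_id", "unique")]
    ratios = table[line_cols]
    bad = (ratios <= 0).any(axis=None)
    if bad:
        raise ValueError("peptide ratios must be positive where present")
    uniq = table[table["unique"].astype(bool)]
    if uniq.empty:
        warnings.warn("no unique peptides; output matrix is empty", stacklevel=2)
        return ExpressionMatrix(pd.DataFrame(columns=line_cols, dtype=float))
    med = uniq.groupby("gene_id")[line_cols].median()
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.log2(med)
    vals = vals.dropna(how="all")
    vals.index = vals.index.astype(str)
    return ExpressionMatrix(vals)


def filter_by_detection(m: ExpressionMatrix, min_frac: float = 0.5) -> ExpressionMatrix:
    """Keep genes observed in at least ceil(min_frac * n_lines) lines."""
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must be in (0, 1]")
    need = int(np.ceil(min_frac * m.n_lines))
    keep = m.values.notna().sum(axis=1) >= need
    return ExpressionMatrix(m.values.loc[keep], m.line_meta)


@dataclass
class QCReport:
    """Replicate-concordance summary with permutation significance."""

    replicate_mean_r: float
    nonreplicate_mean_r: float
    permutation_p: float
    n_permutations: int
    per_pair_r: dict[tuple[str, str], float] = field(default_factory=dict)
    excluded_pairs: list[tuple[str, str]] = field(default_factory=list)


def _pair_spearman(values: pd.DataFrame, a: str, b: str, min_shared: int = 3) -> float:
    x, y = values[a], values[b]
    ok = x.notna() & y.notna()
    if ok.sum() < min_shared:
        return np.nan
    r, _ = stats.spearmanr(x[ok], y[ok])
    return float(r)


def replicate_concordance(
    m: ExpressionMatrix,
    pairs: list[tuple[str, str]],
    n_perm: int = 100_000,
    seed: int = 0,
) -> QCReport:
    """Test that replicate pairs agree better than non-replicate pairs.

    Spearman correlation per line pair on pairwise-complete genes; the
    permutation null relabels which line pairs are called "replicate"
    among all unordered pairs, and
    p = (1 + #{permuted mean >= observed}) / (n_perm + 1).
    """
    if not pairs:
        raise ValueError("need at least one replicate pair")
    lines = list(m.lines)
    all_pairs = list(combinations(lines, 2))
    r_of: dict[tuple[str, str], float] = {}
    for a, b in all_pairs:
        r_of[(a, b)] = _pair_spearman(m.values, a, b)

    def lookup(a: str, b: str) -> float:
        return r_of.get((a, b), r_of.get((b, a), np.nan))

    rep_r, kept_pairs, excluded = [], [], []
    for a, b in pairs:
        r = lookup(a, b)
        if np.isnan(r):
            log.warning("replicate pair (%s, %s) has <3 shared genes; excluded", a, b)
            excluded.append((a, b))
        else:
            rep_r.append(r)
            kept_pairs.append((a, b))
    if not rep_r:
        raise ValueError("no replicate pair with enough shared genes")

    rep_set = {frozenset(p) for p in kept_pairs}
    nonrep_r = np.array(
        [r for (a, b), r in r_of.items() if frozenset((a, b)) not in rep_set and np.isfinite(r)]
    )
    pool = np.array([r for r in r_of.values() if np.isfinite(r)])
    observed = float(np.mean(rep_r))

    rng = np.random.default_rng(seed)
    k = len(rep_r)
    # permute the "replicate" labels over all valid pairs (chunked to bound memory)
    exceed = 0
    done = 0
    while done < n_perm:
        chunk = min(n_perm - done, max(1, 20_000_000 // max(pool.size, 1)))
        idx = rng.random((chunk, pool.size)).argpartition(k - 1, axis=1)[:, :k]
        perm_means = pool[idx].mean(axis=1)
        exceed += int(np.sum(perm_means >= observed - 1e-15))
        done += chunk
    p = (1 + exceed) / (n_perm + 1)

    return QCReport(
        replicate_mean_r=observed,
        nonreplicate_mean_r=float(np.mean(nonrep_r)) if nonrep_r.size else np.nan,
        permutation_p=p,
        n_permutations=n_perm,
        per_pair_r={p_: r_of.get(p_, lookup(*p_)) for p_ in kept_pairs},
        excluded_pairs=excluded,
    )


def per_line_distribution(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-line summaries (mean, SD, skewness, quartiles) on observed cells."""
    if m.values.empty:
        raise ValueError("matrix is empty")
    rows = {}
    for line in m.lines:
        x = m.values[line].dropna().to_numpy()
        if x.size == 0:
            rows[line] = dict.fromkeys(
                ("n", "mean", "sd", "skewness", "q25", "median", "q75"), np.nan
            )
            continue
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        rows[line] = {
            "n": x.size,
            "mean": float(np.mean(x)),
            "sd": sd,
            "skewness": float(stats.skew(x)) if sd > 0 else 0.0,
            "q25": float(np.percentile(x, 25)),
            "median": float(np.median(x)),
            "q75": float(np.percentile(x, 75)),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
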