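"""Over-representation testing with permutation family-wise adjustment.

Each term gets a 2x2 odds ratio (Haldane 0.5 correction for zero cells)
and an upper-tail hypergeometric p-value; family-wise adjusted p-values
come from resampling random query sets of the same size from the explicit
background and recording the minimum raw p per permutation. A term is
called significant when its odds ratio exceeds 2 and its adjusted p is
below 0.05.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats


def enrich(
    query: Sequence[str],
    background: Sequence[str],
    term_map: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    or_min: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Term over-representation of ``query`` within ``background``.

    ``term_map`` has columns ``gene_id`` and ``term_id`` (optionally
    ``term_name``). The background must be explicit; query genes outside
    it raise a validation error.
    """
    query = list(dict.fromkeys(query))
    background = list(dict.fromkeys(background))
    bg_set = set(background)
    offenders = [g for g in query if g not in bg_set]
    if offenders:
        raise ValueError(f"query genes outside background: {offenders[:10]}")
    tm = term_map[term_map["gene_id"].isin(bg_set)]
    terms = sorted(tm["term_id"].unique())
    if not terms:
        raise ValueError("term map covers no background gene")

    N, n = len(background), len(query)
    gene_pos = {g: i for i, g in enumerate(background)}
    term_masks = np.zeros((len(terms), N), dtype=bool)
    for t_i, t in enumerate(terms):
        for g in tm.loc[tm["term_id"] == t, "gene_id"]:
            term_masks[t_i, gene_pos[g]] = True
    query_mask = np.zeros(N, dtype=bool)
    for g in query:
        query_mask[gene_pos[g]] = True

    K = term_masks.sum(axis=1)
    k = (term_masks & query_mask).sum(axis=1)
    raw_p = stats.hypergeom.sf(k - 1, N, K, n)

    # odds ratio with Haldane correction when any cell is zero
    a = k.astype(float)
    b = n - k.astype(float)
    c = K - k.astype(float)
    d = N - n - c
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    a, b, c, d = (np.where(zero, v + 0.5, v) for v in (a, b, c, d))
    odds = (a * d) / (b * c)

    # permutation family-wise adjustment: min raw p over terms per resample
    rng = np.random.default_rng(seed)
    min_p = np.empty(n_perm)
    for bperm in range(n_perm):
        pm = np.zeros(N, dtype=bool)
        pm[rng.choice(N, size=n, replace=False)] = True
        kp = (term_masks & pm).sum(axis=1)
        min_p[bperm] = stats.hypergeom.sf(kp - 1, N, K, n).min()
    adj_p = np.array([(1 + np.sum(min_p <= p)) / (n_perm + 1) for p in raw_p])

    names = (
        tm.drop_duplicates("term_id").set_index("term_id")["term_name"]
        if "term_name" in tm.columns
        else pd.Series(index=terms, dtype=object)
    )
    df = pd.DataFrame(
        {
            "term_id": terms,
            "term_name": [names.get(t, t) for t in terms],
            "query_hits": k,
            "query_size": n,
            "background_hits": K,
            "background_size": N,
            "odds_ratio": odds,
            "p": raw_p,
            "adjusted_p": adj_p,
        }
    ).set_index("term_id")
    df["significant"] = (df["odds_ratio"] > or_min) & (df["adjusted_p"] < alpha)
    return df.sort_values("p")
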