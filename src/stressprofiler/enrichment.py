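"""Fisher's-exact over-representation analysis over hierarchical bins.

Each functional bin (at every level of the hierarchy, with descendant
memberships rolled up into parents) is tested for over-representation
of a DE gene set against a background — by default the genes
expressed under the relevant stress, which avoids flagging bins that
are merely better detected.  The one-sided p-value is the upper tail
of the hypergeometric distribution; Benjamini-Hochberg adjustment
controls the FDR across the bins tested for one gene set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io_core import CategoryMap

ENRICHMENT_COLUMNS = ["bin", "k", "n", "K", "N", "odds_ratio", "p", "q",
                      "significant"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min over j >= i of p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fisher_enrich(de_set, background, categories: CategoryMap,
                  min_bin_size: int = 2, alpha: float = 0.05
                  ) -> pd.DataFrame:
    """Over-representation of a DE gene set in every functional bin.

    Parameters
    ----------
    de_set, background
        The tested gene set and its background universe; the DE set
        must be contained in the background.
    categories
        Hierarchical bin map; a bin's membership includes descendants.
    min_bin_size
        Bins with fewer background members are skipped.
    alpha
        BH-FDR level for the ``significant`` flag.

    Returns one row per tested bin with the 2x2 table margins
    (k of n DE genes in the bin vs K of N background genes), the
    sample odds ratio, the one-sided hypergeometric p, and the BH q,
    sorted by p then bin path.
    """
    de = frozenset(de_set)
    bg = frozenset(background)
    if not de:
        raise ValueError("DE set is empty")
    stray = de - bg
    if stray:
        raise ValueError(
            f"DE genes outside the background: {sorted(stray)[:5]}"
        )
    n, n_bg = len(de), len(bg)
    rows = []
    for b in categories.bins:
        members = categories.genes_in(b) & bg
        big_k = len(members)
        if big_k < min_bin_size:
            continue
        k = len(members & de)
        # upper-tail P(X >= k), X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(k - 1, n_bg, big_k, n))
        a, bb = k, n - k
        c, d = big_k - k, (n_bg - n) - (big_k - k)
        odds = (a * d) / (bb * c) if bb * c > 0 else np.inf
        rows.append({"bin": b, "k": k, "n": n, "K": big_k, "N": n_bg,
                     "odds_ratio": odds, "p": p})
    if not rows:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["q"] < alpha
    return (df.sort_values(["p", "bin"], kind="mergesort")
            .reset_index(drop=True)[ENRICHMENT_COLUMNS])
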