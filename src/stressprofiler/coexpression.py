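"""Co-expression edges among DE genes from fold-change profiles.

Two genes are linked when the Pearson correlation of their log2
fold-change profiles across the 18 treatment columns reaches a
threshold (default r >= 0.9, positive correlations only, both
configurable).  Edges are built from a set of seed genes — typically
transcription factors and hormone/signalling genes — against all
profile genes, supporting assembly of stress-response regulatory
networks.  Constant (zero-variance) profiles never form edges.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_core import CategoryMap


def pearson_matrix(values: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation; rows with zero variance get NaN."""
    vals = np.asarray(values, dtype=float)
    centered = vals - vals.mean(axis=1, keepdims=True)
    ss = np.sqrt((centered ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        normed = centered / ss[:, np.newaxis]
    r = normed @ normed.T
    r[ss == 0, :] = np.nan
    r[:, ss == 0] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)


def coexpression_edges(profile: pd.DataFrame, seeds,
                       r_threshold: float = 0.9,
                       signed: bool = True) -> pd.DataFrame:
    """Build the undirected co-expression edge list.

    Parameters
    ----------
    profile
        Log2 fold-change matrix (genes x 18 treatment columns).
    seeds
        Genes of interest; every emitted edge touches at least one
        seed.  Must be a subset of the profile rows.
    r_threshold
        Minimum correlation; with ``signed=True`` (default) only
        r >= threshold qualifies, otherwise |r| >= threshold.
    signed
        Restrict to positively correlated pairs.

    Returns a DataFrame (gene_a, gene_b, r) with gene_a < gene_b
    lexicographically, sorted, without self-edges or duplicates.
    """
    seed_set = frozenset(seeds)
    genes = list(profile.index)
    missing = seed_set - set(genes)
    if missing:
        raise ValueError(
            f"seed gene(s) not in profile: {sorted(missing)[:5]}"
        )
    if profile.shape[1] < 3:
        raise ValueError("need at least 3 profile columns")
    r = pearson_matrix(profile.to_numpy())
    idx = {g: i for i, g in enumerate(genes)}
    rows = []
    seen: set[tuple[str, str]] = set()
    for s in sorted(seed_set):
        i = idx[s]
        for g in genes:
            if g == s:
                continue
            pair = (min(s, g), max(s, g))
            if pair in seen:
                continue
            rij = r[i, idx[g]]
            if np.isnan(rij):
                continue
            ok = rij >= r_threshold if signed else abs(rij) >= r_threshold
            if ok:
                seen.add(pair)
                rows.append({"gene_a": pair[0], "gene_b": pair[1],
                             "r": float(rij)})
    out = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r"])
    return (out.sort_values(["gene_a", "gene_b"], kind="mergesort")
            .reset_index(drop=True))


def annotate_network(edges: pd.DataFrame,
                     categories: CategoryMap) -> pd.DataFrame:
    """Node table for an edge list, carrying functional-bin paths.

    One row per distinct node, with its leaf bin paths joined by
    ';' (empty string for unannotated genes); deterministic order.
    """
    nodes = sorted(set(edges["gene_a"]) | set(edges["gene_b"]))
    rows = [{"gene": g, "bins": ";".join(categories.bins_for(g))}
            for g in nodes]
    return pd.DataFrame(rows, columns=["gene", "bins"])
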