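"""Response-pattern taxonomy, fold-change profiles, and clustering.

Every DE gene gets a six-slot pattern: its up/down/none status in each
of the six condition series (c.FL, c.FEL, c.RT, d.FL, d.FEL, d.RT).
Non-empty patterns partition the DE universe into groups labelled
G1, G2, ... in a deterministic order, the analogue of a
figure-defined group taxonomy: sorted by number of responding series
ascending, then by slot position, with down before up.

For heatmaps and co-expression the per-gene fold-change profile holds
log2 FC against the series control at each of the 18 treatment
columns; cells of series where the gene is not DE are forced to
log2(1) = 0 so that non-responding series do not contribute
structure.  A pseudocount (default 1 CPM) keeps on/off cells finite;
it applies to display FCs only, never to rule evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, linkage
from scipy.spatial.distance import pdist

from .de_calling import DEGeneCall, Direction
from .io_core import ConditionSeries, SERIES_ORDER, TIME_LABELS

_SLOT_RANK = {Direction.NONE: 0, Direction.DOWN: 1, Direction.UP: 2}


@dataclass(frozen=True)
class ResponsePattern:
    """A six-slot up/down/none vector over the condition series."""

    slots: tuple[Direction, ...]  # aligned with SERIES_ORDER

    def __post_init__(self) -> None:
        if len(self.slots) != len(SERIES_ORDER):
            raise ValueError(
                f"pattern needs {len(SERIES_ORDER)} slots"
            )

    @property
    def n_responding(self) -> int:
        return sum(s is not Direction.NONE for s in self.slots)

    def sort_key(self) -> tuple:
        """Deterministic group order: fewer responding series first,
        then slot-wise with none < down < up."""
        return (self.n_responding,
                tuple(_SLOT_RANK[s] for s in self.slots))

    def __str__(self) -> str:
        return "|".join(f"{k}:{s.value}"
                        for k, s in zip(SERIES_ORDER, self.slots))

    @classmethod
    def from_string(cls, text: str) -> "ResponsePattern":
        parts = dict(p.split(":") for p in text.split("|"))
        return cls(tuple(Direction(parts[k]) for k in SERIES_ORDER))


def assign_pattern(gene: str,
                   calls_by_series: dict[str, dict[str, DEGeneCall]]
                   ) -> ResponsePattern:
    """Pattern of one gene from its series-level DE calls.

    Each slot takes the direction of the gene's DE call in that series
    (none where the gene is not DE).  Genes DE nowhere are a caller
    error: patterns are defined on the DE universe only.
    """
    slots = []
    for key in SERIES_ORDER:
        call = calls_by_series.get(key, {}).get(gene)
        slots.append(call.direction if call else Direction.NONE)
    pattern = ResponsePattern(tuple(slots))
    if pattern.n_responding == 0:
        raise ValueError(f"gene {gene!r} is not DE in any series")
    return pattern


def group_patterns(calls_by_series: dict[str, dict[str, DEGeneCall]]
                   ) -> pd.DataFrame:
    """Partition all DE genes into labelled pattern groups.

    Returns a DataFrame with one row per gene (columns: gene_id,
    group_id, pattern, n_responding), where group labels G1, G2, ...
    follow the deterministic pattern order and are stable under input
    permutation.
    """
    universe = sorted(set().union(*[set(c) for c in
                                    calls_by_series.values()] or [set()]))
    by_pattern: dict[tuple, list[str]] = {}
    pattern_obj: dict[tuple, ResponsePattern] = {}
    for gene in universe:
        p = assign_pattern(gene, calls_by_series)
        by_pattern.setdefault(p.slots, []).append(gene)
        pattern_obj[p.slots] = p
    ordered = sorted(pattern_obj.values(), key=lambda p: p.sort_key())
    rows = []
    for i, p in enumerate(ordered, start=1):
        for gene in sorted(by_pattern[p.slots]):
            rows.append({"gene_id": gene, "group_id": f"G{i}",
                         "pattern": str(p),
                         "n_responding": p.n_responding})
    return pd.DataFrame(
        rows, columns=["gene_id", "group_id", "pattern", "n_responding"]
    )


def group_sizes(membership: pd.DataFrame) -> pd.DataFrame:
    """Group-level summary (group_id, pattern, size) from membership."""
    if membership.empty:
        return pd.DataFrame(columns=["group_id", "pattern", "size"])
    g = (membership.groupby(["group_id", "pattern"], sort=False)
         .size().reset_index(name="size"))
    g["order"] = g["group_id"].str.removeprefix("G").astype(int)
    return (g.sort_values("order").drop(columns="order")
            .reset_index(drop=True))


def profile_columns() -> list[str]:
    """The 18 treatment column labels, e.g. 'c.FL.6h' ... 'd.RT.10d'."""
    cols = []
    for key in SERIES_ORDER:
        stress = "cold" if key.startswith("c.") else "drought"
        for t in (1, 2, 3):
            cols.append(f"{key}.{TIME_LABELS[stress][t]}")
    return cols


def foldchange_profile(expr, series_list: list[ConditionSeries],
                       calls_by_series: dict[str, dict[str, DEGeneCall]],
                       pseudocount: float = 1.0) -> pd.DataFrame:
    """Log2 fold-change matrix of all DE genes over 18 treatment columns.

    For a (gene, series) where the gene is DE:
    ``log2((treat_cpm + pseudocount) / (ctrl_cpm + pseudocount))`` at
    each of the series' three time points.  Where it is not DE, all
    three cells are 0 (the FC = 1 convention for non-DE genes).
    """
    universe = sorted(set().union(*[set(c) for c in
                                    calls_by_series.values()] or [set()]))
    cols = profile_columns()
    out = pd.DataFrame(0.0, index=universe, columns=cols)
    out.index.name = "gene_id"
    series_by_key = {s.key: s for s in series_list}
    for key in SERIES_ORDER:
        series = series_by_key.get(key)
        if series is None:
            continue
        de_genes = [g for g in universe
                    if g in calls_by_series.get(key, {})]
        if not de_genes:
            continue
        ctrl = expr.cpm.loc[de_genes, series.control_sample].to_numpy()
        for t, sample in enumerate(series.treatment_samples):
            treat = expr.cpm.loc[de_genes, sample].to_numpy()
            with np.errstate(divide="ignore"):  # pseudocount 0 + on/off
                vals = np.log2((treat + pseudocount) / (ctrl + pseudocount))
            out.loc[de_genes, cols[SERIES_ORDER.index(key) * 3 + t]] = vals
    return out


@dataclass
class ClusterResult:
    """Agglomerative merge tree with a deterministic leaf order."""

    linkage_matrix: np.ndarray  # scipy (n-1, 4) format
    gene_ids: list[str]
    leaf_order: list[str]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def hcluster(profile: pd.DataFrame, method: str = "complete",
             metric: str = "euclidean") -> ClusterResult:
    """Hierarchically cluster fold-change rows (complete linkage,
    Euclidean distance by default)."""
    if len(profile) < 2:
        raise ValueError("clustering needs at least 2 rows")
    dists = pdist(profile.to_numpy(dtype=float), metric=metric)
    z = linkage(dists, method=method)
    order = dendrogram(z, no_plot=True)["leaves"]
    genes = list(profile.index)
    return ClusterResult(
        linkage_matrix=z,
        gene_ids=genes,
        leaf_order=[genes[i] for i in order],
    )


def cut_clusters(result: ClusterResult, n_clusters: int) -> pd.Series:
    """Flat cluster labels (1..n) from the merge tree."""
    from scipy.cluster.hierarchy import fcluster

    labels = fcluster(result.linkage_matrix, t=n_clusters,
                      criterion="maxclust")
    return pd.Series(labels, index=result.gene_ids, name="cluster")
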