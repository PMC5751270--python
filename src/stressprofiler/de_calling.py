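"""Rule-based differential-expression calling per condition series.

The caller works in two steps, using time-point replication in place
of biological replicates:

1. *Candidate step* — each treatment time point is compared with its
   series control.  A gene is a DE candidate at that time point if
   (a) both CPMs exceed the expression threshold (default 10) and the
   fold change exceeds 3 in either direction (*ratio* rule), or
   (b) one CPM is below the expression threshold while the other
   exceeds the over-expression threshold (default 30) — an *on/off*
   call.  All comparisons are strict.

2. *Replication step* — a gene is DE in a (stress, tissue) series iff
   at least ``min_support`` (default 2) of its 3 time-point candidates
   agree in direction; that shared direction becomes the series call.
   Genes whose significant time points disagree without either
   direction reaching the support threshold are not called.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .io_core import ConditionSeries
from .normalization import ExpressionMatrix


class Direction(str, Enum):
    UP = "up"
    DOWN = "down"
    NONE = "none"


class Rule(str, Enum):
    RATIO = "ratio"
    ON_OFF = "on_off"
    NONE = "none"


@dataclass(frozen=True)
class Thresholds:
    """Tunable cutoffs of the two candidate rules."""

    expr_threshold: float = 10.0   # CPM above which a gene is expressed
    over_threshold: float = 30.0   # CPM for the over-expressed side of on/off
    fc_threshold: float = 3.0      # fold change for the ratio rule
    min_support: int = 2           # time points that must agree


DEFAULT_THRESHOLDS = Thresholds()


@dataclass(frozen=True)
class CandidateCall:
    """Outcome of one treatment-vs-control comparison for one gene."""

    gene_id: str
    time_index: int  # 1-3
    status: Direction
    rule: Rule
    fc: float  # treatment CPM / control CPM; inf when control CPM = 0


@dataclass(frozen=True)
class DEGeneCall:
    """Series-level DE call backed by >= min_support agreeing candidates."""

    gene_id: str
    series: ConditionSeries
    direction: Direction
    n_support: int
    candidates: tuple[CandidateCall, ...]


def candidate_status(treat_cpm: float, ctrl_cpm: float,
                     thresholds: Thresholds = DEFAULT_THRESHOLDS,
                     gene_id: str = "", time_index: int = 0) -> CandidateCall:
    """Classify one treatment/control CPM pair.

    Returns an ``up``/``down``/``none`` candidate together with the
    rule that fired.  The fold change is treatment over control, with
    ``inf`` recorded when the control CPM is exactly zero.
    """
    if treat_cpm < 0 or ctrl_cpm < 0:
        raise ValueError(
            f"negative CPM (treat={treat_cpm}, ctrl={ctrl_cpm})"
        )
    t = thresholds
    fc = treat_cpm / ctrl_cpm if ctrl_cpm > 0 else math.inf
    status, rule = Direction.NONE, Rule.NONE
    if treat_cpm > t.expr_threshold and ctrl_cpm > t.expr_threshold:
        if fc > t.fc_threshold:
            status, rule = Direction.UP, Rule.RATIO
        elif ctrl_cpm / treat_cpm > t.fc_threshold:
            status, rule = Direction.DOWN, Rule.RATIO
    else:
        if ctrl_cpm < t.expr_threshold and treat_cpm > t.over_threshold:
            status, rule = Direction.UP, Rule.ON_OFF
        elif treat_cpm < t.expr_threshold and ctrl_cpm > t.over_threshold:
            status, rule = Direction.DOWN, Rule.ON_OFF
    return CandidateCall(gene_id=gene_id, time_index=time_index,
                         status=status, rule=rule, fc=fc)


def combine_candidates(statuses: tuple[Direction, ...],
                       min_support: int = 2) -> tuple[Direction, int]:
    """Replication rule over a series' candidate statuses.

    Returns the direction supported by >= min_support candidates (and
    its support count), or (NONE, 0) when no direction reaches the
    threshold — including the mixed up/down/none case.
    """
    n_up = sum(s is Direction.UP for s in statuses)
    n_down = sum(s is Direction.DOWN for s in statuses)
    if n_up >= min_support and n_up >= n_down:
        return Direction.UP, n_up
    if n_down >= min_support:
        return Direction.DOWN, n_down
    return Direction.NONE, 0


def call_series(expr: ExpressionMatrix, series: ConditionSeries,
                thresholds: Thresholds = DEFAULT_THRESHOLDS
                ) -> dict[str, DEGeneCall]:
    """Call DE genes for one (stress, tissue) condition series."""
    if len(series.treatment_samples) != 3:
        raise ValueError(
            f"series {series.key}: expected 3 treatment time points"
        )
    missing = [s for s in (series.control_sample, *series.treatment_samples)
               if s not in expr.cpm.columns]
    if missing:
        raise ValueError(f"series {series.key}: samples {missing} "
                         f"absent from expression matrix")
    ctrl = expr.cpm[series.control_sample].to_numpy()
    treats = [expr.cpm[s].to_numpy() for s in series.treatment_samples]
    calls: dict[str, DEGeneCall] = {}
    genes = expr.gene_ids
    for i, gene in enumerate(genes):
        cands = tuple(
            candidate_status(treats[k][i], ctrl[i], thresholds,
                             gene_id=gene, time_index=k + 1)
            for k in range(3)
        )
        direction, n = combine_candidates(
            tuple(c.status for c in cands), thresholds.min_support
        )
        if direction is not Direction.NONE:
            calls[gene] = DEGeneCall(
                gene_id=gene, series=series, direction=direction,
                n_support=n, candidates=cands,
            )
    return calls


def call_all_series(expr: ExpressionMatrix,
                    series_list: list[ConditionSeries],
                    thresholds: Thresholds = DEFAULT_THRESHOLDS
                    ) -> dict[str, dict[str, DEGeneCall]]:
    """Call every series; keyed by series key ('c.FL', ..., 'd.RT')."""
    return {s.key: call_series(expr, s, thresholds) for s in series_list}


def de_summary(all_calls: dict[str, dict[str, DEGeneCall]]
               ) -> tuple[dict[str, int], dict[str, frozenset[str]]]:
    """Per-series DE counts and gene sets."""
    sets = {k: frozenset(v) for k, v in all_calls.items()}
    counts = {k: len(v) for k, v in sets.items()}
    return counts, sets
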