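"""Synthetic two-stress, three-tissue count experiments with known truth.

The generator emulates the study design end to end: 24 single-replicate
libraries (2 stresses x 3 tissues x [1 control + 3 treatment time
points]), negative-binomial read counts over a log-normal baseline
abundance profile, library-size variation, a silent-gene fraction, and
*planted* response patterns — cohorts of genes whose treatment means
are shifted by a configured fold change in chosen condition series, in
a chosen direction, optionally as on/off (unexpressed control, clearly
expressed treatment) calls.  The planted assignment is returned as a
truth table so every downstream stage can be scored against it.

Counts for gene g in sample s are drawn NB with mean
``baseline_cpm[g] * library_size[s] / 1e6 * effect(g, s)`` and
gene-level dispersion ``alpha`` (variance mu + alpha * mu^2), via the
gamma-Poisson mixture.  By default a planted fold change applies to
all three treatment time points of its series; a subset of active
time points can be given to emulate transient (ramp) responses that
the two-of-three replication rule must reject.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .de_calling import Direction
from .io_core import (CountMatrix, SampleDescriptor, SERIES_ORDER, STRESSES,
                      TISSUES, TIME_LABELS)
from .patterns import ResponsePattern


@dataclass(frozen=True)
class PlantedPattern:
    """One cohort of genes sharing a planted response pattern.

    ``slots`` maps series keys ('c.FL', ..., 'd.RT') to 'up' or
    'down'; unmentioned series stay unperturbed.  ``on_off`` plants
    genes whose control sits below the expressed threshold (or above
    it, for down) so the on/off rule, not the ratio rule, fires.
    ``active_timepoints`` restricts the fold change to a subset of the
    three treatment time points (default: all three).
    """

    slots: dict[str, str]
    n_genes: int
    fold_change: float = 8.0
    on_off: bool = False
    active_timepoints: tuple[int, ...] = (1, 2, 3)

    def __post_init__(self) -> None:
        for k, v in self.slots.items():
            if k not in SERIES_ORDER:
                raise ValueError(f"unknown series key {k!r}")
            if v not in ("up", "down"):
                raise ValueError(f"slot direction must be up/down, got {v!r}")
        if not self.slots:
            raise ValueError("planted pattern needs at least one slot")
        if self.fold_change <= 1:
            raise ValueError("fold_change must be > 1")
        if self.on_off and self.fold_change < 5:
            raise ValueError("on/off planting needs fold_change >= 5")
        bad = set(self.active_timepoints) - {1, 2, 3}
        if bad or not self.active_timepoints:
            raise ValueError("active_timepoints must be a subset of {1,2,3}")


def default_planted_patterns() -> list[PlantedPattern]:
    """A realistic planted-truth mix: per-series specific cohorts,
    within-stress shared cohorts, cross-stress shared cohorts, and
    on/off cohorts — echoing the predominance of tissue-specific over
    shared responses seen in multi-tissue stress studies."""
    planted: list[PlantedPattern] = []
    for key in SERIES_ORDER:
        planted.append(PlantedPattern({key: "up"}, n_genes=120))
        planted.append(PlantedPattern({key: "down"}, n_genes=80))
        planted.append(PlantedPattern({key: "up"}, n_genes=25, on_off=True))
    for stress in STRESSES:
        k = stress[0]
        planted.append(PlantedPattern(
            {f"{k}.{t}": "up" for t in TISSUES}, n_genes=60))
    planted.append(PlantedPattern(
        {f"{s[0]}.FL": "up" for s in STRESSES}, n_genes=50))
    planted.append(PlantedPattern(
        {f"{s[0]}.RT": "down" for s in STRESSES}, n_genes=30))
    return planted


def scaled_planted_patterns(n_genes: int,
                            reference_n: int = 20_000
                            ) -> list[PlantedPattern]:
    """The default planted mix with cohort sizes scaled to ``n_genes``
    (at least 1 gene per cohort), for desk-scale simulations."""
    ratio = n_genes / reference_n
    return [replace(p, n_genes=max(1, round(p.n_genes * ratio)))
            for p in default_planted_patterns()]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic experiment.

    Defaults reproduce the study's scale: ~20,000 simulated genes of
    which ~10% are silent, leaving roughly 18,000 expressed per
    stress; ~3.5 million mapped reads per library with modest
    lognormal spread; lognormal baseline abundances; NB dispersion
    0.05, typical of bulk RNA-seq without biological replicates.
    """

    seed: int = 0
    n_genes: int = 20_000
    library_size_mean: float = 3.5e6
    library_size_sigma: float = 0.15   # lognormal sigma of library sizes
    baseline_log_mean: float = np.log(40.0)  # lognormal on mean CPM
    baseline_log_sigma: float = 0.8
    dispersion: float = 0.05
    fraction_silent: float = 0.10
    planted_patterns: list[PlantedPattern] = field(
        default_factory=default_planted_patterns)

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not 0 <= self.fraction_silent < 1:
            raise ValueError("fraction_silent must be in [0, 1)")
        n_planted = sum(p.n_genes for p in self.planted_patterns)
        n_active = int(round(self.n_genes * (1 - self.fraction_silent)))
        if n_planted > n_active:
            raise ValueError(
                f"planted genes ({n_planted}) exceed non-silent genes "
                f"({n_active})"
            )


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-gene pattern and per-series fold change."""

    patterns: dict[str, ResponsePattern]        # planted DE genes only
    fold_changes: dict[str, dict[str, float]]   # gene -> series key -> FC
    on_off: dict[str, bool]
    active_timepoints: dict[str, tuple[int, ...]]

    def de_set(self, series_key: str) -> frozenset[str]:
        """Genes planted with a full (all-3-time-point) response in a
        series — the truth against which series DE calls are scored."""
        out = []
        for g, p in self.patterns.items():
            slot = p.slots[SERIES_ORDER.index(series_key)]
            if slot is not Direction.NONE and \
                    self.active_timepoints[g] == (1, 2, 3):
                out.append(g)
        return frozenset(out)

    def direction(self, gene: str, series_key: str) -> Direction:
        p = self.patterns.get(gene)
        if p is None:
            return Direction.NONE
        return p.slots[SERIES_ORDER.index(series_key)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in sorted(self.patterns):
            rows.append({
                "gene_id": g,
                "pattern": str(self.patterns[g]),
                "fold_changes": ";".join(
                    f"{k}={v:g}" for k, v in
                    sorted(self.fold_changes[g].items())),
                "on_off": self.on_off[g],
                "active_timepoints": ",".join(
                    map(str, self.active_timepoints[g])),
            })
        return pd.DataFrame(
            rows, columns=["gene_id", "pattern", "fold_changes", "on_off",
                           "active_timepoints"])


def _design() -> list[SampleDescriptor]:
    samples = []
    for stress in STRESSES:
        for tissue in TISSUES:
            for t in range(4):
                label = TIME_LABELS[stress][t]
                samples.append(SampleDescriptor(
                    sample_id=f"{stress[0]}.{tissue}.{label}",
                    stress=stress, tissue=tissue, time_index=t,
                    role="control" if t == 0 else "treatment",
                    library_size=None,
                ))
    return samples


def generate_experiment(config: GeneratorConfig
                        ) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw a full 24-sample synthetic count experiment.

    Deterministic under a fixed config (seed included): running twice
    yields identical matrices and truth.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"gene{str(i).zfill(5)}" for i in range(n)]
    n_silent = n - int(round(n * (1 - config.fraction_silent)))

    # baseline mean CPM: lognormal for active genes, near-zero for silent
    baseline = np.exp(rng.normal(config.baseline_log_mean,
                                 config.baseline_log_sigma, size=n))
    silent_idx = rng.choice(n, size=n_silent, replace=False)
    is_silent = np.zeros(n, dtype=bool)
    is_silent[silent_idx] = True
    baseline[is_silent] = rng.exponential(0.5, size=n_silent)

    # planted cohorts occupy distinct non-silent genes
    active_pool = np.flatnonzero(~is_silent)
    rng.shuffle(active_pool)
    cursor = 0
    planted_mask = np.zeros(n, dtype=bool)
    truth = SyntheticTruth({}, {}, {}, {})
    effect = np.ones((n, 24))  # per-gene per-sample FC multiplier
    samples = _design()
    col_of = {s.sample_id: j for j, s in enumerate(samples)}

    for planted in config.planted_patterns:
        idx = active_pool[cursor:cursor + planted.n_genes]
        cursor += planted.n_genes
        planted_mask[idx] = True
        fc = planted.fold_change
        for gi in idx:
            g = gene_ids[gi]
            # baseline windows that make the intended rule fire reliably
            if planted.on_off:
                if "up" in planted.slots.values():
                    baseline[gi] = rng.uniform(max(2.0, 36.0 / fc), 8.0)
                else:
                    baseline[gi] = rng.uniform(36.0, min(80.0, 9.0 * fc))
            else:
                if "down" in planted.slots.values():
                    baseline[gi] = np.exp(rng.uniform(
                        np.log(12.0 * fc), np.log(40.0 * fc)))
                else:
                    baseline[gi] = np.exp(rng.uniform(
                        np.log(15.0), np.log(250.0)))
            slots = [Direction.NONE] * len(SERIES_ORDER)
            fcs: dict[str, float] = {}
            for key, direction in planted.slots.items():
                slots[SERIES_ORDER.index(key)] = Direction(direction)
                fcs[key] = fc
                stress = "cold" if key.startswith("c.") else "drought"
                tissue = key.split(".", 1)[1]
                for t in planted.active_timepoints:
                    sid = f"{stress[0]}.{tissue}.{TIME_LABELS[stress][t]}"
                    effect[gi, col_of[sid]] = (
                        fc if direction == "up" else 1.0 / fc)
            truth.patterns[g] = ResponsePattern(tuple(slots))
            truth.fold_changes[g] = fcs
            truth.on_off[g] = planted.on_off
            truth.active_timepoints[g] = planted.active_timepoints

    # make baselines true control CPMs: rescale the unplanted active
    # genes so all baselines sum to 1e6 (planted windows and the silent
    # tail are left untouched so their CPM guarantees hold exactly)
    rest = ~planted_mask & ~is_silent
    target = 1e6 - baseline[planted_mask].sum() - baseline[is_silent].sum()
    if target <= 0 or not rest.any():
        raise ValueError(
            "planted and silent genes exhaust the expression budget; "
            "increase n_genes"
        )
    baseline[rest] *= target / baseline[rest].sum()

    lib = np.exp(rng.normal(np.log(config.library_size_mean),
                            config.library_size_sigma, size=24))
    # NB via gamma-Poisson: mean mu, variance mu + alpha mu^2
    mu = baseline[:, np.newaxis] / 1e6 * lib[np.newaxis, :] * effect
    shape = 1.0 / config.dispersion
    lam = rng.gamma(shape, mu * config.dispersion)
    counts = rng.poisson(lam).astype(np.int64)

    df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                      columns=[s.sample_id for s in samples])
    return CountMatrix(counts=df, samples=samples), truth


def generate_category_map(config: GeneratorConfig, truth: SyntheticTruth,
                          n_bins: int = 20, enrichment_odds: float = 1.0,
                          loaded_bin: str = "stress.response",
                          seed: int | None = None) -> pd.DataFrame:
    """Random gene -> bin assignments with one optionally loaded bin.

    Every gene gets exactly one two-level bin path.  Planted DE genes
    enter ``loaded_bin`` with odds ``enrichment_odds`` times those of
    background genes, giving the enrichment stage a positive control
    (odds 1 = null).  Returns a (gene_id, bin_path) DataFrame ready
    for :func:`stressprofiler.io_core.read_category_map` semantics or
    direct :class:`~stressprofiler.io_core.CategoryMap` construction.
    """
    if enrichment_odds <= 0:
        raise ValueError("enrichment_odds must be > 0")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    others = [f"metabolism.bin{str(i).zfill(2)}" for i in range(n_bins - 1)]
    gene_ids = [f"gene{str(i).zfill(5)}" for i in range(config.n_genes)]
    p0 = 1.0 / n_bins
    odds0 = p0 / (1 - p0)
    p1 = (enrichment_odds * odds0) / (1 + enrichment_odds * odds0)
    rows = []
    for g in gene_ids:
        p_load = p1 if g in truth.patterns else p0
        if rng.random() < p_load:
            b = loaded_bin
        else:
            b = others[rng.integers(len(others))]
        rows.append({"gene_id": g, "bin_path": b})
    return pd.DataFrame(rows, columns=["gene_id", "bin_path"])


def ramp_config(base: GeneratorConfig, series_key: str = "c.FL",
                n_genes: int = 100, fold_change: float = 8.0
                ) -> GeneratorConfig:
    """Add a transient cohort responding at only the first time point.

    Such genes meet the candidate rule once out of three and must be
    rejected by the replication step."""
    extra = PlantedPattern({series_key: "up"}, n_genes=n_genes,
                           fold_change=fold_change,
                           active_timepoints=(1,))
    return replace(base,
                   planted_patterns=[*base.planted_patterns, extra])
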