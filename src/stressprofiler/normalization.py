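"""TMM scaling factors, CPM expression values, and expressed-gene calls.

Between-sample normalization follows the trimmed mean of M-values
(TMM) scheme: for each sample against a reference, per-gene log2
expression ratios (M) are doubly trimmed — by the ratios themselves
and by average log2 abundance (A) — and averaged with inverse
asymptotic binomial variance weights; 2 to that mean is the sample's
scale factor.  Factors are rescaled to geometric mean 1 so they only
redistribute, never change, the total normalization.

Expression is reported as CPM (counts per million) over the
TMM-adjusted library size.  A gene is called expressed in a sample
when CPM strictly exceeds a threshold (default 10), and expressed in
a tissue when it passes in at least one of that tissue's four time
points under a given stress.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_core import CountMatrix, SampleDescriptor, STRESSES, TISSUES


@dataclass(frozen=True)
class NormalizationFactors:
    """Per-sample positive scale factors with geometric mean 1."""

    sample_ids: tuple[str, ...]
    factors: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.factors, dtype=float)
        object.__setattr__(self, "factors", f)
        if (f <= 0).any():
            raise ValueError("scale factors must be positive")
        if len(f) != len(self.sample_ids):
            raise ValueError("factors misaligned with sample ids")

    def as_series(self) -> pd.Series:
        return pd.Series(self.factors, index=list(self.sample_ids),
                         name="factor")


@dataclass
class ExpressionMatrix:
    """TMM-scaled CPM values, genes x samples."""

    cpm: pd.DataFrame
    samples: list[SampleDescriptor]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.cpm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.cpm.columns)


def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray,
                     n_obs: float, n_ref: float,
                     trim_m: float, trim_a: float) -> float:
    """Log2 TMM factor of one sample against the reference.

    Genes with a zero count in either sample are excluded.  Double
    trimming keeps genes whose M rank and A rank both fall inside the
    central band; ties share average ranks.
    """
    keep = (obs > 0) & (ref > 0)
    obs = obs[keep].astype(float)
    ref = ref[keep].astype(float)
    if obs.size == 0:
        return 0.0
    p_obs = obs / n_obs
    p_ref = ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = (np.log2(p_obs) + np.log2(p_ref)) / 2.0
    # inverse weight: asymptotic variance of M under binomial sampling
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any() or not np.isfinite(v[keep]).any():
        return 0.0
    w = 1.0 / v[keep]
    log_f = float(np.sum(w * m[keep]) / np.sum(w))
    if abs(log_f) < 1e-10:
        return 0.0
    return log_f


def choose_reference(counts: CountMatrix) -> str:
    """Pick the reference sample for TMM.

    The reference is the sample whose 75th-percentile count fraction
    is closest to the mean 75th percentile across samples; ties go to
    the lexicographically smallest sample_id.
    """
    arr = counts.counts.to_numpy(dtype=float)
    lib = counts.library_sizes
    q75 = np.quantile(arr / lib[np.newaxis, :], 0.75, axis=0)
    dist = np.abs(q75 - q75.mean())
    best = dist.min()
    tied = [sid for sid, d in zip(counts.sample_ids, dist)
            if d <= best + 1e-15]
    return min(tied)


def tmm_factors(counts: CountMatrix, trim_m: float = 0.30,
                trim_a: float = 0.05,
                reference: str | None = None) -> NormalizationFactors:
    """Compute TMM scale factors for every sample.

    Parameters
    ----------
    counts
        Raw count matrix; every column needs at least one positive
        count and there must be at least two samples.
    trim_m, trim_a
        Fractions trimmed from each tail of the M (log ratio) and A
        (log abundance) distributions.
    reference
        Optional explicit reference sample id; by default chosen by
        the 75th-percentile rule (see :func:`choose_reference`).
    """
    if len(counts.samples) < 2:
        raise ValueError("TMM needs at least 2 samples")
    arr = counts.counts.to_numpy(dtype=float)
    zero_cols = [sid for sid, tot in
                 zip(counts.sample_ids, arr.sum(axis=0)) if tot <= 0]
    if zero_cols:
        raise ValueError(f"all-zero count column(s): {zero_cols}")
    if reference is None:
        reference = choose_reference(counts)
    elif reference not in counts.sample_ids:
        raise ValueError(f"reference sample {reference!r} not found")
    lib = counts.library_sizes
    ref_idx = counts.sample_ids.index(reference)
    ref = arr[:, ref_idx]
    log_f = np.zeros(arr.shape[1])
    for j in range(arr.shape[1]):
        if j == ref_idx:
            continue
        log_f[j] = _tmm_pair_factor(arr[:, j], ref, lib[j], lib[ref_idx],
                                    trim_m, trim_a)
    f = 2.0 ** log_f
    f = f / np.exp(np.mean(np.log(f)))  # geometric mean 1
    return NormalizationFactors(tuple(counts.sample_ids), f)


def cpm(counts: CountMatrix,
        factors: NormalizationFactors | None = None) -> ExpressionMatrix:
    """Counts per million over the TMM-adjusted library size.

    ``cpm[g, s] = counts[g, s] / (library_size[s] * factor[s]) * 1e6``.
    With ``factors=None`` all factors are taken as 1.
    """
    lib = counts.library_sizes
    if (lib <= 0).any():
        bad = [s.sample_id for s, l in zip(counts.samples, lib) if l <= 0]
        raise ValueError(f"zero library size for sample(s): {bad}")
    if factors is None:
        f = np.ones(len(lib))
    else:
        if tuple(counts.sample_ids) != factors.sample_ids:
            raise ValueError("factors not aligned with count samples")
        f = factors.factors
    vals = counts.counts.to_numpy(dtype=float) / (lib * f)[np.newaxis, :] * 1e6
    return ExpressionMatrix(
        cpm=pd.DataFrame(vals, index=counts.counts.index,
                         columns=counts.counts.columns),
        samples=list(counts.samples),
    )


def expressed_mask(expr: ExpressionMatrix,
                   threshold: float = 10.0) -> pd.DataFrame:
    """Per-sample expressed flags: strictly CPM > threshold."""
    return expr.cpm > threshold


def expressed_sets(expr: ExpressionMatrix, threshold: float = 10.0
                   ) -> dict[tuple[str, str], frozenset[str]]:
    """Tissue-level expressed gene sets per (stress, tissue).

    A gene belongs to a tissue's expressed set under a stress when its
    CPM exceeds the threshold in at least one of that tissue's four
    time points (control plus three treatments).
    """
    mask = expressed_mask(expr, threshold)
    out: dict[tuple[str, str], frozenset[str]] = {}
    for stress in STRESSES:
        for tissue in TISSUES:
            cols = [s.sample_id for s in expr.samples
                    if s.stress == stress and s.tissue == tissue]
            if not cols:
                continue
            any_on = mask[cols].any(axis=1)
            out[(stress, tissue)] = frozenset(any_on.index[any_on])
    return out


def expressed_by_stress(expr: ExpressionMatrix, threshold: float = 10.0
                        ) -> dict[str, frozenset[str]]:
    """Genes expressed anywhere within each stress (enrichment background)."""
    per_tissue = expressed_sets(expr, threshold)
    out: dict[str, frozenset[str]] = {}
    for stress in STRESSES:
        sets = [g for (st, _), g in per_tissue.items() if st == stress]
        if sets:
            out[stress] = frozenset().union(*sets)
    return out
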