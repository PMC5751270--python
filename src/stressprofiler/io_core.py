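"""Experiment data model and tabular I/O.

The experimental design is fixed by the study layout: two stresses
(cold, drought) by three tissues (folded leaves FL, fully expanded
leaves FEL, fibrous roots RT), each sampled at a control time point
and three treatment time points (cold: 6/24/48 h; drought: 4/6/10 d).
A full experiment therefore has 24 samples organised into six
condition series, one per (stress, tissue) pair.

All artifacts are plain TSV: a counts table (first column ``gene_id``,
one column per sample), a sample sheet describing each column, and a
two-column gene -> hierarchical-bin map.  Lines starting with ``#``
are comments.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STRESSES = ("cold", "drought")
TISSUES = ("FL", "FEL", "RT")

#: treatment time labels, by stress, indexed 1..3 (index 0 = control)
TIME_LABELS = {
    "cold": ("0h", "6h", "24h", "48h"),
    "drought": ("0d", "4d", "6d", "10d"),
}


class TableFormatError(ValueError):
    """A tabular artifact violates its declared dialect or contract."""


@dataclass(frozen=True)
class SampleDescriptor:
    """One sequenced library and its place in the design."""

    sample_id: str
    stress: str
    tissue: str
    time_index: int
    role: str
    library_size: int | None = None

    def __post_init__(self) -> None:
        if self.stress not in STRESSES:
            raise TableFormatError(
                f"sample {self.sample_id!r}: unknown stress {self.stress!r}"
            )
        if self.tissue not in TISSUES:
            raise TableFormatError(
                f"sample {self.sample_id!r}: unknown tissue {self.tissue!r}"
            )
        if not 0 <= self.time_index <= 3:
            raise TableFormatError(
                f"sample {self.sample_id!r}: time_index must be 0-3, "
                f"got {self.time_index}"
            )
        if self.role not in ("control", "treatment"):
            raise TableFormatError(
                f"sample {self.sample_id!r}: unknown role {self.role!r}"
            )
        if self.library_size is not None and self.library_size <= 0:
            raise TableFormatError(
                f"sample {self.sample_id!r}: library_size must be positive"
            )

    @property
    def time_label(self) -> str:
        return TIME_LABELS[self.stress][self.time_index]


@dataclass
class CountMatrix:
    """Raw integer read counts, genes x samples.

    ``counts`` is a DataFrame indexed by gene_id with one column per
    sample_id, aligned with ``samples``.  Library sizes default to the
    column sums when the sample sheet does not supply them.
    """

    counts: pd.DataFrame
    samples: list[SampleDescriptor]

    def __post_init__(self) -> None:
        cols = list(self.counts.columns)
        ids = [s.sample_id for s in self.samples]
        if cols != ids:
            raise TableFormatError(
                f"count columns {cols} do not match sample sheet order {ids}"
            )
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise TableFormatError(f"duplicate gene_id(s): {dups[:5]}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise TableFormatError("counts must be integers")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise TableFormatError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {cols[s]!r}"
            )
        # fill missing library sizes from column sums
        sums = self.counts.sum(axis=0)
        filled = []
        for s in self.samples:
            if s.library_size is None:
                s = SampleDescriptor(
                    s.sample_id, s.stress, s.tissue, s.time_index, s.role,
                    int(sums[s.sample_id]),
                )
            filled.append(s)
        self.samples = filled

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> np.ndarray:
        return np.array([s.library_size for s in self.samples], dtype=float)

    def sample(self, sample_id: str) -> SampleDescriptor:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def condition_series(self) -> list["ConditionSeries"]:
        """Group samples into (stress, tissue) series, control first.

        The default pairing uses the time-index-0 sample of each
        (stress, tissue) as the control for all three treatment time
        points.
        """
        by_key: dict[tuple[str, str], dict[int, SampleDescriptor]] = {}
        for s in self.samples:
            by_key.setdefault((s.stress, s.tissue), {})[s.time_index] = s
        out = []
        for stress in STRESSES:
            for tissue in TISSUES:
                tp = by_key.get((stress, tissue))
                if tp is None:
                    continue
                if set(tp) != {0, 1, 2, 3}:
                    raise TableFormatError(
                        f"series ({stress}, {tissue}) needs time points "
                        f"0-3, has {sorted(tp)}"
                    )
                out.append(ConditionSeries(
                    stress=stress,
                    tissue=tissue,
                    control_sample=tp[0].sample_id,
                    treatment_samples=[tp[i].sample_id for i in (1, 2, 3)],
                ))
        return out


@dataclass(frozen=True)
class ConditionSeries:
    """One (stress, tissue) pair: a control and 3 treatment samples."""

    stress: str
    tissue: str
    control_sample: str
    treatment_samples: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "treatment_samples", tuple(self.treatment_samples)
        )
        if len(self.treatment_samples) != 3:
            raise TableFormatError(
                f"series ({self.stress}, {self.tissue}): expected 3 "
                f"treatment samples, got {len(self.treatment_samples)}"
            )

    @property
    def key(self) -> str:
        """Short label, e.g. 'c.FL' or 'd.RT'."""
        return f"{self.stress[0]}.{self.tissue}"


#: canonical series order used by pattern slots and FC profiles
SERIES_ORDER = tuple(
    f"{s[0]}.{t}" for s in STRESSES for t in TISSUES
)


class CategoryMap:
    """Gene -> hierarchical functional bins (dot-separated paths).

    A gene may map to several bins; ancestors of every assigned bin
    are implicitly part of the vocabulary, and hierarchical queries
    roll descendant memberships up into parents.
    """

    def __init__(self, assignments: Mapping[str, Iterable[str]]) -> None:
        self._gene_bins: dict[str, tuple[str, ...]] = {}
        vocab: set[str] = set()
        for gene, bins in assignments.items():
            paths = []
            for b in bins:
                b = b.strip()
                if not b:
                    raise TableFormatError(
                        f"gene {gene!r}: empty bin path"
                    )
                paths.append(b)
                parts = b.split(".")
                for i in range(1, len(parts) + 1):
                    vocab.add(".".join(parts[:i]))
            self._gene_bins[gene] = tuple(sorted(set(paths)))
        self._vocab = tuple(sorted(vocab))
        # bin -> genes, with roll-up: a gene in a.b.c is in a.b and a
        members: dict[str, set[str]] = {b: set() for b in self._vocab}
        for gene, paths in self._gene_bins.items():
            for p in paths:
                parts = p.split(".")
                for i in range(1, len(parts) + 1):
                    members[".".join(parts[:i])].add(gene)
        self._members = members

    @property
    def bins(self) -> tuple[str, ...]:
        return self._vocab

    def bins_for(self, gene: str) -> tuple[str, ...]:
        """Leaf-level bin paths assigned to a gene ('' genes -> empty)."""
        return self._gene_bins.get(gene, ())

    def genes_in(self, bin_path: str) -> frozenset[str]:
        """All genes assigned to the bin or any of its descendants."""
        return frozenset(self._members.get(bin_path, frozenset()))

    def parent(self, bin_path: str) -> str | None:
        if "." not in bin_path:
            return None
        return bin_path.rsplit(".", 1)[0]

    def __contains__(self, gene: str) -> bool:
        return gene in self._gene_bins

    def __len__(self) -> int:
        return len(self._gene_bins)


# ---------------------------------------------------------------------------
# readers / writers

_SAMPLE_SHEET_COLS = ("sample_id", "stress", "tissue", "time_index", "role")


def read_samplesheet(path: str | Path) -> list[SampleDescriptor]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _SAMPLE_SHEET_COLS if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"sample sheet {path}: missing column(s) {missing}"
        )
    out = []
    for _, row in df.iterrows():
        lib = None
        if "library_size" in df.columns and pd.notna(row["library_size"]):
            lib = int(row["library_size"])
        out.append(SampleDescriptor(
            sample_id=row["sample_id"],
            stress=row["stress"],
            tissue=row["tissue"],
            time_index=int(row["time_index"]),
            role=row["role"],
            library_size=lib,
        ))
    ids = [s.sample_id for s in out]
    if len(set(ids)) != len(ids):
        raise TableFormatError(f"sample sheet {path}: duplicate sample_id")
    return out


def read_counts(counts_path: str | Path,
                samplesheet_path: str | Path) -> CountMatrix:
    """Read a counts TSV plus its sample sheet into a CountMatrix.

    The counts file has a header row of sample ids and a first column
    named ``gene_id``.  Samples are returned in sample-sheet order;
    every count column must be described by the sheet.
    """
    samples = read_samplesheet(samplesheet_path)
    df = pd.read_csv(counts_path, sep="\t", comment="#", index_col=0)
    if df.index.name != "gene_id":
        raise TableFormatError(
            f"{counts_path}: first column header must be 'gene_id', "
            f"got {df.index.name!r}"
        )
    sheet_ids = [s.sample_id for s in samples]
    missing = [c for c in df.columns if c not in sheet_ids]
    if missing:
        raise TableFormatError(
            f"{counts_path}: sample(s) {missing} not described in the "
            f"sample sheet"
        )
    absent = [sid for sid in sheet_ids if sid not in df.columns]
    if absent:
        raise TableFormatError(
            f"{counts_path}: sample sheet entries {absent} have no "
            f"count column"
        )
    df = df[sheet_ids]
    for col in df.columns:
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.integer):
            bad = vals[~vals.apply(
                lambda v: float(v).is_integer() if pd.notna(v) else False
            )]
            gene = bad.index[0] if len(bad) else vals.index[0]
            raise TableFormatError(
                f"{counts_path}: non-integer count at "
                f"(gene {gene!r}, sample {col!r})"
            )
        neg = vals[vals < 0]
        if len(neg):
            raise TableFormatError(
                f"{counts_path}: negative count at "
                f"(gene {neg.index[0]!r}, sample {col!r})"
            )
    return CountMatrix(counts=df.astype(np.int64), samples=samples)


def read_category_map(path: str | Path) -> CategoryMap:
    """Read a two-column (gene_id, bin_path) TSV into a CategoryMap."""
    assignments: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.split("\t")[0] in ("gene_id", "gene"):
                continue  # optional header
            parts = line.split("\t")
            if len(parts) < 2 or not parts[1].strip():
                raise TableFormatError(
                    f"{path}:{lineno}: expected 'gene_id<TAB>bin_path'"
                )
            assignments.setdefault(parts[0], []).append(parts[1])
    return CategoryMap(assignments)


def write_table(rows: pd.DataFrame, path: str | Path,
                sort_by: Sequence[str] | None = None) -> None:
    """Write a result table as deterministic UTF-8 TSV.

    Rows are sorted by ``sort_by`` (default: all columns left to
    right) and floats rendered at 6 significant digits, so identical
    inputs give byte-identical files.
    """
    if rows.shape[1] == 0:
        raise TableFormatError("cannot write a table with no columns")
    out = rows.copy()
    if len(out):
        keys = list(sort_by) if sort_by else list(out.columns)
        out = out.sort_values(keys, kind="mergesort")
    buf = io.StringIO()
    out.to_csv(buf, sep="\t", index=False, float_format="%.6g")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")
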