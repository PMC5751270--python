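"""Venn partitioning of DE gene sets and percentage bookkeeping.

Stress specificity within a tissue is summarised by a two-set Venn
partition (cold-only / drought-only / shared), with region
percentages taken over the union of the two sets.  Tissue specificity
within a stress uses the three-set partition (FL / FEL / RT).
Percentages are rounded half-away-from-zero, matching how such tables
are conventionally printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal


def proportion(count: int, total: int, decimals: int = 1) -> float:
    """count/total as a percentage, rounded half-away-from-zero.

    E.g. proportion(270, 1810, 1) -> 14.9 and proportion(11, 78, 0) -> 14.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError(f"count {count} outside [0, {total}]")
    pct = Decimal(count) / Decimal(total) * 100
    q = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class VennPartition2:
    """Exact two-set partition with percentages over the union."""

    label_a: str
    label_b: str
    a_only: frozenset[str]
    b_only: frozenset[str]
    shared: frozenset[str]

    @property
    def union_size(self) -> int:
        return len(self.a_only) + len(self.b_only) + len(self.shared)

    @property
    def sizes(self) -> dict[str, int]:
        return {"a_only": len(self.a_only), "b_only": len(self.b_only),
                "shared": len(self.shared)}

    @property
    def percentages(self) -> dict[str, float] | None:
        """Region percentages of the union at 1 decimal; None if empty."""
        if self.union_size == 0:
            return None
        return {k: proportion(v, self.union_size, 1)
                for k, v in self.sizes.items()}


@dataclass(frozen=True)
class VennPartition3:
    """Exact three-set partition into 7 disjoint regions.

    Region keys are binary membership signatures over (A, B, C):
    '100' = A only, '110' = A and B but not C, '111' = all three.
    """

    labels: tuple[str, str, str]
    regions: dict[str, frozenset[str]]

    @property
    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.regions.items()}

    def set_total(self, which: int) -> int:
        """Recover |set| by summing its 4 regions (which in 0..2)."""
        return sum(len(v) for k, v in self.regions.items()
                   if k[which] == "1")


def venn2(set_a: frozenset[str] | set[str],
          set_b: frozenset[str] | set[str],
          label_a: str = "A", label_b: str = "B") -> VennPartition2:
    """Exact two-set Venn partition."""
    a, b = frozenset(set_a), frozenset(set_b)
    return VennPartition2(
        label_a=label_a, label_b=label_b,
        a_only=a - b, b_only=b - a, shared=a & b,
    )


def venn3(set_a: frozenset[str] | set[str],
          set_b: frozenset[str] | set[str],
          set_c: frozenset[str] | set[str],
          labels: tuple[str, str, str] = ("A", "B", "C")
          ) -> VennPartition3:
    """Exact three-set Venn partition into 7 disjoint regions."""
    sets = (frozenset(set_a), frozenset(set_b), frozenset(set_c))
    universe = sets[0] | sets[1] | sets[2]
    regions: dict[str, set[str]] = {
        f"{i}{j}{k}": set()
        for i in (0, 1) for j in (0, 1) for k in (0, 1)
        if (i, j, k) != (0, 0, 0)
    }
    for g in universe:
        sig = "".join("1" if g in s else "0" for s in sets)
        regions[sig].add(g)
    return VennPartition3(
        labels=labels,
        regions={k: frozenset(v) for k, v in regions.items()},
    )


def venn2_from_sizes(size_a: int, size_b: int,
                     shared: int) -> dict[str, int | float]:
    """Region counts and percentages from printed set sizes alone.

    Convenience for re-deriving specificity arithmetic from published
    totals: given |A|, |B| and |A∩B|, returns the three region counts
    and their percentages of the union.
    """
    if shared > min(size_a, size_b) or min(size_a, size_b, shared) < 0:
        raise ValueError("infeasible sizes")
    a_only = size_a - shared
    b_only = size_b - shared
    union = a_only + b_only + shared
    out: dict[str, int | float] = {
        "a_only": a_only, "b_only": b_only, "shared": shared,
        "union": union,
    }
    if union > 0:
        out["a_only_pct"] = proportion(a_only, union, 1)
        out["b_only_pct"] = proportion(b_only, union, 1)
        out["shared_pct"] = proportion(shared, union, 1)
    return out
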