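"""Pattern taxonomy, fold-change profiles, and clustering oracle checks."""

import numpy as np
import pandas as pd
import pytest

from stressprofiler.de_calling import DEGeneCall, Direction
from stressprofiler.io_core import ConditionSeries, SERIES_ORDER
from stressprofiler.normalization import cpm
from stressprofiler.patterns import (ResponsePattern, assign_pattern,
                                     foldchange_profile, group_patterns,
                                     group_sizes, hcluster,
                                     profile_columns)

from conftest import make_counts, make_samples


def _call(gene, key, direction):
    stress = "cold" if key.startswith("c.") else "drought"
    tissue = key.split(".", 1)[1]
    prefix = f"{stress[0]}.{tissue}"
    labels = ("0h", "6h", "24h", "48h") if stress == "cold" \
        else ("0d", "4d", "6d", "10d")
    series = ConditionSeries(stress, tissue, f"{prefix}.{labels[0]}",
                             tuple(f"{prefix}.{t}" for t in labels[1:]))
    return DEGeneCall(gene, series, direction, 2, ())


def _calls_by_series(spec):
    """spec: {gene: {series_key: Direction}} -> call mapping."""
    out = {k: {} for k in SERIES_ORDER}
    for gene, slots in spec.items():
        for key, d in slots.items():
            out[key][gene] = _call(gene, key, d)
    return out


class TestPatternAssignment:
    def test_single_and_double_series_patterns(self):
        calls = _calls_by_series({
            "g1": {"c.FL": Direction.UP},
            "g2": {"c.FL": Direction.DOWN, "c.FEL": Direction.DOWN},
        })
        p1 = assign_pattern("g1", calls)
        assert str(p1) == ("c.FL:up|c.FEL:none|c.RT:none|"
                           "d.FL:none|d.FEL:none|d.RT:none")
        p2 = assign_pattern("g2", calls)
        assert p2.n_responding == 2
        assert p2.slots[0] is Direction.DOWN
        assert p2.slots[1] is Direction.DOWN

    def test_gene_without_calls_is_an_error(self):
        with pytest.raises(ValueError, match="not DE"):
            assign_pattern("gX", {k: {} for k in SERIES_ORDER})

    def test_pattern_string_round_trip(self):
        calls = _calls_by_series({"g": {"d.RT": Direction.UP}})
        p = assign_pattern("g", calls)
        assert ResponsePattern.from_string(str(p)) == p


class TestGrouping:
    def test_groups_partition_the_de_universe(self):
        calls = _calls_by_series({
            "g1": {"c.FL": Direction.UP},
            "g2": {"c.FL": Direction.UP},
            "g3": {"c.FL": Direction.DOWN},
            "g4": {"c.FL": Direction.DOWN, "d.RT": Direction.UP},
        })
        membership = group_patterns(calls)
        assert len(membership) == 4  # every DE gene exactly once
        sizes = group_sizes(membership)
        assert sizes["size"].sum() == 4
        assert len(sizes) == 3
        # fewer responding series sort first; down before up
        assert list(sizes["group_id"]) == ["G1", "G2", "G3"]
        first = membership[membership.group_id == "G1"]
        assert set(first.gene_id) == {"g3"}  # c.FL down sorts before up

    def test_labels_stable_under_input_permutation(self):
        spec = {
            "g1": {"c.FEL": Direction.UP},
            "g2": {"d.FL": Direction.DOWN},
            "g3": {"c.FEL": Direction.UP, "d.FL": Direction.DOWN},
        }
        a = group_patterns(_calls_by_series(spec))
        b = group_patterns(_calls_by_series(dict(reversed(spec.items()))))
        pd.testing.assert_frame_equal(a, b)

    def test_all_genes_same_pattern_single_group(self):
        calls = _calls_by_series(
            {f"g{i}": {"c.RT": Direction.UP} for i in range(5)})
        sizes = group_sizes(group_patterns(calls))
        assert len(sizes) == 1 and sizes.loc[0, "size"] == 5


class TestFoldChangeProfile:
    def _experiment(self):
        samples = make_samples()
        rngl = np.random.default_rng(3)
        counts = rngl.poisson(200, size=(4, 24)).astype(np.int64)
        idx = {s.sample_id: j for j, s in enumerate(samples)}
        lib = 1_000_000
        arr = np.full((5, 24), 20 * lib // int(1e6), dtype=np.int64)
        # g0: DE up in c.FL (ctrl 20 CPM, treat 70 CPM)
        for sid in ("c.FL.6h", "c.FL.24h", "c.FL.48h"):
            arr[0, idx[sid]] = 70
        # g1: on/off in d.RT (ctrl 0, treat 40)
        arr[1, :] = 0
        for sid in ("d.RT.4d", "d.RT.6d", "d.RT.10d"):
            arr[1, idx[sid]] = 40
        arr[4, :] = lib - arr[:4, :].sum(axis=0)  # filler
        cm = make_counts(arr, samples=samples)
        return cpm(cm), cm.condition_series()

    def test_de_cells_log2_and_non_de_cells_zero(self):
        expr, series_list = self._experiment()
        calls = _calls_by_series({
            "g0": {"c.FL": Direction.UP},
            "g1": {"d.RT": Direction.UP},
        })
        prof = foldchange_profile(expr, series_list, calls, pseudocount=0)
        assert list(prof.columns) == profile_columns()
        assert prof.loc["g0", "c.FL.6h"] == pytest.approx(np.log2(3.5))
        # non-DE series of a DE gene are forced to log2(1) = 0
        assert (prof.loc["g0", [c for c in prof.columns
                                if not c.startswith("c.FL")]] == 0).all()

    def test_pseudocount_keeps_on_off_cells_finite(self):
        expr, series_list = self._experiment()
        calls = _calls_by_series({"g1": {"d.RT": Direction.UP}})
        prof = foldchange_profile(expr, series_list, calls, pseudocount=1)
        got = prof.loc["g1", "d.RT.4d"]
        assert np.isfinite(got)
        assert got == pytest.approx(np.log2(41.0), abs=1e-9)


def naive_complete_linkage(points):
    """O(n^3) agglomerative complete linkage; returns sorted merge
    heights (max Euclidean distance over cross-pairs)."""
    clusters = [[i] for i in range(len(points))]
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                h = max(d[a, b] for a in clusters[i] for b in clusters[j])
                if h < best[0]:
                    best = (h, (i, j))
        h, (i, j) = best
        heights.append(h)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return np.array(heights)


class TestHCluster:
    def test_identical_rows_merge_first(self):
        prof = pd.DataFrame([[0.0, 0], [5, 5], [0, 0]],
                            index=["a", "b", "c"])
        res = hcluster(prof)
        assert res.merge_heights[0] == 0.0
        assert {int(res.linkage_matrix[0, 0]),
                int(res.linkage_matrix[0, 1])} == {0, 2}

    @pytest.mark.parametrize("seed", range(5))
    def test_merge_heights_match_naive_oracle(self, seed):
        rngl = np.random.default_rng(seed)
        pts = rngl.normal(size=(20, 6))
        prof = pd.DataFrame(pts, index=[f"g{i}" for i in range(20)])
        got = np.sort(hcluster(prof).merge_heights)
        want = np.sort(naive_complete_linkage(pts))
        assert np.allclose(got, want, atol=1e-10)

    def test_heights_non_decreasing_and_permutation_invariant(self, rng):
        pts = rng.normal(size=(15, 4))
        prof = pd.DataFrame(pts, index=[f"g{i}" for i in range(15)])
        res = hcluster(prof)
        assert (np.diff(res.merge_heights) >= -1e-12).all()
        perm = rng.permutation(15)
        res2 = hcluster(prof.iloc[perm])
        assert np.allclose(np.sort(res.merge_heights),
                           np.sort(res2.merge_heights))
        assert set(res.leaf_order) == set(res2.leaf_order)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            hcluster(pd.DataFrame([[1.0, 2.0]], index=["g"]))
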