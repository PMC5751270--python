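"""Synthetic-data generator: determinism, planted-truth recovery,
false-positive control, enrichment positive control."""

import numpy as np
import pytest
from scipy.stats import kstest

from stressprofiler.de_calling import Direction, call_all_series, de_summary
from stressprofiler.enrichment import fisher_enrich
from stressprofiler.io_core import CategoryMap, SERIES_ORDER
from stressprofiler.normalization import cpm, tmm_factors
from stressprofiler.patterns import ResponsePattern
from stressprofiler.set_analysis import venn2
from stressprofiler.synthetic import (GeneratorConfig, PlantedPattern,
                                      SyntheticTruth, generate_category_map,
                                      generate_experiment, ramp_config)


def run_caller(counts):
    expr = cpm(counts, tmm_factors(counts))
    calls = call_all_series(expr, counts.condition_series())
    return de_summary(calls)[1], calls


class TestGeneratorBasics:
    def test_fixed_seed_is_deterministic(self):
        cfg = GeneratorConfig(seed=9, n_genes=500,
                              planted_patterns=[PlantedPattern(
                                  {"c.FL": "up"}, n_genes=20)])
        a, ta = generate_experiment(cfg)
        b, tb = generate_experiment(cfg)
        assert a.counts.equals(b.counts)
        assert ta.patterns == tb.patterns

    def test_design_has_24_samples_and_6_series(self):
        cfg = GeneratorConfig(seed=0, n_genes=200, planted_patterns=[])
        cm, _ = generate_experiment(cfg)
        assert cm.counts.shape == (200, 24)
        series = cm.condition_series()
        assert len(series) == 6
        assert sorted(s.key for s in series) == sorted(SERIES_ORDER)

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            GeneratorConfig(n_genes=100, planted_patterns=[
                PlantedPattern({"c.FL": "up"}, n_genes=95)])

    def test_invalid_planted_patterns_rejected(self):
        with pytest.raises(ValueError, match="unknown series"):
            PlantedPattern({"x.FL": "up"}, n_genes=5)
        with pytest.raises(ValueError, match="fold_change"):
            PlantedPattern({"c.FL": "up"}, n_genes=5, fold_change=0.5)
        with pytest.raises(ValueError, match="on/off"):
            PlantedPattern({"c.FL": "up"}, n_genes=5, fold_change=3,
                           on_off=True)


class TestRecovery:
    def test_no_planting_yields_near_zero_de(self):
        cfg = GeneratorConfig(seed=1, n_genes=2000, dispersion=0.02,
                              planted_patterns=[])
        cm, _ = generate_experiment(cfg)
        de_sets, _ = run_caller(cm)
        for key, s in de_sets.items():
            assert len(s) < 0.01 * cfg.n_genes, key

    def test_planted_cold_fl_up_recovered(self):
        cfg = GeneratorConfig(
            seed=1, n_genes=2000, dispersion=0.05,
            planted_patterns=[PlantedPattern({"c.FL": "up"}, 100,
                                             fold_change=8.0)])
        cm, truth = generate_experiment(cfg)
        de_sets, calls = run_caller(cm)
        planted = truth.de_set("c.FL")
        got = de_sets["c.FL"]
        recall = len(got & planted) / len(planted)
        precision = len(got & planted) / len(got)
        assert recall >= 0.95
        assert precision >= 0.95
        # planted direction always matches the recovered direction
        for g in got & planted:
            assert calls["c.FL"][g].direction is truth.direction(g, "c.FL")

    def test_on_off_cohort_called_through_on_off_rule(self):
        cfg = GeneratorConfig(
            seed=4, n_genes=1500, dispersion=0.05,
            planted_patterns=[PlantedPattern({"d.RT": "up"}, 60,
                                             fold_change=10.0,
                                             on_off=True)])
        cm, truth = generate_experiment(cfg)
        de_sets, calls = run_caller(cm)
        planted = truth.de_set("d.RT")
        hit = de_sets["d.RT"] & planted
        assert len(hit) / len(planted) >= 0.9
        from stressprofiler.de_calling import Rule
        rules = [c.rule for g in hit for c in calls["d.RT"][g].candidates
                 if c.status is not Direction.NONE]
        assert sum(r is Rule.ON_OFF for r in rules) > len(rules) * 0.8

    def test_single_time_point_ramp_is_not_called(self):
        base = GeneratorConfig(seed=2, n_genes=1500, dispersion=0.05,
                               planted_patterns=[])
        cfg = ramp_config(base, "c.FL", n_genes=100, fold_change=8.0)
        cm, truth = generate_experiment(cfg)
        de_sets, _ = run_caller(cm)
        ramp_genes = {g for g, tp in truth.active_timepoints.items()
                      if tp == (1,)}
        assert len(ramp_genes) == 100
        assert len(de_sets["c.FL"] & ramp_genes) == 0
        assert truth.de_set("c.FL") == frozenset()

    def test_disjoint_cohorts_reproduce_venn_regions_exactly(self):
        cfg = GeneratorConfig(
            seed=3, n_genes=2000, dispersion=0.02,
            planted_patterns=[
                PlantedPattern({"c.FL": "up"}, 40, fold_change=12.0),
                PlantedPattern({"d.FL": "up"}, 30, fold_change=12.0),
                PlantedPattern({"c.FL": "up", "d.FL": "up"}, 20,
                               fold_change=12.0),
            ])
        cm, truth = generate_experiment(cfg)
        de_sets, _ = run_caller(cm)
        part = venn2(de_sets["c.FL"], de_sets["d.FL"])
        assert part.sizes == {"a_only": 40, "b_only": 30, "shared": 20}


class TestCategoryMapGeneration:
    def _truth(self, n_de, n_genes):
        slots = [Direction.NONE] * 6
        slots[0] = Direction.UP
        p = ResponsePattern(tuple(slots))
        genes = [f"gene{str(i).zfill(5)}" for i in range(n_de)]
        return SyntheticTruth(
            patterns={g: p for g in genes},
            fold_changes={g: {"c.FL": 8.0} for g in genes},
            on_off={g: False for g in genes},
            active_timepoints={g: (1, 2, 3) for g in genes})

    def test_every_gene_gets_a_bin(self):
        cfg = GeneratorConfig(seed=0, n_genes=300, planted_patterns=[])
        df = generate_category_map(cfg, self._truth(50, 300))
        assert len(df) == 300
        assert (df["bin_path"].str.len() > 0).all()

    def test_null_odds_gives_uniform_loaded_bin_p(self):
        """With odds 1 the loaded bin's Fisher p over replicates is
        close to uniform (Kolmogorov distance < 0.1)."""
        cfg = GeneratorConfig(seed=0, n_genes=800, planted_patterns=[])
        truth = self._truth(200, 800)
        de = sorted(truth.patterns)
        bg = [f"gene{str(i).zfill(5)}" for i in range(800)]
        ps = []
        for rep in range(200):
            df = generate_category_map(cfg, truth, n_bins=10,
                                       enrichment_odds=1.0, seed=rep)
            cat = CategoryMap({g: [b] for g, b in
                               zip(df.gene_id, df.bin_path)})
            res = fisher_enrich(de, bg, cat, min_bin_size=1)
            ps.append(float(
                res.loc[res["bin"] == "stress.response", "p"].iloc[0]))
        ks = kstest(ps, "uniform").statistic
        assert ks < 0.1

    def test_loaded_bin_flagged_under_strong_odds(self):
        cfg = GeneratorConfig(seed=0, n_genes=800, planted_patterns=[])
        truth = self._truth(200, 800)
        de = sorted(truth.patterns)
        bg = [f"gene{str(i).zfill(5)}" for i in range(800)]
        flagged = 0
        n_rep = 40
        for rep in range(n_rep):
            df = generate_category_map(cfg, truth, n_bins=10,
                                       enrichment_odds=8.0, seed=1000 + rep)
            cat = CategoryMap({g: [b] for g, b in
                               zip(df.gene_id, df.bin_path)})
            res = fisher_enrich(de, bg, cat, min_bin_size=1)
            row = res.loc[res["bin"] == "stress.response"].iloc[0]
            flagged += bool(row["significant"])
        assert flagged >= 0.95 * n_rep
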