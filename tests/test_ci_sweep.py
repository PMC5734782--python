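"""Bootstrap sweep engine: percentile CIs, determinism, and trend behavior."""

import numpy as np
import pytest

from betaci import (
    CIRecord,
    CountTable,
    GroupMap,
    SweepConfig,
    anosim_r,
    bootstrap_replicates,
    bray_curtis,
    ci_width_decrease,
    css_normalize,
    percentile_ci,
    preset,
    records_to_frame,
    run_sweep,
    simulate_grouped_dataset,
)


class TestPercentileCI:
    def test_evenly_spaced_values(self):
        lower, mean, upper = percentile_ci(np.arange(101.0), 0.95)
        assert (lower, mean, upper) == pytest.approx((2.5, 50.0, 97.5), abs=1e-9)

    def test_constant_values(self):
        assert percentile_ci([3.0, 3.0, 3.0]) == (3.0, 3.0, 3.0)

    def test_two_point_interpolation(self):
        lower, mean, upper = percentile_ci([0.0, 1.0], 0.95)
        assert lower == pytest.approx(0.025)
        assert upper == pytest.approx(0.975)
        assert mean == 0.5

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(ValueError):
            percentile_ci([1.0])


class TestBootstrapReplicates:
    def _config(self, **kw):
        defaults = dict(effort_grid=(4,), n_boot=3, metric="bray-curtis",
                        test="ANOSIM", normalization="css", seed=9)
        defaults.update(kw)
        return SweepConfig(**defaults)

    def test_shape_and_bitwise_determinism(self, random_table_factory):
        table = random_table_factory(n_taxa=15, n_samples=8, seed=1)
        groups = GroupMap({s: ("A" if j < 4 else "B")
                           for j, s in enumerate(table.sample_ids)})
        config = self._config()
        a = bootstrap_replicates(table, groups, config, effort=4)
        b = bootstrap_replicates(table, groups, config, effort=4)
        assert a.values.shape == (3,)
        np.testing.assert_array_equal(a.values, b.values)

    def test_two_distinct_column_groups_give_constant_r_one(self):
        # each group is copies of one distinct composition: perfect separation
        col_a, col_b = [10, 0, 5], [0, 10, 5]
        counts = np.column_stack([col_a, col_a, col_a, col_b, col_b, col_b])
        table = CountTable(("t1", "t2", "t3"),
                           tuple(f"s{j}" for j in range(6)), counts)
        groups = GroupMap({f"s{j}": ("A" if j < 3 else "B") for j in range(6)})
        reps = bootstrap_replicates(table, groups, self._config(n_boot=10), effort=3)
        np.testing.assert_allclose(reps.values, 1.0, atol=1e-12)

    def test_full_effort_mean_tracks_full_data_statistic(self):
        table, groups, _ = simulate_grouped_dataset(preset("strong", seed=0))
        full_r = anosim_r(bray_curtis(css_normalize(table)), groups)
        config = self._config(n_boot=100, effort_grid=(14,), seed=0)
        reps = bootstrap_replicates(table, groups, config, effort=14)
        assert abs(reps.values.mean() - full_r) < 0.1

    def test_renormalize_after_rarefy_switch(self, random_table_factory):
        table = random_table_factory(n_taxa=15, n_samples=8, seed=6, max_count=40)
        groups = GroupMap({s: ("A" if j < 4 else "B")
                           for j, s in enumerate(table.sample_ids)})
        depth = int(table.sample_totals().min())
        raw = bootstrap_replicates(
            table, groups, self._config(), effort=3, depth=depth)
        renorm = bootstrap_replicates(
            table, groups, self._config(renormalize_after_rarefy=True),
            effort=3, depth=depth)
        assert np.all(np.abs(raw.values) <= 1)
        assert np.all(np.abs(renorm.values) <= 1)

    def test_replicates_in_legal_range_and_ci_inside_value_range(self):
        table, groups, _ = simulate_grouped_dataset(
            preset("weak", seed=1, n_samples_per_group=(10, 10)))
        config = self._config(n_boot=50, test="PERMANOVA")
        reps = bootstrap_replicates(table, groups, config, effort=5)
        assert np.all((reps.values >= 0) & (reps.values <= 1))
        lower, mean, upper = percentile_ci(reps.values)
        assert reps.values.min() <= lower <= upper <= reps.values.max()


class TestRunSweep:
    def test_cell_count_and_failed_cells_recorded(self, random_table_factory):
        table = random_table_factory(n_taxa=10, n_samples=8, seed=3, max_count=20)
        groups = GroupMap({s: ("A" if j < 4 else "B")
                           for j, s in enumerate(table.sample_ids)})
        config = SweepConfig(effort_grid=(3, 5), depth_grid=(5, 10 ** 9),
                             n_boot=5, normalization="none", seed=0)
        records = run_sweep(table, groups, None, config)
        assert len(records) == 4
        frame = records_to_frame(records)
        deep = frame[frame.depth == 10 ** 9]
        assert (deep.status.str.startswith("failed")).all()
        assert frame[frame.depth == 5].status.eq("ok").all()

    def test_identical_seed_reproduces_records_exactly(self, random_table_factory):
        table = random_table_factory(n_taxa=10, n_samples=8, seed=5)
        groups = GroupMap({s: ("A" if j < 4 else "B")
                           for j, s in enumerate(table.sample_ids)})
        config = SweepConfig(effort_grid=(3, 4), n_boot=20, seed=77)
        a = records_to_frame(run_sweep(table, groups, None, config))
        b = records_to_frame(run_sweep(table, groups, None, config))
        assert a.equals(b)

    def test_null_preset_cis_cover_zero(self):
        covered = total = 0
        for seed in range(3):
            table, groups, _ = simulate_grouped_dataset(preset("null", seed=seed))
            config = SweepConfig(effort_grid=(5, 10, 15, 20), n_boot=150,
                                 metric="bray-curtis", test="ANOSIM", seed=seed)
            for record in run_sweep(table, groups, None, config):
                total += 1
                covered += record.lower <= 0.0 <= record.upper
        assert covered / total >= 0.8


class TestCIWidthDecrease:
    def _record(self, depth, width, effort=5):
        return CIRecord(test="ANOSIM", metric="bray-curtis", resolution=None,
                        depth=depth, effort=effort, n_boot=10, mean=0.5,
                        lower=0.5 - width / 2, upper=0.5 + width / 2, width=width)

    def test_single_cell_halving(self):
        records = [self._record(100, 0.4), self._record(20000, 0.2)]
        assert ci_width_decrease(records, 100, 20000) == pytest.approx(50.0)

    def test_equal_widths_zero_decrease(self):
        records = [self._record(100, 0.3), self._record(20000, 0.3)]
        assert ci_width_decrease(records, 100, 20000) == pytest.approx(0.0)

    def test_average_over_two_matched_cells(self):
        records = [
            self._record(100, 1.0, effort=5), self._record(20000, 0.2, effort=5),
            self._record(100, 1.0, effort=10), self._record(20000, 0.8, effort=10),
        ]
        assert ci_width_decrease(records, 100, 20000) == pytest.approx(50.0)

    def test_zero_width_cells_excluded(self):
        records = [self._record(100, 0.0), self._record(20000, 0.0)]
        with pytest.raises(ValueError, match="no matched cells"):
            ci_width_decrease(records, 100, 20000)


class TestSweepConfig:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "sweep.yaml"
        path.write_text(
            "effort_grid: [5, 10]\ndepth_grid: [100, none]\n"
            "metric: jaccard\ntest: PERMANOVA\nn_boot: 10\nseed: 3\n"
        )
        config = SweepConfig.from_yaml(path)
        assert config.effort_grid == (5, 10)
        assert config.depth_grid == (100, None)
        assert config.metric == "jaccard"

    @pytest.mark.parametrize("kw", [
        dict(effort_grid=()), dict(effort_grid=(1,)), dict(effort_grid=(5,), n_boot=1),
        dict(effort_grid=(5,), ci_level=1.0), dict(effort_grid=(5,), metric="unifrac"),
        dict(effort_grid=(5,), depth_grid=(0,)),
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SweepConfig(**kw)
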