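"""Statistics layer: dwell distributions, frequencies, occupancy, fits."""

import warnings

import numpy as np
import pytest

from cosmos_kinetics import (
    AcquisitionSchedule,
    build_rastergram,
    bootstrap_se,
    cumulative_dwell_distribution,
    first_binding_times,
    fit_first_binding,
    frequency_by_duration_class,
    frequency_occupancy_ratio,
    intron_retention_curve,
    occupancy_from_table,
    simulate_intron_loss_panel,
    specific_binding_frequency,
    specific_occupancy,
    synergy_ratio,
)
from cosmos_kinetics.stats import DEFAULT_BOOTSTRAP_SAMPLES

from conftest import make_table


def fifty_locations(dwells_for_first, construct="5i3", plus_controls=True):
    """50 locations of one construct (events on the first), opt. 50 controls."""
    dwells = {f"{construct}_{i:03d}": [] for i in range(50)}
    dwells[f"{construct}_000"] = dwells_for_first
    constructs = {lid: construct for lid in dwells}
    if plus_controls:
        for i in range(50):
            lid = f"no_RNA_{i:03d}"
            dwells[lid] = []
            constructs[lid] = "no_RNA"
    return make_table(dwells, constructs)


class TestDwellDistribution:
    def test_counting_example(self):
        table = fifty_locations([10.0, 60.0, 60.0])
        d = cumulative_dwell_distribution(table, "5i3")
        assert d.value(0.0) == pytest.approx(0.06)
        assert d.value(50.0) == pytest.approx(0.04)
        assert d.value(61.0) == 0.0

    def test_no_intervals_is_identically_zero(self):
        d = cumulative_dwell_distribution(fifty_locations([]), "5i3")
        assert (d.values == 0).all()

    def test_non_increasing_on_simulated_table(self, two_construct_table):
        for name in ("5i3", "3e5", "no_RNA"):
            d = cumulative_dwell_distribution(two_construct_table, name)
            assert (np.diff(d.values) <= 1e-12).all()

    def test_absent_construct_errors(self, two_construct_table):
        with pytest.raises(ValueError, match="absent"):
            cumulative_dwell_distribution(two_construct_table, "nope")


class TestSpecificFrequency:
    def test_identical_distributions_give_zero(self):
        table = fifty_locations([10.0, 20.0])
        d = cumulative_dwell_distribution(table, "5i3")
        f = specific_binding_frequency(d, d, n_bootstrap=50)
        assert f.f_specific == 0.0

    def test_intercept_arithmetic_and_per_second_units(self):
        rna = {f"r_{i}": [5.0] for i in range(45)}  # 45 of 50 with one event
        rna.update({f"r_{i+45}": [] for i in range(5)})
        ctrl = {f"c_{i}": [3.0] if i < 5 else [] for i in range(50)}
        constructs = {**{k: "5i3" for k in rna}, **{k: "no_RNA" for k in ctrl}}
        table = make_table({**rna, **ctrl}, constructs)
        d_rna = cumulative_dwell_distribution(table, "5i3")
        d_ctrl = cumulative_dwell_distribution(table, "no_RNA")
        f = specific_binding_frequency(d_rna, d_ctrl, n_bootstrap=50)
        assert f.f_specific == pytest.approx(0.90 - 0.10)
        f_s = specific_binding_frequency(
            d_rna, d_ctrl, normalize_per_s=True, observed_duration=2400.0,
            n_bootstrap=50,
        )
        assert f_s.f_specific == pytest.approx(0.80 / 2400.0)

    def test_mismatched_grids_rejected(self):
        table = fifty_locations([10.0])
        a = cumulative_dwell_distribution(table, "5i3", grid=np.array([0.0, 1.0]))
        b = cumulative_dwell_distribution(table, "5i3", grid=np.array([0.0, 2.0]))
        with pytest.raises(ValueError, match="grid"):
            specific_binding_frequency(a, b)


class TestDurationClasses:
    def test_counting_example(self):
        table = fifty_locations([10.0, 60.0, 60.0])
        short, long_ = frequency_by_duration_class(
            table, "5i3", threshold=50.0, n_bootstrap=50
        )
        assert short.f_specific == pytest.approx(0.02)
        assert long_.f_specific == pytest.approx(0.04)

    def test_all_short_dwells_empty_long_class(self):
        table = fifty_locations([10.0, 10.0])
        _, long_ = frequency_by_duration_class(table, "5i3", n_bootstrap=50)
        assert long_.f_specific == 0.0

    def test_classes_partition_total(self, two_construct_table):
        d_rna = cumulative_dwell_distribution(two_construct_table, "3e5")
        d_ctrl = cumulative_dwell_distribution(two_construct_table, "no_RNA")
        total = specific_binding_frequency(d_rna, d_ctrl, n_bootstrap=10)
        short, long_ = frequency_by_duration_class(
            two_construct_table, "3e5", n_bootstrap=10
        )
        assert short.f_specific + long_.f_specific == pytest.approx(
            total.f_specific
        )


class TestOccupancy:
    def test_background_only_gives_zero(self):
        assert specific_occupancy(0.3, 0.3).specific_occupancy == 0.0

    def test_no_background_identity(self):
        assert specific_occupancy(0.4, 0.0).specific_occupancy == pytest.approx(0.4)

    def test_methods_formula_hand_value(self):
        assert specific_occupancy(0.5, 0.2).specific_occupancy == pytest.approx(0.375)

    def test_full_background_undefined(self):
        with pytest.raises(ValueError):
            specific_occupancy(0.5, 1.0)

    def test_fully_bound_location_with_empty_controls(self):
        sched = AcquisitionSchedule(
            green_block_length=10, red_interleave_length=0, total_duration=10.0
        )
        table = make_table(
            {"r": [10.0], "c1": [], "c2": []},
            {"r": "5i3", "c1": "no_RNA", "c2": "no_RNA"},
            schedule=sched,
            start=0.0,
        )
        occ = occupancy_from_table(table, "5i3", n_bootstrap=50)
        assert occ.specific_occupancy == pytest.approx(1.0)

    def test_all_empty_table_gives_zero(self):
        occ = occupancy_from_table(fifty_locations([]), "5i3", n_bootstrap=50)
        assert occ.specific_occupancy == 0.0

    def test_invariant_to_location_relabeling(self, two_construct_table):
        a = occupancy_from_table(two_construct_table, "5i3", n_bootstrap=100, seed=4)
        relabeled = two_construct_table
        md = relabeled.metadata.copy()
        # permute location ids consistently
        ids = list(md["location_id"])
        mapping = dict(zip(ids, reversed(ids)))
        # relabel only ids within the same construct to keep groups intact
        same = {
            lid: mapping[lid]
            for lid in ids
            if md.set_index("location_id").loc[lid, "construct"]
            == md.set_index("location_id").loc[mapping[lid], "construct"]
        }
        from cosmos_kinetics import Interval, IntervalsTable

        new_ivs = [
            Interval(
                same.get(iv.location_id, iv.location_id),
                iv.start,
                iv.end,
                iv.left_censored,
                iv.right_censored,
                iv.label,
            )
            for iv in relabeled.intervals
        ]
        md2 = md.copy()
        md2["location_id"] = [same.get(l, l) for l in md["location_id"]]
        table2 = IntervalsTable(new_ivs, md2, relabeled.schedule)
        b = occupancy_from_table(table2, "5i3", n_bootstrap=100, seed=4)
        assert a.specific_occupancy == pytest.approx(b.specific_occupancy)


class TestBootstrap:
    def test_identical_values_zero_se(self):
        se, _ = bootstrap_se(np.full(20, 3.0), n_bootstrap=200)
        assert se == 0.0

    def test_matches_closed_form_for_normal_mean(self, rng):
        # the bootstrap SE of the mean estimates sigma_hat / sqrt(n)
        values = rng.normal(0.0, 1.0, 100)
        se, _ = bootstrap_se(values, n_bootstrap=DEFAULT_BOOTSTRAP_SAMPLES, seed=1)
        assert se == pytest.approx(values.std(ddof=1) / np.sqrt(100), rel=0.05)

    def test_deterministic_under_seed(self, rng):
        values = rng.normal(size=30)
        a, _ = bootstrap_se(values, n_bootstrap=100, seed=9)
        b, _ = bootstrap_se(values, n_bootstrap=100, seed=9)
        assert a == b

    def test_fewer_than_two_locations_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_se(np.array([1.0]))


class TestFirstBinding:
    def test_times_and_censoring_partition(self, two_construct_table):
        tf = first_binding_times(two_construct_table, "5i3")
        assert len(tf) == 40
        n_obs = sum(1 for _, o in tf if o)
        n_cens = sum(1 for _, o in tf if not o)
        assert n_obs + n_cens == 40
        assert all(t == 2400.0 for t, o in tf if not o)

    def test_first_event_start_reported(self):
        table = fifty_locations([10.0, 60.0])
        tf = dict(
            (i, (t, o)) for i, (t, o) in enumerate(first_binding_times(table, "5i3"))
        )
        bound = [t for t, o in tf.values() if o]
        assert bound == [10.0]

    def test_all_censored_gives_zero_amplitude_with_warning(self):
        times = [(2400.0, False)] * 20
        with pytest.warns(UserWarning, match="censored"):
            fit = fit_first_binding(times)
        assert fit.amplitude == 0.0

    def test_pure_exponential_rate_recovery(self, rng):
        k = 0.01
        draws = rng.exponential(1 / k, 500)
        times = [(min(t, 2400.0), t < 2400.0) for t in draws]
        fit = fit_first_binding(times)
        assert fit.converged
        assert fit.rate == pytest.approx(k, abs=3 * (fit.rate_se or 0.002))
        assert fit.amplitude > 0.9

    def test_background_correction_leaves_rate_unbiased(self, rng):
        # specific k=0.005 on top of background k_bg=0.002 estimated from controls
        k, k_bg, T = 0.005, 0.002, 2400.0
        errs = []
        for _ in range(20):
            spec = rng.exponential(1 / k, 300)
            bg = rng.exponential(1 / k_bg, 300)
            first = np.minimum(spec, bg)
            times = [(min(t, T), t < T) for t in first]
            ctrl = [(min(t, T), t < T) for t in rng.exponential(1 / k_bg, 300)]
            fit = fit_first_binding(times, ctrl)
            errs.append(fit.rate - k)
        assert abs(np.mean(errs)) < 3 * np.std(errs) / np.sqrt(len(errs)) + 5e-4


class TestSynergy:
    def freq(self, value, n=100, seed=0):
        """FrequencyResult with per-location counts of the given mean."""
        from cosmos_kinetics import FrequencyResult

        rng = np.random.default_rng(seed)
        counts = rng.poisson(value, n).astype(float)
        counts += value - counts.mean()  # pin the mean exactly
        return FrequencyResult(
            f_specific=value,
            se=0.0,
            rna_intercept=value,
            ctrl_intercept=0.0,
            rna_counts=counts,
            ctrl_counts=np.zeros(n),
        )

    def test_additivity_null_is_one(self):
        r = synergy_ratio(self.freq(0.2, seed=1), self.freq(0.1, seed=2),
                          self.freq(0.1, seed=3), n_bootstrap=200)
        assert r.ratio == pytest.approx(1.0)

    def test_ratio_arithmetic(self):
        r = synergy_ratio(self.freq(0.4, seed=1), self.freq(0.1, seed=2),
                          self.freq(0.1, seed=3), n_bootstrap=200)
        assert r.ratio == pytest.approx(2.0)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError, match="denominator|sum <= 0"):
            synergy_ratio(self.freq(0.4), self.freq(0.0), self.freq(0.0))


class TestRetention:
    def test_no_loss_curve_is_one(self):
        panel = simulate_intron_loss_panel(
            200, loss_rate=0.0, intron_bleach_rate=0.0, exon_loss_rate=0.0, seed=1
        )
        curve = intron_retention_curve(panel)
        assert np.allclose(curve.fraction_remaining, 1.0)
        assert curve.fraction_remaining[0] == 1.0

    def test_counting_example_two_of_ten_lost(self):
        from cosmos_kinetics import SplicingTimeline

        panel = [
            SplicingTimeline(f"m{i}", 2400.0, 500.0 if i < 2 else None, True)
            for i in range(10)
        ]
        curve = intron_retention_curve(panel)
        assert curve.fraction_remaining[-1] == pytest.approx(0.8)
        assert curve.n == 10

    def test_exon_dye_losers_excluded_from_n(self):
        from cosmos_kinetics import SplicingTimeline

        panel = [SplicingTimeline(f"m{i}", 2400.0, None, True) for i in range(5)]
        panel += [SplicingTimeline("gone", 100.0, 50.0, True)]
        curve = intron_retention_curve(panel)
        assert curve.n == 5
        assert np.allclose(curve.fraction_remaining, 1.0)

    def test_empty_conditioning_set_rejected(self):
        from cosmos_kinetics import SplicingTimeline

        panel = [SplicingTimeline("m", 10.0, None, True)]
        with pytest.raises(ValueError, match="exon dye"):
            intron_retention_curve(panel)

    def test_curve_non_increasing(self):
        panel = simulate_intron_loss_panel(2000, atp=True, seed=3)
        curve = intron_retention_curve(panel)
        assert (np.diff(curve.fraction_remaining) <= 1e-12).all()


class TestRastergram:
    def test_percent_bound_counting(self):
        dwells = {f"r_{i:02d}": [30.0] if i < 20 else [] for i in range(50)}
        table = make_table(dwells, {k: "5i3" for k in dwells})
        r = build_rastergram(table, "5i3")
        assert r.percent_bound == pytest.approx(40.0)
        assert r.n == 50

    def test_never_bound_rows_first_then_latest_to_earliest(self):
        dwells = {"a": [10.0], "b": [], "c": [5.0]}
        table = make_table(dwells, {k: "5i3" for k in dwells}, start=0.0)
        # 'a' first binds at 0.0; 'c' at 0.0 too -> tie broken by id; all after 'b'
        r = build_rastergram(table, "5i3")
        order = [lid for lid, _ in r.rows]
        assert order[0] == "b"
        assert set(order[1:]) == {"a", "c"}

    def test_row_order_invariant_under_input_shuffling(self, rng):
        dwells = {f"r_{i}": [float(10 + i)] for i in range(10)}
        table = make_table(dwells, {k: "5i3" for k in dwells})
        r1 = build_rastergram(table, "5i3")
        shuffled = list(table.intervals)
        rng.shuffle(shuffled)
        from cosmos_kinetics import IntervalsTable

        table2 = IntervalsTable(
            shuffled, table.metadata.sample(frac=1.0, random_state=3), table.schedule
        )
        r2 = build_rastergram(table2, "5i3")
        assert [lid for lid, _ in r1.rows] == [lid for lid, _ in r2.rows]


class TestFrequencyOccupancyRatio:
    def test_unit_conventions_consistent(self):
        from cosmos_kinetics import FrequencyResult, OccupancyResult

        freq = FrequencyResult(
            f_specific=2.4, se=0.1, rna_intercept=2.5, ctrl_intercept=0.1,
            observed_duration=2400.0,
        )
        occ = OccupancyResult(0.2, 0.0, 0.2)
        ratio = frequency_occupancy_ratio(freq, occ)
        assert ratio["per_experiment"] == pytest.approx(12.0)
        assert ratio["per_second"] == pytest.approx(12.0 / 2400.0)
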