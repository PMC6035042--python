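"""Simulator unit tests: layouts, renewal kinetics, discretization, splicing."""

import numpy as np
import pytest
from scipy import stats as sps

from cosmos_kinetics import (
    AcquisitionSchedule,
    ConstructSpec,
    FIVE_I_THREE,
    KineticModelParams,
    NO_RNA,
    build_slide_layout,
    discretize_timeline,
    simulate_intron_loss_panel,
    simulate_location_timeline,
    simulate_panel,
)
from cosmos_kinetics.constructs import double_5ss_panel
from cosmos_kinetics.simulate import TrueTimeline, location_seed


class TestConstructFlags:
    def test_no_rna_name_reserved_for_all_false_flags(self):
        with pytest.raises(ValueError):
            ConstructSpec("no_RNA", upstream_5ss_functional=True)

    @pytest.mark.parametrize(
        "up,down,expected_multiple",
        [(False, False, 0.0), (True, False, 1.0), (False, True, 1.0), (True, True, 6.0)],
    )
    def test_association_rate_resolves_from_5ss_flags(self, up, down, expected_multiple):
        params = KineticModelParams(k_assoc_specific=1e-3, synergy_factor=3.0)
        c = ConstructSpec("c", up, down, bs_3ss_functional=True)
        assert params.effective_association_rate(c) == pytest.approx(
            1e-3 * expected_multiple
        )

    def test_branch_site_mutation_zeroes_rate_when_required(self):
        params = KineticModelParams(requires_branch_site=True)
        c = ConstructSpec("c", True, True, bs_3ss_functional=False)
        assert params.effective_association_rate(c) == 0.0

    def test_override_wins_over_flag_logic(self):
        params = KineticModelParams(k_assoc_overrides=(("c", 0.123),))
        c = ConstructSpec("c")
        assert params.effective_association_rate(c) == 0.123


class TestSlideLayout:
    def test_deterministic_under_fixed_seed(self):
        counts = {"5i3": 50, "3e5": 50}
        a = build_slide_layout(counts, n_controls=50, seed=7)
        b = build_slide_layout(counts, n_controls=50, seed=7)
        assert len(a.locations) == 150
        assert len({lid for lid, *_ in a.locations}) == 150
        assert a.locations == b.locations

    def test_density_above_bound_rejected(self):
        with pytest.raises(ValueError, match="density"):
            build_slide_layout(
                {"x": 10_000}, field_size=(100.0, 100.0), n_controls=0
            )

    def test_density_driven_totals(self):
        layout = build_slide_layout(
            {"a": 1, "b": 1}, field_size=(100.0, 100.0), density=0.3, seed=3
        )
        assert len(layout.locations) == pytest.approx(3000, abs=2)
        assert layout.density == pytest.approx(0.3, rel=0.01)

    def test_minimum_separation_respected(self):
        layout = build_slide_layout({"a": 200}, n_controls=50, seed=1)
        pts = layout.positions()
        d = np.sqrt(((pts[None] - pts[:, None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 0.8


class TestLocationTimeline:
    def test_zero_rates_give_empty_event_list(self, schedule):
        params = KineticModelParams(k_assoc_specific=0.0, k_assoc_nonspecific=0.0)
        tl = simulate_location_timeline(FIVE_I_THREE, params, schedule, seed=1)
        assert tl.events == []

    def test_labeling_fraction_zero_marks_all_unlabeled(self, schedule):
        params = KineticModelParams(labeling_fraction=0.0)
        tl = simulate_location_timeline(FIVE_I_THREE, params, schedule, seed=2)
        assert tl.events and all(not e.labeled for e in tl.events)

    def test_renewal_event_count_matches_theory(self, schedule):
        # waiting 1/k = 100 s alternating with mean dwell 20 s:
        # expected events per 2,400 s approx 2400 / 120 = 20
        params = KineticModelParams(
            k_assoc_specific=0.01,
            dwell_mixture=((1.0, 20.0),),
            k_assoc_nonspecific=0.0,
            labeling_fraction=1.0,
            bleach_rate=0.0,
            frac_active=1.0,
        )
        counts = [
            len(simulate_location_timeline(FIVE_I_THREE, params, schedule, seed=s).events)
            for s in range(1000)
        ]
        mean, sem = np.mean(counts), sps.sem(counts)
        assert abs(mean - 20.0) < 3 * sem + 0.25  # renewal edge effects O(1/2 cycle)

    def test_dwell_mixture_distribution_recovered(self, schedule):
        params = KineticModelParams(
            k_assoc_specific=0.02,
            dwell_mixture=((0.6, 5.0), (0.4, 80.0)),
            k_assoc_nonspecific=0.0,
            labeling_fraction=1.0,
            bleach_rate=0.0,
            frac_active=1.0,
        )
        dwells = []
        for s in range(300):
            tl = simulate_location_timeline(FIVE_I_THREE, params, schedule, seed=s)
            dwells += [
                e.departure - e.arrival
                for e in tl.events
                if e.departure < schedule.total_duration  # drop censored
            ]
        cdf = lambda t: 1 - 0.6 * np.exp(-np.asarray(t) / 5.0) - 0.4 * np.exp(
            -np.asarray(t) / 80.0
        )
        stat = sps.ks_1samp(dwells, cdf).statistic
        assert len(dwells) > 3000 and stat < 0.03

    def test_bleaching_accrues_only_during_green_frames(self):
        sched = AcquisitionSchedule()
        # dose of 100 s of green reaches wall time 100 s (first block is green)
        assert sched.wall_time_for_green_exposure(100.0) == pytest.approx(100.0, abs=1e-3)
        # beyond one block the red interleave adds wall time without dose
        assert sched.wall_time_for_green_exposure(150.0) == pytest.approx(151.0, abs=1e-3)


class TestDiscretize:
    def test_event_spanning_three_frames(self, schedule):
        tl = TrueTimeline("x", [])
        from cosmos_kinetics.simulate import BindingEvent

        tl.events.append(BindingEvent(10.0, 13.0, labeled=True, specific=True))
        tr = discretize_timeline(tl, schedule)
        assert list(np.flatnonzero(tr.present)) == [10, 11, 12]

    def test_event_inside_red_frame_invisible(self, schedule):
        from cosmos_kinetics.simulate import BindingEvent

        # frame 100 is the red interleave of the first block
        tl = TrueTimeline("x", [BindingEvent(100.1, 100.9, True, True)])
        tr = discretize_timeline(tl, schedule)
        assert not tr.present.any()
        assert tr.missing[100]

    def test_empty_timeline_all_absent_with_missing_flagged(self, schedule):
        tr = discretize_timeline(TrueTimeline("x", []), schedule)
        assert not tr.present.any()
        assert tr.missing.sum() == schedule.n_frames - schedule.n_green_frames()

    def test_half_frame_overlap_rule(self, schedule):
        from cosmos_kinetics.simulate import BindingEvent

        # 0.4 s within frame 10 only: below the 50% rule
        tr = discretize_timeline(
            TrueTimeline("x", [BindingEvent(10.3, 10.7, True, True)]), schedule
        )
        assert not tr.present.any()


class TestPanel:
    def test_identical_seeds_identical_traces(self, schedule, default_params):
        layout = build_slide_layout({"5i3": 10}, n_controls=5, seed=3)
        a = simulate_panel(layout, default_params, schedule, 5, [FIVE_I_THREE])
        b = simulate_panel(layout, default_params, schedule, 5, [FIVE_I_THREE])
        for lid in a.traces:
            assert np.array_equal(a.traces[lid].present, b.traces[lid].present)

    def test_no_rna_locations_have_only_nonspecific_events(self, two_construct_panel):
        for lid, name, *_ in two_construct_panel.layout.locations:
            if name == NO_RNA:
                assert all(
                    not e.specific for e in two_construct_panel.timelines[lid].events
                )

    def test_location_streams_independent_of_iteration_order(
        self, schedule, default_params
    ):
        # a location's draw depends only on (master seed, location id)
        big = build_slide_layout({"5i3": 10}, n_controls=5, seed=3)
        small_locs = [loc for loc in big.locations[5:]]
        from cosmos_kinetics.simulate import SlideLayout

        small = SlideLayout(small_locs, big.field_size, big.density)
        a = simulate_panel(big, default_params, schedule, 5, [FIVE_I_THREE])
        b = simulate_panel(small, default_params, schedule, 5, [FIVE_I_THREE])
        for lid in b.traces:
            assert np.array_equal(a.traces[lid].present, b.traces[lid].present)

    def test_synergy_panel_rank_ordering_of_u2_counts(self, schedule):
        params = KineticModelParams(
            k_assoc_specific=1e-3,
            synergy_factor=3.0,
            labeling_fraction=1.0,
            bleach_rate=0.0,
            frac_active=1.0,
            k_assoc_nonspecific=1e-4,
        )
        panel = double_5ss_panel()
        layout = build_slide_layout(
            {c.name: 60 for c in panel}, n_controls=60, seed=9
        )
        data = simulate_panel(layout, params, schedule, seed=9, panel=panel)
        counts = data.visible_event_counts()
        mean = {
            name: counts[[lid for lid, n, *_ in layout.locations if n == name]].mean()
            for name in [c.name for c in panel] + [NO_RNA]
        }
        assert mean["5i3e5"] > mean["Xi3e5"]
        assert mean["5i3e5"] > mean["5i3eX"]
        assert mean["Xi3e5"] > mean["Xi3eX"] * 1.5
        assert mean["Xi3eX"] == pytest.approx(mean[NO_RNA], abs=0.5)

    def test_doubling_labeling_fraction_doubles_visible_events(self, schedule):
        def mean_visible(lf, seed0):
            params = KineticModelParams(
                k_assoc_specific=2e-3, labeling_fraction=lf, bleach_rate=0.0
            )
            layout = build_slide_layout({"5i3": 100}, n_controls=1, seed=1)
            data = simulate_panel(layout, params, schedule, seed0, [FIVE_I_THREE])
            c = data.visible_event_counts()
            return c[[lid for lid in c.index if lid.startswith("5i3")]].mean()

        m1, m2 = mean_visible(0.25, 21), mean_visible(0.5, 22)
        assert m2 / m1 == pytest.approx(2.0, rel=0.2)

    def test_control_counts_insensitive_to_specific_parameters(self, schedule):
        # no-RNA event counts depend only on the nonspecific parameters
        def control_counts(k_spec, seeds):
            out = []
            params = KineticModelParams(k_assoc_specific=k_spec)
            layout = build_slide_layout({"5i3": 5}, n_controls=15, seed=2)
            for s in seeds:
                data = simulate_panel(layout, params, schedule, s, [FIVE_I_THREE])
                c = data.visible_event_counts()
                out += list(c[[l for l in c.index if l.startswith(NO_RNA)]])
            return out

        a = control_counts(1e-4, range(20))
        b = control_counts(5e-3, range(100, 120))
        assert sps.mannwhitneyu(a, b).pvalue > 0.01


class TestIntronLoss:
    def test_no_atp_loss_matches_bleach_only_prediction(self):
        panel = simulate_intron_loss_panel(
            20_000, atp=False, exon_loss_rate=0.0, seed=4
        )
        lost = sum(1 for m in panel if m.intron_loss_time is not None)
        expected = 1 - np.exp(-4.6e-6 * 2400)  # ~1.1%
        assert lost / len(panel) == pytest.approx(expected, abs=0.003)

    def test_zero_rate_infinite_lag_no_loss(self):
        panel = simulate_intron_loss_panel(
            500, loss_rate=0.0, intron_bleach_rate=0.0, exon_loss_rate=0.0, seed=5
        )
        assert all(m.intron_loss_time is None for m in panel)

    def test_lag_exponential_closed_form(self):
        # lag 600 s, rate 1/600: P(lost by 2400) = 1 - exp(-1800/600) = 0.95
        panel = simulate_intron_loss_panel(
            10_000,
            loss_lag=600.0,
            loss_rate=1 / 600.0,
            frac_spliceable=1.0,
            exon_loss_rate=0.0,
            intron_bleach_rate=0.0,
            seed=6,
        )
        lost = sum(1 for m in panel if m.intron_loss_time is not None)
        assert lost / len(panel) == pytest.approx(1 - np.exp(-3.0), abs=0.01)


def test_location_seed_streams_are_distinct():
    a = location_seed(1, "loc_a").generate_state(4)
    b = location_seed(1, "loc_b").generate_state(4)
    c = location_seed(2, "loc_a").generate_state(4)
    assert not np.array_equal(a, b) and not np.array_equal(a, c)
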