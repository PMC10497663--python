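import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duosync import coordination as coord
from duosync.tempo import BandSpec, BeatTrack
from duosync.xwt import ScaleGrid, XwtField, cross_wavelet, time_average_power


def band(level, lo, hi, center=None):
    return BandSpec(level=level, period_low_s=lo, period_high_s=hi,
                    center_s=center if center is not None else (lo + hi) / 2)


def make_field(power, phase=None, times=None, periods=None):
    nper, nt = power.shape
    return XwtField(
        times_s=np.arange(nt, dtype=float) if times is None else times,
        periods_s=np.geomspace(1, 16, nper) if periods is None else periods,
        power=power,
        phase_rad=np.zeros_like(power) if phase is None else phase,
        coi_s=np.full(nt, np.inf),
    )


class TestFindTopPeaks:
    def test_monotone_curve_has_no_peaks(self):
        periods = np.geomspace(1, 8, 10)
        assert coord.find_top_peaks(periods, np.arange(10.0)) == []

    def test_single_interior_peak(self):
        periods = np.array([1.0, 2.0, 4.0])
        assert coord.find_top_peaks(periods, np.array([1.0, 5.0, 2.0])) == [(2.0, 5.0)]

    def test_plateau_takes_leftmost_index(self):
        periods = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        peaks = coord.find_top_peaks(periods, np.array([0.0, 2.0, 2.0, 2.0, 0.0]))
        assert peaks == [(2.0, 2.0)]

    def test_power_ties_rank_longer_period_first(self):
        periods = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        peaks = coord.find_top_peaks(periods, np.array([0.0, 3.0, 0.0, 3.0, 0.0]), k=1)
        assert peaks == [(4.0, 3.0)]

    def test_endpoints_never_peak(self):
        periods = np.array([1.0, 2.0, 3.0])
        assert coord.find_top_peaks(periods, np.array([5.0, 1.0, 7.0])) == []

    def test_planted_components_found_in_amplitude_order(self):
        # two shared sinusoids with 2:1 amplitudes at 4 s and 8 s
        fs = 16.0
        t = np.arange(0.0, 256.0, 1 / fs)
        from duosync.kinematics import SpeedSeries

        vals = 10 + 4 * np.sin(2 * np.pi * t / 4) + 2 * np.sin(2 * np.pi * t / 8)
        x = SpeedSeries("pianist", "front_head", fs, vals)
        y = SpeedSeries("singer", "front_head", fs, vals)
        grid = ScaleGrid.from_range(1.0, 16.0)
        field = cross_wavelet(x, y, grid)
        curve = time_average_power(field)
        peaks = coord.find_top_peaks(grid.periods_s, curve, k=2)
        assert len(peaks) == 2
        assert abs(np.log2(peaks[0][0] / 4.0)) <= 2 * grid.dj
        assert abs(np.log2(peaks[1][0] / 8.0)) <= 2 * grid.dj


class TestPeakOccurrence:
    def test_all_inside_one_band(self):
        bands = [band("two", 3.0, 5.0)]
        table = coord.tabulate_peak_occurrence([[(4.0, 1.0)]] * 3, [bands] * 3)
        row = table.set_index("level").loc["two"]
        assert row["count"] == 3 and row["percentage"] == 100.0

    def test_half_outside(self):
        bands = [band("two", 3.0, 5.0)]
        table = coord.tabulate_peak_occurrence(
            [[(4.0, 1.0), (10.0, 0.5)]], [bands]
        )
        by = table.set_index("level")
        assert by.loc["two", "percentage"] == 50.0
        assert by.loc["outside", "percentage"] == 50.0

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0.5, 20), min_size=1, max_size=10))
    def test_percentages_sum_to_100(self, periods):
        bands = [band("half", 1, 2), band("one", 2.5, 4), band("two", 5, 8)]
        table = coord.tabulate_peak_occurrence(
            [[(p, 1.0) for p in periods]], [bands]
        )
        assert table["percentage"].sum() == pytest.approx(100.0, abs=0.1)


class TestBandAggregate:
    def test_constant_phase(self):
        power = np.ones((5, 10))
        phase = np.full((5, 10), np.pi / 4)
        field = make_field(power, phase)
        agg = coord.band_aggregate(field, band("one", 1.0, 16.0, center=4.0))
        assert agg.mean_phase_rad == pytest.approx(np.pi / 4)
        assert agg.resultant_length == pytest.approx(1.0)
        assert agg.mean_power == pytest.approx(1.0)

    def test_uniform_phases_give_null_resultant(self):
        n = 360
        phase = np.linspace(-np.pi, np.pi, n, endpoint=False) + np.pi / n
        field = make_field(np.ones((1, n)), phase[None, :], periods=np.array([4.0]))
        agg = coord.band_aggregate(field, band("one", 3.0, 5.0, center=4.0))
        assert agg.resultant_length == pytest.approx(0.0, abs=1e-10)

    def test_lagged_sinusoids_recover_lag(self, speed_pair):
        P, tau = 8.0, 1.0
        x, y = speed_pair(period_s=P, tau_s=tau)
        grid = ScaleGrid.from_range(2.0, 32.0)
        field = cross_wavelet(x, y, grid)
        agg = coord.band_aggregate(field, band("one", P * 2**-0.25, P * 2**0.25, center=P))
        assert agg.mean_phase_rad == pytest.approx(2 * np.pi * tau / P, rel=0.05)
        assert agg.phase_ms == pytest.approx(1000 * tau, rel=0.06)
        assert agg.leadership == "pianist_leads"

    def test_band_outside_grid_rejected(self):
        field = make_field(np.ones((3, 4)), periods=np.array([1.0, 2.0, 4.0]))
        with pytest.raises(ValueError, match="overlap"):
            coord.band_aggregate(field, band("four", 30.0, 40.0))


class TestDominantLevel:
    def agg(self, level, power):
        return coord.BandAggregate(level, power, 0.0, 1.0, 0.0, "in_sync", "in_phase")

    def test_strongest_band_wins(self):
        aggs = [self.agg(lv, p) for lv, p in
                zip(("half", "one", "two", "three", "four"), (5, 3, 1, 1, 1))]
        assert coord.dominant_level(aggs) == "half"

    def test_tie_breaks_to_shorter_period(self):
        aggs = [self.agg("two", 2.0), self.agg("half", 2.0), self.agg("four", 1.0)]
        assert coord.dominant_level(aggs) == "half"


class TestPhaseScheme:
    @pytest.mark.parametrize(
        "phi, leadership, regime",
        [
            (np.pi / 4, "pianist_leads", "in_phase"),
            (-3 * np.pi / 4, "pianist_leads", "out_of_phase"),
            (0.0, "in_sync", "in_phase"),
            (3 * np.pi / 4, "singer_leads", "out_of_phase"),
            (-np.pi / 4, "singer_leads", "in_phase"),
            (np.pi, "singer_leads", "out_of_phase"),
            (np.pi / 2, "singer_leads", "out_of_phase"),
            (-np.pi / 2, "singer_leads", "out_of_phase"),
        ],
    )
    def test_quadrants(self, phi, leadership, regime):
        assert coord.phase_to_leadership(phi) == (leadership, regime)

    def test_mirror_swaps_leader(self):
        rng = np.random.default_rng(4)
        swap = {"pianist_leads": "singer_leads", "singer_leads": "pianist_leads"}
        for phi in rng.uniform(-np.pi, np.pi, 200):
            if min(abs(abs(phi) - b) for b in (0.0, np.pi / 2, np.pi)) < 1e-9:
                continue
            lead, _ = coord.phase_to_leadership(phi)
            mirrored, _ = coord.phase_to_leadership(-phi)
            assert mirrored == swap[lead]

    @pytest.mark.parametrize(
        "phi, period, ms",
        [(-np.pi / 2, 4.0, -1000.0), (0.0, 17.3, 0.0), (np.pi, 2.0, 1000.0)],
    )
    def test_phase_to_ms(self, phi, period, ms):
        assert coord.phase_to_ms(phi, period) == pytest.approx(ms)


class TestSegmentAggregate:
    def setup_method(self):
        rng = np.random.default_rng(8)
        nt = 100
        self.power = rng.uniform(0, 1, (3, nt))
        self.field = make_field(self.power, periods=np.array([2.0, 4.0, 8.0]),
                                times=np.linspace(0, 9.9, nt))
        self.track = BeatTrack(np.arange(11), np.arange(11.0))
        self.bands = [band("one", 3.0, 5.0, center=4.0)]

    def sections(self, specs):
        from duosync.io_config import SectionAnnotation

        return [SectionAnnotation(*s) for s in specs]

    def test_whole_take_section_equals_unmasked(self):
        secs = self.sections([("A", 0, 11, False)])
        table = coord.segment_aggregate(self.field, self.bands, secs, self.track)
        full = coord.band_aggregate(self.field, self.bands[0])
        row = table[table.segment == "A"].iloc[0]
        assert row["mean_power"] == pytest.approx(full.mean_power)

    def test_complementary_sections_combine_with_duration_weights(self):
        secs = self.sections([("A", 0, 5, False), ("B", 5, 11, False)])
        table = coord.segment_aggregate(self.field, self.bands, secs, self.track)
        full = coord.band_aggregate(self.field, self.bands[0])
        a = table[table.segment == "A"].iloc[0]
        b = table[table.segment == "B"].iloc[0]
        na = (self.field.times_s < 5.0).sum()
        nb = len(self.field.times_s) - na
        combined = (na * a["mean_power"] + nb * b["mean_power"]) / (na + nb)
        assert combined == pytest.approx(full.mean_power)

    def test_component_only_in_together_sections_boosts_together_power(self):
        from duosync.kinematics import SpeedSeries
        from duosync.synthetic_data import PlantedComponent, gen_duo_motion
        from duosync.tempo import PhraseLevelSet
        from duosync.xwt import ScaleGrid

        levels = PhraseLevelSet({"half": 1, "one": 2, "two": 4, "three": 6, "four": 8})
        comp = PlantedComponent("one", 8.0, 0.0, time_support=(30.0, 60.0))
        pianist, singer, _ = gen_duo_motion(60.0, 20.0, levels, [comp], 1, 0.0, 0)
        from duosync.kinematics import traj_speed

        field = cross_wavelet(
            traj_speed(pianist[0]), traj_speed(singer[0]),
            ScaleGrid.from_range(0.5, 10.0),
        )
        track = BeatTrack(np.arange(61), np.arange(61.0))
        secs = self.sections([("solo", 0, 30, True), ("together", 30, 60, False)])
        bands = [band("one", 1.7, 2.4, center=2.0)]
        table = coord.segment_aggregate(field, bands, secs, track)
        solo = table[table.segment == "solo"].iloc[0]["mean_power"]
        together = table[table.segment == "together"].iloc[0]["mean_power"]
        assert together > solo

    def test_empty_section_mask_names_section(self):
        secs = self.sections([("Z", 0, 5, True), ("rest", 5, 11, False)])
        late_field = make_field(self.power[:, :5], periods=np.array([2.0, 4.0, 8.0]),
                                times=np.linspace(100, 101, 5))
        with pytest.raises(ValueError, match="'Z'"):
            coord.segment_aggregate(late_field, self.bands, secs, self.track)
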