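"""Two-color gating: background estimation, percent-positive, MFI, dot plots."""

import numpy as np
import pytest

from conftest import make_kymograph
from ivfc.core import CellEvent
from ivfc.exceptions import ConfigError, DataError
from ivfc.segmentation import detect_cells, events_to_mask, fit_threshold
from ivfc.simulate import SimulationParams, simulate_record
from ivfc.twocolor import (
    GateConfig,
    detect_reporter_negative,
    dotplot_table,
    estimate_background,
    gate_events,
    gate_threshold,
    quadrant_counts,
)


def _event(reporter=200.0, antibody=120.0, line=10):
    return CellEvent(bbox=(line, line + 5, 5, 15), d_um=6.0, t_ms=6.0,
                     v_um_s=1000.0, centroid=(line + 2.5, 10.0),
                     mean_intensity={"reporter": reporter, "antibody": antibody},
                     max_intensity={"reporter": reporter, "antibody": antibody})


class TestEstimateBackground:
    def test_constant_background(self):
        kymo = make_kymograph(np.full((100, 64), 100.0),
                              channel_names=("antibody",))
        mask = np.zeros((100, 64), dtype=bool)
        mean, sd = estimate_background(kymo, "antibody", mask)
        assert (mean, sd) == (100.0, 0.0)

    def test_full_mask_rejected(self):
        kymo = make_kymograph(np.full((100, 64), 100.0),
                              channel_names=("antibody",))
        with pytest.raises(DataError):
            estimate_background(kymo, "antibody", np.ones((100, 64), dtype=bool))

    def test_recovers_simulated_plasma_background_within_1pct(self):
        params = SimulationParams(seed=5, T_s=5.0, scan_rate_hz=650.0,
                                  n_pixels=64, pixel_size_um=0.8,
                                  concentration_per_ml=2e6, two_color=True)
        kymo, truth = simulate_record(params)
        state = fit_threshold(kymo.channel("reporter"))
        events = detect_cells(kymo, "reporter", state.base_threshold)
        mask = events_to_mask(events, kymo.channel("antibody").shape, dilate_px=3)
        center = kymo.metadata.n_pixels // 2
        half = int(params.D_um / params.pixel_size_um / 2)
        mean, sd = estimate_background(
            kymo, "antibody", mask, px_bounds=(center - half, center + half))
        assert mean == pytest.approx(params.antibody_plasma_level, rel=0.01)


class TestGateEvents:
    def test_threshold_arithmetic(self):
        assert gate_threshold(GateConfig(k=3.0), (100.0, 10.0)) == 130.0
        assert gate_threshold(GateConfig(mode="fixed", fixed_threshold=42.0),
                              (0.0, 0.0)) == 42.0

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            GateConfig(mode="fixed")
        with pytest.raises(ConfigError):
            GateConfig(k=-1.0)
        with pytest.raises(ConfigError):
            GateConfig(mode="beads")

    def test_all_below_threshold(self):
        events = [_event(antibody=100.0 + i) for i in range(5)]
        res = gate_events(events, GateConfig(k=3.0), (100.0, 10.0))
        assert res.n_positive == 0
        assert res.fraction_positive == 0.0
        assert res.mfi >= 0.0

    def test_missing_channel_rejected(self):
        ev = CellEvent(bbox=(0, 2, 0, 2), d_um=1.0, t_ms=1.0, v_um_s=1000.0,
                       centroid=(1.0, 1.0), mean_intensity={"reporter": 1.0},
                       max_intensity={"reporter": 1.0})
        with pytest.raises(DataError):
            gate_events([ev], GateConfig(), (0.0, 1.0))

    def test_gate_monotone_in_k(self):
        rng = np.random.default_rng(7)
        events = [_event(antibody=float(a)) for a in rng.normal(140, 30, 200)]
        background = (100.0, 10.0)
        counts = [gate_events(events, GateConfig(k=k), background).n_positive
                  for k in (1.0, 2.0, 3.0, 4.0, 6.0)]
        assert counts == sorted(counts, reverse=True)

    def test_mfi_is_background_subtracted(self):
        events = [_event(antibody=250.0)] * 4
        res = gate_events(events, GateConfig(k=3.0), (100.0, 10.0))
        assert res.mfi == pytest.approx(150.0)
        assert res.fraction_positive == 1.0


class TestMixtureRecovery:
    def test_mfi_and_fraction_recovered_from_simulation(self):
        params = SimulationParams(seed=9, T_s=20.0, scan_rate_hz=650.0,
                                  n_pixels=64, pixel_size_um=0.8,
                                  concentration_per_ml=3e6, two_color=True,
                                  positive_fraction=0.5, avoid_overlap=True)
        kymo, truth = simulate_record(params)
        state = fit_threshold(kymo.channel("reporter"))
        events = detect_cells(kymo, "reporter", state.base_threshold)
        assert len(events) >= 50
        mask = events_to_mask(events, kymo.channel("antibody").shape, dilate_px=3)
        center = kymo.metadata.n_pixels // 2
        half = int(params.D_um / params.pixel_size_um / 2)
        background = estimate_background(kymo, "antibody", mask,
                                         px_bounds=(center - half, center + half))
        res = gate_events(events, GateConfig(k=3.0), background)
        true_frac = truth.events["antibody_positive"].mean()
        assert res.fraction_positive == pytest.approx(true_frac, abs=0.08)


class TestDotplot:
    def test_rows_equal_component_means(self):
        events = [_event(reporter=10.0 * i, antibody=5.0 * i) for i in range(1, 4)]
        table = dotplot_table(events)
        assert len(table) == 3
        assert list(table["reporter_intensity"]) == [10.0, 20.0, 30.0]
        assert list(table["antibody_intensity"]) == [5.0, 10.0, 15.0]

    def test_quadrants_partition(self):
        rng = np.random.default_rng(3)
        events = [_event(reporter=float(r), antibody=float(a))
                  for r, a in rng.uniform(0, 300, size=(57, 2))]
        table = dotplot_table(events)
        counts = quadrant_counts(table, 150.0, 150.0)
        assert sum(counts.values()) == 57

    def test_secondary_pass_finds_reporter_negative_cells(self):
        params = SimulationParams(seed=13, T_s=10.0, scan_rate_hz=650.0,
                                  n_pixels=64, pixel_size_um=0.8,
                                  concentration_per_ml=2e6, two_color=True,
                                  reporter_fraction=0.5, positive_fraction=0.8,
                                  avoid_overlap=True)
        kymo, truth = simulate_record(params)
        state = fit_threshold(kymo.channel("reporter"))
        primary = detect_cells(kymo, "reporter", state.base_threshold)
        from ivfc.segmentation import measure_vessel_diameter
        vessel = measure_vessel_diameter(kymo)
        secondary = detect_reporter_negative(kymo, primary, vessel=vessel)
        n_neg_true = int((~truth.events.reporter_positive
                          & truth.events.antibody_positive).sum())
        assert len(primary) == int(truth.events.reporter_positive.sum())
        assert len(secondary) == pytest.approx(n_neg_true, abs=2)
        assert all(ev.source_channel == "antibody" for ev in secondary)
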