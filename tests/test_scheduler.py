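"""Gated-schedule simulation: counters, reacquisition, scan-time statistics."""

import numpy as np
import pytest
from conftest import replay_splicer

from splicersim import (
    GateParams,
    RespModel,
    ScanConfig,
    ZERO_GATE,
    completion_overhead,
    empty_trace,
    generate_trace,
    run_splicer,
    run_triggered,
    run_ungated,
    scan_time_stats,
    subseed,
    unavailable_intervals,
)
from splicersim.scheduler import ACQUIRED, DISCARDED, DUMMY, EventLog


class TestUngated:
    def test_rare_scan_arithmetic(self):
        # 128 phase encodes in trains of 8 at TR 2 s: 16 shots, 32 s
        cfg = ScanConfig(tr=2.0, n_slices=24, n_pe=128, etl=8)
        log = run_ungated(cfg)
        assert cfg.shots_per_slice == 16
        assert log.scan_time == pytest.approx(32.0)
        assert len(log.events) == 24 * 16

    def test_single_event_scan(self):
        cfg = ScanConfig(tr=1.5, n_slices=1, n_pe=1, etl=1)
        log = run_ungated(cfg)
        assert len(log.events) == 1
        assert log.events[0].time == 0.0
        assert log.scan_time == pytest.approx(1.5)

    def test_event_count_scales_with_repeats(self):
        cfg = ScanConfig(tr=1.0, n_slices=3, n_pe=8, etl=2)
        log = run_ungated(cfg, n_repeats=5)
        assert len(log.events) == 5 * 3 * 4
        assert log.scan_time == pytest.approx(5 * 4 * 1.0)


class TestSplicer:
    def test_breath_free_trace_reduces_to_ungated(self, rare_config):
        a = run_splicer(rare_config, empty_trace(1000.0), ZERO_GATE)
        b = run_ungated(rare_config)
        assert a.events == b.events
        assert a.scan_time == b.scan_time
        assert a.completed and b.completed
        np.testing.assert_array_equal(a.per_slice_shots_kept, b.per_slice_shots_kept)

    def test_constant_tr_for_every_slice(self, rare_config):
        model = RespModel(mu=1.5, sigma=0.15, breath_duration=0.5)
        trace = generate_trace(model, 2000.0, seed=13)
        gate = GateParams(0.05, 0.15, 0.15)
        log = run_splicer(rare_config, trace, gate)
        assert log.completed
        for s in range(rare_config.n_slices):
            slots = sorted(e.slot for e in log.events if e.slice == s)
            assert set(np.diff(slots).tolist()) == {rare_config.n_slices}
            times = log.slice_excitation_times(s)
            np.testing.assert_allclose(
                np.diff(times), rare_config.tr, rtol=1e-12
            )

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_replay(self, single_slice_config, seed):
        model = RespModel(mu=1.5, sigma=0.15, breath_duration=0.5)
        trace = generate_trace(model, 2500.0, seed=seed)
        gate = GateParams(0.05, 0.1, 0.15)
        log = run_splicer(single_slice_config, trace, gate, start_time=0.25)
        ref_events, ref_kept, ref_done, ref_time = replay_splicer(
            single_slice_config, trace, gate, start_time=0.25
        )
        assert log.completed == ref_done
        assert log.scan_time == ref_time
        assert log.per_slice_shots_kept.tolist() == ref_kept
        assert len(log.events) == len(ref_events)
        for got, exp in zip(log.events, ref_events):
            assert (got.slot, got.slice, got.shot_index, got.status) == (
                exp.slot,
                exp.slice,
                exp.shot_index,
                exp.status,
            )

    def test_multislice_replay_agreement(self, rare_config):
        model = RespModel(mu=1.2, sigma=0.2, breath_duration=0.3)
        for seed in (101, 202, 303):
            trace = generate_trace(model, 1500.0, seed=seed)
            gate = GateParams(0.05, 0.15, 0.15)
            log = run_splicer(rare_config, trace, gate)
            ref_events, ref_kept, ref_done, ref_time = replay_splicer(
                rare_config, trace, gate
            )
            assert log.completed == ref_done
            assert [
                (e.slot, e.slice, e.shot_index, e.status) for e in log.events
            ] == [(e.slot, e.slice, e.shot_index, e.status) for e in ref_events]

    def test_each_shot_kept_exactly_once(self, single_slice_config):
        model = RespModel(mu=1.5, sigma=0.15, breath_duration=0.5)
        trace = generate_trace(model, 2500.0, seed=77)
        log = run_splicer(single_slice_config, trace, GateParams(0.05, 0.1, 0.15))
        kept = [e.shot_index for e in log.kept_events(0)]
        assert sorted(kept) == list(range(128))

    def test_kept_events_avoid_unavailable_windows(self, rare_config):
        model = RespModel(mu=1.3, sigma=0.2, breath_duration=0.3)
        trace = generate_trace(model, 1500.0, seed=5)
        gate = GateParams(0.05, 0.15, 0.2)
        log = run_splicer(rare_config, trace, gate)
        edges = unavailable_intervals(trace, gate).reshape(-1)
        for e in log.kept_events():
            assert np.searchsorted(edges, e.time, side="right") % 2 == 0

    def test_event_conservation_and_time_bound(self, single_slice_config):
        model = RespModel(mu=1.5, sigma=0.15, breath_duration=0.5)
        trace = generate_trace(model, 2500.0, seed=21)
        log = run_splicer(single_slice_config, trace, GateParams(0.0, 0.1, 0.2))
        counts = log.status_counts()
        assert sum(counts.values()) == len(log.events)
        n_slots = max(e.slot for e in log.events) + 1
        assert len(log.events) == n_slots  # one event per slot up to completion
        assert log.scan_time >= single_slice_config.ungated_time()

    def test_loop_cap_flags_incomplete(self):
        # synchronous breathing at a commensurate TR starves the schedule
        cfg = ScanConfig(tr=2.0, n_slices=1, n_pe=8, etl=1, loop_cap_factor=2.0)
        model = RespModel(mu=2.0, sigma=0.0, breath_duration=0.5)
        trace = generate_trace(model, 500.0, seed=0)
        log = run_splicer(cfg, trace, ZERO_GATE, start_time=0.25)
        assert not log.completed
        assert log.per_slice_shots_kept[0] < 8

    def test_synchronous_clean_start_equals_ungated_time(self):
        # every slot lands in the quiet phase: no time is lost
        cfg = ScanConfig(tr=2.0, n_slices=1, n_pe=16, etl=1)
        model = RespModel(mu=2.0, sigma=0.0, breath_duration=0.5)
        trace = generate_trace(model, 200.0, seed=0)
        log = run_splicer(cfg, trace, ZERO_GATE, start_time=1.0)
        assert log.completed
        assert log.scan_time == pytest.approx(cfg.ungated_time())


class TestTriggered:
    def test_deterministic_breathing_gives_constant_realised_tr(self):
        cfg = ScanConfig(tr=2.0, n_slices=2, n_pe=16, etl=1)
        model = RespModel(mu=2.0, sigma=0.0, breath_duration=0.2)
        trace = generate_trace(model, 300.0, seed=0)
        for n in (1, 2):
            log = run_triggered(
                cfg, trace, GateParams(0.05, 0.15, 0.0), intervals_per_tr=n
            )
            assert log.completed
            d = np.diff(log.slice_excitation_times(0))
            np.testing.assert_allclose(d, n * 2.0, rtol=1e-9)

    def test_variable_breathing_gives_variable_tr(self):
        cfg = ScanConfig(tr=2.0, n_slices=2, n_pe=16, etl=1)
        model = RespModel(mu=2.0, sigma=0.2, breath_duration=0.2)
        trace = generate_trace(model, 500.0, seed=3)
        log = run_triggered(cfg, trace, GateParams(0.05, 0.15, 0.0))
        assert log.completed
        assert np.diff(log.slice_excitation_times(0)).std() > 0.01

    def test_kept_shots_complete_on_completion(self):
        cfg = ScanConfig(tr=2.0, n_slices=3, n_pe=12, etl=1)
        model = RespModel(mu=1.4, sigma=0.2, breath_duration=0.25)
        trace = generate_trace(model, 600.0, seed=8)
        log = run_triggered(cfg, trace, GateParams(0.05, 0.1, 0.1))
        assert log.completed
        assert all(k == 12 for k in log.per_slice_shots_kept)
        for s in range(3):
            kept = sorted(e.shot_index for e in log.kept_events(s))
            assert kept == list(range(12))

    def test_full_relaxation_spacing(self):
        cfg = ScanConfig(tr=2.0, n_slices=1, n_pe=8, etl=1)
        model = RespModel(mu=1.5, sigma=0.15, breath_duration=0.2)
        trace = generate_trace(model, 600.0, seed=1)
        log = run_triggered(
            cfg,
            trace,
            GateParams(0.05, 0.15, 0.0),
            intervals_per_tr="full_relaxation",
            t1=1.0,
        )
        assert log.completed
        assert np.diff(log.slice_excitation_times(0)).min() >= 5.0

    def test_blocks_clashing_with_breaths_are_retried(self):
        # block of 4 slices x 0.5 s slot spans past the next breath onset
        cfg = ScanConfig(tr=2.0, n_slices=4, n_pe=8, etl=1)
        model = RespModel(mu=1.0, sigma=0.05, breath_duration=0.3)
        trace = generate_trace(model, 600.0, seed=6)
        log = run_triggered(cfg, trace, GateParams(0.05, 0.1, 0.1))
        counts = log.status_counts()
        assert counts[DISCARDED] > 0
        assert log.completed


class TestMonteCarlo:
    def test_asynchronous_regime_mean_matches_extended_time(self):
        cfg = ScanConfig(tr=2.0, n_slices=1, n_pe=128, etl=1)
        model = RespModel(mu=2.0, sigma=0.2, breath_duration=0.5)
        stats = scan_time_stats(cfg, model, ZERO_GATE, n_repeats=50, seed=2)
        assert stats.n_incomplete == 0
        assert stats.mean / cfg.ungated_time() == pytest.approx(4.0 / 3.0, rel=0.05)
        assert stats.sd > 0

    def test_reproducible_for_fixed_seed(self):
        cfg = ScanConfig(tr=1.0, n_slices=1, n_pe=32, etl=1)
        model = RespModel(mu=1.5, sigma=0.15, breath_duration=0.5)
        a = scan_time_stats(cfg, model, ZERO_GATE, n_repeats=10, seed=5)
        b = scan_time_stats(cfg, model, ZERO_GATE, n_repeats=10, seed=5)
        np.testing.assert_array_equal(a.scan_times, b.scan_times)

    def test_overhead_fraction_decreases_with_lookback(self):
        # low interval variability: reacquisition losses dominate the overhead
        cfg = ScanConfig(tr=2.0, n_slices=1, n_pe=64, etl=1)
        model = RespModel(mu=1.5, sigma=0.08, breath_duration=0.5)
        fracs = [
            completion_overhead(
                cfg,
                model,
                GateParams(0.05, 0.0, lb),
                n_repeats=200,
                seed=4,
            )
            for lb in (0.0, 0.15, 0.3)
        ]
        assert fracs[0] >= fracs[1] >= fracs[2]
        assert fracs[2] < fracs[0]


def test_eventlog_json_round_trip(tmp_path, rare_config):
    model = RespModel(mu=1.5, sigma=0.15, breath_duration=0.3)
    trace = generate_trace(model, 800.0, seed=3)
    log = run_splicer(rare_config, trace, GateParams(0.05, 0.1, 0.1))
    path = tmp_path / "log.json"
    log.to_json(path)
    back = EventLog.from_json(path)
    assert back.events == log.events
    assert back.scan_time == log.scan_time
    assert back.completed == log.completed
    assert back.config == log.config


def test_scan_config_validation():
    with pytest.raises(ValueError):
        ScanConfig(tr=0.0)
    with pytest.raises(ValueError):
        ScanConfig(tr=1.0, n_pe=10, etl=4)
    with pytest.raises(ValueError):
        ScanConfig(tr=1.0, loop_cap_factor=0.5)


def test_subseed_is_deterministic_and_distinct():
    a = np.random.default_rng(subseed(1, 0)).random(3)
    b = np.random.default_rng(subseed(1, 0)).random(3)
    c = np.random.default_rng(subseed(1, 1)).random(3)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, c)
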