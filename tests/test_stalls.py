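"""Stall detection, hypoxia classes, alignment, regression, neighbors."""

import numpy as np
import pandas as pd
import pytest

from stallox import simkit
from stallox.flux import CapillaryTimeSeries
from stallox.stalls import (
    StallComparison,
    align_peri_stall,
    classify_hypoxia,
    detect_stalls,
    fit_stall_vs_tissue,
    neighbor_effects,
    stall_duration_histogram,
)


def series(flux, po2=None, qc=None, cid="cap", dt=8.0, **kw):
    flux = np.asarray(flux, dtype=float)
    n = flux.size
    po2 = np.full(n, 35.0) if po2 is None else np.asarray(po2, dtype=float)
    qc = np.ones(n, dtype=bool) if qc is None else np.asarray(qc, dtype=bool)
    df = pd.DataFrame(
        {
            "visit_index": np.arange(n),
            "visit_time_s": np.arange(n) * dt,
            "po2_mmhg": po2,
            "flux_rbc_s": flux,
            "speed_um_ms": np.nan,
            "qc_pass": qc,
        }
    )
    return CapillaryTimeSeries(cid, df, **kw)


class TestDetect:
    def test_all_flowing_yields_no_events(self):
        assert detect_stalls(series([5, 8, 9, 7])) == []

    def test_two_zero_visits_make_one_event_of_16s(self):
        ev = detect_stalls(series([8, 0, 0, 9]), revisit_interval_s=8.0)
        assert len(ev) == 1
        assert ev[0].start_visit == 1 and ev[0].end_visit == 2
        assert ev[0].duration_s == pytest.approx(16.0)

    def test_runs_separated_by_flowing_visit_are_distinct(self):
        ev = detect_stalls(series([0, 5, 0, 5, 0]))
        assert len(ev) == 3

    def test_qc_failed_visit_breaks_runs_with_flag(self):
        ev = detect_stalls(series([8, 0, 0, 0, 9], qc=[1, 1, 0, 1, 1]))
        assert len(ev) == 2
        assert all("boundary_uncertain" in e.flags for e in ev)

    def test_union_of_events_is_zero_flux_visit_set(self, rng):
        for _ in range(20):
            flux = rng.choice([0.0, 0.0, 5.0, 10.0], size=30)
            ts = series(flux)
            events = detect_stalls(ts)
            covered = sorted(v for e in events for v in e.visit_indices)
            assert covered == sorted(np.flatnonzero(flux == 0.0).tolist())

    def test_simulated_session_events_match_ledger(self, calib):
        from stallox import pipeline
        from stallox.config import RunConfig
        from stallox.records import AcquisitionConfig

        acq = AcquisitionConfig(n_visits=12)
        truths = [
            simkit.GroundTruthCapillary(
                capillary_id="a", stall_schedule=((2, 3), (7, 7), (10, 10))
            ),
            simkit.GroundTruthCapillary(capillary_id="b"),
        ]
        sess = simkit.simulate_session(
            truths, acq, calib, seed=5, rbc_arrivals="regular"
        )
        cfg = RunConfig(tau0_us=calib.tau0_us, kq_per_us_mmhg=calib.kq_per_us_mmhg)
        visits, _ = pipeline.per_visit_table(sess.measurements, cfg)
        ev_a = detect_stalls(
            pipeline.build_time_series(visits[visits["capillary_id"] == "a"], "a"),
            acq.revisit_interval_s,
        )
        assert [(e.start_visit, e.end_visit) for e in ev_a] == [(2, 3), (7, 7), (10, 10)]
        assert detect_stalls(
            pipeline.build_time_series(visits[visits["capillary_id"] == "b"], "b")
        ) == []


class TestHypoxiaClass:
    @pytest.mark.parametrize(
        "po2,expected",
        [(4.9, "severe"), (5.0, "hypoxic"), (9.99, "hypoxic"),
         (10.0, "normoxic"), (15.4, "normoxic")],
    )
    def test_threshold_conventions(self, po2, expected):
        assert classify_hypoxia(po2) == expected

    def test_classes_partition_events(self, rng):
        po2s = rng.uniform(0, 40, 200)
        classes = [classify_hypoxia(p) for p in po2s]
        counts = {c: classes.count(c) for c in ("severe", "hypoxic", "normoxic")}
        assert sum(counts.values()) == 200


class TestAlignment:
    def test_t0_holds_event_mean_and_zero_flux(self):
        ts = series([8, 9, 0, 0, 7, 8], po2=[35, 34, 10, 12, 33, 36])
        events = detect_stalls(ts)
        aligned, summary = align_peri_stall(events, {"cap": ts})
        row0 = aligned[aligned["offset"] == 0]
        assert row0["flux_rbc_s"].item() == 0.0
        assert row0["po2_mmhg"].item() == pytest.approx(11.0)

    def test_simulated_drop_and_recovery(self, calib):
        from stallox import pipeline
        from stallox.config import RunConfig
        from stallox.records import AcquisitionConfig

        acq = AcquisitionConfig(n_visits=5)
        truths = [
            simkit.GroundTruthCapillary(
                capillary_id=f"c{i}", po2_flowing=35.0, tissue_po2=30.0,
                po2_stalled=8.0, stall_schedule=((2, 2),),
            )
            for i in range(6)
        ]
        sess = simkit.simulate_session(
            truths, acq, calib, seed=3, rbc_arrivals="regular"
        )
        cfg = RunConfig(tau0_us=calib.tau0_us, kq_per_us_mmhg=calib.kq_per_us_mmhg)
        visits, _ = pipeline.per_visit_table(sess.measurements, cfg)
        events, sers = [], {}
        for cid in sess.measurements:
            ts = pipeline.build_time_series(visits[visits["capillary_id"] == cid], cid)
            sers[cid] = ts
            events += detect_stalls(ts, acq.revisit_interval_s)
        _, summary = align_peri_stall(events, sers, max_offset=2)
        mean = summary[("po2_mmhg", "mean")]
        assert mean[0] == pytest.approx(8.0, abs=2.0)
        assert mean[-1] > mean[0] + 15.0
        assert mean[1] > mean[0] + 15.0

    def test_stationary_capillaries_show_no_pre_post_difference(self, rng):
        # no-effect null: pre/post means centred on zero difference
        diffs = []
        for _ in range(100):
            po2 = rng.normal(35.0, 3.0, 12)
            flux = np.full(12, 8.0)
            flux[5] = 0.0
            ts = series(flux, po2=po2)
            ev = detect_stalls(ts)[0]
            diffs.append(ev.pre_po2.mean() - ev.post_po2.mean())
        assert abs(np.mean(diffs)) < 3.0 * np.std(diffs) / np.sqrt(len(diffs))


class TestRegression:
    def test_exact_line_recovered(self):
        x = np.linspace(5, 40, 10)
        cmp = StallComparison(
            pd.DataFrame({"tissue_po2": x, "stall_po2": 0.8 * x - 4.0,
                          "group": "awake"})
        )
        fit = fit_stall_vs_tissue(cmp).iloc[0]
        assert fit["slope"] == pytest.approx(0.8, abs=1e-12)
        assert fit["intercept"] == pytest.approx(-4.0, abs=1e-10)
        assert fit["r_squared"] == pytest.approx(1.0, abs=1e-12)

    def test_identity_data(self):
        x = np.arange(3.0, 20.0)
        cmp = StallComparison(
            pd.DataFrame({"tissue_po2": x, "stall_po2": x, "group": "g"})
        )
        fit = fit_stall_vs_tissue(cmp).iloc[0]
        assert fit["slope"] == pytest.approx(1.0)
        assert fit["r_squared"] == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        from stallox.benchmarks import _ols_normal_equations

        x = rng.uniform(5, 45, 32)
        y = 0.79 * x - 4.0 + rng.normal(0, 6.0, 32)
        cmp = StallComparison(
            pd.DataFrame({"tissue_po2": x, "stall_po2": y, "group": "awake"})
        )
        fit = fit_stall_vs_tissue(cmp).iloc[0]
        slope, intercept, r2 = _ols_normal_equations(x, y)
        assert abs(fit["slope"] - slope) < 1e-10
        assert abs(fit["intercept"] - intercept) < 1e-10
        assert abs(fit["r_squared"] - r2) < 1e-10

    def test_degenerate_inputs_raise(self):
        cmp = StallComparison(
            pd.DataFrame({"tissue_po2": [5.0, 5.0, 5.0],
                          "stall_po2": [1.0, 2.0, 3.0], "group": "g"})
        )
        with pytest.raises(ValueError, match="variance"):
            fit_stall_vs_tissue(cmp)
        with pytest.raises(ValueError, match="fewer"):
            fit_stall_vs_tissue(
                StallComparison(pd.DataFrame(
                    {"tissue_po2": [1.0, 2.0], "stall_po2": [1.0, 2.0],
                     "group": "g"}))
            )


class TestNeighbors:
    def _cohort(self):
        staller = series([8, 8, 0, 8, 8], cid="staller", position_um=(0, 0, 0))
        near = series(
            [10, 10, 9, 10, 10], po2=[40, 40, 36, 40, 40], cid="near",
            position_um=(20.0, 0, 0),
        )
        same = series([7, 7, 7, 7, 7], po2=np.full(5, 30.0), cid="same",
                      position_um=(100.0, 0, 0))
        return {"staller": staller, "near": near, "same": same}

    def test_identical_conditions_give_zero_delta_unit_ratio(self):
        sers = self._cohort()
        events = detect_stalls(sers["staller"])
        table, _ = neighbor_effects(sers, events)
        same = table[table["capillary_id"] == "same"].iloc[0]
        assert same["delta_po2_mmhg"] == pytest.approx(0.0)
        assert same["flux_ratio"] == pytest.approx(1.0)
        near = table[table["capillary_id"] == "near"].iloc[0]
        assert near["delta_po2_mmhg"] == pytest.approx(-4.0)
        assert near["distance_um"] == pytest.approx(20.0)

    def test_no_events_give_empty_table(self):
        sers = self._cohort()
        table, fits = neighbor_effects(sers, [])
        assert table.empty

    def test_injected_coupling_recovered_and_attenuates(self, calib):
        from stallox import pipeline
        from stallox.config import RunConfig
        from stallox.records import AcquisitionConfig

        acq = AcquisitionConfig(n_visits=6)
        truths = [
            simkit.GroundTruthCapillary(
                capillary_id="staller", stall_schedule=((2, 3),),
                position_um=(0.0, 0.0, 0.0),
            )
        ] + [
            simkit.GroundTruthCapillary(
                capillary_id=f"n{d}", position_um=(float(d), 0.0, 0.0),
                po2_flowing=40.0, tissue_po2=35.0,
            )
            for d in (10, 60, 250)
        ]
        sess = simkit.simulate_session(
            truths, acq, calib, seed=17, rbc_arrivals="regular",
            coupling=simkit.NeighborCoupling(-6.0, 50.0, 0.9),
        )
        cfg = RunConfig(tau0_us=calib.tau0_us, kq_per_us_mmhg=calib.kq_per_us_mmhg)
        visits, _ = pipeline.per_visit_table(sess.measurements, cfg)
        sers, events = {}, []
        pos = {t.capillary_id: t.position_um for t in truths}
        for cid in sess.measurements:
            ts = pipeline.build_time_series(
                visits[visits["capillary_id"] == cid], cid, position_um=pos[cid]
            )
            sers[cid] = ts
            events += detect_stalls(ts, acq.revisit_interval_s)
        table, fits = neighbor_effects(sers, events)
        table = table.set_index("capillary_id")
        assert table.loc["n10", "delta_po2_mmhg"] < -2.0
        assert (
            table.loc["n10", "delta_po2_mmhg"]
            < table.loc["n250", "delta_po2_mmhg"] - 1.0
        )


class TestDurations:
    def test_single_visit_events(self):
        ts = series([0, 5, 0, 5, 0, 5, 0, 5, 0, 5])
        hist = stall_duration_histogram(detect_stalls(ts), 8.0)
        assert hist.loc[hist["n_visits"] == 1, "count"].item() == 5

    def test_mixed_durations_by_construction(self):
        flux = [5, 0, 5, 0, 5, 0, 5, 0, 0, 5, 0, 0, 0, 0, 5]
        hist = stall_duration_histogram(detect_stalls(series(flux)), 8.0)
        got = dict(zip(hist["n_visits"], hist["count"]))
        assert got == {1: 3, 2: 1, 4: 1}
        assert hist.loc[hist["n_visits"] == 4, "duration_s"].item() == 32.0

    def test_multiple_capillaries_contribute_all_events(self):
        e1 = detect_stalls(series([0, 5, 0], cid="a"))
        e2 = detect_stalls(series([5, 0, 5], cid="b"))
        hist = stall_duration_histogram(e1 + e2, 8.0)
        assert hist["count"].sum() == 3
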