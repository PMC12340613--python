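"""End-to-end glue: photon records -> per-visit tables -> stall analysis.

These functions chain the module surfaces (lifetime, flux, eat, stalls)
exactly as the command-line ``report`` does, so library users, the CLI and
reproduction scripts share one code path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import eat as eat_mod
from . import flux as flux_mod
from . import lifetime as lt
from . import stalls as stalls_mod
from .config import RunConfig
from .flux import CapillaryTimeSeries
from .records import PointMeasurement

__all__ = [
    "analyze_capillary",
    "build_time_series",
    "per_visit_table",
    "tissue_po2_for_capillary",
    "analyze_cohort",
]


def _calibration(config: RunConfig) -> lt.SternVolmerCalibration:
    if config.tau0_us is None or config.kq_per_us_mmhg is None:
        raise ValueError(
            "RunConfig must carry an explicit Stern-Volmer calibration "
            "(tau0_us, kq_per_us_mmhg); none is assumed"
        )
    return lt.SternVolmerCalibration(config.tau0_us, config.kq_per_us_mmhg)


def analyze_capillary(
    pms: list[PointMeasurement], config: RunConfig
) -> tuple[pd.DataFrame, list[flux_mod.BinarizedTrace]]:
    """Per-visit lifetime, pO2, flux, speed and QC for one capillary."""
    calib = _calibration(config)
    traces = [flux_mod.build_intensity_trace(pm) for pm in pms]
    bts = [
        flux_mod.binarize_otsu(
            tr,
            smooth_window=config.smooth_window,
            min_dip_cycles=config.min_dip_cycles,
            min_contrast_snr=config.min_contrast_snr,
        )
        for tr in traces
    ]
    rows = []
    for pm, tr, bt in zip(pms, traces, bts):
        qc = flux_mod.qc_measurement(
            tr, history=traces, bt=bt, history_bts=bts,
            frac_of_baseline=config.frac_of_baseline,
            min_separation=config.min_separation,
        )
        fit = lt.fit_single_exponential(
            lt.build_decay(pm, discard_head_us=config.discard_head_us),
            min_photons=config.min_photons,
        )
        po2 = lt.lifetime_to_po2(fit.tau_us, calib) if fit.converged else np.nan
        speed = flux_mod.estimate_speed(bt, config.rbc_path_length_um)
        rows.append(
            {
                "capillary_id": pm.capillary_id,
                "visit_index": pm.visit_index,
                "visit_time_s": pm.visit_time_s,
                "tau_us": fit.tau_us,
                "po2_mmhg": po2,
                "n_photons": fit.n_photons,
                "flux_rbc_s": flux_mod.count_flux(bt, tr.duration_s),
                "speed_um_ms": np.nan if speed is None else speed,
                "qc_pass": qc.passed and fit.converged,
                "qc_reasons": ";".join(qc.reasons + ([] if fit.converged else fit.flags)),
            }
        )
    return pd.DataFrame(rows), bts


def build_time_series(
    visits: pd.DataFrame,
    capillary_id: str,
    group: str = "awake",
    depth_um: float | None = None,
    position_um: tuple[float, float, float] | None = None,
) -> CapillaryTimeSeries:
    cols = ["visit_index", "visit_time_s", "po2_mmhg", "flux_rbc_s", "speed_um_ms",
            "qc_pass"]
    return CapillaryTimeSeries(
        capillary_id=capillary_id,
        visits=visits[cols].sort_values("visit_time_s").reset_index(drop=True),
        group=group,
        depth_um=depth_um,
        position_um=position_um,
    )


def per_visit_table(
    measurements: dict[str, list[PointMeasurement]], config: RunConfig
) -> tuple[pd.DataFrame, dict[str, list[flux_mod.BinarizedTrace]]]:
    tables, bts = [], {}
    for cid, pms in measurements.items():
        tab, bt = analyze_capillary(pms, config)
        tables.append(tab)
        bts[cid] = bt
    return pd.concat(tables, ignore_index=True), bts


def tissue_po2_for_capillary(
    pms: list[PointMeasurement],
    bts: list[flux_mod.BinarizedTrace],
    visits: pd.DataFrame,
    config: RunConfig,
) -> eat_mod.TissuePO2Estimate:
    """EAT tissue-pO2 estimate from qc-passing flowing visits."""
    calib = _calibration(config)
    ok = visits["qc_pass"].astype(bool) & (visits["flux_rbc_s"] > 0)
    sel_pms = [pm for pm, keep in zip(pms, ok) if keep]
    sel_bts = [bt for bt, keep in zip(bts, ok) if keep]
    speeds = visits.loc[ok, "speed_um_ms"].dropna()
    if not sel_pms or speeds.empty:
        return eat_mod.TissuePO2Estimate(np.nan, (np.nan, np.nan), 0.0, False)
    prof = eat_mod.build_eat_profile(
        sel_pms, sel_bts, float(speeds.median()),
        bin_width_um=config.eat_bin_width_um, calib=calib,
        discard_head_us=config.discard_head_us,
        min_photons_per_bin=config.min_photons,
    )
    return eat_mod.estimate_tissue_po2(
        prof, calib, min_photons=config.min_photons
    )


def analyze_cohort(
    measurements: dict[str, list[PointMeasurement]],
    config: RunConfig,
    groups: dict[str, str] | None = None,
    depths_um: dict[str, float] | None = None,
    positions_um: dict[str, tuple[float, float, float]] | None = None,
    revisit_interval_s: float | None = None,
) -> dict:
    """Full analysis of one session's container contents.

    Returns a dict with the per-visit table, per-capillary series, stall
    events, aligned peri-stall tables, the stall-vs-tissue comparison,
    neighbor effects, the duration histogram and a summary dict.
    """
    visits, bts = per_visit_table(measurements, config)
    series: dict[str, CapillaryTimeSeries] = {}
    events: list[stalls_mod.StallEvent] = []
    tissue: dict[str, eat_mod.TissuePO2Estimate] = {}
    for cid, pms in measurements.items():
        sub = visits[visits["capillary_id"] == cid]
        ts = build_time_series(
            sub, cid,
            group=(groups or {}).get(cid, "awake"),
            depth_um=(depths_um or {}).get(cid),
            position_um=(positions_um or {}).get(cid),
        )
        series[cid] = ts
        events.extend(stalls_mod.detect_stalls(ts, revisit_interval_s))
        tissue[cid] = tissue_po2_for_capillary(pms, bts[cid], sub, config)

    cmp_rows = []
    for ev in events:
        ts = series[ev.capillary_id]
        flowing = ts.visits[
            ts.visits["qc_pass"].astype(bool) & (ts.visits["flux_rbc_s"] > 0)
        ]
        est = tissue[ev.capillary_id]
        cmp_rows.append(
            {
                "capillary_id": ev.capillary_id,
                "stall_po2": ev.stall_po2_mmhg,
                "tissue_po2": est.value_mmhg if est.sufficient else np.nan,
                "flowing_po2": float(flowing["po2_mmhg"].mean()) if len(flowing) else np.nan,
                "flowing_flux": float(flowing["flux_rbc_s"].mean()) if len(flowing) else np.nan,
                "depth_um": ts.depth_um,
                "group": ts.group,
                "hypoxia_class": ev.hypoxia_class,
                "duration_s": ev.duration_s,
            }
        )
    comparison = stalls_mod.StallComparison(pd.DataFrame(cmp_rows))

    aligned = summary_by_offset = None
    if events:
        aligned, summary_by_offset = stalls_mod.align_peri_stall(events, series)
    neighbor_table, neighbor_fits = stalls_mod.neighbor_effects(series, events)
    if revisit_interval_s is None:
        t = visits["visit_time_s"].sort_values().to_numpy()
        revisit_interval_s = float(np.median(np.diff(np.unique(t)))) if t.size > 1 else 1.0
    durations = stalls_mod.stall_duration_histogram(events, revisit_interval_s)

    stall_po2 = np.array([ev.stall_po2_mmhg for ev in events])
    n_hypoxic = sum(ev.hypoxia_class in ("hypoxic", "severe") for ev in events)
    summary = {
        "n_capillaries": len(measurements),
        "n_visits": int(len(visits)),
        "n_qc_rejected": int((~visits["qc_pass"].astype(bool)).sum()),
        "n_stall_events": len(events),
        "hypoxic_fraction": (n_hypoxic / len(events)) if events else np.nan,
        "mean_stall_po2_mmhg": float(stall_po2.mean()) if events else np.nan,
        "sd_stall_po2_mmhg": float(stall_po2.std(ddof=1)) if len(events) > 1 else np.nan,
        "run_config_hash": config.hash(),
    }
    return {
        "visits": visits,
        "series": series,
        "binarized": bts,
        "events": events,
        "tissue_po2": tissue,
        "comparison": comparison,
        "aligned": aligned,
        "aligned_summary": summary_by_offset,
        "neighbor_table": neighbor_table,
        "neighbor_fits": neighbor_fits,
        "duration_histogram": durations,
        "summary": summary,
    }
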