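"""Ground-truth recovery benchmarks for every pipeline stage.

Each function simulates data with :mod:`stallox.simkit` under realistic
study conditions (1000 cycles of 10 us excitation + 290 us collection per
visit, ~20 photons/cycle in plasma, deep dye-exclusion dips, ~8 s revisit
cadence), runs the analysis pipeline, and measures how well the known
truth is recovered.  They are deterministic given their seed and are used
both by the test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from . import flux as flux_mod
from . import geometry as geom
from . import lifetime as lt
from . import pipeline, simkit
from . import stalls as stalls_mod
from .config import RunConfig
from .eat import build_eat_profile, estimate_tissue_po2
from .records import AcquisitionConfig
from .stalls import StallComparison, fit_stall_vs_tissue

__all__ = [
    "po2_recovery",
    "flux_recovery",
    "otsu_oracle_agreement",
    "eat_recovery",
    "stall_cohort_truths",
    "stall_pipeline_benchmark",
    "regression_recovery",
    "geometry_benchmark",
]


def _seeds(seed, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n)


def _run_config(calib: lt.SternVolmerCalibration) -> RunConfig:
    return RunConfig(tau0_us=calib.tau0_us, kq_per_us_mmhg=calib.kq_per_us_mmhg)


# --------------------------------------------------------------------- pO2


def po2_recovery(
    seed,
    levels: tuple[float, ...] = (5.0, 10.0, 20.0, 40.0, 80.0),
    n_per_level: int = 50,
    budgets: tuple[float, ...] = (2.5, 20.0, 160.0),
    n_budget_reps: int = 40,
) -> dict:
    """Recover known pO2 from Poisson photon streams.

    Simulates ``n_per_level`` single-visit measurements at each true pO2
    (constant-pO2 visits: the capillary pinned at the target value) at
    ~20 photons/cycle, fits the decay and converts back.  Also measures
    RMSE at pO2 = 40 across photon budgets (plasma count rates in
    ``budgets``) to verify precision grows with photon count.
    """
    acq = AcquisitionConfig(n_visits=1)
    calib = simkit.default_calibration()
    sub = _seeds(seed, len(levels) * n_per_level + len(budgets) * n_budget_reps)
    k = 0
    bias = {}
    for p in levels:
        truth = simkit.GroundTruthCapillary(po2_stalled=p, stall_schedule=((0, 0),))
        est = []
        for _ in range(n_per_level):
            pm = simkit.simulate_point_measurement(truth, acq, 0, calib, int(sub[k]))
            k += 1
            fit = lt.fit_single_exponential(lt.build_decay(pm))
            est.append(lt.lifetime_to_po2(fit.tau_us, calib))
        est = np.asarray(est)
        bias[p] = float(est.mean() - p)
    rmse = {}
    for rate in budgets:
        truth = simkit.GroundTruthCapillary(
            po2_stalled=40.0, stall_schedule=((0, 0),),
            count_rate_plasma=rate, count_rate_rbc=rate / 10.0,
        )
        est = []
        for _ in range(n_budget_reps):
            pm = simkit.simulate_point_measurement(truth, acq, 0, calib, int(sub[k]))
            k += 1
            fit = lt.fit_single_exponential(lt.build_decay(pm), min_photons=100)
            est.append(lt.lifetime_to_po2(fit.tau_us, calib))
        est = np.asarray(est)
        rmse[rate] = float(np.sqrt(np.mean((est - 40.0) ** 2)))
    rates = sorted(rmse)
    return {
        "bias_per_level": bias,
        "max_abs_bias_mmhg": max(abs(b) for b in bias.values()),
        "rmse_per_budget": rmse,
        "rmse_monotone_decreasing": all(
            rmse[a] > rmse[b] for a, b in zip(rates, rates[1:])
        ),
        "n_visits": len(levels) * n_per_level,
    }


# -------------------------------------------------------------------- flux


def flux_recovery(
    seed,
    levels: tuple[float, ...] = (2.0, 5.0, 10.0, 20.0),
    n_visits_per_level: int = 50,
    smooth_window: int = 5,
) -> dict:
    """Per-visit flux versus the simulator's scheduled RBC count.

    High-SNR conditions: deep dye-exclusion dips and regularly spaced
    transits (so that nothing is lost to genuinely unresolvable
    coincident arrivals).  Exactness = detected interval count equals the
    ledger's observable dip count.
    """
    acq = AcquisitionConfig(n_visits=n_visits_per_level)
    calib = simkit.default_calibration()
    sub = _seeds(seed, len(levels) * n_visits_per_level)
    k = 0
    exact = total = 0
    per_level = {}
    for f in levels:
        truth = simkit.GroundTruthCapillary(flux_rate=f)
        hits = 0
        for v in range(n_visits_per_level):
            pm, rec = simkit.simulate_point_measurement(
                truth, acq, v, calib, int(sub[k]), rbc_arrivals="regular",
                return_truth=True,
            )
            k += 1
            bt = flux_mod.binarize_otsu(
                flux_mod.build_intensity_trace(pm), smooth_window=smooth_window
            )
            hits += len(bt.rbc_intervals) == rec["n_rbc_intervals"]
        per_level[f] = hits / n_visits_per_level
        exact += hits
        total += n_visits_per_level
    return {
        "exact_fraction": exact / total,
        "per_level": per_level,
        "n_visits": total,
    }


def _otsu_bruteforce(values: np.ndarray) -> float:
    """Independent exhaustive Otsu: minimize intra-class variance over all
    observed values; ties toward the lower threshold."""
    x = np.sort(np.asarray(values, dtype=float))
    candidates = np.unique(x)[:-1]
    best_thr, best = None, np.inf
    for thr in candidates:
        lo, hi = x[x <= thr], x[x > thr]
        within = lo.size * lo.var() + hi.size * hi.var()
        if within < best - 1e-12:
            best, best_thr = within, thr
    return float(best_thr)


def otsu_oracle_agreement(seed, n_traces: int = 50) -> dict:
    """Fraction of random two-level traces where the pipeline threshold
    equals the exhaustive intra-class-variance search."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_traces):
        n = int(rng.integers(200, 1000))
        lo, hi = rng.uniform(1, 8), rng.uniform(12, 40)
        occ = rng.uniform(0.05, 0.5)
        counts = np.where(
            rng.random(n) < occ, rng.poisson(lo, n), rng.poisson(hi, n)
        ).astype(float)
        tr = flux_mod.IntensityTrace(
            (np.arange(n) + 0.5) * 3e-4, counts, n * 3e-4, 3e-4
        )
        bt = flux_mod.binarize_otsu(tr, min_contrast_snr=0.0)
        hits += bt.threshold_used == _otsu_bruteforce(counts)
    return {"agreement_fraction": hits / n_traces, "n_traces": n_traces}


# --------------------------------------------------------------------- EAT


def eat_recovery(
    seed,
    tissue_levels: tuple[float, ...] = (10.0, 25.0, 40.0),
    n_visits: int = 24,
) -> dict:
    """Recover the far-field tissue pO2 from the EAT plateau.

    Low flux (5 RBC/s) leaves long inter-RBC stretches, giving abundant
    far-from-RBC photons (>1e5 pooled over the visits per level).
    """
    acq = AcquisitionConfig(n_visits=n_visits)
    calib = simkit.default_calibration()
    sub = _seeds(seed, len(tissue_levels) * n_visits)
    k = 0
    errors = {}
    n_far = {}
    for tpo2 in tissue_levels:
        truth = simkit.GroundTruthCapillary(
            tissue_po2=tpo2, po2_flowing=tpo2 + 20.0, flux_rate=5.0,
            speed_um_ms=1.0,
        )
        pms, bts = [], []
        for v in range(n_visits):
            pm = simkit.simulate_point_measurement(truth, acq, v, calib, int(sub[k]))
            k += 1
            bt = flux_mod.binarize_otsu(
                flux_mod.build_intensity_trace(pm), smooth_window=5
            )
            if bt.rbc_intervals:
                pms.append(pm)
                bts.append(bt)
        prof = build_eat_profile(pms, bts, speed_um_ms=1.0, calib=calib)
        est = estimate_tissue_po2(prof, calib)
        errors[tpo2] = float(est.value_mmhg - tpo2)
        n_far[tpo2] = est.n_photons
    return {
        "error_per_level": errors,
        "max_abs_error_mmhg": max(abs(e) for e in errors.values()),
        "far_field_photons": n_far,
        "n_visits": len(tissue_levels) * n_visits,
    }


# ------------------------------------------------------------------ stalls


def stall_cohort_truths(
    seed,
    n_stalls: int = 32,
    hypoxic_fraction: float = 0.4,
    n_visits: int = 5,
    stall_visit: int = 2,
) -> list[simkit.GroundTruthCapillary]:
    """A cohort of stalling capillaries with a fixed hypoxic fraction.

    ``round(hypoxic_fraction * n_stalls)`` capillaries get a stalled pO2
    drawn below 10 mmHg (uniform 2-9); the rest above (uniform 12-40).
    Every capillary stalls once, at ``stall_visit``.
    """
    rng = np.random.default_rng(seed)
    n_hyp = int(round(hypoxic_fraction * n_stalls))
    truths = []
    for i in range(n_stalls):
        po2_stall = rng.uniform(2.0, 9.0) if i < n_hyp else rng.uniform(12.0, 40.0)
        truths.append(
            simkit.GroundTruthCapillary(
                capillary_id=f"c{i:03d}",
                po2_flowing=float(rng.uniform(30.0, 60.0)),
                tissue_po2=float(rng.uniform(20.0, 40.0)),
                po2_stalled=float(po2_stall),
                flux_rate=float(rng.uniform(8.0, 20.0)),
                stall_schedule=((stall_visit, stall_visit),),
                position_um=tuple(rng.uniform(0.0, 300.0, 3)),
            )
        )
    return truths


def stall_pipeline_benchmark(
    seed,
    n_seeds: int = 200,
    n_stalls: int = 32,
    hypoxic_fraction: float = 0.4,
    n_visits: int = 5,
) -> dict:
    """Detection count, hypoxic fraction and peri-stall structure.

    Runs ``n_seeds`` independent cohorts of ``n_stalls`` stalling
    capillaries through simulation and the full per-visit pipeline,
    detects events, classifies hypoxia, and aligns pO2 around stall
    onset.
    """
    acq = AcquisitionConfig(n_visits=n_visits)
    calib = simkit.default_calibration()
    cfg = _run_config(calib)
    sub = _seeds(seed, 2 * n_seeds)
    counts, fracs, po2_means = [], [], []
    offset_sums: dict[int, list[float]] = {}
    for r in range(n_seeds):
        truths = stall_cohort_truths(
            int(sub[2 * r]), n_stalls=n_stalls, hypoxic_fraction=hypoxic_fraction,
            n_visits=n_visits,
        )
        sess = simkit.simulate_session(
            truths, acq, calib, seed=int(sub[2 * r + 1]), rbc_arrivals="regular"
        )
        visits, _ = pipeline.per_visit_table(sess.measurements, cfg)
        events, series = [], {}
        for cid in sess.measurements:
            ts = pipeline.build_time_series(
                visits[visits["capillary_id"] == cid], cid
            )
            series[cid] = ts
            events.extend(stalls_mod.detect_stalls(ts, acq.revisit_interval_s))
        counts.append(len(events))
        if events:
            fracs.append(
                sum(e.hypoxia_class in ("hypoxic", "severe") for e in events)
                / len(events)
            )
            po2_means.append(float(np.mean([e.stall_po2_mmhg for e in events])))
            _, summary = stalls_mod.align_peri_stall(events, series, max_offset=2)
            for off, mean in summary[("po2_mmhg", "mean")].items():
                offset_sums.setdefault(int(off), []).append(float(mean))
    offsets = {off: float(np.mean(v)) for off, v in offset_sums.items()}
    target = round(hypoxic_fraction * n_stalls) / n_stalls
    return {
        "event_count_exact_fraction": float(np.mean(np.asarray(counts) == n_stalls)),
        "hypoxic_fraction_mean": float(np.mean(fracs)),
        "hypoxic_fraction_target": target,
        "binomial_se": float(np.sqrt(target * (1 - target) / n_stalls)),
        "mean_stall_po2_mmhg": float(np.mean(po2_means)),
        "peri_offset_po2_mean": offsets,
        "peri_drop_mmhg": offsets[-1] - offsets[0],
        "peri_recovery_mmhg": offsets[1] - offsets[0],
        "n_seeds": n_seeds,
    }


# -------------------------------------------------------------- regression


def _ols_normal_equations(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form OLS oracle: slope, intercept, R^2 from normal equations."""
    n = x.size
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = y - slope * x - intercept
    ss_tot = ((y - sy / n) ** 2).sum()
    return slope, intercept, 1.0 - (resid**2).sum() / ss_tot


def regression_recovery(
    seed,
    slope: float = 0.79,
    intercept: float = -4.0,
    r_squared: float = 0.47,
    n: int = 32,
    n_reps: int = 200,
) -> dict:
    """Recover a known stall-vs-tissue pO2 relation by OLS.

    Cohorts of ``n`` events are generated with the stated slope and
    intercept plus Gaussian scatter sized so the expected R^2 matches;
    reports the mean fitted slope/R^2 over ``n_reps`` cohorts, the
    single-cohort slope standard error, and the worst disagreement
    between the pipeline's OLS and the closed-form normal-equations
    oracle.
    """
    rng = np.random.default_rng(seed)
    slopes, r2s, ses, oracle_diff = [], [], [], 0.0
    for _ in range(n_reps):
        x = rng.uniform(10.0, 45.0, n)
        noise_sd = abs(slope) * x.std() * np.sqrt(1.0 / r_squared - 1.0)
        y = slope * x + intercept + rng.normal(0.0, noise_sd, n)
        cmp = StallComparison(
            table=_comparison_frame(x, y)
        )
        fit = fit_stall_vs_tissue(cmp).iloc[0]
        slopes.append(fit["slope"])
        r2s.append(fit["r_squared"])
        ses.append(fit["slope_stderr"])
        o_slope, o_int, o_r2 = _ols_normal_equations(x, y)
        oracle_diff = max(
            oracle_diff,
            abs(o_slope - fit["slope"]),
            abs(o_int - fit["intercept"]),
            abs(o_r2 - fit["r_squared"]),
        )
    return {
        "slope_mean": float(np.mean(slopes)),
        "intercept_true": intercept,
        "r_squared_mean": float(np.mean(r2s)),
        "slope_stderr_single_cohort": float(np.mean(ses)),
        "oracle_max_abs_diff": float(oracle_diff),
        "n_events": n,
        "n_reps": n_reps,
    }


def _comparison_frame(x: np.ndarray, y: np.ndarray):
    import pandas as pd

    return pd.DataFrame(
        {
            "tissue_po2": x,
            "stall_po2": y,
            "group": "awake",
        }
    )


# ---------------------------------------------------------------- geometry


def geometry_benchmark(seed) -> dict:
    """Exactness checks of the vessel-geometry stage on tube fixtures."""
    voxel = (2.0, 1.0, 1.0)  # anisotropic z
    tubes = [
        simkit.TubeSpec((40.0, 20.0, 0.0), (40.0, 20.0, 79.0), 4.0, "arteriole"),
        simkit.TubeSpec((20.0, 60.0, 0.0), (20.0, 60.0, 79.0), 5.0, "venule"),
        simkit.TubeSpec((0.0, 40.0, 40.0), (79.0, 40.0, 40.0), 2.5, None),
    ]
    angio = simkit.simulate_angiogram(
        (40, 80, 80), voxel, tubes, seed=seed, noise_sd=4.0
    )
    vol = geom.AngiogramVolume(angio.volume, voxel, angio.large_vessel_labels)
    point = (20, 40, 20)
    sub, local = geom.crop_subvolume(vol, point, half_extent_vox=15)
    mask, _ = geom.preprocess_and_binarize(sub)
    hist = geom.density_histogram(local, mask, voxel)
    conservation = abs(float(hist.counts.sum()) - float(mask.sum()))

    near = geom.nearest_large_vessel(point, angio.large_vessel_labels, voxel)
    # independent brute-force scan over every labeled voxel
    oracle_diff = 0.0
    for name, code in geom.LABEL_CODES.items():
        best = np.inf
        lab = angio.large_vessel_labels
        for z in range(lab.shape[0]):
            rows = np.argwhere(lab[z] == code)
            if rows.size == 0:
                continue
            dz = (z - point[0]) * voxel[0]
            dy = (rows[:, 0] - point[1]) * voxel[1]
            dx = (rows[:, 1] - point[2]) * voxel[2]
            best = min(best, float(np.sqrt(dz**2 + dy**2 + dx**2).min()))
        if np.isfinite(best) or near[name] is not None:
            oracle_diff = max(oracle_diff, abs(best - near[name]))

    full_mask, _ = geom.preprocess_and_binarize(vol)
    skel = geom.skeletonize_mask(full_mask)
    outside = int(np.sum(skel & ~full_mask))
    from scipy import ndimage as ndi

    n_mask = ndi.label(full_mask)[1]
    n_skel = ndi.label(skel)[1]

    big = geom.AngiogramVolume(np.zeros((160, 160, 160), dtype=np.uint8), (1, 1, 1))
    crop, _ = geom.crop_subvolume(big, (80, 80, 80), half_extent_vox=75)
    return {
        "density_conservation_abs_diff": conservation,
        "nearest_vessel_oracle_max_diff_um": oracle_diff,
        "skeleton_voxels_outside_mask": outside,
        "component_count_mask": n_mask,
        "component_count_skeleton": n_skel,
        "crop_span_vox": int(crop.intensity.shape[0]),
        "n_vessel_voxels": int(mask.sum()),
    }
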