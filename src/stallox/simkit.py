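"""Synthetic data generator with known ground truth for every pipeline stage.

Emulates (a) Poisson photon streams whose phosphorescence lifetime encodes
pO2 through Stern-Volmer quenching, (b) dye-exclusion intensity dips during
red-blood-cell passage at a programmable flux and speed, (c) stall windows
during which intracapillary pO2 steps to a lower equilibrium, (d) the
erythrocyte-associated transient (EAT): pO2 decays exponentially from its
near-RBC value toward the far-field tissue value with a configurable length
constant, and (e) tube-network angiogram volumes with truth masks,
centerlines and arteriole/venule labels.

An expected-value ("noiseless") mode replaces Poisson sampling with
fractionally weighted photons carrying exact expected counts, for
closed-form fitting tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .lifetime import SternVolmerCalibration
from .records import AcquisitionConfig, PointMeasurement

__all__ = [
    "GroundTruthCapillary",
    "TubeSpec",
    "SyntheticAngiogram",
    "SessionData",
    "NeighborCoupling",
    "default_calibration",
    "simulate_point_measurement",
    "simulate_session",
    "simulate_angiogram",
]


def default_calibration() -> SternVolmerCalibration:
    """Synthetic Stern-Volmer calibration used by the simulator.

    tau0 = 40 us and kq = 5e-4 /(us*mmHg) give lifetimes spanning roughly
    13-40 us over 0-100 mmHg, a realistic dynamic range for a two-photon
    phosphorescent oxygen probe.  This is a simulator constant, not a
    claim about any real dye batch.
    """
    return SternVolmerCalibration(tau0_us=40.0, kq_per_us_mmhg=5e-4)


@dataclass(frozen=True)
class GroundTruthCapillary:
    """True physiological state of one simulated capillary.

    pO2 values are mmHg; flux is RBCs/s; speed is um/ms; count rates are
    expected photons per cycle.  ``stall_schedule`` lists inclusive
    ``(start_visit, end_visit)`` windows during which flux is 0 and pO2
    sits at ``po2_stalled``.  Between RBCs the plasma pO2 relaxes from
    ``po2_flowing`` (at the RBC) toward ``tissue_po2`` with length
    constant ``eat_length_constant_um``.
    """

    capillary_id: str = "cap0"
    po2_flowing: float = 45.0
    po2_stalled: float = 15.0
    tissue_po2: float = 28.0
    flux_rate: float = 15.0
    rbc_transit_time_ms: float = 6.0
    speed_um_ms: float = 1.0
    stall_schedule: tuple[tuple[int, int], ...] = ()
    eat_length_constant_um: float = 10.0
    count_rate_plasma: float = 20.0
    count_rate_rbc: float = 2.0
    dark_rate: float = 0.0
    position_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    group: str = "awake"
    depth_um: float = 150.0

    def __post_init__(self) -> None:
        for name in ("po2_flowing", "po2_stalled", "tissue_po2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.count_rate_rbc >= self.count_rate_plasma:
            raise ValueError("count_rate_rbc must be < count_rate_plasma (dye exclusion)")
        if self.flux_rate < 0:
            raise ValueError("flux_rate must be >= 0")
        if self.speed_um_ms <= 0 or self.rbc_transit_time_ms <= 0:
            raise ValueError("speed and rbc_transit_time must be > 0")
        if self.dark_rate < 0 or self.count_rate_rbc < 0:
            raise ValueError("negative photon rates are not allowed")
        if self.eat_length_constant_um <= 0:
            raise ValueError("eat_length_constant_um must be > 0")

    def stalled_at(self, visit_index: int) -> bool:
        return any(s <= visit_index <= e for s, e in self.stall_schedule)

    def validate_schedule(self, n_visits: int) -> None:
        for s, e in self.stall_schedule:
            if s > e or s < 0 or e >= n_visits:
                raise ValueError(
                    f"stall window ({s},{e}) outside session of {n_visits} visits"
                )


def _rbc_intervals(
    truth: GroundTruthCapillary,
    duration_s: float,
    rng: np.random.Generator,
    arrivals: str,
) -> np.ndarray:
    """(n,2) array of merged RBC passage intervals (s) within one visit."""
    transit_s = truth.rbc_transit_time_ms * 1e-3
    if truth.flux_rate <= 0:
        return np.empty((0, 2))
    if arrivals == "poisson":
        n = rng.poisson(truth.flux_rate * duration_s)
        starts = np.sort(rng.uniform(0.0, duration_s, size=n))
    elif arrivals == "regular":
        n = int(round(truth.flux_rate * duration_s))
        if n == 0:
            return np.empty((0, 2))
        period = duration_s / n
        starts = rng.uniform(0.0, period) + period * np.arange(n)
    else:
        raise ValueError(f"unknown RBC arrival model {arrivals!r}")
    if starts.size == 0:
        return np.empty((0, 2))
    iv = np.column_stack([starts, starts + transit_s])
    iv = np.clip(iv, 0.0, duration_s)
    # merge overlaps: overlapping dips are indistinguishable in the trace
    merged = [iv[0]]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged)


def _cycle_truth(
    truth: GroundTruthCapillary,
    acq: AcquisitionConfig,
    stalled: bool,
    intervals: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle (expected count rate, local pO2)."""
    t_mid = (np.arange(acq.n_cycles) + 0.5) * acq.cycle_duration_s
    if stalled:
        rate = np.full(acq.n_cycles, truth.count_rate_plasma)
        po2 = np.full(acq.n_cycles, truth.po2_stalled)
        return rate, po2
    if intervals.size == 0:
        return (
            np.full(acq.n_cycles, truth.count_rate_plasma),
            np.full(acq.n_cycles, truth.tissue_po2),
        )
    in_rbc = np.zeros(acq.n_cycles, dtype=bool)
    for s, e in intervals:
        in_rbc |= (t_mid >= s) & (t_mid < e)
    mids = intervals.mean(axis=1)
    j = np.searchsorted(mids, t_mid)
    d_lo = np.abs(t_mid - mids[np.clip(j - 1, 0, mids.size - 1)])
    d_hi = np.abs(mids[np.clip(j, 0, mids.size - 1)] - t_mid)
    d_um = np.minimum(d_lo, d_hi) * 1e3 * truth.speed_um_ms  # s -> ms -> um
    po2 = truth.tissue_po2 + (truth.po2_flowing - truth.tissue_po2) * np.exp(
        -d_um / truth.eat_length_constant_um
    )
    po2 = np.where(in_rbc, truth.po2_flowing, po2)
    rate = np.where(in_rbc, truth.count_rate_rbc, truth.count_rate_plasma)
    return rate.astype(float), po2


def _quantize(t_us: np.ndarray, width_us: float) -> np.ndarray:
    """Snap arrival times to decay-bin centers (TCSPC quantization)."""
    return (np.floor(t_us / width_us) + 0.5) * width_us


def simulate_point_measurement(
    truth: GroundTruthCapillary,
    acq: AcquisitionConfig,
    visit_index: int,
    calib: SternVolmerCalibration,
    seed,
    mode: str = "poisson",
    rbc_arrivals: str = "poisson",
    visit_time_s: float | None = None,
    return_truth: bool = False,
):
    """Simulate the photon record of one visit to one capillary point.

    Lays down RBC passage intervals across the visit, assigns each cycle a
    local pO2 (stall value, near-RBC value, or along the EAT gradient by
    distance to the nearest RBC), converts pO2 to a lifetime through the
    inverse Stern-Volmer relation, and draws per-cycle photon counts
    (Poisson, rate depending on RBC presence) with arrival times from the
    truncated exponential decay plus uniform dark counts.

    ``mode="expected"`` emits weighted photons with exact expected bin
    contents instead of sampling.  With ``return_truth=True`` also returns
    a dict of the per-visit truth (intervals, flux, stall state).
    """
    if not 0 <= visit_index < acq.n_visits:
        raise ValueError(f"visit_index {visit_index} outside session of {acq.n_visits}")
    truth.validate_schedule(acq.n_visits)
    rng = np.random.default_rng(seed)
    stalled = truth.stalled_at(visit_index)
    duration = acq.visit_duration_s
    intervals = (
        np.empty((0, 2)) if stalled else _rbc_intervals(truth, duration, rng, rbc_arrivals)
    )
    rate, po2 = _cycle_truth(truth, acq, stalled, intervals)
    tau = np.asarray(calib.tau_for_po2(po2))
    exc, col, w = acq.excitation_window_us, acq.collection_window_us, acq.decay_bin_width_us

    if mode == "poisson":
        counts = rng.poisson(rate)
        n_tot = int(counts.sum())
        cyc = np.repeat(np.arange(acq.n_cycles), counts)
        tau_p = np.repeat(tau, counts)
        u = rng.random(n_tot)
        decay_t = -tau_p * np.log1p(-u * (1.0 - np.exp(-col / tau_p)))
        arr = exc + _quantize(decay_t, w)
        weights = None
        if truth.dark_rate > 0:
            dcounts = rng.poisson(truth.dark_rate, acq.n_cycles)
            dcyc = np.repeat(np.arange(acq.n_cycles), dcounts)
            darr = exc + _quantize(rng.uniform(0.0, col, dcyc.size), w)
            arr = np.concatenate([arr, darr])
            cyc = np.concatenate([cyc, dcyc])
        order = np.lexsort((arr, cyc))
        arr, cyc = arr[order], cyc[order]
    elif mode == "expected":
        n_bins = int(np.floor(col / w + 1e-9))
        edges = w * np.arange(n_bins + 1)
        centers = exc + 0.5 * (edges[:-1] + edges[1:])
        # group cycles sharing (rate, tau) so identical cycles share one weight row
        keys = np.round(np.column_stack([rate, tau]), 12)
        uniq, inv, mult = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
        arr_parts, cyc_parts, w_parts = [], [], []
        rep_cycle = np.full(uniq.shape[0], -1, dtype=np.int64)
        rep_cycle[inv] = np.arange(acq.n_cycles)  # one representative cycle per group
        for g, (r_g, tau_g) in enumerate(uniq):
            cdf = (1.0 - np.exp(-edges / tau_g)) / (1.0 - np.exp(-col / tau_g))
            p_bin = np.diff(cdf)
            wt = r_g * p_bin + truth.dark_rate * (w / col)
            members = np.flatnonzero(inv == g)
            arr_parts.append(np.tile(centers, members.size))
            cyc_parts.append(np.repeat(members, n_bins))
            w_parts.append(np.tile(wt, members.size))
        arr = np.concatenate(arr_parts) if arr_parts else np.empty(0)
        cyc = np.concatenate(cyc_parts) if cyc_parts else np.empty(0, dtype=np.int64)
        weights = np.concatenate(w_parts) if w_parts else np.empty(0)
    else:
        raise ValueError(f"unknown simulation mode {mode!r}")

    if visit_time_s is None:
        visit_time_s = visit_index * acq.revisit_interval_s
    pm = PointMeasurement(
        capillary_id=truth.capillary_id,
        visit_index=visit_index,
        visit_time_s=float(visit_time_s),
        arrival_times_us=arr,
        cycle_index=cyc,
        acq=acq,
        weights=weights,
    )
    if not return_truth:
        return pm
    # a dip is observable only if it covers >= 1 cycle midpoint; sub-cycle
    # slivers at the trace edges have no measurement support
    t_mid = (np.arange(acq.n_cycles) + 0.5) * acq.cycle_duration_s
    n_observable = int(
        sum(np.any((t_mid >= s) & (t_mid < e)) for s, e in intervals)
    )
    record = {
        "stalled": stalled,
        "rbc_intervals_s": intervals,
        "n_rbc_intervals": n_observable,
        "true_flux_rbc_s": n_observable / duration,
        "true_po2_mmhg": truth.po2_stalled if stalled else truth.po2_flowing,
        "true_tissue_po2_mmhg": truth.tissue_po2,
        "true_speed_um_ms": truth.speed_um_ms,
    }
    return pm, record


@dataclass(frozen=True)
class NeighborCoupling:
    """Optional cross-capillary effect of a stall on co-measured neighbors.

    While any other capillary is stalled, a neighbor's flowing and tissue
    pO2 shift by ``delta_po2_mmhg * exp(-d/length_um)`` (d = distance to
    the nearest stalled capillary) and its flux is scaled by
    ``flux_ratio`` (applied with the same exponential attenuation).
    """

    delta_po2_mmhg: float = -3.0
    length_um: float = 50.0
    flux_ratio: float = 0.96


@dataclass
class SessionData:
    """One simulated imaging session plus its ground-truth ledger."""

    measurements: dict[str, list[PointMeasurement]]
    ledger: pd.DataFrame
    truths: list[GroundTruthCapillary]
    acq: AcquisitionConfig
    calib: SternVolmerCalibration


def simulate_session(
    truths: list[GroundTruthCapillary],
    acq: AcquisitionConfig,
    calib: SternVolmerCalibration,
    seed,
    mode: str = "poisson",
    rbc_arrivals: str = "poisson",
    coupling: NeighborCoupling | None = None,
) -> SessionData:
    """Simulate a session: visits interleaved across capillaries.

    The scan iterates through all points once per ``revisit_interval_s``;
    capillary *i* at visit *v* is timestamped
    ``v*revisit + i*revisit/n_points``.  The returned ledger records the
    per-visit true pO2, flux, stall state and RBC interval count for
    recovery tests.
    """
    if not truths:
        raise ValueError("need at least one capillary")
    ids = [t.capillary_id for t in truths]
    if len(set(ids)) != len(ids):
        raise ValueError("capillary_id values must be unique within a session")
    for t in truths:
        t.validate_schedule(acq.n_visits)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(truths) * max(acq.n_visits, 1) * 2)
    pos = np.asarray([t.position_um for t in truths], dtype=float)
    dist = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1))

    measurements: dict[str, list[PointMeasurement]] = {t.capillary_id: [] for t in truths}
    rows = []
    slot = acq.revisit_interval_s / len(truths)
    for v in range(acq.n_visits):
        stalled_now = np.array([t.stalled_at(v) for t in truths])
        for i, truth in enumerate(truths):
            eff = truth
            if coupling is not None and not stalled_now[i] and stalled_now.any():
                others = stalled_now.copy()
                others[i] = False
                if others.any():
                    d = dist[i, others].min()
                    atten = np.exp(-d / coupling.length_um)
                    dpo2 = coupling.delta_po2_mmhg * atten
                    fscale = 1.0 - (1.0 - coupling.flux_ratio) * atten
                    eff = replace(
                        truth,
                        po2_flowing=max(truth.po2_flowing + dpo2, 0.0),
                        tissue_po2=max(truth.tissue_po2 + dpo2, 0.0),
                        flux_rate=truth.flux_rate * fscale,
                    )
            pm, rec = simulate_point_measurement(
                eff, acq, v, calib, int(child_seeds[(v * len(truths) + i)]),
                mode=mode, rbc_arrivals=rbc_arrivals,
                visit_time_s=v * acq.revisit_interval_s + i * slot,
                return_truth=True,
            )
            measurements[truth.capillary_id].append(pm)
            rows.append(
                {
                    "capillary_id": truth.capillary_id,
                    "visit_index": v,
                    "visit_time_s": pm.visit_time_s,
                    "stalled": rec["stalled"],
                    "n_rbc_intervals": rec["n_rbc_intervals"],
                    "true_flux_rbc_s": rec["true_flux_rbc_s"],
                    "true_po2_mmhg": rec["true_po2_mmhg"],
                    "true_tissue_po2_mmhg": rec["true_tissue_po2_mmhg"],
                    "true_speed_um_ms": rec["true_speed_um_ms"],
                    "group": truth.group,
                    "depth_um": truth.depth_um,
                }
            )
    ledger = pd.DataFrame(rows)
    return SessionData(measurements, ledger, list(truths), acq, calib)


def random_cohort(
    n_capillaries: int,
    seed,
    n_visits: int,
    stall_fraction: float = 0.2,
    hypoxic_fraction_of_stalls: float = 0.4,
    stall_duration_visits: tuple[int, ...] = (1, 1, 1, 2, 3),
    field_extent_um: float = 400.0,
) -> list[GroundTruthCapillary]:
    """Draw a physiologically plausible cohort of ground-truth capillaries.

    Flowing pO2, tissue pO2, flux and speed are drawn around typical
    cortical-capillary values; ``stall_fraction`` of capillaries receive
    one stall of a duration drawn from ``stall_duration_visits`` (mostly
    brief), and ``hypoxic_fraction_of_stalls`` of those get a stalled pO2
    below 10 mmHg.  Positions are uniform in a cube of side
    ``field_extent_um``.
    """
    rng = np.random.default_rng(seed)
    n_stall = int(round(stall_fraction * n_capillaries))
    stall_ids = rng.choice(n_capillaries, size=n_stall, replace=False)
    n_hyp = int(round(hypoxic_fraction_of_stalls * n_stall))
    hypoxic_ids = set(stall_ids[:n_hyp].tolist())
    truths = []
    for i in range(n_capillaries):
        flowing = float(np.clip(rng.normal(45.0, 10.0), 15.0, 90.0))
        tissue = float(np.clip(flowing - rng.uniform(5.0, 20.0), 5.0, None))
        schedule: tuple[tuple[int, int], ...] = ()
        stalled_po2 = float(np.clip(tissue - rng.uniform(0.0, 10.0), 11.0, None))
        if i in stall_ids:
            dur = int(rng.choice(stall_duration_visits))
            dur = min(dur, max(n_visits - 4, 1))
            start = int(rng.integers(2, max(n_visits - dur - 1, 3)))
            schedule = ((start, start + dur - 1),)
            if i in hypoxic_ids:
                stalled_po2 = float(rng.uniform(2.0, 9.0))
        truths.append(
            GroundTruthCapillary(
                capillary_id=f"cap{i:03d}",
                po2_flowing=flowing,
                po2_stalled=stalled_po2,
                tissue_po2=tissue,
                flux_rate=float(rng.uniform(5.0, 25.0)),
                rbc_transit_time_ms=float(rng.uniform(4.0, 8.0)),
                speed_um_ms=float(rng.uniform(0.5, 1.5)),
                stall_schedule=schedule,
                position_um=tuple(rng.uniform(0.0, field_extent_um, 3)),
                depth_um=float(rng.uniform(50.0, 300.0)),
            )
        )
    return truths


# --------------------------------------------------------------------------
# Synthetic angiograms


@dataclass(frozen=True)
class TubeSpec:
    """A straight cylindrical vessel segment in physical coordinates (um)."""

    start_um: tuple[float, float, float]
    end_um: tuple[float, float, float]
    radius_um: float
    label: str | None = None  # None | "arteriole" | "venule"


@dataclass
class SyntheticAngiogram:
    volume: np.ndarray                      # float intensity, zyx
    voxel_size_um: tuple[float, float, float]
    vessel_truth_mask: np.ndarray           # bool, zyx
    centerline_truth: np.ndarray            # (n, 3) int voxel coords
    large_vessel_labels: np.ndarray         # uint8: 0 none, 1 arteriole, 2 venule
    measurement_points: list[tuple[int, int, int]] = field(default_factory=list)

    LABELS = {"arteriole": 1, "venule": 2}

    def depth_um(self, point: tuple[int, int, int]) -> float:
        return point[0] * self.voxel_size_um[0]


def _segment_distance(coords: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.linalg.norm(coords - a, axis=-1)
    t = np.clip(((coords - a) @ ab) / denom, 0.0, 1.0)
    proj = a + t[..., None] * ab
    return np.linalg.norm(coords - proj, axis=-1)


def simulate_angiogram(
    shape: tuple[int, int, int],
    voxel_size_um: tuple[float, float, float],
    tube_specs: list[TubeSpec],
    seed,
    background: float = 10.0,
    amplitude: float = 100.0,
    blur_sigma_um: float = 1.0,
    noise_sd: float = 5.0,
    measurement_points: list[tuple[int, int, int]] | None = None,
) -> SyntheticAngiogram:
    """Render a tube-network angiogram volume with ground truth.

    The truth mask is the union of cylinders around each tube's
    centerline; the rendered volume is mask intensity plus Gaussian blur
    plus Gaussian noise (clipped at 0).  Tubes extending outside the
    volume are clipped with a warning.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)
    vs = np.asarray(voxel_size_um, dtype=float)
    if np.any(vs <= 0):
        raise ValueError("voxel sizes must be positive")
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    coords = np.stack([zz, yy, xx], axis=-1) * vs  # voxel centers, um

    mask = np.zeros(shape, dtype=bool)
    labels = np.zeros(shape, dtype=np.uint8)
    centerline: set[tuple[int, int, int]] = set()
    extent_um = (np.asarray(shape) - 1) * vs
    for tube in tube_specs:
        a = np.asarray(tube.start_um, dtype=float)
        b = np.asarray(tube.end_um, dtype=float)
        if np.any(a < -tube.radius_um) or np.any(b < -tube.radius_um) or np.any(
            a > extent_um + tube.radius_um
        ) or np.any(b > extent_um + tube.radius_um):
            warnings.warn("tube extends outside the volume; it will be clipped",
                          stacklevel=2)
        d = _segment_distance(coords, a, b)
        tmask = d <= tube.radius_um
        mask |= tmask
        if tube.label is not None:
            labels[tmask] = SyntheticAngiogram.LABELS[tube.label]
        # rasterize centerline at sub-voxel steps
        n_steps = max(int(np.ceil(np.linalg.norm(b - a) / (vs.min() * 0.5))), 1)
        for t in np.linspace(0.0, 1.0, n_steps + 1):
            p = np.rint((a + t * (b - a)) / vs).astype(int)
            if np.all(p >= 0) and np.all(p < shape):
                centerline.add(tuple(int(q) for q in p))
    # centerline and labels only on vessel voxels (invariant)
    centerline = {c for c in centerline if mask[c]}
    labels[~mask] = 0

    vol = background + amplitude * mask.astype(float)
    if blur_sigma_um > 0:
        vol = ndimage.gaussian_filter(vol, sigma=blur_sigma_um / vs)
    if noise_sd > 0:
        vol = vol + rng.normal(0.0, noise_sd, size=shape)
    vol = np.clip(vol, 0.0, None)

    cl = (
        np.asarray(sorted(centerline), dtype=int)
        if centerline
        else np.empty((0, 3), dtype=int)
    )
    return SyntheticAngiogram(
        volume=vol.astype(np.float32),
        voxel_size_um=tuple(float(v) for v in vs),
        vessel_truth_mask=mask,
        centerline_truth=cl,
        large_vessel_labels=labels,
        measurement_points=list(measurement_points or []),
    )
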