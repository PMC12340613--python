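"""Erythrocyte-associated transient (EAT) and the tissue-pO2 proxy.

Intravascular pO2 is highest next to a passing RBC and relaxes toward the
surrounding tissue value between RBCs.  Rebinning plasma-phase photons by
distance to the nearest RBC (time to the nearest passage times the RBC
speed) and fitting a lifetime per distance bin yields the oxygen profile;
pO2 far from RBCs serves as an estimate of the local tissue pO2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .flux import BinarizedTrace
from .lifetime import (
    DEFAULT_DISCARD_HEAD_US,
    DEFAULT_MIN_PHOTONS,
    DecayHistogram,
    LifetimeFitResult,
    SternVolmerCalibration,
    fit_single_exponential,
    lifetime_to_po2,
)
from .records import PointMeasurement

__all__ = ["EATProfile", "TissuePO2Estimate", "build_eat_profile", "estimate_tissue_po2"]

DEFAULT_EAT_BIN_WIDTH_UM = 1.0
DEFAULT_PLATEAU_MIN_UM = 10.0


@dataclass
class EATProfile:
    """Photons of one capillary rebinned by distance to the nearest RBC.

    ``decay_counts[i]`` is the pooled decay histogram (over
    ``decay_bin_edges_us``) of distance bin *i*; fitting each row gives
    the per-bin pO2.  Bins below the photon threshold keep NaN pO2 but
    their photons are reported.
    """

    distance_bin_edges_um: np.ndarray
    decay_bin_edges_us: np.ndarray
    decay_counts: np.ndarray             # (n_distance_bins, n_decay_bins)
    po2_per_bin: np.ndarray              # mmHg, NaN where insufficient
    tau_per_bin: np.ndarray
    n_photons_per_bin: np.ndarray
    speed_used_um_ms: float
    median_inter_rbc_um: float
    flags: list[str] = field(default_factory=list)

    @property
    def distance_bin_centers_um(self) -> np.ndarray:
        return 0.5 * (self.distance_bin_edges_um[:-1] + self.distance_bin_edges_um[1:])

    @property
    def total_photons(self) -> float:
        return float(self.n_photons_per_bin.sum())


@dataclass
class TissuePO2Estimate:
    value_mmhg: float
    plateau_range_um: tuple[float, float]
    n_photons: float
    sufficient: bool
    fit: LifetimeFitResult | None = None


def _photon_distances_um(
    pm: PointMeasurement, bt: BinarizedTrace, speed_um_ms: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Plasma-phase photons: (distance to nearest RBC midpoint, decay time)."""
    acq = pm.acq
    plasma = ~bt.is_rbc[pm.cycle_index]
    t_abs = (
        pm.cycle_index[plasma] * acq.cycle_duration_s
        + pm.arrival_times_us[plasma] * 1e-6
    )
    mids = np.array([(s + e) / 2.0 for s, e in bt.rbc_intervals])
    j = np.searchsorted(mids, t_abs)
    d_lo = np.abs(t_abs - mids[np.clip(j - 1, 0, mids.size - 1)])
    d_hi = np.abs(mids[np.clip(j, 0, mids.size - 1)] - t_abs)
    dist_um = np.minimum(d_lo, d_hi) * 1e3 * speed_um_ms
    decay_us = pm.arrival_times_us[plasma] - acq.excitation_window_us
    w = None if pm.weights is None else pm.weights[plasma]
    return dist_um, decay_us, w


def build_eat_profile(
    pms: list[PointMeasurement],
    bts: list[BinarizedTrace],
    speed_um_ms: float,
    bin_width_um: float = DEFAULT_EAT_BIN_WIDTH_UM,
    calib: SternVolmerCalibration | None = None,
    discard_head_us: float = DEFAULT_DISCARD_HEAD_US,
    min_photons_per_bin: float = DEFAULT_MIN_PHOTONS,
) -> EATProfile:
    """Build the oxygen-vs-distance-from-RBC profile of one capillary.

    Pools plasma-phase photons across the given (qc-passing, flowing)
    visits.  Each photon's distance is the time to the midpoint of the
    nearest RBC passage times the RBC speed.  Per distance bin, the decay
    histogram is fitted to a single exponential and converted to pO2 when
    ``calib`` is given and the bin holds enough photons.
    """
    if len(pms) != len(bts):
        raise ValueError("need one BinarizedTrace per PointMeasurement")
    if not pms:
        raise ValueError("no visits given")
    if speed_um_ms <= 0:
        raise ValueError("speed must be > 0")
    if not any(bt.rbc_intervals for bt in bts):
        raise ValueError("EAT is undefined without RBC passages in any visit")
    acq = pms[0].acq
    w_us = acq.decay_bin_width_us
    span = acq.collection_window_us - discard_head_us
    n_decay = int(np.floor(span / w_us + 1e-9))
    decay_edges = discard_head_us + w_us * np.arange(n_decay + 1)

    dists, decays, weights = [], [], []
    gaps_um = []
    for pm, bt in zip(pms, bts):
        if not bt.rbc_intervals:
            continue
        d, t, w = _photon_distances_um(pm, bt, speed_um_ms)
        dists.append(d)
        decays.append(t)
        weights.append(np.ones(d.size) if w is None else w)
        mids = [(s + e) / 2.0 for s, e in bt.rbc_intervals]
        if len(mids) > 1:
            gaps_um.extend(np.diff(mids) * 1e3 * speed_um_ms)
    dist = np.concatenate(dists)
    decay = np.concatenate(decays)
    wgt = np.concatenate(weights)
    in_window = (decay >= decay_edges[0]) & (decay < decay_edges[-1])
    dist, decay, wgt = dist[in_window], decay[in_window], wgt[in_window]

    max_d = float(dist.max()) if dist.size else bin_width_um
    n_bins = max(int(np.ceil(max_d / bin_width_um)), 1)
    dist_edges = bin_width_um * np.arange(n_bins + 1)
    counts, _, _ = np.histogram2d(dist, decay, bins=[dist_edges, decay_edges],
                                  weights=wgt)

    n_per_bin = counts.sum(axis=1)
    tau = np.full(n_bins, np.nan)
    po2 = np.full(n_bins, np.nan)
    for i in range(n_bins):
        if n_per_bin[i] < min_photons_per_bin:
            continue
        fit = fit_single_exponential(
            DecayHistogram(decay_edges, counts[i], acq.n_cycles),
            min_photons=min_photons_per_bin,
        )
        if fit.converged:
            tau[i] = fit.tau_us
            if calib is not None:
                po2[i] = lifetime_to_po2(fit.tau_us, calib)
    return EATProfile(
        distance_bin_edges_um=dist_edges,
        decay_bin_edges_us=decay_edges,
        decay_counts=counts,
        po2_per_bin=po2,
        tau_per_bin=tau,
        n_photons_per_bin=n_per_bin,
        speed_used_um_ms=float(speed_um_ms),
        median_inter_rbc_um=float(np.median(gaps_um)) if gaps_um else np.nan,
    )


def estimate_tissue_po2(
    prof: EATProfile,
    calib: SternVolmerCalibration,
    plateau_cutoff_um: float | None = None,
    min_photons: float = DEFAULT_MIN_PHOTONS,
) -> TissuePO2Estimate:
    """Tissue pO2 from the far-from-RBC plateau of the EAT profile.

    Pools the decay photons of all sufficiently filled bins at distances
    at or beyond the plateau cutoff (default: the larger of 10 um and
    half the median inter-RBC distance), fits one lifetime and converts
    to pO2.
    """
    if plateau_cutoff_um is None:
        half_gap = (
            0.5 * prof.median_inter_rbc_um
            if np.isfinite(prof.median_inter_rbc_um)
            else 0.0
        )
        plateau_cutoff_um = max(DEFAULT_PLATEAU_MIN_UM, half_gap)
    left = prof.distance_bin_edges_um[:-1]
    use = (left >= plateau_cutoff_um) & (prof.n_photons_per_bin >= min_photons)
    rng = (float(plateau_cutoff_um), float(prof.distance_bin_edges_um[-1]))
    if not use.any():
        return TissuePO2Estimate(np.nan, rng, 0.0, sufficient=False)
    pooled = prof.decay_counts[use].sum(axis=0)
    fit = fit_single_exponential(
        DecayHistogram(prof.decay_bin_edges_us, pooled, 0), min_photons=min_photons
    )
    if not fit.converged:
        return TissuePO2Estimate(np.nan, rng, float(pooled.sum()), False, fit)
    value = lifetime_to_po2(fit.tau_us, calib)
    return TissuePO2Estimate(float(value), rng, float(pooled.sum()), True, fit)
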