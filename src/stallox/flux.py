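"""RBC flux from intensity time courses.

The plasma-borne phosphorescent dye is excluded from red blood cells, so a
passing RBC appears as a dip in the per-cycle photon count.  Otsu's
threshold separates plasma from RBC cycles; maximal below-threshold runs
are RBC passages, counted to give flux (RBCs/s) and timed to estimate
speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._otsu import otsu_threshold
from .records import PointMeasurement

__all__ = [
    "IntensityTrace",
    "BinarizedTrace",
    "CapillaryTimeSeries",
    "QCResult",
    "build_intensity_trace",
    "binarize_otsu",
    "count_flux",
    "estimate_speed",
    "qc_measurement",
]

DEFAULT_MIN_DIP_CYCLES = 3
DEFAULT_FRAC_OF_BASELINE = 0.5
DEFAULT_MIN_SEPARATION = 0.2
DEFAULT_MIN_CONTRAST_SNR = 3.0
DEFAULT_RBC_PATH_LENGTH_UM = 6.0


@dataclass
class IntensityTrace:
    """Per-cycle photon totals of one visit; times are cycle midpoints (s)."""

    times_s: np.ndarray
    counts_per_cycle: np.ndarray
    duration_s: float
    cycle_duration_s: float
    capillary_id: str = ""
    visit_index: int = 0

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.counts_per_cycle = np.asarray(self.counts_per_cycle, dtype=float)
        if self.times_s.shape != self.counts_per_cycle.shape:
            raise ValueError("times_s and counts_per_cycle must match in length")
        if np.any(self.counts_per_cycle < 0):
            raise ValueError("counts must be nonnegative")


@dataclass
class BinarizedTrace:
    """Plasma/RBC labelling of a trace; RBC intervals are maximal runs.

    ``separation`` is Otsu's goodness (between-class / total variance) at
    the threshold; ``contrast_snr`` is the dip depth in units of the
    plasma shot noise, the statistic that actually distinguishes real
    dye-exclusion dips from a noise split of a unimodal trace.
    """

    is_rbc: np.ndarray                      # bool per cycle
    threshold_used: float
    rbc_intervals: list[tuple[float, float]]  # (start_s, end_s), ordered
    separation: float                        # between-class/total variance at threshold
    contrast_snr: float = np.inf
    flags: list[str] = field(default_factory=list)

    @property
    def has_rbc_evidence(self) -> bool:
        return bool(self.rbc_intervals) and "no_dip_contrast" not in self.flags


@dataclass
class CapillaryTimeSeries:
    """Per-visit pO2/flux/speed/QC for one capillary over a session."""

    capillary_id: str
    visits: pd.DataFrame  # visit_index, visit_time_s, po2_mmhg, flux_rbc_s,
    #                       speed_um_ms, qc_pass
    group: str = "awake"
    depth_um: float | None = None
    position_um: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        t = self.visits["visit_time_s"].to_numpy()
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("visit times must be strictly increasing")
        flux = self.visits["flux_rbc_s"].to_numpy(dtype=float)
        if np.any(flux[np.isfinite(flux)] < 0):
            raise ValueError("flux must be >= 0")


@dataclass
class QCResult:
    passed: bool
    reasons: list[str] = field(default_factory=list)


def build_intensity_trace(pm: PointMeasurement) -> IntensityTrace:
    """Photon counts per full cycle (excitation + collection) vs time."""
    acq = pm.acq
    times = (np.arange(acq.n_cycles) + 0.5) * acq.cycle_duration_s
    return IntensityTrace(
        times_s=times,
        counts_per_cycle=pm.counts_per_cycle(),
        duration_s=acq.visit_duration_s,
        cycle_duration_s=acq.cycle_duration_s,
        capillary_id=pm.capillary_id,
        visit_index=pm.visit_index,
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as (start, stop) cycle indices, stop exclusive."""
    if not mask.any():
        return []
    padded = np.diff(np.concatenate([[0], mask.view(np.int8), [0]]))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def _moving_average(counts: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge correction (no zero-padding bias)."""
    csum = np.cumsum(np.concatenate([[0.0], counts]))
    n = counts.size
    half_lo = (window - 1) // 2
    half_hi = window // 2
    lo = np.clip(np.arange(n) - half_lo, 0, n)
    hi = np.clip(np.arange(n) + half_hi + 1, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def binarize_otsu(
    tr: IntensityTrace,
    smooth_window: int = 0,
    min_dip_cycles: int = DEFAULT_MIN_DIP_CYCLES,
    include_edge_dips: bool = True,
    min_contrast_snr: float = DEFAULT_MIN_CONTRAST_SNR,
) -> BinarizedTrace:
    """Binarize a trace into plasma / RBC cycles with Otsu's threshold.

    The threshold is computed on raw counts (one histogram bin per
    observed value; ties toward the lower threshold); cycles at or below
    it are RBC.  Runs shorter than ``min_dip_cycles`` are discarded as
    shot noise.  ``smooth_window`` > 1 applies an edge-corrected moving
    average before thresholding.

    Otsu always finds *a* split, even of a unimodal shot-noise trace, so
    the split is only accepted as RBC passage when the class contrast
    exceeds ``min_contrast_snr`` times the plasma shot noise
    (``sqrt(mean_plasma / smooth_window)`` per sample); below that the
    trace carries no dip evidence and is returned all-plasma with the
    ``no_dip_contrast`` flag — which for a capillary with otherwise clear
    dips is exactly what a stall looks like.  A constant trace likewise
    returns all-plasma, flagged ``constant_trace``.
    """
    counts = tr.counts_per_cycle
    if smooth_window and smooth_window > 1:
        counts = _moving_average(counts, smooth_window)
    flags: list[str] = []
    if np.all(counts == counts[0]):
        return BinarizedTrace(
            np.zeros(counts.size, dtype=bool), float(counts[0]), [], 0.0,
            np.nan, ["constant_trace"],
        )
    thr, sep = otsu_threshold(counts)
    below = counts <= thr
    mu_rbc = float(counts[below].mean())
    mu_plasma = float(counts[~below].mean())
    w_eff = max(int(smooth_window), 1)
    shot = np.sqrt(mu_plasma / w_eff) if mu_plasma > 0 else np.inf
    z = (mu_plasma - mu_rbc) / shot if np.isfinite(shot) and shot > 0 else 0.0
    if z < min_contrast_snr:
        # Otsu found only a noise split.  A real dye-exclusion dip occupying
        # a tiny fraction of the trace can lose the between-class-variance
        # contest to the noise split; rescue it with an absolute criterion:
        # runs at or below half the overall mean are essentially impossible
        # from shot noise at realistic count rates.
        mu = float(counts.mean())
        deep = counts <= 0.5 * mu
        found = np.zeros(counts.size, dtype=bool)
        for start, stop in _runs(deep):
            at_edge = start == 0 or stop == counts.size
            if stop - start >= min_dip_cycles or at_edge:
                found[start:stop] = True
        if not found.any():
            return BinarizedTrace(
                np.zeros(counts.size, dtype=bool), float(thr), [], sep, float(z),
                ["no_dip_contrast"],
            )
        is_rbc = found
        thr = 0.5 * mu
        flags.append("deep_dip_fallback")
    else:
        is_rbc = below.copy()
    if smooth_window and smooth_window > 1 and include_edge_dips:
        # smoothing dilutes 1-2 cycle partial dips at the trace edges below
        # detectability; rescue them from the raw counts at a conservative
        # threshold (half the Otsu level keeps the plasma false-positive
        # rate negligible)
        raw = tr.counts_per_cycle
        i = 0
        while i < raw.size and raw[i] <= thr / 2.0:
            is_rbc[i] = True
            i += 1
        i = raw.size - 1
        while i >= 0 and raw[i] <= thr / 2.0:
            is_rbc[i] = True
            i -= 1
    for start, stop in _runs(is_rbc):
        # partial dips clipped at the trace edges count as RBC passages,
        # so the shot-noise run-length filter exempts edge runs
        at_edge = start == 0 or stop == counts.size
        if stop - start < min_dip_cycles and not at_edge:
            is_rbc[start:stop] = False
    if not include_edge_dips:
        for start, stop in _runs(is_rbc):
            if start == 0 or stop == counts.size:
                is_rbc[start:stop] = False
    intervals = [
        (start * tr.cycle_duration_s, stop * tr.cycle_duration_s)
        for start, stop in _runs(is_rbc)
    ]
    return BinarizedTrace(is_rbc, float(thr), intervals, sep, float(z), flags)


def count_flux(bt: BinarizedTrace, duration_s: float) -> float:
    """Flux = RBC passages per second."""
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    return len(bt.rbc_intervals) / duration_s


def estimate_speed(
    bt: BinarizedTrace, rbc_path_length_um: float = DEFAULT_RBC_PATH_LENGTH_UM
) -> float | None:
    """Speed = assumed RBC path length / median dip dwell time (um/ms).

    The path length an RBC travels across the measurement point is not
    observable from a point measurement; it is an explicit assumption
    parameter (default 6 um, a capillary RBC's scale) reported alongside.
    Returns None when no RBC intervals exist.
    """
    if not bt.rbc_intervals:
        return None
    durations_ms = np.array([(e - s) * 1e3 for s, e in bt.rbc_intervals])
    return float(rbc_path_length_um / np.median(durations_ms))


def qc_measurement(
    tr: IntensityTrace,
    history: list[IntensityTrace] | None = None,
    bt: BinarizedTrace | None = None,
    history_bts: list[BinarizedTrace] | None = None,
    frac_of_baseline: float = DEFAULT_FRAC_OF_BASELINE,
    min_separation: float = DEFAULT_MIN_SEPARATION,
) -> QCResult:
    """Reject visits with a substantial photon-count drop or poor flux SNR.

    Fails when mean counts/cycle fall below ``frac_of_baseline`` times the
    capillary's session median (computed from ``history``), or when RBC
    intervals are claimed but the Otsu between-class separation is below
    ``min_separation``, or when the visit shows no dip evidence at all
    and neither does any other visit of the capillary (``history_bts``):
    a capillary that never shows clear dye-exclusion dips cannot have its
    flux read, whereas a dipless visit in a capillary with otherwise
    clear dips is a genuine zero-flux (stall) observation and passes.
    """
    reasons: list[str] = []
    if history:
        baseline = float(np.median([h.counts_per_cycle.mean() for h in history]))
        if baseline > 0 and tr.counts_per_cycle.mean() < frac_of_baseline * baseline:
            reasons.append("drop_in_photon_counts")
    if bt is None:
        bt = binarize_otsu(tr)
    if bt.rbc_intervals and bt.separation < min_separation:
        reasons.append("low_flux_snr")
    if "no_dip_contrast" in bt.flags or "constant_trace" in bt.flags:
        others = history_bts if history_bts is not None else []
        if not any(o.has_rbc_evidence for o in others):
            reasons.append("no_flux_contrast")
    return QCResult(passed=not reasons, reasons=reasons)
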