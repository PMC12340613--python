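"""Stall events: detection, hypoxia classification, peri-event alignment,
tissue-pO2 comparison, neighbor effects and duration statistics.

A stall is a maximal run of consecutive quality-passing visits with zero
RBC flux.  Stall pO2 is the mean over the event's visits; events are
classified against the hypoxia thresholds (below 10 mmHg cell respiration
becomes oxygen-limited; below 5 mmHg is treated as severe).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .flux import CapillaryTimeSeries

__all__ = [
    "StallEvent",
    "StallComparison",
    "detect_stalls",
    "classify_hypoxia",
    "align_peri_stall",
    "fit_stall_vs_tissue",
    "neighbor_effects",
    "stall_duration_histogram",
]

HYPOXIA_THRESHOLD_MMHG = 10.0
SEVERE_THRESHOLD_MMHG = 5.0


@dataclass
class StallEvent:
    capillary_id: str
    start_visit: int
    end_visit: int                    # inclusive
    visit_indices: list[int]
    duration_s: float                 # n_visits * revisit interval
    stall_po2_mmhg: float             # mean over event visits
    hypoxia_class: str
    pre_po2: np.ndarray               # context visits before (chronological)
    post_po2: np.ndarray
    pre_flux: np.ndarray
    post_flux: np.ndarray
    flags: list[str] = field(default_factory=list)

    @property
    def n_visits(self) -> int:
        return len(self.visit_indices)


@dataclass
class StallComparison:
    """One row per stall event with its flowing-state covariates."""

    table: pd.DataFrame  # stall_po2, tissue_po2, flowing_po2, flowing_flux,
    #                      depth_um, arteriole_dist_um, venule_dist_um, group


def classify_hypoxia(
    stall_po2_mmhg: float,
    hypoxic_below: float = HYPOXIA_THRESHOLD_MMHG,
    severe_below: float = SEVERE_THRESHOLD_MMHG,
) -> str:
    """'severe' if pO2 < 5, 'hypoxic' if < 10, else 'normoxic' (strict <)."""
    if not np.isfinite(stall_po2_mmhg):
        raise ValueError("stall pO2 must be finite")
    if stall_po2_mmhg < severe_below:
        return "severe"
    if stall_po2_mmhg < hypoxic_below:
        return "hypoxic"
    return "normoxic"


def detect_stalls(
    ts: CapillaryTimeSeries,
    revisit_interval_s: float | None = None,
    context_visits: int = 3,
) -> list[StallEvent]:
    """Find maximal runs of zero-flux qc-passing visits.

    Runs separated by at least one flowing visit are distinct events.
    QC-failed visits break runs (conservative: a stall cannot be asserted
    across unmeasurable visits); events adjacent to a qc-failed visit are
    flagged ``boundary_uncertain``.
    """
    df = ts.visits.sort_values("visit_time_s").reset_index(drop=True)
    if revisit_interval_s is None:
        t = df["visit_time_s"].to_numpy()
        revisit_interval_s = float(np.median(np.diff(t))) if t.size > 1 else 1.0
    qc = df["qc_pass"].to_numpy(dtype=bool)
    flux = df["flux_rbc_s"].to_numpy(dtype=float)
    po2 = df["po2_mmhg"].to_numpy(dtype=float)
    vidx = df["visit_index"].to_numpy()

    events: list[StallEvent] = []
    run: list[int] = []

    def close(run: list[int]) -> None:
        if not run:
            return
        rows = np.asarray(run)
        mean_po2 = float(np.nanmean(po2[rows]))
        pre = rows[0] - np.arange(context_visits, 0, -1)
        post = rows[-1] + np.arange(1, context_visits + 1)
        pre = pre[(pre >= 0)]
        post = post[(post < len(df))]
        pre = pre[qc[pre]] if pre.size else pre
        post = post[qc[post]] if post.size else post
        flags = []
        if (rows[0] > 0 and not qc[rows[0] - 1]) or (
            rows[-1] < len(df) - 1 and not qc[rows[-1] + 1]
        ):
            flags.append("boundary_uncertain")
        events.append(
            StallEvent(
                capillary_id=ts.capillary_id,
                start_visit=int(vidx[rows[0]]),
                end_visit=int(vidx[rows[-1]]),
                visit_indices=[int(v) for v in vidx[rows]],
                duration_s=len(rows) * revisit_interval_s,
                stall_po2_mmhg=mean_po2,
                hypoxia_class=classify_hypoxia(mean_po2) if np.isfinite(mean_po2)
                else "unknown",
                pre_po2=po2[pre],
                post_po2=po2[post],
                pre_flux=flux[pre],
                post_flux=flux[post],
                flags=flags,
            )
        )

    for i in range(len(df)):
        if not qc[i]:
            close(run)
            run = []
        elif flux[i] == 0:
            run.append(i)
        else:
            close(run)
            run = []
    close(run)
    return events


def align_peri_stall(
    events: list[StallEvent],
    series: dict[str, CapillaryTimeSeries],
    max_offset: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align pO2 and flux around stall onset, the event collapsed to t=0.

    Per event, offset 0 holds the event-mean pO2 and flux 0; offset -k is
    the k-th qc-passing visit before onset, +k the k-th after the event
    ends.  Returns the per-event long table and a per-offset summary
    (mean, SD, n) across events.  Events at session edges contribute
    partial rows.
    """
    if not events:
        raise ValueError("need at least one event")
    rows = []
    for ev_i, ev in enumerate(events):
        df = series[ev.capillary_id].visits.sort_values("visit_time_s")
        df = df[df["qc_pass"].astype(bool)].reset_index(drop=True)
        pos = df.index[df["visit_index"] == ev.start_visit]
        end_pos = df.index[df["visit_index"] == ev.end_visit]
        if len(pos) == 0 or len(end_pos) == 0:
            continue
        p0, p1 = int(pos[0]), int(end_pos[0])
        rows.append((ev_i, ev.capillary_id, 0, ev.stall_po2_mmhg, 0.0))
        for k in range(1, max_offset + 1):
            if p0 - k >= 0:
                r = df.iloc[p0 - k]
                rows.append((ev_i, ev.capillary_id, -k, r["po2_mmhg"], r["flux_rbc_s"]))
            if p1 + k < len(df):
                r = df.iloc[p1 + k]
                rows.append((ev_i, ev.capillary_id, k, r["po2_mmhg"], r["flux_rbc_s"]))
    aligned = pd.DataFrame(
        rows, columns=["event", "capillary_id", "offset", "po2_mmhg", "flux_rbc_s"]
    )
    summary = (
        aligned.groupby("offset")[["po2_mmhg", "flux_rbc_s"]]
        .agg(["mean", "std", "count"])
        .sort_index()
    )
    return aligned, summary


def fit_stall_vs_tissue(cmp: StallComparison, min_events: int = 3) -> pd.DataFrame:
    """OLS of stall pO2 on flowing-state tissue pO2, per group.

    Returns one row per group with slope, intercept, R^2, slope standard
    error and n.  Raises when a group has fewer than ``min_events``
    events or no variance in tissue pO2.
    """
    out = []
    for group, sub in cmp.table.groupby("group"):
        x = sub["tissue_po2"].to_numpy(dtype=float)
        y = sub["stall_po2"].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < min_events:
            raise ValueError(f"group {group!r} has fewer than {min_events} events")
        if np.var(x) == 0:
            raise ValueError(f"group {group!r} has degenerate tissue-pO2 variance")
        res = stats.linregress(x, y)
        out.append(
            {
                "group": group,
                "slope": res.slope,
                "intercept": res.intercept,
                "r_squared": res.rvalue**2,
                "slope_stderr": res.stderr,
                "n": int(x.size),
            }
        )
    return pd.DataFrame(out)


def neighbor_effects(
    series: dict[str, CapillaryTimeSeries],
    events: list[StallEvent],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Effect of co-measured stalls on capillaries that kept flowing.

    For every capillary with no event of its own, compare its qc-passing
    visits concurrent with any stall event (same visit sweep) against
    visits concurrent with no detected stall anywhere in the session.
    Returns the per-neighbor table (delta pO2, flux ratio, 3D distance to
    the nearest stalling capillary) and the linear fits of delta pO2 and
    flux ratio versus distance.
    """
    stall_caps = {ev.capillary_id for ev in events}
    stall_visits: set[int] = set()
    for ev in events:
        stall_visits.update(ev.visit_indices)

    rows = []
    for cid, ts in series.items():
        if cid in stall_caps:
            continue
        df = ts.visits[ts.visits["qc_pass"].astype(bool)]
        concurrent = df["visit_index"].isin(stall_visits)
        during = df[concurrent]
        ref = df[~concurrent]
        if len(during) == 0 or len(ref) == 0:
            continue
        dist = np.nan
        if ts.position_um is not None:
            ds = [
                float(np.linalg.norm(
                    np.subtract(ts.position_um, series[ev.capillary_id].position_um)
                ))
                for ev in events
                if series[ev.capillary_id].position_um is not None
            ]
            if ds:
                dist = min(ds)
        ref_flux = float(ref["flux_rbc_s"].mean())
        rows.append(
            {
                "capillary_id": cid,
                "po2_during_stall": float(during["po2_mmhg"].mean()),
                "po2_no_stall": float(ref["po2_mmhg"].mean()),
                "flux_during_stall": float(during["flux_rbc_s"].mean()),
                "flux_no_stall": ref_flux,
                "delta_po2_mmhg": float(
                    during["po2_mmhg"].mean() - ref["po2_mmhg"].mean()
                ),
                "flux_ratio": float(during["flux_rbc_s"].mean() / ref_flux)
                if ref_flux > 0
                else np.nan,
                "distance_um": dist,
                "n_during": int(len(during)),
                "n_reference": int(len(ref)),
            }
        )
    table = pd.DataFrame(rows)
    fits = []
    if len(table) >= 3 and table["distance_um"].notna().sum() >= 3:
        for col in ("delta_po2_mmhg", "flux_ratio"):
            sub = table.dropna(subset=["distance_um", col])
            if len(sub) >= 3 and sub["distance_um"].var() > 0:
                res = stats.linregress(sub["distance_um"], sub[col])
                fits.append(
                    {
                        "response": col,
                        "slope": res.slope,
                        "intercept": res.intercept,
                        "r_squared": res.rvalue**2,
                        "n": int(len(sub)),
                    }
                )
    return table, pd.DataFrame(fits)


def stall_duration_histogram(
    events: list[StallEvent], revisit_interval_s: float
) -> pd.DataFrame:
    """Histogram of stall durations in visits and seconds.

    Capillaries stalling multiple times contribute one count per event.
    """
    durations = [ev.n_visits for ev in events]
    if not durations:
        return pd.DataFrame(columns=["n_visits", "duration_s", "count"])
    values, counts = np.unique(durations, return_counts=True)
    return pd.DataFrame(
        {
            "n_visits": values,
            "duration_s": values * revisit_interval_s,
            "count": counts,
        }
    )
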