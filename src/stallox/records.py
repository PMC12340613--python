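"""Core acquisition records.

A phosphorescence lifetime point measurement repeats a short excitation
pulse followed by a photon-counting collection window many times at one
location ("cycles").  Photon arrival times are recorded relative to the
start of each cycle; pooled over cycles they form the phosphorescence
decay, while the per-cycle photon totals form an intensity time course in
which passing red blood cells (which exclude the plasma-borne dye) appear
as dips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionConfig", "PointMeasurement"]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Timing of the repeated excitation/collection cycle at one point.

    Parameters
    ----------
    excitation_window_us:
        Duration of the excitation gate per cycle, microseconds.
    collection_window_us:
        Duration of the photon-counting window per cycle, microseconds.
    n_cycles:
        Cycles pooled into one visit of a point.
    revisit_interval_s:
        Time between successive visits to the same point while the scan
        iterates through the selected set of capillaries.
    n_visits:
        Number of visits per point in a session.
    decay_bin_width_us:
        Quantization of photon arrival times (TCSPC-style binning).

    Defaults give the standard protocol: 1000 cycles of 10 us excitation
    and 290 us collection, i.e. 300 ms per point per visit, revisited
    every ~8 s for ~10 min.
    """

    excitation_window_us: float = 10.0
    collection_window_us: float = 290.0
    n_cycles: int = 1000
    revisit_interval_s: float = 8.0
    n_visits: int = 75
    decay_bin_width_us: float = 0.5

    def __post_init__(self) -> None:
        if self.excitation_window_us <= 0:
            raise ValueError("excitation_window_us must be > 0")
        if self.collection_window_us <= 0:
            raise ValueError("collection_window_us must be > 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.decay_bin_width_us <= 0:
            raise ValueError("decay_bin_width_us must be > 0")

    @property
    def cycle_duration_us(self) -> float:
        return self.excitation_window_us + self.collection_window_us

    @property
    def cycle_duration_s(self) -> float:
        return self.cycle_duration_us * 1e-6

    @property
    def visit_duration_s(self) -> float:
        """Total span of one visit (all cycles), seconds."""
        return self.n_cycles * self.cycle_duration_s

    @property
    def visit_duration_ms(self) -> float:
        return self.visit_duration_s * 1e3


@dataclass
class PointMeasurement:
    """Raw photon data for one visit of one capillary point.

    Photons are stored flat: ``arrival_times_us[i]`` is the arrival time of
    photon *i* within its cycle (microseconds from cycle start, in
    ``[0, cycle_duration_us)``) and ``cycle_index[i]`` is the cycle it
    belongs to.  ``weights`` is ``None`` for counted photons; the
    simulator's expected-value mode instead emits fractional weighted
    photons so that every downstream histogram equals its exact
    expectation.
    """

    capillary_id: str
    visit_index: int
    visit_time_s: float
    arrival_times_us: np.ndarray
    cycle_index: np.ndarray
    acq: AcquisitionConfig
    weights: np.ndarray | None = None
    partial: bool = False
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.arrival_times_us = np.asarray(self.arrival_times_us, dtype=float)
        self.cycle_index = np.asarray(self.cycle_index, dtype=np.int64)
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.arrival_times_us.shape:
                raise ValueError("weights must match arrival_times_us in length")
        if self.arrival_times_us.shape != self.cycle_index.shape:
            raise ValueError("arrival_times_us and cycle_index must have equal length")
        if self.arrival_times_us.size:
            if self.arrival_times_us.min() < 0 or (
                self.arrival_times_us.max() >= self.acq.cycle_duration_us
            ):
                raise ValueError("arrival times must lie within [0, cycle duration)")
            if self.cycle_index.min() < 0 or self.cycle_index.max() >= self.acq.n_cycles:
                raise ValueError("cycle_index out of range for acquisition config")

    @property
    def n_photons(self) -> float:
        if self.weights is not None:
            return float(self.weights.sum())
        return float(self.arrival_times_us.size)

    def counts_per_cycle(self) -> np.ndarray:
        """Photon total per cycle (the intensity time course sample values)."""
        return np.bincount(
            self.cycle_index, weights=self.weights, minlength=self.acq.n_cycles
        ).astype(float)

    def cycles(self) -> list[np.ndarray]:
        """Arrival times split per cycle (convenience view; may be slow)."""
        order = np.argsort(self.cycle_index, kind="stable")
        split_at = np.searchsorted(self.cycle_index[order], np.arange(1, self.acq.n_cycles))
        return np.split(self.arrival_times_us[order], split_at)
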