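"""Phosphorescence decay fitting and Stern-Volmer oxygen conversion.

The pooled arrival-time histogram of one visit is fitted with a single
exponential ``A*exp(-t/tau) + B``; the lifetime ``tau`` maps to pO2 via
the Stern-Volmer relation ``1/tau = 1/tau0 + kq * pO2``, calibrated per
dye batch by an oxygen titration.  The first few microseconds of the
decay are discarded to avoid the electro-optic modulator's response to
the end of the excitation gate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .records import AcquisitionConfig, PointMeasurement

__all__ = [
    "DecayHistogram",
    "SternVolmerCalibration",
    "LifetimeFitResult",
    "build_decay",
    "fit_single_exponential",
    "fit_stern_volmer",
    "lifetime_to_po2",
]

DEFAULT_DISCARD_HEAD_US = 5.0
DEFAULT_MIN_PHOTONS = 500


@dataclass
class DecayHistogram:
    """Pooled decay histogram of one visit.

    ``bin_edges_us`` are decay times measured from the end of the
    excitation window; counts may be fractional for expected-value input.
    """

    bin_edges_us: np.ndarray
    counts: np.ndarray
    n_cycles_pooled: int
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bin_edges_us = np.asarray(self.bin_edges_us, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_edges_us.size != self.counts.size + 1:
            raise ValueError("bin_edges_us must have len(counts)+1 entries")

    @property
    def bin_centers_us(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_us[:-1] + self.bin_edges_us[1:])

    @property
    def n_photons(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class SternVolmerCalibration:
    """Oxygen quenching calibration: ``1/tau = 1/tau0 + kq * pO2``.

    tau0 is the zero-oxygen lifetime (us), kq the quenching constant
    (1/(us*mmHg)).  Calibrations come from a titration experiment
    (:func:`fit_stern_volmer`) or from the simulator; no literature
    constants are assumed.
    """

    tau0_us: float
    kq_per_us_mmhg: float
    valid_range_mmhg: tuple[float, float] = (0.0, 150.0)

    def __post_init__(self) -> None:
        if self.tau0_us <= 0 or self.kq_per_us_mmhg <= 0:
            raise ValueError("tau0 and kq must both be positive")

    def tau_for_po2(self, po2_mmhg):
        """Inverse relation: lifetime (us) at a given pO2 (mmHg)."""
        po2 = np.asarray(po2_mmhg, dtype=float)
        if np.any(po2 < 0):
            raise ValueError("pO2 must be nonnegative")
        tau = 1.0 / (1.0 / self.tau0_us + self.kq_per_us_mmhg * po2)
        return float(tau) if np.isscalar(po2_mmhg) else tau


@dataclass
class LifetimeFitResult:
    tau_us: float
    amplitude: float
    background: float
    fit_residual: float
    n_photons: float
    converged: bool
    flags: list[str] = field(default_factory=list)


def build_decay(
    pm: PointMeasurement,
    discard_head_us: float = DEFAULT_DISCARD_HEAD_US,
    bin_width_us: float | None = None,
) -> DecayHistogram:
    """Pool arrival times of one visit into a uniform decay histogram.

    Arrival times are re-referenced to the end of the excitation window;
    photons inside the excitation window or within ``discard_head_us`` of
    its end are excluded.  Bin width defaults to the acquisition's decay
    bin width.
    """
    if discard_head_us < 0:
        raise ValueError("discard_head_us must be >= 0")
    acq = pm.acq
    w = acq.decay_bin_width_us if bin_width_us is None else float(bin_width_us)
    span = acq.collection_window_us - discard_head_us
    if span <= 0:
        raise ValueError("discard_head_us leaves no collection window")
    n_bins = int(np.floor(span / w + 1e-9))
    edges = discard_head_us + w * np.arange(n_bins + 1)

    decay_t = pm.arrival_times_us - acq.excitation_window_us
    keep = (decay_t >= edges[0]) & (decay_t < edges[-1])
    weights = None if pm.weights is None else pm.weights[keep]
    counts, _ = np.histogram(decay_t[keep], bins=edges, weights=weights)

    flags: list[str] = []
    if pm.arrival_times_us.size == 0:
        flags.append("empty_measurement")
        warnings.warn(
            f"empty point measurement {pm.capillary_id}/{pm.visit_index}", stacklevel=2
        )
    return DecayHistogram(edges, counts.astype(float), acq.n_cycles, flags)


def _initial_guess(t: np.ndarray, c: np.ndarray, fit_background: bool):
    n_tail = max(1, t.size // 10)
    b0 = float(np.median(c[-n_tail:])) if fit_background else 0.0
    pos = c - b0
    use = pos > max(pos.max() * 0.02, 0.0)
    if use.sum() < 3:
        use = pos > 0
    if use.sum() < 2:
        return max(c.max(), 1.0), (t[-1] - t[0]) / 3.0, b0
    # weighted log-linear slope of the background-subtracted head
    tt, yy, ww = t[use], np.log(pos[use]), pos[use]
    wm = ww.sum()
    tbar, ybar = (ww * tt).sum() / wm, (ww * yy).sum() / wm
    denom = (ww * (tt - tbar) ** 2).sum()
    slope = (ww * (tt - tbar) * (yy - ybar)).sum() / denom if denom > 0 else -0.01
    tau0 = -1.0 / slope if slope < 0 else (t[-1] - t[0]) / 3.0
    a0 = float(np.exp(ybar + slope * (t[0] - tbar)) * np.exp(t[0] / tau0))
    return max(a0, 1e-6), float(np.clip(tau0, 0.5, 1e4)), b0


def fit_single_exponential(
    h: DecayHistogram,
    min_photons: float = DEFAULT_MIN_PHOTONS,
    objective: str = "poisson",
    fit_background: bool = True,
    tau_bounds_us: tuple[float, float] = (0.5, 2000.0),
) -> LifetimeFitResult:
    """Fit ``A*exp(-t/tau) + B`` to a pooled decay histogram.

    The default objective is the Poisson negative log-likelihood, the
    correct noise model for photon counting; ``objective="lsq"`` gives
    ordinary least squares.  Histograms with fewer than ``min_photons``
    photons are rejected as not converged (quality control for
    low-signal visits).
    """
    t = h.bin_centers_us
    c = h.counts
    n = float(c.sum())
    if n < min_photons:
        return LifetimeFitResult(
            np.nan, np.nan, np.nan, np.nan, n, converged=False, flags=["low_photons"]
        )
    a0, tau0, b0 = _initial_guess(t, c, fit_background)
    tau0 = float(np.clip(tau0, *tau_bounds_us))

    if objective == "lsq":

        def model(tt, a, tau, b):
            return a * np.exp(-tt / tau) + b

        p0 = [a0, tau0, b0] if fit_background else [a0, tau0]
        try:
            if fit_background:
                popt, _ = optimize.curve_fit(
                    model, t, c, p0=p0,
                    bounds=([0, tau_bounds_us[0], 0], [np.inf, tau_bounds_us[1], np.inf]),
                    maxfev=20000,
                )
                a, tau, b = popt
            else:
                popt, _ = optimize.curve_fit(
                    lambda tt, a, tau: model(tt, a, tau, 0.0), t, c, p0=p0,
                    bounds=([0, tau_bounds_us[0]], [np.inf, tau_bounds_us[1]]),
                    maxfev=20000,
                )
                a, tau = popt
                b = 0.0
        except RuntimeError:
            return LifetimeFitResult(
                np.nan, np.nan, np.nan, np.nan, n, converged=False, flags=["fit_failed"]
            )
        mu = model(t, a, tau, b)
        resid = float(np.sum((c - mu) ** 2) / max(t.size - (3 if fit_background else 2), 1))
        return LifetimeFitResult(float(tau), float(a), float(b), resid, n, True)

    if objective != "poisson":
        raise ValueError(f"unknown objective {objective!r}")

    eps = 1e-300

    def nll_grad(x):
        la, ltau = x[0], x[1]
        b = x[2] if fit_background else 0.0
        a, tau = np.exp(la), np.exp(ltau)
        e = a * np.exp(-t / tau)
        mu = e + b + eps
        r = 1.0 - c / mu
        f = float(np.sum(mu - c * np.log(mu)))
        g_la = float(np.sum(r * e))                 # d/d logA
        g_ltau = float(np.sum(r * e * t / tau))     # d/d logTau
        if fit_background:
            return f, np.array([g_la, g_ltau, float(np.sum(r))])
        return f, np.array([g_la, g_ltau])

    x0 = [np.log(a0), np.log(tau0)] + ([max(b0, 0.0)] if fit_background else [])
    bounds = [(None, None), (np.log(tau_bounds_us[0]), np.log(tau_bounds_us[1]))]
    if fit_background:
        bounds.append((0.0, None))
    res = optimize.minimize(
        nll_grad, np.asarray(x0, dtype=float), jac=True, method="L-BFGS-B",
        bounds=bounds, options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
    )
    a, tau = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
    b = float(res.x[2]) if fit_background else 0.0
    mu = a * np.exp(-t / tau) + b
    with np.errstate(divide="ignore", invalid="ignore"):
        dev_terms = np.where(c > 0, c * np.log(c / np.maximum(mu, eps)) - (c - mu), mu)
    deviance = float(2.0 * dev_terms.sum())
    flags: list[str] = []
    # L-BFGS-B occasionally ends with a failed line search ("ABNORMAL") at
    # what is numerically the optimum; a near-zero PROJECTED gradient (zero
    # at active bounds pushing outward) is the real convergence criterion
    proj = np.array(res.jac, dtype=float)
    for i, (lo, hi) in enumerate(bounds):
        if lo is not None and res.x[i] <= lo + 1e-12 and proj[i] > 0:
            proj[i] = 0.0
        if hi is not None and res.x[i] >= hi - 1e-12 and proj[i] < 0:
            proj[i] = 0.0
    grad_ok = float(np.max(np.abs(proj))) < 1e-2 * max(1.0, np.sqrt(n))
    converged = (bool(res.success) or grad_ok) and np.isfinite(tau)
    if not res.success and grad_ok:
        flags.append("linesearch_stalled")
    if not np.isfinite(res.fun):
        raise FloatingPointError("non-finite optimum in lifetime fit")
    at_bound = tau <= tau_bounds_us[0] * 1.001 or tau >= tau_bounds_us[1] * 0.999
    if at_bound:
        converged = False
        flags.append("tau_at_bound")
    return LifetimeFitResult(
        tau, a, b, deviance / max(t.size - len(res.x), 1), n, converged, flags
    )


def fit_stern_volmer(
    titration: list[tuple[float, float]], monotone_tol: float = 0.05
) -> SternVolmerCalibration:
    """Calibrate tau0 and kq from an oxygen titration.

    ``titration`` holds ``(pO2 mmHg, tau us)`` pairs; the fit is linear in
    ``1/tau`` versus pO2 (slope = kq, intercept = 1/tau0).  Raises on a
    single pO2 level or a relation that is not decreasing in tau beyond
    ``monotone_tol`` (relative).
    """
    arr = np.asarray(titration, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("titration must hold >= 2 (pO2, tau) pairs")
    po2, tau = arr[:, 0], arr[:, 1]
    if np.any(tau <= 0):
        raise ValueError("lifetimes must be positive")
    if np.unique(po2).size < 2:
        raise ValueError("titration needs >= 2 distinct pO2 levels")
    order = np.argsort(po2)
    tau_sorted = tau[order]
    rel_increase = np.diff(tau_sorted) / tau_sorted[:-1]
    if np.any(rel_increase > monotone_tol):
        raise ValueError("titration not monotone: tau must decrease with pO2")
    slope, intercept = np.polyfit(po2, 1.0 / tau, 1)
    if slope <= 0 or intercept <= 0:
        raise ValueError("degenerate titration: fitted kq or 1/tau0 not positive")
    return SternVolmerCalibration(
        tau0_us=1.0 / intercept,
        kq_per_us_mmhg=float(slope),
        valid_range_mmhg=(float(po2.min()), float(po2.max())),
    )


def lifetime_to_po2(
    tau_us,
    calib: SternVolmerCalibration,
    clip_negative: bool = True,
    out_of_range_tol: float = 0.05,
    return_flags: bool = False,
):
    """Convert lifetime(s) to pO2 via ``pO2 = (1/tau - 1/tau0)/kq``.

    Lifetimes slightly above tau0 (noise around zero oxygen) give small
    negative values which are clipped to 0 and flagged; lifetimes above
    ``tau0*(1+out_of_range_tol)`` are flagged out-of-range and yield NaN.
    """
    tau = np.asarray(tau_us, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau must be positive")
    po2 = (1.0 / tau - 1.0 / calib.tau0_us) / calib.kq_per_us_mmhg
    out_of_range = tau > calib.tau0_us * (1.0 + out_of_range_tol)
    clipped = (po2 < 0) & ~out_of_range
    po2 = np.where(out_of_range, np.nan, po2)
    if clip_negative:
        po2 = np.where(clipped, 0.0, po2)
    if np.isscalar(tau_us):
        po2 = float(po2)
    if return_flags:
        return po2, {"clipped": clipped, "out_of_range": out_of_range}
    return po2


def po2_from_measurement(
    pm: PointMeasurement,
    calib: SternVolmerCalibration,
    discard_head_us: float = DEFAULT_DISCARD_HEAD_US,
    min_photons: float = DEFAULT_MIN_PHOTONS,
    **fit_kwargs,
) -> tuple[float, LifetimeFitResult]:
    """Convenience: decay histogram -> lifetime fit -> pO2 for one visit."""
    fit = fit_single_exponential(
        build_decay(pm, discard_head_us=discard_head_us),
        min_photons=min_photons,
        **fit_kwargs,
    )
    if not fit.converged:
        return np.nan, fit
    return lifetime_to_po2(fit.tau_us, calib), fit
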