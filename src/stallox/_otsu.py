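"""Shared Otsu thresholding.

Used both for binarizing intensity time courses into plasma/RBC phases and
for binarizing angiogram volumes.  For integer-like data the histogram uses
one bin per observed value (full resolution); otherwise a fixed number of
uniform bins.  Ties in between-class variance break toward the lower
threshold.
"""

from __future__ import annotations

import numpy as np

__all__ = ["otsu_threshold"]


def otsu_threshold(
    values: np.ndarray, n_bins: int = 256, max_exact_levels: int = 4096
) -> tuple[float, float]:
    """Return ``(threshold, separation)``.

    The threshold maximizes the between-class variance of the split
    ``x <= threshold`` vs ``x > threshold``; candidates are the observed
    values when there are at most ``max_exact_levels`` distinct ones,
    else ``n_bins`` uniform histogram bin centers.  ``separation`` is the
    between-class variance at the chosen split divided by the total
    variance (1 for perfectly bimodal data, 0 for constant data).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot threshold empty data")
    levels, counts = np.unique(x, return_counts=True)
    if levels.size == 1:
        return float(levels[0]), 0.0
    if levels.size > max_exact_levels:
        hist, edges = np.histogram(x, bins=n_bins)
        levels = 0.5 * (edges[:-1] + edges[1:])
        counts = hist.astype(float)
        keep = counts > 0
        levels, counts = levels[keep], counts[keep]

    w = counts / counts.sum()
    cw = np.cumsum(w)                  # class-0 weight for split at each level
    cmean = np.cumsum(w * levels)      # class-0 weighted partial mean
    mu_total = cmean[-1]
    # splits after levels[k] for k = 0..K-2 (both classes nonempty)
    w0, m0 = cw[:-1], cmean[:-1]
    w1 = 1.0 - w0
    mu0 = m0 / w0
    mu1 = (mu_total - m0) / w1
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    k = int(np.argmax(sigma_b))        # argmax takes first maximum -> lower threshold
    total_var = float(np.sum(w * (levels - mu_total) ** 2))
    separation = float(sigma_b[k] / total_var) if total_var > 0 else 0.0
    return float(levels[k]), separation
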