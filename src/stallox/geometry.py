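"""Vessel geometry around measurement points from angiogram volumes.

Subvolumes cropped around each point are median-filtered, binarized
(Otsu) and skeletonized; local vessel density is the histogram of
Euclidean distances from the point to every vessel-classified voxel
(1-um bins, counts in arbitrary units), and proximity to labeled
arterioles/venules is the distance to the nearest labeled voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import skeletonize

from ._otsu import otsu_threshold

__all__ = [
    "AngiogramVolume",
    "DensityHistogram",
    "crop_subvolume",
    "preprocess_and_binarize",
    "skeletonize_mask",
    "density_histogram",
    "nearest_large_vessel",
    "compare_density_by_class",
]

DEFAULT_HALF_EXTENT_VOX = 75
DEFAULT_DENSITY_BIN_UM = 1.0
LABEL_CODES = {"arteriole": 1, "venule": 2}


@dataclass
class AngiogramVolume:
    """3D fluorescence volume, zyx order, 0-based voxel indices.

    ``voxel_size_um`` may be anisotropic; distances are computed between
    voxel centers with anisotropy honored.  ``origin_vox`` records where
    this (possibly cropped) array sits in its parent volume.
    """

    intensity: np.ndarray
    voxel_size_um: tuple[float, float, float]
    large_vessel_labels: np.ndarray | None = None
    origin_vox: tuple[int, int, int] = (0, 0, 0)
    clipped: bool = False
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be a 3D array")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        if (
            self.large_vessel_labels is not None
            and self.large_vessel_labels.shape != self.intensity.shape
        ):
            raise ValueError("labels must align with the intensity grid")


@dataclass
class DensityHistogram:
    """Vessel-voxel counts vs distance from a measurement point."""

    bin_edges_um: np.ndarray
    counts: np.ndarray                  # arbitrary units (voxel counts)
    point_vox: tuple[int, int, int]
    subvolume_origin_vox: tuple[int, int, int]
    subvolume_shape: tuple[int, int, int]
    clipped: bool = False

    @property
    def bin_centers_um(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_um[:-1] + self.bin_edges_um[1:])


def crop_subvolume(
    vol: AngiogramVolume,
    point_vox: tuple[int, int, int],
    half_extent_vox: int = DEFAULT_HALF_EXTENT_VOX,
) -> tuple[AngiogramVolume, tuple[int, int, int]]:
    """Crop ``half_extent_vox`` voxels in all directions around a point.

    Returns the cropped volume and the point's coordinates within it.
    Crops are clipped at the volume boundary (``clipped`` flag set); the
    actual origin is recorded for provenance.
    """
    shape = vol.intensity.shape
    p = tuple(int(c) for c in point_vox)
    if any(c < 0 or c >= s for c, s in zip(p, shape)):
        raise ValueError(f"point {p} outside volume of shape {shape}")
    lo = [max(c - half_extent_vox, 0) for c in p]
    hi = [min(c + half_extent_vox + 1, s) for c, s in zip(p, shape)]
    clipped = any(
        c - half_extent_vox < 0 or c + half_extent_vox + 1 > s
        for c, s in zip(p, shape)
    )
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    labels = None if vol.large_vessel_labels is None else vol.large_vessel_labels[sl]
    sub = AngiogramVolume(
        intensity=vol.intensity[sl],
        voxel_size_um=vol.voxel_size_um,
        large_vessel_labels=labels,
        origin_vox=tuple(int(vol.origin_vox[i] + lo[i]) for i in range(3)),
        clipped=clipped or vol.clipped,
        flags=(["clipped"] if clipped else []) + list(vol.flags),
    )
    return sub, tuple(p[i] - lo[i] for i in range(3))


def preprocess_and_binarize(
    vol: AngiogramVolume, median_size: int = 3
) -> tuple[np.ndarray, list[str]]:
    """3x3x3 median filter (reflective boundaries) then global Otsu.

    Returns the binary vessel mask and any flags; a constant volume has
    no threshold and yields an empty mask with a flag.
    """
    smoothed = ndimage.median_filter(
        vol.intensity.astype(float), size=median_size, mode="reflect"
    )
    if np.all(smoothed == smoothed.flat[0]):
        return np.zeros(vol.intensity.shape, dtype=bool), ["constant_volume"]
    thr, _ = otsu_threshold(smoothed)
    return smoothed > thr, []


def skeletonize_mask(mask: np.ndarray) -> np.ndarray:
    """3D thinning to one-voxel-wide centerlines; skeleton is within mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    return skeletonize(mask).astype(bool)


def _voxel_distances_um(
    coords: np.ndarray, point_vox, voxel_size_um
) -> np.ndarray:
    delta = (coords - np.asarray(point_vox)) * np.asarray(voxel_size_um)
    return np.sqrt((delta**2).sum(axis=1))


def density_histogram(
    point_vox: tuple[int, int, int],
    mask: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    bin_width_um: float = DEFAULT_DENSITY_BIN_UM,
    subvolume_origin_vox: tuple[int, int, int] = (0, 0, 0),
    clipped: bool = False,
) -> DensityHistogram:
    """Histogram of distances from the point to every vessel voxel.

    Distances are anisotropy-corrected Euclidean distances between voxel
    centers, binned at ``bin_width_um`` (default 1 um).  The histogram
    total equals the number of vessel voxels in the subvolume, exactly.
    """
    if bin_width_um <= 0:
        raise ValueError("bin_width_um must be > 0")
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask)
    if coords.size == 0:
        edges = bin_width_um * np.arange(2)
        return DensityHistogram(
            edges, np.zeros(1), tuple(point_vox), tuple(subvolume_origin_vox),
            mask.shape, clipped,
        )
    d = _voxel_distances_um(coords, point_vox, voxel_size_um)
    n_bins = max(int(np.floor(d.max() / bin_width_um)) + 1, 1)
    edges = bin_width_um * np.arange(n_bins + 1)
    counts, _ = np.histogram(d, bins=edges)
    return DensityHistogram(
        edges, counts.astype(float), tuple(point_vox),
        tuple(subvolume_origin_vox), mask.shape, clipped,
    )


def nearest_large_vessel(
    point_vox: tuple[int, int, int],
    labels: np.ndarray,
    voxel_size_um: tuple[float, float, float],
) -> dict[str, float | None]:
    """Distance (um) from the point to the nearest arteriole/venule voxel.

    Distances are to the vessel edge, i.e. the nearest labeled voxel,
    not to a centerline.  A label absent from the volume yields None.
    """
    labels = np.asarray(labels)
    out: dict[str, float | None] = {}
    for name, code in LABEL_CODES.items():
        coords = np.argwhere(labels == code)
        if coords.size == 0:
            out[name] = None
            continue
        out[name] = float(_voxel_distances_um(coords, point_vox, voxel_size_um).min())
    return out


def compare_density_by_class(
    histograms: list[DensityHistogram], classes: list[str]
) -> pd.DataFrame:
    """Mean (and SD) density curve per hypoxia class.

    Histograms of different radial extent are aligned on their common
    1-um grid; shorter histograms contribute zero counts beyond their
    last bin (no vessel voxels there).  Returns a long DataFrame with
    columns class, bin_center_um, mean_count, sd_count, n.
    """
    if len(histograms) != len(classes):
        raise ValueError("need one class per histogram")
    if not histograms:
        raise ValueError("no histograms given")
    widths = {float(h.bin_edges_um[1] - h.bin_edges_um[0]) for h in histograms}
    if len(widths) != 1:
        raise ValueError("histograms must share a bin width")
    width = widths.pop()
    n_max = max(h.counts.size for h in histograms)
    rows = []
    present = sorted(set(classes))
    for cls in present:
        stack = np.zeros((classes.count(cls), n_max))
        k = 0
        for h, c in zip(histograms, classes):
            if c != cls:
                continue
            stack[k, : h.counts.size] = h.counts
            k += 1
        centers = width * (np.arange(n_max) + 0.5)
        for j in range(n_max):
            rows.append(
                {
                    "class": cls,
                    "bin_center_um": centers[j],
                    "mean_count": float(stack[:, j].mean()),
                    "sd_count": float(stack[:, j].std(ddof=1)) if k > 1 else np.nan,
                    "n": k,
                }
            )
    return pd.DataFrame(rows)
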