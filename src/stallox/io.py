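"""File formats: the photon-record container (HDF5), CSV tables with
provenance headers, and angiogram TIFF volumes with a JSON sidecar.

The container replaces vendor binary photon-counting files with an open,
self-describing layout::

    /                   attrs: schema_version, acquisition (JSON), metadata (JSON)
    /capillaries/<id>/visit_<k>
                        datasets: arrival_times_us, cycle_index[, weights]
                        attrs: visit_index, visit_time_s, partial

A plain-text fallback (one CSV of arrival times per visit) is provided for
inspection.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .config import RunConfig
from .records import AcquisitionConfig, PointMeasurement
from .simkit import SyntheticAngiogram

__all__ = [
    "SCHEMA_VERSION",
    "write_container",
    "read_container",
    "write_visit_csv",
    "read_visit_csv",
    "write_table",
    "read_table",
    "write_angiogram",
    "read_angiogram",
]

SCHEMA_VERSION = "stallox-photon-1"


def _check_consistent_acq(measurements: dict[str, list[PointMeasurement]]) -> AcquisitionConfig:
    acqs = {pm.acq for pms in measurements.values() for pm in pms}
    if len(acqs) > 1:
        raise ValueError("mixed acquisition configs within one session are not allowed")
    if not acqs:
        raise ValueError("empty session: provide the acquisition config explicitly")
    return acqs.pop()


def write_container(
    measurements: dict[str, list[PointMeasurement]],
    path,
    acq: AcquisitionConfig | None = None,
    metadata: dict | None = None,
) -> None:
    """Write a session of photon records; lossless for arrival times."""
    if acq is None:
        acq = _check_consistent_acq(measurements)
    elif measurements and any(pms for pms in measurements.values()):
        found = _check_consistent_acq(measurements)
        if found != acq:
            raise ValueError("acq argument disagrees with the measurements")
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["acquisition"] = json.dumps(dataclasses.asdict(acq))
        f.attrs["metadata"] = json.dumps(metadata or {})
        caps = f.create_group("capillaries")
        for cid, pms in measurements.items():
            g = caps.create_group(str(cid))
            for pm in pms:
                vg = g.create_group(f"visit_{pm.visit_index:06d}")
                vg.create_dataset("arrival_times_us", data=pm.arrival_times_us,
                                  compression="gzip")
                vg.create_dataset("cycle_index", data=pm.cycle_index,
                                  compression="gzip")
                if pm.weights is not None:
                    vg.create_dataset("weights", data=pm.weights, compression="gzip")
                vg.attrs["visit_index"] = pm.visit_index
                vg.attrs["visit_time_s"] = pm.visit_time_s
                vg.attrs["partial"] = pm.partial


def read_container(path) -> tuple[dict[str, list[PointMeasurement]], AcquisitionConfig, dict]:
    """Read a photon-record container written by :func:`write_container`."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported container schema {version!r}; expected {SCHEMA_VERSION!r}"
            )
        acq = AcquisitionConfig(**json.loads(f.attrs["acquisition"]))
        metadata = json.loads(f.attrs["metadata"])
        measurements: dict[str, list[PointMeasurement]] = {}
        for cid, g in f["capillaries"].items():
            pms = []
            for name in sorted(g):
                vg = g[name]
                weights = vg["weights"][()] if "weights" in vg else None
                pms.append(
                    PointMeasurement(
                        capillary_id=cid,
                        visit_index=int(vg.attrs["visit_index"]),
                        visit_time_s=float(vg.attrs["visit_time_s"]),
                        arrival_times_us=vg["arrival_times_us"][()],
                        cycle_index=vg["cycle_index"][()],
                        acq=acq,
                        weights=weights,
                        partial=bool(vg.attrs.get("partial", False)),
                    )
                )
            measurements[cid] = pms
    return measurements, acq, metadata


def write_visit_csv(pm: PointMeasurement, path) -> None:
    """Plain-text fallback: one CSV of photon records for one visit."""
    df = pd.DataFrame(
        {"cycle_index": pm.cycle_index, "arrival_time_us": pm.arrival_times_us}
    )
    if pm.weights is not None:
        df["weight"] = pm.weights
    with open(path, "w") as fh:
        fh.write(
            f"# stallox visit capillary_id={pm.capillary_id} "
            f"visit_index={pm.visit_index} visit_time_s={pm.visit_time_s}\n"
        )
        df.to_csv(fh, index=False)


def read_visit_csv(path, acq: AcquisitionConfig) -> PointMeasurement:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# stallox visit"):
            raise ValueError("not a stallox visit CSV")
        fields = dict(kv.split("=") for kv in header.split()[3:])
        df = pd.read_csv(fh)
    return PointMeasurement(
        capillary_id=fields["capillary_id"],
        visit_index=int(fields["visit_index"]),
        visit_time_s=float(fields["visit_time_s"]),
        arrival_times_us=df["arrival_time_us"].to_numpy(),
        cycle_index=df["cycle_index"].to_numpy(),
        acq=acq,
        weights=df["weight"].to_numpy() if "weight" in df else None,
    )


def write_table(df: pd.DataFrame, path, config: RunConfig | None = None) -> None:
    """CSV with a provenance comment header carrying the RunConfig hash."""
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# run_config_hash: {config.hash()}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_angiogram(angio: SyntheticAngiogram, base_path) -> None:
    """Multi-page TIFFs (volume, truth mask, labels) plus a JSON sidecar."""
    base = Path(base_path)
    tifffile.imwrite(base.with_suffix(".tif"), angio.volume)
    tifffile.imwrite(
        base.parent / (base.stem + "_mask.tif"),
        angio.vessel_truth_mask.astype(np.uint8),
    )
    tifffile.imwrite(base.parent / (base.stem + "_labels.tif"), angio.large_vessel_labels)
    sidecar = {
        "voxel_size_um": list(angio.voxel_size_um),
        "label_codes": SyntheticAngiogram.LABELS,
        "measurement_points": [list(p) for p in angio.measurement_points],
        "centerline_truth": angio.centerline_truth.tolist(),
    }
    with open(base.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh)


def read_angiogram(base_path) -> SyntheticAngiogram:
    base = Path(base_path)
    with open(base.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    return SyntheticAngiogram(
        volume=tifffile.imread(base.with_suffix(".tif")),
        voxel_size_um=tuple(sidecar["voxel_size_um"]),
        vessel_truth_mask=tifffile.imread(base.parent / (base.stem + "_mask.tif")).astype(bool),
        centerline_truth=np.asarray(sidecar["centerline_truth"], dtype=int).reshape(-1, 3),
        large_vessel_labels=tifffile.imread(base.parent / (base.stem + "_labels.tif")),
        measurement_points=[tuple(p) for p in sidecar["measurement_points"]],
    )
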