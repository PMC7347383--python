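"""File formats: TIFF volumes with JSON sidecars, SWC centerlines,
ground-truth JSON, LH series CSV, calibration-profile CSV and report CSVs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simulate_exm import GeneratorTruth, ImageVolume
from .simulate_lh import LHSeries, SecretionTruth
from .synapses import IntensityProfile

__all__ = [
    "save_volume", "load_volume",
    "write_swc", "read_swc",
    "write_truth", "read_truth",
    "write_lh_csv", "read_lh_csv",
    "write_secretion_truth", "read_secretion_truth",
    "read_profiles_csv", "write_profiles_csv",
    "write_appositions_csv",
]


def save_volume(volume: ImageVolume, path) -> None:
    """Write a volume as a multi-page TIFF (pages z-major, channels
    interleaved within each z) plus a ``<path>.json`` calibration sidecar."""
    path = Path(path)
    pages = np.transpose(volume.voxels, (1, 0, 2, 3))  # (z, c, y, x)
    tifffile.imwrite(path, pages.astype(np.float32))
    sidecar = {
        "voxel_xy_um_post": volume.voxel_xy,
        "voxel_z_um_post": volume.voxel_z,
        "expansion_factor": volume.expansion_factor,
        "channel_names": list(volume.channel_names),
        "page_order": "z-major, channel-interleaved",
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2))


def load_volume(path) -> ImageVolume:
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim != 4:
        raise ValueError("expected a (z, c, y, x) multi-page TIFF")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ImageVolume(voxels=np.transpose(pages, (1, 0, 2, 3)),
                       voxel_xy=meta["voxel_xy_um_post"],
                       voxel_z=meta["voxel_z_um_post"],
                       expansion_factor=meta["expansion_factor"],
                       channel_names=tuple(meta["channel_names"]))


def write_swc(centerline: np.ndarray, path, radius: float = 1.0) -> None:
    """Write a polyline as SWC (um post-expansion, 1-based node ids,
    type 3 = dendrite)."""
    lines = ["# id type x y z radius parent"]
    for i, (x, y, z) in enumerate(np.asarray(centerline, dtype=float), start=1):
        parent = i - 1 if i > 1 else -1
        lines.append(f"{i} 3 {x:.4f} {y:.4f} {z:.4f} {radius:.4f} {parent}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_swc(path) -> np.ndarray:
    pts = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split()
        pts.append([float(f[2]), float(f[3]), float(f[4])])
    if len(pts) < 2:
        raise ValueError("SWC centerline needs at least 2 nodes")
    return np.asarray(pts)


def write_truth(truth: GeneratorTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2))


def read_truth(path) -> GeneratorTruth:
    d = json.loads(Path(path).read_text())
    recs = [{**r, "centroid_um_post": np.asarray(r["centroid_um_post"])}
            for r in d["punctum_records"]]
    return GeneratorTruth(
        synapse_positions=np.asarray(d["synapse_positions_um_pre"]),
        decoy_positions=np.asarray(d["decoy_positions_um_pre"]),
        punctum_records=recs)


def write_lh_csv(series_list: list[LHSeries], path) -> None:
    """Long-format CSV: one row per sample, the time column named
    ``time_min`` (pulse mode) or ``clock_hour`` (surge mode)."""
    modes = {s.mode for s in series_list}
    if len(modes) != 1:
        raise ValueError("all series in one file must share a mode")
    time_col = "time_min" if modes == {"pulse"} else "clock_hour"
    frames = [pd.DataFrame({time_col: s.times, "lh_ng_per_ml": s.lh,
                            "animal_id": s.animal_id}) for s in series_list]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_lh_csv(path) -> list[LHSeries]:
    df = pd.read_csv(path)
    if "time_min" in df.columns:
        time_col, mode = "time_min", "pulse"
    elif "clock_hour" in df.columns:
        time_col, mode = "clock_hour", "surge"
    else:
        raise ValueError("expected a time_min or clock_hour column")
    if "animal_id" not in df.columns:
        df["animal_id"] = "animal_1"
    out = []
    for aid, g in df.groupby("animal_id", sort=False):
        g = g.sort_values(time_col)
        out.append(LHSeries(times=g[time_col].to_numpy(),
                            lh=g["lh_ng_per_ml"].to_numpy(),
                            animal_id=str(aid), mode=mode))
    return out


def write_secretion_truth(truths: dict[str, SecretionTruth], path) -> None:
    Path(path).write_text(json.dumps(
        {k: v.to_dict() for k, v in truths.items()}, indent=2))


def read_secretion_truth(path) -> dict[str, SecretionTruth]:
    d = json.loads(Path(path).read_text())
    return {k: SecretionTruth(
        event_times=np.asarray(v["event_times_min"]),
        event_amplitudes=np.asarray(v["event_amplitudes_ng_per_ml"]))
        for k, v in d.items()}


def write_profiles_csv(profiles: list[IntensityProfile], path) -> None:
    """Calibration-profile CSV: position_um, cyto, presyn, axis, profile_id."""
    frames = []
    for i, p in enumerate(profiles):
        frames.append(pd.DataFrame({
            "profile_id": i, "position_um": p.positions,
            "cyto": p.cyto, "presyn": p.presyn, "axis": p.axis}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_profiles_csv(path) -> list[IntensityProfile]:
    df = pd.read_csv(path)
    out = []
    for _, g in df.groupby("profile_id", sort=True):
        g = g.sort_values("position_um")
        out.append(IntensityProfile(positions=g["position_um"].to_numpy(),
                                    cyto=g["cyto"].to_numpy(),
                                    presyn=g["presyn"].to_numpy(),
                                    axis=str(g["axis"].iloc[0])))
    return out


def write_appositions_csv(rows: list[dict], path) -> None:
    """Flat per-apposition table (segment, arc position, orientation,
    overlap, call)."""
    cols = ["segment_id", "arc_length_um", "orientation", "membrane_gap_um",
            "overlap_pre_um", "overlap_post_um", "is_synapse",
            "diameter_um_pre"]
    pd.DataFrame([{c: r[c] for c in cols} for r in rows]).to_csv(
        path, index=False)
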