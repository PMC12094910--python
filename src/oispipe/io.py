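"""Readers and writers for the on-disk formats the pipeline exchanges.

A reflectance stack lives in a directory with one multi-page TIFF per
wavelength plus a ``sidecar.json`` carrying acquisition metadata and trigger
times; hemoglobin maps are one TIFF per chromophore with their own sidecar.
ROI masks are single-channel PNG label images with a JSON provenance record;
locomotion traces and trial tables are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .errors import InputError
from .roi import RoiSet
from .spectroscopy import HemoMaps, ReflectanceStack
from .trials import LocomotionTrace

SIDECAR_FIELDS = (
    "wavelengths_nm",
    "frame_rate_hz",
    "pixel_size_um",
    "trigger_times_s",
    "stim_duration_s",
)


def write_stack(path, stack: ReflectanceStack) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, wl in enumerate(stack.wavelengths_nm):
        tifffile.imwrite(path / f"wl_{int(round(wl)):04d}.tif", stack.data[i])
    sidecar = {
        "wavelengths_nm": stack.wavelengths_nm.tolist(),
        "frame_rate_hz": float(stack.frame_rate_hz),
        "pixel_size_um": float(stack.pixel_size_um),
        "trigger_times_s": stack.trigger_times_s.tolist(),
        "stim_duration_s": float(stack.stim_duration_s),
        "animal": stack.animal,
        "group": stack.group,
        "session": stack.session,
    }
    with open(path / "sidecar.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_stack(path) -> ReflectanceStack:
    path = Path(path)
    sidecar_path = path / "sidecar.json"
    if not sidecar_path.exists():
        raise InputError(f"missing sidecar.json in {path}")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    for fld in SIDECAR_FIELDS:
        if fld not in meta:
            raise InputError(f"sidecar {sidecar_path} lacks required field {fld!r}")
    planes = []
    for wl in meta["wavelengths_nm"]:
        f = path / f"wl_{int(round(wl)):04d}.tif"
        if not f.exists():
            raise InputError(f"missing wavelength image {f}")
        planes.append(tifffile.imread(f))
    data = np.stack(planes)
    return ReflectanceStack(
        data=data,
        wavelengths_nm=np.asarray(meta["wavelengths_nm"], dtype=float),
        frame_rate_hz=meta["frame_rate_hz"],
        pixel_size_um=meta["pixel_size_um"],
        trigger_times_s=np.asarray(meta["trigger_times_s"], dtype=float),
        stim_duration_s=meta["stim_duration_s"],
        animal=meta.get("animal", ""),
        group=meta.get("group", ""),
        session=meta.get("session", ""),
    )


def write_hemomaps(path, hemo: HemoMaps) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name in ("dhbo", "dhbr", "dhbt"):
        tifffile.imwrite(path / f"{name}.tif", getattr(hemo, name))
    with open(path / "sidecar.json", "w") as fh:
        json.dump(
            {
                "frame_rate_hz": float(hemo.frame_rate_hz),
                "baseline_window": list(hemo.baseline_window),
            },
            fh,
        )


def read_hemomaps(path) -> HemoMaps:
    path = Path(path)
    with open(path / "sidecar.json") as fh:
        meta = json.load(fh)
    arrays = {
        name: tifffile.imread(path / f"{name}.tif")
        for name in ("dhbo", "dhbr", "dhbt")
    }
    return HemoMaps(
        frame_rate_hz=meta["frame_rate_hz"],
        baseline_window=tuple(meta["baseline_window"]),
        **arrays,
    )


def write_roiset(path, rois: RoiSet) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, mask in rois.masks.items():
        Image.fromarray((mask.astype(np.uint8)) * 255).save(path / f"{name}.png")
    with open(path / "provenance.json", "w") as fh:
        json.dump(rois.provenance, fh, indent=1)


def read_roiset(path) -> RoiSet:
    path = Path(path)
    masks: Dict[str, np.ndarray] = {}
    for png in sorted(path.glob("*.png")):
        masks[png.stem] = np.asarray(Image.open(png)) > 0
    if not masks:
        raise InputError(f"no mask PNGs found in {path}")
    prov_path = path / "provenance.json"
    provenance = {}
    if prov_path.exists():
        with open(prov_path) as fh:
            provenance = json.load(fh)
    return RoiSet(masks=masks, provenance=provenance)


def write_locomotion(path, loco: LocomotionTrace) -> None:
    path = Path(path)
    pd.DataFrame({"time_s": loco.times_s, "value": loco.values}).to_csv(
        path, index=False
    )
    if loco.trigger_times_s.size:
        pd.DataFrame({"trigger_time_s": loco.trigger_times_s}).to_csv(
            path.with_name(path.stem + "_triggers.csv"), index=False
        )


def read_locomotion(path, triggers_path=None) -> LocomotionTrace:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise InputError(f"locomotion CSV {path} lacks column {col!r}")
    if triggers_path is None:
        cand = path.with_name(path.stem + "_triggers.csv")
        triggers_path = cand if cand.exists() else None
    triggers = np.empty(0)
    if triggers_path is not None:
        tdf = pd.read_csv(triggers_path)
        if "trigger_time_s" not in tdf.columns:
            raise InputError(
                f"trigger CSV {triggers_path} lacks column 'trigger_time_s'"
            )
        triggers = tdf["trigger_time_s"].to_numpy(dtype=float)
    return LocomotionTrace(
        values=df["value"].to_numpy(dtype=float),
        times_s=df["time_s"].to_numpy(dtype=float),
        trigger_times_s=triggers,
    )


def write_trial_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    required = {"animal_id", "group", "session_id", "trial_id", "loco_category"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"trial table {path} lacks columns {sorted(missing)}")
    return df


def read_nor_track(track_csv, objects_json):
    """NOR inputs: per-frame coordinate CSV plus the object-layout JSON."""
    from .behavior import ArenaObject, NorTrack

    df = pd.read_csv(Path(track_csv))
    for col in ("nose_x", "nose_y", "centroid_x", "centroid_y"):
        if col not in df.columns:
            raise InputError(f"track CSV {track_csv} lacks column {col!r}")
    with open(objects_json) as fh:
        meta = json.load(fh)
    objects = [
        ArenaObject(
            id=o["id"],
            role=o["role"],
            center=tuple(o["center"]),
            footprint=[tuple(p) for p in o["footprint"]],
        )
        for o in meta["objects"]
    ]
    return NorTrack(
        nose_xy=df[["nose_x", "nose_y"]].to_numpy(dtype=float),
        centroid_xy=df[["centroid_x", "centroid_y"]].to_numpy(dtype=float),
        frame_rate_hz=float(meta.get("frame_rate_hz", 30.0)),
        objects=objects,
        phase=meta.get("phase", "testing"),
    )
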