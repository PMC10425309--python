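"""Serialization: NIfTI volumes, raw-scan archives, scene JSON, tables.

Reconstructed volumes are written as NIfTI with the voxel size and the world
position of the grid corner in the affine (axis order z, x, y in mm); the
method tag and imaging-sequence id travel in the header description.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .forward import RawScan, ReconImage, ScanConfig
from .phantoms import IronSource, PhantomScene
from .quantify import CalibrationLine

__all__ = [
    "save_nifti", "load_nifti",
    "save_raw", "load_raw",
    "scene_to_json", "scene_from_json",
    "ground_truth_to_csv",
    "calibration_to_csv", "calibration_from_csv",
]


def save_nifti(image: ReconImage, path: str | Path) -> None:
    affine = np.diag([image.voxel_mm] * 3 + [1.0])
    affine[:3, 3] = np.asarray(image.origin_mm) + 0.5 * image.voxel_mm
    img = nib.Nifti1Image(np.asarray(image.values, dtype=np.float32), affine)
    img.header["descrip"] = f"method={image.method};cfg={image.config_id}".encode()[:79]
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> ReconImage:
    img = nib.load(str(path))
    affine = img.affine
    voxel = float(affine[0, 0])
    origin = affine[:3, 3] - 0.5 * voxel
    descrip = img.header["descrip"].tobytes().decode("utf-8", "ignore").rstrip("\x00")
    method, config_id = "unknown", ""
    for part in descrip.split(";"):
        if part.startswith("method="):
            method = part.split("=", 1)[1]
        elif part.startswith("cfg="):
            config_id = part.split("=", 1)[1]
    return ReconImage(np.asarray(img.dataobj, dtype=float), voxel, origin, method, config_id)


def save_raw(raw: RawScan, path: str | Path) -> None:
    """Compressed archive of both channel grids, true offsets and config."""
    np.savez_compressed(
        str(path),
        channel_z=raw.channel_z,
        channel_x=raw.channel_x,
        true_offsets_z=raw.true_offsets_z,
        true_offsets_x=raw.true_offsets_x,
        config_json=np.array(json.dumps(dataclasses.asdict(raw.config))),
        rng_seed=raw.rng_seed,
        noise_sd=raw.noise_sd,
    )


def load_raw(path: str | Path) -> RawScan:
    with np.load(str(path), allow_pickle=False) as f:
        config = ScanConfig(**json.loads(str(f["config_json"])))
        return RawScan(
            f["channel_z"], f["channel_x"],
            f["true_offsets_z"], f["true_offsets_x"],
            config, int(f["rng_seed"]), float(f["noise_sd"]),
        )


def scene_to_json(scene: PhantomScene, path: str | Path | None = None) -> str:
    payload = {
        "per_cell_iron_pg": scene.per_cell_iron_pg,
        "rng_seed": scene.rng_seed,
        "sources": [
            {
                "position": list(s.position),
                "iron_ng": s.iron_ng,
                "extent_sigma_mm": s.extent_sigma_mm,
                "label": s.label,
            }
            for s in scene.sources
        ],
        "ground_truth": scene.ground_truth.to_dict(orient="records"),
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def scene_from_json(source: str | Path) -> PhantomScene:
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    payload = json.loads(text)
    sources = tuple(
        IronSource(tuple(s["position"]), s["iron_ng"], s["extent_sigma_mm"], s["label"])
        for s in payload["sources"]
    )
    truth = pd.DataFrame(payload["ground_truth"], columns=["label", "iron_ng", "cells"])
    return PhantomScene(sources, payload["per_cell_iron_pg"], truth, payload["rng_seed"])


def ground_truth_to_csv(scene: PhantomScene, path: str | Path) -> None:
    scene.ground_truth.to_csv(path, index=False)


def calibration_to_csv(samples, path: str | Path) -> None:
    """Write (iron_ng, total_signal) calibration samples."""
    pd.DataFrame(samples, columns=["iron_ng", "total_signal"]).to_csv(path, index=False)


def calibration_from_csv(path: str | Path) -> list[tuple[float, float]]:
    df = pd.read_csv(path)
    return list(zip(df["iron_ng"].astype(float), df["total_signal"].astype(float)))
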