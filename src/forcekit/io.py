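"""File conventions: TIFF stacks with JSON sidecars, CSV tables, scene YAML.

Displacement stacks are multi-page 32-bit float TIFF in nm; masks are
multi-page 16-bit unsigned label TIFF.  Physical metadata travels in a
JSON sidecar next to the stack: ``{"pixel_size_um": ..., "frame_interval_s": ...}``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .mechanics import DisplacementMap, SubstrateModel
from .synthetic import (
    AdhesionDipole,
    ProtrusionSource,
    SyntheticCell,
    SyntheticScene,
)


def _sidecar_path(stack_path: Path) -> Path:
    return stack_path.with_suffix(".json")


def write_displacement_stack(
    path: str | Path,
    maps: list[DisplacementMap],
    frame_interval_s: float | None = None,
) -> None:
    path = Path(path)
    arr = np.stack([m.values for m in maps]).astype(np.float32)
    tifffile.imwrite(path, arr, photometric="minisblack")
    meta = {"pixel_size_um": maps[0].pixel_size_um, "units": "nm"}
    if frame_interval_s is not None:
        meta["frame_interval_s"] = frame_interval_s
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_displacement_stack(path: str | Path) -> tuple[list[DisplacementMap], dict]:
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    meta = json.loads(_sidecar_path(path).read_text())
    px = float(meta["pixel_size_um"])
    dt = meta.get("frame_interval_s")
    maps = [
        DisplacementMap(
            frame.astype(float), px,
            frame_time_s=None if dt is None else i * float(dt),
        )
        for i, frame in enumerate(arr)
    ]
    return maps, meta


def write_mask_stack(path: str | Path, masks: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(masks, dtype=np.uint16), photometric="minisblack")


def read_mask_stack(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr.astype(np.uint16)


def write_stress_stack(path: str | Path, stacks, pixel_size_um: float) -> None:
    arr = np.stack([s.values for s in stacks]).astype(np.float32)
    tifffile.imwrite(Path(path), arr, photometric="minisblack")
    _sidecar_path(Path(path)).write_text(
        json.dumps({"pixel_size_um": pixel_size_um, "units": "Pa"}, indent=2)
    )


# --- scene (de)serialisation -------------------------------------------------

def scene_to_dict(scene: SyntheticScene, substrate: SubstrateModel) -> dict:
    return {
        "substrate": {
            "effective_stiffness_kpa": substrate.effective_stiffness_kpa,
            "layer_thickness_um": substrate.layer_thickness_um,
            "coupling_sigma_um": substrate.coupling_sigma_um,
            "pixel_size_um": substrate.pixel_size_um,
        },
        "scene": {
            "field_size_um": list(scene.field_size_um),
            "frame_interval_s": scene.frame_interval_s,
            "n_frames": scene.n_frames,
            "noise_sd_nm": scene.noise_sd_nm,
            "rng_seed": scene.rng_seed,
            "cells": [
                {
                    "trajectory_um": cell.trajectory_um.tolist(),
                    "body_radius_um": cell.body_radius_um,
                    "central_indentation_amplitude_nm": cell.central_indentation_amplitude_nm,
                    "indentation_sigma_factor": cell.indentation_sigma_factor,
                    "adhesions": [
                        {
                            "position_um": list(d.position_um),
                            "axis_angle": d.axis_angle,
                            "force_nn": np.asarray(d.force_nn).tolist(),
                            "lobe_separation_um": d.lobe_separation_um,
                            "lobe_sigma_um": d.lobe_sigma_um,
                        }
                        for d in cell.adhesions
                    ],
                    "protrusions": [
                        {
                            "position_um": list(p.position_um),
                            "force_series_pn": p.force_series_pn.tolist(),
                            "core_radius_um": p.core_radius_um,
                            "edge_taper_um": p.edge_taper_um,
                            "ring_radius_um": p.ring_radius_um,
                            "ring_width_um": p.ring_width_um,
                            "oscillation_period_s": p.oscillation_period_s,
                        }
                        for p in cell.protrusions
                    ],
                }
                for cell in scene.cells
            ],
        },
    }


def scene_from_dict(data: dict) -> tuple[SyntheticScene, SubstrateModel]:
    sub = SubstrateModel(**data["substrate"])
    sc = data["scene"]
    cells = []
    for c in sc["cells"]:
        cells.append(
            SyntheticCell(
                trajectory_um=np.asarray(c["trajectory_um"], dtype=float),
                body_radius_um=c["body_radius_um"],
                central_indentation_amplitude_nm=c["central_indentation_amplitude_nm"],
                indentation_sigma_factor=c.get("indentation_sigma_factor", 0.55),
                adhesions=[
                    AdhesionDipole(
                        position_um=tuple(d["position_um"]),
                        axis_angle=d["axis_angle"],
                        force_nn=np.asarray(d["force_nn"], dtype=float)
                        if isinstance(d["force_nn"], list)
                        else d["force_nn"],
                        lobe_separation_um=d["lobe_separation_um"],
                        lobe_sigma_um=d["lobe_sigma_um"],
                    )
                    for d in c.get("adhesions", [])
                ],
                protrusions=[
                    ProtrusionSource(
                        position_um=tuple(p["position_um"]),
                        force_series_pn=np.asarray(p["force_series_pn"], dtype=float),
                        core_radius_um=p["core_radius_um"],
                        edge_taper_um=p.get("edge_taper_um", 0.6),
                        ring_radius_um=p["ring_radius_um"],
                        ring_width_um=p["ring_width_um"],
                        oscillation_period_s=p.get("oscillation_period_s"),
                    )
                    for p in c.get("protrusions", [])
                ],
            )
        )
    scene = SyntheticScene(
        field_size_um=tuple(sc["field_size_um"]),
        frame_interval_s=sc["frame_interval_s"],
        n_frames=sc["n_frames"],
        cells=cells,
        noise_sd_nm=sc["noise_sd_nm"],
        rng_seed=sc["rng_seed"],
    )
    return scene, sub


def save_scene_yaml(
    path: str | Path, scene: SyntheticScene, substrate: SubstrateModel
) -> None:
    Path(path).write_text(yaml.safe_dump(scene_to_dict(scene, substrate)))


def load_scene_yaml(path: str | Path) -> tuple[SyntheticScene, SubstrateModel]:
    return scene_from_dict(yaml.safe_load(Path(path).read_text()))
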