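"""On-disk dialect: multi-page TIFF arrays with JSON sidecars.

Cubes are one TIFF page per wavenumber plus a sidecar carrying the
wavenumber axis, pixel pitch, and seed; movies one page per frame plus
frame rate and stimulus time; heat maps single-page 32-bit float TIFF;
masks 8-bit label TIFF (0 background, 1 cell, 2 intracellular ice).
Sidecars live next to the TIFF with the same stem and a .json suffix.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .calcium import CalciumMovie
from .raman import CellSegmentation, HeatMap, RamanCube


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_cube(path: str | Path, cube: RamanCube, seed: int | None = None, **extra) -> Path:
    path = Path(path)
    tifffile.imwrite(path, cube.intensities.astype(np.float32))
    meta = {
        "wavenumbers_cm1": [float(w) for w in cube.wavenumbers],
        "pixel_pitch_um": cube.pixel_pitch,
        "seed": seed,
        **extra,
    }
    _write_json(_sidecar(path), meta)
    return path


def read_cube(path: str | Path) -> RamanCube:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    data = tifffile.imread(path)
    return RamanCube(data, np.asarray(meta["wavenumbers_cm1"]), meta["pixel_pitch_um"])


def write_movie(path: str | Path, movie: CalciumMovie, seed: int | None = None, **extra) -> Path:
    path = Path(path)
    tifffile.imwrite(path, movie.frames.astype(np.float32))
    _write_json(
        _sidecar(path),
        {
            "frame_rate_hz": movie.frame_rate,
            "stimulus_time_s": movie.stimulus_time,
            "seed": seed,
            **extra,
        },
    )
    return path


def read_movie(path: str | Path) -> CalciumMovie:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    return CalciumMovie(tifffile.imread(path), meta["frame_rate_hz"], meta["stimulus_time_s"])


def write_heatmap(path: str | Path, heatmap: HeatMap, **extra) -> Path:
    path = Path(path)
    tifffile.imwrite(path, heatmap.values.astype(np.float32))
    _write_json(
        _sidecar(path),
        {
            "substance": heatmap.substance,
            "pixel_pitch_um": heatmap.pixel_pitch,
            "deconvolved": heatmap.deconvolved,
            **extra,
        },
    )
    return path


def read_heatmap(path: str | Path) -> HeatMap:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    return HeatMap(
        tifffile.imread(path).astype(float),
        meta["substance"],
        meta["pixel_pitch_um"],
        deconvolved=meta.get("deconvolved", False),
    )


def write_masks(path: str | Path, seg: CellSegmentation) -> Path:
    path = Path(path)
    labels = np.zeros(seg.cell_mask.shape, dtype=np.uint8)
    labels[seg.cell_mask] = 1
    labels[seg.ice_mask] = 2
    tifffile.imwrite(path, labels)
    _write_json(_sidecar(path), {"pixel_pitch_um": seg.pixel_pitch,
                                 "labels": {"0": "background", "1": "cell", "2": "ice"}})
    return path


def read_masks(path: str | Path) -> CellSegmentation:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    labels = tifffile.imread(path)
    return CellSegmentation(labels >= 1, labels == 2, meta["pixel_pitch_um"])
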