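"""End-to-end per-cell analysis: cube -> heat maps -> masks -> metric row.

Deconvolution always precedes segmentation and the per-pixel metrics;
see docs/methods.md for why that ordering was chosen and what it
assumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .bands import DEFAULT_BANDS, Band
from .metrics import (
    CryoMetricsRecord,
    ch_oh_ratio,
    frozen_diameter,
    ice_mask_from_map,
    ice_metrics,
    morans_I,
    partition_ratio,
)
from .raman import (
    BandWindow,
    CellSegmentation,
    HeatMap,
    RamanCube,
    deconvolve,
    integrate_band,
    segment_cell,
)

METRIC_BAND_NAMES = ("amide_I", "ch_stretch", "oh_ice", "cyt_c")


@dataclass
class CellAnalysis:
    """Heat maps, segmentation and the metric record for one cell."""

    heatmaps: dict[str, HeatMap]
    segmentation: CellSegmentation
    record: CryoMetricsRecord


def band_window(band: Band, baseline: str = "linear-endpoints") -> BandWindow:
    lo, hi = band.window
    return BandWindow(band.name, lo, hi, baseline)


def compute_heatmaps(
    cube: RamanCube,
    bands: Mapping[str, Band] = DEFAULT_BANDS,
    names: tuple[str, ...] | None = None,
    deconvolve_maps: bool = True,
    iterations: int = 10,
    baseline: str = "linear-endpoints",
) -> dict[str, HeatMap]:
    """Integrate (and optionally Richardson-Lucy restore) one heat map per band."""
    if names is None:
        names = tuple(
            n for n in bands
            if bands[n].window[0] >= cube.wavenumbers[0]
            and bands[n].window[1] <= cube.wavenumbers[-1]
        )
    maps = {}
    for name in names:
        hm = integrate_band(cube, band_window(bands[name], baseline))
        if deconvolve_maps:
            hm = deconvolve(hm, iterations=iterations)
        maps[name] = hm
    return maps


def segment_from_maps(maps: Mapping[str, HeatMap]) -> CellSegmentation:
    """Cell mask from amide I + C-H union; intracellular ice from the
    O-H/ice map within the cell."""
    seg = segment_cell(maps["amide_I"], maps["ch_stretch"])
    ice = ice_mask_from_map(maps["oh_ice"], seg)
    return CellSegmentation(seg.cell_mask, ice, seg.pixel_pitch)


def analyze_cube(
    cube: RamanCube,
    fresh_mean_diameter: float,
    bands: Mapping[str, Band] = DEFAULT_BANDS,
    solute: str = "glycerol",
    deconvolve_maps: bool = True,
    iterations: int = 10,
    chunky_threshold: float = 0.75,
) -> CellAnalysis:
    """Run the full frozen-cell metric panel on one hyperspectral cube."""
    names = METRIC_BAND_NAMES + (solute,)
    maps = compute_heatmaps(cube, bands, names, deconvolve_maps, iterations)
    seg = segment_from_maps(maps)
    ice_frac, chunky = ice_metrics(None, seg, chunky_threshold)
    ratio = partition_ratio(maps[solute], seg)
    d_frozen, d_frac = frozen_diameter(seg, fresh_mean_diameter)
    choh = ch_oh_ratio(
        cube, seg, band_window(bands["ch_stretch"]), band_window(bands["oh_ice"])
    )
    record = CryoMetricsRecord(
        ice_area_fraction=ice_frac,
        chunky=chunky,
        partition_ratio=ratio,
        moran_amideI=morans_I(maps["amide_I"], seg.cell_mask),
        moran_cytc=morans_I(maps["cyt_c"], seg.cell_mask),
        diameter_frozen_um=d_frozen,
        diameter_fraction=d_frac,
        ch_oh_ratio=choh,
    )
    return CellAnalysis(maps, seg, record)


def record_to_row(cell_id: str, condition: str, record: CryoMetricsRecord) -> dict:
    """One tidy CSV row of the metric panel."""
    return {
        "cell_id": cell_id,
        "condition": condition,
        "ice_area_fraction": record.ice_area_fraction,
        "chunky": record.chunky,
        "partition_ratio": record.partition_ratio,
        "moran_amideI": record.moran_amideI.I,
        "moran_cytc": record.moran_cytc.I,
        "diameter_frozen_um": record.diameter_frozen_um,
        "diameter_fraction": record.diameter_fraction,
        "ch_oh_ratio": record.ch_oh_ratio,
    }
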