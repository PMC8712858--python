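"""Non-imaging quantifications: fresh-cell diameters from micrographs,
CPA-exposure survival curves, post-thaw recovery and attachment rates,
and the PDA membrane-fluidity ratio."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from statsmodels.stats.proportion import proportion_confint

log = logging.getLogger(__name__)


def fresh_diameter(
    micrograph: np.ndarray, pixel_pitch: float, min_size_px: int = 20
) -> list[float]:
    """Equivalent-circle diameters of the cells in a micrograph.

    Otsu threshold, connected-component labelling, rejection of debris
    below ``min_size_px``, then D = 2 sqrt(A / pi) per component with
    A = pixel count x pitch^2. An empty image yields an empty list.
    """
    if pixel_pitch <= 0:
        raise ValueError("pixel_pitch must be > 0")
    img = np.asarray(micrograph, dtype=float)
    if np.ptp(img) == 0:
        return []
    mask = img > threshold_otsu(img)
    diameters = []
    for prop in regionprops(label(mask, connectivity=2)):
        if prop.area >= min_size_px:
            diameters.append(float(2.0 * np.sqrt(prop.area * pixel_pitch**2 / np.pi)))
    return diameters


def survival_curve(table: pd.DataFrame) -> pd.DataFrame:
    """Per-condition viable fractions over time with Wilson 95% CIs.

    ``table`` has columns condition, timepoint_min, viable, nonviable.
    """
    required = {"condition", "timepoint_min", "viable", "nonviable"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    rows = []
    for _, r in table.iterrows():
        total = int(r["viable"]) + int(r["nonviable"])
        if total <= 0:
            raise ValueError(
                f"zero-total row: condition {r['condition']!r} at "
                f"t = {r['timepoint_min']} min"
            )
        frac = r["viable"] / total
        lo, hi = proportion_confint(int(r["viable"]), total, alpha=0.05, method="wilson")
        rows.append(
            {
                "condition": r["condition"],
                "timepoint_min": r["timepoint_min"],
                "fraction_viable": frac,
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows).sort_values(["condition", "timepoint_min"]).reset_index(drop=True)


def recovery_rate(viable_post_thaw: float, viable_pre_cpa: float) -> float:
    """Post-thaw recovery, %: 100 x viable count immediately after thaw
    over viable count immediately before CPA addition prefreeze."""
    if viable_pre_cpa <= 0:
        raise ValueError("pre-CPA viable count must be > 0")
    rate = 100.0 * viable_post_thaw / viable_pre_cpa
    if rate > 100.0:
        log.info("recovery rate %.1f%% exceeds 100%% (reported unclamped)", rate)
    return rate


def attachment_rate(signal_post_thaw: float, signal_fresh_control: float) -> float:
    """Post-thaw attachment, %: 100 x calcein signal 24 h after thaw over
    the fresh-passage control signal."""
    if signal_fresh_control <= 0:
        raise ValueError("fresh control signal must be > 0")
    return 100.0 * signal_post_thaw / signal_fresh_control


@dataclass(frozen=True)
class FluidityReading:
    """PDA fluorescence at 400 nm (monomer) and 460 nm (excimer)."""

    emission_400: float
    emission_460: float

    def __post_init__(self) -> None:
        if self.emission_400 <= 0 or self.emission_460 <= 0:
            raise ValueError("both emissions must be > 0")


def fluidity_ratio(reading: FluidityReading) -> float:
    """Relative membrane fluidity: the PDA excimer (460 nm) to monomer
    (400 nm) emission ratio."""
    return reading.emission_460 / reading.emission_400
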