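"""Per-cell frozen-state metrics.

Quantities measured on a segmented frozen cell: intracellular ice area
fraction and its "chunky" form (one mass filling most of the cytoplasm,
a lethal freezing event, vs small dispersed crystals), the membrane
partitioning ratio of a CPA solute (extracellular / intracellular
concentration — lower means a weaker membrane barrier), Moran's I
spatial autocorrelation of the amide I and cytochrome C signals
(punctate protein = cellular disintegration; dispersed cytochrome C =
release), the frozen equivalent-circle diameter normalized to the fresh
mean, and the C-H / O-H hydration ratio.

Moran's I uses a row-standardized k-nearest-neighbour spatial weight
matrix (k = 8 by default) over the in-mask pixels, with Euclidean
distance and lexicographic (y, x) tie-breaking among equidistant
pixels; row standardization makes S0 = n, so

    I = sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label

from .raman import BandWindow, CellSegmentation, HeatMap, RamanCube, integrate_band, segment_substance

# ---------------------------------------------------------------------------
# spatial weights and Moran's I
# ---------------------------------------------------------------------------


@dataclass
class SpatialWeights:
    """Row-standardized k-NN weights over in-mask pixels.

    ``coords`` are the (y, x) integer pixel coordinates in mask scan
    order; ``neighbors[i]`` holds the indices of pixel i's k nearest
    in-mask pixels (never itself) and ``weights[i]`` the matching
    weights, each row summing to 1.
    """

    coords: np.ndarray
    neighbors: np.ndarray
    weights: np.ndarray
    k: int

    @property
    def n(self) -> int:
        return len(self.coords)


def knn_weights(mask: np.ndarray, k: int = 8) -> SpatialWeights:
    """Build row-standardized k-NN weights for the True pixels of ``mask``.

    Neighbours are ranked by squared Euclidean distance (exact integer
    arithmetic), with ties broken by smaller (y, x). Rows have exactly k
    entries unless the mask holds fewer than k+1 pixels, in which case
    every other pixel is a neighbour.
    """
    mask = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    coords = np.stack([ys, xs], axis=1).astype(np.int64)
    n = len(coords)
    if n < 2:
        raise ValueError("mask must contain at least 2 pixels")
    kk = min(k, n - 1)
    neighbors = np.empty((n, kk), dtype=np.int64)
    for i in range(n):
        dy = coords[:, 0] - coords[i, 0]
        dx = coords[:, 1] - coords[i, 1]
        d2 = dy * dy + dx * dx
        d2[i] = np.iinfo(np.int64).max  # exclude self
        # order by (distance^2, y, x); all keys integral, so ties are exact
        order = np.lexsort((coords[:, 1], coords[:, 0], d2))
        neighbors[i] = order[:kk]
    weights = np.full((n, kk), 1.0 / kk)
    return SpatialWeights(coords, neighbors, weights, k=kk)


@dataclass(frozen=True)
class MoranResult:
    """Moran's I with its null expectation and weight provenance."""

    I: float
    n: int
    expectation_null: float
    weights_spec: str

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("Moran's I requires n >= 3 pixels")
        if not np.isfinite(self.I):
            raise ValueError("Moran's I must be finite")


def _moran_from_weights(values: np.ndarray, w: SpatialWeights) -> float:
    z = values - values.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("constant field: Moran's I undefined (zero variance)")
    lag = (w.weights * z[w.neighbors]).sum(axis=1)
    # row-standardized weights: S0 = n, so the n/S0 prefactor is 1
    return float(z @ lag) / denom


def morans_I(heatmap: HeatMap | np.ndarray, mask: np.ndarray, k: int = 8) -> MoranResult:
    """Moran's I of the in-mask pixel values with row-standardized k-NN weights."""
    values2d = heatmap.values if isinstance(heatmap, HeatMap) else np.asarray(heatmap, float)
    mask = np.asarray(mask, dtype=bool)
    if values2d.shape != mask.shape:
        raise ValueError("map and mask must share shape")
    n = int(mask.sum())
    if n < k + 2:
        raise ValueError(f"Moran's I with k={k} requires at least {k + 2} in-mask pixels, got {n}")
    w = knn_weights(mask, k=k)
    vals = values2d[mask]
    i_stat = _moran_from_weights(vals, w)
    return MoranResult(
        I=i_stat,
        n=n,
        expectation_null=-1.0 / (n - 1),
        weights_spec=f"row-standardized {w.k}-NN, Euclidean, lexicographic (y,x) ties",
    )


def moran_permutation_null(
    values: np.ndarray, w: SpatialWeights, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Moran's I under random relabelling of the field values (the
    permutation null used to check E[I] = -1/(n-1))."""
    values = np.asarray(values, dtype=float)
    out = np.empty(n_perm)
    for p in range(n_perm):
        out[p] = _moran_from_weights(rng.permutation(values), w)
    return out


# ---------------------------------------------------------------------------
# ice metrics
# ---------------------------------------------------------------------------

def ice_mask_from_map(
    ice_map: HeatMap, seg: CellSegmentation, boundary_erosion_px: int = 1
) -> np.ndarray:
    """Derive the intracellular ice mask from an O-H/ice heat map.

    Otsu separates the high-intensity ice/extracellular phase from the
    unfrozen cytoplasm; intersecting with the cell mask (eroded by
    ``boundary_erosion_px`` to drop partial-volume pixels straddling the
    cell boundary) gives intracellular ice. Returns all-False when the
    map has no contrast.

    The raw Otsu class is used rather than a filled substance mask: the
    frozen extracellular matrix is also O-H-bright, so hole filling of
    the high class would swallow the unfrozen cytoplasm.
    """
    vals = ice_map.values
    if np.ptp(vals) == 0:
        return np.zeros_like(seg.cell_mask)
    from skimage.filters import threshold_otsu

    high = vals > threshold_otsu(vals)
    interior = seg.cell_mask
    if boundary_erosion_px > 0:
        interior = ndi.binary_erosion(interior, iterations=boundary_erosion_px)
    return high & interior


def ice_metrics(
    ice_map: HeatMap | None,
    seg: CellSegmentation,
    chunky_threshold: float = 0.75,
) -> tuple[float, bool]:
    """Intracellular ice area fraction and the chunky-ice call.

    ``ice_area_fraction`` = |ice ∩ cell| / |cell|. The cell is "chunky"
    when a single connected ice component covers at least
    ``chunky_threshold`` of the cell area. When ``ice_map`` is None the
    segmentation's own ice mask is used; otherwise the ice mask is
    derived from the map via :func:`ice_mask_from_map`.
    """
    cell_px = int(seg.cell_mask.sum())
    if cell_px == 0:
        raise ValueError("empty cell mask")
    if ice_map is None:
        ice = seg.ice_mask & seg.cell_mask
    else:
        ice = ice_mask_from_map(ice_map, seg)
    frac = float(ice.sum()) / cell_px
    chunky = False
    if ice.any():
        lab = label(ice, connectivity=2)
        largest = np.bincount(lab.ravel())[1:].max()
        chunky = bool(largest / cell_px >= chunky_threshold)
    return frac, chunky


# ---------------------------------------------------------------------------
# partitioning, diameter, hydration
# ---------------------------------------------------------------------------

def partition_ratio(
    solute_map: HeatMap,
    seg: CellSegmentation,
    extracellular_annulus_px: int = 3,
    annulus_gap_px: int = 2,
    exclude_ice: bool = True,
) -> float:
    """Membrane partitioning ratio: extracellular / intracellular solute.

    The extracellular reference is an annulus ``extracellular_annulus_px``
    wide starting ``annulus_gap_px`` outside the cell boundary (clear of
    boundary blur but in the same field of view). The intracellular mean
    is over the cell mask, excluding ice pixels by default (ice displaces
    solution). Intensity is assumed proportional to concentration.
    """
    cell = seg.cell_mask
    inner = ndi.binary_dilation(cell, iterations=annulus_gap_px) if annulus_gap_px else cell
    outer = ndi.binary_dilation(inner, iterations=extracellular_annulus_px)
    annulus = outer & ~inner
    if not annulus.any():
        raise ValueError("extracellular annulus is empty (cell fills the field of view)")
    intra = cell & ~seg.ice_mask if exclude_ice else cell
    if not intra.any():
        raise ValueError("no intracellular (non-ice) pixels")
    intra_mean = float(solute_map.values[intra].mean())
    if intra_mean <= 0:
        raise ValueError("intracellular solute mean <= 0: partition ratio undefined")
    return float(solute_map.values[annulus].mean()) / intra_mean


def frozen_diameter(
    seg: CellSegmentation, fresh_mean_diameter: float
) -> tuple[float, float]:
    """Equivalent-circle diameter of the frozen cell and its fraction of
    the fresh mean: D = 2 sqrt(A / pi), A = pixel count x pitch^2."""
    if fresh_mean_diameter <= 0:
        raise ValueError("fresh_mean_diameter must be > 0")
    area = seg.cell_area_um2
    if area == 0:
        raise ValueError("zero-area cell mask")
    d = 2.0 * np.sqrt(area / np.pi)
    return float(d), float(d / fresh_mean_diameter)


def ch_oh_ratio(
    cube: RamanCube,
    seg: CellSegmentation,
    ch_window: BandWindow,
    oh_window: BandWindow,
    exclude_ice: bool = True,
) -> float:
    """Hydration ratio: intracellular mean C-H band integral over the
    intracellular mean O-H band integral."""
    if not (ch_window.hi <= oh_window.lo or oh_window.hi <= ch_window.lo):
        raise ValueError("C-H and O-H windows must be disjoint")
    intra = seg.cell_mask & ~seg.ice_mask if exclude_ice else seg.cell_mask
    if not intra.any():
        raise ValueError("no intracellular pixels")
    ch = integrate_band(cube, ch_window).values[intra].mean()
    oh = integrate_band(cube, oh_window).values[intra].mean()
    if oh <= 0:
        raise ValueError("zero O-H integral: hydration ratio undefined")
    return float(ch / oh)


# ---------------------------------------------------------------------------
# per-cell record
# ---------------------------------------------------------------------------


@dataclass
class CryoMetricsRecord:
    """One row of the per-cell metric panel."""

    ice_area_fraction: float
    chunky: bool
    partition_ratio: float
    moran_amideI: MoranResult
    moran_cytc: MoranResult
    diameter_frozen_um: float
    diameter_fraction: float
    ch_oh_ratio: float
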