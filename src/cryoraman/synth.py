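"""Seeded synthetic inputs with the statistical structure the analyses assume.

Stands in for the instruments: a confocal Raman microscope scanning one
frozen cell per field at 333-nm pixel pitch, a fluorescence camera
recording 185-s calcium movies at 4 frames/s, a hemocytometer
micrograph of suspended cells, AO/PI viability counts, and the
controlled-rate freezer's temperature log. Every generator takes an
explicit seed and is bit-reproducible; ground truth (masks, true metric
values, labels) is returned alongside each synthetic dataset.

Phantom forward model: per-pixel spectrum = sum over bands of a Gaussian
line profile scaled by that band's spatial amplitude map, the amplitude
maps blurred by the instrument's Gaussian PSF, plus detector noise with
standard deviation proportional to the square root of intensity (the
CCD shot-noise regime without integer-count bookkeeping).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .bands import DEFAULT_BANDS, Band, validate_separability
from .raman import DEFAULT_PSF_FWHM_UM, FWHM_TO_SIGMA, CellSegmentation, RamanCube

# Amplitude levels of the phantom forward model (arbitrary intensity units).
# These are the noise-free band amplitudes inside/outside the cell; the
# defaults put the default detector noise (noise_level=1) at a per-sample
# SNR of ~10 at band peaks, typical of 0.2-s dwell confocal Raman.
AMIDE_LEVEL = 100.0
CH_LEVEL = 80.0
OH_ICE_LEVEL = 100.0       # ice and frozen extracellular matrix
OH_CYTO_LEVEL = 40.0       # unfrozen cytoplasm at hydration = 1
SOLUTE_INTRA_LEVEL = 50.0
CYTC_SPOT_LEVEL = 90.0
CYTC_FLOOR = 10.0
CLUSTERING_CONTRAST = 2.0  # amide fluctuation amplitude at knob = 1
# protein_clustering maps to the Gaussian-random-field correlation length:
# length = MIN + SPAN * knob (px). Both the aggregate size and the
# fluctuation amplitude grow with the knob, so the expected Moran's I of
# the amide I map rises monotonically from ~0 (uniform field, detector
# noise only) toward its smooth-field ceiling.
CLUSTERING_LENGTH_MIN_PX = 0.75
CLUSTERING_LENGTH_SPAN_PX = 3.25

DEFAULT_WAVENUMBERS = np.arange(600.0, 3302.0, 4.0)


@dataclass
class SpectralComponent:
    """One Gaussian band with its spatial amplitude map."""

    name: str
    center: float
    width: float
    amplitude_map: np.ndarray

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"component {self.name!r}: width must be > 0")
        self.amplitude_map = np.asarray(self.amplitude_map, dtype=float)
        if self.amplitude_map.ndim != 2:
            raise ValueError("amplitude_map must be 2D")
        if np.any(self.amplitude_map < -1e-9):
            raise ValueError(f"component {self.name!r}: negative amplitudes")

    def line_profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        d = (np.asarray(wavenumbers, float) - self.center) / self.width
        return np.exp(-0.5 * d * d)


@dataclass(frozen=True)
class CellPhantomSpec:
    """Ground-truth parameters of one frozen-cell Raman phantom.

    ``partition_ratio_true`` is the extracellular / intracellular solute
    concentration; ``protein_clustering`` 0 gives a uniform amide I
    field, 1 a maximally punctate one; ``cytc_release`` 0 keeps
    cytochrome C in mitochondria-like spots, 1 disperses it;
    ``hydration`` scales the cytoplasmic O-H band.
    """

    cell_diameter: float = 13.3  # um, fresh D5-crest scale
    ice_fraction: float = 0.0
    chunky: bool = False
    partition_ratio_true: float = 1.0
    protein_clustering: float = 0.3
    cytc_release: float = 0.0
    hydration: float = 1.0
    noise_level: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ice_fraction", "protein_clustering", "cytc_release", "hydration"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.cell_diameter <= 0:
            raise ValueError("cell_diameter must be > 0")
        if self.partition_ratio_true <= 0:
            raise ValueError("partition_ratio_true must be > 0")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if self.chunky and self.ice_fraction < 0.75:
            raise ValueError("chunky ice requires ice_fraction >= 0.75")


@dataclass
class PhantomTruth:
    """Ground truth emitted with a phantom: masks plus the true metric
    values recomputed from the emitted masks themselves."""

    segmentation: CellSegmentation
    ice_area_fraction: float
    chunky: bool
    partition_ratio: float
    diameter_um: float
    components: list[SpectralComponent]
    spec: CellPhantomSpec


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _dispersed_ice_pattern(
    shape: tuple[int, int], fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Stratified small-blob pattern of the requested areal density whose
    connected components are tile-sized, separated by 1-px gap lines.

    Disjoint components separated by 1-px gaps cannot exceed a density of
    (t/(t+1))^2, so the tile size t grows with the requested fraction;
    above 0.79 no dispersed (multi-component) arrangement exists and the
    call fails.
    """
    if fraction > 0.79:
        raise ValueError(
            "dispersed ice fraction > 0.79 cannot be realized with disjoint "
            "components (1-px separating gaps bound density by (t/(t+1))^2); "
            "use chunky=True"
        )
    t = next(tt for tt in (4, 5, 6, 7, 9) if (tt / (tt + 1)) ** 2 >= fraction + 0.01)
    period = t + 1
    pattern = np.zeros(shape, dtype=bool)
    target = fraction * period * period  # blob area per tile
    oy, ox = rng.integers(0, period, size=2)
    for ty in range(-1, shape[0] // period + 1):
        for tx in range(-1, shape[1] // period + 1):
            s = int(np.floor(np.sqrt(target)))
            # dither the blob side so the expected density matches exactly
            if s < t and rng.random() < (target - s * s) / ((s + 1) ** 2 - s * s):
                s += 1
            s = min(s, t)
            if s == 0:
                continue
            jy = rng.integers(0, t - s + 1)
            jx = rng.integers(0, t - s + 1)
            y0 = ty * period + oy + jy
            x0 = tx * period + ox + jx
            ys, ye = max(y0, 0), min(y0 + s, shape[0])
            xs, xe = max(x0, 0), min(x0 + s, shape[1])
            if ys < ye and xs < xe:
                pattern[ys:ye, xs:xe] = True
    return pattern


def _grf(shape: tuple[int, int], length_px: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length."""
    g = ndi.gaussian_filter(rng.standard_normal(shape), length_px, mode="wrap")
    return g / g.std()


def make_raman_phantom(
    spec: CellPhantomSpec,
    bands: Mapping[str, Band] = DEFAULT_BANDS,
    image_size: int = 96,
    pixel_pitch: float = 0.333,
    wavenumbers: np.ndarray | None = None,
    solute: str = "glycerol",
    psf_fwhm_um: float = DEFAULT_PSF_FWHM_UM,
) -> tuple[RamanCube, PhantomTruth]:
    """Synthesize one frozen-cell hyperspectral cube plus its ground truth.

    The cell is a disk of ``spec.cell_diameter``; intracellular ice is a
    single blob covering the requested fraction when ``spec.chunky``,
    else a stratified pattern of small blobs. The solute band amplitude
    outside the cell is ``partition_ratio_true`` times the intracellular
    level. True metric values in the returned :class:`PhantomTruth` are
    recomputed from the emitted masks, so discretization is already
    accounted for.
    """
    validate_separability(dict(bands))
    if wavenumbers is None:
        wavenumbers = DEFAULT_WAVENUMBERS
    rng = np.random.default_rng(spec.seed)
    shape = (image_size, image_size)

    r_px = 0.5 * spec.cell_diameter / pixel_pitch
    if r_px + 4 > image_size / 2:
        raise ValueError(
            f"cell diameter {spec.cell_diameter:g} um ({2 * r_px:.1f} px) does not fit "
            f"in a {image_size}-px field with a 2-px margin"
        )
    jitter = rng.uniform(-2, 2, size=2)
    center = (image_size / 2 + jitter[0], image_size / 2 + jitter[1])
    cell = _disk_mask(shape, center, r_px)

    # --- intracellular ice ---
    if spec.ice_fraction > 0:
        if spec.chunky:
            r_ice = r_px * np.sqrt(spec.ice_fraction)
            max_off = max(r_px - r_ice, 0.0) * 0.5
            off = rng.uniform(-max_off, max_off, size=2)
            ice = _disk_mask(shape, (center[0] + off[0], center[1] + off[1]), r_ice) & cell
        else:
            ice = _dispersed_ice_pattern(shape, spec.ice_fraction, rng) & cell
    else:
        ice = np.zeros(shape, dtype=bool)

    cyto = cell & ~ice

    # --- band amplitude maps (pre-blur) ---
    amide = np.zeros(shape)
    amide[cell] = AMIDE_LEVEL
    if spec.protein_clustering > 0:
        length = CLUSTERING_LENGTH_MIN_PX + CLUSTERING_LENGTH_SPAN_PX * spec.protein_clustering
        fluct = 1.0 + CLUSTERING_CONTRAST * spec.protein_clustering * _grf(shape, length, rng)
        amide[cell] = AMIDE_LEVEL * np.clip(fluct[cell], 0.0, None)

    ch = np.zeros(shape)
    ch[cell] = CH_LEVEL

    oh = np.full(shape, OH_ICE_LEVEL)
    oh[cyto] = OH_CYTO_LEVEL * spec.hydration

    solute_map = np.zeros(shape)
    solute_map[cyto] = SOLUTE_INTRA_LEVEL
    solute_map[~cell] = SOLUTE_INTRA_LEVEL * spec.partition_ratio_true

    cytc = np.zeros(shape)
    cytc[cell] = CYTC_FLOOR
    interior = ndi.binary_erosion(cell, iterations=4)
    spots = np.zeros(shape, dtype=bool)
    if interior.any():
        iy, ix = np.nonzero(interior)
        for idx in rng.choice(len(iy), size=min(6, len(iy)), replace=False):
            spots |= _disk_mask(shape, (iy[idx], ix[idx]), 2.0)
        spots = spots & cell
    spot_mass = CYTC_SPOT_LEVEL * spots.sum()
    dispersed_level = spot_mass / max(cell.sum(), 1)
    cytc[spots] += (1.0 - spec.cytc_release) * CYTC_SPOT_LEVEL
    cytc[cell] += spec.cytc_release * dispersed_level

    amps = {
        "amide_I": amide,
        "ch_stretch": ch,
        "oh_ice": oh,
        solute: solute_map,
        "cyt_c": cytc,
    }

    sigma_px = psf_fwhm_um * FWHM_TO_SIGMA / pixel_pitch
    components = []
    for name, amp in amps.items():
        band = bands[name]
        blurred = np.clip(ndi.gaussian_filter(amp, sigma_px), 0.0, None)
        components.append(SpectralComponent(name, band.center, band.sigma, blurred))

    # assemble as (wavenumber, pixel) float32 outer products, in place
    n_pix = shape[0] * shape[1]
    cube = np.zeros((len(wavenumbers), n_pix), dtype=np.float32)
    for comp in components:
        prof = comp.line_profile(wavenumbers).astype(np.float32)
        cube += prof[:, None] * comp.amplitude_map.astype(np.float32).ravel()[None, :]

    if spec.noise_level > 0:
        sd = np.sqrt(np.clip(cube, 0.0, None))
        sd *= np.float32(spec.noise_level)
        noise = rng.standard_normal(cube.shape, dtype=np.float32)
        noise *= sd
        cube += noise
    cube = cube.reshape((len(wavenumbers),) + shape)

    seg = CellSegmentation(cell, ice, pixel_pitch=pixel_pitch)
    cell_px = int(cell.sum())
    true_frac = float(ice.sum()) / cell_px
    if ice.any():
        from skimage.measure import label as _label

        largest = np.bincount(_label(ice, connectivity=2).ravel())[1:].max()
        true_chunky = largest / cell_px >= 0.75
    else:
        true_chunky = False
    truth = PhantomTruth(
        segmentation=seg,
        ice_area_fraction=true_frac,
        chunky=bool(true_chunky),
        partition_ratio=spec.partition_ratio_true,
        diameter_um=float(2.0 * np.sqrt(cell_px * pixel_pitch**2 / np.pi)),
        components=components,
        spec=spec,
    )
    return RamanCube(cube, wavenumbers, pixel_pitch), truth


# ---------------------------------------------------------------------------
# calcium movies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalciumMovieSpec:
    """Synthetic stimulus-response calcium movie parameters.

    Acquisition geometry defaults to the study design: 185 s at 4
    frames/s with the stimulus added within the first 10 s. Amplitudes
    and noise are in ΔF/F0 units.
    """

    n_responders: int = 10
    n_nonresponders: int = 10
    frame_rate: float = 4.0
    duration: float = 185.0
    stimulus_time: float = 10.0
    transient_amplitude: float = 1.0
    transient_rise_tau: float = 0.5
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if not 0 <= self.stimulus_time < self.duration:
            raise ValueError("stimulus_time must lie within the record")
        if min(self.n_responders, self.n_nonresponders) < 0:
            raise ValueError("soma counts must be >= 0")
        if self.noise_sd < 0 or self.transient_rise_tau <= 0:
            raise ValueError("noise_sd >= 0 and transient_rise_tau > 0 required")


@dataclass
class CalciumMovieTruth:
    centers: np.ndarray      # (n, 2) y, x
    is_responder: np.ndarray  # (n,) bool


BACKGROUND_LEVEL = 50.0
SOMA_REST_CONTRAST = 1.0   # resting soma brightness over background, dff units
SOMA_RADIUS_PX = 6.0


def _soma_footprint(shape: tuple[int, int], center: tuple[int, int]) -> np.ndarray:
    disk = _disk_mask(shape, center, SOMA_RADIUS_PX).astype(float)
    return ndi.gaussian_filter(disk, 1.0)


def make_calcium_movie(
    spec: CalciumMovieSpec, image_size: int = 128
) -> tuple["CalciumMovie", CalciumMovieTruth]:
    """Synthesize a stimulus-locked calcium movie plus ground-truth labels.

    Somata are soft-edged disks of resting contrast ``SOMA_REST_CONTRAST``
    over a flat background; responders add a rising-exponential ΔF/F0
    transient of ``transient_amplitude`` starting at ``stimulus_time``.
    Placement is rejection-sampled with a minimum center separation; an
    over-dense request fails with the density limit in the message.
    """
    from .calcium import CalciumMovie

    rng = np.random.default_rng(spec.seed)
    n_frames = int(round(spec.duration * spec.frame_rate))
    n_somata = spec.n_responders + spec.n_nonresponders
    shape = (image_size, image_size)
    min_sep = 2 * SOMA_RADIUS_PX + 6
    margin = int(SOMA_RADIUS_PX + 3)

    centers: list[tuple[int, int]] = []
    attempts = 0
    while len(centers) < n_somata:
        attempts += 1
        if attempts > 5000:
            raise ValueError(
                f"could not place {n_somata} somata with separation {min_sep:g} px "
                f"in a {image_size}-px field after 5000 attempts; reduce the density"
            )
        c = tuple(rng.integers(margin, image_size - margin, size=2))
        if all((c[0] - y) ** 2 + (c[1] - x) ** 2 >= min_sep**2 for y, x in centers):
            centers.append(c)

    labels = np.array([True] * spec.n_responders + [False] * spec.n_nonresponders)

    t = np.arange(n_frames) / spec.frame_rate
    g = np.where(
        t >= spec.stimulus_time,
        1.0 - np.exp(-(t - spec.stimulus_time) / spec.transient_rise_tau),
        0.0,
    )

    static = np.zeros(shape)
    dynamic = np.zeros(shape)
    for (cy, cx), resp in zip(centers, labels):
        fp = _soma_footprint(shape, (cy, cx))
        static += fp * SOMA_REST_CONTRAST
        if resp:
            dynamic += fp * spec.transient_amplitude

    # assemble in float32 with in-place ops (the movie is ~12M samples)
    flat = np.float32(1.0) + static.astype(np.float32).ravel()
    frames = g.astype(np.float32)[:, None] * dynamic.astype(np.float32).ravel()[None, :]
    frames += flat[None, :]
    frames *= np.float32(BACKGROUND_LEVEL)
    if spec.noise_sd > 0:
        noise = rng.standard_normal(frames.shape, dtype=np.float32)
        noise *= np.float32(BACKGROUND_LEVEL * spec.noise_sd)
        frames += noise
    frames = frames.reshape((n_frames,) + shape)

    movie = CalciumMovie(
        frames,
        frame_rate=spec.frame_rate,
        stimulus_time=spec.stimulus_time,
    )
    return movie, CalciumMovieTruth(np.array(centers, dtype=float), labels)


# ---------------------------------------------------------------------------
# viability tables
# ---------------------------------------------------------------------------

def make_viability_table(
    true_rates: Mapping[str, Sequence[float]],
    n_cells: int,
    timepoints: Sequence[float] = (0.0, 30.0, 60.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Binomially sampled AO/PI viable counts per condition and timepoint.

    ``true_rates[condition]`` gives the true survival fraction at each of
    ``timepoints`` (default 0/30/60 min of CPA exposure).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cond, rates in true_rates.items():
        if len(rates) != len(timepoints):
            raise ValueError(f"condition {cond!r}: need one rate per timepoint")
        for tp, rate in zip(timepoints, rates):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"survival fraction {rate} outside [0, 1]")
            viable = int(rng.binomial(n_cells, rate))
            rows.append(
                {"condition": cond, "timepoint_min": tp, "viable": viable,
                 "nonviable": n_cells - viable}
            )
    return pd.DataFrame(rows, columns=["condition", "timepoint_min", "viable", "nonviable"])


# ---------------------------------------------------------------------------
# freeze logs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FreezeProfile:
    """Controlled-rate freezer schedule.

    The run starts at 20 C, ramps at -10 C/min to the nucleation
    temperature ``t_nuc``, holds ``hold_min`` minutes (nucleation is
    induced at the hold), then ramps at ``cooling_rate`` (B) to -60 C and
    at -10 C/min to -100 C. ``segments`` overrides the post-hold ramps as
    (rate C/min, end temperature C) pairs.
    """

    t_nuc: float = -4.0
    cooling_rate: float = -1.0
    hold_min: float = 15.0
    segments: tuple[tuple[float, float], ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not -40.0 < self.t_nuc < 0.0:
            raise ValueError("t_nuc must be in (-40, 0) C")
        if self.cooling_rate >= 0:
            raise ValueError("cooling_rate (B) must be negative")
        if self.hold_min < 0:
            raise ValueError("hold_min must be >= 0")
        if self.segments is None:
            object.__setattr__(
                self, "segments", ((self.cooling_rate, -60.0), (-10.0, -100.0))
            )
        prev = self.t_nuc
        for rate, end in self.segments:
            if rate >= 0:
                raise ValueError("segment rates must be negative")
            if end >= prev:
                raise ValueError("segment end temperatures must be strictly decreasing")
            prev = end


def make_freeze_log(profile: FreezeProfile, sampling_dt: float = 1.0) -> pd.DataFrame:
    """Piecewise-linear sample-temperature trace of the freeze schedule,
    sampled every ``sampling_dt`` seconds."""
    if sampling_dt <= 0:
        raise ValueError("sampling_dt must be > 0")
    pts_t = [0.0]
    pts_T = [20.0]

    def ramp_to(temp: float, rate: float) -> None:
        dt_min = (pts_T[-1] - temp) / -rate  # rate < 0, temp below current
        pts_t.append(pts_t[-1] + dt_min * 60.0)
        pts_T.append(temp)

    ramp_to(profile.t_nuc, -10.0)
    pts_t.append(pts_t[-1] + profile.hold_min * 60.0)
    pts_T.append(profile.t_nuc)
    for rate, end in profile.segments:
        ramp_to(end, rate)

    times = np.arange(0.0, pts_t[-1] + sampling_dt / 2, sampling_dt)
    temps = np.interp(times, pts_t, pts_T)
    return pd.DataFrame({"time_s": times, "temperature_C": temps})


# ---------------------------------------------------------------------------
# micrographs of suspended cells
# ---------------------------------------------------------------------------

def make_micrograph(
    diameters_um: Sequence[float],
    image_size: int = 512,
    pixel_pitch: float = 0.5,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Brightfield-like field of non-overlapping bright disks of the
    requested diameters (um), for fresh-cell diameter quantification."""
    rng = np.random.default_rng(seed)
    img = np.zeros((image_size, image_size))
    placed: list[tuple[float, float, float]] = []
    for d in diameters_um:
        r = 0.5 * d / pixel_pitch
        for _ in range(5000):
            cy, cx = rng.uniform(r + 2, image_size - r - 2, size=2)
            if all(
                (cy - py) ** 2 + (cx - px) ** 2 > (r + pr + 3) ** 2
                for py, px, pr in placed
            ):
                placed.append((cy, cx, r))
                img[_disk_mask(img.shape, (cy, cx), r)] = 100.0
                break
        else:
            raise ValueError(
                f"could not place a {d:g}-um cell without overlap; field too dense"
            )
    if noise_sd > 0:
        img = img + noise_sd * rng.standard_normal(img.shape)
    return img
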