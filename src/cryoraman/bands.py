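"""Raman band registry.

Characteristic wavenumbers of the substances tracked in frozen-cell
hyperspectral images. Positions are literature-standard values for the
532-nm confocal configuration; widths are the Gaussian sigma of the
synthetic band model and also set the default integration window
(center +/- 3 sigma). Everything here is data, not behaviour: analyses
take a registry argument so alternative assignments never require code
changes.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Band:
    """A single Raman band: ``center`` and ``sigma`` in cm^-1."""

    name: str
    center: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"band {self.name!r}: sigma must be > 0")

    @property
    def window(self) -> tuple[float, float]:
        """Default integration window, center +/- 3 sigma."""
        return (self.center - 3.0 * self.sigma, self.center + 3.0 * self.sigma)


#: Default band assignments (cm^-1). Editable: pass your own mapping with the
#: same shape to any function that takes ``bands``.
DEFAULT_BANDS: dict[str, Band] = {
    "amide_I": Band("amide_I", 1655.0, 12.0),      # protein backbone C=O
    "ch_stretch": Band("ch_stretch", 2935.0, 20.0),  # cellular C-H
    "oh_ice": Band("oh_ice", 3125.0, 40.0),        # O-H stretch / ice
    "cyt_c": Band("cyt_c", 750.0, 10.0),           # cytochrome C pyrrole
    "glycerol": Band("glycerol", 850.0, 12.0),     # non-DMSO CPA marker
    "dmso": Band("dmso", 670.0, 12.0),             # S=O / C-S
    "sucrose": Band("sucrose", 1120.0, 12.0),
}


def validate_separability(bands: dict[str, Band]) -> None:
    """Require band centers spaced by more than 4x the wider sigma.

    Guarantees the +/-3 sigma integration windows of any two bands do not
    overlap, so single-band integrals are separable.
    """
    items = sorted(bands.values(), key=lambda b: b.center)
    for a, b in zip(items, items[1:]):
        spacing = b.center - a.center
        if spacing <= 4.0 * max(a.sigma, b.sigma):
            raise ValueError(
                f"bands {a.name!r} and {b.name!r} are {spacing:g} cm^-1 apart, "
                f"closer than 4x the wider sigma ({max(a.sigma, b.sigma):g}); "
                "integration windows would overlap"
            )
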