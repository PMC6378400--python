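"""Minimal calibrated-image stage: grey-standard normalization, region means,
and relative marking area.

Images arrive as linear multi-band stacks (one band per cone channel) with an
integer label mask naming each region: wing marking, wing background, the two
PTFE grey standards (7% and 93% reflectance) and off-wing pixels.  The only
photometric correction performed here is the per-band affine map that sends the
observed standard means onto their true reflectances — that removes the global
gain/offset a photographing session imposes.  Camera linearization is assumed
done upstream; an optional power-law linearizer is provided (default exponent
1.0, i.e. identity).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DegenerateStandardsError, EmptyRegionError, InvalidArgumentError
from .vision import ConeCatch

#: Region ids used in label masks (0-based pixel coords, row-major arrays).
LABELS = {
    "off_wing": 0,
    "background": 1,
    "marking": 2,
    "standard_low": 3,
    "standard_high": 4,
}

BAND_NAMES = ("uv", "sw", "mw", "lw", "dbl")


@dataclass(frozen=True)
class LabelledStack:
    """A multi-band image with its region label mask.

    ``bands`` has shape (n_bands, H, W); ``labels`` is (H, W) int using the
    ids in :data:`LABELS`; ``scale`` is pixels per mm (kept for provenance —
    every measure here is scale-free).
    """

    bands: np.ndarray
    labels: np.ndarray
    band_names: tuple = BAND_NAMES
    scale: float = 100.0

    def __post_init__(self):
        bands = np.asarray(self.bands, dtype=float)
        labels = np.asarray(self.labels)
        if bands.ndim != 3 or bands.shape[0] != len(self.band_names):
            raise InvalidArgumentError(
                f"bands must be (n_bands, H, W) with {len(self.band_names)} bands"
            )
        if labels.shape != bands.shape[1:]:
            raise InvalidArgumentError("labels shape must match band shape")
        if not np.all(np.isfinite(bands)) or np.any(bands < 0):
            raise InvalidArgumentError("band values must be finite and >= 0")
        object.__setattr__(self, "bands", bands)
        object.__setattr__(self, "labels", labels.astype(int))

    def mask(self, region: str) -> np.ndarray:
        if region not in LABELS:
            raise InvalidArgumentError(f"unknown region {region!r}; known: {sorted(LABELS)}")
        return self.labels == LABELS[region]


def linearize(img: LabelledStack, exponent: float = 1.0) -> LabelledStack:
    """Optional power-law linearization (identity by default)."""
    if exponent <= 0:
        raise InvalidArgumentError("linearization exponent must be > 0")
    if exponent == 1.0:
        return img
    return replace(img, bands=np.power(img.bands, exponent))


def normalize_image(
    img: LabelledStack,
    low_reflectance: float = 0.07,
    high_reflectance: float = 0.93,
) -> LabelledStack:
    """Normalize each band against the two grey standards.

    Per band, the affine map taking (mean of the low standard, mean of the
    high standard) onto (``low_reflectance``, ``high_reflectance``) is applied
    to every pixel, expressing the image on the reflectance scale.  Idempotent
    on images whose standards already sit at their true values.  Equal or
    inverted standard means raise :class:`DegenerateStandardsError`.
    """
    lo_mask, hi_mask = img.mask("standard_low"), img.mask("standard_high")
    if not lo_mask.any() or not hi_mask.any():
        raise EmptyRegionError("both grey standards must be present in the label mask")
    out = np.empty_like(img.bands)
    for b in range(img.bands.shape[0]):
        band = img.bands[b]
        lo, hi = float(band[lo_mask].mean()), float(band[hi_mask].mean())
        if hi <= lo:
            raise DegenerateStandardsError(
                f"band {img.band_names[b]}: high-standard mean ({hi:g}) must exceed "
                f"low-standard mean ({lo:g}); standards equal, inverted or mislabelled"
            )
        slope = (high_reflectance - low_reflectance) / (hi - lo)
        out[b] = low_reflectance + slope * (band - lo)
    # Affine output can dip microscopically below zero from noise; clip exact
    # negatives introduced by the offset only outside the standards' range.
    out = np.clip(out, 0.0, None)
    return replace(img, bands=out)


def region_mean(img: LabelledStack, region: str) -> ConeCatch:
    """Arithmetic mean of each band over one labelled region, as a ConeCatch."""
    m = img.mask(region)
    if not m.any():
        raise EmptyRegionError(f"region {region!r} contains no pixels")
    means = {name: float(img.bands[b][m].mean()) for b, name in enumerate(img.band_names)}
    return ConeCatch(**means)


def relative_marking_area(img: LabelledStack) -> float:
    """Percentage of the wing (marking + background) occupied by markings."""
    n_mark = int(img.mask("marking").sum())
    n_back = int(img.mask("background").sum())
    if n_mark + n_back == 0:
        raise EmptyRegionError("wing is empty: no marking or background pixels")
    return 100.0 * n_mark / (n_mark + n_back)


# ---------------------------------------------------------------------------
# File I/O (multi-page TIFF for bands, PNG for labels)
# ---------------------------------------------------------------------------

def write_stack(img: LabelledStack, tiff_path, labels_path) -> None:
    """Write bands as a multi-page float TIFF and labels as an 8-bit PNG."""
    import tifffile
    from PIL import Image

    tifffile.imwrite(str(tiff_path), img.bands.astype(np.float32))
    Image.fromarray(img.labels.astype(np.uint8)).save(str(labels_path))


def read_stack(tiff_path, labels_path, band_names: tuple = BAND_NAMES, scale: float = 100.0) -> LabelledStack:
    """Read a stack previously written by :func:`write_stack`."""
    import tifffile
    from PIL import Image

    bands = np.asarray(tifffile.imread(str(tiff_path)), dtype=float)
    labels = np.asarray(Image.open(str(labels_path)), dtype=int)
    return LabelledStack(bands=bands, labels=labels, band_names=band_names, scale=scale)
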