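"""Band densitometry and immunofluorescence pERK/tERK ratios.

Immunoblot bands are quantified as background-corrected integrated
intensity inside a rectangular ROI; pERK and tERK are normalized to the
GAPDH loading control, and the reported readout is the ratio of the
normalized values — in which GAPDH cancels algebraically, a property the
pipeline asserts. Whole-mount immunofluorescence activity is the ratio of
raw integrated densities of pERK and tERK in a shared ROI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .fretindex import ROI, MeasurementError


@dataclass(frozen=True)
class RectROI:
    """Half-open rectangular ROI [y0, y1) x [x0, x1), 0-based pixels."""

    y0: int
    y1: int
    x0: int
    x1: int

    def __post_init__(self) -> None:
        if not (self.y1 > self.y0 and self.x1 > self.x0):
            raise MeasurementError("rectangular ROI must have positive extent")

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def n_pixels(self) -> int:
        return self.height * self.width


@dataclass
class LaneQuant:
    """Background-corrected band densities of one lane and their ratio."""

    sample_id: str
    pERK_density: float
    tERK_density: float
    GAPDH_density: float

    @property
    def norm_ratio(self) -> float:
        return normalized_perk_ratio(self.pERK_density, self.tERK_density, self.GAPDH_density)


def band_density(
    gel_image: np.ndarray,
    roi: RectROI,
    background_rule: str = "flank_median",
) -> float:
    """Integrated band intensity minus a local background estimate.

    Background is the median of a same-size region flanking the band to the
    left (falling back to the right flank at the image edge), times the ROI
    pixel count; this removes any uniform offset exactly. If neither flank
    fits, the uncorrected sum is returned with a warning. Saturated pixels
    (at the dtype maximum for integer images) also raise a warning.
    """
    img = np.asarray(gel_image)
    ny, nx = img.shape
    if not (0 <= roi.y0 and roi.y1 <= ny and 0 <= roi.x0 and roi.x1 <= nx):
        raise MeasurementError("ROI extends outside the gel image")
    patch = img[roi.y0 : roi.y1, roi.x0 : roi.x1].astype(float)
    if np.issubdtype(img.dtype, np.integer) and (patch == np.iinfo(img.dtype).max).any():
        warnings.warn("saturated pixels inside band ROI", stacklevel=2)
    raw = float(patch.sum())
    if background_rule == "none":
        return raw
    if background_rule != "flank_median":
        raise MeasurementError(f"unknown background rule {background_rule!r}")
    w = roi.width
    flanks = []
    if roi.x0 - w >= 0:
        flanks.append(img[roi.y0 : roi.y1, roi.x0 - w : roi.x0].astype(float))
    elif roi.x1 + w <= nx:
        flanks.append(img[roi.y0 : roi.y1, roi.x1 : roi.x1 + w].astype(float))
    if not flanks:
        warnings.warn(
            "no flanking region available; returning uncorrected density", stacklevel=2
        )
        return raw
    background = float(np.median(flanks[0]))
    return raw - background * roi.n_pixels


def normalized_perk_ratio(perk: float, terk: float, gapdh: float) -> float:
    """(pERK/GAPDH) / (tERK/GAPDH); the loading control cancels."""
    bad = [n for n, v in (("tERK", terk), ("GAPDH", gapdh)) if v == 0]
    if bad:
        raise MeasurementError(f"zero denominator band(s): {', '.join(bad)}")
    return (perk / gapdh) / (terk / gapdh)


def quantify_lane(
    gel_image: np.ndarray,
    rois: dict[str, RectROI],
    sample_id: str = "",
    background_rule: str = "flank_median",
) -> LaneQuant:
    """Quantify one lane's pERK, tERK and GAPDH bands."""
    missing = {"pERK", "tERK", "GAPDH"} - set(rois)
    if missing:
        raise MeasurementError(f"missing band ROIs: {sorted(missing)}")
    d = {k: band_density(gel_image, rois[k], background_rule) for k in ("pERK", "tERK", "GAPDH")}
    return LaneQuant(
        sample_id=sample_id,
        pERK_density=d["pERK"],
        tERK_density=d["tERK"],
        GAPDH_density=d["GAPDH"],
    )


def if_perk_ratio(perk_image: np.ndarray, terk_image: np.ndarray, roi: ROI) -> float:
    """Raw-integrated-density ratio pERK/tERK inside a shared ROI."""
    perk = np.asarray(perk_image, dtype=float)
    terk = np.asarray(terk_image, dtype=float)
    if perk.shape != terk.shape:
        raise MeasurementError("pERK and tERK images must share shape")
    if roi.mask.shape != perk.shape:
        raise MeasurementError("ROI shape does not match images")
    terk_sum = float(terk[roi.mask].sum())
    if terk_sum == 0:
        raise MeasurementError("tERK integrated density is zero: ratio undefined")
    return float(perk[roi.mask].sum()) / terk_sum
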