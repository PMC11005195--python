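"""Ratiometric live-imaging readout: the per-ROI "FRET index".

The live readout of the CFP/YPet biosensor is computed as sum-intensity
z-projections of the donor and acceptor channels, a per-pixel
acceptor/donor ratio image (pixels with donor signal below a floor are
masked out rather than divided), and the raw integrated density — the sum
of valid ratio pixels — inside each region of interest. Group effects are
expressed as fold change of treated vs. control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon

from .spectral import ChannelPair

DONOR_FLOOR_FRACTION = 0.01  # default floor: 1% of the donor image maximum


class MeasurementError(ValueError):
    """Raised for invalid ROIs or degenerate measurement inputs."""


@dataclass
class ROI:
    """Labelled region of interest as a boolean pixel mask (0-based)."""

    label: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or not self.mask.any():
            raise MeasurementError(f"ROI {self.label!r} must be a non-empty 2-D mask")

    @classmethod
    def from_polygon(
        cls, label: str, vertices: Sequence[Sequence[float]], shape: tuple[int, int]
    ) -> "ROI":
        """Build from (row, col) polygon vertices; pixels inside the polygon."""
        verts = np.asarray(vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
            raise MeasurementError("polygon needs >= 3 (row, col) vertices")
        rr, cc = draw_polygon(verts[:, 0], verts[:, 1], shape=shape)
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        if not mask.any():
            raise MeasurementError(f"polygon ROI {label!r} covers no pixels")
        return cls(label=label, mask=mask)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class FretIndexMeasurement:
    """Raw integrated density of the ratio image within one ROI."""

    embryo_id: str
    roi_label: str
    index: float
    group: str = ""
    donor_floor: float = float("nan")
    n_valid_pixels: int = 0
    valid: bool = True


def sum_projection(volume: np.ndarray) -> np.ndarray:
    """Sum-intensity z-projection of a (z, y, x) volume."""
    volume = np.asarray(volume, dtype=float)
    if volume.ndim == 2:
        return volume.copy()
    if volume.ndim != 3 or volume.shape[0] < 1:
        raise MeasurementError("need a (z, y, x) volume with >= 1 plane")
    return volume.sum(axis=0)


def ratio_image(
    acceptor_2d: np.ndarray,
    donor_2d: np.ndarray,
    donor_floor: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel acceptor/donor ratio with a validity mask.

    Pixels whose donor signal falls below ``donor_floor`` are marked invalid
    (ratio set to 0 there) and must be excluded from downstream ROI sums;
    this guards the division against background pixels.
    """
    acceptor_2d = np.asarray(acceptor_2d, dtype=float)
    donor_2d = np.asarray(donor_2d, dtype=float)
    if acceptor_2d.shape != donor_2d.shape:
        raise MeasurementError(
            f"channel shapes differ: {acceptor_2d.shape} vs {donor_2d.shape}"
        )
    if not donor_floor > 0:
        raise MeasurementError("donor_floor must be positive")
    valid = donor_2d >= donor_floor
    ratio = np.zeros_like(donor_2d)
    np.divide(acceptor_2d, donor_2d, out=ratio, where=valid)
    return ratio, valid


def default_donor_floor(donor_2d: np.ndarray) -> float:
    floor = DONOR_FLOOR_FRACTION * float(np.max(donor_2d))
    return floor if floor > 0 else np.finfo(float).tiny


def fret_index(
    channel_pair: ChannelPair,
    roi: ROI,
    donor_floor: float | None = None,
    embryo_id: str = "",
    group: str = "",
    ratio_of_projections: bool = True,
) -> FretIndexMeasurement:
    """Per-ROI FRET index: raw integrated density of the ratio image.

    Default order of operations: sum-project each channel over z, divide,
    then sum the valid ratio pixels inside the ROI. Setting
    ``ratio_of_projections=False`` instead divides per z-plane and
    sum-projects the per-plane ratios (the alternative reading of
    "projections of ratiometric images"; kept behind the flag for
    sensitivity analysis).
    """
    donor = np.asarray(channel_pair.donor, dtype=float)
    acceptor = np.asarray(channel_pair.acceptor, dtype=float)
    if ratio_of_projections or donor.ndim == 2:
        donor2d = sum_projection(donor)
        acceptor2d = sum_projection(acceptor)
        floor = default_donor_floor(donor2d) if donor_floor is None else donor_floor
        ratio, valid = ratio_image(acceptor2d, donor2d, floor)
    else:
        floor = default_donor_floor(donor) if donor_floor is None else donor_floor
        planes, valids = zip(
            *(ratio_image(acceptor[z], donor[z], floor) for z in range(donor.shape[0]))
        )
        ratio = np.sum(planes, axis=0)
        valid = np.logical_and.reduce(valids)
    if roi.mask.shape != ratio.shape:
        raise MeasurementError(
            f"ROI {roi.label!r} shape {roi.mask.shape} does not match image {ratio.shape}"
        )
    sel = roi.mask & valid
    n_valid = int(sel.sum())
    if n_valid == 0:
        return FretIndexMeasurement(
            embryo_id=embryo_id,
            roi_label=roi.label,
            index=float("nan"),
            group=group,
            donor_floor=floor,
            n_valid_pixels=0,
            valid=False,
        )
    return FretIndexMeasurement(
        embryo_id=embryo_id,
        roi_label=roi.label,
        index=float(ratio[sel].sum()),
        group=group,
        donor_floor=floor,
        n_valid_pixels=n_valid,
    )


def measurements_frame(measurements: Iterable[FretIndexMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "embryo_id": m.embryo_id,
            "group": m.group,
            "roi": m.roi_label,
            "index": m.index,
            "n_valid_pixels": m.n_valid_pixels,
            "valid": m.valid,
        }
        for m in measurements
    )


def fold_change(
    measurements: Iterable[FretIndexMeasurement],
    treated_group: str,
    control_group: str,
    paired: bool = False,
) -> tuple[float, pd.DataFrame]:
    """Fold change (FC) of treated vs. control FRET indices.

    Unpaired mode: per-embryo FC = index_i / mean(control indices); the
    group FC is the mean of per-embryo FCs (control embryos get their own
    FCs relative to the control mean, so a group against itself gives
    exactly 1). Paired mode matches embryos by ``embryo_id`` across the two
    groups (pre/post design) and computes per-embryo treated/control.
    """
    df = measurements_frame(m for m in measurements if m.valid)
    treated = df[df["group"] == treated_group]
    control = df[df["group"] == control_group]
    if treated.empty or control.empty:
        raise MeasurementError("both treated and control groups must be non-empty")
    if paired:
        merged = treated.merge(
            control, on=["embryo_id", "roi"], suffixes=("_treated", "_control")
        )
        if merged.empty:
            raise MeasurementError("paired mode: no embryo_id/roi matches across groups")
        if (merged["index_control"] <= 0).any():
            raise MeasurementError("paired mode: control index <= 0")
        per = pd.DataFrame(
            {
                "embryo_id": merged["embryo_id"],
                "roi": merged["roi"],
                "fc": merged["index_treated"] / merged["index_control"],
            }
        )
    else:
        control_mean = float(control["index"].mean())
        if control_mean <= 0:
            raise MeasurementError("control mean index must be positive")
        per = pd.DataFrame(
            {
                "embryo_id": treated["embryo_id"],
                "roi": treated["roi"],
                "fc": treated["index"] / control_mean,
            }
        )
    return float(per["fc"].mean()), per
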