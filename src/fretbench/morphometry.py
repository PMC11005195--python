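"""Morphological disease readouts from binary embryo masks.

Two assays: the oval-embryo test (major/minor axis ratio of the
~11 hpf embryo; elevated ratios flag convergence-extension defects) and
body length of hatched larvae (straight snout-to-tail distance). Axes come
from the intensity-equivalent ellipse of the mask's second central moments
— a reproducible substitute for manually drawn axis lines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage.measure import label as cc_label
from skimage.measure import regionprops


class MorphometryError(ValueError):
    """Raised for degenerate masks or group tables."""


@dataclass
class MorphometryResult:
    embryo_id: str
    group: str = ""
    major_axis: float = float("nan")
    minor_axis: float = float("nan")
    axis_ratio: float = float("nan")
    body_length: float = float("nan")
    unit: str = "px"


def axis_lengths(mask: np.ndarray) -> tuple[float, float, float]:
    """Major/minor axis lengths of the moments-equivalent ellipse, and ratio.

    The mask must contain exactly one connected foreground component; the
    axes are those of the ellipse with the same normalized second central
    moments as the region (rotation/translation invariant).
    """
    mask = np.asarray(mask, dtype=bool)
    labeled, n = cc_label(mask, return_num=True)
    if n != 1:
        raise MorphometryError(
            f"mask must have exactly one connected component, found {n}"
        )
    props = regionprops(labeled)[0]
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    if minor <= 0:
        raise MorphometryError("degenerate mask: zero minor axis")
    return major, minor, major / minor


def body_length(
    mask_or_endpoints: np.ndarray | tuple,
    calibration: float | None = None,
) -> float:
    """Straight-line body length: Euclidean snout-to-tail distance.

    Accepts either explicit ((y0, x0), (y1, x1)) endpoints or a binary mask,
    for which the farthest pair of foreground boundary pixels is used (the
    diameter of the mask's convex hull). ``calibration`` converts px to um.
    """
    if isinstance(mask_or_endpoints, np.ndarray) and mask_or_endpoints.dtype != object:
        mask = np.asarray(mask_or_endpoints, dtype=bool)
        pts = np.argwhere(mask)
        if len(pts) < 2:
            raise MorphometryError("mask has fewer than 2 foreground pixels")
        # hull vertices suffice: the diameter of a point set is attained
        # on its convex hull
        if len(pts) > 3:
            try:
                pts = pts[ConvexHull(pts).vertices]
            except Exception:  # collinear rod: hull degenerate, use all points
                pass
        length = float(pdist(pts).max())
    else:
        (y0, x0), (y1, x1) = mask_or_endpoints
        length = float(np.hypot(y1 - y0, x1 - x0))
    if length == 0:
        raise MorphometryError("degenerate measurement: coincident endpoints")
    return length * calibration if calibration is not None else length


def measure_mask(
    mask: np.ndarray,
    embryo_id: str = "",
    group: str = "",
    calibration: float | None = None,
) -> MorphometryResult:
    """Both assays on one mask."""
    major, minor, ratio = axis_lengths(mask)
    scale = calibration if calibration is not None else 1.0
    return MorphometryResult(
        embryo_id=embryo_id,
        group=group,
        major_axis=major * scale,
        minor_axis=minor * scale,
        axis_ratio=ratio,
        body_length=body_length(mask, calibration),
        unit="um" if calibration is not None else "px",
    )


def oval_assay(results_by_group: dict[str, list[MorphometryResult]]) -> pd.DataFrame:
    """Group table of axis-ratio medians and quartiles for >= 2 groups.

    Single-embryo groups are kept but flagged underpowered for comparison.
    """
    if len(results_by_group) < 2:
        raise MorphometryError("oval assay needs >= 2 groups")
    rows = []
    for group, results in results_by_group.items():
        if not results:
            raise MorphometryError(f"group {group!r} has no measurements")
        ratios = np.array([r.axis_ratio for r in results], dtype=float)
        rows.append(
            {
                "group": group,
                "n": ratios.size,
                "median_ratio": float(np.median(ratios)),
                "q25": float(np.percentile(ratios, 25)),
                "q75": float(np.percentile(ratios, 75)),
                "underpowered": ratios.size < 2,
                "values": list(map(float, ratios)),
            }
        )
    return pd.DataFrame(rows)
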