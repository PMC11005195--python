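"""Acceptor-photobleaching (AB) FRET efficiency and donor-acceptor distance.

Destroying the acceptor in an ROI removes the FRET de-excitation path, so
the donor de-quenches: its intensity rises. With ``DA`` the ROI-mean donor
intensity before bleaching and ``DOmega`` after, the transfer efficiency is

    E = (DOmega - DA) / DOmega

and the apparent donor-acceptor separation follows from the Förster
relation E = R0^6 / (R0^6 + R^6):

    R_DA = R0 * (1/E - 1)^(1/6)

with R0 = 4.7 nm for the CFP/YFP-family pair. Non-positive E has no real
distance and is excluded from R_DA (but retained in E-level statistics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fretindex import ROI, MeasurementError

R0_DEFAULT_NM = 4.7
E_CLASS_THRESHOLD_PERCENT = 7.53


@dataclass(frozen=True)
class ForsterConfig:
    """Förster distance of the donor-acceptor pair, nm."""

    r0_nm: float = R0_DEFAULT_NM

    def __post_init__(self) -> None:
        if not self.r0_nm > 0:
            raise MeasurementError("R0 must be positive")


@dataclass
class DonorPrePost:
    """ROI-mean donor intensity before (DA) and after (DOmega) bleaching."""

    DA: float
    DOmega: float


@dataclass
class ABFretMeasurement:
    """Per-ROI AB-FRET record: efficiency, distance, pre-bleach metrics."""

    embryo_id: str
    roi_label: str
    E: float  # efficiency fraction; E_percent = 100 * E
    R_DA_nm: float | None
    excluded_reason: str  # "none" | "E_zero_or_negative" | "roi_not_bleached"
    pre_acceptor_donor_ratio: float
    pre_donor_intensity: float
    group: str = ""

    @property
    def E_percent(self) -> float:
        return 100.0 * self.E


def efficiency(
    pre_donor_frames: np.ndarray,
    post_donor_frame: np.ndarray,
    roi: ROI,
) -> tuple[DonorPrePost, float]:
    """AB-FRET efficiency from ROI-mean donor intensities.

    The pre-bleach scans (any number >= 1, stacked on axis 0) are averaged
    before taking the ROI mean. Negative E (donor dimmer after bleaching,
    i.e. noise or drift) is returned as-is, never clamped — exclusion is the
    caller's decision via the distance step.
    """
    pre = np.asarray(pre_donor_frames, dtype=float)
    if pre.ndim == 2:
        pre = pre[None]
    if pre.ndim != 3 or pre.shape[0] < 1:
        raise MeasurementError("need >= 1 pre-bleach donor frame")
    post = np.asarray(post_donor_frame, dtype=float)
    if pre.shape[1:] != post.shape:
        raise MeasurementError("pre and post frames must share shape")
    if roi.mask.shape != post.shape:
        raise MeasurementError("ROI shape does not match frames")
    pre_mean = pre.mean(axis=0)
    da = float(pre_mean[roi.mask].mean())
    domega = float(post[roi.mask].mean())
    if domega == 0:
        raise MeasurementError("post-bleach donor mean is zero: E undefined")
    return DonorPrePost(DA=da, DOmega=domega), (domega - da) / domega


def distance_from_efficiency(
    e: float, forster: ForsterConfig = ForsterConfig()
) -> float | None:
    """Donor-acceptor distance R_DA = R0 * (1/E - 1)^(1/6), nm.

    Returns ``None`` for E <= 0 (excluded: no real distance for zero or
    negative efficiency). E >= 1 returns the limit 0.0 with a warning.
    """
    if e <= 0:
        return None
    if e >= 1:
        warnings.warn("E >= 1: returning the contact limit R_DA = 0", stacklevel=2)
        return 0.0
    return forster.r0_nm * (1.0 / e - 1.0) ** (1.0 / 6.0)


def pre_ab_metrics(
    pre_donor: np.ndarray, pre_acceptor: np.ndarray, roi: ROI
) -> tuple[float, float]:
    """Pre-bleach intensity metrics: acceptor/donor ratio and donor level.

    Both are ROI means of the averaged pre-bleach frames. Reduced FRET (e.g.
    MEK-inhibited embryos) shows as a lower acceptor/donor ratio and a
    brighter donor (less spatial quenching).
    """
    pre_d = np.asarray(pre_donor, dtype=float)
    pre_a = np.asarray(pre_acceptor, dtype=float)
    if pre_d.ndim == 2:
        pre_d = pre_d[None]
    if pre_a.ndim == 2:
        pre_a = pre_a[None]
    if pre_d.shape[1:] != pre_a.shape[1:]:
        raise MeasurementError("donor and acceptor frames must share shape")
    if roi.mask.shape != pre_d.shape[1:]:
        raise MeasurementError("ROI shape does not match frames")
    donor_mean = float(pre_d.mean(axis=0)[roi.mask].mean())
    acceptor_mean = float(pre_a.mean(axis=0)[roi.mask].mean())
    if donor_mean == 0:
        raise MeasurementError("pre-bleach donor mean is zero: ratio undefined")
    return acceptor_mean / donor_mean, donor_mean


def run_abfret(
    bleach_series,
    rois: Sequence[ROI],
    forster: ForsterConfig = ForsterConfig(),
    embryo_id: str = "",
    group: str = "",
    min_bleach_overlap: float = 0.99,
) -> list[ABFretMeasurement]:
    """Evaluate every ROI of a bleach series into one AB-FRET record each.

    ROIs that do not lie (almost) entirely inside the bleached region carry
    no de-quenching signal; they are flagged ``roi_not_bleached`` and their
    E is reported as NaN.
    """
    out = []
    for roi in rois:
        ratio, donor_level = pre_ab_metrics(
            bleach_series.pre_donor, bleach_series.pre_acceptor, roi
        )
        overlap = float((roi.mask & bleach_series.bleach_roi).sum()) / roi.n_pixels
        if overlap < min_bleach_overlap:
            out.append(
                ABFretMeasurement(
                    embryo_id=embryo_id,
                    roi_label=roi.label,
                    E=float("nan"),
                    R_DA_nm=None,
                    excluded_reason="roi_not_bleached",
                    pre_acceptor_donor_ratio=ratio,
                    pre_donor_intensity=donor_level,
                    group=group,
                )
            )
            continue
        _, e = efficiency(bleach_series.pre_donor, bleach_series.post_donor, roi)
        r_da = distance_from_efficiency(e, forster)
        out.append(
            ABFretMeasurement(
                embryo_id=embryo_id,
                roi_label=roi.label,
                E=e,
                R_DA_nm=r_da,
                excluded_reason="none" if r_da is not None else "E_zero_or_negative",
                pre_acceptor_donor_ratio=ratio,
                pre_donor_intensity=donor_level,
                group=group,
            )
        )
    return out


def measurements_frame(measurements: Iterable[ABFretMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "embryo_id": m.embryo_id,
            "group": m.group,
            "roi": m.roi_label,
            "E_percent": m.E_percent,
            "R_DA_nm": m.R_DA_nm,
            "excluded_reason": m.excluded_reason,
            "pre_ratio": m.pre_acceptor_donor_ratio,
            "pre_donor": m.pre_donor_intensity,
        }
        for m in measurements
    )


def classify_by_threshold(
    e_values_percent: Sequence[float],
    threshold: float = E_CLASS_THRESHOLD_PERCENT,
) -> dict[str, float]:
    """Classify E% values as high (> threshold) or low (< threshold).

    Ties at the threshold go to "low" (the strict >/< rule leaves equality
    undefined; low is the conservative assignment). Returns counts and
    proportions.
    """
    if not threshold > 0:
        raise MeasurementError("threshold must be positive")
    vals = np.asarray(list(e_values_percent), dtype=float)
    if vals.size == 0:
        raise MeasurementError("cannot classify an empty group")
    high = int((vals > threshold).sum())
    low = int(vals.size - high)
    return {
        "n": int(vals.size),
        "n_high": high,
        "n_low": low,
        "prop_high": high / vals.size,
        "prop_low": low / vals.size,
    }
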