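"""Spectral channel extraction from lambda stacks.

A lambda stack is a confocal acquisition in which emission is collected in
contiguous wavelength bands (here 462-572 nm excited at 458 nm for a
CFP-donor / YPet-acceptor ERK biosensor). Two routes turn a stack into
donor and acceptor channel images:

* band-window "dye separation" — sum the bands whose centers fall inside a
  donor window (465-500 nm) or an acceptor window (525-570 nm);
* linear unmixing — per-pixel non-negative least squares of the band
  vector against band-integrated reference emission spectra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import nnls


class SpectralConfigError(ValueError):
    """Raised when acquisition geometry or reference spectra are invalid."""


@dataclass(frozen=True)
class EmissionSpectrum:
    """Relative emission spectrum of one fluorophore, unit trapezoidal area.

    Parameters
    ----------
    name : fluorophore label (e.g. ``"CFP"``, ``"YPet"``).
    grid : wavelengths in nm, strictly increasing.
    emission : relative intensity at each grid point, non-negative;
        normalised so the trapezoidal integral over ``grid`` equals 1.
    """

    name: str
    grid: np.ndarray
    emission: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        em = np.asarray(self.emission, dtype=float)
        if grid.ndim != 1 or grid.shape != em.shape:
            raise SpectralConfigError("grid and emission must be equal-length 1-D")
        if np.any(np.diff(grid) <= 0):
            raise SpectralConfigError("wavelength grid must be strictly increasing")
        if np.any(em < 0):
            raise SpectralConfigError("emission must be non-negative")
        area = np.trapezoid(em, grid)
        if not math.isclose(area, 1.0, abs_tol=1e-9):
            raise SpectralConfigError(
                f"spectrum {self.name!r} not normalised: trapezoidal area {area!r}"
            )
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "emission", em)

    @classmethod
    def gaussian(
        cls,
        name: str,
        peak_nm: float,
        sd_nm: float,
        grid: Sequence[float] | None = None,
    ) -> "EmissionSpectrum":
        """Unit-area Gaussian emission model on a nm grid.

        Default grid spans peak +/- 6 sd at 0.5 nm resolution, wide enough to
        cover any acquisition window used here.
        """
        if grid is None:
            grid = np.arange(peak_nm - 6 * sd_nm, peak_nm + 6 * sd_nm + 0.25, 0.5)
        grid = np.asarray(grid, dtype=float)
        em = np.exp(-0.5 * ((grid - peak_nm) / sd_nm) ** 2)
        em = em / np.trapezoid(em, grid)
        return cls(name=name, grid=grid, emission=em)

    def band_integral(self, lo: float, hi: float) -> float:
        """Integral of the spectrum over [lo, hi] nm (trapezoidal)."""
        if hi <= lo:
            raise SpectralConfigError("band upper edge must exceed lower edge")
        xs = np.unique(np.concatenate([[lo, hi], self.grid[(self.grid > lo) & (self.grid < hi)]]))
        ys = np.interp(xs, self.grid, self.emission, left=0.0, right=0.0)
        return float(np.trapezoid(ys, xs))

    def band_integrals(self, band_edges: Sequence[float]) -> np.ndarray:
        edges = np.asarray(band_edges, dtype=float)
        return np.array([self.band_integral(lo, hi) for lo, hi in zip(edges[:-1], edges[1:])])


# CFP-donor / YPet-acceptor defaults: Gaussian shapes, peaks at the
# fluorophores' nominal emission maxima.
def default_donor_spectrum() -> EmissionSpectrum:
    return EmissionSpectrum.gaussian("CFP", peak_nm=476.0, sd_nm=18.0)


def default_acceptor_spectrum() -> EmissionSpectrum:
    return EmissionSpectrum.gaussian("YPet", peak_nm=530.0, sd_nm=14.0)


DONOR_WINDOW_NM = (465.0, 500.0)
ACCEPTOR_WINDOW_NM = (525.0, 570.0)


@dataclass
class LambdaStack:
    """Spectral image volume: intensity over (z, y, x, band).

    ``band_edges`` has length ``n_bands + 1`` and is strictly increasing;
    the last band may be narrower than the nominal step when the step does
    not divide the spectral range.
    """

    data: np.ndarray
    band_edges: np.ndarray
    excitation_nm: float = 458.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.band_edges = np.asarray(self.band_edges, dtype=float)
        if self.data.ndim != 4:
            raise SpectralConfigError("lambda stack data must be (z, y, x, band)")
        if self.band_edges.ndim != 1 or self.band_edges.size != self.data.shape[-1] + 1:
            raise SpectralConfigError("band_edges length must be n_bands + 1")
        if np.any(np.diff(self.band_edges) <= 0):
            raise SpectralConfigError("band_edges must be strictly increasing")
        if np.any(self.data < 0):
            raise SpectralConfigError("lambda stack intensities must be non-negative")

    @property
    def n_bands(self) -> int:
        return self.data.shape[-1]

    @property
    def band_centers(self) -> np.ndarray:
        return 0.5 * (self.band_edges[:-1] + self.band_edges[1:])


@dataclass
class ChannelPair:
    """Donor and acceptor channel volumes extracted from a lambda stack."""

    donor: np.ndarray
    acceptor: np.ndarray
    donor_window: tuple[float, float]
    acceptor_window: tuple[float, float]
    method: str

    def __post_init__(self) -> None:
        if self.donor.shape != self.acceptor.shape:
            raise SpectralConfigError("donor and acceptor shapes must match")
        d0, d1 = self.donor_window
        a0, a1 = self.acceptor_window
        if max(d0, a0) < min(d1, a1):
            raise SpectralConfigError("donor and acceptor windows must be disjoint")


def n_detection_steps(lambda_min: float, lambda_max: float, step: float) -> int:
    """Number of spectral detection bands covering [lambda_min, lambda_max].

    Convention: ``ceil((lambda_max - lambda_min) / step)``, with the last
    band truncated at ``lambda_max`` if the step does not divide the range.
    This reproduces the instrument's 22 bands for 462-572 nm at a 5 nm step
    and 16 bands at a 7 nm step.
    """
    if step <= 0:
        raise SpectralConfigError("detection step must be positive")
    if lambda_max <= lambda_min:
        raise SpectralConfigError("lambda_max must exceed lambda_min")
    return math.ceil((lambda_max - lambda_min) / step - 1e-12)


def band_edges_for(lambda_min: float, lambda_max: float, step: float) -> np.ndarray:
    """Band edges for a regular acquisition; last band truncated at lambda_max."""
    n = n_detection_steps(lambda_min, lambda_max, step)
    edges = lambda_min + step * np.arange(n + 1, dtype=float)
    edges[-1] = min(edges[-1], lambda_max)
    return edges


def band_window_separation(
    stack: LambdaStack,
    donor_window: tuple[float, float] = DONOR_WINDOW_NM,
    acceptor_window: tuple[float, float] = ACCEPTOR_WINDOW_NM,
) -> ChannelPair:
    """Dye separation by band windows.

    Each channel is the sum of the bands whose centers lie inside the window
    (inclusive bounds). Mirrors the instrument-software separation of CFP
    (465-500 nm) and YPet (525-570 nm) net emission.
    """
    centers = stack.band_centers

    def window_sum(window: tuple[float, float]) -> np.ndarray:
        lo, hi = window
        sel = (centers >= lo) & (centers <= hi)
        if not np.any(sel):
            raise SpectralConfigError(
                f"window {window} covers no band centers (centers span "
                f"{centers[0]:.1f}-{centers[-1]:.1f} nm)"
            )
        return stack.data[..., sel].sum(axis=-1)

    return ChannelPair(
        donor=window_sum(donor_window),
        acceptor=window_sum(acceptor_window),
        donor_window=tuple(donor_window),
        acceptor_window=tuple(acceptor_window),
        method="band_window",
    )


def unmix_design_matrix(
    band_edges: Sequence[float], spectra: Sequence[EmissionSpectrum]
) -> np.ndarray:
    """Band-integrated reference spectra as an (n_bands, n_fluor) design matrix."""
    cols = [s.band_integrals(band_edges) for s in spectra]
    m = np.column_stack(cols)
    if np.linalg.matrix_rank(m, tol=1e-10 * np.abs(m).max()) < m.shape[1]:
        names = ", ".join(s.name for s in spectra)
        raise SpectralConfigError(
            f"reference spectra are collinear on this band grid: {names}"
        )
    return m


def linear_unmix(
    stack: LambdaStack, spectra: Sequence[EmissionSpectrum]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel non-negative least-squares unmixing.

    Solves ``min ||M a - y||`` subject to ``a >= 0`` for every pixel, where
    ``y`` is the pixel's band vector and the columns of ``M`` are the
    band-integrated reference spectra.

    Returns
    -------
    abundances : array of shape ``stack.data.shape[:-1] + (n_fluor,)``
    residuals : per-pixel residual 2-norm, shape ``stack.data.shape[:-1]``
    """
    if stack.n_bands < 2:
        raise SpectralConfigError("unmixing needs at least 2 spectral bands")
    m = unmix_design_matrix(stack.band_edges, spectra)
    y = stack.data.reshape(-1, stack.n_bands)

    # Fast path: unconstrained least squares; refine only pixels where the
    # solution leaves the non-negative orthant.
    sol, *_ = np.linalg.lstsq(m, y.T, rcond=None)
    sol = sol.T
    bad = np.any(sol < 0, axis=1)
    for i in np.nonzero(bad)[0]:
        sol[i], _ = nnls(m, y[i])
    sol = np.where(np.abs(sol) < 1e-300, 0.0, sol)  # squash signed zeros
    resid = np.linalg.norm(y - sol @ m.T, axis=1)
    shape = stack.data.shape[:-1]
    return sol.reshape(shape + (m.shape[1],)), resid.reshape(shape)


def pseudo_inverse_unmix(
    stack: LambdaStack, spectra: Sequence[EmissionSpectrum]
) -> np.ndarray:
    """Unconstrained pseudo-inverse unmixing (oracle; may go negative)."""
    m = unmix_design_matrix(stack.band_edges, spectra)
    y = stack.data.reshape(-1, stack.n_bands)
    sol = np.linalg.pinv(m) @ y.T
    return sol.T.reshape(stack.data.shape[:-1] + (m.shape[1],))
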