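"""Synthetic-microscopy phantom generator with known ground truth.

Every downstream stage of the pipeline (spectral separation, ratiometric
FRET indexing, acceptor-photobleaching efficiency, morphometry,
densitometry) is exercised against phantoms produced here, so each
generator records the truth it encodes.

The biological scenario emulated: a zebrafish line expressing an
intramolecular CFP/YPet ERK biosensor. ERK activity raises the fraction of
sensor molecules in the high-FRET conformation; activity is spatially
patterned (gastrula margin ring; forebrain / midbrain / hindbrain / tailbud
at pharyngula stage), elevated by a gain-of-function Shp2 D61G genotype and
suppressed dose-dependently by a MEK inhibitor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .spectral import (
    EmissionSpectrum,
    LambdaStack,
    band_edges_for,
    default_acceptor_spectrum,
    default_donor_spectrum,
)


class PhantomConfigError(ValueError):
    """Raised for invalid phantom configurations."""


# ---------------------------------------------------------------------------
# Sensor photophysics defaults (two-state intramolecular sensor).
# Molecular efficiencies of the open (inactive) and closed (active)
# conformations are not published for this sensor; these placeholders only
# shape realism — truth is always carried alongside the rendered data.
E_INACTIVE_DEFAULT = 0.05
E_ACTIVE_DEFAULT = 0.35
QY_DONOR = 1.0
QY_ACCEPTOR = 1.0

STAGES = ("gastrula_5hpf", "segmentation_11hpf", "pharyngula_24hpf")


@dataclass(frozen=True)
class Acquisition:
    """Spectral acquisition geometry: emission range and detection step, nm."""

    lambda_min: float = 462.0
    lambda_max: float = 572.0
    step: float = 5.0

    def band_edges(self) -> np.ndarray:
        return band_edges_for(self.lambda_min, self.lambda_max, self.step)


@dataclass(frozen=True)
class NoiseModel:
    """Detector model: Poisson shot noise on expected photons, then
    additive Gaussian read noise, clipped at zero.

    ``photon_budget`` scales expected photons per unit sensor density;
    ``enabled=False`` renders expected values exactly (the noise-free oracle
    regime used throughout the tests).
    """

    photon_budget: float = 1000.0
    read_noise_sd: float = 3.0
    enabled: bool = True

    def apply(self, expected: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if not self.enabled:
            return expected.copy()
        out = rng.poisson(expected).astype(float)
        if self.read_noise_sd > 0:
            out += rng.normal(0.0, self.read_noise_sd, size=out.shape)
        return np.clip(out, 0.0, None)


NOISE_OFF = NoiseModel(enabled=False)


@dataclass
class ActivityPhantom:
    """Ground-truth sensor state of one synthetic embryo.

    ``activity_map`` is the per-pixel fraction of sensor molecules in the
    active (high-FRET) conformation; ``truth_efficiency`` is the effective
    per-pixel transfer efficiency of the two-state mixture,
    ``E_eff = a * E_active + (1 - a) * E_inactive``.
    All maps are (z, y, x).
    """

    activity_map: np.ndarray
    density_map: np.ndarray
    embryo_mask: np.ndarray
    domain_labels: np.ndarray  # integer codes into `domain_names`
    domain_names: dict[int, str]
    stage: str
    e_inactive: float = E_INACTIVE_DEFAULT
    e_active: float = E_ACTIVE_DEFAULT

    def __post_init__(self) -> None:
        if not (0.0 <= self.e_inactive < self.e_active < 1.0):
            raise PhantomConfigError("need 0 <= E_inactive < E_active < 1")
        if np.any(self.activity_map[~self.embryo_mask] != 0):
            raise PhantomConfigError("activity must be 0 outside the embryo mask")

    @property
    def truth_efficiency(self) -> np.ndarray:
        return self.activity_map * self.e_active + (1.0 - self.activity_map) * self.e_inactive

    def domain_mask(self, name: str) -> np.ndarray:
        codes = [c for c, n in self.domain_names.items() if n == name]
        if not codes:
            raise PhantomConfigError(f"unknown domain {name!r}")
        return np.isin(self.domain_labels, codes)

    def domain_mean_activity(self, name: str) -> float:
        m = self.domain_mask(name)
        return float(self.activity_map[m].mean())


def _stage_geometry(stage: str, shape: tuple[int, int]) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Embryo mask and labelled domain masks for one developmental stage.

    Geometry is schematic: a gastrula is a disc with a peripheral margin
    ring; a segmentation-stage embryo is an oval with a tailbud cap; a
    pharyngula embryo is an elongated body with forebrain, midbrain,
    hindbrain and tailbud domains ordered along the anteroposterior axis.
    """
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    domains: dict[str, np.ndarray] = {}

    if stage == "gastrula_5hpf":
        r = 0.42 * min(ny, nx)
        rho = np.hypot(yy - cy, xx - cx)
        mask = rho <= r
        margin = (rho <= r) & (rho >= 0.80 * r)  # margin ring at the periphery
        domains["margin"] = margin
        domains["bulk"] = mask & ~margin
    elif stage == "segmentation_11hpf":
        a = 0.44 * ny  # semi-axes: elongated oval
        b = 0.30 * nx
        ell = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
        mask = ell
        tail = ell & (yy >= cy + 0.68 * a)
        domains["tailbud"] = tail
        domains["bulk"] = mask & ~tail
    elif stage == "pharyngula_24hpf":
        a = 0.46 * ny
        b = 0.22 * nx
        body = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
        mask = body
        # anteroposterior quarters of the body: Fb, Mb, Hb, trunk+Tb
        span = yy - (cy - a)
        frac = span / (2 * a)
        domains["forebrain"] = body & (frac < 0.18)
        domains["midbrain"] = body & (frac >= 0.18) & (frac < 0.34)
        domains["hindbrain"] = body & (frac >= 0.34) & (frac < 0.50)
        domains["tailbud"] = body & (frac >= 0.88)
        named = np.zeros_like(body)
        for m in domains.values():
            named |= m
        domains["bulk"] = body & ~named
    else:
        raise PhantomConfigError(
            f"unknown stage {stage!r}; expected one of {STAGES}"
        )
    return mask, domains


def make_embryo_phantom(
    stage: str,
    shape: tuple[int, int] = (128, 128),
    domain_activities: dict[str, float] | None = None,
    seed: int = 0,
    n_z: int = 3,
    e_inactive: float = E_INACTIVE_DEFAULT,
    e_active: float = E_ACTIVE_DEFAULT,
    density_texture: float = 0.1,
) -> ActivityPhantom:
    """Build a synthetic embryo with exact per-domain activity values.

    ``domain_activities`` maps domain names (stage-dependent; see
    ``_stage_geometry``) to active-sensor fractions in [0, 1]. Unlisted
    domains default to 0.1. Activity is written as an exact constant per
    domain, so domain means equal the requested values before any detector
    noise. Sensor density carries mild multiplicative lognormal texture
    (sd ``density_texture``) to avoid unrealistically flat images;
    everything is deterministic for a fixed seed.
    """
    ny, nx = shape
    if ny < 32 or nx < 32:
        raise PhantomConfigError("phantom shape must be at least 32x32")
    mask2d, domains2d = _stage_geometry(stage, (ny, nx))
    domain_activities = dict(domain_activities or {})
    for k, v in domain_activities.items():
        if k not in domains2d:
            raise PhantomConfigError(
                f"unknown domain {k!r} for stage {stage!r}; have {sorted(domains2d)}"
            )
        if not 0.0 <= v <= 1.0:
            raise PhantomConfigError(f"activity for {k!r} must be in [0, 1]")

    activity2d = np.zeros((ny, nx))
    labels2d = np.zeros((ny, nx), dtype=np.int16)
    names = {0: "background"}
    for code, (name, dmask) in enumerate(sorted(domains2d.items()), start=1):
        names[code] = name
        labels2d[dmask] = code
        activity2d[dmask] = domain_activities.get(name, 0.1)

    rng = np.random.default_rng(seed)
    mask = np.broadcast_to(mask2d, (n_z, ny, nx)).copy()
    activity = np.broadcast_to(activity2d, (n_z, ny, nx)).copy()
    labels = np.broadcast_to(labels2d, (n_z, ny, nx)).copy()
    density = np.where(mask, 1.0, 0.0)
    if density_texture > 0:
        density = density * rng.lognormal(
            mean=-0.5 * density_texture**2, sigma=density_texture, size=(n_z, ny, nx)
        )
        density[~mask] = 0.0

    return ActivityPhantom(
        activity_map=activity,
        density_map=density,
        embryo_mask=mask,
        domain_labels=labels,
        domain_names=names,
        stage=stage,
        e_inactive=e_inactive,
        e_active=e_active,
    )


# ---------------------------------------------------------------------------
# Forward model: spectral rendering


def expected_band_signal(
    density: np.ndarray,
    e_eff: np.ndarray,
    band_edges: np.ndarray,
    donor_spectrum: EmissionSpectrum,
    acceptor_spectrum: EmissionSpectrum,
    photon_budget: float,
) -> np.ndarray:
    """Expected photons per band for a 1:1 intramolecular donor-acceptor pair.

    A fraction ``E_eff`` of absorbed excitation transfers to the acceptor;
    the remainder is emitted by the donor. Expected band signal is

    ``density * budget * [(1 - E) * Q_D * int_band S_D + E * Q_A * int_band S_A]``.
    """
    w_d = donor_spectrum.band_integrals(band_edges)
    w_a = acceptor_spectrum.band_integrals(band_edges)
    donor_part = (1.0 - e_eff)[..., None] * QY_DONOR * w_d
    acceptor_part = e_eff[..., None] * QY_ACCEPTOR * w_a
    return density[..., None] * photon_budget * (donor_part + acceptor_part)


def render_lambda_stack(
    phantom: ActivityPhantom,
    donor_spectrum: EmissionSpectrum | None = None,
    acceptor_spectrum: EmissionSpectrum | None = None,
    acquisition: Acquisition = Acquisition(),
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> LambdaStack:
    """Render the phantom into a spectral (z, y, x, band) lambda stack."""
    donor_spectrum = donor_spectrum or default_donor_spectrum()
    acceptor_spectrum = acceptor_spectrum or default_acceptor_spectrum()
    for s in (donor_spectrum, acceptor_spectrum):
        if s.grid[0] > acquisition.lambda_min or s.grid[-1] < acquisition.lambda_max:
            raise PhantomConfigError(
                f"spectrum {s.name!r} does not cover the acquisition range "
                f"{acquisition.lambda_min}-{acquisition.lambda_max} nm"
            )
    edges = acquisition.band_edges()
    expected = expected_band_signal(
        phantom.density_map,
        phantom.truth_efficiency,
        edges,
        donor_spectrum,
        acceptor_spectrum,
        noise.photon_budget,
    )
    rng = np.random.default_rng(seed)
    data = noise.apply(expected, rng)
    return LambdaStack(
        data=data,
        band_edges=edges,
        excitation_nm=458.0,
        meta={"stage": phantom.stage, "seed": int(seed)},
    )


# ---------------------------------------------------------------------------
# Forward model: acceptor photobleaching


@dataclass
class BleachSeries:
    """Paired pre/post acceptor-photobleaching frames plus the bleach ROI.

    ``pre_donor`` holds the two pre-bleach x,y scans as a (2, y, x) array;
    ``post_donor``/``post_acceptor`` are single frames after ``iterations``
    bleach pulses, each of which lets a fraction ``per_iteration_survival``
    of the acceptor survive inside ``bleach_roi``.
    """

    pre_donor: np.ndarray
    pre_acceptor: np.ndarray
    post_donor: np.ndarray
    post_acceptor: np.ndarray
    bleach_roi: np.ndarray
    iterations: int
    per_iteration_survival: float
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        frame_shape = self.post_donor.shape
        if (
            self.pre_donor.shape[1:] != frame_shape
            or self.pre_acceptor.shape[1:] != frame_shape
            or self.post_acceptor.shape != frame_shape
            or self.bleach_roi.shape != frame_shape
        ):
            raise PhantomConfigError("all bleach-series frames must share one shape")

    @property
    def surviving_fraction(self) -> float:
        return float(self.per_iteration_survival**self.iterations)


def render_bleach_series(
    phantom: ActivityPhantom,
    bleach_roi: np.ndarray,
    iterations: int = 50,
    per_iteration_survival: float = 0.0,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    acceptor_excitation_budget: float | None = None,
) -> BleachSeries:
    """Render a pre/post acceptor-photobleaching pair from the phantom.

    Frames are sum projections over z of the phantom's expected emission.
    Donor channel expectation is ``density * budget * (1 - E) * Q_D``; after
    bleaching, the effective efficiency inside the ROI drops to ``E * s``
    with ``s = survival ** iterations``, de-quenching the donor. The
    acceptor channel is excited directly (separate laser line) and simply
    reports acceptor abundance, scaled by ``s`` inside the ROI post-bleach.
    """
    if iterations < 1:
        raise PhantomConfigError("iterations must be >= 1")
    if not 0.0 <= per_iteration_survival <= 1.0:
        raise PhantomConfigError("per_iteration_survival must be in [0, 1]")
    nz, ny, nx = phantom.density_map.shape
    bleach_roi = np.asarray(bleach_roi, dtype=bool)
    if bleach_roi.shape != (ny, nx):
        raise PhantomConfigError(
            f"bleach ROI shape {bleach_roi.shape} does not match image ({ny}, {nx})"
        )
    if acceptor_excitation_budget is None:
        acceptor_excitation_budget = noise.photon_budget

    e_eff = phantom.truth_efficiency
    s = per_iteration_survival**iterations

    donor_pre_exp = (phantom.density_map * noise.photon_budget * (1.0 - e_eff) * QY_DONOR).sum(axis=0)
    e_post = np.where(bleach_roi, e_eff * s, e_eff)
    donor_post_exp = (phantom.density_map * noise.photon_budget * (1.0 - e_post) * QY_DONOR).sum(axis=0)

    acceptor_pre_exp = (phantom.density_map * acceptor_excitation_budget * QY_ACCEPTOR).sum(axis=0)
    acceptor_post_exp = np.where(bleach_roi, acceptor_pre_exp * s, acceptor_pre_exp)

    rng = np.random.default_rng(seed)
    pre_donor = np.stack([noise.apply(donor_pre_exp, rng) for _ in range(2)])
    pre_acceptor = np.stack([noise.apply(acceptor_pre_exp, rng) for _ in range(2)])
    post_donor = noise.apply(donor_post_exp, rng)
    post_acceptor = noise.apply(acceptor_post_exp, rng)

    roi3d = np.broadcast_to(bleach_roi, (nz, ny, nx))
    in_roi = roi3d & phantom.embryo_mask
    truth = {
        "surviving_fraction": float(s),
        "roi_mean_efficiency": float(e_eff[in_roi].mean()) if in_roi.any() else float("nan"),
    }
    return BleachSeries(
        pre_donor=pre_donor,
        pre_acceptor=pre_acceptor,
        post_donor=post_donor,
        post_acceptor=post_acceptor,
        bleach_roi=bleach_roi,
        iterations=iterations,
        per_iteration_survival=per_iteration_survival,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class GroupSpec:
    """One experimental group: name, size, and per-domain activity multipliers."""

    name: str
    n_embryos: int
    activity_multiplier: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_embryos < 1:
            raise PhantomConfigError("n_embryos must be >= 1")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort design for the genotype / MEK-inhibitor dose scenarios.

    Defaults encode: wild-type margin activity 0.2; the gain-of-function
    genotype triples margin activity; MEK-inhibitor doses suppress the
    mutant margin activity by 0.7 (0.25 uM, partial) and 0.4 (1 uM, strong
    rescue toward — but still above — wild type). Between-embryo variability
    is a 10% CV lognormal multiplier on every domain activity.
    """

    groups: tuple[GroupSpec, ...]
    stage: str = "gastrula_5hpf"
    shape: tuple[int, int] = (128, 128)
    base_activities: tuple[tuple[str, float], ...] = (("margin", 0.2), ("bulk", 0.08))
    genotype_effect: float = 3.0
    dose_response: tuple[tuple[float, float], ...] = ((0.25, 0.7), (1.0, 0.4))
    embryo_cv: float = 0.10
    noise: NoiseModel = NoiseModel()
    acquisition: Acquisition = Acquisition()
    bleach_iterations: int = 50
    bleach_survival: float = 0.0
    seed: int = 0
    n_z: int = 1

    def __post_init__(self) -> None:
        if not self.groups:
            raise PhantomConfigError("cohort needs at least one group")
        doses = sorted(self.dose_response)
        for (d0, s0), (d1, s1) in zip(doses[:-1], doses[1:]):
            if s1 >= s0:
                raise PhantomConfigError("suppression must decrease with dose")


def default_cohort_config(seed: int = 0, n_embryos: int = 8, **overrides) -> CohortConfig:
    """Four-group genotype x dose design: WT, D61G, D61G + low/high MEKi."""
    supp = dict(((0.25, 0.7), (1.0, 0.4)))
    g = 3.0
    groups = (
        GroupSpec("Shp2WT", n_embryos, {"margin": 1.0}),
        GroupSpec("Shp2D61G", n_embryos, {"margin": g}),
        GroupSpec("Shp2D61G+0.25uMPD", n_embryos, {"margin": g * supp[0.25]}),
        GroupSpec("Shp2D61G+1uMPD", n_embryos, {"margin": g * supp[1.0]}),
    )
    return CohortConfig(groups=groups, genotype_effect=g, seed=seed, **overrides)


@dataclass
class CohortMember:
    """One simulated embryo: truth phantom plus its rendered acquisitions."""

    embryo_id: str
    group: str
    phantom: ActivityPhantom
    lambda_stack: LambdaStack
    bleach_series: BleachSeries
    margin_roi: np.ndarray


def _margin_bleach_roi(phantom: ActivityPhantom) -> np.ndarray:
    """The margin (or fallback: whole-embryo) ROI targeted for bleaching."""
    labels2d = phantom.domain_labels[0]
    names = phantom.domain_names
    margin_codes = [c for c, n in names.items() if n in ("margin", "tailbud")]
    roi = np.isin(labels2d, margin_codes)
    if not roi.any():
        roi = phantom.embryo_mask[0]
    return roi


def make_cohort(config: CohortConfig) -> list[CohortMember]:
    """Simulate a reproducible cohort of embryos with rendered data.

    Per-embryo domain activities are the group's base activities times the
    group multipliers times a lognormal between-embryo factor
    (CV ``config.embryo_cv``), clipped to [0, 1]. Child seeds are spawned
    from the cohort seed, so results are bit-identical for a fixed config.
    """
    base = dict(config.base_activities)
    ss = np.random.SeedSequence(config.seed)
    members: list[CohortMember] = []
    for g_idx, group in enumerate(config.groups):
        for e_idx in range(group.n_embryos):
            child = ss.spawn(1)[0]
            seeds = child.generate_state(4) % (2**31)
            rng = np.random.default_rng(int(seeds[0]))
            acts = {}
            for name, a0 in base.items():
                mult = group.activity_multiplier.get(name, 1.0)
                if config.embryo_cv > 0:
                    sigma = np.sqrt(np.log(1 + config.embryo_cv**2))
                    mult = mult * rng.lognormal(-0.5 * sigma**2, sigma)
                acts[name] = float(np.clip(a0 * mult, 0.0, 1.0))
            phantom = make_embryo_phantom(
                config.stage,
                config.shape,
                acts,
                seed=int(seeds[1]),
                n_z=config.n_z,
            )
            stack = render_lambda_stack(
                phantom,
                acquisition=config.acquisition,
                noise=config.noise,
                seed=int(seeds[2]),
            )
            roi = _margin_bleach_roi(phantom)
            series = render_bleach_series(
                phantom,
                roi,
                iterations=config.bleach_iterations,
                per_iteration_survival=config.bleach_survival,
                noise=config.noise,
                seed=int(seeds[3]),
            )
            members.append(
                CohortMember(
                    embryo_id=f"{group.name}_{e_idx:02d}",
                    group=group.name,
                    phantom=phantom,
                    lambda_stack=stack,
                    bleach_series=series,
                    margin_roi=roi,
                )
            )
    return members


def cohort_truth_table(members: list[CohortMember]) -> pd.DataFrame:
    """Tidy truth table (one row per embryo) from the stored phantoms."""
    rows = []
    for m in members:
        row = {"embryo_id": m.embryo_id, "group": m.group}
        for code, name in m.phantom.domain_names.items():
            if name == "background":
                continue
            row[f"activity_{name}"] = m.phantom.domain_mean_activity(name)
        e = m.phantom.truth_efficiency
        roi3d = np.broadcast_to(m.margin_roi, e.shape)
        row["truth_E_margin"] = float(e[roi3d & m.phantom.embryo_mask].mean())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Morphology and gel phantoms


def make_morphology_phantom(
    major_px: float,
    minor_px: float,
    rotation_deg: float = 0.0,
    shape: tuple[int, int] = (256, 256),
) -> np.ndarray:
    """Filled ellipse mask with given full axis lengths and rotation."""
    if not major_px >= minor_px > 0:
        raise PhantomConfigError("need major >= minor > 0")
    ny, nx = shape
    rr, cc = draw_ellipse(
        (ny - 1) / 2.0,
        (nx - 1) / 2.0,
        major_px / 2.0,
        minor_px / 2.0,
        shape=None,
        rotation=np.deg2rad(rotation_deg),
    )
    if rr.min() < 0 or cc.min() < 0 or rr.max() >= ny or cc.max() >= nx:
        raise PhantomConfigError("ellipse axes exceed the image bounds")
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


BAND_ROWS = ("pERK", "tERK", "GAPDH")


def make_gel_phantom(
    lane_intensities: list[dict[str, float]],
    background_level: float = 0.0,
    noise: NoiseModel = NOISE_OFF,
    seed: int = 0,
    band_shape: tuple[int, int] = (12, 30),
    lane_pitch: int = 50,
    row_pitch: int = 40,
    margin: int = 20,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Synthetic immunoblot: rectangular bands on a uniform background.

    Each lane carries three bands (pERK, tERK, GAPDH) whose integrated
    intensity above background equals the requested truth value exactly in
    the noise-free case. Returns the image and a truth table with one row
    per band (lane, target, truth density and the band's ROI bounds,
    half-open 0-based).
    """
    bh, bw = band_shape
    if bw + 2 > lane_pitch or bh + 2 > row_pitch:
        raise PhantomConfigError("bands overlap: enlarge lane_pitch/row_pitch")
    n_lanes = len(lane_intensities)
    ny = 2 * margin + row_pitch * len(BAND_ROWS)
    nx = 2 * margin + lane_pitch * n_lanes
    img = np.full((ny, nx), float(background_level))
    rows = []
    for lane, bands in enumerate(lane_intensities):
        for r, target in enumerate(BAND_ROWS):
            total = float(bands.get(target, 0.0))
            if total < 0:
                raise PhantomConfigError("band intensities must be >= 0")
            y0 = margin + r * row_pitch + (row_pitch - bh) // 2
            x0 = margin + lane * lane_pitch + (lane_pitch - bw) // 2
            img[y0 : y0 + bh, x0 : x0 + bw] += total / (bh * bw)
            rows.append(
                {
                    "lane": lane,
                    "target": target,
                    "truth_density": total,
                    "y0": y0,
                    "y1": y0 + bh,
                    "x0": x0,
                    "x1": x0 + bw,
                }
            )
    rng = np.random.default_rng(seed)
    if noise.enabled:
        img = noise.apply(img, rng)
    return img, pd.DataFrame(rows)
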