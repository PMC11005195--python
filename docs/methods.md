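# Methods

This note documents the models behind `fretbench`, the defaults and why
they were chosen, and what the synthetic phantoms do and do not establish
about real confocal data.

## Sensor and forward model

The simulated sensor is an intramolecular two-state FRET reporter: a CFP
donor and YPet acceptor at fixed 1:1 stoichiometry, with a fraction
`a ∈ [0, 1]` of molecules per pixel in the active (closed, high-FRET)
conformation. Effective per-pixel efficiency is the mixture

    E_eff = a · E_active + (1 − a) · E_inactive.

Molecular efficiencies of the open and closed conformations are not
published for this sensor class; the defaults `E_inactive = 0.05`,
`E_active = 0.35` are placeholders that only shape realism. Every
validation compares estimates against the stored ground truth, never
against these defaults.

Emission spectra are modeled as unit-area Gaussians on a nm grid (donor
peak 476 nm, sd 18 nm; acceptor peak 530 nm, sd 14 nm) — the acquisition
windows are the physically meaningful quantities here and the Gaussian
shapes are overridable. Quantum-yield ratio defaults to 1 since every
downstream readout is ratiometric or ratio-of-ratios. Expected band signal
at a pixel is

    density · photon_budget · [(1 − E_eff) Q_D ∫_band S_D + E_eff Q_A ∫_band S_A],

with band integrals taken over the true (possibly truncated) band widths.
Detector noise is Poisson shot noise on the expected photons followed by
additive Gaussian read noise, clipped at zero. Defaults: photon budget
1000 per unit density, read-noise sd 3 — mid-range confocal counting
statistics. Direct acceptor excitation at 458 nm and donor photobleaching
during AB are excluded from the default model (both available as
parameters); the AB estimator assumes they are negligible.

## Spectral separation

Band-window separation assigns a band to a window when the band's *center*
lies inside the window (inclusive bounds). On the 462–572 nm / 5 nm grid
the centers are 464.5, 469.5, …, so the 465–500 nm donor window sums 7
bands and the 525–570 nm acceptor window 9. The center rule is a
documented choice — how vendor software treats bands straddling a window
edge is not recoverable — and on 5 nm grids the windows align either way.
The band count is `ceil((λ_max − λ_min)/step)`, which reproduces both
acquisition geometries (22 steps at 5 nm, 16 at 7 nm); when the step does
not divide the range the last band is truncated and the forward model
integrates over its true width.

Linear unmixing solves per-pixel non-negative least squares against
band-integrated reference spectra (non-negativity because abundances are
physical); the unconstrained pseudo-inverse solution is kept available and
is used in the tests as the independent oracle wherever it is already
non-negative. Collinear reference spectra are rejected by name.

## FRET index

The live readout is ratio-of-sum-projections: each channel is sum-projected
over z, the acceptor/donor ratio is formed, and the index is the sum of
valid ratio pixels inside the ROI (raw integrated density, i.e. sum — not
mean). Projection-then-division was chosen as the default because the
alternative (per-plane ratios, then projection) is not distinguishable from
the available description; both orders are implemented and a test bounds
their disagreement on noise-free phantoms at 5% relative (after accounting
for the plane count). Pixels whose donor signal falls below a floor —
default 1% of the donor-image maximum, since no background threshold is
otherwise specified — are excluded from the ROI sum rather than divided.
Group fold change is the mean of per-embryo ratios to the control mean,
which preserves per-embryo dispersion for SEM-style reporting and makes a
group's fold change against itself exactly 1.

## AB-FRET

The estimator operates on ROI means (not per-pixel efficiencies averaged
afterwards; the two coincide when E is uniform in the ROI, and ROI means
are what the bleaching protocol measures). The two pre-bleach scans are
averaged before computing D_A. No background subtraction is applied by
default; a constant-offset subtraction is available behind a flag.

Incomplete bleaching: if a fraction `s` of the acceptor survives each of
`k` iterations, `s' = s^k` survives overall and the post-bleach donor
expectation is `density · budget · (1 − E s')`. The estimator then returns

    E_est = E (1 − s') / (1 − E s'),

exactly, on noise-free series — the familiar "biased low by the unbleached
fraction" statement `E_est ≈ (1 − s') E` is the first-order form of this,
accurate to a remainder of `E² s' (1 − s')/(1 − E s')`. With the default 50
iterations even a 90% per-iteration survival leaves `s' ≈ 0.5%`, so the
bias is negligible in practice.

Negative efficiencies (donor dimmer after bleaching) are reported as-is
and flagged, never clamped; they participate in group statistics on E but
are excluded from R_DA, which is only defined for E ∈ (0, 1). Distances
follow `R_DA = R0 (1/E − 1)^{1/6}` with R0 = 4.7 nm; E ≥ 1 returns the
contact limit 0 with a warning. The high/low E% classification threshold
defaults to 7.53 and ties are assigned to "low" (the strict >/< rule leaves
equality undefined; low is the conservative choice).

## Cohort generator

The default cohort emulates the four-group genotype × dose design: margin
activity 0.2 in wild type, multiplied by 3.0 in the Shp2-D61G mutant, with
MEK-inhibitor suppression factors 0.7 (0.25 µM) and 0.4 (1 µM) applied to
the mutant margin. These numbers encode the qualitative structure the
simulation must reproduce — a strong mutant elevation, partial rescue at
low dose, near-complete (but not past-wild-type) rescue at high dose, i.e.
WT < mutant+high < mutant+low < mutant in margin activity. Between-embryo
variability is a lognormal multiplier with 10% CV on every domain activity,
a typical clutch-to-clutch spread for biosensor embryos. One cohort seed
fans out to per-embryo child seeds through `numpy.random.SeedSequence`, so
cohorts are bit-reproducible and adding embryos or stages never perturbs
earlier draws.

Embryo geometry is schematic: a gastrula is a disc with a peripheral
margin ring, a segmentation-stage embryo an oval with a tailbud cap, a
pharyngula embryo an elongated body with forebrain/midbrain/hindbrain/
tailbud domains along the anteroposterior axis. Domain activities are
written as exact constants, so domain means equal the requested values
before noise and the generator can serve as an oracle at 1e-9 tolerance.

**What the phantoms do not model:** realistic embryo anatomy and optics
(point-spread function, depth-dependent attenuation, scattering),
autofluorescence, sensor expression mosaicism, stage drift during
acquisition, or inhibitor pharmacokinetics. Passing tests therefore
establish the correctness of the *analysis* — estimators recover known
truth under the stated noise model — not the biological fidelity of any
particular acquisition.

## Morphometry

Axis lengths come from the moments-equivalent ellipse of the mask
(rotation- and translation-invariant by construction) — a reproducible
substitute for hand-drawn axis lines; for strongly bent embryos the two can
diverge, which is a known approximation. Body length is the straight
Euclidean snout-to-tail distance (the farthest pair of foreground pixels
when endpoints are not given, computed on the convex hull), matching a
straight-line tool even for curved larvae. Outputs default to pixels; µm
only when a calibration (µm/px) is supplied.

## Densitometry

Band density is the ROI sum minus the median of a same-size flanking
region times the pixel count — the flanking-median rule removes any
uniform offset exactly and is robust to a band in one flank. The rule is
this package's choice; whether the original manual workflow subtracted
background at all is unstated, so the uncorrected sum is one flag away.
Saturated pixels (at the integer dtype maximum) raise a warning.

## Statistics

All standard tests run through scipy/statsmodels: one-tailed t
(paired/unpaired), Mann–Whitney, one-way ANOVA with Dunnett
(`scipy.stats.dunnett`, given a fixed `random_state` because its p-value
is a quasi-Monte-Carlo integral) or Holm–Šidák-adjusted pairwise t, and
Kruskal–Wallis with a hand-implemented Dunn post hoc (rank-based z with
tie correction; no installed package provides it). One-tailed directions
are declared in the design object, never inferred from the data. The
one-sided 2×2 chi-square halves the uncorrected chi-square p on the
declared direction; the exact hypergeometric (Fisher) p is the test-suite
oracle for its verdict.

Outlier screening uses median ± 3·1.4826·MAD. This replaces a proprietary
regression-with-FDR procedure (ROUT) that is out of scope; the substitute
is simple, standard, and always reports what it excluded. On clean normal
samples it excludes < 2% of points.

## Problem sizes and numerical choices

Simulated images default to 128×128 px with a single z-plane for cohorts
(3 planes for standalone phantoms), 22 spectral bands, n = 8 embryos per
group — sizes at which a full 4-group simulate-and-analyse cycle takes
about a second, so the repeated-cohort validations (100 seeded repeats)
run in minutes on one CPU. Spectral band integrals use trapezoidal
integration on a 0.5 nm grid (relative tolerance 1e-6 in the conservation
checks). NNLS falls back from the vectorized unconstrained solution only
on pixels that leave the feasible orthant. ROI coordinates are 0-based
with half-open rectangular bounds throughout.

## Known limitations

- The AB estimator's ROI-mean convention differs from per-pixel averaging
  when efficiency varies strongly inside the ROI.
- Moments-based axes understate hand-drawn axes on strongly curved
  embryos.
- The phantom's spectral model omits autofluorescence and channel
  crosstalk beyond donor bleed-through, so unmixing residuals on real data
  will be larger than in simulation.
- Absolute sensor-state efficiencies are placeholders; only relative and
  ground-truth-anchored statements are validated.
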