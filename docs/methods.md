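# Methods

## Photon transport model

`layered_mc` simulates a normally incident, collimated, laterally infinite
beam on a stack of homogeneous turbid layers. Because absorption is scored
against depth only, a pencil beam with lateral integration is exactly
equivalent to the broad beam, and the returned profile A(z) is the energy
absorbed per unit volume per photon launched per unit area (mm⁻¹).

**Similarity domain.** Only the reduced scattering coefficient μs′ is
tabulated for the tissues of interest, so packets scatter isotropically at
μs = μs′. Transport solutions that share (μa, μs′) agree beyond roughly one
transport mean free path regardless of the anisotropy factor g; the
near-surface sub-bin structure is the only place where an explicit phase
function would matter, and no g is available to support one.

**Estimator.** Absorption is deposited continuously along each flight path
(track-length estimator): a segment of length ℓ in a bin deposits
w·(1−e^(−μa·ℓ)) and attenuates the packet weight accordingly; scattering
events are sampled from μs alone. The expectation is identical to
collision-site weight dropping, but the variance is far lower and the
scattering-free limit is exact: a pure absorber reproduces
μa·e^(−μa·z) to the bin-averaging error (~4·10⁻⁶ relative at 10-μm bins).
Energy is conserved per packet up to Russian roulette, which is unbiased
(threshold 10⁻⁴, survival probability 0.1, survivors upweighted ×10).

**Boundaries.** Air (n = 1) bounds the slab above and below — an ear is
air-backed. The specular entry loss is deducted analytically at launch;
every internal index mismatch applies unpolarized Fresnel
reflection/refraction with total internal reflection beyond the critical
angle. Only the polar direction cosine is tracked: the slab is laterally
infinite and azimuthally symmetric, and the isotropic phase function makes
the azimuth irrelevant.

**Grid and determinism.** Depth bins are half-open [z, z+Δz), Δz = 10 μm by
default, z = 0 at the irradiated surface: ≥20 bins per layer of the default
ear model. The seed is mandatory; a fixed (model, config) pair is
bit-reproducible. Defaults: 10⁶ packets (a 405-nm ear run takes a few
seconds on one core after JIT compilation).

**Default tissue.** The built-in three-layer ear model (skin 0.4 mm,
n 1.45 / cartilage 0.2 mm, n 1.4 / skin 0.4 mm) uses literature human
skin/cartilage properties per band: at 405 nm μa = 1.3 and 0.08 mm⁻¹,
μs′ = 5.4 and 3 mm⁻¹ (skin, cartilage); at 660 nm μa = 0.3 and 0.01 mm⁻¹,
μs′ = 4.6 and 1 mm⁻¹. Whether rabbit tissue differs materially from these
human values is unknown; the dosimetry is a preliminary assessment.

## Photobleaching kinetics

The decay of the ROI-mean fluorescence with delivered dose D (J/cm² =
mW/cm² × s / 1000) is modeled as If(D) = If1·e^(−αD). The rate α is fitted
by nonlinear least squares **on the linear intensity scale** so that
multiplicative noise does not over-weight the bleached tail; the log-linear
regression of ln If on D supplies only the starting point, and the standard
error of α comes from the fit covariance. On noiseless model data the fit
is exact to machine precision; at 5% CV the estimator bias is below 0.5%
and the standard error of a 3-replicate mean over a 0–50 J/cm² grid is
≈ 7·10⁻⁴ (J/cm²)⁻¹ — a useful scale when judging rate differences between
sessions.

The "fluorescing area" is segmented as pixels at or above a configurable
fraction (default 0.2) of the 99th-percentile intensity — the percentile
makes the rule robust to hot pixels — and the largest connected component
is kept. The photobleaching efficiency uses the first and last frames of a
session, mirroring before/after-procedure imaging. When the two excitation
channels were sampled at different doses, the ratio series interpolates
both onto the coarser grid restricted to their overlap; the reported trend
is the sign of the log-linear slope of R against dose.

## Depth inference

The forward model of the detected signal at one excitation wavelength is
I = ∫ Φ_exc(z)·C(z)·E(z) dz, with Φ_exc(z) = A(z)/μa(z) the
fluence-equivalent excitation profile, C(z) the photosensitizer
concentration (uniform from the surface to depth d by default — the
topical-application reading — with an exponential profile as an
alternative), and E(z) the Monte Carlo escape fraction: the probability
that a photon emitted isotropically at depth z leaves the top surface at
any angle. Detection geometry is not restricted by numerical aperture
because none is specified for the instrument class modeled; E is computed
once on the transport grid and shared between both excitations, which also
cancels its noise in the ratio. The emission band (702–842 nm) has no
tabulated properties, so the 660-nm values stand in for it — the nearest
tabulated band, and red/NIR skin properties vary slowly. The
photosensitizer's own absorption is neglected in the bulk optics (low
topical dose); this is a known limitation.

The ratio-depth curve R(d) = κ·I₆₆₀exc(d)/I₄₀₅exc(d) is a ratio of
cumulative quadratures (anchored at R(0⁺) = κ·Φ₆₆₀(0⁺)/Φ₄₀₅(0⁺)), so
Monte Carlo noise is strongly correlated along the grid and the curve is
strictly increasing on the default ear model at moderate photon counts; a
non-monotone curve raises an error rather than being inverted silently.
Inversion is monotone piecewise-linear; ratios outside the curve range are
clamped to the end depths and flagged.

**Calibration κ.** The relative excitation irradiance and detector
throughput at the two wavelengths is instrument-specific and defaults to
κ = 1 (uncalibrated relative units). With κ = 1 the ear-model curve spans
R ≈ 1.7–2.5 over 0.1–0.9 mm; measured ratios near 0.8–1.1, which in the
monitored-site literature correspond to ~0.4–0.8-mm penetration, imply
κ ≈ 0.4 for such an instrument. The package deliberately does not fit κ to
that correspondence; uncalibrated runs on ratios near 0.9 therefore clamp
to the shallow end of the curve with `out_of_range=True`, which is the
designed signal to supply a measured κ.

## Synthetic data

The generator inverts the analysis assumptions. Decay series are
If1·e^(−αD)·(1+ε), ε ~ N(0, CV) independently per point and replicate
(Poisson counts optional); the default session is a 0–50 J/cm² procedure
sampled every 10 J/cm², CV 5%, 3 replicates, initial intensities 1000/900
a.u. so the starting ratio (0.9) sits in the typical 0.8–1.1 band. The two
rate presets are the fitted study values: blue-light PDT 0.011/0.009 and
red-light PDT 0.014/0.017 (J/cm²)⁻¹ for 405-/660-nm excitation — the first
ordering makes R rise with dose, the second makes it fall.

Image sessions place a bright disc (the treated area) on a low constant
background; noise is applied **per pixel**, as a camera would, so the
ROI mean of an emitted frame reproduces the generating curve to within
CV/√n_pixels and exactly at CV 0. Consequently image-derived series are
much less noisy than the plain series generator, whose per-point CV
emulates between-measurement variability instead. The per-animal variance
structure of the real measurements is unreported; CV 5% is a fixture
choice. Synthetic data contain no spatial heterogeneity, illumination
drift, spectral cross-talk or motion, so tests passing on them validate
the estimators and plumbing, not robustness to those real-world effects.

Outcome tables draw per-regime grades (0–3 ↔ −/+/++/+++) from central
values jittered by ±1 and then clamped so that every generated table
satisfies the qualitative ordering of the study: red-light regimes never
grade worse than the equal-dose blue-light regime of the same exposure
kind; grades relax from day 4 to day 7 except in the severe-outcome
regimes (blue 100–150 J/cm² PDT, blue 150 J/cm² irradiation-only, and the
150 J/cm² dual-wavelength PDT); and the mildest regime (red 50 J/cm² PDT)
never exceeds moderate edema. No claim is made of reproducing any
particular observed table cell-by-cell. Modal-grade summaries break ties
toward the more severe grade (conservative for safety reporting).

## Pipeline

`run_monitoring_pipeline` chains segmentation → ROI intensities → PE →
rate fits → ratio series → depth estimate → dosimetry, logging each stage
with its parameters; all Monte Carlo seeds derive from the run seed, so a
fixed config is deterministic end-to-end, and every report records the
config hash, seeds and package version. The pipeline's default photon
count (2·10⁵) trades ~0.2% dose-fraction precision for seconds-scale runs;
raise it for publication-grade dosimetry. JSON is the report's source of
truth; CSV/text renderings are derived from it.
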