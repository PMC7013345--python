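"""Synthetic fluorescence-monitoring fixtures.

The animal study behind this package deposited no raw data, so every
analysis input is emulated here with the statistical structure the
analysis assumes:

* dose-indexed ROI-mean intensity series following the single-exponential
  bleaching model If(D) = If1 exp(-alpha D) with multiplicative Gaussian
  noise (coefficient-of-variation parameterized; Poisson optional);
* dual-wavelength image sessions - a bright fluorescing disc on a dark
  background - whose disc-interior mean follows the same decay model;
* ordinal edema-outcome tables over the twenty exposure regimes
  (PDT/irradiation-only x red/blue/combined x 50-150 J/cm^2) shaped by the
  qualitative ordering observed in the study: red-light regimes never grade
  worse than the equal-dose blue-light regime, and grades relax from day 4
  to day 7 except in the severe-outcome regimes.

Bleaching-rate presets are the fitted study values: blue-light PDT
alpha = 0.011 / 0.009 (405- / 660-nm excitation) and red-light PDT
alpha = 0.014 / 0.017 per (J/cm^2), which give a rising red-to-blue ratio
under blue-light PDT and a falling one under red-light PDT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fluor_kinetics import DoseSeries, FluorescenceFrame

__all__ = [
    "EdemaGrade",
    "GRADE_SYMBOLS",
    "PRESETS",
    "REGIMES",
    "SEVERE_REGIMES",
    "SessionSpec",
    "TIMEPOINTS",
    "generate_bleach_series",
    "generate_outcome_table",
    "generate_session_images",
    "grades_to_frame",
    "preset_session",
]

# Fitted bleaching rates per regime: (alpha at 405-nm, alpha at 660-nm
# excitation), in 1/(J/cm^2).
PRESETS = {
    "pdt_b": {"alpha_405": 0.011, "alpha_660": 0.009},
    "pdt_r": {"alpha_405": 0.014, "alpha_660": 0.017},
}

DOSES = (50, 75, 100, 150)
REGIMES = tuple(
    f"{kind}_{color}{dose}"
    for kind in ("PDT", "IRR")
    for color, doses in (("r", DOSES), ("b", DOSES), ("rb", (100, 150)))
    for dose in doses
)
TIMEPOINTS = ("post", "day4", "day7")
GRADE_SYMBOLS = {0: "-", 1: "+", 2: "++", 3: "+++"}
# Regimes in which severe late outcomes were observed, exempt from the
# day-7-not-worse-than-day-4 relaxation rule.
SEVERE_REGIMES = frozenset({"PDT_b100", "PDT_b150", "IRR_b150", "PDT_rb150"})


@dataclass(frozen=True, kw_only=True)
class SessionSpec:
    """Generative parameters for one dual-wavelength monitoring session.

    Initial intensities give a pre-procedure red-to-blue ratio of 0.9,
    inside the 0.8-1.1 band typical of the monitored sites; the default
    dose grid covers a 50 J/cm^2 procedure sampled every 10 J/cm^2 and the
    default noise level is a 5% coefficient of variation.
    """

    seed: int
    If1_405: float = 1000.0
    If1_660: float = 900.0
    alpha_405: float = PRESETS["pdt_b"]["alpha_405"]
    alpha_660: float = PRESETS["pdt_b"]["alpha_660"]
    doses: tuple = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0)
    noise_cv: float = 0.05
    noise_model: str = "gaussian"
    n_replicates: int = 3
    image_shape: tuple = (128, 128)
    roi_center: tuple = (64, 64)
    roi_radius: float = 40.0
    background: float = 20.0

    def __post_init__(self):
        if self.If1_405 <= 0 or self.If1_660 <= 0:
            raise ValueError("initial intensities must be > 0")
        if self.alpha_405 < 0 or self.alpha_660 < 0:
            raise ValueError("bleaching rates must be >= 0")
        d = np.asarray(self.doses, dtype=float)
        if d[0] != 0 or np.any(np.diff(d) <= 0):
            raise ValueError("doses must start at 0 and strictly increase")
        if not 0 <= self.noise_cv < 1:
            raise ValueError("noise_cv must be in [0, 1)")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError("noise_model must be 'gaussian' or 'poisson'")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        cy, cx = self.roi_center
        h, w = self.image_shape
        r = self.roi_radius
        if not (r < cy < h - r and r < cx < w - r):
            raise ValueError("ROI disc does not fit inside image_shape")


def preset_session(preset: str, seed: int, **overrides) -> SessionSpec:
    """SessionSpec for a named regime preset ('pdt_b' or 'pdt_r')."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
    return SessionSpec(seed=seed, **{**PRESETS[preset], **overrides})


def _model_params(spec: SessionSpec, excitation_nm: int):
    if excitation_nm == 405:
        return spec.If1_405, spec.alpha_405
    if excitation_nm == 660:
        return spec.If1_660, spec.alpha_660
    raise ValueError("excitation_nm must be 405 or 660")


def _noisy(rng: np.random.Generator, model: np.ndarray, spec: SessionSpec):
    if spec.noise_model == "poisson":
        return rng.poisson(np.maximum(model, 0)).astype(float)
    vals = model * (1.0 + rng.normal(0.0, spec.noise_cv, size=model.shape))
    # intensities must stay positive for the log-scale fit initialization
    return np.maximum(vals, 1e-6 * np.max(model))


def generate_bleach_series(
    spec: SessionSpec, excitation_nm: int
) -> list[DoseSeries]:
    """Replicate dose-intensity decay series for one excitation wavelength.

    Each point is If1 * exp(-alpha D) * (1 + eps) with eps ~ N(0, noise_cv)
    drawn independently per point and replicate; fully reproducible for a
    fixed spec seed (the excitation wavelength enters the seed sequence so
    the two channels get independent noise).
    """
    if1, alpha = _model_params(spec, excitation_nm)
    rng = np.random.default_rng([spec.seed, excitation_nm])
    doses = np.asarray(spec.doses, dtype=float)
    model = if1 * np.exp(-alpha * doses)
    out = []
    for _ in range(spec.n_replicates):
        out.append(
            DoseSeries(
                doses=doses,
                intensities=_noisy(rng, model, spec),
                excitation_nm=excitation_nm,
            )
        )
    return out


def generate_session_images(
    spec: SessionSpec,
) -> tuple[list[FluorescenceFrame], pd.DataFrame]:
    """One dual-wavelength image session: per dose and excitation, a frame
    with a bright fluorescing disc whose interior mean follows the decay
    model over a low constant background.

    Noise is applied per pixel (camera-like), so the ROI mean of an emitted
    frame reproduces the generating curve to within noise_cv / sqrt(n_pixels)
    and exactly when noise_cv = 0.  Returns the frames in dose order (405-
    then 660-nm at each dose) plus a manifest table.
    """
    rng = np.random.default_rng([spec.seed, 999])
    h, w = spec.image_shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = spec.roi_center
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= spec.roi_radius**2
    frames: list[FluorescenceFrame] = []
    rows = []
    for dose in np.asarray(spec.doses, dtype=float):
        for exc in (405, 660):
            if1, alpha = _model_params(spec, exc)
            level = if1 * np.exp(-alpha * dose)
            img = np.full((h, w), spec.background, dtype=float)
            img[disc] = level
            if spec.noise_cv > 0:
                img = img * (1.0 + rng.normal(0.0, spec.noise_cv, size=img.shape))
                img = np.maximum(img, 0.0)
            frames.append(
                FluorescenceFrame(
                    pixels=img, excitation_nm=exc, cumulative_dose=float(dose)
                )
            )
            rows.append(
                {
                    "file": f"frame_d{dose:05.1f}_x{exc}.tif",
                    "excitation_nm": exc,
                    "dose_Jcm2": float(dose),
                }
            )
    return frames, pd.DataFrame(rows)


@dataclass(frozen=True)
class EdemaGrade:
    """Ordinal tissue-reaction grade for one regime at one timepoint.

    level 0..3 maps to the (-, +, ++, +++) encoding: no/minor edema,
    moderate edema, pronounced edema, severe changes.
    """

    regime: str
    timepoint: str
    level: int

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        if self.level not in (0, 1, 2, 3):
            raise ValueError("level must be an integer in 0..3")

    @property
    def symbol(self) -> str:
        return GRADE_SYMBOLS[self.level]


def _parse_regime(regime: str):
    kind, rest = regime.split("_")
    color = rest.rstrip("0123456789")
    dose = int(rest[len(color):])
    return kind, color, dose


# Central (post, day4, day7) grades per light color and dose, before
# stochastic jitter and the ordering constraints.
_BASE_GRADES = {
    ("r", 50): (0, 1, 0),
    ("r", 75): (1, 1, 0),
    ("r", 100): (1, 1, 1),
    ("r", 150): (1, 1, 1),
    ("b", 50): (1, 1, 0),
    ("b", 75): (1, 1, 1),
    ("b", 100): (1, 2, 1),
    ("b", 150): (2, 3, 2),
    ("rb", 100): (1, 2, 1),
    ("rb", 150): (1, 2, 2),
}


def generate_outcome_table(seed: int) -> list[EdemaGrade]:
    """Plausibility-shaped ordinal outcome table over all 20 regimes and
    3 timepoints.

    Central grades are jittered by +/-1 with a seeded RNG and then clamped
    so that, in every generated table: red-light regimes never exceed the
    grade of the equal-dose blue-light regime of the same exposure kind;
    day-7 grades do not exceed day-4 grades outside the severe-outcome
    regimes; and the mildest regime (PDT_r50) never exceeds moderate edema.
    """
    rng = np.random.default_rng(seed)
    grades: dict[tuple[str, str], int] = {}
    for regime in REGIMES:
        kind, color, dose = _parse_regime(regime)
        base = _BASE_GRADES[(color, dose)]
        # irradiation-only sites relaxed less by day 7 than PDT sites
        bump = 1 if (kind == "IRR" and dose >= 100) else 0
        for tp, g in zip(TIMEPOINTS, base):
            if tp == "day7":
                g = g + bump
            g = g + int(rng.integers(-1, 2))
            grades[(regime, tp)] = int(np.clip(g, 0, 3))
    # day-7 relaxation for non-severe regimes
    for regime in REGIMES:
        if regime not in SEVERE_REGIMES:
            grades[(regime, "day7")] = min(
                grades[(regime, "day7")], grades[(regime, "day4")]
            )
    # red never worse than equal-dose blue (same exposure kind)
    for kind in ("PDT", "IRR"):
        for dose in DOSES:
            for tp in TIMEPOINTS:
                red = (f"{kind}_r{dose}", tp)
                blue = (f"{kind}_b{dose}", tp)
                grades[red] = min(grades[red], grades[blue])
    # the mildest regime shows at most weak edema
    for tp in TIMEPOINTS:
        grades[("PDT_r50", tp)] = min(grades[("PDT_r50", tp)], 1)
    return [
        EdemaGrade(regime=reg, timepoint=tp, level=grades[(reg, tp)])
        for reg in REGIMES
        for tp in TIMEPOINTS
    ]


def grades_to_frame(records: list[EdemaGrade]) -> pd.DataFrame:
    """Grade records as a tidy table with columns regime, timepoint, grade."""
    return pd.DataFrame(
        {
            "regime": [r.regime for r in records],
            "timepoint": [r.timepoint for r in records],
            "grade": [r.level for r in records],
        }
    )
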