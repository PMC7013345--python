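"""Photosensitizer penetration-depth estimation from the red-to-blue ratio.

Topically applied chlorin e6 penetrates a limited depth d into tissue.
Because 660-nm excitation light reaches deeper than 405-nm light, the
ratio R = If660 / If405 of the detected fluorescence under the two
excitations grows with d.  This module builds that forward model from the
layered Monte Carlo transport:

    I_exc(d) = integral over z of Phi_exc(z) * C(z; d) * E(z) dz

where Phi_exc(z) = A(z) / mua(z) is the excitation fluence-equivalent depth
profile from the transport run, C the photosensitizer concentration profile
(uniform from the surface to depth d by default, for topical application),
and E(z) the Monte Carlo escape fraction for isotropic emission at depth z
through the top surface.  The model curve R(d) = kappa * I_660exc / I_405exc
is strictly increasing on the default ear model and is inverted by monotone
piecewise-linear interpolation.  kappa bundles the unknown relative
excitation irradiance and detector throughput at the two wavelengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np

from .layered_mc import (
    TissueModel,
    TransportConfig,
    TransportResult,
    escape_fraction_profile,
    simulate_transport,
)

__all__ = [
    "DepthEstimate",
    "FluorescenceForwardConfig",
    "NonMonotoneCurveError",
    "PSProfile",
    "RatioDepthCurve",
    "build_ratio_depth_curve",
    "estimate_depth",
    "excitation_fluence",
    "simulate_fluorescence_response",
]


class NonMonotoneCurveError(RuntimeError):
    """The forward model produced a ratio-depth curve that is not strictly
    increasing beyond Monte Carlo noise; inversion would be ambiguous."""


@dataclass(frozen=True)
class PSProfile:
    """Photosensitizer depth profile.

    shape 'uniform': constant concentration from the surface to depth_mm.
    shape 'exponential': concentration ~ exp(-z / depth_mm).
    """

    shape: str = "uniform"
    depth_mm: float = 0.5
    concentration_scale: float = 1.0

    def __post_init__(self):
        if self.shape not in ("uniform", "exponential"):
            raise ValueError("shape must be 'uniform' or 'exponential'")
        if self.depth_mm <= 0:
            raise ValueError("depth_mm must be > 0")
        if self.concentration_scale < 0:
            raise ValueError("concentration_scale must be >= 0")

    def concentration(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if self.shape == "uniform":
            return self.concentration_scale * (z < self.depth_mm).astype(float)
        return self.concentration_scale * np.exp(-z / self.depth_mm)


@dataclass(frozen=True)
class FluorescenceForwardConfig:
    """Tissue models and instrument constant for the forward ratio model.

    emission_model carries the optical properties used for the detected
    fluorescence band; kappa is the instrument's red/blue throughput ratio
    (default 1, i.e. uncalibrated relative units).
    """

    excitation_405: TissueModel
    excitation_660: TissueModel
    emission_model: TissueModel
    mc: TransportConfig
    kappa: float = 1.0

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")


def excitation_fluence(result: TransportResult, model: TissueModel) -> np.ndarray:
    """Fluence-equivalent excitation profile Phi(z) = A(z) / mua(z) on the
    transport grid (zero where the local absorption vanishes)."""
    mua = model.mua_profile(result.z_centers)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(mua > 0, result.absorbed_density / mua, 0.0)
    return phi


def simulate_fluorescence_response(
    tissue_at_excitation: TissueModel,
    emission_model: TissueModel,
    ps: PSProfile,
    mc: TransportConfig,
) -> float:
    """Detected fluorescence intensity (a.u.) for one excitation wavelength.

    Quadrature of Phi_exc(z) * C(z) * E(z) over the transport depth grid;
    deterministic for a fixed seed (the escape run uses seed + 1).
    """
    if ps.shape == "uniform" and ps.depth_mm > tissue_at_excitation.total_thickness:
        raise ValueError("photosensitizer profile extends beyond the slab")
    tr = simulate_transport(tissue_at_excitation, mc)
    phi = excitation_fluence(tr, tissue_at_excitation)
    esc_cfg = TransportConfig(
        seed=mc.seed + 1,
        n_photons=mc.n_photons,
        z_bin=mc.z_bin,
        roulette_threshold=mc.roulette_threshold,
        roulette_survival=mc.roulette_survival,
    )
    esc = escape_fraction_profile(emission_model, tr.z_centers, esc_cfg)
    conc = ps.concentration(tr.z_centers)
    return float(np.sum(phi * conc * esc) * tr.z_bin)


@dataclass(frozen=True)
class RatioDepthCurve:
    """Monotone lookup from red-to-blue ratio to photosensitizer depth."""

    depths: np.ndarray  # mm, strictly increasing
    ratios: np.ndarray  # model R at each depth
    kappa: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        d = np.asarray(self.depths, dtype=float)
        r = np.asarray(self.ratios, dtype=float)
        if d.shape != r.shape or d.ndim != 1 or len(d) < 2:
            raise ValueError("curve needs >= 2 (depth, ratio) pairs")
        if np.any(np.diff(d) <= 0):
            raise ValueError("depths must be strictly increasing")
        object.__setattr__(self, "depths", d)
        object.__setattr__(self, "ratios", r)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kappa": self.kappa,
                "depths_mm": self.depths.tolist(),
                "ratios": self.ratios.tolist(),
                "meta": self.meta,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "RatioDepthCurve":
        obj = json.loads(text)
        return cls(
            depths=np.array(obj["depths_mm"]),
            ratios=np.array(obj["ratios"]),
            kappa=obj.get("kappa", 1.0),
            meta=obj.get("meta", {}),
        )


def build_ratio_depth_curve(
    config: FluorescenceForwardConfig, depths: np.ndarray
) -> RatioDepthCurve:
    """Forward-model R(d) = kappa * I_660exc(d) / I_405exc(d) for
    uniform-to-depth photosensitizer profiles on a grid of depths.

    The two excitation transports and the emission escape profile are each
    computed once; every depth then only changes the integration limit, so
    the curve is a ratio of cumulative quadratures and Monte Carlo noise is
    strongly correlated between neighbouring depths.  A curve that is not
    strictly increasing raises NonMonotoneCurveError rather than being
    accepted silently.
    """
    depths = np.asarray(depths, dtype=float)
    if len(depths) < 3:
        raise ValueError("need at least 3 depths")
    if np.any(np.diff(depths) <= 0):
        raise ValueError("depths must be strictly increasing")
    slab = config.excitation_405.total_thickness
    if depths[0] <= 0 or depths[-1] > slab:
        raise ValueError("depths must lie in (0, slab thickness]")
    mc = config.mc
    tr405 = simulate_transport(
        config.excitation_405, _with_seed(mc, mc.seed)
    )
    tr660 = simulate_transport(
        config.excitation_660, _with_seed(mc, mc.seed + 1)
    )
    phi405 = excitation_fluence(tr405, config.excitation_405)
    phi660 = excitation_fluence(tr660, config.excitation_660)
    esc = escape_fraction_profile(
        config.emission_model, tr405.z_centers, _with_seed(mc, mc.seed + 2)
    )
    # cumulative integral up to each requested depth (uniform profile),
    # anchored at (0, 0) so sub-bin depths interpolate proportionally
    edges = np.concatenate([[0.0], tr405.z_centers + tr405.z_bin / 2.0])
    w405 = np.concatenate([[0.0], np.cumsum(phi405 * esc) * tr405.z_bin])
    w660 = np.concatenate([[0.0], np.cumsum(phi660 * esc) * tr660.z_bin])
    i405 = np.interp(depths, edges, w405)
    i660 = np.interp(depths, edges, w660)
    ratios = config.kappa * i660 / i405
    curve = RatioDepthCurve(
        depths=depths,
        ratios=ratios,
        kappa=config.kappa,
        meta={
            "seeds": [mc.seed, mc.seed + 1, mc.seed + 2],
            "n_photons": mc.n_photons,
            "z_bin": mc.z_bin,
        },
    )
    if np.any(np.diff(ratios) <= 0):
        raise NonMonotoneCurveError(
            "forward model produced a non-increasing ratio-depth curve; "
            "increase n_photons or inspect the tissue model"
        )
    return curve


def _with_seed(mc: TransportConfig, seed: int) -> TransportConfig:
    return TransportConfig(
        seed=seed,
        n_photons=mc.n_photons,
        z_bin=mc.z_bin,
        roulette_threshold=mc.roulette_threshold,
        roulette_survival=mc.roulette_survival,
    )


@dataclass(frozen=True)
class DepthEstimate:
    """Inverted photosensitizer depth with an out-of-range flag."""

    depth_mm: float
    ratio: float
    out_of_range: bool


def estimate_depth(curve: RatioDepthCurve, r: float) -> DepthEstimate:
    """Invert the ratio-depth curve at ratio r by monotone piecewise-linear
    interpolation; ratios outside the curve's range are clamped to the end
    depths and flagged."""
    if len(curve.depths) < 2:
        raise ValueError("curve needs at least 2 points")
    if np.any(np.diff(curve.ratios) <= 0):
        raise NonMonotoneCurveError("curve ratios are not strictly increasing")
    out = bool(r < curve.ratios[0] or r > curve.ratios[-1])
    depth = float(np.interp(r, curve.ratios, curve.depths))
    return DepthEstimate(depth_mm=depth, ratio=float(r), out_of_range=out)
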