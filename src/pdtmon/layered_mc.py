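"""Monte Carlo light dosimetry in planar layered tissue.

Simulates normally incident, collimated irradiation of a stack of turbid
layers (the default stack is a 1-mm rabbit-ear model: skin 0.4 mm /
cartilage 0.2 mm / skin 0.4 mm, with literature optical properties for the
405- and 660-nm chlorin-e6 absorption bands) and returns the depth-resolved
absorbed-dose profile A(z) together with the specular/diffuse reflectance
and transmittance energy fractions.

The transport runs in the similarity domain: because only the reduced
scattering coefficient mu_s' is tabulated, scattering is isotropic at
mu_s = mu_s'.  Beyond about one transport mean free path this is equivalent
to anisotropic transport sharing the same (mu_a, mu_s').  The beam is a
pencil beam with absorption scored versus depth only, which is identical to
an infinite broad beam per unit area.  Specular reflection is deducted
analytically at launch; every index-mismatched internal boundary applies
unpolarized Fresnel reflection/refraction with total internal reflection;
low-weight packets are terminated by unbiased Russian roulette.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._mc_kernels import (
    escape_kernel,
    fresnel_unpolarized,
    transport_kernel,
)

__all__ = [
    "ConfigurationError",
    "OpticalLayer",
    "TissueModel",
    "TransportConfig",
    "TransportResult",
    "WAVELENGTHS_NM",
    "absorbed_fraction",
    "default_rabbit_ear_model",
    "escape_fraction_profile",
    "fresnel_reflectance",
    "simulate_transport",
]

WAVELENGTHS_NM = (405, 660)


class ConfigurationError(ValueError):
    """A transport run was requested with an unusable model or config."""


@dataclass(frozen=True)
class OpticalLayer:
    """One homogeneous tissue layer.

    thickness_mm : layer thickness (mm, > 0)
    n            : refractive index (>= 1)
    mua          : absorption coefficient (1/mm, >= 0)
    musp         : reduced scattering coefficient (1/mm, >= 0)
    """

    name: str
    thickness_mm: float
    n: float
    mua: float
    musp: float

    def __post_init__(self):
        if not np.isfinite(self.thickness_mm) or self.thickness_mm <= 0:
            raise ValueError(f"layer {self.name!r}: thickness must be finite and > 0")
        if self.n < 1.0:
            raise ValueError(f"layer {self.name!r}: refractive index must be >= 1")
        if self.mua < 0 or self.musp < 0:
            raise ValueError(f"layer {self.name!r}: mua and musp must be >= 0")
        if self.mua == 0 and self.musp == 0:
            raise ValueError(
                f"layer {self.name!r}: mua and musp cannot both be zero"
            )


@dataclass(frozen=True)
class TissueModel:
    """Ordered stack of optical layers, top (irradiated) layer first."""

    layers: tuple[OpticalLayer, ...]
    n_ambient_top: float = 1.0
    n_ambient_bottom: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "layers", tuple(self.layers))
        if len(self.layers) < 1:
            raise ValueError("a TissueModel needs at least one layer")

    @property
    def total_thickness(self) -> float:
        return float(sum(l.thickness_mm for l in self.layers))

    def boundaries(self) -> np.ndarray:
        """Cumulative layer boundaries, starting at 0 (mm)."""
        return np.concatenate(
            [[0.0], np.cumsum([l.thickness_mm for l in self.layers])]
        )

    def layer_index(self, z) -> np.ndarray:
        """Index of the layer containing each depth z (mm)."""
        z = np.asarray(z, dtype=float)
        idx = np.searchsorted(self.boundaries()[1:], z, side="right")
        return np.clip(idx, 0, len(self.layers) - 1)

    def mua_profile(self, z) -> np.ndarray:
        mua = np.array([l.mua for l in self.layers])
        return mua[self.layer_index(z)]


# Optical properties of human skin and cartilage at the two chlorin-e6
# absorption bands: (n, mua 1/mm, musp 1/mm) per tissue per wavelength.
_EAR_OPTICAL_PROPERTIES = {
    405: {"skin": (1.45, 1.3, 5.4), "cartilage": (1.4, 0.08, 3.0)},
    660: {"skin": (1.45, 0.3, 4.6), "cartilage": (1.4, 0.01, 1.0)},
}
_EAR_STACK = (("skin", 0.4), ("cartilage", 0.2), ("skin", 0.4))


def default_rabbit_ear_model(wavelength_nm: int) -> TissueModel:
    """Three-layer rabbit-ear model (skin / cartilage / skin, 1 mm total)
    with the tabulated optical properties for 405 or 660 nm."""
    try:
        props = _EAR_OPTICAL_PROPERTIES[int(wavelength_nm)]
    except (KeyError, TypeError, ValueError):
        raise ValueError(
            f"no tabulated optical properties for {wavelength_nm} nm; "
            f"available: {sorted(_EAR_OPTICAL_PROPERTIES)}"
        ) from None
    layers = []
    for tissue, thickness in _EAR_STACK:
        n, mua, musp = props[tissue]
        layers.append(OpticalLayer(tissue, thickness, n, mua, musp))
    return TissueModel(tuple(layers))


@dataclass(frozen=True, kw_only=True)
class TransportConfig:
    """Monte Carlo run parameters.

    n_photons          : packets to launch
    z_bin              : depth bin width (mm)
    roulette_threshold : weight below which Russian roulette starts
    roulette_survival  : survival probability in roulette
    seed               : RNG seed (mandatory, for reproducibility)
    """

    seed: int
    n_photons: int = 1_000_000
    z_bin: float = 0.01
    roulette_threshold: float = 1.0e-4
    roulette_survival: float = 0.1

    def __post_init__(self):
        if self.n_photons < 1:
            raise ConfigurationError("n_photons must be >= 1")
        if self.z_bin <= 0:
            raise ConfigurationError("z_bin must be > 0")
        if not 0 < self.roulette_survival < 1:
            raise ConfigurationError("roulette_survival must be in (0, 1)")


@dataclass(frozen=True)
class TransportResult:
    """Depth-resolved absorbed dose and boundary energy fractions.

    absorbed_density is A(z): photons absorbed per unit volume per photon
    launched per unit area (1/mm), on bin centers z_centers (z = 0 at the
    irradiated surface, increasing downward).
    """

    z_centers: np.ndarray
    absorbed_density: np.ndarray
    r_specular: float
    r_diffuse: float
    transmitted: float
    absorbed_total: float
    z_bin: float
    n_photons: int
    seed: int

    def energy_balance(self) -> float:
        """r_specular + r_diffuse + transmitted + absorbed_total (ideally 1)."""
        return (
            self.r_specular + self.r_diffuse + self.transmitted
            + self.absorbed_total
        )


def fresnel_reflectance(n_i: float, n_t: float, cos_theta_i: float) -> float:
    """Unpolarized Fresnel reflectance at a planar interface.

    Returns 1.0 beyond the critical angle when going from dense to rare
    (n_i > n_t).  cos_theta_i is the incident direction cosine in [0, 1].
    """
    if not 0.0 <= cos_theta_i <= 1.0:
        raise ValueError("cos_theta_i must be in [0, 1]")
    if n_i <= 0 or n_t <= 0:
        raise ValueError("refractive indices must be positive")
    return float(fresnel_unpolarized(float(n_i), float(n_t), float(cos_theta_i)))


def _model_arrays(model: TissueModel):
    bounds = model.boundaries()
    n_lay = np.array([l.n for l in model.layers], dtype=float)
    mua = np.array([l.mua for l in model.layers], dtype=float)
    mus = np.array([l.musp for l in model.layers], dtype=float)  # similarity rule
    return bounds, n_lay, mua, mus


def _n_bins(model: TissueModel, z_bin: float) -> int:
    return int(np.ceil(model.total_thickness / z_bin - 1.0e-9))


def simulate_transport(model: TissueModel, config: TransportConfig) -> TransportResult:
    """Run the layered-slab Monte Carlo and return the dose profile.

    Reproducible: identical (model, config) including the seed give a
    bit-identical result.
    """
    bounds, n_lay, mua, mus = _model_arrays(model)
    if np.all(mua + mus == 0):
        raise ConfigurationError("model has no interaction coefficients")
    n_bins = _n_bins(model, config.z_bin)
    r_specular = fresnel_reflectance(model.n_ambient_top, model.layers[0].n, 1.0)
    absorb, refl_w, trans_w = transport_kernel(
        config.seed,
        config.n_photons,
        1.0 - r_specular,
        bounds,
        n_lay,
        mua,
        mus,
        float(model.n_ambient_top),
        float(model.n_ambient_bottom),
        float(config.z_bin),
        n_bins,
        float(config.roulette_threshold),
        float(config.roulette_survival),
    )
    n = float(config.n_photons)
    absorbed_density = absorb / (n * config.z_bin)
    z_centers = (np.arange(n_bins) + 0.5) * config.z_bin
    return TransportResult(
        z_centers=z_centers,
        absorbed_density=absorbed_density,
        r_specular=r_specular,
        r_diffuse=refl_w / n,
        transmitted=trans_w / n,
        absorbed_total=float(np.sum(absorbed_density) * config.z_bin),
        z_bin=float(config.z_bin),
        n_photons=config.n_photons,
        seed=config.seed,
    )


def absorbed_fraction(result: TransportResult, z0: float, z1: float) -> float:
    """Fraction of launched energy absorbed at depths in [z0, z1).

    Sums A(z) * dz over the half-open bins whose centers fall in [z0, z1).
    """
    if z1 < z0:
        raise ValueError("z1 must be >= z0")
    sel = (result.z_centers >= z0) & (result.z_centers < z1)
    return float(np.sum(result.absorbed_density[sel]) * result.z_bin)


def escape_fraction_profile(
    model: TissueModel,
    depths_mm: np.ndarray,
    config: TransportConfig,
    photons_per_depth: int | None = None,
) -> np.ndarray:
    """Escape function E(z): fraction of unit energy emitted isotropically at
    each depth that exits the top surface (any exit angle).

    Used to model detected fluorescence from emitters buried at depth z.
    If photons_per_depth is not given, config.n_photons is split evenly
    across the requested depths.
    """
    depths = np.asarray(depths_mm, dtype=float)
    if depths.ndim != 1 or len(depths) == 0:
        raise ValueError("depths_mm must be a non-empty 1-D array")
    if np.any(depths < 0) or np.any(depths > model.total_thickness):
        raise ValueError("depths must lie within the slab")
    bounds, n_lay, mua, mus = _model_arrays(model)
    if photons_per_depth is None:
        photons_per_depth = max(1, config.n_photons // len(depths))
    n_bins = _n_bins(model, config.z_bin)
    layer0 = model.layer_index(depths).astype(np.int64)
    return escape_kernel(
        config.seed,
        int(photons_per_depth),
        depths,
        layer0,
        bounds,
        n_lay,
        mua,
        mus,
        float(model.n_ambient_top),
        float(model.n_ambient_bottom),
        float(config.z_bin),
        n_bins,
        float(config.roulette_threshold),
        float(config.roulette_survival),
    )
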