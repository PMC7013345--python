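"""Numba kernels for weighted-packet photon transport in a layered slab.

The walk runs in the similarity domain: isotropic scattering at the reduced
scattering coefficient, absorption handled continuously along each flight
path (track-length deposition), so a packet's weight is attenuated by
exp(-mua*path) between scattering events and the deposited energy is scored
analytically in every depth bin the path crosses.  This estimator has far
lower variance than collision-site scoring and is exact in the
scattering-free limit.

State per packet is (z, uz, weight, layer): the slab is laterally infinite
and azimuthally symmetric, so only the polar direction cosine matters.
"""

import numpy as np
from numba import njit

_BIG = 1.0e30


@njit(cache=True)
def fresnel_unpolarized(n_i, n_t, cos_i):
    """Unpolarized Fresnel power reflectance; 1.0 beyond the critical angle."""
    if n_i == n_t:
        return 0.0
    sin2_i = 1.0 - cos_i * cos_i
    sin2_t = (n_i / n_t) * (n_i / n_t) * sin2_i
    if sin2_t >= 1.0:
        return 1.0
    cos_t = np.sqrt(1.0 - sin2_t)
    rs = (n_i * cos_i - n_t * cos_t) / (n_i * cos_i + n_t * cos_t)
    rp = (n_t * cos_i - n_i * cos_t) / (n_t * cos_i + n_i * cos_t)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def _deposit(absorb, z0, uz, ell, w, mua_l, z_bin, n_bins):
    """Attenuate weight w along a straight flight of length ell starting at
    depth z0 with direction cosine uz, scoring the absorbed weight into the
    depth bins crossed.  Returns the attenuated weight."""
    if ell <= 0.0 or mua_l <= 0.0:
        return w
    absuz = abs(uz)
    if absuz < 1.0e-12:
        # horizontal flight: whole path in one bin
        ib = int(z0 / z_bin)
        if ib < 0:
            ib = 0
        elif ib >= n_bins:
            ib = n_bins - 1
        dep = w * (1.0 - np.exp(-mua_l * ell))
        absorb[ib] += dep
        return w - dep
    remaining = ell
    z = z0
    while remaining > 1.0e-15:
        if uz > 0.0:
            ib = int(np.floor(z / z_bin + 1.0e-9))
            if ib < 0:
                ib = 0
            elif ib >= n_bins:
                ib = n_bins - 1
            d_edge = ((ib + 1) * z_bin - z) / uz
        else:
            ib = int(np.ceil(z / z_bin - 1.0e-9)) - 1
            if ib < 0:
                ib = 0
            elif ib >= n_bins:
                ib = n_bins - 1
            d_edge = (z - ib * z_bin) / absuz
        seg = remaining if remaining < d_edge else d_edge
        if seg < 1.0e-15:
            seg = 1.0e-15
        dep = w * (1.0 - np.exp(-mua_l * seg))
        absorb[ib] += dep
        w -= dep
        z += uz * seg
        remaining -= seg
    return w


@njit(cache=True)
def _run_photon(z, uz, w, layer, absorb, bounds, n_lay, mua, mus,
                n_top, n_bot, z_bin, n_bins, w_th, p_surv):
    """Trace one packet to termination.

    Returns (status, weight): status 1 = escaped through the top surface,
    2 = transmitted through the bottom, 0 = terminated inside (roulette)."""
    n_layers = len(n_lay)
    for _ in range(10_000_000):
        # dimensionless scattering step, consumed as mus * path-length
        s_dimless = -np.log(np.random.random() + 1.0e-300)
        while True:
            mus_l = mus[layer]
            s_phys = s_dimless / mus_l if mus_l > 0.0 else _BIG
            if uz > 1.0e-14:
                db = (bounds[layer + 1] - z) / uz
            elif uz < -1.0e-14:
                db = (bounds[layer] - z) / uz
            else:
                db = _BIG
            if s_phys <= db:
                w = _deposit(absorb, z, uz, s_phys, w, mua[layer], z_bin, n_bins)
                z += uz * s_phys
                break
            # reach the boundary first
            w = _deposit(absorb, z, uz, db, w, mua[layer], z_bin, n_bins)
            s_dimless -= db * mus_l
            going_down = uz > 0.0
            if going_down:
                z = bounds[layer + 1]
                n_i = n_lay[layer]
                n_t = n_lay[layer + 1] if layer + 1 < n_layers else n_bot
            else:
                z = bounds[layer]
                n_i = n_lay[layer]
                n_t = n_lay[layer - 1] if layer > 0 else n_top
            refl = fresnel_unpolarized(n_i, n_t, abs(uz))
            if np.random.random() < refl:
                uz = -uz
            else:
                if going_down and layer == n_layers - 1:
                    return 2, w
                if (not going_down) and layer == 0:
                    return 1, w
                # refract into the adjacent layer
                sin2_t = (n_i / n_t) * (n_i / n_t) * (1.0 - uz * uz)
                uz_t = np.sqrt(max(0.0, 1.0 - sin2_t))
                uz = uz_t if going_down else -uz_t
                layer = layer + 1 if going_down else layer - 1
        # isotropic scatter
        uz = 2.0 * np.random.random() - 1.0
        # Russian roulette
        if w < w_th:
            if np.random.random() < p_surv:
                w /= p_surv
            else:
                return 0, 0.0
    return 0, 0.0


@njit(cache=True)
def transport_kernel(seed, n_photons, w_launch, bounds, n_lay, mua, mus,
                     n_top, n_bot, z_bin, n_bins, w_th, p_surv):
    """Pencil beam, normal incidence; returns (absorbed-per-bin weight,
    diffusely reflected weight, transmitted weight), all per launched
    unit-weight packet before specular deduction."""
    np.random.seed(seed)
    absorb = np.zeros(n_bins)
    refl_w = 0.0
    trans_w = 0.0
    for _ in range(n_photons):
        status, w = _run_photon(0.0, 1.0, w_launch, 0, absorb, bounds, n_lay,
                                mua, mus, n_top, n_bot, z_bin, n_bins,
                                w_th, p_surv)
        if status == 1:
            refl_w += w
        elif status == 2:
            trans_w += w
    return absorb, refl_w, trans_w


@njit(cache=True)
def escape_kernel(seed, n_per_depth, z0s, layer0s, bounds, n_lay, mua, mus,
                  n_top, n_bot, z_bin, n_bins, w_th, p_surv):
    """Fraction of unit weight emitted isotropically at each depth in z0s
    that escapes through the top surface."""
    np.random.seed(seed)
    scratch = np.zeros(n_bins)
    out = np.empty(len(z0s))
    for k in range(len(z0s)):
        esc = 0.0
        for _ in range(n_per_depth):
            uz = 2.0 * np.random.random() - 1.0
            status, w = _run_photon(z0s[k], uz, 1.0, layer0s[k], scratch,
                                    bounds, n_lay, mua, mus, n_top, n_bot,
                                    z_bin, n_bins, w_th, p_surv)
            if status == 1:
                esc += w
        out[k] = esc / n_per_depth
    return out
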