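"""Layered-tissue Monte Carlo photon transport.

A standard multi-layer simulation in the MCML tradition: pencil-beam launch at
normal incidence, specular deduction at the air/tissue interface, hop-drop-spin
propagation with Henyey-Greenstein scattering, Fresnel reflection/refraction at
layer boundaries (with total internal reflection), and Russian-roulette
termination.  The quantity of interest is total diffuse reflectance Rd: the
fraction of launched weight that escapes back through the top surface,
excluding the specular component.

Two kernels are provided.  ``run_transport`` is the direct estimator for one
absorption/scattering configuration with exact weight bookkeeping: every unit
of launched weight is attributed to specular, diffuse reflectance,
transmittance or absorption (Russian-roulette gains/losses folded into the
absorption ledger), so the four channels sum to 1 to floating-point precision.
``sample_pathlengths`` runs zero-absorption transport once and records the
per-layer path lengths of photons escaping the top surface; diffuse
reflectance for *any* per-layer absorption vector then follows by Beer-Lambert
reweighting of the recorded paths.  This absorption-reweighting scheme makes a
dense calibration grid affordable: one scattering simulation per wavelength
serves every concentration grid point.

Randomness comes from a self-contained xorshift64* generator so that runs are
bit-reproducible for a given seed across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["MCConfig", "MCResult", "run_transport",
           "PathlengthSample", "sample_pathlengths"]

_SEMI_INFINITE_CM = 1.0e8  # stand-in slab depth for semi-infinite layers
_U64 = np.uint64
_INV_2_53 = 1.0 / 9007199254740992.0


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo run configuration.

    ``n_photons`` below ~1e3 is too noisy for quantitative use; the fast
    profile uses 1e4 and the quality profile 1e6.  ``seed`` is recorded in all
    outputs.  Roulette follows the usual convention: once a photon's weight
    falls below ``weight_threshold`` it survives with probability
    ``survival_chance`` (and is re-weighted) or is terminated.
    """

    n_photons: int = 10_000
    seed: int = 0
    weight_threshold: float = 1e-4
    survival_chance: float = 0.1
    max_interactions: int = 10_000_000

    def __post_init__(self):
        if self.n_photons < 1:
            raise ValueError("n_photons must be positive")
        if not (0 < self.survival_chance <= 1):
            raise ValueError("survival_chance must be in (0, 1]")
        if self.weight_threshold <= 0:
            raise ValueError("weight_threshold must be positive")

    def with_seed(self, seed: int) -> "MCConfig":
        return MCConfig(self.n_photons, int(seed) % (2**31), self.weight_threshold,
                        self.survival_chance, self.max_interactions)


@dataclass(frozen=True)
class MCResult:
    """Per-run tallies, all as fractions of launched photon weight."""

    rd: float          # diffuse reflectance (excludes specular)
    rd_se: float       # Monte Carlo standard error of rd
    specular: float
    transmittance: float
    absorbed: float    # includes roulette bookkeeping corrections
    n_photons: int
    seed: int
    n_truncated: int   # photons stopped by the interaction cap

    @property
    def total(self) -> float:
        """Conservation check: should equal 1 to floating-point precision."""
        return self.rd + self.specular + self.transmittance + self.absorbed


@njit(inline="always")
def _rng_init(seed):
    # splitmix64 scramble of the seed; xorshift64* state must be nonzero
    s = _U64(seed) + _U64(0x9E3779B97F4A7C15)
    s = (s ^ (s >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    s = (s ^ (s >> _U64(27))) * _U64(0x94D049BB133111EB)
    s = s ^ (s >> _U64(31))
    if s == _U64(0):
        s = _U64(0x2545F4914F6CDD1D)
    return s


@njit(inline="always")
def _rng_next(s):
    s ^= s >> _U64(12)
    s ^= s << _U64(25)
    s ^= s >> _U64(27)
    u = (s * _U64(0x2545F4914F6CDD1D)) >> _U64(11)
    return s, float(u) * _INV_2_53


@njit(cache=True, fastmath=True)
def _fresnel(n1, n2, cos_i):
    """Unpolarized Fresnel reflectance for incidence cosine cos_i (>0)."""
    if n1 == n2:
        return 0.0, cos_i
    if cos_i > 0.9999999:
        r = ((n1 - n2) / (n1 + n2)) ** 2
        return r, 1.0
    sin_i = math.sqrt(1.0 - cos_i * cos_i)
    sin_t = n1 * sin_i / n2
    if sin_t >= 1.0:
        return 1.0, 0.0
    cos_t = math.sqrt(1.0 - sin_t * sin_t)
    rs = ((n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)) ** 2
    rp = ((n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)) ** 2
    return 0.5 * (rs + rp), cos_t


@njit(cache=True, fastmath=True)
def _kernel(seed, n_photons, mua, mus, g, n, z_bounds, n_above, n_below,
            w_threshold, p_survive, max_steps):
    rng = _rng_init(seed)
    n_layers = mua.size
    r_sp = ((n_above - n[0]) / (n_above + n[0])) ** 2

    rd_sum = 0.0
    rd_sq = 0.0
    tt_sum = 0.0
    ab_sum = 0.0
    n_trunc = 0

    for _ in range(n_photons):
        w = 1.0 - r_sp
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        layer = 0
        escaped_top = 0.0
        alive = True
        steps = 0
        s_dimless = 0.0  # leftover dimensionless step across a boundary

        while alive:
            steps += 1
            if steps > max_steps:
                n_trunc += 1
                ab_sum += w  # attribute unfinished weight to absorption
                break
            mut = mua[layer] + mus[layer]
            if s_dimless <= 0.0:
                rng, rnd = _rng_next(rng)
                while rnd <= 0.0:
                    rng, rnd = _rng_next(rng)
                s_dimless = -math.log(rnd)

            # --- hop (possibly through boundaries) ---
            while True:
                s = s_dimless / mut
                if uz > 0.0:
                    db = (z_bounds[layer + 1] - z) / uz
                elif uz < 0.0:
                    db = (z_bounds[layer] - z) / uz
                else:
                    db = 1.0e30
                if db > s:
                    z += uz * s
                    s_dimless = 0.0
                    break
                # move to the boundary, keep the unspent dimensionless step
                z = z_bounds[layer + 1] if uz > 0.0 else z_bounds[layer]
                s_dimless -= db * mut
                going_down = uz > 0.0
                cos_i = abs(uz)
                if going_down:
                    n2 = n[layer + 1] if layer + 1 < n_layers else n_below
                else:
                    n2 = n[layer - 1] if layer > 0 else n_above
                r, cos_t = _fresnel(n[layer], n2, cos_i)
                rng, rnd = _rng_next(rng)
                if rnd < r:
                    uz = -uz  # internal reflection
                else:
                    if going_down and layer + 1 >= n_layers:
                        tt_sum += w
                        alive = False
                        break
                    if (not going_down) and layer == 0:
                        escaped_top = w
                        alive = False
                        break
                    ratio = n[layer] / n2
                    ux *= ratio
                    uy *= ratio
                    uz = cos_t if going_down else -cos_t
                    layer = layer + 1 if going_down else layer - 1
                    mut = mua[layer] + mus[layer]
            if not alive:
                break

            # --- drop ---
            d = w * mua[layer] / mut
            ab_sum += d
            w -= d
            if w <= 1e-300:
                break

            # --- spin (Henyey-Greenstein) ---
            gg = g[layer]
            if mus[layer] > 0.0:
                rng, rnd = _rng_next(rng)
                if gg == 0.0:
                    ct = 2.0 * rnd - 1.0
                else:
                    tmp = (1.0 - gg * gg) / (1.0 - gg + 2.0 * gg * rnd)
                    ct = (1.0 + gg * gg - tmp * tmp) / (2.0 * gg)
                    if ct > 1.0:
                        ct = 1.0
                    elif ct < -1.0:
                        ct = -1.0
                st = math.sqrt(1.0 - ct * ct)
                rng, rnd = _rng_next(rng)
                phi = 2.0 * math.pi * rnd
                cp = math.cos(phi)
                sp = math.sin(phi)
                if abs(uz) > 0.99999:
                    ux = st * cp
                    uy = st * sp
                    uz = ct if uz > 0.0 else -ct
                else:
                    den = math.sqrt(1.0 - uz * uz)
                    nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
                    ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
                    nz = -st * cp * den + uz * ct
                    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
                    ux = nx / norm
                    uy = ny / norm
                    uz = nz / norm

            # --- roulette ---
            if w < w_threshold:
                rng, rnd = _rng_next(rng)
                if rnd < p_survive:
                    gained = w * (1.0 / p_survive - 1.0)
                    w += gained
                    ab_sum -= gained  # keep the weight ledger exact
                else:
                    ab_sum += w
                    break

        rd_sum += escaped_top
        rd_sq += escaped_top * escaped_top

    return r_sp, rd_sum, rd_sq, tt_sum, ab_sum, n_trunc


@njit(cache=True, fastmath=True)
def _kernel_pathlengths(seed, n_photons, mus, g, n, z_bounds, n_above, n_below,
                        layer_caps, max_steps, path_out):
    """Zero-absorption transport recording per-layer path lengths of photons
    that escape through the top surface.

    ``layer_caps`` holds a per-layer path-length cap in cm; a photon whose
    accumulated path in any layer exceeds its cap is terminated (used to
    truncate negligible-weight histories when the reweighting absorption has a
    known lower bound).  ``path_out`` is (n_photons, n_layers); rows for
    photons that do not escape the top are marked with -1 in column 0.
    Returns the specular reflectance and the number of capped photons.
    """
    rng = _rng_init(seed)
    n_layers = mus.size
    r_sp = ((n_above - n[0]) / (n_above + n[0])) ** 2
    n_capped = 0

    for ip in range(n_photons):
        for il in range(n_layers):
            path_out[ip, il] = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        layer = 0
        steps = 0
        escaped_top = False
        alive = True
        s_dimless = 0.0

        while alive:
            steps += 1
            if steps > max_steps or path_out[ip, layer] > layer_caps[layer]:
                n_capped += 1
                break
            mut = mus[layer]
            if s_dimless <= 0.0:
                rng, rnd = _rng_next(rng)
                while rnd <= 0.0:
                    rng, rnd = _rng_next(rng)
                s_dimless = -math.log(rnd)

            while True:
                s = s_dimless / mut
                if uz > 0.0:
                    db = (z_bounds[layer + 1] - z) / uz
                elif uz < 0.0:
                    db = (z_bounds[layer] - z) / uz
                else:
                    db = 1.0e30
                if db > s:
                    z += uz * s
                    path_out[ip, layer] += s
                    s_dimless = 0.0
                    break
                path_out[ip, layer] += db
                z = z_bounds[layer + 1] if uz > 0.0 else z_bounds[layer]
                s_dimless -= db * mut
                going_down = uz > 0.0
                cos_i = abs(uz)
                if going_down:
                    n2 = n[layer + 1] if layer + 1 < n_layers else n_below
                else:
                    n2 = n[layer - 1] if layer > 0 else n_above
                r, cos_t = _fresnel(n[layer], n2, cos_i)
                rng, rnd = _rng_next(rng)
                if rnd < r:
                    uz = -uz
                else:
                    if going_down and layer + 1 >= n_layers:
                        alive = False
                        break
                    if (not going_down) and layer == 0:
                        escaped_top = True
                        alive = False
                        break
                    ratio = n[layer] / n2
                    ux *= ratio
                    uy *= ratio
                    uz = cos_t if going_down else -cos_t
                    layer = layer + 1 if going_down else layer - 1
                    mut = mus[layer]
            if not alive:
                break

            gg = g[layer]
            rng, rnd = _rng_next(rng)
            if gg == 0.0:
                ct = 2.0 * rnd - 1.0
            else:
                tmp = (1.0 - gg * gg) / (1.0 - gg + 2.0 * gg * rnd)
                ct = (1.0 + gg * gg - tmp * tmp) / (2.0 * gg)
                if ct > 1.0:
                    ct = 1.0
                elif ct < -1.0:
                    ct = -1.0
            st = math.sqrt(1.0 - ct * ct)
            rng, rnd = _rng_next(rng)
            phi = 2.0 * math.pi * rnd
            cp = math.cos(phi)
            sp = math.sin(phi)
            if abs(uz) > 0.99999:
                ux = st * cp
                uy = st * sp
                uz = ct if uz > 0.0 else -ct
            else:
                den = math.sqrt(1.0 - uz * uz)
                nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
                ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
                nz = -st * cp * den + uz * ct
                norm = math.sqrt(nx * nx + ny * ny + nz * nz)
                ux = nx / norm
                uy = ny / norm
                uz = nz / norm

        if not escaped_top:
            path_out[ip, 0] = -1.0

    return r_sp, n_capped


@dataclass(frozen=True)
class PathlengthSample:
    """Escaping-photon path lengths from a zero-absorption transport run.

    Enables absorption reweighting: for any per-layer absorption vector mua,
    Rd = (1 - specular)/N * sum_i exp(-sum_l mua[l] * L[i, l]) over escaped
    photons i.  Exact in expectation provided the attenuation that capped
    (discarded) histories would carry is negligible, i.e. mua[l] *
    layer_cap[l] is large for the absorptions being evaluated.
    """

    paths: np.ndarray      # (n_escaped, n_layers) path length per layer, cm
    specular: float
    n_photons: int         # photons launched
    n_capped: int
    seed: int
    layer_caps: np.ndarray

    _CHUNK = 128  # absorption vectors per reweighting block (bounds memory)

    def reflectance(self, mua) -> np.ndarray:
        """Rd for one or many absorption vectors (..., n_layers)."""
        mean, _ = self._moments(mua, want_se=False)
        return mean

    def reflectance_se(self, mua):
        """Rd and its Monte Carlo standard error."""
        return self._moments(mua, want_se=True)

    def _moments(self, mua, want_se):
        # float32 keeps the exp over (vectors x photons) fast; 1e-7 relative
        # rounding is far below the Monte Carlo error.  Chunked over vectors
        # so memory stays bounded for large calibration grids.
        mua = np.atleast_2d(np.asarray(mua, dtype=np.float32))
        scalar = mua.shape[0] == 1 and np.asarray(mua).ndim <= 2
        paths_t = self.paths.T.astype(np.float32)
        n = self.n_photons
        w0 = 1.0 - self.specular
        means = np.empty(mua.shape[0])
        ses = np.empty(mua.shape[0]) if want_se else None
        for lo in range(0, mua.shape[0], self._CHUNK):
            c = np.exp(-(mua[lo:lo + self._CHUNK] @ paths_t))
            s1 = c.sum(axis=-1, dtype=np.float64)
            means[lo:lo + self._CHUNK] = w0 * s1 / n
            if want_se:
                s2 = np.einsum("ij,ij->i", c, c, dtype=np.float64)
                var = w0 * w0 * (s2 / n - (s1 / n) ** 2)
                ses[lo:lo + self._CHUNK] = np.sqrt(np.maximum(var, 0.0) / n)
        if scalar and means.size == 1:
            return means[0], (ses[0] if want_se else None)
        return means, ses


def sample_pathlengths(mus, g, n, thickness, config: MCConfig,
                       n_above: float = 1.0, n_below: float | None = None,
                       layer_caps=None) -> PathlengthSample:
    """Run the zero-absorption kernel and collect escaping-photon path lengths.

    ``layer_caps`` gives the per-layer path cap in cm (default 60 cm for every
    layer); see ``PathlengthSample`` for the validity condition.
    """
    mus = np.asarray(mus, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    thickness = np.asarray(thickness, dtype=np.float64)
    if not (mus.shape == g.shape == n.shape == thickness.shape):
        raise ValueError("per-layer property arrays must share length")
    if np.any(mus <= 0):
        raise ValueError("path-length sampling requires mus > 0 in every layer")
    if np.any((g < 0) | (g >= 1)) or np.any(n < 1) or np.any(thickness <= 0):
        raise ValueError("non-physical optical properties")
    if layer_caps is None:
        layer_caps = np.full(mus.size, 60.0)
    else:
        layer_caps = np.asarray(layer_caps, dtype=np.float64)
    th = np.where(np.isinf(thickness), _SEMI_INFINITE_CM, thickness)
    z_bounds = np.concatenate(([0.0], np.cumsum(th)))
    if n_below is None:
        n_below = float(n[-1])
    paths = np.empty((config.n_photons, mus.size))
    r_sp, n_capped = _kernel_pathlengths(
        int(config.seed) % (2**31), int(config.n_photons), mus, g, n, z_bounds,
        float(n_above), float(n_below), layer_caps,
        config.max_interactions, paths)
    escaped = paths[:, 0] >= 0.0
    return PathlengthSample(paths=paths[escaped].copy(), specular=r_sp,
                            n_photons=config.n_photons, n_capped=n_capped,
                            seed=config.seed, layer_caps=layer_caps)


def run_transport(mua, mus, g, n, thickness, config: MCConfig,
                  n_above: float = 1.0, n_below: float | None = None) -> MCResult:
    """Run the transport kernel for one layer stack at one wavelength.

    Parameters are per-layer arrays (top to bottom): absorption and scattering
    coefficients in cm^-1, anisotropy g in [0, 1), refractive index n >= 1,
    thickness in cm (``inf`` allowed for the bottom layer).  ``n_below``
    defaults to the bottom layer's index (no internal reflection at an
    effectively semi-infinite bottom).
    """
    mua = np.asarray(mua, dtype=np.float64)
    mus = np.asarray(mus, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    thickness = np.asarray(thickness, dtype=np.float64)
    if not (mua.shape == mus.shape == g.shape == n.shape == thickness.shape):
        raise ValueError("per-layer property arrays must share length")
    if np.any(mua < 0) or np.any(mus < 0) or np.any(mua + mus <= 0):
        raise ValueError("need mua, mus >= 0 and mua + mus > 0 in every layer")
    if np.any((g < 0) | (g >= 1)):
        raise ValueError("anisotropy g must lie in [0, 1)")
    if np.any(n < 1):
        raise ValueError("refractive index must be >= 1")
    if np.any(thickness <= 0):
        raise ValueError("layer thickness must be positive")
    th = np.where(np.isinf(thickness), _SEMI_INFINITE_CM, thickness)
    z_bounds = np.concatenate(([0.0], np.cumsum(th)))
    if n_below is None:
        n_below = float(n[-1])

    r_sp, rd_sum, rd_sq, tt_sum, ab_sum, n_trunc = _kernel(
        int(config.seed) % (2**31), int(config.n_photons),
        mua, mus, g, n, z_bounds, float(n_above), float(n_below),
        config.weight_threshold, config.survival_chance, config.max_interactions,
    )
    n_ph = config.n_photons
    rd = rd_sum / n_ph
    var = max(rd_sq / n_ph - rd * rd, 0.0)
    rd_se = math.sqrt(var / n_ph)
    return MCResult(rd=rd, rd_se=rd_se, specular=r_sp, transmittance=tt_sum / n_ph,
                    absorbed=ab_sum / n_ph, n_photons=n_ph, seed=config.seed,
                    n_truncated=n_trunc)
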