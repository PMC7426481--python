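"""Numba photon-packet propagation kernel for the layered slab.

Single compiled loop shared by forward and adjoint runs; only the source term
differs.  The walk is 1D in z: lateral coordinates never influence a tally, so
only the z direction cosine is tracked.  The RNG is an explicit
xorshift128+ stream (seeded via splitmix64) so results are bit-reproducible
for a given seed, independent of numpy/numba internals.

Scattering free paths are sampled from mu_s alone; absorption is handled by
continuous weight attenuation exp(-mu_a * l) along each track segment.  The
fluence tally is the track-length estimator with the analytically integrated
segment weight (w_in - w_out) / (mu_a * dz), which stays well-defined (w*l/dz)
as mu_a -> 0.  A useful consequence: photon trajectories depend only on mu_s
and g, so runs that share a seed share trajectories across different mu_a,
enabling common-random-number comparisons.
"""

import math

import numpy as np
from numba import njit

U64 = np.uint64
_DOUBLE_NORM = 1.0 / 9007199254740992.0  # 2^-53

SRC_FRONT = 0  # collimated, normal incidence at z=0, direction +z
SRC_BACK = 1  # collimated, normal incidence at z=d, direction -z
SRC_INTERNAL = 2  # isotropic volumetric source, per-layer density


@njit(cache=True, fastmath=True, inline="always")
def _splitmix64(z):
    z = (z + U64(0x9E3779B97F4A7C15)) & U64(0xFFFFFFFFFFFFFFFF)
    z = (z ^ (z >> U64(30))) * U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> U64(27))) * U64(0x94D049BB133111EB)
    return z ^ (z >> U64(31))


@njit(cache=True, fastmath=True, inline="always")
def _rng_init(seed):
    s0 = _splitmix64(U64(seed))
    s1 = _splitmix64(s0)
    if s0 == U64(0) and s1 == U64(0):
        s1 = U64(1)
    return s0, s1


@njit(cache=True, fastmath=True, inline="always")
def _rng_next(s0, s1):
    x = s0
    y = s1
    s0 = y
    x ^= (x << U64(23)) & U64(0xFFFFFFFFFFFFFFFF)
    s1 = x ^ y ^ (x >> U64(17)) ^ (y >> U64(26))
    return s0, s1, (s1 + y) & U64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True, fastmath=True, inline="always")
def _uniform(s0, s1):
    """Uniform double in [0, 1)."""
    s0, s1, u = _rng_next(s0, s1)
    return s0, s1, (u >> U64(11)) * _DOUBLE_NORM


@njit(cache=True, fastmath=True, inline="always")
def _hg_cos(g, u):
    if abs(g) < 1e-12:
        return 2.0 * u - 1.0
    t = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    ct = (1.0 + g * g - t * t) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(cache=True, fastmath=True)
def propagate(
    mu_a,
    mu_s,
    g,
    dz,
    src_kind,
    src_cdf,
    n_photons,
    weight_threshold,
    survival_prob,
    seed,
    phi_sum,
    phi_sqsum,
    scalars,
):
    """Propagate ``n_photons`` packets; accumulate per-layer track-length tallies.

    phi_sum / phi_sqsum: per-layer sums of per-photon tally contributions (for
    the mean and its standard error).  scalars receives sums and square-sums of
    per-photon reflected / transmitted / absorbed weight:
    [R, T, A, R2, T2, A2].
    """
    n_layers = mu_a.shape[0]
    d = n_layers * dz
    s0, s1 = _rng_init(seed)
    local = np.zeros(n_layers)

    for _ in range(n_photons):
        for j in range(n_layers):
            local[j] = 0.0

        # --- launch ---
        if src_kind == SRC_FRONT:
            i = 0
            z = 0.0
            uz = 1.0
        elif src_kind == SRC_BACK:
            i = n_layers - 1
            z = d
            uz = -1.0
        else:
            s0, s1, u = _uniform(s0, s1)
            i = np.searchsorted(src_cdf, u, side="right")
            if i >= n_layers:
                i = n_layers - 1
            s0, s1, u = _uniform(s0, s1)
            z = (i + u) * dz
            s0, s1, u = _uniform(s0, s1)
            uz = 2.0 * u - 1.0

        w = 1.0
        refl = 0.0
        trans = 0.0
        absorbed = 0.0
        alive = True

        while alive:
            s0, s1, u = _uniform(s0, s1)
            tau = -math.log(1.0 - u)  # optical depth to next scattering event

            while True:
                mua_l = mu_a[i]
                mus_l = mu_s[i]
                if mus_l > 0.0:
                    s_scat = tau / mus_l
                else:
                    s_scat = math.inf
                if uz > 1e-12:
                    db = ((i + 1) * dz - z) / uz
                elif uz < -1e-12:
                    db = (i * dz - z) / uz
                else:
                    db = math.inf

                if s_scat < db:
                    step = s_scat
                else:
                    step = db

                if not math.isfinite(step):
                    # moving parallel to the layers in a non-scattering layer:
                    # the packet never leaves; deposit its remaining weight
                    # (integral of w over an infinite track at mu_a > 0), or
                    # discard it in the measure-zero mu_a = 0 case.
                    if mua_l > 0.0:
                        local[i] += w / (mua_l * dz)
                        absorbed += w
                    alive = False
                    break

                # attenuate along the segment; track-length tally
                if mua_l > 1e-12:
                    w_out = w * math.exp(-mua_l * step)
                    local[i] += (w - w_out) / (mua_l * dz)
                    absorbed += w - w_out
                    w = w_out
                else:
                    local[i] += w * step / dz

                if s_scat < db:
                    # scattering event
                    z += uz * step
                    gl = g[i]
                    s0, s1, u = _uniform(s0, s1)
                    ct = _hg_cos(gl, u)
                    s0, s1, u = _uniform(s0, s1)
                    cphi = math.cos(2.0 * math.pi * u)
                    if abs(uz) > 0.99999999:
                        uz = ct if uz > 0.0 else -ct
                    else:
                        st = math.sqrt(max(0.0, 1.0 - ct * ct))
                        uz = uz * ct - st * cphi * math.sqrt(1.0 - uz * uz)
                    if uz > 1.0:
                        uz = 1.0
                    elif uz < -1.0:
                        uz = -1.0
                    break
                else:
                    # boundary crossing
                    tau -= mus_l * db
                    if tau < 0.0:
                        tau = 0.0
                    if uz > 0.0:
                        i += 1
                        z = i * dz
                        if i >= n_layers:
                            trans = w
                            alive = False
                            break
                    else:
                        z = i * dz
                        i -= 1
                        if i < 0:
                            refl = w
                            alive = False
                            break

            if alive and w < weight_threshold:
                s0, s1, u = _uniform(s0, s1)
                if u < survival_prob:
                    w /= survival_prob
                else:
                    alive = False

        for j in range(n_layers):
            c = local[j]
            phi_sum[j] += c
            phi_sqsum[j] += c * c
        scalars[0] += refl
        scalars[1] += trans
        scalars[2] += absorbed
        scalars[3] += refl * refl
        scalars[4] += trans * trans
        scalars[5] += absorbed * absorbed
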