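"""Numba kernel for time-resolved photon transport in a layered slab.

Photons random-walk through a laterally homogeneous stack of plane-parallel
layers that share a single scattering coefficient, anisotropy and refractive
index; layers differ only in absorption.  Because absorption is applied
afterwards through survival weights ``exp(-sum_j mu_a[j] * l_j)``, the
geometric walk is absorption-free and one simulation serves every absorption
query.  The kernel records, for each photon escaping through the top surface
inside a radial window, its total pathlength and its partial pathlength in
every layer.

Scattering is Henyey–Greenstein; the top surface applies unpolarized Fresnel
reflection for the tissue/air index step, all other boundaries only
terminate photons (mimicking a finite simulation volume).

Implementation notes: a dedicated xorshift64* generator keeps the draw
stream reproducible and cheap, the scattering azimuth is sampled without
trigonometry, and per-layer pathlength bookkeeping is fully inlined — with
a ~0.1 mm mean free path inside 1 mm layers almost every step stays in one
layer, so the common case is a single add.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: speed of light in vacuum, mm/s
C_MM_PER_S = 2.99792458e11

_INV_2_53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True, fastmath=True)
def propagate(
    n_photons: int,
    seed: int,
    mus: float,
    g: float,
    n_rel: float,
    n_layers: int,
    dz: float,
    z_max: float,
    r_term: float,
    keep_rmin: float,
    keep_rmax: float,
    max_path: float,
    out_path,
    out_r,
    out_L,
) -> int:
    """Run the photon walk; fill output arrays, return the number kept.

    ``out_path``/``out_r`` are (n_photons,) float64, ``out_L`` is
    (n_photons, n_layers) float64 (callers may downcast afterwards; passing
    a float32 buffer here makes the whole kernel several times slower).
    Distances in mm, directions are unit cosines, ``seed`` selects the
    deterministic draw stream.
    """
    # splitmix64 scramble of the seed so nearby seeds give unrelated streams
    s0 = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
    s0 = (s0 ^ (s0 >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    s0 = (s0 ^ (s0 >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    rng = s0 ^ (s0 >> np.uint64(31))
    if rng == np.uint64(0):
        rng = np.uint64(0x9E3779B97F4A7C15)

    crit_cos = 0.0
    if n_rel > 1.0:
        sin_c = 1.0 / n_rel
        crit_cos = np.sqrt(1.0 - sin_c * sin_c)
    n_kept = 0
    lbuf = np.zeros(n_layers)
    r_term2 = r_term * r_term
    inv_mus = 1.0 / mus
    nl_top = (n_layers - 1) * dz  # top of the semi-infinite bottom layer
    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        path = 0.0
        for j in range(n_layers):
            lbuf[j] = 0.0
        alive = True
        exited = False
        while alive:
            # xorshift64* draw for the step length
            rng ^= rng >> np.uint64(12)
            rng ^= rng << np.uint64(25)
            rng ^= rng >> np.uint64(27)
            u = (
                np.float64((rng * np.uint64(0x2545F4914F6CDD1D)) >> np.uint64(11))
                + 1.0
            ) * _INV_2_53
            s = -np.log(u) * inv_mus
            while s > 0.0:
                if uz < 0.0 and z + uz * s < 0.0:
                    # segment reaches the top surface: accumulate z -> 0
                    s1 = -z / uz
                    if s1 > 0.0:
                        zc = z
                        remaining = s1
                        while True:
                            li = int(np.ceil(zc / dz)) - 1
                            if li <= 0:
                                # the rest of the segment lies in the top layer
                                lbuf[0] += remaining
                                break
                            elif li > n_layers - 1:
                                li = n_layers - 1
                            db = (li * dz - zc) / uz
                            if db >= remaining:
                                lbuf[li] += remaining
                                break
                            lbuf[li] += db
                            zc = li * dz - 1e-12
                            remaining -= db
                        x += ux * s1
                        y += uy * s1
                        path += s1
                    z = 0.0
                    s -= s1
                    cos_i = -uz
                    # unpolarized Fresnel at the tissue/air interface
                    if cos_i >= 0.999999:
                        rr = (n_rel - 1.0) / (n_rel + 1.0)
                        refl = rr * rr
                    elif cos_i <= crit_cos:
                        refl = 1.0
                    else:
                        sin_i = np.sqrt(1.0 - cos_i * cos_i)
                        sin_t = n_rel * sin_i
                        if sin_t >= 1.0:
                            refl = 1.0
                        else:
                            cos_t2 = np.sqrt(1.0 - sin_t * sin_t)
                            rs = (n_rel * cos_i - cos_t2) / (n_rel * cos_i + cos_t2)
                            rp = (cos_i - n_rel * cos_t2) / (cos_i + n_rel * cos_t2)
                            refl = 0.5 * (rs * rs + rp * rp)
                    rng ^= rng >> np.uint64(12)
                    rng ^= rng << np.uint64(25)
                    rng ^= rng >> np.uint64(27)
                    u = (
                        np.float64(
                            (rng * np.uint64(0x2545F4914F6CDD1D)) >> np.uint64(11)
                        )
                        + 1.0
                    ) * _INV_2_53
                    if u < refl:
                        uz = -uz  # internal reflection, continue the step
                    else:
                        exited = True
                        alive = False
                        s = 0.0
                else:
                    z_end = z + uz * s
                    if z >= nl_top and z_end >= nl_top:
                        lbuf[n_layers - 1] += s
                    else:
                        li0 = int(z / dz)
                        li1 = int(z_end / dz)
                        if li0 == li1:
                            lbuf[li0] += s
                        elif uz > 0.0:
                            zc = z
                            remaining = s
                            while True:
                                li = int(zc / dz)
                                if li >= n_layers - 1:
                                    lbuf[n_layers - 1] += remaining
                                    break
                                db = ((li + 1) * dz - zc) / uz
                                if db >= remaining:
                                    lbuf[li] += remaining
                                    break
                                lbuf[li] += db
                                zc = (li + 1) * dz + 1e-12
                                remaining -= db
                        else:
                            zc = z
                            remaining = s
                            while True:
                                li = int(np.ceil(zc / dz)) - 1
                                if li <= 0:
                                    # segment ends inside the top layer
                                    lbuf[0] += remaining
                                    break
                                elif li > n_layers - 1:
                                    li = n_layers - 1
                                db = (li * dz - zc) / uz
                                if db >= remaining:
                                    lbuf[li] += remaining
                                    break
                                lbuf[li] += db
                                zc = li * dz - 1e-12
                                remaining -= db
                    x += ux * s
                    y += uy * s
                    z = z_end
                    path += s
                    s = 0.0
            if not alive:
                break
            if z >= z_max or x * x + y * y >= r_term2 or path >= max_path:
                alive = False
                break
            # Henyey-Greenstein deflection
            rng ^= rng >> np.uint64(12)
            rng ^= rng << np.uint64(25)
            rng ^= rng >> np.uint64(27)
            u = (
                np.float64((rng * np.uint64(0x2545F4914F6CDD1D)) >> np.uint64(11))
                + 1.0
            ) * _INV_2_53
            if g != 0.0:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
                cos_t = (1.0 + g * g - tmp * tmp) / (2.0 * g)
            else:
                cos_t = 2.0 * u - 1.0
            if cos_t > 1.0:
                cos_t = 1.0
            elif cos_t < -1.0:
                cos_t = -1.0
            sin_t = np.sqrt(1.0 - cos_t * cos_t)
            # azimuth without trig: rejection-sample a point in the unit disk
            while True:
                rng ^= rng >> np.uint64(12)
                rng ^= rng << np.uint64(25)
                rng ^= rng >> np.uint64(27)
                a = (
                    np.float64((rng * np.uint64(0x2545F4914F6CDD1D)) >> np.uint64(11))
                    + 1.0
                ) * _INV_2_53 * 2.0 - 1.0
                rng ^= rng >> np.uint64(12)
                rng ^= rng << np.uint64(25)
                rng ^= rng >> np.uint64(27)
                b = (
                    np.float64((rng * np.uint64(0x2545F4914F6CDD1D)) >> np.uint64(11))
                    + 1.0
                ) * _INV_2_53 * 2.0 - 1.0
                d2 = a * a + b * b
                if 1e-12 < d2 <= 1.0:
                    break
            cp = (a * a - b * b) / d2
            sp = 2.0 * a * b / d2
            if uz > 0.99999 or uz < -0.99999:
                ux = sin_t * cp
                uy = sin_t * sp
                uz = cos_t if uz > 0.0 else -cos_t
            else:
                den = np.sqrt(1.0 - uz * uz)
                uxn = sin_t * (ux * uz * cp - uy * sp) / den + ux * cos_t
                uyn = sin_t * (uy * uz * cp + ux * sp) / den + uy * cos_t
                uzn = -sin_t * cp * den + uz * cos_t
                ux = uxn
                uy = uyn
                uz = uzn
                if uz > 1.0:
                    uz = 1.0
                elif uz < -1.0:
                    uz = -1.0
        if exited and path <= max_path:
            r = np.sqrt(x * x + y * y)
            if keep_rmin <= r <= keep_rmax:
                out_path[n_kept] = path
                out_r[n_kept] = r
                for j in range(n_layers):
                    out_L[n_kept, j] = lbuf[j]
                n_kept += 1
    return n_kept
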