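"""Numba-compiled photon-packet transport kernel.

Mirrors, operation for operation, the pure-Python reference loop in
:mod:`ppgmc.reference` and the stream contract of :mod:`ppgmc.rng`; the
equivalence of the two is pinned by tests.  All distances are mm, z grows
into the tissue (tissue surface at z = 0, sensor plane at z = -d).

Per-photon life cycle:

* launch in the gap at z = -d on the Gaussian beam profile, heading (0,0,1);
* gap flights are straight lines (non-attenuating ambient);
* at the tissue surface and at layer interfaces an unpolarized Fresnel
  coin-flip chooses reflection or refraction (one uniform per encounter);
* in tissue, dimensionless step lengths -ln(xi) are consumed against the
  local mu_t, with the remainder carried across layer interfaces;
* each interaction deposits w*mu_a/mu_t and redraws the direction from the
  Henyey-Greenstein phase function;
* sub-threshold weights play Russian roulette;
* upward crossings of the sensor plane are detected inside the aperture,
  specularly reflected inside the sensor face (non-contact only), and lost
  otherwise.  Reflections off the tissue surface from the gap side, after
  the photon has exited the tissue at least once, increment the air-bounce
  counter N_air.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_U64 = np.uint64
_GAMMA = _U64(0x9E3779B97F4A7C15)
_STREAM_SALT = _U64(0xD1B54A32D192ED03)
_M1 = _U64(0xBF58476D1CE4E5B9)
_M2 = _U64(0x94D049BB133111EB)
_ONE = _U64(1)
_INV53 = 2.0**-53

# terminal states
ALIVE = 0
DETECTED = 1
ESCAPED = 2
ROULETTED = 3
DISCARDED = 4


@njit(inline="always")
def _mix64(z):
    z = (z ^ (z >> _U64(30))) * _M1
    z = (z ^ (z >> _U64(27))) * _M2
    return z ^ (z >> _U64(31))


@njit(inline="always")
def _stream_state(seed, idx):
    a = _mix64((seed + _ONE) * _GAMMA)
    b = _mix64((idx + _ONE) * _STREAM_SALT)
    return a ^ b


@njit(inline="always")
def _next_u(state):
    state = state + _GAMMA
    u = float(_mix64(state) >> _U64(11)) * _INV53
    if u == 0.0:
        u = _INV53
    return u, state


@njit(inline="always")
def _fresnel(n1, n2, cos_i):
    if n1 == n2:
        return 0.0
    sin_i2 = 1.0 - cos_i * cos_i
    if sin_i2 < 0.0:
        sin_i2 = 0.0
    sin_t = n1 * np.sqrt(sin_i2) / n2
    if sin_t >= 1.0:
        return 1.0
    cos_t = np.sqrt(1.0 - sin_t * sin_t)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(inline="always")
def _hg_cos(g, xi):
    if np.abs(g) < 1e-6:
        return 2.0 * xi - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    c = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(inline="always")
def _rotate(ux, uy, uz, cos_t, phi):
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cos_p = np.cos(phi)
    sin_p = np.sin(phi)
    if np.abs(uz) > 0.99999:
        nx = sin_t * cos_p
        ny = sin_t * sin_p
        nz = cos_t if uz >= 0.0 else -cos_t
    else:
        tmp = np.sqrt(1.0 - uz * uz)
        nx = sin_t * (ux * uz * cos_p - uy * sin_p) / tmp + ux * cos_t
        ny = sin_t * (uy * uz * cos_p + ux * sin_p) / tmp + uy * cos_t
        nz = -sin_t * cos_p * tmp + uz * cos_t
    return nx, ny, nz


@njit
def run_photons(
    seed,
    start_index,
    max_photons,
    # tissue stack
    mu_a,
    mu_s,
    g_arr,
    n_arr,
    z_top,
    z_bot,
    ambient_n,
    # geometry
    d_sep,
    beam_b,
    sd_sep,
    aperture_r,
    face_r,
    face_mirror,
    world_r,
    # transport config
    roul_threshold,
    roul_survival,
    max_interactions,
    # detected-photon output buffers (capacity bounds this call)
    out_w,
    out_depth,
    out_nair,
    ndet_start,
    ndet_target,
    # optional interaction-site recording
    record_sites,
    site_x,
    site_y,
    site_z,
    nsites_start,
):
    """Propagate up to ``max_photons`` packets; fill detection buffers.

    Returns ``(n_launched, n_detected_total, n_sites_total, absorbed,
    escaped, detected_w, roulette_killed, roulette_added, discarded)``.
    The call stops early once ``ndet_target`` detections are banked or the
    output buffers are full.
    """
    nlayer = mu_a.shape[0]
    ndet = ndet_start
    nsites = nsites_start
    cap = out_w.shape[0]
    site_cap = site_x.shape[0]

    absorbed = 0.0
    escaped = 0.0
    detected_w = 0.0
    roul_killed = 0.0
    roul_added = 0.0
    discarded = 0.0

    n_launched = 0
    for i in range(max_photons):
        if ndet >= ndet_target or ndet >= cap:
            break
        n_launched += 1
        state = _stream_state(_U64(seed), _U64(start_index + i))

        # --- launch: Gaussian beam, perpendicular incidence, in the gap ---
        xi, state = _next_u(state)
        r = beam_b * np.sqrt(-np.log(xi) / 2.0)
        xi, state = _next_u(state)
        phi = 2.0 * np.pi * xi
        x = r * np.cos(phi)
        y = r * np.sin(phi)
        z = -d_sep
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        layer = -1  # gap
        max_depth = 0.0
        nair = 0
        has_exited = False
        n_inter = 0
        local_abs = 0.0
        status = ALIVE

        while status == ALIVE:
            if layer < 0:
                # ---------------- gap flight (straight, lossless) ----------
                if uz > 0.0:
                    t = (0.0 - z) / uz
                    x += ux * t
                    y += uy * t
                    z = 0.0
                    if x * x + y * y > world_r * world_r:
                        status = ESCAPED
                        escaped += w
                        continue
                    cos_i = uz
                    rf = _fresnel(ambient_n, n_arr[0], cos_i)
                    xi, state = _next_u(state)
                    if xi < rf:
                        uz = -uz
                        if has_exited:
                            nair += 1
                        n_inter += 1
                        if n_inter > max_interactions:
                            status = DISCARDED
                            discarded += w
                    else:
                        ratio = ambient_n / n_arr[0]
                        sin_t2 = ratio * ratio * (1.0 - cos_i * cos_i)
                        cos_t = np.sqrt(max(0.0, 1.0 - sin_t2))
                        ux *= ratio
                        uy *= ratio
                        uz = cos_t
                        layer = 0
                elif uz < 0.0:
                    t = (-d_sep - z) / uz
                    xc = x + ux * t
                    yc = y + uy * t
                    dx = xc - sd_sep
                    rr = dx * dx + yc * yc
                    if rr <= aperture_r * aperture_r:
                        status = DETECTED
                        detected_w += w
                        out_w[ndet] = w
                        out_depth[ndet] = max_depth
                        out_nair[ndet] = nair
                        ndet += 1
                    elif d_sep > 0.0 and face_mirror and rr <= face_r * face_r:
                        x = xc
                        y = yc
                        z = -d_sep
                        uz = -uz
                    else:
                        status = ESCAPED
                        escaped += w
                else:
                    status = ESCAPED
                    escaped += w
            else:
                # ---------------- tissue flight ----------------------------
                xi, state = _next_u(state)
                s = -np.log(xi)  # dimensionless step
                while s > 0.0 and status == ALIVE:
                    mt = mu_a[layer] + mu_s[layer]
                    step = s / mt
                    if uz > 0.0:
                        db = (z_bot[layer] - z) / uz
                        nxt = layer + 1
                    elif uz < 0.0:
                        db = (z_top[layer] - z) / uz
                        nxt = layer - 1
                    else:
                        db = 1e30
                        nxt = layer
                    if step < db:
                        x += ux * step
                        y += uy * step
                        z += uz * step
                        if z > max_depth:
                            max_depth = z
                        s = 0.0
                        # ------------- interaction: absorb + scatter -------
                        n_inter += 1
                        if n_inter > max_interactions:
                            status = DISCARDED
                            discarded += w
                            break
                        dw = w * mu_a[layer] / mt
                        local_abs += dw
                        w -= dw
                        if w <= 0.0:
                            # fully deposited (pure absorber): nothing left
                            status = ROULETTED
                            break
                        if record_sites and nsites < site_cap:
                            site_x[nsites] = x
                            site_y[nsites] = y
                            site_z[nsites] = z
                            nsites += 1
                        xi, state = _next_u(state)
                        cos_t = _hg_cos(g_arr[layer], xi)
                        xi, state = _next_u(state)
                        phi = 2.0 * np.pi * xi
                        ux, uy, uz = _rotate(ux, uy, uz, cos_t, phi)
                        if w < roul_threshold:
                            xi, state = _next_u(state)
                            if xi < roul_survival:
                                wn = w / roul_survival
                                roul_added += wn - w
                                w = wn
                            else:
                                roul_killed += w
                                status = ROULETTED
                    else:
                        # ------------- boundary hit ------------------------
                        x += ux * db
                        y += uy * db
                        z = z_bot[layer] if uz > 0.0 else z_top[layer]
                        if z > max_depth:
                            max_depth = z
                        s -= db * mt
                        if x * x + y * y > world_r * world_r:
                            status = ESCAPED
                            escaped += w
                            break
                        n2 = ambient_n if (nxt < 0 or nxt >= nlayer) else n_arr[nxt]
                        cos_i = np.abs(uz)
                        rf = _fresnel(n_arr[layer], n2, cos_i)
                        xi, state = _next_u(state)
                        if xi < rf:
                            uz = -uz
                        else:
                            ratio = n_arr[layer] / n2
                            sin_t2 = ratio * ratio * (1.0 - cos_i * cos_i)
                            cos_t = np.sqrt(max(0.0, 1.0 - sin_t2))
                            ux *= ratio
                            uy *= ratio
                            uz = cos_t if uz > 0.0 else -cos_t
                            if nxt < 0:
                                layer = -1
                                has_exited = True
                                s = 0.0  # fresh step on any re-entry
                            elif nxt >= nlayer:
                                # transmitted through the deepest boundary
                                status = ESCAPED
                                escaped += w
                            else:
                                layer = nxt

        absorbed += local_abs

    return (
        n_launched,
        ndet,
        nsites,
        absorbed,
        escaped,
        detected_w,
        roul_killed,
        roul_added,
        discarded,
    )
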