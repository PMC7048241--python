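"""Scalar single-photon physics primitives.

Pure-Python building blocks of the transport step: exponential step
sampling, Henyey-Greenstein deflection, direction-cosine rotation,
unpolarized Fresnel reflectance, weight deposition and Russian roulette.
These are the operations the compiled kernel inlines; they are exposed here
for unit testing, for the naive reference loop, and for reuse.
"""

from __future__ import annotations

import math

__all__ = [
    "sample_step",
    "sample_hg_deflection",
    "rotate_direction",
    "fresnel_reflectance",
    "refract_direction",
    "absorb_fraction",
    "sample_beam_radius",
    "roulette_weight",
]


def sample_step(mu_t: float, xi: float) -> float:
    """Free path length -ln(xi)/mu_t (mm) for total interaction coefficient mu_t."""
    if mu_t <= 0:
        raise ValueError("mu_t must be positive")
    if not 0.0 < xi < 1.0:
        raise ValueError("xi must lie strictly in (0, 1)")
    return -math.log(xi) / mu_t


def sample_hg_deflection(g: float, xi: float) -> float:
    """Cosine of the scattering deflection angle, Henyey-Greenstein inverse CDF.

    For |g| below 1e-6 the phase function is treated as isotropic
    (cos theta = 2 xi - 1); the closed-form inverse is singular at g = 0.
    """
    if abs(g) >= 1.0:
        raise ValueError("anisotropy g must lie strictly in (-1, 1)")
    if abs(g) < 1e-6:
        return 2.0 * xi - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    cos_t = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    return min(1.0, max(-1.0, cos_t))


def rotate_direction(
    direction: tuple[float, float, float], cos_theta: float, phi: float
) -> tuple[float, float, float]:
    """Deflect a unit direction by (theta, phi) in its local frame.

    Standard direction-cosine update with the special-case formula when the
    photon travels near-parallel to the z axis (|uz| > 0.99999).
    """
    ux, uy, uz = direction
    sin_t = math.sqrt(max(0.0, 1.0 - cos_theta * cos_theta))
    cos_p = math.cos(phi)
    sin_p = math.sin(phi)
    if abs(uz) > 0.99999:
        return (
            sin_t * cos_p,
            sin_t * sin_p,
            cos_theta if uz >= 0.0 else -cos_theta,
        )
    tmp = math.sqrt(1.0 - uz * uz)
    return (
        sin_t * (ux * uz * cos_p - uy * sin_p) / tmp + ux * cos_theta,
        sin_t * (uy * uz * cos_p + ux * sin_p) / tmp + uy * cos_theta,
        -sin_t * cos_p * tmp + uz * cos_theta,
    )


def fresnel_reflectance(n_from: float, n_to: float, cos_incident: float) -> float:
    """Unpolarized Fresnel reflectance for incidence cosine ``cos_incident``.

    Returns 1.0 beyond the critical angle (total internal reflection) and
    0.0 across a matched boundary.
    """
    if n_from == n_to:
        return 0.0
    sin_i2 = max(0.0, 1.0 - cos_incident * cos_incident)
    sin_t = n_from * math.sqrt(sin_i2) / n_to
    if sin_t >= 1.0:
        return 1.0
    cos_t = math.sqrt(1.0 - sin_t * sin_t)
    rs = (n_from * cos_incident - n_to * cos_t) / (n_from * cos_incident + n_to * cos_t)
    rp = (n_from * cos_t - n_to * cos_incident) / (n_from * cos_t + n_to * cos_incident)
    return 0.5 * (rs * rs + rp * rp)


def refract_direction(
    direction: tuple[float, float, float], n_from: float, n_to: float
) -> tuple[float, float, float]:
    """Refract across a horizontal interface (normal along z), Snell's law."""
    ux, uy, uz = direction
    ratio = n_from / n_to
    sin_t2 = ratio * ratio * (1.0 - uz * uz)
    cos_t = math.sqrt(max(0.0, 1.0 - sin_t2))
    return (ux * ratio, uy * ratio, cos_t if uz > 0.0 else -cos_t)


def absorb_fraction(weight: float, mu_a: float, mu_s: float) -> float:
    """Weight deposited at an interaction site: w * mu_a / (mu_a + mu_s)."""
    mu_t = mu_a + mu_s
    if mu_t <= 0:
        raise ValueError("mu_a + mu_s must be positive")
    return weight * mu_a / mu_t


def sample_beam_radius(beam_1e2_radius: float, xi: float) -> float:
    """Radial launch offset of a Gaussian beam with 1/e^2 radius b.

    Inverse CDF of the radial density p(r) = (4 r / b^2) exp(-2 r^2 / b^2):
    r = b sqrt(-ln(xi) / 2).
    """
    if beam_1e2_radius <= 0:
        raise ValueError("beam radius must be positive")
    return beam_1e2_radius * math.sqrt(-math.log(xi) / 2.0)


def roulette_weight(
    weight: float, threshold: float, survival: float, xi: float
) -> float:
    """Russian roulette: returns the post-roulette weight (0.0 if terminated).

    Weights at or above ``threshold`` pass through unchanged; below it the
    packet survives with probability ``survival`` and is rescaled by
    1/survival, keeping the expected weight unbiased.
    """
    if not 0.0 < survival < 1.0:
        raise ValueError("survival probability must lie in (0, 1)")
    if weight >= threshold:
        return weight
    if xi < survival:
        return weight / survival
    return 0.0
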