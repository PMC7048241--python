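"""Naive one-photon-at-a-time reference transport loop.

A deliberately simple, uncompiled implementation of the same transport
physics as the batched kernel, written over the scalar primitives in
:mod:`ppgmc.physics` and consuming the per-photon random streams of
:mod:`ppgmc.rng` in the documented draw order.  It exists to validate the
compiled engine: given the same seed, both must produce identical launched
counts, detected photons and ledgers.  It is orders of magnitude slower and
meant for small photon numbers only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import physics
from .optics import BloodOpticalProperties, PerfusionState, TissueModel, resolve_layer_properties
from .rng import PhotonStream
from .transport import RawResult, SensorGeometry, TransportConfig

__all__ = ["PhotonPacket", "trace_photon", "run_reference"]

GAP = -1


@dataclass
class PhotonPacket:
    """Mutable state of one photon packet during its life."""

    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    ux: float = 0.0
    uy: float = 0.0
    uz: float = 1.0
    weight: float = 1.0
    layer: int = GAP
    max_depth: float = 0.0
    n_air_reflections: int = 0
    has_exited: bool = False
    n_interactions: int = 0
    status: str = "alive"  # alive | detected | escaped | rouletted | discarded

    def direction_norm(self) -> float:
        return math.sqrt(self.ux**2 + self.uy**2 + self.uz**2)


@dataclass
class _Ledger:
    absorbed: float = 0.0
    escaped: float = 0.0
    detected: float = 0.0
    roulette_killed: float = 0.0
    roulette_added: float = 0.0
    discarded: float = 0.0


def trace_photon(
    stream: PhotonStream,
    layers,  # list[OpticalProperties]
    z_top: list[float],
    z_bot: list[float],
    geometry: SensorGeometry,
    config: TransportConfig,
    ledger: _Ledger,
) -> PhotonPacket:
    """Propagate one packet from launch to a terminal state."""
    d = geometry.tissue_separation
    p = PhotonPacket(z=-d)

    r = physics.sample_beam_radius(geometry.beam_1e2_radius, stream.uniform())
    phi = 2.0 * math.pi * stream.uniform()
    p.x = r * math.cos(phi)
    p.y = r * math.sin(phi)

    while p.status == "alive":
        if p.layer == GAP:
            _gap_event(p, stream, layers, geometry, config, ledger)
        else:
            _tissue_flight(p, stream, layers, z_top, z_bot, geometry, config, ledger)
    return p


def _gap_event(p, stream, layers, geometry, config, ledger) -> None:
    d = geometry.tissue_separation
    if p.uz > 0.0:  # heading for the tissue surface
        t = (0.0 - p.z) / p.uz
        p.x += p.ux * t
        p.y += p.uy * t
        p.z = 0.0
        if p.x**2 + p.y**2 > geometry.world_radius**2:
            p.status = "escaped"
            ledger.escaped += p.weight
            return
        refl = physics.fresnel_reflectance(geometry.ambient_n, layers[0].n, p.uz)
        if stream.uniform() < refl:
            p.uz = -p.uz
            if p.has_exited:
                p.n_air_reflections += 1
            p.n_interactions += 1
            if p.n_interactions > config.max_interactions:
                p.status = "discarded"
                ledger.discarded += p.weight
        else:
            p.ux, p.uy, p.uz = physics.refract_direction(
                (p.ux, p.uy, p.uz), geometry.ambient_n, layers[0].n
            )
            p.layer = 0
    elif p.uz < 0.0:  # heading for the sensor plane
        t = (-d - p.z) / p.uz
        xc = p.x + p.ux * t
        yc = p.y + p.uy * t
        rr = (xc - geometry.sd_separation) ** 2 + yc**2
        if rr <= geometry.aperture_radius**2:
            p.status = "detected"
            ledger.detected += p.weight
        elif d > 0.0 and geometry.face_mirror and rr <= geometry.face_radius**2:
            p.x, p.y, p.z = xc, yc, -d
            p.uz = -p.uz
        else:
            p.status = "escaped"
            ledger.escaped += p.weight
    else:
        p.status = "escaped"
        ledger.escaped += p.weight


def _tissue_flight(p, stream, layers, z_top, z_bot, geometry, config, ledger) -> None:
    s = -math.log(stream.uniform())  # dimensionless step
    while s > 0.0 and p.status == "alive":
        lay = layers[p.layer]
        step = s / lay.mu_t
        if p.uz > 0.0:
            d_bound = (z_bot[p.layer] - p.z) / p.uz
            nxt = p.layer + 1
        elif p.uz < 0.0:
            d_bound = (z_top[p.layer] - p.z) / p.uz
            nxt = p.layer - 1
        else:
            d_bound = math.inf
            nxt = p.layer
        if step < d_bound:
            _advance(p, step)
            s = 0.0
            _interact(p, stream, lay, config, ledger)
        else:
            _advance(p, d_bound)
            p.z = z_bot[p.layer] if p.uz > 0.0 else z_top[p.layer]
            s -= d_bound * lay.mu_t
            if p.x**2 + p.y**2 > geometry.world_radius**2:
                p.status = "escaped"
                ledger.escaped += p.weight
                return
            outside = nxt < 0 or nxt >= len(layers)
            n2 = geometry.ambient_n if outside else layers[nxt].n
            refl = physics.fresnel_reflectance(lay.n, n2, abs(p.uz))
            if stream.uniform() < refl:
                p.uz = -p.uz
            else:
                p.ux, p.uy, p.uz = physics.refract_direction(
                    (p.ux, p.uy, p.uz), lay.n, n2
                )
                if nxt < 0:
                    p.layer = GAP
                    p.has_exited = True
                    return  # fresh step drawn on any re-entry
                if nxt >= len(layers):
                    # transmitted through the deepest boundary: lost below
                    p.status = "escaped"
                    ledger.escaped += p.weight
                    return
                p.layer = nxt


def _advance(p, dist) -> None:
    p.x += p.ux * dist
    p.y += p.uy * dist
    p.z += p.uz * dist
    if p.z > p.max_depth:
        p.max_depth = p.z


def _interact(p, stream, lay, config, ledger) -> None:
    p.n_interactions += 1
    if p.n_interactions > config.max_interactions:
        p.status = "discarded"
        ledger.discarded += p.weight
        return
    dw = physics.absorb_fraction(p.weight, lay.mu_a, lay.mu_s)
    ledger.absorbed += dw
    p.weight -= dw
    if p.weight <= 0.0:  # fully deposited (pure absorber)
        p.status = "rouletted"
        return
    cos_t = physics.sample_hg_deflection(lay.g, stream.uniform())
    phi = 2.0 * math.pi * stream.uniform()
    p.ux, p.uy, p.uz = physics.rotate_direction((p.ux, p.uy, p.uz), cos_t, phi)
    if p.weight < config.roulette_threshold:
        before = p.weight
        after = physics.roulette_weight(
            before, config.roulette_threshold, config.roulette_survival, stream.uniform()
        )
        if after == 0.0:
            ledger.roulette_killed += before
            p.status = "rouletted"
        else:
            ledger.roulette_added += after - before
            p.weight = after


def run_reference(
    model: TissueModel,
    geometry: SensorGeometry,
    perfusion: PerfusionState,
    blood: BloodOpticalProperties,
    wavelength: float,
    config: TransportConfig,
) -> RawResult:
    """Reference counterpart of :func:`ppgmc.transport.run_simulation`."""
    layers = resolve_layer_properties(model, wavelength, perfusion, blood)
    tops = model.interfaces()
    z_top = list(tops)
    last = model.layers[-1].thickness
    z_bot = z_top[1:] + [1e30 if last is None else z_top[-1] + last]

    if config.n_detect_target is not None:
        target = config.n_detect_target
        budget = config.max_launch or 100_000 * target
    else:
        target = None
        budget = config.n_launch_target

    weights: list[float] = []
    depths: list[float] = []
    nairs: list[int] = []
    ledger = _Ledger()
    launched = 0
    while launched < budget and (target is None or len(weights) < target):
        stream = PhotonStream(config.seed, launched)
        p = trace_photon(stream, layers, z_top, z_bot, geometry, config, ledger)
        launched += 1
        if p.status == "detected":
            weights.append(p.weight)
            depths.append(p.max_depth)
            nairs.append(p.n_air_reflections)

    if not weights and target is not None:
        raise RuntimeError(f"reference run: no detections after {launched} launches")

    return RawResult(
        detected_weights=np.asarray(weights, dtype=np.float64),
        detected_max_depths=np.asarray(depths, dtype=np.float64),
        detected_nair=np.asarray(nairs, dtype=np.int64),
        n_incident=launched,
        wavelength=wavelength,
        seed=config.seed,
        tissue_separation=geometry.tissue_separation,
        absorbed_weight=ledger.absorbed,
        escaped_weight=ledger.escaped,
        detected_weight=ledger.detected,
        roulette_killed=ledger.roulette_killed,
        roulette_added=ledger.roulette_added,
        discarded_weight=ledger.discarded,
        perfusion=perfusion,
        geometry=geometry,
    )
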