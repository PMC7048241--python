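"""Photon-packet Monte Carlo runs through the layered model and the air gap.

:func:`run_simulation` launches photon packets until a stopping rule is met
(a target number of detected photons, or a fixed number of launches) and
returns a :class:`RawResult` with per-detected-photon weights, maximum
depths and air-bounce counts, the launched-photon count, and a weight
conservation ledger.  Runs are exactly reproducible given the seed: every
photon owns a counter-based random stream keyed by (seed, photon index).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from ._kernel import run_photons
from .optics import (
    BloodOpticalProperties,
    PerfusionState,
    TissueModel,
    resolve_layer_properties,
)

__all__ = [
    "SensorGeometry",
    "TransportConfig",
    "RawResult",
    "ConvergenceError",
    "run_simulation",
]


class ConvergenceError(RuntimeError):
    """Launch budget exhausted without a single detection."""


@dataclass(frozen=True)
class SensorGeometry:
    """Reflectance sensor geometry.

    ``sd_separation``: source-to-detector centre distance (mm).
    ``beam_1e2_radius``: Gaussian-beam 1/e^2 radius b (mm); the nominal
    1-mm beam diameter gives b = 0.5.
    ``detector_area``: circular detector aperture (mm^2).
    ``tissue_separation``: air gap d between the sensor face and the tissue
    surface (mm); 0 is contact.
    By default every photon crossing the sensor plane outside the detector
    aperture is terminated as escaped.  Setting ``face_mirror=True``
    instead models the sensor face as a specular reflector of radius
    ``face_radius`` centred on the detector (the default radius is the
    half-height of the 6-mm sensor capsule), which recycles near-miss
    photons back toward the tissue in non-contact geometry.
    ``world_radius``: lateral bound beyond which photons are abandoned.
    """

    sd_separation: float = 5.0
    beam_1e2_radius: float = 0.5
    detector_area: float = 0.66
    tissue_separation: float = 0.0
    ambient_n: float = 1.0
    face_radius: float = 3.0
    face_mirror: bool = False
    world_radius: float = 50.0

    def __post_init__(self) -> None:
        if self.sd_separation <= 0:
            raise ValueError("source-detector separation must be > 0")
        if self.beam_1e2_radius <= 0:
            raise ValueError("beam radius must be > 0")
        if self.detector_area <= 0:
            raise ValueError("detector area must be > 0")
        if self.tissue_separation < 0:
            raise ValueError("sensor-tissue separation must be >= 0")
        if self.ambient_n < 1:
            raise ValueError("ambient refractive index must be >= 1")

    @property
    def aperture_radius(self) -> float:
        """Radius (mm) of the circular detector aperture."""
        return math.sqrt(self.detector_area / math.pi)

    def with_separation(self, d: float) -> "SensorGeometry":
        return SensorGeometry(
            sd_separation=self.sd_separation,
            beam_1e2_radius=self.beam_1e2_radius,
            detector_area=self.detector_area,
            tissue_separation=d,
            ambient_n=self.ambient_n,
            face_radius=self.face_radius,
            face_mirror=self.face_mirror,
            world_radius=self.world_radius,
        )


@dataclass
class TransportConfig:
    """Run controls: stopping rule, roulette, caps, seed.

    Exactly one of ``n_detect_target`` / ``n_launch_target`` must be set.
    ``max_launch`` bounds the total number of launches under the detection
    stop rule (default: 1e5 launches per requested detection).
    """

    n_detect_target: int | None = 100_000
    n_launch_target: int | None = None
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1
    max_interactions: int = 1_000_000
    max_launch: int | None = None
    seed: int = 0
    record_interactions: bool = False
    max_recorded_sites: int = 2_000_000

    def __post_init__(self) -> None:
        if (self.n_detect_target is None) == (self.n_launch_target is None):
            raise ValueError(
                "set exactly one stopping rule: n_detect_target or n_launch_target"
            )
        if not 0.0 < self.roulette_survival < 1.0:
            raise ValueError("roulette survival must lie in (0, 1)")
        if self.roulette_threshold <= 0:
            raise ValueError("roulette threshold must be > 0")
        if self.seed < 0 or self.seed >= 2**62:
            raise ValueError("seed must lie in [0, 2**62)")


@dataclass
class RawResult:
    """Per-run raw output and provenance.

    ``detected_*`` arrays are aligned per detected photon; ``n_incident``
    counts every launched packet including discarded ones.  The weight
    ledger satisfies ``detected + absorbed + escaped + roulette_killed +
    discarded - roulette_added == n_incident`` to float precision.
    """

    detected_weights: np.ndarray
    detected_max_depths: np.ndarray
    detected_nair: np.ndarray
    n_incident: int
    wavelength: float
    seed: int
    tissue_separation: float
    absorbed_weight: float
    escaped_weight: float
    detected_weight: float
    roulette_killed: float
    roulette_added: float
    discarded_weight: float
    perfusion: PerfusionState | None = None
    geometry: SensorGeometry | None = None
    interaction_sites: np.ndarray | None = None

    @property
    def n_detected(self) -> int:
        return int(self.detected_weights.shape[0])

    def conservation_residual(self) -> float:
        """Relative closure error of the weight ledger."""
        total = (
            self.detected_weight
            + self.absorbed_weight
            + self.escaped_weight
            + self.roulette_killed
            + self.discarded_weight
            - self.roulette_added
        )
        return abs(total - self.n_incident) / max(self.n_incident, 1)

    # -- persistence ---------------------------------------------------------

    def save_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("detected_weights", data=self.detected_weights)
            f.create_dataset("detected_max_depths", data=self.detected_max_depths)
            f.create_dataset("detected_nair", data=self.detected_nair)
            if self.interaction_sites is not None:
                f.create_dataset("interaction_sites", data=self.interaction_sites)
            f.attrs["n_incident"] = self.n_incident
            f.attrs["wavelength"] = self.wavelength
            f.attrs["seed"] = self.seed
            f.attrs["tissue_separation"] = self.tissue_separation
            for k in (
                "absorbed_weight",
                "escaped_weight",
                "detected_weight",
                "roulette_killed",
                "roulette_added",
                "discarded_weight",
            ):
                f.attrs[k] = getattr(self, k)
            if self.perfusion is not None:
                f.attrs["blood_volume"] = self.perfusion.blood_volume
                f.attrs["sto2"] = self.perfusion.sto2

    @classmethod
    def load_hdf5(cls, path: str | Path) -> "RawResult":
        with h5py.File(path, "r") as f:
            perf = None
            if "blood_volume" in f.attrs:
                perf = PerfusionState(
                    blood_volume=float(f.attrs["blood_volume"]),
                    sto2=float(f.attrs["sto2"]),
                )
            return cls(
                detected_weights=f["detected_weights"][:],
                detected_max_depths=f["detected_max_depths"][:],
                detected_nair=f["detected_nair"][:],
                interaction_sites=(
                    f["interaction_sites"][:] if "interaction_sites" in f else None
                ),
                n_incident=int(f.attrs["n_incident"]),
                wavelength=float(f.attrs["wavelength"]),
                seed=int(f.attrs["seed"]),
                tissue_separation=float(f.attrs["tissue_separation"]),
                absorbed_weight=float(f.attrs["absorbed_weight"]),
                escaped_weight=float(f.attrs["escaped_weight"]),
                detected_weight=float(f.attrs["detected_weight"]),
                roulette_killed=float(f.attrs["roulette_killed"]),
                roulette_added=float(f.attrs["roulette_added"]),
                discarded_weight=float(f.attrs["discarded_weight"]),
                perfusion=perf,
            )


def _layer_arrays(model: TissueModel, props) -> tuple[np.ndarray, ...]:
    nl = len(props)
    mu_a = np.array([p.mu_a for p in props], dtype=np.float64)
    mu_s = np.array([p.mu_s for p in props], dtype=np.float64)
    g = np.array([p.g for p in props], dtype=np.float64)
    n = np.array([p.n for p in props], dtype=np.float64)
    tops = model.interfaces()
    z_top = np.array(tops, dtype=np.float64)
    z_bot = np.empty(nl, dtype=np.float64)
    z_bot[:-1] = z_top[1:]
    last = model.layers[-1].thickness
    z_bot[-1] = 1e30 if last is None else z_top[-1] + last
    return mu_a, mu_s, g, n, z_top, z_bot


def run_simulation(
    model: TissueModel,
    geometry: SensorGeometry,
    perfusion: PerfusionState,
    blood: BloodOpticalProperties,
    wavelength: float,
    config: TransportConfig,
) -> RawResult:
    """Run the transport engine for one configuration.

    Launches photon packets until the stopping rule is satisfied; raises
    :class:`ConvergenceError` if the launch budget is exhausted with zero
    detections.  With a detection target the run may return fewer detected
    photons than requested only when the launch budget runs out first.
    """
    props = resolve_layer_properties(model, wavelength, perfusion, blood)
    mu_a, mu_s, g, n, z_top, z_bot = _layer_arrays(model, props)

    if config.n_detect_target is not None:
        ndet_target = int(config.n_detect_target)
        budget = config.max_launch or 100_000 * ndet_target
        cap = ndet_target
    else:
        ndet_target = 2**62
        budget = int(config.n_launch_target)
        cap = max(1024, budget // 64)

    out_w = np.empty(cap, dtype=np.float64)
    out_depth = np.empty(cap, dtype=np.float64)
    out_nair = np.empty(cap, dtype=np.int64)

    record = bool(config.record_interactions)
    site_cap = int(config.max_recorded_sites) if record else 1
    site_x = np.empty(site_cap, dtype=np.float32)
    site_y = np.empty(site_cap, dtype=np.float32)
    site_z = np.empty(site_cap, dtype=np.float32)

    launched = 0
    ndet = 0
    nsites = 0
    ledger = np.zeros(6, dtype=np.float64)  # abs, esc, det, killed, added, disc

    chunk = 262_144
    while launched < budget and ndet < ndet_target:
        n_this = min(chunk, budget - launched)
        (nl, ndet, nsites, a, e, dw, rk, ra, dd) = run_photons(
            config.seed,
            launched,
            n_this,
            mu_a,
            mu_s,
            g,
            n,
            z_top,
            z_bot,
            geometry.ambient_n,
            geometry.tissue_separation,
            geometry.beam_1e2_radius,
            geometry.sd_separation,
            geometry.aperture_radius,
            geometry.face_radius,
            geometry.face_mirror,
            geometry.world_radius,
            config.roulette_threshold,
            config.roulette_survival,
            config.max_interactions,
            out_w,
            out_depth,
            out_nair,
            ndet,
            ndet_target,
            record,
            site_x,
            site_y,
            site_z,
            nsites,
        )
        launched += nl
        ledger += (a, e, dw, rk, ra, dd)
        if ndet >= out_w.shape[0] and ndet < ndet_target:
            # fixed-launch rule filled the buffers: grow and continue
            grow = out_w.shape[0]
            out_w = np.concatenate([out_w, np.empty(grow)])
            out_depth = np.concatenate([out_depth, np.empty(grow)])
            out_nair = np.concatenate([out_nair, np.empty(grow, dtype=np.int64)])
        # adapt chunking to the observed detection rate
        if config.n_detect_target is not None and ndet > 0:
            per_det = max(launched // max(ndet, 1), 1)
            chunk = int(min(4_000_000, max(262_144, per_det * (ndet_target - ndet) // 4)))

    if ndet == 0 and config.n_detect_target is not None:
        raise ConvergenceError(
            f"no detections after {launched} launches "
            f"(wavelength {wavelength} nm, d = {geometry.tissue_separation} mm)"
        )

    sites = None
    if record:
        sites = np.stack(
            [site_x[:nsites], site_y[:nsites], site_z[:nsites]], axis=1
        ).astype(np.float64)

    return RawResult(
        detected_weights=out_w[:ndet].copy(),
        detected_max_depths=out_depth[:ndet].copy(),
        detected_nair=out_nair[:ndet].copy(),
        n_incident=launched,
        wavelength=wavelength,
        seed=config.seed,
        tissue_separation=geometry.tissue_separation,
        absorbed_weight=float(ledger[0]),
        escaped_weight=float(ledger[1]),
        detected_weight=float(ledger[2]),
        roulette_killed=float(ledger[3]),
        roulette_added=float(ledger[4]),
        discarded_weight=float(ledger[5]),
        perfusion=perfusion,
        geometry=geometry,
        interaction_sites=sites,
    )
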