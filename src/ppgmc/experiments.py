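"""In-silico experiment orchestration.

Two canonical studies of the endocavitary reflectance sensor:

* :func:`separation_sweep` — detected intensity, penetration depth, DIR and
  mean air-bounce count across sensor-tissue separations 0-10 mm at both
  wavelengths, nominal perfusion;
* :func:`perfusion_grid` — the contact-geometry grid of submucosal blood
  volume (2-10% step 2) x oxygen saturation (50-100% step 5), 55
  configurations per wavelength.

Both return tidy result tables (one row per configuration), wavelength-major
with the swept variable ascending, so repeated runs diff cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .observables import summarize
from .optics import BloodOpticalProperties, PerfusionState, TissueModel
from .rng import mix64
from .transport import SensorGeometry, TransportConfig, run_simulation

__all__ = [
    "SweepSpec",
    "DEFAULT_SEPARATIONS_MM",
    "DEFAULT_BLOOD_VOLUMES",
    "DEFAULT_STO2_LEVELS",
    "perfusion_grid_states",
    "separation_sweep",
    "perfusion_grid",
    "pearson_r",
]

DEFAULT_SEPARATIONS_MM: tuple[float, ...] = tuple(float(d) for d in range(11))
DEFAULT_WAVELENGTHS: tuple[float, ...] = (660.0, 880.0)
DEFAULT_BLOOD_VOLUMES: tuple[float, ...] = (0.02, 0.04, 0.06, 0.08, 0.10)
DEFAULT_STO2_LEVELS: tuple[float, ...] = tuple(
    round(0.50 + 0.05 * i, 2) for i in range(11)
)

_COLUMNS = [
    "wavelength",
    "tissue_separation",
    "blood_volume",
    "sto2",
    "seed",
    "intensity",
    "intensity_se",
    "penetration_depth",
    "penetration_depth_se",
    "dir",
    "mean_nair",
    "n_detected",
    "n_incident",
]


@dataclass(frozen=True)
class SweepSpec:
    """Declarative description of a sweep."""

    separations: tuple[float, ...] = DEFAULT_SEPARATIONS_MM
    wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS
    perfusion_states: tuple[PerfusionState, ...] = (PerfusionState(),)
    seeds: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        if not (self.separations and self.wavelengths and self.perfusion_states and self.seeds):
            raise ValueError("sweep lists must be non-empty")
        if any(d < 0 for d in self.separations):
            raise ValueError("separations must be >= 0")


def perfusion_grid_states(
    blood_volumes: tuple[float, ...] = DEFAULT_BLOOD_VOLUMES,
    sto2_levels: tuple[float, ...] = DEFAULT_STO2_LEVELS,
) -> list[PerfusionState]:
    """Enumerate the perfusion grid (V-major, StO2 ascending)."""
    return [
        PerfusionState(blood_volume=v, sto2=s)
        for v in blood_volumes
        for s in sto2_levels
    ]


def derive_seed(base_seed: int, *indices: int) -> int:
    """Stable per-configuration sub-seed below 2**31."""
    h = base_seed & 0xFFFFFFFFFFFFFFFF
    for ix in indices:
        h = mix64(h ^ mix64(ix + 0x9E37))
    return int(h % (2**31))


def _run_row(model, geometry, perfusion, blood, wavelength, config) -> dict:
    raw = run_simulation(model, geometry, perfusion, blood, wavelength, config)
    s = summarize(raw)
    row = s.to_dict()
    row["blood_volume"] = perfusion.blood_volume
    row["sto2"] = perfusion.sto2
    row["seed"] = config.seed
    return row


def separation_sweep(
    model: TissueModel,
    geometry: SensorGeometry,
    blood: BloodOpticalProperties,
    config: TransportConfig,
    separations: tuple[float, ...] = DEFAULT_SEPARATIONS_MM,
    wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS,
    perfusion: PerfusionState | None = None,
) -> pd.DataFrame:
    """Sweep the sensor-tissue separation at nominal perfusion.

    Returns one row per (wavelength, separation), wavelength-major with
    separation ascending.  Each configuration gets a stable sub-seed derived
    from ``config.seed``.
    """
    perfusion = perfusion or PerfusionState()
    rows = []
    for iw, wl in enumerate(wavelengths):
        for id_, d in enumerate(sorted(separations)):
            cfg = replace(config, seed=derive_seed(config.seed, 1, iw, id_))
            rows.append(
                _run_row(model, geometry.with_separation(d), perfusion, blood, wl, cfg)
            )
    return pd.DataFrame(rows)[_COLUMNS]


def perfusion_grid(
    model: TissueModel,
    geometry: SensorGeometry,
    blood: BloodOpticalProperties,
    config: TransportConfig,
    blood_volumes: tuple[float, ...] = DEFAULT_BLOOD_VOLUMES,
    sto2_levels: tuple[float, ...] = DEFAULT_STO2_LEVELS,
    wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS,
) -> pd.DataFrame:
    """Contact-geometry grid over submucosal blood volume and StO2.

    With the defaults: 5 volumes x 11 saturations = 55 configurations per
    wavelength, 110 rows total, wavelength-major, V-major, StO2 ascending.
    """
    if geometry.tissue_separation != 0.0:
        raise ValueError("the perfusion grid is a contact-geometry experiment")
    states = perfusion_grid_states(tuple(blood_volumes), tuple(sto2_levels))
    rows = []
    for iw, wl in enumerate(wavelengths):
        for ip, state in enumerate(states):
            cfg = replace(config, seed=derive_seed(config.seed, 2, iw, ip))
            rows.append(_run_row(model, geometry, state, blood, wl, cfg))
    return pd.DataFrame(rows)[_COLUMNS]


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation coefficient.

    Used to compare the simulated DIR profile against an experimentally
    measured signal-to-noise series over the same separations.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(stats.pearsonr(x, y).statistic)
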