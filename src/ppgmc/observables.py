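"""Summary quantities of a transport run.

Detected intensity I is the mean weight of detected photons; penetration
depth D the mean of their per-photon maximum z coordinates; DIR the ratio
of detected to incident (launched) photon counts.  Interaction maps bin
recorded interaction sites onto a voxel grid for banana-path visualization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .transport import RawResult

__all__ = [
    "SimulationSummary",
    "InteractionMap",
    "detected_intensity",
    "penetration_depth",
    "compute_dir",
    "summarize",
    "build_interaction_map",
    "convergence_rate",
]


def convergence_rate(n_iterations: float) -> float:
    """Monte Carlo convergence metric 1/sqrt(Q) for Q iterations.

    The statistical error of a Monte Carlo estimate scales with the inverse
    square root of the number of simulated photons; 1e8 iterations give a
    convergence rate of 1e-4.
    """
    if n_iterations <= 0:
        raise ValueError("iteration count must be positive")
    return 1.0 / math.sqrt(n_iterations)


def detected_intensity(detected_weights: np.ndarray) -> float:
    """Mean weight of all detected photons (dimensionless)."""
    w = np.asarray(detected_weights, dtype=np.float64)
    if w.size == 0:
        raise ValueError("detected intensity is undefined with zero detections")
    return float(w.mean())


def penetration_depth(detected_max_depths: np.ndarray) -> float:
    """Mean of the per-photon maximum z coordinates of detected photons (mm)."""
    z = np.asarray(detected_max_depths, dtype=np.float64)
    if z.size == 0:
        raise ValueError("penetration depth is undefined with zero detections")
    return float(z.mean())


def compute_dir(n_detected: int, n_incident: int) -> float:
    """Detected-to-incident photon ratio Ndet/Ninc."""
    if n_incident <= 0:
        raise ValueError("incident photon count must be positive")
    if not 0 <= n_detected <= n_incident:
        raise ValueError("need 0 <= n_detected <= n_incident")
    return n_detected / n_incident


@dataclass(frozen=True)
class SimulationSummary:
    """Headline quantities of one run with standard errors.

    When ``n_detected`` is zero, ``dir`` is 0 and the remaining statistics
    are NaN (flagged undefined).
    """

    intensity: float
    intensity_se: float
    penetration_depth: float
    penetration_depth_se: float
    dir: float
    mean_nair: float
    n_detected: int
    n_incident: int
    wavelength: float
    tissue_separation: float

    def to_dict(self) -> dict:
        return {
            "wavelength": self.wavelength,
            "tissue_separation": self.tissue_separation,
            "intensity": self.intensity,
            "intensity_se": self.intensity_se,
            "penetration_depth": self.penetration_depth,
            "penetration_depth_se": self.penetration_depth_se,
            "dir": self.dir,
            "mean_nair": self.mean_nair,
            "n_detected": self.n_detected,
            "n_incident": self.n_incident,
        }


def _se(x: np.ndarray) -> float:
    if x.size < 2:
        return float("nan")
    return float(x.std(ddof=1) / math.sqrt(x.size))


def summarize(raw: RawResult) -> SimulationSummary:
    """Reduce a :class:`RawResult` to its summary statistics."""
    ndet = raw.n_detected
    if ndet == 0:
        return SimulationSummary(
            intensity=float("nan"),
            intensity_se=float("nan"),
            penetration_depth=float("nan"),
            penetration_depth_se=float("nan"),
            dir=0.0,
            mean_nair=float("nan"),
            n_detected=0,
            n_incident=raw.n_incident,
            wavelength=raw.wavelength,
            tissue_separation=raw.tissue_separation,
        )
    w = raw.detected_weights
    z = raw.detected_max_depths
    return SimulationSummary(
        intensity=detected_intensity(w),
        intensity_se=_se(w),
        penetration_depth=penetration_depth(z),
        penetration_depth_se=_se(z),
        dir=compute_dir(ndet, raw.n_incident),
        mean_nair=float(raw.detected_nair.mean()),
        n_detected=ndet,
        n_incident=raw.n_incident,
        wavelength=raw.wavelength,
        tissue_separation=raw.tissue_separation,
    )


@dataclass
class InteractionMap:
    """Voxelized counts of photon-tissue interaction sites."""

    grid: np.ndarray  # (nx, ny, nz) int64 counts
    voxel_size: float  # mm
    origin: tuple[float, float, float]  # mm offset of grid[0,0,0] corner

    @property
    def total_count(self) -> int:
        return int(self.grid.sum())

    def project_xz(self) -> np.ndarray:
        """Sum over y: the banana-path view in the xz plane."""
        return self.grid.sum(axis=1)


def build_interaction_map(
    sites: np.ndarray | None,
    voxel_size: float = 0.1,
    bounds: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]
    | None = None,
) -> InteractionMap:
    """Bin interaction sites (N, 3) into an :class:`InteractionMap`.

    ``bounds`` are ((xmin, xmax), (ymin, ymax), (zmin, zmax)) in mm; by
    default they hug the recorded sites.  Raises if recording was disabled.
    """
    if sites is None:
        raise ValueError(
            "no interaction sites recorded; run with record_interactions=True"
        )
    if voxel_size <= 0:
        raise ValueError("voxel size must be positive")
    pts = np.asarray(sites, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("sites must have shape (N, 3)")
    if bounds is None:
        lo = pts.min(axis=0)
        hi = pts.max(axis=0)
    else:
        lo = np.array([b[0] for b in bounds], dtype=np.float64)
        hi = np.array([b[1] for b in bounds], dtype=np.float64)
    shape = np.maximum(np.ceil((hi - lo) / voxel_size).astype(int), 1)
    idx = np.floor((pts - lo) / voxel_size).astype(int)
    keep = np.all((idx >= 0) & (idx < shape), axis=1)
    # sites exactly on the upper bound fall into the last voxel
    edge = np.all((idx >= 0) & (idx <= shape), axis=1) & ~keep
    idx_edge = np.minimum(idx[edge], shape - 1)
    grid = np.zeros(shape, dtype=np.int64)
    np.add.at(grid, tuple(idx[keep].T), 1)
    if idx_edge.size:
        np.add.at(grid, tuple(idx_edge.T), 1)
    return InteractionMap(grid=grid, voxel_size=voxel_size, origin=tuple(lo))
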