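# Methods

`ppgmc` is a Monte Carlo photon-transport code for reflectance-mode
photoplethysmography (PPG) sensing of layered mucosal tissue, built to
characterize an endocavitary dual-wavelength (660/880 nm) sensor in
contact and non-contact geometry.

## Transport model

Photon packets of initial weight w = 1 are launched perpendicular to the
tissue surface from a Gaussian beam of 1/e² radius b = 0.5 mm (radial
density p(r) ∝ r·exp(−2r²/b²), sampled by inverse CDF as
r = b·√(−ln ξ / 2)).  In tissue, free paths are sampled as l = −ln ξ / μt
with μt = μa + μs; a dimensionless remainder is carried across layer
interfaces (MCML convention).  Each interaction deposits Δw = (μa/μt)·w
and redraws the direction from the Henyey–Greenstein phase function with
the layer anisotropy g (closed-form inverse CDF; isotropic fallback for
|g| < 1e−6, where the closed form is singular), with uniform azimuth.
Interfaces (layer/layer, tissue/air) apply unpolarized Fresnel
reflectance with a single uniform per encounter (reflect if ξ < R; total
internal reflection gives R = 1), and Snell refraction otherwise.
Packets below a weight threshold play Russian roulette (threshold 1e−4,
survival 0.1 — standard MCML values), keeping the expected weight
unbiased.  A packet whose weight reaches exactly zero (pure absorber) is
terminated with its weight fully deposited.

Coordinates: z = 0 at the tissue surface, +z into the tissue; the sensor
plane sits at z = −d for sensor–tissue separation d (d = 0 is contact).
The air gap is lossless and straight-line.  A photon crossing the sensor
plane upward is detected if the crossing point falls inside the circular
detector aperture (area 0.66 mm², centre 5 mm from the beam axis);
otherwise it is terminated as escaped.  Optionally
(`SensorGeometry(face_mirror=True)`) the sensor face is modelled as a
specular disc (default radius 3 mm — the capsule half-height) that
recycles near-miss photons; reflections off the tissue surface from the
gap side, after first tissue exit, increment the per-photon air-bounce
counter N_air.  The default keeps the absorbing sensor plane; see
"Known limitations".

Per run the engine reports: detected intensity I (mean detected weight),
penetration depth D (mean of per-photon maximum z among detected
photons), DIR = Ndet/Ninc, mean N_air, and a weight-conservation ledger
(detected + absorbed + escaped + roulette-killed + discarded −
roulette-boosts = Ninc, closed to float precision; the suite asserts
1e−6 relative).  The Monte Carlo convergence metric is reported as
1/√Q for Q iterations (1e8 iterations → 1e−4).

## Reproducibility and the twin engines

Every photon owns a counter-based SplitMix64 stream keyed by
(run seed, photon index), with a documented draw order (launch radius,
azimuth; step; one uniform per interface encounter; deflection cosine,
azimuth; roulette).  Results are therefore independent of batching, and
the compiled (numba) kernel is validated against a deliberately naive
pure-Python per-photon loop: at 10³ launches both produce identical
launch counts, detected-photon arrays and ledgers.  Sub-seeds for
experiment grids are derived by hashing the base seed with the
configuration indices, so tables are byte-reproducible.

## Tissue model

Three layers (mucosa, submucosa, muscle) with published composite
optical properties at 660/880 nm and per-layer total blood volumes
(8%, 4%, 10%).  Tissue perfusion enters through the submucosal
absorption coefficient,

    μa,sm = (1 − V)·μa,baseline + V·[StO2·μa,HbO + (1 − StO2)·μa,Hb],

linear in blood volume fraction V and total oxygen saturation StO2.  The
tabulated submucosal μa is interpreted as the composite value at the
nominal state (V = 4%, StO2 = 95%), and the bloodless baseline is
back-solved from the mixing rule, so perfusion sweeps pivot around the
nominal state.  Whole-blood absorption at hematocrit 45% ships as a
small CSV (derived from the Prahl/van Assendelft extinction compilation
at 150 g/L hemoglobin: 660 nm — HbO 0.171, Hb 1.728 mm⁻¹; 880 nm — HbO
0.650, Hb 0.395 mm⁻¹) and is overridable.  The 1:5 arteriovenous volume
split of the submucosal pool is carried as metadata only; the static
mixing rule uses a single total StO2.

Layer thicknesses are not part of the published optical table and were
set as follows: mucosa 0.5 mm and submucosa 0.9 mm (anatomy-derived
defaults), and the simulated volume truncated 0.15 mm into the
muscularis (total depth 1.55 mm) with photons crossing the posterior
boundary counted as transmitted losses — the cheek wall is only a few
millimetres thick and deeper structures are outside the model.  The
truncation depth is the calibrated parameter: it was chosen once so that
the mean penetration depth of detected photons at contact and nominal
perfusion matches the reported red-wavelength band (1.45–1.47 mm);
D at 660 nm is 1.46 mm with these defaults.  A semi-infinite muscle
(`muscle_thickness=None`) raises D to ≈2.9 mm and is available for
sensitivity studies.

## Experiments

* Separation sweep: d = 0…10 mm step 1, both wavelengths, nominal
  perfusion (22 configurations).
* Perfusion grid: contact geometry, submucosal V = 2–10% step 2 and
  StO2 = 50–100% step 5 (55 configurations per wavelength, 110 total).

The publication-scale runs detect 1e8 photons per configuration; the
package default stopping rule is 1e5 detections, and the bundled test
suite and acceptance script scale further down (1.5e3–1e4 detections per
configuration) to keep a full run on one CPU in minutes.  Standard
errors are reported per summary so scaled-down runs carry their own
uncertainty; depth-band checks are asserted within 3 standard errors of
the Monte Carlo estimate.

## Design choices where the published description is open

* Beam "diameter 1 mm" is read as the 1/e² diameter (b = 0.5 mm).
* The detector has no angular acceptance cutoff.
* Specular reflection at first tissue entry uses the same Fresnel
  operation as every other interface encounter.
* Photons crossing the sensor plane outside the aperture are terminated
  (absorbing sensor plane); the reflective-face variant exists but is
  off by default (see below).
* Table-value μa are composites at nominal perfusion (back-solved
  baseline), not bloodless baselines.
* The stopping rule counts detections; Ninc is the number of launches
  when the rule fires, and DIR = Ndet/Ninc.

## Known limitations

* **Non-contact trends.**  In this planar escape geometry the detected
  intensity *rises* with separation (the detected set shifts toward
  shallow, high-weight paths exiting near the source) and no detected
  photon can re-approach the tissue from the gap, so mean N_air is
  identically zero without the mirror face.  The reported in-vivo decay
  of signal amplitude with separation, and air-bounce counts growing
  with separation, involve return paths (catheter wall, lumen curvature,
  sensor-face reflections) that a planar slab with an absorbing sensor
  plane cannot represent.  Enabling the mirror face produces nonzero
  N_air but does not reverse either trend.  The DIR-versus-separation
  curve, in contrast, reproduces the reported shape (rise from contact
  to a peak near 2–3 mm, then gradual decay, with DIR(6 mm) ≈
  2 × DIR(1 mm)), though its absolute scale is about half the printed
  values.
* **Wavelength separation of penetration depth.**  With the posterior
  truncation that the red depth band requires, detected-photon maximum
  depths are boundary-limited and the two wavelengths give nearly equal
  D; the model cannot simultaneously satisfy the reported infrared band
  (1.55–1.6 mm).  The calibration favours the (narrower) red band.
* The synthetic studies model static perfusion states only: no pulse
  waveform, no ac/dc decomposition, no polarization, fluorescence,
  time-of-flight, or curved lumen geometry.
* Blood optical properties are a two-wavelength table; arbitrary
  wavelengths require user-supplied coefficients.
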