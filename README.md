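# ppgmc — Monte Carlo photon transport for reflectance PPG sensing

`ppgmc` simulates photon-packet migration through a layered mucosal
tissue model to characterize a reflectance-mode, dual-wavelength
(660/880 nm) photoplethysmography (PPG) sensor — the kind of indwelling
probe used to monitor the perfusion of intestinal or buccal mucosa — in
both contact and non-contact (air-gap) geometry.  It is aimed at
biomedical-optics researchers designing endocavitary PPG/pulse-oximetry
probes who need the standard Monte Carlo observables for sensor layout
decisions before building hardware.

## Model

Photon packets (initial weight w = 1) are launched from a Gaussian beam
(1/e² radius b = 0.5 mm) perpendicular to a three-layer buccal tissue
stack (mucosa / submucosa / muscle, published μa, μs, g, n at 660 and
880 nm).  Transport follows the MCML conventions: step lengths
l = −ln ξ/μt, weight deposition Δw = (μa/μt)·w per interaction,
Henyey–Greenstein scattering, Fresnel/Snell boundary physics, Russian
roulette (threshold 1e−4, survival 0.1).  Perfusion enters through the
submucosal absorption coefficient

μa,sm = (1 − V)·μa,baseline + V·[StO2·μa,HbO + (1 − StO2)·μa,Hb]

with V the submucosal blood volume fraction and StO2 the total oxygen
saturation.  A run reports

* **I** — detected intensity, the mean weight of detected photons,
* **D** — penetration depth, the mean of per-photon maximum depths,
* **DIR** = Ndet/Ninc — detected-to-incident photon ratio,
* **N_air** — air-boundary bounce counts (non-contact),

plus standard errors and a weight-conservation ledger.  A detector of
0.66 mm² sits 5 mm from the source; the sensor-tissue separation d
sweeps 0–10 mm.  See `docs/methods.md` for assumptions, calibration and
limitations.

## Worked example

```python
import ppgmc

model = ppgmc.builtin_buccal_model()
blood = ppgmc.BloodOpticalProperties.default()
geo = ppgmc.SensorGeometry(tissue_separation=0.0)   # contact
cfg = ppgmc.TransportConfig(n_detect_target=4000, seed=29)

raw = ppgmc.run_simulation(model, geo, ppgmc.NOMINAL_PERFUSION, blood, 660.0, cfg)
s = ppgmc.summarize(raw)
print(f"I={s.intensity:.3f}  D={s.penetration_depth:.4f} mm  DIR={s.dir:.2e}")
```

prints (seed 29):

```
I=0.526  D=1.4636 mm  DIR=3.80e-04
```

i.e. at contact and nominal perfusion (V = 4%, StO2 = 95%), detected red
photons keep on average 53% of their launched weight, dive 1.46 mm deep
(into the muscularis), and roughly 1 launch in 2600 is detected.  The
same run at 880 nm gives I = 0.561 and D = 1.4613 mm — infrared returns
brighter from the perfused stack.

The command line mirrors the library:

```bash
ppgmc simulate --wavelength 660 --separation 0 --ndet 4000 --seed 29 --out run
ppgmc sweep-separation --ndet 2000 --seed 1 --out sweep.csv
ppgmc sweep-perfusion  --ndet 2000 --seed 1 --out grid.csv   # 110 rows
ppgmc correlate --dir-csv sweep.csv --snr-csv my_snr.csv --wavelength 660
```

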