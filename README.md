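# cortexmaps

Tools for studying how orientation-preference (OP) and ocular-dominance (OD)
maps in primary visual cortex develop together and how their spatial
relationship changes when the two eyes see systematically different
orientations (cross-rearing with orthogonal cylindrical lenses).  The package
is aimed at researchers modelling cortical feature maps or analysing
intrinsic-signal optical imaging of them.  It provides:

* an annealed **elastic-net simulator** of joint OP/OD development.  The
  cortical sheet `y_j` (128×128, 4-neighbor lattice) embeds a 5-D feature set
  (retinotopy, ocularity ±d, orientation double-angle vector of radius r) by
  minimizing coverage vs continuity,

  `E(Y,K) = −K Σ_i α_i log Σ_j e^{−‖x_i−y_j‖²/2K²} + (β/2) Σ_edges ‖y_j−y_k‖²`,

  annealing K geometrically.  A per-feature coverage weight α > 1 on one
  orientation per eye models biased visual input;
* **map statistics**: pinwheel detection by ±180° winding number, Fourier map
  wavelength Λ, dimensionless pinwheel density (count per pixel × Λ², theory
  predicts π), equal-area OD quintile localization of pinwheels
  (column centre → border), OP/OD contour crossing angles, orientation
  histograms with fixed-period sine fits;
* an **extraction pipeline** for intrinsic-signal imaging stacks (50 frames at
  5 Hz, stimulus frames 11–35): alignment, condition averaging, band-pass
  preprocessing, composition of per-frame OP/OD map stacks, and blind source
  separation by single-shift extended spatial decorrelation (ESD, shift
  Δr = (5,5) px), with a vector-average baseline for comparison;
* **tuning-curve models** for single units: von Mises orientation tuning,
  skewed log-Gaussian spatial/temporal frequency tuning, Naka–Rushton
  contrast response, monocularity index and interocular ΔOP;
* **synthetic-data generators** (maps, imaging stacks with vessel/drift/noise
  artifacts, unit response tables) so every stage can be validated against
  known ground truth without animal data.

See `docs/methods.md` for the models, parameter defaults and limitations.

## Worked example

Simulate a control map, read out its statistics, and compare a cross-reared
simulation with the same seed:

```python
from cortexmaps import elastic_net as en
from cortexmaps import map_stats

cfg = en.SimulationConfig(seed=1)                  # α = 1: control
op, od = en.extract_maps(en.run_simulation(cfg))   # ~2 min on one core

pins = map_stats.detect_pinwheels(op)
lam = map_stats.map_wavelength(op)
rho = map_stats.pinwheel_density(op)
_, props = map_stats.pinwheel_od_histogram(pins, od)
print(f"{len(pins)} pinwheels, wavelength {lam:.1f} px, density {rho:.2f}")
print("OD quintile proportions (centre→border):", props.round(3))

cfg5 = en.SimulationConfig(seed=1, alpha_over=5.0)  # cross-reared
op5, od5 = en.extract_maps(en.run_simulation(cfg5))
_, props5 = map_stats.pinwheel_od_histogram(map_stats.detect_pinwheels(op5), od5)
print("cross-reared centre→border:", props5.round(3))
disp = map_stats.pinwheel_displacement(op, op5, lam)
print(f"matched pinwheel displacement: {disp.mean_displacement:.2f} wavelengths")
```

Output:

```
105 pinwheels, wavelength 22.5 px, density 3.24
OD quintile proportions (centre→border): [0.486 0.21  0.152 0.067 0.086]
cross-reared centre→border: [0.198 0.277 0.277 0.119 0.129]
matched pinwheel displacement: 0.23 wavelengths
```

The control density is close to the theoretical π and control pinwheels
concentrate in the centre-most OD quintile (0.49 vs 0.2 under uniformity);
over-representing one orientation per eye (α = 5) flattens the histogram —
pinwheels move away from OD column centres — and displaces matched pinwheels
by ~0.23 Λ.

The same works from the shell:

```bash
cortexmaps simulate --seed 1 --alpha 1 --out maps.h5
cortexmaps stats --maps maps.h5 --out stats.json
cortexmaps synth units --n 50 --population cross_reared --out units.csv
cortexmaps fit-units --in units.csv --out fits.json
```

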