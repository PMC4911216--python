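# Methods

This note documents the models implemented in `cortexmaps`, the numerical
choices behind them, what the synthetic-data generators do and do not emulate,
and the known limitations.

## Elastic-net model of joint OP/OD development

The cortex is a 128×128 sheet of reference vectors `y_j` in a 5-D feature
space: retinotopic position `(sx, sy)` in the unit square, ocularity
`od ∈ {−d, +d}` and an orientation double-angle vector `(opx, opy)` of radius
`r`.  The training set contains every combination of a 20×20 retinotopic grid,
2 ocularities and `n_op = 6` orientations equally spaced on [0°, 180°) —
4800 feature points `x_i`.  The sheet minimizes, at annealing scale `K`,

```
E(Y, K) = −K Σ_i α_i log Σ_j exp(−‖x_i − y_j‖² / 2K²)
          + (β/2) Σ_{edges (j,k)} ‖y_j − y_k‖²
```

a trade-off between *coverage* of the feature points (each weighted by
`α_i ≥ 1`) and *continuity* of the cortical sheet (4-neighbor lattice, free
boundary).  Biased rearing is modelled by `α_i = α_over > 1` on the
horizontal-orientation features of the left eye and the vertical features of
the right eye; all controls use `α_i = 1`.

Reference parameters: `d = 0.05`, `r = 0.08`, `β = 10`, `K` annealed from 0.2
by ×0.9925 per iteration until `K ≤ 0.0358` (229 iterations), one update per
`K`.

### The annealing step

`elastic_net_step` supports two update rules.

* **implicit** (default): with responsibilities
  `p_ij = exp(−‖x_i−y_j‖²/2K²) / Σ_j' exp(−‖x_i−y_j'‖²/2K²)` frozen, the
  minimizer of the resulting quadratic majorizer solves the sparse SPD system
  `(diag(g) + βK(D−A)) Y' = M` with `g_j = Σ_i α_i p_ij` and
  `M_j = Σ_i α_i p_ij x_i`.  This is an EM-style step: the energy above is
  non-increasing, and it is the update used by the published MATLAB
  elastic-net implementations for cortical maps (one Cholesky-type solve per
  annealing step).
* **explicit**: the gradient-style update
  `y_j ← y_j + s·[Σ_i α_i p_ij (x_i − y_j) + βK L(y)_j]` with step size `s`.
  At the reference parameters the explicit *unit* step is linearly unstable
  (the continuity term alone gives per-step amplification up to
  `|1 − βKλ| ≈ 15` for the highest lattice mode at `K = 0.2`), so it is only
  usable with small `s` on small problems; it is provided because the two
  forms share all closed-form limits (β = 0, single node) and make the update
  convention testable.

Responsibilities are evaluated with log-sum-exp row normalization (`K` shrinks
5.6-fold over a run; naive exponentials underflow).  The production path is a
fused numba kernel that accumulates `g` and `M` without materializing the
4800×16384 responsibility matrix, drops terms below `exp(−16)` of each row
maximum, and uses a range-reduced polynomial `exp` (relative error < 4e-6).
Results are reproducible for a fixed seed and thread count.

### Initialization and symmetry-breaking noise

Retinotopy is initialized as the affine embedding of the lattice in the unit
square; `od/opx/opy` start as zero-mean uniform noise of amplitude 0.005 /
0.008 (≪ `d`, `r`).  Because the feature set is exactly symmetric in `±od` and
in the orientation vectors, the unorganized sheet (`od = op = 0`) is an
invariant manifold of the implicit iteration: at `K ≈ 0.2` responsibilities
are nearly uniform and the first few steps contract the feature components to
round-off, after which nothing can grow when `K` crosses the instability.  The
simulator therefore maintains a small symmetry-breaking noise floor: before
each update, zero-mean uniform jitter of the same amplitude as the
initialization noise is added to the od/op components (seed-controlled, so
fixed-seed comparisons across `α` share the identical jitter sequence).  With
this floor the od/op bifurcations express in the final iterations of the
schedule and the run terminates shortly after the maps have formed, with both
OD signs present and a control pinwheel density close to the theoretical value
π.  The amplitude is configurable (`jitter_od`, `jitter_op`); setting it to
zero reproduces the bare EM iteration.

## Map statistics

* **Pinwheels**: at each interior pixel the preference differences around the
  8-neighbor closed loop are wrapped into (−90°, +90°] and summed; totals of
  ±180° flag the pixel.  8-connected flagged clusters merge into one pinwheel
  at the cluster centre of mass with the winding sign.
* **Wavelength**: the mean-subtracted complex field (zero outside the mask)
  is Fourier transformed; power is summed in annular bins of width `1/L`
  (`L` = min map side, DC excluded, `f ≤ 0.5`), and
  `Λ = Σ P_k (1/f_k) / Σ P_k` — the power-weighted mean wavelength.  For two
  equal-power plane waves at 8 and 12 px this gives 10 px (the mean), not the
  harmonic mean; the choice follows the estimator definition "power-weighted
  mean of 1/f".
* **Pinwheel density**: `ρ = (count / masked pixels) · Λ²`.  For control
  elastic-net maps `ρ` should be near π.
* **OD quintiles**: positive and negative OD pixels are ranked separately by
  |value| and split into five equal-count bins (±1 pixel), pooled so bin 0 is
  the centre-most fifth of both eyes' columns and bin 4 the border fifth.
  Ranking (not value quantiles) guarantees the equal-area property that makes
  the uniform null exactly 0.2 per bin.
* **Crossing angles**: the OD zero contour and the iso-orientation contours at
  0°, 22.5°, …, 157.5° are extracted by marching squares; orientation levels
  are taken on the doubled-angle field (zero contours of `Im(z·e^{−2iθ0})`
  restricted to `Re > 0`) to avoid the 0°/180° wrap.  At each polyline
  intersection the tangent orientations (central differences at ±0.75 px
  arclength) are differenced and folded into [0°, 90°].  For independent maps
  the angle density follows sin(angle).
* **Sine fits**: `A·sin(2π(θ−φ)/P) + C` with fixed period `P` (90° for
  control orientation histograms, 180° for cross-reared) is linear in
  `(A cos, A sin, C)` and solved by least squares; `r²` is the squared
  correlation of data and fit, with the degenerate flat fit reported as
  `A = 0, r² = 0`.
* **Pinwheel matching**: greedy nearest-neighbor with a Λ/2 distance cap,
  same-sign pairs matched first; displacement is reported in Λ units over
  matched pairs together with the unmatched count.

Default analysis mask for experimental-style maps: smoothed selectivity
(σ = 5 px) above its 10th percentile (both configurable); smoothing before
thresholding keeps pinwheel cores — pointwise selectivity minima inside
selective tissue — in the mask while removing genuinely weakly-tuned regions.
Simulated maps use the full grid.

## ESD extraction pipeline

Stacks are 50 frames at 5 Hz per trial with the stimulus during frames 11–35.
The pipeline: optional integer-pixel alignment to a reference frame
(FFT cross-correlation, ±10 px); pooling of opposite drift directions and
trial averaging to 8 orientations × 2 eyes; per-frame band-pass (subtract
σ=20 px Gaussian blur, then σ=2 px blur, then sign reversal so activity is
positive); frame-wise composition of the OP vector components and the OD
difference; and single-shift extended spatial decorrelation per 50-frame map
stack: per-frame centering, PCA whitening of the frame covariance, then
eigendecomposition of the symmetrized spatial cross-covariance at shift
(5, 5) px computed over the valid overlap (no wrap-around).  The source whose
baselined coefficient time series matches a rise-to-plateau template
(zero before stimulus onset, 2 s linear rise, plateau to offset, linear
decay; Pearson `|r| ≥ 0.6`) is the feature map; among sources passing the
threshold the one with the largest template-matched amplitude is selected,
because residual unmixing leakage of a dominant stimulus component gives many
weak sources template-shaped series.  The map is the coefficient-scaled
source averaged over frames 31–35, low-pass filtered at σ = 12 px; the
coefficient×source product is invariant to the per-source sign ambiguity.

Gaussian blurs are edge-normalized (filtered with zero padding and divided by
the filtered indicator), so a constant frame high-passes to exactly zero; the
interior behaviour matches plain zero-padded filtering.

**Applicability.** Single-shift ESD separates sources only where their
spatial autocorrelations *at the chosen shift* differ.  At the recording
scale (24 μm/px) an OP map with ~1 mm columns has shift-(5,5)
autocorrelation ≈ 0.7–0.8, well away from white noise (~0) and from
narrow-vessel or drift patterns; toy maps with wavelengths ≲ 3× the shift
fall into the noise eigenvalue cluster and mix.  Round-trip scores therefore
correlate against the ground truth passed through the pipeline's own linear
filters (`pipeline_filter_reference`), which is the only part of the planted
map the pipeline is asked to recover.

A classical vector-average readout (`vector_average_baseline`) is included as
the comparison baseline; its correlation with planted maps degrades
monotonically as vessel-artifact amplitude grows while the ESD readout is
essentially unaffected — the motivation for using ESD at all.

## Tuning-curve models

* Orientation: von Mises `R(θ) = Rp·exp(k(cos2(θ−θp)−1)) + R0`, fit after
  averaging opposite drift directions; bounded least squares with 8 multi-start
  values of θp (the 180°-periodic likelihood has local minima); bandwidth is
  the numeric FWHM in degrees.  Flat curves are flagged unselective.
* Frequency (spatial and temporal, same code path): skewed log-Gaussian
  `R(f) = Rp·exp(−(log(f/fp)/(k + λ·log(f/fp)))²) + R0`, multi-start over the
  stimulus grid; bandwidth is the numeric FWHM in octaves.
* Contrast: Naka–Rushton `R(c) = Rm·cⁿ/(cⁿ+σⁿ) + R0`; fits with σ beyond the
  maximum tested contrast are flagged non-saturating (such units are excluded
  from population analyses).
* `MI = |RR−RL|/(RR+RL)`; `ΔOP` is the signed right-minus-left preference
  difference wrapped to (−90°, 90°].

All fits use tolerance 1e-10; noiseless synthetic curves are recovered to
optimizer precision.

## Synthetic-data generators

All generators are deterministic given their seed and carry their ground truth.

* **Maps** (`synth_maps`): band-pass filtered Gaussian noise with an annular
  spectrum (relative bandwidth 0.15) — complex for OP, real for OD; defaults
  192 px field and 44 px wavelength, i.e. ~4.6 mm and ~1.05 mm at the
  camera's 24 μm/px, matching cat area 17/18 column spacing.  An optional
  coupling parameter rescales |OD| by the OP selectivity so pinwheels sit
  near OD borders (>0) or centres (<0) for validating the quintile statistic;
  coupling 0 gives independent maps (the null).
* **Stacks** (`synth_stack`): reflectance 1 − gain·amplitude·h(f) with
  amplitude `w_e·(1 + s·cos(2θ − φ))/2`, eye weight
  `w_e = (1 ± tanh(1.5·od))/2`, and `h(f)` a rise-to-plateau kernel (0.6 s
  latency, 2 s rise, plateau to stimulus offset, 2 s exponential decay)
  qualitatively matching the measured intrinsic time course.  Artifacts:
  ~70 μm-wide curvilinear dark vessels (Gaussian-profile random walks) with
  30% white temporal jitter, a slow global illumination drift (random-walk
  time course on a smooth spatial pattern), and white pixel noise, all scaled
  relative to the stimulus-locked signal (defaults: vessel 1×, drift 1×,
  noise 0.1×; 4 trials per condition, chosen for tractable stack sizes —
  the pipeline is linear in trials, so more trials only lowers the
  noise-per-condition).  Not emulated: photon statistics, heartbeat/breathing
  periodicity, cortical curvature, anatomy-realistic vasculature, eye
  movements.  Passing the round trip therefore shows the pipeline recovers
  maps under additive smooth artifacts and white noise, not that it is robust
  to every physiological nuisance.
* **Units** (`synth_units`): preferred orientations drawn from sine-modulated
  densities (period 90° control with cardinal bias; per-eye period 180° for
  cross-rearing, left eye peaked at 0° and right at 90°), tuning parameters
  drawn from physiologically plausible ranges, responses generated from the
  tuning models with multiplicative Gaussian noise, clipped at zero.

## Pipeline and reproducibility

`run_pipeline` executes a stage list (simulate / synth_maps / synth_stack /
extract / stats / synth_units / fit_units) with per-stage seeds spawned from
one master seed, checkpoints intermediates as HDF5/CSV, and writes a sorted
`summary.json`; identical config + seed reproduces identical summaries for
deterministic stages.  The `cortexmaps` CLI is a thin wrapper over these
stages.

## Problem sizes used by the validation suite

Full-size elastic-net runs (128×128, 229 iterations) appear only in the
acceptance-level checks: three control seeds for the density statistic and two
fixed seeds for each of α ∈ {3, 5} — the package's scaled-down version of the
ten-runs-per-condition protocol.  Imaging round trips use one 192² stack per
noise condition; the crossing-angle null pools 20 independent map pairs; the
tuning recovery uses 200 noisy replicates.  Unit tests run on toy instances.

## Known limitations

* The elastic-net update convention (implicit vs explicit, step size, noise
  floor) is a documented choice; published descriptions of the annealed
  elastic net do not fully pin it down.  Different conventions shift the
  bifurcation points in `K`, so map amplitudes at a fixed termination `K`
  are convention-dependent even though the map layouts are comparable.
* Single-shift ESD cannot separate sources with equal shift-lag
  autocorrelation (see Applicability above); the multi-shift and
  frequency-domain variants that relax this are out of scope.
* Crossing-angle tangents are estimated from marching-squares polylines
  without smoothing; on coarse grids individual angles carry a few degrees of
  discretization error (the distributional tests absorb this).
* The displacement statistic caps matches at Λ/2; once maps decorrelate,
  matched displacement saturates near the cap and the unmatched count, not
  the mean, carries the remaining signal.
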