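"""Synthetic ground truth and simulated recordings for pipeline validation.

Three generators, all seed-deterministic and carrying their ground truth:

* ``synth_maps`` — quasi-periodic OP/OD maps, either parametric (band-pass
  filtered Gaussian noise with an annular spectrum, the standard null model
  for cortical map statistics) or from the elastic-net simulator.
* ``synth_stack`` — intrinsic-signal imaging stacks: a stimulus-locked
  reflectance *decrease* whose spatial pattern follows the planted maps and
  whose time course follows a rise-to-plateau hemodynamic kernel, plus
  blood-vessel artifacts (dark curvilinear structures with temporal jitter),
  slow global illumination drift, and white pixel noise.
* ``synth_units`` — single-unit response tables drawn from the von Mises /
  skewed-Gaussian / Naka–Rushton tuning models with orientation preferences
  from sine-modulated population densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.ndimage as ndi

from .esd import EYES, ImagingStack, N_FRAMES, STIM_FRAMES
from .map_stats import ODMap, OPMap
from .tuning import naka_rushton, skewed_gaussian, von_mises

DIRECTIONS = 22.5 * np.arange(16)

SF_GRID = np.array([0.05, 0.1, 0.2, 0.4, 0.8, 1.6])      # cyc/deg
TF_GRID = np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 24.0])  # Hz
CONTRAST_GRID = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 100.0])  # percent


@dataclass
class GroundTruth:
    op: OPMap
    od: ODMap
    provenance: str          # "parametric" or "elastic_net"
    seed: int
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class StackRecipe:
    """Generation parameters for a synthetic imaging stack.

    Timing matches the recording protocol: 50 frames at 5 Hz, stimulus during
    frames 11–35 (5 s starting 2 s after acquisition onset).  Amplitudes are
    relative to the stimulus-locked signal (gain = peak ΔR/R).
    """

    gain: float = 0.01
    trials_per_condition: int = 4
    n_frames: int = N_FRAMES
    frame_rate: float = 5.0
    stim_frames: tuple[int, int] = STIM_FRAMES
    hemo_latency: float = 0.6    # s after stimulus onset
    hemo_rise: float = 2.0       # s to plateau
    hemo_decay_tau: float = 2.0  # s, after stimulus offset
    vessel_count: int = 6
    vessel_amplitude: float = 1.0   # × signal amplitude
    vessel_width: float = 3.0       # px (~70 μm at 24 μm/px surface vessels)
    vessel_jitter: float = 0.3      # temporal modulation, fractional
    drift_amplitude: float = 1.0    # × signal amplitude, low-frequency
    noise_sigma: float = 0.1        # × signal amplitude, white, per pixel/frame
    od_gain: float = 1.5            # eye weight (1 ± tanh(g·od_norm))/2
    include_blank: bool = True


def _bandpass_noise(rng, shape, wavelength, rel_bandwidth=0.15, complex_field=False):
    H, W = shape
    if complex_field:
        white = rng.normal(size=(H, W)) + 1j * rng.normal(size=(H, W))
    else:
        white = rng.normal(size=(H, W))
    f0 = 1.0 / wavelength
    fy = np.fft.fftfreq(H)
    fx = np.fft.fftfreq(W)
    fr = np.hypot(fy[:, None], fx[None, :])
    filt = np.exp(-((fr - f0) ** 2) / (2 * (rel_bandwidth * f0) ** 2))
    filt[0, 0] = 0.0
    out = np.fft.ifft2(np.fft.fft2(white) * filt)
    return out if complex_field else out.real


def synth_maps(mode: str = "parametric", seed: int = 0, size: int = 192,
               wavelength: float = 44.0, coupling: float = 0.0,
               sim_config=None) -> GroundTruth:
    """Ground-truth OP/OD maps.

    parametric: OP = band-pass filtered complex Gaussian noise (annular
    spectrum at 1/wavelength), OD = an independent band-pass field; the
    optional ``coupling`` ∈ [−1, 1] rescales |OD| by the normalized OP
    selectivity so pinwheels (selectivity minima) sit near OD borders
    (coupling > 0) or near OD column centres (coupling < 0) while the borders
    themselves stay put.  elastic_net: delegates to the simulator.
    """
    if mode == "elastic_net":
        from .elastic_net import SimulationConfig, extract_maps, run_simulation

        config = sim_config if sim_config is not None else SimulationConfig(seed=seed)
        if config.seed != seed:
            config = replace(config, seed=seed)
        op, od = extract_maps(run_simulation(config))
        return GroundTruth(op, od, "elastic_net", seed,
                           {"alpha_over": config.alpha_over})
    if mode != "parametric":
        raise ValueError(f"unknown mode {mode!r}")
    if size < 4 * wavelength:
        raise ValueError("size must be at least 4x the wavelength")
    rng = np.random.default_rng(seed)
    z = _bandpass_noise(rng, (size, size), wavelength, complex_field=True)
    z = z / np.abs(z).max()
    od = _bandpass_noise(rng, (size, size), wavelength)
    od = od / np.abs(od).max()
    if coupling:
        s = np.abs(z) / np.abs(z).max()
        shape_field = s if coupling > 0 else 1.0 - s
        w = 1.0 - abs(coupling)
        od = od * (w + (1.0 - w) * shape_field)
        od = od / np.abs(od).max()
    return GroundTruth(OPMap(z), ODMap(od), "parametric", seed,
                       {"wavelength": wavelength, "coupling": coupling})


def hemodynamic_kernel(recipe: StackRecipe) -> np.ndarray:
    """Rise-to-plateau response time course h(f) ∈ [0, 1] over the frame grid."""
    on, off = recipe.stim_frames
    t = (np.arange(recipe.n_frames) + 0.5) / recipe.frame_rate
    t_on = (on - 1) / recipe.frame_rate + recipe.hemo_latency
    t_rise_end = t_on + recipe.hemo_rise
    t_off = off / recipe.frame_rate
    h = np.zeros(recipe.n_frames)
    rising = (t >= t_on) & (t < t_rise_end)
    h[rising] = (t[rising] - t_on) / recipe.hemo_rise
    h[(t >= t_rise_end) & (t <= t_off)] = 1.0
    after = t > t_off
    h[after] = np.exp(-(t[after] - t_off) / recipe.hemo_decay_tau)
    return h


def _vessel_image(rng, shape, width, count):
    """Dark curvilinear structures: Gaussian-profile random walks."""
    H, W = shape
    img = np.zeros(shape)
    for _ in range(count):
        edge = rng.integers(4)
        if edge == 0:
            r, c = 0.0, rng.uniform(0, W)
        elif edge == 1:
            r, c = H - 1.0, rng.uniform(0, W)
        elif edge == 2:
            r, c = rng.uniform(0, H), 0.0
        else:
            r, c = rng.uniform(0, H), W - 1.0
        ang = np.arctan2(H / 2 - r, W / 2 - c) + rng.normal(0, 0.3)
        for _ in range(int(2.2 * max(H, W))):
            ang += rng.normal(0, 0.12)
            r += np.sin(ang)
            c += np.cos(ang)
            if not (0 <= r < H and 0 <= c < W):
                break
            img[int(r), int(c)] = 1.0
    img = ndi.gaussian_filter(img, width)
    if img.max() > 0:
        img /= img.max()
    return img


def synth_stack(truth: GroundTruth, recipe: StackRecipe = StackRecipe(),
                seed: int = 0) -> ImagingStack:
    """Simulated imaging stack for the planted maps.

    Pixel response amplitude to (direction θ, eye e) is
    w_e·(1 + s·cos(2(θ − φ)))/2 with φ/s the planted preference/selectivity and
    w_e = (1 ± tanh(g·od))/2; reflectance decreases by gain × amplitude × h(f)
    during the response.  Vessel artifacts, drift and pixel noise are additive;
    trials differ by seed-derived noise realizations.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x57AC]))
    op, od = truth.op, truth.od
    H, W = op.field.shape
    s = np.abs(op.field)
    s = s / s.max() if s.max() > 0 else s
    phi = np.angle(op.field)  # doubled angle
    odn = od.field / np.abs(od.field).max() if np.abs(od.field).max() > 0 else od.field
    w_eye = {"L": (1.0 - np.tanh(recipe.od_gain * odn)) / 2.0,
             "R": (1.0 + np.tanh(recipe.od_gain * odn)) / 2.0}
    h = hemodynamic_kernel(recipe)
    vessels = _vessel_image(rng, (H, W), recipe.vessel_width, recipe.vessel_count)
    drift_pattern = ndi.gaussian_filter(rng.normal(size=(H, W)), min(H, W) / 4.0)
    if drift_pattern.std() > 0:
        drift_pattern = drift_pattern / np.abs(drift_pattern).max()
    g = recipe.gain

    conditions = [(d, e) for e in EYES for d in DIRECTIONS]
    if recipe.include_blank:
        conditions.append((np.nan, ""))
    trials, dirs, eyes = [], [], []
    for d, e in conditions:
        if np.isnan(d):
            amp = np.zeros((H, W))
        else:
            theta = np.deg2rad(d % 180.0)
            amp = w_eye[e] * (1.0 + s * np.cos(2 * theta - phi)) / 2.0
        for _ in range(recipe.trials_per_condition):
            signal = g * amp[None, :, :] * h[:, None, None]
            frames = 1.0 - signal
            if recipe.vessel_count and recipe.vessel_amplitude:
                jit = 1.0 + rng.normal(0, recipe.vessel_jitter, recipe.n_frames)
                frames = frames - (g * recipe.vessel_amplitude) * \
                    jit[:, None, None] * vessels[None, :, :]
            if recipe.drift_amplitude:
                walk = np.cumsum(rng.normal(0, 1, recipe.n_frames))
                walk /= max(np.abs(walk).max(), 1e-12)
                frames = frames + (g * recipe.drift_amplitude) * \
                    walk[:, None, None] * drift_pattern[None, :, :]
            if recipe.noise_sigma:
                frames = frames + rng.normal(
                    0, g * recipe.noise_sigma, frames.shape)
            trials.append(frames.astype(np.float32))
            dirs.append(d)
            eyes.append(e)
    return ImagingStack(np.asarray(trials), np.asarray(dirs, float),
                        np.asarray(eyes), recipe.frame_rate, recipe.stim_frames)


@dataclass
class UnitRecord:
    """Single-unit response curves per eye plus the generating parameters."""

    unit_id: int
    responses: dict       # eye -> {"orientation": (dirs, rates), "sf": ..., "tf": ..., "contrast": ...}
    spontaneous: float
    dominant_eye: str
    truth: dict           # eye -> generating parameter dict


def _sample_sine_density(rng, n, period, peak_deg, amplitude):
    """Rejection-sample orientations on [0, 180) from 1 + a·cos(2π(θ−peak)/P)."""
    out = np.empty(n)
    have = 0
    while have < n:
        cand = rng.uniform(0, 180, 4 * (n - have))
        dens = 1.0 + amplitude * np.cos(2 * np.pi * (cand - peak_deg) / period)
        keep = cand[rng.uniform(0, 1 + amplitude, len(cand)) < dens]
        take = min(len(keep), n - have)
        out[have:have + take] = keep[:take]
        have += take
    return out


def synth_units(n: int, population: str = "control", seed: int = 0,
                noise_sigma: float = 0.1, modulation: float | None = None,
                left_peak: float = 0.0, right_peak: float = 90.0) -> list[UnitRecord]:
    """Noisy unit response tables from the tuning models.

    control: preferred orientations from a period-90° (cardinal-bias) density,
    both eyes sharing the preference up to a small jitter.  cross_reared:
    per-eye period-180° densities peaked at ``left_peak`` / ``right_peak``.
    noise_sigma scales multiplicative Gaussian rate noise (× Rp).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if population not in ("control", "cross_reared"):
        raise ValueError("population must be 'control' or 'cross_reared'")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0117]))
    amp = 0.4 if population == "control" else 0.8
    if modulation is not None:
        amp = modulation
    if population == "control":
        th_shared = _sample_sine_density(rng, n, 90.0, 0.0, amp)
        th_left = np.mod(th_shared + rng.normal(0, 4.0, n), 180.0)
        th_right = np.mod(th_shared + rng.normal(0, 4.0, n), 180.0)
    else:
        th_left = _sample_sine_density(rng, n, 180.0, left_peak, amp)
        th_right = _sample_sine_density(rng, n, 180.0, right_peak, amp)

    units = []
    for i in range(n):
        Rp = rng.uniform(10, 40)
        R0 = rng.uniform(0, 5)
        k = rng.uniform(1.0, 3.0)
        mi = rng.uniform(0, 0.6) if population == "control" else rng.uniform(0.2, 0.9)
        dominant = "R" if rng.uniform() < 0.5 else "L"
        scale = {dominant: 1.0,
                 ("L" if dominant == "R" else "R"): (1 - mi) / (1 + mi)}
        sf_p = float(np.exp(rng.uniform(np.log(0.1), np.log(0.8))))
        tf_p = float(np.exp(rng.uniform(np.log(1.0), np.log(8.0))))
        sf_k = rng.uniform(0.8, 2.0)
        tf_k = rng.uniform(0.8, 2.0)
        lam_s = rng.uniform(-0.4, 0.4)
        lam_t = rng.uniform(-0.4, 0.4)
        c_sig = rng.uniform(10, 40)
        c_n = rng.uniform(1.5, 3.5)
        th_eye = {"L": th_left[i], "R": th_right[i]}

        def noisy(vals):
            out = vals + rng.normal(0, noise_sigma * Rp, np.shape(vals))
            return np.clip(out, 0, None)

        responses, truth = {}, {}
        for eye in EYES:
            Rp_e = Rp * scale[eye]
            ori = von_mises(DIRECTIONS % 180.0, Rp_e, th_eye[eye], k, R0)
            sf = skewed_gaussian(SF_GRID, Rp_e, sf_p, sf_k, lam_s, R0)
            tf = skewed_gaussian(TF_GRID, Rp_e, tf_p, tf_k, lam_t, R0)
            con = naka_rushton(CONTRAST_GRID, Rp_e, c_sig, c_n, R0)
            responses[eye] = {
                "orientation": (DIRECTIONS.copy(), noisy(ori)),
                "sf": (SF_GRID.copy(), noisy(sf)),
                "tf": (TF_GRID.copy(), noisy(tf)),
                "contrast": (CONTRAST_GRID.copy(), noisy(con)),
            }
            truth[eye] = {"Rp": Rp_e, "theta_p": th_eye[eye], "k": k, "R0": R0,
                          "fp_sf": sf_p, "k_sf": sf_k, "lam_sf": lam_s,
                          "fp_tf": tf_p, "k_tf": tf_k, "lam_tf": lam_t,
                          "sigma_c": c_sig, "n_c": c_n, "mi": mi}
        units.append(UnitRecord(unit_id=i, responses=responses, spontaneous=R0,
                                dominant_eye=dominant, truth=truth))
    return units


def units_to_dataframe(units: list[UnitRecord]):
    """Long-format table: unit_id, eye, stimulus_type, stimulus_value, rate."""
    import pandas as pd

    rows = []
    for u in units:
        for eye, curves in u.responses.items():
            for stim, (xs, ys) in curves.items():
                for x, y in zip(xs, ys):
                    rows.append((u.unit_id, eye, stim, float(x), float(y)))
    return pd.DataFrame(rows, columns=["unit_id", "eye", "stimulus_type",
                                       "stimulus_value", "rate"])
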