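"""Single-unit tuning-curve models and population statistics.

Models: a von Mises orientation tuning curve
R(θ) = Rp·exp(k(cos2(θ−θp) − 1)) + R0, a skewed log-Gaussian for spatial and
temporal frequency tuning R(f) = Rp·exp(−(log(f/fp)/(k + λ·log(f/fp)))²) + R0,
and a Naka–Rushton contrast-response sigmoid R(c) = Rm·cⁿ/(cⁿ + σⁿ) + R0.
Population statistics: the monocularity index MI = |RR−RL|/(RR+RL), the signed
interocular preferred-orientation difference ΔOP wrapped to (−90°, 90°], and
binned preferred-orientation histograms with fixed-period sine fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .map_stats import SineFit, fit_sine_distribution

__all__ = [
    "VonMisesFit", "SkewGaussFit", "ContrastFit",
    "von_mises", "skewed_gaussian", "naka_rushton",
    "fit_von_mises", "fit_skewed_gaussian", "fit_contrast_response",
    "monocularity_index", "interocular_op_difference",
    "population_orientation_histogram", "average_opposite_directions",
]

_TOL = dict(xtol=1e-10, ftol=1e-10, gtol=1e-10)


def von_mises(theta_deg, Rp, theta_p, k, R0):
    """R(θ) = Rp·exp(k(cos(2(θ−θp)) − 1)) + R0 (θ in degrees)."""
    d = np.deg2rad(np.asarray(theta_deg, float) - theta_p)
    return Rp * np.exp(k * (np.cos(2 * d) - 1.0)) + R0


def skewed_gaussian(f, Rp, fp, k, lam, R0):
    """R(f) = Rp·exp(−(log(f/fp) / (k + λ·log(f/fp)))²) + R0."""
    x = np.log(np.asarray(f, float) / fp)
    den = k + lam * x
    arg = np.where(np.abs(den) > 1e-12, x / np.where(den == 0, 1e-12, den), np.inf)
    return Rp * np.exp(-arg ** 2) + R0


def naka_rushton(c, Rm, sigma, n, R0):
    """R(c) = Rm·cⁿ / (cⁿ + σⁿ) + R0 (c as percent contrast)."""
    c = np.asarray(c, float)
    cn = c ** n
    return Rm * cn / (cn + sigma ** n) + R0


def _r_squared(y, fit):
    if np.allclose(fit, fit[0]) or np.allclose(y, y[0]):
        return 0.0
    r = np.corrcoef(y, fit)[0, 1]
    return float(r ** 2) if np.isfinite(r) else 0.0


@dataclass(frozen=True)
class VonMisesFit:
    Rp: float
    theta_p: float       # degrees, [0, 180)
    k: float
    R0: float
    r_squared: float
    bandwidth: float     # FWHM of the fitted curve, degrees
    unselective: bool = False

    def __call__(self, theta_deg):
        return von_mises(theta_deg, self.Rp, self.theta_p, self.k, self.R0)


@dataclass(frozen=True)
class SkewGaussFit:
    Rp: float
    fp: float
    k: float
    lam: float
    R0: float
    r_squared: float
    bandwidth: float     # FWHM in octaves

    def __call__(self, f):
        return skewed_gaussian(f, self.Rp, self.fp, self.k, self.lam, self.R0)


@dataclass(frozen=True)
class ContrastFit:
    Rm: float
    sigma: float         # semi-saturation contrast, percent
    n: float
    R0: float
    r_squared: float
    saturating: bool

    def __call__(self, c):
        return naka_rushton(c, self.Rm, self.sigma, self.n, self.R0)


def average_opposite_directions(directions_deg, responses):
    """Average responses to opposite drift directions → (orientations, rates).

    directions are reduced mod 180°; returns orientations sorted ascending.
    """
    d = np.mod(np.asarray(directions_deg, float), 180.0)
    r = np.asarray(responses, float)
    oris = np.unique(d)
    rates = np.array([r[d == o].mean() for o in oris])
    return oris, rates


def _fwhm_circular(fit_fun, peak_x, peak_y, base_y, period=180.0):
    """FWHM (degrees) of a 180°-periodic curve around its peak, numeric."""
    half = base_y + (peak_y - base_y) / 2.0
    xs = peak_x + np.linspace(0, period / 2, 2001)
    ys = fit_fun(xs)
    below = np.nonzero(ys <= half)[0]
    if len(below) == 0:
        return float(period)
    return float(2 * (xs[below[0]] - peak_x))


def fit_von_mises(orientations_deg, responses) -> VonMisesFit:
    """Nonlinear least-squares fit of the von Mises tuning curve.

    Multi-start over an 8-point θp grid avoids the 180°-periodic local minima.
    Flat data are flagged unselective (k → 0).
    """
    th = np.asarray(orientations_deg, float)
    y = np.asarray(responses, float)
    if len(th) < 8:
        raise ValueError("need at least 8 orientation samples")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite responses")
    span = y.max() - y.min()
    if span == 0:
        return VonMisesFit(Rp=0.0, theta_p=float(th[0]), k=0.0, R0=float(y[0]),
                           r_squared=0.0, bandwidth=180.0, unselective=True)

    def resid(p):
        return von_mises(th, *p) - y

    best = None
    lb = [0.0, -360.0, 1e-6, -np.inf]
    ub = [np.inf, 720.0, 500.0, np.inf]
    for start in np.arange(0, 180, 22.5):
        p0 = [span, start, 2.0, max(y.min(), 0.0)]
        sol = least_squares(resid, p0, bounds=(lb, ub), **_TOL)
        if best is None or sol.cost < best.cost:
            best = sol
    Rp, th_p, k, R0 = best.x
    th_p = float(np.mod(th_p, 180.0))
    fit = von_mises(th, Rp, th_p, k, R0)
    unsel = k < 1e-3
    bw = _fwhm_circular(lambda x: von_mises(x, Rp, th_p, k, R0),
                        th_p, Rp + R0, von_mises(th_p + 90.0, Rp, th_p, k, R0))
    return VonMisesFit(Rp=float(Rp), theta_p=th_p, k=float(k), R0=float(R0),
                       r_squared=_r_squared(y, fit), bandwidth=bw,
                       unselective=bool(unsel))


def fit_skewed_gaussian(frequencies, responses, domain: str = "spatial") -> SkewGaussFit:
    """Least-squares fit of the skewed log-Gaussian frequency tuning curve.

    Identical code path for spatial (cyc/°) and temporal (Hz) frequency;
    multi-start over the stimulus grid for fp.
    """
    f = np.asarray(frequencies, float)
    y = np.asarray(responses, float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    if len(f) < 5:
        raise ValueError("need at least 5 frequency samples")
    if domain not in ("spatial", "temporal"):
        raise ValueError("domain must be 'spatial' or 'temporal'")
    span = max(y.max() - y.min(), 1e-12)

    def resid(p):
        return skewed_gaussian(f, *p) - y

    lb = [0.0, f.min() / 4, 1e-3, -5.0, -np.inf]
    ub = [np.inf, f.max() * 4, 50.0, 5.0, np.inf]
    best = None
    for fp0 in f:
        p0 = [span, fp0, 1.5, 0.0, max(y.min(), 0.0)]
        sol = least_squares(resid, p0, bounds=(lb, ub), **_TOL)
        if best is None or sol.cost < best.cost:
            best = sol
    Rp, fp, k, lam, R0 = best.x
    fit = skewed_gaussian(f, Rp, fp, k, lam, R0)
    # FWHM in octaves, numeric on a log grid around fp
    grid = fp * 2.0 ** np.linspace(-8, 8, 4001)
    vals = skewed_gaussian(grid, Rp, fp, k, lam, R0)
    half = R0 + Rp / 2.0
    above = vals >= half
    idx = np.nonzero(above)[0]
    bw = float(np.log2(grid[idx[-1]] / grid[idx[0]])) if len(idx) else 0.0
    return SkewGaussFit(Rp=float(Rp), fp=float(fp), k=float(k), lam=float(lam),
                        R0=float(R0), r_squared=_r_squared(y, fit), bandwidth=bw)


def fit_contrast_response(contrasts, responses, max_contrast: float = 100.0) -> ContrastFit:
    """Naka–Rushton sigmoid fit; flags non-saturating units (σ beyond max contrast)."""
    c = np.asarray(contrasts, float)
    y = np.asarray(responses, float)
    if len(c) < 5:
        raise ValueError("need at least 5 contrast levels")
    if not y.any():
        raise ValueError("all-zero responses")
    span = max(y.max() - y.min(), 1e-12)

    def resid(p):
        return naka_rushton(c, *p) - y

    lb = [0.0, 1e-3, 0.1, -np.inf]
    ub = [np.inf, 1e4, 10.0, np.inf]
    best = None
    for s0 in (5.0, 20.0, 50.0, 90.0):
        p0 = [span, s0, 2.0, max(y.min(), 0.0)]
        sol = least_squares(resid, p0, bounds=(lb, ub), **_TOL)
        if best is None or sol.cost < best.cost:
            best = sol
    Rm, sigma, n, R0 = best.x
    fit = naka_rushton(c, Rm, sigma, n, R0)
    return ContrastFit(Rm=float(Rm), sigma=float(sigma), n=float(n), R0=float(R0),
                       r_squared=_r_squared(y, fit),
                       saturating=bool(sigma <= max_contrast))


def monocularity_index(RR: float, RL: float) -> float:
    """MI = |RR − RL| / (RR + RL); 0 = binocular, 1 = monocular."""
    if RR + RL <= 0:
        raise ValueError("MI undefined for RR + RL <= 0")
    return abs(RR - RL) / (RR + RL)


def interocular_op_difference(theta_right: float, theta_left: float) -> float:
    """Signed ΔOP = right − left preference, 180°-circular, wrapped to (−90°, 90°]."""
    d = (theta_right - theta_left) % 180.0
    if d > 90.0:
        d -= 180.0
    return float(d)


def population_orientation_histogram(theta_p_deg, bin_width: float = 22.5):
    """Histogram of preferred orientations with period-90° and period-180° sine fits.

    Returns (proportions, bin_centers, {90.0: SineFit, 180.0: SineFit}); the two
    r² values support the control (90°, cardinal bias) vs cross-reared (180°,
    one peak per eye) model comparison.
    """
    th = np.mod(np.asarray(theta_p_deg, float), 180.0)
    if len(th) < 8:
        raise ValueError("need at least 8 units")
    nbins = int(round(180.0 / bin_width))
    edges = np.linspace(0, 180, nbins + 1)
    counts, _ = np.histogram(th, bins=edges)
    props = counts / counts.sum()
    centers = edges[:-1] + bin_width / 2
    fits: dict[float, SineFit] = {
        90.0: fit_sine_distribution(props, 90.0, centers),
        180.0: fit_sine_distribution(props, 180.0, centers),
    }
    return props, centers, fits
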