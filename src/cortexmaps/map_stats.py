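"""Statistics of orientation-preference and ocular-dominance maps.

Quantifies map structure and the spatial relationship between the two maps:
pinwheel detection by winding number, Fourier map wavelength, dimensionless
pinwheel density (pinwheels per pixel × Λ²; theory predicts π for a stable
pinwheel layout), localization of pinwheels on ocular-dominance quintiles
(five equal-area bins per OD sign, ordered column centre → border), orientation
proportions, fixed-period sine fits to angular histograms, and OP/OD contour
crossing angles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage import measure
from shapely.geometry import LineString

__all__ = [
    "OPMap", "ODMap", "Pinwheel", "SineFit", "MatchResult",
    "detect_pinwheels", "map_wavelength", "pinwheel_density",
    "od_quintile_bins", "pinwheel_od_histogram", "selectivity_by_od_bin",
    "orientation_proportions", "fit_sine_distribution", "crossing_angles",
    "pinwheel_displacement", "selectivity_mask",
]


@dataclass
class OPMap:
    """Complex orientation field: angle = 2×preferred orientation, magnitude = selectivity."""

    field: np.ndarray
    mask: np.ndarray = None

    def __post_init__(self):
        self.field = np.asarray(self.field)
        if self.mask is None:
            self.mask = np.ones(self.field.shape, bool)
        self.mask = np.asarray(self.mask, bool)
        if self.mask.shape != self.field.shape:
            raise ValueError("mask shape must match field")

    @property
    def orientation(self) -> np.ndarray:
        """Preferred orientation per pixel, degrees in [0, 180)."""
        return np.mod(np.degrees(np.angle(self.field)) / 2.0, 180.0)

    @property
    def selectivity(self) -> np.ndarray:
        return np.abs(self.field)


@dataclass
class ODMap:
    """Signed ocularity field: negative = left eye, positive = right eye."""

    field: np.ndarray
    mask: np.ndarray = None

    def __post_init__(self):
        self.field = np.asarray(self.field, float)
        if self.mask is None:
            self.mask = np.ones(self.field.shape, bool)
        self.mask = np.asarray(self.mask, bool)


@dataclass(frozen=True)
class Pinwheel:
    position: tuple[float, float]  # (row, col), sub-pixel
    sign: int                      # winding direction, ±1


@dataclass(frozen=True)
class SineFit:
    amplitude: float
    phase: float        # degrees, in [0, period)
    offset: float
    period: float       # degrees (90 or 180)
    r_squared: float
    peak_angles: tuple  # degrees in [0, 180)


@dataclass(frozen=True)
class MatchResult:
    mean_displacement: float   # in wavelength units, matched pairs only
    n_matched: int
    n_unmatched: int
    displacements: np.ndarray = field(repr=False, default=None)


def selectivity_mask(op: OPMap, percentile: float = 10.0,
                     smooth_sigma: float = 5.0) -> np.ndarray:
    """Analysis mask: regions of strong orientation preference.

    The selectivity image is smoothed (σ = smooth_sigma px) before
    thresholding at the given percentile, so that pinwheel cores — pointwise
    selectivity minima surrounded by selective tissue — stay inside the mask
    while genuinely weakly-tuned regions are removed.
    """
    sel = ndi.gaussian_filter(np.abs(op.field), smooth_sigma, mode="nearest")
    thr = np.percentile(sel[op.mask], percentile)
    return op.mask & (sel > thr)


def _winding(theta_deg: np.ndarray) -> np.ndarray:
    """Winding totals (degrees) of the 8-neighbor closed loop at interior pixels.

    Each step difference is wrapped into (−90°, +90°]; the closed-loop total is
    a multiple of 180° (0 away from singularities, ±180° at a pinwheel).
    """
    H, W = theta_deg.shape
    offs = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]
    ring = np.stack([theta_deg[1 + dr:H - 1 + dr, 1 + dc:W - 1 + dc]
                     for dr, dc in offs + [offs[0]]])
    d = np.diff(ring, axis=0)
    d = 90.0 - np.mod(90.0 - d, 180.0)  # wrap into (-90, 90]
    return d.sum(axis=0)


def detect_pinwheels(op: OPMap) -> list[Pinwheel]:
    """Find orientation singularities via the ±180° winding of preference.

    Flagged pixels are merged into 8-connected clusters; each cluster yields
    one pinwheel at the cluster centre of mass, with the winding sign.
    """
    H, W = op.field.shape
    if H < 3 or W < 3:
        raise ValueError("map must be at least 3x3")
    if not op.mask.any():
        return []
    theta = op.orientation
    tot = _winding(theta)
    # require the full 3x3 neighborhood inside the mask
    core = ndi.minimum_filter(op.mask.astype(np.uint8), size=3)[1:-1, 1:-1] > 0
    flagged = core & np.isclose(np.abs(tot), 180.0, atol=1e-6)
    if not flagged.any():
        return []
    labels = measure.label(flagged, connectivity=2)
    pins = []
    for region in measure.regionprops(labels):
        r, c = region.centroid
        rows, cols = np.nonzero(labels == region.label)
        sign = int(np.sign(tot[rows, cols].mean()))
        pins.append(Pinwheel(position=(r + 1.0, c + 1.0), sign=sign))
    return pins


def map_wavelength(op: OPMap) -> float:
    """Mean Fourier wavelength: power-weighted mean of 1/f, averaged over directions.

    The mean-subtracted complex field (zero outside the mask) is Fourier
    transformed; power is summed in annular frequency bins of width 1/L
    (L = min map side), DC excluded, and the wavelength is Σ P_k/f_k / Σ P_k.
    """
    z = np.where(op.mask, op.field, 0).astype(complex)
    n = op.mask.sum()
    if n == 0 or not np.any(op.field[op.mask]):
        raise ValueError("all-zero or empty field")
    z[op.mask] -= op.field[op.mask].mean()
    H, W = z.shape
    F = np.abs(np.fft.fft2(z)) ** 2
    fy = np.fft.fftfreq(H)
    fx = np.fft.fftfreq(W)
    fr = np.hypot(fy[:, None], fx[None, :])
    L = min(H, W)
    k = np.rint(fr * L).astype(int)
    sel = (k >= 1) & (fr <= 0.5)
    P = np.bincount(k[sel], weights=F[sel])
    ks = np.arange(len(P))
    good = P > 0
    good[0] = False
    if not good.any():
        raise ValueError("no spectral power off DC")
    fk = ks[good] / L
    return float(np.sum(P[good] / fk) / np.sum(P[good]))


def pinwheel_density(op: OPMap) -> float:
    """Dimensionless density: (pinwheel count / masked pixels) × wavelength²."""
    pins = detect_pinwheels(op)
    if not pins:
        raise ValueError("no pinwheels detected")
    lam = map_wavelength(op)
    return len(pins) / float(op.mask.sum()) * lam ** 2


def od_quintile_bins(od: ODMap) -> np.ndarray:
    """Per-pixel quintile index 0 (column centre, highest |OD|) … 4 (border).

    Positive and negative OD pixels are ranked separately by |value| and split
    into five equal-area bins each (±1 pixel), then pooled: bin 0 holds the
    centre-most fifth of each eye's columns, bin 4 the border fifth.
    Unmasked pixels get −1.
    """
    bins = np.full(od.field.shape, -1, int)
    pos = od.mask & (od.field > 0)
    neg = od.mask & (od.field <= 0)
    for m in (pos, neg):
        cnt = int(m.sum())
        if cnt == 0:
            continue
        vals = np.abs(od.field[m])
        rank = np.empty(cnt, int)
        rank[np.argsort(-vals, kind="stable")] = np.arange(cnt)
        bins[m] = (rank * 5) // cnt
    return bins


def pinwheel_od_histogram(pinwheels: list[Pinwheel], od: ODMap):
    """Counts and proportions of pinwheels per OD quintile, centre → border.

    Each pinwheel is assigned the bin of its nearest pixel; pinwheels whose
    nearest pixel is outside the mask are excluded with a warning.
    """
    if not ((od.field[od.mask] > 0).any() and (od.field[od.mask] < 0).any()):
        raise ValueError("OD map must contain both signs within the mask")
    bins = od_quintile_bins(od)
    H, W = od.field.shape
    counts = np.zeros(5, int)
    excluded = 0
    for pw in pinwheels:
        r = min(max(int(round(pw.position[0])), 0), H - 1)
        c = min(max(int(round(pw.position[1])), 0), W - 1)
        b = bins[r, c]
        if b < 0:
            excluded += 1
            continue
        counts[b] += 1
    if excluded:
        warnings.warn(f"{excluded} pinwheel(s) outside the OD mask were excluded")
    total = counts.sum()
    proportions = counts / total if total else np.zeros(5)
    return counts, proportions


def selectivity_by_od_bin(op: OPMap, od: ODMap) -> np.ndarray:
    """Mean normalized orientation selectivity in each OD quintile (centre → border)."""
    mask = op.mask & od.mask
    smax = np.abs(op.field[mask]).max() if mask.any() else 0.0
    if smax == 0:
        raise ValueError("zero maximum selectivity within mask")
    sel = np.abs(op.field) / smax
    bins = od_quintile_bins(ODMap(od.field, mask))
    return np.array([sel[bins == b].mean() for b in range(5)])


def orientation_proportions(op: OPMap) -> np.ndarray:
    """Proportions in the eight 22.5°-wide orientation bins centred on 11.25°, 33.75°, …

    Bin edges at 0°, 22.5°, …, 180°, left-closed right-open (180° wraps to 0°).
    """
    if not op.mask.any():
        raise ValueError("empty mask")
    theta = op.orientation[op.mask] % 180.0
    idx = np.floor(theta / 22.5).astype(int) % 8
    counts = np.bincount(idx, minlength=8)
    return counts / counts.sum()


ORIENTATION_BIN_CENTERS = 11.25 + 22.5 * np.arange(8)


def fit_sine_distribution(proportions, period: float,
                          bin_centers=None) -> SineFit:
    """Least-squares fit of A·sin(2π(θ−φ)/P) + C with the period P fixed.

    A is reported non-negative (sign absorbed into the phase); r² is the
    squared correlation of the data with the fitted curve (0 for a flat fit).
    Peak angles are the curve maxima within [0°, 180°).
    """
    y = np.asarray(proportions, float)
    if bin_centers is None:
        if len(y) != 8:
            raise ValueError("bin_centers required when not using the 8 default bins")
        bin_centers = ORIENTATION_BIN_CENTERS
    th = np.asarray(bin_centers, float)
    if len(y) < 4:
        raise ValueError("need at least 4 bins")
    w = 2 * np.pi / period
    X = np.column_stack([np.sin(w * th), np.cos(w * th), np.ones_like(th)])
    (a, b, C), *_ = np.linalg.lstsq(X, y, rcond=None)
    A = float(np.hypot(a, b))
    phi = float(np.mod(-np.arctan2(b, a) / w, period))
    fit = X @ (a, b, C)
    if A < 1e-12 * max(1.0, np.abs(y).max()) or np.allclose(fit, fit[0]):
        r2 = 0.0
        A = 0.0
    else:
        r = np.corrcoef(y, fit)[0, 1]
        r2 = float(r ** 2) if np.isfinite(r) else 0.0
    peak = np.mod(phi + period / 4.0, period)
    peaks = tuple(np.sort(np.mod(peak + period * np.arange(int(180 // period)), 180.0)))
    return SineFit(amplitude=A, phase=phi, offset=float(C), period=float(period),
                   r_squared=r2, peak_angles=peaks)


def _iso_orientation_contours(op: OPMap, level_deg: float) -> list[np.ndarray]:
    """Iso-orientation polylines at the given level, on the doubled-angle field.

    Zero contours of Im(z·e^{−2iθ0}) are extracted and split to the runs where
    Re(z·e^{−2iθ0}) > 0, which selects orientation θ0 (not θ0 + 90°) without a
    0/180 wrap artifact.
    """
    rot = op.field * np.exp(-2j * np.deg2rad(level_deg))
    segments = []
    for poly in measure.find_contours(rot.imag, 0.0):
        rr, cc = poly[:, 0], poly[:, 1]
        re = ndi.map_coordinates(rot.real, [rr, cc], order=1, mode="nearest")
        keep = re > 0
        start = None
        for i, k in enumerate(np.append(keep, False)):
            if k and start is None:
                start = i
            elif not k and start is not None:
                if i - start >= 2:
                    segments.append(poly[start:i])
                start = None
    return segments


def _tangent_angle(line: LineString, s: float, delta: float = 0.75) -> float:
    """Orientation (degrees, mod 180) of the contour tangent at arclength s."""
    p0 = line.interpolate(max(s - delta, 0.0))
    p1 = line.interpolate(min(s + delta, line.length))
    return float(np.degrees(np.arctan2(p1.y - p0.y, p1.x - p0.x)) % 180.0)


def crossing_angles(op: OPMap, od: ODMap,
                    op_levels=np.arange(0.0, 180.0, 22.5)) -> np.ndarray:
    """Angles (degrees, in [0, 90]) between OD-border and iso-orientation contours.

    The OD zero-level contour and the OP contours at the given orientation
    levels are extracted by marching squares; at each polyline intersection the
    absolute difference of the tangent orientations is folded into [0°, 90°].
    Returns an empty array when the families do not intersect.
    """
    if op.field.shape != od.field.shape:
        raise ValueError("maps must share a grid")
    od_lines = [LineString(p[:, ::-1]) for p in measure.find_contours(od.field, 0.0)
                if len(p) >= 2]
    angles = []
    for level in op_levels:
        for seg in _iso_orientation_contours(op, level):
            if len(seg) < 2:
                continue
            op_line = LineString(seg[:, ::-1])
            for od_line in od_lines:
                inter = op_line.intersection(od_line)
                if inter.is_empty:
                    continue
                pts = []
                if inter.geom_type == "Point":
                    pts = [inter]
                elif inter.geom_type in ("MultiPoint", "GeometryCollection"):
                    pts = [g for g in inter.geoms if g.geom_type == "Point"]
                for pt in pts:
                    a1 = _tangent_angle(op_line, op_line.project(pt))
                    a2 = _tangent_angle(od_line, od_line.project(pt))
                    d = abs(a1 - a2) % 180.0
                    angles.append(min(d, 180.0 - d))
    return np.asarray(angles, float)


def pinwheel_displacement(map_a: OPMap, map_b: OPMap, wavelength: float) -> MatchResult:
    """Mean matched pinwheel displacement between two maps, in wavelength units.

    Greedy nearest-neighbor matching with a distance cap of Λ/2; same-sign
    pairs are matched first, remaining pinwheels may match across signs.
    Ties break by smallest distance, then smallest index.
    """
    if map_a.field.shape != map_b.field.shape:
        raise ValueError("maps must share a shape")
    pa = detect_pinwheels(map_a)
    pb = detect_pinwheels(map_b)
    if not pa or not pb:
        raise ValueError("pinwheel set empty in one of the maps")
    A = np.array([p.position for p in pa])
    B = np.array([p.position for p in pb])
    sa = np.array([p.sign for p in pa])
    sb = np.array([p.sign for p in pb])
    cap = wavelength / 2.0
    dist = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=-1)
    used_a = np.zeros(len(pa), bool)
    used_b = np.zeros(len(pb), bool)
    matched = []

    def greedy(pair_ok):
        order = np.argsort(dist, axis=None, kind="stable")
        for flat in order:
            i, j = np.unravel_index(flat, dist.shape)
            if dist[i, j] > cap:
                break
            if used_a[i] or used_b[j] or not pair_ok(i, j):
                continue
            used_a[i] = used_b[j] = True
            matched.append(dist[i, j])

    greedy(lambda i, j: sa[i] == sb[j])
    greedy(lambda i, j: True)
    disp = np.asarray(matched) / wavelength
    n_un = int((~used_a).sum() + (~used_b).sum())
    mean = float(disp.mean()) if len(disp) else float("nan")
    return MatchResult(mean_displacement=mean, n_matched=len(disp),
                       n_unmatched=n_un, displacements=disp)
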