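"""The 2D decoding pipeline: data cube -> calibrated 2D mass spectrum.

Processing chain (each step a plain function over :class:`Spectrum2D`):

1. :func:`transform_cube` — per product-m/z column, subtract the column
   mean, zero-fill once (N -> 2N), Fourier transform, keep the magnitude of
   the N non-negative-frequency rows.  Column mean subtraction suppresses
   the f_e = 0 ridge so unmodulated background (e.g. upstream
   photofragments) stays in row 0.
2. :func:`first_pass_axis` — re-express the encoding-frequency axis as
   precursor m/z through the reciprocal map m/z = k1/(f_e + k0) ("eq5",
   Dehmelt) or the high-q-accurate closed form ("eq6", Koizumi with
   exact-beta fallback).  Rows mapping outside the nominal m/z 90-4500
   precursor range carry NaN sentinels, never dropped.
3. :func:`detect_autocorrelation_peaks` / :func:`recalibrate` — every peak
   on the diagonal (precursor m/z = product m/z) is an intact precursor
   whose ToF-accurate product m/z is ground truth; a low-order polynomial
   in the first-pass mass removes the residual axis error.
4. :func:`pick_peaks` — 2D local maxima above a per-column
   MAD-based SNR threshold, 7-point centroid in the precursor axis;
   :func:`flag_harmonics` labels peaks at integer multiples of a stronger
   peak's encoding frequency.
5. Slices: horizontal (product-ion spectrum of one precursor), vertical
   (precursor scan of one product), and the autocorrelation-line diagonal
   (an MS1-like precursor spectrum).

No apodization is applied by default (the resolving-power figure assumes a
rectangular window); a Hann window is available via ``window="hann"``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
from scipy.ndimage import maximum_filter

from .config import InstrumentConfig
from .forward_sim import DataCube
from .secular import (
    CalibrationFit,
    KOIZUMI_DOMAIN_MAX_FS_RATIO,
    beta_exact,
    calibration_k0,
    calibration_k1,
    mz_from_q,
    q_koizumi,
    secular_from_encoding,
)

__all__ = [
    "MZ_BAND",
    "Spectrum2D",
    "Peak2D",
    "transform_cube",
    "first_pass_axis",
    "detect_autocorrelation_peaks",
    "recalibrate",
    "pick_peaks",
    "flag_harmonics",
    "slice_horizontal",
    "slice_vertical",
    "autocorrelation_spectrum",
    "resolving_power",
]

#: Nominal precursor m/z range; rows mapping outside it get NaN sentinels.
MZ_BAND = (90.0, 4500.0)


@dataclass
class Spectrum2D:
    """Magnitude 2D mass spectrum over (encoding frequency / precursor m/z)
    x product m/z.

    ``fe_axis`` is in cycles per SWIM index; ``precursor_axis`` (after
    :func:`first_pass_axis` or :func:`recalibrate`) is strictly decreasing
    where defined — the reciprocal frequency-to-mass map makes precursor
    bins narrower at low m/z — with NaN sentinels outside the nominal band.
    """

    magnitude: np.ndarray
    fe_axis: np.ndarray
    product_axis: np.ndarray
    instrument: InstrumentConfig
    precursor_axis: np.ndarray | None = None
    first_pass: np.ndarray | None = None
    axis_method: str | None = None
    calibration: CalibrationFit | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.fe_axis = np.asarray(self.fe_axis, dtype=float)
        self.product_axis = np.asarray(self.product_axis, dtype=float)
        if self.magnitude.shape != (len(self.fe_axis), len(self.product_axis)):
            raise ValueError("magnitude shape does not match axes")

    @property
    def n_rows(self) -> int:
        return self.magnitude.shape[0]

    def row_nearest(self, precursor_mz: float) -> int:
        if self.precursor_axis is None:
            raise ValueError("precursor axis not assigned yet")
        d = np.abs(self.precursor_axis - precursor_mz)
        if np.all(np.isnan(d)):
            raise ValueError("no in-band precursor rows")
        return int(np.nanargmin(d))

    def column_nearest(self, product_mz: float) -> int:
        return int(np.argmin(np.abs(self.product_axis - product_mz)))


@dataclass
class Peak2D:
    """A detected 2D peak (centroided in the precursor axis)."""

    product_mz: float
    precursor_mz: float
    fe: float
    height: float
    snr: float
    harmonic_order: int = 1
    on_autocorrelation: bool = False
    row: int = 0
    col: int = 0


# ---------------------------------------------------------------------------
# Transform and axes
# ---------------------------------------------------------------------------

def transform_cube(cube: DataCube, window: str = "none") -> Spectrum2D:
    """Index-domain -> frequency-domain transform of a data cube.

    Per column: subtract the column mean, optionally apodize, zero-fill
    once (N rows -> 2N), FFT, magnitude; the N non-negative-frequency rows
    are retained, giving evenly spaced real modulation frequencies
    row/(2N) in cycles/index.
    """
    n = cube.n_indices
    if n < 8:
        raise ValueError("need at least 8 SWIM indices to transform")
    data = cube.intensities
    if np.any(~np.isfinite(data)):
        raise ValueError("non-finite values in cube")
    centered = data - data.mean(axis=0, keepdims=True)
    if window == "hann":
        centered = centered * np.hanning(n)[:, None]
    elif window != "none":
        raise ValueError(f"unknown window {window!r}")
    spec = np.fft.rfft(centered, n=2 * n, axis=0)
    magnitude = np.abs(spec[:n, :])
    fe_axis = np.arange(n) / (2.0 * n)
    return Spectrum2D(
        magnitude=magnitude,
        fe_axis=fe_axis,
        product_axis=cube.product_axis.copy(),
        instrument=cube.instrument,
        meta={"window": window, "n_indices": n,
              "index_rate": cube.instrument.index_rate},
    )


def _koizumi_axis_interpolator(cfg: InstrumentConfig):
    """Dense beta_exact(q) table for fast exact-beta fallback on axis rows."""
    from .secular import Q_MAX

    q_grid = np.linspace(1e-6, Q_MAX - 1e-6, 1500)
    beta_grid = np.array([beta_exact(float(q), tol=1e-10) for q in q_grid])
    return q_grid, beta_grid


def _first_pass_mz(fe, cfg: InstrumentConfig, method: str) -> np.ndarray:
    """Vectorized first-pass frequency-to-mass map (no band sentinels)."""
    fe = np.asarray(fe, dtype=float)
    k0 = calibration_k0(cfg)
    k1 = calibration_k1(cfg)
    if method == "eq5":
        return k1 / (fe + k0)
    if method != "eq6":
        raise ValueError(f"unknown axis method {method!r}")
    f_s = 2.0 * fe * cfg.band_width + cfg.f_min
    beta = 2.0 * f_s / cfg.f_trap
    q = np.array([q_koizumi(float(b)) for b in beta.ravel()]).reshape(beta.shape)
    outside = f_s / cfg.f_trap > KOIZUMI_DOMAIN_MAX_FS_RATIO
    if np.any(outside):
        # exact-beta fallback, scaled to join the closed form continuously
        # at the domain edge so the axis stays strictly monotone
        q_grid, beta_grid = _koizumi_axis_interpolator(cfg)
        beta_edge = 2.0 * KOIZUMI_DOMAIN_MAX_FS_RATIO
        seam = q_koizumi(beta_edge) / np.interp(beta_edge, beta_grid, q_grid)
        q[outside] = seam * np.interp(beta[outside], beta_grid, q_grid)
    return mz_from_q(1.0, cfg) / q  # mz_from_q(q) = const/q


def first_pass_axis(spec: Spectrum2D, cfg: InstrumentConfig | None = None,
                    method: str = "eq5") -> Spectrum2D:
    """Assign the first-pass precursor m/z axis (identity calibration).

    Rows whose m/z falls outside the nominal band (including row 0, whose
    f_e = 0 maps above it) are set to NaN sentinels but kept.
    """
    cfg = cfg or spec.instrument
    mz = _first_pass_mz(spec.fe_axis, cfg, method)
    axis = mz.copy()
    axis[(mz < MZ_BAND[0]) | (mz > MZ_BAND[1])] = np.nan
    fit = CalibrationFit(k0=calibration_k0(cfg), k1=calibration_k1(cfg))
    return _dc_replace(
        spec,
        precursor_axis=axis,
        first_pass=mz,
        axis_method=method,
        calibration=fit,
    )


# ---------------------------------------------------------------------------
# Peak picking
# ---------------------------------------------------------------------------

def _column_noise(magnitude: np.ndarray) -> np.ndarray:
    """Per-column noise scale: 1.4826 x median absolute deviation."""
    med = np.median(magnitude, axis=0)
    sigma = 1.4826 * np.median(np.abs(magnitude - med), axis=0)
    floor = 1e-12 * (magnitude.max() if magnitude.size else 1.0) + 1e-300
    return np.maximum(sigma, floor)


def _centroid_7pt(values: np.ndarray, weights: np.ndarray, apex: int):
    """Intensity-weighted mean of apex +/- 3 entries, NaN entries skipped."""
    lo = max(apex - 3, 0)
    hi = min(apex + 4, len(values))
    v = values[lo:hi]
    w = weights[lo:hi]
    ok = np.isfinite(v) & (w > 0)
    if not np.any(ok):
        return float(values[apex])
    return float(np.sum(v[ok] * w[ok]) / np.sum(w[ok]))


def pick_peaks(spec: Spectrum2D, snr_threshold: float = 5.0,
               neighborhood: int = 3, min_sep_rows: int = 6,
               autocorr_tol_ppm: float = 5000.0) -> list[Peak2D]:
    """Detect 2D peaks: local maxima above a per-column SNR threshold.

    Noise is estimated per column (1.4826 x MAD), so the elevated floor of
    a vertical streak under an intense precursor raises that column's
    threshold — streak artifacts are suppressed by the local-maximum + SNR
    rule rather than by a global cut.  Candidate maxima touching each
    other (a peak split across adjacent product bins) are merged, and
    within each column weaker maxima closer than ``min_sep_rows`` rows to
    a stronger one are dropped — with zero-fill-once the rectangular
    window's sidelobes sit a fixed ~3 rows out, independent of the index
    count.  Each surviving peak's precursor coordinate is refined with a
    7-point centroid (apex row +/- 3) in precursor m/z coordinates; NaN
    sentinel rows contribute nothing.
    """
    from scipy.ndimage import label as _label

    mag = spec.magnitude
    sigma = _column_noise(mag)
    snr = mag / sigma[None, :]
    local_max = (mag == maximum_filter(mag, size=neighborhood, mode="nearest"))
    candidates = local_max & (snr >= snr_threshold) & (mag > 0)
    # merge touching candidates (plateaus / peaks split across bin edges):
    # keep each connected component's strongest cell, strongest first
    labels, _ = _label(candidates, structure=np.ones((3, 3), dtype=int))
    rr, cc = np.nonzero(candidates)
    order = np.argsort(-mag[rr, cc])
    seen: set[int] = set()
    apexes = []
    for i in order:
        lab = int(labels[rr[i], cc[i]])
        if lab not in seen:
            seen.add(lab)
            apexes.append((int(rr[i]), int(cc[i])))
    # sidelobe suppression against stronger peaks in the same or adjacent
    # product column: an absolute exclusion zone of min_sep_rows, plus a
    # height test against the rectangular-window sidelobe envelope
    # ~ 2/(pi d) at a row offset d (zero-fill-once units)
    kept_by_col: dict[int, list[tuple[int, float]]] = {}
    kept = []
    for r, c in apexes:
        h = mag[r, c]
        shadowed = False
        for cc in (c - 1, c, c + 1):
            for r2, h2 in kept_by_col.get(cc, ()):
                d = abs(r - r2)
                if d <= min_sep_rows:
                    shadowed = True
                elif d <= 40 and h < 2.0 * (2.0 / (math.pi * d)) * h2:
                    shadowed = True
                if shadowed:
                    break
            if shadowed:
                break
        if shadowed:
            continue
        kept_by_col.setdefault(c, []).append((r, h))
        kept.append((r, c))
    peaks: list[Peak2D] = []
    pre_axis = (spec.precursor_axis if spec.precursor_axis is not None
                else np.full(spec.n_rows, np.nan))
    for r, c in kept:
        col = mag[:, c]
        fe_c = _centroid_7pt(spec.fe_axis, col, r)
        mz_c = _centroid_7pt(pre_axis, col, r)
        pmz = float(spec.product_axis[c])
        on_diag = bool(
            np.isfinite(mz_c)
            and abs(mz_c - pmz) <= autocorr_tol_ppm * 1e-6 * pmz
        )
        peaks.append(Peak2D(
            product_mz=pmz,
            precursor_mz=mz_c,
            fe=fe_c,
            height=float(mag[r, c]),
            snr=float(snr[r, c]),
            on_autocorrelation=on_diag,
            row=int(r), col=int(c),
        ))
    peaks.sort(key=lambda p: p.height, reverse=True)
    return peaks


def detect_autocorrelation_peaks(spec: Spectrum2D, tol_ppm: float = 5000.0,
                                 snr_threshold: float = 5.0):
    """Calibration pairs (f_e, product m/z) from diagonal precursor peaks.

    A peak lies on the autocorrelation line when its first-pass precursor
    m/z matches its product m/z within ``tol_ppm`` (generous by default —
    the first pass may carry percent-level error before recalibration).
    Harmonic peaks are flagged first and excluded, so a modulation
    harmonic that happens to fall near the diagonal cannot pollute the
    calibration.  The ToF-accurate product m/z is taken as ground truth.
    """
    if spec.precursor_axis is None:
        raise ValueError("assign a first-pass axis before peak detection")
    peaks = pick_peaks(spec, snr_threshold=snr_threshold)
    fe_bin = (float(spec.fe_axis[1] - spec.fe_axis[0])
              if len(spec.fe_axis) > 1 else 1.0)
    flag_harmonics(peaks, fe_bin)
    pairs = []
    for p in peaks:
        if p.harmonic_order > 1 or not np.isfinite(p.precursor_mz):
            continue
        if abs(p.precursor_mz - p.product_mz) <= tol_ppm * 1e-6 * p.product_mz:
            pairs.append((p.fe, p.product_mz))
    if not pairs:
        raise ValueError(
            "no autocorrelation-line peaks found: calibration impossible"
        )
    return pairs


def recalibrate(spec: Spectrum2D, pairs, order: int = 1) -> Spectrum2D:
    """Remap the precursor axis with a polynomial fit in the first-pass mass.

    ``pairs`` are (f_e, known precursor m/z) calibrants, typically from
    :func:`detect_autocorrelation_peaks`.  The polynomial is fit in the
    spectrum's own first-pass mass (eq5 or eq6, whichever produced the
    axis), so the correction absorbs both beta-approximation curvature and
    any trap-amplitude scale error.
    """
    if spec.first_pass is None:
        raise ValueError("assign a first-pass axis before recalibrating")
    if order not in (1, 2, 3):
        raise ValueError("calibration order must be 1, 2 or 3")
    pairs = np.asarray(pairs, dtype=float)
    if len(pairs) < order + 2:
        raise ValueError(f"need at least {order + 2} pairs for order {order}")
    cfg = spec.instrument
    x = _first_pass_mz(pairs[:, 0], cfg, spec.axis_method)
    design = np.vander(x, order + 1, increasing=True)
    if np.linalg.matrix_rank(design) < order + 1:
        raise np.linalg.LinAlgError("rank-deficient calibration design matrix")
    coeffs, *_ = np.linalg.lstsq(design, pairs[:, 1], rcond=None)
    resid = design @ coeffs - pairs[:, 1]
    fit = CalibrationFit(
        k0=calibration_k0(cfg),
        k1=calibration_k1(cfg),
        poly_coeffs=list(coeffs),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        order=order,
    )
    new_axis = np.polynomial.polynomial.polyval(spec.first_pass, coeffs)
    axis = np.where(
        (new_axis >= MZ_BAND[0]) & (new_axis <= MZ_BAND[1]), new_axis, np.nan
    )
    return _dc_replace(spec, precursor_axis=axis, calibration=fit)


def flag_harmonics(peaks: list[Peak2D], fe_bin: float,
                   tol_bins: float = 1.5, product_tol: float | None = None,
                   max_order: int = 5) -> list[Peak2D]:
    """Label peaks sitting at integer multiples of a stronger peak's f_e.

    A peak at (f_e, product m/z) whose frequency is k x that of a stronger
    peak in the same product column (k >= 2, within ``tol_bins`` frequency
    bins) is a modulation-distortion harmonic, not an independent
    precursor; it gets ``harmonic_order = k`` (times the parent's order,
    so a harmonic of a harmonic is labelled by its total multiple).
    Multiples beyond the 0.5 cycles/index Nyquist limit fold back into the
    band and are matched at their aliased frequency.
    """
    if product_tol is None:
        prods = sorted({p.product_mz for p in peaks})
        product_tol = 5e-4 * (prods[-1] if prods else 1.0)
    # group by product m/z so only peaks sharing a product column compete
    groups: dict[int, list[Peak2D]] = {}
    for p in peaks:
        groups.setdefault(round(p.product_mz / max(product_tol, 1e-12)), []).append(p)
    for key, members in groups.items():
        near = members + groups.get(key - 1, []) + groups.get(key + 1, [])
        near.sort(key=lambda p: p.height, reverse=True)
        for i, p in enumerate(near):
            if p not in members:
                continue
            for stronger in near[:i]:
                if (stronger.height <= p.height or stronger.fe <= 0
                        or abs(stronger.product_mz - p.product_mz) > product_tol):
                    continue
                for k in range(2, max_order + 1):
                    # multiples above Nyquist fold back into [0, 0.5]
                    folded = abs(((k * stronger.fe + 0.5) % 1.0) - 0.5)
                    if abs(p.fe - folded) <= tol_bins * fe_bin:
                        p.harmonic_order = k * stronger.harmonic_order
                        break
                if p.harmonic_order > 1:
                    break
    return peaks


# ---------------------------------------------------------------------------
# Slices
# ---------------------------------------------------------------------------

def slice_horizontal(spec: Spectrum2D, precursor_mz: float,
                     half_width: int = 0):
    """Product-ion spectrum of one precursor (rows nearest the m/z, summed).

    Equivalent to the MS/MS spectrum that a targeted isolation of this
    precursor would have produced.
    """
    if spec.precursor_axis is None:
        raise ValueError("precursor axis not assigned")
    finite = spec.precursor_axis[np.isfinite(spec.precursor_axis)]
    if (not len(finite)) or not (finite.min() <= precursor_mz <= finite.max()):
        raise ValueError(f"precursor m/z {precursor_mz:g} outside axis range")
    r = spec.row_nearest(precursor_mz)
    lo = max(r - half_width, 0)
    hi = min(r + half_width + 1, spec.n_rows)
    return spec.product_axis.copy(), spec.magnitude[lo:hi].sum(axis=0)


def slice_vertical(spec: Spectrum2D, product_mz: float, tol: float = 0.0):
    """Precursor scan of one product ion (columns within ``tol``, summed)."""
    axis = spec.product_axis
    if not axis.min() <= product_mz <= axis.max():
        raise ValueError(f"product m/z {product_mz:g} outside axis range")
    if tol <= 0:
        cols = [spec.column_nearest(product_mz)]
    else:
        cols = np.nonzero(np.abs(axis - product_mz) <= tol)[0]
    pre = (spec.precursor_axis if spec.precursor_axis is not None
           else spec.fe_axis)
    return pre.copy(), spec.magnitude[:, cols].sum(axis=1)


def autocorrelation_spectrum(spec: Spectrum2D):
    """Intensity along the diagonal precursor m/z = product m/z.

    An MS1-like precursor spectrum: every intact species appears here, but
    intensities also reflect how much of each precursor survived
    fragmentation, not abundance alone.
    """
    if spec.precursor_axis is None:
        raise ValueError("precursor axis not assigned")
    ok = np.isfinite(spec.precursor_axis)
    pre = spec.precursor_axis[ok]
    mag = spec.magnitude[ok, :]
    order = np.argsort(pre)
    pre_sorted = pre[order]
    diag = np.zeros(len(spec.product_axis))
    for j, m in enumerate(spec.product_axis):
        if pre_sorted[0] <= m <= pre_sorted[-1]:
            diag[j] = np.interp(m, pre_sorted, mag[order, j])
    return spec.product_axis.copy(), diag


def resolving_power(spec: Spectrum2D, product_mz: float) -> float:
    """Precursor-axis resolving power M/dM (FWHM definition) of the
    strongest peak in the column nearest ``product_mz``.

    The half-maximum crossings are located by linear interpolation in row
    space and converted to m/z through the precursor axis; with 1024
    indices, zero-fill once and a rectangular window this lands near the
    ~100 figure set by the number of modulation steps.
    """
    if spec.precursor_axis is None:
        raise ValueError("assign a precursor axis first")
    col = spec.magnitude[:, spec.column_nearest(product_mz)]
    apex = int(np.argmax(col))
    half = col[apex] / 2.0

    def crossing(direction: int) -> float:
        i = apex
        while 0 <= i + direction < len(col) and col[i + direction] > half:
            i += direction
        j = i + direction
        if not 0 <= j < len(col):
            raise ValueError("half-maximum crossing outside the spectrum")
        frac = (col[i] - half) / (col[i] - col[j])
        return i + direction * frac

    rows = np.arange(spec.n_rows, dtype=float)
    ok = np.isfinite(spec.precursor_axis)
    lo_r, hi_r = crossing(-1), crossing(+1)
    mz_hi = np.interp(lo_r, rows[ok], spec.precursor_axis[ok])
    mz_lo = np.interp(hi_r, rows[ok], spec.precursor_axis[ok])
    apex_mz = float(np.interp(apex, rows[ok], spec.precursor_axis[ok]))
    return apex_mz / (mz_hi - mz_lo)


def plot_contour(spec: Spectrum2D, ax=None, threshold_snr: float = 3.0,
                 **contour_kw):  # pragma: no cover - display helper
    """Minimal contour-map display helper (thresholded at 3 x noise)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sigma = float(np.median(_column_noise(spec.magnitude)))
    z = np.where(spec.magnitude > threshold_snr * sigma, spec.magnitude, 0.0)
    y = (spec.precursor_axis if spec.precursor_axis is not None
         else spec.fe_axis)
    ok = np.isfinite(y)
    ax.contourf(spec.product_axis, y[ok], z[ok, :], **contour_kw)
    ax.set_xlabel("product m/z")
    ax.set_ylabel("precursor m/z" if spec.precursor_axis is not None
                  else "encoding frequency (cycles/index)")
    return ax
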