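"""Secular-frequency calculus and the autocorrelation-line calibration.

This module holds every conversion among mass-to-charge, the Mathieu
stability parameter ``q``, the characteristic exponent ``beta``, the secular
frequency ``f_s = beta * f_trap / 2``, and the SWIM encoding frequency

    f_e = (f_s - f_min) / (2 (f_max - f_min))        (cycles per index)

which spans [0, 0.5] — the Nyquist interval for one spectrum per index.
Because ``q`` is linear in charge over mass, the encoding frequency is a
reciprocal function of m/z,

    m/z = k1 / (f_e + k0),   k0 = f_min / (2 (f_max - f_min)),

which is the first-pass mass axis; residual error (field imperfections,
beta approximations, uncertain trap amplitude) is removed by fitting a
low-order polynomial in the first-pass mass to known precursor masses on
the autocorrelation line (:func:`fit_calibration`).

Three beta(q) treatments are available:

``dehmelt``
    The adiabatic approximation ``beta = q / sqrt(2)``, adequate below
    q ~ 0.4, and the model behind the closed-form first-pass axis.
``koizumi``
    A closed form accurate over the whole stability region, obtained from
    the three-term harmonic-balance truncation of the Mathieu continued
    fraction:  q^2 = beta^2 (4 - beta^2)^2 / (8 + 2 beta^2).  It is exact
    in the small-q limit and within 0.3% of the exact exponent for
    q <= 0.5.  The closed direction is beta -> q, i.e. secular frequency
    to m/z, which is precisely the decoding use case.  Its validity domain
    is capped at f_s / f_trap = arccos(-11/14) / (2 pi) ~ 0.394; beyond
    that the exact-beta numeric inversion takes over.
``exact``
    The continued-fraction characteristic exponent, truncated when terms
    fall below 1e-12; serves as the oracle for both approximations.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import constants as _const
from scipy.optimize import brentq

from .config import InstrumentConfig

__all__ = [
    "Q_MAX",
    "KOIZUMI_DOMAIN_MAX_FS_RATIO",
    "DEHMELT_Q_LIMIT",
    "SecularPoint",
    "CalibrationFit",
    "mathieu_q",
    "mz_from_q",
    "beta_exact",
    "beta_dehmelt",
    "beta_koizumi",
    "q_koizumi",
    "secular_frequency",
    "encoding_frequency",
    "encoding_from_mz",
    "mz_from_encoding",
    "calibration_k0",
    "calibration_k1",
    "fit_calibration",
]

#: First stability region boundary for a = 0.
Q_MAX = 0.908

#: Above this q the Dehmelt approximation is considered unreliable.
DEHMELT_Q_LIMIT = 0.4

#: Validity cap of the closed-form (koizumi) m/z conversion, expressed as
#: f_s / f_trap; beyond it :func:`mz_from_encoding` falls back to exact-beta
#: numeric inversion.
KOIZUMI_DOMAIN_MAX_FS_RATIO = math.acos(-11.0 / 14.0) / (2.0 * math.pi)

_E = _const.e
_U = _const.u


class UnstableIonError(ValueError):
    """Raised when a species falls outside the q < 0.908 stability region."""


class KoizumiDomainError(ValueError):
    """Raised when a secular frequency lies outside the closed-form domain."""


# ---------------------------------------------------------------------------
# Mathieu parameter and beta treatments
# ---------------------------------------------------------------------------

def mathieu_q(mz: float, cfg: InstrumentConfig) -> float:
    """Mathieu stability parameter for a species of mass-to-charge ``mz`` (Th).

    q = e V_trap / (pi^2 (m/z) u r0^2 f_trap^2) with V_trap zero-to-peak;
    the charge count cancels because only m/z enters.

    Raises
    ------
    UnstableIonError
        If q >= 0.908 (outside the first stability region; the ion is
        ejected rather than trapped).
    """
    mz = float(mz)
    if mz <= 0:
        raise ValueError("mz must be positive")
    q = _E * cfg.V_trap / (math.pi**2 * mz * _U * cfg.r0**2 * cfg.f_trap**2)
    if q >= Q_MAX:
        raise UnstableIonError(
            f"q = {q:.4f} >= {Q_MAX} for m/z {mz:g}: ion unstable/ejected"
        )
    return q


def mz_from_q(q: float, cfg: InstrumentConfig) -> float:
    """Inverse of :func:`mathieu_q` (no stability check)."""
    return _E * cfg.V_trap / (math.pi**2 * q * _U * cfg.r0**2 * cfg.f_trap**2)


def beta_dehmelt(q: float) -> float:
    """Adiabatic (Dehmelt) approximation beta = q/sqrt(2), valid for q < 0.4."""
    return q / math.sqrt(2.0)


def q_koizumi(beta: float) -> float:
    """Closed-form q(beta) from the three-term harmonic-balance truncation.

    q^2 = beta^2 (4 - beta^2)^2 / (8 + 2 beta^2); exact as beta -> 0 and
    within 0.3% of the exact exponent for q <= 0.5.
    """
    b2 = beta * beta
    return beta * (4.0 - b2) / math.sqrt(8.0 + 2.0 * b2)


def beta_koizumi(q: float) -> float:
    """Invert :func:`q_koizumi` numerically (monotone on 0 < beta < 1)."""
    if q == 0.0:
        return 0.0
    return brentq(lambda b: q_koizumi(b) - q, 0.0, 1.0, xtol=1e-14, rtol=8.9e-16)


def _cf_tail(beta: float, q: float, sign: int, tol: float = 1e-12) -> float:
    # Evaluate q^2/((2+sb)^2 - q^2/((4+sb)^2 - ...)) bottom-up, growing the
    # depth until the truncated term is below tol.
    depth = 10
    prev = None
    while True:
        val = 0.0
        for k in range(depth, 0, -1):
            val = q * q / ((2.0 * k + sign * beta) ** 2 - val)
        if prev is not None and abs(val - prev) < tol:
            return val
        prev = val
        depth += 10
        if depth > 400:  # pragma: no cover - safety net
            return val


def beta_exact(q: float, tol: float = 1e-12, max_iter: int = 500) -> float:
    """Continued-fraction characteristic exponent for a = 0 (oracle).

    Fixed-point iteration of beta^2 = S(+beta) + S(-beta) where S is the
    standard continued-fraction tail, truncated when terms < ``tol``.
    """
    if q == 0.0:
        return 0.0
    if not 0.0 < q < Q_MAX:
        raise UnstableIonError(f"q = {q} outside the first stability region")
    b = q / math.sqrt(2.0)
    for _ in range(max_iter):
        b2 = _cf_tail(b, q, +1, tol) + _cf_tail(b, q, -1, tol)
        bn = math.sqrt(b2)
        if abs(bn - b) < 1e-14:
            return bn
        b = bn
    return b  # pragma: no cover


_BETA_FUNCS = {
    "dehmelt": beta_dehmelt,
    "koizumi": beta_koizumi,
    "exact": beta_exact,
}


# ---------------------------------------------------------------------------
# Frequency maps
# ---------------------------------------------------------------------------

def secular_frequency(mz: float, cfg: InstrumentConfig, method: str = "dehmelt") -> float:
    """Secular frequency f_s = beta f_trap / 2 (Hz) for a stable species.

    ``method`` selects the beta(q) treatment ("dehmelt", "koizumi" or
    "exact").  A warning is issued when the Dehmelt approximation is used
    beyond its q < 0.4 comfort zone.
    """
    q = mathieu_q(mz, cfg)
    if method == "dehmelt" and q >= DEHMELT_Q_LIMIT:
        warnings.warn(
            f"Dehmelt approximation applied at q = {q:.3f} >= {DEHMELT_Q_LIMIT}",
            stacklevel=2,
        )
    try:
        beta = _BETA_FUNCS[method](q)
    except KeyError:
        raise ValueError(f"unknown beta method {method!r}") from None
    return beta * cfg.f_trap / 2.0


def encoding_frequency(f_s: float, cfg: InstrumentConfig) -> float:
    """SWIM encoding frequency (cycles/index; Hz at a 1 Hz index rate).

    f_e = (f_s - f_min) / (2 (f_max - f_min)), mapping the excitation band
    onto [0, 0.5] with f_max at the Nyquist limit.
    """
    if not cfg.f_min <= f_s <= cfg.f_max:
        raise ValueError(
            f"secular frequency {f_s:g} Hz outside SWIM band "
            f"[{cfg.f_min:g}, {cfg.f_max:g}]"
        )
    return (f_s - cfg.f_min) / (2.0 * cfg.band_width)


def secular_from_encoding(f_e: float, cfg: InstrumentConfig) -> float:
    """Invert the encoding map: f_s = 2 f_e (f_max - f_min) + f_min."""
    if not 0.0 <= f_e <= 0.5:
        raise ValueError(f"encoding frequency {f_e} outside [0, 0.5]")
    return 2.0 * f_e * cfg.band_width + cfg.f_min


def encoding_from_mz(mz: float, cfg: InstrumentConfig, method: str = "dehmelt") -> float:
    """Expected encoding frequency of a precursor (cycles/index).

    With the default Dehmelt beta this is the closed Eq-5-style map, linear
    in charge over mass: f_e + k0 = k1 / (m/z).
    """
    return encoding_frequency(secular_frequency(mz, cfg, method=method), cfg)


def mz_from_encoding(
    f_e: float,
    cfg: InstrumentConfig,
    method: str = "koizumi",
    *,
    strict: bool = False,
) -> float:
    """Convert an encoding frequency back to precursor m/z (Th).

    ``method="dehmelt"`` inverts the reciprocal first-pass form directly.
    ``method="koizumi"`` (default) uses the closed-form q(beta), accurate
    at high q (low m/z); outside its validity domain
    (f_s/f_trap > arccos(-11/14)/2pi) it falls back to exact-beta numeric
    inversion, or raises :class:`KoizumiDomainError` when ``strict``.
    ``method="exact"`` numerically inverts the continued-fraction exponent.
    """
    f_s = secular_from_encoding(f_e, cfg)
    if method == "dehmelt":
        beta = 2.0 * f_s / cfg.f_trap
        return mz_from_q(math.sqrt(2.0) * beta, cfg)
    if method == "koizumi":
        if f_s / cfg.f_trap > KOIZUMI_DOMAIN_MAX_FS_RATIO:
            if strict:
                raise KoizumiDomainError(
                    f"f_s/f_trap = {f_s / cfg.f_trap:.4f} > "
                    f"{KOIZUMI_DOMAIN_MAX_FS_RATIO:.4f}: outside Koizumi domain"
                )
            method = "exact"
        else:
            beta = 2.0 * f_s / cfg.f_trap
            return mz_from_q(q_koizumi(beta), cfg)
    if method == "exact":
        beta_target = 2.0 * f_s / cfg.f_trap

        def err(q: float) -> float:
            return beta_exact(q) - beta_target

        q = brentq(err, 1e-12, Q_MAX - 1e-9, xtol=1e-15, rtol=8.9e-16)
        return mz_from_q(q, cfg)
    raise ValueError(f"unknown method {method!r}")


def calibration_k0(cfg: InstrumentConfig) -> float:
    """Frequency offset k0 = f_min / (2 (f_max - f_min)), cycles/index."""
    return cfg.f_min / (2.0 * cfg.band_width)


def calibration_k1(cfg: InstrumentConfig) -> float:
    """Reciprocal-axis scale k1 (Th * cycles/index): m/z = k1/(f_e + k0).

    k1 = e V_trap / (4 sqrt(2) pi^2 u r0^2 f_trap (f_max - f_min)) under the
    Dehmelt beta.
    """
    return _E * cfg.V_trap / (
        4.0 * math.sqrt(2.0) * math.pi**2 * _U * cfg.r0**2 * cfg.f_trap * cfg.band_width
    )


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SecularPoint:
    """Snapshot of one species' trap/encoding coordinates."""

    mz: float
    z: int
    q: float
    beta: float
    f_s: float
    f_e: float

    @classmethod
    def from_mz(
        cls, mz: float, cfg: InstrumentConfig, z: int = 1, method: str = "dehmelt"
    ) -> "SecularPoint":
        q = mathieu_q(mz, cfg)
        beta = _BETA_FUNCS[method](q)
        f_s = beta * cfg.f_trap / 2.0
        f_e = encoding_frequency(f_s, cfg)
        return cls(mz=mz, z=z, q=q, beta=beta, f_s=f_s, f_e=f_e)

    @property
    def dehmelt_valid(self) -> bool:
        return self.q < DEHMELT_Q_LIMIT


@dataclass
class CalibrationFit:
    """Polynomial recalibration of the reciprocal first-pass mass axis.

    The model is m/z = sum_j c_j * x^j with x = k1/(f_e + k0) the
    first-pass mass; an identity fit has coefficients [0, 1].
    """

    k0: float
    k1: float
    poly_coeffs: list = field(default_factory=lambda: [0.0, 1.0])
    residual_rms: float = 0.0
    order: int = 1

    def first_pass(self, f_e):
        return self.k1 / (np.asarray(f_e, dtype=float) + self.k0)

    def apply(self, f_e):
        """Calibrated precursor m/z for encoding frequency ``f_e``."""
        x = self.first_pass(f_e)
        return np.polynomial.polynomial.polyval(x, np.asarray(self.poly_coeffs))

    def apply_first_pass(self, x):
        """Calibrated m/z from an already-computed first-pass mass."""
        return np.polynomial.polynomial.polyval(
            np.asarray(x, dtype=float), np.asarray(self.poly_coeffs)
        )

    # -- serialization ------------------------------------------------------

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)

    @classmethod
    def from_json(cls, s: str) -> "CalibrationFit":
        return cls(**json.loads(s))


def fit_calibration(pairs, order: int, cfg: InstrumentConfig) -> CalibrationFit:
    """Least-squares polynomial recalibration from (f_e, known m/z) pairs.

    The polynomial is fit in the first-pass mass k1/(f_e + k0) — not in
    f_e — mirroring the modified calibration form
    (m/z)_precursor = c1 (k1/(f_e + k0)) + c0 and its higher-order
    extensions.

    Parameters
    ----------
    pairs : sequence of (f_e, mz_known)
        Autocorrelation-line calibrants; f_e values must be distinct.
    order : int
        Polynomial order, 1-3.
    cfg : InstrumentConfig
        Supplies k0 and k1.
    """
    if order not in (1, 2, 3):
        raise ValueError("calibration order must be 1, 2 or 3")
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (f_e, mz_known)")
    if len(pairs) < order + 2:
        raise ValueError(f"need at least {order + 2} pairs for an order-{order} fit")
    fe, mz_known = pairs[:, 0], pairs[:, 1]
    if len(np.unique(fe)) < len(fe):
        raise ValueError("f_e values must be distinct")
    k0 = calibration_k0(cfg)
    k1 = calibration_k1(cfg)
    x = k1 / (fe + k0)
    design = np.vander(x, order + 1, increasing=True)
    rank = np.linalg.matrix_rank(design)
    if rank < order + 1:
        raise np.linalg.LinAlgError("rank-deficient calibration design matrix")
    coeffs, *_ = np.linalg.lstsq(design, mz_known, rcond=None)
    resid = design @ coeffs - mz_known
    return CalibrationFit(
        k0=k0,
        k1=k1,
        poly_coeffs=list(coeffs),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        order=order,
    )
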