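"""SWIM excitation-pulse synthesis.

A stored-waveform ion radius modulation (SWIM) sequence is a set of
broadband excitation pulses indexed by n.  In the frequency domain the
magnitude at in-band frequency f of pulse n is

    M(f, n) = 1/2 (1 + sin(n pi (f - f_min)/(f_max - f_min) - pi/2)),

so the amplitude seen by an ion of secular frequency f_s varies
sinusoidally with n — that per-frequency modulation rate is the encoding
frequency.  A quadratic phase spreads the pulse energy over a window of
width ~T so the DAC and amplifier dynamic-range demands stay modest; the
time-domain pulse is the real part of the inverse Fourier transform of
M e^{i phi}.

Two phase conventions are provided.  The adopted one normalizes the
quadratic phase so the group delay (1/2pi) dphi/df runs from 0 at f_min to
T at f_max, matching the stated temporal localization of the excitation;
the literal form phi = T (f - f_min)^2 / (f_max - f_min) (dimensionally
s*Hz, i.e. missing a 2pi-scale) is kept behind ``phase="literal"`` for
cross-checks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import InstrumentConfig

__all__ = [
    "SwimPulse",
    "magnitude_profile",
    "quadratic_phase",
    "synthesize_pulse",
    "pulse_sequence",
    "amplitude_scale",
    "export_pulse",
]


@dataclass(frozen=True)
class SwimPulse:
    """One time-domain SWIM excitation waveform.

    Attributes
    ----------
    n : int
        SWIM index; the n = 0 pulse is identically zero (no excitation).
    samples : numpy.ndarray
        Real amplitude series, volts.
    sample_rate : float
        Samples per second.
    """

    n: int
    samples: np.ndarray
    sample_rate: float

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate

    @property
    def energy(self) -> float:
        """Sum of squared samples (V^2 * sample)."""
        return float(np.dot(self.samples, self.samples))

    def inverted(self) -> "SwimPulse":
        """Polarity-inverted twin (the opposing-rod drive)."""
        return SwimPulse(n=self.n, samples=-self.samples, sample_rate=self.sample_rate)


def _check_band(f, cfg: InstrumentConfig) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if np.any(f < cfg.f_min) or np.any(f > cfg.f_max):
        raise ValueError(
            f"frequency outside SWIM band [{cfg.f_min:g}, {cfg.f_max:g}] Hz"
        )
    return f


def magnitude_profile(f, n: int, cfg: InstrumentConfig):
    """Spectral magnitude M(f, n) in [0, 1] of SWIM pulse n at frequency f.

    Vanishes identically at n = 0 and at f = f_min; at fixed f the sequence
    over n is a sampled sinusoid whose frequency is the encoding frequency
    of f.
    """
    f = _check_band(f, cfg)
    if n < 0:
        raise ValueError("pulse index n must be >= 0")
    x = (f - cfg.f_min) / cfg.band_width
    m = 0.5 * (1.0 + np.sin(n * np.pi * x - np.pi / 2.0))
    return m if m.ndim else float(m)


def quadratic_phase(f, cfg: InstrumentConfig, convention: str = "group-delay"):
    """Quadratic spreading phase phi(f), radians.

    ``convention="group-delay"`` (default): phi = pi T (f - f_min)^2 / (f_max
    - f_min), whose group delay (1/2pi) dphi/df rises linearly from 0 at
    f_min to T at f_max.  ``convention="literal"`` evaluates the bare
    T (f - f_min)^2/(f_max - f_min) form for cross-checking.
    """
    f = _check_band(f, cfg)
    base = (f - cfg.f_min) ** 2 / cfg.band_width
    if convention == "group-delay":
        phi = math.pi * cfg.T * base
    elif convention == "literal":
        phi = cfg.T * base
    else:
        raise ValueError(f"unknown phase convention {convention!r}")
    return phi if np.ndim(phi) else float(phi)


def _spectrum(n: int, cfg: InstrumentConfig):
    """Frequency-domain prescription P_M(f, n) on the DFT grid of the pulse."""
    n_samp = cfg.n_samples
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / cfg.dac_rate)
    in_band = (freqs >= cfg.f_min) & (freqs <= cfg.f_max)
    spec = np.zeros(len(freqs), dtype=complex)
    fb = freqs[in_band]
    # e^{-i phi} under numpy's inverse-FFT sign convention delays each
    # frequency by the (positive) group delay (1/2pi) dphi/df
    spec[in_band] = magnitude_profile(fb, n, cfg) * np.exp(
        -1j * quadratic_phase(fb, cfg)
    )
    return freqs, spec


def amplitude_scale(cfg: InstrumentConfig) -> float:
    """Volts-per-unit scale giving ``cfg.amplitude`` V zero-peak at the
    maximum-band-mean index.

    The band-integrated magnitude is essentially index-independent for
    n >= 1, so the n = 2 pulse (mid-band maximum) serves as the reference;
    the scale is chosen once per config so its peak sample reaches the
    configured amplitude.
    """
    _, spec = _spectrum(2, cfg)
    raw = np.fft.irfft(spec, n=cfg.n_samples)
    peak = np.max(np.abs(raw))
    if peak == 0.0:
        return 1.0
    return cfg.amplitude / peak


def synthesize_pulse(
    n: int, cfg: InstrumentConfig, scale: float | None = None
) -> SwimPulse:
    """Synthesize the index-n SWIM pulse.

    The magnitude prescription is laid on the DFT grid of the pulse window
    (uniform spacing 1/pulse_duration), zero outside [f_min, f_max], the
    quadratic phase applied, and the real inverse FFT taken.  ``scale``
    overrides the per-config amplitude normalization (useful when
    synthesizing many pulses: compute :func:`amplitude_scale` once).
    """
    if n < 0:
        raise ValueError("pulse index n must be >= 0")
    if cfg.dac_rate < 2.0 * cfg.f_max:
        raise ValueError(
            f"dac_rate {cfg.dac_rate:g} < 2*f_max {2 * cfg.f_max:g}: "
            "band would alias"
        )
    if scale is None:
        scale = amplitude_scale(cfg)
    _, spec = _spectrum(n, cfg)
    samples = np.fft.irfft(spec, n=cfg.n_samples) * scale
    return SwimPulse(n=n, samples=samples, sample_rate=cfg.dac_rate)


def pulse_sequence(cfg: InstrumentConfig, n_indices: int | None = None):
    """The ordered SWIM sequence, n = 0 .. n_indices - 1 (deterministic).

    The n = 0 entry is the unexcited pulse; acquisition covers
    ``cfg.n_indices`` indices by default.
    """
    count = cfg.n_indices if n_indices is None else int(n_indices)
    scale = amplitude_scale(cfg)
    return [synthesize_pulse(n, cfg, scale=scale) for n in range(count)]


def export_pulse(pulse: SwimPulse, path, cfg: InstrumentConfig | None = None,
                 fmt: str = "f32") -> None:
    """Write one pulse to disk with a JSON sidecar.

    ``fmt="f32"`` writes little-endian 32-bit float raw samples;
    ``fmt="txt"`` writes two columns (t, V).
    """
    path = Path(path)
    if fmt == "f32":
        pulse.samples.astype("<f4").tofile(path)
    elif fmt == "txt":
        np.savetxt(path, np.column_stack([pulse.times, pulse.samples]))
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    sidecar = {
        "n": pulse.n,
        "sample_rate": pulse.sample_rate,
        "n_samples": len(pulse.samples),
        "format": fmt,
    }
    if cfg is not None:
        sidecar["instrument"] = cfg.to_dict()
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
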