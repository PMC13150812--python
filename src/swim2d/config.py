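"""Instrument and acquisition configuration.

The :class:`InstrumentConfig` collects everything that describes the
SWIM-enabled quadrupole trap: the RF trapping waveform (frequency and
zero-to-peak amplitude), the field radius, the excitation band swept by the
stored-waveform pulses, and the acquisition bookkeeping (number of SWIM
indices, spectrum-saving rate, trap-and-release fills per index).

The default field radius ``r0`` is a fixture convention: the quadrupole
radius is instrument-specific, and the shipped value was back-solved once
from the predicted substance P [M+3H]3+ encoding frequency (0.102 Hz at
m/z 449.92) under the default band and RF settings, so that absolute
frequency predictions are internally consistent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field, replace

__all__ = ["InstrumentConfig", "DEFAULT_R0"]

#: Quadrupole field radius in metres, back-solved from the substance P
#: encoding-frequency prediction (fixture convention, not a measured value).
DEFAULT_R0 = 2.895435443226416e-3


def _is_power_of_two(n: int) -> bool:
    return n > 0 and (n & (n - 1)) == 0


@dataclass(frozen=True)
class InstrumentConfig:
    """Trap, SWIM-band, and acquisition parameters.

    Parameters
    ----------
    f_trap : float
        RF trapping waveform frequency, Hz.
    V_trap : float
        RF trapping waveform amplitude, volts zero-to-peak.  The common
        peak-to-peak figure (240 Vpp on the modified instrument) corresponds
        to ``V_trap = 120``.
    r0 : float
        Quadrupole field radius, m.
    f_min, f_max : float
        Lower and upper edges of the SWIM excitation band, Hz.  Secular
        frequencies inside this band are modulated; ``f_max`` must not
        exceed the ``f_trap/2`` stability ceiling.
    T : float
        Quadratic-phase spreading width, s.  The synthesized pulse energy is
        spread over roughly this much time.
    dac_rate : float
        Waveform sample rate, samples/s.
    pulse_duration : float
        Length of each SWIM pulse (also the trap-and-release cycle time), s.
    n_indices : int
        Number of SWIM indices per acquisition (power of two).
    index_rate : float
        SWIM-index sampling rate, Hz (summed spectra saved per second).
    n_fills : int
        Trap-and-release cycles summed per SWIM index.
    amplitude : float
        Target pulse amplitude, volts zero-to-peak, used to scale the
        synthesized waveforms.
    """

    f_trap: float = 1.0e6
    V_trap: float = 120.0
    r0: float = DEFAULT_R0
    f_min: float = 10.0e3
    f_max: float = 500.0e3
    T: float = 10.0e-3
    dac_rate: float = 25.0e6
    pulse_duration: float = 20.0e-3
    n_indices: int = 1024
    index_rate: float = 1.0
    n_fills: int = 50
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.f_min < self.f_max):
            raise ValueError("require 0 < f_min < f_max")
        if self.f_max > self.f_trap / 2.0:
            raise ValueError("f_max exceeds f_trap/2 (secular frequencies cannot reach it)")
        if self.V_trap <= 0 or self.r0 <= 0 or self.T <= 0:
            raise ValueError("V_trap, r0 and T must be positive")
        if not _is_power_of_two(self.n_indices):
            raise ValueError("n_indices must be a power of two")
        if self.pulse_duration <= 0 or self.dac_rate <= 0:
            raise ValueError("pulse_duration and dac_rate must be positive")

    # -- derived quantities -------------------------------------------------

    @property
    def band_width(self) -> float:
        """SWIM band width ``f_max - f_min``, Hz."""
        return self.f_max - self.f_min

    @property
    def n_samples(self) -> int:
        """Samples per pulse at the DAC rate."""
        return int(round(self.pulse_duration * self.dac_rate))

    def acquisition_time(self) -> float:
        """Total 2D acquisition time in seconds.

        ``n_indices`` SWIM indices, each summed over ``n_fills``
        trap-and-release cycles of ``pulse_duration`` seconds.
        """
        return self.n_indices * self.n_fills * self.pulse_duration

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "InstrumentConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown InstrumentConfig fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "InstrumentConfig":
        return cls.from_dict(json.loads(s))

    def replace(self, **changes) -> "InstrumentConfig":
        return replace(self, **changes)

    @classmethod
    def from_vpp(cls, vpp: float, **kwargs) -> "InstrumentConfig":
        """Build a config from a peak-to-peak trap amplitude (halved to zero-to-peak)."""
        return cls(V_trap=vpp / 2.0, **kwargs)
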