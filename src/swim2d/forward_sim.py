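"""Signal-level forward simulator of SWIM-modulated 2D acquisitions.

Generates synthetic data cubes — one product-ion spectrum per SWIM index —
with the modulation structure of the three operating regimes:

flux-constant
    No ion losses; the ion-cloud radius is modulated, and a
    radius-dependent fragmentation step (UVPD through a coaxial Gaussian
    laser beam, or in-trap collisional activation above a threshold
    amplitude) trades precursor for fragments, so precursor + fragment
    totals are conserved and the fragment traces are 180 degrees out of
    phase with the precursor.
flux-periodic
    Above a critical excitation amplitude part of the cloud fails to exit
    the trap; transmitted flux dips once per modulation cycle.  Beam CID
    downstream fragments a fixed fraction of whatever is transmitted, so
    its fragment traces are in phase with the precursor.
mixed
    Both at once — the flux-periodic dips acquire a second, laser-overlap
    dip at the radius minimum, introducing a 2 f_e harmonic.

The cloud radius is represented by the scalar excitation amplitude
a(n) = excitation_scale * M(f_s, n) (resonant-response proxy); the
trajectory-level simulator provides the higher-fidelity cross-check.
Peaks are rendered on a ToF-like product axis as bin-integrated Gaussians
of ppm-constant width, and noise is proportional-plus-floor, matching the
observed signal-proportional noise amplitude.  Upstream photofragmentation
(ions fragmented before SWIM is applied) is emulated as a low, unmodulated
fragment baseline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy.special import erf

from .config import InstrumentConfig
from .secular import encoding_frequency, secular_frequency

__all__ = [
    "FragChannel",
    "IonSpecies",
    "SimulationConfig",
    "DataCube",
    "ISOTOPE_SPACING",
    "modulation_amplitude",
    "uvpd_survival",
    "intrap_cid_survival",
    "flux_transmission",
    "species_traces",
    "render_spectrum",
    "generate_cube",
]

#: Mean spacing between adjacent isotopologues for unit charge, Th.
ISOTOPE_SPACING = 1.003355

_MECHANISMS = ("uvpd", "intrap_cid", "beam_cid")


@dataclass(frozen=True)
class FragChannel:
    """One fragmentation channel of a precursor."""

    product_mz: float
    product_z: int = 1
    mechanism: str = "uvpd"
    max_yield: float = 0.2

    def __post_init__(self):
        if self.mechanism not in _MECHANISMS:
            raise ValueError(f"mechanism must be one of {_MECHANISMS}")
        if not 0.0 <= self.max_yield <= 1.0:
            raise ValueError("max_yield must lie in [0, 1]")
        if self.product_mz <= 0 or self.product_z < 1:
            raise ValueError("product_mz must be positive, product_z >= 1")


@dataclass(frozen=True)
class IonSpecies:
    """A precursor with isotopologues and fragmentation channels.

    ``isotopologues`` is a list of (m/z offset, relative abundance); the
    offsets are k * 1.003355 / z for the k-th heavy isotopologue and the
    relative abundances must sum to 1.
    """

    mz: float
    z: int = 1
    abundance: float = 1.0
    isotopologues: tuple = ((0.0, 1.0),)
    channels: tuple = ()
    label: str = ""

    def __post_init__(self):
        iso = tuple((float(o), float(r)) for o, r in self.isotopologues)
        object.__setattr__(self, "isotopologues", iso)
        object.__setattr__(self, "channels", tuple(self.channels))
        offsets = [o for o, _ in iso]
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise ValueError("isotopologue offsets must be strictly increasing")
        if abs(sum(r for _, r in iso) - 1.0) > 1e-9:
            raise ValueError("isotopologue relative abundances must sum to 1")
        if sum(c.max_yield for c in self.channels) > 1.0 + 1e-12:
            raise ValueError("sum of channel max_yield exceeds 1")
        mass_proxy = self.mz * self.z
        for c in self.channels:
            if c.product_mz * c.product_z > mass_proxy + 1e-9:
                raise ValueError(
                    f"fragment {c.product_mz} (+{c.product_z}) heavier than precursor"
                )

    @classmethod
    def with_isotopes(cls, mz, z, abundance, rel_abundances, channels=(), label=""):
        """Convenience constructor placing isotopologues at k*1.003355/z."""
        iso = tuple(
            (k * ISOTOPE_SPACING / z, r) for k, r in enumerate(rel_abundances)
        )
        return cls(mz=mz, z=z, abundance=abundance, isotopologues=iso,
                   channels=channels, label=label)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the signal-level simulator.

    Amplitude-domain parameters are in volts on the same scale as
    ``excitation_scale`` (the peak excitation amplitude A_exc multiplying
    the spectral magnitude M).  ``v_crit`` is the flux-periodic loss
    threshold; ``loss_depth``/``loss_width`` shape the smooth transmission
    decrease above it.  ``laser_sigma_frac`` expresses the Gaussian laser
    width as a fraction of the maximum modulated radius (amplitude scale).
    Noise coefficients follow the proportional-plus-floor model, the floor
    being relative to the cube maximum.
    """

    excitation_scale: float = 1.0
    v_crit: float = 0.5
    loss_depth: float = 0.8
    loss_width: float = 0.125
    cid_threshold: float = 0.4
    laser_sigma_frac: float = 0.35
    uvpd_pmax: float = 0.5
    beam_cid_frac: float = 0.3
    upstream_frac: float = 0.02
    noise_prop: float = 0.05
    noise_floor: float = 0.001
    peak_width_ppm: float = 20.0
    product_axis: tuple = (80.0, 1400.0, 13200)
    fs_method: str = "dehmelt"
    seed: int = 0

    def __post_init__(self):
        for name in ("uvpd_pmax", "beam_cid_frac", "upstream_frac",
                     "laser_sigma_frac", "loss_depth"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.v_crit <= 0:
            raise ValueError("v_crit must be positive (use inf for flux-constant)")
        if self.excitation_scale < 0 or self.cid_threshold < 0:
            raise ValueError("amplitudes must be non-negative")

    def replace(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["product_axis"] = list(d["product_axis"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "product_axis" in d:
            d["product_axis"] = tuple(d["product_axis"])
        return cls(**d)


@dataclass
class DataCube:
    """Per-SWIM-index product-ion spectra.

    ``intensities`` has one row per SWIM index and one column per product
    m/z bin (bin-integrated counts, arbitrary units, non-negative);
    ``product_axis`` holds the bin centres.
    """

    intensities: np.ndarray
    product_axis: np.ndarray
    instrument: InstrumentConfig
    sim: SimulationConfig | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.product_axis = np.asarray(self.product_axis, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2-D [n_indices x n_bins]")
        if self.intensities.shape[1] != len(self.product_axis):
            raise ValueError("product_axis length does not match intensities")
        if np.any(~np.isfinite(self.intensities)):
            raise ValueError("non-finite intensities in cube")
        if np.any(self.intensities < 0):
            raise ValueError("cube intensities must be non-negative")

    @property
    def n_indices(self) -> int:
        return self.intensities.shape[0]

    @property
    def index_axis(self) -> np.ndarray:
        return np.arange(self.n_indices)

    def column_nearest(self, mz: float) -> int:
        """Index of the product bin nearest ``mz``."""
        return int(np.argmin(np.abs(self.product_axis - mz)))


# ---------------------------------------------------------------------------
# Modulation and survival models
# ---------------------------------------------------------------------------

def _magnitude_series(f_s: float, n, cfg: InstrumentConfig):
    """M(f_s, n) for scalar f_s over an array of indices."""
    x = (f_s - cfg.f_min) / cfg.band_width
    n = np.asarray(n, dtype=float)
    return 0.5 * (1.0 + np.sin(n * np.pi * x - np.pi / 2.0))


def modulation_amplitude(sp: IonSpecies, n, cfg: InstrumentConfig,
                         sim: SimulationConfig):
    """Excitation amplitude a(n) = A_exc * M(f_s, n) seen by a species, volts.

    Raises if the species' secular frequency lies outside the SWIM band
    (out-of-band species are rejected rather than aliased).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # Dehmelt-range warning handled upstream
        f_s = secular_frequency(sp.mz, cfg, method=sim.fs_method)
    if not cfg.f_min <= f_s <= cfg.f_max:
        raise ValueError(
            f"species m/z {sp.mz:g}: secular frequency {f_s:g} Hz outside band"
        )
    a = sim.excitation_scale * _magnitude_series(f_s, n, cfg)
    return a if np.ndim(a) else float(a)


def uvpd_survival(a, sim: SimulationConfig, channels=None):
    """Precursor survival and per-channel fragment fractions under UVPD.

    Photofragmentation probability p(a) = p_max exp(-a^2 / 2 sigma^2) with
    sigma = laser_sigma_frac * excitation_scale: maximal at zero radius
    (beam centre), so fragment traces are anti-phase with the radius.
    Fragment fractions are p * max_yield per channel; survival is 1 minus
    their sum.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("excitation amplitude must be >= 0")
    sigma = sim.laser_sigma_frac * sim.excitation_scale
    if sigma == 0.0:
        p = np.where(a == 0.0, sim.uvpd_pmax, 0.0)
    else:
        p = sim.uvpd_pmax * np.exp(-(a**2) / (2.0 * sigma**2))
    if channels is None:
        frac = {None: p}
        total = p
    else:
        frac = {c: p * c.max_yield for c in channels}
        total = p * sum(c.max_yield for c in channels)
    survival = 1.0 - total
    return survival, frac


def intrap_cid_survival(a, sim: SimulationConfig, channels=None):
    """Precursor survival and fragment fractions for in-trap CID.

    Collisional activation needs kinetic energy: nothing fragments below
    ``cid_threshold``; above it the probability ramps linearly, saturating
    at 1 when a reaches the full excitation scale.  The clipped ramp makes
    the fragment waveform periodic but asymmetric, feeding harmonics.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("excitation amplitude must be >= 0")
    span = max(sim.excitation_scale - sim.cid_threshold, 1e-300)
    p = np.clip((a - sim.cid_threshold) / span, 0.0, 1.0)
    if channels is None:
        frac = {None: p}
        total = p
    else:
        frac = {c: p * c.max_yield for c in channels}
        total = p * sum(c.max_yield for c in channels)
    return 1.0 - total, frac


def flux_transmission(a, sim: SimulationConfig):
    """Transmitted fraction of the cloud through the exit aperture.

    Unity at or below ``v_crit``; above it a smooth (tanh-shaped) loss of
    configurable depth and width, rather than a hard step, models the
    growing part of the cloud that discharges on the exit lens.  Applied
    identically to precursors and in-trap fragments.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("excitation amplitude must be >= 0")
    if not np.isfinite(sim.v_crit):
        t = np.ones_like(a)
    else:
        over = np.clip(a - sim.v_crit, 0.0, None)
        t = 1.0 - sim.loss_depth * np.tanh(over / max(sim.loss_width, 1e-300))
    return t if t.ndim else float(t)


# ---------------------------------------------------------------------------
# Bookkeeping and rendering
# ---------------------------------------------------------------------------

def species_traces(sp: IonSpecies, n, cfg: InstrumentConfig,
                   sim: SimulationConfig):
    """Noise-free intensity traces for one species across SWIM indices.

    Returns a list of rendered components, each a dict with keys
    ``mz`` (peak position), ``trace`` (per-index intensity), ``kind``
    ("precursor" or "fragment"), ``channel`` and ``parent``.  Each
    isotopologue is treated as its own sub-species with its own secular
    frequency; fragments inherit the isotopologue index at the product
    charge spacing.

    The per-index bookkeeping: in-trap fragmentation (UVPD + in-trap CID)
    converts precursor to fragments, exit-aperture transmission scales the
    whole cloud, and beam CID converts a fixed fraction of transmitted
    precursors downstream.  An unmodulated upstream-photofragment baseline
    (``upstream_frac`` of each channel's capacity) is added on top.
    """
    n = np.asarray(n)
    components = []
    uv = [c for c in sp.channels if c.mechanism == "uvpd"]
    it = [c for c in sp.channels if c.mechanism == "intrap_cid"]
    beam = [c for c in sp.channels if c.mechanism == "beam_cid"]
    for k_iso, (offset, rel) in enumerate(sp.isotopologues):
        iso = replace(sp, mz=sp.mz + offset, isotopologues=((0.0, 1.0),))
        a = modulation_amplitude(iso, n, cfg, sim)
        base = sp.abundance * rel
        surv_uv, frac_uv = uvpd_survival(a, sim, uv)
        surv_it, frac_it = intrap_cid_survival(a, sim, it)
        in_trap_loss = (1.0 - surv_uv) + (1.0 - surv_it)
        survival = 1.0 - in_trap_loss
        t = flux_transmission(a, sim)
        beam_total = sim.beam_cid_frac * sum(c.max_yield for c in beam)
        precursor = base * t * survival * (1.0 - beam_total)
        components.append({
            "mz": sp.mz + offset, "trace": precursor, "kind": "precursor",
            "channel": None, "parent": sp, "iso": k_iso,
        })
        for c in sp.channels:
            pmz = c.product_mz + k_iso * ISOTOPE_SPACING / c.product_z
            if c.mechanism == "uvpd":
                trace = base * t * frac_uv[c]
            elif c.mechanism == "intrap_cid":
                trace = base * t * frac_it[c]
            else:  # beam CID: in phase with the transmitted precursor
                trace = base * t * survival * sim.beam_cid_frac * c.max_yield
            trace = trace + base * sim.upstream_frac * c.max_yield
            components.append({
                "mz": pmz, "trace": trace, "kind": "fragment",
                "channel": c, "parent": sp, "iso": k_iso,
            })
    return components


def _axis_edges(sim: SimulationConfig):
    lo, hi, nb = sim.product_axis
    nb = int(nb)
    edges = np.linspace(lo, hi, nb + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return edges, centers


def _render_components(components, edges, sim: SimulationConfig, n_rows: int):
    """Accumulate bin-integrated Gaussian peaks into an (n_rows x bins) array."""
    out = np.zeros((n_rows, len(edges) - 1))
    for comp in components:
        mz = comp["mz"]
        fwhm = sim.peak_width_ppm * 1e-6 * mz
        sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        lo_i = np.searchsorted(edges, mz - 8 * sigma)
        hi_i = np.searchsorted(edges, mz + 8 * sigma)
        if lo_i >= len(edges) - 1 or hi_i <= 0 or mz < edges[0] or mz > edges[-1]:
            warnings.warn(f"peak at m/z {mz:g} outside product axis; dropped")
            continue
        lo_i = max(lo_i - 1, 0)
        hi_i = min(hi_i + 1, len(edges) - 1)
        e = edges[lo_i:hi_i + 1]
        cdf = 0.5 * (1.0 + erf((e - mz) / (sigma * math.sqrt(2.0))))
        profile = np.diff(cdf)  # unit area across bins
        trace = np.atleast_1d(np.asarray(comp["trace"], dtype=float))
        out[:, lo_i:hi_i] += np.outer(trace, profile)
    return out


def _apply_noise(clean: np.ndarray, sim: SimulationConfig,
                 rng: np.random.Generator) -> np.ndarray:
    if sim.noise_prop == 0.0 and sim.noise_floor == 0.0:
        return clean
    floor = sim.noise_floor * (clean.max() if clean.size else 0.0)
    noisy = (clean
             + sim.noise_prop * clean * rng.standard_normal(clean.shape)
             + floor * rng.standard_normal(clean.shape))
    return np.clip(noisy, 0.0, None)


def render_spectrum(species, n: int, cfg: InstrumentConfig,
                    sim: SimulationConfig, rng: np.random.Generator | None = None):
    """One product-ion spectrum (intensity per bin) at SWIM index ``n``."""
    edges, centers = _axis_edges(sim)
    comps = []
    for sp in species:
        for comp in species_traces(sp, np.asarray([n]), cfg, sim):
            comps.append(comp)
    clean = _render_components(comps, edges, sim, 1)[0]
    if rng is not None:
        clean = _apply_noise(clean[None, :], sim, rng)[0]
    return centers, clean


def generate_cube(species, cfg: InstrumentConfig,
                  sim: SimulationConfig) -> DataCube:
    """Simulate a full acquisition: ``cfg.n_indices`` spectra, seeded noise.

    Deterministic for a fixed seed; identical species and configs always
    produce bit-identical cubes.
    """
    edges, centers = _axis_edges(sim)
    n = np.arange(cfg.n_indices)
    comps = []
    for sp in species:
        comps.extend(species_traces(sp, n, cfg, sim))
    clean = _render_components(comps, edges, sim, cfg.n_indices)
    rng = np.random.default_rng(sim.seed)
    noisy = _apply_noise(clean, sim, rng)
    return DataCube(
        intensities=noisy,
        product_axis=centers,
        instrument=cfg,
        sim=sim,
        meta={"n_species": len(list(species)), "seed": sim.seed},
    )
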