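"""Monte Carlo trajectory simulator of SWIM excitation and UVPD.

A reduced-scale, trajectory-level cross-check of the signal-level forward
model: ions move in the radial plane of an ideal linear quadrupole (axial
motion decouples in an ideal trap), driven by the RF trapping field plus
the dipolar SWIM excitation along x.  Background-gas collisions follow a
hard-sphere model with Maxwell-Boltzmann partners; photofragmentation
probability is computed from the path-averaged photon exposure during one
secular orbit through a Gaussian laser beam, and each precursor's fate is
decided by a Monte Carlo draw.  The output per SWIM pulse is a tally of
surviving precursors, fragments, and ions lost at the exit aperture.

The integrator is velocity Verlet at a fixed step ``dt <= 1/(50 f_trap)``
with the inner loops compiled by numba.  All stochastic draws (initial
cloud, collisions, fragment fates) descend from a single seeded generator,
so runs are reproducible.

Physical conventions: the quadrupole potential is
``Phi = V_trap cos(2 pi f_trap t)(x^2 - y^2)/r0^2`` (zero-to-peak rod
amplitude), reproducing the Mathieu parameter
``q = e z V / (pi^2 m r0^2 f_trap^2)``; the dipolar excitation field is
``V_exc(t)/r0`` along x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import constants as _const

from .config import InstrumentConfig
from .pulsegen import SwimPulse, amplitude_scale, synthesize_pulse

__all__ = [
    "GasModel",
    "LaserModel",
    "TrajectoryConfig",
    "IonEnsemble",
    "field_force",
    "step",
    "maybe_collide",
    "integrate_ensemble",
    "photon_exposure",
    "fragment_fate",
    "run_pulse_sequence",
]

_E = _const.e
_U = _const.u
_KB = _const.k
_H = _const.h
_C = _const.c


@dataclass(frozen=True)
class GasModel:
    """Hard-sphere background gas (defaults: room-temperature N2).

    The pressure and cross-section are plausible trap-chamber values, not
    measured ones; both are free knobs of the collision model.
    """

    mass_u: float = 28.0
    pressure: float = 1.0e-3
    temperature: float = 300.0
    cross_section: float = 2.0e-18

    def __post_init__(self):
        if min(self.mass_u, self.temperature, self.cross_section) <= 0:
            raise ValueError("gas mass, temperature and cross-section must be positive")
        if self.pressure < 0:
            raise ValueError("pressure must be >= 0")

    @property
    def number_density(self) -> float:
        return self.pressure / (_KB * self.temperature)

    @property
    def thermal_sigma(self) -> float:
        """Per-component Maxwell-Boltzmann velocity sigma, m/s."""
        return math.sqrt(_KB * self.temperature / (self.mass_u * _U))


@dataclass(frozen=True)
class LaserModel:
    """Coaxial Gaussian UVPD beam (213 nm, 0.6 mm fwhm, 25 uJ defaults).

    ``rate_constant`` (m^2/J) converts path-averaged fluence into a
    fragmentation rate; when None it is calibrated so an ion parked on the
    beam axis fragments with probability 0.5 per exposure evaluation.
    ``energy_frac`` is the fraction of one photon's energy converted into
    fragment kinetic energy (isotropic kick in the centre-of-mass frame).
    """

    fwhm: float = 0.6e-3
    pulse_energy: float = 25.0e-6
    wavelength: float = 213.0e-9
    offset: tuple = (0.0, 0.0)
    rate_constant: float | None = None
    energy_frac: float = 0.1

    def __post_init__(self):
        if self.fwhm <= 0 or self.pulse_energy < 0:
            raise ValueError("fwhm must be positive and pulse_energy >= 0")

    @property
    def sigma(self) -> float:
        return self.fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    @property
    def peak_fluence(self) -> float:
        """On-axis fluence of the Gaussian beam, J/m^2."""
        return self.pulse_energy / (2.0 * math.pi * self.sigma**2)

    @property
    def photon_energy(self) -> float:
        return _H * _C / self.wavelength

    def effective_rate_constant(self) -> float:
        if self.rate_constant is not None:
            return self.rate_constant
        if self.peak_fluence == 0.0:
            return 0.0
        return math.log(2.0) / self.peak_fluence


@dataclass(frozen=True)
class TrajectoryConfig:
    """Ensemble, integrator, and loss-criterion settings."""

    ensemble_size: int = 300
    cloud_sigma: float = 0.2e-3
    ion_temperature: float = 300.0
    dt_factor: int = 50
    loss_radius_frac: float = 0.8
    seed: int = 0

    def dt(self, cfg: InstrumentConfig) -> float:
        return 1.0 / (self.dt_factor * cfg.f_trap)


@dataclass
class IonEnsemble:
    """Radial-plane state of a same-species ensemble (SI units)."""

    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    mz: float
    z: int
    alive: np.ndarray = None
    collisions: np.ndarray = None

    def __post_init__(self):
        n = len(self.x)
        for name in ("y", "vx", "vy"):
            if len(getattr(self, name)) != n:
                raise ValueError("state arrays must share a length")
        if self.alive is None:
            self.alive = np.ones(n, dtype=np.bool_)
        if self.collisions is None:
            self.collisions = np.zeros(n, dtype=np.int64)

    @property
    def mass(self) -> float:
        """Ion mass, kg."""
        return self.mz * self.z * _U

    @property
    def n(self) -> int:
        return len(self.x)

    @classmethod
    def thermal(cls, mz: float, z: int, cfg: InstrumentConfig,
                traj: TrajectoryConfig, rng: np.random.Generator) -> "IonEnsemble":
        """Thermalized 2D Gaussian cloud at the trap centre."""
        n = traj.ensemble_size
        m = mz * z * _U
        sv = math.sqrt(_KB * traj.ion_temperature / m)
        return cls(
            x=rng.normal(0.0, traj.cloud_sigma, n),
            y=rng.normal(0.0, traj.cloud_sigma, n),
            vx=rng.normal(0.0, sv, n),
            vy=rng.normal(0.0, sv, n),
            mz=mz, z=z,
        )

    def kinetic_energy(self) -> np.ndarray:
        return 0.5 * self.mass * (self.vx**2 + self.vy**2)


# ---------------------------------------------------------------------------
# Fields and integration
# ---------------------------------------------------------------------------

def field_force(state: IonEnsemble, t: float, cfg: InstrumentConfig,
                exc_voltage: float = 0.0):
    """Force (N) on each ion: ideal quadrupole RF + dipolar excitation.

    The quadrupole term is linear in position; the dipolar term is a
    uniform field ``V_exc/r0`` along x (one excited rod pair).
    """
    ze = state.z * _E
    c = math.cos(2.0 * math.pi * cfg.f_trap * t)
    quad = 2.0 * ze * cfg.V_trap * c / cfg.r0**2
    fx = -quad * state.x + ze * exc_voltage / cfg.r0
    fy = quad * state.y
    return fx, fy


def step(state: IonEnsemble, t: float, dt: float, cfg: InstrumentConfig,
         exc_now: float = 0.0, exc_next: float = 0.0) -> float:
    """One velocity-Verlet step (in place); returns the new time.

    Reference implementation used by the convergence tests; the bulk
    integration goes through the compiled kernel.
    """
    m = state.mass
    fx, fy = field_force(state, t, cfg, exc_now)
    ax, ay = fx / m, fy / m
    state.x += state.vx * dt + 0.5 * ax * dt * dt
    state.y += state.vy * dt + 0.5 * ay * dt * dt
    fx2, fy2 = field_force(state, t + dt, cfg, exc_next)
    state.vx += 0.5 * (ax + fx2 / m) * dt
    state.vy += 0.5 * (ay + fy2 / m) * dt
    bad = ~np.isfinite(state.x) | ~np.isfinite(state.vx)
    if np.any(bad):
        raise FloatingPointError(
            f"integrator instability: {bad.sum()} ion(s) went non-finite at t={t:g}"
        )
    state.alive &= (state.x**2 + state.y**2) < cfg.r0**2
    return t + dt


def maybe_collide(state: IonEnsemble, gas: GasModel, dt: float,
                  rng: np.random.Generator):
    """Hard-sphere collision test for one time step (in place).

    For each ion a Maxwell-Boltzmann gas partner is sampled; a collision
    occurs with probability ``n_gas sigma v_rel dt`` and updates the ion
    velocity elastically with an isotropic scattering angle in the
    centre-of-mass frame.  Returns the boolean collision mask.
    """
    n = state.n
    if gas.pressure == 0.0:
        return np.zeros(n, dtype=bool)
    sv = gas.thermal_sigma
    gx = rng.normal(0.0, sv, n)
    gy = rng.normal(0.0, sv, n)
    relx, rely = state.vx - gx, state.vy - gy
    vrel = np.hypot(relx, rely)
    p = gas.number_density * gas.cross_section * vrel * dt
    hit = rng.random(n) < p
    if np.any(hit):
        mi = state.mass
        mg = gas.mass_u * _U
        mu = mg / (mi + mg)
        phi = rng.uniform(0.0, 2.0 * math.pi, int(hit.sum()))
        cmx = (mi * state.vx[hit] + mg * gx[hit]) / (mi + mg)
        cmy = (mi * state.vy[hit] + mg * gy[hit]) / (mi + mg)
        state.vx[hit] = cmx + mu * vrel[hit] * np.cos(phi)
        state.vy[hit] = cmy + mu * vrel[hit] * np.sin(phi)
        state.collisions[hit] += 1
    return hit


@njit(cache=False)
def _kernel(x, y, vx, vy, alive, coll, acc_coef, dip_coef, omega, r0sq,
            dt, exc, do_collide, rate_coef, m_ratio, vth, seed,
            rec_start, rec_x, rec_y):  # pragma: no cover - compiled
    np.random.seed(seed)
    nsteps = exc.shape[0] - 1
    nions = x.shape[0]
    for s in range(nsteps):
        t = s * dt
        c1 = math.cos(omega * t)
        c2 = math.cos(omega * (t + dt))
        e1 = exc[s]
        e2 = exc[s + 1]
        for i in range(nions):
            if not alive[i]:
                continue
            ax1 = -acc_coef * c1 * x[i] + dip_coef * e1
            ay1 = acc_coef * c1 * y[i]
            xn = x[i] + vx[i] * dt + 0.5 * ax1 * dt * dt
            yn = y[i] + vy[i] * dt + 0.5 * ay1 * dt * dt
            ax2 = -acc_coef * c2 * xn + dip_coef * e2
            ay2 = acc_coef * c2 * yn
            vx[i] += 0.5 * (ax1 + ax2) * dt
            vy[i] += 0.5 * (ay1 + ay2) * dt
            x[i] = xn
            y[i] = yn
            if x[i] * x[i] + y[i] * y[i] >= r0sq:
                alive[i] = False
                continue
            if do_collide:
                gx = np.random.normal() * vth
                gy = np.random.normal() * vth
                relx = vx[i] - gx
                rely = vy[i] - gy
                vrel = math.sqrt(relx * relx + rely * rely)
                if np.random.random() < rate_coef * vrel * dt:
                    cmx = (vx[i] + m_ratio * gx) / (1.0 + m_ratio)
                    cmy = (vy[i] + m_ratio * gy) / (1.0 + m_ratio)
                    mu = m_ratio / (1.0 + m_ratio)
                    phi = np.random.random() * 2.0 * math.pi
                    vx[i] = cmx + mu * vrel * math.cos(phi)
                    vy[i] = cmy + mu * vrel * math.sin(phi)
                    coll[i] += 1
        if s >= rec_start:
            r = s - rec_start
            if r < rec_x.shape[0]:
                for i in range(nions):
                    rec_x[r, i] = x[i]
                    rec_y[r, i] = y[i]


def integrate_ensemble(state: IonEnsemble, cfg: InstrumentConfig,
                       exc: np.ndarray, dt: float,
                       gas: GasModel | None = None,
                       record_last: int = 0, seed: int = 0):
    """Integrate an ensemble through an excitation waveform (in place).

    ``exc`` holds the dipolar excitation voltage at each of nsteps+1 step
    edges.  When ``record_last`` > 0 the positions of the final steps are
    returned as (rec_x, rec_y) arrays of shape (record_last, n_ions) for
    exposure and amplitude analysis.
    """
    if dt > 1.0 / (50.0 * cfg.f_trap) + 1e-20:
        raise ValueError("dt must be <= 1/(50 f_trap)")
    m = state.mass
    acc_coef = 2.0 * state.z * _E * cfg.V_trap / (m * cfg.r0**2)
    dip_coef = state.z * _E / (m * cfg.r0)
    nsteps = len(exc) - 1
    rec_start = nsteps - record_last if record_last > 0 else nsteps + 1
    rec_x = np.zeros((max(record_last, 1), state.n))
    rec_y = np.zeros((max(record_last, 1), state.n))
    do_collide = gas is not None and gas.pressure > 0.0
    rate_coef = (gas.number_density * gas.cross_section) if do_collide else 0.0
    m_ratio = (gas.mass_u * _U / m) if do_collide else 0.0
    vth = gas.thermal_sigma if do_collide else 0.0
    _kernel(state.x, state.y, state.vx, state.vy, state.alive,
            state.collisions, acc_coef, dip_coef,
            2.0 * math.pi * cfg.f_trap, cfg.r0**2, dt,
            np.ascontiguousarray(exc, dtype=np.float64),
            do_collide, rate_coef, m_ratio, vth, seed,
            rec_start, rec_x, rec_y)
    if np.any(~np.isfinite(state.x[state.alive])):
        raise FloatingPointError("integrator instability: non-finite positions")
    if record_last > 0:
        return rec_x, rec_y
    return None


# ---------------------------------------------------------------------------
# UVPD
# ---------------------------------------------------------------------------

def photon_exposure(xs: np.ndarray, ys: np.ndarray, laser: LaserModel):
    """Path-averaged fluence (J/m^2) over a trajectory segment.

    ``xs``/``ys`` may be 1-D (one ion) or (n_samples, n_ions); the
    average of the Gaussian beam profile over the sampled path is returned
    per ion.  The beam propagates along the trap axis, so exposure depends
    only on radial position.
    """
    x0, y0 = laser.offset
    s2 = 2.0 * laser.sigma**2
    w = np.exp(-(((np.asarray(xs) - x0) ** 2) + (np.asarray(ys) - y0) ** 2) / s2)
    return laser.peak_fluence * w.mean(axis=0)


def fragment_fate(exposure, laser: LaserModel, rng: np.random.Generator):
    """Monte Carlo fragmentation decision: p = 1 - exp(-k * exposure)."""
    exposure = np.asarray(exposure, dtype=float)
    if np.any(exposure < 0):
        raise ValueError("exposure must be >= 0")
    k = laser.effective_rate_constant()
    p = 1.0 - np.exp(-k * exposure)
    return rng.random(exposure.shape) < p


def fragment_kick(vx, vy, fragment_mass: float, laser: LaserModel,
                  rng: np.random.Generator):
    """Velocity after fragmentation: parent velocity plus an isotropic
    centre-of-mass kick carrying ``energy_frac`` of one photon's energy."""
    n = len(np.atleast_1d(vx))
    e_kick = laser.energy_frac * laser.photon_energy
    speed = math.sqrt(2.0 * e_kick / fragment_mass)
    phi = rng.uniform(0.0, 2.0 * math.pi, n)
    return vx + speed * np.cos(phi), vy + speed * np.sin(phi)


# ---------------------------------------------------------------------------
# Full pulse-sequence runs
# ---------------------------------------------------------------------------

def run_pulse_sequence(mz: float, z: int, cfg: InstrumentConfig,
                       traj: TrajectoryConfig | None = None,
                       gas: GasModel | None = None,
                       laser: LaserModel | None = None,
                       n_indices: int | None = None) -> pd.DataFrame:
    """Trajectory-level simulation of a SWIM acquisition for one species.

    For each SWIM index a fresh thermal cloud is filled, integrated through
    the index's excitation pulse (optionally with collisions), exposed to
    the laser over its final secular orbit, and tallied: ions whose radial
    amplitude exceeds ``loss_radius_frac * r0`` at release are counted
    lost (unable to pass the exit aperture); the rest are surviving
    precursors or UVPD fragments per the Monte Carlo fate.

    Returns a DataFrame with columns n, survivors, fragments, lost.
    """
    traj = traj or TrajectoryConfig()
    if traj.ensemble_size < 100:
        raise ValueError("ensemble_size must be >= 100 for meaningful tallies")
    count = cfg.n_indices if n_indices is None else int(n_indices)
    rng = np.random.default_rng(traj.seed)
    dt = traj.dt(cfg)
    nsteps = int(round(cfg.pulse_duration / dt))
    t_grid = np.arange(nsteps + 1) * dt
    scale = amplitude_scale(cfg)
    from .secular import secular_frequency

    f_s = secular_frequency(mz, cfg, method="exact")
    orbit_steps = max(int(round(1.0 / (f_s * dt))), 8)
    rows = []
    for n in range(count):
        pulse = synthesize_pulse(n, cfg, scale=scale)
        exc = np.interp(t_grid, pulse.times, pulse.samples)
        state = IonEnsemble.thermal(mz, z, cfg, traj, rng)
        rec = integrate_ensemble(
            state, cfg, exc, dt, gas=gas, record_last=orbit_steps,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rec_x, rec_y = rec
        alive = state.alive
        amp = np.sqrt(rec_x**2 + rec_y**2).max(axis=0)
        transmitted = alive & (amp <= traj.loss_radius_frac * cfg.r0)
        fragments = np.zeros(state.n, dtype=bool)
        if laser is not None:
            exposure = photon_exposure(rec_x, rec_y, laser)
            fragments = fragment_fate(exposure, laser, rng) & transmitted
        survivors = transmitted & ~fragments
        rows.append((n, int(survivors.sum()), int(fragments.sum()),
                     int((~transmitted).sum())))
    df = pd.DataFrame(rows, columns=["n", "survivors", "fragments", "lost"])
    if df[["survivors", "fragments"]].to_numpy().sum() == 0:
        import warnings

        warnings.warn("all ions lost in every index; check excitation amplitude")
    return df
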