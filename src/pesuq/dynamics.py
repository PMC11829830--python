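"""NVE molecular dynamics and harmonic analysis on any energy/force provider.

A "provider" is a callable ``coords -> (energy, forces)`` with energies in
kcal/mol and forces in kcal/mol/Å — the analytic toy PES and trained
backbone models both satisfy it. Velocity-Verlet integration in NVE serves
as the energy-conservation diagnostic; the finite-difference Hessian gives
harmonic frequencies (and the imaginary mode count at saddle points).

Units: Å, fs, amu; velocities in Å/fs; kinetic energy converted to kcal/mol.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .constants import (
    AMU_A2_FS2_TO_KCAL_PER_MOL,
    ATOMIC_MASSES,
    KB_KCAL_PER_MOL_K,
    KCAL_PER_MOL_A2_AMU_TO_S2,
    SPEED_OF_LIGHT_CM_S,
)


@dataclasses.dataclass
class MDConfig:
    timestep: float = 0.1        # fs
    n_steps: int = 500_000
    temperature: float = 300.0   # K
    save_every: int = 1000       # steps between saved frames
    seed: int = 0
    remove_com_motion: bool = True

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")


@dataclasses.dataclass
class Trajectory:
    times: np.ndarray        # fs, saved frames
    coordinates: np.ndarray  # (n_frames, n_atoms, 3)
    velocities: np.ndarray   # (n_frames, n_atoms, 3)
    potential: np.ndarray    # kcal/mol
    kinetic: np.ndarray      # kcal/mol

    @property
    def total(self) -> np.ndarray:
        return self.potential + self.kinetic

    @property
    def max_deviation(self) -> float:
        """max |E_tot(t) - E_tot(0)| over saved frames, kcal/mol."""
        return float(np.abs(self.total - self.total[0]).max())

    @property
    def drift(self) -> float:
        """|slope of a linear fit to E_tot| x simulated time, kcal/mol."""
        if len(self.times) < 2:
            return 0.0
        slope = np.polyfit(self.times, self.total, 1)[0]
        return float(abs(slope) * (self.times[-1] - self.times[0]))


def masses_for(atomic_numbers) -> np.ndarray:
    return np.array([ATOMIC_MASSES[int(z)] for z in atomic_numbers])


def kinetic_energy(velocities: np.ndarray, masses: np.ndarray) -> float:
    """Kinetic energy in kcal/mol for velocities in Å/fs, masses in amu."""
    return float(
        0.5
        * AMU_A2_FS2_TO_KCAL_PER_MOL
        * np.sum(masses[:, None] * velocities**2)
    )


def maxwell_boltzmann_velocities(
    atomic_numbers, temperature: float, seed: int, remove_com: bool = True
) -> np.ndarray:
    """Draw velocities (Å/fs) from the Maxwell-Boltzmann distribution.

    Each Cartesian component is Gaussian with variance k_B T / m_i; the
    centre-of-mass momentum is removed afterwards (default).
    """
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    masses = masses_for(atomic_numbers)
    if temperature == 0:
        return np.zeros((len(masses), 3))
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(
        KB_KCAL_PER_MOL_K
        * temperature
        / (masses * AMU_A2_FS2_TO_KCAL_PER_MOL)
    )
    v = rng.normal(size=(len(masses), 3)) * sigma[:, None]
    if remove_com:
        p = (masses[:, None] * v).sum(axis=0)
        v -= p / masses.sum()
    return v


def velocity_verlet_nve(
    provider,
    coordinates: np.ndarray,
    velocities: np.ndarray,
    masses: np.ndarray,
    config: MDConfig,
) -> Trajectory:
    """Integrate NVE dynamics with the velocity-Verlet scheme.

    Saves every ``config.save_every`` steps (plus the initial frame).
    Aborts with the last saved frames if the energy turns non-finite.
    """
    dt = config.timestep
    x = np.array(coordinates, dtype=float)
    v = np.array(velocities, dtype=float)
    inv_m = 1.0 / (masses[:, None] * AMU_A2_FS2_TO_KCAL_PER_MOL)
    e_pot, forces = provider(x)
    times, xs, vs, pots, kins = [], [], [], [], []

    def save(step):
        times.append(step * dt)
        xs.append(x.copy())
        vs.append(v.copy())
        pots.append(e_pot)
        kins.append(kinetic_energy(v, masses))

    save(0)
    a = forces * inv_m
    for step in range(1, config.n_steps + 1):
        x += v * dt + 0.5 * a * dt**2
        e_pot, forces = provider(x)
        if not np.isfinite(e_pot):
            break
        a_new = forces * inv_m
        v += 0.5 * (a + a_new) * dt
        a = a_new
        if step % config.save_every == 0:
            save(step)
    return Trajectory(
        times=np.array(times),
        coordinates=np.array(xs),
        velocities=np.array(vs),
        potential=np.array(pots),
        kinetic=np.array(kins),
    )


def trajectory_to_dataset(trajectory: Trajectory, atomic_numbers):
    """Saved frames as a Dataset (per-frame potential energy as the label)."""
    from .chemio import Dataset, Structure

    return Dataset(
        [
            Structure(
                atomic_numbers=atomic_numbers,
                coordinates=coords,
                energy=float(e_pot),
                tag=f"t={t:.1f}fs",
            )
            for t, coords, e_pot in zip(
                trajectory.times, trajectory.coordinates, trajectory.potential
            )
        ]
    )


def hessian(provider, geometry: np.ndarray, displacement: float = 0.005):
    """Central-difference Hessian (kcal/mol/Å²) from analytic forces."""
    if displacement <= 0:
        raise ValueError("displacement must be positive")
    x0 = np.asarray(geometry, dtype=float)
    n = x0.size
    h = np.empty((n, n))
    flat = x0.ravel()
    for k in range(n):
        xp = flat.copy()
        xp[k] += displacement
        xm = flat.copy()
        xm[k] -= displacement
        fp = provider(xp.reshape(x0.shape))[1].ravel()
        fm = provider(xm.reshape(x0.shape))[1].ravel()
        h[:, k] = -(fp - fm) / (2.0 * displacement)
    return h


@dataclasses.dataclass
class FrequencyResult:
    frequencies: np.ndarray       # cm^-1, negative = imaginary
    n_near_zero: int              # identified translation/rotation modes
    n_imaginary: int
    max_force: float              # kcal/mol/Å at the input geometry


def hessian_frequencies(
    provider,
    geometry: np.ndarray,
    masses: np.ndarray,
    displacement: float = 0.005,
    zero_tol_cm: float = 5.0,
) -> FrequencyResult:
    """Harmonic wavenumbers from the mass-weighted finite-difference Hessian.

    Negative entries encode imaginary frequencies (one at a first-order
    saddle). Modes with |wavenumber| below ``zero_tol_cm`` are counted as
    the translation/rotation block (6 for a nonlinear molecule).
    """
    h = hessian(provider, geometry, displacement)
    h = 0.5 * (h + h.T)
    m = np.repeat(masses, 3)
    h_mw = h / np.sqrt(np.outer(m, m))
    w = np.linalg.eigvalsh(h_mw)
    omega_sq = w * KCAL_PER_MOL_A2_AMU_TO_S2  # s^-2
    wavenumbers = (
        np.sign(omega_sq)
        * np.sqrt(np.abs(omega_sq))
        / (2.0 * np.pi * SPEED_OF_LIGHT_CM_S)
    )
    near_zero = int(np.sum(np.abs(wavenumbers) < zero_tol_cm))
    imaginary = int(np.sum(wavenumbers < -zero_tol_cm))
    max_force = float(np.abs(provider(geometry)[1]).max())
    return FrequencyResult(
        frequencies=wavenumbers,
        n_near_zero=near_zero,
        n_imaginary=imaginary,
        max_force=max_force,
    )
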