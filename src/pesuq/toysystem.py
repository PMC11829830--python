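"""Synthetic reactive benchmark: an analytic double-well H-transfer PES.

The toy molecule is an 8-atom C2O2H4 system (28 atom pairs, matching the
pair count of the CH3CHOO reference system) with

* Morse potentials on the covalent bonds and on a shallow "scaffold" bond
  holding the donor...acceptor distance (the ring-like conformation that
  makes intramolecular H-transfer possible),
* harmonic angle terms on the heavy-atom skeleton and the spectator
  hydrogens (without them the minimum would be degenerate),
* two Morse terms sharing the transfer hydrogen (donor-H and acceptor-H)
  plus a Gaussian ridge on the transfer coordinate q = r(D-H) - r(A-H),
  which together produce a double well along q,
* Lennard-Jones interactions between all pairs separated by 3+ bonds.

The transfer-term parameters are calibrated numerically at construction so
that a rigid scan of the H along the donor-acceptor axis shows a barrier
and a well asymmetry matching the configured values. Forces are exact
analytic gradients, so every downstream module has an exact oracle.

A deliberately held-out window on q around the transition state provides
ground-truth out-of-distribution (OOD) structures: the sampler never places
training or validation structures inside the window, while the benchmark
test set mixes in-distribution draws with draws from inside it.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.optimize import fsolve, minimize, root

from .chemio import Dataset, Structure
from .constants import ATOMIC_NUMBERS

logger = logging.getLogger("pesuq")

# 1 e*Å = 4.80320 Debye
EA_TO_DEBYE = 4.80320

# fixed point charges (e) per element for the toy dipole surface
POINT_CHARGES = {6: 0.15, 8: -0.25, 1: 0.05}


class SingularGeometryError(ValueError):
    """Two atoms closer than 0.1 Å."""


class SamplingEfficiencyError(RuntimeError):
    """Fewer than 10% of proposed samples survived the filters."""


@dataclasses.dataclass
class MorseTerm:
    i: int
    j: int
    depth: float  # kcal/mol
    width: float  # 1/Å
    r0: float     # Å


@dataclasses.dataclass
class AngleTerm:
    i: int
    j: int  # vertex
    k: int
    force_const: float  # kcal/mol/rad^2
    theta0: float       # rad


@dataclasses.dataclass
class TransferTerm:
    """Two Morse terms sharing one H, plus a Gaussian ridge on q."""

    donor: int
    h: int
    acceptor: int
    donor_morse: tuple   # (depth, width, r0)
    acceptor_morse: tuple
    gauss_height: float  # kcal/mol
    gauss_center: float  # Å, on q
    gauss_width: float   # Å


@dataclasses.dataclass
class ToyPESParams:
    elements: list
    bonds: list            # list[MorseTerm]
    angles: list           # list[AngleTerm]
    transfer: TransferTerm
    lj_eps: dict           # element symbol -> kcal/mol
    lj_sigma: dict         # element symbol -> Å
    reference_geometry: np.ndarray | None = None


@dataclasses.dataclass
class SamplerConfig:
    temperatures: list = dataclasses.field(default_factory=lambda: [300.0])
    n_samples: int = 1000
    displacement_scale: float = 0.05  # Å at 300 K
    energy_cap: float = 400.0         # kcal/mol above the global minimum
    ood_window: tuple | None = None   # (q_lo, q_hi); None -> from the PES
    path_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.energy_cap <= 0:
            raise ValueError("energy_cap must be positive")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")


def _template_geometry() -> np.ndarray:
    """Hand-built ring-like starting geometry (Å); refined by minimization."""
    return np.array(
        [
            [0.000, 0.000, 0.000],   # C0 donor
            [0.550, -1.440, 0.000],  # C1
            [1.978, -1.371, 0.000],  # O2
            [2.600, 0.000, 0.000],   # O3 acceptor
            [1.090, 0.000, 0.000],   # H4 transfer H
            [-0.436, 0.545, 0.839],  # H5
            [-0.436, 0.545, -0.839], # H6
            [-0.046, -2.352, 0.000], # H7
        ]
    )


def default_params(
    barrier: float = 20.0,
    asymmetry: float = 5.0,
    calibrate: bool = True,
) -> ToyPESParams:
    """Default 8-atom composition with a calibrated H-transfer double well.

    ``barrier`` is the rigid-scan barrier above the reactant well and
    ``asymmetry`` the product-minus-reactant well offset, both in kcal/mol.
    """
    tet = np.deg2rad(109.47)
    params = ToyPESParams(
        elements=["C", "C", "O", "O", "H", "H", "H", "H"],
        bonds=[
            MorseTerm(0, 1, 85.0, 1.9, 1.54),
            MorseTerm(1, 2, 92.0, 2.0, 1.43),
            MorseTerm(2, 3, 55.0, 2.2, 1.45),
            MorseTerm(0, 5, 100.0, 1.8, 1.09),
            MorseTerm(0, 6, 100.0, 1.8, 1.09),
            MorseTerm(1, 7, 100.0, 1.8, 1.09),
            # scaffold: keeps the donor-acceptor distance transfer-ready
            MorseTerm(0, 3, 40.0, 1.2, 2.60),
        ],
        angles=[
            AngleTerm(1, 0, 5, 40.0, tet),
            AngleTerm(1, 0, 6, 40.0, tet),
            AngleTerm(5, 0, 6, 40.0, tet),
            AngleTerm(0, 1, 2, 40.0, tet),
            AngleTerm(0, 1, 7, 40.0, tet),
            AngleTerm(2, 1, 7, 40.0, tet),
            AngleTerm(1, 2, 3, 40.0, tet),
        ],
        transfer=TransferTerm(
            donor=0,
            h=4,
            acceptor=3,
            donor_morse=(100.0, 1.8, 1.09),
            acceptor_morse=(70.0, 2.2, 0.96),
            gauss_height=20.0,
            gauss_center=0.1,
            gauss_width=0.28,
        ),
        lj_eps={"H": 0.02, "C": 0.08, "O": 0.16},
        lj_sigma={"H": 2.50, "C": 3.40, "O": 3.00},
    )
    if calibrate:
        _calibrate_transfer(params, barrier, asymmetry)
    return params


def _calibrate_transfer(params: ToyPESParams, barrier: float, asymmetry: float):
    """Solve (gauss_height, acceptor depth) so the rigid H-scan matches."""

    def residual(x):
        height, depth = x
        params.transfer.gauss_height = float(height)
        params.transfer.acceptor_morse = (
            float(depth),
            params.transfer.acceptor_morse[1],
            params.transfer.acceptor_morse[2],
        )
        pes = ToyPES(params, validate=False)
        b, a = pes.rigid_scan_barrier()
        return [b - barrier, a - asymmetry]

    sol, info, ier, msg = fsolve(
        residual, x0=[barrier, 70.0], full_output=True, xtol=1e-10
    )
    if ier != 1:
        raise RuntimeError(f"transfer calibration failed: {msg}")
    residual(sol)  # leave params at the solution
    logger.info(
        "calibrated transfer term: gauss_height=%.4f acceptor_depth=%.4f",
        sol[0],
        sol[1],
    )


class ToyPES:
    """Analytic toy PES with exact forces and benchmark helpers."""

    def __init__(self, params: ToyPESParams, validate: bool = True):
        self.params = params
        self.atomic_numbers = np.array(
            [ATOMIC_NUMBERS[e] for e in params.elements]
        )
        n = len(params.elements)
        self.n_atoms = n
        # every atom must appear in >= 1 bonded or transfer term
        touched = set()
        for b in params.bonds:
            touched |= {b.i, b.j}
        t = params.transfer
        touched |= {t.donor, t.h, t.acceptor}
        if touched != set(range(n)):
            raise ValueError("every atom must appear in a bonded/transfer term")
        self._build_lj_tables()
        self._build_term_tables()
        self._cache = {}
        if validate:
            self._validate_double_well()

    # -- construction helpers --------------------------------------------
    def _build_lj_tables(self):
        n = self.n_atoms
        bonds = [(b.i, b.j) for b in self.params.bonds]
        t = self.params.transfer
        bonds += [(t.donor, t.h), (t.acceptor, t.h)]
        adj = [set() for _ in range(n)]
        for i, j in bonds:
            adj[i].add(j)
            adj[j].add(i)
        excluded = {tuple(sorted(p)) for p in bonds}
        for j in range(n):  # 1-3 pairs share a neighbour
            for i in adj[j]:
                for k in adj[j]:
                    if i < k:
                        excluded.add((i, k))
        pairs = [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if (i, j) not in excluded
        ]
        eps = self.params.lj_eps
        sig = self.params.lj_sigma
        el = self.params.elements
        self.lj_pairs = np.array(pairs, dtype=int).reshape(-1, 2)
        self.lj_eps_ij = np.array(
            [np.sqrt(eps[el[i]] * eps[el[j]]) for i, j in pairs]
        )
        self.lj_sig_ij = np.array(
            [0.5 * (sig[el[i]] + sig[el[j]]) for i, j in pairs]
        )

    def _build_term_tables(self):
        """Flatten Morse and angle terms into arrays for vectorized evaluation."""
        t = self.params.transfer
        morse = [(b.i, b.j, b.depth, b.width, b.r0) for b in self.params.bonds]
        morse.append((t.donor, t.h) + t.donor_morse)
        morse.append((t.acceptor, t.h) + t.acceptor_morse)
        arr = np.array(morse, dtype=float)
        self._m_i = arr[:, 0].astype(int)
        self._m_j = arr[:, 1].astype(int)
        self._m_d = arr[:, 2]
        self._m_a = arr[:, 3]
        self._m_r0 = arr[:, 4]
        if self.params.angles:
            aarr = np.array(
                [
                    (a.i, a.j, a.k, a.force_const, a.theta0)
                    for a in self.params.angles
                ],
                dtype=float,
            )
            self._a_i = aarr[:, 0].astype(int)
            self._a_j = aarr[:, 1].astype(int)
            self._a_k = aarr[:, 2].astype(int)
            self._a_kf = aarr[:, 3]
            self._a_t0 = aarr[:, 4]
        else:
            self._a_i = np.array([], dtype=int)

    def _validate_double_well(self):
        q, e = self.rigid_scan()
        n_min = _count_local_minima(e)
        if n_min != 2:
            raise ValueError(
                f"transfer superposition has {n_min} minima along the "
                "H-scan; expected exactly 2"
            )

    # -- energies and forces ----------------------------------------------
    def energy_forces(self, coordinates: np.ndarray):
        """Total energy (kcal/mol) and analytic forces (kcal/mol/Å)."""
        x = np.asarray(coordinates, dtype=float)
        if x.shape != (self.n_atoms, 3):
            raise ValueError(f"coordinates must have shape ({self.n_atoms}, 3)")
        forces = np.zeros_like(x)

        # Morse terms (bonds + the two transfer bonds), vectorized
        rij = x[self._m_i] - x[self._m_j]
        r = np.sqrt(np.sum(rij * rij, axis=1))
        if np.any(r < 0.1):
            k = int(np.argmin(r))
            raise SingularGeometryError(
                f"atoms {self._m_i[k]},{self._m_j[k]} at r={r[k]:.3f} Å"
            )
        e = np.exp(-self._m_a * (r - self._m_r0))
        energy = float(np.sum(self._m_d * (1.0 - e) ** 2))
        dv = 2.0 * self._m_d * (1.0 - e) * self._m_a * e  # dV/dr
        fpair = -(dv / r)[:, None] * rij  # force on atom i
        np.add.at(forces, self._m_i, fpair)
        np.add.at(forces, self._m_j, -fpair)

        # Gaussian ridge on the transfer coordinate
        t = self.params.transfer
        r_dh_vec = x[t.h] - x[t.donor]
        r_ah_vec = x[t.h] - x[t.acceptor]
        r_dh = np.linalg.norm(r_dh_vec)
        r_ah = np.linalg.norm(r_ah_vec)
        q = r_dh - r_ah
        g = t.gauss_height * np.exp(
            -((q - t.gauss_center) ** 2) / (2.0 * t.gauss_width**2)
        )
        energy += g
        dg_dq = -g * (q - t.gauss_center) / t.gauss_width**2
        # q gradients: dq/dx_h = u_dh - u_ah etc.
        u_dh = r_dh_vec / r_dh
        u_ah = r_ah_vec / r_ah
        forces[t.h] -= dg_dq * (u_dh - u_ah)
        forces[t.donor] -= dg_dq * (-u_dh)
        forces[t.acceptor] -= dg_dq * (u_ah)

        # harmonic angles, vectorized
        if len(self._a_i):
            u = x[self._a_i] - x[self._a_j]
            v = x[self._a_k] - x[self._a_j]
            nu = np.sqrt(np.sum(u * u, axis=1))
            nv = np.sqrt(np.sum(v * v, axis=1))
            cos_t = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1.0, 1.0)
            theta = np.arccos(cos_t)
            sin_t = np.maximum(np.sqrt(1.0 - cos_t**2), 1e-8)
            energy += float(np.sum(self._a_kf * (theta - self._a_t0) ** 2))
            dv_dtheta = 2.0 * self._a_kf * (theta - self._a_t0)
            inv = 1.0 / (nu * nv)
            dcos_di = v * inv[:, None] - u * (cos_t / nu**2)[:, None]
            dcos_dk = u * inv[:, None] - v * (cos_t / nv**2)[:, None]
            coef = (dv_dtheta / sin_t)[:, None]
            fi = coef * dcos_di  # = -dV/dr_i
            fk = coef * dcos_dk
            np.add.at(forces, self._a_i, fi)
            np.add.at(forces, self._a_k, fk)
            np.add.at(forces, self._a_j, -(fi + fk))

        # Lennard-Jones on non-excluded pairs (vectorized)
        if len(self.lj_pairs):
            rij = x[self.lj_pairs[:, 0]] - x[self.lj_pairs[:, 1]]
            r = np.linalg.norm(rij, axis=1)
            if np.any(r < 0.1):
                raise SingularGeometryError("overlapping non-bonded atoms")
            sr6 = (self.lj_sig_ij / r) ** 6
            energy += float(np.sum(4.0 * self.lj_eps_ij * (sr6**2 - sr6)))
            dv = 4.0 * self.lj_eps_ij * (-12.0 * sr6**2 + 6.0 * sr6) / r
            fpair = -(dv / r)[:, None] * rij
            np.add.at(forces, self.lj_pairs[:, 0], fpair)
            np.add.at(forces, self.lj_pairs[:, 1], -fpair)

        return float(energy), forces

    def energy(self, coordinates) -> float:
        return self.energy_forces(coordinates)[0]

    def transfer_coordinate(self, coordinates) -> float:
        """q = r(donor-H) - r(acceptor-H), Å."""
        t = self.params.transfer
        x = np.asarray(coordinates, dtype=float)
        return float(
            np.linalg.norm(x[t.h] - x[t.donor])
            - np.linalg.norm(x[t.h] - x[t.acceptor])
        )

    # -- stationary points and scans --------------------------------------
    def rigid_scan(self, n_points: int = 400):
        """Energy along the H position between donor and acceptor.

        All other atoms fixed at the template geometry. Returns (q, E).
        """
        t = self.params.transfer
        x0 = (
            self.params.reference_geometry
            if self.params.reference_geometry is not None
            else _template_geometry()
        ).copy()
        d, a = x0[t.donor], x0[t.acceptor]
        axis = (a - d) / np.linalg.norm(a - d)
        span = np.linalg.norm(a - d)
        s = np.linspace(0.85, span - 0.80, n_points)
        qs, es = [], []
        for si in s:
            x0[t.h] = d + si * axis
            es.append(self.energy(x0))
            qs.append(self.transfer_coordinate(x0))
        return np.array(qs), np.array(es)

    def rigid_scan_barrier(self):
        """(barrier above the reactant well, product-minus-reactant offset)."""
        q, e = self.rigid_scan()
        minima = _local_minima_indices(e)
        if len(minima) != 2:
            return np.nan, np.nan
        i_react, i_prod = minima
        saddle = i_react + int(np.argmax(e[i_react:i_prod + 1]))
        return (
            float(e[saddle] - e[i_react]),
            float(e[i_prod] - e[i_react]),
        )

    def _minimize_from(self, x0: np.ndarray) -> np.ndarray:
        res = minimize(
            lambda v: self.energy_forces(v.reshape(-1, 3))[0],
            x0.ravel(),
            jac=lambda v: -self.energy_forces(v.reshape(-1, 3))[1].ravel(),
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-9},
        )
        return res.x.reshape(-1, 3)

    def _penalized_min(self, q_target: float, x_start: np.ndarray,
                       k_pen: float = 500.0) -> np.ndarray:
        """Minimize E + k (q - q_target)^2 — a relaxed-scan point."""
        t = self.params.transfer

        def fun(v):
            x = v.reshape(-1, 3)
            try:
                e, f = self.energy_forces(x)
            except SingularGeometryError:
                # huge finite value: the line search backtracks
                return 1e9, np.zeros_like(v)
            r_dh_vec = x[t.h] - x[t.donor]
            r_ah_vec = x[t.h] - x[t.acceptor]
            r_dh = np.linalg.norm(r_dh_vec)
            r_ah = np.linalg.norm(r_ah_vec)
            q = r_dh - r_ah
            grad = -f
            pen_dq = 2.0 * k_pen * (q - q_target)
            u_dh = r_dh_vec / r_dh
            u_ah = r_ah_vec / r_ah
            grad[t.h] += pen_dq * (u_dh - u_ah)
            grad[t.donor] += pen_dq * (-u_dh)
            grad[t.acceptor] += pen_dq * (u_ah)
            return e + k_pen * (q - q_target) ** 2, grad.ravel()

        res = minimize(
            fun,
            x_start.ravel(),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-8},
        )
        return res.x.reshape(-1, 3)

    def _newton_polish(self, geom: np.ndarray, n_iter: int = 10) -> np.ndarray:
        """Newton steps on grad E = 0 with near-zero modes projected out."""
        x = geom.ravel().copy()
        h = 1e-5
        for _ in range(n_iter):
            g = -self.energy_forces(x.reshape(-1, 3))[1].ravel()
            if np.abs(g).max() < 1e-10:
                break
            hess = np.empty((x.size, x.size))
            for k in range(x.size):
                xp = x.copy()
                xp[k] += h
                xm = x.copy()
                xm[k] -= h
                fp = -self.energy_forces(xp.reshape(-1, 3))[1].ravel()
                fm = -self.energy_forces(xm.reshape(-1, 3))[1].ravel()
                hess[:, k] = (fp - fm) / (2 * h)
            hess = 0.5 * (hess + hess.T)
            w, v = np.linalg.eigh(hess)
            keep = np.abs(w) > 1e-4  # drop translation/rotation modes
            step = v[:, keep] @ ((v[:, keep].T @ g) / w[keep])
            x -= step
        return x.reshape(-1, 3)

    def _stationary(self, key):
        if key in self._cache:
            return self._cache[key]
        t = self.params.transfer
        x0 = _template_geometry().copy()
        # the template has exact mirror symmetry; a tiny deterministic
        # perturbation lets the optimizer leave the symmetric subspace
        # (which can be a saddle of the full space)
        x0 += 0.02 * np.random.default_rng(12345).standard_normal(x0.shape)
        d, a = x0[t.donor], x0[t.acceptor]
        axis = (a - d) / np.linalg.norm(a - d)
        if key == "reactant":
            x0[t.h] = d + t.donor_morse[2] * axis
            geom = self._newton_polish(self._minimize_from(x0))
        elif key == "product":
            x0[t.h] = a - t.acceptor_morse[2] * axis
            geom = self._newton_polish(self._minimize_from(x0))
        elif key == "saddle":
            # relaxed scan along q: constrain q by a quadratic penalty,
            # minimize all other degrees of freedom (with continuation from
            # the reactant well), take the path maximum — a first-order
            # saddle — and Newton-polish it to grad E = 0
            q_r = self.transfer_coordinate(self.reactant_geometry)
            q_p = self.transfer_coordinate(self.product_geometry)
            targets = np.linspace(q_r + 0.08, q_p - 0.08, 17)
            xcur = self.reactant_geometry.copy()
            path = []
            for q_t in targets:
                xcur = self._penalized_min(q_t, xcur)
                path.append((self.energy(xcur), xcur.copy()))
            geom = self._newton_polish(max(path, key=lambda p: p[0])[1])
            if np.abs(self.energy_forces(geom)[1]).max() > 1e-7:
                raise RuntimeError("saddle search did not converge")
        else:  # pragma: no cover
            raise KeyError(key)
        self._cache[key] = geom
        return geom

    @property
    def reactant_geometry(self) -> np.ndarray:
        return self._stationary("reactant")

    @property
    def product_geometry(self) -> np.ndarray:
        return self._stationary("product")

    @property
    def saddle_geometry(self) -> np.ndarray:
        return self._stationary("saddle")

    @property
    def min_energy(self) -> float:
        return min(
            self.energy(self.reactant_geometry),
            self.energy(self.product_geometry),
        )

    def default_ood_window(self) -> tuple:
        """A q-window around the transition state, clear of both wells.

        The window spans 60% of the distance from the saddle towards each
        well, leaving a genuine coverage gap between the training samples
        (wells + path outside the window) and the held-out region.
        """
        q_r = self.transfer_coordinate(self.reactant_geometry)
        q_p = self.transfer_coordinate(self.product_geometry)
        q_ts = self.transfer_coordinate(self.saddle_geometry)
        return (
            q_ts - 0.6 * (q_ts - q_r),
            q_ts + 0.6 * (q_p - q_ts),
        )

    # -- labelling ---------------------------------------------------------
    def dipole(self, coordinates) -> np.ndarray:
        charges = np.array(
            [POINT_CHARGES[z] for z in self.atomic_numbers]
        )
        return EA_TO_DEBYE * charges @ np.asarray(coordinates, dtype=float)

    def label(self, coordinates, tag: str = "") -> Structure:
        e, f = self.energy_forces(coordinates)
        return Structure(
            atomic_numbers=self.atomic_numbers,
            coordinates=np.asarray(coordinates, dtype=float),
            energy=e,
            forces=f,
            total_charge=0.0,
            dipole=self.dipole(coordinates),
            tag=tag,
        )


def _local_minima_indices(e: np.ndarray) -> list:
    return [
        i
        for i in range(1, len(e) - 1)
        if e[i] < e[i - 1] and e[i] < e[i + 1]
    ]


def _count_local_minima(e: np.ndarray) -> int:
    return len(_local_minima_indices(e))


def _ensure_pes(pes_or_params) -> ToyPES:
    if isinstance(pes_or_params, ToyPES):
        return pes_or_params
    return ToyPES(pes_or_params)


def _draw_structures(
    pes: ToyPES,
    config: SamplerConfig,
    rng: np.random.Generator,
    n: int,
    region: str,
    temperatures=None,
):
    """Rejection-sample labelled structures from one region.

    region: "id"  — well displacements + path points outside the OOD window
            "ood" — path points inside the OOD window
    Returns (structures, n_proposed, n_cap_rejected).
    """
    window = (
        config.ood_window
        if config.ood_window is not None
        else pes.default_ood_window()
    )
    temps = list(temperatures if temperatures is not None else config.temperatures)
    react = pes.reactant_geometry
    prod = pes.product_geometry
    e_min = pes.min_energy
    out = []
    n_prop = 0
    n_cap = 0
    max_prop = max(200, 10 * n) * 5
    while len(out) < n and n_prop < max_prop:
        n_prop += 1
        temp = temps[n_prop % len(temps)]
        scale = config.displacement_scale * np.sqrt(max(temp, 1.0) / 300.0)
        if region == "ood":
            t = rng.uniform(0.25, 0.75)
            base = (1 - t) * react + t * prod
            noise = 0.4 * scale
        else:
            u = rng.uniform()
            if u < config.path_fraction:
                t = rng.uniform(0.0, 1.0)
                base = (1 - t) * react + t * prod
                noise = 0.4 * scale
            else:
                base = react if u < (1 + config.path_fraction) / 2 else prod
                noise = scale
        coords = base + rng.normal(0.0, noise, size=base.shape)
        q = pes.transfer_coordinate(coords)
        inside = window[0] < q < window[1]
        if region == "ood" and not inside:
            continue
        if region == "id" and inside:
            continue
        try:
            e = pes.energy(coords)
        except SingularGeometryError:
            continue
        if e - e_min > config.energy_cap:
            n_cap += 1
            continue
        out.append(pes.label(coords, tag="ood" if region == "ood" else ""))
    if len(out) < n:
        raise SamplingEfficiencyError(
            f"only {len(out)}/{n} samples accepted after {n_prop} proposals "
            f"({n_cap} rejected by the {config.energy_cap} kcal/mol cap); "
            "raise the cap or reduce displacement_scale"
        )
    return out, n_prop, n_cap


def sample_dataset(pes_or_params, config: SamplerConfig) -> Dataset:
    """Draw an in-distribution dataset under the energy-cap filter.

    Structures inside the OOD window are never produced here; every retained
    structure satisfies E - E_min <= energy_cap. Deterministic given
    ``config.seed``.
    """
    pes = _ensure_pes(pes_or_params)
    rng = np.random.default_rng(config.seed)
    structures, n_prop, n_cap = _draw_structures(
        pes, config, rng, config.n_samples, region="id"
    )
    accept = len(structures) / n_prop
    if accept < 0.10:
        raise SamplingEfficiencyError(
            f"acceptance rate {accept:.1%} < 10% "
            f"({n_cap} cap rejections of {n_prop} proposals)"
        )
    logger.info(
        "sampled %d structures (%d proposals, %d over the %.0f kcal/mol cap)",
        len(structures),
        n_prop,
        n_cap,
        config.energy_cap,
    )
    return Dataset(structures)


def make_benchmark(
    pes_or_params,
    config: SamplerConfig,
    n_test_id: int = 400,
    n_test_ood: int = 100,
    test_temperatures=(300.0, 600.0, 1000.0),
    train_fraction: float = 0.8,
):
    """Build the full benchmark: train/validation set, test set, OOD flags.

    The test set mixes in-distribution draws (over a wider temperature range
    than training, emulating an unseen test distribution) with draws from
    the held-out transition-state window; the boolean flags mark the latter.
    """
    from .chemio import split_dataset

    pes = _ensure_pes(pes_or_params)
    trainval = sample_dataset(pes, config)
    trainval = split_dataset(trainval, train_fraction, seed=config.seed + 1)
    rng = np.random.default_rng(config.seed + 2)
    id_structs, _, _ = _draw_structures(
        pes, config, rng, n_test_id, region="id",
        temperatures=test_temperatures,
    )
    ood_structs = []
    if n_test_ood > 0:
        ood_structs, _, _ = _draw_structures(
            pes, config, rng, n_test_ood, region="ood"
        )
    test = Dataset(
        id_structs + ood_structs,
        ["test"] * (len(id_structs) + len(ood_structs)),
    )
    flags = np.array(
        [False] * len(id_structs) + [True] * len(ood_structs)
    )
    return trainval, test, flags
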