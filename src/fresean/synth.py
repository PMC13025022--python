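"""Synthetic bead systems with known ground truth.

This module generates every kind of input the analysis stages consume:

* harmonic bead-spring networks (:class:`HarmonicNetwork`) and general
  prescribed-spectrum quadratic networks (:class:`QuadraticNetwork`)
  with analytic normal modes as oracles,
* Langevin (BAOAB) trajectories of those networks at a set temperature,
* rigid-body trajectories with exact translational/rotational diffusion,
* a two-state system with a known soft transition mode, and
* a toy well-tempered metadynamics engine writing PLUMED-dialect
  COLVAR/HILLS data.

Units follow the GROMACS convention (nm, ps, amu, kJ/mol, K), so
kT = 0.008314 * T kJ/mol and angular frequencies in rad/ps map to
wavenumbers via nu = omega / (2 pi c).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import KB, angular_to_wavenumber, wavenumber_to_angular
from .metad import ColvarSeries, HillsSeries
from .spectral import ModeSet
from .trajectory import Trajectory

__all__ = [
    "soft_mode_network",
    "diffusing_network_trajectory",
    "HarmonicNetwork",
    "QuadraticNetwork",
    "TwoStateSystem",
    "ToyPotential",
    "NormalModeResult",
    "analytic_normal_modes",
    "langevin_trajectory",
    "rigid_body_trajectory",
    "two_state_system",
    "toy_wt_metadynamics",
]


# ---------------------------------------------------------------------------
# bead systems
# ---------------------------------------------------------------------------

@dataclass
class HarmonicNetwork:
    """Bead-spring network: pairwise springs between point masses.

    ``springs`` is a list of ``(i, j, stiffness kJ/mol/nm^2, rest length
    nm)``; a rest length of ``None`` means "the distance in ``coords``"
    (the network is then at mechanical equilibrium by construction).
    """

    coords: np.ndarray                       # (n, 3) nm, rest geometry
    masses: np.ndarray                       # (n,) amu
    springs: list[tuple]                     # (i, j, k, L0-or-None)
    temperature: float = 300.0               # K
    friction: float = 1.0                    # 1/ps

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if np.any(self.masses <= 0):
            raise ValueError("bead masses must be positive")
        resolved = []
        for (i, j, k, L0) in self.springs:
            if k <= 0:
                raise ValueError("spring stiffness must be positive")
            if L0 is None:
                L0 = float(np.linalg.norm(self.coords[i] - self.coords[j]))
            resolved.append((int(i), int(j), float(k), float(L0)))
        self.springs = resolved
        self._si = np.array([s[0] for s in resolved], dtype=int)
        self._sj = np.array([s[1] for s in resolved], dtype=int)
        self._sk = np.array([s[2] for s in resolved])
        self._sl = np.array([s[3] for s in resolved])

    @property
    def n_beads(self) -> int:
        return len(self.masses)

    @property
    def n_connected_components(self) -> int:
        """Connected components of the spring graph (extra zero modes
        are expected, not an error, when this exceeds 1)."""
        parent = list(range(self.n_beads))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for (i, j, _, _) in self.springs:
            parent[find(i)] = find(j)
        return len({find(a) for a in range(self.n_beads)})

    def potential(self, x: np.ndarray) -> float:
        d = x[self._si] - x[self._sj]
        L = np.linalg.norm(d, axis=1)
        return float(0.5 * np.sum(self._sk * (L - self._sl) ** 2))

    def force(self, x: np.ndarray) -> np.ndarray:
        d = x[self._si] - x[self._sj]
        L = np.linalg.norm(d, axis=1)
        f_pair = (-self._sk * (L - self._sl) / L)[:, None] * d
        F = np.zeros_like(x)
        np.add.at(F, self._si, f_pair)
        np.add.at(F, self._sj, -f_pair)
        return F

    def hessian(self) -> np.ndarray:
        """Analytic Hessian (3n x 3n) at the rest geometry."""
        n = self.n_beads
        H = np.zeros((3 * n, 3 * n))
        for (i, j, k, L0) in self.springs:
            d = self.coords[i] - self.coords[j]
            L = np.linalg.norm(d)
            nij = d / L
            P = np.outer(nij, nij)
            B = k * (P + (1.0 - L0 / L) * (np.eye(3) - P))
            si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
            H[si, si] += B
            H[sj, sj] += B
            H[si, sj] -= B
            H[sj, si] -= B
        return H

    def max_frequency_cm(self) -> float:
        return analytic_normal_modes(self).frequencies_cm.max()


@dataclass
class QuadraticNetwork:
    """General quadratic bead system with a prescribed mode spectrum.

    Built from orthonormal mass-weighted eigenvectors and wavenumbers:
    V(x) = 1/2 y^T (sum_k omega_k^2 e_k e_k^T) y with
    y = M^(1/2) (x - x0).  Wavenumber 0 gives a flat (freely diffusing)
    internal direction — the toy analogue of an anharmonic
    zero-frequency motion.
    """

    coords: np.ndarray                 # (n, 3) nm
    masses: np.ndarray                 # (n,) amu
    mode_vectors: np.ndarray           # (m, 3n) orthonormal, mass-weighted space
    wavenumbers: np.ndarray            # (m,) cm^-1, >= 0
    temperature: float = 300.0
    friction: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.mode_vectors = np.asarray(self.mode_vectors, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        g = self.mode_vectors @ self.mode_vectors.T
        if np.abs(g - np.eye(len(g))).max() > 1e-8:
            raise ValueError("mode_vectors must be orthonormal")
        self._sqm = np.repeat(np.sqrt(self.masses), 3)
        om2 = wavenumber_to_angular(self.wavenumbers) ** 2
        self._Kmw = (self.mode_vectors.T * om2) @ self.mode_vectors

    @property
    def n_beads(self) -> int:
        return len(self.masses)

    def potential(self, x: np.ndarray) -> float:
        y = self._sqm * (x - self.coords).ravel()
        return float(0.5 * y @ self._Kmw @ y)

    def force(self, x: np.ndarray) -> np.ndarray:
        y = self._sqm * (x - self.coords).ravel()
        return (-(self._Kmw @ y) * self._sqm).reshape(-1, 3)

    def hessian(self) -> np.ndarray:
        return (self._Kmw * self._sqm[None, :]) * self._sqm[:, None]

    def max_frequency_cm(self) -> float:
        return float(self.wavenumbers.max()) if len(self.wavenumbers) else 0.0


# ---------------------------------------------------------------------------
# analytic normal modes (oracle)
# ---------------------------------------------------------------------------

@dataclass
class NormalModeResult:
    modes: ModeSet                 # eigenvalues = omega^2 (rad/ps)^2, ascending
    frequencies_cm: np.ndarray     # (3n,)
    n_zero_modes: int
    disconnected: bool


def analytic_normal_modes(network, zero_tol: float = 1e-8) -> NormalModeResult:
    """Mass-weighted Hessian eigenmodes with frequencies in cm^-1.

    A free 3D non-collinear connected network has exactly 6 zero modes
    (3 translations + 3 rotations); disconnected networks are flagged
    and carry extra zero modes by construction.
    """
    if network.n_beads < 2:
        raise ValueError("need at least two beads for normal modes")
    H = network.hessian()
    sqm = np.repeat(np.sqrt(network.masses), 3)
    Hmw = H / sqm[:, None] / sqm[None, :]
    Hmw = 0.5 * (Hmw + Hmw.T)
    evals, evecs = np.linalg.eigh(Hmw)
    scale = max(abs(evals).max(), 1.0)
    n_zero = int(np.sum(np.abs(evals) < zero_tol * scale))
    freqs = angular_to_wavenumber(np.sqrt(np.clip(evals, 0.0, None)))
    modes = ModeSet(
        vectors=evecs.T,
        eigenvalues=evals,
        masses=network.masses,
        frequency=None,
        reference=network.coords,
    )
    disconnected = getattr(network, "n_connected_components", 1) > 1
    return NormalModeResult(modes, np.asarray(freqs), n_zero, disconnected)


# ---------------------------------------------------------------------------
# Langevin dynamics (BAOAB)
# ---------------------------------------------------------------------------

def langevin_trajectory(
    system,
    dt: float,
    n_steps: int,
    output_stride: int = 1,
    seed: int = 0,
    *,
    burn_in: float = 0.1,
    x0: np.ndarray | None = None,
    check_every: int = 1000,
) -> Trajectory:
    """BAOAB Langevin trajectory of any system with .force/.masses.

    Positions and velocities are recorded every ``output_stride`` steps
    after discarding the first ``burn_in`` fraction of steps; a fixed
    seed makes the output reproducible bit for bit.
    """
    nu_max = system.max_frequency_cm() if hasattr(system, "max_frequency_cm") else 0.0
    from .constants import C_CM_PS

    if nu_max > 0 and dt * nu_max * C_CM_PS >= 0.05:
        raise ValueError(
            f"dt={dt} ps too large for fastest mode at {nu_max:.1f} cm^-1 "
            "(require dt * nu_max * c < 0.05)"
        )
    rng = np.random.default_rng(seed)
    m = system.masses[:, None]
    kT = KB * system.temperature
    gamma = system.friction
    c1 = math.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kT / m)
    sig_v = np.sqrt(kT / m)

    x = np.array(x0 if x0 is not None else system.coords, dtype=float)
    v = rng.standard_normal(x.shape) * sig_v if system.temperature > 0 else np.zeros_like(x)
    F = system.force(x)

    n_burn = int(burn_in * n_steps)
    n_out = (n_steps - n_burn) // output_stride
    times = np.arange(n_out) * dt * output_stride
    pos = np.empty((n_out, system.n_beads, 3))
    vel = np.empty((n_out, system.n_beads, 3))
    iout = 0
    for step in range(n_steps):
        v += 0.5 * dt * F / m
        x += 0.5 * dt * v
        v = c1 * v + c2 * rng.standard_normal(x.shape)
        x += 0.5 * dt * v
        F = system.force(x)
        v += 0.5 * dt * F / m
        if step >= n_burn and (step - n_burn) % output_stride == 0 and iout < n_out:
            pos[iout] = x
            vel[iout] = v
            iout += 1
        if check_every and step % check_every == 0:
            ke = 0.5 * float((m * v * v).sum())
            if not np.isfinite(ke) or (kT > 0 and ke > 1e4 * x.size * kT):
                raise RuntimeError(
                    f"Langevin integration unstable at step {step}: "
                    f"kinetic energy {ke:.3g} kJ/mol diverged (dt too large?)"
                )
    return Trajectory(times, pos, vel)


# ---------------------------------------------------------------------------
# rigid-body diffusion
# ---------------------------------------------------------------------------

def _ou_exact_step_params(gamma, kT_over_m, dt):
    """Exact one-step covariances of the Langevin (v, dx) pair."""
    a = math.exp(-gamma * dt)
    var_v = kT_over_m * (1.0 - a * a)
    var_x = kT_over_m / gamma**2 * (2.0 * gamma * dt - 3.0 + 4.0 * a - a * a)
    cov = kT_over_m / gamma * (1.0 - a) ** 2
    return a, var_v, var_x, cov


def _rodrigues(omega_dt: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(omega_dt)
    if theta < 1e-12:
        return np.eye(3)
    k = omega_dt / theta
    Kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + math.sin(theta) * Kx + (1 - math.cos(theta)) * (Kx @ Kx)


def _rigid_body_states(coords, masses, temperature, seed, n_steps, dt, friction):
    """Rigid-body diffusion states: (X, R, V, w_lab) per frame.

    Centre-of-mass velocity and body-frame angular velocities follow
    exact Ornstein-Uhlenbeck updates at the output interval ``dt``.
    """
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if len(coords) < 3:
        raise ValueError("need at least 3 beads for a rigid body")
    M = masses.sum()
    com = (masses[:, None] * coords).sum(axis=0) / M
    b = coords - com
    inertia = np.einsum("n,nij->ij",
                        masses,
                        (np.einsum("nx,nx->n", b, b)[:, None, None] * np.eye(3)
                         - b[:, :, None] * b[:, None, :]))
    Imom, axes = np.linalg.eigh(inertia)
    if Imom[0] < 1e-10 * Imom[-1]:
        raise ValueError("collinear body: rotation about its axis is undefined")

    rng = np.random.default_rng(seed)
    kT = KB * temperature
    aT, vvT, xxT, cvT = _ou_exact_step_params(friction, kT / M, dt)
    rot_p = [_ou_exact_step_params(friction, kT / I, dt) for I in Imom]

    V = rng.standard_normal(3) * math.sqrt(kT / M) if temperature > 0 else np.zeros(3)
    W = (rng.standard_normal(3) * np.sqrt(kT / Imom)) if temperature > 0 else np.zeros(3)
    X = com.copy()
    R = np.eye(3)

    Xs = np.empty((n_steps, 3))
    Rs = np.empty((n_steps, 3, 3))
    Vs = np.empty((n_steps, 3))
    Ws = np.empty((n_steps, 3))
    for f in range(n_steps):
        Xs[f], Rs[f], Vs[f] = X, R, V
        Ws[f] = R @ (axes @ W)  # principal -> lab angular velocity
        if temperature > 0:
            z1, z2 = rng.standard_normal(3), rng.standard_normal(3)
            dx = (1 - aT) / friction * V + (cvT / math.sqrt(vvT)) * z1 \
                + math.sqrt(max(xxT - cvT**2 / vvT, 0.0)) * z2
            V = aT * V + math.sqrt(vvT) * z1
            X = X + dx
            for axis in range(3):
                aR, vvR, _, _ = rot_p[axis]
                W[axis] = aR * W[axis] + math.sqrt(vvR) * rng.standard_normal()
        R = R @ _rodrigues((axes @ W) * dt)
        if f % 1000 == 0:
            # keep R orthonormal against accumulated round-off
            u, _, vt = np.linalg.svd(R)
            R = u @ vt
    return Xs, Rs, Vs, Ws, com


def rigid_body_trajectory(
    coords: np.ndarray,
    masses: np.ndarray,
    temperature: float,
    seed: int,
    n_steps: int,
    dt: float = 0.02,
    friction: float = 1.0,
) -> Trajectory:
    """Thermal translational/rotational diffusion of a rigid bead body.

    Intra-body distances are constant by construction; translational and
    angular velocities are thermal (exact OU processes).
    """
    Xs, Rs, Vs, Ws, com = _rigid_body_states(
        coords, masses, temperature, seed, n_steps, dt, friction
    )
    b = np.asarray(coords, dtype=float) - com
    arm = np.einsum("fxy,ny->fnx", Rs, b)
    pos = Xs[:, None, :] + arm
    vel = Vs[:, None, :] + np.cross(Ws[:, None, :], arm)
    times = np.arange(n_steps) * dt
    return Trajectory(times, pos, vel)


def soft_mode_network(
    seed: int = 0,
    *,
    n_beads: int = 10,
    soft_wavenumbers: tuple[float, ...] = (8.0, 9.0, 10.0),
    rigid_confinement: float = 70.0,
    stiff_range: tuple[float, float] = (60.0, 80.0),
    bead_mass: float = 100.0,
    temperature: float = 300.0,
    friction: float = 1.0,
) -> tuple[QuadraticNetwork, np.ndarray]:
    """Random network with a designed trio of soft low-frequency modes.

    Returns ``(network, soft_vectors)``.  The network's mode list starts
    with the 6 linearized rigid-body directions (confined at
    ``rigid_confinement`` so the quadratic model stays valid), followed
    by the designed soft modes and a stiff remainder; true rigid-body
    diffusion is superimposed by :func:`diffusing_network_trajectory`.
    """
    from .compare import rigid_body_basis

    rng = np.random.default_rng(seed)
    coords = _random_geometry(rng, n_beads)
    masses = np.full(n_beads, bead_mass)
    dof = 3 * n_beads
    B = rigid_body_basis(masses, coords)
    Q, _ = np.linalg.qr(np.hstack([B.T, rng.standard_normal((dof, dof - 6))]))
    internal = Q[:, 6:].T
    n_soft = len(soft_wavenumbers)
    wn = np.concatenate([
        np.full(6, rigid_confinement),
        np.asarray(soft_wavenumbers, dtype=float),
        np.linspace(*stiff_range, dof - 6 - n_soft),
    ])
    vecs = np.vstack([B, internal])
    net = QuadraticNetwork(coords, masses, vecs, wn,
                           temperature=temperature, friction=friction)
    return net, internal[:n_soft].copy()


def diffusing_network_trajectory(
    network: QuadraticNetwork,
    seed: int,
    n_steps: int,
    dt: float = 0.02,
    *,
    burn_in: float = 0.05,
) -> Trajectory:
    """Internal vibrations superimposed on rigid-body diffusion.

    The internal Langevin dynamics of ``network`` (simulated in the
    reference frame) is carried by a freely diffusing rigid body, giving
    a trajectory whose zero-frequency spectrum contains 6 rigid-body
    modes followed by the network's softest internal vibrations — the
    toy analogue of a diffusing protein.  Rotation-vibration coupling is
    neglected, which is exactly the approximation an aligned-frame
    spectral analysis assumes.
    """
    internal = langevin_trajectory(
        network, dt=dt, n_steps=n_steps, seed=seed, burn_in=burn_in
    )
    F = internal.n_frames
    Xs, Rs, Vs, Ws, com = _rigid_body_states(
        network.coords, network.masses, network.temperature,
        seed + 7_654_321, F, dt, network.friction,
    )
    d = internal.positions - com
    arm = np.einsum("fxy,fny->fnx", Rs, d)
    pos = Xs[:, None, :] + arm
    vel = (Vs[:, None, :] + np.cross(Ws[:, None, :], arm)
           + np.einsum("fxy,fny->fnx", Rs, internal.velocities))
    return Trajectory(internal.times.copy(), pos, vel)


# ---------------------------------------------------------------------------
# two-state system
# ---------------------------------------------------------------------------

@dataclass
class TwoStateSystem:
    """Bead system with a quartic double well along one collective mode.

    In mass-weighted coordinates y = M^(1/2)(x - x0), the potential is
    harmonic along all basis directions except ``u``, where it is
    V(q) = B ((q/q0)^2 - 1)^2 with q = u . y — two minima at q = +-q0
    separated by a barrier of height B.
    """

    coords: np.ndarray
    masses: np.ndarray
    basis: np.ndarray          # (3n, 3n) orthonormal rows, mass-weighted space
    wavenumbers: np.ndarray    # (3n,) cm^-1 for harmonic directions
    u_index: int               # which basis row is the double-well direction
    barrier: float             # kJ/mol
    q0: float                  # nm amu^1/2
    temperature: float = 300.0
    friction: float = 5.0

    def __post_init__(self) -> None:
        self._sqm = np.repeat(np.sqrt(np.asarray(self.masses, dtype=float)), 3)
        om2 = wavenumber_to_angular(np.asarray(self.wavenumbers, dtype=float)) ** 2
        om2[self.u_index] = 0.0
        self._om2 = om2

    @property
    def n_beads(self) -> int:
        return len(self.masses)

    @property
    def transition_mode(self) -> np.ndarray:
        """Unit Cartesian displacement connecting the two minima."""
        d = self.basis[self.u_index] / self._sqm
        return d / np.linalg.norm(d)

    def minima(self) -> tuple[np.ndarray, np.ndarray]:
        du = (self.q0 * self.basis[self.u_index] / self._sqm).reshape(-1, 3)
        return self.coords - du, self.coords + du

    def _split(self, x):
        y = self._sqm * (x - self.coords).ravel()
        p = self.basis @ y
        return y, p

    def potential(self, x: np.ndarray) -> float:
        _, p = self._split(x)
        q = p[self.u_index]
        vh = 0.5 * float(np.sum(self._om2 * p * p))
        return vh + self.barrier * ((q / self.q0) ** 2 - 1.0) ** 2

    def force(self, x: np.ndarray) -> np.ndarray:
        _, p = self._split(x)
        dVdp = self._om2 * p
        q = p[self.u_index]
        dVdp[self.u_index] = 4.0 * self.barrier * q / self.q0**2 * ((q / self.q0) ** 2 - 1.0)
        grad_y = self.basis.T @ dVdp
        return (-(grad_y) * self._sqm).reshape(-1, 3)

    def max_frequency_cm(self) -> float:
        well = angular_to_wavenumber(math.sqrt(8.0 * self.barrier / self.q0**2))
        return max(angular_to_wavenumber(float(np.sqrt(np.max(self._om2)))), well)


def _random_geometry(rng, n_beads, spread=0.6):
    while True:
        coords = rng.normal(scale=spread, size=(n_beads, 3))
        try:
            from .trajectory import _check_not_collinear

            _check_not_collinear(coords, np.ones(n_beads))
            return coords
        except ValueError:  # pragma: no cover - vanishingly unlikely
            continue


def _random_orthonormal_internal_basis(rng, n_dof):
    q, _ = np.linalg.qr(rng.standard_normal((n_dof, n_dof)))
    return q.T


def two_state_system(
    seed: int = 0,
    *,
    n_beads: int = 5,
    barrier_kt: float = 8.0,
    temperature: float = 300.0,
    friction: float = 5.0,
    q0_nm: float = 0.5,
    soft_wavenumber: float = 10.0,
    stiff_wavenumber: float = 80.0,
    bead_mass: float = 10.0,
) -> TwoStateSystem:
    """Toy analogue of a protein with "closed" and "open" conformations.

    One mass-weighted direction carries a double well of height
    ``barrier_kt`` (in units of kT); one carries a soft harmonic
    vibration at ``soft_wavenumber``; the remainder is stiff.
    """
    rng = np.random.default_rng(seed)
    coords = _random_geometry(rng, n_beads)
    masses = np.full(n_beads, bead_mass)
    basis = _random_orthonormal_internal_basis(rng, 3 * n_beads)
    wavenumbers = np.full(3 * n_beads, stiff_wavenumber)
    wavenumbers[1] = soft_wavenumber
    return TwoStateSystem(
        coords=coords,
        masses=masses,
        basis=basis,
        wavenumbers=wavenumbers,
        u_index=0,
        barrier=barrier_kt * KB * temperature,
        q0=q0_nm * math.sqrt(bead_mass),
        temperature=temperature,
        friction=friction,
    )


# ---------------------------------------------------------------------------
# toy potentials and well-tempered metadynamics
# ---------------------------------------------------------------------------

_MB_DEFAULT = {
    "A": (-200.0, -100.0, -170.0, 15.0),
    "a": (-1.0, -1.0, -6.5, 0.7),
    "b": (0.0, 0.0, 11.0, 0.6),
    "c": (-10.0, -10.0, -6.5, 0.7),
    "x0": (1.0, 0.0, -0.5, -1.0),
    "y0": (0.0, 0.5, 1.5, 1.0),
    "scale": 0.02,
}


@dataclass
class ToyPotential:
    """Analytic low-dimensional potential with known minima.

    kinds: ``double_well`` (params: barrier kJ/mol, a nm, k_y), 1D or 2D;
    ``harmonic_valley`` (params: k_x, k_y); ``mueller_brown`` (2D,
    Mueller-Brown-like sum of four Gaussians scaled to molecular
    energies).
    """

    kind: str
    params: dict = field(default_factory=dict)
    dim: int = 1

    def __post_init__(self) -> None:
        if self.kind not in {"double_well", "harmonic_valley", "mueller_brown"}:
            raise ValueError(f"unknown potential kind {self.kind!r}")
        if self.kind == "mueller_brown":
            self.dim = 2
            self.params = {**_MB_DEFAULT, **self.params}
        elif self.kind == "double_well":
            self.params = {"barrier": 10.0, "a": 1.0, "k_y": 20.0, **self.params}
        else:
            self.params = {"k_x": 20.0, "k_y": 20.0, **self.params}

    def energy(self, s: np.ndarray) -> np.ndarray:
        s = np.atleast_2d(s)
        if self.kind == "double_well":
            B, a = self.params["barrier"], self.params["a"]
            v = B * ((s[:, 0] / a) ** 2 - 1.0) ** 2
            if self.dim == 2:
                v = v + 0.5 * self.params["k_y"] * s[:, 1] ** 2
            return v
        if self.kind == "harmonic_valley":
            v = 0.5 * self.params["k_x"] * s[:, 0] ** 2
            if self.dim == 2:
                v = v + 0.5 * self.params["k_y"] * s[:, 1] ** 2
            return v
        p = self.params
        v = np.zeros(len(s))
        for A, a_, b_, c_, x0, y0 in zip(*(p[k] for k in ("A", "a", "b", "c", "x0", "y0"))):
            dx, dy = s[:, 0] - x0, s[:, 1] - y0
            v += A * np.exp(a_ * dx**2 + b_ * dx * dy + c_ * dy**2)
        return p["scale"] * v

    def gradient(self, s: np.ndarray) -> np.ndarray:
        s = np.atleast_2d(s)
        g = np.zeros_like(s)
        if self.kind == "double_well":
            B, a = self.params["barrier"], self.params["a"]
            g[:, 0] = 4.0 * B * s[:, 0] / a**2 * ((s[:, 0] / a) ** 2 - 1.0)
            if self.dim == 2:
                g[:, 1] = self.params["k_y"] * s[:, 1]
            return g
        if self.kind == "harmonic_valley":
            g[:, 0] = self.params["k_x"] * s[:, 0]
            if self.dim == 2:
                g[:, 1] = self.params["k_y"] * s[:, 1]
            return g
        p = self.params
        for A, a_, b_, c_, x0, y0 in zip(*(p[k] for k in ("A", "a", "b", "c", "x0", "y0"))):
            dx, dy = s[:, 0] - x0, s[:, 1] - y0
            e = A * np.exp(a_ * dx**2 + b_ * dx * dy + c_ * dy**2)
            g[:, 0] += e * (2 * a_ * dx + b_ * dy)
            g[:, 1] += e * (b_ * dx + 2 * c_ * dy)
        return p["scale"] * g

    def minima(self) -> np.ndarray:
        if self.kind == "double_well":
            a = self.params["a"]
            pts = np.array([[-a], [a]])
            if self.dim == 2:
                pts = np.hstack([pts, np.zeros((2, 1))])
            return pts
        if self.kind == "harmonic_valley":
            return np.zeros((1, self.dim))
        return np.array([[-0.558, 1.442], [0.623, 0.028]])  # principal MB minima


def toy_wt_metadynamics(
    potential: ToyPotential,
    cv_names: tuple[str, ...] | None = None,
    *,
    height: float,
    sigma,
    pace: int,
    bias_factor: float,
    temperature: float = 300.0,
    seed: int = 0,
    n_steps: int = 100_000,
    dt: float = 0.02,
    mass: float = 1.0,
    friction: float = 5.0,
    x0: np.ndarray | None = None,
    colvar_stride: int = 10,
    cv_matrix: np.ndarray | None = None,
) -> tuple[ColvarSeries, HillsSeries]:
    """Langevin dynamics on a toy potential with well-tempered biasing.

    Every ``pace`` steps a Gaussian hill of width ``sigma`` is deposited
    with the well-tempered height h * exp(-V_bias / ((gamma-1) kT)); the
    CV series and hill history are returned as PLUMED-dialect objects.
    ``height = 0`` disables biasing (plain Langevin sampling).

    The biased CVs are linear combinations of the coordinates, rows of
    ``cv_matrix`` (default: identity — every coordinate is a CV).  The
    COLVAR output always contains the raw coordinates as well, so
    reweighted ensembles can be projected onto unbiased variables.
    """
    if bias_factor <= 1.0:
        raise ValueError("well-tempered bias factor must exceed 1")
    if pace < 1:
        raise ValueError("pace must be >= 1")
    d = potential.dim
    coord_names = tuple("xy"[:d]) if d <= 2 else tuple(f"s{i}" for i in range(d))
    C = np.eye(d) if cv_matrix is None else np.atleast_2d(np.asarray(cv_matrix, dtype=float))
    if C.shape[1] != d:
        raise ValueError("cv_matrix columns must match the potential dimension")
    ncv = len(C)
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (ncv,)).copy()
    if np.any(sigma <= 0):
        raise ValueError("hill widths must be positive")
    if cv_names is None:
        cv_names = coord_names if cv_matrix is None else tuple(
            f"cv{i + 1}" for i in range(ncv)
        )
    kT = KB * temperature
    rng = np.random.default_rng(seed)

    n_hills_max = n_steps // pace + 1
    h_t = np.empty(n_hills_max)
    h_c = np.empty((n_hills_max, ncv))
    h_h = np.empty(n_hills_max)
    nh = 0

    def bias_and_force(x):
        """Bias value and its force on the *coordinates*."""
        s = C @ x
        if nh == 0:
            return 0.0, np.zeros(d)
        diff = (s[None, :] - h_c[:nh]) / sigma[None, :]
        e = h_h[:nh] * np.exp(-0.5 * np.sum(diff * diff, axis=1))
        f_cv = (e[:, None] * diff / sigma[None, :]).sum(axis=0)
        return float(e.sum()), C.T @ f_cv

    x = np.array(x0 if x0 is not None else potential.minima()[0], dtype=float)
    v = rng.standard_normal(d) * math.sqrt(kT / mass)
    c1 = math.exp(-friction * dt)
    c2 = math.sqrt((1.0 - c1 * c1) * kT / mass)

    def total_force(s):
        vb, fb = bias_and_force(s)
        return -potential.gradient(s)[0] + fb, vb

    F, vb = total_force(x)
    n_out = n_steps // colvar_stride
    ct = np.empty(n_out)
    cs = np.empty((n_out, d))
    cb = np.empty(n_out)
    iout = 0
    for step in range(1, n_steps + 1):
        v += 0.5 * dt * F / mass
        x += 0.5 * dt * v
        v = c1 * v + c2 * rng.standard_normal(d)
        x += 0.5 * dt * v
        F, vb = total_force(x)
        v += 0.5 * dt * F / mass
        t = step * dt
        if height > 0.0 and step % pace == 0:
            h_t[nh] = t
            h_c[nh] = C @ x
            h_h[nh] = height * math.exp(-vb / ((bias_factor - 1.0) * kT))
            nh += 1
            F, vb = total_force(x)
        if step % colvar_stride == 0 and iout < n_out:
            ct[iout] = t
            cs[iout] = x
            cb[iout] = vb
            iout += 1

    import pandas as pd

    data = {"time": ct}
    for i, name in enumerate(coord_names):
        data[name] = cs[:, i]
    if cv_matrix is not None:
        s_all = cs @ C.T
        for i, name in enumerate(cv_names):
            data[name] = s_all[:, i]
    data["metad.bias"] = cb
    colvar = ColvarSeries(data=pd.DataFrame(data), cv_names=tuple(cv_names))
    hills = HillsSeries(
        times=h_t[:nh].copy(),
        centers=h_c[:nh].copy(),
        sigmas=np.tile(sigma, (nh, 1)),
        heights=h_h[:nh].copy(),
        biasf=float(bias_factor),
        cv_names=tuple(cv_names),
    )
    return colvar, hills
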