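"""Mass-weighted velocity cross-correlations and frequency-resolved modes.

The central object is the matrix of mass-weighted velocity
cross-correlation functions of all coarse-grained degrees of freedom,

    C_ab(t) = < sqrt(m_a m_b) v_a(0) v_b(t) >,   a, b = 1 .. 3n,

estimated over all time origins up to a maximum lag (2 ps by default)
and time-symmetrized, C(t) <- [C(t) + C(t)^T] / 2.  A Gaussian-tapered
cosine transform takes the series to the frequency domain on a cm^-1
grid; the taper width is chosen so the implied spectral smoothing has a
configurable full width at half maximum (10 cm^-1 by default).

Eigenvectors of the spectral matrix at a chosen frequency are the
frequency-resolved anharmonic (FRESEAN) modes; their eigenvalues are the
modes' contributions to the vibrational density of states (VDoS) at that
frequency.  At zero frequency, modes 1-3 describe translation, modes 4-6
rotation, and modes 7+ anharmonic low-frequency vibrations.

Transform convention: with lag spacing dt (ps) and windowed, symmetrized
correlations C_k, the one-sided spectral density per cm^-1 is

    S(nu_j) = g_j * c * dt * [C_0 + 2 sum_k C_k w_k cos(2 pi c nu_j k dt)]

evaluated by an FFT of the symmetric, zero-padded lag series; g_j = 2
except at nu = 0 and the Nyquist frequency (g = 1), and c is the speed
of light in cm/ps.  With this convention the discrete sum
``sum_j S(nu_j) dnu`` equals C(0) exactly (Parseval/equipartition
check), because the taper is 1 at t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import C_CM_PS
from .trajectory import Trajectory

__all__ = [
    "CorrelationMatrixSeries",
    "SpectralMatrixSet",
    "ModeSet",
    "Spectrum",
    "velocity_cross_correlation",
    "spectral_matrix",
    "fresean_modes",
    "mode_projected_vdos",
    "total_vdos",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrixSeries:
    """C(t) on a lag grid 0..t_max; entries in amu nm^2/ps^2."""

    lags: np.ndarray        # (K+1,) ps
    matrices: np.ndarray    # (K+1, 3n, 3n)
    symmetrized: bool
    dt: float               # lag spacing, ps

    @property
    def n_dof(self) -> int:
        return self.matrices.shape[1]


@dataclass
class SpectralMatrixSet:
    """Real symmetric spectral matrices on a cm^-1 frequency grid."""

    frequencies: np.ndarray  # (n_freq,) cm^-1, starts at exactly 0
    matrices: np.ndarray     # (n_freq, 3n, 3n)
    window_fwhm: float       # cm^-1

    @property
    def n_dof(self) -> int:
        return self.matrices.shape[1]

    def at(self, frequency: float) -> np.ndarray:
        """Matrix at the grid point nearest ``frequency`` (must lie on grid)."""
        dnu = self.frequencies[1] - self.frequencies[0]
        j = int(round(frequency / dnu))
        if j < 0 or j >= len(self.frequencies) or abs(
            self.frequencies[j] - frequency
        ) > 0.51 * dnu:
            raise ValueError(
                f"frequency {frequency} cm^-1 is not on the spectral grid"
            )
        return self.matrices[j]


@dataclass
class ModeSet:
    """Orthonormal displacement eigenvectors in mass-weighted space.

    ``vectors[k]`` is the k-th mode (length 3n); for FRESEAN modes the
    eigenvalues are VDoS contributions sorted in descending order.
    """

    vectors: np.ndarray               # (k, 3n), rows orthonormal
    eigenvalues: np.ndarray           # (k,)
    masses: np.ndarray                # (n,) amu
    frequency: float | None = None    # cm^-1 tag (None: not frequency-resolved)
    reference: np.ndarray | None = None  # (n, 3) nm
    window_fwhm: float | None = None

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_beads(self) -> int:
        return len(self.masses)

    def mode(self, index: int) -> np.ndarray:
        """1-based access following the field convention (mode 7 = index 7)."""
        if not 1 <= index <= self.n_modes:
            raise IndexError(f"mode index {index} out of range 1..{self.n_modes}")
        return self.vectors[index - 1]

    def orthonormality_error(self) -> float:
        g = self.vectors @ self.vectors.T
        return float(np.abs(g - np.eye(len(g))).max())


@dataclass
class Spectrum:
    """A scalar VDoS-type spectrum on a cm^-1 grid."""

    frequencies: np.ndarray
    intensity: np.ndarray   # amu nm^2/ps^2 per cm^-1

    def integral(self) -> float:
        """Discrete integral over the grid (recovers C(0) by convention)."""
        dnu = self.frequencies[1] - self.frequencies[0]
        return float(self.intensity.sum() * dnu)


# ---------------------------------------------------------------------------
# correlation estimation
# ---------------------------------------------------------------------------

def _mass_weighted_dof_series(traj: Trajectory, masses: np.ndarray) -> np.ndarray:
    if traj.velocities is None:
        raise ValueError("trajectory has no velocities; spectral analysis needs them")
    if len(masses) != traj.n_sites:
        raise ValueError("masses and trajectory disagree on bead count")
    F = traj.n_frames
    U = traj.velocities.reshape(F, -1) * np.repeat(np.sqrt(masses), 3)[None, :]
    return np.ascontiguousarray(U)


def _n_lags(t_max: float, dt: float) -> int:
    k = t_max / dt
    if abs(k - round(k)) > 1e-6:
        raise ValueError(f"t_max={t_max} ps is not a multiple of dt={dt} ps")
    return int(round(k))


def velocity_cross_correlation(
    traj: Trajectory,
    masses: np.ndarray,
    t_max: float = 2.0,
    *,
    origin_stride: int = 1,
    symmetrize: bool = True,
) -> CorrelationMatrixSeries:
    """Estimate the mass-weighted velocity cross-correlation matrices.

    Every frame (or every ``origin_stride``-th frame) serves as a time
    origin; the trajectory must be aligned to a common reference first.
    """
    dt = traj.dt * 1  # ps
    K = _n_lags(t_max, dt)
    if traj.n_frames <= 10 * K:
        raise ValueError(
            f"trajectory too short: need > {10 * K} frames for t_max={t_max} ps"
        )
    U = _mass_weighted_dof_series(traj, masses)
    F, d = U.shape
    mats = np.empty((K + 1, d, d))
    for k in range(K + 1):
        A = U[: F - k : origin_stride]
        B = U[k : F : origin_stride]
        n = len(A)
        mats[k] = A.T @ B / n
    if symmetrize:
        mats = 0.5 * (mats + mats.transpose(0, 2, 1))
    return CorrelationMatrixSeries(
        lags=np.arange(K + 1) * dt, matrices=mats, symmetrized=symmetrize, dt=dt
    )


# ---------------------------------------------------------------------------
# frequency domain
# ---------------------------------------------------------------------------

def gaussian_taper(lags: np.ndarray, window_fwhm: float) -> np.ndarray:
    """Time-domain Gaussian giving a spectral Gaussian of given FWHM (cm^-1)."""
    if window_fwhm <= 0:
        raise ValueError("window width must be positive")
    # FWHM_nu = 2 sqrt(2 ln 2) / (2 pi c sigma_t)
    sigma_t = 2.0 * np.sqrt(2.0 * np.log(2.0)) / (2.0 * np.pi * C_CM_PS * window_fwhm)
    return np.exp(-0.5 * (lags / sigma_t) ** 2)


def _cosine_transform(series: np.ndarray, dt: float, window_fwhm: float,
                      pad_factor: int):
    """Windowed symmetric cosine transform of a lag series.

    ``series`` has shape (K+1, ...); returns (frequencies cm^-1,
    spectrum with leading frequency axis) under the module's one-sided
    per-cm^-1 convention.
    """
    K = series.shape[0] - 1
    lags = np.arange(K + 1) * dt
    w = gaussian_taper(lags, window_fwhm)
    tapered = series * w.reshape((K + 1,) + (1,) * (series.ndim - 1))
    M = pad_factor * (2 * K + 1)
    M += M % 2  # even length so the Nyquist bin is explicit
    buf = np.zeros((M,) + series.shape[1:])
    buf[: K + 1] = tapered
    buf[M - K :] = tapered[1:][::-1]
    spec = np.fft.rfft(buf, axis=0).real * dt
    # one-sided doubling (except nu=0 and Nyquist) and per-cm^-1 scale:
    # S(nu) dnu = g F(f) df with f = c nu
    scale = np.full(len(spec), 2.0)
    scale[0] = 1.0
    scale[-1] = 1.0
    spec *= C_CM_PS * scale.reshape((-1,) + (1,) * (series.ndim - 1))
    freqs = np.fft.rfftfreq(M, d=dt) / C_CM_PS  # cm^-1
    return freqs, spec


def spectral_matrix(
    corr: CorrelationMatrixSeries,
    window_fwhm: float = 10.0,
    pad_factor: int = 4,
) -> SpectralMatrixSet:
    """Fourier-transform a correlation series with a Gaussian window."""
    if not corr.symmetrized:
        raise ValueError("spectral_matrix expects a time-symmetrized series")
    freqs, spec = _cosine_transform(corr.matrices, corr.dt, window_fwhm, pad_factor)
    spec = 0.5 * (spec + spec.transpose(0, 2, 1))
    return SpectralMatrixSet(frequencies=freqs, matrices=spec, window_fwhm=window_fwhm)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Reproducible sign convention: largest-magnitude component positive."""
    idx = np.argmax(np.abs(vectors), axis=1)
    signs = np.sign(vectors[np.arange(len(vectors)), idx])
    signs[signs == 0] = 1.0
    return vectors * signs[:, None]


def fresean_modes(
    spec: SpectralMatrixSet,
    frequency: float = 0.0,
    *,
    masses: np.ndarray | None = None,
    reference: np.ndarray | None = None,
    symmetry_tol: float = 1e-8,
) -> ModeSet:
    """Eigenmodes of the spectral matrix at one frequency grid point.

    Modes are sorted by eigenvalue (VDoS contribution) in descending
    order, so at zero frequency modes 1-6 are rigid-body motion and
    modes 7+ the leading anharmonic vibrations.
    """
    mat = spec.at(frequency)
    asym = np.abs(mat - mat.T).max()
    scale = max(np.abs(mat).max(), 1e-300)
    if asym > max(symmetry_tol * scale, 1e-12):
        raise ValueError("spectral matrix is not symmetric within tolerance")
    evals, evecs = np.linalg.eigh(0.5 * (mat + mat.T))
    order = np.argsort(evals, kind="stable")[::-1]
    vectors = _fix_signs(evecs.T[order])
    if masses is None:
        masses = np.ones(spec.n_dof // 3)
    dnu = spec.frequencies[1] - spec.frequencies[0]
    return ModeSet(
        vectors=vectors,
        eigenvalues=evals[order],
        masses=np.asarray(masses, dtype=float),
        frequency=float(spec.frequencies[int(round(frequency / dnu))]),
        reference=reference,
        window_fwhm=spec.window_fwhm,
    )


def mode_projected_vdos(
    traj: Trajectory,
    mode: np.ndarray,
    masses: np.ndarray,
    t_max: float = 2.0,
    window_fwhm: float = 10.0,
    pad_factor: int = 4,
) -> Spectrum:
    """Spectrum of the velocity component along one mode.

    The scalar velocity is v_k(t) = e_k . u(t) with u the mass-weighted
    bead velocities; summed over a complete orthonormal ModeSet these
    spectra reproduce the total VDoS exactly.
    """
    mode = np.asarray(mode, dtype=float)
    U = _mass_weighted_dof_series(traj, masses)
    if mode.shape != (U.shape[1],):
        raise ValueError("mode vector and trajectory disagree on dimension")
    u = U @ mode
    dt = traj.dt
    K = _n_lags(t_max, dt)
    F = len(u)
    acf = np.empty(K + 1)
    for k in range(K + 1):
        acf[k] = np.dot(u[: F - k], u[k:]) / (F - k)
    freqs, spec = _cosine_transform(acf, dt, window_fwhm, pad_factor)
    return Spectrum(frequencies=freqs, intensity=spec)


def total_vdos(
    corr: CorrelationMatrixSeries,
    window_fwhm: float = 10.0,
    pad_factor: int = 4,
) -> Spectrum:
    """Total vibrational density of states: trace of the spectral matrix."""
    tr = np.trace(corr.matrices, axis1=1, axis2=2)
    freqs, spec = _cosine_transform(tr, corr.dt, window_fwhm, pad_factor)
    return Spectrum(frequencies=freqs, intensity=spec)
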