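"""Shared fixtures: synthetic systems and (expensive) reference analyses.

Heavy trajectory generation is session-scoped so several tests can share
one simulation.  All randomness is seeded; the suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from fresean import (
    ReferenceFrame,
    align_trajectory,
    classify_rigid_modes,
    diffusing_network_trajectory,
    fresean_modes,
    langevin_trajectory,
    reweight,
    rigid_body_trajectory,
    soft_mode_network,
    spectral_matrix,
    toy_wt_metadynamics,
    two_state_system,
    velocity_cross_correlation,
    weighted_fes,
    ToyPotential,
)


class FreeParticles:
    """Force-free thermal beads (duck-typed Langevin system)."""

    def __init__(self, n, mass=10.0, temperature=300.0, friction=20.0):
        self.coords = np.zeros((n, 3))
        self.masses = np.full(n, mass)
        self.temperature = temperature
        self.friction = friction
        self.n_beads = n

    def force(self, x):
        return np.zeros_like(x)

    def max_frequency_cm(self):
        return 0.0


@pytest.fixture(scope="session")
def free_particle_traj():
    sys_ = FreeParticles(2)
    return sys_, langevin_trajectory(sys_, dt=0.02, n_steps=120_000, seed=10)


@pytest.fixture(scope="session")
def soft_network():
    """10-bead network with designed soft modes at 8/9/10 cm^-1."""
    net, soft = soft_mode_network(42)
    return net, soft


def _zero_frequency_modes(net, seed, n_steps):
    traj = diffusing_network_trajectory(net, seed=seed, n_steps=n_steps)
    ref = ReferenceFrame(net.coords, net.masses)
    aligned = align_trajectory(traj, ref)
    corr = velocity_cross_correlation(aligned, net.masses, 2.0)
    spec = spectral_matrix(corr, 10.0)
    modes = fresean_modes(spec, 0.0, masses=net.masses, reference=net.coords)
    return modes, corr, spec, aligned


@pytest.fixture(scope="session")
def replica_mode_analyses(soft_network):
    """Two independent-seed replicas of the soft-mode network.

    Each replica spans >2000 oscillation periods of the slowest designed
    mode (8 cm^-1, 4.2 ps period -> ~8.4 ns at 20 fs output).
    """
    net, soft = soft_network
    out = [_zero_frequency_modes(net, seed, 440_000) for seed in (1, 2)]
    return net, soft, out


@pytest.fixture(scope="session")
def resonance_analysis():
    """Network with one isolated designed 20 cm^-1 mode, analysed at
    its resonance frequency."""
    net, soft = soft_mode_network(7, soft_wavenumbers=(20.0,))
    traj = diffusing_network_trajectory(net, seed=2, n_steps=100_000)
    aligned = align_trajectory(traj, ReferenceFrame(net.coords, net.masses))
    corr = velocity_cross_correlation(aligned, net.masses, 2.0)
    spec = spectral_matrix(corr, 10.0)
    return net, soft, aligned, corr, spec


@pytest.fixture(scope="session")
def rigid_body_analysis():
    """Freely diffusing rigid 10-bead body and its zero-frequency modes."""
    rng = np.random.default_rng(2024)
    coords = rng.normal(scale=0.5, size=(10, 3))
    masses = np.full(10, 12.0)
    traj = rigid_body_trajectory(coords, masses, 300.0, seed=1, n_steps=100_000)
    ref = ReferenceFrame(traj.positions[0], masses)
    aligned = align_trajectory(traj, ref)
    corr = velocity_cross_correlation(aligned, masses, 2.0)
    spec = spectral_matrix(corr, 10.0)
    modes = fresean_modes(spec, 0.0, masses=masses, reference=ref.coords)
    overlaps, flags = classify_rigid_modes(modes)
    return coords, masses, traj, modes, overlaps, flags


@pytest.fixture(scope="session")
def double_well_replicas():
    """Six seeded well-tempered metadynamics replicas on a double well."""
    pot = ToyPotential("double_well", {"barrier": 12.0, "a": 1.0})
    runs, surfaces = [], []
    for s in range(6):
        colvar, hills = toy_wt_metadynamics(
            pot, height=1.2, sigma=0.15, pace=250, bias_factor=10.0,
            seed=100 + s, n_steps=120_000,
        )
        ens = reweight(colvar, hills, 300.0)
        fes = weighted_fes(ens, ("x",), bins=50, ranges=[(-1.5, 1.5)],
                           temperature=300.0)
        runs.append((colvar, hills, ens))
        surfaces.append(fes)
    return pot, runs, surfaces


@pytest.fixture(scope="session")
def two_state_replicas():
    """Six Langevin replicas of the rare-event two-state system.

    At a 7 kT barrier a ~2 ns replica crosses the barrier zero-to-few
    times, so displacement statistics are seed-dependent while velocity
    statistics are not.
    """
    sys_ = two_state_system(0, barrier_kt=7.0, friction=5.0)
    trajs = [
        langevin_trajectory(sys_, dt=0.02, n_steps=100_000, seed=seed,
                            x0=sys_.minima()[0], burn_in=0.05)
        for seed in range(6)
    ]
    return sys_, trajs


@pytest.fixture(scope="session")
def dipeptide_gro(tmp_path_factory):
    """Synthetic Gly-Ala dipeptide GRO file (not a real structure)."""
    atoms = [
        (1, "GLY", "N", 0.000, 0.000, 0.000),
        (1, "GLY", "CA", 0.150, 0.000, 0.000),
        (1, "GLY", "C", 0.200, 0.140, 0.000),
        (1, "GLY", "O", 0.150, 0.250, 0.000),
        (2, "ALA", "N", 0.330, 0.150, 0.000),
        (2, "ALA", "CA", 0.420, 0.260, 0.000),
        (2, "ALA", "CB", 0.560, 0.200, 0.050),
        (2, "ALA", "HB1", 0.640, 0.270, 0.060),
        (2, "ALA", "HB2", 0.570, 0.120, 0.120),
        (2, "ALA", "HB3", 0.560, 0.160, 0.950),
        (2, "ALA", "C", 0.400, 0.400, 0.000),
        (2, "ALA", "O", 0.290, 0.460, 0.000),
    ]
    lines = ["synthetic Gly-Ala dipeptide", f"{len(atoms):5d}"]
    for i, (rid, rn, nm, x, y, z) in enumerate(atoms, 1):
        lines.append(f"{rid:5d}{rn:<5s}{nm:>5s}{i:5d}{x:8.3f}{y:8.3f}{z:8.3f}")
    lines.append("   2.00000   2.00000   2.00000")
    path = tmp_path_factory.mktemp("topo") / "gly_ala.gro"
    path.write_text("\n".join(lines) + "\n")
    return path


def make_gro(path, residues):
    """Write a synthetic GRO from [(resname, [atom names]), ...]."""
    rng = np.random.default_rng(1)
    lines = ["synthetic peptide", None]
    idx = 0
    for rid, (resname, names) in enumerate(residues, 1):
        base = np.array([0.4 * rid, 0.0, 0.0])
        for nm in names:
            idx += 1
            x, y, z = base + rng.normal(scale=0.05, size=3)
            lines.append(f"{rid:5d}{resname:<5s}{nm:>5s}{idx:5d}{x:8.3f}{y:8.3f}{z:8.3f}")
    lines[1] = f"{idx:5d}"
    lines.append("   5.00000   5.00000   5.00000")
    path.write_text("\n".join(lines) + "\n")
    return path
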