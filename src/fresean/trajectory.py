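"""Topology/trajectory I/O, reference-frame alignment, coarse-graining.

Trajectories carry positions (nm) and, for spectral analysis, velocities
(nm/ps) on a uniform time grid (ps).  Proteins are coarse-grained to one
bead per glycine and two beads (backbone/side chain) per other residue;
bead positions and velocities are mass-weighted averages of the member
atoms, so total mass and total momentum are conserved exactly.

All frames can be rotated into a common reference coordinate system with
a weighted Kabsch superposition; velocities are rotated with the same
rotation as the positions of their frame.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from .constants import ELEMENT_MASSES, STANDARD_RESIDUES

__all__ = [
    "Topology",
    "CGTopology",
    "Trajectory",
    "ReferenceFrame",
    "read_topology",
    "read_trajectory",
    "write_trajectory",
    "coarse_grain",
    "kabsch_align",
    "align_trajectory",
]

#: Atom names assigned to the backbone bead; everything else is side chain.
BACKBONE_ATOMS = frozenset(
    {
        "N", "H", "HN", "H1", "H2", "H3", "CA", "HA", "HA1", "HA2", "HA3",
        "C", "O", "OXT", "OT1", "OT2", "O1", "O2",
    }
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Topology:
    """Atomistic topology: names, masses and residue assignment."""

    names: np.ndarray          # (n_atoms,) str
    elements: np.ndarray       # (n_atoms,) str
    masses: np.ndarray         # (n_atoms,) amu
    resids: np.ndarray         # (n_atoms,) int, 0-based residue index
    resnames: np.ndarray       # (n_residues,) str
    source_path: str | None = None

    def __post_init__(self) -> None:
        if np.any(self.masses <= 0):
            raise ValueError("all atom masses must be positive")
        if self.resids.min() < 0 or self.resids.max() >= len(self.resnames):
            raise ValueError("every atom must map to exactly one residue")

    @property
    def n_atoms(self) -> int:
        return len(self.masses)

    @property
    def n_residues(self) -> int:
        return len(self.resnames)

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())


@dataclass
class CGTopology:
    """Coarse-grained bead topology and the atom->bead map."""

    bead_masses: np.ndarray    # (n_beads,) amu
    bead_resids: np.ndarray    # (n_beads,) int
    bead_roles: np.ndarray     # (n_beads,) str, 'backbone' | 'sidechain' | 'residue'
    atom_to_bead: np.ndarray   # (n_atoms,) int

    @property
    def n_beads(self) -> int:
        return len(self.bead_masses)


@dataclass
class Trajectory:
    """Positions (and optionally velocities) on a uniform time grid."""

    times: np.ndarray                     # (F,) ps
    positions: np.ndarray                 # (F, n, 3) nm
    velocities: np.ndarray | None = None  # (F, n, 3) nm/ps

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (frames, sites, 3)")
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions disagree on frame count")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities must match positions in shape")
        if len(self.times) > 1:
            steps = np.diff(self.times)
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValueError("trajectory time grid is not uniform")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_sites(self) -> int:
        return self.positions.shape[1]

    @property
    def dt(self) -> float:
        """Sampling interval in ps."""
        if len(self.times) < 2:
            raise ValueError("need at least two frames to define dt")
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class ReferenceFrame:
    """Reference coordinates plus per-site alignment weights."""

    coords: np.ndarray            # (n, 3) nm
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.weights is None:
            self.weights = np.ones(len(self.coords))
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0) or self.weights.sum() <= 0:
            raise ValueError("alignment weights must be non-negative, not all zero")
        _check_not_collinear(self.coords, self.weights)


def _check_not_collinear(coords: np.ndarray, weights: np.ndarray) -> None:
    w = weights / weights.sum()
    c = (w[:, None] * coords).sum(axis=0)
    d = coords - c
    gyr = (w[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0)
    ev = np.linalg.eigvalsh(gyr)
    if np.sum(ev > 1e-12 * max(ev.max(), 1e-30)) < 2:
        raise ValueError("reference sites are collinear; rotation is ill-defined")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _element_from_name(name: str) -> str:
    """Guess the element from a PDB/GRO atom name (field convention)."""
    stripped = name.strip()
    # names like '1HB' start with a digit
    alpha = "".join(ch for ch in stripped if ch.isalpha()).upper()
    if not alpha:
        return ""
    if alpha[:2] in ELEMENT_MASSES and alpha[:2] not in {"CA", "CL", "NA"}:
        # two-letter protein elements (SE of selenomethionine); CA/CL/NA as
        # atom-name prefixes are almost always carbon/nitrogen in proteins
        return alpha[:2]
    return alpha[0]


def read_topology(
    path: str | os.PathLike,
    *,
    strict_residues: bool = True,
    fallback_mass: float | None = None,
) -> Topology:
    """Read a PDB or GRO file into a :class:`Topology`.

    Masses come from the element table; an unknown element raises unless
    ``fallback_mass`` is given.  With ``strict_residues`` (default) any
    residue name outside the standard amino-acid set is an error.
    """
    import MDAnalysis as mda

    if not os.path.exists(path):
        raise FileNotFoundError(str(path))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    names = np.array([a.name for a in u.atoms])
    resnames_res = np.array([r.resname.strip().upper() for r in u.residues])
    if strict_residues:
        bad = sorted(set(resnames_res) - STANDARD_RESIDUES)
        if bad:
            raise ValueError(
                "nonstandard residue name(s) in %s: %s" % (path, ", ".join(bad))
            )
    resids = np.array([a.residue.ix for a in u.atoms], dtype=int)
    elements, masses = [], []
    for name in names:
        el = _element_from_name(name)
        if el not in ELEMENT_MASSES:
            if fallback_mass is None:
                raise ValueError(
                    f"unknown element for atom name {name!r}; "
                    "pass fallback_mass to accept it"
                )
            elements.append(el)
            masses.append(fallback_mass)
        else:
            elements.append(el)
            masses.append(ELEMENT_MASSES[el])
    return Topology(
        names=names,
        elements=np.array(elements),
        masses=np.array(masses),
        resids=resids,
        resnames=resnames_res,
        source_path=str(path),
    )


def write_trajectory(
    traj: Trajectory,
    path: str | os.PathLike,
    *,
    masses: np.ndarray | None = None,
    bead_map: np.ndarray | None = None,
) -> None:
    """Write the self-describing HDF5 container used for synthetic data."""
    with h5py.File(path, "w") as h5:
        h5.attrs["format"] = "fresean-trajectory"
        h5.attrs["version"] = 1
        h5.attrs["units"] = "nm ps amu"
        h5.create_dataset("time", data=traj.times)
        h5.create_dataset("positions", data=traj.positions)
        if traj.velocities is not None:
            h5.create_dataset("velocities", data=traj.velocities)
        if masses is not None:
            h5.create_dataset("masses", data=np.asarray(masses, dtype=float))
        if bead_map is not None:
            h5.create_dataset("bead_map", data=np.asarray(bead_map, dtype=int))


def _read_container(path, velocities_required):
    with h5py.File(path, "r") as h5:
        if h5.attrs.get("format") != "fresean-trajectory":
            raise ValueError(f"{path}: not a fresean trajectory container")
        times = h5["time"][...]
        pos = h5["positions"][...]
        vel = h5["velocities"][...] if "velocities" in h5 else None
        masses = h5["masses"][...] if "masses" in h5 else None
    if velocities_required and vel is None:
        raise ValueError(f"{path}: velocity block absent but required")
    return Trajectory(times, pos, vel), masses


def read_trajectory(
    path: str | os.PathLike,
    topology: Topology | str | None = None,
    *,
    velocities_required: bool = True,
):
    """Read a trajectory from TRR or the internal HDF5 container.

    Returns ``(Trajectory, masses-or-None)``.  TRR needs a topology (a
    :class:`Topology` read from PDB/GRO, or the path of such a file);
    TRR native units (A, A/ps) are converted to nm, nm/ps.
    """
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        return _read_container(path, velocities_required)

    import MDAnalysis as mda

    if topology is None:
        raise ValueError("a topology (PDB/GRO) is required to read TRR")
    top_path = topology.source_path if isinstance(topology, Topology) else str(topology)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(top_path, path)
    times, pos, vel = [], [], []
    has_vel = True
    for ts in u.trajectory:
        times.append(ts.time)          # MDAnalysis: ps
        pos.append(ts.positions / 10.0)  # A -> nm
        if ts.has_velocities:
            vel.append(ts.velocities / 10.0)  # A/ps -> nm/ps
        else:
            has_vel = False
    if velocities_required and not has_vel:
        raise ValueError(f"{path}: velocity block absent but required")
    times = np.array(times)
    steps = np.diff(times)
    if len(steps) and not np.allclose(steps, steps[0], rtol=1e-5, atol=1e-6):
        raise ValueError(f"{path}: non-uniform time grid")
    traj = Trajectory(times, np.array(pos), np.array(vel) if has_vel else None)
    masses = topology.masses if isinstance(topology, Topology) else None
    return traj, masses


# ---------------------------------------------------------------------------
# coarse-graining
# ---------------------------------------------------------------------------

def build_cg_map(topology: Topology, backbone_atoms=BACKBONE_ATOMS) -> CGTopology:
    """Assign every atom to a bead: Gly -> one bead, others -> two beads."""
    atom_to_bead = np.full(topology.n_atoms, -1, dtype=int)
    masses, resids, roles = [], [], []
    for r in range(topology.n_residues):
        atoms = np.where(topology.resids == r)[0]
        resname = topology.resnames[r].upper()
        names = topology.names[atoms]
        if resname == "GLY":
            groups = [(atoms, "residue")]
        else:
            is_bb = np.array([n.strip().upper() in backbone_atoms for n in names])
            if not np.any(~is_bb):
                warnings.warn(
                    f"residue {r} ({resname}) has no side-chain atoms; "
                    "treating it as a single bead"
                )
                groups = [(atoms, "residue")]
            else:
                groups = [(atoms[is_bb], "backbone"), (atoms[~is_bb], "sidechain")]
        for members, role in groups:
            bead = len(masses)
            atom_to_bead[members] = bead
            masses.append(topology.masses[members].sum())
            resids.append(r)
            roles.append(role)
    return CGTopology(
        bead_masses=np.array(masses),
        bead_resids=np.array(resids, dtype=int),
        bead_roles=np.array(roles),
        atom_to_bead=atom_to_bead,
    )


def coarse_grain(
    traj: Trajectory, topology: Topology, backbone_atoms=BACKBONE_ATOMS
) -> tuple[CGTopology, Trajectory]:
    """Coarse-grain an atomistic trajectory onto beads.

    Bead position and velocity are the mass-weighted means over member
    atoms, so each bead carries the group's centre of mass and momentum.
    """
    cg = build_cg_map(topology, backbone_atoms)
    nb = cg.n_beads
    # sparse projection as a dense (nb, n_atoms) weight matrix; fine at CG scale
    W = np.zeros((nb, topology.n_atoms))
    W[cg.atom_to_bead, np.arange(topology.n_atoms)] = topology.masses
    W /= cg.bead_masses[:, None]
    pos = np.einsum("ba,fax->fbx", W, traj.positions)
    vel = None
    if traj.velocities is not None:
        vel = np.einsum("ba,fax->fbx", W, traj.velocities)
    return cg, Trajectory(traj.times.copy(), pos, vel)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _kabsch_batched(P, Q, w):
    """Optimal rotations R_f with R_f @ (P_f - cP_f) ~= Q - cQ (weighted).

    P: (F, n, 3) mobile frames; Q: (n, 3) reference; w: (n,) weights.
    Returns (R (F,3,3), cP (F,3), cQ (3,)).
    """
    w = w / w.sum()
    cP = np.einsum("n,fnx->fx", w, P)
    cQ = np.einsum("n,nx->x", w, Q)
    Pc = P - cP[:, None, :]
    Qc = Q - cQ
    # cross-covariance H_f = sum_n w_n Qc_n Pc_fn^T
    H = np.einsum("n,nx,fny->fxy", w, Qc, Pc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.einsum("fxy,fyz->fxz", U, Vt)))
    U[:, :, 2] *= d[:, None]
    R = np.einsum("fxy,fyz->fxz", U, Vt)
    return R, cP, cQ


def kabsch_align(
    positions: np.ndarray,
    reference: ReferenceFrame,
    velocities: np.ndarray | None = None,
):
    """Superpose one frame onto a reference (weighted Kabsch).

    Returns ``(rotation (3,3), translation (3,), aligned positions,
    aligned velocities)``.  The rotation is proper (det +1) and minimizes
    the weighted RMSD; velocities are rotated by the same rotation.
    """
    positions = np.asarray(positions, dtype=float)
    _check_not_collinear(positions, reference.weights)
    R, cP, cQ = _kabsch_batched(positions[None], reference.coords, reference.weights)
    R, cP = R[0], cP[0]
    aligned = (positions - cP) @ R.T + cQ
    t = cQ - R @ cP
    vel = velocities @ R.T if velocities is not None else None
    return R, t, aligned, vel


def align_trajectory(traj: Trajectory, reference: ReferenceFrame) -> Trajectory:
    """Rotate every frame into the reference coordinate system."""
    if traj.positions.shape[1] != len(reference.coords):
        raise ValueError("trajectory and reference disagree on site count")
    R, cP, cQ = _kabsch_batched(traj.positions, reference.coords, reference.weights)
    pos = np.einsum("fnx,fyx->fny", traj.positions - cP[:, None, :], R) + cQ
    vel = None
    if traj.velocities is not None:
        vel = np.einsum("fnx,fyx->fny", traj.velocities, R)
    return Trajectory(traj.times.copy(), pos, vel)
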