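"""Modes as collective variables: internal evaluator and PLUMED export.

A mode-projection CV is evaluated in four steps: (i) align the frame to
a reference structure, (ii) switch to the coarse-grained representation,
(iii) compute displacement vectors relative to the reference, and
(iv) project the (mass-weighted) displacements onto the mode vector.
Because of the alignment the CV is invariant under rigid rotation and
translation of the input frame, which is what makes it usable as a
biasing coordinate; along its own mode direction it is exactly linear.

The PLUMED writer emits one concrete realization of the same recipe
(FIT_TO_TEMPLATE alignment, CENTER beads, and a COMBINE projection) plus
auxiliary mode/reference files, for running well-tempered metadynamics
in an external engine.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass

import numpy as np

from .spectral import ModeSet
from .trajectory import CGTopology, ReferenceFrame, kabsch_align

__all__ = [
    "CVDefinition",
    "evaluate_cv",
    "write_plumed_input",
    "write_mode_file",
    "read_mode_file",
    "export_nmd",
    "read_nmd",
]


@dataclass
class CVDefinition:
    """Projection of aligned CG displacements onto one mode vector.

    With mass weighting (default, consistent with the eigenproblem) the
    CV is s = sum_i sqrt(m_i) (r_i - r_ref,i) . e_i in nm amu^1/2;
    without, s = sum_i (r_i - r_ref,i) . e_i in nm.
    """

    mode: np.ndarray                    # (3n,), normalized
    reference: np.ndarray               # (n, 3) nm
    masses: np.ndarray                  # (n,) amu
    weights: np.ndarray | None = None   # alignment weights; default masses
    mass_weighted: bool = True
    name: str = "cv"

    def __post_init__(self) -> None:
        self.mode = np.asarray(self.mode, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.mode.shape != (3 * len(self.reference),):
            raise ValueError("mode vector and reference disagree on bead count")
        nrm = np.linalg.norm(self.mode)
        if abs(nrm - 1.0) > 1e-6:
            raise ValueError(f"mode vector must be normalized (|e| = {nrm:.6g})")
        if self.weights is None:
            self.weights = self.masses.copy()

    @property
    def n_beads(self) -> int:
        return len(self.reference)

    def coefficients(self) -> np.ndarray:
        """Per-coordinate projection coefficients (the COMBINE row)."""
        if self.mass_weighted:
            return self.mode * np.repeat(np.sqrt(self.masses), 3)
        return self.mode.copy()


def evaluate_cv(positions: np.ndarray, cv: CVDefinition):
    """Evaluate the CV for one frame (n, 3) or a stack (F, n, 3)."""
    positions = np.asarray(positions, dtype=float)
    single = positions.ndim == 2
    frames = positions[None] if single else positions
    if frames.shape[1] != cv.n_beads:
        raise ValueError("frame and CV disagree on bead count")
    ref = ReferenceFrame(cv.reference, cv.weights)
    coeff = cv.coefficients()
    out = np.empty(len(frames))
    for f, frame in enumerate(frames):
        _, _, aligned, _ = kabsch_align(frame, ref)
        out[f] = coeff @ (aligned - cv.reference).ravel()
    return float(out[0]) if single else out


# ---------------------------------------------------------------------------
# mode file format (text, lossless, checksummed)
# ---------------------------------------------------------------------------

_MODEFILE_VERSION = 1


def write_mode_file(modes: ModeSet, path: str | os.PathLike) -> None:
    """Write a ModeSet to the package's self-describing text format.

    Floats are stored as C99 hex literals, so a write/read round-trip is
    bit-exact on any platform; a sha256 checksum guards the payload.
    """
    if modes.reference is None:
        raise ValueError("mode file requires reference coordinates")
    freq_s = "nan" if modes.frequency is None else repr(float(modes.frequency))
    win_s = "nan" if modes.window_fwhm is None else repr(float(modes.window_fwhm))
    lines = [
        f"version {_MODEFILE_VERSION}",
        f"n_beads {modes.n_beads}",
        f"n_modes {modes.n_modes}",
        f"frequency_cm {freq_s}",
        f"window_fwhm_cm {win_s}",
        "masses " + " ".join(float(m).hex() for m in modes.masses),
        "reference " + " ".join(float(x).hex() for x in modes.reference.ravel()),
    ]
    for k in range(modes.n_modes):
        lines.append(f"mode {k + 1} eigenvalue {float(modes.eigenvalues[k]).hex()}")
        lines.append(" ".join(float(x).hex() for x in modes.vectors[k]))
    payload = "\n".join(lines) + "\n"
    digest = hashlib.sha256(payload.encode()).hexdigest()
    with open(path, "w") as fh:
        fh.write("# fresean mode file\n")
        fh.write(payload)
        fh.write(f"checksum sha256:{digest}\n")


class ModeFileError(ValueError):
    pass


def read_mode_file(path: str | os.PathLike) -> ModeSet:
    """Read a mode file back, verifying version and checksum."""
    with open(path) as fh:
        text = fh.read()
    lines = text.splitlines()

    def fail(msg, nline):
        offset = sum(len(l) + 1 for l in lines[:nline])
        raise ModeFileError(f"{path}: {msg} (byte offset {offset})")

    if not lines or not lines[0].startswith("# fresean mode file"):
        raise ModeFileError(f"{path}: not a fresean mode file")
    if not lines[-1].startswith("checksum sha256:"):
        fail("truncated file: checksum line missing", len(lines))
    payload = "\n".join(lines[1:-1]) + "\n"
    expect = lines[-1].split("sha256:")[1].strip()
    got = hashlib.sha256(payload.encode()).hexdigest()
    if got != expect:
        raise ModeFileError(f"{path}: checksum mismatch (corrupt or edited file)")

    fields = {}
    i = 1
    try:
        while not lines[i].startswith("mode "):
            key, _, val = lines[i].partition(" ")
            fields[key] = val
            i += 1
    except IndexError:
        fail("truncated file: no mode records", len(lines))
    version = int(fields["version"])
    if version != _MODEFILE_VERSION:
        raise ModeFileError(
            f"{path}: unsupported mode file version {version} "
            f"(expected {_MODEFILE_VERSION})"
        )
    n_beads = int(fields["n_beads"])
    n_modes = int(fields["n_modes"])
    freq = float.fromhex(fields["frequency_cm"]) if "0x" in fields["frequency_cm"] \
        else (None if fields["frequency_cm"] == "nan" else float(fields["frequency_cm"]))
    window = None if fields["window_fwhm_cm"] == "nan" else float(fields["window_fwhm_cm"])
    masses = np.array([float.fromhex(t) for t in fields["masses"].split()])
    reference = np.array(
        [float.fromhex(t) for t in fields["reference"].split()]
    ).reshape(n_beads, 3)
    eigenvalues = np.empty(n_modes)
    vectors = np.empty((n_modes, 3 * n_beads))
    for k in range(n_modes):
        if i + 1 >= len(lines):
            fail(f"truncated file: mode {k + 1} record incomplete", len(lines))
        head = lines[i].split()
        if head[:1] != ["mode"] or head[2] != "eigenvalue":
            fail(f"malformed mode header {lines[i]!r}", i)
        eigenvalues[k] = float.fromhex(head[3])
        comps = lines[i + 1].split()
        if len(comps) != 3 * n_beads:
            fail(f"mode {k + 1} has {len(comps)} components, expected {3 * n_beads}", i + 1)
        vectors[k] = [float.fromhex(t) for t in comps]
        i += 2
    return ModeSet(
        vectors=vectors, eigenvalues=eigenvalues, masses=masses,
        frequency=freq, reference=reference, window_fwhm=window,
    )


# ---------------------------------------------------------------------------
# PLUMED input generation
# ---------------------------------------------------------------------------

def _write_reference_pdb(cv: CVDefinition, path: str) -> None:
    """Minimal bead PDB (A) usable as a PLUMED FIT_TO_TEMPLATE reference."""
    with open(path, "w") as fh:
        for i, (x, y, z) in enumerate(cv.reference * 10.0, start=1):
            fh.write(
                f"ATOM  {i:5d}  CA  BEA A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n"
            )
        fh.write("END\n")


def write_plumed_input(
    cvs: list[CVDefinition],
    metad: dict,
    path: str | os.PathLike,
    *,
    cg_map: CGTopology | None = None,
    reference_pdb: str = "reference.pdb",
    colvar_file: str = "COLVAR",
    hills_file: str = "HILLS",
    stride: int = 500,
) -> None:
    """Emit a PLUMED input biasing along mode-projection CVs.

    ``metad`` must provide height (kJ/mol), sigma (one per CV), pace,
    bias_factor and temperature; there are deliberately no defaults so a
    production run cannot pick silent parameters.  If ``cg_map`` is
    given, beads are CENTERs of their atom groups (1-based PLUMED
    serials); otherwise input atoms are taken to be the beads.
    """
    for key in ("height", "sigma", "pace", "bias_factor", "temperature"):
        if key not in metad:
            raise ValueError(f"missing metadynamics parameter {key!r}")
    if len(cvs) != 2:
        raise ValueError("the biasing protocol uses exactly two CVs")
    sigma = np.broadcast_to(np.asarray(metad["sigma"], dtype=float), (2,))
    ref = cvs[0]
    for cv in cvs[1:]:
        if not np.allclose(cv.reference, ref.reference):
            raise ValueError("all CVs must share one reference structure")
    n = ref.n_beads
    path = str(path)
    out_dir = os.path.dirname(path) or "."
    _write_reference_pdb(ref, os.path.join(out_dir, reference_pdb))

    lines = ["# fresean mode-projection CVs for well-tempered metadynamics"]
    for key in ("height", "sigma", "pace", "bias_factor", "temperature"):
        lines.append(f"# {key} = {metad[key]}")
    lines.append("UNITS LENGTH=nm TIME=ps ENERGY=kj/mol")
    lines.append(f"FIT_TO_TEMPLATE REFERENCE={reference_pdb} TYPE=OPTIMAL")
    for b in range(n):
        if cg_map is not None:
            atoms = ",".join(
                str(a + 1) for a in np.where(cg_map.atom_to_bead == b)[0]
            )
        else:
            atoms = str(b + 1)
        lines.append(f"b{b + 1}: CENTER ATOMS={atoms} MASS")
        lines.append(f"p{b + 1}: POSITION ATOM=b{b + 1} NOPBC")
    args = ",".join(f"p{b + 1}.{ax}" for b in range(n) for ax in "xyz")
    params = ",".join(repr(float(x)) for x in ref.reference.ravel())
    names = []
    for cv in cvs:
        coeff = ",".join(repr(float(c)) for c in cv.coefficients())
        lines.append(
            f"{cv.name}: COMBINE ARG={args} COEFFICIENTS={coeff} "
            f"PARAMETERS={params} PERIODIC=NO"
        )
        names.append(cv.name)
    lines.append(
        "metad: METAD ARG={} SIGMA={},{} HEIGHT={} PACE={} BIASFACTOR={} "
        "TEMP={} FILE={}".format(
            ",".join(names), sigma[0], sigma[1], metad["height"], metad["pace"],
            metad["bias_factor"], metad["temperature"], hills_file,
        )
    )
    lines.append(
        f"PRINT ARG={','.join(names)},metad.bias FILE={colvar_file} STRIDE={stride}"
    )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def parse_plumed_projection(path: str | os.PathLike, name: str):
    """Re-read COEFFICIENTS/PARAMETERS of one COMBINE CV (self-check)."""
    with open(path) as fh:
        for line in fh:
            if line.startswith(f"{name}: COMBINE"):
                fields = dict(
                    tok.split("=", 1) for tok in line.split()[2:] if "=" in tok
                )
                coeff = np.array([float(t) for t in fields["COEFFICIENTS"].split(",")])
                params = np.array([float(t) for t in fields["PARAMETERS"].split(",")])
                return coeff, params
    raise ValueError(f"{path}: no COMBINE action named {name!r}")


# ---------------------------------------------------------------------------
# NMD export (visualization)
# ---------------------------------------------------------------------------

def export_nmd(
    modes: ModeSet,
    path: str | os.PathLike,
    *,
    mode_indices: tuple[int, ...] | None = None,
    names: list[str] | None = None,
    resids: list[int] | None = None,
    title: str = "fresean modes",
) -> None:
    """Write modes in the NMD text format (coordinates in Angstrom)."""
    if modes.reference is None:
        raise ValueError("NMD export requires reference coordinates")
    n = modes.n_beads
    if mode_indices is None:
        mode_indices = tuple(range(1, modes.n_modes + 1))
    names = names or ["CA"] * n
    resids = resids or list(range(1, n + 1))
    with open(path, "w") as fh:
        fh.write(f"title {title}\n")
        fh.write("names " + " ".join(names) + "\n")
        fh.write("resids " + " ".join(str(r) for r in resids) + "\n")
        fh.write(
            "coordinates "
            + " ".join(f"{x:.6f}" for x in (modes.reference * 10.0).ravel())
            + "\n"
        )
        for k in mode_indices:
            vec = modes.mode(k)
            fh.write(
                f"mode {k} {modes.eigenvalues[k - 1]:.6e} "
                + " ".join(f"{x:.6e}" for x in vec)
                + "\n"
            )


def read_nmd(path: str | os.PathLike):
    """Read back an NMD file: (coordinates nm, {index: vector})."""
    coords = None
    vectors = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "coordinates":
                coords = np.array([float(x) for x in parts[1:]]).reshape(-1, 3) / 10.0
            elif parts[0] == "mode":
                vectors[int(parts[1])] = np.array([float(x) for x in parts[3:]])
    return coords, vectors
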