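"""Biased-trajectory post-processing: reweighting, FES statistics, metrics.

Parses PLUMED-dialect COLVAR/HILLS text, reconstructs the deposited
well-tempered bias, assigns unbiasing weights to trajectory frames, and
builds (replica-averaged) free-energy surfaces F(s) = -kT ln P(s) with
per-bin standard deviation and standard error of the mean.  Surfaces are
compared through their information content (Shannon entropy S2 in bits)
and similarity (Bhattacharyya coefficient), and summarized via state
free-energy differences, k-means microstates, and 1D minimum-free-energy
paths.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import KB

__all__ = [
    "ColvarSeries",
    "HillsRecord",
    "HillsSeries",
    "WeightedEnsemble",
    "FreeEnergySurface",
    "GeometricCV",
    "read_colvar",
    "read_hills",
    "write_colvar",
    "write_hills",
    "bias_at",
    "reweight",
    "weighted_fes",
    "average_fes",
    "shannon_entropy",
    "bhattacharyya",
    "state_delta_f",
    "kmeans_microstates",
    "min_free_energy_path",
    "eval_geometric_cv",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ColvarSeries:
    """CV time series (plus optional instantaneous bias) from a COLVAR file."""

    data: pd.DataFrame
    cv_names: tuple[str, ...]

    @property
    def times(self) -> np.ndarray:
        return self.data["time"].to_numpy()

    @property
    def cv_values(self) -> np.ndarray:
        return self.data[list(self.cv_names)].to_numpy()

    @property
    def bias(self) -> np.ndarray | None:
        return self.data["metad.bias"].to_numpy() if "metad.bias" in self.data else None


@dataclass
class HillsRecord:
    """One deposited Gaussian hill."""

    time: float
    center: np.ndarray
    sigma: np.ndarray
    height: float          # kJ/mol, well-tempered scaling already applied
    biasf: float


@dataclass
class HillsSeries:
    """Full metadynamics bias history."""

    times: np.ndarray      # (H,) ps, increasing
    centers: np.ndarray    # (H, d)
    sigmas: np.ndarray     # (H, d), > 0
    heights: np.ndarray    # (H,), > 0
    biasf: float
    cv_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.times) and np.any(np.diff(self.times) < 0):
            raise ValueError("hill deposit times must be increasing")
        if np.any(self.sigmas <= 0) or np.any(self.heights < 0):
            raise ValueError("hill widths must be positive and heights >= 0")

    def __len__(self) -> int:
        return len(self.times)

    def __getitem__(self, i: int) -> HillsRecord:
        return HillsRecord(
            float(self.times[i]), self.centers[i].copy(), self.sigmas[i].copy(),
            float(self.heights[i]), self.biasf,
        )

    def bias_at(self, points: np.ndarray, up_to_time: float | None = None,
                chunk: int = 2048) -> np.ndarray:
        """Exact deposited bias (kJ/mol) at points, summed over hills."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        H = len(self.times) if up_to_time is None else int(
            np.searchsorted(self.times, up_to_time, side="right")
        )
        out = np.zeros(len(points))
        if H == 0:
            return out
        c, s, h = self.centers[:H], self.sigmas[:H], self.heights[:H]
        for lo in range(0, len(points), chunk):
            p = points[lo : lo + chunk]
            z = (p[:, None, :] - c[None, :, :]) / s[None, :, :]
            out[lo : lo + len(p)] = (
                h[None, :] * np.exp(-0.5 * np.sum(z * z, axis=2))
            ).sum(axis=1)
        return out


@dataclass
class WeightedEnsemble:
    """Samples with normalized statistical weights (w >= 0, sum w = 1)."""

    samples: pd.DataFrame
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        tot = self.weights.sum()
        if tot <= 0:
            raise ValueError("weights sum to zero")
        self.weights = self.weights / tot

    def values(self, columns) -> np.ndarray:
        return self.samples[list(columns)].to_numpy()


@dataclass
class FreeEnergySurface:
    """Gridded free energy with probabilities, counts and uncertainties.

    ``free`` is gauge-fixed to min 0; unoccupied / under-sampled bins are
    NaN.  For 1D surfaces the arrays have one axis.
    """

    names: tuple[str, ...]
    edges: list[np.ndarray]
    prob: np.ndarray             # normalized over occupied bins
    free: np.ndarray             # kJ/mol, NaN where masked
    counts: np.ndarray           # effective sample count per bin
    temperature: float
    std: np.ndarray | None = None   # kJ/mol, across replicas
    sem: np.ndarray | None = None

    @property
    def ndim(self) -> int:
        return len(self.edges)

    @property
    def centers(self) -> list[np.ndarray]:
        return [0.5 * (e[1:] + e[:-1]) for e in self.edges]

    def occupied(self) -> np.ndarray:
        return np.isfinite(self.free)


@dataclass
class GeometricCV:
    """A generic distance / angle / dihedral over bead-group centres."""

    kind: str                       # 'distance' | 'angle' | 'dihedral'
    groups: list[list[int]]
    name: str = ""

    def __post_init__(self) -> None:
        need = {"distance": 2, "angle": 3, "dihedral": 4}
        if self.kind not in need:
            raise ValueError(f"unknown geometric CV kind {self.kind!r}")
        if len(self.groups) != need[self.kind]:
            raise ValueError(f"{self.kind} needs {need[self.kind]} site groups")
        if any(len(g) == 0 for g in self.groups):
            raise ValueError("empty site group")
        if not self.name:
            self.name = self.kind


# ---------------------------------------------------------------------------
# PLUMED text I/O
# ---------------------------------------------------------------------------

def _read_plumed_table(path: str) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#! FIELDS"):
            raise ValueError(f"{path}: missing '#! FIELDS' header")
        cols = header.split()[2:]
        rows = []
        for ln, line in enumerate(fh, start=2):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != len(cols):
                raise ValueError(f"{path}:{ln}: malformed line ({len(parts)} fields, "
                                 f"expected {len(cols)})")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as err:
                raise ValueError(f"{path}:{ln}: {err}") from None
    return pd.DataFrame(rows, columns=cols)


def read_colvar(path: str, cv_names: tuple[str, ...] | None = None) -> ColvarSeries:
    """Parse a PLUMED COLVAR file; columns are mapped by header name."""
    df = _read_plumed_table(path)
    if "time" not in df.columns:
        raise ValueError(f"{path}: header lacks required field 'time'")
    if cv_names is None:
        cv_names = tuple(c for c in df.columns if c not in {"time"} and not c.endswith(".bias"))
    else:
        missing = [c for c in cv_names if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: header lacks field(s) {', '.join(missing)}")
    return ColvarSeries(data=df, cv_names=tuple(cv_names))


def read_hills(path: str) -> HillsSeries:
    """Parse a PLUMED HILLS file into a hill history."""
    df = _read_plumed_table(path)
    for col in ("time", "height", "biasf"):
        if col not in df.columns:
            raise ValueError(f"{path}: header lacks required field '{col}'")
    cvs = tuple(
        c for c in df.columns
        if c not in {"time", "height", "biasf"} and not c.startswith("sigma_")
    )
    sig_cols = [f"sigma_{c}" for c in cvs]
    missing = [c for c in sig_cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: header lacks field(s) {', '.join(missing)}")
    return HillsSeries(
        times=df["time"].to_numpy(),
        centers=df[list(cvs)].to_numpy(),
        sigmas=df[sig_cols].to_numpy(),
        heights=df["height"].to_numpy(),
        biasf=float(df["biasf"].iloc[0]) if len(df) else 1.0,
        cv_names=cvs,
    )


def _fmt(x: float) -> str:
    return repr(float(x))  # shortest exact round-trip representation


def write_colvar(colvar: ColvarSeries, path: str) -> None:
    cols = list(colvar.data.columns)
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(cols) + "\n")
        for row in colvar.data.itertuples(index=False):
            fh.write(" ".join(_fmt(v) for v in row) + "\n")


def write_hills(hills: HillsSeries, path: str) -> None:
    cols = (["time"] + list(hills.cv_names)
            + [f"sigma_{c}" for c in hills.cv_names] + ["height", "biasf"])
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(cols) + "\n")
        for i in range(len(hills)):
            vals = ([hills.times[i]] + list(hills.centers[i])
                    + list(hills.sigmas[i]) + [hills.heights[i], hills.biasf])
            fh.write(" ".join(_fmt(v) for v in vals) + "\n")


# ---------------------------------------------------------------------------
# reweighting
# ---------------------------------------------------------------------------

def bias_at(hills: HillsSeries, point, up_to_time: float | None = None) -> float:
    """Deposited bias (kJ/mol) at one CV point, exactly summed."""
    return float(hills.bias_at(np.atleast_2d(point), up_to_time)[0])


def _tiwary_offset(hills: HillsSeries, temperature: float, n_grid: int = 80):
    """c(t) at each hill time, estimated on a CV-space grid."""
    kT = KB * temperature
    g = hills.biasf
    lo = (hills.centers - 5 * hills.sigmas).min(axis=0)
    hi = (hills.centers + 5 * hills.sigmas).max(axis=0)
    axes = [np.linspace(lo[d], hi[d], n_grid) for d in range(hills.centers.shape[1])]
    mesh = np.stack([m.ravel() for m in np.meshgrid(*axes, indexing="ij")], axis=1)
    V = np.zeros(len(mesh))
    c_of_t = np.empty(len(hills))
    for i in range(len(hills)):
        z = (mesh - hills.centers[i]) / hills.sigmas[i]
        V += hills.heights[i] * np.exp(-0.5 * np.sum(z * z, axis=1))
        num = np.logaddexp.reduce(g / (g - 1.0) * V / kT)
        den = np.logaddexp.reduce(1.0 / (g - 1.0) * V / kT)
        c_of_t[i] = kT * (num - den)
    return c_of_t


def reweight(
    colvar: ColvarSeries,
    hills: HillsSeries,
    temperature: float = 300.0,
    scheme: str = "final_bias",
    *,
    discard_fraction: float = 0.2,
) -> WeightedEnsemble:
    """Assign unbiasing weights to biased-trajectory frames.

    ``final_bias``: w_i ~ exp(+V_bias(s_i, t_end)/kT) — the converged
    well-tempered bias is (up to a constant) proportional to -F.
    ``time_dependent``: Tiwary-Parrinello weights
    w_i ~ exp(+(V_bias(s_i, t_i) - c(t_i))/kT).
    The first ``discard_fraction`` of the deposition period is dropped.
    """
    if len(hills) and set(colvar.cv_names) >= set(hills.cv_names):
        s = colvar.data[list(hills.cv_names)].to_numpy()
    elif len(hills):
        raise ValueError(
            f"COLVAR lacks hill CVs {hills.cv_names!r}; has {colvar.cv_names!r}"
        )
    else:
        s = colvar.cv_values
    kT = KB * temperature
    t = colvar.times
    t_cut = t[0] + discard_fraction * (t[-1] - t[0])
    keep = t >= t_cut
    samples = colvar.data.loc[keep].reset_index(drop=True)
    if len(hills) == 0:
        w = np.ones(keep.sum())
    elif scheme == "final_bias":
        V = hills.bias_at(s[keep])
        w = np.exp((V - V.max()) / kT)
    elif scheme == "time_dependent":
        c_of_t = _tiwary_offset(hills, temperature)
        sk, tk = s[keep], t[keep]
        # index of the last hill deposited at or before each sample time
        idx = np.searchsorted(hills.times, tk, side="right") - 1
        V = np.empty(len(sk))
        for lo in range(0, len(sk), 2048):
            hi = min(lo + 2048, len(sk))
            z = (sk[lo:hi, None, :] - hills.centers[None, :, :]) / hills.sigmas[None, :, :]
            g = hills.heights[None, :] * np.exp(-0.5 * np.sum(z * z, axis=2))
            live = np.arange(len(hills))[None, :] <= idx[lo:hi, None]
            V[lo:hi] = np.where(live, g, 0.0).sum(axis=1)
        c_vals = np.where(idx >= 0, c_of_t[np.clip(idx, 0, None)], 0.0)
        arg = (V - c_vals) / kT
        w = np.exp(arg - arg.max())
    else:
        raise ValueError(f"unknown reweighting scheme {scheme!r}")
    return WeightedEnsemble(samples=samples, weights=w)


# ---------------------------------------------------------------------------
# free-energy surfaces
# ---------------------------------------------------------------------------

def _grid_edges(values, bins, ranges, pad=0.05):
    edges = []
    d = values.shape[1]
    bins = np.broadcast_to(np.asarray(bins), (d,))
    for k in range(d):
        if ranges is not None and ranges[k] is not None:
            lo, hi = ranges[k]
        else:
            lo, hi = values[:, k].min(), values[:, k].max()
            span = (hi - lo) or 1.0
            lo, hi = lo - pad * span, hi + pad * span
        edges.append(np.linspace(lo, hi, int(bins[k]) + 1))
    return edges


def weighted_fes(
    ensemble: WeightedEnsemble,
    columns,
    *,
    bins=50,
    ranges=None,
    temperature: float = 300.0,
    min_effective: float = 5.0,
) -> FreeEnergySurface:
    """F = -kT ln of the weighted histogram, gauge-fixed to min 0.

    Bins with fewer than ``min_effective`` effective samples (Kish
    count (sum w)^2 / sum w^2 per bin) are masked.
    """
    columns = tuple(columns)
    vals = ensemble.values(columns)
    if len(vals) == 0:
        raise ValueError("ensemble has no samples")
    edges = _grid_edges(vals, bins, ranges)
    w = ensemble.weights
    hist_w, _ = np.histogramdd(vals, bins=edges, weights=w)
    hist_w2, _ = np.histogramdd(vals, bins=edges, weights=w * w)
    if hist_w.sum() == 0:
        raise ValueError("all samples fall outside the grid")
    with np.errstate(divide="ignore", invalid="ignore"):
        n_eff = np.where(hist_w2 > 0, hist_w**2 / hist_w2, 0.0)
    mask = (hist_w > 0) & (n_eff >= min_effective)
    prob = np.where(mask, hist_w, 0.0)
    prob = prob / prob.sum()
    kT = KB * temperature
    with np.errstate(divide="ignore"):
        F = np.where(prob > 0, -kT * np.log(np.where(prob > 0, prob, 1.0)), np.nan)
    F = F - np.nanmin(F)
    return FreeEnergySurface(
        names=columns, edges=edges, prob=prob, free=F, counts=n_eff,
        temperature=temperature,
    )


def average_fes(surfaces: list[FreeEnergySurface]) -> FreeEnergySurface:
    """Replica-average: mean probability distribution, then F = -kT ln.

    Per-bin std across replicas (each replica's F gauge-shifted to
    min 0 first) describes a single run's uncertainty; SEM = std/sqrt(R).
    """
    if not surfaces:
        raise ValueError("no surfaces to average")
    ref = surfaces[0]
    for s in surfaces[1:]:
        if s.names != ref.names or any(
            not np.array_equal(a, b) for a, b in zip(s.edges, ref.edges)
        ):
            raise ValueError("replica surfaces must share an identical grid")
        if s.temperature != ref.temperature:
            raise ValueError("replica surfaces must share a temperature")
    P = np.mean([s.prob for s in surfaces], axis=0)
    P = P / P.sum()
    kT = KB * ref.temperature
    with np.errstate(divide="ignore"):
        F = np.where(P > 0, -kT * np.log(np.where(P > 0, P, 1.0)), np.nan)
    F = F - np.nanmin(F)
    Fs = np.stack([s.free for s in surfaces])
    ok = np.all(np.isfinite(Fs), axis=0)
    std = np.full(F.shape, np.nan)
    std[ok] = np.std(Fs[:, ok], axis=0, ddof=0)
    sem = std / math.sqrt(len(surfaces))
    counts = np.sum([s.counts for s in surfaces], axis=0)
    return FreeEnergySurface(
        names=ref.names, edges=ref.edges, prob=P, free=F, counts=counts,
        temperature=ref.temperature, std=std, sem=sem,
    )


# ---------------------------------------------------------------------------
# information metrics
# ---------------------------------------------------------------------------

def _as_prob(obj, tol=1e-6) -> np.ndarray:
    p = obj.prob if isinstance(obj, FreeEnergySurface) else np.asarray(obj, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    tot = p.sum()
    if abs(tot - 1.0) > tol:
        raise ValueError(f"distribution not normalized (sum = {tot:.6g})")
    return p / tot


def shannon_entropy(dist) -> float:
    """S2 = -sum p log2 p over occupied bins, in bits."""
    p = _as_prob(dist)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def bhattacharyya(dist_a, dist_b) -> float:
    """BC = sum sqrt(p_a p_b) in [0, 1]; 1 for identical distributions."""
    pa, pb = _as_prob(dist_a), _as_prob(dist_b)
    if pa.shape != pb.shape:
        raise ValueError("distributions must share one grid")
    return float(np.sqrt(pa * pb).sum())


# ---------------------------------------------------------------------------
# states, microstates, paths
# ---------------------------------------------------------------------------

def _region_mask(points: np.ndarray, region) -> np.ndarray:
    if callable(region):
        return np.asarray(region(points), dtype=bool)
    kind = region["kind"]
    if kind == "rect":
        lo = np.asarray([b[0] for b in region["bounds"]])
        hi = np.asarray([b[1] for b in region["bounds"]])
        return np.all((points >= lo) & (points <= hi), axis=1)
    if kind == "ellipse":
        c = np.asarray(region["center"], dtype=float)
        r = np.asarray(region["radii"], dtype=float)
        return np.sum(((points - c) / r) ** 2, axis=1) <= 1.0
    raise ValueError(f"unknown region kind {kind!r}")


def state_delta_f(
    ensemble: WeightedEnsemble,
    columns,
    region_a,
    region_b,
    temperature: float = 300.0,
) -> float:
    """Delta F = -kT ln(P_B / P_A) between two CV-space regions.

    An empty region is signaled distinctly by an infinite result
    (+inf if B is empty, -inf if A is empty).
    """
    pts = ensemble.values(columns)
    pa = float(ensemble.weights[_region_mask(pts, region_a)].sum())
    pb = float(ensemble.weights[_region_mask(pts, region_b)].sum())
    if pa == 0.0 and pb == 0.0:
        raise ValueError("both regions are empty")
    if pb == 0.0:
        return math.inf
    if pa == 0.0:
        return -math.inf
    return float(-KB * temperature * math.log(pb / pa))


def kmeans_microstates(
    ensemble: WeightedEnsemble,
    columns,
    k: int = 40,
    seed: int = 0,
    region=None,
):
    """k representative microstates of a (restricted) weighted ensemble.

    Returns ``(centers (k, d), assignments, inertia)``; deterministic
    for a fixed seed.
    """
    from sklearn.cluster import KMeans

    pts = ensemble.values(columns)
    w = ensemble.weights
    if region is not None:
        m = _region_mask(pts, region)
        pts, w = pts[m], w[m]
    if k > len(pts):
        raise ValueError(f"k={k} exceeds the {len(pts)} available samples")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(pts, sample_weight=w / w.sum())
    return km.cluster_centers_, labels, float(km.inertia_)


def _bin_of(fes: FreeEnergySurface, point) -> tuple[int, ...]:
    idx = []
    for x, e in zip(np.atleast_1d(point), fes.edges):
        j = int(np.clip(np.searchsorted(e, x, side="right") - 1, 0, len(e) - 2))
        idx.append(j)
    return tuple(idx)


def min_free_energy_path(
    fes: FreeEnergySurface,
    start,
    end,
) -> dict:
    """Lowest-maximum (minimax) grid path between two occupied bins.

    Dijkstra-style search on the 8-connected (2D) bin graph where a
    path's cost is the highest free energy it crosses.  Returns the bin
    path, CV coordinates, the F profile and propagated per-bin std/SEM.
    """
    F = fes.free
    start_bin, end_bin = _bin_of(fes, start), _bin_of(fes, end)
    for name, b in (("start", start_bin), ("end", end_bin)):
        if not np.isfinite(F[b]):
            raise ValueError(f"{name} bin {b} is not occupied")
    if fes.ndim == 1:
        neighbors = [(-1,), (1,)]
    else:
        neighbors = [(i, j) for i in (-1, 0, 1) for j in (-1, 0, 1) if (i, j) != (0, 0)]
    best = {start_bin: F[start_bin]}
    prev: dict = {start_bin: None}
    heap = [(F[start_bin], start_bin)]
    while heap:
        cost, node = heapq.heappop(heap)
        if node == end_bin:
            break
        if cost > best.get(node, math.inf):
            continue
        for off in neighbors:
            nb = tuple(n + o for n, o in zip(node, off))
            if any(n < 0 or n >= F.shape[d] for d, n in enumerate(nb)):
                continue
            if not np.isfinite(F[nb]):
                continue
            c = max(cost, float(F[nb]))
            if c < best.get(nb, math.inf):
                best[nb] = c
                prev[nb] = node
                heapq.heappush(heap, (c, nb))
    if end_bin not in prev:
        raise ValueError("no finite-free-energy path connects the end points")
    path = []
    node = end_bin
    while node is not None:
        path.append(node)
        node = prev[node]
    path.reverse()
    centers = fes.centers
    coords = np.array([[centers[d][b[d]] for d in range(fes.ndim)] for b in path])
    take = tuple(np.array([b[d] for b in path]) for d in range(fes.ndim))
    profile = F[take]
    std = fes.std[take] if fes.std is not None else None
    sem = fes.sem[take] if fes.sem is not None else None
    return {
        "bins": path, "coords": coords, "free": profile,
        "std": std, "sem": sem, "barrier": float(best[end_bin]),
    }


# ---------------------------------------------------------------------------
# geometric CVs
# ---------------------------------------------------------------------------

def _group_com(positions, group, masses):
    sub = positions[:, group, :]
    if masses is None:
        return sub.mean(axis=1)
    m = np.asarray(masses, dtype=float)[group]
    return (sub * m[None, :, None]).sum(axis=1) / m.sum()


def eval_geometric_cv(
    positions: np.ndarray,
    defs: list[GeometricCV],
    masses: np.ndarray | None = None,
) -> pd.DataFrame:
    """Distances (nm) and angles/dihedrals (degrees) on group centres."""
    positions = np.asarray(positions, dtype=float)
    if positions.ndim == 2:
        positions = positions[None]
    out = {}
    for cv in defs:
        coms = [_group_com(positions, g, masses) for g in cv.groups]
        if cv.kind == "distance":
            out[cv.name] = np.linalg.norm(coms[1] - coms[0], axis=1)
        elif cv.kind == "angle":
            u = coms[0] - coms[1]
            v = coms[2] - coms[1]
            cosang = np.sum(u * v, axis=1) / (
                np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
            )
            out[cv.name] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        else:
            b1 = coms[1] - coms[0]
            b2 = coms[2] - coms[1]
            b3 = coms[3] - coms[2]
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
            x = np.sum(n1 * n2, axis=1)
            y = np.sum(m1 * n2, axis=1)
            out[cv.name] = np.degrees(np.arctan2(y, x))
    return pd.DataFrame(out)
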