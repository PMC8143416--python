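"""Conformational-change metrics for MD trajectories.

Deviation from the initial structure is measured as least-squares
fitted RMSD per frame; modified and non-modified runs are compared by
the time-normalized difference of the areas under their RMSD curves.
Direct conformational comparison uses gromos (Daura) clustering of the
production tail and the fitted RMSD between the representatives of the
largest clusters.  A periodic-image minimum-distance check flags
systems whose molecule approaches its own periodic copy.

Lengths are Å internally; the gromos cutoff is conventionally quoted
in nm and converted on input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "AtomLabel",
    "Frame",
    "Trajectory",
    "RMSDSeries",
    "ClusterParams",
    "ClusterResult",
    "Box",
    "kabsch_superpose",
    "rmsd_series",
    "rmsd_auc_difference",
    "gromos_cluster",
    "representative_rmsd",
    "periodic_image_min_distance",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
]

NM_TO_ANGSTROM = 10.0


@dataclass(frozen=True)
class AtomLabel:
    chain_id: str
    resnum: int
    atom_name: str
    backbone: bool


@dataclass(frozen=True)
class Frame:
    coords: np.ndarray  # (n_atoms, 3), Å
    labels: tuple[AtomLabel, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_atoms, 3)")
        if len(self.labels) != len(self.coords):
            raise ValueError("labels and coords disagree in length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("atom labels must be unique")

    def select(self, selection: str) -> np.ndarray:
        """Index array for 'backbone' or 'all_atoms'."""
        if selection == "all_atoms":
            return np.arange(len(self.labels))
        if selection == "backbone":
            idx = np.array([i for i, a in enumerate(self.labels) if a.backbone])
            if idx.size == 0:
                raise ValueError("empty selection")
            return idx
        raise ValueError(f"unknown selection {selection!r}")


@dataclass(frozen=True)
class Trajectory:
    frames: tuple[Frame, ...]
    times: np.ndarray  # ps, strictly increasing

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if len(self.frames) != len(self.times):
            raise ValueError("frames and times disagree in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        labels = self.frames[0].labels
        if any(f.labels != labels for f in self.frames[1:]):
            raise ValueError("all frames must share atom labels")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class RMSDSeries:
    times: np.ndarray  # ps
    values: np.ndarray  # Å
    selection: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.times.shape != self.values.shape:
            raise ValueError("times and values disagree in length")
        if np.any(self.values < 0):
            raise ValueError("RMSD values must be non-negative")


@dataclass(frozen=True)
class ClusterParams:
    cutoff_nm: float = 0.25
    selection: str = "all_atoms"

    def __post_init__(self) -> None:
        if self.cutoff_nm <= 0:
            raise ValueError("cutoff must be positive")

    @property
    def cutoff_angstrom(self) -> float:
        return self.cutoff_nm * NM_TO_ANGSTROM


@dataclass(frozen=True)
class ClusterResult:
    clusters: tuple[tuple[tuple[int, ...], int], ...]  # (members, center)

    def __post_init__(self) -> None:
        for members, center in self.clusters:
            if center not in members:
                raise ValueError("center must be a member of its cluster")

    @property
    def largest_center(self) -> int:
        return self.clusters[0][1]


@dataclass(frozen=True)
class Box:
    edges: tuple[float, float, float]  # orthorhombic, Å

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.edges):
            raise ValueError("box edges must be positive")


def kabsch_superpose(
    reference: np.ndarray, mobile: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation, translation, rmsd) with
    ``mobile @ rotation.T + translation`` the fitted coordinates.  The
    rotation is proper (det +1); a reflection solution is corrected by
    flipping the smallest singular direction.
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.shape[0] < 3:
        raise ValueError("need matching coordinate sets of >= 3 atoms")
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    if np.linalg.matrix_rank(ref_c, tol=1e-9) < 2 or np.linalg.matrix_rank(mob_c, tol=1e-9) < 2:
        raise ValueError("degenerate geometry: atoms are collinear")
    h = mob_c.T @ ref_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ref.mean(axis=0) - rot @ mob.mean(axis=0)
    fitted = mob @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return rot, trans, rmsd


def _pair_rmsd(a: np.ndarray, b: np.ndarray, fit: bool) -> float:
    if fit:
        return kabsch_superpose(a, b)[2]
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_series(
    traj: Trajectory, reference: Frame, selection: str = "backbone", fit: bool = True
) -> RMSDSeries:
    """RMSD of every frame against a reference (typically the initial
    structure), over the selected atoms, after least-squares fitting by
    default."""
    if reference.labels != traj.frames[0].labels:
        raise ValueError("reference must share atom labels with the trajectory")
    idx = reference.select(selection)
    ref = reference.coords[idx]
    values = np.array(
        [_pair_rmsd(ref, f.coords[idx], fit) for f in traj.frames]
    )
    return RMSDSeries(times=traj.times.copy(), values=values, selection=selection)


def rmsd_auc_difference(series_mod: RMSDSeries, series_nonmod: RMSDSeries) -> float:
    """Time-normalized difference of areas under two RMSD curves
    (modified minus non-modified); positive means the modified complex
    deviates more from the initial structure on average."""
    for s in (series_mod, series_nonmod):
        if len(s.times) < 2:
            raise ValueError("series needs at least two points")
    span_m = (series_mod.times[0], series_mod.times[-1])
    span_n = (series_nonmod.times[0], series_nonmod.times[-1])
    if not np.allclose(span_m, span_n):
        raise ValueError("series must span the same time interval")
    duration = span_m[1] - span_m[0]
    auc_m = np.trapezoid(series_mod.values, series_mod.times)
    auc_n = np.trapezoid(series_nonmod.values, series_nonmod.times)
    return float((auc_m - auc_n) / duration)


def gromos_cluster(traj: Trajectory, params: ClusterParams = ClusterParams()) -> ClusterResult:
    """Daura neighbor-counting clustering of the frames given.

    Pairwise fitted RMSD over the selection; the frame with the most
    neighbors within the cutoff becomes a cluster center, the center
    and its neighbors are removed, and the step repeats.  Ties in
    neighbor count break to the lowest frame index.  Clusters are
    ordered by size descending, then by center index.
    """
    n = len(traj)
    if n == 0:
        raise ValueError("need at least one frame")
    idx = traj.frames[0].select(params.selection)
    coords = [f.coords[idx] for f in traj.frames]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = _pair_rmsd(coords[i], coords[j], fit=True)

    cutoff = params.cutoff_angstrom
    remaining = list(range(n))
    clusters: list[tuple[tuple[int, ...], int]] = []
    while remaining:
        counts = [
            sum(1 for j in remaining if dist[i, j] <= cutoff) for i in remaining
        ]
        best = remaining[int(np.argmax(counts))]  # argmax takes first on ties
        members = tuple(j for j in remaining if dist[best, j] <= cutoff)
        clusters.append((members, best))
        remaining = [j for j in remaining if j not in members]
    clusters.sort(key=lambda c: (-len(c[0]), c[1]))
    return ClusterResult(clusters=tuple(clusters))


def representative_rmsd(
    traj_a: Trajectory,
    traj_b: Trajectory,
    params: ClusterParams = ClusterParams(),
    tail_fraction: float = 0.5,
) -> float:
    """Fitted RMSD between the largest-cluster representatives of two
    trajectories, each clustered over the final ``tail_fraction`` of
    its frames (the production tail)."""
    if not 0 < tail_fraction <= 1:
        raise ValueError("tail_fraction must be in (0, 1]")

    def tail(traj: Trajectory) -> Trajectory:
        k = max(1, int(round(len(traj) * tail_fraction)))
        return Trajectory(frames=traj.frames[-k:], times=traj.times[-k:])

    ta, tb = tail(traj_a), tail(traj_b)
    rep_a = ta.frames[gromos_cluster(ta, params).largest_center]
    rep_b = tb.frames[gromos_cluster(tb, params).largest_center]
    idx = rep_a.select(params.selection)
    return _pair_rmsd(rep_a.coords[idx], rep_b.coords[idx], fit=True)


# the 26 nonzero neighbor-cell translations of an orthorhombic box
_NEIGHBOR_SHIFTS = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ],
    dtype=float,
)


def periodic_image_min_distance(
    frame: Frame, box: Box, threshold: float = 12.0
) -> tuple[float, bool]:
    """Minimum distance between the atom set and any of its 26 periodic
    images; a distance below ``threshold`` (default 12 Å, the nonbonded
    cutoff) means the molecule can interact with its own image.
    Coordinates must already be wrapped into the box.
    """
    xyz = frame.coords
    edges = np.asarray(box.edges)
    if np.any(xyz < 0) or np.any(xyz > edges):
        raise ValueError("unwrapped_coordinates")
    best = np.inf
    for shift in _NEIGHBOR_SHIFTS:
        translated = xyz + shift * edges
        d = cdist(xyz, translated).min()
        best = min(best, float(d))
    return best, best < threshold


# ---------------------------------------------------------------------------
# simple whitespace XYZ-with-labels trajectory format
#
#   frame <time_ps>
#   <chain> <resnum> <atom_name> <backbone 0/1> <x> <y> <z>
#   ...

def write_xyz_trajectory(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        for frame, t in zip(traj.frames, traj.times):
            fh.write(f"frame {t:.6f}\n")
            for a, (x, y, z) in zip(frame.labels, frame.coords):
                fh.write(
                    f"{a.chain_id} {a.resnum} {a.atom_name} {int(a.backbone)} "
                    f"{x:.6f} {y:.6f} {z:.6f}\n"
                )


def read_xyz_trajectory(path) -> Trajectory:
    frames: list[Frame] = []
    times: list[float] = []
    labels: list[AtomLabel] = []
    coords: list[list[float]] = []

    def flush() -> None:
        if labels:
            frames.append(Frame(coords=np.array(coords), labels=tuple(labels)))
            labels.clear()
            coords.clear()

    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "frame":
                flush()
                times.append(float(parts[1]))
            else:
                chain, resnum, name, bb, x, y, z = parts
                labels.append(AtomLabel(chain, int(resnum), name, bool(int(bb))))
                coords.append([float(x), float(y), float(z)])
    flush()
    return Trajectory(frames=tuple(frames), times=np.array(times))
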