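"""Trajectory-level statistics over halogen-bond geometry series.

Covers the statistics a bound-ligand MD study reports per contact:
primary-region occupancy (fraction of simulation time the geometry is a
correct halogen bond), mean ± SD of distance and σ-hole angle, interval
medians and boxplot summaries for time-resolved plots, ligand RMSD after
binding-pocket superposition, hierarchical frame clustering with a
representative frame, and replicate selection by geometric stability.

Population (not sample) standard deviations are used throughout: the
trajectory is the whole population being described, not a sample from a
larger one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.spatial.transform import Rotation

from .exceptions import EmptyInputError, ParameterError, SelectionError
from .io_structures import Trajectory
from .xb_geometry import REGIONS, GeometrySeries

#: Cα atoms of receptor residues with any atom within this distance (Å) of
#: the ligand in the reference frame define the superposition selection.
POCKET_CUTOFF = 6.0


# ---------------------------------------------------------------------------
# Per-contact summaries
# ---------------------------------------------------------------------------

@dataclass
class ContactSummary:
    """Occupancy and mean ± SD geometry for one contact over a trajectory."""

    label: str
    n_frames: int
    primary_occupancy: float
    mean_d: float
    sd_d: float
    mean_theta: float
    sd_theta: float
    region_fractions: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "contact": self.label,
            "n_frames": self.n_frames,
            "primary_occupancy": self.primary_occupancy,
            "mean_distance_A": self.mean_d,
            "sd_distance_A": self.sd_d,
            "mean_sigma_hole_deg": self.mean_theta,
            "sd_sigma_hole_deg": self.sd_theta,
            "region_fractions": self.region_fractions,
        }

    def human_report(self) -> str:
        """One-line report at the precision used in the literature."""
        return (
            f"{self.label}: primary XB {self.primary_occupancy * 100:.0f}% "
            f"of simulation time; distance {self.mean_d:.1f} ± {self.sd_d:.1f} Å; "
            f"sigma-hole {self.mean_theta:.1f} ± {self.sd_theta:.1f} deg"
        )


def summarize(series: GeometrySeries) -> ContactSummary:
    """Occupancy, per-region fractions and mean ± SD over all frames."""
    df = series.data
    n = len(df)
    if n == 0:
        raise EmptyInputError("cannot summarize an empty geometry series")
    fractions = {
        r: float(np.mean(df["region"].to_numpy() == r)) for r in REGIONS
    }
    return ContactSummary(
        label=series.label,
        n_frames=n,
        primary_occupancy=fractions["primary"],
        mean_d=float(df["distance_A"].mean()),
        sd_d=float(df["distance_A"].std(ddof=0)),
        mean_theta=float(df["sigma_hole_deg"].mean()),
        sd_theta=float(df["sigma_hole_deg"].std(ddof=0)),
        region_fractions=fractions,
    )


# ---------------------------------------------------------------------------
# Interval statistics
# ---------------------------------------------------------------------------

@dataclass
class IntervalMedians:
    """Per-interval medians of d and θ for a time-sliced trajectory.

    Intervals are half-open ``[k·L, (k+1)·L)`` relative to the first
    frame, with the final frame included in the last interval, so a 60 ns
    trajectory at L = 6 ns yields exactly 10 intervals.  Empty intervals
    are recorded as NaN, not errors.
    """

    interval_ns: float
    table: pd.DataFrame  # columns: interval, t_start_ns, median_d, median_theta

    def __len__(self) -> int:
        return len(self.table)


def _interval_index(series: GeometrySeries, interval_ns: float):
    t = series.data["time_ns"].to_numpy(dtype=float)
    if len(t) == 0:
        raise EmptyInputError("empty geometry series")
    if interval_ns <= 0:
        raise ParameterError("interval_ns must be positive")
    t0 = t[0]
    duration = t[-1] - t0
    n_int = max(1, int(math.ceil(duration / interval_ns - 1e-9)))
    idx = np.floor((t - t0) / interval_ns).astype(int)
    idx = np.clip(idx, 0, n_int - 1)  # final frame joins the last interval
    return idx, n_int, t0


def interval_medians(
    series: GeometrySeries, interval_ns: float = 6.0
) -> IntervalMedians:
    """Median d and θ per time interval (default 6 ns slices).

    Interval medians condense an overplotted per-frame distance–angle
    cloud into one point per time slice, making drift between the primary
    and secondary regions visible.
    """
    idx, n_int, t0 = _interval_index(series, interval_ns)
    d = series.data["distance_A"].to_numpy(dtype=float)
    th = series.data["sigma_hole_deg"].to_numpy(dtype=float)
    rows = []
    for k in range(n_int):
        mask = idx == k
        rows.append(
            {
                "interval": k,
                "t_start_ns": t0 + k * interval_ns,
                "median_d": float(np.median(d[mask])) if mask.any() else float("nan"),
                "median_theta": (
                    float(np.median(th[mask])) if mask.any() else float("nan")
                ),
            }
        )
    return IntervalMedians(interval_ns=interval_ns, table=pd.DataFrame(rows))


def boxplot_stats(series: GeometrySeries, interval_ns: float = 6.0) -> pd.DataFrame:
    """Five-number summaries of d and θ per interval (Tukey boxplot stats).

    Quartiles use linear interpolation; whiskers extend to the most
    extreme data point within 1.5·IQR of the quartiles.
    """
    idx, n_int, t0 = _interval_index(series, interval_ns)
    rows = []
    for k in range(n_int):
        mask = idx == k
        row: dict[str, float] = {"interval": k, "t_start_ns": t0 + k * interval_ns}
        for col, tag in (("distance_A", "d"), ("sigma_hole_deg", "theta")):
            vals = series.data[col].to_numpy(dtype=float)[mask]
            if len(vals) == 0:
                for stat in ("lo", "q1", "median", "q3", "hi"):
                    row[f"{tag}_{stat}"] = float("nan")
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
            row[f"{tag}_lo"] = float(inside.min())
            row[f"{tag}_q1"] = float(q1)
            row[f"{tag}_median"] = float(med)
            row[f"{tag}_q3"] = float(q3)
            row[f"{tag}_hi"] = float(inside.max())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

def pocket_calpha_indices(
    traj: Trajectory, reference_frame_index: int = 0, cutoff: float = POCKET_CUTOFF
) -> list[int]:
    """Coordinate indices of binding-pocket Cα atoms.

    Selects the Cα of every receptor residue having any atom within
    ``cutoff`` Å of any ligand atom in the reference frame.
    """
    ref = traj.frames[reference_frame_index].coordinates
    lig_idx = [a.coords_index for a in traj.ligand_atoms()]
    if not lig_idx:
        raise SelectionError("trajectory has no ligand atoms")
    lig = ref[lig_idx]
    near_residues: set[tuple[str, int]] = set()
    for a in traj.receptor_atoms():
        dmin = np.min(np.linalg.norm(lig - ref[a.coords_index], axis=1))
        if dmin <= cutoff:
            near_residues.add((a.chain, a.residue_seq))
    out = [
        a.coords_index
        for a in traj.receptor_atoms()
        if a.name == "CA" and (a.chain, a.residue_seq) in near_residues
    ]
    if not out:
        raise SelectionError(
            f"no pocket C-alpha atoms within {cutoff} Å of the ligand"
        )
    return out


def _superpose(mobile: np.ndarray, target: np.ndarray):
    """Least-squares (Kabsch) fit of ``mobile`` onto ``target``.

    Returns (rotation matrix, mobile centroid, target centroid); apply as
    ``(x - mob_c) @ R.T + tgt_c``.
    """
    mob_c = mobile.mean(axis=0)
    tgt_c = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tgt_c, mobile - mob_c)
    return rot.as_matrix(), mob_c, tgt_c


def ligand_rmsd(
    traj: Trajectory,
    reference_frame_index: int = 0,
    superpose_indices: list[int] | None = None,
) -> pd.DataFrame:
    """Per-frame ligand heavy-atom RMSD (Å) after binding-pocket fit.

    Each frame's receptor selection (default: pocket Cα within
    6 Å of the ligand in the reference frame) is least-squares superposed
    onto the reference; the ligand RMSD is then computed in that fitted
    frame without re-fitting the ligand, so it reports binding-mode drift,
    not internal flexibility alone.
    """
    if superpose_indices is None:
        superpose_indices = pocket_calpha_indices(traj, reference_frame_index)
    if not superpose_indices:
        raise SelectionError("empty superposition selection")
    lig_idx = [
        a.coords_index for a in traj.ligand_atoms() if a.element not in ("H", "D")
    ]
    if not lig_idx:
        raise SelectionError("trajectory has no ligand heavy atoms")

    ref = traj.frames[reference_frame_index].coordinates
    ref_sel = ref[superpose_indices]
    ref_lig = ref[lig_idx]
    rows = []
    for fr in traj.frames:
        R, mob_c, tgt_c = _superpose(fr.coordinates[superpose_indices], ref_sel)
        lig = (fr.coordinates[lig_idx] - mob_c) @ R.T + tgt_c
        rmsd = float(np.sqrt(np.mean(np.sum((lig - ref_lig) ** 2, axis=1))))
        rows.append({"time_ns": fr.time_ns, "rmsd_A": rmsd})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Frame clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Hierarchical clustering of frames on the ligand-RMSD matrix."""

    k: int
    assignment: np.ndarray  # cluster id per frame, 0-based
    sizes: dict[int, int]
    representative_frame: int  # from the most populated cluster

    @property
    def largest_cluster(self) -> int:
        return int(self.assignment[self.representative_frame])


def _ligand_rmsd_matrix(traj: Trajectory, reference_frame_index: int = 0):
    """Pairwise ligand RMSD between frames after pocket superposition."""
    sup = pocket_calpha_indices(traj, reference_frame_index)
    lig_idx = [
        a.coords_index for a in traj.ligand_atoms() if a.element not in ("H", "D")
    ]
    if not lig_idx:
        raise SelectionError("trajectory has no ligand heavy atoms")
    ref = traj.frames[reference_frame_index].coordinates
    ref_sel = ref[sup]
    fitted = []
    for fr in traj.frames:
        R, mob_c, tgt_c = _superpose(fr.coordinates[sup], ref_sel)
        fitted.append((fr.coordinates[lig_idx] - mob_c) @ R.T + tgt_c)
    X = np.stack(fitted).reshape(len(fitted), -1)
    from scipy.spatial.distance import pdist

    return pdist(X) / math.sqrt(len(lig_idx))


def cluster_frames(
    traj: Trajectory, k: int = 10, reference_frame_index: int = 0
) -> ClusterResult:
    """Average-linkage hierarchical clustering of frames into k clusters.

    Distances are pairwise ligand heavy-atom RMSDs after binding-pocket
    superposition.  The representative frame is the member of the most
    populated cluster minimizing the summed RMSD to the rest of its
    cluster; all ties break deterministically by frame order.  When the
    distance structure is degenerate (linkage yields fewer than k distinct
    clusters), the split is completed by peeling trailing frames into
    singletons in frame order.
    """
    n = traj.n_frames
    if n < k:
        raise ParameterError(f"cannot form k={k} clusters from {n} frames")
    condensed = _ligand_rmsd_matrix(traj, reference_frame_index)
    Z = linkage(condensed, method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    # relabel to 0-based ids ordered by first appearance (deterministic)
    remap: dict[int, int] = {}
    assignment = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap)
        assignment[i] = remap[lab]
    # degenerate distances: force exactly k clusters by frame order
    next_id = assignment.max() + 1
    i = n - 1
    while next_id < k:
        sizes = np.bincount(assignment)
        if sizes[assignment[i]] > 1:
            assignment[i] = next_id
            next_id += 1
        i -= 1

    sizes = {int(c): int(np.sum(assignment == c)) for c in np.unique(assignment)}
    largest = max(sizes, key=lambda c: (sizes[c], -int(np.argmax(assignment == c))))
    members = np.flatnonzero(assignment == largest)
    D = squareform(condensed)
    sub = D[np.ix_(members, members)]
    rep = int(members[int(np.argmin(sub.sum(axis=1)))])
    return ClusterResult(
        k=k, assignment=assignment, sizes=sizes, representative_frame=rep
    )


# ---------------------------------------------------------------------------
# Replicate selection
# ---------------------------------------------------------------------------

def select_replicate(replicates: list[GeometrySeries]) -> int:
    """Index of the replicate with the most stable halogen-bond geometry.

    Stability is scored as CV(d) + CV(θ) with CV = population SD / mean;
    the replicate minimizing the score is returned, ties broken by lowest
    index.  This mirrors the practice of illustrating results with the
    replicate showing the lowest variation of the bond's distance and
    angle.
    """
    if not replicates:
        raise EmptyInputError("no replicates given")
    scores = []
    for s in replicates:
        d = s.data["distance_A"].to_numpy(dtype=float)
        th = s.data["sigma_hole_deg"].to_numpy(dtype=float)
        cv_d = d.std(ddof=0) / d.mean() if d.mean() != 0 else np.inf
        cv_t = th.std(ddof=0) / th.mean() if th.mean() != 0 else np.inf
        scores.append(cv_d + cv_t)
    return int(np.argmin(scores))
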