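"""Per-state structural statistics on trajectories.

Given a topology, a trajectory and a frame -> state assignment, this
module computes the quantities reported per equilibrium state:

* mass-weighted per-residue RMSF about the time-average position,
  RMSF_res = sqrt( sum_i m_i < |r_i(t) - <r_i>|^2 > / sum_i m_i );
* hydrogen-bond "percentage of existence" under the geometric
  criterion D-A distance <= 0.35 nm and H-D-A angle <= 30 deg (the
  conventional defaults, configurable), keeping pairs present in more
  than 25% of frames of at least one state;
* conformational clustering with the gromos neighbor-counting method
  at a fixed pairwise superposed-RMSD cutoff, with a medoid
  representative per cluster;
* the nick width: COM distance between the pooled bases at positions
  -1 and +1 flanking the cleavage site.

Superpositions are mass-weighted least squares (Kabsch, via scipy's
rotation alignment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .cvs import AtomGroup, com_distance
from .landscape import StateAssignment
from .system import Topology, Trajectory

__all__ = [
    "HBondCriteria",
    "rmsf",
    "detect_hbonds",
    "hbond_percentages",
    "rmsd_superposed",
    "superpose",
    "ClusterResult",
    "gromos_cluster",
    "nick_width",
]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criterion (donor-acceptor distance,
    hydrogen-donor-acceptor angle)."""

    distance_cutoff: float = 0.35  # nm
    angle_cutoff: float = 30.0  # degrees

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ValueError("H-bond cutoffs must be positive")


# --- superposition and RMSD ---------------------------------------------


def superpose(
    mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Weighted least-squares rigid-body fit of ``mobile`` onto ``reference``."""
    w = np.asarray(weights, dtype=float)
    mu_m = np.average(mobile, axis=0, weights=w)
    mu_r = np.average(reference, axis=0, weights=w)
    am = mobile - mu_m
    ar = reference - mu_r
    rot, _ = Rotation.align_vectors(ar, am, weights=w)
    return rot.apply(am) + mu_r


def rmsd_superposed(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    selection: tuple[int, ...] | None = None,
    masses: np.ndarray | None = None,
) -> float:
    """Mass-weighted RMSD after optimal rigid-body superposition (nm)."""
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if selection is not None:
        sel = list(selection)
        a, b = a[sel], b[sel]
        masses = None if masses is None else np.asarray(masses)[sel]
    if a.shape != b.shape:
        raise ValueError("frames have different atom counts")
    n = a.shape[0]
    w = np.ones(n) if masses is None else np.asarray(masses, dtype=float)
    centered = a - np.average(a, axis=0, weights=w)
    if n < 3 or np.linalg.matrix_rank(centered, tol=1e-10) < 2:
        raise ValueError("need >= 3 non-collinear atoms to define the rotation")
    fitted = superpose(a, b, w)
    d2 = np.sum((fitted - b) ** 2, axis=1)
    return float(np.sqrt(np.average(d2, weights=w)))


# --- RMSF ----------------------------------------------------------------


def rmsf(
    traj: Trajectory,
    top: Topology,
    selection: tuple[int, ...] | None = None,
    fit: bool = True,
    fit_selection: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """Mass-weighted per-residue RMSF (nm) over the trajectory.

    With ``fit=True`` every frame is first least-squares superposed to
    the first frame (on ``fit_selection``, default all atoms) so that
    rigid-body drift does not inflate the fluctuations; ``fit=False``
    uses the raw coordinates.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF is undefined for a single frame")
    masses = top.masses
    sel = tuple(range(traj.n_atoms)) if selection is None else tuple(selection)
    if not sel:
        raise ValueError("empty selection")
    coords = traj.coords
    if fit:
        fsel = tuple(range(traj.n_atoms)) if fit_selection is None else tuple(fit_selection)
        if len(fsel) < 3:
            warnings.warn("fewer than 3 fit atoms; skipping superposition")
        else:
            ref = coords[0][list(fsel)]
            w = masses[list(fsel)]
            fitted = np.empty_like(coords)
            for f in range(traj.n_frames):
                mob = coords[f][list(fsel)]
                mu_m = np.average(mob, axis=0, weights=w)
                mu_r = np.average(ref, axis=0, weights=w)
                rot, _ = Rotation.align_vectors(ref - mu_r, mob - mu_m, weights=w)
                fitted[f] = rot.apply(coords[f] - mu_m) + mu_r
            coords = fitted
    mean = coords.mean(axis=0)
    msd = ((coords - mean) ** 2).sum(axis=2).mean(axis=0)  # per atom
    rows = []
    for (resid, resname), idx in top.residue_groups().items():
        idx = [i for i in idx if i in set(sel)]
        if not idx:
            continue
        w = masses[idx]
        rows.append(
            {
                "resid": resid,
                "resname": resname,
                "rmsf": float(np.sqrt(np.average(msd[idx], weights=w))),
            }
        )
    return pd.DataFrame(rows)


# --- hydrogen bonds ------------------------------------------------------


def detect_hbonds(
    frame: np.ndarray, top: Topology, criteria: HBondCriteria = HBondCriteria()
) -> list[tuple[int, int, int]]:
    """Hydrogen bonds in one frame as (donor, hydrogen, acceptor) triples.

    A bond is reported iff the donor-acceptor distance is within the
    cutoff and the H-D-A angle (at the donor) is within the angle
    cutoff.  Output is sorted by (donor, acceptor).
    """
    frame = np.asarray(frame, dtype=float)
    out = []
    for d, h in top.donors:
        for a in top.acceptors:
            if a == d or a == h:
                continue
            v_da = frame[a] - frame[d]
            r_da = np.linalg.norm(v_da)
            if r_da > criteria.distance_cutoff:
                continue
            v_dh = frame[h] - frame[d]
            n_dh = np.linalg.norm(v_dh)
            if n_dh == 0 or r_da == 0:
                continue
            cosang = np.clip(np.dot(v_dh, v_da) / (n_dh * r_da), -1.0, 1.0)
            angle = np.degrees(np.arccos(cosang))
            if angle <= criteria.angle_cutoff:
                out.append((d, h, a))
    out.sort(key=lambda t: (t[0], t[2]))
    return out


def hbond_percentages(
    traj: Trajectory,
    top: Topology,
    states: StateAssignment,
    criteria: HBondCriteria = HBondCriteria(),
    report_threshold: float = 25.0,
) -> pd.DataFrame:
    """Per-state percentage of existence of each donor-acceptor pair.

    Percentages are over the frames assigned to each state; unassigned
    frames are excluded.  Rows are kept iff the pair exceeds
    ``report_threshold`` percent in at least one state.
    """
    state_labels = sorted(states.counts().keys())
    counts: dict[tuple[int, int], dict[str, int]] = {}
    totals = {s: 0 for s in state_labels}
    for f in range(traj.n_frames):
        s = states.labels[f] if f < len(states.labels) else None
        if s is None:
            continue
        totals[s] += 1
        for d, h, a in detect_hbonds(traj.coords[f], top, criteria):
            counts.setdefault((d, a), {lab: 0 for lab in state_labels})[s] += 1
    rows = []
    for (d, a), per_state in sorted(counts.items()):
        pct = {
            s: (100.0 * per_state[s] / totals[s]) if totals[s] > 0 else np.nan
            for s in state_labels
        }
        if not any(
            (not np.isnan(p)) and p > report_threshold for p in pct.values()
        ):
            continue
        da, aa = top.atoms[d], top.atoms[a]
        row = {
            "donor": da.name,
            "donor_res": da.resname,
            "acceptor": aa.name,
            "acceptor_res": aa.resname,
        }
        for s in state_labels:
            row[s] = round(pct[s], 1) if not np.isnan(pct[s]) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# --- gromos clustering ---------------------------------------------------


@dataclass
class ClusterResult:
    """Clusters as frame-index lists (descending size) with medoid reps."""

    clusters: list[list[int]]
    representatives: list[int]
    cutoff: float
    rmsd_matrix: np.ndarray


def gromos_cluster(
    traj: Trajectory,
    selection: tuple[int, ...] | None = None,
    masses: np.ndarray | None = None,
    cutoff: float = 0.1,
) -> ClusterResult:
    """Neighbor-counting (gromos) clustering at a pairwise-RMSD cutoff.

    Iteratively, the frame with the most neighbors within ``cutoff``
    (ties to the lowest frame index) forms a cluster with its
    neighbors; the cluster is removed and the count repeated.  The
    representative of a cluster is the member minimizing the summed
    RMSD to the other members.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = traj.n_frames
    if n < 1:
        raise ValueError("empty trajectory")
    sel = list(range(traj.n_atoms)) if selection is None else list(selection)
    w = None if masses is None else np.asarray(masses)[sel]
    coords = traj.coords[:, sel, :]
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = rmsd_superposed(coords[i], coords[j], masses=w)
    remaining = set(range(n))
    clusters: list[list[int]] = []
    reps: list[int] = []
    while remaining:
        best_center, best_nb = -1, None
        for i in sorted(remaining):
            nb = [j for j in remaining if dm[i, j] <= cutoff]  # includes i
            if best_nb is None or len(nb) > len(best_nb):
                best_center, best_nb = i, nb
        members = sorted(best_nb)
        clusters.append(members)
        sums = [(dm[np.ix_([m], members)].sum(), m) for m in members]
        reps.append(min(sums)[1])
        remaining -= set(members)
    order = sorted(range(len(clusters)), key=lambda k: (-len(clusters[k]), k))
    return ClusterResult(
        clusters=[clusters[k] for k in order],
        representatives=[reps[k] for k in order],
        cutoff=cutoff,
        rmsd_matrix=dm,
    )


# --- nick width ----------------------------------------------------------


def nick_width(frame: np.ndarray, top: Topology) -> float:
    """COM distance between the pooled bases at positions -1 and +1 (nm)."""
    minus = top.base_indices(-1)
    plus = top.base_indices(1)
    if not minus or not plus:
        raise ValueError("topology lacks base labels at positions -1/+1")
    g_minus = AtomGroup(minus, "bases -1")
    g_plus = AtomGroup(plus, "bases +1")
    return com_distance(frame, g_minus, g_plus, top.masses)
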