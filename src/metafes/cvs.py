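"""Collective variables for ligand unbinding.

Two CVs describe the escape of an intercalated ligand from its binding
site: the distance between the centers of mass of the ligand and of the
flanking nucleobases, and the number of ligand--nucleobase atomic
contacts counted with the rational switching function used for
coordination-number CVs,

    s(r) = (1 - x^n) / (1 - x^m),   x = (r - d0) / r0,

with s(r) = 1 for r <= d0.  The switching parameters d0 and r0 are fit
from the radial atom-pair distance distribution observed in an unbiased
equilibration run: d0 at the first peak, r0 as the full width at half
maximum of that peak.

Internal units: nm, kJ/mol, ps, amu.  Toy systems are non-periodic; no
minimum-image convention is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SwitchingParams",
    "AtomGroup",
    "com",
    "com_distance",
    "switching_value",
    "coordination_number",
    "DistanceHistogram",
    "pair_distance_distribution",
    "fit_switching_params",
    "write_colvar",
    "read_colvar",
]


@dataclass(frozen=True)
class SwitchingParams:
    """Rational switching function parameters (d0 offset, r0 scale, exponents)."""

    d0: float  # nm
    r0: float  # nm
    n_exp: int = 6
    m_exp: int = 12

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError(f"r0 must be > 0, got {self.r0}")
        if not (0 < self.n_exp < self.m_exp):
            raise ValueError(
                f"need m_exp > n_exp > 0, got n={self.n_exp}, m={self.m_exp}"
            )
        if self.n_exp % 2 or self.m_exp % 2:
            raise ValueError("switching exponents must be even")


@dataclass(frozen=True)
class AtomGroup:
    """A named, non-empty set of atom indices into a topology."""

    indices: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.indices) == 0:
            raise ValueError(f"atom group {self.label!r} is empty")
        if min(self.indices) < 0:
            raise ValueError("negative atom index")

    def __len__(self) -> int:
        return len(self.indices)


def com(frame: np.ndarray, group: AtomGroup, masses: np.ndarray) -> np.ndarray:
    """Mass-weighted centroid of ``group`` in a single frame (nm)."""
    frame = np.asarray(frame, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if masses.shape[0] != frame.shape[0]:
        raise ValueError(
            f"mass array length {masses.shape[0]} != atom count {frame.shape[0]}"
        )
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    idx = list(group.indices)
    w = masses[idx]
    return np.average(frame[idx], axis=0, weights=w)


def com_distance(
    frame: np.ndarray, a: AtomGroup, b: AtomGroup, masses: np.ndarray
) -> float:
    """Distance between the centers of mass of groups ``a`` and ``b`` (nm)."""
    return float(np.linalg.norm(com(frame, a, masses) - com(frame, b, masses)))


def switching_value(r: np.ndarray, p: SwitchingParams) -> np.ndarray:
    """Pairwise switching term s(r) in (0, 1]; s = 1 for r <= d0.

    The removable singularity at x = 1 is handled by the first-order
    expansion s(1+eps) ~ (n/m) (1 + eps (n-m)/2) when |x-1| < 1e-6.
    """
    r = np.asarray(r, dtype=float)
    x = (r - p.d0) / p.r0
    x = np.maximum(x, 0.0)  # r <= d0: limiting value 1
    n, m = p.n_exp, p.m_exp
    out = np.empty_like(x)
    near_one = np.abs(x - 1.0) < 1e-6
    safe = ~near_one
    xs = x[safe]
    out[safe] = (1.0 - xs**n) / (1.0 - xs**m)
    eps = x[near_one] - 1.0
    out[near_one] = (n / m) * (1.0 + eps * (n - m) / 2.0)
    return out


def coordination_number(
    frame: np.ndarray, a: AtomGroup, b: AtomGroup, p: SwitchingParams
) -> float:
    """Coordination number between groups a and b: sum of s(r_ij) over all pairs."""
    frame = np.asarray(frame, dtype=float)
    ra = frame[list(a.indices)]
    rb = frame[list(b.indices)]
    d = np.linalg.norm(ra[:, None, :] - rb[None, :, :], axis=-1)
    return float(switching_value(d, p).sum())


@dataclass
class DistanceHistogram:
    """Histogram of pair distances: ``counts[i]`` covers [edges[i], edges[i+1])."""

    counts: np.ndarray
    edges: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])


def pair_distance_distribution(
    traj: np.ndarray, a: AtomGroup, b: AtomGroup, bin_width: float
) -> DistanceHistogram:
    """Radial atom-pair distance distribution over all frames and a x b pairs.

    ``traj`` has shape (n_frames, n_atoms, 3).  Total counts equal
    n_frames * |a| * |b|.
    """
    traj = np.asarray(traj, dtype=float)
    if traj.ndim != 3 or traj.shape[0] < 1:
        raise ValueError("trajectory must be a non-empty (frames, atoms, 3) array")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    ra = traj[:, list(a.indices), :]
    rb = traj[:, list(b.indices), :]
    d = np.linalg.norm(ra[:, :, None, :] - rb[:, None, :, :], axis=-1).ravel()
    n_bins = int(np.ceil((d.max() + 0.5 * bin_width) / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(d, bins=edges)
    return DistanceHistogram(counts=counts.astype(float), edges=edges)


def fit_switching_params(
    hist: DistanceHistogram,
    n_exp: int = 6,
    m_exp: int = 12,
    noise_floor: float = 0.05,
) -> SwitchingParams:
    """Fit d0/r0 from a pair-distance histogram.

    d0 is the center of the first local maximum scanning from zero
    (ignoring bins below ``noise_floor`` x the global maximum, so a
    single stray count does not register as a peak); r0 is the width of
    the contiguous region around that peak where counts stay at or
    above half the peak count -- the full width at half maximum.
    """
    c = np.asarray(hist.counts, dtype=float)
    if c.size == 0 or c.max() <= 0:
        raise ValueError("empty histogram")
    if np.all(c == c[0]):
        raise ValueError("flat histogram has no peak")
    floor = noise_floor * c.max()
    peak = None
    for i in range(c.size):
        left = c[i - 1] if i > 0 else -np.inf
        right = c[i + 1] if i < c.size - 1 else -np.inf
        if c[i] >= floor and c[i] >= left and c[i] > right:
            peak = i
            break
        if c[i] >= floor and c[i] >= left and i == c.size - 1:
            peak = i
            break
    if peak is None:
        raise ValueError("no local maximum found above the noise floor")
    half = 0.5 * c[peak]
    lo = peak
    while lo > 0 and c[lo - 1] >= half:
        lo -= 1
    hi = peak
    while hi < c.size - 1 and c[hi + 1] >= half:
        hi += 1
    width = (hi - lo + 1) * hist.bin_width
    return SwitchingParams(
        d0=float(hist.centers[peak]), r0=float(width), n_exp=n_exp, m_exp=m_exp
    )


# --- COLVAR-style time-series persistence -------------------------------

COLVAR_HEADER = "#! FIELDS time dist cn"


def write_colvar(df: pd.DataFrame, path) -> None:
    """Write a CV time series (columns time, dist, cn) as COLVAR-style text."""
    with open(path, "w") as fh:
        fh.write(COLVAR_HEADER + "\n")
        for row in df.itertuples(index=False):
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_colvar(path) -> pd.DataFrame:
    names = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#!") and "FIELDS" in line:
                    names = line.split()[2:]
                continue
            rows.append([float(t) for t in line.split()])
    if names is None:
        ncol = len(rows[0]) if rows else 1
        names = ["time", "dist", "cn"][:ncol]
    return pd.DataFrame(rows, columns=names)
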