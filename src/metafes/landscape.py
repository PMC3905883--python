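"""Basin, transition-state and minimum-energy-path analysis on a gridded FES.

States are the catchment basins of local minima: from every grid node a
steepest-descent walk over the 8-neighborhood ends in some local
minimum, and the node is assigned to it ("grid search minimization").
Trajectory frames are assigned to the basin of their nearest grid node
if their interpolated free energy lies within a cutoff (default 20
kJ/mol) of that basin's minimum; everything else is left unassigned.

The minimum-energy path between two minima is the 8-connected grid
path minimizing the maximum free energy en route (minimax criterion,
ties broken by the lower cumulative energy), found with a Dijkstra-like
search.  Its highest node is the transition state, and the activation
energy is F(saddle) - F(start minimum).  The path is reported against a
normalized reaction coordinate s in [0, 1].
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fes import FESGrid

__all__ = [
    "Minimum",
    "BasinMap",
    "StateAssignment",
    "MEPProfile",
    "find_minima",
    "basin_assign",
    "assign_frames",
    "minimum_energy_path",
    "profile_along_path",
]


@dataclass(frozen=True)
class Minimum:
    node: tuple[int, ...]
    coords: tuple[float, ...]
    energy: float
    label: str


def _neighbor_offsets(ndim: int) -> list[tuple[int, ...]]:
    if ndim == 1:
        return [(-1,), (1,)]
    return [
        (di, dj)
        for di in (-1, 0, 1)
        for dj in (-1, 0, 1)
        if not (di == 0 and dj == 0)
    ]


def find_minima(fes: FESGrid) -> list[Minimum]:
    """Grid nodes strictly lower than all available (8-)neighbors,
    sorted by energy ascending and labeled M0, M1, ..."""
    v = fes.values
    ndim = v.ndim
    padded = np.pad(v, 1, mode="constant", constant_values=np.inf)
    is_min = np.ones_like(v, dtype=bool)
    core = tuple(slice(1, -1) for _ in range(ndim))
    for off in _neighbor_offsets(ndim):
        shifted = padded[tuple(slice(1 + o, padded.shape[d] - 1 + o)
                               for d, o in enumerate(off))]
        is_min &= v < shifted
    nodes = np.argwhere(is_min)
    if nodes.size == 0:
        warnings.warn("no strict local minima found (flat grid?)")
        return []
    axes = fes.spec.axis_arrays()
    order = np.argsort([v[tuple(n)] for n in nodes], kind="stable")
    minima = []
    for rank, k in enumerate(order):
        node = tuple(int(i) for i in nodes[k])
        minima.append(
            Minimum(
                node=node,
                coords=tuple(float(axes[d][node[d]]) for d in range(ndim)),
                energy=float(v[node]),
                label=f"M{rank}",
            )
        )
    return minima


@dataclass
class BasinMap:
    """Node -> minimum assignment from discrete steepest descent."""

    minima: list[Minimum]
    basin_index: np.ndarray  # index into minima, -1 for plateau terminals

    def populations(self) -> dict[str, int]:
        out = {}
        for i, m in enumerate(self.minima):
            out[m.label] = int(np.sum(self.basin_index == i))
        return out

    def label_of_node(self, node: tuple[int, ...]) -> str | None:
        i = int(self.basin_index[node])
        return self.minima[i].label if i >= 0 else None


def basin_assign(fes: FESGrid, minima: list[Minimum] | None = None) -> BasinMap:
    """Assign every node to the minimum its steepest-descent walk reaches.

    From each node, repeatedly step to the lowest strictly-lower
    neighbor (ties broken by lowest flat index) until no neighbor is
    lower.  Implemented with pointer jumping, which converges because
    strict descent cannot cycle.
    """
    if minima is None:
        minima = find_minima(fes)
    if not minima:
        raise ValueError("no minima to assign basins to")
    v = fes.values
    shape = v.shape
    flat = v.ravel()
    n = flat.size
    nxt = np.arange(n)
    best = np.full(n, np.inf)
    idx_grid = np.arange(n).reshape(shape)
    padded_v = np.pad(v, 1, mode="constant", constant_values=np.inf)
    padded_i = np.pad(idx_grid, 1, mode="constant", constant_values=-1)
    for off in _neighbor_offsets(v.ndim):
        sl = tuple(slice(1 + o, padded_v.shape[d] - 1 + o)
                   for d, o in enumerate(off))
        nv = padded_v[sl].ravel()
        ni = padded_i[sl].ravel()
        # strictly-lower neighbors only; among them the lowest value,
        # ties broken by lowest flat index
        strict = nv < flat
        sel = strict & ((nv < best) | ((nv == best) & (ni < nxt)))
        nxt = np.where(sel, ni, nxt)
        best = np.where(sel, nv, best)
    # pointer jumping to the terminal of each descent chain
    while True:
        nxt2 = nxt[nxt]
        if np.array_equal(nxt2, nxt):
            break
        nxt = nxt2
    min_index = {int(np.ravel_multi_index(m.node, shape)): i
                 for i, m in enumerate(minima)}
    basin = np.array([min_index.get(int(t), -1) for t in nxt], dtype=int)
    if np.any(basin < 0):
        warnings.warn("some nodes terminate on a plateau, left unassigned")
    return BasinMap(minima=minima, basin_index=basin.reshape(shape))


@dataclass
class StateAssignment:
    """Frame -> state label (or None) with the free-energy gap used."""

    labels: list[str | None]
    delta_f: np.ndarray  # F(frame) - F(basin minimum), NaN if outside grid
    cutoff: float
    times: np.ndarray | None = None

    def frames_of(self, label: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.labels) if s == label])

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.labels:
            if s is not None:
                out[s] = out.get(s, 0) + 1
        return out


def assign_frames(
    colvar: pd.DataFrame,
    fes: FESGrid,
    basins: BasinMap,
    cutoff: float = 20.0,
) -> StateAssignment:
    """Assign frames to basins when their interpolated free energy is
    within ``cutoff`` kJ/mol of the basin minimum.

    The basin of a frame is that of its nearest grid node.  Frames
    outside the grid are left unassigned (with a warning).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    cvs = colvar[colvar.columns[1:]].to_numpy(dtype=float)
    times = colvar["time"].to_numpy(dtype=float)
    axes = fes.spec.axes
    labels: list[str | None] = []
    dfs = np.full(len(cvs), np.nan)
    n_outside = 0
    for k, pt in enumerate(cvs):
        inside = all(lo <= x <= hi for x, (lo, hi, _) in zip(pt, axes))
        if not inside:
            labels.append(None)
            n_outside += 1
            continue
        node = fes.nearest_node(pt)
        bi = int(basins.basin_index[node])
        if bi < 0:
            labels.append(None)
            continue
        m = basins.minima[bi]
        df = float(fes.interpolate(pt)) - m.energy
        dfs[k] = df
        labels.append(m.label if df < cutoff else None)
    if n_outside:
        warnings.warn(f"{n_outside} frames outside the FES grid left unassigned")
    return StateAssignment(labels=labels, delta_f=dfs, cutoff=cutoff, times=times)


@dataclass
class MEPProfile:
    """Minimum-energy path between two basin minima."""

    nodes: list[tuple[int, ...]]
    coords: np.ndarray  # (n, ndim) CV coordinates
    energy: np.ndarray  # kJ/mol along the path
    s: np.ndarray  # normalized reaction coordinate in [0, 1]
    saddle_index: int
    from_label: str
    to_label: str

    @property
    def activation_energy(self) -> float:
        """F(saddle) - F(start minimum), kJ/mol."""
        return float(self.energy[self.saddle_index] - self.energy[0])

    @property
    def saddle_energy(self) -> float:
        return float(self.energy[self.saddle_index])


def _minimum_by_label(basins: BasinMap, label: str) -> Minimum:
    for m in basins.minima:
        if m.label == label:
            return m
    raise KeyError(f"no minimum labeled {label!r}")


def minimum_energy_path(
    fes: FESGrid, basins: BasinMap, from_label: str, to_label: str
) -> MEPProfile:
    """Minimax (lowest-saddle) 8-connected grid path between two minima.

    Dijkstra-like search with lexicographic cost (max energy along the
    path, cumulative energy): the first key yields the minimax saddle,
    the second breaks ties in favor of the lower-energy route.
    """
    a = _minimum_by_label(basins, from_label)
    b = _minimum_by_label(basins, to_label)
    v = fes.values
    shape = v.shape
    ndim = v.ndim
    offsets = _neighbor_offsets(ndim)
    start = a.node
    goal = b.node
    if start == goal:
        axes = fes.spec.axis_arrays()
        coords = np.array([[axes[d][start[d]] for d in range(ndim)]])
        return MEPProfile(
            nodes=[start],
            coords=coords,
            energy=np.array([v[start]]),
            s=np.array([0.0]),
            saddle_index=0,
            from_label=from_label,
            to_label=to_label,
        )
    INF = (np.inf, np.inf)
    best: dict[tuple[int, ...], tuple[float, float]] = {start: (float(v[start]), float(v[start]))}
    parent: dict[tuple[int, ...], tuple[int, ...] | None] = {start: None}
    heap = [(float(v[start]), float(v[start]), start)]
    visited: set[tuple[int, ...]] = set()
    while heap:
        mx, cum, node = heapq.heappop(heap)
        if node in visited:
            continue
        visited.add(node)
        if node == goal:
            break
        for off in offsets:
            nb = tuple(node[d] + off[d] for d in range(ndim))
            if any(not (0 <= nb[d] < shape[d]) for d in range(ndim)):
                continue
            if nb in visited:
                continue
            e = float(v[nb])
            cand = (max(mx, e), cum + e)
            if cand < best.get(nb, INF):
                best[nb] = cand
                parent[nb] = node
                heapq.heappush(heap, (cand[0], cand[1], nb))
    if goal not in parent:
        raise RuntimeError("minima are disconnected on the grid")
    path = [goal]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    path.reverse()
    axes = fes.spec.axis_arrays()
    coords = np.array([[axes[d][n[d]] for d in range(ndim)] for n in path])
    energy = np.array([v[n] for n in path])
    # arc length in grid-index space, normalized to [0, 1]
    steps = np.array(
        [np.linalg.norm(np.subtract(path[i + 1], path[i])) for i in range(len(path) - 1)]
    )
    s = np.concatenate([[0.0], np.cumsum(steps)])
    s /= s[-1]
    saddle = int(np.argmax(energy))
    return MEPProfile(
        nodes=path,
        coords=coords,
        energy=energy,
        s=s,
        saddle_index=saddle,
        from_label=from_label,
        to_label=to_label,
    )


def profile_along_path(mep: MEPProfile) -> pd.DataFrame:
    """Two-column (plus CV coordinates) monotone-s free-energy profile."""
    ndim = mep.coords.shape[1]
    data = {"s": mep.s}
    for d in range(ndim):
        data[f"cv{d+1}"] = mep.coords[:, d]
    data["F"] = mep.energy
    df = pd.DataFrame(data)
    df.attrs["from_label"] = mep.from_label
    df.attrs["to_label"] = mep.to_label
    return df


def prominences(fes: FESGrid, basins: BasinMap) -> dict[str, float]:
    """Topographic prominence of each minimum: the minimax escape saddle
    toward any strictly lower minimum, minus the minimum's own energy.

    The global minimum gets infinite prominence.  Shallow minima carved
    by hill roughness have prominence on the scale of one hill height
    and can be filtered against a physically meaningful threshold.
    Computed by the persistence sweep: process nodes by ascending
    energy, union-find connected components; when two components merge,
    the one rooted at the higher minimum dies and its prominence is the
    merge energy minus its root energy.
    """
    v = fes.values
    shape = v.shape
    flat = v.ravel()
    n = flat.size
    order = np.lexsort((np.arange(n), flat))  # energy asc, index tie-break
    offsets = _neighbor_offsets(v.ndim)
    parent = np.full(n, -1, dtype=np.int64)  # union-find, -1 = unprocessed
    root_of = {}  # component representative -> root (minimum) flat index
    prom: dict[int, float] = {}

    def find(i: int) -> int:
        r = i
        while parent[r] != r:
            r = parent[r]
        while parent[i] != r:
            parent[i], i = r, parent[i]
        return r

    # neighbor flat offsets with explicit bounds checks per dimension
    if v.ndim == 1:
        def neighbors(idx):
            if idx > 0:
                yield idx - 1
            if idx < n - 1:
                yield idx + 1
    else:
        n0, n1 = shape

        def neighbors(idx):
            i, j = divmod(idx, n1)
            for di, dj in offsets:
                i2, j2 = i + di, j + dj
                if 0 <= i2 < n0 and 0 <= j2 < n1:
                    yield i2 * n1 + j2

    flat_l = flat.tolist()
    for idx in order.tolist():
        parent[idx] = idx
        root_of[idx] = idx
        comps = []
        for nb in neighbors(idx):
            if parent[nb] < 0:
                continue
            r = find(nb)
            if r not in comps:
                comps.append(r)
        if not comps:
            continue  # idx starts a new component (a local minimum)
        # survivor: component whose root minimum is lowest (tie: lowest index)
        keys = [(flat_l[root_of[r]], root_of[r]) for r in comps]
        surv = comps[min(range(len(comps)), key=lambda t: keys[t])]
        for r in comps:
            if r != surv:
                dead_root = root_of[r]
                prom[dead_root] = float(flat_l[idx] - flat_l[dead_root])
            parent[r] = surv
        parent[idx] = surv
    out: dict[str, float] = {}
    for m in basins.minima:
        fi = int(np.ravel_multi_index(m.node, shape))
        out[m.label] = prom.get(fi, np.inf)
    return out
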