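"""Free-energy-surface reconstruction from deposited Gaussian hills.

At the end of a run the FES on a rectangular CV grid is the negative of
the summed hills, F(x) = -sum_k G_k(x) in standard metadynamics and
F(x) = -(gamma/(gamma-1)) sum_k G_k(x) in the well-tempered variant,
shifted so the global minimum sits at zero.  Hills are summed exactly
(no tail truncation), using the separability of the Gaussian across CV
axes.  Summation is stopped at escape: hills deposited after the
distance CV first reaches a reference threshold (4.0 nm by default in
the pipeline, the point where the ligand no longer touches the
receptor) are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import Hill

__all__ = [
    "GridSpec",
    "FESGrid",
    "grid_from_hills",
    "reconstruct_fes",
    "truncate_at_escape",
    "write_fes",
    "read_fes",
]


@dataclass(frozen=True)
class GridSpec:
    """Rectangular CV grid: per-CV (min, max, n_points)."""

    axes: tuple[tuple[float, float, int], ...]

    def __post_init__(self) -> None:
        for lo, hi, n in self.axes:
            if hi <= lo:
                raise ValueError(f"grid axis max {hi} <= min {lo}")
            if n < 2:
                raise ValueError("grid needs >= 2 points per axis")

    @property
    def ndim(self) -> int:
        return len(self.axes)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(n for _, _, n in self.axes)

    def axis_arrays(self) -> list[np.ndarray]:
        return [np.linspace(lo, hi, n) for lo, hi, n in self.axes]


def grid_from_hills(
    hills: list[Hill], n_points: tuple[int, ...] | None = None, pad_sigmas: float = 3.0
) -> GridSpec:
    """Default grid: hill-center bounding box padded by ``pad_sigmas`` widths."""
    if not hills:
        raise ValueError("no hills")
    ndim = len(hills[0].center)
    if n_points is None:
        n_points = (500,) * ndim
    c = np.array([h.center for h in hills])
    w = np.array([h.width for h in hills])
    lo = c.min(axis=0) - pad_sigmas * w.max(axis=0)
    hi = c.max(axis=0) + pad_sigmas * w.max(axis=0)
    return GridSpec(tuple((float(l), float(h), int(n)) for l, h, n in zip(lo, hi, n_points)))


@dataclass
class FESGrid:
    """Free-energy values (kJ/mol) on a grid; global minimum shifted to 0."""

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError("value array does not match grid spec")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite free-energy values")

    def interpolate(self, points) -> np.ndarray:
        """(Bi)linear interpolation at CV point(s) of shape (..., ndim)."""
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            self.spec.axis_arrays(), self.values, method="linear",
            bounds_error=True,
        )
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = interp(pts)
        return float(out[0]) if np.asarray(points).ndim == 1 else out

    def nearest_node(self, point) -> tuple[int, ...]:
        idx = []
        for x, (lo, hi, n) in zip(point, self.spec.axes):
            i = int(round((x - lo) / (hi - lo) * (n - 1)))
            idx.append(min(max(i, 0), n - 1))
        return tuple(idx)


def reconstruct_fes(
    hills: list[Hill],
    spec: GridSpec | None = None,
    mode: str = "standard",
    bias_factor: float | None = None,
    shift: bool = True,
    average_from: float | None = None,
) -> FESGrid:
    """Sum the deposited hills on the grid and negate (exact Gaussians).

    Well-tempered mode rescales by gamma/(gamma-1) before shifting the
    global minimum to zero.

    ``average_from`` (a fraction in [0, 1)) switches to the
    time-averaged estimator: the running FES estimate -sum_{j<=k} G_j
    is averaged over deposition indices k from ``average_from * K`` to
    K.  For non-tempered runs this damps the late-time churn of the
    instantaneous bias and is the standard convergence device; it
    reduces to a weighted hill sum with weights
    (K - max(j, K0) + 1) / (K - K0 + 1).
    """
    if not hills:
        raise ValueError("empty hill list")
    if spec is None:
        spec = grid_from_hills(hills)
    if mode not in ("standard", "well_tempered"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "well_tempered":
        if bias_factor is None or bias_factor <= 1:
            raise ValueError("well-tempered reconstruction needs bias_factor > 1")
    weights = np.ones(len(hills))
    if average_from is not None:
        if not 0.0 <= average_from < 1.0:
            raise ValueError("average_from must be a fraction in [0, 1)")
        k_tot = len(hills)
        k0 = int(average_from * k_tot)
        j = np.arange(1, k_tot + 1)
        weights = (k_tot - np.maximum(j, k0) + 1) / (k_tot - k0 + 1)
    axes = spec.axis_arrays()
    bias = np.zeros(spec.shape)
    if spec.ndim == 1:
        ax = axes[0]
        for w, h in zip(weights, hills):
            bias += (w * h.height) * np.exp(
                -((ax - h.center[0]) ** 2) / (2.0 * h.width[0] ** 2)
            )
    elif spec.ndim == 2:
        ax0, ax1 = axes
        for w, h in zip(weights, hills):
            gx = np.exp(-((ax0 - h.center[0]) ** 2) / (2.0 * h.width[0] ** 2))
            gy = np.exp(-((ax1 - h.center[1]) ** 2) / (2.0 * h.width[1] ** 2))
            bias += (w * h.height) * np.outer(gx, gy)
    else:
        raise ValueError("only 1-D and 2-D grids supported")
    f = -bias
    if mode == "well_tempered":
        f *= bias_factor / (bias_factor - 1.0)
    if shift:
        f -= f.min()
    return FESGrid(spec=spec, values=f)


def truncate_at_escape(
    colvar: pd.DataFrame,
    hills: list[Hill],
    distance_threshold: float,
    distance_col: str | None = None,
) -> list[Hill]:
    """Keep hills deposited up to the first time the distance CV reaches
    ``distance_threshold`` (all hills if it never does)."""
    if distance_threshold <= 0:
        raise ValueError("distance threshold must be positive")
    if distance_col is None:
        distance_col = colvar.columns[1]
    d = colvar[distance_col].to_numpy()
    t = colvar["time"].to_numpy()
    crossed = np.nonzero(d >= distance_threshold)[0]
    if crossed.size == 0:
        return list(hills)
    t_escape = float(t[crossed[0]])
    return [h for h in hills if h.time <= t_escape]


# --- persistence ---------------------------------------------------------


def write_fes(fes: FESGrid, path) -> None:
    """Grid-major three-column text (cv..., F) with a shape header."""
    axes = fes.spec.axis_arrays()
    with open(path, "w") as fh:
        fh.write(
            "# fes grid "
            + " ".join(f"{lo:.10g}:{hi:.10g}:{n}" for lo, hi, n in fes.spec.axes)
            + "\n"
        )
        if fes.spec.ndim == 1:
            for x, v in zip(axes[0], fes.values):
                fh.write(f"{x:.10g} {v:.10g}\n")
        else:
            for i, x in enumerate(axes[0]):
                for j, y in enumerate(axes[1]):
                    fh.write(f"{x:.10g} {y:.10g} {fes.values[i, j]:.10g}\n")


def read_fes(path) -> FESGrid:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# fes grid"):
            raise ValueError(f"{path}: missing FES grid header")
        axes = tuple(
            (float(a), float(b), int(c))
            for a, b, c in (tok.split(":") for tok in header.split()[3:])
        )
        spec = GridSpec(axes)
        vals = np.loadtxt(fh, usecols=spec.ndim)
    return FESGrid(spec=spec, values=vals.reshape(spec.shape))
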