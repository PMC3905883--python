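"""Metadynamics on toy potentials: hill deposition and Langevin sampling.

The sampler integrates Langevin dynamics directly in CV space (BAOAB
splitting, reflecting walls at the domain edges) on a toy potential
plus the accumulated history-dependent bias

    V(x, t) = sum_k h_k exp( -sum_d (x_d - c_kd)^2 / (2 s_kd^2) ),

depositing one Gaussian hill at the current CV position at a fixed
pace.  In standard mode every hill has the initial height w0; in the
well-tempered variant the height decays with the bias already present
at the deposition point, w = w0 exp(-V / (kB (gamma-1) T)).

For speed the engine tabulates the force (toy gradient + bias
gradient) on an internal grid and interpolates it (bi)linearly per
step; hills are added to the tables on a +-6 sigma patch.  The exact
Gaussian summation is used everywhere outside the integrator
(:func:`bias_value`, FES reconstruction).

Hills persist as PLUMED-style whitespace text, one hill per line:
time, centers, widths, height, bias factor.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import ToyPotential

__all__ = [
    "KB",
    "Hill",
    "MetaParams",
    "bias_value",
    "bias_gradient",
    "next_hill_height",
    "run_metadynamics",
    "write_hills",
    "read_hills",
    "deposition_period_ps",
    "hills_to_time_ns",
]

KB = 0.008314463  # kJ/(mol K)

log = logging.getLogger("metafes.engine")


@dataclass(frozen=True)
class Hill:
    """One deposited Gaussian bias term."""

    time: float  # ps
    center: tuple[float, ...]
    width: tuple[float, ...]  # sigma per CV
    height: float  # kJ/mol

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.width):
            raise ValueError("hill widths must be positive")
        if self.height <= 0:
            raise ValueError("hill height must be positive")
        if len(self.center) != len(self.width):
            raise ValueError("center and width dimensionality differ")


@dataclass
class MetaParams:
    """Metadynamics protocol parameters."""

    height: float = 1.0  # initial hill height w0, kJ/mol
    widths: tuple[float, ...] = (0.05, 50.0)  # sigma per CV
    pace: float = 0.5  # ps between depositions
    mode: str = "standard"  # standard | well_tempered
    bias_factor: float = 10.0  # gamma, well-tempered only
    temperature: float = 300.0  # K

    def __post_init__(self) -> None:
        if self.pace <= 0:
            raise ValueError("pace must be positive")
        if self.height < 0:
            raise ValueError("hill height must be >= 0 (0 disables deposition)")
        if any(w <= 0 for w in self.widths):
            raise ValueError("hill widths must be positive")
        if self.mode not in ("standard", "well_tempered"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "well_tempered" and self.bias_factor <= 1:
            raise ValueError("well-tempered bias factor must be > 1")


def _hill_arrays(hills: list[Hill]):
    centers = np.array([h.center for h in hills], dtype=float)
    widths = np.array([h.width for h in hills], dtype=float)
    heights = np.array([h.height for h in hills], dtype=float)
    return centers, widths, heights


def bias_value(hills: list[Hill], x) -> np.ndarray | float:
    """Exact bias sum at point(s) ``x`` of shape (..., ndim), kJ/mol."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 1
    if not hills:
        return 0.0 if scalar else np.zeros(x.shape[:-1])
    c, s, h = _hill_arrays(hills)
    arg = ((x[..., None, :] - c) ** 2 / (2.0 * s**2)).sum(axis=-1)
    v = (h * np.exp(-arg)).sum(axis=-1)
    return float(v) if scalar else v


def bias_gradient(hills: list[Hill], x) -> np.ndarray:
    """Analytic gradient of the bias at point(s) ``x``."""
    x = np.asarray(x, dtype=float)
    if not hills:
        return np.zeros_like(x)
    c, s, h = _hill_arrays(hills)
    diff = x[..., None, :] - c  # (..., K, D)
    arg = (diff**2 / (2.0 * s**2)).sum(axis=-1)
    g = (h * np.exp(-arg))[..., None] * (-diff / s**2)
    return g.sum(axis=-2)


def next_hill_height(params: MetaParams, v_current: float) -> float:
    """Height of the next hill given the bias already present locally."""
    if v_current < 0:
        raise ValueError("accumulated bias cannot be negative")
    if params.mode == "standard":
        return params.height
    denom = KB * (params.bias_factor - 1.0) * params.temperature
    return params.height * math.exp(-v_current / denom)


# --- hill-count / wall-time bookkeeping ---------------------------------


def deposition_period_ps(frames_per_hill: int, timestep_fs: float) -> float:
    """Time between hill depositions, ps (e.g. 250 frames x 2.0 fs = 0.5 ps)."""
    return frames_per_hill * timestep_fs * 1e-3


def hills_to_time_ns(n_hills: int, pace_ps: float) -> float:
    """Simulated time represented by ``n_hills`` at the given pace, ns."""
    return n_hills * pace_ps * 1e-3


# --- the Langevin/metadynamics driver -----------------------------------


@dataclass
class RunResult:
    colvar: pd.DataFrame  # time + one column per CV
    hills: list[Hill]


_DEFAULT_GRID = {1: (2001,), 2: (400, 200)}


def run_metadynamics(
    potential: ToyPotential,
    params: MetaParams,
    dt: float,
    friction: float = 1.0,
    temperature: float | None = None,
    n_steps: int = 0,
    seed: int = 0,
    masses: tuple[float, ...] | None = None,
    x0: tuple[float, ...] | None = None,
    colvar_stride: int | None = None,
    grid_points: tuple[int, ...] | None = None,
    cv_names: tuple[str, ...] | None = None,
) -> RunResult:
    """Run biased (or, with height 0, plain) Langevin dynamics on a toy potential.

    One hill is deposited at the current CV point every ``params.pace``
    ps (which must be an integer multiple of ``dt``); the number of
    deposited hills is floor(n_steps * dt / pace).  The run is bitwise
    reproducible for a fixed seed.
    """
    ndim = potential.ndim
    if ndim not in (1, 2):
        raise ValueError("only 1-D and 2-D toy potentials are supported")
    if dt <= 0:
        raise ValueError("dt must be positive")
    pace_steps = int(round(params.pace / dt))
    if pace_steps < 1 or abs(pace_steps * dt - params.pace) > 1e-9:
        raise ValueError(
            f"pace {params.pace} ps is not an integer multiple of dt {dt} ps"
        )
    temperature = params.temperature if temperature is None else temperature
    kT = KB * temperature
    m = np.ones(ndim) if masses is None else np.asarray(masses, dtype=float)
    widths = tuple(params.widths[:ndim])
    if len(widths) != ndim:
        raise ValueError("one hill width per CV required")
    if colvar_stride is None:
        colvar_stride = pace_steps

    pts = grid_points or _DEFAULT_GRID[ndim]
    axes = [
        np.linspace(lo, hi, n) for (lo, hi), n in zip(potential.domain, pts)
    ]
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    e_grid = potential.energy(mesh)
    if not np.all(np.isfinite(e_grid)):
        raise RuntimeError("NaN/inf energy on the potential grid; aborting")
    g_grid = potential.gradient(mesh)  # (..., D)
    force = [-(g_grid[..., d]) for d in range(ndim)]
    vbias = np.zeros(e_grid.shape)

    rng = np.random.default_rng(seed)
    # BAOAB coefficients
    c1 = math.exp(-friction * dt)
    c2 = [math.sqrt(kT * (1.0 - c1 * c1) / m[d]) for d in range(ndim)]
    half = [0.5 * dt / m[d] for d in range(ndim)]

    if x0 is None:
        flat = int(np.argmin(e_grid))
        idx = np.unravel_index(flat, e_grid.shape)
        x0 = tuple(float(axes[d][idx[d]]) for d in range(ndim))
    lo = [float(a[0]) for a in axes]
    hi = [float(a[-1]) for a in axes]
    inv_dx = [(len(axes[d]) - 1) / (hi[d] - lo[d]) for d in range(ndim)]

    hills: list[Hill] = []
    rec_t: list[float] = []
    rec_x: list[tuple[float, ...]] = []
    noise = rng.standard_normal((n_steps, ndim))

    if ndim == 1:
        _run_1d(
            x0, n_steps, dt, c1, c2, half, lo, hi, inv_dx, axes, force, vbias,
            params, widths, pace_steps, colvar_stride, noise, hills,
            rec_t, rec_x,
        )
    else:
        _run_2d(
            x0, n_steps, dt, c1, c2, half, lo, hi, inv_dx, axes, force, vbias,
            params, widths, pace_steps, colvar_stride, noise, hills,
            rec_t, rec_x,
        )

    if cv_names is None:
        cv_names = ("cv1",) if ndim == 1 else ("dist", "cn")
    data = {"time": rec_t}
    for d, nm_ in enumerate(cv_names):
        data[nm_] = [x[d] for x in rec_x]
    return RunResult(colvar=pd.DataFrame(data), hills=hills)


def _patch_1d(ax, c, sig):
    lo_i = int(np.searchsorted(ax, c - 6.0 * sig))
    hi_i = int(np.searchsorted(ax, c + 6.0 * sig)) + 1
    lo_i = max(lo_i - 1, 0)
    hi_i = min(hi_i, len(ax))
    return lo_i, hi_i


def _run_1d(x0, n_steps, dt, c1, c2, half, lo, hi, inv_dx, axes, force, vbias,
            params, widths, pace_steps, colvar_stride, noise, hills,
            rec_t, rec_x):
    ax = axes[0]
    n0 = len(ax)
    f_list = force[0].tolist()
    lo0, hi0, inv0 = lo[0], hi[0], inv_dx[0]
    h0, c2_0, cc1 = half[0], c2[0], c1
    sig = widths[0]
    x = float(x0[0])
    v = 0.0

    def f_at(xx):
        t = (xx - lo0) * inv0
        i = int(t)
        if i < 0:
            i = 0
        elif i > n0 - 2:
            i = n0 - 2
        fr = t - i
        return f_list[i] * (1.0 - fr) + f_list[i + 1] * fr

    fx = f_at(x)
    nz = noise[:, 0].tolist()
    for s in range(1, n_steps + 1):
        v += h0 * fx
        x += 0.5 * dt * v
        if x < lo0:
            x = 2.0 * lo0 - x
            v = -v
        elif x > hi0:
            x = 2.0 * hi0 - x
            v = -v
        v = cc1 * v + c2_0 * nz[s - 1]
        x += 0.5 * dt * v
        if x < lo0:
            x = 2.0 * lo0 - x
            v = -v
        elif x > hi0:
            x = 2.0 * hi0 - x
            v = -v
        fx = f_at(x)
        v += h0 * fx
        if params.height > 0.0 and s % pace_steps == 0:
            t = (x - lo0) * inv0
            i = min(max(int(t), 0), n0 - 2)
            fr = t - i
            vcur = vbias[i] * (1.0 - fr) + vbias[i + 1] * fr
            hgt = next_hill_height(params, max(vcur, 0.0))
            hills.append(Hill(time=s * dt, center=(x,), width=(sig,), height=hgt))
            if len(hills) % 1000 == 0:
                log.info("deposited %d hills (t = %.1f ps)", len(hills), s * dt)
            a, b = _patch_1d(ax, x, sig)
            g = hgt * np.exp(-((ax[a:b] - x) ** 2) / (2.0 * sig * sig))
            vbias[a:b] += g
            df = g * (ax[a:b] - x) / (sig * sig)  # force contribution = -dV/dx
            seg = force[0][a:b] + df
            force[0][a:b] = seg
            f_list[a:b] = seg.tolist()
            fx = f_at(x)
            if not math.isfinite(vbias[i]):
                raise RuntimeError(f"NaN bias at step {s}; aborting")
        if s % colvar_stride == 0:
            rec_t.append(s * dt)
            rec_x.append((x,))


def _run_2d(x0, n_steps, dt, c1, c2, half, lo, hi, inv_dx, axes, force, vbias,
            params, widths, pace_steps, colvar_stride, noise, hills,
            rec_t, rec_x):
    ax0, ax1 = axes
    n0, n1 = len(ax0), len(ax1)
    f0 = force[0].ravel().tolist()
    f1 = force[1].ravel().tolist()
    lo0, hi0, inv0 = lo[0], hi[0], inv_dx[0]
    lo1, hi1, inv1 = lo[1], hi[1], inv_dx[1]
    h0, h1 = half
    c20, c21 = c2
    cc1 = c1
    s0, s1 = widths
    x = float(x0[0])
    y = float(x0[1])
    vx = vy = 0.0
    n0m2, n1m2 = n0 - 2, n1 - 2

    def forces_at(xx, yy):
        t0 = (xx - lo0) * inv0
        i = int(t0)
        if i < 0:
            i = 0
        elif i > n0m2:
            i = n0m2
        fr0 = t0 - i
        t1 = (yy - lo1) * inv1
        j = int(t1)
        if j < 0:
            j = 0
        elif j > n1m2:
            j = n1m2
        fr1 = t1 - j
        base = i * n1 + j
        w00 = (1.0 - fr0) * (1.0 - fr1)
        w10 = fr0 * (1.0 - fr1)
        w01 = (1.0 - fr0) * fr1
        w11 = fr0 * fr1
        fa = (f0[base] * w00 + f0[base + n1] * w10
              + f0[base + 1] * w01 + f0[base + n1 + 1] * w11)
        fb = (f1[base] * w00 + f1[base + n1] * w10
              + f1[base + 1] * w01 + f1[base + n1 + 1] * w11)
        return fa, fb

    fxv, fyv = forces_at(x, y)
    for s in range(1, n_steps + 1):
        vx += h0 * fxv
        vy += h1 * fyv
        x += 0.5 * dt * vx
        y += 0.5 * dt * vy
        if x < lo0:
            x = 2.0 * lo0 - x
            vx = -vx
        elif x > hi0:
            x = 2.0 * hi0 - x
            vx = -vx
        if y < lo1:
            y = 2.0 * lo1 - y
            vy = -vy
        elif y > hi1:
            y = 2.0 * hi1 - y
            vy = -vy
        nzx, nzy = noise[s - 1]
        vx = cc1 * vx + c20 * nzx
        vy = cc1 * vy + c21 * nzy
        x += 0.5 * dt * vx
        y += 0.5 * dt * vy
        if x < lo0:
            x = 2.0 * lo0 - x
            vx = -vx
        elif x > hi0:
            x = 2.0 * hi0 - x
            vx = -vx
        if y < lo1:
            y = 2.0 * lo1 - y
            vy = -vy
        elif y > hi1:
            y = 2.0 * hi1 - y
            vy = -vy
        fxv, fyv = forces_at(x, y)
        vx += h0 * fxv
        vy += h1 * fyv
        if params.height > 0.0 and s % pace_steps == 0:
            i = min(max(int((x - lo0) * inv0), 0), n0 - 1)
            j = min(max(int((y - lo1) * inv1), 0), n1 - 1)
            vcur = float(vbias[i, j])
            hgt = next_hill_height(params, max(vcur, 0.0))
            hills.append(
                Hill(time=s * dt, center=(x, y), width=(s0, s1), height=hgt)
            )
            if len(hills) % 1000 == 0:
                log.info("deposited %d hills (t = %.1f ps)", len(hills), s * dt)
            a0, b0 = _patch_1d(ax0, x, s0)
            a1, b1 = _patch_1d(ax1, y, s1)
            gx = np.exp(-((ax0[a0:b0] - x) ** 2) / (2.0 * s0 * s0))
            gy = np.exp(-((ax1[a1:b1] - y) ** 2) / (2.0 * s1 * s1))
            patch = hgt * np.outer(gx, gy)
            vbias[a0:b0, a1:b1] += patch
            force[0][a0:b0, a1:b1] += patch * ((ax0[a0:b0] - x) / (s0 * s0))[:, None]
            force[1][a0:b0, a1:b1] += patch * ((ax1[a1:b1] - y) / (s1 * s1))[None, :]
            for i2 in range(a0, b0):
                row0 = force[0][i2, a1:b1].tolist()
                row1 = force[1][i2, a1:b1].tolist()
                f0[i2 * n1 + a1 : i2 * n1 + b1] = row0
                f1[i2 * n1 + a1 : i2 * n1 + b1] = row1
            fxv, fyv = forces_at(x, y)
            if not math.isfinite(vcur):
                raise RuntimeError(f"NaN bias at step {s}; aborting")
        if s % colvar_stride == 0:
            rec_t.append(s * dt)
            rec_x.append((x, y))


# --- HILLS persistence ---------------------------------------------------


def write_hills(hills: list[Hill], path, bias_factor: float = 1.0) -> None:
    """PLUMED-style HILLS text: time, centers, widths, height, biasf."""
    ndim = len(hills[0].center) if hills else 2
    cols = (
        ["time"]
        + [f"cv{d+1}" for d in range(ndim)]
        + [f"sigma_cv{d+1}" for d in range(ndim)]
        + ["height", "biasf"]
    )
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(cols) + "\n")
        for h in hills:
            vals = [h.time, *h.center, *h.width, h.height, bias_factor]
            fh.write(" ".join(f"{v:.10g}" for v in vals) + "\n")


def read_hills(path) -> list[Hill]:
    hills: list[Hill] = []
    prev_t = -math.inf
    warned = False
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                vals = [float(v) for v in line.split()]
            except ValueError as e:
                raise ValueError(f"{path}: malformed HILLS line {ln}: {line!r}") from e
            n = len(vals)
            if n >= 5 and (n - 3) % 2 == 0:
                ndim = (n - 3) // 2  # with biasf column
                height = vals[-2]
            elif n >= 4 and (n - 2) % 2 == 0:
                ndim = (n - 2) // 2
                height = vals[-1]
            else:
                raise ValueError(f"{path}: malformed HILLS line {ln}: {line!r}")
            t = vals[0]
            if t < prev_t and not warned:
                warnings.warn(f"{path}: non-monotonic hill times at line {ln}")
                warned = True
            prev_t = t
            hills.append(
                Hill(
                    time=t,
                    center=tuple(vals[1 : 1 + ndim]),
                    width=tuple(vals[1 + ndim : 1 + 2 * ndim]),
                    height=height,
                )
            )
    return hills
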