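"""Landscape analysis: minima, basins, frame states, minimum-energy paths."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from metafes.fes import FESGrid, GridSpec
from metafes.landscape import (
    assign_frames,
    basin_assign,
    find_minima,
    minimum_energy_path,
    profile_along_path,
    prominences,
)


def grid_of(values, lo=(0.0, 0.0), hi=(1.0, 1.0)):
    values = np.asarray(values, dtype=float)
    spec = GridSpec(
        tuple((lo[d], hi[d], values.shape[d]) for d in range(values.ndim))
    )
    return FESGrid(spec=spec, values=values - values.min())


def smooth_random_grid(rng, shape):
    """Random surface smoothed enough to have a handful of minima."""
    raw = rng.normal(size=shape)
    return ndimage.gaussian_filter(raw, sigma=1.2, mode="nearest")


def steepest_descent_oracle(values):
    """Recursive steepest descent to a local minimum at every node."""
    shape = values.shape
    offs = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
            if (di, dj) != (0, 0)]

    def step(node):
        i, j = node
        best = None
        for di, dj in offs:
            i2, j2 = i + di, j + dj
            if 0 <= i2 < shape[0] and 0 <= j2 < shape[1]:
                v = values[i2, j2]
                if v < values[i, j] and (
                    best is None
                    or v < values[best]
                    or (v == values[best] and (i2 * shape[1] + j2)
                        < (best[0] * shape[1] + best[1]))
                ):
                    best = (i2, j2)
        return best

    labels = np.empty(shape, dtype=object)
    def terminal(node):
        nxt = step(node)
        return node if nxt is None else terminal(nxt)

    for i in range(shape[0]):
        for j in range(shape[1]):
            labels[i, j] = terminal((i, j))
    return labels


def minimax_saddle_oracle(values, a, b):
    """Exhaustive minimax: lowest level at which a and b are 8-connected."""
    levels = np.unique(values)
    lo, hi = 0, len(levels) - 1
    while lo < hi:
        mid = (lo + hi) // 2
        mask = values <= levels[mid]
        lab, _ = ndimage.label(mask, structure=np.ones((3, 3)))
        if lab[a] == lab[b] and lab[a] > 0:
            hi = mid
        else:
            lo = mid + 1
    return levels[lo]


class TestFindMinima:
    def test_double_well_grid_has_two(self):
        x = np.linspace(-1.5, 1.5, 41)
        y = np.linspace(-1.0, 1.0, 31)
        X, Y = np.meshgrid(x, y, indexing="ij")
        V = (X**2 - 1) ** 2 + 0.5 * Y**2
        f = grid_of(V)
        assert len(find_minima(f)) == 2

    def test_monotone_plane_has_corner_minimum(self):
        X, Y = np.meshgrid(np.arange(10.0), np.arange(12.0), indexing="ij")
        f = grid_of(X + Y)
        minima = find_minima(f)
        assert len(minima) == 1
        assert minima[0].node == (0, 0)

    def test_negative_single_hill_matches_neighborhood_oracle(self, rng):
        x = np.linspace(-1, 1, 25)
        X, Y = np.meshgrid(x, x, indexing="ij")
        V = -np.exp(-(X**2 + Y**2) / 0.08)
        f = grid_of(V)
        got = {m.node for m in find_minima(f)}
        expect = set()
        for i in range(25):
            for j in range(25):
                nb = [
                    V[i2, j2]
                    for i2 in range(max(i - 1, 0), min(i + 2, 25))
                    for j2 in range(max(j - 1, 0), min(j + 2, 25))
                    if (i2, j2) != (i, j)
                ]
                if all(V[i, j] < v for v in nb):
                    expect.add((i, j))
        assert got == expect

    def test_flat_grid_warns_and_returns_empty(self):
        f = grid_of(np.zeros((5, 5)))
        with pytest.warns(UserWarning):
            assert find_minima(f) == []

    def test_sorted_by_energy(self, rng):
        f = grid_of(smooth_random_grid(rng, (20, 20)))
        minima = find_minima(f)
        energies = [m.energy for m in minima]
        assert energies == sorted(energies)


class TestBasinAssign:
    def test_single_bowl_all_assigned(self):
        x = np.linspace(-1, 1, 21)
        X, Y = np.meshgrid(x, x, indexing="ij")
        f = grid_of(X**2 + Y**2)
        basins = basin_assign(f)
        assert np.all(basins.basin_index == 0)

    def test_double_well_partitions_grid(self):
        x = np.linspace(-1.5, 1.5, 31)
        y = np.linspace(-1.0, 1.0, 21)
        X, Y = np.meshgrid(x, y, indexing="ij")
        f = grid_of((X**2 - 1) ** 2 + 0.5 * Y**2)
        basins = basin_assign(f)
        pops = basins.populations()
        assert sum(pops.values()) == 31 * 21
        assert len(pops) == 2

    def test_matches_recursive_oracle_on_random_grids(self, rng):
        for _ in range(10):
            v = smooth_random_grid(rng, (12, 12))
            f = grid_of(v)
            minima = find_minima(f)
            basins = basin_assign(f, minima)
            oracle = steepest_descent_oracle(f.values)
            node_of = {i: m.node for i, m in enumerate(minima)}
            for i in range(12):
                for j in range(12):
                    bi = basins.basin_index[i, j]
                    assert node_of[bi] == oracle[i, j]

    def test_idempotent_partition(self, rng):
        f = grid_of(smooth_random_grid(rng, (15, 15)))
        b1 = basin_assign(f)
        b2 = basin_assign(f)
        assert np.array_equal(b1.basin_index, b2.basin_index)
        assert np.all(b1.basin_index >= 0)


class TestAssignFrames:
    def setup_fes(self):
        x = np.linspace(-1.5, 1.5, 61)
        y = np.linspace(-1.0, 1.0, 41)
        X, Y = np.meshgrid(x, y, indexing="ij")
        V = 30 * (X**2 - 1) ** 2 + 15 * Y**2
        f = grid_of(V, lo=(-1.5, -1.0), hi=(1.5, 1.0))
        return f, basin_assign(f)

    def test_frame_at_minimum_assigned(self):
        f, basins = self.setup_fes()
        colvar = pd.DataFrame({"time": [0.5], "dist": [-1.0], "cn": [0.0]})
        st = assign_frames(colvar, f, basins)
        assert st.labels[0] is not None
        assert st.delta_f[0] == pytest.approx(0.0, abs=1e-9)

    def test_high_energy_frame_unassigned(self):
        f, basins = self.setup_fes()
        # at x=0, y=0 the FES is 30 kJ/mol above both minima
        colvar = pd.DataFrame({"time": [0.5], "dist": [0.0], "cn": [0.0]})
        st = assign_frames(colvar, f, basins, cutoff=20.0)
        assert st.labels[0] is None

    def test_outside_grid_unassigned_with_warning(self):
        f, basins = self.setup_fes()
        colvar = pd.DataFrame({"time": [0.5], "dist": [9.0], "cn": [0.0]})
        with pytest.warns(UserWarning, match="outside"):
            st = assign_frames(colvar, f, basins)
        assert st.labels[0] is None

    def test_ground_truth_recovery_around_minima(self, rng):
        f, basins = self.setup_fes()
        n = 200
        which = rng.integers(0, 2, n)
        xs = np.where(which == 0, -1.0, 1.0) + rng.normal(0, 0.05, n)
        ys = rng.normal(0, 0.05, n)
        colvar = pd.DataFrame({"time": np.arange(n) * 0.5, "dist": xs, "cn": ys})
        st = assign_frames(colvar, f, basins)
        lab_by_side = {0: None, 1: None}
        for m in basins.minima:
            lab_by_side[0 if m.coords[0] < 0 else 1] = m.label
        correct = sum(
            st.labels[k] == lab_by_side[int(which[k])] for k in range(n)
        )
        assert correct >= 0.95 * n

    def test_invalid_cutoff_rejected(self):
        f, basins = self.setup_fes()
        colvar = pd.DataFrame({"time": [0.5], "dist": [0.0], "cn": [0.0]})
        with pytest.raises(ValueError):
            assign_frames(colvar, f, basins, cutoff=-1.0)


class TestMinimumEnergyPath:
    def test_same_label_gives_single_node(self):
        x = np.linspace(-1, 1, 21)
        X, Y = np.meshgrid(x, x, indexing="ij")
        f = grid_of(X**2 + Y**2)
        basins = basin_assign(f)
        lab = basins.minima[0].label
        mep = minimum_energy_path(f, basins, lab, lab)
        assert len(mep.nodes) == 1
        assert mep.activation_energy == 0.0

    def test_analytic_double_well_barrier(self):
        x = np.linspace(-1.5, 1.5, 201)
        y = np.linspace(-1.0, 1.0, 121)
        X, Y = np.meshgrid(x, y, indexing="ij")
        V = 20.0 * (X**2 - 1) ** 2 + 10.0 * Y**2
        f = grid_of(V, lo=(-1.5, -1.0), hi=(1.5, 1.0))
        basins = basin_assign(f)
        m0, m1 = basins.minima[0].label, basins.minima[1].label
        mep = minimum_energy_path(f, basins, m0, m1)
        assert mep.activation_energy == pytest.approx(20.0, abs=0.5)

    def test_saddle_matches_exhaustive_minimax_oracle(self, rng):
        for _ in range(8):
            v = smooth_random_grid(rng, (15, 15))
            f = grid_of(v)
            minima = find_minima(f)
            if len(minima) < 2:
                continue
            basins = basin_assign(f, minima)
            mep = minimum_energy_path(f, basins, minima[0].label, minima[1].label)
            oracle = minimax_saddle_oracle(
                f.values, minima[0].node, minima[1].node
            )
            assert mep.saddle_energy == pytest.approx(oracle, abs=1e-12)

    def test_forward_backward_saddle_shared(self, rng):
        v = smooth_random_grid(rng, (18, 18))
        f = grid_of(v)
        minima = find_minima(f)
        if len(minima) < 2:
            pytest.skip("degenerate random grid")
        basins = basin_assign(f, minima)
        a, b = minima[0].label, minima[1].label
        fwd = minimum_energy_path(f, basins, a, b)
        bwd = minimum_energy_path(f, basins, b, a)
        assert fwd.activation_energy >= 0
        assert fwd.saddle_energy == pytest.approx(bwd.saddle_energy, abs=1e-12)
        diff = fwd.activation_energy - bwd.activation_energy
        assert diff == pytest.approx(
            minima_energy(basins, b) - minima_energy(basins, a), abs=1e-12
        )


def minima_energy(basins, label):
    return next(m.energy for m in basins.minima if m.label == label)


class TestProfile:
    def test_collinear_equal_spacing(self):
        from metafes.landscape import MEPProfile

        prof = MEPProfile(
            nodes=[(0, 0), (1, 0), (2, 0)],
            coords=np.array([[0.0, 0], [0.1, 0], [0.2, 0]]),
            energy=np.array([0.0, 1.0, 0.5]),
            s=np.array([0.0, 0.5, 1.0]),
            saddle_index=1,
            from_label="M0",
            to_label="M1",
        )
        table = profile_along_path(prof)
        np.testing.assert_allclose(table["s"], [0.0, 0.5, 1.0])
        assert table["F"].max() == prof.saddle_energy

    def test_profile_starts_at_zero_for_global_minimum(self):
        x = np.linspace(-1.5, 1.5, 61)
        y = np.linspace(-1.0, 1.0, 41)
        X, Y = np.meshgrid(x, y, indexing="ij")
        V = 30 * (X**2 - 1) ** 2 + 15 * Y**2 + 2 * X  # tilt: unique global min
        f = grid_of(V, lo=(-1.5, -1.0), hi=(1.5, 1.0))
        basins = basin_assign(f)
        mep = minimum_energy_path(
            f, basins, basins.minima[0].label, basins.minima[1].label
        )
        table = profile_along_path(mep)
        assert table["F"].iloc[0] == pytest.approx(0.0)
        assert table["s"].is_monotonic_increasing


class TestProminences:
    def test_double_well_prominence_is_barrier(self):
        x = np.linspace(-1.5, 1.5, 201)
        y = np.linspace(-1.0, 1.0, 81)
        X, Y = np.meshgrid(x, y, indexing="ij")
        V = 20.0 * (X**2 - 1) ** 2 + 10.0 * Y**2 + 3.0 * X
        f = grid_of(V, lo=(-1.5, -1.0), hi=(1.5, 1.0))
        basins = basin_assign(f)
        prom = prominences(f, basins)
        glob = basins.minima[0].label  # lowest energy
        assert prom[glob] == np.inf
        other = basins.minima[1]
        mep = minimum_energy_path(f, basins, other.label, glob)
        assert prom[other.label] == pytest.approx(
            mep.saddle_energy - other.energy, abs=1e-9
        )

    def test_matches_mep_oracle_on_random_grids(self, rng):
        for _ in range(5):
            v = smooth_random_grid(rng, (14, 14))
            f = grid_of(v)
            minima = find_minima(f)
            basins = basin_assign(f, minima)
            prom = prominences(f, basins)
            for m in minima:
                lower = [o for o in minima if o.energy < m.energy]
                if not lower:
                    assert prom[m.label] == np.inf
                    continue
                best = min(
                    minimum_energy_path(f, basins, m.label, o.label).saddle_energy
                    for o in lower
                )
                assert prom[m.label] == pytest.approx(best - m.energy, abs=1e-12)
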