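"""Empirical ST variography against a brute-force pair-enumeration oracle."""

import numpy as np
import pytest

import stcokriging as sk
from tests.conftest import random_dataset


def brute_force_bins(points_u, points_v, grid):
    """O(n^2) oracle: loop over all unordered fully co-located pairs.

    ``points_u``/``points_v`` are parallel lists of (x, y, t, value); the
    auto case passes the same list twice. Returns {(s_bin, h_T): (gamma, n)}.
    """
    edges = list(grid.spatial_edges)
    out = {}
    n = len(points_u)
    for i in range(n):
        for j in range(i + 1, n):
            xi, yi, ti, ui = points_u[i]
            xj, yj, tj, uj = points_u[j]
            vi, vj = points_v[i][3], points_v[j][3]
            d = ((xi - xj) ** 2 + (yi - yj) ** 2) ** 0.5
            dt = abs(ti - tj)
            sbin = None
            for k in range(len(edges) - 1):
                if edges[k] <= d < edges[k + 1]:
                    sbin = k
                    break
            if sbin is None:
                continue
            for ht in grid.temporal_lags:
                if abs(dt - ht) <= grid.temporal_tol:
                    acc, cnt = out.get((sbin, ht), (0.0, 0))
                    out[(sbin, ht)] = (acc + (ui - uj) * (vi - vj), cnt + 1)
    return {k: (acc / (2 * cnt), cnt) for k, (acc, cnt) in out.items()}


class TestSemivariogram:
    def test_single_pair_hand_value(self):
        ds = sk.STDataset(
            [
                sk.STSample(sk.STPoint(0, 0, 2010), "a", 1.0, "s0"),
                sk.STSample(sk.STPoint(100, 0, 2010), "a", 3.0, "s1"),
            ]
        )
        grid = sk.LagGrid((0.0, 200.0), (0.0,), 0.25)
        ev = sk.empirical_semivariogram(ds, "a", grid)
        (b,) = ev.nonempty()
        assert b.gamma_hat == pytest.approx(2.0)  # (3-1)^2 / 2
        assert b.n_pairs == 1
        assert b.h_S_center == pytest.approx(100.0)

    def test_constant_field_zero_everywhere(self, rng):
        ds = random_dataset(rng, n=15, variables=("a",))
        const = sk.STDataset(
            [sk.STSample(s.point, "a", 4.2, s.sample_id) for s in ds.samples]
        )
        grid = sk.default_lag_grid(const)
        ev = sk.empirical_semivariogram(const, "a", grid)
        assert ev.nonempty()
        assert all(b.gamma_hat == 0.0 for b in ev.nonempty())

    def test_matches_brute_force_oracle(self, rng):
        ds = random_dataset(rng, n=30, variables=("a",))
        edges = (0.0, 150.0, 400.0, 800.0, 1500.0)
        grid = sk.LagGrid(edges, (0.0, 1.0, 2.0), 0.3)
        ev = sk.empirical_semivariogram(ds, "a", grid)
        pts = [(s.point.x, s.point.y, s.point.t, s.value) for s in ds.samples_of("a")]
        oracle = brute_force_bins(pts, pts, grid)
        got = {(b.s_bin, b.h_T): (b.gamma_hat, b.n_pairs) for b in ev.nonempty()}
        assert set(got) == set(oracle)
        for key in oracle:
            assert got[key][1] == oracle[key][1]
            assert got[key][0] == pytest.approx(oracle[key][0], abs=1e-10)

    def test_insufficient_data(self):
        ds = sk.STDataset([sk.STSample(sk.STPoint(0, 0, 0), "a", 1.0, "s")])
        with pytest.raises(sk.InsufficientDataError):
            sk.empirical_semivariogram(ds, "a", sk.LagGrid((0.0, 1.0)))

    def test_scaling_by_constant(self, rng):
        ds = random_dataset(rng, n=20, variables=("a",))
        scaled = sk.STDataset(
            [sk.STSample(s.point, "a", 3.0 * s.value, s.sample_id) for s in ds.samples]
        )
        grid = sk.default_lag_grid(ds)
        g1 = sk.empirical_semivariogram(ds, "a", grid)
        g2 = sk.empirical_semivariogram(scaled, "a", grid)
        for b1, b2 in zip(g1.nonempty(), g2.nonempty()):
            assert b2.gamma_hat == pytest.approx(9.0 * b1.gamma_hat)

    def test_pair_conservation(self, rng):
        """Every admissible pair lands in exactly one lag class."""
        ds = random_dataset(rng, n=25, variables=("a",), years=(0.0, 1.0))
        x, y, t, _ = ds.arrays("a")
        n = len(x)
        dmax = max(
            np.hypot(x[i] - x[j], y[i] - y[j])
            for i in range(n) for j in range(i + 1, n)
        )
        grid = sk.LagGrid((0.0, dmax + 1.0), (0.0, 1.0), 0.25)
        ev = sk.empirical_semivariogram(ds, "a", grid)
        assert sum(b.n_pairs for b in ev.bins) == n * (n - 1) // 2


class TestCrossSemivariogram:
    def test_hand_value_two_points(self):
        samples = []
        for i, (u, v) in enumerate([(0.0, 0.0), (2.0, 3.0)]):
            p = sk.STPoint(100.0 * i, 0.0, 2010.0)
            samples.append(sk.STSample(p, "u", u, f"u{i}"))
            samples.append(sk.STSample(p, "v", v, f"v{i}"))
        ds = sk.STDataset(samples)
        grid = sk.LagGrid((0.0, 200.0), (0.0,), 0.25)
        ev = sk.empirical_cross_semivariogram(ds, "u", "v", grid)
        (b,) = ev.nonempty()
        assert b.gamma_hat == pytest.approx(3.0)  # (2*3)/2

    def test_equal_variables_reduce_to_auto(self, rng):
        ds = random_dataset(rng, n=20, variables=("u",))
        both = sk.STDataset(
            ds.samples
            + [sk.STSample(s.point, "v", s.value, "v" + s.sample_id) for s in ds.samples]
        )
        grid = sk.default_lag_grid(both)
        auto = sk.empirical_semivariogram(both, "u", grid)
        cross = sk.empirical_cross_semivariogram(both, "u", "v", grid)
        for a, c in zip(auto.nonempty(), cross.nonempty()):
            assert c.gamma_hat == pytest.approx(a.gamma_hat, abs=1e-12)

    def test_matches_oracle_and_swap_symmetry(self, rng):
        ds = random_dataset(rng, n=30, variables=("u", "v"), missing=0.2)
        grid = sk.LagGrid((0.0, 200.0, 500.0, 1100.0), (0.0, 1.0, 2.0), 0.3)
        uv = sk.empirical_cross_semivariogram(ds, "u", "v", grid)
        vu = sk.empirical_cross_semivariogram(ds, "v", "u", grid)
        assert [(b.gamma_hat, b.n_pairs) for b in uv.bins] == [
            (b.gamma_hat, b.n_pairs) for b in vu.bins
        ]
        # oracle over fully co-located points only
        labels = ds.point_labels()
        by_var = {"u": {}, "v": {}}
        coords = {}
        for lab, s in zip(labels, ds.samples):
            by_var[s.variable][lab] = s.value
            coords[lab] = (s.point.x, s.point.y, s.point.t)
        common = sorted(set(by_var["u"]) & set(by_var["v"]))
        pu = [(*coords[k], by_var["u"][k]) for k in common]
        pv = [(*coords[k], by_var["v"][k]) for k in common]
        oracle = brute_force_bins(pu, pv, grid)
        got = {(b.s_bin, b.h_T): b.gamma_hat for b in uv.nonempty()}
        assert set(got) == set(oracle)
        for key in oracle:
            assert got[key] == pytest.approx(oracle[key][0], abs=1e-10)

    def test_cross_scaling_is_linear(self, rng):
        ds = random_dataset(rng, n=15, variables=("u", "v"))
        scaled = sk.STDataset(
            [
                sk.STSample(s.point, s.variable,
                            5.0 * s.value if s.variable == "u" else s.value,
                            s.sample_id)
                for s in ds.samples
            ]
        )
        grid = sk.default_lag_grid(ds)
        g1 = sk.empirical_cross_semivariogram(ds, "u", "v", grid)
        g2 = sk.empirical_cross_semivariogram(scaled, "u", "v", grid)
        for b1, b2 in zip(g1.nonempty(), g2.nonempty()):
            assert b2.gamma_hat == pytest.approx(5.0 * b1.gamma_hat)

    def test_insufficient_overlap(self):
        samples = [
            sk.STSample(sk.STPoint(0, 0, 0), "u", 1.0, "u0"),
            sk.STSample(sk.STPoint(10, 0, 0), "v", 2.0, "v0"),
        ]
        ds = sk.STDataset(samples)
        with pytest.raises(sk.InsufficientOverlapError):
            sk.empirical_cross_semivariogram(ds, "u", "v", sk.LagGrid((0.0, 100.0)))


class TestMarginalProfiles:
    def test_profiles_are_subselections(self, rng):
        ds = random_dataset(rng, n=25, variables=("a",))
        ev = sk.empirical_semivariogram(ds, "a", sk.default_lag_grid(ds))
        spatial, temporal = sk.marginal_profiles(ev)
        all_bins = {(b.h_S_center, b.h_T, b.gamma_hat, b.n_pairs) for b in ev.bins}
        for lag, g, n in spatial:
            assert any(b[0] == lag and b[2] == g and b[3] == n for b in all_bins)
        assert len(temporal) <= len(ev.grid.temporal_lags)

    def test_empty_margin_warns(self, rng):
        ds = random_dataset(rng, n=10, variables=("a",), years=(0.0,))
        grid = sk.LagGrid((0.0, 5000.0), (1.0, 2.0), 0.25)  # no h_T=0 class
        ev = sk.empirical_semivariogram(ds, "a", grid)
        with pytest.warns(UserWarning, match="spatial margin"):
            spatial, _ = sk.marginal_profiles(ev)
        assert spatial == []


class TestCsvRoundTrip:
    def test_export_import(self, rng, tmp_path):
        ds = random_dataset(rng, n=20, variables=("u", "v"))
        grid = sk.default_lag_grid(ds)
        evs = [
            sk.empirical_semivariogram(ds, "u", grid),
            sk.empirical_cross_semivariogram(ds, "u", "v", grid),
        ]
        path = tmp_path / "vg.csv"
        from stcokriging.variogram import read_variograms_csv, write_variograms_csv

        write_variograms_csv(evs, path)
        back = read_variograms_csv(path)
        assert {(e.var_u, e.var_v) for e in back} == {("u", "u"), ("u", "v")}
        orig = {(e.var_u, e.var_v): e for e in evs}
        for e in back:
            o = orig[(e.var_u, e.var_v)]
            got = [(b.s_bin, b.h_T, b.n_pairs) for b in e.nonempty()]
            want = [(b.s_bin, b.h_T, b.n_pairs) for b in o.nonempty()]
            assert got == want
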