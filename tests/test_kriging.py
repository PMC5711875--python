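"""Cokriging system assembly, closed forms, exactness, LOOCV arithmetic."""

import numpy as np
import pytest

import stcokriging as sk
from tests.conftest import random_dataset


def single_var_model(C0=0.0, CS=1.0, aS=500.0, CST=0.0, aST=300.0, alpha=400.0,
                     var="u"):
    return sk.ModelSet.from_models(
        [sk.BilonickModel(var, var, C0, 0.0, CS, aS, CST, aST)],
        sk.SharedAnisotropy(alpha),
    )


class TestFindNeighbors:
    def test_st_metric_ranking(self):
        ds = sk.STDataset(
            [
                sk.STSample(sk.STPoint(3.0, 0.0, 0.0), "u", 1.0, "A"),
                sk.STSample(sk.STPoint(0.0, 0.0, 2.0), "u", 2.0, "B"),
            ]
        )
        nb = sk.find_neighbors(
            ds, sk.STPoint(0, 0, 0), ["u"], 1, sk.SharedAnisotropy(4.0)
        )
        # d(A) = 3 beats d(B) = sqrt(4*4) = 4
        assert nb.samples["u"][0].sample_id == "A"

    def test_k_clamped_to_available(self, rng):
        ds = random_dataset(rng, n=5, variables=("u",))
        nb = sk.find_neighbors(
            ds, sk.STPoint(0, 0, 0), ["u"], 50, sk.SharedAnisotropy(1.0)
        )
        assert len(nb.samples["u"]) == 5

    def test_alpha_zero_is_spatial_ranking(self, rng):
        ds = random_dataset(rng, n=20, variables=("u",), years=(0.0, 5.0))
        target = sk.STPoint(500.0, 500.0, 0.0)
        nb0 = sk.find_neighbors(ds, target, ["u"], 20, sk.SharedAnisotropy(0.0))
        d_spatial = sorted(
            ds.samples_of("u"),
            key=lambda s: (np.hypot(s.point.x - 500, s.point.y - 500), s.sample_id),
        )
        assert [s.sample_id for s in nb0.samples["u"]] == [
            s.sample_id for s in d_spatial
        ]

    def test_no_primary_samples_is_error(self, rng):
        ds = random_dataset(rng, n=3, variables=("u",))
        empty_primary = sk.STDataset(ds.samples, variables=("u", "w"))
        with pytest.raises(sk.InsufficientDataError):
            sk.find_neighbors(
                empty_primary, sk.STPoint(0, 0, 0), ["w", "u"], 2,
                sk.SharedAnisotropy(1.0),
            )


class TestAssembleSystem:
    def test_single_neighbor_minimal_system(self):
        ds = sk.STDataset([sk.STSample(sk.STPoint(100.0, 0.0, 0.0), "u", 7.0, "s")])
        ms = single_var_model()
        nb = sk.find_neighbors(ds, sk.STPoint(0, 0, 0), ["u"], 1, ms.anisotropy)
        sys = sk.assemble_system(nb, ms, "u")
        assert sys.lhs.shape == (2, 2)
        assert sys.lhs[0, 0] == 0.0 and sys.lhs[0, 1] == 1.0 and sys.lhs[1, 0] == 1.0
        assert sys.rhs[0] == pytest.approx(float(ms.gamma("u", "u", 100.0, 0.0)))
        assert sys.rhs[1] == 1.0

    def test_dimension_two_variables(self, rng, simple_model_set):
        ds = random_dataset(rng, n=10, variables=("u", "v"))
        nb = sk.find_neighbors(
            ds, sk.STPoint(500, 500, 1.0), ["u", "v"], 2, simple_model_set.anisotropy
        )
        sys = sk.assemble_system(nb, simple_model_set, "u")
        assert sys.lhs.shape == (6, 6)  # 2 + 2 samples + 2 constraints

    def test_lhs_symmetry_random_configurations(self, rng, simple_model_set):
        for _ in range(10):
            ds = random_dataset(rng, n=8, variables=("u", "v"), missing=0.2)
            if not ds.samples_of("u"):
                continue
            nb = sk.find_neighbors(
                ds,
                sk.STPoint(float(rng.uniform(0, 1000)), float(rng.uniform(0, 1000)), 1.0),
                ["u", "v"], 4, simple_model_set.anisotropy,
            )
            sys = sk.assemble_system(nb, simple_model_set, "u")
            assert np.allclose(sys.lhs, sys.lhs.T, atol=1e-12)


class TestSolveAndPredict:
    def test_one_neighbor_closed_form(self):
        """lambda = 1, psi = gamma(x1, x0), variance = 2 * gamma(x1, x0)."""
        ds = sk.STDataset([sk.STSample(sk.STPoint(100.0, 0.0, 0.0), "u", 7.0, "s")])
        ms = single_var_model(CS=1.0, aS=500.0)
        g10 = float(ms.gamma("u", "u", 100.0, 0.0))
        sol = sk.predict_point(ds, ms, "u", [], sk.STPoint(0, 0, 0), k=1)
        assert sol.weights["u"][0] == pytest.approx(1.0)
        assert sol.multipliers["u"] == pytest.approx(g10)
        assert sol.estimate == pytest.approx(7.0)
        assert sol.variance == pytest.approx(2.0 * g10)

    def test_symmetric_pair_equal_weights(self):
        ds = sk.STDataset(
            [
                sk.STSample(sk.STPoint(-100.0, 0.0, 0.0), "u", 2.0, "a"),
                sk.STSample(sk.STPoint(100.0, 0.0, 0.0), "u", 4.0, "b"),
            ]
        )
        sol = sk.predict_point(ds, single_var_model(), "u", [], sk.STPoint(0, 0, 0), k=2)
        assert sol.weights["u"] == pytest.approx([0.5, 0.5])
        assert sol.estimate == pytest.approx(3.0)

    def test_zero_cross_structure_reduces_to_single_variable_kriging(self, rng):
        models = [
            sk.BilonickModel("u", "u", 0.1, 0.0, 1.0, 500.0, 0.5, 300.0),
            sk.BilonickModel("v", "v", 0.1, 0.0, 1.0, 500.0, 0.5, 300.0),
            sk.BilonickModel("u", "v", 0.0, 0.0, 0.0, 500.0, 0.0, 300.0),
        ]
        ms = sk.ModelSet.from_models(models, sk.SharedAnisotropy(400.0))
        ds = random_dataset(rng, n=15, variables=("u", "v"))
        target = sk.STPoint(400.0, 600.0, 1.0)
        with_cov = sk.predict_point(ds, ms, "u", ["v"], target, k=6)
        without = sk.predict_point(ds, ms, "u", [], target, k=6)
        assert np.allclose(with_cov.weights["v"], 0.0, atol=1e-10)
        assert with_cov.estimate == pytest.approx(without.estimate, abs=1e-10)
        assert with_cov.variance == pytest.approx(without.variance, abs=1e-10)

    def test_unbiasedness_constraints_random_configurations(self, rng, simple_model_set):
        checked = 0
        while checked < 25:
            ds = random_dataset(rng, n=12, variables=("u", "v"), missing=0.25)
            if len(ds.samples_of("u")) < 2 or len(ds.samples_of("v")) < 2:
                continue
            target = sk.STPoint(
                float(rng.uniform(0, 1000)), float(rng.uniform(0, 1000)),
                float(rng.choice([0.0, 1.0, 2.0])),
            )
            sol = sk.predict_point(ds, simple_model_set, "u", ["v"], target, k=5)
            assert abs(sol.weights["u"].sum() - 1.0) < 1e-8
            assert abs(sol.weights["v"].sum()) < 1e-8
            checked += 1

    def test_duplicate_points_raise_singular(self):
        # two samples at the same location for one variable cannot coexist in
        # a dataset, but two co-located different-variable samples with a
        # cross model equal to the autos make the system singular
        models = [
            sk.BilonickModel("u", "u", 0.0, 0.0, 1.0, 500.0, 0.0, 300.0),
            sk.BilonickModel("v", "v", 0.0, 0.0, 1.0, 500.0, 0.0, 300.0),
            sk.BilonickModel("u", "v", 0.0, 0.0, 1.0, 500.0, 0.0, 300.0),
        ]
        ms = sk.ModelSet.from_models(models, sk.SharedAnisotropy(0.0))
        samples = [
            sk.STSample(sk.STPoint(100.0, 0.0, 0.0), "u", 1.0, "u0"),
            sk.STSample(sk.STPoint(100.0, 0.0, 0.0), "v", 1.0, "v0"),
            sk.STSample(sk.STPoint(0.0, 100.0, 0.0), "u", 2.0, "u1"),
            sk.STSample(sk.STPoint(0.0, 100.0, 0.0), "v", 2.0, "v1"),
        ]
        ds = sk.STDataset(samples)
        with pytest.raises(sk.SingularSystemError):
            sk.predict_point(ds, ms, "u", ["v"], sk.STPoint(50, 50, 0), k=2)


class TestPredictPoint:
    def test_exactness_at_sampled_point_zero_nugget(self, rng):
        ds = random_dataset(rng, n=12, variables=("u",))
        ms = single_var_model(C0=0.0, CS=1.0, aS=800.0)
        s0 = ds.samples_of("u")[3]
        sol = sk.predict_point(ds, ms, "u", [], s0.point, k=6)
        assert sol.estimate == pytest.approx(s0.value, abs=1e-8)
        assert sol.variance <= 1e-8

    def test_variance_decreases_with_nested_neighborhoods(self, rng):
        ds = random_dataset(rng, n=40, variables=("u",))
        ms = single_var_model(C0=0.2, CS=1.0, aS=800.0, CST=0.4, aST=400.0)
        target = sk.STPoint(500.0, 500.0, 1.0)
        variances = [
            sk.predict_point(ds, ms, "u", [], target, k=k).variance
            for k in range(2, 21)
        ]
        for a, b in zip(variances, variances[1:]):
            assert b <= a + 1e-10

    def test_empty_covariable_list_matches_primary_only(self, rng, simple_model_set):
        ds = random_dataset(rng, n=10, variables=("u", "v"))
        target = sk.STPoint(300, 300, 0.0)
        a = sk.predict_point(ds, simple_model_set, "u", [], target, k=4)
        nb = sk.find_neighbors(ds, target, ["u"], 4, simple_model_set.anisotropy)
        b = sk.solve_and_predict(
            sk.assemble_system(nb, simple_model_set, "u"), nb, "u"
        )
        assert a.estimate == b.estimate and a.variance == b.variance


class TestPredictGrid:
    def test_single_cell_reduces_to_predict_point(self, rng):
        ds = random_dataset(rng, n=10, variables=("u",))
        ms = single_var_model(C0=0.1)
        grid = sk.GridSpec(400.0, 600.0, 400.0, 600.0, 200.0, 1.0)
        df = sk.predict_grid(ds, ms, "u", [], grid, k=5)
        assert len(df) == 1
        sol = sk.predict_point(ds, ms, "u", [], sk.STPoint(500.0, 500.0, 1.0), k=5)
        assert df.estimate.iloc[0] == pytest.approx(sol.estimate)
        assert df.variance.iloc[0] == pytest.approx(sol.variance)

    def test_constant_dataset_gives_constant_surface(self, rng):
        base = random_dataset(rng, n=12, variables=("u",))
        ds = sk.STDataset(
            [sk.STSample(s.point, "u", 3.25, s.sample_id) for s in base.samples]
        )
        ms = single_var_model(C0=0.1)
        df = sk.predict_grid(ds, ms, "u", [], sk.GridSpec(0, 1000, 0, 1000, 250.0, 1.0), k=5)
        assert np.allclose(df.estimate, 3.25)

    def test_log2_back_transform_positive(self, rng):
        base = random_dataset(rng, n=12, variables=("u",))
        ds = sk.STDataset(
            [sk.STSample(s.point, "u", abs(s.value) + 0.5, s.sample_id) for s in base.samples]
        )
        ds = sk.log2_transform(ds, ["u"])
        ms = single_var_model(C0=0.1)
        df = sk.predict_grid(
            ds, ms, "u", [], sk.GridSpec(0, 1000, 0, 1000, 250.0, 1.0), k=5,
            back_transform=True,
        )
        assert (df.estimate > 0).all()


class TestLoocv:
    def test_rmse_hand_value(self):
        rep = sk.ValidationReport("u", (), 4, [(2, 2), (3, 5), (4, 3)], [0.1] * 3)
        assert rep.rmse == pytest.approx(np.sqrt(5 / 3))  # (0 + 4 + 1) / 3

    def test_zero_rmse_for_perfect_predictions(self):
        rep = sk.ValidationReport("u", (), 4, [(1.0, 1.0), (2.0, 2.0)], [0.0, 0.0])
        assert rep.rmse == 0.0

    def test_held_out_sample_is_excluded(self, rng):
        """With a zero-nugget model, leaving the sample in would give RMSE 0;
        excluding it must give a strictly positive RMSE."""
        ds = random_dataset(rng, n=15, variables=("u",))
        ms = single_var_model(C0=0.0, CS=1.0, aS=800.0)
        rep = sk.loocv(ds, ms, "u", [], k=6)
        assert rep.rmse > 1e-3
        assert len(rep.pairs) == len(ds.samples_of("u"))

    def test_covariable_helps_on_correlated_field(self):
        spec = sk.SyntheticFieldSpec(
            variables=("A", "B"),
            nugget=np.array([[0.2, 0.16], [0.16, 0.2]]),
            spatial=sk.StructureSpec(
                "spherical", 2000.0, np.array([[0.8, 0.64], [0.64, 0.8]])
            ),
            alpha=1000.0,
            design=sk.SamplingDesign((2012.0, 2013.0, 2014.0), (25,) * 3, (0, 4000, 0, 4000), 40),
            seed=5,
        )
        sim = sk.simulate(spec)
        with_cov = sk.loocv(sim.dataset, sim.truth, "A", ["B"], k=8)
        without = sk.loocv(sim.dataset, sim.truth, "A", [], k=8)
        assert with_cov.mean_variance <= without.mean_variance + 1e-10

    def test_delete_all_at_point(self, rng):
        spec = sk.SyntheticFieldSpec(
            variables=("A", "B"),
            nugget=np.array([[0.2, 0.1], [0.1, 0.2]]),
            spatial=sk.StructureSpec(
                "spherical", 2000.0, np.array([[0.8, 0.5], [0.5, 0.8]])
            ),
            design=sk.SamplingDesign((2014.0,), (20,), (0, 3000, 0, 3000), 20),
            seed=6,
        )
        sim = sk.simulate(spec)
        keep = sk.loocv(sim.dataset, sim.truth, "A", ["B"], k=6)
        drop = sk.loocv(sim.dataset, sim.truth, "A", ["B"], k=6, delete_all_at_point=True)
        # collocated secondaries are strong predictors; removing them must
        # not reduce the kriging variance
        assert drop.mean_variance >= keep.mean_variance - 1e-10
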