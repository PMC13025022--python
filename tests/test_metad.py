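"""PLUMED parsing, reweighting, FES statistics, metrics, paths."""

import math

import numpy as np
import pandas as pd
import pytest

from fresean import (
    KB,
    FreeEnergySurface,
    GeometricCV,
    HillsSeries,
    ToyPotential,
    WeightedEnsemble,
    average_fes,
    bhattacharyya,
    bias_at,
    eval_geometric_cv,
    kmeans_microstates,
    min_free_energy_path,
    read_colvar,
    read_hills,
    reweight,
    shannon_entropy,
    state_delta_f,
    toy_wt_metadynamics,
    two_state_system,
    weighted_fes,
    write_colvar,
    write_hills,
)

kT = KB * 300.0


def make_hills(centers, heights, sigma=0.1, biasf=10.0, names=("x",)):
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    H, d = centers.shape
    return HillsSeries(
        times=np.arange(1.0, H + 1),
        centers=centers,
        sigmas=np.full((H, d), sigma),
        heights=np.asarray(heights, dtype=float),
        biasf=biasf,
        cv_names=tuple(names[:d]) if len(names) >= d else tuple(f"s{i}" for i in range(d)),
    )


class TestPlumedIO:
    def test_three_record_toy_file(self, tmp_path):
        p = tmp_path / "HILLS"
        p.write_text(
            "#! FIELDS time x sigma_x height biasf\n"
            "1.0 -0.5 0.1 1.0 10.0\n"
            "2.0 0.0 0.1 0.9 10.0\n"
            "3.0 0.5 0.1 0.8 10.0\n"
        )
        hills = read_hills(p)
        assert len(hills) == 3
        assert hills[1].center[0] == 0.0
        assert hills.biasf == 10.0

    def test_round_trip_of_generated_files(self, tmp_path):
        pot = ToyPotential("double_well", {"barrier": 6.0, "a": 1.0})
        colvar, hills = toy_wt_metadynamics(
            pot, height=0.8, sigma=0.1, pace=100, bias_factor=8.0,
            seed=1, n_steps=5_000,
        )
        cp, hp = tmp_path / "COLVAR", tmp_path / "HILLS"
        write_colvar(colvar, cp)
        write_hills(hills, hp)
        colvar2, hills2 = read_colvar(cp), read_hills(hp)
        pd.testing.assert_frame_equal(colvar.data, colvar2.data)
        assert np.array_equal(hills.centers, hills2.centers)
        assert np.array_equal(hills.heights, hills2.heights)
        # writing again reproduces the byte-identical file
        hp2 = tmp_path / "HILLS2"
        write_hills(hills2, hp2)
        assert hp.read_text() == hp2.read_text()

    def test_missing_field_named_in_error(self, tmp_path):
        p = tmp_path / "COLVAR"
        p.write_text("#! FIELDS time x\n0.0 1.0\n")
        with pytest.raises(ValueError, match="metad.bias"):
            read_colvar(p, cv_names=("metad.bias",))
        q = tmp_path / "HILLS"
        q.write_text("#! FIELDS time x height biasf\n1.0 0.0 1.0 10.0\n")
        with pytest.raises(ValueError, match="sigma_x"):
            read_hills(q)

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "COLVAR"
        p.write_text("#! FIELDS time x\n0.0 1.0\n0.1 oops extra\n")
        with pytest.raises(ValueError, match=":3"):
            read_colvar(p)


class TestBias:
    def test_no_hills_zero(self):
        hills = make_hills(np.empty((0, 1)), [])
        assert bias_at(hills, [0.3]) == 0.0

    def test_single_hill_at_center(self):
        hills = make_hills([[0.5]], [2.0])
        assert bias_at(hills, [0.5]) == pytest.approx(2.0)

    def test_two_identical_hills_add(self):
        hills = make_hills([[0.5], [0.5]], [2.0, 2.0])
        assert bias_at(hills, [0.5]) == pytest.approx(4.0)
        # up_to_time cuts the second deposit
        assert bias_at(hills, [0.5], up_to_time=1.5) == pytest.approx(2.0)


class TestReweight:
    def test_zero_bias_gives_uniform_weights(self):
        df = pd.DataFrame({"time": np.arange(10.0), "x": np.linspace(-1, 1, 10)})
        from fresean import ColvarSeries

        colvar = ColvarSeries(df, ("x",))
        hills = make_hills(np.empty((0, 1)), [])
        ens = reweight(colvar, hills, 300.0, discard_fraction=0.0)
        np.testing.assert_allclose(ens.weights, 0.1)

    def test_weights_normalized(self, double_well_replicas):
        _, runs, _ = double_well_replicas
        for _, _, ens in runs:
            assert ens.weights.sum() == pytest.approx(1.0)
            assert np.all(ens.weights >= 0)

    def test_final_bias_recovers_analytic_double_well(self, double_well_replicas):
        pot, runs, surfaces = double_well_replicas
        fes = surfaces[0]
        ctr = fes.centers[0]
        ok = np.isfinite(fes.free)
        ana = pot.energy(ctr[:, None])
        ana = ana - ana[ok].min()
        wells = ok & (ana < 8.0)
        assert np.abs(fes.free[wells] - ana[wells]).max() < kT

    def test_time_dependent_scheme_agrees(self, double_well_replicas):
        pot, runs, _ = double_well_replicas
        colvar, hills, _ = runs[0]
        ens = reweight(colvar, hills, 300.0, scheme="time_dependent")
        fes = weighted_fes(ens, ("x",), bins=50, ranges=[(-1.5, 1.5)],
                           temperature=300.0)
        ctr = fes.centers[0]
        ok = np.isfinite(fes.free)
        ana = pot.energy(ctr[:, None])
        ana = ana - ana[ok].min()
        wells = ok & (ana < 8.0)
        assert np.abs(fes.free[wells] - ana[wells]).max() < kT

    def test_unknown_scheme(self, double_well_replicas):
        _, runs, _ = double_well_replicas
        colvar, hills, _ = runs[0]
        with pytest.raises(ValueError, match="scheme"):
            reweight(colvar, hills, 300.0, scheme="magic")

    def test_bias_gauge_invariance(self, double_well_replicas):
        # a constant added to the bias everywhere renormalizes away
        _, runs, _ = double_well_replicas
        colvar, hills, ens = runs[0]
        shifted = HillsSeries(
            times=np.concatenate([[0.5], hills.times]),
            centers=np.vstack([[[0.0]], hills.centers]),
            sigmas=np.vstack([[[1e6]], hills.sigmas]),  # ~constant offset
            heights=np.concatenate([[25.0], hills.heights]),
            biasf=hills.biasf,
            cv_names=hills.cv_names,
        )
        ens2 = reweight(colvar, shifted, 300.0)
        np.testing.assert_allclose(ens2.weights, ens.weights, rtol=1e-6)


class TestWeightedFes:
    def test_gaussian_sample_curvature(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(100_000, 2)) * [0.5, 0.8]
        ens = WeightedEnsemble(pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1]}),
                               np.ones(len(pts)))
        fes = weighted_fes(ens, ("x", "y"), bins=40,
                           ranges=[(-1.5, 1.5), (-2.4, 2.4)], temperature=300.0)
        # along x at y~0: F = kT x^2 / (2 * 0.25)
        iy = 20
        x = fes.centers[0]
        ok = np.isfinite(fes.free[:, iy]) & (np.abs(x) < 1.0)
        coef = np.polyfit(x[ok], fes.free[ok, iy], 2)[0]
        assert coef == pytest.approx(kT / (2 * 0.25), rel=0.1)

    def test_single_occupied_bin(self):
        ens = WeightedEnsemble(pd.DataFrame({"x": np.full(10, 0.5)}),
                               np.ones(10))
        fes = weighted_fes(ens, ("x",), bins=10, ranges=[(0, 1)],
                           temperature=300.0)
        occ = np.isfinite(fes.free)
        assert occ.sum() == 1
        assert fes.free[occ][0] == 0.0

    def test_weight_scaling_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=5_000)
        df = pd.DataFrame({"x": x})
        w = rng.random(5_000)
        f1 = weighted_fes(WeightedEnsemble(df, w), ("x",), bins=20,
                          ranges=[(-3, 3)], temperature=300.0)
        f2 = weighted_fes(WeightedEnsemble(df, 2 * w), ("x",), bins=20,
                          ranges=[(-3, 3)], temperature=300.0)
        np.testing.assert_allclose(f1.free, f2.free, equal_nan=True)

    def test_all_samples_outside_grid(self):
        ens = WeightedEnsemble(pd.DataFrame({"x": np.full(5, 10.0)}), np.ones(5))
        with pytest.raises(ValueError, match="outside"):
            weighted_fes(ens, ("x",), bins=5, ranges=[(0, 1)])


class TestAverageFes:
    def test_identical_replicas_zero_spread(self, double_well_replicas):
        _, _, surfaces = double_well_replicas
        avg = average_fes([surfaces[0]] * 4)
        ok = np.isfinite(avg.std)
        assert np.allclose(avg.std[ok], 0.0)
        assert np.allclose(avg.sem[ok], 0.0)

    def test_sem_is_std_over_sqrt_r(self, double_well_replicas):
        _, _, surfaces = double_well_replicas
        avg = average_fes(surfaces)
        ok = np.isfinite(avg.std)
        np.testing.assert_allclose(avg.sem[ok], avg.std[ok] / math.sqrt(6))

    def test_average_beats_median_single_replica(self, double_well_replicas):
        pot, _, surfaces = double_well_replicas
        avg = average_fes(surfaces)

        def rmse(fes):
            ok = np.isfinite(fes.free)
            ana = pot.energy(fes.centers[0][:, None])
            d = fes.free[ok] - (ana[ok] - ana[ok].min())
            d = d - d.mean()  # gauge-free comparison
            return float(np.sqrt((d**2).mean()))

        assert rmse(avg) < np.median([rmse(s) for s in surfaces])

    def test_grid_mismatch_rejected(self, double_well_replicas):
        _, _, surfaces = double_well_replicas
        other = FreeEnergySurface(
            names=("x",), edges=[np.linspace(-2, 2, 51)],
            prob=np.full(50, 0.02), free=np.zeros(50),
            counts=np.ones(50), temperature=300.0,
        )
        with pytest.raises(ValueError, match="grid"):
            average_fes([surfaces[0], other])


class TestInformationMetrics:
    def test_entropy_closed_forms(self):
        assert shannon_entropy(np.full(256, 1 / 256)) == pytest.approx(8.0)
        assert shannon_entropy(np.array([1.0])) == 0.0
        assert shannon_entropy(np.array([0.5, 0.5])) == pytest.approx(1.0)

    def test_entropy_rejects_unnormalized(self):
        with pytest.raises(ValueError, match="normalized"):
            shannon_entropy(np.array([0.5, 0.2]))

    def test_bhattacharyya_closed_forms(self):
        p = np.full(64, 1 / 64)
        assert bhattacharyya(p, p) == pytest.approx(1.0)
        a = np.zeros(10)
        a[:5] = 0.2
        b = np.zeros(10)
        b[5:] = 0.2
        assert bhattacharyya(a, b) == 0.0
        # unit Gaussians with means 0 and 2: BC = exp(-dmu^2/8)
        g = np.linspace(-10, 12, 4001)
        pa = np.exp(-0.5 * g**2)
        pb = np.exp(-0.5 * (g - 2) ** 2)
        val = bhattacharyya(pa / pa.sum(), pb / pb.sum())
        assert val == pytest.approx(math.exp(-0.5), abs=1e-3)

    def test_entropy_recovered_across_cv_spaces(self):
        # bias along the true transition coordinate, reweight into a
        # rotated coordinate: the entropy of that surface matches (>=85%
        # of) the entropy from biasing the rotated coordinate directly
        pot = ToyPotential("double_well",
                           {"barrier": 10.0, "a": 1.0, "k_y": 15.0}, dim=2)
        g = np.array([[2**-0.5, 2**-0.5]])
        run_u = toy_wt_metadynamics(
            pot, height=1.2, sigma=0.15, pace=250, bias_factor=10.0,
            seed=21, n_steps=200_000, cv_matrix=[[1.0, 0.0]], cv_names=("u",),
        )
        run_g = toy_wt_metadynamics(
            pot, height=1.2, sigma=0.15, pace=250, bias_factor=10.0,
            seed=22, n_steps=200_000, cv_matrix=g, cv_names=("gv",),
        )
        ens_u = reweight(*run_u, 300.0)
        ens_g = reweight(*run_g, 300.0)
        proj = ens_u.values(("x", "y")) @ g[0]
        ens_u2 = WeightedEnsemble(pd.DataFrame({"gv": proj}), ens_u.weights)
        ranges = [(-1.6, 1.6)]
        f_re = weighted_fes(ens_u2, ("gv",), bins=50, ranges=ranges,
                            temperature=300.0)
        f_direct = weighted_fes(ens_g, ("gv",), bins=50, ranges=ranges,
                                temperature=300.0)
        assert shannon_entropy(f_re) >= 0.85 * shannon_entropy(f_direct)
        assert bhattacharyya(f_re, f_direct) > 0.9


class TestStatesAndPaths:
    def _two_blob_ensemble(self, delta_kt=2.0, n=200_000, seed=0):
        rng = np.random.default_rng(seed)
        p_b = math.exp(-delta_kt) / (1 + math.exp(-delta_kt))
        in_b = rng.random(n) < p_b
        pts = np.where(in_b[:, None],
                       rng.normal([2.0, 0.0], 0.3, (n, 2)),
                       rng.normal([-2.0, 0.0], 0.3, (n, 2)))
        return WeightedEnsemble(pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1]}),
                                np.ones(n))

    def test_symmetric_regions_zero_delta_f(self):
        ens = self._two_blob_ensemble(delta_kt=0.0)
        dF = state_delta_f(ens, ("x", "y"),
                           {"kind": "rect", "bounds": [(-3.5, 0), (-2, 2)]},
                           {"kind": "rect", "bounds": [(0, 3.5), (-2, 2)]})
        assert abs(dF) < 0.15 * kT

    def test_designed_delta_f_recovered(self):
        ens = self._two_blob_ensemble(delta_kt=2.0)
        dF = state_delta_f(ens, ("x", "y"),
                           {"kind": "ellipse", "center": (-2, 0), "radii": (1.2, 1.2)},
                           {"kind": "ellipse", "center": (2, 0), "radii": (1.2, 1.2)})
        assert abs(dF - 2 * kT) < 0.3 * kT

    def test_empty_region_signaled(self):
        ens = self._two_blob_ensemble()
        dF = state_delta_f(ens, ("x", "y"),
                           {"kind": "rect", "bounds": [(-3.5, 0), (-2, 2)]},
                           {"kind": "rect", "bounds": [(90, 99), (90, 99)]})
        assert math.isinf(dF)

    def test_kmeans_microstates(self):
        ens = self._two_blob_ensemble(n=10_000)
        centers, labels, inertia = kmeans_microstates(ens, ("x", "y"), k=40,
                                                      seed=0)
        assert centers.shape == (40, 2)
        c2, _, _ = kmeans_microstates(ens, ("x", "y"), k=2, seed=0)
        assert np.abs(np.sort(c2[:, 0]) - [-2.0, 2.0]).max() < 0.03
        small = WeightedEnsemble(ens.samples.iloc[:5], np.ones(5))
        _, _, inert0 = kmeans_microstates(small, ("x", "y"), k=5, seed=0)
        assert inert0 == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_microstates(small, ("x", "y"), k=6, seed=0)

    def _valley_fes(self):
        x = np.linspace(-2, 2, 41)
        y = np.linspace(-1, 1, 21)
        X, Y = np.meshgrid(0.5 * (x[1:] + x[:-1]), 0.5 * (y[1:] + y[:-1]),
                           indexing="ij")
        F = 30.0 * Y**2
        P = np.exp(-F / kT)
        P /= P.sum()
        return FreeEnergySurface(("x", "y"), [x, y], P, F - F.min(),
                                 np.full(F.shape, 100.0), 300.0)

    def test_flat_profile_on_flat_surface(self):
        fes = self._valley_fes()
        flat = FreeEnergySurface(fes.names, fes.edges, fes.prob,
                                 np.zeros_like(fes.free), fes.counts, 300.0)
        res = min_free_energy_path(flat, (-1.95, 0.0), (1.95, 0.0))
        assert np.allclose(res["free"], 0.0)
        assert res["bins"][0] == (0, 10) and res["bins"][-1] == (39, 10)

    def test_path_follows_valley_floor(self):
        fes = self._valley_fes()
        res = min_free_energy_path(fes, (-1.9, 0.0), (1.9, 0.0))
        # never leaves the central bin row by more than one bin
        assert np.abs(res["coords"][:, 1]).max() <= 0.15
        assert res["barrier"] == pytest.approx(0.0, abs=1e-9)

    def test_unoccupied_endpoint_rejected(self):
        fes = self._valley_fes()
        fes.free[0, 10] = np.nan
        with pytest.raises(ValueError, match="occupied"):
            min_free_energy_path(fes, (-1.95, 0.0), (1.95, 0.0))


class TestGeometricCV:
    def test_distance_and_angle(self):
        pos = np.array([[0.0, 0, 0], [0, 0, 1.0], [0, 0, 2.0]])
        out = eval_geometric_cv(pos, [GeometricCV("distance", [[0], [1]]),
                                      GeometricCV("angle", [[0], [1], [2]])])
        assert out["distance"].iloc[0] == pytest.approx(1.0)
        assert out["angle"].iloc[0] == pytest.approx(180.0)

    def test_dihedral(self):
        pos = np.array([[1.0, 0, 0], [0, 0, 0], [0, 0, 1.0], [0, 1.0, 1.0]])
        out = eval_geometric_cv(pos, [GeometricCV("dihedral",
                                                  [[0], [1], [2], [3]])])
        assert abs(out["dihedral"].iloc[0]) == pytest.approx(90.0)

    def test_invalid_definition(self):
        with pytest.raises(ValueError, match="groups"):
            GeometricCV("angle", [[0], [1]])
        with pytest.raises(ValueError, match="empty"):
            GeometricCV("distance", [[0], []])

    def test_biased_sampling_doubles_geometric_range(self):
        # map a biased vs unbiased 1D series through the two-state bead
        # geometry: metadynamics at least doubles the explored range of a
        # distance between bead groups
        sys_ = two_state_system(0, barrier_kt=8.0, friction=5.0)
        pot = ToyPotential("double_well", {"barrier": sys_.barrier,
                                           "a": sys_.q0})
        biased, hills = toy_wt_metadynamics(
            pot, height=1.5, sigma=0.15, pace=250, bias_factor=15.0,
            seed=5, n_steps=100_000,
        )
        unbiased, _ = toy_wt_metadynamics(
            pot, height=0.0, sigma=0.15, pace=250, bias_factor=15.0,
            seed=6, n_steps=100_000, x0=np.array([-sys_.q0]),
        )
        sqm = np.repeat(np.sqrt(sys_.masses), 3)

        def frames(q):
            disp = (q[:, None] / sqm) * sys_.basis[0][None, :]
            return sys_.coords[None] + disp.reshape(len(q), -1, 3)

        gcv = GeometricCV("distance", [[0, 1], [3, 4]])
        db = eval_geometric_cv(frames(biased.cv_values[:, 0]), [gcv],
                               sys_.masses)["distance"]
        du = eval_geometric_cv(frames(unbiased.cv_values[:, 0]), [gcv],
                               sys_.masses)["distance"]
        assert (db.max() - db.min()) >= 2.0 * (du.max() - du.min())
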