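"""Quantile delta mapping, bilinear regridding, map prediction, ensembles."""

import numpy as np
import pytest

from anppgrid import harness, projection as proj
from anppgrid.grids import GridMeta


class Const:
    def __init__(self, c):
        self.c = c

    def predict(self, X):
        return np.full(len(X), float(self.c))


def const_model(c, names):
    return harness.FittedModel(Const(c), tuple(names), harness.LearnerSpec("linear"))


class TestQdm:
    def test_identity_when_model_unbiased(self, rng):
        obs = rng.gamma(2.0, 30.0, 62)
        out = proj.qdm_correct(obs, obs, obs, proj.QdmSpec("precipitation"))
        np.testing.assert_allclose(out, obs, atol=1e-9)

    def test_constant_additive_bias_removed(self, rng):
        obs = rng.normal(5.0, 3.0, 62)
        hist = obs + 2.0
        target = hist + 0.7  # warmer future, same bias
        out = proj.qdm_correct(obs, hist, target, proj.QdmSpec("temperature"))
        np.testing.assert_allclose(out, target - 2.0, atol=1e-9)

    def test_constant_multiplicative_bias_removed(self, rng):
        obs = rng.gamma(2.0, 30.0, 62)
        hist = obs * 2.0
        target = hist * 1.3
        out = proj.qdm_correct(obs, hist, target, proj.QdmSpec("precipitation"))
        np.testing.assert_allclose(out, target / 2.0, atol=1e-8)

    def test_calibration_window_reproduces_observed_quantiles(self, rng):
        obs = rng.gamma(3.0, 20.0, 80)
        hist = rng.gamma(3.5, 25.0, 80)  # a genuinely different distribution
        out = proj.qdm_correct(obs, hist, hist, proj.QdmSpec("precipitation"))
        taus = np.linspace(0, 1, min(len(obs), 100))
        np.testing.assert_allclose(
            np.quantile(out, taus), np.quantile(obs, taus), atol=1e-6
        )

    def test_delta_preservation(self, rng):
        """Additive mode preserves target-hist quantile differences;
        multiplicative mode preserves their ratios (within interpolation)."""
        taus = np.linspace(0.05, 0.95, 19)
        obs = rng.normal(10.0, 2.0, 300)
        hist = rng.normal(12.0, 2.5, 300)
        target = rng.normal(14.0, 3.0, 300)
        out = proj.qdm_correct(obs, hist, target, proj.QdmSpec("temperature"))
        got = np.quantile(out, taus) - np.quantile(obs, taus)
        want = np.quantile(target, taus) - np.quantile(hist, taus)
        np.testing.assert_allclose(got, want, atol=0.35)

        obs = rng.gamma(3.0, 20.0, 300)
        hist = rng.gamma(3.0, 30.0, 300)
        target = rng.gamma(3.0, 40.0, 300)
        out = proj.qdm_correct(obs, hist, target, proj.QdmSpec("pet"))
        got = np.quantile(out, taus) / np.quantile(obs, taus)
        want = np.quantile(target, taus) / np.quantile(hist, taus)
        np.testing.assert_allclose(got, want, rtol=0.1)

    def test_negative_values_rejected_in_multiplicative_mode(self):
        with pytest.raises(ValueError):
            proj.qdm_correct(np.array([-1.0, 2.0, 3.0]), np.ones(3), np.ones(3),
                             proj.QdmSpec("precipitation"))

    def test_cube_correction_identity(self, small_world):
        obs = small_world.monthly["precipitation"]
        out = proj.qdm_correct_cube(
            obs, obs, proj.QdmSpec("precipitation", calibration=(1970, 2000))
        )
        np.testing.assert_allclose(out.values, obs.values, atol=1e-8)

    def test_cube_correction_removes_constant_bias(self, small_world):
        obs = small_world.monthly["temperature"]
        biased = obs + 2.0
        out = proj.qdm_correct_cube(
            obs, biased, proj.QdmSpec("temperature", calibration=(1970, 2000))
        )
        np.testing.assert_allclose(out.values, obs.values, atol=1e-8)


class TestBilinear:
    SRC = GridMeta(rows=6, cols=6, cell_size=1.0, lon0=0.0, lat0=6.0)
    DST = GridMeta(rows=4, cols=4, cell_size=1.2, lon0=0.3, lat0=5.5)

    def test_constant_preserved(self):
        out = proj.bilinear_regrid(np.full(self.SRC.shape, 3.5), self.SRC, self.DST)
        np.testing.assert_allclose(out, 3.5)

    def test_exact_on_affine_fields(self):
        lon = self.SRC.lon_centers()[None, :]
        lat = self.SRC.lat_centers()[:, None]
        plane = 2.0 * lon + 3.0 * lat + 1.0
        out = proj.bilinear_regrid(plane, self.SRC, self.DST)
        want = 2.0 * self.DST.lon_centers()[None, :] + 3.0 * self.DST.lat_centers()[:, None] + 1.0
        np.testing.assert_allclose(out, want, atol=1e-10)

    def test_interior_point_matches_hand_weights(self):
        src = GridMeta(rows=3, cols=3, cell_size=1.0, lon0=0.0, lat0=3.0)
        r = np.arange(9, dtype=float).reshape(3, 3)
        # target at lon=1.25, lat=1.75: x frac 0.75 between cols 0,1 of the
        # centre lattice; y frac 0.75 between rows 0,1
        dst = GridMeta(rows=1, cols=1, cell_size=0.5, lon0=1.0, lat0=2.0)
        out = proj.bilinear_regrid(r, src, dst)
        want = (r[0, 0] * 0.25 * 0.25 + r[0, 1] * 0.25 * 0.75
                + r[1, 0] * 0.75 * 0.25 + r[1, 1] * 0.75 * 0.75)
        assert out[0, 0] == pytest.approx(want)

    def test_nan_corner_propagates(self):
        r = np.ones(self.SRC.shape)
        r[2, 2] = np.nan
        out = proj.bilinear_regrid(r, self.SRC, self.DST)
        assert np.isnan(out).any()

    def test_disjoint_grids_error(self):
        far = GridMeta(rows=2, cols=2, cell_size=1.0, lon0=100.0, lat0=50.0)
        with pytest.raises(ValueError, match="overlap"):
            proj.bilinear_regrid(np.ones(self.SRC.shape), self.SRC, far)


class TestPredictMap:
    def _inputs(self, study):
        w = study["world"]
        annual_vals = {n: c.values[0] for n, c in study["annual"].items()}
        return w, study["normals"], annual_vals

    def test_constant_model_paints_mask(self, study):
        w, normals, annual_vals = self._inputs(study)
        names = ["mean_anpp"] + [f"baseline_{v}" for v in sorted(normals)] + [
            f"anomaly_{v}" for v in sorted(normals)
        ]
        m = proj.predict_map(const_model(42.0, names), normals, annual_vals, w.mean_anpp, w.mask)
        ok = np.isfinite(m)
        assert np.allclose(m[ok], 42.0)
        assert not np.isfinite(m[~w.mask]).any()

    def test_never_negative(self, study):
        w, normals, annual_vals = self._inputs(study)
        names = ["mean_anpp"]
        m = proj.predict_map(const_model(-5.0, names), normals, annual_vals, w.mean_anpp, w.mask)
        assert np.nanmin(m) == 0.0

    def test_identical_anomaly_years_identical_maps(self, quiet_world):
        from conftest import world_features

        annual, normals = world_features(quiet_world)
        names = ["mean_anpp"] + [f"baseline_{v}" for v in sorted(normals)] + [
            f"anomaly_{v}" for v in sorted(normals)
        ]

        class Sum:
            def predict(self, X):
                return X.sum(axis=1)

        model = harness.FittedModel(Sum(), tuple(names), harness.LearnerSpec("linear"))
        m0 = proj.predict_map(model, normals, {n: c.values[0] for n, c in annual.items()},
                              quiet_world.mean_anpp, quiet_world.mask)
        m5 = proj.predict_map(model, normals, {n: c.values[5] for n, c in annual.items()},
                              quiet_world.mean_anpp, quiet_world.mask)
        np.testing.assert_allclose(m0, m5)

    def test_schema_mismatch_error(self, study):
        w, normals, annual_vals = self._inputs(study)
        with pytest.raises(ValueError, match="schema"):
            proj.predict_map(const_model(1.0, ["nope"]), normals, annual_vals, w.mean_anpp, w.mask)


class TestEnsembleLayers:
    def test_identical_members(self):
        m = np.arange(12, dtype=float).reshape(3, 4)
        layers = proj.ensemble_layers([m, m.copy(), m.copy()])
        assert np.allclose(layers["std"], 0.0)
        for k in ("mean", "median", "p05", "p95"):
            np.testing.assert_allclose(layers[k], m)

    def test_thirteen_member_quantile_oracle(self):
        members = [np.full((2, 2), float(v)) for v in range(1, 14)]
        layers = proj.ensemble_layers(members)
        vals = np.arange(1, 14, dtype=float)
        assert np.allclose(layers["median"], 7.0)
        np.testing.assert_allclose(layers["p05"], np.percentile(vals, 5))
        np.testing.assert_allclose(layers["p95"], np.percentile(vals, 95))

    def test_two_member_mean(self):
        layers = proj.ensemble_layers([np.zeros((2, 2)), np.full((2, 2), 10.0)])
        assert np.allclose(layers["mean"], 5.0)

    def test_ordering_and_nan_rules(self, rng):
        members = [rng.normal(size=(6, 6)) for _ in range(5)]
        members[0][0, 0] = np.nan
        layers = proj.ensemble_layers(members)
        for k in ("mean", "std", "median", "p05", "p95"):
            assert np.isnan(layers[k][0, 0])
        ok = np.isfinite(layers["median"])
        assert (layers["p05"][ok] <= layers["median"][ok] + 1e-12).all()
        assert (layers["median"][ok] <= layers["p95"][ok] + 1e-12).all()
        assert (layers["std"][ok] >= 0).all()
        stack = np.stack(members)
        assert (layers["mean"][ok] >= np.min(stack, axis=0)[ok] - 1e-12).all()
        assert (layers["mean"][ok] <= np.max(stack, axis=0)[ok] + 1e-12).all()

    def test_errors(self):
        with pytest.raises(ValueError):
            proj.ensemble_layers([np.ones((2, 2))])
        with pytest.raises(ValueError, match="grid"):
            proj.ensemble_layers([np.ones((2, 2)), np.ones((3, 3))])
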