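"""Synthetic cohort generator: demographics, forward models, pit surface,
eye sampling, cohort assembly."""

import dataclasses
import math

import numpy as np
import pytest

import octmorph as om
from octmorph.config import ConfigurationError
from octmorph.synthetic import (PitGeometry, _pit_bump, assign_eyes,
                                layer_template, pit_surface,
                                template_disc_mean)


class TestDemographics:
    def test_bucket_proportions_and_sex(self, default_config):
        subs = om.sample_demographics(default_config, seed=7)
        assert len(subs) == 444
        ages = np.array([s.age for s in subs])
        edges = default_config.age_bucket_edges
        counts = np.histogram(ages, bins=edges)[0]
        expected = np.array(default_config.age_bucket_weights) * 444
        # binomial tolerance: 4 sigma per bucket
        tol = 4 * np.sqrt(expected * (1 - expected / 444)) + 1
        assert np.all(np.abs(counts - expected) < tol)
        n_female = sum(s.sex == "F" for s in subs)
        assert abs(n_female - 281) < 4 * math.sqrt(444 * 0.633 * 0.367) + 1
        assert ages.min() >= 21 and ages.max() <= 88

    def test_empty_and_determinism(self, default_config):
        assert om.sample_demographics(dataclasses.replace(default_config,
                                                          n_subjects=0), seed=1) == []
        a = om.sample_demographics(default_config, seed=5)
        b = om.sample_demographics(default_config, seed=5)
        assert a == b

    def test_invalid_weights_rejected(self, default_config):
        with pytest.raises(ConfigurationError):
            dataclasses.replace(default_config, age_bucket_weights=(0.5, 0.5, 0.1, 0.0))
        with pytest.raises(ConfigurationError):
            dataclasses.replace(default_config, age_bucket_weights=(-0.1, 0.6, 0.4, 0.1))


class TestLayerMeanModel:
    def _subject(self, age=40.0, sex="F", sf=0.0, intercept=0.0):
        return om.SubjectRecord("S1", age, sex, sf, intercept,
                                z_intercept=intercept / 14.0)

    def test_reference_point_returns_mu(self, default_config):
        s = self._subject()
        for layer in om.ALL_LAYERS:
            assert om.layer_mean_model(s, layer, default_config) == pytest.approx(
                default_config.layer_models[layer].mu)

    def test_linearized_trt_decade_change(self, default_config):
        # with a linear (non-quadratic) TRT age model the 40->50 change is
        # ten times the per-year coefficient: -3.25 um
        models = dict(default_config.layer_models)
        models["TRT"] = dataclasses.replace(models["TRT"], quadratic=False)
        cfg = dataclasses.replace(default_config, layer_models=models)
        d = (om.layer_mean_model(self._subject(age=50), "TRT", cfg)
             - om.layer_mean_model(self._subject(age=40), "TRT", cfg))
        assert d == pytest.approx(-3.25)

    def test_quadratic_decade_change_formula(self, default_config):
        # quadratic default: 10*b1 + 100*b2 with b1 = 0.9c, b2 = c/400
        m = default_config.layer_models["TRT"]
        d = (om.layer_mean_model(self._subject(age=50), "TRT", default_config)
             - om.layer_mean_model(self._subject(age=40), "TRT", default_config))
        assert d == pytest.approx(10 * m.age_linear + 100 * m.age_quadratic)

    def test_sex_difference(self, default_config):
        d = (om.layer_mean_model(self._subject(sex="M"), "TRT", default_config)
             - om.layer_mean_model(self._subject(sex="F"), "TRT", default_config))
        assert d == pytest.approx(4.14)

    def test_unknown_layer(self, default_config):
        with pytest.raises(KeyError):
            om.layer_mean_model(self._subject(), "GCL", default_config)

    def test_subject_intercept_scaled_by_layer_mean(self, default_config):
        s = self._subject(intercept=14.0)
        mu_t = default_config.layer_models["TRT"].mu
        for layer in om.LAYERS:
            mu = default_config.layer_models[layer].mu
            assert (om.layer_mean_model(s, layer, default_config)
                    - om.layer_mean_model(self._subject(), layer, default_config)
                    ) == pytest.approx(14.0 * mu / mu_t)


class TestPitSurface:
    def test_anchor_points(self, default_pit):
        assert pit_surface(0.0, 0.0, default_pit) == pytest.approx(230.3)
        assert pit_surface(1.134, 0.7, default_pit) == pytest.approx(350.8)

    def test_invalid_shape(self, default_pit):
        bad = dataclasses.replace(default_pit, shape=0.0)
        with pytest.raises(ConfigurationError):
            pit_surface(0.5, 0.0, bad)
        with pytest.raises(ValueError):
            pit_surface(-0.1, 0.0, default_pit)

    def test_closed_form_oracle(self, default_pit):
        # independent evaluation of T = CFT + (RH-CFT) * u^a * exp(a(1-u))
        for r in (0.05, 0.3, 0.567, 0.9, 1.134, 1.5, 2.0):
            u = r / 1.134
            expected = 230.3 + (350.8 - 230.3) * u**2 * math.exp(2 * (1 - u))
            assert pit_surface(r, 0.0, default_pit) == pytest.approx(expected, abs=1e-9)

    def test_unique_maximum_at_rim(self):
        u = np.linspace(0, 3, 3001)
        g = _pit_bump(u, 3.0)
        assert g[0] == 0.0
        assert np.argmax(g) == 1000  # u = 1
        assert g.max() == pytest.approx(1.0)

    def test_angular_modulation_broader_horizontally(self, default_pit):
        pit = dataclasses.replace(default_pit, rim_radius_cos2=0.1)
        assert pit.rim_radius_at(0.0) > pit.rim_radius_at(np.pi / 2)


class TestTemplates:
    def test_disc_mean_normalized(self):
        r = np.linspace(0, 3, 30000)
        for layer in om.LAYERS:
            t = layer_template(layer, r)
            mean = np.sum(t * r) / np.sum(r)  # area-weighted radial mean
            assert mean == pytest.approx(1.0, abs=2e-3)

    def test_inner_layers_thin_centrally(self, default_config):
        r = np.linspace(0, 0.3, 50)
        for layer in ("RNFL", "GCIPL", "INL"):
            field = default_config.layer_models[layer].mu * layer_template(layer, r)
            assert field.max() < 1.0

    def test_mu_renormalization_exact(self, default_config):
        total = sum(default_config.layer_models[l].mu for l in om.LAYERS)
        assert total == pytest.approx(default_config.layer_models["TRT"].mu, abs=1e-9)
        # derived reference means agree with the raw coefficient ratios to 1%
        raw = {"RNFL": 0.22 / 0.69, "GCIPL": 1.77 / 2.41, "INL": 0.45 / 1.31,
               "ONPL": 0.66 / 0.73, "ELM_BM": 0.45 / 0.56}
        for layer, ratio in raw.items():
            assert default_config.layer_models[layer].mu == pytest.approx(
                100 * ratio, rel=0.01)


class TestSampleEye:
    def test_standard_raster_sample_count(self, noiseless_config, rng):
        s = om.sample_demographics(noiseless_config, rng=rng)[0]
        scan = om.sample_eye(s, "OD", noiseless_config, seed=0)
        assert scan.n_samples == 25 * 512 == 12800

    def test_highres_raster_sample_count(self, noiseless_config, rng):
        cfg = dataclasses.replace(noiseless_config, protocol="highres")
        s = om.sample_demographics(cfg, rng=rng)[0]
        scan = om.sample_eye(s, "OD", cfg, seed=0)
        assert scan.n_samples == 97 * 1024 == 99328

    def test_layer_additivity(self, default_config, rng):
        s = om.sample_demographics(default_config, rng=rng)[0]
        for mode in ("template", "pit"):
            cfg = dataclasses.replace(default_config, mode=mode)
            scan = om.sample_eye(s, "OD", cfg, seed=2)
            total = sum(scan.layers[l] for l in om.LAYERS)
            np.testing.assert_allclose(total, scan.layers["TRT"], atol=1e-6)
            for l in om.ALL_LAYERS:
                assert (scan.layers[l] >= 0).all()

    def test_os_eye_mirrors_od(self, noiseless_config, rng):
        s = om.sample_demographics(noiseless_config, rng=rng)[0]
        od = om.sample_eye(s, "OD", noiseless_config, seed=9)
        osc = om.sample_eye(s, "OS", noiseless_config, seed=9)
        # zero fixation offset: the OS field is the x-mirror of the OD field
        n_b, n_a = 25, 512
        od_trt = od.layers["TRT"].reshape(n_b, n_a)
        os_trt = osc.layers["TRT"].reshape(n_b, n_a)
        np.testing.assert_allclose(os_trt, od_trt[:, ::-1], atol=1e-9)

    def test_deterministic_given_seed(self, default_config, rng):
        s = om.sample_demographics(default_config, rng=rng)[0]
        a = om.sample_eye(s, "OD", default_config, seed=4)
        b = om.sample_eye(s, "OD", default_config, seed=4)
        np.testing.assert_array_equal(a.layers["TRT"], b.layers["TRT"])


class TestCohortAssembly:
    def test_expected_eye_count(self, default_config):
        r = np.random.default_rng(11)
        subs = om.sample_demographics(default_config, rng=r)
        pairs = assign_eyes(default_config, r, subs)
        # E[eyes] = 444 * (1 + 411/444) = 855; binomial sd ~ 5.5
        assert abs(len(pairs) - 855) < 4 * math.sqrt(444 * (411 / 444) * (33 / 444)) + 1

    def test_both_eyes_prob_one(self, default_config, tmp_path):
        cfg = dataclasses.replace(default_config, n_subjects=2, both_eyes_prob=1.0)
        out = om.generate_cohort(cfg, tmp_path / "c", seed=0)
        assert len(list((out / "scans").glob("*.csv"))) == 4

    def test_regeneration_byte_identical(self, default_config, tmp_path):
        cfg = dataclasses.replace(default_config, n_subjects=3)
        a = om.generate_cohort(cfg, tmp_path / "a", seed=5)
        b = om.generate_cohort(cfg, tmp_path / "b", seed=5)
        assert (a / "metadata.csv").read_bytes() == (b / "metadata.csv").read_bytes()
        for f in sorted((a / "scans").glob("*.csv")):
            assert f.read_bytes() == (b / "scans" / f.name).read_bytes()


class TestTrueParameterTable:
    def test_noiseless_values_match_models(self, noiseless_config):
        df = om.true_parameter_table(noiseless_config, seed=2)
        trt = df[df.parameter == "TRT"]
        layers = df[df.parameter.isin(om.LAYERS)]
        merged = layers.groupby(["subject_id", "eye"])["value"].sum()
        joined = trt.set_index(["subject_id", "eye"])["value"]
        # TRT model uses the printed whole-retina coefficients; the layer sum
        # differs only through table rounding of the age coefficients
        assert np.abs(merged - joined).max() < 1.0
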