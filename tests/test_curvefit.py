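import numpy as np
import pandas as pd
import pytest

from plumage import curvefit as cf
from plumage.errors import PlumageError
from plumage.spectra import brightness

from conftest import make_spectrum

GRID = np.arange(300.0, 701.0)


def logistic(w, a, b, c, r0=0.0):
    return r0 + a / (1.0 + np.exp(-(w - b) / c))


class TestFitSigmoid:
    def test_exact_recovery(self):
        s = make_spectrum(GRID, logistic(GRID, 0.06, 620.0, 22.0))
        m = cf.fit_sigmoid(s)
        assert m.a == pytest.approx(0.06, abs=1e-6)
        assert m.b == pytest.approx(620.0, abs=1e-4)
        assert m.c == pytest.approx(22.0, abs=1e-4)
        assert m.r0 == pytest.approx(0.0, abs=1e-6)

    def test_noisy_recovery_simulation_oracle(self):
        # 100 replicate fits at noise sd 0.002: amplitude recovered within
        # +/- 0.005 on average and in nearly every replicate
        rng = np.random.default_rng(7)
        errs = []
        for _ in range(100):
            r = logistic(GRID, 0.06, 620.0, 22.0) + rng.normal(0, 0.002, GRID.size)
            m = cf.fit_sigmoid(make_spectrum(GRID, np.clip(r, 0, None)))
            errs.append(m.a - 0.06)
        errs = np.array(errs)
        assert np.mean(np.abs(errs) < 0.005) > 0.95
        assert abs(errs.mean()) < 0.003

    def test_flat_spectrum_degenerate(self, flat_spectrum):
        m = cf.fit_sigmoid(flat_spectrum)
        assert m.degenerate
        assert m.a == pytest.approx(0.0)

    def test_fixed_b_c(self):
        s = make_spectrum(GRID, logistic(GRID, 0.02, 620.0, 22.0, r0=0.01))
        m = cf.fit_sigmoid(s, fixed={"b": 620.0, "c": 22.0})
        assert m.b == 620.0 and m.c == 22.0
        assert m.a == pytest.approx(0.02, abs=1e-6)
        assert m.r0 == pytest.approx(0.01, abs=1e-6)


class TestMelaninRemoval:
    def test_zero_baseline_sigmoid_unchanged(self):
        s = make_spectrum(GRID, logistic(GRID, 0.06, 620.0, 22.0))
        out = cf.remove_melanin(s, cf.fit_sigmoid(s))
        np.testing.assert_allclose(out.reflectance, s.reflectance, atol=1e-6)

    def test_baseline_removed(self):
        s = make_spectrum(GRID, logistic(GRID, 0.02, 620.0, 22.0, r0=0.01))
        out = cf.remove_melanin(s, cf.fit_sigmoid(s))
        np.testing.assert_allclose(
            out.reflectance, logistic(GRID, 0.02, 620.0, 22.0), atol=1e-5)

    def test_noisy_female_smoothed_and_brighter_after_boost(self):
        rng = np.random.default_rng(3)
        raw = logistic(GRID, 0.02, 620.0, 22.0, r0=0.01) + rng.normal(0, 0.002, GRID.size)
        s = make_spectrum(GRID, np.clip(raw, 0, None))
        model = cf.fit_sigmoid(s)
        boosted = cf.apply_barb_enhancement(model, 0.06)
        assert brightness(boosted) > brightness(cf.remove_melanin(s, model))


class TestBarbEnhancement:
    def test_peak_reflectance_logistic_value(self):
        model = cf.SigmoidColorModel(0.02, 620.0, 22.0, 0.0)
        out = cf.apply_barb_enhancement(model, 0.06)
        expected = 0.06 / (1 + np.exp(-(700.0 - 620.0) / 22.0))
        assert expected == pytest.approx(0.06 * 0.9743, abs=2e-4)
        assert out.reflectance[out.wavelengths == 700.0][0] == pytest.approx(expected)

    def test_identity_at_same_amplitude(self):
        model = cf.SigmoidColorModel(0.02, 620.0, 22.0, 0.0)
        out = cf.apply_barb_enhancement(model, 0.02)
        np.testing.assert_allclose(out.reflectance, model.evaluate(out.wavelengths))

    def test_lower_target_rejected(self):
        model = cf.SigmoidColorModel(0.06, 620.0, 22.0, 0.0)
        with pytest.raises(PlumageError):
            cf.apply_barb_enhancement(model, 0.02)


class TestDivide:
    def test_identity_and_quarter(self, flat_spectrum):
        out = cf.divide_spectrum(flat_spectrum, 1.0)
        np.testing.assert_array_equal(out.reflectance, flat_spectrum.reflectance)
        s = make_spectrum(GRID, np.full(GRID.size, 0.08))
        np.testing.assert_allclose(cf.divide_spectrum(s, 4.0).reflectance, 0.02)

    def test_commutes_with_brightness(self):
        s = make_spectrum(GRID, logistic(GRID, 0.06, 620.0, 22.0))
        assert brightness(cf.divide_spectrum(s, 8.0)) == \
            pytest.approx(brightness(s) / 8.0, rel=1e-12)


class TestAngleToDivisor:
    @pytest.fixture
    def sweep(self):
        return pd.DataFrame({"theta_deg": [0.0, 20.0, 40.0, 60.0, 80.0],
                             "R_mean": [0.04, 0.03, 0.02, 0.008, 0.005]})

    def test_zero_angle_is_unity(self, sweep):
        assert cf.angle_to_divisor(0.0, sweep) == pytest.approx(1.0)

    def test_endpoint_ratio(self, sweep):
        assert cf.angle_to_divisor(80.0, sweep) == pytest.approx(0.04 / 0.005)

    def test_monotone_in_angle(self, sweep):
        divs = [cf.angle_to_divisor(t, sweep) for t in np.linspace(0, 80, 17)]
        assert all(b >= a for a, b in zip(divs, divs[1:]))

    def test_extrapolation_rejected(self, sweep):
        with pytest.raises(PlumageError):
            cf.angle_to_divisor(85.0, sweep)


def brute_force_hausdorff(p1, p2):
    from scipy.spatial.distance import cdist
    d = cdist(p1, p2)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


class TestHausdorff:
    def test_identity(self):
        s = make_spectrum(GRID, logistic(GRID, 0.06, 620.0, 22.0))
        assert cf.hausdorff_distance(s, s) == 0.0

    def test_constant_percent_offset(self):
        # +1 percent everywhere on a dense shared grid: distance exactly 1
        dense = np.arange(300.0, 700.0 + 0.1, 0.25)
        s1 = make_spectrum(dense, np.full(dense.size, 0.05))
        s2 = make_spectrum(dense, np.full(dense.size, 0.06))
        d = cf.hausdorff_distance(s1, s2, resample=False)
        p1 = np.column_stack([dense, s1.reflectance * 100])
        p2 = np.column_stack([dense, s2.reflectance * 100])
        assert d == pytest.approx(brute_force_hausdorff(p1, p2), abs=1e-12)
        assert d == pytest.approx(1.0, abs=1e-9)

    def test_metric_properties_against_brute_force(self):
        rng = np.random.default_rng(11)
        w = np.arange(300.0, 701.0, 10.0)
        curves = [make_spectrum(w, np.abs(rng.normal(0.05, 0.02, w.size)))
                  for _ in range(3)]
        ds = {}
        for i in range(3):
            for j in range(3):
                ds[i, j] = cf.hausdorff_distance(curves[i], curves[j], resample=False)
                pi = np.column_stack([w, curves[i].reflectance * 100])
                pj = np.column_stack([w, curves[j].reflectance * 100])
                assert ds[i, j] == pytest.approx(brute_force_hausdorff(pi, pj), abs=1e-12)
        for i in range(3):
            assert ds[i, i] == 0.0
            for j in range(3):
                assert ds[i, j] == ds[j, i]                     # symmetry
                for k in range(3):
                    assert ds[i, k] <= ds[i, j] + ds[j, k] + 1e-12  # triangle

    def test_empty_rejected(self, flat_spectrum):
        with pytest.raises(PlumageError):
            cf.hausdorff_distance(
                flat_spectrum,
                make_spectrum([100.0, 101.0], [0.1, 0.1]))


class TestPipelines:
    def test_melanin_barb_improves_match(self):
        rng = np.random.default_rng(4)
        female = make_spectrum(GRID, np.clip(
            logistic(GRID, 0.02, 620.0, 22.0, r0=0.01)
            + rng.normal(0, 0.001, GRID.size), 0, None), sex="F")
        male = make_spectrum(GRID, logistic(GRID, 0.06, 620.0, 22.0), sex="M")
        res = cf.melanin_barb_pipeline(female, male, a_male=0.06,
                                       fixed={"b": 620.0, "c": 22.0})
        assert res.improved
        assert res.hausdorff_after < 0.5 < res.hausdorff_before

    def test_divisor_pipeline_velvet(self):
        female = make_spectrum(GRID, np.full(GRID.size, 0.08), sex="F")
        male = make_spectrum(GRID, np.full(GRID.size, 0.02), sex="M")
        res = cf.divisor_pipeline(female, male, 4.0)
        assert res.hausdorff_after == pytest.approx(0.0, abs=1e-9)
        assert res.hausdorff_before == pytest.approx(6.0, abs=1e-9)
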