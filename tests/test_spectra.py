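import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plumage import spectra as sp
from plumage.errors import CoverageError, GridMismatchError, HalfMaxWarning, PatchMismatchError

from conftest import make_spectrum

GRID = np.arange(300.0, 701.0)


class TestAverageReplicates:
    def test_identical_replicates_unchanged(self):
        s = make_spectrum(GRID, np.linspace(0.1, 0.5, GRID.size), replicate_id=1)
        avg = sp.average_replicates([s, s, s])
        np.testing.assert_allclose(avg.reflectance, s.reflectance)
        assert avg.replicate_id is None

    def test_constant_replicates_mean(self):
        reps = [make_spectrum(GRID, np.full(GRID.size, v), replicate_id=i)
                for i, v in enumerate((0.1, 0.2, 0.3))]
        avg = sp.average_replicates(reps)
        np.testing.assert_allclose(avg.reflectance, 0.2)

    def test_noisy_sigmoids_match_loop_oracle(self, synth_cfg, spectra_bundle):
        reps = [s for s in spectra_bundle
                if s.key == ("sp01", "M", "rump", 90)]
        assert len(reps) == 3
        avg = sp.average_replicates(reps)
        # brute-force per-wavelength mean
        expected = np.array([np.mean([r.reflectance[k] for r in reps])
                             for k in range(reps[0].wavelengths.size)])
        np.testing.assert_allclose(avg.reflectance, expected, rtol=0, atol=1e-15)

    def test_grid_mismatch_raises(self):
        s1 = make_spectrum(GRID, np.full(GRID.size, 0.1))
        s2 = make_spectrum(GRID + 0.5, np.full(GRID.size, 0.1))
        with pytest.raises(GridMismatchError):
            sp.average_replicates([s1, s2])


class TestBrightness:
    def test_unit_flat_curve(self):
        assert sp.brightness(make_spectrum(GRID, np.ones(GRID.size))) == pytest.approx(1.0)

    def test_zero_curve(self):
        assert sp.brightness(make_spectrum(GRID, np.zeros(GRID.size))) == 0.0

    def test_linear_ramp_against_trapezoid_oracle(self):
        dense = np.linspace(300.0, 700.0, 4001)
        ramp = (dense - 300.0) / 400.0
        oracle = np.trapezoid(ramp, dense) / 400.0
        assert sp.brightness(make_spectrum(dense, ramp)) == pytest.approx(oracle, rel=1e-9)
        assert oracle == pytest.approx(0.5, rel=1e-6)

    def test_coverage_gap_raises(self):
        w = np.arange(400.0, 701.0)
        with pytest.raises(CoverageError):
            sp.brightness(make_spectrum(w, np.ones(w.size)))

    @given(a=st.floats(0.0, 3.0), b=st.floats(0.0, 3.0))
    @settings(max_examples=30, deadline=None)
    def test_linearity(self, a, b):
        r1 = np.linspace(0.0, 0.4, GRID.size)
        r2 = 0.3 + 0.1 * np.sin(GRID / 40.0)
        lhs = sp.brightness(make_spectrum(GRID, a * r1 + b * r2))
        rhs = (a * sp.brightness(make_spectrum(GRID, r1))
               + b * sp.brightness(make_spectrum(GRID, r2)))
        assert lhs == pytest.approx(rhs, abs=1e-12)


class TestSaturationLWHM:
    def test_step_width_shrinks_with_grid(self):
        widths = []
        for step in (4.0, 1.0, 0.25):
            w = np.arange(300.0, 700.0 + step / 2, step)
            r = np.where(w >= 600.0, 0.5, 0.0)
            widths.append(sp.saturation_lwhm(make_spectrum(w, r)).saturation_lwhm)
        assert widths[0] > widths[1] > widths[2]
        assert widths[2] <= 0.25

    def test_logistic_against_root_find_oracle(self):
        # logistic a/(1+exp(-(w-620)/22)): peak at 700; half-max crossing
        # solved numerically from L(w) = 0.5 * L(700)
        from scipy.optimize import brentq
        a, b, c = 0.06, 620.0, 22.0
        L = lambda w: a / (1 + np.exp(-(w - b) / c))
        lam_half = brentq(lambda w: L(w) - 0.5 * L(700.0), 300.0, 700.0)
        oracle = 700.0 - lam_half
        assert oracle == pytest.approx(81.1, abs=0.2)
        dense = np.arange(300.0, 700.0 + 0.05, 0.1)
        m = sp.saturation_lwhm(make_spectrum(dense, L(dense)))
        assert m.saturation_lwhm == pytest.approx(oracle, abs=0.2)

    def test_gaussian_closed_form(self):
        # half width at half maximum of a Gaussian = sigma * sqrt(2 ln 2)
        sigma = 50.0
        dense = np.arange(300.0, 700.0 + 0.05, 0.1)
        r = 0.3 * np.exp(-0.5 * ((dense - 550.0) / sigma) ** 2)
        m = sp.saturation_lwhm(make_spectrum(dense, r))
        assert m.saturation_lwhm == pytest.approx(sigma * np.sqrt(2 * np.log(2)), abs=0.2)
        assert m.saturation_lwhm == pytest.approx(58.87, abs=0.1)

    def test_scale_invariance(self):
        r = 0.02 / (1 + np.exp(-(GRID - 620.0) / 22.0))
        w1 = sp.saturation_lwhm(make_spectrum(GRID, r)).saturation_lwhm
        w2 = sp.saturation_lwhm(make_spectrum(GRID, 7.3 * r)).saturation_lwhm
        assert w1 == pytest.approx(w2, abs=1e-9)

    def test_monotone_rise_fallback_warns(self):
        r = np.linspace(0.35, 0.6, GRID.size)  # never reaches half-max on the left
        with pytest.warns(HalfMaxWarning):
            m = sp.saturation_lwhm(make_spectrum(GRID, r))
        assert m.lwhm_fallback
        assert m.saturation_lwhm == pytest.approx(GRID[-1] - GRID[0])


class TestVelvetClassification:
    def test_constant_low_flat_is_super_black(self):
        assert sp.classify_velvet(make_spectrum(GRID, np.full(GRID.size, 0.003))) \
            == "super_black"

    def test_bright_red_is_normal(self):
        r = 0.20 / (1 + np.exp(-(GRID - 650) / 10.0))
        assert sp.classify_velvet(make_spectrum(GRID, r)) == "normal"

    def test_dark_red_is_velvet(self):
        r = np.where(GRID < 500, 0.01, 0.01 + 0.035 * (GRID - 500) / 200.0)
        assert sp.classify_velvet(make_spectrum(GRID, r)) == "velvet_red"


class TestDirectionality:
    def test_identical_spectra(self):
        s = make_spectrum(GRID, np.full(GRID.size, 0.02))
        d = sp.directionality(s, s)
        assert d["difference"] == pytest.approx(0.0)
        assert d["ratio"] == pytest.approx(1.0)

    def test_doubled_45deg(self):
        s90 = make_spectrum(GRID, np.full(GRID.size, 0.01), incidence_deg=90)
        s45 = make_spectrum(GRID, np.full(GRID.size, 0.02), incidence_deg=45)
        d = sp.directionality(s90, s45)
        assert d["difference"] == pytest.approx(0.01)
        assert d["ratio"] == pytest.approx(2.0)

    def test_velvet_pair_difference(self):
        s90 = make_spectrum(GRID, np.full(GRID.size, 0.005), incidence_deg=90)
        s45 = make_spectrum(GRID, np.full(GRID.size, 0.060), incidence_deg=45)
        assert sp.directionality(s90, s45)["difference"] == pytest.approx(0.055)

    def test_patch_mismatch(self):
        s90 = make_spectrum(GRID, np.full(GRID.size, 0.01), patch="rump")
        s45 = make_spectrum(GRID, np.full(GRID.size, 0.01), patch="back")
        with pytest.raises(PatchMismatchError):
            sp.directionality(s90, s45)


class TestIO:
    def test_long_roundtrip_bit_identical(self, tmp_path, spectra_bundle):
        subset = spectra_bundle[:12]
        path = tmp_path / "spectra.csv"
        sp.write_spectra(subset, path)
        back = sp.read_spectra(path)
        assert len(back) == len(subset)
        by_key = {(s.key, s.replicate_id): s for s in back}
        for s in subset:
            b = by_key[(s.key, s.replicate_id)]
            np.testing.assert_array_equal(b.wavelengths, s.wavelengths)
            np.testing.assert_array_equal(b.reflectance, s.reflectance)

    def test_percent_autodetect(self, tmp_path):
        w = GRID
        rows = [{"species": "sp", "sex": "M", "patch": "rump",
                 "incidence_deg": 90, "replicate": 1,
                 "wavelength_nm": wl, "reflectance": 55.0} for wl in w]
        path = tmp_path / "pct.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        s = sp.read_spectra(path)[0]
        assert s.detected_unit == "percent"
        np.testing.assert_allclose(s.reflectance, 0.55)

    def test_wide_dialect(self, tmp_path):
        wide = pd.DataFrame({"wavelength_nm": GRID, "m1": 0.2, "m2": 0.4})
        meta = pd.DataFrame({"column": ["m1", "m2"], "species": ["a", "a"],
                             "sex": ["M", "F"], "patch": ["rump", "rump"],
                             "incidence_deg": [90, 90], "replicate": [1, 1]})
        wide.to_csv(tmp_path / "wide.csv", index=False)
        meta.to_csv(tmp_path / "meta.csv", index=False)
        out = sp.read_spectra_wide(tmp_path / "wide.csv", tmp_path / "meta.csv")
        assert {s.sex for s in out} == {"M", "F"}

    def test_metrics_table_averages_before_metrics(self, spectra_bundle):
        table = sp.metrics_table([s for s in spectra_bundle if s.species == "sp01"])
        assert (table.n_replicates == 3).all()
        male_rump = table[(table.sex == "M") & (table.patch == "rump")
                          & (table.incidence_deg == 90)]
        female_rump = table[(table.sex == "F") & (table.patch == "rump")
                            & (table.incidence_deg == 90)]
        # male carotenoid edge is more saturated (narrower left shoulder)
        assert male_rump.saturation_lwhm.iloc[0] < female_rump.saturation_lwhm.iloc[0]


def test_metric_of_average_equals_average_of_metrics(spectra_bundle):
    # brightness is linear, so averaging replicates then taking brightness
    # equals averaging the replicate brightness values
    reps = [s for s in spectra_bundle if s.key == ("sp02", "F", "breast", 90)]
    avg_then = sp.brightness(sp.average_replicates(reps))
    then_avg = np.mean([sp.brightness(r) for r in reps])
    assert avg_then == pytest.approx(then_avg, abs=1e-14)
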