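"""Spectral curve manipulation: sigmoid color model, melanin removal,
structural saturation enhancement, and Hausdorff curve matching.

Carotenoid reflectance edges are well described by a logistic step

    R(lambda) = r0 + a / (1 + exp(-(lambda - b) / c))

with amplitude ``a`` (fraction), inflection wavelength ``b`` (nm), width
``c`` (nm) and a broadband baseline ``r0``.  Female colorful patches differ
from male ones in two separable ways: melanin depresses the curve broadband
(baseline and amplitude), and the male's expanded oblong barb boosts the
amplitude of the carotenoid edge.  The pipeline therefore (i) fits the
sigmoid, (ii) removes the melanin baseline, (iii) regenerates the curve at
the male amplitude, and scores the match to a real male spectrum with a
symmetric Hausdorff distance on (nm, percent-reflectance) points.  Matte
(velvet/super-black) patches are instead compared after dividing by the
structural attenuation factor of angled barbules taken from the FDTD angle
sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial.distance import directed_hausdorff

from .errors import FitError, PlumageError
from .spectra import ReflectanceSpectrum

#: shared 1 nm matching grid (instrument grids differ between files)
MATCH_GRID = np.arange(300.0, 700.0 + 0.5, 1.0)


@dataclass
class SigmoidColorModel:
    """Logistic carotenoid reflectance edge (fractions and nm)."""

    a: float
    b: float
    c: float
    r0: float = 0.0
    rms: float = 0.0
    degenerate: bool = False

    def __post_init__(self):
        if self.a < 0 or self.c <= 0 or self.r0 < 0:
            raise PlumageError("sigmoid parameters out of range")

    def evaluate(self, wavelengths: np.ndarray) -> np.ndarray:
        w = np.asarray(wavelengths, dtype=float)
        return self.r0 + self.a / (1.0 + np.exp(-(w - self.b) / self.c))

    def spectrum(self, wavelengths: np.ndarray = MATCH_GRID,
                 **meta) -> ReflectanceSpectrum:
        return ReflectanceSpectrum(np.asarray(wavelengths, dtype=float),
                                   self.evaluate(wavelengths), **meta)


@dataclass
class CurveMatchResult:
    hausdorff_before: float
    hausdorff_after: float
    manipulation: str

    @property
    def improved(self) -> bool:
        return self.hausdorff_after < self.hausdorff_before


def _sigmoid(w, a, b, c, r0):
    return r0 + a / (1.0 + np.exp(-(w - b) / c))


def fit_sigmoid(s: ReflectanceSpectrum,
                fixed: Optional[dict] = None) -> SigmoidColorModel:
    """Least-squares logistic fit to a colorful (non-black) spectrum.

    ``fixed`` may pin ``b`` and/or ``c`` (the shared inflection and width of
    a male/female pair).  A flat spectrum yields a degenerate model with
    a -> 0 and the ``degenerate`` flag set.
    """
    w, r = s.wavelengths, s.reflectance
    if np.ptp(r) < 1e-12:
        return SigmoidColorModel(0.0, float(np.median(w)), 50.0,
                                 float(r[0]), 0.0, degenerate=True)
    fixed = dict(fixed or {})
    span = float(np.ptp(r))
    p0 = {"a": span, "b": float(w[np.argmin(np.abs(r - (r.min() + span / 2)))]),
          "c": 20.0, "r0": float(max(r.min(), 0.0))}
    names = [n for n in ("a", "b", "c", "r0") if n not in fixed]

    def f(wv, *theta):
        p = dict(zip(names, theta))
        p.update(fixed)
        return _sigmoid(wv, p["a"], p["b"], p["c"], p["r0"])

    lo = {"a": 0.0, "b": w[0], "c": 1e-3, "r0": 0.0}
    hi = {"a": 2.0, "b": w[-1], "c": 400.0, "r0": 1.0}
    try:
        popt, _ = curve_fit(
            f, w, r, p0=[p0[n] for n in names],
            bounds=([lo[n] for n in names], [hi[n] for n in names]),
            maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    except RuntimeError as exc:
        raise FitError(f"sigmoid fit did not converge: {exc}") from exc
    p = dict(zip(names, popt))
    p.update(fixed)
    resid = r - _sigmoid(w, p["a"], p["b"], p["c"], p["r0"])
    return SigmoidColorModel(p["a"], p["b"], p["c"], p["r0"],
                             float(np.sqrt(np.mean(resid ** 2))))


def remove_melanin(s: ReflectanceSpectrum,
                   model: SigmoidColorModel) -> ReflectanceSpectrum:
    """Idealized melanin-free curve: the fitted sigmoid with its baseline zeroed.

    Melanin in these feathers acts as a broadband depression of the
    reflectance curve; removing it keeps the fitted carotenoid edge (female
    amplitude retained) and drops r0 to zero.
    """
    clean = replace(model, r0=0.0)
    return ReflectanceSpectrum(s.wavelengths.copy(), clean.evaluate(s.wavelengths),
                               species=s.species, sex=s.sex, patch=s.patch,
                               incidence_deg=s.incidence_deg)


def apply_barb_enhancement(model: SigmoidColorModel, a_target: float,
                           wavelengths: np.ndarray = MATCH_GRID) -> ReflectanceSpectrum:
    """Regenerate the sigmoid at the male amplitude (b, c unchanged, r0 = 0).

    Models the saturation increase predicted for an oblong expanded barb:
    more optical power through the pigmented barb acts as an amplitude gain
    on the carotenoid edge.
    """
    if a_target < model.a:
        raise PlumageError("a_target must not be below the fitted amplitude")
    boosted = SigmoidColorModel(a_target, model.b, model.c, 0.0)
    return boosted.spectrum(wavelengths)


def divide_spectrum(s: ReflectanceSpectrum, divisor: float) -> ReflectanceSpectrum:
    """Pointwise division (structural attenuation by angled barbules)."""
    if divisor <= 0:
        raise PlumageError("divisor must be positive")
    return replace(s, reflectance=s.reflectance / divisor)


def angle_to_divisor(theta: float, angle_table: pd.DataFrame) -> float:
    """Structural divisor R(0°)/R(theta) from an FDTD angle-sweep table.

    ``angle_table`` has columns theta_deg and R_mean (the sweep output);
    reflectance is interpolated linearly between simulated angles.
    """
    tab = angle_table.sort_values("theta_deg")
    th = tab["theta_deg"].to_numpy(dtype=float)
    r = tab["R_mean"].to_numpy(dtype=float)
    if th[0] != 0.0:
        raise PlumageError("angle sweep must include 0 degrees (the reference)")
    if theta < th[0] or theta > th[-1]:
        raise PlumageError(
            f"angle {theta} outside the simulated sweep [{th[0]}, {th[-1]}]")
    r_theta = float(np.interp(theta, th, r))
    if r_theta <= 0:
        raise PlumageError("interpolated reflectance is not positive")
    return float(r[0] / r_theta)


def hausdorff_distance(s1: ReflectanceSpectrum, s2: ReflectanceSpectrum,
                       *, resample: bool = True) -> float:
    """Symmetric Hausdorff distance between two curves on (nm, percent) axes.

    Both spectra are linearly resampled to a shared 1 nm grid over the
    overlap of their ranges, then treated as planar point sets with
    wavelength in nm and reflectance in percent (matching the magnitude
    range of published distances).
    """
    if s1.wavelengths.size == 0 or s2.wavelengths.size == 0:
        raise PlumageError("empty spectrum")
    if resample:
        lo = max(s1.wavelengths[0], s2.wavelengths[0])
        hi = min(s1.wavelengths[-1], s2.wavelengths[-1])
        if hi <= lo:
            raise PlumageError("spectra do not overlap in wavelength")
        grid = MATCH_GRID[(MATCH_GRID >= lo) & (MATCH_GRID <= hi)]
        if grid.size < 2:
            grid = np.linspace(lo, hi, 51)
        s1 = s1.resample(grid)
        s2 = s2.resample(grid)
    p1 = np.column_stack([s1.wavelengths, s1.reflectance * 100.0])
    p2 = np.column_stack([s2.wavelengths, s2.reflectance * 100.0])
    return float(max(directed_hausdorff(p1, p2)[0], directed_hausdorff(p2, p1)[0]))


def melanin_barb_pipeline(female: ReflectanceSpectrum,
                          male: ReflectanceSpectrum,
                          a_male: Optional[float] = None,
                          fixed: Optional[dict] = None) -> CurveMatchResult:
    """Full colorful-patch manipulation: fit, remove melanin, boost amplitude.

    Scores the manipulated female curve against the real male spectrum; the
    pre-manipulation distance is the raw female/male Hausdorff.
    """
    model = fit_sigmoid(female, fixed=fixed)
    if a_male is None:
        a_male = max(fit_sigmoid(male, fixed=fixed).a, model.a)
    manipulated = apply_barb_enhancement(model, a_male)
    before = hausdorff_distance(female, male)
    after = hausdorff_distance(manipulated, male)
    return CurveMatchResult(before, after, "melanin-removal + barb-enhancement")


def divisor_pipeline(female: ReflectanceSpectrum, male: ReflectanceSpectrum,
                     divisor: float) -> CurveMatchResult:
    """Matte-patch manipulation: divide the female curve by the structural factor."""
    before = hausdorff_distance(female, male)
    after = hausdorff_distance(divide_spectrum(female, divisor), male)
    return CurveMatchResult(before, after, f"divide-by-{divisor:g}")
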