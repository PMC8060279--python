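"""Reflectance spectra and color metrics.

A :class:`ReflectanceSpectrum` is one spectrophotometer measurement of one
plumage patch at one angle of light incidence (90° or 45°), stored as a
wavelength grid (nm) plus fractional reflectance.  The metrics implemented
here are the ones used to compare male and female tanager plumage:

* ``brightness`` — the integral of fractional reflectance over 300–700 nm
  divided by 400 (a grid-independent mean reflectance);
* ``saturation_lwhm`` — the leftwards width at half-maximum reflectance, in
  nm; a narrow left shoulder means a sharp color edge, i.e. a purer color;
* ``classify_velvet`` — flags "super black" (<0.5 %, spectrally flat) and
  "velvet red" (<5 % everywhere, red-biased) patches;
* ``directionality`` — the 45° minus 90° brightness contrast that marks
  structurally absorbing, directional plumage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._io import read_table

from .errors import (
    CoverageError,
    GridMismatchError,
    HalfMaxWarning,
    PatchMismatchError,
    PlumageError,
)

PATCHES = ("crown", "back", "rump", "tail", "throat", "breast", "belly", "other")

#: any reflectance value above this is taken to be on the percent scale
PERCENT_DETECT_THRESHOLD = 1.5


@dataclass
class ReflectanceSpectrum:
    """One patch × incidence measurement (reflectance as fraction in [0, 1])."""

    wavelengths: np.ndarray
    reflectance: np.ndarray
    species: str = ""
    sex: str = ""
    patch: str = "other"
    incidence_deg: int = 90
    replicate_id: Optional[int] = None

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.shape != self.reflectance.shape:
            raise PlumageError("wavelengths and reflectance must have equal length")
        if self.wavelengths.size < 2:
            raise PlumageError("a spectrum needs at least two samples")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise PlumageError("wavelengths must be strictly increasing")
        if np.any(self.reflectance < 0):
            raise PlumageError("reflectance must be non-negative")

    @property
    def key(self):
        return (self.species, self.sex, self.patch, self.incidence_deg)

    def to_percent(self) -> "ReflectanceSpectrum":
        return replace(self, reflectance=self.reflectance * 100.0)

    def resample(self, grid: np.ndarray) -> "ReflectanceSpectrum":
        """Linear interpolation onto a new grid (explicit, never silent)."""
        grid = np.asarray(grid, dtype=float)
        r = np.interp(grid, self.wavelengths, self.reflectance)
        return replace(self, wavelengths=grid, reflectance=r)


@dataclass
class SpectralMetrics:
    brightness: float
    saturation_lwhm: float
    peak_wavelength: float
    peak_reflectance: float
    lwhm_fallback: bool = False


def average_replicates(spectra: Sequence[ReflectanceSpectrum]) -> ReflectanceSpectrum:
    """Pointwise mean of replicate spectra sharing a (species, sex, patch, incidence) key.

    Raises :class:`GridMismatchError` if the wavelength grids differ — replicates
    from the same instrument session share a grid, and averaging across grids
    would silently interpolate.
    """
    if not spectra:
        raise PlumageError("no spectra to average")
    first = spectra[0]
    for s in spectra[1:]:
        if s.key != first.key:
            raise PlumageError(f"replicates mix keys: {s.key} vs {first.key}")
        if s.wavelengths.shape != first.wavelengths.shape or not np.array_equal(
            s.wavelengths, first.wavelengths
        ):
            raise GridMismatchError("replicates are not on a common wavelength grid")
    mean = np.mean([s.reflectance for s in spectra], axis=0)
    return replace(first, reflectance=mean, replicate_id=None)


def brightness(s: ReflectanceSpectrum, *, lo: float = 300.0, hi: float = 700.0,
               endpoint_tol: float = 5.0) -> float:
    """Trapezoidal integral of fractional reflectance over [lo, hi] divided by (hi-lo).

    The native grid is used directly (no resampling).  A coverage gap larger
    than ``endpoint_tol`` nm at either endpoint raises :class:`CoverageError`.
    """
    w, r = s.wavelengths, s.reflectance
    if w[0] > lo + endpoint_tol or w[-1] < hi - endpoint_tol:
        raise CoverageError(
            f"spectrum covers [{w[0]:.1f}, {w[-1]:.1f}] nm; need [{lo}, {hi}] ± {endpoint_tol}"
        )
    wlo, whi = max(w[0], lo), min(w[-1], hi)
    mask = (w >= wlo) & (w <= whi)
    wc = w[mask]
    rc = r[mask]
    # include exact interpolated endpoints so the integral window is [lo, hi]
    if wc[0] > wlo:
        wc = np.insert(wc, 0, wlo)
        rc = np.insert(rc, 0, np.interp(wlo, w, r))
    if wc[-1] < whi:
        wc = np.append(wc, whi)
        rc = np.append(rc, np.interp(whi, w, r))
    return float(np.trapezoid(rc, wc) / (hi - lo))


def saturation_lwhm(s: ReflectanceSpectrum) -> SpectralMetrics:
    """Leftwards width at half-maximum reflectance (nm); smaller = more saturated.

    The peak is the first (smallest-wavelength) sample attaining the maximum;
    the half-maximum crossing left of the peak is located by linear
    interpolation between the bracketing samples.  If reflectance never drops
    below half-maximum left of the peak the width falls back to
    ``lambda_max - lambda_min`` and a :class:`HalfMaxWarning` is issued.
    """
    w, r = s.wavelengths, s.reflectance
    if np.ptp(r) == 0:
        raise PlumageError("saturation_lwhm undefined for a constant spectrum")
    imax = int(np.argmax(r))  # argmax returns the first maximal sample
    rmax = r[imax]
    half = rmax / 2.0
    b = brightness_or_nan(s)
    # walk left from the peak for the first crossing below half-max
    for i in range(imax, 0, -1):
        if r[i - 1] <= half <= r[i]:
            if r[i] == r[i - 1]:
                lam_half = w[i - 1]
            else:
                lam_half = w[i - 1] + (half - r[i - 1]) / (r[i] - r[i - 1]) * (w[i] - w[i - 1])
            return SpectralMetrics(b, float(w[imax] - lam_half), float(w[imax]), float(rmax))
    warnings.warn(
        "no leftward half-max crossing; using lambda_max - lambda_min", HalfMaxWarning
    )
    return SpectralMetrics(b, float(w[imax] - w[0]), float(w[imax]), float(rmax), True)


def brightness_or_nan(s: ReflectanceSpectrum) -> float:
    try:
        return brightness(s)
    except CoverageError:
        return float("nan")


def classify_velvet(s: ReflectanceSpectrum, *, black_level: float = 0.005,
                    flat_range: float = 0.003, velvet_level: float = 0.05) -> str:
    """Classify an averaged 90° spectrum as ``super_black``, ``velvet_red`` or ``normal``.

    ``super_black``: reflectance below ``black_level`` (default 0.5 %) at every
    wavelength and spectrally flat (absolute range below ``flat_range``).
    ``velvet_red``: below ``velvet_level`` (5 %) everywhere with the mean
    long-wavelength (>600 nm) reflectance exceeding the mean below 500 nm.
    """
    r = s.reflectance
    w = s.wavelengths
    if np.all(r < black_level) and np.ptp(r) < flat_range:
        return "super_black"
    if np.all(r < velvet_level):
        long_mean = float(np.mean(r[w > 600])) if np.any(w > 600) else 0.0
        short_mean = float(np.mean(r[w < 500])) if np.any(w < 500) else 0.0
        if long_mean > short_mean:
            return "velvet_red"
    return "normal"


def directionality(s90: ReflectanceSpectrum, s45: ReflectanceSpectrum) -> dict:
    """Brightness contrast between 45° and 90° incidence for one patch.

    A positive difference (brighter at 45°) is the hallmark of structurally
    absorbing, directional plumage such as velvet red patches.
    """
    if (s90.species, s90.sex, s90.patch) != (s45.species, s45.sex, s45.patch):
        raise PatchMismatchError(
            f"patch mismatch: {(s90.species, s90.sex, s90.patch)} vs "
            f"{(s45.species, s45.sex, s45.patch)}"
        )
    b90 = brightness(s90)
    b45 = brightness(s45)
    return {
        "difference": b45 - b90,
        "ratio": b45 / b90 if b90 > 0 else float("inf"),
        "directional": b45 > b90,
    }


# ---------------------------------------------------------------------------
# readers / writers

LONG_COLUMNS = [
    "species", "sex", "patch", "incidence_deg", "replicate", "wavelength_nm", "reflectance",
]


def _detect_unit(values: np.ndarray, unit: str) -> str:
    if unit != "auto":
        return unit
    return "percent" if np.nanmax(values) > PERCENT_DETECT_THRESHOLD else "fraction"


def read_spectra(path, *, unit: str = "auto") -> list[ReflectanceSpectrum]:
    """Read long-format delimited spectra (CSV or TSV; sniffed from the header).

    Percent-scale reflectance is auto-detected (any value > 1.5 means percent)
    and converted to fraction; the detected unit is attached to each spectrum
    as ``detected_unit``.
    """
    df = read_table(path)
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise PlumageError(f"spectra file missing columns: {missing}")
    detected = _detect_unit(df["reflectance"].to_numpy(dtype=float), unit)
    scale = 0.01 if detected == "percent" else 1.0
    out = []
    keys = ["species", "sex", "patch", "incidence_deg", "replicate"]
    for key, grp in df.groupby(keys, sort=False, dropna=False):
        grp = grp.sort_values("wavelength_nm")
        s = ReflectanceSpectrum(
            wavelengths=grp["wavelength_nm"].to_numpy(dtype=float),
            reflectance=grp["reflectance"].to_numpy(dtype=float) * scale,
            species=str(key[0]), sex=str(key[1]), patch=str(key[2]),
            incidence_deg=int(key[3]),
            replicate_id=int(key[4]) if not pd.isna(key[4]) else None,
        )
        s.detected_unit = detected
        out.append(s)
    return out


def read_spectra_wide(path, metadata_path, *, unit: str = "auto") -> list[ReflectanceSpectrum]:
    """Wide dialect: first column wavelength, one column per measurement.

    ``metadata_path`` is a sidecar table with columns
    [column, species, sex, patch, incidence_deg, replicate].
    """
    df = read_table(path)
    meta = read_table(metadata_path).set_index("column")
    wav = df.iloc[:, 0].to_numpy(dtype=float)
    out = []
    for col in df.columns[1:]:
        vals = df[col].to_numpy(dtype=float)
        detected = _detect_unit(vals, unit)
        scale = 0.01 if detected == "percent" else 1.0
        m = meta.loc[col]
        s = ReflectanceSpectrum(
            wavelengths=wav, reflectance=vals * scale,
            species=str(m["species"]), sex=str(m["sex"]), patch=str(m["patch"]),
            incidence_deg=int(m["incidence_deg"]),
            replicate_id=int(m["replicate"]) if not pd.isna(m["replicate"]) else None,
        )
        s.detected_unit = detected
        out.append(s)
    return out


def write_spectra(spectra: Iterable[ReflectanceSpectrum], path) -> None:
    rows = []
    for s in spectra:
        for w, r in zip(s.wavelengths, s.reflectance):
            rows.append({
                "species": s.species, "sex": s.sex, "patch": s.patch,
                "incidence_deg": s.incidence_deg,
                "replicate": s.replicate_id if s.replicate_id is not None else "",
                "wavelength_nm": w, "reflectance": r,
            })
    # %.17g guarantees float64 round-trip through the text format
    pd.DataFrame(rows, columns=LONG_COLUMNS).to_csv(path, index=False,
                                                    float_format="%.17g")


def metrics_table(spectra: Sequence[ReflectanceSpectrum]) -> pd.DataFrame:
    """Average replicates per (species, sex, patch, incidence) and tabulate metrics."""
    groups: dict = {}
    for s in spectra:
        groups.setdefault(s.key, []).append(s)
    rows = []
    for key, reps in groups.items():
        avg = average_replicates(reps)
        m = saturation_lwhm(avg) if np.ptp(avg.reflectance) > 0 else None
        rows.append({
            "species": key[0], "sex": key[1], "patch": key[2], "incidence_deg": key[3],
            "n_replicates": len(reps),
            "brightness": brightness_or_nan(avg),
            "saturation_lwhm": m.saturation_lwhm if m else float("nan"),
            "peak_wavelength": m.peak_wavelength if m else float("nan"),
            "peak_reflectance": m.peak_reflectance if m else float(avg.reflectance.max()),
            "velvet_class": classify_velvet(avg) if key[3] == 90 else "",
        })
    return pd.DataFrame(rows)
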