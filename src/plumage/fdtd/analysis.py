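"""The two simulation campaigns: barbule-angle sweep and barb power transmission."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import FDTDConfig
from .scenes import dihedral_scene, oblong_barb_scene
from .solver import power_transmission, run_fdtd

#: side of the four square monitor regions (µm)
REGION_SIZE_UM = 7.5

#: nominal offsets of the monitor squares from the barb center, as printed
#: for the male-typical barb (its side edge, 45° ellipse point and top edge)
REGION_OFFSETS = {
    "center": (0.0, 0.0),
    "side": (15.0, 0.0),
    "diagonal": (10.0, 10.0),
    "top": (0.0, 20.0),
}


def region_centers(height_um: float, width_um: float) -> dict:
    """Monitor centers anchored to the barb's own landmarks.

    All four regions are locations of the barb: its center, the midpoint of
    its side edge, the point of the ellipse along the 45° ray, and its top
    edge.  For the male-typical barb these reduce to approximately the
    nominal printed offsets; for the smaller female barb they scale with the
    ellipse so the monitors stay on the barb.
    """
    a, b = width_um / 2.0, height_um / 2.0
    t45 = 1.0 / np.sqrt(1.0 / a ** 2 + 1.0 / b ** 2)   # x = y on the ellipse
    return {
        "center": (0.0, 0.0),
        "side": (a, 0.0),
        "diagonal": (t45, t45),
        "top": (0.0, b),
    }

#: average barb cross-sections measured from SEM: (height, width) µm
FEMALE_BARB_UM = (22.2, 18.9)
MALE_BARB_UM = (39.8, 27.7)
VACUOLE_DIAMETER_UM = 10.0


def reflectance_vs_barbule_angle(angles: Sequence[float], cfg: FDTDConfig, *,
                                 barbule_length: float = 80.0,
                                 barbule_thickness: float = 2.0) -> pd.DataFrame:
    """Wavelength-averaged reflectance of the dihedral barbule array per angle.

    Returns a DataFrame sorted by angle with columns theta_deg, R_mean, R_sd
    (mean and standard deviation over the configured wavelength set).
    """
    rows = []
    for theta in sorted(float(a) for a in angles):
        scene = dihedral_scene(theta, barbule_length=barbule_length,
                               barbule_thickness=barbule_thickness, cfg=cfg)
        res = run_fdtd(scene, cfg)
        rows.append({"theta_deg": theta,
                     "R_mean": float(np.mean(res.reflectance)),
                     "R_sd": float(np.std(res.reflectance))})
    return pd.DataFrame(rows)


def _regions(sex: str) -> dict:
    h, w = MALE_BARB_UM if sex == "male" else FEMALE_BARB_UM
    return {label: (cx, cy, REGION_SIZE_UM)
            for label, (cx, cy) in region_centers(h, w).items()}


def barb_scene_variant(sex: str, variant: str, cfg: FDTDConfig, *,
                       domain_width: Optional[float] = None):
    h, w = MALE_BARB_UM if sex == "male" else FEMALE_BARB_UM
    # the scene strip must contain the topmost monitor square
    top_extent = h / 2.0 + REGION_SIZE_UM / 2.0
    kw = dict(domain_width=domain_width, cfg=cfg,
              margin_top=max(5.0, top_extent + 1.0 - h / 2.0))
    if variant == "whole":
        return oblong_barb_scene(h, w, **kw)
    if variant == "truncated":
        return oblong_barb_scene(h, w, truncate=True, **kw)
    if variant == "vacuole":
        return oblong_barb_scene(h, w, vacuole_diameter=VACUOLE_DIAMETER_UM, **kw)
    raise ValueError(f"unknown variant {variant!r}")


def barb_power(sex: str, variant: str, cfg: FDTDConfig,
               wavelength_nm: float = 700.0) -> dict:
    """Region powers (W/m², source-normalized) for one barb scene at one wavelength."""
    scene = barb_scene_variant(sex, variant, cfg)
    res = power_transmission(scene, cfg.with_(wavelengths_nm=(wavelength_nm,)),
                             _regions(sex))
    return {label: float(v[0]) for label, v in res.region_powers.items()}


def male_female_power_experiment(cfg: FDTDConfig,
                                 wavelength_nm: float = 700.0) -> dict:
    """The 11-pair barb power comparison with a one-sided paired t-test.

    Three sensitivity geometries (whole feather, truncated base, central air
    vacuole) x four monitor regions, minus the barb center of the vacuole
    geometry (the vacuole displaces the pigmented keratin there), give 11
    paired female/male measurements.  The t-test asks whether females transmit
    less power than males (alternative: female < male), mirroring a paired
    t.test(female, male, alternative="less").
    """
    variants = ("whole", "truncated", "vacuole")
    rows = []
    for variant in variants:
        pf = barb_power("female", variant, cfg, wavelength_nm)
        pm = barb_power("male", variant, cfg, wavelength_nm)
        for label in REGION_OFFSETS:
            if variant == "vacuole" and label == "center":
                continue
            rows.append({"variant": variant, "region": label,
                         "female": pf[label], "male": pm[label],
                         "difference": pf[label] - pm[label]})
    table = pd.DataFrame(rows)
    f = table["female"].to_numpy()
    m = table["male"].to_numpy()
    tt = stats.ttest_rel(f, m, alternative="less")
    return {
        "table": table,
        "mean_difference": float(np.mean(f - m)),
        "t": float(tt.statistic),
        "df": int(len(f) - 1),
        "p": float(tt.pvalue),
        "all_male_greater": bool(np.all(m > f)),
    }
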