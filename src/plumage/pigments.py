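"""LC-MS carotenoid signal processing.

LC-MS reports a signal intensity per detected molecule, not an amount, and
response factors differ between carotenoid species — so signals are only
comparable within a pigment *family* (isomers sharing a monoisotopic mass
within a ppm tolerance).  This module implements the downstream numerics:
per-specimen weight/max normalization, accurate-mass family assignment at a
5 ppm tolerance, replicate-repeatability regressions, and summed-isomer
views with a base-10 log transform.

Tables are long-format pandas DataFrames with columns
[species, sex, patch, specimen_id, molecule_id, accurate_mass, family,
signal, sample_weight].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._io import read_table
import yaml

from .errors import (
    AmbiguousFamilyError,
    InsufficientDataError,
    MissingWeightError,
    PlumageError,
)

PIGMENT_COLUMNS = [
    "species", "sex", "patch", "specimen_id", "molecule_id",
    "accurate_mass", "family", "signal", "sample_weight",
]

#: default accurate-mass tolerance (parts per million)
DEFAULT_PPM = 5.0


@dataclass
class FamilyCatalog:
    """Pigment family name -> reference monoisotopic mass (Da)."""

    masses: dict
    ppm: float = DEFAULT_PPM

    def __post_init__(self):
        if self.ppm <= 0:
            raise PlumageError("ppm tolerance must be positive")
        names = sorted(self.masses)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                ma, mb = self.masses[a], self.masses[b]
                if abs(ma - mb) / min(ma, mb) <= 2 * self.ppm * 1e-6:
                    raise PlumageError(
                        f"families {a!r} and {b!r} are closer than twice the "
                        f"{self.ppm} ppm tolerance")

    @classmethod
    def from_yaml(cls, path) -> "FamilyCatalog":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(doc["masses"], doc.get("ppm", DEFAULT_PPM))

    @classmethod
    def from_csv(cls, path, ppm: float = DEFAULT_PPM) -> "FamilyCatalog":
        df = pd.read_csv(path)
        return cls(dict(zip(df["family"], df["mass"])), ppm)


def assign_family(mass: float, catalog: FamilyCatalog) -> Optional[str]:
    """Family whose reference mass is within the ppm tolerance, or None.

    Raises :class:`AmbiguousFamilyError` if two families match (possible
    only with a catalog violating the 2x-tolerance spacing invariant).
    """
    if mass <= 0:
        raise PlumageError("accurate mass must be positive")
    hits = [name for name, ref in catalog.masses.items()
            if abs(mass - ref) / ref <= catalog.ppm * 1e-6]
    if len(hits) > 1:
        raise AmbiguousFamilyError(f"mass {mass} matches {hits}")
    return hits[0] if hits else None


def assign_families(table: pd.DataFrame, catalog: FamilyCatalog) -> pd.DataFrame:
    """Vectorized family assignment for a pigment table (column ``family``)."""
    out = table.copy()
    out["family"] = [assign_family(m, catalog) for m in out["accurate_mass"]]
    return out


def normalize_signals(table: pd.DataFrame) -> pd.DataFrame:
    """Per-specimen normalization: signal / sample weight, then / specimen max.

    After normalization the largest signal of every specimen with any
    nonzero signal equals 1.  Specimens whose signals are all zero are
    flagged in the ``all_zero`` column.
    """
    t = table.copy()
    missing = t.loc[t["sample_weight"].isna() | (t["sample_weight"] <= 0),
                    "specimen_id"].unique()
    if len(missing):
        raise MissingWeightError(missing)
    if (t["signal"] < 0).any():
        raise PlumageError("signals must be non-negative")
    t["signal"] = t["signal"] / t["sample_weight"]
    gmax = t.groupby("specimen_id")["signal"].transform("max")
    t["all_zero"] = gmax == 0
    t["signal"] = np.where(gmax > 0, t["signal"] / gmax.replace(0, np.nan), 0.0)
    t["sample_weight"] = 1.0  # weights are consumed by the normalization
    return t


def repeatability_regression(t1: pd.DataFrame, t2: pd.DataFrame) -> dict:
    """OLS of individual 2's normalized signals on individual 1's.

    Both tables must be normalized and share molecule identifiers; used for
    replicate extractions of the same species (and for within-bird
    patch-vs-patch comparisons).
    """
    m1 = t1.set_index("molecule_id")["signal"]
    m2 = t2.set_index("molecule_id")["signal"]
    shared = m1.index.intersection(m2.index)
    if len(shared) < 3:
        raise InsufficientDataError(
            f"only {len(shared)} shared molecules; need at least 3")
    x = m1.loc[shared].to_numpy(dtype=float)
    y = m2.loc[shared].to_numpy(dtype=float)
    from scipy import stats
    res = stats.linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "se": float(res.stderr), "r2": float(res.rvalue ** 2),
            "p": float(res.pvalue), "n": int(len(shared))}


def sum_isomers(table: pd.DataFrame, *, log10: bool = False) -> pd.DataFrame:
    """One row per (specimen, family): summed isomer signal.

    With ``log10=True`` the summed signal is log-transformed base 10, using
    log10(x + eps) where eps is one tenth of the smallest positive summed
    signal (zero-handling convention).
    """
    if table["family"].isna().any():
        raise PlumageError("families must be assigned before summing isomers")
    keys = ["species", "sex", "patch", "specimen_id", "family"]
    out = (table.groupby(keys, as_index=False, sort=True)
           .agg(signal=("signal", "sum"), n_isomers=("molecule_id", "nunique")))
    if log10:
        pos = out.loc[out["signal"] > 0, "signal"]
        eps = float(pos.min()) / 10.0 if len(pos) else 1e-12
        out["log10_signal"] = np.log10(out["signal"] + eps)
    return out


def read_pigments(path) -> pd.DataFrame:
    df = read_table(path)
    missing = [c for c in PIGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise PlumageError(f"pigment file missing columns: {missing}")
    return df


def write_pigments(table: pd.DataFrame, path) -> None:
    cols = [c for c in PIGMENT_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, index=False)


def default_catalog() -> FamilyCatalog:
    """A synthetic eight-family catalog for fixtures and generated data.

    Masses are representative monoisotopic masses of common avian carotenoid
    families (zeaxanthin-like C40H56O2 at 568.428, canthaxanthin-like
    C40H52O2 at 564.397, astaxanthin-like C40H52O4 at 596.386, ...); they are
    fixture values for synthetic data, not study-derived reference chemistry.
    """
    return FamilyCatalog({
        "zeaxanthin": 568.4280,
        "canthaxanthin": 564.3967,
        "astaxanthin": 596.3866,
        "alloxanthin": 564.3760,
        "apo-8-carotenal": 416.3079,
        "lycopene": 536.4382,
        "cryptoxanthin": 552.4331,
        "echinenone": 550.4175,
    })
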