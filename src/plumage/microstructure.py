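"""Feather microstructure measurements and categorical feature flags.

Six continuous SEM measurements are recorded per feather: maximum barb
width, top-down barb width, barbule width, inter-barbule distance,
barb-barbule angle, and barbule length (µm / degrees).  Two booleans are
coded from imagery (angled 3-D barbules; strap-shaped barbules) and two are
derived numerically against pooled medians: a barb is *oblong* when its
height-to-width ratio (max width / top-down width) exceeds the median ratio,
and *expanded* (wide) when its maximum width exceeds the median width.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._io import read_table

from .errors import PlumageError

CONTINUOUS_COLUMNS = [
    "max_barb_width", "topdown_barb_width", "barbule_width",
    "interbarbule_distance", "barb_barbule_angle", "barbule_length",
]
CODED_COLUMNS = ["strap_shaped", "angled_3d"]
KEY_COLUMNS = ["species", "sex", "patch"]


def validate_table(t: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in KEY_COLUMNS + CONTINUOUS_COLUMNS + CODED_COLUMNS
               if c not in t.columns]
    if missing:
        raise PlumageError(f"microstructure table missing columns: {missing}")
    if (t[CONTINUOUS_COLUMNS] <= 0).any().any():
        raise PlumageError("continuous measurements must be positive")
    if ((t["barb_barbule_angle"] < 0) | (t["barb_barbule_angle"] > 90)).any():
        raise PlumageError("barb-barbule angle must lie in [0, 90] degrees")
    return t


def derive_flags(t: pd.DataFrame) -> pd.DataFrame:
    """Append the four categorical feature flags.

    Medians are pooled over all rows (both sexes, all patches).  Strict
    inequality means that with all-identical widths nothing is flagged
    expanded.
    """
    validate_table(t)
    out = t.copy()
    if (out["topdown_barb_width"] == 0).any():
        raise PlumageError("zero top-down barb width")
    ratio = out["max_barb_width"] / out["topdown_barb_width"]
    out["oblong_barb"] = ratio > ratio.median()
    out["expanded_barb"] = out["max_barb_width"] > out["max_barb_width"].median()
    out["angled_barbules"] = out["angled_3d"].astype(bool)
    out["strap_shaped_barbules"] = out["strap_shaped"].astype(bool)
    return out


def prepare_pca_matrix(t: pd.DataFrame):
    """Log-transformed continuous measurements, one row per (species, sex, patch).

    Returns ``(matrix, keys)`` where ``matrix`` is an (n, 6) float array and
    ``keys`` the corresponding key DataFrame; feeds the comparative PCA.
    """
    validate_table(t)
    grouped = t.groupby(KEY_COLUMNS, as_index=False, sort=True)[CONTINUOUS_COLUMNS].mean()
    vals = grouped[CONTINUOUS_COLUMNS].to_numpy(dtype=float)
    if (vals <= 0).any():
        raise PlumageError("log transform requires positive measurements")
    return np.log(vals), grouped[KEY_COLUMNS]


def sex_separation_report(scores: np.ndarray, sexes, *, n_perm: int = 10000,
                          seed: int = 0) -> dict:
    """Distance between male and female centroids in the PC1-PC2 plane,
    with a permutation test of the separation (label shuffles, seeded).

    This is diagnostic plumbing for synthetic and exploratory data; the
    comparative analyses proper run through PGLS.
    """
    scores = np.asarray(scores, dtype=float)[:, :2]
    sexes = np.asarray(sexes)
    labels = np.unique(sexes)
    if len(labels) != 2:
        raise PlumageError(f"need exactly two sexes, got {labels}")
    a = scores[sexes == labels[0]]
    b = scores[sexes == labels[1]]
    obs = float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(sexes)
        pa = scores[perm == labels[0]].mean(axis=0)
        pb = scores[perm == labels[1]].mean(axis=0)
        if np.linalg.norm(pa - pb) >= obs:
            count += 1
    return {"separation": obs, "p": (count + 1) / (n_perm + 1),
            "n_permutations": n_perm, "seed": seed}


def read_microstructure(path) -> pd.DataFrame:
    return validate_table(read_table(path))


def write_microstructure(t: pd.DataFrame, path) -> None:
    t.to_csv(path, index=False)
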