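"""Seeded generators for every input the pipeline consumes.

The generators emulate the study design with known ground truth so that
recovery can be tested end to end: a pure-birth phylogeny of n species
scaled to unit depth; reflectance spectra (three replicates x seven patches
x two incidence angles x two sexes per species) built from the logistic
carotenoid edge for colorful patches and flat low curves for black patches;
male/female LC-MS pigment tables with a prescribed cross-sex regression
slope plus family, phylogenetic (Brownian) and residual variance
components; and microstructure measurement tables with sex-structured
means and one male-like female outlier species.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

from .phylo import brownian_cov, tip_labels
from .spectra import ReflectanceSpectrum

PATCH_SET = ("crown", "back", "rump", "tail", "throat", "breast", "belly")
#: patches carrying carotenoid color in the emulated design; others are black
COLORFUL_PATCHES = ("rump", "breast")


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_species: int = 10
    # logistic carotenoid-edge parameters per sex (fractions / nm)
    a_female: float = 0.02
    a_male: float = 0.06
    b_nm: float = 620.0
    c_nm: float = 22.0
    r0_female: float = 0.01      # broadband melanin baseline in females
    r0_male: float = 0.0
    # black patches: males are super black, females dark with a red tilt
    black_male: float = 0.003
    black_female: float = 0.015
    black_female_slope: float = 0.005   # rise toward 700 nm (fraction)
    # instrument noise after scan averaging; black patches carry less
    # (photon noise scales with signal)
    noise_sd: float = 0.001
    noise_sd_black: float = 0.0005
    grid_start: float = 300.0
    grid_stop: float = 700.0
    grid_step: float = 1.0
    # pigments
    n_molecules: int = 29
    n_families: int = 8
    slope: float = 0.55          # cross-sex regression slope on the log scale
    sd_family: float = 0.3
    sd_phylo: float = 0.2
    sd_residual: float = 0.3
    male_log_mean: float = -1.0
    male_log_sd: float = 1.0
    # microstructure (µm / degrees): male barbs wider and more oblong
    micro_male_mean: dict = field(default_factory=lambda: {
        "max_barb_width": 45.0, "topdown_barb_width": 28.0,
        "barbule_width": 28.0, "interbarbule_distance": 55.0,
        "barb_barbule_angle": 40.0, "barbule_length": 250.0})
    micro_female_mean: dict = field(default_factory=lambda: {
        "max_barb_width": 22.0, "topdown_barb_width": 20.0,
        "barbule_width": 14.0, "interbarbule_distance": 40.0,
        "barb_barbule_angle": 15.0, "barbule_length": 320.0})
    micro_cv: float = 0.15
    flag_prob_male: float = 0.9
    flag_prob_female: float = 0.1

    def wavelengths(self) -> np.ndarray:
        return np.arange(self.grid_start, self.grid_stop + self.grid_step / 2,
                         self.grid_step)

    def species_names(self) -> list:
        return [f"sp{i+1:02d}" for i in range(self.n_species)]


def gen_tree(cfg: SyntheticConfig) -> dendropy.Tree:
    """Pure-birth (Yule) tree with unit root-to-tip depth, seeded.

    Waiting times between speciation events are exponential with rate equal
    to the number of extant lineages; a uniformly chosen lineage splits.
    The tree is emitted as newick and parsed back, so the same seed always
    yields the same newick string.
    """
    if cfg.n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(cfg.seed)
    names = cfg.species_names()
    # root = the first split (MRCA at depth 0, no stem)
    c1 = {"birth": 0.0, "children": None}
    c2 = {"birth": 0.0, "children": None}
    root = {"birth": 0.0, "split": 0.0, "children": [c1, c2]}
    active = [c1, c2]
    t = 0.0
    while len(active) < cfg.n_species:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(int(rng.integers(len(active))))
        node["split"] = t
        node["children"] = [{"birth": t, "children": None},
                            {"birth": t, "children": None}]
        active.extend(node["children"])
    t_end = t + rng.exponential(1.0 / len(active))
    for name, leaf in zip(names, active):
        leaf["name"] = name

    def newick(node):
        end = node.get("split", t_end)
        bl = (end - node["birth"]) / t_end     # scale to unit depth
        if node["children"] is None:
            return f"{node['name']}:{bl:.10f}"
        inner = ",".join(newick(c) for c in node["children"])
        return f"({inner}):{bl:.10f}"

    return dendropy.Tree.get(data=newick(root) + ";", schema="newick")


def _sigmoid(w, a, b, c, r0):
    return r0 + a / (1.0 + np.exp(-(w - b) / c))


def gen_spectra(cfg: SyntheticConfig) -> list:
    """Reflectance spectra: 3 replicates x 7 patches x {90°, 45°} x 2 sexes x n species.

    Colorful patches follow the logistic edge (females carry the melanin
    baseline r0 > 0); black patches are flat and low, with the female black
    rising gently toward 700 nm.  At 45° incidence matte male patches gain
    brightness (directional structural absorption); Gaussian noise is added
    and clipped at zero.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    w = cfg.wavelengths()
    out = []
    for sp in cfg.species_names():
        for sex in ("M", "F"):
            for patch in PATCH_SET:
                colorful = patch in COLORFUL_PATCHES
                for incidence in (90, 45):
                    noise = cfg.noise_sd if colorful else cfg.noise_sd_black
                    if colorful:
                        a = cfg.a_male if sex == "M" else cfg.a_female
                        r0 = cfg.r0_male if sex == "M" else cfg.r0_female
                        base = _sigmoid(w, a, cfg.b_nm, cfg.c_nm, r0)
                    else:
                        if sex == "M":
                            base = np.full_like(w, cfg.black_male)
                            if incidence == 45:   # velvet directionality
                                base = base + 0.055
                        else:
                            base = (cfg.black_female
                                    + cfg.black_female_slope
                                    * (w - w[0]) / (w[-1] - w[0]))
                    for rep in range(1, 4):
                        r = np.clip(base + rng.normal(0, noise, w.size), 0, None)
                        out.append(ReflectanceSpectrum(
                            w.copy(), r, species=sp, sex=sex, patch=patch,
                            incidence_deg=incidence, replicate_id=rep))
    return out


def gen_pigments(cfg: SyntheticConfig, tree: dendropy.Tree):
    """Male/female pigment tables with known cross-sex structure.

    Male log signals are Gaussian; female log signal =
    slope * male + family effect + phylogenetic (BM) effect + residual.
    Returns ``(male_table, female_table, truth)`` where ``truth`` records the
    generating parameters and realized random effects.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    species = tip_labels(tree)
    n_sp = len(species)
    fam_names = [f"fam{i+1}" for i in range(cfg.n_families)]
    # each molecule belongs to a family; every family gets at least one
    fam_of_mol = list(range(cfg.n_families)) + list(
        rng.integers(0, cfg.n_families, cfg.n_molecules - cfg.n_families))
    rng.shuffle(fam_of_mol)
    fam_eff = rng.normal(0, cfg.sd_family, cfg.n_families)
    C = brownian_cov(tree, 1.0, species).to_numpy()
    phylo_eff = (np.linalg.cholesky(C + 1e-10 * np.eye(n_sp))
                 @ rng.standard_normal(n_sp)) * cfg.sd_phylo

    rows_m, rows_f = [], []
    for si, sp in enumerate(species):
        for mi in range(cfg.n_molecules):
            male = rng.normal(cfg.male_log_mean, cfg.male_log_sd)
            female = (cfg.slope * male + fam_eff[fam_of_mol[mi]]
                      + phylo_eff[si]
                      + rng.normal(0, cfg.sd_residual))
            base = {"species": sp, "patch": "rump",
                    "molecule_id": f"mol{mi+1:02d}",
                    "family": fam_names[fam_of_mol[mi]],
                    "accurate_mass": 500.0 + 10.0 * fam_of_mol[mi],
                    "sample_weight": 1.0}
            # tables carry raw intensities; the model scale is log10
            rows_m.append({**base, "sex": "M", "specimen_id": f"{sp}_M",
                           "signal": 10.0 ** male})
            rows_f.append({**base, "sex": "F", "specimen_id": f"{sp}_F",
                           "signal": 10.0 ** female})
    truth = {"slope": cfg.slope, "sd_family": cfg.sd_family,
             "sd_phylo": cfg.sd_phylo, "sd_residual": cfg.sd_residual,
             "family_effects": dict(zip(fam_names, fam_eff)),
             "phylo_effects": dict(zip(species, phylo_eff)),
             "family_of_molecule": {f"mol{m+1:02d}": fam_names[fam_of_mol[m]]
                                    for m in range(cfg.n_molecules)}}
    return pd.DataFrame(rows_m), pd.DataFrame(rows_f), truth


def paired_pigment_frame(male: pd.DataFrame, female: pd.DataFrame,
                         *, log10: bool = True) -> pd.DataFrame:
    """Merge the sex tables into the mixed-model layout.

    With ``log10=True`` (the modelling scale) signals are log-transformed,
    using an epsilon of one tenth of the smallest positive signal for zeros.
    """
    m = male[["species", "family", "molecule_id", "signal"]].rename(
        columns={"signal": "male"})
    f = female[["species", "family", "molecule_id", "signal"]].rename(
        columns={"signal": "female"})
    out = m.merge(f, on=["species", "family", "molecule_id"])
    if log10:
        for col in ("male", "female"):
            v = out[col].to_numpy(dtype=float)
            pos = v[v > 0]
            eps = pos.min() / 10.0 if len(pos) else 1e-12
            out[col] = np.log10(v + eps)
    return out


def gen_microstructure(cfg: SyntheticConfig) -> pd.DataFrame:
    """Microstructure tables: male rows larger/more oblong, flags sex-biased.

    Exactly one female (the first species) is a male-like outlier with all
    flags set and male-scale measurements, emulating the one species whose
    females share the elaborate morphology.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    rows = []
    species = cfg.species_names()
    outlier = species[0]
    for sp in species:
        for sex in ("M", "F"):
            male_like = sex == "M" or sp == outlier
            means = cfg.micro_male_mean if male_like else cfg.micro_female_mean
            p_flag = 1.0 if (sex == "F" and sp == outlier) else (
                cfg.flag_prob_male if sex == "M" else cfg.flag_prob_female)
            row = {"species": sp, "sex": sex, "patch": "rump"}
            for key, mu in means.items():
                row[key] = max(rng.normal(mu, cfg.micro_cv * mu), 0.05 * mu)
            row["strap_shaped"] = bool(rng.random() < p_flag)
            row["angled_3d"] = bool(rng.random() < p_flag)
            rows.append(row)
    return pd.DataFrame(rows)


def gen_all(cfg: SyntheticConfig, out_dir=None) -> dict:
    """Generate the full synthetic bundle; optionally write it to ``out_dir``.

    Writes spectra.csv, pigments.csv (both sexes stacked), microstructure.csv,
    tree.nwk and truth.json when a directory is given.
    """
    import json
    from pathlib import Path

    from .spectra import write_spectra

    tree = gen_tree(cfg)
    spectra = gen_spectra(cfg)
    male, female, truth = gen_pigments(cfg, tree)
    micro = gen_microstructure(cfg)
    bundle = {"tree": tree, "spectra": spectra, "pigments_male": male,
              "pigments_female": female, "microstructure": micro,
              "truth": truth, "config": cfg}
    if out_dir is not None:
        d = Path(out_dir)
        d.mkdir(parents=True, exist_ok=True)
        write_spectra(spectra, d / "spectra.csv")
        pd.concat([male, female]).to_csv(d / "pigments.csv", index=False)
        micro.to_csv(d / "microstructure.csv", index=False)
        tree.write(path=str(d / "tree.nwk"), schema="newick")
        clean = {k: v for k, v in truth.items() if k != "interpolate"}
        with open(d / "truth.json", "w") as fh:
            json.dump(clean, fh, indent=1, default=float)
    return bundle
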