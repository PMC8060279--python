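"""End-to-end orchestration: spectra metrics -> paired tests -> pigments ->
mixed model -> microstructure PCA/PGLS -> FDTD campaigns -> curve matching.

Each stage writes plain CSV/JSON into the output directory and the run ends
with a provenance log (config hash, seeds, package versions).  Stages are
independent library calls; a failure aborts with a stage-tagged error while
earlier outputs stay on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .errors import PlumageError

log = logging.getLogger("plumage")


@dataclass
class PipelineConfig:
    out_dir: str = "plumage_out"
    seed: int = 0
    synthetic: bool = True
    spectra_path: Optional[str] = None
    pigments_path: Optional[str] = None
    microstructure_path: Optional[str] = None
    tree_path: Optional[str] = None
    fdtd_profile: str = "coarse"      # "paper" | "coarse"
    chain_profile: str = "fast"       # "paper" | "fast" | "smoke"
    run_fdtd_stage: bool = True
    log_level: str = "INFO"

    def validate(self):
        if not self.synthetic:
            for name in ("spectra_path", "pigments_path",
                         "microstructure_path", "tree_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise PlumageError(f"input file for {name} missing: {p}")
        if self.fdtd_profile not in ("paper", "coarse"):
            raise PlumageError(f"unknown FDTD profile {self.fdtd_profile!r}")
        if self.chain_profile not in ("paper", "fast", "smoke"):
            raise PlumageError(f"unknown chain profile {self.chain_profile!r}")


class StageError(PlumageError):
    def __init__(self, stage, exc):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def _hash_config(cfg: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True).encode()).hexdigest()[:16]


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns a report dict and writes files."""
    from . import curvefit, microstructure, mixedmodel, phylo, pigments, spectra, synth
    from .fdtd import COARSE_PROFILE, PAPER_PROFILE
    from .fdtd.analysis import male_female_power_experiment, reflectance_vs_barbule_angle

    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)
    t_start = time.time()
    report = {"config": asdict(cfg), "config_hash": _hash_config(cfg),
              "seed": cfg.seed, "version": __version__}

    # ---- inputs -----------------------------------------------------------
    stage = "inputs"
    try:
        if cfg.synthetic:
            scfg = synth.SyntheticConfig(seed=cfg.seed)
            bundle = synth.gen_all(scfg, out / "synthetic")
            tree = bundle["tree"]
            all_spectra = bundle["spectra"]
            pig = pd.concat([bundle["pigments_male"], bundle["pigments_female"]])
            micro = bundle["microstructure"]
            input_files = sorted((out / "synthetic").glob("*"))
        else:
            tree = phylo.read_tree(cfg.tree_path)
            all_spectra = spectra.read_spectra(cfg.spectra_path)
            pig = pigments.read_pigments(cfg.pigments_path)
            micro = microstructure.read_microstructure(cfg.microstructure_path)
            input_files = [Path(p) for p in (cfg.spectra_path, cfg.pigments_path,
                                             cfg.microstructure_path, cfg.tree_path)]
        report["input_hashes"] = {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()[:16]
            for p in input_files}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- spectral metrics and paired tests --------------------------------
    stage = "spectra"
    try:
        metrics = spectra.metrics_table(all_spectra)
        metrics.to_csv(out / "spectral_metrics.csv", index=False)
        m90 = metrics[metrics.incidence_deg == 90]
        # most saturated colorful patch and darkest patch per (species, sex)
        sat, dark = {}, {}
        for (sp, sex), grp in m90.groupby(["species", "sex"]):
            colorful = grp[grp.peak_reflectance > 0.05]
            pick = (colorful if len(colorful) else grp).nlargest(1, "peak_reflectance")
            sat[(sp, sex)] = float(pick["saturation_lwhm"].iloc[0])
            dark[(sp, sex)] = float(grp.nsmallest(1, "brightness")["brightness"].iloc[0])
        species = sorted({k[0] for k in sat})
        sat_m = pd.Series({s: sat[(s, "M")] for s in species})
        sat_f = pd.Series({s: sat[(s, "F")] for s in species})
        # darkness compared on the percent scale (integrated reflectance)
        dark_m = pd.Series({s: dark[(s, "M")] * 100 for s in species})
        dark_f = pd.Series({s: dark[(s, "F")] * 100 for s in species})
        tt_sat = phylo.phylo_paired_ttest(sat_f, sat_m, tree)   # F - M > 0
        tt_dark = phylo.phylo_paired_ttest(dark_f, dark_m, tree)
        report["spectra"] = {
            "saturation_test": {"t": tt_sat.t, "p": tt_sat.p, "ci": tt_sat.ci,
                                "mean_difference": tt_sat.mean_difference,
                                "lambda": tt_sat.lam},
            "darkness_test": {"t": tt_dark.t, "p": tt_dark.p, "ci": tt_dark.ci,
                              "mean_difference": tt_dark.mean_difference,
                              "lambda": tt_dark.lam},
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- pigments + mixed model -------------------------------------------
    stage = "pigments"
    try:
        pig = pigments.normalize_signals(pig)
        pig.to_csv(out / "pigments_normalized.csv", index=False)
        male = pig[pig.sex == "M"]
        female = pig[pig.sex == "F"]
        data = synth.paired_pigment_frame(male, female)
        chain = {"paper": mixedmodel.MixedModelSpec(seed=cfg.seed),
                 "fast": mixedmodel.MixedModelSpec.fast(seed=cfg.seed),
                 "smoke": mixedmodel.MixedModelSpec.smoke(seed=cfg.seed)}[cfg.chain_profile]
        mm = mixedmodel.fit(chain, data, tree)
        ratio = mixedmodel.predict_fm_ratio(mm, n_subsample=min(50, len(data) // 2),
                                            seed=cfg.seed)
        mm.table.to_csv(out / "mixedmodel_summary.csv")
        mm.samples.to_csv(out / "mixedmodel_samples.csv", index=False)
        report["pigments"] = {"slope": mm.slope, "slope_ci": mm.slope_ci,
                              "dic": mm.dic, "lambda": mm.lam,
                              "fm_ratio": ratio["mean"]}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- microstructure: flags, PCA, PGLS ---------------------------------
    stage = "microstructure"
    try:
        flagged = microstructure.derive_flags(micro)
        flagged.to_csv(out / "microstructure_flags.csv", index=False)
        M, keys = microstructure.prepare_pca_matrix(micro)
        table = pd.DataFrame(M, columns=microstructure.CONTINUOUS_COLUMNS,
                             index=pd.MultiIndex.from_frame(keys))
        p = phylo.pca(table, log=False)   # measurements already log-transformed
        pd.concat([keys.reset_index(drop=True),
                   p["scores"].reset_index(drop=True)], axis=1).to_csv(
            out / "microstructure_pca_scores.csv", index=False)
        sexes = keys["sex"].to_numpy()
        sep = microstructure.sex_separation_report(
            p["scores"].to_numpy(), sexes, seed=cfg.seed)
        # PGLS: male saturation ~ male microstructure PC2 + PC1
        male_rows = keys.sex == "M"
        male_scores = p["scores"][male_rows.to_numpy()].copy()
        male_scores.index = keys.loc[male_rows.to_numpy(), "species"].to_numpy()
        male_scores = male_scores.groupby(level=0).mean()
        ydat = sat_m.loc[male_scores.index]
        res_pgls = phylo.pgls(ydat, male_scores[["PC2", "PC1"]], tree)
        # cross-sex PC1 correlation
        f_scores = p["scores"][(keys.sex == "F").to_numpy()].copy()
        f_scores.index = keys.loc[(keys.sex == "F").to_numpy(), "species"].to_numpy()
        f_scores = f_scores.groupby(level=0).mean()
        res_cross = phylo.pgls(f_scores["PC1"], male_scores[["PC1"]], tree)
        report["microstructure"] = {
            "variance_fraction": p["variance_fraction"].to_dict(),
            "sex_separation_p": sep["p"],
            "pgls_saturation_pc2": float(res_pgls["coefficients"]["PC2"]),
            "pgls_saturation_pc2_p": float(res_pgls["p"]["PC2"]),
            "pgls_cross_sex_pc1": float(res_cross["coefficients"]["PC1"]),
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- ancestral reconstruction of summed log pigment families ----------
    stage = "ancestral"
    try:
        fam = pigments.sum_isomers(pig, log10=True)
        anc = {}
        for (sex, family), grp in fam.groupby(["sex", "family"]):
            vals = grp.set_index("species")["log10_signal"]
            vals = vals[~vals.isna()]
            if len(set(phylo.tip_labels(tree)) - set(vals.index)) > 0:
                continue  # species missing data are skipped for that family
            rec = phylo.ancestral_states(tree, vals)
            anc[f"{sex}:{family}"] = rec["root_state"]
        with open(out / "ancestral_root_states.json", "w") as fh:
            json.dump(anc, fh, indent=1)
        report["ancestral"] = {"n_reconstructions": len(anc)}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- FDTD campaigns ----------------------------------------------------
    if cfg.run_fdtd_stage:
        stage = "fdtd"
        try:
            prof = PAPER_PROFILE if cfg.fdtd_profile == "paper" else COARSE_PROFILE
            prof = prof.with_(mesh_nm=40.0, wavelengths_nm=(500.0, 600.0, 700.0)) \
                if cfg.fdtd_profile == "coarse" else prof
            L = 80.0 if cfg.fdtd_profile == "paper" else 20.0
            sweep = reflectance_vs_barbule_angle(
                [0, 20, 40, 60, 80], prof, barbule_length=L)
            sweep.to_csv(out / "fdtd_angle_sweep.csv", index=False)
            pw = male_female_power_experiment(
                prof.with_(mesh_nm=75.0) if cfg.fdtd_profile == "coarse" else prof)
            pw["table"].to_csv(out / "fdtd_power_pairs.csv", index=False)
            report["fdtd"] = {
                "R_theta0_pct": float(sweep.R_mean.iloc[0] * 100),
                "R_theta80_pct": float(sweep.R_mean.iloc[-1] * 100),
                "power_mean_difference": pw["mean_difference"],
                "power_p": pw["p"],
            }
        except Exception as exc:
            raise StageError(stage, exc) from exc
    else:
        sweep = None

    # ---- curve matching ----------------------------------------------------
    stage = "curvefit"
    try:
        by_key = {}
        for s in all_spectra:
            by_key.setdefault(s.key, []).append(s)
        rump_f = spectra.average_replicates(
            by_key[(species[0], "F", "rump", 90)])
        rump_m = spectra.average_replicates(
            by_key[(species[0], "M", "rump", 90)])
        match = curvefit.melanin_barb_pipeline(rump_f, rump_m)
        cf_report = {"hausdorff_before": match.hausdorff_before,
                     "hausdorff_after": match.hausdorff_after,
                     "improved": match.improved}
        if sweep is not None:
            div35 = curvefit.angle_to_divisor(35.0, sweep)
            cf_report["divisor_35deg"] = div35
        with open(out / "curvefit_report.json", "w") as fh:
            json.dump(cf_report, fh, indent=1)
        report["curvefit"] = cf_report
    except Exception as exc:
        raise StageError(stage, exc) from exc

    report["runtime_s"] = time.time() - t_start
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    log.info("pipeline complete in %.1f s", report["runtime_s"])
    return report
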