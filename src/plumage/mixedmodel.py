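"""Gibbs-sampled Gaussian mixed model for cross-sex pigment concordance.

The response is the female normalized log pigment signal per
(species, family, molecule) row; the fixed part is an intercept plus the
male signal of the same molecule; random intercepts capture pigment family
(LC-MS response factors differ between families) and phylogeny (a species
effect with Brownian covariance C from the tree):

    female = b0 + b1 * male + u_family + u_species + e,
    u_family ~ N(0, s_f^2 I),  u_species ~ N(0, s_p^2 C),  e ~ N(0, s_e^2 I).

All conditionals are conjugate, so the model is sampled with a blocked
Gibbs sampler: (b, u) jointly from their multivariate normal conditional,
and each variance from a scaled inverse chi-square with inverse-gamma prior
(V = 1, nu = 0.002 by default, the conventional weakly informative choice).
Phylogenetic signal lambda is summarized as the posterior mean of
s_p^2 / (s_p^2 + s_f^2 + s_e^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import linalg

from .errors import ESSWarning, PlumageError
from .phylo import brownian_cov, tip_labels

DATA_COLUMNS = ["species", "family", "molecule_id", "male", "female"]


@dataclass
class MixedModelSpec:
    iterations: int = 1_000_000
    burn_in: int = 100_000
    thinning: int = 500
    prior_v: float = 1.0         # inverse-gamma V, shared by all components
    prior_nu: float = 0.002      # inverse-gamma nu ("low belief" default)
    seed: int = 0

    def __post_init__(self):
        if self.iterations <= self.burn_in:
            raise PlumageError("iterations must exceed burn-in")
        if self.thinning < 1:
            raise PlumageError("thinning must be >= 1")

    @classmethod
    def fast(cls, seed: int = 0) -> "MixedModelSpec":
        """Reduced chain for tests and desk runs (50k / 5k / 50)."""
        return cls(iterations=50_000, burn_in=5_000, thinning=50, seed=seed)

    @classmethod
    def smoke(cls, seed: int = 0) -> "MixedModelSpec":
        """Very short chain for smoke tests (5k / 500 / 5)."""
        return cls(iterations=5_000, burn_in=500, thinning=5, seed=seed)


@dataclass
class PosteriorSummary:
    table: pd.DataFrame            # mean, ci_low, ci_high, ess, pmcmc per parameter
    samples: pd.DataFrame          # stored thinned draws
    dic: float
    lam: float                     # phylogenetic signal
    spec: MixedModelSpec
    blup: pd.Series                # posterior-mean random effects
    fixed_names: tuple = ("intercept", "male")

    @property
    def slope(self) -> float:
        return float(self.table.loc["male", "mean"])

    @property
    def slope_ci(self) -> tuple:
        row = self.table.loc["male"]
        return (float(row["ci_low"]), float(row["ci_high"]))


def _ess(x: np.ndarray) -> float:
    """Effective sample size via the initial-positive-sequence estimator."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.ptp(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1))
    acf = acf / acf[0]
    s = 0.0
    for k in range(1, n // 2):
        pair = acf[2 * k - 1] + acf[2 * k] if 2 * k < len(acf) else 0.0
        if pair <= 0:
            break
        s += pair
    return float(min(n, n / (1.0 + 2.0 * s)))


def _invgamma_draw(rng, shape, scale):
    return scale / rng.gamma(shape)


def fit(spec: MixedModelSpec, data: pd.DataFrame, tree) -> PosteriorSummary:
    """Run the Gibbs sampler; deterministic given the spec's seed.

    ``data`` has columns [species, family, molecule_id, male, female]; every
    species must be a tip of ``tree``.  The species-level phylogenetic
    effect is shared by all rows of a species.
    """
    missing = [c for c in DATA_COLUMNS if c not in data.columns]
    if missing:
        raise PlumageError(f"mixed-model data missing columns: {missing}")
    labels = tip_labels(tree)
    bad = set(data["species"]) - set(labels)
    if bad:
        raise PlumageError(f"species not in tree: {sorted(bad)}")
    used = [l for l in labels if l in set(data["species"])]
    C = brownian_cov(tree, 1.0, used).to_numpy()
    # guard against numerically non-PD covariance
    try:
        Cinv = linalg.inv(C)
        linalg.cholesky(C)
    except linalg.LinAlgError as exc:
        raise PlumageError(f"phylogenetic covariance not positive definite: {exc}")

    y = data["female"].to_numpy(dtype=float)
    x = data["male"].to_numpy(dtype=float)
    fams = sorted(data["family"].unique())
    n = len(y)
    qf, qp = len(fams), len(used)
    Zf = np.zeros((n, qf))
    Zf[np.arange(n), [fams.index(f) for f in data["family"]]] = 1.0
    Zp = np.zeros((n, qp))
    Zp[np.arange(n), [used.index(s) for s in data["species"]]] = 1.0
    W = np.column_stack([np.ones(n), x, Zf, Zp])
    q = W.shape[1]
    WtW = W.T @ W
    Wty = W.T @ y

    rng = np.random.default_rng(spec.seed)
    nu, V = spec.prior_nu, spec.prior_v
    s2f = s2p = s2e = 1.0
    theta = np.zeros(q)
    beta_prec = 1e-8  # effectively flat prior on the fixed effects

    kept_rows = []
    n_kept = (spec.iterations - spec.burn_in) // spec.thinning
    dev_samples = np.zeros(n_kept)
    blup_acc = np.zeros(q)
    ki = 0
    for it in range(spec.iterations):
        # (beta, u) | variances: one joint Gaussian draw
        M = WtW / s2e
        M[0, 0] += beta_prec
        M[1, 1] += beta_prec
        M[2:2 + qf, 2:2 + qf] += np.eye(qf) / s2f
        M[2 + qf:, 2 + qf:] += Cinv / s2p
        cf = linalg.cho_factor(M, lower=True)
        mean = linalg.cho_solve(cf, Wty / s2e)
        z = rng.standard_normal(q)
        theta = mean + linalg.solve_triangular(cf[0], z, lower=True, trans="T")
        uf = theta[2:2 + qf]
        up = theta[2 + qf:]
        resid = y - W @ theta
        # variances | effects: scaled inverse chi-square
        s2e = _invgamma_draw(rng, (nu + n) / 2.0, (nu * V + resid @ resid) / 2.0)
        s2f = _invgamma_draw(rng, (nu + qf) / 2.0, (nu * V + uf @ uf) / 2.0)
        s2p = _invgamma_draw(rng, (nu + qp) / 2.0,
                             (nu * V + up @ Cinv @ up) / 2.0)
        if it >= spec.burn_in and (it - spec.burn_in) % spec.thinning == 0 and ki < n_kept:
            dev_samples[ki] = n * np.log(2 * np.pi * s2e) + (resid @ resid) / s2e
            blup_acc += theta
            kept_rows.append((theta[0], theta[1], s2f, s2p, s2e))
            ki += 1

    cols = ["intercept", "male", "var_family", "var_phylo", "var_residual"]
    samples = pd.DataFrame(kept_rows, columns=cols)
    blup = pd.Series(blup_acc / max(ki, 1),
                     index=(["intercept", "male"] + [f"family:{f}" for f in fams]
                            + [f"species:{s}" for s in used]))

    rows = {}
    for c in cols:
        s = samples[c].to_numpy()
        lo, hi = np.percentile(s, [2.5, 97.5])
        pm = float(np.mean(s))
        pg = float(np.mean(s > 0))
        rows[c] = {"mean": pm, "ci_low": float(lo), "ci_high": float(hi),
                   "ess": _ess(s), "pmcmc": float(2 * min(pg, 1 - pg))}
    table = pd.DataFrame(rows).T

    if table["ess"].min() < 200:
        import warnings
        warnings.warn(f"minimum effective sample size "
                      f"{table['ess'].min():.0f} < 200", ESSWarning)

    # DIC = mean deviance + pD, pD = mean deviance - deviance at posterior mean
    theta_bar = blup.to_numpy()
    resid_bar = y - W @ theta_bar
    s2e_bar = float(samples["var_residual"].mean())
    d_at_mean = n * np.log(2 * np.pi * s2e_bar) + (resid_bar @ resid_bar) / s2e_bar
    d_bar = float(np.mean(dev_samples[:ki]))
    dic = 2 * d_bar - d_at_mean

    lam = float(np.mean(samples["var_phylo"]
                        / (samples["var_phylo"] + samples["var_family"]
                           + samples["var_residual"])))
    summary = PosteriorSummary(table, samples, float(dic), lam, spec, blup)
    summary._design = {"W": W, "data": data.reset_index(drop=True)}
    return summary


def dic(fit_result: PosteriorSummary) -> float:
    return fit_result.dic


def autocorrelation_check(fit_result: PosteriorSummary,
                          threshold: float = 0.1) -> pd.Series:
    """Lag-1 autocorrelation of the stored (thinned) chains vs threshold."""
    if len(fit_result.samples) < 100:
        raise PlumageError("need at least 100 stored samples")
    out = {}
    for c in fit_result.samples.columns:
        s = fit_result.samples[c].to_numpy()
        sc = s - s.mean()
        denom = float(sc @ sc)
        r1 = float(sc[:-1] @ sc[1:]) / denom if denom > 0 else 0.0
        out[c] = abs(r1) < threshold
    return pd.Series(out)


def predict_fm_ratio(fit_result: PosteriorSummary, data: Optional[pd.DataFrame] = None,
                     n_subsample: int = 50, reps: int = 100,
                     seed: int = 0) -> dict:
    """Female:male pigment ratio by repeated subsampled model prediction.

    Each repetition draws ``n_subsample`` rows, predicts their female values
    from the posterior-mean fixed and random effects, and forms
    sum(predicted female) / sum(real male).
    """
    design = getattr(fit_result, "_design", None)
    if design is None:
        raise PlumageError("fit carries no design information")
    W = design["W"]
    if data is None:
        data = design["data"]
    if n_subsample > len(data):
        raise PlumageError(
            f"subsample {n_subsample} exceeds data size {len(data)}")
    pred = W @ fit_result.blup.to_numpy()
    male = data["male"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    est = np.empty(reps)
    for r in range(reps):
        idx = rng.choice(len(data), size=n_subsample, replace=False)
        denom = male[idx].sum()
        est[r] = pred[idx].sum() / denom if denom != 0 else np.nan
    est = est[np.isfinite(est)]
    return {"estimates": est, "mean": float(np.mean(est)), "reps": int(len(est))}


def fit_variants(spec: MixedModelSpec, data: pd.DataFrame, tree,
                 *, apo_family: str = "apo-8-carotenal") -> dict:
    """The four sensitivity variants: all isomers, all minus apo-8-carotenal,
    summed isomers, summed minus apo-8-carotenal."""
    out = {"all": fit(spec, data, tree)}
    no_apo = data[data["family"] != apo_family]
    out["all-minus-apo"] = fit(spec, no_apo, tree)

    def summed(d):
        g = (d.groupby(["species", "family"], as_index=False)
             .agg(male=("male", "sum"), female=("female", "sum")))
        g["molecule_id"] = g["family"]
        return g

    out["sum"] = fit(spec, summed(data), tree)
    out["sum-minus-apo"] = fit(spec, summed(no_apo), tree)
    return out
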