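# plumage

Feather color metrics, 2D electromagnetic simulation of feather
microstructure, carotenoid LC-MS profile statistics, and phylogenetic
comparative methods — a reusable pipeline for studying how feather
*microstructure*, rather than pigment, drives male–female color differences
in carotenoid-colored birds such as *Ramphocelus* tanagers.

Males of these species carry the same carotenoid pigments as females, yet
look far more saturated, and some patches are "super black" or "velvet
red". Two microstructures explain much of the gap:

* **Dihedral barbules** — strap-shaped barbules angled up out of the
  feather plane form V-grooves that trap light: keratin-only reflectance
  falls from ~4–5 % (flat surface, Fresnel) toward ~0.5 % at steep angles.
* **Oblong, expanded barbs** — the male's larger elliptical barb cross
  section acts as a cylindrical lens, focusing more optical power through
  the pigmented keratin (more light–pigment interaction for the same
  pigment), which behaves as an amplitude gain on the carotenoid
  reflectance edge R(λ) = r₀ + a/(1 + e^{−(λ−b)/c}).

The package implements, per module: reflectance spectra IO and color
metrics (brightness ∫R dλ/400; saturation as leftwards width at
half-maximum; super-black/velvet-red classification; 45°/90°
directionality) — `plumage.spectra`; a 2D Yee-grid FDTD solver with
periodic x boundaries, split-field PML, CW steady-state phasor monitors,
and feather scene builders for both campaigns — `plumage.fdtd`; sigmoid
curve fitting, melanin removal, barb enhancement, structural divisors and
Hausdorff curve matching — `plumage.curvefit`; LC-MS signal normalization,
5 ppm accurate-mass family assignment, repeatability regressions and
summed-isomer views — `plumage.pigments`; Brownian covariance,
phylogenetic paired t-tests, PGLS (BM/OU), standard and phylogenetic PCA,
and ML ancestral states — `plumage.phylo`; a blocked Gibbs sampler for the
cross-sex pigment mixed model with family and phylogenetic random
effects — `plumage.mixedmodel`; microstructure feature flags —
`plumage.microstructure`; seeded synthetic-data generators with known
ground truth — `plumage.synth`; and an orchestrating CLI —
`plumage.cli` / `plumage.pipeline`.

See `docs/methods.md` for the models, conventions and their rationale.

## Worked example

Generate a synthetic plumage bundle and compare a male and female colorful
patch, then test whether removing the female's melanin baseline and
boosting the carotenoid edge to the male amplitude reproduces his spectrum:

```python
from plumage.synth import SyntheticConfig, gen_spectra
from plumage.spectra import average_replicates, metrics_table
from plumage.curvefit import melanin_barb_pipeline

spectra = gen_spectra(SyntheticConfig(seed=42))
table = metrics_table([s for s in spectra
                       if s.species == "sp01" and s.patch == "rump"
                       and s.incidence_deg == 90])
print(table[["sex", "brightness", "saturation_lwhm", "peak_reflectance"]]
      .round(4).to_string(index=False))

groups = {}
for s in spectra:
    groups.setdefault(s.key, []).append(s)
female = average_replicates(groups[("sp01", "F", "rump", 90)])
male = average_replicates(groups[("sp01", "M", "rump", 90)])
match = melanin_barb_pipeline(female, male, a_male=0.06,
                              fixed={"b": 620.0, "c": 22.0})
print(f"Hausdorff before manipulation: {match.hausdorff_before:.2f}")
print(f"Hausdorff after melanin removal + barb enhancement: {match.hausdorff_after:.2f}")
```

which prints

```
sex  brightness  saturation_lwhm  peak_reflectance
  M      0.0123          82.0139            0.0591
  F      0.0140          99.8744            0.0301
Hausdorff before manipulation: 2.95
Hausdorff after melanin removal + barb enhancement: 0.17
```

The male's left width at half maximum (82 nm) is narrower than the
female's (100 nm): his color is more saturated even though his overall
brightness is similar. The manipulated female curve matches the male
seventeen times more closely than the raw one (Hausdorff 0.17 vs 2.95, in
nm/percent units) — melanin plus barb structure accounts for the gap.

The same analyses run from the shell:

```bash
plumage synth all --seed 42 --out bundle/
plumage spectra metrics --in bundle/spectra.csv --out metrics.csv
plumage fdtd sweep-angle --angles 0:80:5 --profile coarse --out sweep.csv
plumage fdtd barb --sex male --variant whole --out male_power.csv
plumage mixedmodel --pigments bundle/pigments.csv --tree bundle/tree.nwk \
    --fast --out posterior.json
plumage run --seed 42 --out run_out/        # full pipeline
```

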