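# dermaquant

Quantitative image analysis of **particle-assisted dermal penetration**.

When a topical formulation containing dispersed particles (e.g. TiO₂ or
nanostructured lipid carriers, NLC) dries on skin, aqueous menisci form
between the particles and the skin surface, prolonging contact and
driving dissolved actives into the tissue.  The standard read-out for
this effect is digital image analysis of fluorescence micrographs of
vertical skin sections after applying a formulation spiked with sodium
fluorescein as a surrogate active ingredient.  `dermaquant` implements
that analysis as a tested, reusable pipeline for formulation scientists:

* **Particle sizing** — ImageJ-style dispersion analysis: 8-bit
  conversion, brightness threshold (≥ 80 grey values), 8-connected
  components, maximum-caliper (**Feret**) diameters over the
  pixel-corner polygon, and a 0.4 µm artefact filter.
* **Penetration quantification** — autofluorescence subtraction by an
  RGB green-dominance threshold (`G ≥ g_min` and `G − max(R,B) ≥
  margin`); **ART** (amount after RGB threshold, in mean grey value per
  pixel of the tissue region); **MPD** (mean penetration depth, µm,
  measured from a per-column detected skin surface); **SCT** (stratum
  corneum thickness, µm) and relative SCT in % of untreated control;
  TEWL > 15 g/cm²/h barrier-integrity exclusion.
* **Statistics** — the decision tree Shapiro–Wilk → Levene → {ANOVA +
  Tukey | Welch ANOVA + Games–Howell | Kruskal–Wallis + Dunn(Holm)},
  star labels (\* ≤ 0.05, \*\* ≤ 0.01, \*\*\* ≤ 0.001), and clustering
  of formulations by connecting pairs that are not significantly
  different.
* **Synthetic micrographs** — a seeded generator of ground-truthed skin
  sections and particle dispersions, so every stage is verifiable
  without animal tissue.  Registered formulation presets encode the
  study arms (penetration front 43 / 80 / 110 µm; relative amounts 1.0
  / 1.6 / 2.0; SCT 100–115 % of untreated).

## Worked example

```python
from dermaquant import RunConfig, run_pipeline

bundle = run_pipeline(RunConfig(
    design=[("control", "control_groupI", 20),
            ("nlc_20pct", "nlc_groupIII", 20)],
    seed=20_260_102, reference="control",
))
print(bundle.per_group[["group", "n", "art_mean", "depth_mean"]])
print(bundle.fold_change)
```

prints (numbers from this exact seed):

```
       group   n   art_mean  depth_mean
0    control  19  30.951535   44.792439
1  nlc_20pct  17  59.868870  109.009942

       group  art_pct_change  depth_pct_change  sct_pct_change
0    control        0.000000          0.000000        0.000000
1  nlc_20pct       93.427788        143.366838        5.606871
```

i.e. the 20 % particle arm roughly **doubles the penetrated amount**
(ART +93 %) and carries the dye **2.4× deeper** (109 µm, past the
~100 µm epidermis into the dermis), while the particle-free control
reaches only the stratum corneum / upper epidermis (~45 µm).  One and
three images were excluded by the TEWL rule, hence n < 20.

The full analyses live under `analysis/`:

* `01_size_particles.py` — Feret sizing of the water vs surfactant
  TiO₂ dispersions,
* `02_particle_penetration_study.py` — the six-arm NLC concentration
  series with fold changes, region calls and penetration clusters,
* `03_humectant_study.py` — glycerol (hydration) vs particles, via
  relative SCT.

Each writes its tables to `results/`.

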