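# sgfound

Quantitative analyses for an X-linked distal myopathy caused by
aggregating missense mutations in the small muscle protein SMPX.
The package bundles, as one tested pipeline, the four computational
stages such a study needs:

1. **Stress-granule (SG) image quantification** — segment nuclei/cytoplasm
   in three-channel fluorescence images (Hoechst, V5-tagged SMPX, TIAL1),
   call transfected cells on V5 intensity, detect cytoplasmic TIAL1 spots,
   and classify each granule as V5-enriched by the *donut ratio*: the
   median V5 inside the spot divided by the median V5 in the surrounding
   5-px annulus, with granules scored enriched when the ratio exceeds 1.2.
2. **Repeated-measures statistics** — two-way within-subject ANOVA with
   the Greenhouse–Geisser sphericity correction and Dunnett's many-to-one
   comparisons against wild type, with the independent experiment as the
   pairing unit.
3. **Founder-haplotype dating** — detect the maximal X-chromosome segment
   shared by hemizygous carriers, measure it in Mb and cM, and date the
   founder mutation with the length-decay rule *g* = 200 / *L*(cM) at a
   25-year generation time.
4. **Rare-variant prioritization and protein-solubility statistics** —
   strict population-allele-frequency filtering (AF < 0.001), restriction
   to muscle-expressed genes, HGVS coding-coordinate arithmetic, and
   supernatant/pellet densitometry normalized to per-experiment wild type
   with exact Mann–Whitney U tests and Bonferroni correction.

Because raw microscopy and densitometry from such experiments are rarely
deposited, the package ships a first-class synthetic-data module that
generates every input with known ground truth (textured cells with
planted granules, carrier genotype panels with a planted shared segment,
densitometry tables with planted solubility shifts, toy variant lists),
so each stage can be validated by exact recovery of what was planted.

## Worked example

Simulate a two-construct stress experiment (4 independent replicates,
2 fields of ~30 cells per condition), quantify granules, and test a
planted mutant deficit of −0.8 SGs per transfected cell under MG132
stress (about one minute of compute):

```python
from sgfound.synthetic import SceneConfig, simulate_experiment
from sgfound.imaging import quantify_experiment
from sgfound.sgstats import aggregate_wells, RepeatedMeasuresAnova, DunnettComparison

design, seed = [], 0
for con in ("WT", "S78N"):
    for trt in ("NT", "MG"):
        for rep in range(1, 5):
            for _img in range(2):
                rate = {"NT": 0.4, "MG": 2.0}[trt]
                if con == "S78N" and trt == "MG":
                    rate = 1.2                      # planted stress deficit
                design.append((con, trt, rep,
                               SceneConfig(n_cells=30, sg_rate=rate,
                                           sg_rate_untransfected=rate, seed=seed)))
                seed += 1

images = quantify_experiment(simulate_experiment(design))
wells = aggregate_wells(images)
anova = RepeatedMeasuresAnova(wells, dv="mean_sg_per_cell",
                              within=("construct", "treatment"),
                              subject="replicate").fit()
print(anova.summary())
mg = wells[wells.treatment == "MG"]
print(DunnettComparison(mg, dv="mean_sg_per_cell", group="construct",
                        subject="replicate").fit().summary())
```

Output:

```
Repeated-measures ANOVA on 'mean_sg_per_cell' (4 subjects; within: construct, treatment; Greenhouse-Geisser corrected)

                          SS  df1  df2  SS_error       F  eps_GG       p_unc        p_GG
effect
construct           0.575069    1    3  0.061875 27.8822       1   0.0132455   0.0132455
treatment            6.29174    1    3  0.051875 363.859       1 0.000314623 0.000314623
construct:treatment 0.550069    1    3 0.0579861 28.4587       1   0.0128756   0.0128756

Dunnett's multiple comparisons vs WT on 'mean_sg_per_cell' (df_err=3, |T|crit=3.182)
  S78N vs WT: p = 0.01217; mean diff. -0.75; 95% CI -1.188 to -0.3115
```

Stress raises the granule load (treatment effect), the mutant's deficit
under stress appears as the construct and interaction effects, and
Dunnett recovers the planted −0.8 shift as −0.75 with a simultaneous 95%
confidence interval. With two factor levels the Greenhouse–Geisser
epsilon is exactly 1, so corrected and uncorrected p coincide.

Founder dating from a genotype panel takes one line each:

```python
from sgfound import find_shared_segment, genetic_length_cm, estimate_founder_age
est = estimate_founder_age(8.07)   # generations=25, years=625.0
```

A `sgfound` console command exposes the same stages for shell use
(`sgfound simulate scene|panel|densitometry`, `sgfound sg-quant`,
`sgfound sg-stats`, `sgfound haplotype`, `sgfound variants`,
`sgfound solubility`); run any of them with `--help`.

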