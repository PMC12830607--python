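# epimorph

Observer-independent morphometry of corneal epithelial thickness profiles,
tissue cellularity, and longitudinal OCT pachymetry — built for evaluating
animal models of limbal stem cell deficiency (LSCD), where injury shows up
not as a uniform change in epithelial thickness but as localized "hot spots"
of extreme thinning and thickening along the section.

## Who this is for

Groups doing quantitative histology of the ocular surface (or any layered
epithelium): you have per-position epithelial thickness measurements
exported from a slide-analysis tool, labeled tissue masks, and serial OCT
thickness readings, and you want reproducible, observer-independent numbers
instead of semiquantitative scoring.

## The metrics

Each eye's measurements form an ordered thickness profile
t₁, …, t_n (µm) along the sectioned contour. To remove between-animal
baseline differences, profiles are standardized per animal
(pooling that animal's eye series):

    zᵢ = (tᵢ − μ) / σ          (μ, σ: per-animal mean and population SD)

On the standardized profile the package computes

* **Ra** (arithmetic mean roughness)  Ra = mean(|z − mean(z)|)
* **Rz** (maximum height of profile)  Rz = max(z) − min(z)
  — the plain max–min amplitude, not the ISO five-peak variant
* **σ-exceedance** — fraction of samples with |z| > 1, 2, 3: the "hot-spot
  burden"
* **skewness** — Fisher–Pearson g₁ = m₃/m₂^{3/2} (bias-uncorrected), the
  asymmetry of thinning vs thickening
* **rolling SD** — sample SD in windows of five consecutive measurements,
  on the raw µm scale: a local-variability index

plus raw-scale mean/min/max/range per eye. Study (injured right eye) and
control (left eye) are compared per metric: pooled per-measurement
thickness with an unpaired t-test, every per-eye metric with a paired
t-test matching the two eyes of each animal.

Other stages: thickness-profile **extraction** from labeled rasters
(background/stroma/epithelium/nucleus) measuring along the local basal
normal so curvature does not bias thickness; **cellularity** (nuclei per
mm² of compartment); **OCT** analysis (percent-of-baseline curves, per-day
paired t-tests against the day −1 baseline, swelling-peak location and
residual swelling fraction); and a seeded **synthetic-data generator** that
emulates all three data streams with known ground truth.

## Worked example

```python
from epimorph import synthetic_data as sd, morphometry as mm, stats_report as sr
from epimorph import io_formats as iof

df, truth = sd.generate_cohort(sd.SyntheticCohortSpec(seed=1))
table = sr.build_table(mm.summarize_cohort(df), measurements=df)
print(iof.comparisons_to_frame(table).round(3).to_string(index=False))
```

prints (abridged):

```
                          metric  study_mean  control_mean     test  p_value
Epithelium thickness (avg total)      77.783        77.321 unpaired    0.369
  Arithmetic Mean Roughness (Ra)       0.906         0.385   paired    0.002
  Maximum Height of Profile (Rz)       7.164         2.756   paired    0.016
Measurements exceeding 1 sigma (%)    23.553         6.447   paired    0.001
                        Skewness      -0.112         0.054   paired    0.820
      Rolling Standard Deviation       5.197         4.339   paired    0.011
```

Read: mean thickness barely separates the groups (77.8 vs 77.3 µm,
p = 0.37) — exactly the situation in early LSCD — while the roughness
metrics (Ra, Rz) and the σ-exceedance fractions, which respond to the
injected hot spots rather than to the average, separate them clearly.

The same pipeline runs from the shell:

```bash
epimorph all --seed 1 --outdir run1      # simulate → morphometry → oct → report
epimorph report --measurements my_export.csv --outdir results
```

Foreign CSV dialects are adapted with a column map (see
`epimorph.io_formats.read_measurements`).

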