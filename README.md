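# optoquant

Quantification pipeline for live-imaging optogenetics experiments on
morphogen gradients in early *Drosophila* embryos — built for
experiments where a transcription factor (Dorsal) is reversibly
exported from nuclei (LEXY-type tag) or degraded (BLID-type tag) under
blue light, and the consequences are read out through nuclear
fluorescence movies, MS2/MCP transcription-reporter movies, FRAP, and
fixed-embryo stainings.

The package is aimed at imaging labs that need a reproducible,
scriptable version of this analysis chain:

* **Transcription-site detection** (`optoquant.foci`) — per-frame
  MS2-focus detection with a dual-threshold scheme (low threshold on a
  median-background-subtracted image, high threshold on raw pixels), a
  logarithmically rising threshold through nc14, embryo masking and
  edge/size filters; instantaneous counts normalized to the starting
  count.
* **Expression-domain area** (`optoquant.area`) — centroids pooled per
  nuclear cycle, MAD outlier removal, convex-hull area, and the
  nc14 − nc13 area change.
* **Nuclear quantification and tracking** (`optoquant.nuclei`) —
  LoG/watershed nuclei segmentation with carry-forward across failed
  frames, embryo ellipse + midline-band selection, per-frame
  mean ± s.d. intensity traces, and nearest-neighbor tracking with
  10-frame gap closing and track-quality filters.
* **Recovery kinetics** (`optoquant.kinetics`) — fits of the
  single-exponential recovery model

  &nbsp;&nbsp;&nbsp;&nbsp;I(t) = I_ss − α·e^(−βt)

  where I_ss is the steady-state intensity, α the recovery depth, and
  β (min⁻¹) the inverse recovery time — applied per nucleus after
  light-off (nuclear re-import) and to the center-most bleached
  nucleus in FRAP movies — plus pooled t-test comparison of rates
  between conditions.
* **Fixed-embryo geometry** (`optoquant.geometry`) — Gaussian fits
  A·e^(−(x−µ)²/2σ²)+B of the dorsal–ventral intensity profile, nuclear
  ring segmentation by coarse LoG with dual ellipse fitting, and
  gene-expression domain widths as ellipse arc length normalized by
  perimeter.
* **Statistics** (`optoquant.stats`) — pooled two-sample t-test,
  one-way ANOVA with Tukey HSD, exact noncentral-t sample-size
  calculation, and cross-embryo series averaging by modified Akima
  interpolation.
* **Synthetic embryos** (`optoquant.simulate`) — a ground-truth
  generator rendering all of the above regimes (hexagonal nuclear
  fields with a DV Gaussian gradient, export/degradation dynamics,
  diffraction-limited spots, FRAP bleach ROIs, fixed cross-sections),
  so the entire pipeline is testable without any microscopy data.

## Worked example

Fit FRAP-style recovery traces and compare conditions:

```python
import numpy as np
from optoquant.kinetics import fit_single_exponential, compare_rates

t = np.arange(0, 19 * 60, 2) / 60.0          # 2 s sampling, minutes
rng = np.random.default_rng(0)
dark = 8628 - 7807 * np.exp(-0.23 * t) + rng.normal(0, 100, t.size)
fit = fit_single_exponential(t, dark)
print(f"I_ss={fit.I_ss:.0f}  alpha={fit.alpha:.0f}  beta={fit.beta:.3f}/min")

r = compare_rates([0.23, 0.25, 0.17], [0.84, 0.80, 1.14])
print(f"t={r.t:.3f}  df={r.df}  p={r.p:.3f}")
```

prints

```
I_ss=8631  alpha=7795  beta=0.229/min
t=-6.458  df=4  p=0.003
```

— the recovery parameters are recovered from the noisy trace to three
significant figures, and the dark-vs-light rate comparison is
significant at p = 0.003 (pooled two-sample t-test, df = 4).

An end-to-end movie analysis from the command line:

```sh
optoquant simulate --kind foci --seed 0 --out run/      # synthetic movie + truth
optoquant foci --stack run/foci.tif --out run/          # detect + count
optoquant area --foci run/foci.csv --nc13 0:30 --nc14 30:100 --out run/
```

`run/counts.csv` holds the instantaneous and start-normalized site
counts per frame; `run/area.json` the convex-hull areas and their
nc14 − nc13 difference in px².

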