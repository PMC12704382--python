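# tipflux

Quantification of secretory-vesicle accumulation dynamics at the tips of
growing fungal hyphae, from single-channel time-lapse fluorescence movies.

Filamentous fungi grow by polarized exocytosis: Golgi-derived secretory
vesicles are delivered to the hyphal apex, where they either gather into a
stable spheroidal cluster just behind the tip (a **Spitzenkörper**) or occupy
shifting submembranous positions across the apical dome, whose time-averaged
footprint is a **crescent**. `tipflux` measures this spatial organization and
its temporal dynamics, for cell biologists analyzing tip-growth movies:

- **Apex tracking** — a moving 50×50 px region of interest follows the
  growing tip so that the apex (the first 4 µm of the cell) is pinned in every
  cropped frame; the elongation rate comes from the OLS slope of tip
  displacement vs time, with kymograph support.
- **Spatial footprint** — the average-intensity time projection is thresholded
  at its top 4.5% brightest pixels; the resulting accumulation region is
  scored by ellipse-fit roundness 4·area/(π·major-axis²): 1 for a spheroid,
  lower for a crescent. Hyphal width and apex curvature complete the
  morphology.
- **Apical time series** — two mean + 2·SD background thresholds (an
  extracellular one over all frames, and a subapical cytosolic one over the
  first 20 frames) mask below-threshold pixels to NaN before the per-frame
  apical mean intensity is taken; series are detrended with a Savitzky-Golay
  filter (window 10, degree 2), without normalization.
- **Temporal Dynamics Clustering (TDC)** — each detrended series is summarized
  by moments of its sorted absolute first differences |Δy_t| split at the
  quantile I_q = 1 − u/(T−1), u = (T−1)^(2/3)/ln ln(T−1): μ_main, σ_main
  (ordinary variability) and μ_tail (extreme events). k-means over these
  three features with silhouette-based selection of k separates oscillatory
  from non-oscillatory hyphae.
- **Periodicity** — detrended, smoothed series are zero-padded to 16 384
  points; the amplitude spectrum A(f) = 2·|FFT|/N is restricted to periods of
  9–150 s, its dominant peak gives the pulsation period, a short-time Fourier
  transform (Hann, 32-point segments, 50% overlap) checks its stability, and a
  sinusoid A_p·sin(2π(t−φ)/p) is fit by a 2° phase grid search.
- **Statistics** — Pearson/Spearman + OLS with Cook's-distance (4/N) and
  leave-one-out diagnostics; Shapiro-Wilk → Bartlett → Student/Welch/
  Mann-Whitney decision tree; lag-0 cross-correlation of standardized series
  as the control against axial (z) drift artifacts.

A fully seeded **synthetic-movie generator** renders elongating hyphae with
Spitzenkörper, crescent or cytosolic-control fluorescence over realistic
background noise, with complete ground truth (tip track, regime, period,
rate), so the whole pipeline is testable without microscope data.

## Worked example

Run the full pipeline on the default synthetic cohort (5 cytosolic controls,
6 crescent, 7 oscillatory hyphae; 135 frames at 4.455 s, 0.1356 µm pixels):

```python
import tipflux as tf

report = tf.run_pipeline(tf.PipelineConfig(seed=1))
print("k =", report.cluster_k, " silhouette =", round(report.silhouette, 3))
print(report.records[["growth_rate_um_min", "roundness", "mu_tail",
                      "cluster", "period_s"]].round(3))
```

prints

```
k = 2  silhouette = 0.822
                             growth_rate_um_min  roundness  mu_tail  cluster  period_s
acquisition
synthetic_00_control                      0.270      0.329    2.842        0       NaN
synthetic_05_crescent                     0.282      0.611    3.044        0       NaN
synthetic_11_spitzenkoerper               0.559      0.754    8.412        1    38.135
synthetic_13_spitzenkoerper               0.586      0.768    5.915        1    64.196
...
```

(12 similar rows omitted). Reading the output: the temporal-dynamics features
split the cohort into two clusters (silhouette 0.822) — cluster 1 holds
exactly the seven oscillatory hyphae, whose μ_tail (mean extreme
frame-to-frame intensity change) is 2–3× that of controls and crescents.
Dominant FFT periods are reported only for the oscillatory cluster and land
within a fraction of a second of the generating periods. Roundness of the
accumulation footprint separates spheroid (≈0.75–0.78) from crescent
(≈0.61–0.67) and control (≈0.16–0.33) movies; across the cohort it correlates
positively with elongation rate (here r = 0.505, p = 0.03) and differs
between clusters (Mann-Whitney U, p = 3.1e-05).

The same pipeline runs from the shell:

```bash
tipflux simulate -o movie.tif --regime spitzenkoerper --period 44.55 --rate 0.3 --seed 2
tipflux track movie.tif -o trackdir      # prints: growth rate: 0.300 +/- 0.002 um/min
tipflux footprint movie.tif              # area/roundness of the top-4.5% region
tipflux run -o out --seed 1              # full cohort analysis, CSV + JSON reports
```

`tipflux run` writes `acquisitions.csv` (one row per movie with the columns
shown above plus area, width, curvature, σ_main, θ and model MSE),
`series.csv` (long-format time series) and `report.json` (cohort statistics
with a config hash for provenance).

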