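# caosc

Quantification of single-cell Ca²⁺ oscillations in two-channel 4D
light-sheet movies of sprouting endothelium, with a ground-truth synthetic
movie generator.

During angiogenic sprouting in the zebrafish trunk, budding endothelial
cells (ECs) show sustained, non-periodic intracellular Ca²⁺ oscillations
reported by a cytoplasmic GCaMP indicator, while their nuclei are tracked
through an H2B-fused red label. Quantifying that activity per cell — who
oscillates, how often, how strongly, how synchronously with neighbours, and
where along the aorta — is the measurement this package automates, for
anyone analysing volumetric two-channel Ca²⁺ recordings of sparse labelled
cells (5-s frame interval, 4-µm z-step in the emulated regime).

## Method

For each tracked cell the pipeline computes, inside a spherical ROI of
4–11 µm centred on the nucleus (sized so neighbouring ROIs never overlap):

* **F(t)** — the highest indicator voxel intensity in the ROI per frame;
* **F₀** — the baseline, the minimum over all 50-s sliding windows of the
  window-mean F (the quietest stretch of the recording);
* **ΔF/F₀ = (F − F₀)/F₀** — the normalised trace;
* **oscillations** — ΔF/F₀ excursions of at least 20% of the cohort
  reference, where 100% is the mean of the three highest ΔF/F₀ peaks in
  oscillating wild-type cells (self-calibrated by fixed-point iteration),
  detected as local maxima with matching prominence, ≥ 10 s apart;
* **frequency** (min⁻¹), **mean ΔF/F₀**, **time-to-peak** (onset at the
  10%-of-apex crossing, extrapolated to the full rise);
* **synchrony** — a rise is synchronous with a partner cell if the partner
  has a rise within |Δt| ≤ 10 s;
* **spatial summaries** — Region 1–3 assignment between somite boundaries
  (equal thirds, nucleus position at the first frame) and counts of
  oscillating budding cells per boundary (categories 1 / 2 / 3+).

Cells that divide during the recording are flagged and excluded (ECs show
no Ca²⁺ rise in M phase). Nuclei are detected by Gaussian smoothing +
thresholding with sub-voxel centroids and linked by gated optimal
assignment with gap closing.

The synthetic generator (`caosc.synthgen`) builds scenes with known ground
truth — refractory-thinned Poisson spike trains (rise times uniform on
5.6–18.7 s), cell-to-cell baseline variation, dorsally migrating tip/stalk
cells, preset cohorts (`wildtype`, `vegfr_inhibited`, `dll4_morphant`) —
and renders them as two-channel TIFF movies with Poisson + Gaussian camera
noise. See `docs/methods.md` for the full model and its limitations.

## Worked example

Run the numbered analysis, or equivalently the one-shot pipeline CLI
(`caosc run --preset wildtype --seed 1 --out runs/wt`):

```sh
python analysis/01_simulate_cohorts.py
python analysis/02_track_and_extract.py
python analysis/03_quantify_oscillations.py
python analysis/04_synchrony_and_space.py
python analysis/05_group_comparisons.py
```

which prints (seed 1):

```
wildtype: 24 cells {'tip': 8, 'stalk': 8, 'da': 8}, 174 ground-truth spikes, ...
wildtype: 24 tracks, link recall 100.0% over 4776 links, 24 annotated cells -> traces.csv
wild-type calibration: reference 2.342, threshold 0.468 (182 pooled peaks)
wildtype: 177/174 ground-truth spikes recovered (101.7%), 5 peaks in quiescent cells, ...
wild-type synchrony: 78.8% of 118 tip rises and 59.3% of 59 stalk rises are independent ...
dll4_morphant: boundaries with 1 / 2 / 3+ oscillating budding cells = 8.3% / 91.7% / 0.0% ...
frequency: tip (0.885, n=8) vs stalk (0.443, n=8): t=5.84, p=4.3e-05 ***
frequency: stalk (0.443, n=8) vs da (0.037, n=8): t=6.05, p=3e-05 ***
```

Reading the numbers: nucleus tracking recovers every ground-truth link;
the self-calibrated oscillation threshold lands at ΔF/F₀ ≈ 0.47 (20% of the
2.34 reference); 177 detected rises against 174 planted ones (the small
excess is bleed-through from bright neighbours into quiescent-cell ROIs);
most tip and stalk rises are independent of the partner cell, arguing
against intercellular waves; the dll4 cohort shows two or more oscillating
budding cells at most boundaries, exactly as planted; and the detected
frequency ordering tip > stalk > quiescent DA is highly significant
(Student's t). Detected means (0.885, 0.443 min⁻¹) sit on the
refractory-corrected generator rates 1.2/(1+1.2·20/60) = 0.857 and
0.6/(1+0.6·20/60) = 0.500 min⁻¹.

Per-stage tables land in `results/runs/<preset>/` (`tracks.csv`,
`traces.csv`, `dff.csv`, `peaks.csv`, `metrics.csv`, `threshold.json`,
`synchrony.csv`, `regions.csv`, `boundary_counts.csv`); rendered movies go
to `scratch/` (TIFF + JSON calibration sidecar).

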