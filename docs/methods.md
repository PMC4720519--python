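# Methods

`caosc` quantifies intracellular Ca²⁺ oscillations of single endothelial
cells (ECs) in two-channel volumetric time-lapse recordings: a nuclear label
(H2B-fused red fluorophore) used for tracking, and a cytoplasmic GCaMP-class
Ca²⁺ indicator whose fluorescence F rises with intracellular Ca²⁺. The
pipeline turns a (T, Z, Y, X) movie pair into per-cell ΔF/F₀ traces,
calibrated oscillation calls, per-cell frequency and amplitude summaries,
tip–stalk synchrony percentages and spatial counts around somite boundaries.
Because public recordings of this kind are not available, the package ships
a synthetic-movie generator whose ground truth makes every stage verifiable.

## Synthetic data model

**Spike trains.** Ca²⁺ oscillations in sprouting ECs are sustained and
non-periodic. Each cell's rise onsets are a homogeneous Poisson process of
rate λ (min⁻¹) thinned by a hard refractory period τ_r (default 20 s): a
candidate closer than τ_r to the last accepted onset is discarded. Accepted
inter-spike intervals are therefore τ_r + Exp(λ), and the long-run event
rate is λ/(1 + λ·τ_r) — the *refractory-corrected rate* that recovery tests
compare against. The refractory period keeps consecutive events resolvable
at 5-s volumetric sampling.

**Kinetics.** Each spike contributes to ΔF/F₀ a linear rise over its rise
time, drawn uniformly on [5.6, 18.7] s (the range observed in vivo by fast
2-D imaging; mean 12.15 s), followed by an exponential decay with time
constant 8 s. The decay constant is a package choice: with slower decay
(e.g. 15 s) a spike arriving near the refractory bound after a long-rise
predecessor rides so high on the predecessor's tail that it leaves no
resolvable local maximum, and a detectable fraction of genuine events
becomes unmeasurable by *any* threshold detector at 5-s sampling. τ = 8 s
keeps that merge loss near 1%.

**Amplitudes and baselines.** Spike amplitudes are uniform on [1.5, 2.5]
ΔF/F₀. The lower bound is deliberately above what the cohort-calibrated
threshold (≈0.45–0.6 ΔF/F₀, see below) can reach after 5-s sampling
undershoot, so that every generated spike is an oscillation *by the
definition the pipeline applies* — otherwise "ground-truth rate" would be
ill-posed. Baseline indicator brightness F₀ varies between cells
(lognormal, mean 100 au, CV 0.3), emulating variable indicator expression.
Trace-level noise is additive Gaussian (default 5% of F₀).

**Scenes.** A scene places cells along a dorsal aorta running in x, with
evenly spaced somite boundaries (default 8 boundaries, 26 µm apart):

* *wildtype* — per boundary one budding tip cell (λ = 1.2 min⁻¹), one
  budding stalk cell following it (λ = 0.6 min⁻¹) and one quiescent
  non-budding DA cell (λ = 0). Tip and stalk migrate dorsally (0.4 and
  0.2 µm/min); DA cells are quasi-static. All positions carry small
  mean-reverting jitter (sd 0.15 µm).
* *vegfr_inhibited* — identical geometry, all rates zero.
* *dll4_morphant* — at 80% of boundaries two neighbouring oscillating
  budding cells (both at tip rate), no stalk stage.

Scenes can also include dividing cells (a trajectory that ends mid-movie
and two daughters that begin 8 µm apart) to exercise mitosis flagging.

**Rendering.** Channel 1 renders each nucleus as a 3-D Gaussian blob
(σ = 2 µm); channel 2 renders the cytoplasmic indicator as a wider blob
(σ = 4 µm) whose *brightest voxel equals the cell's fluorescence value* at
that frame, so the max-voxel readout of a noise-free movie reproduces the
trace exactly. Kernels are evaluated in physical micrometres, honouring
anisotropic voxels (default 4-µm z-step; preset scenes use a 1.0-µm lateral
pixel, adequate sampling for σ ≥ 2 µm kernels and small enough volumes to
render quickly). Overlapping blobs and the flat background (10 au)
composite by maximum. Camera noise is Poisson shot noise on the expected
intensity plus Gaussian read noise (sd 2 au).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: light-sheet PSF anisotropy and scattering,
bounded cell shapes (Gaussian tails extend past a real cytoplasm, so a very
close bright neighbour can bleed into a quiescent cell's ROI; this produces
the occasional spurious DA-cell peak at realistic packing), vessel-lumen
geometry, blood-flow artefacts, photobleaching, and any Dll4/Notch or
Vegfr signalling dynamics (presets encode outcomes, not mechanism).

## Tracking

Nuclei are detected per frame in the nuclear channel: Gaussian smoothing at
σ = 2 µm (converted per axis to voxels), an absolute intensity threshold
(default 50 au), connected components, and an intensity-weighted sub-voxel
centroid per component. Detections are linked frame-to-frame by optimal
bipartite assignment (Hungarian algorithm) on Euclidean distance in
micrometres, gated at max_disp (default 6 µm per elapsed frame) with gap
closing up to gap_max missed frames; unmatched detections start new tracks;
tracks shorter than min_track_len (default 5) are dropped. Equal-cost
ambiguities resolve deterministically through stable track/detection
ordering. No detection ever belongs to two trajectories (asserted).

**Mitosis.** ECs show no Ca²⁺ rise during M phase, so dividing cells are
excluded from quantification. A division is declared at trajectory P and
frame t when exactly one detection lies within split_radius (default 6 µm)
of P's position at t but two or more do at t + 1; P and any trajectory
starting at t + 1 from those detections are flagged and excluded. Working
on raw detections rather than track topology matters because the optimal
linker always bridges the parent into one daughter (a parent track never
"ends" at a division), and because daughters appearing only in the final
frame are too short to form tracks yet still identify the event.

## ROI extraction

Each analysed cell gets one spherical ROI, diameter searched on a 0.5-µm
grid in [4, 11] µm — the largest value such that, with every neighbour sized
by the same rule, the spheres never intersect at any frame (two spheres just
touch when the centre distance equals the common diameter). If even 4 µm
cannot clear a neighbour, the minimum is used and flagged. F(t) is the
maximum voxel value whose *centre* lies inside the sphere (closed ball,
physical-distance test, so 1 z-step and 8 lateral pixels at 0.5 µm are
equivalent 4-µm offsets); a whole-cytoplasm Ca²⁺ spike makes this max
readout insensitive to the exact diameter. Track-gap frames are missing
values, never interpolated.

## Oscillation quantification

* **Baseline.** F₀ is the minimum over all 50-s sliding windows of the
  window-mean F — the quietest stretch of the recording. Only the window
  *length* is fixed by convention; taking the minimum keeps the baseline
  honest for cells that oscillate from the first frame. Windows with fewer
  than half their samples valid are skipped.
* **Normalisation.** ΔF/F₀ = (F − F₀)/F₀ elementwise. The whole chain
  downstream is invariant under any positive rescaling of raw F.
* **Threshold calibration.** An oscillation is a ΔF/F₀ excursion of at
  least 20% of a cohort reference, where the reference (the "100%" level)
  is the mean of the three highest ΔF/F₀ peaks pooled across oscillating
  wild-type cells. Stated that way the definition is circular (peaks are
  needed to find the threshold that defines peaks), so calibration runs in
  two passes: pass 1 detects provisional peaks at an absolute floor of
  ΔF/F₀ ≥ 0.2 to identify oscillating cells; pass 2 pools their peak
  heights, sets reference = mean of the top three and threshold = 0.2 ×
  reference, then iterates detection to a fixed point (the reference is
  non-increasing once set, so iteration terminates). Pooling across the
  cohort is the default; a per-cell top-three variant is available. Fewer
  than three pooled peaks is an error instructing an explicit override.
* **Peak detection.** Peaks are local maxima of ΔF/F₀ with apex ≥ threshold
  and topographic prominence ≥ threshold, pruned so apexes are ≥ 10 s apart
  (greedy by descending height, ties to the earlier apex). Plateau maxima
  resolve to the plateau midpoint. Missing stretches split the trace; no
  peak spans a gap. The detector is verified equal to an exhaustive
  brute-force oracle on randomised grid-valued traces.
* **Onset and time-to-peak.** The onset is the last upward crossing of 10%
  of the apex ΔF/F₀ before the apex, linearly interpolated between samples.
  The reported rise duration extrapolates the 10%→100% interval to a full
  linear rise, time_to_peak = (t_apex − t_onset)/0.9, which makes the
  estimator unbiased for the generator's linear rises; the uncorrected
  interval would systematically read 10% short. Rise times are meaningful
  at fast sampling (the 0.1-s regime of 2-D imaging); at 5-s volumetric
  sampling apex quantisation and tail stacking inflate them, which is why
  rise-time recovery is validated at 0.1 s.
* **Metrics.** frequency = n_peaks/(observed span in min), with the span
  the cell's own first-to-last valid sample (plus one frame interval);
  mean ΔF/F₀ = arithmetic mean of all valid samples. A cell oscillates if
  it has ≥ 1 peak. Mitotic/excluded cells never reach this stage.

## Synchrony and space

* **Synchrony.** A rise in cell A is *synchronous* if some rise in cell B
  lies within |Δt| ≤ 10 s (boundary inclusive, any-match). The published
  criterion is worded directionally ("within 10 s late behind") but applied
  in both directions; the symmetric absolute lag implements that. Cells
  with no rises get missing percentages, not 0%. Rise times are onsets
  (apex as fallback when the onset is undetectable).
* **Regions.** The interval between consecutive somite boundaries is split
  into three equal thirds, half-open [left, left+L/3) ∪ [left+L/3,
  left+2L/3) ∪ [left+2L/3, right); a cell's region is fixed by its nucleus
  x at the first frame. The very last boundary closes the final third so
  the covered range is a true partition.
* **Boundary counts.** Each oscillating *budding* cell (one lateral side
  only) is assigned to its nearest boundary by |Δx| (ties anterior);
  boundaries with ≥ 1 such cell are categorised 1 / 2 / 3+ and reported as
  percentages of those boundaries. The per-ISV mode restricts to cells
  following a tip cell.

## Statistics

Two-group comparisons use the classical equal-variance two-sample t test
(two-sided, significant at p < 0.05), matching the original analysis
convention; Welch and paired variants are flags. No multiple-testing
correction is applied by default. Identical constant groups report t = 0,
p = 1 rather than NaN.

## Determinism and numerics

Every stochastic component takes an explicit seed; scenes, movies and full
pipeline runs are bit-reproducible (two runs of the same configuration give
byte-identical `summary.json` and stage tables; no timestamps in outputs).
Movies are stored float32; CSV floats use shortest-repr writing and
round-trip parsing, so read(write(x)) is exact. ΔF/F₀ scale invariance is
bitwise for power-of-two gains and agrees to ≤ 1e-12 relative for arbitrary
gains (IEEE-754 multiplication is only exact for dyadic factors), with peak
calls and frequencies identical either way.

## Problem sizes

Default validation sizes, chosen to make every check run comfortably on one
CPU: preset scenes with 8 boundaries (24 cells; 35 for the dll4 preset at
12 boundaries), 1000-s recordings at 5-s frames, ~7×28×235-voxel volumes at
1 µm lateral pixel; trace-level recovery cohorts of 50 cells per rate;
rise-time recovery on 200 single-spike traces at 0.1-s sampling; oracle
sweeps of 1000 randomised instances per operator.

## Known limitations

Bleed-through from unbounded Gaussian cytoplasm tails can produce rare
false peaks in quiescent cells adjacent to bright oscillators (visible as
DA-cell frequencies slightly above zero); detection assumes roughly
Gaussian nuclei and fails on strongly non-convex shapes; the linker handles
at most one division per track neighbourhood (no lineage trees); frequency
estimates are mildly right-censored because a rise whose apex falls after
the last frame is not counted (≈1–2% at 1000 s); the threshold calibration
inherits the cohort's three largest excursions, so a cohort of fewer than
~5 active cells calibrates noisily.
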