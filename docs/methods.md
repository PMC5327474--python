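# Methods

This note documents the models, the numerical choices behind them, the
default parameters, and the known limitations. All problem sizes quoted
here (cohort sizes, volume dimensions, permutation counts) are the
package's own validation choices.

## ΔF/F and the baseline

For a fluorescence trace F sampled on a uniform grid, ΔF/F_t =
(F_t − F0_t)/F0_t where F0 is the running median over a centered 600-s
window, truncated at the trace edges. The median (not the mean) keeps the
baseline insensitive to the dips being measured, and the ratio form makes
every downstream quantity invariant to rescaling the raw fluorescence.

A plain running median is still biased by the events themselves: with
events occupying a fraction q of the window, the window median sits at the
(0.5/(1−q)) quantile of the baseline noise plus a shift toward the dip
level, which both shrinks measured magnitudes and — when events crowd more
than half the window — hides events entirely. `analyze_trace` therefore
iterates: detect events, mask the detected samples (± twice the smoothing
window) out of the median, recompute ΔF/F, and re-detect, until the masked
set stops growing (at most 5 passes). On synthetic cohorts this removes
the magnitude bias to within sampling error (see "Validation" below).

## Vasospasm detection

- Noise scale: σ = 1.4826 × MAD of the ΔF/F series. The MAD ignores the
  events; the factor calibrates it to a Gaussian standard deviation.
- Candidates: samples below −k·σ (default k = 3).
- Hysteresis: each candidate grows to its enclosing run below −k·σ/2, so
  event extents do not collapse to the deepest samples.
- Gap bridging: grown runs separated by less than the minimum duration are
  merged. Near the detection threshold a single noise sample above −k·σ/2
  would otherwise split one episode in two; physiologically, two dips
  10 s apart are one episode.
- Duration filter: events shorter than 10 s are discarded.

### Per-event measures

Each event is fitted with a five-parameter trapezoid (onset time, ramp
width, plateau width, recovery width, depth) by least squares
(`scipy.optimize.least_squares`). The reported measures are:

- **magnitude** — mean ΔF/F over the fitted plateau interior (excluding one
  sample at each end), in percent. The raw |minimum| of the series is
  biased deep by the expected extreme of the plateau noise (≈2.5σ over a
  100-sample plateau — a ~29% relative error at 4.27% magnitude and 0.5%
  noise), so it is kept only as the `trough_dff` diagnostic. The plateau
  mean is unbiased; when the fitted plateau is shorter than 3 samples the
  fitted depth is used instead.
- **duration** — the fitted trapezoid support. The hysteresis crossings sit
  inside the true ramps (they mark where the dip passes 1.5σ, not where it
  starts), so the raw run length underestimates duration; the fitted
  support does not.
- **onset_time / termination_time** — the fitted ramp widths.

Per-vessel metrics are the event rate (events per recorded hour) and the
likelihood (percent of recording time inside events). Cohort summaries
report mean ± s.e.m. per measure with an explicit unit of analysis:
vessel-level by default for rate/likelihood/event measures, animal-level
for the fraction of vessels with ≥1 event (vessels within an animal are
not independent; the default comparisons follow this convention and the
unit is recorded in the output).

## Seizure–vasospasm timing

All seizure−vasospasm onset lags Δ = t_seizure − t_spasm within ±400 s are
pooled per animal into left-closed 80-s bins. The null preserves each
animal's seizure count and session length while destroying timing: every
permutation redraws the seizure onsets uniformly within the session and
recomputes the pooled histogram (vasospasms stay fixed). Per-bin one-sided
p = (1 + #{null ≥ observed})/(1 + n_perm) — the plus-one rule keeps p in
(0, 1] and accounts for the identity permutation. The normalized rate is
100 × (observed − null mean)/null mean. Bonferroni correction across the
10 bins is applied at the reporting stage.

Calibration caveat: with sparse trains the per-bin null counts take few
distinct values, and the plus-one rule is then conservative (measured
type-I fraction 0.027 at nominal 0.05 for 2 seizures/hr over 10-h
sessions). At denser counts the test is calibrated (0.041, within the 99%
binomial band, at 6 seizures/hr over 20-h sessions). This is a property of
discrete permutation tests, not an implementation artifact.

## Stereology and distances

- **Sphere probe.** The nearest-vessel distance of a cell centroid is the
  smallest radius in {2, 4, 6, …} μm at which a sphere around the centroid
  contains a vessel voxel center. Computed as step·max(1, ceil(d_E/step))
  with d_E the exact Euclidean distance to the nearest mask voxel center
  (KD-tree over voxel centers in physical coordinates, so anisotropic
  voxels are handled exactly). Voxel index i sits at coordinate
  i × spacing (voxel-center convention).
- **Quantization bias.** Quantized distances overestimate d_E by ~step/2 on
  average, which *shrinks* a relative shift measured on quantized
  distances: if the true class means are m_p < m_n, the measured shift is
  approximately (m_n − m_p)/(m_n + step/2) — e.g. a 15.2% exact-distance
  shift reads ≈14% after 2-μm quantization. The acceptance tolerance
  (±2 percentage points against ground truth) absorbs this; comparisons
  between classes measured the same way are unaffected.
- **Disector.** Square counting frame (5600 μm² default) with two inclusion
  edges (left, bottom; closed) and two exclusion edges (right, top; open),
  restricted to a central 6-μm guard slab of the section.
- **Fractionator.** Total = count/(ssf · asf · tsf), with tsf = guard/mean
  section thickness. `fractionator_survey` samples every 1/ssf-th section
  (random start) and places frames on a systematic-random grid with
  spacing frame_side/√asf, starting one grid period before the field
  origin so edge coverage is exact; this realizes the nominal fractions in
  expectation, making the estimator design-unbiased.
- **Distance distributions.** 2-μm bins (k·step, (k+1)·step]; the relative
  shift is 100 × (mean_neg − mean_pos)/mean_neg; inference uses the
  Cochran–Armitage trend test on the raw binned counts (df = 1, bin
  midpoints as scores; at K = 2 it reduces exactly to the uncorrected 2×2
  chi-square). Gaussian fits to the binned counts are display-only and
  never used for inference.
- **Diameters.** Full width at half maximum of a background-subtracted
  intensity line profile (linear interpolation along the physical-unit
  segment, sub-sample interpolation of the two crossings).
- **Strictures.** The vessel mask is skeletonized; the local diameter at a
  centerline voxel is twice the anisotropic Euclidean distance to the
  background; the reference is the running 90th percentile of diameter
  within ±10 μm along the centerline; a contiguous run strictly below half
  the reference is one stricture, reported at its narrowest point together
  with the sphere-probe distance to the nearest mural-marker voxel. The
  comparison is strict because the discrete diameter of a healthy tube
  lands exactly on half the reference wherever the skeleton sits one voxel
  off-center.

## Synthetic generators

All generators take an explicit integer seed (`numpy.random.default_rng`)
and return ground truth alongside the data; identical seeds give
bit-identical output.

- **Traces.** Per vessel, a Poisson number of trapezoid dips (10-s ramps,
  100-s plateau, 20% depth by default) placed uniformly without overlap
  (bounded retries; impossible densities raise), on a constant baseline
  with additive Gaussian noise (0.5% of baseline by default).
- **Event trains.** Seizures as a Poisson process; each seizure spawns a
  coupled vasospasm with the configured probability at a non-negative
  truncated-normal lag (40 ± 20 s); background vasospasms arrive
  independently. Ground truth records which spasms were coupled.
- **Volumes.** Vessels are analytic capsules clipped to the volume's
  bounding box (end caps outside the field, so no spurious cap surfaces),
  oriented mostly in-plane; cells are uniform points strictly outside
  every lumen. Marker-positive cells are drawn from a large uniform pool
  by weighted sampling without replacement with weight exp(−β·d) (Gumbel
  top-k); β is calibrated by bisection until the realized shift of exact
  (analytic-geometry) distances matches the target within ±1 percentage
  point. Because the selected set changes in discrete steps, a single
  step can jump the tolerance band where the shift–β curve is steep; the
  generator then redraws the (seeded) keys and retries. Strictures are
  Gaussian radius dips rendered into the rasterized lumen, each with a
  mural blob in a separate channel. Exact nearest-surface distances come
  from the analytic tubes, never from the rasterized mask.

## Validation summary

Highlights from the test suite (`tests/test_acceptance.py`):

- p-values for seven reference t/χ²/F statistics match to the printed
  precision.
- Rate, likelihood, and magnitude recovery at reference values
  (0.456/hr, 8.87%, 4.27%) within two standard errors on 150–200-trace
  cohorts; detector recall 1.00 and precision 0.995 at magnitude = 4×noise
  under strict one-to-one event matching.
- Distance-shift recovery through mask → probe → distributions within
  ±2 percentage points of the generator's realized shift.
- Sphere probe identical to a brute-force scan on 1000 random anisotropic
  masks; fractionator survey unbiased (50-seed checks at two population
  sizes); permutation type-I error calibrated in the dense regime;
  pipeline reruns bit-identical apart from wall-clock timings.

## Limitations

- The nucleus "segmentation" (`find_nuclei`) is a threshold-and-label blob
  detector intended only for generator-produced volumes; adjacent rendered
  nuclei merge.
- Stricture detection reports diagonal-voxel artifacts (local diameter
  ≈ 0.71 voxel diagonals) where generated tubes cross; records without a
  nearby mural voxel should be screened by `mural_distance_um`.
- The permutation test is conservative at sparse event counts (see above).
- The trace generator produces stationary baselines; slow drifts are
  handled by the running median in analysis but are not simulated.
- Detected events at magnitudes near the threshold (≲3σ) have upward-biased
  magnitudes by selection; the validation conditions keep magnitude ≥ 4σ.
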