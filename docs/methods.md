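# Methods

This note documents the models, numerical choices and limitations behind
`organoidtrack`. It describes what the code computes and why; every
empirical number quoted here is produced by the test suite or by
`scripts/acceptance.py`, not asserted independently.

## 1. The measurement model

The pipeline emulates a two-timepoint widefield experiment on gridded
glass dishes: organoids are plated in gel, imaged on Day 0 (brightfield +
NAD(P)H + FAD autofluorescence), treated, and re-imaged on Day 4 in the
same positions. Because the gel immobilises organoids, re-identification
across days reduces to nearest-centroid matching with a small tolerated
drift.

Per organoid, two readouts are computed:

* **Relative change in diameter** — the maximum Feret diameter of the
  segmented brightfield mask on each day, combined as
  `100·(d4 − d0)/d0`. Feret (longest chord between boundary points) is
  used because the manual line-tool measurement it replaces is a Feret
  measurement in spirit; one pixel of pixel extent is added so that a
  single-pixel object has diameter 1 px rather than 0.
* **ΔORR** — the optical redox ratio `ORR = I_N/(I_N + I_F)` from
  background-normalized channel intensities averaged over the organoid's
  leading edge, differenced across days (`ΔORR = ORR₄ − ORR₀`). The
  simple difference is the convention here: it makes a treatment-induced
  shift toward an oxidized state a *negative* ΔORR. Channel aggregation
  uses mask-mean intensities and the ratio of means (not the mean of
  per-pixel ratios), which is robust to per-pixel zeros.

Arms are summarised by the median (robust to the heavy right skew of
per-organoid growth) and compared with the modified Glass's delta
`mGΔ = (x̃_c − x̃_t)/σ_c`, pooling organoids across technical replicates.
The SD uses the n−1 denominator. mGΔ is invariant to shifting all values
by a constant and to rescaling by any positive constant; both invariances
are property-tested. No multiple-testing correction is applied across
lines or treatments; the accompanying Mann–Whitney p-values are
descriptive (the per-organoid distributions are skewed, so a rank test is
the default; Welch's t is available behind a flag).

## 2. Synthetic cohorts

The generator's role is to provide inputs with known truth, not to model
optics. Each arm is described by sampling laws on the scales the
statistics summarise:

| quantity | default law | rationale |
|---|---|---|
| baseline diameter d₀ | lognormal, median 200 µm, log-SD 0.15 | plausible plating distribution; sizes are strictly positive and right-skewed |
| growth (%) | normal, per-arm median/SD | growth percent is the scale on which arm medians are stated |
| baseline ORR | normal(0.60, 0.05), clipped to [0.01, 0.99] | mid-range redox state with moderate spread |
| ΔORR | normal, per-arm median/SD | differences are approximately symmetric |

Geometry: fields are 3.34 mm × 3.34 mm at 2044 × 2048 px (1.634 µm/px)
by default, five fields per technical replicate, three replicates per
arm. A *reduced-field mode* (768² px at 4 µm/px) keeps the same biology
at coarser sampling for large simulated cohorts; geometry is a parameter
throughout. Organoids are placed one per grid cell with jittered centers,
which emulates the gridded dish and *guarantees* non-overlapping masks
(an invariant the tests assert). Day-4 positions are Day-0 positions plus
Gaussian jitter (σ = 5 µm).

Growth samples are truncated below at the arm's `growth_floor_pct` and
above so the Day-4 mask stays inside its grid cell. The floor is −95 % by
default (Day-4 diameter stays positive). The reference cohorts use −75 %:
an organoid shrunk below a quarter of its baseline has disintegrated
beyond measurability, and keeping Day-4 objects detectable makes the
recovery experiment a test of the pipeline rather than of the detection
floor. Both truncations act far below/above every arm median, so arm
medians — and hence the numerator of mGΔ — are unaffected; at the default
laws the control-arm SD shrinks by about 1 %, shifting the implied effect
size by roughly +0.015.

Rendering: brightfield organoids are dark-rimmed ellipses (rim just
inside the true boundary, so the outer rendered edge coincides with the
true diameter); the fluorescence channels share one rim-concentrated
radial profile split between NAD(P)H and FAD in proportion ORR :
(1 − ORR), so the background-subtracted intensity ratio reproduces the
true ORR exactly — on noise-free renders the pipeline recovers
per-organoid ORR to ±0.005. Additive Gaussian noise (SD 20 a.u. on
backgrounds of 400–3000 a.u.) models read noise. No optical physics
(PSF, photobleaching, excitation dose) is simulated, and rendered
organoids are simple ellipses: passing tests demonstrate pipeline
correctness on well-formed phantoms, not segmentation robustness on real
morphologies (cystic or dense lumens, debris, gel artefacts).

Comparator simulators: well luminescence is `Σ d₄³ · viability` with
multiplicative noise (ATP mass scales with viable volume); clinical
outcomes are a linear link from true effect size to percent SLD change
with Gaussian noise, calibrated so an effect of 1.25 maps just beyond the
−30 % partial-response boundary.

## 3. Image processing

Segmentation is classical: invert the brightfield, Gaussian-smooth
(σ = 1 px), Otsu-threshold, fill holes (interiors are brighter than
rims), remove objects below `min_area` (default 2000 µm² ≈ a 50 µm
object; recovery experiments lower it to 500 µm² so −75 %-shrunk Day-4
organoids remain detectable), and split components containing more than
one distance-transform peak with a marker watershed. Peak spacing scales
with each component's inscribed radius (0.8 × max distance), so interior
plateau jitter does not split single objects while tangent objects still
separate. Two numerical guards matter:

* **Empty-field gate.** Otsu always returns a threshold, even on pure
  noise. A scale-free separability statistic (foreground/background mean
  difference over pooled SD) distinguishes the two regimes: pure-noise
  fields score ≈ 2.6, fields with real objects > 4; the gate is 3.2.
  Being a ratio, it leaves segmentation invariant to intensity gain,
  which is property-tested.
* **Boundary recentring.** The Otsu boundary lands on the outer flank of
  the blurred rim edge, ≈ 1 smoothing-σ outside the true outline; the
  final masks are eroded by 1 px to recentre it. With this correction,
  noise-free phantoms at native resolution give per-object Jaccard
  ≥ 0.95 against the simulator's own masks and diameter bias ≤ 2 px.

The pretrained-network segmenter used on real micrographs is out of
scope; the classical segmenter sits behind the same interface
(`segment_organoids`) so a learned model can be swapped in.

Leading edge: pixels of a mask within 20 px of its boundary (the 20 px
band is ≈ 33 µm at native resolution; reduced-field runs use 8 px to
preserve the physical band). An object thinner than twice the band is
used whole. Background normalization subtracts the median intensity over
the background region (complement of all masks dilated by 10 px), clipped
at zero; division is available behind a flag — under the shared-background
rendering both leave the effect sizes unchanged. The background level is
recorded for provenance.

## 4. Tracking

Greedy nearest-centroid matching within each field, accepting shifts up
to 150 µm (well below the grid pitch, far above the 5 µm jitter);
deterministic by sorting candidates on (distance, labels); each detection
used at most once. Optimal assignment is unnecessary at gridded-dish
densities. Unmatched Day-0 detections become unpaired records that are
counted, reported, and excluded from change-based statistics; unmatched
Day-4 detections are logged as new/unidentified objects.

## 5. Classification and concordance

Thresholds are stored with explicit inclusivity flags, serialized with
results: the diameter chemotherapy cutoffs ("1.25 or higher", "0.75 or
lower") are inclusive; the ΔORR cutoffs ("> 1.5", "< 0") exclusive. Two
named presets exist for the chemoradiation diameter rule — resistant
≤ 0 (`validated`, the default) and resistant < 0.5 (`novel-xrt`) — since
both conventions circulate; neither is adjudicated here. Combination of
modalities is most-sensitive-wins: the redox readout can upgrade an
intermediate size response; require-both or averaging variants can be
composed from the parts. "Clinical response" means PR or CR. RECIST
v1.1 is implemented for target lesions only (SLD rules; no non-target or
new-lesion logic).

## 6. Validation experiments and problem sizes

* **Effect-size recovery** (`recovery.recover_reference_effects`): three
  reference cohorts are simulated at their published arm medians, with
  control SDs solved from the published effect-size identity
  (σ = Δmedian / mGΔ; the two LARC12 identities agree within 0.5 % and
  the shared value 56.6 reproduces both printed effects to 2 d.p.).
  Where ΔORR medians are unpublished (LARC7, CRC8), stand-in medians
  (control 0.050, SD 0.040) are chosen to reproduce the published mGΔ.
  The experiment runs 500 organoids/arm in reduced-field mode, averaged
  over 5 seeds — about 6 minutes on one CPU. Single-seed mGΔ estimates
  scatter with SD ≈ 0.1 (order-statistic error of two medians at
  n = 500); the 5-seed average recovers each published effect within
  ±0.15.
* **Power ordering** (`recovery.method_power_comparison`): 200 tabular
  replicates at 60 organoids/arm, growth +50 % vs +20 % (SD 30), baseline
  log-SD 0.5, 3 wells/arm with 10 % luminescence CV. Change-in-diameter
  testing rejects in essentially every replicate; endpoint-diameter in
  roughly two-thirds; the 3-vs-3 well comparison rarely. The mechanism is
  variance conditioning: the change readout cancels each organoid's
  baseline size; the other readouts carry it.
* **Concordance round-trip** (`recovery.zero_noise_concordance`): with a
  noise-free link aligned to the thresholds, the sensitive row's clinical
  response rate is exactly 100 %.

## 7. Known limitations

* Generative laws for organoid size and ORR are documented stand-ins; the
  source study publishes only arm medians and effect sizes.
* Phantom fields are far easier to segment than real micrographs; the
  fidelity numbers certify the pipeline's bookkeeping and statistics, not
  real-world segmentation accuracy.
* The clinical link is a one-parameter monotone map with noise — adequate
  for exercising the concordance machinery, not a model of radiographic
  response.
* Normal growth laws place mass below −100 %; truncation handles it, but
  a bounded family (e.g. shifted lognormal on 1 + g/100) would be a
  cleaner model at extreme effect sizes.
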