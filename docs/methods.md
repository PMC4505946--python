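# Methods

`vtmorph` analyzes how classical singers reshape the lower vocal tract (VT)
relative to natural, speech-like phonation, and what that reshaping does
acoustically. This note documents the models, parameters and numerical
choices; nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Morphometric model

All geometric measures live in a centerline-based coordinate system: the
airway volume is resampled into binary cross-sections in planes normal to a
mid-lumen centerline at a fixed spacing of **0.3255 mm** (30 slices span
exactly 9.765 mm; the spacing equals a 1.3 mm image resolution divided by a
4x upsampling factor). Slice 0 is the most caudal (glottal) slice.

The *epilarynx-exit reference plane* is the first slice just below the
uppermost slice with complete posterior closure of the arytenoid
cartilages. From it:

- **ELA** (endolaryngeal area, mm^2): area of the slice 5 below the
  reference (about 1.6 mm),
- **HPA** (hypopharyngeal area, mm^2): area of the slice 30 above (9.765 mm),
- **ELV** (endolaryngeal volume, mm^3): integral from the ventricular-fold
  width minimum up to the reference plane,
- **HPV** (hypopharyngeal volume, mm^3): integral from the reference plane
  over the 30 slices above it,
- **LH** (laryngeal height, mm): with helpline A through the C1 and C7
  anterior vertebral rims and helpline B normal to A through the anterior
  commissure, LH is the distance from the A-B intersection to the C7
  landmark, positive toward C1.

Volumes are left Riemann sums over half-open slice ranges `[lo, hi)`, so
the reference slice shared by ELV and HPV is counted exactly once. The
ventricular-fold border is the slice of minimal left-right lumen width
below the reference; ties break toward the slice nearest the reference, and
the resulting ELV height must lie in 4-20 mm (warning outside 6-14.5 mm).
The width is measured along the in-plane mediolateral axis because no finer
anatomical definition of "distance between the folds" survives resampling.

Singing values are expressed relative to speech-like phonation as
`pc = singing / speech x 100` (reported alongside `delta_pc = pc - 100`),
and `delta_LH = LH_speech - LH_singing` is positive when the larynx is
lower in singing. Aggregates are means of per-record pc values, not pc of
means.

The analytic error estimate treats a measured area as a circle: a diameter
uncertainty `dd` brackets the real area between `pi((d-dd)/2)^2` and
`pi((d+dd)/2)^2`, with relative errors quoted against the perturbed areas.
For 55 mm^2 and dd = 1 mm this gives 29 % / 20 %; for 860 mm^2, 6.3 % /
5.8 % — small laryngeal areas are intrinsically less reliable than large
hypopharyngeal ones.

## Geometry extraction

`build_centerline` finds the two tube ends of the lumen by a double
geodesic-farthest-point sweep seeded at the arytenoid-ventricular-crossing
landmark, snaps each end from the face rim to the mid-lumen ridge (maximal
wall distance within the end cap), routes a minimal path with cost
`1/(1 + D)^2` on the Euclidean distance transform `D`, smooths it with a
parametric spline, and prolongs it to the tube ends with a
predictor-corrector march (step along the running tangent, re-center on the
normal-plane lumen centroid). The march's in-plane correction is capped at
0.4 steps and the direction update damped (0.8/0.2 blend): without both,
centroid jitter can turn the march around inside the lumen. How the
centerline continues beyond the two defining landmarks is not anatomically
prescribed; following the mid-lumen ridge to the tube ends is this
package's choice.

Resampling uses nearest-neighbor interpolation for label volumes and linear
interpolation with a 0.5 threshold for gray values; the in-plane pixel
pitch defaults to the slice spacing. Per slice only the connected component
containing the centerline point is kept, which retains piriform-sinus
recesses exactly when they connect to the main lumen within that slice.
Slices whose plane leaves the volume or misses the lumen are flagged and
carried as NaN gaps, never dropped. Gray-scale preprocessing is integer
trilinear upsampling plus Perona-Malik diffusion (exponential conductance,
step 0.1); label volumes bypass smoothing. Semiautomatic contour
correction of real MRI is out of scope.

On voxelized test tubes (0.5 mm voxels) this chain recovers a straight
tube's axis to under one voxel, arc lengths to under 2 %, and constant
areas to a few percent; through the full pipeline at 0.7 mm voxels the HPA
of a generated tract is recovered to about 1-2 %, while the ELV is the
least stable measure (its lower border rides on a quantized width minimum —
the same mechanism that makes the ELV height "dynamic" on real data).

## Synthetic data generator

No imaging or audio from the original study is distributable, so the
generator emulates its design: 13 subjects x 5 vowels (/a e i o u/) x 2
phonation modes, with a tubular airway whose area profile has a glottal
segment, a ventricular-fold constriction (40 mm^2 at the minimum), an
epilaryngeal tube (~55 mm^2), a steep hypopharyngeal widening to ~190 mm^2
at the HPA level, and an oropharynx/oral cavity reaching the lips at
~175 mm, bent 90 degrees at the oropharynx by default. Cross-sections are
circular so analytic areas exist as oracles (an equal-area elliptical
option exists for robustness tests); landmarks are emitted as coordinates
because their identification on real images is manual.

The singing transform encodes the study conditions as generator defaults:

| effect | default | meaning |
| --- | --- | --- |
| `larynx_lowering` | 8 mm | caudal shift of laryngeal landmarks; also stretches the pharynx above the HPA level by the same amount |
| `hpa_scale` / `hpv_scale` | 1.219 / 1.168 | hypopharyngeal widening at the HPA level / integrated over the HPV window |
| `ela_scale` / `elv_scale` | 1.121 / 1.072 | epilaryngeal widening at the ELA level / integrated over the ELV window |

Because the area and volume effects differ, the widening is applied as a
linear arc-length taper whose free coefficient is solved (in closed form,
against the discrete slice grid) so that the area at the measurement slice
and the windowed volume integral hit both targets exactly. The pharynx
stretch sits entirely above every measurement window, so it changes the
acoustics (a longer lower VT) without touching the morphometric truth.

Cohort noise has three layers, chosen so the estimators the statistics
module uses are unbiased for the injected effects:

- subject anatomy: multiplicative size factors, Normal(1, 0.10), separate
  for lower and upper VT, plus a Normal(0, 4 mm) LH offset — these cancel
  in all relative measures;
- mode-effect heterogeneity: off by default (each subject receives the
  injected effect exactly, so the truth table carries, e.g., delta-LH = 8 mm
  in every record); configurable SDs exist for robustness and coupling
  studies;
- measurement error: per-record lognormal with 1 % relative SD on areas
  and volumes (sub-voxel segmentation repeatability at the 0.3255 mm grid)
  and 0.3 mm additive on LH. Keeping this small keeps the Jensen bias of
  mean-of-ratio pc estimates (~exp(sigma^2)) far below the simulation's
  standard error.

Under the null (all effects neutral) the per-subject mode contrasts are
symmetric scale mixtures, and the RM-ANOVA mode effect rejects at 5.1 %
over 1000 replications (computed by the acceptance script). What passing
these tests does *not* show: robustness to real inter-subject anatomy
variation (vowel shape factors here are fixed multipliers), to irregular
cross-sections, to segmentation bias, or to vibrato-driven motion artifacts
— the generator has none of these. ΔHI values in cohorts are drawn from a
configurable linear model (mean 4.5 dB, SD 6 dB, optional coupling to the
subject's HPA change), not rendered through the acoustics chain, which
keeps cohort statistics fast; the audio path is exercised separately.

## Acoustics

The 1D model is native: per-segment chain matrices of the lossy
telegraphist equations, with series impedance `R' + jwL'` (viscous
boundary layer + air mass) and shunt admittance `G' + jwC'` (thermal
conduction + compliance), `L' = rho/A`, `C' = A/(rho c^2)`,
`R' = (S/A^2) sqrt(w rho mu / 2)`,
`G' = S (gamma-1)/(rho c^2) sqrt(lambda w / (2 rho c_p))` for perimeter
`S`. Defaults: c = 350 m/s, rho = 1.14 kg/m^3 (warm moist air), lip
radiation as a piston in an infinite baffle (full Bessel/Struve
expressions), glottal source with internal resistance 20x the glottal
characteristic impedance. Segments are the cylinders between consecutive
area samples (mean of endpoint areas); segments under 1e-6 mm are merged.
Formants are strict local maxima of the gain on the frequency grid
(default 0-5500 Hz, 5 Hz), reported ascending. Formant *frequencies* are
the supported comparison surface; levels and bandwidths depend on the
damping configuration. Side branches are not modeled as shunts, matching
the analysis convention of disregarding the inferior piriform sinuses.

Closed-form anchors: a lossless closed-open uniform tube (L = 175 mm,
c = 350 m/s) yields 500/1500/2500 Hz within one grid step, and a
constriction-cavity geometry in the lumped regime matches the Helmholtz
frequency with the baffled-piston end correction (l_eff = l + 8a/3pi) to
0.4 %. A parameter sweep confirms the decoupling argument: as the
outlet/pharynx area ratio falls below 1:6, the lumped lower-VT resonance
grows monotonically less sensitive to upper-VT perturbations.

Hybrid area functions splice a donor's lower VT (glottis to the
vallecula-inferior junction, half-open) onto a recipient's upper VT with no
smoothing at the junction; self-splicing is bitwise exact. On the default
synthetic pair, the hybrid with the singing lower VT moves the 4th formant
from 3555 Hz to 3405 Hz relative to the all-speech tract — the direction,
not the magnitude, is the claim under test, and it is driven jointly by the
hypopharyngeal widening and the pharynx stretch of larynx lowering.

## Spectrum analysis

The LTAS is a Welch PSD (Hann, 4096 samples, 50 % overlap by default)
integrated into half-open 250 Hz bands up to 5.5 kHz. The Hammarberg index
is the highest band level in [0, 2000) Hz minus the highest in
[2000, 5000] Hz — the 2 kHz band-edge belongs to the upper range — and
`delta_HI = HI_speech - HI_singing`, positive when the singer's formant
cluster is more prominent in singing. Peak frequencies are reported
alongside HI because the upper-range maximum need not be the cluster. The
dB reference is arbitrary; every supported comparison is a level
difference, and amplitude scaling provably cancels. Loudness compensation
(`level'_k = level_k + gain_k * delta_Leq`) requires an explicit per-band
gain profile: the published numeric factors are not reproduced here, so the
profile is a configuration input (an illustrative example profile ships for
tests) and compensated results are configuration-sensitive.

## Statistics

Two-way repeated-measures ANOVA (phonation mode x vowel, both within
subjects) is delegated to `pingouin.rm_anova`; Greenhouse-Geisser corrected
p-values are always reported next to uncorrected ones (for the two-level
mode factor the correction is the identity), and unbalanced designs raise
rather than impute. Regressions are OLS with the signed correlation `r`
reported separately from `r^2`, because summaries of this kind sometimes
print signed values under the name R^2. No multiple-testing correction is
applied (matching the analysis style being reproduced); reports flag this.

## Problem sizes

Test volumes are 40-80 mm tubes at 0.5 mm voxels and one full tract at
0.7 mm; cohort simulations use n = 13 subjects with 100 replications for
effect recovery and 1000 for the null calibration. These sizes were chosen
so the whole suite exercises every stage end to end in well under a minute
of compute while keeping Monte-Carlo standard errors an order of magnitude
below the tested tolerances.

## Known limitations

- The centerline chord-projection monotonicity filter assumes total path
  turning below ~90 degrees - adequate for vocal tracts, wrong for hooks.
- ELV depends on a width-minimum border and inherits its quantization;
  treat synthetic ELV tolerances (5-8 %) as the method's honest precision.
- The 1D acoustics assumes plane waves (valid well below ~10 kHz for these
  areas), no wall vibration, and no side-branch shunts.
- Absolute spectral levels and formant bandwidths are configuration-
  dependent and deliberately unsupported as comparison surfaces.
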