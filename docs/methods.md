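# Methods

`batmap` re-implements, as a tested pipeline, the computational chain of
a water–fat MRI cooling–reheating experiment on human brown adipose
tissue: simulation of multi-echo chemical-shift-encoded scans of the
neck, water–fat/R2* map reconstruction, segmentation of the
cervical-supraclavicular fat depot (suspected brown adipose tissue,
"sBAT") and of posterior subcutaneous fat ("SAT"), rigid transfer of
VOIs between the three scan states (Baseline → Cold → Reheated), and
the paired statistics that attribute a cold-induced fat-fraction
decrease to lipid consumption or to perfusion.

## Signal model

Each voxel's complex multi-echo signal follows the standard
chemical-shift-encoded model

    s(TE_n) = (W + F · c_n) · exp(i·2π·ψ·TE_n) · exp(−R2*·TE_n)

with water and fat amplitudes W, F (arbitrary units), B0 off-resonance
ψ (Hz), one shared relaxation rate R2* (s⁻¹), and the fat modulation
c_n = Σ_p α_p exp(i·2π·f_p·TE_n) from a multi-peak fat spectrum.  The
fat fraction is FF = F/(F+W); changes are quoted in percentage points
(pp).  T1 weighting is not modelled: the emulated protocol uses a 6°
flip angle precisely so that T1 effects are negligible.

The default acquisition matches the emulated protocol: 1.5 T, six
unipolar echoes with TE1 = 1.68 ms and ΔTE = 2.87 ms, TR = 32.7 ms,
1.0×1.0×2.0 mm³ voxels, axial slices, axes x = right-left,
y = anterior-posterior (posterior = +y), z = feet-head.

### Fat spectrum

The original reconstruction used a nine-peak fat model whose numeric
values are not public.  The package default derives the nine resonances
from the standard triglyceride proton model with chain length
cl = 17.4, double bonds ndb = 2.8 and methylene-interrupted double
bonds nmidb = 0.7 (typical in-vivo values).  Proton counts per
resonance follow the usual bookkeeping (methyl 9H, methylene
6(cl−4)−8·ndb+2·nmidb, β-carboxyl 6H, allylic 4(ndb−nmidb), α-carboxyl
6H, diallylic 2·nmidb, glycerol 4H+1H, olefinic 2·ndb), normalised to
relative amplitudes.  Frequencies are ppm offsets from water (4.7 ppm)
scaled to the field strength; the dominant methylene peak lands at
−217 Hz at 1.5 T.  The spectrum is configurable and every CLI
reconstruction logs the spectrum in use; simulator and reconstructor
share one spectrum object by construction.

## Reconstruction

Estimation is decoupled, in three stages plus a polish:

1. **Field map.**  ψ is searched on a discrete grid covering one
   aliasing period ±1/(2ΔTE) ≈ ±174 Hz in 2 Hz steps, with R2* held at
   0.  For fixed ψ the amplitudes are linear, so a candidate's fit
   residual is ‖s‖² minus the energy of s projected onto the span of
   the demodulated {1, c_n} basis; the per-candidate orthonormal bases
   are precomputed, which turns the whole search into a handful of thin
   real matrix products.  Spatial consistency is enforced by the cost
   Σ_v R̂_v(ψ_v) + μ Σ_{⟨u,v⟩} ((ψ_u−ψ_v)/f_s)² with per-voxel
   residuals normalised by signal power, six-neighbour cliques,
   f_s = 1/(2ΔTE), and regularisation weight μ = 10 by default.  The
   optimiser is iterated conditional modes (checkerboard sweeps) on a
   dyadic three-level coarse-to-fine pyramid (block-averaged complex
   data); the coarsest level is initialised by an exact dynamic-program
   solve of the same cost along a serpentine chain through the volume.
   The chain initialisation is what prevents large coherently
   water-fat-swapped regions — pure per-voxel initialisation leaves the
   swapped branch locally self-consistent on wide field gradients, and
   ICM cannot escape it.  With μ = 0 the estimate reduces exactly to
   independent per-voxel exhaustive search.
2. **R2*.**  At the estimated ψ, a per-voxel 1D discrete search over
   0–150 s⁻¹ in 0.5 s⁻¹ steps (same projection trick), wide enough for
   adipose, muscle and marrow values with fine resolution.
3. **Polish.**  A vectorised Gauss–Newton refinement of (ψ, R2*)
   jointly, using the variable-projection residual with the Kaufman
   Jacobian (the dA/dθ·x term projected onto the orthogonal complement
   of the basis span).  This removes the discretisation floor: on
   noiseless data the iteration converges to machine precision, so the
   reconstruction inverts the forward model exactly.  Discrete-map
   outputs of stage 1 are kept as the field-mapping result so the μ = 0
   oracle equivalence is exact.
4. **Amplitudes.**  A final complex 2×2 least squares at the refined
   (ψ, R2*); W and F are reported as magnitudes and FF = |F|/(|F|+|W|),
   with FF := 0 and a degeneracy flag where F+W is below the machine
   noise floor (e.g. empty background in noiseless data).

Numerical conventions: field-map candidates are ordered by |ψ|
(positive before negative at equal magnitude) so residual ties break
toward smaller |ψ|; R2* ties break toward smaller R2*.  With magnitude
discrimination enabled (default), exactly tied field-map candidates are
instead resolved toward the solution whose dominant species fraction
max(|W|,|F|)/(|W|+|F|) is largest; with the nine-peak spectrum exact
ties essentially never occur, so this matters only for degenerate
single-peak spectra.  A rank-deficient basis (all c_n = 1, i.e. a
single on-resonance peak) raises a degeneracy error.

## Phantom and cohort generator

The digital neck phantom is built from analytic geometry — an
elliptical body cross-section filled with muscle, a posterior
subcutaneous fat band along the back surface, two interior sBAT
ellipsoids flanked by fat-free vessels, and a central vertebral-marrow
blob — so tissue labels are exact at any rigid pose: inter-state motion
is applied by evaluating the geometry at back-transformed coordinates,
giving interpolation-free ground truth.  Within-tissue heterogeneity is
a smooth random cosine field per tissue (default SD 1.5 pp FF,
0.5 s⁻¹ R2*) that moves with the anatomy; the B0 field map is a smooth
random low-order polynomial (default amplitude ~25 Hz) fixed in the
scanner frame, as shim fields do not move with the subject.  Complex
Gaussian noise is added independently per voxel/echo to the real and
imaginary channels; with unit in-body proton density the default
noise SD 0.02 corresponds to SNR ≈ 50.

Default tissue values: sBAT FF 82.8 %, R2* 21.0 s⁻¹; SAT FF 85.2 %,
R2* 19.6 s⁻¹ (the study's baseline group means); muscle FF 10 %,
R2* 30 s⁻¹; vessels pure water, R2* 25 s⁻¹; marrow FF 60 %, R2*
60 s⁻¹.  Marrow is deliberately placed centrally and given a
trabecular-bone-dominated R2* above the 50 s⁻¹ VOI ceiling: early
phantom versions with low-R2* marrow adjacent to the posterior band
leaked marrow voxels into the automatic SAT VOI under inter-state
rotation, biasing SAT-FF changes by ~0.2 pp — anatomically the two
depots are separated, and trabecular marrow R2* at 1.5 T is well above
adipose values.

The cohort generator emulates the study design.  Per subject it draws
baseline sBAT/SAT FF and R2* from the reported group distributions,
then applies per-subject effects, each drawn from a normal (mean, SD)
at the reported group statistics:

* lipid-type sBAT-FF change −1.94 ± 1.83 pp at Cold, persisting
  through Reheated;
* perfusion-type sBAT-FF change (default 0) at Cold, reversing at
  Reheated;
* posture-related SAT-FF drift −0.79 ± 0.27 pp applied between the
  Cold and Reheated scans regardless of temperature (−0.75 ± 0.64 pp
  between the two scans of the procedure-study mode, n = 8);
* R2* changes at Cold: sBAT +0.65 ± 0.88 s⁻¹ (reversible), SAT
  +0.40 ± 0.46 s⁻¹ (persistent).

States after the first receive a random rigid offset (uniform ≤3 mm
in-plane, ≤1 slice through-plane, ≤3° per axis) to exercise
registration.  The crude sBAT mask over-segments the true blob by one
26-neighbourhood dilation, so boundary voxels (muscle/vessel) exceed
10 % of the mask and threshold-plus-erosion refinement is
consequential.  A truth ledger records exact per-subject, per-state VOI
means.

What the generator does *not* emulate: partial-volume mixing at tissue
boundaries (labels are binary per voxel), coil sensitivities and
correlated noise, chemical-shift spatial displacement, respiratory
motion, and T1 weighting.  Passing recovery tests therefore show the
pipeline is unbiased under the stated signal model and realistic noise,
not that it is robust to every artefact of real scans.

## Segmentation and VOI transfer

The crude sBAT VOI is refined by inclusive thresholds — keep FF ≥ 40 %
(removes non-fatty tissue) and R2* ≤ 50 s⁻¹ (removes partial-volume
boundary voxels) — followed by one pass of 3D binary erosion with the
six-neighbourhood structuring element (grid borders count as
out-of-mask).  The R2* ceiling is sometimes quoted with mismatched
units ("≤ 50 ms"); this package fixes it as R2* ≤ 50 s⁻¹ (equivalently
T2* ≥ 20 ms), the only reading consistent with R2* values in s⁻¹.
Erosion is applied once, after thresholding; the original analysis
documents neither the ordering nor the pass count.

The SAT VOI is fully automatic and computed independently per state: a
body mask from Otsu thresholding of W+F, then per axial slice the
fat-passing connected components touching the posterior skin, restricted
to ≤10 mm depth from the posterior surface (both parameters
configurable; the depth has no documented reference value), then the
same single erosion.  The procedure is deterministic and
translation-equivariant along the right–left axis.

Refined sBAT VOIs are defined once on the first state and carried to
the other states by rigid registration of the FF maps (SimpleITK:
normalised cross-correlation, Euler3D transform, two-level
multi-resolution, dense sampling, geometric-centre initialisation —
deterministic given the inputs), with nearest-neighbour mask
resampling; voxels mapping outside the grid are dropped, mirroring the
slightly smaller registered VOIs seen with imperfect scan overlap.
Refining at baseline and transferring the refined VOI (rather than
re-thresholding per state) keeps the VOI definition identical across
states; at the depot's FF (~80 %) the thresholds are far from active
within the refined VOI, so the two orderings agree.  A rigid model is
an approximation of neck posture change; deformable registration is out
of scope.

## Statistics and attribution

All within-subject comparisons use the two-sided Wilcoxon matched-pairs
signed-rank test at α = 0.05.  Zero differences are dropped and tied
|differences| receive midranks; for effective n ≤ 25 the null
distribution of the rank sum is computed exactly by dynamic programming
over the 2ⁿ sign assignments (midranks doubled to integers), and the
two-sided p is the exact probability of a rank sum at least as far from
the symmetric centre as observed; above n = 25 the tie-corrected normal
approximation is used.  These conventions (zero-drop, midranks) are the
classical exact construction; the original analysis software's
conventions are unknown.  P values in [0.05, 0.10) carry a separate
"trend" label that plays no role in attribution.  No multiple-testing
correction is applied, matching the per-comparison α of the emulated
analysis.

The attribution rule formalises the protocol's reasoning — perfusion is
rapidly regulated and reverses after ~15 min of reheating, lipid
content is slowly regulated and persists:

| Cold−Baseline | Reheated−Baseline | Reheated−Cold | mechanism |
|---|---|---|---|
| sig. decrease | sig. decrease | n.s. | lipid |
| sig. decrease | n.s. | sig. rebound | perfusion |
| sig. decrease | sig. decrease | sig. | mixed |
| n.s. | — | — | none |
| anything else | | | indeterminate |

The rule is a pure function of the three tests' significance flags and
change signs.  It is an interpretation: the verbal argument it encodes
was never stated as an algorithm.

### Detection power at the reported effect sizes

With per-subject lipid effects drawn at the reported cold-change
statistics (−1.94 ± 1.83 pp, n = 9, standardised effect ≈ 1.06), the
exact Wilcoxon test at α = 0.05 has power ≈ 0.75–0.80 per comparison;
the joint "lipid" pattern (two significant decreases plus one null
result) is detected in ≈ 74 % of simulated cohorts, and the analogous
perfusion-only pattern in a similar fraction.  A ≥ 90 % attribution
rate is therefore not attainable at those effect sizes — the single
observed cohort succeeding (as reported) is consistent with ~0.75
per-cohort probability.  At larger effects (e.g. a reversible
−3 ± 1 pp perfusion effect) the rate exceeds 90 %.  The package's
attribution-rate checks run at the measurement level (generator truth
draws plus VOI-mean measurement error of 0.1 pp, the imaging chain's
repeatability scale), since the attribution rule consumes only VOI
means.

## Problem sizes and defaults

Cohort experiments default to 32×32×8 grids at 1×1×2 mm³ — large
enough to host every tissue structure with erodible VOIs and small
enough that a full three-state, nine-subject cohort reconstructs in
well under a minute, so recovery experiments over 20 independent
cohort replicates per protocol mode are routine.  The acceptance script
(`scripts/acceptance.py`) uses exactly these sizes; single-phantom
verification (noiseless inversion, swap resistance) uses up to 48×48×8.
Larger grids change nothing qualitatively: geometry, VOI rules and
reconstruction are resolution-independent, and voxel counts per VOI
only grow.

## Known limitations

* Binary tissue labels mean no true partial-volume voxels; the
  threshold-plus-erosion rules are exercised against mask
  over-segmentation, not against continuous tissue mixing.
* The attribution rule's power at the reported effect sizes is ~0.75
  (see above); conclusions from a single n = 9 cohort are fragile.
* The rigid motion model and NCC registration are idealised relative
  to real neck posture changes and slice-coverage mismatch.
* The magnitude-discrimination tie-break cannot distinguish water from
  fat for a *single-peak* spectrum's exactly symmetric swap; the
  multi-peak default does not suffer from this.
* R2* estimation shares one decay rate between water and fat; separate
  decays are out of scope.
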