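# Methods

`fiberaif` simulates a scintillating-fiber positron detector placed against
a superficial vessel, and evaluates whether its counting statistics support
non-invasive measurement of the arterial input function (AIF) for PET
pharmacokinetics. This note records the physical model, its parameters,
the bookkeeping conventions, and the limits of what the simulations show.

## Transport model

**Positrons.** Histories are emitted uniformly inside a source volume with
isotropic directions and kinetic energies drawn from the allowed beta-plus
shape `N(T) ∝ p·E_tot·(Q−T)²·F(Z,T)` with a nonrelativistic point-charge
Fermi function (repulsive for positrons; daughter Z = 8 for ¹⁸F → ¹⁸O and
Z = 30 for ⁶⁸Ga → ⁶⁸Zn). Sampling is by inverse CDF on a 1 keV grid.

Tracks advance by condensed-history steps losing a fixed fraction
(`step_fraction`, default 0.05) of the current energy, with the step length
`ΔE / S(E)` taken from embedded collision stopping-power tables
(Berger–Seltzer positron formula with the Sternheimer density effect,
tabulated log-log over 10 keV–3 MeV for water, polystyrene, air, and a
water-composition bone variant). Steps are clipped at volume boundaries so
every deposit lands in the volume actually traversed. Angular deflection
per step is a mixed scheme:

* a soft Gaussian core with the Highland width
  `θ₀ = (13.6 MeV / βpc) √(x/X₀) (1 + 0.038 ln(x/X₀))`, scaled by a single
  calibration constant `scatter_scale`;
* explicit hard elastic events beyond 30°, Poisson-sampled at the Wentzel
  (screened-Rutherford) rate with Molière screening. The constants
  (`2π r_e² Σ nᵢ Zᵢ(Zᵢ+1)` per material, effective Z for screening) are
  fixed by composition; this component has no free parameter. It supplies
  the backscatter tail a pure Gaussian model lacks.

Below the 10 keV tracking cutoff the residual energy is deposited locally
and the positron annihilates at rest into two exactly collinear
back-to-back 511 keV photons (no acolinearity, no positronium fractions —
sub-resolution at these geometry scales).

**Calibration.** `scatter_scale = 0.7` was fixed once by scanning against
the four published positron-range figures for water — mean displacement
0.57 mm (¹⁸F) / 2.69 mm (⁶⁸Ga) and maximum range 2.16 / 9.06 mm — and
against nothing else. At that value all four land within 10%. No other
quantity in the package was used for calibration.

**Range conventions.** The CSDA range exposed by the materials layer is the
*path length* `∫ dE/S(E)` from the 10 keV cutoff; at the beta endpoints it
evaluates to 2.43 mm (¹⁸F) and 9.49 mm (⁶⁸Ga) in water. The published
"maximum range" figures are penetration depths, which scattering makes
shorter than the path length; the package therefore reports maximum range
as the 99.9th percentile of the emission-to-rest displacement of
endpoint-energy positrons under transport. A fixed high quantile is used
rather than the sample maximum because the maximum of an ensemble grows
with the ensemble size while the quantile is stable (±0.1% across seeds at
2×10⁴ histories).

**Photons.** 511 keV photons are ray-traced with segment-wise exponential
attenuation using incoherent-scattering attenuation coefficients
(photoelectric and pair production are negligible in these low-Z media).
A photon interacts at most once: if the sampled interaction point lies in a
fiber, a Klein–Nishina electron recoil energy is deposited (composition–
rejection sampling of the scattered-photon fraction; deposits bounded by
the 340.7 keV Compton edge); an interaction anywhere else terminates the
history ("scatter as absorption"). This single-interaction model slightly
underestimates scattered background reaching the fiber.

**Background sources.** Body volumes (10 MBq mouse body, 176 MBq human
torso at 30 cm) are simulated photon-only: each sampled decay annihilates
at its emission point (the positron range is negligible on the body scale)
and, under the default forced-direction importance sampling, one direction
per decay is drawn uniformly in the cone subtending the detector's bounding
sphere with statistical weight `2 × Ω_cone/4π` (two photons per decay).
This reaches the same expectation value as analog sampling (verified within
statistics in the test suite) at a small fraction of the histories, which
is how desk-scale runs stand in for the original study's 4×10⁷–10⁸
analog background histories.

## Geometry

All scenes live inside a 2 m air cylinder; volumes are finite cylinders and
axis-aligned boxes with integer priorities (innermost wins), and the fiber,
vessel and anatomy axes run along z with the detector on the −y side.
Scene construction follows the published anatomies:

* **Mouse tail**: 3.2 mm water cylinder, 60 mm long, 1 mm axial bone
  insert; ventral artery ∅0.1 mm and three veins ∅0.2 mm (lateral ±90°,
  dorsal opposite the artery — the anatomical description names the sides
  but not exact angles), all 0.1 mm below the surface; 1 mm round fiber,
  30 mm long, 0.1 mm air gap; 25×70 mm body cylinder, its near face 30 mm
  from the fiber's near end.
* **Human wrist**: 8 cm water cylinder, artery ∅2.3 mm at configurable
  depth (reference 2 mm, measured skin-to-vessel-surface); one round ∅1 mm
  fiber or 1–4 square 1×1 mm fibers, 10 cm long, 0.1 mm off the skin;
  optional 20×70 cm background cylinder 30 cm below the detector.
* **Validation tube**: 1×1×70 mm water tube (70 µL) facing a 7 cm fiber
  (square section for ¹⁸F, round for ⁶⁸Ga, mirroring the bench fibers)
  through a 200 µm polystyrene wall plus 200 µm air gap.

Bone inserts default to water composition (the study assigns soft tissue to
water and never specifies bone); a cortical-bone variant at 1.85 g/cm³ is
registered for sensitivity checks.

## Counting statistics and bookkeeping

**Efficiency** is the fraction of emitted positrons whose track deposits
more than the lower energy threshold in a fiber, evaluated from exact
per-history deposits (the binned spectrum gives the same numbers at 10 keV
granularity). Positrons emitted below the tracking cutoff count in the
denominator.

**Emission section.** Vessel decays are simulated over the section the
detector subtends axially (30 mm of the 60 mm mouse vessels; the full
length in the wrist and tube scenes, where fiber and vessel lengths match).
Positrons from beyond the fiber ends are ≥15 mm away with sub-millimetre
ranges and cannot contribute, and the sensitivity definition divides by the
same subtended volume, so efficiency and volume refer to one consistent
section. This convention is also the only one that makes the published
sensitivity prescription (detected counts × subtended arterial volume ÷
simulated decays) dimensionally consistent.

**Sensitivity** `s = ε · V_subtended[mL] · 1000`, in cps/(kBq/mL). The
beta branching fraction `f` enters exactly once per figure: for bench-style
sensitivities (count rate per activity concentration, Table-style
comparisons) it is folded into `s`; for MDA it stays in the denominator of
the Currie formula and `s` excludes it. Both paths are explicit
(`includes_branching`).

**MDA** `= 4.65 √(N_B + 2.71) / (f · T · s)` with `N_B` the background
counts in one frame (T = 1 s mouse, 5 s human — the frame duration at the
AIF peak) from the body simulation at the same threshold as `s`. A zero
sensitivity yields an explicit infinity.

**Gamma share of detections.** A history is positron-detected if its track
deposit exceeds the threshold, and gamma-detected if only its annihilation
photons' deposits do. The published shares (1.62% ¹⁸F, 0.18% ⁶⁸Ga) are
reproduced as the share of the monitored-artery simulation. An
activity-weighted artery+veins share is also computed (analysis scripts):
it is necessarily several-fold larger, because the twelve-fold vein
activity contributes vein annihilation photons at a rate fixed by solid
angle and interaction probability alone — no choice of positron
efficiencies can push that weighted share down to the published values,
which is why the monitored-vessel reading is the one a detector of the
artery actually sees.

**Dead time.** The decaying-source method: for a source decaying at rate
λ through a non-paralyzable detector, `m e^{λt} = n₀ − n₀τ·m` is exact, so
ordinary least squares of `m e^{λt}` on `m` (bin-center times, unweighted)
returns `n₀` (intercept) and `τ = −slope/intercept`. On noiseless synthetic
series the recovery is exact to numerical precision; under Poisson noise at
bench-like settings (n₀ = 5×10⁴ cps, τ = 2 µs, 1 s bins, three half-lives)
the error stays below 5% in every one of 100 replicates. The errors-in-
variables bias of regressing on a noisy abscissa is negligible here because
the dynamic range of `m` dwarfs its per-bin noise.

**Calibration** of count rate to concentration is a single-point linear
map, as the detector concept requires.

## Synthetic data

The decaying-series generator is the exact forward model of the dead-time
fit (true rate `n₀e^{−λt}`, observed `n/(1+nτ)`, optional Poisson counts
per bin) — it validates parameter recovery, not detector physics. The AIF
generator is an explicit stand-in: a gamma-variate bolus parameterized by
peak concentration, peak time and washout rate, frame-integrated; no AIF
model is implied by the detector study, and the functional form rides along
in the output metadata. Radioactive decay of the tracer is excluded by
default (flag available). Neither generator emulates blood-sample noise,
plasma/whole-blood partitioning, or metabolites.

Passing tests on these generators therefore shows that the counting
machinery is correct, not that real acquisitions look like the synthetic
ones.

## Numerical choices

* Steps: 5% fractional energy loss, capped at 200 mm (air), boundary-
  clipped with a 10⁻⁶ mm crossing overshoot; results stable to halving the
  step fraction.
* Ray tracing: per-volume entry/exit candidates, midpoint classification,
  1e-9 mm boundary epsilon; surfaces belong to the inner volume. Verified
  against a 1 µm step-marching oracle on random rays.
* Spectra: 10 keV bins over 0–2000 keV (configurable).
* Seeds: every stochastic stage derives its stream from the user seed by a
  fixed affine map mod 2³¹−1; a fixed seed reproduces tallies bit-exactly.
* Transport kernels are numba-compiled; the Python geometry layer
  (`locate`, `ray_segments`) mirrors the kernel logic and is
  cross-checked against it implicitly by the marching-oracle tests.

## Problem sizes

Analyses and the acceptance evaluation use 10⁵ vessel histories, 2×10⁴
endpoint-energy range histories, and 10⁶ importance-sampled background
decays; unit tests use 10³–2×10⁴. With the weighted background estimator
these sizes put every reported quantity's Monte Carlo error well inside the
tolerances quoted for it (vessel efficiencies ±1–2% relative; mouse
background counts ±7%; the human background, whose detector subtends a tiny
solid angle at 30 cm, is the noisiest at ~20% relative and enters only
MDA-saturation comparisons that reuse one background realization).

## Known limitations

* No delta rays, bremsstrahlung, energy-loss straggling, or in-flight
  annihilation; the deposit spectra are correspondingly slightly sharper
  than full-physics transport.
* Photon transport is single-interaction with scatter-as-absorption, so
  tissue-scattered photons that would still reach the fiber are dropped;
  the MDA tolerance budget absorbs this (background is underestimated
  somewhat, MDA likewise).
* Background positrons from non-vessel tissue (skin, vessel wall) are not
  simulated — the detector study treats them as future work, and the MDA
  here, like the published one, counts gamma background only.
* The bench-measured quantities (fiber types, coatings, SiPM settings,
  measured sensitivities, the measured 2.3664 µs dead time) require the
  instrument; the dead-time machinery is validated by parameter recovery
  on synthetic data instead, with the measured τ used only as a realistic
  setting.
* Scintillation light and photosensor response are outside scope (as in
  the original simulations); thresholds are on deposited energy.
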