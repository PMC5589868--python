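# Methods

`ionoptode` models, calibrates and quantifies ionophore-based optode
nanosensors for ratiometric intracellular ion imaging, with calcium as the
worked ion. This note records the models, the defaults and why they are
what they are, the numerical choices, and what the synthetic-data tests do
and do not establish about real data.

## The equilibrium model

An ion-selective optode holds three lipophilic components in a hydrophobic
matrix: an optically silent ionophore `I` that binds the analyte
`M^{z+}` with stoichiometry `n`, a fluorescent pH-indicator
chromoionophore `C` whose protonation state is the optical readout, and a
cation exchanger `R⁻` that fixes the total positive charge the phase can
hold. Extraction of one ion displaces `z` protons. Writing `alpha` for
the **protonated fraction** of chromoionophore (`alpha = 1` at zero
analyte; some treatments use the opposite convention — the algebra here is
consistent with `(1-alpha)/alpha = [C]/[CH+]`), mass balance and
electroneutrality give the aqueous activity in closed form:

    a_M(alpha) = (z K_exch)^-1 ((1-alpha)/alpha · a_H)^z
                 · (R_T - alpha C_T) / (I_T - (R_T - alpha C_T) n/z)^n

* `C_T`, `R_T`, `I_T` — total component concentrations in the sensor
  phase. Only their ratios matter; `K_exch` absorbs the absolute scale.
  The default composition uses the molar ratios of a practical Ca2+
  recipe: `I_T : C_T : R_T = 2.278 : 1 : 1.276`, `z = 2`.
* `n` — ionophores per complexed ion. Not fixed by the recipe; default 2
  for the 2:1 Ca2+ ionophore complex, configurable 1–4 and tested across
  that range.
* `K_exch` — a single lumped, dimensionless exchange constant. Its
  decomposition into acidity/complexation constants is deliberately not
  modelled; it has **no default** and is either supplied or solved from a
  target midpoint (`exchange_constant_for_midpoint`, a one-evaluation
  solve since `a_M ∝ 1/K_exch` at fixed alpha). The shipped default
  equilibrium places the midpoint at 105 nM at pH 7.2, a sensor tuned to
  the ~100 nM resting cytosolic Ca2+ level.
* `a_H = 10^-pH`. Because the proton term enters as `a_H^z`, the midpoint
  scales exactly as `10^(z·ΔpH)` — a ×100 shift per pH unit for Ca2+,
  which is why quantitative intracellular use leans on cytosolic pH
  buffering. This closed form is used as an exact test of the
  implementation.
* Aqueous activity is equated to molar concentration (dilute-solution
  assumption); an `activity_coefficient` hook on the grid-level functions
  scales it when needed (default 1).

**Feasibility domain.** alpha is confined to the open interval
`(max(0, (R_T − I_T z/n)/C_T), min(1, R_T/C_T))`: above it the exchanger
could not balance the protonated chromoionophore, below it the free
ionophore is exhausted. The closed endpoints are evaluated exactly (upper
endpoint → activity 0; a positive lower endpoint → +∞) rather than clamped,
so the zero-ion and saturation limits are exact; out-of-domain input raises
an error naming the violated constraint.

**model_ec50.** The model-side sensitivity index is the concentration at
which alpha sits midway between its two domain endpoint values, computed in
closed form (the exact root). Defining it from the domain endpoints rather
than from a particular grid makes it grid-independent and makes the pH
scaling law exact — the two properties tested.

**Tunability direction.** In the exchanger-limited regime (`R_T ≤ C_T`,
ionophore in excess) raising `R_T/C_T` monotonically lowers the midpoint
(more sensitive). This is the regime in which "add exchanger to
sensitize" holds; for `R_T > C_T` the upper alpha endpoint pins at 1 while
the extractable ion load keeps growing, and the trend reverses. The
tunability test sweeps the exchanger-limited regime and the restriction is
intentional, a property of the algebra above.

**Inversion.** `alpha_from_ion_activity` uses bracketed bisection on the
strictly monotone forward map (200 iterations max, relative tolerance
1e-12). Bisection is deliberately preferred over derivative-based root
finders: it cannot escape the bracket and behaves identically well
arbitrarily close to the domain endpoints, where the forward map is stiff.
It is verified against an independent brute-force bisection of a separate
formula transcription to 1e-8 across randomized compositions.

## Calibration

The readout is the emission ratio `R = I_670 / I_575` (chromoionophore :
reference dye). Acid/base endpoint standards give the fully
protonated/deprotonated ratios `R_P`, `R_D`, and
`alpha = (R − R_D)/(R_P − R_D)`; noisy values slightly outside [0, 1] are
returned unclipped with a warning, never silently truncated.

Ratio–concentration series are fitted with the four-parameter
dose-response (Hill) model in log10 concentration,

    R(C) = R_min + (R_max − R_min) / (1 + 10^((log EC50 − log C) · p)),

whose exact algebraic inverse,

    C = EC50 · ((R − R_min)/(R_max − R))^(1/p),

is the quantification rule. Numerical choices:

* **Signed slope.** For these sensors the ratio falls as the ion rises, so
  `p < 0`; no absolute values anywhere, and the inverse inherits the sign
  through `1/p`. The parameterization is degenerate under
  (`R_min ↔ R_max`, `p → −p`); fits are canonicalized to `R_max > R_min`
  (the Top/Bottom convention), including the covariance permutation.
* **C = 0 point.** The ion-free chelator buffer has no logarithm; it is
  excluded from the regression and used only to initialize the zero-ion
  plateau — standard dose-response practice.
* **Initialization and multi-start.** Plateaus from observed extremes,
  EC50 from the concentration nearest the ratio midpoint, slope started at
  ±1; the lowest-SSE converged start wins. Non-convergence of all starts
  raises an error carrying the per-start diagnostics.
* **Plateau constraints.** The emission ratio of any protonation state is
  physically confined between the endpoint-standard ratios. `fit_hill`
  therefore bounds both plateau parameters to the endpoint ratios ±25% of
  their span; without this, a series that does not reach its plateaus (the
  default 10 nM–10 µM grid does not — see below) makes the free
  four-parameter fit ill-posed and 1% well noise can send EC50 orders of
  magnitude away. For short stepped series (in situ calibration) the
  plateaus are pinned **at** the endpoint ratios outright, fitting only
  EC50 and slope. Fits without endpoint information fall back to bounds
  derived from the observed ratio span.
* **Replicates.** Fitting uses per-concentration means by default
  (`pooled=True` fits every well; `weighted=True` applies inverse-variance
  weights from replicate spread). The covariance is reported in the fitted
  space (`r_min`, `r_max`, `log10_ec50`, `slope`).
* **EC50, not Kd.** The fitted EC50 is an empirical half-response index of
  the whole exchange system, not a binding constant, and is never labelled
  Kd.

Selectivity against a fixed interfering ion is the optical-sensor
(Nicolskii–Eisenman-style) coefficient
`log K = log10 EC50_interferent − log10 EC50_primary`, invariant to the
common unit of both inputs. The worked example — Mg2+ at 1 mM vs Ca2+ at
105 nM — gives 3.98, i.e. ~4 orders of magnitude of selectivity.

**Model vs empirical fit.** The equilibrium model for `z = 2` is not a
Hill curve. Its effective slope is capped near `|p| ≈ 0.5` (the squared
proton term alone spreads the response over ≥3.5 decades); the default
composition fits at `|p| ≈ 0.36`. The EC50 *parameter* of a Hill fit to
model-generated data therefore sits systematically a few percent to ~13%
from the model midpoint depending on fit constraints (the documented
model-vs-empirical-fit discrepancy check bounds it at 15% under the
default conditions), while the fitted *curve* interpolates the response to
~0.3% pointwise — which is what the inversion actually uses. Real sensors
are often reported with much steeper empirical slopes than ideal-equilibrium
theory predicts; such cooperativity is outside this model.

## Quantification of time-lapse data

The chain for a stimulus experiment is: per-frame mean ROI intensity per
channel → background subtraction (cell-free ROI; negative results floored
at 0 and flagged, since noise near background is expected) → per-channel
photobleach correction → emission ratio → dose-response inversion →
summary. Per-frame quality flags (bitmask: negative-after-subtraction,
out-of-calibration-range, bleach-fit-failed, zero-reference) are carried
through and flagged frames are excluded from summaries. Ratios at or
beyond the fitted plateaus are flagged and left undefined — the inverse
diverges there and clipping would fabricate concentrations.

**Noise amplification.** With the shallow `z = 2` response, a relative
ratio error is amplified roughly ninefold into concentration around the
100–400 nM range (`d lnC = (1/p) · R (1/(R−R_min) + 1/(R_max−R)) · d lnR`).
Several design choices below exist specifically to stop estimators from
inheriting that amplification.

**Photobleach correction.** A monoexponential `I_0 e^{−kt}` is fitted per
channel on the pre-stimulus baseline window (default: all frames before
the stimulus, minimum 10) via log-linear least squares and divided out,
normalized to t = 0; a linear-drift alternative is a switch. Correction is
applied per channel, not to the ratio (equal rates then cancel exactly in
the ratio). Three safeguards, each optional and each motivated by the
statistics of extrapolating a short fit window far beyond itself:

* *Significance gate* (default 2 s.e.): a rate indistinguishable from zero
  is reported but not extrapolated — correcting with pure noise injects
  more ratio error than the uncorrected drift it would remove.
* *Static reference* (`static_reference=True`): when the reference dye's
  ion dependence is weak (the default channel model gives it a 5% span),
  its intensity is almost a pure bleach reporter and its rate can be
  fitted on the whole recording, shrinking its uncertainty ~20-fold.
* *Quiescent windows*: frame ranges known to sit at the baseline ion level
  (e.g. the tail of a fully recovered transient) extend the fit's time
  span, turning an ill-conditioned extrapolation into an interpolation.
  A fit from a 60 s baseline alone has a rate uncertainty around
  `10^-4 s^-1` at realistic noise — enough to corrupt late-trace
  concentrations by tens of percent once amplified.

A failed decay fit falls back to no correction with a prominent warning
and a per-frame flag.

**Trace summary.** Baseline is the median over valid pre-stimulus frames.
The peak is estimated on split frames: odd-indexed frames (median-smoothed
at the transient's rise time scale, `peak_smooth_s`, default 20 s) locate
the peak; the even-indexed frames near it provide the value estimate, and
the two split roles are swapped and averaged. Locating and estimating on
frames with independent noise removes the upward selection bias of a
running maximum — under ninefold noise amplification, "max of a smoothed
trace" overestimated peaks by tens of percent, while the split estimator
is unbiased to within the window-curvature term (~−3% at the defaults).
`peak_search_s` optionally restricts how far past the stimulus the peak is
sought; agonist-evoked store release peaks within the first minute or two,
and restricting the search keeps slow late-trace drift from masquerading
as the response. Recovery is reported both as the late-trace level and as
the fractional return from peak toward baseline.

**Plateau protocols.** For alternating-bath (reversibility) recordings,
`plateau_concentrations` takes the per-plateau **median ratio** (pooled
across ROIs, skipping the exchange frame) and converts it once —
median-then-convert, because converting per frame near the saturated
plateau amplifies and skews noise that the ratio-space median would have
suppressed. The repeated low plateaus double as quiescent windows for the
bleach fit; the high plateaus then remain an independent check of cycling.

**In situ calibration.** Stepped superfusion with an ion carrier
(ionomycin) equilibrates bath and cytosolic levels; each step's
equilibrium ratio is the median over its frames, each analysis ROI is a
replicate, and the endpoint-pinned two-parameter fit (above) is applied.
The result is tagged `in_situ` and is the calibration of record for
intracellular concentrations when both exist.

## The synthetic-data generator

The generator is the bridge between the equilibrium model and the imaging
pipeline: every downstream stage is tested against data whose ground truth
(Ca(t), alpha(t), masks, bleach rates, density field) is returned with the
data. Every stochastic operation is a pure function of its parameters and
a mandatory seed.

* **Channel model.** Brightness is linear in the protonated /
  deprotonated fractions with strictly positive offsets:
  `I_sense = g_s (a_s·alpha + b_s)` (brighter when protonated),
  `I_ref = g_r (a_r·(1−alpha) + b_r)` (opposite). Defaults give the
  chromoionophore channel a full-span response and the reference dye a
  weak 5% opposite-moving span — a nearly constant reference keeps the
  ratio close to affine in alpha, which is both what one wants physically
  from a reference channel and what keeps the empirical EC50 tracking the
  model midpoint (a strongly modulated reference makes the ratio a curved
  Möbius function of alpha and decouples the two by ~2 orders of
  magnitude). Real dye responses are not exactly linear in alpha; the
  linear map is the minimal assumption consistent with two indicators
  moving oppositely, and it makes the ratio → alpha chain exactly
  invertible for testing.
* **Scenarios.** (i) Plate-reader calibration series over an 11-point
  log grid, 10 nM–10 µM, plus the C = 0 chelator buffer, with acid/base
  endpoint standards and (default) triplicate wells; (ii) stepped in situ
  series with a fixed cell layout across steps, optionally with a
  cytosol-shifted equilibrium; (iii) an agonist-evoked transient —
  100 nM baseline rising to 400 nM shortly after onset (rise τ 5 s), then
  exponential decay (τ 120 s) back, 1 s frames for 10 min, the waveform
  normalized so its maximum equals the peak exactly; (iv) a reversibility
  square wave, 100/1350 nM exchanged every 2 min for five cycles at 10 s
  frames.
* **Image rendering.** 256×256 frames (16-bit range) containing 2–3
  elliptical cells with 5–20 punctate nanosensor foci each on a diffuse
  cytosolic background; the sensor-density field multiplies both channels
  identically — sensor amount cancels in the ratio, the core premise of
  ratiometric imaging. Per-channel exponential bleaching, additive
  background, Poisson shot noise (`photon_scale` counts per intensity
  unit) and Gaussian read noise.
* **Noise presets.** `paper_like` (default) is calibrated so a
  single-frame whole-cell ROI ratio has a CV of roughly 3%
  (`photon_scale = 0.008`, read noise 3 a.u., bleach 2×10⁻⁴ / 1×10⁻⁴ s⁻¹
  sense/reference). `plate_reader` models well-level integration (~1%
  shot noise, no bleach or cellular background). `flowchamber` models a
  bright surface-bound sensor film imaged at 10 s intervals, where the
  tenfold-sparser illumination duty cycle scales bleaching down tenfold.
  `noiseless`, `high_snr`, `low_snr` complete the ladder. All values live
  in the spec/config, not hard-coded in the pipeline.

**What the synthetic tests do not show.** The generator has no optics
(no PSF, no depth attenuation), no cell motion, no focal drift, no sensor
aggregation or compartmentalization, no autofluorescence structure beyond
a flat background, a bleach process that is exactly monoexponential, and a
channel map that is exactly linear in alpha. Passing tests therefore
demonstrate that the *analysis chain is correct and quantitative under its
own stated model* at realistic noise — not that a real microscope dataset
will reach the same accuracy. In particular the end-to-end 10% recovery
figures lean on the generator's bleaching truly being monoexponential and
on the reference dye truly being near-static; both are stated assumptions,
switchable and checkable, not hidden ones.

## Statistical design of the end-to-end checks

The transient-recovery and reversibility checks are stochastic
experiments (calibration draw × imaging draw). Single draws at this noise
level pass ~90% of the time, so each check is evaluated as the median over
three fixed seeded replicates — enough to make the verdict reflect the
method rather than one seed, while staying well inside desk-scale run
times (the full suite runs in about half a minute; the 600-frame 256×256
renders are the dominant cost). Problem sizes throughout (grid points,
replicate counts, frame counts, image sizes) are the study conditions
stated above, chosen once.

## Known limitations

* The equilibrium model is ideal-solution and single-ion; the only
  interference treatment is the fixed-interferent selectivity coefficient.
  Kinetics (response time) are out of scope — the model is equilibrium
  only.
* The shallow `z = 2` response makes single-frame concentration estimates
  intrinsically noisy (~9× the ratio CV); all quantitative summaries are
  therefore window statistics, and single-frame excursions should not be
  over-read.
* `K_exch` is lumped; no attempt is made to reverse-engineer a physical
  exchange constant for any specific sensor batch.
* ROI definition is manual (or generator-supplied); there is no
  segmentation, registration or motion correction.
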