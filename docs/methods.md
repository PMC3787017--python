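# Methods

This note records the models, conventions and design choices behind
`nocisyn`, in the order the analysis runs.

## Behavioural scoring

Formalin injection evokes a biphasic flinching response; the package
quantifies only the second-phase **phase 2A** window, 15–40 min
post-injection, which reflects the descending-inhibition mechanisms the
combination treatments target. The window is **half-open** `[15, 40)` so a
bin boundary is never counted twice; whether the upper edge is open or
closed is a pure convention (counts at an instant have measure zero for a
fine-binned automated counter) and is documented rather than configurable.
Bins that straddle a window edge contribute proportionally to the
overlapped fraction of their width — with the fine bins of an automated
nociception analyzer this apportionment is a no-op, but it keeps coarse
synthetic bins exact.

Percent inhibition normalises each animal to the **mean phase-2A total of
the vehicle arm run in the same session** (concurrent controls); the
dataset schema therefore carries a `session` key and normalisation fails
loudly if a session lacks vehicle animals. Negative percent inhibition
(flinching above vehicle) is retained in per-animal data; only the fitted
curve is floor-constrained, because the constraint belongs to the model,
not the data.

## Dose-response model

The two-parameter constrained logistic in log10 dose:

    E(d) = 100 / (1 + 10^(h (log10 ED50 − log10 d)))

* Floor and ceiling are **hard-fixed at 0 and 100%**; only `log10 ED50`
  and the Hill slope `h` are free.
* The loss is unweighted least squares over **per-animal points**, not
  dose means, so unequal group sizes weight themselves naturally.
* Initialisation is deterministic: `log10 ED50` starts at the tested dose
  whose mean response is nearest 50%, `h` at 1. This is robust for any
  monotone data set and makes fits reproducible bit-for-bit on identical
  input.
* `h` is bounded to (0.1, 10) to exclude degenerate step-function fits on
  sparse designs; `log10 ED50` is unbounded.
* The 95% CI is asymptotic-normal on `log10 ED50` (SE from the curvature
  of the least-squares problem, t critical value with n − 2 df),
  back-transformed to the dose scale, hence asymmetric there. Commercial
  curve-fitting packages compute something equivalent by default; the exact
  construction used in any given report is rarely stated, so published CIs
  are validation guides rather than bit-exact targets. A fit whose CI
  degenerates to zero width (noise-free data) reports no CI.
* Requires ≥ 3 distinct positive doses; vehicle/zero-dose animals set the
  normalisation but never enter the regression.

## Fixed-dose and fixed-ratio synergy

**Fixed-dose**: the adjunct is held at a subefficacious dose while the
partner's dose-response is re-measured. A shift is *significant* only when
the two 95% CIs fail to overlap — strictly: touching intervals are
`no_shift`. This is deliberately conservative, as CI-overlap tests are.

**Fixed-ratio (isobolographic)**: mixtures at constant ratio `r` (parts of
A per part of B) are fitted on **total mixture dose**. The Loewe-additive
prediction is

    Z_add = F·ED50_A + (1 − F)·ED50_B,  F = r / (r + ED50_A / ED50_B)

which is bracketed by the component ED50s and moves monotonically from
ED50_B to ED50_A as the mixture enriches in A. Fitting on total dose is
the Loewe-consistent reading (axes in published isobolograms are sometimes
ambiguous between total and component dose; the verdicts here are robust
to either reading for the interval widths involved).

The additive point's CI uses the **delta method**:
`Var(Z_add) = F² Var(A) + (1 − F)² Var(B)`, with each component SE
recovered from its CI as the mean of the upper and lower half-widths on
the linear dose scale divided by the 97.5% normal quantile, and the
interval `Z_add ± 1.96·SE`. This treats the component estimates as
independent normals on the dose scale — a first-order approximation whose
error is small relative to the interval widths at play (verified in the
test suite against a Monte-Carlo resampling oracle to within 2% on the
endpoints). Whether a published additive CI was combined on the log or
linear scale is generally unrecoverable; the linear-scale combination is
this package's documented choice.

Verdict rule: *synergistic* iff the observed CI lies strictly below the
additive CI; *antagonistic* strictly above; *additive* otherwise;
*indeterminate* when a CI is missing. The continuous **interaction index**
`Z_obs / Z_add` is always reported alongside the category.

## Ex vivo occupancy

The initial rate `v_i` of radioligand binding over a 0–3 min time course
is the OLS slope with a **free intercept** (nonzero t = 0 background is
plausible in homogenate filtration assays); an origin-constrained variant
would be a trivial restriction but is not the default. Slopes within
floating-point noise of zero are clamped silently; genuinely negative
slopes are floored at 0 with a warning.

Occupancy is the fractional rate suppression relative to the **mean** of
vehicle animals' rates, `100 (1 − v_i / mean v_vehicle)` — the only
dimensionally consistent reading of the conventional formula, giving 0%
for a vehicle-level rate and 100% at complete blockade. A literal archival
variant `100 (1 − v_i) / mean` is available behind `literal=True` and
should not be used for analysis. Vehicle normalisation is per session by
default (mirroring behavioural normalisation) with a pooled option.
Negative occupancies from noise are retained — group means near zero
legitimately straddle it.

## In vitro selectivity

Fold selectivity is `10^|ΔpIC50|` rounded to **one significant figure,
half away from zero** (so 10^1.5 ≈ 31.6 → 30, 10^4.3 ≈ 19 953 → 20 000);
the preferred transporter is the one with the larger pIC50, with an exact
tie reported as fold 1 / preference "none" rather than an arbitrary label.
Potencies are carried as −log10 molar throughout and never converted to
nM internally. Unbound concentrations are `total × fu` with `fu ∈ (0, 1]`.

## Synthetic-data generator

The generator emulates the data structure of the assay, not its biology:

* **Flinch counts** are negative-binomial with mean
  `vehicle_mean · (1 − E(d)/100)` and size (dispersion) parameter 10 —
  overdispersed relative to Poisson, matching the large animal-to-animal
  variability evident in formalin-test group SEMs. The vehicle mean
  defaults to 150 flinches per phase-2A window, a realistic magnitude for
  an automated counter; it is a config knob and nothing downstream depends
  on it. Default group size is 8 animals/dose with 4 doses.
* **Fixed-ratio mixtures** respond to total dose through the same sigmoid
  with true ED50 `interaction_index · Z_add`; a single multiplicative
  index is the minimal deviation model able to produce all three verdicts.
  Default mixture doses span 0.2×–6× the additive prediction — centred on
  the *additive* point regardless of the true index, exactly as an
  experimentalist doses around the expected potency.
* **Binding courses** are exact lines at 0/1/2/3 min; vehicle animals'
  slope is fixed at `v0` (the noise-free reference) while treated animals'
  slopes are `v0 (1 − θ/100)` times mean-one lognormal noise with CV 0.1.
  Putting all noise on the treated side keeps the reference exact, so
  round-trip recovery error is governed purely by the treated sample.

What the generator does **not** emulate: within-window flinch dynamics
(each animal carries one phase-2A bin), pharmacokinetic drift, session
effects beyond the session key, correlations between an animal's
behavioural and binding read-outs, and any mechanistic PK/PD. Passing
tests therefore demonstrate that the analysis chain is correct and
calibrated under the stated statistical model — not that the model
captures every feature of real animals.

## Calibration and problem sizes

The test suite runs the full simulate → fit → verdict loop at
paper-like experiment sizes (8 animals/group, 4 doses/arm): 200 replicate
single-drug experiments for parameter recovery (median fitted ED50 within
10% of truth), 100 replicate fixed-ratio experiments per interaction-index
setting for verdict calibration (≥ 90% "additive" under exact additivity;
majority "synergistic" at index 0.33, the effect size observed for a 3:1
NET-inhibitor:morphine mixture), and 100 simulated animals for the
occupancy round trip. These sizes give stable pass/fail behaviour while
keeping the whole suite under a minute of CPU for the stochastic parts.
The fitter is additionally checked against a brute-force grid-search
oracle (log10 ED50 ∈ [−2, 2] step 0.001, Hill ∈ (0, 5] step 0.01) on
small noisy instances.

## Known limitations

* The CI construction for fitted ED50s is asymptotic; at n = 8/dose with
  overdispersed counts the nominal 95% coverage is approximate (the
  calibration tests quantify the practical consequence: ~5% false synergy
  and antagonism calls combined under exact additivity).
* The additive-point CI assumes independent, linear-scale-normal component
  estimates.
* CI-overlap verdicts are conservative relative to a direct test of the
  interaction index.
* Occupancy assumes linear (initial-rate) binding over 0–3 min; no
  association-kinetics modelling.
* Two-drug mixtures only; no response-surface or three-way designs.

## File schemas

* **Flinch CSV**: `session, animal_id, arm, drug1, dose1_mg_kg
  [, drug2, dose2_mg_kg, …], bin_start_min, bin_end_min, flinches`;
  blanks in drug columns mean vehicle.
* **Binding CSV**: `session, animal_id, arm, transporter, time_min,
  signal`.
* **Compound CSV**: `name, pic50_sert, pic50_net, pki_sert, pki_net,
  fu_plasma, fu_brain` (optionals blank).

Units are fixed by convention: doses mg/kg, times minutes, potencies
−log10 molar, binding signals arbitrary units. CLI runs that write files
also write a `manifest.json` with a config hash, seed and output list.
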