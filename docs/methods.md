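# Methods

## The system being modeled

Chikusetsusaponin IVa (CS-IVa, C42H66O14, MW 795.0 g/mol) is given
intraperitoneally to rats; plasma concentration is followed over 24 h
(0–1440 min) and, in the myocardial ischemia/reperfusion (MIRI) setting,
serum CK-MB — an injury-release biomarker — is followed as a group-level
pharmacodynamic endpoint. Because dosing is extravascular and
bioavailability F is not separable, every volume and clearance in this
package is apparent (V/F, CL/F). Units are fixed throughout: minutes,
mg/L, L/kg, mg/kg, 1/min; no unit inference is attempted.

## Forward kinetic models

The one-compartment first-order-absorption solution
C(t) = D·ka/(V(ka−ke))·(e^{−ke·τ} − e^{−ka·τ}), τ = t − tlag, and the
standard triexponential two-compartment solution are implemented in
closed form. When |ka − ke| < 1e−8·max(ka, ke) the analytic limit
(D·ka/V)·τ·e^{−ka·τ} replaces the difference quotient to avoid
catastrophic cancellation; the same guard protects every pairwise
exponential difference, including the effect-site convolution. A ka that
numerically coincides with a two-compartment hybrid macro-constant
(a measure-zero input) is nudged by one part in 1e9.

The effect-site concentration solves dCe/dt = ke0·(Cp − Ce) with
Ce(0) = 0. For a one-compartment plasma curve the analytic convolution is
used; for tabulated plasma profiles each linear interpolation segment is
advanced with its exact closed-form response
Ce(h) = Ce₀e^{−ke0·h} + a(1−e^{−ke0·h}) + b(h − (1−e^{−ke0·h})/ke0),
which is deterministic and robust to grid choice (no ODE stepping).

## Synthetic study generator

The generator reproduces the study design: arms Nor-7.5, Nor-15, Nor-30
and MIRI-15, n = 8 rats each, a 13-point schedule
{5, 10, 15, 30, 45, 60, 90, 120, 240, 360, 480, 720, 1440} min, plus a
pre-dose zero row. The 13-point count is inferred from the published
information-criterion pair: SBC − AIC = p(ln n − 2) equals the printed gap
1.695 at p = 3 exactly when n = 13. The schedule itself is configurable
because the study's appendix schedule is not public.

True parameters are anchored to the published summary table:
ke = ln2/T½ (Nor: 445.89 min; MIRI: 238.66 min), V = Vz (5.83 and
7.21 L/kg), which makes the model AUC(0–∞) = D/(V·ke) match the published
AUC(0–∞) (1655 and 717 min·mg/L) by construction. ka (0.10 normal,
0.025 MIRI 1/min) was chosen so the MIRI curve peaks later and lower than
the dose-matched normal curve, with a predicted MIRI Tmax (~97 min) and
Cmax (~1.57 mg/L) in the neighbourhood of the published model-predicted
ranges. A one-compartment curve cannot simultaneously reproduce the
published *observed* Cmax (9.34 mg/L for Nor-15) and the published
AUC/T½; the generator therefore guarantees the directional contrasts
(lower Cmax, later Tmax, shorter T½, larger V in MIRI; AUC rising with
dose), not the observed-Cmax magnitudes.

Noise model: per-rat parameters are log-normal around the group truth
(15% CV by default, mean-one on the natural scale), and each observation
gets proportional (10% CV) plus additive (0.005 mg/L) Gaussian error,
truncated at zero. Observations below the quantification threshold —
1.22 nM converted to 9.70e−4 mg/L at MW 795.0 — keep their measured value
and carry a flag; they are zeroed for AUC and excluded from the terminal
regression only at analysis time.

CK-MB is generated at {30, 60, 120, 240, 360, 480, 720, 1440} min (the
PD sampling times are not public): the untreated course is a logistic
rise-and-plateau (plateau 200 ng/mL, midpoint 240 min, width 120 min),
and the treated course subtracts a PD function of Ce(t; ke0_true = 0.001
1/min) — linear with slope 150 ng·mL⁻¹ per mg·L⁻¹ by default — plus
5 ng/mL of noise, floored at zero with a clip warning.

What passing tests show, and do not show: the generator produces exactly
the delayed-response, dose-proportional, one-compartment world the
analysis assumes, so green tests demonstrate that the machinery recovers
known truth under the study's design and noise levels — not that real
CS-IVa kinetics are one-compartmental (the real profiles show a secondary
rise consistent with enterohepatic recycling, which this generator does
not emulate), nor that CK-MB dynamics are linear in Ce.

## Non-compartmental analysis

Default AUC/AUMC is the linear trapezoid; lin-up/log-down is available by
flag (the originating tool's setting is unstated). The terminal slope
uses the usual automatic best-fit rule: all windows of ≥ 3 positive
concentrations that end at the last positive observation and exclude
Tmax; maximize adjusted R²; ties (within 1e−10) go to the longer window;
a non-negative slope or no valid window yields a failure marker that
propagates as NaN through the ∞-extrapolated parameters. Extrapolations:
AUC(0–∞) = AUC(0–t) + Clast/λz and
AUMC(0–∞) = AUMC(0–t) + Clast·tlast/λz + Clast/λz². Welch's test is
computed from summary statistics with Welch–Satterthwaite degrees of
freedom; a pairwise test is suppressed and reported "N.C." when the two
groups are indistinguishable at report rounding (2 decimals for Vz/CL),
mirroring how apparent clearance was reported.

## Fitting engine

The default fit target is the group mean profile (naive-mean fit): the
study reports a single criterion set per group, and the mean profile
gives n_obs = 13. Weighted least squares Σ wᵢ(Cᵢ − Ĉᵢ)² with
wᵢ ∈ {1, 1/Ĉᵢ, 1/Ĉᵢ²} is solved by iteratively reweighted
Levenberg–Marquardt: weights are frozen from the current predictions,
an inner LM solve runs on a log-parameter scale (tlag linear), and the
outer loop repeats until the relative parameter change is < 1e−6 and the
relative WSS change < 1e−8, up to 200 outer rounds. Predicted
concentrations are floored at 1e−8 of their maximum inside the weight
computation so early-time zeros cannot produce infinite weights.

The inner solver is unconstrained LM with a wide safety clip on the
internal scale (0.5 bound-spans beyond the declared box) and a cap of 200
function evaluations per solve; declared bounds are rates ∈ [1e−6, 10]
1/min, volumes ∈ [1e−3, 1e3] L/kg, tlag ∈ [0, first sampling time].
Convergence classification requires the outer criteria, all parameters
strictly interior to the declared bounds, and finite standard errors;
violations yield converged = false with a reason
(max_iterations / parameter_at_bound / singular_normal_equations), never
an exception.

Initial values come from curve stripping: λz from the terminal regression
gives ke, back-extrapolation through AUC gives V, and the residual
(feathering) method gives ka with a 5·ke fallback. Multi-start adds
one-at-a-time ×0.3 and ×3 perturbations of each rate/volume parameter,
capped at 9 starts; the best converged WSS wins, in deterministic order.
One-compartment results are canonicalized to the ka ≥ ke branch of the
flip-flop ambiguity ((ka, ke, V) → (ke, ka, V·ke/ka) leaves the curve
invariant), so reported estimates are comparable across starts and folds.

Diagnostics at the optimum: standard errors from
(JᵀWJ)⁻¹·WSS/(n−p) with a central-difference Jacobian on the natural
scale; CV% = 100·SE/|estimate|; condition number = ratio of extreme
singular values of √W·J (rank deficiency → +∞). AIC = n·ln(WSS) + 2p and
SBC = n·ln(WSS) + p·ln n (the convention that makes small-WSS fits print
negative criteria); a numerically perfect fit reports the −∞ sentinel.
Because weighted WSS values live on different scales, AIC/SBC are flagged
comparable only within one weighting scheme, and the selection policy
respects this: discard non-converged rows and rows with any CV% > 50 or
condition number > 1e4; within each scheme keep the lowest-AIC row,
preferring fewer parameters when ΔAIC < 2; across schemes prefer the
simplest weighting with a survivor. Every discard is recorded in an audit
trail.

Leave-one-rat-out refits the chosen model on the mean profile of the
remaining rats, once per excluded rat, and reports per-fold diagnostics
plus min–max ranges of predicted Cmax, Tmax and AUC(0–tlast) (dense-grid
trapezoid of the fitted curve) over converged folds.

## Exposure–response

ΔCK-MB is computed only at exactly matched times (no interpolation;
≥ 3 matches required). The hysteresis loop closes the time-ordered
(concentration, effect) path last-to-first, takes the signed shoelace
area, and normalizes by the bounding rectangle, making the area invariant
to affine rescaling of either axis and bounded by 1; positive area means
counterclockwise traversal with concentration on the x-axis, the
signature of an effect lagging exposure. Paths with a zero axis range or
numerically zero area are flagged degenerate.

The PD model linking Ce to ΔCK-MB is linear (E0 + S·Ce) by default —
the fewest assumptions for an exploratory difference endpoint — with an
Emax alternative (bounded least squares; an estimate at its bound counts
as non-convergence). "CORR" is the Pearson correlation of observed vs
fitted effect; PD AIC uses the same n·ln(SSR) + 2p convention as the
kinetic fits. The ke0 scan covers
{0.01, 0.005, 0.002, 0.001, 0.0005, 0.0002, 0.0001, 0.00005} 1/min by
default; the best row is the lowest PD AIC among converged rows, ties
broken by higher correlation, then larger ke0. For zero-noise data
generated with a linear link, the (Ce, Δ) loop area attains its minimum
at the generating ke0 (collapse-the-loop principle) — this is the
recovery property the acceptance checks exercise. One caveat found while
validating: for an effect that is *instantaneous* in plasma
concentration, the loop only collapses monotonically once the ke0 grid
extends beyond the kinetic rate constants; on the default (slow) grid a
very slow Ce can fit such data with a lower AIC than the grid's fastest
value, so the no-delay diagnostic is only meaningful on an extended grid.

Analysis is group-level throughout: the PD endpoint is a group mean
course, and no per-animal PD fitting is attempted.

## Problem sizes used by the tests and acceptance script

Parameter recovery uses 100 replicates of 13-point profiles at 10%
proportional noise; model selection simulates 100 full studies and refits
the 12-candidate ledger on each; leave-one-rat-out uses the 8-rat MIRI
arm; the forward-model oracles compare against LSODA integration at
rtol 1e−10 on seeded random parameter draws. These sizes keep the full
suite comfortably fast while leaving the Monte-Carlo margins (e.g. worst
median recovery error ~10% against a 15% bound) far from their
thresholds.

## Known limitations

- The generator is one-compartmental by design; it cannot produce the
  secondary concentration rise seen in the real medium/high-dose curves.
- Biomarker dynamics are phenomenological: CK-MB release/clearance
  kinetics (an indirect-response description) are out of scope, so ke0
  has no mechanistic interpretation here.
- The condition-number and information-criterion conventions match this
  package's definitions; other tools may report square-root or
  likelihood-based variants, so absolute values are comparable only
  within this artifact.
- Welch comparisons operate on summary statistics; with n = 8 per arm
  they are exact but the "N.C." suppression rule is a reporting
  convention, not a statistical judgment.
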