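# Methods

## Signaling model

The network is a logic-based ODE (LBODE) system in the Netflux style: species
activities are normalized to `[0, ymax]`, every directed edge is a normalized
Hill sigmoid, and Boolean structure enters through continuous AND/OR
composition. The closed form used for activation is

    f(x) = B·xⁿ / (Kⁿ + xⁿ),   B = (EC50ⁿ − 1)/(2·EC50ⁿ − 1),   Kⁿ = B − 1,

which pins f(0)=0, f(EC50)=½, f(1)=1; inhibition is 1 − f(x). AND gates multiply
the per-input factors of one reaction; OR folds the weighted reaction drives
left-associatively as a + b − a·b in table order (OR is associative and
commutative, so the order is fixed only for bit-reproducibility). Drives are
clipped to [0,1] before the OR fold. The glucose stimulus is exempt from
clipping: its drive is the schedule weight W'(t), which may exceed 1, and
downstream edges evaluate their Hill transfer at x > 1, saturating toward B.

Species dynamics are first-order relaxations dy/dt = (ymax·F − y)/τ. Time
constants are assigned by reaction class: receptor binding 0.35 h, NF-κB
activation 0.055 h, generic signaling 1 h, translation 1.13 h, transcription
88 h, combined transcription+translation for the secreted cytokines (IL-6,
TNF-α, IL-1β) 90 h, and a fitted 400 h constant for pMLC.

### Network reconstruction

The shipped 34-species table (`data/species.tsv`, `data/reactions.tsv`) was
reconstructed from the published network diagram and the reactions named in the
accompanying text; the full supplementary parameter tables of the source model
were not available to us. Consequently every reaction uses the documented
default parameters (W = 1, n = 1.4, EC50 = 0.5) and every species the default
ymax = 1, y0 = 0 with its class time constant; the `provenance` column marks
the one transcribed exception (τ_pMLC). The backbone is the glycation cascade
glucose → AGE → RAGE(GEC) → NADPH oxidase → ROS → NF-κB(GEC) → IL-1β →
IL-1R(macrophage) → NF-κB → VEGF-A mRNA → VEGF-A → VEGFR2 → Rho/Rock → pMLC,
closed by the macrophage autocrine loop NF-κB → IL-1β → IL-1R → NF-κB. The
myosin cycle (MLCK, MLCP, MLC, pMLC) and the two actin pools couple the
signaling layer to structure; the healthy variant flips the single
Rho/Rock–MLCP edge from inhibiting to activating, which re-balances stressed
and relaxed fibers.

Two consequences of the all-default parameterization are worth knowing:

- MLCP and MLCK have purely inhibitory (or mixed) inputs, so they carry basal
  drive at rest — a constitutively active phosphatase/kinase pair that the
  stimulus then modulates. A zero-glucose simulation relaxes them to 1, not 0.
- The autocrine IL-1β loop is bistable. With defaults it commits between weeks
  3.5 and 4 of the glucose ramp; glycemic control applied by ~week 3 fully
  reverts the network, later control suppresses only the glucose-proximal
  nodes (AGE, RAGE, NADPH) while the loop self-sustains and the structural
  damage proceeds. With the original calibrated parameters the committed point
  lies somewhat later (control at 4 weeks still reverts); the qualitative
  early/late dichotomy is identical.

## Glucose input

Dimensional glucose follows the printed linear fit G(t) = 0.051·t − 9.38 mmol/l
on 336–1008 h, then piecewise-constant interval means (weekly to 11 weeks,
biweekly 12–20). The network weight is the affine normalization
W'(t) = (G − gmin)/(gmax − gmin) with gmin = G(336 h) = 7.756 mmol/l. gmax is a
fixture policy value: we set it to the linear prediction at week 5
(33.46 mmol/l) so that normalized glucose reaches 1 at 5 weeks and stays above
1 afterwards — the regime in which the published network self-sustains maximal
activation. The synthetic plateau defaults to 43 mmol/l (SD 3), typical of
severely diabetic leptin-deficient mice and above the week-6 linear endpoint so
the schedule never steps downward at the splice. Note that a literal
"gmax = max(mean + SD) of the plateau intervals" cannot coexist with a mean
weight ≥ 1; we prioritized the dynamical regime over that bookkeeping identity.

The virtual population draws one normal sample per interval per mouse
(`normrnd`-style, seeded, n = 100 by default); negative draws are kept with a
warning rather than truncated, since the model consumes only the normalized
weight.

## Fenestration structure

Number and diameter follow the two ODEs given in the README. Both
`|ss − N|^nf` terms make their fixed points semi-stable: approach is
polynomial, ε(t) ≈ (3·k·t)^(−1/3) for nf = 4, so the diseased state 4.02 is
approached to ~0.02 by 5000 h but never crossed. The diameter power
(pMLC − pMLC0)^nf is evaluated sign-preservingly (|x|^nf·sign x) so transient
excursions below baseline remain defined for non-integer nf; with the default
pMLC0 = 0 this never triggers. Number is continuous-valued throughout — it is
a normalized density, not a count. Initial conditions default to the healthy
baselines (7.00, 47.91 nm). Driven-mode integration interpolates the network
outputs piecewise-linearly on the simulation grid (6 h by default); a joint
co-integration mode exists and agrees with the driven mode to solver tolerance
(there is no feedback from structure to signaling).

Integration uses LSODA with rtol = atol = 1e-6 throughout the simulation
surface, matching the stiff-solver tolerance of the original analysis.

## Calibration

Stage 1 fits (kform, Nss1, nf) to healthy-arm densities with only the
formation term active, on the healthy network variant. Stage 2 fixes nf and
fits (kloss, Nss2) to diabetic densities and (ks, kd, τ_pMLC) to diabetic
widths as independent sub-fits on the disease variant. Every sub-fit launches
a bound-constrained local optimization from 25 Latin-hypercube starts over the
printed sampling ranges (which double as bounds) and keeps the lowest-SSE
solution; the SSE is unweighted.

Optimizers: the density-type sub-fits use trust-region-reflective least
squares with a finite-difference step of 1e-4 (relative) — large enough to sit
above the ODE-solver noise floor — and fmincon-like tolerances (1e-8 on the
objective, 1e-6 on parameters). The width sub-fit instead uses an
interior-point trust-region minimizer (`trust-constr`), because its SSE
surface is rank-deficient along the ks/kd ray (see below) and a reflective
solver drifts along the box edge; the interior-point method, like the
original fmincon default, handles the flat direction gracefully (zero-noise
recovery: ks within 0.5%).

Two performance devices keep the multi-start affordable without changing the
estimator: (1) only the sub-network downstream of a changed parameter is
re-integrated, with frozen interpolants for unaffected inputs — exact because
the affected set is closed under influence; for τ_pMLC this is the
{pMLC, MLC} pair. (2) The linear diameter ODE is solved by an exact
exponential integrator (piecewise-linear forcing), vectorized over the grid.
τ values are cache-keyed at 1e-3 h, far below both the finite-difference step
(~0.05 h) and any identifiable τ change.

### Identifiability

The calibration design observes both arms at weeks 6/10/15/20, close to their
structural steady states, which makes several parameters practically
non-identifiable at realistic noise:

- Healthy densities sit within ~0.15 of Nss1 = 7.00 from week 6 on; only the
  slow ε-tail carries (kform, nf) information, so at 10% observation noise
  their fitted values scatter across the sampling range (median relative
  errors ≈ 190% and 40% over 20 replicates). Zero-noise recovery is sharp
  (≤1%), confirming the objective has a well-defined global minimum at truth.
- With kd ≈ 2 h⁻¹ the diameter is quasi-steady at weekly spacing: the data
  constrain the ratio ks/kd (and τ_pMLC) tightly, but the lag signal that
  separates ks from kd is ~0.01–0.05 nm — invisible under nm-scale noise. The
  per-replicate best fit therefore tends to a ks sampling bound, and the
  replicate-median ks can land at 75 nm/h depending on the noise seeds. This
  is a property of the published observation design and parameter regime, not
  of the optimizer: at zero noise all five stage-2 parameters are recovered
  within 0.5–3%.

The corresponding noisy-recovery acceptance test is left failing by design;
its assertion states the intended tolerance, and the failure documents the
identifiability limit quantitatively.

## Uncertainty, sensitivity, interventions

Uncertainty propagation follows the resampling recipe exactly: fits within 20%
of the lowest SSE are "acceptable"; each parameter is resampled independently,
uniformly with replacement, from its values in that subset (marginals
preserved, joint correlations deliberately broken — this is a heuristic
ensemble, not a Bayesian posterior); 100 parameter vectors are rerun and the
2.5%/97.5% empirical quantiles (linear interpolation between order statistics)
form the 95% equal-tail band per time point.

The sensitivity screen reduces each species ymax and each reaction weight
one-at-a-time to zero for the whole simulation and evaluates
S = 100·(ΔY/ΔP)·(P/Y) on the final-time number and diameter; |S| > 1.5%
classifies "sensitive". The sign convention makes inhibition that lowers the
output positive. Interventions reuse the event mechanism (timed overrides that
scale the pristine parameter, so repeated events never compound): glycemic
control resets the schedule weight to 0 from t_c; the five chemical agents map
KN93 → Ca, ML-7 → MLCK, Y27632 → Rho/Rock, calyculin A → MLCP,
cytochalasin B → stressed actin with ymax → 0 at the initial time, simulated
over the seeded virtual population with pooled-variance two-sample t-tests
(raw-value and summary-statistic forms agree algebraically); timed 50%
knockdowns run to 30 weeks with glucose held at its 20-week value.

## Synthetic data

The generator stands in for the external mouse measurements the original
calibration used. Glucose: the plateau fixture described above. Observations:
the model itself is run under the true parameters (Table-defaults) and
independent additive normal noise is applied — density for both arms, width
for the diabetic arm, at weeks 6/10/15/20. Default noise SDs are ~10% of the
baseline values (0.7 for density, 4.8 nm for width). The healthy arm starts
its number at 5.0, i.e. the cohort is observed while fenestration density is
still maturing toward the adult 7.00 — without that transient the formation
parameters would be unidentifiable even in principle. Noiseless mode
reproduces the model predictions exactly, which anchors the recovery oracles.

What the generator does not emulate: per-animal structural variability (all
mice share one structural truth; only glucose varies across the population),
non-Gaussian or heteroscedastic measurement error, drop-out, and any
within-mouse correlation between density and width errors. Passing recovery
tests therefore certify the estimation machinery, not robustness to real
measurement pathologies.

## Problem sizes

Default test-suite and acceptance-script sizes: network simulations on a 6 h
output grid over weeks 2–20 (2–30 for timed interventions); 25 optimizer
starts per sub-fit; 20 replicates for recovery statistics; 100-member
ensembles and populations in the full pipeline, reduced to handfuls in unit
tests where only wiring is under test.
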