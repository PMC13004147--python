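# Methods

## Setting and assumptions

A hybrid controlled trial (HCT) pools an RCT's internal control arm with
external real-world patients on the same control treatment. Notation:
A treatment (randomized within the trial; external subjects are controls
only), Y a binary outcome, S trial inclusion, U a categorical unmeasured
confounder of S and Y, α = n_treated/n_IC the allocation ratio, and
η = n_EC/n_IC the borrowing ratio. Measured covariates are assumed
handled upstream (here by entropy balancing), so the residual difference
between control arms is interpretable as unmeasured confounding. Two
identification assumptions matter: trial inclusion has no direct effect on
the outcome (S affects Y only through U given A = 0), and associations are
expressed as maximal risk ratios over confounder categories, which makes
the bounds below sharp and attainable at RR_SU = RR_UY.

## The bounds and tipping values

The bias factor BF — pooled HCT effect over the confounding-free
within-trial effect — satisfies

    BF ≤ (1+η)·RR_SU·RR_UY / (RR_SU·RR_UY + η(RR_SU + RR_UY) − η),

which lies in [1, 1+η]; with no borrowing (η = 0) the pooled estimate is
the trial estimate and no inclusion confounding is possible, and as
η → ∞ the bound degenerates to the classic E-value geometry. Solving the
bound's diagonal for the confounder strength gives the HC-value

    HC(RR, η) = (η·RR + √(RR(RR−1)·η(η+1))) / (1 − RR + η),

defined for folded RR < 1+η and +∞ beyond (reported as a flagged
infinity, never an exception, because "no confounder suffices" is a
legitimate, informative answer). The residual difference obeys
RD ≤ RR_SU·RR_UY/(RR_SU+RR_UY−1), giving the RD-value
RD + √(RD(RD−1)) — algebraically identical to the E-value formula but
with a different interpretation: the confounding already implied by the
observed control-arm discrepancy.

Both formulas are validated by round-trip identities rather than external
references: plugging HC(RR, η) into the bias bound at equal coordinates
recovers folded RR to 1e-10 across parameter grids, and likewise for the
RD pair; the η → ∞ limit reproduces the E-value to 1e-3 at η = 1e6.

### Folding

Every metric folds its input (x ↦ max(x, 1/x)) internally, so callers may
pass protective or harmful ratios; reports keep the original orientation.
A confidence interval containing 1 — including exactly touching it — needs
no confounding to explain, so its CI-limit HC-value is 1.

### Frontier curves

The single-number tipping values summarize a two-dimensional region; the
frontier functions return the exact boundary using the algebraic inverses

    effect: RR_UY = b·η·(RR_SU − 1) / ((1+η)·RR_SU − b·(RR_SU + η)),
    RD:     RR_UY = r·(RR_SU − 1) / (RR_SU − r),

each valid where the denominator is positive and omitted elsewhere.
Default grid: 200 log-spaced RR_SU values from the threshold to 10× the
threshold. Frontier points are verified against the forward bounds to
1e-8.

## Decision rules

Step 1 gates on significance of the pooled estimate (Wald CI excluding 1
at the configured level, default 95%); without significance there is
nothing to explain away and verdicts are "not applicable". The effect
verdict rejects the null when RD-value < HC-value of the point estimate;
the significance verdict compares against the CI-limit HC-value. Ties
resolve to fail-to-reject (the benchmark confounding is already strong
enough). An infinite HC-value rejects automatically, flagged in the
narrative. Two Discussion-grade variants — RD-value of an RD CI limit and
non-95% confidence levels — are available but off by default; the RD
upper-limit variant in particular is unnecessarily conservative, and the
defaults reproduce the two rules whose operating characteristics the
simulation study evaluates.

## Estimation

With a single binary predictor the log-binomial MLE is the ratio of arm
proportions, so estimation is closed-form; the test suite checks this
against an independent iteratively fitted GLM. CIs are Wald on the log
scale with variance (1−p₁)/(n₁p₁) + (1−p₀)/(n₀p₀); under weights, arm
sizes are replaced by Kish effective sample sizes ((Σw)²/Σw²), a
sandwich-type correction. Weighted estimates are invariant to rescaling
all weights. Zero-event arms are non-estimable by design — no continuity
correction, because at the study's arm sizes and risks such replicates are
vanishingly rare and corrections would bias medians; the simulation layer
drops and counts them, warning loudly above 1%.

## Entropy balancing

External-control weights minimize KL divergence from uniform (or supplied)
base weights subject to matching trial summary moments and a fixed total,
defaulting to n_IC so the weighted external arm has effective η = 1.
Constraints: mean per continuous covariate, plus an optional second
moment implemented as E[(X − μ_target)²] = σ²_target with the population
(n) convention; level proportions with the reference level dropped for
categorical covariates. The strictly convex dual is solved by Newton with
Armijo backtracking (convergence: max moment violation < 1e-8, ≤ 200
iterations), falling back to BFGS near singular Hessians. Collinear
constraint columns are removed by pivoted QR before solving — a redundant
constraint therefore cannot change the solution — and targets outside the
observed covariate range raise an infeasibility error naming the
constraint. No weight trimming is applied; diagnostics (range, CV, Kish
ESS, achieved-vs-target table) surface extremes instead.

## Simulation engine

The generator emulates the reference study conditions and doubles as the
package's synthetic-data source. Defaults: 300 trial subjects randomized
2:1 (200/100), η = 5 (500 external), P(U=1|S=1) = 0.5 with
P(U=1|S=0) = 0.5/RR_SU, baseline risk P(Y=1|A=0,U=0) = 0.2, RR_UY = 2
multiplying (poorer external outcomes) or dividing (better) the risk at
U = 1, treatment effect RR_AY ∈ {1, 1.5} applied multiplicatively with no
A×U interaction, 5000 replicates. Arm sizes are deterministic; only U and
Y are random. Any parameter combination implying a cell probability above
1 is rejected at construction. Replicate r draws from the substream
`default_rng([seed, r])`, making scenarios bitwise reproducible and
order-independent.

Closed-form population values (mixture arithmetic over U within each arm)
provide the parameter-recovery oracle: e.g. mild confounding implies
RD = 0.30/0.2667 = 1.125 and, at η = 5, a null-effect pooled RR of
0.30/0.2722 ≈ 1.10 (1.227 under strong confounding). Scenario medians
reproduce these and the published simulation table within Monte-Carlo
noise.

Because replicates reduce to arm event counts under this design, the
scenario runner computes estimates from counts through the same
closed-form estimator used for subject tables (verified identical
per-replicate in the tests); the full 12-scenario grid at 5000 replicates
runs in a few seconds on one CPU, so no scaled-down replicate counts are
needed anywhere — the fast unit tests simply use fewer replicates (50–2000)
where only smoke-level or ordering behavior is at stake.

### What the generator does not emulate

Measured covariates (balancing is exercised on separately generated
cohorts), non-concurrent enrollment, outcome-definition drift between
data sources, K > 2 confounder categories, and non-binary endpoints
(supported in the metrics only through approximate risk-ratio
conversions: √OR, the hazard-ratio transform, exp(0.91·d)). Passing
simulations therefore demonstrate the operating characteristics of the
decision rules under the stated confounding mechanism, not robustness to
these other threats.

## Known limitations and observed behavior

The CI-limit decision rule is deliberately conservative: its Type I error
tracks or undercuts the trial-only analysis at mild-to-moderate
confounding (where the pooled test's inflation is small and the gate
bites hardest) and rises slowly with confounding strength, while
retaining a 15–20-percentage-point power advantage over trial-only
analysis at moderate confounding. The effect-estimate rule trims only
modest amounts of the pooled analysis's Type I inflation. Both behaviors
are visible in the operating-characteristics tests. The framework
assesses robustness to the *observed* benchmark; it does not estimate the
actual confounding magnitude, and verdicts are sensitivity statements,
not hypothesis tests with guaranteed error rates.
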