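# Methods

This note records the models, numerical choices and deliberate design
decisions behind mmlsim, at the level a maintainer or reviewer needs to
judge what a passing test does and does not demonstrate.

## The language subset

The input language is a closed declarative subset of the MML family:
`realDomain` declarations with uniform inclusive grids (`min`, `max` and
exactly one of `delta`/`ct`; if `delta` is given, `ct =
round((max−min)/delta)+1`), `real` parameters (value with an optional
unit on the literal), variables on up to two domains, `extern` inputs,
`when`-guarded clauses anchored at a domain extremum, and equations over
`+ − * / ^`, the elementary functions `exp ln log sqrt abs sin cos`, and
derivative notation `V:d` / `V:d:d`.  Excluded on purpose: classes and
templates, procedural-code hooks, arrays, state events, mixed second
derivatives, guards other than domain extrema.  Identifiers are
case-sensitive; `real`, `realDomain`, `extern`, `when`, `math` and
`import` are reserved.

Parsing is two-pass: the grammar is consumed by a hand-written
recursive-descent parser (the subset is tiny and error positions matter
more than grammar generality), and all name resolution happens after the
whole block is read, so declaration order is irrelevant — property
assignments like `x.ct = Ngrid` may precede or follow anything they
reference.  Domain properties are stored as expressions and folded to
numbers only at solve time, which is also what makes run-time overrides
of `t.max`/`t.delta`/`x.ct` possible (used heavily to keep fitting
cheap: the solved window can be narrowed without touching the source).

## Units

A unit is a positive scale relative to coherent SI times a vector of
seven rational exponents (length, mass, time, amount, current,
temperature, luminosity).  Seven slots are kept even though the shipped
models use four.  The built-in vocabulary covers the names the example
models and their field need (`m cm mm um, kg g mg, s sec min hour, L ml
ul, mol mmol umol, M mM uM, Pa kPa mmHg, A K cd`); users can extend it
from `name = expr` text lines.  Grams of tissue are ordinary mass — no
separate "tissue gram" dimension is introduced.  No offset units (°C/°F)
and no logarithmic units.

Balance checking infers a unit for every subexpression.  Bare numeric
literals are unit-polymorphic, so `C = 0` and `1 + H/Kmh` balance without
annotation.  Transcendental functions require dimensionless arguments;
`sqrt` halves exponents; exponentiation of a unitful base needs a
constant integer exponent.  Under `unit conversion on`, additive terms
that are commensurable but differently scaled get an explicit numeric
factor inserted into the annotated equation (the BTEX model's mM/min flux
terms against a mM/s time derivative draw exactly 1/60); with conversion
off the same situation is an error — silent conversion is never
performed.  Imbalance is always a verdict in a report, not an exception,
so a `check` run can list every offending term.

## Compilation

Classification proceeds from derivatives: an interior equation
differentiating V in time is V's ODE/PDE; with two domains, the domain
carrying the second-order derivative is space and the other is time (no
second-order derivative on either domain is ambiguous and rejected).
Algebraic equations must isolate a variable or be linear in a single
unknown.  All implicit solving — algebraic, `V:t` extraction, boundary
relations — uses the same primitive: the residual is affine in the
unknown's slot, so two evaluations determine it exactly
(`u = −f(0)/(f(1)−f(0))`); affinity is verified at plan time by a
three-point collinearity probe on varied environments, and genuinely
nonlinear implicit equations are rejected with a diagnostic rather than
iterated (scope decision: simultaneous nonlinear systems are out).

Completeness accounting gives each non-extern variable exactly one
interior definition, dynamic variables exactly one initial condition,
and PDE variables exactly one boundary condition per spatial edge; a
time-only variable may instead be defined inside a spatial boundary
clause (the outflow sampler `Cout = Ccap` at `x = x.max`).  Diagnostics
are deduplicated to one per variable, with "no interior equation"
suppressing the then-dangling IC/BC complaints, so that any single
deletion or duplication of an equation produces exactly one
UNDER-/OVERSPECIFIED message — this property is tested exhaustively over
both shipped models.

Boundary clauses containing a spatial derivative are matched numerically
against the linear form a·V + b·V:x + c = 0 by probing coefficients:
b=0 → Dirichlet, a=0 → reflecting Neumann, both nonzero → Robin
(total-flux).  Sequencing is: parameters, algebraic assignments in
lexicographic topological order (cycles rejected), then the simultaneous
dynamic block.  Plans serialize to sorted-key JSON, byte-stable for a
given source.

## ODE engines

`euler`, `rk2` (explicit midpoint) and `rk4` take one step per reporting
interval unless substepping is requested — deliberately, so their order
of accuracy is visible on the reporting grid.  `rk45` is a hand-stepped
Runge–Kutta–Fehlberg 4(5) with the standard controller (scaled RMS error
norm, accept at err ≤ 1, next h = 0.9·h·err^(−1/5), growth capped at 5,
steps shortened to land exactly on grid points — step-to-grid was chosen
over dense output for simplicity).  `dopri5` delegates to scipy's RK45,
which implements the Dormand–Prince 5(4) pair, with `t_eval` on the
model grid.  `auto` starts with dopri5 and restarts the whole interval
with scipy's implicit Radau when the explicit attempt fails; since a
stable but very stiff system makes an explicit solver grind rather than
fail, "failure" is proxied by an rhs-evaluation budget (default 200 000)
in addition to scipy's own step-underflow status.  Default tolerances are
rel 1e-7 / abs 1e-9.

## PDE engines

Each PDE is put in the form V_t = −v·V_x + D·V_xx + S by probing the
compiled right-hand side's derivative slots; v and D must not depend on
the state (quasilinear equations are rejected).  The space grid is
`x.ct` points inclusive of both ends (Ngrid = 31 → dx = L/30).

*MacCormack*: predictor with forward-difference advection, corrector
with backward differences on the predictor, averaged; diffusion by
central differences; sources pointwise; at the outflow edge the advective
derivative is one-sided upwind.  Substeps per reporting interval are the
smallest n meeting both dt ≤ s·dx/|v| and dt ≤ s·dx²/(2·D_max) with
safety s = 0.8.

*LSFEA-style split*: the convective step is solved separately and
exactly — the internal step is slaved to dt = dx/v and the convected
profile slides one cell per step — then diffusion, exchange and reaction
advance per node over that dt with an RK4 update (subcycled if dt
exceeds the diffusive limit); results are linearly interpolated onto the
reporting grid.  This reproduces the published split *structure*; the
original algorithm's internals are not reproduced line-by-line.  All
convected variables must share one positive velocity.

Boundary handling matters for conservation: Robin and Dirichlet
conditions are solved for the edge value each substep using a
first-order one-sided derivative (for the total-flux inflow this is
exactly v(C₀−C_in) = D(C₁−C₀)/dx solved for C₀), while reflecting
Neumann edges act as mirror ghosts *inside* the diffusion operator and
never overwrite the edge value — overwriting would truncate the advected
profile at the outflow and bias transit times by one cell.  With this
treatment the sliding scheme advects a bolus with zero shape error and
both schemes close the mass balance to ≲0.1% on the default grid.
MacCormack undershoots near sharp fronts are tracked across every
substep and reported in the metadata; clipping to zero is available but
off by default (mass conservation is prioritized over positivity).

## Input functions

Signal kinds (pulse, pulse train, sine, rise-fraction-parameterized
triangle sawtooth) use their parameters directly.  Density kinds
(exponential, Gaussian, lognormal, gamma-variate) are normalized by
numeric quadrature so their integral over the evaluation window equals
the requested area to 1e-6 relative — area accounting against a finite
observation window is what input/output mass comparisons need.  The
gamma variate is A·(t−t₀)^α e^(−(t−t₀)/β) normalized by Γ(α+1)β^(α+1),
the standard indicator-dilution form.  Data curves interpolate linearly
or hold the left sample; outside their range they return 0 (bolus
semantics, not extrapolation).  Stochastic signal generators (Poisson
streams, random walks) are excluded along with all stochastic
simulation.

The canonical demonstration input used throughout the tests and examples
is a lognormal bolus with median 3 s, log-sd 0.4 and unit area in mM·s:
a realistic arterial injection shape for a 30 s observation window whose
median matches the unit's vascular transit time.

## Sensitivity, loops, residuals

Sensitivities are finite differences with relative perturbation δ
(default 1%): forward S = [Q(P(1+δ))−Q(P)]/(Pδ) costs one extra solve
per parameter, central is optional and halves the step dependence.  The
normalized form (dQ/Q)/(dP/P) is reported as 0 wherever |Q| ≤ 1e-8 of
its peak, because the ratio is numerically meaningless there.  A
parameter whose base value is 0 cannot take a relative perturbation and
is rejected explicitly.  Loop families evaluate the Cartesian grid inner
level fastest, record failures without stopping, and never mutate the
base problem (purity is tested bit-for-bit).  Residual diagnostics
report weighted SSR, sign counts and a two-sided Wald–Wolfowitz runs
test under the normal approximation; single-signed residuals short-cut
to the maximal-bias verdict.

## Estimation

The objective is Σ w_i(data_i − model_i)² summed plainly across curves
(per-curve normalization only through explicit weights; weights default
to 1).  Four optimizers, one per algorithm family:

* `simplex` — scipy's bounded Nelder–Mead;
* `gridsearch` — N points per dimension (default 5), the best point
  becomes the center of a grid shrunk by 0.5, for a fixed number of
  passes (default 20);
* `sensop` — Levenberg–Marquardt on the weighted residual vector:
  finite-difference Jacobian, λ·diag(JᵀJ) damping with up/down factors
  4 and 0.5, trial points projected onto the bounds, convergence on
  relative cost change < 1e-10.  This is a standard weighted LM, the
  behavioral stand-in for the published SENSOP variant whose step-length
  rule is specified only by citation;
* `simanneal` — Gaussian proposals with a geometric temperature schedule
  and Metropolis acceptance, fully determined by its seed.

Failed model solves at a trial point cost +∞ and are counted.  The
iteration history records only accepted costs and is asserted
non-increasing.

Jacobian confidence: covariance s²(JᵀWJ)⁻¹ with s² = SSR_w/(n−p), SDs
from the diagonal, 95% ranges via the Gaussian quantile, correlation from
the covariance; condition numbers above 1e12 switch to the
pseudo-inverse and set a flag rather than failing — structural
non-identifiability should be reported, not hidden.

Monte-Carlo confidence: each replicate r perturbs every data point with
fresh draws (proportional or additive Gaussian) from stream `seed + r`
and re-optimizes starting from the baseline optimum — restarting from
the optimum rather than from scratch is a documented speed choice; with
unimodal costs near the optimum it gives the same estimates.  The
ensemble yields per-parameter histograms and 2.5/97.5 percentile
intervals with no symmetry assumption.  The problem's data and start
vector are restored afterwards, so ensembles are reproducible
run-to-run.

## Synthetic data and what the tests show

The synthetic-data generator samples a solved trajectory at requested
times and applies the chosen noise model, returning the generating
("truth") parameters alongside.  The recovery study used in tests and
examples samples the reaction-chain product U(t) at 57 points over
10–290 s — the transient is over by ~100 s, so this window is the
informative one — solving a 300 s / 2 s-reporting window via the
run-time grid override.  Passing recovery tests show the estimator
machinery is correct on data generated by the same model family with
known noise; they say nothing about model misspecification, correlated
noise, or real measurement error, which real indicator-dilution data
have.

Problem sizes throughout (31-point space grid, 301-point reporting grid,
≤100 Monte-Carlo replicates, 400 meta-replicates on the closed-form
linear model) are chosen so the whole suite exercises every claim in
minutes on one core while keeping each assertion's tolerance dictated by
the physics or the closed form, not by the budget.

## Known limitations

* One spatial dimension, uniform grids, a single time axis per solve.
* No differential-algebraic index analysis; simultaneous nonlinear
  algebraic systems rejected.
* PDE coefficients must be state-independent (linear advection and
  diffusion); sources may be nonlinear.
* The project container is this package's own documented JSON dialect;
  no compatibility with any external archive format is claimed.
* Figure-level behaviours of the exchange model that depend on an
  unpublished input waveform are covered qualitatively (orderings, sign
  changes), not numerically.
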