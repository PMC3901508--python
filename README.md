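# mmlsim

A declarative, unit-checked modeling and data-analysis toolkit for
physiological and pharmacological systems: write a model as mathematical
equations, let the compiler verify it, and take it through simulation,
sensitivity analysis, least-squares fitting against data, and parameter
confidence estimation — the full hypothesis-testing loop that indicator
dilution, enzyme kinetics and PK/PD work keeps repeating.

## Who this is for

Modelers who want the equations on the page and the code to be the same
object.  Models are written in a small declarative equation language (a
subset of MML, the Mathematical Modeling Language family used in
physiome-style modeling): you declare domains, unit-annotated parameters
and variables, then state the equations.  Equations mean mathematical
equality, not assignment — the compiler decides what computes what,
checks that every variable is *completely but not overly* specified, and
rejects equations whose units don't balance.

```text
realDomain t sec; t.min=0; t.max=5000.0; t.delta=1.00;
real Vhmax = 1.84 uM/s;     real Kmh = 3.67 uM;
real H(t) uM;  real X(t) uM;  real U(t) uM;
when (t=t.min){ H = Hzero; X = Xzero; U = Uzero; }
H:t = - (Vhmax*H/Kmh) / (1 + H/Kmh + X/Kmx);
```

Two example models ship with the package:

* **`mm2irrev`** — two sequential irreversible Michaelis–Menten reactions
  sharing one enzyme (hypoxanthine → xanthine → uric acid, competitive
  binding):  dH/dt = −(V_h·H/K_h)/(1 + H/K_h + X/K_x), and cyclic
  permutations.  The invariant H+X+U = H₀ is forced by the structure.
* **`btex20simple`** — an axially distributed two-region capillary /
  interstitium blood-tissue exchange (BTEX) unit:

  ∂C_cap/∂t = −(F·L/V_cap)·∂C_cap/∂x + D_cap·∂²C_cap/∂x² + (PS/V_cap)(C_isf − C_cap)

  ∂C_isf/∂t = −(G_isf/V_isf)·C_isf + D_isf·∂²C_isf/∂x² + (PS/V_isf)(C_cap − C_isf)

  with a total-flux (Robin) inflow condition
  −(F·L/V_cap)(C_cap − C_in) + D_cap·∂C_cap/∂x = 0 at the entrance and
  reflecting edges elsewhere.  Flow F and permeability–surface product PS
  are in ml/(g·min) while the rate equations are per second — the unit
  engine inserts the 1/60 factors automatically.

## What's inside

| layer | contents |
|---|---|
| language | lexer/parser, symbol resolution, pretty-printer (`mmlsim.mml`) |
| units | 7-dimensional unit algebra, balance checking, automatic conversion factors (`mmlsim.units`) |
| compiler | dependency graph, completeness diagnostics, equation classification and sequencing (`mmlsim.plan`) |
| ODE | euler/rk2/rk4 fixed-step, Fehlberg RK45, Dormand–Prince 5(4), auto-with-Radau-fallback (`mmlsim.ode`) |
| PDE | MacCormack predictor–corrector and a Lagrangian sliding-element operator split for 1-D convection–diffusion–exchange (`mmlsim.pde`) |
| inputs | pulse/train/sine/sawtooth signals, exponential/Gaussian/lognormal/gamma-variate densities, data-curve interpolants (`mmlsim.funcgen`) |
| analysis | parameter loops, normalized sensitivity functions (dQ/Q)/(dP/P), residual diagnostics with a runs test (`mmlsim.analysis`) |
| estimation | weighted least squares with Nelder–Mead, grid search, Levenberg–Marquardt (SENSOP-style) and simulated annealing; Jacobian and Monte-Carlo confidence ranges (`mmlsim.estimation`) |
| projects | data CSV I/O, a single-file JSON container bundling models + data + configurations + results (`mmlsim.project`) |

## Worked example

```python
import numpy as np
from mmlsim import (classify_and_sequence, parse_model, fixture_source,
                    sensitivity, solve_model_pde, FuncSpec, make_generator)
from mmlsim.ode import SolverConfig, solve_model_ode

model = parse_model(fixture_source("mm2irrev"))
plan = classify_and_sequence(model)
traj = solve_model_ode(plan, config=SolverConfig(method="dopri5"))
print(f"U(5000 s)   = {traj['U'][-1]:.4f} uM")
tot = traj['H'] + traj['X'] + traj['U']
print(f"max |H+X+U - 46.3|/46.3 = {np.max(np.abs(tot - 46.3))/46.3:.2e}")

btex = classify_and_sequence(parse_model(fixture_source("btex20simple")))
cin = make_generator(FuncSpec("lognormal",
                              {"median": 3.0, "sigma": 0.4, "area": 1.0},
                              unit="mM", window=(0.0, 30.0)))
sol = solve_model_pde(btex, inputs={"Cin": cin})
ipk = int(np.argmax(sol["Cout"]))
print(f"Cout peak   = {sol['Cout'][ipk]:.4f} mM at t = {sol.t[ipk]:.1f} s")
sens = sensitivity(btex, ["Cout"], ["PS"], delta_rel=0.01,
                   inputs={"Cin": cin})
s = sens.dQdP["Cout"]["PS"]
print(f"dCout/dPS turns positive at t = {sol.t[np.argmax(s > 0)]:.1f} s")
```

prints

```text
U(5000 s)   = 46.3000 uM
max |H+X+U - 46.3|/46.3 = 1.84e-15
Cout peak   = 0.1435 mM at t = 5.7 s
dCout/dPS turns positive at t = 8.1 s
```

The first two lines are the enzymatic progress curve run to completion:
all 46.3 µM of substrate ends up as product, and the solver conserves the
total to machine precision.  The last two describe the exchange unit
driven by a unit-area lognormal bolus: the outflow peaks at 5.7 s
(vascular transit ~3 s plus dispersion), and the sensitivity of the
outflow to the wall conductance PS flips sign at ~8 s — raising PS lowers
the early peak (more solute escapes into the tissue) but raises the tail
(it comes back).

The same operations are available from the shell:

```sh
mmlsim check btex20simple
mmlsim run mm2irrev --solver dopri5 --out run.csv
mmlsim loop btex20simple --param PS=0,1,2,4 \
    --input "Cin=lognormal(median=3,sigma=0.4,area=1 mM*s)" --out fam
mmlsim fit mm2irrev --data u.csv --free Vhmax,Kmh \
    --start Vhmax=1 --start Kmh=1 --bounds Vhmax=0.01:50 \
    --method sensop --out fit.json
```

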