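# Methods

## Model

The state is a vector of follicle sizes $x_i \ge 0$ (arbitrary units; the
model is invariant to a common rescaling of all sizes). Competition
dynamics:

$$\dot x_i = \alpha\, u_i\, \varphi(u_i + A_{ex}), \qquad u_i = x_i/x_T,
\qquad x_T = \textstyle\sum_j x_j,$$

where the sum runs over **all** follicles regardless of phase or size.
$\varphi$ is biphasic with zero crossings at $1/M_2 < 1/M_1$; the default
is the parabola $(1-M_1u)(M_2u-1)$, and any other biphasic callable with
the same crossings can be supplied (`BiphasicParams.phi_fn`). For the
parabola all stability quantities are closed-form; for a pluggable shape
the maximum is found by bounded scalar minimization on
$(1/M_2,\,1/M_1)$ to $10^{-12}$.

Underlying physiology, compressed into the equation: FSH-driven growth
is proportional to relative size because circulating estradiol (which
suppresses FSH) is proportional to total follicle size, and the local
androgen concentration of follicle $i$ is $A_i = (A_T/\eta)\,u_i$ —
again a function of relative, not absolute, size (`local_androgen`
implements this bookkeeping and conserves $\eta\sum A_i = A_T$).
Mechanistic hormone time courses are deliberately out of scope.

## Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| $M_1, M_2$ | zero-crossing (androgen threshold) parameters, $0<M_1<M_2$ | per scenario | dimensionless |
| $\alpha$ | velocity constant; pure time rescale | 1 | size/time |
| $A_{ex}$ | external androgen shift of $\varphi$'s argument | 0 | relative-size units |
| surge multiplier | $x_T$ growth factor that triggers the LH surge | 4.6 | — |
| init\_low, init\_high | uniform initial-size bounds | 0.05, 0.15 | size |
| $\gamma$ | pre-competition exponential growth rate | 1 | 1/time |
| $x_c$ | critical size of the developmental switch | 1 | size |

$A_{ex}$ enters additively in $\varphi$'s argument, so its natural scale
is relative-size units; $A_{ex} \ge 1/M_1$ provably closes the growth
window on all of $u\in[0,1]$. Model time is arbitrary ($\alpha$ absorbs
the unit); `normalize_time` relabels a run so the surge lands on a
14-day follicular phase for display.

## Symmetric-solution analysis

$M$ equal follicles at $u=1/M$ move at constant velocity
$v=(\alpha/M)\varphi(1/M + A_{ex})$. Stability of a *growing* symmetric
solution requires $1/M + A_{ex}$ on the declining branch of $\varphi$;
for the parabola at $A_{ex}=0$ this is $M < M_{max} = 2M_1M_2/(M_1+M_2)$,
and all criteria here apply the $A_{ex}$ shift consistently in $u$-space
(they reduce to the printed inequalities at $A_{ex}=0$). Boundary cases
($M = M_1$ or $M = M_{max}$ exactly) are classified unstable — the
inequalities are strict. $M_2=\infty$ is accepted as a sentinel for the
wide-window limit ($M_{max}\to 2M_1$).

$M=1$ is special: the symmetric-perturbation criterion can reject it
(e.g. $M_1=0.5, M_2=4$ gives $M_{max}\approx 0.89$), but a lone follicle
has $u=1$ exactly, larger perturbations are impossible, and an
infinitesimal competitor sits at $u\approx 0$ where $\varphi<0$ and
shrinks. `is_stable` therefore treats $M=1$ as stable iff
$\varphi(1+A_{ex})>0$. This also yields the uniqueness property —
$M=1$ achievable $\Rightarrow M_1<1 \Rightarrow M_{max}<2$, so no
$M\ge2$ qualifies — without special-casing.

The analytic verdicts are cross-checked in the test suite against a
simulation oracle: $M$ follicles, one perturbed by +1%, plus a
near-zero competitor, integrated until $x_T$ grows 30-fold; stability
requires group growth, decay of the within-group spread, and shrinkage
of the tiny follicle.

## Numerical integration

`scipy.integrate.solve_ivp` (RK45), rtol $10^{-8}$, atol $10^{-10}$,
dense output evaluated on a 400-point uniform reporting grid whose last
point is exactly the terminal event. The surge ($x_T$ crossing
`surge_multiplier`·$x_T(0)$ from below) is localized by the solver's
event root-finding (verified accurate to $10^{-6}$ relative in the
suite). Sizes are clamped at zero and zero is absorbing (atresia).

**Extinction.** A symmetric state below the growth window shrinks at
constant *negative* velocity and reaches zero total size in finite time.
This is a genuine outcome: e.g. with $M_1=5.9, M_2=13$ and 15 follicles,
every initial $u_i\approx 1/15$ is below $1/M_2$, and roughly 15% of
random cohorts get absorbed into a shrinking 5-follicle symmetric
configuration ($1/5$ lies on the declining branch, so the configuration
is an attractor of the relative-size flow, but $5 < M_1$ means it cannot
grow) and go fully atretic. Runs are terminated when
$x_T < 10^{-6}\,x_T(0)$ (kept well above the solver's absolute
tolerance) and classified as zero ovulations.

**Continual entry.** Entry times $t_i$ are uniform on
$[0, \text{entry\_window}]$; every follicle exists from $t=0$ at size
$x_c e^{-\gamma t_i}$, grows exponentially ($\dot x = \gamma x$,
independent of the cohort) and switches permanently to the competition
law at its first crossing of $x_c$ — which by construction is exactly
$t_i$, so the switch schedule is known analytically and integration
proceeds piecewise between switches (no event tolerance enters).
Pre-switch follicles are included in $x_T$ by default (a flag excludes
them for sensitivity analyses). No surge by default in this mode; when
enabled, the threshold anchors to $x_T$ at the first switch.

## Ovulation classification

The model itself has no ovulation observable; the classifier
operationalizes it at the surge (or horizon). Default rule
(`growth+size`): follicle $i$ ovulates iff it is instantaneously growing
($\varphi(u_i+A_{ex})>0$, $u_i>0$) **and** its size is at least half the
largest follicle's. The size condition matters when $1/M_2$ is small: a
runner-up far behind the leader can sit just inside the positive window
and still be creeping upward at the surge despite having lost the race
(measured over 100 seeds at $M_1=0.9, M_2=10$, 15 follicles, the pure
growth rule yields two "winners" about half the time, while the combined
rule gives the single dominant follicle in 84% of cohorts, the remainder
being genuine near-ties). Co-dominant winners of a stable $M$-race are
near-equal by construction and always pass the size condition; the
threshold 0.5 sits in the wide gap between those two populations rather
than at a tuned boundary. Pure `growth` and pure `fraction` (within 0.8
of the leader) rules remain available, and every outcome records the
rule used.

## Scenario presets and the synthetic protocol

The preset scenarios (`fig2c/d/e/f`, `fig3d`, `fig4b/d`, with
descriptive aliases) encode the standard protocol: uniform(0.05, 0.15)
initial sizes, surge at 4.6×, and for continual entry $\gamma=1$,
$x_c=1$. Entry counts for the continual-entry regimes are not pinned by
the protocol; the presets use 25 entries (anovulatory) and 7 entries
(ovulatory) over a 40-unit window with a 60-unit horizon, chosen to give
clearly overlapping turnover in the first case and a well-separated
dominant follicle in the second, and both are plain config fields. The
generator emulates the *statistical* protocol only — it does not model
follicle-parameter heterogeneity, measurement noise, diameter↔mass
conversion, or luteal-phase dynamics, so passing tests demonstrate the
model's internal behavior, not quantitative agreement with ultrasound
data (qualitative agreement is the model's stated ambition).

Because several ovulation numbers can be simultaneously stable and
initial sizes are random, figure-level outcomes are reported as modal
counts over 100-seed ensembles. One integer seed drives both initial
sizes and entry times and is logged in every run summary.

## Lacker reference

Implemented exactly as the rescaled form above. The symmetric ODE
$\dot x_T = x_T + \mu x_T^3$ is integrated in the reciprocal-square
variable $w = x_T^{-2}$ (linear ODE $\dot w = -2w-2\mu$): integrating
$x_T$ directly stalls near the singularity because past
$x_T \sim 10^8$ the remaining time to blow-up ($\approx 1/(2\mu x_T^2)$)
drops below the floating-point spacing of $t$. Blow-up is reported at
the $10^{12}\times$ threshold crossing and matches the separable closed
form $t^* = \tfrac12\ln(1+1/(\mu x_0^2))$ to $\sim 10^{-11}$ relative.
The growth-arrest steady state is taken from the ODE's fixed point,
$x_T^* = |\mu|^{-1/2}$ (per follicle $x_T^*/M$; both are reported), and
confirmed by long integration. `time_transform_check` integrates the
de-constanted Lacker flow and the biphasic flow from the same initial
sizes and compares relative-size vectors at matched $x_T$ (the common
clock along the shared orbit), restricted to the first strictly
monotone stretch of $x_T$ and flagged when restricted; agreement is
$\sim 10^{-10}$, against a contract of $10^{-5}$.

## Known limitations

- Outcomes are protocol-level (modal counts, qualitative turnover);
  the model is not meant to fit individual growth curves.
- Asymmetric fixed points are probed only through the simulation
  oracle, not analyzed in closed form.
- The full-atresia (extinction) regime described above means "every
  random cohort resolves into a stable ovulation number" is false for
  parameter sets whose initial relative sizes all start below the
  growth window; consumers should inspect the count-0 fraction.
- Heterogeneous follicle parameters and stochastic growth noise are not
  modeled; size rankings in fixed cohorts are therefore strictly
  preserved, which real data need not obey.
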