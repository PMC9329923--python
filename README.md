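# follisim

Simulation and analysis of ovulation-number control by biphasic
local-androgen feedback.

Every menstrual cycle many ovarian follicles start to grow but only a
species-specific number *M* ovulate (one in humans, around eight in young
mice); the rest die by atresia. `follisim` implements a minimal dynamical
model of how *M* is selected: each follicle's intra-follicular androgen
concentration measures its size *relative to the whole cohort*, and
androgen has a biphasic (inverse-U) effect on growth — follicles that are
too small *or* too large relative to the others shrink. The package is
aimed at systems biologists and modelers who want to simulate follicle
races, derive achievable ovulation numbers from the control parameters,
and explore twin ovulations and PCOS-like anovulation.

## The model

Follicle *i* of size $x_i$ obeys

$$\frac{dx_i}{dt} = \alpha\,u_i\,\varphi(u_i + A_{ex}), \qquad
u_i = \frac{x_i}{x_T},\quad x_T = \sum_j x_j,$$

with the biphasic function (parabola by default, any biphasic shape
pluggable)

$$\varphi(u) = (1 - M_1 u)(M_2 u - 1),$$

positive only on the window $1/M_2 < u < 1/M_1$. $A_{ex}$ is chronic
external androgen, shifting the curve left. Key consequences, all
implemented and tested here:

- **Symmetric solutions.** *M* equal follicles grow linearly at velocity
  $v = (\alpha/M)\varphi(1/M)$; the solution grows iff $M_1 < M < M_2$ and
  is stable iff $M_1 < M < M_{max} = 2M_1M_2/(M_1+M_2)$ (in the wide-window
  limit $M_2 \gg M_1$: $M_1 < M < 2M_1$). The stable integers are the
  achievable ovulation numbers; whenever $M=1$ is achievable it is the
  only one.
- **The LH surge** is modeled as the total size (an estradiol proxy)
  reaching 4.6× its initial value; races start from uniform(0.05, 0.15)
  initial sizes.
- **Twins**: two follicles starting within ~0.1% can reach the surge
  still tied and both ovulate even when $M=1$ is the only stable number.
- **PCOS**: with $A_{ex} \ge 1/M_1$ the positive window is gone; under
  continual follicle entry (exponential pre-growth to a critical size
  $x_c$, then competition) every follicle peaks near $x_c$ and shrinks —
  turnover without ovulation.
- **Lacker's classic model** is included for contrast
  ($dx_i/dt = x_i g$, $g = 1-(x_T-M_1x_i)(x_T-M_2x_i)$): its symmetric
  solutions blow up in finite time ($\mu > 0$) or growth-arrest
  ($\mu < 0$, $x_T^* = |\mu|^{-1/2}$), where
  $\mu = -(1-M_1/M)(1-M_2/M)$; removing the constant from *g* and
  rescaling time by $x_T^3$ recovers the relative-size flow exactly.

## Worked example

```sh
python examples/ovulation_race.py
```

```
initial sizes        : [0.1137 0.077  0.0541 0.0517 0.1313]
stable ovulation set : [1]
surge at model time  : 6.671 (rescaled to day 14)
sizes at the surge   : [2.3000e-03 1.0000e-04 0.0000e+00 0.0000e+00 1.9651e+00]
ovulating follicles  : [4] (count 1)
```

Five follicles with $M_1=0.9$, $M_2=3.5$: the analysis says only $M=1$
is stable, and the race agrees — follicle 4 (largest at the start) holds
1.965 of the 1.968 total at the surge and is the only one classified as
ovulating; the others have collapsed toward zero. Rescaling the surge to
day 14 displays the run on a human follicular-phase timescale.

Other examples: `stability_analysis.py` (velocities, stable sets, the
ovulation-number-vs-$M_1$ sweep), `twin_ovulation.py`,
`pcos_dynamics.py`, `lacker_comparison.py`.

The same functionality is available from the shell:

```sh
follisim simulate --preset fig2c --seed 0 --out-dir out/   # CSV + JSON summary
follisim scenario fig2d --seeds 100                        # count histogram
follisim stable-set --m1 3.4 --m2 inf                      # {"stable_numbers": [4, 5, 6]}
follisim phase-diagram --m1-range 0.5:6:0.1 --m2 inf --out pd.csv
follisim lacker --m1 0.9 --m2 3.5 --m 1
follisim lacker-compare --preset fig2c
```

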