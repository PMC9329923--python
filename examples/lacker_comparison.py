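"""Contrast with Lacker's classic model.

Lacker's growth law (on absolute sizes) sends the dominant follicles to
infinite size in finite time (mu > 0) or parks them at a growth-arrest
steady state (mu < 0).  The relative-size law avoids both: dropping the
constant term from Lacker's g and rescaling time by x_T^3 yields exactly
the biphasic flow, whose winners grow linearly instead.
"""

from follisim import (
    LackerParams,
    SimulationConfig,
    blowup_time_closed_form,
    mu,
    sample_initial_sizes,
    symmetric_fate,
    time_transform_check,
)

blow = LackerParams(m1=0.9, m2=3.5)
print(f"mu(M=1; 0.9, 3.5) = {mu(1, blow):+.4f}  -> blow-up")
fate = symmetric_fate(1, 1.0, blow)
print(f"  blow-up time (integrated)  : {fate.blow_up_time:.10f}")
print(f"  blow-up time (closed form) : {blowup_time_closed_form(0.25, 1.0):.10f}")

arrest = LackerParams(m1=2.0, m2=3.0)
print(f"\nmu(M=1; 2, 3)     = {mu(1, arrest):+.4f}  -> growth arrest")
f2 = symmetric_fate(1, 0.1, arrest)
print(f"  steady-state total size    : {f2.arrest_size:.6f} (= 1/sqrt|mu|)")

cfg = SimulationConfig(n_follicles=5, seed=0)
rep = time_transform_check(sample_initial_sizes(cfg), blow, horizon=30.0)
print(f"\nde-constanted Lacker vs biphasic flow, matched at equal x_T:")
print(f"  max relative-size discrepancy over {rep.n_points} checkpoints: "
      f"{rep.max_discrepancy:.2e}")
# The tiny discrepancy confirms the two flows share orbits exactly; only
# their clocks differ, which is what turns finite-time blow-up into the
# linear growth seen in ultrasound data.
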