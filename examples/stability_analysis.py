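"""Which ovulation numbers are achievable, straight from the formulas.

The M-follicle symmetric solution grows at v = (alpha/M) phi(1/M) and is
stable iff M1 < M < M_max = 2 M1 M2/(M1+M2).  Sweeping the androgen
toxicity parameter M1 maps out the achievable ovulation numbers.
"""

import numpy as np

from follisim import (
    BiphasicParams,
    m1_interval_for,
    m_max,
    stable_set,
    symmetric_solution,
)

INF = float("inf")

p = BiphasicParams(m1=2.9, m2=7.5)
print(f"M1={p.m1}, M2={p.m2}:  M_max = {m_max(p):.3f}")
for M in range(1, 7):
    s = symmetric_solution(M, p)
    print(f"  M={M}: velocity={s.velocity:+.4f}  grows={s.grows}  stable={s.stable}")
print(f"  stable set: {sorted(stable_set(p))}")

# wide-window limit (M2 >> M1): stable numbers are the integers in (M1, 2*M1)
print("\novulation numbers vs M1 (M2 -> inf):")
for m1 in np.arange(0.5, 6.0, 0.5):
    s = stable_set(BiphasicParams(float(m1), INF), m_cap=15)
    print(f"  M1={m1:4.1f}: {sorted(s)}")

iv = m1_interval_for(3, INF)
print(f"\nto ovulate exactly 3, M1 must lie in ({iv.low}, {iv.high})")
# At M1=3.4 the set is {4, 5, 6}: several litter sizes coexist, and the
# realized count then depends on the initial condition of the race.
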