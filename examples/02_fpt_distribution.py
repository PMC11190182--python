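"""Full first-passage-time distribution for bursty expression.

Integrates the target-reduced master equation for the bursty birth-death
model (K = 20 bursts per unit time, burst size r = 10, target at 90% of
the steady-state mean) and prints the survival function S(t) = P(FPT > t)
at a few times, plus consistency of its area with the moment solve.
"""

import numpy as np

import fptcme as f

bundle = f.bursty_bd(K=20.0, r=10)
target, N = bundle.target(0.9)
space = f.enumerate_states(bundle.network)
A = f.build_transition_matrix(bundle.network, space)

curve = f.fpt_survival(A, space, target, [0])
density = f.fpt_density(curve)
moments = f.fpt_moments(A, space, target, k_max=2)

print(f"target N = {N}, state space = {space.n_states} states")
for t_query in (0.5, 1.0, 2.0, 4.0, 8.0):
    s = np.interp(t_query, curve.time_grid, curve.survival)
    print(f"  S({t_query:4.1f}) = {s:.4f}")
area = np.trapezoid(curve.survival, curve.time_grid)
print(f"area under S(t)        = {area:.4f}")
print(f"moment-solve MFPT      = {moments.mean_from([0]):.4f}")
print(f"CV^2 of the FPT        = {moments.cv2_from([0]):.4f}")
print()
print("The area under the survival curve equals the mean FPT; CV^2 well")
print("below 1 shows the crossing is far more regular than a single")
print("exponential wait, since ~18 bursts accumulate before the threshold.")
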