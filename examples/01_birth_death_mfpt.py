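"""Constitutive expression: noise always shortens the mean time to threshold.

Builds the simple birth-death model (production rate K = 50, unit-rate
degradation), sets the target at 80% of the steady-state mean (N = 40),
and compares three routes to the waiting time: the falling-factorial
closed form, the finite-state-projection linear solve, and the
deterministic crossing time -ln(1 - rho).
"""

import fptcme as f

K, rho = 50.0, 0.8
bundle = f.simple_bd(K=K)
target, N = bundle.target(rho)

closed = f.mfpt_birth_death_closed_form(K, N, 0)
moments, report = f.mfpt_with_refinement(bundle.network, target)
fsp = moments.mean_from([0])
tau_d = f.deterministic_fpt_closed_form(rho)

print(f"target N = {N} molecules (rho = {rho} of steady-state mean {K:g})")
print(f"closed-form MFPT      <tau_0> = {closed:.6f}")
print(f"FSP linear-solve MFPT <tau_0> = {fsp:.6f}")
print(f"deterministic FPT     tau_d   = {tau_d:.6f}")
print(f"eta = MFPT / tau_d            = {fsp / tau_d:.4f}")
print()
print("eta < 1: intrinsic noise makes the average crossing *earlier* than")
print("the deterministic model predicts; the two MFPT routes agree to")
print(f"{abs(fsp - closed) / closed:.1e} relative, and the deterministic")
print("time is a strict upper bound for every 0 < rho < 1.")
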