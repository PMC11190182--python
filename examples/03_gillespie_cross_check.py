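"""Cross-check the FSP solver against exact stochastic simulation.

Draws 10,000 first-passage times for the simple birth-death model with
Gillespie's direct method and compares their mean and empirical
distribution with the finite-state-projection results.
"""

import numpy as np

import fptcme as f

bundle = f.simple_bd(K=50.0)
target, N = bundle.target(0.8)
space = f.enumerate_states(bundle.network)
A = f.build_transition_matrix(bundle.network, space)

moments = f.fpt_moments(A, space, target, k_max=1)
fsp = moments.mean_from([0])
sample = f.ssa_fpt_sample(bundle.network, [0], target, 10_000, seed=1)

xs = np.sort(sample.samples)
curve = f.fpt_survival(A, space, target, [0], t_max=float(xs[-1]) * 1.05)
cdf = 1.0 - np.interp(xs, curve.time_grid, curve.survival)
n = xs.size
ks = max(
    np.abs(np.arange(1, n + 1) / n - cdf).max(),
    np.abs(cdf - np.arange(n) / n).max(),
)

print(f"FSP MFPT              = {fsp:.4f}")
print(f"SSA mean (n = {n})  = {sample.mean:.4f} +- {sample.standard_error:.4f}")
print(f"|z| = {abs(fsp - sample.mean) / sample.standard_error:.2f} "
      "(should be < 3)")
print(f"Kolmogorov-Smirnov distance = {ks:.4f} (should be < 0.02)")
print()
print("The linear solve reproduces both the mean and the full shape of the")
print("Monte-Carlo FPT distribution, at a fraction of the cost.")
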