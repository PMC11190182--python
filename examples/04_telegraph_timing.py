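"""Telegraph model: the gene activation rate decides who wins the race.

The two-state gene starts inactive, so the stochastic mean FPT can never
beat the mean activation waiting time 1/lambda.  With fast activation
(lambda = 2) the stochastic model still reaches 60% of the steady-state
mean *sooner* on average than the deterministic model; with slow
activation (lambda = 0.3) the ordering flips.
"""

import fptcme as f

for lam, K in ((2.0, 625.0), (0.3, 1333.0)):
    bundle = f.telegraph(lambda_on=lam, mu_off=0.5, K=K, rho=0.6)
    res = f.eta(bundle, 0.6)
    faster = "stochastic" if res.mfpt < res.tau_d else "deterministic"
    print(f"lambda = {lam:<4g} K = {K:<6g} N = {res.N}")
    print(f"  MFPT = {res.mfpt:.4f}   tau_d = {res.tau_d:.4f}   "
          f"eta = {res.eta:.3f}   1/lambda = {1/lam:.3f}")
    print(f"  -> the {faster} model crosses first on average")

approx = f.telegraph_piecewise_mfpt(2.0, 0.5, 625.0, 300.0)
print()
print(f"piecewise-deterministic approximation (lambda = 2): {approx:.4f}")
print("The approximation treats mRNA as deterministic conditional on the")
print("gene state and is valid within one on/off cycle; it underestimates")
print("the exact MFPT slightly but captures the fast-activation regime.")
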