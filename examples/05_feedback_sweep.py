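"""Autoregulatory feedback: where noise delays triggering tenfold.

Sweeps the bound-state production rate rho_b for two binding regimes of
the self-regulating gene (target = 90% of the numerically computed
steady-state mean, started from zero protein).
"""

import fptcme as f

grids = f.default_feedback_grid()

low = grids["low_sigma_b"]
print(f"--- infrequent binding (sigma_b = {low['sigma_b']})")
df = f.sweep_feedback(
    low["rho_u"], low["sigma_b"], low["sigma_u"], low["rho_b_grid"], rho=0.9
)
print(df[["rho_b", "steady_state_mean", "N", "mfpt", "tau_d", "eta"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("Both FPTs rise then fall: the target chases the rising steady-state")
print("mean until strong bound-state production takes over.\n")

rare = grids["rare_binding"]
print(f"--- rare binding (sigma_b = {rare['sigma_b']})")
df = f.sweep_feedback(
    rare["rho_u"], rare["sigma_b"], rare["sigma_u"], rare["rho_b_grid"], rho=0.9
)
print(df[["rho_b", "N", "mfpt", "tau_d", "eta"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"max eta = {df['eta'].max():.1f}: crossing waits for the first rare")
print("binding burst, so noise lengthens the mean trigger time tenfold.\n")

high = grids["high_sigma_b"]
print(f"--- strong binding (sigma_b = {high['sigma_b']})")
df = f.sweep_feedback(
    high["rho_u"], high["sigma_b"], high["sigma_u"], high["rho_b_grid"], rho=0.9
)
print(df[["rho_b", "N", "mfpt", "tau_d", "eta"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("Binding is effectively instantaneous: the loop behaves like")
print("constitutive expression and tau_d bounds the MFPT from above.")
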