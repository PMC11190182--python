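# fptcme

First-passage-time analysis for stochastic chemical reaction networks.

Many cellular events are triggered when the copy number of a regulatory
molecule first reaches a threshold — cyclins licensing cell-cycle
transitions, p53 deciding between arrest and apoptosis, calcium bursts
firing downstream signalling.  The time of that first crossing is the
**first-passage time (FPT)**: for a continuous-time Markov model
**x**(t) of a reaction network and a target set **Y**,

    tau_n = inf { t >= 0 : x(t) in Y | x(0) = n }.

Biochemistry is routinely modelled with deterministic rate equations, and
one might hope their crossing time tau_d is a good stand-in for the mean
FPT.  It is not: intrinsic molecular noise systematically shifts mean
trigger times, in either direction, and `fptcme` exists to compute and
map that shift, summarised by the ratio

    eta = <tau_n> / tau_d     (eta < 1: noise accelerates triggering).

## What it computes

* **FPT moments, exactly.** The raw moments of tau satisfy the sparse
  linear recursion `A_Y^T E[tau^k] = -k E[tau^(k-1)]`, where `A` is the
  chemical-master-equation generator truncated by a finite state
  projection (FSP) and `A_Y` drops the rows/columns of the target set.
  One sparse LU factorization yields mean, variance and CV² of the FPT
  for **every** initial state simultaneously, with automatic truncation
  refinement (FSP truncation biases MFPTs low; the solver doubles the box
  until the answer stabilizes).
* **Full FPT distributions** by stiff time integration of the reduced
  master equation: survival function S(t) and density −dS/dt.
* **Deterministic crossing times** tau_d from the mean-field
  reaction-rate equations, with closed forms where they exist (for the
  birth–death process, tau_d = −ln(1−rho) for a target at a fraction rho
  of the steady-state mean — independent of the production rate).
* **Closed-form birth–death MFPT** via the falling-factorial double sum,
  evaluated by stable term recursion.
* **Exact Gillespie simulation** (direct method, vectorized over chains)
  as an independent Monte-Carlo oracle.
* **Model library and sweeps** for constitutive, fixed-burst and
  geometric-burst expression, the two-state telegraph gene, and an
  autoregulatory feedback loop, plus eta sweeps over production rate,
  gene-switching rates and feedback strength.

## A worked example

```python
import fptcme as f

bundle = f.simple_bd(K=50.0)          # production 50/unit time, unit decay
target, N = bundle.target(0.8)        # N = floor(0.8 * 50) = 40 molecules

moments, report = f.mfpt_with_refinement(bundle.network, target)
mfpt  = moments.mean_from([0])        # 1.477279
tau_d = f.deterministic_fpt_closed_form(0.8)   # 1.609438
print(mfpt, tau_d, mfpt / tau_d)
```

prints

```
1.4772791539161494 1.6094379124341003 0.9178848172359294
```

The mean stochastic crossing happens ~8% sooner than the deterministic
model predicts (eta = 0.918 < 1).  For constitutive expression this is a
theorem — the stochastic sum is a falling-factorial-damped truncation of
the Taylor series of −ln(1−rho) — and the gap closes as copy numbers grow
(eta = 0.994 at K = 1000).  Bursty production flips the ordering at low
thresholds: with bursts of 10 at K = 20, eta = 0.83 for a target at 90%
of the mean but eta = 1.10 at 20%, and any target below the burst size is
hit after exactly one production event (MFPT = 1/K).  In autoregulatory
feedback loops the effect can exceed an order of magnitude (eta ≈ 18 on
the shipped rare-binding grid).

The `examples/` directory holds one narrative script per capability
(moments, distributions, SSA cross-checks, telegraph timing, feedback
sweeps, config-defined networks); each prints the numbers it computes and
one line on what they mean.  The same functionality is exposed on the
command line:

```bash
fptcme eta telegraph -p lambda_on=2 -p mu_off=0.5 -p K=625 --rho 0.6
fptcme mfpt simple_bd -p K=50 --rho 0.8 -o moments.csv
fptcme sweep-k --family bursty_bd -r 10 --rho 0.2
```

## Documentation

`docs/methods.md` describes the model assumptions, numerical choices,
truncation heuristics and known limitations in detail.
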