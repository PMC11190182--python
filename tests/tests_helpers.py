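"""Small shared helpers for the test suite."""

import fptcme as f


def refined_mfpt(bundle, target, initial_state=None, rtol=1e-6):
    """Mean FPT from the bundle's default initial state with refinement."""
    x0 = bundle.default_initial_state if initial_state is None else initial_state
    moments, _ = f.mfpt_with_refinement(
        bundle.network, target, rtol=rtol, k_max=1, initial_state=x0
    )
    return moments.mean_from(x0)
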