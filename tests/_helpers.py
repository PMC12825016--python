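"""Shared helpers for the test suite."""

import numpy as np


def random_kinetics(rng, n):
    """Random valid kinetic parameter sets (for mass-balance style checks)."""
    from nanopbpk import KineticParams

    out = []
    for _ in range(n):
        out.append(
            KineticParams(
                f_lu=rng.uniform(0.0, 1.0),
                f_mps=rng.uniform(0.0, 1.0),
                f_k=rng.uniform(0.0, 1.0),
                f_o=rng.uniform(0.0, 1.0),
                k_e_mps=rng.uniform(0.0, 30.0),
                k_e_k=rng.uniform(0.0, 30.0),
                q_mps=rng.uniform(0.1, 600.0),
                q_o=rng.uniform(0.1, 600.0),
            )
        )
    return out
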