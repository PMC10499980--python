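"""Shared test helpers."""

import numpy as np

from cellfile.membrane import DimensionlessParameters


def random_params(rng) -> DimensionlessParameters:
    """Random but physically sensible dimensionless parameter draw."""
    P_ca, P_ac = rng.uniform(1e-4, 0.1), rng.uniform(0.05, 1.0)
    P_cv, P_vc = rng.uniform(0.1, 5.0), rng.uniform(0.05, 2.0)
    return DimensionlessParameters(
        eps=0.05,
        lam=rng.uniform(0.002, 0.2),
        omega=rng.uniform(0.05, 1.0),
        phi=rng.uniform(0.05, 0.9),
        P_pass=0.2, P_imp=0.01, P_exp=0.3, P_plas=rng.uniform(0, 1.0),
        P_ca=P_ca, P_ac=P_ac, P_cv=P_cv, P_vc=P_vc,
        ratio_a=P_ca / P_ac, ratio_v=P_cv / P_vc,
        time_scale=1e4, l_ref=20.0, file_length=410.0, d_apo=32.0,
    )
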