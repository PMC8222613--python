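import numpy as np
import pytest

from dcmsearch.model_space import Condition, ConstraintSpec
from dcmsearch.semantic import semantic_constraints
from dcmsearch.synthetic import LandscapeSpec, generate_landscape


def make_spec(n_regions=3, n_modulatory=1, n_driving=1, mod_on_diag=True,
              require_connection=False):
    """A compact constraint space: all off-diagonal A free, modulation free
    on self-connections only (by default), driving inputs fixed on."""
    n = n_regions
    conditions = [Condition(f"mod{k}", "modulatory") for k in range(n_modulatory)]
    conditions += [Condition(f"drv{k}", "driving") for k in range(n_driving)]
    fixed_off_b = np.ones((n_modulatory, n, n), dtype=bool)
    if mod_on_diag:
        for k in range(n_modulatory):
            for r in range(n):
                fixed_off_b[k, r, r] = False
    fixed_on_c = np.ones((n, n_driving), dtype=bool)
    return ConstraintSpec(
        n_regions=n,
        conditions=conditions,
        fixed_off_b=fixed_off_b,
        fixed_on_c=fixed_on_c,
        modulation_requires_connection=require_connection,
    )


@pytest.fixture(scope="session")
def semantic_spec():
    return semantic_constraints()


@pytest.fixture(scope="session")
def spec9():
    """9 free bits: 6 off-diagonal A + 3 diagonal modulations."""
    return make_spec(n_regions=3)


@pytest.fixture(scope="session")
def spec12():
    """12 free bits: 12 off-diagonal A entries of a 4-region network."""
    return make_spec(n_regions=4, n_modulatory=0, n_driving=1)


@pytest.fixture(scope="session")
def spec8():
    """8 free bits: 2 regions, one modulatory input free everywhere, free C."""
    n = 2
    return ConstraintSpec(
        n_regions=n,
        conditions=[Condition("mod", "modulatory"), Condition("drv", "driving")],
        fixed_on_c=None,
        modulation_requires_connection=False,
    )


@pytest.fixture(scope="session")
def landscape12(spec12):
    """Noiseless additive landscape over 2^12 models (unimodal, planted
    optimum)."""
    return generate_landscape(LandscapeSpec(constraints=spec12, seed=101))


@pytest.fixture(scope="session")
def sharp_landscape16(semantic_spec):
    """The default 16-bit synthetic space with sharp synthetic posterior
    probabilities (shaped like the 65,536-model semantic space)."""
    return generate_landscape(
        LandscapeSpec(constraints=semantic_spec, sharpness=8.0, seed=202))
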