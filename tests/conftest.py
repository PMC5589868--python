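import numpy as np
import pytest

import ionoptode as ion


@pytest.fixture(scope="session")
def comp():
    """Ca2+ optode composition in the molar ratios of the reference recipe."""
    return ion.DEFAULT_COMPOSITION


@pytest.fixture(scope="session")
def eq(comp):
    """Equilibrium with the model midpoint placed at 105 nM, pH 7.2."""
    return ion.default_equilibrium(comp)


@pytest.fixture(scope="session")
def gains():
    return ion.ChannelGains()


def random_feasible_composition(rng: np.random.Generator) -> ion.OptodeComposition:
    """Rejection-sample a composition with a non-empty protonation domain."""
    for _ in range(100):
        z = int(rng.integers(1, 3))
        n = int(rng.integers(1, 4))
        r = float(rng.uniform(0.3, 2.0))
        i = float(rng.uniform(0.4, 3.5))
        try:
            return ion.OptodeComposition(
                chromoionophore_total=1.0,
                exchanger_total=r,
                ionophore_total=i,
                ion_charge=z,
                stoichiometry=n,
            )
        except ion.OptodeInputError:
            continue
    raise AssertionError("failed to sample a feasible composition")
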