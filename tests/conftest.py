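import numpy as np
import pytest

from myodwell import (Condition, ForceModel, RateConstants,
                      build_absorbing_chain, build_branched, build_unicycle)


@pytest.fixture(scope="session")
def rc():
    return RateConstants()


@pytest.fixture(scope="session")
def fm():
    return ForceModel()


@pytest.fixture(scope="session")
def unicycle(rc):
    return build_unicycle(rc)


@pytest.fixture(scope="session")
def branched():
    return build_branched(RateConstants(gating_g=10.0))


@pytest.fixture(scope="session")
def sat_chain(unicycle, fm):
    """Uni-cycle absorbing chain at saturating ATP, no ADP/P, no load."""
    return build_absorbing_chain(unicycle, Condition(atp=1000.0), fm)


def random_conditions(n, seed, atp=(1.0, 2000.0), adp=(0.0, 500.0),
                      p=(0.0, 10.0), force=(0.0, 2.0)):
    """Deterministic batch of plausible experimental conditions."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        out.append(Condition(
            atp=float(rng.uniform(*atp)),
            adp=float(rng.uniform(*adp)),
            p=float(rng.uniform(*p)),
            force=float(rng.uniform(*force)),
        ))
    return out
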