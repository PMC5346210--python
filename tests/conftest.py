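import numpy as np
import pytest
from dataclasses import replace

from likertfa import (SyntheticPopulationSpec, calibrate_floor,
                      generate_responses)


@pytest.fixture(scope="session")
def uncensored_population():
    """Clean two-factor ordinal population (floor effect ~0)."""
    return generate_responses(SyntheticPopulationSpec(N=2000, seed=42))


@pytest.fixture(scope="session")
def censored_population():
    """Two-factor population with the floor calibrated to 32% zero rows."""
    spec = SyntheticPopulationSpec(N=20_000, seed=42)
    delta = calibrate_floor(spec, 0.32)
    return generate_responses(replace(spec, severity_offset=delta))


def assert_rotation_invariant(solution, atol=1e-8):
    """Lambda Phi Lambda' must reproduce the unrotated common part."""
    L, Phi, A = (solution.pattern, solution.factor_correlations,
                 solution.unrotated)
    assert np.max(np.abs(L @ Phi @ L.T - A @ A.T)) < atol
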