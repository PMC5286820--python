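import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulated expression study shared by tests."""
    from rootskew import ExprSimConfig, simulate_expression

    return simulate_expression(ExprSimConfig(seed=1))


@pytest.fixture(scope="session")
def default_pipeline(default_sim):
    from rootskew import build_comparison_matrix, run_pipeline

    study, truth = default_sim
    matrix = build_comparison_matrix(study)
    return matrix, run_pipeline(matrix), truth


def semicircle(radius=10.0, n=1000):
    """Semicircular arc from (-r, 0) to (r, 0), opening downward."""
    theta = np.linspace(np.pi, 0.0, n)
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
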