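import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mlpacall as m

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def tiny_experiment():
    """3 probes, 1 control + 1 case run, one reference probe."""
    return m.setup_experiment(
        control_intensities=np.array([[2.0], [4.0], [6.0]]),
        case_intensities=np.array([[2.0], [4.0], [6.0]]),
        sizes_bp=[100.0, 200.0, 300.0],
        reference_ids=["P001"],
    )


@pytest.fixture
def demo_experiment():
    """Replicate-free experiment in the standard panel shape (34 probes, 9
    reference, 10 case + 5 control), with moderate noise."""
    exp, _ = m.simulate_experiment(m.SimConfig(seed=11))
    return exp


@pytest.fixture
def replicated_experiment():
    """Triplicate experiment with moderate noise and no alterations."""
    exp, _ = m.simulate_experiment(m.SimConfig(n_replicates=3, seed=12))
    return exp


def make_normalized(control_cols: np.ndarray, case_cols: np.ndarray, sizes=None,
                    reference_ids=("P001",)):
    """Wrap already-comparable matrices as a NormalizedExperiment."""
    control_cols = np.atleast_2d(np.asarray(control_cols, dtype=float))
    case_cols = np.atleast_2d(np.asarray(case_cols, dtype=float))
    n = control_cols.shape[0]
    if sizes is None:
        sizes = np.linspace(100, 100 * n, n)
    exp = m.setup_experiment(control_cols, case_cols, sizes, list(reference_ids))
    return m.NormalizedExperiment.pre_normalized(exp)
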