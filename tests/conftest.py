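import numpy as np
import pytest

from genestab.model import ModelParams, frequency_trajectory
from genestab.simulate import CountSeries, TransferDesign, simulate_experiment


@pytest.fixture(scope="session")
def pseudo_exact():
    """Factory for noise-free count data: x_j = round(n * p(t_j)).

    With very large n the binomial likelihood concentrates at the generating
    parameters, so the fitted estimates must recover them.
    """

    def make(mu, s, r=0.1, n=10**6, n_transfers=30, T=24.0, p0=1.0):
        params = ModelParams(r=r, s=s, mu=mu)
        t = np.arange(n_transfers + 1) * T
        p = frequency_trajectory(p0, params, t)
        return [
            CountSeries(
                replicate="exact",
                t=t,
                n=np.full(t.shape, n, dtype=int),
                x=np.round(n * p).astype(int),
            )
        ]

    return make


@pytest.fixture(scope="session")
def simulated_default():
    """One stochastic experiment at default design (r=0.1, K=2e6, T=24,
    n=100, beta=1e4, R=3) with truth mu=1e-3, s=0.05."""
    params = ModelParams(r=0.1, s=0.05, mu=1e-3, K=2e6)
    design = TransferDesign(seed=42)
    return simulate_experiment(params, design), params, design
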