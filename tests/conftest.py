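import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mfpatch import MFDFA, CascadeSpec, FgnSpec, simulate_cascade, simulate_fgn

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

N_FGN = 2**16
N_SEEDS = 20


@pytest.fixture(scope="session")
def fgn_mfdfa_runs():
    """Fitted MFDFA estimators for fGn at H in {0.3, 0.5, 0.7}, 20 seeds each.

    Shared across the monofractal-recovery, flatness and spectrum-narrowness
    checks so the heavy simulation runs once per session.
    """
    runs = {}
    for hurst in (0.3, 0.5, 0.7):
        runs[hurst] = [
            MFDFA().fit(simulate_fgn(FgnSpec(hurst=hurst, n_samples=N_FGN, seed=seed)))
            for seed in range(N_SEEDS)
        ]
    return runs


@pytest.fixture(scope="session")
def cascade_mfdfa_run():
    """Fitted MFDFA estimator on the deterministic a=0.75, k=16 cascade."""
    x = simulate_cascade(CascadeSpec(a=0.75, k_levels=16))
    return MFDFA().fit(x)


@pytest.fixture
def rng():
    return np.random.default_rng(20230403)
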