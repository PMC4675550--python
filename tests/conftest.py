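import numpy as np
import pytest

from tgpmodel import CohortCounts, TGPParameters, calibrate_gamma


@pytest.fixture(scope="session")
def cohort() -> CohortCounts:
    """The published genetic-profiling cohort: 57 benign, 9 aggressive."""
    return CohortCounts(benign=57, aggressive=9)


@pytest.fixture(scope="session")
def gamma_hat(cohort) -> float:
    return calibrate_gamma(cohort.benign / cohort.total)


@pytest.fixture(scope="session")
def calibrated_params(gamma_hat) -> TGPParameters:
    return TGPParameters(N=50, gamma=gamma_hat, u=0.0)


def brute_force_absorption(N: int, v: float) -> dict[str, np.ndarray]:
    """Independent oracle: fixed-point iteration of first-step equations
    on the one-step Moran chain, self-loops kept.

    From k type-I cells of N: the birth cell is uniform, a type-I birth
    mutates with probability v (-> E), the death cell is uniform.
    """
    states = N + 2  # 0..N plus E at index N+1
    P = np.zeros((states, states))
    for k in range(1, N):
        p_e = (k / N) * v
        p_up = (k / N) * (1 - v) * ((N - k) / N)
        p_down = ((N - k) / N) * (k / N)
        P[k, N + 1] = p_e
        P[k, k + 1] = p_up
        P[k, k - 1] = p_down
        P[k, k] = 1.0 - p_e - p_up - p_down
    for a in (0, N, N + 1):
        P[a, a] = 1.0
    out = {}
    for name, target in (("hit_zero", 0), ("hit_N", N), ("hit_E", N + 1)):
        h = np.zeros(states)
        h[target] = 1.0
        for _ in range(2_000_000):
            h_new = P @ h
            h_new[target] = 1.0
            if np.max(np.abs(h_new - h)) < 1e-14:
                h = h_new
                break
            h = h_new
        out[name] = h[: N + 1]
    return out
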