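"""Compiled trajectory kernels for the embedded TGP jump chain.

Each replicate seeds numba's per-thread legacy RNG with its own uint32
word, giving per-replicate streams derived from a master seed at the
caller. Outcome codes: 0 -> extinction, 1 -> fixation at N, 2 -> E,
-1 -> step cap exceeded.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _steps_from(N, v, k, step_cap):  # pragma: no cover - jit body
    """Iterate the embedded chain from transient k; returns (code, steps)."""
    steps = 0
    while True:
        if k == 0:
            return 0, steps
        if k == N:
            return 1, steps
        r_up = k * (1.0 - v) * (N - k) / N
        r_down = (N - k) * k / N
        r_e = k * v
        x = np.random.random() * (r_up + r_down + r_e)
        if x < r_e:
            return 2, steps + 1
        elif x < r_e + r_up:
            k += 1
        else:
            k -= 1
        steps += 1
        if steps >= step_cap:
            return -1, steps


@njit(cache=False)
def run_trajectory(N, v, inject, k0, seed, step_cap):  # pragma: no cover
    np.random.seed(seed)
    k = k0
    total = 0
    while True:
        if k == 0:
            if not inject:
                return 0, total
            k = 1
            total += 1  # the injection 0 -> 1 counts as one jump
            continue
        code, steps = _steps_from(N, v, k, step_cap - total)
        total += steps
        if code == 0 and inject:
            k = 0
            continue
        if code == -1 or total >= step_cap:
            return -1, total
        return code, total


@njit(cache=False)
def run_batch(N, v, inject, k0, seeds, step_cap):  # pragma: no cover
    reps = seeds.shape[0]
    codes = np.empty(reps, dtype=np.int64)
    steps = np.empty(reps, dtype=np.int64)
    for r in range(reps):
        c, s = run_trajectory(N, v, inject, k0, seeds[r], step_cap)
        codes[r] = c
        steps[r] = s
    return codes, steps
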