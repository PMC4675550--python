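"""Embedded jump chain of the growth-and-progression process."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tgpmodel import (
    StepCapExceeded,
    TGPParameters,
    jump_distribution,
    simulate_batch,
    simulate_trajectory,
    trajectories_to_frame,
)


class TestParameters:
    def test_gamma_derived_from_v(self):
        p = TGPParameters(N=10, v=0.001)
        assert p.gamma == pytest.approx(10**2 * 0.001, abs=0)

    def test_v_derived_from_gamma(self):
        p = TGPParameters(N=20, gamma=0.152)
        assert p.v == 0.152 / 400
        assert p.gamma == 0.152

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(N=1, v=0.1),
            dict(N=10, v=0.1, gamma=10.0),  # both supplied
            dict(N=10),  # neither supplied
            dict(N=2, gamma=4.5),  # implies v >= 1
            dict(N=10, v=1.0),
            dict(N=10, v=-0.1),
            dict(N=10, gamma=-1.0),
            dict(N=10, v=0.1, u=1.5),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TGPParameters(**kwargs)

    def test_rare_mutation_regime_check(self):
        TGPParameters(N=10, v=0.0, u=0.05).require_rare_type_i()
        with pytest.raises(ValueError):
            TGPParameters(N=10, v=0.0, u=0.2).require_rare_type_i()


class TestJumpDistribution:
    def test_neutral_symmetric(self):
        d = jump_distribution(TGPParameters(N=2, v=0.0, u=0.0), 1)
        assert d.p_up == d.p_down == 0.5
        assert d.p_to_E == 0.0

    def test_small_case_rates(self):
        # N=2, v=0.1, k=1: raw rates up 0.45, down 0.5, to-E 0.1
        d = jump_distribution(TGPParameters(N=2, v=0.1, u=0.0), 1)
        assert d.p_up == pytest.approx(0.45 / 1.05, abs=1e-15)
        assert d.p_down == pytest.approx(0.5 / 1.05, abs=1e-15)
        assert d.p_to_E == pytest.approx(0.1 / 1.05, abs=1e-15)

    @pytest.mark.parametrize("k", [0, 2])
    def test_boundary_states_rejected(self, k):
        with pytest.raises(ValueError):
            jump_distribution(TGPParameters(N=2, v=0.1, u=0.0), k)

    @given(
        N=st.integers(2, 500),
        v=st.floats(0.0, 0.999),
        frac=st.floats(0.0, 1.0, exclude_max=True),
    )
    @settings(max_examples=200, deadline=None)
    def test_normalization_and_ranges(self, N, v, frac):
        k = 1 + int(frac * (N - 1))
        d = jump_distribution(TGPParameters(N=N, v=v, u=0.0), k)
        assert abs(d.p_up + d.p_down + d.p_to_E - 1.0) < 1e-12
        assert all(0.0 <= x <= 1.0 for x in d.as_array())


class TestTrajectories:
    def test_start_at_absorbing_state(self):
        p = TGPParameters(N=10, v=0.0, u=0.0)
        out = simulate_trajectory(p, k0=10, seed=1)
        assert out.absorbing_state == "N" and out.steps == 0
        out = simulate_trajectory(p, k0=0, seed=1)
        assert out.absorbing_state == "0" and out.steps == 0

    def test_no_progression_without_second_mutation(self):
        p = TGPParameters(N=20, v=0.0, u=0.0)
        for seed in range(20):
            out = simulate_trajectory(p, k0=10, seed=seed)
            assert out.absorbing_state in {"0", "N"}
            assert out.steps >= 1

    def test_high_second_mutation_rate_blocks_fixation(self):
        # with v close to 1 the up-rate is tiny, so almost every
        # trajectory from k=1 ends at 0 or E
        p = TGPParameters(N=10, v=0.99, u=0.0)
        outcomes = {simulate_trajectory(p, 1, seed=s).absorbing_state for s in range(50)}
        assert "N" not in outcomes

    def test_full_process_injection_from_zero(self):
        # u > 0: unsuccessful mutants are re-injected until one absorbs
        p = TGPParameters(N=10, gamma=0.5)  # default u = 0.1/N > 0
        out = simulate_trajectory(p, k0=0, seed=3)
        assert out.absorbing_state in {"N", "E"}
        assert out.steps >= 1

    def test_determinism(self):
        p = TGPParameters(N=30, gamma=0.152, u=0.0)
        a = simulate_trajectory(p, 15, seed=99)
        b = simulate_trajectory(p, 15, seed=99)
        assert a == b

    def test_step_cap_raises(self):
        p = TGPParameters(N=50, v=0.0, u=0.0)
        with pytest.raises(StepCapExceeded):
            simulate_trajectory(p, k0=25, seed=0, step_cap=5)


class TestBatch:
    def test_neutral_extinction_matches_moran_formula(self):
        # v = 0 reduces to the symmetric Moran chain: extinction
        # probability from k is 1 - k/N
        p = TGPParameters(N=50, v=0.0, u=0.0)
        s = simulate_batch(p, k0=25, reps=10_000, seed=7)
        assert s.fraction_E == 0.0
        assert abs(s.fraction_0 - 0.5) <= 3 * np.sqrt(0.25 / 10_000)

    def test_fractions_and_stderrs_consistent(self):
        p = TGPParameters(N=20, gamma=0.5, u=0.0)
        s = simulate_batch(p, k0=5, reps=2_000, seed=21)
        assert s.fraction_0 + s.fraction_N + s.fraction_E == pytest.approx(1.0, abs=1e-12)
        for f, e in [
            (s.fraction_0, s.stderr_0),
            (s.fraction_N, s.stderr_N),
            (s.fraction_E, s.stderr_E),
        ]:
            assert e == pytest.approx(np.sqrt(f * (1 - f) / 2_000), abs=1e-15)

    def test_bit_identical_reproducibility(self):
        p = TGPParameters(N=30, gamma=0.152, u=0.0)
        a = simulate_batch(p, k0=10, reps=500, seed=5)
        b = simulate_batch(p, k0=10, reps=500, seed=5)
        assert a == b
        c = simulate_batch(p, k0=10, reps=500, seed=6)
        assert c != a

    def test_invalid_reps_rejected(self):
        p = TGPParameters(N=10, v=0.0, u=0.0)
        with pytest.raises(ValueError):
            simulate_batch(p, k0=5, reps=0, seed=1)

    def test_absorbed_start_with_u_zero_rejected(self):
        p = TGPParameters(N=10, v=0.0, u=0.0)
        with pytest.raises(ValueError):
            simulate_batch(p, k0=0, reps=10, seed=1)


def test_trajectory_frame_schema_and_determinism(tmp_path):
    p = TGPParameters(N=20, gamma=0.3, u=0.0)
    frame = trajectories_to_frame(p, k0=5, reps=50, seed=4)
    assert list(frame.columns) == ["replicate", "k0", "absorbing_state", "steps", "seed"]
    assert len(frame) == 50
    assert set(frame["absorbing_state"]).issubset({"0", "N", "E"})
    path = tmp_path / "traj.csv"
    frame.to_csv(path, index=False)
    again = trajectories_to_frame(p, k0=5, reps=50, seed=4)
    assert frame.equals(again)
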