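"""Tsodyks-Markram resource dynamics: closed form, jumps, plasticity rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from granulayer import presyn
from granulayer.presyn import (
    Plasticity,
    PlasticityMode,
    ReleaseParams,
    ReleaseState,
    apply_plasticity,
    apply_spike,
    evolve_state,
    initial_state,
    release_train,
)


class TestEvolveState:
    def test_long_time_reaches_fixed_point(self, mf_grc_params):
        st0 = ReleaseState(X=0.2, Y=0.5, Z=0.3, P=0.9)
        out = evolve_state(st0, 50 * max(8.0, 5.0, 1.0), mf_grc_params)
        assert out.X == pytest.approx(1.0, abs=1e-6)
        assert out.Y == pytest.approx(0.0, abs=1e-6)
        assert out.Z == pytest.approx(0.0, abs=1e-6)
        assert out.P == pytest.approx(mf_grc_params.p_init, abs=1e-6)

    def test_dt_zero_is_identity(self, mf_grc_params):
        st0 = ReleaseState(X=0.58, Y=0.42, Z=0.0, P=0.6636)
        assert evolve_state(st0, 0.0, mf_grc_params) is st0

    def test_negative_dt_rejected(self, mf_grc_params):
        with pytest.raises(ValueError):
            evolve_state(initial_state(mf_grc_params), -1.0, mf_grc_params)

    def test_matches_rk4_oracle_post_spike(self, mf_grc_params, rk4_presyn_oracle):
        st0 = ReleaseState(X=0.58, Y=0.42, Z=0.0, P=0.6636)
        out = evolve_state(st0, 20.0, mf_grc_params)
        expect = rk4_presyn_oracle(st0, 20.0, mf_grc_params)
        got = np.array([out.X, out.Y, out.Z, out.P])
        np.testing.assert_allclose(got, expect, atol=1e-6)

    def test_matches_rk4_oracle_random_draws(self, rk4_presyn_oracle):
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = ReleaseParams(
                p_init=rng.uniform(0.05, 0.95),
                tau_rec=rng.uniform(1.0, 50.0),
                tau_facil=rng.uniform(1.0, 80.0),
                tau_inact=rng.uniform(0.1, 5.0),
            )
            y = rng.dirichlet([1, 1, 1])
            st0 = ReleaseState(X=y[0], Y=y[1], Z=y[2], P=rng.uniform(0, 1))
            dt = rng.uniform(0.1, 30.0)
            out = evolve_state(st0, dt, p)
            expect = rk4_presyn_oracle(st0, dt, p)
            np.testing.assert_allclose(
                [out.X, out.Y, out.Z, out.P], expect, atol=1e-6)
            assert abs(out.X + out.Y + out.Z - 1.0) < 1e-9

    def test_degenerate_equal_time_constants(self, rk4_presyn_oracle):
        p = ReleaseParams(p_init=0.4, tau_rec=5.0, tau_facil=10.0, tau_inact=5.0)
        st0 = ReleaseState(X=0.3, Y=0.6, Z=0.1, P=0.5)
        out = evolve_state(st0, 7.0, p)
        expect = rk4_presyn_oracle(st0, 7.0, p)
        assert np.all(np.isfinite([out.X, out.Y, out.Z, out.P]))
        np.testing.assert_allclose([out.X, out.Y, out.Z, out.P], expect, atol=1e-6)


class TestApplySpike:
    def test_first_spike_from_rest(self, mf_grc_params):
        new, released = apply_spike(initial_state(mf_grc_params), mf_grc_params)
        assert released == pytest.approx(0.42)
        assert new.X == pytest.approx(0.58)
        assert new.Y == pytest.approx(0.42)
        assert new.P == pytest.approx(0.6636)

    def test_zero_probability_releases_nothing(self, mf_grc_params):
        st0 = ReleaseState(X=1.0, Y=0.0, Z=0.0, P=0.0)
        new, released = apply_spike(st0, mf_grc_params)
        assert released == 0.0
        assert new.X == 1.0
        assert new.P == pytest.approx(mf_grc_params.p_init)  # facilitation jump

    def test_full_probability_empties_pool(self, mf_grc_params):
        st0 = ReleaseState(X=0.3, Y=0.5, Z=0.2, P=1.0)
        new, released = apply_spike(st0, mf_grc_params)
        assert released == pytest.approx(0.3)
        assert new.X == pytest.approx(0.0)


@given(
    dts=st.lists(st.floats(0.01, 40.0), min_size=1, max_size=12),
    p_init=st.floats(0.05, 0.95),
)
@settings(max_examples=50, deadline=None)
def test_conservation_under_any_sequence(dts, p_init):
    """X + Y + Z stays 1 through arbitrary evolve/spike interleavings."""
    params = ReleaseParams(p_init=p_init, tau_rec=8.0, tau_facil=5.0, tau_inact=1.0)
    state = initial_state(params)
    for dt in dts:
        state = evolve_state(state, dt, params)
        state, _ = apply_spike(state, params)
        assert abs(state.X + state.Y + state.Z - 1.0) < 1e-9
        assert 0.0 <= state.P <= 1.0 + 1e-12


class TestReleaseTrain:
    def test_empty_train(self, mf_grc_params):
        out = release_train([], mf_grc_params)
        assert out.shape == (0, mf_grc_params.n_sites)

    def test_unsorted_times_rejected(self, mf_grc_params):
        with pytest.raises(ValueError):
            release_train([10.0, 5.0], mf_grc_params)

    def test_deterministic_pair_matches_hand_composition(self, mf_grc_params):
        out = release_train([0.0, 20.0], mf_grc_params)
        st0 = initial_state(mf_grc_params)
        st1, r1 = apply_spike(st0, mf_grc_params)
        st2 = evolve_state(st1, 20.0, mf_grc_params)
        _, r2 = apply_spike(st2, mf_grc_params)
        np.testing.assert_allclose(out[0], r1)
        np.testing.assert_allclose(out[1], r2)

    def test_certain_release_fires_all_sites(self):
        p = ReleaseParams(p_init=1.0, tau_rec=8.0, tau_facil=5.0,
                          tau_inact=1.0, n_sites=7)
        out = release_train([0.0], p, stochastic=True, seed=0)
        np.testing.assert_allclose(out[0], np.ones(7))

    def test_pure_depression_is_nonincreasing(self):
        # facilitation effectively off (tiny tau_facil), tau_inact << tau_rec
        p = ReleaseParams(p_init=0.5, tau_rec=50.0, tau_facil=1e-6, tau_inact=0.5)
        times = np.arange(8) * 10.0
        rel = release_train(times, p)[:, 0]
        assert np.all(np.diff(rel) <= 1e-12)

    def test_stochastic_mean_converges_to_deterministic(self, mf_grc_params):
        from dataclasses import replace

        times = np.arange(5) * 20.0
        det = release_train(times, mf_grc_params)[:, 0]
        big = replace(mf_grc_params, n_sites=10_000)
        sto = release_train(times, big, stochastic=True, seed=7).mean(axis=1)
        np.testing.assert_allclose(sto, det, rtol=0.02)

    def test_seeded_reproducibility(self, mf_grc_params):
        t = [0.0, 10.0, 30.0]
        a = release_train(t, mf_grc_params, stochastic=True, seed=3)
        b = release_train(t, mf_grc_params, stochastic=True, seed=3)
        np.testing.assert_array_equal(a, b)


class TestApplyPlasticity:
    @pytest.mark.parametrize("p0,mode,expect", [
        (0.42, PlasticityMode.LTP, 0.63),
        (0.42, PlasticityMode.LTD, 0.21),
        (0.35, PlasticityMode.LTP, 0.525),
        (0.35, PlasticityMode.LTD, 0.175),
    ])
    def test_fifty_percent_scaling(self, p0, mode, expect):
        params = ReleaseParams(p_init=p0, tau_rec=8.0, tau_facil=5.0, tau_inact=1.0)
        out = apply_plasticity(params, Plasticity(mode))
        assert out.p_init == pytest.approx(expect)

    def test_control_is_identity(self, mf_grc_params):
        assert apply_plasticity(
            mf_grc_params, Plasticity(PlasticityMode.CONTROL)) is mf_grc_params

    def test_overflow_rejected(self):
        params = ReleaseParams(p_init=0.8, tau_rec=8.0, tau_facil=5.0, tau_inact=1.0)
        with pytest.raises(ValueError):
            apply_plasticity(params, Plasticity(PlasticityMode.LTP))
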