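import numpy as np
import pytest

from granulayer import presyn


@pytest.fixture(scope="session")
def mf_grc_params():
    return presyn.MF_GRC


@pytest.fixture(scope="session")
def rk4_presyn_oracle():
    """Brute-force RK4 integrator of the resource/facilitation ODE system."""

    def integrate(state, dt, params, step=1e-3):
        y = np.array([state.X, state.Y, state.Z, state.P], dtype=float)

        def f(y):
            X, Y, Z, P = y
            return np.array([
                Z / params.tau_rec,
                -Y / params.tau_inact,
                Y / params.tau_inact - Z / params.tau_rec,
                -(P - params.p_init) / params.tau_facil,
            ])

        n = max(1, int(round(dt / step)))
        h = dt / n
        for _ in range(n):
            k1 = f(y)
            k2 = f(y + h / 2 * k1)
            k3 = f(y + h / 2 * k2)
            k4 = f(y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        return y

    return integrate
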