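"""Three-state presynaptic resource dynamics (Tsodyks-Markram scheme).

The releasable transmitter is partitioned into available (X), released (Y)
and recovered (Z) fractions obeying first-order kinetics between spikes:

    dX/dt = Z/tau_rec,   dY/dt = -Y/tau_inact,
    dZ/dt = Y/tau_inact - Z/tau_rec,

with X + Y + Z = 1 conserved.  The dynamic release probability P relaxes
toward its initial value p with time constant tau_facil.  At a presynaptic
spike a fraction P*X of the available resource is released (depression) and
P jumps by p*(1-P) for subsequent events (facilitation); release is computed
with the pre-jump P.

Long-term plasticity is expressed purely presynaptically as a +/-50 %
scaling of the initial release probability (mf-GrC control 0.42 -> LTP 0.63,
LTD 0.21; GoC-GrC 0.35 -> 0.525 / 0.175).

Between-spike evolution uses the closed-form solution of the linear system,
so arbitrarily long intervals cost one evaluation and conservation holds
exactly.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ReleaseParams",
    "ReleaseState",
    "PlasticityMode",
    "Plasticity",
    "MF_GRC",
    "GOC_GRC",
    "PF_GOC",
    "AA_GOC",
    "MF_GOC",
    "evolve_state",
    "apply_spike",
    "release_train",
    "apply_plasticity",
]

_CONS_TOL = 1e-9


@dataclass(frozen=True)
class ReleaseParams:
    """Parameters of one release-site class.

    p_init : initial release probability, in (0, 1]
    tau_rec : recovery from depression (ms)
    tau_facil : facilitation decay (ms)
    tau_inact : transmitter inactivation (ms)
    n_sites : number of independent release sites
    """

    p_init: float
    tau_rec: float
    tau_facil: float
    tau_inact: float
    n_sites: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.p_init <= 1.0):
            raise ValueError(f"p_init must be in (0, 1], got {self.p_init}")
        for name in ("tau_rec", "tau_facil", "tau_inact"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be > 0")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")


# Synapse classes with the release parameters of the granular-layer circuit.
MF_GRC = ReleaseParams(p_init=0.42, tau_rec=8.0, tau_facil=5.0, tau_inact=1.0, n_sites=6)
MF_GOC = ReleaseParams(p_init=0.42, tau_rec=8.0, tau_facil=5.0, tau_inact=1.0, n_sites=1)
PF_GOC = ReleaseParams(p_init=0.10, tau_rec=8.0, tau_facil=5.0, tau_inact=1.0, n_sites=1)
AA_GOC = ReleaseParams(p_init=0.10, tau_rec=8.0, tau_facil=5.0, tau_inact=1.0, n_sites=1)
GOC_GRC = ReleaseParams(p_init=0.35, tau_rec=36.0, tau_facil=58.5, tau_inact=0.1, n_sites=1)


@dataclass(frozen=True)
class ReleaseState:
    """Instantaneous state of the resource pool of one release site."""

    X: float = 1.0
    Y: float = 0.0
    Z: float = 0.0
    P: float = 0.0
    t_last: float = 0.0

    def validate(self) -> None:
        if min(self.X, self.Y, self.Z) < -_CONS_TOL:
            raise ValueError("resource fractions must be non-negative")
        if abs(self.X + self.Y + self.Z - 1.0) > 1e-6:
            raise ValueError("X + Y + Z must equal 1")
        if not (-_CONS_TOL <= self.P <= 1.0 + _CONS_TOL):
            raise ValueError("P must lie in [0, 1]")


def initial_state(params: ReleaseParams, t: float = 0.0) -> ReleaseState:
    """Fully recovered pool with P at its initial value."""
    return ReleaseState(X=1.0, Y=0.0, Z=0.0, P=params.p_init, t_last=t)


class PlasticityMode(str, enum.Enum):
    CONTROL = "control"
    LTP = "ltp"
    LTD = "ltd"


@dataclass(frozen=True)
class Plasticity:
    """Long-term plasticity descriptor: sign and fractional change of p."""

    mode: PlasticityMode = PlasticityMode.CONTROL
    fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction < 1.0):
            raise ValueError("fraction must be in (0, 1)")


def evolve_state(state: ReleaseState, dt: float, params: ReleaseParams) -> ReleaseState:
    """Advance the pool by ``dt`` ms with no spike (closed form).

    Y decays with tau_inact into Z, Z recovers into X with tau_rec, P
    relaxes to p_init with tau_facil.  The degenerate case
    tau_inact == tau_rec uses the t*exp(-t/tau) limiting solution.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if dt == 0:
        return state
    tr, ti, tf = params.tau_rec, params.tau_inact, params.tau_facil
    ey = math.exp(-dt / ti)
    er = math.exp(-dt / tr)
    Y = state.Y * ey
    if abs(ti - tr) < 1e-12 * max(ti, tr):
        Z = (state.Z + state.Y * dt / ti) * er
    else:
        c = state.Y * tr / (ti - tr)
        Z = (state.Z - c) * er + c * ey
    X = 1.0 - Y - Z  # exact conservation
    P = params.p_init + (state.P - params.p_init) * math.exp(-dt / tf)
    return ReleaseState(X=X, Y=Y, Z=Z, P=P, t_last=state.t_last + dt)


def apply_spike(
    state: ReleaseState, params: ReleaseParams
) -> tuple[ReleaseState, float]:
    """Apply the spike jump rules; returns (new state, released fraction).

    Release uses the pre-facilitation P; the facilitation jump
    P <- P + p_init*(1 - P) takes effect for the next event.
    """
    state.validate()
    released = state.P * state.X
    new = ReleaseState(
        X=state.X - released,
        Y=state.Y + released,
        Z=state.Z,
        P=state.P + params.p_init * (1.0 - state.P),
        t_last=state.t_last,
    )
    return new, released


def release_train(
    spike_times,
    params: ReleaseParams,
    stochastic: bool = False,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Released amount per site at each spike of a presynaptic train.

    Returns an array of shape (n_spikes, n_sites).  In deterministic mode
    every site releases P*X of its resource at each spike.  In stochastic
    mode each site independently releases its full available resource X
    with Bernoulli probability P (all-or-none site release); only sites
    that released are depleted.  Draws are consumed in site order, one row
    per spike, from a single seeded generator.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.ndim != 1:
        raise ValueError("spike_times must be one-dimensional")
    if spike_times.size == 0:
        return np.zeros((0, params.n_sites))
    if np.any(np.diff(spike_times) <= 0):
        raise ValueError("spike_times must be strictly increasing")

    n = params.n_sites
    out = np.zeros((spike_times.size, n))
    if not stochastic:
        st = initial_state(params, t=spike_times[0])
        for i, t in enumerate(spike_times):
            if i > 0:
                st = evolve_state(st, t - spike_times[i - 1], params)
            st, rel = apply_spike(st, params)
            out[i, :] = rel
        return out

    if rng is None:
        rng = np.random.default_rng(seed)
    states = [initial_state(params, t=spike_times[0]) for _ in range(n)]
    for i, t in enumerate(spike_times):
        for s in range(n):
            st = states[s]
            if i > 0:
                st = evolve_state(st, t - spike_times[i - 1], params)
            fired = rng.random() < st.P
            if fired:
                out[i, s] = st.X
                st = ReleaseState(X=0.0, Y=st.Y + st.X, Z=st.Z, P=st.P, t_last=st.t_last)
            # facilitation jump happens at every spike regardless of success
            states[s] = replace(st, P=st.P + params.p_init * (1.0 - st.P))
    return out


def apply_plasticity(params: ReleaseParams, plasticity: Plasticity) -> ReleaseParams:
    """Scale the initial release probability by +/- the plasticity fraction."""
    if plasticity.mode is PlasticityMode.CONTROL:
        return params
    sign = 1.0 if plasticity.mode is PlasticityMode.LTP else -1.0
    p_new = params.p_init * (1.0 + sign * plasticity.fraction)
    if not (0.0 < p_new <= 1.0):
        raise ValueError(f"plasticity would drive p_init to {p_new}, outside (0, 1]")
    return replace(params, p_init=p_new)
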