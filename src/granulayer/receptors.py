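"""Transmitter waveforms and Markov receptor kinetic schemes.

Release events are converted into a cleft transmitter concentration that
combines a brief synaptic pulse Ts (rectangular, direct release) with a
diffusion/spillover wave Td (exponential decay):

    T(t) = sum_events Y * [ Ts_max * rect(t; pulse) + Td_max * exp(-dt/tau_d) ]

Extra-synaptic NMDA receptors see only the diffusion component Td.

Receptor gating is a continuous-time Markov chain over closed, open and
desensitized states.  Binding transitions scale linearly with T, except the
AMPA opening step which uses the saturating two-site drive

    S(T) = T^2 / (T + K_B)^2,    K_B = 0.44 mM.

The postsynaptic current is I = gmax * O * B(V) * (V - Vrev) with O the
summed open-state occupancy and B(V) the magnesium block (NMDA only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TransmitterParams",
    "Transition",
    "KineticScheme",
    "KineticSchemeState",
    "transmitter_waveform",
    "ampa_drive",
    "generator_matrix",
    "step_scheme",
    "mg_block",
    "receptor_current",
    "build_default_schemes",
]


@dataclass(frozen=True)
class TransmitterParams:
    """Glutamate (or GABA) transient shape.

    Ts_max, Td_max in mM; pulse_duration and diff_tau in ms.  The waveform
    constants are not tightly constrained by recordings; the defaults give a
    ~1 mM, ~1 ms cleft transient with a smaller spillover tail.
    """

    Ts_max: float = 1.0
    Td_max: float = 0.3
    pulse_duration: float = 1.0
    diff_tau: float = 1.2

    def __post_init__(self) -> None:
        if self.Ts_max < 0 or self.Td_max < 0:
            raise ValueError("peak concentrations must be >= 0")
        if self.pulse_duration <= 0 or self.diff_tau <= 0:
            raise ValueError("durations must be > 0")


@dataclass(frozen=True)
class Transition:
    """One first-order transition of a kinetic scheme.

    ``drive`` selects the transmitter dependence of the rate:
    'const' (rate), 'linear' (rate*T) or 'sat' (rate*S(T)).
    """

    source: str
    target: str
    rate: float
    drive: str = "const"

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rates must be >= 0")
        if self.drive not in ("const", "linear", "sat"):
            raise ValueError(f"unknown drive {self.drive!r}")


@dataclass(frozen=True)
class KineticScheme:
    state_names: tuple[str, ...]
    transitions: tuple[Transition, ...]
    open_states: tuple[str, ...]
    gmax: float = 0.0           # pS
    Vrev: float = 0.0           # mV
    mg_block: bool = False
    kb: float = 0.44            # mM, saturation constant of the 'sat' drive
    transmitter: str = "total"  # 'total' or 'diffusion' (spillover-only)

    def __post_init__(self) -> None:
        names = set(self.state_names)
        if not self.open_states or not set(self.open_states) <= names:
            raise ValueError("open_states must be a non-empty subset of state_names")
        for tr in self.transitions:
            if tr.source not in names or tr.target not in names:
                raise ValueError(f"transition references unknown state: {tr}")

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def index(self, name: str) -> int:
        return self.state_names.index(name)

    def open_indices(self) -> np.ndarray:
        return np.array([self.index(s) for s in self.open_states], dtype=int)

    def scale_rates(self, factor: float) -> "KineticScheme":
        """Uniformly speed up every transition (e.g. Q10 temperature scaling)."""
        return replace(
            self,
            transitions=tuple(replace(t, rate=t.rate * factor) for t in self.transitions),
        )


@dataclass
class KineticSchemeState:
    """Occupancy probability vector over the scheme's states."""

    occupancy: np.ndarray = field(default_factory=lambda: np.array([1.0]))

    def validate(self) -> None:
        occ = np.asarray(self.occupancy)
        if np.any(occ < -1e-9) or np.any(occ > 1 + 1e-9):
            raise ValueError("occupancies must lie in [0, 1]")
        if abs(occ.sum() - 1.0) > 1e-6:
            raise ValueError("occupancies must sum to 1")


def resting_state(scheme: KineticScheme) -> KineticSchemeState:
    """All occupancy in the first (fully unbound, closed) state."""
    occ = np.zeros(scheme.n_states)
    occ[0] = 1.0
    return KineticSchemeState(occupancy=occ)


def transmitter_waveform(
    release_events,
    params: TransmitterParams,
    t,
    component: str = "total",
) -> np.ndarray | float:
    """Transmitter concentration (mM) at time(s) ``t`` from past release events.

    ``release_events`` is a sequence of (time_ms, released_fraction) pairs,
    time-sorted.  ``component`` is 'total', 'pulse' or 'diffusion'.
    """
    if component not in ("total", "pulse", "diffusion"):
        raise ValueError(f"unknown component {component!r}")
    t_arr = np.asarray(t, dtype=float)
    out = np.zeros_like(t_arr, dtype=float)
    last = -math.inf
    for te, amount in release_events:
        if te < last:
            raise ValueError("release events must be time-sorted")
        last = te
        dt = t_arr - te
        active = dt >= 0
        if component in ("total", "pulse"):
            out += np.where(active & (dt < params.pulse_duration), amount * params.Ts_max, 0.0)
        if component in ("total", "diffusion"):
            out += np.where(active, amount * params.Td_max * np.exp(-np.clip(dt, 0, None) / params.diff_tau), 0.0)
    return out if out.shape else float(out)


def ampa_drive(T, kb: float = 0.44):
    """Saturating two-site binding drive S(T) = T^2/(T + K_B)^2, in [0, 1)."""
    T = np.asarray(T, dtype=float)
    s = (T / (T + kb)) ** 2
    return s if s.shape else float(s)


def generator_matrix(scheme: KineticScheme, T: float) -> np.ndarray:
    """Master-equation generator A (columns sum to zero): dx/dt = A @ x."""
    n = scheme.n_states
    A = np.zeros((n, n))
    sat = ampa_drive(T, scheme.kb)
    for tr in scheme.transitions:
        i, j = scheme.index(tr.target), scheme.index(tr.source)
        rate = tr.rate
        if tr.drive == "linear":
            rate *= T
        elif tr.drive == "sat":
            rate *= sat
        A[i, j] += rate
        A[j, j] -= rate
    return A


def step_scheme(
    state: KineticSchemeState,
    scheme: KineticScheme,
    T: float,
    dt: float,
) -> KineticSchemeState:
    """Advance the occupancy by ``dt`` ms under constant transmitter T.

    RK4 on the linear master equation with internal substepping so that
    rate*dt stays small.  Runge-Kutta methods conserve linear invariants
    exactly, so the occupancy sum is preserved to machine precision.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if T < 0:
        raise ValueError("T must be >= 0")
    A = generator_matrix(scheme, T)
    total_rate = float(np.max(-np.diag(A), initial=0.0))
    n_sub = max(1, int(math.ceil(dt * total_rate / 0.1)))
    h = dt / n_sub
    x = np.asarray(state.occupancy, dtype=float).copy()
    for _ in range(n_sub):
        k1 = A @ x
        k2 = A @ (x + 0.5 * h * k1)
        k3 = A @ (x + 0.5 * h * k2)
        k4 = A @ (x + h * k3)
        x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    np.clip(x, 0.0, 1.0, out=x)
    x /= x.sum()
    return KineticSchemeState(occupancy=x)


def mg_block(V, mg_mM: float = 1.2):
    """Voltage-dependent magnesium unblock of the NMDA channel.

    B(V) = 1 / (1 + exp(-0.062 V) * [Mg]/3.57), [Mg] in mM.
    """
    V = np.asarray(V, dtype=float)
    b = 1.0 / (1.0 + np.exp(-0.062 * V) * mg_mM / 3.57)
    return b if b.shape else float(b)


def open_fraction(state: KineticSchemeState, scheme: KineticScheme) -> float:
    return float(np.sum(np.asarray(state.occupancy)[scheme.open_indices()]))


def receptor_current(state: KineticSchemeState, scheme: KineticScheme, V: float) -> float:
    """Postsynaptic current in pA: I = gmax * O * B(V) * (V - Vrev).

    gmax is in pS, V in mV (pS * mV = 1e-3 pA).
    """
    O = open_fraction(state, scheme)
    B = mg_block(V) if scheme.mg_block else 1.0
    return scheme.gmax * 1e-3 * O * B * (V - scheme.Vrev)


def conductance(state: KineticSchemeState, scheme: KineticScheme, V: float) -> float:
    """Instantaneous conductance in nS (including the NMDA Mg block at V)."""
    O = open_fraction(state, scheme)
    B = mg_block(V) if scheme.mg_block else 1.0
    return scheme.gmax * 1e-3 * O * B


def build_default_schemes() -> dict[str, KineticScheme]:
    """Registry of the receptor schemes used by the granular-layer synapses.

    AMPA: three states C-O-D; opening driven by the saturating drive S(T),
    desensitization off the open state.  NMDA: two sequential, identical
    glutamate-binding steps (U-C1-C2), opening and desensitization both off
    the doubly-bound closed state; activated by the diffusion (spillover)
    component only, with voltage-dependent Mg block.  Kainate: AMPA scheme
    with 20x slower recovery from desensitization (slow temporal summation).
    GABA-A: fast and slow two/three-state surrogates sharing the GABA
    transient, giving transient plus sustained inhibitory components.
    """
    ampa = KineticScheme(
        state_names=("C", "O", "D"),
        transitions=(
            Transition("C", "O", 5.4, "sat"),
            Transition("O", "C", 0.82),
            Transition("O", "D", 1.12),
            Transition("D", "O", 0.013),
        ),
        open_states=("O",),
        gmax=1200.0,
        Vrev=0.0,
    )
    nmda = KineticScheme(
        state_names=("U", "C1", "C2", "O", "D"),
        transitions=(
            Transition("U", "C1", 5.0, "linear"),
            Transition("C1", "U", 0.1),
            Transition("C1", "C2", 5.0, "linear"),
            Transition("C2", "C1", 0.1),
            Transition("C2", "O", 0.03),
            Transition("O", "C2", 0.966),
            Transition("C2", "D", 0.00012),
            Transition("D", "C2", 0.009),
        ),
        open_states=("O",),
        gmax=18800.0,
        Vrev=0.0,
        mg_block=True,
        transmitter="diffusion",
    )
    kainate = KineticScheme(
        state_names=("C", "O", "D"),
        transitions=(
            Transition("C", "O", 5.4, "sat"),
            Transition("O", "C", 0.82),
            Transition("O", "D", 1.12),
            Transition("D", "O", 0.013 / 20.0),
        ),
        open_states=("O",),
        gmax=400.0,
        Vrev=0.0,
    )
    gabaa_fast = KineticScheme(
        state_names=("C", "O", "D"),
        transitions=(
            Transition("C", "O", 10.0, "linear"),
            Transition("O", "C", 0.8),
            Transition("O", "D", 0.6),
            Transition("D", "O", 0.02),
        ),
        open_states=("O",),
        gmax=2000.0,
        Vrev=-65.0,
    )
    gabaa_slow = KineticScheme(
        state_names=("C", "O"),
        transitions=(
            Transition("C", "O", 1.0, "linear"),
            Transition("O", "C", 0.06),
        ),
        open_states=("O",),
        gmax=800.0,
        Vrev=-65.0,
        transmitter="diffusion",
    )
    return {
        "ampa": ampa,
        "nmda": nmda,
        "kainate": kainate,
        "gabaa_fast": gabaa_fast,
        "gabaa_slow": gabaa_slow,
    }
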