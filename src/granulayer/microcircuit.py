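"""The simplified granular-layer microcircuit: mf -> GrC <- GoC.

One granule cell receives up to four mossy fibers (one per dendrite) and
feedforward/feedback inhibition from up to four Golgi cells.  Mossy fibers
excite both the GrC and the GoCs; the GrC excites GoCs through its parallel
fiber (PF) and ascending axon (AA); GoCs inhibit the GrC dendrites.  Every
synapse combines Tsodyks-Markram presynaptic dynamics (optionally stochastic
multi-site release) with Markov receptor schemes, and transmission is
delayed by 1 ms.

The mf-GrC synapse splits its maximal conductance equally over n_rel = 6
release sites (AMPA 1200/n_rel pS, NMDA 18800/n_rel pS per site).  The
mf-GoC synapse is calibrated at wiring time so a single deterministic
stimulus evokes a -66 pA EPSC at -70 mV.

Protocols: frequency bursts (five pulses, 10-500 Hz, repeated trials),
theta-burst stimulation (8 x 10 pulses at 100 Hz every 250 ms; induction
itself is modelled separately as a release-probability change), and ideal
somatic voltage clamp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import presyn as ps
from . import receptors as rc
from . import neuron as nr

__all__ = [
    "CircuitConfig",
    "BurstProtocol",
    "TBSProtocol",
    "TraceSet",
    "SynapseSpec",
    "Synapse",
    "Circuit",
    "default_synapse_specs",
    "wire_circuit",
    "run_burst",
    "run_voltage_clamp",
    "run_tbs",
    "calibrate_mf_goc_gmax",
    "PRESETS",
]

TRANSMISSION_DELAY_MS = 1.0
SPIKE_THRESHOLD_MV = -20.0

# The four named excitatory/inhibitory combinations analysed quantitatively.
PRESETS = {
    "1mf_3goc": (1, 3),
    "2mf_2goc": (2, 2),
    "3mf_2goc": (3, 2),
    "4mf_3goc": (4, 3),
}


# ---------------------------------------------------------------------------
# Protocols and containers

@dataclass(frozen=True)
class BurstProtocol:
    """Five-pulse frequency burst repeated over trials (0.1 Hz repetition)."""

    frequency: float = 50.0
    n_pulses: int = 5
    n_trials: int = 10
    inter_trial_s: float = 10.0

    def __post_init__(self) -> None:
        if self.frequency <= 0 or self.n_pulses < 1:
            raise ValueError("frequency must be > 0 and n_pulses >= 1")

    def stimulus_times(self, t0: float = 0.0) -> np.ndarray:
        return t0 + np.arange(self.n_pulses) * 1000.0 / self.frequency


@dataclass(frozen=True)
class TBSProtocol:
    """Theta-burst stimulation: bursts of pulses repeated at theta rhythm."""

    pulses_per_burst: int = 10
    intra_burst_freq: float = 100.0
    n_bursts: int = 8
    burst_interval: float = 250.0

    def stimulus_times(self, t0: float = 0.0) -> np.ndarray:
        times = []
        for b in range(self.n_bursts):
            start = t0 + b * self.burst_interval
            times.extend(start + np.arange(self.pulses_per_burst)
                         * 1000.0 / self.intra_burst_freq)
        return np.asarray(times)


@dataclass
class TraceSet:
    """Repeated-trial uniformly-sampled traces with protocol metadata."""

    time_ms: np.ndarray
    data: np.ndarray            # (n_trials, n_samples)
    modality: str               # 'voltage' or 'current'
    stim_times: np.ndarray
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.stim_times = np.asarray(self.stim_times, dtype=float)
        if self.data.size and self.data.shape[1] != self.time_ms.size:
            raise ValueError("trial length must match the time base")
        if self.time_ms.size >= 2:
            steps = np.diff(self.time_ms)
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time base must be uniform")
        if self.modality not in ("voltage", "current"):
            raise ValueError("modality must be 'voltage' or 'current'")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def dt(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0]) if self.time_ms.size > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        n_t, n_s = self.data.shape
        return pd.DataFrame({
            "trial": np.repeat(np.arange(n_t), n_s),
            "time_ms": np.tile(self.time_ms, n_t),
            "value": self.data.ravel(),
        })


@dataclass(frozen=True)
class CircuitConfig:
    n_mf: int = 2
    n_goc: int = 2
    n_release_sites: int = 6
    stochastic: bool = True
    plasticity: dict = field(default_factory=dict)  # 'mf_grc'/'goc_grc' -> mode
    seed: int = 0
    dt: float = 0.025
    synapse_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (1 <= self.n_mf <= 4):
            raise ValueError("n_mf must be 1..4")
        if not (0 <= self.n_goc <= 4):
            raise ValueError("n_goc must be 0..4")
        if self.n_release_sites < 1:
            raise ValueError("n_release_sites must be >= 1")


# ---------------------------------------------------------------------------
# Synapse machinery

@dataclass(frozen=True)
class SynapseSpec:
    """Everything needed to instantiate one synapse class."""

    release: ps.ReleaseParams
    receptor_names: tuple[str, ...]
    gmax: dict            # receptor name -> total gmax (pS) per synapse
    transmitter: rc.TransmitterParams = rc.TransmitterParams()


def default_synapse_specs(n_release_sites: int = 6) -> dict[str, SynapseSpec]:
    """The five synapse classes of the circuit with their parameter sets.

    AMPA/NMDA parameters of the PF/AA synapses are inherited from the
    mf-GrC synapse; AA conductances are ~2x the PF ones.
    """
    reg = rc.build_default_schemes()
    mf_grc = SynapseSpec(
        release=replace(ps.MF_GRC, n_sites=n_release_sites),
        receptor_names=("ampa", "nmda"),
        gmax={"ampa": 1200.0, "nmda": 18800.0},
    )
    mf_goc = SynapseSpec(
        release=ps.MF_GOC,
        receptor_names=("ampa", "nmda"),
        gmax=dict(calibrate_mf_goc_gmax()),
    )
    pf_goc = SynapseSpec(
        release=ps.PF_GOC,
        receptor_names=("ampa", "nmda", "kainate"),
        gmax={"ampa": 1200.0, "nmda": 18800.0, "kainate": reg["kainate"].gmax},
    )
    aa_goc = SynapseSpec(
        release=ps.AA_GOC,
        receptor_names=("ampa", "nmda"),
        gmax={"ampa": 2 * 1200.0, "nmda": 2 * 18800.0},
    )
    goc_grc = SynapseSpec(
        release=ps.GOC_GRC,
        receptor_names=("gabaa_fast", "gabaa_slow"),
        gmax={"gabaa_fast": reg["gabaa_fast"].gmax,
              "gabaa_slow": reg["gabaa_slow"].gmax},
    )
    return {"mf_grc": mf_grc, "mf_goc": mf_goc, "pf_goc": pf_goc,
            "aa_goc": aa_goc, "goc_grc": goc_grc}


class Synapse:
    """A multi-site synapse: presynaptic pool + receptor schemes on a target.

    Sites are independent; each carries 1/n_sites of every receptor's gmax.
    Deterministic mode releases P*X per site, stochastic mode releases the
    site's full resource with Bernoulli probability P.
    """

    def __init__(self, spec: SynapseSpec, target_comp: int, *,
                 stochastic: bool = False, rng: np.random.Generator | None = None,
                 schemes: dict[str, rc.KineticScheme] | None = None):
        self.spec = spec
        self.target_comp = target_comp
        self.stochastic = stochastic
        self.rng = rng if rng is not None else np.random.default_rng(0)
        registry = schemes if schemes is not None else rc.build_default_schemes()
        self.schemes = [replace(registry[n], gmax=spec.gmax[n])
                        for n in spec.receptor_names]
        self.n_sites = spec.release.n_sites
        self.pending: list[float] = []
        self.reset()

    def reset(self) -> None:
        n = self.n_sites
        self.X = np.ones(n)
        self.Y = np.zeros(n)
        self.Z = np.zeros(n)
        self.P = self.spec.release.p_init
        self.t_last = 0.0
        self.occ = [np.tile(_rest_occ(s), (n, 1)) for s in self.schemes]
        self.td = np.zeros(n)                      # diffusion-wave level (mM)
        self.pulses: list[list[tuple[float, float]]] = [[] for _ in range(n)]
        self.pending = []

    # -- presynaptic pool -------------------------------------------------
    def _evolve_pool(self, t: float) -> None:
        dt = t - self.t_last
        if dt <= 0:
            return
        p = self.spec.release
        ey = math.exp(-dt / p.tau_inact)
        er = math.exp(-dt / p.tau_rec)
        Y0 = self.Y.copy()
        self.Y = self.Y * ey
        if abs(p.tau_inact - p.tau_rec) < 1e-12:
            self.Z = (self.Z + Y0 * dt / p.tau_inact) * er
        else:
            c = Y0 * p.tau_rec / (p.tau_inact - p.tau_rec)
            self.Z = (self.Z - c) * er + c * ey
        self.X = 1.0 - self.Y - self.Z
        self.P = p.p_init + (self.P - p.p_init) * math.exp(-dt / p.tau_facil)
        self.t_last = t

    def deliver(self, t_event: float) -> None:
        """Schedule a presynaptic spike (already including any delay)."""
        self.pending.append(t_event)

    def _fire(self, t: float) -> None:
        self._evolve_pool(t)
        if self.stochastic:
            fired = self.rng.random(self.n_sites) < self.P
            rel = np.where(fired, self.X, 0.0)
        else:
            rel = self.P * self.X
        self.X = self.X - rel
        self.Y = self.Y + rel
        self.P = self.P + self.spec.release.p_init * (1.0 - self.P)
        tp = self.spec.transmitter
        for s in range(self.n_sites):
            if rel[s] > 0:
                self.td[s] += rel[s] * tp.Td_max
                self.pulses[s].append((t + tp.pulse_duration, rel[s] * tp.Ts_max))

    # -- per-step update --------------------------------------------------
    def step(self, t: float, dt: float, v_target: float):
        """Advance transmitter + schemes over [t, t+dt]; return (g_nS, E) list.

        Pending events at or before t fire first.  The returned conductances
        use end-of-step occupancies with the Mg block at the current target
        voltage.
        """
        while self.pending and self.pending[0] <= t + 1e-9:
            self._fire(self.pending.pop(0))
        tp = self.spec.transmitter
        ts_now = np.zeros(self.n_sites)
        for s in range(self.n_sites):
            if self.pulses[s]:
                self.pulses[s] = [pu for pu in self.pulses[s] if pu[0] > t]
                ts_now[s] = sum(a for _, a in self.pulses[s])
        out = []
        for scheme, occ in zip(self.schemes, self.occ):
            T = self.td if scheme.transmitter == "diffusion" else self.td + ts_now
            self._step_scheme_sites(scheme, occ, T, dt)
            o_frac = occ[:, _open_idx(scheme)].sum(axis=1)
            block = rc.mg_block(v_target) if scheme.mg_block else 1.0
            g = scheme.gmax / self.n_sites * 1e-3 * block * float(o_frac.sum())
            out.append((g, scheme.Vrev))
        self.td = self.td * math.exp(-dt / tp.diff_tau)
        return out

    @staticmethod
    def _step_scheme_sites(scheme: rc.KineticScheme, occ: np.ndarray,
                           T: np.ndarray, dt: float) -> None:
        """Vectorised RK4 master-equation step for all sites of one scheme."""
        idx = _scheme_cache(scheme)
        rates = []
        max_rate = 0.0
        for tr, (i_src, i_tgt) in zip(scheme.transitions, idx):
            if tr.drive == "linear":
                r = tr.rate * T
            elif tr.drive == "sat":
                r = tr.rate * (T / (T + scheme.kb)) ** 2
            else:
                r = np.full_like(T, tr.rate)
            rates.append((i_src, i_tgt, r))
            m = float(np.max(r))
            if m > max_rate:
                max_rate = m
        n_sub = max(1, int(math.ceil(dt * max_rate / 0.1)))
        h = dt / n_sub

        def rhs(x):
            dx = np.zeros_like(x)
            for i_src, i_tgt, r in rates:
                flux = r * x[:, i_src]
                dx[:, i_src] -= flux
                dx[:, i_tgt] += flux
            return dx

        x = occ
        for _ in range(n_sub):
            k1 = rhs(x)
            k2 = rhs(x + 0.5 * h * k1)
            k3 = rhs(x + 0.5 * h * k2)
            k4 = rhs(x + h * k3)
            x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        np.clip(x, 0.0, 1.0, out=x)
        x /= x.sum(axis=1, keepdims=True)
        occ[:] = x


def _rest_occ(scheme: rc.KineticScheme) -> np.ndarray:
    occ = np.zeros(scheme.n_states)
    occ[0] = 1.0
    return occ


_SCHEME_IDX: dict[tuple, list] = {}


def _scheme_cache(scheme: rc.KineticScheme):
    key = (scheme.state_names, scheme.transitions)
    if key not in _SCHEME_IDX:
        _SCHEME_IDX[key] = [(scheme.index(t.source), scheme.index(t.target))
                            for t in scheme.transitions]
    return _SCHEME_IDX[key]


_OPEN_IDX: dict[tuple, np.ndarray] = {}


def _open_idx(scheme: rc.KineticScheme) -> np.ndarray:
    key = (scheme.state_names, scheme.open_states)
    if key not in _OPEN_IDX:
        _OPEN_IDX[key] = scheme.open_indices()
    return _OPEN_IDX[key]


# ---------------------------------------------------------------------------
# mf-GoC calibration

_MF_GOC_CACHE: dict[str, float] | None = None


def calibrate_mf_goc_gmax(target_pA: float = -66.0) -> dict[str, float]:
    """AMPA/NMDA gmax of the mf-GoC synapse, scaled to a -66 pA peak EPSC.

    Starting from the mf-GrC conductances, one deterministic stimulus is
    delivered to a voltage-clamped (-70 mV) GoC and both gmax values are
    scaled linearly so the baseline-subtracted peak matches the target.
    Under ideal clamp the EPSC is linear in gmax, so one run suffices.
    """
    global _MF_GOC_CACHE
    if _MF_GOC_CACHE is not None and target_pA == -66.0:
        return dict(_MF_GOC_CACHE)
    out = {"ampa": 1200.0, "nmda": 18800.0}
    for _ in range(2):  # second pass removes any residual nonlinearity
        peak = mf_goc_epsc_peak(out)
        out = {k: v * target_pA / peak for k, v in out.items()}
    if target_pA == -66.0:
        _MF_GOC_CACHE = dict(out)
    return out


def mf_goc_epsc_peak(gmax: dict, v_hold: float = -70.0, dt: float = 0.025) -> float:
    """Peak clamp-current deflection for one mf stimulus onto a clamped GoC."""
    goc = nr.build_goc()
    solver = nr.CellSolver(goc, dt=dt)
    solver.V[:] = v_hold
    solver.reset_gates_to_steady_state()
    solver.set_clamp(goc.soma_index, v_hold)
    for _ in range(int(200.0 / dt)):  # settle unclamped compartments
        solver.step()
    spec = SynapseSpec(release=ps.MF_GOC, receptor_names=("ampa", "nmda"),
                       gmax=dict(gmax))
    syn = Synapse(spec, target_comp=goc.soma_index, stochastic=False)
    t_stim = 20.0
    syn.deliver(t_stim + TRANSMISSION_DELAY_MS)
    n_steps = int(80.0 / dt)
    current = np.empty(n_steps)
    t = 0.0
    for i in range(n_steps):
        contrib = syn.step(t, dt, solver.V[syn.target_comp])
        solver.step(syn=[(syn.target_comp, g, e) for g, e in contrib])
        current[i] = solver.clamp_current[goc.soma_index]
        t += dt
    baseline = current[: int(t_stim / dt)].mean()
    trace = current - baseline
    return float(trace[np.argmax(np.abs(trace))])


# ---------------------------------------------------------------------------
# The circuit

class Circuit:
    """Wired mf-GrC-GoC microcircuit ready to run protocols."""

    def __init__(self, config: CircuitConfig):
        self.config = config
        self.grc = nr.build_grc()
        self.gocs = [nr.build_goc() for _ in range(config.n_goc)]
        specs = default_synapse_specs(config.n_release_sites)
        for name, over in config.synapse_overrides.items():
            specs[name] = over
        for name, mode in config.plasticity.items():
            if name not in ("mf_grc", "goc_grc"):
                raise ValueError(
                    f"plasticity applies to mf_grc or goc_grc, not {name!r}")
            spec = specs[name]
            specs[name] = replace(
                spec, release=ps.apply_plasticity(
                    spec.release, ps.Plasticity(ps.PlasticityMode(mode)))
            )
        self.specs = specs
        self._registry = rc.build_default_schemes()
        self._grc_bias: float | None = None
        self._grc_rest: nr.CellSolver | None = None
        self._grc_rest_bias: float | None = None
        self._build_synapses()

    def _build_synapses(self) -> None:
        cfg = self.config
        rng_root = np.random.default_rng([cfg.seed, 0])
        self.mf_grc: list[Synapse] = []
        self.mf_goc: list[list[Synapse]] = [[] for _ in range(cfg.n_goc)]
        self.grc_goc: list[list[Synapse]] = [[] for _ in range(cfg.n_goc)]
        self.goc_grc: list[Synapse] = []
        tips = self._grc_tips()
        for m in range(cfg.n_mf):
            self.mf_grc.append(Synapse(
                self.specs["mf_grc"], target_comp=tips[m % 4],
                stochastic=cfg.stochastic,
                rng=np.random.default_rng(int(rng_root.integers(2**31))),
                schemes=self._registry))
        for g in range(cfg.n_goc):
            for m in range(cfg.n_mf):
                self.mf_goc[g].append(Synapse(
                    self.specs["mf_goc"], target_comp=self.gocs[g].soma_index,
                    stochastic=False, schemes=self._registry))
            for kind in ("pf_goc", "aa_goc"):
                self.grc_goc[g].append(Synapse(
                    self.specs[kind], target_comp=self.gocs[g].soma_index,
                    stochastic=False, schemes=self._registry))
            # inhibition assigned to GrC dendrites round-robin
            self.goc_grc.append(Synapse(
                self.specs["goc_grc"], target_comp=tips[g % 4],
                stochastic=False, schemes=self._registry))

    def _grc_tips(self) -> list[int]:
        return [i for i, c in enumerate(self.grc.compartments)
                if c.name.startswith("dend") and c.name.endswith("_3")]

    def reseed_trial(self, trial: int) -> None:
        """Reset all synapses; stochastic draws from a counter-based stream."""
        root = np.random.default_rng([self.config.seed, 1 + trial])
        for syn in self.mf_grc:
            syn.rng = np.random.default_rng(int(root.integers(2**31)))
            syn.reset()
        for g in range(self.config.n_goc):
            for syn in self.mf_goc[g] + self.grc_goc[g]:
                syn.reset()
        for syn in self.goc_grc:
            syn.reset()

    def grc_bias_current(self, v_target: float = -65.0) -> float:
        if self._grc_bias is None:
            self._grc_bias = nr.find_bias_current(self.grc, v_target)
        return self._grc_bias


def wire_circuit(config: CircuitConfig) -> Circuit:
    """Instantiate the circuit of ``config`` (validates ranges)."""
    return Circuit(config)


# ---------------------------------------------------------------------------
# Protocol runners

def _simulate(circuit: Circuit, t_total: float, stim_times: np.ndarray, *,
              clamp_mV: float | None = None, clamp_rs_MOhm: float | None = None,
              i_bias_pA: float = 0.0, trial: int = 0):
    """Core event loop: one trial of duration t_total with mf stimuli.

    ``clamp_rs_MOhm`` switches the ideal clamp to a series-resistance
    clamp: the electrode injects (V_cmd - V_soma)/Rs instead of pinning
    the somatic voltage.
    """
    cfg = circuit.config
    dt = cfg.dt
    circuit.reseed_trial(trial)
    grc = circuit.grc
    grc_solver = nr.CellSolver(grc, dt=dt)
    if clamp_mV is not None:
        grc_solver.V[:] = clamp_mV
        grc_solver.reset_gates_to_steady_state()
        if clamp_rs_MOhm is None:
            grc_solver.set_clamp(grc.soma_index, clamp_mV)
    else:
        if circuit._grc_rest is None or circuit._grc_rest_bias != i_bias_pA:
            circuit._grc_rest = nr.steady_state(grc, i_inj_soma=i_bias_pA)
            circuit._grc_rest_bias = i_bias_pA
        rest = circuit._grc_rest
        grc_solver.V = rest.V.copy()
        grc_solver.ca = dict(rest.ca)
        grc_solver.reset_gates_to_steady_state()
    goc_solvers = [nr.CellSolver(c, dt=dt) for c in circuit.gocs]

    for t_stim in stim_times:
        for syn in circuit.mf_grc:
            syn.deliver(t_stim + TRANSMISSION_DELAY_MS)
        for g in range(cfg.n_goc):
            for syn in circuit.mf_goc[g]:
                syn.deliver(t_stim + TRANSMISSION_DELAY_MS)

    n_steps = int(round(t_total / dt))
    out = np.empty(n_steps)
    time_ms = np.arange(n_steps) * dt
    grc_prev = grc_solver.V[grc.soma_index]
    goc_prev = [s.V[0] for s in goc_solvers]
    for i in range(n_steps):
        t = time_ms[i]
        grc_syn = []
        for syn in circuit.mf_grc:
            for g, e in syn.step(t, dt, grc_solver.V[syn.target_comp]):
                grc_syn.append((syn.target_comp, g, e))
        for syn in circuit.goc_grc:
            for g, e in syn.step(t, dt, grc_solver.V[syn.target_comp]):
                grc_syn.append((syn.target_comp, g, e))
        goc_syn = [[] for _ in range(cfg.n_goc)]
        for gidx in range(cfg.n_goc):
            for syn in circuit.mf_goc[gidx] + circuit.grc_goc[gidx]:
                for g, e in syn.step(t, dt, goc_solvers[gidx].V[syn.target_comp]):
                    goc_syn[gidx].append((syn.target_comp, g, e))
        if clamp_mV is None:
            inj = {grc.soma_index: i_bias_pA}
        elif clamp_rs_MOhm is not None:
            i_rs = (clamp_mV - grc_solver.V[grc.soma_index]) / (clamp_rs_MOhm * 1e-3)
            inj = {grc.soma_index: i_rs}
        else:
            inj = None
        grc_solver.step(syn=grc_syn, i_inj=inj)
        for gidx, s in enumerate(goc_solvers):
            s.step(syn=goc_syn[gidx])
        # spike detection -> delayed transmission
        v_grc = grc_solver.V[grc.soma_index]
        if grc_prev < SPIKE_THRESHOLD_MV <= v_grc:
            for gidx in range(cfg.n_goc):
                for syn in circuit.grc_goc[gidx]:
                    syn.deliver(t + TRANSMISSION_DELAY_MS)
        grc_prev = v_grc
        for gidx, s in enumerate(goc_solvers):
            v = s.V[0]
            if goc_prev[gidx] < SPIKE_THRESHOLD_MV <= v:
                circuit.goc_grc[gidx].deliver(t + TRANSMISSION_DELAY_MS)
            goc_prev[gidx] = v
        if clamp_mV is None:
            out[i] = v_grc
        elif clamp_rs_MOhm is not None:
            out[i] = inj[grc.soma_index]
        else:
            out[i] = grc_solver.clamp_current[grc.soma_index]
    return time_ms, out


def run_burst(circuit: Circuit, protocol: BurstProtocol, *,
              pre_ms: float = 20.0, post_ms: float = 50.0,
              v_hold: float = -65.0) -> TraceSet:
    """Current-clamp burst protocol recording the GrC somatic voltage.

    The holding potential is set through a constant somatic bias current
    solved so the isolated GrC rests at ``v_hold``; stochastic release is
    redrawn per trial from a counter-based seed stream.
    """
    bias = circuit.grc_bias_current(v_hold)
    stim = protocol.stimulus_times(pre_ms)
    t_total = stim[-1] + post_ms
    trials = []
    time_ms = None
    for k in range(protocol.n_trials):
        time_ms, v = _simulate(circuit, t_total, stim, i_bias_pA=bias, trial=k)
        trials.append(v)
    return TraceSet(
        time_ms=time_ms, data=np.array(trials), modality="voltage",
        stim_times=stim, seed=circuit.config.seed,
        meta={"protocol": "burst", "frequency": protocol.frequency,
              "n_mf": circuit.config.n_mf, "n_goc": circuit.config.n_goc,
              "bias_pA": bias, "plasticity": dict(circuit.config.plasticity)},
    )


def run_voltage_clamp(circuit: Circuit, v_hold: float, stim_times, *,
                      post_ms: float = 50.0, n_trials: int = 1,
                      rs_MOhm: float | None = None) -> TraceSet:
    """Somatic voltage clamp of the GrC; records the clamp current.

    Ideal clamp by default; pass ``rs_MOhm`` for a series-resistance clamp.
    """
    stim = np.asarray(stim_times, dtype=float)
    t_total = (stim[-1] if stim.size else 20.0) + post_ms
    trials = []
    time_ms = None
    for k in range(n_trials):
        time_ms, i = _simulate(circuit, t_total, stim, clamp_mV=v_hold,
                               clamp_rs_MOhm=rs_MOhm, trial=k)
        trials.append(i)
    return TraceSet(
        time_ms=time_ms, data=np.array(trials), modality="current",
        stim_times=stim, seed=circuit.config.seed,
        meta={"protocol": "voltage_clamp", "v_hold": v_hold,
              "n_mf": circuit.config.n_mf, "n_goc": circuit.config.n_goc},
    )


def run_tbs(circuit: Circuit, protocol: TBSProtocol = TBSProtocol(), *,
            pre_ms: float = 20.0, simulate: bool = False) -> dict:
    """Deliver the TBS schedule and return an event log.

    TBS is the induction protocol; in this artifact it does not itself
    change synaptic weights (plasticity expression is applied separately as
    a release-probability scaling), so by default only the stimulus
    schedule is generated and verified.  With ``simulate=True`` the GrC
    response is also recorded.
    """
    stim = protocol.stimulus_times(pre_ms)
    log = {
        "stim_times_ms": stim,
        "n_stimuli": int(stim.size),
        "burst_onsets_ms": stim[:: protocol.pulses_per_burst],
        "span_ms": float(stim[-1] - stim[0]),
    }
    if simulate:
        bias = circuit.grc_bias_current(-65.0)
        time_ms, v = _simulate(circuit, stim[-1] + 50.0, stim, i_bias_pA=bias)
        log["trace"] = TraceSet(time_ms=time_ms, data=v[None, :],
                                modality="voltage", stim_times=stim,
                                seed=circuit.config.seed,
                                meta={"protocol": "tbs"})
    return log
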