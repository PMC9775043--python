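"""Seeded generators of patch-clamp-like synthetic data.

These emulate the statistical structure the analysis pipelines assume —
capacitive clamp transients from an Rs-Rm-Cm circuit, double-exponential
EPSC trains with a set paired-pulse ratio, frequency-dependent burst
responses with sigmoidal spike-probability/depolarization profiles and
latency jitter, and noisy sigmoidal gain curves — so that every stage is
testable without recordings (analysis-of-synthesis closure).

Default parameter values are the experimental means of the study
conditions: EPSC 29.7 pA, EPSP 11.4 mV, PPR 0.78, passive parameters
Cm 2.4 pF / Rm 2.3 GOhm / Rs 17.5 MOhm, LTP/LTD amplitude effects
+28.5 % / -36.8 % with PPR shifts -27.4 % / +23.8 %, and cGI gain-curve
parameters A1 = 1.03, A2 = 2.69, fc = 43.2 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .microcircuit import TraceSet
from .presyn import PlasticityMode

__all__ = [
    "SynthConfig",
    "gen_vc_transient",
    "gen_epsc_train",
    "gen_burst_responses",
    "gen_gain_curve",
    "apply_plasticity_effect",
]

SAMPLING_KHZ = 20.0  # digitization rate of the emulated recordings


@dataclass(frozen=True)
class SigmoidProfile:
    """Frequency profile g(f) = (A1 - A2)/(1 + (f/fc)^p) + A2."""

    A1: float
    A2: float
    fc: float
    power: float = 4.0

    def __call__(self, f):
        f = np.asarray(f, dtype=float)
        return (self.A1 - self.A2) / (1.0 + (f / self.fc) ** self.power) + self.A2


@dataclass(frozen=True)
class SynthConfig:
    """Ground-truth parameters of the synthetic recordings."""

    seed: int = 0
    # noise (Gaussian white)
    noise_current_pA: float = 2.0
    noise_voltage_mV: float = 0.5
    # EPSC kinetics and amplitudes
    epsc_rise_ms: float = 0.3
    epsc_decay_ms: float = 3.0
    epsc_amplitude_pA: float = 29.7
    epsc_amplitude_sd_pA: float = 4.4
    epsp_amplitude_mV: float = 11.4
    ppr: float = 0.78
    # burst-response profiles, all sigmoidal in frequency: probability of
    # >= 1 spike per burst, maximum depolarization (mV) and first-spike
    # latency jitter SD (ms; precision improves with frequency)
    sp_profile: SigmoidProfile = SigmoidProfile(0.05, 0.9, 60.0, 4.0)
    amd_profile: SigmoidProfile = SigmoidProfile(4.0, 14.0, 60.0, 4.0)
    jitter_profile: SigmoidProfile = SigmoidProfile(1.5, 0.3, 60.0, 4.0)
    extra_spike_p: float = 0.5   # conditional P(spike) on pulses after the first
    latency_ms: float = 2.5
    v_rest_mV: float = -65.0
    # plasticity effect sizes (percent changes applied by LTP / LTD)
    ltp_epsc_pct: float = 28.5
    ltd_epsc_pct: float = -36.8
    ltp_epsp_pct: float = 31.2
    ltd_epsp_pct: float = -27.8
    ltp_ppr_pct: float = -27.4
    ltd_ppr_pct: float = 23.8
    ltp_fc_pct: float = -67.0
    ltd_fc_pct: float = 89.0
    ltp_gain_pct: float = 24.0
    ltd_gain_pct: float = -13.0


def _time_base(duration_ms: float) -> np.ndarray:
    n = int(round(duration_ms * SAMPLING_KHZ))
    return np.arange(n) / SAMPLING_KHZ


def gen_vc_transient(cm_pF: float = 2.4, rm_GOhm: float = 2.3,
                     rs_MOhm: float = 17.5, dV_mV: float = 10.0, *,
                     noise_frac: float = 0.02, duration_ms: float = 5.0,
                     seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Voltage-clamp step transient of the two-resistor RC pipette circuit.

    I(t) = (dV/Rs) exp(-t/tau) + dV/(Rs + Rm),  tau = Cm Rs Rm/(Rs + Rm),
    sampled at 20 kHz with Gaussian noise of SD ``noise_frac`` times the
    peak.  Returns (time_ms, current_pA).
    """
    if min(cm_pF, rm_GOhm, rs_MOhm) <= 0:
        raise ValueError("passive parameters must be positive")
    rs_GOhm = rs_MOhm * 1e-3
    tau_ms = cm_pF * rs_GOhm * rm_GOhm / (rs_GOhm + rm_GOhm)  # pF*GOhm = ms
    t = _time_base(duration_ms)
    i_peak = dV_mV / rs_GOhm                    # mV/GOhm = pA
    i_ss = dV_mV / (rs_GOhm + rm_GOhm)
    i = (i_peak - i_ss) * np.exp(-t / tau_ms) + i_ss
    rng = np.random.default_rng(seed)
    # proportional (multiplicative) amplitude noise
    i = i * (1.0 + rng.normal(0.0, noise_frac, size=t.size))
    return t, i


def _epsc_kernel(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Unit-peak double-exponential: decay minus rise, peak-normalized."""
    tp = rise * decay / (decay - rise) * np.log(decay / rise)
    norm = np.exp(-tp / decay) - np.exp(-tp / rise)
    k = np.where(t >= 0, np.exp(-np.clip(t, 0, None) / decay)
                 - np.exp(-np.clip(t, 0, None) / rise), 0.0)
    return k / norm


def gen_epsc_train(stim_times, amplitude_pA: float, ppr_profile=None, *,
                   rise_ms: float = 0.3, decay_ms: float = 3.0,
                   noise_sd_pA: float = 2.0, duration_ms: float | None = None,
                   seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Sum of inward double-exponential EPSCs at the stimulus times.

    ``ppr_profile`` scales the per-stimulus amplitude (e.g. [1, 0.78] for a
    paired pulse with PPR 0.78).  Returns (time_ms, current_pA); EPSCs are
    negative (inward) deflections on a zero baseline.
    """
    stim = np.asarray(stim_times, dtype=float)
    if stim.size and np.any(np.diff(stim) <= 0):
        raise ValueError("stim_times must be sorted strictly increasing")
    scale = (np.ones(stim.size) if ppr_profile is None
             else np.asarray(ppr_profile, dtype=float))
    if scale.size != stim.size:
        raise ValueError("ppr_profile must match stim_times")
    if duration_ms is None:
        duration_ms = (stim[-1] if stim.size else 0.0) + 10 * decay_ms
    t = _time_base(duration_ms)
    i = np.zeros_like(t)
    for ts, s in zip(stim, scale):
        i -= amplitude_pA * s * _epsc_kernel(t - ts, rise_ms, decay_ms)
    rng = np.random.default_rng(seed)
    return t, i + rng.normal(0.0, noise_sd_pA, size=t.size)


def _spike_waveform(t: np.ndarray, t_spike: float, v_base: float,
                    peak_mV: float = 30.0, width_ms: float = 1.0) -> np.ndarray:
    """Stereotyped triangular spike; only threshold crossings matter."""
    half = width_ms / 2.0
    d = np.abs(t - t_spike)
    return np.where(d < half, (peak_mV - v_base) * (1.0 - d / half), 0.0)


def gen_burst_responses(frequency: float, config: SynthConfig, *,
                        n_pulses: int = 5, n_trials: int = 10,
                        pre_ms: float = 20.0, post_ms: float = 50.0,
                        seed: int | None = None) -> TraceSet:
    """Voltage responses to a five-pulse burst at one frequency.

    Each trial is an EPSP staircase whose peak depolarization follows the
    config's amd profile.  A trial spikes with the burst-level probability
    of the sp profile; a spiking trial fires on the first pulse (latency
    with the frequency-dependent Gaussian jitter of the jitter profile)
    and on each later pulse with a fixed conditional probability, so spike
    count, spike probability, precision and depolarization all share the
    profiles' frequency dependence.
    """
    if frequency <= 0:
        raise ValueError("frequency must be > 0")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    stim = pre_ms + np.arange(n_pulses) * 1000.0 / frequency
    t = _time_base(stim[-1] + post_ms)
    sp_burst = float(np.clip(config.sp_profile(frequency), 0.0, 1.0))
    # constant conditional probability on later pulses keeps the expected
    # spike count proportional to the sp profile: sc = sp*(1 + (n-1)*r)
    r = config.extra_spike_p
    jitter = max(float(config.jitter_profile(frequency)), 0.0)
    amd = float(config.amd_profile(frequency))
    # EPSP staircase: unit events whose summated peak is scaled to amd
    rise, decay = 1.0, 12.0
    stack = np.zeros_like(t)
    for ts in stim:
        stack += _epsc_kernel(t - ts, rise, decay)
    peak = stack.max()
    trials = np.empty((n_trials, t.size))
    for k in range(n_trials):
        v = config.v_rest_mV + amd / peak * stack
        if rng.random() < sp_burst:
            # first spike on the first pulse carries the latency jitter
            t_sp = stim[0] + config.latency_ms + rng.normal(0.0, jitter)
            v = v + _spike_waveform(t, t_sp, config.v_rest_mV)
            for ts in stim[1:]:
                if rng.random() < r:
                    v = v + _spike_waveform(t, ts + config.latency_ms,
                                            config.v_rest_mV)
        trials[k] = v + rng.normal(0.0, config.noise_voltage_mV, size=t.size)
    return TraceSet(time_ms=t, data=trials, modality="voltage",
                    stim_times=stim, seed=seed,
                    meta={"frequency": frequency, "generator": "gen_burst_responses",
                          "sp_burst": sp_burst, "conditional_pulse_p": r,
                          "amd_mV": amd, "jitter_sd_ms": jitter})


def gen_gain_curve(A1: float, A2: float, fc: float, power: float, freqs, *,
                   noise_sd: float = 0.1, n_reps: int = 1,
                   seed: int | None = None) -> np.ndarray:
    """Noisy replicates of the sigmoidal gain curve; shape (n_reps, n_freqs)."""
    if fc <= 0 or power <= 0:
        raise ValueError("fc and power must be > 0")
    prof = SigmoidProfile(A1, A2, fc, power)
    g = prof(np.asarray(freqs, dtype=float))
    rng = np.random.default_rng(seed)
    return g[None, :] + rng.normal(0.0, noise_sd, size=(n_reps, g.size))


def apply_plasticity_effect(config: SynthConfig,
                            mode: PlasticityMode | str) -> SynthConfig:
    """Return a config with the long-term plasticity effect sizes applied.

    LTP scales EPSC/EPSP amplitudes up and PPR down (and conversely for
    LTD) by the configured percent effects, and shifts the gain profiles
    (cutoff down, amplitudes up for LTP; converse for LTD).
    """
    mode = PlasticityMode(mode)
    if mode is PlasticityMode.CONTROL:
        return config
    if mode is PlasticityMode.LTP:
        d_epsc, d_epsp = config.ltp_epsc_pct, config.ltp_epsp_pct
        d_ppr, d_fc, d_gain = config.ltp_ppr_pct, config.ltp_fc_pct, config.ltp_gain_pct
    else:
        d_epsc, d_epsp = config.ltd_epsc_pct, config.ltd_epsp_pct
        d_ppr, d_fc, d_gain = config.ltd_ppr_pct, config.ltd_fc_pct, config.ltd_gain_pct

    def pct(x, d):
        return x * (1.0 + d / 100.0)

    return replace(
        config,
        epsc_amplitude_pA=pct(config.epsc_amplitude_pA, d_epsc),
        epsp_amplitude_mV=pct(config.epsp_amplitude_mV, d_epsp),
        ppr=pct(config.ppr, d_ppr),
        sp_profile=replace(config.sp_profile,
                           fc=pct(config.sp_profile.fc, d_fc),
                           A2=pct(config.sp_profile.A2, d_gain)),
        amd_profile=replace(config.amd_profile,
                            fc=pct(config.amd_profile.fc, d_fc),
                            A1=pct(config.amd_profile.A1, d_gain),
                            A2=pct(config.amd_profile.A2, d_gain)),
    )
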