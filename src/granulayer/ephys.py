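"""Patch-clamp trace analysis: passive parameters, EPSCs, PPR, plasticity.

Voltage-clamp capacitive transients evoked by a voltage step dV from a
holding potential are fitted with a monoexponential,

    I(t) = I_ss + (I_peak - I_ss) * exp(-t / tau),

from which the series resistance Rs = dV/I_peak, membrane resistance
Rm = dV/I_ss - Rs and capacitance Cm = tau * (Rs + Rm)/(Rs * Rm) follow.

EPSC amplitudes are baseline-subtracted extrema in a post-stimulus window;
the paired-pulse ratio is second/first peak (depression < 1); long-term
plasticity is quantified as the percent change of the mean amplitude and
classified LTP/LTD with a small dead band.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "PassiveParams",
    "PlasticityOutcome",
    "PlasticityClass",
    "fit_passive",
    "epsc_peaks",
    "ppr",
    "percent_change",
    "classify_plasticity",
]


@dataclass(frozen=True)
class PassiveParams:
    """Whole-cell passive parameters from a clamp-step transient."""

    Cm_pF: float
    Rm_GOhm: float
    Rs_MOhm: float
    tau_us: float
    fit_residual: float

    def __post_init__(self) -> None:
        if min(self.Cm_pF, self.Rm_GOhm, self.Rs_MOhm) < 0:
            raise ValueError("passive parameters must be non-negative")


class PlasticityClass(str, enum.Enum):
    LTP = "LTP"
    LTD = "LTD"
    NONE = "NONE"


@dataclass(frozen=True)
class PlasticityOutcome:
    epsc_change_pct: float
    epsc_change_sem: float
    ppr_pre: float | None = None
    ppr_post: float | None = None
    epsp_change_pct: float | None = None


def fit_passive(time_ms: np.ndarray, current_pA: np.ndarray, dV_mV: float) -> PassiveParams:
    """Fit a monoexponential to a clamp-step current transient.

    ``time_ms`` starts at the step onset.  Currents in pA, dV in mV, so
    resistances come out in GOhm (dV/I); they are reported in the units the
    quantities are conventionally quoted in (Rs MOhm, Rm GOhm, tau us).
    """
    if dV_mV == 0:
        raise ValueError("dV must be nonzero")
    t = np.asarray(time_ms, dtype=float)
    i = np.asarray(current_pA, dtype=float)
    if t.size != i.size or t.size < 5:
        raise ValueError("need matching time/current arrays with >= 5 samples")
    i_ss0 = float(np.mean(i[int(0.8 * i.size):]))
    i_pk0 = float(i[np.argmax(np.abs(i - i_ss0))])
    amp0 = i_pk0 - i_ss0
    if abs(amp0) < 1e-12 * max(abs(i_ss0), 1.0):
        warnings.warn("no transient detected (pure resistor); Cm ~ 0", stacklevel=2)
        rs = dV_mV / i_ss0 * 1e3  # GOhm -> MOhm
        return PassiveParams(0.0, 0.0, rs, 0.0, 0.0)
    # tau guess from the 1/e crossing of the decay
    dec = np.abs(i - i_ss0) < abs(amp0) / np.e
    tau0 = float(t[np.argmax(dec)]) if dec.any() else float(t[-1] / 5.0)
    tau0 = max(tau0, float(t[1] - t[0]))

    def model(tt, i_ss, amp, tau):
        return i_ss + amp * np.exp(-tt / tau)

    try:
        popt, _ = curve_fit(model, t, i, p0=[i_ss0, amp0, tau0], maxfev=10000)
    except RuntimeError as err:
        resid = float(np.sqrt(np.mean((i - model(t, i_ss0, amp0, tau0)) ** 2)))
        raise RuntimeError(f"passive fit did not converge (rms residual {resid:.3g} pA)") from err
    i_ss, amp, tau = popt
    i_peak = i_ss + amp  # extrapolated to step onset
    resid = float(np.sqrt(np.mean((i - model(t, *popt)) ** 2)))
    rs_GOhm = dV_mV / i_peak           # mV/pA = GOhm
    rm_GOhm = dV_mV / i_ss - rs_GOhm
    cm_pF = tau * (rs_GOhm + rm_GOhm) / (rs_GOhm * rm_GOhm)  # ms/GOhm = pF
    return PassiveParams(
        Cm_pF=float(cm_pF),
        Rm_GOhm=float(rm_GOhm),
        Rs_MOhm=float(rs_GOhm * 1e3),
        tau_us=float(tau * 1e3),
        fit_residual=resid,
    )


def epsc_peaks(time_ms, current_pA, stim_times, *, window_ms: float = 10.0,
               baseline_ms: float = 5.0, smooth_ms: float = 0.3,
               signed: bool = False) -> np.ndarray:
    """Baseline-subtracted EPSC amplitude after each stimulus.

    Baseline is the mean over the ``baseline_ms`` preceding each stimulus;
    the amplitude is the largest absolute deflection of the lightly
    boxcar-smoothed trace (``smooth_ms``, suppresses the upward bias of a
    raw max over noise) within ``window_ms`` after the stimulus, reported
    as a magnitude unless ``signed``.
    """
    t = np.asarray(time_ms, dtype=float)
    i = np.asarray(current_pA, dtype=float)
    if smooth_ms > 0 and t.size > 2:
        dt = t[1] - t[0]
        w = max(1, int(round(smooth_ms / dt)))
        if w > 1:
            kernel = np.ones(w) / w
            i = np.convolve(i, kernel, mode="same")
    stim = np.asarray(stim_times, dtype=float)
    if stim.size == 0:
        return np.zeros(0)
    if np.any(stim < t[0]) or np.any(stim > t[-1]):
        raise ValueError("stimulus times fall outside the trace")
    if stim.size > 1 and np.any(np.diff(stim) < window_ms):
        raise ValueError("peak windows overlap; reduce window_ms")
    out = np.empty(stim.size)
    for k, ts in enumerate(stim):
        base_mask = (t >= ts - baseline_ms) & (t < ts)
        base = float(i[base_mask].mean()) if base_mask.any() else 0.0
        win = (t >= ts) & (t <= ts + window_ms)
        seg = i[win] - base
        pk = seg[np.argmax(np.abs(seg))] if seg.size else 0.0
        out[k] = pk if signed else abs(pk)
    return out


def ppr(time_ms, current_pA, stim_times, **kwargs) -> float:
    """Paired-pulse ratio: second / first EPSC peak (20 ms pairs; < 1 means
    depression)."""
    stim = np.asarray(stim_times, dtype=float)
    if stim.size != 2:
        raise ValueError("PPR requires exactly two stimuli")
    peaks = epsc_peaks(time_ms, current_pA, stim, **kwargs)
    if peaks[0] == 0:
        raise ValueError("first EPSC peak is zero; PPR undefined")
    return float(peaks[1] / peaks[0])


def percent_change(pre, post) -> tuple[float, float]:
    """Percent change of the mean response, with the SEM of per-trace changes.

    Returns (100*(mean_post - mean_pre)/mean_pre, SEM).  The SEM propagates
    the trial-to-trial variability of both epochs through the ratio.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size == 0 or post.size == 0:
        raise ValueError("pre and post must be non-empty")
    m_pre = pre.mean()
    if m_pre == 0:
        raise ValueError("pre mean is zero; percent change undefined")
    change = 100.0 * (post.mean() - m_pre) / m_pre
    # delta-method SEM of the ratio of means
    se_pre = pre.std(ddof=1) / np.sqrt(pre.size) if pre.size > 1 else 0.0
    se_post = post.std(ddof=1) / np.sqrt(post.size) if post.size > 1 else 0.0
    sem = 100.0 * np.hypot(se_post / abs(m_pre),
                           post.mean() * se_pre / m_pre**2)
    return float(change), float(sem)


def classify_plasticity(outcome: PlasticityOutcome,
                        dead_band_pct: float = 5.0) -> PlasticityClass:
    """LTP if the EPSC grew beyond the dead band, LTD if it shrank, else NONE."""
    if outcome.epsc_change_pct > dead_band_pct:
        return PlasticityClass.LTP
    if outcome.epsc_change_pct < -dead_band_pct:
        return PlasticityClass.LTD
    return PlasticityClass.NONE
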