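"""Gain-function analysis of burst transmission.

For each stimulation frequency four metrics are measured over repeated
trials: mean spike count (sc), probability of emitting at least one spike
in the burst (sp), standard deviation of the first-spike latency (fssd) and
average maximum depolarization relative to the pre-stimulus baseline (amd).
Each metric is min-max normalized to [0, 1] across the cell's frequencies
(fssd inverted, so 1 means maximal precision) and the four are summed into
a compound gain index cGI in [0, 4].

Gain curves g(f) are fitted with the sigmoid

    g(f) = (A1 - A2) / (1 + (f/fc)^p) + A2

where A1 and A2 are the low- and high-frequency asymptotes, fc the cutoff
frequency and p the power; g(fc) = (A1+A2)/2.  Plasticity is summarized by
the change in fc, in the maximum gain max(A1, A2) and in the relative gain
(Gmax - Gmin)/Gmin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .microcircuit import TraceSet

__all__ = [
    "BurstMetrics",
    "GainCurve",
    "SigmoidFit",
    "detect_spikes",
    "burst_metrics",
    "normalize_and_compound",
    "sigmoid",
    "fit_gain_sigmoid",
    "gain_summary",
    "cutoff_histogram",
]

DEFAULT_THRESHOLD_MV = -20.0
DEFAULT_FC_BINS = (0.0, 20.0, 50.0, 100.0, 200.0, 500.0)


@dataclass(frozen=True)
class BurstMetrics:
    """Per-frequency burst response metrics over trials."""

    frequency: float
    sc: float                    # mean spike count per trial
    sp: float                    # P(>= 1 spike in the burst)
    fssd: float | None           # SD of first-spike latency (ms); None if < 2 spiking trials
    amd: float                   # mean max depolarization above baseline (mV)
    n_trials: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.sp <= 1.0):
            raise ValueError("sp must be a probability")
        if self.sc < 0 or (self.fssd is not None and self.fssd < 0):
            raise ValueError("sc and fssd must be non-negative")


@dataclass(frozen=True)
class GainCurve:
    frequencies: np.ndarray
    gains: np.ndarray
    kind: str = "cGI"            # 'cGI' (range 0-4) or 'amd' (range 0-1)
    cell_id: str = ""

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        g = np.asarray(self.gains, dtype=float)
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "gains", g)
        if f.size != g.size:
            raise ValueError("frequencies and gains must match")
        if f.size >= 2 and np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")


@dataclass(frozen=True)
class SigmoidFit:
    A1: float
    A2: float
    fc: float
    power: float
    chi2_p: float = float("nan")
    residual: float = float("nan")

    def __post_init__(self) -> None:
        if self.fc <= 0 or self.power <= 0:
            raise ValueError("fc and power must be > 0")

    def __call__(self, f):
        return sigmoid(f, self.A1, self.A2, self.fc, self.power)


def detect_spikes(time_ms, voltage_mV, threshold: float = DEFAULT_THRESHOLD_MV,
                  refractory_ms: float = 1.0) -> np.ndarray:
    """Upward threshold crossings with refractory de-duplication."""
    t = np.asarray(time_ms, dtype=float)
    v = np.asarray(voltage_mV, dtype=float)
    idx = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold)) + 1
    times = []
    for i in idx:
        if not times or t[i] - times[-1] >= refractory_ms:
            times.append(float(t[i]))
    return np.asarray(times)


def burst_metrics(traces: TraceSet, window: tuple[float, float] | None = None,
                  threshold: float = DEFAULT_THRESHOLD_MV,
                  frequency: float | None = None) -> BurstMetrics:
    """Measure sc, sp, fssd and amd for one frequency's TraceSet.

    ``window`` defaults to [first stimulus, last stimulus + 50 ms].  amd is
    the trial-mean of (max V in window - pre-stimulus baseline); fssd uses
    the n-1 SD over spiking trials and is None with fewer than two.
    """
    if traces.n_trials < 2:
        raise ValueError("burst metrics need >= 2 trials")
    if window is None:
        window = (float(traces.stim_times[0]), float(traces.stim_times[-1]) + 50.0)
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty analysis window")
    t = traces.time_ms
    mask = (t >= lo) & (t <= hi)
    if not mask.any():
        raise ValueError("analysis window contains no samples")
    pre_mask = t < lo
    counts, first_lat, depols = [], [], []
    for trial in traces.data:
        spikes = detect_spikes(t[mask], trial[mask], threshold)
        counts.append(len(spikes))
        if len(spikes):
            first_lat.append(spikes[0] - lo)
        base = float(trial[pre_mask].mean()) if pre_mask.any() else float(trial[0])
        depols.append(float(trial[mask].max()) - base)
    fssd = float(np.std(first_lat, ddof=1)) if len(first_lat) >= 2 else None
    return BurstMetrics(
        frequency=float(frequency if frequency is not None
                        else traces.meta.get("frequency", 0.0)),
        sc=float(np.mean(counts)),
        sp=float(np.mean([c >= 1 for c in counts])),
        fssd=fssd,
        amd=float(np.mean(depols)),
        n_trials=traces.n_trials,
    )


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = np.min(values), np.max(values)
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def normalize_and_compound(metrics: list[BurstMetrics], cell_id: str = "") -> GainCurve:
    """Per-cell min-max normalization and summation into the cGI curve.

    fssd is inverted (1 = most precise); frequencies where fssd is
    undefined (too few spiking trials) count as worst (0).  A metric that
    is constant across frequencies contributes 0 everywhere.
    """
    if len(metrics) < 3:
        raise ValueError("need >= 3 frequencies to normalize a gain curve")
    ms = sorted(metrics, key=lambda m: m.frequency)
    f = np.array([m.frequency for m in ms])
    sc = _minmax(np.array([m.sc for m in ms]))
    sp = _minmax(np.array([m.sp for m in ms]))
    amd = _minmax(np.array([m.amd for m in ms]))
    raw_fssd = np.array([m.fssd if m.fssd is not None else np.nan for m in ms])
    if np.isnan(raw_fssd).all():
        prec = np.zeros_like(raw_fssd)
    else:
        finite = ~np.isnan(raw_fssd)
        prec = np.zeros_like(raw_fssd)
        vals = raw_fssd[finite]
        if vals.max() > vals.min():
            prec[finite] = 1.0 - (vals - vals.min()) / (vals.max() - vals.min())
        # undefined fssd stays at 0 (worst precision)
    cgi = sc + sp + amd + prec
    return GainCurve(frequencies=f, gains=cgi, kind="cGI", cell_id=cell_id)


def sigmoid(f, A1, A2, fc, p):
    """g(f) = (A1 - A2)/(1 + (f/fc)^p) + A2."""
    f = np.asarray(f, dtype=float)
    return (A1 - A2) / (1.0 + (f / fc) ** p) + A2


_FC_GRID = (10.0, 30.0, 50.0, 100.0, 200.0)


def fit_gain_sigmoid(curve: GainCurve, sigma: np.ndarray | float | None = None,
                     power_bounds: tuple[float, float] = (0.5, 20.0)) -> SigmoidFit:
    """Least-squares sigmoid fit with a multi-start over the fc grid."""
    f = curve.frequencies
    g = curve.gains
    if f.size < 4:
        raise ValueError("need >= 4 points to fit the sigmoid")
    lo = np.array([-np.inf, -np.inf, 1e-3, power_bounds[0]])
    hi = np.array([np.inf, np.inf, 10.0 * f.max(), power_bounds[1]])
    best = None
    for fc0 in _FC_GRID:
        p0 = [float(g[0]), float(g[-1]), fc0, 4.0]
        try:
            popt, _ = curve_fit(sigmoid, f, g, p0=p0, bounds=(lo, hi), maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        resid = float(np.sum((g - sigmoid(f, *popt)) ** 2))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        raise RuntimeError("sigmoid fit failed from every start")
    popt, ss = best
    dof = max(f.size - 4, 1)
    if sigma is not None:
        chi2 = float(np.sum(((g - sigmoid(f, *popt)) / sigma) ** 2))
        chi2_p = float(stats.chi2.sf(chi2, dof))
    else:
        chi2_p = float("nan")
    return SigmoidFit(A1=float(popt[0]), A2=float(popt[1]), fc=float(popt[2]),
                      power=float(popt[3]), chi2_p=chi2_p, residual=ss)


def gain_summary(fit_pre: SigmoidFit, fit_post: SigmoidFit) -> dict:
    """Plasticity-induced changes in cutoff, maximum gain and relative gain.

    Relative gain is (Gmax - Gmin)/Gmin with Gmax = max(A1, A2); it is
    undefined (None) when Gmin <= 0.
    """
    def gmax(f):
        return max(f.A1, f.A2)

    def rel(f):
        gmin = min(f.A1, f.A2)
        return (gmax(f) - gmin) / gmin if gmin > 0 else None

    out = {
        "fc_pre": fit_pre.fc,
        "fc_post": fit_post.fc,
        "delta_fc_pct": 100.0 * (fit_post.fc - fit_pre.fc) / fit_pre.fc,
        "max_gain_pre": gmax(fit_pre),
        "max_gain_post": gmax(fit_post),
        "delta_max_gain_pct": 100.0 * (gmax(fit_post) - gmax(fit_pre)) / gmax(fit_pre),
        "relative_gain_pre": rel(fit_pre),
        "relative_gain_post": rel(fit_post),
    }
    if out["relative_gain_pre"] not in (None, 0) and out["relative_gain_post"] is not None:
        out["delta_relative_gain_pct"] = 100.0 * (
            out["relative_gain_post"] - out["relative_gain_pre"]
        ) / out["relative_gain_pre"]
    else:
        out["delta_relative_gain_pct"] = None
    return out


def plot_gain_curves(curves: list[GainCurve], fits: list[SigmoidFit] | None = None,
                     ax=None, labels: list[str] | None = None):
    """Plot gain curves (points) with their sigmoid fits (lines), log-f axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for k, curve in enumerate(curves):
        label = labels[k] if labels else (curve.cell_id or None)
        pts = ax.semilogx(curve.frequencies, curve.gains, "o", label=label)
        if fits is not None:
            f = np.geomspace(curve.frequencies[0], curve.frequencies[-1], 200)
            ax.semilogx(f, fits[k](f), "-", color=pts[0].get_color())
    ax.set_xlabel("burst frequency (Hz)")
    ax.set_ylabel("gain")
    if labels or any(c.cell_id for c in curves):
        ax.legend()
    return ax


def cutoff_histogram(fits: list[SigmoidFit],
                     bin_edges=DEFAULT_FC_BINS) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of cutoff frequencies over left-closed bins.

    Returns (counts, edges); a value on an edge goes to the right bin.
    """
    if not fits:
        raise ValueError("need at least one fit")
    edges = np.asarray(bin_edges, dtype=float)
    fcs = np.array([f.fc for f in fits])
    counts, _ = np.histogram(fcs, bins=edges)
    # np.histogram closes the last bin on the right; keep it half-open
    counts[-1] = np.sum((fcs >= edges[-2]) & (fcs < edges[-1]))
    return counts, edges
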