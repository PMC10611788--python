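"""Magnetic-tweezers bead-trace analysis for topoisomerase II activity.

Traces are uniform time series (40 fps) of bead extension, magnet turns and
force.  During an extension clamp, magnet rotation counteracts enzyme
activity, so the (sign-reversed, filtered) magnet-turn rate reads out the
topo II relaxation rate at constant topology.  Activity records end at the
first long pause (> 30 s below a rate floor); survival ("active fraction")
curves over time or cumulative turns are fit to exponentials to estimate the
activity lifetime and processivity.  Repeated-winding experiments are
analyzed by reconstructing the pre-buckled supercoiling state from the
extension right after each rewinding step and the extension-supercoiling
calibration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "BeadTrace",
    "RateSeries",
    "ActivityRecord",
    "SurvivalCurve",
    "ExpFit",
    "sliding_filter",
    "clamp_rate",
    "detect_activity",
    "survival_and_fit",
    "exponential_mle",
    "rewind_reconstruction",
    "prebuckled_state_after_rewind",
    "buckled_rate_linear",
    "buckling_crossing_index",
    "direct_prebuckled_timecourse",
    "poisson_window_probability",
    "write_trace",
    "read_trace",
]

FRAME_RATE = 40.0  # Hz


@dataclass
class BeadTrace:
    """One bead-tracking trace on a uniform 40 fps time grid."""

    time: np.ndarray  # s
    extension: np.ndarray  # nm
    magnet_turns: np.ndarray  # turns
    force: float  # pN
    annotations: list = field(default_factory=list)  # protocol events (dicts)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        self.magnet_turns = np.asarray(self.magnet_turns, dtype=float)
        dt = np.diff(self.time)
        if np.any(dt <= 0) or (dt.size and np.ptp(dt) > 1e-6):
            raise ValueError("time must be strictly increasing and uniform")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0]) if self.time.size > 1 else 1.0 / FRAME_RATE

    def events(self, kind: str):
        return [a for a in self.annotations if a.get("kind") == kind]


@dataclass
class RateSeries:
    time: np.ndarray  # s
    rate: np.ndarray  # turns/s


@dataclass
class ActivityRecord:
    """Activity of one trace up to its first long pause."""

    active_duration: float  # s
    turns_relaxed: float  # turns while active
    first_pause_time: Optional[float]  # s, None if censored
    censored: bool


@dataclass
class SurvivalCurve:
    abscissa: np.ndarray  # min (time) or turns
    active_fraction: np.ndarray
    se: np.ndarray  # standard error of the proportion
    n: int
    kind: str = "time"


@dataclass
class ExpFit:
    mean: float  # min (lifetime) or turns (processivity)
    uncertainty: float
    lower_bound: bool = False
    censoring_aware: bool = False


def sliding_filter(series, window_s: float, dt: float = 1.0 / FRAME_RATE):
    """Centered moving average; the window shrinks symmetrically at the edges.

    Keeping the window symmetric (rather than truncating one side) preserves
    linear trends exactly everywhere, so filtered ramps keep their slope and
    endpoint values.
    """
    if window_s < dt:
        raise ValueError("window must be at least one sample interval")
    x = np.asarray(series, dtype=float)
    n = x.size
    h = max(int(round(window_s / dt)) // 2, 0)
    idx = np.arange(n)
    half = np.minimum(np.minimum(idx, n - 1 - idx), h)
    c = np.concatenate([[0.0], np.cumsum(x)])
    lo = idx - half
    hi = idx + half
    return (c[hi + 1] - c[lo]) / (hi - lo + 1)


def clamp_rate(trace: BeadTrace, window_s: float = 20.0) -> RateSeries:
    """Topo relaxation rate (turns/s) during the extension clamp.

    The magnet rotation mirrors enzyme activity, so the relaxation rate is
    minus the time derivative of the magnet turns, filtered by ``window_s``.
    """
    ons = trace.events("clamp_on")
    if not ons:
        raise ValueError("trace has no clamp_on annotation: not a clamp trace")
    t_on = ons[0]["time"]
    offs = trace.events("clamp_off")
    t_off = offs[0]["time"] if offs else trace.time[-1]
    sel = (trace.time >= t_on) & (trace.time <= t_off)
    if sel.sum() < 3:
        raise ValueError("clamp segment too short")
    t = trace.time[sel]
    turns = sliding_filter(trace.magnet_turns[sel], window_s, trace.dt)
    rate = -np.gradient(turns, t)
    return RateSeries(time=t, rate=rate)


def detect_activity(
    rates: RateSeries, pause_threshold_s: float = 30.0, rate_floor: float = 0.5
) -> ActivityRecord:
    """End the activity record at the first pause (> threshold below floor)."""
    t = rates.time
    low = np.abs(rates.rate) < rate_floor
    dt = float(t[1] - t[0]) if t.size > 1 else 0.0
    first_pause = None
    end = low.size
    i = 0
    n = low.size
    while i < n:
        if low[i]:
            j = i
            while j < n and low[j]:
                j += 1
            if (j - i) * dt > pause_threshold_s:
                first_pause = float(t[i] - t[0])
                end = i
                break
            i = j
        else:
            i += 1
    if first_pause is None:
        dur = float(t[-1] - t[0])
        censored = True
    else:
        dur = first_pause
        censored = False
    end = max(end, 2)
    # signed integral (then magnitude): measurement noise averages out instead
    # of rectifying into spurious turns
    turns = float(abs(np.trapezoid(rates.rate[:end], t[:end])))
    return ActivityRecord(
        active_duration=dur,
        turns_relaxed=turns,
        first_pause_time=first_pause,
        censored=censored,
    )


def _durations(records: Sequence[ActivityRecord], abscissa: str):
    if abscissa == "time":
        return np.array([r.active_duration / 60.0 for r in records])  # min
    if abscissa == "turns":
        return np.array([r.turns_relaxed for r in records])
    raise ValueError("abscissa must be 'time' or 'turns'")


def survival_and_fit(
    records: Sequence[ActivityRecord],
    abscissa: str = "time",
    grid: Optional[np.ndarray] = None,
):
    """Active-fraction curve with proportion SEs, plus an exponential fit.

    The active fraction at x is the share of records still active among those
    under observation (censored records contribute until their censoring
    point and never decrement the curve before it); SE = sqrt(p(1-p)/n) with
    the at-risk n.  The fit is unweighted least squares of f = exp(-x/mu)
    with f(0) = 1 fixed.  If no record ever ends in a pause the estimate is
    only a lower bound and is flagged as such.
    """
    records = list(records)
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    x = _durations(records, abscissa)
    cens = np.array([r.censored for r in records])
    if grid is None:
        grid = np.linspace(0.0, float(x.max()), 61)
    p = np.empty_like(grid, dtype=float)
    se = np.empty_like(p)
    n_eff = np.empty_like(p)
    for i, g in enumerate(grid):
        observed = ~(cens & (x < g))  # censored records drop out after censoring
        n_obs = int(observed.sum())
        alive = np.sum(x[observed] >= g) if n_obs else 0
        pi = alive / n_obs if n_obs else np.nan
        p[i] = pi
        se[i] = math.sqrt(pi * (1.0 - pi) / n_obs) if n_obs else np.nan
        n_eff[i] = n_obs
    curve = SurvivalCurve(abscissa=grid, active_fraction=p, se=se,
                          n=len(records), kind=abscissa)
    if not np.any(~cens):
        return curve, ExpFit(mean=float(x.max()), uncertainty=float("nan"),
                             lower_bound=True)
    ok = np.isfinite(p)
    popt, pcov = curve_fit(
        lambda xx, mu: np.exp(-xx / mu), grid[ok], p[ok],
        p0=[max(float(np.mean(x)), 1e-9)], maxfev=10000,
    )
    unc = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")
    return curve, ExpFit(mean=float(popt[0]), uncertainty=unc)


def exponential_mle(records: Sequence[ActivityRecord], abscissa: str = "time") -> ExpFit:
    """Censoring-aware exponential MLE of the mean (lifelines-backed)."""
    from lifelines import ExponentialFitter

    x = _durations(records, abscissa)
    ev = np.array([not r.censored for r in records])
    if not ev.any():
        return ExpFit(mean=float(x.max()), uncertainty=float("nan"),
                      lower_bound=True, censoring_aware=True)
    ef = ExponentialFitter().fit(np.clip(x, 1e-12, None), event_observed=ev)
    return ExpFit(
        mean=float(ef.lambda_),
        uncertainty=float(ef.summary["se(coef)"].iloc[0]),
        censoring_aware=True,
    )


def rewind_reconstruction(
    dlk_after: float, n_added: float, rate_buckled: float,
    t_rewind: float, t_average: float = 1.0,
) -> float:
    """Supercoiling state before a rewinding step.

    dLk_pre = dLk_after - n_added + r_buckled * (t_rewind + t_average):
    the state measured just after rewinding, minus the turns added, plus the
    turns the enzyme relaxed on buckled DNA during the rewind and the
    averaging window.
    """
    return dlk_after - n_added + rate_buckled * (t_rewind + t_average)


def prebuckled_state_after_rewind(
    trace: BeadTrace, rewind, calibration, rate_buckled: float,
    t_average: float = 1.0,
) -> float:
    """Reconstruct the pre-buckled dLk preceding an annotated rewind step.

    Uses the mean extension over ``t_average`` seconds after the rewind ends,
    inverted through the buckled branch of the calibration matching the
    winding sign.
    """
    t_end = rewind["time"] + rewind["duration"]
    sel = (trace.time >= t_end) & (trace.time < t_end + t_average)
    if not np.any(sel):
        raise ValueError("no samples in the post-rewind averaging window")
    mean_ext = float(trace.extension[sel].mean())
    branch = "right" if rewind["turns"] > 0 else "left"
    dlk_after = float(calibration.turns_from_ext(mean_ext, branch))
    return rewind_reconstruction(
        dlk_after, rewind["turns"], rate_buckled, rewind["duration"], t_average
    )


def buckled_rate_linear(
    time: np.ndarray, ext: np.ndarray, calibration, branch: str = "right",
    window_s: float = 5.0,
) -> float:
    """Relaxation rate (turns/s) from a linear fit on a buckled segment.

    Extension is filtered by a sliding window, converted to supercoiling
    state through the buckled calibration branch, and fit linearly; samples
    that left the buckled branch are truncated with a warning.
    """
    t = np.asarray(time, dtype=float)
    e = sliding_filter(ext, window_s, float(t[1] - t[0]))
    el, er = calibration.buckling_extensions
    lim = el if branch == "left" else er
    inside = e <= lim
    if not inside.all():
        first_out = int(np.argmin(inside))
        if first_out < 5:
            raise ValueError("segment is not in the buckled branch")
        warnings.warn("segment exits the buckled branch; truncating")
        t, e = t[:first_out], e[:first_out]
    dlk = np.asarray(calibration.turns_from_ext(e, branch), dtype=float)
    slope = np.polyfit(t, dlk, 1)[0]
    return float(abs(slope))


def buckling_crossing_index(filtered_ext: np.ndarray, transition_ext: float):
    """Index of the first upward crossing of the buckling-transition extension.

    The tether must first visit the buckled branch (extension below the
    transition) and then relax through it; returns None if either phase is
    missing.
    """
    below = filtered_ext < transition_ext
    if not below.any():
        return None
    j = int(np.argmax(below))
    after = filtered_ext[j:] >= transition_ext
    if not after.any():
        return None
    return j + int(np.argmax(after))


def direct_prebuckled_timecourse(
    traces: Sequence[BeadTrace], calibration, lk0: float, branch: str = "pre_plus",
    window_s: float = 5.0, n_grid: int = 200,
):
    """Mean sigma(t) from relaxation traces aligned at the buckling transition.

    Each trace is time-shifted so its first crossing of the buckling-
    transition extension is t = 0, the filtered extensions are averaged on a
    common grid, and the mean curve is mapped through the pre-buckled branch
    of the calibration to supercoiling state.  Returns (t, sigma, sem).
    """
    el, er = calibration.buckling_extensions
    lim = er if branch == "pre_plus" else el
    shifted = []
    for k, tr in enumerate(traces):
        e = sliding_filter(tr.extension, window_s, tr.dt)
        i0 = buckling_crossing_index(e, lim)
        if i0 is None:
            warnings.warn(f"trace {k} never crosses the buckling transition; excluded")
            continue
        shifted.append((tr.time[i0:] - tr.time[i0], e[i0:]))
    if not shifted:
        raise ValueError("no trace crosses the buckling transition")
    t_max = min(t[-1] for t, _ in shifted)
    grid = np.linspace(0.0, t_max, n_grid)
    mat = np.vstack([np.interp(grid, t, e) for t, e in shifted])
    mean_ext = np.clip(mat.mean(axis=0), lim, calibration.e0)
    sem_ext = mat.std(axis=0, ddof=1) / math.sqrt(mat.shape[0]) if mat.shape[0] > 1 else np.zeros_like(mean_ext)
    dlk = np.asarray(calibration.turns_from_ext(mean_ext, branch), dtype=float)
    # propagate extension SEM through the local slope of the calibration
    eps = 1e-6
    ddlk = np.abs(
        np.asarray(calibration.turns_from_ext(np.clip(mean_ext - eps, lim, calibration.e0), branch)) - dlk
    ) / eps
    return grid, dlk / lk0, (ddlk * sem_ext) / lk0


def poisson_window_probability(p_long: float, t_long: float, t_short: float) -> float:
    """Probability of >= 1 event in a short window, from the long-window one.

    Assumes a constant-rate memoryless (Poisson) process:
    lambda = -ln(1 - p_long)/t_long and P_short = 1 - exp(-lambda t_short).
    """
    if not (0.0 <= p_long < 1.0):
        raise ValueError("p_long must be in [0, 1)")
    if p_long == 0.0:
        return 0.0
    lam = -math.log(1.0 - p_long) / t_long
    return 1.0 - math.exp(-lam * t_short)


# ---------------------------------------------------------------------------
# Trace I/O: delimited text with a '#'-prefixed metadata header
# ---------------------------------------------------------------------------

def write_trace(trace: BeadTrace, path) -> None:
    import json

    with open(path, "w") as fh:
        fh.write(f"# force_pN\t{trace.force:.6g}\n")
        fh.write("# annotations\t" + json.dumps(trace.annotations, sort_keys=True) + "\n")
        fh.write("time_s\textension_nm\tmagnet_turns\n")
        for t, e, m in zip(trace.time, trace.extension, trace.magnet_turns):
            fh.write(f"{t:.6f}\t{e:.6f}\t{m:.6f}\n")


def read_trace(path) -> BeadTrace:
    import json

    force = 0.0
    annotations = []
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("\t")
            if key == "force_pN":
                force = float(val)
            elif key == "annotations":
                annotations = json.loads(val)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    return BeadTrace(
        time=df["time_s"].to_numpy(),
        extension=df["extension_nm"].to_numpy(),
        magnet_turns=df["magnet_turns"].to_numpy(),
        force=force,
        annotations=annotations,
    )
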