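"""Mechanical models and calibration fits for naked DNA and chromatin.

Naked, torsionally constrained DNA under constant force responds to added
turns (dLk) in two regimes: pre-buckling, where torque rises linearly with
slope set by the effective twist persistence length L_t,eff and added turns
partition into twist and writhe in the ratio L_t,eff / L_t; and
post-buckling, where a plectoneme grows, torque plateaus, and every further
turn converts to writhe.  The extension-versus-turns calibration is a central
parabola capped by two linear plectonemic wings.

Chromatin shows three topological regimes — two steep buckled branches and a
wide, slightly tilted extension plateau in which nucleosomes absorb roughly
one turn each — and is fit by a five-piece function: three linear regions
joined by two parabolic (C1-continuous) joins.  The buckling-like transitions
w_t- and w_t+ are the intercepts of the middle linear regime with the outer
linear regimes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TorsionModel",
    "NakedCalibration",
    "ChromatinCalibration",
    "NucleosomeCensus",
    "ChromatinBenchmark",
    "SelectionResult",
    "CalibrationFitError",
    "ChromatinFitError",
    "partition_twist_writhe",
    "prebuckle_torque",
    "fit_effective_twist_persistence",
    "fit_naked_calibration",
    "fit_chromatin_fivepiece",
    "nucleosome_census",
    "selection_check",
]


class CalibrationFitError(RuntimeError):
    pass


class ChromatinFitError(CalibrationFitError):
    pass


# ---------------------------------------------------------------------------
# Torsional response of naked DNA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TorsionModel:
    """Pre/post-buckling torque and twist-writhe partition parameters.

    lt_eff is the effective twist persistence length from the pre-buckled
    torque slope (writhe fluctuations soften the intrinsic lt); torque
    plateaus at the buckling transitions.
    """

    lc: float  # contour length, nm
    lt_eff: float = 78.9  # nm
    lt: float = 109.0  # nm
    kbt: float = 4.09  # pN nm (23 degC)
    plateau_torque_pos: float = 7.7  # pN nm
    plateau_torque_neg: float = -7.6  # pN nm
    buckling_turns_pos: Optional[float] = None
    buckling_turns_neg: Optional[float] = None

    def __post_init__(self):
        if not (0.0 < self.lt_eff < self.lt):
            raise ValueError("require 0 < lt_eff < lt")
        if not (self.plateau_torque_pos > 0 > self.plateau_torque_neg):
            raise ValueError("plateau torques must have opposite signs")

    @property
    def torque_slope(self) -> float:
        """Pre-buckled torque per turn: 2 pi k_BT L_t,eff / L_c (pN nm/turn)."""
        return 2.0 * math.pi * self.kbt * self.lt_eff / self.lc

    @property
    def buckling_pos(self) -> float:
        if self.buckling_turns_pos is not None:
            return self.buckling_turns_pos
        return self.plateau_torque_pos / self.torque_slope

    @property
    def buckling_neg(self) -> float:
        if self.buckling_turns_neg is not None:
            return self.buckling_turns_neg
        return self.plateau_torque_neg / self.torque_slope


def partition_twist_writhe(dlk: float, model: TorsionModel) -> tuple:
    """Split dLk into (dTw, dWr); dTw + dWr = dLk exactly.

    Pre-buckling, dTw = (lt_eff/lt) dLk; past buckling the twist freezes at
    its transition value and all further turns go into writhe.
    """
    ratio = model.lt_eff / model.lt
    if dlk > model.buckling_pos:
        tw = ratio * model.buckling_pos
    elif dlk < model.buckling_neg:
        tw = ratio * model.buckling_neg
    else:
        tw = ratio * dlk
    return tw, dlk - tw


def prebuckle_torque(dlk, model: TorsionModel):
    """Torque (pN nm): linear in dLk pre-buckling, clipped at the plateaus."""
    tau = model.torque_slope * np.asarray(dlk, dtype=float)
    return np.clip(tau, model.plateau_torque_neg, model.plateau_torque_pos)[()]


def fit_effective_twist_persistence(
    turns: np.ndarray, torque: np.ndarray, lc: float, kbt: float = 4.09
) -> float:
    """L_t,eff (nm) from the slope of pre-buckled torque versus turns data."""
    slope = np.polyfit(np.asarray(turns, float), np.asarray(torque, float), 1)[0]
    return float(slope * lc / (2.0 * math.pi * kbt))


# ---------------------------------------------------------------------------
# Naked-DNA extension calibration: parabola + two linear wings
# ---------------------------------------------------------------------------

@dataclass
class NakedCalibration:
    """Extension-versus-turns map: central parabola, two plectonemic wings.

    ext(x) = e0 - a (x - x0)^2 on [x0 - bm, x0 + bp]; beyond the buckling
    transitions the extension falls linearly with slopes s_left (> 0, the
    (-) wing as turns increase toward the apex) and s_right (< 0).  Value-
    continuous at the junctions; each branch is monotone, hence invertible.
    """

    x0: float  # apex, turns
    e0: float  # apex extension, nm
    a: float  # parabola curvature, nm/turn^2
    bm: float  # (-) buckling offset (turns, > 0)
    bp: float  # (+) buckling offset (turns, > 0)
    s_left: float  # nm/turn, > 0
    s_right: float  # nm/turn, < 0
    force: float = 0.5

    def __post_init__(self):
        if self.a < 0 or self.bm <= 0 or self.bp <= 0:
            raise ValueError("curvature and buckling offsets must be positive")
        if not (self.s_left > 0 > self.s_right):
            raise ValueError("wing slopes must bracket zero")

    @property
    def buckling_turns(self) -> tuple:
        return (self.x0 - self.bm, self.x0 + self.bp)

    @property
    def buckling_extensions(self) -> tuple:
        return (self.e0 - self.a * self.bm**2, self.e0 - self.a * self.bp**2)

    def ext(self, turns):
        x = np.asarray(turns, dtype=float)
        xl, xr = self.buckling_turns
        el, er = self.buckling_extensions
        out = self.e0 - self.a * (x - self.x0) ** 2
        out = np.where(x < xl, el + self.s_left * (x - xl), out)
        out = np.where(x > xr, er + self.s_right * (x - xr), out)
        return out[()]

    def turns_from_ext(self, ext, branch: str):
        """Invert one monotone branch: 'left'/'right' wings, 'pre-' halves."""
        e = np.asarray(ext, dtype=float)
        xl, xr = self.buckling_turns
        el, er = self.buckling_extensions
        if branch == "left":
            out = xl + (e - el) / self.s_left
            bad = e > el
        elif branch == "right":
            out = xr + (e - er) / self.s_right
            bad = e > er
        elif branch in ("pre_minus", "pre_plus"):
            lim = el if branch == "pre_minus" else er
            bad = (e > self.e0 + 1e-9) | (e < lim - 1e-9)
            arg = np.clip((self.e0 - e) / max(self.a, 1e-300), 0.0, None)
            off = np.sqrt(arg)
            out = self.x0 - off if branch == "pre_minus" else self.x0 + off
        else:
            raise ValueError(f"unknown branch {branch!r}")
        if np.any(bad):
            raise ValueError("extension outside the requested branch")
        return out[()]


def fit_naked_calibration(turns, ext, force: float = 0.5) -> NakedCalibration:
    """Least-squares piecewise fit of the naked extension-turns relation."""
    x = np.asarray(turns, dtype=float)
    y = np.asarray(ext, dtype=float)
    if x.size < 8:
        raise CalibrationFitError("too few points for the piecewise fit")
    i0 = int(np.argmax(y))
    x0g, e0g = float(x[i0]), float(y[i0])
    span = x.max() - x.min()
    bg = max(span / 6.0, 1.0)
    # rough wing slopes from the outer thirds
    ltail = x < x.min() + span / 4
    rtail = x > x.max() - span / 4
    if ltail.sum() < 2 or rtail.sum() < 2:
        raise CalibrationFitError("insufficient wing coverage")
    slg = max(np.polyfit(x[ltail], y[ltail], 1)[0], 1e-3)
    srg = min(np.polyfit(x[rtail], y[rtail], 1)[0], -1e-3)

    def model(p, xx):
        cal = NakedCalibration(
            x0=p[0], e0=p[1], a=abs(p[2]), bm=abs(p[3]), bp=abs(p[4]),
            s_left=abs(p[5]), s_right=-abs(p[6]), force=force,
        )
        return cal.ext(xx)

    p0 = np.array([x0g, e0g, 0.5, bg, bg, slg, abs(srg)])
    res = least_squares(lambda p: model(p, x) - y, p0, x_scale="jac", max_nfev=20000)
    if not res.success:
        raise CalibrationFitError(f"naked calibration fit failed: {res.message}")
    p = res.x
    cal = NakedCalibration(
        x0=p[0], e0=p[1], a=abs(p[2]), bm=abs(p[3]), bp=abs(p[4]),
        s_left=abs(p[5]), s_right=-abs(p[6]), force=force,
    )
    xl, xr = cal.buckling_turns
    if x.min() > xl or x.max() < xr:
        raise CalibrationFitError("data do not span both buckled wings")
    return cal


# ---------------------------------------------------------------------------
# Chromatin five-piece calibration
# ---------------------------------------------------------------------------

@dataclass
class ChromatinCalibration:
    """Five-piece extension-turns function for a chromatin fiber.

    The slope is s1 left of the first join, ramps linearly to s2 across
    [c1 - h1, c1 + h1] (a parabolic piece), stays s2 in the plateau, ramps to
    s3 across [c2 - h2, c2 + h2], and is s3 beyond — three linear regions
    joined by two parabolic regimes, value- and slope-continuous at all four
    junctions.  The middle linear regime extended intersects the outer linear
    regimes exactly at the join centers, so w_t- = c1 and w_t+ = c2.
    """

    s1: float  # nm/turn, left steep slope (> 0)
    s2: float  # nm/turn, plateau slope (slightly negative)
    s3: float  # nm/turn, right steep slope (< 0)
    c1: float  # turns, (-) buckling-like transition
    c2: float  # turns, (+) buckling-like transition
    h1: float  # turns, half-width of the left join
    h2: float  # turns, half-width of the right join
    y_ref: float  # nm, extension at x = c1
    force: float = 0.5
    n_nuc_estimate: Optional[float] = None

    def __post_init__(self):
        if self.c1 >= self.c2:
            raise ValueError("require w_t- < w_t+")
        if self.h1 <= 0 or self.h2 <= 0:
            raise ValueError("join half-widths must be positive")

    @property
    def w_t_minus(self) -> float:
        return self.c1

    @property
    def w_t_plus(self) -> float:
        return self.c2

    def _knots(self):
        return (
            np.array([self.c1 - self.h1, self.c1 + self.h1,
                      self.c2 - self.h2, self.c2 + self.h2]),
            np.array([self.s1, self.s2, self.s2, self.s3]),
        )

    def slope(self, turns):
        k, s = self._knots()
        return np.interp(np.asarray(turns, dtype=float), k, s)[()]

    def ext(self, turns):
        """Exact integral of the piecewise-linear slope, anchored at c1."""
        x = np.atleast_1d(np.asarray(turns, dtype=float))
        k, s = self._knots()

        def antideriv(xx):
            # integral of slope from k[0] to xx (piecewise quadratic)
            xx = np.asarray(xx, dtype=float)
            out = np.zeros_like(xx)
            out = out + np.where(xx < k[0], self.s1 * (xx - k[0]), 0.0)
            acc = 0.0
            for seg in range(3):
                a, b = k[seg], k[seg + 1]
                sa, sb = s[seg], s[seg + 1]
                xcl = np.clip(xx, a, b)
                dx = xcl - a
                w = np.where(b > a, (sb - sa) / max(b - a, 1e-300), 0.0)
                out = out + sa * dx + 0.5 * w * dx**2
                acc += sa * (b - a) + 0.5 * (sb - sa) * (b - a)
            out = out + np.where(xx > k[3], self.s3 * (xx - k[3]), 0.0)
            return out

        val = antideriv(x) - antideriv(np.array([self.c1]))[0] + self.y_ref
        return val if np.asarray(turns).ndim else float(val[0])

    @property
    def peak_extension(self) -> float:
        """Maximum of the curve (at the zero crossing of the slope)."""
        k, s = self._knots()
        grid = np.linspace(k[0] - 1.0, k[3] + 1.0, 4001)
        return float(np.max(self.ext(grid)))

    def intercept_transitions(self) -> tuple:
        """(w_t-, w_t+) from intersecting the three tangent lines."""
        k, _ = self._knots()
        y = self.ext(k)
        # lines: (point, slope)
        def isect(xa, ya, sa, xb, yb, sb):
            return ((yb - sb * xb) - (ya - sa * xa)) / (sa - sb)

        wtm = isect(k[0], y[0], self.s1, k[1], y[1], self.s2)
        wtp = isect(k[3], y[3], self.s3, k[2], y[2], self.s2)
        return (float(wtm), float(wtp))


def fit_chromatin_fivepiece(turns, ext, force: float = 0.5) -> ChromatinCalibration:
    """Constrained least-squares fit of the five-piece chromatin function.

    Raises ChromatinFitError when no extension plateau exists (naked-DNA-like
    input), i.e. when the fitted middle linear regime collapses or its slope
    is not shallow relative to the outer branches.
    """
    x = np.asarray(turns, dtype=float)
    y = np.asarray(ext, dtype=float)
    if x.size < 12:
        raise ChromatinFitError("too few points for the five-piece fit")
    order = np.argsort(x)
    x, y = x[order], y[order]
    span = x[-1] - x[0]
    nq = max(x.size // 6, 2)
    s1g = np.polyfit(x[:nq], y[:nq], 1)[0]
    s3g = np.polyfit(x[-nq:], y[-nq:], 1)[0]
    ymax = y.max()
    high = y > ymax - 0.15 * (ymax - y.min())
    c1g, c2g = float(x[high].min()), float(x[high].max())
    if c2g - c1g < span / 20:
        c1g, c2g = x[0] + span / 3, x[-1] - span / 3
    mid = (x > c1g) & (x < c2g)
    s2g = np.polyfit(x[mid], y[mid], 1)[0] if mid.sum() >= 2 else 0.0

    def build(p):
        s1, s2, s3, c1, dc, h1, h2, y_ref = p
        return ChromatinCalibration(
            s1=s1, s2=s2, s3=s3, c1=c1, c2=c1 + abs(dc) + 1e-6,
            h1=abs(h1) + 1e-3, h2=abs(h2) + 1e-3, y_ref=y_ref, force=force,
        )

    p0 = np.array([s1g, s2g, s3g, c1g, c2g - c1g, 2.0, 2.0, ymax])
    res = least_squares(lambda p: build(p).ext(x) - y, p0, x_scale="jac",
                        max_nfev=40000)
    if not res.success:
        raise ChromatinFitError(f"five-piece fit failed: {res.message}")
    cal = build(res.x)
    inner = (cal.c2 - cal.h2) - (cal.c1 + cal.h1)
    steep = min(abs(cal.s1), abs(cal.s3))
    if inner < 2.0 or not (cal.s1 > 0 > cal.s3) or abs(cal.s2) > 0.5 * steep:
        raise ChromatinFitError(
            "no extension plateau found: input is not chromatin-like"
        )
    # a true plateau is linear; reject inputs whose middle region carries the
    # parabolic sag of a naked pre-buckled response
    mid = (x >= cal.c1 + cal.h1) & (x <= cal.c2 - cal.h2)
    outer = (x <= cal.c1 - cal.h1) | (x >= cal.c2 + cal.h2)
    resid = cal.ext(x) - y
    noise = float(np.sqrt(np.mean(resid[outer] ** 2))) if outer.sum() >= 4 else float(
        np.sqrt(np.mean(resid**2))
    )
    if mid.sum() >= 8:
        q = np.polyfit(x[mid], y[mid], 2)
        sag = abs(q[0]) * (inner / 2.0) ** 2
        if sag > max(4.0 * noise, 0.005 * float(y.max() - y.min())):
            raise ChromatinFitError(
                "middle region is curved, not a plateau: input is not chromatin-like"
            )
    return cal


# ---------------------------------------------------------------------------
# Nucleosome census and fiber selection
# ---------------------------------------------------------------------------

BP_PER_OUTER_TURN = 72.0
BP_PER_INNER_TURN = 75.0


@dataclass(frozen=True)
class NucleosomeCensus:
    n_out: int
    n_in: int
    n_nuc: float
    composition_ok: bool
    reason: str = ""


def _round_half_even(x: float) -> int:
    return int(np.rint(x))


def nucleosome_census(
    len_release_2to6pn_bp: float, len_release_highsalt_bp: float
) -> NucleosomeCensus:
    """Count nucleosomes from disruption-assay DNA release lengths.

    N_out from the outer-turn release (~72 bp per nucleosome between 2 and
    6 pN), N_in from the high-salt inner-turn release (~75 bp per tetramer);
    N_nuc = (N_out + N_in) / 2, with composition acceptable when
    |N_in - N_out| / N_in <= 0.15.
    """
    if len_release_2to6pn_bp < 0 or len_release_highsalt_bp < 0:
        raise ValueError("release lengths must be nonnegative")
    n_out = _round_half_even(len_release_2to6pn_bp / BP_PER_OUTER_TURN)
    n_in = _round_half_even(len_release_highsalt_bp / BP_PER_INNER_TURN)
    n_nuc = (n_out + n_in) / 2.0
    if n_in == 0:
        return NucleosomeCensus(n_out, n_in, n_nuc, False,
                                "no inner-turn release: composition undefined")
    ok = abs(n_in - n_out) / n_in <= 0.15
    return NucleosomeCensus(n_out, n_in, n_nuc, ok,
                            "" if ok else "composition imbalance > 15%")


@dataclass(frozen=True)
class ChromatinBenchmark:
    """Linear benchmark relations versus nucleosome count, with 95% CI bands.

    Each line is (intercept, slope); ci half-widths are in the line's units.
    peak_line maps N_nuc to peak extension (nm) and is inverted to estimate
    N_nuc; wt lines map N_nuc to the buckling-like transitions (turns).
    """

    peak_line: tuple
    wt_plus_line: tuple
    wt_minus_line: tuple
    wt_plus_ci: float
    wt_minus_ci: float
    n_nuc_window: tuple = (45.0, 55.0)


@dataclass(frozen=True)
class SelectionResult:
    passed: bool
    n_nuc_estimate: float
    reasons: tuple = ()

    def __bool__(self):
        return self.passed


def selection_check(cal: ChromatinCalibration, benchmark: ChromatinBenchmark) -> SelectionResult:
    """Apply the fiber selection criteria from the initial calibration.

    Pass iff the peak-extension-based nucleosome estimate lies in the
    saturation window (50 +- 5 by default) and both w_t+ and w_t- fall within
    the 95% confidence bands of the benchmark lines at that estimate.
    """
    if benchmark is None:
        raise ValueError("a chromatin benchmark is required")
    b0, b1 = benchmark.peak_line
    if b1 == 0:
        raise ValueError("degenerate peak-extension benchmark line")
    n_est = (cal.peak_extension - b0) / b1
    reasons = []
    lo, hi = benchmark.n_nuc_window
    if not (lo <= n_est <= hi):
        reasons.append("saturation")
    a0, a1 = benchmark.wt_plus_line
    if abs(cal.w_t_plus - (a0 + a1 * n_est)) > benchmark.wt_plus_ci:
        reasons.append("composition")
    m0, m1 = benchmark.wt_minus_line
    if abs(cal.w_t_minus - (m0 + m1 * n_est)) > benchmark.wt_minus_ci:
        reasons.append("composition")
    return SelectionResult(not reasons, float(n_est), tuple(dict.fromkeys(reasons)))
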