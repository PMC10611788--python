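"""Loop-capture kinetics and Michaelis-Menten relaxation by topoisomerase II.

The site-to-site distance distribution p(R) of an equilibrium chain ensemble
is Boltzmann-inverted into an effective free-energy profile F(R) = -ln p(R)
(k_BT units) along the distance reaction coordinate.  Loop (crossing)
formation is modeled as one-dimensional diffusion on F(R) with an absorbing
boundary at the capture radius R_T and a reflecting boundary at the largest
populated distance L; the mean first-passage time from the equilibrated
uncrossed state is

    <T> = (1/ D Z) int_{R_T}^{L} dR int_{R_T}^{R} dR' int_{R'}^{L} dR''
              exp(-[F(R) - F(R') + F(R'')])

with Z = int_{R_T}^{L} exp(-F) dR the uncrossed-state partition function and
D the effective diffusion coefficient.  The crossing rate is k = 1/<T>, and
the supercoil relaxation rate of topo II follows the Michaelis-Menten form

    d(dLk)/dt = V_max * k / (k + k_1/2),

with V_max fixed per force from buckled-state measurements and k_1/2 a global
fit parameter obtained by chi-squared minimization against relaxation
time courses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid
from scipy.optimize import brentq, minimize_scalar

from .wlc import DistanceDistribution

__all__ = [
    "FreeEnergyProfile",
    "CrossingRate",
    "CrossingRateTable",
    "RelaxationModel",
    "KHalfFit",
    "TrajectoryData",
    "free_energy_profile",
    "mfpt",
    "crossing_rate",
    "mm_rate",
    "integrate_relaxation",
    "fit_k_half",
    "writhe_mm_rate",
]


@dataclass
class FreeEnergyProfile:
    """Effective free energy F(R) = -ln p(R) (k_BT) on distance bins.

    ``f_values`` keeps the raw Boltzmann inversion of the histogram masses so
    that exp(-F) renormalizes to the source histogram; the partition constant
    and the MFPT quadrature use the min-shifted profile (additive constants
    cancel exactly in <T>).
    """

    r_bins: np.ndarray  # bin centers, nm, ascending
    f_values: np.ndarray  # k_BT
    sigma: Optional[float] = None
    force: Optional[float] = None
    partition_z: float = field(init=False, default=0.0)

    def __post_init__(self):
        self.r_bins = np.asarray(self.r_bins, dtype=float)
        self.f_values = np.asarray(self.f_values, dtype=float)
        if not np.all(np.isfinite(self.f_values)):
            raise ValueError("free energy profile contains non-finite values")
        self.partition_z = float(
            trapezoid(np.exp(-(self.f_values - self.f_values.min())), self.r_bins)
        )
        if self.partition_z <= 0:
            raise ValueError("partition constant must be positive")


@dataclass(frozen=True)
class CrossingRate:
    k: float  # loops/s
    sigma: Optional[float] = None
    force: Optional[float] = None


@dataclass
class CrossingRateTable:
    """Crossing rate k (loops/s) versus superhelical density at fixed force.

    Lookup is by |sigma| with linear interpolation; values outside the grid
    are clamped to the edge entries (flagged by the integrator).
    """

    sigmas: np.ndarray
    ks: np.ndarray
    force: float

    def __post_init__(self):
        s = np.abs(np.asarray(self.sigmas, dtype=float))
        k = np.asarray(self.ks, dtype=float)
        if np.any(k <= 0):
            raise ValueError("crossing rates must be positive")
        order = np.argsort(s)
        self.sigmas = s[order]
        self.ks = k[order]

    def k_of_sigma(self, sigma):
        return np.interp(np.abs(sigma), self.sigmas, self.ks)

    def in_range(self, sigma) -> bool:
        return bool(
            np.all(np.abs(sigma) >= self.sigmas[0])
            and np.all(np.abs(sigma) <= self.sigmas[-1])
        )


@dataclass
class RelaxationModel:
    """Michaelis-Menten relaxation parameters.

    v_max maps force (pN) to the saturated relaxation rate (turns/s) measured
    on buckled DNA; k_half is the crossing rate (loops/s) at half-saturation.
    diffusion_d sets the absolute timescale of the MFPT (<T> scales as 1/D),
    so absolute crossing rates are calibration-dependent through it.
    """

    v_max: dict = field(default_factory=lambda: {0.5: 3.4, 1.1: 3.1, 1.6: 3.0})
    k_half: float = 6.8  # loops/s
    diffusion_d: float = 1.0e7  # nm^2/s
    capture_radius: float = 10.0  # nm

    def __post_init__(self):
        if self.k_half <= 0 or self.diffusion_d <= 0 or self.capture_radius <= 0:
            raise ValueError("all relaxation-model parameters must be positive")
        if any(v <= 0 for v in self.v_max.values()):
            raise ValueError("V_max values must be positive")

    def vmax_at(self, force: float) -> float:
        for f, v in self.v_max.items():
            if abs(f - force) < 1e-9:
                return v
        raise KeyError(f"no V_max entry for force {force} pN")


def free_energy_profile(
    dist: DistanceDistribution, capture_radius: float = 10.0
) -> FreeEnergyProfile:
    """Boltzmann inversion of a distance histogram on [R_T, L_max].

    F = -ln p on populated bins; empty interior bins are filled by linear
    interpolation in F; bins below the capture radius and beyond the last
    populated bin are dropped.
    """
    centers = dist.centers
    masses = np.asarray(dist.masses, dtype=float)
    sel = centers >= capture_radius
    if not np.any(sel) or masses[sel].sum() <= 0:
        raise ValueError("all histogram mass lies below the capture radius")
    c = centers[sel]
    m = masses[sel]
    populated = np.nonzero(m > 0)[0]
    lo, hi = populated[0], populated[-1]
    c = c[lo : hi + 1]
    m = m[lo : hi + 1]
    f = np.full_like(m, np.nan)
    good = m > 0
    f[good] = -np.log(m[good])
    if not np.all(good):
        f[~good] = np.interp(c[~good], c[good], f[good])
    return FreeEnergyProfile(
        r_bins=c, f_values=f, sigma=dist.sigma, force=dist.force
    )


def _resampled(profile: FreeEnergyProfile, min_bins: int = 200):
    r = profile.r_bins
    f = profile.f_values - profile.f_values.min()
    if r.size >= min_bins:
        return r, f
    rr = np.linspace(r[0], r[-1], min_bins)
    return rr, np.interp(rr, r, f)


def mfpt(profile: FreeEnergyProfile, model: RelaxationModel) -> float:
    """Mean first-passage time <T> (s) for loop capture on the profile.

    The triple integral is evaluated by nested cumulative trapezoid sums
    (O(n) after prefix sums) on the profile grid, resampled to at least 200
    bins.  Absorbing boundary at R_T (the grid start), reflecting at L_max.
    """
    r, f = _resampled(profile)
    if r.size < 2 or r[-1] <= r[0]:
        return 0.0
    ez = np.exp(-f)
    ezi = np.exp(f)
    z = trapezoid(ez, r)
    # G(R') = int_{R'}^{L} exp(-F(R'')) dR''
    cum = cumulative_trapezoid(ez, r, initial=0.0)
    g = cum[-1] - cum
    # H(R) = int_{R_T}^{R} exp(+F(R')) G(R') dR'
    h = cumulative_trapezoid(ezi * g, r, initial=0.0)
    t = trapezoid(ez * h, r) / (model.diffusion_d * z)
    return float(t)


def crossing_rate(profile: FreeEnergyProfile, model: RelaxationModel) -> CrossingRate:
    """Average crossing (loop-formation) rate k = 1 / <T> with metadata."""
    t = mfpt(profile, model)
    if t <= 0:
        raise ZeroDivisionError("mean first-passage time is zero; rate undefined")
    return CrossingRate(k=1.0 / t, sigma=profile.sigma, force=profile.force)


def mm_rate(k: float, model: RelaxationModel, force: float) -> float:
    """Relaxation rate V_max(F) * k / (k + k_1/2) in turns/s."""
    if k < 0:
        raise ValueError("crossing rate must be nonnegative")
    vmax = model.vmax_at(force)
    if math.isinf(k):
        return vmax
    return vmax * k / (k + model.k_half)


def writhe_mm_rate(mean_abs_writhe: float, v_max: float, w_half: float) -> float:
    """Alternative model: rate depends on writhe only, V|W|/(|W| + w_half)."""
    if mean_abs_writhe < 0 or w_half < 0:
        raise ValueError("inputs must be nonnegative")
    if mean_abs_writhe == 0:
        return 0.0
    return v_max * mean_abs_writhe / (mean_abs_writhe + w_half)


def integrate_relaxation(
    sigma0: float,
    table: CrossingRateTable,
    model: RelaxationModel,
    force: float,
    t_grid: np.ndarray,
    lk0: float,
    k_half: Optional[float] = None,
    substeps: int = 4,
) -> np.ndarray:
    """Integrate d(dLk)/dt = -sign(dLk) V_max k(sigma)/(k(sigma)+k_1/2).

    Returns sigma(t) on ``t_grid`` (fixed-step RK4 with ``substeps``
    subdivisions per grid interval); sigma never crosses zero (the fully
    relaxed state is absorbing).  If the trajectory leaves the table's sigma
    coverage, the rate is clamped to the nearest table entry and a warning is
    issued.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    kh = model.k_half if k_half is None else float(k_half)
    vmax = model.vmax_at(force)
    warned = [False]

    def rhs(sig):
        if sig == 0.0:
            return 0.0
        if not table.in_range(sig) and not warned[0]:
            warned[0] = True
        k = float(table.k_of_sigma(sig))
        return -math.copysign(1.0, sig) * vmax * k / (k + kh) / lk0

    out = np.empty_like(t_grid)
    sig = float(sigma0)
    out[0] = sig
    sign0 = math.copysign(1.0, sig) if sig != 0 else 0.0
    for i in range(1, t_grid.size):
        h = (t_grid[i] - t_grid[i - 1]) / substeps
        for _ in range(substeps):
            k1 = rhs(sig)
            k2 = rhs(sig + 0.5 * h * k1)
            k3 = rhs(sig + 0.5 * h * k2)
            k4 = rhs(sig + h * k3)
            sig = sig + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            if sign0 != 0 and math.copysign(1.0, sig) != sign0:
                sig = 0.0
        out[i] = sig
    if warned[0]:
        warnings.warn("relaxation trajectory left table coverage; rate clamped")
    return out


@dataclass(frozen=True)
class TrajectoryData:
    """One measured relaxation time course: sigma(t) with optional SEMs."""

    t: np.ndarray
    sigma: np.ndarray
    force: float
    sem: Optional[np.ndarray] = None


@dataclass(frozen=True)
class KHalfFit:
    k_half: float
    uncertainty: float  # half-width of the delta-chi-squared = 1 interval
    chi2: float
    n_points: int


def fit_k_half(
    trajectories: Sequence[TrajectoryData],
    table,
    model: RelaxationModel,
    lk0: float,
    bounds: tuple = (1e-3, 1e3),
) -> KHalfFit:
    """Global chi-squared fit of k_1/2 across forces.

    V_max per force is held fixed; each trajectory is integrated from its
    first data point and compared to the data with SEM weights (unit weights
    when SEMs are absent).  The uncertainty is the half-width of the
    delta-chi-squared = 1 interval around the minimum.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    tables = table if isinstance(table, dict) else None

    def chi2(kh):
        total = 0.0
        for traj in trajectories:
            tab = tables[traj.force] if tables is not None else table
            mdl = integrate_relaxation(
                traj.sigma[0], tab, model, traj.force, traj.t, lk0, k_half=kh
            )
            res = mdl - traj.sigma
            if traj.sem is not None:
                res = res / traj.sem
            total += float(np.sum(res**2))
        return total

    res = minimize_scalar(
        lambda x: chi2(10.0**x),
        bounds=(math.log10(bounds[0]), math.log10(bounds[1])),
        method="bounded",
        options={"xatol": 1e-6},
    )
    if not res.success:
        raise RuntimeError(f"k_1/2 fit failed to converge: {res}")
    k_best = 10.0**res.x
    c_min = res.fun

    def excess(kh):
        return chi2(kh) - c_min - 1.0

    lo = hi = k_best
    try:
        if excess(bounds[0]) > 0:
            lo = brentq(excess, bounds[0], k_best, xtol=1e-6)
        if excess(bounds[1]) > 0:
            hi = brentq(excess, k_best, bounds[1], xtol=1e-6)
    except ValueError:
        pass
    unc = 0.5 * (hi - lo) if hi > lo else float("nan")
    n_pts = int(sum(t.t.size for t in trajectories))
    return KHalfFit(k_half=k_best, uncertainty=unc, chi2=c_min, n_points=n_pts)
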