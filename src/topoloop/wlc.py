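"""Discrete worm-like-chain Monte Carlo for tethered, torsionally constrained DNA.

The DNA is a chain of ``n_segments`` rigid segments under a stretching force
F along z, with the first vertex anchored at the origin and both terminal
segment tangents held parallel to the force axis (tether / bead geometry).
The total energy, in units of k_BT, is

    E = (L_p / l) * sum_i (1 - cos theta_i)          bending
        - (F / k_BT) * z_end                         stretching
        + (2 pi^2 L_t / L_c) * (dLk - dWr)^2         torsional

where l is the segment length, L_p and L_t the bending and twist persistence
lengths, L_c the contour length, dLk the linking-number offset carried by the
chain, and dWr the writhe of the virtually closed chain.  The quadratic twist
term is the unique form whose difference under a replica swap reduces to

    dE_swap = (4 pi^2 L_t / L_c) (dLk_i - dLk_j) (dWr_i - dWr_j),

the modified Metropolis criterion used for full-chain exchanges between
replicas at neighboring linking numbers.

Sampling alternates blocks of local moves (crankshaft and pivot rotations,
angle uniform on [-amplitude, +amplitude]) with replica-exchange sweeps;
configurations are saved after a fixed number of successful exchanges, and a
knot check (Alexander determinant of the closed chain) runs on a fixed move
cadence, reverting to the last knot-free checkpoint on detection.  Segments
may pass through one another during moves; topology is enforced solely by
knot rejection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .topology import (
    alexander_determinant,
    close_chain,
    writhe_closed,
    writhe_pairs_partial,
)

__all__ = [
    "BOLTZMANN_PN_NM",
    "BendConstraint",
    "SamplerConfig",
    "ChainConformation",
    "ReplicaSamples",
    "Ensemble",
    "DistanceDistribution",
    "straight_chain",
    "bent_initial_chain",
    "bend_energy",
    "extension",
    "writhe",
    "twist_energy",
    "total_energy",
    "propose_local_move",
    "metropolis_accept",
    "replica_exchange_delta",
    "knot_check",
    "make_bent_chain",
    "run_sampler",
    "distance_distribution",
    "wlc_extension_fraction",
]

#: Boltzmann constant in pN nm / K.
BOLTZMANN_PN_NM = 0.0138065


@dataclass(frozen=True)
class BendConstraint:
    """Rigid two-kink bend: a flat-bottomed 'V' of fixed total angle.

    Two adjacent joints, at ``joint`` and ``joint + 1``, are frozen at
    ``total_angle_deg / 2`` each and excluded from move proposals, so the
    bend geometry is rigid under all accepted moves.
    """

    total_angle_deg: float = 120.0
    joint: Optional[int] = None  # defaults to the chain center


@dataclass(frozen=True)
class SamplerConfig:
    """Parameters of the tethered-chain sampler.

    Lengths are in nm, the force in pN and the temperature in K.  The
    defaults reproduce the standard coarse-grained parameterization of
    double-stranded DNA: 10 nm segments, 50 nm bending persistence length,
    109 nm twist persistence length, 23 degC.
    """

    n_segments: int
    force: float
    dlk_grid: tuple = (0.0,)
    segment_length: float = 10.0
    bend_persistence: float = 50.0
    twist_persistence: float = 109.0
    temperature: float = 296.0
    move_amplitude: float = 50.0  # degrees
    knot_check_interval: int = 1000
    local_moves_per_cycle: int = 1000
    save_target: int = 25000
    exchange_saves_threshold: int = 5
    seed: int = 0
    bend_constraint: Optional[BendConstraint] = None
    burn_in_cycles: int = 0
    store_conformations: bool = True
    max_cycles: Optional[int] = None

    def __post_init__(self):
        if self.segment_length <= 0:
            raise ValueError("segment_length must be positive")
        if self.n_segments < 4:
            raise ValueError("n_segments must be >= 4")
        if not (0.0 < self.move_amplitude < 180.0):
            raise ValueError("move_amplitude must be in (0, 180) degrees")
        grid = tuple(float(x) for x in self.dlk_grid)
        if len(grid) > 1 and not (
            all(a < b for a, b in zip(grid, grid[1:]))
            or all(a > b for a, b in zip(grid, grid[1:]))
        ):
            raise ValueError("dlk_grid must be strictly monotone")
        object.__setattr__(self, "dlk_grid", grid)
        if self.bend_constraint is not None:
            j = self.kink_joint
            if j < 2 or j + 1 > self.n_segments - 2:
                raise ValueError("bend constraint must be interior to the chain")

    @property
    def contour_length(self) -> float:
        return self.segment_length * self.n_segments

    @property
    def kbt(self) -> float:
        """Thermal energy in pN nm."""
        return BOLTZMANN_PN_NM * self.temperature

    @property
    def k_bend(self) -> float:
        """Bending stiffness L_p / l in k_BT per (1 - cos theta)."""
        return self.bend_persistence / self.segment_length

    @property
    def f_reduced(self) -> float:
        """Force in k_BT / nm."""
        return self.force / self.kbt

    @property
    def k_twist(self) -> float:
        """Twist-energy prefactor 2 pi^2 L_t / L_c in k_BT / turn^2."""
        return 2.0 * math.pi**2 * self.twist_persistence / self.contour_length

    @property
    def closure_reach(self) -> float:
        return 10.0 * self.contour_length

    @property
    def kink_joint(self) -> int:
        if self.bend_constraint is None:
            raise ValueError("no bend constraint configured")
        j = self.bend_constraint.joint
        return self.n_segments // 2 if j is None else int(j)


@dataclass
class ChainConformation:
    """A chain state: vertices plus its linking-number label and caches."""

    vertices: np.ndarray  # (n_segments + 1, 3), nm; first vertex at origin
    dlk: float
    writhe: Optional[float] = None  # cached dWr, turns
    energy: Optional[float] = None  # cached total energy, k_BT

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n+1, 3)")


@dataclass
class ReplicaSamples:
    """Per-replica saved observables (and optionally conformations)."""

    dlk: float
    extensions: np.ndarray
    writhes: np.ndarray
    energies: np.ndarray
    conformations: Optional[list] = None
    equilibration_warning: bool = False


@dataclass
class Ensemble:
    config: SamplerConfig
    replicas: list
    local_acceptance: float = 0.0
    exchange_acceptance: float = 0.0
    knot_rejections: int = 0

    @property
    def dlk_labels(self) -> tuple:
        return tuple(r.dlk for r in self.replicas)


@dataclass
class DistanceDistribution:
    """Normalized histogram of site-to-site distances R (masses sum to 1)."""

    bin_edges: np.ndarray
    masses: np.ndarray
    n_pairs: int
    sigma: Optional[float] = None
    force: Optional[float] = None

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


# ---------------------------------------------------------------------------
# Chain construction
# ---------------------------------------------------------------------------

def straight_chain(cfg: SamplerConfig, dlk: float = 0.0) -> ChainConformation:
    """Fully extended chain along the force axis (zero bend, zero writhe)."""
    n = cfg.n_segments
    v = np.zeros((n + 1, 3))
    v[:, 2] = np.arange(n + 1) * cfg.segment_length
    conf = ChainConformation(v, dlk=dlk, writhe=0.0)
    conf.energy = total_energy(conf, cfg)
    return conf


def bent_initial_chain(cfg: SamplerConfig, dlk: float = 0.0) -> ChainConformation:
    """Initial conformation honoring the two-kink bend constraint.

    Tangents run along +z up to the kink, turn by half the total angle at
    each of the two kink joints, then relax back to +z over the remaining
    joints so the terminal tangent constraint is met.
    """
    if cfg.bend_constraint is None:
        return straight_chain(cfg, dlk)
    n = cfg.n_segments
    m = cfg.kink_joint
    half = math.radians(cfg.bend_constraint.total_angle_deg) / 2.0
    tilts = np.zeros(n)
    tilts[m] = half
    tilts[m + 1] = 2.0 * half
    rest = n - (m + 2)
    if rest > 0:
        tilts[m + 2 :] = 2.0 * half * (1.0 - np.arange(1, rest + 1) / rest)
    dirs = np.c_[np.sin(tilts), np.zeros(n), np.cos(tilts)] * cfg.segment_length
    v = np.zeros((n + 1, 3))
    v[1:] = np.cumsum(dirs, axis=0)
    conf = ChainConformation(v, dlk=dlk)
    conf.writhe = writhe(conf, cfg)
    conf.energy = total_energy(conf, cfg)
    return conf


def make_bent_chain(cfg: SamplerConfig, midpoint: Optional[int] = None,
                    total_angle_deg: float = 120.0) -> SamplerConfig:
    """Config variant with a rigid two-kink 'V' bend at the chain center."""
    joint = cfg.n_segments // 2 if midpoint is None else int(midpoint)
    if joint < 2 or joint + 1 > cfg.n_segments - 2:
        raise ValueError("bend must be placed at interior joints, away from anchors")
    return replace(cfg, bend_constraint=BendConstraint(total_angle_deg, joint))


# ---------------------------------------------------------------------------
# Energies and geometry
# ---------------------------------------------------------------------------

def _check_chain(conf: ChainConformation, cfg: SamplerConfig) -> None:
    if conf.vertices.shape[0] != cfg.n_segments + 1:
        raise ValueError(
            f"chain has {conf.vertices.shape[0] - 1} segments, "
            f"config expects {cfg.n_segments}"
        )


def bend_sum(vertices: np.ndarray) -> float:
    """sum_i (1 - cos theta_i) over interior joints."""
    t = np.diff(vertices, axis=0)
    t /= np.linalg.norm(t, axis=1)[:, None]
    cos = np.sum(t[:-1] * t[1:], axis=1)
    return float(np.sum(1.0 - np.clip(cos, -1.0, 1.0)))


def bend_energy(vertices: np.ndarray, cfg: SamplerConfig) -> float:
    return cfg.k_bend * bend_sum(vertices)


def extension(vertices: np.ndarray) -> float:
    """End-to-end extension along the force axis, nm."""
    return float(vertices[-1, 2] - vertices[0, 2])


def writhe(conf: ChainConformation, cfg: Optional[SamplerConfig] = None) -> float:
    """Writhe dWr (turns) of the virtually closed chain.

    The chain is closed by long straight extensions along the force axis from
    both anchored ends, joined far from the chain, and the exact Gauss
    segment-pair sum is evaluated over the closed polygon.
    """
    v = conf.vertices
    seg = np.linalg.norm(np.diff(v, axis=0), axis=1)
    if np.any(seg < 1e-12):
        raise ValueError("coincident vertices: writhe undefined")
    lc = float(seg.sum())
    reach = 10.0 * lc if cfg is None else cfg.closure_reach
    return float(writhe_closed(close_chain(v, reach)))


def twist_energy(dlk: float, wr: float, cfg: SamplerConfig) -> float:
    return cfg.k_twist * (dlk - wr) ** 2


def total_energy(conf: ChainConformation, cfg: SamplerConfig) -> float:
    """Total energy in k_BT: bending + stretching + torsional."""
    _check_chain(conf, cfg)
    wr = conf.writhe if conf.writhe is not None else writhe(conf, cfg)
    return (
        bend_energy(conf.vertices, cfg)
        - cfg.f_reduced * extension(conf.vertices)
        + twist_energy(conf.dlk, wr, cfg)
    )


def knot_check(conf: ChainConformation, cfg: Optional[SamplerConfig] = None) -> bool:
    """True iff the virtually closed chain is knotted (|Delta(-1)| != 1)."""
    v = conf.vertices
    lc = float(np.linalg.norm(np.diff(v, axis=0), axis=1).sum())
    reach = 10.0 * lc if cfg is None else cfg.closure_reach
    return alexander_determinant(close_chain(v, reach)) != 1


def metropolis_accept(delta_e: float, rng: np.random.Generator) -> bool:
    """Metropolis rule: accept with probability min(1, exp(-dE))."""
    if not np.isfinite(delta_e):
        raise ValueError("energy difference must be finite")
    return delta_e <= 0.0 or rng.random() < math.exp(-delta_e)


def replica_exchange_delta(
    lk_i: float, lk_j: float, wr_i: float, wr_j: float, cfg: SamplerConfig
) -> float:
    """Swap criterion dE = (4 pi^2 L_t / L_c)(dLk_i - dLk_j)(dWr_i - dWr_j)."""
    grid = cfg.dlk_grid
    idx_i = grid.index(float(lk_i))
    idx_j = grid.index(float(lk_j))
    if abs(idx_i - idx_j) != 1:
        raise ValueError("replica exchange only between neighboring dLk values")
    return 2.0 * cfg.k_twist * (lk_i - lk_j) * (wr_i - wr_j)


# ---------------------------------------------------------------------------
# Local moves (single-move Python version; the sampler uses the JIT kernel)
# ---------------------------------------------------------------------------

def _rodrigues(points: np.ndarray, origin: np.ndarray, axis: np.ndarray,
               theta: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    p = points - origin
    c, s = math.cos(theta), math.sin(theta)
    return (
        origin
        + p * c
        + np.cross(axis, p) * s
        + np.outer(p @ axis, axis) * (1.0 - c)
    )


def propose_local_move(
    conf: ChainConformation,
    cfg: SamplerConfig,
    rng: np.random.Generator,
    kind: Optional[str] = None,
    angle: Optional[float] = None,
    indices: Optional[tuple] = None,
):
    """Propose a crankshaft or pivot rotation; returns (candidate, valid, kind).

    Crankshaft: an interior subchain rotates about the axis through its two
    boundary vertices.  Pivot: the tail beyond an interior vertex rotates
    about a random axis through it, and the final vertex is re-appended along
    the force axis so both terminal tangents stay exactly on the force axis.
    Rotation angles are uniform on [-amplitude, +amplitude]; segment lengths
    are preserved exactly.  Proposals whose hinges fall on frozen kink joints
    are flagged invalid rather than raising.
    """
    _check_chain(conf, cfg)
    n = cfg.n_segments
    if kind is None:
        kind = "crankshaft" if rng.random() < 0.5 else "pivot"
    theta = (
        math.radians(cfg.move_amplitude) * (2.0 * rng.random() - 1.0)
        if angle is None
        else float(angle)
    )
    frozen = set()
    if cfg.bend_constraint is not None:
        frozen = {cfg.kink_joint, cfg.kink_joint + 1}
    v = conf.vertices.copy()
    if kind == "crankshaft":
        if indices is None:
            i = int(rng.integers(1, n - 2))
            j = int(rng.integers(i + 2, n))
        else:
            i, j = indices
        if i in frozen or j in frozen:
            return ChainConformation(v, conf.dlk), False, kind
        axis = v[j] - v[i]
        v[i + 1 : j] = _rodrigues(v[i + 1 : j], v[i], axis, theta)
    elif kind == "pivot":
        p = int(rng.integers(1, n - 1)) if indices is None else int(indices[0])
        if p in frozen:
            return ChainConformation(v, conf.dlk), False, kind
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        v[p + 1 : n] = _rodrigues(v[p + 1 : n], v[p], u, theta)
        v[n] = v[n - 1] + np.array([0.0, 0.0, cfg.segment_length])
    else:
        raise ValueError(f"unknown move kind {kind!r}")
    return ChainConformation(v, conf.dlk), True, kind


# ---------------------------------------------------------------------------
# JIT inner loop
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _joint_bend(P, k):
    ax = P[k, 0] - P[k - 1, 0]
    ay = P[k, 1] - P[k - 1, 1]
    az = P[k, 2] - P[k - 1, 2]
    bx = P[k + 1, 0] - P[k, 0]
    by = P[k + 1, 1] - P[k, 1]
    bz = P[k + 1, 2] - P[k, 2]
    na = math.sqrt(ax * ax + ay * ay + az * az)
    nb = math.sqrt(bx * bx + by * by + bz * bz)
    c = (ax * bx + ay * by + az * bz) / (na * nb)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return 1.0 - c


@njit(cache=True, inline="always")
def _rotate_block(P, a, b, ox, oy, oz, ux, uy, uz, theta):
    """Rodrigues rotation of vertices a..b (inclusive) about (o, u)."""
    c = math.cos(theta)
    s = math.sin(theta)
    for k in range(a, b + 1):
        px = P[k, 0] - ox
        py = P[k, 1] - oy
        pz = P[k, 2] - oz
        d = px * ux + py * uy + pz * uz
        cx = uy * pz - uz * py
        cy = uz * px - ux * pz
        cz = ux * py - uy * px
        P[k, 0] = ox + px * c + cx * s + ux * d * (1.0 - c)
        P[k, 1] = oy + py * c + cy * s + uy * d * (1.0 - c)
        P[k, 2] = oz + pz * c + cz * s + uz * d * (1.0 - c)


@njit(cache=True)
def _sweep(
    P,
    cls,
    scratch,
    n,
    dlk,
    wr,
    s_bend,
    k_bend,
    f_red,
    k_tw,
    seglen,
    reach,
    kink_a,
    kink_b,
    kinds,
    ia,
    ja,
    angles,
    axes,
    uacc,
):
    """Run a block of local moves in place; returns (wr, s_bend, n_accept).

    ``P`` is the closed polygon (chain vertices 0..n, then the four closure
    vertices); the closure vertex above the free end follows it laterally.
    Writhe and the bend sum are maintained incrementally: only Gauss pair
    terms involving changed segments are re-evaluated.
    """
    M = P.shape[0]
    nacc = 0
    for m in range(kinds.shape[0]):
        theta = angles[m]
        if kinds[m] == 0:
            i = ia[m]
            j = ja[m]
            if i == kink_a or i == kink_b or j == kink_a or j == kink_b:
                continue
            axx = P[j, 0] - P[i, 0]
            axy = P[j, 1] - P[i, 1]
            axz = P[j, 2] - P[i, 2]
            norm = math.sqrt(axx * axx + axy * axy + axz * axz)
            if norm < 1e-12:
                continue
            axx /= norm
            axy /= norm
            axz /= norm
            for k in range(M):
                cls[k] = 0
            cls[i] = 2
            cls[j - 1] = 2
            for k in range(i + 1, j - 1):
                cls[k] = 1
            b_old = _joint_bend(P, i) + _joint_bend(P, j)
            w_old = writhe_pairs_partial(P, cls)
            nb = j - 1 - i
            for k in range(nb):
                scratch[k, 0] = P[i + 1 + k, 0]
                scratch[k, 1] = P[i + 1 + k, 1]
                scratch[k, 2] = P[i + 1 + k, 2]
            _rotate_block(P, i + 1, j - 1, P[i, 0], P[i, 1], P[i, 2],
                          axx, axy, axz, theta)
            b_new = _joint_bend(P, i) + _joint_bend(P, j)
            w_new = writhe_pairs_partial(P, cls)
            dwr = w_new - w_old
            de = k_bend * (b_new - b_old) + k_tw * (
                (dlk - wr - dwr) ** 2 - (dlk - wr) ** 2
            )
            if de <= 0.0 or uacc[m] < math.exp(-de):
                wr += dwr
                s_bend += b_new - b_old
                nacc += 1
            else:
                for k in range(nb):
                    P[i + 1 + k, 0] = scratch[k, 0]
                    P[i + 1 + k, 1] = scratch[k, 1]
                    P[i + 1 + k, 2] = scratch[k, 2]
        else:
            p = ia[m]
            if p == kink_a or p == kink_b:
                continue
            for k in range(M):
                cls[k] = 0
            cls[p] = 2
            for k in range(p + 1, n - 1):
                cls[k] = 1
            cls[n - 1] = 2
            cls[n] = 2
            cls[n + 1] = 2
            b_old = _joint_bend(P, p) + _joint_bend(P, n - 1)
            z_old = P[n, 2]
            w_old = writhe_pairs_partial(P, cls)
            nb = n - p  # vertices p+1 .. n
            for k in range(nb):
                scratch[k, 0] = P[p + 1 + k, 0]
                scratch[k, 1] = P[p + 1 + k, 1]
                scratch[k, 2] = P[p + 1 + k, 2]
            scratch[nb, 0] = P[n + 1, 0]
            scratch[nb, 1] = P[n + 1, 1]
            scratch[nb, 2] = P[n + 1, 2]
            _rotate_block(P, p + 1, n - 1, P[p, 0], P[p, 1], P[p, 2],
                          axes[m, 0], axes[m, 1], axes[m, 2], theta)
            P[n, 0] = P[n - 1, 0]
            P[n, 1] = P[n - 1, 1]
            P[n, 2] = P[n - 1, 2] + seglen
            P[n + 1, 0] = P[n, 0]
            P[n + 1, 1] = P[n, 1]
            P[n + 1, 2] = reach
            b_new = _joint_bend(P, p) + _joint_bend(P, n - 1)
            z_new = P[n, 2]
            w_new = writhe_pairs_partial(P, cls)
            dwr = w_new - w_old
            de = (
                k_bend * (b_new - b_old)
                - f_red * (z_new - z_old)
                + k_tw * ((dlk - wr - dwr) ** 2 - (dlk - wr) ** 2)
            )
            if de <= 0.0 or uacc[m] < math.exp(-de):
                wr += dwr
                s_bend += b_new - b_old
                nacc += 1
            else:
                for k in range(nb):
                    P[p + 1 + k, 0] = scratch[k, 0]
                    P[p + 1 + k, 1] = scratch[k, 1]
                    P[p + 1 + k, 2] = scratch[k, 2]
                P[n + 1, 0] = scratch[nb, 0]
                P[n + 1, 1] = scratch[nb, 1]
                P[n + 1, 2] = scratch[nb, 2]
    return wr, s_bend, nacc


# ---------------------------------------------------------------------------
# Replica-exchange sampler
# ---------------------------------------------------------------------------

class _ReplicaState:
    __slots__ = ("P", "wr", "s_bend", "checkpoint")

    def __init__(self, P, wr, s_bend):
        self.P = P
        self.wr = wr
        self.s_bend = s_bend
        self.checkpoint = (P.copy(), wr, s_bend)


def _initial_state(cfg: SamplerConfig, dlk: float) -> _ReplicaState:
    conf = bent_initial_chain(cfg, dlk) if cfg.bend_constraint else straight_chain(cfg, dlk)
    P = close_chain(conf.vertices, cfg.closure_reach)
    wr = float(writhe_closed(P))
    return _ReplicaState(P, wr, bend_sum(conf.vertices))


def run_sampler(cfg: SamplerConfig) -> Ensemble:
    """Sample the replica ensemble; one replica per dlk_grid entry.

    Each cycle applies ``local_moves_per_cycle`` move trials per replica
    followed by exchange trials between neighboring linking numbers; a save
    of all replicas is triggered after ``exchange_saves_threshold``
    successful exchanges (between any neighboring pair).  Knot checks run
    every ``knot_check_interval`` moves and before every save, reverting a
    knotted replica to its last knot-free checkpoint.  Replica dLk labels
    are fixed to replicas; exchanges swap conformations, never labels.
    """
    n = cfg.n_segments
    n_rep = len(cfg.dlk_grid)
    states = [_initial_state(cfg, d) for d in cfg.dlk_grid]
    rngs = [np.random.default_rng(cfg.seed + 1 + r) for r in range(n_rep)]
    ex_rng = np.random.default_rng(cfg.seed + 10_000_019)

    cls = np.zeros(n + 5, dtype=np.int64)
    scratch = np.zeros((n + 2, 3))
    saves = [
        {"ext": [], "wr": [], "en": [], "conf": [] if cfg.store_conformations else None}
        for _ in range(n_rep)
    ]
    if cfg.bend_constraint is not None:
        kink_a = cfg.kink_joint
        kink_b = kink_a + 1
    else:
        kink_a = kink_b = -1

    amp = math.radians(cfg.move_amplitude)
    n_local_acc = 0
    n_local_try = 0
    n_ex_acc = 0
    n_ex_try = 0
    knot_rejects = 0
    success_counter = 0
    n_saved = 0
    cycle = 0
    max_cycles = cfg.max_cycles or (1000 + 200 * cfg.save_target + cfg.burn_in_cycles)

    def total_en(st: _ReplicaState, dlk: float) -> float:
        return (
            cfg.k_bend * st.s_bend
            - cfg.f_reduced * (st.P[n, 2] - st.P[0, 2])
            + cfg.k_twist * (dlk - st.wr) ** 2
        )

    def run_knot_check(r: int) -> None:
        nonlocal knot_rejects
        st = states[r]
        if alexander_determinant(st.P) != 1:
            st.P[:] = st.checkpoint[0]
            st.wr = st.checkpoint[1]
            st.s_bend = st.checkpoint[2]
            knot_rejects += 1
        else:
            st.checkpoint = (st.P.copy(), st.wr, st.s_bend)

    moves_since_check = 0
    while n_saved < cfg.save_target:
        cycle += 1
        if cycle > max_cycles:
            warnings.warn(
                "run_sampler hit max_cycles before reaching save_target; "
                "returning a truncated ensemble"
            )
            break
        # -- local moves, chunked at the knot-check cadence
        remaining = cfg.local_moves_per_cycle
        while remaining > 0:
            chunk = min(remaining, cfg.knot_check_interval - moves_since_check)
            for r in range(n_rep):
                rng = rngs[r]
                kinds = (rng.random(chunk) < 0.5).astype(np.uint8)
                ia = rng.integers(1, n - 2, size=chunk)
                ja = ia + 2 + rng.integers(0, np.maximum(n - 1 - (ia + 2), 0) + 1)
                pivots = kinds == 1
                ia = np.where(pivots, rng.integers(1, n - 1, size=chunk), ia)
                angles = amp * (2.0 * rng.random(chunk) - 1.0)
                axes = rng.normal(size=(chunk, 3))
                axes /= np.linalg.norm(axes, axis=1)[:, None]
                uacc = rng.random(chunk)
                st = states[r]
                st.wr, st.s_bend, acc = _sweep(
                    st.P, cls, scratch, n, cfg.dlk_grid[r], st.wr, st.s_bend,
                    cfg.k_bend, cfg.f_reduced, cfg.k_twist,
                    cfg.segment_length, cfg.closure_reach,
                    kink_a, kink_b, kinds, ia, ja, angles, axes, uacc,
                )
                n_local_acc += acc
                n_local_try += chunk
            remaining -= chunk
            moves_since_check += chunk
            if moves_since_check >= cfg.knot_check_interval:
                for r in range(n_rep):
                    run_knot_check(r)
                moves_since_check = 0
        # -- replica exchange between neighbors (alternating parity); a
        # single-replica run has no exchange partners, so each cycle counts
        # toward the save cadence instead
        if n_rep == 1:
            success_counter += 1
        start = cycle % 2
        for r in range(start, n_rep - 1, 2):
            de = 2.0 * cfg.k_twist * (
                (cfg.dlk_grid[r] - cfg.dlk_grid[r + 1])
                * (states[r].wr - states[r + 1].wr)
            )
            n_ex_try += 1
            if metropolis_accept(de, ex_rng):
                states[r], states[r + 1] = states[r + 1], states[r]
                n_ex_acc += 1
                success_counter += 1
        # -- save rule
        if success_counter >= cfg.exchange_saves_threshold and cycle > cfg.burn_in_cycles:
            success_counter = 0
            for r in range(n_rep):
                run_knot_check(r)
            moves_since_check = 0
            for r in range(n_rep):
                st = states[r]
                saves[r]["ext"].append(st.P[n, 2] - st.P[0, 2])
                saves[r]["wr"].append(st.wr)
                saves[r]["en"].append(total_en(st, cfg.dlk_grid[r]))
                if cfg.store_conformations:
                    saves[r]["conf"].append(st.P[: n + 1].copy())
            n_saved += 1

    replicas = []
    for r in range(n_rep):
        ext = np.asarray(saves[r]["ext"])
        warn = False
        if ext.size >= 9:
            third = ext.size // 3
            m2 = ext[third : 2 * third].mean()
            m3 = ext[2 * third :].mean()
            warn = abs(m3 - m2) > 0.05 * max(abs(ext.mean()), 1.0)
        replicas.append(
            ReplicaSamples(
                dlk=cfg.dlk_grid[r],
                extensions=ext,
                writhes=np.asarray(saves[r]["wr"]),
                energies=np.asarray(saves[r]["en"]),
                conformations=saves[r]["conf"],
                equilibration_warning=warn,
            )
        )
    return Ensemble(
        config=cfg,
        replicas=replicas,
        local_acceptance=n_local_acc / max(n_local_try, 1),
        exchange_acceptance=n_ex_acc / max(n_ex_try, 1),
        knot_rejections=knot_rejects,
    )


# ---------------------------------------------------------------------------
# Distance statistics
# ---------------------------------------------------------------------------

def distance_distribution(
    ensemble_or_confs,
    min_contour_separation: int = 10,
    replica: int = 0,
    n_bins: int = 200,
    r_max: Optional[float] = None,
    sigma: Optional[float] = None,
    force: Optional[float] = None,
) -> DistanceDistribution:
    """Histogram of site-to-site distances R over saved conformations.

    Pools pairwise vertex distances for vertex pairs at contour separation
    >= ``min_contour_separation`` segments, over the saved conformations of
    one replica (or an explicit list of vertex arrays).  The returned masses
    sum to 1.
    """
    if isinstance(ensemble_or_confs, Ensemble):
        rep = ensemble_or_confs.replicas[replica]
        if rep.conformations is None:
            raise ValueError("ensemble was sampled without stored conformations")
        confs = rep.conformations
    else:
        confs = list(ensemble_or_confs)
    if not confs:
        raise ValueError("no conformations to analyze")
    nv = confs[0].shape[0]
    ii, jj = np.triu_indices(nv, k=int(min_contour_separation))
    if ii.size == 0:
        raise ValueError("no vertex pairs at the requested contour separation")
    dists = np.concatenate(
        [np.linalg.norm(c[ii] - c[jj], axis=1) for c in confs]
    )
    hi = float(r_max) if r_max is not None else float(dists.max()) * 1.0000001
    counts, edges = np.histogram(dists, bins=n_bins, range=(0.0, hi))
    masses = counts / counts.sum()
    return DistanceDistribution(
        bin_edges=edges, masses=masses, n_pairs=dists.size, sigma=sigma, force=force
    )


def wlc_extension_fraction(force_pn: float, lp_nm: float, kbt_pn_nm: float = 4.09) -> float:
    """Relative extension x/L from the worm-like-chain interpolation formula.

    Solves F = (k_BT/L_p) [ 1/(4(1-x)^2) - 1/4 + x ] for x in (0, 1).
    """
    from scipy.optimize import brentq

    fr = force_pn * lp_nm / kbt_pn_nm

    def g(x):
        return 0.25 / (1.0 - x) ** 2 - 0.25 + x - fr

    return brentq(g, 1e-9, 1.0 - 1e-9)
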