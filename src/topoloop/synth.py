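"""Synthetic single-molecule data with the statistical structure the
analysis pipeline assumes.

Generates 40 fps bead traces with Ornstein-Uhlenbeck measurement noise,
naked-DNA and chromatin extension-versus-turns calibrations, stochastic
topo II stepping (linking-number steps of 2 at exponential waiting times with
a Michaelis-Menten rate set by the loop-formation rate k(sigma)), exponential
activity lifetimes, long pauses, and rare contaminating second-enzyme binding
events.  Every generator returns a ground-truth log so each analysis stage
can be checked against what was actually simulated.

The default parameters are the measured study conditions: a 12.7 kb tether
(relaxed linking number Lk0 = n_bp / 10.5), V_max = 3.4 / 3.1 / 3.0 turns/s
at 0.5 / 1.1 / 1.6 pN, k_1/2 = 6.8 loops/s, 2-turn strand-passage steps,
pre-buckled activity lifetime 8.9 min, ~50-nucleosome fibers absorbing about
1 turn each, and a 17% / 30 min contamination probability.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import kinetics, mechanics
from .clamp import ControllerConfig, ProtocolStep, protocol_duration, controller_update
from .kinetics import CrossingRateTable, RelaxationModel, TrajectoryData
from .mechanics import ChromatinBenchmark, ChromatinCalibration, NakedCalibration
from .traces import ActivityRecord, BeadTrace, write_trace
from .wlc import wlc_extension_fraction

__all__ = [
    "EnzymeModel",
    "SubstrateSpec",
    "NoiseModel",
    "naked_calibration",
    "chromatin_curve",
    "parametric_rate_table",
    "TetherPlant",
    "simulate_topo_trace",
    "simulate_activity_records",
    "simulate_prebuckled_timecourses",
    "inject_contamination",
    "make_default_benchmark",
    "generate_fixture_suite",
]

RISE_NM_PER_BP = 0.338
HELICAL_REPEAT_BP = 10.5

#: plectonemic wing slope (nm per turn) and buckling superhelical density
#: by force (pN); interpolated for other forces
_WING_SLOPE = {0.5: 55.0, 1.1: 42.0, 1.6: 38.0}
_SIGMA_BUCKLE = {0.5: 0.011, 1.1: 0.015, 1.6: 0.018}


def _by_force(table: dict, force: float) -> float:
    fs = np.array(sorted(table))
    vs = np.array([table[f] for f in fs])
    return float(np.interp(force, fs, vs))


@dataclass(frozen=True)
class EnzymeModel:
    """Stochastic topo II model: Michaelis-Menten stepping, lifetime, pauses."""

    v_max: dict = field(default_factory=lambda: {0.5: 3.4, 1.1: 3.1, 1.6: 3.0})
    k_half: float = 6.8  # loops/s
    step_size: float = 2.0  # turns per strand passage
    lifetime_mean_s: float = 8.9 * 60.0  # pre-buckled naked-DNA default
    pause_rate_per_s: float = -math.log(0.6) / 1800.0  # 40% of 30 min traces pause
    pause_duration_median_s: float = 60.0
    pause_duration_sigma: float = 0.5  # lognormal shape
    contamination_p_30min: float = 0.17

    def __post_init__(self):
        if self.step_size != 2.0:
            raise ValueError("type IIA strand passage changes Lk in steps of 2")
        if self.k_half <= 0 or self.lifetime_mean_s <= 0:
            raise ValueError("rates and lifetimes must be positive")

    @property
    def contamination_rate_per_s(self) -> float:
        return -math.log(1.0 - self.contamination_p_30min) / 1800.0

    def relaxation_model(self, diffusion_d: float = 1.0e7) -> RelaxationModel:
        return RelaxationModel(v_max=dict(self.v_max), k_half=self.k_half,
                               diffusion_d=diffusion_d)


@dataclass(frozen=True)
class SubstrateSpec:
    """Tether substrate: naked DNA or a nucleosome array on the same DNA."""

    kind: str = "naked"  # 'naked' | 'chromatin'
    n_bp: int = 12688
    n_nuc: int = 0
    turns_per_nucleosome: float = 1.0
    nucleosome_loss_rate_per_min: float = 1.0 / 30.0
    wrap_nm_per_nucleosome: float = 50.0  # ~147 bp of wrapped DNA

    def __post_init__(self):
        if self.kind not in ("naked", "chromatin"):
            raise ValueError("kind must be 'naked' or 'chromatin'")
        if self.kind == "chromatin" and self.n_nuc <= 0:
            raise ValueError("chromatin requires n_nuc > 0")

    @property
    def lk0(self) -> float:
        return self.n_bp / HELICAL_REPEAT_BP

    @property
    def contour_length(self) -> float:
        return self.n_bp * RISE_NM_PER_BP


@dataclass(frozen=True)
class NoiseModel:
    """Ornstein-Uhlenbeck extension noise at the camera frame rate."""

    extension_sd: float = 15.0  # nm at 40 fps
    correlation_time: float = 0.05  # s

    def __post_init__(self):
        if self.extension_sd < 0:
            raise ValueError("noise SD must be nonnegative")


class _OUState:
    def __init__(self, noise: NoiseModel, dt: float):
        self.sd = noise.extension_sd
        self.rho = math.exp(-dt / noise.correlation_time) if noise.correlation_time > 0 else 0.0
        self.x = 0.0

    def step(self, rng: np.random.Generator) -> float:
        if self.sd == 0.0:
            return 0.0
        self.x = self.rho * self.x + self.sd * math.sqrt(1.0 - self.rho**2) * rng.standard_normal()
        return self.x


# ---------------------------------------------------------------------------
# Calibrations
# ---------------------------------------------------------------------------

def naked_calibration(spec: SubstrateSpec, force: float = 0.5) -> NakedCalibration:
    """Default naked-DNA extension-turns relation for the tether at a force."""
    lc = spec.contour_length
    e0 = wlc_extension_fraction(force, 50.0) * lc
    bk = _by_force(_SIGMA_BUCKLE, force) * spec.lk0
    a = 0.03 * e0 / bk**2  # ~3% extension drop at the buckling transition
    s = _by_force(_WING_SLOPE, force)
    return NakedCalibration(x0=0.0, e0=e0, a=a, bm=bk, bp=bk,
                            s_left=s, s_right=-s, force=force)


def chromatin_curve(spec: SubstrateSpec, force: float = 0.5):
    """Five-piece extension-turns curve of a nucleosome array.

    The outer branches mirror the naked plectonemic slopes; the plateau width
    is n_nuc x turns_per_nucleosome with a slight negative slope; the peak
    extension is reduced by the wrapped DNA length.  With n_nuc = 0 the naked
    calibration is returned (contract, not an error).
    """
    if spec.n_nuc == 0:
        return naked_calibration(spec, force)
    lc_free = spec.contour_length - spec.wrap_nm_per_nucleosome * spec.n_nuc
    if lc_free <= 0:
        raise ValueError("nucleosomes wrap more DNA than the tether contains")
    peak = wlc_extension_fraction(force, 50.0) * lc_free
    s = _by_force(_WING_SLOPE, force)
    c1 = 0.0
    c2 = spec.n_nuc * spec.turns_per_nucleosome
    return ChromatinCalibration(
        s1=s, s2=-2.0, s3=-s, c1=c1, c2=c2, h1=2.5, h2=2.5,
        y_ref=peak, force=force, n_nuc_estimate=float(spec.n_nuc),
    )


def parametric_rate_table(
    force: float = 0.5,
    k_sat: float = 200.0,
    sigma_buckle: Optional[float] = None,
    n_points: int = 121,
    sigma_max: float = 0.06,
) -> CrossingRateTable:
    """Parametric stand-in for the loop-formation rate k(sigma).

    k(sigma) = k_sat u^4 / (1 + u^4) with u = |sigma| / sigma_buckle: nearly
    zero on relaxed DNA, rising steeply toward the buckling transition and
    saturating beyond it.  Keeps fixtures fast; the Monte Carlo ensemble
    route produces tables of the same shape.
    """
    sb = _by_force(_SIGMA_BUCKLE, force) if sigma_buckle is None else sigma_buckle
    sig = np.linspace(0.0, sigma_max, n_points)
    u4 = (sig / sb) ** 4
    k = k_sat * u4 / (1.0 + u4)
    k[0] = 1e-12  # strictly positive for the table contract
    return CrossingRateTable(sigmas=sig, ks=k, force=force)


# ---------------------------------------------------------------------------
# Plant for closed-loop clamp simulations
# ---------------------------------------------------------------------------

class TetherPlant:
    """Substrate + enzyme model driven frame by frame by the clamp loop.

    ``enzyme`` selects the activity model: 'off', 'constant' (continuous
    relaxation at ``enzyme_rate`` turns/s) or 'stepping' (Poisson strand
    passages of -2 sign(dLk) turns at ``enzyme_rate``/2 events per second).
    """

    def __init__(self, calibration, dlk0: float, force: float = 0.5,
                 noise: Optional[NoiseModel] = None, enzyme: str = "constant",
                 enzyme_rate: float = 3.0, frame_rate: float = 40.0):
        self.calibration = calibration
        self.dlk0 = float(dlk0)
        self.force = force
        self.enzyme = enzyme
        self.enzyme_rate = enzyme_rate
        self.noise = noise or NoiseModel(extension_sd=0.0)
        self._ou = _OUState(self.noise, 1.0 / frame_rate)

    @property
    def wind_sign(self) -> float:
        """Winding direction that lowers extension at the operating point."""
        return 1.0 if self.dlk0 >= 0 else -1.0

    def extension(self, dlk: float, rng: np.random.Generator) -> float:
        return float(self.calibration.ext(dlk)) + self._ou.step(rng)

    def in_domain(self, dlk: float) -> bool:
        return bool(self.calibration.ext(dlk) > 0.0)

    def enzyme_delta(self, t: float, dlk: float, dt: float,
                     rng: np.random.Generator) -> float:
        if self.enzyme == "off" or dlk == 0.0:
            return 0.0
        sgn = math.copysign(1.0, dlk)
        if self.enzyme == "constant":
            return -sgn * min(self.enzyme_rate * dt, abs(dlk))
        if self.enzyme == "stepping":
            lam = self.enzyme_rate / 2.0
            if rng.random() < -math.expm1(-lam * dt):
                return -sgn * min(2.0, abs(dlk))
            return 0.0
        raise ValueError(f"unknown enzyme mode {self.enzyme!r}")


# ---------------------------------------------------------------------------
# Event-driven trace generator
# ---------------------------------------------------------------------------

def simulate_topo_trace(
    substrate: SubstrateSpec,
    enzyme: EnzymeModel,
    protocol: Sequence[ProtocolStep],
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    force: float = 0.5,
    calibration=None,
    rate_table: Optional[CrossingRateTable] = None,
    frame_rate: float = 40.0,
    clamp_gain: float = 0.05,
    clamp_block: int = 5,
    clamp_max_rate: float = 10.0,
):
    """Simulate one 40 fps bead trace through a winding/wait/clamp protocol.

    Strand passages of -2 sign(dLk) turns occur at exponential waiting times
    with instantaneous rate V_max(F) k(sigma) / (k + k_1/2) / 2 events per
    second; the enzyme dies at an exponential lifetime; long pauses are
    injected at a Poisson rate with lognormal durations.  Extension is the
    calibration of the instantaneous dLk plus OU noise.  Returns the trace
    and a ground-truth log of every event.
    """
    rng = np.random.default_rng(seed)
    cal = calibration if calibration is not None else (
        chromatin_curve(substrate, force) if substrate.kind == "chromatin"
        else naked_calibration(substrate, force)
    )
    table = rate_table if rate_table is not None else parametric_rate_table(force)
    model = enzyme.relaxation_model()
    vmax = model.vmax_at(force)
    dt = 1.0 / frame_rate
    ou = _OUState(noise, dt)

    death_time = rng.exponential(enzyme.lifetime_mean_s)
    pauses = []
    t_cursor = 0.0
    total_t = sum(
        protocol_duration(s) if s.kind == "wind" else float(s.duration or 0.0)
        for s in protocol
    )
    # pre-draw the pause process over the whole trace
    t = rng.exponential(1.0 / enzyme.pause_rate_per_s) if enzyme.pause_rate_per_s > 0 else math.inf
    while t < total_t:
        d = float(rng.lognormal(math.log(enzyme.pause_duration_median_s),
                                enzyme.pause_duration_sigma))
        pauses.append((t, t + d))
        t = t + d + rng.exponential(1.0 / enzyme.pause_rate_per_s)

    def paused(tt: float) -> bool:
        return any(a <= tt < b for a, b in pauses)

    times, exts, mags = [], [], []
    annotations = []
    passage_times = []
    dlk_truth = []
    dlk = 0.0
    magnet = 0.0
    t_now = 0.0

    def step_frame(magnet_rate: float):
        nonlocal dlk, magnet, t_now
        if t_now < death_time and not paused(t_now) and dlk != 0.0:
            sigma = dlk / substrate.lk0
            k = float(table.k_of_sigma(sigma))
            lam = vmax * k / (k + enzyme.k_half) / enzyme.step_size
            if rng.random() < -math.expm1(-lam * dt):
                sgn = math.copysign(1.0, dlk)
                dlk -= sgn * min(enzyme.step_size, abs(dlk))
                passage_times.append(t_now)
        d_mag = magnet_rate * dt
        dlk += d_mag
        magnet += d_mag
        times.append(t_now)
        exts.append(float(cal.ext(dlk)) + ou.step(rng))
        mags.append(magnet)
        dlk_truth.append(dlk)
        t_now += dt

    for step in protocol:
        if step.kind == "wind":
            dur = protocol_duration(step)
            n_frames = max(int(round(dur * frame_rate)), 1) if step.turns else 0
            rate = step.turns / (n_frames * dt) if n_frames else 0.0
            annotations.append({
                "kind": "wind", "time": t_now, "turns": step.turns,
                "rate": step.rate, "duration": dur,
            })
            for _ in range(n_frames):
                step_frame(rate)
        elif step.kind == "wait":
            annotations.append({"kind": "wait", "time": t_now,
                                "duration": step.duration})
            for _ in range(int(round(step.duration * frame_rate))):
                step_frame(0.0)
        else:  # clamp
            setpoint = float(cal.ext(dlk))
            annotations.append({"kind": "clamp_on", "time": t_now,
                                "setpoint": setpoint})
            ctl = ControllerConfig(setpoint=setpoint, gain=clamp_gain,
                                   frame_rate=frame_rate, block=clamp_block,
                                   max_rate=clamp_max_rate)
            wind_sign = 1.0 if dlk >= 0 else -1.0
            err_buf = []
            magnet_rate = 0.0
            for _ in range(int(round(step.duration * frame_rate))):
                step_frame(magnet_rate)
                err_buf.append(exts[-1] - setpoint)
                if len(err_buf) == clamp_block:
                    magnet_rate = controller_update(err_buf, ctl) * wind_sign
                    err_buf = []
            annotations.append({"kind": "clamp_off", "time": t_now})

    trace = BeadTrace(
        time=np.asarray(times), extension=np.asarray(exts),
        magnet_turns=np.asarray(mags), force=force, annotations=annotations,
    )
    log = {
        "dlk": np.asarray(dlk_truth),
        "passage_times": np.asarray(passage_times),
        "death_time": float(death_time),
        "pauses": pauses,
        "turns_relaxed": 2.0 * len(passage_times),
        "calibration": cal,
    }
    return trace, log


def simulate_activity_records(
    n: int,
    lifetime_mean_s: float,
    rate_turns_per_s: float,
    observation_window_s: float,
    seed: int = 0,
) -> list:
    """Record-level generator: i.i.d. exponential activity lifetimes.

    Records still active at the end of the observation window are censored;
    turns relaxed accumulate at ``rate_turns_per_s`` while active, so the
    ground-truth processivity is rate x lifetime.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        life = rng.exponential(lifetime_mean_s)
        censored = life >= observation_window_s
        dur = min(life, observation_window_s)
        out.append(ActivityRecord(
            active_duration=float(dur),
            turns_relaxed=float(rate_turns_per_s * dur),
            first_pause_time=None if censored else float(dur),
            censored=bool(censored),
        ))
    return out


def simulate_prebuckled_timecourses(
    forces: Sequence[float] = (0.5, 1.1, 1.6),
    k_half_true: float = 6.8,
    sigma0: Optional[float] = None,
    t_grid: Optional[np.ndarray] = None,
    noise_frac: float = 0.05,
    n_traces: int = 10,
    seed: int = 0,
    enzyme: Optional[EnzymeModel] = None,
    substrate: Optional[SubstrateSpec] = None,
) -> list:
    """Noisy sigma(t) relaxation time courses at several forces.

    The mean curve integrates the Michaelis-Menten relaxation with the true
    k_1/2 from the buckling transition into the pre-buckled regime; each
    returned trajectory carries the SEM of ``n_traces`` noisy repeats.
    """
    rng = np.random.default_rng(seed)
    enzyme = enzyme or EnzymeModel(k_half=k_half_true)
    substrate = substrate or SubstrateSpec()
    model = enzyme.relaxation_model()
    out = []
    for force in forces:
        table = parametric_rate_table(force)
        s0 = _by_force(_SIGMA_BUCKLE, force) if sigma0 is None else sigma0
        tg = np.linspace(0.0, 15.0, 16) if t_grid is None else np.asarray(t_grid)
        clean = kinetics.integrate_relaxation(
            s0, table, model, force, tg, substrate.lk0, k_half=k_half_true
        )
        scale = noise_frac * abs(s0)
        reps = clean[None, :] + scale * rng.standard_normal((n_traces, tg.size))
        sig = reps.mean(axis=0)
        sig[0] = s0  # the initial state is set by the protocol, not measured
        sem = np.full(tg.size, scale / math.sqrt(n_traces))
        out.append(TrajectoryData(t=tg, sigma=sig, force=force, sem=sem))
    return out


def inject_contamination(trace: BeadTrace, enzyme: EnzymeModel, seed: int = 0,
                         calibration=None, log=None):
    """Add Poisson-timed second-enzyme binding events to a trace.

    Binding times follow the memoryless rate implied by the long-window
    contamination probability (17% / 30 min by default).  When the ground
    truth (``log`` with per-frame dLk) and a calibration are available, the
    second enzyme's relaxation (steps of -2 sign(dLk) at the saturated rate)
    is applied to the extension; rate-doubling episodes then appear during
    clamps.  Returns (trace, binding_times).
    """
    rng = np.random.default_rng(seed)
    lam = enzyme.contamination_rate_per_s
    duration = float(trace.time[-1] - trace.time[0]) + (trace.dt if trace.time.size else 0.0)
    t = rng.exponential(1.0 / lam) if lam > 0 else math.inf
    binds = []
    while t < duration:
        binds.append(t)
        t += rng.exponential(1.0 / lam)
    if not binds:
        return trace, []
    annotations = trace.annotations + [
        {"kind": "contamination_binding", "time": float(b)} for b in binds
    ]
    extension = trace.extension.copy()
    if calibration is not None and log is not None:
        dlk = log["dlk"].copy()
        vmax = _by_force(enzyme.v_max, trace.force)
        extra = 0.0
        dt = trace.dt
        t0 = float(trace.time[0])
        for i, tt in enumerate(trace.time):
            if (tt - t0) >= binds[0] and dlk[i] != 0.0:
                lam2 = vmax / enzyme.step_size
                if rng.random() < -math.expm1(-lam2 * dt):
                    extra -= math.copysign(1.0, dlk[i]) * enzyme.step_size
            dlk[i] += extra
            extension[i] = float(calibration.ext(dlk[i])) + (
                extension[i] - float(calibration.ext(log["dlk"][i]))
            )
    new = BeadTrace(
        time=trace.time.copy(), extension=extension,
        magnet_turns=trace.magnet_turns.copy(), force=trace.force,
        annotations=annotations,
    )
    return new, binds


def make_default_benchmark(force: float = 0.5, ci_turns: float = 2.0,
                           peak_noise: float = 0.0) -> ChromatinBenchmark:
    """Benchmark lines (peak extension and w_t+- vs N_nuc) from the generator."""
    ns = np.arange(30, 71, 5, dtype=float)
    peaks, wtp, wtm = [], [], []
    for n in ns:
        cal = chromatin_curve(SubstrateSpec(kind="chromatin", n_nuc=int(n)), force)
        peaks.append(cal.peak_extension)
        wtp.append(cal.w_t_plus)
        wtm.append(cal.w_t_minus)
    p = np.polyfit(ns, peaks, 1)
    a = np.polyfit(ns, wtp, 1)
    m = np.polyfit(ns, wtm, 1)
    return ChromatinBenchmark(
        peak_line=(float(p[1]), float(p[0])),
        wt_plus_line=(float(a[1]), float(a[0])),
        wt_minus_line=(float(m[1]), float(m[0])),
        wt_plus_ci=ci_turns,
        wt_minus_ci=ci_turns,
    )


# ---------------------------------------------------------------------------
# Fixture suite
# ---------------------------------------------------------------------------

def generate_fixture_suite(seed: int, outdir) -> dict:
    """Write a deterministic set of synthetic fixtures as delimited text.

    Covers: naked and chromatin calibrations, a buckled-state clamp trace,
    pre-buckled repeated-winding traces of both signs, a chromatin clamp
    trace, and pre-buckled relaxation time courses at 0.5/1.1/1.6 pN.  The
    manifest records seeds, parameters and ground truth.  Identical seeds
    produce byte-identical output.
    """
    os.makedirs(outdir, exist_ok=True)
    manifest = {"seed": int(seed), "files": {}}
    spec = SubstrateSpec()
    enzyme = EnzymeModel()
    rng = np.random.default_rng(seed)

    def save_curve(name, turns, ext):
        path = os.path.join(outdir, name)
        with open(path, "w") as fh:
            fh.write("turns\textension_nm\n")
            for x, y in zip(turns, ext):
                fh.write(f"{x:.4f}\t{y:.6f}\n")
        return name

    cal = naked_calibration(spec, 0.5)
    turns = np.arange(-25.0, 25.01, 0.5)
    ext = cal.ext(turns) + 5.0 * rng.standard_normal(turns.size)
    manifest["files"]["naked_calibration"] = save_curve(
        "naked_calibration_0.5pN.tsv", turns, ext)

    chrom = SubstrateSpec(kind="chromatin", n_nuc=50)
    ccal = chromatin_curve(chrom, 0.5)
    cturns = np.arange(-40.0, 70.01, 1.0)
    cext = ccal.ext(cturns) + 5.0 * rng.standard_normal(cturns.size)
    manifest["files"]["chromatin_calibration"] = save_curve(
        "chromatin_calibration_50nuc.tsv", cturns, cext)
    manifest["chromatin_n_nuc"] = 50

    protocols = {
        "naked_buckled_clamp": (spec, [ProtocolStep("wind", turns=30.0),
                                       ProtocolStep("clamp", duration=60.0)]),
        "naked_prebuckled_plus": (spec, [ProtocolStep("wind", turns=30.0),
                                         ProtocolStep("wait", duration=60.0),
                                         ProtocolStep("wind", turns=30.0),
                                         ProtocolStep("wait", duration=60.0)]),
        "naked_prebuckled_minus": (spec, [ProtocolStep("wind", turns=-30.0),
                                          ProtocolStep("wait", duration=60.0),
                                          ProtocolStep("wind", turns=-30.0),
                                          ProtocolStep("wait", duration=60.0)]),
        "chromatin_clamp": (chrom, [ProtocolStep("wind", turns=60.0),
                                    ProtocolStep("clamp", duration=60.0)]),
        "chromatin_low_torsion": (chrom, [ProtocolStep("wind", turns=20.0),
                                          ProtocolStep("wait", duration=60.0),
                                          ProtocolStep("wind", turns=20.0),
                                          ProtocolStep("wait", duration=60.0)]),
    }
    for i, (name, (sub, prot)) in enumerate(sorted(protocols.items())):
        trace, log = simulate_topo_trace(
            sub, enzyme, prot, NoiseModel(), seed=seed + 100 + i, force=0.5)
        fname = f"trace_{name}.tsv"
        write_trace(trace, os.path.join(outdir, fname))
        manifest["files"][name] = fname
        manifest.setdefault("ground_truth", {})[name] = {
            "turns_relaxed": log["turns_relaxed"],
            "death_time_s": log["death_time"],
            "n_pauses": len(log["pauses"]),
        }

    trajs = simulate_prebuckled_timecourses(seed=seed + 500)
    for traj in trajs:
        fname = f"prebuckled_timecourse_{traj.force:.1f}pN.tsv"
        with open(os.path.join(outdir, fname), "w") as fh:
            fh.write("t_s\tsigma\tsem\n")
            for t, s, e in zip(traj.t, traj.sigma, traj.sem):
                fh.write(f"{t:.4f}\t{s:.8f}\t{e:.8f}\n")
        manifest["files"][f"timecourse_{traj.force:.1f}pN"] = fname
    manifest["k_half_true"] = 6.8

    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    return manifest
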