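"""Constant-extension feedback clamp and winding protocols.

The extension clamp is a proportional controller: every ``block`` camera
frames, the mean extension error over those frames is multiplied by the gain
(0.05 turns/s per nm) to set the magnet rotation rate (zero-order hold
between updates, saturated at ``max_rate``).  Winding steps add a fixed
number of turns by rapid open-loop magnet rotation (40 turns/s by default).
In steady state the clamp's magnet rotation is equal and opposite to the
enzyme's relaxation rate, so the magnet-turn record reads out topo II
activity at constant topology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .traces import BeadTrace

__all__ = [
    "ControllerConfig",
    "ProtocolStep",
    "controller_update",
    "protocol_duration",
    "simulate_closed_loop",
]


@dataclass(frozen=True)
class ControllerConfig:
    """Proportional extension-clamp parameters."""

    setpoint: float  # nm
    gain: float = 0.05  # turns/s per nm
    frame_rate: float = 40.0  # Hz
    block: int = 5  # frames per controller update
    max_rate: float = 10.0  # turns/s saturation

    def __post_init__(self):
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.block < 1:
            raise ValueError("block must be >= 1")


@dataclass(frozen=True)
class ProtocolStep:
    """One protocol element: rapid winding, a wait, or a clamp hold."""

    kind: str  # 'wind' | 'wait' | 'clamp'
    turns: float = 0.0
    rate: float = 40.0  # turns/s for winding
    duration: Optional[float] = None  # s (wait/clamp); winds derive it

    def __post_init__(self):
        if self.kind not in ("wind", "wait", "clamp"):
            raise ValueError(f"unknown protocol step kind {self.kind!r}")


def protocol_duration(step: ProtocolStep) -> float:
    """Duration of a winding step: |turns| / rate (s)."""
    if step.kind != "wind":
        if step.duration is None:
            raise ValueError("non-wind steps need an explicit duration")
        return float(step.duration)
    if step.turns == 0:
        return 0.0
    if step.rate == 0:
        raise ZeroDivisionError("winding rate must be nonzero")
    return abs(step.turns) / abs(step.rate)


def controller_update(errors: Sequence[float], cfg: ControllerConfig) -> float:
    """Commanded magnet rate from one block of extension errors (nm).

    Positive error (extension above setpoint) commands winding in the
    direction that lowers the extension; the plant maps the command onto the
    winding sign of its calibration branch.  Saturates at +-max_rate.
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size != cfg.block:
        raise ValueError(f"expected {cfg.block} errors, got {errors.size}")
    rate = cfg.gain * float(errors.mean())
    return float(np.clip(rate, -cfg.max_rate, cfg.max_rate))


def simulate_closed_loop(plant, controller: ControllerConfig, duration: float,
                         seed: int = 0):
    """Closed-loop clamp simulation; returns (BeadTrace, ground-truth log).

    The plant supplies the substrate and enzyme model (see
    ``topoloop.synth.TetherPlant``): an extension map of the supercoiling
    state, a winding sign (the turn direction that lowers extension at the
    setpoint), per-frame enzyme turn removal, and measurement noise.  Magnet
    turns respond to the extension error every ``block`` frames with a
    zero-order hold.
    """
    rng = np.random.default_rng(seed)
    fr = controller.frame_rate
    dt = 1.0 / fr
    n_frames = int(round(duration * fr))
    dlk = float(plant.dlk0)
    magnet = 0.0
    magnet_rate = 0.0
    enzyme_total = 0.0
    t_arr = np.arange(n_frames) * dt
    ext_arr = np.empty(n_frames)
    mag_arr = np.empty(n_frames)
    enz_arr = np.empty(n_frames)
    err_buf = []
    wind_sign = plant.wind_sign
    for i in range(n_frames):
        d_enz = plant.enzyme_delta(t_arr[i], dlk, dt, rng)
        dlk += d_enz
        enzyme_total += d_enz
        d_mag = magnet_rate * dt
        dlk += d_mag
        magnet += d_mag
        ext = plant.extension(dlk, rng)
        if not plant.in_domain(dlk):
            raise RuntimeError(
                f"plant left the calibration domain at t={t_arr[i]:.2f} s "
                f"(dLk={dlk:.2f}); clamp simulation halted"
            )
        err_buf.append(ext - controller.setpoint)
        if len(err_buf) == controller.block:
            cmd = controller_update(err_buf, controller)
            magnet_rate = cmd * wind_sign
            err_buf = []
        ext_arr[i] = ext
        mag_arr[i] = magnet
        enz_arr[i] = enzyme_total
    trace = BeadTrace(
        time=t_arr,
        extension=ext_arr,
        magnet_turns=mag_arr,
        force=plant.force,
        annotations=[{"kind": "clamp_on", "time": 0.0}],
    )
    log = {
        "enzyme_turns": enz_arr,
        "final_dlk": dlk,
        "dlk0": plant.dlk0,
        "turns_relaxed": -enzyme_total * (1.0 if plant.dlk0 >= 0 else -1.0),
    }
    return trace, log
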