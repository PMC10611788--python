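import numpy as np
import pytest

from topoloop import synth, wlc


@pytest.fixture(scope="session")
def naked_spec():
    return synth.SubstrateSpec()


@pytest.fixture(scope="session")
def chromatin_spec():
    return synth.SubstrateSpec(kind="chromatin", n_nuc=50)


@pytest.fixture(scope="session")
def naked_cal(naked_spec):
    return synth.naked_calibration(naked_spec, 0.5)


@pytest.fixture(scope="session")
def chromatin_cal(chromatin_spec):
    return synth.chromatin_curve(chromatin_spec, 0.5)


@pytest.fixture(scope="session")
def small_ensemble():
    """Small two-replica ensemble reused by the sampler unit tests."""
    cfg = wlc.SamplerConfig(
        n_segments=16,
        force=0.5,
        dlk_grid=(0.0, 1.0),
        local_moves_per_cycle=100,
        save_target=40,
        knot_check_interval=500,
        burn_in_cycles=10,
        seed=321,
    )
    return wlc.run_sampler(cfg), cfg


def random_open_chain(rng, n=30, min_gap=0.3):
    """Random unit-step chain whose non-adjacent segments stay separated."""
    while True:
        steps = rng.normal(size=(n, 3))
        steps /= np.linalg.norm(steps, axis=1)[:, None]
        v = np.vstack([[0.0, 0.0, 0.0], np.cumsum(steps, axis=0)])
        t = np.linspace(0.0, 1.0, 12)[:, None]
        ok = True
        for a in range(n):
            pa = v[a] + t * (v[a + 1] - v[a])
            for b in range(a + 2, n):
                pb = v[b] + t * (v[b + 1] - v[b])
                if np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2).min() < min_gap:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return v
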