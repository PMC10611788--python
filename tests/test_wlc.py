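"""Tethered worm-like-chain sampler: energies, moves, replica exchange."""

import math

import numpy as np
import pytest

from topoloop import wlc


@pytest.fixture
def cfg4300():
    # 4.3 um chain matching the torsional-energy worked examples
    return wlc.SamplerConfig(n_segments=430, force=0.5, dlk_grid=(0.0, 3.0))


class TestConfig:
    def test_contour_length_is_exact_product(self):
        cfg = wlc.SamplerConfig(n_segments=48, force=0.5, segment_length=10.0)
        assert cfg.contour_length == 480.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_segments=3, force=0.5),
            dict(n_segments=48, force=0.5, segment_length=0.0),
            dict(n_segments=48, force=0.5, move_amplitude=0.0),
            dict(n_segments=48, force=0.5, move_amplitude=185.0),
            dict(n_segments=48, force=0.5, dlk_grid=(0.0, 2.0, 1.0)),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            wlc.SamplerConfig(**kwargs)


class TestEnergy:
    def test_straight_chain_energy_is_pure_stretching(self, cfg4300):
        conf = wlc.straight_chain(cfg4300, dlk=0.0)
        e = wlc.total_energy(conf, cfg4300)
        assert e == pytest.approx(-cfg4300.f_reduced * cfg4300.contour_length)
        assert wlc.bend_energy(conf.vertices, cfg4300) == 0.0

    def test_twist_energy_quadratic_form(self, cfg4300):
        # 2 pi^2 * 109 * 9 / 4300 ~ 4.50 k_BT at dLk - dWr = 3
        assert wlc.twist_energy(3.0, 0.0, cfg4300) == pytest.approx(4.503, abs=5e-3)

    def test_exchange_delta_matches_twist_energy_difference(self, cfg4300):
        # brute force: difference of the four quadratic twist terms
        lk_i, lk_j = 0.0, 3.0
        wr_i, wr_j = 1.2, 3.2  # dWr difference -2 with dLk difference -3
        direct = (
            wlc.twist_energy(lk_i, wr_j, cfg4300)
            + wlc.twist_energy(lk_j, wr_i, cfg4300)
            - wlc.twist_energy(lk_i, wr_i, cfg4300)
            - wlc.twist_energy(lk_j, wr_j, cfg4300)
        )
        de = wlc.replica_exchange_delta(lk_i, lk_j, wr_i, wr_j, cfg4300)
        assert de == pytest.approx(direct, rel=1e-12)
        assert de == pytest.approx(6.01, abs=0.01)

    def test_exchange_delta_symmetric_under_pair_swap(self, cfg4300):
        a = wlc.replica_exchange_delta(0.0, 3.0, 1.0, 2.5, cfg4300)
        b = wlc.replica_exchange_delta(3.0, 0.0, 2.5, 1.0, cfg4300)
        assert a == pytest.approx(b, rel=1e-12)

    def test_equal_writhe_exchange_always_accepted(self, cfg4300):
        de = wlc.replica_exchange_delta(0.0, 3.0, 1.7, 1.7, cfg4300)
        assert de == 0.0
        rng = np.random.default_rng(0)
        assert all(wlc.metropolis_accept(de, rng) for _ in range(100))

    def test_non_neighboring_replicas_rejected(self):
        cfg = wlc.SamplerConfig(n_segments=48, force=0.5, dlk_grid=(0.0, 1.0, 2.0))
        with pytest.raises(ValueError, match="neighboring"):
            wlc.replica_exchange_delta(0.0, 2.0, 0.1, 0.2, cfg)

    def test_mismatched_chain_size_raises(self, cfg4300):
        conf = wlc.straight_chain(cfg4300)
        small = wlc.SamplerConfig(n_segments=10, force=0.5)
        with pytest.raises(ValueError, match="segments"):
            wlc.total_energy(conf, small)


class TestMetropolis:
    def test_zero_and_downhill_always_accepted(self):
        rng = np.random.default_rng(1)
        assert all(wlc.metropolis_accept(0.0, rng) for _ in range(200))
        assert all(wlc.metropolis_accept(-5.0, rng) for _ in range(200))

    def test_uphill_acceptance_frequency(self):
        rng = np.random.default_rng(2)
        n = 100_000
        acc = sum(wlc.metropolis_accept(1.0, rng) for _ in range(n))
        p = math.exp(-1.0)
        sd = math.sqrt(n * p * (1 - p))
        assert abs(acc - n * p) < 3 * sd

    def test_non_finite_delta_raises(self):
        with pytest.raises(ValueError):
            wlc.metropolis_accept(float("nan"), np.random.default_rng(0))


class TestLocalMoves:
    def test_zero_angle_is_identity(self):
        cfg = wlc.SamplerConfig(n_segments=20, force=0.5)
        conf = wlc.straight_chain(cfg)
        for kind in ("crankshaft", "pivot"):
            cand, valid, _ = wlc.propose_local_move(
                conf, cfg, np.random.default_rng(3), kind=kind, angle=0.0
            )
            assert valid
            np.testing.assert_allclose(cand.vertices, conf.vertices, atol=1e-12)

    def test_crankshaft_preserves_outside_and_bonds(self):
        cfg = wlc.SamplerConfig(n_segments=20, force=0.5)
        rng = np.random.default_rng(4)
        conf = wlc.straight_chain(cfg)
        # pre-randomize with a few pivots
        for _ in range(10):
            conf, ok, _ = wlc.propose_local_move(conf, cfg, rng, kind="pivot")
        i, j = 4, 12
        cand, valid, _ = wlc.propose_local_move(
            conf, cfg, rng, kind="crankshaft", indices=(i, j)
        )
        assert valid
        np.testing.assert_array_equal(cand.vertices[: i + 1], conf.vertices[: i + 1])
        np.testing.assert_array_equal(cand.vertices[j:], conf.vertices[j:])
        lens = np.linalg.norm(np.diff(cand.vertices, axis=0), axis=1)
        np.testing.assert_allclose(lens, cfg.segment_length, rtol=1e-12)

    def test_pivot_preserves_terminal_tangents_and_bonds(self):
        cfg = wlc.SamplerConfig(n_segments=20, force=0.5)
        rng = np.random.default_rng(5)
        conf = wlc.straight_chain(cfg)
        for _ in range(50):
            conf, ok, _ = wlc.propose_local_move(conf, cfg, rng)
        v = conf.vertices
        lens = np.linalg.norm(np.diff(v, axis=0), axis=1)
        np.testing.assert_allclose(lens, cfg.segment_length, rtol=1e-12)
        zhat = np.array([0.0, 0.0, 1.0])
        np.testing.assert_allclose((v[1] - v[0]) / cfg.segment_length, zhat, atol=1e-12)
        np.testing.assert_allclose((v[-1] - v[-2]) / cfg.segment_length, zhat, atol=1e-12)

    def test_moves_on_frozen_kink_joints_are_invalid(self):
        cfg = wlc.make_bent_chain(wlc.SamplerConfig(n_segments=20, force=0.5))
        conf = wlc.bent_initial_chain(cfg)
        m = cfg.kink_joint
        cand, valid, _ = wlc.propose_local_move(
            conf, cfg, np.random.default_rng(0), kind="pivot", indices=(m,)
        )
        assert not valid
        np.testing.assert_array_equal(cand.vertices, conf.vertices)


class TestSampler:
    def test_dlk_labels_conserved(self, small_ensemble):
        ens, cfg = small_ensemble
        assert sorted(ens.dlk_labels) == sorted(cfg.dlk_grid)
        for rep in ens.replicas:
            assert len(rep.extensions) == cfg.save_target

    def test_saved_conformations_are_knot_free(self, small_ensemble):
        ens, cfg = small_ensemble
        for rep in ens.replicas:
            for v in rep.conformations[::10]:
                assert not wlc.knot_check(wlc.ChainConformation(v, rep.dlk), cfg)

    def test_incremental_bookkeeping_matches_recomputation(self, small_ensemble):
        ens, cfg = small_ensemble
        for rep in ens.replicas:
            conf = wlc.ChainConformation(rep.conformations[-1], dlk=rep.dlk)
            wr = wlc.writhe(conf, cfg)
            assert wr == pytest.approx(rep.writhes[-1], abs=1e-8)
            conf.writhe = wr
            assert wlc.total_energy(conf, cfg) == pytest.approx(
                rep.energies[-1], abs=1e-8
            )

    def test_saved_chains_keep_geometry_constraints(self, small_ensemble):
        ens, cfg = small_ensemble
        v = ens.replicas[0].conformations[-1]
        lens = np.linalg.norm(np.diff(v, axis=0), axis=1)
        np.testing.assert_allclose(lens, cfg.segment_length, rtol=1e-9)
        np.testing.assert_allclose(v[0], 0.0, atol=1e-12)


class TestBentChain:
    def test_bend_at_terminus_rejected(self):
        cfg = wlc.SamplerConfig(n_segments=20, force=0.5)
        with pytest.raises(ValueError, match="interior"):
            wlc.make_bent_chain(cfg, midpoint=0)

    def test_zero_total_angle_reduces_to_straight_chain(self):
        cfg = wlc.make_bent_chain(
            wlc.SamplerConfig(n_segments=20, force=0.5), total_angle_deg=0.0
        )
        conf = wlc.bent_initial_chain(cfg)
        straight = wlc.straight_chain(cfg)
        np.testing.assert_allclose(conf.vertices, straight.vertices, atol=1e-9)

    def test_kink_angles_preserved_through_sampling(self):
        cfg = wlc.make_bent_chain(
            wlc.SamplerConfig(
                n_segments=16,
                force=0.5,
                dlk_grid=(0.0,),
                local_moves_per_cycle=100,
                save_target=20,
                seed=9,
            )
        )
        ens = wlc.run_sampler(cfg)
        v = ens.replicas[0].conformations[-1]
        t = np.diff(v, axis=0)
        t /= np.linalg.norm(t, axis=1)[:, None]
        m = cfg.kink_joint
        a1 = math.degrees(math.acos(np.clip(t[m - 1] @ t[m], -1, 1)))
        a2 = math.degrees(math.acos(np.clip(t[m] @ t[m + 1], -1, 1)))
        assert a1 + a2 == pytest.approx(120.0, abs=1e-6)


class TestDistanceDistribution:
    def test_collinear_triple_gives_single_mass(self):
        v = np.array([[0, 0, 0], [0, 0, 10], [0, 0, 20.0]])
        dd = wlc.distance_distribution([v], min_contour_separation=2, n_bins=50)
        assert dd.masses.sum() == pytest.approx(1.0, abs=1e-12)
        assert dd.masses[np.argmax(dd.masses)] == 1.0
        assert abs(dd.centers[np.argmax(dd.masses)] - 20.0) <= dd.bin_width

    def test_rigid_rod_supported_on_multiples_of_segment_length(self):
        cfg = wlc.SamplerConfig(n_segments=8, force=0.5)
        rod = wlc.straight_chain(cfg).vertices
        dd = wlc.distance_distribution([rod] * 5, min_contour_separation=2, n_bins=200)
        populated = dd.centers[dd.masses > 0]
        assert np.all(np.abs(populated / 10.0 - np.round(populated / 10.0)) < 0.5)

    def test_empty_pair_set_raises(self):
        v = np.array([[0, 0, 0], [0, 0, 10.0]])
        with pytest.raises(ValueError):
            wlc.distance_distribution([v], min_contour_separation=5)
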