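"""Pulse-design oracles: closed forms, brute force, and ordering properties."""

import numpy as np
import pytest

from b1net.model import CP_WEIGHTS
from b1net.phantom import slice_coordinates
from b1net.ptx import (
    B1_SCALE_T,
    FAMap,
    GAMMA,
    KtPointPulse,
    ShimSetting,
    bloch_simulate_fa,
    coefficient_of_variation,
    combine_channels,
    cp_shim,
    design_ktpoints,
    design_phase_shim,
    rf_power,
    shim_efficiency,
    solve_mls,
    sta_forward,
)


@pytest.fixture(scope="module")
def gt_volume(tiny_library_normalized):
    lib, _ = tiny_library_normalized
    pair = lib[sorted(lib)[0]]["transversal"]
    pos = slice_coordinates(
        "transversal", np.atleast_1d(pair.b1.positions),
        pair.b1.data.shape[1:3], pair.b1.spacing,
    )
    return pair.b1.data.astype(np.complex128), pair.b1.mask, pos


class TestCombineChannels:
    def test_two_channel_toy(self):
        b1 = np.array([[[1 + 0j, 0 + 1j]]])
        assert combine_channels(b1, np.ones(2)) == 1 + 1j

    def test_conjugate_weights_fully_constructive(self):
        rng = np.random.default_rng(0)
        vox = rng.normal(size=8) + 1j * rng.normal(size=8)
        w = np.exp(-1j * np.angle(vox))
        got = combine_channels(vox[None], ShimSetting(weights=w))
        assert np.isclose(got[0], np.abs(vox).sum())

    def test_zero_weights(self):
        b1 = np.ones((2, 2, 8), dtype=complex)
        assert np.allclose(combine_channels(b1, ShimSetting(
            weights=np.zeros(8), constraint="unconstrained")), 0)

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError, match="channel"):
            combine_channels(np.ones((2, 2, 4), complex), np.ones(8))


class TestCV:
    def test_uniform_is_zero(self):
        assert coefficient_of_variation(np.full((5, 5), 7.0)) == 0

    def test_two_value_closed_form(self):
        assert np.isclose(coefficient_of_variation(np.array([1.0, 3.0])), 0.5)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        fa = rng.uniform(1, 2, size=(6, 6))
        assert np.isclose(
            coefficient_of_variation(fa), coefficient_of_variation(5 * fa)
        )

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="undefined|zero"):
            coefficient_of_variation(np.zeros((3, 3)))


class TestPhaseShim:
    def test_single_channel_returns_trivially(self):
        b1 = np.abs(np.random.default_rng(2).normal(size=(1, 4, 4, 1))) + 0.5 + 0j
        shim = design_phase_shim(b1, np.ones((1, 4, 4), bool), efficiency_target=1.0)
        assert shim.achieved_efficiency == 1.0
        assert np.isclose(np.abs(shim.weights[0]), 1.0)

    def test_matches_one_degree_grid_brute_force(self):
        b1 = np.array(
            [[[[1 + 0j, 0.5 + 0.5j], [0.8 + 0j, 0.2 - 0.6j], [1.2 + 0j, -0.3 + 0.4j]]]]
        )
        mask = np.ones((1, 1, 3), bool)
        target = 0.8
        best = None
        for deg in range(360):
            w = np.array([1, np.exp(1j * np.deg2rad(deg))])
            mos = np.abs(b1 @ w)[mask]
            eff = mos.mean() / np.abs(b1).sum(-1)[mask].mean()
            if abs(eff - target) <= 0.01 * target:
                cv = mos.std() / mos.mean()
                if best is None or cv < best[1]:
                    best = (deg, cv)
        shim = design_phase_shim(b1, mask, efficiency_target=target, seed=0)
        phase = np.rad2deg(np.angle(shim.weights[1] / shim.weights[0])) % 360
        assert shim.feasible
        assert shim.achieved_cv <= best[1] + 1e-6
        assert min(abs(phase - best[0]), 360 - abs(phase - best[0])) <= 1.5

    def test_efficiency_constraint_satisfied_on_phantom(self, gt_volume):
        b1, mask, _ = gt_volume
        shim = design_phase_shim(b1, mask, efficiency_target=0.6, seed=1)
        assert shim.feasible
        assert abs(shim.achieved_efficiency - 0.6) <= 0.006 + 1e-6
        assert np.allclose(np.abs(shim.weights), 1.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            design_phase_shim(np.ones((1, 2, 2, 8), complex), np.zeros((1, 2, 2), bool))


class TestKtPointDesign:
    def test_homogeneous_limit(self):
        b1 = np.ones((1, 8, 8, 1), dtype=complex)
        pos = np.zeros((1, 8, 8, 3))
        pulse = design_ktpoints(
            b1, np.ones((1, 8, 8), bool), pos, n_points=1, n_iter=10
        )
        fa = np.rad2deg(np.abs(sta_forward(pulse, b1, pos)))
        assert np.allclose(fa, 10.0, atol=1e-3)
        assert pulse.predicted_cv < 1e-6

    def test_four_points_dominate_single_point(self, gt_volume):
        b1, mask, pos = gt_volume
        p1 = design_ktpoints(b1, mask, pos, n_points=1, n_iter=15)
        p4 = design_ktpoints(b1, mask, pos, n_points=4, n_iter=15)
        assert p4.predicted_cv < p1.predicted_cv

    def test_tiny_instance_matches_exhaustive_search(self):
        """2 channels, 4 voxels, 2 candidate k-locations: greedy + variable
        exchange matches exhaustive subset search with the same solver."""
        rng = np.random.default_rng(3)
        b1 = (rng.normal(size=(1, 2, 2, 2)) + 1j * rng.normal(size=(1, 2, 2, 2))) + 1.5
        pos = rng.normal(size=(1, 2, 2, 3)) * 0.05
        mask = np.ones((1, 2, 2), bool)
        from b1net.ptx import _system_matrix

        target = np.full(4, np.deg2rad(10.0))
        cands = [np.zeros(3), np.array([20.0, 0, 0])]
        best = None
        for ks in ([cands[0]], [cands[1]], cands, cands[::-1]):
            if len(ks) != 2:
                continue
            A = _system_matrix(b1[mask], pos[mask], np.array(ks), 100e-6)
            w, cost = solve_mls(A, target, reg=1e-6, n_iter=40)
            if best is None or cost < best[0]:
                best = (cost, np.array(ks))
        pulse = design_ktpoints(
            b1, mask, pos, n_points=2, k_max=20.0, n_iter=40
        )
        A = _system_matrix(b1[mask], pos[mask], pulse.k_locations, 100e-6)
        _, cost = solve_mls(A, target, reg=1e-6, n_iter=40)
        assert cost <= best[0] * 1.05

    def test_regularization_monotonically_reduces_power(self, gt_volume):
        b1, mask, pos = gt_volume
        from b1net.ptx import _system_matrix

        A = _system_matrix(
            b1[mask], pos[mask], np.array([[0.0, 0, 0], [20.0, 0, 0]]), 100e-6
        )
        target = np.full(mask.sum(), np.deg2rad(10.0))
        powers = []
        for reg in (1e-8, 1e-6, 1e-4, 1e-2, 1.0):
            w, _ = solve_mls(A, target, reg=reg, n_iter=25)
            powers.append((np.abs(w) ** 2).sum())
        assert all(b <= a * (1 + 1e-9) for a, b in zip(powers, powers[1:]))

    def test_empty_mask_rejected(self, gt_volume):
        b1, _, pos = gt_volume
        with pytest.raises(ValueError, match="mask"):
            design_ktpoints(b1, np.zeros(b1.shape[:3], bool), pos)


class TestSTAForward:
    def test_zero_weights_give_zero_fa(self, gt_volume):
        b1, _, pos = gt_volume
        pulse = KtPointPulse(
            k_locations=np.zeros((2, 3)), rf_weights=np.zeros((2, 8))
        )
        assert np.allclose(sta_forward(pulse, b1, pos), 0)

    def test_single_point_closed_form(self):
        b1 = np.ones((1, 2, 2, 1), dtype=complex)
        pos = np.zeros((1, 2, 2, 3))
        w = 0.003
        pulse = KtPointPulse(k_locations=[[0, 0, 0]], rf_weights=[[w]])
        expect = GAMMA * pulse.subpulse_duration * B1_SCALE_T * w
        assert np.allclose(np.abs(sta_forward(pulse, b1, pos)), expect)

    def test_linearity(self, gt_volume):
        b1, _, pos = gt_volume
        rng = np.random.default_rng(4)
        pulse = KtPointPulse(
            k_locations=rng.normal(size=(3, 3)) * 10,
            rf_weights=rng.normal(size=(3, 8)) + 1j * rng.normal(size=(3, 8)),
        )
        th1 = sta_forward(pulse, b1, pos)
        pulse2 = KtPointPulse(
            k_locations=pulse.k_locations, rf_weights=2 * pulse.rf_weights
        )
        assert np.allclose(sta_forward(pulse2, b1, pos), 2 * th1, rtol=1e-10)


class TestBloch:
    def test_zero_pulse_gives_zero_fa(self, gt_volume):
        b1, _, pos = gt_volume
        pulse = KtPointPulse(k_locations=np.zeros((1, 3)), rf_weights=np.zeros((1, 8)))
        fa = bloch_simulate_fa(pulse, b1, pos)
        assert np.allclose(fa.fa_deg, 0)

    def test_single_hard_pulse_matches_rotation_angle(self):
        b1 = np.full((1, 3, 3, 1), 1.0 + 0j)
        pos = np.zeros((1, 3, 3, 3))
        w = 0.004 + 0.002j
        pulse = KtPointPulse(k_locations=[[0, 0, 0]], rf_weights=[[w]])
        fa = bloch_simulate_fa(pulse, b1, pos)
        expect = np.rad2deg(GAMMA * pulse.subpulse_duration * B1_SCALE_T * abs(w))
        assert np.allclose(fa.fa_deg, expect, atol=1e-9)

    def test_small_tip_consistency_for_designed_pulse(self, gt_volume):
        """Bloch FA and STA FA agree within 2% per voxel at target <= 5 deg."""
        b1, mask, pos = gt_volume
        pulse = design_ktpoints(b1, mask, pos, n_points=4, target_fa_deg=5.0, n_iter=15)
        sta_fa = np.rad2deg(np.abs(sta_forward(pulse, b1, pos)))
        bloch_fa = bloch_simulate_fa(pulse, b1, pos).fa_deg
        rel = np.abs(bloch_fa - sta_fa)[mask] / np.maximum(sta_fa[mask], 1e-9)
        assert rel.max() <= 0.02

    def test_grid_mismatch_rejected(self, gt_volume):
        b1, _, pos = gt_volume
        pulse = KtPointPulse(k_locations=[[0, 0, 0]], rf_weights=[np.ones(8)])
        with pytest.raises(ValueError, match="match"):
            bloch_simulate_fa(pulse, b1, pos[:, :-1])


class TestPulseSerialization:
    def test_json_roundtrip(self):
        rng = np.random.default_rng(5)
        pulse = KtPointPulse(
            k_locations=rng.normal(size=(4, 3)),
            rf_weights=rng.normal(size=(4, 8)) + 1j * rng.normal(size=(4, 8)),
            target_fa_deg=7.5,
        )
        back = KtPointPulse.from_json(pulse.to_json())
        assert np.allclose(back.k_locations, pulse.k_locations)
        assert np.allclose(back.rf_weights, pulse.rf_weights)
        assert back.target_fa_deg == 7.5

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            KtPointPulse(
                k_locations=[[0, 0, 0]], rf_weights=[[1.0]], subpulse_duration=0
            )

    def test_rf_power_surrogate(self):
        pulse = KtPointPulse(
            k_locations=[[0, 0, 0]], rf_weights=[[3.0, 4.0]], subpulse_duration=1e-4
        )
        assert np.isclose(rf_power(pulse), 25 * 1e-4)


def test_cp_shim_weights_are_unit_magnitude_cp_phases():
    shim = cp_shim()
    assert np.allclose(np.abs(shim.weights), 1.0)
    assert np.allclose(shim.weights, CP_WEIGHTS.astype(complex), atol=1e-6)


def test_shim_efficiency_of_fully_constructive_combination():
    b1 = np.abs(np.random.default_rng(6).normal(size=(1, 3, 3, 8))) + 0.1 + 0j
    mask = np.ones((1, 3, 3), bool)
    assert np.isclose(shim_efficiency(b1, np.ones(8), mask), 1.0)
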