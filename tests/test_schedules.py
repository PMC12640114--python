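"""Worked examples and state-machine tests for regimens and LR schedules."""

import pytest

from plastinet.degradations import DegradationSpec
from plastinet.schedules import (
    LRSchedule,
    PlateauParams,
    RegimenSchedule,
    degradation_at_epoch,
    initial_plateau_state,
    lr_at_epoch,
    make_lr_schedule,
    make_regimen,
    matched_pairs,
    plateau_update,
)

ALL_LR_PRESETS = ("const1", "const2", "const3", "dec1", "dec2", "dec3", "gradual", "plateau")


class TestRegimens:
    def test_d2f_blur_phase_structure(self):
        reg = make_regimen("D2F", 100, degraded_kind="blur")
        assert reg.phases == (
            (DegradationSpec("blur", sigma_ref=4.0), 50),
            (DegradationSpec("none"), 50),
        )

    def test_gradual_blur_staircase(self):
        reg = make_regimen("gradual_blur", 100)
        sigmas = [
            (p.sigma_ref if p.kind == "blur" else 0.0, n) for p, n in reg.phases
        ]
        assert sigmas == [(4.0, 20), (3.0, 20), (2.0, 20), (1.0, 20), (0.0, 20)]

    def test_f2f_is_identity_every_epoch(self):
        reg = make_regimen("F2F", 100)
        assert all(
            degradation_at_epoch(reg, e).kind == "none" for e in range(1, 101)
        )

    def test_phase_boundary_inclusive(self):
        reg = make_regimen("D2F", 100, degraded_kind="blur")
        assert degradation_at_epoch(reg, 50).kind == "blur"
        assert degradation_at_epoch(reg, 51).kind == "none"

    def test_gradual_blur_epoch_70_at_level_one(self):
        reg = make_regimen("gradual_blur", 100)
        assert degradation_at_epoch(reg, 70) == DegradationSpec("blur", sigma_ref=1.0)

    def test_epoch_out_of_range(self):
        reg = make_regimen("F2F", 10)
        for bad in (0, 11):
            with pytest.raises(ValueError):
                degradation_at_epoch(reg, bad)

    @pytest.mark.parametrize("k", [10, 20, 30, 40])
    def test_partial_degraded_lengths(self, k):
        reg = make_regimen("D2F_partial", 100, degraded_kind="grayscale", partial_epochs=k)
        assert reg.phases[0][1] == k
        assert reg.phases[1][1] == 100 - k

    def test_proportional_scaling(self):
        reg = make_regimen("D2F", 20, degraded_kind="blur")
        assert degradation_at_epoch(reg, 10).kind == "blur"
        assert degradation_at_epoch(reg, 11).kind == "none"

    @pytest.mark.parametrize("name", ["F2F", "D2D", "D2F", "F2D", "gradual_blur"])
    @pytest.mark.parametrize("total", [10, 20, 100])
    def test_phases_cover_every_epoch(self, name, total):
        reg = make_regimen(name, total, degraded_kind="blur")
        assert sum(n for _, n in reg.phases) == total
        for e in range(1, total + 1):
            degradation_at_epoch(reg, e)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            make_regimen("mixed", 100)

    def test_json_round_trip(self):
        reg = make_regimen("D2F", 100, degraded_kind="grayscale")
        assert RegimenSchedule.from_json_dict(reg.to_json_dict()) == reg


class TestLRSchedules:
    def test_dec1_drop_after_epoch_50(self):
        sch = make_lr_schedule("dec1", 100)
        assert lr_at_epoch(sch, 50) == 0.01
        assert lr_at_epoch(sch, 51) == 0.001

    def test_gradual_third_block_value(self):
        sch = make_lr_schedule("gradual", 100)
        for epoch in (41, 50, 60):
            assert lr_at_epoch(sch, epoch) == 0.005
        assert lr_at_epoch(sch, 40) == 0.0075
        assert lr_at_epoch(sch, 61) == 0.0025

    def test_constant_presets(self):
        for name, value in (("const1", 0.01), ("const2", 0.001), ("const3", 0.0001)):
            sch = make_lr_schedule(name, 100)
            assert all(lr_at_epoch(sch, e) == value for e in (1, 50, 100))

    def test_plateau_preset_parameters(self):
        sch = make_lr_schedule("plateau", 100)
        p = sch.plateau_params
        assert (sch.initial_lr, p.factor, p.patience, p.min_delta, p.cooldown, p.min_lr) == (
            0.01, 0.5, 5, 0.0, 0, 0.0,
        )

    def test_scaled_switch_epoch(self):
        sch = make_lr_schedule("dec1", 20)
        assert lr_at_epoch(sch, 10) == 0.01
        assert lr_at_epoch(sch, 11) == 0.001

    @pytest.mark.parametrize("name", ["const1", "const2", "const3", "dec1", "dec2", "dec3", "gradual"])
    def test_non_increasing_over_epochs(self, name):
        sch = make_lr_schedule(name, 100)
        lrs = [lr_at_epoch(sch, e) for e in range(1, 101)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))

    def test_plateau_requires_state(self):
        sch = make_lr_schedule("plateau", 100)
        with pytest.raises(ValueError):
            lr_at_epoch(sch, 1)

    def test_increasing_steps_rejected(self):
        with pytest.raises(ValueError):
            LRSchedule(name="bad", kind="step", initial_lr=0.001, steps=((10, 0.01),))


class TestPlateauStateMachine:
    def test_improving_metric_never_reduces(self):
        sch = make_lr_schedule("plateau", 100)
        state = initial_plateau_state(sch)
        for step in range(20):
            state = plateau_update(state, sch.plateau_params, 0.1 * step)
        assert state.current_lr == 0.01

    def test_flat_metric_halves_after_patience(self):
        sch = make_lr_schedule("plateau", 100)
        state = initial_plateau_state(sch)
        state = plateau_update(state, sch.plateau_params, 0.5)  # establishes best
        # with min_delta 0 each further flat epoch counts as stagnation
        lrs = []
        for _ in range(6):
            state = plateau_update(state, sch.plateau_params, 0.5)
            lrs.append(state.current_lr)
        assert lrs[:5] == [0.01] * 5
        assert lrs[5] == pytest.approx(0.005)

    def test_min_lr_floor(self):
        params = PlateauParams(factor=0.5, patience=0, min_lr=0.004)
        state = initial_plateau_state(make_lr_schedule("plateau", 100))
        for _ in range(10):
            state = plateau_update(state, params, 0.0)
        assert state.current_lr == 0.004

    def test_lr_sequence_non_increasing(self, rng):
        sch = make_lr_schedule("plateau", 100)
        state = initial_plateau_state(sch)
        prev = state.current_lr
        for value in rng.random(50):
            state = plateau_update(state, sch.plateau_params, float(value))
            assert state.current_lr <= prev
            prev = state.current_lr


class TestMatchedPairs:
    def test_initial_basis(self):
        pairs = {(d, c) for d, c, _ in matched_pairs("initial")}
        assert pairs == {("dec1", "const1"), ("dec2", "const1"), ("dec3", "const2")}

    def test_final_basis(self):
        pairs = {(d, c) for d, c, _ in matched_pairs("final")}
        assert pairs == {("dec1", "const2"), ("dec2", "const3"), ("dec3", "const3")}

    def test_unknown_basis(self):
        with pytest.raises(ValueError):
            matched_pairs("median")
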