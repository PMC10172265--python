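"""Synthetic creep generator: creep law, recovery, flipping, dataset build."""

import numpy as np
import pytest

from spinecreep import (
    GeneratorConfig,
    apply_break_recovery,
    build_dataset,
    creep_multiplier,
    eval_boltzmann,
    fit_hysteresis,
    flip_params,
    flip_sequence,
    generate_group,
    sequence_ratios,
)
from spinecreep.hysteresis import sample_loop
from spinecreep.synthetic import (
    decay_factor,
    generate_sequence,
    make_profile,
    start_hour,
)


class TestCreepMultiplier:
    def test_zero_gain_is_identity(self):
        k = np.arange(1, 40)
        np.testing.assert_array_equal(creep_multiplier(k, 2, 0.0, 0.4, 0.08), 1.0)

    def test_anchored_at_cycle_three(self):
        assert creep_multiplier(3, 1, 0.09, 0.4, 0.08) == pytest.approx(1.0)

    def test_saturation_limit(self):
        c_s = 0.09 * (1 - 0.08 * 2)
        assert creep_multiplier(500, 3, 0.09, 1e3, 0.08) == pytest.approx(1 + c_s)

    def test_monotone_nondecreasing_in_cycle(self):
        vals = creep_multiplier(np.arange(1, 61), 1, 0.09, 0.4, 0.08)
        assert np.all(np.diff(vals) >= 0)

    def test_invalid_cycle_index(self):
        with pytest.raises(ValueError):
            creep_multiplier(0, 1, 0.09, 0.4, 0.08)

    def test_decay_factor_modes(self):
        cfg_lin = GeneratorConfig(decay_mode="linear", sequence_decay=0.1)
        assert decay_factor(1, cfg_lin) == 1.0
        assert decay_factor(6, cfg_lin) == pytest.approx(0.5)
        cfg_exp = GeneratorConfig()
        d = [decay_factor(s, cfg_exp) for s in range(1, 7)]
        assert d[0] == 1.0 and np.all(np.diff(d) < 0)
        assert d[-1] > cfg_exp.decay_floor


class TestBreakRecovery:
    def test_full_recovery_returns_to_anchor(self):
        assert apply_break_recovery(1.09, 1.0, 1.0) == pytest.approx(1.0)

    def test_no_recovery_keeps_creep(self):
        assert apply_break_recovery(1.09, 1.0, 0.0) == pytest.approx(1.09)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            apply_break_recovery(1.09, 1.0, 1.5)


class TestGenerateSequence:
    def _quiet_config(self, **kw):
        quiet = dict(
            specimen_amp_sigma=0.0, specimen_shape_sigma=0.0, specimen_center_sigma=0.0,
            creep_jitter_sigma=0.0, sequence_shape_sigma=0.0, cycle_shape_sigma=0.0,
            cycle_center_sigma=0.0, cycle_rom_sigma=0.0, noise_sigma=0.0,
        )
        quiet.update(kw)
        return GeneratorConfig(**quiet)

    def test_no_noise_no_creep_gives_identical_cycles(self, rng):
        cfg = self._quiet_config(creep_gain=0.0)
        profile = make_profile(cfg, "x", rng)
        seq, _, _ = generate_sequence(profile, cfg, "FE", 1, 1.0, rng)
        mats = seq.params_matrix()
        assert np.allclose(mats, mats[0])

    def test_envelope_nondecreasing_under_positive_creep(self, rng):
        cfg = self._quiet_config()
        profile = make_profile(cfg, "x", rng)
        seq, _, _ = generate_sequence(profile, cfg, "AR", 1, 1.0, rng)
        env = np.array([p.B - p.A for p in seq.cycles])
        assert np.all(np.diff(env) >= -1e-12)

    def test_recovered_anchor_between_no_and_full_recovery(self, rng):
        cfg = self._quiet_config()
        profile = make_profile(cfg, "x", rng)
        _, anchor, _ = generate_sequence(profile, cfg, "FE", 1, 1.0, rng)
        assert 1.0 < anchor < 1.0 + cfg.creep_gain

    def test_generated_loops_are_fit_recoverable(self, rng):
        cfg = self._quiet_config()
        profile = make_profile(cfg, "x", rng)
        seq, _, _ = generate_sequence(profile, cfg, "FE", 1, 1.0, rng)
        res = fit_hysteresis(sample_loop(seq.cycles[5], 80))
        assert res.accepted

    def test_start_hours_follow_session_layout(self):
        assert start_hour("FE", 1) == 0.0
        assert start_hour("AR", 1) == 1.0
        assert start_hour("LB", 2) == 5.0
        assert start_hour("FE", 6) == 15.0


class TestFlip:
    def test_flip_is_involution(self, base_params):
        back = flip_params(flip_params(base_params))
        np.testing.assert_allclose(back.to_vector(), base_params.to_vector(), atol=1e-12)

    def test_flip_defining_property_pointmirror(self, base_params):
        flipped = flip_params(base_params)
        m = np.linspace(-7.5, 7.5, 41)
        for orig_branch, flip_branch in (("upper", "lower"), ("lower", "upper")):
            orig = eval_boltzmann(base_params.A, base_params.B,
                                  *base_params.branch(orig_branch), -m)
            mirrored = eval_boltzmann(flipped.A, flipped.B,
                                      *flipped.branch(flip_branch), m)
            np.testing.assert_allclose(mirrored, -orig, atol=1e-12)

    def test_flip_swaps_and_negates_extrema(self, base_params):
        flipped = flip_params(base_params)
        assert flipped.A == -base_params.B
        assert flipped.B == -base_params.A

    def test_flipping_fe_rejected(self, tiny_dataset):
        sequences, _ = tiny_dataset
        fe = next(s for s in sequences if s.direction == "FE")
        with pytest.raises(ValueError):
            flip_sequence(fe)


class TestBuildDataset:
    def test_default_dataset_scale_and_partition(self):
        sequences, split = build_dataset(seed=3)
        # 6 specimens x 3 directions x 6 blocks + LB/AR flips
        assert len(sequences) == 180
        ids = {s.sequence_id for s in sequences}
        assert split.all_ids == ids
        assert len(split.train) == 116 and len(split.validation) == 9
        assert len(split.train) + len(split.validation) + len(split.test) == 180

    def test_first_cycle_dropped(self):
        sequences, _ = build_dataset(seed=3)
        assert all(s.cycle_indices[0] == 2 for s in sequences)

    def test_same_seed_reproduces_identical_dataset(self):
        a, split_a = build_dataset(seed=11)
        b, split_b = build_dataset(seed=11)
        assert split_a == split_b
        for sa, sb in zip(a, b):
            assert sa.sequence_id == sb.sequence_id
            np.testing.assert_array_equal(sa.params_matrix(), sb.params_matrix())
            assert sa.tau_t == sb.tau_t

    def test_oversized_split_rejected(self):
        with pytest.raises(ValueError):
            build_dataset(seed=0, n_train=500)

    def test_tau_t_positive_correlation_and_group_ordering(self):
        cfgs = [
            GeneratorConfig.for_temperature("BT", n_specimens=25, seed=5),
            GeneratorConfig.for_temperature("RT", n_specimens=25, seed=6),
        ]
        groups = {c.temperature_group: generate_group(c) for c in cfgs}
        med = {}
        for temp, seqs in groups.items():
            ratios = [sequence_ratios(s) for s in seqs]
            med[temp] = (np.median([r[0] for r in ratios]), np.median([r[1] for r in ratios]))
        # body temperature creeps more and recovers more
        assert med["BT"][0] < med["RT"][0]
        assert med["BT"][1] > med["RT"][1]

    def test_flipped_sequences_mirror_source_cycles(self, tiny_dataset):
        sequences, _ = tiny_dataset
        flipped = next(s for s in sequences if s.flipped)
        source = next(s for s in sequences
                      if s.sequence_id == flipped.sequence_id.replace("-flip", ""))
        # defining property per cycle: RoM'(m) = -RoM(-m) with branches swapped
        np.testing.assert_allclose(
            flipped.rom_trace(7.5, "upper"),
            -source.rom_trace(-7.5, "lower"),
            atol=1e-12,
        )
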