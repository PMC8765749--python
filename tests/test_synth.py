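import numpy as np
import pandas as pd
import pytest
from scipy import ndimage
from scipy.special import ndtr

from optomask.config import SessionConfig
from optomask.synth import (GroundTruth, PsychParams, simulate_choices,
                            render_trial_stack, generate_session, trial_rng,
                            blank_condition_id)
from optomask.timeline import build_timeline

from conftest import make_config, DEFAULT_NOISE


def _table(n, block="vis", contrast=0.1, present=True):
    return pd.DataFrame({
        "trial_id": np.arange(n),
        "block_id": block,
        "condition_contrast": contrast,
        "target_present": present,
        "target_contrast": contrast if present else 0.0,
        "opto_power": 0.0,
    })


class TestSimulateChoices:
    def test_hit_rate_at_threshold_matches_phi_half(self):
        # oracle: binomial 3-sigma CI around high-precision Phi(0.5)
        n = 10_000
        p = ndtr(0.5)  # 0.6914624612740131
        table = _table(n, contrast=0.1)
        pp = {"vis": PsychParams(alpha=0.1, beta=2.0, delta=0.0)}
        out = simulate_choices(table, pp, np.random.default_rng(7))
        rate = (out["outcome"] == "hit").mean()
        assert abs(rate - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_zero_contrast_zero_bias_gives_half(self):
        n = 20_000
        present = _table(n, contrast=1e-30)
        absent = _table(n, contrast=1e-30, present=False)
        pp = {"vis": PsychParams(alpha=0.1, beta=2.0, delta=0.0)}
        rng = np.random.default_rng(0)
        hit = (simulate_choices(present, pp, rng)["outcome"] == "hit").mean()
        cr = (simulate_choices(absent, pp, rng)["outcome"] == "correct_rejection").mean()
        assert abs(hit - 0.5) < 0.02
        assert abs(cr - 0.5) < 0.02

    def test_same_seed_identical_outcomes(self):
        table = _table(500)
        pp = {"vis": PsychParams(alpha=0.1, beta=1.5, delta=0.2)}
        a = simulate_choices(table, pp, np.random.default_rng(42))
        b = simulate_choices(table, pp, np.random.default_rng(42))
        assert (a["outcome"] == b["outcome"]).all()

    def test_absent_trials_use_block_contrast(self):
        # high block contrast + big positive bias => CRs nearly certain
        absent = _table(2000, contrast=1.0, present=False)
        pp = {"vis": PsychParams(alpha=0.05, beta=1.0, delta=1.0)}
        out = simulate_choices(absent, pp, np.random.default_rng(3))
        assert (out["outcome"] == "correct_rejection").mean() > 0.99

    def test_outcome_consistent_with_presence_and_choice(self):
        table = pd.concat([_table(200), _table(200, present=False)],
                          ignore_index=True)
        pp = {"vis": PsychParams(alpha=0.1, beta=1.5, delta=0.0)}
        out = simulate_choices(table, pp, np.random.default_rng(5))
        present = out["target_present"]
        sacc = out["choice"] == "saccade"
        assert (out.loc[present & sacc, "outcome"] == "hit").all()
        assert (out.loc[present & ~sacc, "outcome"] == "miss").all()
        assert (out.loc[~present & sacc, "outcome"] == "false_alarm").all()
        assert (out.loc[~present & ~sacc, "outcome"] == "correct_rejection").all()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PsychParams(alpha=-1.0, beta=1.0)
        with pytest.raises(ValueError):
            PsychParams(alpha=0.1, beta=0.0)

    def test_unknown_block_rejected(self):
        with pytest.raises(ValueError, match="block"):
            simulate_choices(_table(5, block="mystery"),
                             {"vis": PsychParams(0.1, 1.0)},
                             np.random.default_rng(0))


def _one_trial(contrast=0.2, power=0.0, hr=180.0):
    return {"target_contrast": contrast, "opto_power": power, "heart_rate": hr}


class TestRenderTrialStack:
    def test_all_amplitudes_zero_gives_constant_stack(self, timeline):
        gt = GroundTruth(nr_amp_max=0.0, opto_amplitude={})
        stack, _ = render_trial_stack(gt, _one_trial(), timeline,
                                      np.random.default_rng(0))
        base = gt.baseline_map(64, 64)
        assert np.max(np.abs(stack - base[None])) == 0.0

    def test_rho_one_combined_equals_opto_only(self, timeline):
        # crosstalk off: the GCaMP-only site sees the visual target too,
        # which rho (a C1V1-site quantity) does not silence
        gt = GroundTruth(rho_true=1.0, opto_amplitude={0.6: 0.04},
                         crosstalk_site2=0.0)
        rng = lambda: np.random.default_rng(9)
        combined, sc = render_trial_stack(gt, _one_trial(0.4, 0.6), timeline, rng())
        opto_only, _ = render_trial_stack(gt, _one_trial(0.0, 0.6), timeline, rng())
        assert sc["resp_amp_site1"] == pytest.approx(0.04)  # visual part gone
        np.testing.assert_array_equal(combined, opto_only)

    def test_rho_zero_combined_is_additive(self, timeline):
        gt = GroundTruth(rho_true=0.0, opto_amplitude={0.6: 0.04})
        rng = lambda: np.random.default_rng(9)
        combined, sc = render_trial_stack(gt, _one_trial(0.4, 0.6), timeline, rng())
        assert sc["resp_amp_site1"] == pytest.approx(
            gt.visual_amplitude(0.4) + 0.04)

    def test_injected_motion_recoverable_by_bruteforce(self, timeline):
        # oracle: exhaustive integer-shift cross-correlation + parabolic interp
        gt = GroundTruth(motion_sd_px=0.5, noise_sd=0.0)
        stack, sc = render_trial_stack(gt, _one_trial(), timeline,
                                       np.random.default_rng(21))
        from oracles import bruteforce_shift
        ref = stack[np.argmin(np.abs(sc["motion"]).sum(axis=1))]
        v_ref = sc["motion"][np.argmin(np.abs(sc["motion"]).sum(axis=1))]
        for t in range(0, timeline.n_frames, 4):
            est = bruteforce_shift(ref, stack[t], max_shift=4)
            expected = sc["motion"][t] - v_ref
            assert np.max(np.abs(est - expected)) < 0.1

    def test_rho_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            GroundTruth(rho_true=1.5)

    def test_nonpositive_dimensions_rejected(self, timeline):
        with pytest.raises(ValueError):
            render_trial_stack(GroundTruth(), _one_trial(), timeline,
                               np.random.default_rng(0), ny=0, nx=64)

    def test_sidecar_inverse_restores_within_noise(self, timeline):
        """Undoing each injected artifact leaves only additive noise."""
        gt = GroundTruth(noise_sd=1.0, heartbeat_amplitude=2.0,
                         motion_sd_px=0.3)
        srng = np.random.default_rng(2)
        gt.heartbeat_map = gt.make_heartbeat_map(64, 64, srng)
        stack, sc = render_trial_stack(gt, _one_trial(0.2, 0.0, hr=195.0),
                                       timeline, np.random.default_rng(8),
                                       keep_clean=True)
        w = gt.heartbeat_waveform(timeline)
        hb = gt.heartbeat_amplitude * sc["hb_scale"] * w[:, None, None] * gt.heartbeat_map
        no_hb = stack - hb
        restored = np.stack([ndimage.shift(no_hb[t], -sc["motion"][t], order=3,
                                           mode="nearest")
                             for t in range(timeline.n_frames)])
        inner = (slice(None), slice(4, -4), slice(4, -4))  # skip shift edges
        rmse = np.sqrt(np.mean((restored[inner] - sc["clean"][inner]) ** 2))
        assert rmse <= gt.noise_sd * 1.05


class TestGenerateSession:
    def test_bookkeeping_400_rows(self):
        cfg = make_config(trials_per_cell=50)
        s = generate_session(cfg, seed=0, render=False)
        assert len(s.trial_table) == 400
        assert set(s.trial_table["outcome"]) <= {
            "hit", "miss", "false_alarm", "correct_rejection"}
        assert s.trial_table["outcome"].notna().all()

    def test_blocks_emitted_separately(self):
        s = generate_session(make_config(), seed=0, render=False)
        assert set(s.trial_table["block_id"]) == {"vis", "opto0.6"}
        opto = s.trial_table[s.trial_table["block_id"] == "opto0.6"]
        assert (opto["opto_power"] == 0.6).all()

    def test_blank_trials_present(self):
        s = generate_session(make_config(), seed=0, render=False)
        assert (s.trial_table["condition_id"] == blank_condition_id()).sum() >= 2

    def test_present_count_reproducible(self):
        cfg = make_config(trials_per_cell=75)
        a = generate_session(cfg, seed=123, render=False)
        b = generate_session(cfg, seed=123, render=False)
        pd.testing.assert_frame_equal(a.trial_table, b.trial_table)
        n_present = a.trial_table["target_present"].sum()
        assert 0 < n_present < len(a.trial_table)

    def test_paper_default_timeline_embedded(self):
        s = generate_session(make_config(), seed=0, render=False)
        assert s.timeline.frame_rate_hz == 20.0
        assert s.timeline.target_onset_ms == 250.0
        assert s.timeline.optostim_onset_ms == 290.0

    def test_stacks_rendered_and_finite(self, noisy_session):
        s = noisy_session
        assert s.stacks.shape == (200, 24, 64, 64)
        assert np.isfinite(s.stacks).all()

    def test_trial_rerenderable_in_isolation(self):
        # no drift => the per-trial child seed fully determines the stack
        cfg = make_config(trials_per_cell=3, ground_truth=dict(
            noise_sd=1.0, heartbeat_amplitude=1.0, motion_sd_px=0.1,
            rho_true=0.5))
        s = generate_session(cfg, seed=7)
        k = 17
        trial = s.trial_table.iloc[k]
        assert trial["trial_id"] == k
        stack, _ = render_trial_stack(s.ground_truth, trial, s.timeline,
                                      trial_rng(7, k), ny=cfg.ny, nx=cfg.nx)
        np.testing.assert_array_equal(s.stacks[k], stack.astype(np.float32))

    def test_zero_amplitude_session_constant_in_time(self):
        cfg = make_config(trials_per_cell=10, contrasts=(0.1,),
                          ground_truth=dict(nr_amp_max=0.0,
                                            opto_amplitude={0.6: 0.0}))
        s = generate_session(cfg, seed=5)
        # every frame identical to the first frame of its trial
        assert np.max(np.abs(s.stacks - s.stacks[:, :1])) == 0.0

    def test_no_blanks_raises(self):
        cfg = make_config(target_present_fraction=0.999, trials_per_cell=2)
        with pytest.raises(ValueError, match="blank"):
            generate_session(cfg, seed=1, render=False)


class TestChoiceProportionsConverge:
    def test_generated_proportions_match_model(self):
        """Hit/CR proportions converge to closed-form probabilities (3-sigma)."""
        n = 10_000
        alpha, beta, delta = 0.1, 1.5, 0.2
        pp = {"vis": PsychParams(alpha, beta, delta)}
        for c in (0.05, 0.1, 0.2):
            present = _table(n, contrast=c)
            out = simulate_choices(present, pp, np.random.default_rng(int(c * 1e4)))
            p = ndtr(0.5 * (c / alpha) ** beta - delta)
            rate = (out["outcome"] == "hit").mean()
            assert abs(rate - p) < 3 * np.sqrt(p * (1 - p) / n)
            absent = _table(n, contrast=c, present=False)
            out = simulate_choices(absent, pp, np.random.default_rng(int(c * 2e4)))
            q = ndtr(0.5 * (c / alpha) ** beta + delta)
            rate = (out["outcome"] == "correct_rejection").mean()
            assert abs(rate - q) < 3 * np.sqrt(q * (1 - q) / n)
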