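"""Unit and property tests of the RNAP-traffic layer."""


from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import convtx
from convtx import ParameterError, PauseSite, PromoterParams, TIConfig
from convtx.traffic import (FATES, check_occlusion, compute_rate_table,
                            draw_collision_outcome, meet_time,
                            occlusion_window, resolve_collision, resolve_sdi,
                            sample_firing_schedule, sample_trajectory,
                            sdi_boundary, simulate_traffic)

from _reference import brute_force_traffic


def noiseless_config(**kw):
    base = dict(
        pX=PromoterParams("pX", 20.0, 12.0, noise_cv=0.0),
        pY=PromoterParams("pY", 13.7, 9.5, noise_cv=0.0),
        v_sd=0.0, n_rounds=10, seed=0,
        sdc_survival=0.0, collision_one_survives=0.0)
    base.update(kw)
    return TIConfig(**base)


# ---------------------------------------------------------------------------
# firing schedules
# ---------------------------------------------------------------------------

class TestFiringSchedule:
    def test_zero_noise_is_deterministic(self, rng):
        p = PromoterParams("pX", tau_B=20.0, tau_I=12.0, noise_cv=0.0)
        bind, fire = sample_firing_schedule(p, 3, rng)
        assert bind.tolist() == [20.0, 40.0, 60.0]
        assert fire.tolist() == [32.0, 52.0, 72.0]

    def test_mean_interval_matches_tau_B(self, rng):
        p = PromoterParams("pX", tau_B=20.0, tau_I=12.0, noise_cv=0.05)
        bind, _ = sample_firing_schedule(p, 10_000, rng)
        intervals = np.diff(np.concatenate([[0.0], bind]))
        assert abs(intervals.mean() - 20.0) / 20.0 < 0.01
        assert abs(intervals.std() - 1.0) / 1.0 < 0.05

    def test_invalid_promoter_params_rejected(self):
        with pytest.raises(ParameterError):
            PromoterParams("pX", tau_B=-5.0, tau_I=1.0)
        with pytest.raises(ParameterError):
            PromoterParams("pX", tau_B=10.0, tau_I=12.0)  # tau_I >= tau_B


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

class TestTrajectory:
    def test_constant_velocity_arrival(self, rng):
        cfg = noiseless_config()
        tr = sample_trajectory("pX", 0.0, cfg, rng)
        assert tr.time_at(201.0) == pytest.approx((201 - 1) / 50.0)
        assert tr.time_at(1.0) == 0.0

    def test_pause_adds_dwell_time(self, rng):
        cfg = noiseless_config(pause_sites=(PauseSite("sense", 160, 2.0),))
        tr = sample_trajectory("pX", 0.0, cfg, rng)
        assert tr.time_at(201.0) == pytest.approx(4.0 + 2.0)
        assert tr.time_at(150.0) == pytest.approx(149 / 50.0)  # before pause
        assert tr.pause_at(3.5) == (160.0, 0.9)

    def test_antisense_coordinates(self, rng):
        cfg = noiseless_config()
        tr = sample_trajectory("pY", 10.0, cfg, rng)
        assert tr.time_at(301.0) == pytest.approx(10 + (400 - 301) / 50.0)
        assert tr.time_at(400.0) == 10.0

    def test_pause_on_other_strand_ignored(self, rng):
        cfg = noiseless_config(pause_sites=(PauseSite("antisense", 160, 2.0),))
        tr = sample_trajectory("pX", 0.0, cfg, rng)
        assert tr.time_at(201.0) == pytest.approx(4.0)

    def test_trajectory_covers_occlusion_window(self, rng):
        cfg = noiseless_config()
        for origin, target in (("pX", "pY"), ("pY", "pX")):
            tr = sample_trajectory(origin, 0.0, cfg, rng)
            entry, exit_ = occlusion_window(target, cfg)
            assert tr.time_at(entry) < tr.time_at(exit_) <= tr.end_time


# ---------------------------------------------------------------------------
# occlusion
# ---------------------------------------------------------------------------

class TestOcclusion:
    def test_no_opposing_traffic(self, rng):
        cfg = noiseless_config()
        assert not check_occlusion(5.0, "pY", [], cfg)

    def test_closed_form_window_at_pY(self, rng):
        cfg = noiseless_config()
        tr = sample_trajectory("pX", 0.0, cfg, rng)
        # center transits 382.5 -> 487.5 at 50 bp/s from position 1
        t_in, t_out = (382.5 - 1) / 50.0, (487.5 - 1) / 50.0
        assert t_in == pytest.approx(7.63)
        assert t_out == pytest.approx(9.73)
        assert check_occlusion(8.0, "pY", [tr], cfg)
        assert not check_occlusion(10.0, "pY", [tr], cfg)
        assert not check_occlusion(7.5, "pY", [tr], cfg)

    def test_symmetric_window_at_pX(self, rng):
        cfg = noiseless_config()
        tr = sample_trajectory("pY", 0.0, cfg, rng)
        t_in = (400 - 18.5) / 50.0
        assert check_occlusion(t_in + 0.5, "pX", [tr], cfg)
        assert not check_occlusion(t_in - 0.5, "pX", [tr], cfg)


# ---------------------------------------------------------------------------
# sitting ducks
# ---------------------------------------------------------------------------

class TestSDI:
    def _ec_and_sdc(self, rng, survival):
        cfg = noiseless_config(sdc_survival=survival)
        ec = sample_trajectory("pX", 0.0, cfg, rng)
        t_cross = ec.time_at(sdi_boundary("pY", cfg))
        sdc = (t_cross - 1.0, t_cross + 5.0, "pY")  # bound, still initiating
        return cfg, ec, sdc

    def test_zero_survival_always_dislodges(self, rng):
        cfg, ec, sdc = self._ec_and_sdc(rng, 0.0)
        for _ in range(50):
            assert resolve_sdi(ec, sdc, cfg, rng) == "sdc_dislodged"

    def test_certain_survival_truncates_at_l_minus_half_footprint(self, rng):
        cfg, ec, sdc = self._ec_and_sdc(rng, 1.0)
        assert resolve_sdi(ec, sdc, cfg, rng) == "ec_truncated"
        from convtx.traffic import truncated_length
        assert truncated_length("pX", 382.5, 400) == 382
        assert truncated_length("pY", 18.5, 400) == 382

    def test_outside_window_is_logic_error(self, rng):
        cfg, ec, sdc = self._ec_and_sdc(rng, 0.0)
        bad = (sdc[0], ec.time_at(sdi_boundary("pY", cfg)) - 0.5, "pY")
        with pytest.raises(RuntimeError):
            resolve_sdi(ec, bad, cfg, rng)

    def test_survival_fraction_binomial(self, rng):
        cfg, ec, sdc = self._ec_and_sdc(rng, 0.1)
        n = 100_000
        dislodged = sum(resolve_sdi(ec, sdc, cfg, rng) == "sdc_dislodged"
                        for _ in range(n))
        assert abs(dislodged / n - 0.9) < 0.005


# ---------------------------------------------------------------------------
# collisions
# ---------------------------------------------------------------------------

class TestCollision:
    def test_symmetric_closed_form(self, rng):
        cfg = noiseless_config(collision_one_survives=1.0)
        s = sample_trajectory("pX", 0.0, cfg, rng)
        a = sample_trajectory("pY", 0.0, cfg, rng)
        t, ps, pa = meet_time(s, a, cfg)
        assert t == pytest.approx((399 - 35) / 100.0)
        assert ps == pytest.approx(183.0)
        assert pa == pytest.approx(218.0)
        from convtx.traffic import truncated_length
        assert truncated_length("pX", ps, 400) == 183
        assert truncated_length("pY", pa, 400) == 183

    def test_non_overlapping_lifetimes_never_meet(self, rng):
        cfg = noiseless_config()
        s = sample_trajectory("pX", 0.0, cfg, rng)
        a = sample_trajectory("pY", 1000.0, cfg, rng)
        assert meet_time(s, a, cfg) is None
        out = resolve_collision(s, a, cfg, rng)
        assert out.kind == "no_collision"

    def test_immediate_contact_on_firing(self, rng):
        cfg = noiseless_config()
        s = sample_trajectory("pX", 0.0, cfg, rng)
        # antisense fires when the sense center sits at 380: gap is 20 < 35
        t_fire = s.time_at(380.0)
        a = sample_trajectory("pY", t_fire, cfg, rng)
        t, ps, pa = meet_time(s, a, cfg)
        assert t == pytest.approx(t_fire)
        assert ps == pytest.approx(380.0)

    def test_outcome_frequencies(self, rng):
        n = 100_000
        counts = {"both_fall": 0, "sense_survives": 0, "anti_survives": 0}
        for _ in range(n):
            counts[draw_collision_outcome(rng, 0.8)] += 1
        assert abs(counts["both_fall"] / n - 0.20) < 0.005
        assert abs(counts["sense_survives"] / n - 0.40) < 0.005
        assert abs(counts["anti_survives"] / n - 0.40) < 0.005


# ---------------------------------------------------------------------------
# whole simulations
# ---------------------------------------------------------------------------

class TestSimulateTraffic:
    def test_fates_partition_rounds(self, study_ti):
        res = simulate_traffic(study_ti)
        for prom, total in (("pX", res.n_rounds_pX), ("pY", res.n_rounds_pY)):
            counts = res.counts(prom)
            assert sum(counts.values()) == total
            assert set(counts) == set(FATES)

    def test_disabled_antisense_promoter_means_no_interference(self):
        cfg = TIConfig(
            pX=PromoterParams("pX", 20.0, 12.0),
            pY=PromoterParams("pY", 1e7, 9.5),
            n_rounds=200, seed=3)
        res = simulate_traffic(cfg)
        rt = compute_rate_table(res)
        assert rt.eta_x == 1.0
        assert rt.eta_xk == {}
        assert res.n_rounds_pY == 0

    def test_seed_reproducibility(self, study_ti):
        r1 = simulate_traffic(study_ti)
        r2 = simulate_traffic(study_ti)
        assert [(o.origin, o.round_index, o.fate, o.cause, o.truncated_length)
                for o in r1.outcomes] == \
               [(o.origin, o.round_index, o.fate, o.cause, o.truncated_length)
                for o in r2.outcomes]

    def test_different_seed_changes_outcomes(self, study_ti):
        r1 = simulate_traffic(study_ti)
        r2 = simulate_traffic(study_ti.with_seed(study_ti.seed + 1))
        assert [o.fate for o in r1.outcomes] != [o.fate for o in r2.outcomes]

    def test_truncation_lengths_bounded(self, study_ti):
        res = simulate_traffic(study_ti)
        for prom in ("pX", "pY"):
            lengths = res.truncated_lengths(prom)
            if lengths.size:
                assert lengths.min() >= 1
                assert lengths.max() <= study_ti.L - study_ti.fp_ec / 2

    @pytest.mark.parametrize("alpha_lo,alpha_hi", [(0.4, 1.7)])
    def test_collisions_shift_toward_sense_promoter(self, alpha_lo, alpha_hi):
        med = {}
        for a in (alpha_lo, alpha_hi):
            cfg = TIConfig.study_defaults(n_rounds=6000, seed=5).with_alpha(a)
            res = simulate_traffic(cfg)
            lengths = [o.truncated_length for o in res.outcomes
                       if o.origin == "pX" and o.fate == "truncated"
                       and o.cause.startswith("collision")]
            med[a] = np.median(lengths)
        assert med[alpha_hi] < med[alpha_lo]

    def test_monotone_interference_with_promoter_strength(self):
        etas_x, etas_y = [], []
        for a in (0.1, 0.5, 1.0, 2.0):
            cfg = TIConfig.study_defaults(n_rounds=4000, seed=11).with_alpha(a)
            rt = compute_rate_table(simulate_traffic(cfg))
            etas_x.append(rt.eta_x)
            etas_y.append(rt.eta_y)
        assert all(np.diff(etas_x) < 0)
        assert all(np.diff(etas_y) > -0.03)  # non-decreasing within MC noise


# ---------------------------------------------------------------------------
# equivalence with the fixed-step oracle
# ---------------------------------------------------------------------------

class TestOracleEquivalence:
    @pytest.mark.parametrize("kw", [
        dict(),
        dict(sdc_survival=1.0),
        dict(pY=PromoterParams("pY", 27.3, 9.5, noise_cv=0.0)),
        dict(pY=PromoterParams("pY", 27.3, 9.5, noise_cv=0.0),
             sdc_survival=1.0),
        dict(pY=PromoterParams("pY", 26.0, 9.5, noise_cv=0.0),
             pause_sites=(PauseSite("sense", 160, 5.0,
                                    removal_prob_on_hit=1.0),)),
        dict(pY=PromoterParams("pY", 26.0, 9.5, noise_cv=0.0),
             pause_sites=(PauseSite("sense", 160, 5.0,
                                    removal_prob_on_hit=0.0),)),
        dict(L=150),
        dict(pX=PromoterParams("pX", 11.3, 8.0, noise_cv=0.0), L=700,
             n_rounds=8),
    ])
    def test_event_driven_matches_time_stepping(self, kw):
        cfg = noiseless_config(**kw)
        res = simulate_traffic(cfg)
        ref = brute_force_traffic(cfg)
        mine = sorted((o.origin, o.round_index, o.fate, o.truncated_length)
                      for o in res.outcomes)
        theirs = sorted((r.origin, r.index, r.fate, r.truncated_length)
                        for r in ref)
        assert len(mine) == len(theirs)
        for m, t in zip(mine, theirs):
            assert m[:3] == t[:3]
            if m[3] is not None:
                assert abs(m[3] - t[3]) <= 1

    def test_pause_oracle_case_actually_exercises_pause(self):
        # guard: the pause configuration above must produce a pause-site
        # truncation, otherwise it tests nothing
        cfg = noiseless_config(
            pY=PromoterParams("pY", 26.0, 9.5, noise_cv=0.0),
            pause_sites=(PauseSite("sense", 160, 5.0,
                                   removal_prob_on_hit=1.0),))
        res = simulate_traffic(cfg)
        lengths = res.truncated_lengths("pX")
        assert (np.abs(lengths - 160) <= 1).any()


# ---------------------------------------------------------------------------
# rate table
# ---------------------------------------------------------------------------

class TestRateTable:
    def test_counting_oracle(self):
        from convtx.traffic import RoundOutcome, TrafficResult
        cfg = noiseless_config()
        outcomes = (
            [RoundOutcome("pX", i, "full_length") for i in range(6)]
            + [RoundOutcome("pX", 6, "occluded")]
            + [RoundOutcome("pX", 7, "truncated", 100, "collision_both_fall")]
            + [RoundOutcome("pX", 8, "truncated", 40, "collision_both_fall")]
            + [RoundOutcome("pX", 9, "truncated", 100, "sdc_roadblock")]
            + [RoundOutcome("pY", i, "full_length") for i in range(4)]
            + [RoundOutcome("pY", 4, "sdi_dislodged")])
        res = TrafficResult(cfg, outcomes, n_rounds_pX=10, n_rounds_pY=5)
        rt = compute_rate_table(res)
        assert rt.eta_x == 0.6
        assert rt.eta_y == 0.8
        assert rt.eta_xk == {100: 0.2, 40: 0.1}
        # lengths <= 60 nt are excluded from the antisense-competent pool
        assert rt.k_xk_total == pytest.approx((1 / 20.0) * 0.2)
        assert rt.k_x == pytest.approx((1 / 20.0) * 0.6)
        assert rt.k_y == pytest.approx((1 / 13.7) * 0.8)

    def test_full_success_rate_identity(self):
        from convtx.traffic import RoundOutcome, TrafficResult
        cfg = noiseless_config()
        outcomes = [RoundOutcome("pX", i, "full_length") for i in range(5)]
        res = TrafficResult(cfg, outcomes, n_rounds_pX=5, n_rounds_pY=0)
        rt = compute_rate_table(res)
        assert rt.k_x == pytest.approx(0.05)
        assert rt.k_y == 0.0


@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_fate_conservation_under_random_small_configs(seed):
    """Every round receives exactly one fate, for arbitrary seeds."""
    from convtx.config import make_fixture
    cfg = make_fixture("randomized", seed).ti
    cfg = replace(cfg, n_rounds=60)
    res = simulate_traffic(cfg)
    assert sum(res.counts("pX").values()) == res.n_rounds_pX
    assert sum(res.counts("pY").values()) == res.n_rounds_pY
    for o in res.outcomes:
        assert (o.truncated_length is not None) == (o.fate == "truncated")
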