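"""Affinity-maturation model: scoring, rates, stage machine, sampling."""

import math

import numpy as np
import pytest

from clonesim.am import (
    AMConfig,
    N_SLOTS,
    SLOT_G,
    SLOT_GA,
    TargetScorer,
    affinity,
    aa_to_codes,
    blosum62,
    blosum_delta,
    cdr_mask,
    cell_rates,
    codes_to_aa,
    diverged_target,
    dormant_spec,
    infected_spec,
    make_slots,
    memory_activation_rate,
    materialize_sequence,
    should_switch,
    reduced_config,
    run_am,
    sample_cells,
    synthetic_root_sequence,
    translate_codes,
)
from clonesim.bdt import EngineState, Genealogy, total_rates
from clonesim.shm import encode_dna

B62 = blosum62()


def small_cfg(**overrides) -> AMConfig:
    """Tiny fast-activating configuration (C = 300) for quick end-to-end runs."""
    cfg = reduced_config()
    cfg.C = 300.0
    cfg.lambda_t = 2.0
    cfg.t_start = (0.0, 12.0)
    cfg.max_infected_days = 60.0
    for k, v in overrides.items():
        setattr(cfg, k, v)
    if cfg.targets is not None and len(cfg.targets) != cfg.r:
        cfg.targets = cfg.targets[:cfg.r]
    return cfg


class TestBlosumDelta:
    def test_identity_is_zero(self):
        z = "ACDEFGHIKLMNPQRSTVWYACDEF"
        mask = cdr_mask(25, ((6, 7), (10, 12), (20, 22)))
        assert blosum_delta(z, z, mask, 1 / 3) == 0.0

    def test_single_cdr_mismatch(self):
        z = "A" * 10
        x = "A" * 5 + "W" + "A" * 4  # mismatch at position 6 (CDR)
        mask = cdr_mask(10, ((6, 7),))
        expected = B62[aa_to_codes("W")[0], aa_to_codes("A")[0]] - B62[0, 0]
        assert blosum_delta(x, z, mask, 1 / 3) == pytest.approx(expected)

    def test_framework_mismatch_scaled_by_wf(self):
        z = "A" * 10
        x = "W" + "A" * 9  # mismatch at position 1 (framework)
        mask = cdr_mask(10, ((6, 7),))
        base = B62[aa_to_codes("W")[0], 0] - B62[0, 0]
        for wf in (1 / 3, 1 / 5, 2.0):
            assert blosum_delta(x, z, mask, wf) == pytest.approx(wf * base)

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError, match="length mismatch"):
            blosum_delta("AAA", "AAAA", cdr_mask(4, ()), 1.0)

    def test_nonpositive_for_standard_matrix(self, rng):
        mask = cdr_mask(20, ((3, 8),))
        z = codes_to_aa(rng.integers(0, 20, size=20))
        for _ in range(50):
            x = codes_to_aa(rng.integers(0, 20, size=20))
            assert blosum_delta(x, z, mask, 1 / 3) <= 0.0


class TestAffinityAndActivation:
    def test_score_zero_gives_unit_affinity(self):
        assert affinity(0.0, 0.1) == 1.0

    def test_baseline_score_default_pressure(self):
        assert affinity(-120.0, 0.1) == pytest.approx(math.exp(-12))

    def test_stop_codon_scores_none(self):
        codes = encode_dna("TAA" + synthetic_root_sequence(25)[3:])
        aa = translate_codes(codes)
        scorer = TargetScorer(np.zeros(25, dtype=np.int64),
                              cdr_mask(25, ((6, 7),)), 1 / 3)
        assert scorer.score(aa) is None

    def test_typical_memory_cell_activates_at_lambda_t(self):
        a = affinity(-120.0, 0.1)  # f = Delta_0 under defaults
        rate = memory_activation_rate(a, 0.01, 0.5, 0.1, -120.0)
        assert rate == pytest.approx(0.01, rel=1e-12)

    def test_zero_affinity_never_activates(self):
        assert memory_activation_rate(0.0, 0.01, 0.5, 0.1, -120.0) == 0.0

    def test_twenty_points_above_baseline(self):
        a = affinity(-100.0, 0.1)
        rate = memory_activation_rate(a, 0.01, 0.5, 0.1, -120.0)
        assert rate == pytest.approx(0.01 * math.e, rel=1e-12)

    def test_monotone_in_affinity(self):
        rates = [memory_activation_rate(a, 0.01, 0.5, 0.1, -120.0)
                 for a in (0.01, 0.1, 1.0, 10.0)]
        assert rates == sorted(rates)


class TestCellRates:
    CFG = AMConfig(r=1, t_start=(0.0,))

    def test_memory_cell_dormant_defaults(self):
        assert cell_rates(0, 1.0, "dormant", 0.0, self.CFG) == (0.0, 1 / 402, 0.0)

    def test_activated_birth_rate_default(self):
        b, _, _ = cell_rates(1, 1.0, "infected", 10.0, self.CFG)
        assert b == 6.0

    def test_homogeneous_death_independent_of_affinity(self):
        cfg = self.CFG
        n = 50
        for a in (0.01, 1.0, 100.0):
            _, d, _ = cell_rates(1, a, "infected", n * a, cfg)
            expect = cfg.lambda_b * (1 - cfg.rho_p - cfg.rho_m) * n / cfg.C \
                + cfg.rho_p * cfg.lambda_b
            assert d == pytest.approx(expect, rel=1e-12)

    def test_stop_codon_cell_gets_fast_death(self):
        _, d, t = cell_rates(1, 0.0, "infected", 5.0, self.CFG)
        assert d == pytest.approx(self.CFG.lambda_d + self.CFG.rho_p * self.CFG.lambda_b)
        assert t == pytest.approx(self.CFG.rho_m * self.CFG.lambda_b)

    def test_all_rates_nonnegative_on_random_states(self, rng):
        cfg = self.CFG
        for _ in range(200):
            g = int(rng.integers(0, 2))
            a = float(rng.choice([0.0, rng.uniform(0, 5)]))
            sigma = float(rng.uniform(0, 1e4))
            stage = str(rng.choice(["infected", "dormant"]))
            assert all(r >= 0 for r in cell_rates(g, a, stage, sigma, cfg))


class TestRateSpecAgainstDirectEvaluation:
    """The engine's polynomial terms must reproduce the per-cell rate table."""

    @pytest.mark.parametrize("stage", ["infected", "dormant"])
    def test_slots_reproduce_direct_rates(self, stage, rng):
        cfg = AMConfig(r=1, t_start=(0.0,))
        spec = infected_spec(cfg) if stage == "infected" else dormant_spec(cfg)
        state = EngineState(N_SLOTS)
        cells = []
        for eid in range(20):
            g = int(rng.integers(0, 2))
            a = float(rng.choice([0.0, float(rng.uniform(0.001, 3.0))]))
            t_act = memory_activation_rate(a, cfg.lambda_t, cfg.rho_a, cfg.A, cfg.Delta_0)
            state.add(eid, make_slots(g, a, t_act))
            cells.append((g, a))
        sigma = state.totals[SLOT_GA]
        lam_direct = 0.0
        for eid, (g, a) in enumerate(cells):
            b, d, t = cell_rates(g, a, stage, sigma, cfg)
            be, de, te = spec.entity_rates(state.entity_slots(eid), state)
            assert be == pytest.approx(b, rel=1e-9, abs=1e-12)
            assert de == pytest.approx(d, rel=1e-9, abs=1e-12)
            assert te == pytest.approx(t, rel=1e-9, abs=1e-12)
            lam_direct += b + d + t
        *_, lam = total_rates(state, spec)
        assert lam == pytest.approx(lam_direct, rel=1e-9)

    def test_dormant_stage_has_no_birth_or_transform(self):
        cfg = AMConfig(r=1, t_start=(0.0,))
        state = EngineState(N_SLOTS)
        state.add(0, make_slots(1, 2.0, 0.0))
        state.add(1, make_slots(0, 0.5, 0.004))
        b, _, t, _ = total_rates(state, dormant_spec(cfg))
        assert b == 0.0 and t == 0.0


class TestTransformAndBirth:
    def test_transform_flips_g_and_keeps_sequence(self):
        # slot bookkeeping of the flip: sigma loses the cell's affinity
        s_act = make_slots(1, 2.0, 0.1)
        s_mem = make_slots(0, 2.0, 0.1)
        assert s_act[SLOT_GA] == 2.0 and s_mem[SLOT_GA] == 0.0
        assert s_mem[SLOT_G] == 0 and s_act[SLOT_G] == 1

    def test_memory_slots_zero_out_activated_terms(self):
        s = make_slots(0, 3.0, 0.02)
        assert s[SLOT_GA] == 0.0 and s[3] == 0.0  # g/a slot

    def test_child_closer_to_target_has_higher_affinity(self):
        cfg = reduced_config()
        mask = cfg.cdr_mask
        zeta = cfg.targets[1]
        parent = cfg.targets[0]
        # substitute one CDR position of the parent toward the target
        pos = next(p for p in np.flatnonzero(mask) if parent[p] != zeta[p])
        child = parent[:pos] + zeta[pos] + parent[pos + 1:]
        d_parent = blosum_delta(parent, zeta, mask, cfg.w_f)
        d_child = blosum_delta(child, zeta, mask, cfg.w_f)
        assert affinity(d_child, cfg.A) > affinity(d_parent, cfg.A)


class TestShouldSwitch:
    def test_threshold_boundary_inclusive(self):
        cfg = reduced_config()
        M = cfg.M_value
        assert should_switch(cfg, 0.0, 5.0, M)
        assert not should_switch(cfg, 0.0, 5.0, M * (1 - 1e-12))

    def test_fixed_duration_boundary(self):
        cfg = reduced_config()
        cfg.switch_rule = "fixed_duration"
        cfg.infected_duration = 50.0
        assert should_switch(cfg, 10.0, 60.0, 0.0)
        assert not should_switch(cfg, 10.0, 59.9, 1e9)


class TestConfigValidation:
    def test_rho_sum_must_stay_below_one(self):
        cfg = AMConfig(r=1, t_start=(0.0,), rho_p=0.5, rho_m=0.6)
        with pytest.raises(ValueError, match="rho"):
            cfg.validate()

    def test_round_times_strictly_increasing(self):
        cfg = reduced_config()
        cfg.t_start = (0.0, 0.0)
        with pytest.raises(ValueError, match="increasing"):
            cfg.validate()

    def test_root_with_stop_codon_rejected(self):
        cfg = reduced_config()
        cfg.root_sequence = "TAA" + cfg.root_sequence[3:]
        with pytest.raises(ValueError, match="stop"):
            cfg.validate()

    def test_target_length_checked(self):
        cfg = reduced_config()
        cfg.targets = (cfg.targets[0], cfg.targets[1][:-1])
        with pytest.raises(ValueError, match="length"):
            cfg.validate()

    def test_default_switch_threshold_formula(self):
        cfg = AMConfig(r=1, t_start=(0.0,))
        assert cfg.M_value == pytest.approx(1e5 * math.exp(0.1 * -75.0), rel=1e-12)

    def test_diverged_target_only_touches_cdr(self):
        cfg = reduced_config()
        mask = cfg.cdr_mask
        t0, t1 = cfg.targets
        for p in range(cfg.L):
            if not mask[p]:
                assert t0[p] == t1[p]


class TestRunAM:
    def test_no_activation_means_no_births(self):
        cfg = small_cfg(r=1, t_start=(0.0,), lambda_t=1e-12,
                        switch_rule="fixed_duration", infected_duration=5.0)
        res = run_am(cfg, seed=11)
        assert all(m is None for m in res.muts)
        assert (res.series[:, 3] == 0).all()  # never any activated cells

    def test_determinism_same_seed(self):
        cfg = small_cfg()
        r1 = run_am(cfg, seed=42)
        r2 = run_am(cfg, seed=42)
        assert r1.n_events == r2.n_events and r1.reason == r2.reason
        assert len(r1.genealogy) == len(r2.genealogy)
        np.testing.assert_array_equal(r1.series, r2.series)

    def test_reduced_run_reaches_threshold_with_bounded_population(self):
        cfg = small_cfg()
        res = run_am(cfg, seed=42)
        assert res.reason == "completed"
        final = res.rounds[-1]
        assert final.sigma_end >= cfg.M_value
        assert final.n_activated_end <= 2 * cfg.C

    def test_sigma_matches_recomputed_total_affinity(self):
        cfg = small_cfg()
        res = run_am(cfg, seed=42)
        scorer = TargetScorer(aa_to_codes(cfg.targets[-1]), cfg.cdr_mask, cfg.w_f)
        sigma = 0.0
        for eid in res.alive:
            if res.g[eid] == 1:
                sc = scorer.score(translate_codes(res.sequences[eid]))
                sigma += 0.0 if sc is None else affinity(sc, cfg.A)
        assert res.rounds[-1].sigma_end == pytest.approx(sigma, rel=1e-6)

    def test_materialized_sequences_match_live_cells(self):
        cfg = small_cfg()
        res = run_am(cfg, seed=42)
        labels = sample_cells(res, 5, seed=0)
        for eid in labels.values():
            np.testing.assert_array_equal(
                materialize_sequence(res, eid), res.sequences[eid])

    def test_carrying_capacity_equilibrium(self):
        """Homogeneous activated population settles near n* = C(1-rho_p)/(1-rho_p-rho_m)."""
        cfg = small_cfg(r=1, t_start=(0.0,), mu=1e-9,
                        switch_rule="fixed_duration", infected_duration=10.0)
        n_star = cfg.C * (1 - cfg.rho_p) / (1 - cfg.rho_p - cfg.rho_m)
        ok = 0
        total = 0
        for seed in range(20):
            res = run_am(cfg, seed=100 + seed)
            if res.reason != "completed":
                continue
            sel = res.series[:, 0] >= 5.0
            if not sel.any() or res.series[sel, 3].max() == 0:
                continue
            total += 1
            mean_pop = res.series[sel, 3].mean()
            if abs(mean_pop - n_star) / n_star < 0.25:
                ok += 1
        assert total >= 15 and ok == total

    def test_selective_pressure_widens_affinity_proportion(self):
        """With a fixed sequence gap, the share of the better type grows with A."""
        gap = 10.0  # score advantage of H over L
        shares = []
        for A in (0.05, 0.1, 0.2, 0.4):
            rho = math.exp(A * gap)
            shares.append(rho / (1 + rho))
        assert shares == sorted(shares) and shares[0] > 0.5


@pytest.fixture(scope="module")
def completed():
    return run_am(small_cfg(), seed=42)


class TestSampling:

    def test_zero_sample_empty(self, completed):
        assert sample_cells(completed, 0, seed=1) == {}

    def test_full_pool_sampled(self, completed):
        pool = [e for e in completed.alive if completed.g[e] == 0]
        labels = sample_cells(completed, len(pool), seed=1)
        assert sorted(labels.values()) == sorted(pool)

    def test_oversampling_reports_pool_size(self, completed):
        pool = [e for e in completed.alive if completed.g[e] == 0]
        with pytest.raises(ValueError, match=str(len(pool))):
            sample_cells(completed, len(pool) + 1, seed=1)

    def test_same_seed_same_sample(self, completed):
        assert sample_cells(completed, 10, seed=3) == sample_cells(completed, 10, seed=3)

    def test_labels_unique_and_well_formed(self, completed):
        labels = sample_cells(completed, 10, seed=3)
        assert len(labels) == 10 == len(set(labels.values()))
        assert all(k.startswith("Psi_") for k in labels)
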