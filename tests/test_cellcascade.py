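"""Hepatocyte event-cascade kernels, mechanism presets, and variants.

The binomial-count kernels are checked against a brute-force per-object
Bernoulli simulator: the two must be distributionally identical, verified
by chi-squared goodness of fit on 10^5 replicates of small states.
"""

import numpy as np
import pytest
from scipy import stats

from vlobule.cellcascade import (
    CASCADE_PHASES,
    HOUR,
    VARIANT_KNOBS,
    CellParams,
    HepatocyteState,
    MechanismConfig,
    amplification_step,
    apply_deaths,
    bind_config,
    death_trigger_check,
    draw_death_delay,
    hepatocyte_step,
    make_variant,
    mechanism_preset,
    metabolism_step,
    mitigation_step,
    napqi_fate_step,
)
from vlobule.lobule import GradientSpec, canonical_dpp_population, gradient_value

ALPHA = 0.01
N_REP = 100_000


def single_cell(dpp=0.0, cfg=None, **counters):
    cfg = cfg or mechanism_preset("NZ")
    h = HepatocyteState.zeros([dpp])
    for k, v in counters.items():
        getattr(h, k)[0] = v
    return h, bind_config(cfg, h.dpp, 50.0)


def replicate_counts(kernel, field, n_rep, seed, **kw):
    """Distribution of one counter after `kernel` over n_rep fresh replicates."""
    rng = np.random.default_rng(seed)
    # vectorized replicates: one population of n_rep identical cells
    h = HepatocyteState.zeros(np.full(n_rep, kw.pop("dpp", 0.0)))
    cfg = kw.pop("cfg")
    for k, v in kw.items():
        getattr(h, k)[:] = v
    params = bind_config(cfg, h.dpp, 50.0)
    kernel(h, params, rng)
    return getattr(h, field)


def bernoulli_reference(n_objects, p, n_rep, seed):
    """Per-object Bernoulli brute force: number of successes among n objects."""
    rng = np.random.default_rng(seed)
    return (rng.random((n_rep, n_objects)) < p).sum(axis=1)


def chi2_same_distribution(a, b, n_max):
    """Chi-squared two-sample test over integer support [0, n_max]."""
    ca = np.bincount(a, minlength=n_max + 1)
    cb = np.bincount(b, minlength=n_max + 1)
    keep = (ca + cb) >= 10
    obs = np.vstack([ca[keep], cb[keep]])
    return stats.chi2_contingency(obs)[1]


class TestOracleEquivalence:
    """Binomial kernels vs per-object Bernoulli brute force (chi-squared)."""

    def test_metabolism_consumption(self):
        cfg = mechanism_preset("NZ")
        # at the CV end p_metabolize = 0.95
        consumed = 10 - replicate_counts(
            metabolism_step, "apap", N_REP, seed=1, cfg=cfg, dpp=50.0, apap=10
        )
        ref = bernoulli_reference(10, 0.95, N_REP, seed=2)
        assert consumed.mean() == pytest.approx(9.5, abs=0.02)
        assert chi2_same_distribution(consumed, ref, 10) > ALPHA

    def test_metabolism_napqi_split_at_entrance(self):
        # per-object NAPQI probability at the PP entrance is 0.35 * 0.33
        cfg = mechanism_preset("NZ")
        napqi = replicate_counts(
            metabolism_step, "napqi", N_REP, seed=3, cfg=cfg, dpp=0.0, apap=10
        )
        ref = bernoulli_reference(10, 0.35 * 0.33, N_REP, seed=4)
        assert chi2_same_distribution(napqi, ref, 10) > ALPHA

    def test_gsh_depletion_below_threshold(self):
        cfg = mechanism_preset("NZ")
        dep = replicate_counts(
            napqi_fate_step, "gsh_depletion_events", N_REP, seed=5, cfg=cfg, napqi=4
        )
        ref = bernoulli_reference(4, 0.5, N_REP, seed=6)
        assert dep.mean() == pytest.approx(2.0, abs=0.02)
        assert chi2_same_distribution(dep, ref, 4) > ALPHA

    def test_damage_split_above_threshold(self):
        cfg = mechanism_preset("NZ")
        kw = dict(cfg=cfg, napqi=10, gsh_depletion_events=10)
        mitod = replicate_counts(napqi_fate_step, "mitod_unamplified", N_REP, seed=7, **kw)
        nonmd = replicate_counts(napqi_fate_step, "nonmd", N_REP, seed=8, **kw)
        # thinned Bernoulli chain: react with 0.5, then mitoD with 0.5
        ref = bernoulli_reference(10, 0.25, N_REP, seed=9)
        assert mitod.mean() == pytest.approx(2.5, abs=0.02)
        assert nonmd.mean() == pytest.approx(2.5, abs=0.02)
        assert chi2_same_distribution(mitod, ref, 10) > ALPHA

    def test_amplification_additions(self):
        cfg = mechanism_preset("NZ")
        total = replicate_counts(
            amplification_step, "mitod_amplified", N_REP, seed=10, cfg=cfg,
            mitod_unamplified=1,
        )
        # 1 + DiscreteUniform{1..6}: support {2..7}, mean 4.5
        rng = np.random.default_rng(11)
        ref = 1 + rng.integers(1, 7, N_REP)
        assert total.min() >= 2 and total.max() <= 7
        assert total.mean() == pytest.approx(4.5, abs=0.02)
        assert chi2_same_distribution(total, ref, 7) > ALPHA

    def test_mitigation_removal(self):
        cfg = mechanism_preset("NZ")  # constant 0.67 mitigation
        left = replicate_counts(
            mitigation_step, "mitod_amplified", N_REP, seed=12, cfg=cfg,
            mitod_amplified=6,
        )
        removed = 6 - left
        ref = bernoulli_reference(6, 0.67, N_REP, seed=13)
        assert removed.mean() == pytest.approx(4.02, abs=0.03)
        assert chi2_same_distribution(removed, ref, 6) > ALPHA


class TestMetabolism:
    def test_triggered_cells_stop_metabolizing(self, rng):
        h, p = single_cell(apap=50)
        h.triggered[0] = True
        metabolism_step(h, p, rng)
        assert h.apap[0] == 50 and h.napqi[0] == 0

    def test_zero_apap_noop(self, rng):
        h, p = single_cell()
        s = metabolism_step(h, p, rng)
        assert s.apap_consumed == 0

    def test_count_conservation(self, rng):
        h, p = single_cell(dpp=25.0, apap=1000)
        s = metabolism_step(h, p, rng)
        assert s.apap_consumed == s.napqi_created + s.gs_created
        assert h.apap[0] + s.apap_consumed == 1000
        assert h.napqi[0] == s.napqi_created
        assert h.gs_exported[0] == s.gs_created


class TestNapqiFate:
    def test_no_damage_below_threshold(self, rng):
        h, p = single_cell(napqi=4)  # threshold 3.5, zero depletion events
        s = napqi_fate_step(h, p, rng)
        assert s.damage_created == 0
        assert h.gsh_depletion_events[0] == s.gsh_depletion_events

    def test_zero_napqi_noop(self, rng):
        h, p = single_cell(gsh_depletion_events=10)
        s = napqi_fate_step(h, p, rng)
        assert s.damage_created == 0 and s.gsh_depletion_events == 0

    def test_napqi_conservation(self, rng):
        h, p = single_cell(napqi=1000, gsh_depletion_events=0)
        before = h.napqi[0]
        s = napqi_fate_step(h, p, rng)
        assert before - h.napqi[0] == s.gsh_depletion_events + s.damage_created

    def test_fractional_threshold_uses_geq(self, rng):
        # threshold 3.5 on the cumulative counter: 3 events is below, 4 above
        h, p = single_cell(napqi=100, gsh_depletion_events=4)
        s = napqi_fate_step(h, p, np.random.default_rng(0))
        assert s.gsh_depletion_events == 0 and s.damage_created > 0
        h2, p2 = single_cell(napqi=100, gsh_depletion_events=3)
        s2 = napqi_fate_step(h2, p2, np.random.default_rng(0))
        assert s2.damage_created == 0 and s2.gsh_depletion_events > 0


class TestAmplification:
    def test_each_mitod_amplified_at_most_once(self, rng):
        h, p = single_cell(mitod_unamplified=5)
        amplification_step(h, p, rng)
        assert h.mitod_unamplified[0] == 0
        first = h.mitod_amplified[0]
        assert 10 <= first <= 35
        amplification_step(h, p, rng)  # amplified pool is absorbing
        assert h.mitod_amplified[0] == first

    def test_empty_pool_noop(self, rng):
        h, p = single_cell(mitod_amplified=3)
        s = amplification_step(h, p, rng)
        assert s.amplification_added == 0 and h.mitod_amplified[0] == 3

    def test_disabled_amplification_migrates_without_additions(self, rng):
        cfg = mechanism_preset("NZ")
        cfg = make_variant(cfg, {})  # copy
        from dataclasses import replace

        h, p = single_cell(cfg=replace(cfg, amplification=None), mitod_unamplified=4)
        amplification_step(h, p, rng)
        assert h.mitod_amplified[0] == 4 and h.mitod_unamplified[0] == 0


class TestTrigger:
    def test_threshold_boundary(self, rng):
        h, p = single_cell(mitod_amplified=6)
        death_trigger_check(h, p, 100.0, rng)
        assert h.triggered[0] and h.trigger_time[0] == 100.0
        h2, p2 = single_cell(mitod_amplified=5)
        death_trigger_check(h2, p2, 100.0, rng)
        assert not h2.triggered[0]

    def test_delay_within_uniform_support(self, rng):
        h = HepatocyteState.zeros(np.zeros(5000))
        h.mitod_amplified[:] = 10
        _, p = single_cell()
        death_trigger_check(h, p, 0.0, rng)
        delays = h.death_time - h.trigger_time
        assert delays.min() >= 1.2 * HOUR and delays.max() <= 12 * HOUR

    def test_trigger_is_irreversible_and_monotone(self, rng):
        h, p = single_cell(mitod_amplified=10)
        death_trigger_check(h, p, 5.0, rng)
        t0, d0 = h.trigger_time[0], h.death_time[0]
        h.mitod_amplified[0] = 0
        death_trigger_check(h, p, 6.0, rng)
        assert h.triggered[0] and h.trigger_time[0] == t0 and h.death_time[0] == d0

    def test_normal_delay_rule_floored_at_zero(self, rng):
        d = draw_death_delay(("normal", 7.2 * HOUR, 4.1 * HOUR), rng, 10_000)
        assert d.min() >= 0.0
        assert d.mean() == pytest.approx(7.2 * HOUR, rel=0.05)

    def test_dead_cells_are_inert(self, rng):
        h, p = single_cell(apap=100, napqi=50, mitod_amplified=50)
        h.triggered[0], h.death_time[0] = True, 10.0
        apply_deaths(h, 11.0)
        assert h.dead[0]
        for kernel in (metabolism_step, napqi_fate_step, mitigation_step):
            before = (h.apap[0], h.napqi[0], h.mitod[0])
            kernel(h, p, rng)
            assert (h.apap[0], h.napqi[0], h.mitod[0]) == before


class TestHepatocyteStep:
    def test_all_zero_state_is_absorbing(self, rng):
        h, p = single_cell()
        out = hepatocyte_step(h, p, 1.0, rng)
        assert set(out) == set(CASCADE_PHASES)
        assert h.apap[0] == h.napqi[0] == h.mitod[0] == h.nonmd[0] == 0
        assert not h.triggered[0]

    def test_deterministic_limit_triggers_within_bounded_steps(self):
        # all probabilities 1, threshold 1, at the CV: a single APAP must
        # metabolize to NAPQI, deplete past threshold 0, react to mitoD and
        # trigger within a handful of steps
        cfg = MechanismConfig(
            name="limit",
            p_metabolize=GradientSpec.constant(1.0),
            p_napqi=GradientSpec.constant(1.0),
            gsh_threshold=GradientSpec.constant(0.0),
            p_mitod_mitigation=GradientSpec.constant(0.0),
            p_react=1.0,
            p_mitod_split=1.0,
            p_nonmd_mitigation=0.0,
            death_trigger_threshold=1,
        )
        h = HepatocyteState.zeros([50.0])
        h.apap[0] = 1
        p = bind_config(cfg, h.dpp, 50.0)
        rng = np.random.default_rng(0)
        for t in range(1, 10):
            hepatocyte_step(h, p, float(t), rng)
            if h.triggered[0]:
                break
        assert h.triggered[0]

    def test_single_napqi_cannot_reach_threshold_two_without_amplification(self):
        # with amplification disabled and perfect mitigation, one NAPQI can
        # yield at most one concurrent mitoD, so a threshold of 2 never fires
        from dataclasses import replace

        cfg = replace(
            mechanism_preset("NZ"),
            amplification=None,
            p_mitod_mitigation=GradientSpec.constant(1.0),
            death_trigger_threshold=2,
        )
        h = HepatocyteState.zeros([0.0])
        h.napqi[0] = 1
        h.gsh_depletion_events[0] = 10
        p = bind_config(cfg, h.dpp, 50.0)
        rng = np.random.default_rng(1)
        for t in range(1, 200):
            hepatocyte_step(h, p, float(t), rng)
        assert not h.triggered[0]

    def test_mean_step_outcome_matches_bernoulli_oracle(self):
        # one full shuffled step on 10^5 replicate cells: mean APAP consumed
        # must match the per-object Bernoulli mean within 3 standard errors
        n = 100_000
        cfg = mechanism_preset("NZ")
        h = HepatocyteState.zeros(np.full(n, 25.0))
        h.apap[:] = 5
        p = bind_config(cfg, h.dpp, 50.0)
        hepatocyte_step(h, p, 1.0, np.random.default_rng(2))
        p_mid = 0.65  # p_metabolize at the midpoint
        consumed = 5 - h.apap
        se = np.sqrt(5 * p_mid * (1 - p_mid) / n)
        assert abs(consumed.mean() - 5 * p_mid) < 3 * se


class TestPresets:
    def test_nz_is_location_independent_downstream(self):
        nz = mechanism_preset("NZ")
        assert nz.gsh_threshold.shape == "constant"
        assert nz.gsh_threshold.v_pp == 3.5
        assert nz.p_mitod_mitigation.shape == "constant"
        assert nz.p_mitod_mitigation.v_pp == 0.67

    def test_gnz_differs_from_nz_only_in_threshold(self):
        nz, gnz = mechanism_preset("NZ"), mechanism_preset("GNZ")
        assert gnz.gsh_threshold != nz.gsh_threshold
        assert gnz.gsh_threshold.v_pp == 5.0
        assert gnz.p_mitod_mitigation == nz.p_mitod_mitigation
        assert gnz.p_metabolize == nz.p_metabolize and gnz.p_napqi == nz.p_napqi

    def test_mgnz_combines_both_zonations(self):
        mgnz = mechanism_preset("MGNZ")
        assert mgnz.gsh_threshold.shape == "linear"
        assert mgnz.p_mitod_mitigation.shape == "reverse_sigmoid"

    @pytest.mark.parametrize("name,field,target", [
        ("MGNZ", "p_mitod_mitigation", 0.67),
        ("MNZ", "p_mitod_mitigation", 0.67),
        ("MGNZ", "gsh_threshold", 3.5),
        ("GNZ", "gsh_threshold", 3.5),
    ])
    def test_calibrated_population_means(self, name, field, target):
        pop, d_max = canonical_dpp_population()
        cfg = mechanism_preset(name)
        mean = float(np.mean(gradient_value(getattr(cfg, field), pop, d_max)))
        assert mean == pytest.approx(target, abs=1e-6)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            mechanism_preset("XYZ")


class TestVariants:
    def test_override_gsh_entrance_values(self):
        base = mechanism_preset("MGNZ")
        for v_pp in (8.0, 3.0):
            var = make_variant(
                base, {"gsh_threshold": GradientSpec.linear(v_pp, base.gsh_threshold.v_cv)}
            )
            assert var.gsh_threshold.v_pp == v_pp
            assert base.gsh_threshold.v_pp == 5.0  # base unchanged

    def test_empty_overrides_equal_base(self):
        base = mechanism_preset("NZ")
        assert make_variant(base, {}) == base

    def test_non_knob_rejected(self):
        with pytest.raises(ValueError, match="not variant knobs"):
            make_variant(mechanism_preset("NZ"), {"amplification": None})

    def test_more_than_seven_overrides_rejected(self):
        base = mechanism_preset("NZ")
        overrides = {k: getattr(base, k) for k in VARIANT_KNOBS[:8]}
        with pytest.raises(ValueError, match="at most 7"):
            make_variant(base, overrides)

    def test_all_ten_knobs_are_valid_individually(self):
        base = mechanism_preset("MGNZ")
        for k in VARIANT_KNOBS:
            make_variant(base, {k: getattr(base, k)})
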