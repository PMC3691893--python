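"""Atom maps, steady state, truncated propagation and the bounding claims.

The brute-force oracle here re-implements the label chemistry independently
on tuple-of-booleans molecules and enumerates every labeled-molecule
trajectory recursively; the package's level-synchronous propagation must
reproduce it exactly on event-capped systems.
"""

import numpy as np
import pytest

from pabaflux import (FluxConfig, QuantificationError, TracerScheme,
                      cycle_pyruvate, feed_pyruvate, pdh_map,
                      predict_bounds_validity, scramble_oaa, steady_state,
                      substrate_pyruvate, turn_cycle)
from pabaflux.cycling import (AC_1, AC_2, AC_12, N_AC, N_OAA, N_PYR,
                              truncated_acetyl_flux)

from conftest import random_flux_config, random_tracer_scheme


def delta(n, idx=0):
    v = np.zeros(n)
    v[idx] = 1.0
    return v


# ---------------------------------------------------------------------------
# Independent oracle: tuple-based molecules, recursive trajectory enumeration
# ---------------------------------------------------------------------------

def oracle_acetyl_appearance(cfg: FluxConfig, scheme: TracerScheme,
                             max_events: int) -> dict[str, np.ndarray]:
    """Exhaustive enumeration of labeled-molecule trajectories.

    Molecules are tuples of per-carbon label booleans.  Branch
    probabilities follow the flux fractions at each pool; each
    citrate-synthase turn or PEPCK transit consumes one event.
    """
    cyc = cfg.pyruvate_cycling_flux
    ana = cfg.anaplerotic_unlabeled_inflow
    pyr_out = cfg.feed_total + cyc
    p_pdh = cfg.pdh_flux / pyr_out
    p_pc = cyc / pyr_out
    oaa_out = 1.0 + cyc + ana
    p_turn = 1.0 / oaa_out
    p_pepck = cyc / oaa_out

    def acetyl_index(ac):
        return int(ac[0]) + 2 * int(ac[1])

    def scramble_branches(oaa):
        return [(oaa, 0.5), (tuple(reversed(oaa)), 0.5)]

    def visit_pyr(pyr, w, e, acc):
        # PDH: C1 lost, (C2, C3) -> acetyl (C1, C2)
        ac = (pyr[1], pyr[2])
        if any(ac):
            acc[acetyl_index(ac)] += w * p_pdh
            if e < max_events:
                # acetyl -> citrate: new OAA = (F, F, acC2, acC1), scrambled
                for oaa, q in scramble_branches((False, False, ac[1], ac[0])):
                    visit_oaa(oaa, w * p_pdh * q, e + 1, acc)
        # PC: (C1, C2, C3) -> OAA C1..C3, unlabeled CO2 -> C4, scrambled
        oaa0 = (pyr[0], pyr[1], pyr[2], False)
        if any(oaa0):
            for oaa, q in scramble_branches(oaa0):
                visit_oaa(oaa, w * p_pc * q, e, acc)

    def visit_oaa(oaa, w, e, acc):
        if not any(oaa) or e >= max_events:
            return
        # CS turn: old C1, C4 lost; new OAA = (old C3, old C2, F, F), scrambled
        surv = (oaa[2], oaa[1], False, False)
        if any(surv):
            for o2, q in scramble_branches(surv):
                visit_oaa(o2, w * p_turn * q, e + 1, acc)
        # PEPCK: C4 lost
        pyr = (oaa[0], oaa[1], oaa[2])
        if any(pyr):
            visit_pyr(pyr, w * p_pepck, e + 1, acc)

    labeled = {
        "glucose": ((False, False, True),
                    scheme.glucose_labeled_fraction * scheme.tracer_purity),
        "fructose": ((True, True, True),
                     scheme.fructose_labeled_fraction * scheme.tracer_purity),
        "unlabeled": ((False, False, False), 0.0),
    }
    out = {}
    for name, flux in cfg.glycolytic_feed.items():
        acc = np.zeros(4)
        mol, p = labeled[name]
        if flux * p > 0:
            visit_pyr(mol, flux * p, 0, acc)
        acc[0] = 0.0
        out[name] = acc
    return out


# ---------------------------------------------------------------------------
# Atom-map unit behaviour
# ---------------------------------------------------------------------------

class TestAtomMaps:
    def test_pdh_uniform_pyruvate_gives_doubly_labeled_acetyl(self):
        assert pdh_map(delta(N_PYR, 0b111))[AC_12] == 1.0

    def test_pdh_c3_pyruvate_gives_methyl_labeled_acetyl(self):
        assert pdh_map(delta(N_PYR, 0b100))[AC_2] == 1.0

    def test_pdh_c1_label_lost_as_co2(self):
        assert pdh_map(delta(N_PYR, 0b001))[0] == 1.0

    def test_turn_doubly_labeled_acetyl_splits_12_34(self):
        out = turn_cycle(delta(N_AC, AC_12), delta(N_OAA, 0))
        assert out[0b0011] == pytest.approx(0.5)
        assert out[0b1100] == pytest.approx(0.5)

    def test_turn_methyl_label_lands_on_oaa_c2_or_c3(self):
        out = turn_cycle(delta(N_AC, AC_2), delta(N_OAA, 0))
        assert out[0b0010] == pytest.approx(0.5)
        assert out[0b0100] == pytest.approx(0.5)

    def test_turn_unlabeled_stays_unlabeled(self):
        out = turn_cycle(delta(N_AC, 0), delta(N_OAA, 0))
        assert out[0] == pytest.approx(1.0)

    def test_cycled_12_oaa_returns_carboxyl_labeled_acetyl(self):
        assert pdh_map(cycle_pyruvate(delta(N_OAA, 0b0011)))[AC_1] == 1.0

    def test_cycled_34_oaa_returns_methyl_labeled_acetyl(self):
        assert pdh_map(cycle_pyruvate(delta(N_OAA, 0b1100)))[AC_2] == 1.0

    def test_scramble_is_involution_on_symmetric_distributions(self):
        rng = np.random.default_rng(7)
        p = rng.dirichlet(np.ones(N_OAA))
        once = scramble_oaa(p)
        assert np.allclose(scramble_oaa(once), once)

    def test_probability_conserved_by_every_map(self):
        from pabaflux import pc_map
        rng = np.random.default_rng(11)
        p_pyr = rng.dirichlet(np.ones(N_PYR))
        p_ac = rng.dirichlet(np.ones(N_AC))
        p_oaa = rng.dirichlet(np.ones(N_OAA))
        for out in (pdh_map(p_pyr), pc_map(p_pyr), scramble_oaa(p_oaa),
                    cycle_pyruvate(p_oaa), turn_cycle(p_ac, p_oaa)):
            assert out.sum() == pytest.approx(1.0)


class TestFeed:
    def test_pure_uniformly_labeled_fructose(self):
        scheme = TracerScheme(fructose_labeled_fraction=1.0, tracer_purity=1.0)
        d = feed_pyruvate(scheme, {"fructose": 1.0})
        assert d[0b111] == pytest.approx(1.0)

    def test_glucose_at_99_percent_purity(self):
        scheme = TracerScheme(tracer_purity=0.99)
        d = substrate_pyruvate(scheme)["glucose"]
        assert d[0b100] == pytest.approx(0.495)

    def test_unlabeled_feed(self):
        d = feed_pyruvate(TracerScheme(), {"unlabeled": 1.0})
        assert d[0] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Steady state
# ---------------------------------------------------------------------------

class TestSteadyState:
    def test_no_cycling_equals_direct_pdh(self, scheme):
        cfg = FluxConfig(pyruvate_cycling_flux=0.0)
        res = steady_state(cfg, scheme)
        feed = feed_pyruvate(scheme, dict(cfg.glycolytic_feed))
        expected = cfg.pdh_flux * pdh_map(feed)
        e1, _e2, _e12 = res.acetyl_excess_pct
        assert e1 == pytest.approx(0.0, abs=1e-12)
        for s in (AC_1, AC_2, AC_12):
            assert res.state.acetyl[s] == pytest.approx(expected[s], abs=1e-9)

    def test_single_pass_cycled_c3_pyruvate_splits_evenly(self):
        """One PC->fumarate->PEPCK->PDH pass of [3-13C]pyruvate yields equal
        [1-13C] and [2-13C]acetyl (fumarate symmetry)."""
        scheme = TracerScheme(glucose_labeled_fraction=1.0, tracer_purity=1.0)
        cfg = FluxConfig(pdh_flux=0.2, pyruvate_cycling_flux=1.0,
                         anaplerotic_unlabeled_inflow=0.5,
                         glycolytic_feed={"glucose": 1.0})
        flux = truncated_acetyl_flux(cfg, scheme, max_events=1)["glucose"]
        # events=1 admits exactly one PEPCK transit and no post-turn returns
        cycled = flux - truncated_acetyl_flux(cfg, scheme,
                                              max_events=0)["glucose"]
        assert cycled[AC_1] == pytest.approx(cycled[AC_2], rel=1e-12)
        assert cycled[AC_12] == 0.0

    def test_pool_distributions_are_normalized(self, scheme):
        res = steady_state(FluxConfig(), scheme)
        for pool in (res.state.pyruvate, res.state.acetyl,
                     res.state.oxaloacetate):
            assert pool.sum() == pytest.approx(1.0)
            assert np.all(pool >= 0)

    def test_joint_mode_agrees_with_linear_at_low_enrichment(self, scheme):
        cfg = FluxConfig()
        lin = steady_state(cfg, scheme, mode="linear")
        joint = steady_state(cfg, scheme, mode="joint")
        # agreement to first order: discrepancy bounded by (labeled mass)^2
        labeled = 1.0 - lin.state.acetyl[0]
        assert np.allclose(lin.state.acetyl, joint.state.acetyl,
                           atol=max(1e-6, labeled ** 2))

    def test_truncated_propagation_converges_to_steady_state(self, scheme):
        cfg = FluxConfig()
        res = steady_state(cfg, scheme)
        ss = sum(res.acetyl_by_source.values())
        t = sum(truncated_acetyl_flux(cfg, scheme, max_events=60).values())
        assert np.allclose(t, ss, atol=1e-8)


# ---------------------------------------------------------------------------
# Oracle equivalence and bounding claims
# ---------------------------------------------------------------------------

class TestOracleEquivalence:
    @pytest.mark.parametrize("max_events", [0, 1, 2, 3])
    def test_truncated_matches_trajectory_enumeration(self, max_events):
        rng = np.random.default_rng(2024)
        for _ in range(10):
            cfg = random_flux_config(rng)
            scheme = random_tracer_scheme(rng)
            mine = truncated_acetyl_flux(cfg, scheme, max_events=max_events)
            oracle = oracle_acetyl_appearance(cfg, scheme, max_events)
            for name in mine:
                np.testing.assert_allclose(mine[name], oracle[name],
                                           atol=1e-12)


class TestBoundsValidity:
    def test_fructose_estimate_exact_under_default_scenario(self, scheme):
        rep = predict_bounds_validity(FluxConfig(), scheme)
        assert rep.fructose_estimate_pct == pytest.approx(
            rep.fructose_truth_pct, abs=1e-6)
        assert rep.doubly_labeled_from_glucose == 0.0

    def test_no_cycling_bounds_collapse_onto_truth(self, scheme):
        rep = predict_bounds_validity(
            FluxConfig(pyruvate_cycling_flux=0.0), scheme)
        assert rep.glucose_lower_pct == pytest.approx(rep.glucose_upper_pct)
        assert rep.glucose_truth_pct == pytest.approx(rep.glucose_upper_pct,
                                                      abs=1e-9)

    def test_truth_within_bounds_over_random_configurations(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            cfg = random_flux_config(rng)
            scheme = random_tracer_scheme(rng)
            rep = predict_bounds_validity(cfg, scheme)
            assert rep.truth_within_bounds
            assert rep.fructose_estimate_pct == pytest.approx(
                rep.fructose_truth_pct, abs=0.1)

    def test_default_scenario_half_of_c1_label_from_direct_cycling(self,
                                                                   scheme):
        rep = predict_bounds_validity(FluxConfig(), scheme)
        assert 0.35 <= rep.c1_fraction_direct_cycling <= 0.65


class TestValidation:
    def test_infeasible_feed_rejected(self):
        with pytest.raises(QuantificationError, match="mass balance"):
            FluxConfig(pdh_flux=0.5, glycolytic_feed={"glucose": 0.1})

    def test_negative_flux_rejected(self):
        with pytest.raises(QuantificationError):
            FluxConfig(pyruvate_cycling_flux=-1.0)
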