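"""Anagenetic generators, cladogenetic tables, pruning likelihood,
fitting and AICc model selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import islandrad as ir
from islandrad.rangemodel import FAMILIES

from .oracles import oracle_loglik


def _spec(family="BAYAREALIKE", jump=False, maxsize=2):
    return ir.ModelSpec(family, jump=jump, max_range_size=maxsize)


class TestAnageneticGenerator:
    def test_gain_rate_scales_with_occupied_regions(self, three_region_scene):
        geo, _ = three_region_scene
        space = ir.StateSpace(geo, 2)
        d, e = 0.3, 0.2
        Q = ir.anagenetic_generator(space, ir.Params(d, e), frozenset({0, 1, 2}))
        one = space.index_of(frozenset({0}))
        two = space.index_of(frozenset({0, 1}))
        assert Q[one, two] == pytest.approx(d * 1)
        assert Q[one, space.index_of(frozenset({0, 2}))] == pytest.approx(d)

    def test_total_loss_rate_is_e_per_occupied_region(self, three_region_scene):
        geo, _ = three_region_scene
        space = ir.StateSpace(geo, 2)
        Q = ir.anagenetic_generator(space, ir.Params(0.3, 0.2),
                                    frozenset({0, 1, 2}))
        two = space.index_of(frozenset({0, 1}))
        losses = Q[two, space.index_of(frozenset({0}))] + \
            Q[two, space.index_of(frozenset({1}))]
        assert losses == pytest.approx(2 * 0.2)

    def test_gain_into_unemerged_region_blocked(self):
        geo, strata = ir.build_geography(["T", "H"], {"H": 1.1},
                                         root_age=3.0)
        space = ir.StateSpace(geo, 2)
        Q_old = ir.anagenetic_generator(space, ir.Params(0.3, 0.0),
                                        strata.masks[0])
        one = space.index_of(frozenset({0}))
        both = space.index_of(frozenset({0, 1}))
        assert Q_old[one, both] == 0.0
        Q_young = ir.anagenetic_generator(space, ir.Params(0.3, 0.0),
                                          strata.masks[1])
        assert Q_young[one, both] == pytest.approx(0.3)

    @settings(max_examples=25, deadline=None)
    @given(
        d=st.floats(0.0, 2.0), e=st.floats(0.0, 2.0),
        n=st.integers(2, 5), maxsize=st.integers(1, 4),
    )
    def test_rows_sum_to_zero_null_absorbing(self, d, e, n, maxsize):
        maxsize = min(maxsize, n)
        geo, _ = ir.build_geography([f"R{i}" for i in range(n)])
        space = ir.StateSpace(geo, maxsize)
        Q = ir.anagenetic_generator(space, ir.Params(d, e),
                                    frozenset(range(n)))
        assert np.abs(Q.sum(axis=1)).max() < 1e-10
        assert np.all(Q[space.index_of(frozenset())] == 0.0)


class TestCladogeneticTable:
    def test_bayarealike_widespread_parent_only_copies(self):
        tab = ir.cladogenetic_event_table(
            _spec("BAYAREALIKE"), ir.Params(0.1, 0.1),
            frozenset({0, 1}), frozenset({0, 1}),
        )
        assert tab == [(frozenset({0, 1}), frozenset({0, 1}), 1.0)]

    @pytest.mark.parametrize("family", FAMILIES)
    def test_single_region_parent_copies_itself(self, family):
        tab = ir.cladogenetic_event_table(
            _spec(family), ir.Params(0.1, 0.1),
            frozenset({0}), frozenset({0, 1, 2}),
        )
        assert tab == [(frozenset({0}), frozenset({0}), 1.0)]

    def test_founder_probability_follows_weight_rule(self):
        # one occupied region, two available targets, j = 0.05:
        # each founder pair has probability j / ((3-j)/3 + 2j)
        j = 0.05
        tab = ir.cladogenetic_event_table(
            _spec("BAYAREALIKE", jump=True), ir.Params(0.1, 0.1, j),
            frozenset({0}), frozenset({0, 1, 2}),
        )
        expected = j / ((3 - j) / 3 + 2 * j)
        founder_pairs = {}
        for l, r, p in tab:
            if l != r:
                target = l if len(l) == 1 and l != frozenset({0}) else r
                founder_pairs[target] = founder_pairs.get(target, 0.0) + p
        assert founder_pairs == {
            frozenset({1}): pytest.approx(expected),
            frozenset({2}): pytest.approx(expected),
        }

    def test_dec_allows_subset_and_vicariance(self):
        tab = ir.cladogenetic_event_table(
            _spec("DEC"), ir.Params(0.1, 0.1),
            frozenset({0, 1}), frozenset({0, 1}),
        )
        pairs = {(l, r) for l, r, _ in tab}
        # subset sympatry present in both orientations
        assert (frozenset({0, 1}), frozenset({0})) in pairs
        # vicariance present
        assert (frozenset({0}), frozenset({1})) in pairs

    def test_divalike_widespread_parent_only_vicariance(self):
        tab = ir.cladogenetic_event_table(
            _spec("DIVALIKE"), ir.Params(0.1, 0.1),
            frozenset({0, 1, 2}), frozenset({0, 1, 2}),
        )
        for l, r, _ in tab:
            assert len(l) == 1 or len(r) == 1
            assert (l | r) == frozenset({0, 1, 2}) and not (l & r)

    def test_null_parent_rejected(self):
        with pytest.raises(ValueError):
            ir.cladogenetic_event_table(
                _spec("DEC"), ir.Params(0.1, 0.1), frozenset(), frozenset({0})
            )

    @settings(max_examples=60, deadline=None)
    @given(
        family=st.sampled_from(FAMILIES),
        jump=st.booleans(),
        j=st.floats(0.0, 3.0),
        bits=st.integers(1, 14),
        avail_bits=st.integers(0, 15),
    )
    def test_probabilities_normalised(self, family, jump, j, bits, avail_bits):
        A = frozenset(i for i in range(4) if bits >> i & 1)
        avail = frozenset(i for i in range(4) if avail_bits >> i & 1) | A
        tab = ir.cladogenetic_event_table(
            _spec(family, jump=jump, maxsize=4), ir.Params(0.1, 0.1, j),
            A, avail,
        )
        assert sum(p for _, _, p in tab) == pytest.approx(1.0, abs=1e-12)


class TestLogLikelihood:
    def test_identical_single_region_tips_zero_rates_lnl_zero(
        self, two_region_scene
    ):
        geo, strata = two_region_scene
        tree = ir.DatedTree.from_newick("(a:1.0,b:1.0);")
        tips = {"a": frozenset({0}), "b": frozenset({0})}
        for family in FAMILIES:
            lnL = ir.log_likelihood(tree, tips, _spec(family),
                                    ir.Params(0.0, 0.0), geo, strata)
            assert lnL == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("family", FAMILIES)
    @pytest.mark.parametrize("jump", [False, True])
    def test_matches_exact_enumeration_oracle(self, family, jump,
                                              three_tip_tree):
        geo, strata = ir.build_geography(["T", "G", "C"])
        tips = {"a": frozenset({0}), "b": frozenset({0, 1}),
                "c": frozenset({1})}
        d, e, j = 0.3, 0.2, (0.4 if jump else 0.0)
        mine = ir.log_likelihood(three_tip_tree, tips,
                                 _spec(family, jump, maxsize=3),
                                 ir.Params(d, e, j), geo, strata)
        oracle = oracle_loglik(three_tip_tree, tips, family, jump, d, e, j,
                               n_regions=3, max_size=3)
        assert mine == pytest.approx(oracle, rel=1e-6)

    def test_matches_oracle_on_four_tips(self, four_tip_tree):
        geo, strata = ir.build_geography(["T", "G"])
        tips = {"a": frozenset({0}), "b": frozenset({1}),
                "c": frozenset({0, 1}), "d": frozenset({0})}
        mine = ir.log_likelihood(four_tip_tree, tips,
                                 _spec("DEC", jump=True),
                                 ir.Params(0.25, 0.15, 0.3), geo, strata)
        oracle = oracle_loglik(four_tip_tree, tips, "DEC", True,
                               0.25, 0.15, 0.3, n_regions=2, max_size=2)
        assert mine == pytest.approx(oracle, rel=1e-6)

    def test_matches_euler_discretization_oracle(self, three_tip_tree):
        geo, strata = ir.build_geography(["T", "G"])
        tips = {"a": frozenset({0}), "b": frozenset({0}),
                "c": frozenset({1})}
        mine = ir.log_likelihood(three_tip_tree, tips, _spec("DEC"),
                                 ir.Params(0.2, 0.1), geo, strata)
        oracle = oracle_loglik(three_tip_tree, tips, "DEC", False,
                               0.2, 0.1, 0.0, n_regions=2, max_size=2,
                               method="euler", euler_steps=2000)
        assert mine == pytest.approx(oracle, abs=1e-3)

    def test_likelihood_decreases_as_extirpation_grows(self, three_tip_tree):
        # all tips share one region, d = 0: any extirpation can only
        # destroy the data's probability
        geo, strata = ir.build_geography(["T", "G"])
        tips = {t: frozenset({0}) for t in "abc"}
        lls = [
            ir.log_likelihood(three_tip_tree, tips, _spec("BAYAREALIKE"),
                              ir.Params(0.0, e), geo, strata)
            for e in (0.0, 0.1, 0.3, 0.8)
        ]
        assert all(a > b for a, b in zip(lls, lls[1:]))

    def test_invariant_to_child_order(self):
        geo, strata = ir.build_geography(["T", "G", "C"])
        tips = {"a": frozenset({0}), "b": frozenset({1}),
                "c": frozenset({2})}
        t1 = ir.DatedTree.from_newick("((a:0.6,b:0.6):0.9,c:1.5);")
        t2 = ir.DatedTree.from_newick("(c:1.5,(b:0.6,a:0.6):0.9);")
        p = ir.Params(0.3, 0.1, 0.2)
        for fam in FAMILIES:
            s = _spec(fam, jump=True, maxsize=2)
            assert ir.log_likelihood(t1, tips, s, p, geo, strata) == \
                pytest.approx(ir.log_likelihood(t2, tips, s, p, geo, strata),
                              rel=1e-12)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_jump_model_converges_to_base_as_j_vanishes(self, family,
                                                        three_tip_tree):
        geo, strata = ir.build_geography(["T", "G", "C"])
        tips = {"a": frozenset({0}), "b": frozenset({0, 1}),
                "c": frozenset({2})}
        base = ir.log_likelihood(three_tip_tree, tips,
                                 _spec(family, maxsize=2),
                                 ir.Params(0.3, 0.2), geo, strata)
        tiny = ir.log_likelihood(three_tip_tree, tips,
                                 _spec(family, jump=True, maxsize=2),
                                 ir.Params(0.3, 0.2, 1e-8), geo, strata)
        assert abs(base - tiny) < 1e-6

    def test_emergence_zeroes_older_occupancy(self):
        # a region that emerged 1.1 myr ago cannot host a 2 myr old lineage:
        # with zero rates a tip observed there has probability zero
        geo, strata = ir.build_geography(["T", "H"], {"H": 1.1},
                                         root_age=2.0)
        tree = ir.DatedTree.from_newick("(a:2.0,b:2.0);")
        tips = {"a": frozenset({1}), "b": frozenset({1})}
        lnL = ir.log_likelihood(tree, tips, _spec("BAYAREALIKE"),
                                ir.Params(0.0, 0.0), geo, strata)
        assert lnL == -np.inf

    def test_tip_label_mismatch_raises(self, two_region_scene):
        geo, strata = two_region_scene
        tree = ir.DatedTree.from_newick("(a:1.0,b:1.0);")
        with pytest.raises(ValueError, match="range data"):
            ir.log_likelihood(tree, {"a": frozenset({0})}, _spec(),
                              ir.Params(0.1, 0.1), geo, strata)


class TestFitModel:
    def test_jump_fit_never_below_nested_base_fit(self, recovery_scene,
                                                  fifty_tip_radiation):
        geo, strata = recovery_scene
        spec = _spec("BAYAREALIKE", maxsize=3)
        tips, _ = ir.simulate_ranges_on_tree(
            fifty_tip_radiation.tree, _spec("BAYAREALIKE", jump=True, maxsize=3),
            ir.Params(0.021, 0.044, 0.0), geo, strata, seed=9,
        )
        base = ir.fit_model(fifty_tip_radiation.tree, tips, spec, geo,
                            strata, n_starts=2)
        jump = ir.fit_model(fifty_tip_radiation.tree, tips,
                            _spec("BAYAREALIKE", jump=True, maxsize=3),
                            geo, strata, n_starts=2)
        assert jump.lnL >= base.lnL - 1e-6
        assert base.k == 2 and jump.k == 3

    def test_zero_variation_data_drives_rates_to_lower_bound(
        self, two_region_scene
    ):
        geo, strata = two_region_scene
        tree = ir.DatedTree.from_newick(
            "((a:0.5,b:0.5):0.5,(c:0.6,d:0.6):0.4);"
        )
        tips = {t: frozenset({0}) for t in "abcd"}
        fit = ir.fit_model(tree, tips, _spec("BAYAREALIKE"), geo, strata,
                           n_starts=2)
        # effectively zero on the /myr scale; lnL at the optimum is ~0
        assert fit.mle.d < 1e-4 and fit.mle.e < 1e-4
        assert fit.lnL == pytest.approx(0.0, abs=1e-3)

    def test_fit_is_deterministic(self, two_region_scene):
        geo, strata = two_region_scene
        tree = ir.DatedTree.from_newick("((a:0.5,b:0.5):0.5,c:1.0);")
        tips = {"a": frozenset({0}), "b": frozenset({1}),
                "c": frozenset({0})}
        f1 = ir.fit_model(tree, tips, _spec("DEC"), geo, strata, n_starts=2)
        f2 = ir.fit_model(tree, tips, _spec("DEC"), geo, strata, n_starts=2)
        assert (f1.mle, f1.lnL) == (f2.mle, f2.lnL)

    def test_estimator_consistent_when_extirpation_observable(
        self, recovery_scene, fifty_tip_radiation
    ):
        # widespread ranges make losses visible: e-hat leaves the boundary
        geo, strata = recovery_scene
        spec = _spec("BAYAREALIKE", jump=True, maxsize=3)
        truth = ir.Params(0.5, 0.15, 0.05)
        tips, _ = ir.simulate_ranges_on_tree(
            fifty_tip_radiation.tree, spec, truth, geo, strata, seed=601
        )
        fit = ir.fit_model(fifty_tip_radiation.tree, tips, spec, geo,
                           strata, n_starts=2)
        assert truth.e / 3 <= fit.mle.e <= truth.e * 3
        assert truth.d / 3 <= fit.mle.d <= truth.d * 3


class TestModelSelection:
    def test_equal_aicc_gives_equal_weights(self):
        w = ir.akaike_weights([100.0, 100.0])
        assert w == pytest.approx([0.5, 0.5])

    def test_aicc_formula(self):
        # -2 lnL + 2k + 2k(k+1)/(n-k-1)
        assert ir.aicc(-100.0, 2, 50) == pytest.approx(
            200.0 + 4.0 + 12.0 / 47.0
        )
        with pytest.raises(ValueError):
            ir.aicc(-100.0, 3, 4)

    def test_published_model_table_weights_reproduced(self):
        """Recomputing Akaike weights from the six published AICc values
        reproduces the printed weights to two significant figures."""
        table = ir.fixtures.load_model_table()
        w = ir.akaike_weights(table["AICc"].to_numpy())
        by_model = dict(zip(table["model"], w))
        assert by_model["DIVALIKE+J"] == pytest.approx(2.4e-5, rel=0.05)
        assert by_model["DEC"] == pytest.approx(1.2e-10, rel=0.05)
        assert by_model["BAYAREALIKE+J"] == pytest.approx(1.0, abs=0.05)

    def test_selection_table_requires_two_fits(self):
        fit = ir.FitResult(spec=_spec(), mle=ir.Params(0.1, 0.1), lnL=-10.0,
                           k=2)
        with pytest.raises(ValueError):
            ir.model_selection_table([fit], n_for_aicc=50)

    def test_selection_table_weights_sum_to_one(self):
        fits = [
            ir.FitResult(spec=_spec("DEC"), mle=ir.Params(0.1, 0.1),
                         lnL=-50.0, k=2),
            ir.FitResult(spec=_spec("DEC", jump=True),
                         mle=ir.Params(0.1, 0.1, 0.1), lnL=-45.0, k=3),
        ]
        table = ir.model_selection_table(fits, n_for_aicc=50)
        assert table["AICc_wt"].sum() == pytest.approx(1.0)
        assert fits[1].akaike_weight > fits[0].akaike_weight
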