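import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm

from phylopop import dec_dispersal as dec
from phylopop.io_formats import read_newick_dated


AREAS2 = ("X", "Y")
AREAS3 = ("X", "Y", "Z")


class TestEnumerateRanges:
    def test_three_areas_no_null(self):
        sp = dec.enumerate_ranges(AREAS3, include_null=False)
        assert sp.n_states == 7

    def test_six_areas(self):
        sp = dec.enumerate_ranges(tuple("ABCDEF"), include_null=False)
        assert sp.n_states == 63

    def test_max_range_size_binomial_count(self):
        sp = dec.enumerate_ranges(tuple("ABCDEF"), max_range_size=2, include_null=False)
        assert sp.n_states == 6 + 15

    def test_null_included(self):
        sp = dec.enumerate_ranges(AREAS2, include_null=True)
        assert sp.states[0] == ()
        assert sp.n_states == 4

    def test_too_many_areas_refused(self):
        with pytest.raises(ValueError):
            dec.enumerate_ranges(tuple(str(i) for i in range(11)))

    def test_deterministic_ordering(self):
        sp = dec.enumerate_ranges(AREAS3, include_null=False)
        sizes = [len(s) for s in sp.states]
        assert sizes == sorted(sizes)


class TestAnageneticRates:
    def test_zero_rates_zero_matrix(self):
        sp = dec.enumerate_ranges(AREAS2)
        q = dec.anagenetic_rates(sp, dec.DECModel("DEC", d=0.0, e=0.0), np.ones((2, 2)))
        assert np.allclose(q, 0.0)

    def test_gain_rate_formula(self):
        sp = dec.enumerate_ranges(AREAS2)
        m = np.ones((2, 2))
        m[0, 1] = 0.01
        model = dec.DECModel("DEC", d=0.5, e=0.0)
        q = dec.anagenetic_rates(sp, model, m)
        i_x = sp.index(("X",))
        i_xy = sp.index(("X", "Y"))
        assert q[i_x, i_xy] == pytest.approx(0.5 * 0.01)

    def test_rows_sum_to_zero(self):
        sp = dec.enumerate_ranges(AREAS3)
        rng = np.random.default_rng(0)
        m = rng.uniform(0.01, 1.0, size=(3, 3))
        q = dec.anagenetic_rates(sp, dec.DECModel("DEC", d=0.3, e=0.07), m)
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)

    def test_transition_matrices_stochastic(self):
        sp = dec.enumerate_ranges(AREAS3)
        q = dec.anagenetic_rates(sp, dec.DECModel("DEC", d=0.4, e=0.1), np.ones((3, 3)))
        for dt in (0.01, 0.5, 3.0):
            p = expm(q * dt)
            assert np.all(p >= -1e-12)
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)


class TestCladogenesis:
    def test_single_area_copy(self):
        sp = dec.enumerate_ranges(AREAS2)
        table = dec.cladogenesis_table(sp, dec.DECModel("DEC"))
        i_x = sp.index(("X",))
        li, ri, w = table[i_x]
        assert len(w) == 1
        assert li[0] == ri[0] == i_x
        assert w[0] == pytest.approx(1.0)

    def test_dec_two_area_parent_enumeration(self):
        # published DEC outcomes for parent {X,Y}: subset sympatry and narrow
        # vicariance; both collapse to ordered pairs ({X},{X,Y}), ({X,Y},{X}),
        # ({Y},{X,Y}), ({X,Y},{Y}), ({X},{Y}), ({Y},{X})
        sp = dec.enumerate_ranges(AREAS2)
        table = dec.cladogenesis_table(sp, dec.DECModel("DEC"))
        i_xy = sp.index(("X", "Y"))
        li, ri, w = table[i_xy]
        got = {(sp.states[a], sp.states[b]) for a, b in zip(li, ri)}
        x, y, xy = (0,), (1,), (0, 1)
        expected = {(x, xy), (xy, x), (y, xy), (xy, y), (x, y), (y, x)}
        assert got == expected
        assert w.sum() == pytest.approx(1.0)

    def test_bayarealike_copy_only(self):
        sp = dec.enumerate_ranges(AREAS2)
        table = dec.cladogenesis_table(sp, dec.DECModel("BAYAREALIKE"))
        i_xy = sp.index(("X", "Y"))
        li, ri, w = table[i_xy]
        assert len(w) == 1
        assert (li[0], ri[0]) == (i_xy, i_xy)

    def test_divalike_allows_wide_vicariance(self):
        sp = dec.enumerate_ranges(AREAS3)
        table = dec.cladogenesis_table(sp, dec.DECModel("DIVALIKE"))
        i_xyz = sp.index(AREAS3)
        li, ri, _ = table[i_xyz]
        pairs = {(sp.states[a], sp.states[b]) for a, b in zip(li, ri)}
        assert ((0, 1), (2,)) in pairs  # both-daughter split, no sympatry
        assert all(len(a) + len(b) == 3 for a, b in pairs)

    def test_jump_adds_outside_daughters(self):
        sp = dec.enumerate_ranges(AREAS2)
        table = dec.cladogenesis_table(sp, dec.DECModel("DEC", founder_j=True, j=1.0))
        i_x = sp.index(("X",))
        li, ri, w = table[i_x]
        pairs = {(sp.states[a], sp.states[b]) for a, b in zip(li, ri)}
        assert ((0,), (1,)) in pairs and ((1,), (0,)) in pairs
        assert w.sum() == pytest.approx(1.0)


def _two_tip_oracle(model, strat, space, tip_states, ages):
    """Dense, independent likelihood for a two-tip tree ((A:r,B:r):0-ish).

    Composes per-stratum matrix exponentials explicitly and sums over root
    states and cladogenetic events by brute force.
    """
    qs = [dec.anagenetic_rates(space, model, m) for m in strat.matrices]
    root_age = ages

    def branch_matrix(lo, hi):
        p = np.eye(space.n_states)
        t = lo
        while t < hi - 1e-12:
            s = strat.stratum_of(min(t + 1e-12, hi))
            top = min(strat.boundaries[s], hi)
            p = expm(qs[s] * (top - t)) @ p
            t = top
        return p

    pmat = branch_matrix(0.0, root_age)
    clado = dec.cladogenesis_table(space, model)
    nn = space.non_null()
    total = 0.0
    for root in nn:
        li, ri, w = clado[root]
        for a, b, wt in zip(li, ri, w):
            total += (
                wt * pmat[a, tip_states[0]] * pmat[b, tip_states[1]] / len(nn)
            )
    return math.log(total)


class TestStratifiedLoglik:
    def test_one_area_no_rates_loglik_zero(self):
        tree = read_newick_dated("(A:1,B:1);")
        sp = dec.enumerate_ranges(("X",))
        strat = dec.StratifiedDispersal.uniform(1, root_age=2.0)
        model = dec.DECModel("DEC", d=0.0, e=0.0)
        ll = dec.stratified_loglik(tree, {"A": ("X",), "B": ("X",)}, model, strat, sp)
        assert ll == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("model_name", ["DEC", "DIVALIKE", "BAYAREALIKE", "DEC+J"])
    def test_two_tip_matches_dense_oracle(self, model_name):
        tree = read_newick_dated("(A:1.5,B:1.5);")
        sp = dec.enumerate_ranges(AREAS2)
        strat = dec.StratifiedDispersal(
            (3.0, 1.0, 0.0),
            (np.array([[1.0, 0.01], [0.01, 1.0]]), np.ones((2, 2))),
        )
        base, _, j = model_name.partition("+")
        model = dec.DECModel(base, founder_j=(j == "J"), d=0.23, e=0.045, j=0.4 if j else 0.0)
        tips = {"A": ("X",), "B": ("Y",)}
        got = dec.stratified_loglik(tree, tips, model, strat, sp)
        want = _two_tip_oracle(
            model, strat, sp, (sp.index(("X",)), sp.index(("Y",))), 1.5
        )
        assert got == pytest.approx(want, abs=1e-8)

    def test_stratum_split_consistency(self):
        tree = read_newick_dated("((A:1,B:1):1.5,C:2.5);")
        sp = dec.enumerate_ranges(AREAS2)
        model = dec.DECModel("DEC", d=0.15, e=0.02)
        tips = {"A": ("X",), "B": ("Y",), "C": ("X", "Y")}
        one = dec.StratifiedDispersal((4.0, 0.0), (np.ones((2, 2)),))
        two = dec.StratifiedDispersal((4.0, 1.3, 0.0), (np.ones((2, 2)), np.ones((2, 2))))
        a = dec.stratified_loglik(tree, tips, model, one, sp)
        b = dec.stratified_loglik(tree, tips, model, two, sp)
        assert a == pytest.approx(b, abs=1e-8)

    def test_area_relabeling_invariance(self):
        tree = read_newick_dated("((A:1,B:1):1,C:2);")
        model = dec.DECModel("DEC", d=0.2, e=0.05)
        strat = dec.StratifiedDispersal.uniform(2, root_age=3.0)
        sp = dec.enumerate_ranges(AREAS2)
        tips = {"A": ("X",), "B": ("Y",), "C": ("Y",)}
        swapped = {"A": ("Y",), "B": ("X",), "C": ("X",)}
        a = dec.stratified_loglik(tree, tips, model, strat, sp)
        b = dec.stratified_loglik(tree, swapped, model, strat, sp)
        assert a == pytest.approx(b, abs=1e-10)

    def test_root_older_than_strata_error(self):
        tree = read_newick_dated("(A:10,B:10);")
        sp = dec.enumerate_ranges(AREAS2)
        strat = dec.StratifiedDispersal.uniform(2, root_age=6.0)
        with pytest.raises(ValueError, match="strata"):
            dec.stratified_loglik(
                tree, {"A": ("X",), "B": ("Y",)}, dec.DECModel("DEC"), strat, sp
            )

    def test_missing_tip_assignment_error(self):
        tree = read_newick_dated("(A:1,B:1);")
        sp = dec.enumerate_ranges(AREAS2)
        strat = dec.StratifiedDispersal.uniform(2, root_age=2.0)
        with pytest.raises(KeyError):
            dec.stratified_loglik(tree, {"A": ("X",)}, dec.DECModel("DEC"), strat, sp)


class TestHypothesisDispersal:
    REGION = {
        "Insular": "Insular",
        "Western": "Mainland",
        "Central": "Mainland",
        "EasternRanges": "Mainland",
        "EasternCoastal": "Southeastern",
        "Southern": "Southeastern",
    }
    AREAS = tuple(REGION)

    def test_h0_all_ones(self):
        strat = dec.hypothesis_dispersal("H0", self.AREAS, self.REGION)
        assert strat.boundaries == (6.0, 3.0, 0.2, 0.0)
        for m in strat.matrices:
            assert np.allclose(m, 1.0)

    def test_h1_between_region_restriction(self):
        strat = dec.hypothesis_dispersal("H1", self.AREAS, self.REGION)
        assert np.allclose(strat.matrices[0], 1.0)
        m = strat.matrices[1]
        i, w = self.AREAS.index("Insular"), self.AREAS.index("Western")
        c = self.AREAS.index("Central")
        assert m[i, w] == pytest.approx(0.01)
        assert m[w, c] == pytest.approx(1.0)
        assert np.allclose(strat.matrices[2], m)

    def test_h2_recent_breakdown_and_new_barrier(self):
        strat = dec.hypothesis_dispersal("H2", self.AREAS, self.REGION)
        recent = strat.matrices[2]
        w = self.AREAS.index("Western")
        s = self.AREAS.index("Southern")
        ec = self.AREAS.index("EasternCoastal")
        i = self.AREAS.index("Insular")
        assert recent[w, s] == pytest.approx(1.0)  # barrier lifted
        assert recent[s, ec] == pytest.approx(0.01)  # new barrier
        assert recent[i, w] == pytest.approx(0.01)  # insular barrier stays


class TestFitting:
    def _sim(self, seed=0):
        rng = np.random.default_rng(seed)
        tree = dec.random_ultrametric_tree(12, 4.0, rng)
        sp = dec.enumerate_ranges(AREAS3)
        strat = dec.StratifiedDispersal.uniform(3, root_age=6.0)
        truth = dec.DECModel("DEC", d=0.25, e=0.02)
        tips = dec.simulate_history(tree, truth, strat, sp, rng)
        return tree, sp, strat, tips

    def test_plus_j_never_decreases_loglik(self):
        tree, sp, strat, tips = self._sim(1)
        base = dec.fit_model(tree, tips, "DEC", strat, sp, n_starts=2, rng_seed=0)
        plus = dec.fit_model(tree, tips, "DEC+J", strat, sp, n_starts=2, rng_seed=0)
        assert plus.loglik >= base.loglik - 1e-6
        assert plus.n_params == 3
        assert plus.aicc >= plus.aic

    def test_compare_weights_sum_to_one(self):
        tree, sp, strat, tips = self._sim(2)
        hyps = {"same1": strat, "same2": strat}
        table, weights = dec.compare_dispersal_hypotheses(
            tree, tips, hyps, base_models=("DEC", "BAYAREALIKE"), space=sp,
            n_starts=1, rng_seed=0, maxiter=60,
        )
        assert table["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert sum(weights.values()) == pytest.approx(1.0, abs=1e-12)
        # identical multiplier matrices -> identical lnL per base model
        for model_name in ("DEC", "BAYAREALIKE"):
            sub = table[table.model == model_name]
            assert sub.lnL.max() - sub.lnL.min() < 0.2  # same optimum +- NM noise
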