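import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from saforge.chain import (
    ChainSystem,
    RadioactiveSource,
    branch_partial_activity,
    chain_product_atoms,
    intermediate_yield,
    mixture_sa,
    sa_with_ingrowth,
    stable_ingrowth,
)
from saforge.nuclear_data import DecayBranch, Isotope, NeutronField
from saforge.oracle import LinearNetwork, integrate

_FIELD = NeutronField(5e13, R_epi=0.02)


def _make_system(omega_b=3.16, delta_parent=None, t_half_x=1.911 * 3600,
                 t_half_i=6.71 * 86400, stable_product=False,
                 delta_intermediate=0.0):
    parent = Isotope("S-1", 176.0, None, weight_percent=100.0)
    inter = Isotope("X-1", 177.0, t_half_x, branches=(DecayBranch("beta", 1.0),))
    product = Isotope(
        "R-1", 177.0, None if stable_product else t_half_i,
        branches=(DecayBranch("beta", 1.0),),
    )
    if delta_parent is None:
        delta_parent = _FIELD.phi_th * omega_b * 1e-24
    return ChainSystem(
        parent=parent, intermediate=inter, product=product, field=_FIELD,
        omega_production=omega_b, delta_parent=delta_parent,
        delta_intermediate=delta_intermediate,
    )


def _chain_oracle(system, N0, t_irr, t_c=0.0):
    """Matrix-exponential reference for the full 3-state chain."""
    net = LinearNetwork.from_edges(
        ["S", "X", "R"],
        [
            ("S", "X", system.production_rate),
            ("S", None, max(system.delta_parent - system.production_rate, 0.0)),
            ("X", "R", system.lambda_x_branch),
            ("X", None, system.Lambda_x - system.lambda_x_branch),
            ("R", None, system.Lambda_i),
        ],
        [N0, 0.0, 0.0],
    )
    eob = integrate(net, [t_irr])[0]
    if t_c == 0.0:
        return eob
    cool = LinearNetwork.from_edges(
        ["S", "X", "R"],
        [
            ("X", "R", system.lambda_x_branch),
            ("X", None, system.intermediate.lambda_total - system.lambda_x_branch),
            ("R", None, system.product.lambda_total),
        ],
        eob,
    )
    return integrate(cool, [t_c])[0]


class TestChainProductAtoms:
    def test_zero_at_start(self):
        assert chain_product_atoms(_make_system(), 1e18, 0.0) == 0.0

    def test_matches_ode_oracle_randomized(self, rng):
        for _ in range(100):
            omega_b = 10 ** rng.uniform(-1, 3)
            t_half_x = 10 ** rng.uniform(3, 6)
            t_half_i = 10 ** rng.uniform(4, 7)
            t = 10 ** rng.uniform(4, 7)
            system = _make_system(omega_b=omega_b, t_half_x=t_half_x, t_half_i=t_half_i)
            expected = _chain_oracle(system, 1e18, t)[2]
            got = chain_product_atoms(system, 1e18, t)
            if expected > 1e-250:
                assert got == pytest.approx(expected, rel=1e-8)

    def test_cooling_applies_decay_factor_to_eob_value(self):
        # convention: cooling decays the EOB inventory; continued feed from
        # the remaining intermediate is excluded (hence the recommended
        # cooling of many intermediate half-lives before reporting)
        system = _make_system()
        t_irr, t_c = 8.64e5, 2.0e5
        eob = chain_product_atoms(system, 1e18, t_irr)
        got = chain_product_atoms(system, 1e18, t_irr, t_c)
        assert got == pytest.approx(
            eob * math.exp(-system.product.lambda_total * t_c), rel=1e-12
        )

    def test_cooling_simplification_error_is_small_after_intermediate_dies(self):
        # the oracle keeps feeding R from X during cooling; after ~12
        # intermediate half-lives the relative difference is tiny
        system = _make_system()
        t_irr = 8.64e5
        t_c = 12 * system.intermediate.half_life_s
        full = _chain_oracle(system, 1e18, t_irr, t_c)[2]
        simplified = chain_product_atoms(system, 1e18, t_irr, t_c)
        assert simplified <= full
        # the deficit is bounded by the intermediate's EOB inventory share
        n_x_eob, _ = intermediate_yield(system, 1e18, t_irr)
        n_r_eob = chain_product_atoms(system, 1e18, t_irr)
        assert (full - simplified) / full <= n_x_eob / n_r_eob + 1e-9

    def test_fast_intermediate_reduces_to_direct_formula(self):
        # lambda_x -> infinity: chain behaves like direct production with
        # the parent's capture cross-section
        from saforge.activation import DepletionConstants, product_atoms

        system = _make_system(t_half_x=1e-3)
        t = 1e6
        consts = DepletionConstants(system.delta_parent, system.product.lambda_total)
        direct = product_atoms(1e18, system.omega_production, _FIELD, consts, t)
        assert chain_product_atoms(system, 1e18, t) == pytest.approx(direct, rel=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            chain_product_atoms(_make_system(), 1e18, -1.0)


class TestIntermediateYield:
    def test_zero_at_start(self):
        atoms, act = intermediate_yield(_make_system(), 1e18, 0.0)
        assert atoms == 0.0 and act == 0.0

    def test_oracle_agreement(self):
        system = _make_system()
        t = 5e5
        expected = _chain_oracle(system, 1e18, t)[1]
        atoms, act = intermediate_yield(system, 1e18, t)
        assert atoms == pytest.approx(expected, rel=1e-8)

    def test_activity_ratio_definitional(self):
        system = _make_system()
        atoms, act = intermediate_yield(system, 1e18, 3e5)
        assert act == pytest.approx(system.intermediate.lambda_total * atoms, rel=1e-14)


class TestBranchPartialActivity:
    def test_identity(self):
        assert branch_partial_activity(123.0, 1.0) == 123.0

    def test_zero(self):
        assert branch_partial_activity(123.0, 0.0) == 0.0

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            branch_partial_activity(1.0, 1.5)


class TestStableIngrowth:
    def test_zero_at_start(self):
        system = _make_system(stable_product=True, t_half_x=4.2 * 86400)
        assert stable_ingrowth(system, 1e18, 0.0) == 0.0

    def test_oracle_agreement_randomized(self, rng):
        for _ in range(100):
            omega_b = 10 ** rng.uniform(0, 2)
            t_half_x = 10 ** rng.uniform(4, 6)
            t_irr = 10 ** rng.uniform(4, 6.5)
            t_c = 10 ** rng.uniform(3, 6)
            system = _make_system(
                omega_b=omega_b, t_half_x=t_half_x, stable_product=True
            )
            expected = _chain_oracle(system, 1e18, t_irr, t_c)[2]
            got = stable_ingrowth(system, 1e18, t_irr, t_c)
            assert got == pytest.approx(expected, rel=1e-8)

    def test_monotone_in_both_times(self):
        system = _make_system(stable_product=True, t_half_x=4.2 * 86400)
        t_irr = np.linspace(0, 2e6, 50)
        vals = stable_ingrowth(system, 1e18, t_irr, 0.0)
        assert np.all(np.diff(vals) >= 0)
        t_c = np.linspace(0, 2e6, 50)
        vals_c = stable_ingrowth(system, 1e18, 8.64e5, t_c)
        assert np.all(np.diff(vals_c) >= 0)

    def test_infinite_cooling_asymptote(self):
        # all intermediate atoms at EOB eventually land in the stable pool
        system = _make_system(stable_product=True, t_half_x=4.2 * 86400)
        t_irr = 8.64e5
        eob_during = stable_ingrowth(system, 1e18, t_irr, 0.0)
        n_x_eob, _ = intermediate_yield(system, 1e18, t_irr)
        asymptote = stable_ingrowth(system, 1e18, t_irr, 1e12)
        assert asymptote == pytest.approx(eob_during + n_x_eob, rel=1e-10)


class TestSAWithIngrowth:
    def _systems(self):
        main = _make_system()
        imp = _make_system(omega_b=64.2, t_half_x=4.2 * 86400, stable_product=True)
        return main, imp

    def test_carrier_free_without_impurity(self):
        main, imp = self._systems()
        assert sa_with_ingrowth(main, imp, 1e18, 0.0, 8.64e5, 0.0) == 100.0

    def test_monotone_decrease_with_cooling(self):
        main, imp = self._systems()
        t_c = np.linspace(0.0, 8.64e5, 60)
        vals = sa_with_ingrowth(main, imp, 1e20, 1e18, 8.64e5, t_c)
        assert np.all(np.diff(vals) < 0)

    def test_t_c_zero_dominates(self):
        main, imp = self._systems()
        base = sa_with_ingrowth(main, imp, 1e20, 1e18, 8.64e5, 0.0)
        for tc in (1e4, 1e5, 1e6):
            assert base >= sa_with_ingrowth(main, imp, 1e20, 1e18, 8.64e5, tc)

    def test_pooled_oracle_agreement(self):
        main, imp = self._systems()
        t_irr, t_c = 8.64e5, 4.32e4
        n_ri = _chain_oracle(main, 1e20, t_irr)[2] * math.exp(
            -main.product.lambda_total * t_c
        )
        n_sg = _chain_oracle(imp, 1e18, t_irr, t_c)[2]
        expected = 100.0 * n_ri / (n_ri + n_sg)
        got = sa_with_ingrowth(main, imp, 1e20, 1e18, t_irr, t_c)
        assert got == pytest.approx(expected, rel=1e-8)

    def test_different_elements_rejected(self):
        main = _make_system()
        imp = _make_system(stable_product=True)
        object.__setattr__(imp, "product", Isotope("Q-1", 100.0, None))
        with pytest.raises(ValueError):
            sa_with_ingrowth(main, imp, 1e18, 1e18, 1e5, 0.0)


class TestMixtureSA:
    def test_single_source(self):
        assert mixture_sa([RadioactiveSource("a", 5.0, 42.0)]) == 42.0

    def test_equal_sa_sources(self):
        sources = [RadioactiveSource(str(i), q, 37.0) for i, q in enumerate((1, 5, 9))]
        assert mixture_sa(sources) == pytest.approx(37.0, rel=1e-12)

    def test_pooled_atom_brute_force(self):
        # hot 9 at SA 100% + hot 1 at SA 10%: elements = 9 + 10 -> 52.63%
        got = mixture_sa(
            [RadioactiveSource("a", 9.0, 100.0), RadioactiveSource("b", 1.0, 10.0)]
        )
        assert got == pytest.approx(100 * 10 / 19, rel=1e-12)

    def test_result_within_source_bounds(self, rng):
        for _ in range(50):
            sources = [
                RadioactiveSource(str(i), rng.uniform(0.1, 10), rng.uniform(1, 100))
                for i in range(4)
            ]
            mix = mixture_sa(sources)
            assert min(s.sa for s in sources) <= mix <= max(s.sa for s in sources)

    def test_permutation_invariance_and_pairwise_pooling(self):
        a = RadioactiveSource("a", 3.0, 80.0)
        b = RadioactiveSource("b", 5.0, 20.0)
        c = RadioactiveSource("c", 2.0, 50.0)
        direct = mixture_sa([a, b, c])
        assert direct == pytest.approx(mixture_sa([c, a, b]), rel=1e-14)
        ab = RadioactiveSource("ab", a.quantity + b.quantity, mixture_sa([a, b]))
        assert mixture_sa([ab, c]) == pytest.approx(direct, rel=1e-12)

    def test_zero_sa_rejected_with_guidance(self):
        with pytest.raises(ValueError, match="combine its stable atoms"):
            mixture_sa(
                [RadioactiveSource("a", 1.0, 50.0), RadioactiveSource("b", 1.0, 0.0)]
            )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mixture_sa([])

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=1e-6, max_value=1e6),
                st.floats(min_value=1e-3, max_value=100.0),
            ),
            min_size=1,
            max_size=6,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_hot_atom_pooling(self, pairs):
        sources = [RadioactiveSource(str(i), q, sa) for i, (q, sa) in enumerate(pairs)]
        hot = sum(q for q, _ in pairs)
        element = sum(100.0 * q / sa for q, sa in pairs)
        assert mixture_sa(sources) == pytest.approx(100.0 * hot / element, rel=1e-10)


class TestChainSystemValidation:
    def test_stable_intermediate_rejected(self):
        parent = Isotope("S-1", 176.0, None)
        inter = Isotope("X-1", 177.0, None)
        product = Isotope("R-1", 177.0, 1e5)
        with pytest.raises(ValueError):
            ChainSystem(parent, inter, product, _FIELD, 1.0, 1e-9)

    def test_conservation_with_sink(self):
        system = _make_system()
        net = LinearNetwork.from_edges(
            ["S", "X", "R"],
            [
                ("S", "X", system.production_rate),
                ("S", None, system.delta_parent - system.production_rate),
                ("X", "R", system.lambda_x_branch),
                ("R", None, system.Lambda_i),
            ],
            [1e18, 0.0, 0.0],
        ).with_sink()
        traj = integrate(net, np.linspace(0, 5e6, 20))
        totals = traj.sum(axis=1)
        assert np.allclose(totals, 1e18, rtol=1e-10)
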