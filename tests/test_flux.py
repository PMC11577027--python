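import math

import numpy as np
import pytest

from soilwebflux.community import Community, Population
from soilwebflux.diet import PreferenceMatrix
from soilwebflux.flux import (
    EfficiencyTable,
    InfeasibleWebError,
    aggregate_fluxes,
    compute_community_fluxes,
    individual_metabolic_rate,
    iterate_fluxes,
    population_metabolic_loss,
    sensitivity_perturb,
    solve_fluxes,
)
from soilwebflux.traits import TaxonTraits, TraitTable, default_resource_nodes

EFF = EfficiencyTable()


def _web(node_ids, node_types, cols):
    n = len(node_ids)
    W = np.zeros((n, n))
    for j, col in cols.items():
        for i, w in col.items():
            W[node_ids.index(i), node_ids.index(j)] = w
    return PreferenceMatrix(node_ids, node_types, W)


class TestMetabolicRate:
    def test_constant_model(self):
        for mass in (0.001, 1.0, 50.0):
            assert individual_metabolic_rate(mass, (0.0, 0.0, 0.0)) == pytest.approx(1.0)

    def test_allometric_closed_form(self):
        assert individual_metabolic_rate(math.e, (0.0, 1.0, 0.0)) == pytest.approx(math.e)

    def test_monotone_in_mass(self):
        masses = np.logspace(-3, 2, 20)
        rates = individual_metabolic_rate(masses, (2.0, 0.7, 0.69))
        assert np.all(np.diff(rates) > 0)

    def test_nonpositive_mass_errors(self):
        with pytest.raises(ValueError):
            individual_metabolic_rate(0.0, (0.0, 0.0, 0.0))

    def test_population_loss(self):
        assert population_metabolic_loss(0.0, 1.0, (0.0, 0.0, 0.0)) == 0.0
        # density 10 x individual rate 0.5
        coeffs = (math.log(0.5), 0.0, 0.0)
        assert population_metabolic_loss(10, 2.0, coeffs) == pytest.approx(5.0)
        # with a = 0 the loss is independent of body mass
        assert population_metabolic_loss(10, 1.0, coeffs) == pytest.approx(
            population_metabolic_loss(10, 2.0, coeffs)
        )


class TestSolveClosedForms:
    def test_single_detritivore(self):
        pref = _web(
            ["worm", "detritus"], ["animal", "detritus"], {"worm": {"detritus": 1.0}}
        )
        res = solve_fluxes(pref, np.array([1.0]), EFF)
        expected = 1.0 / 0.158
        assert res.consumption[0] == pytest.approx(expected, rel=1e-12)
        assert res.total == pytest.approx(expected, rel=1e-12)
        assert res.by_function["detritivory"] == pytest.approx(expected, rel=1e-12)
        assert res.by_function["predation"] == 0.0

    def test_detritivore_predator_chain(self):
        pref = _web(
            ["worm", "pred", "detritus"],
            ["animal", "animal", "detritus"],
            {"worm": {"detritus": 1.0}, "pred": {"worm": 1.0}},
        )
        res = solve_fluxes(pref, np.array([1.0, 1.0]), EFF)
        g_p = 1.0 / 0.906
        g_d = (1.0 + g_p) / 0.158
        got = dict(zip(["worm", "pred"], res.consumption))
        assert got["pred"] == pytest.approx(g_p, rel=1e-12)
        assert got["worm"] == pytest.approx(g_d, rel=1e-12)
        assert res.by_function["predation"] == pytest.approx(g_p, rel=1e-12)
        assert res.by_function["detritivory"] == pytest.approx(g_d, rel=1e-12)
        assert res.total == pytest.approx(g_p + g_d, rel=1e-12)

    def test_zero_losses_zero_fluxes(self):
        pref = _web(
            ["worm", "pred", "detritus"],
            ["animal", "animal", "detritus"],
            {"worm": {"detritus": 1.0}, "pred": {"worm": 1.0}},
        )
        res = solve_fluxes(pref, np.zeros(2), EFF)
        assert np.all(res.fluxes == 0) and res.total == 0


class TestSolveProperties:
    def test_scale_equivariance(self, random_web_suite):
        pref, X = random_web_suite[0]
        r1 = solve_fluxes(pref, X, EFF)
        r2 = solve_fluxes(pref, 3.5 * X, EFF)
        np.testing.assert_allclose(r2.fluxes, 3.5 * r1.fluxes, rtol=1e-10)

    def test_monotone_in_losses(self, random_web_suite):
        for pref, X in random_web_suite[:25]:
            base = solve_fluxes(pref, X, EFF).total
            X2 = X.copy()
            X2[0] *= 1.5
            assert solve_fluxes(pref, X2, EFF).total >= base - 1e-12 * base

    def test_aggregate_permutation_invariance(self, random_web_suite):
        rng = np.random.default_rng(5)
        pref, X = random_web_suite[1]
        res = solve_fluxes(pref, X, EFF)
        perm = rng.permutation(len(pref.node_ids))
        shuffled = aggregate_fluxes(
            res.fluxes[np.ix_(perm, perm)], [pref.node_types[i] for i in perm]
        )
        for fn, v in res.by_function.items():
            assert shuffled[fn] == pytest.approx(v, rel=1e-12)

    def test_infeasible_mutual_predators(self):
        pref = _web(
            ["a", "b", "detritus"],
            ["animal", "animal", "detritus"],
            {"a": {"b": 1.0}, "b": {"a": 1.0}},
        )
        with pytest.raises(InfeasibleWebError, match="infeasible"):
            solve_fluxes(pref, np.array([1.0, 1.0]), EFF)

    def test_singular_system(self):
        pref = _web(
            ["a", "b", "detritus"],
            ["animal", "animal", "detritus"],
            {"a": {"b": 1.0}, "b": {"a": 1.0}},
        )
        perfect = EfficiencyTable(animal=1.0, plant=1.0, microbe=1.0, detritus=1.0)
        with pytest.raises(InfeasibleWebError, match="degenerate"):
            solve_fluxes(pref, np.array([1.0, 1.0]), perfect)

    def test_iteration_agrees_with_direct(self, random_web_suite):
        for pref, X in random_web_suite[:20]:
            direct = solve_fluxes(pref, X, EFF).consumption
            iterated = iterate_fluxes(pref, X, EFF)
            np.testing.assert_allclose(iterated, direct, rtol=1e-9)


def _two_taxon_setup(mass_small):
    """A detritivore community where body mass varies at fixed biomass."""
    taxa = {
        "worm": TaxonTraits(
            taxon_id="worm",
            fauna_class="macrofauna",
            basal_fractions={"animal": 0, "plant": 0, "microbe": 0, "detritus": 1.0},
            agility=0.1,
            defended=False,
            stratum="euedaphic",
            metab_coeffs=(5.0, 0.7, 0.0),
            fixed_body_mass=1.0,
        )
    }
    table = TraitTable(taxa=taxa, resources=default_resource_nodes())
    biomass = 100.0
    comm = Community(
        "M1", [Population("worm", biomass / mass_small, mass_small)]
    )
    return comm, table


def test_smaller_bodies_yield_higher_flux():
    # sublinear metabolic scaling: same biomass in smaller bodies burns more
    comm_small, table = _two_taxon_setup(0.5)
    comm_large, _ = _two_taxon_setup(2.0)
    f_small = compute_community_fluxes(comm_small, table).total
    f_large = compute_community_fluxes(comm_large, table).total
    assert f_small > f_large


class TestSensitivityPerturb:
    def _community(self, pool):
        from soilwebflux.synth import generate_experiment, EffectConfig
        from soilwebflux.community import build_communities

        exp = generate_experiment(seed=3, effects=EffectConfig(n_taxa=15))
        comms = build_communities(
            exp.samples, exp.traits, exp.cores,
            mesocosm_ids=list(exp.design["mesocosm_id"]),
        )
        return next(iter(comms.values())), exp.traits

    def test_zero_cv_reproduces_baseline(self, pool):
        comm, traits = self._community(pool)
        base = compute_community_fluxes(comm, traits).total
        draws = sensitivity_perturb(comm, traits, 0.0, 0.0, n_draws=5, seed=1)
        assert np.allclose(draws["total"], base)

    def test_seed_determinism(self, pool):
        comm, traits = self._community(pool)
        d1 = sensitivity_perturb(comm, traits, 0.2, 0.2, n_draws=50, seed=42)
        d2 = sensitivity_perturb(comm, traits, 0.2, 0.2, n_draws=50, seed=42)
        assert d1.equals(d2)

    def test_mean_total_converges_to_baseline(self, pool):
        # metabolism noise only: fluxes stay linear in the perturbation,
        # so the mean-one noise leaves the expected total unchanged
        comm, traits = self._community(pool)
        base = compute_community_fluxes(comm, traits).total
        draws = sensitivity_perturb(
            comm, traits, biomass_cv=0.0, metabolism_cv=0.1, n_draws=10_000, seed=11
        )
        mc_sem = draws["total"].std() / math.sqrt(len(draws))
        assert abs(draws["total"].mean() - base) < 4 * mc_sem
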