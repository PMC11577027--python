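import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from soilwebflux.community import Community, Population
from soilwebflux.diet import (
    DietConfig,
    LinkModelCoeffs,
    build_preference_matrix,
    link_probability,
    refine_animal_diet,
)
from soilwebflux.traits import (
    LengthMassModel,
    TaxonTraits,
    TraitTable,
    default_resource_nodes,
)


def _taxon(tid, fracs, mass=None, agility=0.0, defended=False, stratum="hemiedaphic"):
    return TaxonTraits(
        taxon_id=tid,
        fauna_class="mesofauna",
        basal_fractions=dict(zip(("animal", "plant", "microbe", "detritus"), fracs)),
        agility=agility,
        defended=defended,
        stratum=stratum,
        metab_coeffs=(0.0, 0.0, 0.0),
        fixed_body_mass=mass or 1.0,
    )


def _setup(taxa, pops):
    table = TraitTable(
        taxa={t.taxon_id: t for t in taxa}, resources=default_resource_nodes()
    )
    community = Community("M1", [Population(*p) for p in pops])
    return community, table


class TestLinkProbability:
    def test_logistic_at_zero(self):
        c = LinkModelCoeffs(0.0, 0.0, -1.0)
        assert link_probability(1.0, 1.0, c) == pytest.approx(0.5)

    @pytest.mark.parametrize("ratio", [2.0, 10.0, 123.0])
    def test_pure_quadratic_symmetric(self, ratio):
        c = LinkModelCoeffs(0.0, 0.0, -1.0)
        assert link_probability(ratio, 1.0, c) == pytest.approx(
            link_probability(1.0, ratio, c)
        )

    def test_linear_term(self):
        c = LinkModelCoeffs(0.0, 1.0, 0.0)
        assert link_probability(10.0, 1.0, c) == pytest.approx(1 / (1 + math.exp(-1)))

    def test_nonpositive_mass_errors(self):
        with pytest.raises(ValueError):
            link_probability(0.0, 1.0)

    def test_unimodality_invariant(self):
        with pytest.raises(ValueError):
            LinkModelCoeffs(0.0, 0.0, 0.5)


class TestRefineAnimalDiet:
    def _pair(self, **prey2_over):
        consumer = _taxon("pred", (1, 0, 0, 0), mass=10.0)
        p1 = dict(tid="p1", fracs=(0, 0, 0, 1), mass=1.0)
        p2 = {**p1, "tid": "p2", **prey2_over}
        prey1 = _taxon(p1["tid"], p1["fracs"], p1["mass"],
                       agility=p1.get("agility", 0.0), defended=p1.get("defended", False),
                       stratum=p1.get("stratum", "hemiedaphic"))
        prey2 = _taxon(p2["tid"], p2["fracs"], p2["mass"],
                       agility=p2.get("agility", 0.0), defended=p2.get("defended", False),
                       stratum=p2.get("stratum", "hemiedaphic"))
        return consumer, prey1, prey2

    def test_linear_in_biomass(self):
        consumer, prey1, prey2 = self._pair()
        w = refine_animal_diet(
            consumer, 10.0,
            [(prey1, Population("p1", 2.0, 1.0)), (prey2, Population("p2", 1.0, 1.0))],
        )
        assert w["p1"] == pytest.approx(2 * w["p2"])

    def test_disjoint_stratum_zeroes_link(self):
        consumer, prey1, prey2 = self._pair(stratum="euedaphic")
        c = TaxonTraits(**{**consumer.__dict__, "stratum": "epigeic"})
        w = refine_animal_diet(
            c, 10.0,
            [(prey1, Population("p1", 1.0, 1.0)), (prey2, Population("p2", 1.0, 1.0))],
        )
        assert w["p2"] == 0.0 and w["p1"] > 0.0

    def test_defense_modifier(self):
        consumer, prey1, prey2 = self._pair(defended=True)
        w = refine_animal_diet(
            consumer, 10.0,
            [(prey1, Population("p1", 1.0, 1.0)), (prey2, Population("p2", 1.0, 1.0))],
            config=DietConfig(defense_factor=0.5),
        )
        assert w["p2"] == pytest.approx(0.5 * w["p1"])


class TestPreferenceMatrix:
    def test_pure_detritivore_column(self):
        comm, table = _setup(
            [_taxon("worm", (0, 0, 0, 1))], [("worm", 10.0, 1.0, 10.0)]
        )
        pref = build_preference_matrix(comm, table)
        col = pref.matrix[:, 0]
        assert col[pref.node_ids.index("detritus")] == pytest.approx(1.0)
        assert col.sum() == pytest.approx(1.0)

    def test_omnivore_split(self):
        taxa = [
            _taxon("omni", (0.5, 0, 0, 0.5), mass=10.0),
            _taxon("a", (0, 0, 0, 1), mass=1.0),
            _taxon("b", (0, 0, 0, 1), mass=1.0),
        ]
        comm, table = _setup(
            taxa, [("omni", 1, 10.0, 10.0), ("a", 1, 1.0, 1.0), ("b", 1, 1.0, 1.0)]
        )
        pref = build_preference_matrix(comm, table)
        j = pref.node_ids.index("omni")
        col = pref.matrix[:, j]
        assert col[pref.node_ids.index("a")] == pytest.approx(0.25)
        assert col[pref.node_ids.index("b")] == pytest.approx(0.25)
        assert col[pref.node_ids.index("detritus")] == pytest.approx(0.5)

    def test_absent_component_renormalized(self):
        # animal fraction 0.4 but no prey in the mesocosm
        comm, table = _setup(
            [_taxon("omni", (0.4, 0, 0, 0.6), mass=10.0)], [("omni", 1, 10.0, 10.0)]
        )
        pref = build_preference_matrix(comm, table)
        col = pref.matrix[:, 0]
        assert col.sum() == pytest.approx(1.0)
        assert col[pref.node_ids.index("detritus")] == pytest.approx(1.0)

    def test_impossible_consumer_errors(self):
        comm, table = _setup(
            [_taxon("pred", (1, 0, 0, 0), mass=10.0)], [("pred", 1, 10.0, 10.0)]
        )
        with pytest.raises(ValueError, match="pred"):
            build_preference_matrix(comm, table)

    def test_identical_prey_uniform_diet(self):
        taxa = [_taxon("pred", (1, 0, 0, 0), mass=50.0)] + [
            _taxon(f"p{i}", (0, 0, 0, 1), mass=1.0) for i in range(4)
        ]
        pops = [("pred", 1, 50.0, 50.0)] + [(f"p{i}", 3, 1.0, 3.0) for i in range(4)]
        comm, table = _setup(taxa, pops)
        pref = build_preference_matrix(comm, table)
        j = pref.node_ids.index("pred")
        prey_w = [pref.matrix[pref.node_ids.index(f"p{i}"), j] for i in range(4)]
        assert prey_w == pytest.approx([0.25] * 4)

    def _random_setup(self, seed, n_taxa):
        rng = np.random.default_rng(seed)
        taxa, pops = [], []
        strata = ("epigeic", "hemiedaphic", "euedaphic")
        for i in range(n_taxa):
            fr = rng.dirichlet(np.ones(4)) * rng.uniform(0.5, 1.0)
            # keep one guaranteed basal component so columns never vanish
            fr[3] = max(fr[3], 0.05)
            if fr.sum() > 1.0:
                fr = fr / fr.sum()
            mass = 10 ** rng.uniform(-4, 2)
            taxa.append(
                _taxon(
                    f"t{i}", fr, mass=mass,
                    agility=rng.uniform(), defended=bool(rng.integers(2)),
                    stratum=strata[rng.integers(3)],
                )
            )
            pops.append((f"t{i}", 10 ** rng.uniform(0, 4), mass))
        comm, table = _setup(taxa, [(t, n, m, n * m) for t, n, m in pops])
        return comm, table

    @given(seed=st.integers(0, 10_000), n_taxa=st.integers(2, 12))
    @settings(max_examples=40, deadline=None)
    def test_columns_stochastic_no_self_loops(self, seed, n_taxa):
        comm, table = self._random_setup(seed, n_taxa)
        pref = build_preference_matrix(comm, table)
        n_a = pref.n_animals
        np.testing.assert_allclose(pref.matrix[:, :n_a].sum(axis=0), 1.0, atol=1e-12)
        assert np.all(pref.matrix >= 0)
        assert np.all(np.diag(pref.matrix) == 0)
        # basal nodes consume nothing
        assert np.all(pref.matrix[:, n_a:] == 0)

    def test_biomass_scale_invariance(self):
        comm, table = self._random_setup(7, 8)
        pref = build_preference_matrix(comm, table)
        scaled = Community(
            comm.mesocosm_id,
            [
                Population(p.taxon_id, p.density * 13.7, p.mean_body_mass)
                for p in comm.populations
            ],
            comm.basal_nodes,
        )
        pref2 = build_preference_matrix(scaled, table)
        np.testing.assert_allclose(pref.matrix, pref2.matrix, atol=1e-12)

    def test_zero_weight_prey_removal_invariance(self):
        # a defended, zero-defense-factor prey contributes nothing
        taxa = [
            _taxon("pred", (0.6, 0, 0, 0.4), mass=10.0),
            _taxon("ghost", (0, 0, 0, 1), mass=1.0, defended=True),
            _taxon("prey", (0, 0, 0, 1), mass=1.0),
        ]
        cfg = DietConfig(defense_factor=0.0)
        comm, table = _setup(
            taxa,
            [("pred", 1, 10.0, 10.0), ("ghost", 5, 1.0, 5.0), ("prey", 5, 1.0, 5.0)],
        )
        pref = build_preference_matrix(comm, table, config=cfg)
        comm2, table2 = _setup(
            [taxa[0], taxa[2]], [("pred", 1, 10.0, 10.0), ("prey", 5, 1.0, 5.0)]
        )
        pref2 = build_preference_matrix(comm2, table2, config=cfg)
        for rid in ("prey", "detritus"):
            i1 = pref.node_ids.index(rid)
            i2 = pref2.node_ids.index(rid)
            j1 = pref.node_ids.index("pred")
            j2 = pref2.node_ids.index("pred")
            assert pref.matrix[i1, j1] == pytest.approx(pref2.matrix[i2, j2])
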