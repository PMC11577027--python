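"""Mesocosm-specific trophic preference matrices.

Each consumer's expected diet is expressed as a column of proportions
over the web's nodes (animal taxa first, then the basal plant, microbe
and detritus pools), summing to one. The column is assembled in two
stages:

1. The consumer's general diet fractions (animal / plant / microbe /
   detritus) come from its traits.
2. The animal fraction is distributed over the prey taxa present in the
   mesocosm, weighting each prey by (i) the probability that a predator
   of this size consumes prey of that size — a quadratic-logistic
   function of the log10 predator:prey mass ratio, (ii) a prey-agility
   modifier, (iii) a defense modifier, (iv) the vertical-stratum
   overlap between consumer and prey, and (v) the prey's relative
   biomass in that mesocosm. Basal fractions are split uniformly (or
   biomass-proportionally, if configured) over the nodes of their type.

Diet components that are locally absent (no basal node of the type, or
all prey weights zero) are redistributed proportionally over the
remaining components, keeping columns stochastic; a consumer left with
no feasible resource at all is an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .community import Community, Population
from .traits import DIET_COMPONENTS, RESOURCE_TYPES, STRATA, TaxonTraits, TraitTable

__all__ = [
    "LinkModelCoeffs",
    "DEFAULT_LINK_COEFFS",
    "DietConfig",
    "PreferenceMatrix",
    "link_probability",
    "refine_animal_diet",
    "build_preference_matrix",
]


@dataclass(frozen=True)
class LinkModelCoeffs:
    """Coefficients of the mass-ratio link-probability model.

    The probability that a consumer of mass M_pred feeds on prey of
    mass M_prey is ``logistic(b0 + b1*r + b2*r**2)`` with
    ``r = log10(M_pred / M_prey)``. ``b2 <= 0`` makes the probability
    unimodal in the log mass ratio, peaking at an optimal ratio
    ``10**(-b1 / (2*b2))``.
    """

    b0: float
    b1: float
    b2: float

    def __post_init__(self) -> None:
        if self.b2 > 0:
            raise ValueError("b2 must be <= 0 (unimodal link probability)")


#: Illustrative default coefficients: optimum predator:prey mass ratio 100,
#: peak link probability ~0.55, falling off over ~2 orders of magnitude.
DEFAULT_LINK_COEFFS = LinkModelCoeffs(b0=-1.8, b1=2.0, b2=-0.5)


def _default_overlap() -> np.ndarray:
    # identity plus adjacent overlap: strata share fauna with neighbours only
    return np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.5], [0.0, 0.5, 1.0]])


@dataclass(frozen=True)
class DietConfig:
    """Tunable modifiers of the animal-diet refinement.

    ``agility_strength`` (k in [0, 1]) sets how strongly prey agility
    discounts a link: the modifier is ``(1 - agility)*k + (1 - k)``, so
    k=0 disables agility and k=1 makes a maximally agile prey
    uncatchable. ``defense_factor`` multiplies links to defended prey.
    ``stratum_overlap`` is a symmetric 3x3 matrix over (epigeic,
    hemiedaphic, euedaphic). ``basal_biomass_scaling`` splits basal
    fractions across same-type nodes by pool biomass instead of
    uniformly.
    """

    agility_strength: float = 0.5
    defense_factor: float = 0.5
    stratum_overlap: np.ndarray = field(default_factory=_default_overlap)
    basal_biomass_scaling: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.agility_strength <= 1.0):
            raise ValueError("agility_strength must be in [0, 1]")
        if not (0.0 <= self.defense_factor <= 1.0):
            raise ValueError("defense_factor must be in [0, 1]")
        ov = np.asarray(self.stratum_overlap, dtype=float)
        if ov.shape != (3, 3) or np.any(ov < 0):
            raise ValueError("stratum_overlap must be a nonnegative 3x3 matrix")
        object.__setattr__(self, "stratum_overlap", ov)


@dataclass
class PreferenceMatrix:
    """Column-stochastic diet matrix over the web's nodes.

    ``matrix[i, j]`` is the proportion of consumer j's diet taken from
    node i. Animal taxa come first in ``node_ids``/``node_types``, then
    basal nodes; basal columns are all-zero (they consume nothing).
    """

    node_ids: list[str]
    node_types: list[str]  # 'animal' or one of RESOURCE_TYPES
    matrix: np.ndarray

    @property
    def n_animals(self) -> int:
        return sum(t == "animal" for t in self.node_types)

    @property
    def animal_ids(self) -> list[str]:
        return [i for i, t in zip(self.node_ids, self.node_types) if t == "animal"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.node_ids, columns=self.node_ids)


def link_probability(
    pred_mass, prey_mass, coeffs: LinkModelCoeffs = DEFAULT_LINK_COEFFS
):
    """Probability that a consumer of ``pred_mass`` eats prey of ``prey_mass``.

    Vectorized over both arguments (mg). Raises on nonpositive masses.
    """
    pred = np.asarray(pred_mass, dtype=float)
    prey = np.asarray(prey_mass, dtype=float)
    if np.any(pred <= 0) or np.any(prey <= 0):
        raise ValueError("body masses must be > 0")
    r = np.log10(pred / prey)
    z = coeffs.b0 + coeffs.b1 * r + coeffs.b2 * r**2
    out = 1.0 / (1.0 + np.exp(-z))
    return float(out) if out.ndim == 0 else out


def _stratum_idx(stratum: str) -> int:
    return STRATA.index(stratum)


def refine_animal_diet(
    consumer: TaxonTraits,
    consumer_mass: float,
    prey: Sequence[tuple[TaxonTraits, Population]],
    coeffs: LinkModelCoeffs = DEFAULT_LINK_COEFFS,
    config: DietConfig | None = None,
) -> dict[str, float]:
    """Unnormalized diet weights of one consumer over a candidate prey pool.

    weight = link probability x agility modifier x defense modifier x
    stratum overlap x prey biomass. Self-predation is excluded.
    """
    if config is None:
        config = DietConfig()
    k = config.agility_strength
    out: dict[str, float] = {}
    ci = _stratum_idx(consumer.stratum)
    for traits, pop in prey:
        if traits.taxon_id == consumer.taxon_id:
            continue
        p = link_probability(consumer_mass, pop.mean_body_mass, coeffs)
        agility_mod = (1.0 - traits.agility) * k + (1.0 - k)
        defense_mod = config.defense_factor if traits.defended else 1.0
        overlap = config.stratum_overlap[_stratum_idx(traits.stratum), ci]
        out[traits.taxon_id] = p * agility_mod * defense_mod * overlap * pop.biomass
    return out


def build_preference_matrix(
    community: Community,
    traits: TraitTable,
    coeffs: LinkModelCoeffs = DEFAULT_LINK_COEFFS,
    config: DietConfig | None = None,
    biomass_override: Mapping[str, float] | None = None,
) -> PreferenceMatrix:
    """Assemble the column-normalized preference matrix of one mesocosm.

    ``biomass_override`` substitutes prey biomasses (mg) without
    touching the community object; used by the perturbation analysis.
    """
    if config is None:
        config = DietConfig()
    pops = community.populations
    n_a = len(pops)
    basal = community.basal_nodes
    node_ids = [p.taxon_id for p in pops] + [r.node_id for r in basal]
    node_types = ["animal"] * n_a + [r.resource_type for r in basal]
    n = len(node_ids)
    W = np.zeros((n, n))
    if n_a == 0:
        return PreferenceMatrix(node_ids, node_types, W)

    masses = np.array([p.mean_body_mass for p in pops])
    if biomass_override is None:
        biomasses = np.array([p.biomass for p in pops])
    else:
        biomasses = np.array([biomass_override[p.taxon_id] for p in pops])
    tlist = [traits[p.taxon_id] for p in pops]
    agility = np.array([t.agility for t in tlist])
    defended = np.array([t.defended for t in tlist])
    strata = np.array([_stratum_idx(t.stratum) for t in tlist])

    # pairwise animal-animal weights: rows prey, columns consumer
    if np.any(masses <= 0):
        raise ValueError("animal consumers/prey must have positive body mass")
    r = np.log10(masses[None, :] / masses[:, None])
    link = 1.0 / (1.0 + np.exp(-(coeffs.b0 + coeffs.b1 * r + coeffs.b2 * r**2)))
    k = config.agility_strength
    prey_mod = ((1.0 - agility) * k + (1.0 - k)) * np.where(
        defended, config.defense_factor, 1.0
    )
    overlap = config.stratum_overlap[strata[:, None], strata[None, :]]
    animal_w = link * prey_mod[:, None] * overlap * biomasses[:, None]
    np.fill_diagonal(animal_w, 0.0)

    # basal node membership and within-type split
    basal_split = np.zeros((len(basal), len(RESOURCE_TYPES)))
    for bi, node in enumerate(basal):
        basal_split[bi, RESOURCE_TYPES.index(node.resource_type)] = (
            node.pool_biomass if config.basal_biomass_scaling else 1.0
        )
    col_sums = basal_split.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        basal_split = np.where(col_sums > 0, basal_split / col_sums, 0.0)

    for j, (pop, t) in enumerate(zip(pops, tlist)):
        fractions = t.diet_vector.copy()  # (animal, plant, microbe, detritus)
        w_animal = animal_w[:, j]
        available = np.empty(4, dtype=bool)
        available[0] = w_animal.sum() > 0
        available[1:] = col_sums > 0
        fractions[~available] = 0.0
        total = fractions.sum()
        if total <= 0:
            raise ValueError(
                f"consumer {pop.taxon_id} in {community.mesocosm_id} has no "
                "feasible resource (all diet components absent)"
            )
        fractions /= total  # redistribute absent components proportionally
        if fractions[0] > 0:
            W[:n_a, j] = fractions[0] * w_animal / w_animal.sum()
        W[n_a:, j] = basal_split @ fractions[1:]
    return PreferenceMatrix(node_ids, node_types, W)
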