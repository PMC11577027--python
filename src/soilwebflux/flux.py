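"""Steady-state energy fluxes through a soil food web.

Under the steady-state assumption, the energy each animal node loses to
metabolism and to its consumers is exactly balanced by assimilated
energy gained from its resources. Writing G_j for consumer j's total
consumption rate (J/h), X_j for its population metabolic loss and
W[i, j] for the proportion of j's diet taken from node i, the balance
for every animal node j is

    e_bar_j * G_j = X_j + sum_k W[j, k] * G_k

where e_bar_j = sum_i e(type_i) * W[i, j] is the diet-weighted
assimilation efficiency of j (efficiencies attach to the resource
type). Basal nodes (plant, microbe, detritus) carry no balance
equation. The system is linear and solved directly; per-link fluxes
are F[i, j] = W[i, j] * G_j, and summing F over resource-node types
decomposes the total flux into predation, herbivory, microbivory and
detritivory — the community's trophic functions.

Metabolic losses follow an Arrhenius-allometric regression: the rate of
an average individual of body mass M (mg) is
``exp(ln x0 + a * ln M - E / (k T))`` J/h, extrapolated to the
population by multiplying with density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .community import Community, with_fixed_taxon_masses
from .diet import DietConfig, LinkModelCoeffs, DEFAULT_LINK_COEFFS, PreferenceMatrix, build_preference_matrix
from .traits import TraitTable

__all__ = [
    "BOLTZMANN_EV_PER_K",
    "DEFAULT_TEMPERATURE_K",
    "EfficiencyTable",
    "FluxResult",
    "InfeasibleWebError",
    "individual_metabolic_rate",
    "population_metabolic_loss",
    "metabolic_losses",
    "solve_fluxes",
    "iterate_fluxes",
    "aggregate_fluxes",
    "compute_community_fluxes",
    "sensitivity_fixed_bodymass",
    "sensitivity_perturb",
]

#: Boltzmann constant in eV/K.
BOLTZMANN_EV_PER_K = 8.617333262e-5

#: System temperature (K); the facility keeps a controlled climate, so a
#: single temperature applies to every mesocosm. 15 degC.
DEFAULT_TEMPERATURE_K = 288.15

#: Trophic function associated with each resource-node type.
FUNCTION_OF_TYPE = {
    "animal": "predation",
    "plant": "herbivory",
    "microbe": "microbivory",
    "detritus": "detritivory",
}


class InfeasibleWebError(ValueError):
    """The steady-state system has no nonnegative solution."""


@dataclass(frozen=True)
class EfficiencyTable:
    """Assimilation efficiency by resource type.

    Defaults: 0.906 for animal prey and microbes, 0.545 for plant
    tissue, 0.158 for detritus.
    """

    animal: float = 0.906
    plant: float = 0.545
    microbe: float = 0.906
    detritus: float = 0.158

    def __post_init__(self) -> None:
        for name in ("animal", "plant", "microbe", "detritus"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"efficiency {name}={v} outside (0, 1]")

    def for_types(self, node_types: Sequence[str]) -> np.ndarray:
        return np.array([getattr(self, t) for t in node_types])


def individual_metabolic_rate(
    mass: float,
    coeffs: tuple[float, float, float],
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """Metabolic rate (J/h) of an average individual of ``mass`` mg.

    ``coeffs`` are (ln x0, a, E): normalisation, allometric exponent and
    activation energy (eV).
    """
    m = np.asarray(mass, dtype=float)
    if np.any(m <= 0):
        raise ValueError("body mass must be > 0")
    if temperature_K <= 0:
        raise ValueError("temperature must be > 0 K")
    ln_x0, a, E = coeffs
    out = np.exp(ln_x0 + a * np.log(m) - E / (BOLTZMANN_EV_PER_K * temperature_K))
    return float(out) if out.ndim == 0 else out


def population_metabolic_loss(
    density: float,
    mean_body_mass: float,
    coeffs: tuple[float, float, float],
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """Population-level metabolic loss: individual rate times density."""
    if density == 0:
        return 0.0
    return density * individual_metabolic_rate(mean_body_mass, coeffs, temperature_K)


def metabolic_losses(
    community: Community,
    traits: TraitTable,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> np.ndarray:
    """Per-population metabolic losses (J/h), in community order."""
    return np.array(
        [
            population_metabolic_loss(
                p.density, p.mean_body_mass, traits[p.taxon_id].metab_coeffs, temperature_K
            )
            for p in community.populations
        ]
    )


@dataclass
class FluxResult:
    """Solved fluxes of one web.

    ``fluxes[i, j]`` is the J/h flowing from node i to consumer j;
    ``consumption`` is per-consumer total intake G (animal nodes, in
    node order); ``by_function`` decomposes the grand total by the
    resource type of the donor node, and ``total`` is their sum (the
    decomposition is exact by construction). ``residuals`` are the
    relative balance residuals of the animal nodes.
    """

    node_ids: list[str]
    node_types: list[str]
    fluxes: np.ndarray
    consumption: np.ndarray
    by_function: dict[str, float]
    residuals: np.ndarray
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = sum(self.by_function.values())

    def to_frame(self) -> pd.DataFrame:
        """Long-format nonzero links: resource, consumer, flux."""
        rows = []
        animals = [i for i, t in enumerate(self.node_types) if t == "animal"]
        for j in animals:
            for i in range(len(self.node_ids)):
                f = self.fluxes[i, j]
                if f > 0:
                    rows.append(
                        {
                            "resource": self.node_ids[i],
                            "consumer": self.node_ids[j],
                            "flux": f,
                        }
                    )
        return pd.DataFrame(rows, columns=["resource", "consumer", "flux"])


def aggregate_fluxes(
    fluxes: np.ndarray, node_types: Sequence[str]
) -> dict[str, float]:
    """Sum per-link fluxes by the donor node's trophic function.

    Returns predation/herbivory/microbivory/detritivory; the caller's
    grand total is their sum, making the decomposition exact.
    """
    out = {fn: 0.0 for fn in FUNCTION_OF_TYPE.values()}
    row_totals = np.asarray(fluxes).sum(axis=1)
    for i, t in enumerate(node_types):
        out[FUNCTION_OF_TYPE[t]] += float(row_totals[i])
    return out


def _consumer_system(
    pref: PreferenceMatrix, efficiencies: EfficiencyTable
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(e_bar, W_aa, animal index) for the consumer balance system."""
    W = pref.matrix
    types = pref.node_types
    animal_idx = np.array([i for i, t in enumerate(types) if t == "animal"])
    e_node = efficiencies.for_types(types)
    e_bar = e_node @ W[:, animal_idx]
    W_aa = W[np.ix_(animal_idx, animal_idx)]
    return e_bar, W_aa, animal_idx


def solve_fluxes(
    pref: PreferenceMatrix,
    losses: np.ndarray,
    efficiencies: EfficiencyTable | None = None,
) -> FluxResult:
    """Solve the steady-state balance and return per-link fluxes.

    ``losses`` are per-animal-node metabolic losses X (J/h), in the
    animal-node order of ``pref``. Raises :class:`InfeasibleWebError`
    when the system is singular or any consumption rate is negative.
    """
    if efficiencies is None:
        efficiencies = EfficiencyTable()
    X = np.asarray(losses, dtype=float)
    if np.any(X < 0):
        raise ValueError("metabolic losses must be >= 0")
    e_bar, W_aa, animal_idx = _consumer_system(pref, efficiencies)
    if animal_idx.size == 0:
        raise ValueError("web has no consumers")
    if X.shape != (animal_idx.size,):
        raise ValueError("losses must align with the animal nodes")
    A = np.diag(e_bar) - W_aa
    try:
        G = np.linalg.solve(A, X)
    except np.linalg.LinAlgError as exc:
        raise InfeasibleWebError("degenerate food web (singular balance system)") from exc
    scale = max(G.max(initial=0.0), 1.0)
    if np.any(G < -1e-12 * scale):
        bad = [pref.node_ids[animal_idx[j]] for j in np.where(G < 0)[0]]
        raise InfeasibleWebError(
            f"infeasible steady state: negative consumption for {bad}"
        )
    G = np.maximum(G, 0.0)

    n = len(pref.node_ids)
    F = np.zeros((n, n))
    F[:, animal_idx] = pref.matrix[:, animal_idx] * G[None, :]
    outflow = F[animal_idx, :].sum(axis=1)
    resid = np.abs(e_bar * G - X - outflow) / np.maximum(X, 1e-30)
    by_function = aggregate_fluxes(F, pref.node_types)
    return FluxResult(
        node_ids=list(pref.node_ids),
        node_types=list(pref.node_types),
        fluxes=F,
        consumption=G,
        by_function=by_function,
        residuals=resid,
    )


def iterate_fluxes(
    pref: PreferenceMatrix,
    losses: np.ndarray,
    efficiencies: EfficiencyTable | None = None,
    damping: float = 1.0,
    tol: float = 1e-12,
    max_iter: int = 200_000,
) -> np.ndarray:
    """Consumption rates by damped fixed-point iteration.

    Iterates ``G <- (1 - d) G + d (X + W_aa G) / e_bar``. Kept as an
    independent cross-check of :func:`solve_fluxes`; converges whenever
    the web's loop gains are below one.
    """
    if efficiencies is None:
        efficiencies = EfficiencyTable()
    X = np.asarray(losses, dtype=float)
    e_bar, W_aa, _ = _consumer_system(pref, efficiencies)
    G = X / e_bar
    for _ in range(max_iter):
        G_new = (1.0 - damping) * G + damping * (X + W_aa @ G) / e_bar
        if np.max(np.abs(G_new - G)) <= tol * max(1.0, np.max(np.abs(G_new))):
            return G_new
        G = G_new
    raise RuntimeError("fixed-point iteration did not converge")


def compute_community_fluxes(
    community: Community,
    traits: TraitTable,
    coeffs: LinkModelCoeffs = DEFAULT_LINK_COEFFS,
    config: DietConfig | None = None,
    efficiencies: EfficiencyTable | None = None,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> FluxResult:
    """Preference matrix + metabolic losses + steady-state solve, in one call."""
    pref = build_preference_matrix(community, traits, coeffs, config)
    X = metabolic_losses(community, traits, temperature_K)
    return solve_fluxes(pref, X, efficiencies)


def sensitivity_fixed_bodymass(
    communities: Mapping[str, Community],
    traits: TraitTable,
    coeffs: LinkModelCoeffs = DEFAULT_LINK_COEFFS,
    config: DietConfig | None = None,
    efficiencies: EfficiencyTable | None = None,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
    weighted: bool = True,
) -> tuple[dict[str, Community], dict[str, FluxResult]]:
    """Re-run the flux pipeline ignoring between-mesocosm body-mass shifts.

    Every population's mean body mass is replaced by its taxon's
    cross-mesocosm (density-weighted) average, separating the
    contribution of within-taxon mass variation from compositional
    change. Returns the adjusted communities and their flux results.
    """
    fixed = with_fixed_taxon_masses(communities, weighted=weighted)
    results = {
        mid: compute_community_fluxes(
            c, traits, coeffs, config, efficiencies, temperature_K
        )
        for mid, c in fixed.items()
    }
    return fixed, results


def sensitivity_perturb(
    community: Community,
    traits: TraitTable,
    biomass_cv: float = 0.0,
    metabolism_cv: float = 0.0,
    n_draws: int = 1000,
    seed: int | np.random.Generator = 0,
    coeffs: LinkModelCoeffs = DEFAULT_LINK_COEFFS,
    config: DietConfig | None = None,
    efficiencies: EfficiencyTable | None = None,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> pd.DataFrame:
    """Monte-Carlo perturbation of population biomasses and metabolic losses.

    Each draw multiplies every population's biomass and metabolic loss
    by independent mean-one lognormal factors with the given
    coefficients of variation (relaxing the steady-state assumption),
    rebuilds the preference matrix (prey-biomass weighting responds to
    the biomass perturbation) and re-solves. Returns one row per draw
    with the total and per-function fluxes.
    """
    if biomass_cv < 0 or metabolism_cv < 0:
        raise ValueError("coefficients of variation must be >= 0")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pops = community.populations
    n = len(pops)
    X0 = metabolic_losses(community, traits, temperature_K)
    base_biomass = np.array([p.biomass for p in pops])

    def _factors(cv: float, size: int) -> np.ndarray:
        if cv == 0:
            return np.ones(size)
        sigma = np.sqrt(np.log1p(cv**2))
        return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)

    rows = []
    for _ in range(n_draws):
        fb = _factors(biomass_cv, n)
        fm = _factors(metabolism_cv, n)
        override = {p.taxon_id: b for p, b in zip(pops, base_biomass * fb)}
        pref = build_preference_matrix(
            community, traits, coeffs, config, biomass_override=override
        )
        res = solve_fluxes(pref, X0 * fb * fm, efficiencies)
        rows.append({"total": res.total, **res.by_function})
    return pd.DataFrame(rows)
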