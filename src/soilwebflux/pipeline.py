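"""End-to-end pipeline: raw samples to per-mesocosm responses.

Ties the stages together: sample records -> communities -> preference
matrices -> steady-state fluxes -> one row per mesocosm with the total
and per-function energy fluxes (J/h) and the three community metrics,
joined to the design table for the contrasts stage.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .community import (
    Community,
    CoreSpec,
    build_communities,
    community_biomass,
    cwm_body_mass,
    shannon_exponent_diversity,
)
from .diet import DEFAULT_LINK_COEFFS, DietConfig, LinkModelCoeffs
from .flux import (
    DEFAULT_TEMPERATURE_K,
    EfficiencyTable,
    compute_community_fluxes,
)
from .traits import TraitTable

__all__ = ["mesocosm_responses", "run_pipeline"]

RESPONSES = (
    "total_flux",
    "predation",
    "herbivory",
    "microbivory",
    "detritivory",
    "biomass",
    "cwm_body_mass",
    "diversity",
)


def mesocosm_responses(
    communities: Mapping[str, Community],
    traits: TraitTable,
    coeffs: LinkModelCoeffs = DEFAULT_LINK_COEFFS,
    config: DietConfig | None = None,
    efficiencies: EfficiencyTable | None = None,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
    include_fluxes: bool = True,
) -> pd.DataFrame:
    """Fluxes and community metrics, one row per mesocosm."""
    rows = []
    for mid, c in communities.items():
        row: dict = {"mesocosm_id": mid, "n_taxa": len(c)}
        row["biomass"] = community_biomass(c)
        row["cwm_body_mass"] = cwm_body_mass(c)
        row["diversity"] = shannon_exponent_diversity(c)
        if include_fluxes:
            res = compute_community_fluxes(
                c, traits, coeffs, config, efficiencies, temperature_K
            )
            row["total_flux"] = res.total
            row.update(res.by_function)
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    samples: pd.DataFrame,
    traits: TraitTable,
    design: pd.DataFrame,
    cores: Mapping[str, CoreSpec] | None = None,
    coeffs: LinkModelCoeffs = DEFAULT_LINK_COEFFS,
    config: DietConfig | None = None,
    efficiencies: EfficiencyTable | None = None,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
    include_fluxes: bool = True,
) -> pd.DataFrame:
    """Raw samples + design -> per-mesocosm response table.

    The returned frame carries the design columns (block, ecounit,
    history, richness) next to the responses, ready for
    :mod:`soilwebflux.contrasts`.
    """
    communities = build_communities(
        samples, traits, cores, mesocosm_ids=list(design["mesocosm_id"])
    )
    responses = mesocosm_responses(
        communities,
        traits,
        coeffs,
        config,
        efficiencies,
        temperature_K,
        include_fluxes=include_fluxes,
    )
    return design.merge(responses, on="mesocosm_id", validate="one_to_one")
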