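"""From raw faunal sample records to per-mesocosm communities.

A mesocosm is sampled with class-specific soil cores (a 15 cm diameter
core for macrofauna, a 5 cm core for mesofauna, three pooled 2 cm cores
for nematodes, all to 10 cm depth). Counts in a core are scaled to the
whole mesocosm surface; nematode counts, which are made on animals
extracted from a known fresh-soil mass, are scaled through the dry-soil
fraction and dry soil bulk density instead. Body masses come from
group-specific length(–width)–mass regressions applied to up to 10
measured individuals per taxon per mesocosm, or from a reference mass
for taxa (nematodes) that are not measured individually.

The resulting :class:`Community` carries, per taxon, density
(individuals per mesocosm), mean individual body mass (mg) and biomass
(mg per mesocosm), and supports the three community metrics used
downstream: total biomass, community-weighted mean (CWM) body mass, and
diversity as the exponent of Shannon entropy of relative biomass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .traits import ResourceNode, TraitTable, default_resource_nodes

__all__ = [
    "CoreSpec",
    "SampleRecord",
    "Population",
    "Community",
    "MESOCOSM_DIAMETER_CM",
    "estimate_body_mass",
    "scale_core_abundance",
    "scale_nematode_abundance",
    "apportion_to_taxa",
    "community_biomass",
    "cwm_body_mass",
    "shannon_exponent_diversity",
    "build_communities",
    "community_metrics",
    "default_core_specs",
    "parse_measurements",
    "format_measurements",
]

#: Inner diameter (cm) of the lysimeters housing each community.
MESOCOSM_DIAMETER_CM = 50.0

#: Depth (cm) to which all soil cores are taken.
CORE_DEPTH_CM = 10.0


@dataclass(frozen=True)
class CoreSpec:
    """Geometry (and, for nematodes, soil-mass conversion) of a sampler.

    ``fresh_soil_mass_g``, ``dry_fraction`` and ``dry_soil_density`` are
    only needed for the nematode workflow, where counts refer to animals
    extracted from a fresh-soil subsample rather than to a whole core.
    """

    core_diameter_cm: float
    n_cores_pooled: int = 1
    depth_cm: float = CORE_DEPTH_CM
    fresh_soil_mass_g: float | None = None
    dry_fraction: float | None = None
    dry_soil_density: float | None = None  # g dry soil per cm^3

    def __post_init__(self) -> None:
        if not (self.core_diameter_cm > 0):
            raise ValueError("core diameter must be > 0")
        if self.n_cores_pooled < 1:
            raise ValueError("n_cores_pooled must be >= 1")

    @property
    def total_area_cm2(self) -> float:
        return self.n_cores_pooled * math.pi * (self.core_diameter_cm / 2.0) ** 2


def default_core_specs() -> dict[str, CoreSpec]:
    """The three samplers: macrofauna, mesofauna and nematode cores."""
    return {
        "macro": CoreSpec(core_diameter_cm=15.0, n_cores_pooled=1),
        "meso": CoreSpec(core_diameter_cm=5.0, n_cores_pooled=1),
        "nema": CoreSpec(
            core_diameter_cm=2.0,
            n_cores_pooled=3,
            fresh_soil_mass_g=20.0,
            dry_fraction=0.8,
            dry_soil_density=1.0,
        ),
    }


@dataclass(frozen=True)
class SampleRecord:
    """One taxon's raw record in one mesocosm's sample."""

    mesocosm_id: str
    taxon_id: str
    count: float
    lengths: tuple[float, ...] = ()
    widths: tuple[float, ...] = ()
    sampler: str = "meso"

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if any(L < 0 for L in self.lengths):
            raise ValueError("negative body length")


@dataclass(frozen=True)
class Population:
    """One taxon realized in one mesocosm."""

    taxon_id: str
    density: float  # individuals per mesocosm
    mean_body_mass: float  # mg per individual
    biomass: float = field(default=float("nan"))  # mg per mesocosm

    def __post_init__(self) -> None:
        if self.density < 0 or self.mean_body_mass < 0:
            raise ValueError("density and body mass must be >= 0")
        if math.isnan(self.biomass):
            object.__setattr__(self, "biomass", self.density * self.mean_body_mass)
        else:
            expected = self.density * self.mean_body_mass
            if expected > 0 and abs(self.biomass - expected) > 1e-12 * expected:
                raise ValueError("biomass inconsistent with density * mean_body_mass")


@dataclass
class Community:
    """One mesocosm's fauna plus its basal resource pools."""

    mesocosm_id: str
    populations: list[Population]
    basal_nodes: list[ResourceNode] = field(default_factory=default_resource_nodes)
    mesocosm_diameter_cm: float = MESOCOSM_DIAMETER_CM

    def __post_init__(self) -> None:
        ids = [p.taxon_id for p in self.populations]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.mesocosm_id}: duplicated taxon in community")

    def __len__(self) -> int:
        return len(self.populations)


# ---------------------------------------------------------------------------
# elementary operations


def estimate_body_mass(
    lengths: Sequence[float],
    widths: Sequence[float] | None,
    lenmass,
    fallback_mass: float | None = None,
) -> float:
    """Mean individual body mass (mg) for one taxon in one mesocosm.

    The regression is applied to each measured individual and the
    resulting masses averaged arithmetically (mass of the mean length
    would understate the population mean for convex allometries). With
    no measurements, ``fallback_mass`` is used; with neither, raises.
    """
    have_lengths = lengths is not None and len(lengths) > 0
    if not have_lengths or lenmass is None:
        if fallback_mass is None:
            raise ValueError("no measurements and no fallback body mass")
        return float(fallback_mass)
    return float(np.mean(lenmass.masses(lengths, widths)))


def scale_core_abundance(
    count: float, core: CoreSpec, mesocosm_diameter_cm: float = MESOCOSM_DIAMETER_CM
) -> float:
    """Individuals per mesocosm from a count in one (possibly pooled) core.

    Area-proportional: ``count * mesocosm_area / total_core_area``.
    """
    core_area = core.total_area_cm2
    if core_area <= 0:
        raise ValueError("core area must be > 0")
    meso_area = math.pi * (mesocosm_diameter_cm / 2.0) ** 2
    if meso_area <= 0:
        raise ValueError("mesocosm area must be > 0")
    return count * meso_area / core_area


def scale_nematode_abundance(
    count: float, core: CoreSpec, mesocosm_diameter_cm: float = MESOCOSM_DIAMETER_CM
) -> float:
    """Individuals per mesocosm from a count per extracted fresh-soil mass.

    The count (animals extracted from ``fresh_soil_mass_g`` grams of
    fresh soil) is first converted to individuals per gram of dry soil
    via the dry fraction, then to the whole mesocosm via dry soil bulk
    density and the sampled soil volume: mesocosm surface area times the
    sampling depth.
    """
    if core.fresh_soil_mass_g is None or not core.fresh_soil_mass_g > 0:
        raise ValueError("fresh_soil_mass_g must be > 0 for nematode scaling")
    if core.dry_fraction is None or not (0 < core.dry_fraction <= 1):
        raise ValueError("dry_fraction must be in (0, 1]")
    if core.dry_soil_density is None or not core.dry_soil_density > 0:
        raise ValueError("dry_soil_density must be > 0")
    per_g_dry = count / (core.fresh_soil_mass_g * core.dry_fraction)
    meso_area = math.pi * (mesocosm_diameter_cm / 2.0) ** 2
    soil_volume = meso_area * core.depth_cm  # cm^3 in the sampled layer
    return per_g_dry * core.dry_soil_density * soil_volume


def apportion_to_taxa(
    total_density: float, identified_composition: Mapping[str, float]
) -> dict[str, float]:
    """Split a total density across taxa by identified-subsample composition.

    Used for nematodes, where the full extract is counted but only up to
    100 individuals are identified. Conserves the total exactly.
    """
    counts = {k: float(v) for k, v in identified_composition.items()}
    if any(v < 0 for v in counts.values()):
        raise ValueError("identified counts must be >= 0")
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("identified composition sums to zero")
    return {k: total_density * v / total for k, v in counts.items()}


def community_biomass(c: Community) -> float:
    """Total fauna biomass (mg per mesocosm)."""
    return float(sum(p.biomass for p in c.populations))


def cwm_body_mass(c: Community) -> float:
    """Community-weighted mean body mass (mg).

    Abundance-weighted mean of ln(mass), back-transformed — the
    geometric-style mean appropriate for right-skewed body-mass
    distributions spanning several orders of magnitude.
    """
    dens = np.array([p.density for p in c.populations])
    total = dens.sum()
    if total <= 0:
        raise ValueError("cwm_body_mass undefined for zero total density")
    mass = np.array([p.mean_body_mass for p in c.populations])
    keep = dens > 0
    if np.any(mass[keep] <= 0):
        raise ValueError("cwm_body_mass requires positive body masses")
    w = dens[keep] / total
    return float(np.exp(np.sum(w * np.log(mass[keep]))))


def shannon_exponent_diversity(c: Community) -> float:
    """Effective number of taxa: exp(H) of relative-biomass shares."""
    b = np.array([p.biomass for p in c.populations])
    b = b[b > 0]
    total = b.sum()
    if total <= 0:
        raise ValueError("diversity undefined for zero total biomass")
    p = b / total
    return float(np.exp(-np.sum(p * np.log(p))))


# ---------------------------------------------------------------------------
# record parsing and community assembly

_SEP = ";"


def format_measurements(values: Iterable[float]) -> str:
    return _SEP.join(f"{v:.6g}" for v in values)


def parse_measurements(cell) -> tuple[float, ...]:
    """Parse a semicolon-delimited measurement subfield; empty -> ()."""
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return ()
    s = str(cell).strip()
    if not s:
        return ()
    return tuple(float(x) for x in s.split(_SEP))


def _records_from_frame(samples: pd.DataFrame) -> list[SampleRecord]:
    required = {"mesocosm_id", "taxon_id", "count", "sampler"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample table missing column(s): {sorted(missing)}")
    recs = []
    has_len = "lengths" in samples.columns
    has_wid = "widths" in samples.columns
    for row in samples.itertuples(index=False):
        recs.append(
            SampleRecord(
                mesocosm_id=str(row.mesocosm_id),
                taxon_id=str(row.taxon_id),
                count=float(row.count),
                lengths=parse_measurements(row.lengths) if has_len else (),
                widths=parse_measurements(row.widths) if has_wid else (),
                sampler=str(row.sampler),
            )
        )
    return recs


def build_communities(
    samples: pd.DataFrame | Sequence[SampleRecord],
    traits: TraitTable,
    cores: Mapping[str, CoreSpec] | None = None,
    mesocosm_diameter_cm: float = MESOCOSM_DIAMETER_CM,
    mesocosm_ids: Sequence[str] | None = None,
) -> dict[str, Community]:
    """Assemble per-mesocosm communities from raw sample records.

    Records are scaled to whole-mesocosm densities with the sampler
    named in their ``sampler`` field, and body masses estimated from the
    measured individuals. A taxon with no measurements in some mesocosm
    falls back to its density-weighted mean mass across the mesocosms
    where it was measured, then to the trait table's fixed body mass.

    Parameters
    ----------
    samples
        Long-format records: one row per taxon x mesocosm.
    mesocosm_ids
        Optional explicit community list (mesocosms where nothing was
        caught still yield an empty community).
    """
    if cores is None:
        cores = default_core_specs()
    if isinstance(samples, pd.DataFrame):
        records = _records_from_frame(samples)
    else:
        records = list(samples)

    unknown = sorted({r.taxon_id for r in records if r.taxon_id not in traits})
    if unknown:
        raise ValueError(f"sample taxa absent from trait table: {unknown}")

    # first pass: densities, and masses where measured
    rows: list[dict] = []
    for r in records:
        if r.count <= 0:
            continue
        core = cores[r.sampler]
        t = traits[r.taxon_id]
        if core.fresh_soil_mass_g is not None:
            density = scale_nematode_abundance(r.count, core, mesocosm_diameter_cm)
        else:
            density = scale_core_abundance(r.count, core, mesocosm_diameter_cm)
        mass = None
        if r.lengths and t.lenmass is not None:
            mass = estimate_body_mass(
                r.lengths, r.widths if r.widths else None, t.lenmass
            )
        rows.append(
            {"mesocosm": r.mesocosm_id, "taxon": r.taxon_id, "density": density, "mass": mass}
        )

    # cross-mesocosm fallback masses (density-weighted over measured rows)
    pooled: dict[str, float] = {}
    acc: dict[str, list[tuple[float, float]]] = {}
    for row in rows:
        if row["mass"] is not None:
            acc.setdefault(row["taxon"], []).append((row["density"], row["mass"]))
    for taxon, pairs in acc.items():
        w = np.array([p[0] for p in pairs])
        m = np.array([p[1] for p in pairs])
        pooled[taxon] = float(np.sum(w * m) / np.sum(w))
    for row in rows:
        if row["mass"] is None:
            t = traits[row["taxon"]]
            if row["taxon"] in pooled:
                row["mass"] = pooled[row["taxon"]]
            elif t.fixed_body_mass is not None:
                row["mass"] = t.fixed_body_mass
            else:
                raise ValueError(
                    f"taxon {row['taxon']} has no measurements anywhere and no "
                    "fixed body mass"
                )

    by_meso: dict[str, list[Population]] = {}
    for row in rows:
        by_meso.setdefault(row["mesocosm"], []).append(
            Population(row["taxon"], row["density"], row["mass"])
        )
    ids = list(mesocosm_ids) if mesocosm_ids is not None else sorted(by_meso)
    return {
        mid: Community(
            mesocosm_id=mid,
            populations=by_meso.get(mid, []),
            basal_nodes=list(traits.resources),
            mesocosm_diameter_cm=mesocosm_diameter_cm,
        )
        for mid in ids
    }


def community_metrics(communities: Mapping[str, Community]) -> pd.DataFrame:
    """Biomass, CWM body mass and diversity for every community."""
    rows = []
    for mid, c in communities.items():
        rows.append(
            {
                "mesocosm_id": mid,
                "n_taxa": len(c),
                "biomass": community_biomass(c),
                "cwm_body_mass": cwm_body_mass(c) if len(c) else float("nan"),
                "diversity": shannon_exponent_diversity(c) if len(c) else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def with_fixed_taxon_masses(
    communities: Mapping[str, Community], weighted: bool = True
) -> dict[str, Community]:
    """Replace every population's mass by its taxon's cross-mesocosm average.

    The averaging is density-weighted by default (each measured
    individual counts equally); ``weighted=False`` averages mesocosm
    means instead. When a taxon's mass is already identical everywhere
    the value is passed through unchanged (exact, not re-averaged).
    """
    num: dict[str, float] = {}
    den: dict[str, float] = {}
    values: dict[str, set[float]] = {}
    for c in communities.values():
        for p in c.populations:
            w = p.density if weighted else 1.0
            num[p.taxon_id] = num.get(p.taxon_id, 0.0) + w * p.mean_body_mass
            den[p.taxon_id] = den.get(p.taxon_id, 0.0) + w
            values.setdefault(p.taxon_id, set()).add(p.mean_body_mass)
    avg = {}
    for taxon in num:
        if len(values[taxon]) == 1:
            avg[taxon] = next(iter(values[taxon]))
        else:
            avg[taxon] = num[taxon] / den[taxon]
    out = {}
    for mid, c in communities.items():
        pops = [
            Population(p.taxon_id, p.density, avg[p.taxon_id]) for p in c.populations
        ]
        out[mid] = replace(c, populations=pops)
    return out
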