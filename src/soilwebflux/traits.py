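"""Per-taxon biological constants consumed by the rest of the pipeline.

Every downstream stage — body-mass estimation, diet-matrix construction,
metabolic scaling — is parameterised by a :class:`TraitTable`: one
:class:`TaxonTraits` record per taxon (diet fractions over the four
resource types, an agility score, a defense flag, a vertical stratum,
metabolic and length–mass regression coefficients), plus the basal
resource nodes (plant, microbe, detritus) of the web.

Trait values are user-supplied configuration, read from delimited text.
The module validates eagerly: a malformed table raises
:class:`TraitError` naming the offending row or column; it never yields
a partially loaded table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FAUNA_CLASSES",
    "STRATA",
    "RESOURCE_TYPES",
    "DIET_COMPONENTS",
    "TraitError",
    "LengthMassModel",
    "TaxonTraits",
    "ResourceNode",
    "TraitTable",
    "load_trait_table",
    "load_resource_nodes",
    "write_trait_table",
    "default_resource_nodes",
    "validate_against_samples",
]

FAUNA_CLASSES = ("macrofauna", "mesofauna", "nematode")
#: Vertical position in the soil profile, surface to depth.
STRATA = ("epigeic", "hemiedaphic", "euedaphic")
#: Basal (non-animal) resource types.
RESOURCE_TYPES = ("plant", "microbe", "detritus")
#: Diet components of a consumer: animal prey plus the basal types.
DIET_COMPONENTS = ("animal", "plant", "microbe", "detritus")


class TraitError(ValueError):
    """Raised when a trait table or a single trait record is invalid."""


@dataclass(frozen=True)
class LengthMassModel:
    """Allometric length(–width)–mass regression for one taxon.

    Two functional forms are supported, both applied per measured
    individual and back-transformed to the arithmetic mass scale before
    averaging:

    ``power``
        ``M = a * L**b`` (length only).
    ``power_lw``
        ``M = a * L**b * W**c`` (length and width; macrofauna).

    Lengths and widths are in mm, masses in mg.
    """

    form: str
    a: float
    b: float
    c: float = float("nan")

    def __post_init__(self) -> None:
        if self.form not in ("power", "power_lw"):
            raise TraitError(f"unknown length-mass form {self.form!r}")
        if not (self.a > 0):
            raise TraitError("length-mass coefficient a must be > 0")
        if self.form == "power_lw" and not math.isfinite(self.c):
            raise TraitError("power_lw form requires coefficient c")

    @property
    def needs_width(self) -> bool:
        return self.form == "power_lw"

    def masses(
        self, lengths: Sequence[float], widths: Sequence[float] | None = None
    ) -> np.ndarray:
        """Per-individual body masses (mg) from measurements (mm)."""
        L = np.asarray(lengths, dtype=float)
        if L.size == 0:
            raise TraitError("no measurements supplied")
        if np.any(L < 0):
            raise TraitError("negative body length")
        if self.form == "power":
            return self.a * L**self.b
        W = np.asarray(widths, dtype=float) if widths is not None else None
        if W is None or W.size != L.size:
            raise TraitError("power_lw regression requires one width per length")
        if np.any(W < 0):
            raise TraitError("negative body width")
        return self.a * L**self.b * W**self.c

    def invert_length(self, mass: float) -> float:
        """Length (mm) whose predicted mass equals ``mass`` (power form only)."""
        if self.form != "power":
            raise TraitError("invert_length defined for the power form only")
        return (mass / self.a) ** (1.0 / self.b)


@dataclass(frozen=True)
class TaxonTraits:
    """Biology of one taxon.

    ``basal_fractions`` maps the four diet components
    (animal/plant/microbe/detritus) to proportions of the consumer's
    diet; each lies in [0, 1] and their sum in (0, 1]. ``agility`` is a
    prey-escape score in [0, 1] (1 = highly agile); ``defended`` flags
    physical or chemical defenses. ``metab_coeffs`` are ``(ln x0, a, E)``
    of the Arrhenius–allometric metabolic regression. Exactly one of
    ``lenmass`` / ``fixed_body_mass`` must be usable: measured taxa carry
    a regression, nematodes a reference mass (mg).
    """

    taxon_id: str
    fauna_class: str
    basal_fractions: Mapping[str, float]
    agility: float
    defended: bool
    stratum: str
    metab_coeffs: tuple[float, float, float]
    lenmass: LengthMassModel | None = None
    fixed_body_mass: float | None = None

    def __post_init__(self) -> None:
        tid = self.taxon_id
        if self.fauna_class not in FAUNA_CLASSES:
            raise TraitError(f"{tid}: unknown fauna_class {self.fauna_class!r}")
        if self.stratum not in STRATA:
            raise TraitError(f"{tid}: unknown stratum {self.stratum!r}")
        fracs = dict(self.basal_fractions)
        if set(fracs) != set(DIET_COMPONENTS):
            raise TraitError(f"{tid}: diet fractions must cover {DIET_COMPONENTS}")
        for comp, v in fracs.items():
            if not (0.0 <= v <= 1.0):
                raise TraitError(f"{tid}: diet fraction {comp}={v} outside [0, 1]")
        total = sum(fracs.values())
        if not (0.0 < total <= 1.0 + 1e-9):
            raise TraitError(
                f"{tid}: diet fractions sum to {total}, expected in (0, 1]"
            )
        if not (0.0 <= self.agility <= 1.0):
            raise TraitError(f"{tid}: agility {self.agility} outside [0, 1]")
        if len(self.metab_coeffs) != 3:
            raise TraitError(f"{tid}: metab_coeffs must be (ln x0, a, E)")
        has_fixed = self.fixed_body_mass is not None
        if has_fixed and not (self.fixed_body_mass > 0):
            raise TraitError(f"{tid}: fixed_body_mass must be > 0")
        if self.lenmass is None and not has_fixed:
            raise TraitError(
                f"{tid}: needs a length-mass regression or a fixed body mass"
            )
        object.__setattr__(self, "basal_fractions", fracs)

    @property
    def diet_vector(self) -> np.ndarray:
        """Diet fractions as an array ordered like :data:`DIET_COMPONENTS`."""
        return np.array([self.basal_fractions[c] for c in DIET_COMPONENTS], dtype=float)


@dataclass(frozen=True)
class ResourceNode:
    """A basal resource pool (plant, microbe or detritus).

    ``pool_biomass`` (mg per mesocosm) is used only when basal diet
    fractions are split biomass-proportionally across multiple nodes of
    the same type; with the default single node per type it is inert.
    """

    node_id: str
    resource_type: str
    pool_biomass: float = 1.0

    def __post_init__(self) -> None:
        if self.resource_type not in RESOURCE_TYPES:
            raise TraitError(
                f"{self.node_id}: unknown resource_type {self.resource_type!r}"
            )
        if not (self.pool_biomass > 0):
            raise TraitError(f"{self.node_id}: pool_biomass must be > 0")


def default_resource_nodes() -> list[ResourceNode]:
    """One unit-biomass node per basal resource type."""
    return [ResourceNode(t, t) for t in RESOURCE_TYPES]


@dataclass
class TraitTable:
    """All taxa plus the basal resource nodes of an experiment."""

    taxa: dict[str, TaxonTraits]
    resources: list[ResourceNode] = field(default_factory=default_resource_nodes)

    def __post_init__(self) -> None:
        ids = [r.node_id for r in self.resources]
        if len(set(ids)) != len(ids):
            raise TraitError("duplicated resource node_id")

    def __getitem__(self, taxon_id: str) -> TaxonTraits:
        try:
            return self.taxa[taxon_id]
        except KeyError:
            raise TraitError(f"taxon {taxon_id!r} absent from trait table") from None

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.taxa

    def __len__(self) -> int:
        return len(self.taxa)

    def __iter__(self):
        return iter(self.taxa.values())


_REQUIRED_COLUMNS = (
    "taxon_id",
    "fauna_class",
    "frac_animal",
    "frac_plant",
    "frac_microbe",
    "frac_detritus",
    "agility",
    "defended",
    "stratum",
    "metab_ln_x0",
    "metab_a",
    "metab_E",
)
_OPTIONAL_COLUMNS = ("lenmass_form", "lm_a", "lm_b", "lm_c", "fixed_body_mass")


def _row_to_traits(row: pd.Series) -> TaxonTraits:
    form = row.get("lenmass_form")
    lenmass = None
    if isinstance(form, str) and form and form != "none":
        lenmass = LengthMassModel(
            form=form,
            a=float(row["lm_a"]),
            b=float(row["lm_b"]),
            c=float(row.get("lm_c", float("nan"))),
        )
    fixed = row.get("fixed_body_mass")
    fixed = None if fixed is None or pd.isna(fixed) else float(fixed)
    return TaxonTraits(
        taxon_id=str(row["taxon_id"]),
        fauna_class=str(row["fauna_class"]),
        basal_fractions={
            "animal": float(row["frac_animal"]),
            "plant": float(row["frac_plant"]),
            "microbe": float(row["frac_microbe"]),
            "detritus": float(row["frac_detritus"]),
        },
        agility=float(row["agility"]),
        defended=bool(row["defended"]),
        stratum=str(row["stratum"]),
        metab_coeffs=(
            float(row["metab_ln_x0"]),
            float(row["metab_a"]),
            float(row["metab_E"]),
        ),
        lenmass=lenmass,
        fixed_body_mass=fixed,
    )


def load_trait_table(
    path: str | Path, resources: Iterable[ResourceNode] | None = None
) -> TraitTable:
    """Read and validate a taxon trait table from CSV.

    Raises :class:`TraitError` naming the missing column, duplicated
    taxon or out-of-range value; never returns a partial table.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TraitError(f"trait table missing column(s): {', '.join(missing)}")
    dupes = df["taxon_id"][df["taxon_id"].duplicated()].tolist()
    if dupes:
        raise TraitError(f"duplicated taxon_id(s): {', '.join(map(str, dupes))}")
    taxa: dict[str, TaxonTraits] = {}
    for _, row in df.iterrows():
        t = _row_to_traits(row)
        taxa[t.taxon_id] = t
    res = list(resources) if resources is not None else default_resource_nodes()
    return TraitTable(taxa=taxa, resources=res)


def write_trait_table(table: TraitTable, path: str | Path) -> None:
    """Write a trait table to CSV; inverse of :func:`load_trait_table`."""
    rows = []
    for t in table:
        lm = t.lenmass
        rows.append(
            {
                "taxon_id": t.taxon_id,
                "fauna_class": t.fauna_class,
                "frac_animal": t.basal_fractions["animal"],
                "frac_plant": t.basal_fractions["plant"],
                "frac_microbe": t.basal_fractions["microbe"],
                "frac_detritus": t.basal_fractions["detritus"],
                "agility": t.agility,
                "defended": t.defended,
                "stratum": t.stratum,
                "metab_ln_x0": t.metab_coeffs[0],
                "metab_a": t.metab_coeffs[1],
                "metab_E": t.metab_coeffs[2],
                "lenmass_form": lm.form if lm else "none",
                "lm_a": lm.a if lm else float("nan"),
                "lm_b": lm.b if lm else float("nan"),
                "lm_c": lm.c if lm else float("nan"),
                "fixed_body_mass": (
                    t.fixed_body_mass if t.fixed_body_mass is not None else float("nan")
                ),
            }
        )
    # %.17g keeps float64 values exactly round-trippable
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def load_resource_nodes(path: str | Path) -> list[ResourceNode]:
    """Read basal resource nodes from CSV (node_id, resource_type[, pool_biomass])."""
    df = pd.read_csv(path)
    for col in ("node_id", "resource_type"):
        if col not in df.columns:
            raise TraitError(f"resource table missing column: {col}")
    out = []
    for _, row in df.iterrows():
        biomass = float(row["pool_biomass"]) if "pool_biomass" in df.columns else 1.0
        out.append(ResourceNode(str(row["node_id"]), str(row["resource_type"]), biomass))
    return out


def validate_against_samples(
    traits: TraitTable, sample_taxa: Iterable[str]
) -> list[str]:
    """Sample taxa absent from the trait table (empty list = consistent)."""
    seen: list[str] = []
    for tid in sample_taxa:
        if tid not in traits and tid not in seen:
            seen.append(tid)
    return seen
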