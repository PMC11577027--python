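"""Synthetic mesocosm experiments with known treatment effects.

Generates complete experiments in the raw-sample format the rest of the
pipeline reads: a nested design (6 blocks x 4 EcoUnits each, 4
mesocosms per EcoUnit crossing soil history x plant history, plant
richness 1/2/3/6 per EcoUnit; 96 mesocosms in total), a ~30-taxon
trait table spanning nematodes, mesofauna and macrofauna with realistic
body-mass ranges (1e-4 to 1e2 mg), and per-mesocosm sample records
(counts per sampler core, individual length measurements).

Treatment effects are imposed exactly, so downstream estimators can be
validated against known truth:

* Soil history multiplies community biomass by
  ``soil_history_biomass_multiplier`` and the community-weighted mean
  body mass by ``soil_history_bodymass_multiplier``. The body-mass
  effect is a compositional shift — abundances are tilted toward
  smaller-bodied taxa within each fauna class, never by shrinking
  individuals of a taxon — with the tilt strength solved numerically so
  the expected CWM shift matches the multiplier, and a global abundance
  rescaling restores the biomass target exactly.
* Plant history and plant richness have neutral defaults.

Noise is multiplicative lognormal on per-taxon abundances (mean-one,
configurable cv), with block- and EcoUnit-level random intercepts on
the log scale so the nested bootstrap has true hierarchy to recover,
plus Poisson sampling of core counts and lognormal within-taxon
body-size variation among measured individuals.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import logsumexp

from .community import (
    CoreSpec,
    MESOCOSM_DIAMETER_CM,
    default_core_specs,
    format_measurements,
)
from .traits import LengthMassModel, TaxonTraits, TraitTable, default_resource_nodes

__all__ = [
    "HISTORY_LEVELS",
    "RICHNESS_LEVELS",
    "EffectConfig",
    "SyntheticExperiment",
    "generate_design",
    "default_taxon_pool",
    "generate_samples",
    "generate_experiment",
    "write_experiment",
    "read_experiment",
]

#: The four community-history treatments: soil history x plant history.
HISTORY_LEVELS = ("S-P-", "S-P+", "S+P-", "S+P+")
RICHNESS_LEVELS = (1, 2, 3, 6)

N_BLOCKS = 6
ECOUNITS_PER_BLOCK = 4


@dataclass(frozen=True)
class EffectConfig:
    """Imposed treatment effects and noise levels of the generator.

    Multipliers act on the natural scale: the defaults impose a
    log-scale biomass effect of +0.41 and a log-scale CWM body-mass
    effect of -0.64 with soil history, a neutral plant-history effect
    and no richness slope. ``noise_cv`` is the lognormal coefficient of
    variation of per-taxon, per-mesocosm abundances; ``block_sd`` and
    ``ecounit_sd`` are log-scale random-intercept standard deviations.
    """

    soil_history_biomass_multiplier: float = math.exp(0.41)
    soil_history_bodymass_multiplier: float = math.exp(-0.64)
    plant_history_multiplier: float = 1.0
    richness_slope: float = 0.0
    n_taxa: int | None = None
    abundance_dispersion: float = 0.6
    noise_cv: float = 0.3
    block_sd: float = 0.1
    ecounit_sd: float = 0.15
    mass_cv: float = 0.2
    max_measured: int = 10

    def __post_init__(self) -> None:
        for name in (
            "soil_history_biomass_multiplier",
            "soil_history_bodymass_multiplier",
            "plant_history_multiplier",
        ):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        if self.abundance_dispersion < 0 or self.noise_cv < 0 or self.mass_cv < 0:
            raise ValueError("dispersion and cv parameters must be >= 0")

    @classmethod
    def neutral(cls, **overrides) -> "EffectConfig":
        """A null generator: no treatment effects at all."""
        defaults = dict(
            soil_history_biomass_multiplier=1.0,
            soil_history_bodymass_multiplier=1.0,
            plant_history_multiplier=1.0,
            richness_slope=0.0,
        )
        defaults.update(overrides)
        return cls(**defaults)


def generate_design(seed: int = 0) -> pd.DataFrame:
    """The fully-labeled nested design: 96 mesocosm rows.

    Each of 6 blocks holds 4 EcoUnits; each EcoUnit holds one mesocosm
    of every soil x plant history combination and is assigned one plant
    richness level from {1, 2, 3, 6} (shuffled within block).
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    eco_counter = 0
    for b in range(N_BLOCKS):
        richness = rng.permutation(RICHNESS_LEVELS)
        for e in range(ECOUNITS_PER_BLOCK):
            eco_counter += 1
            for hist in HISTORY_LEVELS:
                rows.append(
                    {
                        "block": f"B{b + 1}",
                        "ecounit": f"E{eco_counter:02d}",
                        "mesocosm_id": f"E{eco_counter:02d}-{hist}",
                        "history": hist,
                        "soil_history": hist.startswith("S+"),
                        "plant_history": hist.endswith("P+"),
                        "richness": int(richness[e]),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# taxon pool

# (taxon_id, class, (animal, plant, microbe, detritus), agility, defended,
#  stratum, typical mass mg, typical length mm or None, width ratio or None)
_POOL = [
    # nematodes: reference body masses, no individual measurements
    ("Rhabditis", "nematode", (0, 0, 1.0, 0), 0.10, False, "euedaphic", 4.0e-4, None, None),
    ("Acrobeles", "nematode", (0, 0, 1.0, 0), 0.10, False, "euedaphic", 1.5e-4, None, None),
    ("Plectus", "nematode", (0, 0, 1.0, 0), 0.10, False, "euedaphic", 6.0e-4, None, None),
    ("Cephalobus", "nematode", (0, 0, 1.0, 0), 0.10, False, "euedaphic", 2.5e-4, None, None),
    ("Aphelenchus", "nematode", (0, 0, 1.0, 0), 0.10, False, "euedaphic", 2.0e-4, None, None),
    ("Aphelenchoides", "nematode", (0, 0, 1.0, 0), 0.10, False, "euedaphic", 8.0e-5, None, None),
    ("Tylenchus", "nematode", (0, 1.0, 0, 0), 0.10, False, "euedaphic", 1.2e-4, None, None),
    ("Helicotylenchus", "nematode", (0, 1.0, 0, 0), 0.10, False, "euedaphic", 1.0e-3, None, None),
    ("Mononchus", "nematode", (1.0, 0, 0, 0), 0.20, False, "euedaphic", 5.0e-3, None, None),
    ("Eudorylaimus", "nematode", (0.4, 0.3, 0.3, 0), 0.20, False, "euedaphic", 2.0e-3, None, None),
    # mesofauna: length-mass power regressions
    ("Isotomidae", "mesofauna", (0, 0, 0.6, 0.4), 0.70, False, "hemiedaphic", 4.0e-3, 1.0, None),
    ("Entomobryidae", "mesofauna", (0, 0, 0.5, 0.5), 0.90, False, "epigeic", 2.0e-2, 1.8, None),
    ("Hypogastruridae", "mesofauna", (0, 0, 0.7, 0.3), 0.50, False, "hemiedaphic", 3.0e-3, 0.9, None),
    ("Onychiuridae", "mesofauna", (0, 0, 0.6, 0.4), 0.20, False, "euedaphic", 5.0e-3, 1.1, None),
    ("Sminthuridae", "mesofauna", (0, 0.4, 0.4, 0.2), 0.90, False, "epigeic", 1.0e-2, 1.0, None),
    ("Oppiidae", "mesofauna", (0, 0, 0.5, 0.5), 0.10, True, "hemiedaphic", 2.0e-3, 0.5, None),
    ("Galumnidae", "mesofauna", (0, 0, 0.4, 0.6), 0.10, True, "epigeic", 1.0e-2, 0.8, None),
    ("Scheloribatidae", "mesofauna", (0, 0, 0.5, 0.5), 0.10, True, "hemiedaphic", 5.0e-3, 0.6, None),
    ("Gamasina", "mesofauna", (1.0, 0, 0, 0), 0.60, False, "hemiedaphic", 2.0e-2, 0.9, None),
    ("Uropodina", "mesofauna", (0.7, 0, 0, 0.3), 0.30, True, "hemiedaphic", 1.0e-2, 0.7, None),
    ("Enchytraeidae", "mesofauna", (0, 0, 0.3, 0.7), 0.10, False, "euedaphic", 1.0e-1, 5.0, None),
    # macrofauna: power or length-width-mass regressions
    ("Lumbricidae", "macrofauna", (0, 0, 0, 1.0), 0.10, False, "euedaphic", 4.0e1, 50.0, 0.08),
    ("Lithobiidae", "macrofauna", (1.0, 0, 0, 0), 0.80, False, "epigeic", 2.5e1, 12.0, None),
    ("Geophilidae", "macrofauna", (1.0, 0, 0, 0), 0.40, False, "euedaphic", 1.0e1, 20.0, None),
    ("Araneae", "macrofauna", (1.0, 0, 0, 0), 0.90, False, "epigeic", 8.0e0, 4.0, None),
    ("Staphylinidae", "macrofauna", (0.7, 0, 0, 0.3), 0.80, False, "epigeic", 4.0e0, 5.0, None),
    ("Carabidae", "macrofauna", (0.8, 0, 0, 0.2), 0.50, False, "hemiedaphic", 1.5e1, 8.0, None),
    ("Julidae", "macrofauna", (0, 0.2, 0, 0.8), 0.10, True, "epigeic", 4.0e1, 18.0, 0.12),
    ("Isopoda", "macrofauna", (0, 0, 0.1, 0.9), 0.20, True, "epigeic", 2.0e1, 8.0, None),
    ("Elateridae", "macrofauna", (0, 0.7, 0, 0.3), 0.20, False, "hemiedaphic", 1.2e1, 12.0, None),
]

_METAB_BY_CLASS = {
    # (ln x0, allometric exponent, activation energy eV)
    "macrofauna": (22.8, 0.71, 0.69),
    "mesofauna": (23.1, 0.70, 0.69),
    "nematode": (23.0, 0.72, 0.69),
}

#: Baseline expected individuals per mesocosm, per taxon, by class.
_DENSITY_ANCHOR = {"nematode": 2.0e5, "mesofauna": 5.0e3, "macrofauna": 1.0e2}

_LENMASS_EXPONENT = 2.7  # shared allometric exponent of the power regressions


def default_taxon_pool(n_taxa: int | None = None) -> TraitTable:
    """The generator's taxon pool as a ready-to-use trait table.

    ``n_taxa`` keeps only the first n entries (class order preserved);
    the full pool has 30 taxa.
    """
    entries = _POOL if n_taxa is None else _POOL[:n_taxa]
    taxa = {}
    for tid, cls, fracs, agility, defended, stratum, mass, length, wratio in entries:
        lenmass = None
        fixed = None
        if length is None:
            fixed = mass
        elif wratio is None:
            b = _LENMASS_EXPONENT
            lenmass = LengthMassModel("power", a=mass / length**b, b=b)
        else:
            b, c = 2.0, 1.0
            width = wratio * length
            lenmass = LengthMassModel(
                "power_lw", a=mass / (length**b * width**c), b=b, c=c
            )
        taxa[tid] = TaxonTraits(
            taxon_id=tid,
            fauna_class=cls,
            basal_fractions=dict(zip(("animal", "plant", "microbe", "detritus"), fracs)),
            agility=agility,
            defended=defended,
            stratum=stratum,
            metab_coeffs=_METAB_BY_CLASS[cls],
            lenmass=lenmass,
            fixed_body_mass=fixed,
        )
    return TraitTable(taxa=taxa, resources=default_resource_nodes())


# typical masses/lengths by taxon for generation (not part of the trait API)
_TYPICAL = {e[0]: {"class": e[1], "mass": e[6], "length": e[7], "wratio": e[8]} for e in _POOL}


def _cwm_log(lam: np.ndarray, masses: np.ndarray) -> float:
    w = lam / lam.sum()
    return float(np.sum(w * np.log(masses)))


def _solve_tilt(
    lam: np.ndarray, masses: np.ndarray, classes: np.ndarray, target_shift: float
) -> np.ndarray:
    """Abundance multipliers imposing a CWM log-mass shift compositionally.

    Within each fauna class, abundances are exponentially tilted toward
    smaller-bodied taxa (``exp(-beta * (ln m - class mean ln m))``,
    renormalized so each class keeps its total expected abundance); the
    common beta is solved so the abundance-weighted CWM of log body
    mass shifts by exactly ``target_shift`` (negative = smaller). The
    achievable shift is bounded by the smallest taxon of each class; an
    unreachable target raises ``ValueError``.
    """
    if target_shift == 0.0:
        return np.ones_like(lam)
    logm = np.log(masses)
    centred = np.empty_like(logm)
    class_sel = {cls: classes == cls for cls in np.unique(classes)}
    for cls, sel in class_sel.items():
        centred[sel] = logm[sel] - logm[sel].mean()
    base = _cwm_log(lam, masses)

    def tilt(beta: float) -> np.ndarray:
        # log-space, class-share preserving: overflow-safe at any beta
        z = -beta * centred
        out = np.empty_like(z)
        for cls, sel in class_sel.items():
            logw = np.log(lam[sel]) + z[sel]
            norm = logsumexp(logw) - math.log(lam[sel].sum())
            out[sel] = np.exp(z[sel] - norm)
        return out

    def shift(beta: float) -> float:
        return _cwm_log(lam * tilt(beta), masses) - base - target_shift

    # monotone decreasing in beta, saturating at the per-class extremes
    sign = 1.0 if target_shift < 0 else -1.0
    saturation = shift(sign * 1e4)
    if sign * saturation > 0:
        raise ValueError(
            f"CWM shift {target_shift:+.3f} unreachable by compositional "
            f"tilting (achievable limit {saturation + target_shift:+.3f})"
        )
    hi = sign
    for _ in range(40):
        if shift(0.0) * shift(hi) <= 0:
            break
        hi *= 2.0
    beta = brentq(shift, min(0.0, hi), max(0.0, hi), xtol=1e-12)
    return tilt(beta)


@dataclass
class SyntheticExperiment:
    """A generated experiment: design + traits + raw samples + core specs."""

    design: pd.DataFrame
    traits: TraitTable
    samples: pd.DataFrame
    cores: dict[str, CoreSpec] = field(default_factory=default_core_specs)
    config: EffectConfig = field(default_factory=EffectConfig)


def generate_samples(
    design: pd.DataFrame,
    traits: TraitTable,
    effects: EffectConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, dict[str, CoreSpec]]:
    """Draw raw sample records for every mesocosm of a design.

    Emits the long-format table (and sampler core specs) that
    :func:`soilwebflux.community.build_communities` reads. Expected
    per-mesocosm abundances carry the treatment effects, the nested
    random intercepts and lognormal noise; realized core counts are
    Poisson; measured individuals get lognormal body-size variation.
    """
    if effects is None:
        effects = EffectConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cores = default_core_specs()

    taxa = [t.taxon_id for t in traits]
    info = [_TYPICAL[tid] for tid in taxa]
    masses = np.array([i["mass"] for i in info])
    classes = np.array([i["class"] for i in info])
    anchors = np.array([_DENSITY_ANCHOR[c] for c in classes])

    # per-experiment baseline abundances
    lam0 = anchors * rng.lognormal(0.0, effects.abundance_dispersion, size=len(taxa))

    # soil-history effect: compositional tilt (exact CWM shift) plus a
    # global rescaling (exact biomass shift)
    tilt = _solve_tilt(
        lam0, masses, classes, math.log(effects.soil_history_bodymass_multiplier)
    )
    b0 = float(np.sum(lam0 * masses))
    b_tilt = float(np.sum(lam0 * tilt * masses))
    scale = effects.soil_history_biomass_multiplier * b0 / b_tilt
    soil_mult = tilt * scale

    blocks = design["block"].unique()
    ecos = design["ecounit"].unique()
    block_eff = dict(zip(blocks, rng.normal(0.0, effects.block_sd, size=len(blocks))))
    eco_eff = dict(zip(ecos, rng.normal(0.0, effects.ecounit_sd, size=len(ecos))))

    z_rich = (design["richness"] - design["richness"].mean()) / design[
        "richness"
    ].std(ddof=0)
    z_by_meso = dict(zip(design["mesocosm_id"], z_rich))

    sigma = math.sqrt(math.log1p(effects.noise_cv**2))
    meso_area = math.pi * (MESOCOSM_DIAMETER_CM / 2.0) ** 2
    # expected core count per expected mesocosm individual, by class
    nema_core = cores["nema"]
    count_factor = {
        "macrofauna": cores["macro"].total_area_cm2 / meso_area,
        "mesofauna": cores["meso"].total_area_cm2 / meso_area,
        "nematode": (
            nema_core.fresh_soil_mass_g
            * nema_core.dry_fraction
            / (nema_core.dry_soil_density * meso_area * nema_core.depth_cm)
        ),
    }
    sampler_of = {"macrofauna": "macro", "mesofauna": "meso", "nematode": "nema"}

    rows = []
    for rec in design.itertuples(index=False):
        lam = lam0.copy()
        if rec.soil_history:
            lam = lam * soil_mult
        if rec.plant_history:
            lam = lam * effects.plant_history_multiplier
        lam = lam * math.exp(
            effects.richness_slope * z_by_meso[rec.mesocosm_id]
            + block_eff[rec.block]
            + eco_eff[rec.ecounit]
        )
        if sigma > 0:
            lam = lam * rng.lognormal(-0.5 * sigma**2, sigma, size=lam.size)

        for t_i, tid in enumerate(taxa):
            cls = classes[t_i]
            expected = lam[t_i] * count_factor[cls]
            count = int(rng.poisson(expected))
            if count == 0:
                continue
            lengths = widths = ""
            if cls != "nematode":
                k = min(effects.max_measured, count)
                m_typ = masses[t_i]
                if effects.mass_cv > 0:
                    s_m = math.sqrt(math.log1p(effects.mass_cv**2))
                    ind_mass = rng.lognormal(
                        math.log(m_typ) - 0.5 * s_m**2, s_m, size=k
                    )
                else:
                    ind_mass = np.full(k, m_typ)
                lm = traits[tid].lenmass
                if lm.form == "power":
                    L = (ind_mass / lm.a) ** (1.0 / lm.b)
                    lengths = format_measurements(L)
                else:  # power_lw with a fixed width:length ratio
                    r = _TYPICAL[tid]["wratio"]
                    L = (ind_mass / (lm.a * r**lm.c)) ** (1.0 / (lm.b + lm.c))
                    lengths = format_measurements(L)
                    widths = format_measurements(r * L)
            rows.append(
                {
                    "mesocosm_id": rec.mesocosm_id,
                    "taxon_id": tid,
                    "count": count,
                    "lengths": lengths,
                    "widths": widths,
                    "sampler": sampler_of[cls],
                }
            )
    return pd.DataFrame(rows), cores


def generate_experiment(
    seed: int = 0,
    effects: EffectConfig | None = None,
    traits: TraitTable | None = None,
) -> SyntheticExperiment:
    """Design + trait table + raw samples in one seeded call."""
    if effects is None:
        effects = EffectConfig()
    if traits is None:
        traits = default_taxon_pool(effects.n_taxa)
    rng = np.random.default_rng(seed)
    design = generate_design(int(rng.integers(2**31)))
    samples, cores = generate_samples(design, traits, effects, rng)
    return SyntheticExperiment(
        design=design, traits=traits, samples=samples, cores=cores, config=effects
    )


def write_experiment(exp: SyntheticExperiment, directory: str | Path) -> None:
    """Write an experiment to a directory of CSV/JSON files."""
    from .traits import write_trait_table

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    exp.design.to_csv(d / "design.csv", index=False)
    exp.samples.to_csv(d / "samples.csv", index=False)
    write_trait_table(exp.traits, d / "traits.csv")
    cores = {
        name: {k: v for k, v in asdict(spec).items() if v is not None}
        for name, spec in exp.cores.items()
    }
    (d / "cores.json").write_text(json.dumps(cores, indent=2))


def read_experiment(directory: str | Path) -> SyntheticExperiment:
    """Read an experiment directory written by :func:`write_experiment`."""
    from .traits import load_trait_table

    d = Path(directory)
    design = pd.read_csv(d / "design.csv")
    samples = pd.read_csv(
        d / "samples.csv", dtype={"lengths": str, "widths": str}, keep_default_na=False
    )
    traits = load_trait_table(d / "traits.csv")
    cores_raw = json.loads((d / "cores.json").read_text())
    cores = {name: CoreSpec(**kw) for name, kw in cores_raw.items()}
    return SyntheticExperiment(
        design=design, traits=traits, samples=samples, cores=cores
    )
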