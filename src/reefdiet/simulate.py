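"""Synthetic data generator emulating a zone-structured reef survey.

The generator produces every table the downstream analyses consume: fish
morphometrics with otolith ages, a dietary-metabarcoding OTU read table with
taxonomy, benthic photo-quadrat point counts, invertebrate quadrat counts and
fish belt-transect counts. The default configuration mirrors a two-species
study across three habitat zones (outer bay / inner bay / inner bay
disturbed), three reefs per zone and 20 fish per reef and species.

Generative model
----------------
* ages: integer uniform on a species age range;
* lengths: zone-specific von Bertalanffy prediction at age plus Gaussian noise;
* weights: allometric ``W = a L^b exp(eps)`` with zone-specific lognormal noise;
* diets: per-fish composition from a species-by-zone Dirichlet, read depth
  lognormal, reads multinomial (a Dirichlet-multinomial read table);
* benthos: 100 annotation points per photo quadrat, multinomial over benthic
  categories with reef-level coral cover drawn around the zone mean;
* invertebrates: Poisson counts per taxon per 0.25 m**2 quadrat;
* fish transects: Poisson counts per 100 m**2 belt transect.

All randomness flows from a single seed through named substreams
(:func:`reefdiet._rng.substream`), so each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .growth import VBGFParams, vbgf_predict

__all__ = [
    "SpeciesSpec",
    "SimConfig",
    "SyntheticDataset",
    "default_config",
    "simulate_fish",
    "simulate_diet_reads",
    "simulate_surveys",
    "simulate_dataset",
    "DEFAULT_TAXONOMY",
    "DEFAULT_HABITS",
]

ZONES = ("outer_bay", "inner_bay", "inner_bay_disturbed")

# OTU lineages (phylum..genus) for the default prey pool. One OTU per genus-level
# taxon keeps the table small while exercising aggregation at every rank.
DEFAULT_TAXONOMY: dict[str, dict[str, str]] = {
    "Porites": dict(phylum="Cnidaria", class_="Anthozoa", order="Scleractinia", family="Poritidae", genus="Porites"),
    "Orbicella": dict(phylum="Cnidaria", class_="Anthozoa", order="Scleractinia", family="Merulinidae", genus="Orbicella"),
    "Isophyllia": dict(phylum="Cnidaria", class_="Anthozoa", order="Scleractinia", family="Mussidae", genus="Isophyllia"),
    "Plexaura": dict(phylum="Cnidaria", class_="Anthozoa", order="Alcyonacea", family="Plexauridae", genus="Plexaura"),
    "Gorgonia": dict(phylum="Cnidaria", class_="Anthozoa", order="Alcyonacea", family="Gorgoniidae", genus="Gorgonia"),
    "Aiptasia": dict(phylum="Cnidaria", class_="Anthozoa", order="Actiniaria", family="Aiptasiidae", genus="Aiptasia"),
    "Discosoma": dict(phylum="Cnidaria", class_="Anthozoa", order="Corallimorpharia", family="Discosomatidae", genus="Discosoma"),
    "Cassiopea": dict(phylum="Cnidaria", class_="Scyphozoa", order="Rhizostomeae", family="Cassiopeidae", genus="Cassiopea"),
    "Loimia": dict(phylum="Annelida", class_="Polychaeta", order="Terebellida", family="Terebellidae", genus="Loimia"),
    "Terebella": dict(phylum="Annelida", class_="Polychaeta", order="Terebellida", family="Terebellidae", genus="Terebella"),
    "Polydora": dict(phylum="Annelida", class_="Polychaeta", order="Spionida", family="Spionidae", genus="Polydora"),
    "Mithraculus": dict(phylum="Arthropoda", class_="Malacostraca", order="Decapoda", family="Mithracidae", genus="Mithraculus"),
    "Panoplax": dict(phylum="Arthropoda", class_="Malacostraca", order="Decapoda", family="Pseudorhombilidae", genus="Panoplax"),
    "Synalpheus": dict(phylum="Arthropoda", class_="Malacostraca", order="Decapoda", family="Alpheidae", genus="Synalpheus"),
    "Sicyonia": dict(phylum="Arthropoda", class_="Malacostraca", order="Decapoda", family="Sicyoniidae", genus="Sicyonia"),
    "Pseudosquilla": dict(phylum="Arthropoda", class_="Malacostraca", order="Stomatopoda", family="Pseudosquillidae", genus="Pseudosquilla"),
    "Neogonodactylus": dict(phylum="Arthropoda", class_="Malacostraca", order="Stomatopoda", family="Gonodactylidae", genus="Neogonodactylus"),
    "Leptochelia": dict(phylum="Arthropoda", class_="Malacostraca", order="Tanaidacea", family="Leptocheliidae", genus="Leptochelia"),
    "Temora": dict(phylum="Arthropoda", class_="Copepoda", order="Calanoida", family="Temoridae", genus="Temora"),
    "Paracalanus": dict(phylum="Arthropoda", class_="Copepoda", order="Calanoida", family="Paracalanidae", genus="Paracalanus"),
    "Coryphopterus": dict(phylum="Chordata", class_="Actinopterygii", order="Gobiiformes", family="Gobiidae", genus="Coryphopterus"),
    "Emblemariopsis": dict(phylum="Chordata", class_="Actinopterygii", order="Blenniiformes", family="Chaenopsidae", genus="Emblemariopsis"),
    "Ophiothrix": dict(phylum="Echinodermata", class_="Ophiuroidea", order="Amphilepidida", family="Ophiotrichidae", genus="Ophiothrix"),
    "Cerithium": dict(phylum="Mollusca", class_="Gastropoda", order="Caenogastropoda", family="Cerithiidae", genus="Cerithium"),
}

# Benthic-habit lookup for arthropod prey (planktonic vs benthic crustaceans).
DEFAULT_HABITS: dict[str, str] = {
    "Temora": "planktonic",
    "Paracalanus": "planktonic",
    "Mithraculus": "benthic",
    "Leptochelia": "benthic",
    "Pseudosquilla": "benthic",
    "Sicyonia": "benthic",
    "Panoplax": "benthic",
    "Synalpheus": "benthic",
    "Neogonodactylus": "benthic",
}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates an invariant."""


@dataclass
class SpeciesSpec:
    """Generating parameters for one species.

    Attributes
    ----------
    name : str
        Species label used in the fish table.
    a, b : float
        Allometric weight-length coefficients (W = a L^b, g and mm).
    weight_sigma : mapping zone -> float
        SD of the lognormal weight noise, per zone (dimensionless, log scale).
    vbgf : mapping zone -> VBGFParams
        Zone-specific growth parameters generating mean length at age.
    age_range : (int, int)
        Inclusive integer age range in years.
    length_sigma : float
        SD (mm) of Gaussian length noise around the growth curve.
    diet : mapping zone -> mapping taxon -> float
        Dirichlet concentration vector over prey taxa, per zone.
    depth_meanlog, depth_sdlog : float
        Lognormal read-depth parameters (median = exp(depth_meanlog)).
    """

    name: str
    a: float
    b: float
    weight_sigma: Mapping[str, float]
    vbgf: Mapping[str, VBGFParams]
    age_range: tuple[int, int]
    length_sigma: float
    diet: Mapping[str, Mapping[str, float]]
    depth_meanlog: float
    depth_sdlog: float

    def validate(self, zones: Sequence[str]) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ConfigurationError(f"{self.name}: allometric a and b must be > 0")
        for z in zones:
            if self.weight_sigma[z] < 0:
                raise ConfigurationError(f"{self.name}/{z}: weight sigma must be >= 0")
        if self.length_sigma < 0:
            raise ConfigurationError(f"{self.name}: length sigma must be >= 0")
        taxa0 = tuple(self.diet[zones[0]])
        for z in zones:
            if tuple(self.diet[z]) != taxa0:
                raise ConfigurationError(
                    f"{self.name}: prey taxa differ between zones {zones[0]} and {z}"
                )
            if any(v <= 0 for v in self.diet[z].values()):
                raise ConfigurationError(
                    f"{self.name}/{z}: Dirichlet concentrations must be strictly positive"
                )


@dataclass
class SimConfig:
    """Full description of a synthetic study.

    Defaults (via :func:`default_config`) follow the emulated design: 3 zones,
    3 reefs per zone, 20 fish per reef per species, zone-mean live coral
    covers near 33.46 / 12.06 / 0.34 %, and lognormal read depths with
    species medians near 25,000 and 6,000 reads.
    """

    seed: int = 0
    zones: tuple[str, ...] = ZONES
    reefs_per_zone: int = 3
    fish_per_reef_per_species: int = 20
    species: tuple[SpeciesSpec, ...] = ()
    coral_cover: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "outer_bay": (33.46, 3.41),
            "inner_bay": (12.06, 2.3),
            "inner_bay_disturbed": (0.34, 0.39),
        }
    )
    quadrats_per_transect: int = 10
    transects_per_reef: int = 3
    points_per_quadrat: int = 100
    invert_quadrats_per_reef: int = 3
    quadrat_area_m2: float = 0.25
    transect_area_m2: float = 100.0

    def validate(self) -> None:
        if self.reefs_per_zone < 1 or len(self.zones) < 1:
            raise ConfigurationError("zone and reef counts must be >= 1")
        if self.fish_per_reef_per_species < 1:
            raise ConfigurationError("fish_per_reef_per_species must be >= 1")
        if not self.species:
            raise ConfigurationError("at least one species spec required")
        for sp in self.species:
            sp.validate(self.zones)
        for z in self.zones:
            mean, sd = self.coral_cover[z]
            if not (0 <= mean <= 100) or sd < 0:
                raise ConfigurationError(f"coral cover spec invalid for zone {z}")

    def reef_names(self) -> dict[str, list[str]]:
        return {
            z: [f"{z}_R{i + 1}" for i in range(self.reefs_per_zone)] for z in self.zones
        }


def _mix(base: Mapping[str, float], weights: Mapping[str, float], conc: float) -> dict[str, float]:
    """Dirichlet concentration vector: `conc` times a normalized profile, with a
    small floor so every taxon stays strictly positive."""
    total = sum(weights.values())
    return {t: conc * (weights.get(t, 0.0) / total) + 0.05 for t in base}


def default_config(seed: int = 0) -> SimConfig:
    """The emulated study design: a browsing corallivore whose diet shifts from
    anthozoan- to annelid-dominated along the degradation gradient, and an
    active predator shifting from benthic macrocrustaceans to planktonic
    copepods, with growth parameters per zone."""
    taxa = {t: 0.0 for t in DEFAULT_TAXONOMY}
    conc = 25.0

    browser_profiles = {
        "outer_bay": _mix(taxa, {
            "Porites": 0.45, "Orbicella": 0.05, "Plexaura": 0.10, "Gorgonia": 0.08,
            "Aiptasia": 0.04, "Discosoma": 0.03, "Loimia": 0.08, "Terebella": 0.04,
            "Polydora": 0.03, "Ophiothrix": 0.04, "Cerithium": 0.03, "Temora": 0.03,
        }, conc),
        "inner_bay": _mix(taxa, {
            "Porites": 0.30, "Aiptasia": 0.15, "Isophyllia": 0.05, "Loimia": 0.25,
            "Terebella": 0.08, "Polydora": 0.05, "Ophiothrix": 0.05, "Cerithium": 0.04,
            "Temora": 0.03,
        }, conc),
        "inner_bay_disturbed": _mix(taxa, {
            "Loimia": 0.55, "Terebella": 0.10, "Polydora": 0.05, "Aiptasia": 0.08,
            "Isophyllia": 0.06, "Cassiopea": 0.05, "Discosoma": 0.04, "Porites": 0.03,
            "Ophiothrix": 0.02, "Cerithium": 0.02,
        }, conc),
    }
    predator_profiles = {
        "outer_bay": _mix(taxa, {
            "Mithraculus": 0.35, "Leptochelia": 0.12, "Pseudosquilla": 0.08,
            "Sicyonia": 0.05, "Panoplax": 0.04, "Synalpheus": 0.04,
            "Neogonodactylus": 0.03, "Temora": 0.05, "Paracalanus": 0.03,
            "Coryphopterus": 0.12, "Emblemariopsis": 0.06, "Cerithium": 0.03,
        }, conc),
        "inner_bay": _mix(taxa, {
            "Temora": 0.35, "Paracalanus": 0.10, "Mithraculus": 0.10,
            "Leptochelia": 0.07, "Synalpheus": 0.05, "Panoplax": 0.04,
            "Coryphopterus": 0.15, "Emblemariopsis": 0.08, "Cerithium": 0.06,
        }, conc),
        "inner_bay_disturbed": _mix(taxa, {
            "Temora": 0.40, "Paracalanus": 0.12, "Mithraculus": 0.06,
            "Leptochelia": 0.06, "Synalpheus": 0.04, "Panoplax": 0.03,
            "Coryphopterus": 0.16, "Emblemariopsis": 0.08, "Cerithium": 0.05,
        }, conc),
    }

    browser = SpeciesSpec(
        name="C_capistratus",
        a=3.5e-5, b=3.0,
        # disturbed-zone inflation gives a designed ~4-fold condition variance
        weight_sigma={"outer_bay": 0.06, "inner_bay": 0.05, "inner_bay_disturbed": 0.10},
        vbgf={
            "inner_bay": VBGFParams(110.47, 0.19, -2.0),
            "inner_bay_disturbed": VBGFParams(102.27, 0.17, -2.0),
            "outer_bay": VBGFParams(97.86, 0.23, -2.0),
        },
        age_range=(3, 9),
        length_sigma=3.0,
        diet=browser_profiles,
        depth_meanlog=float(np.log(25_000.0)),
        depth_sdlog=0.5,
    )
    predator = SpeciesSpec(
        name="H_puella",
        a=1.9e-5, b=3.0,
        weight_sigma={"outer_bay": 0.05, "inner_bay": 0.05, "inner_bay_disturbed": 0.05},
        vbgf={
            "inner_bay": VBGFParams(125.23, 0.19, -2.0),
            "inner_bay_disturbed": VBGFParams(102.04, 0.36, -2.0),
            "outer_bay": VBGFParams(100.28, 0.30, -2.0),
        },
        age_range=(3, 8),
        length_sigma=3.0,
        diet=predator_profiles,
        depth_meanlog=float(np.log(6_000.0)),
        depth_sdlog=0.5,
    )
    return SimConfig(seed=seed, species=(browser, predator))


@dataclass
class SyntheticDataset:
    """All generated tables plus an immutable echo of the generating truth."""

    fish: pd.DataFrame
    otu: pd.DataFrame
    taxonomy: pd.DataFrame
    benthic: pd.DataFrame
    invertebrates: pd.DataFrame
    fish_transects: pd.DataFrame
    truth: dict

    def __post_init__(self):
        missing = set(self.otu.index) - set(self.fish["id"])
        if missing:
            raise ConfigurationError(f"OTU samples without fish records: {sorted(missing)[:5]}")


def simulate_fish(config: SimConfig) -> pd.DataFrame:
    """Simulate the fish metadata table.

    Per fish: integer age uniform on the species range, length from the
    zone-specific growth curve plus Gaussian noise, and weight
    ``a L^b exp(eps)`` with eps ~ N(0, sigma_z^2). Deterministic per seed.
    """
    config.validate()
    rng = substream(config.seed, "fish")
    reefs = config.reef_names()
    rows = []
    for sp in config.species:
        lo, hi = sp.age_range
        for zone in config.zones:
            for reef in reefs[zone]:
                for i in range(config.fish_per_reef_per_species):
                    age = int(rng.integers(lo, hi + 1))
                    mean_len = vbgf_predict(sp.vbgf[zone], age)
                    length = max(1.0, mean_len + rng.normal(0.0, sp.length_sigma)
                                 if sp.length_sigma > 0 else mean_len)
                    eps = rng.normal(0.0, sp.weight_sigma[zone]) if sp.weight_sigma[zone] > 0 else 0.0
                    weight = sp.a * length ** sp.b * np.exp(eps)
                    rows.append({
                        "id": f"{sp.name}_{reef}_{i + 1:03d}",
                        "species": sp.name,
                        "zone": zone,
                        "reef": reef,
                        "length_mm": length,
                        "weight_g": weight,
                        "age_yr": age,
                    })
    return pd.DataFrame(rows)


def simulate_diet_reads(
    config: SimConfig, fish: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the OTU read table (samples x OTUs) and its taxonomy table.

    Per fish: a composition from the species-by-zone Dirichlet, a lognormal
    read depth (rounded, floor 100) and a multinomial read vector.
    """
    config.validate()
    rng = substream(config.seed, "diet")
    specs = {sp.name: sp for sp in config.species}
    taxa = list(next(iter(config.species)).diet[config.zones[0]])
    for sp in config.species:
        if list(sp.diet[config.zones[0]]) != taxa:
            raise ConfigurationError("prey taxa lists inconsistent between species specs")
    otu_ids = [f"OTU_{i + 1:03d}" for i in range(len(taxa))]
    counts = np.zeros((len(fish), len(taxa)), dtype=np.int64)
    for row_i, rec in enumerate(fish.itertuples(index=False)):
        sp = specs[rec.species]
        alpha = np.array([sp.diet[rec.zone][t] for t in taxa])
        comp = rng.dirichlet(alpha)
        depth = max(100, int(round(rng.lognormal(sp.depth_meanlog, sp.depth_sdlog))))
        counts[row_i] = rng.multinomial(depth, comp)
    otu = pd.DataFrame(counts, index=pd.Index(fish["id"], name="sample"), columns=otu_ids)
    tax_rows = []
    for oid, taxon in zip(otu_ids, taxa):
        lin = DEFAULT_TAXONOMY.get(taxon, {})
        tax_rows.append({
            "otu_id": oid,
            "phylum": lin.get("phylum", "unassigned"),
            "class": lin.get("class_", "unassigned"),
            "order": lin.get("order", "unassigned"),
            "family": lin.get("family", "unassigned"),
            "genus": lin.get("genus", taxon),
        })
    taxonomy = pd.DataFrame(tax_rows).set_index("otu_id")
    return otu, taxonomy


_BENTHIC_OTHER = ("soft_coral", "macroalgae", "sponge", "dead_coral", "rubble", "other")
_CORAL_GENERA = ("coral_Porites", "coral_Agaricia", "coral_Siderastrea")
# zone-specific evenness of the coral assemblage (drives the diversity gradient)
_CORAL_SPLIT = {
    "outer_bay": (0.45, 0.35, 0.20),
    "inner_bay": (0.70, 0.20, 0.10),
    "inner_bay_disturbed": (0.90, 0.07, 0.03),
}
_OTHER_SPLIT = {
    "outer_bay": (0.25, 0.30, 0.10, 0.10, 0.15, 0.10),
    "inner_bay": (0.15, 0.30, 0.15, 0.15, 0.15, 0.10),
    "inner_bay_disturbed": (0.05, 0.25, 0.25, 0.25, 0.12, 0.08),
}
_INVERT_TAXA = ("Mithraculus", "Leptochelia", "Synalpheus", "Terebellidae", "Ophiuroidea", "Gastropoda")
_INVERT_RATES = {
    "outer_bay": (6.0, 8.0, 3.0, 2.0, 4.0, 3.0),
    "inner_bay": (4.0, 6.0, 2.5, 3.0, 3.0, 3.0),
    "inner_bay_disturbed": (1.5, 4.0, 1.5, 4.0, 2.0, 2.5),
}
# belt-transect mean counts per species per 100 m^2 (density peaks inner bay)
_FISH_RATES = {
    "outer_bay": (6.0, 2.0),
    "inner_bay": (8.0, 4.0),
    "inner_bay_disturbed": (6.5, 3.0),
}


def simulate_surveys(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate benthic photo-quadrat, invertebrate quadrat and fish belt
    transect tables.

    Benthic quadrats annotate ``points_per_quadrat`` points multinomially; the
    expected live-coral fraction is drawn per reef around the zone mean, so
    reefs vary realistically within zones.
    """
    config.validate()
    rng = substream(config.seed, "surveys")
    reefs = config.reef_names()
    fallback = _OTHER_SPLIT["inner_bay"]
    b_rows, i_rows, f_rows = [], [], []
    for zone in config.zones:
        mean, sd = config.coral_cover[zone]
        c_split = np.array(_CORAL_SPLIT.get(zone, (0.6, 0.25, 0.15)))
        o_split = np.array(_OTHER_SPLIT.get(zone, fallback))
        for reef in reefs[zone]:
            reef_cover = float(np.clip(rng.normal(mean, sd), 0.0, 100.0)) / 100.0
            probs = np.concatenate([reef_cover * c_split, (1 - reef_cover) * o_split])
            probs = probs / probs.sum()
            for t in range(1, config.transects_per_reef + 1):
                for q in range(1, config.quadrats_per_transect + 1):
                    pts = rng.multinomial(config.points_per_quadrat, probs)
                    row = {"zone": zone, "reef": reef, "transect": t, "quadrat": q}
                    row.update(dict(zip(_CORAL_GENERA + _BENTHIC_OTHER, map(int, pts))))
                    b_rows.append(row)
                f_counts = rng.poisson([r for r in _FISH_RATES.get(zone, (5.0, 3.0))])
                f_rows.append({
                    "zone": zone, "reef": reef, "transect": t,
                    "area_m2": config.transect_area_m2,
                    **{sp.name: int(c) for sp, c in zip(config.species, f_counts)},
                })
            for q in range(1, config.invert_quadrats_per_reef + 1):
                lam = _INVERT_RATES.get(zone, (3.0,) * len(_INVERT_TAXA))
                cts = rng.poisson(lam)
                i_rows.append({
                    "zone": zone, "reef": reef, "quadrat": q,
                    "area_m2": config.quadrat_area_m2,
                    **{t: int(c) for t, c in zip(_INVERT_TAXA, cts)},
                })
    return pd.DataFrame(b_rows), pd.DataFrame(i_rows), pd.DataFrame(f_rows)


def simulate_dataset(config: SimConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """Generate the full synthetic study (all tables plus the truth echo)."""
    if config is None:
        config = default_config(seed if seed is not None else 0)
    elif seed is not None:
        raise ValueError("pass either a config or a seed, not both")
    fish = simulate_fish(config)
    otu, taxonomy = simulate_diet_reads(config, fish)
    benthic, inverts, transects = simulate_surveys(config)
    truth = asdict(config)
    return SyntheticDataset(fish, otu, taxonomy, benthic, inverts, transects, truth)
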