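"""Species traits: the specialization register and the functional trait matrix.

Two complementary views of ecological specialization are kept side by side:

1. A coarse rule-based *specialization register* scoring three niche
   dimensions — larval food breadth, northern distributional limit in Europe,
   and habitat breadth — each from 1 (most specialized) to 4 (least
   specialized). The per-species total is the sum over the three dimensions,
   so it ranges from 3 (extreme specialist) to 12 (extreme generalist).

2. A 12-trait mixed-type functional matrix (quantitative, ordinal, binary and
   categorical columns) feeding Gower dissimilarity and functional dispersion
   in :mod:`mothdrift.funcdiv`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# specialization register
# --------------------------------------------------------------------------

HOST_BREADTH_CATEGORIES = (
    "monophagous_genus",           # monophagous within one plant genus
    "oligophagous_family",         # oligophagous within one plant family
    "polyphagous_gt1_family",      # polyphagous: more than one plant family
    "highly_polyphagous_gt5_families",  # highly polyphagous: >5 plant families
)

_FOOD_SCORE = {cat: i + 1 for i, cat in enumerate(HOST_BREADTH_CATEGORIES)}

#: Northern-limit bands (degrees N, inclusive) and their register scores.
NORTHERN_LIMIT_BANDS = (
    (43, 46, 1),  # range limit south of the Alps
    (47, 50, 2),  # range limit around the German highlands
    (51, 54, 3),  # range limit at the North or Baltic sea coast
    (55, 71, 4),  # range limit further north
)


def score_food_specialization(host_breadth: str) -> int:
    """Register score (1-4) for larval food breadth."""
    try:
        return _FOOD_SCORE[host_breadth]
    except KeyError:
        raise ValueError(
            f"unknown host-breadth category {host_breadth!r}; "
            f"expected one of {HOST_BREADTH_CATEGORIES}"
        ) from None


def host_breadth_from_family_count(n_families: int, monophagous_genus: bool = False) -> str:
    """Map a host plant-family count to a register category.

    A species restricted to a single genus is monophagous regardless of the
    count. One family is oligophagous; 2-5 families polyphagous; more than 5
    highly polyphagous.
    """
    if monophagous_genus:
        return "monophagous_genus"
    if n_families < 1:
        raise ValueError("a feeding species uses at least one plant family")
    if n_families == 1:
        return "oligophagous_family"
    if n_families <= 5:
        return "polyphagous_gt1_family"
    return "highly_polyphagous_gt5_families"


def score_northern_limit(northern_limit_deg: float) -> int:
    """Register score (1-4) for the northern distribution limit in Europe.

    The register is defined on whole-degree bands, so fractional latitudes
    are rounded to the nearest whole degree first.
    """
    deg = int(round(float(northern_limit_deg)))
    for lo, hi, score in NORTHERN_LIMIT_BANDS:
        if lo <= deg <= hi:
            return score
    raise ValueError(
        f"northern limit {northern_limit_deg}°N outside the register's 43-71°N range"
    )


def score_habitat(
    habitat_types: list[str],
    anthropogenic: bool = False,
    common_habitat: bool = False,
) -> int:
    """Register score (1-4) for habitat breadth.

    1-2 distinct habitat types score 1; 3-4 score 2; 5 or more — or any
    number of "common/nonspecial" habitat types — score 3; numerous and/or
    anthropogenic-influenced habitats (gardens, parks, urban areas) score 4.
    The anthropogenic flag overrides the count.
    """
    if not habitat_types:
        raise ValueError("habitat_types must be non-empty")
    if anthropogenic:
        return 4
    n = len(set(habitat_types))
    if common_habitat or n >= 5:
        return 3
    return 1 if n <= 2 else 2


@dataclass(frozen=True)
class SpecializationScores:
    food: int
    range: int
    habitat: int

    def __post_init__(self) -> None:
        for name, v in (("food", self.food), ("range", self.range), ("habitat", self.habitat)):
            if v not in (1, 2, 3, 4):
                raise ValueError(f"{name} score {v} outside {{1,2,3,4}}")

    @property
    def total(self) -> int:
        return self.food + self.range + self.habitat


def total_specialization(scores: SpecializationScores) -> int:
    """Total specialization: sum of the three dimension scores, in [3, 12]."""
    return scores.total


def score_species(row: pd.Series) -> SpecializationScores:
    """Apply the full register to one trait-table row."""
    habitats = row["habitat_types"]
    if isinstance(habitats, str):
        habitats = [h for h in habitats.split(";") if h]
    return SpecializationScores(
        food=score_food_specialization(row["host_breadth"]),
        range=score_northern_limit(row["northern_limit_deg"]),
        habitat=score_habitat(
            habitats,
            anthropogenic=bool(row.get("anthropogenic_habitat", False)),
            common_habitat=bool(row.get("common_habitat", False)),
        ),
    )


def score_table(trait_table: pd.DataFrame) -> pd.DataFrame:
    """Score every species; returns columns food/range/habitat/total_specialization."""
    recs = []
    for _, row in trait_table.iterrows():
        s = score_species(row)
        recs.append((row["species_id"], s.food, s.range, s.habitat, s.total))
    return pd.DataFrame(
        recs,
        columns=["species_id", "food_score", "range_score", "habitat_score", "total_specialization"],
    )


# --------------------------------------------------------------------------
# 12-trait functional matrix
# --------------------------------------------------------------------------

#: Default label set for the larval food-source block: two non-plant feeding
#: modes plus 15 host plant families common among European macro-moths.
DEFAULT_FOOD_SOURCES = (
    "detritivore",
    "lichen",
    "Fagaceae",
    "Pinaceae",
    "Salicaceae",
    "Betulaceae",
    "Rosaceae",
    "Fabaceae",
    "Poaceae",
    "Asteraceae",
    "Lamiaceae",
    "Brassicaceae",
    "Ranunculaceae",
    "Ericaceae",
    "Oleaceae",
    "Polygonaceae",
    "Amaranthaceae",
)

HABITAT_GUILDS = ("forest", "open", "shrub", "reed")
PHENOLOGY_LEVELS = ("spring", "early_summer", "summer")
HIBERNATION_STAGES = ("egg", "larva", "pupa", "adult")
GROWTH_FORMS = ("woody", "herbaceous", "graminoid", "mixed")

QUANTITATIVE, ORDINAL, BINARY, CATEGORICAL = "quantitative", "ordinal", "binary", "categorical"


@dataclass
class FunctionalMatrix:
    """A typed mixed trait matrix ready for Gower dissimilarity.

    ``values`` holds one column per elementary trait; multi-label blocks
    (the larval food sources) are expanded to one binary column each but
    down-weighted so the block counts as a single trait slot out of 12.
    ``column_types`` maps columns to quantitative/ordinal/binary/categorical;
    ``column_weights`` carries the Gower weights.
    """

    values: pd.DataFrame
    column_types: dict[str, str]
    column_weights: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.column_types)
        if missing:
            raise ValueError(f"columns without a declared type: {sorted(missing)}")

    @property
    def species_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()


def build_functional_matrix(
    trait_table: pd.DataFrame,
    species_order: list[str] | None = None,
    food_sources: tuple[str, ...] = DEFAULT_FOOD_SOURCES,
) -> FunctionalMatrix:
    """Assemble the 12-trait functional matrix from the species trait table.

    The 12 trait slots are: wingspan (quantitative), proboscis (binary),
    larval food source (multi-label binary block over ``food_sources``),
    salt tolerance of hosts (binary), ruderal hosts (binary), host growth
    form (categorical), larval food specialization (ordinal 1-4), habitat
    type (categorical guild), adult phenology (categorical), voltinism
    (ordinal), hibernating stage (categorical) and latitudinal range extent
    (ordinal 1-4).

    Parameters
    ----------
    species_order
        Row order to enforce (typically the incidence matrix's species
        index). Species present there but absent from the trait table raise.
    """
    df = trait_table.set_index("species_id") if "species_id" in trait_table.columns else trait_table
    if species_order is not None:
        absent = [s for s in species_order if s not in df.index]
        if absent:
            raise KeyError(f"species in incidence but absent from trait table: {absent}")
        df = df.loc[list(species_order)]

    cols: dict[str, pd.Series] = {}
    types: dict[str, str] = {}
    weights: dict[str, float] = {}

    def add(name: str, series: pd.Series, kind: str, weight: float = 1.0) -> None:
        cols[name] = series
        types[name] = kind
        weights[name] = weight

    add("wingspan_mm", pd.to_numeric(df["wingspan_mm"]), QUANTITATIVE)
    add("proboscis", df["proboscis"].astype("boolean").astype(object), BINARY)

    # multi-label food-source block: one binary column per label, jointly
    # weighted as one of the 12 trait slots
    listed = df["food_sources"].apply(
        lambda v: set(v.split(";")) if isinstance(v, str) else (set(v) if isinstance(v, (list, set, tuple)) else None)
    )
    w = 1.0 / len(food_sources)
    for label in food_sources:
        add(
            f"food_source::{label}",
            listed.apply(lambda s, label=label: (label in s) if s is not None else np.nan),
            BINARY,
            weight=w,
        )

    add("salt_tolerant_hosts", df["salt_tolerant_hosts"].astype(object), BINARY)
    add("ruderal_hosts", df["ruderal_hosts"].astype(object), BINARY)
    add("host_growth_form", df["host_growth_form"].astype(object), CATEGORICAL)
    add("food_specialization", pd.to_numeric(df["food_specialization"]), ORDINAL)
    add("habitat_type", df["habitat_type"].astype(object), CATEGORICAL)
    add("phenology", df["phenology"].astype(object), CATEGORICAL)
    add("voltinism", pd.to_numeric(df["voltinism"]), ORDINAL)
    add("hibernating_stage", df["hibernating_stage"].astype(object), CATEGORICAL)
    add("range_extent", pd.to_numeric(df["range_extent"]), ORDINAL)

    values = pd.DataFrame(cols, index=df.index)
    n_missing = int(values.isna().sum().sum())
    if n_missing:
        logger.warning("functional matrix has %d missing value(s); Gower uses pairwise deletion", n_missing)
    return FunctionalMatrix(values=values, column_types=types, column_weights=weights)
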