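import numpy as np
import pandas as pd
import pytest

from mothdrift import records
from mothdrift.records import TimeLayer, TimeLayerScheme
from mothdrift.synthetic_data import generate_species_pool


@pytest.fixture
def scheme() -> TimeLayerScheme:
    return records.default_scheme()


@pytest.fixture
def small_pool() -> pd.DataFrame:
    """A deterministic 20-species trait table."""
    return generate_species_pool(n_species=20, seed=123)


@pytest.fixture
def tiny_traits() -> pd.DataFrame:
    """Five hand-written species with known traits and flags."""
    return pd.DataFrame([
        dict(species_id="oak_leafroller", family="Geometridae", wingspan_mm=24.0,
             host_breadth="monophagous_genus", northern_limit_deg=45,
             habitat_types="oak_forest", anthropogenic_habitat=False, common_habitat=False,
             open_habitat=False, early_late_flyer=False, long_distance_migrant=False,
             strictly_diurnal=False, proboscis=True, food_sources="Fagaceae",
             salt_tolerant_hosts=False, ruderal_hosts=False, host_growth_form="woody",
             food_specialization=1, habitat_type="forest", phenology="summer",
             voltinism=1, hibernating_stage="egg", range_extent=1),
        dict(species_id="meadow_generalist", family="Noctuidae", wingspan_mm=38.0,
             host_breadth="highly_polyphagous_gt5_families", northern_limit_deg=60,
             habitat_types="meadow;fallow;heath;hedgerow;forest_edge;marsh",
             anthropogenic_habitat=True, common_habitat=True,
             open_habitat=True, early_late_flyer=False, long_distance_migrant=False,
             strictly_diurnal=False, proboscis=True,
             food_sources="Poaceae;Asteraceae;Lamiaceae;Fabaceae;Rosaceae;Brassicaceae",
             salt_tolerant_hosts=False, ruderal_hosts=True, host_growth_form="herbaceous",
             food_specialization=4, habitat_type="open", phenology="early_summer",
             voltinism=2, hibernating_stage="larva", range_extent=4),
        dict(species_id="reed_borer", family="Noctuidae", wingspan_mm=30.0,
             host_breadth="oligophagous_family", northern_limit_deg=49,
             habitat_types="reed_bed;marsh;wet_meadow", anthropogenic_habitat=False,
             common_habitat=False, open_habitat=False, early_late_flyer=False,
             long_distance_migrant=False, strictly_diurnal=False, proboscis=True,
             food_sources="Poaceae", salt_tolerant_hosts=True, ruderal_hosts=False,
             host_growth_form="graminoid", food_specialization=2, habitat_type="reed",
             phenology="summer", voltinism=1, hibernating_stage="larva", range_extent=2),
        dict(species_id="migrant_hawkmoth", family="Sphingidae", wingspan_mm=90.0,
             host_breadth="polyphagous_gt1_family", northern_limit_deg=68,
             habitat_types="meadow;fallow;hedgerow;forest_edge;scrub_margin",
             anthropogenic_habitat=False, common_habitat=False,
             open_habitat=True, early_late_flyer=False, long_distance_migrant=True,
             strictly_diurnal=False, proboscis=True, food_sources="Oleaceae;Rosaceae",
             salt_tolerant_hosts=False, ruderal_hosts=False, host_growth_form="woody",
             food_specialization=3, habitat_type="open", phenology="summer",
             voltinism=1, hibernating_stage="pupa", range_extent=4),
        dict(species_id="pine_processionary", family="Notodontidae", wingspan_mm=33.0,
             host_breadth="oligophagous_family", northern_limit_deg=46,
             habitat_types="pine_forest;coppice_forest;oak_forest",
             anthropogenic_habitat=False, common_habitat=False,
             open_habitat=False, early_late_flyer=True, long_distance_migrant=False,
             strictly_diurnal=False, proboscis=False, food_sources="Pinaceae",
             salt_tolerant_hosts=False, ruderal_hosts=False, host_growth_form="woody",
             food_specialization=2, habitat_type="forest", phenology="spring",
             voltinism=1, hibernating_stage="larva", range_extent=1),
    ])


@pytest.fixture
def tiny_records() -> pd.DataFrame:
    rows = [
        ("oak_leafroller", 1940, "museum"),
        ("oak_leafroller", 1999, "survey"),
        ("meadow_generalist", 1962, "museum"),
        ("meadow_generalist", 1976, "museum"),
        ("reed_borer", 1997, "survey"),
        ("migrant_hawkmoth", 1980, "museum"),
        ("migrant_hawkmoth", 2011, "survey"),
        ("pine_processionary", 1940, "museum"),
        ("pine_processionary", 1940, "museum"),  # duplicate voucher
    ]
    return pd.DataFrame(rows, columns=["species_id", "year", "source"])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
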