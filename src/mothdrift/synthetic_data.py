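"""Synthetic species pools and occurrence histories for pipeline testing.

The generators emulate the statistical structure the analysis assumes: a
pool of a few hundred macro-moth species with right-skewed wingspans (median
near 33 mm), taxonomic families of uneven size, habitat guilds
(forest/open/shrub/reed), rule-consistent specialization inputs whose totals
pile up near 10, and mixed-type functional traits correlated with guild.
Occupancy evolves as a two-state (present/absent) Markov chain per species
across time layers, modified by scenario:

``neutral``
    trait-independent extinction/colonization — ecological drift;
``size_filter``
    per-layer extinction log-odds increase with log wingspan, so larger
    species accumulate local losses;
``succession``
    open-habitat species' occupancy declines multiplicatively each layer
    while forest colonization rises — the land-abandonment scenario in which
    the community converges on forest dwellers;
``generalization``
    drift dynamics, but species first colonizing in the later half of the
    series carry traits shrunk toward the pool centroid, so the community
    becomes functionally blander without any guild shift.

Observed records are latent presences thinned by an independent detection
probability; historic layers sample record years across their multi-year
windows to mimic museum pooling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .records import TimeLayerScheme, TimeLayer, HISTORIC_PARTITIONS
from .traits import (
    DEFAULT_FOOD_SOURCES,
    GROWTH_FORMS,
    HABITAT_GUILDS,
    HIBERNATION_STAGES,
    PHENOLOGY_LEVELS,
)

logger = logging.getLogger(__name__)

SCENARIOS = ("neutral", "size_filter", "succession", "generalization")

MOTH_FAMILIES = (
    "Noctuidae", "Geometridae", "Erebidae", "Notodontidae", "Sphingidae",
    "Lasiocampidae", "Nolidae", "Drepanidae", "Cossidae", "Hepialidae",
    "Saturniidae", "Limacodidae",
)

GUILD_PROBS = {"forest": 0.45, "open": 0.30, "shrub": 0.15, "reed": 0.10}

#: register-component score distributions; chosen so totals span 3-12 with
#: the mode near 10 (a community dominated by moderate generalists)
FOOD_SCORE_PROBS = (0.08, 0.17, 0.35, 0.40)
RANGE_SCORE_PROBS = (0.05, 0.12, 0.23, 0.60)
HABITAT_SCORE_PROBS = (0.10, 0.20, 0.40, 0.30)

HABITAT_LABEL_POOL = {
    "forest": ["coppice_forest", "pine_forest", "oak_forest", "riparian_forest", "forest_edge"],
    "open": ["xeric_grassland", "meadow", "dune_grassland", "fallow", "heath"],
    "shrub": ["shrubland", "hedgerow", "scrub_margin", "bushy_grassland"],
    "reed": ["reed_bed", "marsh", "wet_meadow"],
}

#: guild-weighted preferences over the larval food-source labels
_PLANT_FAMILIES = [s for s in DEFAULT_FOOD_SOURCES if s not in ("detritivore", "lichen")]
_WOODY = ["Fagaceae", "Pinaceae", "Salicaceae", "Betulaceae", "Rosaceae", "Oleaceae"]
_HERBY = ["Poaceae", "Asteraceae", "Lamiaceae", "Brassicaceae", "Ranunculaceae",
          "Fabaceae", "Polygonaceae", "Amaranthaceae", "Ericaceae"]


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of the drift / filter / succession / generalization generators."""

    scenario: str = "neutral"
    n_species: int = 300
    n_layers: int = 12
    seed: int = 0
    baseline_extinction_prob: float = 0.06
    baseline_colonization_prob: float = 0.06
    #: None starts the chain at its stationary occupancy c/(c+e), so the
    #: neutral scenario is stationary (drift without directional change)
    initial_occupancy: float | None = None
    #: log-odds of per-layer local extinction per unit of centred log wingspan
    size_effect_slope: float = 2.0
    #: per-layer multiplicative decline of open-habitat occupancy (succession)
    open_habitat_decline_rate: float = 0.7
    #: per-layer relative increase of forest colonization (succession)
    forest_colonization_boost: float = 0.15
    #: shrinkage of late colonists' traits toward the pool centroid (generalization)
    trait_shrink_factor: float = 0.5
    detection_prob: float = 0.9

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}")
        if self.n_species < 10:
            raise ValueError("n_species must be >= 10")
        if self.n_layers < 4:
            raise ValueError("n_layers must be >= 4")
        for name in ("baseline_extinction_prob", "baseline_colonization_prob",
                     "initial_occupancy", "open_habitat_decline_rate", "detection_prob"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.trait_shrink_factor <= 1.0:
            raise ValueError("trait_shrink_factor must be in (0, 1]")
        if self.detection_prob == 0:
            raise ValueError("detection_prob must be positive")


@dataclass
class SyntheticCommunity:
    trait_table: pd.DataFrame
    occurrences: pd.DataFrame
    truth: pd.DataFrame          # latent occupancy, species x layer labels
    scheme: TimeLayerScheme
    config: ScenarioConfig


def _choice(rng, options, p=None, size=None):
    return rng.choice(np.asarray(options, dtype=object), size=size, p=p)


def generate_species_pool(
    n_species: int = 300,
    seed: int = 0,
    wingspan_median_mm: float = 33.0,
    wingspan_sigma: float = 0.35,
    p_flagged: float = 0.0,
) -> pd.DataFrame:
    """Draw a species trait table with realistic marginal structure.

    Wingspans are log-normal (right-skewed) with the given median; families
    come from a Dirichlet-multinomial so a few families dominate; habitat
    guilds follow :data:`GUILD_PROBS`; the three specialization components
    are drawn so the raw inputs (host breadth, northern limit, habitat list)
    reproduce the drawn scores exactly under the register; the remaining
    functional traits are correlated with guild. ``p_flagged`` is the
    per-flag probability of each phenological cleaning flag (0 emulates a
    pool already cleaned).
    """
    if n_species < 10:
        raise ValueError("n_species must be >= 10")
    rng = np.random.default_rng(seed)

    wingspan = np.exp(rng.normal(np.log(wingspan_median_mm), wingspan_sigma, n_species))
    fam_probs = rng.dirichlet(np.full(len(MOTH_FAMILIES), 1.2))
    families = _choice(rng, MOTH_FAMILIES, p=fam_probs, size=n_species)
    guilds = _choice(rng, list(GUILD_PROBS), p=list(GUILD_PROBS.values()), size=n_species)

    food_scores = rng.choice([1, 2, 3, 4], p=FOOD_SCORE_PROBS, size=n_species)
    range_scores = rng.choice([1, 2, 3, 4], p=RANGE_SCORE_PROBS, size=n_species)
    habitat_scores = rng.choice([1, 2, 3, 4], p=HABITAT_SCORE_PROBS, size=n_species)

    rows = []
    for i in range(n_species):
        guild = str(guilds[i])
        fs, rs, hs = int(food_scores[i]), int(range_scores[i]), int(habitat_scores[i])

        # --- food: host breadth and the food-source label set
        if fs == 1:
            host_breadth, n_fams = "monophagous_genus", 1
        elif fs == 2:
            host_breadth, n_fams = "oligophagous_family", 1
        elif fs == 3:
            host_breadth, n_fams = "polyphagous_gt1_family", int(rng.integers(2, 6))
        else:
            host_breadth, n_fams = "highly_polyphagous_gt5_families", int(rng.integers(6, 9))
        u = rng.random()
        if u < 0.04:
            food_sources = ["detritivore"]
        elif u < 0.08:
            food_sources = ["lichen"]
        else:
            pref = _WOODY if guild in ("forest", "shrub") else _HERBY
            pool = pref + [f for f in _PLANT_FAMILIES if f not in pref]
            w = np.array([3.0] * len(pref) + [1.0] * (len(pool) - len(pref)))
            w /= w.sum()
            food_sources = list(rng.choice(pool, size=min(n_fams, len(pool)), replace=False, p=w))

        # --- range: northern limit within the drawn band
        lo, hi = {1: (43, 46), 2: (47, 50), 3: (51, 54), 4: (55, 71)}[rs]
        northern = int(rng.integers(lo, hi + 1))

        # --- habitat: list length and qualifiers consistent with the score
        anthropogenic = hs == 4
        common = False
        if hs == 1:
            n_hab = int(rng.integers(1, 3))
        elif hs == 2:
            n_hab = int(rng.integers(3, 5))
        else:
            n_hab = int(rng.integers(5, 8))
        labels = [HABITAT_LABEL_POOL[guild][0]]
        others = [h for g in HABITAT_GUILDS for h in HABITAT_LABEL_POOL[g] if h not in labels]
        extra = rng.choice(others, size=min(n_hab - 1, len(others)), replace=False)
        labels += [str(h) for h in extra]

        growth_probs = {
            "forest": (0.85, 0.08, 0.02, 0.05),
            "open": (0.05, 0.70, 0.20, 0.05),
            "shrub": (0.60, 0.25, 0.05, 0.10),
            "reed": (0.02, 0.15, 0.78, 0.05),
        }[guild]
        rows.append({
            "species_id": f"sp{i:04d}",
            "family": str(families[i]),
            "wingspan_mm": float(wingspan[i]),
            "host_breadth": host_breadth,
            "northern_limit_deg": northern,
            "habitat_types": ";".join(labels),
            "anthropogenic_habitat": anthropogenic,
            "common_habitat": common,
            "open_habitat": guild == "open",
            "early_late_flyer": bool(rng.random() < p_flagged),
            "long_distance_migrant": bool(rng.random() < p_flagged),
            "strictly_diurnal": bool(rng.random() < p_flagged),
            "proboscis": bool(rng.random() < 0.9),
            "food_sources": ";".join(food_sources),
            "salt_tolerant_hosts": bool(rng.random() < {"reed": 0.5, "open": 0.15}.get(guild, 0.03)),
            "ruderal_hosts": bool(rng.random() < (0.4 if guild == "open" else 0.1)),
            "host_growth_form": str(_choice(rng, GROWTH_FORMS, p=growth_probs)),
            "food_specialization": fs,
            "habitat_type": guild,
            "phenology": str(_choice(rng, PHENOLOGY_LEVELS, p=[0.2, 0.35, 0.45])),
            "voltinism": int(rng.choice([1, 2, 3], p=[0.55, 0.35, 0.10])),
            "hibernating_stage": str(_choice(rng, HIBERNATION_STAGES, p=[0.25, 0.35, 0.3, 0.1])),
            "range_extent": rs,
        })
    return pd.DataFrame(rows)


def scheme_for_layers(n_layers: int) -> TimeLayerScheme:
    """Default simulated scheme: the 4 historic partitions plus consecutive
    survey years from 1997 for the remaining layers."""
    layers = [TimeLayer(lbl, a, b) for lbl, a, b in HISTORIC_PARTITIONS[: min(4, n_layers)]]
    n_survey = n_layers - len(layers)
    layers += [TimeLayer(str(1997 + k), 1997 + k, 1997 + k) for k in range(n_survey)]
    return TimeLayerScheme(layers)


def simulate_occurrence_history(pool: pd.DataFrame, config: ScenarioConfig) -> SyntheticCommunity:
    """Run the scenario's occupancy Markov chain and emit occurrence records.

    Latent per-layer presence evolves by per-species extinction and
    colonization probabilities (scenario-modified, see the module docstring);
    observed records are latent presences thinned by ``detection_prob``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 9000]))
    n = len(pool)
    L = config.n_layers
    scheme = scheme_for_layers(L)
    layers = scheme.layers

    logw = np.log(pool["wingspan_mm"].to_numpy(dtype=float))
    is_open = pool["open_habitat"].to_numpy(dtype=bool)
    is_forest = (pool["habitat_type"] == "forest").to_numpy()

    base_e = np.full(n, config.baseline_extinction_prob)
    if config.scenario == "size_filter":
        lo = np.log(base_e / (1 - base_e)) + config.size_effect_slope * (logw - logw.mean())
        base_e = 1.0 / (1.0 + np.exp(-lo))

    p0 = config.initial_occupancy
    if p0 is None:
        e0, c0 = config.baseline_extinction_prob, config.baseline_colonization_prob
        p0 = c0 / (c0 + e0) if (c0 + e0) > 0 else 1.0
    z = np.zeros((n, L), dtype=bool)
    z[:, 0] = rng.random(n) < p0
    for l in range(1, L):
        survive = 1.0 - base_e
        colonize = np.full(n, config.baseline_colonization_prob)
        if config.scenario == "succession":
            decay = config.open_habitat_decline_rate
            survive = np.where(is_open, survive * decay, survive)
            colonize = np.where(is_open, colonize * decay ** l, colonize)
            colonize = np.where(
                is_forest,
                np.minimum(colonize * (1.0 + config.forest_colonization_boost * l), 1.0),
                colonize,
            )
        u = rng.random(n)
        z[:, l] = np.where(z[:, l - 1], u < survive, u < colonize)

    detected = z & (rng.random((n, L)) < config.detection_prob)

    trait_table = pool.copy()
    if config.scenario == "generalization":
        trait_table = _shrink_late_colonists(trait_table, z, detected, config, rng)

    records = []
    for li, layer in enumerate(layers):
        present = np.where(detected[:, li])[0]
        historic = layer.year_min != layer.year_max
        source = "museum" if historic else "survey"
        for s in present:
            year = int(rng.integers(layer.year_min, layer.year_max + 1)) if historic else layer.year_min
            records.append((pool["species_id"].iat[s], year, source))
    occurrences = pd.DataFrame(records, columns=["species_id", "year", "source"])

    truth = pd.DataFrame(z.astype(int), index=pool["species_id"], columns=scheme.labels)
    return SyntheticCommunity(trait_table, occurrences, truth, scheme, config)


def _shrink_late_colonists(
    pool: pd.DataFrame,
    z: np.ndarray,
    detected: np.ndarray,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Pull traits of late-arriving colonists toward the pool centroid.

    Species whose first latent presence falls in the later half of the
    series get quantitative/ordinal traits interpolated toward the pool mean
    by ``trait_shrink_factor`` and categorical traits switched to the modal
    category with probability 1 - trait_shrink_factor.
    """
    L = z.shape[1]
    ever = z.any(axis=1)
    first = np.where(ever, z.argmax(axis=1), L)
    late = ever & (first >= L // 2)
    if not late.any():
        return pool

    out = pool.copy()
    s = config.trait_shrink_factor
    logw = np.log(out["wingspan_mm"].to_numpy(dtype=float))
    out.loc[late, "wingspan_mm"] = np.exp(logw.mean() + s * (logw[late] - logw.mean()))
    for col in ("voltinism", "food_specialization", "range_extent"):
        med = float(out[col].median())
        v = out.loc[late, col].to_numpy(dtype=float)
        out.loc[late, col] = np.rint(med + s * (v - med)).astype(int)
    switch = rng.random(int(late.sum())) > s
    for col in ("host_growth_form", "habitat_type", "phenology", "hibernating_stage"):
        mode = out[col].mode().iat[0]
        vals = out.loc[late, col].to_numpy(dtype=object)
        vals[switch] = mode
        out.loc[late, col] = vals
    out.loc[late, "open_habitat"] = out.loc[late, "habitat_type"] == "open"
    return out


def simulate(config: ScenarioConfig, pool_kwargs: dict | None = None) -> SyntheticCommunity:
    """Generate a pool and its occurrence history in one step."""
    pool = generate_species_pool(config.n_species, seed=config.seed, **(pool_kwargs or {}))
    return simulate_occurrence_history(pool, config)


def scenario_expectation_suite(
    config: ScenarioConfig,
    n_replicates: int = 200,
    seed: int = 0,
    components: tuple[str, ...] = ("wingspan", "fdis"),
    alpha: float = 0.05,
) -> dict:
    """Run the pipeline over many replicates and summarize scenario signatures.

    Per replicate the full chain (incidence, status partition, wingspan
    mixed model, FDis series and its GAM trend) is recomputed on a fresh
    community, and frequencies of the scenario-implied outcomes are
    reported:

    - ``wingspan``: rejection rate of the lost vs previously-unrecorded
      contrast at ``alpha``, and the frequency with which the lost group's
      mean wingspan exceeds the previously-unrecorded group's;
    - ``fdis``: frequency of a negative and significant (at ``alpha``)
      GAM trend of FDis over layers, plus the mean trend coefficient.
    """
    from . import pipeline

    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    ss = np.random.SeedSequence([seed, 77])
    rep_seeds = [int(s) for s in ss.generate_state(n_replicates) >> 1]

    reject = np.zeros(n_replicates, dtype=bool)
    direction = np.zeros(n_replicates, dtype=bool)
    contrast = np.full(n_replicates, np.nan)
    fdis_sig_neg = np.zeros(n_replicates, dtype=bool)
    fdis_sig_pos = np.zeros(n_replicates, dtype=bool)
    fdis_coef = np.full(n_replicates, np.nan)

    for i, s in enumerate(rep_seeds):
        community = simulate(replace(config, seed=s))
        res = pipeline.analyze_community(
            community,
            compute_wingspan_model="wingspan" in components,
            compute_fdis_trend="fdis" in components,
        )
        if "wingspan" in components:
            fit = res["wingspan_status_model"]
            reject[i] = fit.p_value < alpha
            direction[i] = res["group_mean_wingspan"].get("lost", np.nan) > res[
                "group_mean_wingspan"
            ].get("previously_unrecorded", np.nan)
            contrast[i] = fit.coefficient
        if "fdis" in components:
            tf = res["fdis_trend"]
            fdis_sig_neg[i] = (tf.coefficient < 0) and (tf.p_value < alpha)
            fdis_sig_pos[i] = (tf.coefficient > 0) and (tf.p_value < alpha)
            fdis_coef[i] = tf.coefficient

    out: dict = {"scenario": config.scenario, "n_replicates": n_replicates, "alpha": alpha}
    if "wingspan" in components:
        out["wingspan_rejection_rate"] = float(reject.mean())
        out["lost_larger_rate"] = float(direction.mean())
        out["mean_status_contrast"] = float(np.nanmean(contrast))
    if "fdis" in components:
        out["fdis_negative_significant_rate"] = float(fdis_sig_neg.mean())
        out["fdis_positive_significant_rate"] = float(fdis_sig_pos.mean())
        out["mean_fdis_trend_coefficient"] = float(np.nanmean(fdis_coef))
    return out
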