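"""End-to-end orchestration: records -> traits -> funcdiv -> trends -> ordination.

Two entry points are provided: :func:`analyze_community` runs the analysis
chain on an in-memory community (synthetic or assembled from loaded tables)
and returns result objects; :func:`run_pipeline` is the file-based driver
behind the CLI, reading a :class:`RunConfig`, writing CSV/JSON outputs and a
manifest of seeds, options and warnings.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, community_trends, funcdiv, ordination, records, traits
from .synthetic_data import ScenarioConfig, SyntheticCommunity, simulate

logger = logging.getLogger(__name__)

BOOL_COLUMNS = (
    "anthropogenic_habitat", "common_habitat", "open_habitat", "proboscis",
    "salt_tolerant_hosts", "ruderal_hosts",
) + records.CLEANING_FLAGS


def load_trait_table(path) -> pd.DataFrame:
    """Read a species trait table CSV, coercing the boolean columns."""
    df = pd.read_csv(path)
    if "species_id" not in df.columns:
        raise records.SchemaError(f"trait table {path} lacks a species_id column")
    for col in BOOL_COLUMNS:
        if col in df.columns:
            df[col] = df[col].map(
                {True: True, False: False, "True": True, "False": False, 1: True, 0: False}
            ).fillna(False).astype(bool)
    return df


@dataclass
class RunConfig:
    """Configuration of one pipeline run (real data or a synthetic scenario)."""

    out_dir: str = "mothdrift_out"
    occurrences: str | None = None
    traits: str | None = None
    scheme: str | None = None
    scenario: dict | None = None
    cut_year: int = 1997
    gower_correction: str = "sqrt"
    gam_basis_dim: int = 4
    nmds_restarts: int = 50
    nmds_seed: int = 0
    n_permutations: int = 999
    permutation_seed: int = 0
    plot: bool = False

    def __post_init__(self) -> None:
        real = all(p is not None for p in (self.occurrences, self.traits))
        synthetic = self.scenario is not None
        if real == synthetic:
            raise records.SchemaError(
                "exactly one of {occurrences+traits paths, scenario config} must be given"
            )
        if real:
            for p in (self.occurrences, self.traits, self.scheme):
                if p is not None and not Path(p).exists():
                    raise records.SchemaError(f"input file not found: {p}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _community_from_config(cfg: RunConfig) -> SyntheticCommunity:
    if cfg.scenario is not None:
        return simulate(ScenarioConfig(**cfg.scenario))
    occ = records.load_occurrences(cfg.occurrences)
    trait_table = load_trait_table(cfg.traits)
    if cfg.scheme:
        with open(cfg.scheme) as fh:
            scheme = records.scheme_from_dict(yaml.safe_load(fh))
    else:
        scheme = records.default_scheme()
    return SyntheticCommunity(
        trait_table=trait_table,
        occurrences=occ,
        truth=pd.DataFrame(),
        scheme=scheme,
        config=None,  # type: ignore[arg-type]
    )


def analyze_community(
    community: SyntheticCommunity,
    cut_year: int = 1997,
    compute_wingspan_model: bool = True,
    compute_fdis_trend: bool = True,
    compute_specialization: bool = False,
    compute_ordination: bool = False,
    gower_correction: str = "sqrt",
    gam_basis_dim: int = 4,
    nmds_restarts: int = 50,
    nmds_seed: int = 0,
    n_permutations: int = 999,
    permutation_seed: int = 0,
) -> dict:
    """Run the analysis chain on an in-memory community.

    Always computes the incidence matrix and status partition; the heavier
    stages (mixed models, Gower/PCoA/FDis, GAM trends, NMDS + vector fits)
    are switched on individually so simulation studies pay only for what
    they measure.
    """
    occ, removal_log = records.apply_phenological_filter(
        community.occurrences, community.trait_table
    )
    labelled = records.assign_time_layers(occ, community.scheme)
    incidence = records.build_incidence(labelled, community.scheme)
    statuses = records.assign_status(incidence, community.scheme, cut_year)

    trait_table = community.trait_table
    observed = trait_table[trait_table["species_id"].isin(incidence.index)]

    results: dict = {
        "incidence": incidence,
        "statuses": statuses,
        "removal_log": removal_log,
        "status_counts": statuses["status"].value_counts().to_dict(),
    }

    if compute_wingspan_model:
        merged = observed.merge(statuses[["species_id", "status"]], on="species_id")
        results["group_mean_wingspan"] = (
            merged.groupby("status")["wingspan_mm"].mean().to_dict()
        )
        results["wingspan_status_model"] = community_trends.fit_wingspan_status_model(
            observed, statuses
        )

    needs_scores = compute_specialization or compute_ordination
    scores = traits.score_table(observed) if needs_scores else None

    needs_fdis = compute_fdis_trend or compute_ordination
    if needs_fdis:
        fm = traits.build_functional_matrix(trait_table, species_order=list(incidence.index))
        gower = funcdiv.gower_matrix(fm)
        embedding = funcdiv.pcoa_embed(gower, correction=gower_correction)
        fdis_series = funcdiv.fdis_per_layer(embedding, incidence)
        results["fdis_per_layer"] = fdis_series
        results["gower_correction_applied"] = embedding.correction_applied
        midpoints = community.scheme.midpoints()
        fdis_df = pd.DataFrame({
            "layer": fdis_series.index,
            "layer_midpoint_year": [midpoints[l] for l in fdis_series.index],
            "fdis": fdis_series.to_numpy(),
        })
        if compute_fdis_trend:
            results["fdis_trend"] = community_trends.fit_trend_gam(
                fdis_df, "fdis", basis_dim=gam_basis_dim
            )

    if needs_scores:
        series = community_trends.layer_metrics(
            incidence, observed, scores,
            results.get("fdis_per_layer"), community.scheme,
        )
        results["community_timeseries"] = series
        results["scores"] = scores

    if compute_specialization:
        results["specialization_trend"] = community_trends.fit_trend_gam(
            results["community_timeseries"], "mean_total_specialization",
            basis_dim=gam_basis_dim,
        )
        results["wingspan_trend"] = community_trends.fit_trend_gam(
            results["community_timeseries"], "log_mean_wingspan", basis_dim=gam_basis_dim
        )
        results["open_habitat_trend"] = community_trends.fit_trend_gam(
            results["community_timeseries"], "logit_prop_open", basis_dim=gam_basis_dim
        )
        results["specialization_status_model"] = community_trends.fit_specialization_status_model(
            scores, statuses, observed
        )

    if compute_ordination:
        soren = ordination.sorensen_dissimilarity(incidence)
        ord_res = ordination.nmds(
            soren, n_restarts=nmds_restarts, seed=nmds_seed
        )
        series = results["community_timeseries"].set_index("layer")
        descriptors = series.loc[
            list(ord_res.layer_labels),
            ["log_mean_wingspan", "mean_total_specialization", "logit_prop_open"],
        ]
        results["ordination"] = ord_res
        results["vector_fits"] = ordination.permutation_vector_fit(
            ord_res, descriptors, n_permutations=n_permutations, seed=permutation_seed
        )

    return results


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and write outputs + manifest to ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    warnings_log: list[str] = []

    class _Collect(logging.Handler):
        def emit(self, record: logging.LogRecord) -> None:
            if record.levelno >= logging.WARNING:
                warnings_log.append(record.getMessage())

    collector = _Collect()
    logging.getLogger("mothdrift").addHandler(collector)
    try:
        community = _community_from_config(cfg)
        stages.append("records")
        results = analyze_community(
            community,
            cut_year=cfg.cut_year,
            compute_wingspan_model=True,
            compute_fdis_trend=True,
            compute_specialization=True,
            compute_ordination=True,
            gower_correction=cfg.gower_correction,
            gam_basis_dim=cfg.gam_basis_dim,
            nmds_restarts=cfg.nmds_restarts,
            nmds_seed=cfg.nmds_seed,
            n_permutations=cfg.n_permutations,
            permutation_seed=cfg.permutation_seed,
        )
        stages += ["traits", "funcdiv", "community_trends", "ordination"]
    finally:
        logging.getLogger("mothdrift").removeHandler(collector)

    results["incidence"].to_csv(out / "incidence.csv")
    results["statuses"].to_csv(out / "status.csv", index=False)
    results["community_timeseries"].to_csv(out / "community_timeseries.csv", index=False)
    results["ordination"].to_frame().to_csv(out / "ordination_coords.csv")

    fits = {
        "wingspan_status_model": results["wingspan_status_model"].to_dict(),
        "specialization_status_model": results["specialization_status_model"].to_dict(),
        "fdis_trend": results["fdis_trend"].to_dict(),
        "specialization_trend": results["specialization_trend"].to_dict(),
        "wingspan_trend": results["wingspan_trend"].to_dict(),
        "open_habitat_trend": results["open_habitat_trend"].to_dict(),
        "vector_fits": [v.to_dict() for v in results["vector_fits"]],
        "nmds_stress": results["ordination"].stress,
        "gower_correction_applied": results["gower_correction_applied"],
    }
    with open(out / "model_fits.json", "w") as fh:
        json.dump(fits, fh, indent=2)

    if cfg.plot:
        _plot_ordination(results, out / "ordination.png")

    manifest = {
        "package_version": __version__,
        "stages": stages,
        "options": {
            "cut_year": cfg.cut_year,
            "gower_correction": cfg.gower_correction,
            "gam_basis_dim": cfg.gam_basis_dim,
            "nmds_restarts": cfg.nmds_restarts,
            "n_permutations": cfg.n_permutations,
        },
        "seeds": {
            "nmds_seed": cfg.nmds_seed,
            "permutation_seed": cfg.permutation_seed,
            "scenario_seed": (cfg.scenario or {}).get("seed"),
        },
        "status_counts": results["status_counts"],
        "warnings": warnings_log,
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.glob("*"))
            if p.suffix in (".csv", ".json") and p.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("pipeline finished: %d stages, outputs in %s", len(stages), out)
    results["manifest"] = manifest
    return results


def _plot_ordination(results: dict, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordr = results["ordination"]
    fig, ax = plt.subplots(figsize=(6, 5))
    xy = ordr.coordinates
    ax.scatter(xy[:, 0], xy[:, 1], c="tab:blue")
    for lbl, (x, y) in zip(ordr.layer_labels, xy):
        ax.annotate(lbl, (x, y), fontsize=8)
    scale = np.abs(xy).max()
    for vf in results["vector_fits"]:
        dx, dy = vf.direction_cosines * np.sqrt(vf.r_squared) * scale
        ax.arrow(0, 0, dx, dy, color="tab:red", head_width=0.01 * scale)
        ax.annotate(vf.variable_name, (dx, dy), color="tab:red", fontsize=8)
    ax.set_xlabel("NMDS1")
    ax.set_ylabel("NMDS2")
    ax.set_title(f"stress-1 = {ordr.stress:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
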