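"""Occurrence records, time layers, incidence matrices and species status.

The community object at the heart of the pipeline is a binary species x
time-layer incidence matrix. Occurrence records (one row per detection of a
species in a year, with the source collection) are pooled into *time layers*:
historic museum material is aggregated into multi-year partitions because the
collections hold too few vouchers per single year, while standardized survey
years are kept as individual layers. Species are then partitioned around a
cut-year into ``lost`` (recorded only before), ``persistent`` (before and
after) and ``previously_unrecorded`` (only from the cut-year onward).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

#: Species-level flags that trigger phenological cleaning: species flying
#: outside the comparable sampling season, long-distance migrants and strictly
#: day-active species are not comparably represented across data sources.
CLEANING_FLAGS = ("early_late_flyer", "long_distance_migrant", "strictly_diurnal")

STATUS_LOST = "lost"
STATUS_PERSISTENT = "persistent"
STATUS_PREVIOUSLY_UNRECORDED = "previously_unrecorded"
STATUSES = (STATUS_LOST, STATUS_PERSISTENT, STATUS_PREVIOUSLY_UNRECORDED)

REQUIRED_COLUMNS = ("species_id", "year", "source")

#: Default study window used to validate record years.
DEFAULT_YEAR_RANGE = (1900, 2100)


class SchemaError(ValueError):
    """A required column is missing or a scheme/configuration is invalid."""


@dataclass(frozen=True)
class TimeLayer:
    label: str
    year_min: int
    year_max: int

    def __post_init__(self) -> None:
        if self.year_min > self.year_max:
            raise SchemaError(
                f"layer {self.label!r}: year_min {self.year_min} > year_max {self.year_max}"
            )

    @property
    def midpoint(self) -> float:
        return (self.year_min + self.year_max) / 2.0

    def contains(self, year: int) -> bool:
        return self.year_min <= year <= self.year_max


@dataclass
class TimeLayerScheme:
    """An ordered, non-overlapping partition of the study years.

    Multi-year layers represent pooled museum collections; single-year layers
    represent standardized survey years (the "split up by year" rule).
    """

    layers: list[TimeLayer] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.layers:
            raise SchemaError("scheme has no layers")
        ordered = sorted(self.layers, key=lambda l: l.year_min)
        for a, b in zip(ordered, ordered[1:]):
            if b.year_min <= a.year_max:
                raise SchemaError(f"layers {a.label!r} and {b.label!r} overlap")
        self.layers = ordered
        labels = [l.label for l in self.layers]
        if len(set(labels)) != len(labels):
            raise SchemaError("duplicate layer labels")

    @property
    def labels(self) -> list[str]:
        return [l.label for l in self.layers]

    def layer_for_year(self, year: int) -> TimeLayer | None:
        for layer in self.layers:
            if layer.contains(year):
                return layer
        return None

    def midpoints(self) -> dict[str, float]:
        return {l.label: l.midpoint for l in self.layers}

    def split_at(self, cut_year: int) -> tuple[list[str], list[str]]:
        """Labels of layers entirely before / entirely from ``cut_year`` on.

        A layer straddling the cut-year makes the status partition ambiguous
        and is a configuration error.
        """
        pre, post = [], []
        for layer in self.layers:
            if layer.year_max < cut_year:
                pre.append(layer.label)
            elif layer.year_min >= cut_year:
                post.append(layer.label)
            else:
                raise SchemaError(
                    f"layer {layer.label!r} ({layer.year_min}-{layer.year_max}) "
                    f"straddles the cut-year {cut_year}"
                )
        return pre, post


#: The study's four pooled museum partitions. Two partitions of the
#: Callegari/Martinasco material and two of the Bertaccini collection.
HISTORIC_PARTITIONS = (
    ("1940s", 1933, 1949),
    ("1960s", 1950, 1976),
    ("1970s", 1977, 1984),
    ("1980s", 1985, 1996),
)

#: Survey years with standardized light-trap sampling, kept as single-year
#: layers. Together with the four museum partitions this yields the 12-layer
#: scheme used for ordination.
DEFAULT_SURVEY_YEARS = (1997, 1998, 1999, 2000, 2001, 2002, 2011, 2012)


def default_scheme(survey_years: tuple[int, ...] = DEFAULT_SURVEY_YEARS) -> TimeLayerScheme:
    """The bundled scheme: 4 pooled historic partitions + per-year survey layers."""
    layers = [TimeLayer(lbl, a, b) for lbl, a, b in HISTORIC_PARTITIONS]
    layers += [TimeLayer(str(y), y, y) for y in survey_years]
    return TimeLayerScheme(layers)


def scheme_from_dict(spec: dict) -> TimeLayerScheme:
    """Build a scheme from a config mapping.

    Expected shape::

        layers:
          - {label: "1940s", year_min: 1933, year_max: 1949}
        survey_years: [1997, 1998]      # optional per-year expansion
    """
    layers = [
        TimeLayer(str(d["label"]), int(d["year_min"]), int(d["year_max"]))
        for d in spec.get("layers", [])
    ]
    layers += [TimeLayer(str(y), int(y), int(y)) for y in spec.get("survey_years", [])]
    return TimeLayerScheme(layers)


def load_occurrences(
    path,
    column_map: dict[str, str] | None = None,
    sep: str = ",",
    strict: bool = False,
    year_range: tuple[int, int] = DEFAULT_YEAR_RANGE,
) -> pd.DataFrame:
    """Read a delimited occurrence file into a validated record table.

    Parameters
    ----------
    path
        Delimited text file with a header naming species, year and source
        columns.
    column_map
        Mapping from the canonical names (``species_id``, ``year``,
        ``source``) to the file's column names, when they differ.
    strict
        If True, any malformed row (non-integer year, empty species, year
        outside ``year_range``) raises; otherwise malformed rows are dropped
        and reported in the log.

    Returns
    -------
    DataFrame with columns ``species_id`` (str), ``year`` (int), ``source``
    (str). Duplicate (species, year) rows are retained; incidence
    construction collapses them later.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str)
    column_map = column_map or {}
    rename = {column_map.get(c, c): c for c in REQUIRED_COLUMNS}
    raw = raw.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing} in {path}")

    bad_rows: list[tuple[int, str]] = []
    years = pd.to_numeric(raw["year"], errors="coerce")
    lo, hi = year_range
    ok = years.notna() & (years == years.round()) & years.between(lo, hi)
    ok &= raw["species_id"].notna() & (raw["species_id"].str.strip() != "")
    for idx in raw.index[~ok]:
        # +2: header line plus 1-based numbering, matching what an editor shows
        bad_rows.append((int(idx) + 2, f"year={raw.loc[idx, 'year']!r}"))
    if bad_rows:
        msg = "; ".join(f"line {ln}: {why}" for ln, why in bad_rows)
        if strict:
            raise ValueError(f"malformed occurrence rows: {msg}")
        logger.warning("dropping %d malformed occurrence row(s): %s", len(bad_rows), msg)

    out = raw.loc[ok, ["species_id", "year", "source"]].copy()
    out["species_id"] = out["species_id"].str.strip()
    out["year"] = years[ok].astype(int)
    out["source"] = out["source"].fillna("")
    return out.reset_index(drop=True)


def apply_phenological_filter(
    records: pd.DataFrame,
    trait_table: pd.DataFrame,
    missing_species: str = "warn",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove all records of species bearing any phenological cleaning flag.

    Species flagged as early/late flyers, long-distance migrants or strictly
    diurnal are not comparably sampled by season-limited night light-trapping
    and are removed wholesale before any community analysis.

    Parameters
    ----------
    records
        Occurrence table (``load_occurrences`` output).
    trait_table
        Species trait table carrying boolean columns named after
        :data:`CLEANING_FLAGS` (absent columns are treated as all-False).
    missing_species
        ``"warn"`` drops records of species absent from the trait table with
        a warning; ``"error"`` raises.

    Returns
    -------
    (filtered_records, removal_log) where the log has columns
    ``species_id`` and ``reason``.
    """
    traits = trait_table.set_index("species_id") if "species_id" in trait_table.columns else trait_table
    removal: list[tuple[str, str]] = []

    flagged: set[str] = set()
    for flag in CLEANING_FLAGS:
        if flag in traits.columns:
            hits = traits.index[traits[flag].fillna(False).astype(bool)]
            for sp in hits:
                removal.append((sp, flag))
            flagged.update(hits)

    known = set(traits.index)
    present = set(records["species_id"])
    unknown = present - known
    if unknown:
        msg = f"{len(unknown)} species in records but absent from trait table: {sorted(unknown)[:5]}..."
        if missing_species == "error":
            raise KeyError(msg)
        logger.warning("%s (records dropped)", msg)
        for sp in unknown:
            removal.append((sp, "absent_from_trait_table"))

    drop = flagged | unknown
    kept = records[~records["species_id"].isin(drop)].reset_index(drop=True)
    if kept.empty and not records.empty:
        logger.warning("phenological filter removed every record")
    log = pd.DataFrame(removal, columns=["species_id", "reason"])
    return kept, log


def assign_time_layers(records: pd.DataFrame, scheme: TimeLayerScheme) -> pd.DataFrame:
    """Label each record with its time layer; reject years outside the scheme."""
    year_to_label: dict[int, str] = {}
    labels = []
    rejected = []
    for year in records["year"]:
        y = int(year)
        if y not in year_to_label:
            layer = scheme.layer_for_year(y)
            year_to_label[y] = layer.label if layer is not None else ""
        lbl = year_to_label[y]
        labels.append(lbl)
        if not lbl:
            rejected.append(y)
    out = records.copy()
    out["layer"] = labels
    if rejected:
        logger.warning(
            "%d record(s) with years outside all layers rejected: %s",
            len(rejected), sorted(set(rejected)),
        )
        out = out[out["layer"] != ""].reset_index(drop=True)
    return out


def build_incidence(labelled_records: pd.DataFrame, scheme: TimeLayerScheme) -> pd.DataFrame:
    """Pool labelled records into a binary species x layer incidence matrix.

    A cell is 1 iff the species has at least one record in the layer
    (duplicate vouchers collapse). Columns follow layer chronology; layers
    with no records are dropped. Species rows are sorted by id.
    """
    if labelled_records.empty:
        raise ValueError("cannot build an incidence matrix from an empty record table")
    if "layer" not in labelled_records.columns:
        raise ValueError("records lack a 'layer' column; run assign_time_layers first")
    tab = pd.crosstab(labelled_records["species_id"], labelled_records["layer"])
    inc = (tab > 0).astype(int)
    cols = [lbl for lbl in scheme.labels if lbl in inc.columns]
    inc = inc[cols]
    inc = inc.loc[sorted(inc.index)]
    inc.index.name = "species_id"
    inc.columns.name = "layer"
    return inc


def assign_status(
    incidence: pd.DataFrame,
    scheme: TimeLayerScheme,
    cut_year: int = 1997,
) -> pd.DataFrame:
    """Partition species by their occurrence relative to ``cut_year``.

    ``lost``: recorded only in layers entirely before the cut-year;
    ``previously_unrecorded``: only in layers from the cut-year onward;
    ``persistent``: on both sides. Records in the cut-year itself count as
    post-cut (the recent, survey side).

    Returns a DataFrame with columns ``species_id``, ``status`` and logs the
    per-status counts.
    """
    pre, post = scheme.split_at(cut_year)
    pre_cols = [c for c in incidence.columns if c in pre]
    post_cols = [c for c in incidence.columns if c in post]
    seen_pre = incidence[pre_cols].sum(axis=1) > 0 if pre_cols else pd.Series(False, index=incidence.index)
    seen_post = incidence[post_cols].sum(axis=1) > 0 if post_cols else pd.Series(False, index=incidence.index)

    status = pd.Series(index=incidence.index, dtype=object)
    status[seen_pre & ~seen_post] = STATUS_LOST
    status[seen_pre & seen_post] = STATUS_PERSISTENT
    status[~seen_pre & seen_post] = STATUS_PREVIOUSLY_UNRECORDED
    if status.isna().any():
        bad = list(status.index[status.isna()])
        raise ValueError(f"species with no incidence in any layer: {bad}")

    counts = status.value_counts()
    logger.info(
        "status partition at %d: %d lost, %d persistent, %d previously unrecorded (total %d)",
        cut_year,
        counts.get(STATUS_LOST, 0),
        counts.get(STATUS_PERSISTENT, 0),
        counts.get(STATUS_PREVIOUSLY_UNRECORDED, 0),
        len(status),
    )
    out = status.rename("status").reset_index()
    out["cut_year"] = cut_year
    return out
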