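"""Reading, filtering and time-binning of PBDB-style fossil occurrence tables.

The canonical in-memory representation is a :class:`pandas.DataFrame` with
columns ``species`` (normalized binomial), ``collection`` (integer id),
``lon``/``lat`` (paleocoordinates, degrees), ``early``/``late`` (interval
names) and ``taxon_path`` (tuple of higher-taxon names).  Structural filters
only are applied on load: records without coordinates, a collection id, or a
species-level identification are dropped and tallied in a
:class:`LoadReport`.  Additional occurrence-cleaning rules can be supplied as
an explicit exclusion list of species names.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
import yaml

__all__ = [
    "ConfigurationError",
    "LoadReport",
    "GroupRule",
    "TimeBinScheme",
    "DEFAULT_COLUMN_MAP",
    "DEFAULT_GROUPS",
    "load_occurrences",
    "filter_group",
    "assign_time_bins",
]


class ConfigurationError(ValueError):
    """Raised for unusable inputs or configuration (e.g. a missing column)."""


#: Canonical field -> PBDB flat-CSV column name.
DEFAULT_COLUMN_MAP = {
    "species": "accepted_name",
    "rank": "accepted_rank",
    "collection": "collection_no",
    "lon": "paleolng",
    "lat": "paleolat",
    "early": "early_interval",
    "late": "late_interval",
}

#: Higher-taxon columns searched (in order) to build ``taxon_path``.
DEFAULT_TAXON_COLUMNS = ("phylum", "class", "order", "family", "genus")


@dataclass
class LoadReport:
    """Bookkeeping for one load: input rows, kept rows and drop tallies."""

    n_input: int = 0
    n_kept: int = 0
    dropped: dict = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())

    def as_dict(self) -> dict:
        return {"n_input": self.n_input, "n_kept": self.n_kept, "dropped": dict(self.dropped)}


@dataclass(frozen=True)
class GroupRule:
    """Clade-based inclusion rule, e.g. Dinosauria excluding Aves."""

    name: str
    include: str
    exclude: tuple = ()


#: Study-style group definitions for North American tetrapods.
DEFAULT_GROUPS = {
    "tetrapods": GroupRule("tetrapods", "Tetrapoda", ("Aves", "Chiroptera", "Pterosauria")),
    "dinosaurs": GroupRule("dinosaurs", "Dinosauria", ("Aves",)),
    "mammals": GroupRule("mammals", "Mammaliamorpha", ("Chiroptera",)),
    "squamates": GroupRule("squamates", "Squamata"),
    "crocodilians": GroupRule("crocodilians", "Crocodylomorpha"),
    "turtles": GroupRule("turtles", "Testudinata"),
    "lissamphibians": GroupRule("lissamphibians", "Lissamphibia"),
}


@dataclass(frozen=True)
class TimeBinScheme:
    """Ordered (oldest -> youngest) composite time bins.

    Each bin is ``(bin_name, member_interval_names)``; a record is assigned to
    a bin only when both its early and late intervals map into that same bin.
    Member sets must be disjoint across bins.
    """

    bins: tuple
    resolution_tag: str = "stage_composite"

    def __post_init__(self):
        seen: dict = {}
        for name, members in self.bins:
            for m in members:
                key = m.lower()
                if key in seen:
                    raise ConfigurationError(
                        f"interval {m!r} appears in bins {seen[key]!r} and {name!r}"
                    )
                seen[key] = name

    @property
    def bin_names(self) -> list:
        return [name for name, _ in self.bins]

    def interval_to_bin(self) -> dict:
        out = {}
        for name, members in self.bins:
            for m in members:
                out[m.lower()] = name
        return out

    @classmethod
    def stage_composite(cls) -> "TimeBinScheme":
        """Campanian--Ypresian composite stage bins (NALMAs mapped to stages)."""
        return cls(
            bins=(
                ("Campanian", ("Campanian", "Early Campanian", "Middle Campanian",
                               "Late Campanian", "Judithian")),
                ("Maastrichtian", ("Maastrichtian", "Early Maastrichtian",
                                   "Late Maastrichtian", "Edmontonian", "Lancian")),
                ("Danian", ("Danian", "Puercan", "Torrejonian")),
                ("Thanetian-Selandian", ("Selandian", "Thanetian", "Tiffanian",
                                         "Clarkforkian")),
                ("Ypresian", ("Ypresian", "Wasatchian")),
            ),
            resolution_tag="stage_composite",
        )

    @classmethod
    def substage_nalma(cls) -> "TimeBinScheme":
        """Finer bins: Cretaceous substages plus Paleogene NALMAs."""
        names = ("Early Campanian", "Late Campanian", "Early Maastrichtian",
                 "Late Maastrichtian", "Puercan", "Torrejonian", "Tiffanian",
                 "Clarkforkian", "Wasatchian", "Bridgerian", "Uintan")
        return cls(bins=tuple((n, (n,)) for n in names), resolution_tag="substage_nalma")

    @classmethod
    def single_bin(cls, name: str = "Synthetic") -> "TimeBinScheme":
        """One-bin scheme, convenient for synthetic single-interval tables."""
        return cls(bins=((name, (name,)),), resolution_tag="stage_composite")

    @classmethod
    def from_yaml(cls, path) -> "TimeBinScheme":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        bins = tuple((b["name"], tuple(b["members"])) for b in cfg["bins"])
        return cls(bins=bins, resolution_tag=cfg.get("resolution_tag", "stage_composite"))


def normalize_name(name) -> str:
    """Trim and collapse internal whitespace; case is preserved."""
    return " ".join(str(name).split())


def load_occurrences(path, column_map=None, taxon_columns=None,
                     exclude_species=()):
    """Read a PBDB flat CSV into the canonical occurrence table.

    Parameters
    ----------
    path : str or file-like
        CSV with at least the mapped species/collection/coordinate/interval
        columns.
    column_map : dict, optional
        Overrides for :data:`DEFAULT_COLUMN_MAP` (canonical -> file column).
    taxon_columns : sequence of str, optional
        Higher-taxon columns composing ``taxon_path``; missing columns are
        skipped silently.
    exclude_species : iterable of str, optional
        Normalized species names to drop (user-supplied cleaning list).

    Returns
    -------
    (DataFrame, LoadReport)
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    except pd.errors.EmptyDataError as exc:
        raise ConfigurationError(f"empty occurrence file: {path}") from exc

    required = ("species", "collection", "lon", "lat", "early", "late")
    for key in required:
        if cmap[key] not in raw.columns:
            raise ConfigurationError(
                f"required column {cmap[key]!r} (for {key!r}) not found in {path}"
            )

    report = LoadReport(n_input=len(raw))

    def _tally(mask, reason):
        n = int(mask.sum())
        if n:
            report.dropped[reason] = report.dropped.get(reason, 0) + n
        return ~mask

    lon = pd.to_numeric(raw[cmap["lon"]], errors="coerce")
    lat = pd.to_numeric(raw[cmap["lat"]], errors="coerce")
    coll = pd.to_numeric(raw[cmap["collection"]], errors="coerce")
    species = raw[cmap["species"]].fillna("").map(normalize_name)

    keep = _tally(lon.isna() | lat.isna(), "missing coordinate")
    keep &= _tally(keep & (lon.abs() > 180.0) | keep & (lat.abs() > 90.0),
                   "out-of-bounds coordinate")
    keep &= _tally(keep & coll.isna(), "missing collection id")
    keep &= _tally(keep & (species == ""), "missing species name")
    if cmap["rank"] in raw.columns:
        rank = raw[cmap["rank"]].fillna("").str.strip().str.lower()
        keep &= _tally(keep & (rank != "species"), "not species level")
    if exclude_species:
        excl = {normalize_name(s) for s in exclude_species}
        keep &= _tally(keep & species.isin(excl), "user exclusion")

    cols = taxon_columns if taxon_columns is not None else DEFAULT_TAXON_COLUMNS
    present = [c for c in cols if c in raw.columns]

    sub = raw.loc[keep]
    out = pd.DataFrame({
        "species": species.loc[keep],
        "collection": coll.loc[keep].astype(int),
        "lon": lon.loc[keep],
        "lat": lat.loc[keep],
        "early": sub[cmap["early"]].fillna("").map(normalize_name),
        "late": sub[cmap["late"]].fillna("").map(normalize_name),
    })
    if present:
        paths = sub[present].fillna("")
        out["taxon_path"] = [
            tuple(normalize_name(v) for v in row if normalize_name(v))
            for row in paths.itertuples(index=False)
        ]
    else:
        out["taxon_path"] = [()] * len(out)
    out = out.reset_index(drop=True)
    report.n_kept = len(out)
    return out, report


def filter_group(table: pd.DataFrame, rule: GroupRule) -> pd.DataFrame:
    """Keep records whose taxon_path contains the include clade and none of
    the excluded clades.  Idempotent; emits a warning (and an empty result)
    when the include clade is absent from every record."""
    if "taxon_path" not in table.columns:
        raise ConfigurationError("table lacks taxon_path; load with taxon columns")
    inc = rule.include
    exc = set(rule.exclude)
    mask = table["taxon_path"].map(lambda p: inc in p and not (exc & set(p)))
    if len(table) and not table["taxon_path"].map(lambda p: inc in p).any():
        warnings.warn(f"clade {inc!r} absent from every record; result is empty",
                      stacklevel=2)
    return table.loc[mask].reset_index(drop=True)


def assign_time_bins(table: pd.DataFrame, scheme: TimeBinScheme):
    """Attach a ``bin`` column; drop (and tally) records whose early/late
    intervals resolve to different bins or to no bin at all.

    Returns ``(binned_table, report)`` where the report's drop tallies use the
    reasons ``"spanning bins"`` and ``"unresolvable interval"``.
    """
    if not scheme.bins:
        raise ConfigurationError("empty time-bin scheme")
    lookup = scheme.interval_to_bin()
    early = table["early"].str.lower().map(lookup)
    late = table["late"].str.lower().map(lookup)
    # records with a blank late interval inherit the early one (PBDB habit)
    late = late.where(table["late"].str.len() > 0, early)

    report = LoadReport(n_input=len(table))
    unresolved = early.isna() | late.isna()
    spanning = ~unresolved & (early != late)
    if int(unresolved.sum()):
        report.dropped["unresolvable interval"] = int(unresolved.sum())
    if int(spanning.sum()):
        report.dropped["spanning bins"] = int(spanning.sum())
    keep = ~(unresolved | spanning)
    out = table.loc[keep].copy()
    out["bin"] = early.loc[keep]
    out = out.reset_index(drop=True)
    report.n_kept = len(out)
    return out, report
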