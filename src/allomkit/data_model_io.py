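"""Inventory data model, CSV IO, and wood-density resolution.

The core container is :class:`ForestDataset`, an ordered collection of
:class:`TreeRecord` (one row per inventoried stem) plus plot areas.  Wood
density is resolved per tree by a taxonomic fallback chain: species mean →
genus mean → family mean → mean of the already-resolved trees in the same
plot, the convention used by tropical biomass studies working from the
global wood-density database.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger("allomkit")

__all__ = [
    "ForestType",
    "TreeRecord",
    "ForestDataset",
    "WoodDensityTable",
    "FormatError",
    "DataError",
    "read_inventory",
    "write_inventory",
    "read_wood_density",
    "assign_wood_density",
    "AssignmentReport",
]

DBH_RANGE = (0.0, 500.0)      # cm, exclusive bounds
HEIGHT_RANGE = (0.0, 120.0)   # m, exclusive bounds
DENSITY_RANGE = (0.05, 1.5)   # g cm^-3, exclusive bounds


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class DataError(ValueError):
    """Input data violate a precondition of an operation."""


class ForestType(str, Enum):
    terra_firme = "terra_firme"
    varzea = "varzea"


def _norm(s: str | None) -> str:
    return (s or "").strip().casefold()


@dataclass(frozen=True)
class TreeRecord:
    """One inventoried stem.

    dbh is the diameter at breast height in cm (measured at 1.3 m above
    ground); height the total height in m, optional so that diameter-only
    biomass paths work on inventories without height measurements.
    """

    plot_id: str
    tag: str
    family: str
    genus: str
    species: str
    dbh: float
    forest_type: ForestType
    height: float | None = None
    wood_density: float | None = None
    expansion_factor: float | None = None  # subplot-to-plot weight, per-ha scaling

    def __post_init__(self) -> None:
        if not DBH_RANGE[0] < self.dbh < DBH_RANGE[1]:
            raise DataError(f"dbh {self.dbh} outside {DBH_RANGE} cm")
        if self.height is not None and not HEIGHT_RANGE[0] < self.height < HEIGHT_RANGE[1]:
            raise DataError(f"height {self.height} outside {HEIGHT_RANGE} m")
        if not isinstance(self.forest_type, ForestType):
            object.__setattr__(self, "forest_type", ForestType(self.forest_type))

    @property
    def binomial(self) -> str:
        return f"{self.genus} {self.species}".strip()

    @property
    def is_identified(self) -> bool:
        return _norm(self.species) not in ("", "indet", "indet.", "sp", "sp.")


@dataclass
class ForestDataset:
    """Ordered tree records plus per-plot areas (ha) and provenance text."""

    records: list[TreeRecord]
    plot_areas: dict[str, float] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for r in self.records:
            key = (r.plot_id, r.tag)
            if key in seen:
                raise DataError(f"duplicate tag {r.tag!r} in plot {r.plot_id!r}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def filter(self, pred) -> "ForestDataset":
        return ForestDataset([r for r in self.records if pred(r)],
                             dict(self.plot_areas), self.provenance)

    def with_heights(self) -> "ForestDataset":
        return self.filter(lambda r: r.height is not None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plot_id": [r.plot_id for r in self.records],
                "tag": [r.tag for r in self.records],
                "family": [r.family for r in self.records],
                "genus": [r.genus for r in self.records],
                "species": [r.species for r in self.records],
                "dbh": [r.dbh for r in self.records],
                "height": [r.height for r in self.records],
                "forest_type": [r.forest_type.value for r in self.records],
                "wood_density": [r.wood_density for r in self.records],
                "expansion_factor": [r.expansion_factor for r in self.records],
            }
        )


class WoodDensityTable:
    """Wood densities keyed by normalized (family, genus, species).

    Genus- and family-level means are precomputed at construction so the
    fallback chain is a sequence of dictionary lookups.
    """

    def __init__(self, entries: Mapping[tuple[str, str, str], float]):
        self.species_level: dict[tuple[str, str, str], float] = {}
        for (fam, gen, sp), rho in entries.items():
            key = (_norm(fam), _norm(gen), _norm(sp))
            if not DENSITY_RANGE[0] < rho < DENSITY_RANGE[1]:
                raise DataError(f"wood density {rho} outside {DENSITY_RANGE} for {key}")
            self.species_level[key] = float(rho)
        by_genus: dict[str, list[float]] = {}
        by_family: dict[str, list[float]] = {}
        for (fam, gen, _sp), rho in self.species_level.items():
            if gen:
                by_genus.setdefault(gen, []).append(rho)
            if fam:
                by_family.setdefault(fam, []).append(rho)
        self.genus_level = {g: sum(v) / len(v) for g, v in by_genus.items()}
        self.family_level = {f: sum(v) / len(v) for f, v in by_family.items()}

    def lookup(self, family: str, genus: str, species: str) -> tuple[float, str] | None:
        """Return (rho, level) for the deepest taxonomic match, or None."""
        fam, gen, sp = _norm(family), _norm(genus), _norm(species)
        if sp and (fam, gen, sp) in self.species_level:
            return self.species_level[(fam, gen, sp)], "species"
        # species keys may carry a different/absent family; match genus+species too
        if sp and gen:
            hits = [r for (f, g, s), r in self.species_level.items() if g == gen and s == sp]
            if hits:
                return sum(hits) / len(hits), "species"
        if gen and gen in self.genus_level:
            return self.genus_level[gen], "genus"
        if fam and fam in self.family_level:
            return self.family_level[fam], "family"
        return None


_REQUIRED = ("plot_id", "tag", "dbh")
_DEFAULT_DIALECT = {
    "plot_id": "plot_id",
    "tag": "tree_tag",
    "family": "family",
    "genus": "genus",
    "species": "species",
    "dbh": "dbh_cm",
    "height": "height_m",
    "forest_type": "forest_type",
    "wood_density": "wood_density_g_cm3",
    "expansion_factor": "expansion_factor",
}


def _parse_float(text: str, decimal: str) -> float:
    if decimal != ".":
        text = text.replace(decimal, ".")
    return float(text)


def read_inventory(
    path,
    dialect: Mapping[str, str] | None = None,
    decimal: str = ".",
    forest_type: str | None = None,
    plot_areas: Mapping[str, float] | None = None,
) -> ForestDataset:
    """Read an inventory CSV into a :class:`ForestDataset`.

    ``dialect`` maps canonical field names (plot_id, tag, family, genus,
    species, dbh, height, forest_type, wood_density) to the file's column
    names.  Rows with non-positive or unparseable DBH are rejected and
    counted in the log.  When no genus column exists, the genus is the
    first token of the scientific name.
    """
    d = dict(_DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file")
        cols = set(reader.fieldnames)
        for fld in _REQUIRED:
            if d[fld] not in cols:
                raise FormatError(f"{path}: missing required column {d[fld]!r}")
        if d["forest_type"] not in cols and forest_type is None:
            raise FormatError(
                f"{path}: missing column {d['forest_type']!r} and no forest_type override"
            )
        records: list[TreeRecord] = []
        rejected = 0
        for i, row in enumerate(reader):
            try:
                dbh = _parse_float(row[d["dbh"]], decimal)
            except (ValueError, TypeError):
                rejected += 1
                continue
            species_field = (row.get(d["species"]) or "").strip()
            genus = (row.get(d["genus"]) or "").strip()
            species = species_field
            # genus from the scientific name's first token only when the
            # file has no genus column at all
            if d["genus"] not in cols and species_field:
                parts = species_field.split()
                genus = parts[0]
                species = " ".join(parts[1:]) or "indet"
            height = None
            htext = (row.get(d["height"]) or "").strip()
            if htext:
                height = _parse_float(htext, decimal)
            rho = None
            rtext = (row.get(d["wood_density"]) or "").strip()
            if rtext:
                rho = _parse_float(rtext, decimal)
            ef = None
            etext = (row.get(d["expansion_factor"]) or "").strip()
            if etext:
                ef = _parse_float(etext, decimal)
            ftype = (row.get(d["forest_type"]) or forest_type or "").strip()
            try:
                rec = TreeRecord(
                    plot_id=row[d["plot_id"]].strip(),
                    tag=row[d["tag"]].strip(),
                    family=(row.get(d["family"]) or "").strip(),
                    genus=genus,
                    species=species,
                    dbh=dbh,
                    height=height,
                    forest_type=ForestType(ftype),
                    wood_density=rho,
                    expansion_factor=ef,
                )
            except (DataError, ValueError):
                rejected += 1
                continue
            records.append(rec)
    if rejected:
        logger.info("read_inventory: rejected %d invalid rows from %s", rejected, path)
    if not records:
        raise FormatError(f"{path}: no valid records")
    return ForestDataset(records, dict(plot_areas or {}), provenance=str(path))


def write_inventory(ds: ForestDataset, path, dialect: Mapping[str, str] | None = None) -> None:
    """Write a dataset in the canonical inventory CSV dialect (round-trips)."""
    d = dict(_DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    fields = ["plot_id", "tag", "family", "genus", "species", "dbh",
              "height", "forest_type", "wood_density", "expansion_factor"]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([d[f] for f in fields])
        for r in ds.records:
            writer.writerow([
                r.plot_id, r.tag, r.family, r.genus, r.species,
                repr(r.dbh),
                "" if r.height is None else repr(r.height),
                r.forest_type.value,
                "" if r.wood_density is None else repr(r.wood_density),
                "" if r.expansion_factor is None else repr(r.expansion_factor),
            ])


_WD_DIALECT = {
    "family": "family",
    "genus": "genus",
    "binomial": "binomial",
    "wood_density": "wood_density_g_cm3",
}


def read_wood_density(path, dialect: Mapping[str, str] | None = None,
                      decimal: str = ".") -> WoodDensityTable:
    """Read a wood-density CSV (family, genus, binomial, density in g cm⁻³).

    Multiple rows for one binomial are averaged into a single entry.
    """
    d = dict(_WD_DIALECT)
    if dialect:
        d.update(dialect)
    sums: dict[tuple[str, str, str], list[float]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file")
        for fld in ("binomial", "wood_density"):
            if d[fld] not in set(reader.fieldnames):
                raise FormatError(f"{path}: missing required column {d[fld]!r}")
        for i, row in enumerate(reader):
            try:
                rho = _parse_float(row[d["wood_density"]], decimal)
            except (ValueError, TypeError):
                raise FormatError(f"{path}: non-numeric wood density at row {i + 2}")
            binom = (row.get(d["binomial"]) or "").strip()
            genus = (row.get(d["genus"]) or "").strip()
            parts = binom.split()
            if not genus and parts:
                genus = parts[0]
            species = " ".join(parts[1:]) if len(parts) > 1 else ""
            fam = (row.get(d["family"]) or "").strip()
            sums.setdefault((fam, genus, species), []).append(rho)
    entries = {k: sum(v) / len(v) for k, v in sums.items()}
    return WoodDensityTable(entries)


@dataclass
class AssignmentReport:
    """Counts of wood-density resolutions per fallback level."""

    species: int = 0
    genus: int = 0
    family: int = 0
    plot: int = 0
    preset: int = 0  # already carried a density; never overwritten

    @property
    def total(self) -> int:
        return self.species + self.genus + self.family + self.plot + self.preset

    def as_dict(self) -> dict[str, int]:
        return {"species": self.species, "genus": self.genus, "family": self.family,
                "plot": self.plot, "preset": self.preset}


def assign_wood_density(ds: ForestDataset, wd: WoodDensityTable) -> tuple[ForestDataset, AssignmentReport]:
    """Fill each tree's wood density by taxonomic fallback.

    Order: species mean, genus mean, family mean, then — computed after all
    taxonomic matches — the arithmetic mean density of the taxonomically
    resolved trees in the same plot.  Idempotent: densities already present
    are kept.
    """
    report = AssignmentReport()
    resolved: list[TreeRecord | None] = []
    levels: list[str | None] = []
    for r in ds.records:
        if r.wood_density is not None:
            report.preset += 1
            resolved.append(r)
            levels.append("preset")
            continue
        hit = wd.lookup(r.family, r.genus, r.species)
        if hit is not None:
            rho, level = hit
            setattr(report, level, getattr(report, level) + 1)
            resolved.append(replace(r, wood_density=rho))
            levels.append(level)
        else:
            resolved.append(None)
            levels.append(None)
    # plot-mean fallback, computed after all taxonomic matches
    plot_means: dict[str, float] = {}
    for plot_id in {r.plot_id for r in ds.records}:
        vals = [rec.wood_density for rec in resolved
                if rec is not None and rec.plot_id == plot_id and rec.wood_density is not None]
        if vals:
            plot_means[plot_id] = sum(vals) / len(vals)
    out: list[TreeRecord] = []
    for orig, rec in zip(ds.records, resolved):
        if rec is not None:
            out.append(rec)
            continue
        if orig.plot_id not in plot_means:
            raise DataError(
                f"plot {orig.plot_id!r} has no taxonomically resolved trees; "
                "cannot compute a plot-mean wood density"
            )
        report.plot += 1
        out.append(replace(orig, wood_density=plot_means[orig.plot_id]))
    logger.info("assign_wood_density: %s", report.as_dict())
    return ForestDataset(out, dict(ds.plot_areas), ds.provenance), report
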