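"""Tabular input/output for the trophic-niche pipeline.

All field tables are long-format UTF-8 CSV with "." decimals:

* stomach table — one row per fish x prey item, plus the visually scored
  total fullness of the stomach (columns: ``fish_id, site, species,
  fork_length_mm, total_fullness_pct, prey_taxon, fullness_points``);
  empty stomachs appear as a single row with total 0 and blank prey.
* taxonomy table — ``taxon, group, is_surface``; group is one of the seven
  aquatic categories (Ephemeroptera, Plecoptera, Trichoptera, Diptera,
  Mollusca, Coleoptera, others) or ``surface``.
* benthos table — ``site, replicate, taxon, count, area_m2``.
* removal table — ``site, species, pass, count, area_m2``.

A packaged 11-site summary of the River Reisa survey (prey diversity and
abundance, fish densities, Levins breadth, individual specialization,
surface-prey contribution, and total/aquatic dietary overlap) is exposed via
:func:`load_site_summary_fixture`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

AQUATIC_GROUPS = (
    "Ephemeroptera",
    "Plecoptera",
    "Trichoptera",
    "Diptera",
    "Mollusca",
    "Coleoptera",
    "others",
)
SURFACE_GROUP = "surface"

FULLNESS_TOL = 1e-6  # fullness points are human-scored percentages


class SchemaError(ValueError):
    """A table is missing required columns or has malformed values."""


class ValidationError(ValueError):
    """A table parsed but violates a record-level invariant."""


@dataclass(frozen=True)
class PreyTaxon:
    """One prey taxon at the study's finest resolution."""

    name: str
    group: str
    is_surface: bool

    def __post_init__(self) -> None:
        if self.is_surface != (self.group == SURFACE_GROUP):
            raise ValidationError(
                f"taxon {self.name!r}: is_surface must be true iff group == 'surface'"
            )


class Taxonomy:
    """Lookup table taxon -> :class:`PreyTaxon`."""

    def __init__(self, taxa: Iterable[PreyTaxon]):
        self._taxa: dict[str, PreyTaxon] = {}
        for t in taxa:
            if t.name in self._taxa:
                raise ValidationError(f"duplicate taxon {t.name!r} in taxonomy")
            self._taxa[t.name] = t

    def __contains__(self, name: str) -> bool:
        return name in self._taxa

    def __len__(self) -> int:
        return len(self._taxa)

    def __getitem__(self, name: str) -> PreyTaxon:
        return self._taxa[name]

    def is_surface(self, name: str) -> bool:
        return self._taxa[name].is_surface

    def group_of(self, name: str) -> str:
        return self._taxa[name].group

    @property
    def names(self) -> list[str]:
        return list(self._taxa)


@dataclass
class StomachRecord:
    """One fish's stomach content in fullness points.

    ``prey_points`` maps taxon to the fullness points assigned to that prey;
    the points sum to ``total_fullness_pct`` (the visually determined total,
    0-100).  An empty stomach is total 0 with an empty map.
    """

    fish_id: str
    site: str
    species: str
    fork_length_mm: float
    total_fullness_pct: float
    prey_points: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fork_length_mm <= 0:
            raise ValidationError(f"fish {self.fish_id}: fork length must be positive")
        if not 0 <= self.total_fullness_pct <= 100:
            raise ValidationError(
                f"fish {self.fish_id}: total fullness {self.total_fullness_pct} outside [0, 100]"
            )
        if any(v < 0 for v in self.prey_points.values()):
            raise ValidationError(f"fish {self.fish_id}: negative fullness points")
        s = sum(self.prey_points.values())
        if self.prey_points:
            if not math.isclose(s, self.total_fullness_pct, abs_tol=FULLNESS_TOL):
                raise ValidationError(
                    f"fish {self.fish_id}: prey points sum {s:g} != total fullness "
                    f"{self.total_fullness_pct:g}"
                )
        elif self.total_fullness_pct != 0:
            raise ValidationError(
                f"fish {self.fish_id}: nonzero total fullness with no prey rows"
            )

    @property
    def is_empty(self) -> bool:
        return not self.prey_points


@dataclass
class BenthosSample:
    """Taxon counts from one kick replicate over a known swept area (m^2)."""

    site: str
    replicate: int
    counts: dict[str, int]
    area_m2: float = 2.25

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError("replicate index must be >= 1")
        if self.area_m2 <= 0:
            raise ValidationError("swept area must be positive")
        if any(c < 0 for c in self.counts.values()):
            raise ValidationError("negative benthos count")


@dataclass
class RemovalCatch:
    """Per-pass catch counts for one site x species removal series."""

    site: str
    species: str
    catches: list[int]
    area_m2: float

    def __post_init__(self) -> None:
        if len(self.catches) < 2:
            raise ValidationError("removal estimation needs >= 2 passes")
        if any(c < 0 for c in self.catches):
            raise ValidationError("negative catch count")
        if self.area_m2 <= 0:
            raise ValidationError("sampled area must be positive")

    @property
    def total(self) -> int:
        return int(sum(self.catches))


#: column layout of the per-site summary table (one row per site)
SITE_SUMMARY_COLUMNS = [
    "site",
    "prey_diversity",
    "prey_abundance",
    "density_bullhead",
    "density_salmon",
    "density_trout",
    "density_charr",
    "density_total",
    "levins_bullhead",
    "levins_salmon",
    "one_minus_is_bullhead_mean",
    "one_minus_is_bullhead_sd",
    "one_minus_is_salmon_mean",
    "one_minus_is_salmon_sd",
    "surface_bullhead",
    "surface_salmon",
    "overlap_total",
    "overlap_aquatic",
    "n_bullhead",
    "n_salmon",
]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")


def read_taxonomy(path: str | Path) -> Taxonomy:
    df = pd.read_csv(path)
    _require_columns(df, ["taxon", "group", "is_surface"], "taxonomy table")
    taxa = [
        PreyTaxon(str(r.taxon), str(r.group), bool(r.is_surface))
        for r in df.itertuples()
    ]
    return Taxonomy(taxa)


def write_taxonomy(taxonomy: Taxonomy, path: str | Path) -> None:
    rows = [
        {"taxon": t, "group": taxonomy.group_of(t), "is_surface": taxonomy.is_surface(t)}
        for t in taxonomy.names
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_stomach_table(
    path: str | Path, taxonomy: Taxonomy | None = None
) -> list[StomachRecord]:
    """Read a long-format stomach table into per-fish records.

    Rows are grouped by ``fish_id``; the per-fish sum of fullness points is
    checked against the scored total.  If a taxonomy is given, prey taxa
    absent from it raise :class:`ValidationError` (listing the offenders).
    """
    df = pd.read_csv(path)
    _require_columns(
        df,
        [
            "fish_id",
            "site",
            "species",
            "fork_length_mm",
            "total_fullness_pct",
            "prey_taxon",
            "fullness_points",
        ],
        "stomach table",
    )
    if taxonomy is not None:
        seen = set(df["prey_taxon"].dropna().astype(str))
        unknown = sorted(t for t in seen if t not in taxonomy)
        if unknown:
            raise ValidationError(f"stomach table: unknown prey taxa {unknown}")
    records = []
    for fish_id, g in df.groupby("fish_id", sort=False):
        meta = g.iloc[0]
        prey: dict[str, float] = {}
        for r in g.itertuples():
            if pd.isna(r.prey_taxon) or str(r.prey_taxon) == "":
                continue
            prey[str(r.prey_taxon)] = prey.get(str(r.prey_taxon), 0.0) + float(
                r.fullness_points
            )
        records.append(
            StomachRecord(
                fish_id=str(fish_id),
                site=str(meta["site"]),
                species=str(meta["species"]),
                fork_length_mm=float(meta["fork_length_mm"]),
                total_fullness_pct=float(meta["total_fullness_pct"]),
                prey_points=prey,
            )
        )
    return records


def write_stomach_table(records: Iterable[StomachRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        base = {
            "fish_id": rec.fish_id,
            "site": rec.site,
            "species": rec.species,
            "fork_length_mm": rec.fork_length_mm,
            "total_fullness_pct": rec.total_fullness_pct,
        }
        if rec.prey_points:
            for taxon, pts in rec.prey_points.items():
                rows.append({**base, "prey_taxon": taxon, "fullness_points": pts})
        else:
            rows.append({**base, "prey_taxon": "", "fullness_points": 0.0})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_benthos_table(path: str | Path) -> list[BenthosSample]:
    df = pd.read_csv(path)
    _require_columns(df, ["site", "replicate", "taxon", "count", "area_m2"], "benthos table")
    samples = []
    for (site, rep), g in df.groupby(["site", "replicate"], sort=False):
        counts = {str(r.taxon): int(r.count) for r in g.itertuples()}
        samples.append(
            BenthosSample(
                site=str(site),
                replicate=int(rep),
                counts=counts,
                area_m2=float(g["area_m2"].iloc[0]),
            )
        )
    return samples


def write_benthos_table(samples: Iterable[BenthosSample], path: str | Path) -> None:
    rows = [
        {
            "site": s.site,
            "replicate": s.replicate,
            "taxon": taxon,
            "count": count,
            "area_m2": s.area_m2,
        }
        for s in samples
        for taxon, count in s.counts.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_removal_table(path: str | Path) -> list[RemovalCatch]:
    df = pd.read_csv(path)
    _require_columns(df, ["site", "species", "pass", "count", "area_m2"], "removal table")
    catches = []
    for (site, species), g in df.groupby(["site", "species"], sort=False):
        g = g.sort_values("pass")
        catches.append(
            RemovalCatch(
                site=str(site),
                species=str(species),
                catches=[int(c) for c in g["count"]],
                area_m2=float(g["area_m2"].iloc[0]),
            )
        )
    return catches


def write_removal_table(catches: Iterable[RemovalCatch], path: str | Path) -> None:
    rows = [
        {
            "site": c.site,
            "species": c.species,
            "pass": i + 1,
            "count": count,
            "area_m2": c.area_m2,
        }
        for c in catches
        for i, count in enumerate(c.catches)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_site_summary(path: str | Path) -> pd.DataFrame:
    """Read a per-site summary table, validating the column layout."""
    df = pd.read_csv(path)
    _require_columns(df, SITE_SUMMARY_COLUMNS, "site summary")
    bad = df[(df["overlap_total"] < 0) | (df["overlap_total"] > 100)]
    if len(bad):
        raise ValidationError(f"overlap outside [0, 100] at sites {list(bad['site'])}")
    return df[SITE_SUMMARY_COLUMNS]


def write_site_summary(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a site-summary table; round-trips through :func:`read_site_summary`."""
    if len(rows) == 0:
        raise ValidationError("refusing to write an empty site summary")
    _require_columns(rows, SITE_SUMMARY_COLUMNS, "site summary")
    rows[SITE_SUMMARY_COLUMNS].to_csv(path, index=False)


def load_site_summary_fixture() -> pd.DataFrame:
    """The packaged 11-site River Reisa summary (one row per sampling site).

    Values are transcribed survey summaries: Shannon prey diversity (base-10
    log), benthos abundance (ind./m^2), Zippin fish densities (fish/100 m^2),
    Levins breadth, prevalence of individual specialization (1-IS, mean and
    SD), surface-prey diet share (%), and Schoener dietary overlap between
    juvenile Atlantic salmon and alpine bullhead computed over all prey and
    over aquatic prey only.
    """
    with resources.files("troph.data").joinpath("site_summary_reisa.csv").open() as fh:
        return read_site_summary(fh)
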