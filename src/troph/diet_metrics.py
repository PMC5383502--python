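"""Stomach-content statistics: diet composition, overlap, breadth, specialization.

The fullness-points method scores each stomach's total fullness visually
(0-100%) and splits it over prey taxa, so the points of one stomach sum to
its total fullness.  All population-level statistics derive from these
points:

* percent prey abundance  A_i = 100 * (sum of points on prey i over all
  fish) / (sum of total fullness over all fish) — the population diet
  composition; sums to 100.
* Schoener percentage overlap  P_jk = sum_i min(A_ij, A_ik) between two
  populations j, k; 0 (disjoint diets) to 100 (identical).
* Levins niche breadth  B = 1 / sum P_i^2 on the composition as fractions;
  1 (monophagy) to k (uniform use of k prey).
* proportional similarity  PS_i = 1 - 0.5 * sum_j |p_ij - Q_j| of each
  individual's proportions p_ij against the population's Q_j; the prevalence
  of individual specialization is 1 - mean(PS_i).

Empty stomachs contribute zero to composition sums and are excluded from
PS_i, but are counted in n_fish.  The aquatic-only overlap drops
surface-flagged taxa from each fish and renormalizes the compositions to 100
before applying the overlap sum, so it can exceed the all-prey overlap when
one species feeds heavily at the surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_tables import (
    AQUATIC_GROUPS,
    SURFACE_GROUP,
    StomachRecord,
    Taxonomy,
    ValidationError,
)

COMPOSITION_TOL = 1e-9


@dataclass
class DietComposition:
    """Population diet of one site x species as percent prey abundance."""

    site: str
    species: str
    percent_abundance: dict[str, float]
    n_fish: int
    n_nonempty: int


@dataclass
class IndividualDiet:
    """One fish's diet as proportions summing to 1."""

    fish_id: str
    proportions: dict[str, float]


@dataclass
class SpecializationResult:
    """Per-individual PS_i values and the population prevalence 1 - mean(PS_i)."""

    psi_values: dict[str, float]
    mean_psi: float
    sd_psi: float
    prevalence: float


def _check_composition(comp: Mapping[str, float], total: float, what: str) -> None:
    s = sum(comp.values())
    if abs(s - total) > max(COMPOSITION_TOL, 1e-9 * total):
        raise ValidationError(f"{what} sums to {s:.12g}, expected {total:g}")
    if any(v < 0 for v in comp.values()):
        raise ValidationError(f"{what} has negative entries")


def percent_prey_abundance(records: Sequence[StomachRecord]) -> DietComposition:
    """Population diet composition A_i from one site x species' stomachs."""
    if not records:
        raise ValidationError("no stomach records supplied")
    nonempty = [r for r in records if not r.is_empty]
    if not nonempty:
        raise ValidationError("all stomachs empty: diet composition undefined")
    total_points: dict[str, float] = {}
    total_fullness = 0.0
    for r in nonempty:
        total_fullness += r.total_fullness_pct
        for taxon, pts in r.prey_points.items():
            total_points[taxon] = total_points.get(taxon, 0.0) + pts
    percent = {t: 100.0 * s / total_fullness for t, s in total_points.items()}
    return DietComposition(
        site=records[0].site,
        species=records[0].species,
        percent_abundance=percent,
        n_fish=len(records),
        n_nonempty=len(nonempty),
    )


def percentage_overlap(a: DietComposition, b: DietComposition) -> float:
    """Schoener percentage overlap sum_i min(A_ij, A_ik), in [0, 100]."""
    _check_composition(a.percent_abundance, 100.0, "first composition")
    _check_composition(b.percent_abundance, 100.0, "second composition")
    taxa = set(a.percent_abundance) | set(b.percent_abundance)
    return float(
        sum(
            min(a.percent_abundance.get(t, 0.0), b.percent_abundance.get(t, 0.0))
            for t in taxa
        )
    )


def _strip_surface(records: Sequence[StomachRecord], taxonomy: Taxonomy) -> list[StomachRecord]:
    out = []
    for r in records:
        aquatic = {t: v for t, v in r.prey_points.items() if not taxonomy.is_surface(t)}
        total = min(sum(aquatic.values()), 100.0)  # guard float drift past 100
        out.append(
            StomachRecord(
                fish_id=r.fish_id,
                site=r.site,
                species=r.species,
                fork_length_mm=r.fork_length_mm,
                total_fullness_pct=total,
                prey_points=aquatic,
            )
        )
    return out


def aquatic_overlap(
    a_records: Sequence[StomachRecord],
    b_records: Sequence[StomachRecord],
    taxonomy: Taxonomy,
) -> float:
    """Overlap after removing surface prey and renormalizing each diet to 100."""
    comps = []
    for records in (a_records, b_records):
        stripped = _strip_surface(records, taxonomy)
        if all(r.is_empty for r in stripped):
            raise ValidationError(
                f"{records[0].species} diet is entirely surface prey; "
                "aquatic overlap undefined"
            )
        comps.append(percent_prey_abundance(stripped))
    return percentage_overlap(*comps)


def levins_breadth(composition: DietComposition) -> float:
    """Levins B = 1 / sum P_i^2 on the diet fractions; 1 <= B <= #prey."""
    if not composition.percent_abundance:
        raise ValidationError("empty composition: Levins breadth undefined")
    _check_composition(composition.percent_abundance, 100.0, "composition")
    p = np.asarray(list(composition.percent_abundance.values())) / 100.0
    return float(1.0 / np.sum(p**2))


def individual_diet(record: StomachRecord) -> IndividualDiet:
    """A fish's own fullness points normalized to proportions."""
    if record.is_empty:
        raise ValidationError(f"fish {record.fish_id}: empty stomach has no diet")
    total = sum(record.prey_points.values())
    return IndividualDiet(
        fish_id=record.fish_id,
        proportions={t: v / total for t, v in record.prey_points.items()},
    )


def proportional_similarity(
    individual: IndividualDiet, population: DietComposition
) -> float:
    """PS_i = 1 - 0.5 sum_j |p_ij - Q_j| in (0, 1]."""
    _check_composition(individual.proportions, 1.0, "individual proportions")
    _check_composition(population.percent_abundance, 100.0, "population composition")
    q = {t: v / 100.0 for t, v in population.percent_abundance.items()}
    taxa = set(individual.proportions) | set(q)
    l1 = sum(abs(individual.proportions.get(t, 0.0) - q.get(t, 0.0)) for t in taxa)
    return float(1.0 - 0.5 * l1)


def specialization_prevalence(records: Sequence[StomachRecord]) -> SpecializationResult:
    """Prevalence of individual specialization 1 - mean(PS_i) for a population.

    PS_i compares each nonempty stomach against the population composition
    built from the same records; the SD over individuals is reported
    alongside (populations are summarized as mean +/- SD).
    """
    nonempty = [r for r in records if not r.is_empty]
    if len(nonempty) < 2:
        raise ValidationError(
            "individual specialization needs >= 2 nonempty stomachs"
        )
    population = percent_prey_abundance(records)
    psi = {
        r.fish_id: proportional_similarity(individual_diet(r), population)
        for r in nonempty
    }
    values = np.asarray(list(psi.values()))
    return SpecializationResult(
        psi_values=psi,
        mean_psi=float(values.mean()),
        sd_psi=float(values.std(ddof=1)),
        prevalence=float(1.0 - values.mean()),
    )


def surface_fraction(records: Sequence[StomachRecord], taxonomy: Taxonomy) -> float:
    """Percent of the population diet made up of surface-flagged prey."""
    comp = percent_prey_abundance(records)
    return float(
        sum(v for t, v in comp.percent_abundance.items() if taxonomy.is_surface(t))
    )


def coarse_diet_groups(
    composition: DietComposition, taxonomy: Taxonomy
) -> dict[str, float]:
    """Sum percent abundance into the seven aquatic groups plus surface."""
    unmapped = sorted(t for t in composition.percent_abundance if t not in taxonomy)
    if unmapped:
        raise ValidationError(f"taxa with no group mapping: {unmapped}")
    groups = {g: 0.0 for g in (*AQUATIC_GROUPS, SURFACE_GROUP)}
    for taxon, pct in composition.percent_abundance.items():
        group = taxonomy.group_of(taxon)
        if group not in groups:
            raise ValidationError(f"taxon {taxon!r} has unknown group {group!r}")
        groups[group] += pct
    return groups


def coarsen_records(
    records: Iterable[StomachRecord], taxonomy: Taxonomy
) -> list[StomachRecord]:
    """Re-express stomach records at the coarse group resolution."""
    out = []
    for r in records:
        pts: dict[str, float] = {}
        for taxon, v in r.prey_points.items():
            pts[taxonomy.group_of(taxon)] = pts.get(taxonomy.group_of(taxon), 0.0) + v
        out.append(
            StomachRecord(
                fish_id=r.fish_id,
                site=r.site,
                species=r.species,
                fork_length_mm=r.fork_length_mm,
                total_fullness_pct=r.total_fullness_pct,
                prey_points=pts,
            )
        )
    return out
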