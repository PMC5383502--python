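"""Prey-community descriptors from benthos kick samples.

Shannon diversity is computed in base-10 logarithm, the convention under
which the Reisa survey's printed range (0.50-0.98 over communities of up to
~30 taxa) is interpretable; ``base`` switches to natural log or log2 where a
different convention is needed.  Replicate kick samples from a site are
pooled (summed), not averaged, before proportions are formed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_tables import BenthosSample, ValidationError

PROPORTION_TOL = 1e-9


@dataclass
class CommunityProfile:
    """Pooled prey-community state for one site."""

    site: str
    proportions: dict[str, float]
    total_count: int
    abundance_per_m2: float
    diversity_H: float


def shannon_diversity(proportions: Mapping[str, float], base: float = 10.0) -> float:
    """Shannon diversity H' = -sum p_i log_base(p_i) of a proportion vector.

    Zero-proportion taxa contribute nothing.  Raises if the proportions do
    not form a distribution.
    """
    p = np.asarray(list(proportions.values()), dtype=float)
    if np.any(p < 0):
        raise ValidationError("negative proportion")
    if abs(p.sum() - 1.0) > PROPORTION_TOL:
        raise ValidationError(f"proportions sum to {p.sum():.12g}, not 1")
    p = p[p > 0]
    return float(-(p * np.log(p) / np.log(base)).sum())


def community_profile(
    samples: Sequence[BenthosSample], base: float = 10.0
) -> CommunityProfile:
    """Pool replicate kick samples of one site into a community profile.

    Counts are summed across replicates; abundance is total individuals per
    total swept area; diversity is Shannon H' of the pooled proportions.
    """
    if not samples:
        raise ValidationError("no benthos samples supplied")
    sites = {s.site for s in samples}
    if len(sites) > 1:
        raise ValidationError(f"samples span several sites: {sorted(sites)}")
    pooled: dict[str, int] = {}
    for s in samples:
        for taxon, count in s.counts.items():
            pooled[taxon] = pooled.get(taxon, 0) + count
    total = sum(pooled.values())
    if total == 0:
        raise ValidationError(f"site {samples[0].site}: all counts zero, diversity undefined")
    area = sum(s.area_m2 for s in samples)
    proportions = {t: c / total for t, c in pooled.items() if c > 0}
    return CommunityProfile(
        site=samples[0].site,
        proportions=proportions,
        total_count=total,
        abundance_per_m2=total / area,
        diversity_H=shannon_diversity(proportions, base=base),
    )


def community_profiles(
    samples: Iterable[BenthosSample], base: float = 10.0
) -> list[CommunityProfile]:
    """Group samples by site and profile each site, sorted by site label."""
    by_site: dict[str, list[BenthosSample]] = {}
    for s in samples:
        by_site.setdefault(s.site, []).append(s)
    return [community_profile(by_site[k], base=base) for k in sorted(by_site)]
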