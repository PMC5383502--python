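"""Synthetic river-survey generator with known ground truth.

Emulates the field design the pipeline analyzes: a set of riffle sites each
with (i) a benthic prey community sampled by three kick replicates, (ii)
stomach contents of two coexisting fishes (juvenile Atlantic salmon and
alpine bullhead), and (iii) three-pass removal electrofishing catches.

Mechanism built in: each site's prey pool is a draw from a symmetric
Dirichlet whose concentration is solved (by bisection on the closed-form
expected entropy of a Dirichlet, psi(k a + 1) - psi(a + 1) in nats) to hit
a target Shannon diversity.  The two species' diet preferences start from
the pool and are pushed apart by exponential tilting with strength
``partition_strength * H'``: at diverse sites the species specialize on
different prey, so expected dietary overlap declines with prey diversity —
the ground truth the downstream models should recover.  Salmon additionally
take surface prey with a configurable bias; bullhead mostly do not.

Per fish, total fullness is scored on a 0-100 scale in steps of 5
(mimicking visual estimation) and split over prey by a Dirichlet-multinomial
draw around the species diet; empty stomachs occur with a small
probability.  Removal catches are sequential binomial thinnings of a true
population size with a common capture probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy import optimize, special

from .abundance_estimation import zippin_estimate
from .community_metrics import community_profile, shannon_diversity
from .diet_metrics import percent_prey_abundance, percentage_overlap
from .io_tables import (
    BenthosSample,
    PreyTaxon,
    RemovalCatch,
    StomachRecord,
    Taxonomy,
    ValidationError,
)

SPECIES = ("salmon", "bullhead")


@dataclass
class SimulationConfig:
    """Study-level knobs for the generator; defaults mirror the survey design.

    Eleven sites, Shannon diversity (base 10) spanning 0.5-0.98, three kick
    replicates of 2.25 m^2, three electrofishing passes, fullness scored in
    steps of 5 with a 5% empty-stomach rate.
    """

    n_sites: int = 11
    taxa_pool: int = 20
    n_surface_taxa: int = 3
    diversity_range: tuple[float, float] = (0.5, 0.98)
    partition_strength: float = 2.0
    fish_per_site: dict[str, int] = dc_field(
        default_factory=lambda: {"salmon": 30, "bullhead": 60}
    )
    capture_prob: float = 0.6
    passes: int = 3
    benthos_individuals: int = 600
    kick_replicates: int = 3
    kick_area_m2: float = 2.25
    site_area_m2: float = 400.0
    stomach_sample: int = 15
    fullness_mean: float = 50.0
    empty_stomach_prob: float = 0.05
    surface_prey_bias: dict[str, float] = dc_field(
        default_factory=lambda: {"salmon": 0.3, "bullhead": 0.02}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.diversity_range
        if not 0 <= lo <= hi <= math.log10(self.taxa_pool):
            raise ValidationError(
                f"diversity range {self.diversity_range} outside "
                f"[0, log10({self.taxa_pool})]"
            )
        if not 0 < self.capture_prob <= 1:
            raise ValidationError("capture_prob must be in (0, 1]")


@dataclass
class SiteTruth:
    """Ground truth behind one simulated site."""

    site: str
    target_H: float
    pool: dict[str, float]
    diet_preferences: dict[str, dict[str, float]]
    expected_overlap: float
    true_N: dict[str, int]
    capture_prob: float


@dataclass
class SimulatedSite:
    benthos: list[BenthosSample]
    stomachs: list[StomachRecord]
    removals: list[RemovalCatch]
    truth: SiteTruth


def dirichlet_concentration_for_H(
    target_H: float, k: int, base: float = 10.0, tol: float = 1e-4
) -> float:
    """Symmetric-Dirichlet concentration whose expected Shannon H' hits target.

    Uses the closed form E[H_nats] = psi(k a + 1) - psi(a + 1) and brackets
    the root; expected H' is increasing in the concentration a.
    """
    target_nats = target_H * math.log(base)
    if not 0 < target_nats < math.log(k):
        raise ValidationError(
            f"target H'={target_H:g} unreachable with {k} taxa (base {base:g})"
        )

    def expected_H(log_a: float) -> float:
        a = math.exp(log_a)
        return special.digamma(k * a + 1) - special.digamma(a + 1)

    lo, hi = -12.0, 12.0
    if expected_H(lo) > target_nats or expected_H(hi) < target_nats:
        raise ValidationError(f"target H'={target_H:g} outside bracketable range")
    log_a = optimize.brentq(
        lambda la: expected_H(la) - target_nats, lo, hi, xtol=1e-10
    )
    a = math.exp(log_a)
    if abs(expected_H(log_a) - target_nats) > tol * math.log(base):
        raise ValidationError("concentration solve did not reach tolerance")
    return a


def make_taxonomy(config: SimulationConfig) -> Taxonomy:
    """Invented taxon labels: aquatic taxa cycled over the seven groups, plus surface."""
    from .io_tables import AQUATIC_GROUPS, SURFACE_GROUP

    taxa = []
    n_aquatic = config.taxa_pool
    for i in range(n_aquatic):
        group = AQUATIC_GROUPS[i % len(AQUATIC_GROUPS)]
        taxa.append(PreyTaxon(f"taxon_{i:02d}", group, False))
    for j in range(config.n_surface_taxa):
        taxa.append(PreyTaxon(f"surface_{j:02d}", SURFACE_GROUP, True))
    return Taxonomy(taxa)


def _tilt(pool: np.ndarray, direction: np.ndarray, strength: float) -> np.ndarray:
    """Exponential tilting of a simplex vector; strength 0 returns the pool."""
    w = pool * np.exp(strength * direction)
    return w / w.sum()


def species_diet_preferences(
    pool: np.ndarray,
    H: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Per-species diet preference over aquatic + surface taxa.

    A shared random +/-1 contrast pushes the two species toward opposite
    halves of the prey pool with strength partition_strength * H', then each
    species' aquatic mass is scaled down by its surface-prey bias and the
    remainder spread uniformly over surface taxa.
    """
    k = len(pool)
    contrast = rng.choice([-1.0, 1.0], size=k)
    diets = {}
    for sign, sp in zip((+1.0, -1.0), SPECIES):
        aquatic = _tilt(pool, sign * contrast, config.partition_strength * H)
        s_bias = config.surface_prey_bias.get(sp, 0.0)
        surface = np.full(config.n_surface_taxa, s_bias / max(config.n_surface_taxa, 1))
        diets[sp] = np.concatenate([(1.0 - s_bias) * aquatic, surface])
    return diets


def simulate_site(
    config: SimulationConfig, site_index: int, taxonomy: Taxonomy | None = None
) -> SimulatedSite:
    """Generate benthos, stomach and removal data for one site.

    Deterministic given (config, site_index): the RNG stream is spawned from
    ``config.seed`` and the site index.
    """
    if taxonomy is None:
        taxonomy = make_taxonomy(config)
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(config.n_sites + 1)[site_index]
    )
    site = f"S{site_index + 1:02d}"
    lo, hi = config.diversity_range
    frac = site_index / max(config.n_sites - 1, 1)
    target_H = lo + (hi - lo) * frac

    alpha = dirichlet_concentration_for_H(target_H, config.taxa_pool)
    pool = rng.dirichlet(np.full(config.taxa_pool, alpha))
    pool = np.maximum(pool, 1e-12)
    pool = pool / pool.sum()

    aquatic_names = [t for t in taxonomy.names if not taxonomy.is_surface(t)]
    surface_names = [t for t in taxonomy.names if taxonomy.is_surface(t)]
    assert len(aquatic_names) == config.taxa_pool

    # benthos: multinomial draws of the pool split over replicates
    benthos = []
    per_rep = config.benthos_individuals // config.kick_replicates
    for rep in range(1, config.kick_replicates + 1):
        counts = rng.multinomial(per_rep, pool)
        benthos.append(
            BenthosSample(
                site=site,
                replicate=rep,
                counts={t: int(c) for t, c in zip(aquatic_names, counts) if c > 0},
                area_m2=config.kick_area_m2,
            )
        )

    diets = species_diet_preferences(pool, target_H, config, rng)
    all_names = aquatic_names + surface_names

    stomachs = []
    for sp in SPECIES:
        pref = diets[sp]
        for i in range(config.stomach_sample):
            fish_id = f"{site}_{sp}_{i:03d}"
            length = float(np.round(rng.uniform(45, 99), 1))
            if rng.random() < config.empty_stomach_prob:
                stomachs.append(
                    StomachRecord(fish_id, site, sp, length, 0.0, {})
                )
                continue
            # visual 0-100 fullness in steps of 5, never 0 for a feeding fish
            fullness = 5.0 * int(
                np.clip(round(rng.normal(config.fullness_mean, 20) / 5), 1, 20)
            )
            support = np.flatnonzero(pref > 1e-6)
            props = np.zeros_like(pref)
            props[support] = rng.dirichlet(50.0 * pref[support])
            # keep the 6 largest prey per stomach: real stomachs hold few taxa
            keep = np.argsort(props)[-6:]
            trimmed = np.zeros_like(props)
            trimmed[keep] = props[keep]
            trimmed /= trimmed.sum()
            points = {
                all_names[j]: float(fullness * trimmed[j])
                for j in np.flatnonzero(trimmed)
            }
            # force exact sum to the scored total against float drift
            drift = fullness - sum(points.values())
            points[max(points, key=points.get)] += drift
            stomachs.append(
                StomachRecord(fish_id, site, sp, length, float(fullness), points)
            )

    removals = []
    true_N = {}
    for sp in SPECIES:
        N = config.fish_per_site.get(sp, 0)
        true_N[sp] = N
        remaining = N
        catches = []
        for _ in range(config.passes):
            c = int(rng.binomial(remaining, config.capture_prob))
            catches.append(c)
            remaining -= c
        removals.append(
            RemovalCatch(site=site, species=sp, catches=catches, area_m2=config.site_area_m2)
        )

    expected_overlap = 100.0 * float(
        np.minimum(diets[SPECIES[0]], diets[SPECIES[1]]).sum()
    )
    truth = SiteTruth(
        site=site,
        target_H=target_H,
        pool={t: float(p) for t, p in zip(aquatic_names, pool)},
        diet_preferences={
            sp: {t: float(v) for t, v in zip(all_names, diets[sp])} for sp in SPECIES
        },
        expected_overlap=expected_overlap,
        true_N=true_N,
        capture_prob=config.capture_prob,
    )
    return SimulatedSite(benthos=benthos, stomachs=stomachs, removals=removals, truth=truth)


def simulate_study(
    config: SimulationConfig,
) -> tuple[Taxonomy, list[SimulatedSite]]:
    """Simulate every site of a study under one config."""
    taxonomy = make_taxonomy(config)
    return taxonomy, [
        simulate_site(config, i, taxonomy) for i in range(config.n_sites)
    ]


def recover_parameters(sites: Sequence[SimulatedSite]) -> dict:
    """Compare pipeline estimates against the generator's ground truth.

    Reports the mean relative bias of the Zippin abundance estimate, the
    mean absolute error of benthos Shannon diversity against its target, and
    the observed diversity-overlap relationship across sites.
    """
    n_bias = []
    h_err = []
    h_pool_err = []
    H_obs, overlap_obs = [], []
    for s in sites:
        for rc in s.removals:
            if rc.total >= 1:
                est = zippin_estimate(rc)
                truth_N = s.truth.true_N[rc.species]
                if truth_N > 0:
                    n_bias.append((est.N_hat - truth_N) / truth_N)
        profile = community_profile(s.benthos)
        h_err.append(abs(profile.diversity_H - s.truth.target_H))
        h_pool_err.append(
            abs(profile.diversity_H - shannon_diversity(s.truth.pool))
        )
        H_obs.append(profile.diversity_H)
        by_sp = {}
        for sp in SPECIES:
            recs = [r for r in s.stomachs if r.species == sp]
            by_sp[sp] = percent_prey_abundance(recs)
        overlap_obs.append(percentage_overlap(by_sp[SPECIES[0]], by_sp[SPECIES[1]]))
    slope = float(np.polyfit(H_obs, overlap_obs, 1)[0]) if len(H_obs) > 2 else math.nan
    return {
        "zippin_mean_relative_bias": float(np.mean(n_bias)) if n_bias else math.nan,
        "shannon_mean_abs_error": float(np.mean(h_err)),
        "shannon_vs_pool_mean_abs_error": float(np.mean(h_pool_err)),
        "diversity_overlap_slope": slope,
        "observed_H": H_obs,
        "observed_overlap": overlap_obs,
    }
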