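"""End-to-end orchestration: raw field tables -> site summary -> models.

The pipeline can start either from the raw tables (stomach, benthos,
removal, taxonomy CSVs) or from a precomputed per-site summary — the latter
matters because published surveys often print only the site-level matrix.
Every stage writes its intermediate table so stages are individually
re-runnable, and all outputs are sorted by site label so a rerun with the
same seed reproduces files byte-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abundance_estimation import zippin_estimate
from .community_metrics import community_profiles
from .diet_metrics import (
    aquatic_overlap,
    levins_breadth,
    percent_prey_abundance,
    percentage_overlap,
    specialization_prevalence,
    surface_fraction,
)
from .io_tables import (
    SITE_SUMMARY_COLUMNS,
    Taxonomy,
    ValidationError,
    read_benthos_table,
    read_removal_table,
    read_site_summary,
    read_stomach_table,
    read_taxonomy,
    write_site_summary,
)
from .model_selection import (
    CANDIDATE_VARIABLES,
    ModelSpec,
    fit_lmm,
    forward_stepwise,
    parametric_bootstrap,
    pearson,
    rank_models,
)

log = logging.getLogger("troph")

SPECIES_COLUMNS = {"salmon": "salmon", "bullhead": "bullhead"}


@dataclass
class PipelineConfig:
    """Paths and options for a full pipeline run."""

    out_dir: Path
    stomach_path: Path | None = None
    benthos_path: Path | None = None
    removal_path: Path | None = None
    taxonomy_path: Path | None = None
    site_summary_path: Path | None = None
    response: str = "overlap_total"
    taxonomic_resolution: str = "fine"
    bootstrap_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.bootstrap_reps < 0:
            raise ValidationError("bootstrap_reps must be >= 0")
        if self.response not in ("overlap_total", "overlap_aquatic"):
            raise ValidationError(f"unknown response {self.response!r}")


def build_site_summary(
    stomachs, benthos, removals, taxonomy: Taxonomy
) -> pd.DataFrame:
    """Compute the per-site summary matrix from raw records."""
    profiles = {p.site: p for p in community_profiles(benthos)}
    sites = sorted(profiles)
    removal_by = {(r.site, r.species): r for r in removals}
    rows = []
    for site in sites:
        try:
            prof = profiles[site]
            site_stomachs = [r for r in stomachs if r.site == site]
            by_sp = {
                sp: [r for r in site_stomachs if r.species == sp]
                for sp in SPECIES_COLUMNS
            }
            comps = {sp: percent_prey_abundance(by_sp[sp]) for sp in by_sp}
            spec_res = {sp: specialization_prevalence(by_sp[sp]) for sp in by_sp}
            row = {
                "site": site,
                "prey_diversity": prof.diversity_H,
                "prey_abundance": prof.abundance_per_m2,
                "density_trout": 0.0,
                "density_charr": 0.0,
            }
            density_total = 0.0
            for sp in SPECIES_COLUMNS:
                rc = removal_by.get((site, sp))
                dens = zippin_estimate(rc).density_per_100m2 if rc and rc.total else 0.0
                row[f"density_{sp}"] = dens
                density_total += dens
                row[f"levins_{sp}"] = levins_breadth(comps[sp])
                row[f"one_minus_is_{sp}_mean"] = spec_res[sp].prevalence
                row[f"one_minus_is_{sp}_sd"] = spec_res[sp].sd_psi
                row[f"surface_{sp}"] = surface_fraction(by_sp[sp], taxonomy)
                row[f"n_{sp}"] = len(by_sp[sp])
            row["density_total"] = density_total
            row["overlap_total"] = percentage_overlap(comps["salmon"], comps["bullhead"])
            row["overlap_aquatic"] = aquatic_overlap(
                by_sp["salmon"], by_sp["bullhead"], taxonomy
            )
        except ValidationError as err:
            raise ValidationError(f"site summary failed at site {site}: {err}") from err
        rows.append(row)
    return pd.DataFrame(rows)[SITE_SUMMARY_COLUMNS]


def correlation_table(summary: pd.DataFrame, response: str) -> pd.DataFrame:
    """Pearson r and p of every available candidate variable vs the response."""
    rows = []
    for var in CANDIDATE_VARIABLES:
        if var not in summary.columns:
            continue
        x = summary[var].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            continue
        res = pearson(x, summary[response].to_numpy(dtype=float))
        rows.append({"variable": var, "r": res.r, "p": res.p, "n": res.n})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns a dict with the in-memory results (summary frame, correlation
    table, model ranking, best fit, bootstrap summary).
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    if config.site_summary_path is not None:
        summary = read_site_summary(config.site_summary_path)
        log.info("loaded site summary with %d sites", len(summary))
    else:
        for name in ("stomach_path", "benthos_path", "removal_path", "taxonomy_path"):
            p = getattr(config, name)
            if p is None or not Path(p).exists():
                raise ValidationError(f"input stage: missing or absent {name}: {p}")
        taxonomy = read_taxonomy(config.taxonomy_path)
        stomachs = read_stomach_table(config.stomach_path, taxonomy)
        benthos = read_benthos_table(config.benthos_path)
        removals = read_removal_table(config.removal_path)
        summary = build_site_summary(stomachs, benthos, removals, taxonomy)
    summary = summary.sort_values("site", kind="mergesort").reset_index(drop=True)
    write_site_summary(summary, out / "site_summary.csv")

    corr = correlation_table(summary, config.response)
    corr.to_csv(out / "correlations.csv", index=False, float_format="%.4g")

    candidates = [v for v in corr["variable"]]
    selected = forward_stepwise(summary, candidates, config.response)
    log.info("forward selection kept %s", selected or "nothing")
    rank_vars = selected if selected else candidates
    ranking = rank_models(summary, rank_vars, config.response)
    ranking.to_csv(out / "model_ranking.csv", index=False, float_format="%.4g")

    best_terms = ranking["model"].iloc[0].split(" + ")
    best = fit_lmm(ModelSpec(config.response, best_terms), summary, method="reml")
    coef = pd.DataFrame(
        [{"term": t, **v} for t, v in best.coefficients.items()]
    )
    coef.to_csv(out / "best_model_coefficients.csv", index=False, float_format="%.6g")

    boot = None
    if config.bootstrap_reps > 0:
        boot = parametric_bootstrap(
            best, summary, n_boot=config.bootstrap_reps, seed=config.seed
        )
        (out / "bootstrap_summary.json").write_text(
            json.dumps(
                {
                    "n_boot": boot.n_boot,
                    "slope_mean": boot.slope_mean,
                    "slope_sd": boot.slope_sd,
                    "slope_ci_2.5": boot.slope_ci[0],
                    "slope_ci_97.5": boot.slope_ci[1],
                    "sign_consistency": boot.sign_consistency,
                    "r_mean": boot.r_mean,
                    "seed": boot.seed,
                },
                indent=2,
            )
            + "\n"
        )

    (out / "run_log.json").write_text(
        json.dumps(
            {
                "troph_version": __version__,
                "seed": config.seed,
                "response": config.response,
                "n_sites": int(len(summary)),
                "selected_variables": selected,
                "best_model": ranking["model"].iloc[0],
                "best_AICc": float(ranking["AICc"].iloc[0]),
            },
            indent=2,
        )
        + "\n"
    )
    return {
        "summary": summary,
        "correlations": corr,
        "ranking": ranking,
        "best_fit": best,
        "bootstrap": boot,
    }
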