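"""End-to-end driver: table in, niche metrics and overlap matrices out.

Stages: validate -> lipid-correct -> per-group Mardia check and Layman
ranges -> Bayesian posterior fit per group -> posterior volume summaries
at the working coverage -> pairwise posterior overlap within each area
(never across areas) -> significance flags at the 60% threshold.

Groups below the minimum sample size are reported and skipped, not
errors: surveys routinely yield singleton groups.  Normality verdicts
are reported, never used to auto-exclude; whether a flagged group stays
in is an analyst's call.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bayes as bayes_mod
from . import prep
from .model import IsotopeNicheModel

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("isoniche")


@dataclasses.dataclass
class PipelineConfig:
    """Settings for one pipeline run; mirrors the CLI flags.

    Volume-posterior sampler defaults are 15000/10000/25
    (iterations/burn-in/thin); the overlap posterior uses the shorter
    7500/5000 chain with no thinning, optionally subsampled via
    ``max_overlap_draws`` since every retained draw pair costs a mesh
    intersection.
    """

    coverage: float = 0.75
    iterations: int = bayes_mod.DEFAULT_ITERATIONS
    burn_in: int = bayes_mod.DEFAULT_BURN_IN
    thin: int = bayes_mod.DEFAULT_THIN
    overlap_iterations: int = bayes_mod.OVERLAP_ITERATIONS
    overlap_burn_in: int = bayes_mod.OVERLAP_BURN_IN
    overlap_thin: int = bayes_mod.OVERLAP_THIN
    subdivision: int = 4
    max_overlap_draws: int | None = None
    seed: int | None = None
    min_n: int = 4
    alpha: float = 0.05
    compute_overlap: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class PipelineResult:
    """Bundle of pipeline outputs (also written as CSVs when requested)."""

    table: pd.DataFrame
    metrics: pd.DataFrame
    volumes: pd.DataFrame
    overlap_long: pd.DataFrame
    overlap_matrices: dict[str, pd.DataFrame]
    exclusions: list[tuple]
    config: PipelineConfig


def _format_cell(median: float, lo: float, hi: float) -> str:
    return f"{median:.0f} ({lo:.0f}-{hi:.0f})"


def _overlap_matrix(
    long: pd.DataFrame, species: list[str]
) -> pd.DataFrame:
    mat = pd.DataFrame("", index=species, columns=species)
    for sp in species:
        mat.loc[sp, sp] = "-"
    for row in long.itertuples():
        mat.loc[row.group_a, row.group_b] = _format_cell(
            row.percent_of_a, row.lo, row.hi
        )
        mat.loc[row.group_b, row.group_a] = _format_cell(
            row.percent_of_b, row.lo_ba, row.hi_ba
        )
    return mat


def run_pipeline(
    table: pd.DataFrame,
    config: PipelineConfig | None = None,
    output_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full niche analysis on an isotope table.

    Returns all result frames; when ``output_dir`` is given, also writes
    ``metrics.csv``, ``volumes.csv``, ``overlap_long.csv``, one
    ``overlap_<area>.csv`` matrix per area, ``exclusions.csv``,
    ``config.yaml`` and ``run.log``.
    """
    config = config or PipelineConfig()
    out = Path(output_dir) if output_dir is not None else None
    old_level = logger.level
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(handler)
        if logger.getEffectiveLevel() > logging.INFO:
            logger.setLevel(logging.INFO)
    try:
        return _run(table, config, out)
    finally:
        if out is not None:
            handler.close()
            logger.removeHandler(handler)
            logger.setLevel(old_level)


def _run(
    table: pd.DataFrame, config: PipelineConfig, out: Path | None
) -> PipelineResult:
    seed_seq = np.random.SeedSequence(config.seed)
    logger.info("pipeline start: %d rows, seed=%s", len(table), config.seed)

    clean, exclusions = prep.validate_table(table)
    for idx, reason in exclusions:
        logger.info("excluded row %s: %s", idx, reason)
    clean = prep.lipid_correct_table(clean)
    logger.info(
        "lipid correction applied to %d of %d rows",
        int(clean["lipid_corrected"].sum()),
        len(clean),
    )

    metrics_rows = []
    volume_rows = []
    fits: dict[tuple[str, str], bayes_mod.PosteriorDraws] = {}
    group_exclusions: list[tuple] = list(exclusions)

    groups = clean.groupby(["area", "species"], sort=True)
    group_seeds = {
        key: seed for key, seed in zip(
            sorted(groups.groups), seed_seq.spawn(len(groups.groups))
        )
    }
    for (area, species), sub in groups:
        n = len(sub)
        if n < config.min_n:
            reason = (
                f"group below minimum sample size ({n} < {config.min_n})"
            )
            logger.info("skipped %s / %s: %s", species, area, reason)
            group_exclusions.append(((species, area), reason))
            continue
        model = IsotopeNicheModel.from_dataframe(
            sub, label=f"{species} ({area})"
        )
        res = model.fit()
        ranges = res.layman_ranges()
        row = {
            "species": species,
            "area": area,
            "n": n,
            "CR": ranges.cr,
            "NR": ranges.nr,
            "SR": ranges.sr,
            "SEV": res.sev,
            "SEV_C": res.sev_c,
        }
        if n >= 5:
            mardia = res.mardia(alpha=config.alpha)
            row.update(
                mardia_skew_p=mardia.skew_p,
                mardia_kurt_p=mardia.kurt_p,
                mardia_normal=mardia.normal,
            )
            if not mardia.normal:
                logger.info(
                    "%s / %s departs from multivariate normality "
                    "(skew p=%.3f, kurt p=%.3f); retained",
                    species, area, mardia.skew_p, mardia.kurt_p,
                )
        metrics_rows.append(row)

        child = np.random.default_rng(group_seeds[(area, species)])
        bres = model.fit_bayes(
            iterations=config.iterations,
            burn_in=config.burn_in,
            thin=config.thin,
            seed=child,
        )
        vs = bres.volume_summary(coverage=config.coverage)
        volume_rows.append(
            {
                "species": species,
                "area": area,
                "n": n,
                "coverage": config.coverage,
                "median_EV_B": vs.median,
                "iqr_25": vs.iqr_25,
                "iqr_75": vs.iqr_75,
                "n_draws": vs.n_draws,
            }
        )
        # Overlap uses its own (shorter) chain, refit with the same seed
        # stream so the run stays reproducible end to end.
        if config.compute_overlap:
            fits[(area, species)] = bayes_mod.fit_posterior(
                model.endog,
                iterations=config.overlap_iterations,
                burn_in=config.overlap_burn_in,
                thin=config.overlap_thin,
                seed=np.random.default_rng(group_seeds[(area, species)].spawn(1)[0]),
            )

    metrics = pd.DataFrame(metrics_rows)
    volumes = pd.DataFrame(volume_rows)

    overlap_rows = []
    matrices: dict[str, pd.DataFrame] = {}
    if config.compute_overlap:
        sub_seq = seed_seq.spawn(1)[0]
        for area in sorted({a for a, _ in fits}):
            species_here = sorted(s for a, s in fits if a == area)
            for i, sp_a in enumerate(species_here):
                for sp_b in species_here[i + 1:]:
                    post = bayes_mod.overlap_posterior(
                        fits[(area, sp_a)],
                        fits[(area, sp_b)],
                        coverage=config.coverage,
                        subdivision=config.subdivision,
                        max_draws=config.max_overlap_draws,
                        seed=np.random.default_rng(sub_seq.spawn(1)[0]),
                    )
                    overlap_rows.append(
                        {
                            "area": area,
                            "group_a": sp_a,
                            "group_b": sp_b,
                            "percent_of_a": post.median_ab,
                            "lo": post.ci_ab[0],
                            "hi": post.ci_ab[1],
                            "percent_of_b": post.median_ba,
                            "lo_ba": post.ci_ba[0],
                            "hi_ba": post.ci_ba[1],
                            "significant_a_in_b": post.significant_ab,
                            "significant_b_in_a": post.significant_ba,
                            "subdivision": post.subdivision,
                        }
                    )
            area_long = pd.DataFrame(
                [r for r in overlap_rows if r["area"] == area]
            )
            if not area_long.empty:
                matrices[area] = _overlap_matrix(area_long, species_here)
    overlap_long = pd.DataFrame(overlap_rows)

    result = PipelineResult(
        table=clean,
        metrics=metrics,
        volumes=volumes,
        overlap_long=overlap_long,
        overlap_matrices=matrices,
        exclusions=group_exclusions,
        config=config,
    )
    if out is not None:
        _write_outputs(result, out)
    logger.info(
        "pipeline done: %d groups fitted, %d overlap pairs",
        len(volumes), len(overlap_long),
    )
    return result


def _write_outputs(result: PipelineResult, out: Path) -> None:
    result.metrics.to_csv(out / "metrics.csv", index=False)
    result.volumes.to_csv(out / "volumes.csv", index=False)
    result.overlap_long.to_csv(out / "overlap_long.csv", index=False)
    for area, mat in result.overlap_matrices.items():
        mat.to_csv(out / f"overlap_{area}.csv")
    pd.DataFrame(
        [{"group": str(g), "reason": r} for g, r in result.exclusions]
    ).to_csv(out / "exclusions.csv", index=False)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(result.config.to_dict(), fh, sort_keys=True)
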