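"""End-to-end orchestration: fields + population + regions -> indicator bundle.

``run_pipeline`` chains the stages: population-weighted regional series,
WHO-guideline exceedance and exposure-time indicators, clean-air
classification and population tallies, compound-episode accounting, and
nonparametric trends.  Outputs are plain CSV/JSON; given identical inputs
and seed the bundle is reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .grids import ConcentrationField, PopulationGrid, RegionSet, pw_regional_series
from .indicators import (
    GuidelineSet,
    O3_INTERIM_TARGET_2,
    PollutantGuideline,
    WHO_2021,
    classify_long_term,
    classify_short_term,
    daily_exceedance,
    peak_season_mean,
    population_in_clean_air,
    unclean_exposure_time,
)
from .compound import (
    compound_exposure_by_category,
    compound_exposure_time,
    compound_mask,
    compound_composition,
    population_with_any_compound,
    compound_share_of_unclean,
    seasonal_profile,
)
from .trends import trend_table

__all__ = ["PipelineConfig", "run_pipeline", "with_o3_interim_target"]


def with_o3_interim_target(gs: GuidelineSet = WHO_2021) -> GuidelineSet:
    """Guideline set with the O3 long-term limit replaced by interim
    target 2 (70 µg/m³), the reference threshold used where almost no
    area meets the 60 µg/m³ peak-season AQG."""
    limits = dict(gs.limits)
    if "O3" in limits:
        g = limits["O3"]
        limits["O3"] = PollutantGuideline(
            g.short_term_limit, O3_INTERIM_TARGET_2, long_term_basis=g.long_term_basis
        )
    return GuidelineSet(limits=limits, compliance_fraction=gs.compliance_fraction)


@dataclass
class PipelineConfig:
    """Configuration of a pipeline run.

    Either ``simulate`` (keyword arguments of
    :class:`airexposure.synth.SimulationConfig`) or the three input paths
    must be provided.  ``classification_mode`` selects region- or
    cell-level clean-air classification for population tallies.
    """

    field_paths: dict[str, str] | None = None
    population_path: str | None = None
    regions_path: str | None = None
    guideline_path: str | None = None
    simulate: dict | None = None
    n_population_clusters: int = 5
    total_population: int = 1_000_000
    region_layout: tuple[int, int] = (3, 3)
    years: list[int] | None = None
    classification_mode: str = "region"
    compound_population_mode: str = "cell"
    use_o3_interim_target: bool = True
    exclude_years: list[int] = dc_field(default_factory=list)
    alpha: float = 0.05
    seed: int = 0
    output_dir: str | None = None

    def config_hash(self) -> str:
        doc = asdict(self)
        doc.pop("output_dir", None)  # where outputs land does not change them
        payload = json.dumps(doc, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_inputs(config: PipelineConfig):
    from . import io as aio
    from .synth import SimulationConfig, make_population, make_regions, simulate_fields

    if config.simulate is not None:
        sim = SimulationConfig(**{**config.simulate, "rng_seed": config.seed})
        fields = simulate_fields(sim)
        grid = sim.grid
        pop = make_population(
            grid,
            n_clusters=config.n_population_clusters,
            total_pop=config.total_population,
            seed=config.seed + 1,
        )
        regions = make_regions(grid, *config.region_layout)
    else:
        if not (config.field_paths and config.population_path and config.regions_path):
            raise ValueError("provide either simulate= or all three input paths")
        fields = {p: aio.read_field(path, pollutant=p)
                  for p, path in config.field_paths.items()}
        pop = aio.read_population(config.population_path)
        any_field = next(iter(fields.values()))
        regions = aio.read_regions(config.regions_path, grid=any_field.grid)
    if config.guideline_path:
        guidelines = aio.read_guidelines(config.guideline_path)
    else:
        guidelines = with_o3_interim_target() if config.use_o3_interim_target else WHO_2021
    for p in fields:
        guidelines[p]  # raises with a clear message when a pollutant lacks limits
    return fields, pop, regions, guidelines


def _region_population(regions: RegionSet, pop: PopulationGrid) -> pd.Series:
    return pd.Series(
        {r: float((regions.cell_weights(r) * pop.counts).sum())
         for r in regions.region_ids},
        name="population",
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full exposure-assessment pipeline.

    Returns a bundle dict with the PW series, exposure table, clean-air
    population tallies, compound tables, trend tables and a JSON-able run
    report; when ``config.output_dir`` is set every table is also written
    as CSV (plus ``report.json``).
    """
    captured: list[str] = []
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        bundle = _run(config)
        captured = sorted({str(w.message) for w in wrec})
    bundle["report"]["warnings"] = captured
    if config.output_dir:
        _write_bundle(bundle, Path(config.output_dir))
    return bundle


def _run(config: PipelineConfig) -> dict:
    fields, pop, regions, guidelines = _load_inputs(config)
    pollutants = list(fields.keys())
    region_pop = _region_population(regions, pop)
    years = config.years
    if years is None:
        years = sorted(next(iter(fields.values())).years.tolist())

    # --- population-weighted regional series -----------------------------
    pw = {p: pw_regional_series(fields[p], pop, regions) for p in pollutants}
    pw_long = pd.concat(
        [
            df.stack().rename("pw_value").reset_index().assign(pollutant=p).rename(
                columns={"level_0": "date", "level_1": "region_id"}
            )
            for p, df in pw.items()
        ],
        ignore_index=True,
    )[["region_id", "date", "pollutant", "pw_value"]]

    # annual PW means per region, and continental population-weighted mean
    annual_pw = {}
    continental_pw = {}
    w = region_pop / region_pop.sum()
    for p in pollutants:
        ann = pw[p].groupby(pw[p].index.year).mean()
        ann = ann.loc[ann.index.isin(years)]
        annual_pw[p] = ann
        continental_pw[p] = ann.mul(w, axis=1).sum(axis=1)
    continental = pd.DataFrame(continental_pw)
    continental.index.name = "year"

    # --- short-term indicators -------------------------------------------
    exceed = {p: daily_exceedance(fields[p], guidelines[p].short_term_limit)
              for p in pollutants}
    exposure_rows = []
    clean_pop_rows = []
    for p in pollutants:
        g = guidelines[p]
        for year in years:
            days_in_year = int((fields[p].dates.year == year).sum())
            expo = unclean_exposure_time(exceed[p], pop, regions, year=year)
            short = classify_short_term(
                expo, days_in_year=days_in_year,
                compliance_fraction=guidelines.compliance_fraction,
            )
            if g.long_term_basis == "peak_season":
                yearly = pw[p].loc[pw[p].index.year == year]
                metric = pd.Series(
                    {r: peak_season_mean(yearly[r]) for r in regions.region_ids}
                )
            else:
                metric = annual_pw[p].loc[year]
            long = pd.Series(
                {r: classify_long_term(float(metric[r]), g.long_term_limit)
                 for r in regions.region_ids}
            )
            for r in regions.region_ids:
                exposure_rows.append(
                    {
                        "region_id": r,
                        "year": year,
                        "pollutant": p,
                        "exposure_days": expo[r],
                        "population": region_pop[r],
                        "long_term_metric": float(metric[r]),
                        "clean_short": short[r],
                        "clean_long": long[r],
                    }
                )
            pct_s, persons_s = population_in_clean_air(short, regions, pop)
            pct_l, persons_l = population_in_clean_air(long, regions, pop)
            clean_pop_rows.append(
                {
                    "year": year,
                    "pollutant": p,
                    "clean_short_pct": pct_s,
                    "clean_short_persons": persons_s,
                    "clean_long_pct": pct_l,
                    "clean_long_persons": persons_l,
                }
            )
    exposure_table = pd.DataFrame(exposure_rows)
    clean_pop = pd.DataFrame(clean_pop_rows)

    # --- compound episodes ------------------------------------------------
    cf = compound_mask(exceed)
    compound_rows = []
    any_rows = []
    for year in years:
        cat_table = compound_exposure_by_category(cf, pop, regions, year=year)
        any_expo = compound_exposure_time(cf, pop, regions, year=year)
        for r in regions.region_ids:
            for label in cat_table.columns:
                compound_rows.append(
                    {
                        "region_id": r,
                        "year": year,
                        "category": label,
                        "exposure_days": cat_table.loc[r, label],
                    }
                )
            compound_rows.append(
                {
                    "region_id": r,
                    "year": year,
                    "category": "any",
                    "exposure_days": any_expo[r],
                }
            )
        any_rows.append(
            {
                "year": year,
                "any_compound_days_pw": float((any_expo * w).sum()),
                "population_pct_ge1_day": population_with_any_compound(
                    cf, pop, regions, year=year,
                    mode=config.compound_population_mode,
                ),
            }
        )
    compound_table = pd.DataFrame(compound_rows)
    compound_annual = pd.DataFrame(any_rows)

    # continental composition over the whole period
    cat_cont = (
        compound_table[compound_table["category"] != "any"]
        .merge(region_pop.rename("pop"), left_on="region_id", right_index=True)
        .assign(person_days=lambda d: d["exposure_days"] * d["pop"])
        .groupby("category")["person_days"].sum()
        / region_pop.sum()
    )
    composition = compound_composition(cat_cont) if len(cat_cont) else pd.Series(dtype=float)
    share = compound_share_of_unclean(exceed, cf, pop, regions)
    seasonal = seasonal_profile(cf, pop, regions)

    # --- trends ------------------------------------------------------------
    trends_continental = trend_table(
        continental, alpha=config.alpha, exclude_years=config.exclude_years
    )
    # PW continental exposure days per pollutant-year
    expo_cont = (
        exposure_table.assign(
            person_days=lambda d: d["exposure_days"] * d["population"]
        )
        .groupby(["year", "pollutant"])["person_days"].sum()
        .unstack("pollutant")
        / region_pop.sum()
    )
    trends_exposure = trend_table(
        expo_cont, alpha=config.alpha, exclude_years=config.exclude_years
    )

    report = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "pollutants": pollutants,
        "years": [int(y) for y in years],
        "n_regions": regions.n_regions,
        "total_population": pop.total,
        "data_coverage": cf.coverage,
        "classification_mode": config.classification_mode,
        "guidelines": {
            p: {
                "short_term_limit": guidelines[p].short_term_limit,
                "long_term_limit": guidelines[p].long_term_limit,
                "long_term_basis": guidelines[p].long_term_basis,
            }
            for p in pollutants
        },
    }
    return {
        "pw_series": pw_long,
        "pw_annual_continental": continental,
        "exposure_table": exposure_table,
        "clean_air_population": clean_pop,
        "compound_table": compound_table,
        "compound_annual": compound_annual,
        "compound_composition": composition,
        "compound_share_of_unclean": share,
        "seasonal_profile": seasonal,
        "trends_concentration": trends_continental,
        "trends_exposure": trends_exposure,
        "report": report,
    }


_CSV_UNITS_HEADER = {
    "pw_series": "# pw_value: ug/m3",
    "exposure_table": "# exposure_days: days; population: persons; long_term_metric: ug/m3",
    "clean_air_population": "# *_pct: percent of total population; *_persons: persons",
    "compound_table": "# exposure_days: days (population-weighted)",
    "compound_annual": "# any_compound_days_pw: days; population_pct_ge1_day: percent",
    "trends_concentration": "# slope: ug/m3 per year; pct_per_year: percent",
    "trends_exposure": "# slope: days per year; pct_per_year: percent",
}


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for name, obj in bundle.items():
        if name == "report":
            (outdir / "report.json").write_text(json.dumps(obj, indent=2, sort_keys=True))
            continue
        path = outdir / f"{name}.csv"
        header = _CSV_UNITS_HEADER.get(name)
        with open(path, "w") as fh:
            if header:
                fh.write(header + "\n")
            if isinstance(obj, pd.Series):
                obj.to_frame().to_csv(fh)
            else:
                obj.to_csv(fh, index=not isinstance(obj.index, pd.RangeIndex))
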