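"""End-to-end orchestration: ingestion, transforms, autocorrelation series,
model comparison and the report tables.

The reporting surfaces mirror the study's outputs: a coefficient-distribution
summary (AVG/MIN/LQ/MED/UQ/MAX per variable), a two-phase mean-coefficient
comparison with the B − A change column, per-year mean coefficient trends, and
per-city coefficient maps exportable onto GeoJSON geometries. The two default
phases split the decade at the 2017 birth-rate peak: the Fluctuation Phase
(2012–2016) and the Downward Phase (2017–2021).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import gtwr, spatial, synthetic
from .panel import (
    IngestionError,
    PanelDataset,
    TransformError,
    filter_complete,
    REQUIRED_COLUMNS,
)

__all__ = [
    "PhaseDefinition",
    "FLUCTUATION_PHASE",
    "DOWNWARD_PHASE",
    "load_panel",
    "compute_birth_rate",
    "apply_transforms",
    "annual_moran_series",
    "summarize_coefficients",
    "phase_comparison",
    "temporal_trend",
    "coefficient_map",
    "run_full_analysis",
    "DEFAULT_TRANSFORMS",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class PhaseDefinition:
    name: str
    years: frozenset[int]

    @classmethod
    def of(cls, name: str, years: Sequence[int]) -> "PhaseDefinition":
        return cls(name=name, years=frozenset(int(y) for y in years))


FLUCTUATION_PHASE = PhaseDefinition.of("fluctuation", range(2012, 2017))
DOWNWARD_PHASE = PhaseDefinition.of("downward", range(2017, 2022))


def load_panel(
    table: str | Path | pd.DataFrame,
    variable_names: Sequence[str] | None = None,
) -> PanelDataset:
    """Ingest a long-format city-year table, dropping incomplete rows.

    Rows missing any required field (coordinates, year, birth rate or a
    declared covariate) are dropped and counted (``dropped_count`` on the
    returned panel). Duplicate (city_id, year) keys raise
    :class:`IngestionError` listing the offenders; non-numeric fields raise
    with a row reference.
    """
    df = pd.read_csv(table) if not isinstance(table, pd.DataFrame) else table.copy()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise IngestionError(f"input table is missing required columns: {missing}")
    if variable_names is None:
        variable_names = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    numeric_cols = [c for c in list(REQUIRED_COLUMNS) + list(variable_names) if c != "city_id"]
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            rows = list(df.index[bad][:5])
            raise IngestionError(f"non-numeric values in column {col!r} at rows {rows}")
        df[col] = coerced
    df, dropped = filter_complete(df, list(REQUIRED_COLUMNS) + list(variable_names))
    logger.info("ingestion: kept %d records, dropped %d incomplete", len(df), dropped)
    panel = PanelDataset(data=df, variable_names=list(variable_names), dropped_count=dropped)
    return panel


def compute_birth_rate(births, average_population):
    """Birth rate in per-mille: 1000 * births / average annual population."""
    births = np.asarray(births, dtype=float)
    pop = np.asarray(average_population, dtype=float)
    if np.any(pop <= 0):
        raise ValueError("average_population must be positive")
    out = 1000.0 * births / pop
    return float(out) if out.ndim == 0 else out


#: Transform applied to each raw covariate column at ingestion. ``ln_per_10k``
#: divides by 10,000 before the log (GDP per capita arrives in yuan); share
#: and ratio variables pass through unchanged.
DEFAULT_TRANSFORMS: dict[str, str] = {
    "pgdp": "ln_per_10k",
    "ur": "identity",
    "urig": "identity",
    "fste": "identity",
    "aqi": "ln",
    "hp": "ln",
    "fee": "identity",
    "pbph": "ln",
    "hbpt": "ln",
}


def apply_transforms(
    panel: PanelDataset,
    transforms: Mapping[str, str] | None = None,
) -> PanelDataset:
    """Apply the analysis-scale variable transforms to a raw panel.

    Log transforms require strictly positive raw values; a violation raises
    :class:`TransformError` naming the city-year.
    """
    transforms = dict(DEFAULT_TRANSFORMS if transforms is None else transforms)
    df = panel.data.copy()
    log_entries = []
    for var in panel.variable_names:
        rule = transforms.get(var, "identity")
        if rule == "identity":
            continue
        vals = df[var].to_numpy(dtype=float)
        if rule == "ln_per_10k":
            vals = vals / 10_000.0
        elif rule != "ln":
            raise TransformError(f"unknown transform {rule!r} for variable {var!r}")
        bad = vals <= 0
        if bad.any():
            i = int(np.argmax(bad))
            raise TransformError(
                f"non-positive value for ln transform of {var!r} at "
                f"{df['city_id'].iloc[i]}/{int(df['year'].iloc[i])}"
            )
        df[var] = np.log(vals)
        log_entries.append(f"{var}: {rule}")
    return PanelDataset(
        data=df,
        variable_names=list(panel.variable_names),
        transform_log=list(panel.transform_log) + log_entries,
        truth=panel.truth,
        dropped_count=panel.dropped_count,
    )


def annual_moran_series(
    panel: PanelDataset,
    weights_recipe: Mapping | None = None,
    n_permutations: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Global Moran's I of the birth rate for each annual cross-section.

    Years with fewer than 3 cities are skipped with a warning. Returns a
    year-indexed frame: I, expected, z_score, p_analytic, p_permutation.
    """
    rows = []
    for year in panel.years:
        cs = panel.cross_section(year)
        if len(cs) < 3:
            warnings.warn(f"year {year}: fewer than 3 cities, skipped", UserWarning, stacklevel=2)
            continue
        W = spatial.weights_from_recipe(
            cs[["u", "v"]].to_numpy(), weights_recipe, ids=cs["city_id"].to_numpy()
        )
        res = spatial.morans_i(
            cs["birth_rate"].to_numpy(), W, n_permutations=n_permutations, seed=seed
        )
        rows.append(
            {
                "year": year,
                "I": res.statistic,
                "expected": res.expected_value,
                "z_score": res.z_score,
                "p_analytic": res.p_analytic,
                "p_permutation": res.p_permutation,
            }
        )
    return pd.DataFrame(rows).set_index("year")


def summarize_coefficients(fit: gtwr.GTWRFit) -> pd.DataFrame:
    """Coefficient-distribution summary: AVG, MIN, LQ, MED, UQ, MAX per
    variable over all local coefficients (quartiles by linear interpolation).
    The model adjusted R² is attached as frame metadata ``attrs['adjusted_r2']``."""
    if fit.n < 1:
        raise ValueError("fit carries no observations")
    co = fit.coefficients
    out = pd.DataFrame(
        {
            "AVG": co.mean(),
            "MIN": co.min(),
            "LQ": co.quantile(0.25, interpolation="linear"),
            "MED": co.quantile(0.50, interpolation="linear"),
            "UQ": co.quantile(0.75, interpolation="linear"),
            "MAX": co.max(),
        }
    )
    out.attrs["adjusted_r2"] = fit.adjusted_r2
    return out


def _phase_mask(fit: gtwr.GTWRFit, phase: PhaseDefinition) -> np.ndarray:
    years = fit.index["year"].to_numpy()
    return np.isin(years, list(phase.years))


def phase_comparison(
    fit: gtwr.GTWRFit,
    phase_a: PhaseDefinition = FLUCTUATION_PHASE,
    phase_b: PhaseDefinition = DOWNWARD_PHASE,
) -> pd.DataFrame:
    """Observation-weighted mean local coefficient per phase and the change.

    Returns a frame indexed by variable with columns named after the phases
    plus ``change`` = mean_B − mean_A (exact, before any display rounding).
    """
    if phase_a.years & phase_b.years:
        raise ValueError("phases must be disjoint")
    mask_a = _phase_mask(fit, phase_a)
    mask_b = _phase_mask(fit, phase_b)
    if not mask_a.any():
        raise ValueError(f"phase {phase_a.name!r} contains no observations")
    if not mask_b.any():
        raise ValueError(f"phase {phase_b.name!r} contains no observations")
    mean_a = fit.coefficients[mask_a].mean()
    mean_b = fit.coefficients[mask_b].mean()
    return pd.DataFrame(
        {phase_a.name: mean_a, phase_b.name: mean_b, "change": mean_b - mean_a}
    )


def temporal_trend(fit: gtwr.GTWRFit, weighting: str = "observation") -> pd.DataFrame:
    """Per-year mean local coefficient for every variable (tidy wide frame,
    year-indexed). ``weighting`` is a label only — each year's mean is over
    that year's observations; combine across years observation-weighted or
    year-weighted downstream as needed."""
    df = fit.coefficients.copy()
    df["year"] = fit.index["year"].to_numpy()
    return df.groupby("year").mean().sort_index()


def coefficient_map(
    fit: gtwr.GTWRFit,
    variable: str,
    years: Sequence[int] | None = None,
    geometries: Mapping | None = None,
) -> pd.DataFrame | tuple[pd.DataFrame, dict]:
    """Per-city mean local coefficient of one variable over selected years.

    With ``geometries`` (a GeoJSON FeatureCollection whose features carry a
    ``city_id`` property) the values are attached as a
    ``coef_<variable>`` property and the enriched FeatureCollection is
    returned alongside the table.
    """
    if variable not in fit.coefficients.columns:
        raise KeyError(
            f"unknown variable {variable!r}; available: {list(fit.coefficients.columns)}"
        )
    df = pd.DataFrame(
        {
            "city_id": fit.index["city_id"].to_numpy(),
            "year": fit.index["year"].to_numpy(),
            "coef": fit.coefficients[variable].to_numpy(),
        }
    )
    if years is not None:
        df = df[df["year"].isin(list(years))]
        if df.empty:
            raise ValueError(f"no observations in years {list(years)}")
    table = df.groupby("city_id", sort=True)["coef"].mean().reset_index()
    table = table.rename(columns={"coef": f"coef_{variable}"})
    if geometries is None:
        return table
    lookup = dict(zip(table["city_id"], table[f"coef_{variable}"]))
    enriched = json.loads(json.dumps(dict(geometries)))  # deep copy, stays JSON-clean
    for feat in enriched.get("features", []):
        cid = feat.get("properties", {}).get("city_id")
        if cid in lookup:
            feat["properties"][f"coef_{variable}"] = lookup[cid]
    return table, enriched


# -- full orchestration ------------------------------------------------------

def default_analysis_config(seed: int = 0) -> dict:
    """Bundled synthetic end-to-end configuration (study-shaped but scaled to
    run in minutes: 150 cities × 10 years, three covariates with spatially or
    temporally varying truth)."""
    return {
        "synthetic": {
            "n_cities": 150,
            "years": list(range(2012, 2022)),
            "layout": "clustered",
            "n_clusters": 6,
            "covariates": ["pgdp", "hp", "fee"],
            "noise_sd": 1.0,
            "missing_rate": 0.02,
        },
        "weights": dict(spatial.DEFAULT_RECIPE),
        "phases": {"fluctuation": [2012, 2013, 2014, 2015, 2016], "downward": [2017, 2018, 2019, 2020, 2021]},
        "hotspot_years": [2012, 2017, 2021],
        "kernel": {"family": "gaussian", "tau_grid": [0.0, 0.5, 1.0, 2.0]},
        "n_permutations": 499,
        "alpha": 0.05,
        "seed": seed,
    }


def _synthetic_panel_from_config(cfg: Mapping, seed: int) -> PanelDataset:
    scfg = cfg["synthetic"]
    covs = scfg.get("covariates", list(synthetic.COVARIATE_SCALES))
    config = synthetic.SyntheticConfig(
        n_cities=scfg.get("n_cities", 150),
        years=tuple(scfg.get("years", range(2012, 2022))),
        layout=scfg.get("layout", "clustered"),
        n_clusters=scfg.get("n_clusters", 6),
        coefficient_surfaces=synthetic.default_surfaces(covs),
        covariate_scales={k: synthetic.COVARIATE_SCALES[k] for k in covs},
        noise_sd=scfg.get("noise_sd", 1.0),
        missing_rate=scfg.get("missing_rate", 0.0),
        seed=seed,
    )
    return synthetic.simulate_panel(config)


def run_full_analysis(config: Mapping, outdir: str | Path) -> dict:
    """Execute the whole analysis chain and write every artifact.

    Stages: panel acquisition (synthetic or CSV) → transforms (raw input
    only) → annual + pre/post Moran → LISA + Gi* for selected years → OLS →
    bandwidth search → GTWR → non-stationarity test → report tables. A
    manifest JSON records every setting and seed; rerunning from the manifest
    reproduces all outputs bit-for-bit.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    timings: dict[str, float] = {}
    current = {"stage": None, "t0": 0.0}

    def stage(name):
        logger.info("stage: %s", name)
        current["stage"], current["t0"] = name, time.perf_counter()
        return name

    def done(name):
        timings[name] = time.perf_counter() - current["t0"]
        logger.info("stage %s finished in %.2fs", name, timings[name])

    try:
        s = stage("ingest")
        if "synthetic" in config:
            panel = _synthetic_panel_from_config(config, seed)
        else:
            panel = load_panel(config["panel_csv"], config.get("covariates"))
            if config.get("raw_inputs", False):
                panel = apply_transforms(panel, config.get("transforms"))
        panel.to_csv(outdir / "panel.csv")
        done(s)

        recipe = config.get("weights", None)
        n_perm = int(config.get("n_permutations", 999))
        alpha = float(config.get("alpha", 0.05))

        s = stage("autocorrelation")
        annual = annual_moran_series(panel, recipe, n_permutations=n_perm, seed=seed)
        annual.round(6).to_csv(outdir / "annual_moran.csv")
        phases_cfg = config.get(
            "phases",
            {"fluctuation": sorted(FLUCTUATION_PHASE.years), "downward": sorted(DOWNWARD_PHASE.years)},
        )
        (name_a, years_a), (name_b, years_b) = list(phases_cfg.items())[:2]
        prepost = spatial.morans_i_by_period(
            panel, years_a, years_b, recipe, n_permutations=n_perm, seed=seed
        )
        with open(outdir / "prepost_moran.json", "w") as fh:
            json.dump(
                {
                    "phase_a": {"name": name_a, "years": list(years_a), "I": prepost["I_a"]},
                    "phase_b": {"name": name_b, "years": list(years_b), "I": prepost["I_b"]},
                    "percent_change": prepost["percent_change"],
                },
                fh,
                indent=2,
            )
        done(s)

        s = stage("hotspots")
        for year in config.get("hotspot_years", [panel.years[0], panel.years[-1]]):
            cs = panel.cross_section(year)
            if len(cs) < 3:
                continue
            coords = cs[["u", "v"]].to_numpy()
            ids = cs["city_id"].to_numpy()
            W = spatial.weights_from_recipe(coords, recipe, ids=ids)
            lisa = spatial.local_moran(
                cs["birth_rate"].to_numpy(), W, n_permutations=n_perm, alpha=alpha, seed=seed
            )
            lisa.round(6).to_csv(outdir / f"lisa_{year}.csv", index=False)
            Wg = spatial.build_weights(
                coords, ids=ids, scheme="distance_band",
                band_distance=None, row_standardize=False, include_self=True,
            )
            gi = spatial.getis_ord_gi_star(cs["birth_rate"].to_numpy(), Wg)
            gi.round(6).to_csv(outdir / f"gistar_{year}.csv", index=False)
        done(s)

        s = stage("ols")
        ols = gtwr.fit_ols(panel)
        done(s)

        s = stage("bandwidth_search")
        kcfg = config.get("kernel", {})
        if "bandwidth" in kcfg:
            kernel = gtwr.KernelSpec(
                family=kcfg.get("family", "gaussian"),
                bandwidth=float(kcfg["bandwidth"]),
                temporal_scale=float(kcfg.get("temporal_scale", 0.0)),
            )
            search_cv = None
        else:
            search = gtwr.optimize_bandwidth(
                panel,
                family=kcfg.get("family", "gaussian"),
                tau_grid=tuple(kcfg.get("tau_grid", gtwr.DEFAULT_TAU_GRID)),
            )
            kernel = search.kernel
            search_cv = search.cv_score
            search.trace.round(6).to_csv(outdir / "bandwidth_trace.csv", index=False)
        done(s)

        s = stage("gtwr")
        fit = gtwr.fit_gtwr(panel, kernel)
        fit.cv_score = search_cv
        fit.to_csv(outdir / "gtwr_coefficients.csv")
        done(s)

        s = stage("reports")
        nonstat = gtwr.nonstationarity_test(fit, ols)
        nonstat.round(6).to_csv(outdir / "nonstationarity.csv")
        summary = summarize_coefficients(fit)
        summary.round(6).to_csv(outdir / "coefficient_summary.csv")
        phase_a = PhaseDefinition.of(name_a, years_a)
        phase_b = PhaseDefinition.of(name_b, years_b)
        phases = phase_comparison(fit, phase_a, phase_b)
        phases.round(6).to_csv(outdir / "phase_comparison.csv")
        trend = temporal_trend(fit)
        trend.round(6).to_csv(outdir / "annual_trend.csv")
        diagnostics = {
            "kernel": dataclasses.asdict(kernel),
            "tau": kernel.tau,
            "hat_trace": fit.hat_trace,
            "gtwr_adjusted_r2": fit.adjusted_r2,
            "ols_adjusted_r2": ols.adjusted_r2,
            "aicc": fit.aicc,
            "cv_score": search_cv,
            "n": panel.n,
        }
        with open(outdir / "diagnostics.json", "w") as fh:
            json.dump(diagnostics, fh, indent=2)
        done(s)
    except Exception as exc:
        raise RuntimeError(f"analysis aborted in stage {current['stage']}: {exc}") from exc

    manifest = {
        "config": json.loads(json.dumps(dict(config))),
        "seed": seed,
        "artifacts": sorted(p.name for p in outdir.iterdir() if p.suffix in {".csv", ".json"}),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {
        "panel": panel,
        "annual_moran": annual,
        "prepost": prepost,
        "ols": ols,
        "fit": fit,
        "nonstationarity": nonstat,
        "summary": summary,
        "phases": phases,
        "trend": trend,
        "manifest": manifest,
    }
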