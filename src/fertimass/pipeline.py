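"""End-to-end analysis pipeline and report rendering.

Stages: gravimetric mass logs -> transpiration; solution samples ->
depletion uptake; harvest tissue -> WUE and per-source input predictions;
deviation scoring and best-predictor selection; repeated-measures
statistics; a report bundle of tidy tables with provenance.
"""

from __future__ import annotations

import logging
import os
import shutil
import tempfile
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .elements import MEASURED_ELEMENTS
from .errors import InvalidInputError
from .gravimetric import analyze_series, window_water_loss
from .io import (
    FLOAT_FORMAT,
    RunConfig,
    read_mass_log,
    read_solution_samples,
    read_tissue,
    write_csv,
)
from .mass_balance import (
    DepletionCycle,
    TissueProfile,
    biomass_weighted_mean,
    compute_wue,
    summarize_deviations,
    uptake_from_depletion,
)
from .stats import (
    RMDesign,
    pairwise_emmeans_bonferroni,
    rm_anova,
    welch_t_test,
)

logger = logging.getLogger(__name__)


@dataclass
class ReportBundle:
    """All output tables of one pipeline run."""

    table1: pd.DataFrame  # cultivar x element x source: mean, sem, n
    deviations: pd.DataFrame  # cultivar, element, source, deviation_percent, best flags
    uptake_records: pd.DataFrame  # per plant x event x element uptake
    wue: pd.DataFrame  # per plant WUE inputs and value
    anova: pd.DataFrame  # per element RM-ANOVA effects
    contrasts: pd.DataFrame  # per element Bonferroni-adjusted contrasts
    welch: pd.DataFrame  # per element x source cultivar comparison
    provenance: dict


def _sem(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        return float("nan")
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


def compute_uptake_table(
    solution: pd.DataFrame,
    mass_series: dict,
    config: RunConfig,
) -> pd.DataFrame:
    """Per plant x event x element uptake records from depletion cycles."""
    rows = []
    for (plant, date), grp in solution.groupby(["plant_id", "date"], sort=True):
        cultivar = grp["cultivar"].iloc[0]
        supply = dict(
            zip(
                grp.loc[grp.sample_type == "supply", "element"],
                grp.loc[grp.sample_type == "supply", "concentration_mg_per_L"],
            )
        )
        leachate = dict(
            zip(
                grp.loc[grp.sample_type == "leachate", "element"],
                grp.loc[grp.sample_type == "leachate", "concentration_mg_per_L"],
            )
        )
        if plant not in mass_series:
            raise InvalidInputError(f"no gravimetric trace for plant {plant}")
        v_t = window_water_loss(
            mass_series[plant],
            date,
            start_time=config.day_window_start,
            end_time=config.day_window_end,
            threshold=config.event_threshold_g,
            smooth_window=config.smooth_window,
        )
        cycle = DepletionCycle(
            plant_id=plant,
            cultivar=cultivar,
            date=date,
            supply_concentration=supply,
            leachate_concentration=leachate,
            solution_volume_at_capacity=config.capacity_volume_L,
            transpired_volume=v_t,
        )
        for rec in uptake_from_depletion(cycle):
            rows.append(
                {
                    "plant_id": rec.plant_id,
                    "cultivar": rec.cultivar,
                    "date": rec.date,
                    "element": rec.element,
                    "uptake_mg_per_L": rec.uptake_concentration,
                    "negative_flag": rec.negative_flag,
                }
            )
    return pd.DataFrame(rows)


def compute_wue_table(tissue: pd.DataFrame, mass_series: dict, config: RunConfig) -> pd.DataFrame:
    """Per-plant WUE from harvest dry mass and cumulative gravimetric water use."""
    rows = []
    for plant, grp in tissue.groupby("plant_id", sort=True):
        dry_mass = float(
            grp.drop_duplicates(["organ"])["organ_dry_mass_g"].sum()
        )
        if plant not in mass_series:
            raise InvalidInputError(f"no gravimetric trace for plant {plant}")
        _, summary = analyze_series(
            mass_series[plant],
            threshold=config.event_threshold_g,
            smooth_window=config.smooth_window,
        )
        wue = compute_wue(dry_mass, summary.total_L, plant_id=plant)
        rows.append(
            {
                "plant_id": plant,
                "cultivar": grp["cultivar"].iloc[0],
                "dry_mass_g": wue.dry_mass,
                "transpiration_L": wue.irrigation_volume,
                "wue_g_per_L": wue.value,
            }
        )
    return pd.DataFrame(rows)


def compute_predictions(tissue: pd.DataFrame, wue_table: pd.DataFrame) -> pd.DataFrame:
    """Per plant x source x element predicted input concentration (mg L^-1)."""
    wue_by_plant = wue_table.set_index("plant_id")["wue_g_per_L"]
    rows = []
    for plant, grp in tissue.groupby("plant_id", sort=True):
        cultivar = grp["cultivar"].iloc[0]
        profiles = []
        for organ, og in grp.groupby("organ", sort=True):
            profiles.append(
                TissueProfile(
                    organ=organ,
                    concentrations=dict(
                        zip(og["element"], og["concentration_mg_per_g"])
                    ),
                    dry_mass=float(og["organ_dry_mass_g"].iloc[0]),
                )
            )
        w = float(wue_by_plant.loc[plant])
        panels = {p.organ: p.concentrations for p in profiles}
        panels["weighted"] = biomass_weighted_mean(profiles)
        for source, panel in panels.items():
            for el, conc in panel.items():
                rows.append(
                    {
                        "plant_id": plant,
                        "cultivar": cultivar,
                        "source": source,
                        "element": el,
                        "predicted_mg_per_L": conc * w,
                    }
                )
    return pd.DataFrame(rows)


def compute_deviation_table(
    uptake: pd.DataFrame, predictions: pd.DataFrame, *, ndigits: int = 1
) -> pd.DataFrame:
    """Cultivar x element x source percent deviations and best predictor.

    Measured uptake per cultivar x element is the mean over replicate-plant
    means (each plant first averaged over its sampling events); predictions
    are cultivar means over replicate plants.
    """
    plant_means = uptake.groupby(
        ["cultivar", "plant_id", "element"], as_index=False
    )["uptake_mg_per_L"].mean()
    measured = plant_means.groupby(["cultivar", "element"])["uptake_mg_per_L"].mean()
    predicted = predictions.groupby(["cultivar", "element", "source"])[
        "predicted_mg_per_L"
    ].mean()
    rows = []
    for (cultivar, element), meas in measured.items():
        preds = predicted.loc[cultivar, element].to_dict()
        summary = summarize_deviations(
            cultivar, element, preds, meas, ndigits=ndigits
        )
        for source, dev in summary.deviations.items():
            rows.append(
                {
                    "cultivar": cultivar,
                    "element": element,
                    "source": source,
                    "measured_mg_per_L": meas,
                    "predicted_mg_per_L": preds[source],
                    "deviation_percent": dev,
                    "best_source": summary.best_source,
                    "tie_flag": summary.tie_flag,
                }
            )
    return pd.DataFrame(rows)


def compute_table1(uptake: pd.DataFrame, predictions: pd.DataFrame) -> pd.DataFrame:
    """Means +/- SEM over replicate plants, per cultivar x element x source."""
    plant_uptake = uptake.groupby(
        ["cultivar", "plant_id", "element"], as_index=False
    )["uptake_mg_per_L"].mean()
    plant_uptake["source"] = "uptake"
    plant_uptake = plant_uptake.rename(columns={"uptake_mg_per_L": "value"})
    preds = predictions.rename(columns={"predicted_mg_per_L": "value"})[
        ["cultivar", "plant_id", "element", "source", "value"]
    ]
    both = pd.concat([plant_uptake, preds], ignore_index=True)
    out = both.groupby(["cultivar", "element", "source"], as_index=False).agg(
        mean=("value", "mean"), sem=("value", _sem), n=("value", "size")
    )
    return out


def compute_statistics(
    uptake: pd.DataFrame, predictions: pd.DataFrame, config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-element RM-ANOVA, adjusted contrasts, and Welch cultivar tests."""
    anova_rows, contrast_rows, welch_rows = [], [], []
    for el in [e for e in MEASURED_ELEMENTS if e in set(uptake["element"])]:
        sub = uptake.loc[uptake["element"] == el]
        design = RMDesign(
            sub.rename(
                columns={
                    "plant_id": "subject",
                    "cultivar": "group",
                    "date": "time",
                    "uptake_mg_per_L": "value",
                }
            )[["subject", "group", "time", "value"]]
        )
        result = rm_anova(design)
        for effect in ("group", "time", "group:time"):
            row = result.effect(effect)
            anova_rows.append(
                {
                    "element": el,
                    "effect": effect,
                    "SS": row["SS"],
                    "df": row["df"],
                    "F": row["F"],
                    "p": row["p"],
                    "gg_epsilon": result.gg_epsilon
                    if config.report_gg_epsilon
                    else np.nan,
                }
            )
        if result.degenerate:
            logger.warning(
                "contrasts skipped for %s: an error stratum is zero "
                "(replicates identical)", el
            )
            continue
        for c in pairwise_emmeans_bonferroni(design, family=config.contrast_family):
            contrast_rows.append(
                {
                    "element": el,
                    "contrast": c.contrast,
                    "estimate": c.estimate,
                    "se": c.se,
                    "df": c.df,
                    "t": c.t,
                    "p_raw": c.p_raw,
                    "p_adjusted": c.p_adjusted,
                }
            )
    cultivars = sorted(predictions["cultivar"].unique())
    if len(cultivars) == 2:
        a_name, b_name = cultivars
        for (el, source), grp in predictions.groupby(["element", "source"], sort=True):
            a = grp.loc[grp.cultivar == a_name, "predicted_mg_per_L"].to_numpy()
            b = grp.loc[grp.cultivar == b_name, "predicted_mg_per_L"].to_numpy()
            if len(a) < 2 or len(b) < 2:
                continue
            if np.var(a, ddof=1) == 0 or np.var(b, ddof=1) == 0:
                logger.warning("welch skipped for %s/%s: zero variance", el, source)
                continue
            res = welch_t_test(a, b)
            welch_rows.append(
                {
                    "element": el,
                    "source": source,
                    "contrast": f"{a_name} - {b_name}",
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                }
            )
    return (
        pd.DataFrame(anova_rows),
        pd.DataFrame(contrast_rows),
        pd.DataFrame(welch_rows),
    )


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis described by ``config``; deterministic."""
    solution = read_solution_samples(config.solution_csv)
    tissue = read_tissue(config.tissue_csv)
    mass_series = read_mass_log(config.mass_log_csv)
    return analyze_tables(solution, tissue, mass_series, config)


def analyze_dataset(dataset, config: RunConfig | None = None) -> ReportBundle:
    """Run the full analysis directly on a simulated :class:`TrialDataset`."""
    config = config if config is not None else RunConfig()
    solution = dataset.solution_samples.copy()
    solution["date"] = pd.to_datetime(solution["date"]).dt.date
    return analyze_tables(solution, dataset.tissue, dataset.mass_series, config)


def analyze_tables(
    solution: pd.DataFrame,
    tissue: pd.DataFrame,
    mass_series: dict,
    config: RunConfig,
) -> ReportBundle:
    """Analysis core shared by the file-based and in-memory entry points."""
    uptake = compute_uptake_table(solution, mass_series, config)
    wue_table = compute_wue_table(tissue, mass_series, config)
    predictions = compute_predictions(tissue, wue_table)
    deviations = compute_deviation_table(
        uptake, predictions, ndigits=config.deviation_ndigits
    )
    table1 = compute_table1(uptake, predictions)
    anova, contrasts, welch = compute_statistics(uptake, predictions, config)
    provenance = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "version": __version__,
    }
    return ReportBundle(
        table1=table1,
        deviations=deviations,
        uptake_records=uptake,
        wue=wue_table,
        anova=anova,
        contrasts=contrasts,
        welch=welch,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Rendering and atomic output
# ---------------------------------------------------------------------------

_SOURCE_ORDER = ("uptake", "leaf", "stem", "root", "weighted")


def render_table1(bundle: ReportBundle, *, precision: int = 2) -> pd.DataFrame:
    """Wide summary table: element rows, one 'mean +/- SEM' cell per source.

    Missing cells render as the explicit string ``NA``; an empty bundle
    yields a header-only frame (with a logged warning).
    """
    t1 = bundle.table1
    if t1.empty:
        logger.warning("render_table1: empty report; rendering header only")
        return pd.DataFrame(
            columns=["cultivar", "element", *(s.capitalize() for s in _SOURCE_ORDER)]
        )
    rows = []
    for cultivar in sorted(t1["cultivar"].unique()):
        sub = t1.loc[t1["cultivar"] == cultivar].set_index(["element", "source"])
        for el in [e for e in MEASURED_ELEMENTS if e in set(t1["element"])]:
            row = {"cultivar": cultivar, "element": el}
            for source in _SOURCE_ORDER:
                try:
                    cell = sub.loc[(el, source)]
                    row[source.capitalize()] = (
                        f"{cell['mean']:.{precision}f} ± {cell['sem']:.{precision}f}"
                    )
                except KeyError:
                    row[source.capitalize()] = "NA"
            rows.append(row)
    return pd.DataFrame(rows)


def write_report(bundle: ReportBundle, output_dir) -> None:
    """Write the report bundle atomically (no partial output on failure)."""
    output_dir = str(output_dir)
    parent = os.path.dirname(os.path.abspath(output_dir)) or "."
    os.makedirs(parent, exist_ok=True)
    tables = {
        "table1.csv": bundle.table1,
        "table1_rendered.csv": render_table1(bundle),
        "deviations.csv": bundle.deviations,
        "uptake_records.csv": bundle.uptake_records,
        "wue.csv": bundle.wue,
        "anova.csv": bundle.anova,
        "contrasts.csv": bundle.contrasts,
        "welch.csv": bundle.welch,
    }
    tmp = tempfile.mkdtemp(dir=parent, prefix=".fertimass-partial-")
    try:
        for name, df in tables.items():
            write_csv(df, os.path.join(tmp, name))
        with open(os.path.join(tmp, "report.md"), "w", encoding="utf-8") as fh:
            fh.write("# Fertigation mass-balance report\n\n")
            for key, value in bundle.provenance.items():
                fh.write(f"- {key}: {value}\n")
            fh.write("\n## Uptake and predicted inputs (mean ± SEM)\n\n")
            fh.write(render_table1(bundle).to_markdown(index=False))
            fh.write("\n\n## Deviations (percent, predicted vs measured uptake)\n\n")
            fh.write(bundle.deviations.to_markdown(index=False, floatfmt=".4g"))
            fh.write("\n")
    except BaseException:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    if os.path.exists(output_dir):
        shutil.rmtree(output_dir)
    os.rename(tmp, output_dir)


def simulate_to_dir(dataset, out_dir) -> dict[str, str]:
    """Write a simulated trial as the CSV set the pipeline reads."""
    from .synthetic import mass_log_frame

    out = {}
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "mass_log_csv": os.path.join(out_dir, "mass_log.csv"),
        "solution_csv": os.path.join(out_dir, "solution_samples.csv"),
        "tissue_csv": os.path.join(out_dir, "tissue.csv"),
    }
    write_csv(mass_log_frame(dataset), paths["mass_log_csv"])
    write_csv(dataset.solution_samples, paths["solution_csv"])
    write_csv(dataset.tissue, paths["tissue_csv"])
    ledger_dir = os.path.join(out_dir, "ledger")
    os.makedirs(ledger_dir, exist_ok=True)
    for name in ("plants", "daily", "events", "absorbed", "tissue_true"):
        write_csv(getattr(dataset.ledger, name), os.path.join(ledger_dir, f"{name}.csv"))
    out.update(paths)
    return out
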