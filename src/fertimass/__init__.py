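"""fertimass: transpiration-driven nutrient mass balance for fertigation.

Estimates per-element nutrient uptake from solution depletion, predicts
required fertigation input concentrations from tissue chemistry and
water-use efficiency (organ-explicit and organ biomass-weighted), scores
prediction deviations, and runs the repeated-measures statistical layer —
with a mass-conserving synthetic trial generator for end-to-end testing.
"""

__version__ = "0.1.0"

from .elements import (  # noqa: F401
    MACRO_ELEMENTS,
    MEASURED_ELEMENTS,
    MICRO_ELEMENTS,
    ORGANS,
    PREDICTION_SOURCES,
    SUPPLY_ONLY_ELEMENTS,
)
from .errors import (  # noqa: F401
    ConfigError,
    DegenerateInputError,
    FertimassError,
    InvalidInputError,
    SchemaError,
    UnbalancedDesignError,
)
from .mass_balance import (  # noqa: F401
    DepletionCycle,
    DeviationSummary,
    PredictedInput,
    TissueProfile,
    UptakeRecord,
    WaterUseEfficiency,
    best_predictor,
    biomass_weighted_mean,
    compute_wue,
    deviation_percent,
    predict_input_concentration,
    replenishment_estimate,
    uptake_from_depletion,
)
from .gravimetric import (  # noqa: F401
    IrrigationEvent,
    MassSeries,
    TranspirationSummary,
    cumulative_water_use,
    detect_irrigation_events,
    segment_water_loss,
    window_water_loss,
)
from .stats import (  # noqa: F401
    AnovaTable,
    PairwiseComparison,
    RMDesign,
    WelchResult,
    influence_diagnostics,
    pairwise_emmeans_bonferroni,
    rm_anova,
    welch_t_test,
)
from .synthetic import (  # noqa: F401
    CultivarParams,
    Trajectory,
    TrialConfig,
    TrialDataset,
    cj2_like,
    default_params,
    default_recipe,
    first_light_like,
    ledger_audit,
    simulate_trial,
)
from .io import RunConfig  # noqa: F401
from .pipeline import (  # noqa: F401
    ReportBundle,
    analyze_dataset,
    render_table1,
    run_pipeline,
    write_report,
)


def worked_example_means():
    """The published two-cultivar trial summary (means ± SEM) bundled as a
    worked example: measured uptake and tissue-derived input concentrations
    per cultivar x element x source.  Returns a tidy DataFrame."""
    from importlib.resources import files

    import pandas as pd

    path = files("fertimass").joinpath("data/worked_example_means.csv")
    with path.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)
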