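"""Mass-conserving synthetic fertigation trials with a ground-truth ledger.

The generator emulates a containerized vegetative-phase trial: two
cultivars x four replicate plants on gravimetric balances, a 38-day phase,
ten 12-h pour-through depletion cycles, and a destructive harvest with
organ-level tissue chemistry.  Everything downstream of the instruments is
driven by a small set of physiological parameters:

* biomass grows exponentially at a constant relative growth rate,
* daily transpiration is proportional to daily biomass gain, scaled so the
  harvest dry mass over total transpiration equals the target water-use
  efficiency exactly,
* per-element uptake concentration (mg per L transpired) follows a linear
  trajectory across the phase (declining for N/K, rising for Ca/Mg,
  configurable per element),
* leachate concentrations come from the forward depletion model
  ``C_leach = C_supply - C_uptake * V_t / V_cap``,
* harvest tissue concentrations place the cumulative absorbed element mass
  into organs by fixed allocation fractions, so element conservation holds
  exactly before measurement noise.

Measurement noise is additive Gaussian on balance masses and multiplicative
Gaussian on assay concentrations (leachate and tissue).  The pre-noise
truth is retained in a ledger for parameter-recovery and audit tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .elements import MEASURED_ELEMENTS
from .errors import ConfigError
from .gravimetric import MassSeries

TRAJECTORY_SHAPES = ("declining", "rising", "flat")

#: Samples per day at the 10-minute logging cadence.
_SAMPLES_PER_DAY = 144


def default_recipe() -> dict[str, float]:
    """Default complete-recipe supply concentrations, mg L^-1.

    N is total nitrogen (nitrate-N 250 + ammonium-N 6.3).  Mo is supplied
    but excluded from uptake analysis.
    """
    return {
        "N": 256.3,
        "K": 350.0,
        "P": 50.0,
        "Mg": 61.7,
        "Ca": 100.0,
        "Fe": 2.0,
        "Zn": 0.23,
        "B": 0.09,
        "Cu": 0.23,
        "Mo": 0.07,
        "Mn": 0.27,
    }


@dataclass(frozen=True)
class Trajectory:
    """Linear uptake-concentration trajectory (mg per L transpired).

    The line runs from ``start`` to ``end`` across ``domain`` (a
    ``(first_day, last_day)`` pair; ``None`` means the whole phase) and is
    held constant outside it.  Presets pin the domain to the leachate
    sampling window, so the configured dynamic range is the range a
    monitored trial would actually observe.
    """

    start: float
    end: float
    shape: str = "flat"
    domain: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.shape not in TRAJECTORY_SHAPES:
            raise ConfigError(f"unknown trajectory shape {self.shape!r}")
        if self.start < 0 or self.end < 0:
            raise ConfigError("trajectory concentrations must be >= 0")
        if self.shape == "declining" and self.end > self.start:
            raise ConfigError("declining trajectory must have end <= start")
        if self.shape == "rising" and self.end < self.start:
            raise ConfigError("rising trajectory must have end >= start")
        if self.domain is not None and self.domain[1] <= self.domain[0]:
            raise ConfigError("trajectory domain must be an increasing day pair")

    def value(self, day: int, phase_days: int) -> float:
        lo, hi = (0, phase_days - 1) if self.domain is None else self.domain
        if hi <= lo:
            return self.start
        frac = min(max((day - lo) / (hi - lo), 0.0), 1.0)
        return self.start + (self.end - self.start) * frac


#: Default sampling window (phase days) the presets pin trajectories to.
_DEFAULT_WINDOW = (17, 35)


def _traj(start: float, end: float, domain: tuple[int, int] | None = _DEFAULT_WINDOW) -> Trajectory:
    shape = "flat" if start == end else ("declining" if end < start else "rising")
    return Trajectory(start, end, shape, domain)


#: How each element's absorbed mass is split among organs (leaf, stem, root).
#: Mirrors the qualitative organ patterns of vegetative tissue assays:
#: Fe and Cu root-dominant, Ca and B leaf-dominant, K relatively stem-rich.
DEFAULT_ELEMENT_ALLOCATION: dict[str, dict[str, float]] = {
    "N": {"leaf": 0.55, "stem": 0.15, "root": 0.30},
    "P": {"leaf": 0.45, "stem": 0.20, "root": 0.35},
    "K": {"leaf": 0.40, "stem": 0.35, "root": 0.25},
    "Ca": {"leaf": 0.60, "stem": 0.20, "root": 0.20},
    "Mg": {"leaf": 0.50, "stem": 0.20, "root": 0.30},
    "Fe": {"leaf": 0.15, "stem": 0.05, "root": 0.80},
    "Mn": {"leaf": 0.45, "stem": 0.25, "root": 0.30},
    "B": {"leaf": 0.60, "stem": 0.20, "root": 0.20},
    "Cu": {"leaf": 0.20, "stem": 0.20, "root": 0.60},
    "Zn": {"leaf": 0.45, "stem": 0.20, "root": 0.35},
}


@dataclass(frozen=True)
class CultivarParams:
    """Physiological presets for one cultivar."""

    name: str
    initial_dry_mass_g: float
    rgr_per_day: float
    target_wue_g_per_L: float
    biomass_allocation: dict[str, float]  # leaf/stem/root fractions, sum 1
    uptake: dict[str, Trajectory]  # per-element trajectories
    element_allocation: dict[str, dict[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_ELEMENT_ALLOCATION)
    )

    def __post_init__(self) -> None:
        if self.initial_dry_mass_g <= 0 or self.target_wue_g_per_L <= 0:
            raise ConfigError("initial dry mass and target WUE must be > 0")
        if abs(sum(self.biomass_allocation.values()) - 1.0) > 1e-12:
            raise ConfigError(
                f"{self.name}: biomass allocation fractions must sum to 1"
            )
        for el, alloc in self.element_allocation.items():
            if abs(sum(alloc.values()) - 1.0) > 1e-12:
                raise ConfigError(
                    f"{self.name}: element allocation for {el} must sum to 1"
                )
        missing = set(MEASURED_ELEMENTS) - set(self.uptake)
        if missing:
            raise ConfigError(f"{self.name}: missing trajectories for {sorted(missing)}")


def cj2_like() -> CultivarParams:
    """Preset resembling a vigorous cultivar with WUE 4.71 g L^-1."""
    return CultivarParams(
        name="CJ2",
        initial_dry_mass_g=12.0,
        rgr_per_day=math.log(190.0 / 12.0) / 38.0,
        target_wue_g_per_L=4.71,
        biomass_allocation={"leaf": 0.45, "stem": 0.35, "root": 0.20},
        uptake={
            "N": _traj(135.0, 75.0),
            "K": _traj(205.0, 106.0),
            "P": _traj(47.0, 12.0),
            "Ca": _traj(37.0, 96.0),
            "Mg": _traj(24.0, 51.0),
            "Fe": _traj(1.1, 2.1),
            "Mn": _traj(0.26, 0.12),
            "B": _traj(0.05, 0.09),
            "Cu": _traj(0.07, 0.15),
            "Zn": _traj(0.06, 0.14),
        },
    )


def first_light_like() -> CultivarParams:
    """Preset resembling a slightly less water-efficient cultivar (WUE 4.59)."""
    return CultivarParams(
        name="FirstLight",
        initial_dry_mass_g=12.0,
        rgr_per_day=math.log(185.0 / 12.0) / 38.0,
        target_wue_g_per_L=4.59,
        biomass_allocation={"leaf": 0.47, "stem": 0.33, "root": 0.20},
        uptake={
            "N": _traj(144.0, 97.0),
            "K": _traj(216.0, 112.0),
            "P": _traj(47.0, 14.0),
            "Ca": _traj(44.0, 97.0),
            "Mg": _traj(31.0, 52.0),
            "Fe": _traj(0.9, 1.85),
            "Mn": _traj(0.24, 0.10),
            "B": _traj(0.06, 0.10),
            "Cu": _traj(0.05, 0.09),
            "Zn": _traj(0.05, 0.09),
        },
    )


def default_params() -> tuple[CultivarParams, CultivarParams]:
    return (cj2_like(), first_light_like())


@dataclass(frozen=True)
class TrialConfig:
    """Trial layout, instrument schedule and noise levels."""

    replicates: int = 4
    phase_days: int = 38
    n_events: int = 10
    sampling_start_day: int = 17
    sampling_interval_days: int = 2
    capacity_volume_L: float = 4.0
    capacity_mass_g: float = 9000.0
    leachate_draw_ml: float = 230.0
    evening_refill_fraction: float = 0.5
    balance_noise_sd_g: float = 2.0
    assay_noise_rel_sd: float = 0.02
    replicate_biomass_cv: float = 0.05
    start_date: str = "2024-07-07"
    supply: dict[str, float] = field(default_factory=default_recipe)

    def __post_init__(self) -> None:
        if self.replicates < 1 or self.phase_days < 2 or self.n_events < 1:
            raise ConfigError("replicates, phase days and events must be positive")
        last = self.sampling_start_day + (self.n_events - 1) * self.sampling_interval_days
        if last > self.phase_days - 1:
            raise ConfigError(
                f"sampling events (last day {last}) do not fit within the "
                f"{self.phase_days}-day phase"
            )
        for sd in (self.balance_noise_sd_g, self.assay_noise_rel_sd,
                   self.replicate_biomass_cv):
            if sd < 0:
                raise ConfigError("noise SDs must be >= 0")
        if not 0.0 < self.evening_refill_fraction < 1.0:
            raise ConfigError("evening refill fraction must be in (0, 1)")
        if self.capacity_volume_L <= 0:
            raise ConfigError("capacity volume must be > 0")

    @property
    def event_days(self) -> tuple[int, ...]:
        return tuple(
            self.sampling_start_day + k * self.sampling_interval_days
            for k in range(self.n_events)
        )

    def zero_noise(self) -> "TrialConfig":
        """Copy with all measurement noise and replicate jitter removed."""
        return replace(
            self,
            balance_noise_sd_g=0.0,
            assay_noise_rel_sd=0.0,
            replicate_biomass_cv=0.0,
        )


@dataclass
class GroundTruthLedger:
    """Pre-noise truth retained for recovery and conservation tests."""

    plants: pd.DataFrame  # plant_id, cultivar, m0_g, harvest_dry_mass_g, wue, total_transpiration_L
    daily: pd.DataFrame  # plant_id, day, date, transpiration_L
    events: pd.DataFrame  # plant_id, cultivar, date, element, true_uptake, true_leachate, transpired_L
    absorbed: pd.DataFrame  # plant_id, element, absorbed_mg
    tissue_true: pd.DataFrame  # plant_id, organ, element, concentration_mg_per_g


@dataclass
class TrialDataset:
    """A complete simulated trial in the CSV schemas the pipeline reads."""

    config: TrialConfig
    seed: int
    mass_series: dict[str, MassSeries]
    solution_samples: pd.DataFrame  # date, plant_id, cultivar, element, concentration_mg_per_L, sample_type
    tissue: pd.DataFrame  # plant_id, cultivar, organ, element, concentration_mg_per_g, organ_dry_mass_g
    ledger: GroundTruthLedger


def _mass_trace(
    transpiration_g: np.ndarray, capacity_mass_g: float, evening_fraction: float
) -> np.ndarray:
    """Balance masses at 10-min cadence for one plant over the phase.

    Per day: flat until 07:00; the 07:00 irrigation restores container
    capacity; linear decline 07:00-19:00 totalling the day's transpiration;
    flat until the 20:00 irrigation replaces ``evening_fraction`` of it;
    flat overnight.  The morning event therefore delivers the remainder of
    the previous day's deficit, so both scheduled irrigations produce
    balance-detectable gains.
    """
    days = len(transpiration_g)
    out = np.empty(days * _SAMPLES_PER_DAY)
    i_morning, i_decline_end, i_evening = 42, 114, 120  # 07:00, 19:00, 20:00
    carry = 0.0  # deficit left after the previous evening refill
    for d in range(days):
        t = transpiration_g[d]
        base = d * _SAMPLES_PER_DAY
        day_vals = out[base : base + _SAMPLES_PER_DAY]
        day_vals[:i_morning] = capacity_mass_g - carry
        # decline: 72 equal 10-min steps from 07:00 (at capacity) to 19:00
        steps = np.arange(0, i_decline_end - i_morning + 1)
        day_vals[i_morning : i_decline_end + 1] = capacity_mass_g - t * steps / (
            i_decline_end - i_morning
        )
        day_vals[i_decline_end + 1 : i_evening] = capacity_mass_g - t
        evening = evening_fraction * t
        day_vals[i_evening:] = capacity_mass_g - t + evening
        carry = t - evening
    return out


def simulate_trial(
    config: TrialConfig | None = None,
    params: tuple[CultivarParams, ...] | None = None,
    seed: int = 0,
) -> TrialDataset:
    """Generate a complete trial dataset plus its ground-truth ledger."""
    config = config if config is not None else TrialConfig()
    params = params if params is not None else default_params()
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(config.start_date)
    times = pd.date_range(
        start, periods=config.phase_days * _SAMPLES_PER_DAY, freq="10min"
    ).to_numpy()

    mass_series: dict[str, MassSeries] = {}
    plant_rows, daily_rows, event_rows, absorbed_rows = [], [], [], []
    tissue_true_rows, tissue_obs_rows, solution_rows = [], [], []

    for cv in params:
        for rep in range(config.replicates):
            plant_id = f"{cv.name}-{rep + 1}"
            jitter = (
                1.0 + config.replicate_biomass_cv * rng.standard_normal()
                if config.replicate_biomass_cv > 0
                else 1.0
            )
            m0 = max(cv.initial_dry_mass_g * jitter, 0.2 * cv.initial_dry_mass_g)
            days = np.arange(config.phase_days + 1)
            biomass = m0 * np.exp(cv.rgr_per_day * days)
            harvest_mass = float(biomass[-1])
            gains = np.diff(biomass)  # daily dry-mass gain, g
            total_transp_L = harvest_mass / cv.target_wue_g_per_L
            transp_L = gains * total_transp_L / (harvest_mass - m0)
            transp_g = transp_L * 1000.0

            masses = _mass_trace(
                transp_g, config.capacity_mass_g, config.evening_refill_fraction
            )
            if config.balance_noise_sd_g > 0:
                masses = masses + rng.normal(
                    0.0, config.balance_noise_sd_g, size=masses.shape
                )
            mass_series[plant_id] = MassSeries(plant_id, times, masses)

            plant_rows.append(
                {
                    "plant_id": plant_id,
                    "cultivar": cv.name,
                    "m0_g": m0,
                    "harvest_dry_mass_g": harvest_mass,
                    "wue_g_per_L": cv.target_wue_g_per_L,
                    "total_transpiration_L": total_transp_L,
                }
            )
            for d in range(config.phase_days):
                daily_rows.append(
                    {
                        "plant_id": plant_id,
                        "day": d,
                        "date": (start + pd.Timedelta(days=d)).date(),
                        "transpiration_L": float(transp_L[d]),
                    }
                )

            # depletion cycles on sampling days
            for d in config.event_days:
                date = (start + pd.Timedelta(days=d)).date()
                v_t = float(transp_L[d])
                for el in MEASURED_ELEMENTS:
                    c_up = cv.uptake[el].value(d, config.phase_days)
                    c_supply = config.supply[el]
                    c_leach = c_supply - c_up * v_t / config.capacity_volume_L
                    if c_leach < 0:
                        raise ConfigError(
                            f"{plant_id} day {d} {el}: configured uptake "
                            "exhausts the supplied element mass"
                        )
                    obs = c_leach
                    if config.assay_noise_rel_sd > 0:
                        obs = max(
                            c_leach
                            * (1.0 + config.assay_noise_rel_sd * rng.standard_normal()),
                            0.0,
                        )
                    event_rows.append(
                        {
                            "plant_id": plant_id,
                            "cultivar": cv.name,
                            "date": date,
                            "element": el,
                            "true_uptake_mg_per_L": c_up,
                            "true_leachate_mg_per_L": c_leach,
                            "transpired_L": v_t,
                        }
                    )
                    solution_rows.append(
                        {
                            "date": date,
                            "plant_id": plant_id,
                            "cultivar": cv.name,
                            "element": el,
                            "concentration_mg_per_L": c_supply,
                            "sample_type": "supply",
                        }
                    )
                    solution_rows.append(
                        {
                            "date": date,
                            "plant_id": plant_id,
                            "cultivar": cv.name,
                            "element": el,
                            "concentration_mg_per_L": obs,
                            "sample_type": "leachate",
                        }
                    )

            # cumulative absorbed mass and harvest tissue chemistry
            day_idx = np.arange(config.phase_days)
            for el in MEASURED_ELEMENTS:
                conc = np.array(
                    [cv.uptake[el].value(int(d), config.phase_days) for d in day_idx]
                )
                absorbed = float(np.sum(conc * transp_L))  # mg
                absorbed_rows.append(
                    {"plant_id": plant_id, "element": el, "absorbed_mg": absorbed}
                )
                for organ, bio_frac in cv.biomass_allocation.items():
                    organ_mass = bio_frac * harvest_mass
                    true_c = absorbed * cv.element_allocation[el][organ] / organ_mass
                    tissue_true_rows.append(
                        {
                            "plant_id": plant_id,
                            "organ": organ,
                            "element": el,
                            "concentration_mg_per_g": true_c,
                        }
                    )
                    obs_c = true_c
                    if config.assay_noise_rel_sd > 0:
                        obs_c = max(
                            true_c
                            * (1.0 + config.assay_noise_rel_sd * rng.standard_normal()),
                            0.0,
                        )
                    tissue_obs_rows.append(
                        {
                            "plant_id": plant_id,
                            "cultivar": cv.name,
                            "organ": organ,
                            "element": el,
                            "concentration_mg_per_g": obs_c,
                            "organ_dry_mass_g": organ_mass,
                        }
                    )

    ledger = GroundTruthLedger(
        plants=pd.DataFrame(plant_rows),
        daily=pd.DataFrame(daily_rows),
        events=pd.DataFrame(event_rows),
        absorbed=pd.DataFrame(absorbed_rows),
        tissue_true=pd.DataFrame(tissue_true_rows),
    )
    return TrialDataset(
        config=config,
        seed=seed,
        mass_series=mass_series,
        solution_samples=pd.DataFrame(solution_rows),
        tissue=pd.DataFrame(tissue_obs_rows),
        ledger=ledger,
    )


# ---------------------------------------------------------------------------
# Conservation audit
# ---------------------------------------------------------------------------


@dataclass
class ConservationReport:
    """Element-conservation audit of a simulated dataset.

    ``tissue_balance`` compares each plant's cumulative absorbed element
    mass with the organ-summed *true* tissue element mass (exact by
    construction).  ``event_residuals`` checks every depletion cycle
    against the *observed* leachate: residual = (C_leach_true -
    C_leach_observed) x V_cap, i.e. the supply mass not accounted for by
    observed leachate plus true uptake.  Nonzero residuals are assay noise
    (or corruption).
    """

    tissue_balance: pd.DataFrame
    event_residuals: pd.DataFrame
    max_tissue_discrepancy_mg: float
    max_event_residual_mg: float


def ledger_audit(dataset: TrialDataset) -> ConservationReport:
    led = dataset.ledger
    organ_mass = dataset.tissue.drop_duplicates(["plant_id", "organ"]).set_index(
        ["plant_id", "organ"]
    )["organ_dry_mass_g"]
    tt = led.tissue_true.copy()
    tt["organ_mass_g"] = [
        organ_mass.loc[(p, o)] for p, o in zip(tt["plant_id"], tt["organ"])
    ]
    tt["element_mass_mg"] = tt["concentration_mg_per_g"] * tt["organ_mass_g"]
    stored = tt.groupby(["plant_id", "element"], as_index=False)[
        "element_mass_mg"
    ].sum()
    balance = stored.merge(led.absorbed, on=["plant_id", "element"])
    balance["discrepancy_mg"] = balance["element_mass_mg"] - balance["absorbed_mg"]

    leach_obs = dataset.solution_samples.query("sample_type == 'leachate'")[
        ["plant_id", "date", "element", "concentration_mg_per_L"]
    ].rename(columns={"concentration_mg_per_L": "observed_leachate_mg_per_L"})
    ev = led.events.merge(leach_obs, on=["plant_id", "date", "element"])
    v_cap = dataset.config.capacity_volume_L
    ev["residual_mg"] = (
        ev["true_leachate_mg_per_L"] - ev["observed_leachate_mg_per_L"]
    ) * v_cap
    return ConservationReport(
        tissue_balance=balance,
        event_residuals=ev,
        max_tissue_discrepancy_mg=float(balance["discrepancy_mg"].abs().max()),
        max_event_residual_mg=float(ev["residual_mg"].abs().max()),
    )


def mass_log_frame(dataset: TrialDataset) -> pd.DataFrame:
    """All plants' mass traces as one tidy gravimetric-log DataFrame."""
    frames = []
    for pid, series in dataset.mass_series.items():
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": series.times,
                    "container_id": pid,
                    "mass_g": series.masses,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
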