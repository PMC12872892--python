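"""Transpiration-driven nutrient mass balance: the analytical core.

The model links three measurable quantities for a containerized crop under
fertigation:

* **Water-use efficiency** ``WUE = M_dry / V_irrigation`` (g dry biomass per
  litre transpired),
* **Predicted input concentration** ``C_input = C_tissue x WUE`` (mg L^-1):
  the element concentration a nutrient solution must carry so that water
  taken up to build biomass delivers exactly the element mass stored in
  that biomass,
* **Solution-depletion uptake**: after a 12-h uptake cycle in which the
  plant transpires ``V_t`` litres from a substrate holding ``V_cap`` litres
  of solution and the transpired water is replaced with deionized water,
  element conservation gives

      ``C_uptake = (C_supply - C_leachate) * V_cap / V_t``  (mg per L transpired).

  Absorbed element mass leaves the solution with the transpiration stream;
  the DI refill dilutes the residual back to the capacity volume, so the
  leachate assay reads ``C_supply - C_uptake * V_t / V_cap``.

Tissue chemistry enters either organ-explicitly (leaf, stem, root) or as an
organ biomass-weighted whole-plant mean
``C_weighted = sum_organ C_organ * (M_organ / M_total)``.

Percent deviations of predicted inputs from measured uptake
(``100 * (predicted - measured) / measured``) quantify how well each tissue
source forecasts the fertigation recipe actually depleted from solution.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .elements import MEASURED_ELEMENTS, ORGANS, validate_panel
from .errors import InvalidInputError

logger = logging.getLogger(__name__)

#: Fixed priority used to break deviation ties at reporting precision.
SOURCE_PRIORITY: tuple[str, ...] = ("weighted", "leaf", "root", "stem")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WaterUseEfficiency:
    """Whole-plant water-use efficiency (g dry biomass per L transpired)."""

    value: float
    dry_mass: float  # g plant^-1
    irrigation_volume: float  # L plant^-1, total transpired

    def __float__(self) -> float:
        return self.value


@dataclass
class TissueProfile:
    """Element concentrations (mg per g dry mass) of one organ plus its dry mass."""

    organ: str
    concentrations: dict[str, float]
    dry_mass: float  # g

    def __post_init__(self) -> None:
        if self.organ not in ORGANS:
            raise InvalidInputError(f"unknown organ {self.organ!r}")
        self.concentrations = validate_panel(
            self.concentrations, context=f"tissue[{self.organ}]"
        )
        if not math.isfinite(self.dry_mass) or self.dry_mass < 0:
            raise InvalidInputError(f"tissue[{self.organ}]: dry mass must be >= 0")


@dataclass(frozen=True)
class PredictedInput:
    """A predicted solution input concentration for one element and source."""

    element: str
    source: str  # leaf | stem | root | weighted
    concentration: float  # mg L^-1

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise InvalidInputError("predicted input concentration must be >= 0")


@dataclass
class DepletionCycle:
    """One 12-h pour-through uptake cycle for a single plant.

    ``solution_volume_at_capacity`` is the solution volume the substrate
    holds at container capacity; ``transpired_volume`` is the water lost
    over the cycle (both litres).  ``sanity_bound`` caps how large a
    fraction of the held solution may plausibly transpire in one cycle.
    """

    plant_id: str
    cultivar: str
    date: object  # datetime.date or ISO string; carried through, not parsed
    supply_concentration: dict[str, float]
    leachate_concentration: dict[str, float]
    solution_volume_at_capacity: float
    transpired_volume: float
    sanity_bound: float = 1.0

    def __post_init__(self) -> None:
        self.supply_concentration = validate_panel(
            self.supply_concentration, context=f"supply[{self.plant_id}]"
        )
        self.leachate_concentration = validate_panel(
            self.leachate_concentration, context=f"leachate[{self.plant_id}]"
        )
        if self.solution_volume_at_capacity <= 0:
            raise InvalidInputError(
                f"plant {self.plant_id}: capacity volume must be > 0"
            )
        if self.transpired_volume <= 0:
            raise InvalidInputError(
                f"plant {self.plant_id}: transpired volume must be > 0"
            )
        bound = self.solution_volume_at_capacity * self.sanity_bound
        if self.transpired_volume >= bound:
            raise InvalidInputError(
                f"plant {self.plant_id}: transpired volume "
                f"{self.transpired_volume:.3f} L exceeds sanity bound "
                f"{bound:.3f} L (capacity x {self.sanity_bound})"
            )


@dataclass(frozen=True)
class UptakeRecord:
    """Per-element uptake inferred from one depletion cycle (mg per L transpired)."""

    plant_id: str
    cultivar: str
    date: object
    element: str
    uptake_concentration: float
    negative_flag: bool


@dataclass
class DeviationSummary:
    """Signed percent deviations of each prediction source for one cultivar x element."""

    cultivar: str
    element: str
    deviations: dict[str, float]
    best_source: str = field(init=False)
    tie_flag: bool = field(init=False)

    def __post_init__(self) -> None:
        self.best_source, self.tie_flag = best_predictor(self.deviations)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def compute_wue(
    dry_mass: float, irrigation_volume: float, *, plant_id: str | None = None
) -> WaterUseEfficiency:
    """Water-use efficiency: total dry biomass over total volume transpired.

    Parameters
    ----------
    dry_mass : float
        Whole-plant dry biomass at harvest, g.
    irrigation_volume : float
        Total irrigation volume transpired over the monitored phase, L.
    """
    who = f"plant {plant_id}" if plant_id is not None else "input"
    if irrigation_volume <= 0:
        raise InvalidInputError(f"{who}: irrigation volume must be > 0")
    if dry_mass < 0:
        raise InvalidInputError(f"{who}: dry mass must be >= 0")
    return WaterUseEfficiency(
        value=dry_mass / irrigation_volume,
        dry_mass=dry_mass,
        irrigation_volume=irrigation_volume,
    )


def predict_input_concentration(tissue_concentration, wue):
    """Predicted solution input concentration ``C_input = C_tissue x WUE``.

    ``tissue_concentration`` may be a scalar (mg g^-1) or an element panel;
    the product is applied element-wise for panels.  ``wue`` accepts a float
    or a :class:`WaterUseEfficiency`.  Result is in mg L^-1.
    """
    w = float(wue)
    if w < 0:
        raise InvalidInputError("WUE must be >= 0")
    if isinstance(tissue_concentration, Mapping):
        panel = validate_panel(tissue_concentration, context="tissue panel")
        return {el: c * w for el, c in panel.items()}
    c = float(tissue_concentration)
    if c < 0:
        raise InvalidInputError("tissue concentration must be >= 0")
    return c * w


def biomass_weighted_mean(profiles: Iterable[TissueProfile]) -> dict[str, float]:
    """Organ biomass-weighted whole-plant element concentrations.

    Each organ contributes its concentration weighted by its share of total
    dry biomass; weights sum to one by construction.
    """
    profiles = list(profiles)
    if not profiles:
        raise InvalidInputError("at least one organ profile is required")
    total = sum(p.dry_mass for p in profiles)
    if total <= 0:
        raise InvalidInputError("total dry mass must be > 0")
    elements = set(profiles[0].concentrations)
    for p in profiles[1:]:
        if set(p.concentrations) != elements:
            raise InvalidInputError(
                "all organ profiles must report the same element set"
            )
    return {
        el: sum(p.concentrations[el] * (p.dry_mass / total) for p in profiles)
        for el in profiles[0].concentrations
    }


def uptake_from_depletion(
    cycle: DepletionCycle, elements: Iterable[str] = MEASURED_ELEMENTS
) -> list[UptakeRecord]:
    """Per-element uptake from one depletion cycle.

    ``C_uptake = (C_supply - C_leachate) * V_cap / V_t``, mg per litre
    transpired.  A negative result (leachate above supply: apparent
    exclusion or washout) is returned with ``negative_flag`` set, never
    clipped.  Elements missing from either panel are skipped with a logged
    warning.
    """
    scale = cycle.solution_volume_at_capacity / cycle.transpired_volume
    records: list[UptakeRecord] = []
    for el in elements:
        if el not in cycle.supply_concentration or el not in cycle.leachate_concentration:
            logger.warning(
                "plant %s %s: element %s missing from supply or leachate panel; skipped",
                cycle.plant_id,
                cycle.date,
                el,
            )
            continue
        uptake = (
            cycle.supply_concentration[el] - cycle.leachate_concentration[el]
        ) * scale
        records.append(
            UptakeRecord(
                plant_id=cycle.plant_id,
                cultivar=cycle.cultivar,
                date=cycle.date,
                element=el,
                uptake_concentration=uptake,
                negative_flag=uptake < 0,
            )
        )
    return records


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (reporting convention for percents)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def deviation_percent(
    predicted: float, measured: float, *, ndigits: int | None = 1
) -> float:
    """Signed percent deviation of a prediction from the measured value.

    ``100 * (predicted - measured) / measured``; positive means
    overprediction.  By default rounded to one decimal, ties away from
    zero; pass ``ndigits=None`` for full precision.
    """
    if measured <= 0:
        raise InvalidInputError("measured value must be > 0 for percent deviation")
    dev = 100.0 * (predicted - measured) / measured
    if ndigits is None:
        return dev
    return round_half_away(dev, ndigits)


def best_predictor(
    deviations: Mapping[str, float], *, ndigits: int = 1
) -> tuple[str, bool]:
    """Source with the smallest absolute deviation.

    Ties at reporting precision (``ndigits`` decimals) are broken by the
    fixed priority weighted > leaf > root > stem and flagged.
    """
    if not deviations:
        raise InvalidInputError("deviation map must be non-empty")
    rounded = {s: abs(round_half_away(d, ndigits)) for s, d in deviations.items()}
    low = min(rounded.values())
    candidates = [s for s, v in rounded.items() if v == low]

    def priority(source: str) -> tuple[int, str]:
        try:
            return (SOURCE_PRIORITY.index(source), source)
        except ValueError:
            return (len(SOURCE_PRIORITY), source)

    best = min(candidates, key=priority)
    return best, len(candidates) > 1


def replenishment_estimate(
    uptake_concentrations: Mapping[str, float], transpired_volume: float
) -> dict[str, float]:
    """Daily element replenishment mass (mg d^-1) needed to hold the recipe.

    The element mass leaving solution in a day is the mean uptake
    concentration times the day's transpired volume; replacing exactly that
    mass keeps the input solution stable.
    """
    if transpired_volume < 0:
        raise InvalidInputError("transpired volume must be >= 0")
    panel = validate_panel(
        uptake_concentrations, context="uptake panel", nonnegative=False
    )
    return {el: c * transpired_volume for el, c in panel.items()}


def summarize_deviations(
    cultivar: str,
    element: str,
    predicted_by_source: Mapping[str, float],
    measured: float,
    *,
    ndigits: int | None = 1,
) -> DeviationSummary:
    """Build a :class:`DeviationSummary` from predictions and measured uptake."""
    devs = {
        source: deviation_percent(pred, measured, ndigits=ndigits)
        for source, pred in predicted_by_source.items()
    }
    return DeviationSummary(cultivar=cultivar, element=element, deviations=devs)
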