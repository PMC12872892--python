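# Methods

## The mass-balance model

The package treats nutrient uptake as a conserved-mass bookkeeping problem
around the transpiration stream. Three relations carry the analysis:

1. **Water-use efficiency.** WUE = M_dry / V_irrigation, grams of
   whole-plant dry biomass per litre of water transpired over the monitored
   phase. V_irrigation is measured gravimetrically: containers sit on
   balances logged every 10 minutes, substrate surfaces are covered, so
   mass loss between irrigation events is transpiration (1 g = 1 mL).
2. **Input prediction.** C_input = C_tissue × WUE. If a plant stores
   C_tissue mg of an element per gram of dry mass and builds WUE grams of
   dry mass per litre transpired, a solution carrying C_tissue × WUE
   mg L⁻¹ delivers element and water in exactly the plant's ratio of use.
   C_tissue is taken per organ (leaf, stem, root) and as the organ
   biomass-weighted mean C_weighted = Σ C_organ · M_organ / M_total, whose
   weights sum to one by construction.
3. **Depletion uptake.** The pour-through protocol waters the substrate to
   container capacity (holding V_cap litres of solution at supply
   concentration C_supply), lets the plant draw solution for a 12-h day
   course while transpiring V_t litres, then replaces the transpired
   volume with deionized water and samples the drainage. Element
   conservation gives the leachate assay C_leach = C_supply − C_up·V_t/V_cap
   and hence the uptake per litre transpired

       C_up = (C_supply − C_leach) · V_cap / V_t.

   The protocol itself never states this inversion; it follows from
   assuming (a) absorbed element mass leaves the solution pool with the
   uptake stream, (b) the DI refill only dilutes, and (c) the 230 mL
   pour-through draw samples the bulk solution representatively. A forward
   simulation of the cycle is used as the oracle for this inversion in the
   tests. Negative uptake values (leachate above supply — apparent
   exclusion or washout) are reported with a flag, never clipped, because
   clipping would hide conservation violations.

Assumptions shared by all three: no evaporation from covered substrate, no
ion speciation or antagonism, drift-free balances, and an inert substrate
(perlite) that neither binds nor releases nutrient ions.

## Parameters that matter

| parameter | unit | default | rationale |
|---|---|---|---|
| capacity volume V_cap | L | 4.0 | solution held by 1.5 kg perlite in an 11-L container at capacity; per-container configurable because holding capacity is rarely printed |
| irrigation-event threshold | g | 50 | dripper delivery (≈1.9 L min⁻¹ for minutes) dwarfs balance noise (σ ≈ 2 g); configurable |
| smoothing window | samples | 3 | rolling median before differencing; suppresses isolated spikes, preserves monotone segments and their endpoints exactly |
| day-course window | clock | 07:00–19:00 | the 12-h uptake cycle; exact clock bounds are configurable since protocols differ |
| deviation rounding | decimals | 1 | percent deviations reported at one decimal, ties away from zero; full precision kept internally |
| cycle sanity bound | — | 1.0 | a 12-h transpired volume may not exceed the solution held at capacity |

Best-predictor ties at reporting precision are broken by the fixed
priority weighted > leaf > root > stem and flagged; real data essentially
never produce exact ties, but the rule makes the selection deterministic.

## Statistical layer

The uptake trial is a balanced split-plot: cultivar between subjects,
sampling date within, replicate plants as subjects. `rm_anova` implements
the closed-form strata for the balanced complete layout (cultivar over
subject-within-cultivar error; date and cultivar × date over the
subject × date residual) and refuses unbalanced input — listwise handling
belongs upstream. The uncorrected univariate F is reported; the
Greenhouse–Geisser epsilon is attached for information only, since no
sphericity correction is part of the default analysis. p-values are
two-tailed with a reporting floor of 1e-16.

Marginal-mean contrasts default to the family "all cultivar pairs at each
date" (family size = number of dates for two cultivars), Bonferroni
adjusted (p_adj = min(1, m·p)). Between-cultivar differences at a fixed
date combine both error strata, SE² = 2[(t−1)·MS_resid + MS_subj]/(t·n),
with Satterthwaite-combined degrees of freedom; within-cultivar date pairs
use the residual stratum alone. The family choice is configuration, not
doctrine — per-date versus crossed families answer different questions.

Welch's two-sample test (unpooled variances, Welch–Satterthwaite df) is
used for cultivar comparisons of tissue-derived predictions at n = 4 per
cultivar; samples with zero variance raise a degenerate-input error
rather than returning an infinite statistic. Influence diagnostics
(hat-matrix leverage, Cook's distance) come from an OLS cell-means fit.

## The synthetic trial generator

The generator emulates the study design — 2 cultivars × 4 replicate
plants, a 38-day vegetative phase, ten 12-h depletion cycles, harvest
organ chemistry — with exact element conservation before noise:

- **Growth**: exponential, M(d) = M₀·e^(r·d), with M₀ = 12 g (an
  established transplanted clone) and r chosen so harvest mass reaches
  ≈190 g (vigorous preset) / ≈185 g (second preset). No published growth
  curve exists for the emulated trial; constant relative growth rate is
  the minimal defensible choice for a vegetative phase.
- **Transpiration**: proportional to daily biomass gain and scaled so
  harvest dry mass over total transpired volume equals the target WUE
  exactly (4.71 and 4.59 g L⁻¹ for the two presets — the published
  cultivar values, used as calibration).
- **Uptake trajectories**: linear in time, pinned to the leachate sampling
  window (phase days 17–35, ten events at 2-day spacing — the monitored
  window of the emulated trial) and held constant outside it. Preset
  endpoints use the reported observed ranges: N and K decline (e.g. N
  135→75 and 144→97 mg L⁻¹), Ca and Mg rise, micro-elements follow gentle
  trends whose means match the published uptake means.
- **Instrument records**: the balance trace is built per day (flat
  overnight, linear 07:00–19:00 decline, refills at 07:00 and 20:00) with
  additive Gaussian noise (σ = 2 g); the evening irrigation replaces half
  the day's transpiration and the morning irrigation restores capacity, so
  both scheduled events produce detectable gains. Leachate and tissue
  assays get multiplicative Gaussian noise (2 % relative — a typical
  optical-emission assay CV). Replicates differ through a 5 % CV jitter on
  initial dry mass. All randomness flows from one seeded generator;
  identical seeds give byte-identical datasets.
- **Tissue chemistry**: cumulative absorbed element mass is distributed to
  organs by fixed per-element allocation fractions (iron and copper
  root-dominant, calcium and boron leaf-dominant, potassium stem-rich),
  then divided by organ dry mass. The ledger retains the pre-noise truth;
  `ledger_audit` verifies that stored tissue mass equals absorbed mass
  exactly and localizes any corrupted leachate record as the largest
  per-event conservation residual.

What the generator does **not** emulate: diurnal transpiration dynamics
within the day course (the decline is linear), evaporation, substrate
retention or biofilm losses, ion interactions, balance drift, or true
biological organ-allocation variability. Passing recovery tests therefore
demonstrates that the analysis inverts the stated measurement model
correctly — not that real trials are free of the system-level retention
effects that make, for example, potassium uptake hard to predict from
tissue alone.

## Numerical choices

- Segment water loss is the difference of segment-endpoint masses after a
  within-segment median filter (window 3, edges preserved); smoothing
  never crosses an irrigation jump. Losses are clipped at zero per
  segment; sub-threshold positive jitters are ignored, not subtracted.
- CSVs are written with pandas' shortest round-trip float repr and read
  with the `round_trip` parser, so file-based reruns are byte-identical
  and lossless.
- Deviation rounding is decimal-exact (ties away from zero via `Decimal`),
  not binary-float rounding.
- Degenerate inputs (zero-variance samples, constant ANOVA responses,
  zero error strata) yield explicit flags or typed errors, never NaNs
  propagating silently.

## Known limitations

- The depletion inversion inherits the pour-through assumptions; if the
  draw under-samples the bulk solution the uptake estimate is biased in a
  way no internal check can detect.
- Uptake estimates scale noise by V_cap/V_t, so early-phase cycles (small
  plants, small transpired volumes) carry much larger uncertainty than
  late ones; the repeated-measures layer treats all dates
  homoscedastically.
- The statistical layer requires complete balanced layouts by design; a
  mixed-model engine for unbalanced data is out of scope.
- Flowering-phase nutrition, EC/pH chemistry and mechanistic uptake
  kinetics are out of scope.
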