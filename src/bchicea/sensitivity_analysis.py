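"""Univariate (tornado) scenarios and probabilistic sensitivity analysis.

The univariate analysis re-runs the deterministic engine with exactly one
parameter dimension changed per scenario. The PSA draws every model input
from beta (utilities on [0, 1] supports and reoperation-type proportions),
gamma (costs) or normal (demographics and utility gains) distributions
parameterised by method of moments, runs the deterministic engine per draw,
and summarises the draws as a cost-effectiveness acceptability curve.

Draws are consumed in a fixed, documented parameter order from a single
seeded generator, so a run is reproducible bit-for-bit from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import pandas as pd

from bchicea.event_rates import ReoperationSplit, rate_to_cycle_probability
from bchicea.markov_engine import (
    ArmParameters,
    CEResult,
    LifeTable,
    ModelConfig,
    UtilitySchedule,
    run_model,
)

__all__ = [
    "Scenario",
    "default_scenarios",
    "run_univariate",
    "converge_transition_probabilities",
    "make_converging_rate_fn",
    "ParamDist",
    "build_psa_distributions",
    "run_psa",
    "ceac",
]


# ---------------------------------------------------------------------------
# Univariate scenarios


@dataclass(frozen=True)
class Scenario:
    """One univariate scenario: a name plus a transform of the base inputs.

    ``transform(osia, baha, config)`` returns
    ``(osia, baha, config, rate_fns)`` with exactly one parameter dimension
    changed; ``rate_fns`` is ``None`` or a per-arm pair of per-cycle rate
    overrides.
    """

    name: str
    group: str
    transform: Callable


def _scale_costs(arm: ArmParameters, factor: float, fields: tuple[str, ...]) -> ArmParameters:
    new = replace(
        arm.costs, **{f: getattr(arm.costs, f) * factor for f in fields}
    )
    return replace(arm, costs=new)


def _chl_mhl_utilities(arm: ArmParameters, gains: tuple[float, float], baseline: float) -> ArmParameters:
    return replace(
        arm,
        utilities=UtilitySchedule(baseline=baseline, gain_3m=gains[0], gain_6m=gains[1]),
    )


def default_scenarios(
    chl_mhl: dict | None = None,
) -> list[Scenario]:
    """The standard univariate scenario battery.

    ``chl_mhl`` optionally overrides the subgroup utility settings
    (keys: baseline, osia_gain_3m, osia_gain_6m, baha_gain).
    """
    sub = {
        "baseline": 0.62,
        "osia_gain_3m": 0.11,
        "osia_gain_6m": 0.12,
        "baha_gain": 0.06,
    }
    if chl_mhl:
        sub.update(chl_mhl)

    def horizon(y):
        return lambda o, b, c: (o, b, replace(c, horizon_years=y), None)

    def discount(r):
        return lambda o, b, c: (o, b, replace(c, discount_annual=r), None)

    def procedures(f):
        fields = ("surgery", "hospitalisation")
        return lambda o, b, c: (
            _scale_costs(o, f, fields),
            _scale_costs(b, f, fields),
            c,
            None,
        )

    def ae_cost(f):
        return lambda o, b, c: (
            _scale_costs(o, f, ("ae_management",)),
            _scale_costs(b, f, ("ae_management",)),
            c,
            None,
        )

    def converging(o, b, c):
        return o, b, c, (None, make_converging_rate_fn(b, o, c))

    def subgroup_utilities(o, b, c):
        return (
            _chl_mhl_utilities(o, (sub["osia_gain_3m"], sub["osia_gain_6m"]), sub["baseline"]),
            _chl_mhl_utilities(b, (sub["baha_gain"], sub["baha_gain"]), sub["baseline"]),
            c,
            None,
        )

    return [
        Scenario("horizon_5y", "time_horizon", horizon(5.0)),
        Scenario("horizon_lifetime", "time_horizon", horizon(None)),
        Scenario("discount_2.5pct", "discounting", discount(0.025)),
        Scenario("discount_7.5pct", "discounting", discount(0.075)),
        Scenario("procedure_costs_+10pct", "procedure_costs", procedures(1.1)),
        Scenario("procedure_costs_-10pct", "procedure_costs", procedures(0.9)),
        Scenario("ae_cost_+10pct", "ae_cost", ae_cost(1.1)),
        Scenario("ae_cost_-10pct", "ae_cost", ae_cost(0.9)),
        Scenario("converging_transition_probabilities", "transition_probabilities", converging),
        Scenario("chl_mhl_utilities", "utilities", subgroup_utilities),
    ]


def run_univariate(
    osia: ArmParameters,
    baha: ArmParameters,
    config: ModelConfig,
    life_table: LifeTable,
    scenarios: list[Scenario] | None = None,
) -> pd.DataFrame:
    """Solve the base case, then one run per scenario.

    Returns a table with the base row first and scenarios sorted by
    ``|ICER - base ICER|`` descending (tornado order).
    """
    scenarios = default_scenarios() if scenarios is None else scenarios
    base = run_model(osia, baha, config, life_table)
    if base.icer is None:
        raise ValueError("base case has zero incremental QALYs; no tornado possible")

    rows = [
        {
            "scenario": "base_case",
            "group": "base",
            "icer": base.icer,
            "icer_undiscounted": base.icer_undiscounted,
            "incremental_cost": base.incremental_cost,
            "incremental_qalys": base.incremental_qalys,
            "abs_change_vs_base": 0.0,
        }
    ]
    for sc in scenarios:
        o, b, c, rate_fns = sc.transform(osia, baha, config)
        res = run_model(o, b, c, life_table, rate_fns=rate_fns)
        rows.append(
            {
                "scenario": sc.name,
                "group": sc.group,
                "icer": res.icer,
                "icer_undiscounted": res.icer_undiscounted,
                "incremental_cost": res.incremental_cost,
                "incremental_qalys": res.incremental_qalys,
                "abs_change_vs_base": (
                    math.inf if res.icer is None else abs(res.icer - base.icer)
                ),
            }
        )
    df = pd.DataFrame(rows)
    head, tail = df.iloc[:1], df.iloc[1:]
    tail = tail.sort_values("abs_change_vs_base", ascending=False, kind="mergesort")
    return pd.concat([head, tail], ignore_index=True)


# ---------------------------------------------------------------------------
# Converging transition probabilities


def converge_transition_probabilities(
    base_rate: float,
    target_rate: float,
    t_months: float,
    window: tuple[float, float] = (12.0, 24.0),
) -> float:
    """Linear convergence of ``base_rate`` toward ``target_rate``.

    Before the window the base rate applies unchanged; across the window the
    rate interpolates linearly; from the window end onward both arms share
    the target rate.
    """
    lo, hi = window
    w = min(1.0, max(0.0, (t_months - lo) / (hi - lo)))
    return (1.0 - w) * base_rate + w * target_rate


def make_converging_rate_fn(
    arm: ArmParameters, target: ArmParameters, config: ModelConfig
) -> Callable[[int], tuple[float, float, float, float]]:
    """Per-cycle rate override converging one arm's rates to another's.

    Rates are interpolated on the monthly scale at the cycle start time and
    then converted to per-cycle probabilities; the arm keeps its own
    reoperation-type split.
    """

    def rate_fn(cycle_index: int) -> tuple[float, float, float, float]:
        t_months = (cycle_index - 1) * config.cycle_months
        reop = converge_transition_probabilities(
            arm.reop_rate_monthly, target.reop_rate_monthly, t_months
        )
        ae = converge_transition_probabilities(
            arm.ae_rate_monthly, target.ae_rate_monthly, t_months
        )
        p_reop = rate_to_cycle_probability(reop, config.cycle_months)
        p_ae = rate_to_cycle_probability(ae, config.cycle_months)
        return (
            p_reop * arm.reop_split.p_revision,
            p_reop * arm.reop_split.p_explant,
            p_reop * arm.reop_split.p_reimplant,
            p_ae,
        )

    return rate_fn


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis


@dataclass(frozen=True)
class ParamDist:
    """A sampling distribution for one scalar model input.

    kinds
    -----
    ``fixed``         value
    ``normal``        mean, se
    ``gamma``         mean, se (method of moments; shape = (mean/se)²)
    ``beta_moments``  mean, se (method of moments on [0, 1])
    ``beta_counts``   events, non_events (Beta(events, non_events))
    """

    name: str
    kind: str
    args: tuple[float, ...]

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "fixed":
            return self.args[0]
        if self.kind == "normal":
            mean, se = self.args
            if se < 0:
                raise ValueError(f"{self.name}: se must be >= 0")
            return mean if se == 0 else float(rng.normal(mean, se))
        if self.kind == "gamma":
            mean, se = self.args
            if se < 0 or mean < 0:
                raise ValueError(f"{self.name}: gamma needs mean, se >= 0")
            if se == 0 or mean == 0:
                return mean
            shape = (mean / se) ** 2
            scale = se**2 / mean
            return float(rng.gamma(shape, scale))
        if self.kind == "beta_moments":
            mean, se = self.args
            if not 0 < mean < 1:
                raise ValueError(f"{self.name}: beta mean must be in (0, 1)")
            if se == 0:
                return mean
            nu = mean * (1 - mean) / se**2 - 1
            if nu <= 0:
                raise ValueError(f"{self.name}: se {se} too large for beta mean {mean}")
            return float(rng.beta(mean * nu, (1 - mean) * nu))
        if self.kind == "beta_counts":
            a, b = self.args
            if a <= 0 or b <= 0:
                raise ValueError(f"{self.name}: beta counts must be > 0")
            return float(rng.beta(a, b))
        raise ValueError(f"unknown distribution kind {self.kind!r}")


def build_psa_distributions(
    osia: ArmParameters,
    baha: ArmParameters,
    config: ModelConfig,
    *,
    baseline_utility_se: float = 0.0258,
    gain_se_mode: str = "ten_percent",
    study_gain_ses: dict[str, float] | None = None,
    cost_cv: float = 0.10,
    start_age_se: float = 1.86,
    event_counts: dict[str, tuple[float, float]] | None = None,
) -> list[ParamDist]:
    """Assemble the PSA input distributions in their fixed sampling order.

    Order (one draw each per iteration): baseline utility; osia 3-month and
    6-month gains; baha gain; the five osia costs; the five baha costs; the
    four event rates (osia/baha reoperation and soft-tissue); the baha
    explant fraction; start age.

    ``gain_se_mode='ten_percent'`` sets each utility-gain SE to 10% of its
    mean (in line with the ±10% univariate cost ranges);
    ``'study'`` uses the study-level standard errors supplied via
    ``study_gain_ses`` (keys: osia_gain_3m, osia_gain_6m, baha_gain).
    """
    if gain_se_mode not in ("ten_percent", "study"):
        raise ValueError(f"unknown gain_se_mode {gain_se_mode!r}")

    def gain_se(key: str, mean: float) -> float:
        if gain_se_mode == "ten_percent":
            return 0.10 * abs(mean)
        if not study_gain_ses or key not in study_gain_ses:
            raise ValueError(f"study gain SE missing for {key!r}")
        return study_gain_ses[key]

    if event_counts is None:
        # reconstruct (events, non-events) from the monthly rates and the
        # base-case exposure denominators
        event_counts = {
            "osia_reop": (786 * osia.reop_rate_monthly, 786 * (1 - osia.reop_rate_monthly)),
            "osia_ae": (786 * osia.ae_rate_monthly, 786 * (1 - osia.ae_rate_monthly)),
            "baha_reop": (1296 * baha.reop_rate_monthly, 1296 * (1 - baha.reop_rate_monthly)),
            "baha_ae": (324 * baha.ae_rate_monthly, 324 * (1 - baha.ae_rate_monthly)),
        }

    dists: list[ParamDist] = [
        ParamDist(
            "baseline_utility",
            "beta_moments",
            (osia.utilities.baseline, baseline_utility_se),
        ),
        ParamDist(
            "osia_gain_3m",
            "normal",
            (osia.utilities.gain_3m, gain_se("osia_gain_3m", osia.utilities.gain_3m)),
        ),
        ParamDist(
            "osia_gain_6m",
            "normal",
            (osia.utilities.gain_6m, gain_se("osia_gain_6m", osia.utilities.gain_6m)),
        ),
        ParamDist(
            "baha_gain",
            "normal",
            (baha.utilities.gain_6m, gain_se("baha_gain", baha.utilities.gain_6m)),
        ),
    ]
    for label, arm in (("osia", osia), ("baha", baha)):
        for f in (
            "device",
            "replacement_sound_processor",
            "surgery",
            "hospitalisation",
            "ae_management",
        ):
            mean = getattr(arm.costs, f)
            dists.append(ParamDist(f"{label}_cost_{f}", "gamma", (mean, cost_cv * mean)))
    for key in ("osia_reop", "osia_ae", "baha_reop", "baha_ae"):
        dists.append(ParamDist(f"rate_{key}", "beta_counts", event_counts[key]))
    dists.append(ParamDist("baha_explant_fraction", "beta_counts", (2.0, 2.0)))
    dists.append(ParamDist("start_age", "normal", (config.start_age, start_age_se)))
    return dists


def _apply_draw(
    values: dict[str, float],
    osia: ArmParameters,
    baha: ArmParameters,
    config: ModelConfig,
) -> tuple[ArmParameters, ArmParameters, ModelConfig]:
    def clamp01(x: float) -> float:
        return min(1.0, max(0.0, x))

    baseline = clamp01(values["baseline_utility"])

    def cap_gain(g: float) -> float:
        return min(g, 1.0 - baseline)  # aided utility may not exceed 1

    def costs_for(label: str, arm: ArmParameters):
        return replace(
            arm.costs,
            device=values[f"{label}_cost_device"],
            replacement_sound_processor=values[f"{label}_cost_replacement_sound_processor"],
            surgery=values[f"{label}_cost_surgery"],
            hospitalisation=values[f"{label}_cost_hospitalisation"],
            ae_management=values[f"{label}_cost_ae_management"],
        )

    osia_new = replace(
        osia,
        costs=costs_for("osia", osia),
        utilities=UtilitySchedule(
            baseline=baseline,
            gain_3m=cap_gain(values["osia_gain_3m"]),
            gain_6m=cap_gain(values["osia_gain_6m"]),
        ),
        reop_rate_monthly=clamp01(values["rate_osia_reop"]),
        ae_rate_monthly=clamp01(values["rate_osia_ae"]),
    )
    explant = clamp01(values["baha_explant_fraction"])
    baha_new = replace(
        baha,
        costs=costs_for("baha", baha),
        utilities=UtilitySchedule(
            baseline=baseline,
            gain_3m=cap_gain(values["baha_gain"]),
            gain_6m=cap_gain(values["baha_gain"]),
        ),
        reop_rate_monthly=clamp01(values["rate_baha_reop"]),
        ae_rate_monthly=clamp01(values["rate_baha_ae"]),
        reop_split=ReoperationSplit(0.0, explant, 1.0 - explant),
    )
    cfg_new = replace(config, start_age=max(18.0, values["start_age"]))
    return osia_new, baha_new, cfg_new


def run_psa(
    osia: ArmParameters,
    baha: ArmParameters,
    config: ModelConfig,
    life_table: LifeTable,
    n_draws: int = 1000,
    seed: int = 0,
    dists: list[ParamDist] | None = None,
    **dist_kwargs,
) -> pd.DataFrame:
    """Monte Carlo PSA: sample inputs, run the deterministic engine per draw.

    Returns one row per draw with the sampled parameter values, incremental
    cost and QALYs (discounted), and the draw's ICER (NaN where incremental
    QALYs are zero).
    """
    if n_draws < 1:
        raise ValueError(f"n_draws must be >= 1, got {n_draws}")
    if dists is None:
        dists = build_psa_distributions(osia, baha, config, **dist_kwargs)
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_draws):
        values = {d.name: d.sample(rng) for d in dists}
        o, b, c = _apply_draw(values, osia, baha, config)
        res = run_model(o, b, c, life_table)
        rec = {"draw": i, **values}
        rec["incremental_cost"] = res.incremental_cost
        rec["incremental_qalys"] = res.incremental_qalys
        rec["icer"] = np.nan if res.icer is None else res.icer
        records.append(rec)
    return pd.DataFrame.from_records(records)


def ceac(samples: pd.DataFrame, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve from PSA draws.

    For each willingness-to-pay λ, the fraction of draws with positive net
    monetary benefit λ·ΔQ − ΔC. The empirical curve is not forced monotone.
    """
    if len(samples) == 0:
        raise ValueError("ceac requires a nonempty sample set")
    dq = samples["incremental_qalys"].to_numpy()
    dc = samples["incremental_cost"].to_numpy()
    rows = [
        {"wtp": float(lam), "probability": float(np.mean(lam * dq - dc > 0))}
        for lam in wtp_grid
    ]
    return pd.DataFrame(rows)
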