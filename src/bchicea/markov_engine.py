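"""Two-arm Markov cohort cost-utility engine.

Quarterly cycles, half-cycle correction for continuous accruals (utilities,
adverse-event management costs), event-time discounting for one-off costs,
a one-year reimplantation tunnel with time-dependent utilities, age-matched
background mortality from an annual life table, and ICER computation.

The engine is fully deterministic; all randomness lives in
:mod:`bchicea.sensitivity_analysis`.

State space
-----------
======================  ====================================================
``AIDED_FIRST``         aided with the initial device
``AIDED_REVISED``       aided after a revision of the first device
``TUNNEL_REIMPLANT_Q1`` .. ``Q4``  quarters 1-4 after reimplantation
``AIDED_SECOND``        aided with the replacement device
``UNAIDED_EXPLANTED``   device explanted, no further device (absorbing but
                        for death)
``DEAD``                absorbing
======================  ====================================================

A second explantation (from ``AIDED_SECOND``) is terminal: no third device
is modelled, so the reimplant fraction of reoperations from the second
device also leads to ``UNAIDED_EXPLANTED``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from bchicea.event_rates import ReoperationSplit, rate_to_cycle_probability

__all__ = [
    "STATES",
    "UtilitySchedule",
    "CostSet",
    "LifeTable",
    "ArmParameters",
    "ModelConfig",
    "CohortTrace",
    "ArmOutcomes",
    "CEResult",
    "build_transition_matrix",
    "run_cohort",
    "utility_for",
    "accrue_outcomes",
    "run_arm",
    "compute_icer",
    "run_model",
]

STATES = (
    "AIDED_FIRST",
    "AIDED_REVISED",
    "TUNNEL_REIMPLANT_Q1",
    "TUNNEL_REIMPLANT_Q2",
    "TUNNEL_REIMPLANT_Q3",
    "TUNNEL_REIMPLANT_Q4",
    "AIDED_SECOND",
    "UNAIDED_EXPLANTED",
    "DEAD",
)
S = {name: i for i, name in enumerate(STATES)}
N_STATES = len(STATES)
#: States in which the cohort carries a working device (eligible for sound
#: processor upgrades and at risk of soft-tissue complications).
DEVICE_STATES = tuple(range(7))
#: States eligible for reoperation (tunnel quarters are excluded: the device
#: was just replaced).
AT_RISK_STATES = (S["AIDED_FIRST"], S["AIDED_REVISED"], S["AIDED_SECOND"])


class ConfigurationError(ValueError):
    pass


class ConstructionError(ValueError):
    pass


@dataclass(frozen=True)
class UtilitySchedule:
    """Health-state utilities: a pre-operative baseline plus aided gains.

    ``gain_3m`` applies in the second quarter after (re)implantation and
    ``gain_6m`` from the third quarter onward, constant thereafter.
    """

    baseline: float
    gain_3m: float
    gain_6m: float

    def __post_init__(self) -> None:
        for name, u in (
            ("baseline", self.baseline),
            ("aided at 3m", self.baseline + self.gain_3m),
            ("aided at 6m", self.baseline + self.gain_6m),
        ):
            if not -1.0 <= u <= 1.0:
                raise ConfigurationError(f"utility {name} out of [-1, 1]: {u}")


@dataclass(frozen=True)
class CostSet:
    """Tariffs in AUD for one intervention arm."""

    device: float
    replacement_sound_processor: float
    surgery: float
    hospitalisation: float
    ae_management: float

    def __post_init__(self) -> None:
        for f in (
            self.device,
            self.replacement_sound_processor,
            self.surgery,
            self.hospitalisation,
            self.ae_management,
        ):
            if f < 0:
                raise ConfigurationError(f"costs must be >= 0, got {f}")

    @property
    def procedure(self) -> float:
        """Cost of a reoperation procedure (surgery + hospitalisation)."""
        return self.surgery + self.hospitalisation

    @property
    def initial(self) -> float:
        """Up-front cost at implantation: device + surgery + hospitalisation."""
        return self.device + self.surgery + self.hospitalisation


class LifeTable:
    """Annual death probabilities by single year of age.

    q is constant within each year of age; ages beyond the table use the last
    row. Quarterly death probabilities are ``1 - (1 - q)**0.25``.
    """

    def __init__(self, ages: np.ndarray, qx: np.ndarray):
        ages = np.asarray(ages, dtype=int)
        qx = np.asarray(qx, dtype=float)
        if ages.shape != qx.shape or ages.ndim != 1 or len(ages) == 0:
            raise ConfigurationError("life table needs matching 1-d age/qx arrays")
        order = np.argsort(ages)
        ages, qx = ages[order], qx[order]
        if np.any(np.diff(ages) != 1):
            raise ConfigurationError("life table ages must be contiguous")
        if np.any((qx < 0) | (qx > 1)):
            raise ConfigurationError("life table qx must lie in [0, 1]")
        self.ages = ages
        self.qx = qx

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path, comment="#")
        if not {"age", "qx"} <= set(df.columns):
            raise ConfigurationError("life table CSV needs 'age' and 'qx' columns")
        return cls(df["age"].to_numpy(), df["qx"].to_numpy())

    @classmethod
    def zero_mortality(cls, max_age: int = 120) -> "LifeTable":
        return cls(np.arange(max_age + 1), np.zeros(max_age + 1))

    def annual_q(self, age: float) -> float:
        idx = int(np.clip(math.floor(age) - self.ages[0], 0, len(self.ages) - 1))
        return float(self.qx[idx])

    def cycle_death_prob(self, age: float, cycle_years: float) -> float:
        return 1.0 - (1.0 - self.annual_q(age)) ** cycle_years


@dataclass(frozen=True)
class ArmParameters:
    """Complete parameterisation of one model arm."""

    name: str
    costs: CostSet
    utilities: UtilitySchedule
    reop_rate_monthly: float
    reop_split: ReoperationSplit
    ae_rate_monthly: float

    def cycle_probs(self, cycle_months: int) -> tuple[float, float, float, float]:
        """(p_revision, p_explant, p_reimplant, p_ae) per cycle."""
        p_reop = rate_to_cycle_probability(self.reop_rate_monthly, cycle_months)
        p_ae = rate_to_cycle_probability(self.ae_rate_monthly, cycle_months)
        return (
            p_reop * self.reop_split.p_revision,
            p_reop * self.reop_split.p_explant,
            p_reop * self.reop_split.p_reimplant,
            p_ae,
        )


@dataclass(frozen=True)
class ModelConfig:
    """Run configuration shared by both arms.

    ``horizon_years = None`` means a lifetime horizon: the run continues
    until the alive occupancy drops below 1e-6 or the cohort reaches age 100.

    Sound processor upgrades occur at every ``sp_upgrade_interval_years``
    anniversary inside the horizon; ``include_boundary_upgrade`` controls
    whether an upgrade falling exactly on the horizon end is costed (the
    base-case convention includes it, which reproduces the published total
    costs).

    ``reimplant_includes_device``: when True, reimplantation is costed as
    device + surgery + hospitalisation; when False (default) as a procedure
    only (surgery + hospitalisation), treating the replacement implant as
    part of the procedure tariff.
    """

    start_age: float = 47.15
    horizon_years: float | None = 10.0
    cycle_months: int = 3
    discount_annual: float = 0.05
    sp_upgrade_interval_years: float = 5.0
    wtp: float = 50_000.0
    include_boundary_upgrade: bool = True
    reimplant_includes_device: bool = False
    max_age: float = 100.0
    alive_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.horizon_years is not None and self.horizon_years <= 0:
            raise ConfigurationError(f"horizon must be > 0, got {self.horizon_years}")
        if self.discount_annual < 0:
            raise ConfigurationError(f"discount must be >= 0, got {self.discount_annual}")
        if 12 % self.cycle_months != 0:
            raise ConfigurationError(f"cycle_months must divide 12, got {self.cycle_months}")

    @property
    def cycle_years(self) -> float:
        return self.cycle_months / 12.0

    def n_cycles(self) -> int:
        if self.horizon_years is not None:
            n = self.horizon_years / self.cycle_years
            if abs(n - round(n)) > 1e-9:
                raise ConfigurationError(
                    f"horizon {self.horizon_years}y is not a whole number of cycles"
                )
            return int(round(n))
        return int(math.ceil((self.max_age - self.start_age) / self.cycle_years))

    def discount_factor(self, t_years: float) -> float:
        return (1.0 + self.discount_annual) ** (-t_years)


@dataclass
class CohortTrace:
    """Per-cycle state occupancy and expected event counts for one arm."""

    arm: str
    n_cycles: int
    cycle_years: float
    ages: np.ndarray  # age at the start of each cycle, length n_cycles
    occupancy: np.ndarray  # (n_cycles + 1, N_STATES); row 0 = initial
    revisions: np.ndarray  # expected revision procedures per cycle
    explants: np.ndarray  # expected explantation procedures per cycle
    reimplants: np.ndarray  # expected reimplantation procedures per cycle
    ae_events: np.ndarray  # expected soft-tissue complications per cycle

    def occupancy_hcc(self) -> np.ndarray:
        """Half-cycle-corrected occupancy: average of cycle start and end."""
        return 0.5 * (self.occupancy[:-1] + self.occupancy[1:])

    @property
    def alive(self) -> np.ndarray:
        return 1.0 - self.occupancy[:, S["DEAD"]]


@dataclass(frozen=True)
class ArmOutcomes:
    """Accrued totals for one arm."""

    arm: str
    cost_discounted: float
    cost_undiscounted: float
    qalys_discounted: float
    qalys_undiscounted: float
    cost_breakdown: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CEResult:
    """Incremental cost-effectiveness comparison of two arms."""

    osia: ArmOutcomes
    baha: ArmOutcomes
    incremental_cost: float
    incremental_qalys: float
    icer: float | None
    incremental_cost_undiscounted: float
    incremental_qalys_undiscounted: float
    icer_undiscounted: float | None
    wtp: float
    cost_effective: bool | None


def build_transition_matrix(
    p_revision: float,
    p_explant: float,
    p_reimplant: float,
    q_death: float,
) -> np.ndarray:
    """Single-cycle transition matrix given per-cycle event probabilities.

    Death competes first (probability ``q_death`` from every alive state);
    device transitions apply to survivors. Rows must sum to 1.
    """
    probs = (p_revision, p_explant, p_reimplant, q_death)
    if any(not 0 <= p <= 1 for p in probs):
        raise ConstructionError(f"probabilities out of [0, 1]: {probs}")
    p_reop = p_revision + p_explant + p_reimplant
    if p_reop > 1:
        raise ConstructionError(f"reoperation probabilities sum above 1: {p_reop}")
    s = 1.0 - q_death
    m = np.zeros((N_STATES, N_STATES))

    m[S["AIDED_FIRST"], S["AIDED_FIRST"]] = s * (1 - p_reop)
    m[S["AIDED_FIRST"], S["AIDED_REVISED"]] = s * p_revision
    m[S["AIDED_FIRST"], S["UNAIDED_EXPLANTED"]] = s * p_explant
    m[S["AIDED_FIRST"], S["TUNNEL_REIMPLANT_Q1"]] = s * p_reimplant

    # A revised first device faces the same risks; further revisions keep it
    # in the revised state.
    m[S["AIDED_REVISED"], S["AIDED_REVISED"]] = s * (1 - p_explant - p_reimplant)
    m[S["AIDED_REVISED"], S["UNAIDED_EXPLANTED"]] = s * p_explant
    m[S["AIDED_REVISED"], S["TUNNEL_REIMPLANT_Q1"]] = s * p_reimplant

    for q in range(1, 4):
        m[S[f"TUNNEL_REIMPLANT_Q{q}"], S[f"TUNNEL_REIMPLANT_Q{q + 1}"]] = s
    m[S["TUNNEL_REIMPLANT_Q4"], S["AIDED_SECOND"]] = s

    # Second device: revisions keep the state; explantation OR a would-be
    # reimplantation is terminal (no third device).
    m[S["AIDED_SECOND"], S["AIDED_SECOND"]] = s * (1 - p_explant - p_reimplant)
    m[S["AIDED_SECOND"], S["UNAIDED_EXPLANTED"]] = s * (p_explant + p_reimplant)

    m[S["UNAIDED_EXPLANTED"], S["UNAIDED_EXPLANTED"]] = s

    m[:, S["DEAD"]] = q_death
    m[S["DEAD"], :] = 0.0
    m[S["DEAD"], S["DEAD"]] = 1.0

    rowsums = m.sum(axis=1)
    if np.any(np.abs(rowsums - 1.0) > 1e-9):
        raise ConstructionError(f"non-stochastic rows: {rowsums}")
    return m


def run_cohort(
    arm: ArmParameters,
    config: ModelConfig,
    life_table: LifeTable,
    rate_fn=None,
) -> CohortTrace:
    """Propagate a cohort starting 100% in ``AIDED_FIRST`` at surgery.

    ``rate_fn(cycle_index)``, if given, returns the per-cycle
    ``(p_revision, p_explant, p_reimplant, p_ae)`` tuple for that cycle
    (1-based index), overriding the arm's constant probabilities — used by
    the converging-transition-probability scenario.
    """
    n = config.n_cycles()
    dt = config.cycle_years
    occ = np.zeros((n + 1, N_STATES))
    occ[0, S["AIDED_FIRST"]] = 1.0
    ages = config.start_age + dt * np.arange(n)

    base_probs = arm.cycle_probs(config.cycle_months)
    revisions = np.zeros(n)
    explants = np.zeros(n)
    reimplants = np.zeros(n)
    ae_events = np.zeros(n)

    n_used = n
    for i in range(n):
        p_rev, p_exp, p_reimp, p_ae = (
            base_probs if rate_fn is None else rate_fn(i + 1)
        )
        q = life_table.cycle_death_prob(ages[i], dt)
        m = build_transition_matrix(p_rev, p_exp, p_reimp, q)
        x = occ[i]
        occ[i + 1] = x @ m

        at_risk = x[list(AT_RISK_STATES)].sum() * (1 - q)
        revisions[i] = at_risk * p_rev
        # a reimplant-fraction event from the second device is an explantation
        second = x[S["AIDED_SECOND"]] * (1 - q)
        first = (x[S["AIDED_FIRST"]] + x[S["AIDED_REVISED"]]) * (1 - q)
        explants[i] = (first + second) * p_exp + second * p_reimp
        reimplants[i] = first * p_reimp
        # soft-tissue complications: cost-only events over device states,
        # half-cycle corrected occupancy
        ae_events[i] = p_ae * 0.5 * (
            x[list(DEVICE_STATES)].sum() + occ[i + 1, list(DEVICE_STATES)].sum()
        )

        total = occ[i + 1].sum()
        if abs(total - 1.0) > 1e-9:
            raise ConstructionError(f"occupancy leak at cycle {i + 1}: {total}")
        if (
            config.horizon_years is None
            and 1.0 - occ[i + 1, S["DEAD"]] < config.alive_epsilon
        ):
            n_used = i + 1
            break

    return CohortTrace(
        arm=arm.name,
        n_cycles=n_used,
        cycle_years=dt,
        ages=ages[:n_used],
        occupancy=occ[: n_used + 1],
        revisions=revisions[:n_used],
        explants=explants[:n_used],
        reimplants=reimplants[:n_used],
        ae_events=ae_events[:n_used],
    )


def utility_for(
    state: str, cycles_since_current_implant: int, utilities: UtilitySchedule
) -> float:
    """Utility of a state given quarters elapsed since the current implant.

    Quarter 1 after (re)implantation carries the pre-operative baseline,
    quarter 2 the 3-month gain, quarters 3+ the 6-month gain (constant
    thereafter). Explanted patients revert to baseline; the dead accrue 0.
    """
    if state == "DEAD":
        return 0.0
    if state == "UNAIDED_EXPLANTED":
        return utilities.baseline
    if cycles_since_current_implant <= 1:
        return utilities.baseline
    if cycles_since_current_implant == 2:
        return utilities.baseline + utilities.gain_3m
    return utilities.baseline + utilities.gain_6m


def _utility_vector(cycle_index: int, utilities: UtilitySchedule) -> np.ndarray:
    """Per-state utilities for a given (1-based) model cycle.

    For the first-device states the time since implant is the model time
    itself; tunnel states encode their own time since reimplantation.
    """
    u = np.empty(N_STATES)
    u[S["AIDED_FIRST"]] = utility_for("AIDED_FIRST", cycle_index, utilities)
    u[S["AIDED_REVISED"]] = utility_for("AIDED_REVISED", cycle_index, utilities)
    for q in range(1, 5):
        u[S[f"TUNNEL_REIMPLANT_Q{q}"]] = utility_for("TUNNEL", q, utilities)
    u[S["AIDED_SECOND"]] = utility_for("AIDED_SECOND", 99, utilities)
    u[S["UNAIDED_EXPLANTED"]] = utility_for("UNAIDED_EXPLANTED", 99, utilities)
    u[S["DEAD"]] = 0.0
    return u


def accrue_outcomes(
    trace: CohortTrace, arm: ArmParameters, config: ModelConfig
) -> ArmOutcomes:
    """Accrue discounted and undiscounted costs and QALYs over a trace.

    Continuous accruals (utilities, AE management costs) use half-cycle
    corrected occupancy and are discounted at the cycle midpoint; one-off
    costs (initial implantation at t=0, reoperation procedures, sound
    processor upgrades) are discounted at their event time without half-cycle
    correction.
    """
    dt = trace.cycle_years
    n = trace.n_cycles
    t_mid = dt * (np.arange(n) + 0.5)
    disc_mid = (1.0 + config.discount_annual) ** (-t_mid)

    occ_hcc = trace.occupancy_hcc()
    u = np.stack([_utility_vector(i + 1, arm.utilities) for i in range(n)])
    q_per_cycle = (u * occ_hcc).sum(axis=1) * dt
    qalys_undisc = float(q_per_cycle.sum())
    qalys_disc = float((q_per_cycle * disc_mid).sum())

    costs = arm.costs
    reimplant_cost = costs.procedure + (
        costs.device if config.reimplant_includes_device else 0.0
    )
    proc_per_cycle = (
        trace.revisions * costs.procedure
        + trace.explants * costs.procedure
        + trace.reimplants * reimplant_cost
    )
    ae_per_cycle = trace.ae_events * costs.ae_management

    cost_undisc = costs.initial + float(proc_per_cycle.sum() + ae_per_cycle.sum())
    cost_disc = costs.initial + float(
        (proc_per_cycle * disc_mid).sum() + (ae_per_cycle * disc_mid).sum()
    )

    # Sound processor upgrades at 5-year anniversaries, weighted by the
    # occupancy of device states at the anniversary.
    upgrade_undisc = 0.0
    upgrade_disc = 0.0
    horizon = n * dt
    interval = config.sp_upgrade_interval_years
    k = 1
    while True:
        t = k * interval
        limit_ok = t < horizon or (
            config.include_boundary_upgrade and abs(t - horizon) < 1e-9
        )
        if not limit_ok:
            break
        idx = int(round(t / dt))
        if abs(idx * dt - t) > 1e-9:
            raise ConfigurationError(
                f"upgrade time {t}y does not align with the cycle grid"
            )
        aided = float(trace.occupancy[idx, list(DEVICE_STATES)].sum())
        c = costs.replacement_sound_processor * aided
        upgrade_undisc += c
        upgrade_disc += c * config.discount_factor(t)
        k += 1

    breakdown = {
        "initial": costs.initial,
        "procedures_undiscounted": float(proc_per_cycle.sum()),
        "ae_undiscounted": float(ae_per_cycle.sum()),
        "upgrades_undiscounted": upgrade_undisc,
        "procedures_discounted": float((proc_per_cycle * disc_mid).sum()),
        "ae_discounted": float((ae_per_cycle * disc_mid).sum()),
        "upgrades_discounted": upgrade_disc,
    }
    return ArmOutcomes(
        arm=trace.arm,
        cost_discounted=cost_disc + upgrade_disc,
        cost_undiscounted=cost_undisc + upgrade_undisc,
        qalys_discounted=qalys_disc,
        qalys_undiscounted=qalys_undisc,
        cost_breakdown=breakdown,
    )


def run_arm(
    arm: ArmParameters,
    config: ModelConfig,
    life_table: LifeTable,
    rate_fn=None,
) -> tuple[ArmOutcomes, CohortTrace]:
    trace = run_cohort(arm, config, life_table, rate_fn=rate_fn)
    return accrue_outcomes(trace, arm, config), trace


def compute_icer(
    osia: ArmOutcomes, baha: ArmOutcomes, config: ModelConfig
) -> CEResult:
    """Incremental cost, incremental QALYs and ICER (discounted and not)."""
    dc = osia.cost_discounted - baha.cost_discounted
    dq = osia.qalys_discounted - baha.qalys_discounted
    dcu = osia.cost_undiscounted - baha.cost_undiscounted
    dqu = osia.qalys_undiscounted - baha.qalys_undiscounted
    icer = dc / dq if dq != 0 else None
    icer_u = dcu / dqu if dqu != 0 else None
    effective = None if icer is None else bool(dq > 0 and icer <= config.wtp)
    return CEResult(
        osia=osia,
        baha=baha,
        incremental_cost=dc,
        incremental_qalys=dq,
        icer=icer,
        incremental_cost_undiscounted=dcu,
        incremental_qalys_undiscounted=dqu,
        icer_undiscounted=icer_u,
        wtp=config.wtp,
        cost_effective=effective,
    )


def run_model(
    osia: ArmParameters,
    baha: ArmParameters,
    config: ModelConfig,
    life_table: LifeTable,
    rate_fns: tuple | None = None,
) -> CEResult:
    """Run both arms under one configuration and compare them."""
    fn_o, fn_b = rate_fns if rate_fns is not None else (None, None)
    out_o, _ = run_arm(osia, config, life_table, rate_fn=fn_o)
    out_b, _ = run_arm(baha, config, life_table, rate_fn=fn_b)
    return compute_icer(out_o, out_b, config)


def trace_to_frame(trace: CohortTrace) -> pd.DataFrame:
    """Tabular view of a trace (cycle, age, occupancy columns, events)."""
    df = pd.DataFrame(trace.occupancy[1:], columns=list(STATES))
    df.insert(0, "cycle", np.arange(1, trace.n_cycles + 1))
    df.insert(1, "age", trace.ages + trace.cycle_years)
    df["revisions"] = trace.revisions
    df["explants"] = trace.explants
    df["reimplants"] = trace.reimplants
    df["ae_events"] = trace.ae_events
    return df
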