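"""Configuration loading, validation, parameter assembly and report writing.

A run configuration is a YAML file; any key omitted falls back to the
packaged default (10-year horizon, 5% annual discount, quarterly cycles,
AUD 50,000 willingness-to-pay). Unknown keys are rejected by name so typos
fail loudly. Fixture paths of ``null`` resolve to the CSVs shipped inside
``bchicea/data``.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from bchicea.event_rates import (
    EventExposure,
    ReoperationSplit,
    load_event_exposures,
    monthly_rate,
)
from bchicea.markov_engine import (
    ArmParameters,
    CostSet,
    LifeTable,
    ModelConfig,
    UtilitySchedule,
)

__all__ = [
    "RunConfig",
    "ValidationError",
    "load_and_validate",
    "packaged_path",
    "build_parameters",
    "write_report",
]

log = logging.getLogger("bchicea")


class ValidationError(ValueError):
    pass


def packaged_path(name: str) -> Path:
    """Path to a data file shipped with the package."""
    return Path(resources.files("bchicea").joinpath("data", name))


def _default_config() -> dict:
    with open(packaged_path("default_config.yaml")) as fh:
        return yaml.safe_load(fh)


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValidationError(f"unknown configuration key: {here!r}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = value
    return out


@dataclass
class RunConfig:
    """Validated run configuration with resolved fixture paths."""

    raw: dict
    study_summaries: Path
    costs: Path
    adverse_events: Path
    life_table: Path
    model: ModelConfig
    baseline_utility: float
    utilities: dict  # arm -> {"gain_3m": .., "gain_6m": ..}
    reoperation_split: dict  # arm -> ReoperationSplit
    psa: dict
    output_dir: Path


def load_and_validate(path: str | Path | None = None) -> RunConfig:
    """Load a YAML configuration, merge with defaults and validate ranges."""
    defaults = _default_config()
    if path is None:
        merged = defaults
    else:
        p = Path(path)
        if not p.exists():
            raise ValidationError(f"configuration file not found: {p}")
        with open(p) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValidationError("configuration root must be a mapping")
        merged = _merge(defaults, user)

    fx = merged["fixtures"]

    def resolve(key: str, default_name: str) -> Path:
        value = fx.get(key)
        out = packaged_path(default_name) if value is None else Path(value)
        if not out.exists():
            raise ValidationError(f"fixture file for {key!r} not found: {out}")
        return out

    m = merged["model"]
    for key, low, high in (
        ("start_age", 0, 110),
        ("discount_annual", 0, 1),
        ("sp_upgrade_interval_years", 0.25, 1000),
        ("wtp", 0, float("inf")),
        ("baseline_utility", -1, 1),
    ):
        v = m[key]
        if not (low <= v <= high):
            raise ValidationError(f"model.{key} out of range [{low}, {high}]: {v}")
    if m["horizon_years"] is not None and m["horizon_years"] <= 0:
        raise ValidationError(f"model.horizon_years must be > 0 or null: {m['horizon_years']}")

    model = ModelConfig(
        start_age=float(m["start_age"]),
        horizon_years=None if m["horizon_years"] is None else float(m["horizon_years"]),
        cycle_months=int(m["cycle_months"]),
        discount_annual=float(m["discount_annual"]),
        sp_upgrade_interval_years=float(m["sp_upgrade_interval_years"]),
        wtp=float(m["wtp"]),
        include_boundary_upgrade=bool(m["include_boundary_upgrade"]),
        reimplant_includes_device=bool(m["reimplant_includes_device"]),
    )

    splits = {}
    for arm in ("osia", "baha"):
        s = merged["reoperation_split"][arm]
        splits[arm] = ReoperationSplit(
            p_revision=float(s["revision"]),
            p_explant=float(s["explant"]),
            p_reimplant=float(s["reimplant"]),
        )

    psa = merged["psa"]
    if psa["n_draws"] < 1:
        raise ValidationError(f"psa.n_draws must be >= 1: {psa['n_draws']}")
    if psa["utility_gain_se_mode"] not in ("ten_percent", "study"):
        raise ValidationError(
            f"psa.utility_gain_se_mode must be 'ten_percent' or 'study': "
            f"{psa['utility_gain_se_mode']!r}"
        )

    cfg = RunConfig(
        raw=merged,
        study_summaries=resolve("study_summaries", "study_summaries.csv"),
        costs=resolve("costs", "costs.csv"),
        adverse_events=resolve("adverse_events", "adverse_events.csv"),
        life_table=resolve("life_table", "life_table.csv"),
        model=model,
        baseline_utility=float(m["baseline_utility"]),
        utilities={
            arm: {k: float(v) for k, v in merged["utilities"][arm].items()}
            for arm in ("osia", "baha")
        },
        reoperation_split=splits,
        psa=psa,
        output_dir=Path(merged["output_dir"]),
    )
    log.info(
        "configuration loaded: horizon=%s y, discount=%.3f, cycle=%d m, wtp=%.0f",
        model.horizon_years,
        model.discount_annual,
        model.cycle_months,
        model.wtp,
    )
    return cfg


def load_costs(path) -> dict[str, CostSet]:
    df = pd.read_csv(path, comment="#").set_index("item")
    out = {}
    for arm in ("osia", "baha"):
        out[arm] = CostSet(
            device=float(df.loc["device", arm]),
            replacement_sound_processor=float(
                df.loc["replacement_sound_processor", arm]
            ),
            surgery=float(df.loc["surgery", arm]),
            hospitalisation=float(df.loc["hospitalisation", arm]),
            ae_management=float(df.loc["ae_management", arm]),
        )
    return out


def build_parameters(
    cfg: RunConfig,
) -> tuple[ArmParameters, ArmParameters, ModelConfig, LifeTable]:
    """Assemble both arms' parameters from the configured fixtures.

    Event rates come from the adverse-event fixture (events / exposure
    months); utilities combine the common baseline with the configured
    arm-specific gains.
    """
    costs = load_costs(cfg.costs)
    events = load_event_exposures(cfg.adverse_events)
    life_table = LifeTable.from_csv(cfg.life_table)

    arms = []
    for arm in ("osia", "baha"):
        reop = events[(arm, "reoperation")]
        ae = events[(arm, "soft_tissue_complication")]
        params = ArmParameters(
            name=arm,
            costs=costs[arm],
            utilities=UtilitySchedule(
                baseline=cfg.baseline_utility,
                gain_3m=cfg.utilities[arm]["gain_3m"],
                gain_6m=cfg.utilities[arm]["gain_6m"],
            ),
            reop_rate_monthly=monthly_rate(reop),
            reop_split=cfg.reoperation_split[arm],
            ae_rate_monthly=monthly_rate(ae),
        )
        log.info(
            "arm %s: reop %.4f%%/month, AE %.4f%%/month, utilities %s",
            arm,
            100 * params.reop_rate_monthly,
            100 * params.ae_rate_monthly,
            params.utilities,
        )
        arms.append(params)
    return arms[0], arms[1], cfg.model, life_table


# ---------------------------------------------------------------------------
# Reporting


def _fmt(x: float, dp: int) -> float:
    return float(round(x, dp))


def write_report(
    outdir: str | Path,
    *,
    base_result=None,
    itc_frame: pd.DataFrame | None = None,
    tornado_frame: pd.DataFrame | None = None,
    psa_frame: pd.DataFrame | None = None,
    ceac_frame: pd.DataFrame | None = None,
) -> list[Path]:
    """Write result tables as CSV files; returns the paths written.

    Headline values are reported both at printed precision and at full
    precision (``*_full`` columns).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if itc_frame is not None:
        p = outdir / "itc_results.csv"
        itc_frame.to_csv(p, index=False)
        written.append(p)

    if base_result is not None:
        r = base_result
        rows = []
        for label, arm in (("osia", r.osia), ("baha", r.baha)):
            rows.append(
                {
                    "arm": label,
                    "cost_discounted": _fmt(arm.cost_discounted, 0),
                    "cost_undiscounted": _fmt(arm.cost_undiscounted, 0),
                    "qalys_discounted": _fmt(arm.qalys_discounted, 2),
                    "qalys_undiscounted": _fmt(arm.qalys_undiscounted, 2),
                    "cost_discounted_full": arm.cost_discounted,
                    "cost_undiscounted_full": arm.cost_undiscounted,
                    "qalys_discounted_full": arm.qalys_discounted,
                    "qalys_undiscounted_full": arm.qalys_undiscounted,
                }
            )
        rows.append(
            {
                "arm": "incremental",
                "cost_discounted": _fmt(r.incremental_cost, 0),
                "cost_undiscounted": _fmt(r.incremental_cost_undiscounted, 0),
                "qalys_discounted": _fmt(r.incremental_qalys, 2),
                "qalys_undiscounted": _fmt(r.incremental_qalys_undiscounted, 2),
                "cost_discounted_full": r.incremental_cost,
                "cost_undiscounted_full": r.incremental_cost_undiscounted,
                "qalys_discounted_full": r.incremental_qalys,
                "qalys_undiscounted_full": r.incremental_qalys_undiscounted,
                "icer_discounted": None if r.icer is None else _fmt(r.icer, 0),
                "icer_undiscounted": (
                    None if r.icer_undiscounted is None else _fmt(r.icer_undiscounted, 0)
                ),
                "icer_discounted_full": r.icer,
                "icer_undiscounted_full": r.icer_undiscounted,
            }
        )
        p = outdir / "base_case_results.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        written.append(p)

    if tornado_frame is not None:
        p = outdir / "tornado.csv"
        tornado_frame.to_csv(p, index=False)
        written.append(p)

    if psa_frame is not None:
        p = outdir / "psa_draws.csv"
        psa_frame.to_csv(p, index=False)
        written.append(p)

    if ceac_frame is not None:
        p = outdir / "ceac.csv"
        ceac_frame.to_csv(p, index=False)
        written.append(p)
    else:
        log.info("PSA disabled: no CEAC file written")

    for p in written:
        log.info("wrote %s", p)
    return written
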