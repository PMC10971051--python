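"""Event-rate derivation: counts over exposure time -> per-cycle probabilities.

Monthly rates are simple event counts divided by person-months of follow-up.
Conversion to a per-cycle probability treats the rate as a constant hazard
(complement-product), keeping probabilities bounded in [0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "EventExposure",
    "ReoperationSplit",
    "monthly_rate",
    "rate_to_cycle_probability",
    "split_reoperation",
    "load_event_exposures",
]


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class EventExposure:
    """Event count with its person-time denominator."""

    event_type: str  # "soft_tissue_complication" | "reoperation"
    events: int
    patients: int
    exposure_months: float

    def __post_init__(self) -> None:
        if self.events < 0:
            raise InputError(f"events must be >= 0, got {self.events}")
        if self.exposure_months <= 0:
            raise InputError(f"exposure_months must be > 0, got {self.exposure_months}")


@dataclass(frozen=True)
class ReoperationSplit:
    """Fractions of reoperations by destination; must sum to 1."""

    p_revision: float
    p_explant: float
    p_reimplant: float

    def __post_init__(self) -> None:
        parts = (self.p_revision, self.p_explant, self.p_reimplant)
        if any(p < 0 for p in parts):
            raise InputError(f"split fractions must be >= 0, got {parts}")
        if abs(sum(parts) - 1.0) > 1e-9:
            raise InputError(f"split fractions must sum to 1, got {sum(parts)!r}")


def monthly_rate(e: EventExposure) -> float:
    """Events per exposure-month (a probability per month when small)."""
    return e.events / e.exposure_months


def rate_to_cycle_probability(monthly: float, cycle_months: int) -> float:
    """Constant-hazard conversion: ``1 - (1 - r)**cycle_months``."""
    if not 0 <= monthly < 1:
        raise InputError(f"monthly rate must be in [0, 1), got {monthly}")
    if cycle_months < 1:
        raise InputError(f"cycle_months must be >= 1, got {cycle_months}")
    return 1.0 - (1.0 - monthly) ** cycle_months


def split_reoperation(p_cycle: float, split: ReoperationSplit) -> dict[str, float]:
    """Allocate a per-cycle reoperation probability across destinations.

    The returned revision/explant/reimplant probabilities sum to ``p_cycle``
    exactly.
    """
    if not 0 <= p_cycle <= 1:
        raise InputError(f"p_cycle must be in [0, 1], got {p_cycle}")
    return {
        "revision": p_cycle * split.p_revision,
        "explant": p_cycle * split.p_explant,
        "reimplant": p_cycle * split.p_reimplant,
    }


def load_event_exposures(path) -> dict[tuple[str, str], EventExposure]:
    """Read the adverse-event CSV: arm, event_type, events, patients, exposure_months.

    Returns a mapping keyed by ``(arm, event_type)``.
    """
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    required = ["arm", "event_type", "events", "patients", "exposure_months"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"event table missing columns: {missing}")
    out: dict[tuple[str, str], EventExposure] = {}
    for _, r in df.iterrows():
        key = (str(r["arm"]), str(r["event_type"]))
        if key in out:
            raise InputError(f"duplicate event row for {key}")
        out[key] = EventExposure(
            event_type=str(r["event_type"]),
            events=int(r["events"]),
            patients=int(r["patients"]),
            exposure_months=float(r["exposure_months"]),
        )
    return out
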