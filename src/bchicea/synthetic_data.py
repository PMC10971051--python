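"""Synthetic patient-level datasets and life tables for pipeline validation.

Endpoint values are drawn from per-subgroup normal distributions (the
pooling and meta-analysis formulas are moment-based, so the normal model is
the natural testbed). Seeds are mandatory arguments — no global random
state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bchicea.evidence_synthesis import StudyArmSummary, SubgroupSummary
from bchicea.markov_engine import LifeTable

__all__ = [
    "SubgroupSpec",
    "StudySpec",
    "generate_study",
    "summarize",
    "make_life_table",
]


class DegenerateInputError(ValueError):
    pass


@dataclass(frozen=True)
class SubgroupSpec:
    """Generating parameters for one subgroup: n patients per endpoint."""

    label: str
    n: int
    baseline_mean: float
    baseline_sd: float
    change_mean: float
    change_sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"subgroup {self.label!r}: n must be >= 1")
        if self.baseline_sd < 0 or self.change_sd < 0:
            raise ValueError(f"subgroup {self.label!r}: SDs must be >= 0")


@dataclass(frozen=True)
class StudySpec:
    """Generating specification for one synthetic before/after study."""

    study_id: str
    endpoint: str
    subgroups: tuple[SubgroupSpec, ...]
    seed: int
    timepoint_months: int = 6


def generate_study(spec: StudySpec) -> pd.DataFrame:
    """Draw patient-level records for one study; deterministic given seed.

    Columns: patient_id, study_id, subgroup, endpoint, baseline, change.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    offset = 0
    for sg in spec.subgroups:
        baseline = rng.normal(sg.baseline_mean, sg.baseline_sd, size=sg.n)
        change = rng.normal(sg.change_mean, sg.change_sd, size=sg.n)
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": np.arange(offset, offset + sg.n),
                    "study_id": spec.study_id,
                    "subgroup": sg.label,
                    "endpoint": spec.endpoint,
                    "baseline": baseline,
                    "change": change,
                }
            )
        )
        offset += sg.n
    return pd.concat(frames, ignore_index=True)


def summarize(
    records: pd.DataFrame,
    by_subgroup: bool = False,
    value: str = "change",
    timepoint_months: int = 6,
):
    """Sample mean, (n-1)-denominator SD and n of generated records.

    With ``by_subgroup=True`` returns one :class:`SubgroupSummary` per
    subgroup label; otherwise a whole-cohort :class:`StudyArmSummary`.
    A single-record (sub)sample has no defined SD and raises
    :class:`DegenerateInputError`.
    """
    if len(records) == 0:
        raise ValueError("summarize requires at least one record")
    if value not in records.columns:
        raise ValueError(f"no column {value!r} in records")

    def _stats(x: np.ndarray) -> tuple[float, float]:
        if len(x) < 2:
            raise DegenerateInputError("SD undefined for a single record")
        return float(np.mean(x)), float(np.std(x, ddof=1))

    if by_subgroup:
        out = []
        for label, grp in records.groupby("subgroup", sort=False):
            mean, sd = _stats(grp[value].to_numpy())
            out.append(
                SubgroupSummary(label=str(label), n=len(grp), mean=mean, variance=sd**2)
            )
        return out
    mean, sd = _stats(records[value].to_numpy())
    return StudyArmSummary(
        study_id=str(records["study_id"].iloc[0]),
        endpoint=str(records["endpoint"].iloc[0]),
        timepoint_months=timepoint_months,
        measure="change" if value == "change" else "baseline",
        n=len(records),
        mean=mean,
        sd=sd,
    )


def make_life_table(
    model: str = "constant",
    *,
    q: float = 0.0,
    a: float = 1e-4,
    b: float = 0.09,
    path=None,
    max_age: int = 110,
) -> LifeTable:
    """Construct a life table from a named mortality model.

    ``constant``: q_x = q for every age.
    ``gompertz``: hazard a * exp(b * age), q_x = 1 - exp(-hazard).
    ``file``: read ``path`` as a (age, qx) CSV.
    """
    ages = np.arange(max_age + 1)
    if model == "constant":
        if not 0 <= q <= 1:
            raise ValueError(f"q must be in [0, 1], got {q}")
        return LifeTable(ages, np.full(len(ages), float(q)))
    if model == "gompertz":
        if a < 0 or b < 0:
            raise ValueError("gompertz parameters must be >= 0")
        qx = 1.0 - np.exp(-a * np.exp(b * ages))
        return LifeTable(ages, qx)
    if model == "file":
        if path is None:
            raise ValueError("model='file' requires a path")
        return LifeTable.from_csv(path)
    raise ValueError(f"unknown life-table model {model!r}")
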