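"""Subgroup pooling, random-effects meta-analysis and indirect treatment comparison.

Implements the evidence-synthesis stage of the pipeline:

* combining subgroup summary statistics (mean, variance, n) into whole-cohort
  summaries from first principles,
* DerSimonian–Laird random-effects inverse-variance meta-analysis of study
  arms sharing an endpoint and timepoint, and
* the anchored indirect comparison of two interventions through their common
  change-from-baseline anchor.

All computation is carried out at full floating-point precision; rounding is
left to the reporting layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SubgroupSummary",
    "StudyArmSummary",
    "PooledEffect",
    "ITCResult",
    "pool_subgroup_summaries",
    "meta_analyze",
    "itc_difference",
    "confidence_interval",
    "load_study_summaries",
    "synthesize_endpoint",
    "itc_table",
]

#: Standard-normal quantile used for 95% intervals throughout.
Z_95 = 1.959964


class InputError(ValueError):
    """Raised when inputs violate an operation's preconditions."""


@dataclass(frozen=True)
class SubgroupSummary:
    """Summary statistics for one subgroup of a study arm.

    Parameters
    ----------
    label : str
        Subgroup identifier, e.g. ``"CHL/MHL"`` or ``"SSD"``.
    n : int
        Number of observations (>= 1).
    mean : float
        Endpoint mean in endpoint units (dB, %, or utility).
    variance : float
        Endpoint variance (>= 0), i.e. SD squared.
    """

    label: str
    n: int
    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InputError(f"subgroup {self.label!r}: n must be >= 1, got {self.n}")
        if self.variance < 0:
            raise InputError(
                f"subgroup {self.label!r}: variance must be >= 0, got {self.variance}"
            )

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)


@dataclass(frozen=True)
class StudyArmSummary:
    """Mean/SD/n for one endpoint of one study arm at one timepoint.

    ``measure`` distinguishes a baseline level (``"baseline"``) from a
    change-from-baseline (``"change"``).
    """

    study_id: str
    endpoint: str
    timepoint_months: int
    measure: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InputError(f"arm {self.study_id!r}: n must be >= 1, got {self.n}")
        if self.sd < 0:
            raise InputError(f"arm {self.study_id!r}: sd must be >= 0, got {self.sd}")

    @property
    def variance_of_mean(self) -> float:
        """Sampling variance of the arm mean, sd**2 / n."""
        return self.sd**2 / self.n

    @property
    def se(self) -> float:
        return math.sqrt(self.variance_of_mean)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        return confidence_interval(self.mean, self.se, level)


@dataclass(frozen=True)
class PooledEffect:
    """Random-effects pooled estimate for one endpoint/timepoint."""

    mean: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    q: float
    weights: tuple[float, ...]
    k: int
    endpoint: str | None = None
    timepoint_months: int | None = None
    measure: str | None = None

    @property
    def variance(self) -> float:
        return self.se**2


@dataclass(frozen=True)
class ITCResult:
    """Anchored indirect comparison of two pooled change-from-baseline effects."""

    difference: float
    se: float
    ci_low: float
    ci_high: float
    significant: bool
    endpoint: str | None = None
    timepoint_months: int | None = None


def confidence_interval(
    estimate: float, se: float, level: float = 0.95
) -> tuple[float, float]:
    """Symmetric normal-quantile confidence interval ``estimate ± z * se``.

    The 95% level uses z = 1.959964; other levels use the corresponding
    standard-normal quantile.
    """
    if se < 0:
        raise InputError(f"se must be >= 0, got {se}")
    if not 0 < level < 1:
        raise InputError(f"level must be in (0, 1), got {level}")
    if abs(level - 0.95) < 1e-12:
        z = Z_95
    else:
        from scipy.stats import norm

        z = float(norm.ppf(0.5 + level / 2))
    return estimate - z * se, estimate + z * se


def pool_subgroup_summaries(
    a: SubgroupSummary,
    b: SubgroupSummary,
    *,
    study_id: str = "pooled",
    endpoint: str = "",
    timepoint_months: int = 0,
    measure: str = "change",
) -> StudyArmSummary:
    """Combine two subgroup summaries into a whole-cohort summary.

    Exact algebraic identity with the mean and (n-1)-denominator SD of the
    concatenated per-patient samples:

    .. math::

        \\bar Z = (m \\bar X + n \\bar Y) / (m + n)

        SD(Z)^2 = \\frac{(m-1)VAR(X) + (n-1)VAR(Y)
                   + m(\\bar X - \\bar Z)^2 + n(\\bar Y - \\bar Z)^2}{m + n - 1}

    where the subgroup variances are themselves (n-1)-denominator variances.
    """
    m, n = a.n, b.n
    if m + n < 2:
        raise InputError("pooling requires a combined sample of at least 2")
    z_mean = (m * a.mean + n * b.mean) / (m + n)
    num = (
        (m - 1) * a.variance
        + (n - 1) * b.variance
        + m * (a.mean - z_mean) ** 2
        + n * (b.mean - z_mean) ** 2
    )
    sd = math.sqrt(num / (m + n - 1))
    return StudyArmSummary(
        study_id=study_id,
        endpoint=endpoint,
        timepoint_months=timepoint_months,
        measure=measure,
        n=m + n,
        mean=z_mean,
        sd=sd,
    )


def _check_compatible(arms: list[StudyArmSummary]) -> None:
    endpoints = {(a.endpoint, a.timepoint_months, a.measure) for a in arms}
    if len(endpoints) > 1:
        raise InputError(f"arms mix endpoints/timepoints/measures: {sorted(endpoints)}")


def meta_analyze(arms: list[StudyArmSummary]) -> PooledEffect:
    """DerSimonian–Laird random-effects inverse-variance meta-analysis.

    Each arm contributes its mean with sampling variance ``sd**2 / n``.  The
    between-study variance tau² is the DerSimonian–Laird moment estimator
    truncated at zero; random-effects weights are
    ``w_i = 1 / (sd_i**2 / n_i + tau2)``.  With a single arm the arm's own
    mean and standard error are returned unchanged (tau² = Q = 0).
    """
    if not arms:
        raise InputError("meta_analyze requires at least one arm")
    _check_compatible(arms)
    ref = arms[0]
    means = np.array([a.mean for a in arms], dtype=float)
    v = np.array([a.variance_of_mean for a in arms], dtype=float)
    k = len(arms)

    if np.any(v <= 0) and k > 1:
        raise InputError("meta-analysis with k > 1 requires positive arm variances")

    if k == 1:
        se = math.sqrt(v[0])
        lo, hi = confidence_interval(float(means[0]), se)
        return PooledEffect(
            mean=float(means[0]),
            se=se,
            ci_low=lo,
            ci_high=hi,
            tau2=0.0,
            q=0.0,
            weights=(1.0 / v[0] if v[0] > 0 else math.inf,),
            k=1,
            endpoint=ref.endpoint,
            timepoint_months=ref.timepoint_months,
            measure=ref.measure,
        )

    w_fixed = 1.0 / v
    wsum = w_fixed.sum()
    mu_fixed = float((w_fixed * means).sum() / wsum)
    q = float((w_fixed * (means - mu_fixed) ** 2).sum())
    df = k - 1
    c = wsum - (w_fixed**2).sum() / wsum
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0

    w = 1.0 / (v + tau2)
    mu = float((w * means).sum() / w.sum())
    se = math.sqrt(1.0 / w.sum())
    lo, hi = confidence_interval(mu, se)
    return PooledEffect(
        mean=mu,
        se=se,
        ci_low=lo,
        ci_high=hi,
        tau2=tau2,
        q=q,
        weights=tuple(float(x) for x in w),
        k=k,
        endpoint=ref.endpoint,
        timepoint_months=ref.timepoint_months,
        measure=ref.measure,
    )


def itc_difference(osia: PooledEffect, baha: PooledEffect) -> ITCResult:
    """Anchored indirect comparison: difference of pooled changes.

    ``difference = osia.mean - baha.mean`` with
    ``se = sqrt(osia.variance + baha.variance)``.  Significance at the 5%
    level, no multiplicity correction.
    """
    for eff, name in ((osia, "first"), (baha, "second")):
        if eff.measure is not None and eff.measure != "change":
            raise InputError(f"{name} effect is not a change-from-baseline measure")
    if (
        osia.endpoint is not None
        and baha.endpoint is not None
        and (osia.endpoint, osia.timepoint_months)
        != (baha.endpoint, baha.timepoint_months)
    ):
        raise InputError(
            f"endpoint mismatch: {osia.endpoint}@{osia.timepoint_months}m vs "
            f"{baha.endpoint}@{baha.timepoint_months}m"
        )
    d = osia.mean - baha.mean
    se = math.sqrt(osia.variance + baha.variance)
    lo, hi = confidence_interval(d, se)
    return ITCResult(
        difference=d,
        se=se,
        ci_low=lo,
        ci_high=hi,
        significant=bool(lo > 0 or hi < 0),
        endpoint=osia.endpoint,
        timepoint_months=osia.timepoint_months,
    )


# ---------------------------------------------------------------------------
# Table-level interface


REQUIRED_COLUMNS = [
    "study_id",
    "endpoint",
    "timepoint_months",
    "measure",
    "subgroup",
    "n",
    "mean",
    "sd",
]


def load_study_summaries(path) -> pd.DataFrame:
    """Read a study-summary CSV and validate its schema.

    Expected columns: study_id, endpoint, timepoint_months, measure,
    subgroup, n, mean, sd (extra columns such as a provenance note are
    preserved).  Rows with ``subgroup == "all"`` are whole-cohort summaries;
    other values are subgroup rows to be pooled first.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"study summary table missing columns: {missing}")
    df["n"] = df["n"].astype(int)
    if (df["n"] < 1).any():
        raise InputError("study summary table contains n < 1")
    if (df["sd"] < 0).any():
        raise InputError("study summary table contains negative sd")
    return df


def _arm_from_rows(rows: pd.DataFrame, subgroup: str = "all") -> StudyArmSummary:
    """Collapse the rows of one study arm for the requested subgroup.

    A row matching ``subgroup`` directly is used as-is; when the whole
    cohort (``"all"``) is requested but only subgroup rows exist, exactly two
    of them are pooled from first principles.
    """
    first = rows.iloc[0]
    key = dict(
        study_id=str(first["study_id"]),
        endpoint=str(first["endpoint"]),
        timepoint_months=int(first["timepoint_months"]),
        measure=str(first["measure"]),
    )
    direct = rows[rows["subgroup"] == subgroup]
    if len(direct) == 1:
        r = direct.iloc[0]
        return StudyArmSummary(n=int(r["n"]), mean=float(r["mean"]), sd=float(r["sd"]), **key)
    if len(direct) > 1:
        raise InputError(f"duplicate rows for subgroup {subgroup!r}, {key}")
    if subgroup != "all":
        raise InputError(f"no row for subgroup {subgroup!r}, {key}")
    subs = [
        SubgroupSummary(
            label=str(r["subgroup"]),
            n=int(r["n"]),
            mean=float(r["mean"]),
            variance=float(r["sd"]) ** 2,
        )
        for _, r in rows.iterrows()
    ]
    if len(subs) != 2:
        raise InputError(
            f"expected exactly 2 subgroup rows or one 'all' row for {key}, got {len(subs)}"
        )
    return pool_subgroup_summaries(subs[0], subs[1], **key)


def synthesize_endpoint(
    df: pd.DataFrame,
    endpoint: str,
    timepoint_months: int,
    measure: str,
    studies: list[str],
    subgroup: str = "all",
) -> PooledEffect:
    """Pool the named studies' arms for one endpoint/timepoint/measure."""
    arms = []
    for sid in studies:
        rows = df[
            (df["study_id"] == sid)
            & (df["endpoint"] == endpoint)
            & (df["timepoint_months"] == timepoint_months)
            & (df["measure"] == measure)
        ]
        if rows.empty:
            raise InputError(
                f"no rows for study {sid!r}, endpoint {endpoint!r} at "
                f"{timepoint_months} months ({measure})"
            )
        arms.append(_arm_from_rows(rows, subgroup=subgroup))
    return meta_analyze(arms)


#: Which studies inform each intervention for each endpoint.  The noise
#: endpoint drops the study whose noise presentation differed; the utility
#: endpoint at 6 months has a single informing arm per intervention.
DEFAULT_ENDPOINT_STUDIES: dict[str, dict[str, list[str]]] = {
    "pta4": {"osia": ["mylanus", "briggs"], "baha": ["den_besten"]},
    "speech_quiet": {"osia": ["mylanus", "briggs"], "baha": ["den_besten"]},
    "speech_noise": {"osia": ["mylanus"], "baha": ["den_besten"]},
    "hui3": {"osia": ["briggs"], "baha": ["den_besten"]},
}


def itc_table(
    df: pd.DataFrame,
    endpoint_studies: dict[str, dict[str, list[str]]] | None = None,
    timepoint_months: int = 6,
) -> pd.DataFrame:
    """Run the full indirect comparison over every configured endpoint.

    Returns one row per endpoint with pooled means, CIs, tau², Q, weights and
    the indirect difference with its CI and significance flag.
    """
    mapping = DEFAULT_ENDPOINT_STUDIES if endpoint_studies is None else endpoint_studies
    records = []
    for endpoint, sides in mapping.items():
        osia = synthesize_endpoint(df, endpoint, timepoint_months, "change", sides["osia"])
        baha = synthesize_endpoint(df, endpoint, timepoint_months, "change", sides["baha"])
        diff = itc_difference(osia, baha)
        records.append(
            {
                "endpoint": endpoint,
                "timepoint_months": timepoint_months,
                "osia_mean": osia.mean,
                "osia_ci_low": osia.ci_low,
                "osia_ci_high": osia.ci_high,
                "osia_tau2": osia.tau2,
                "osia_q": osia.q,
                "osia_k": osia.k,
                "baha_mean": baha.mean,
                "baha_ci_low": baha.ci_low,
                "baha_ci_high": baha.ci_high,
                "difference": diff.difference,
                "diff_se": diff.se,
                "diff_ci_low": diff.ci_low,
                "diff_ci_high": diff.ci_high,
                "significant": diff.significant,
            }
        )
    return pd.DataFrame.from_records(records)
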