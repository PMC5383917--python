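"""CO2-removal rates from paired pre/post-dialyzer blood gases.

The removal rate across the dialyzer follows from the drop in blood CO2
content between inlet and outlet,

    VCO2 = (d[HCO3-] + dpCO2 * ks) * Qb * Vm        [mL/min, STP]

with deltas taken inlet minus outlet so that CO2 removal is positive,
bicarbonate computed from measured pH and pCO2 via Henderson-Hasselbalch
(the blood-gas analyzer's own convention), Qb in L/min and Vm the molar
volume of CO2.  Bench rates are projected to clinical scale by the
membrane-area ratio of the full-size and bench dialyzers.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .chemistry import hh_bicarbonate
from .constants import DEFAULT_CONSTANTS, EquilibriumConstants
from .errors import (
    DomainError,
    InsufficientReplicatesError,
    PairingError,
    ValidationError,
)

__all__ = [
    "BloodGasRecord",
    "FlowCondition",
    "RemovalResult",
    "PairedTestResult",
    "PhDeltaSummary",
    "DEFAULT_SCALE_FACTOR",
    "scale_factor",
    "scale_value",
    "vco2_rate",
    "percent_change",
    "ph_delta_table",
    "paired_comparison",
]

logger = logging.getLogger(__name__)

#: M100 (0.9 m^2) over M10 (0.04 m^2) membrane areas.
DEFAULT_SCALE_FACTOR = 22.5


@dataclass(frozen=True)
class BloodGasRecord:
    """One measured or simulated blood-gas sample at the dialyzer inlet
    ('pre') or outlet ('post')."""

    condition_id: str
    side: str  # "pre" | "post"
    replicate: int
    ph: float
    pco2: float
    hemoglobin: float | None = None

    def __post_init__(self) -> None:
        if self.side not in ("pre", "post"):
            raise ValidationError(f"side must be 'pre' or 'post', got {self.side!r}")
        if not (6.0 < self.ph < 8.0):
            raise ValidationError(
                f"blood ph must lie in (6, 8), got {self.ph!r} "
                f"({self.condition_id}/{self.side})"
            )
        if not (self.pco2 > 0):
            raise ValidationError(f"blood pco2 must be > 0, got {self.pco2!r}")

    def hco3(self, k: EquilibriumConstants = DEFAULT_CONSTANTS) -> float:
        """Henderson-Hasselbalch bicarbonate for this sample, mmol/L."""
        return hh_bicarbonate(self.ph, self.pco2, k)


@dataclass(frozen=True)
class FlowCondition:
    """One cell of the experimental grid."""

    qb: float  # blood flow, mL/min
    qd: float  # dialysate flow, mL/min
    inlet_pco2_target: float  # mmHg

    def __post_init__(self) -> None:
        if not (self.qb > 0):
            raise ValidationError(f"qb must be > 0, got {self.qb!r}")
        if self.qd < 0:
            raise ValidationError(f"qd must be >= 0, got {self.qd!r}")

    @property
    def condition_id(self) -> str:
        return f"qb{self.qb:g}_qd{self.qd:g}_in{self.inlet_pco2_target:g}"


@dataclass(frozen=True)
class RemovalResult:
    """CO2 removal across the dialyzer for one pre/post pair.

    Deltas are inlet minus outlet (removal positive); ``vco2_scaled`` is
    ``vco2_bench * scale_factor`` exactly.
    """

    condition_id: str
    vco2_bench: float  # mL/min at bench scale
    vco2_scaled: float  # mL/min at clinical scale
    delta_hco3: float  # mmol/L
    delta_pco2: float  # mmHg
    delta_ph: float  # dimensionless, pre - post
    scale_factor: float


def scale_factor(area_full: float, area_bench: float) -> float:
    """Membrane-area scale factor full/bench (e.g. 0.9/0.04 = 22.5)."""
    if not (area_full > 0) or not (area_bench > 0):
        raise ValidationError(
            f"areas must be > 0, got full={area_full!r}, bench={area_bench!r}"
        )
    return area_full / area_bench


def scale_value(x: float, factor: float, rounding: str = "none") -> float:
    """Project a bench-scale rate or flow to full scale.

    ``rounding='half_up_int'`` applies decimal round-half-up to an integer,
    the convention used when reporting scaled flows (e.g. 18.7 * 22.5 =
    420.75 -> 421).  Decimal arithmetic avoids binary-float artefacts such
    as 420.74999... from the product of two floats.
    """
    if not (factor > 0):
        raise ValidationError(f"factor must be > 0, got {factor!r}")
    d = Decimal(repr(float(x))) * Decimal(repr(float(factor)))
    if rounding == "none":
        return float(d)
    if rounding == "half_up_int":
        return float(d.quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    raise ValidationError(f"rounding must be 'none' or 'half_up_int', got {rounding!r}")


def vco2_rate(
    pre: BloodGasRecord,
    post: BloodGasRecord,
    qb_l_min: float,
    k: EquilibriumConstants = DEFAULT_CONSTANTS,
    factor: float = DEFAULT_SCALE_FACTOR,
) -> RemovalResult:
    """CO2 removal rate for one matched pre/post pair, mL/min.

    ``qb_l_min`` is the blood flow in L/min.  A negative computed removal
    (outlet richer in CO2 than inlet) is allowed but logged as a warning.
    """
    if pre.condition_id != post.condition_id:
        raise PairingError(
            f"pre/post condition ids differ: {pre.condition_id!r} vs {post.condition_id!r}"
        )
    if not (qb_l_min > 0):
        raise ValidationError(f"qb_l_min must be > 0, got {qb_l_min!r}")
    d_hco3 = pre.hco3(k) - post.hco3(k)
    d_pco2 = pre.pco2 - post.pco2
    bench = (d_hco3 + d_pco2 * k.ks) * qb_l_min * k.vm
    if bench < 0:
        logger.warning(
            "negative CO2 removal (%.4g mL/min) for condition %s",
            bench,
            pre.condition_id,
        )
    return RemovalResult(
        condition_id=pre.condition_id,
        vco2_bench=bench,
        vco2_scaled=bench * factor,
        delta_hco3=d_hco3,
        delta_pco2=d_pco2,
        delta_ph=pre.ph - post.ph,
        scale_factor=factor,
    )


def percent_change(a: float, b: float) -> float:
    """Percent change from ``a`` to ``b``: 100 * (b - a) / a."""
    if a == 0:
        raise DomainError("percent_change undefined for a = 0")
    if not (a > 0):
        raise ValidationError(f"baseline rate must be > 0, got {a!r}")
    return 100.0 * (b - a) / a


@dataclass(frozen=True)
class PhDeltaSummary:
    """Condition-level pH summary.

    ``table`` has one row per condition with pre/post means, sds, counts
    and ``delta_ph`` = post mean - pre mean (a pH increase is positive, the
    reporting convention for "the largest increase in blood pH").  Maxima
    are rounded to two decimals, the printed precision of pH tables.
    """

    table: pd.DataFrame
    max_delta: float
    max_delta_condition: str
    max_delta_by_stratum: dict
    warnings: tuple = ()


def ph_delta_table(
    df: pd.DataFrame,
    stratify_by: str = "inlet_pco2_target",
) -> PhDeltaSummary:
    """Summarise pre/post pH per condition and report the maximal increases.

    ``df`` needs columns ``condition_id``, ``side`` and ``ph`` (replicate
    rows or single mean rows per side); any of ``qb_ml_min``, ``qd_ml_min``
    and the stratification column are carried through when present.
    Conditions with a missing side are listed in ``warnings`` and excluded
    from the maxima.  Deltas are computed on condition means.
    """
    required = {"condition_id", "side", "ph"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"ph_delta_table input lacks columns {sorted(missing)}")

    carried = [
        c
        for c in ("qb_ml_min", "qd_ml_min", stratify_by)
        if c in df.columns and c not in required
    ]
    grouped = (
        df.groupby(["condition_id", "side"])["ph"].agg(["mean", "std", "count"]).unstack("side")
    )
    rows = []
    warn: list[str] = []
    for cond, row in grouped.iterrows():
        rec: dict = {"condition_id": cond}
        for c in carried:
            rec[c] = df.loc[df["condition_id"] == cond, c].iloc[0]
        ok = True
        for side in ("pre", "post"):
            try:
                rec[f"{side}_mean"] = row[("mean", side)]
                rec[f"{side}_sd"] = row[("std", side)]
                rec[f"{side}_n"] = row[("count", side)]
            except KeyError:
                rec[f"{side}_mean"] = math.nan
            if not math.isfinite(rec[f"{side}_mean"]):
                ok = False
        if ok:
            rec["delta_ph"] = rec["post_mean"] - rec["pre_mean"]
        else:
            rec["delta_ph"] = math.nan
            warn.append(f"condition {cond!r} lacks a matched pre/post pair")
        rows.append(rec)
    table = pd.DataFrame(rows)

    paired = table.dropna(subset=["delta_ph"])
    if paired.empty:
        raise ValidationError("no condition has a matched pre/post pair")
    imax = paired["delta_ph"].idxmax()
    max_delta = round(float(paired.loc[imax, "delta_ph"]), 2)
    max_cond = str(paired.loc[imax, "condition_id"])

    by_stratum: dict = {}
    if stratify_by in paired.columns:
        for stratum, sub in paired.groupby(stratify_by):
            j = sub["delta_ph"].idxmax()
            by_stratum[stratum] = {
                "max_delta": round(float(sub.loc[j, "delta_ph"]), 2),
                "condition_id": str(sub.loc[j, "condition_id"]),
            }
    return PhDeltaSummary(
        table=table,
        max_delta=max_delta,
        max_delta_condition=max_cond,
        max_delta_by_stratum=by_stratum,
        warnings=tuple(warn),
    )


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    p_value: float
    n: int
    mean_difference: float
    significant: bool


def paired_comparison(
    pre, post, alpha: float = 0.05
) -> PairedTestResult:
    """Two-sided paired t-test on matched replicate values.

    Closed-form paired t with the difference standard deviation floored at
    machine epsilon: identical samples give p = 1 (with a warning), a
    constant nonzero shift gives p ~ 0 rather than nan.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValidationError(
            f"pre and post must have equal length, got {pre.shape} vs {post.shape}"
        )
    n = pre.size
    if n < 2:
        raise InsufficientReplicatesError(
            f"paired comparison needs >= 2 replicates, got {n}"
        )
    diff = post - pre
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            warnings.warn(
                "identical pre/post samples: zero-variance differences, p set to 1",
                stacklevel=2,
            )
            return PairedTestResult(t=0.0, p_value=1.0, n=n, mean_difference=0.0,
                                    significant=False)
        sd = np.finfo(float).eps
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return PairedTestResult(t=t, p_value=p, n=n, mean_difference=mean,
                            significant=p < alpha)
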