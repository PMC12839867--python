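"""Margin-of-exposure risk characterization.

MOE = POD / exposure with the point of departure (BMDL10, mg/kg bw/d)
converted to ng/kg bw/d; an MOE above 1000 is classified as no significant
health concern. Reported MOEs are rounded half away from zero to integers;
classification always uses the unrounded ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .dataio import AnalyteClass, AnalyteConstants, DEFAULT_CONSTANTS
from .exposure import ExposureSummary

__all__ = ["MOEResult", "MOE_THRESHOLD", "moe", "moe_table"]

MOE_THRESHOLD = 1000.0
_MG_TO_NG = 1e6


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class MOEResult:
    """Margin of exposure for one stratum, analyte class and basis."""

    label: str
    analyte_class: Optional[AnalyteClass]
    basis: str                # "mean" (MOE^a) or "p95" (MOE^b)
    exposure: float           # ng/kg bw/d
    moe: float                # unrounded POD_ng / exposure
    moe_reported: Optional[int]  # rounded; None when exposure is 0
    risk_flag: bool           # True <=> no significant concern (moe > 1000)
    infinite: bool = False    # zero exposure

    def __post_init__(self) -> None:
        if self.basis not in ("mean", "p95"):
            raise ValueError(f"unknown basis {self.basis!r}")
        if not self.infinite:
            if self.risk_flag != (self.moe > MOE_THRESHOLD):
                raise ValueError("risk_flag inconsistent with moe")
            if self.moe_reported != _round_half_away(self.moe):
                raise ValueError("moe_reported inconsistent with moe")


def moe(
    pod: float,
    exposure: float,
    label: str = "",
    analyte_class: Optional[AnalyteClass] = None,
    basis: str = "mean",
) -> MOEResult:
    """Margin of exposure from a POD in mg/kg bw/d and an exposure in
    ng/kg bw/d.

    Zero exposure yields an infinite-MOE result (flagged, no concern);
    negative inputs are rejected.
    """
    if pod <= 0:
        raise ValueError("pod must be > 0")
    if exposure < 0:
        raise ValueError("exposure must be >= 0")
    if exposure == 0:
        return MOEResult(
            label=label, analyte_class=analyte_class, basis=basis,
            exposure=0.0, moe=math.inf, moe_reported=None,
            risk_flag=True, infinite=True,
        )
    ratio = pod * _MG_TO_NG / exposure
    return MOEResult(
        label=label,
        analyte_class=analyte_class,
        basis=basis,
        exposure=exposure,
        moe=ratio,
        moe_reported=_round_half_away(ratio),
        risk_flag=ratio > MOE_THRESHOLD,
    )


def moe_table(
    summaries: Iterable[ExposureSummary],
    constants: Optional[Mapping[AnalyteClass, AnalyteConstants]] = None,
) -> list[MOEResult]:
    """Mean-basis (MOE^a) and P95-basis (MOE^b) rows for each summary."""
    constants = constants or DEFAULT_CONSTANTS
    results = []
    for summary in summaries:
        if summary.analyte_class is None:
            raise ValueError(
                f"summary {summary.subgroup!r} lacks an analyte class"
            )
        pod = constants[summary.analyte_class].bmdl10
        for basis, exposure in (("mean", summary.mean), ("p95", summary.p95)):
            results.append(
                moe(pod, exposure, label=summary.subgroup,
                    analyte_class=summary.analyte_class, basis=basis)
            )
    return results
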