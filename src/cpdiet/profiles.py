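"""Homologue-composition analytics.

Decomposes congener-resolved concentrations into carbon-chain fractions,
chlorination-degree fractions (both within analyte class), and SCCP/MCCP
class shares of total chlorinated paraffins, per sample or per region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .dataio import AnalyteClass, ConcentrationRecord, CongenerGroup

__all__ = ["ProfileDecomposition", "decompose", "dominant_groups"]

_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class ProfileDecomposition:
    """Fraction decomposition of one scope unit (a sample or a region).

    Fraction maps are ``None`` for a class whose total concentration is
    zero (listed in ``undefined_classes``). ``class_shares`` is ``None``
    when the grand total is zero.
    """

    scope: str
    carbon_fractions: dict[AnalyteClass, Optional[dict[int, float]]]
    chlorine_fractions: dict[AnalyteClass, Optional[dict[int, float]]]
    group_fractions: dict[AnalyteClass, Optional[dict[CongenerGroup, float]]]
    class_shares: Optional[dict[AnalyteClass, float]]
    undefined_classes: frozenset[AnalyteClass] = frozenset()

    def __post_init__(self) -> None:
        for table in (self.carbon_fractions, self.chlorine_fractions,
                      self.group_fractions):
            for fracs in table.values():
                if fracs is None:
                    continue
                values = list(fracs.values())
                if any(not 0.0 <= v <= 1.0 + _FRACTION_TOL for v in values):
                    raise ValueError("fraction outside [0, 1]")
                if abs(math.fsum(values) - 1.0) > _FRACTION_TOL:
                    raise ValueError("fractions do not sum to 1")
        if self.class_shares is not None:
            if abs(math.fsum(self.class_shares.values()) - 1.0) > _FRACTION_TOL:
                raise ValueError("class shares do not sum to 1")


def _decompose_concentrations(
    scope: str, conc: dict[CongenerGroup, float]
) -> ProfileDecomposition:
    carbon: dict[AnalyteClass, Optional[dict[int, float]]] = {}
    chlorine: dict[AnalyteClass, Optional[dict[int, float]]] = {}
    groups: dict[AnalyteClass, Optional[dict[CongenerGroup, float]]] = {}
    undefined = set()
    class_totals = {}
    for ac in AnalyteClass:
        members = {g: v for g, v in conc.items() if g.analyte_class is ac}
        total = math.fsum(members.values())
        class_totals[ac] = total
        if total <= 0.0:
            carbon[ac] = chlorine[ac] = groups[ac] = None
            undefined.add(ac)
            continue
        by_carbon: dict[int, float] = {}
        by_chlorine: dict[int, float] = {}
        for g, v in members.items():
            by_carbon[g.carbon] = by_carbon.get(g.carbon, 0.0) + v
            by_chlorine[g.chlorine] = by_chlorine.get(g.chlorine, 0.0) + v
        carbon[ac] = {c: v / total for c, v in sorted(by_carbon.items())}
        chlorine[ac] = {cl: v / total for cl, v in sorted(by_chlorine.items())}
        groups[ac] = {g: v / total for g, v in sorted(members.items())}

    grand = math.fsum(class_totals.values())
    shares = (
        {ac: t / grand for ac, t in class_totals.items()} if grand > 0 else None
    )
    return ProfileDecomposition(
        scope=scope,
        carbon_fractions=carbon,
        chlorine_fractions=chlorine,
        group_fractions=groups,
        class_shares=shares,
        undefined_classes=frozenset(undefined),
    )


def decompose(
    records: Iterable[ConcentrationRecord],
    scope: str = "per_sample",
    aggregation: str = "concentration_weighted",
) -> list[ProfileDecomposition]:
    """Fraction decomposition per sample or per region.

    For ``scope="per_region"`` the default aggregation sums concentrations
    over the region's samples before normalizing (concentration-weighted);
    ``aggregation="mean_of_fractions"`` instead averages the per-sample
    fraction vectors (samples with an undefined class are skipped for that
    class).
    """
    records = list(records)
    if not records:
        raise ValueError("no records to decompose")

    if scope == "per_sample":
        return [_decompose_concentrations(r.sample_id, r.concentrations)
                for r in records]
    if scope != "per_region":
        raise ValueError(f"unknown scope {scope!r}")

    by_region: dict[str, list[ConcentrationRecord]] = {}
    for rec in records:
        by_region.setdefault(rec.region, []).append(rec)

    if aggregation == "concentration_weighted":
        out = []
        for region, recs in by_region.items():
            summed: dict[CongenerGroup, float] = {}
            for rec in recs:
                for g, v in rec.concentrations.items():
                    summed[g] = summed.get(g, 0.0) + v
            out.append(_decompose_concentrations(region, summed))
        return out

    if aggregation != "mean_of_fractions":
        raise ValueError(f"unknown aggregation {aggregation!r}")

    out = []
    for region, recs in by_region.items():
        per_sample = [
            _decompose_concentrations(r.sample_id, r.concentrations)
            for r in recs
        ]
        carbon: dict[AnalyteClass, Optional[dict[int, float]]] = {}
        chlorine: dict[AnalyteClass, Optional[dict[int, float]]] = {}
        groups: dict[AnalyteClass, Optional[dict[CongenerGroup, float]]] = {}
        undefined = set()
        for ac in AnalyteClass:
            defined = [d for d in per_sample if ac not in d.undefined_classes]
            if not defined:
                carbon[ac] = chlorine[ac] = groups[ac] = None
                undefined.add(ac)
                continue
            carbon[ac] = _mean_fractions([d.carbon_fractions[ac] for d in defined])
            chlorine[ac] = _mean_fractions(
                [d.chlorine_fractions[ac] for d in defined]
            )
            groups[ac] = _mean_fractions([d.group_fractions[ac] for d in defined])
        share_samples = [d.class_shares for d in per_sample
                         if d.class_shares is not None]
        shares = _mean_fractions(share_samples) if share_samples else None
        out.append(
            ProfileDecomposition(
                scope=region,
                carbon_fractions=carbon,
                chlorine_fractions=chlorine,
                group_fractions=groups,
                class_shares=shares,
                undefined_classes=frozenset(undefined),
            )
        )
    return out


def _mean_fractions(dicts):
    keys = sorted(dicts[0])
    return {k: math.fsum(d[k] for d in dicts) / len(dicts) for k in keys}


@dataclass(frozen=True)
class DominantGroups:
    """Top-k congener groups of one class by concentration share."""

    scope: str
    analyte_class: AnalyteClass
    groups: tuple[CongenerGroup, ...]
    shares: tuple[float, ...]
    tie_flag: bool = False        # ties broken by (carbon, chlorine) ascending
    truncated_flag: bool = False  # k exceeded the available group count


def dominant_groups(
    decomposition: ProfileDecomposition,
    k: int,
    analyte_class: AnalyteClass,
) -> DominantGroups:
    """Rank the top-k congener groups of one class by share.

    Ties are broken by (carbon, chlorine) ascending and flagged; asking
    for more groups than exist returns them all with ``truncated_flag``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    fracs = decomposition.group_fractions[analyte_class]
    if fracs is None:
        raise ValueError(
            f"{decomposition.scope}: {analyte_class.value} fractions undefined"
        )
    ranked = sorted(fracs.items(), key=lambda item: (-item[1], item[0]))
    truncated = k > len(ranked)
    top = ranked[:k]
    # a tie matters when it straddles the selection boundary or lies inside
    shares = [s for _, s in ranked]
    tie = len(set(shares[:min(k + 1, len(shares))])) < min(k + 1, len(shares))
    return DominantGroups(
        scope=decomposition.scope,
        analyte_class=analyte_class,
        groups=tuple(g for g, _ in top),
        shares=tuple(s for _, s in top),
        tie_flag=tie,
        truncated_flag=truncated,
    )
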