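"""Published summary statistics of the chicken-meat study, as package data.

These are the printed regional concentration summaries, subgroup/regional
exposure statistics, and survey-level consumption figures that calibrate
the synthetic-data generator and drive the desk-scale reproduction checks.
All concentrations are ng/g wet weight; exposures are ng/kg bw/d.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dataio import AnalyteClass

__all__ = [
    "RegionStats",
    "ExposureStat",
    "REGION_ORDER",
    "REGION_STATS",
    "REGION_BLOCKS",
    "TOTAL_N",
    "SUBGROUP_EXPOSURE",
    "REGIONAL_EXPOSURE",
    "POPULATION_MEAN_CONSUMPTION_G",
    "CONSUMER_ONLY_MEAN_CONSUMPTION_G",
    "CONSUMER_ONLY_P95_CONSUMPTION_G",
]


@dataclass(frozen=True)
class RegionStats:
    """n, mean and observed range of class-total concentrations in one region."""

    region: str
    n: int
    mean: dict[AnalyteClass, float]
    range: dict[AnalyteClass, tuple[float, float]]


_S = AnalyteClass.SCCP
_M = AnalyteClass.MCCP

REGION_ORDER = [
    "Jilin", "Heilongjiang", "Hebei", "Tianjin",
    "Beijing", "Shandong", "Jiangxi", "Jiangsu",
]

REGION_STATS: dict[str, RegionStats] = {
    "Jilin": RegionStats(
        "Jilin", 45,
        {_S: 99.7, _M: 228.4},
        {_S: (26.6, 470.2), _M: (86.3, 910.7)},
    ),
    "Heilongjiang": RegionStats(
        "Heilongjiang", 20,
        {_S: 35.0, _M: 77.6},
        {_S: (16.7, 82.3), _M: (20.8, 161.6)},
    ),
    "Hebei": RegionStats(
        "Hebei", 15,
        {_S: 102.7, _M: 246.4},
        {_S: (9.5, 374.8), _M: (32.8, 1517.9)},
    ),
    "Tianjin": RegionStats(
        "Tianjin", 7,
        {_S: 42.6, _M: 29.9},
        {_S: (23.0, 63.3), _M: (20.0, 57.6)},
    ),
    "Beijing": RegionStats(
        "Beijing", 10,
        {_S: 51.2, _M: 44.3},
        {_S: (16.8, 135.5), _M: (20.5, 94.5)},
    ),
    "Shandong": RegionStats(
        "Shandong", 10,
        {_S: 21.5, _M: 52.0},
        {_S: (14.4, 30.6), _M: (29.7, 73.6)},
    ),
    "Jiangxi": RegionStats(
        "Jiangxi", 11,
        {_S: 30.4, _M: 58.3},
        {_S: (12.2, 125.9), _M: (23.4, 136.7)},
    ),
    "Jiangsu": RegionStats(
        "Jiangsu", 8,
        {_S: 497.6, _M: 299.2},
        {_S: (32.1, 1542.4), _M: (49.3, 990.8)},
    ),
}

#: Geographic pooling of the eight sampling regions.
REGION_BLOCKS: dict[str, list[str]] = {
    "Northeast China": ["Jilin", "Heilongjiang"],
    "North China": ["Hebei", "Tianjin", "Beijing"],
    "East China": ["Shandong", "Jiangxi", "Jiangsu"],
}

TOTAL_N = sum(rs.n for rs in REGION_STATS.values())  # 126


@dataclass(frozen=True)
class ExposureStat:
    """Printed mean, CI half-width and P95 exposure for one stratum."""

    label: str
    analyte_class: AnalyteClass
    mean: float
    ci_half_width: float
    p95: float


#: Sex-age subgroup exposure statistics (ng/kg bw/d).
SUBGROUP_EXPOSURE: list[ExposureStat] = [
    ExposureStat("3-6", _S, 89.0, 1.8, 275.2),
    ExposureStat("7-12", _S, 66.2, 1.4, 206.7),
    ExposureStat("13-17 male", _S, 39.8, 0.8, 122.6),
    ExposureStat("13-17 female", _S, 49.1, 1.0, 150.0),
    ExposureStat("18-59 male", _S, 30.2, 0.6, 91.8),
    ExposureStat("18-59 female", _S, 30.6, 0.6, 92.1),
    ExposureStat(">=60 male", _S, 22.5, 0.5, 70.0),
    ExposureStat(">=60 female", _S, 22.3, 0.5, 68.3),
    ExposureStat("Consumer only", _S, 93.9, 22.0, 290.7),
    ExposureStat("All", _S, 32.8, 2.4, 106.4),
    ExposureStat("3-6", _M, 132.6, 2.7, 412.0),
    ExposureStat("7-12", _M, 99.4, 2.1, 313.4),
    ExposureStat("13-17 male", _M, 59.6, 1.3, 183.0),
    ExposureStat("13-17 female", _M, 73.1, 1.5, 222.7),
    ExposureStat("18-59 male", _M, 45.2, 0.9, 137.5),
    ExposureStat("18-59 female", _M, 45.5, 0.9, 137.6),
    ExposureStat(">=60 male", _M, 33.5, 0.7, 101.7),
    ExposureStat(">=60 female", _M, 33.2, 0.7, 100.8),
    ExposureStat("Consumer only", _M, 153.2, 31.1, 450.9),
    ExposureStat("All", _M, 52.6, 3.5, 159.8),
]

#: Whole-population exposure by sampling region (ng/kg bw/d).
REGIONAL_EXPOSURE: list[ExposureStat] = [
    ExposureStat("Jilin", _S, 27.0, 4.7, 92.2),
    ExposureStat("Heilongjiang", _S, 10.7, 0.4, 33.7),
    ExposureStat("Hebei", _S, 29.7, 6.4, 97.4),
    ExposureStat("Tianjin", _S, 15.6, 4.0, 42.1),
    ExposureStat("Beijing", _S, 17.9, 2.8, 53.1),
    ExposureStat("Shandong", _S, 6.9, 0.6, 21.3),
    ExposureStat("Jiangxi", _S, 8.8, 2.3, 33.1),
    ExposureStat("Jiangsu", _S, 159.1, 13.2, 485.6),
    ExposureStat("Jilin", _M, 68.8, 6.5, 225.3),
    ExposureStat("Heilongjiang", _M, 36.5, 22.3, 78.2),
    ExposureStat("Hebei", _M, 75.3, 4.4, 241.1),
    ExposureStat("Tianjin", _M, 7.6, 2.0, 20.3),
    ExposureStat("Beijing", _M, 13.7, 2.0, 41.2),
    ExposureStat("Shandong", _M, 16.6, 1.5, 50.9),
    ExposureStat("Jiangxi", _M, 17.1, 2.0, 53.9),
    ExposureStat("Jiangsu", _M, 84.4, 7.2, 261.7),
]

POPULATION_MEAN_CONSUMPTION_G = 16.8
CONSUMER_ONLY_MEAN_CONSUMPTION_G = 54.7
CONSUMER_ONLY_P95_CONSUMPTION_G = 133.3
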