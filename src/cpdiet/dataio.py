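"""Domain types, validation, and CSV readers/writers.

Exchange formats are plain UTF-8 CSV with a period decimal separator:

* concentration table (long format):
  ``sample_id,region,carbon,chlorine,conc_ng_g`` where ``conc_ng_g`` is a
  non-negative number in ng/g wet weight or the token ``<MDL`` for a
  left-censored observation;
* consumption survey: ``person_id,sex,age,body_weight,day1,day2,day3``
  with the day columns holding g/d chicken consumption per 24-h recall
  day (trailing days may be blank or absent).
"""

from __future__ import annotations

import csv
import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

log = logging.getLogger(__name__)

__all__ = [
    "AnalyteClass",
    "AnalyteConstants",
    "CongenerGroup",
    "ConcentrationRecord",
    "MdlPolicy",
    "Sex",
    "Subgroup",
    "SurveyIndividual",
    "SurveyTable",
    "DEFAULT_CONSTANTS",
    "ALL_LABEL",
    "CONSUMER_ONLY_LABEL",
    "all_congener_groups",
    "assign_subgroup",
    "default_partition",
    "read_concentrations",
    "read_survey",
    "write_concentrations",
    "write_survey",
]

SCCP_CARBONS = range(10, 14)
MCCP_CARBONS = range(14, 18)
CHLORINES = range(5, 11)

ALL_LABEL = "All"
CONSUMER_ONLY_LABEL = "Consumer only"


class AnalyteClass(str, enum.Enum):
    SCCP = "SCCP"
    MCCP = "MCCP"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class MdlPolicy(str, enum.Enum):
    """Substitution rule for observations reported below the MDL."""

    LOWER = "lower"    # 0
    MIDDLE = "middle"  # MDL / 2
    UPPER = "upper"    # MDL


@dataclass(frozen=True, order=True)
class CongenerGroup:
    """One carbon/chlorine homologue class, e.g. C10Cl6."""

    carbon: int
    chlorine: int

    def __post_init__(self) -> None:
        if self.carbon not in range(10, 18):
            raise ValueError(
                f"carbon chain length {self.carbon} outside the C10-C17 range "
                "covered by SCCP/MCCP classes"
            )
        if self.chlorine not in CHLORINES:
            raise ValueError(
                f"chlorine count {self.chlorine} outside the Cl5-Cl10 range"
            )

    @property
    def analyte_class(self) -> AnalyteClass:
        return AnalyteClass.SCCP if self.carbon <= 13 else AnalyteClass.MCCP

    def __str__(self) -> str:
        return f"C{self.carbon}Cl{self.chlorine}"


def all_congener_groups(analyte_class: AnalyteClass) -> list[CongenerGroup]:
    """The 24 congener groups of one analyte class, canonically ordered."""
    carbons = SCCP_CARBONS if analyte_class is AnalyteClass.SCCP else MCCP_CARBONS
    return [CongenerGroup(c, cl) for c in carbons for cl in CHLORINES]


@dataclass(frozen=True)
class AnalyteConstants:
    """Toxicological point of departure and detection limit for one class."""

    analyte_class: AnalyteClass
    bmdl10: float  # mg/kg bw/d
    mdl: float     # ng/g ww

    def __post_init__(self) -> None:
        if self.bmdl10 <= 0:
            raise ValueError("bmdl10 must be positive")
        if self.mdl <= 0:
            raise ValueError("mdl must be positive")


#: EFSA BMDL10 values and the study MDLs (SCCP 2.3 mg/kg bw/d, 3 ng/g;
#: MCCP 36 mg/kg bw/d, 5.0 ng/g).
DEFAULT_CONSTANTS: dict[AnalyteClass, AnalyteConstants] = {
    AnalyteClass.SCCP: AnalyteConstants(AnalyteClass.SCCP, bmdl10=2.3, mdl=3.0),
    AnalyteClass.MCCP: AnalyteConstants(AnalyteClass.MCCP, bmdl10=36.0, mdl=5.0),
}


@dataclass
class ConcentrationRecord:
    """Congener-resolved wet-weight concentrations for one sample."""

    sample_id: str
    region: str
    concentrations: dict[CongenerGroup, float]
    censored: frozenset[CongenerGroup] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.region:
            raise ValueError(f"sample {self.sample_id!r}: region must be non-empty")
        for group, value in self.concentrations.items():
            if not math.isfinite(value) or value < 0:
                raise ValueError(
                    f"sample {self.sample_id!r}, group {group}: concentration "
                    f"{value!r} must be a finite non-negative number"
                )

    def class_total(self, analyte_class: AnalyteClass) -> float:
        """Sum of member congener concentrations, ng/g ww."""
        return math.fsum(
            v for g, v in self.concentrations.items()
            if g.analyte_class is analyte_class
        )


@dataclass
class SurveyIndividual:
    """One survey respondent with up to three 24-h recall days."""

    person_id: str
    sex: Sex
    age: float
    body_weight: float  # kg
    recall_consumptions: list[float]  # g/d, one entry per recall day

    def __post_init__(self) -> None:
        if self.body_weight <= 0 or not math.isfinite(self.body_weight):
            raise ValueError(f"{self.person_id!r}: body weight must be > 0")
        if self.age < 0:
            raise ValueError(f"{self.person_id!r}: age must be >= 0")
        if not 1 <= len(self.recall_consumptions) <= 3:
            raise ValueError(f"{self.person_id!r}: need 1-3 recall days")
        if any(c < 0 or not math.isfinite(c) for c in self.recall_consumptions):
            raise ValueError(f"{self.person_id!r}: consumptions must be >= 0")

    @property
    def mean_consumption(self) -> float:
        """Arithmetic mean over present recall days, g/d."""
        return math.fsum(self.recall_consumptions) / len(self.recall_consumptions)

    def is_daily_consumer(self, rule: str = "all_days") -> bool:
        """Whether the individual belongs to the consumer-only subpopulation.

        ``all_days`` (default): positive consumption on every recall day.
        ``any_day``: positive consumption on at least one recall day.
        """
        if rule == "all_days":
            return all(c > 0 for c in self.recall_consumptions)
        if rule == "any_day":
            return any(c > 0 for c in self.recall_consumptions)
        raise ValueError(f"unknown consumer rule {rule!r}")


@dataclass(frozen=True)
class Subgroup:
    """A sex/age stratum of the survey population.

    ``age_range`` is half-open ``[min, max)``; ``sex_filter`` of ``None``
    pools both sexes.
    """

    label: str
    age_range: tuple[float, float]
    sex_filter: Optional[Sex] = None
    consumer_only: bool = False

    def matches(self, individual: SurveyIndividual,
                consumer_rule: str = "all_days") -> bool:
        lo, hi = self.age_range
        if not (lo <= individual.age < hi):
            return False
        if self.sex_filter is not None and individual.sex is not self.sex_filter:
            return False
        if self.consumer_only and not individual.is_daily_consumer(consumer_rule):
            return False
        return True


def default_partition() -> list[Subgroup]:
    """The study's eight sex-age subgroups (sexes pooled for 3-6 and 7-12)."""
    inf = math.inf
    return [
        Subgroup("3-6", (3, 7)),
        Subgroup("7-12", (7, 13)),
        Subgroup("13-17 male", (13, 18), Sex.MALE),
        Subgroup("13-17 female", (13, 18), Sex.FEMALE),
        Subgroup("18-59 male", (18, 60), Sex.MALE),
        Subgroup("18-59 female", (18, 60), Sex.FEMALE),
        Subgroup(">=60 male", (60, inf), Sex.MALE),
        Subgroup(">=60 female", (60, inf), Sex.FEMALE),
    ]


def assign_subgroup(
    individual: SurveyIndividual,
    partition: Optional[Sequence[Subgroup]] = None,
    consumer_rule: str = "all_days",
) -> list[str]:
    """Labels of every stratum the individual belongs to.

    Always contains ``"All"``; contains exactly one sex-age label when the
    individual's age is covered by the partition (a warning is logged
    otherwise); contains ``"Consumer only"`` iff the consumer rule holds.
    """
    if partition is None:
        partition = default_partition()
    labels = [ALL_LABEL]
    matched = [sg.label for sg in partition
               if sg.matches(individual, consumer_rule)]
    if len(matched) > 1:
        raise ValueError(
            f"{individual.person_id!r} matched several sex-age subgroups: "
            f"{matched} — partition is not disjoint"
        )
    if matched:
        labels.extend(matched)
    else:
        log.warning(
            "individual %s (age %.1f) not covered by the subgroup partition; "
            "assigned only to %r", individual.person_id, individual.age,
            ALL_LABEL,
        )
    if individual.is_daily_consumer(consumer_rule):
        labels.append(CONSUMER_ONLY_LABEL)
    return labels


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

_CONC_HEADER = ["sample_id", "region", "carbon", "chlorine", "conc_ng_g"]
_SURVEY_HEADER = ["person_id", "sex", "age", "body_weight", "day1", "day2", "day3"]
MDL_TOKEN = "<MDL"


class ParseError(ValueError):
    """Malformed input row; message names the offending line."""


def _substitute(mdl: float, policy: MdlPolicy) -> float:
    if policy is MdlPolicy.LOWER:
        return 0.0
    if policy is MdlPolicy.MIDDLE:
        return mdl / 2.0
    return mdl


def read_concentrations(
    path: Union[str, Path],
    mdl_policy: Union[MdlPolicy, str] = MdlPolicy.MIDDLE,
    constants: Optional[Mapping[AnalyteClass, AnalyteConstants]] = None,
) -> list[ConcentrationRecord]:
    """Read a long-format congener concentration table.

    Below-MDL cells (token ``<MDL``) are substituted according to
    ``mdl_policy`` — ``lower`` -> 0, ``middle`` -> MDL/2, ``upper`` -> MDL,
    using the MDL of the congener's analyte class — and flagged in the
    record's ``censored`` set.
    """
    policy = MdlPolicy(mdl_policy)
    constants = constants or DEFAULT_CONSTANTS
    path = Path(path)

    by_sample: dict[str, dict] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [
            f.strip() for f in reader.fieldnames
        ] != _CONC_HEADER:
            raise ParseError(
                f"{path}: expected header {','.join(_CONC_HEADER)!r}, "
                f"got {reader.fieldnames!r}"
            )
        for row in reader:
            line = reader.line_num
            try:
                sample_id = row["sample_id"].strip()
                region = row["region"].strip()
                group = CongenerGroup(int(row["carbon"]), int(row["chlorine"]))
            except (TypeError, ValueError, AttributeError) as exc:
                raise ParseError(f"{path} line {line}: {exc}") from exc

            raw = (row["conc_ng_g"] or "").strip()
            censored = False
            if raw == MDL_TOKEN:
                value = _substitute(constants[group.analyte_class].mdl, policy)
                censored = True
            else:
                try:
                    value = float(raw)
                except ValueError as exc:
                    raise ParseError(
                        f"{path} line {line}: bad concentration {raw!r}"
                    ) from exc
                if value < 0 or not math.isfinite(value):
                    raise ParseError(
                        f"{path} line {line}: concentration must be finite "
                        f"and non-negative, got {raw!r}"
                    )

            entry = by_sample.setdefault(
                sample_id, {"region": region, "conc": {}, "cens": set()}
            )
            if entry["region"] != region:
                raise ParseError(
                    f"{path} line {line}: sample {sample_id!r} appears under "
                    f"two regions ({entry['region']!r}, {region!r})"
                )
            if group in entry["conc"]:
                raise ParseError(
                    f"{path} line {line}: duplicate group {group} for sample "
                    f"{sample_id!r}"
                )
            entry["conc"][group] = value
            if censored:
                entry["cens"].add(group)

    return [
        ConcentrationRecord(
            sample_id=sid,
            region=entry["region"],
            concentrations=entry["conc"],
            censored=frozenset(entry["cens"]),
        )
        for sid, entry in by_sample.items()
    ]


def write_concentrations(
    records: Iterable[ConcentrationRecord], path: Union[str, Path]
) -> None:
    """Write records in the long CSV format at full ``repr`` precision.

    Censored cells are written back as the ``<MDL`` token, so a
    write/read round trip preserves the censoring flags.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CONC_HEADER)
        for rec in records:
            for group in sorted(rec.concentrations):
                value = rec.concentrations[group]
                cell = MDL_TOKEN if group in rec.censored else repr(float(value))
                writer.writerow(
                    [rec.sample_id, rec.region, group.carbon, group.chlorine, cell]
                )


@dataclass
class SurveyTable:
    """Survey read result: valid individuals plus the exclusion tally."""

    individuals: list[SurveyIndividual]
    n_excluded_missing_bw: int = 0

    def __iter__(self) -> Iterator[SurveyIndividual]:
        return iter(self.individuals)

    def __len__(self) -> int:
        return len(self.individuals)


def read_survey(path: Union[str, Path]) -> SurveyTable:
    """Read a consumption survey CSV.

    Individuals with a missing/blank body weight are excluded and counted
    (the count is logged), mirroring the study's handling. Blank recall-day
    cells are treated as days not surveyed, not as zero consumption.
    """
    path = Path(path)
    individuals: list[SurveyIndividual] = []
    n_excluded = 0
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            log.warning("%s: empty survey file", path)
            return SurveyTable([], 0)
        names = [f.strip() for f in reader.fieldnames]
        if names[:4] != _SURVEY_HEADER[:4] or not set(names[4:]) <= {
            "day1", "day2", "day3"
        }:
            raise ParseError(
                f"{path}: expected header {','.join(_SURVEY_HEADER)!r} "
                f"(day columns optional), got {reader.fieldnames!r}"
            )
        for row in reader:
            line = reader.line_num
            bw_raw = (row.get("body_weight") or "").strip()
            if not bw_raw:
                n_excluded += 1
                continue
            days = []
            for col in ("day1", "day2", "day3"):
                cell = (row.get(col) or "").strip()
                if cell:
                    try:
                        days.append(float(cell))
                    except ValueError as exc:
                        raise ParseError(
                            f"{path} line {line}: bad consumption {cell!r}"
                        ) from exc
            try:
                individuals.append(
                    SurveyIndividual(
                        person_id=row["person_id"].strip(),
                        sex=Sex(row["sex"].strip().lower()),
                        age=float(row["age"]),
                        body_weight=float(bw_raw),
                        recall_consumptions=days,
                    )
                )
            except (TypeError, ValueError, AttributeError) as exc:
                raise ParseError(f"{path} line {line}: {exc}") from exc
    if n_excluded:
        log.info(
            "%s: excluded %d individuals with missing body weight",
            path, n_excluded,
        )
    if not individuals:
        log.warning("%s: no usable survey individuals", path)
    return SurveyTable(individuals, n_excluded)


def write_survey(
    individuals: Iterable[SurveyIndividual], path: Union[str, Path]
) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SURVEY_HEADER)
        for ind in individuals:
            days = [repr(float(c)) for c in ind.recall_consumptions]
            days += [""] * (3 - len(days))
            writer.writerow(
                [ind.person_id, ind.sex.value, repr(float(ind.age)),
                 repr(float(ind.body_weight)), *days]
            )
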