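"""Pipeline orchestration: configuration, stage runners, CSV artifacts.

Stage order: simulate/ingest -> occurrence -> profiles -> exposure -> risk.
Every stage output is a pure function of (inputs, config, seed); a JSON run
manifest records config and input/output digests so a run can be replayed
and verified bit-for-bit.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import yaml

from . import __version__
from .dataio import (
    ALL_LABEL,
    CONSUMER_ONLY_LABEL,
    AnalyteClass,
    AnalyteConstants,
    ConcentrationRecord,
    DEFAULT_CONSTANTS,
    MdlPolicy,
    ParseError,
    Sex,
    Subgroup,
    SurveyIndividual,
    default_partition,
    read_concentrations,
    read_survey,
    write_concentrations,
    write_survey,
)
from .exposure import (
    DegenerateDataError,
    DistributionFit,
    ExposureSummary,
    SensitivityResult,
    consumption_model,
    contribution_to_variance,
    fit_distribution,
    point_mass,
    simulate_exposure,
)
from .occurrence import (
    RegionSummary,
    correlation_with_ci,
    kruskal_wallis,
    pairwise_wilcoxon_bh,
    pooled_mean,
    summarize_regions,
)
from .profiles import decompose
from .risk import MOEResult, moe_table
from .synthetic import default_study_specs, gen_concentrations, gen_survey

__all__ = ["RunConfig", "assess_population", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration (YAML/JSON)."""

    seed: int = 0
    iterations: int = 10_000
    mdl_policy: MdlPolicy = MdlPolicy.MIDDLE
    consumer_rule: str = "all_days"
    correlation_method: str = "spearman"
    profile_aggregation: str = "concentration_weighted"
    simulate: bool = True
    survey_scale: float = 1.0
    concentrations_csv: Optional[str] = None
    survey_csv: Optional[str] = None
    constants: Mapping[AnalyteClass, AnalyteConstants] = field(
        default_factory=lambda: dict(DEFAULT_CONSTANTS)
    )
    partition: Sequence[Subgroup] = field(default_factory=default_partition)

    def __post_init__(self) -> None:
        if self.iterations < 1000:
            raise ValueError("iterations must be >= 1000")
        if self.consumer_rule not in ("all_days", "any_day"):
            raise ValueError(f"unknown consumer rule {self.consumer_rule!r}")
        if self.correlation_method not in ("pearson", "spearman"):
            raise ValueError(
                f"unknown correlation method {self.correlation_method!r}"
            )
        if not self.simulate and not (self.concentrations_csv and self.survey_csv):
            raise ValueError(
                "simulate=false requires concentrations_csv and survey_csv"
            )
        labels = [sg.label for sg in self.partition]
        if len(set(labels)) != len(labels):
            raise ValueError("subgroup labels must be unique")

    @classmethod
    def from_mapping(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        if "mdl_policy" in data:
            data["mdl_policy"] = MdlPolicy(data["mdl_policy"])
        if "constants" in data:
            data["constants"] = {
                AnalyteClass(ac): AnalyteConstants(
                    AnalyteClass(ac), float(vals["bmdl10"]), float(vals["mdl"])
                )
                for ac, vals in data["constants"].items()
            }
        if "partition" in data:
            data["partition"] = [
                Subgroup(
                    label=sg["label"],
                    age_range=(float(sg["age_min"]),
                               float(sg.get("age_max", math.inf))),
                    sex_filter=Sex(sg["sex"]) if sg.get("sex") else None,
                    consumer_only=bool(sg.get("consumer_only", False)),
                )
                for sg in data["partition"]
            ]
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)

    def canonical_json(self) -> str:
        def default(obj):
            if isinstance(obj, (MdlPolicy, AnalyteClass, Sex)):
                return obj.value
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            if obj == math.inf:
                return "inf"
            raise TypeError(type(obj))

        payload = dataclasses.asdict(self)
        payload["constants"] = {
            ac.value: {"bmdl10": c.bmdl10, "mdl": c.mdl}
            for ac, c in self.constants.items()
        }
        payload["partition"] = [
            {
                "label": sg.label,
                "age_min": sg.age_range[0],
                "age_max": ("inf" if math.isinf(sg.age_range[1])
                            else sg.age_range[1]),
                "sex": sg.sex_filter.value if sg.sex_filter else None,
                "consumer_only": sg.consumer_only,
            }
            for sg in self.partition
        ]
        return json.dumps(payload, sort_keys=True, default=default)


def _stable_seed(seed: int, *names: str) -> int:
    digest = hashlib.sha256(
        (str(seed) + "\x1f" + "\x1f".join(names)).encode("utf-8")
    ).digest()
    return int.from_bytes(digest[:8], "big")


def _fit_or_point(values: Sequence[float]) -> DistributionFit:
    values = [v for v in values if v > 0]
    if not values:
        raise ValueError("no positive values to model")
    try:
        return fit_distribution(values).best
    except (DegenerateDataError, ValueError):
        return point_mass(float(np.mean(values)))


def assess_population(
    records: Sequence[ConcentrationRecord],
    individuals: Sequence[SurveyIndividual],
    config: RunConfig,
    by: str = "subgroup",
) -> tuple[list[ExposureSummary], dict[tuple[str, AnalyteClass], SensitivityResult]]:
    """Monte Carlo exposure for every stratum x analyte class.

    ``by="subgroup"`` pools concentrations over all samples and varies the
    consumption/body-weight models across the sex-age partition plus the
    "All" and "Consumer only" strata; ``by="region"`` fits concentrations
    per region against the whole-population consumption model.
    """
    if by not in ("subgroup", "region"):
        raise ValueError(f"unknown stratification {by!r}")

    strata: list[tuple[str, list[SurveyIndividual], list[ConcentrationRecord]]] = []
    if by == "subgroup":
        for sg in config.partition:
            members = [i for i in individuals
                       if sg.matches(i, config.consumer_rule)]
            strata.append((sg.label, members, list(records)))
        consumers = [i for i in individuals
                     if i.is_daily_consumer(config.consumer_rule)]
        strata.append((CONSUMER_ONLY_LABEL, consumers, list(records)))
        strata.append((ALL_LABEL, list(individuals), list(records)))
    else:
        by_region: dict[str, list[ConcentrationRecord]] = {}
        for rec in records:
            by_region.setdefault(rec.region, []).append(rec)
        for region, recs in by_region.items():
            strata.append((region, list(individuals), recs))

    summaries: list[ExposureSummary] = []
    sensitivities: dict[tuple[str, AnalyteClass], SensitivityResult] = {}
    for label, members, recs in strata:
        if not members:
            continue
        cons = consumption_model(members)
        bw_fit = _fit_or_point([i.body_weight for i in members])
        for ac in AnalyteClass:
            conc_fit = _fit_or_point([r.class_total(ac) for r in recs])
            summary, draws = simulate_exposure(
                conc_fit,
                cons,
                bw_fit,
                n_iter=config.iterations,
                seed=_stable_seed(config.seed, "exposure", by, label, ac.value),
                subgroup=label,
                analyte_class=ac,
                return_draws=True,
            )
            summaries.append(summary)
            sensitivities[(label, ac)] = contribution_to_variance(
                {k: draws[k] for k in
                 ("concentration", "consumption", "body_weight")},
                draws["edi"],
            )
    return summaries, sensitivities


# ---------------------------------------------------------------------------
# CSV artifacts (each carries a leading '#' units comment row)
# ---------------------------------------------------------------------------

def _write_csv(path: Path, units_comment: str, header: list[str],
               rows: list[list]) -> None:
    with path.open("w", newline="", encoding="utf-8") as fh:
        fh.write(f"# {units_comment}\n")
        writer = csv.writer(fh)
        writer.writerow(header)
        writer.writerows(rows)


def write_region_summaries(summaries: Sequence[RegionSummary],
                           path: Union[str, Path]) -> None:
    _write_csv(
        Path(path),
        "concentrations in ng/g wet weight",
        ["region", "analyte_class", "n", "n_detected", "detection_rate",
         "mean", "sd", "min", "max", "sd_undefined"],
        [[s.region, s.analyte_class.value, s.n, s.n_detected,
          repr(s.detection_rate), repr(s.mean), repr(s.sd), repr(s.min),
          repr(s.max), s.sd_undefined] for s in summaries],
    )


def write_exposure_summaries(summaries: Sequence[ExposureSummary],
                             path: Union[str, Path]) -> None:
    _write_csv(
        Path(path),
        "exposures in ng/kg bw/d",
        ["subgroup", "analyte_class", "mean", "ci_half_width", "p95",
         "n_iterations", "seed"],
        [[s.subgroup, s.analyte_class.value if s.analyte_class else "",
          repr(s.mean), repr(s.ci_half_width), repr(s.p95), s.n_iterations,
          s.seed] for s in summaries],
    )


def read_exposure_summaries(path: Union[str, Path]) -> list[ExposureSummary]:
    summaries = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        rows = csv.DictReader(line for line in fh if not line.startswith("#"))
        for row in rows:
            summaries.append(
                ExposureSummary(
                    subgroup=row["subgroup"],
                    analyte_class=(AnalyteClass(row["analyte_class"])
                                   if row["analyte_class"] else None),
                    mean=float(row["mean"]),
                    ci_half_width=float(row["ci_half_width"]),
                    p95=float(row["p95"]),
                    n_iterations=int(row["n_iterations"]),
                    seed=int(row["seed"]) if row.get("seed") else None,
                )
            )
    return summaries


def write_moe_results(results: Sequence[MOEResult],
                      path: Union[str, Path]) -> None:
    _write_csv(
        Path(path),
        "exposure in ng/kg bw/d; moe dimensionless",
        ["label", "analyte_class", "basis", "exposure", "moe",
         "moe_reported", "no_significant_concern"],
        [[r.label, r.analyte_class.value if r.analyte_class else "", r.basis,
          repr(r.exposure), "inf" if r.infinite else repr(r.moe),
          "" if r.moe_reported is None else r.moe_reported, r.risk_flag]
         for r in results],
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: Union[str, Path]) -> Path:
    """Run every stage and write artifacts plus ``manifest.json``.

    Returns the output directory. Any stage failure raises with the stage
    name prefixed to the message.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "ingest"
    try:
        if config.simulate:
            stage = "simulate-data"
            region_specs, survey_specs = default_study_specs(
                survey_scale=config.survey_scale
            )
            records = [
                rec for spec in region_specs
                for rec in gen_concentrations(spec, config.seed)
            ]
            individuals = gen_survey(survey_specs, config.seed)
            write_concentrations(records, out / "concentrations.csv")
            write_survey(individuals, out / "survey.csv")
            input_files = []
        else:
            records = read_concentrations(
                config.concentrations_csv, config.mdl_policy, config.constants
            )
            individuals = list(read_survey(config.survey_csv))
            input_files = [Path(config.concentrations_csv),
                           Path(config.survey_csv)]

        stage = "occurrence"
        summaries = summarize_regions(records, config.constants)
        write_region_summaries(summaries, out / "occurrence_summary.csv")

        by_region: dict[str, list[ConcentrationRecord]] = {}
        for rec in records:
            by_region.setdefault(rec.region, []).append(rec)
        regions = sorted(by_region)
        test_rows = []
        for ac in AnalyteClass:
            groups = [[r.class_total(ac) for r in by_region[reg]]
                      for reg in regions]
            kw = kruskal_wallis(groups, labels=regions)
            test_rows.append([ac.value, "|".join(regions), kw.method,
                              repr(kw.statistic), repr(kw.raw_p), ""])
            for tr in pairwise_wilcoxon_bh(groups, labels=regions):
                test_rows.append([ac.value, "|".join(tr.groups), tr.method,
                                  repr(tr.statistic), repr(tr.raw_p),
                                  repr(tr.adjusted_p)])
        _write_csv(out / "regional_tests.csv",
                   "test statistics dimensionless",
                   ["analyte_class", "groups", "method", "statistic",
                    "raw_p", "adjusted_p"], test_rows)

        corr_rows = []
        scopes = [("Total", records)] + [(r, by_region[r]) for r in regions]
        for scope_label, recs in scopes:
            sccp = [r.class_total(AnalyteClass.SCCP) for r in recs]
            mccp = [r.class_total(AnalyteClass.MCCP) for r in recs]
            if len(recs) < 4:
                continue
            try:
                res = correlation_with_ci(sccp, mccp,
                                          method=config.correlation_method)
            except ValueError:
                continue
            corr_rows.append([scope_label, res.method, res.n, repr(res.r),
                              repr(res.ci_low), repr(res.ci_high),
                              repr(res.p)])
        _write_csv(out / "correlations.csv",
                   "correlation coefficients dimensionless",
                   ["scope", "method", "n", "r", "ci_low", "ci_high", "p"],
                   corr_rows)

        stage = "profile"
        decomps = decompose(records, scope="per_region",
                            aggregation=config.profile_aggregation)
        profile_rows = []
        for d in decomps:
            for ac in AnalyteClass:
                if ac in d.undefined_classes:
                    continue
                for c, frac in d.carbon_fractions[ac].items():
                    profile_rows.append([d.scope, ac.value, "carbon", c,
                                         repr(frac)])
                for cl, frac in d.chlorine_fractions[ac].items():
                    profile_rows.append([d.scope, ac.value, "chlorine", cl,
                                         repr(frac)])
            if d.class_shares is not None:
                for ac, share in d.class_shares.items():
                    profile_rows.append([d.scope, ac.value, "class_share",
                                         ac.value, repr(share)])
        _write_csv(out / "congener_profiles.csv",
                   "fractions dimensionless (sum to 1 per scope/class/axis)",
                   ["scope", "analyte_class", "axis", "key", "fraction"],
                   profile_rows)

        stage = "exposure"
        exposure_rows: list[ExposureSummary] = []
        sensitivity_rows = []
        for by in ("subgroup", "region"):
            summaries_mc, sens = assess_population(
                records, individuals, config, by=by
            )
            exposure_rows.extend(summaries_mc)
            for (label, ac), result in sens.items():
                for variable, pct in result.contributions.items():
                    sensitivity_rows.append(
                        [by, label, ac.value, variable, repr(pct),
                         repr(result.r_squared)]
                    )
        write_exposure_summaries(exposure_rows, out / "exposure.csv")
        _write_csv(out / "sensitivity.csv",
                   "contribution to variance in percent",
                   ["stratification", "label", "analyte_class", "variable",
                    "contribution_pct", "r_squared"], sensitivity_rows)

        stage = "risk"
        moes = moe_table(exposure_rows, config.constants)
        write_moe_results(moes, out / "moe.csv")
    except (FileNotFoundError, ParseError) as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    artifacts = sorted(p.name for p in out.glob("*.csv"))
    manifest = {
        "config_sha256": hashlib.sha256(
            config.canonical_json().encode()).hexdigest(),
        "config": json.loads(config.canonical_json()),
        "input_digests": {str(p): _sha256(p) for p in input_files},
        "output_digests": {name: _sha256(out / name) for name in artifacts},
        "master_seed": config.seed,
        "version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return out
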