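"""Dietary exposure engine.

Deterministic per-individual estimated daily intake (EDI = concentration x
consumption / body weight, ng/kg bw/d), maximum-likelihood fitting of
positive-support distributions with AIC model selection, Monte Carlo
population exposure simulation, and rank-regression contribution-to-variance
sensitivity analysis.

Consumption is modeled as zero-inflated: a point mass at zero (probability
``1 - consumer_probability``) mixed with a fitted positive-support amount
distribution; the parametric families never see zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .dataio import (
    AnalyteClass,
    ConcentrationRecord,
    Subgroup,
    SurveyIndividual,
)

__all__ = [
    "DistributionFit",
    "FitSelection",
    "ExposureSummary",
    "SensitivityResult",
    "DegenerateDataError",
    "point_mass",
    "edi",
    "fit_distribution",
    "simulate_exposure",
    "empirical_exposure",
    "contribution_to_variance",
    "consumption_model",
]

DEFAULT_FAMILIES = ("lognormal", "gamma", "weibull")
_SCIPY_FAMILY = {
    "lognormal": stats.lognorm,
    "gamma": stats.gamma,
    "weibull": stats.weibull_min,
}
#: Parameters estimated per family (shape + scale; location fixed at 0).
_N_PARAMS = {"lognormal": 2, "gamma": 2, "weibull": 2}

DEFAULT_ITERATIONS = 10_000
_MIN_ITERATIONS = 1000
_N_BATCHES = 20


class DegenerateDataError(ValueError):
    """Constant data: parametric fitting refused; use a point mass."""

    def __init__(self, value: float):
        super().__init__(f"data is constant at {value}; fitting refused")
        self.value = value


@dataclass(frozen=True)
class DistributionFit:
    """A fitted positive-support distribution (or a degenerate point mass).

    ``params`` follows scipy's ``(shape, loc, scale)`` convention for the
    parametric families and holds ``(value,)`` for ``family="point"``.
    """

    family: str
    params: tuple[float, ...]
    loglik: float
    aic: float
    n: int

    def __post_init__(self) -> None:
        if self.family == "point":
            if len(self.params) != 1 or self.params[0] < 0:
                raise ValueError("point mass needs one non-negative value")
            return
        if self.family not in _SCIPY_FAMILY:
            raise ValueError(f"unknown family {self.family!r}")
        expected_aic = 2 * _N_PARAMS[self.family] - 2 * self.loglik
        if not math.isclose(self.aic, expected_aic, rel_tol=1e-9, abs_tol=1e-6):
            raise ValueError("AIC inconsistent with log-likelihood")
        shape, loc, scale = self.params
        if loc != 0 or scale <= 0 or shape <= 0:
            raise ValueError("invalid positive-support parameters")

    @classmethod
    def from_params(cls, family: str, shape: float,
                    scale: float) -> "DistributionFit":
        """Fit object from known parameters (no data attached)."""
        k = _N_PARAMS[family]
        return cls(family, (float(shape), 0.0, float(scale)),
                   loglik=0.0, aic=2.0 * k, n=0)

    def frozen(self):
        if self.family == "point":
            raise ValueError("point mass has no scipy counterpart")
        return _SCIPY_FAMILY[self.family](*self.params)

    def mean(self) -> float:
        if self.family == "point":
            return self.params[0]
        return float(self.frozen().mean())

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "point":
            return np.full(size, self.params[0])
        dist = self.frozen()
        return np.asarray(dist.ppf(rng.random(size)))


def point_mass(value: float) -> DistributionFit:
    """Degenerate distribution concentrated at ``value``."""
    return DistributionFit("point", (float(value),), math.nan, math.nan, 0)


@dataclass(frozen=True)
class FitSelection:
    """Minimum-AIC fit plus every candidate family's fit."""

    best: DistributionFit
    candidates: tuple[DistributionFit, ...]


def fit_distribution(
    values: Sequence[float],
    families: Sequence[str] = DEFAULT_FAMILIES,
) -> FitSelection:
    """Maximum-likelihood fit of each family; selection by minimum AIC.

    Requires >= 10 strictly positive values (model zeros through the
    consumer-probability mass instead). Location is fixed at 0.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 10:
        raise ValueError(f"need >= 10 values to fit, got {len(x)}")
    if (x <= 0).any() or not np.isfinite(x).all():
        raise ValueError("values must be strictly positive and finite")
    if np.ptp(x) == 0:
        raise DegenerateDataError(float(x[0]))
    if not families:
        raise ValueError("no candidate families")

    candidates = []
    for family in families:
        dist = _SCIPY_FAMILY[family]
        params = dist.fit(x, floc=0)
        loglik = float(dist.logpdf(x, *params).sum())
        candidates.append(
            DistributionFit(
                family=family,
                params=tuple(float(p) for p in params),
                loglik=loglik,
                aic=2 * _N_PARAMS[family] - 2 * loglik,
                n=len(x),
            )
        )
    best = min(candidates, key=lambda f: f.aic)
    return FitSelection(best=best, candidates=tuple(candidates))


@dataclass(frozen=True)
class ExposureSummary:
    """Mean, 95% CI half-width and P95 of EDI for one stratum (ng/kg bw/d)."""

    subgroup: str
    analyte_class: Optional[AnalyteClass]
    mean: float
    ci_half_width: float
    p95: float
    n_iterations: int
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mean < 0 or self.p95 < 0 or self.ci_half_width < 0:
            raise ValueError("exposure statistics must be non-negative")


def edi(c: float, f: float, bw: float):
    """Estimated daily intake: concentration (ng/g) x consumption (g/d) /
    body weight (kg), in ng/kg bw/d. Vectorizes over array inputs."""
    c = np.asarray(c, dtype=float)
    f = np.asarray(f, dtype=float)
    bw = np.asarray(bw, dtype=float)
    if (bw <= 0).any():
        raise ValueError("body weight must be > 0")
    if (c < 0).any() or (f < 0).any():
        raise ValueError("concentration and consumption must be >= 0")
    out = c * f / bw
    return float(out) if out.ndim == 0 else out


ConsumptionModel = tuple[float, Optional[DistributionFit]]


def _p95(values: np.ndarray) -> float:
    # linear interpolation between order statistics ("type 7")
    return float(np.percentile(values, 95.0, method="linear"))


def simulate_exposure(
    conc_fit: DistributionFit,
    cons_model: ConsumptionModel,
    bw_fit: DistributionFit,
    n_iter: int = DEFAULT_ITERATIONS,
    seed: Optional[int] = None,
    subgroup: str = "All",
    analyte_class: Optional[AnalyteClass] = None,
    return_draws: bool = False,
):
    """Monte Carlo exposure simulation over independent (c, f, bw) draws.

    ``cons_model = (consumer_probability, amount_fit)``: each iterate
    consumes with the given probability, drawing the amount from
    ``amount_fit`` (``None`` is allowed only when the probability is 0).
    The 95% CI half-width of the mean uses batch means over 20 equal
    batches: ``1.96 * sd(batch means) / sqrt(20)``.

    With ``return_draws=True`` returns ``(summary, draws)`` where ``draws``
    maps ``concentration``/``consumption``/``body_weight``/``edi`` to the
    iterate vectors (for sensitivity analysis).
    """
    if n_iter < _MIN_ITERATIONS:
        raise ValueError(
            f"n_iter must be >= {_MIN_ITERATIONS} for a stable P95"
        )
    consumer_probability, amount_fit = cons_model
    if not 0.0 <= consumer_probability <= 1.0:
        raise ValueError("consumer probability must be in [0, 1]")
    if amount_fit is None and consumer_probability > 0:
        raise ValueError("amount fit required when consumer probability > 0")

    rng = np.random.default_rng(seed)
    c = conc_fit.sample(rng, n_iter)
    if consumer_probability == 0.0:
        f = np.zeros(n_iter)
    else:
        amounts = amount_fit.sample(rng, n_iter)
        consuming = (
            np.ones(n_iter, dtype=bool)
            if consumer_probability == 1.0
            else rng.random(n_iter) < consumer_probability
        )
        f = np.where(consuming, amounts, 0.0)
    bw = bw_fit.sample(rng, n_iter)

    iterates = edi(c, f, bw)
    batch = iterates[: (n_iter // _N_BATCHES) * _N_BATCHES].reshape(
        _N_BATCHES, -1
    )
    batch_means = batch.mean(axis=1)
    spread = float(batch_means.std(ddof=1))
    summary = ExposureSummary(
        subgroup=subgroup,
        analyte_class=analyte_class,
        mean=float(iterates.mean()),
        ci_half_width=1.96 * spread / math.sqrt(_N_BATCHES),
        p95=_p95(iterates),
        n_iterations=n_iter,
        seed=seed,
    )
    if return_draws:
        draws = {
            "concentration": c,
            "consumption": f,
            "body_weight": bw,
            "edi": iterates,
        }
        return summary, draws
    return summary


def empirical_exposure(
    records: Sequence[ConcentrationRecord],
    individuals: Sequence[SurveyIndividual],
    subgroup: Optional[Subgroup] = None,
    pairing: str = "resample",
    analyte_class: AnalyteClass = AnalyteClass.SCCP,
    seed: Optional[int] = None,
    consumer_rule: str = "all_days",
) -> ExposureSummary:
    """Nonparametric exposure over the surveyed individuals.

    Each individual contributes EDI with consumption equal to their mean
    over recall days and concentration either resampled from the empirical
    class-total set (``pairing="resample"``) or set to the pooled mean
    (``pairing="point"``). The empirical (consumption, body weight) joint
    per individual is always preserved.
    """
    if not records:
        raise ValueError("no concentration records")
    members = [
        ind for ind in individuals
        if subgroup is None or subgroup.matches(ind, consumer_rule)
    ]
    if not members:
        raise ValueError("empty subgroup")

    totals = np.array([r.class_total(analyte_class) for r in records])
    f = np.array([ind.mean_consumption for ind in members])
    bw = np.array([ind.body_weight for ind in members])
    if pairing == "point":
        c = np.full(len(members), totals.mean())
    elif pairing == "resample":
        rng = np.random.default_rng(seed)
        c = rng.choice(totals, size=len(members), replace=True)
    else:
        raise ValueError(f"unknown pairing {pairing!r}")

    exposures = edi(c, f, bw)
    n = len(exposures)
    sd = float(exposures.std(ddof=1)) if n > 1 else 0.0
    return ExposureSummary(
        subgroup=subgroup.label if subgroup else "All",
        analyte_class=analyte_class,
        mean=float(exposures.mean()),
        ci_half_width=1.96 * sd / math.sqrt(n),
        p95=_p95(exposures),
        n_iterations=n,
        seed=seed,
    )


@dataclass(frozen=True)
class SensitivityResult:
    """Rank-regression contribution-to-variance shares, in percent."""

    contributions: dict[str, float]
    r_squared: float
    constant_inputs: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name, value in self.contributions.items():
            if not -1e-9 <= value <= 100.0 + 1e-9:
                raise ValueError(f"{name}: contribution {value} outside [0, 100]")
        if sum(self.contributions.values()) > 100.0 + 1e-6:
            raise ValueError("contributions exceed 100%")


def contribution_to_variance(
    input_draws: Mapping[str, np.ndarray],
    output_draws: np.ndarray,
) -> SensitivityResult:
    """Apportion output variance among simulation inputs by rank regression.

    All vectors are rank-transformed and standardized; the output is
    regressed on the inputs by OLS, and each input's share is
    ``100 * (beta_i^2 / sum_j beta_j^2) * R^2``. Constant inputs get a zero
    share and are flagged. This approximates spreadsheet-style
    "contribution to variance" sensitivity metrics.
    """
    output = np.asarray(output_draws, dtype=float)
    n = len(output)
    if n < 3:
        raise ValueError("need at least 3 draws")
    names = list(input_draws)
    constant = [
        name for name in names
        if np.ptp(np.asarray(input_draws[name], dtype=float)) == 0
    ]
    active = [name for name in names if name not in constant]

    if np.ptp(output) == 0 or not active:
        return SensitivityResult(
            contributions={name: 0.0 for name in names},
            r_squared=0.0,
            constant_inputs=frozenset(constant),
        )

    def standardized_ranks(v: np.ndarray) -> np.ndarray:
        r = stats.rankdata(v)
        return (r - r.mean()) / r.std(ddof=0)

    y = standardized_ranks(output)
    X = np.column_stack(
        [standardized_ranks(np.asarray(input_draws[name], dtype=float))
         for name in active]
    )
    beta, *_ = np.linalg.lstsq(
        np.column_stack([np.ones(n), X]), y, rcond=None
    )
    beta = beta[1:]  # drop intercept
    fitted = X @ beta
    ss_res = float(((y - fitted - (y - fitted).mean()) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r_squared = max(0.0, min(1.0, 1.0 - ss_res / ss_tot))

    beta_sq = beta ** 2
    total = beta_sq.sum()
    contributions = {name: 0.0 for name in names}
    if total > 0:
        for name, b2 in zip(active, beta_sq):
            contributions[name] = float(100.0 * (b2 / total) * r_squared)
    return SensitivityResult(
        contributions=contributions,
        r_squared=r_squared,
        constant_inputs=frozenset(constant),
    )


def consumption_model(
    individuals: Iterable[SurveyIndividual],
    families: Sequence[str] = DEFAULT_FAMILIES,
) -> ConsumptionModel:
    """Zero-inflated consumption model from survey recall days.

    The consumer probability is the fraction of all recall days with
    positive consumption; amounts on consuming days feed the parametric
    fit. Fewer than 10 positive amounts (or constant amounts) fall back to
    a point mass at their mean.
    """
    positive: list[float] = []
    n_days = 0
    for ind in individuals:
        n_days += len(ind.recall_consumptions)
        positive.extend(c for c in ind.recall_consumptions if c > 0)
    if n_days == 0:
        raise ValueError("no recall days in subgroup")
    probability = len(positive) / n_days
    if not positive:
        return 0.0, None
    try:
        fit = fit_distribution(positive, families).best
    except (DegenerateDataError, ValueError):
        fit = point_mass(float(np.mean(positive)))
    return probability, fit
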