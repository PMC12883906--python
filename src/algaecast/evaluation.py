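"""Forecast verification and production analysis.

Implements the verification toolkit for the forecasting system: CRPS for
ensemble weather forecasts, confusion-matrix accuracy for strategy selection,
occurrence probabilities of winning strategies, a balanced two-way ANOVA
variance partition (strain x depth x year), the coefficient of variation, and
baseline-vs-alternative production comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decision import Strategy
from .errors import DataError, DomainError

logger = logging.getLogger(__name__)


def crps(members, observation: float) -> float:
    """Continuous Ranked Probability Score of an ensemble against one value.

    The integral of (F - H)^2 — forecast empirical CDF versus the observation
    step function — evaluated in closed form:
    mean|X_i - x| - 0.5 * mean_{i,j} |X_i - X_j|.
    Units follow the forecast variable; 0 is a perfect forecast.
    """
    x = np.asarray(members, dtype=float)
    if x.size == 0:
        raise DataError("empty ensemble")
    if not (np.all(np.isfinite(x)) and np.isfinite(observation)):
        raise DataError("CRPS requires finite values")
    term1 = np.mean(np.abs(x - observation))
    term2 = 0.5 * np.mean(np.abs(x[:, None] - x[None, :]))
    return float(term1 - term2)


def mean_monthly_crps(
    forecasts: dict[tuple[int, int], np.ndarray],
    observations: dict[tuple[int, int], np.ndarray],
) -> pd.Series:
    """Mean CRPS per calendar month for daily ensemble forecasts.

    ``forecasts[(year, month)]`` is an (n_members, n_days) array of member
    daily values; ``observations[(year, month)]`` the matching observed daily
    values.  CRPS is computed per day and averaged within each calendar month
    across all years present; calendar months with no data are omitted with a
    warning.
    """
    per_month: dict[int, list[float]] = {}
    for (year, month), fc in forecasts.items():
        if (year, month) not in observations:
            continue
        fc = np.asarray(fc, dtype=float)
        obs = np.asarray(observations[(year, month)], dtype=float)
        if fc.ndim != 2 or fc.shape[1] != obs.shape[0]:
            raise DataError(
                f"{year}-{month:02d}: forecast shape {fc.shape} does not match "
                f"{obs.shape[0]} observed days"
            )
        daily = [crps(fc[:, d], obs[d]) for d in range(obs.shape[0])]
        per_month.setdefault(month, []).extend(daily)
    missing = [m for m in range(1, 13) if m not in per_month]
    if missing:
        logger.warning("mean_monthly_crps: no data for months %s", missing)
    return pd.Series(
        {m: float(np.mean(v)) for m, v in sorted(per_month.items())}, name="crps"
    )


@dataclass
class ConfusionMatrix:
    """Counts of (forecast strategy x true strategy) over evaluated months."""

    labels: list[str]
    counts: np.ndarray  # shape (n_labels, n_labels), rows = forecast

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.labels), len(self.labels)):
            raise DataError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise DataError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


def _strategy_label(s) -> str:
    return s.label if isinstance(s, Strategy) else str(s)


def confusion_and_accuracy(selected, optimal):
    """Confusion matrix plus total and strain-only selection accuracies.

    ``selected`` and ``optimal`` are aligned per-month lists of
    :class:`~algaecast.decision.Strategy` (or labels ``"strain-depth"``).
    Total accuracy is the diagonal fraction; strain-only accuracy counts a
    month as correct whenever the strain matches regardless of depth.
    """
    if len(selected) != len(optimal):
        raise DataError("selected and optimal lists differ in length")
    if len(selected) == 0:
        raise DataError("no months to evaluate")
    sel_labels = [_strategy_label(s) for s in selected]
    opt_labels = [_strategy_label(s) for s in optimal]
    labels = sorted(set(sel_labels) | set(opt_labels))
    pos = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    strain_hits = 0
    for s_lab, o_lab in zip(sel_labels, opt_labels):
        counts[pos[s_lab], pos[o_lab]] += 1
        if s_lab.rsplit("-", 1)[0] == o_lab.rsplit("-", 1)[0]:
            strain_hits += 1
    matrix = ConfusionMatrix(labels, counts)
    total_accuracy = float(np.trace(counts)) / len(selected)
    strain_only_accuracy = strain_hits / len(selected)
    return matrix, total_accuracy, strain_only_accuracy


def occurrence_probability(winners) -> dict[str, float]:
    """Fraction of years in which each strategy was the top producer."""
    labels = [_strategy_label(w) for w in winners]
    if not labels:
        raise DataError("no winners supplied")
    out: dict[str, float] = {}
    for lab in labels:
        out[lab] = out.get(lab, 0.0) + 1.0
    n = len(labels)
    return {lab: c / n for lab, c in out.items()}


@dataclass
class VariancePartition:
    """Share of total sum of squares by factor; shares sum to one."""

    ratio_strain: float
    ratio_depth: float
    ratio_interaction: float
    ratio_residual: float

    def __post_init__(self):
        ratios = [self.ratio_strain, self.ratio_depth, self.ratio_interaction,
                  self.ratio_residual]
        if any(r < -1e-12 or r > 1 + 1e-12 for r in ratios):
            raise DataError("variance ratios must lie in [0, 1]")
        if abs(sum(ratios) - 1.0) > 1e-10:
            raise DataError("variance ratios must sum to 1")


def anova_partition(Y) -> VariancePartition:
    """Balanced two-way ANOVA variance partition of production.

    ``Y`` has shape (n_strains, n_depths, n_years): replicated observations of
    production for each strain-depth cell across years.  The classical sums
    of squares SS_strain, SS_depth, SS_interaction, SS_residual are divided by
    the total sum of squares.  Requires >= 2 replicates per cell and
    non-constant data.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 3:
        raise DataError("Y must be a (strain, depth, year) array (balanced design)")
    a, b, n = Y.shape
    if n < 2:
        raise DataError("need at least 2 replicate years per cell")
    if not np.all(np.isfinite(Y)):
        raise DataError("Y must be finite (unbalanced/missing cells not supported)")
    grand = Y.mean()
    ss_total = float(((Y - grand) ** 2).sum())
    if ss_total == 0.0:
        raise DomainError("constant data: variance partition undefined")
    mean_i = Y.mean(axis=(1, 2))
    mean_j = Y.mean(axis=(0, 2))
    mean_ij = Y.mean(axis=2)
    ss_a = b * n * float(((mean_i - grand) ** 2).sum())
    ss_b = a * n * float(((mean_j - grand) ** 2).sum())
    ss_ab = n * float(
        ((mean_ij - mean_i[:, None] - mean_j[None, :] + grand) ** 2).sum()
    )
    ss_e = float(((Y - mean_ij[:, :, None]) ** 2).sum())
    return VariancePartition(
        ratio_strain=ss_a / ss_total,
        ratio_depth=ss_b / ss_total,
        ratio_interaction=ss_ab / ss_total,
        ratio_residual=ss_e / ss_total,
    )


def coefficient_of_variation(values) -> float:
    """Sample standard deviation divided by the mean (n >= 2, mean != 0)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DataError("need at least 2 values")
    mean = x.mean()
    if mean == 0.0:
        raise DomainError("zero mean: CV undefined")
    return float(x.std(ddof=1) / mean)


@dataclass
class ProductionComparison:
    """Month-by-month production of a baseline vs an alternative strategy.

    Percent differences are (alternative - baseline)/baseline * 100; the
    headline average difference is computed from the two average productions,
    not by averaging monthly percentages.
    """

    pairs: pd.DataFrame  # columns: baseline, alternative (g/m^2/day)
    monthly_pct_diff: pd.Series = field(init=False)
    baseline_avg: float = field(init=False)
    alternative_avg: float = field(init=False)
    avg_pct_diff: float = field(init=False)

    def __post_init__(self):
        base = self.pairs["baseline"]
        alt = self.pairs["alternative"]
        self.monthly_pct_diff = (alt - base) / base * 100.0
        self.baseline_avg = float(base.mean())
        self.alternative_avg = float(alt.mean())
        self.avg_pct_diff = (
            (self.alternative_avg - self.baseline_avg) / self.baseline_avg * 100.0
        )


def compare_production(baseline, alternative, index=None) -> ProductionComparison:
    """Build a :class:`ProductionComparison` from aligned monthly productions."""
    base = np.asarray(baseline, dtype=float)
    alt = np.asarray(alternative, dtype=float)
    if base.shape != alt.shape or base.ndim != 1 or base.size == 0:
        raise DataError("baseline and alternative must be aligned nonempty 1-D series")
    if np.any(base <= 0):
        raise DomainError("baseline productions must be positive")
    pairs = pd.DataFrame({"baseline": base, "alternative": alt},
                         index=index if index is not None else range(base.size))
    return ProductionComparison(pairs)
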