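"""Half-sector frequency estimation and replicate-level comparisons.

The per-division rate of silencing loss is estimated from plate tallies by

    rate = (# half-sectored colonies) / (# total colonies - # fully green colonies)

Fully green colonies are founded by cells that switched before their first
division on the plate and therefore carry no information about per-division
switching; they are removed from the denominator. Partially sectored colonies
are tallied but never enter the estimator.

Replicate plates (independent experiments) are summarized as mean +/- sample
standard deviation; strains are compared by fold-change of means (with a
delta-method standard error) and by a two-sided, equal-variance Student's t
test on the replicate frequencies. A percentile bootstrap over colonies within
replicates provides optional confidence intervals.

A small statsmodels-flavored surface is provided on top of the functional API:
``HalfSectorModel.from_dataframe(df).fit()`` returns a
:class:`HalfSectorResults` object carrying the estimate, its spread, optional
bootstrap interval and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import ensure_rng
from .errors import DegeneratePlateError, ParameterError

__all__ = [
    "SectorCounts",
    "RateEstimate",
    "FoldChange",
    "TTestResult",
    "half_sector_frequency",
    "summarize_replicates",
    "fold_change",
    "two_sample_t",
    "bootstrap_ci",
    "recover_rate",
    "HalfSectorModel",
    "HalfSectorResults",
]


@dataclass(frozen=True)
class SectorCounts:
    """Plate-level colony tallies for one replicate experiment.

    Only ``total_colonies``, ``half_sectored`` and ``fully_green`` enter the
    estimator; partial-sector and red tallies are informational.
    """

    total_colonies: int
    half_sectored: int
    fully_green: int
    replicate_id: str = ""
    partial_sectored: int | None = None
    red: int | None = None

    def __post_init__(self) -> None:
        for name in ("total_colonies", "half_sectored", "fully_green"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ParameterError(f"{name} must be a non-negative integer, got {v!r}")
        if self.half_sectored + self.fully_green > self.total_colonies:
            raise ParameterError(
                "half_sectored + fully_green exceeds total_colonies "
                f"({self.half_sectored} + {self.fully_green} > {self.total_colonies})"
            )
        if self.partial_sectored is not None and self.red is not None:
            parts = self.half_sectored + self.fully_green + self.partial_sectored + self.red
            if parts != self.total_colonies:
                raise ParameterError(
                    f"class tallies sum to {parts}, expected total_colonies={self.total_colonies}"
                )


@dataclass(frozen=True)
class RateEstimate:
    """Per-division switching-rate estimate over replicate experiments.

    ``sd`` is the sample (n-1) standard deviation of the replicate estimates,
    ``None`` when only one replicate is available. ``ci`` is an optional
    percentile-bootstrap interval ``(level, lower, upper)``.
    """

    replicate_estimates: tuple[float, ...]
    mean: float
    sd: float | None
    n_replicates: int
    ci: tuple[float, float, float] | None = None

    @property
    def estimate(self) -> float:
        return self.mean


@dataclass(frozen=True)
class FoldChange:
    """Ratio of two rate means, with a delta-method standard error."""

    ratio: float
    se: float | None


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    df: int
    degenerate: bool = False


def half_sector_frequency(counts: SectorCounts) -> float:
    """Per-division switching rate from one plate tally (the printed formula)."""
    denom = counts.total_colonies - counts.fully_green
    if denom <= 0:
        raise DegeneratePlateError(
            f"total - fully_green = {denom}; no informative colonies on this plate"
        )
    return counts.half_sectored / denom


def summarize_replicates(estimates: Sequence[float]) -> RateEstimate:
    """Mean and sample SD of replicate frequencies (SD undefined for n=1)."""
    est = tuple(float(x) for x in estimates)
    if len(est) == 0:
        raise ParameterError("at least one replicate estimate is required")
    arr = np.asarray(est, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else None
    return RateEstimate(replicate_estimates=est, mean=float(arr.mean()), sd=sd, n_replicates=arr.size)


def fold_change(numerator: RateEstimate, denominator: RateEstimate) -> FoldChange:
    """Ratio of means, with SE propagated by the first-order delta method."""
    if denominator.mean <= 0:
        raise ParameterError("denominator mean must be > 0 for a fold-change")
    ratio = numerator.mean / denominator.mean
    se = None
    if numerator.sd is not None and denominator.sd is not None and numerator.mean > 0:
        rel_a = (numerator.sd / math.sqrt(numerator.n_replicates)) / numerator.mean
        rel_b = (denominator.sd / math.sqrt(denominator.n_replicates)) / denominator.mean
        se = ratio * math.sqrt(rel_a**2 + rel_b**2)
    return FoldChange(ratio=ratio, se=se)


def two_sample_t(group_a: Sequence[float], group_b: Sequence[float]) -> TTestResult:
    """Two-sided, equal-variance Student's t test on replicate frequencies."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs >= 2 replicates for a t test")
    df = a.size + b.size - 2
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        # zero pooled variance: identical means -> no evidence; different means
        # -> infinitely strong evidence, flagged as degenerate
        if a.mean() == b.mean():
            return TTestResult(statistic=0.0, pvalue=1.0, df=df, degenerate=True)
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return TTestResult(statistic=sign * math.inf, pvalue=0.0, df=df, degenerate=True)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(statistic=float(t), pvalue=float(p), df=df)


def bootstrap_ci(
    counts: Sequence[SectorCounts],
    seed: int | np.random.Generator,
    n_boot: int = 2000,
    level: float = 0.95,
) -> tuple[float, float, float]:
    """Percentile bootstrap of the mean rate, resampling colonies within replicates.

    Each resample redraws every plate's (half, fully green, other) tally from a
    multinomial at the observed proportions, re-applies the estimator per
    replicate, and averages across replicates.
    """
    if not counts:
        raise ParameterError("at least one replicate is required")
    if not (0 < level < 1):
        raise ParameterError("level must be in (0, 1)")
    rng = ensure_rng(seed)
    means = np.empty(n_boot)
    probs = [
        (
            c.total_colonies,
            np.array([c.half_sectored, c.fully_green, c.total_colonies - c.half_sectored - c.fully_green])
            / c.total_colonies,
        )
        for c in counts
    ]
    for i in range(n_boot):
        reps = []
        for total, p in probs:
            half, full, _ = rng.multinomial(total, p)
            denom = total - full
            reps.append(half / denom if denom > 0 else np.nan)
        means[i] = np.nanmean(reps)
    lo, hi = np.nanquantile(means, [(1 - level) / 2, 1 - (1 - level) / 2])
    return (level, float(lo), float(hi))


def recover_rate(
    params,
    n_colonies: int,
    n_replicates: int,
    seed: int | np.random.Generator,
    method: str = "thinned",
    ci: bool = False,
    n_boot: int = 2000,
) -> RateEstimate:
    """Simulation + estimation round trip.

    Simulates ``n_replicates`` independent colony populations under ``params``
    and applies the half-sector estimator to each, returning the replicate
    summary (optionally with a bootstrap CI).
    """
    from . import colony  # late import: colony builds SectorCounts from here

    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    rng = ensure_rng(seed)
    tallies = [
        colony.simulate_population(params, n_colonies, rng, method=method, replicate_id=f"rep{i + 1}")
        for i in range(n_replicates)
    ]
    est = summarize_replicates([half_sector_frequency(c) for c in tallies])
    if ci:
        interval = bootstrap_ci(tallies, rng, n_boot=n_boot)
        est = RateEstimate(
            replicate_estimates=est.replicate_estimates,
            mean=est.mean,
            sd=est.sd,
            n_replicates=est.n_replicates,
            ci=interval,
        )
    return est


# ---------------------------------------------------------------------------
# model / results surface


class HalfSectorModel:
    """Half-sector rate model over replicate plate tallies.

    Parameters
    ----------
    counts : sequence of SectorCounts
        One entry per independent experiment (replicate).
    name : str
        Label for summaries (e.g. a strain name).
    """

    def __init__(self, counts: Sequence[SectorCounts], name: str = ""):
        counts = list(counts)
        if not counts:
            raise ParameterError("at least one replicate of counts is required")
        self.counts = counts
        self.name = name

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, name: str = "") -> "HalfSectorModel":
        """Build from a table with columns replicate_id, total_colonies,
        half_sectored, fully_green."""
        required = {"replicate_id", "total_colonies", "half_sectored", "fully_green"}
        missing = required - set(df.columns)
        if missing:
            raise ParameterError(f"missing column(s): {sorted(missing)}")
        counts = [
            SectorCounts(
                total_colonies=int(r.total_colonies),
                half_sectored=int(r.half_sectored),
                fully_green=int(r.fully_green),
                replicate_id=str(r.replicate_id),
            )
            for r in df.itertuples()
        ]
        return cls(counts, name=name)

    @classmethod
    def from_csv(cls, path, name: str = "") -> "HalfSectorModel":
        return cls.from_dataframe(pd.read_csv(path, comment="#"), name=name)

    def fit(
        self,
        bootstrap: int = 0,
        level: float = 0.95,
        seed: int | np.random.Generator | None = None,
    ) -> "HalfSectorResults":
        """Estimate the per-division rate; ``bootstrap > 0`` adds a percentile CI."""
        est = summarize_replicates([half_sector_frequency(c) for c in self.counts])
        if bootstrap > 0:
            if seed is None:
                raise ParameterError("bootstrap requires an explicit seed")
            interval = bootstrap_ci(self.counts, seed, n_boot=bootstrap, level=level)
            est = RateEstimate(
                replicate_estimates=est.replicate_estimates,
                mean=est.mean,
                sd=est.sd,
                n_replicates=est.n_replicates,
                ci=interval,
            )
        return HalfSectorResults(self, est)


class HalfSectorResults:
    """Fitted half-sector rate with replicate spread and comparisons."""

    def __init__(self, model: HalfSectorModel, estimate: RateEstimate):
        self.model = model
        self.rate_estimate = estimate

    @property
    def rate(self) -> float:
        return self.rate_estimate.mean

    @property
    def sd(self) -> float | None:
        return self.rate_estimate.sd

    def conf_int(self) -> tuple[float, float] | None:
        if self.rate_estimate.ci is None:
            return None
        _, lo, hi = self.rate_estimate.ci
        return (lo, hi)

    def compare(self, other: "HalfSectorResults") -> dict:
        """Fold-change (self / other) and Student's t test on replicates."""
        fc = fold_change(self.rate_estimate, other.rate_estimate)
        tt = two_sample_t(self.rate_estimate.replicate_estimates, other.rate_estimate.replicate_estimates)
        return {
            "fold": fc.ratio,
            "fold_se": fc.se,
            "t": tt.statistic,
            "p": tt.pvalue,
            "df": tt.df,
            "degenerate": tt.degenerate,
        }

    def summary(self) -> str:
        e = self.rate_estimate
        lines = [
            "Half-sector rate estimate" + (f" [{self.model.name}]" if self.model.name else ""),
            "=" * 50,
            f"{'replicates':<28}{e.n_replicates}",
            f"{'rate (per division)':<28}{e.mean:.4g}",
            f"{'sd (replicates)':<28}{'--' if e.sd is None else format(e.sd, '.3g')}",
        ]
        if e.ci is not None:
            level, lo, hi = e.ci
            lines.append(f"{f'{level * 100:.0f}% bootstrap CI':<28}[{lo:.4g}, {hi:.4g}]")
        for c, r in zip(self.model.counts, e.replicate_estimates):
            rid = c.replicate_id or "?"
            lines.append(
                f"  {rid:<12} total={c.total_colonies:<8} half={c.half_sectored:<6} "
                f"green={c.fully_green:<6} rate={r:.4g}"
            )
        lines.append("=" * 50)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<HalfSectorResults rate={self.rate:.4g} n={self.rate_estimate.n_replicates}>"
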