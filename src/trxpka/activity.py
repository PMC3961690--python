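"""Replicate densitometry statistics and relative in vivo activities.

Gel densitometry of heme-stained cytochrome cd1 bands measures how much
functional DsbD a strain carries: each experiment grows the variant and the
wild type in triplicate, and the variant's activity is expressed as a
percentage of the wild type's mean reading within the same dataset.

Conventions implemented here:

- replicate summary: arithmetic mean, sample SD (n-1 denominator), and the
  percentage standard error ``100 * (sd / sqrt(n)) / mean``;
- per-dataset relative activity: ``100 * mean_variant / mean_wild_type``
  with uncertainty propagated in quadrature from the relative sample SDs,
  ``percent * sqrt((sd_v/mean_v)**2 + (sd_wt/mean_wt)**2)``;
- cross-dataset average: unweighted mean of the per-dataset percentages
  with uncertainty ``sqrt(sum(u_i**2)) / n`` (independent per-dataset
  errors propagated through the mean).

Values are kept unrounded internally; display rounding (integers, half away
from zero) lives in :mod:`trxpka.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ReplicateSet",
    "ReplicateSummary",
    "RelativeActivity",
    "summarize_replicates",
    "relative_activity",
    "average_relative_activity",
]


@dataclass(frozen=True)
class ReplicateSet:
    """Raw densitometry peak heights for one construct in one dataset."""

    construct_label: str
    dataset_label: str
    readings: tuple[float, ...]

    def __post_init__(self) -> None:
        readings = tuple(float(r) for r in self.readings)
        if len(readings) < 2:
            raise ValueError("at least 2 replicate readings are required")
        if any(not math.isfinite(r) or r <= 0 for r in readings):
            raise ValueError("all readings must be finite and > 0")
        object.__setattr__(self, "readings", readings)


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean, sample SD, percentage standard error, and count of a replicate set."""

    mean: float
    sd: float
    pct_se: float
    n: int
    construct_label: str = ""
    dataset_label: str = ""

    @property
    def rel_sd(self) -> float:
        """Relative sample standard deviation (dimensionless)."""
        return self.sd / self.mean


@dataclass(frozen=True)
class RelativeActivity:
    """Activity as a percentage of wild type, with propagated uncertainty."""

    percent: float
    uncertainty: float
    level: Literal["per_dataset", "average"]
    construct_label: str = ""
    dataset_label: str = ""

    def __post_init__(self) -> None:
        if self.percent <= 0:
            raise ValueError("percent must be > 0")
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be >= 0")


def summarize_replicates(replicates: ReplicateSet) -> ReplicateSummary:
    """Mean, sample SD and percentage standard error of one replicate set."""
    x = np.asarray(replicates.readings, dtype=float)
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    pct_se = 100.0 * (sd / math.sqrt(len(x))) / mean
    return ReplicateSummary(
        mean=mean,
        sd=sd,
        pct_se=pct_se,
        n=len(x),
        construct_label=replicates.construct_label,
        dataset_label=replicates.dataset_label,
    )


def relative_activity(
    variant: ReplicateSummary, wild_type: ReplicateSummary
) -> RelativeActivity:
    """Variant activity as a percentage of wild type within one dataset.

    Both summaries must come from the same dataset; labels are checked when
    both are present.  Uncertainty is the quadrature sum of the two relative
    sample SDs, scaled by the percentage.
    """
    if (
        variant.dataset_label
        and wild_type.dataset_label
        and variant.dataset_label != wild_type.dataset_label
    ):
        raise ValueError(
            f"dataset labels differ: {variant.dataset_label!r} vs "
            f"{wild_type.dataset_label!r}"
        )
    if wild_type.mean == 0:
        raise ValueError("wild-type mean must be nonzero")
    percent = 100.0 * variant.mean / wild_type.mean
    uncertainty = percent * math.hypot(variant.rel_sd, wild_type.rel_sd)
    return RelativeActivity(
        percent=percent,
        uncertainty=uncertainty,
        level="per_dataset",
        construct_label=variant.construct_label,
        dataset_label=variant.dataset_label,
    )


def average_relative_activity(
    per_dataset: Sequence[RelativeActivity],
) -> RelativeActivity:
    """Average the per-dataset relative activities across experiments.

    Unweighted mean of the percentages; the uncertainty treats the
    per-dataset errors as independent and propagates them through the mean,
    ``sqrt(sum(u_i**2)) / n``.
    """
    if len(per_dataset) == 0:
        raise ValueError("at least one per-dataset relative activity is required")
    if any(r.level != "per_dataset" for r in per_dataset):
        raise ValueError("inputs must all be per-dataset relative activities")
    percents = [r.percent for r in per_dataset]
    n = len(percents)
    percent = sum(percents) / n
    uncertainty = math.sqrt(sum(r.uncertainty**2 for r in per_dataset)) / n
    label = per_dataset[0].construct_label
    return RelativeActivity(
        percent=percent,
        uncertainty=uncertainty,
        level="average",
        construct_label=label,
    )
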