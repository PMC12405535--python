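"""Sample-level QC gates, barcode-level filters, and recovery metrics.

Three gates protect the FOR statistic:

* outgrowth gate — linear fit of the positive-control barcodes'
  +spectinomycin vs -spectinomycin normalised read fractions; rejects
  samples with high outgrowth variability (r^2 and slope thresholds);
* abundance filter — drops barcodes below a minimum fraction of the
  -spectinomycin culture's reads (default 1/5000), where counts reflect
  only tens of cells at the culture split;
* fold-change gate — requires a minimum separation (geometric-mean OR
  ratio, default > 30) between positive and negative control strains.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

from scipy import stats

if TYPE_CHECKING:
    from .assigner import BarcodeSensorMap
    from .for_quant import NormalizationContext, NormalizationSet, ScreenSample

logger = logging.getLogger(__name__)

__all__ = [
    "QCConfig",
    "QCReport",
    "abundance_filter",
    "outgrowth_fit",
    "fold_change_check",
    "recovered_fraction",
    "cfu_after_split_dilution",
]


@dataclass(frozen=True)
class QCConfig:
    min_r2: float = 0.6
    slope_range: tuple[float, float] = (0.5, 2.0)
    min_abundance_fraction: float = 1.0 / 5000.0
    min_positive_reads: int = 100
    min_fold_change: float = 30.0

    def __post_init__(self) -> None:
        if (
            self.min_r2 <= 0
            or self.min_abundance_fraction <= 0
            or self.min_positive_reads <= 0
            or self.min_fold_change <= 0
        ):
            raise ValueError("QC thresholds must be positive")
        if self.slope_range[0] >= self.slope_range[1]:
            raise ValueError("slope_range lower bound must be below upper bound")


@dataclass
class QCReport:
    sample_id: str
    outgrowth_slope: float
    outgrowth_r2: float
    outgrowth_pass: bool
    n_kept: int
    n_total: int
    fold_change: float
    fold_change_pass: bool
    fold_change_reason: str | None = None
    excluded_positive_barcodes: list[str] = field(default_factory=list)

    @property
    def overall_pass(self) -> bool:
        """A sample passes iff both the outgrowth and fold-change gates pass."""
        return self.outgrowth_pass and self.fold_change_pass


def abundance_filter(sample: "ScreenSample", config: QCConfig | None = None) -> set[str]:
    """Barcodes whose -spectinomycin read fraction strictly exceeds the floor."""
    config = config or QCConfig()
    total = sample.total_minus
    if total <= 0:
        raise ValueError(f"sample {sample.sample_id!r}: no -spectinomycin reads")
    return {
        bc
        for bc, n in sample.counts_minus.items()
        if n / total > config.min_abundance_fraction
    }


def _usable_positive_barcodes(sample, positives, config) -> list[str]:
    # Accept either a resolved NormalizationContext or a raw NormalizationSet.
    if hasattr(positives, "usable_positive_barcodes"):
        return list(positives.usable_positive_barcodes)
    return [
        bc
        for bc in positives.positive_barcodes
        if sample.counts_plus.get(bc, 0) >= config.min_positive_reads
        and sample.counts_minus.get(bc, 0) >= config.min_positive_reads
    ]


def outgrowth_fit(
    sample: "ScreenSample",
    positives: "NormalizationSet | NormalizationContext",
    config: QCConfig | None = None,
) -> tuple[float, float, bool]:
    """Outgrowth-variability gate.

    OLS fit of +spectinomycin read fraction against -spectinomycin read
    fraction across the positive-control barcodes (both fractions rescaled
    by their means so a well-behaved sample sits on the identity line).
    Passes iff r^2 > min_r2 and slope inside slope_range.
    """
    config = config or QCConfig()
    usable = _usable_positive_barcodes(sample, positives, config)
    if len(usable) < 3:
        raise ValueError(
            f"sample {sample.sample_id!r}: only {len(usable)} usable positive "
            "barcodes; need >= 3 for the outgrowth fit"
        )
    total_plus = sample.total_plus
    total_minus = sample.total_minus
    if total_plus <= 0 or total_minus <= 0:
        raise ValueError(f"sample {sample.sample_id!r}: a culture has no reads")
    y = [sample.counts_plus[bc] / total_plus for bc in usable]
    x = [sample.counts_minus[bc] / total_minus for bc in usable]
    mean_x = sum(x) / len(x)
    mean_y = sum(y) / len(y)
    x = [v / mean_x for v in x]
    y = [v / mean_y for v in y]
    fit = stats.linregress(x, y)
    r2 = fit.rvalue**2
    passed = bool(
        r2 > config.min_r2
        and config.slope_range[0] < fit.slope < config.slope_range[1]
    )
    return float(fit.slope), float(r2), passed


def _geometric_mean(values: list[float]) -> float | None:
    usable = [v for v in values if v > 0]
    if not usable:
        return None
    return math.exp(sum(math.log(v) for v in usable) / len(usable))


def fold_change_check(
    sample: "ScreenSample",
    ctx: "NormalizationContext",
    config: QCConfig | None = None,
) -> tuple[float, bool, str | None]:
    """Fold-change gate: geometric-mean positive OR over negative OR.

    Zero or undefined ORs are excluded from either geometric mean; if a side
    has none usable the sample fails with reason "insufficient difference
    between positive and negative strains".
    """
    from .for_quant import compute_odds_ratio

    config = config or QCConfig()

    def _ors(barcodes: list[str]) -> list[float]:
        out = []
        for bc in barcodes:
            r = compute_odds_ratio(
                sample.counts_plus.get(bc, 0),
                sample.counts_minus.get(bc, 0),
                ctx.pnb_plus,
                ctx.pnb_minus,
            )
            if r is not None:
                out.append(r)
        return out

    pos = _geometric_mean(_ors(ctx.usable_positive_barcodes))
    neg = _geometric_mean(_ors(ctx.negative_barcodes))
    if pos is None or neg is None:
        return (
            math.nan,
            False,
            "insufficient difference between positive and negative strains",
        )
    fc = pos / neg
    return fc, bool(fc > config.min_fold_change), None


def recovered_fraction(
    sample: "ScreenSample",
    bc_map: "BarcodeSensorMap",
    min_reads: int = 1,
) -> tuple[float, float]:
    """Fractions of assigned barcodes and sensors seen in the -SPECT culture.

    A barcode counts as recovered with at least ``min_reads`` reads; a sensor
    counts as recovered when any of its barcodes is.
    """
    assigned = sorted(bc_map.assignments)
    if not assigned:
        raise ValueError("barcode-sensor map is empty")
    recovered = {
        bc for bc in assigned if sample.counts_minus.get(bc, 0) >= min_reads
    }
    sensors = bc_map.sensors
    recovered_sensors = {bc_map.assignments[bc] for bc in recovered}
    return len(recovered) / len(assigned), len(recovered_sensors) / len(sensors)


def cfu_after_split_dilution(
    culture_cfu_per_ml: float,
    abundance_fraction: float,
    dilution_factor: float = 1000.0,
) -> float:
    """CFU/mL of one strain after diluting the mixed culture into the split.

    E.g. a strain at 1/5000 of a 1e8 CFU/mL stationary culture, diluted
    1:1000 into the paired cultures, is present at 20 CFU/mL — the rationale
    for the abundance floor.
    """
    if culture_cfu_per_ml < 0 or not 0 <= abundance_fraction <= 1:
        raise ValueError("invalid culture density or abundance fraction")
    if dilution_factor < 1:
        raise ValueError("dilution factor must be >= 1")
    return culture_cfu_per_ml * abundance_fraction / dilution_factor
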