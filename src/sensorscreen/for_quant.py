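"""Odds-ratio and fractional-odds-ratio (FOR) quantification.

For each barcode in a sample split into +spectinomycin and -spectinomycin
cultures:

    OR = (BC_plus / mean(PNB_plus)) / (BC_minus / mean(PNB_minus))

where PNB are the positive-normalisation barcode counts. The FOR linearly
rescales OR between the negative-control anchor (~0, fully OFF) and the
positive-control anchor (~1, fully ON):

    FOR = (OR - OR_neg) / (OR_pos - OR_neg)

OR_pos / OR_neg are arithmetic means of the control-strain ORs. FOR is the
population ON-fraction under the bacteriostatic selection model and is
reported unclipped.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .assigner import BarcodeSensorMap

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenSample",
    "NormalizationSet",
    "NormalizationContext",
    "FORRecord",
    "compute_odds_ratio",
    "compute_for",
    "classify_activation",
    "aggregate_sensor_for",
    "build_normalization_context",
    "quantify_sample",
]


@dataclass
class ScreenSample:
    """Per-barcode read counts from one sample's paired cultures."""

    sample_id: str
    condition: str
    counts_plus: dict[str, int]
    counts_minus: dict[str, int]

    def __post_init__(self) -> None:
        universe = set(self.counts_plus) | set(self.counts_minus)
        for bc in universe:
            self.counts_plus.setdefault(bc, 0)
            self.counts_minus.setdefault(bc, 0)
        if any(v < 0 for v in self.counts_plus.values()) or any(
            v < 0 for v in self.counts_minus.values()
        ):
            raise ValueError(f"sample {self.sample_id!r}: negative read counts")

    @property
    def barcodes(self) -> set[str]:
        return set(self.counts_plus)

    @property
    def total_plus(self) -> float:
        return float(sum(self.counts_plus.values()))

    @property
    def total_minus(self) -> float:
        return float(sum(self.counts_minus.values()))


@dataclass(frozen=True)
class NormalizationSet:
    """Control strains used to anchor the FOR scale."""

    positive_barcodes: tuple[str, ...]
    negative_sensor: str

    def negative_barcodes(self, bc_map: BarcodeSensorMap) -> list[str]:
        return bc_map.barcodes_of(self.negative_sensor)


@dataclass
class NormalizationContext:
    """Sample-level normalisation state shared by all OR/FOR computations."""

    usable_positive_barcodes: list[str]
    excluded_positive_barcodes: list[str]
    pnb_plus: list[int]
    pnb_minus: list[int]
    or_pos: float
    or_neg: float
    negative_barcodes: list[str]


@dataclass
class FORRecord:
    key: str  # barcode_id or sensor_id
    odds_ratio: float | None  # None when undefined (zero -SPECT reads)
    fractional_odds_ratio: float | None
    qc_pass: bool
    n_barcodes: int = 1


def compute_odds_ratio(
    bc_plus: float,
    bc_minus: float,
    pnb_plus: Sequence[float],
    pnb_minus: Sequence[float],
) -> float | None:
    """Positive-normalised +SPECT/-SPECT odds ratio for one barcode.

    Returns None (undefined) when ``bc_minus`` is zero; such barcodes are
    expected to fail the abundance QC. Raises if either PNB mean is zero —
    normalisation is then impossible for the whole sample.
    """
    if not pnb_plus or not pnb_minus:
        raise ValueError("positive normalisation barcode counts are required")
    mean_plus = statistics.fmean(pnb_plus)
    mean_minus = statistics.fmean(pnb_minus)
    if mean_plus <= 0 or mean_minus <= 0:
        raise ValueError("positive normalisation barcodes have zero mean counts")
    if bc_minus == 0:
        return None
    return (bc_plus / mean_plus) / (bc_minus / mean_minus)


def compute_for(or_sensor: float, or_pos: float, or_neg: float) -> float:
    """Rescale an odds ratio between the control anchors; not clipped."""
    if or_pos <= or_neg:
        raise ValueError(
            f"positive anchor ({or_pos}) must exceed negative anchor ({or_neg})"
        )
    return (or_sensor - or_neg) / (or_pos - or_neg)


def classify_activation(for_value: float, threshold: float = 0.01) -> str:
    """'activated' iff the FOR is strictly greater than the threshold."""
    return "activated" if for_value > threshold else "not_activated"


def build_normalization_context(
    sample: ScreenSample,
    norm: NormalizationSet,
    bc_map: BarcodeSensorMap,
    min_positive_reads: int = 100,
) -> NormalizationContext:
    """Resolve control barcodes and anchors for one sample.

    Positive barcodes with fewer than ``min_positive_reads`` reads in either
    culture are excluded before anything else. OR_pos / OR_neg are arithmetic
    means over the usable control barcodes' ORs (undefined ORs skipped).
    """
    excluded = [
        bc
        for bc in norm.positive_barcodes
        if sample.counts_plus.get(bc, 0) < min_positive_reads
        or sample.counts_minus.get(bc, 0) < min_positive_reads
    ]
    usable = [bc for bc in norm.positive_barcodes if bc not in excluded]
    if len(usable) < 2:
        raise ValueError(
            f"sample {sample.sample_id!r}: only {len(usable)} usable positive "
            f"normalisation barcodes after the {min_positive_reads}-read exclusion"
        )
    pnb_plus = [sample.counts_plus[bc] for bc in usable]
    pnb_minus = [sample.counts_minus[bc] for bc in usable]

    pos_ors = [
        r
        for bc in usable
        if (
            r := compute_odds_ratio(
                sample.counts_plus[bc], sample.counts_minus[bc], pnb_plus, pnb_minus
            )
        )
        is not None
    ]
    neg_barcodes = norm.negative_barcodes(bc_map)
    neg_ors = [
        r
        for bc in neg_barcodes
        if (
            r := compute_odds_ratio(
                sample.counts_plus.get(bc, 0),
                sample.counts_minus.get(bc, 0),
                pnb_plus,
                pnb_minus,
            )
        )
        is not None
    ]
    if not neg_ors:
        raise ValueError(
            f"sample {sample.sample_id!r}: no usable negative-control barcode"
        )
    return NormalizationContext(
        usable_positive_barcodes=usable,
        excluded_positive_barcodes=excluded,
        pnb_plus=pnb_plus,
        pnb_minus=pnb_minus,
        or_pos=statistics.fmean(pos_ors),
        or_neg=statistics.fmean(neg_ors),
        negative_barcodes=neg_barcodes,
    )


def barcode_for_record(
    barcode_id: str,
    sample: ScreenSample,
    ctx: NormalizationContext,
    qc_pass: bool = True,
) -> FORRecord:
    odds = compute_odds_ratio(
        sample.counts_plus.get(barcode_id, 0),
        sample.counts_minus.get(barcode_id, 0),
        ctx.pnb_plus,
        ctx.pnb_minus,
    )
    fractional = (
        compute_for(odds, ctx.or_pos, ctx.or_neg) if odds is not None else None
    )
    return FORRecord(
        key=barcode_id,
        odds_ratio=odds,
        fractional_odds_ratio=fractional,
        qc_pass=qc_pass and odds is not None,
    )


def aggregate_sensor_for(
    sensor_id: str,
    records: Sequence[FORRecord],
    mode: str,
    sample: ScreenSample,
    bc_map: BarcodeSensorMap,
    ctx: NormalizationContext,
) -> FORRecord:
    """Sensor-level FOR from its barcodes.

    ``median`` takes the median of the QC-passing barcode FORs. ``pooled``
    sums the sensor's barcode counts in both cultures and recomputes OR/FOR
    on the pooled counts (the treatment used for high-barcode-count
    libraries). A sensor with no usable data is returned with qc_pass=False
    (the screen's "insufficient data" marker).
    """
    if mode not in ("median", "pooled"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    if mode == "median":
        values = [
            r.fractional_odds_ratio
            for r in records
            if r.qc_pass and r.fractional_odds_ratio is not None
        ]
        if not values:
            return FORRecord(sensor_id, None, None, False, n_barcodes=0)
        odds = [r.odds_ratio for r in records if r.qc_pass and r.odds_ratio is not None]
        return FORRecord(
            key=sensor_id,
            odds_ratio=statistics.median(odds) if odds else None,
            fractional_odds_ratio=statistics.median(values),
            qc_pass=True,
            n_barcodes=len(values),
        )
    barcodes = bc_map.barcodes_of(sensor_id)
    pooled_plus = sum(sample.counts_plus.get(bc, 0) for bc in barcodes)
    pooled_minus = sum(sample.counts_minus.get(bc, 0) for bc in barcodes)
    if pooled_plus + pooled_minus == 0:
        return FORRecord(sensor_id, None, None, False, n_barcodes=0)
    odds = compute_odds_ratio(pooled_plus, pooled_minus, ctx.pnb_plus, ctx.pnb_minus)
    fractional = (
        compute_for(odds, ctx.or_pos, ctx.or_neg) if odds is not None else None
    )
    return FORRecord(
        key=sensor_id,
        odds_ratio=odds,
        fractional_odds_ratio=fractional,
        qc_pass=odds is not None,
        n_barcodes=len(barcodes),
    )


def quantify_sample(
    sample: ScreenSample,
    bc_map: BarcodeSensorMap,
    norm: NormalizationSet,
    mode: str = "median",
    qc_config=None,
) -> tuple[pd.DataFrame, pd.DataFrame, "object"]:
    """Full per-sample quantification with the QC gate sequence.

    Order: positive-barcode read exclusion -> outgrowth gate -> abundance
    filter -> OR/FOR -> fold-change gate -> sensor aggregation. Returns
    (barcode table, sensor table, QCReport). Sample-level gate failures are
    recorded on the report and propagate into per-row ``sample_qc_pass``.
    """
    from .qc import QCConfig, abundance_filter, fold_change_check, outgrowth_fit

    config = qc_config or QCConfig()
    ctx = build_normalization_context(
        sample, norm, bc_map, min_positive_reads=config.min_positive_reads
    )
    slope, r2, outgrowth_pass = outgrowth_fit(sample, ctx, config)
    kept = abundance_filter(sample, config)

    assigned = sorted(bc_map.assignments)
    records: dict[str, FORRecord] = {}
    for bc in assigned:
        records[bc] = barcode_for_record(bc, sample, ctx, qc_pass=bc in kept)
    fc, fc_pass, fc_reason = fold_change_check(sample, ctx, config)
    sample_pass = bool(outgrowth_pass and fc_pass)

    barcode_rows = [
        {
            "barcode_id": bc,
            "sensor_id": bc_map.sensor_of(bc),
            "reads_plus": sample.counts_plus.get(bc, 0),
            "reads_minus": sample.counts_minus.get(bc, 0),
            "odds_ratio": rec.odds_ratio,
            "fractional_odds_ratio": rec.fractional_odds_ratio,
            "qc_pass": rec.qc_pass,
            "sample_qc_pass": sample_pass,
        }
        for bc, rec in records.items()
    ]
    sensor_rows = []
    for sensor_id in sorted(bc_map.sensors):
        sensor_records = [
            records[bc] for bc in bc_map.barcodes_of(sensor_id) if bc in records
        ]
        agg = aggregate_sensor_for(sensor_id, sensor_records, mode, sample, bc_map, ctx)
        sensor_rows.append(
            {
                "sensor_id": sensor_id,
                "odds_ratio": agg.odds_ratio,
                "fractional_odds_ratio": agg.fractional_odds_ratio,
                "n_barcodes": agg.n_barcodes,
                "qc_pass": agg.qc_pass,
                "sample_qc_pass": sample_pass,
            }
        )

    from .qc import QCReport

    report = QCReport(
        sample_id=sample.sample_id,
        outgrowth_slope=slope,
        outgrowth_r2=r2,
        outgrowth_pass=outgrowth_pass,
        n_kept=len(kept),
        n_total=len(sample.barcodes),
        fold_change=fc,
        fold_change_pass=fc_pass,
        fold_change_reason=fc_reason,
        excluded_positive_barcodes=list(ctx.excluded_positive_barcodes),
    )
    return pd.DataFrame(barcode_rows), pd.DataFrame(sensor_rows), report
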