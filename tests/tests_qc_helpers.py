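"""Constructed-sample builders shared by the QC unit and acceptance tests."""

from sensorscreen.assigner import BarcodeSensorMap
from sensorscreen.for_quant import (
    NormalizationSet,
    ScreenSample,
    build_normalization_context,
)


def build_positives_sample(minus_counts, plus_counts, extra=None):
    positives = tuple(f"P{i}" for i in range(len(minus_counts)))
    counts_minus = dict(zip(positives, minus_counts))
    counts_plus = dict(zip(positives, plus_counts))
    for bc, (p, m) in (extra or {}).items():
        counts_plus[bc] = p
        counts_minus[bc] = m
    sample = ScreenSample("s", "c", counts_plus, counts_minus)
    return sample, NormalizationSet(positive_barcodes=positives, negative_sensor="NEG")


def build_fc_context(neg_plus):
    """Three clean positives (OR 1) and one negative at OR = neg_plus/1000."""
    sample, norm = build_positives_sample(
        [1000, 1000, 1000], [1000, 1000, 1000], extra={"n1": (neg_plus, 1000)}
    )
    bc_map = BarcodeSensorMap(
        assignments={"P0": "POS", "P1": "POS", "P2": "POS", "n1": "NEG"},
        discarded=[],
    )
    ctx = build_normalization_context(sample, norm, bc_map)
    return sample, ctx
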