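"""Synthetic screening experiments with known ground truth.

Generates barcoded sensor libraries (log-normal barcode multiplicity and
abundance, mutually dissimilar 106-bp barcodes), simulates induction and
paired +/-spectinomycin outgrowth under a bacteriostatic selection model,
draws multinomial sequencing reads with configurable per-base error (low for
short reads; substitutions plus geometric indels for long reads), and models
colonisation bottlenecks.

Growth model: spectinomycin is bacteriostatic, so OFF cells persist without
replicating while ON cells grow by the outgrowth fold change G. The
+spectinomycin relative abundance of a strain with ON-fraction f is
proportional to a * (f*G + (1 - f)); the -spectinomycin culture preserves
composition. Hence the expected odds ratio is f + (1 - f)/G and the expected
FOR is exactly f.

All randomness flows from ``SimConfig.seed``; identical configs reproduce
identical outputs byte-for-byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alignment import identity_upper_bound, pairwise_identity
from .assigner import NANOPORE_ADAPTER, BarcodeSensorMap
from .for_quant import NormalizationSet, ScreenSample
from .tcs_miner import GeneRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_library",
    "simulate_screen_counts",
    "simulate_reads",
    "simulate_bottleneck",
    "simulate_experiment",
    "random_dna",
    "mutate_sequence",
    "write_fastq",
    "generate_annotated_genome",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Knobs for one synthetic screen; see module docstring for the model."""

    n_sensors: int = 20
    n_positive_sensors: int = 3  # constitutively ON normalisation sensors
    barcodes_per_sensor_median: float = 5.0
    barcodes_per_sensor_sigma: float = 0.6
    max_barcodes_per_sensor: int = 1000
    abundance_sigma: float = 1.0
    outgrowth_fold_change: float = 1000.0
    read_depth: int = 200_000
    short_read_error_rate: float = 0.002
    long_read_error_rate: float = 0.07
    long_read_indel_fraction: float = 0.3  # of long-read errors, this many are indels
    long_reads_per_barcode: int = 10
    barcode_length: int = 106
    sensor_length: int = 600
    adapter: str = NANOPORE_ADAPTER
    max_barcode_identity: float = 0.80
    lag_sigma: float = 0.0  # per-barcode outgrowth (lag-phase) heterogeneity
    # condition -> ON-fraction spec for the variable sensors: a scalar, a
    # {sensor_id: f} mapping, or None for a uniform random draw per sensor.
    true_on_fraction: Mapping[str, object] = field(
        default_factory=lambda: {"control": None}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.short_read_error_rate <= 1:
            raise ValueError("short_read_error_rate must be in [0, 1]")
        if not 0 <= self.long_read_error_rate <= 1:
            raise ValueError("long_read_error_rate must be in [0, 1]")
        if self.outgrowth_fold_change <= 1:
            raise ValueError("outgrowth_fold_change must be > 1")
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")
        if self.n_positive_sensors + 1 > self.n_sensors:
            raise ValueError("need at least one variable sensor beyond the controls")


@dataclass
class GroundTruth:
    """Everything the simulator knows and downstream modules must recover."""

    barcodes: dict[str, str]  # barcode_id -> sequence
    bc_to_sensor: dict[str, str]
    abundance: dict[str, float]  # sums to 1
    sensor_refs: dict[str, str]
    positive_sensors: list[str]
    negative_sensor: str
    on_fraction: dict[str, dict[str, float]]  # condition -> sensor -> f

    @property
    def sensors(self) -> list[str]:
        return sorted(self.sensor_refs)

    def true_map(self) -> BarcodeSensorMap:
        return BarcodeSensorMap(assignments=dict(self.bc_to_sensor), discarded=[])

    def normalization_set(self) -> NormalizationSet:
        positives = tuple(
            bc
            for bc, s in sorted(self.bc_to_sensor.items())
            if s in self.positive_sensors
        )
        return NormalizationSet(
            positive_barcodes=positives, negative_sensor=self.negative_sensor
        )


def random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _draw_barcode(
    rng: np.random.Generator,
    accepted: list[str],
    length: int,
    max_identity: float,
    max_attempts: int = 200,
) -> str:
    """Rejection-sample a barcode mutually < max_identity to all accepted."""
    for _ in range(max_attempts):
        candidate = random_dna(rng, length)
        ok = True
        for other in accepted:
            # score-only bound prunes nearly every full-identity computation
            if identity_upper_bound(candidate, other) < max_identity:
                continue
            if pairwise_identity(candidate, other) >= max_identity:
                ok = False
                break
        if ok:
            return candidate
    raise RuntimeError(
        f"failed to sample a barcode below {max_identity:.0%} identity "
        f"after {max_attempts} attempts"
    )


def _resolve_on_fraction(
    spec: object,
    variable_sensors: Sequence[str],
    rng: np.random.Generator,
) -> dict[str, float]:
    if spec is None:
        values = rng.uniform(0.0, 1.0, size=len(variable_sensors))
        return dict(zip(variable_sensors, values.tolist()))
    if isinstance(spec, (int, float)):
        return {s: float(spec) for s in variable_sensors}
    if isinstance(spec, Mapping):
        out = {}
        for s in variable_sensors:
            if s not in spec:
                raise ValueError(f"on-fraction spec missing sensor {s!r}")
            out[s] = float(spec[s])
        return out
    raise TypeError(f"unsupported on-fraction spec: {type(spec).__name__}")


def generate_library(
    config: SimConfig, rng: np.random.Generator | None = None
) -> GroundTruth:
    """Sample a barcoded sensor library with ground truth.

    Sensors ``S001..`` — the first ``n_positive_sensors`` are constitutively
    ON (f = 1 in every condition), the next one is the constitutively OFF
    negative control (f = 0); the rest take f from
    ``config.true_on_fraction``. Barcode counts per sensor are log-normal
    around the configured median (clipped to [1, max]); barcode abundances
    are log-normal and normalised to sum to 1. Barcodes are mutually below
    ``max_barcode_identity`` by rejection sampling.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    width = max(3, len(str(config.n_sensors)))
    sensors = [f"S{i + 1:0{width}d}" for i in range(config.n_sensors)]
    positive = sensors[: config.n_positive_sensors]
    negative = sensors[config.n_positive_sensors]
    variable = sensors[config.n_positive_sensors + 1 :]

    sensor_refs = {s: random_dna(rng, config.sensor_length) for s in sensors}

    mu = np.log(config.barcodes_per_sensor_median)
    n_bc = np.clip(
        np.rint(
            np.exp(rng.normal(mu, config.barcodes_per_sensor_sigma, len(sensors)))
        ).astype(int),
        1,
        config.max_barcodes_per_sensor,
    )

    barcodes: dict[str, str] = {}
    bc_to_sensor: dict[str, str] = {}
    accepted: list[str] = []
    idx = 0
    for sensor, count in zip(sensors, n_bc):
        for _ in range(int(count)):
            idx += 1
            seq = _draw_barcode(
                rng, accepted, config.barcode_length, config.max_barcode_identity
            )
            accepted.append(seq)
            bc_id = f"BC{idx:05d}"
            barcodes[bc_id] = seq
            bc_to_sensor[bc_id] = sensor

    raw = np.exp(rng.normal(0.0, config.abundance_sigma, len(barcodes)))
    abundance = dict(zip(sorted(barcodes), (raw / raw.sum()).tolist()))

    on_fraction: dict[str, dict[str, float]] = {}
    for condition, spec in config.true_on_fraction.items():
        f = _resolve_on_fraction(spec, variable, rng)
        f.update({s: 1.0 for s in positive})
        f[negative] = 0.0
        on_fraction[condition] = f

    return GroundTruth(
        barcodes=barcodes,
        bc_to_sensor=bc_to_sensor,
        abundance=abundance,
        sensor_refs=sensor_refs,
        positive_sensors=positive,
        negative_sensor=negative,
        on_fraction=on_fraction,
    )


def simulate_screen_counts(
    truth: GroundTruth,
    condition: str,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    noiseless: bool = False,
    sample_id: str | None = None,
    surviving_barcodes: set[str] | None = None,
) -> ScreenSample:
    """Counts for one sample's paired cultures under the selection model.

    ``noiseless`` emits expected (float) counts instead of multinomial
    draws. ``surviving_barcodes`` restricts the library (bottleneck
    survivors). Optional lag-phase heterogeneity multiplies each barcode's
    weight in each culture by an independent log-normal factor.
    """
    if condition not in truth.on_fraction:
        raise ValueError(f"condition {condition!r} has no configured ON-fractions")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    f_by_sensor = truth.on_fraction[condition]
    ids = sorted(truth.barcodes)
    if surviving_barcodes is not None:
        ids = [bc for bc in ids if bc in surviving_barcodes]
        if not ids:
            raise ValueError("no barcodes survive the bottleneck")
    a = np.array([truth.abundance[bc] for bc in ids])
    f = np.array([f_by_sensor[truth.bc_to_sensor[bc]] for bc in ids])
    G = config.outgrowth_fold_change

    minus_w = a.copy()
    plus_w = a * (f * G + (1.0 - f))
    if config.lag_sigma > 0:
        minus_w = minus_w * np.exp(rng.normal(0.0, config.lag_sigma, len(ids)))
        plus_w = plus_w * np.exp(rng.normal(0.0, config.lag_sigma, len(ids)))
    minus_p = minus_w / minus_w.sum()
    plus_p = plus_w / plus_w.sum()

    if noiseless:
        minus_counts = config.read_depth * minus_p
        plus_counts = config.read_depth * plus_p
    else:
        minus_counts = rng.multinomial(config.read_depth, minus_p)
        plus_counts = rng.multinomial(config.read_depth, plus_p)

    return ScreenSample(
        sample_id=sample_id or f"sim-{condition}",
        condition=condition,
        counts_plus=dict(zip(ids, plus_counts.tolist())),
        counts_minus=dict(zip(ids, minus_counts.tolist())),
    )


def mutate_sequence(
    seq: str,
    sub_rate: float,
    rng: np.random.Generator,
    indel_rate: float = 0.0,
    indel_extension: float = 0.5,
) -> str:
    """Apply i.i.d. substitutions and geometric-length indels to a sequence."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    if sub_rate > 0:
        hits = np.nonzero(rng.random(arr.size) < sub_rate)[0]
        if hits.size:
            # shift by 1..3 positions in base space => always a different base
            idx = np.searchsorted(_BASES, arr[hits])
            arr[hits] = _BASES[(idx + rng.integers(1, 4, hits.size)) % 4]
    if indel_rate <= 0:
        return arr.tobytes().decode()
    n_events = rng.binomial(arr.size, indel_rate)
    if n_events == 0:
        return arr.tobytes().decode()
    positions = np.sort(rng.integers(0, arr.size, n_events))[::-1]
    out = arr.tobytes()
    for pos in positions.tolist():
        length = int(rng.geometric(1.0 - indel_extension))
        if rng.random() < 0.5:  # insertion
            insert = _BASES[rng.integers(0, 4, length)].tobytes()
            out = out[:pos] + insert + out[pos:]
        else:  # deletion
            out = out[:pos] + out[pos + length :]
    return out.decode()


def simulate_reads(
    truth: GroundTruth,
    sample: ScreenSample,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Short barcode-amplicon reads plus sensor-spanning long reads.

    Short reads reproduce the sample's per-culture counts exactly (one read
    per counted molecule, substitution errors only). Long reads are
    adapter + sensor + barcode + adapter concatenations with substitutions
    and indels, ``long_reads_per_barcode`` per library barcode.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    short_reads: list[tuple[str, str]] = []
    for culture, counts in (("plus", sample.counts_plus), ("minus", sample.counts_minus)):
        for bc in sorted(counts):
            n = counts[bc]
            if n != int(n):
                raise ValueError("simulate_reads requires integer counts")
            seq = truth.barcodes[bc]
            for i in range(int(n)):
                short_reads.append(
                    (
                        f"{sample.sample_id}:{culture}:{bc}:{i}",
                        mutate_sequence(seq, config.short_read_error_rate, rng),
                    )
                )

    e = config.long_read_error_rate
    sub_rate = e * (1.0 - config.long_read_indel_fraction)
    indel_rate = e * config.long_read_indel_fraction
    long_reads: list[tuple[str, str]] = []
    for bc in sorted(truth.barcodes):
        sensor = truth.bc_to_sensor[bc]
        template = (
            config.adapter
            + truth.sensor_refs[sensor]
            + truth.barcodes[bc]
            + config.adapter
        )
        for i in range(config.long_reads_per_barcode):
            long_reads.append(
                (
                    f"long:{bc}:{i}",
                    mutate_sequence(template, sub_rate, rng, indel_rate=indel_rate),
                )
            )
    return short_reads, long_reads


def simulate_bottleneck(
    truth: GroundTruth,
    n_cells: int,
    rng: np.random.Generator | None = None,
    config: SimConfig | None = None,
) -> set[str]:
    """Barcodes surviving a multinomial bottleneck of ``n_cells`` cells."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    seed = config.seed if config is not None else 0
    rng = np.random.default_rng(seed) if rng is None else rng
    ids = sorted(truth.barcodes)
    p = np.array([truth.abundance[bc] for bc in ids])
    draws = rng.multinomial(n_cells, p / p.sum())
    return {bc for bc, n in zip(ids, draws.tolist()) if n > 0}


def simulate_experiment(
    config: SimConfig,
    noiseless: bool = False,
) -> tuple[GroundTruth, dict[str, ScreenSample]]:
    """Library plus one sample per configured condition, from a single seed."""
    rng = np.random.default_rng(config.seed)
    truth = generate_library(config, rng)
    samples = {
        condition: simulate_screen_counts(
            truth, condition, config, rng, noiseless=noiseless,
            sample_id=f"{condition}",
        )
        for condition in config.true_on_fraction
    }
    return truth, samples


def write_fastq(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) records as FASTQ with constant quality."""
    with open(path, "w") as fh:
        for read_id, seq in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Synthetic annotated genomes for exercising the grouped-TCS miner.
# ---------------------------------------------------------------------------


def generate_annotated_genome(
    rng: np.random.Generator,
    n_grouped: int = 3,
    n_decoys: int = 6,
    contig: str = "chr1",
    spacer: int = 6000,
) -> tuple[dict[str, str], list[GeneRecord], list[tuple[str, str, str]]]:
    """A random genome with planted grouped TCSs and decoy arrangements.

    Decoys cycle through: tandem neighbour (same strand), distant HK-RR pair
    (gap >= 200), opposite-strand HK/RR genes, and an isolated pair with no
    neighbour inside the search window. Blocks are separated by ``spacer``
    bp (> the 5 kb divergent-gene search window) so they cannot interact.
    Returns (genome, genes, expected (hk_id, rr_id, divergent_id) triples).
    """
    genes: list[GeneRecord] = []
    expected: list[tuple[str, str, str]] = []
    cursor = 1 + spacer
    counter = 0

    def new_id(prefix: str) -> str:
        nonlocal counter
        counter += 1
        return f"{prefix}{counter:03d}"

    def place(start: int, length: int, strand: str, role: str, prefix: str) -> GeneRecord:
        gene = GeneRecord(
            gene_id=new_id(prefix),
            contig=contig,
            start=start,
            end=start + length - 1,
            strand=strand,
            role=role,
        )
        genes.append(gene)
        return gene

    blocks = ["grouped"] * n_grouped + [
        ("tandem", "distant", "opposite", "isolated")[i % 4] for i in range(n_decoys)
    ]
    order = list(rng.permutation(len(blocks)))
    for which in (blocks[i] for i in order):
        div_len = int(rng.integers(300, 900))
        hk_len = int(rng.integers(900, 1500))
        rr_len = int(rng.integers(500, 800))
        intergenic = int(rng.integers(80, 400))
        pair_gap = int(rng.integers(0, 200))
        flip = bool(rng.random() < 0.5)  # pair on the minus strand, mirrored

        if which == "grouped":
            if not flip:
                div = place(cursor, div_len, "-", "other", "div")
                hk = place(div.end + 1 + intergenic, hk_len, "+", "HK", "hk")
                rr = place(hk.end + 1 + pair_gap, rr_len, "+", "RR", "rr")
                cursor = rr.end + 1 + spacer
            else:
                hk = place(cursor, hk_len, "-", "HK", "hk")
                rr = place(hk.end + 1 + pair_gap, rr_len, "-", "RR", "rr")
                div = place(rr.end + 1 + intergenic, div_len, "+", "other", "div")
                cursor = div.end + 1 + spacer
            expected.append((hk.gene_id, rr.gene_id, div.gene_id))
        elif which == "tandem":
            strand = "-" if flip else "+"
            if not flip:
                nb = place(cursor, div_len, "+", "other", "nb")
                hk = place(nb.end + 1 + intergenic, hk_len, strand, "HK", "hk")
                rr = place(hk.end + 1 + pair_gap, rr_len, strand, "RR", "rr")
                cursor = rr.end + 1 + spacer
            else:
                hk = place(cursor, hk_len, strand, "HK", "hk")
                rr = place(hk.end + 1 + pair_gap, rr_len, strand, "RR", "rr")
                nb = place(rr.end + 1 + intergenic, div_len, "-", "other", "nb")
                cursor = nb.end + 1 + spacer
        elif which == "distant":
            wide_gap = int(rng.integers(200, 1000))
            div = place(cursor, div_len, "-", "other", "div")
            hk = place(div.end + 1 + intergenic, hk_len, "+", "HK", "hk")
            rr = place(hk.end + 1 + wide_gap, rr_len, "+", "RR", "rr")
            cursor = rr.end + 1 + spacer
        elif which == "opposite":
            div = place(cursor, div_len, "-", "other", "div")
            hk = place(div.end + 1 + intergenic, hk_len, "+", "HK", "hk")
            rr = place(hk.end + 1 + pair_gap, rr_len, "-", "RR", "rr")
            cursor = rr.end + 1 + spacer
        else:  # isolated: valid pair, nothing upstream within the window
            strand = "-" if flip else "+"
            hk = place(cursor, hk_len, strand, "HK", "hk")
            rr = place(hk.end + 1 + pair_gap, rr_len, strand, "RR", "rr")
            cursor = rr.end + 1 + spacer

    genome_len = cursor + spacer
    genome = {contig: random_dna(rng, genome_len)}
    return genome, genes, expected
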