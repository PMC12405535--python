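"""Linking reference barcodes to sensors with spanning long reads.

Long reads are adapter-trimmed and length-filtered, placed on the best
sensor reference by semi-global alignment, and the read tail extending past
the reference 3' end is matched against the reference barcodes. A barcode is
assigned to a sensor only when that sensor wins both evidence criteria —
highest read count for the barcode AND highest sensor-normalised read
fraction — with at least ``min_reads`` supporting reads; disagreements and
thin evidence are discarded with a reason.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .alignment import infix_identity, kmer_set, overlap_align

logger = logging.getLogger(__name__)

__all__ = [
    "NANOPORE_ADAPTER",
    "LongReadEvidence",
    "Assignment",
    "BarcodeSensorMap",
    "preprocess_long_read",
    "SequenceIndex",
    "align_and_trim",
    "match_tail_to_barcode",
    "collect_evidence",
    "assign_barcode_to_sensor",
    "build_map",
]

#: Nanopore ligation adapter trimmed off long reads before alignment.
NANOPORE_ADAPTER = "CCTGTACTTCGTTCAGTTACGTATTGCT"


@dataclass
class LongReadEvidence:
    """Per-barcode long-read support, split by sensor."""

    barcode_id: str
    per_sensor_counts: dict[str, int] = field(default_factory=dict)
    per_sensor_totals: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class Assignment:
    barcode_id: str
    sensor_id: str | None
    status: str  # "assigned" or "discarded"
    reason: str | None = None  # ambiguous | insufficient_reads | no_alignment
    n_reads: int = 0


@dataclass
class BarcodeSensorMap:
    """Each barcode is either assigned to exactly one sensor or discarded."""

    assignments: dict[str, str]
    discarded: list[tuple[str, str]]  # (barcode_id, reason)

    def sensor_of(self, barcode_id: str) -> str | None:
        return self.assignments.get(barcode_id)

    @property
    def sensors(self) -> set[str]:
        return set(self.assignments.values())

    def barcodes_of(self, sensor_id: str) -> list[str]:
        return sorted(b for b, s in self.assignments.items() if s == sensor_id)


def _find_adapter(
    read: str,
    adapter: str,
    max_mismatch: int,
    min_match: int,
    search_window: int,
    leading: bool,
) -> int | None:
    """Locate an adapter occurrence near one end of the read.

    Occurrences may be truncated at the read boundary. The mismatch budget
    scales with the overlap (``max_mismatch`` applies to a full-length
    occurrence) and at least ``min_match`` bases must actually match, so
    short chance overlaps cannot trigger a trim. Returns the trim point
    (read index just past a leading adapter, or the start of a trailing
    adapter), or None.
    """
    la = len(adapter)
    n = len(read)
    best: int | None = None

    def allowed(overlap: int) -> int:
        return int(overlap * max_mismatch / la)

    if leading:
        # adapter may start before the read (offset < 0) or within the window
        for offset in range(-(la - min_match), min(search_window, n - min_match) + 1):
            a_seg = adapter[max(0, -offset) :]
            r_seg = read[max(0, offset) : max(0, offset) + len(a_seg)]
            overlap = min(len(a_seg), len(r_seg))
            if overlap < min_match:
                continue
            mism = sum(x != y for x, y in zip(a_seg[:overlap], r_seg[:overlap]))
            if mism <= allowed(overlap) and overlap - mism >= min_match:
                end = max(0, offset) + overlap
                if best is None or end > best:
                    best = end
        return best
    # trailing: adapter may run off the read 3' end
    for offset in range(max(0, n - search_window - la), n - min_match + 1):
        a_len = min(la, n - offset)
        if a_len < min_match:
            continue
        r_seg = read[offset : offset + a_len]
        mism = sum(x != y for x, y in zip(adapter[:a_len], r_seg))
        if mism <= allowed(a_len) and a_len - mism >= min_match:
            if best is None or offset < best:
                best = offset
    return best


def preprocess_long_read(
    read: str,
    adapter: str = NANOPORE_ADAPTER,
    max_mismatch: int = 5,
    min_length: int = 400,
    min_match: int = 10,
    search_window: int = 100,
) -> str | None:
    """Trim leading/trailing adapter occurrences and length-filter.

    Adapter occurrences allow up to ``max_mismatch`` substitutions with at
    least ``min_match`` bases matched, and are searched only near the read
    ends. Reads whose remaining length is not strictly greater than
    ``min_length`` are discarded (returns None).
    """
    if len(adapter) < 10:
        raise ValueError("adapter must be at least 10 bp")
    trimmed = read
    lead = _find_adapter(trimmed, adapter, max_mismatch, min_match, search_window, True)
    if lead is not None:
        trimmed = trimmed[lead:]
    trail = _find_adapter(trimmed, adapter, max_mismatch, min_match, search_window, False)
    if trail is not None:
        trimmed = trimmed[:trail]
    if len(trimmed) <= min_length:
        logger.debug("read discarded after trimming: length %d", len(trimmed))
        return None
    return trimmed


class SequenceIndex:
    """k-mer index over a set of named references, for candidate selection."""

    def __init__(self, refs: Mapping[str, str], k: int):
        self.refs = dict(refs)
        self.k = k
        self._kmer_to_refs: dict[str, list[str]] = defaultdict(list)
        for name, seq in self.refs.items():
            for kmer in kmer_set(seq, k):
                self._kmer_to_refs[kmer].append(name)

    def ranked(self, seq: str) -> list[tuple[str, int]]:
        """(name, shared k-mer count) pairs, best first."""
        hits: dict[str, int] = defaultdict(int)
        for kmer in kmer_set(seq, self.k):
            for name in self._kmer_to_refs.get(kmer, ()):
                hits[name] += 1
        return sorted(hits.items(), key=lambda kv: (-kv[1], kv[0]))

    def candidates(
        self, seq: str, top: int, min_hits: int, dominance: float = 0.0
    ) -> list[str]:
        """Reference names ranked by shared k-mer count (best first).

        With ``dominance`` > 0, returns only the best candidate when the
        runner-up has fewer than ``dominance * best`` shared k-mers — skips
        pointless alignments against clearly unrelated references.
        """
        ranked = [(name, n) for name, n in self.ranked(seq) if n >= min_hits]
        if (
            dominance > 0
            and len(ranked) > 1
            and ranked[1][1] < dominance * ranked[0][1]
        ):
            return [ranked[0][0]]
        return [name for name, _ in ranked[:top]]


def align_and_trim(
    read: str,
    sensor_refs: Mapping[str, str] | SequenceIndex,
    min_identity: float = 0.75,
    k: int = 11,
    max_candidates: int = 3,
    min_kmer_hits: int = 3,
) -> tuple[str, str] | None:
    """Place a trimmed long read on its best sensor reference.

    Returns ``(sensor_id, tail)`` where ``tail`` is the read suffix extending
    past the reference 3' end (empty when the read stops inside the
    reference), or None when no reference reaches ``min_identity`` or the
    best identity is tied between sensors.

    Passing a prebuilt :class:`SequenceIndex` avoids re-indexing per read.
    """
    index = (
        sensor_refs
        if isinstance(sensor_refs, SequenceIndex)
        else SequenceIndex(sensor_refs, k)
    )
    names = index.candidates(
        read, top=max_candidates, min_hits=min_kmer_hits, dominance=0.25
    )
    if not names:
        return None
    best_name: str | None = None
    best_hit = None
    tied = False
    for name in names:
        hit = overlap_align(read, index.refs[name])
        if hit is None:
            continue
        if best_hit is None or hit.identity > best_hit.identity + 1e-12:
            best_name, best_hit, tied = name, hit, False
        elif abs(hit.identity - best_hit.identity) <= 1e-12:
            tied = True
    if best_hit is None or tied or best_hit.identity < min_identity:
        return None
    ref_len = len(index.refs[best_name])
    tail = read[best_hit.read_end :] if best_hit.ref_end >= ref_len else ""
    return best_name, tail


def match_tail_to_barcode(
    tail: str,
    barcodes: Mapping[str, str] | SequenceIndex,
    min_identity: float = 0.80,
    k: int = 8,
    max_candidates: int = 5,
    min_kmer_hits: int = 2,
) -> str | None:
    """Match a trimmed read tail to its best reference barcode.

    Identity is computed over the barcode length (barcode global, tail end
    gaps free). Ties for best identity contribute no evidence.
    """
    if not tail:
        return None
    index = (
        barcodes if isinstance(barcodes, SequenceIndex) else SequenceIndex(barcodes, k)
    )
    names = index.candidates(tail, top=max_candidates, min_hits=min_kmer_hits)
    best_name: str | None = None
    best_identity = -1.0
    tied = False
    for name in names:
        identity = infix_identity(tail, index.refs[name])
        if identity > best_identity + 1e-12:
            best_name, best_identity, tied = name, identity, False
        elif abs(identity - best_identity) <= 1e-12:
            tied = True
    if best_name is None or tied or best_identity < min_identity:
        return None
    return best_name


def collect_evidence(
    long_reads: Iterable[str],
    sensor_refs: Mapping[str, str],
    barcodes: Mapping[str, str],
    adapter: str = NANOPORE_ADAPTER,
    min_identity: float = 0.75,
    barcode_min_identity: float = 0.80,
    min_length: int = 400,
    max_mismatch: int = 5,
) -> dict[str, LongReadEvidence]:
    """Run the long-read evidence pipeline over raw reads.

    ``per_sensor_totals`` counts every read placed on a sensor (before
    barcode matching); ``per_sensor_counts`` counts reads whose tail also
    matched the barcode.
    """
    sensor_index = SequenceIndex(sensor_refs, k=11)
    barcode_index = SequenceIndex(barcodes, k=8)
    totals: dict[str, int] = defaultdict(int)
    counts: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for raw in long_reads:
        read = preprocess_long_read(
            raw, adapter=adapter, max_mismatch=max_mismatch, min_length=min_length
        )
        if read is None:
            continue
        placed = align_and_trim(read, sensor_index, min_identity=min_identity)
        if placed is None:
            continue
        sensor_id, tail = placed
        totals[sensor_id] += 1
        barcode_id = match_tail_to_barcode(
            tail, barcode_index, min_identity=barcode_min_identity
        )
        if barcode_id is not None:
            counts[barcode_id][sensor_id] += 1

    evidence: dict[str, LongReadEvidence] = {}
    for barcode_id in barcodes:
        per_sensor = dict(counts.get(barcode_id, {}))
        evidence[barcode_id] = LongReadEvidence(
            barcode_id=barcode_id,
            per_sensor_counts=per_sensor,
            per_sensor_totals={s: totals[s] for s in per_sensor},
        )
    return evidence


def assign_barcode_to_sensor(
    evidence: LongReadEvidence, min_reads: int = 5
) -> Assignment:
    """Dual-criterion assignment of one barcode.

    The winning sensor must be the unique argmax of both the read count and
    the count normalised by the sensor's total reads, with at least
    ``min_reads`` reads; otherwise the barcode is discarded with a reason.
    """
    counts = evidence.per_sensor_counts
    if not counts or all(v == 0 for v in counts.values()):
        return Assignment(evidence.barcode_id, None, "discarded", "no_alignment")
    fractions: dict[str, float] = {}
    for sensor, n in counts.items():
        total = evidence.per_sensor_totals.get(sensor, 0)
        if n > 0 and total <= 0:
            raise ValueError(
                f"barcode {evidence.barcode_id!r}: sensor {sensor!r} has "
                f"{n} supporting reads but zero total reads"
            )
        if n > total:
            raise ValueError(
                f"barcode {evidence.barcode_id!r}: sensor {sensor!r} count "
                f"{n} exceeds total {total}"
            )
        fractions[sensor] = n / total if total else 0.0

    max_count = max(counts.values())
    count_winners = [s for s, n in counts.items() if n == max_count]
    max_frac = max(fractions.values())
    frac_winners = [s for s, f in fractions.items() if f == max_frac]
    if len(count_winners) != 1 or len(frac_winners) != 1:
        return Assignment(evidence.barcode_id, None, "discarded", "ambiguous")
    if count_winners[0] != frac_winners[0]:
        return Assignment(evidence.barcode_id, None, "discarded", "ambiguous")
    winner = count_winners[0]
    if counts[winner] < min_reads:
        return Assignment(
            evidence.barcode_id, None, "discarded", "insufficient_reads",
            n_reads=counts[winner],
        )
    return Assignment(
        evidence.barcode_id, winner, "assigned", n_reads=counts[winner]
    )


def build_map(
    evidence: Mapping[str, LongReadEvidence] | Sequence[LongReadEvidence],
    min_reads: int = 5,
) -> BarcodeSensorMap:
    """Assign every barcode, partitioning into assignments and discards."""
    items = (
        list(evidence.values()) if isinstance(evidence, Mapping) else list(evidence)
    )
    assignments: dict[str, str] = {}
    discarded: list[tuple[str, str]] = []
    for ev in items:
        result = assign_barcode_to_sensor(ev, min_reads=min_reads)
        if result.status == "assigned":
            assignments[result.barcode_id] = result.sensor_id
        else:
            discarded.append((result.barcode_id, result.reason))
    return BarcodeSensorMap(assignments=assignments, discarded=discarded)
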