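"""Reference-barcode calling from short-read amplicon data.

Reads are dereplicated, filtered to the expected barcode length (106 bp by
default), and greedily clustered at 95% global-alignment identity; each
cluster is represented by its highest-count exact sequence and carries the
summed counts of all members.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .alignment import (
    hamming_distance,
    identity_upper_bound,
    pairwise_identity,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BarcodeCluster",
    "dereplicate_and_filter",
    "pairwise_identity",
    "cluster_barcodes",
    "call_barcodes",
    "read_sequences",
]


@dataclass
class BarcodeCluster:
    """One 95%-identity barcode cluster.

    ``reference_sequence`` is the member with the highest read count;
    ``total_count`` is the sum over all members.
    """

    reference_sequence: str
    members: list[tuple[str, int]]
    total_count: int

    @property
    def n_members(self) -> int:
        return len(self.members)


def dereplicate_and_filter(
    reads: Iterable[str],
    expected_length: int = 106,
    min_count: int = 1,
) -> list[tuple[str, int]]:
    """Unique sequences of exactly ``expected_length`` with multiplicities.

    Sorted by descending count, ties broken lexicographically. ``min_count``
    can be raised to drop singletons (off by default).
    """
    counts = Counter(
        read for read in reads if len(read) == expected_length
    )
    uniques = [
        (seq, n) for seq, n in counts.items() if n >= min_count
    ]
    uniques.sort(key=lambda item: (-item[1], item[0]))
    return uniques


def cluster_barcodes(
    uniques: Sequence[tuple[str, int]],
    threshold: float = 0.95,
) -> list[BarcodeCluster]:
    """Greedy centroid clustering of dereplicated barcodes.

    Sequences are processed in descending-count order (the order produced by
    :func:`dereplicate_and_filter`); each joins the first existing centroid
    with global identity >= ``threshold``, otherwise founds a new cluster.
    Because processing is count-descending, each cluster's founder is also
    its highest-count member and therefore its reference.
    """
    ordered = sorted(uniques, key=lambda item: (-item[1], item[0]))
    clusters: list[BarcodeCluster] = []
    for seq, count in ordered:
        joined = False
        for cluster in clusters:
            ref = cluster.reference_sequence
            # Fast accept: the gapless alignment is one valid global
            # alignment, so (L - hamming)/L is a lower bound on identity.
            if len(ref) == len(seq):
                if (len(seq) - hamming_distance(ref, seq)) / len(seq) >= threshold:
                    cluster.members.append((seq, count))
                    cluster.total_count += count
                    joined = True
                    break
            # Fast reject: score-only upper bound.
            if identity_upper_bound(ref, seq) < threshold:
                continue
            if pairwise_identity(ref, seq) >= threshold:
                cluster.members.append((seq, count))
                cluster.total_count += count
                joined = True
                break
        if not joined:
            clusters.append(
                BarcodeCluster(
                    reference_sequence=seq,
                    members=[(seq, count)],
                    total_count=count,
                )
            )
    return clusters


def call_barcodes(
    reads: Iterable[str],
    expected_length: int = 106,
    threshold: float = 0.95,
    min_count: int = 1,
) -> list[BarcodeCluster]:
    """Dereplicate, length-filter and cluster reads in one call."""
    uniques = dereplicate_and_filter(
        reads, expected_length=expected_length, min_count=min_count
    )
    return cluster_barcodes(uniques, threshold=threshold)


def read_sequences(path: str | Path) -> list[str]:
    """Load plain sequences from FASTA/FASTQ (format chosen by extension)."""
    path = Path(path)
    suffix = path.suffix.lower()
    fmt = "fastq" if suffix in (".fastq", ".fq") else "fasta"
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), fmt)]
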