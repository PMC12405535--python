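"""Shared pairwise-alignment primitives.

All identity values in this package are fractions in [0, 1]. Global identity
is defined as ``matches / alignment_length`` under unit match/mismatch/gap
scoring, i.e. gap columns count against identity. Semi-global ("overlap")
alignment is used for placing long reads on sensor references: end gaps on
both sequences are free and identity is computed over the aligned core
(internal gap columns included).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align

__all__ = [
    "pairwise_identity",
    "identity_upper_bound",
    "OverlapHit",
    "overlap_align",
    "infix_identity",
    "kmer_set",
    "hamming_distance",
]


@lru_cache(maxsize=None)
def _global_aligner() -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-1,
        extend_gap_score=-1,
    )


@lru_cache(maxsize=None)
def _overlap_aligner() -> Align.PairwiseAligner:
    # Affine gaps keep noisy long-read alignments from fragmenting; free end
    # gaps on both sequences give classic overlap semantics.
    aligner = Align.PairwiseAligner(
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-2,
        extend_gap_score=-1,
    )
    for attr in (
        "open_left_insertion_score",
        "extend_left_insertion_score",
        "open_right_insertion_score",
        "extend_right_insertion_score",
        "open_left_deletion_score",
        "extend_left_deletion_score",
        "open_right_deletion_score",
        "extend_right_deletion_score",
    ):
        setattr(aligner, attr, 0)
    return aligner


@lru_cache(maxsize=None)
def _infix_aligner() -> Align.PairwiseAligner:
    # Query (short sequence) global, target (containing sequence) end gaps free.
    aligner = Align.PairwiseAligner(
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-2,
        extend_gap_score=-1,
    )
    for attr in (
        "open_left_insertion_score",
        "extend_left_insertion_score",
        "open_right_insertion_score",
        "extend_right_insertion_score",
    ):
        setattr(aligner, attr, 0)
    return aligner


def hamming_distance(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming_distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity between two sequences.

    Identity is matches divided by the number of alignment columns of the
    maximum-score global alignment (unit match/mismatch/gap scores), so gaps
    count against identity. Symmetric in its arguments.

    Raises
    ------
    ValueError
        If either sequence is empty.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if a == b:
        return 1.0
    if b < a:  # co-optimal alignments differ by input order; canonicalise
        a, b = b, a
    alignment = _global_aligner().align(a, b)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def identity_upper_bound(a: str, b: str) -> float:
    """Cheap upper bound on :func:`pairwise_identity` (score-only alignment).

    For the maximum-score alignment with unit scoring, score = 2*matches -
    columns, and columns >= max(len(a), len(b)); hence identity <= 1/2 +
    max(score, 0) / (2 * max_len). Used to prune hopeless comparisons before
    paying for a traceback.
    """
    if not a or not b:
        raise ValueError("identity_upper_bound requires non-empty sequences")
    score = _global_aligner().score(a, b)
    return 0.5 + max(score, 0.0) / (2.0 * max(len(a), len(b)))


@dataclass(frozen=True)
class OverlapHit:
    """Placement of a read on a reference from semi-global alignment."""

    identity: float  # matches / aligned-core columns (internal gaps counted)
    read_start: int
    read_end: int
    ref_start: int
    ref_end: int


def overlap_align(read: str, ref: str) -> OverlapHit | None:
    """Semi-global alignment of ``read`` against ``ref`` with free end gaps."""
    if not read or not ref:
        return None
    alignment = _overlap_aligner().align(read, ref)[0]
    counts = alignment.counts()
    core = counts.aligned + counts.internal_gaps
    if core == 0:
        return None
    aligned = alignment.aligned
    if aligned.shape[1] == 0:
        return None
    return OverlapHit(
        identity=counts.identities / core,
        read_start=int(aligned[0][0][0]),
        read_end=int(aligned[0][-1][1]),
        ref_start=int(aligned[1][0][0]),
        ref_end=int(aligned[1][-1][1]),
    )


def infix_identity(container: str, probe: str) -> float:
    """Identity of ``probe`` aligned end-to-end inside ``container``.

    The probe pays for end gaps, the container does not; the denominator is
    the probe length, so the value is comparable across probes.
    """
    if not container or not probe:
        raise ValueError("infix_identity requires non-empty sequences")
    alignment = _infix_aligner().align(container, probe)[0]
    return alignment.counts().identities / len(probe)


def kmer_set(seq: str, k: int) -> frozenset[str]:
    """All k-mers of ``seq`` as a frozenset (empty if seq shorter than k)."""
    if len(seq) < k:
        return frozenset()
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))
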