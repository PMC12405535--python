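"""Mining of "grouped" two-component systems (TCSs) from genome annotation.

A grouped TCS is a histidine kinase / response regulator (HK-RR) gene pair in
close proximity on the same strand, sitting head-to-head with a divergently
transcribed neighbour gene, so that the shared intergenic region plausibly
carries the pair's regulated promoter. The miner finds such pairs, extracts
the sensor region (intergenic promoter through the far end of the pair) and
classifies Golden Gate cloning compatibility by scanning for Type IIS
recognition sites.

Coordinates are 1-based inclusive throughout (GFF3 convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "HKRRPair",
    "GroupedTCS",
    "EnzymeCompatibility",
    "TYPE_IIS_ENZYMES",
    "identify_hk_rr_pairs",
    "classify_grouped",
    "extract_sensor_region",
    "scan_typeIIS_sites",
    "mine_genome",
    "read_gff3_genes",
    "read_roles_table",
    "grouped_to_frame",
]

#: Recognition sequences of the Type IIS enzymes used for Golden Gate cloning.
TYPE_IIS_ENZYMES: dict[str, str] = {"SapI": "GCTCTTC", "BsaI": "GGTCTC"}


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene with an HK/RR/other role label."""

    gene_id: str
    contig: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive, >= start
    strand: str  # "+" or "-"
    role: str = "other"  # "HK", "RR" or "other"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id!r}: malformed coordinates "
                f"[{self.start}, {self.end}]"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: invalid strand {self.strand!r}")
        if self.role not in ("HK", "RR", "other"):
            raise ValueError(f"gene {self.gene_id!r}: invalid role {self.role!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class HKRRPair:
    """Same-strand HK-RR pair in close proximity; order is genomic order."""

    hk: GeneRecord
    rr: GeneRecord
    gap: int  # bp between the two gene bodies; overlaps reported as 0
    first_in_genome: str  # "HK" or "RR"

    @property
    def contig(self) -> str:
        return self.hk.contig

    @property
    def strand(self) -> str:
        return self.hk.strand

    @property
    def span(self) -> tuple[int, int]:
        return (min(self.hk.start, self.rr.start), max(self.hk.end, self.rr.end))


@dataclass(frozen=True)
class GroupedTCS:
    """An HK-RR pair plus its divergent neighbour and shared intergenic span."""

    hk: GeneRecord
    rr: GeneRecord
    divergent_gene: GeneRecord
    intergenic_start: int
    intergenic_end: int  # may be intergenic_start - 1 for abutting genes
    gap: int
    region_sequence: str = ""

    @property
    def contig(self) -> str:
        return self.hk.contig

    @property
    def strand(self) -> str:
        return self.hk.strand

    @property
    def pair_span(self) -> tuple[int, int]:
        return (min(self.hk.start, self.rr.start), max(self.hk.end, self.rr.end))

    @property
    def region_span(self) -> tuple[int, int]:
        """Genomic span of the sensor region (intergenic + pair), + strand coords."""
        lo, hi = self.pair_span
        if self.strand == "+":
            return (self.intergenic_start, hi)
        return (lo, self.intergenic_end)

    @property
    def tcs_id(self) -> str:
        return f"{self.hk.gene_id}--{self.rr.gene_id}"


@dataclass(frozen=True)
class EnzymeCompatibility:
    sapi_compatible: bool
    bsai_compatible: bool
    site_positions: tuple[tuple[str, int, str], ...] = field(default_factory=tuple)


def identify_hk_rr_pairs(
    genes: Iterable[GeneRecord], max_gap: int = 200
) -> list[HKRRPair]:
    """Find HK-RR pairs on the same contig and strand separated by < max_gap bp.

    The gap is ``downstream.start - upstream.end - 1``; overlapping genes are
    treated as gap 0 (reported via logging, not fatal). Either genomic order
    (HK first or RR first) is accepted. Output order is deterministic:
    sorted by (contig, leftmost start).
    """
    by_group: dict[tuple[str, str], list[GeneRecord]] = {}
    seen_ids: set[str] = set()
    for gene in genes:
        if gene.gene_id in seen_ids:
            raise ValueError(f"duplicate gene_id {gene.gene_id!r}")
        seen_ids.add(gene.gene_id)
        if gene.role in ("HK", "RR"):
            by_group.setdefault((gene.contig, gene.strand), []).append(gene)

    pairs: list[HKRRPair] = []
    for (_, _), members in sorted(by_group.items()):
        members.sort(key=lambda g: (g.start, g.end, g.gene_id))
        for i, upstream in enumerate(members):
            for downstream in members[i + 1 :]:
                gap = downstream.start - upstream.end - 1
                if gap >= max_gap:
                    # start-sorted, so the gap only grows from here
                    break
                if {upstream.role, downstream.role} != {"HK", "RR"}:
                    continue
                if gap < 0:
                    logger.warning(
                        "overlapping HK/RR genes %s/%s; gap treated as 0",
                        upstream.gene_id,
                        downstream.gene_id,
                    )
                    gap = 0
                hk, rr = (
                    (upstream, downstream)
                    if upstream.role == "HK"
                    else (downstream, upstream)
                )
                pairs.append(
                    HKRRPair(hk=hk, rr=rr, gap=gap, first_in_genome=upstream.role)
                )
    pairs.sort(key=lambda p: (p.contig, p.span[0], p.span[1]))
    return pairs


def classify_grouped(
    pair: HKRRPair,
    genes: Sequence[GeneRecord],
    max_search: int = 5000,
) -> GroupedTCS | None:
    """Return a :class:`GroupedTCS` if the pair has a divergent neighbour.

    The nearest annotated gene upstream of the pair's transcriptional 5' end
    must lie head-to-head on the opposite strand (both transcription units
    pointing away from the shared intergenic region), within ``max_search``
    bp, with no intervening gene. Tandem neighbours, absent neighbours and
    neighbours beyond the window all yield ``None``.
    """
    lo, hi = pair.span
    contig_genes = [
        g
        for g in genes
        if g.contig == pair.contig
        and g.gene_id not in (pair.hk.gene_id, pair.rr.gene_id)
    ]
    if pair.strand == "+":
        upstream = [g for g in contig_genes if g.end < lo]
        if not upstream:
            logger.info("pair %s--%s: no upstream gene", pair.hk.gene_id, pair.rr.gene_id)
            return None
        nearest = max(upstream, key=lambda g: (g.end, g.start))
        distance = lo - nearest.end - 1
        if distance > max_search or nearest.strand != "-":
            return None
        intergenic = (nearest.end + 1, lo - 1)
    else:
        downstream = [g for g in contig_genes if g.start > hi]
        if not downstream:
            logger.info("pair %s--%s: no upstream gene", pair.hk.gene_id, pair.rr.gene_id)
            return None
        nearest = min(downstream, key=lambda g: (g.start, g.end))
        distance = nearest.start - hi - 1
        if distance > max_search or nearest.strand != "+":
            return None
        intergenic = (hi + 1, nearest.start - 1)

    # The shared intergenic span must be free of other gene bodies.
    if intergenic[0] <= intergenic[1]:
        for g in contig_genes:
            if g.gene_id == nearest.gene_id:
                continue
            if g.start <= intergenic[1] and g.end >= intergenic[0]:
                return None

    return GroupedTCS(
        hk=pair.hk,
        rr=pair.rr,
        divergent_gene=nearest,
        intergenic_start=intergenic[0],
        intergenic_end=intergenic[1],
        gap=pair.gap,
    )


def extract_sensor_region(
    grouped: GroupedTCS,
    genome: Mapping[str, str] | str,
    include_divergent_codons: int = 0,
) -> str:
    """Extract the sensor-region sequence for a grouped TCS.

    The region runs from the boundary nearest the divergent gene's start
    codon (the codon itself excluded, unless ``include_divergent_codons`` > 0)
    through the far end of the HK-RR pair, reverse-complemented when the pair
    is on the - strand so the pair always reads 5'->3'.
    """
    if isinstance(genome, str):
        contig_seq = genome
    else:
        if grouped.contig not in genome:
            raise ValueError(f"contig {grouped.contig!r} not present in genome")
        contig_seq = genome[grouped.contig]

    lo, hi = grouped.region_span
    extra = 3 * include_divergent_codons
    if grouped.strand == "+":
        lo -= extra
    else:
        hi += extra
    if lo < 1 or hi > len(contig_seq):
        raise ValueError(
            f"region [{lo}, {hi}] out of bounds for contig {grouped.contig!r} "
            f"of length {len(contig_seq)}"
        )
    seq = contig_seq[lo - 1 : hi].upper()
    if grouped.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def scan_typeIIS_sites(
    region: str, enzymes: Mapping[str, str] = TYPE_IIS_ENZYMES
) -> EnzymeCompatibility:
    """Scan both strands of ``region`` for Type IIS recognition sites.

    Positions are 1-based on the forward strand of the region; N-containing
    windows never match. A region is compatible with an enzyme iff it has no
    internal recognition site in either orientation.
    """
    region = region.upper()
    sites: list[tuple[str, int, str]] = []
    for enzyme, motif in enzymes.items():
        motif = motif.upper()
        rc = str(Seq(motif).reverse_complement())
        for probe, strand in ((motif, "+"), (rc, "-")):
            start = region.find(probe)
            while start != -1:
                sites.append((enzyme, start + 1, strand))
                start = region.find(probe, start + 1)
    sites.sort(key=lambda s: (s[1], s[0], s[2]))
    found = {s[0] for s in sites}
    return EnzymeCompatibility(
        sapi_compatible="SapI" not in found,
        bsai_compatible="BsaI" not in found,
        site_positions=tuple(sites),
    )


def mine_genome(
    genome: Mapping[str, str],
    genes: Sequence[GeneRecord],
    max_gap: int = 200,
    max_search: int = 5000,
    include_divergent_codons: int = 0,
) -> list[GroupedTCS]:
    """Full miner: pairs -> grouped classification -> region extraction."""
    grouped: list[GroupedTCS] = []
    for pair in identify_hk_rr_pairs(genes, max_gap=max_gap):
        hit = classify_grouped(pair, genes, max_search=max_search)
        if hit is None:
            continue
        seq = extract_sensor_region(
            hit, genome, include_divergent_codons=include_divergent_codons
        )
        grouped.append(replace(hit, region_sequence=seq))
    return grouped


def grouped_to_frame(grouped: Sequence[GroupedTCS]) -> pd.DataFrame:
    """Tabulate grouped TCSs with compatibility calls for TSV output."""
    rows = []
    for g in grouped:
        compat = scan_typeIIS_sites(g.region_sequence) if g.region_sequence else None
        lo, hi = g.region_span
        rows.append(
            {
                "tcs_id": g.tcs_id,
                "contig": g.contig,
                "strand": g.strand,
                "hk_gene": g.hk.gene_id,
                "rr_gene": g.rr.gene_id,
                "divergent_gene": g.divergent_gene.gene_id,
                "pair_gap": g.gap,
                "region_start": lo,
                "region_end": hi,
                "region_length": hi - lo + 1,
                "sapi_compatible": compat.sapi_compatible if compat else pd.NA,
                "bsai_compatible": compat.bsai_compatible if compat else pd.NA,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "tcs_id",
            "contig",
            "strand",
            "hk_gene",
            "rr_gene",
            "divergent_gene",
            "pair_gap",
            "region_start",
            "region_end",
            "region_length",
            "sapi_compatible",
            "bsai_compatible",
        ],
    )


def read_roles_table(path: str | Path) -> dict[str, str]:
    """Read a two-column (gene_id, role) TSV; roles are HK/RR/other."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if "gene_id" in cols and "role" in cols:
        df.columns = cols
    else:  # headerless
        df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "role"], dtype=str)
    return dict(zip(df["gene_id"], df["role"].str.upper().where(df["role"].str.upper().isin(["HK", "RR"]), "other")))


def read_gff3_genes(path: str | Path, roles: Mapping[str, str]) -> list[GeneRecord]:
    """Parse gene features from a GFF3 file into :class:`GeneRecord` objects."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneRecord] = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                contig=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                role=roles.get(gene_id, "other"),
            )
        )
    return genes


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
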