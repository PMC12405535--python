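import numpy as np
import pytest

from sensorscreen.synthetic import generate_annotated_genome, random_dna
from sensorscreen.tcs_miner import (
    GeneRecord,
    HKRRPair,
    classify_grouped,
    extract_sensor_region,
    grouped_to_frame,
    identify_hk_rr_pairs,
    mine_genome,
    scan_typeIIS_sites,
)


def gene(gene_id, start, end, strand, role="other", contig="c1"):
    return GeneRecord(gene_id, contig, start, end, strand, role)


# ---------------------------------------------------------------------------
# identify_hk_rr_pairs
# ---------------------------------------------------------------------------


class TestIdentifyPairs:
    def test_close_pair_found(self):
        genes = [gene("h", 100, 1300, "+", "HK"), gene("r", 1400, 2100, "+", "RR")]
        pairs = identify_hk_rr_pairs(genes)
        assert len(pairs) == 1
        assert pairs[0].gap == 99
        assert pairs[0].hk.gene_id == "h" and pairs[0].rr.gene_id == "r"
        assert pairs[0].first_in_genome == "HK"

    def test_gap_at_threshold_excluded(self):
        genes = [gene("h", 100, 1300, "+", "HK"), gene("r", 1551, 2100, "+", "RR")]
        assert identify_hk_rr_pairs(genes) == []
        # gap exactly 200 is not < 200
        genes = [gene("h", 100, 1300, "+", "HK"), gene("r", 1501, 2100, "+", "RR")]
        assert identify_hk_rr_pairs(genes) == []

    def test_opposite_strands_excluded(self):
        genes = [gene("h", 100, 1300, "+", "HK"), gene("r", 1400, 2100, "-", "RR")]
        assert identify_hk_rr_pairs(genes) == []

    def test_rr_first_order_accepted(self):
        genes = [gene("r", 100, 700, "-", "RR"), gene("h", 750, 1900, "-", "HK")]
        pairs = identify_hk_rr_pairs(genes)
        assert len(pairs) == 1
        assert pairs[0].first_in_genome == "RR"

    def test_overlapping_pair_gap_zero(self):
        genes = [gene("h", 100, 1300, "+", "HK"), gene("r", 1250, 2100, "+", "RR")]
        pairs = identify_hk_rr_pairs(genes)
        assert len(pairs) == 1 and pairs[0].gap == 0

    def test_malformed_coordinates_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            gene("bad", 500, 100, "+", "HK")
        with pytest.raises(ValueError, match="strand"):
            gene("bad", 1, 10, "*", "HK")

    def test_duplicate_ids_rejected(self):
        genes = [gene("x", 1, 10, "+", "HK"), gene("x", 20, 30, "+", "RR")]
        with pytest.raises(ValueError, match="duplicate"):
            identify_hk_rr_pairs(genes)

    def test_order_invariance(self, rng):
        genome, genes, _ = generate_annotated_genome(rng, n_grouped=4, n_decoys=8)
        ref = identify_hk_rr_pairs(genes)
        for _ in range(3):
            shuffled = [genes[i] for i in rng.permutation(len(genes))]
            assert identify_hk_rr_pairs(shuffled) == ref


# ---------------------------------------------------------------------------
# classify_grouped / extract_sensor_region
# ---------------------------------------------------------------------------


def make_pair(hk, rr):
    gap = max(0, max(hk.start, rr.start) - min(hk.end, rr.end) - 1)
    first = hk.role if hk.start <= rr.start else rr.role
    return HKRRPair(hk=hk, rr=rr, gap=gap, first_in_genome=first)


class TestClassifyGrouped:
    def test_divergent_neighbour_found(self):
        hk = gene("h", 1000, 2000, "+", "HK")
        rr = gene("r", 2100, 3000, "+", "RR")
        div = gene("d", 200, 800, "-")
        grouped = classify_grouped(make_pair(hk, rr), [hk, rr, div])
        assert grouped is not None
        assert grouped.divergent_gene.gene_id == "d"
        assert (grouped.intergenic_start, grouped.intergenic_end) == (801, 999)

    def test_tandem_neighbour_rejected(self):
        hk = gene("h", 1000, 2000, "+", "HK")
        rr = gene("r", 2100, 3000, "+", "RR")
        tandem = gene("d", 200, 800, "+")
        assert classify_grouped(make_pair(hk, rr), [hk, rr, tandem]) is None

    def test_no_upstream_gene_rejected(self):
        hk = gene("h", 1000, 2000, "+", "HK")
        rr = gene("r", 2100, 3000, "+", "RR")
        assert classify_grouped(make_pair(hk, rr), [hk, rr]) is None

    def test_neighbour_beyond_window_rejected(self):
        hk = gene("h", 10000, 11000, "+", "HK")
        rr = gene("r", 11100, 12000, "+", "RR")
        div = gene("d", 200, 800, "-")
        assert classify_grouped(make_pair(hk, rr), [hk, rr, div]) is None
        assert (
            classify_grouped(make_pair(hk, rr), [hk, rr, div], max_search=20000)
            is not None
        )

    def test_minus_strand_pair_mirrored(self):
        hk = gene("h", 1000, 2000, "-", "HK")
        rr = gene("r", 2100, 3000, "-", "RR")
        div = gene("d", 3200, 3800, "+")
        grouped = classify_grouped(make_pair(hk, rr), [hk, rr, div])
        assert grouped is not None
        assert (grouped.intergenic_start, grouped.intergenic_end) == (3001, 3199)


class TestExtractRegion:
    def test_plus_strand_span(self, rng):
        contig = random_dna(rng, 4000)
        hk = gene("h", 1000, 2000, "+", "HK")
        rr = gene("r", 2100, 3000, "+", "RR")
        div = gene("d", 200, 800, "-")
        grouped = classify_grouped(make_pair(hk, rr), [hk, rr, div])
        region = extract_sensor_region(grouped, {"c1": contig})
        assert len(region) == 2200
        assert region == contig[800:3000]

    def test_minus_strand_reverse_complement(self, rng):
        from Bio.Seq import Seq

        contig = random_dna(rng, 4200)
        hk = gene("h", 1000, 2000, "-", "HK")
        rr = gene("r", 2100, 3000, "-", "RR")
        div = gene("d", 3200, 3800, "+")
        grouped = classify_grouped(make_pair(hk, rr), [hk, rr, div])
        region = extract_sensor_region(grouped, {"c1": contig})
        assert region == str(Seq(contig[999:3199]).reverse_complement())

    def test_length_conservation(self, rng):
        genome, genes, _ = generate_annotated_genome(rng, n_grouped=3, n_decoys=4)
        for g in mine_genome(genome, genes):
            lo, hi = g.region_span
            pair_lo, pair_hi = g.pair_span
            intergenic = max(0, g.intergenic_end - g.intergenic_start + 1)
            assert len(g.region_sequence) == hi - lo + 1
            assert len(g.region_sequence) == intergenic + (pair_hi - pair_lo + 1)

    def test_out_of_bounds_raises(self):
        hk = gene("h", 1000, 2000, "+", "HK")
        rr = gene("r", 2100, 3000, "+", "RR")
        div = gene("d", 200, 800, "-")
        grouped = classify_grouped(make_pair(hk, rr), [hk, rr, div])
        with pytest.raises(ValueError, match="c1"):
            extract_sensor_region(grouped, {"c1": "ACGT" * 100})


# ---------------------------------------------------------------------------
# scan_typeIIS_sites
# ---------------------------------------------------------------------------


class TestEnzymeScan:
    def test_sapi_forward_site(self):
        compat = scan_typeIIS_sites("AAAA" + "GCTCTTC" + "AAAA")
        assert not compat.sapi_compatible
        assert ("SapI", 5, "+") in compat.site_positions

    def test_sapi_reverse_site(self):
        compat = scan_typeIIS_sites("AAAA" + "GAAGAGC" + "AAAA")
        assert not compat.sapi_compatible
        assert ("SapI", 5, "-") in compat.site_positions

    def test_clean_region_compatible(self):
        compat = scan_typeIIS_sites("ACACACACACACACAC")
        assert compat.sapi_compatible and compat.bsai_compatible
        assert compat.site_positions == ()

    def test_bsai_both_strands(self):
        assert not scan_typeIIS_sites("TTGGTCTCTT").bsai_compatible
        assert not scan_typeIIS_sites("TTGAGACCTT").bsai_compatible

    def test_n_never_matches(self):
        compat = scan_typeIIS_sites("AAAGCTCTNCAAA")
        assert compat.sapi_compatible

    def test_string_search_oracle(self, rng):
        from Bio.Seq import Seq

        region = random_dna(rng, 5000)
        compat = scan_typeIIS_sites(region)
        for enzyme, motif in (("SapI", "GCTCTTC"), ("BsaI", "GGTCTC")):
            expected = set()
            for probe, strand in ((motif, "+"), (str(Seq(motif).reverse_complement()), "-")):
                for i in range(len(region) - len(probe) + 1):
                    if region[i : i + len(probe)] == probe:
                        expected.add((enzyme, i + 1, strand))
            got = {s for s in compat.site_positions if s[0] == enzyme}
            assert got == expected


# ---------------------------------------------------------------------------
# whole-miner properties against a brute-force oracle
# ---------------------------------------------------------------------------


def brute_force_grouped(genes, max_gap=200, max_search=5000):
    """Independent enumeration of grouped TCSs straight from the definition."""
    triples = set()
    for a in genes:
        for b in genes:
            if a.gene_id == b.gene_id or a.contig != b.contig:
                continue
            if a.strand != b.strand or {a.role, b.role} != {"HK", "RR"}:
                continue
            if a.start > b.start:
                continue
            if b.start - a.end - 1 >= max_gap:
                continue
            lo = min(a.start, b.start)
            hi = max(a.end, b.end)
            others = [
                g
                for g in genes
                if g.contig == a.contig
                and g.gene_id not in (a.gene_id, b.gene_id)
            ]
            if a.strand == "+":
                upstream = [g for g in others if g.end < lo]
                if not upstream:
                    continue
                nearest = max(upstream, key=lambda g: g.end)
                if lo - nearest.end - 1 > max_search or nearest.strand != "-":
                    continue
                span = (nearest.end + 1, lo - 1)
            else:
                downstream = [g for g in others if g.start > hi]
                if not downstream:
                    continue
                nearest = min(downstream, key=lambda g: g.start)
                if nearest.start - hi - 1 > max_search or nearest.strand != "+":
                    continue
                span = (hi + 1, nearest.start - 1)
            blocked = any(
                g.start <= span[1] and g.end >= span[0]
                for g in others
                if g.gene_id != nearest.gene_id
            )
            if blocked:
                continue
            hk, rr = (a, b) if a.role == "HK" else (b, a)
            triples.add((hk.gene_id, rr.gene_id, nearest.gene_id))
    return triples


@pytest.mark.parametrize("seed", range(8))
def test_miner_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    genome, genes, expected = generate_annotated_genome(rng, n_grouped=4, n_decoys=8)
    found = {
        (g.hk.gene_id, g.rr.gene_id, g.divergent_gene.gene_id)
        for g in mine_genome(genome, genes)
    }
    assert found == set(expected)
    assert found == brute_force_grouped(genes)


def test_reverse_complement_invariance(rng):
    from Bio.Seq import Seq

    genome, genes, expected = generate_annotated_genome(rng, n_grouped=3, n_decoys=6)
    contig = "chr1"
    length = len(genome[contig])
    rc_genome = {contig: str(Seq(genome[contig]).reverse_complement())}
    rc_genes = [
        GeneRecord(
            gene_id=g.gene_id,
            contig=g.contig,
            start=length - g.end + 1,
            end=length - g.start + 1,
            strand="-" if g.strand == "+" else "+",
            role=g.role,
        )
        for g in genes
    ]
    fwd = mine_genome(genome, genes)
    rev = mine_genome(rc_genome, rc_genes)
    fwd_ids = {(g.hk.gene_id, g.rr.gene_id, g.divergent_gene.gene_id) for g in fwd}
    rev_ids = {(g.hk.gene_id, g.rr.gene_id, g.divergent_gene.gene_id) for g in rev}
    assert fwd_ids == rev_ids
    # extracted regions are strand-normalised, so sequences agree too
    assert {g.region_sequence for g in fwd} == {g.region_sequence for g in rev}


def test_grouped_frame_columns(rng):
    genome, genes, _ = generate_annotated_genome(rng, n_grouped=2, n_decoys=2)
    df = grouped_to_frame(mine_genome(genome, genes))
    assert list(df["region_length"]) == [
        row.region_end - row.region_start + 1 for row in df.itertuples()
    ]
    assert df["sapi_compatible"].notna().all()
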