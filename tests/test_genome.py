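import numpy as np
import pytest

from attenuscan.genome import (
    GeneRecord,
    GenomeAnnotation,
    Replicon,
    extract_search_regions,
    read_annotation_tsv,
    read_genome,
)

from conftest import make_annotation, random_dna


def _write_genome(tmp_path, seq, gff_lines):
    fa = tmp_path / "g.fasta"
    fa.write_text(">chr\n" + seq + "\n")
    gff = tmp_path / "g.gff3"
    gff.write_text("##gff-version 3\n" + "".join(line + "\n" for line in gff_lines))
    return fa, gff


class TestReadGenome:
    def test_two_genes_parsed_and_sorted(self, tmp_path):
        seq = random_dna(np.random.default_rng(0), 1000)
        fa, gff = _write_genome(
            tmp_path,
            seq,
            [
                "chr\tsrc\tgene\t500\t800\t.\t+\t.\tID=g2;product=kinase",
                "chr\tsrc\tgene\t10\t300\t.\t-\t.\tID=g1;product=ligase",
            ],
        )
        ann = read_genome(fa, gff)
        assert [g.gene_id for g in ann.genes] == ["g1", "g2"]
        assert ann.gene("g1").strand == "-"
        assert len(ann.replicons[0]) == 1000

    def test_gene_past_replicon_end_rejected(self, tmp_path):
        fa, gff = _write_genome(
            tmp_path, "ACGT" * 25,
            ["chr\tsrc\tgene\t50\t200\t.\t+\t.\tID=g1"],
        )
        with pytest.raises(ValueError, match="g1"):
            read_genome(fa, gff)

    def test_hypothetical_flag_from_product(self, tmp_path):
        fa, gff = _write_genome(
            tmp_path, random_dna(np.random.default_rng(1), 600),
            ["chr\tsrc\tCDS\t101\t400\t.\t-\t.\tID=c1;product=hypothetical protein"],
        )
        ann = read_genome(fa, gff)
        g = ann.gene("c1")
        assert g.hypothetical and g.length == 300 and g.strand == "-"

    def test_malformed_line_reports_line_number(self, tmp_path):
        fa, gff = _write_genome(
            tmp_path, "ACGT" * 50, ["chr\tonly\tthree"],
        )
        with pytest.raises(ValueError, match=":2"):
            read_genome(fa, gff)

    def test_unknown_replicon_named_in_error(self, tmp_path):
        fa, gff = _write_genome(
            tmp_path, "ACGT" * 50,
            ["plasmid\tsrc\tgene\t1\t50\t.\t+\t.\tID=gX"],
        )
        with pytest.raises(ValueError, match="gX"):
            read_genome(fa, gff)

    def test_tsv_dialect(self, tmp_path):
        fa = tmp_path / "g.fasta"
        fa.write_text(">chr\n" + "ACGT" * 100 + "\n")
        tsv = tmp_path / "g.tsv"
        tsv.write_text(
            "gene_id\treplicon\tstart\tend\tstrand\tproduct\n"
            "g1\tchr\t11\t100\t+\thypothetical protein\n"
        )
        ann = read_annotation_tsv(fa, tsv)
        assert ann.gene("g1").hypothetical

    def test_lowercase_and_u_normalized(self):
        rep = Replicon("r", "acgu")
        assert rep.sequence == "ACGT"


class TestSearchRegions:
    def test_simple_gap(self):
        ann = make_annotation(1000, [("g1", 1, 300, "+"), ("g2", 501, 900, "+")])
        regions = extract_search_regions(ann)
        mid = [r for r in regions if r.left_gene_id == "g1"]
        assert len(mid) == 1
        r = mid[0]
        assert (r.lo, r.hi, r.right_gene_id) == (301, 500, "g2")

    def test_short_hypothetical_orf_absorbed(self):
        ann = make_annotation(
            1000,
            [
                ("g1", 1, 300, "+"),
                ("s1", 350, 499, "+", "hypothetical protein"),
                ("g2", 601, 900, "+"),
            ],
        )
        regions = [r for r in extract_search_regions(ann) if r.left_gene_id == "g1"]
        assert len(regions) == 1
        assert (regions[0].lo, regions[0].hi) == (301, 600)
        assert regions[0].absorbed_orf_ids == ["s1"]

    def test_long_hypothetical_orf_not_absorbed(self):
        ann = make_annotation(
            1200,
            [
                ("g1", 1, 300, "+"),
                ("s1", 400, 649, "+", "hypothetical protein"),  # 250 nt
                ("g2", 801, 1100, "+"),
            ],
        )
        inner = [
            r for r in extract_search_regions(ann)
            if r.left_gene_id in ("g1", "s1")
        ]
        assert {(r.lo, r.hi) for r in inner} == {(301, 399), (650, 800)}

    def test_overlapping_genes_yield_no_region(self):
        ann = make_annotation(600, [("g1", 1, 300, "+"), ("g2", 250, 500, "+")])
        regions = extract_search_regions(ann)
        assert all(r.left_gene_id != "g1" or r.right_gene_id != "g2" for r in regions)

    def test_empty_annotation_is_one_region(self):
        ann = make_annotation(500, [])
        regions = extract_search_regions(ann)
        assert len(regions) == 1 and (regions[0].lo, regions[0].hi) == (1, 500)

    def test_circular_wraparound(self):
        rng = np.random.default_rng(2)
        rep = Replicon("chr", random_dna(rng, 1000), topology="circular")
        ann = GenomeAnnotation(
            "sp",
            [rep],
            [
                GeneRecord("g1", "chr", 101, 300, "+"),
                GeneRecord("g2", "chr", 601, 900, "+"),
            ],
        )
        regions = extract_search_regions(ann)
        wrap = [r for r in regions if r.hi > 1000]
        assert len(wrap) == 1
        assert (wrap[0].lo, wrap[0].hi) == (901, 1100)
        assert len(wrap[0].sequence(ann)) == 200

    @pytest.mark.parametrize("seed", range(5))
    def test_regions_and_genes_tile_replicon(self, seed):
        """Non-absorbed gene spans plus regions cover the replicon without
        overlap (linear layouts with random gaps and absorbed ORFs)."""
        rng = np.random.default_rng(seed)
        genes = []
        pos = 1
        i = 0
        while pos < 4500:
            gap = int(rng.integers(0, 200))
            length = int(rng.integers(80, 400))
            start = pos + gap
            hyp = rng.random() < 0.3 and length < 200
            genes.append(
                (f"g{i}", start, start + length - 1,
                 "+" if rng.random() < 0.5 else "-",
                 "hypothetical protein" if hyp else "enzyme")
            )
            pos = start + length
            i += 1
        ann = make_annotation(5000, genes)
        regions = extract_search_regions(ann)
        covered = np.zeros(5001, dtype=int)
        for r in regions:
            covered[r.lo : r.hi + 1] += 1
        for g in ann.genes:
            if not (g.hypothetical and g.length < 200):
                covered[g.start : g.end + 1] += 1
        # overlapping real genes may double-cover; regions never overlap genes
        assert covered[1:].min() >= 1
        for r in regions:
            for g in ann.genes:
                if g.hypothetical and g.length < 200:
                    continue
                assert r.hi < g.start or g.end < r.lo

    def test_absorbed_invariant_and_determinism(self, default_cohort):
        ann = default_cohort.annotations[0]
        r1 = extract_search_regions(ann)
        r2 = extract_search_regions(ann)
        assert [(r.lo, r.hi, r.absorbed_orf_ids) for r in r1] == [
            (r.lo, r.hi, r.absorbed_orf_ids) for r in r2
        ]
        for r in r1:
            for oid in r.absorbed_orf_ids:
                g = ann.gene(oid)
                assert g.hypothetical and g.length < 200
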