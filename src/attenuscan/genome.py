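"""Annotated-genome model and search-region extraction.

The screen operates on bacterial replicons with gene annotations.  Everything
downstream (terminator detection, attenuator filters, leader extraction) works
in the coordinate frame defined here: 1-based, inclusive, forward-strand
coordinates, as in GFF3.

Intergenic *search regions* are the maximal gaps between consecutive genes.
Short hypothetical ORFs (< 200 nt by default) are treated as part of the
intergenic space — many of them are misannotated leader peptides — and are
"absorbed" into the surrounding region rather than splitting it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio import SeqIO

__all__ = [
    "Replicon",
    "GeneRecord",
    "GenomeAnnotation",
    "SearchRegion",
    "read_genome",
    "read_annotation_tsv",
    "extract_search_regions",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

HYPOTHETICAL_PATTERNS = [r"hypothetical"]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> str:
    """Uppercase, map U->T, and validate the alphabet."""
    s = seq.upper().replace("U", "T")
    if not s:
        raise ValueError("empty replicon sequence")
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    return s


@dataclass
class Replicon:
    replicon_id: str
    sequence: str
    topology: str = "linear"  # or "circular"

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"bad topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, lo: int, hi: int) -> str:
        """1-based inclusive slice; coordinates past the end wrap on circular
        replicons (used by the wrap-around search region)."""
        n = len(self.sequence)
        if lo < 1 or lo > hi:
            raise ValueError(f"bad interval [{lo},{hi}]")
        if hi <= n:
            return self.sequence[lo - 1 : hi]
        if self.topology != "circular":
            raise ValueError(f"interval [{lo},{hi}] outside linear replicon of length {n}")
        return (self.sequence[lo - 1 :] + self.sequence * ((hi - n) // n + 1))[: hi - lo + 1]


@dataclass
class GeneRecord:
    gene_id: str
    replicon_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # "+" or "-"
    product: str = ""
    hypothetical: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"gene {self.gene_id}: bad coordinates {self.start}..{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeAnnotation:
    species_id: str
    replicons: list[Replicon]
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._replicon_index = {r.replicon_id: r for r in self.replicons}
        for g in self.genes:
            rep = self._replicon_index.get(g.replicon_id)
            if rep is None:
                raise ValueError(f"gene {g.gene_id}: unknown replicon {g.replicon_id!r}")
            if g.end > len(rep):
                raise ValueError(
                    f"gene {g.gene_id}: end {g.end} beyond replicon "
                    f"{g.replicon_id} length {len(rep)}"
                )
        self.genes.sort(key=lambda g: (g.replicon_id, g.start, g.end, g.gene_id))
        self._gene_index = {g.gene_id: g for g in self.genes}

    def replicon(self, replicon_id: str) -> Replicon:
        return self._replicon_index[replicon_id]

    def gene(self, gene_id: str) -> GeneRecord:
        return self._gene_index[gene_id]

    def genes_on(self, replicon_id: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.replicon_id == replicon_id]


@dataclass
class SearchRegion:
    """A maximal intergenic interval in which terminators are sought.

    ``lo``/``hi`` are 1-based inclusive; for the wrap-around region of a
    circular replicon ``hi`` may exceed the replicon length (positions wrap).
    ``absorbed_orf_ids`` lists short hypothetical ORFs lying inside the
    interval that were treated as intergenic sequence.
    """

    replicon_id: str
    lo: int
    hi: int
    left_gene_id: str | None
    right_gene_id: str | None
    absorbed_orf_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"empty region [{self.lo},{self.hi}]")

    def __len__(self) -> int:
        return self.hi - self.lo + 1

    def sequence(self, ann: GenomeAnnotation) -> str:
        return ann.replicon(self.replicon_id).fetch(self.lo, self.hi)


def _is_hypothetical(product: str, patterns: list[str] | None = None) -> bool:
    pats = patterns if patterns is not None else HYPOTHETICAL_PATTERNS
    return any(re.search(p, product, re.IGNORECASE) for p in pats)


def _parse_gff_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_genome(
    fasta_path,
    gff_path,
    species_id: str | None = None,
    feature_types: tuple[str, ...] = ("gene", "CDS"),
    hypothetical_patterns: list[str] | None = None,
    topology: str = "linear",
) -> GenomeAnnotation:
    """Load replicon sequences (FASTA) and gene coordinates (GFF3).

    Rows whose feature type is not in ``feature_types`` are ignored.  When a
    gene and a CDS share an ID the first row wins.  A gene is flagged
    hypothetical when its ``product`` attribute matches one of
    ``hypothetical_patterns`` (default: the substring "hypothetical"), or when
    it carries a truthy ``hypothetical`` attribute.
    """
    replicons = [
        Replicon(rec.id, str(rec.seq), topology=topology)
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    ]
    if not replicons:
        raise ValueError(f"no FASTA records in {fasta_path}")

    genes: list[GeneRecord] = []
    seen: set[str] = set()
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{gff_path}:{lineno}: expected 9 tab-separated fields")
            seqid, _src, ftype, start_s, end_s, _score, strand, _phase, attr = fields
            if ftype not in feature_types:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{gff_path}:{lineno}: non-integer coordinates") from exc
            if strand not in ("+", "-"):
                raise ValueError(f"{gff_path}:{lineno}: bad strand {strand!r}")
            attrs = _parse_gff_attributes(attr)
            gene_id = attrs.get("ID") or attrs.get("locus_tag")
            if not gene_id:
                raise ValueError(f"{gff_path}:{lineno}: feature has no ID attribute")
            if gene_id in seen:
                continue
            seen.add(gene_id)
            product = attrs.get("product", "")
            hyp = _is_hypothetical(product, hypothetical_patterns) or attrs.get(
                "hypothetical", ""
            ).lower() in ("1", "true", "yes")
            genes.append(GeneRecord(gene_id, seqid, start, end, strand, product, hyp))

    sp = species_id or replicons[0].replicon_id
    return GenomeAnnotation(sp, replicons, genes)


def read_annotation_tsv(
    fasta_path, tsv_path, species_id: str | None = None, **kwargs
) -> GenomeAnnotation:
    """Minimal TSV annotation dialect:
    gene_id <tab> replicon <tab> start <tab> end <tab> strand <tab> product
    """
    replicons = [
        Replicon(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(fasta_path), "fasta")
    ]
    genes = []
    with open(tsv_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{tsv_path}:{lineno}: expected >= 5 fields")
            gene_id, rep, start_s, end_s, strand = fields[:5]
            product = fields[5] if len(fields) > 5 else ""
            genes.append(
                GeneRecord(
                    gene_id, rep, int(start_s), int(end_s), strand, product,
                    _is_hypothetical(product),
                )
            )
    sp = species_id or replicons[0].replicon_id
    return GenomeAnnotation(sp, replicons, genes)


def extract_search_regions(
    ann: GenomeAnnotation, short_orf_max: int = 200
) -> list[SearchRegion]:
    """Derive one search region per maximal gap between consecutive genes.

    Hypothetical ORFs shorter than ``short_orf_max`` are absorbed: they do not
    delimit regions and are recorded in ``absorbed_orf_ids`` of the region that
    covers them.  Overlapping or abutting genes yield no region.  Linear
    replicons additionally get the two terminal regions (no flanking gene on
    one side); circular replicons get a single wrap-around region instead.
    """
    regions: list[SearchRegion] = []
    for rep in ann.replicons:
        genes = ann.genes_on(rep.replicon_id)
        keep = [g for g in genes if not (g.hypothetical and g.length < short_orf_max)]
        absorbed = [g for g in genes if g.hypothetical and g.length < short_orf_max]
        n = len(rep)

        def absorbed_in(lo: int, hi: int) -> list[str]:
            return [a.gene_id for a in absorbed if lo <= a.start and a.end <= hi]

        if not keep:
            regions.append(
                SearchRegion(rep.replicon_id, 1, n, None, None, absorbed_in(1, n))
            )
            continue

        gaps: list[tuple[int, int, str | None, str | None]] = []
        if rep.topology == "circular":
            lo, hi = keep[-1].end + 1, keep[0].start - 1 + n
            if lo <= hi:
                gaps.append((lo, hi, keep[-1].gene_id, keep[0].gene_id))
        else:
            if keep[0].start > 1:
                gaps.append((1, keep[0].start - 1, None, keep[0].gene_id))
            if keep[-1].end < n:
                gaps.append((keep[-1].end + 1, n, keep[-1].gene_id, None))
        cursor_end = keep[0].end
        cursor_gene = keep[0]
        for g in keep[1:]:
            if g.start > cursor_end + 1:
                gaps.append((cursor_end + 1, g.start - 1, cursor_gene.gene_id, g.gene_id))
            if g.end > cursor_end:
                cursor_end = g.end
                cursor_gene = g
        for lo, hi, left, right in sorted(gaps):
            regions.append(
                SearchRegion(rep.replicon_id, lo, hi, left, right, absorbed_in(lo, hi))
            )
    return regions
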