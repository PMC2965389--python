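"""Writers for the screen's tabular and sequence outputs.

All coordinates written are 1-based inclusive, forward strand (GFF
convention), stated in each header.
"""

from __future__ import annotations

import os

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import SearchRegion
from .scan import TerminatorHit
from .screen import AttenuatorCandidate

__all__ = [
    "write_regions_tsv",
    "write_hits_gff3",
    "write_candidates_tsv",
    "write_leaders_fasta",
    "write_clusters_tsv",
    "write_cohort",
]


def write_regions_tsv(regions: list[SearchRegion], path) -> None:
    with open(path, "w") as fh:
        fh.write("# search regions; coordinates 1-based inclusive\n")
        fh.write("replicon\tlo\thi\tleft_gene\tright_gene\tabsorbed_orfs\n")
        for r in regions:
            fh.write(
                f"{r.replicon_id}\t{r.lo}\t{r.hi}\t{r.left_gene_id or '.'}\t"
                f"{r.right_gene_id or '.'}\t{','.join(r.absorbed_orf_ids) or '.'}\n"
            )


def write_hits_gff3(hits: list[TerminatorHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for h in hits:
            lo, hi = h.span
            score = f"{h.score:.2f}" if h.score is not None else "."
            attrs = (
                f"stem_len={h.stem_len};delta_g={h.delta_g:.2f};score={score};"
                f"method={h.method};spacer_len={h.spacer_len};utr_class={h.utr_class}"
            )
            fh.write(
                f"{h.replicon_id}\tattenuscan\tterminator\t{lo}\t{hi}\t{score}\t"
                f"{h.strand}\t.\t{attrs}\n"
            )


def write_candidates_tsv(cands: list[AttenuatorCandidate], path) -> None:
    with open(path, "w") as fh:
        fh.write("# attenuator candidates; coordinates 1-based inclusive\n")
        fh.write(
            "candidate_id\treplicon\tstrand\tdownstream_gene\tupstream_gene\t"
            "d_down\td_up\tratio\tdelta_g\tstem_len\tleader_lo\tleader_hi\n"
        )
        for c in cands:
            fh.write(
                f"{c.candidate_id}\t{c.hit.replicon_id}\t{c.hit.strand}\t"
                f"{c.downstream_gene_id}\t{c.upstream_gene_id or '.'}\t{c.d_down}\t"
                f"{c.d_up}\t{c.ratio:.3f}\t{c.hit.delta_g:.2f}\t{c.hit.stem_len}\t"
                f"{c.leader_interval[0]}\t{c.leader_interval[1]}\n"
            )


def write_leaders_fasta(cands: list[AttenuatorCandidate], species_id: str, path) -> None:
    recs = []
    for c in cands:
        lo, hi = c.leader_interval
        rid = f"{species_id}|{c.downstream_gene_id}|{lo}-{hi}|{c.hit.strand}"
        recs.append(SeqRecord(Seq(c.leader_seq), id=rid, description=""))
    SeqIO.write(recs, str(path), "fasta")


def write_clusters_tsv(cs, family_by_member, species_by_member, gene_by_member, path):
    with open(path, "w") as fh:
        fh.write("cluster_id\tmember\tspecies\tgene\tfamily\tclass\tmobile\n")
        for cid in sorted(cs.clusters):
            for m in cs.clusters[cid]:
                fh.write(
                    f"{cid}\t{m}\t{species_by_member.get(m, '.')}\t"
                    f"{gene_by_member.get(m, '.')}\t{family_by_member.get(m, '.')}\t"
                    f"{cs.classes.get(cid, '.')}\t{int(cs.mobile.get(cid, False))}\n"
                )


def _gff_escape(s: str) -> str:
    return s.replace(";", "%3B").replace("=", "%3D")


def write_cohort(cohort, outdir) -> None:
    """Emit FASTA + GFF3 per species, the family map, the species order and
    the truth table."""
    os.makedirs(outdir, exist_ok=True)
    for ann in cohort.annotations:
        sp = ann.species_id
        recs = [
            SeqRecord(Seq(r.sequence), id=r.replicon_id, description="")
            for r in ann.replicons
        ]
        SeqIO.write(recs, os.path.join(outdir, f"{sp}.fasta"), "fasta")
        with open(os.path.join(outdir, f"{sp}.gff3"), "w") as fh:
            fh.write("##gff-version 3\n")
            for g in ann.genes:
                attrs = f"ID={g.gene_id};product={_gff_escape(g.product)}"
                fh.write(
                    f"{g.replicon_id}\tattenuscan-sim\tgene\t{g.start}\t{g.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )
    with open(os.path.join(outdir, "families.tsv"), "w") as fh:
        fh.write("gene_id\tspecies_id\tfamily_id\n")
        for gene, fam in sorted(cohort.family_map.gene_to_family.items()):
            fh.write(f"{gene}\t{cohort.family_map.gene_to_species[gene]}\t{fam}\n")
    with open(os.path.join(outdir, "species_order.txt"), "w") as fh:
        for sp in cohort.species_order.order:
            fh.write(sp + "\n")
    cohort.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
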