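"""Synthetic multi-species cohorts with planted ground truth.

Generates annotated genomes that look like the screen's real inputs — iid
background sequence at a chosen GC, genes with intergenic gaps, gene families
assigned round-robin across species — with terminators planted at known
coordinates:

* 5' attenuator plants upstream of target genes, placed to satisfy the
  attenuator filters (close to the start codon, closer to it than to the
  upstream gene);
* labeled *violator* plants that each break exactly one filter (distance,
  ratio or strand), for filter-soundness tests;
* 3' terminator plants after genes, drawn with a longer mean stem than the 5'
  plants so the 5'-vs-3' stability contrast has a known sign;
* an *enriched* gene family planted in a block of consecutive species, so the
  phylogeny-aware family score has a known winner;
* insertion-sequence (IS) cassettes: transposase genes that all carry copies
  of one shared leader template, emulating a mobile attenuator spread by
  transposition.

Plants that share a template (the enriched family, each IS group) have
identical leader motifs and must co-cluster; everything is reproducible
byte-for-byte from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .energy import hairpin_delta_g
from .genome import GeneRecord, GenomeAnnotation, Replicon, reverse_complement
from .enrichment import FamilyMap, SpeciesOrder

__all__ = ["SyntheticSpec", "Cohort", "plant_terminator", "generate_cohort",
           "training_alignment"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticSpec:
    n_species: int = 10
    genes_per_species: int = 300
    n_families: int = 50
    background_gc: float = 0.5
    intergenic_len: tuple[int, int] = (50, 400)
    gene_len: tuple[int, int] = (300, 900)
    minus_strand_frac: float = 0.3
    # 5' plants (class 5p): strong attenuator-like terminators
    n_5p_plants: int = 200
    stem_len_5p: tuple[float, float] = (8.0, 1.0)  # mean, sd (bp)
    stem_len_3p: tuple[float, float] = (9.0, 1.0)  # default: 5' mean + 1
    stem_gc: float = 0.8
    tail_t_count: int = 12
    loop_len: int = 4
    plant_3p_all: bool = True
    n_3p_plants: int | None = None  # cap; None plants after every gene that fits
    # enrichment structure
    enriched_family: str = "F000"
    enriched_species: int = 8  # plants in this many *consecutive* species
    enriched_per_species: int = 3
    # mobile elements: one shared IS leader template, this many copies
    n_is_elements: int = 5
    # labeled filter violators: (distance, ratio, strand)
    n_violators: tuple[int, int, int] = (4, 4, 4)
    n_absorbed_orfs: int = 5  # short hypothetical ORFs per species
    seed: int = 1

    def __post_init__(self) -> None:
        for frac in (self.background_gc, self.stem_gc, self.minus_strand_frac):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        for mean, _sd in (self.stem_len_5p, self.stem_len_3p):
            if not 4 <= mean <= 18:
                raise ValueError("stem-length means must lie in [4, 18]")
        if self.enriched_species > self.n_species:
            raise ValueError("enriched_species exceeds n_species")


@dataclass
class Cohort:
    spec: SyntheticSpec
    annotations: list[GenomeAnnotation]
    family_map: FamilyMap
    species_order: SpeciesOrder
    truth: pd.DataFrame

    def annotation(self, species_id: str) -> GenomeAnnotation:
        for a in self.annotations:
            if a.species_id == species_id:
                return a
        raise KeyError(species_id)

    def write(self, outdir) -> None:
        from .io import write_cohort

        write_cohort(self, outdir)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def _seq_str(arr: np.ndarray) -> str:
    return "".join(_BASES[arr])


def random_motif(
    rng: np.random.Generator,
    stem_len: int,
    stem_gc: float,
    tail_t: int,
    loop_len: int = 4,
    spacer_len: int | None = None,
) -> dict:
    """Draw one terminator motif (stem5 + loop + revcomp(stem5) + spacer +
    12-nt tail) as a dict of parts."""
    if stem_len < 4:
        raise ValueError("plants below the 4-bp descriptor minimum are disallowed")
    pair_pool_gc = ["G", "C"]
    pair_pool_at = ["A", "T"]
    stem5 = "".join(
        rng.choice(pair_pool_gc if rng.random() < stem_gc else pair_pool_at)
        for _ in range(stem_len)
    )
    loop = _seq_str(_random_seq(rng, loop_len, 0.5))
    sp_len = int(rng.integers(0, 3)) if spacer_len is None else spacer_len
    spacer = _seq_str(_random_seq(rng, sp_len, 0.5))
    tail = ["T"] * 3 + [""] * 9
    extra = min(max(tail_t - 3, 0), 9)
    t_pos = list(rng.choice(9, size=extra, replace=False))
    for i in range(9):
        tail[3 + i] = "T" if i in t_pos else str(rng.choice(["A", "C", "G"]))
    tail_s = "".join(tail)
    stem3 = reverse_complement(stem5)
    return {
        "stem5": stem5,
        "loop": loop,
        "stem3": stem3,
        "spacer": spacer,
        "tail": tail_s,
        "seq": stem5 + loop + stem3 + spacer + tail_s,
        "stem_len": stem_len,
        "loop_len": loop_len,
        "spacer_len": sp_len,
        "expected_dg": hairpin_delta_g(stem5, stem3, loop_len),
    }


def plant_terminator(
    seq: np.ndarray,
    pos: int,
    motif: dict,
    strand: str = "+",
    occupied: list[tuple[int, int]] | None = None,
) -> dict:
    """Write a motif into the (mutable, coded) sequence array at 0-based
    ``pos`` on the given strand; returns a truth record with 1-based forward
    coordinates.  Raises if the motif does not fit or overlaps a previously
    planted interval registered in ``occupied``."""
    m = motif["seq"] if strand == "+" else reverse_complement(motif["seq"])
    if pos < 0 or pos + len(m) > len(seq):
        raise ValueError("insufficient room for the planted motif")
    iv = (pos, pos + len(m) - 1)
    if occupied is not None:
        for lo, hi in occupied:
            if iv[0] <= hi and lo <= iv[1]:
                raise ValueError(f"plant at {pos} overlaps existing plant [{lo},{hi}]")
        occupied.append(iv)
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    seq[pos : pos + len(m)] = [code[c] for c in m]

    s, l, spl = motif["stem_len"], motif["loop_len"], motif["spacer_len"]
    if strand == "+":
        stem5 = (pos + 1, pos + s)
        stem3 = (pos + s + l + 1, pos + 2 * s + l)
        tail = (pos + 2 * s + l + spl + 1, pos + len(m))
    else:
        hi = pos + len(m)  # 1-based end
        stem5 = (hi - s + 1, hi)
        stem3 = (hi - 2 * s - l + 1, hi - s - l)
        tail = (pos + 1, pos + 12)
    return {
        "strand": strand,
        "motif_lo": pos + 1,
        "motif_hi": pos + len(m),
        "stem5_lo": stem5[0],
        "stem5_hi": stem5[1],
        "stem3_lo": stem3[0],
        "stem3_hi": stem3[1],
        "tail_lo": tail[0],
        "tail_hi": tail[1],
        "stem_len": s,
        "loop_len": l,
        "spacer_len": spl,
        "expected_dg": motif["expected_dg"],
    }


def _draw_stem_len(rng: np.random.Generator, mean_sd: tuple[float, float]) -> int:
    mean, sd = mean_sd
    return int(np.clip(round(rng.normal(mean, sd)), 4, 18))


class _SpeciesLayout:
    """Gene/gap layout of one synthetic replicon, with plant bookkeeping."""

    def __init__(self, spec: SyntheticSpec, sp_idx: int, rng: np.random.Generator):
        self.spec = spec
        self.sp_idx = sp_idx
        self.species_id = f"sp{sp_idx:02d}"
        self.rng = rng
        lo_g, hi_g = spec.gene_len
        lo_i, hi_i = spec.intergenic_len
        n = spec.genes_per_species
        glens = rng.integers(lo_g, hi_g + 1, size=n)
        gaps = rng.integers(lo_i, hi_i + 1, size=n + 1)
        strands = np.where(rng.random(n) < spec.minus_strand_frac, "-", "+")
        starts = np.zeros(n, dtype=int)
        pos = 1
        self.genes: list[GeneRecord] = []
        for i in range(n):
            pos += gaps[i]
            starts[i] = pos
            fam = f"F{i % spec.n_families:03d}"
            self.genes.append(
                GeneRecord(
                    gene_id=f"{self.species_id}_g{i:04d}",
                    replicon_id=f"{self.species_id}_chr",
                    start=int(pos),
                    end=int(pos + glens[i] - 1),
                    strand=str(strands[i]),
                    product=f"{fam} protein",
                )
            )
            pos += glens[i]
        self.length = pos + int(gaps[n]) - 1
        self.seq = _random_seq(rng, self.length, spec.background_gc)
        self.family: dict[str, str] = {
            g.gene_id: f"F{i % spec.n_families:03d}" for i, g in enumerate(self.genes)
        }
        # occupied planted intervals per gap index (gap i precedes gene i)
        self.occupied: dict[int, list[tuple[int, int]]] = {}
        self.truth_rows: list[dict] = []
        self.absorbed: list[GeneRecord] = []

    def gap_interval(self, gap_idx: int) -> tuple[int, int]:
        """1-based inclusive interval of gap ``gap_idx`` (before gene
        ``gap_idx``; gap n is after the last gene)."""
        n = len(self.genes)
        lo = 1 if gap_idx == 0 else self.genes[gap_idx - 1].end + 1
        hi = self.length if gap_idx == n else self.genes[gap_idx].start - 1
        return lo, hi

    def upstream_gap(self, gene_idx: int) -> int:
        return gene_idx if self.genes[gene_idx].strand == "+" else gene_idx + 1

    def downstream_gap(self, gene_idx: int) -> int:
        return gene_idx + 1 if self.genes[gene_idx].strand == "+" else gene_idx

    def _try_place(self, gap_idx: int, mlen: int, d_down_range, gene_idx: int):
        """Choose a motif placement in the 5' gap of gene ``gene_idx`` with
        d_down drawn from ``d_down_range`` and d_up >= d_down; returns the
        0-based motif start or None."""
        lo, hi = self.gap_interval(gap_idx)
        g = self.genes[gene_idx]
        occ = self.occupied.setdefault(gap_idx, [])
        lo_d, hi_d = d_down_range
        for _ in range(8):
            if hi_d < lo_d:
                return None
            d_down = int(self.rng.integers(lo_d, hi_d + 1))
            if g.strand == "+":
                tail_end = g.start - 1 - d_down  # 1-based
                start0 = tail_end - mlen  # 0-based motif start
                iv = (start0, start0 + mlen - 1)
                if start0 + 1 < lo:
                    continue
            else:
                motif_lo = g.end + 1 + d_down  # 1-based motif start (fwd)
                start0 = motif_lo - 1
                iv = (start0, start0 + mlen - 1)
                if iv[1] + 1 > hi:
                    continue
            if any(iv[0] <= h and l <= iv[1] for l, h in occ):
                continue
            return start0
        return None

    def plant_5p(
        self, gene_idx: int, motif: dict, klass: str, group: str, violation: str = ""
    ) -> bool:
        """Plant a 5'-oriented terminator upstream of gene ``gene_idx``.

        For positive truths the placement satisfies d_down <= 300 and
        ratio <= 1; violators break exactly the labeled rule."""
        g = self.genes[gene_idx]
        gap_idx = self.upstream_gap(gene_idx)
        lo, hi = self.gap_interval(gap_idx)
        gap_len = hi - lo + 1
        mlen = len(motif["seq"])
        n = len(self.genes)
        has_upstream = gap_idx >= 1 if g.strand == "+" else gap_idx <= n - 1
        if violation == "distance":
            lo_d, hi_d = 301, gap_len - mlen - 1
        elif violation == "ratio":
            if not has_upstream:  # ratio passes automatically without one
                return False
            # closer to the upstream gene: d_up < d_down <= 300
            lo_d = max(3, (gap_len - mlen) // 2 + 2)
            hi_d = min(300, gap_len - mlen - 2)
        else:
            lo_d = 3
            hi_d = min(150, (gap_len - mlen) // 2 - 1)
        strand = g.strand
        if violation == "strand":
            # needs co-oriented flanks so the flipped hit is 5' for neither
            left = self.genes[gap_idx - 1] if gap_idx > 0 else None
            right = self.genes[gap_idx] if gap_idx < n else None
            if left is None or right is None or left.strand != right.strand:
                return False
            strand = "-" if g.strand == "+" else "+"
        start0 = self._try_place(gap_idx, mlen, (lo_d, hi_d), gene_idx)
        if start0 is None:
            return False
        rec = plant_terminator(
            self.seq, start0, motif, strand=strand,
            occupied=self.occupied.setdefault(gap_idx, []),
        )
        rec.update(
            species=self.species_id,
            replicon=f"{self.species_id}_chr",
            klass=klass,
            target_gene=g.gene_id,
            family=self.family[g.gene_id],
            violation=violation,
            group=group,
        )
        self.truth_rows.append(rec)
        return True

    def plant_3p(self, gene_idx: int, motif: dict) -> bool:
        """Plant a 3' terminator just downstream of gene ``gene_idx`` (small
        d_up so that, read as a 5' candidate of the next gene, the distance
        ratio fails)."""
        g = self.genes[gene_idx]
        gap_idx = self.downstream_gap(gene_idx)
        lo, hi = self.gap_interval(gap_idx)
        mlen = len(motif["seq"])
        occ = self.occupied.setdefault(gap_idx, [])
        for _ in range(6):
            d_up = int(self.rng.integers(2, 11))
            if g.strand == "+":
                start0 = g.end + d_up  # 0-based: g.end 1-based + gap offset
                iv = (start0, start0 + mlen - 1)
                if iv[1] + 1 > hi:
                    continue
                d_rest = hi - (iv[1] + 1)  # distance to gap end
            else:
                end1 = g.start - 1 - d_up  # 1-based motif end
                start0 = end1 - mlen
                iv = (start0, start0 + mlen - 1)
                if start0 + 1 < lo:
                    continue
                d_rest = start0 + 1 - lo
            if d_rest <= d_up + 2:  # keep ratio > 1 toward the next gene
                continue
            if any(iv[0] <= h and l <= iv[1] for l, h in occ):
                continue
            rec = plant_terminator(self.seq, start0, motif, strand=g.strand,
                                   occupied=occ)
            rec.update(
                species=self.species_id,
                replicon=f"{self.species_id}_chr",
                klass="3p",
                target_gene=g.gene_id,
                family=self.family[g.gene_id],
                violation="",
                group="",
            )
            self.truth_rows.append(rec)
            return True
        return False

    def add_absorbed_orfs(self, n: int) -> None:
        """Drop short hypothetical ORFs into gaps without plants (annotation
        only; they are absorbed into search regions)."""
        big = [
            i for i in range(len(self.genes) + 1)
            if self.gap_interval(i)[1] - self.gap_interval(i)[0] > 220
            and not self.occupied.get(i)
        ]
        big = [int(x) for x in self.rng.permutation(big)]
        for k, gap_idx in enumerate(big[:n]):
            lo, hi = self.gap_interval(gap_idx)
            olen = int(self.rng.integers(60, 190))
            start = int(self.rng.integers(lo, hi - olen))
            self.absorbed.append(
                GeneRecord(
                    gene_id=f"{self.species_id}_sorf{k:02d}",
                    replicon_id=f"{self.species_id}_chr",
                    start=start,
                    end=start + olen - 1,
                    strand="+" if self.rng.random() < 0.5 else "-",
                    product="hypothetical protein",
                    hypothetical=True,
                )
            )
            # keep plants out of this gap from now on
            self.occupied.setdefault(gap_idx, []).append((start - 1, start + olen - 2))

    def to_annotation(self) -> GenomeAnnotation:
        rep = Replicon(f"{self.species_id}_chr", _seq_str(self.seq))
        return GenomeAnnotation(self.species_id, [rep], list(self.genes) + list(self.absorbed))


def generate_cohort(spec: SyntheticSpec | None = None) -> Cohort:
    """Generate the full multi-species cohort with its truth table."""
    spec = spec or SyntheticSpec()
    root = np.random.SeedSequence(spec.seed)
    sp_seeds = root.spawn(spec.n_species)
    global_rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(999,)))

    layouts = [
        _SpeciesLayout(spec, i, np.random.default_rng(sp_seeds[i]))
        for i in range(spec.n_species)
    ]

    # shared leader templates: enriched family and the IS element
    tmpl_rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(1000,)))
    enr_motif = random_motif(
        tmpl_rng, _draw_stem_len(tmpl_rng, spec.stem_len_5p), spec.stem_gc,
        spec.tail_t_count, spec.loop_len,
    )
    is_motif = random_motif(
        tmpl_rng, _draw_stem_len(tmpl_rng, spec.stem_len_5p), spec.stem_gc,
        spec.tail_t_count, spec.loop_len,
    )

    n_5p = 0
    enr_idx = int(spec.enriched_family[1:])
    # 1) enriched family: plants in consecutive species 0..enriched_species-1
    for lay in layouts[: spec.enriched_species]:
        members = [
            i for i in range(spec.genes_per_species)
            if i % spec.n_families == enr_idx
        ]
        members = [int(x) for x in lay.rng.permutation(members)]
        planted = 0
        for gi in members:
            if planted >= spec.enriched_per_species or n_5p >= spec.n_5p_plants:
                break
            if lay.plant_5p(gi, enr_motif, "5p", group="ENR"):
                planted += 1
                n_5p += 1

    # 2) IS cassettes: transposase genes carrying the shared IS leader
    is_done = 0
    attempts = 0
    while is_done < spec.n_is_elements and attempts < 50 * max(1, spec.n_is_elements):
        attempts += 1
        lay = layouts[int(global_rng.integers(len(layouts)))]
        gi = int(global_rng.integers(spec.genes_per_species))
        g = lay.genes[gi]
        if gi % spec.n_families == enr_idx or g.product.startswith("IS"):
            continue
        if any(r["target_gene"] == g.gene_id for r in lay.truth_rows):
            continue
        if lay.plant_5p(gi, is_motif, "IS", group="IS"):
            lay.genes[gi] = replace(g, product="IS3 family transposase")
            lay.family[g.gene_id] = "FIS"
            is_done += 1

    # 3) random singleton 5' plants up to the requested total
    attempts = 0
    while n_5p < spec.n_5p_plants and attempts < 100 * spec.n_5p_plants:
        attempts += 1
        lay = layouts[int(global_rng.integers(len(layouts)))]
        gi = int(global_rng.integers(spec.genes_per_species))
        g = lay.genes[gi]
        if any(r["target_gene"] == g.gene_id for r in lay.truth_rows):
            continue
        motif = random_motif(
            lay.rng, _draw_stem_len(lay.rng, spec.stem_len_5p), spec.stem_gc,
            spec.tail_t_count, spec.loop_len,
        )
        if lay.plant_5p(gi, motif, "5p", group=""):
            n_5p += 1
    if n_5p < spec.n_5p_plants:
        raise ValueError(
            f"layout infeasible: placed {n_5p} of {spec.n_5p_plants} 5' plants"
        )

    # 4) labeled violators
    for violation, count in zip(("distance", "ratio", "strand"), spec.n_violators):
        done = 0
        attempts = 0
        while done < count and attempts < 300 * max(1, count):
            attempts += 1
            lay = layouts[int(global_rng.integers(len(layouts)))]
            gi = int(global_rng.integers(spec.genes_per_species))
            g = lay.genes[gi]
            if any(r["target_gene"] == g.gene_id for r in lay.truth_rows):
                continue
            motif = random_motif(
                lay.rng, _draw_stem_len(lay.rng, spec.stem_len_5p), spec.stem_gc,
                spec.tail_t_count, spec.loop_len,
            )
            if lay.plant_5p(gi, motif, "violator", group="", violation=violation):
                done += 1

    # 5) 3' terminators after (ideally) every gene, or a capped random subset
    if spec.plant_3p_all:
        slots = [
            (si, gi)
            for si in range(spec.n_species)
            for gi in range(spec.genes_per_species)
        ]
        if spec.n_3p_plants is not None:
            slots = [slots[int(i)] for i in global_rng.permutation(len(slots))]
        n_3p = 0
        for si, gi in slots:
            if spec.n_3p_plants is not None and n_3p >= spec.n_3p_plants:
                break
            lay = layouts[si]
            motif = random_motif(
                lay.rng, _draw_stem_len(lay.rng, spec.stem_len_3p), spec.stem_gc,
                spec.tail_t_count, spec.loop_len,
            )
            n_3p += lay.plant_3p(gi, motif)

    # 6) absorbed short ORFs (annotation only)
    for lay in layouts:
        lay.add_absorbed_orfs(spec.n_absorbed_orfs)

    annotations = [lay.to_annotation() for lay in layouts]
    g2f: dict[str, str] = {}
    g2s: dict[str, str] = {}
    for lay in layouts:
        for g in lay.genes:
            g2f[g.gene_id] = lay.family[g.gene_id]
            g2s[g.gene_id] = lay.species_id
    fam = FamilyMap(g2f, g2s)
    order = SpeciesOrder([lay.species_id for lay in layouts])

    rows = []
    eid = 0
    for lay in layouts:
        for r in lay.truth_rows:
            r = dict(r)
            r["element_id"] = f"t{eid:05d}"
            eid += 1
            rows.append(r)
    cols = [
        "element_id", "species", "replicon", "klass", "strand", "motif_lo",
        "motif_hi", "stem5_lo", "stem5_hi", "stem3_lo", "stem3_hi", "tail_lo",
        "tail_hi", "stem_len", "loop_len", "spacer_len", "expected_dg",
        "target_gene", "family", "violation", "group",
    ]
    truth = pd.DataFrame(rows, columns=cols)
    return Cohort(spec, annotations, fam, order, truth)


def training_alignment(
    n: int = 60,
    seed: int = 0,
    stem_len: tuple[float, float] = (8.0, 1.0),
    stem_gc: float = 0.8,
    tail_t: int = 12,
    loop_len: int = 4,
) -> MultipleSeqAlignment:
    """A structure-annotated alignment of planted terminator motifs, for
    training the profile scanner.  Variable-length stems are gapped on their
    outer side (loop-proximal pairs aligned), the spacer on its 5' side."""
    rng = np.random.default_rng(seed)
    motifs = [
        random_motif(rng, _draw_stem_len(rng, stem_len), stem_gc, tail_t, loop_len)
        for _ in range(n)
    ]
    S = max(m["stem_len"] for m in motifs)
    P = 2  # spacer columns
    recs = []
    for i, m in enumerate(motifs):
        s = m["stem_len"]
        row = (
            "-" * (S - s) + m["stem5"] + m["loop"] + m["stem3"] + "-" * (S - s)
            + "-" * (P - m["spacer_len"]) + m["spacer"] + m["tail"]
        )
        recs.append(SeqRecord(Seq(row), id=f"train{i:03d}", description=""))
    aln = MultipleSeqAlignment(recs)
    aln.column_annotations["secondary_structure"] = (
        "<" * S + "." * loop_len + ">" * S + "." * (P + 12)
    )
    return aln
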