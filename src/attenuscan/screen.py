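"""From terminator hits to attenuator candidates.

A terminator hit in an intergenic region becomes an attenuator candidate when
it sits in the 5' leader of the downstream gene, in that gene's orientation,
close to its start codon (<= 300 nt) and closer to it than to the upstream
gene (distance ratio <= 1:1).  These filters remove canonical 3' terminators
of the upstream gene and terminators of undetected intergenic non-coding
RNAs.  For each candidate the putative leader sequence is extracted (from the
upstream-gene boundary, capped at 200 nt before the stem, to just past the
terminator) for downstream clustering.

The module also provides the 5'-vs-3' stability comparison and the
dinucleotide-shuffle false-positive control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genome import GenomeAnnotation, SearchRegion, reverse_complement
from .scan import DescriptorParams, TerminatorHit, scan_descriptor, scan_region
from .shuffle import dinucleotide_shuffle

__all__ = [
    "AttenuatorCandidate",
    "UtrStatsReport",
    "ShuffleReport",
    "classify_hits",
    "apply_attenuator_filters",
    "filter_with_reasons",
    "extract_candidate_sequence",
    "compare_utr_stats",
    "estimate_false_positive_rate",
    "screen_genome",
]


@dataclass
class AttenuatorCandidate:
    hit: TerminatorHit
    downstream_gene_id: str
    upstream_gene_id: str | None
    d_down: int  # tail 3' end -> base before the start codon (exclusive count)
    d_up: int  # stem 5' start -> nearest upstream-gene boundary, floored at 1
    ratio: float
    leader_interval: tuple[int, int] = (0, 0)  # forward coordinates
    leader_seq: str = ""

    @property
    def candidate_id(self) -> str:
        lo, hi = self.hit.span
        return f"{self.hit.replicon_id}:{lo}-{hi}({self.hit.strand})"


@dataclass
class UtrStatsReport:
    n5: int
    n3: int
    mean_dg5: float
    mean_dg3: float
    mean_stem5: float
    mean_stem3: float
    p_dg: float | None
    p_stem: float | None


@dataclass
class ShuffleReport:
    n_shuffles: int
    fp_rate_5utr: float
    fp_rate_3utr: float
    observed_rate: float
    seed: int


def classify_hits(
    hits: list[TerminatorHit],
    region: SearchRegion,
    ann: GenomeAnnotation,
) -> list[TerminatorHit]:
    """Set ``utr_class`` for each hit relative to the region's flanking genes.

    A hit is *five_prime* when it points toward a flanking gene on its own
    strand (right gene for "+", left gene for "-"); failing that it is
    *three_prime* when it follows the 3' end of a co-oriented flanking gene;
    otherwise *unassigned*.  The relevant gene ids are recorded on the hit.
    """
    left = ann.gene(region.left_gene_id) if region.left_gene_id else None
    right = ann.gene(region.right_gene_id) if region.right_gene_id else None
    for h in hits:
        down = right if h.strand == "+" else left
        up = left if h.strand == "+" else right
        if down is not None and down.strand == h.strand:
            h.utr_class = "five_prime"
            h.downstream_gene_id = down.gene_id
            h.upstream_gene_id = up.gene_id if up else None
        elif up is not None and up.strand == h.strand:
            h.utr_class = "three_prime"
            h.upstream_gene_id = up.gene_id
            h.downstream_gene_id = down.gene_id if down else None
        else:
            h.utr_class = "unassigned"
            h.downstream_gene_id = down.gene_id if down else None
            h.upstream_gene_id = up.gene_id if up else None
    return hits


def _distances(h: TerminatorHit, ann: GenomeAnnotation) -> tuple[int, int | None]:
    """(d_down, d_up) in forward coordinates for a five_prime hit."""
    down = ann.gene(h.downstream_gene_id)
    if h.strand == "+":
        tail_end = h.tail[1]
        d_down = down.start - tail_end - 1
        stem5_start = h.stem5[0]
        if h.upstream_gene_id:
            up = ann.gene(h.upstream_gene_id)
            d_up = max(1, stem5_start - up.end - 1)
        else:
            d_up = None
    else:
        tail_end = h.tail[0]
        d_down = tail_end - down.end - 1
        stem5_start = h.stem5[1]
        if h.upstream_gene_id:
            up = ann.gene(h.upstream_gene_id)
            d_up = max(1, up.start - stem5_start - 1)
        else:
            d_up = None
    return d_down, d_up


def filter_with_reasons(
    hits: list[TerminatorHit],
    ann: GenomeAnnotation,
    max_dist: int = 300,
) -> tuple[list[AttenuatorCandidate], list[tuple[TerminatorHit, str]]]:
    """Apply the attenuator filters, recording why each hit was rejected.

    Reasons: ``strand`` (not a 5'-oriented hit), ``distance`` (further than
    ``max_dist`` from the downstream start codon), ``ratio`` (closer to the
    upstream gene than to the downstream one).
    """
    kept: list[AttenuatorCandidate] = []
    rejected: list[tuple[TerminatorHit, str]] = []

    def demote(h: TerminatorHit) -> None:
        # a 5'-oriented hit that fails the filters is, in the end, a plain
        # terminator; call it 3' when it follows a co-oriented upstream gene
        if h.upstream_gene_id and ann.gene(h.upstream_gene_id).strand == h.strand:
            h.utr_class = "three_prime"

    for h in hits:
        if h.utr_class != "five_prime":
            rejected.append((h, "strand"))
            continue
        d_down, d_up = _distances(h, ann)
        if d_down > max_dist or d_down < 0:
            demote(h)
            rejected.append((h, "distance"))
            continue
        ratio = d_down / d_up if d_up is not None else 0.0
        if d_up is not None and ratio > 1.0:
            demote(h)
            rejected.append((h, "ratio"))
            continue
        kept.append(
            AttenuatorCandidate(
                hit=h,
                downstream_gene_id=h.downstream_gene_id,
                upstream_gene_id=h.upstream_gene_id,
                d_down=d_down,
                d_up=d_up if d_up is not None else max_dist + 1,
                ratio=ratio,
            )
        )
    return kept, rejected


def apply_attenuator_filters(
    hits: list[TerminatorHit], ann: GenomeAnnotation, max_dist: int = 300
) -> list[AttenuatorCandidate]:
    return filter_with_reasons(hits, ann, max_dist)[0]


def extract_candidate_sequence(
    cand: AttenuatorCandidate, ann: GenomeAnnotation, cap: int = 200
) -> str:
    """Extract the candidate leader: from the upstream-gene boundary — or at
    most ``cap`` nt 5' of the stem — to the position immediately 3' of the
    terminator, reported 5'->3' on the candidate strand."""
    h = cand.hit
    rep = ann.replicon(h.replicon_id)
    if h.strand == "+":
        start = h.stem5[0] - cap
        if cand.upstream_gene_id:
            start = max(start, ann.gene(cand.upstream_gene_id).end + 1)
        start = max(start, 1)
        end = min(h.tail[1] + 1, len(rep))
        down = ann.gene(cand.downstream_gene_id)
        end = min(end, down.start - 1)
        seq = rep.fetch(start, end)
    else:
        end = h.stem5[1] + cap
        if cand.upstream_gene_id:
            end = min(end, ann.gene(cand.upstream_gene_id).start - 1)
        end = min(end, len(rep))
        start = max(h.tail[0] - 1, 1)
        down = ann.gene(cand.downstream_gene_id)
        start = max(start, down.end + 1)
        seq = reverse_complement(rep.fetch(start, end))
    cand.leader_interval = (start, end)
    cand.leader_seq = seq
    return seq


def compare_utr_stats(
    hits5: list[TerminatorHit], hits3: list[TerminatorHit]
) -> UtrStatsReport:
    """Mean folding free energy and stem length of 5' vs 3' terminators, with
    two-sided Welch t-tests.  The expectation for genuine attenuators is that
    5' terminators are less stable (less negative ΔG, shorter stems): they
    must be able to fold alternatively into a readthrough structure."""
    if not hits5 or not hits3:
        raise ValueError("both hit lists must be non-empty")
    dg5 = np.array([h.delta_g for h in hits5])
    dg3 = np.array([h.delta_g for h in hits3])
    st5 = np.array([h.stem_len for h in hits5], dtype=float)
    st3 = np.array([h.stem_len for h in hits3], dtype=float)
    p_dg = p_stem = None
    if len(dg5) >= 2 and len(dg3) >= 2:
        p_dg = float(stats.ttest_ind(dg5, dg3, equal_var=False).pvalue)
        p_stem = float(stats.ttest_ind(st5, st3, equal_var=False).pvalue)
    return UtrStatsReport(
        n5=len(dg5),
        n3=len(dg3),
        mean_dg5=float(dg5.mean()),
        mean_dg3=float(dg3.mean()),
        mean_stem5=float(st5.mean()),
        mean_stem3=float(st3.mean()),
        p_dg=p_dg,
        p_stem=p_stem,
    )


def _any_hit(seq: str, model, params: DescriptorParams) -> bool:
    """Two-pass detection (profile first, descriptor fallback) on both
    strands of a raw sequence."""
    for s in (seq, reverse_complement(seq)):
        if model is not None:
            from .profile import scan_profile

            if scan_profile(s, model, params):
                return True
        if scan_descriptor(s, params):
            return True
    return False


def estimate_false_positive_rate(
    regions: list[SearchRegion],
    ann: GenomeAnnotation,
    model=None,
    params: DescriptorParams | None = None,
    n_shuffles: int = 100,
    seed: int = 0,
    region_classes: dict[int, str] | None = None,
) -> ShuffleReport:
    """Detection rate on dinucleotide-shuffled copies of each region.

    Every region is shuffled ``n_shuffles`` times; the false-positive rate is
    the fraction of shuffles with at least one hit, averaged over regions.
    ``region_classes`` optionally maps region index -> "5" / "3" to report the
    two UTR classes separately (both equal the pooled rate otherwise).
    """
    if not regions:
        raise ValueError("no regions given")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    params = params or DescriptorParams()
    rates: list[float] = []
    observed: list[float] = []
    for ridx, region in enumerate(regions):
        seq = region.sequence(ann)
        observed.append(float(_any_hit(seq, model, params)))
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(ridx,)))
        n_pos = 0
        for _ in range(n_shuffles):
            n_pos += _any_hit(dinucleotide_shuffle(seq, rng), model, params)
        rates.append(n_pos / n_shuffles)
    rates_arr = np.array(rates)
    if region_classes:
        i5 = [i for i in range(len(regions)) if region_classes.get(i) == "5"]
        i3 = [i for i in range(len(regions)) if region_classes.get(i) == "3"]
        fp5 = float(rates_arr[i5].mean()) if i5 else float(rates_arr.mean())
        fp3 = float(rates_arr[i3].mean()) if i3 else float(rates_arr.mean())
    else:
        fp5 = fp3 = float(rates_arr.mean())
    return ShuffleReport(
        n_shuffles=n_shuffles,
        fp_rate_5utr=fp5,
        fp_rate_3utr=fp3,
        observed_rate=float(np.mean(observed)),
        seed=seed,
    )


def screen_genome(
    ann: GenomeAnnotation,
    model=None,
    params: DescriptorParams | None = None,
    max_dist: int = 300,
    cap: int = 200,
    short_orf_max: int = 200,
):
    """Full per-genome screen: regions -> hits -> classification -> filters ->
    leader extraction.  Returns (candidates, all classified hits, rejections).
    """
    from .genome import extract_search_regions

    params = params or DescriptorParams()
    candidates: list[AttenuatorCandidate] = []
    all_hits: list[TerminatorHit] = []
    rejections: list[tuple[TerminatorHit, str]] = []
    for region in extract_search_regions(ann, short_orf_max=short_orf_max):
        hits = scan_region(region, ann, model=model, params=params)
        hits = classify_hits(hits, region, ann)
        all_hits.extend(hits)
        kept, rej = filter_with_reasons(hits, ann, max_dist=max_dist)
        rejections.extend(rej)
        for cand in kept:
            extract_candidate_sequence(cand, ann, cap=cap)
            candidates.append(cand)
    return candidates, all_hits, rejections
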