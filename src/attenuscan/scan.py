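"""Descriptor-based detection of Rho-independent terminator motifs.

A Rho-independent (intrinsic) terminator is a stable RNA hairpin immediately
followed by a U-rich stretch.  The descriptor follows the canonical intrinsic
terminator geometry of Lesnik et al. (2001) NAR 29:3583: a 4-18 bp helix
(Watson-Crick plus GU wobble), a 3-10 nt loop, a 0-2 nt spacer and a 12-nt
T-rich tail (>= 7 T overall, >= 3 T among the first 5), with the hairpin
required to be thermodynamically stable (nearest-neighbor ΔG at most
``max_dg`` kcal/mol, default -6.0).

All coordinates on a scanned sequence are 1-based inclusive in scan
orientation; ``scan_region`` maps hits back to forward replicon coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .energy import default_energy_model, hairpin_delta_g, pairs_allowed
from .genome import GenomeAnnotation, SearchRegion, reverse_complement

__all__ = ["DescriptorParams", "TerminatorHit", "scan_descriptor", "scan_region",
           "resolve_overlaps"]


@dataclass(frozen=True)
class DescriptorParams:
    stem_min: int = 4
    stem_max: int = 18
    spacer_min: int = 0
    spacer_max: int = 2
    tail_len: int = 12
    loop_min: int = 3
    loop_max: int = 10
    tail_min_t: int = 7
    tail_head_min_t: int = 3  # of the first 5 tail positions
    allow_gu: bool = True
    allow_bulge: bool = False
    max_dg: float = -6.0  # kcal/mol; hairpin must be at least this stable

    def __post_init__(self) -> None:
        if not (1 <= self.stem_min <= self.stem_max):
            raise ValueError("need 1 <= stem_min <= stem_max")
        if not (0 <= self.spacer_min <= self.spacer_max):
            raise ValueError("need 0 <= spacer_min <= spacer_max")
        if not (self.tail_min_t <= self.tail_len):
            raise ValueError("tail_min_t must not exceed tail_len")
        if self.loop_min < 3:
            raise ValueError("loops below 3 nt are sterically impossible")

    @property
    def min_motif_len(self) -> int:
        return 2 * self.stem_min + self.loop_min + self.spacer_min + self.tail_len


@dataclass
class TerminatorHit:
    """A located hairpin + tail.  Intervals are 1-based inclusive (lo, hi)
    tuples.  On a raw sequence scan they refer to the scanned sequence; after
    ``scan_region`` they are forward replicon coordinates and ``stem5`` is the
    arm that is 5' in transcript orientation (higher coordinates than
    ``stem3`` on the "-" strand)."""

    replicon_id: str
    strand: str
    stem5: tuple[int, int]
    loop: tuple[int, int]
    stem3: tuple[int, int]
    spacer_len: int
    tail: tuple[int, int]
    stem_len: int
    delta_g: float
    score: float | None = None
    method: str = "descriptor"
    utr_class: str = "unassigned"  # five_prime | three_prime | unassigned
    # filled in during classification against the annotation:
    downstream_gene_id: str | None = None
    upstream_gene_id: str | None = None

    @property
    def span(self) -> tuple[int, int]:
        lo = min(self.stem5[0], self.stem3[0], self.tail[0])
        hi = max(self.stem5[1], self.stem3[1], self.tail[1])
        return lo, hi

    def stem_positions(self) -> set[int]:
        return set(range(self.stem5[0], self.stem5[1] + 1)) | set(
            range(self.stem3[0], self.stem3[1] + 1)
        )

    def key(self) -> tuple:
        return (self.stem5, self.loop, self.stem3, self.spacer_len, self.tail)


def _tail_ok_mask(seq: str, params: DescriptorParams) -> np.ndarray:
    """Boolean mask over 0-based tail start positions satisfying the T rules."""
    n = len(seq)
    tl = params.tail_len
    mask = np.zeros(n, dtype=bool)
    if n < tl or n < 5:
        return mask
    is_t = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("T")
    c = np.concatenate(([0], np.cumsum(is_t)))
    full = c[tl:] - c[:-tl] >= params.tail_min_t
    head = c[5:] - c[:-5] >= params.tail_head_min_t
    nstart = n - tl + 1
    mask[:nstart] = full[:nstart] & head[:nstart]
    return mask


def _make_hit(seq, a, loop, s, sp, t0, params, model) -> TerminatorHit | None:
    """Build a hit for loop starting at 0-based ``a`` (length ``loop``), stem
    length ``s``, spacer ``sp``, tail at 0-based ``t0``; None if too unstable."""
    b = a + loop - 1
    stem5_seq = seq[a - s : a]
    stem3_seq = seq[b + 1 : b + 1 + s]
    dg = hairpin_delta_g(stem5_seq, stem3_seq, loop, model, params.allow_gu)
    if dg > params.max_dg:
        return None
    return TerminatorHit(
        replicon_id="",
        strand="+",
        stem5=(a - s + 1, a),
        loop=(a + 1, b + 1),
        stem3=(b + 2, b + 1 + s),
        spacer_len=sp,
        tail=(t0 + 1, t0 + params.tail_len),
        stem_len=s,
        delta_g=dg,
    )


def _enumerate_hits(seq: str, params: DescriptorParams) -> list[TerminatorHit]:
    """All admissible (stem5, loop, stem3, spacer, tail) decompositions.

    For every loop placement, stems are grown outward pair by pair (the only
    incremental direction); each admissible stem length is then combined with
    every spacer whose tail window passes the T rules.
    """
    n = len(seq)
    hits: list[TerminatorHit] = []
    if n < params.min_motif_len:
        return hits
    if params.allow_bulge:
        return _enumerate_hits_bulged(seq, params)
    allowed = pairs_allowed(params.allow_gu)
    model = default_energy_model()
    tail_ok = _tail_ok_mask(seq, params)
    spacers = range(params.spacer_min, params.spacer_max + 1)

    for a in range(1, n):  # 0-based loop start (needs >= 1 nt to the left)
        for loop in range(params.loop_min, params.loop_max + 1):
            b = a + loop - 1  # loop end
            s = 0
            while s < params.stem_max:
                top, bot = a - 1 - s, b + 1 + s
                if top < 0 or bot >= n or (seq[top], seq[bot]) not in allowed:
                    break
                s += 1
                if s < params.stem_min:
                    continue
                for sp in spacers:
                    t0 = b + s + sp + 1
                    if t0 + params.tail_len <= n and tail_ok[t0]:
                        h = _make_hit(seq, a, loop, s, sp, t0, params, model)
                        if h is not None:
                            hits.append(h)
    return hits


def _enumerate_hits_bulged(seq: str, params: DescriptorParams) -> list[TerminatorHit]:
    """Generic enumeration additionally permitting one single-nt bulge per
    arm (unpaired nucleotide inside an arm, not counted in stem_len).  The
    bulged hairpin's ΔG is approximated by scoring the paired positions as a
    contiguous helix.  Much slower than the bulge-free path; off by default.
    """
    n = len(seq)
    allowed = pairs_allowed(params.allow_gu)
    model = default_energy_model()
    tail_ok = _tail_ok_mask(seq, params)
    spacers = range(params.spacer_min, params.spacer_max + 1)
    found: dict[tuple, TerminatorHit] = {}

    def grow(a, loop, top_next, bot_next, b5_used, b3_used, top_idx, bot_idx):
        # try to add one more pair, with optional single-nt skips
        options = [(top_next, bot_next, b5_used, b3_used)]
        if not b5_used and top_next - 1 >= 0:
            options.append((top_next - 1, bot_next, True, b3_used))
        if not b3_used and bot_next + 1 < n:
            options.append((top_next, bot_next + 1, b5_used, True))
        for t, bt, u5, u3 in options:
            if t < 0 or bt >= n or (seq[t], seq[bt]) not in allowed:
                continue
            ntop, nbot = top_idx + [t], bot_idx + [bt]
            s = len(ntop)
            if s >= params.stem_min:
                record(a, loop, ntop, nbot, u5, u3)
            if s < params.stem_max:
                grow(a, loop, t - 1, bt + 1, u5, u3, ntop, nbot)

    def record(a, loop, top_idx, bot_idx, b5_used, b3_used):
        s = len(top_idx)
        b = a + loop - 1
        arm5 = (top_idx[-1], a - 1)  # 0-based inclusive span incl. bulge
        arm3 = (b + 1, bot_idx[-1])
        stem5_seq = "".join(seq[i] for i in reversed(top_idx))
        stem3_seq = "".join(seq[i] for i in bot_idx)
        try:
            dg = hairpin_delta_g(stem5_seq, stem3_seq, loop, model,
                                 params.allow_gu)
        except ValueError:
            return
        if dg > params.max_dg:
            return
        for sp in spacers:
            t0 = arm3[1] + sp + 1
            if t0 + params.tail_len <= n and tail_ok[t0]:
                h = TerminatorHit(
                    replicon_id="", strand="+",
                    stem5=(arm5[0] + 1, arm5[1] + 1),
                    loop=(a + 1, b + 1),
                    stem3=(arm3[0] + 1, arm3[1] + 1),
                    spacer_len=sp,
                    tail=(t0 + 1, t0 + params.tail_len),
                    stem_len=s, delta_g=dg,
                )
                found.setdefault(h.key(), h)

    for a in range(1, n):
        for loop in range(params.loop_min, params.loop_max + 1):
            b = a + loop - 1
            if b + 1 >= n:
                continue
            grow(a, loop, a - 1, b + 1, False, False, [], [])
    return list(found.values())


def resolve_overlaps(
    hits: list[TerminatorHit], by_score: bool = False
) -> list[TerminatorHit]:
    """Collapse hits sharing any stem position.

    Descriptor mode keeps the lowest-ΔG hit (tie: leftmost, then longest
    stem); profile mode (``by_score``) keeps the highest score (tie: lowest
    ΔG, then leftmost).
    """
    if by_score:
        def key(h):
            return (-(h.score or 0.0), h.delta_g, min(h.stem5[0], h.stem3[0]))
    else:
        def key(h):
            return (h.delta_g, min(h.stem5[0], h.stem3[0]), -h.stem_len)
    taken: set[int] = set()
    kept: list[TerminatorHit] = []
    for h in sorted(hits, key=key):
        pos = h.stem_positions()
        if pos & taken:
            continue
        taken |= pos
        kept.append(h)
    return sorted(kept, key=lambda h: h.span)


def scan_descriptor(seq: str, params: DescriptorParams | None = None) -> list[TerminatorHit]:
    """Find all terminator motifs in ``seq`` (scan orientation, "+")."""
    params = params or DescriptorParams()
    return resolve_overlaps(_enumerate_hits(seq, params))


def _map_hit_to_forward(h: TerminatorHit, region: SearchRegion, strand: str) -> TerminatorHit:
    """Map a hit on the scanned (possibly reverse-complemented) region
    sequence onto forward replicon coordinates."""
    L = region.hi - region.lo + 1

    def fwd(iv: tuple[int, int]) -> tuple[int, int]:
        if strand == "+":
            return (region.lo + iv[0] - 1, region.lo + iv[1] - 1)
        return (region.lo + L - iv[1], region.lo + L - iv[0])

    return replace(
        h,
        replicon_id=region.replicon_id,
        strand=strand,
        stem5=fwd(h.stem5),
        loop=fwd(h.loop),
        stem3=fwd(h.stem3),
        tail=fwd(h.tail),
    )


def scan_region(
    region: SearchRegion,
    ann: GenomeAnnotation,
    model=None,
    params: DescriptorParams | None = None,
) -> list[TerminatorHit]:
    """Scan both strands of a search region with the two-pass strategy.

    Per strand, the trained profile scanner is consulted first when a model is
    given; the descriptor pass is used only when the profile yields no hit on
    that strand.  Hits are returned in forward replicon coordinates.
    """
    params = params or DescriptorParams()
    fwd_seq = region.sequence(ann)
    out: list[TerminatorHit] = []
    for strand, seq in (("+", fwd_seq), ("-", reverse_complement(fwd_seq))):
        hits: list[TerminatorHit] = []
        if model is not None:
            from .profile import scan_profile

            hits = scan_profile(seq, model, params)
        if not hits:
            hits = scan_descriptor(seq, params)
        out.extend(_map_hit_to_forward(h, region, strand) for h in hits)
    return sorted(out, key=lambda h: (h.span, h.strand))
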