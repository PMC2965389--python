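"""Trainable profile scorer for terminator motifs.

A log-odds profile is estimated from a structure-annotated alignment of known
terminators (Stockholm format with a ``#=GC SS_cons`` line): per stem column a
16-way distribution over ordered base pairs, per unpaired column a 4-way base
distribution, both with pseudocounts against a background model.  Scanning
scores every descriptor-admissible hairpin decomposition of a sequence against
the profile (in bits) and reports those above a threshold, so the profile pass
sees exactly the same candidate space as the descriptor pass but ranks it by
sequence similarity to the training set rather than by geometry alone.

Columns are weighted by their occupancy (fraction of training sequences with a
residue in the column), which normalizes candidate stems and loops of varying
length to the profile's span: rarely occupied outer stem columns contribute
proportionally little.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO

from .scan import DescriptorParams, TerminatorHit, resolve_overlaps

__all__ = ["ProfileModel", "train_profile", "scan_profile", "calibrate_threshold"]

_BASES = "ACGT"
_GAP = set("-.~")

_BRACKETS = {"<": ">", "(": ")", "[": "]", "{": "}"}


def _pair_columns(ss: str) -> list[tuple[int, int]]:
    """Paired column indices from a consensus-structure line, outermost first."""
    stacks: dict[str, list[int]] = {b: [] for b in _BRACKETS}
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(ss):
        if c in _BRACKETS:
            stacks[c].append(i)
        else:
            for op, cl in _BRACKETS.items():
                if c == cl:
                    if not stacks[op]:
                        raise ValueError(f"unbalanced structure annotation at column {i}")
                    pairs.append((stacks[op].pop(), i))
    for op, st in stacks.items():
        if st:
            raise ValueError(f"unbalanced structure annotation: unclosed {op!r}")
    return sorted(pairs)


@dataclass
class ProfileModel:
    """Log-odds tables (base 2) plus per-column occupancy weights.

    ``stem_cols``: (S, 16) array over ordered pairs (4*i+j for bases i,j),
    outermost stem column first.  ``loop_cols``/``spacer_cols``/``tail_cols``:
    (L, 4) arrays.  ``*_occ``: occupancy weight per column in [0, 1].
    """

    stem_cols: np.ndarray
    stem_occ: np.ndarray
    loop_cols: np.ndarray
    loop_occ: np.ndarray
    spacer_cols: np.ndarray
    spacer_occ: np.ndarray
    tail_cols: np.ndarray
    tail_occ: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1.0
    score_threshold: float = 10.0
    trained_n: int = 0

    @property
    def stem_span(self) -> int:
        return self.stem_cols.shape[0]


def _col_logodds(counts: np.ndarray, n: float, bg: np.ndarray, pc: float) -> np.ndarray:
    freq = (counts + pc * bg) / (n + pc)
    return np.log2(freq / bg)


def train_profile(
    alignment,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    score_threshold: float | None = None,
) -> ProfileModel:
    """Estimate a ProfileModel from a structure-annotated alignment.

    ``alignment`` is a path / handle to a Stockholm file or a Bio.Align
    MultipleSeqAlignment whose ``column_annotations["secondary_structure"]``
    holds the consensus structure.  Unpaired columns between the innermost
    pair are loop columns; unpaired columns after the last paired column form
    the spacer (all but the last ``tail_len``) and the 12-nt tail.
    """
    if not hasattr(alignment, "column_annotations"):
        alignment = AlignIO.read(alignment, "stockholm")
    if len(alignment) < 1:
        raise ValueError("empty alignment")
    if len(alignment) < 10:
        raise ValueError(f"need >= 10 training sequences, got {len(alignment)}")
    ss = alignment.column_annotations.get("secondary_structure")
    if not ss:
        raise ValueError("alignment lacks a #=GC SS_cons structure line")
    pairs = _pair_columns(ss)
    if not pairs:
        raise ValueError("structure line annotates no base pairs")
    bg = np.asarray(background if background is not None else [0.25] * 4, dtype=float)
    bg = bg / bg.sum()
    pc = float(pseudocount)
    if pc <= 0:
        raise ValueError("pseudocount must be > 0")

    seqs = [str(rec.seq).upper().replace("U", "T") for rec in alignment]
    n = len(seqs)
    b2i = {b: i for i, b in enumerate(_BASES)}

    def column(ci: int) -> list[int]:
        return [b2i[s[ci]] for s in seqs if s[ci] in b2i]

    # stem pair columns, outermost first
    stem_lo = np.zeros((len(pairs), 16))
    stem_occ = np.zeros(len(pairs))
    bg_pair = np.outer(bg, bg).ravel()
    for k, (i, j) in enumerate(pairs):
        obs = [
            4 * b2i[s[i]] + b2i[s[j]] for s in seqs if s[i] in b2i and s[j] in b2i
        ]
        counts = np.bincount(obs, minlength=16).astype(float)
        m = len(obs)
        freq = (counts + pc * bg_pair) / (m + pc)
        stem_lo[k] = np.log2(freq / bg_pair)
        stem_occ[k] = m / n

    last_paired = max(j for _, j in pairs)
    inner_i = max(i for i, _ in pairs)
    inner_j = min(j for _, j in pairs)
    loop_idx = [
        c for c in range(inner_i + 1, inner_j) if ss[c] not in "<>()[]{}"
    ]
    after = [c for c in range(last_paired + 1, len(ss)) if ss[c] not in "<>()[]{}"]
    tail_len = min(12, len(after))
    spacer_idx, tail_idx = after[: len(after) - tail_len], after[len(after) - tail_len :]

    def unpaired_block(cols: list[int]) -> tuple[np.ndarray, np.ndarray]:
        lo = np.zeros((len(cols), 4))
        occ = np.zeros(len(cols))
        for k, c in enumerate(cols):
            obs = column(c)
            counts = np.bincount(obs, minlength=4).astype(float)
            lo[k] = _col_logodds(counts, len(obs), bg, pc)
            occ[k] = len(obs) / n
        return lo, occ

    loop_lo, loop_occ = unpaired_block(loop_idx)
    spacer_lo, spacer_occ = unpaired_block(spacer_idx)
    tail_lo, tail_occ = unpaired_block(tail_idx)

    return ProfileModel(
        stem_cols=stem_lo,
        stem_occ=stem_occ,
        loop_cols=loop_lo,
        loop_occ=loop_occ,
        spacer_cols=spacer_lo,
        spacer_occ=spacer_occ,
        tail_cols=tail_lo,
        tail_occ=tail_occ,
        background=bg,
        pseudocount=pc,
        score_threshold=10.0 if score_threshold is None else float(score_threshold),
        trained_n=n,
    )


def _score_block(cols: np.ndarray, occ: np.ndarray, idxs: list[int], obs: list[int]) -> float:
    """Occupancy-weighted sum of per-column log-odds for observed bases/pairs
    mapped onto profile columns ``idxs``."""
    return float(sum(occ[c] * cols[c, o] for c, o in zip(idxs, obs)))


def _map_linear(k: int, n_from: int, n_to: int) -> int:
    if n_to == 0:
        return 0
    if n_from <= 1:
        return 0
    return min(n_to - 1, (k * n_to) // n_from)


def score_decomposition(
    seq: str, hit: TerminatorHit, model: ProfileModel
) -> float:
    """Profile score (bits) of one hairpin decomposition on a raw sequence.

    Candidate stem pairs are right-justified onto profile stem columns toward
    the loop (outer gaps), matching how variable-length stems are gapped in
    the training alignment; loops map linearly onto the profile's loop span.
    """
    b2i = {b: i for i, b in enumerate(_BASES)}
    s = hit.stem_len
    S = model.stem_span
    score = 0.0
    for k in range(s):  # k = 0 outermost
        a = seq[hit.stem5[0] - 1 + k]
        b = seq[hit.stem3[1] - 1 - k]
        col = max(0, S - s + k) if s <= S else (0 if k < s - S else k - (s - S))
        if a in b2i and b in b2i:
            score += model.stem_occ[col] * model.stem_cols[col, 4 * b2i[a] + b2i[b]]
    loop_seq = seq[hit.loop[0] - 1 : hit.loop[1]]
    L = model.loop_cols.shape[0]
    for k, base in enumerate(loop_seq):
        if base in b2i and L:
            col = _map_linear(k, len(loop_seq), L)
            score += model.loop_occ[col] * model.loop_cols[col, b2i[base]]
    tail_seq = seq[hit.tail[0] - 1 : hit.tail[1]]
    T = model.tail_cols.shape[0]
    for k, base in enumerate(tail_seq):
        if base in b2i and T:
            col = _map_linear(k, len(tail_seq), T)
            score += model.tail_occ[col] * model.tail_cols[col, b2i[base]]
    if model.spacer_cols.shape[0] and hit.spacer_len:
        sp_seq = seq[hit.stem3[1] : hit.stem3[1] + hit.spacer_len]
        P = model.spacer_cols.shape[0]
        for k, base in enumerate(sp_seq):
            if base in b2i:
                col = P - hit.spacer_len + k if hit.spacer_len <= P else _map_linear(k, hit.spacer_len, P)
                if 0 <= col < P:
                    score += model.spacer_occ[col] * model.spacer_cols[col, b2i[base]]
    return score


def scan_profile(
    seq: str, model: ProfileModel, params: DescriptorParams | None = None
) -> list[TerminatorHit]:
    """Profile pass: score every descriptor-admissible decomposition, keep
    those at or above the model threshold, overlap-resolve by score."""
    from .scan import _enumerate_hits

    params = params or DescriptorParams()
    # The profile pass ranks by similarity, not stability: lift the energy
    # cutoff so the profile sees the full geometric candidate space.
    geom = DescriptorParams(
        **{**params.__dict__, "max_dg": 0.0}
    )
    scored: list[TerminatorHit] = []
    for h in _enumerate_hits(seq, geom):
        sc = score_decomposition(seq, h, model)
        if sc >= model.score_threshold:
            h.score = sc
            h.method = "profile"
            scored.append(h)
    return resolve_overlaps(scored, by_score=True)


def calibrate_threshold(
    model: ProfileModel,
    negatives: list[str],
    target_fp_per_kb: float,
    params: DescriptorParams | None = None,
) -> float:
    """Smallest threshold whose hit density on background sequences does not
    exceed ``target_fp_per_kb``.  Monotone: a looser target never raises the
    threshold.  If no hits score at all, the minimum representable threshold
    is returned; if the target cannot be met below the maximum observed score,
    max + 1 is returned with a warning.
    """
    if target_fp_per_kb < 0:
        raise ValueError("target_fp_per_kb must be >= 0")
    params = params or DescriptorParams()
    total_kb = sum(len(s) for s in negatives) / 1000.0
    if total_kb == 0:
        raise ValueError("no negative sequence material")
    open_model = ProfileModel(**{**model.__dict__, "score_threshold": -math.inf})
    scores: list[float] = []
    for s in negatives:
        scores.extend(h.score for h in scan_profile(s, open_model, params))
    if not scores or math.isinf(target_fp_per_kb):
        return -math.inf
    scores.sort()
    # density at threshold tau = #{score >= tau} / total_kb, non-increasing
    # in tau; pick the smallest observed score that satisfies the target.
    import bisect

    for tau in sorted(set(scores)):
        n_ge = len(scores) - bisect.bisect_left(scores, tau)
        if n_ge / total_kb <= target_fp_per_kb:
            return tau
    warnings.warn(
        "false-positive target unreachable below the maximum observed score; "
        "returning max + 1"
    )
    return scores[-1] + 1.0
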