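"""Independent brute-force oracles, written separately from the production
code paths they check."""

from __future__ import annotations

import math

WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
GU = {("G", "T"), ("T", "G")}


def oracle_delta_g(stem5: str, stem3: str, loop_len: int, model) -> float:
    """Re-summation of the nearest-neighbor terms straight from the model's
    tables, by explicit pair-list construction."""
    s = len(stem5)
    pair_list = []
    for k in range(s):
        pair_list.append(stem5[k] + stem3[s - 1 - k])
    total = model.hairpin_loop_dg[min(loop_len, 30)]
    for k in range(len(pair_list) - 1):
        total += model.stack_dg[(pair_list[k], pair_list[k + 1])]
    if pair_list[0] not in ("GC", "CG"):
        total += model.terminal_au_penalty
    return total


def oracle_descriptor_hits(seq: str, params, model) -> list[dict]:
    """Exhaustive enumeration of every (stem5, loop, stem3, spacer, tail)
    decomposition admissible under the descriptor, by direct index
    arithmetic over all (start, stem, loop, spacer) tuples."""
    n = len(seq)
    allowed = WC | GU if params.allow_gu else WC
    out = []
    for i in range(n):
        for s in range(params.stem_min, params.stem_max + 1):
            for l in range(params.loop_min, params.loop_max + 1):
                j = i + s + l  # stem3 start
                if j + s > n:
                    continue
                stem5 = seq[i : i + s]
                stem3 = seq[j : j + s]
                if any((stem5[k], stem3[s - 1 - k]) not in allowed for k in range(s)):
                    continue
                for sp in range(params.spacer_min, params.spacer_max + 1):
                    t = j + s + sp
                    if t + params.tail_len > n:
                        continue
                    tail = seq[t : t + params.tail_len]
                    if tail.count("T") < params.tail_min_t:
                        continue
                    if tail[:5].count("T") < params.tail_head_min_t:
                        continue
                    dg = oracle_delta_g(stem5, stem3, l, model)
                    if dg > params.max_dg:
                        continue
                    out.append(
                        {
                            "stem5": (i + 1, i + s),
                            "loop": (i + s + 1, i + s + l),
                            "stem3": (j + 1, j + s),
                            "spacer_len": sp,
                            "tail": (t + 1, t + params.tail_len),
                            "stem_len": s,
                            "delta_g": dg,
                        }
                    )
    return out


def oracle_resolve(hits: list[dict]) -> list[dict]:
    """The pinned overlap-resolution rule (lowest ΔG, tie leftmost, then
    longest stem), re-implemented on plain dicts."""
    ordered = sorted(
        hits, key=lambda h: (h["delta_g"], h["stem5"][0], -h["stem_len"])
    )
    taken: set[int] = set()
    kept = []
    for h in ordered:
        pos = set(range(h["stem5"][0], h["stem5"][1] + 1)) | set(
            range(h["stem3"][0], h["stem3"][1] + 1)
        )
        if pos & taken:
            continue
        taken |= pos
        kept.append(h)
    return kept


def hit_key(h) -> tuple:
    """Comparable identity of a hit (production object or oracle dict)."""
    if isinstance(h, dict):
        return (h["stem5"], h["loop"], h["stem3"], h["spacer_len"], h["tail"],
                round(h["delta_g"], 6))
    return (h.stem5, h.loop, h.stem3, h.spacer_len, h.tail, round(h.delta_g, 6))


def oracle_fisher_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) by exact integer enumeration."""
    denom = math.comb(N, n)
    num = 0
    for i in range(k, min(K, n) + 1):
        num += math.comb(K, i) * math.comb(N - K, n - i)
    return num / denom


def oracle_local_align_bits(a: str, b: str, sc) -> float:
    """Smith-Waterman-Gotoh with gap cost open + k*extend, cubic in memory
    terms kept simple; independent of Bio.Align."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(
                E[i][j - 1] - sc.gap_extend, H[i][j - 1] - sc.gap_open - sc.gap_extend
            )
            F[i][j] = max(
                F[i - 1][j] - sc.gap_extend, H[i - 1][j] - sc.gap_open - sc.gap_extend
            )
            sub = sc.match if a[i - 1] == b[j - 1] else sc.mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    if best <= 0:
        return 0.0
    return (sc.lambda_ * best - math.log(sc.K)) / math.log(2.0)


def oracle_eulerian_shuffles(seq: str) -> set[str]:
    """All sequences with the same dinucleotide counts and terminal bases,
    by brute-force permutation of the interior multiset (small inputs only)."""
    from itertools import permutations
    from collections import Counter

    target = Counter(seq[i : i + 2] for i in range(len(seq) - 1))
    interior = list(seq[1:-1])
    out = set()
    for perm in set(permutations(interior)):
        cand = seq[0] + "".join(perm) + seq[-1]
        if Counter(cand[i : i + 2] for i in range(len(cand) - 1)) == target:
            out.add(cand)
    return out
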