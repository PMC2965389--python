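"""Dinucleotide-preserving sequence randomization.

The Altschul-Erickson Eulerian-path shuffle: a sequence is viewed as a walk on
the graph whose vertices are nucleotides and whose edges are its dinucleotides.
A uniform random Eulerian walk with the same start and end vertices preserves
the 16-entry dinucleotide count vector exactly (and hence the mononucleotide
composition, up to the fixed first and last base).  Used to build null
sequences for false-positive-rate estimation, where preserving dinucleotide
structure matters because both hairpin stems and T-tails are dinucleotide
clumps.
"""

from __future__ import annotations

from collections import Counter, defaultdict

import numpy as np

__all__ = ["dinucleotide_shuffle", "dinucleotide_counts"]


def dinucleotide_counts(seq: str) -> Counter:
    return Counter(seq[i : i + 2] for i in range(len(seq) - 1))


def dinucleotide_shuffle(seq: str, seed: int | np.random.Generator = 0) -> str:
    """Return a uniform-random sequence with exactly the dinucleotide counts
    of ``seq`` and the same first and last nucleotide.

    Altschul & Erickson (1985) Mol Biol Evol 2:526: pick, for every vertex
    except the sink (last base), a random "last exit" edge such that the last
    exits form an arborescence into the sink; permute all remaining exits
    uniformly; the walk that uses each vertex's designated last exit last is
    then a uniform random Eulerian path.
    """
    if len(seq) < 2:
        raise ValueError("need at least 2 nucleotides to shuffle")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    sink = seq[-1]
    vertices = [v for v in edges if v != sink]

    while True:
        # candidate last-exit edge per non-sink vertex
        last = {v: edges[v][rng.integers(len(edges[v]))] for v in vertices}
        # check the last-exit edges form a tree rooted at the sink
        ok = True
        for v in vertices:
            seen = set()
            cur = v
            while cur != sink:
                if cur in seen or cur not in last:
                    ok = False
                    break
                seen.add(cur)
                cur = last[cur]
            if not ok:
                break
        if ok:
            break

    pools: dict[str, list[str]] = {}
    for v, out in edges.items():
        out = list(out)
        if v in last:
            out.remove(last[v])
        order = rng.permutation(len(out))
        pools[v] = [out[i] for i in order]

    walk = [seq[0]]
    cur = seq[0]
    used_last: set[str] = set()
    for _ in range(len(seq) - 1):
        if pools[cur]:
            nxt = pools[cur].pop()
        else:
            nxt = last[cur]
            used_last.add(cur)
        walk.append(nxt)
        cur = nxt
    return "".join(walk)
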