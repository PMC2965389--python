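"""Clustering candidate leaders into putative regulons.

Candidate attenuators controlled by the same regulatory system (a riboswitch
class, a T-box, a leader peptide, or a mobile insertion-sequence element)
share leader sequence.  Leaders are compared all-against-all by local
alignment; the distance between two leaders is the inverse of their best
local-alignment bit score (capped for non-matching pairs), hierarchical
clustering is cut at a fixed height, and each resulting cluster is classified
by the families of its members:

* ``a`` — all downstream genes from one family (an orthologous regulon);
* ``b`` — assorted non-orthologous genes;
* ``c`` — a "super-cluster": several families each represented at least
  twice, i.e. one leader class regulating several orthologous gene sets.

Clusters whose downstream genes look like transposases / insertion-sequence
or prophage genes are flagged *mobile*: their terminators ride a mobile
element and may have been exapted as regulators of neighboring genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from scipy.cluster import hierarchy
from scipy.optimize import brentq
from scipy.spatial.distance import squareform

__all__ = [
    "AlignScoring",
    "DistanceMatrix",
    "ClusterSet",
    "local_alignment_score",
    "pairwise_distance_matrix",
    "cluster_and_cut",
    "classify_cluster",
    "flag_mobile",
    "MOBILE_KEYWORDS",
]

MOBILE_KEYWORDS = [
    "transposase",
    "insertion sequence",
    "integrase",
    "IS element",
    "prophage",
]


@dataclass
class AlignScoring:
    """Local-alignment scoring with a Karlin-Altschul bit conversion.

    Gap of length k costs gap_open + k * gap_extend.  ``lambda_`` is the
    ungapped Karlin-Altschul parameter for (match, mismatch) on a uniform
    background, solved from sum_ij p_i p_j exp(lambda * s_ij) = 1; K is the
    tabulated blastn value for +1/-2.  bits = (lambda*raw - ln K) / ln 2.
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = 2.0
    gap_extend: float = 1.0
    K: float = 0.621
    lambda_: float | None = None

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.gap_open < 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lambda_ is None:
            self.lambda_ = self._solve_lambda()

    def _solve_lambda(self) -> float:
        # uniform background: 4 matching / 12 mismatching ordered base pairs
        def f(lam: float) -> float:
            return 0.25 * math.exp(lam * self.match) + 0.75 * math.exp(
                lam * self.mismatch
            ) - 1.0

        return brentq(f, 1e-6, 10.0)

    def bits(self, raw: float) -> float:
        if raw <= 0:
            return 0.0
        return (self.lambda_ * raw - math.log(self.K)) / math.log(2.0)

    def aligner(self) -> Align.PairwiseAligner:
        al = Align.PairwiseAligner()
        al.mode = "local"
        al.match_score = self.match
        al.mismatch_score = self.mismatch
        # PairwiseAligner charges open on the first gapped position:
        # a k-gap costs open + (k-1)*extend there vs open + k*extend here.
        al.open_gap_score = -(self.gap_open + self.gap_extend)
        al.extend_gap_score = -self.gap_extend
        return al


def local_alignment_score(a: str, b: str, sc: AlignScoring | None = None) -> float:
    """Best local-alignment score of two sequences in bits
    (Smith-Waterman-Gotoh affine gaps; 0 when no positive-scoring alignment
    exists)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    sc = sc or AlignScoring()
    raw = sc.aligner().score(a, b)
    return sc.bits(raw)


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray  # square, symmetric, zero diagonal
    cap: float = 1.0

    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)


def pairwise_distance_matrix(
    leaders: dict[str, str], sc: AlignScoring | None = None, cap: float = 1.0
) -> DistanceMatrix:
    """d(i, j) = 1 / bits(i, j), capped at ``cap`` for weak or absent
    similarity."""
    if len(leaders) < 2:
        raise ValueError("need at least two leaders")
    sc = sc or AlignScoring()
    ids = list(leaders)
    n = len(ids)
    m = np.full((n, n), cap, dtype=float)
    np.fill_diagonal(m, 0.0)
    aligner = sc.aligner()
    for i in range(n):
        for j in range(i + 1, n):
            raw = aligner.score(leaders[ids[i]], leaders[ids[j]])
            bits = sc.bits(raw)
            d = 1.0 / bits if bits > 1.0 / cap else cap
            m[i, j] = m[j, i] = d
    return DistanceMatrix(ids=ids, matrix=m, cap=cap)


@dataclass
class ClusterSet:
    clusters: dict[int, list[str]]
    cut_height: float
    linkage: str
    classes: dict[int, str] = field(default_factory=dict)
    mobile: dict[int, bool] = field(default_factory=dict)
    linkage_matrix: np.ndarray | None = None
    ids: list[str] = field(default_factory=list)

    def cluster_of(self, member_id: str) -> int:
        for cid, members in self.clusters.items():
            if member_id in members:
                return cid
        raise KeyError(member_id)


def cluster_and_cut(
    dm: DistanceMatrix, linkage: str = "complete", h: float = 0.038
) -> ClusterSet:
    """Agglomerative clustering of the distance matrix, cut so that every
    within-cluster merge has height <= h (a pair at exactly h is merged)."""
    Z = hierarchy.linkage(dm.condensed(), method=linkage)
    # fcluster's 'distance' criterion uses strict <= t
    labels = hierarchy.fcluster(Z, t=h, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for cid, member in zip(labels, dm.ids):
        clusters.setdefault(int(cid), []).append(member)
    return ClusterSet(
        clusters=clusters,
        cut_height=h,
        linkage=linkage,
        linkage_matrix=Z,
        ids=list(dm.ids),
    )


def classify_cluster(member_families: list[str]) -> str:
    """a: one family only; c: >= 2 families each appearing >= 2 times;
    b: anything else."""
    counts: dict[str, int] = {}
    for f in member_families:
        counts[f] = counts.get(f, 0) + 1
    if len(counts) == 1:
        return "a"
    if sum(1 for v in counts.values() if v >= 2) >= 2:
        return "c"
    return "b"


def flag_mobile(member_products: list[str], keywords: list[str] | None = None) -> bool:
    """True when any member's downstream gene product matches a mobile-element
    keyword (case-insensitive substring)."""
    kws = [k.lower() for k in (keywords if keywords is not None else MOBILE_KEYWORDS)]
    return any(any(k in (p or "").lower() for k in kws) for p in member_products)


def annotate_clusters(
    cs: ClusterSet,
    family_by_member: dict[str, str],
    product_by_member: dict[str, str],
    keywords: list[str] | None = None,
) -> ClusterSet:
    """Fill per-cluster class and mobile flags from member annotations."""
    for cid, members in cs.clusters.items():
        cs.classes[cid] = classify_cluster(
            [family_by_member.get(m, "?") for m in members]
        )
        cs.mobile[cid] = flag_mobile(
            [product_by_member.get(m, "") for m in members], keywords
        )
    return cs


def dendrogram_newick(cs: ClusterSet) -> str:
    """Newick export of the full dendrogram (branch lengths from merge
    heights)."""
    if cs.linkage_matrix is None:
        raise ValueError("no linkage matrix stored")
    tree = hierarchy.to_tree(cs.linkage_matrix)

    def rec(node) -> str:
        if node.is_leaf():
            return cs.ids[node.id]
        left, right = node.get_left(), node.get_right()
        parts = []
        for child in (left, right):
            bl = node.dist - (0.0 if child.is_leaf() else child.dist)
            parts.append(f"{rec(child)}:{bl:.6g}")
        return "(" + ",".join(parts) + ")"

    return rec(tree) + ";"
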