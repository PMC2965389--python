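"""Gene-family scoring for attenuation propensity.

Families of homologous genes are ranked by how often their members carry a
predicted 5' attenuator:

* **absolute score** — the raw number of candidate attenuators upstream of
  family members, summed over all screened species;
* **normalized score** — per species, candidates divided by the family's gene
  count in that species, summed over species (so large families in many
  genomes do not dominate);
* **weighted score** — the normalized per-species scores arranged in
  phylogenetic order, with each species in a run of L consecutive non-zero
  scores multiplied by (1 + w·L), w = 0.1 by default.  Runs along the
  phylogeny reward evolutionarily parsimonious distributions: attenuation
  conserved in a clade counts for more than the same number of scattered,
  independently-arising hits.

Enrichment significance uses a one-sided Fisher's exact (hypergeometric
tail) test on genes-with-attenuator vs family membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FamilyMap",
    "FamilyScore",
    "UNASSIGNED_FAMILY",
    "absolute_family_scores",
    "normalized_family_score",
    "fisher_enrichment",
    "score_families",
    "rank_families",
]

UNASSIGNED_FAMILY = "__unassigned__"


@dataclass
class FamilyMap:
    """gene_id -> family_id mapping with per-species family gene totals.

    Built from a TSV with columns (gene_id, species_id, family_id)."""

    gene_to_family: dict[str, str]
    gene_to_species: dict[str, str]

    @classmethod
    def from_tsv(cls, path) -> "FamilyMap":
        g2f: dict[str, str] = {}
        g2s: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("gene_id\t"):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: expected 3 fields")
                gene, species, fam = fields[:3]
                if gene in g2f and g2f[gene] != fam:
                    raise ValueError(f"{path}:{lineno}: gene {gene} in two families")
                g2f[gene] = fam
                g2s[gene] = species
        return cls(g2f, g2s)

    def family_of(self, gene_id: str) -> str:
        return self.gene_to_family.get(gene_id, UNASSIGNED_FAMILY)

    def species_of(self, gene_id: str) -> str | None:
        return self.gene_to_species.get(gene_id)

    def genes_per_family_species(self) -> dict[tuple[str, str], int]:
        out: dict[tuple[str, str], int] = {}
        for g, fam in self.gene_to_family.items():
            key = (fam, self.gene_to_species[g])
            out[key] = out.get(key, 0) + 1
        return out

    @property
    def n_genes(self) -> int:
        return len(self.gene_to_family)

    def families(self) -> set[str]:
        return set(self.gene_to_family.values())


@dataclass
class SpeciesOrder:
    """Species ids in phylogenetic order (adjacent species are phylogenetic
    neighbors; used only by the run weighting)."""

    order: list[str]

    @classmethod
    def from_file(cls, path) -> "SpeciesOrder":
        with open(path) as fh:
            order = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
        return cls(order)

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise ValueError("duplicate species in order")

    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.order)}


@dataclass
class FamilyScore:
    family_id: str
    n_genes_family: int
    n_hit_family: int
    absolute_score: int
    normalized_score: float
    weighted_score: float
    fisher_p: float


def _candidate_genes(candidates) -> list[str]:
    """Downstream gene id per candidate (accepts AttenuatorCandidate objects
    or raw gene ids)."""
    out = []
    for c in candidates:
        out.append(c if isinstance(c, str) else c.downstream_gene_id)
    return out


def absolute_family_scores(candidates, fam: FamilyMap) -> dict[str, int]:
    """Candidate attenuators per family, over all species; genes without a
    family are pooled under the reserved unassigned family."""
    counts: dict[str, int] = {}
    for gene in _candidate_genes(candidates):
        f = fam.family_of(gene)
        counts[f] = counts.get(f, 0) + 1
    return counts


def _run_lengths(b: np.ndarray) -> np.ndarray:
    """For each position, the length of the maximal run of consecutive
    non-zero entries containing it (0 where b == 0)."""
    L = np.zeros(len(b), dtype=int)
    i = 0
    while i < len(b):
        if b[i] != 0:
            j = i
            while j < len(b) and b[j] != 0:
                j += 1
            L[i:j] = j - i
            i = j
        else:
            i += 1
    return L


def normalized_family_score(
    candidates,
    fam: FamilyMap,
    order: SpeciesOrder,
    run_weight: float = 0.1,
    mode: str = "multiplicative",
) -> dict[str, tuple[float, float]]:
    """(normalized_score, weighted_score) per family.

    ``mode="multiplicative"`` (default): weighted = sum b_s * (1 + w * L_s);
    ``mode="additive"``: weighted = sum b_s + w * sum of run lengths.
    """
    if mode not in ("multiplicative", "additive"):
        raise ValueError(f"unknown weighting mode {mode!r}")
    idx = order.index()
    totals = fam.genes_per_family_species()
    # candidate counts per (family, species)
    ccount: dict[tuple[str, str], int] = {}
    for gene in _candidate_genes(candidates):
        f = fam.family_of(gene)
        sp = fam.species_of(gene)
        if sp is None:
            continue
        ccount[(f, sp)] = ccount.get((f, sp), 0) + 1

    out: dict[str, tuple[float, float]] = {}
    fams = {f for f, _ in ccount} | {f for f, _ in totals}
    ns = len(order.order)
    for f in sorted(fams):
        b = np.zeros(ns)
        for s, i in idx.items():
            c = ccount.get((f, s), 0)
            g = totals.get((f, s), 0)
            if c and not g:
                raise ValueError(
                    f"family {f} has {c} candidates but no genes in species {s}"
                )
            if g:
                b[i] = c / g
        L = _run_lengths(b)
        normalized = float(b.sum())
        if mode == "multiplicative":
            weighted = float((b * (1.0 + run_weight * L)).sum())
        else:
            # additive bonus: + w per species inside a non-zero run
            weighted = normalized + run_weight * float((L > 0).sum())
        out[f] = (normalized, weighted)
    return out


def fisher_enrichment(
    n_genes_family: int,
    n_genes_total: int,
    n_hit_family: int,
    n_hit_total: int,
) -> float:
    """One-sided enrichment p-value: probability of >= ``n_hit_family``
    attenuated genes in the family under a hypergeometric draw of
    ``n_hit_total`` attenuated genes from ``n_genes_total``."""
    if not (0 <= n_hit_family <= min(n_genes_family, n_hit_total)):
        raise ValueError("inconsistent table: n_hit_family exceeds a margin")
    if n_genes_family > n_genes_total or n_hit_total > n_genes_total:
        raise ValueError("inconsistent table margins")
    return float(
        stats.hypergeom.sf(
            n_hit_family - 1, n_genes_total, n_genes_family, n_hit_total
        )
    )


def score_families(
    candidates,
    fam: FamilyMap,
    order: SpeciesOrder,
    n_genes_total: int | None = None,
    run_weight: float = 0.1,
    mode: str = "multiplicative",
) -> list[FamilyScore]:
    """Assemble FamilyScore records for every family with at least one gene."""
    absolute = absolute_family_scores(candidates, fam)
    norm = normalized_family_score(candidates, fam, order, run_weight, mode)
    genes_by_family: dict[str, int] = {}
    for g, f in fam.gene_to_family.items():
        genes_by_family[f] = genes_by_family.get(f, 0) + 1
    hit_genes = set(_candidate_genes(candidates))
    hits_by_family: dict[str, int] = {}
    for g in hit_genes:
        f = fam.family_of(g)
        hits_by_family[f] = hits_by_family.get(f, 0) + 1
    total = n_genes_total if n_genes_total is not None else fam.n_genes
    n_hit_total = len(hit_genes)
    out = []
    for f in sorted(genes_by_family):
        ng = genes_by_family[f]
        nh = hits_by_family.get(f, 0)
        nscore, wscore = norm.get(f, (0.0, 0.0))
        out.append(
            FamilyScore(
                family_id=f,
                n_genes_family=ng,
                n_hit_family=nh,
                absolute_score=absolute.get(f, 0),
                normalized_score=nscore,
                weighted_score=wscore,
                fisher_p=fisher_enrichment(ng, total, nh, n_hit_total),
            )
        )
    return out


def rank_families(scores: list[FamilyScore], by: str = "weighted") -> pd.DataFrame:
    """Stable descending sort by the chosen score; ties by ascending Fisher
    p, then family id."""
    key = {"absolute": "absolute_score", "weighted": "weighted_score"}.get(by)
    if key is None:
        raise ValueError("by must be 'absolute' or 'weighted'")
    df = pd.DataFrame(
        [
            {
                "family_id": s.family_id,
                "n_genes_family": s.n_genes_family,
                "n_hit_family": s.n_hit_family,
                "absolute_score": s.absolute_score,
                "normalized_score": s.normalized_score,
                "weighted_score": s.weighted_score,
                "fisher_p": s.fisher_p,
            }
            for s in scores
        ]
    )
    df = df.sort_values(
        [key, "fisher_p", "family_id"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    return df


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted q-values (optional; raw p-values are reported by default)."""
    return stats.false_discovery_control(np.asarray(pvalues, dtype=float))
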