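import numpy as np
import pytest

from attenuscan.evaluate import run_cohort_screen
from attenuscan.genome import GeneRecord, GenomeAnnotation, Replicon
from attenuscan.simulate import SyntheticSpec, generate_cohort


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def make_annotation(seq_len=2000, genes=(), species="spX", seq=None):
    """Tiny hand-built annotation: genes = iterable of
    (gene_id, start, end, strand[, product])."""
    rng = np.random.default_rng(0)
    s = seq if seq is not None else random_dna(rng, seq_len)
    recs = []
    for g in genes:
        gid, start, end, strand = g[:4]
        product = g[4] if len(g) > 4 else ""
        recs.append(GeneRecord(gid, "chr", start, end, strand, product,
                               "hypothetical" in product.lower()))
    return GenomeAnnotation(species, [Replicon("chr", s)], recs)


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (seed 1): 10 species x 300 genes, 200
    strong 5' plants, 3' plants after every gene, labeled violators, IS
    cassettes."""
    return generate_cohort(SyntheticSpec())


@pytest.fixture(scope="session")
def default_screen(default_cohort):
    """Descriptor-mode screen of every genome in the default cohort."""
    return run_cohort_screen(default_cohort)


@pytest.fixture(scope="session")
def cluster_cohort():
    """Small cohort tuned for leader clustering: impure tails (9 T of 12,
    like real terminators) so unrelated leaders do not merge through their
    poly-T stretches, shared templates for the enriched family and the IS
    element."""
    spec = SyntheticSpec(
        n_species=6, genes_per_species=80, n_5p_plants=40, tail_t_count=9,
        n_is_elements=4, enriched_species=4, enriched_per_species=2,
        n_violators=(0, 0, 0), plant_3p_all=False, seed=42,
    )
    return generate_cohort(spec)
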