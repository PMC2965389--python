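# Methods

## Scope and model

`attenuscan` screens annotated bacterial genomes for intrinsic (Rho-independent)
terminators located where an attenuator would sit: in the 5' leader of a gene,
in the gene's orientation. The screen is deliberately agnostic about *which*
attenuation mechanism produced the terminator — riboswitch, T-box, leader
peptide or an exapted mobile element all terminate transcription through the
same hairpin + poly-U signature. It searches for single terminator motifs
only; it does not model the alternative (antiterminator) fold, and it cannot
see Rho-dependent termination.

## Search space

Search regions are the maximal intergenic gaps between consecutive genes.
Hypothetical ORFs shorter than 200 nt do not delimit regions: many annotated
"short hypothetical proteins" upstream of operons are leader peptides, so they
are treated as intergenic sequence and recorded per region. Overlapping or
abutting genes produce no region; circular replicons contribute one
wrap-around region. All external coordinates are 1-based inclusive, forward
strand; minus-strand scanning reverse-complements the region and maps hits
back.

## Descriptor scanner

The geometric descriptor is the canonical intrinsic-terminator shape
(Lesnik et al. 2001, NAR 29:3583):

| parameter | default | meaning |
|---|---|---|
| stem | 4–18 bp | contiguous helix, WC + GU wobble |
| loop | 3–10 nt | hairpin loop |
| spacer | 0–2 nt | between stem and tail |
| tail | 12 nt, ≥ 7 T, ≥ 3 T of first 5 | the poly-U termination signal |
| max ΔG | −6.0 kcal/mol | minimum hairpin stability |
| bulge | off | optionally one 1-nt bulge per arm |

Every admissible decomposition is enumerated (stems grown outward from each
loop placement — the only incremental direction); hits sharing any stem
position are collapsed to the lowest-ΔG one (ties: leftmost, then longest
stem). The enumeration is exhaustive by construction, which is what makes the
brute-force oracle equivalence test in the suite possible.

The ΔG cutoff is part of the descriptor, not an afterthought: the bare
geometry matches random sequence far too often (≈ 0.4 hits per 250-nt region
at GC 0.5; poly-T tails are common and 4-bp helices are everywhere). A
null-model calibration on iid and dinucleotide-shuffled backgrounds put the
operating point at −6 kcal/mol: detection of 8±1 bp GC-rich planted stems
stays ≈ 1.0 while the shuffled-region false-positive rate drops to ~4–7% per
region. −4 kcal/mol leaves ~13% false positives on shuffled terminator-bearing
regions (their conserved TT dinucleotides keep re-creating tails); −8 starts
to lose genuine weak stems. Real weak terminators fold around −8 to −10
kcal/mol, so −6 is permissive for biology while restrictive for noise.

Bulged stems (off by default) are scored by treating the paired positions as a
contiguous helix — a crude approximation that slightly overestimates their
stability; the flag exists because real attenuator stems are occasionally
bulged, and it is excluded from the oracle-equivalence guarantee.

## Energy model

Stacking free energies are the Turner-style nearest-neighbor ΔG°₃₇ values
(Xia et al. 1998 for WC/WC steps; the Turner 2004 compilation for
GU-containing steps), hairpin-loop initiation penalties for sizes 3–30 (larger
loops clamp to 30), and a +0.45 kcal/mol terminal penalty when the outermost
pair is AU or GU. DNA input is scored as its transcript (T ≡ U). The 21
unique stack values are embedded with their physical read-direction symmetry
expanded programmatically, so a transcription error in one entry would break
the symmetry self-check at import.

## Profile scanner

Where a structure-annotated terminator alignment is available (Stockholm,
`#=GC SS_cons`), a log-odds profile is trained: per stem column a 16-way
ordered-pair table, per loop/spacer/tail column a 4-way base table, with
pseudocount 1 against a uniform background. Columns are weighted by their
training occupancy, which is how variable-length stems are normalized onto
the profile's span: candidate pairs are right-justified toward the loop
(matching the training alignment's outer-gap convention), and rarely occupied
outer columns contribute proportionally little. Scanning scores every
descriptor-admissible decomposition (energy cutoff lifted to 0 — the profile
ranks by similarity, not stability) and keeps scores above the threshold;
overlaps resolve by score. The two-pass rule: on each strand the profile is
consulted first, and the descriptor only when the profile finds nothing.

The score threshold defaults to 10 bits and should be calibrated with
`calibrate_threshold` against shuffled background at a chosen false-positive
density (the monotone, smallest-threshold-meeting-target rule). This scanner
is a statistical stand-in for covariance/profile tools trained on curated
terminator alignments; its absolute scores are not comparable across training
sets, which is why the threshold is calibrated rather than fixed.

## Attenuator filters

For a 5'-oriented hit, d_down counts the bases between the tail's 3' end and
the downstream start codon (exclusive), and d_up the bases between the stem's
5' start and the nearest boundary of the upstream gene, floored at 1 so an
overlapping upstream gene gives a huge ratio and a discard. Candidates
require d_down ≤ 300 and d_down/d_up ≤ 1; with no upstream gene the ratio test
passes vacuously. A 5'-oriented hit that fails these filters is re-labelled a
3' terminator when it follows a co-oriented upstream gene — that is exactly
what the filters are designed to recognize. Leaders run from the upstream
gene's limit — or at most 200 nt 5' of the stem — to one base past the tail
(clipped at the downstream gene), reported 5'→3' on the candidate strand.
The 200-nt cap is anchored at the stem start; anchoring it at the leader's 3'
end instead would shave at most the tail length off long leaders and was the
less natural reading.

## Statistics

* 5'-vs-3' contrast: Welch's unequal-variance t-test, two-sided, on ΔG and
  stem length. The biological expectation — 5' terminators less stable,
  shorter-stemmed, because they must also fold into a readthrough structure —
  is a sign prediction, and the synthetic generator plants that sign (3' stem
  mean 1 bp longer) so recovery is testable.
* Family enrichment: one-sided hypergeometric tail on (genes in family,
  total genes, attenuated genes in family, total attenuated genes). Raw
  p-values are reported (a Benjamini–Hochberg helper is provided but not
  default), matching how single-family enrichment is usually read in this
  setting.
* Run weighting: multiplicative, Σ b_s(1 + w·L_s) with w = 0.1. The additive
  reading (Σ b_s + w·ΣL) is implemented behind `mode="additive"`; the
  multiplicative form keeps the invariant weighted ≥ normalized with equality
  exactly when no two attenuated species are adjacent.
* Dinucleotide shuffles are exact Eulerian-path shuffles (Altschul–Erickson):
  the dinucleotide count vector and both terminal bases are preserved, and
  the sampler has full support over valid shuffles (checked by enumeration on
  small words). This matters here because both failure modes of the detector
  — spurious helices and spurious tails — live in dinucleotide space.

## Clustering

Leader distance is 1/bits of the best local alignment, capped at 1. Scoring
is +1/−2 with affine gap cost 2 + k (open 2, extend 1); λ ≈ 1.34 nats is
solved numerically from Σ pᵢpⱼe^{λs} = 1 on a uniform background at
construction (never hard-coded), and K = 0.621 is the tabulated ungapped
value for +1/−2. Under this conversion the 0.038 cut corresponds to ≈ 26.3
bits — roughly a 14-nt exact match — and to E ≈ 10⁻⁴ for leader-sized
comparisons. Complete linkage (merging two clusters requires *every*
cross-pair to be similar) is deliberately conservative for regulon calling;
single and average linkage are available. A pair at exactly the cut height
merges. Classes: `a` one family; `c` ≥ 2 families each ≥ 2 members (one
leader class serving several orthologous gene sets); `b` otherwise. Mobile
flags are keyword matches on downstream products (transposase, insertion
sequence, integrase, IS element, prophage; configurable).

## Synthetic cohorts

The generator emulates the screen's input structure, not real genomes: iid
background at a chosen GC (default 0.5), 300 genes of 300–900 nt per species
with 50–400 nt gaps, 30% minus-strand genes, families assigned round-robin
(50 families), and a handful of short hypothetical ORFs per species dropped
into plant-free gaps. Planted elements:

* 200 5' attenuators (stem 8±1 bp at GC 0.8, loop 4, spacer 0–2, 12-T tail),
  placed to satisfy d_down ≤ 300 and ratio ≤ 1, one per target gene;
* 3' terminators after every gene that has room (stem mean +1 bp), placed
  2–10 nt after the stop so their distance ratio toward the next gene fails —
  as real 3' terminators' does;
* 12 labeled violators, four per failure mode (distance, ratio, strand), each
  violating exactly its labeled rule;
* an enriched family planted in 8 consecutive species (3 genes each) with a
  shared leader template, giving the weighted score a known winner;
* IS cassettes: transposase-annotated genes (family `FIS`) carrying copies of
  one shared leader template — a mobile attenuator's signature.

Everything derives from `numpy` SeedSequence spawns of one seed and is
byte-for-byte reproducible. Clustering experiments use tails of 9 T of 12
(typical of real terminators): with fully pure 12-T tails, unrelated leaders
share a 12-match run and sit near the 0.038 boundary, which is a property of
the cut itself, not a detector artifact.

What passing on these cohorts does **not** show: performance on real genomes
with Markovian composition, repeats, overlapping genes and mis-annotation;
iid background makes the detector's specificity look slightly better than
reality (the dinucleotide-shuffle control is the honest specificity
estimate). Sensitivity numbers apply to canonical, strong planted stems;
bulged, GC-poor real stems will be under-detected, which is the known failure
mode of descriptor screens.

## Problem sizes and numerics

The default cohort (10 × 300 genes, ≈ 2.4 Mb total, ≈ 3 000 regions) screens
in ≈ 4 s on one CPU; the acceptance script's full set of analyses runs in
≈ 10 s. Shuffle controls in the shipped analyses use 25 shuffles of ~10
planted regions per genome — enough for a rate estimate whose comparison
(< 10% of detection) has a wide margin. Degenerate inputs: empty gene lists
give one whole-replicon region; sequences shorter than the minimal motif scan
to empty lists, not errors; identical 5'/3' hit lists give p ≈ 1; n < 2 per
class reports no p-value; calibration with an unreachable false-positive
target returns max-score + 1 with a warning. Ties everywhere are broken
deterministically (documented per function), so every pipeline stage is
reproducible given its inputs and seed.
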