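import numpy as np
import pytest

from attenuscan.energy import default_energy_model
from attenuscan.genome import reverse_complement
from attenuscan.scan import DescriptorParams, scan_descriptor, scan_region
from attenuscan.screen import classify_hits
from attenuscan.evaluate import match_hits_to_truth

from conftest import random_dna
from oracles import hit_key, oracle_descriptor_hits, oracle_resolve


class TestScanDescriptor:
    def test_planted_canonical_motif(self):
        # non-pairing flanks (C against tail T does not pair) keep the
        # planted 8-bp decomposition the minimum-energy one
        seq = "CC" + "GCCGGGCC" + "GAAA" + "GGCCCGGC" + "TTTTTTTTTTTT" + "AA"
        hits = scan_descriptor(seq)
        assert len(hits) == 1
        h = hits[0]
        assert h.stem_len == 8 and h.spacer_len == 0
        assert h.stem5 == (3, 10) and h.stem3 == (15, 22) and h.tail == (23, 34)
        assert h.method == "descriptor" and h.score is None

    def test_homopolymer_has_no_hits(self):
        assert scan_descriptor("A" * 60) == []

    def test_too_short_sequence_is_empty_not_error(self):
        assert scan_descriptor("ACGT") == []

    @pytest.mark.parametrize("gc", [0.4, 0.6])
    def test_matches_bruteforce_oracle(self, gc):
        from attenuscan.simulate import random_motif

        params = DescriptorParams()
        model = default_energy_model()
        rng = np.random.default_rng(123)
        n_nonempty = 0
        for i in range(100):
            seq = random_dna(rng, 80, gc)
            if i % 2:  # embed a motif so hits are actually exercised
                m = random_motif(rng, int(rng.integers(4, 12)), 0.8,
                                 int(rng.integers(7, 13)))["seq"]
                pos = int(rng.integers(0, 80 - len(m)))
                seq = seq[:pos] + m + seq[pos + len(m):]
            got = {hit_key(h) for h in scan_descriptor(seq, params)}
            want = {hit_key(h) for h in oracle_resolve(
                oracle_descriptor_hits(seq, params, model))}
            assert got == want
            n_nonempty += bool(want)
        assert n_nonempty >= 20  # the comparison actually exercised hits

    def test_overlap_resolution_prefers_lowest_dg(self):
        # one strong GC hairpin and one weaker overlapping decomposition:
        # only the lowest-ΔG hit survives per stem locus
        seq = "CC" + "GCGCGCGC" + "TTAA" + "GCGCGCGC" + "TTTTTTTTTTTT" + "CC"
        hits = scan_descriptor(seq)
        assert len(hits) == 1
        assert hits[0].delta_g == min(h.delta_g for h in hits)

    def test_strand_symmetry(self):
        """A hit on the reverse complement, mapped back to forward
        coordinates, is a genuine hairpin of the "-" strand: its arms (read
        from the forward sequence and complemented) pair with the same free
        energy, and its tail is A-rich on the forward strand."""
        from attenuscan.energy import hairpin_delta_g

        from attenuscan.simulate import random_motif

        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(40):
            seq = random_dna(rng, 100)
            # plant a motif in "-" orientation on the forward sequence
            m = random_motif(rng, int(rng.integers(5, 11)), 0.8, 10)["seq"]
            pos = int(rng.integers(0, 100 - len(m)))
            seq = seq[:pos] + reverse_complement(m) + seq[pos + len(m):]
            rc = reverse_complement(seq)
            n = len(seq)
            for h in scan_descriptor(rc):
                def m(iv):
                    return (n - iv[1] + 1, n - iv[0] + 1)

                f5, f3, ft = m(h.stem5), m(h.stem3), m(h.tail)
                stem5 = reverse_complement(seq[f5[0] - 1 : f5[1]])
                stem3 = reverse_complement(seq[f3[0] - 1 : f3[1]])
                loop_len = h.loop[1] - h.loop[0] + 1
                assert hairpin_delta_g(stem5, stem3, loop_len) == pytest.approx(
                    h.delta_g, abs=1e-9
                )
                tail_fwd = seq[ft[0] - 1 : ft[1]]
                assert tail_fwd.count("A") >= 7
                checked += 1
        assert checked >= 5

    def test_bulged_stem_found_only_in_bulge_mode(self):
        p0 = DescriptorParams()
        p1 = DescriptorParams(allow_bulge=True)
        stem5 = "GCGGCC"
        bulged5 = "GCGAGCC"  # A bulge inserted in the 5' arm
        seq = "A" + bulged5 + "TTCG" + reverse_complement(stem5) + "TTTTTTTTTTTT" + "A"
        assert not any(h.stem_len >= 6 for h in scan_descriptor(seq, p0))
        assert any(h.stem_len >= 6 for h in scan_descriptor(seq, p1))


class TestScanRegion:
    def test_minus_strand_plant_maps_to_forward_truth(self, default_cohort):
        truth = default_cohort.truth
        minus = truth[(truth.strand == "-") & (truth.klass == "5p")]
        row = minus.iloc[0]
        ann = default_cohort.annotation(row.species)
        from attenuscan.genome import extract_search_regions

        region = next(
            r for r in extract_search_regions(ann)
            if r.replicon_id == row.replicon and r.lo <= row.motif_lo <= r.hi
        )
        hits = scan_region(region, ann)
        match = match_hits_to_truth(hits, truth.loc[[row.name]])
        assert any(eid == row.element_id for eid in match.values())
        matched = [h for i, h in enumerate(hits) if match[i]]
        assert all(h.strand == "-" for h in matched)

    def test_profile_pass_suppresses_descriptor(self, default_cohort):
        """Two-pass rule: when the profile yields a hit on a strand, the
        descriptor is not consulted for that strand."""
        from attenuscan.profile import train_profile
        from attenuscan.simulate import training_alignment
        from attenuscan.genome import extract_search_regions

        model = train_profile(training_alignment(n=60, seed=3))
        model.score_threshold = 5.0
        truth = default_cohort.truth
        row = truth[(truth.klass == "5p") & (truth.strand == "+")].iloc[0]
        ann = default_cohort.annotation(row.species)
        region = next(
            r for r in extract_search_regions(ann)
            if r.replicon_id == row.replicon and r.lo <= row.motif_lo <= r.hi
        )
        hits = scan_region(region, ann, model=model)
        plus = [h for h in hits if h.strand == "+"]
        assert plus and all(h.method == "profile" for h in plus)

    def test_model_none_is_pure_descriptor(self, default_cohort):
        from attenuscan.genome import extract_search_regions

        ann = default_cohort.annotations[0]
        region = extract_search_regions(ann)[3]
        hits = scan_region(region, ann, model=None)
        assert all(h.method == "descriptor" for h in hits)

    def test_hit_invariants(self, default_screen):
        p = DescriptorParams()
        for h in default_screen.hits[:500]:
            assert p.stem_min <= h.stem_len <= p.stem_max
            assert p.spacer_min <= h.spacer_len <= p.spacer_max
            assert h.tail[1] - h.tail[0] + 1 == p.tail_len
            assert h.delta_g <= p.max_dg
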