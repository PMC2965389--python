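import numpy as np
import pytest

from attenuscan.genome import SearchRegion, extract_search_regions, reverse_complement
from attenuscan.scan import TerminatorHit
from attenuscan.screen import (
    apply_attenuator_filters,
    classify_hits,
    compare_utr_stats,
    estimate_false_positive_rate,
    extract_candidate_sequence,
    filter_with_reasons,
)

from conftest import make_annotation


def _hit(strand="+", stem5=(400, 407), loop=(408, 411), stem3=(412, 419),
         tail=(420, 431), dg=-12.0):
    if strand == "-":
        stem5, stem3 = stem3, stem5
    return TerminatorHit(
        replicon_id="chr", strand=strand, stem5=stem5, loop=loop, stem3=stem3,
        spacer_len=0, tail=tail, stem_len=8, delta_g=dg,
    )


@pytest.fixture
def simple_ann():
    # g1 [1,300]+, g2 [601,900]+, region [301,600]
    return make_annotation(1200, [("g1", 1, 300, "+"), ("g2", 601, 900, "+")])


@pytest.fixture
def region(simple_ann):
    return next(
        r for r in extract_search_regions(simple_ann) if r.left_gene_id == "g1"
    )


class TestClassify:
    def test_plus_hit_toward_plus_gene_is_five_prime(self, simple_ann, region):
        h = classify_hits([_hit("+")], region, simple_ann)[0]
        assert h.utr_class == "five_prime"
        assert h.downstream_gene_id == "g2" and h.upstream_gene_id == "g1"

    def test_plus_hit_with_minus_right_gene_is_three_prime(self):
        ann = make_annotation(1200, [("g1", 1, 300, "+"), ("g2", 601, 900, "-")])
        region = next(
            r for r in extract_search_regions(ann) if r.left_gene_id == "g1"
        )
        h = classify_hits([_hit("+")], region, ann)[0]
        assert h.utr_class == "three_prime" and h.upstream_gene_id == "g1"

    def test_no_relevant_flank_is_unassigned(self):
        # "-" hit in the terminal region after g1(+): its downstream side has
        # no gene and the upstream flank is not co-oriented
        ann = make_annotation(1200, [("g1", 1, 300, "+")])
        region = next(
            r for r in extract_search_regions(ann) if r.left_gene_id == "g1"
        )
        h = classify_hits([_hit("-")], region, ann)[0]
        assert h.utr_class == "unassigned"

    def test_minus_hit_toward_minus_left_gene(self):
        ann = make_annotation(1200, [("g1", 1, 300, "-"), ("g2", 601, 900, "-")])
        region = next(
            r for r in extract_search_regions(ann) if r.left_gene_id == "g1"
        )
        h = classify_hits([_hit("-")], region, ann)[0]
        assert h.utr_class == "five_prime" and h.downstream_gene_id == "g1"


class TestFilters:
    def _classified(self, ann, region, **kw):
        return classify_hits([_hit(**kw)], region, ann)

    def test_kept_when_ratio_small(self, simple_ann, region):
        # d_down = 601 - 431 - 1 = 169 <= 300; d_up = 400 - 300 - 1 = 99;
        # wait: ratio = 169/99 > 1 -> choose a hit closer to g2
        hits = self._classified(
            simple_ann, region,
            stem5=(540, 547), loop=(548, 551), stem3=(552, 559), tail=(560, 571),
        )
        cands = apply_attenuator_filters(hits, simple_ann)
        assert len(cands) == 1
        c = cands[0]
        assert c.d_down == 601 - 571 - 1 == 29
        assert c.d_up == 540 - 300 - 1 == 239
        assert c.ratio == pytest.approx(29 / 239)

    def test_distance_over_300_discarded(self):
        ann = make_annotation(2000, [("g1", 1, 100, "+"), ("g2", 1201, 1500, "+")])
        region = next(r for r in extract_search_regions(ann) if r.left_gene_id == "g1")
        hits = classify_hits(
            [_hit("+", stem5=(700, 707), loop=(708, 711), stem3=(712, 719),
                  tail=(720, 731))],
            region, ann,
        )
        kept, rej = filter_with_reasons(hits, ann)
        assert not kept and rej[0][1] == "distance"

    def test_ratio_over_one_discarded(self, simple_ann, region):
        hits = self._classified(simple_ann, region)  # d_down 169 > d_up 99
        kept, rej = filter_with_reasons(hits, simple_ann)
        assert not kept and rej[0][1] == "ratio"
        # and the rejected hit is demoted to a canonical 3' terminator
        assert rej[0][0].utr_class == "three_prime"

    def test_non_five_prime_rejected_as_strand(self, simple_ann, region):
        hits = self._classified(simple_ann, region, strand="-")
        kept, rej = filter_with_reasons(hits, simple_ann)
        assert not kept and rej[0][1] == "strand"

    def test_no_upstream_gene_passes_ratio_automatically(self):
        ann = make_annotation(1200, [("g2", 601, 900, "+")])
        region = next(
            r for r in extract_search_regions(ann) if r.right_gene_id == "g2"
        )
        hits = classify_hits([_hit("+", stem5=(340, 347), loop=(348, 351),
                                   stem3=(352, 359), tail=(360, 371))], region, ann)
        cands = apply_attenuator_filters(hits, ann)
        assert len(cands) == 1 and cands[0].ratio == 0.0

    def test_tightening_max_dist_shrinks_candidates(self, default_screen, default_cohort):
        ann = default_cohort.annotations[0]
        from attenuscan.screen import screen_genome

        wide, _, _ = screen_genome(ann, max_dist=300)
        narrow, _, _ = screen_genome(ann, max_dist=100)
        assert len(narrow) <= len(wide)
        wide_ids = {c.candidate_id for c in wide}
        assert all(c.candidate_id in wide_ids for c in narrow)


class TestLeaderExtraction:
    def test_leader_starts_at_upstream_gene_limit(self, simple_ann, region):
        hits = classify_hits(
            [_hit("+", stem5=(470, 477), loop=(478, 481), stem3=(482, 489),
                  tail=(490, 501))], region, simple_ann)
        c = apply_attenuator_filters(hits, simple_ann)[0]
        seq = extract_candidate_sequence(c, simple_ann)
        # upstream gene ends at 300, within 200 nt of the stem at 470
        assert c.leader_interval == (301, 502)
        assert seq == simple_ann.replicons[0].sequence[300:502]

    def test_leader_capped_at_200(self):
        ann = make_annotation(2000, [("g1", 1, 100, "+"), ("g2", 1201, 1500, "+")])
        region = next(r for r in extract_search_regions(ann) if r.left_gene_id == "g1")
        hits = classify_hits(
            [_hit("+", stem5=(1000, 1007), loop=(1008, 1011), stem3=(1012, 1019),
                  tail=(1020, 1031))], region, ann)
        c = apply_attenuator_filters(hits, ann)[0]
        extract_candidate_sequence(c, ann)
        assert c.leader_interval[0] == 1000 - 200

    def test_minus_strand_leader_is_reverse_complement(self):
        ann = make_annotation(1200, [("g1", 1, 300, "-"), ("g2", 601, 900, "-")])
        region = next(r for r in extract_search_regions(ann) if r.left_gene_id == "g1")
        hits = classify_hits([_hit("-")], region, ann)
        c = apply_attenuator_filters(hits, ann)[0]
        seq = extract_candidate_sequence(c, ann)
        lo, hi = c.leader_interval
        assert seq == reverse_complement(ann.replicons[0].sequence[lo - 1 : hi])
        # 5'->3' on the "-" strand: ends just 3' of the tail (lower coords)
        assert lo == c.hit.tail[0] - 1


class TestUtrStats:
    def _hits(self, dgs, stems):
        return [
            TerminatorHit("chr", "+", (1, s), (s + 1, s + 4), (s + 5, 2 * s + 4), 0,
                          (2 * s + 5, 2 * s + 16), s, dg)
            for dg, s in zip(dgs, stems)
        ]

    def test_means(self):
        rep = compare_utr_stats(
            self._hits([-10, -12], [6, 6]), self._hits([-20, -22], [8, 8])
        )
        assert rep.mean_dg5 == -11 and rep.mean_dg3 == -21
        assert rep.mean_stem5 == 6 and rep.mean_stem3 == 8

    def test_identical_lists_p_near_one(self):
        h = self._hits([-10, -11, -12, -13], [6, 7, 8, 9])
        rep = compare_utr_stats(h, list(h))
        assert rep.p_dg == pytest.approx(1.0)

    def test_single_member_lists_have_no_pvalue(self):
        rep = compare_utr_stats(self._hits([-10], [6]), self._hits([-20], [8]))
        assert rep.p_dg is None and rep.p_stem is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compare_utr_stats([], self._hits([-10], [6]))


class TestShuffleControl:
    def test_pure_a_regions_have_zero_rates(self):
        ann = make_annotation(
            1200, [("g1", 1, 300, "+"), ("g2", 601, 900, "+")], seq="A" * 1200
        )
        region = next(r for r in extract_search_regions(ann) if r.left_gene_id == "g1")
        rep = estimate_false_positive_rate([region], ann, n_shuffles=5, seed=1)
        assert rep.fp_rate_5utr == 0.0 and rep.observed_rate == 0.0

    def test_zero_shuffles_rejected(self, simple_ann, region):
        with pytest.raises(ValueError):
            estimate_false_positive_rate([region], simple_ann, n_shuffles=0)

    def test_reproducible_given_seed(self, default_cohort):
        ann = default_cohort.annotations[0]
        regions = extract_search_regions(ann)[:4]
        r1 = estimate_false_positive_rate(regions, ann, n_shuffles=5, seed=9)
        r2 = estimate_false_positive_rate(regions, ann, n_shuffles=5, seed=9)
        assert r1 == r2
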