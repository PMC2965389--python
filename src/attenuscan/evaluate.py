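"""Evaluation of a screen run against a synthetic cohort's truth table.

A detected hit *matches* a planted element when they lie on the same replicon
and strand and their stem spans overlap (the detector may extend a planted
stem by chance pairing, so exact coordinates are not required).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .scan import DescriptorParams, TerminatorHit
from .screen import AttenuatorCandidate, screen_genome
from .simulate import Cohort

__all__ = ["CohortResults", "run_cohort_screen", "match_hits_to_truth",
           "screen_metrics"]


@dataclass
class CohortResults:
    candidates: list[AttenuatorCandidate] = field(default_factory=list)
    hits: list[TerminatorHit] = field(default_factory=list)
    rejections: list[tuple[TerminatorHit, str]] = field(default_factory=list)
    species_of_candidate: dict[str, str] = field(default_factory=dict)


def run_cohort_screen(
    cohort: Cohort, model=None, params: DescriptorParams | None = None, **kwargs
) -> CohortResults:
    res = CohortResults()
    for ann in cohort.annotations:
        cands, hits, rej = screen_genome(ann, model=model, params=params, **kwargs)
        res.candidates.extend(cands)
        res.hits.extend(hits)
        res.rejections.extend(rej)
        for c in cands:
            res.species_of_candidate[c.candidate_id] = ann.species_id
    return res


def _stem_span(h: TerminatorHit) -> tuple[int, int]:
    return (min(h.stem5[0], h.stem3[0]), max(h.stem5[1], h.stem3[1]))


def match_hits_to_truth(
    hits: list[TerminatorHit], truth: pd.DataFrame
) -> dict[int, str | None]:
    """Map hit index -> matching truth element_id (or None)."""
    by_key: dict[tuple[str, str], list] = defaultdict(list)
    for row in truth.itertuples():
        by_key[(row.replicon, row.strand)].append(
            (min(row.stem5_lo, row.stem3_lo), max(row.stem5_hi, row.stem3_hi),
             row.element_id)
        )
    out: dict[int, str | None] = {}
    for i, h in enumerate(hits):
        lo, hi = _stem_span(h)
        out[i] = None
        for a, b, eid in by_key.get((h.replicon_id, h.strand), ()):
            if lo <= b and a <= hi:
                out[i] = eid
                break
    return out


def screen_metrics(res: CohortResults, truth: pd.DataFrame) -> dict:
    """Sensitivity over planted 5' elements, precision of all hits, candidate
    filter audit and violator accounting."""
    matches = match_hits_to_truth(res.hits, truth)
    matched_ids = {m for m in matches.values() if m}
    n_matched_hits = sum(1 for m in matches.values() if m)

    t5 = truth[(truth.klass == "5p") & (truth.violation == "")]
    positives = truth[truth.violation == ""]
    sens_5p = len(matched_ids & set(t5.element_id)) / len(t5) if len(t5) else float("nan")
    sens_all = (
        len(matched_ids & set(positives.element_id)) / len(positives)
        if len(positives) else float("nan")
    )
    precision = n_matched_hits / len(res.hits) if res.hits else float("nan")

    cand_matches = match_hits_to_truth([c.hit for c in res.candidates], truth)
    cand_ids = {m for m in cand_matches.values() if m}
    viol = truth[truth.violation != ""]
    viol_as_candidates = cand_ids & set(viol.element_id)

    rej_hits = [h for h, _ in res.rejections]
    rej_matches = match_hits_to_truth(rej_hits, truth)
    reason_by_element: dict[str, str] = {}
    for i, (_, reason) in enumerate(res.rejections):
        eid = rej_matches[i]
        if eid and eid not in reason_by_element:
            reason_by_element[eid] = reason
    viol_correct = sum(
        1 for row in viol.itertuples()
        if reason_by_element.get(row.element_id) == row.violation
    )
    filter_violations = sum(
        1 for c in res.candidates if c.d_down > 300 or c.ratio > 1.0
    )
    return {
        "sensitivity_5p": sens_5p,
        "sensitivity_all": sens_all,
        "precision": precision,
        "n_hits": len(res.hits),
        "n_candidates": len(res.candidates),
        "n_violators": len(viol),
        "violators_as_candidates": len(viol_as_candidates),
        "violators_rejected_with_labeled_reason": viol_correct,
        "candidates_violating_filters": filter_violations,
    }
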