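"""End-to-end pipeline on a simulated study, with truth-based evaluation.

Chains simulate -> detect -> classify -> date -> deletion detection per
variety -> polymorphism scoring -> gene-context annotation -> report, and
computes the parameter-recovery metrics against the planted truth.  Used by
the test suite, the acceptance script and the ``run-all`` CLI command.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .classify import ClassifiedElement, classify_elements
from .dating import AgedElement, DatingConfig, date_all
from .detect import DetectorConfig, LTRCandidate, find_candidates
from .genes import GeneRecord, annotate_context
from .polymorph import DeletionCall, detect_deletions, reciprocal_overlap, \
    score_polymorphisms
from .report import age_histogram, summarize_counts
from .simulate import SimConfig, derive_varieties, simulate_reference

#: Matching rule between a detected and a planted element: reciprocal
#: element-interval overlap of at least this fraction.
MATCH_RECIPROCAL_OVERLAP = 0.8


@dataclass
class PipelineResult:
    config: SimConfig
    genome: Dict[str, str]
    truth: pd.DataFrame
    gene_records: List[GeneRecord]
    varieties: Dict[str, Dict[str, str]]
    candidates: List[LTRCandidate]
    classified: List[ClassifiedElement]
    aged: List[AgedElement]
    deletion_calls: List[DeletionCall]
    polymorphism_records: list
    polymorphism_summary: pd.DataFrame
    gene_context: pd.DataFrame
    counts: pd.DataFrame
    histogram: pd.DataFrame
    timings: Dict[str, float] = field(default_factory=dict)


def run_pipeline(config: Optional[SimConfig] = None,
                 detector_config: Optional[DetectorConfig] = None,
                 dating_config: Optional[DatingConfig] = None,
                 reciprocal_threshold: float = 0.90,
                 upstream_window: int = 1000) -> PipelineResult:
    cfg = config or SimConfig()
    timings: Dict[str, float] = {}

    def timed(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        out = fn(*args, **kwargs)
        timings[name] = time.perf_counter() - t0
        return out

    genome, truth, gene_records = timed("simulate", simulate_reference, cfg)
    varieties, truth = timed("varieties", derive_varieties, genome, truth, cfg)
    candidates = timed("detect", find_candidates, genome, detector_config)
    classified = timed("classify", classify_elements, candidates, genome)
    aged = timed("date", date_all, classified, genome, dating_config)

    t0 = time.perf_counter()
    calls: List[DeletionCall] = []
    for name, var_genome in varieties.items():
        calls.extend(detect_deletions(genome, var_genome, name))
    timings["deletions"] = time.perf_counter() - t0

    records, summary = timed(
        "polymorph", score_polymorphisms, aged, calls,
        reciprocal_threshold, True, sorted(varieties))
    context = timed("genes", annotate_context, aged, gene_records,
                    upstream_window)
    counts = summarize_counts(
        aged, (dating_config or DatingConfig()).young_threshold_mya)
    hist = age_histogram(aged)

    return PipelineResult(cfg, genome, truth, gene_records, varieties, candidates,
                          classified, aged, calls, records, summary, context,
                          counts, hist, timings)


# ---------------------------------------------------------------------------
# Parameter-recovery evaluation against planted truth
# ---------------------------------------------------------------------------

def match_candidates_to_truth(candidates, truth: pd.DataFrame,
                              min_overlap: float = MATCH_RECIPROCAL_OVERLAP
                              ) -> Dict[str, str]:
    """Map candidate element_id -> planted element_id by best reciprocal
    overlap >= *min_overlap*; one-to-one (greedy by overlap)."""
    pairs = []
    for cand in candidates:
        for row in truth.itertuples():
            if row.chrom != cand.chrom:
                continue
            f_c, f_t = reciprocal_overlap(
                (cand.chrom, cand.start, cand.end),
                (row.chrom, int(row.start), int(row.end)))
            m = min(f_c, f_t)
            if m >= min_overlap:
                pairs.append((m, cand.element_id, row.element_id))
    pairs.sort(reverse=True)
    mapping: Dict[str, str] = {}
    used = set()
    for _, cid, tid in pairs:
        if cid in mapping or tid in used:
            continue
        mapping[cid] = tid
        used.add(tid)
    return mapping


def evaluate_recovery(result: PipelineResult) -> Dict[str, float]:
    """Recovery metrics of every stage against the planted truth."""
    truth = result.truth
    mapping = match_candidates_to_truth(result.candidates, truth)
    n_truth = len(truth)
    n_cand = len(result.candidates)
    recall = len(mapping) / n_truth if n_truth else float("nan")
    precision = len(mapping) / n_cand if n_cand else float("nan")

    truth_by_id = {r.element_id: r for r in truth.itertuples()}

    # superfamily accuracy over matched, classified elements
    cls_ok = cls_n = 0
    for el in result.classified:
        tid = mapping.get(el.element_id)
        if tid is None:
            continue
        cls_n += 1
        if el.superfamily == truth_by_id[tid].superfamily:
            cls_ok += 1
    classification_accuracy = cls_ok / cls_n if cls_n else float("nan")

    # age regression (estimated on true), non-saturated matched elements
    true_ages, est_ages = [], []
    for a in result.aged:
        tid = mapping.get(a.element_id)
        if tid is None or a.saturated or a.age_mya is None:
            continue
        true_ages.append(float(truth_by_id[tid].true_age_mya))
        est_ages.append(a.age_mya)
    if len(true_ages) >= 3:
        slope, intercept = np.polyfit(true_ages, est_ages, 1)
    else:
        slope, intercept = float("nan"), float("nan")

    # polymorphism confusion vs planted presence flags
    var_names = sorted(result.varieties)
    status = {(r.element_id, r.sample_id): r.status
              for r in result.polymorphism_records}
    tp = fp = tn = fn = 0
    for a in result.aged:
        tid = mapping.get(a.element_id)
        if tid is None:
            continue
        row = truth_by_id[tid]
        for v in var_names:
            truly_absent = not getattr(row, f"present_{v}")
            called_absent = status.get((a.element_id, v)) == "absent"
            if truly_absent and called_absent:
                tp += 1
            elif truly_absent:
                fn += 1
            elif called_absent:
                fp += 1
            else:
                tn += 1
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")

    # upstream near-gene flags: detected flagged set vs planted subset
    flagged = {mapping[eid] for eid, near in
               zip(result.gene_context.element_id, result.gene_context.near_gene)
               if near and eid in mapping}
    planted = {r.element_id for r in truth.itertuples()
               if pd.notna(r.upstream_distance)}
    upstream_exact = float(flagged == planted)
    inter = len(flagged & planted)
    union = len(flagged | planted)
    upstream_jaccard = inter / union if union else 1.0

    return {
        "n_planted": n_truth,
        "n_detected": n_cand,
        "n_matched": len(mapping),
        "detector_recall": recall,
        "detector_precision": precision,
        "classification_accuracy": classification_accuracy,
        "n_classified_matched": cls_n,
        "age_regression_slope": float(slope),
        "age_regression_intercept": float(intercept),
        "n_dated": len(true_ages),
        "polymorphism_sensitivity": sensitivity,
        "polymorphism_specificity": specificity,
        "n_polymorphism_pairs": tp + fp + tn + fn,
        "upstream_flags_exact": upstream_exact,
        "upstream_flags_jaccard": upstream_jaccard,
        "n_upstream_planted": len(planted),
    }


def dating_recovery_regression(n_pairs: int = 400, seed: int = 0,
                               age_range_mya=(0.1, 3.0),
                               ltr_length_range=(300, 1500),
                               mutation_rate: float = 7e-9,
                               kappa: float = 2.0):
    """Regression of estimated on true insertion age over simulated LTR pairs.

    For each pair an ancestral LTR is drawn, both copies are evolved
    independently to a uniform age, and the age is re-estimated through the
    full alignment -> Kimura-2P -> age chain.  Returns ``(slope, intercept,
    n_pairs)``.  The slope should sit in [0.9, 1.1] for an unbiased dating
    chain; the per-element scatter is the binomial sampling variance of K at
    the drawn LTR length.
    """
    from .dating import estimate_age, kimura2p
    from .detect import ltr_pair_identity
    from .simulate import evolve_sequence, indices_to_str, random_sequence

    rng = np.random.default_rng([seed, 0xda7e])
    cfg = DatingConfig(mutation_rate=mutation_rate)
    true_ages, est_ages = [], []
    for _ in range(n_pairs):
        age = float(rng.uniform(*age_range_mya))
        length = int(rng.integers(ltr_length_range[0], ltr_length_range[1] + 1))
        d = mutation_rate * age * 1e6
        anc = random_sequence(length, 0.38, rng)
        a = evolve_sequence(anc, d, kappa, rng)
        b = evolve_sequence(anc, d, kappa, rng)
        _, aln = ltr_pair_identity(indices_to_str(a), indices_to_str(b))
        k2p = kimura2p(str(aln[0]), str(aln[1]))
        if k2p.saturated:
            continue
        true_ages.append(age)
        est_ages.append(estimate_age(k2p.K, cfg))
    slope, intercept = np.polyfit(true_ages, est_ages, 1)
    return float(slope), float(intercept), len(true_ages)
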