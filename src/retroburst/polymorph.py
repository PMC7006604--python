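"""Insertion-polymorphism scoring across accessions.

A reference element is called absent in an accession when a deletion call
overlaps it reciprocally by at least 90% of both lengths — the rule used to
score polymorphic insertions from resequencing-derived deletion calls.  Calls
can come from external BED/VCF files (e.g. produced by a split-read caller on
mapped short reads) or from the built-in genome-vs-genome anchor detector,
which is what the synthetic varieties use.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd


@dataclass(frozen=True)
class DeletionCall:
    sample_id: str
    chrom: str
    start: int  # reference coordinates, 0-based half-open
    end: int
    support: Optional[int] = None
    source: str = "external"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("deletion interval must be non-empty")


@dataclass(frozen=True)
class PolymorphismRecord:
    element_id: str
    sample_id: str
    status: str  # 'present' or 'absent'
    f_element: float
    f_deletion: float
    deletion: Optional[Tuple[int, int]]  # matching call interval, if any


# ---------------------------------------------------------------------------
# Built-in genome-vs-genome deletion detector
# ---------------------------------------------------------------------------

def _unique_kmer_positions(seq: str, k: int) -> Dict[str, int]:
    counts = Counter(seq[i:i + k] for i in range(len(seq) - k + 1))
    pos: Dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if counts[kmer] == 1 and "N" not in kmer:
            pos[kmer] = i
    return pos


def detect_deletions(reference: Dict[str, str], variety: Dict[str, str],
                     sample_id: str, anchor_k: int = 31, min_deletion: int = 50,
                     max_gap_ratio: float = 0.10) -> List[DeletionCall]:
    """Call deletions in *variety* relative to *reference* via unique k-mer anchors.

    Anchors are k-mers unique in both genomes' homologous chromosome; a
    collinear chain of anchors is built and a deletion is emitted for every
    reference-side gap of at least *min_deletion* bp between adjacent anchors
    whose variety-side gap is below ``max_gap_ratio`` of the reference gap.
    Coordinates are on the reference.
    """
    calls: List[DeletionCall] = []
    for chrom in sorted(set(reference) | set(variety)):
        if chrom not in reference or chrom not in variety:
            warnings.warn(f"chromosome {chrom} present in only one genome; skipped")
            continue
        ref_pos = _unique_kmer_positions(reference[chrom].upper(), anchor_k)
        var_pos = _unique_kmer_positions(variety[chrom].upper(), anchor_k)
        anchors = sorted(
            (p, var_pos[kmer]) for kmer, p in ref_pos.items() if kmer in var_pos
        )
        # enforce collinearity: keep anchors whose variety position increases
        chain: List[Tuple[int, int]] = []
        last_v = -1
        for r, v in anchors:
            if v > last_v:
                chain.append((r, v))
                last_v = v
        for (r1, v1), (r2, v2) in zip(chain, chain[1:]):
            ref_gap = r2 - (r1 + anchor_k)
            var_gap = v2 - (v1 + anchor_k)
            if ref_gap >= min_deletion and var_gap < max_gap_ratio * ref_gap:
                calls.append(DeletionCall(sample_id, chrom, r1 + anchor_k, r2,
                                          support=None, source="anchor_detector"))
    calls.sort(key=lambda c: (c.chrom, c.start))
    return calls


# ---------------------------------------------------------------------------
# External call readers
# ---------------------------------------------------------------------------

def read_bed_calls(path: str, sample_id: str) -> List[DeletionCall]:
    """Deletion calls from a BED file (0-based half-open; optional 5th column
    read as supporting-evidence count)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    calls = []
    for row in df.itertuples(index=False):
        support = int(row[4]) if len(row) > 4 and pd.notna(row[4]) else None
        calls.append(DeletionCall(sample_id, str(row[0]), int(row[1]), int(row[2]),
                                  support=support, source="external"))
    return calls


def read_vcf_calls(path: str, sample_id: str,
                   min_support: Optional[int] = None) -> List[DeletionCall]:
    """Deletion calls from a VCF: symbolic <DEL> records (using INFO/END) or
    explicit REF/ALT length differences.  Support is taken from INFO/SUPPORT
    when present; *min_support* optionally filters (external callers typically
    require >= 5 supporting reads)."""
    import pysam

    calls = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            alt = rec.alts[0] if rec.alts else None
            if alt == "<DEL>":
                start, end = rec.start, rec.stop
            elif alt is not None and len(rec.ref) > len(alt):
                start, end = rec.start + len(alt), rec.start + len(rec.ref)
            else:
                continue
            support = rec.info.get("SUPPORT", None)
            if isinstance(support, tuple):
                support = support[0]
            if min_support is not None and support is not None and support < min_support:
                continue
            calls.append(DeletionCall(sample_id, rec.chrom, start, end,
                                      support=support, source="external"))
    return calls


# ---------------------------------------------------------------------------
# Reciprocal-overlap scoring
# ---------------------------------------------------------------------------

Interval = Tuple[str, int, int]


def reciprocal_overlap(a: Interval, b: Interval) -> Tuple[float, float]:
    """Overlap fractions ``(|a∩b|/|a|, |a∩b|/|b|)``; (0,0) across chromosomes."""
    chrom_a, start_a, end_a = a
    chrom_b, start_b, end_b = b
    if chrom_a != chrom_b:
        return 0.0, 0.0
    inter = min(end_a, end_b) - max(start_a, start_b)
    if inter <= 0:
        return 0.0, 0.0
    return inter / (end_a - start_a), inter / (end_b - start_b)


def score_polymorphisms(elements: Sequence, calls: Sequence[DeletionCall],
                        threshold: float = 0.90, inclusive: bool = True,
                        samples: Optional[Sequence[str]] = None):
    """Score each (element, sample) pair as present/absent.

    An element is absent in a sample when some deletion call overlaps it with
    ``min(f_element, f_deletion) >= threshold`` (strictly greater when
    *inclusive* is false).  The element interval spans LTR to LTR, excluding
    TSDs.  Returns ``(records, summary)``: per-pair records and a per-element
    summary with the number of samples lacking the element and a
    ``polymorphic`` flag (absent in at least one sample).
    """
    samples = sorted(samples) if samples is not None else sorted(
        {c.sample_id for c in calls})
    by_sample: Dict[str, List[DeletionCall]] = defaultdict(list)
    for c in calls:
        by_sample[c.sample_id].append(c)

    records: List[PolymorphismRecord] = []
    for el in elements:
        for sample in samples:
            best = (0.0, 0.0, None)
            for call in by_sample[sample]:
                f_e, f_d = reciprocal_overlap(
                    (el.chrom, el.start, el.end), (call.chrom, call.start, call.end))
                if min(f_e, f_d) > min(best[0], best[1]):
                    best = (f_e, f_d, (call.start, call.end))
            m = min(best[0], best[1])
            absent = (m >= threshold) if inclusive else (m > threshold)
            records.append(PolymorphismRecord(
                el.element_id, sample, "absent" if absent else "present",
                best[0], best[1], best[2] if absent else None))

    rec_df = pd.DataFrame(
        [(r.element_id, r.sample_id, r.status, r.f_element, r.f_deletion)
         for r in records],
        columns=["element_id", "sample_id", "status", "f_element", "f_deletion"])
    if rec_df.empty:
        summary = pd.DataFrame(columns=["element_id", "n_absent", "polymorphic"])
    else:
        summary = (
            rec_df.assign(absent=rec_df.status == "absent")
            .groupby("element_id", sort=True)["absent"].sum()
            .rename("n_absent").reset_index()
        )
        summary["polymorphic"] = summary.n_absent >= 1
    return records, summary
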