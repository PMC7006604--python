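"""Structural detection of full-length LTR-retrotransposon candidates.

A full-length element is recognised purely from genome structure: two similar
direct repeats (the LTRs) at a plausible distance, optionally flanked by an
identical short target-site duplication.  The detector seeds exact k-mer
matches on the forward strand, clusters them by diagonal, extends each
cluster into a maximal repeat pair with an ungapped X-drop extension, scores
the pair by global alignment identity, and greedily resolves overlapping
candidates.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from Bio import Align

_VALID_CHARS = set("ACGTNRYSWKMBDHVU")

# X-drop extension scoring: ungapped, match +1 / mismatch -2, stop once the
# running score falls this far below its maximum.
_XDROP = 8
_DIAG_BAND = 20  # seed matches within this diagonal distance join one cluster
_MAX_KMER_OCC = 12  # k-mers more frequent than this are skipped as repetitive


@dataclass
class DetectorConfig:
    min_ltr_len: int = 100
    max_ltr_len: int = 3500
    min_element_len: int = 1000
    max_element_len: int = 16000
    min_ltr_identity: float = 85.0
    seed_kmer: int = 20
    tsd_len_range: Tuple[int, int] = (4, 6)
    tsd_required: bool = False

    def __post_init__(self):
        if self.min_ltr_len > self.max_ltr_len:
            raise ValueError("min_ltr_len > max_ltr_len")
        if self.min_element_len > self.max_element_len:
            raise ValueError("min_element_len > max_element_len")
        if not 0 < self.min_ltr_identity <= 100:
            raise ValueError("min_ltr_identity must lie in (0,100]")
        if self.seed_kmer < 8:
            raise ValueError("seed_kmer must be >= 8")
        if self.tsd_len_range[0] > self.tsd_len_range[1]:
            raise ValueError("tsd_len_range empty")


@dataclass
class LTRCandidate:
    """A structurally detected element; coordinates 0-based half-open.

    The element interval runs from the start of the 5' LTR to the end of the
    3' LTR (TSDs excluded).
    """

    element_id: str
    chrom: str
    start: int
    end: int
    ltr5_start: int
    ltr5_end: int
    ltr3_start: int
    ltr3_end: int
    ltr_identity: float
    tsd: Optional[str]
    score: float

    @property
    def length(self) -> int:
        return self.end - self.start


def _nucleotide_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -2
    aligner.open_gap_score = -6
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _nucleotide_aligner()


def ltr_pair_identity(seq_a: str, seq_b: str):
    """Global end-gap-penalised alignment of two LTRs.

    Returns ``(identity_percent, alignment)``; identity is matches over all
    aligned columns (a pairwise alignment never produces a both-gap column).
    The alignment is reused by the dating stage.
    """
    if not seq_a or not seq_b:
        raise ValueError("both sequences must be non-empty")
    alignment = _ALIGNER.align(seq_a.upper(), seq_b.upper())[0]
    counts = alignment.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    return 100.0 * counts.identities / columns, alignment


def _index_kmers(seq: str, k: int) -> Dict[str, List[int]]:
    index: Dict[str, List[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if "N" not in kmer:
            index[kmer].append(i)
    return index


def _seed_pairs(index: Dict[str, List[int]], lo: int, hi: int) -> List[Tuple[int, int]]:
    pairs = []
    for positions in index.values():
        if len(positions) < 2 or len(positions) > _MAX_KMER_OCC:
            continue
        for a in range(len(positions)):
            for b in range(a + 1, len(positions)):
                dist = positions[b] - positions[a]
                if lo <= dist <= hi:
                    pairs.append((positions[a], positions[b]))
    return pairs


def _cluster_seeds(pairs: List[Tuple[int, int]], max_ltr_len: int):
    """Group seed matches into diagonal clusters (one per putative LTR pair)."""
    pairs = sorted(pairs, key=lambda p: (p[1] - p[0], p[0]))
    clusters: List[List[Tuple[int, int]]] = []
    for p1, p2 in pairs:
        d = p2 - p1
        placed = False
        if clusters:
            last = clusters[-1]
            last_d = last[-1][1] - last[-1][0]
            if abs(d - last_d) <= _DIAG_BAND and 0 <= p1 - last[-1][0] <= max_ltr_len:
                last.append((p1, p2))
                placed = True
        if not placed:
            clusters.append([(p1, p2)])
    return clusters


def _extend(seq: str, i: int, j: int, step: int, stop_i: int, stop_j: int) -> int:
    """Ungapped X-drop extension; returns the number of columns kept."""
    score = best = 0
    best_len = 0
    length = 0
    while True:
        i += step
        j += step
        if step < 0 and (i < stop_i or j <= stop_j):
            break
        if step > 0 and (i >= stop_i or j >= stop_j):
            break
        a, b = seq[i], seq[j]
        if a == "N" or b == "N":
            break
        length += 1
        score += 1 if a == b else -2
        if score > best:
            best, best_len = score, length
        elif score < best - _XDROP:
            break
    return best_len


def _find_tsd(seq: str, start: int, end: int, cfg: DetectorConfig) -> Optional[str]:
    lo, hi = cfg.tsd_len_range
    for L in range(hi, lo - 1, -1):
        if start - L < 0 or end + L > len(seq):
            continue
        left = seq[start - L:start]
        right = seq[end:end + L]
        if left == right and "N" not in left:
            return left
    return None


def find_candidates(genome: Dict[str, str], config: DetectorConfig | None = None
                    ) -> List[LTRCandidate]:
    """Detect candidate full-length LTR-retrotransposons in *genome*.

    *genome* maps chromosome names to sequences over the IUPAC nucleotide
    alphabet; reported candidates never span an N run.  Output is sorted by
    (chrom, start) and is invariant under permutation of the input records.
    """
    cfg = config or DetectorConfig()
    k = cfg.seed_kmer
    candidates: List[LTRCandidate] = []
    lo = max(cfg.min_ltr_len, cfg.min_element_len - cfg.max_ltr_len)
    hi = cfg.max_element_len

    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        bad = set(seq) - _VALID_CHARS
        if bad:
            raise ValueError(
                f"record '{chrom}' contains non-IUPAC characters: {sorted(bad)}"
            )
        # ambiguity codes other than N carry no seedable information here
        if set(seq) - set("ACGTN"):
            seq = "".join(c if c in "ACGTN" else "N" for c in seq)
        if len(seq) < k:
            continue
        index = _index_kmers(seq, k)
        for cluster in _cluster_seeds(_seed_pairs(index, lo, hi), cfg.max_ltr_len):
            cand = _cluster_to_candidate(seq, chrom, cluster, k, cfg)
            if cand is not None:
                candidates.append(cand)

    resolved = _resolve_overlaps(candidates)
    resolved.sort(key=lambda c: (c.chrom, c.start, c.end))
    for i, cand in enumerate(resolved):
        cand.element_id = f"RB{i + 1:04d}"
    return resolved


def _cluster_to_candidate(seq: str, chrom: str, cluster, k: int,
                          cfg: DetectorConfig) -> Optional[LTRCandidate]:
    a1 = min(p for p, _ in cluster)
    b1 = max(p for p, _ in cluster) + k
    a2 = min(q for _, q in cluster)
    b2 = max(q for _, q in cluster) + k
    if a2 < b1:  # the two repeat copies must not overlap
        return None
    left = _extend(seq, a1, a2, -1, 0, b1 - 1)
    right = _extend(seq, b1 - 1, b2 - 1, +1, a2, len(seq))
    l1, r1 = a1 - left, b1 + right
    l2, r2 = a2 - left, b2 + right

    len5, len3 = r1 - l1, r2 - l2
    elem_len = r2 - l1
    if not (cfg.min_ltr_len <= len5 <= cfg.max_ltr_len):
        return None
    if not (cfg.min_ltr_len <= len3 <= cfg.max_ltr_len):
        return None
    if not (cfg.min_element_len <= elem_len <= cfg.max_element_len):
        return None
    if "N" in seq[l1:r2]:
        return None
    identity, _ = ltr_pair_identity(seq[l1:r1], seq[l2:r2])
    if identity < cfg.min_ltr_identity:
        return None
    tsd = _find_tsd(seq, l1, r2, cfg)
    if cfg.tsd_required and tsd is None:
        return None
    score = identity * (len5 + len3) / 2.0
    return LTRCandidate("", chrom, l1, r2, l1, r1, l2, r2, identity, tsd, score)


def _resolve_overlaps(candidates: List[LTRCandidate]) -> List[LTRCandidate]:
    """Greedy selection by score; ties broken leftmost, then longest."""
    ordered = sorted(
        candidates, key=lambda c: (-c.score, c.chrom, c.start, -(c.end - c.start))
    )
    kept: List[LTRCandidate] = []
    by_chrom: Dict[str, List[Tuple[int, int]]] = defaultdict(list)
    for cand in ordered:
        if any(cand.start < e and s < cand.end for s, e in by_chrom[cand.chrom]):
            continue
        kept.append(cand)
        by_chrom[cand.chrom].append((cand.start, cand.end))
    return kept
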