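"""Coding-domain scan and Gypsy/Copia superfamily classification.

Each candidate's internal region is translated in all six frames and scanned
for the five canonical retroelement domains (GAG, PR, INT, RT, RH) by local
protein alignment against packaged consensus peptides.  Candidates without
any domain hit are filtered out as non-coding; the remainder are classified
by the order of the order-defining domains along the inferred coding strand:
integrase upstream of reverse transcriptase is Copia
(GAG-PR-INT-RT-RH), integrase downstream is Gypsy (GAG-PR-RT-RH-INT), and
elements missing either domain — or with hits on contradictory strands — are
tagged unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .detect import LTRCandidate
from .domains import COPIA_ORDER, DOMAIN_NAMES, DOMAIN_PEPTIDES, GYPSY_ORDER

#: Fraction of a profile's self-alignment score required to call a hit.
#: Calibrated on the synthetic null: shuffled sequences of realistic length
#: score well below half of a perfect match under BLOSUM62.
DEFAULT_SCORE_FRACTION = 0.5


@dataclass(frozen=True)
class DomainProfile:
    name: str
    consensus: str
    min_score: float

    def __post_init__(self):
        if len(self.consensus) < 20:
            raise ValueError(f"profile {self.name}: consensus must be >= 20 aa")


@dataclass
class DomainHit:
    domain: str
    frame: int  # 0-2 forward, 3-5 reverse
    peptide_start: int
    peptide_end: int
    nt_start: int  # projected onto the scanned (internal) sequence, forward coords
    nt_end: int
    score: float

    @property
    def strand(self) -> str:
        return "+" if self.frame < 3 else "-"


@dataclass
class ClassifiedElement:
    candidate: LTRCandidate
    hits: List[DomainHit] = field(default_factory=list)
    coding: bool = False
    superfamily: str = "Unclassified"
    strand: Optional[str] = None
    strand_conflict: bool = False

    # convenience pass-throughs used across the pipeline
    @property
    def element_id(self) -> str:
        return self.candidate.element_id

    @property
    def chrom(self) -> str:
        return self.candidate.chrom

    @property
    def start(self) -> int:
        return self.candidate.start

    @property
    def end(self) -> int:
        return self.candidate.end


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    matrix = substitution_matrices.load("BLOSUM62")
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


_PROT_ALIGNER = _protein_aligner()


def self_score(peptide: str) -> float:
    matrix = _PROT_ALIGNER.substitution_matrix
    return float(sum(matrix[aa, aa] for aa in peptide))


def default_profiles(score_fraction: float = DEFAULT_SCORE_FRACTION
                     ) -> List[DomainProfile]:
    """The packaged consensus profiles with thresholds at a fraction of self-score."""
    return [
        DomainProfile(name, pep, score_fraction * self_score(pep))
        for name, pep in DOMAIN_PEPTIDES.items()
    ]


def load_profiles(fasta_path: str, thresholds_path: Optional[str] = None,
                  score_fraction: float = DEFAULT_SCORE_FRACTION) -> List[DomainProfile]:
    """Load a user-supplied profile set: peptide FASTA plus optional TSV of
    per-profile minimum scores (columns: name, min_score)."""
    from Bio import SeqIO

    thresholds: Dict[str, float] = {}
    if thresholds_path:
        with open(thresholds_path) as fh:
            for line in fh:
                if line.strip() and not line.startswith("#"):
                    name, value = line.split()[:2]
                    thresholds[name] = float(value)
    profiles = []
    for rec in SeqIO.parse(fasta_path, "fasta"):
        pep = str(rec.seq)
        min_score = thresholds.get(rec.id, score_fraction * self_score(pep))
        profiles.append(DomainProfile(rec.id, pep, min_score))
    if not profiles:
        raise ValueError(f"no profiles found in {fasta_path}")
    return profiles


def six_frame_translate(seq: str) -> List[str]:
    """Translate *seq* in the six frames (0-2 forward, 3-5 on the reverse
    complement), standard genetic code, stops rendered as '*'."""
    if len(seq) < 3:
        raise ValueError("sequence must be at least 3 nt")
    seq = seq.upper()
    rc = str(Seq(seq).reverse_complement())
    frames = []
    for source in (seq, rc):
        for f in range(3):
            sub = source[f:]
            sub = sub[: len(sub) - len(sub) % 3]
            frames.append(str(Seq(sub).translate()))
    return frames


def _project_to_nucleotides(frame: int, pep_start: int, pep_end: int,
                            seq_len: int) -> Tuple[int, int]:
    if frame < 3:
        return frame + 3 * pep_start, frame + 3 * pep_end
    f = frame - 3
    # peptide coordinates live on the reverse complement; map back
    rc_start, rc_end = f + 3 * pep_start, f + 3 * pep_end
    return seq_len - rc_end, seq_len - rc_start


def scan_domains(seq: str, profiles: Sequence[DomainProfile]) -> List[DomainHit]:
    """Scan an internal-region sequence for domain hits.

    Best local alignment of each profile against each translated frame; at
    most one hit per domain name is retained (highest score; ties resolved by
    leftmost projected nucleotide start, then lowest frame).
    """
    if not profiles:
        raise ValueError("empty profile set")
    frames = six_frame_translate(seq)
    best: Dict[str, DomainHit] = {}
    for profile in profiles:
        for frame_idx, pep in enumerate(frames):
            if not pep:
                continue
            alignments = _PROT_ALIGNER.align(pep, profile.consensus)
            if alignments.score < profile.min_score:
                continue
            aln = alignments[0]
            tstart, tend = int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1])
            nt_start, nt_end = _project_to_nucleotides(frame_idx, tstart, tend, len(seq))
            hit = DomainHit(profile.name, frame_idx, tstart, tend,
                            nt_start, nt_end, float(alignments.score))
            prev = best.get(profile.name)
            if prev is None or (hit.score, -hit.nt_start, -hit.frame) > (
                    prev.score, -prev.nt_start, -prev.frame):
                best[profile.name] = hit
    return sorted(best.values(), key=lambda h: h.nt_start)


def classify(hits: Sequence[DomainHit], strict_five_domains: bool = False):
    """Superfamily call from domain hits alone.

    Returns ``(superfamily, coding, strand, strand_conflict)``.  *coding* is
    true when at least one domain hit exists.  With the default rule only the
    relative order of INT and RT along the coding strand decides Copia vs
    Gypsy; ``strict_five_domains`` instead requires all five domains in exact
    canonical order.
    """
    coding = len(hits) > 0
    if not coding:
        return "Unclassified", False, None, False
    strands = {h.strand for h in hits}
    if len(strands) > 1:
        return "Unclassified", True, None, True
    strand = strands.pop()
    ordered = sorted(hits, key=lambda h: h.nt_start if strand == "+" else -h.nt_start)
    names = [h.domain for h in ordered]
    if strict_five_domains:
        if tuple(names) == COPIA_ORDER:
            return "Copia", True, strand, False
        if tuple(names) == GYPSY_ORDER:
            return "Gypsy", True, strand, False
        return "Unclassified", True, strand, False
    if "INT" not in names or "RT" not in names:
        return "Unclassified", True, strand, False
    if names.index("INT") < names.index("RT"):
        return "Copia", True, strand, False
    return "Gypsy", True, strand, False


def classify_elements(candidates: Sequence[LTRCandidate], genome: Dict[str, str],
                      profiles: Optional[Sequence[DomainProfile]] = None,
                      strict_five_domains: bool = False) -> List[ClassifiedElement]:
    """Scan and classify all candidates; non-coding candidates are dropped."""
    profiles = list(profiles) if profiles is not None else default_profiles()
    out: List[ClassifiedElement] = []
    for cand in candidates:
        internal = genome[cand.chrom][cand.ltr5_end:cand.ltr3_start]
        hits = scan_domains(internal, profiles) if len(internal) >= 3 else []
        superfamily, coding, strand, conflict = classify(hits, strict_five_domains)
        if not coding:
            continue
        out.append(ClassifiedElement(cand, hits, coding, superfamily, strand, conflict))
    return out
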