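"""Synthetic genome simulator with planted LTR-retrotransposons and ground truth.

Generates a multi-chromosome reference genome carrying full-length
LTR-retrotransposons whose two terminal repeats start identical and are then
evolved apart so that their expected Kimura two-parameter divergence equals
2·mu·T for a drawn insertion age T, plus target-site duplications, internal
coding cassettes in Copia or Gypsy domain order, decoy repeats (solo LTRs,
truncated elements), planted genes (a configurable fraction of elements lands
< 1,000 bp upstream of a gene start), and derived "variety" genomes in which a
random subset of elements is cleanly excised back to the pre-insertion allele.
Every planted feature is recorded in a truth table so downstream detection,
classification, dating, polymorphism scoring and gene-context annotation can
all be validated by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .domains import COPIA_ORDER, GYPSY_ORDER, DOMAIN_PEPTIDES, encode_peptide
from .genes import GeneRecord

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: Minimum background gap between any two planted features (bp).  Large enough
#: that a non-paired element can never fall inside the upstream window of a
#: neighbouring gene, so the planted near-gene subset is exactly recoverable.
MIN_SPACER = 1500

#: Gap drawn between a paired element and its downstream gene, in bp.  Kept
#: well inside the 1,000 bp window (with the TSD added, max < 950) so detector
#: boundary uncertainty of a few bp cannot flip the flag.
UPSTREAM_GAP_RANGE = (20, 920)


class SimulationError(ValueError):
    """Raised when a configuration cannot be realised (e.g. placement overflow)."""


@dataclass
class SimConfig:
    """Parameters of one simulated study.

    Defaults describe the standard desk-scale benchmark: two 1-Mb
    chromosomes, 50 planted elements with insertion ages uniform on
    [0.1, 3] Mya under the Arabidopsis-calibrated per-year substitution rate
    mu = 7e-9, six derived varieties with each element excised independently
    with probability 0.5, and 20% of elements planted < 1,000 bp upstream of
    a gene.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    gc_content: float = 0.38
    n_elements: int = 50
    ltr_length_range: Tuple[int, int] = (300, 1500)
    internal_length_range: Tuple[int, int] = (3000, 6000)
    tsd_length_range: Tuple[int, int] = (4, 6)
    age_range_mya: Tuple[float, float] = (0.1, 3.0)
    mutation_rate: float = 7e-9  # substitutions / site / year
    transition_bias: float = 2.0  # kappa = transition rate / transversion rate
    superfamily_mix: Dict[str, float] = field(
        default_factory=lambda: {"Gypsy": 0.4, "Copia": 0.4, "Unclassified": 0.2}
    )
    n_varieties: int = 6
    excision_probability: float = 0.5
    n_genes: int = 30
    upstream_fraction: float = 0.2
    n_solo_ltrs: int = 10
    n_truncated: int = 10
    indel_rate: float = 0.0  # per-site indel rate inside LTRs; dating assumes 0
    gene_length_range: Tuple[int, int] = (1000, 3000)

    def __post_init__(self):
        if self.mutation_rate <= 0:
            raise SimulationError("mutation_rate must be > 0")
        if not 0 < self.gc_content < 1:
            raise SimulationError("gc_content must lie in (0,1)")
        for name in ("ltr_length_range", "internal_length_range",
                     "tsd_length_range", "age_range_mya", "gene_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise SimulationError(f"{name} must be a non-empty non-negative range")
        for name in ("excision_probability", "upstream_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimulationError(f"{name} must lie in [0,1]")
        if abs(sum(self.superfamily_mix.values()) - 1.0) > 1e-9:
            raise SimulationError("superfamily_mix must sum to 1")
        if self.indel_rate != 0:
            raise SimulationError("indels inside LTRs are not supported (set indel_rate=0)")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Sequence-level primitives
# ---------------------------------------------------------------------------

def random_sequence(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    """Random base-index array (A=0, C=1, G=2, T=3) at the given GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.int8)


def _k80_substitution_probs(d: float, kappa: float) -> Tuple[float, float]:
    """Per-site transition / total-transversion probabilities after branch length d.

    Rates are normalised so one unit of branch length equals one expected
    substitution per site (alpha + 2*beta = 1 with alpha/beta = kappa).
    """
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = math.exp(-4.0 * beta * d)
    e2 = math.exp(-2.0 * (alpha + beta) * d)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.5 - 0.5 * e1
    return p_ts, p_tv


def evolve_sequence(seq: np.ndarray, d: float, kappa: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Evolve a base-index array along a branch of length *d* under Kimura's
    two-parameter substitution model.

    Transitions are A<->G / C<->T (index XOR 2); each of the two transversion
    targets (XOR 1, XOR 3) is hit with half the total transversion
    probability.
    """
    if d < 0:
        raise ValueError("branch length must be >= 0")
    out = seq.copy()
    if d == 0:
        return out
    p_ts, p_tv = _k80_substitution_probs(d, kappa)
    u = rng.random(seq.size)
    out[u < p_ts] ^= 2
    out[(u >= p_ts) & (u < p_ts + p_tv / 2)] ^= 1
    out[(u >= p_ts + p_tv / 2) & (u < p_ts + p_tv)] ^= 3
    return out


def indices_to_str(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def str_to_indices(s: str) -> np.ndarray:
    arr = np.frombuffer(s.encode(), dtype="S1")
    out = np.full(arr.size, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        out[arr == b] = i
    return out


def revcomp(s: str) -> str:
    return "".join(_COMP.get(c, "N") for c in reversed(s))


# ---------------------------------------------------------------------------
# Feature construction
# ---------------------------------------------------------------------------

_SUPERFAMILY_ORDERS = {
    "Copia": COPIA_ORDER,
    "Gypsy": GYPSY_ORDER,
    # Coding but missing both order-defining domains (INT, RT): classifies as
    # Unclassified, mirroring elements lacking one or more domains.
    "Unclassified": ("GAG", "PR", "RH"),
}


def _build_internal(length: int, superfamily: str, strand: str, gc: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Internal region: domain CDS cassette in frame 0 with random spacers.

    Spacer lengths are multiples of 3 so every domain stays in frame 0 of the
    cassette; for '-' strand elements the whole cassette is reverse
    complemented, putting the domains on reverse-strand frames.
    """
    order = _SUPERFAMILY_ORDERS[superfamily]
    cds = [str_to_indices(encode_peptide(DOMAIN_PEPTIDES[n])) for n in order]
    total_cds = sum(len(c) for c in cds)
    n_spacers = len(cds) + 1
    background = length - total_cds
    if background < 3 * n_spacers:
        raise SimulationError(
            f"internal length {length} too short for the {superfamily} domain cassette"
        )
    units = background // 3
    tail = background - units * 3
    weights = rng.random(n_spacers)
    alloc = np.floor(weights / weights.sum() * (units - n_spacers)).astype(int) + 1
    alloc[-1] += units - alloc.sum()
    parts: List[np.ndarray] = []
    for i, c in enumerate(cds):
        parts.append(random_sequence(3 * alloc[i], gc, rng))
        parts.append(c)
    parts.append(random_sequence(3 * alloc[-1] + tail, gc, rng))
    internal = np.concatenate(parts)
    assert internal.size == length
    if strand == "-":
        internal = (internal[::-1] ^ 3).astype(np.int8)  # index XOR 3 complements
    return internal


@dataclass
class _Feature:
    kind: str  # 'element', 'solo', 'truncated', 'gene'
    seq: np.ndarray
    meta: dict


def _make_element_feature(idx: int, cfg: SimConfig, superfamily: str,
                          paired_gene: bool, rng: np.random.Generator) -> _Feature:
    ltr_len = int(rng.integers(cfg.ltr_length_range[0], cfg.ltr_length_range[1] + 1))
    internal_len = int(rng.integers(cfg.internal_length_range[0],
                                    cfg.internal_length_range[1] + 1))
    tsd_len = int(rng.integers(cfg.tsd_length_range[0], cfg.tsd_length_range[1] + 1))
    age = float(rng.uniform(*cfg.age_range_mya))
    strand = "+" if rng.random() < 0.5 else "-"
    d = cfg.mutation_rate * age * 1e6  # per-branch expected substitutions/site

    ancestral = random_sequence(ltr_len, cfg.gc_content, rng)
    ltr5 = evolve_sequence(ancestral, d, cfg.transition_bias, rng)
    ltr3 = evolve_sequence(ancestral, d, cfg.transition_bias, rng)
    internal = evolve_sequence(
        _build_internal(internal_len, superfamily, strand, cfg.gc_content, rng),
        d, cfg.transition_bias, rng,
    )
    tsd = random_sequence(tsd_len, cfg.gc_content, rng)
    parts = [tsd, ltr5, internal, ltr3, tsd]

    meta = {
        "element_id": f"TE{idx:04d}",
        "superfamily": superfamily,
        "strand": strand,
        "true_age_mya": age,
        "k_target": 2.0 * d,
        "tsd": indices_to_str(tsd),
        "tsd_len": tsd_len,
        "ltr_len": ltr_len,
        "internal_len": internal_len,
        "gene": None,
    }
    if paired_gene:
        gap = int(rng.integers(*UPSTREAM_GAP_RANGE))
        gene_len = int(rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1))
        gene_strand = "+" if rng.random() < 0.5 else "-"
        gene_seq = random_sequence(gene_len, cfg.gc_content, rng)
        gap_seq = random_sequence(gap, cfg.gc_content, rng)
        if gene_strand == "+":
            # element ... gap ... gene: upstream distance = tsd_len + gap
            parts = parts + [gap_seq, gene_seq]
            meta["gene"] = {"strand": "+", "gap": gap, "gene_len": gene_len,
                            "layout": "element_first"}
        else:
            parts = [gene_seq, gap_seq] + parts
            meta["gene"] = {"strand": "-", "gap": gap, "gene_len": gene_len,
                            "layout": "gene_first"}
    return _Feature("element", np.concatenate(parts), meta)


def _make_solo_ltr(idx: int, cfg: SimConfig, rng: np.random.Generator) -> _Feature:
    ltr_len = int(rng.integers(cfg.ltr_length_range[0], cfg.ltr_length_range[1] + 1))
    tsd_len = int(rng.integers(cfg.tsd_length_range[0], cfg.tsd_length_range[1] + 1))
    tsd = random_sequence(tsd_len, cfg.gc_content, rng)
    seq = np.concatenate([tsd, random_sequence(ltr_len, cfg.gc_content, rng), tsd])
    return _Feature("solo", seq, {"decoy_id": f"SOLO{idx:03d}"})


def _make_truncated(idx: int, cfg: SimConfig, rng: np.random.Generator) -> _Feature:
    ltr_len = int(rng.integers(cfg.ltr_length_range[0], cfg.ltr_length_range[1] + 1))
    frag = int(rng.integers(500, max(501, cfg.internal_length_range[0])))
    seq = np.concatenate([random_sequence(ltr_len, cfg.gc_content, rng),
                          random_sequence(frag, cfg.gc_content, rng)])
    return _Feature("truncated", seq, {"decoy_id": f"TRUNC{idx:03d}"})


def _make_gene_feature(idx: int, cfg: SimConfig, rng: np.random.Generator) -> _Feature:
    gene_len = int(rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    return _Feature("gene", random_sequence(gene_len, cfg.gc_content, rng),
                    {"strand": strand})


# ---------------------------------------------------------------------------
# Reference assembly
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = [
    "element_id", "chrom", "start", "end", "ltr5_start", "ltr5_end",
    "ltr3_start", "ltr3_end", "tsd", "superfamily", "strand",
    "true_age_mya", "k_target", "gene_id", "upstream_distance",
]


def simulate_reference(config: SimConfig):
    """Build the reference genome, its ground-truth table and planted genes.

    Returns ``(genome, truth, genes)`` where *genome* maps chromosome name to
    sequence string, *truth* is a DataFrame (one row per planted element,
    0-based half-open coordinates, element interval excluding the TSDs) and
    *genes* is a list of :class:`~retroburst.genes.GeneRecord`.
    """
    rng = np.random.default_rng([config.seed, 0x5e1f])

    n_paired = min(int(round(config.upstream_fraction * config.n_elements)),
                   config.n_genes)
    superfams = list(config.superfamily_mix)
    probs = np.array([config.superfamily_mix[s] for s in superfams], dtype=float)
    fam_draw = rng.choice(len(superfams), size=config.n_elements, p=probs)
    paired_idx = set(rng.choice(config.n_elements, size=n_paired, replace=False).tolist()) \
        if n_paired and config.n_elements else set()

    features: List[_Feature] = []
    for i in range(config.n_elements):
        features.append(_make_element_feature(
            i, config, superfams[fam_draw[i]], i in paired_idx, rng))
    for i in range(config.n_solo_ltrs):
        features.append(_make_solo_ltr(i, config, rng))
    for i in range(config.n_truncated):
        features.append(_make_truncated(i, config, rng))
    for i in range(config.n_genes - n_paired):
        features.append(_make_gene_feature(i, config, rng))

    order = rng.permutation(len(features))
    per_chrom: List[List[_Feature]] = [[] for _ in range(config.n_chromosomes)]
    for rank, fi in enumerate(order):
        per_chrom[rank % config.n_chromosomes].append(features[fi])

    genome: Dict[str, str] = {}
    truth_rows: List[dict] = []
    gene_records: List[GeneRecord] = []
    gene_counter = [0]

    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        feats = per_chrom[ci]
        total = sum(f.seq.size for f in feats)
        n_slots = len(feats) + 1
        background = config.chrom_length - total
        if background < n_slots * MIN_SPACER:
            raise SimulationError(
                f"{chrom}: planted features ({total} bp + {n_slots} spacers of "
                f">= {MIN_SPACER} bp) exceed chromosome length {config.chrom_length}"
            )
        extra = background - n_slots * MIN_SPACER
        alloc = rng.multinomial(extra, np.full(n_slots, 1.0 / n_slots))
        parts: List[np.ndarray] = []
        pos = 0
        for si, feat in enumerate(feats):
            spacer = MIN_SPACER + int(alloc[si])
            parts.append(random_sequence(spacer, config.gc_content, rng))
            pos += spacer
            _record_feature(feat, chrom, pos, truth_rows, gene_records, gene_counter)
            parts.append(feat.seq)
            pos += feat.seq.size
        parts.append(random_sequence(MIN_SPACER + int(alloc[-1]), config.gc_content, rng))
        genome[chrom] = indices_to_str(np.concatenate(parts))
        assert len(genome[chrom]) == config.chrom_length

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    truth = truth.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return genome, truth, gene_records


def _record_feature(feat: _Feature, chrom: str, pos: int, truth_rows: List[dict],
                    gene_records: List[GeneRecord], gene_counter: List[int]) -> None:
    def new_gene(start: int, end: int, strand: str) -> GeneRecord:
        rec = GeneRecord(f"GENE{gene_counter[0]:04d}", chrom, start, end, strand)
        gene_counter[0] += 1
        gene_records.append(rec)
        return rec

    if feat.kind == "gene":
        new_gene(pos, pos + feat.seq.size, feat.meta["strand"])
        return
    if feat.kind != "element":
        return
    m = feat.meta
    tsd_len, ltr_len, internal_len = m["tsd_len"], m["ltr_len"], m["internal_len"]
    g = m["gene"]
    if g is not None and g["layout"] == "gene_first":
        offset = pos + g["gene_len"] + g["gap"]
    else:
        offset = pos
    start = offset + tsd_len
    end = start + 2 * ltr_len + internal_len
    gene_id = None
    upstream = None
    if g is not None:
        upstream = g["gap"] + tsd_len
        if g["layout"] == "element_first":
            g_start = end + tsd_len + g["gap"]
            rec = new_gene(g_start, g_start + g["gene_len"], "+")
        else:
            rec = new_gene(pos, pos + g["gene_len"], "-")
        gene_id = rec.gene_id
    truth_rows.append({
        "element_id": m["element_id"], "chrom": chrom, "start": start, "end": end,
        "ltr5_start": start, "ltr5_end": start + ltr_len,
        "ltr3_start": end - ltr_len, "ltr3_end": end,
        "tsd": m["tsd"], "superfamily": m["superfamily"], "strand": m["strand"],
        "true_age_mya": m["true_age_mya"], "k_target": m["k_target"],
        "gene_id": gene_id, "upstream_distance": upstream,
    })


# ---------------------------------------------------------------------------
# Variety derivation
# ---------------------------------------------------------------------------

def derive_varieties(genome: Dict[str, str], truth: pd.DataFrame, config: SimConfig):
    """Excise a random subset of elements from each variety genome.

    Each element is removed independently with probability
    ``excision_probability``; an excision deletes the element plus one TSD
    copy, reconstructing the pre-insertion allele.  Returns
    ``(varieties, truth)`` where *varieties* maps variety name to a genome
    dict and *truth* gains one boolean ``present_<variety>`` column per
    variety.
    """
    rng = np.random.default_rng([config.seed, 0xa7])
    truth = truth.copy()
    names = [f"var{v + 1}" for v in range(config.n_varieties)]
    present = rng.random((len(truth), config.n_varieties)) >= config.excision_probability
    varieties: Dict[str, Dict[str, str]] = {}
    for vi, name in enumerate(names):
        truth[f"present_{name}"] = present[:, vi]
        var_genome: Dict[str, str] = {}
        for chrom, seq in genome.items():
            rows = truth[(truth.chrom == chrom) & ~present[:, vi][truth.index]]
            spans = sorted(
                (int(r.start), int(r.end) + len(r.tsd)) for r in rows.itertuples()
            )
            pieces, cursor = [], 0
            for s, e in spans:
                pieces.append(seq[cursor:s])
                cursor = e
            pieces.append(seq[cursor:])
            var_genome[chrom] = "".join(pieces)
        varieties[name] = var_genome
    return varieties, truth
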