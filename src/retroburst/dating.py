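"""Insertion-age estimation from LTR-LTR divergence.

At integration the two terminal repeats of an LTR-retrotransposon are
identical; they subsequently diverge neutrally, so their substitution-
corrected distance clocks the insertion.  The Kimura two-parameter distance

    K = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

(P, Q the transition and transversion proportions over aligned columns) is
converted to an age T = K / (2*mu) under a per-year substitution rate mu
(default 7e-9, the Arabidopsis calibration), reported in millions of years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, NamedTuple, Optional, Sequence

from .classify import ClassifiedElement
from .detect import ltr_pair_identity

_PURINES = {"A", "G"}
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_ACGT = set("ACGT")


@dataclass
class DatingConfig:
    mutation_rate: float = 7e-9  # substitutions / site / year
    young_threshold_mya: float = 2.0

    def __post_init__(self):
        if self.mutation_rate <= 0:
            raise ValueError("mutation_rate must be > 0")
        if self.young_threshold_mya <= 0:
            raise ValueError("young_threshold_mya must be > 0")


class Kimura2P(NamedTuple):
    columns: int  # usable columns (both bases in ACGT)
    P: float
    Q: float
    K: Optional[float]
    saturated: bool


@dataclass
class AgedElement:
    element: ClassifiedElement
    aligned_columns: int
    P: float
    Q: float
    K: Optional[float]
    age_mya: Optional[float]
    saturated: bool
    ltr_identity: float

    @property
    def element_id(self) -> str:
        return self.element.element_id

    @property
    def chrom(self) -> str:
        return self.element.chrom

    @property
    def start(self) -> int:
        return self.element.start

    @property
    def end(self) -> int:
        return self.element.end

    @property
    def superfamily(self) -> str:
        return self.element.superfamily


def kimura2p(aligned_a: str, aligned_b: str) -> Kimura2P:
    """Kimura two-parameter distance over an aligned LTR pair.

    Columns with a gap or an ambiguity code in either row are excluded from
    the P and Q denominators.  Saturation (the logarithm's argument
    non-positive) yields ``K=None, saturated=True``; an alignment with zero
    usable columns is an error, distinct from saturation.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    n = ts = tv = 0
    for a, b in zip(aligned_a.upper(), aligned_b.upper()):
        if a not in _ACGT or b not in _ACGT:
            continue
        n += 1
        if a == b:
            continue
        if (a, b) in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no usable (gap-free, unambiguous) aligned columns")
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return Kimura2P(n, P, Q, None, True)
    return Kimura2P(n, P, Q, -0.5 * math.log(w1 * math.sqrt(w2)), False)


def estimate_age(K: float, config: DatingConfig | None = None) -> float:
    """Insertion age in Mya: T = K / (2*mu), mu per year."""
    cfg = config or DatingConfig()
    if K < 0:
        raise ValueError("K must be >= 0")
    return K / (2.0 * cfg.mutation_rate) / 1e6


def date_element(element: ClassifiedElement, genome: Dict[str, str],
                 config: DatingConfig) -> AgedElement:
    cand = element.candidate
    seq = genome[cand.chrom]
    ltr5 = seq[cand.ltr5_start:cand.ltr5_end]
    ltr3 = seq[cand.ltr3_start:cand.ltr3_end]
    identity, alignment = ltr_pair_identity(ltr5, ltr3)
    k2p = kimura2p(str(alignment[0]), str(alignment[1]))
    age = None if k2p.saturated else estimate_age(k2p.K, config)
    return AgedElement(element, k2p.columns, k2p.P, k2p.Q, k2p.K, age,
                       k2p.saturated, identity)


def date_all(elements: Sequence[ClassifiedElement], genome: Dict[str, str],
             config: DatingConfig | None = None) -> List[AgedElement]:
    """Date every element; per-element saturation is flagged, never fatal."""
    cfg = config or DatingConfig()
    return [date_element(el, genome, cfg) for el in elements]
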