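"""Gene-proximity annotation of LTR-retrotransposons.

Flags elements sitting in the close upstream region of a gene (default
window: 1,000 bp ahead of the strand-aware gene start), where an insertion
can plausibly rewire the promoter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import gffutils
import pandas as pd

Interval = Tuple[str, int, int]  # (chrom, start, end), 0-based half-open


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str  # '+' or '-'

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty gene interval for {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")


def read_genes_gff3(path: str) -> list[GeneRecord]:
    """Load gene features from a GFF3 file (coordinates converted to 0-based half-open)."""
    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes.append(GeneRecord(gid, feat.seqid, feat.start - 1, feat.end, feat.strand))
    return genes


def write_genes_gff3(genes: Iterable[GeneRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tretroburst\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def upstream_distance(element: Interval, gene: GeneRecord) -> Optional[int]:
    """Distance (bp) from an element to the strand-aware start of *gene*.

    Defined only when the element lies entirely upstream of the gene: 5' of
    the start for a '+' gene, 3' of the end for a '-' gene.  Returns 0 when
    the element abuts the gene start, None when the element overlaps the
    gene, lies downstream, or sits on a different chromosome.
    """
    chrom, start, end = element
    if chrom != gene.chrom:
        return None
    if gene.strand == "+":
        if end <= gene.start:
            return gene.start - end
        return None
    if start >= gene.end:
        return start - gene.end
    return None


def annotate_context(
    elements: Sequence,
    genes: Sequence[GeneRecord],
    window: int = 1000,
) -> pd.DataFrame:
    """Nearest upstream gene per element, with a near-gene flag.

    *elements* is any sequence of objects exposing ``element_id``, ``chrom``,
    ``start`` and ``end``.  For each element the qualifying gene with the
    smallest upstream distance is kept (ties broken by gene_id, lexicographic);
    the element is flagged when that distance is strictly below *window*.
    """
    rows = []
    for el in elements:
        best: Optional[Tuple[int, str]] = None
        for g in genes:
            d = upstream_distance((el.chrom, el.start, el.end), g)
            if d is None:
                continue
            key = (d, g.gene_id)
            if best is None or key < best:
                best = key
        if best is None:
            rows.append((el.element_id, None, pd.NA, False))
        else:
            rows.append((el.element_id, best[1], best[0], best[0] < window))
    return pd.DataFrame(
        rows, columns=["element_id", "nearest_gene", "upstream_distance", "near_gene"]
    ).astype({"upstream_distance": "Int64"})
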