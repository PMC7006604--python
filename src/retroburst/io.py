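"""File-format glue: FASTA, GFF3 and TSV readers/writers for pipeline stages."""

from __future__ import annotations

import json
from typing import Dict, List, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dating import AgedElement
from .detect import LTRCandidate


def read_fasta(path: str) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(genome: Dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, path, "fasta")


def write_truth(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_config_json(config, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def candidates_to_gff3(candidates: Sequence[LTRCandidate], path: str,
                       extra_attrs: Dict[str, Dict[str, str]] | None = None) -> None:
    """Write candidates as GFF3 (1-based inclusive): an LTR_retrotransposon
    feature with two long_terminal_repeat children."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in candidates:
            attrs = {"ID": c.element_id, "ltr_identity": f"{c.ltr_identity:.2f}"}
            if c.tsd:
                attrs["tsd"] = c.tsd
            if extra_attrs and c.element_id in extra_attrs:
                attrs.update(extra_attrs[c.element_id])
            attr_str = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(f"{c.chrom}\tretroburst\tLTR_retrotransposon\t{c.start + 1}\t"
                     f"{c.end}\t{c.score:.1f}\t.\t.\t{attr_str}\n")
            for name, (s, e) in (("five_prime", (c.ltr5_start, c.ltr5_end)),
                                 ("three_prime", (c.ltr3_start, c.ltr3_end))):
                fh.write(f"{c.chrom}\tretroburst\tlong_terminal_repeat\t{s + 1}\t{e}\t"
                         f".\t.\t.\tID={c.element_id}_{name};Parent={c.element_id}\n")


def candidates_to_tsv(candidates: Sequence[LTRCandidate], path: str) -> None:
    df = pd.DataFrame([{
        "element_id": c.element_id, "chrom": c.chrom, "start": c.start, "end": c.end,
        "ltr5_start": c.ltr5_start, "ltr5_end": c.ltr5_end,
        "ltr3_start": c.ltr3_start, "ltr3_end": c.ltr3_end,
        "ltr_identity": round(c.ltr_identity, 3),
        "tsd": c.tsd if c.tsd else ".", "score": round(c.score, 2),
    } for c in candidates])
    df.to_csv(path, sep="\t", index=False)


def read_candidates_tsv(path: str) -> List[LTRCandidate]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples(index=False):
        tsd = None if pd.isna(r.tsd) or r.tsd == "." else str(r.tsd)
        out.append(LTRCandidate(str(r.element_id), str(r.chrom), int(r.start),
                                int(r.end), int(r.ltr5_start), int(r.ltr5_end),
                                int(r.ltr3_start), int(r.ltr3_end),
                                float(r.ltr_identity), tsd, float(r.score)))
    return out


def aged_to_tsv(aged: Sequence[AgedElement], path: str) -> None:
    aged_to_df(aged).to_csv(path, sep="\t", index=False)


def aged_to_df(aged: Sequence[AgedElement]) -> pd.DataFrame:
    return pd.DataFrame([{
        "element_id": a.element_id, "chrom": a.chrom, "start": a.start, "end": a.end,
        "superfamily": a.superfamily, "strand": a.element.strand or ".",
        "aligned_columns": a.aligned_columns,
        "P": round(a.P, 6), "Q": round(a.Q, 6),
        "K": round(a.K, 6) if a.K is not None else float("nan"),
        "age_mya": round(a.age_mya, 3) if a.age_mya is not None else float("nan"),
        "saturated": a.saturated,
        "ltr_identity": round(a.ltr_identity, 3),
    } for a in aged])
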