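"""Small IO helpers shared across modules (FASTA, GFF3, TSV tables)."""

from __future__ import annotations

import os
from typing import Dict, Iterable, Mapping, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end",
    "score", "strand", "phase", "attributes",
]


def write_fasta(path: str | os.PathLike, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_gff3(path: str | os.PathLike) -> pd.DataFrame:
    """Parse a GFF3 file into a DataFrame (coordinates kept 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=GFF3_COLUMNS)
    return df


def gff3_attributes(attr: str) -> Dict[str, str]:
    out = {}
    for field in attr.strip().split(";"):
        if not field:
            continue
        key, _, value = field.partition("=")
        out[key.strip()] = value.strip()
    return out


def write_gff3(path: str | os.PathLike, rows: Iterable[Tuple]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_tsv(path: str | os.PathLike, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_tsv(path: str | os.PathLike, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
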