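"""Sequence encoding and file-format helpers shared across the package.

FASTA I/O goes through Biopython; BED and TSV tables through pandas.
Sequences are handled internally as uppercase DNA strings or int8 arrays
with the encoding A=0, C=1, G=2, T=3, anything else (gap, N) = 4.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA = "ACGT"
GAP_CODE = 4

_ENC = np.full(256, GAP_CODE, dtype=np.int8)
for _i, _c in enumerate(DNA):
    _ENC[ord(_c)] = _i
    _ENC[ord(_c.lower())] = _i

_DEC = np.frombuffer(b"ACGT-", dtype="S1")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to int8 codes (A=0 C=1 G=2 T=3, other=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DEC[np.asarray(codes, dtype=np.int8)].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(seq: str) -> str:
    """Translate a nucleotide string (frame 0); trailing partial codon dropped."""
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: dict[str, str] | Iterable[tuple[str, str]]) -> None:
    items = records.items() if isinstance(records, dict) else records
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED6_COLUMNS[: df.shape[1]]
    return df


def write_bed(path: str | Path, df: pd.DataFrame) -> None:
    cols = [c for c in BED6_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def as_str_list(seqs: Sequence[str]) -> list[str]:
    out = []
    for s in seqs:
        if not isinstance(s, str):
            s = str(s)
        out.append(s.upper())
    return out
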