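"""Readers and writers for the plain-text formats the pipeline exchanges.

BED/bedGraph tables are plain TSV handled with pandas; FASTQ goes through
Bio.SeqIO; sparse matrices use the MatrixMarket format via scipy.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import io as spio
from scipy import sparse

BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def write_bed(df: pd.DataFrame, path, cols=None) -> None:
    cols = cols or [c for c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=BED6_COLS)


def read_bed(path, columns) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=columns)


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "value"])


def write_fastq(reads, path) -> None:
    """Write ``[(read_id, sequence), ...]`` with uniform quality."""
    records = [SeqRecord(Seq(seq), id=rid, description="",
                         letter_annotations={
                             "phred_quality": [40] * len(seq)})
               for rid, seq in reads]
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path):
    """Yield ``(read_id, sequence)`` pairs from a FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq)


def write_mtx(matrix, row_names, col_names, prefix: Path,
              row_file="barcodes.tsv", col_file="features.tsv",
              mtx_file="matrix.mtx") -> None:
    prefix = Path(prefix)
    prefix.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(prefix / mtx_file), sparse.csr_matrix(matrix))
    pd.Series(row_names).to_csv(prefix / row_file, index=False, header=False)
    pd.Series(col_names).to_csv(prefix / col_file, index=False, header=False)


def read_mtx(prefix: Path, row_file="barcodes.tsv", col_file="features.tsv",
             mtx_file="matrix.mtx"):
    prefix = Path(prefix)
    X = sparse.csr_matrix(spio.mmread(str(prefix / mtx_file)))
    rows = pd.read_csv(prefix / row_file, header=None)[0].tolist()
    cols = pd.read_csv(prefix / col_file, header=None)[0].tolist()
    return X, rows, cols


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(obj, indent=2, default=_default))


def read_json(path):
    return json.loads(Path(path).read_text())
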