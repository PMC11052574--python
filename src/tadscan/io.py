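"""Readers and writers for the plain-text formats the pipeline consumes.

All genomic intervals are 0-based half-open internally. BED files are written
as-is (BED is already 0-based half-open); matrix files are TSV with features on
rows and a header row of sample IDs.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

BED_COLUMNS = ["chrom", "start", "end", "name"]


def write_bed(df: pd.DataFrame, path: str, extra_cols: list[str] | None = None) -> None:
    """Write intervals as BED (chrom, start, end, name[, extras]), no header."""
    cols = BED_COLUMNS + (extra_cols or [])
    out = df.loc[:, [c for c in cols if c in df.columns]]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str, extra_cols: list[str] | None = None) -> pd.DataFrame:
    names = BED_COLUMNS + (extra_cols or [])
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_matrix(values: np.ndarray, feature_ids, sample_ids, path: str) -> None:
    """Feature x sample TSV with a header row of sample IDs."""
    pd.DataFrame(values, index=list(feature_ids), columns=list(sample_ids)).to_csv(
        path, sep="\t", index_label="feature_id"
    )


def read_matrix(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_config(config: Mapping, path: str) -> None:
    if "seed" not in config:
        raise ValueError("config must record the seed used for generation")
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)


def read_config(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_fasta(sequences: Mapping[str, str], path: str) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    seqio_write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    from Bio.SeqIO import parse

    return {rec.id: str(rec.seq).upper() for rec in parse(path, "fasta")}


def ensure_dir(path: str) -> None:
    os.makedirs(path, exist_ok=True)
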