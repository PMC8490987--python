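"""Readers and writers for the study's plain-text table formats."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError("count matrix contains negative entries")
    return df


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "compartment", "treatment"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns {sorted(missing)}")
    if df["sample"].duplicated().any():
        raise ValueError("duplicate sample ids in design table")
    return df


def read_intensities(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gene_list(path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines()
            if line.strip()}


def read_utr_fasta(path) -> dict[str, str]:
    """FASTA of 3'UTRs keyed by gene; record ids may be ``gene|transcript``."""
    seqs = {}
    for record in SeqIO.parse(str(path), "fasta"):
        gene = record.id.split("|")[0]
        seqs[gene] = str(record.seq)
    return seqs


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
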