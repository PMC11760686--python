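"""Plain-text I/O helpers shared across pipeline stages.

All on-disk formats are text: FASTA (Biopython), 4-line FASTQ, TSV
(pandas), and the whitespace-delimited HMMER domain table handled in
:mod:`markergeo.hits`.
"""
from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping.

    The id is the first whitespace-delimited token of the header.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def read_fasta_attrs(path: str | Path) -> tuple[dict[str, str], dict[str, dict[str, str]]]:
    """Read FASTA where headers carry ``key=value`` tokens after the id.

    Returns (seqs, attrs); attrs maps each id to its token dict.  This is
    the convention gene callers use to carry per-ORF metadata (source of
    the gene, ORF completeness) alongside the sequence itself.
    """
    seqs: dict[str, str] = {}
    attrs: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
        tokens = rec.description.split()[1:]
        attrs[rec.id] = dict(t.split("=", 1) for t in tokens if "=" in t)
    return seqs, attrs


def write_fasta(
    path: str | Path,
    seqs: Mapping[str, str],
    attrs: Mapping[str, Mapping[str, object]] | None = None,
    width: int = 80,
) -> None:
    records = []
    for sid, seq in seqs.items():
        desc = ""
        if attrs and sid in attrs:
            desc = " ".join(f"{k}={v}" for k, v in attrs[sid].items())
        records.append(SeqRecord(Seq(seq), id=sid, description=desc))
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(records)


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read a 4-line FASTQ file; returns (read_id, sequence) pairs.

    Base qualities are parsed (they must exist and match the sequence
    length) but not retained: downstream statistics are quality-blind.
    """
    out = []
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            if len(qual) != len(seq):
                raise ValueError(f"quality/sequence length mismatch for {title}")
            out.append((title.split()[0], seq.upper()))
    return out


def read_roster(path: str | Path) -> pd.DataFrame:
    """Read the source roster TSV (source_id, source_type[, from_profiled_samples])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"source_id", "source_type"}
    if not required.issubset(df.columns):
        raise ValueError(f"roster {path} must carry columns {sorted(required)}")
    if "from_profiled_samples" in df.columns:
        df["from_profiled_samples"] = df["from_profiled_samples"].map(
            lambda v: str(v).strip().lower() in {"1", "true", "yes"}
        )
    else:
        df["from_profiled_samples"] = False
    return df


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """Read gene_id -> lineage TSV (two columns, header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if "gene_id" in cols and "lineage" in cols:
        pairs = zip(df["gene_id"], df["lineage"])
    else:  # headerless two-column file
        df = pd.read_csv(path, sep="\t", dtype=str, header=None)
        pairs = zip(df[0], df[1])
    return {g: l for g, l in pairs if isinstance(l, str) and l.strip()}


def md5_file(path: str | Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)
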