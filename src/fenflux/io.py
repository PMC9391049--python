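"""TSV / FASTA readers and writers for the pipeline's external interfaces."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chemistry import validate_measurements
from .community import PhylotypeTable


def read_measurements(
    path: str | Path, sep: str = "\t", decimal: str = "."
) -> pd.DataFrame:
    """Read a tidy measurement table (treatment, replicate, day, analyte,
    phase, value, censored) and validate its schema."""
    df = pd.read_csv(path, sep=sep, decimal=decimal)
    if "censored" not in df.columns:
        df["censored"] = False
    df["censored"] = df["censored"].astype(bool)
    return validate_measurements(df)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a TSV (UTF-8, POSIX newlines) atomically: tmp file then rename."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, sep="\t", index=index, lineterminator="\n")
    tmp.replace(path)


def read_phylotype_table(
    counts_path: str | Path,
    meta_path: str | Path,
    fasta_path: str | Path | None = None,
) -> PhylotypeTable:
    """Assemble a :class:`PhylotypeTable` from a features-in-rows counts TSV,
    a sample-metadata TSV (sample_id, marker, treatment, replicate), and an
    optional FASTA of representative sequences."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t").set_index("sample_id")
    feature_meta = None
    if fasta_path is not None:
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
        feature_meta = pd.DataFrame(
            {"sequence": pd.Series(seqs)}
        ).reindex(counts.index)
    return PhylotypeTable(counts=counts, sample_meta=meta, feature_meta=feature_meta)


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
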