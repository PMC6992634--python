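"""Readers and writers for the pipeline's plain-text interchange formats:
BLAST tabular (outfmt 6, plus taxon/panel columns), counts + design TSVs,
GMT gene-set collections, Ct tables, and FASTA."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression import CountMatrix

__all__ = [
    "read_hit_table",
    "write_hit_table",
    "read_count_matrix",
    "write_count_matrix",
    "read_gmt",
    "write_gmt",
    "read_ct_table",
    "write_ct_table",
    "read_fasta",
    "write_fasta",
]

# standard BLAST -outfmt 6 columns, then two extras carried by this pipeline
OUTFMT6_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]
EXTRA_COLUMNS = ["taxon_label", "is_panel"]


def write_hit_table(hits: pd.DataFrame, path: str | Path) -> None:
    """Write a hit table as outfmt-6 TSV with taxon-label and panel columns.

    Standard alignment columns absent from the frame are filled with zeros;
    ``taxon_label`` defaults to ``NA`` and ``is_panel`` to 0.
    """
    out = pd.DataFrame()
    for col in OUTFMT6_COLUMNS:
        out[col] = hits[col] if col in hits.columns else 0
    out["taxon_label"] = hits.get("taxon_label", pd.Series("NA", index=hits.index))
    out["is_panel"] = hits.get("is_panel", pd.Series(False, index=hits.index)).astype(int)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_hit_table(
    path: str | Path, deuterostome_labels: set[str] | None = None
) -> pd.DataFrame:
    """Read an outfmt-6 TSV (12 or 14 columns) into a hit-table DataFrame.

    ``deuterostome_labels`` maps taxon labels to the ``is_deuterostome``
    flag the contaminant filter needs; labels not in the set are treated as
    non-deuterostome.
    """
    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] == len(OUTFMT6_COLUMNS):
        df.columns = OUTFMT6_COLUMNS
        df["taxon_label"] = "NA"
        df["is_panel"] = False
    elif df.shape[1] == len(OUTFMT6_COLUMNS) + 2:
        df.columns = OUTFMT6_COLUMNS + EXTRA_COLUMNS
        df["is_panel"] = df["is_panel"].astype(bool)
    else:
        raise ValueError(f"expected 12 or 14 tab-separated columns, got {df.shape[1]}")
    if deuterostome_labels is not None:
        df["is_deuterostome"] = df["taxon_label"].isin(deuterostome_labels)
    return df


def write_count_matrix(cm: CountMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>.counts.tsv`` (gene × sample), ``<prefix>.design.tsv``
    and ``<prefix>.lengths.tsv``."""
    prefix = Path(prefix)
    cm.counts.to_csv(Path(f"{prefix}.counts.tsv"), sep="\t", index_label="gene")
    cm.design.to_csv(Path(f"{prefix}.design.tsv"), sep="\t", index_label="sample")
    cm.eff_length.rename("eff_length").to_csv(
        Path(f"{prefix}.lengths.tsv"), sep="\t", index_label="gene"
    )


def read_count_matrix(prefix: str | Path, read_length: int = 100) -> CountMatrix:
    prefix = Path(prefix)
    counts = pd.read_csv(Path(f"{prefix}.counts.tsv"), sep="\t", index_col="gene")
    design = pd.read_csv(Path(f"{prefix}.design.tsv"), sep="\t", index_col="sample")
    lengths = pd.read_csv(
        Path(f"{prefix}.lengths.tsv"), sep="\t", index_col="gene"
    )["eff_length"]
    return CountMatrix(counts, design, lengths, read_length=read_length)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: one set per line — name, description, then member genes."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = set(fields[2:])
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, "na", *sorted(set(members))]) for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "condition", "replicate", "ct"} - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return df


def write_ct_table(ct: pd.DataFrame, path: str | Path) -> None:
    ct.to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )
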