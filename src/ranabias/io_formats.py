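"""Readers and writers for the tabular and sequence formats the pipeline uses.

All tabular files are tab-separated, UTF-8, with '.' as the decimal mark.
Gene and sample identifiers are opaque strings. Readers validate and reject
malformed input rather than coercing it; ``write_*(read_*(f))`` is the
identity on canonical files.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ranabias.constants import SAMPLE_CLASSES, SEXES

BLAST_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
    "qlen",
    "slen",
)


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass(frozen=True)
class CountsMatrix:
    """Gene x sample matrix of non-negative integer read counts.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one integer column per sample.
    lengths
        Transcript length in bp per gene (same index as ``counts``).
    """

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        idx = self.counts.index
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        if not np.issubdtype(self.counts.to_numpy().dtype, np.integer):
            raise FormatError("counts must be integers")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("counts must be non-negative")
        if not self.lengths.index.equals(idx):
            raise FormatError("lengths index must match gene ids")
        if (self.lengths.to_numpy() < 3).any():
            raise FormatError("transcript lengths must be >= 3 bp")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass(frozen=True)
class HitRecord:
    """One row of extended BLAST tabular output (outfmt '6 std qlen slen')."""

    query_id: str
    subject_id: str
    pident: float
    aln_len: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    qlen: int
    slen: int


def read_counts(path: str | Path) -> CountsMatrix:
    """Read a counts TSV: gene id column, optional ``length`` column, samples.

    Raises
    ------
    FormatError
        On duplicate gene/sample ids or non-integer counts (naming the
        offending row and column).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a gene id column and at least one sample")
    gene_col = df.columns[0]
    if df[gene_col].duplicated().any():
        dup = df[gene_col][df[gene_col].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    df = df.set_index(gene_col)
    df.index.name = "gene"
    if "length" in df.columns:
        lengths = pd.to_numeric(df["length"], errors="coerce")
        if lengths.isna().any():
            bad = lengths.index[lengths.isna()][0]
            raise FormatError(f"{path}: non-numeric length for gene {bad!r}")
        lengths = lengths.astype(np.int64)
        df = df.drop(columns=["length"])
    else:
        lengths = pd.Series(1000, index=df.index, dtype=np.int64)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals.fillna(0)))
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(f"{path}: non-integer count at gene {row!r}, sample {col!r}")
    counts = df.astype(np.int64)
    lengths.name = "length"
    return CountsMatrix(counts=counts, lengths=lengths)


def write_counts(cm: CountsMatrix, path: str | Path) -> None:
    """Write a :class:`CountsMatrix` in canonical TSV form."""
    out = cm.counts.copy()
    out.insert(0, "length", cm.lengths)
    out.to_csv(path, sep="\t", index_label="gene")


def read_sample_table(path: str | Path, counts: CountsMatrix | None = None) -> pd.DataFrame:
    """Read sample metadata: columns sample_id, class, sex, replicate.

    When ``counts`` is given, the table is cross-checked against it: every
    sample in the counts matrix must appear exactly once.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ["sample_id", "class", "sex", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    bad_class = sorted(set(df["class"]) - set(SAMPLE_CLASSES))
    if bad_class:
        raise FormatError(
            f"{path}: unknown class {bad_class[0]!r}; allowed: {', '.join(SAMPLE_CLASSES)}"
        )
    bad_sex = sorted(set(df["sex"]) - set(SEXES))
    if bad_sex:
        raise FormatError(f"{path}: unknown sex {bad_sex[0]!r}; allowed: {', '.join(SEXES)}")
    df = df[required].reset_index(drop=True)
    if counts is not None:
        validate_samples(counts, df)
    return df


def validate_samples(counts: CountsMatrix, samples: pd.DataFrame) -> None:
    """Cross-check a sample table against a counts matrix."""
    table_ids = set(samples["sample_id"])
    matrix_ids = set(counts.sample_ids)
    orphans = sorted(matrix_ids - table_ids)
    if orphans:
        raise FormatError(f"sample {orphans[0]!r} in counts but absent from sample table")
    extra = sorted(table_ids - matrix_ids)
    if extra:
        raise FormatError(f"sample {extra[0]!r} in sample table but absent from counts")


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_blast_tab(path: str | Path) -> list[HitRecord]:
    """Read extended BLAST tabular output (12 standard columns + qlen, slen)."""
    records: list[HitRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 14:
                raise FormatError(
                    f"{path}:{lineno}: expected 14 columns, got {len(fields)}"
                )
            try:
                rec = HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pident=float(fields[2]),
                    aln_len=int(fields[3]),
                    mismatch=int(fields[4]),
                    gapopen=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    qlen=int(fields[12]),
                    slen=int(fields[13]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if rec.evalue < 0:
                raise FormatError(f"{path}:{lineno}: negative e-value")
            records.append(rec)
    return records


def write_blast_tab(records: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        r.query_id,
                        r.subject_id,
                        f"{r.pident:.2f}",
                        r.aln_len,
                        r.mismatch,
                        r.gapopen,
                        r.qstart,
                        r.qend,
                        r.sstart,
                        r.send,
                        f"{r.evalue:.3g}",
                        f"{r.bitscore:.1f}",
                        r.qlen,
                        r.slen,
                    )
                )
                + "\n"
            )


def read_codon_pairs(path: str | Path) -> list[tuple[str, str, str]]:
    """Read paired gap-free codon sequences from FASTA.

    Sequences are stored as consecutive record pairs ``<id>_A`` / ``<id>_B``.
    Returns ``(pair_id, seq_a, seq_b)`` tuples.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) % 2 != 0:
        raise FormatError(f"{path}: odd number of sequences; expected A/B pairs")
    pairs: list[tuple[str, str, str]] = []
    for a, b in zip(records[0::2], records[1::2]):
        if not (a.id.endswith("_A") and b.id.endswith("_B") and a.id[:-2] == b.id[:-2]):
            raise FormatError(f"{path}: mismatched pair {a.id!r} / {b.id!r}")
        pairs.append((a.id[:-2], str(a.seq).upper(), str(b.seq).upper()))
    return pairs


def write_codon_pairs(pairs: Sequence[tuple[str, str, str]], path: str | Path) -> None:
    records = []
    for pid, sa, sb in pairs:
        records.append(SeqRecord(Seq(sa), id=f"{pid}_A", description=""))
        records.append(SeqRecord(Seq(sb), id=f"{pid}_B", description=""))
    SeqIO.write(records, str(path), "fasta")


def write_result_tsv(
    df: pd.DataFrame,
    path: str | Path,
    *,
    config_hash: str | None = None,
    seed: int | None = None,
    index: bool = False,
) -> None:
    """Write a results table with a header comment recording provenance."""
    buf = io.StringIO()
    meta = []
    if config_hash is not None:
        meta.append(f"config={config_hash}")
    if seed is not None:
        meta.append(f"seed={seed}")
    if meta:
        buf.write("# " + " ".join(meta) + "\n")
    df.to_csv(buf, sep="\t", index=index)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")
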