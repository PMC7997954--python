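"""Readers and writers for the on-disk formats the pipeline consumes and emits.

Formats
-------
* Fragment files: BED3+ — tab-separated ``chrom  start  end``, 0-based
  half-open coordinates, one fragment per line. Extra columns are ignored.
* TSS annotation: 4-column TSV ``gene_id  chrom  tss  strand`` (no header),
  or BED6 via :func:`tss_table_from_bed6`.
* Expression: 2-column TSV ``gene_id  tpm`` (no header), TPM >= 0.
* Matrices: TSV with a header row of sample ids and a first column of
  feature ids; floats are written at full round-trip precision.
* Result records: JSON objects carrying an explicit ``schema_version``.

All coordinates are 0-based half-open (BED convention) throughout the
package.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

SCHEMA_VERSION = 1

_COMMENT_PREFIXES = ("#", "track", "browser")


@dataclasses.dataclass(frozen=True)
class Fragment:
    """One sequenced fragment as a genomic interval (0-based half-open)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"fragment end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclasses.dataclass
class FragmentSet:
    """All fragments of one sample, stored as parallel numpy arrays.

    ``total_count`` is the number of fragments and serves as the
    "million mapped reads" denominator in RPKM normalization.
    """

    sample_id: str
    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise ValidationError("chroms/starts/ends must have equal lengths")
        if np.any(self.ends <= self.starts):
            bad = int(np.argmax(self.ends <= self.starts))
            raise ValidationError(
                f"fragment end must exceed start at record {bad}: "
                f"{self.chroms[bad]}:{self.starts[bad]}-{self.ends[bad]}"
            )

    @property
    def total_count(self) -> int:
        return len(self.starts)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def midpoints(self) -> np.ndarray:
        # integer midpoint, floor of the interval centre
        return (self.starts + self.ends) // 2

    @property
    def fragments(self) -> Iterator[Fragment]:
        for c, s, e in zip(self.chroms, self.starts, self.ends):
            yield Fragment(str(c), int(s), int(e))

    def by_chrom(self) -> dict:
        """Map chrom name -> (starts, ends) arrays, in file order."""
        out: dict = {}
        for chrom in pd.unique(self.chroms):
            mask = self.chroms == chrom
            out[str(chrom)] = (self.starts[mask], self.ends[mask])
        return out

    @classmethod
    def from_fragments(cls, sample_id: str, fragments: Iterable[Fragment]) -> "FragmentSet":
        frags = list(fragments)
        return cls(
            sample_id=sample_id,
            chroms=np.array([f.chrom for f in frags], dtype=object),
            starts=np.array([f.start for f in frags], dtype=np.int64),
            ends=np.array([f.end for f in frags], dtype=np.int64),
        )


class TssRecord:
    """Lightweight record: (gene_id, chrom, tss, strand)."""

    __slots__ = ("gene_id", "chrom", "tss", "strand")

    def __init__(self, gene_id: str, chrom: str, tss: int, strand: str):
        if strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {strand!r}")
        self.gene_id = gene_id
        self.chrom = chrom
        self.tss = int(tss)
        self.strand = strand

    def __repr__(self) -> str:  # pragma: no cover
        return f"TssRecord({self.gene_id}, {self.chrom}:{self.tss}{self.strand})"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TssRecord)
            and (self.gene_id, self.chrom, self.tss, self.strand)
            == (other.gene_id, other.chrom, other.tss, other.strand)
        )


@dataclasses.dataclass
class TssTable:
    """Strand-aware TSS anchors, one row per gene, stable iteration order.

    The table keeps exactly one TSS per gene id; collapsing multiple
    isoform TSSs to one representative is the caller's responsibility.
    """

    df: pd.DataFrame  # index: gene_id; columns: chrom, tss, strand

    def __post_init__(self) -> None:
        required = {"chrom", "tss", "strand"}
        if not required.issubset(self.df.columns):
            raise ValidationError(f"TssTable frame must have columns {sorted(required)}")
        if self.df.index.has_duplicates:
            dup = self.df.index[self.df.index.duplicated()][0]
            raise ValidationError(f"duplicate gene_id in TSS table: {dup}")
        bad = ~self.df["strand"].isin(["+", "-"])
        if bad.any():
            raise ValidationError(
                f"invalid strand for gene {self.df.index[bad][0]}: "
                f"{self.df.loc[bad, 'strand'].iloc[0]!r}"
            )
        self.df = self.df.copy()
        self.df["tss"] = self.df["tss"].astype(np.int64)

    @property
    def gene_ids(self) -> list:
        return list(self.df.index)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def records(self) -> Iterator[TssRecord]:
        for gid, row in self.df.iterrows():
            yield TssRecord(str(gid), str(row["chrom"]), int(row["tss"]), str(row["strand"]))

    @classmethod
    def from_records(cls, records: Iterable[TssRecord]) -> "TssTable":
        recs = list(records)
        df = pd.DataFrame(
            {
                "chrom": [r.chrom for r in recs],
                "tss": [r.tss for r in recs],
                "strand": [r.strand for r in recs],
            },
            index=pd.Index([r.gene_id for r in recs], name="gene_id"),
        )
        return cls(df)


def _data_lines(path) -> Iterator[tuple]:
    with open(path, "rt") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.startswith(_COMMENT_PREFIXES):
                continue
            yield lineno, line


def read_fragments(path, sample_id: str) -> FragmentSet:
    """Read a BED3+ fragment file. Duplicate intervals are retained."""
    chroms, starts, ends = [], [], []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
        if end <= start:
            raise ParseError(f"{path}:{lineno}: end must exceed start ({start} >= {end})")
        chroms.append(parts[0])
        starts.append(start)
        ends.append(end)
    return FragmentSet(
        sample_id=sample_id,
        chroms=np.array(chroms, dtype=object),
        starts=np.array(starts, dtype=np.int64),
        ends=np.array(ends, dtype=np.int64),
    )


def write_fragments(fragments: FragmentSet, path) -> None:
    with open(path, "wt") as fh:
        for c, s, e in zip(fragments.chroms, fragments.starts, fragments.ends):
            fh.write(f"{c}\t{s}\t{e}\n")


def read_tss_table(path) -> TssTable:
    """Read the 4-column TSS TSV: gene_id, chrom, tss, strand."""
    records = []
    seen = set()
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 tab-separated fields")
        gene_id, chrom, tss_str, strand = parts[0], parts[1], parts[2], parts[3]
        try:
            tss = int(tss_str)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer TSS coordinate") from exc
        if strand not in ("+", "-"):
            raise ParseError(f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}")
        if gene_id in seen:
            raise ParseError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        records.append(TssRecord(gene_id, chrom, tss, strand))
    return TssTable.from_records(records)


def write_tss_table(table: TssTable, path) -> None:
    with open(path, "wt") as fh:
        for r in table.records:
            fh.write(f"{r.gene_id}\t{r.chrom}\t{r.tss}\t{r.strand}\n")


def tss_table_from_bed6(path) -> TssTable:
    """Convert a BED6 file to a TssTable.

    The BED name column supplies the gene id; the TSS is ``start`` for
    '+' entries and ``end - 1`` for '-' entries (the first transcribed
    base in 0-based coordinates).
    """
    records = []
    seen = set()
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 6:
            raise ParseError(f"{path}:{lineno}: BED6 requires 6 fields")
        chrom, start_s, end_s, name, _score, strand = parts[:6]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
        if strand not in ("+", "-"):
            raise ParseError(f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}")
        if name in seen:
            raise ParseError(f"{path}:{lineno}: duplicate gene_id {name!r}")
        seen.add(name)
        tss = start if strand == "+" else end - 1
        records.append(TssRecord(name, chrom, tss, strand))
    return TssTable.from_records(records)


def read_expression(path) -> pd.Series:
    """Read the 2-column expression TSV into a Series of TPM, indexed by gene id."""
    ids, tpms = [], []
    seen = set()
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 tab-separated fields")
        try:
            tpm = float(parts[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric TPM") from exc
        if tpm < 0:
            raise ValidationError(f"{path}:{lineno}: negative TPM {tpm}")
        if parts[0] in seen:
            raise ParseError(f"{path}:{lineno}: duplicate gene_id {parts[0]!r}")
        seen.add(parts[0])
        ids.append(parts[0])
        tpms.append(tpm)
    return pd.Series(tpms, index=pd.Index(ids, name="gene_id"), name="tpm", dtype=float)


def write_expression(expression: pd.Series, path) -> None:
    with open(path, "wt") as fh:
        for gid, tpm in expression.items():
            fh.write(f"{gid}\t{tpm!r}\n")


def write_matrix(path, matrix: pd.DataFrame, index_label: str = "feature_id") -> None:
    """Write a feature x sample matrix as TSV at full round-trip precision."""
    matrix.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path) -> pd.DataFrame:
    """Read a matrix TSV written by :func:`write_matrix`."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: inconsistent column counts: {exc}") from exc
    if df.isna().any().any():
        raise ParseError(f"{path}: ragged or missing values in matrix")
    df.index = df.index.astype(str)
    return df


def write_json_result(path, payload: dict) -> None:
    """Write a result record as JSON with an explicit schema version."""
    record = {"schema_version": SCHEMA_VERSION}
    record.update(payload)
    with open(path, "wt") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json_result(path) -> dict:
    with open(path, "rt") as fh:
        record = json.load(fh)
    if "schema_version" not in record:
        raise ParseError(f"{path}: missing schema_version field")
    return record
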