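"""Reading and writing the pipeline's file formats.

The wet-lab protocol delivers three FASTQ files per sample: Read 1, Read 2,
and an index read that carries the single molecule tag (SMT, a random 8- or
12-mer attached to each template before amplification).  Some demultiplexers
instead append the tag to the read name; both dialects are supported.  Target
designs (per-amplicon primers, insert, SNP annotations) travel as TSV, as do
all result tables.
"""

from __future__ import annotations

import dataclasses
import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._dna import is_acgt

SMT_LENGTHS = (8, 12)


@dataclass(frozen=True)
class SnpAnnotation:
    """A biallelic SNP at a 0-based offset within an amplicon insert."""

    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.ref_allele not in "ACGT" or len(self.ref_allele) != 1:
            raise ValueError(f"invalid ref allele {self.ref_allele!r}")
        if self.alt_allele not in "ACGT" or len(self.alt_allele) != 1:
            raise ValueError(f"invalid alt allele {self.alt_allele!r}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.position < 0:
            raise ValueError("SNP position must be >= 0")


@dataclass(frozen=True)
class TargetDesign:
    """One amplicon target: locus-specific primers flanking a ~150 bp insert.

    ``upstream_primer`` is the forward-strand primer at the 5' end of the
    amplicon (Read 2 starts with it); ``downstream_primer`` is the
    forward-strand sequence at the 3' end (Read 1 starts with its reverse
    complement).  SNP positions are 0-based offsets within ``insert_seq``.
    """

    target_id: str
    upstream_primer: str
    downstream_primer: str
    insert_seq: str
    snps: tuple[SnpAnnotation, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for name, seq in (
            ("upstream_primer", self.upstream_primer),
            ("downstream_primer", self.downstream_primer),
            ("insert_seq", self.insert_seq),
        ):
            if not is_acgt(seq):
                raise ValueError(
                    f"target {self.target_id}: {name} contains non-ACGT characters"
                )
        if len(self.upstream_primer) < 22 or len(self.downstream_primer) < 22:
            raise ValueError(f"target {self.target_id}: primers must be >= 22 bases")
        object.__setattr__(self, "snps", tuple(self.snps))
        for snp in self.snps:
            if not 0 <= snp.position < len(self.insert_seq):
                raise ValueError(
                    f"target {self.target_id}: SNP position {snp.position} outside "
                    f"insert of length {len(self.insert_seq)}"
                )


@dataclass
class TaggedReadPair:
    """A paired-end read with its single molecule tag."""

    read_id: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str
    smt: str
    sample_id: str = ""

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"read {self.read_id}: sequence/quality length mismatch")


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _base_name(title: str) -> str:
    """First whitespace token with any /1 /2 /3 mate suffix removed."""
    name = title.split(None, 1)[0]
    if len(name) > 2 and name[-2] == "/" and name[-1] in "123":
        name = name[:-2]
    return name


def _fastq_records(path: str | Path) -> Iterator[tuple[str, str, str]]:
    with _open_text(path) as handle:
        try:
            yield from FastqGeneralIterator(handle)
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ in {path}: {exc}") from exc


def read_fastq_triplet(
    r1_path: str | Path,
    r2_path: str | Path,
    index_path: str | Path,
    sample_id: str = "",
) -> Iterator[TaggedReadPair]:
    """Stream read pairs from an (R1, R2, index) FASTQ triplet.

    The index read's sequence is taken verbatim as the SMT.  Records must
    appear in the same order in all three files; a count or identifier
    mismatch is a hard error naming the first divergent record.  Gzipped
    input is accepted transparently by ``.gz`` suffix.
    """
    it1 = _fastq_records(r1_path)
    it2 = _fastq_records(r2_path)
    it3 = _fastq_records(index_path)
    n = 0
    while True:
        rec1 = next(it1, None)
        rec2 = next(it2, None)
        rec3 = next(it3, None)
        present = [rec is not None for rec in (rec1, rec2, rec3)]
        if not any(present):
            return
        if not all(present):
            which = [p for p, ok in zip(("R1", "R2", "index"), present) if not ok]
            raise ValueError(
                f"FASTQ record count mismatch at record {n + 1}: "
                f"{', '.join(which)} exhausted early"
            )
        name1, name2, name3 = (_base_name(r[0]) for r in (rec1, rec2, rec3))
        if not (name1 == name2 == name3):
            raise ValueError(
                f"read identifier mismatch at record {n + 1}: "
                f"{name1!r} / {name2!r} / {name3!r}"
            )
        n += 1
        yield TaggedReadPair(
            read_id=name1,
            seq1=rec1[1],
            qual1=rec1[2],
            seq2=rec2[1],
            qual2=rec2[2],
            smt=rec3[1],
            sample_id=sample_id,
        )


def read_fastq_with_header_smt(
    r1_path: str | Path,
    r2_path: str | Path,
    delimiter: str = ":",
    sample_id: str = "",
) -> Iterator[TaggedReadPair]:
    """Stream read pairs whose SMT is carried as a read-name suffix.

    The tag is parsed from after the last ``delimiter`` in the read name and
    stripped from the reported ``read_id``.
    """
    it1 = _fastq_records(r1_path)
    it2 = _fastq_records(r2_path)
    n = 0
    while True:
        rec1 = next(it1, None)
        rec2 = next(it2, None)
        if rec1 is None and rec2 is None:
            return
        if (rec1 is None) != (rec2 is None):
            raise ValueError(f"FASTQ record count mismatch at record {n + 1}")
        name1, name2 = _base_name(rec1[0]), _base_name(rec2[0])
        if name1 != name2:
            raise ValueError(
                f"read identifier mismatch at record {n + 1}: {name1!r} / {name2!r}"
            )
        if delimiter not in name1:
            raise ValueError(
                f"record {n + 1}: read name {name1!r} lacks SMT delimiter {delimiter!r}"
            )
        stem, smt = name1.rsplit(delimiter, 1)
        n += 1
        yield TaggedReadPair(
            read_id=stem,
            seq1=rec1[1],
            qual1=rec1[2],
            seq2=rec2[1],
            qual2=rec2[2],
            smt=smt,
            sample_id=sample_id,
        )


def write_fastq_triplet(
    pairs: Iterable[TaggedReadPair],
    r1_path: str | Path,
    r2_path: str | Path,
    index_path: str | Path,
    smt_quality_char: str = "?",
) -> int:
    """Write read pairs to an (R1, R2, index) FASTQ triplet; returns the count."""
    n = 0
    with _open_text(r1_path, "wt") as f1, _open_text(r2_path, "wt") as f2, _open_text(
        index_path, "wt"
    ) as f3:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.read_id}/2\n{p.seq2}\n+\n{p.qual2}\n")
            f3.write(f"@{p.read_id}/3\n{p.smt}\n+\n{smt_quality_char * len(p.smt)}\n")
            n += 1
    return n


def _split_list(cell: object) -> list[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return []
    return [tok for tok in str(cell).split(";") if tok != ""]


def load_design(tsv_path: str | Path) -> list[TargetDesign]:
    """Load a target design table.

    Expected TSV columns: ``target_id``, ``upstream_primer``,
    ``downstream_primer``, ``insert_seq`` and optionally ``snp_positions``,
    ``snp_ref``, ``snp_alt`` (semicolon-separated, equal lengths).
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    required = {"target_id", "upstream_primer", "downstream_primer", "insert_seq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    designs: list[TargetDesign] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        tid = row.target_id
        if tid in seen:
            raise ValueError(f"duplicate target_id {tid!r} in design table")
        seen.add(tid)
        positions = _split_list(getattr(row, "snp_positions", ""))
        refs = _split_list(getattr(row, "snp_ref", ""))
        alts = _split_list(getattr(row, "snp_alt", ""))
        if not len(positions) == len(refs) == len(alts):
            raise ValueError(f"target {tid}: inconsistent SNP annotation list lengths")
        snps = tuple(
            SnpAnnotation(position=int(p), ref_allele=r, alt_allele=a)
            for p, r, a in zip(positions, refs, alts)
        )
        designs.append(
            TargetDesign(
                target_id=tid,
                upstream_primer=row.upstream_primer,
                downstream_primer=row.downstream_primer,
                insert_seq=row.insert_seq,
                snps=snps,
            )
        )
    return designs


def write_design(designs: Iterable[TargetDesign], tsv_path: str | Path) -> None:
    rows = []
    for d in designs:
        rows.append(
            {
                "target_id": d.target_id,
                "upstream_primer": d.upstream_primer,
                "downstream_primer": d.downstream_primer,
                "insert_seq": d.insert_seq,
                "snp_positions": ";".join(str(s.position) for s in d.snps),
                "snp_ref": ";".join(s.ref_allele for s in d.snps),
                "snp_alt": ";".join(s.alt_allele for s in d.snps),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "target_id",
            "upstream_primer",
            "downstream_primer",
            "insert_seq",
            "snp_positions",
            "snp_ref",
            "snp_alt",
        ],
    ).to_csv(tsv_path, sep="\t", index=False)


def write_results_table(records: Iterable[object], path: str | Path) -> None:
    """Write homogeneous records (dataclasses, dicts, or a DataFrame) as TSV.

    Column order is the dataclass field order (or dict insertion order), so
    output is deterministic and round-trips through ``read_results_table``.
    An empty record list produces a header-only file when the record type is
    a DataFrame, otherwise an empty file with no header (the column set is
    unknowable).
    """
    if isinstance(records, pd.DataFrame):
        records.to_csv(path, sep="\t", index=False)
        return
    records = list(records)
    if records and dataclasses.is_dataclass(records[0]):
        cols = [f.name for f in dataclasses.fields(records[0])]
        df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=cols)
    else:
        df = pd.DataFrame(records)
    df.to_csv(path, sep="\t", index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
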