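"""Strict readers and writers for the formats the pipeline exchanges.

Every writer produces files the corresponding reader accepts (round-trip
property); every reader rejects malformed input with the offending record
named, rather than silently dropping it.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A format violation, carrying the file and record/line it occurred at."""


@dataclasses.dataclass(frozen=True)
class GeneLocus:
    """1-based inclusive gene coordinates; chromosome may be 'scaffold'."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start > self.end:
            raise FormatError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in {"+", "-"}:
            raise FormatError(f"{self.gene_id}: bad strand {self.strand!r}")

    @property
    def placed(self) -> bool:
        return self.chromosome.lower() != "scaffold"


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered id -> sequence map; duplicate ids rejected."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}:{lineno}: not a FASTA header where one was expected")
                break
    seqs: dict[str, str] = {}
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate id {rec.id!r} (record {i + 1})")
        if not rec.id:
            raise FormatError(f"{path}: empty id at record {i + 1}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    recs = [SeqRecord(Seq(s), id=k, description="") for k, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta-2line" if width == 0 else "fasta")


def read_locus_tsv(path) -> list[GeneLocus]:
    """5-column locus TSV: gene_id, chrom, start, end, strand (header required)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = ["gene_id", "chrom", "start", "end", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    loci = [
        GeneLocus(r.gene_id, r.chrom, int(r.start), int(r.end), r.strand)
        for r in df.itertuples()
    ]
    ids = [l.gene_id for l in loci]
    if len(set(ids)) != len(ids):
        dup = sorted({g for g in ids if ids.count(g) > 1})
        raise FormatError(f"{path}: duplicate gene ids {dup}")
    return loci


def write_locus_tsv(loci: Iterable[GeneLocus], path) -> None:
    df = pd.DataFrame(
        [(l.gene_id, l.chromosome, l.start, l.end, l.strand) for l in loci],
        columns=["gene_id", "chrom", "start", "end", "strand"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_gff3_genes(path, known_chromosomes: set[str] | None = None) -> list[GeneLocus]:
    """Parse gene features from GFF3. Features on chromosomes outside
    `known_chromosomes` (when given) are flagged as scaffold, not dropped."""
    loci = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(parts)}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            gene_id = None
            for field in attrs.split(";"):
                if field.startswith("ID="):
                    gene_id = field[3:]
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: gene feature without ID attribute")
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            if known_chromosomes is not None and chrom not in known_chromosomes:
                chrom = "scaffold"
            loci.append(GeneLocus(gene_id, chrom, int(start), int(end), strand))
    return loci


def write_gff3_genes(loci: Iterable[GeneLocus], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for l in loci:
            fh.write(
                f"{l.chromosome}\terfkit\tgene\t{l.start}\t{l.end}\t.\t{l.strand}\t.\tID={l.gene_id}\n"
            )


def read_manifest(path) -> dict[str, str]:
    """2-column tissue manifest TSV: read_id, tissue."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["read_id", "tissue"]:
        raise FormatError(f"{path}: expected columns read_id, tissue")
    if df.read_id.duplicated().any():
        dup = df.read_id[df.read_id.duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate read id {dup!r}")
    return dict(zip(df.read_id, df.tissue))


def write_manifest(manifest: dict[str, str], path) -> None:
    pd.DataFrame(sorted(manifest.items()), columns=["read_id", "tissue"]).to_csv(
        path, sep="\t", index=False
    )


def write_tsv(df: pd.DataFrame, path, float_format: str | None = None) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
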