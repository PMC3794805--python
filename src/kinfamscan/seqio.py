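"""Sequence and annotation I/O shared by every pipeline stage.

Conventions
-----------
* Coordinates are 1-based inclusive in files (GFF style) and 0-based
  half-open inside the library; the readers/writers here are the only
  place the shift happens.
* Protein alphabet: the 20 standard residues. Nucleotide alphabet:
  ACGT plus N (ambiguity; an N never matches anything in the exact-match
  operations downstream).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

logger = logging.getLogger("kinfamscan")

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
_KNOWN = PROTEIN_ALPHABET | NUCLEOTIDE_ALPHABET

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class SeqIOError(ValueError):
    """Raised on malformed sequence or annotation input."""


@dataclass(frozen=True)
class SeqEntry:
    """One FASTA/FASTQ record: identifier, free-text description, residues."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SeqIOError(f"invalid sequence id {self.id!r}")
        if not self.sequence:
            raise SeqIOError(f"empty sequence for id {self.id!r}")
        bad = set(self.sequence) - _KNOWN
        if bad:
            raise SeqIOError(
                f"sequence {self.id!r} contains characters outside both "
                f"alphabets: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneAnnotation:
    """A gene locus with its exon layout, forward-strand file coordinates.

    ``start``/``end`` and each exon interval are 1-based inclusive; exons are
    sorted, non-overlapping and contained in [start, end].
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise SeqIOError(f"{self.gene_id}: strand must be + or -")
        if not 1 <= self.start <= self.end:
            raise SeqIOError(f"{self.gene_id}: bad span {self.start}..{self.end}")
        if not self.exons:
            raise SeqIOError(f"{self.gene_id}: at least one exon required")
        prev_end = 0
        for s, e in self.exons:
            if s > e or s < self.start or e > self.end:
                raise SeqIOError(f"{self.gene_id}: exon {s}..{e} outside gene span")
            if s <= prev_end:
                raise SeqIOError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def intron_lengths(self) -> list[int]:
        return [
            self.exons[i + 1][0] - self.exons[i][1] - 1
            for i in range(len(self.exons) - 1)
        ]


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[SeqEntry]:
    """Parse a FASTA file into SeqEntry records, order preserved.

    Sequences are uppercased; internal whitespace is stripped. Errors on an
    empty file, duplicate ids, or characters outside both alphabets.
    """
    entries: list[SeqEntry] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if header is None:
            return
        fields = header.split(None, 1)
        rid = fields[0]
        desc = fields[1] if len(fields) > 1 else ""
        if rid in seen:
            raise SeqIOError(f"duplicate id {rid}")
        seen.add(rid)
        entries.append(SeqEntry(rid, desc, "".join(chunks).upper()))

    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].strip()
                chunks = []
            else:
                if header is None:
                    raise SeqIOError("sequence data before first FASTA header")
                chunks.append("".join(line.split()))
    _flush()
    if not entries:
        raise SeqIOError(f"no FASTA records in {path}")
    logger.info("read_fasta: %d records from %s", len(entries), path)
    return entries


def write_fasta(entries: Iterable[SeqEntry], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for e in entries:
            head = f">{e.id} {e.description}".rstrip()
            fh.write(head + "\n")
            for i in range(0, len(e.sequence), width):
                fh.write(e.sequence[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[SeqEntry]:
    """Parse 4-line-per-record FASTQ; quality strings are validated for
    length then discarded (the pipeline uses sequence only).

    An empty file yields an empty list. A truncated record or a
    sequence/quality length mismatch raises with the record index.
    """
    entries: list[SeqEntry] = []
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    while lines and lines[-1] == "":
        lines.pop()
    if len(lines) % 4 != 0:
        raise SeqIOError(
            f"truncated FASTQ record at index {len(lines) // 4} in {path}"
        )
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        idx = i // 4
        if not head.startswith("@") or not plus.startswith("+"):
            raise SeqIOError(f"malformed FASTQ record at index {idx} in {path}")
        if len(seq) != len(qual):
            raise SeqIOError(
                f"sequence/quality length mismatch at record {idx} in {path}"
            )
        fields = head[1:].split(None, 1)
        entries.append(
            SeqEntry(fields[0], fields[1] if len(fields) > 1 else "", seq.upper())
        )
    logger.info("read_fastq: %d reads from %s", len(entries), path)
    return entries


def write_fastq(entries: Iterable[SeqEntry], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for e in entries:
            fh.write(f"@{e.id}\n{e.sequence}\n+\n{'I' * len(e.sequence)}\n")


_GFF_HEADER = "##gff-version 3"


def write_annotations(annos: Sequence[GeneAnnotation], path: str | Path) -> None:
    """Write gene/exon annotations as a GFF3-like TSV (1-based inclusive)."""
    with _open_text(path, "wt") as fh:
        fh.write(_GFF_HEADER + "\n")
        for a in annos:
            fh.write(
                "\t".join(
                    [a.chromosome, "kinfamscan", "gene", str(a.start), str(a.end),
                     ".", a.strand, ".", f"ID={a.gene_id}"]
                )
                + "\n"
            )
            for k, (s, e) in enumerate(a.exons, 1):
                fh.write(
                    "\t".join(
                        [a.chromosome, "kinfamscan", "exon", str(s), str(e),
                         ".", a.strand, ".", f"ID={a.gene_id}.exon{k};Parent={a.gene_id}"]
                    )
                    + "\n"
                )
    logger.info("write_annotations: %d genes to %s", len(annos), path)


def read_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read the GFF3-like TSV written by :func:`write_annotations`."""
    genes: dict[str, GeneAnnotation] = {}
    order: list[str] = []
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, int, int, str]] = {}
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = line.split("\t")
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if kv)
            if ftype == "gene":
                gid = attr["ID"]
                order.append(gid)
                meta[gid] = (chrom, int(start), int(end), strand)
                exons.setdefault(gid, [])
            elif ftype == "exon":
                exons.setdefault(attr["Parent"], []).append((int(start), int(end)))
    for gid in order:
        chrom, start, end, strand = meta[gid]
        genes[gid] = GeneAnnotation(gid, chrom, start, end, strand, sorted(exons[gid]))
    return [genes[g] for g in order]


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON — YAML superset) config file into a dict."""
    with _open_text(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SeqIOError(f"config {path} did not parse to a mapping")
    return cfg


def write_tsv(rows: Sequence[dict], path: str | Path, columns: Sequence[str]) -> None:
    """Write a list of dict rows as a TSV with a fixed column order."""
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")
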