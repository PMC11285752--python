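"""Core genomic value types and flat-file I/O.

Every coordinate inside the package is 0-based half-open on the forward
strand of its chromosome.  The only place the 1-based inclusive GTF
convention appears is :func:`read_gtf` / :func:`write_gtf`; all other
readers and writers (FASTA, BED, TSV) pass coordinates through unchanged.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

NUCLEOTIDES = frozenset("ACGTN")
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWYUX*")

__all__ = [
    "FormatError",
    "Interval",
    "GeneModel",
    "SeqRecordSet",
    "ReadSet",
    "read_fasta",
    "write_fasta",
    "read_gtf",
    "write_gtf",
    "read_bed_reads",
    "write_bed_reads",
    "read_library_totals",
    "write_library_totals",
    "reverse_complement",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Interval:
    """A 0-based half-open genomic interval on one strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def shifted(self, offset: int, chrom: str | None = None) -> "Interval":
        return Interval(
            chrom if chrom is not None else self.chrom,
            self.start + offset,
            self.end + offset,
            self.strand,
        )


@dataclass
class GeneModel:
    """Exon structure of one transcript.

    ``exons`` are stored in transcription order: ascending genomic start for
    ``+`` strand genes, descending for ``-``.  ``cds_phase[i]`` is the
    within-codon offset at which exon ``i`` begins — the sum of upstream
    exon lengths mod 3 (0 for the first exon).
    """

    gene_id: str
    transcript_id: str
    exons: list[Interval]
    cds_phase: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"gene {self.gene_id}: exons span chrom/strand")
        ordered = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(ordered, ordered[1:]):
            if a.end > b.start:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        expected = ordered if self.strand == "+" else ordered[::-1]
        if self.exons != expected:
            raise ValueError(
                f"gene {self.gene_id}: exons not in transcription order"
            )
        if not self.cds_phase:
            phase, phases = 0, []
            for e in self.exons:
                phases.append(phase)
                phase = (phase + e.length) % 3
            self.cds_phase = phases
        if len(self.cds_phase) != len(self.exons):
            raise ValueError(f"gene {self.gene_id}: phase/exon count mismatch")
        if any(p not in (0, 1, 2) for p in self.cds_phase):
            raise ValueError(f"gene {self.gene_id}: phase outside {{0,1,2}}")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> Interval:
        start = min(e.start for e in self.exons)
        end = max(e.end for e in self.exons)
        return Interval(self.chrom, start, end, self.strand)

    @property
    def exon_union_length(self) -> int:
        return sum(e.length for e in self.exons)

    def introns(self) -> list[Interval]:
        """Introns in transcription order (genome forward coordinates)."""
        out = []
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            out.append(Interval(self.chrom, a.end, b.start, self.strand))
        if self.strand == "-":
            out.reverse()
        return out

    def spliced_sequence(self, genome: Mapping[str, str] | "SeqRecordSet") -> str:
        seqs = genome.entries if isinstance(genome, SeqRecordSet) else genome
        chrom_seq = seqs[self.chrom]
        parts = []
        for e in self.exons:
            piece = chrom_seq[e.start : e.end]
            parts.append(reverse_complement(piece) if self.strand == "-" else piece)
        return "".join(parts)

    def cds_to_genome(self, offset: int) -> int:
        """Genome coordinate of spliced-CDS position ``offset``."""
        if offset < 0:
            raise ValueError("negative CDS offset")
        rem = offset
        for e in self.exons:
            if rem < e.length:
                if self.strand == "+":
                    return e.start + rem
                return e.end - 1 - rem
            rem -= e.length
        raise ValueError(f"CDS offset {offset} beyond spliced length")

    def exon_index_at(self, pos: int) -> int | None:
        """1-based transcription-order exon index containing ``pos``."""
        for i, e in enumerate(self.exons, start=1):
            if e.start <= pos < e.end:
                return i
        return None


@dataclass
class SeqRecordSet:
    """Ordered named sequences (nucleotide or protein), uppercase."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        for name in self.entries:
            if not name:
                raise ValueError("sequence names must be non-empty")

    def __getitem__(self, name: str) -> str:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.entries.items()}


@dataclass
class ReadSet:
    """Mapped reads as genomic intervals plus the library's mapped total."""

    reads: list[Interval]
    library_total: int

    def __post_init__(self) -> None:
        if self.library_total < len(self.reads):
            raise ValueError(
                f"library_total {self.library_total} < number of reads "
                f"{len(self.reads)}"
            )


# ---------------------------------------------------------------------------
# FASTA


def _alphabet_for(mode: str) -> frozenset[str]:
    if mode == "nucleotide":
        return NUCLEOTIDES
    if mode == "protein":
        return AMINO_ACIDS
    if mode == "auto":
        return NUCLEOTIDES | AMINO_ACIDS
    raise ValueError(f"unknown alphabet {mode!r}")


def read_fasta(path: str | Path, alphabet: str = "auto") -> SeqRecordSet:
    """Read a FASTA file, uppercasing sequence and validating characters.

    ``alphabet`` is ``"nucleotide"``, ``"protein"`` or ``"auto"``; illegal
    characters raise :class:`FormatError` naming the offending line.
    """
    allowed = _alphabet_for(alphabet)
    entries: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if name is not None:
            entries[name] = "".join(chunks)

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                if name in entries:
                    raise FormatError(f"{path}:{lineno}: duplicate record {name!r}")
                chunks = []
            else:
                if name is None:
                    raise FormatError(f"{path}:{lineno}: sequence before header")
                up = line.upper()
                bad = set(up) - allowed
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: illegal character(s) "
                        f"{''.join(sorted(bad))!r}"
                    )
                chunks.append(up)
    flush()
    return SeqRecordSet(entries)


def write_fasta(records: SeqRecordSet | Mapping[str, str], path: str | Path,
                width: int = 80) -> Path:
    entries = records.entries if isinstance(records, SeqRecordSet) else records
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in entries.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


# ---------------------------------------------------------------------------
# GTF


def _parse_gtf_attributes(text: str, path: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: malformed attribute {chunk!r}")
        key, value = parts
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Parse exon features of a GTF into :class:`GeneModel` objects.

    GTF coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention; exons are grouped per transcript and
    sorted into transcription order regardless of file order.
    """
    per_tx: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab fields")
            chrom, _src, feature, start_s, end_s, _score, strand, frame, attr_s = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start1 > end1:
                raise FormatError(f"{path}:{lineno}: start {start1} > end {end1}")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            attrs = _parse_gtf_attributes(attr_s, str(path), lineno)
            if "gene_id" not in attrs:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            tx = attrs.get("transcript_id", attrs["gene_id"])
            phase = int(frame) if frame in ("0", "1", "2") else None
            iv = Interval(chrom, start1 - 1, end1, strand)
            rec = per_tx.setdefault(tx, {"gene_id": attrs["gene_id"], "exons": []})
            rec["exons"].append((iv, phase))
            if tx not in order:
                order.append(tx)

    models: list[GeneModel] = []
    for tx in order:
        rec = per_tx[tx]
        exons = sorted(rec["exons"], key=lambda pair: pair[0].start)
        if exons[0][0].strand == "-":
            exons.reverse()
        phases = [p for _, p in exons]
        models.append(
            GeneModel(
                gene_id=rec["gene_id"],
                transcript_id=tx,
                exons=[iv for iv, _ in exons],
                cds_phase=phases if all(p is not None for p in phases) else [],
            )
        )
    return models


def write_gtf(models: Sequence[GeneModel], path: str | Path,
              source: str = "relicscan") -> Path:
    """Write gene models as GTF exon features (1-based inclusive)."""
    path = Path(path)
    with open(path, "w") as fh:
        for model in models:
            for exon, phase in zip(model.exons, model.cds_phase):
                attrs = (
                    f'gene_id "{model.gene_id}"; '
                    f'transcript_id "{model.transcript_id}";'
                )
                fh.write(
                    "\t".join(
                        [
                            exon.chrom,
                            source,
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            exon.strand,
                            str(phase),
                            attrs,
                        ]
                    )
                    + "\n"
                )
    return path


# ---------------------------------------------------------------------------
# BED reads and library totals


def read_bed_reads(path: str | Path, library_total: int) -> ReadSet:
    """Read mapped reads from a BED3+ file (0-based half-open)."""
    reads: list[Interval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "+"
            try:
                reads.append(Interval(fields[0], start, end, strand))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    if library_total < len(reads):
        raise FormatError(
            f"{path}: library_total {library_total} < {len(reads)} read lines"
        )
    return ReadSet(reads=reads, library_total=library_total)


def write_bed_reads(readset: ReadSet, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for i, read in enumerate(readset.reads):
            fh.write(
                f"{read.chrom}\t{read.start}\t{read.end}\tread{i}\t0\t{read.strand}\n"
            )
    return path


def read_library_totals(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV of tissue -> mapped-read library total."""
    totals: dict[str, int] = {}
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[0].lower() in ("tissue", "sample"):
                continue
            if len(row) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 TSV columns")
            try:
                totals[row[0]] = int(row[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer total") from exc
    return totals


def write_library_totals(totals: Mapping[str, int], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("tissue\tlibrary_total\n")
        for tissue, total in totals.items():
            fh.write(f"{tissue}\t{total}\n")
    return path
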