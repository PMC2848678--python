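"""Genome, gene-table, truth-label and detection I/O.

All coordinates are 0-based half-open (BED convention) throughout the
package.  Sequences are upper-cased on input and any character outside
``{A, C, G, T}`` is mapped to ``N``; ``N`` positions are excluded from
k-mer counting downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

_VALID = set("ACGTN")
_NON_ACGT = re.compile(r"[^ACGT]")

NATIVE_LABEL = "native"


class FormatError(ValueError):
    """Raised on malformed input files."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over the alphabet {A, C, G, T, N}."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Gene:
    """A gene interval: 0-based half-open [start, end) with a strand."""

    id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"gene {self.id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id!r}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedGenome:
    """A sequence plus its gene intervals and optional per-gene truth labels.

    ``truth`` maps gene id to ``"native"`` or to a donor-species id for
    horizontally transferred genes.  Genes are kept sorted by start and
    ids must be unique.
    """

    record: SequenceRecord
    genes: list[Gene] = field(default_factory=list)
    truth: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))
        ids = [g.id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("gene ids must be unique")
        n = len(self.record.seq)
        for g in self.genes:
            if g.end > n:
                raise ValueError(
                    f"gene {g.id!r} end {g.end} exceeds genome length {n}"
                )
        if self.truth is not None:
            unknown = set(self.truth) - set(ids)
            if unknown:
                raise ValueError(f"truth labels for unknown genes: {sorted(unknown)}")

    @property
    def length(self) -> int:
        return len(self.record.seq)

    def gene_sequence(self, gene: Gene) -> str:
        """Forward-strand slice of the gene; minus-strand genes are
        reverse-complemented so that CDS-dependent criteria read the
        coding strand."""
        s = self.record.seq[gene.start : gene.end]
        if gene.strand == "-":
            s = str(Seq(s).reverse_complement())
        return s


def _clean(seq: str) -> str:
    return _NON_ACGT.sub("N", seq.upper())


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file; sequences are upper-cased and non-ACGT bases
    mapped to N."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(rec.id, _clean(str(rec.seq))))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_gene_table(path: str | Path, genome_length: int) -> list[Gene]:
    """Read a BED4/BED6 gene table (0-based half-open), validate against
    the genome length, and return genes sorted by start."""
    path = Path(path)
    genes: list[Gene] = []
    seen: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{ln}: expected >=4 BED columns")
            _, start_s, end_s, name = fields[:4]
            strand = fields[5] if len(fields) >= 6 else "+"
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer coordinates") from exc
            if end <= start:
                raise FormatError(f"{path}:{ln}: end <= start")
            if end > genome_length:
                raise FormatError(
                    f"{path}:{ln}: end {end} exceeds genome length {genome_length}"
                )
            if name in seen:
                raise FormatError(f"{path}:{ln}: duplicate gene id {name!r}")
            seen.add(name)
            genes.append(Gene(name, start, end, strand))
    genes.sort(key=lambda g: (g.start, g.end))
    return genes


def write_gene_table(
    genes: Iterable[Gene], path: str | Path, seqid: str = "genome"
) -> None:
    """Write genes as BED6 (score column fixed to 0)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{seqid}\t{g.start}\t{g.end}\t{g.id}\t0\t{g.strand}\n")


def read_truth_table(path: str | Path) -> dict[str, str]:
    """Read a gene-id → label TSV (header ``gene_id<TAB>label``)."""
    truth: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["gene_id", "label"]:
            raise FormatError(f"{path}: expected header 'gene_id\\tlabel'")
        for ln, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{ln}: expected 2 columns")
            gid, label = fields
            if gid in truth:
                raise FormatError(f"{path}:{ln}: duplicate gene id {gid!r}")
            truth[gid] = label
    return truth


def write_truth_table(truth: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlabel\n")
        for gid, label in truth.items():
            fh.write(f"{gid}\t{label}\n")


def write_detections(
    calls: Mapping[str, bool],
    genes: list[Gene],
    bed_path: str | Path,
    tsv_path: str | Path,
    scores: Mapping[str, float] | None = None,
    method: str = "NA",
    seqid: str = "genome",
) -> None:
    """Write atypical genes as BED plus a full per-gene score/call TSV.

    The TSV has columns ``gene_id  method  score  call`` for every gene;
    the BED lists only genes called atypical.
    """
    by_id = {g.id: g for g in genes}
    unknown = set(calls) - set(by_id)
    if unknown:
        raise ValueError(f"calls for unknown genes: {sorted(unknown)}")
    with open(bed_path, "w") as bed:
        for g in genes:
            if calls.get(g.id, False):
                bed.write(f"{seqid}\t{g.start}\t{g.end}\t{g.id}\t0\t{g.strand}\n")
    with open(tsv_path, "w") as tsv:
        tsv.write("gene_id\tmethod\tscore\tcall\n")
        for g in genes:
            score = scores.get(g.id, float("nan")) if scores else float("nan")
            call = int(bool(calls.get(g.id, False)))
            tsv.write(f"{g.id}\t{method}\t{score:.6g}\t{call}\n")


def read_detections(tsv_path: str | Path) -> tuple[dict[str, float], dict[str, bool]]:
    """Read back a detection TSV written by :func:`write_detections`."""
    scores: dict[str, float] = {}
    calls: dict[str, bool] = {}
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene_id", "method", "score", "call"]:
            raise FormatError(f"{tsv_path}: unexpected header {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            gid, _method, score, call = line.split("\t")
            scores[gid] = float(score)
            calls[gid] = bool(int(call))
    return scores, calls
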