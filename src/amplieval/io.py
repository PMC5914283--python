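"""FASTA / FASTQ / Greengenes-style taxonomy readers and writers.

Parsing is delegated to Biopython's SeqIO; this module adds the package's
validation rules (duplicate ids, empty sequences, Phred+33 only) and the
lineage dialect. Files ending in ``.gz`` are transparently decompressed.
"""

from __future__ import annotations

import gzip
import warnings
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio import SeqIO

from .records import (
    EMPTY_LINEAGE,
    FormatError,
    Platform,
    RANK_PREFIXES,
    Read,
    ReferenceRecord,
    is_empty_label,
)

PHRED_OFFSET = 33


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fasta(path: str | Path) -> list[ReferenceRecord]:
    """Read FASTA into :class:`ReferenceRecord` objects (no lineages).

    Headers are split on the first whitespace for the id; sequences are
    uppercased. Duplicate ids and empty sequences are format errors.
    """
    records: list[ReferenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for entry in SeqIO.parse(handle, "fasta"):
            if entry.id in seen:
                raise FormatError(f"duplicate FASTA id {entry.id!r} in {path}")
            seen.add(entry.id)
            records.append(ReferenceRecord(id=entry.id, sequence=str(entry.seq).upper()))
    return records


def write_fasta(records: Iterable[ReferenceRecord], path: str | Path, width: int = 80) -> None:
    with _open_text(path, "wt") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


def parse_lineage(text: str) -> tuple[str, ...]:
    """Parse ``"k__X; p__Y; ..."`` into a 7-slot lineage tuple.

    Missing trailing ranks are filled with their bare prefixes; more than
    seven ranks is a format error.
    """
    labels = [part.strip() for part in text.split(";")] if text.strip() else []
    if len(labels) > len(RANK_PREFIXES):
        raise FormatError(f"lineage {text!r} has more than 7 ranks")
    out: list[str] = []
    for i, prefix in enumerate(RANK_PREFIXES):
        label = labels[i] if i < len(labels) else prefix
        out.append(prefix if is_empty_label(label) else label)
    return tuple(out)


def format_lineage(lineage: tuple[str, ...]) -> str:
    return "; ".join(lineage)


def read_taxonomy(path: str | Path, fasta_ids: set[str] | None = None) -> dict[str, tuple[str, ...]]:
    """Read a two-column (id, lineage string) tab-separated taxonomy table.

    When ``fasta_ids`` is given, ids absent from it trigger a warning but
    are kept (the companion FASTA may be a subset).
    """
    lineages: dict[str, tuple[str, ...]] = {}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected two tab-separated columns")
            seq_id, lineage_text = parts[0], parts[1]
            lineages[seq_id] = parse_lineage(lineage_text)
            if fasta_ids is not None and seq_id not in fasta_ids:
                warnings.warn(f"taxonomy id {seq_id!r} absent from FASTA", stacklevel=2)
    return lineages


def attach_taxonomy(
    records: Iterable[ReferenceRecord], lineages: dict[str, tuple[str, ...]]
) -> list[ReferenceRecord]:
    """Return records with lineages attached where available."""
    out = []
    for rec in records:
        lineage = lineages.get(rec.id, EMPTY_LINEAGE)
        out.append(
            ReferenceRecord(
                id=rec.id,
                sequence=rec.sequence,
                lineage=lineage,
                truth_cluster=rec.truth_cluster,
            )
        )
    return out


def read_fastq(path: str | Path, platform: Platform = Platform.MISEQ) -> list[Read]:
    """Read Sanger (Phred+33) FASTQ; any other dialect is rejected upstream."""
    reads: list[Read] = []
    with _open_text(path) as handle:
        parser = SeqIO.parse(handle, "fastq")
        index = 0
        while True:
            try:
                entry = next(parser)
            except StopIteration:
                break
            except ValueError as exc:
                raise FormatError(f"{path}: malformed FASTQ at record {index}: {exc}") from exc
            quals = tuple(entry.letter_annotations["phred_quality"])
            reads.append(
                Read(id=entry.id, bases=str(entry.seq).upper(), quals=quals, platform=platform)
            )
            index += 1
    return reads


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for read in reads:
            qual = "".join(chr(q + PHRED_OFFSET) for q in read.quals)
            handle.write(f"@{read.id}\n{read.bases}\n+\n{qual}\n")


def read_truth(path: str | Path) -> dict[str, str]:
    """Read a two-column (id, truth cluster) tab-separated table."""
    truth: dict[str, str] = {}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected two tab-separated columns")
            truth[parts[0]] = parts[1]
    return truth


def write_truth(records: Iterable[ReferenceRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for rec in records:
            if rec.truth_cluster is not None:
                handle.write(f"{rec.id}\t{rec.truth_cluster}\n")


def write_taxonomy(records: Iterable[ReferenceRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for rec in records:
            handle.write(f"{rec.id}\t{format_lineage(rec.lineage)}\n")
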