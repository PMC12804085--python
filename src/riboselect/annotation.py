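"""Transcript annotation records with membrane-topology segments.

Coordinate conventions used throughout the package:

* residue indices are 1-based inclusive on the *precursor* protein, i.e.
  the cleaved signal peptide (when present) occupies residues
  ``1..sp_end``;
* codon ``i`` of the CDS encodes residue ``i``, so codon indices live in
  the same coordinate system as residues;
* nucleotide positions on transcripts are 0-based half-open (BED
  convention), with position 0 being the first nucleotide of the start
  codon unless an explicit 5' UTR offset is supplied.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

SEGMENT_KINDS = ("SP", "lumenal", "TM", "cytosolic")
TRANSCRIPT_CLASSES = ("secretory", "membrane", "cytosolic")

ANNOTATION_COLUMNS = [
    "transcript_id",
    "gene_name",
    "protein_length",
    "cds_length",
    "class",
    "sp_end",
    "segments",
]


class AnnotationError(ValueError):
    """Malformed annotation record or annotation file."""


@dataclass(frozen=True)
class Segment:
    """A contiguous topological span of a protein, residues inclusive."""

    kind: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise AnnotationError(f"unknown segment kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise AnnotationError(
                f"invalid segment span {self.start}-{self.end} (1-based inclusive)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:
        return f"{self.kind}:{self.start}-{self.end}"


@dataclass(frozen=True)
class TranscriptAnnotation:
    """One transcript: CDS geometry, class and topology segments.

    ``cds_length`` is in nucleotides and may either include the stop codon
    (``3 * (protein_length + 1)``) or not (``3 * protein_length``); both
    dialects are accepted.  ``sp_end`` is the last residue of the signal
    peptide, or ``None`` for proteins without one.
    """

    transcript_id: str
    gene_name: str
    protein_length: int
    cds_length: int
    transcript_class: str
    sp_end: int | None
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        self.validate()

    def validate(self) -> None:
        tid = self.transcript_id
        if self.transcript_class not in TRANSCRIPT_CLASSES:
            raise AnnotationError(
                f"{tid}: unknown transcript class {self.transcript_class!r}"
            )
        if self.protein_length < 1:
            raise AnnotationError(f"{tid}: protein_length must be >= 1")
        expected = (3 * self.protein_length, 3 * (self.protein_length + 1))
        if self.cds_length not in expected:
            raise AnnotationError(
                f"{tid}: cds_length {self.cds_length} is neither "
                f"3*protein_length ({expected[0]}) nor 3*(protein_length+1) "
                f"({expected[1]})"
            )
        prev_end = 0
        sp_segments = []
        for seg in self.segments:
            if seg.start <= prev_end:
                raise AnnotationError(
                    f"{tid}: segments overlap or are out of order at {seg}"
                )
            if seg.end > self.protein_length:
                raise AnnotationError(
                    f"{tid}: segment {seg} exceeds protein length "
                    f"{self.protein_length}"
                )
            if seg.kind == "SP":
                sp_segments.append(seg)
            prev_end = seg.end
        if self.sp_end is not None:
            if not sp_segments:
                raise AnnotationError(f"{tid}: sp_end set but no SP segment")
            if sp_segments[0].end != self.sp_end:
                raise AnnotationError(
                    f"{tid}: sp_end {self.sp_end} disagrees with SP segment "
                    f"{sp_segments[0]}"
                )
        elif sp_segments:
            raise AnnotationError(f"{tid}: SP segment present but sp_end unset")

    @property
    def lumenal_segments(self) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.kind == "lumenal")


def parse_segments(text: str) -> tuple[Segment, ...]:
    """Parse the semicolon-separated ``kind:start-end`` segment dialect."""
    text = text.strip()
    if not text:
        return ()
    segments = []
    for token in text.split(";"):
        token = token.strip()
        try:
            kind, span = token.split(":")
            start_s, end_s = span.split("-")
            segments.append(Segment(kind.strip(), int(start_s), int(end_s)))
        except (ValueError, TypeError) as exc:
            if isinstance(exc, AnnotationError):
                raise
            raise AnnotationError(f"cannot parse segment token {token!r}") from exc
    return tuple(segments)


def format_segments(segments: Iterable[Segment]) -> str:
    return ";".join(str(s) for s in segments)


def read_annotation(path: str | Path) -> dict[str, TranscriptAnnotation]:
    """Read the annotation TSV into an ordered ``{transcript_id: record}`` map.

    Raises :class:`AnnotationError` naming the offending line for duplicate
    ids, unknown class tokens, overlapping segments or inconsistent
    signal-peptide fields.
    """
    records: dict[str, TranscriptAnnotation] = {}
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = set(ANNOTATION_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise AnnotationError(
                f"{path}: missing annotation columns {sorted(missing)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                sp_text = (row["sp_end"] or "").strip()
                record = TranscriptAnnotation(
                    transcript_id=row["transcript_id"].strip(),
                    gene_name=row["gene_name"].strip(),
                    protein_length=int(row["protein_length"]),
                    cds_length=int(row["cds_length"]),
                    transcript_class=row["class"].strip(),
                    sp_end=int(sp_text) if sp_text else None,
                    segments=parse_segments(row["segments"] or ""),
                )
            except (AnnotationError, ValueError, KeyError) as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            if record.transcript_id in records:
                raise AnnotationError(
                    f"{path}:{lineno}: duplicate transcript_id "
                    f"{record.transcript_id!r}"
                )
            records[record.transcript_id] = record
    return records


def write_annotation(
    records: Mapping[str, TranscriptAnnotation] | Iterable[TranscriptAnnotation],
    path: str | Path,
) -> None:
    if isinstance(records, Mapping):
        records = records.values()
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATION_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.transcript_id,
                    rec.gene_name,
                    rec.protein_length,
                    rec.cds_length,
                    rec.transcript_class,
                    "" if rec.sp_end is None else rec.sp_end,
                    format_segments(rec.segments),
                ]
            )
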