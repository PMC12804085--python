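"""Raw footprint reads, A-site offset calibration and codon assignment.

Footprints are held in long-format DataFrames with columns
``transcript_id, five_prime, length, sample, replicate`` (transcript
coordinates, 0-based 5' ends).  On disk they are 6-column BED in
transcript coordinates: ``transcript_id  start  end  read_id  length  +``.

The A-site of a ribosome-protected fragment sits a read-length-specific
number of nucleotides downstream of the fragment 5' end.  We calibrate
that offset per read length from the 3-nt periodicity of footprints over
coding sequence: the correct offset places the adjusted 5' ends of a
periodic read population in frame 0 of the CDS.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotation import TranscriptAnnotation
from .counts import CodonCountMatrix, empty_matrix

READ_COLUMNS = ["transcript_id", "five_prime", "length", "sample", "replicate"]

DEFAULT_SEARCH_RANGE = (10, 15)
DEFAULT_PERIODICITY_MIN = 0.5


@dataclass(frozen=True)
class FootprintRead:
    transcript_id: str
    five_prime: int
    length: int
    sample: str = "input"
    replicate: int = 1


def reads_to_frame(reads: Iterable[FootprintRead]) -> pd.DataFrame:
    rows = [
        (r.transcript_id, r.five_prime, r.length, r.sample, r.replicate)
        for r in reads
    ]
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def read_bed(path: str | Path, sample: str, replicate: int) -> pd.DataFrame:
    """Read transcript-coordinate BED6 footprints for one library."""
    rows = []
    with open(path, newline="") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            start, end = int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: empty or inverted interval")
            rows.append((fields[0], start, end - start, sample, replicate))
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def write_bed(reads: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        for i, row in enumerate(reads.itertuples(index=False)):
            writer.writerow(
                [
                    row.transcript_id,
                    row.five_prime,
                    row.five_prime + row.length,
                    f"read{i:07d}",
                    row.length,
                    "+",
                ]
            )


@dataclass(frozen=True)
class OffsetEntry:
    offset_nt: int
    frame0_fraction: float
    accepted: bool


@dataclass
class OffsetTable:
    """Per-read-length A-site offsets with their periodicity support."""

    entries: dict[int, OffsetEntry]

    def offset(self, length: int) -> int | None:
        entry = self.entries.get(length)
        if entry is None or not entry.accepted:
            return None
        return entry.offset_nt

    def accepted_lengths(self) -> list[int]:
        return sorted(k for k, v in self.entries.items() if v.accepted)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (length, e.offset_nt, e.frame0_fraction, e.accepted)
            for length, e in sorted(self.entries.items())
        ]
        return pd.DataFrame(
            rows, columns=["length", "offset_nt", "frame0_fraction", "accepted"]
        )


def calibrate_asite(
    reads: pd.DataFrame,
    annotation: Mapping[str, TranscriptAnnotation],
    search_range: tuple[int, int] = DEFAULT_SEARCH_RANGE,
    periodicity_min: float = DEFAULT_PERIODICITY_MIN,
    cds_start: int = 0,
) -> OffsetTable:
    """Calibrate the per-read-length A-site offset from frame periodicity.

    For each read length, every candidate offset in ``search_range``
    (inclusive) is scored by the number of reads whose shifted 5' end
    lands in frame 0 of the CDS.  Frame counts are invariant to shifting
    the offset by 3 nt, so exact ties are resolved first by the number of
    reads assigned to an in-bounds codon (1..protein_length) and then
    toward the smaller offset.  Lengths whose best frame-0 fraction falls
    below ``periodicity_min`` are marked not accepted.
    """
    if len(reads) == 0:
        raise ValueError("cannot calibrate offsets from an empty read set")
    lo, hi = search_range
    if lo > hi or lo < 0:
        raise ValueError(f"invalid search range {search_range}")
    plen_map = {tid: rec.protein_length for tid, rec in annotation.items()}
    plen = reads["transcript_id"].map(plen_map)
    if plen.isna().any():
        unknown = reads.loc[plen.isna(), "transcript_id"].iloc[0]
        raise ValueError(f"read on unannotated transcript {unknown!r}")
    rel = reads["five_prime"].to_numpy(dtype=np.int64) - cds_start
    plen_arr = plen.to_numpy(dtype=np.int64)
    lengths = reads["length"].to_numpy(dtype=np.int64)

    entries: dict[int, OffsetEntry] = {}
    for length in sorted(np.unique(lengths)):
        mask = lengths == length
        sub_rel = rel[mask]
        sub_plen = plen_arr[mask]
        n = len(sub_rel)
        best_key: tuple[int, int, int] | None = None
        best_offset = lo
        for offset in range(lo, hi + 1):
            shifted = sub_rel + offset
            frame0 = int(np.count_nonzero(shifted % 3 == 0))
            codon = np.floor_divide(shifted, 3) + 1
            in_bounds = int(np.count_nonzero((codon >= 1) & (codon <= sub_plen)))
            key = (frame0, in_bounds, -offset)
            if best_key is None or key > best_key:
                best_key = key
                best_offset = offset
        frac = best_key[0] / n
        entries[int(length)] = OffsetEntry(
            offset_nt=best_offset,
            frame0_fraction=frac,
            accepted=frac >= periodicity_min,
        )
    return OffsetTable(entries)


def assign_asite(
    reads: pd.DataFrame,
    offsets: OffsetTable,
    annotation: Mapping[str, TranscriptAnnotation],
    cds_start: int = 0,
) -> tuple[CodonCountMatrix, dict[str, int]]:
    """Assign accepted reads to A-site codons and tally per-codon counts.

    A read of length ``l`` with 5' end ``p`` contributes one count to codon
    ``floor((p + offset(l) - cds_start) / 3) + 1``.  Reads of unaccepted or
    uncalibrated lengths, reads on unannotated transcripts and reads whose
    A-site falls outside ``1..protein_length`` are dropped and reported in
    the QC counters.
    """
    qc = {
        "total": int(len(reads)),
        "assigned": 0,
        "dropped_unaccepted_length": 0,
        "dropped_unknown_transcript": 0,
        "dropped_out_of_cds": 0,
    }
    if len(reads) == 0:
        return empty_matrix(), qc

    offset_map = {l: offsets.entries[l].offset_nt for l in offsets.accepted_lengths()}
    off = reads["length"].map(offset_map)
    known_length = off.notna()
    qc["dropped_unaccepted_length"] = int((~known_length).sum())

    plen_map = {tid: rec.protein_length for tid, rec in annotation.items()}
    plen = reads["transcript_id"].map(plen_map)
    known_tid = plen.notna()
    qc["dropped_unknown_transcript"] = int((known_length & ~known_tid).sum())

    usable = known_length & known_tid
    sub = reads[usable]
    codon = (
        sub["five_prime"].to_numpy(dtype=np.int64)
        + off[usable].to_numpy(dtype=np.int64)
        - cds_start
    ) // 3 + 1
    in_bounds = (codon >= 1) & (codon <= plen[usable].to_numpy(dtype=np.int64))
    qc["dropped_out_of_cds"] = int(np.count_nonzero(~in_bounds))
    qc["assigned"] = int(np.count_nonzero(in_bounds))

    kept = sub[in_bounds].copy()
    if len(kept) == 0:
        return empty_matrix(), qc
    kept["codon"] = codon[in_bounds]
    grouped = (
        kept.groupby(["transcript_id", "codon", "sample", "replicate"])
        .size()
        .rename("count")
        .reset_index()
    )
    return CodonCountMatrix(grouped), qc
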