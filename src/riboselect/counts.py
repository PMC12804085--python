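"""Sparse per-codon A-site count matrices and their TSV dialect.

A :class:`CodonCountMatrix` holds counts indexed by
``(transcript_id, codon, sample, replicate)`` where ``sample`` is one of
``input`` / ``IP`` and ``codon`` is 1-based (codon i encodes residue i).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import TranscriptAnnotation

COUNT_COLUMNS = ["transcript_id", "codon", "sample", "replicate", "count"]
SAMPLES = ("input", "IP")


class CountsError(ValueError):
    """Malformed count matrix or counts file."""


@dataclass
class CodonCountMatrix:
    """Long-format sparse codon counts for paired input/IP libraries."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        missing = set(COUNT_COLUMNS) - set(df.columns)
        if missing:
            raise CountsError(f"count matrix missing columns {sorted(missing)}")
        df = df.loc[:, COUNT_COLUMNS].copy()
        for col in ("codon", "replicate", "count"):
            values = df[col].to_numpy()
            as_int = np.asarray(values).astype(np.int64, casting="unsafe")
            if not np.array_equal(as_int, np.asarray(values, dtype=float)):
                raise CountsError(f"non-integer values in column {col!r}")
            df[col] = as_int
        if (df["count"] < 0).any():
            raise CountsError("negative counts are not allowed")
        if (df["codon"] < 1).any():
            raise CountsError("codon indices are 1-based and must be >= 1")
        bad = set(df["sample"].unique()) - set(SAMPLES)
        if bad:
            raise CountsError(f"unknown sample labels {sorted(bad)}")
        self.counts = df

    # -- summaries -------------------------------------------------------
    def library_sizes(self) -> pd.Series:
        """Total counts per (sample, replicate) library."""
        return self.counts.groupby(["sample", "replicate"])["count"].sum()

    def transcript_totals(self) -> pd.DataFrame:
        """Per-transcript totals; columns are a (sample, replicate) MultiIndex."""
        return pd.pivot_table(
            self.counts,
            index="transcript_id",
            columns=["sample", "replicate"],
            values="count",
            aggfunc="sum",
            fill_value=0,
        )

    def replicates(self) -> list[int]:
        return sorted(self.counts["replicate"].unique())

    def codon_vector(
        self, transcript_id: str, sample: str, replicate: int, length: int
    ) -> np.ndarray:
        """Dense count vector over codons ``1..length`` for one library."""
        sub = self.counts[
            (self.counts["transcript_id"] == transcript_id)
            & (self.counts["sample"] == sample)
            & (self.counts["replicate"] == replicate)
        ]
        out = np.zeros(length, dtype=np.int64)
        codons = sub["codon"].to_numpy()
        if len(codons) and codons.max() > length:
            raise CountsError(
                f"{transcript_id}: codon {codons.max()} beyond length {length}"
            )
        out[codons - 1] = sub["count"].to_numpy()
        return out

    def sorted_frame(self) -> pd.DataFrame:
        return (
            self.counts[self.counts["count"] > 0]
            .sort_values(COUNT_COLUMNS[:4], kind="mergesort")
            .reset_index(drop=True)
        )


def empty_matrix() -> CodonCountMatrix:
    frame = pd.DataFrame(
        {
            "transcript_id": pd.Series(dtype=str),
            "codon": pd.Series(dtype=np.int64),
            "sample": pd.Series(dtype=str),
            "replicate": pd.Series(dtype=np.int64),
            "count": pd.Series(dtype=np.int64),
        }
    )
    return CodonCountMatrix(frame)


def write_counts(matrix: CodonCountMatrix, path: str | Path) -> None:
    matrix.sorted_frame().to_csv(path, sep="\t", index=False)


def read_counts(
    path: str | Path,
    annotation: Mapping[str, TranscriptAnnotation] | None = None,
) -> CodonCountMatrix:
    """Read a counts TSV; with an annotation, validate codon bounds.

    Negative or non-integer counts, and (when an annotation is supplied)
    codons beyond the protein length or unknown transcripts, are rejected
    with an error naming the offending record.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "sample": str})
    except ValueError as exc:
        raise CountsError(f"{path}: {exc}") from exc
    matrix = CodonCountMatrix(df)
    if annotation is not None:
        for tid, group in matrix.counts.groupby("transcript_id"):
            rec = annotation.get(tid)
            if rec is None:
                raise CountsError(f"{path}: unknown transcript {tid!r}")
            worst = int(group["codon"].max())
            if worst > rec.protein_length:
                raise CountsError(
                    f"{path}: {tid} codon {worst} beyond protein length "
                    f"{rec.protein_length}"
                )
    return matrix
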