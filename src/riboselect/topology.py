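"""Topology summaries and cross-transcript comparisons.

Clients of the secretory translocon expose "translocated" spans — the
lumenal portions of their topology — during synthesis; a useful summary
per transcript is the length of its longest lumenal segment, against
which IP/input enrichment can be stratified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import TranscriptAnnotation


def longest_translocated_segment(record: TranscriptAnnotation) -> int:
    """Length (residues) of the longest lumenal segment; 0 if none.

    TM spans are membrane-embedded, not translocated, and are excluded.
    """
    lumenal = record.lumenal_segments
    return max((s.length for s in lumenal), default=0)


def topology_summary(
    annotation: Mapping[str, TranscriptAnnotation],
) -> pd.DataFrame:
    rows = [
        (
            tid,
            longest_translocated_segment(rec),
            rec.transcript_class in ("secretory", "membrane"),
        )
        for tid, rec in annotation.items()
    ]
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "longest_translocated_segment", "is_secretory_or_TM"],
    )


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_permutation: float
    n_pairs: int
    n_permutations: int


def spearman_permutation(
    x: np.ndarray,
    y: np.ndarray,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> SpearmanResult:
    """Spearman rank correlation with a two-sided permutation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    norm = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    if norm == 0:
        raise ValueError("constant ranks; correlation undefined")
    rho = float(rxc @ ryc / norm)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(
        np.tile(rxc, (n_permutations, 1)), axis=1
    )
    rho_perm = perms @ ryc / norm
    exceed = int(np.count_nonzero(np.abs(rho_perm) >= abs(rho) - 1e-12))
    p = (1 + exceed) / (n_permutations + 1)
    return SpearmanResult(rho, p, len(x), n_permutations)


def enrichment_vs_length(
    table: pd.DataFrame,
    annotation: Mapping[str, TranscriptAnnotation],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, SpearmanResult]:
    """Pair centred enrichment with log2 longest-translocated-segment length
    over secretory/TM transcripts, plus a Spearman permutation test.

    Only quantified transcripts of the secretory/membrane classes with a
    non-empty translocated span enter the comparison.
    """
    summary = topology_summary(annotation).set_index("transcript_id")
    merged = table.set_index("transcript_id").join(
        summary["is_secretory_or_TM"], how="inner"
    )
    keep = (
        merged["is_secretory_or_TM"]
        & merged["quantified"]
        & (merged["longest_translocated_segment"] >= 1)
    )
    pairs = merged[keep]
    if len(pairs) == 0:
        raise ValueError("no quantified secretory/TM transcripts to compare")
    out = pd.DataFrame(
        {
            "transcript_id": pairs.index,
            "longest_translocated_segment": pairs[
                "longest_translocated_segment"
            ].to_numpy(),
            "log2_segment_length": np.log2(
                pairs["longest_translocated_segment"].to_numpy(dtype=float)
            ),
            "log2_enrichment_centred": pairs["log2_enrichment_centred"].to_numpy(),
        }
    ).reset_index(drop=True)
    corr = spearman_permutation(
        out["log2_segment_length"].to_numpy(),
        out["log2_enrichment_centred"].to_numpy(),
        n_permutations=n_permutations,
        seed=seed,
    )
    return out, corr


def compare_factors(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    q_threshold: float = 0.05,
    suffixes: tuple[str, str] = ("_a", "_b"),
) -> pd.DataFrame:
    """Inner-join two factors' enrichment tables and flag which factor(s)
    call each transcript enriched (q below threshold and centred enrichment
    above zero)."""
    cols = [
        "transcript_id",
        "log2_enrichment_centred",
        "tpm_input",
        "tpm_ip",
        "p_adj",
    ]
    a = table_a[cols + ["class", "longest_translocated_segment"]].copy()
    b = table_b[cols].copy()
    joined = a.merge(b, on="transcript_id", suffixes=suffixes, how="inner")
    for suffix in suffixes:
        joined[f"enriched{suffix}"] = (
            (joined[f"p_adj{suffix}"] < q_threshold)
            & (joined[f"log2_enrichment_centred{suffix}"] > 0)
        ).fillna(False)
    ea, eb = (joined[f"enriched{s}"] for s in suffixes)
    joined["enriched_in"] = np.select(
        [ea & eb, ea & ~eb, ~ea & eb],
        ["both", "a_only", "b_only"],
        default="neither",
    )
    return joined
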