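"""Transcript-level quantification and IP/input enrichment statistics.

Abundance is quantified as transcripts per million (TPM) over CDS counts.
Enrichment is the log2 ratio of IP to input TPM, computed per replicate
and averaged, then median-centred across all quantified transcripts so
that the bulk of the transcriptome sits at zero.  Significance per
transcript comes from a Pearson chi-squared test on the 2x2 table of
(reads on transcript, reads elsewhere) x (IP, input) with replicates
pooled, followed by Benjamini-Hochberg correction.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import TranscriptAnnotation
from .counts import CodonCountMatrix
from .topology import longest_translocated_segment

DEFAULT_ALPHA = 0.5  # symmetric TPM pseudocount
DEFAULT_MIN_INPUT_READS = 32  # pooled input reads required to quantify


def compute_tpm(
    matrix: CodonCountMatrix,
    annotation: Mapping[str, TranscriptAnnotation],
) -> pd.DataFrame:
    """Transcripts-per-million per library over all annotated transcripts.

    ``rate_g = counts_g / (cds_length_g / 1000)`` and
    ``TPM_g = 1e6 * rate_g / sum_h rate_h`` within each
    (sample, replicate) library.  Transcripts absent from the matrix get
    TPM 0.  Raises on a library with zero total reads.
    """
    if len(matrix.counts) == 0:
        raise ValueError("cannot quantify an empty count matrix")
    totals = matrix.transcript_totals()
    unknown = set(totals.index) - set(annotation)
    if unknown:
        raise ValueError(f"counts for unannotated transcripts: {sorted(unknown)[:5]}")
    totals = totals.reindex(list(annotation), fill_value=0)
    cds_kb = pd.Series(
        {tid: rec.cds_length / 1000.0 for tid, rec in annotation.items()}
    )
    rates = totals.div(cds_kb, axis=0)
    denom = rates.sum(axis=0)
    zero = denom[denom == 0]
    if len(zero):
        raise ValueError(f"library {zero.index[0]} has zero total reads")
    return 1e6 * rates.div(denom, axis=1)


def compute_enrichment(
    tpm_ip: np.ndarray | pd.Series | float,
    tpm_input: np.ndarray | pd.Series | float,
    alpha: float = DEFAULT_ALPHA,
) -> np.ndarray | float:
    """log2((TPM_IP + alpha) / (TPM_input + alpha)); alpha in TPM units."""
    ip = np.asarray(tpm_ip, dtype=float)
    inp = np.asarray(tpm_input, dtype=float)
    if (ip < 0).any() or (inp < 0).any():
        raise ValueError("TPM values must be non-negative")
    out = np.log2((ip + alpha) / (inp + alpha))
    return out if out.ndim else float(out)


def median_centre(values: np.ndarray | pd.Series) -> np.ndarray:
    """Subtract the median of the full value set (midpoint rule for even n)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot median-centre an empty set")
    return arr - np.median(arr)


def test_enrichment(
    n_ip: np.ndarray | int,
    N_ip: np.ndarray | int,
    n_input: np.ndarray | int,
    N_input: np.ndarray | int,
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Pearson chi-squared (1 df, no continuity correction) on the 2x2 table
    ``[[n_ip, N_ip - n_ip], [n_input, N_input - n_input]]``.

    Returns (statistic, p).  Tables with a zero margin have undefined
    expected cells; those entries come back as NaN (untestable).
    """
    a = np.asarray(n_ip, dtype=float)
    c = np.asarray(n_input, dtype=float)
    Nip = np.asarray(N_ip, dtype=float)
    Nin = np.asarray(N_input, dtype=float)
    if (a < 0).any() or (c < 0).any() or (Nip < a).any() or (Nin < c).any():
        raise ValueError("need N >= n >= 0 in both libraries")
    b = Nip - a
    d = Nin - c
    N = Nip + Nin
    col1 = a + c
    col2 = b + d
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = N * (a * d - b * c) ** 2 / (Nip * Nin * col1 * col2)
    stat = np.where((Nip > 0) & (Nin > 0) & (col1 > 0) & (col2 > 0), stat, np.nan)
    p = np.where(np.isnan(stat), np.nan, stats.chi2.sf(stat, df=1))
    if stat.ndim == 0:
        return float(stat), float(p)
    return stat, p


test_enrichment.__test__ = False  # not a pytest test, despite the name


def adjust_bh(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrichment_table(
    matrix: CodonCountMatrix,
    annotation: Mapping[str, TranscriptAnnotation],
    alpha: float = DEFAULT_ALPHA,
    min_input_reads: int = DEFAULT_MIN_INPUT_READS,
) -> pd.DataFrame:
    """Full per-transcript enrichment table for one factor.

    Enrichment is computed per replicate and averaged across replicates;
    counts are pooled across replicates for the chi-squared test.
    Transcripts with fewer than ``min_input_reads`` pooled input reads are
    excluded from centring and testing (``quantified`` False, NaN
    statistics).  BH correction runs over all tested transcripts.
    """
    tpm = compute_tpm(matrix, annotation)
    samples = sorted({s for s, _ in tpm.columns})
    if set(samples) != {"IP", "input"}:
        raise ValueError(f"need paired input/IP libraries, got samples {samples}")
    reps_ip = sorted(r for s, r in tpm.columns if s == "IP")
    reps_in = sorted(r for s, r in tpm.columns if s == "input")
    if reps_ip != reps_in:
        raise ValueError(
            f"replicate mismatch between samples: IP {reps_ip} vs input {reps_in}"
        )

    per_rep = np.column_stack(
        [
            compute_enrichment(tpm[("IP", r)], tpm[("input", r)], alpha=alpha)
            for r in reps_ip
        ]
    )
    raw = per_rep.mean(axis=1)

    totals = matrix.transcript_totals().reindex(tpm.index, fill_value=0)
    n_input = totals["input"].sum(axis=1).to_numpy(dtype=np.int64)
    n_ip = totals["IP"].sum(axis=1).to_numpy(dtype=np.int64)
    N_input = int(n_input.sum())
    N_ip = int(n_ip.sum())

    quantified = n_input >= min_input_reads
    if not quantified.any():
        raise ValueError("no transcript passes the minimum input coverage filter")

    centred = np.full(len(tpm.index), np.nan)
    centred[quantified] = median_centre(raw[quantified])

    chi2_stat = np.full(len(tpm.index), np.nan)
    p_value = np.full(len(tpm.index), np.nan)
    stat_q, p_q = test_enrichment(
        n_ip[quantified], N_ip, n_input[quantified], N_input
    )
    chi2_stat[quantified] = stat_q
    p_value[quantified] = p_q

    tested = ~np.isnan(p_value)
    p_adj = np.full(len(tpm.index), np.nan)
    if tested.any():
        p_adj[tested] = adjust_bh(p_value[tested])

    records = [annotation[tid] for tid in tpm.index]
    table = pd.DataFrame(
        {
            "transcript_id": tpm.index,
            "gene_name": [r.gene_name for r in records],
            "class": [r.transcript_class for r in records],
            "longest_translocated_segment": [
                longest_translocated_segment(r) for r in records
            ],
            "n_input": n_input,
            "n_ip": n_ip,
            "tpm_input": tpm["input"].mean(axis=1).to_numpy(),
            "tpm_ip": tpm["IP"].mean(axis=1).to_numpy(),
            "log2_enrichment_raw": raw,
            "log2_enrichment_centred": centred,
            "chi2_stat": chi2_stat,
            "p_value": p_value,
            "p_adj": p_adj,
            "quantified": quantified,
            "tested": tested,
        }
    ).reset_index(drop=True)
    return table
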