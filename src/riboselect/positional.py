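"""Codon-resolved interaction profiles and engagement-onset detection.

The codon-level enrichment of a factor on one transcript is

    e_c = log2( (n_IP,c / N_IP + beta) / (n_input,c / N_input + beta) )

computed per replicate from per-codon A-site counts n and library sizes
N, with a small rate-scale pseudocount beta.  Replicates are aggregated
as mean and range per codon, the mean profile is smoothed with a centred
running mean, and the onset of engagement is called as the first codon
where the smoothed profile climbs a set fraction of the way from its
pre-onset baseline to its plateau and stays there.

Because roughly ``buried_offset`` (default 55) residues of nascent chain
are concealed in the ribosome exit tunnel and the SEC61 channel, a
ribosome decoding codon L has exposed residues ``sp_end+1 .. L - buried_offset``
to the ER lumen; the coordinate maps below convert between nascent-chain
length and the lumenal residue window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .annotation import TranscriptAnnotation
from .counts import CodonCountMatrix

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 15  # codons, smoothing
DEFAULT_THETA = 0.5  # fraction of baseline->plateau rise
DEFAULT_PERSISTENCE = 10  # codons the rise must hold
DEFAULT_BASELINE_WINDOW = 50  # codons defining the pre-onset baseline
DEFAULT_MIN_EFFECT = 0.5  # log2 units; below this, no onset is called
DEFAULT_BURIED_OFFSET = 55  # residues hidden in exit tunnel + channel


@dataclass
class PositionalProfile:
    """Per-replicate codon-level log2 IP/input enrichment for one transcript."""

    transcript_id: str
    replicates: tuple[int, ...]
    e: np.ndarray  # shape (n_replicates, protein_length)

    def mean(self) -> np.ndarray:
        return self.e.mean(axis=0)

    def range(self) -> np.ndarray:
        return self.e.max(axis=0) - self.e.min(axis=0)


@dataclass(frozen=True)
class OnsetResult:
    onset_codon: int | None
    baseline: float
    plateau: float
    threshold: float


@dataclass(frozen=True)
class EngagementCall:
    """Detected onset of factor engagement on one transcript."""

    transcript_id: str
    onset_codon: int | None
    onset_chain_length_aa: int | None
    lumenal_window: tuple[int, int] | None
    buried_offset: int
    plateau_level: float


def codon_enrichment(
    matrix: CodonCountMatrix,
    transcript_id: str,
    annotation: Mapping[str, TranscriptAnnotation],
    beta: float | None = None,
) -> PositionalProfile:
    """Per-replicate codon-level enrichment profile for one transcript.

    ``beta`` is in per-read rate units; the default ``0.5 / min(N_IP,
    N_input)`` (per replicate) keeps zero-count codons finite while
    leaving the profile invariant to joint rescaling of both libraries.
    """
    record = annotation.get(transcript_id)
    if record is None:
        raise ValueError(f"unknown transcript {transcript_id!r}")
    present = set(matrix.counts["transcript_id"].unique())
    if transcript_id not in present:
        raise ValueError(f"transcript {transcript_id!r} absent from count matrix")
    sizes = matrix.library_sizes()
    reps = tuple(matrix.replicates())
    rows = []
    for rep in reps:
        n_ip = sizes.get(("IP", rep), 0)
        n_in = sizes.get(("input", rep), 0)
        if n_ip == 0 or n_in == 0:
            raise ValueError(f"replicate {rep}: empty IP or input library")
        b = 0.5 / min(n_ip, n_in) if beta is None else beta
        ip_rate = matrix.codon_vector(transcript_id, "IP", rep, record.protein_length) / n_ip
        in_rate = matrix.codon_vector(transcript_id, "input", rep, record.protein_length) / n_in
        rows.append(np.log2((ip_rate + b) / (in_rate + b)))
    return PositionalProfile(transcript_id, reps, np.vstack(rows))


def smooth_profile(values: np.ndarray, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Centred running mean with shrinking (truncated) windows at the edges."""
    arr = np.asarray(values, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    if window > 2 * len(arr):
        raise ValueError(f"window {window} too wide for profile of length {len(arr)}")
    if window == 1:
        return arr.copy()
    kernel = np.ones(window)
    sums = np.convolve(arr, kernel, mode="same")
    norms = np.convolve(np.ones_like(arr), kernel, mode="same")
    return sums / norms


def aggregate_replicates(e: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and range (max - min) per codon across replicate profiles."""
    arr = np.asarray(e, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("need a (replicates x codons) array with >= 1 replicate")
    return arr.mean(axis=0), arr.max(axis=0) - arr.min(axis=0)


def detect_onset(
    smoothed: np.ndarray,
    theta: float = DEFAULT_THETA,
    persistence: int = DEFAULT_PERSISTENCE,
    baseline_window: int = DEFAULT_BASELINE_WINDOW,
    min_effect: float = DEFAULT_MIN_EFFECT,
) -> OnsetResult:
    """Call the onset codon on a smoothed mean enrichment profile.

    baseline = mean of the first ``baseline_window`` codons; plateau =
    mean of the top decile of smoothed values; onset = first codon where
    the profile exceeds ``baseline + theta * (plateau - baseline)`` for at
    least ``persistence`` consecutive codons.  Profiles whose rise
    (plateau - baseline) is below ``min_effect`` return no onset.
    """
    arr = np.asarray(smoothed, dtype=float)
    if len(arr) < baseline_window + persistence:
        raise ValueError(
            f"profile length {len(arr)} shorter than baseline window "
            f"{baseline_window} + persistence {persistence}"
        )
    baseline = float(arr[:baseline_window].mean())
    n_top = max(1, int(np.ceil(len(arr) / 10)))
    plateau = float(np.sort(arr)[-n_top:].mean())
    threshold = baseline + theta * (plateau - baseline)
    if plateau - baseline < min_effect:
        return OnsetResult(None, baseline, plateau, threshold)
    above = arr > threshold
    if persistence > 1:
        window_all = (
            np.convolve(above.astype(int), np.ones(persistence, dtype=int), "valid")
            == persistence
        )
    else:
        window_all = above
    hits = np.nonzero(window_all)[0]
    if len(hits) == 0:
        return OnsetResult(None, baseline, plateau, threshold)
    return OnsetResult(int(hits[0]) + 1, baseline, plateau, threshold)


def map_chain_length_to_lumenal(
    chain_length: int,
    sp_end: int | None,
    buried_offset: int = DEFAULT_BURIED_OFFSET,
) -> tuple[int, int] | None:
    """Residues exposed to the lumen when the nascent chain is ``chain_length``
    residues long: ``(sp_end + 1, chain_length - buried_offset)``, or None
    when nothing mature has yet emerged."""
    if chain_length < 1:
        raise ValueError("chain length must be >= 1")
    if buried_offset < 0:
        raise ValueError("buried offset must be >= 0")
    start = (sp_end or 0) + 1
    end = chain_length - buried_offset
    if end < start:
        return None
    return (start, end)


def map_residue_to_chain_length(
    residue: int, buried_offset: int = DEFAULT_BURIED_OFFSET
) -> int:
    """Nascent-chain length at which ``residue`` has just cleared the buried
    segment: ``L = residue + buried_offset``."""
    if residue < 1:
        raise ValueError("residue index must be >= 1")
    return residue + buried_offset


def call_engagement(
    matrix: CodonCountMatrix,
    transcript_id: str,
    annotation: Mapping[str, TranscriptAnnotation],
    beta: float | None = None,
    window: int = DEFAULT_WINDOW,
    theta: float = DEFAULT_THETA,
    persistence: int = DEFAULT_PERSISTENCE,
    baseline_window: int = DEFAULT_BASELINE_WINDOW,
    min_effect: float = DEFAULT_MIN_EFFECT,
    buried_offset: int = DEFAULT_BURIED_OFFSET,
) -> EngagementCall:
    """Profile one transcript, detect the engagement onset and map it to the
    lumenal residue window exposed at onset."""
    record = annotation[transcript_id]
    profile = codon_enrichment(matrix, transcript_id, annotation, beta=beta)
    mean, _ = aggregate_replicates(profile.e)
    smoothed = smooth_profile(mean, window=window)
    result = detect_onset(
        smoothed,
        theta=theta,
        persistence=persistence,
        baseline_window=baseline_window,
        min_effect=min_effect,
    )
    if result.onset_codon is None:
        return EngagementCall(
            transcript_id, None, None, None, buried_offset, result.plateau
        )
    lumenal = map_chain_length_to_lumenal(
        result.onset_codon, record.sp_end, buried_offset
    )
    return EngagementCall(
        transcript_id=transcript_id,
        onset_codon=result.onset_codon,
        onset_chain_length_aa=result.onset_codon,
        lumenal_window=lumenal,
        buried_offset=buried_offset,
        plateau_level=result.plateau,
    )
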