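"""Synthetic topology-annotated transcriptomes and paired input/IP libraries.

The generator emulates a selective ribosome profiling experiment for a
translocon accessory factor.  Ribosome density is uniform along each CDS
(no pause sites); input libraries sample that occupancy directly, while
IP libraries are a thinning of occupancy with a capture probability that
is ``baseline_capture`` before a target's onset codon and
``baseline_capture * capture_fold`` (capped at 1) from the onset codon
onward — once recruited, the factor persists until termination.  Counts
are Poisson; an optional gamma-mixing knob adds negative-binomial
overdispersion.  Transcript abundance weights are log-normal, with one
designated GRP94-like transcript (803 residues, signal peptide 1-21)
pinned as the most abundant transcript when requested.

In ``raw_reads`` mode each A-site count is expanded into a footprint read
whose 5' end sits a read-length-specific offset upstream of the A-site
codon, so the offset-calibration and codon-assignment stages can be
exercised end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import Segment, TranscriptAnnotation
from .counts import CodonCountMatrix
from .footprints import READ_COLUMNS

logger = logging.getLogger(__name__)

GRP94_LIKE_ID = "GRP94L"
GRP94_LIKE_LENGTH = 803
GRP94_LIKE_SP_END = 21

# stream keys for the per-purpose RNG hierarchy
_STREAM_ANNOTATION = 0
_STREAM_ABUNDANCE = 1
_STREAM_COUNTS = 2
_STREAM_READS = 3


class SimulationError(ValueError):
    """Invalid simulation configuration or impossible record geometry."""


@dataclass(frozen=True)
class EngagementTarget:
    """A transcript on which the factor engages at ``onset_aa`` and stays
    bound until termination, boosting IP capture by ``capture_fold``."""

    selector: str  # transcript_id or gene_name
    onset_aa: int
    capture_fold: float

    def __post_init__(self) -> None:
        if self.capture_fold < 1:
            raise SimulationError("capture_fold must be >= 1")
        if self.onset_aa < 1:
            raise SimulationError("onset_aa must be >= 1")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated selective-profiling experiment."""

    n_transcripts: int = 300
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "secretory": 0.25,
            "membrane": 0.25,
            "cytosolic": 0.5,
        }
    )
    protein_length_range: tuple[int, int] = (120, 900)
    sp_length_range: tuple[int, int] = (15, 30)
    include_grp94_like: bool = True
    engagement_targets: list[EngagementTarget] = field(
        default_factory=lambda: [EngagementTarget(GRP94_LIKE_ID, 204, 4.0)]
    )
    baseline_capture: float = 0.2
    depth_input: int = 60_000
    depth_ip: int = 60_000
    n_replicates: int = 2
    read_mode: str = "counts"  # or "raw_reads"
    abundance_sigma: float = 1.0
    overdispersion: float | None = None  # NB dispersion; None = pure Poisson
    read_length_probs: dict[int, float] = field(
        default_factory=lambda: {28: 0.25, 29: 0.3, 30: 0.3, 31: 0.15}
    )
    asite_offsets: dict[int, int] = field(
        default_factory=lambda: {28: 11, 29: 12, 30: 12, 31: 13}
    )
    frame_error_rate: float = 0.0
    utr5_nt: int = 0
    utr3_nt: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        # normalize containers that may arrive from YAML as lists/str keys
        self.protein_length_range = tuple(self.protein_length_range)  # type: ignore[assignment]
        self.sp_length_range = tuple(self.sp_length_range)  # type: ignore[assignment]
        self.read_length_probs = {
            int(k): float(v) for k, v in self.read_length_probs.items()
        }
        self.asite_offsets = {int(k): int(v) for k, v in self.asite_offsets.items()}

    def validate(self) -> None:
        if self.n_transcripts < 1:
            raise SimulationError("n_transcripts must be >= 1")
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise SimulationError("class_fractions must sum to 1")
        unknown = set(self.class_fractions) - {"secretory", "membrane", "cytosolic"}
        if unknown:
            raise SimulationError(f"unknown transcript classes {sorted(unknown)}")
        lo, hi = self.protein_length_range
        if not (1 <= lo <= hi):
            raise SimulationError("invalid protein_length_range")
        sp_lo, sp_hi = self.sp_length_range
        if not (1 <= sp_lo <= sp_hi):
            raise SimulationError("invalid sp_length_range")
        if sp_hi + 10 >= lo:
            raise SimulationError(
                "sp_length_range too long for protein_length_range: need "
                "sp_max + 10 < protein_min to leave a mature region"
            )
        if not (0 < self.baseline_capture <= 1):
            raise SimulationError("baseline_capture must lie in (0, 1]")
        if self.read_mode not in ("counts", "raw_reads"):
            raise SimulationError(f"unknown read_mode {self.read_mode!r}")
        if self.n_replicates < 1:
            raise SimulationError("n_replicates must be >= 1")
        if abs(sum(self.read_length_probs.values()) - 1.0) > 1e-9:
            raise SimulationError("read_length_probs must sum to 1")
        if set(self.read_length_probs) - set(self.asite_offsets):
            raise SimulationError("every read length needs an A-site offset")


@dataclass
class SimulatedDataset:
    """Annotation, counts (and optionally raw reads), plus ground truth."""

    annotation: dict[str, TranscriptAnnotation]
    counts: CodonCountMatrix
    reads: pd.DataFrame | None
    truth: pd.DataFrame  # transcript_id, onset_aa, capture_fold
    abundance: pd.Series  # per-transcript weight
    config: SimulationConfig


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _class_counts(fractions: Mapping[str, float], n: int) -> dict[str, int]:
    # largest-remainder allocation, deterministic tie-break by class order
    order = ["secretory", "membrane", "cytosolic"]
    ideal = {c: fractions.get(c, 0.0) * n for c in order}
    base = {c: int(np.floor(v)) for c, v in ideal.items()}
    short = n - sum(base.values())
    remainders = sorted(order, key=lambda c: (-(ideal[c] - base[c]), order.index(c)))
    for c in remainders[:short]:
        base[c] += 1
    return base


def _secretory_record(
    rng: np.random.Generator, tid: str, gene: str, config: SimulationConfig
) -> TranscriptAnnotation:
    lo, hi = config.protein_length_range
    length = int(rng.integers(lo, hi + 1))
    sp_end = int(rng.integers(*config.sp_length_range, endpoint=True))
    segments = (
        Segment("SP", 1, sp_end),
        Segment("lumenal", sp_end + 1, length),
    )
    return TranscriptAnnotation(
        tid, gene, length, 3 * (length + 1), "secretory", sp_end, segments
    )


def _membrane_record(
    rng: np.random.Generator, tid: str, gene: str, config: SimulationConfig
) -> TranscriptAnnotation:
    lo, hi = config.protein_length_range
    length = int(rng.integers(lo, hi + 1))
    tm_len = 21
    pattern = ("lumenal", "TM", "cytosolic", "TM")
    segments: list[Segment] = []
    pos = 1
    i = 0
    has_tm = False
    while pos <= length:
        kind = pattern[i % 4]
        if kind == "TM":
            seg_len = tm_len
        elif kind == "lumenal":
            seg_len = int(rng.integers(30, 201))
        else:
            seg_len = int(rng.integers(10, 81))
        end = min(pos + seg_len - 1, length)
        if kind != "TM" and not has_tm:
            # leave room for at least one membrane span
            end = max(pos, min(end, length - tm_len))
        if kind == "TM" and end - pos + 1 < 15:
            # not enough room for a membrane span: extend the previous
            # segment to the C terminus instead
            last = segments.pop()
            segments.append(Segment(last.kind, last.start, length))
            pos = length + 1
            break
        segments.append(Segment(kind, pos, end))
        has_tm = has_tm or kind == "TM"
        pos = end + 1
        i += 1
    return TranscriptAnnotation(
        tid, gene, length, 3 * (length + 1), "membrane", None, tuple(segments)
    )


def _cytosolic_record(
    rng: np.random.Generator, tid: str, gene: str, config: SimulationConfig
) -> TranscriptAnnotation:
    lo, hi = config.protein_length_range
    length = int(rng.integers(lo, hi + 1))
    return TranscriptAnnotation(
        tid,
        gene,
        length,
        3 * (length + 1),
        "cytosolic",
        None,
        (Segment("cytosolic", 1, length),),
    )


def grp94_like_record() -> TranscriptAnnotation:
    """The designated GRP94-like transcript: 803 residues, SP 1-21, one
    lumenal segment spanning the mature protein (22-803)."""
    return TranscriptAnnotation(
        GRP94_LIKE_ID,
        GRP94_LIKE_ID,
        GRP94_LIKE_LENGTH,
        3 * (GRP94_LIKE_LENGTH + 1),
        "secretory",
        GRP94_LIKE_SP_END,
        (
            Segment("SP", 1, GRP94_LIKE_SP_END),
            Segment("lumenal", GRP94_LIKE_SP_END + 1, GRP94_LIKE_LENGTH),
        ),
    )


def simulate_annotation(config: SimulationConfig) -> dict[str, TranscriptAnnotation]:
    """Generate a topology-annotated transcriptome under ``config``."""
    config.validate()
    rng = _rng(config.seed, _STREAM_ANNOTATION)
    records: dict[str, TranscriptAnnotation] = {}
    n_random = config.n_transcripts - (1 if config.include_grp94_like else 0)
    if config.include_grp94_like:
        records[GRP94_LIKE_ID] = grp94_like_record()
    counts = _class_counts(config.class_fractions, n_random)
    labels = np.repeat(
        ["secretory", "membrane", "cytosolic"],
        [counts["secretory"], counts["membrane"], counts["cytosolic"]],
    )
    rng.shuffle(labels)
    makers = {
        "secretory": _secretory_record,
        "membrane": _membrane_record,
        "cytosolic": _cytosolic_record,
    }
    for i, label in enumerate(labels, start=1):
        tid = f"T{i:05d}"
        try:
            records[tid] = makers[label](rng, tid, f"G{i:05d}", config)
        except ValueError as exc:
            raise SimulationError(f"impossible geometry for {tid}: {exc}") from exc
    return records


def _resolve_targets(
    annotation: Mapping[str, TranscriptAnnotation],
    targets: Sequence[EngagementTarget],
) -> dict[str, EngagementTarget]:
    by_gene = {rec.gene_name: tid for tid, rec in annotation.items()}
    resolved: dict[str, EngagementTarget] = {}
    for target in targets:
        tid = target.selector if target.selector in annotation else by_gene.get(
            target.selector
        )
        if tid is None:
            raise SimulationError(
                f"engagement target {target.selector!r} matches no transcript"
            )
        if target.onset_aa >= annotation[tid].protein_length:
            raise SimulationError(
                f"target {tid}: onset {target.onset_aa} not below protein "
                f"length {annotation[tid].protein_length}"
            )
        resolved[tid] = target
    return resolved


def _abundance_weights(
    annotation: Mapping[str, TranscriptAnnotation], config: SimulationConfig
) -> pd.Series:
    rng = _rng(config.seed, _STREAM_ABUNDANCE)
    tids = list(annotation)
    weights = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=len(tids))
    series = pd.Series(weights, index=tids)
    if GRP94_LIKE_ID in series.index:
        # the GRP94-like message is pinned as the most abundant transcript
        series[GRP94_LIKE_ID] = 1.5 * series.max()
    return series


def _capture_profile(
    record: TranscriptAnnotation,
    target: EngagementTarget | None,
    baseline: float,
) -> np.ndarray:
    p = np.full(record.protein_length, baseline)
    if target is not None:
        boosted = baseline * target.capture_fold
        if boosted > 1:
            logger.warning(
                "%s: capture probability %.3f capped at 1", record.transcript_id, boosted
            )
            boosted = 1.0
        p[target.onset_aa - 1 :] = boosted
    return p


def simulate_libraries(
    annotation: Mapping[str, TranscriptAnnotation],
    config: SimulationConfig,
) -> SimulatedDataset:
    """Sample paired input/IP codon counts (and optionally raw reads).

    Input counts per codon are Poisson with mean proportional to the
    transcript's abundance weight, uniform along the CDS, normalized so a
    library's expected total equals its configured depth.  IP counts are a
    thinning of occupancy by the per-codon capture probability, likewise
    normalized to the IP depth, so engagement shows up as a relative,
    position-dependent capture gain rather than a change in library size.
    Each (sample, replicate) library uses its own derived RNG stream.
    """
    config.validate()
    targets = _resolve_targets(annotation, config.engagement_targets)
    weights = _abundance_weights(annotation, config)

    tids = list(annotation)
    lengths = np.array([annotation[t].protein_length for t in tids])
    w = weights[tids].to_numpy()
    capture = [
        _capture_profile(annotation[t], targets.get(t), config.baseline_capture)
        for t in tids
    ]

    input_norm = float((w * lengths).sum())
    ip_norm = float(sum(wi * ci.sum() for wi, ci in zip(w, capture)))

    frames = []
    read_frames = []
    for sample, depth in (("input", config.depth_input), ("IP", config.depth_ip)):
        for rep in range(1, config.n_replicates + 1):
            rng = _rng(config.seed, _STREAM_COUNTS, 0 if sample == "input" else 1, rep)
            for idx, tid in enumerate(tids):
                if sample == "input":
                    lam = np.full(lengths[idx], depth * w[idx] / input_norm)
                else:
                    lam = depth * w[idx] * capture[idx] / ip_norm
                if config.overdispersion:
                    shape = 1.0 / config.overdispersion
                    lam = lam * rng.gamma(shape, config.overdispersion, size=len(lam))
                counts = rng.poisson(lam)
                nz = np.nonzero(counts)[0]
                if len(nz) == 0:
                    continue
                frames.append(
                    pd.DataFrame(
                        {
                            "transcript_id": tid,
                            "codon": nz + 1,
                            "sample": sample,
                            "replicate": rep,
                            "count": counts[nz],
                        }
                    )
                )
    counts_df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["transcript_id", "codon", "sample", "replicate", "count"])
    )
    matrix = CodonCountMatrix(counts_df)

    reads = None
    if config.read_mode == "raw_reads":
        reads = _expand_to_reads(matrix, annotation, config)

    truth = pd.DataFrame(
        [
            (tid, target.onset_aa, target.capture_fold)
            for tid, target in targets.items()
        ],
        columns=["transcript_id", "onset_aa", "capture_fold"],
    )
    return SimulatedDataset(
        annotation=dict(annotation),
        counts=matrix,
        reads=reads,
        truth=truth,
        abundance=weights,
        config=config,
    )


def _expand_to_reads(
    matrix: CodonCountMatrix,
    annotation: Mapping[str, TranscriptAnnotation],
    config: SimulationConfig,
) -> pd.DataFrame:
    """Expand A-site counts into footprint reads with 5' ends offset
    upstream of the A-site codon; reads that would run outside the
    transcript (CDS plus configured UTRs) are dropped."""
    read_lengths = np.array(sorted(config.read_length_probs))
    probs = np.array([config.read_length_probs[l] for l in read_lengths])
    offsets = np.array([config.asite_offsets[l] for l in read_lengths])
    plen = {tid: rec.protein_length for tid, rec in annotation.items()}
    cds_len = {tid: rec.cds_length for tid, rec in annotation.items()}

    out = []
    for (sample, rep), lib in matrix.counts.groupby(["sample", "replicate"]):
        rng = _rng(
            config.seed, _STREAM_READS, 0 if sample == "input" else 1, int(rep)
        )
        codons = np.repeat(lib["codon"].to_numpy(), lib["count"].to_numpy())
        tid_arr = np.repeat(lib["transcript_id"].to_numpy(), lib["count"].to_numpy())
        n = len(codons)
        pick = rng.choice(len(read_lengths), size=n, p=probs)
        length_arr = read_lengths[pick]
        five_prime = config.utr5_nt + 3 * (codons - 1) - offsets[pick]
        if config.frame_error_rate > 0:
            err = rng.random(n) < config.frame_error_rate
            shift = rng.choice([-1, 1], size=n)
            five_prime = five_prime + err * shift
        bound = np.array([config.utr5_nt + cds_len[t] + config.utr3_nt for t in tid_arr])
        keep = (five_prime >= 0) & (five_prime + length_arr <= bound)
        dropped = int(np.count_nonzero(~keep))
        if dropped:
            logger.info(
                "%s rep %s: dropped %d reads outside transcript bounds",
                sample,
                rep,
                dropped,
            )
        out.append(
            pd.DataFrame(
                {
                    "transcript_id": tid_arr[keep],
                    "five_prime": five_prime[keep],
                    "length": length_arr[keep],
                    "sample": sample,
                    "replicate": int(rep),
                }
            )
        )
    if not out:
        return pd.DataFrame(columns=READ_COLUMNS)
    return pd.concat(out, ignore_index=True)[READ_COLUMNS]


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Convenience wrapper: annotation then libraries under one config."""
    annotation = simulate_annotation(config)
    return simulate_libraries(annotation, config)
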