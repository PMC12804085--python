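from __future__ import annotations

import pytest
from hypothesis import settings

from riboselect import (
    Segment,
    SimulationConfig,
    TranscriptAnnotation,
    simulate,
)
from riboselect.simulate import grp94_like_record

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tiny_annotation() -> dict[str, TranscriptAnnotation]:
    """Three hand-built transcripts: one GRP94-like secretory, one
    multi-spanning membrane protein, one cytosolic protein."""
    grp94 = grp94_like_record()
    membrane = TranscriptAnnotation(
        "TMEM1",
        "TMEM1",
        300,
        3 * 301,
        "membrane",
        None,
        (
            Segment("lumenal", 22, 105),
            Segment("TM", 106, 126),
            Segment("cytosolic", 127, 178),
            Segment("TM", 179, 199),
            Segment("lumenal", 200, 229),
            Segment("TM", 230, 250),
            Segment("cytosolic", 251, 300),
        ),
    )
    cyto = TranscriptAnnotation(
        "CYTO1",
        "CYTO1",
        250,
        3 * 251,
        "cytosolic",
        None,
        (Segment("cytosolic", 1, 250),),
    )
    return {r.transcript_id: r for r in (grp94, membrane, cyto)}


@pytest.fixture(scope="session")
def small_dataset():
    """One deeply sequenced simulated experiment with the GRP94-like
    engagement target (onset 204, fold 4); shared across tests."""
    config = SimulationConfig(
        n_transcripts=80,
        depth_input=40_000,
        depth_ip=40_000,
        seed=11,
    )
    return simulate(config)
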