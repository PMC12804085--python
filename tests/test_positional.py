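from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from riboselect import (
    CodonCountMatrix,
    aggregate_replicates,
    call_engagement,
    codon_enrichment,
    detect_onset,
    map_chain_length_to_lumenal,
    map_residue_to_chain_length,
    smooth_profile,
)
from riboselect.simulate import GRP94_LIKE_ID


def _matrix_from_vectors(tid, ip, inp, filler=1000):
    """Counts for one 'filler' transcript plus per-codon vectors on tid;
    the filler sets the remaining library mass (one int, or a separate
    (IP, input) pair to pin the two library sizes independently)."""
    filler_ip, filler_in = (filler, filler) if isinstance(filler, int) else filler
    rows = [(f"{tid}_filler", 1, "input", 1, filler_in), (f"{tid}_filler", 1, "IP", 1, filler_ip)]
    rows += [(tid, c + 1, "IP", 1, int(n)) for c, n in enumerate(ip) if n]
    rows += [(tid, c + 1, "input", 1, int(n)) for c, n in enumerate(inp) if n]
    return CodonCountMatrix(
        pd.DataFrame(rows, columns=["transcript_id", "codon", "sample", "replicate", "count"])
    )


def _annotation_for(tid, length):
    from riboselect import Segment, TranscriptAnnotation

    return {
        tid: TranscriptAnnotation(
            tid, tid, length, 3 * (length + 1), "cytosolic", None,
            (Segment("cytosolic", 1, length),),
        ),
        f"{tid}_filler": TranscriptAnnotation(
            f"{tid}_filler", "F", 10, 33, "cytosolic", None,
            (Segment("cytosolic", 1, 10),),
        ),
    }


class TestCodonEnrichment:
    def test_matched_rates_give_zero(self):
        ip = np.full(20, 4)
        matrix = _matrix_from_vectors("X", ip, ip)
        profile = codon_enrichment(matrix, "X", _annotation_for("X", 20))
        assert np.allclose(profile.e, 0.0)

    def test_fourfold_rate_gives_two_log_units(self):
        # equal library sizes (9000 each) so per-read rates differ 4-fold
        matrix = _matrix_from_vectors(
            "X", np.full(20, 400), np.full(20, 100), filler=(1000, 7000)
        )
        profile = codon_enrichment(matrix, "X", _annotation_for("X", 20), beta=1e-12)
        assert np.allclose(profile.e, 2.0, atol=1e-6)

    def test_library_scale_invariance(self):
        # scaling both libraries jointly leaves every per-read rate, and
        # hence the profile at a given rate pseudocount, unchanged
        ip = np.array([3, 0, 9, 2, 5] * 4)
        inp = np.array([1, 2, 0, 4, 5] * 4)
        ann = _annotation_for("X", 20)
        beta = 1e-3
        base = codon_enrichment(_matrix_from_vectors("X", ip, inp), "X", ann, beta=beta)
        scaled = codon_enrichment(
            _matrix_from_vectors("X", 10 * ip, 10 * inp, filler=10_000),
            "X",
            ann,
            beta=beta,
        )
        assert np.allclose(base.e, scaled.e)

    def test_absent_transcript_rejected(self):
        matrix = _matrix_from_vectors("X", np.ones(5), np.ones(5))
        with pytest.raises(ValueError, match="absent"):
            codon_enrichment(matrix, "Y", _annotation_for("X", 5) | _annotation_for("Y", 5))


class TestSmoothing:
    def test_window_one_is_identity(self):
        values = np.array([1.0, -2.0, 3.5, 0.0])
        assert np.array_equal(smooth_profile(values, 1), values)

    def test_constant_profile_unchanged(self):
        assert np.allclose(smooth_profile(np.full(50, 1.7), 15), 1.7)

    def test_step_matches_brute_force_window_mean(self):
        profile = np.where(np.arange(200) >= 99, 2.0, 0.0)
        smoothed = smooth_profile(profile, 15)
        for c in range(200):
            window = profile[max(0, c - 7) : min(200, c + 8)]
            assert smoothed[c] == pytest.approx(window.mean())

    def test_even_or_huge_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_profile(np.zeros(10), 4)
        with pytest.raises(ValueError):
            smooth_profile(np.zeros(10), 21)


class TestAggregation:
    def test_mean_and_range(self):
        mean, rng_ = aggregate_replicates(np.array([[1.0, 5.0], [3.0, 5.0]]))
        assert list(mean) == [2.0, 5.0]
        assert list(rng_) == [2.0, 0.0]

    def test_single_replicate_range_zero(self):
        mean, rng_ = aggregate_replicates(np.array([[1.0, 2.0]]))
        assert list(mean) == [1.0, 2.0]
        assert list(rng_) == [0.0, 0.0]

    def test_replicate_order_irrelevant(self):
        e = np.array([[1.0, 2.0, 0.5], [0.0, 3.0, 0.5]])
        forward = aggregate_replicates(e)
        backward = aggregate_replicates(e[::-1])
        assert np.array_equal(forward[0], backward[0])
        assert np.array_equal(forward[1], backward[1])


class TestOnsetDetection:
    def test_flat_profile_has_no_onset(self):
        assert detect_onset(np.zeros(400)).onset_codon is None

    def test_ideal_step_detected_at_step(self):
        profile = np.where(np.arange(1, 501) >= 204, 2.0, 0.0)
        result = detect_onset(profile)
        assert result.onset_codon == 204

    def test_constant_shift_invariance(self):
        profile = np.where(np.arange(1, 501) >= 204, 2.0, 0.0)
        shifted = detect_onset(profile + 5.0)
        assert shifted.onset_codon == detect_onset(profile).onset_codon

    def test_small_effect_returns_absent(self):
        profile = np.where(np.arange(1, 501) >= 204, 0.3, 0.0)
        assert detect_onset(profile).onset_codon is None

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            detect_onset(np.zeros(30))


class TestCoordinateMaps:
    @pytest.mark.parametrize(
        "chain_length, expected",
        [(161, (22, 106)), (204, (22, 149)), (76, None), (77, (22, 22))],
    )
    def test_lumenal_window_for_nascent_chain(self, chain_length, expected):
        assert map_chain_length_to_lumenal(chain_length, sp_end=21) == expected

    @pytest.mark.parametrize("residue, expected", [(106, 161), (149, 204), (22, 77)])
    def test_chain_length_for_cleared_residue(self, residue, expected):
        assert map_residue_to_chain_length(residue) == expected

    @given(
        st.integers(min_value=22, max_value=2000),
        st.integers(min_value=0, max_value=120),
    )
    def test_maps_are_inverse_on_window_end(self, residue, delta):
        length = map_residue_to_chain_length(residue, delta)
        window = map_chain_length_to_lumenal(length, sp_end=21, buried_offset=delta)
        assert window is not None and window[1] == residue
        assert window[0] == 22

    def test_no_signal_peptide_starts_at_residue_one(self):
        assert map_chain_length_to_lumenal(100, sp_end=None) == (1, 45)


def test_engagement_call_on_simulated_target(small_dataset):
    call = call_engagement(small_dataset.counts, GRP94_LIKE_ID, small_dataset.annotation)
    truth = int(small_dataset.truth.loc[0, "onset_aa"])
    assert call.onset_codon is not None
    assert abs(call.onset_codon - truth) <= 15
    assert call.lumenal_window is not None
    assert call.lumenal_window[0] == 22
    assert call.lumenal_window[1] == call.onset_chain_length_aa - 55
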