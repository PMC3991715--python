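"""Tract scanning, sparsity splitting, threshold derivation, QC, calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lohtrack import (
    CallerParams,
    CNVSegment,
    Genotype,
    TransitionType,
    call_patient,
    classify_transitions,
    derive_gap_threshold,
    qc_filter,
    scan_tracts,
    split_sparse,
    stratify_by_cnv,
)
from lohtrack.calling import LOHTract

from util import make_table, oracle_scan, random_paired_vectors, relabel_alleles

G = Genotype
T = TransitionType


def scan_from_codes(positions, germ, tiss, min_events):
    tr = classify_transitions(
        np.array(germ, dtype=np.uint8), np.array(tiss, dtype=np.uint8)
    )
    return scan_tracts(np.array(positions), tr, min_events)


class TestScanTracts:
    def test_hom_to_hom_does_not_interrupt(self):
        # events at 100 and 300 separated by an uninformative HOM->HOM locus
        tracts = scan_from_codes(
            [100, 200, 300], [G.AB, G.AA, G.AB], [G.AA, G.AA, G.BB], min_events=2
        )
        assert [(t.start, t.end, t.n_events, t.length) for t in tracts] == [
            (100, 300, 2, 201)
        ]

    def test_het_to_het_terminates(self):
        args = ([100, 200, 300], [G.AB, G.AB, G.AB], [G.AA, G.AB, G.BB])
        assert scan_from_codes(*args, min_events=2) == []
        loose = scan_from_codes(*args, min_events=1)
        assert [(t.start, t.end, t.length) for t in loose] == [
            (100, 100, 1),
            (300, 300, 1),
        ]

    def test_single_event_has_length_one(self):
        tracts = scan_from_codes([5000], [G.AB], [G.AA], min_events=1)
        assert len(tracts) == 1 and tracts[0].length == 1

    @pytest.mark.parametrize(
        "interior,breaks",
        [
            (T.HOM_TO_HOM, False),
            (T.MONOALLELIC_MUTATION, False),
            (T.HOM_TO_UNK, False),
            (T.UNK_TO_HOM, False),
            (T.HET_TO_HET, True),
            (T.HET_TO_UNK, True),
            (T.UNK_TO_UNK, True),
            (T.UNK_TO_HET, True),
            (T.BIALLELIC_MUTATION, True),
        ],
    )
    def test_interior_transition_semantics(self, interior, breaks):
        """Terminators split an event run; uninformative loci do not."""
        tr = np.array([T.HET_TO_HOM, interior, T.HET_TO_HOM], dtype=np.uint8)
        tracts = scan_tracts(np.array([10, 20, 30]), tr, min_events=2)
        if breaks:
            assert tracts == []
        else:
            assert len(tracts) == 1 and (tracts[0].start, tracts[0].end) == (10, 30)

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError):
            scan_tracts(
                np.array([30, 10]),
                np.array([T.HET_TO_HOM, T.HET_TO_HOM], dtype=np.uint8),
                1,
            )

    @settings(max_examples=300)
    @given(st.integers(0, 2**32 - 1), st.sampled_from([1, 2]))
    def test_matches_bruteforce_oracle(self, seed, min_events):
        """Scanner output equals naive enumeration of maximal legal runs."""
        rng = np.random.default_rng(seed)
        positions, germ, tiss = random_paired_vectors(rng)
        tr = classify_transitions(germ, tiss)
        got = [
            (t.start, t.end, t.n_events)
            for t in scan_tracts(positions, tr, min_events)
        ]
        assert got == oracle_scan(positions, tr, min_events)

    @settings(max_examples=150)
    @given(st.integers(0, 2**32 - 1))
    def test_stringent_subset_of_loose(self, seed):
        rng = np.random.default_rng(seed)
        positions, germ, tiss = random_paired_vectors(rng)
        tr = classify_transitions(germ, tiss)
        loose = {(t.start, t.end) for t in scan_tracts(positions, tr, 1)}
        stringent = {(t.start, t.end) for t in scan_tracts(positions, tr, 2)}
        assert stringent <= loose

    @settings(max_examples=150)
    @given(st.integers(0, 2**32 - 1))
    def test_events_bounded_by_sample_total(self, seed):
        rng = np.random.default_rng(seed)
        positions, germ, tiss = random_paired_vectors(rng)
        tr = classify_transitions(germ, tiss)
        total = int(np.sum(tr == T.HET_TO_HOM))
        assert sum(t.n_events for t in scan_tracts(positions, tr, 1)) <= total


def _neutral_tract(event_positions, copy_state="neutral"):
    pos = np.array(event_positions)
    return LOHTract(
        chrom=1, arm="p", start=int(pos[0]), end=int(pos[-1]),
        n_events=len(pos), copy_state=copy_state, event_positions=pos,
    )


class TestSplitSparse:
    def test_wide_gap_splits_and_refilters(self):
        params = CallerParams(min_events=2)
        out = split_sparse([_neutral_tract([10_000, 60_000])], params)
        assert out == []  # both fragments have a single event
        loose = split_sparse(
            [_neutral_tract([10_000, 60_000])], CallerParams(min_events=1)
        )
        assert [(t.start, t.end) for t in loose] == [(10_000, 10_000), (60_000, 60_000)]

    def test_gap_of_exactly_threshold_not_split(self):
        out = split_sparse(
            [_neutral_tract([10_000, 50_000])], CallerParams(min_events=2)
        )
        assert [(t.start, t.end) for t in out] == [(10_000, 50_000)]

    def test_non_neutral_tracts_unchanged(self):
        t = _neutral_tract([10_000, 60_000], copy_state="loss")
        out = split_sparse([t], CallerParams(min_events=2))
        assert [(x.start, x.end) for x in out] == [(10_000, 60_000)]

    @settings(max_examples=100)
    @given(st.integers(0, 2**32 - 1))
    def test_split_never_lengthens_or_adds_events(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 30))
        pos = np.sort(rng.choice(np.arange(1, 500_000), size=n, replace=False))
        t = _neutral_tract(pos)
        out = split_sparse([t], CallerParams(min_events=1))
        assert all(f.length <= t.length for f in out)
        assert sum(f.n_events for f in out) <= t.n_events
        assert all(f.start >= t.start and f.end <= t.end for f in out)


class TestGapThreshold:
    def test_interpolated_quantile_fence(self):
        distances = list(range(0, 101, 10))  # Q1=25, Q3=75, IQR=50
        assert derive_gap_threshold(distances) == pytest.approx(225.0)

    def test_constant_spacings_give_fence_at_value(self):
        assert derive_gap_threshold([7, 7, 7, 7, 7]) == pytest.approx(7.0)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            derive_gap_threshold([1, 2, 3])


class TestStratifyByCNV:
    positions = np.arange(1, 11) * 1_000  # 1k..10k

    def test_no_segments_single_neutral_block(self):
        blocks = stratify_by_cnv(self.positions, 1, [], CallerParams())
        assert len(blocks) == 1
        state, idx = blocks[0]
        assert state == "neutral" and len(idx) == 10

    def test_interior_loss_segment_makes_three_blocks(self):
        segs = [CNVSegment(1, 5_000, 8_000, "loss", "Td")]
        blocks = stratify_by_cnv(self.positions, 1, segs, CallerParams(), sample="Td")
        assert [(s, len(i)) for s, i in blocks] == [
            ("neutral", 4), ("loss", 4), ("neutral", 2)
        ]

    def test_short_segment_dropped_by_min_length(self):
        segs = [CNVSegment(1, 5_000, 5_050, "loss", "Td")]
        params = CallerParams(cnv_min_length_bp=100_000)
        blocks = stratify_by_cnv(self.positions, 1, segs, params, sample="Td")
        assert [(s, len(i)) for s, i in blocks] == [("neutral", 10)]

    def test_overlapping_segments_rejected(self):
        segs = [
            CNVSegment(1, 1_000, 5_000, "loss", "Td"),
            CNVSegment(1, 4_000, 9_000, "gain", "Td"),
        ]
        with pytest.raises(ValueError, match="overlapping"):
            stratify_by_cnv(self.positions, 1, segs, CallerParams(), sample="Td")


def _qc_case(n_mono):
    """10 span loci: events at both ends, n_mono monoallelic interior loci."""
    positions = np.arange(1, 11) * 100
    germ = [G.AB] + [G.AA] * 8 + [G.AB]
    tiss = [G.AA] + [G.AB] * n_mono + [G.AA] * (8 - n_mono) + [G.BB]
    tr = classify_transitions(
        np.array(germ, dtype=np.uint8), np.array(tiss, dtype=np.uint8)
    )
    tracts = scan_tracts(positions, tr, 2)
    assert len(tracts) == 1
    return tracts[0], positions, tr, np.array(germ, np.uint8), np.array(tiss, np.uint8)


class TestQCFilter:
    def test_thirty_percent_monoallelic_dropped(self):
        t, *ctx = _qc_case(3)
        keep, scored = qc_filter(t, *ctx, CallerParams())
        assert not keep and scored.qc_monoallelic == pytest.approx(0.3)

    def test_twenty_percent_exactly_kept(self):
        t, *ctx = _qc_case(2)
        keep, scored = qc_filter(t, *ctx, CallerParams())
        assert keep and scored.qc_monoallelic == pytest.approx(0.2)

    def test_tissue_nocall_over_bound_dropped(self):
        positions = np.arange(1, 13) * 100
        germ = np.array([G.AB] + [G.AA] * 10 + [G.AB], dtype=np.uint8)
        tiss = np.array(
            [G.AA] + [G.NOCALL] * 3 + [G.AA] * 7 + [G.BB], dtype=np.uint8
        )
        tr = classify_transitions(germ, tiss)
        (t,) = scan_tracts(positions, tr, 2)
        keep, scored = qc_filter(t, positions, tr, germ, tiss, CallerParams())
        assert not keep
        assert scored.qc_nocall_tissue == pytest.approx(0.25)
        assert scored.qc_nocall_germline == 0.0

    def test_decision_invariant_to_allele_relabeling(self):
        t, positions, tr, germ, tiss = _qc_case(3)
        keep1, _ = qc_filter(t, positions, tr, germ, tiss, CallerParams())
        germ2, tiss2 = relabel_alleles(germ), relabel_alleles(tiss)
        tr2 = classify_transitions(germ2, tiss2)
        (t2,) = scan_tracts(positions, tr2, 2)
        keep2, _ = qc_filter(t2, positions, tr2, germ2, tiss2, CallerParams())
        assert keep1 == keep2


class TestCallPatient:
    def test_no_informative_loci_gives_empty_set(self, toy_annotation):
        table = make_table([10, 20, 30], [G.AA] * 3, [G.AA, G.BB, G.AB])
        out = call_patient(table, "Td", toy_annotation)
        assert len(out) == 0

    def test_cnv_state_inherited_from_segment(self, toy_annotation):
        # two events inside a loss segment, two in a neutral region
        positions = [1_000, 2_000, 20_000, 21_000]
        germ = [G.AB] * 4
        tiss = [G.AA] * 4
        table = make_table(positions, germ, tiss)
        cnv = [CNVSegment(1, 500, 2_500, "loss", "Td")]
        out = call_patient(table, "Td", toy_annotation, cnv, CallerParams())
        states = {(t.start, t.end): t.copy_state for t in out}
        assert states == {(1_000, 2_000): "loss", (20_000, 21_000): "neutral"}

    def test_arm_boundary_respected(self, toy_annotation):
        # events on p and q arms never join into one tract
        positions = [49_000, 49_500, 61_000, 61_500]
        table = make_table(positions, [G.AB] * 4, [G.AA] * 4)
        out = call_patient(table, "Td", toy_annotation)
        assert [(t.arm_name, t.start, t.end) for t in out] == [
            ("1p", 49_000, 49_500),
            ("1q", 61_000, 61_500),
        ]
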