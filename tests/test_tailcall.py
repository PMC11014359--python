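"""Tail anchoring, four-class classification, censored length estimation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from racetails.references import ReferenceAmplicon
from racetails.seq import revcomp
from racetails.tailcall import (
    TailCallParams,
    TailInputError,
    TailView,
    anchor_templated_end,
    call_pairs,
    classify_tail,
    estimate_length,
)
from tests.conftest import simulate_parsed


class TestClassifyTail:
    @pytest.mark.parametrize(
        "nta, expected",
        [
            ("", ("NONE", 0, 0)),  # 3' ends lacking any NTA
            ("AAAAAAA", ("A", 7, 0)),  # pure adenosine run
            ("AAATT", ("AU", 3, 2)),  # A-run appended with uridines (T==U)
            ("AAAUU", ("AU", 3, 2)),  # U spelled as RNA
            ("TT", ("U", 0, 2)),  # pure uridine run
            ("AAGAA", ("OTHER", 0, 0)),  # fails the A+U+ pattern strictly
            ("TTAA", ("OTHER", 0, 0)),  # U before A is not an AU tail
        ],
    )
    def test_strict_patterns(self, nta, expected):
        assert classify_tail(nta, tolerance=0) == expected

    def test_tolerance_corrects_one_isolated_error_in_long_tail(self):
        noisy = "AAAAAGAAAAAA"  # 12 nt, one isolated G
        assert classify_tail(noisy, tolerance=0) == ("OTHER", 0, 0)
        assert classify_tail(noisy, tolerance=1) == ("A", 12, 0)

    def test_tolerance_leaves_short_tails_strict(self):
        assert classify_tail("AAGAA", tolerance=1) == ("OTHER", 0, 0)

    def test_invalid_characters_raise(self):
        with pytest.raises(TailInputError):
            classify_tail("AAXAA")


class TestEstimateLength:
    def test_complete_r2_view_is_exact(self):
        out = estimate_length(TailView("A" * 12, True), None, window=80)
        assert out == ("A", 12, 0, False)

    def test_agreeing_views_report_shared_length(self):
        out = estimate_length(
            TailView("A" * 40, True), TailView("A" * 40, True), window=80
        )
        assert out == ("A", 40, 0, False)

    def test_truncated_views_censor_at_window(self):
        # true tail 90 nt, neither read spans: only an 81-nt suffix visible
        out = estimate_length(TailView("A" * 81, False), None, window=80)
        assert out == ("A", 80, 0, True)

    def test_fully_observed_tail_beyond_window_is_capped_and_censored(self):
        out = estimate_length(TailView("A" * 90 + "TT", True), None, window=80)
        assert out == ("AU", 78, 2, True)

    def test_censored_au_tail_keeps_class_from_terminal_bases(self):
        out = estimate_length(TailView("A" * 78 + "TTT", False), None, window=80)
        assert out == ("AU", 77, 3, True)

    def test_r1_only_complete_view_used_when_r2_truncated(self):
        out = estimate_length(
            TailView("A" * 75, False), TailView("A" * 75, True), window=80
        )
        assert out == ("A", 75, 0, False)

    def test_no_evidence_is_rejected(self):
        assert estimate_length(None, None, window=80) == "no_tail_evidence"

    @given(
        a=st.integers(0, 120),
        u=st.integers(0, 10),
        window=st.integers(20, 120),
    )
    @settings(max_examples=300, deadline=None)
    def test_total_never_exceeds_window_and_censored_pins_total(self, a, u, window):
        out = estimate_length(TailView("A" * a + "T" * u, True), None, window)
        assert not isinstance(out, str)
        cls, a_len, u_len, censored = out
        assert 0 <= a_len + u_len <= window
        if censored:
            assert a_len + u_len == window

    def test_window_monotonicity(self):
        """Raising the window never shrinks a reported total length."""
        seq = "A" * 95 + "TT"
        totals = []
        for window in (40, 60, 80, 100, 120):
            cls, a_len, u_len, _ = estimate_length(TailView(seq, True), None, window)
            totals.append(a_len + u_len)
        assert totals == sorted(totals)


@pytest.fixture
def simple_ref():
    # 60-nt reference ending ...GAA to exercise the greedy templated rule
    seq = "CCGTATGGTCAACGTTCGACCTGATTCGGCATGTTACCAGCGGATCTTGCAATCGTTGAA"
    return ReferenceAmplicon(name="ref", sequence=seq, primer_offset=0)


class TestAnchoring:
    def test_exact_suffix_plus_pure_tail(self, simple_ref):
        tail_facing = simple_ref.sequence[-30:] + "AAAAA"
        out = anchor_templated_end(
            simple_ref.sequence[:40], tail_facing, simple_ref
        )
        anchor, r2_view, _ = out
        assert anchor == simple_ref.terminus
        assert r2_view == TailView("AAAAA", True)

    def test_terminal_reference_As_are_templated(self, simple_ref):
        # reference ends ...GAA; a read ending ...GAAAA has only "AA" of tail
        tail_facing = simple_ref.sequence[-30:] + "AA"
        _, r2_view, _ = anchor_templated_end(
            simple_ref.sequence[:40], tail_facing, simple_ref
        )
        assert r2_view == TailView("AA", True)

    def test_one_mismatch_in_40nt_span_accepted(self, simple_ref):
        span = list(simple_ref.sequence[-40:])
        span[10] = "A" if span[10] != "A" else "C"
        tail_facing = "".join(span) + "AAAA"
        out = anchor_templated_end(
            simple_ref.sequence[:40], tail_facing, simple_ref,
            TailCallParams(max_mismatch_rate=0.05),
        )
        assert not isinstance(out, str)
        _, r2_view, _ = out
        assert r2_view == TailView("AAAA", True)

    def test_short_segment_rejected(self, simple_ref):
        out = anchor_templated_end("ACGT", "ACGT", simple_ref)
        assert out == "short_anchor"

    def test_unrelated_sequence_rejected(self, simple_ref):
        junk = "GGCCGGCCGGCCGGCCGGCCGGCCGGCC"
        out = anchor_templated_end(junk, junk, simple_ref)
        assert out == "unanchored"


class TestEndToEndRecovery:
    def test_zero_error_spanning_reads_recover_ground_truth_exactly(self, refs):
        """With no sequencing error and tails inside the window, every
        molecule's (class, a_len, u_len) is recovered exactly."""
        mols, parsed = simulate_parsed(
            refs, 600, seed=31,
            error_rate=0.0,
            a_len_dist={"name": "uniform", "low": 1, "high": 70},
            u_len_dist={"name": "uniform", "low": 1, "high": 8},
            copy_dist={"name": "fixed", "k": 1},
        )
        calls, fates = call_pairs(parsed, refs)
        assert fates == {"called": len(mols)}
        by_umi = {m.umi: m for m in mols}
        for c in calls:
            m = by_umi[c.umi]
            assert (c.tail_class, c.a_len, c.u_len) == (
                m.true_class, m.a_len, m.u_len,
            )
            assert not c.censored

    def test_long_tails_censored_in_top_category(self, refs):
        mols, parsed = simulate_parsed(
            refs, 300, seed=32,
            error_rate=0.0,
            class_probs={"A": 0.6, "AU": 0.4, "U": 0.0, "NONE": 0.0},
            a_len_dist={"name": "uniform", "low": 81, "high": 120},
            u_len_dist={"name": "uniform", "low": 1, "high": 6},
            copy_dist={"name": "fixed", "k": 1},
        )
        calls, _ = call_pairs(parsed, refs)
        assert len(calls) == len(mols)
        by_umi = {m.umi: m for m in mols}
        for c in calls:
            assert c.censored and c.total_len == 80
            if by_umi[c.umi].true_class == "AU":
                assert c.tail_class == "AU"

    def test_subfamily_recovered_at_zero_error(self, refs, diagnostics):
        mols, parsed = simulate_parsed(
            refs, 400, seed=33, diagnostics=diagnostics,
            error_rate=0.0,
            copy_dist={"name": "fixed", "k": 1},
        )
        calls, _ = call_pairs(parsed, refs, diagnostics=diagnostics)
        by_umi = {m.umi: m for m in mols}
        l1_calls = [c for c in calls if c.reference == "L1_consensus"]
        assert l1_calls
        for c in l1_calls:
            assert c.subfamily == by_umi[c.umi].subfamily
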