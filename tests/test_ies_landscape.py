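import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ieslandscape import ies_landscape as il
from ieslandscape.io_formats import Contig, Genome, IesRecord, revcomp

BASES = "ACGT"


def make_context(left, ies_seq, right, ies_id="i1", mac_point=None):
    mp = len(left) if mac_point is None else mac_point
    return il.IesContext(IesRecord(ies_id, "c1", mp, ies_seq), left, right)


dna = st.text(alphabet=BASES, min_size=0, max_size=40)
dna1 = st.text(alphabet=BASES, min_size=1, max_size=40)


# ---------------------------------------------------------------------------
# filter / context
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "length,score,kept,reason_part",
    [
        (40, 0.5, False, "length"),
        (200, 0.05, False, "retention_score"),
        (200, None, True, None),
        (50, 0.075, True, None),
    ],
)
def test_filter_removes_short_or_low_score(length, score, kept, reason_part):
    rec = IesRecord("x", "c1", 0, "A" * length, score)
    kept_recs, removed = il.filter_ies([rec])
    assert (rec in kept_recs) == kept
    if not kept:
        assert reason_part in removed[0][1]


def test_extract_context_flanks_and_clipping():
    genome = Genome([Contig("c1", "".join(BASES[i % 4] for i in range(100)))])
    rec = IesRecord("i", "c1", 10, "TTTT")
    ctx = il.extract_context(genome, rec, flank_len=5)
    assert ctx.left_flank == genome["c1"].seq[5:10]
    assert ctx.right_flank == genome["c1"].seq[10:15]
    assert not ctx.left_truncated and not ctx.right_truncated

    ctx = il.extract_context(genome, IesRecord("i", "c1", 2, "TT"), flank_len=5)
    assert len(ctx.left_flank) == 2 and ctx.left_truncated

    ctx = il.extract_context(genome, IesRecord("i", "c1", 100, "TT"), flank_len=5)
    assert ctx.right_flank == "" and ctx.right_truncated

    with pytest.raises(ValueError, match="unknown contig"):
        il.extract_context(genome, IesRecord("i", "nope", 0, "TT"))


# ---------------------------------------------------------------------------
# normalize_left
# ---------------------------------------------------------------------------


class TestNormalizeLeft:
    def test_hand_rotation(self):
        shift, ctx = il.normalize_left(make_context("GGA", "CGTA", "CGTT"))
        assert shift == 1
        assert ctx.ies.seq == "ACGT"
        assert ctx.left_flank == "GG" and ctx.right_flank == "ACGTT"
        assert ctx.ies.mac_point == 2

    def test_no_match_no_shift(self):
        shift, ctx = il.normalize_left(make_context("GGC", "CGTA", "CGTT"))
        assert shift == 0 and ctx.ies.seq == "CGTA"

    @given(left=dna, ies=dna1, right=dna)
    def test_idempotent_and_mac_product_preserved(self, left, ies, right):
        ctx = make_context(left, ies, right, mac_point=len(left))
        s1, n1 = il.normalize_left(ctx)
        s2, n2 = il.normalize_left(n1)
        assert s2 == 0 and n2.ies.seq == n1.ies.seq
        # the excision product (left + right flank) never changes
        assert n1.left_flank + n1.right_flank == left + right
        # the hybrid local sequence never changes either
        assert (
            n1.left_flank + n1.ies.seq + n1.right_flank == left + ies + right
        )


# ---------------------------------------------------------------------------
# find_tdr / find_tir
# ---------------------------------------------------------------------------


def brute_tdr(ies_seq, right, max_tdr=None):
    limit = min(len(ies_seq), len(right))
    if max_tdr is not None:
        limit = min(limit, max_tdr)
    return max(
        (j for j in range(limit + 1) if ies_seq[:j] == right[:j]), default=0
    )


def brute_tir(element, cap):
    n = len(element)
    limit = n // 2 if cap is None else min(cap, n // 2)
    best = 0
    for i in range(limit + 1):
        if element[:i] == revcomp(element[n - i :]) if i else True:
            best = i
        else:
            break
    return best


class TestFindTdr:
    @pytest.mark.parametrize(
        "ies,right,k,klass",
        [
            ("TACGG", "TAGCC", 2, "TA_TDR"),
            ("GGGCA", "GGGAT", 3, "OTHER_TDR"),
            ("CATTA", "GATTA", 0, "NONE"),
            ("TCCCC", "TGGGG", 1, "NONE"),  # below min_tdr
        ],
    )
    def test_examples(self, ies, right, k, klass):
        res = il.find_tdr(make_context("GGC", ies, right))
        assert (res.k, res.klass) == (k, klass)
        assert res.tdr_seq == ies[:k]

    def test_ta_offset_is_leftmost(self):
        res = il.find_tdr(make_context("GGC", "GTATAC", "GTATAG"))
        assert res.klass == "TA_TDR" and res.ta_offset == 1

    @given(ies=dna1, right=dna)
    def test_matches_brute_force(self, ies, right):
        res = il.find_tdr(make_context("", ies, right, mac_point=0))
        assert res.k == brute_tdr(ies, right)


class TestFindTir:
    def test_hand_example(self):
        res = il.find_tir("TACCGAAACGG", 2)
        assert res.tir_len == 3 and res.arm_seq == "CCG"

    def test_immediate_mismatch(self):
        assert il.find_tir("AAAAAAAA", 0).tir_len == 0  # A vs T at i=0

    def test_cap_behavior(self):
        half = "".join(BASES[i % 4] for i in range(30))
        palindrome = half + revcomp(half)  # 60 bp perfect palindrome
        res = il.find_tir(palindrome, 0, cap=25)
        assert res.tir_len == 25 and res.capped
        res = il.find_tir(palindrome, 0, cap=None)
        assert res.tir_len == 30 and not res.capped

    def test_empty_element(self):
        assert il.find_tir("TA", 2).tir_len == 0

    @given(element=dna1, cap=st.sampled_from([25, None]))
    def test_matches_brute_force(self, element, cap):
        assert il.find_tir(element, 0, cap=cap).tir_len == brute_tir(element, cap)


# ---------------------------------------------------------------------------
# null model
# ---------------------------------------------------------------------------


class TestNullModel:
    def test_uniform_expected_count(self):
        null = il.NullModel((0.25,) * 4)
        rows = il.expected_observed({2: 10}, null, 1000, "direct")
        L, obs, exp, ratio = rows[2]
        assert exp == pytest.approx(1000 * 0.0625 * 0.75)
        assert exp == pytest.approx(46.875)
        assert ratio == pytest.approx(10 / 46.875)

    def test_expected_sums_to_n(self):
        null = il.NullModel((0.33, 0.17, 0.17, 0.33))
        for mode in ("direct", "inverted"):
            rows = il.expected_observed({60: 0}, null, 5000, mode)
            total = sum(r[2] for r in rows)
            m = null.m_direct if mode == "direct" else null.m_inverted
            # geometric tail beyond L=60 is negligible
            assert total == pytest.approx(5000 * (1 - m**61), rel=1e-12)

    def test_degenerate_composition(self):
        null = il.NullModel((1.0, 0.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="degenerate"):
            il.expected_observed({0: 1}, null, 10, "direct")

    def test_estimated_from_sequences(self):
        null = il.NullModel.from_sequences(["AATT", "GC"])
        assert null.p == pytest.approx((2 / 6, 1 / 6, 1 / 6, 2 / 6))


# ---------------------------------------------------------------------------
# junction matrix
# ---------------------------------------------------------------------------


def _ta_pair(ctx):
    res = il.find_tdr(ctx)
    assert res.klass == "TA_TDR"
    return ctx, res


class TestJunctionMatrix:
    def test_column_sums_and_shape(self, rng):
        left = "".join(BASES[i] for i in rng.integers(0, 4, 30))
        core = "".join(BASES[i] for i in rng.integers(0, 4, 40))
        right = "TAG" + "".join(BASES[i] for i in rng.integers(0, 4, 27))
        ctx = make_context(left, "TA" + core + "C", right)
        ctx, res = _ta_pair(ctx)
        jm = il.junction_matrix([ctx], [res])
        assert jm.counts.shape == (24, 4)
        assert jm.n_junctions == 2 and jm.n_skipped == 0
        assert (jm.counts.sum(axis=1) == 2).all()

    def test_rejects_non_ta(self):
        ctx = make_context("GGC", "GGGCA", "GGGAT")
        res = il.find_tdr(ctx)
        with pytest.raises(ValueError, match="TA-bound"):
            il.junction_matrix([ctx], [res])

    def test_short_flank_skipped(self):
        ctx = make_context("GG", "TA" + "C" * 30, "TAG" + "G" * 30)
        ctx, res = _ta_pair(ctx)
        jm = il.junction_matrix([ctx], [res])
        assert jm.n_junctions == 1 and jm.n_skipped == 1

    def test_mirror_symmetry(self, rng):
        """Reverse-complementing the whole locus leaves the matrix unchanged
        (exact when the anchor TA occurs once in the TDR)."""
        contexts, results = [], []
        mirrored, mirrored_res = [], []
        for _ in range(50):
            motif = ["TA", "TAT"][rng.integers(0, 2)]
            left = "".join(BASES[i] for i in rng.integers(0, 4, 30))
            core = "".join(BASES[i] for i in rng.integers(0, 4, 40))
            right_rest = "".join(BASES[i] for i in rng.integers(0, 4, 27))
            ies = motif + core
            right = motif + ("C" if right_rest[:1] == "C" else "G") + right_rest
            # force exact TDR = motif and left-normalized form
            if ies[len(motif)] == right[len(motif)]:
                ies = motif + ("A" if right[len(motif)] != "A" else "C") + core[1:]
            if left[-1] == ies[-1]:
                left = left[:-1] + ("G" if ies[-1] != "G" else "C")
            ctx, res = _ta_pair(make_context(left, ies, right))
            contexts.append(ctx)
            results.append(res)
            # the mirrored locus: revcomp everything, flanks swap roles
            m_ctx = make_context(revcomp(right), revcomp(ies), revcomp(left))
            _, m_ctx = il.normalize_left(m_ctx)
            m_ctx, m_res = _ta_pair(m_ctx)
            mirrored.append(m_ctx)
            mirrored_res.append(m_res)
        jm = il.junction_matrix(contexts, results)
        jm_m = il.junction_matrix(mirrored, mirrored_res)
        assert (jm.counts == jm_m.counts).all()


# ---------------------------------------------------------------------------
# peaks, period, size classes
# ---------------------------------------------------------------------------


class TestLengthPeaks:
    def test_hand_example(self):
        peaks = il.call_length_peaks({63: 50, 64: 200, 65: 300, 66: 200, 67: 50})
        assert len(peaks) == 1
        p = peaks[0]
        assert (p.center, p.lo, p.hi, p.height) == (65, 64, 66, 300)

    def test_empty_histogram(self):
        assert il.call_length_peaks({60: 0, 61: 0}) == []

    def test_two_peaks_ascending(self):
        hist = {60: 500, 61: 10, 90: 10, 91: 700, 92: 10}
        centers = [p.center for p in il.call_length_peaks(hist)]
        assert centers == [60, 91]

    def test_plateau_resolves_leftmost(self):
        hist = {60: 10, 61: 300, 62: 300, 63: 10}
        (p,) = il.call_length_peaks(hist)
        assert p.center == 61

    def test_below_cutoff_ignored(self):
        assert il.call_length_peaks({60: 10, 61: 99, 62: 10}) == []

    def test_recovers_planted_gaussian_mixture(self, rng):
        centers = [65, 75, 85]
        hist: dict[int, int] = {}
        for c in centers:
            for v in np.round(rng.normal(c, 1.0, size=600)).astype(int):
                hist[v] = hist.get(v, 0) + 1
        called = il.call_length_peaks(hist, height_cutoff=100)
        got = sorted(p.center for p in called)
        assert len(got) == 3
        assert all(abs(g - c) <= 1 for g, c in zip(got, centers))


class TestPeriodAndClasses:
    def test_period_examples(self):
        assert il.estimate_period([60, 70, 81, 91], window=(50, 120)) == 10
        assert il.estimate_period([65, 75]) == 10
        with pytest.raises(ValueError, match="insufficient peaks"):
            il.estimate_period([65])

    def test_size_class_assignment(self):
        peaks = [
            il.LengthPeak(65, 300, 64, 66, "peak_65"),
            il.LengthPeak(389, 300, 388, 390, "peak_389"),
        ]
        recs = [
            IesRecord("a", "c", 0, "A" * 66),
            IesRecord("b", "c", 0, "A" * 100),
            IesRecord("c", "c", 0, "A" * 389),
            IesRecord("d", "c", 0, "A" * 500),
        ]
        sc = il.assign_size_classes(recs, peaks)
        assert sc.labels == {
            "a": "peak_65",
            "b": "periodic-offpeak",
            "c": "peak_389",
            "d": "nonperiodic-offpeak",
        }

    def test_tie_breaks_to_nearest_then_smaller_center(self):
        peaks = [
            il.LengthPeak(60, 300, 55, 70, "p60"),
            il.LengthPeak(70, 300, 60, 75, "p70"),
        ]
        sc = il.assign_size_classes([IesRecord("x", "c", 0, "A" * 65)], peaks)
        assert sc.labels["x"] == "p60"


# ---------------------------------------------------------------------------
# intragenic test
# ---------------------------------------------------------------------------


class TestIntragenicDepletion:
    def test_exact_small_cases(self):
        p, _, expected, frac = il.intragenic_depletion_test(3, 10, 0.5)
        assert p == pytest.approx(176 / 1024, rel=1e-12)
        assert expected == 5.0 and frac == 0.3
        p, _, _, _ = il.intragenic_depletion_test(0, 3, 0.77)
        assert p == pytest.approx(0.23**3, rel=1e-12)

    def test_boundary_cases(self):
        assert il.intragenic_depletion_test(10, 10, 1.0)[0] == 1.0
        assert il.intragenic_depletion_test(5, 10, 0.0)[0] == 1.0

    def test_extreme_p_in_log_space(self):
        # far-left tail: p underflows but log10(p) stays finite
        p, log10p, _, _ = il.intragenic_depletion_test(100, 100_000, 0.77)
        assert p == 0.0
        assert log10p < -30000 and math.isfinite(log10p)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError, match="fraction"):
            il.intragenic_depletion_test(1, 2, 1.5)


# ---------------------------------------------------------------------------
# hybrid assembly
# ---------------------------------------------------------------------------


class TestInsertExcise:
    def test_single_insertion_round_trip(self):
        genome = Genome([Contig("c", "AAAA")])
        hybrid, lift, recs = il.insert_ies(genome, [IesRecord("i", "c", 2, "TTT")])
        assert hybrid["c"].seq == "AATTTAA"
        assert recs[0].hybrid_span.start == 2 and recs[0].hybrid_span.end == 5
        assert il.excise(hybrid, recs) == genome

    def test_cumulative_offsets(self):
        genome = Genome([Contig("c", "ACGTACGT")])
        recs_in = [IesRecord("a", "c", 1, "TT"), IesRecord("b", "c", 3, "GGG")]
        hybrid, lift, recs = il.insert_ies(genome, recs_in)
        assert hybrid["c"].seq == "ATTCGGGGTACGT"
        spans = {r.id: (r.hybrid_span.start, r.hybrid_span.end) for r in recs}
        assert spans == {"a": (1, 3), "b": (5, 8)}
        assert lift.mac_to_hybrid("c", 0) == 0
        assert lift.mac_to_hybrid("c", 2) == 4  # past the 2 bp IES at point 1
        assert lift.mac_to_hybrid("c", 3) == 8  # past both insertions

    def test_empty_is_identity(self):
        genome = Genome([Contig("c", "ACGT")])
        hybrid, _, _ = il.insert_ies(genome, [])
        assert hybrid == genome

    def test_collision_rejected(self):
        genome = Genome([Contig("c", "ACGT")])
        with pytest.raises(ValueError, match="a.*b|multiple IESs"):
            il.insert_ies(
                genome, [IesRecord("a", "c", 2, "TT"), IesRecord("b", "c", 2, "GG")]
            )

    def test_point_beyond_contig(self):
        genome = Genome([Contig("c", "ACGT")])
        with pytest.raises(ValueError, match="beyond contig"):
            il.insert_ies(genome, [IesRecord("a", "c", 9, "TT")])

    @given(data=st.data())
    def test_round_trip_property(self, data):
        contig_seq = data.draw(st.text(alphabet=BASES, min_size=5, max_size=80))
        points = data.draw(
            st.lists(
                st.integers(0, len(contig_seq)), min_size=0, max_size=5, unique=True
            )
        )
        genome = Genome([Contig("c", contig_seq)])
        recs = [
            IesRecord(f"i{j}", "c", p, data.draw(dna1))
            for j, p in enumerate(sorted(points))
        ]
        hybrid, _, out = il.insert_ies(genome, recs)
        assert il.excise(hybrid, out) == genome
        assert hybrid.total_length == genome.total_length + sum(
            r.length for r in recs
        )
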