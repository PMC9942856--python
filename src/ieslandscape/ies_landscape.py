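"""Core IES characterization.

An internal eliminated sequence (IES) is flanked on both sides by
MAC-destined sequence (MDS).  Its boundaries typically carry a terminal
direct repeat (TDR, "pointer"): a sequence exactly repeated at both ends,
one copy inside the IES and one in the MDS.  Because the two copies are
identical the physical excision point cannot be determined from sequence
alone ("floating" IES); all records are therefore left-normalized so the
TDR is reported from its left-most possible coordinate.  An IES whose TDR
contains the dinucleotide 5'-TA-3' is called "TA-bound", regardless of the
TDR's total length.

This module provides: the post-prediction filter, TDR and terminal
inverted-repeat (TIR) detection with brute-force-verified exact extension,
a geometric i.i.d. null model for repeat lengths under empirical base
frequencies, length-histogram peak calling with half-height size classes,
junction base-count matrices around the TA, an exact binomial test for
intragenic IES depletion, and construction of the hybrid MAC+IES assembly.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import signal, special

from .io_formats import Contig, Genome, IesRecord, Interval, complement_base, revcomp

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class IesContext:
    """An IES with its MAC-destined flanks (up to ``flank_len`` bp each side)."""

    ies: IesRecord
    left_flank: str
    right_flank: str
    left_truncated: bool = False
    right_truncated: bool = False


@dataclass(frozen=True)
class TdrResult:
    """Terminal direct repeat call at an IES boundary.

    ``klass`` is TA_TDR when the repeat is long enough and contains "TA",
    OTHER_TDR for other repeats of at least ``min_tdr`` bp, NONE otherwise.
    ``ta_offset`` is the leftmost index of "TA" within the TDR (TA_TDR only).
    """

    ies_id: str
    tdr_seq: str
    k: int
    klass: str
    ta_offset: Optional[int] = None


@dataclass(frozen=True)
class TirResult:
    """Terminal inverted repeat call: exact ungapped extension from both ends."""

    ies_id: str
    tir_len: int
    arm_seq: str
    capped: bool
    cap: Optional[int]


@dataclass(frozen=True)
class NullModel:
    """Geometric i.i.d. null for terminal-repeat lengths.

    With base frequencies ``p``, the per-position probability that two
    independent bases form a direct match is ``m_direct = sum(p_b^2)`` and an
    inverted (reverse-complement) match is ``m_inverted = sum(p_b *
    p_complement(b))``; repeat length is then geometric with success
    probability ``1 - m``.
    """

    p: tuple[float, float, float, float]  # A, C, G, T

    def __post_init__(self):
        if abs(sum(self.p) - 1.0) > 1e-9 or any(x < 0 for x in self.p):
            raise ValueError("base frequencies must be nonnegative and sum to 1")

    @property
    def m_direct(self) -> float:
        return sum(x * x for x in self.p)

    @property
    def m_inverted(self) -> float:
        pa, pc, pg, pt = self.p
        return 2.0 * (pa * pt + pc * pg)

    @classmethod
    def from_sequences(cls, seqs: Iterable[str]) -> "NullModel":
        counts = np.zeros(4, dtype=np.int64)
        for s in seqs:
            for i, b in enumerate(BASES):
                counts[i] += s.count(b)
        total = int(counts.sum())
        if total == 0:
            raise ValueError("no A/C/G/T bases to estimate frequencies from")
        return cls(tuple(counts / total))


@dataclass(frozen=True)
class LengthPeak:
    """A called peak of the IES length histogram with half-height bounds."""

    center: int
    height: int
    lo: int
    hi: int
    label: str = ""

    def __post_init__(self):
        if not (self.lo <= self.center <= self.hi):
            raise ValueError("peak bounds must bracket the center")

    def contains(self, length: int) -> bool:
        return self.lo <= length <= self.hi


@dataclass
class SizeClassing:
    """Per-IES size-class labels derived from called length peaks."""

    periodic_range: tuple[int, int]
    peaks: list[LengthPeak]
    labels: dict[str, str]  # ies_id -> peak label / periodic-offpeak / nonperiodic-offpeak


@dataclass
class JunctionMatrix:
    """Base counts at TA-bound IES junctions in MDS-TA-IES orientation.

    24 positions: 10 bp of MDS ending just before the TA, then 14 bp of IES
    starting just after it — the TA itself is excluded.  Each TA-bound IES
    contributes its left junction (sense) and its right junction
    (reverse-complemented), so with no truncation every column sums to twice
    the number of IESs.
    """

    counts: np.ndarray  # (24, 4) int, columns ordered A,C,G,T
    n_junctions: int
    n_skipped: int = 0

    MDS_LEN = 10
    IES_LEN = 14

    def frequencies(self) -> np.ndarray:
        colsum = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            return np.where(colsum > 0, self.counts / colsum, 0.0)


# ---------------------------------------------------------------------------
# Filtering and context extraction
# ---------------------------------------------------------------------------


def filter_ies(
    records: Sequence[IesRecord],
    min_len: int = 50,
    min_score: float = 0.075,
) -> tuple[list[IesRecord], list[tuple[IesRecord, str]]]:
    """Remove likely-spurious IES predictions.

    A record is removed iff its length is below ``min_len`` OR its retention
    score is present and below ``min_score``; records lacking a score are
    kept.  Returns (kept, removed-with-reason).
    """
    kept: list[IesRecord] = []
    removed: list[tuple[IesRecord, str]] = []
    for rec in records:
        if rec.length < min_len:
            removed.append((rec, f"length {rec.length} < {min_len}"))
        elif rec.retention_score is not None and rec.retention_score < min_score:
            removed.append(
                (rec, f"retention_score {rec.retention_score:g} < {min_score:g}")
            )
        else:
            kept.append(rec)
    return kept, removed


def extract_context(genome: Genome, ies: IesRecord, flank_len: int = 50) -> IesContext:
    """Extract the MAC-destined flanks around an IES insertion point."""
    if ies.contig not in genome:
        raise ValueError(f"IES {ies.id}: unknown contig {ies.contig!r}")
    contig = genome[ies.contig]
    if ies.mac_point > contig.length:
        raise ValueError(
            f"IES {ies.id}: mac_point {ies.mac_point} beyond contig end"
        )
    lo = max(0, ies.mac_point - flank_len)
    hi = min(contig.length, ies.mac_point + flank_len)
    return IesContext(
        ies=ies,
        left_flank=contig.seq[lo : ies.mac_point],
        right_flank=contig.seq[ies.mac_point : hi],
        left_truncated=ies.mac_point < flank_len,
        right_truncated=contig.length - ies.mac_point < flank_len,
    )


def normalize_left(context: IesContext) -> tuple[int, IesContext]:
    """Shift a floating IES to its left-most equivalent coordinate.

    While the last base of the left flank equals the last base of the IES,
    the IES window can slide one base left without changing the excision
    product; the displaced base joins the right flank.  Returns (shift,
    normalized context).  Idempotent, and the MAC product (left flank +
    right flank) is unchanged.
    """
    left = context.left_flank
    ies_seq = context.ies.seq
    right = context.right_flank
    shift = 0
    while left and ies_seq and left[-1] == ies_seq[-1]:
        moved = left[-1]
        right = ies_seq[-1] + right
        ies_seq = moved + ies_seq[:-1]
        left = left[:-1]
        shift += 1
    if shift == 0:
        return 0, context
    rec = replace(context.ies, mac_point=context.ies.mac_point - shift, seq=ies_seq)
    return shift, IesContext(
        ies=rec,
        left_flank=left,
        right_flank=right,
        left_truncated=context.left_truncated,
        right_truncated=context.right_truncated,
    )


# ---------------------------------------------------------------------------
# Terminal repeats
# ---------------------------------------------------------------------------


def find_tdr(
    context: IesContext,
    min_tdr: int = 2,
    max_tdr: Optional[int] = None,
) -> TdrResult:
    """Find the terminal direct repeat of a left-normalized IES.

    The TDR length k is the longest prefix shared between the IES and its
    right (downstream MDS) flank, capped at ``max_tdr``.  An IES is TA-bound
    when k >= ``min_tdr`` and the TDR contains "TA".
    """
    ies_seq = context.ies.seq
    right = context.right_flank
    limit = min(len(ies_seq), len(right))
    if max_tdr is not None:
        limit = min(limit, max_tdr)
    k = 0
    while k < limit and ies_seq[k] == right[k]:
        k += 1
    tdr = ies_seq[:k]
    if k < min_tdr:
        klass, ta_offset = "NONE", None
    else:
        ta_offset = tdr.find("TA")
        if ta_offset >= 0:
            klass = "TA_TDR"
        else:
            klass, ta_offset = "OTHER_TDR", None
    return TdrResult(context.ies.id, tdr, k, klass, ta_offset)


def find_tir(
    ies_seq: str,
    tdr_len: int,
    cap: Optional[int] = 25,
    strip: str = "left",
    ies_id: str = "",
) -> TirResult:
    """Exact ungapped terminal inverted-repeat extension.

    After stripping the in-IES TDR copy (``strip``: "left" removes the
    leading ``tdr_len`` bases, "both" also the trailing, "none" keeps all),
    each base from the element's 5' end is compared with the complement of
    the corresponding base from the 3' end, extending until the first
    mismatch, the element midpoint, or ``cap`` (None disables the cap —
    used when curating full repeat-family elements).
    """
    if strip not in ("none", "left", "both"):
        raise ValueError(f"invalid strip mode {strip!r}")
    if tdr_len > len(ies_seq):
        raise ValueError("tdr_len exceeds IES length")
    element = ies_seq
    if strip in ("left", "both"):
        element = element[tdr_len:]
    if strip == "both" and tdr_len:
        element = element[:-tdr_len] if len(element) >= tdr_len else ""
    n = len(element)
    limit = n // 2
    if cap is not None:
        limit = min(limit, cap)
    i = 0
    while i < limit and element[i] == complement_base(element[n - 1 - i]):
        i += 1
    capped = cap is not None and i == cap and i < n // 2
    return TirResult(ies_id, i, element[:i], capped, cap)


def expected_observed(
    observed_counts_by_length: dict[int, int],
    null: NullModel,
    n_ies: int,
    mode: str = "direct",
) -> list[tuple[int, int, float, Optional[float]]]:
    """Expected vs observed terminal-repeat length counts under the null.

    Under the geometric i.i.d. model the expected number of IESs whose
    repeat length is exactly L is ``n_ies * m**L * (1 - m)``; these sum to
    ``n_ies`` over L >= 0.  Returns rows (L, observed, expected, ratio)
    where ratio = observed/expected, None when expected is zero.
    """
    if n_ies <= 0:
        raise ValueError("n_ies must be positive")
    if mode == "direct":
        m = null.m_direct
    elif mode == "inverted":
        m = null.m_inverted
    else:
        raise ValueError(f"invalid mode {mode!r}")
    if m >= 1.0:
        raise ValueError("degenerate composition: match probability is 1")
    max_len = max(observed_counts_by_length, default=0)
    rows = []
    for L in range(max_len + 1):
        obs = observed_counts_by_length.get(L, 0)
        exp = n_ies * m**L * (1.0 - m)
        ratio = obs / exp if exp > 0 else None
        rows.append((L, obs, exp, ratio))
    return rows


# ---------------------------------------------------------------------------
# Junction matrices
# ---------------------------------------------------------------------------


def junction_matrix(
    contexts: Sequence[IesContext],
    tdr_results: Sequence[TdrResult],
    mds_len: int = JunctionMatrix.MDS_LEN,
    ies_len: int = JunctionMatrix.IES_LEN,
) -> JunctionMatrix:
    """Count bases around the TA of TA-bound IES junctions.

    Each IES contributes two junction strings anchored on the TA inside each
    TDR copy, both oriented 5'-(MDS)-TA-(IES)-3': the left junction in sense
    and the right junction reverse-complemented.  Junctions with
    insufficient flanking sequence are skipped and counted.
    """
    n_pos = mds_len + ies_len
    counts = np.zeros((n_pos, 4), dtype=np.int64)
    n_junctions = 0
    n_skipped = 0

    def tally(junction: str) -> bool:
        if len(junction) != n_pos or any(b not in _BASE_INDEX for b in junction):
            return False
        for pos, b in enumerate(junction):
            counts[pos, _BASE_INDEX[b]] += 1
        return True

    for ctx, tdr in zip(contexts, tdr_results):
        if tdr.klass != "TA_TDR":
            raise ValueError(
                f"IES {tdr.ies_id}: junction matrices are defined for TA-bound "
                f"IESs only (got {tdr.klass})"
            )
        t = tdr.ta_offset
        ies_seq = ctx.ies.seq
        right = ctx.right_flank

        # Left junction: TA at ies_seq[t:t+2]; upstream context runs through
        # the left flank, downstream is IES sequence.
        upstream = (ctx.left_flank + ies_seq[:t])[-mds_len:]
        downstream = ies_seq[t + 2 : t + 2 + ies_len]
        if tally(upstream + downstream):
            n_junctions += 1
        else:
            n_skipped += 1

        # Right junction: TA at right[t:t+2]; on the forward strand the
        # element side is upstream, the MDS side downstream; reverse
        # complementing flips it into MDS-TA-IES orientation.
        up_fwd = (ies_seq + right[:t])[-ies_len:]
        down_fwd = right[t + 2 : t + 2 + mds_len]
        if len(up_fwd) == ies_len and len(down_fwd) == mds_len:
            junction = revcomp(down_fwd) + revcomp(up_fwd)
            if tally(junction):
                n_junctions += 1
            else:
                n_skipped += 1
        else:
            n_skipped += 1

    return JunctionMatrix(counts=counts, n_junctions=n_junctions, n_skipped=n_skipped)


# ---------------------------------------------------------------------------
# Length peaks and size classes
# ---------------------------------------------------------------------------


def call_length_peaks(
    length_histogram: dict[int, int],
    height_cutoff: int = 100,
) -> list[LengthPeak]:
    """Call peaks on a 1 bp-binned IES length histogram.

    A peak is a bin strictly greater than both neighbors with count >=
    ``height_cutoff``; a maximal plateau resolves to its leftmost bin.  The
    size-class range [lo, hi] is the outermost run of contiguous bins with
    count >= half the peak height.
    """
    if not length_histogram:
        return []
    lo_bin = min(length_histogram)
    hi_bin = max(length_histogram)
    lengths = np.arange(lo_bin, hi_bin + 1)
    counts = np.array([length_histogram.get(int(x), 0) for x in lengths])
    # Zero-pad so boundary bins can be peaks; plateau_size reports left edges.
    padded = np.concatenate([[0], counts, [0]])
    idx, props = signal.find_peaks(padded, height=height_cutoff, plateau_size=1)
    peaks: list[LengthPeak] = []
    for j, peak_i in enumerate(idx):
        left_edge = int(props["left_edges"][j]) - 1  # unpad
        height = int(props["peak_heights"][j])
        half = height / 2.0
        lo = left_edge
        while lo - 1 >= 0 and counts[lo - 1] >= half:
            lo -= 1
        hi = left_edge
        while hi + 1 < len(counts) and counts[hi + 1] >= half:
            hi += 1
        center = int(lengths[left_edge])
        peaks.append(
            LengthPeak(
                center=center,
                height=height,
                lo=int(lengths[lo]),
                hi=int(lengths[hi]),
                label=f"peak_{center}",
            )
        )
    peaks.sort(key=lambda p: p.center)
    return peaks


def estimate_period(
    peak_centers: Sequence[int],
    window: tuple[int, int] = (65, 115),
) -> float:
    """Median spacing of consecutive peak centers inside ``window`` (bp)."""
    inside = sorted(c for c in peak_centers if window[0] <= c <= window[1])
    if len(inside) < 2:
        raise ValueError(
            f"insufficient peaks in window {window}: need >= 2, got {len(inside)}"
        )
    diffs = np.diff(inside)
    return float(np.median(diffs))


def assign_size_classes(
    ies_records: Sequence[IesRecord],
    peaks: Sequence[LengthPeak],
    periodic_range: tuple[int, int] = (65, 115),
) -> SizeClassing:
    """Label every IES with a peak size class or an off-peak category.

    An IES takes the label of the peak whose [lo, hi] range contains its
    length (ties broken by nearest center, then smaller center); otherwise
    "periodic-offpeak" if its length falls in ``periodic_range``, else
    "nonperiodic-offpeak".
    """
    labels: dict[str, str] = {}
    for rec in ies_records:
        candidates = [p for p in peaks if p.contains(rec.length)]
        if candidates:
            best = min(candidates, key=lambda p: (abs(rec.length - p.center), p.center))
            labels[rec.id] = best.label
        elif periodic_range[0] <= rec.length <= periodic_range[1]:
            labels[rec.id] = "periodic-offpeak"
        else:
            labels[rec.id] = "nonperiodic-offpeak"
    return SizeClassing(
        periodic_range=tuple(periodic_range), peaks=list(peaks), labels=labels
    )


# ---------------------------------------------------------------------------
# Intragenic depletion
# ---------------------------------------------------------------------------


def intragenic_depletion_test(
    n_intragenic: int,
    n_total: int,
    genic_fraction: float,
) -> tuple[float, float, float, float]:
    """One-sided exact binomial test for depletion of intragenic IESs.

    Under the null, each IES lands in genic sequence independently with
    probability ``genic_fraction``; the lower-tail p-value
    P(X <= n_intragenic) is computed in log space (log-gamma binomial terms
    combined with logsumexp) so that p-values far below the float underflow
    limit remain meaningful.  Returns (p_value, log10_p, expected_count,
    observed_fraction).
    """
    if not (0 <= n_intragenic <= n_total):
        raise ValueError("need 0 <= n_intragenic <= n_total")
    if not (0.0 <= genic_fraction <= 1.0):
        raise ValueError(f"invalid genic fraction: {genic_fraction}")
    n, f = n_total, genic_fraction
    if f == 0.0:
        logp = 0.0
    elif f == 1.0:
        logp = 0.0 if n_intragenic == n else -math.inf
    else:
        ks = np.arange(0, n_intragenic + 1)
        log_terms = (
            special.gammaln(n + 1)
            - special.gammaln(ks + 1)
            - special.gammaln(n - ks + 1)
            + ks * math.log(f)
            + (n - ks) * math.log1p(-f)
        )
        logp = float(special.logsumexp(log_terms))
        logp = min(logp, 0.0)
    p = math.exp(logp) if logp > -745 else 0.0
    expected = n * f
    observed_frac = n_intragenic / n if n else float("nan")
    return p, logp / math.log(10), expected, observed_frac


# ---------------------------------------------------------------------------
# Hybrid MAC+IES assembly
# ---------------------------------------------------------------------------


class Liftover:
    """Maps MAC coordinates to hybrid MAC+IES coordinates per contig."""

    def __init__(self, breakpoints: dict[str, tuple[list[int], list[int]]]):
        # breakpoints[contig] = (sorted mac insertion points, cumulative offsets
        # applying at-or-after each point)
        self._bp = breakpoints

    def mac_to_hybrid(self, contig: str, pos: int) -> int:
        points, offsets = self._bp.get(contig, ([], []))
        i = bisect_right(points, pos)
        return pos + (offsets[i - 1] if i else 0)

    def lift_interval(self, iv: Interval) -> Interval:
        # End is exclusive: lift the last covered base so an insertion at
        # exactly iv.end stays outside the lifted interval.
        return replace(
            iv,
            start=self.mac_to_hybrid(iv.contig, iv.start),
            end=self.mac_to_hybrid(iv.contig, iv.end - 1) + 1,
        )


def insert_ies(
    genome: Genome, ies_records: Sequence[IesRecord]
) -> tuple[Genome, Liftover, list[IesRecord]]:
    """Insert IES sequences into the MAC assembly to build the hybrid genome.

    Each IES sequence is inserted before its ``mac_point`` with cumulative
    offsets; the returned records carry filled ``hybrid_span``s and excising
    all spans reproduces the input genome exactly.  Multiple IESs at one
    point are rejected.
    """
    by_contig: dict[str, list[IesRecord]] = {}
    for rec in ies_records:
        if rec.contig not in genome:
            raise ValueError(f"IES {rec.id}: unknown contig {rec.contig!r}")
        if rec.mac_point > genome[rec.contig].length:
            raise ValueError(
                f"IES {rec.id}: mac_point {rec.mac_point} beyond contig end"
            )
        by_contig.setdefault(rec.contig, []).append(rec)

    out_records: list[IesRecord] = []
    breakpoints: dict[str, tuple[list[int], list[int]]] = {}
    hybrid = Genome()
    for contig in genome:
        recs = sorted(by_contig.get(contig.id, []), key=lambda r: r.mac_point)
        points = [r.mac_point for r in recs]
        dupes = {p for a, b in zip(points, points[1:]) if a == b for p in (a,)}
        if dupes:
            ids = [r.id for r in recs if r.mac_point in dupes]
            raise ValueError(
                f"contig {contig.id}: multiple IESs at one insertion point: {ids}"
            )
        parts: list[str] = []
        offsets: list[int] = []
        offset = 0
        prev = 0
        for rec in recs:
            parts.append(contig.seq[prev : rec.mac_point])
            span = Interval(
                contig.id,
                rec.mac_point + offset,
                rec.mac_point + offset + rec.length,
                ".",
                "IES",
            )
            out_records.append(replace(rec, hybrid_span=span))
            parts.append(rec.seq)
            offset += rec.length
            offsets.append(offset)
            prev = rec.mac_point
        parts.append(contig.seq[prev:])
        hybrid.add(Contig(contig.id, "".join(parts)))
        breakpoints[contig.id] = (points, offsets)
    return hybrid, Liftover(breakpoints), out_records


def excise(hybrid: Genome, ies_records: Sequence[IesRecord]) -> Genome:
    """Remove all hybrid IES spans, reconstructing the MAC genome."""
    by_contig: dict[str, list[Interval]] = {}
    for rec in ies_records:
        if rec.hybrid_span is None:
            raise ValueError(f"IES {rec.id}: no hybrid span to excise")
        by_contig.setdefault(rec.hybrid_span.contig, []).append(rec.hybrid_span)
    out = Genome()
    for contig in hybrid:
        spans = sorted(by_contig.get(contig.id, []), key=lambda s: s.start)
        parts = []
        prev = 0
        for s in spans:
            if s.start < prev:
                raise ValueError(f"contig {contig.id}: overlapping IES spans")
            parts.append(contig.seq[prev : s.start])
            prev = s.end
        parts.append(contig.seq[prev:])
        out.add(Contig(contig.id, "".join(parts)))
    return out
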