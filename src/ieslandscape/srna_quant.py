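"""Developmental small-RNA quantification over the hybrid MAC+IES assembly.

Classifies mapped sRNA reads by the feature they overlap (IES, CDS, or
neither, excluding tRNA/rRNA), converts counts to RPKM using the total
length of each feature *type* in place of transcript length, and profiles
positional base composition — in particular the 5'-U fraction that
distinguishes scnRNA-like 24 nt reads.

Assignment rules (logged in output headers): a read overlapping any
excluded feature by >= 1 bp is excluded first; otherwise IES takes priority
over CDS; anything else is NON.  Each read is counted exactly once, from
its single primary placement.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .io_formats import Interval, ReadPlacement

FEATURE_PRIORITY = ("IES", "CDS", "NON")


@dataclass
class FeatureCounts:
    """Read counts per (read length, feature type) for one time point."""

    timepoint: str
    counts: dict[tuple[int, str], int]  # (read length, IES/CDS/NON) -> count
    excluded_count: int
    total_mapped: int

    def by_feature(self, read_length: Optional[int] = None) -> dict[str, int]:
        out = {ft: 0 for ft in FEATURE_PRIORITY}
        for (length, ft), n in self.counts.items():
            if read_length is None or length == read_length:
                out[ft] += n
        return out

    @property
    def assigned_count(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class BaseBias:
    """Positional base-frequency matrix for a fixed-length read subset.

    Position 1 is the read's 5' end as sequenced; ``five_prime_u_fraction``
    is the position-1 frequency of T (U in the RNA).
    """

    freqs: np.ndarray  # (read_length, 4), columns A,C,G,T; rows sum to 1
    n_reads: int

    @property
    def five_prime_u_fraction(self) -> float:
        return float(self.freqs[0, 3])


def length_histogram(
    reads: Sequence[ReadPlacement],
) -> tuple[dict[int, int], dict[int, float]]:
    """Read counts and fractions by length; fractions are empty for no reads."""
    counts = dict(sorted(Counter(r.length for r in reads).items()))
    total = sum(counts.values())
    fractions = {L: n / total for L, n in counts.items()} if total else {}
    return counts, fractions


def _build_trees(intervals: Iterable[Interval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for iv in intervals:
        trees[iv.contig].addi(iv.start, iv.end)
    return dict(trees)


def classify_reads(
    reads: Sequence[ReadPlacement],
    ies_intervals: Sequence[Interval],
    cds_intervals: Sequence[Interval],
    exclude_intervals: Sequence[Interval] = (),
) -> list[str]:
    """Per-read feature label: EXCLUDED, IES, CDS or NON (priority in that
    order, >= 1 bp overlap)."""
    excl = _build_trees(exclude_intervals)
    ies = _build_trees(ies_intervals)
    cds = _build_trees(cds_intervals)
    labels: list[str] = []
    for r in reads:
        if r.contig in excl and excl[r.contig].overlaps(r.start, r.end):
            labels.append("EXCLUDED")
        elif r.contig in ies and ies[r.contig].overlaps(r.start, r.end):
            labels.append("IES")
        elif r.contig in cds and cds[r.contig].overlaps(r.start, r.end):
            labels.append("CDS")
        else:
            labels.append("NON")
    return labels


def assign_features(
    reads: Sequence[ReadPlacement],
    ies_intervals: Sequence[Interval],
    cds_intervals: Sequence[Interval],
    exclude_intervals: Sequence[Interval] = (),
    timepoint: str = "",
    known_contigs: Optional[set[str]] = None,
) -> FeatureCounts:
    """Assign each read to IES/CDS/NON with tRNA/rRNA exclusion.

    ``known_contigs`` optionally validates placements; reads on unknown
    contigs raise an error listing the offending contigs.
    """
    if known_contigs is not None:
        unknown = sorted({r.contig for r in reads} - known_contigs)
        if unknown:
            raise ValueError(f"read placements on unknown contigs: {unknown}")
    labels = classify_reads(reads, ies_intervals, cds_intervals, exclude_intervals)
    counts: dict[tuple[int, str], int] = defaultdict(int)
    excluded = 0
    for r, label in zip(reads, labels):
        if label == "EXCLUDED":
            excluded += 1
        else:
            counts[(r.length, label)] += 1
    return FeatureCounts(
        timepoint=timepoint,
        counts=dict(counts),
        excluded_count=excluded,
        total_mapped=len(reads),
    )


def rpkm(count: int, total_mapped: int, feature_total_length_bp: int) -> float:
    """Reads per kb of feature-type length per million mapped reads:
    1e9 * count / (total_mapped * feature_total_length_bp)."""
    if total_mapped <= 0 or feature_total_length_bp <= 0:
        raise ValueError("total_mapped and feature_total_length must be positive")
    return 1e9 * count / (total_mapped * feature_total_length_bp)


def rpkm_table(
    feature_counts: FeatureCounts,
    feature_total_lengths: dict[str, int],
    read_lengths: Sequence[int] = (22, 24),
) -> list[tuple[str, int, str, int, float]]:
    """Tidy rows (timepoint, read_length, feature_type, count, rpkm)."""
    rows = []
    for L in read_lengths:
        for ft in FEATURE_PRIORITY:
            n = feature_counts.counts.get((L, ft), 0)
            value = rpkm(n, feature_counts.total_mapped, feature_total_lengths[ft])
            rows.append((feature_counts.timepoint, L, ft, n, value))
    return rows


def base_bias(reads: Sequence[ReadPlacement]) -> BaseBias:
    """Positional base frequencies for a same-length read subset.

    Frequencies come from the read sequence as sequenced (5'->3'), so no
    strand complementing is needed.
    """
    if not reads:
        raise ValueError("empty read subset")
    lengths = {r.length for r in reads}
    if len(lengths) != 1:
        raise ValueError(f"mixed read lengths: {sorted(lengths)}")
    (L,) = lengths
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts = np.zeros((L, 4), dtype=np.int64)
    for r in reads:
        if len(r.read_seq) != L:
            raise ValueError(f"read {r.read_id}: sequence length != placement length")
        for pos, b in enumerate(r.read_seq):
            if b in base_index:
                counts[pos, base_index[b]] += 1
    colsum = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        freqs = np.where(colsum > 0, counts / colsum, 0.0)
    return BaseBias(freqs=freqs, n_reads=len(reads))


def feature_total_lengths(
    ies_intervals: Sequence[Interval],
    cds_intervals: Sequence[Interval],
    genome_total_length: int,
    exclude_intervals: Sequence[Interval] = (),
) -> dict[str, int]:
    """Disjoint total bp per feature type, mirroring the assignment priority.

    CDS bases that fall inside an IES (or an excluded feature) are counted
    as IES (excluded), matching ``assign_features``; NON is the remainder of
    the assembly.
    """
    from .io_formats import group_spans, subtract_spans

    ies_g = group_spans(ies_intervals)
    cds_g = group_spans(cds_intervals)
    excl_g = group_spans(exclude_intervals)
    ies_len = sum(e - s for ivs in ies_g.values() for s, e in ivs)
    excl_len = sum(e - s for ivs in excl_g.values() for s, e in ivs)
    cds_len = 0
    for cid, ivs in cds_g.items():
        clean = subtract_spans(
            subtract_spans(ivs, ies_g.get(cid, [])), excl_g.get(cid, [])
        )
        cds_len += sum(e - s for s, e in clean)
    non_len = genome_total_length - ies_len - cds_len - excl_len
    if non_len <= 0:
        raise ValueError("feature intervals exceed genome length")
    return {"IES": ies_len, "CDS": cds_len, "NON": non_len}
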