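"""Repeat-family downstream analysis: MITEs and mobile IESs.

A mobile IES ("MITIES": simultaneously a MITE and an IES) is an IES whose
terminal direct repeat coincides with the target-site duplication (TSD) of
a DNA transposon family and whose element termini carry that family's
terminal inverted repeat (TIR).  This module profiles repeat copies by
divergence from family consensus, calls mobile and nested IESs against
family TIR/TSD signatures, finds the smallest tandem-repeat (microsatellite)
unit of a sequence, and formats catalytic-triad motif strings for DDE/D
transposases.

A packaged preset (``families/bstoltei.tsv``) carries the curated
*Blepharisma stoltei* germline family signatures: the Pogo/Tigger-family
transposon Bogo with its nonautonomous derivative BogoMITE (~30 bp C-rich
TIR, TSD TAA/TTA) and the Tc1-family transposon BstTc1 (38 bp TIR, TSD
TATA, with a 10 bp microsatellite unit).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .io_formats import Interval, revcomp, write_tsv
from .ies_landscape import IesContext, TdrResult


@dataclass(frozen=True)
class RepeatFamily:
    """A mobile-element family signature.

    ``tsd_motifs`` must be closed under reverse complement (a TSD read on
    the opposite strand is the reverse complement of the motif).
    """

    name: str
    tir_consensus: str
    tsd_motifs: frozenset[str]
    consensus_len: int
    classification: str = ""
    consensus_seq: Optional[str] = None
    microsat_unit: Optional[str] = None

    def __post_init__(self):
        if not self.tir_consensus:
            raise ValueError(f"family {self.name}: empty TIR consensus")
        closed = set(self.tsd_motifs) | {revcomp(m) for m in self.tsd_motifs}
        object.__setattr__(self, "tsd_motifs", frozenset(closed))


@dataclass(frozen=True)
class RepeatCopy:
    """One annotated copy of a repeat family on the hybrid assembly."""

    family: str
    interval: Interval
    divergence_pct: float

    def __post_init__(self):
        if self.divergence_pct < 0:
            raise ValueError(f"negative divergence: {self.divergence_pct}")

    @property
    def copy_len(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class MitiesCall:
    """Per-IES mobile-element match status for one family.

    MOBILE_IES: the IES's TDR is one of the family's TSD motifs and both
    element termini match the family TIR within tolerance.  NESTED: not
    mobile, but an annotated copy of the family lies strictly inside the
    IES's hybrid span.  NONE otherwise.
    """

    ies_id: str
    family: str
    status: str
    tir_mismatch_frac: float = float("nan")
    tsd_matched: bool = False


@dataclass
class DivergenceProfile:
    family: str
    histogram: dict[float, int]  # bin lower edge -> count
    full_length_flags: list[bool]
    median_full_length: Optional[float]
    median_partial: Optional[float]


# ---------------------------------------------------------------------------
# Family preset / TSV IO
# ---------------------------------------------------------------------------


def read_families_tsv(path: Union[str, Path]) -> list[RepeatFamily]:
    """Read family signatures: columns name, tir, tsd_list, consensus_len
    [, classification, microsat_unit]."""
    families = []
    with open(path) as fh:
        header: Optional[list[str]] = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            row = dict(zip(header, line.split("\t")))
            families.append(
                RepeatFamily(
                    name=row["name"],
                    tir_consensus=row["tir"].upper(),
                    tsd_motifs=frozenset(row["tsd_list"].upper().split(",")),
                    consensus_len=int(row["consensus_len"]),
                    classification=row.get("classification", ""),
                    microsat_unit=row.get("microsat_unit", "") or None,
                )
            )
    if not families:
        raise ValueError(f"no family rows in {path}")
    return families


def load_preset_families() -> list[RepeatFamily]:
    """Load the packaged B. stoltei family signatures (Bogo/BogoMITE/BstTc1)."""
    ref = resources.files("ieslandscape") / "families" / "bstoltei.tsv"
    with resources.as_file(ref) as path:
        return read_families_tsv(path)


def read_repeat_tsv(path: Union[str, Path]) -> list[RepeatCopy]:
    """Read repeat-copy annotations.

    Simplified RepeatMasker-.out-like dialect: TSV with header columns
    family, contig, start, end (0-based half-open on the hybrid assembly),
    divergence_pct.
    """
    copies: list[RepeatCopy] = []
    required = ("family", "contig", "start", "end", "divergence_pct")
    with open(path) as fh:
        header: Optional[list[str]] = None
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in required if c not in header]
                if missing:
                    raise ValueError(
                        f"{path}: missing required column(s): {', '.join(missing)}"
                    )
                continue
            row = dict(zip(header, fields))
            start, end = int(row["start"]), int(row["end"])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            div = float(row["divergence_pct"])
            if div < 0:
                raise ValueError(f"{path}:{lineno}: negative divergence")
            copies.append(
                RepeatCopy(
                    family=row["family"],
                    interval=Interval(
                        row["contig"], start, end, ".", f"repeat:{row['family']}"
                    ),
                    divergence_pct=div,
                )
            )
    return copies


def write_repeat_tsv(copies: Sequence[RepeatCopy], path: Union[str, Path]) -> None:
    write_tsv(
        path,
        ["family", "contig", "start", "end", "divergence_pct"],
        (
            (
                c.family,
                c.interval.contig,
                c.interval.start,
                c.interval.end,
                f"{c.divergence_pct:g}",
            )
            for c in copies
        ),
    )


# ---------------------------------------------------------------------------
# Divergence / full-length profiling
# ---------------------------------------------------------------------------


def divergence_profile(
    copies: Sequence[RepeatCopy],
    family: RepeatFamily,
    f_min: float = 0.95,
    bin_width: float = 1.0,
) -> DivergenceProfile:
    """Histogram copy divergences and flag full-length copies.

    A copy is full-length when its length is at least ``f_min`` of the
    family consensus length (0.95 for intactness, 0.80 for a looser
    full-length criterion).  Lowering ``f_min`` never unflags a copy.
    """
    fam_copies = [c for c in copies if c.family == family.name]
    flags = [c.copy_len >= f_min * family.consensus_len for c in fam_copies]
    hist: dict[float, int] = {}
    for c in fam_copies:
        edge = np.floor(c.divergence_pct / bin_width) * bin_width
        hist[float(edge)] = hist.get(float(edge), 0) + 1
    full = [c.divergence_pct for c, f in zip(fam_copies, flags) if f]
    part = [c.divergence_pct for c, f in zip(fam_copies, flags) if not f]
    return DivergenceProfile(
        family=family.name,
        histogram=dict(sorted(hist.items())),
        full_length_flags=flags,
        median_full_length=float(np.median(full)) if full else None,
        median_partial=float(np.median(part)) if part else None,
    )


# ---------------------------------------------------------------------------
# Mobile-IES (MITIES) calling
# ---------------------------------------------------------------------------


def _collapse_homopolymers(seq: str, min_run: int = 4) -> str:
    return re.sub(r"(.)\1{%d,}" % (min_run - 1), r"\1" * min_run, seq)


def _mismatch_frac(a: str, b: str) -> float:
    if len(a) != len(b) or not a:
        return 1.0
    return sum(x != y for x, y in zip(a, b)) / len(a)


def detect_mities(
    ies_contexts: Sequence[IesContext],
    tdr_results: Sequence[TdrResult],
    family: RepeatFamily,
    max_tir_mismatch_frac: float = 0.1,
    nested_copies: Optional[Sequence[RepeatCopy]] = None,
    nested_margin: int = 5,
    collapse_homopolymers: bool = False,
) -> list[MitiesCall]:
    """Call mobile and nested IESs against one family signature.

    MOBILE_IES requires (i) the IES's TDR to be one of the family's TSD
    motifs (exact, strand-symmetric) and (ii) after stripping the TDR
    prefix, the element's first |TIR| bases to match the family TIR and its
    last |TIR| bases to match the TIR's reverse complement, each with
    mismatch fraction <= tolerance.  ``collapse_homopolymers`` collapses
    runs >= 4 before comparison, tolerating variable-length poly-C runs.
    NESTED requires an annotated family copy strictly inside the IES's
    hybrid span with at least ``nested_margin`` bp to either IES end.
    """
    if not family.tsd_motifs:
        raise ValueError(f"family {family.name}: no TSD motifs defined")
    tir = family.tir_consensus
    tir_rc = revcomp(tir)
    nested_by_contig: dict[str, list[RepeatCopy]] = {}
    for c in nested_copies or ():
        if c.family == family.name:
            nested_by_contig.setdefault(c.interval.contig, []).append(c)

    calls: list[MitiesCall] = []
    for ctx, tdr in zip(ies_contexts, tdr_results):
        mismatch = float("nan")
        tsd_ok = tdr.tdr_seq in family.tsd_motifs and tdr.k > 0
        mobile = False
        if tsd_ok:
            element = ctx.ies.seq[tdr.k :]
            if len(element) >= 2 * len(tir):
                left_arm, right_arm = element[: len(tir)], element[-len(tir) :]
                if collapse_homopolymers:
                    fl = _mismatch_frac(
                        _collapse_homopolymers(left_arm), _collapse_homopolymers(tir)
                    )
                    fr = _mismatch_frac(
                        _collapse_homopolymers(right_arm),
                        _collapse_homopolymers(tir_rc),
                    )
                else:
                    fl = _mismatch_frac(left_arm, tir)
                    fr = _mismatch_frac(right_arm, tir_rc)
                mismatch = max(fl, fr)
                mobile = mismatch <= max_tir_mismatch_frac
        if mobile:
            status = "MOBILE_IES"
        else:
            status = "NONE"
            span = ctx.ies.hybrid_span
            if span is not None:
                for copy in nested_by_contig.get(span.contig, ()):  # strict interior
                    if (
                        copy.interval.start >= span.start + nested_margin
                        and copy.interval.end <= span.end - nested_margin
                    ):
                        status = "NESTED"
                        break
        calls.append(
            MitiesCall(
                ies_id=ctx.ies.id,
                family=family.name,
                status=status,
                tir_mismatch_frac=mismatch,
                tsd_matched=tsd_ok,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Microsatellite unit and triad motifs
# ---------------------------------------------------------------------------


def smallest_repeat_unit(seq: str) -> tuple[int, str, float]:
    """Smallest tandem-repeat unit of a string.

    Returns (unit_len, unit, copies) where unit_len is the smallest p with
    seq[i] == seq[i+p] for all valid i (the string period, via the KMP
    failure function) and copies = len(seq)/p, fractional copies allowed.
    """
    if not seq:
        raise ValueError("empty sequence")
    n = len(seq)
    fail = [0] * n
    k = 0
    for i in range(1, n):
        while k > 0 and seq[i] != seq[k]:
            k = fail[k - 1]
        if seq[i] == seq[k]:
            k += 1
        fail[i] = k
    p = n - fail[-1]
    return p, seq[:p], n / p


def find_microsatellites(
    seq: str,
    max_unit: int = 15,
    min_copies: float = 3.0,
    window: int = 40,
    step: int = 10,
) -> list[tuple[int, int, str, float]]:
    """Locate tandem-repeat (microsatellite) arrays in a sequence.

    Scans fixed windows with :func:`smallest_repeat_unit`; windows whose
    period is short (<= ``max_unit``) seed candidate arrays that are then
    extended base-by-base while the exact unit continues.  Returns
    (start, end, unit, copies) tuples for arrays with at least
    ``min_copies`` copies.
    """
    n = len(seq)
    found: list[tuple[int, int, str, float]] = []
    covered_to = 0
    for w_start in range(0, max(1, n - window + 1), step):
        if w_start < covered_to:
            continue
        w = seq[w_start : w_start + window]
        if len(w) < window:
            break
        p, unit, _ = smallest_repeat_unit(w)
        if p > max_unit:
            continue
        # extend left
        start = w_start
        while start > 0 and seq[start - 1] == seq[start - 1 + p]:
            start -= 1
        # extend right
        end = w_start + window
        while end < n and seq[end] == seq[end - p]:
            end += 1
        # re-derive the minimal unit of the full array (window may have
        # caught a multiple of the true period)
        p2, unit2, copies = smallest_repeat_unit(seq[start:end])
        if copies >= min_copies and p2 <= max_unit:
            found.append((start, end, unit2, copies))
            covered_to = end
    return found


def triad_motif(residues: Sequence[str], positions: Sequence[int]) -> str:
    """Format a DDE/D catalytic-triad motif string, e.g. ("D","D","D") at
    spacing 35 between the 2nd and 3rd residues -> "DD35D"."""
    if len(residues) != 3 or len(positions) != 3:
        raise ValueError("need exactly three residues and positions")
    r1, r2, r3 = residues
    p1, p2, p3 = positions
    if not (p1 < p2 < p3):
        raise ValueError(f"positions must be strictly increasing: {positions}")
    for r in (r1, r2, r3):
        if not (len(r) == 1 and r.isalpha() and r.isupper()):
            raise ValueError(f"invalid residue {r!r}")
    return f"{r1}{r2}{p3 - p2 - 1}{r3}"
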