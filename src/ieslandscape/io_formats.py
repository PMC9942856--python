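"""Readers and writers for the formats the pipeline touches.

All coordinates are 0-based half-open internally.  GFF3 (1-based inclusive)
is converted at the boundary; BED (0-based half-open) passes through
unchanged.  An IES on the somatic (MAC) genome is a point insertion
(``mac_point``), because the IES itself is absent from the MAC product; on
the hybrid MAC+IES assembly the same IES occupies a span.

GFF3 dialect for IES annotations (modeled on MILRAA-style output):

* On the MAC assembly an IES row has ``start == end == mac_point``, meaning
  the IES is inserted *before* 0-based position ``mac_point``.
* Column 9 must carry ``ID=``; optional keys are ``retention_score`` (the
  fraction of reads supporting the unexcised form) and ``seq`` (the IES
  sequence).  Sequences may instead live in a companion FASTA keyed by ID.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, TextIO, Union

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Contig:
    """One assembly sequence: uppercase over {A,C,G,T,N}."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


class Genome:
    """Ordered collection of contigs; iteration order equals file order."""

    def __init__(self, contigs: Iterable[Contig] = ()):
        self._contigs: dict[str, Contig] = {}
        for c in contigs:
            self.add(c)

    def add(self, contig: Contig) -> None:
        if not contig.id:
            raise ValueError("contig id must be nonempty")
        if contig.id in self._contigs:
            raise ValueError(f"duplicate contig id: {contig.id!r}")
        bad = set(contig.seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"contig {contig.id!r} contains invalid characters: {sorted(bad)}"
            )
        self._contigs[contig.id] = contig

    def __getitem__(self, cid: str) -> Contig:
        return self._contigs[cid]

    def __contains__(self, cid: str) -> bool:
        return cid in self._contigs

    def __iter__(self) -> Iterator[Contig]:
        return iter(self._contigs.values())

    def __len__(self) -> int:
        return len(self._contigs)

    @property
    def ids(self) -> list[str]:
        return list(self._contigs)

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self)

    def gc_fraction(self) -> float:
        gc = sum(c.seq.count("G") + c.seq.count("C") for c in self)
        acgt = sum(c.length - c.seq.count("N") for c in self)
        return gc / acgt if acgt else float("nan")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return list(self) == list(other)


@dataclass(frozen=True)
class Interval:
    """Genomic interval, 0-based half-open, with a feature-type label."""

    contig: str
    start: int
    end: int
    strand: str = "."
    feature_type: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class IesRecord:
    """One internal eliminated sequence.

    ``mac_point`` is the 0-based MAC coordinate *before* which the IES is
    inserted; ``hybrid_span`` is the same IES as a span on the MAC+IES
    hybrid assembly, filled by :func:`ies_landscape.insert_ies`.
    """

    id: str
    contig: str
    mac_point: int
    seq: str
    retention_score: Optional[float] = None
    hybrid_span: Optional[Interval] = None

    def __post_init__(self):
        if self.retention_score is not None and not (
            0.0 <= self.retention_score <= 1.0
        ):
            raise ValueError(
                f"IES {self.id}: retention score out of range: {self.retention_score}"
            )
        if self.mac_point < 0:
            raise ValueError(f"IES {self.id}: negative mac_point")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReadPlacement:
    """An ungapped primary placement of one sequenced small-RNA read.

    ``read_seq`` is the read as sequenced 5'->3' (i.e. already the reverse
    complement of the reference for minus-strand placements).
    """

    read_id: str
    contig: str
    start: int
    end: int
    strand: str
    read_seq: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _open_text(path: Union[str, Path], mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: Union[str, Path]) -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Sequences are uppercased (soft-masking is not semantically used by any
    stage); characters outside {A,C,G,T,N} are rejected; record order is
    preserved.  Duplicate ids and empty files are errors.
    """
    genome = Genome()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            genome.add(Contig(rec.id, str(rec.seq).upper()))
    if len(genome) == 0:
        raise ValueError(f"no FASTA records in {path}")
    return genome


def write_fasta(genome: Genome, path: Union[str, Path], width: int = 60) -> None:
    with _open_text(path, "wt") as fh:
        for contig in genome:
            fh.write(f">{contig.id}\n")
            for i in range(0, contig.length, width):
                fh.write(contig.seq[i : i + width] + "\n")


def read_seq_dict(path: Union[str, Path]) -> dict[str, str]:
    """Read a FASTA of per-ID sequences (e.g. IES sequences) into a dict."""
    seqs: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate sequence id: {rec.id!r}")
            seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_seq_dict(seqs: dict[str, str], path: Union[str, Path], width: int = 60) -> None:
    with _open_text(path, "wt") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def parse_gff_attributes(col9: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in col9.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise ValueError(f"malformed GFF3 attribute: {part!r}")
        key, value = part.split("=", 1)
        attrs[key] = value
    return attrs


def _gff_rows(path: Union[str, Path]) -> Iterator[tuple[int, list[str]]]:
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            yield lineno, fields


def read_ies_gff(
    path: Union[str, Path],
    genome: Genome,
    feature_types: Sequence[str] = ("internal_eliminated_sequence", "IES"),
    seq_fasta: Optional[Union[str, Path]] = None,
) -> list[IesRecord]:
    """Read MAC-point IES annotations in the dialect described in the module docstring.

    ``seq_fasta`` supplies IES sequences for records lacking a ``seq=``
    attribute.  Missing sequences are an error listing the offending IDs.
    """
    companion = read_seq_dict(seq_fasta) if seq_fasta is not None else {}
    records: list[IesRecord] = []
    missing_seq: list[str] = []
    for lineno, f in _gff_rows(path):
        if f[2] not in feature_types:
            continue
        contig, start, end = f[0], int(f[3]), int(f[4])
        if contig not in genome:
            raise ValueError(f"{path}:{lineno}: unknown contig {contig!r}")
        if start != end:
            raise ValueError(
                f"{path}:{lineno}: MAC IES rows must be insertion points "
                f"(start == end), got {start}..{end}"
            )
        mac_point = start  # start == end == mac_point by dialect definition
        if mac_point > genome[contig].length:
            raise ValueError(
                f"{path}:{lineno}: point {mac_point} outside contig {contig!r}"
            )
        attrs = parse_gff_attributes(f[8])
        if "ID" not in attrs:
            raise ValueError(f"{path}:{lineno}: missing ID attribute")
        ies_id = attrs["ID"]
        seq = attrs.get("seq", companion.get(ies_id, "")).upper()
        if not seq:
            missing_seq.append(ies_id)
            continue
        score = None
        if "retention_score" in attrs:
            score = float(attrs["retention_score"])
            if not (0.0 <= score <= 1.0):
                raise ValueError(
                    f"{path}:{lineno}: IES {ies_id}: score out of range: {score}"
                )
        records.append(
            IesRecord(
                id=ies_id,
                contig=contig,
                mac_point=mac_point,
                seq=seq,
                retention_score=score,
            )
        )
    if missing_seq:
        shown = ", ".join(missing_seq[:10])
        raise ValueError(
            f"{path}: {len(missing_seq)} IES records lack a sequence "
            f"(no seq= attribute and no companion FASTA entry): {shown}"
        )
    return records


def write_ies_gff(
    records: Sequence[IesRecord],
    path: Union[str, Path],
    embed_seq: bool = False,
    source: str = "ieslandscape",
) -> None:
    """Write MAC-point IES rows (start == end == mac_point)."""
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            attrs = [f"ID={rec.id}"]
            if rec.retention_score is not None:
                attrs.append(f"retention_score={rec.retention_score:g}")
            if embed_seq:
                attrs.append(f"seq={rec.seq}")
            fh.write(
                "\t".join(
                    [
                        rec.contig,
                        source,
                        "internal_eliminated_sequence",
                        str(rec.mac_point),
                        str(rec.mac_point),
                        ".",
                        ".",
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_gff_intervals(
    path: Union[str, Path],
    feature_types: Optional[Sequence[str]] = None,
    type_map: Optional[dict[str, str]] = None,
) -> list[Interval]:
    """Read ordinary (span) GFF3 rows into internal 0-based half-open intervals.

    ``feature_types`` restricts column 3; ``type_map`` renames feature types
    (e.g. {"tRNA": "exclude"}).
    """
    out: list[Interval] = []
    for lineno, f in _gff_rows(path):
        ftype = f[2]
        if feature_types is not None and ftype not in feature_types:
            continue
        if type_map:
            ftype = type_map.get(ftype, ftype)
        start1, end1 = int(f[3]), int(f[4])
        if start1 < 1 or end1 < start1:
            raise ValueError(f"{path}:{lineno}: bad GFF3 coordinates {start1}..{end1}")
        strand = f[6] if f[6] in ("+", "-") else "."
        out.append(Interval(f[0], start1 - 1, end1, strand, ftype))
    return out


def write_gff_intervals(
    intervals: Sequence[Interval],
    path: Union[str, Path],
    source: str = "ieslandscape",
    ids: Optional[Sequence[str]] = None,
) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for i, iv in enumerate(intervals):
            attr = f"ID={ids[i]}" if ids is not None else f"ID=feat{i}"
            fh.write(
                "\t".join(
                    [
                        iv.contig,
                        source,
                        iv.feature_type or "region",
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand,
                        ".",
                        attr,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(
    path: Union[str, Path],
    read_seqs: Optional[dict[str, str]] = None,
) -> list[Union[Interval, ReadPlacement]]:
    """Read BED3/BED6.

    BED6 rows become :class:`ReadPlacement` (name = read id); BED3 rows
    become plain :class:`Interval` with strand ".".  ``read_seqs`` attaches
    read sequences by id.
    """
    out: list[Union[Interval, ReadPlacement]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            contig, start, end = f[0], int(f[1]), int(f[2])
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            if len(f) >= 6:
                name, strand = f[3], f[5]
                if strand not in ("+", "-", "."):
                    raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
                seq = (read_seqs or {}).get(name, "")
                out.append(ReadPlacement(name, contig, start, end, strand, seq))
            else:
                out.append(Interval(contig, start, end, ".", ""))
    return out


def write_bed(
    placements: Sequence[ReadPlacement], path: Union[str, Path]
) -> None:
    with _open_text(path, "wt") as fh:
        for p in placements:
            fh.write(
                f"{p.contig}\t{p.start}\t{p.end}\t{p.read_id}\t{p.length}\t{p.strand}\n"
            )


# ---------------------------------------------------------------------------
# Interval arithmetic (sorted half-open tuples per contig)
# ---------------------------------------------------------------------------


def merge_spans(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open spans as a sorted non-overlapping list."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(spans):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_spans(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """a minus b; both must be sorted non-overlapping half-open span lists."""
    out: list[tuple[int, int]] = []
    bi = 0
    for s, e in a:
        cur = s
        while bi < len(b) and b[bi][1] <= cur:
            bi += 1
        j = bi
        while j < len(b) and b[j][0] < e:
            bs, be = b[j]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            j += 1
        if cur < e:
            out.append((cur, e))
    return out


def group_spans(intervals: Iterable[Interval]) -> dict[str, list[tuple[int, int]]]:
    """Merge intervals into per-contig sorted span lists."""
    d: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        d.setdefault(iv.contig, []).append((iv.start, iv.end))
    return {cid: merge_spans(v) for cid, v in d.items()}


# ---------------------------------------------------------------------------
# TSV report helpers
# ---------------------------------------------------------------------------


def write_tsv(
    path: Union[str, Path],
    header: Sequence[str],
    rows: Iterable[Sequence],
    comments: Sequence[str] = (),
) -> None:
    """Tab-separated report with a header row and '#' comment lines."""
    with _open_text(path, "wt") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
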