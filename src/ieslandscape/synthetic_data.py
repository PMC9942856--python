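"""Ground-truth generator for every structure the pipeline measures.

Simulates an AT-rich somatic (MAC) genome with a gene-dense layout, plants
IESs with known terminal direct repeats, length-peak structure, mobile and
nested repeat-family copies (TSD + TIR signatures), degenerate partial
copies, and developmental small-RNA time courses with configurable length
mixtures, feature-origin mixtures and 5'-U bias.

Every planted structure is recorded in a :class:`SimTruth` so downstream
measurements can be checked against exact ground truth.  The generator
owns the MAC sequence, so junction bases are set to make each planted
terminal repeat exact: the MDS copy of the TDR is written into the MAC at
the insertion site, the bases immediately beyond both repeat copies are
forced to mismatch (no accidental repeat extension), and the base left of
the insertion point is forced to differ from the IES's last base (every
record is emitted already left-normalized).

All draws come from per-submodule numpy Generators spawned from one seed,
so reruns are byte-identical and adding sRNA reads does not perturb the
genome draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from .io_formats import (
    Contig,
    merge_spans,
    subtract_spans,
    Genome,
    IesRecord,
    Interval,
    ReadPlacement,
    revcomp,
)
from .ies_landscape import Liftover, insert_ies
from .repeat_mites import RepeatCopy, RepeatFamily, load_preset_families

BASES = "ACGT"

# Packaged length-peak preset.  The periodic centers interpolate a 10-11 bp
# ladder around the anchor peaks at 65, 72 and 110 bp; the nonperiodic
# centers are the isolated long-IES peaks.  The ~389 bp class is supplied by
# the MITE family rather than listed here.
PERIODIC_PEAK_CENTERS = (65, 72, 83, 93, 104, 110)
NONPERIODIC_PEAK_CENTERS = (153, 174, 228)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class FamilySimConfig:
    """How many copies of one repeat family to plant, and how degenerate."""

    name: str
    n_mobile: int = 0  # IESs whose TDR is the family TSD and termini its TIR
    n_nested: int = 0  # full-length copies nested inside longer host IESs
    n_partial: int = 0  # truncated, higher-divergence copies in host IESs
    element_len: int = 389  # full element length (TIR..TIR inclusive)
    divergence_pct: float = 0.0  # point-mutation rate for mobile/nested copies
    partial_divergence_range: tuple[float, float] = (5.0, 15.0)
    partial_len_range: tuple[float, float] = (0.4, 0.8)  # fraction of element
    host_len: int = 900  # host IES length for nested/partial copies
    microsat_unit: Optional[str] = None
    microsat_copies_range: tuple[int, int] = (5, 12)
    p_microsat: float = 0.0  # fraction of mobile copies carrying the microsat


@dataclass
class IesSimConfig:
    """Counts, terminal-repeat motif mixture and length mixture for plain IESs."""

    n: int = 6000
    # TDR motif weights; "" plants no terminal repeat, "OTHER" draws a random
    # non-TA 2-mer.  TA-containing motifs make the IES TA-bound.
    tdr_weights: dict[str, float] = field(
        default_factory=lambda: {
            "TA": 0.50,
            "TAT": 0.16,
            "TATA": 0.10,
            "OTHER": 0.16,
            "": 0.08,
        }
    )
    periodic_peaks: dict[int, float] = field(
        default_factory=lambda: {c: 0.10 for c in PERIODIC_PEAK_CENTERS}
    )
    nonperiodic_peaks: dict[int, float] = field(
        default_factory=lambda: {c: 0.08 for c in NONPERIODIC_PEAK_CENTERS}
    )
    peak_sigma: float = 1.0
    offpeak_range: tuple[int, int] = (50, 600)  # uniform tail, remaining weight
    p_intragenic: float = 0.70
    n_spurious: int = 120  # short or low-retention records the filter removes
    retention_range: tuple[float, float] = (0.12, 0.90)


@dataclass
class TimepointSimConfig:
    """One sRNA library in the developmental time course."""

    label: str
    n_reads: int = 20000
    # Read-length mixture over 18-30 nt; 22 and 24 nt dominate.
    length_weights: dict[int, float] = field(
        default_factory=lambda: {
            **{L: 0.38 / 11 for L in range(18, 31) if L not in (22, 24)},
            22: 0.32,
            24: 0.30,
        }
    )
    # Feature-origin mixture keyed by read length (fallback "default").
    origin_weights: dict[Union[int, str], dict[str, float]] = field(
        default_factory=lambda: {
            "default": {"IES": 0.05, "CDS": 0.57, "NON": 0.36, "EXCLUDED": 0.02}
        }
    )
    p_five_prime_u: dict[Union[int, str], float] = field(
        default_factory=lambda: {24: 0.90, "default": 0.30}
    )

    def origin_for(self, length: int) -> dict[str, float]:
        return self.origin_weights.get(length, self.origin_weights["default"])

    def p5u_for(self, length: int) -> float:
        return self.p_five_prime_u.get(length, self.p_five_prime_u["default"])


def default_timecourse() -> list[TimepointSimConfig]:
    """scnRNA-like schedule: 24 nt IES-origin weight rises after the 14 h
    switch while the CDS weight falls; other lengths stay CDS/NON-dominated."""
    schedule = {
        "02h": 0.05,
        "14h": 0.15,
        "22h": 0.35,
        "38h": 0.55,
    }
    tps = []
    for label, w_ies in schedule.items():
        w_cds = max(0.10, 0.70 - w_ies)
        origin = {
            24: {"IES": w_ies, "CDS": w_cds, "NON": 1.0 - w_ies - w_cds},
            "default": {"IES": 0.04, "CDS": 0.56, "NON": 0.38, "EXCLUDED": 0.02},
        }
        tps.append(TimepointSimConfig(label=label, origin_weights=origin))
    return tps


@dataclass
class SimConfig:
    seed: int = 0
    n_contigs: int = 4
    contig_length: int = 600_000
    gc: float = 0.335
    gene_fraction: float = 0.77
    gene_len_mean: float = 2000.0
    gene_len_sd: float = 400.0
    ies: IesSimConfig = field(default_factory=IesSimConfig)
    families: list[FamilySimConfig] = field(
        default_factory=lambda: [
            FamilySimConfig(
                name="BogoMITE",
                n_mobile=480,
                n_nested=40,
                n_partial=40,
                element_len=389,
            ),
            FamilySimConfig(
                name="BstTc1",
                n_mobile=30,
                n_nested=10,
                element_len=520,
                host_len=1100,
                microsat_unit="GGGAAGGACT",
                p_microsat=0.5,
            ),
        ]
    )
    srna: list[TimepointSimConfig] = field(default_factory=default_timecourse)
    min_site_separation: int = 160
    edge_margin: int = 80

    def __post_init__(self):
        if not (0.0 < self.gc < 1.0):
            raise ValueError(f"gc must be in (0,1): {self.gc}")
        if not (0.0 <= self.gene_fraction <= 1.0):
            raise ValueError(f"invalid gene fraction: {self.gene_fraction}")
        w = sum(self.ies.tdr_weights.values())
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"TDR motif weights must sum to 1, got {w}")
        peak_w = sum(self.ies.periodic_peaks.values()) + sum(
            self.ies.nonperiodic_peaks.values()
        )
        if peak_w > 1.0 + 1e-9:
            raise ValueError("peak weights exceed 1")


def config_from_yaml(path: Union[str, Path]) -> SimConfig:
    """Load a SimConfig from YAML; keys mirror the dataclass fields and
    missing keys take the package defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "ies" in kwargs:
        ies = dict(kwargs["ies"])
        for key in ("periodic_peaks", "nonperiodic_peaks"):
            if key in ies:
                ies[key] = {int(k): float(v) for k, v in ies[key].items()}
        for key in ("offpeak_range", "retention_range"):
            if key in ies:
                ies[key] = tuple(ies[key])
        kwargs["ies"] = IesSimConfig(**ies)
    if "families" in kwargs:
        fams = []
        for f in kwargs["families"]:
            f = dict(f)
            for key in (
                "partial_divergence_range",
                "partial_len_range",
                "microsat_copies_range",
            ):
                if key in f:
                    f[key] = tuple(f[key])
            fams.append(FamilySimConfig(**f))
        kwargs["families"] = fams
    if "srna" in kwargs:
        tps = []
        for t in kwargs["srna"]:
            t = dict(t)
            if "length_weights" in t:
                t["length_weights"] = {
                    int(k): float(v) for k, v in t["length_weights"].items()
                }
            for key in ("origin_weights", "p_five_prime_u"):
                if key in t:
                    t[key] = {
                        (int(k) if str(k).isdigit() else k): v
                        for k, v in t[key].items()
                    }
            tps.append(TimepointSimConfig(**t))
        kwargs["srna"] = tps
    return SimConfig(**kwargs)


# ---------------------------------------------------------------------------
# Truth bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class IesTruth:
    ies_id: str
    tdr_motif: str
    ta_bound: bool
    length: int
    category: str  # periodic/nonperiodic/offpeak/family-mobile/host/spurious
    peak_center: Optional[int] = None
    family: Optional[str] = None
    family_status: str = "NONE"  # MOBILE_IES / NESTED / NONE
    planted_tir_len: int = 0
    intragenic: bool = False
    should_filter: bool = False
    has_microsat: bool = False


@dataclass
class ReadTruth:
    read_id: str
    origin: str  # IES / CDS / NON / EXCLUDED
    length: int
    five_prime_forced: bool


@dataclass
class SimTruth:
    config: SimConfig
    ies: dict[str, IesTruth] = field(default_factory=dict)
    repeat_copies: list[RepeatCopy] = field(default_factory=list)
    reads: dict[str, dict[str, ReadTruth]] = field(default_factory=dict)

    def planted_peak_centers(self, min_copies: int = 300) -> list[int]:
        """Length-histogram peak centers the generator plants.

        Mobile family IESs have deterministic length TSD + element (unless a
        microsatellite is inserted), so an abundant family contributes a
        sharp peak of its own.
        """
        centers = set(self.config.ies.periodic_peaks) | set(
            self.config.ies.nonperiodic_peaks
        )
        for fam in self.config.families:
            if fam.n_mobile >= min_copies and fam.p_microsat == 0.0:
                tsd_len = min(
                    len(m) for m in _family_signature(fam).tsd_motifs
                )
                centers.add(fam.element_len + tsd_len)
        return sorted(centers)

    def ta_bound_fraction(self, kept_only: bool = True) -> float:
        pool = [
            t
            for t in self.ies.values()
            if not (kept_only and t.should_filter)
        ]
        return sum(t.ta_bound for t in pool) / len(pool)


_PRESETS: Optional[dict[str, RepeatFamily]] = None


def _family_signature(fam_cfg: FamilySimConfig) -> RepeatFamily:
    global _PRESETS
    if _PRESETS is None:
        _PRESETS = {f.name: f for f in load_preset_families()}
    if fam_cfg.name not in _PRESETS:
        raise ValueError(f"unknown repeat family {fam_cfg.name!r} (no preset)")
    return _PRESETS[fam_cfg.name]


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------


def simulate_genome(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[Genome, list[Interval], list[Interval]]:
    """Simulate the MAC assembly plus gene and tRNA/rRNA intervals.

    Bases are i.i.d. with P(G) = P(C) = gc/2; genes are tiled with
    intergenic gaps sized so genic coverage approximates ``gene_fraction``;
    short tRNA/rRNA features are dropped into a subset of the gaps.
    Deterministic given the config seed.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[0])
    p = np.array(
        [(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2]
    )
    genome = Genome()
    genes: list[Interval] = []
    excludes: list[Interval] = []
    base_arr = np.frombuffer(BASES.encode(), dtype="S1")
    for ci in range(config.n_contigs):
        cid = f"contig_{ci + 1}"
        L = config.contig_length
        if L < 4 * (config.gene_len_mean + 4 * config.gene_len_sd):
            raise ValueError(f"contig length {L} too short for requested features")
        draws = rng.choice(4, size=L, p=p)
        seq = base_arr[draws].tobytes().decode()
        genome.add(Contig(cid, seq))
        if config.gene_fraction <= 0:
            continue
        pos = 0
        gap_count = 0
        f = config.gene_fraction
        while True:
            gene_len = max(300, int(rng.normal(config.gene_len_mean, config.gene_len_sd)))
            gap_len = max(30, int(gene_len * (1.0 / f - 1.0) * rng.uniform(0.7, 1.3)))
            # Leading gap, then the gene.
            gap_start = pos
            pos += gap_len
            if pos + gene_len > L:
                break
            # Occasionally park a tRNA or rRNA feature inside the gap.
            gap_count += 1
            if gap_count % 15 == 0 and gap_len >= 200:
                ftype = "tRNA" if gap_count % 30 else "rRNA"
                flen = 80 if ftype == "tRNA" else 150
                fstart = gap_start + (gap_len - flen) // 2
                excludes.append(Interval(cid, fstart, fstart + flen, "+", ftype))
            genes.append(Interval(cid, pos, pos + gene_len, "+", "CDS"))
            pos += gene_len
    return genome, genes, excludes


# ---------------------------------------------------------------------------
# IES and repeat planting
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, float]:
    """Uniform random point mutations at ``rate``; returns (seq, realized %)."""
    if rate <= 0 or not seq:
        return seq, 0.0
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < rate / 100.0)[0]
    for i in hits:
        choices = [b for b in BASES if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr), 100.0 * len(hits) / len(arr)


class _SitePlanner:
    """Samples non-colliding IES insertion points on the MAC assembly."""

    def __init__(self, genome: Genome, genes: Sequence[Interval], config: SimConfig,
                 rng: np.random.Generator, forbidden: Sequence[Interval] = ()):
        self.rng = rng
        self.sep = config.min_site_separation
        self.margin = config.edge_margin
        self.forbidden: dict[str, list[tuple[int, int]]] = {}
        for iv in forbidden:
            self.forbidden.setdefault(iv.contig, []).append((iv.start, iv.end))
        self.lengths = {c.id: c.length for c in genome}
        self.ids = list(self.lengths)
        self.taken: dict[str, list[int]] = {cid: [] for cid in self.ids}
        self.genes_by_contig: dict[str, list[Interval]] = {}
        for g in genes:
            self.genes_by_contig.setdefault(g.contig, []).append(g)
        self.gene_list = list(genes)
        total = sum(self.lengths.values())
        self.contig_probs = [self.lengths[c] / total for c in self.ids]

    def _free(self, cid: str, point: int) -> bool:
        from bisect import bisect_left

        pts = self.taken[cid]
        i = bisect_left(pts, point)
        if i > 0 and point - pts[i - 1] < self.sep:
            return False
        if i < len(pts) and pts[i] - point < self.sep:
            return False
        return True

    def claim(self, intragenic: bool) -> tuple[str, int, bool]:
        """Returns (contig, point, actually_intragenic)."""
        from bisect import insort

        for _ in range(400):
            if intragenic and self.gene_list:
                g = self.gene_list[self.rng.integers(0, len(self.gene_list))]
                cid = g.contig
                point = int(self.rng.integers(g.start + 5, g.end - 5))
            else:
                cid = self.ids[
                    self.rng.choice(len(self.ids), p=self.contig_probs)
                ]
                point = int(
                    self.rng.integers(self.margin, self.lengths[cid] - self.margin)
                )
                if intragenic is False and self._in_gene(cid, point):
                    continue
            if point < self.margin or point > self.lengths[cid] - self.margin:
                continue
            # never insert inside a tRNA/rRNA feature: the lifted feature
            # would swallow the IES span and break read-origin truth
            if any(s < point < e for s, e in self.forbidden.get(cid, ())):
                continue
            if self._free(cid, point):
                insort(self.taken[cid], point)
                return cid, point, self._in_gene(cid, point)
        raise RuntimeError(
            "could not place IES insertion point; genome too crowded "
            "(reduce IES count or site separation)"
        )

    def _in_gene(self, cid: str, point: int) -> bool:
        from bisect import bisect_right

        genes = self.genes_by_contig.get(cid, [])
        # linear scan is fine at these densities; genes are sorted by start
        for g in genes:
            if g.start <= point < g.end:
                return True
            if g.start > point:
                break
        return False


def simulate_ies_repeats(
    genome: Genome,
    genes: Sequence[Interval],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    excludes: Sequence[Interval] = (),
) -> tuple[list[IesRecord], list[RepeatCopy], Genome, Genome, Liftover, SimTruth]:
    """Plant IESs and repeat-family copies; returns (records, repeat copies,
    final MAC genome, hybrid genome, liftover, truth).

    The MAC sequence is edited at each insertion site so the planted TDR is
    exact and already left-normalized (see module docstring); the hybrid
    genome is then built by inserting every IES sequence, and excising all
    hybrid spans reproduces the returned MAC genome byte-for-byte.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[1])
    mac = {c.id: bytearray(c.seq.encode()) for c in genome}
    planner = _SitePlanner(genome, genes, config, rng, forbidden=excludes)
    truth = SimTruth(config=config)
    plan: list[dict] = []

    ies_cfg = config.ies
    motifs = list(ies_cfg.tdr_weights)
    motif_w = np.array([ies_cfg.tdr_weights[m] for m in motifs])
    other_motifs = ["AT", "GC", "CG", "GG", "CC"]

    def draw_motif() -> str:
        m = motifs[rng.choice(len(motifs), p=motif_w)]
        if m == "OTHER":
            m = other_motifs[rng.integers(0, len(other_motifs))]
        return m

    # --- plain IESs -------------------------------------------------------
    peak_items = list(ies_cfg.periodic_peaks.items()) + list(
        ies_cfg.nonperiodic_peaks.items()
    )
    peak_w = sum(w for _, w in peak_items)
    cat_probs = [w for _, w in peak_items] + [1.0 - peak_w]
    for i in range(ies_cfg.n):
        cat = int(rng.choice(len(cat_probs), p=np.array(cat_probs)))
        if cat < len(peak_items):
            center = peak_items[cat][0]
            length = int(round(rng.normal(center, ies_cfg.peak_sigma)))
            category = (
                "periodic" if center in ies_cfg.periodic_peaks else "nonperiodic"
            )
            peak_center = center
        else:
            length = int(rng.integers(ies_cfg.offpeak_range[0], ies_cfg.offpeak_range[1] + 1))
            category, peak_center = "offpeak", None
        motif = draw_motif()
        length = max(length, len(motif) + 12)
        plan.append(
            dict(
                kind="plain",
                motif=motif,
                length=length,
                category=category,
                peak_center=peak_center,
            )
        )

    # --- spurious records the post-prediction filter should remove --------
    for i in range(ies_cfg.n_spurious):
        if rng.random() < 0.5:
            plan.append(
                dict(kind="spurious", motif="TA", length=int(rng.integers(16, 50)),
                     category="spurious", low_score=False)
            )
        else:
            plan.append(
                dict(kind="spurious", motif="TA", length=int(rng.integers(60, 400)),
                     category="spurious", low_score=True)
            )

    # --- repeat families ---------------------------------------------------
    for fam_cfg in config.families:
        sig = _family_signature(fam_cfg)
        tsd = min(sig.tsd_motifs, key=lambda m: (len(m), m))
        # keep the canonical (as-curated) motif orientation where possible
        if "TAA" in sig.tsd_motifs:
            tsd = "TAA"
        for i in range(fam_cfg.n_mobile):
            plan.append(dict(kind="mobile", fam=fam_cfg, sig=sig, tsd=tsd))
        for i in range(fam_cfg.n_nested):
            plan.append(dict(kind="nested", fam=fam_cfg, sig=sig))
        for i in range(fam_cfg.n_partial):
            plan.append(dict(kind="partial", fam=fam_cfg, sig=sig))

    # --- realize the plan ---------------------------------------------------
    records: list[IesRecord] = []
    nested_specs: list[tuple[str, int, int, float, str]] = []  # id, off, len, div, fam
    order = rng.permutation(len(plan))
    for serial, pi in enumerate(order):
        item = plan[pi]
        ies_id = f"IES{serial + 1:05d}"
        fam_cfg: Optional[FamilySimConfig] = item.get("fam")
        sig: Optional[RepeatFamily] = item.get("sig")
        has_microsat = False
        planted_tir = 0
        family_status = "NONE"
        if item["kind"] in ("plain", "spurious"):
            motif = item["motif"]
            seq = motif + _random_seq(rng, item["length"] - len(motif))
            category = item["category"]
            peak_center = item.get("peak_center")
        elif item["kind"] == "mobile":
            motif = item["tsd"]
            tir = sig.tir_consensus
            core_len = fam_cfg.element_len - 2 * len(tir)
            core = _random_seq(rng, core_len)
            if fam_cfg.microsat_unit and rng.random() < fam_cfg.p_microsat:
                ncopies = int(
                    rng.integers(
                        fam_cfg.microsat_copies_range[0],
                        fam_cfg.microsat_copies_range[1] + 1,
                    )
                )
                ms = fam_cfg.microsat_unit * ncopies
                at = int(rng.integers(20, max(21, core_len - len(ms) - 20)))
                core = core[:at] + ms + core[at:]
                has_microsat = True
            # keep the planted TIR length exact: the core ends must not be
            # reverse-complementary, or the TIR would extend by chance
            if core and core[0] == revcomp(core[-1]):
                repl = [b for b in BASES if b != revcomp(core[0])]
                core = core[:-1] + repl[rng.integers(0, len(repl))]
            element, _ = _mutate(
                rng, tir + core + revcomp(tir), fam_cfg.divergence_pct
            )
            seq = motif + element
            category = "family-mobile"
            peak_center = None
            planted_tir = len(tir)
            family_status = "MOBILE_IES"
        else:  # nested or partial: a host IES containing an interior copy
            motif = "TA"
            tir = sig.tir_consensus
            if item["kind"] == "nested":
                elem_len = fam_cfg.element_len
                div = fam_cfg.divergence_pct
                family_status = "NESTED"
            else:
                frac = rng.uniform(*fam_cfg.partial_len_range)
                elem_len = int(fam_cfg.element_len * frac)
                div = rng.uniform(*fam_cfg.partial_divergence_range)
                family_status = "NONE"  # partial copies are not nested calls
            core_len = max(0, elem_len - 2 * len(tir))
            element = (tir + _random_seq(rng, core_len) + revcomp(tir))[:elem_len]
            element, realized_div = _mutate(rng, element, div)
            host_len = max(fam_cfg.host_len, elem_len + 120)
            cp1 = int(rng.integers(50, host_len - elem_len - 50))
            head = _random_seq(rng, cp1 - len(motif))
            tail = _random_seq(rng, host_len - cp1 - elem_len)
            seq = motif + head + element + tail
            nested_specs.append((ies_id, cp1, elem_len, realized_div, sig.name))
            category = "family-host"
            peak_center = None

        intragenic_wanted = rng.random() < ies_cfg.p_intragenic
        cid, point, intragenic = planner.claim(intragenic_wanted)
        contig = mac[cid]

        # Write the MDS copy of the TDR into the MAC right of the point.
        k = len(motif)
        contig[point : point + k] = motif.encode()
        # Prevent repeat extension: base after the MDS copy must differ from
        # the IES base after the in-IES copy.
        nxt = seq[k] if len(seq) > k else None
        if nxt is not None and chr(contig[point + k]) == nxt:
            contig[point + k] = ord([b for b in BASES if b != nxt][rng.integers(0, 3)])
        # Left-normalization: MAC base left of the point differs from the
        # IES's last base.
        if chr(contig[point - 1]) == seq[-1]:
            contig[point - 1] = ord(
                [b for b in BASES if b != seq[-1]][rng.integers(0, 3)]
            )

        score_lo, score_hi = ies_cfg.retention_range
        if item["kind"] == "spurious" and item["low_score"]:
            score = rng.uniform(0.0, 0.07)
        else:
            score = rng.uniform(score_lo, score_hi)
        records.append(
            IesRecord(
                id=ies_id,
                contig=cid,
                mac_point=point,
                seq=seq,
                retention_score=round(float(score), 4),
            )
        )
        truth.ies[ies_id] = IesTruth(
            ies_id=ies_id,
            tdr_motif=motif,
            ta_bound="TA" in motif,
            length=len(seq),
            category=category,
            peak_center=peak_center,
            family=sig.name if sig else None,
            family_status=family_status,
            planted_tir_len=planted_tir,
            intragenic=intragenic,
            should_filter=item["kind"] == "spurious",
            has_microsat=has_microsat,
        )

    mac_final = Genome(
        Contig(cid, bytes(arr).decode()) for cid, arr in mac.items()
    )
    records.sort(key=lambda r: (r.contig, r.mac_point))
    hybrid, liftover, records = insert_ies(mac_final, records)

    # Repeat-copy annotations on the hybrid assembly.
    copies: list[RepeatCopy] = []
    span_by_id = {r.id: r.hybrid_span for r in records}
    for rec in records:
        t = truth.ies[rec.id]
        if t.category == "family-mobile":
            span = span_by_id[rec.id]
            tsd_len = len(t.tdr_motif)
            copies.append(
                RepeatCopy(
                    family=t.family,
                    interval=Interval(
                        span.contig,
                        span.start + tsd_len,
                        span.end,
                        ".",
                        f"repeat:{t.family}",
                    ),
                    divergence_pct=round(
                        _config_divergence(config, t.family), 4
                    ),
                )
            )
    for ies_id, off, elem_len, div, fam_name in nested_specs:
        span = span_by_id[ies_id]
        copies.append(
            RepeatCopy(
                family=fam_name,
                interval=Interval(
                    span.contig,
                    span.start + off,
                    span.start + off + elem_len,
                    ".",
                    f"repeat:{fam_name}",
                ),
                divergence_pct=round(div, 4),
            )
        )
    truth.repeat_copies = copies
    return records, copies, mac_final, hybrid, liftover, truth


def _config_divergence(config: SimConfig, fam_name: str) -> float:
    for f in config.families:
        if f.name == fam_name:
            return f.divergence_pct
    return 0.0


# ---------------------------------------------------------------------------
# Interval arithmetic for sRNA origin pools
# ---------------------------------------------------------------------------




def _pool(
    per_contig: dict[str, list[tuple[int, int]]], min_len: int
) -> list[tuple[str, int, int]]:
    flat = [
        (cid, s, e)
        for cid, ivs in per_contig.items()
        for s, e in ivs
        if e - s >= min_len
    ]
    if not flat:
        raise ValueError("empty origin pool")
    return flat


# ---------------------------------------------------------------------------
# sRNA time-course simulation
# ---------------------------------------------------------------------------


def simulate_srna_timecourse(
    hybrid: Genome,
    ies_spans: Sequence[Interval],
    cds_hybrid: Sequence[Interval],
    exclude_hybrid: Sequence[Interval],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, list[ReadPlacement]], SimTruth]:
    """Simulate sRNA read placements for every configured time point.

    Reads are drawn from each time point's (length mixture x feature-origin
    mixture); a read of origin F is placed uniformly within a uniformly
    chosen interval of F's pool, where the CDS pool excludes IES and
    tRNA/rRNA bases and the NON pool excludes all annotated features — so
    the truth label matches the priority assignment rule exactly.  The
    first base is forced to T with the configured 5'-U probability.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])

    def group(ivs: Sequence[Interval]) -> dict[str, list[tuple[int, int]]]:
        d: dict[str, list[tuple[int, int]]] = {}
        for iv in ivs:
            d.setdefault(iv.contig, []).append((iv.start, iv.end))
        return {cid: merge_spans(v) for cid, v in d.items()}

    ies_g = group(ies_spans)
    cds_g = group(cds_hybrid)
    excl_g = group(exclude_hybrid)
    lengths = {c.id: c.length for c in hybrid}

    cds_clean = {
        cid: subtract_spans(subtract_spans(ivs, ies_g.get(cid, [])), excl_g.get(cid, []))
        for cid, ivs in cds_g.items()
    }
    non_clean = {}
    for cid, L in lengths.items():
        whole = [(0, L)]
        for other in (ies_g, cds_g, excl_g):
            whole = subtract_spans(whole, other.get(cid, []))
        non_clean[cid] = whole

    min_read = 18
    pools = {
        "IES": _pool(ies_g, 31),
        "CDS": _pool(cds_clean, 31),
        "NON": _pool(non_clean, 31),
    }
    if any(tp.origin_for(L).get("EXCLUDED", 0) > 0
           for tp in config.srna for L in tp.length_weights):
        pools["EXCLUDED"] = _pool(excl_g, 31)

    truth = SimTruth(config=config)
    out: dict[str, list[ReadPlacement]] = {}
    for tp in config.srna:
        placements: list[ReadPlacement] = []
        tp_truth: dict[str, ReadTruth] = {}
        read_lengths = sorted(tp.length_weights)
        lw = np.array([tp.length_weights[L] for L in read_lengths])
        lw = lw / lw.sum()
        for ri in range(tp.n_reads):
            L = read_lengths[rng.choice(len(read_lengths), p=lw)]
            ow = tp.origin_for(L)
            origins = sorted(ow)
            w = np.array([ow[o] for o in origins])
            origin = origins[rng.choice(len(origins), p=w / w.sum())]
            pool = pools[origin]
            cid, s, e = pool[rng.integers(0, len(pool))]
            start = int(rng.integers(s, e - L + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            ref = hybrid[cid].seq[start : start + L]
            seq = ref if strand == "+" else revcomp(ref)
            forced = False
            if rng.random() < tp.p5u_for(L):
                forced = seq[0] != "T"
                seq = "T" + seq[1:]
            rid = f"{tp.label}_r{ri + 1:06d}"
            placements.append(ReadPlacement(rid, cid, start, start + L, strand, seq))
            tp_truth[rid] = ReadTruth(rid, origin, L, forced)
        out[tp.label] = placements
        truth.reads[tp.label] = tp_truth
    return out, truth


# ---------------------------------------------------------------------------
# One-call driver
# ---------------------------------------------------------------------------


@dataclass
class Simulation:
    """Everything one simulation run produces, ready for the pipeline."""

    config: SimConfig
    mac: Genome
    hybrid: Genome
    genes: list[Interval]
    excludes: list[Interval]
    ies_records: list[IesRecord]
    repeat_copies: list[RepeatCopy]
    liftover: Liftover
    reads: dict[str, list[ReadPlacement]]
    truth: SimTruth

    @property
    def ies_spans(self) -> list[Interval]:
        return [r.hybrid_span for r in self.ies_records]

    @property
    def genes_hybrid(self) -> list[Interval]:
        return [self.liftover.lift_interval(g) for g in self.genes]

    @property
    def excludes_hybrid(self) -> list[Interval]:
        return [self.liftover.lift_interval(x) for x in self.excludes]


def simulate(config: SimConfig, with_srna: bool = True) -> Simulation:
    """Run the full generator with per-submodule random streams."""
    streams = np.random.SeedSequence(config.seed).spawn(3)
    g_rng, i_rng, s_rng = (np.random.default_rng(s) for s in streams)
    genome, genes, excludes = simulate_genome(config, g_rng)
    records, copies, mac_final, hybrid, liftover, truth = simulate_ies_repeats(
        genome, genes, config, i_rng, excludes=excludes
    )
    reads: dict[str, list[ReadPlacement]] = {}
    if with_srna and config.srna:
        lifted_genes = [liftover.lift_interval(g) for g in genes]
        lifted_excl = [liftover.lift_interval(x) for x in excludes]
        spans = [r.hybrid_span for r in records]
        reads, srna_truth = simulate_srna_timecourse(
            hybrid, spans, lifted_genes, lifted_excl, config, s_rng
        )
        truth.reads = srna_truth.reads
    return Simulation(
        config=config,
        mac=mac_final,
        hybrid=hybrid,
        genes=genes,
        excludes=excludes,
        ies_records=records,
        repeat_copies=copies,
        liftover=liftover,
        reads=reads,
        truth=truth,
    )
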