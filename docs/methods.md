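# Methods

## The editing landscape being measured

In ciliates, the somatic MAC genome is produced from the germline MIC
genome by eliminating thousands of internal eliminated sequences (IESs).
An IES is flanked by MAC-destined sequence (MDS) and typically bounded by a
terminal direct repeat (TDR, or "pointer"): a sequence present once inside
the IES and once in the adjacent MDS. Excision retains a single copy, so
the IES position is ambiguous within the repeat ("floating"). This package
characterizes a predicted IES set by its terminal repeats, length
structure, mobile-element content and small-RNA coverage, and ships a
generator that plants all of these structures with exact ground truth.

## Core procedures

**Left normalization.** While the last base of the left flank equals the
last base of the IES, the IES window slides one base left; the excision
product (left flank + right flank) is invariant under the slide, which is
why the convention is safe. All TDR/TIR statistics assume left-normalized
records, and every reported TDR starts at its left-most coordinate.

**TDR.** The TDR length *k* is the longest common prefix of the
(normalized) IES and its right MDS flank. `min_tdr = 2` defines
"TDR-bound": single-base repeats arise by chance at rate Σp² ≈ 0.28 under
the AT-rich composition and carry no signal. An IES is TA-bound when the
TDR contains `TA` anywhere, however long the TDR is.

**TIR.** After stripping the in-IES TDR copy (`strip="left"`, configurable
`none`/`left`/`both` because the boundary convention is genuinely
ambiguous in the field), base *i* from the 5' end is compared with the
complement of base *i* from the 3' end until the first mismatch, the
element midpoint, or the 25 bp cap. The cap is disabled (`cap=None`) when
curating full repeat-family elements, whose TIRs (30 and 38 bp in the
packaged preset) exceed it.

**Null model.** Repeat lengths under a composition-only null follow a
geometric law: with per-position match probability *m* (direct:
Σp_b²; inverted: Σp_b·p_comp(b)), the expected count at length exactly
*L* is *n·m^L·(1−m)*, which sums to *n* over L ≥ 0. Base frequencies are
estimated from the concatenation of all analyzed IES sequences and both
flanks (a user-supplied vector overrides) and echoed in `summary.json`.
This i.i.d. model ignores local composition heterogeneity and
dinucleotide structure; it is a deliberate, labeled simplification and is
validated against Monte-Carlo simulation in the acceptance suite.

**Length peaks and size classes.** Peaks are called on the 1 bp-binned
length histogram of TA-bound IESs only (other junction types have no
common alignment point). A peak is a bin strictly above both neighbors
with count ≥ 100; a plateau resolves to its leftmost bin (implemented via
`scipy.signal.find_peaks` with `plateau_size`, taking left edges). The
size-class range is the outermost contiguous run of bins ≥ half the peak
height. Each IES takes the label of the covering peak (ties: nearest
center, then smaller center), else `periodic-offpeak` within 65–115 bp,
else `nonperiodic-offpeak`. Periodicity is the median spacing of peak
centers inside the periodic range — robust to a single ±1 bp peak shift.

**Junction matrices.** Each TA-bound IES contributes two 24-position
junction strings (10 bp MDS + 14 bp IES, the TA itself excluded), anchored
on the leftmost `TA` of each TDR copy, with the right junction
reverse-complemented into 5'-(MDS)-TA-(IES)-3' orientation. Junctions with
insufficient flanking sequence are skipped and counted. Count matrices are
emitted (TSV); logo rendering is downstream. Note the mirror-image
identity (reverse-complementing the whole locus leaves the matrix
unchanged) is exact only when the anchor TA occurs once in the TDR; with
`TATA` the leftmost-TA rule picks different physical TAs in the two
orientations.

**Intragenic depletion.** A one-sided exact binomial lower tail:
P(X ≤ n_intragenic | n_total, genic_fraction), computed from log-gamma
binomial terms combined with logsumexp so that log10(p) remains finite far
below the float underflow limit (~1e-308). The binomial is this package's
choice of statistic; it assumes insertion points are independent and that
genic fraction is a fixed known quantity.

**Mobile IESs (MITIES).** An IES is a mobile-element copy of a family when
its TDR is one of the family's TSD motifs (exact, and the motif set is
closed under reverse complement) and, after stripping the TDR prefix, its
first and last |TIR| bases match the family TIR / its reverse complement
with mismatch fraction ≤ 0.10 per arm. The exact-TSD / tolerant-TIR split
reflects how such families present: TSDs coincide with junctions exactly,
while C-rich TIR runs vary (optionally collapse homopolymer runs ≥ 4
before comparison with `--collapse-homopolymers`). A non-mobile IES is
NESTED when an annotated family copy lies strictly inside its hybrid span
with ≥ 5 bp margin to either end (the field gives no minimum margin; 5 bp
is this package's configurable default). With 0.10 tolerance on a 30 bp
TIR, 2% uniform point mutations leave ≥ 98% of arms within tolerance,
while a random 30-mer passes with probability ≪ 1e-6 — hence the
sensitivity/specificity figures the acceptance suite checks.

**Microsatellites and triads.** The smallest tandem unit of a string is
its period, n − (longest border), via the KMP failure function; fractional
copy numbers are allowed. Arrays inside elements are located by a
window-scan (40 bp windows, unit ≤ 15 bp, ≥ 3 copies) followed by exact
extension. Catalytic-triad motifs are formatted as
r1 + r2 + (gap between 2nd and 3rd residues) + r3, e.g. `DD35D`, `DD34E`.

**sRNA quantification.** One primary placement per read. Assignment:
exclusion (tRNA/rRNA) first, then IES > CDS > NON, any ≥ 1 bp overlap;
each read counted once. RPKM = 10⁹·count / (total mapped × total
feature-type length); type totals are disjoint (CDS bases inside an IES or
an excluded feature are counted with the higher-priority type), mirroring
the assignment rule so RPKM denominators and counts describe the same
partition. The 5' base comes from the read as sequenced, so minus-strand
placements need no complementing.

## The synthetic-data generator

The generator is a pure function of (config, seed); per-submodule RNG
streams (genome / IES-planting / sRNA) are spawned from one seed so adding
reads never perturbs genome draws. Defaults describe the study system the
package targets: 4 × 600 kb contigs of i.i.d. bases at 33.5% GC, genes
tiled to ≈ 77% coverage (length ~N(2000, 400²), jittered gaps, short
tRNA/rRNA features in a subset of gaps), 6,000 plain IESs plus 120
filterable spurious records plus family copies (480 mobile BogoMITE, 40
nested, 40 degenerate partials; 30 mobile + 10 nested BstTc1 with a
planted `GGGAAGGACT` microsatellite in half the mobile copies).

TDR motifs are drawn from {TA 0.50, TAT 0.16, TATA 0.10, other non-TA
2-mers 0.16, none 0.08}, giving a TA-bound fraction around three-quarters
once the family IESs (whose TSDs all contain TA) are included. Lengths mix
discretized Gaussians (σ = 1) at the packaged peak preset — periodic
centers 65, 72, 83, 93, 104, 110 (a 10–11 bp ladder interpolating the
printed anchors; the interpolated members are a package choice, not a
reproduced table) and nonperiodic 153, 174, 228 — plus a uniform 50–600 bp
off-peak tail; the ~390 bp class arises from the planted MITE family
itself (3 bp TSD + 389 bp element). Mobile elements are built as
TSD + TIR + core + revcomp(TIR) inserted where the MAC carries the TSD, so
the planted TDR *is* the TSD; divergence is applied as uniform point
mutations to the element.

Because the generator owns the MAC sequence, it makes every planted
structure exact rather than merely likely: the MDS TDR copy is written at
the insertion site; the bases just beyond both repeat copies are forced to
mismatch (no chance extension); the base left of the insertion point
differs from the IES's last base (records are born left-normalized);
mobile cores are resampled when their ends happen to be
reverse-complementary (which would extend the TIR); and insertion points
avoid tRNA/rRNA interiors. sRNA reads are drawn per time point from a
length mixture (22 and 24 nt at 0.32/0.30) × feature-origin mixture, with
origin pools made disjoint (CDS minus IES minus excluded; NON minus
everything) so the planted origin equals the priority assignment for every
read — verified exactly in the tests. The default four-point time course
raises the 24 nt IES-origin weight 0.05 → 0.55 after the mid-course
switch while the CDS weight falls, with 5'-U probability 0.9 for 24-mers,
emulating an scnRNA-like schedule.

What the generator does **not** emulate: sequencing error, read mapping
ambiguity and multi-mappers, coverage variation, assembly artifacts,
scrambled or nested excision ambiguity, local composition heterogeneity,
and real gene structure (introns, UTRs). Passing recovery tests therefore
demonstrates correctness of the measurement code on clean planted signal,
not robustness to real-data noise.

## Problem sizes and numerics

The default simulation (2.4 Mbp, 6,720 IESs, 4 × 20,000 reads) runs in a
few seconds and is the scale at which the recovery suite operates — large
enough that every planted peak clears the 100-count cutoff with ~4σ margin
after restricting to TA-bound records, small enough for routine runs.
Monte-Carlo null validation uses 10⁵ junction pairs and compares per-bin
counts within 3 binomial SDs where the expectation is ≥ 10 (below that the
normal approximation has no power), with the remaining tail aggregated.
Oracle-equivalence suites run 10⁴ random instances per detector against
brute-force references. Ratios against a zero expectation are reported as
`NA`; an empty element yields TIR length 0; empty inputs yield empty
outputs rather than errors wherever the result is well defined.

## Known limitations

* TDR/TIR matching is exact (no probabilistic or fuzzy matching); the only
  tolerance is the mobile-IES TIR mismatch fraction.
* The composition null ignores dinucleotide and positional structure.
* Divergence of repeat copies is an input column (or generator truth), not
  recomputed by alignment.
* The intragenic test treats the genic fraction as fixed and insertions as
  independent.
* BAM/SAM input is not supported; read placements arrive as BED6 + FASTA.
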