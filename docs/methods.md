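# Methods

This note documents the models, parameter choices and numerical conventions
behind `mitobreaks`, and what the synthetic test bed does and does not
establish about real data.

## Coordinates and the circular genome

All coordinates are 1-based inclusive in light-strand (rCRS) numbering.
Wrapping intervals are encoded as a single region with `end < start`, so the
major arc (5,799→109) is one interval of size L − start + 1 + end. The four
built-in regions — major arc, minor arc, O<sub>H</sub> (110–441),
O<sub>L</sub> (5,721–5,798) — tile the 16,569 bp circle exactly once and are
validated position-by-position; other genome lengths require a user-supplied
partition (TSV: name, start, end, class). `N` bases are accepted (some rCRS
distributions carry a placeholder at position 3,107) but are excluded from
composition counts and contribute neither curvature deflection nor
bendability.

## Deletion tables

A breakpoint field may be a single position or a dash/en-dash interval (the
ambiguity left by a flanking direct repeat); intervals are collapsed to their
smallest value. Rows repeating both extremities of an earlier row are
dropped; rows sharing one breakpoint are distinct deletions. The removed span
is the open interval (5′, 3′) traversed 5′→3′ along the light strand. A
deletion is arc-exclusive when span and both breakpoints lie in one arc; any
span or breakpoint contact with O<sub>H</sub>/O<sub>L</sub> makes it
origin-involving. Density membership is edge-inclusive and wrap-aware, and
positions count with multiplicity, so density is invariant under interval
subdivision. A breakpoint lying exactly on a region boundary counts in the
single region that contains it under the partition (boundaries never overlap).

## Curvature and bendability

Curvature uses the dinucleotide wedge model: each step contributes a
deflection of magnitude `wedge` at angle `direction`, phased by the running
sum of helical twists; the profile value at a position is the magnitude of
the vector sum over a centered window, divided by the number of steps and
scaled by 10.5 to express degrees per helical turn. Because a constant phase
offset cannot change the magnitude of a contiguous window sum, the profile is
exactly rotation-equivariant on the circle; windows crossing the origin are
evaluated on a doubled sequence so the twist phase stays continuous.
Bendability assigns each trinucleotide's DNase-I sensitivity value to its
center base and averages over a centered window.

Parameter tables are plain dicts in `geometry_tables.py` so alternates can be
swapped: the Bolshoy–Trifonov twist/wedge/direction set (16 dinucleotides,
reverse-complement symmetric) and the Brukner trinucleotide scale (32
complement classes covering all 64 trinucleotides). The raw trinucleotide
scale is centered near zero, which would make a curvature/bendability
quotient undefined over half the genome; profiles therefore use the scale
shifted by +1.0 (range ≈ 0.72–1.19). The shift, windows (curvature 31 bp ≈
three helical turns; bendability 3 bp) and the peak threshold (ratio > 1.0)
are all configurable. Absolute profile values depend on these choices; the
analysis rests on peak *positions*, which are far less sensitive. Local
maxima are strict against the left half-window and non-strict against the
right, so the leftmost point of a plateau is reported; peaks are returned by
descending ratio. Peak bins are ±50 bp (101 bp) around each maximum.

## Quadruplex rule

A site is a maximal chain of G-runs (≥3 G) linked by gaps of 1–7 nt that can
supply at least four G₃ pieces. Loops may themselves contain G, so one
maximal run of length ℓ can contribute ⌊(ℓ+1)/4⌋ pieces (three G per piece,
one G spent as an internal loop); a single run of ≥15 G is a site on its own,
and extra runs at a locus extend the one reported site rather than producing
overlapping reports. Gaps longer than 7 can never be bridged, because
donating edge G's to a loop only lengthens it. The C-run analogue represents
the complementary strand; scanning is light-strand only, wrap-aware by
default. The test suite proves the scanner equivalent to an independent
greedy-regex enumeration on 1,000 random G-biased 500-mers.

## Composition windows

Non-overlapping windows (default 20 bp) tile from position 1; the trailing
partial window (9 bp on the reference length) is dropped, and breakpoints
falling there inherit the last full window's values. GC-skew is (G−C)/(G+C),
undefined when a window has no G or C. Genome means are per-window (the
convention of window-analysis tools); per-base means differ only in the
third decimal at 20 bp. Bin edges default to width 0.2 for skew over [−1,1]
and width 10 percentage points for GC, left-closed right-open.

## Motifs, distances and shuffles

IUPAC motifs are scanned as overlapping matches (a degenerate 11-mer occurs
hundreds of times on a 16.6 kb genome; excluding overlaps would be a strong
hidden assumption — a flag disables them), with wrap-spanning matches
included. The breakpoint–motif distance is 0 inside a match span, else the
circular distance to the nearest span edge; the 5 bp threshold is strict
(<5) and the 20 bp threshold inclusive (≤20), following the usual phrasing
of such cut-offs. Shuffle backgrounds (default 130 shuffles) preserve the
k-mer multiset exactly: k=1 by permutation, k≥2 by reserving a random
last-exit edge per de Bruijn vertex such that the reserved edges form an
arborescence into the terminal (k−1)-mer (rejection-sampled; the DNA graph
has ≤16 vertices at k=3, so retries are cheap), shuffling the remaining
out-edges and reading off the Euler path. Preserving k-mers preserves all
k′-mers for k′ ≤ k. Shuffled genomes are linear permutations, counted with
the same wrap convention as the original.

## Randomization statistics

The *random* model draws positions i.i.d. uniform with replacement; the
*partially random* model draws the prescribed count uniformly within each
region class (counts default to the observed dataset's). Defaults: 200
datasets, n equal to the observed breakpoint count. z uses the sample (n−1)
standard deviation; p = erfc(|z|/√2) is the two-sided normal tail. A null
with zero variance is flagged degenerate (z reported as 0 when the observed
value equals the constant null, NaN otherwise; p as 1). With 200 finite
datasets, z under its own null is slightly heavier-tailed than N(0,1)
(t-like, sd ≈ 1.02 at 60 datasets); the calibration tests allow for this. No
multiple-testing correction is applied; reports carry raw p-values and
significance stars (\*, \*\*, \*\*\* at 0.05, 0.01, 0.001).

## Synthetic test bed

The generator emulates exactly the statistical structure the analysis
assumes: i.i.d. per-segment base composition (default mtDNA light strand:
A .309, C .313, G .131, T .247, giving GC ≈ 44.4% and skew ≈ −0.41), literal
or IUPAC-sampled elements planted at known coordinates, and breakpoints from
a two-component mixture — probability π uniform over the ±d neighborhoods of
planted features, otherwise uniform on the circle. Defaults are study-scale:
L = 16,569, n = 1,508 breakpoints (754 deletions), π = 0.5, d = 10 bp. π is
re-estimated from data by inverting the mixture expectation
f = π + (1−π)·footprint. What the generator deliberately lacks: genic
structure, Markov dependence (a k=3 background option exists for shuffle
comparisons), replication mechanics, repeat-mediated deletion formation, and
any coupling between breakpoints and curvature or skew other than the
planted proximity. Passing tests therefore demonstrate that the machinery
measures what it claims on data satisfying its assumptions — not that real
mitochondrial breakpoints follow the mixture model.

## Problem sizes in the checked runs

The shipped drivers and the acceptance script use the full study scale
(16,569 bp, 1,508 breakpoints, 200 randomization datasets, 130 shuffles);
unit tests use smaller genomes (300–5,000 bp) and 10–60 null datasets, with
500 repetitions for the z-calibration property. Everything runs in seconds
on one CPU.

## Known limitations

- The curvature component depends on the embedded parameter tables and
  window defaults; other published wedge/bendability sets shift absolute
  values and can reorder minor peaks.
- Triplex and Z-DNA detection is not implemented; such elements enter only
  as annotated BED intervals.
- The interval-collapsing rule keeps the smallest breakpoint of a reported
  range, which biases positions leftward by up to the repeat length for
  repeat-flanked deletions.
- Region-boundary breakpoints are counted once, in their containing region;
  analyses that double-count boundary positions will differ marginally.
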