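# mitobreaks

Deletions of mitochondrial DNA accumulate in aged post-mitotic tissues and
cause a spectrum of human disorders. Their breakpoints are not scattered
uniformly around the 16,569 bp circular genome: they cluster near sequence
contexts that favour non-canonical (non-B) DNA — intrinsically curved but
rigid regions, long G-quadruplex-forming runs, strongly GC-skewed windows —
and near a degenerate pyrimidine-rich 11-mer, `YMMYMNNMMHM`
(Y = C/T, M = A/C, H = A/C/T, N = any).

`mitobreaks` is a tested reimplementation of that association analysis for
anyone studying mitochondrial genome instability: it parses curated deletion
tables, scans a circular genome for the candidate elements, stratifies
breakpoint density by sequence features, and quantifies enrichment with
randomization statistics. A synthetic-data generator with recoverable ground
truth makes every stage verifiable without downloading any reference data.

## What it computes

**Breakpoint spectrum.** Each deletion contributes a 5′ and a 3′ breakpoint
(light-strand rCRS coordinates; interval reports such as `7,508–7,515` are
collapsed to their smallest value, and rows repeating both extremities are
excluded). Densities are reported in breakpoints per 0.1 kb,
ρ = Σ breakpoints / Σ fragment sizes × 100, over the canonical partition:
major arc (5,799→109, wrapping the origin), minor arc (442–5,720), and the
replication origins O<sub>H</sub> (110–441) and O<sub>L</sub> (5,721–5,798).

**Non-B elements.** Canonical quadruplex-forming sites are maximal
non-overlapping matches of G≥3 N1–7 G≥3 N1–7 G≥3 N1–7 G≥3 (and the C-run
analogue) on the light strand, wrap-aware; annotated triplex/Z-DNA intervals
can be supplied as BED. Curvature is the windowed vector sum of dinucleotide
wedge geometries (degrees per helical turn, 10.5°/turn = 1°/bp); bendability
is the windowed trinucleotide DNase-I scale; their ratio flags curved, rigid,
topologically stressed regions whose local maxima define ±50 bp peak bins.

**Composition and motifs.** GC-content and GC-skew = (G−C)/(G+C) in
non-overlapping 20 bp windows; breakpoint density per skew/GC bin. IUPAC
motif scanning with overlap and wrap, breakpoint–motif distance thresholds
(<5 bp strict, ≤20 bp), and occurrence backgrounds from k-let-preserving
shuffles (k = 1 permutes bases; k = 3 walks a random Euler path on the
de Bruijn multigraph, conserving the trinucleotide multiset exactly).

**Enrichment.** An observed statistic P is compared with 200 randomized
breakpoint datasets — fully random (uniform, with replacement) or partially
random (preserving per-region abundances) — via
z = (P − P̄)/σ_P and the two-sided normal tail p = erfc(|z|/√2).

## Worked example

```
python analysis/01_simulate_fixture.py
python analysis/02_breakpoint_spectrum.py
python analysis/03_nonb_elements.py
python analysis/07_enrichment_tests.py
```

prints (seed 1):

```
754 deletions -> 1508 breakpoints (877 distinct)
density per 0.1 kb: global 9.10, major arc 11.32, minor arc 4.89

found 3 non-B elements:
  G1  6198-6222  density 580.0/0.1kb (planted)
  C1  8252-8281  density 383.3/0.1kb (planted)
  G2  15516-15530  density 506.7/0.1kb (planted)
pooled density 480.0 per 0.1 kb

planted_element_density [random]: observed 523, null 9.3 +/- 3.76, z 136.61 ***
planted_element_density [partially_random]: observed 523, null 11.9 +/- 4.35, z 117.34 ***
```

The fixture plants three quadruplex-forming sites in a genome with
mitochondrial light-strand composition and draws half of the 1,508
breakpoints within 10 bp of a planted feature. The scan recovers exactly the
planted sites (their spans may extend a few bases where the random background
happens to continue a G/C run), the global density matches the analytic
1,508/16,569 × 100 = 9.1 per 0.1 kb, and the planted elements carry a ~50×
local excess that both null models reject at z > 100. (Motif proximity shows
a mild *deficit*, z ≈ −3.8: the feature-proximal breakpoints sit inside G/C
runs, which the pyrimidine-rich degenerate motif avoids.) The same stages run
on real inputs by pointing the scripts (or `mitobreaks report`) at a genome
FASTA and deletion TSV.

There is also a CLI mirroring the stages:
`mitobreaks scan-quadruplex|composition|curvature|motif-scan|motif-background|enrich|simulate|report`.

## Layout

- `src/mitobreaks/` — the library (genome I/O, breakpoints, curvature,
  non-B scan, composition, motifs, randomization, synthetic data, pipeline, CLI)
- `analysis/` — numbered narrative drivers writing tables under `results/`
- `tests/` — unit, property and acceptance tests
- `docs/methods.md` — models, parameters, numerical choices, limitations
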