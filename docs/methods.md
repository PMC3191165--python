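# Methods

## The segmentation model

`chromoband` treats interband demarcation as consensus interval calling
over heterogeneous open-chromatin evidence. The assumptions are:

1. Interbands are short (sub-kb to few-kb) decompacted regions where
   several *orthogonal* open-chromatin signatures co-localize:
   interband-associated proteins, DNase I hypersensitivity, histone H1
   dips, ORC binding, active chromatin states, histone variant H3.3.
2. Any single track is noisy (spurious peaks, array gaps), but spurious
   features of *different* evidence classes rarely coincide.
3. Bands carry none of these signatures; they are simply the intervals
   between neighbouring interband borders.

Evidence is therefore counted per **class**, not per track: five
redundant interband-protein tracks still contribute one vote per base,
so they cannot outvote the absence of DHS or H1-dip evidence. Per-marker
tracks from multiple cell types are pooled first (default: union, since
interband positions are observed to be cell-type-invariant;
intersection and majority modes are available for sensitivity
analyses). The per-base class count is computed with a breakpoint sweep
(exactly equivalent to per-base voting, and tested against a literal
per-base oracle on ≤50 kb instances).

### Caller parameters

| parameter | default | rationale |
|---|---|---|
| `min_support` | 2 classes | one orthogonal confirmation; spurious cross-class coincidence is rare |
| `combine_cells` | union | interband positions are cell-type-invariant |
| `merge_gap` | 500 bp | one smoothing step of the 1 kb / 500 bp window |
| `min_size` / `max_size` | 300 bp / 10 kb | mapped interbands span ~600–3000 bp; gates are deliberately loose |
| `signal_cutoff` | 0.0 (M-value scale) | binarization of windowed profiles where pre-called enrichment regions are unavailable; no published cutoff exists, so enrichment means "above the log-ratio baseline" |

The candidate extent returned by `call_interbands` is the consensus run
itself (where ≥ `min_support` classes overlap); `refine_borders`
optionally widens a call to the outermost edges of the supporting
feature distributions ("edges" vs "peak" borders). Refined extents of
adjacent calls may touch; all disjointness guarantees are stated for
the consensus extents. Peak ties (several runs at the maximal count)
resolve to the leftmost run's midpoint.

## Track preprocessing

Windowed smoothing uses a 1 kb window advanced in 500 bp steps (the
convention of the tiling-array enrichment profiles this pipeline
consumes); each window's value is the mean of its *defined* bases —
array gaps are NaN and are excluded from the mean rather than
zero-filled, which would fabricate depletion; an all-NaN window stays
NaN. Insertion density is insertions per 1 kb within 10 kb windows,
half-open tiling, boundary positions counted to the window starting
there. Thresholding marks the footprint of every qualifying window and
returns maximal marked intervals, so two qualifying windows separated
by one failing window still produce the per-base-correct footprint
union.

## Coordinates and the reference tables

Internal coordinates are 0-based half-open. The bundled reference map
of region 9F13–10B3 prints 1-based pairs `s..e` whose printed length
equals `e − s`, with each element starting one base after its
predecessor's printed end. Pairs are converted as `[s−1, s−1+(e−s))`,
which reproduces every printed length exactly and makes consecutive
elements tile the 427,600 bp span without gaps. Under the source
table's own arithmetic one base per border belongs to neither
structure; this package resolves the ambiguity by keeping interband
extents exactly as printed and letting bands (built as the complement)
absorb the orphan border bases — band lengths therefore exceed the
printed values by 2 bp, which leaves every 2-decimal compaction value
unchanged.

The published region totals quoted in prose (20,100 bp of interbands in
428,307 bp, i.e. 4.69%) are not consistent with the printed
coordinates (18,400 bp in 427,600 bp, 4.30%). `summarize_region`
computes from coordinates; the 4.69% figure is reproduced only as a
worked example of `interband_fraction` applied to the stated totals.

## Compaction arithmetic

`c = b × 0.34 / 1000` µm (B-DNA rise of 0.34 nm/bp), `ratio = c / a`.
The table-faithful default rounds `c` to 2 decimals *before* dividing —
the convention under which reference compaction tables are
self-consistent (600 bp → 0.20 µm → 0.20/0.043 = 4.65, not the
full-precision 4.74) — and rounds the ratio to 2 decimals with ties at
the last decimal going toward zero (the one midpoint that occurs in the
reference data, 2.04/0.064 = 31.875, rounds to 31.87 under this
convention). A full-precision mode (`rounded_first=False`,
`rounded=False`) is exposed for analysis. Axial-length standard
deviations are carried through but not propagated into a ratio
uncertainty.

## Band classification

`IH_late` requires repressive evidence — late-replication coverage
≥ `t_late` (default 0.4: a known IH band completes replication late
over only the distal ~40% of its extent, and should still classify as
IH) *or* SUUR and lamin coverage both ≥ 0.5 — and zero overlap with
open-chromatin features. Everything else is `faint_early`. The rule is
monotone in `t_late`. The late-replication track is mandatory; missing
SUUR/lamin/open tracks are treated as empty.

## Interband genomic context

Precedence: `five_prime` (TSS ± 250 bp or 5′UTR overlap) > `first_exon`
> `intergenic` (no gene-body overlap) > `internal`. The 250 bp TSS slop
reflects that interbands are sub-kb structures; no published window
exists. The precedence order is declared explicitly because observed
interbands mix these categories freely; a `mixed` outcome is reserved
for distinct categories tying at the same precedence, which the
declared order makes unreachable — it exists as a defensive contract.
Whole-feature containment (for ORC-in-interband fractions) uses the
midpoint rule, since ORC peaks are point-like relative to interbands.

## The synthetic generator

`simulate.generate` plants a banding map and emulates its evidence:

- **Layout**: 9 interbands (600–3000 bp, uniform), flanked structure
  starting and ending with an interband (flag `flank="band"` for
  band-terminated regions); 2 IH bands (150–200 kb) at the outermost
  band slots enclosing 6 faint bands (2–17 kb) — the "two dark flanks
  around a paling of thin bands" structure.
- **Marker features**: each of the 6 evidence classes appears in each
  interband with probability `snr/(1+snr)`, borders jittered N(0, 25 bp)
  (≈ tiling-array probe resolution). Spurious features (100–600 bp,
  short like real noise peaks) fall as a Poisson process inside bands,
  confined to their band so noise can never bridge two interbands; with
  `false_feature_rate=None` the rate is calibrated so the odds that a
  feature is true versus spurious equal `snr` exactly.
- **Domains**: IH bands get SUUR, lamin and BLACK-state cover; the
  second IH band is late-replicating over only 45% of its extent (the
  partially-late IH case); faint bands are YELLOW with no open markers;
  interbands are RED.
- **Genes**: a deterministic layout cycles divergent-TSS-pair / 5′-end /
  intergenic-gap / first-exon contexts across interbands, with the last
  interband planted as the gene-internal exception — 8 of 9 interbands
  sit in open-chromatin-typical contexts.
- **Insertions**: Poisson, 2.0/kb in interbands vs 0.1/kb in bands.
- **Axial lengths**: back-computed as `c/ratio` with class-typical
  compaction ratios (interband 3–15, faint 10–75, IH 150–210).

One integer seed drives a single `numpy` generator stream with a fixed
draw order (element sizes → per-class presence and jitter → per-class
spurious features → insertions → axial ratios), so a seed reproduces
the truth bit-identically.

What the generator does **not** emulate: probe-level M-values or read
data, array gaps, correlated noise between evidence classes,
cell-type-specific differences, overlapping/isoform-rich gene
annotation, underreplication. Passing recovery tests therefore show the
calling rule is correct and robust to independent per-track noise at
realistic geometry — not that it is robust to systematically correlated
artefacts in real tiling-array data.

## Evaluation

Calls are matched to planted interbands by maximal overlap (ties to the
leftmost). Precision = overlapping calls / calls (1.0 with no calls),
recall = planted interbands hit / planted, mean Jaccard is taken over
planted interbands (0 for missed ones), border error is the mean
absolute edge displacement over matched pairs. At the default
conditions (snr = 10) and at snr = 5 the caller attains precision =
recall = 1 and mean Jaccard ≥ 0.9 on at least 18 of 20 seeds, and
degrades monotonically under feature deletion.

Problem sizes throughout the test suite and the acceptance script are
the study conditions themselves: the 17-element reference region
(427,600 bp) and 20 synthetic replicates of ~400 kb regions, which run
in seconds.

## Known limitations

- Single-region, single-chromosome scope; no genome-wide indexing, no
  bigWig/BAM ingestion (text BED/TSV/bedGraph only).
- No statistical significance model for enrichment: the caller consumes
  upstream "significant enrichment" intervals or a fixed M-value cutoff,
  and reports consensus, not probability. No HMM/Bayesian segmentation.
- Map comparison reports overlap/Jaccard only; observed discrepancies
  with legacy band tables are qualitative, so no significance test is
  attached.
- FISH probes are relatable to calls only by distance; two reference
  probes lie just outside their printed interband's extent, and
  `probe_concordance` reports such distances rather than asserting
  containment.
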