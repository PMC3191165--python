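# chromoband

Demarcating polytene-chromosome **band/interband borders on a physical
genome map** by integrating open-chromatin feature tracks, with the
downstream arithmetic a chromosome cytogeneticist needs: element lengths
and DNA fractions, EM-based DNA compaction ratios, band classification
(late-replicating intercalary heterochromatin vs early faint bands),
interband genomic context, ORC spacing and banding-map comparison.

Polytene chromosomes (e.g. *Drosophila* salivary gland) show a
reproducible alternation of condensed **bands** and decompacted
**interbands**. Interbands are open chromatin: they carry
interband-associated proteins (Chriz/CHRO, BEAF-32, WDS, BRE-1, RNA Pol
II), DNase I hypersensitive sites, dips in linker histone H1, the histone
variant H3.3, active chromatin states, and nearly all ORC
(origin-recognition-complex) binding. `chromoband` turns this
co-localization into a calling rule:

- each *evidence class* (interband proteins, DHS, H1 dips, ORC, active
  states, histone variants) contributes at most one vote per base;
- maximal runs with at least `min_support` (default 2) distinct classes
  become interband candidates; runs are merged across gaps ≤ 500 bp (one
  smoothing step) and gated to plausible interband sizes (0.3–10 kb);
- each call gets a consensus **peak** (leftmost midpoint of the
  maximal-count run) and, optionally, refined **edges** (outermost extent
  of the supporting feature distributions);
- bands are the complement: the stretches between neighbouring interband
  borders.

Bands are classified as `IH_late` when they are covered by
late-replication calls (fraction ≥ 0.4) or by SUUR *and* lamin domains,
with zero open-chromatin overlap; otherwise `faint_early`. Compaction
ratios follow `c = b × 0.34 nm/bp` (contour length, reported in µm)
divided by the EM axial length `a`.

The package bundles the published reference tables for the X-chromosome
region 9F13–10B3 (element coordinates, EM axial lengths, FISH probes) and
a synthetic-region generator (`chromoband.simulate`) that plants a
ground-truth banding map with the same track structure, so the whole
pipeline is testable without any downloads.

## Worked example

```python
from chromoband import datasets, build_banding_map, summarize_region, compaction_table
from chromoband.simulate import SimParams, generate, evaluate_calls
from chromoband.caller import call_interbands

bmap = build_banding_map(datasets.load_interbands(), datasets.region_extent(),
                         labels=datasets.load_region_map())
s = summarize_region(bmap)
print(f"{s.n_interbands} interbands ({s.interband_bp:,} bp, "
      f"{s.interband_fraction:.2f}% of {s.region_bp:,} bp), {s.n_bands} bands")

for rec in compaction_table(bmap, datasets.load_axial_lengths()):
    if rec.name in {"9F13/10A1-2", "10A1-2", "10B1-2"}:
        print(f"{rec.name:>12}  b={rec.b_bp:>7,} bp  c={rec.c_um:>6.2f} um  c/a={rec.ratio:>7.2f}")

truth = generate(SimParams(seed=0))
ev = evaluate_calls(call_interbands(truth.panel), truth.map)
print(f"synthetic recovery: precision={ev.precision:.2f} recall={ev.recall:.2f} "
      f"mean Jaccard={ev.mean_jaccard:.3f} border error={ev.border_error_bp:.0f} bp")
```

prints

```
9 interbands (18,400 bp, 4.30% of 427,600 bp), 8 bands
 9F13/10A1-2  b=    600 bp  c=  0.20 um  c/a=   4.65
      10A1-2  b=190,800 bp  c= 64.87 um  c/a= 158.22
      10B1-2  b=167,800 bp  c= 57.05 um  c/a= 204.48
synthetic recovery: precision=1.00 recall=1.00 mean Jaccard=0.975 border error=17 bp
```

The nine interbands of the reference region occupy 18,400 bp of the
427,600 bp coordinate span and delimit eight bands; the two large
flanking bands compact their DNA ~158- and ~204-fold while the 600 bp
interband between 9F13 and 10A1–2 compacts only ~4.7-fold. On a
synthetic panel at the default signal-to-noise, the caller recovers all
nine planted interbands exactly, with borders ~17 bp off the planted
truth.

## Command line

```bash
chromoband simulate --seed 0 --out sim/          # synthetic panel + truth
chromoband call --panel sim/panel.yaml --region chrSim:0-427000 \
    --min-support 2 --out interbands.bed         # consensus calls
chromoband summarize --map sim/truth_map.bed
chromoband classify  --map sim/truth_map.bed --late late.bed --suur suur.bed --lamin lamin.bed
chromoband compaction --map sim/truth_map.bed --axial sim/axial.tsv --out table.tsv
chromoband annotate  --map sim/truth_map.bed --genes sim/genes.tsv
chromoband compare   --a ours.bed --b other.bed
```

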