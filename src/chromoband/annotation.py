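"""Genomic context of interbands, ORC spacing and chromatin-state mix.

Interbands typically sit at the 5' ends of genes (often between
divergently transcribed pairs), in intergenic gaps, or over first exons;
origin-recognition-complex (ORC) sites concentrate in them.  This module
classifies each interband against gene models, computes ORC
density/spacing arithmetic, and measures chromatin-state ("colour")
composition per map element.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from .banding import BandingMap
from .intervals import GenomicInterval, IntervalSet, merge_intervals

CONTEXTS = ("five_prime", "first_exon", "intergenic", "internal", "mixed")


@dataclass(frozen=True)
class GeneModel:
    """A minimal gene model: extent, strand, first exon, optional 5'UTR.

    The TSS is the strand-appropriate end of the gene extent (first base
    for '+', last base for '-').
    """

    id: str
    interval: GenomicInterval
    strand: str
    first_exon: GenomicInterval
    utr5: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.interval.contains_interval(self.first_exon):
            raise ValueError(
                f"gene {self.id}: first exon outside gene extent"
            )

    @property
    def tss(self) -> int:
        if self.strand == "+":
            return self.interval.start
        return self.interval.end - 1


@dataclass(frozen=True)
class ContextCall:
    interband: GenomicInterval
    context: str
    genes: tuple[str, ...]


def interband_context(
    ib: GenomicInterval,
    genes: Sequence[GeneModel],
    tss_slop: int = 250,
) -> ContextCall:
    """Classify an interband against gene models.

    Precedence: ``five_prime`` (overlaps a TSS +- ``tss_slop`` or a 5'UTR)
    > ``first_exon`` > ``intergenic`` (no gene-body overlap) >
    ``internal``.  If distinct categories tie at the winning precedence
    (defensive; cannot arise under this precedence order), ``mixed`` is
    reported with all genes listed.
    """
    if tss_slop < 0:
        raise ValueError("tss_slop must be >= 0")
    five_prime_genes: list[str] = []
    first_exon_genes: list[str] = []
    body_genes: list[str] = []
    for g in genes:
        tss_window = GenomicInterval(
            g.interval.chrom,
            max(0, g.tss - tss_slop),
            g.tss + tss_slop + 1,
        )
        if ib.overlaps(tss_window) or (
            g.utr5 is not None and ib.overlaps(g.utr5)
        ):
            five_prime_genes.append(g.id)
        elif ib.overlaps(g.first_exon):
            first_exon_genes.append(g.id)
        elif ib.overlaps(g.interval):
            body_genes.append(g.id)
    if five_prime_genes:
        return ContextCall(ib, "five_prime", tuple(five_prime_genes))
    if first_exon_genes:
        return ContextCall(ib, "first_exon", tuple(first_exon_genes))
    if not body_genes:
        return ContextCall(ib, "intergenic", ())
    return ContextCall(ib, "internal", tuple(body_genes))


def orc_spacing(n_sites: int, span_kb: float) -> float | None:
    """kb of DNA per ORC site over a span; ``None`` means ORC-absent.

    E.g. 7 sites over 68 kb -> 9.7 kb/site.
    """
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    if span_kb <= 0:
        raise ValueError("span_kb must be positive")
    if n_sites == 0:
        return None
    return round(span_kb / n_sites, 1)


class FeatureFractions(NamedTuple):
    base_fraction: float
    feature_fraction: float


def feature_in_interband_fraction(
    features: IntervalSet, bmap: BandingMap
) -> FeatureFractions:
    """How much of a feature set lies inside the map's interbands.

    ``base_fraction``: covered feature bases inside interbands / total
    feature bases (invariant under splitting features into adjacent
    pieces).  ``feature_fraction``: whole features counted in by the
    midpoint rule (features are point-like relative to interbands).
    Both are 0.0 for an empty feature set.
    """
    ib = merge_intervals(bmap.interband_set())
    total_bp = sum(iv.length for iv in features)
    in_bp = sum(ib.overlap_bp(iv) for iv in features)
    n = len(features)
    n_in = sum(
        1
        for iv in features
        if any(piece.contains(iv.midpoint) for piece in ib)
    )
    return FeatureFractions(
        base_fraction=in_bp / total_bp if total_bp else 0.0,
        feature_fraction=n_in / n if n else 0.0,
    )


def state_composition(
    element: GenomicInterval, states: IntervalSet
) -> dict[str, float]:
    """Per-label covered fraction of an element under a state segmentation.

    Overlapping state segments with different labels raise; same-label
    overlap is counted once.  Uncovered remainder is reported as
    ``"none"``.  Fractions (including "none") sum to 1.
    """
    if element.length == 0:
        raise ValueError("empty element")
    clipped: list[GenomicInterval] = []
    for iv in states:
        a = max(iv.start, element.start)
        b = min(iv.end, element.end)
        if b > a:
            clipped.append(iv.replace(start=a, end=b))
    clipped.sort(key=lambda iv: (iv.start, iv.end))
    for x, y in zip(clipped, clipped[1:]):
        if y.start < x.end and x.label != y.label:
            raise ValueError(
                f"overlapping state segments with different labels "
                f"({x.label!r} vs {y.label!r}) at {y.start}"
            )
    by_label: dict[str, list[GenomicInterval]] = {}
    for iv in clipped:
        by_label.setdefault(iv.label, []).append(iv)
    out: dict[str, float] = {}
    covered = 0
    for label, ivs in by_label.items():
        bp = merge_intervals(IntervalSet(ivs)).total_length
        covered += bp
        out[label] = bp / element.length
    if covered < element.length:
        out["none"] = (element.length - covered) / element.length
    return out


def read_gene_models(path) -> list[GeneModel]:
    """Read a gene-model TSV: id, chrom, start, end, strand,
    first_exon_start, first_exon_end[, utr5_start, utr5_end]."""
    path = Path(path)
    out = []
    with open(path) as fh:
        header = [h.strip().lower() for h in fh.readline().rstrip("\n").split("\t")]
        idx = {name: header.index(name) for name in header}
        required = [
            "id", "chrom", "start", "end", "strand",
            "first_exon_start", "first_exon_end",
        ]
        missing = [c for c in required if c not in idx]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            try:
                chrom = cols[idx["chrom"]]
                iv = GenomicInterval(
                    chrom, int(cols[idx["start"]]), int(cols[idx["end"]])
                )
                fe = GenomicInterval(
                    chrom,
                    int(cols[idx["first_exon_start"]]),
                    int(cols[idx["first_exon_end"]]),
                )
                utr5 = None
                if "utr5_start" in idx and cols[idx["utr5_start"]]:
                    utr5 = GenomicInterval(
                        chrom,
                        int(cols[idx["utr5_start"]]),
                        int(cols[idx["utr5_end"]]),
                    )
                out.append(
                    GeneModel(cols[idx["id"]], iv, cols[idx["strand"]], fe, utr5)
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_gene_models(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "id\tchrom\tstart\tend\tstrand\t"
            "first_exon_start\tfirst_exon_end\tutr5_start\tutr5_end\n"
        )
        for g in genes:
            u5s = g.utr5.start if g.utr5 else ""
            u5e = g.utr5.end if g.utr5 else ""
            fh.write(
                f"{g.id}\t{g.interval.chrom}\t{g.interval.start}\t"
                f"{g.interval.end}\t{g.strand}\t{g.first_exon.start}\t"
                f"{g.first_exon.end}\t{u5s}\t{u5e}\n"
            )
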