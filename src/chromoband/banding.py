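"""Banding maps: alternation of bands and interbands tiling a region.

Bands are defined as the complement of the called interbands — the
distances between neighbouring interband borders.  Bands are classified
into the two types seen in polytene chromosomes: large late-replicating
intercalary-heterochromatin (IH) bands covered by SUUR/lamin/D1 and
repressive chromatin, versus thin early-replicating faint bands that
carry neither repressive domains nor open-chromatin markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean

import pandas as pd

from .caller import InterbandCall
from .intervals import (
    GenomicInterval,
    IntervalSet,
    complement,
    coverage_atleast,
    merge_intervals,
)

IH_LATE = "IH_late"
FAINT_EARLY = "faint_early"


@dataclass
class BandRecord:
    """A band (inter-interband stretch) and its chromatin annotations."""

    interval: GenomicInterval
    name: str = ""
    band_class: str | None = None
    chromatin_mix: dict[str, float] = field(default_factory=dict)
    late_fraction: float | None = None
    suur_fraction: float | None = None
    lamin_fraction: float | None = None

    def __post_init__(self) -> None:
        total = sum(self.chromatin_mix.values())
        if total > 1 + 1e-9:
            raise ValueError(f"chromatin_mix fractions sum to {total} > 1")

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class BandingMap:
    """Ordered alternation of interbands and bands tiling a region."""

    region: GenomicInterval
    interbands: tuple[InterbandCall, ...]
    bands: tuple[BandRecord, ...]

    def __post_init__(self) -> None:
        self.interbands = tuple(
            sorted(self.interbands, key=lambda c: c.interval.start)
        )
        self.bands = tuple(sorted(self.bands, key=lambda b: b.interval.start))
        elems = self.elements
        cursor = self.region.start
        prev_kind = None
        for kind, iv in elems:
            if iv.start != cursor:
                raise ValueError(
                    f"map does not tile region: gap/overlap at {cursor}"
                )
            if kind == prev_kind:
                raise ValueError(
                    f"alternation violated: consecutive {kind}s at {iv.start}"
                )
            cursor = iv.end
            prev_kind = kind
        if cursor != self.region.end:
            raise ValueError(
                f"map ends at {cursor}, region ends at {self.region.end}"
            )

    @property
    def elements(self) -> list[tuple[str, GenomicInterval]]:
        """(kind, interval) pairs in genomic order; kind in
        {"interband", "band"}."""
        tagged = [("interband", c.interval) for c in self.interbands] + [
            ("band", b.interval) for b in self.bands
        ]
        return sorted(tagged, key=lambda t: t[1].start)

    @property
    def first_element(self) -> str:
        return self.elements[0][0] if self.elements else "band"

    @property
    def last_element(self) -> str:
        return self.elements[-1][0] if self.elements else "band"

    def interband_set(self) -> IntervalSet:
        return IntervalSet(c.interval for c in self.interbands)

    def band_set(self) -> IntervalSet:
        return IntervalSet(b.interval for b in self.bands)

    def named_elements(self) -> list[tuple[str, str, GenomicInterval]]:
        """(name, kind, interval) in genomic order."""
        out = []
        for kind, iv in self.elements:
            out.append((iv.label, kind, iv))
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for kind, iv in self.elements:
            rows.append(
                {
                    "name": iv.label,
                    "kind": kind,
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "length": iv.length,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class RegionSummary:
    n_interbands: int
    n_bands: int
    interband_bp: int
    band_bp: int
    interband_fraction: float  # percent of region length
    interband_min: int
    interband_max: int
    interband_mean: float
    band_min: int
    band_max: int
    band_mean: float
    region_bp: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def build_banding_map(
    calls,
    region: GenomicInterval,
    labels: IntervalSet | None = None,
) -> BandingMap:
    """Fill the space between interband calls with bands.

    ``calls`` is a list of :class:`InterbandCall` or an
    :class:`~chromoband.intervals.IntervalSet` (each interval wrapped as a
    call).  Calls must be disjoint and inside the region.  ``labels``, if
    given, is a labelled interval set (e.g. a published cytological map);
    each element takes the label of the entry it overlaps most.  Unnamed
    elements are auto-numbered ``interband_1..``/``band_1..``.
    """
    if isinstance(calls, IntervalSet):
        calls = [InterbandCall.from_interval(iv) for iv in calls]
    calls = sorted(calls, key=lambda c: c.interval.start)
    for a, b in zip(calls, calls[1:]):
        if a.interval.end > b.interval.start:
            raise ValueError(
                f"overlapping calls at [{b.interval.start}, ...)"
            )
    ib_set = IntervalSet(c.interval for c in calls)
    band_ivs = complement(ib_set, region)  # validates containment

    def name_for(iv: GenomicInterval, fallback: str) -> str:
        if labels is not None:
            best, best_ov = None, 0
            for lab in labels:
                ov = lab.overlap_bp(iv)
                if ov > best_ov:
                    best, best_ov = lab.label, ov
            if best:
                return best
        return fallback

    named_calls = []
    for i, c in enumerate(calls, start=1):
        label = c.interval.label or name_for(c.interval, f"interband_{i}")
        named_calls.append(
            InterbandCall(
                c.interval.replace(label=label),
                c.peak, c.support, c.n_markers, c.cell_types,
            )
        )
    bands = [
        BandRecord(iv.replace(label=name_for(iv, f"band_{i}")), name=name_for(iv, f"band_{i}"))
        for i, iv in enumerate(band_ivs, start=1)
    ]
    return BandingMap(region, tuple(named_calls), tuple(bands))


def classify_band(
    band,
    late: IntervalSet | None = None,
    suur: IntervalSet | None = None,
    lamin: IntervalSet | None = None,
    open_chromatin: IntervalSet | None = None,
    t_late: float = 0.4,
    t_suur: float = 0.5,
    t_lamin: float = 0.5,
) -> str:
    """Classify a band as late-replicating IH or early faint.

    IH_late requires repressive evidence — late-replication coverage
    >= ``t_late`` (default 0.4: one IH band completes replication late
    over only the distal 40% of its extent) or SUUR and lamin coverage
    both >= 0.5 — together with zero open-chromatin overlap.  Everything
    else is faint_early.  The late-replication track is mandatory.
    Monotone: raising ``t_late`` never converts faint_early to IH_late.

    Accepts a :class:`BandRecord` (annotated in place) or a bare interval.
    """
    if late is None:
        raise ValueError("missing replication track: 'late' is required")
    iv = band.interval if isinstance(band, BandRecord) else band
    L = max(iv.length, 1)
    late_f = late.overlap_bp(iv) / L
    suur_f = suur.overlap_bp(iv) / L if suur is not None else 0.0
    lamin_f = lamin.overlap_bp(iv) / L if lamin is not None else 0.0
    open_bp = open_chromatin.overlap_bp(iv) if open_chromatin is not None else 0
    repressive = late_f >= t_late or (suur_f >= t_suur and lamin_f >= t_lamin)
    cls = IH_LATE if (repressive and open_bp == 0) else FAINT_EARLY
    if isinstance(band, BandRecord):
        band.late_fraction = late_f
        band.suur_fraction = suur_f
        band.lamin_fraction = lamin_f
        band.band_class = cls
    return cls


def classify_bands(bmap: BandingMap, tracks: dict, **thresholds) -> list[str]:
    """Classify every band of a map.

    ``tracks`` keys: "late" (required), "suur", "lamin", "open".
    """
    return [
        classify_band(
            band,
            late=tracks.get("late"),
            suur=tracks.get("suur"),
            lamin=tracks.get("lamin"),
            open_chromatin=tracks.get("open"),
            **thresholds,
        )
        for band in bmap.bands
    ]


def summarize_region(bmap: BandingMap) -> RegionSummary:
    """Counts, base totals and size statistics of a banding map.

    ``interband_bp + band_bp`` equals the region length by construction;
    ``interband_fraction`` is a percentage of region length.
    """
    ib_lens = [c.interval.length for c in bmap.interbands]
    b_lens = [b.interval.length for b in bmap.bands]
    ib_bp, b_bp = sum(ib_lens), sum(b_lens)
    return RegionSummary(
        n_interbands=len(ib_lens),
        n_bands=len(b_lens),
        interband_bp=ib_bp,
        band_bp=b_bp,
        interband_fraction=100.0 * ib_bp / bmap.region.length,
        interband_min=min(ib_lens, default=0),
        interband_max=max(ib_lens, default=0),
        interband_mean=mean(ib_lens) if ib_lens else 0.0,
        band_min=min(b_lens, default=0),
        band_max=max(b_lens, default=0),
        band_mean=mean(b_lens) if b_lens else 0.0,
        region_bp=bmap.region.length,
    )


def interband_fraction(interband_bp: int, region_bp: int) -> float:
    """Percent of a region's DNA residing in interbands."""
    if region_bp <= 0:
        raise ValueError("region_bp must be positive")
    return 100.0 * interband_bp / region_bp


def compare_maps(a: BandingMap, b: BandingMap):
    """Compare two banding maps of the same region.

    Returns ``(table, global_jaccard)``: per band of ``a`` the
    best-overlapping band of ``b`` (overlap bp and Jaccard), and the
    symmetric Jaccard of the two maps' interband base sets.
    """
    if (a.region.chrom, a.region.start, a.region.end) != (
        b.region.chrom, b.region.start, b.region.end,
    ):
        raise ValueError("maps cover different regions")
    rows = []
    for band in a.bands:
        best, best_ov = None, -1
        for other in b.bands:
            ov = band.interval.overlap_bp(other.interval)
            if ov > best_ov:
                best, best_ov = other, ov
        rows.append(
            {
                "band_a": band.interval.label or band.name,
                "a_start": band.interval.start,
                "a_end": band.interval.end,
                "band_b": (best.interval.label or best.name) if best else pd.NA,
                "overlap_bp": max(best_ov, 0),
                "jaccard": band.interval.jaccard(best.interval) if best else 0.0,
            }
        )
    ib_a = merge_intervals(a.interband_set())
    ib_b = merge_intervals(b.interband_set())
    inter = coverage_atleast([ib_a, ib_b], 2).total_length
    union = coverage_atleast([ib_a, ib_b], 1).total_length
    global_jaccard = inter / union if union else 1.0
    return pd.DataFrame(rows), global_jaccard
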