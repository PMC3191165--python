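"""Consensus calling of interbands from open-chromatin evidence tracks.

An interband is called where several independent *classes* of
open-chromatin evidence co-localize: interband-associated proteins
(Chriz/CHRO, BEAF-32, WDS, BRE-1, NURF, RNA Pol II, TRX, GAF), DNase I
hypersensitive sites, histone H1 dips, ORC binding, active chromatin
states and the replication-independent histone variant H3.3.  Evidence is
counted per *class*, not per track, so that many redundant protein tracks
cannot outvote the absence of an orthogonal signature such as DHS or an
H1 dip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .intervals import (
    GenomicInterval,
    IntervalSet,
    coverage_atleast,
    coverage_segments,
    merge_intervals,
)
from .tracks import SignalTrack, threshold_enrichment

logger = logging.getLogger(__name__)

EVIDENCE_CLASSES = (
    "interband_protein",
    "dhs",
    "h1_dip",
    "orc",
    "active_state",
    "histone_variant",
)


@dataclass
class MarkerPanel:
    """Feature tracks for one region, keyed by (marker name, cell type).

    ``class_of`` maps each marker name to its evidence class.  Tracks may
    be interval sets (regions of significant enrichment) or windowed
    signal tracks (smoothed M-value profiles), which are binarized at call
    time.
    """

    region: GenomicInterval
    tracks: dict[tuple[str, str], IntervalSet | SignalTrack]
    class_of: dict[str, str]

    def __post_init__(self) -> None:
        for (marker, cell), track in self.tracks.items():
            if marker not in self.class_of:
                raise ValueError(f"marker {marker!r} has no evidence class")
            chrom = track.chrom
            if chrom is not None and chrom != self.region.chrom:
                raise ValueError(
                    f"track ({marker}, {cell}) on {chrom!r}, "
                    f"region on {self.region.chrom!r}"
                )

    @property
    def markers(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for marker, _ in self.tracks:
            seen.setdefault(marker)
        return tuple(seen)

    def cell_types(self, marker: str) -> tuple[str, ...]:
        return tuple(c for m, c in self.tracks if m == marker)

    @property
    def evidence_classes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for marker in self.markers:
            seen.setdefault(self.class_of[marker])
        return tuple(seen)


@dataclass(frozen=True)
class CallerParams:
    """Tunable thresholds of the consensus caller.

    min_support
        Distinct evidence classes that must co-occur per base (default 2).
    combine_cells
        How per-marker tracks from different cell types are pooled:
        "union" (default), "intersection" or "majority" (>= half of the
        available cell types).
    merge_gap
        Candidate runs closer than this are merged (default 500 bp, one
        smoothing step).
    min_size, max_size
        Size gate on candidates (defaults 300 bp / 10 kb; mapped
        interbands span roughly 600-3000 bp).
    signal_cutoff, signal_min_run
        Binarization applied to any SignalTrack in the panel.
    """

    min_support: int = 2
    combine_cells: str = "union"
    merge_gap: int = 500
    min_size: int = 300
    max_size: int = 10_000
    signal_cutoff: float = 0.0
    signal_min_run: int = 0

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if self.combine_cells not in {"union", "intersection", "majority"}:
            raise ValueError(f"unknown combine mode {self.combine_cells!r}")
        if self.min_size >= self.max_size:
            raise ValueError("min_size must be < max_size")


@dataclass(frozen=True)
class InterbandCall:
    """A called interband.

    ``interval`` is the call extent, ``peak`` the consensus centre (the
    base of maximal summed evidence), ``support`` the evidence classes
    present, ``n_markers`` the distinct markers contributing and
    ``cell_types`` the cell types they came from.
    """

    interval: GenomicInterval
    peak: int
    support: frozenset[str]
    n_markers: int
    cell_types: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.support:
            raise ValueError("support must be nonempty")
        if not self.interval.contains(self.peak):
            raise ValueError("peak must lie inside the call interval")

    @classmethod
    def from_interval(
        cls, iv: GenomicInterval, support: Iterable[str] = ("annotation",)
    ) -> "InterbandCall":
        """Wrap a bare interval (e.g. a published interband) as a call."""
        return cls(iv, iv.midpoint, frozenset(support), 0)

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


def _as_interval_set(track, params: CallerParams) -> IntervalSet:
    if isinstance(track, SignalTrack):
        return threshold_enrichment(
            track, params.signal_cutoff, params.signal_min_run
        )
    return track


def combine_cell_types(
    panel: MarkerPanel,
    marker: str,
    mode: str = "union",
    params: CallerParams | None = None,
) -> IntervalSet:
    """Pool one marker's tracks across cell types.

    "union": bases covered in any cell type; "intersection": in all;
    "majority": in at least half of the available cell types.
    """
    params = params or CallerParams()
    cells = panel.cell_types(marker)
    if not cells:
        raise ValueError(f"unknown marker {marker!r}")
    sets = [
        _as_interval_set(panel.tracks[(marker, c)], params) for c in cells
    ]
    if len(sets) == 1:
        return merge_intervals(sets[0])
    if mode == "union":
        k = 1
    elif mode == "intersection":
        k = len(sets)
    elif mode == "majority":
        k = (len(sets) + 1) // 2
    else:
        raise ValueError(f"unknown combine mode {mode!r}")
    return coverage_atleast(sets, k)


def class_coverage(
    panel: MarkerPanel, params: CallerParams | None = None
) -> dict[str, IntervalSet]:
    """Per evidence class, the union over its markers of the
    cell-type-combined coverage."""
    params = params or CallerParams()
    per_class: dict[str, list[GenomicInterval]] = {}
    for marker in panel.markers:
        combined = combine_cell_types(
            panel, marker, params.combine_cells, params
        )
        per_class.setdefault(panel.class_of[marker], []).extend(combined)
    return {
        cls: merge_intervals(IntervalSet(ivs))
        for cls, ivs in per_class.items()
    }


def _peak_of(segs: Sequence[tuple[int, int, int]], lo: int, hi: int) -> int:
    """Leftmost midpoint of the maximal-count run within [lo, hi)."""
    clipped = [
        (max(a, lo), min(b, hi), c)
        for a, b, c in segs
        if min(b, hi) > max(a, lo)
    ]
    if not clipped:
        return (lo + hi) // 2
    best = max(c for _, _, c in clipped)
    # merge adjacent maximal segments into runs, take the leftmost run
    run_start = run_end = None
    for a, b, c in clipped:
        if c == best:
            if run_end is not None and a == run_end:
                run_end = b
            elif run_start is None:
                run_start, run_end = a, b
            else:
                break  # later maximal run; leftmost already captured
        elif run_start is not None:
            break
    return (run_start + run_end) // 2


def call_interbands(
    panel: MarkerPanel, params: CallerParams | None = None
) -> list[InterbandCall]:
    """Call interbands as runs of multi-class open-chromatin consensus.

    Per-base counts of distinct evidence classes are computed from the
    combined tracks; maximal runs with count >= ``min_support`` become
    candidates; candidates within ``merge_gap`` are merged; candidates
    outside ``[min_size, max_size]`` are dropped (logged).  Each call is
    annotated with its supporting classes, contributing markers/cell
    types, and the consensus peak (leftmost midpoint of the
    maximal-count run).  Calls are sorted and pairwise disjoint.
    """
    params = params or CallerParams()
    if panel.region.length < params.min_size:
        raise ValueError(
            f"region length {panel.region.length} < min_size "
            f"{params.min_size}"
        )
    coverages = class_coverage(panel, params)
    sets = list(coverages.values())
    segs = coverage_segments(sets)
    candidate_pieces = [
        GenomicInterval(panel.region.chrom, a, b)
        for a, b, c in segs
        if c >= params.min_support
    ]
    merged = merge_intervals(
        IntervalSet(candidate_pieces), max_gap=params.merge_gap
    )
    # pre-binarize marker tracks once for the per-call annotations
    marker_sets = {
        marker: combine_cell_types(panel, marker, params.combine_cells, params)
        for marker in panel.markers
    }
    calls: list[InterbandCall] = []
    for cand in merged:
        if not (params.min_size <= cand.length <= params.max_size):
            logger.info(
                "dropped candidate [%d, %d): size %d outside [%d, %d]",
                cand.start, cand.end, cand.length,
                params.min_size, params.max_size,
            )
            continue
        support = frozenset(
            cls for cls, cov in coverages.items() if cov.overlap_bp(cand) > 0
        )
        contributing = [
            m for m, s in marker_sets.items() if s.overlap_bp(cand) > 0
        ]
        cells = frozenset(
            c
            for m in contributing
            for c in panel.cell_types(m)
            if _as_interval_set(panel.tracks[(m, c)], params).overlap_bp(cand) > 0
        )
        calls.append(
            InterbandCall(
                interval=cand,
                peak=_peak_of(segs, cand.start, cand.end),
                support=support,
                n_markers=len(contributing),
                cell_types=cells,
            )
        )
    return calls


def refine_borders(
    call: InterbandCall, panel: MarkerPanel, params: CallerParams | None = None
) -> InterbandCall:
    """Widen a call to the edges of its supporting feature distributions.

    The refined extent runs from the outermost start to the outermost end
    of the union of features overlapping the call (the "edges of
    distributions"); the peak (maximal-count run midpoint) is unchanged.
    Refined extents of neighbouring calls may touch or overlap.
    """
    params = params or CallerParams()
    lo, hi = call.interval.start, call.interval.end
    for marker in panel.markers:
        for iv in combine_cell_types(panel, marker, params.combine_cells, params):
            if iv.overlaps(call.interval):
                lo = min(lo, iv.start)
                hi = max(hi, iv.end)
    lo = max(lo, panel.region.start)
    hi = min(hi, panel.region.end)
    return replace(
        call, interval=call.interval.replace(start=lo, end=hi)
    )


def probe_concordance(
    calls: Sequence[InterbandCall], probes: IntervalSet
) -> pd.DataFrame:
    """Relate FISH probes to calls.

    For each probe: the call it overlaps (distance 0; ties by largest
    overlap, then leftmost), else the nearest call with a signed distance
    (negative = call lies left of the probe).  A probe equidistant from
    two calls reports the left one with ``tie=True``.
    """
    rows = []
    for probe in probes:
        best = None  # (overlap, -start) maximization
        for i, call in enumerate(calls):
            ov = call.interval.overlap_bp(probe)
            if ov > 0 and (best is None or ov > best[0]):
                best = (ov, i)
        tie = False
        if best is not None:
            i = best[1]
            dist = 0
        elif calls:
            dists = []
            for j, call in enumerate(calls):
                if call.end <= probe.start:
                    d = call.end - probe.start  # call left: negative
                else:
                    d = call.start - probe.end  # call right: positive
                dists.append((abs(d), j, d))
            dists.sort(key=lambda t: (t[0], t[1]))
            tie = len(dists) > 1 and dists[0][0] == dists[1][0]
            _, i, dist = dists[0]
        else:
            i, dist = -1, None
        call = calls[i] if i >= 0 else None
        rows.append(
            {
                "probe": probe.label,
                "probe_start": probe.start,
                "probe_end": probe.end,
                "call_index": i,
                "call_start": call.start if call else pd.NA,
                "call_end": call.end if call else pd.NA,
                "distance_bp": dist,
                "tie": tie,
            }
        )
    return pd.DataFrame(rows)
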