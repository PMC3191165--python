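"""Genomic interval data model and arithmetic.

All coordinates are 0-based half-open ``[start, end)``.  Intervals with
``start == end`` (empty) are legal in memory — they arise when clipping —
but contribute no covered bases and are never written to BED.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence


@dataclass(frozen=True)
class GenomicInterval:
    """A span ``[start, end)`` on a named chromosome.

    Parameters
    ----------
    chrom
        Chromosome / contig name.
    start, end
        0-based half-open coordinates, ``0 <= start <= end``.
    label
        Free-text name (e.g. a cytological band label).
    meta
        Arbitrary key/value annotations; ignored for equality and hashing.
    """

    chrom: str
    start: int
    end: int
    label: str = ""
    meta: Mapping[str, object] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if int(self.start) != self.start or int(self.end) != self.end:
            raise ValueError("interval coordinates must be integers")
        object.__setattr__(self, "start", int(self.start))
        object.__setattr__(self, "end", int(self.end))
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_bp(other) > 0

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def jaccard(self, other: "GenomicInterval") -> float:
        inter = self.overlap_bp(other)
        union = self.length + other.length - inter
        return inter / union if union else 1.0

    def replace(self, **kw) -> "GenomicInterval":
        data = dict(
            chrom=self.chrom, start=self.start, end=self.end,
            label=self.label, meta=self.meta,
        )
        data.update(kw)
        return GenomicInterval(**data)


def interval_length(iv: GenomicInterval) -> int:
    """Number of bases in ``iv`` (``end - start``; 0 for empty)."""
    return iv.length


class IntervalSet:
    """An ordered collection of intervals on one chromosome.

    Intervals are kept sorted by ``(start, end)``.  Overlap is allowed in a
    raw set; :func:`merge_intervals` produces the disjoint (normalized)
    form.
    """

    __slots__ = ("_intervals", "_chrom")

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
        chroms = {iv.chrom for iv in ivs}
        if len(chroms) > 1:
            raise ValueError(
                f"intervals span multiple chromosomes: {sorted(chroms)}"
            )
        self._intervals: tuple[GenomicInterval, ...] = tuple(ivs)
        self._chrom = chroms.pop() if chroms else None

    @property
    def chrom(self) -> str | None:
        return self._chrom

    @property
    def intervals(self) -> tuple[GenomicInterval, ...]:
        return self._intervals

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __getitem__(self, i):
        return self._intervals[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._intervals == other._intervals

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)}, chrom={self._chrom!r})"

    @property
    def total_length(self) -> int:
        """Sum of interval lengths (double-counts overlap)."""
        return sum(iv.length for iv in self._intervals)

    @property
    def covered_bp(self) -> int:
        """Number of distinct bases covered (overlap counted once)."""
        return merge_intervals(self).total_length

    @property
    def span(self) -> GenomicInterval | None:
        if not self._intervals:
            return None
        return GenomicInterval(
            self._chrom, self._intervals[0].start,
            max(iv.end for iv in self._intervals),
        )

    def overlap_bp(self, iv: GenomicInterval) -> int:
        """Distinct bases of ``iv`` covered by this set."""
        return sum(
            piece.overlap_bp(iv) for piece in merge_intervals(self)
        )


def merge_intervals(s: IntervalSet, max_gap: int = 0) -> IntervalSet:
    """Union intervals that overlap or are separated by ``<= max_gap`` bases.

    Empty intervals are dropped.  The result is sorted and disjoint; at
    ``max_gap=0`` adjacent intervals (``end == next start``) are joined.
    Idempotent at fixed ``max_gap``.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out: list[GenomicInterval] = []
    cur_start = cur_end = None
    cur_label = ""
    for iv in s:
        if iv.length == 0:
            continue
        if cur_start is None:
            cur_start, cur_end, cur_label = iv.start, iv.end, iv.label
        elif iv.start <= cur_end + max_gap:
            cur_end = max(cur_end, iv.end)
        else:
            out.append(GenomicInterval(s.chrom, cur_start, cur_end, cur_label))
            cur_start, cur_end, cur_label = iv.start, iv.end, iv.label
    if cur_start is not None:
        out.append(GenomicInterval(s.chrom, cur_start, cur_end, cur_label))
    return IntervalSet(out)


def complement(s: IntervalSet, region: GenomicInterval) -> IntervalSet:
    """Maximal sub-intervals of ``region`` not covered by ``s``.

    ``s`` is normalized first.  Raises if ``s`` extends outside ``region``
    or sits on a different chromosome.  ``complement(s, region)`` together
    with the normalized ``s`` tiles ``region`` exactly.
    """
    merged = merge_intervals(s)
    if merged.chrom is not None and merged.chrom != region.chrom:
        raise ValueError(
            f"set on {merged.chrom!r} but region on {region.chrom!r}"
        )
    gaps: list[GenomicInterval] = []
    cursor = region.start
    for iv in merged:
        if iv.start < region.start or iv.end > region.end:
            raise ValueError(
                f"interval [{iv.start}, {iv.end}) extends outside region "
                f"[{region.start}, {region.end})"
            )
        if iv.start > cursor:
            gaps.append(GenomicInterval(region.chrom, cursor, iv.start))
        cursor = iv.end
    if cursor < region.end:
        gaps.append(GenomicInterval(region.chrom, cursor, region.end))
    return IntervalSet(gaps)


def coverage_segments(
    sets: Sequence[IntervalSet],
) -> list[tuple[int, int, int]]:
    """Breakpoint sweep over several (independently normalized) sets.

    Returns ``(start, end, count)`` segments with count > 0, where count is
    the number of input sets covering the segment.  Each set contributes at
    most 1 per base regardless of internal overlap.
    """
    events: list[tuple[int, int]] = []
    for s in sets:
        for iv in merge_intervals(s):
            events.append((iv.start, +1))
            events.append((iv.end, -1))
    if not events:
        return []
    events.sort()
    segs: list[tuple[int, int, int]] = []
    count = 0
    prev = events[0][0]
    i = 0
    n = len(events)
    while i < n:
        pos = events[i][0]
        if pos > prev and count > 0:
            segs.append((prev, pos, count))
        while i < n and events[i][0] == pos:
            count += events[i][1]
            i += 1
        prev = pos
    return segs


def coverage_atleast(sets: Sequence[IntervalSet], k: int) -> IntervalSet:
    """Bases covered by at least ``k`` of the given sets, as intervals."""
    if k < 1:
        raise ValueError("k must be >= 1")
    chrom = next((s.chrom for s in sets if s.chrom is not None), None)
    if chrom is None:
        return IntervalSet()
    pieces = [
        GenomicInterval(chrom, a, b)
        for a, b, c in coverage_segments(sets)
        if c >= k
    ]
    return merge_intervals(IntervalSet(pieces))


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Bases covered by both sets."""
    return coverage_atleast([a, b], 2)


def clip(s: IntervalSet, region: GenomicInterval) -> IntervalSet:
    """Restrict a set to ``region``, dropping what falls outside."""
    out = []
    for iv in s:
        if iv.chrom != region.chrom:
            continue
        a, b = max(iv.start, region.start), min(iv.end, region.end)
        if b > a:
            out.append(iv.replace(start=a, end=b))
    return IntervalSet(out)


# ---------------------------------------------------------------------------
# readers / writers

_BED_SUFFIXES = {".bed"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    return "bed" if path.suffix.lower() in _BED_SUFFIXES else "tsv"


def read_intervals(path, fmt: str | None = None) -> IntervalSet:
    """Read intervals from a BED (3-6 column) or headered TSV file.

    BED is 0-based half-open; column 4 becomes ``label`` (``"."`` reads as
    empty), columns 5-6 go into ``meta`` as ``score``/``strand``.  TSV must
    declare a header containing ``chrom``, ``start`` and ``end``; a
    ``label`` (or ``name``) column is honoured and any remaining columns go
    into ``meta``.  Malformed lines raise :class:`ValueError` naming the
    line number.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "bed":
        return _read_bed(path)
    if fmt == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown format {fmt!r}")


def _read_bed(path: Path) -> IntervalSet:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 3 BED columns, "
                    f"got {len(cols)}"
                )
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start > end:
                raise ValueError(
                    f"{path}: line {lineno}: start {start} > end {end}"
                )
            label = cols[3] if len(cols) > 3 and cols[3] != "." else ""
            meta = {}
            if len(cols) > 4:
                meta["score"] = cols[4]
            if len(cols) > 5:
                meta["strand"] = cols[5]
            out.append(GenomicInterval(cols[0], start, end, label, meta))
    return IntervalSet(out)


def _read_tsv(path: Path) -> IntervalSet:
    out = []
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        header = [h.strip() for h in header_line.split("\t")]
        lower = [h.lower() for h in header]
        try:
            ic = lower.index("chrom")
            is_ = lower.index("start")
            ie = lower.index("end")
        except ValueError as exc:
            raise ValueError(
                f"{path}: line 1: TSV header must contain "
                f"chrom/start/end, got {header}"
            ) from exc
        il = lower.index("label") if "label" in lower else (
            lower.index("name") if "name" in lower else None
        )
        extra = [
            j for j in range(len(header))
            if j not in {ic, is_, ie} and j != il
        ]
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != len(header):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(header)} "
                    f"columns, got {len(cols)}"
                )
            try:
                start, end = int(cols[is_]), int(cols[ie])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start > end:
                raise ValueError(
                    f"{path}: line {lineno}: start {start} > end {end}"
                )
            label = cols[il] if il is not None else ""
            meta = {header[j]: cols[j] for j in extra}
            out.append(GenomicInterval(cols[ic], start, end, label, meta))
    return IntervalSet(out)


def write_intervals(s: IntervalSet, path, fmt: str | None = None) -> None:
    """Write a set as BED (0-based half-open) or headered TSV.

    Empty intervals are skipped.  ``read_intervals(write_intervals(s))``
    is the identity on (chrom, start, end, label).
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    with open(path, "w") as fh:
        if fmt == "bed":
            any_label = any(iv.label for iv in s)
            for iv in s:
                if iv.length == 0:
                    continue
                cols = [iv.chrom, str(iv.start), str(iv.end)]
                if any_label:
                    cols.append(iv.label or ".")
                fh.write("\t".join(cols) + "\n")
        elif fmt == "tsv":
            fh.write("chrom\tstart\tend\tlabel\n")
            for iv in s:
                if iv.length == 0:
                    continue
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")
        else:
            raise ValueError(f"unknown format {fmt!r}")
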