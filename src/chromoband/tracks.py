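"""Signal-track preprocessing.

Windowed smoothing of per-base enrichment values (the 1 kb / 500 bp
sliding window applied to smoothed M-value profiles), transposon
insertion-density tracks, and thresholding of windowed signals into
enrichment interval calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .intervals import GenomicInterval, IntervalSet, merge_intervals

logger = logging.getLogger(__name__)


@dataclass
class SignalTrack:
    """Regularly spaced windowed values on one chromosome.

    Window ``i`` covers ``[start + i*step, start + i*step + window)`` and
    carries ``values[i]``.  NaN marks a window with no defined data
    (e.g. an array gap); infinities are rejected.
    """

    chrom: str
    start: int
    step: int
    window: int
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.window <= 0:
            raise ValueError("window must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if np.isinf(self.values).any():
            raise ValueError("values must be finite (NaN allowed for gaps)")

    @property
    def n_windows(self) -> int:
        return len(self.values)

    @property
    def window_starts(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_windows)

    def window_interval(self, i: int) -> tuple[int, int]:
        s = self.start + self.step * int(i)
        return s, s + self.window

    @property
    def footprint_end(self) -> int:
        if self.n_windows == 0:
            return self.start
        return self.start + self.step * (self.n_windows - 1) + self.window


@dataclass
class InsertionTable:
    """Base positions of transposon (P-element) insertion sites.

    Duplicate positions are allowed: independent insertions can hit the
    same site.
    """

    chrom: str
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.positions)


def sliding_window_smooth(
    raw,
    window: int = 1000,
    step: int = 500,
    chrom: str | None = None,
    start: int = 0,
) -> SignalTrack:
    """Mean-smooth per-base values over a sliding window.

    ``raw`` is either a per-base float array (first base at ``start``) or a
    per-base :class:`SignalTrack` (``window == step == 1``), in which case
    ``chrom``/``start`` are taken from it.  The output has
    ``floor((L - window)/step) + 1`` windows; each value is the mean of the
    *defined* (non-NaN) bases it covers, NaN if none are defined.
    """
    if isinstance(raw, SignalTrack):
        if raw.step != 1 or raw.window != 1:
            raise ValueError("SignalTrack input must be per-base (step=window=1)")
        chrom, start = raw.chrom, raw.start
        values = raw.values
    else:
        values = np.asarray(raw, dtype=float)
    if window <= 0:
        raise ValueError("window must be positive")
    if step <= 0:
        raise ValueError("step must be positive")
    L = len(values)
    if L < window:
        raise ValueError(f"region length {L} shorter than window {window}")
    defined = np.isfinite(values)
    filled = np.where(defined, values, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(filled)])
    ccnt = np.concatenate([[0], np.cumsum(defined)])
    n = (L - window) // step + 1
    starts = step * np.arange(n)
    sums = csum[starts + window] - csum[starts]
    cnts = ccnt[starts + window] - ccnt[starts]
    with np.errstate(invalid="ignore"):
        out = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    return SignalTrack(chrom or "chr", start, step, window, out)


def insertion_density(
    ins: InsertionTable,
    region: GenomicInterval,
    interval: int = 10_000,
    per: int = 1_000,
    step: int | None = None,
) -> SignalTrack:
    """Insertion density: insertions per ``per`` bp within ``interval``-bp
    windows (default: per 1 kb in a 10 kb interval).

    Windows tile the region from its start (``step`` defaults to
    ``interval``; a smaller step gives the sliding variant).  Insertions
    outside the region are ignored with a logged count; a position on a
    window boundary belongs to the window that starts there (half-open
    tiling).
    """
    if interval <= 0 or per <= 0:
        raise ValueError("interval and per must be positive")
    if interval % per != 0:
        raise ValueError(f"interval {interval} not divisible by per {per}")
    step = interval if step is None else step
    if step <= 0:
        raise ValueError("step must be positive")
    pos = ins.positions
    inside = (pos >= region.start) & (pos < region.end)
    n_out = int((~inside).sum())
    if n_out:
        logger.info(
            "insertion_density: ignored %d insertion(s) outside region "
            "[%d, %d)", n_out, region.start, region.end,
        )
    pos = pos[inside]
    if step == interval:
        # non-overlapping tiling of the whole region; last bin may be partial
        n = (region.length + step - 1) // step
    else:
        n = max(0, region.length - interval) // step + 1
    n = max(n, 1)
    starts = region.start + step * np.arange(n)
    counts = np.empty(n, dtype=float)
    for i, s in enumerate(starts):
        counts[i] = np.count_nonzero((pos >= s) & (pos < min(s + interval, region.end)))
    values = counts / (interval // per)
    return SignalTrack(region.chrom, region.start, step, interval, values)


def threshold_enrichment(
    track: SignalTrack, cutoff: float, min_run: int = 0
) -> IntervalSet:
    """Binarize a windowed track into enrichment intervals.

    Bases covered by any window with value ``>= cutoff`` are marked; the
    maximal marked intervals are returned, dropping those shorter than
    ``min_run`` bases.  NaN windows never qualify; an all-NaN track is an
    error.  Monotone: raising ``cutoff`` never enlarges the covered bases.
    """
    if track.n_windows == 0:
        raise ValueError("empty track")
    if not np.isfinite(track.values).any():
        raise ValueError("all-NaN track cannot be thresholded")
    qual = np.zeros(track.n_windows, dtype=bool)
    finite = np.isfinite(track.values)
    qual[finite] = track.values[finite] >= cutoff
    pieces = [
        GenomicInterval(track.chrom, *track.window_interval(i))
        for i in np.flatnonzero(qual)
    ]
    merged = merge_intervals(IntervalSet(pieces))
    return IntervalSet(iv for iv in merged if iv.length >= min_run)


def read_signal_track(path, window: int | None = None) -> SignalTrack:
    """Read a bedGraph-style 4-column TSV (chrom, start, end, value).

    Rows must be regularly spaced (constant start-to-start step); the
    window size is ``end - start`` of the rows unless overridden.
    """
    path = Path(path)
    chroms, starts, ends, vals = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected 4 columns"
                )
            chroms.append(cols[0])
            starts.append(int(cols[1]))
            ends.append(int(cols[2]))
            vals.append(float(cols[3]) if cols[3].lower() != "nan" else np.nan)
    if not starts:
        raise ValueError(f"{path}: no data rows")
    if len(set(chroms)) > 1:
        raise ValueError(f"{path}: multiple chromosomes")
    starts_a = np.asarray(starts)
    steps = np.diff(starts_a)
    if len(steps) and not (steps == steps[0]).all():
        raise ValueError(f"{path}: window starts not regularly spaced")
    step = int(steps[0]) if len(steps) else (ends[0] - starts[0])
    win = window if window is not None else ends[0] - starts[0]
    return SignalTrack(chroms[0], int(starts_a[0]), step, win, np.asarray(vals))


def write_signal_track(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(track.values):
            s, e = track.window_interval(i)
            fh.write(f"{track.chrom}\t{s}\t{e}\t{v}\n")


def read_insertions(path) -> InsertionTable:
    """Read an insertion TSV with header columns chrom, position[, id]."""
    path = Path(path)
    chroms, positions = [], []
    with open(path) as fh:
        header = [h.strip().lower() for h in fh.readline().rstrip("\n").split("\t")]
        try:
            ic, ip = header.index("chrom"), header.index("position")
        except ValueError as exc:
            raise ValueError(
                f"{path}: header must contain chrom and position"
            ) from exc
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            try:
                positions.append(int(cols[ip]))
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path}: line {lineno}: bad position"
                ) from exc
            chroms.append(cols[ic])
    if len(set(chroms)) > 1:
        raise ValueError(f"{path}: multiple chromosomes")
    chrom = chroms[0] if chroms else "chr"
    return InsertionTable(chrom, np.asarray(positions, dtype=np.int64))


def write_insertions(ins: InsertionTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tposition\tid\n")
        for i, p in enumerate(ins.positions):
            fh.write(f"{ins.chrom}\t{int(p)}\tins_{i}\n")
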