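"""Bundled reference tables for the X-chromosome region 9F13-10B3.

The tables transcribe the published EM/physical map of this region of the
*D. melanogaster* X chromosome (FlyBase release FB2011_03 / dm3
coordinates): the alternating band/interband map with printed coordinate
pairs, the EM axial-length measurements used for compaction ratios, and
the FISH probe coordinates.

Printed coordinate pairs are 1-based ``s..e`` whose printed length equals
``e - s``, with consecutive structures satisfying ``next_s = prev_e + 1``.
They are converted on load to the internal 0-based half-open convention as
``[s-1, s-1+(e-s))``, under which the printed length column reproduces
exactly and consecutive structures tile the region with no gaps.
"""

from __future__ import annotations

from importlib import resources

from .intervals import GenomicInterval, IntervalSet

CHROM = "chrX"

_PKG = "chromoband.data"


def _data_lines(name: str) -> list[list[str]]:
    text = resources.files(_PKG).joinpath(name).read_text()
    rows = [line.split("\t") for line in text.strip().splitlines()]
    return rows[1:]  # drop header


def _convert_pair(start_printed: int, end_printed: int) -> tuple[int, int]:
    """1-based printed pair -> 0-based half-open with length e - s."""
    length = end_printed - start_printed
    return start_printed - 1, start_printed - 1 + length


def load_region_map() -> IntervalSet:
    """All 17 structures of the region, labelled, with ``meta['kind']``
    in ``{"interband", "band"}``, alternating."""
    out = []
    for name, kind, s, e, length in _data_lines("region_9f13_10b3_map.tsv"):
        a, b = _convert_pair(int(s), int(e))
        assert b - a == int(length)
        out.append(GenomicInterval(CHROM, a, b, name, {"kind": kind}))
    return IntervalSet(out)


def load_interbands() -> IntervalSet:
    return IntervalSet(
        iv for iv in load_region_map() if iv.meta["kind"] == "interband"
    )


def load_bands() -> IntervalSet:
    return IntervalSet(
        iv for iv in load_region_map() if iv.meta["kind"] == "band"
    )


def region_extent() -> GenomicInterval:
    """The full converted span of the 9F13-10B3 map (427,600 bp)."""
    ivs = load_region_map()
    return GenomicInterval(CHROM, ivs[0].start, ivs[-1].end, "9F13-10B3")


def load_axial_lengths() -> dict[str, tuple[float, float]]:
    """EM axial length along the chromosome per structure: name ->
    (mean um, sd um); means over sections of 50 polytene chromosomes."""
    return {
        name: (float(a), float(sd))
        for name, a, sd in _data_lines("region_9f13_10b3_axial.tsv")
    }


def load_fish_probes() -> IntervalSet:
    """FISH probe intervals, labelled by probe name, with the interband
    each probe was assigned to in ``meta['target_interband']``."""
    out = []
    for name, target, s, e in _data_lines("region_9f13_10b3_probes.tsv"):
        a, b = _convert_pair(int(s), int(e))
        out.append(
            GenomicInterval(CHROM, a, b, name, {"target_interband": target})
        )
    return IntervalSet(out)
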