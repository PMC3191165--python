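"""Banding-map construction, classification, summaries and comparison."""

import numpy as np
import pytest

from chromoband import datasets
from chromoband.banding import (
    FAINT_EARLY,
    IH_LATE,
    BandingMap,
    build_banding_map,
    classify_band,
    classify_bands,
    compare_maps,
    interband_fraction,
    summarize_region,
)
from chromoband.caller import InterbandCall
from chromoband.intervals import GenomicInterval, IntervalSet
from chromoband.simulate import SimParams, generate


@pytest.fixture(scope="module")
def reference_map():
    return build_banding_map(
        datasets.load_interbands(),
        datasets.region_extent(),
        labels=datasets.load_region_map(),
    )


def _random_map(rng, region_len=10_000, n=4):
    region = GenomicInterval("c", 0, region_len)
    starts = np.sort(rng.choice(region_len - 200, size=n, replace=False))
    calls = []
    prev_end = 0
    for s in starts:
        s = max(int(s), prev_end + 1)
        e = min(s + int(rng.integers(50, 400)), region_len)
        if e <= s:
            continue
        calls.append(GenomicInterval("c", s, e))
        prev_end = e
    return build_banding_map(IntervalSet(calls), region)


class TestBuildBandingMap:
    def test_reference_interbands_give_eight_bands(self, reference_map):
        assert len(reference_map.interbands) == 9
        assert len(reference_map.bands) == 8
        assert reference_map.first_element == "interband"
        assert reference_map.last_element == "interband"
        names = [b.interval.label for b in reference_map.bands]
        assert names[0] == "10A1-2" and names[-1] == "10B1-2"

    def test_zero_calls_single_band(self):
        region = GenomicInterval("c", 0, 5000)
        bmap = build_banding_map(IntervalSet(), region)
        assert len(bmap.bands) == 1 and len(bmap.interbands) == 0
        assert bmap.bands[0].interval.length == 5000

    def test_random_calls_tile_region(self, rng):
        for _ in range(10):
            bmap = _random_map(rng)
            arr = np.zeros(10_000, dtype=int)
            for _, iv in bmap.elements:
                arr[iv.start: iv.end] += 1
            assert (arr == 1).all()

    def test_alternation_enforced(self):
        region = GenomicInterval("c", 0, 1000)
        with pytest.raises(ValueError, match="overlapping calls"):
            build_banding_map(
                [
                    InterbandCall.from_interval(GenomicInterval("c", 0, 500)),
                    InterbandCall.from_interval(GenomicInterval("c", 400, 600)),
                ],
                region,
            )

    def test_rebuild_from_extracted_interbands_is_identity(self, rng):
        bmap = _random_map(rng)
        again = build_banding_map(bmap.interband_set(), bmap.region)
        assert [iv.start for _, iv in again.elements] == [
            iv.start for _, iv in bmap.elements
        ]


class TestClassifyBand:
    def _iv(self, a, b):
        return GenomicInterval("c", a, b)

    def test_fully_repressive_band_is_ih(self):
        band = self._iv(0, 10_000)
        full = IntervalSet([band])
        assert classify_band(
            band, late=full, suur=full, lamin=full, open_chromatin=IntervalSet()
        ) == IH_LATE

    def test_unmarked_band_is_faint(self):
        band = self._iv(0, 10_000)
        assert classify_band(
            band, late=IntervalSet(), suur=IntervalSet(), lamin=IntervalSet()
        ) == FAINT_EARLY

    def test_open_chromatin_vetoes_ih(self):
        band = self._iv(0, 10_000)
        full = IntervalSet([band])
        assert classify_band(
            band, late=full, suur=full, lamin=full,
            open_chromatin=IntervalSet([self._iv(100, 200)]),
        ) == FAINT_EARLY

    def test_partial_late_replication_qualifies_at_default_threshold(self):
        band = self._iv(0, 10_000)
        distal_40 = IntervalSet([self._iv(0, 4000)])
        assert classify_band(band, late=distal_40) == IH_LATE
        assert classify_band(band, late=IntervalSet([self._iv(0, 3000)])) \
            == FAINT_EARLY

    def test_synthetic_region_gives_two_ih_six_faint(self):
        truth = generate(
            SimParams(seed=3, false_feature_rate=0.0, border_jitter_sd=0.0)
        )
        classes = classify_bands(truth.map, truth.domain_tracks)
        assert classes.count(IH_LATE) == 2
        assert classes.count(FAINT_EARLY) == 6
        assert classes == [b.band_class for b in truth.map.bands]

    def test_threshold_monotone(self, rng):
        band = self._iv(0, 10_000)
        late = IntervalSet([self._iv(0, int(rng.integers(1, 10_000)))])
        prev = None
        for t in (0.1, 0.3, 0.5, 0.7, 0.9):
            cls = classify_band(band, late=late, t_late=t)
            if prev == FAINT_EARLY:
                assert cls == FAINT_EARLY
            prev = cls

    def test_missing_replication_track_named(self):
        with pytest.raises(ValueError, match="late"):
            classify_band(self._iv(0, 100))


class TestSummarize:
    def test_reference_map_counts(self, reference_map):
        s = summarize_region(reference_map)
        assert s.n_interbands == 9
        assert s.n_bands == 8
        assert s.interband_bp + s.band_bp == s.region_bp
        assert s.interband_min == 600 and s.interband_max == 3000
        # bands are the complement of the printed interband extents; the
        # source map's own arithmetic leaves one base per border to
        # neither structure, which the bands absorb (+2 bp vs printed)
        assert s.band_max == 190_800

    def test_stated_totals_worked_example(self):
        # fraction computed from the published region totals
        assert round(interband_fraction(20_100, 428_307), 2) == 4.69

    def test_single_band_map(self):
        bmap = build_banding_map(IntervalSet(), GenomicInterval("c", 0, 1000))
        assert summarize_region(bmap).interband_fraction == 0.0

    def test_conservation_on_random_maps(self, rng):
        for _ in range(10):
            bmap = _random_map(rng)
            s = summarize_region(bmap)
            assert s.interband_bp + s.band_bp == bmap.region.length


class TestCompareMaps:
    def test_identical_maps(self, rng):
        a = _random_map(rng)
        table, gj = compare_maps(a, a)
        assert gj == 1.0
        assert (table["jaccard"] == 1.0).all()

    def test_disjoint_interband_sets(self):
        region = GenomicInterval("c", 0, 10_000)
        a = build_banding_map(
            IntervalSet([GenomicInterval("c", 1000, 2000)]), region
        )
        b = build_banding_map(
            IntervalSet([GenomicInterval("c", 5000, 6000)]), region
        )
        _, gj = compare_maps(a, b)
        assert gj == 0.0

    def test_overlaps_match_brute_force(self, rng):
        a, b = _random_map(rng), _random_map(rng)
        table, gj = compare_maps(a, b)
        for row, band in zip(table.itertuples(), a.bands):
            best = max(
                b.bands,
                key=lambda ob: band.interval.overlap_bp(ob.interval),
            )
            expect = band.interval.overlap_bp(best.interval)
            assert row.overlap_bp == expect
        ia = np.zeros(10_000, dtype=bool)
        ib_arr = np.zeros(10_000, dtype=bool)
        for c in a.interbands:
            ia[c.start: c.end] = True
        for c in b.interbands:
            ib_arr[c.start: c.end] = True
        union = np.logical_or(ia, ib_arr).sum()
        expect_gj = np.logical_and(ia, ib_arr).sum() / union if union else 1.0
        assert gj == pytest.approx(expect_gj)

    def test_different_regions_rejected(self):
        a = build_banding_map(IntervalSet(), GenomicInterval("c", 0, 1000))
        b = build_banding_map(IntervalSet(), GenomicInterval("c", 0, 2000))
        with pytest.raises(ValueError, match="different regions"):
            compare_maps(a, b)
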