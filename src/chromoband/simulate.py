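"""Synthetic region generator with planted band/interband ground truth.

Emulates the observed track structure of a polytene-mapped region:
alternating interbands and bands where open-chromatin marker classes
(interband proteins, DHS, H1 dips, ORC, active states, H3.3) co-localize
in short interbands; two large intercalary-heterochromatin (IH) bands on
the flanks of a "paling" of faint bands carry late-replication, SUUR and
lamin domains and BLACK chromatin; faint bands carry YELLOW chromatin
and no open markers.  Gene models are laid out so interbands coincide
with divergent TSS pairs, 5' ends, intergenic gaps or first exons, and
P-element insertions are enriched in interbands.

One integer seed drives a single generator stream; the draw order is
fixed (element sizes, marker presence + border jitter per class, spurious
features per class, insertions, axial ratios) so a given seed always
yields an identical truth object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .annotation import GeneModel
from .banding import BandingMap, FAINT_EARLY, IH_LATE, build_banding_map
from .caller import EVIDENCE_CLASSES, InterbandCall, MarkerPanel
from .intervals import GenomicInterval, IntervalSet, merge_intervals
from .tracks import InsertionTable

# one representative marker per evidence class
CLASS_MARKERS = {
    "interband_protein": "Chriz",
    "dhs": "DHS",
    "h1_dip": "H1_dip",
    "orc": "ORC2",
    "active_state": "PolII",
    "histone_variant": "H3.3",
}

# compaction-ratio ranges used to back-compute axial lengths
RATIO_RANGES = {"interband": (3, 15), "faint": (10, 75), "ih": (150, 210)}

_SPURIOUS_SIZE = (100, 600)  # bp; noise peaks are short
_CELL = "S2"


@dataclass(frozen=True)
class SimParams:
    """Study conditions of the synthetic region.

    Defaults follow the mapped 9F13-10B3-like structure: nine interbands
    of 600-3000 bp, two flanking IH bands of 150-200 kb around six faint
    bands of 2-17 kb, the region starting and ending with an interband.
    ``snr`` is the odds that a marker-class feature is a true interband
    feature rather than a spurious one; with ``false_feature_rate=None``
    the spurious Poisson rate is calibrated so those odds hold exactly.
    ``border_jitter_sd`` (25 bp, about tiling-array probe resolution)
    jitters each feature border independently.
    """

    region_length: int | None = None  # None: sum of drawn element sizes
    region_start: int = 0
    chrom: str = "chrSim"
    n_interbands: int = 9
    interband_size_range: tuple[int, int] = (600, 3000)
    ih_band_count: int = 2
    ih_band_size_range: tuple[int, int] = (150_000, 200_000)
    faint_band_size_range: tuple[int, int] = (2_000, 17_000)
    marker_classes: tuple[str, ...] = EVIDENCE_CLASSES
    snr: float = 10.0
    false_feature_rate: float | None = None  # spurious per kb outside truth
    border_jitter_sd: float = 25.0
    flank: str = "interband"  # region starts/ends with this element kind
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_interbands < 1:
            raise ValueError("n_interbands must be >= 1")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.flank not in {"interband", "band"}:
            raise ValueError("flank must be 'interband' or 'band'")
        for lo, hi in (
            self.interband_size_range,
            self.ih_band_size_range,
            self.faint_band_size_range,
        ):
            if lo <= 0 or hi < lo:
                raise ValueError("size ranges must be positive and ordered")
        unknown = set(self.marker_classes) - set(CLASS_MARKERS)
        if unknown:
            raise ValueError(f"unknown marker classes {sorted(unknown)}")


@dataclass
class SyntheticTruth:
    """Planted ground truth plus every derived synthetic input."""

    params: SimParams
    map: BandingMap
    panel: MarkerPanel
    states: IntervalSet
    genes: list[GeneModel]
    insertions: InsertionTable
    axial: dict[str, tuple[float, float]]
    domain_tracks: dict[str, IntervalSet]  # late / suur / lamin / open

    def serialize(self) -> str:
        """Stable textual form of the full truth, for determinism checks."""
        payload = {
            "map": [
                (kind, iv.label, iv.start, iv.end)
                for kind, iv in self.map.elements
            ],
            "panel": {
                f"{m}|{c}": [(iv.start, iv.end) for iv in trk]
                for (m, c), trk in sorted(self.panel.tracks.items())
            },
            "states": [
                (iv.label, iv.start, iv.end) for iv in self.states
            ],
            "genes": [
                (g.id, g.strand, g.interval.start, g.interval.end,
                 g.first_exon.start, g.first_exon.end)
                for g in self.genes
            ],
            "insertions": self.insertions.positions.tolist(),
            "axial": {k: list(v) for k, v in sorted(self.axial.items())},
        }
        return json.dumps(payload, sort_keys=True)


def _plan_elements(params: SimParams, rng: np.random.Generator):
    """Draw the ordered (kind, size) layout.  kind in
    {interband, ih, faint}."""
    n_ib = params.n_interbands
    n_band = n_ib - 1 if params.flank == "interband" else n_ib + 1
    if params.ih_band_count > n_band:
        raise ValueError(
            f"ih_band_count {params.ih_band_count} exceeds band count {n_band}"
        )
    if params.ih_band_count == 0:
        ih_slots: set[int] = set()
    elif params.ih_band_count == 1:
        ih_slots = {0}
    else:
        ih_slots = set(
            np.round(
                np.linspace(0, n_band - 1, params.ih_band_count)
            ).astype(int)
        )
    band_kinds = ["ih" if i in ih_slots else "faint" for i in range(n_band)]
    kinds: list[str] = []
    if params.flank == "interband":
        for i in range(n_band):
            kinds += ["interband", band_kinds[i]]
        kinds.append("interband")
    else:
        # band-flanked: B IB B ... IB B
        for i in range(n_band):
            kinds.append(band_kinds[i])
            if i < n_band - 1:
                kinds.append("interband")
    sizes = []
    ranges = {
        "interband": params.interband_size_range,
        "ih": params.ih_band_size_range,
        "faint": params.faint_band_size_range,
    }
    for kind in kinds:
        lo, hi = ranges[kind]
        sizes.append(int(rng.integers(lo, hi + 1)))
    if params.region_length is not None:
        ib_total = sum(s for k, s in zip(kinds, sizes) if k == "interband")
        band_total = sum(s for k, s in zip(kinds, sizes) if k != "interband")
        spare = params.region_length - ib_total
        if spare <= 0 or band_total == 0:
            raise ValueError(
                f"region_length {params.region_length} cannot hold "
                f"{ib_total} bp of interbands"
            )
        scale = spare / band_total
        sizes = [
            s if k == "interband" else max(1, int(round(s * scale)))
            for k, s in zip(kinds, sizes)
        ]
        drift = params.region_length - sum(sizes)
        # absorb rounding drift in the largest band
        j = max(
            (i for i, k in enumerate(kinds) if k != "interband"),
            key=lambda i: sizes[i],
        )
        sizes[j] += drift
        if sizes[j] <= 0:
            raise ValueError("infeasible packing for requested region_length")
    return kinds, sizes


def _jittered(
    iv: GenomicInterval,
    sd: float,
    rng: np.random.Generator,
    region: GenomicInterval,
) -> GenomicInterval:
    s = iv.start + int(round(rng.normal(0.0, sd))) if sd > 0 else iv.start
    e = iv.end + int(round(rng.normal(0.0, sd))) if sd > 0 else iv.end
    s = max(region.start, min(s, iv.end - 1))
    e = min(region.end, max(e, s + 1))
    return GenomicInterval(iv.chrom, s, e)


def _sample_positions_in(
    sets: Sequence[GenomicInterval], n: int, rng: np.random.Generator
) -> np.ndarray:
    """n positions uniform over the union of disjoint intervals."""
    lens = np.array([iv.length for iv in sets], dtype=np.int64)
    if lens.sum() == 0 or n == 0:
        return np.empty(0, dtype=np.int64)
    offsets = rng.integers(0, lens.sum(), size=n)
    edges = np.concatenate([[0], np.cumsum(lens)])
    idx = np.searchsorted(edges, offsets, side="right") - 1
    return np.array(
        [sets[i].start + (o - edges[i]) for i, o in zip(idx, offsets)],
        dtype=np.int64,
    )


def _gene_layout(
    ib_ivs: Sequence[GenomicInterval],
    band_ivs: Sequence[GenomicInterval],
    region: GenomicInterval,
) -> list[GeneModel]:
    """Deterministic gene layout giving each interband a planted genomic
    context: cycling divergent-pair / 5' end / intergenic / first exon,
    with the last interband planted as the internal (gene-body) case."""
    chrom = region.chrom
    genes: list[GeneModel] = []
    band_set = IntervalSet(band_ivs)

    def clamp_right(pos: int, ib_end: int) -> int:
        # keep gene ends inside the band to the right of the interband
        for b in band_set:
            if b.start >= ib_end:
                return min(pos, b.end - 300)
        return min(pos, region.end)

    def clamp_left(pos: int, ib_start: int) -> int:
        left = None
        for b in band_set:
            if b.end <= ib_start:
                left = b
        return max(pos, left.start + 300) if left else max(pos, region.start)

    patterns = ["divergent", "five_prime", "intergenic", "first_exon"]
    for i, ib in enumerate(ib_ivs):
        kind = (
            "internal" if i == len(ib_ivs) - 1 and len(ib_ivs) > 1
            else patterns[i % len(patterns)]
        )
        gid = f"gene_{i}"
        if kind == "divergent":
            a_start = clamp_left(ib.start - 2000, ib.start)
            a = GenomicInterval(chrom, a_start, min(ib.start + 50, ib.end))
            genes.append(GeneModel(
                gid + "a", a, "-",
                GenomicInterval(chrom, max(a.end - 400, a.start), a.end),
            ))
            b_end = clamp_right(ib.end + 2000, ib.end)
            b = GenomicInterval(chrom, max(ib.end - 50, ib.start), b_end)
            genes.append(GeneModel(
                gid + "b", b, "+",
                GenomicInterval(chrom, b.start, min(b.start + 400, b.end)),
            ))
        elif kind == "five_prime":
            end = clamp_right(ib.midpoint + 2500, ib.end)
            g = GenomicInterval(chrom, ib.midpoint, end)
            genes.append(GeneModel(
                gid, g, "+",
                GenomicInterval(chrom, g.start, min(g.start + 300, g.end)),
            ))
        elif kind == "intergenic":
            # keep gene ends clear of the interband by more than any
            # plausible tss_slop so the gap is genuinely intergenic
            left_end = ib.start - 400
            left_start = clamp_left(left_end - 1500, ib.start)
            if left_end > left_start:
                g = GenomicInterval(chrom, left_start, left_end)
                genes.append(GeneModel(
                    gid + "a", g, "+",
                    GenomicInterval(chrom, g.start, min(g.start + 300, g.end)),
                ))
            right_start = ib.end + 400
            right_end = clamp_right(right_start + 1500, ib.end)
            if right_end > right_start:
                g = GenomicInterval(chrom, right_start, right_end)
                genes.append(GeneModel(
                    gid + "b", g, "+",
                    GenomicInterval(chrom, g.start, min(g.start + 300, g.end)),
                ))
        elif kind == "first_exon":
            start = clamp_left(ib.start - 400, ib.start)
            end = clamp_right(ib.end + 1000, ib.end)
            g = GenomicInterval(chrom, start, end)
            fe_end = min(ib.start + 200, g.end)
            genes.append(GeneModel(
                gid, g, "+", GenomicInterval(chrom, g.start, fe_end),
            ))
        else:  # internal
            start = clamp_left(ib.start - 1000, ib.start)
            end = clamp_right(ib.end + 1000, ib.end)
            g = GenomicInterval(chrom, start, end)
            fe_end = min(g.start + 300, ib.start)
            genes.append(GeneModel(
                gid, g, "+", GenomicInterval(chrom, g.start, max(fe_end, g.start)),
            ))
    return genes


def generate(params: SimParams | None = None) -> SyntheticTruth:
    """Generate a synthetic region with planted ground truth.

    Deterministic given ``params.seed``.  Raises on infeasible packing.
    """
    params = params or SimParams()
    rng = np.random.default_rng(params.seed)
    chrom = params.chrom
    kinds, sizes = _plan_elements(params, rng)

    # --- planted map
    ivs: list[GenomicInterval] = []
    cursor = params.region_start
    ib_i = band_i = ih_i = 0
    for kind, size in zip(kinds, sizes):
        if kind == "interband":
            ib_i += 1
            label = f"interband_{ib_i}"
        elif kind == "ih":
            ih_i += 1
            label = f"IH_band_{ih_i}"
        else:
            band_i += 1
            label = f"band_{band_i}"
        ivs.append(GenomicInterval(chrom, cursor, cursor + size, label,
                                   {"kind": kind}))
        cursor += size
    region = GenomicInterval(chrom, params.region_start, cursor, "synthetic")
    ib_ivs = [iv for iv in ivs if iv.meta["kind"] == "interband"]
    band_ivs = [iv for iv in ivs if iv.meta["kind"] != "interband"]
    truth_map = build_banding_map(
        IntervalSet(ib_ivs), region, labels=IntervalSet(ivs)
    )
    planted_class = {}
    for iv in band_ivs:
        planted_class[iv.label] = IH_LATE if iv.meta["kind"] == "ih" else FAINT_EARLY
    bands = []
    for b in truth_map.bands:
        b.band_class = planted_class[b.interval.label]
        bands.append(b)

    # --- marker panel: true features per class, then spurious
    p_true = params.snr / (1.0 + params.snr)
    outside_kb = sum(iv.length for iv in band_ivs) / 1000.0
    if params.false_feature_rate is None:
        lam = params.n_interbands * (1.0 - p_true)
    else:
        lam = params.false_feature_rate * outside_kb
    tracks: dict[tuple[str, str], IntervalSet] = {}
    class_of: dict[str, str] = {}
    for cls in params.marker_classes:
        marker = CLASS_MARKERS[cls]
        class_of[marker] = cls
        feats: list[GenomicInterval] = []
        for ib in ib_ivs:
            if rng.random() < p_true:
                feats.append(
                    _jittered(ib, params.border_jitter_sd, rng, region)
                )
        n_spur = int(rng.poisson(lam))
        if n_spur and band_ivs:
            pos = _sample_positions_in(band_ivs, n_spur, rng)
            lens = rng.integers(
                _SPURIOUS_SIZE[0], _SPURIOUS_SIZE[1] + 1, size=n_spur
            )
            for p0, ln in zip(pos, lens):
                # confine noise to its band so it cannot bridge interbands
                host = next(b for b in band_ivs if b.contains(int(p0)))
                e = min(int(p0) + int(ln), host.end)
                if e > p0:
                    feats.append(GenomicInterval(chrom, int(p0), e))
        tracks[(marker, _CELL)] = IntervalSet(feats)
    panel = MarkerPanel(region=region, tracks=tracks, class_of=class_of)

    # --- chromatin states / repressive domains
    colour = {"interband": "RED", "faint": "YELLOW", "ih": "BLACK"}
    states = IntervalSet(
        iv.replace(label=colour[iv.meta["kind"]]) for iv in ivs
    )
    ih_ivs = [iv for iv in ivs if iv.meta["kind"] == "ih"]
    late = []
    for j, iv in enumerate(ih_ivs):
        if j == 1:
            # second IH band completes replication late over only ~45%
            # of its extent (partially late-replicating IH)
            late.append(iv.replace(end=iv.start + int(0.45 * iv.length)))
        else:
            late.append(iv)
    domain_tracks = {
        "late": IntervalSet(late),
        "suur": IntervalSet(ih_ivs),
        "lamin": IntervalSet(ih_ivs),
        "open": merge_intervals(
            IntervalSet(iv for s in tracks.values() for iv in s)
        ),
    }

    # --- genes (deterministic layout)
    genes = _gene_layout(ib_ivs, band_ivs, region)

    # --- P-element insertions: enriched in interbands
    ins_pos: list[int] = []
    for iv in ivs:
        rate = 2.0 if iv.meta["kind"] == "interband" else 0.1  # per kb
        n_ins = int(rng.poisson(rate * iv.length / 1000.0))
        if n_ins:
            ins_pos.extend(
                int(x) for x in rng.integers(iv.start, iv.end, size=n_ins)
            )
    insertions = InsertionTable(chrom, np.sort(np.array(ins_pos, dtype=np.int64)))

    # --- axial lengths back-computed from class-typical compaction ratios
    axial: dict[str, tuple[float, float]] = {}
    for iv in ivs:
        lo, hi = RATIO_RANGES[iv.meta["kind"]]
        ratio = rng.uniform(lo, hi)
        c_um = iv.length * 0.34 / 1000.0
        a = c_um / ratio
        axial[iv.label] = (a, 0.1 * a)

    return SyntheticTruth(
        params=params,
        map=BandingMap(region, truth_map.interbands, tuple(bands)),
        panel=panel,
        states=states,
        genes=genes,
        insertions=insertions,
        axial=axial,
        domain_tracks=domain_tracks,
    )


def corrupt(
    truth: SyntheticTruth,
    delete_rate: float = 0.0,
    spurious_per_kb: float = 0.0,
    seed: int = 0,
) -> MarkerPanel:
    """Degrade a truth panel: delete true features / add spurious ones.

    Each existing feature survives with probability ``1 - delete_rate``;
    spurious features are added as a Poisson process over the whole
    region at ``spurious_per_kb``.  Ground truth is untouched, so the
    result can be evaluated against ``truth.map``.
    """
    if not 0.0 <= delete_rate <= 1.0:
        raise ValueError("delete_rate must be in [0, 1]")
    if spurious_per_kb < 0:
        raise ValueError("spurious_per_kb must be >= 0")
    rng = np.random.default_rng(seed)
    region = truth.panel.region
    new_tracks: dict[tuple[str, str], IntervalSet] = {}
    for key in sorted(truth.panel.tracks):
        track = truth.panel.tracks[key]
        kept = [iv for iv in track if rng.random() >= delete_rate]
        n_spur = int(rng.poisson(spurious_per_kb * region.length / 1000.0))
        for _ in range(n_spur):
            p0 = int(rng.integers(region.start, region.end))
            ln = int(rng.integers(_SPURIOUS_SIZE[0], _SPURIOUS_SIZE[1] + 1))
            kept.append(
                GenomicInterval(region.chrom, p0, min(p0 + ln, region.end))
            )
        new_tracks[key] = IntervalSet(kept)
    return MarkerPanel(
        region=region, tracks=new_tracks, class_of=dict(truth.panel.class_of)
    )


@dataclass(frozen=True)
class CallEvaluation:
    precision: float
    recall: float
    mean_jaccard: float
    border_error_bp: float
    n_calls: int
    n_planted: int


def evaluate_calls(
    calls: Sequence[InterbandCall], truth_map: BandingMap
) -> CallEvaluation:
    """Score calls against a planted map.

    Each call is matched to the planted interband it overlaps most (ties
    to the leftmost).  precision = overlapping calls / calls (1.0 when
    there are no calls); recall = planted interbands hit by >= 1 call /
    planted; mean Jaccard is over planted interbands with their
    best-overlapping call (0 for missed ones); border error is the mean
    |edge displacement| over matched pairs.
    """
    planted = [c.interval for c in truth_map.interbands]
    n_calls = len(calls)
    matched_calls = 0
    hit = [False] * len(planted)
    edge_errors: list[float] = []
    for call in calls:
        best_j, best_ov = None, 0
        for j, p in enumerate(planted):
            ov = call.interval.overlap_bp(p)
            if ov > best_ov:
                best_j, best_ov = j, ov
        if best_j is not None:
            matched_calls += 1
            hit[best_j] = True
            p = planted[best_j]
            edge_errors.append(
                (abs(call.interval.start - p.start)
                 + abs(call.interval.end - p.end)) / 2.0
            )
    jaccards = []
    for p in planted:
        best = max(
            (call.interval.jaccard(p) for call in calls
             if call.interval.overlap_bp(p) > 0),
            default=0.0,
        )
        jaccards.append(best)
    return CallEvaluation(
        precision=matched_calls / n_calls if n_calls else 1.0,
        recall=sum(hit) / len(planted) if planted else 1.0,
        mean_jaccard=float(np.mean(jaccards)) if jaccards else 1.0,
        border_error_bp=float(np.mean(edge_errors)) if edge_errors else 0.0,
        n_calls=n_calls,
        n_planted=len(planted),
    )
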