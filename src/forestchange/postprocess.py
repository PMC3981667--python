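"""From per-pixel labels to a polygon-based six-category map.

Per-pixel classifications are noisy at the pixel scale, so the map is
composed per region: the disturbed layer is first cleaned by a binary
opening, the bi-temporal imagery (red, NIR, SWIR at both dates) is
segmented by best-merge region growing, each segment takes the plurality
of the per-pixel labels it covers, segments below the minimum mapping unit
are absorbed into their spectrally nearest neighbour, and finally the
masked categories (water, cloud, cloud shadow, stable non-forest) are
painted back in with fixed precedence.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import PipelineConfig
from .masking import MaskSet
from .raster_io import CLASS_CODES, ChangeMap, Grid, ScenePair, vectorize
from .training import DISTURBED, NO_CHANGE

logger = logging.getLogger(__name__)

#: bands driving segmentation, at both dates
SEGMENT_BANDS = ("red", "nir", "swir1")


def morphological_clean(labels: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    """Open the disturbed layer; pixels opened away revert to no-change."""
    out = labels.copy()
    disturbed = labels == DISTURBED
    if cfg.morph_radius < 1 or not disturbed.any():
        return out
    foot = np.ones((2 * cfg.morph_radius + 1,) * 2, dtype=bool)
    opened = ndimage.binary_opening(disturbed, structure=foot)
    out[disturbed & ~opened] = NO_CHANGE
    return out


@dataclass
class SegmentMap:
    """Segment ids (1..n) over valid pixels, 0 elsewhere."""

    ids: np.ndarray  # (H, W) int
    sizes: np.ndarray  # (n+1,), sizes[0] unused
    means: np.ndarray  # (n+1, 6) mean spectral vectors

    @property
    def n_segments(self) -> int:
        return int(self.ids.max())


def segment(pair: ScenePair, masks: MaskSet, cfg: PipelineConfig) -> SegmentMap:
    """Region-merging segmentation of the six-band bi-temporal stack.

    Every valid pixel starts as its own segment.  Merging proceeds in
    rounds: each round, every segment locates its spectrally nearest
    8-connected neighbour (Euclidean distance between segment mean
    vectors); the resulting candidate pairs below ``merge_threshold`` are
    scanned in increasing distance order and merged greedily, each segment
    participating in at most one merge per round.  The globally closest
    pair is always merged first, so the rounds approximate best-merge
    behaviour while the per-round work stays vectorized and the number of
    rounds logarithmic; merging stops when no adjacent pair is closer than
    the threshold.  A final pass force-merges every segment smaller than
    the minimum mapping unit into its spectrally nearest neighbour.
    Connected components of the valid region that are themselves smaller
    than the minimum mapping unit cannot form a legal polygon and are
    excluded from segmentation (they keep id 0).  Entirely deterministic:
    ties break toward smaller ids.
    """
    from skimage.measure import label as cc_label

    valid = masks.valid.copy()
    h, w = valid.shape
    comp = cc_label(valid, connectivity=2)
    comp_sizes = np.bincount(comp.ravel())
    tiny = comp_sizes < cfg.mmu
    tiny[0] = False
    if tiny.any():
        valid &= ~tiny[comp]
    ids = np.full((h, w), 0, dtype=np.int64)
    n = int(valid.sum())
    if n == 0:
        return SegmentMap(ids=ids, sizes=np.zeros(1, dtype=np.int64), means=np.zeros((1, 6)))

    stack = np.stack(
        [pair.early.bands[b] for b in SEGMENT_BANDS]
        + [pair.late.bands[b] for b in SEGMENT_BANDS],
        axis=-1,
    )
    rows, cols = np.nonzero(valid)
    pix_id = np.full((h, w), -1, dtype=np.int64)
    pix_id[rows, cols] = np.arange(n)

    sums = stack[rows, cols].astype(np.float64)  # (n, 6) running band sums
    sizes = np.ones(n, dtype=np.int64)
    root = np.arange(n, dtype=np.int64)

    # initial 8-connected edges among valid pixels (each unordered pair once)
    parts = []
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        a = pix_id[max(0, -dr) : h - max(0, dr), max(0, -dc) : w - max(0, dc)]
        b = pix_id[max(0, dr) : h - max(0, -dr), max(0, dc) : w - max(0, -dc)]
        both = (a >= 0) & (b >= 0)
        parts.append(np.stack([a[both], b[both]], axis=1))
    edges = np.concatenate(parts)

    thr = cfg.merge_threshold
    while len(edges):
        ea = root[edges[:, 0]]
        eb = root[edges[:, 1]]
        live = ea != eb
        edges = edges[live]
        if not len(edges):
            break
        ea, eb = ea[live], eb[live]
        means = sums / sizes[:, None]
        d = np.sqrt(((means[ea] - means[eb]) ** 2).sum(axis=1))
        under = d < thr
        if not under.any():
            break
        ea_u, eb_u, d_u = ea[under], eb[under], d[under]
        # nearest neighbour of every segment: order half-edges by (distance,
        # partner id) and keep each segment's first occurrence
        seg = np.concatenate([ea_u, eb_u])
        partner = np.concatenate([eb_u, ea_u])
        order = np.lexsort((partner, np.concatenate([d_u, d_u])))
        seg_sorted = seg[order]
        first = np.unique(seg_sorted, return_index=True)[1]
        seg_first = seg_sorted[first]
        part_first = partner[order][first]
        d_first = np.concatenate([d_u, d_u])[order][first]
        # greedy absorption: scan candidate pairs in increasing distance
        # order; the larger segment keeps its identity and may absorb
        # several partners in one round, while each absorbed segment is
        # consumed at most once
        lo = np.minimum(seg_first, part_first)
        hi = np.maximum(seg_first, part_first)
        scan = np.lexsort((hi, lo, d_first))
        consumed = np.zeros(n, dtype=bool)
        root_map = np.arange(n, dtype=np.int64)
        n_merged = 0
        for i in scan:
            a, b = int(lo[i]), int(hi[i])
            if consumed[a] or consumed[b]:
                continue
            if sizes[b] > sizes[a] or (sizes[b] == sizes[a] and b < a):
                a, b = b, a
            sums[a] += sums[b]
            sizes[a] += sizes[b]
            consumed[b] = True
            root_map[b] = a
            n_merged += 1
        if n_merged == 0:
            break
        # compress absorption chains before relabelling pixels
        while True:
            nxt = root_map[root_map]
            if (nxt == root_map).all():
                break
            root_map = nxt
        root = root_map[root]

    # MMU pass: absorb small segments into their spectrally nearest neighbour
    ea = root[edges[:, 0]] if len(edges) else np.empty(0, dtype=np.int64)
    eb = root[edges[:, 1]] if len(edges) else np.empty(0, dtype=np.int64)
    live = ea != eb
    seg_edges = {(int(a), int(b)) if a < b else (int(b), int(a))
                 for a, b in zip(ea[live], eb[live])}
    neighbors: dict[int, set[int]] = {}
    for a, b in seg_edges:
        neighbors.setdefault(a, set()).add(b)
        neighbors.setdefault(b, set()).add(a)

    def _resolve(i: int) -> int:
        while root[i] != i:
            root[i] = root[root[i]]
            i = root[i]
        return int(i)

    small = [
        (int(sizes[r]), int(r)) for r in np.unique(root) if sizes[r] < cfg.mmu
    ]
    heapq.heapify(small)
    while small:
        sz, r = heapq.heappop(small)
        r = _resolve(r)
        if sizes[r] >= cfg.mmu:
            continue
        nbs = {_resolve(nb) for nb in neighbors.get(r, set())} - {r}
        neighbors[r] = nbs
        if not nbs:
            continue  # isolated valid component smaller than the MMU: kept
        m_r = sums[r] / sizes[r]
        best_nb, best_d = -1, np.inf
        for nb in sorted(nbs):
            dd = float(np.sqrt(((m_r - sums[nb] / sizes[nb]) ** 2).sum()))
            if dd < best_d:
                best_nb, best_d = nb, dd
        keep, gone = (r, best_nb) if r < best_nb else (best_nb, r)
        root[gone] = keep
        sums[keep] += sums[gone]
        sizes[keep] += sizes[gone]
        merged_nbs = (neighbors.get(r, set()) | neighbors.get(best_nb, set())) - {r, best_nb}
        neighbors[keep] = merged_nbs
        for nb in merged_nbs:
            neighbors.setdefault(nb, set()).discard(gone)
            neighbors[nb].add(keep)
        neighbors.pop(gone, None)
        if sizes[keep] < cfg.mmu:
            heapq.heappush(small, (int(sizes[keep]), keep))

    # relabel to consecutive ids starting at 1
    for _ in range(64):  # full path compression
        nxt = root[root]
        if (nxt == root).all():
            break
        root = nxt
    uniq, inverse = np.unique(root, return_inverse=True)
    ids[rows, cols] = inverse + 1
    seg_sizes = np.concatenate(([0], sizes[uniq]))
    seg_means = np.concatenate(
        ([np.zeros(6)], sums[uniq] / sizes[uniq][:, None]), axis=0
    )
    logger.info("segmentation produced %d segments over %d valid pixels", len(uniq), n)
    return SegmentMap(ids=ids, sizes=seg_sizes, means=seg_means)


def plurality_label(seg: SegmentMap, labels: np.ndarray) -> np.ndarray:
    """Most frequent per-pixel label per segment; any tie goes to no-change.

    Returns an array of per-segment labels indexed by segment id (entry 0
    unused).  Pixels with the prediction sentinel are ignored in the count.
    """
    n_seg = seg.n_segments
    out = np.full(n_seg + 1, NO_CHANGE, dtype=np.int64)
    inside = (seg.ids > 0) & (labels >= 0)
    if not inside.any():
        return out
    sid = seg.ids[inside]
    lab = labels[inside]
    n_labels = int(lab.max()) + 1
    counts = np.zeros((n_seg + 1, n_labels), dtype=np.int64)
    np.add.at(counts, (sid, lab), 1)
    top = counts.max(axis=1)
    argtop = counts.argmax(axis=1)
    tie = (counts == top[:, None]).sum(axis=1) > 1
    has_pixels = top > 0
    out[has_pixels & ~tie] = argtop[has_pixels & ~tie]
    return out


def compose_final(
    seg: SegmentMap,
    segment_labels: np.ndarray,
    masks: MaskSet,
    nodata: np.ndarray,
    grid: Grid,
) -> ChangeMap:
    """Assemble the six-category map with fixed precedence.

    Precedence (highest wins): cloud > shadow > water > stable non-forest >
    classified labels.  Segment labels map disturbed → code 1 and both
    no-change and regrowth → stable forest (code 2); valid-era pixels that
    were never forest become stable non-forest (code 3).
    """
    h, w = seg.ids.shape
    raster = np.full((h, w), CLASS_CODES["stable_nonforest"], dtype=np.uint8)
    # forested pixels that produced no segment (e.g. fragments below the
    # minimum mapping unit) default to stable forest rather than non-forest
    raster[masks.forest_early] = CLASS_CODES["stable_forest"]
    inside = seg.ids > 0
    lab = segment_labels[seg.ids[inside]]
    codes = np.where(
        lab == DISTURBED, CLASS_CODES["disturbed"], CLASS_CODES["stable_forest"]
    )
    raster[inside] = codes
    # increasing precedence
    raster[masks.water_early | masks.water_late] = CLASS_CODES["water"]
    raster[masks.shadow_early | masks.shadow_late] = CLASS_CODES["cloud_shadow"]
    raster[masks.cloud_early | masks.cloud_late] = CLASS_CODES["cloud"]
    raster[nodata] = CLASS_CODES["nodata"]
    cmap = ChangeMap(class_raster=raster, grid=grid)
    cmap.polygons = vectorize(raster, grid)
    return cmap
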