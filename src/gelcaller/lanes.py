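"""Curved-lane segmentation by strip-wise intensity histograms.

The gel is cut into N horizontal strips whose heights follow the banding
pattern: the row-intensity profile r(m) = Σ_n p[m,n] localises
high-contrast (band-bearing) regions, and strip boundaries fall at the
midpoints between them.  Within each strip the column-intensity profile
c_i(n) = Σ_m p[m,n] is smoothed with a 3-point moving average; lane
boundaries are its prominent local minima (bands-bright convention — the
gaps between lanes carry the least stain).  Per-strip boundaries are then
stitched across strips by a minimum-total-displacement monotone matching,
yielding piecewise-linear lane boundaries that track laterally drifting
lanes.  A straight-lane mode runs the same machinery on a single strip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter, uniform_filter1d
from scipy.signal import peak_prominences, peak_widths

from .config import BoundaryConfig, RunConfig, StitchConfig, StripConfig
from .image import GelImage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StripSet:
    """Contiguous half-open row intervals tiling [0, H)."""

    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("empty strip set")
        prev = 0
        for start, end in self.intervals:
            if start != prev or end <= start:
                raise ValueError(f"strips must tile [0, H) contiguously, got {self.intervals}")
            prev = end

    @property
    def heights(self) -> list[int]:
        return [end - start for start, end in self.intervals]

    @property
    def total_height(self) -> int:
        return self.intervals[-1][1]


@dataclass(frozen=True)
class IntensityProfile:
    """Summed intensities along one axis (column profile c(n) or row profile r(m))."""

    values: np.ndarray
    axis: str  # "column" or "row"
    smoothed: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1 or (v < 0).any():
            raise ValueError("profile must be a 1-D non-negative vector")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class LaneBoundary:
    """Piecewise-linear boundary: (row, column) breakpoints, rows increasing 0..H."""

    breakpoints: tuple[tuple[float, float], ...]

    def columns_at(self, rows: np.ndarray) -> np.ndarray:
        bp_rows = np.array([r for r, _ in self.breakpoints])
        bp_cols = np.array([c for _, c in self.breakpoints])
        return np.interp(rows, bp_rows, bp_cols)


@dataclass(frozen=True)
class Lane:
    """A rectified lane: rows resampled between two boundaries to fixed width."""

    index: int
    left: LaneBoundary
    right: LaneBoundary
    width: int
    pixels: np.ndarray  # H x width, uint8

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


def row_profile(image: GelImage) -> IntensityProfile:
    """r(m) = Σ_n p[m,n] — total intensity per row."""
    return IntensityProfile(image.pixels.sum(axis=1, dtype=np.float64), axis="row")


def column_profile(image: GelImage, strip: tuple[int, int]) -> IntensityProfile:
    """c_i(n) = Σ_{m in strip} p[m,n] — total intensity per column within a strip."""
    start, end = strip
    if not (0 <= start < end <= image.height):
        raise ValueError(f"strip {strip} outside image of height {image.height}")
    return IntensityProfile(
        image.pixels[start:end].sum(axis=0, dtype=np.float64), axis="column"
    )


def smooth_profile(profile: IntensityProfile) -> IntensityProfile:
    """3-point moving average with edge replication (length preserved)."""
    if len(profile.values) < 3:
        raise ValueError("profile too short to smooth (need length >= 3)")
    sm = uniform_filter1d(profile.values, size=3, mode="nearest")
    return IntensityProfile(sm, axis=profile.axis, smoothed=True)


def _high_contrast_regions(values: np.ndarray, percentile: float, merge_gap: int) -> list[tuple[int, int]]:
    """Half-open runs of high-contrast rows, merged across small gaps.

    Contrast is measured on the detrended profile (a wide running median
    removes background illumination gradients), thresholded at the given
    percentile but never below 10% of the residual's peak — so sensor
    noise alone cannot manufacture a region.
    """
    baseline = median_filter(values, size=max(3, len(values) // 4), mode="nearest")
    res = values - baseline
    if res.max() <= 0:
        return []
    thresh = max(np.percentile(res, percentile), 0.1 * res.max())
    mask = res > thresh
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    regions: list[list[int]] = [[idx[0], idx[0] + 1]]
    for i in idx[1:]:
        if i - regions[-1][1] <= merge_gap:
            regions[-1][1] = i + 1
        else:
            regions.append([i, i + 1])
    return [(a, b) for a, b in regions]


def compute_strips(image: GelImage, cfg: StripConfig | None = None) -> StripSet:
    """Place strip boundaries at midpoints between band-bearing row regions.

    Falls back to ``fallback_n`` equal strips when fewer than two
    high-contrast regions exist (sparse banding or a uniform image).
    """
    cfg = cfg or StripConfig()
    H = image.height
    rp = smooth_profile(row_profile(image)) if H >= 3 else row_profile(image)
    regions = _high_contrast_regions(rp.values, cfg.percentile, cfg.merge_gap)
    if len(regions) < 2:
        return _equal_strips(H, cfg.fallback_n, cfg.min_height)
    centers = [(a + b - 1) / 2 for a, b in regions]
    cuts = [int(round((centers[i] + centers[i + 1]) / 2)) for i in range(len(centers) - 1)]
    edges = [0] + [c for c in cuts if 0 < c < H] + [H]
    edges = sorted(set(edges))
    # merge strips shorter than min_height into the previous (or next) one
    merged = [edges[0]]
    for e in edges[1:-1]:
        if e - merged[-1] >= cfg.min_height and H - e >= cfg.min_height:
            merged.append(e)
    merged.append(H)
    if len(merged) < 3:
        return _equal_strips(H, cfg.fallback_n, cfg.min_height)
    return StripSet(tuple((merged[i], merged[i + 1]) for i in range(len(merged) - 1)))


def _equal_strips(H: int, n: int, min_height: int) -> StripSet:
    n = max(1, min(n, H // max(min_height, 1)) or 1)
    edges = np.linspace(0, H, n + 1).round().astype(int)
    return StripSet(tuple((int(edges[i]), int(edges[i + 1])) for i in range(n)))


def detect_boundaries(
    smoothed: IntensityProfile,
    cfg: BoundaryConfig | None = None,
    min_prominence: float = 0.0,
) -> list[int]:
    """Columns of prominent local minima of a smoothed column profile.

    Under the bands-bright convention the inter-lane gaps are profile
    valleys.  Three gates separate them from look-alikes:

    * prominence >= ``prominence_frac`` of the profile range (or the
      absolute ``min_prominence`` floor a caller may pass for strips that
      carry no bands) — a real valley is carved by band-scale intensity;
    * prominence >= ``noise_sigmas`` x the profile's estimated noise, so
      sensor noise alone cannot make a boundary;
    * the valley bottom must lie in the lower ``max_rel_depth`` of the
      range — inter-lane gaps descend to background, while noise dips on
      a bright lane plateau stay high.

    Surviving minima closer than ``min_lane_width`` are thinned
    deepest-first (ties to the leftmost).  Columns 0 and W-1 are always
    returned as the outer boundaries; a flat profile yields only those,
    signalling "no lanes".
    """
    cfg = cfg or BoundaryConfig()
    v = smoothed.values
    W = len(v)
    outer = [0, W - 1] if W > 1 else [0]
    rng = v.max() - v.min()
    if rng == 0:
        return outer
    neg = -v
    # local maxima of neg == local minima of v; plateaus take the leftmost column
    cand = [
        n
        for n in range(1, W - 1)
        if neg[n] > neg[n - 1] and (neg[n] > neg[n + 1] or _plateau_right_drops(neg, n))
    ]
    if not cand:
        return outer
    # robust noise scale: median |first difference| is dominated by the
    # flat stretches of the profile, not the few band-edge transitions
    sigma = 1.4826 * float(np.median(np.abs(np.diff(v)))) / np.sqrt(2.0)
    prom = peak_prominences(neg, cand)[0]
    min_prom = max(cfg.prominence_frac * rng, min_prominence, cfg.noise_sigmas * sigma)
    depth_cut = v.min() + cfg.max_rel_depth * rng
    cand = [(n, p) for n, p in zip(cand, prom) if p >= min_prom and v[n] <= depth_cut]
    # deepest-first thinning with min_lane_width spacing; tie -> leftmost
    cand.sort(key=lambda t: (v[t[0]], t[0]))
    kept: list[int] = []
    for n, _ in cand:
        if all(abs(n - k) >= cfg.min_lane_width for k in kept):
            kept.append(n)
    return sorted(set(outer + kept))


def valley_widths(smoothed: IntensityProfile, cols: list[int]) -> dict[int, float]:
    """Half-prominence width of each interior valley, in columns.

    An inter-lane gap is a narrow notch between two bright lane plateaus;
    the centre of a lane that happens to carry no band in a strip sits in
    a background basin roughly a full lane pitch wide.  Width at half
    prominence separates the two geometries.
    """
    v = smoothed.values
    interior = [c for c in cols if 0 < c < len(v) - 1]
    if not interior:
        return {}
    w = peak_widths(-v, interior, rel_height=0.5)[0]
    return {c: float(x) for c, x in zip(interior, w)}


def _plateau_right_drops(neg: np.ndarray, n: int) -> bool:
    """True when n starts a plateau that eventually falls off to the right."""
    j = n + 1
    while j < len(neg) and neg[j] == neg[n]:
        j += 1
    return j < len(neg) and neg[j] < neg[n]


def match_boundaries(
    cols_a: list[int],
    cols_b: list[int],
    max_drift: int,
    allow_a: list[float] | None = None,
) -> list[tuple[int | None, int | None]]:
    """Minimum-total-displacement monotone matching of two boundary lists.

    Dynamic programming over the two ordered lists: matching a with b
    costs |a-b| and is allowed only within ``max_drift``; leaving a
    boundary unmatched costs ``max_drift`` (it will be propagated
    vertically).  ``allow_a`` widens the admissible displacement per
    entry of ``cols_a`` (used for chains unobserved in recent strips,
    whose accumulated drift can exceed one step's bound); their match
    cost is rescaled so wide-radius matches never beat near ones.
    Returns (i, j) pairs in order, with None marking an unmatched side.
    Ties prefer matching, then the leftmost option.
    """
    na, nb = len(cols_a), len(cols_b)
    INF = float("inf")
    gap = float(max_drift)
    allow = [float(max_drift)] * na if allow_a is None else [float(a) for a in allow_a]
    cost = np.full((na + 1, nb + 1), INF)
    choice = np.zeros((na + 1, nb + 1), dtype=np.int8)  # 1=match, 2=skip a, 3=skip b
    cost[0, 0] = 0.0
    for i in range(na + 1):
        for j in range(nb + 1):
            if i == 0 and j == 0:
                continue
            best, pick = INF, 0
            if i > 0 and j > 0:
                d = abs(cols_a[i - 1] - cols_b[j - 1])
                if d <= allow[i - 1]:
                    c = cost[i - 1, j - 1] + d * gap / allow[i - 1]
                    if c < best:
                        best, pick = c, 1
            if i > 0 and cost[i - 1, j] + gap < best:
                best, pick = cost[i - 1, j] + gap, 2
            if j > 0 and cost[i, j - 1] + gap < best:
                best, pick = cost[i, j - 1] + gap, 3
            cost[i, j], choice[i, j] = best, pick
    pairs: list[tuple[int | None, int | None]] = []
    i, j = na, nb
    while i > 0 or j > 0:
        pick = choice[i, j]
        if pick == 1:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif pick == 2:
            pairs.append((i - 1, None))
            i -= 1
        else:
            pairs.append((None, j - 1))
            j -= 1
    pairs.reverse()
    return pairs


def stitch_boundaries(
    per_strip: list[list[int]],
    strips: StripSet,
    cfg: StitchConfig | None = None,
    min_lane_width: int = 5,
    per_strip_widths: list[dict[int, float]] | None = None,
    breakpoint_rows: list[float] | None = None,
) -> list[LaneBoundary]:
    """Chain per-strip boundary columns into full-height lane boundaries.

    Adjacent strips are joined by :func:`match_boundaries`; unmatched
    boundaries propagate vertically (same column) so every chain spans
    all strips.  Each chain becomes a piecewise-linear boundary with a
    breakpoint at every strip's vertical midpoint, extended to rows 0
    and H.  A final repair pass enforces the non-crossing invariant.
    """
    cfg = cfg or StitchConfig()
    n_strips = len(strips.intervals)
    if not per_strip or len(per_strip) != n_strips:
        raise ValueError("need one boundary list per strip")
    if cfg.max_drift is not None:
        max_drift = cfg.max_drift
    else:
        # A boundary may drift laterally by a sizeable fraction of the lane
        # pitch between strip midlines; cap matching just under half the
        # pitch so a boundary can never jump across a lane to the wrong
        # valley.  Pitch is estimated from the richest strip's spacings.
        richest = max(per_strip, key=len)
        spacings = np.diff(richest)
        pitch = float(np.median(spacings)) if len(spacings) else min_lane_width
        max_drift = max(min_lane_width, int(0.45 * pitch))

    # Chains are seeded from the anchor strip — the strip with the most
    # detected valleys.  With a band present in every lane somewhere (the
    # usual reference-band protocol), the densest strip sees every
    # inter-lane gap; sparser strips cannot tell an empty lane's centre
    # from a gap, so their unmatched valleys are not trusted to start new
    # chains.  Walking outward strip by strip keeps the per-step drift
    # small, and unmatched chains propagate vertically so every boundary
    # spans the full height.
    anchor = _pick_anchor(per_strip, max_drift)

    # Width veto: outside the anchor strip, only valleys with gap-like
    # width (vs. the anchor's median) may update a chain.  A lane with no
    # band in a strip reads as a wide background basin whose minimum
    # mimics a valley near mid-lane; matching it would drag the boundary
    # into the lane.
    matchable = [list(p) for p in per_strip]
    if per_strip_widths is not None:
        aw = [w for c, w in per_strip_widths[anchor].items()]
        if aw:
            cap = 2.5 * float(np.median(aw))
            for s in range(n_strips):
                if s == anchor:
                    continue
                matchable[s] = [
                    c
                    for c in per_strip[s]
                    if per_strip_widths[s].get(c, 0.0) <= cap
                ]

    cols = np.zeros((len(per_strip[anchor]), n_strips), dtype=float)
    cols[:, anchor] = per_strip[anchor]

    n_chains = cols.shape[0]
    match_count = np.zeros(n_chains, dtype=int)

    def walk(from_s: int, to_s: int, step: int) -> None:
        since = np.zeros(n_chains, dtype=int)  # strips since last real match
        for s in range(from_s + step, to_s, step):
            prev = cols[:, s - step]
            allow = np.minimum(since + 1, 3) * float(max_drift)
            pairs = match_boundaries(
                [int(round(c)) for c in prev], matchable[s], max_drift, allow_a=list(allow)
            )
            new = prev.copy()
            matched = np.zeros(n_chains, dtype=bool)
            for ia, jb in pairs:
                if ia is not None and jb is not None:
                    new[ia] = matchable[s][jb]
                    matched[ia] = True
            # Lateral drift (curvature, slant) moves the whole lane
            # register coherently, so displacements of matched boundaries
            # define a drift field.  Re-match against drift-corrected
            # predictions: this stops a chain with a little accumulated
            # error from snapping to the neighbouring gap, and carries
            # unobserved chains along with their neighbours instead of
            # leaving them behind.  Interior chains only — image edges
            # do not drift.
            interior = np.zeros(n_chains, dtype=bool)
            interior[1:-1] = True
            field = matched & interior
            if field.any():
                delta = new - prev
                med = float(np.median(delta[field]))
                good = field & (np.abs(delta - med) <= max(3.0, max_drift / 2.0))
                xp, fp = (prev[good], delta[good]) if good.any() else (prev[field], delta[field])
                pred = prev.copy()
                pred[interior] = prev[interior] + np.interp(prev[interior], xp, fp)
                pairs = match_boundaries(
                    [int(round(c)) for c in pred], matchable[s], max_drift
                )
                new = pred
                matched = np.zeros(n_chains, dtype=bool)
                for ia, jb in pairs:
                    if ia is not None and jb is not None:
                        new[ia] = matchable[s][jb]
                        matched[ia] = True
            cols[:, s] = new
            since += 1
            since[matched] = 0
            match_count[matched] += 1

    walk(anchor, n_strips, 1)
    walk(anchor, -1, -1)

    # Duplicate suppression: two chains tracking the same physical gap sit
    # far closer together than the lane pitch.  Of such a pair, keep the
    # chain corroborated by more strips (tie: the left one); the outer
    # chains are never dropped.
    while n_chains > 3:
        spacing = np.array([
            float(np.median(cols[i + 1] - cols[i])) for i in range(n_chains - 1)
        ])
        med = float(np.median(spacing))
        tight = np.flatnonzero(spacing < 0.4 * med)
        if med <= 0 or len(tight) == 0:
            break
        i = int(tight[0])
        if i == 0:
            drop = 1
        elif i + 1 == n_chains - 1:
            drop = i
        else:
            drop = i if match_count[i] < match_count[i + 1] else i + 1
        cols = np.delete(cols, drop, axis=0)
        match_count = np.delete(match_count, drop)
        n_chains -= 1

    # A strip's valley column reflects the gap where the strip's intensity
    # mass sits (its band rows), not the geometric midline; callers can
    # pass those intensity-centroid rows for more faithful interpolation.
    if breakpoint_rows is not None and len(breakpoint_rows) == n_strips:
        mids = list(breakpoint_rows)
    else:
        mids = [(a + b) / 2 for a, b in strips.intervals]
    H = strips.total_height
    # non-crossing repair: enforce strictly increasing columns per strip
    for s in range(cols.shape[1]):
        for c in range(1, cols.shape[0]):
            if cols[c, s] <= cols[c - 1, s]:
                cols[c, s] = cols[c - 1, s] + 1.0

    # Extend to rows 0 and H following the local drift slope of the two
    # outermost midlines (vertical when only one strip exists); drift
    # does not stop at the last observed strip.
    w_max = float(max(p[-1] for p in per_strip))
    if n_strips >= 2:
        top_slope = (cols[:, 1] - cols[:, 0]) / (mids[1] - mids[0])
        bot_slope = (cols[:, -1] - cols[:, -2]) / (mids[-1] - mids[-2])
        top_cols = np.clip(cols[:, 0] - top_slope * mids[0], 0.0, w_max)
        bot_cols = np.clip(cols[:, -1] + bot_slope * (H - mids[-1]), 0.0, w_max)
    else:
        top_cols = cols[:, 0].copy()
        bot_cols = cols[:, -1].copy()
    for arr in (top_cols, bot_cols):
        for c in range(1, len(arr)):
            if arr[c] <= arr[c - 1]:
                arr[c] = arr[c - 1] + 1.0

    boundaries = []
    for c in range(cols.shape[0]):
        bps = [(0.0, top_cols[c])]
        bps += [(mids[s], cols[c, s]) for s in range(n_strips)]
        bps += [(float(H), bot_cols[c])]
        # drop duplicate rows (single strip: mid may equal 0 only if H==0, not possible)
        uniq = [bps[0]]
        for r, col in bps[1:]:
            if r > uniq[-1][0]:
                uniq.append((r, col))
        boundaries.append(LaneBoundary(tuple(uniq)))
    return boundaries


def _pick_anchor(per_strip: list[list[int]], max_drift: int) -> int:
    """Choose the seed strip for stitching.

    A genuine inter-lane valley reappears (within the drift bound) in
    every other strip whose flanking lanes carry bands, while an empty
    lane's centre valley is specific to its own strip.  The anchor is the
    strip with the most corroborated interior valleys, penalising
    uncorroborated ones; ties go to the valley-richest, then topmost,
    strip.
    """
    n = len(per_strip)
    if n == 1:
        return 0
    best, best_key = 0, None
    for i in range(n):
        interior = per_strip[i][1:-1]
        corro = 0
        for v in interior:
            if any(
                any(abs(v - u) <= max_drift for u in per_strip[j][1:-1])
                for j in range(n)
                if j != i
            ):
                corro += 1
        key = (len(interior), corro, -i)
        if best_key is None or key > best_key:
            best, best_key = i, key
    return best


def segment_lanes(image: GelImage, boundaries: list[LaneBoundary], min_lane_width: int = 5) -> list[Lane]:
    """Extract one rectified lane per adjacent boundary pair.

    Each row's pixel run between the two interpolated boundary columns is
    resampled by nearest neighbour to the lane's median width; lanes
    narrower than ``min_lane_width`` are dropped (logged).
    """
    H, W = image.height, image.width
    rows = np.arange(H)
    cols = [b.columns_at(rows) for b in boundaries]
    for j in range(1, len(cols)):
        if not (cols[j] > cols[j - 1]).all():
            raise RuntimeError("lane boundaries cross: invariant violation")
    # The outermost boundaries are the static image edges while interior
    # boundaries drift with the lanes; extracting an outer lane between a
    # drifting and a fixed line makes its width vary by row, and the
    # nearest-neighbour resampling then smears band and margin pixels
    # together.  Run the edge-side boundary parallel to its interior
    # neighbour instead, at the outer lane's median width.
    # Outer lanes are additionally clipped to the interior lanes' median
    # width: the slab margin beyond the first/last lane otherwise rides
    # along and dilutes their profiles.
    boundaries = list(boundaries)
    if len(boundaries) >= 3:
        pair_w = [float(np.median(cols[j + 1] - cols[j])) for j in range(len(cols) - 1)]
        w_int = float(np.median(pair_w[1:-1])) if len(pair_w) >= 3 else min(pair_w)
        w0 = min(pair_w[0], w_int)
        boundaries[0] = LaneBoundary(
            tuple((r, max(c - w0, 0.0)) for r, c in boundaries[1].breakpoints)
        )
        cols[0] = boundaries[0].columns_at(rows)
        wn = min(pair_w[-1], w_int)
        boundaries[-1] = LaneBoundary(
            tuple((r, min(c + wn, W - 1.0)) for r, c in boundaries[-2].breakpoints)
        )
        cols[-1] = boundaries[-1].columns_at(rows)
    lanes: list[Lane] = []
    idx = 0
    for j in range(len(boundaries) - 1):
        left, right = cols[j], cols[j + 1]
        widths = right - left
        w_i = int(round(float(np.median(widths))))
        if w_i < min_lane_width:
            logger.info("dropping lane between boundaries %d-%d: width %d < %d", j, j + 1, w_i, min_lane_width)
            continue
        out = np.zeros((H, w_i), dtype=np.uint8)
        frac = (np.arange(w_i) + 0.5) / w_i
        for m in range(H):
            src = np.floor(left[m] + frac * widths[m]).astype(int)
            np.clip(src, 0, W - 1, out=src)
            out[m] = image.pixels[m, src]
        lanes.append(Lane(index=idx, left=boundaries[j], right=boundaries[j + 1], width=w_i, pixels=out))
        idx += 1
    return lanes


def segment_image(image: GelImage, cfg: RunConfig | None = None, mode: str | None = None) -> tuple[list[Lane], list[LaneBoundary], StripSet]:
    """Full lane-segmentation pipeline: strips → valleys → stitch → extract.

    ``mode="straight"`` treats the whole image as one strip, giving
    vertical boundaries — robust when lanes carry too few bands for the
    strip histograms to be informative.
    """
    cfg = cfg or RunConfig()
    mode = mode or cfg.mode
    if mode == "straight":
        strips = StripSet(((0, image.height),))
    elif mode == "curved":
        strips = compute_strips(image, cfg.strip)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    bcfg = _effective_boundary_cfg(image, cfg)
    # Absolute valley floor: a genuine inter-lane valley should be at least as
    # deep, per strip row, as prominence_frac x the image-wide per-row column
    # contrast.  Strips that carry no bands (pure background noise) then
    # contribute no interior boundaries instead of noise valleys.
    gprof = smooth_profile(column_profile(image, (0, image.height)))
    per_row_contrast = (gprof.values.max() - gprof.values.min()) / image.height
    per_strip = []
    per_widths = []
    for s in strips.intervals:
        floor = bcfg.prominence_frac * per_row_contrast * (s[1] - s[0])
        prof = smooth_profile(column_profile(image, s))
        cols = detect_boundaries(prof, bcfg, min_prominence=floor)
        per_strip.append(cols)
        per_widths.append(valley_widths(prof, cols))
    if all(len(b) <= 2 for b in per_strip):
        return [], [], strips  # no interior valleys anywhere: no lanes
    boundaries = stitch_boundaries(
        per_strip, strips, cfg.stitch, bcfg.min_lane_width, per_strip_widths=per_widths
    )
    boundaries = refine_boundaries(image, boundaries)
    lanes = segment_lanes(image, boundaries, bcfg.min_lane_width)
    lanes = _drop_empty_lanes(lanes)
    return lanes, boundaries, strips


def refine_boundaries(
    image: GelImage,
    boundaries: list[LaneBoundary],
    slab: int = 16,
    window: int = 4,
) -> list[LaneBoundary]:
    """Snap stitched boundaries to the local valley on a fine row grid.

    Stitching localises each boundary only at strip midlines; between
    them the piecewise-linear interpolation lags a quickly curving lane.
    For every ``slab``-row band, the boundary column is re-measured as
    the minimum of that band's smoothed column profile within ±``window``
    px of the interpolated position — but only where the band shows real
    contrast there (bands present), so featureless regions keep the
    interpolated course.  A final pass restores strict left-to-right
    order.
    """
    H, W = image.height, image.width
    if H < 2 * slab or len(boundaries) < 2:
        return boundaries
    grid = np.arange(slab // 2, H, slab, dtype=float)
    n_b = len(boundaries)
    cols = np.array([b.columns_at(grid) for b in boundaries])  # (n_b, n_grid)

    for gi, r in enumerate(grid):
        a, b = max(0, int(r) - slab // 2), min(H, int(r) + slab // 2)
        prof = uniform_filter1d(
            image.pixels[a:b].sum(axis=0, dtype=np.float64), size=3, mode="nearest"
        )
        sigma = 1.4826 * float(np.median(np.abs(np.diff(prof)))) / np.sqrt(2.0)
        for j in range(1, n_b - 1):  # outer boundaries stay put
            c0 = int(round(cols[j, gi]))
            lo, hi = max(0, c0 - window), min(W, c0 + window + 1)
            if hi - lo < 3:
                continue
            local = prof[lo:hi]
            c_min = lo + int(np.argmin(local))
            # require valley-like contrast: the profile must rise clearly
            # on both sides of the candidate within a pitch-scale reach
            reach = 3 * window
            left = prof[max(0, c_min - reach) : c_min + 1]
            right = prof[c_min : min(W, c_min + reach + 1)]
            if min(left.max(), right.max()) - prof[c_min] >= 6 * sigma:
                cols[j, gi] = c_min
        # keep strictly increasing
        for j in range(1, n_b):
            if cols[j, gi] <= cols[j - 1, gi]:
                cols[j, gi] = cols[j - 1, gi] + 1.0

    out = []
    for j in range(n_b):
        bps = [(0.0, _extrapolate(grid, cols[j], 0.0))]
        bps += [(float(r), float(c)) for r, c in zip(grid, cols[j])]
        bps += [(float(H), _extrapolate(grid, cols[j], float(H)))]
        out.append(LaneBoundary(tuple(bps)))
    return out


def _extrapolate(grid: np.ndarray, cols: np.ndarray, row: float) -> float:
    if len(grid) < 2:
        return float(cols[0])
    if row <= grid[0]:
        slope = (cols[1] - cols[0]) / (grid[1] - grid[0])
        return float(cols[0] + slope * (row - grid[0]))
    slope = (cols[-1] - cols[-2]) / (grid[-1] - grid[-2])
    return float(cols[-1] + slope * (row - grid[-1]))


def _drop_empty_lanes(lanes: list[Lane]) -> list[Lane]:
    """Discard lanes with background-level content (slab margins).

    A stray valley at the transition between the outermost lane and the
    slab margin can promote the empty margin to a lane.  Band-bearing
    lanes show strong contrast between their summed profile's peak and
    its median; a margin shows only noise.  Lanes below 5% of the
    strongest lane's contrast are dropped and the rest reindexed.
    """
    if len(lanes) <= 1:
        return lanes
    contrasts = []
    for lane in lanes:
        prof = lane.pixels.sum(axis=1, dtype=np.float64) / lane.width
        # detrend: background illumination gradients are not band signal
        if len(prof) >= 30:
            prof = prof - median_filter(prof, size=max(15, len(prof) // 4) | 1, mode="nearest")
        contrasts.append(float(prof.max() - np.median(prof)))
    cut = 0.05 * max(contrasts)
    kept = [lane for lane, c in zip(lanes, contrasts) if c >= cut]
    if len(kept) < len(lanes):
        logger.info("dropped %d empty margin lane(s)", len(lanes) - len(kept))
    return [
        Lane(i, lane.left, lane.right, lane.width, lane.pixels) for i, lane in enumerate(kept)
    ]


def segment_lanes_straight(image: GelImage, cfg: RunConfig | None = None) -> list[Lane]:
    """Straight-lane mode: single strip spanning the whole image."""
    return segment_image(image, cfg, mode="straight")[0]


def _effective_boundary_cfg(image: GelImage, cfg: RunConfig) -> BoundaryConfig:
    if cfg.expected_lanes:
        mlw = max(2, image.width // (4 * cfg.expected_lanes))
        return BoundaryConfig(cfg.boundary.prominence_frac, mlw)
    return cfg.boundary
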