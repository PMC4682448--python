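"""Band straightening and band calling within a rectified lane.

Bands on real gels are rarely straight: smiling/frowning (edges migrate
slower or faster than the centre) and slant leave each pixel column of a
lane vertically offset from its neighbours.  The straightener estimates
each column's offset against a reference column by maximising the
truncated-overlap cross-correlation

    R(k) = Σ_h p[h+k, ref] · p[h, n]

over a bounded shift range, then translates the column to cancel the
offset.  Band positions are then read off the summed lane profile
b(n) = Σ_m p[n, m]: candidate peaks are +→− sign changes of the first
difference G(n) = b(n+1) − b(n) (every sign change counts, so doublets
survive), and candidates at or below the 15th percentile of the profile
are rejected as background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import peak_prominences

from .lanes import IntensityProfile, Lane

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColumnShiftMap:
    """Signed row shift per lane column, relative to the reference column."""

    offsets: np.ndarray
    search_bound: int
    reference_column: int


@dataclass(frozen=True)
class BandProfile:
    """Summed intensities b(n) along the migration axis of one lane."""

    values: np.ndarray
    lane_index: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1 or (v < 0).any():
            raise ValueError("band profile must be a 1-D non-negative vector")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class Band:
    """A called band: row position within its lane, plus detection metadata.

    ``position`` is the integer profile row of the peak; ``position_sub``
    refines it to sub-pixel precision by a parabola through the peak and
    its neighbours (mobility offsets downstream benefit from the extra
    half-pixel).
    """

    lane_index: int
    position: int
    intensity: float
    prominence: float
    position_sub: float = 0.0
    offset: float | None = None  # mobility relative to the reference band; set at genotyping


def cross_correlation(a: np.ndarray, b: np.ndarray, k: int) -> float:
    """Truncated-overlap inner product Σ_h a[h+k]·b[h] over valid indices.

    For k outside (−len, len) the overlap is empty and the value is 0.
    The k<0 case uses the same index-validity rule (only terms where both
    h and h+k are in range contribute).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    H = len(a)
    if k >= 0:
        n = min(H - k, len(b))
        if n <= 0:
            return 0.0
        return float(a[k : k + n] @ b[:n])
    n = min(H + k, len(b) + k)
    if n <= 0:
        return 0.0
    return float(a[:n] @ b[-k : -k + n])


def column_cross_correlation(lane: Lane, n: int, k: int, reference_column: int = 0) -> float:
    """R(k) between lane column ``n`` and the reference column."""
    return cross_correlation(
        lane.pixels[:, reference_column].astype(np.float64),
        lane.pixels[:, n].astype(np.float64),
        k,
    )


def _argmax_shift(ref: np.ndarray, col: np.ndarray, bound: int, normalized: bool) -> int:
    """argmax_k R(k) over |k| <= bound; ties -> smallest |k|, then negative."""
    H = len(ref)
    full = np.correlate(ref, col, mode="full")  # full[j] = Σ ref[h + j - (H-1)]·col[h]
    ks = np.arange(-bound, bound + 1)
    vals = full[ks + H - 1].astype(np.float64)
    if normalized:
        norms = np.array(
            [_overlap_norm(ref, col, int(k)) for k in ks], dtype=np.float64
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(norms > 0, vals / norms, 0.0)
    if vals.max() <= 0:
        return 0  # no signal overlap anywhere
    best = vals.max()
    tied = ks[vals == best]
    tied = sorted(tied, key=lambda k: (abs(k), k))
    return int(tied[0])


def _overlap_norm(a: np.ndarray, b: np.ndarray, k: int) -> float:
    H = len(a)
    if k >= 0:
        n = H - k
        if n <= 0:
            return 0.0
        return float(np.linalg.norm(a[k:]) * np.linalg.norm(b[:n]))
    n = H + k
    if n <= 0:
        return 0.0
    return float(np.linalg.norm(a[:n]) * np.linalg.norm(b[-k:]))


def default_reference_column(pixels: np.ndarray) -> int:
    """First column carrying real band signal, not just sensor noise.

    Lanes often include empty margin columns whose variance is noise-only;
    correlating against those would assign arbitrary shifts.  The first
    column whose variance reaches a quarter of the lane's maximum column
    variance is taken as the reference (falling back to the max-variance
    column itself).
    """
    var = pixels.astype(np.float64).var(axis=0)
    vmax = var.max()
    if vmax == 0:
        return 0
    strong = np.flatnonzero(var >= 0.25 * vmax)
    return int(strong[0]) if len(strong) else int(np.argmax(var))


def straighten_lane(
    lane: Lane,
    search_bound: int | None = None,
    reference_column: int | None = None,
    normalized: bool = False,
) -> tuple[Lane, ColumnShiftMap]:
    """Cancel per-column vertical offsets so bands run horizontally.

    Each column is translated by its estimated offset k* (argmax of the
    cross-correlation against the reference column); vacated rows are
    zero-filled, never wrapped, so no intensity is fabricated.  Columns
    with no correlation signal keep shift 0.
    """
    H, W = lane.pixels.shape
    bound = search_bound if search_bound is not None else max(1, H // 8)
    bound = min(bound, H - 1)
    ref_col = reference_column if reference_column is not None else default_reference_column(lane.pixels)
    ref = lane.pixels[:, ref_col].astype(np.float64)
    offsets = np.zeros(W, dtype=int)
    out = np.zeros_like(lane.pixels)
    for n in range(W):
        col = lane.pixels[:, n].astype(np.float64)
        k = 0 if n == ref_col else _argmax_shift(ref, col, bound, normalized)
        offsets[n] = k
        if k == 0:
            out[:, n] = lane.pixels[:, n]
        elif k > 0:  # column's features sit k rows above the reference: move down
            out[k:, n] = lane.pixels[: H - k, n]
        else:
            out[:k, n] = lane.pixels[-k:, n]
    rect = Lane(lane.index, lane.left, lane.right, lane.width, out)
    return rect, ColumnShiftMap(offsets=offsets, search_bound=bound, reference_column=ref_col)


def band_profile(lane: Lane) -> BandProfile:
    """b(n) = Σ across the lane width at each migration position n."""
    return BandProfile(lane.pixels.sum(axis=1, dtype=np.float64), lane_index=lane.index)


def robust_band_profile(lane: Lane, trim_frac: float = 0.25) -> BandProfile:
    """Per-row trimmed sum across the lane width.

    Dropping the ``trim_frac`` highest and lowest column values in each
    row before summing makes the profile insensitive to a sliver of a
    neighbouring lane's band that crossed the boundary, and to stray
    bright speckles — a genuine band spans the whole lane width, so the
    trim costs it almost nothing.
    """
    px = np.sort(lane.pixels, axis=1).astype(np.float64)
    W = px.shape[1]
    k = int(np.ceil(trim_frac * W))
    if 2 * k >= W:
        k = max(0, (W - 1) // 2)
    core = px[:, k : W - k] if k else px
    return BandProfile(core.sum(axis=1), lane_index=lane.index)


def candidate_peaks(values: np.ndarray) -> list[int]:
    """Rows where the first difference G changes sign + → −.

    Zero runs of G carry the last nonzero sign forward, so a plateau
    maximum is reported once, at its leftmost row.  Every sign change
    counts — no minimum peak separation — which is what preserves
    doublets.
    """
    G = np.diff(values)
    peaks: list[int] = []
    sign = 0
    for i, g in enumerate(G):
        s = 0 if g == 0 else (1 if g > 0 else -1)
        if s == 0:
            continue
        if sign > 0 and s < 0:
            # peak is the first row of the (possibly plateau) maximum
            j = i
            while j > 0 and G[j - 1] == 0:
                j -= 1
            peaks.append(j)
        sign = s
    return peaks


def profile_baseline(values: np.ndarray) -> np.ndarray:
    """Slowly varying background of a summed lane profile.

    A wide running median follows illumination gradients and diffuse
    background staining but not the narrow band peaks.  Profiles too
    short to estimate a baseline from (length < 30) get a zero baseline.
    """
    n = len(values)
    if n < 30:
        return np.zeros(n)
    win = max(15, n // 4) | 1
    return median_filter(values, size=win, mode="nearest")


def detect_bands(profile: BandProfile, percentile: float = 85.0) -> list[Band]:
    """Call bands from a summed lane profile.

    Candidates are local maxima of b (sign changes of G); candidates
    whose baseline-subtracted height is at or below the
    ``percentile``-th percentile of the baseline-subtracted profile are
    discarded as background/artifact.  Returned sorted by position.

    The threshold convention: on a raw silver-stain scan bands are the
    *darkest* rows, so the classic rule keeps peaks whose summed
    intensity falls in the bottom 15% of values; under this package's
    bands-bright internal convention the same rule reads "keep peaks
    above the 85th percentile", hence the default.
    """
    v = profile.values
    if len(v) < 3:
        raise ValueError("profile too short for band detection (need length >= 3)")
    peaks = candidate_peaks(v)
    if not peaks:
        return []
    resid = v - profile_baseline(v)
    thresh = np.percentile(resid, percentile)
    kept = [p for p in peaks if resid[p] > thresh]
    if not kept:
        return []
    proms = peak_prominences(v, kept)[0]
    return [
        Band(
            lane_index=profile.lane_index,
            position=int(p),
            intensity=float(v[p]),
            prominence=float(pr),
            position_sub=_subpixel(v, int(p)),
        )
        for p, pr in sorted(zip(kept, proms))
    ]


def _subpixel(v: np.ndarray, p: int) -> float:
    """Parabolic refinement of a peak row (clamped to ±1 px)."""
    if p <= 0 or p >= len(v) - 1:
        return float(p)
    denom = v[p - 1] - 2.0 * v[p] + v[p + 1]
    if denom >= 0:
        return float(p)
    delta = 0.5 * (v[p - 1] - v[p + 1]) / denom
    return float(p + max(-1.0, min(1.0, delta)))
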