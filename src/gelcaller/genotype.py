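"""Inter-lane alignment, band clustering and genotype calling.

Bands of similar electrophoretic mobility across lanes usually represent
the same DNA species, but lane-to-lane migration error blurs the
correspondence.  The workflow registers every lane against a *reference
band* — a band present in all lanes with near-constant mobility, designed
into the electrophoresis protocol — in two steps: a global inter-lane
cross-correlation of summed band profiles (same truncated-overlap form as
the intra-lane straightener), then a local refinement restricted to a
window around the expected reference position.  Band mobilities are then
expressed as offsets relative to the reference band (offset 0 by
construction) and pooled across lanes.

DBSCAN clusters the pooled offsets into DNA species: ε is the observed
range of reference-band mobilities across lanes (how much residual
wobble the gel shows), and minPts is the integer closest to 10% of the
lane count.  Each cluster gets a Gaussian (mean, variance) fitted from
its member offsets, and individual bands are assigned to clusters by
maximum likelihood — which lets a model fitted on one gel classify bands
from related gels, correcting gel-to-gel systematic error.  A lane's
genotype is its presence/absence vector over the non-reference clusters;
lanes sharing a vector share a genotype group.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN

from .bands import Band, BandProfile, cross_correlation
from .config import GenotypeConfig

logger = logging.getLogger(__name__)

NOVEL = "NOVEL"

_MODEL_SCHEMA = "gelcaller-cluster-model"
_MODEL_VERSION = 1


class ModelSchemaError(ValueError):
    """Raised when a serialized cluster model has the wrong schema/version."""


@dataclass(frozen=True)
class ReferenceSpec:
    """Where to look for the reference band in every lane."""

    expected_position: int
    window: int

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("reference window must be >= 1 px")


@dataclass(frozen=True)
class LaneAlignment:
    lane_index: int
    global_shift: int
    local_shift: int
    reference_found: bool
    reference_position: float  # in the lane's own coordinates (sub-pixel); valid iff reference_found

    @property
    def total_shift(self) -> int:
        return self.global_shift + self.local_shift


@dataclass(frozen=True)
class BandCluster:
    cluster_id: int
    mean: float
    variance: float
    count: int
    is_reference: bool


@dataclass(frozen=True)
class ClusterModel:
    clusters: tuple[BandCluster, ...]
    epsilon_used: float
    minpts_used: int
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        means = [c.mean for c in self.clusters]
        if any(b <= a for a, b in zip(means, means[1:])):
            raise ValueError("cluster means must be strictly increasing")
        if sum(c.is_reference for c in self.clusters) != 1:
            raise ValueError("exactly one reference cluster required")

    @property
    def reference_cluster(self) -> BandCluster:
        return next(c for c in self.clusters if c.is_reference)


@dataclass(frozen=True)
class GenotypeCall:
    lane_index: int
    presence: tuple[int, ...]     # over non-reference cluster ids, ascending mean
    novel_bands: tuple[float, ...]
    group_id: int
    missing: bool = False         # reference band not found in this lane


def interlane_correlation(b1: BandProfile, bj: BandProfile, k: int) -> float:
    """R(k) = Σ_n b1(n+k)·bj(n), truncated overlap."""
    return cross_correlation(b1.values, bj.values, k)


def _argmax_lag(a: np.ndarray, b: np.ndarray, bound: int) -> int:
    """argmax_k Σ a[n+k]·b[n] over |k| <= bound; tie -> smallest |k|, then negative."""
    H = len(a)
    bound = min(bound, H - 1)
    full = np.correlate(a, b, mode="full")
    ks = np.arange(-bound, bound + 1)
    vals = full[ks + H - 1]
    if vals.max() <= 0:
        return 0
    best = vals.max()
    tied = sorted(ks[vals == best], key=lambda k: (abs(k), k))
    return int(tied[0])


def align_lanes(
    profiles: list[BandProfile],
    bands_per_lane: list[list[Band]],
    ref: ReferenceSpec,
    search_bound: int | None = None,
    anchor: str = "leftmost",
) -> list[LaneAlignment]:
    """Register every lane to the anchor lane, then locate its reference band.

    Positive total shift means the lane's features sit above the anchor's:
    adding the shift to a lane-local row gives the anchor-frame row.
    Lanes where no detected band falls within ``ref.window`` of the
    expected position (after shifting) are flagged not-found and excluded
    from clustering downstream.
    """
    if len(profiles) < 2:
        raise ValueError("inter-lane alignment needs at least 2 lanes")
    H = len(profiles[0].values)
    bound = search_bound if search_bound is not None else max(1, H // 8)
    if anchor == "max_intensity":
        a_idx = int(np.argmax([p.values.sum() for p in profiles]))
    else:
        a_idx = 0
    b1 = profiles[a_idx].values

    out: list[LaneAlignment] = []
    for j, (prof, bands) in enumerate(zip(profiles, bands_per_lane)):
        if j == a_idx:
            g, l = 0, 0
        else:
            g = _argmax_lag(b1, prof.values, bound)
            l = _local_refine(b1, prof.values, g, ref)
        t = g + l
        # nearest detected band to the expected reference position
        best_pos, best_d = -1.0, math.inf
        for band in bands:
            d = abs(band.position + t - ref.expected_position)
            if d < best_d:
                best_pos, best_d = band.position_sub, d
        found = best_d <= ref.window
        if not found:
            logger.warning("lane %d: reference band not found within ±%d px of %d", j, ref.window, ref.expected_position)
        out.append(LaneAlignment(j, g, l, found, best_pos if found else -1))
    if sum(a.reference_found for a in out) < 2:
        raise RuntimeError(
            "genotyping aborted: fewer than 2 lanes contain the reference band "
            f"near position {ref.expected_position} (window ±{ref.window})"
        )
    return out


def _local_refine(b1: np.ndarray, bj: np.ndarray, global_shift: int, ref: ReferenceSpec) -> int:
    """Windowed correlation around the expected reference position."""
    H = len(b1)
    lo = max(0, ref.expected_position - ref.window)
    hi = min(H, ref.expected_position + ref.window + 1)
    wa = b1[lo:hi]
    best_k, best_v = 0, -math.inf
    for k in range(-ref.window, ref.window + 1):
        src_lo = lo - global_shift - k
        val = 0.0
        for i in range(len(wa)):
            s = src_lo + i
            if 0 <= s < H:
                val += wa[i] * bj[s]
        if val > best_v or (val == best_v and (abs(k), k) < (abs(best_k), best_k)):
            best_k, best_v = k, val
    return best_k if best_v > 0 else 0


def band_offsets(
    bands_per_lane: list[list[Band]], alignments: list[LaneAlignment]
) -> list[tuple[int, float]]:
    """Band mobilities relative to each lane's own reference band.

    The reference band itself gets offset exactly 0; lanes without a
    reference band are omitted.
    """
    out: list[tuple[int, float]] = []
    for bands, al in zip(bands_per_lane, alignments):
        if not al.reference_found:
            continue
        for band in bands:
            out.append((al.lane_index, float(band.position_sub - al.reference_position)))
    return out


def epsilon_from_alignments(alignments: list[LaneAlignment], eps_floor: float = 2.0) -> float:
    """ε = range of reference-band positions after global (not local) alignment.

    Measured before local refinement — refining first would collapse the
    spread to ~0 by construction.  Floored to keep DBSCAN meaningful on a
    single clean gel.
    """
    pos = [a.reference_position + a.global_shift for a in alignments if a.reference_found]
    if not pos:
        raise ValueError("no lanes with a located reference band")
    return max(float(max(pos) - min(pos)), eps_floor)


def cluster_bands(
    offsets: list[tuple[int, float]],
    n_lanes: int,
    alignments: list[LaneAlignment] | None = None,
    eps_override: float | None = None,
    minpts_override: int | None = None,
    cfg: GenotypeConfig | None = None,
    provenance: tuple[str, ...] = (),
) -> ClusterModel:
    """DBSCAN the pooled band offsets into mobility clusters.

    ε defaults to the reference-band mobility range across lanes (from
    ``alignments``); minPts to round(0.1 × n_lanes), floored at 2.  Noise
    points are left unclustered.  Per-cluster Gaussian parameters are
    fitted from member offsets, variance floored at ``cfg.var_floor``.
    """
    cfg = cfg or GenotypeConfig()
    if not offsets:
        raise ValueError("no band offsets to cluster")
    if n_lanes < 2:
        raise ValueError("clustering needs at least 2 lanes")
    if eps_override is not None:
        eps = float(eps_override)
    elif cfg.eps_override is not None:
        eps = float(cfg.eps_override)
    elif alignments is not None:
        eps = epsilon_from_alignments(alignments, cfg.eps_floor)
    else:
        raise ValueError("provide alignments or an eps override")
    minpts = minpts_override if minpts_override is not None else (
        cfg.minpts_override if cfg.minpts_override is not None else max(2, round(0.1 * n_lanes))
    )

    xs = np.array([o for _, o in offsets], dtype=np.float64).reshape(-1, 1)
    labels = DBSCAN(eps=eps, min_samples=minpts).fit_predict(xs)
    n_noise = int((labels == -1).sum())
    if n_noise:
        logger.info("DBSCAN: %d offsets left as noise", n_noise)

    clusters: list[BandCluster] = []
    ref_label = None
    sq_dev, n_pool = 0.0, 0
    for lab in sorted(set(labels) - {-1}, key=lambda l: xs[labels == l].mean()):
        member = xs[labels == lab, 0]
        var = max(float(member.var()), cfg.var_floor)
        is_ref = bool((member == 0.0).any())
        if is_ref:
            ref_label = lab
        else:
            sq_dev += float(((member - member.mean()) ** 2).sum())
            n_pool += len(member)
        clusters.append(
            BandCluster(
                cluster_id=len(clusters),
                mean=float(member.mean()),
                variance=var,
                count=int(len(member)),
                is_reference=is_ref,
            )
        )
    if ref_label is None:
        raise RuntimeError("reference cluster not recovered: no cluster contains offset 0")
    if cfg.pooled_variance and n_pool > 0:
        # one shared variance for all DNA-species clusters: migration error
        # is a property of the gel, not of a particular fragment size, and
        # per-cluster sample variances from a dozen lanes whipsaw the
        # maximum-likelihood boundaries and the novelty gate
        pooled = max(sq_dev / n_pool, cfg.var_floor)
        clusters = [
            c if c.is_reference else BandCluster(c.cluster_id, c.mean, pooled, c.count, False)
            for c in clusters
        ]
    return ClusterModel(
        clusters=tuple(clusters),
        epsilon_used=eps,
        minpts_used=int(minpts),
        provenance=provenance,
    )


def classify_band(offset: float, model: ClusterModel, max_z: float = 4.0):
    """Maximum-likelihood Gaussian assignment of one band offset.

    Returns the winning cluster_id, or :data:`NOVEL` when the offset is
    more than ``max_z`` standard deviations from the winning mean
    (``max_z=inf`` disables the gate).  Exact likelihood ties go to the
    cluster with the smaller mean.
    """
    if not model.clusters:
        raise ValueError("empty cluster model")
    best_id, best_ll = None, -math.inf
    for c in model.clusters:  # ascending mean: strict > keeps the smaller-mean winner on ties
        ll = -0.5 * math.log(c.variance) - (offset - c.mean) ** 2 / (2.0 * c.variance)
        if ll > best_ll:
            best_id, best_ll = c.cluster_id, ll
    win = model.clusters[best_id]
    if abs(offset - win.mean) / math.sqrt(win.variance) > max_z:
        return NOVEL
    return best_id


def call_genotypes(
    offsets: list[tuple[int, float]],
    model: ClusterModel,
    missing_lanes: tuple[int, ...] = (),
    max_z: float = 4.0,
) -> list[GenotypeCall]:
    """Per-lane presence/absence calls over the non-reference clusters.

    Lanes with identical presence vectors share a group_id, assigned in
    order of first appearance (lowest lane index first).  Lanes listed in
    ``missing_lanes`` (reference band absent) are emitted with an
    all-missing call (group_id −1).
    """
    non_ref = [c.cluster_id for c in model.clusters if not c.is_reference]
    col_of = {cid: i for i, cid in enumerate(non_ref)}

    per_lane: dict[int, list[float]] = {}
    for lane, off in offsets:
        per_lane.setdefault(lane, []).append(off)

    calls: list[GenotypeCall] = []
    groups: dict[tuple[int, ...], int] = {}
    lanes = sorted(set(per_lane) | set(missing_lanes))
    for lane in lanes:
        if lane in missing_lanes:
            calls.append(GenotypeCall(lane, tuple([0] * len(non_ref)), (), -1, missing=True))
            continue
        presence = [0] * len(non_ref)
        novel: list[float] = []
        for off in per_lane.get(lane, []):
            cid = classify_band(off, model, max_z=max_z)
            if cid == NOVEL:
                novel.append(off)
            elif cid in col_of:
                presence[col_of[cid]] = 1
        key = tuple(presence)
        if key not in groups:
            groups[key] = len(groups)
        calls.append(GenotypeCall(lane, key, tuple(novel), groups[key]))
    return calls


def save_model(model: ClusterModel, path: str) -> None:
    payload = {
        "schema": _MODEL_SCHEMA,
        "version": _MODEL_VERSION,
        "epsilon_used": model.epsilon_used,
        "minpts_used": model.minpts_used,
        "provenance": list(model.provenance),
        "clusters": [asdict(c) for c in model.clusters],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_model(path: str) -> ClusterModel:
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelSchemaError(f"not a valid cluster-model file: {path!r}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("schema") != _MODEL_SCHEMA:
        raise ModelSchemaError(f"unrecognized model schema in {path!r}")
    if payload.get("version") != _MODEL_VERSION:
        raise ModelSchemaError(
            f"model version {payload.get('version')} unsupported (expected {_MODEL_VERSION})"
        )
    clusters = tuple(BandCluster(**c) for c in payload["clusters"])
    return ClusterModel(
        clusters=clusters,
        epsilon_used=float(payload["epsilon_used"]),
        minpts_used=int(payload["minpts_used"]),
        provenance=tuple(payload.get("provenance", ())),
    )
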