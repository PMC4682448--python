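"""End-to-end workflow: segment lanes → straighten & call bands → genotype.

Ties the stage modules together for one or more gel images and writes the
machine-readable artifacts (lanes.json, bands.csv, clusters.csv,
genotypes.csv, model.json, overlay PNGs).  All coordinates in outputs are
0-based pixels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bands as band_mod
from . import genotype as geno_mod
from .config import RunConfig
from .image import CropRect, GelImage, crop, load_image, normalize_polarity, save_image
from .lanes import Lane, LaneBoundary, StripSet, segment_image
from .bands import Band, BandProfile, ColumnShiftMap
from .genotype import ClusterModel, GenotypeCall, LaneAlignment, ReferenceSpec

logger = logging.getLogger(__name__)


@dataclass
class LaneResult:
    lane: Lane
    rectified: Lane
    shifts: ColumnShiftMap
    profile: BandProfile
    bands: list[Band]


@dataclass
class ImageResult:
    source: str
    image: GelImage
    lanes: list[LaneResult]
    boundaries: list[LaneBoundary]
    strips: StripSet
    alignments: list[LaneAlignment] | None = None


@dataclass
class PipelineResult:
    images: list[ImageResult]
    model: ClusterModel | None = None
    calls: list[tuple[str, GenotypeCall]] = field(default_factory=list)  # (source, call)


def analyze_image(
    image: GelImage,
    cfg: RunConfig | None = None,
    source: str = "",
) -> ImageResult:
    """Segment one normalized image and extract bands from every lane."""
    cfg = cfg or RunConfig()
    lanes, boundaries, strips = segment_image(image, cfg)
    results: list[LaneResult] = []
    for lane in lanes:
        bound = cfg.band.search_bound
        rect, shifts = band_mod.straighten_lane(lane, search_bound=bound, normalized=cfg.band.normalized)
        prof = band_mod.robust_band_profile(rect, trim_frac=cfg.band.edge_trim_frac)
        called = band_mod.detect_bands(prof, percentile=cfg.band.percentile)
        results.append(LaneResult(lane, rect, shifts, prof, called))
    return ImageResult(source=source, image=image, lanes=results, boundaries=boundaries, strips=strips)


def genotype_images(
    images: list[ImageResult],
    ref: ReferenceSpec,
    cfg: RunConfig | None = None,
    model: ClusterModel | None = None,
) -> PipelineResult:
    """Align, cluster (unless a model is supplied) and call genotypes.

    Lanes are aligned within each image; band offsets are relative to each
    lane's own reference band, so they pool consistently across related
    gels.  minPts uses the total lane count; ε is the largest per-image
    reference-mobility range.
    """
    cfg = cfg or RunConfig()
    gcfg = cfg.genotype
    # one composite integer key per (image, lane), stable across the run
    key_of: dict[tuple[str, int], int] = {}
    keyed_offsets: list[tuple[int, float]] = []
    missing_keys: list[int] = []
    eps_candidates: list[float] = []
    n_lanes_total = 0

    for res in images:
        profiles = [lr.profile for lr in res.lanes]
        bands_per_lane = [lr.bands for lr in res.lanes]
        if len(profiles) < 2:
            logger.warning("%s: fewer than 2 lanes, skipped for genotyping", res.source)
            continue
        alignments = geno_mod.align_lanes(
            profiles, bands_per_lane, ref, search_bound=gcfg.search_bound, anchor=gcfg.anchor
        )
        res.alignments = alignments
        n_lanes_total += len(profiles)
        eps_candidates.append(geno_mod.epsilon_from_alignments(alignments, gcfg.eps_floor))
        for lr, al in zip(res.lanes, alignments):
            key_of[(res.source, lr.lane.index)] = len(key_of)
            if not al.reference_found:
                missing_keys.append(key_of[(res.source, lr.lane.index)])
        for lane_idx, off in geno_mod.band_offsets(bands_per_lane, alignments):
            keyed_offsets.append((key_of[(res.source, lane_idx)], off))
    if not keyed_offsets:
        raise RuntimeError("no image yielded lanes with a reference band; cannot genotype")

    if model is None:
        model = geno_mod.cluster_bands(
            keyed_offsets,
            n_lanes=max(2, n_lanes_total),
            eps_override=gcfg.eps_override if gcfg.eps_override is not None else max(eps_candidates),
            minpts_override=gcfg.minpts_override,
            cfg=gcfg,
            provenance=tuple(sorted({src for src, _ in key_of})),
        )

    raw_calls = geno_mod.call_genotypes(
        keyed_offsets, model, missing_lanes=tuple(missing_keys), max_z=gcfg.max_z
    )
    key_to_src_lane = {k: sl for sl, k in key_of.items()}
    calls = [
        (
            key_to_src_lane[c.lane_index][0],
            GenotypeCall(key_to_src_lane[c.lane_index][1], c.presence, c.novel_bands, c.group_id, c.missing),
        )
        for c in raw_calls
    ]
    return PipelineResult(images=images, model=model, calls=calls)


def run_pipeline(
    paths: list[str],
    cfg: RunConfig | None = None,
    ref: ReferenceSpec | None = None,
    out_dir: str | None = None,
    model: ClusterModel | None = None,
    crop_rect: CropRect | None = None,
    strict: bool = False,
) -> PipelineResult:
    """Full workflow over image files, writing artifacts when ``out_dir`` given."""
    cfg = cfg or RunConfig()
    results: list[ImageResult] = []
    for p in paths:
        try:
            img = load_image(p)
            if crop_rect is not None:
                img = crop(img, crop_rect)
            img = normalize_polarity(img, cfg.polarity)
            results.append(analyze_image(img, cfg, source=str(p)))
        except Exception:
            if strict:
                raise
            logger.exception("failed to process %s; skipped", p)
    if not results:
        raise RuntimeError("no image could be processed")

    if ref is not None:
        out = genotype_images(results, ref, cfg, model=model)
    else:
        out = PipelineResult(images=results)

    if out_dir is not None:
        write_artifacts(out, Path(out_dir), cfg)
    return out


def write_artifacts(result: PipelineResult, out_dir: Path, cfg: RunConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(str(out_dir / "config.yaml"))
    band_rows = []
    for res in result.images:
        stem = Path(res.source).stem or "image"
        img_dir = out_dir / stem
        img_dir.mkdir(exist_ok=True)
        lanes_json = {
            "coordinates": "0-based pixels, row-major, origin top-left",
            "strips": list(res.strips.intervals),
            "boundaries": [
                [[float(r), float(c)] for r, c in b.breakpoints] for b in res.boundaries
            ],
            "lane_widths": [lr.lane.width for lr in res.lanes],
        }
        with open(img_dir / "lanes.json", "w") as fh:
            json.dump(lanes_json, fh, indent=2)
        for lr in res.lanes:
            save_image(
                GelImage(lr.rectified.pixels), str(img_dir / f"lane_{lr.lane.index:02d}.png")
            )
            for b in lr.bands:
                band_rows.append(
                    {
                        "image": res.source,
                        "lane_index": lr.lane.index,
                        "position_px": b.position,
                        "intensity": b.intensity,
                        "prominence": b.prominence,
                    }
                )
        save_image(render_overlay(res), str(img_dir / "overlay.png"))
    pd.DataFrame(
        band_rows, columns=["image", "lane_index", "position_px", "intensity", "prominence"]
    ).to_csv(out_dir / "bands.csv", index=False)

    if result.model is not None:
        geno_mod.save_model(result.model, str(out_dir / "model.json"))
        pd.DataFrame(
            [
                {
                    "cluster_id": c.cluster_id,
                    "mean_px": c.mean,
                    "var_px2": c.variance,
                    "count": c.count,
                    "is_reference": int(c.is_reference),
                }
                for c in result.model.clusters
            ]
        ).to_csv(out_dir / "clusters.csv", index=False)
    if result.calls:
        pd.DataFrame(
            [
                {
                    "image": src,
                    "lane_index": call.lane_index,
                    "group_id": call.group_id,
                    "presence": "".join(map(str, call.presence)),
                    "novel_bands": ";".join(f"{x:g}" for x in call.novel_bands),
                    "missing": int(call.missing),
                }
                for src, call in result.calls
            ]
        ).to_csv(out_dir / "genotypes.csv", index=False)


def render_overlay(res: ImageResult) -> GelImage:
    """Grayscale image with lane boundaries burned in bright and band rows dark.

    A lightweight diagnostic: boundary polylines at full white, detected
    band positions marked across each lane's width at full black.
    """
    H, W = res.image.height, res.image.width
    canvas = res.image.pixels.copy()
    rows = np.arange(H)
    for b in res.boundaries:
        cols = np.clip(np.rint(b.columns_at(rows)).astype(int), 0, W - 1)
        canvas[rows, cols] = 255
    for lr in res.lanes:
        left = np.clip(np.rint(lr.lane.left.columns_at(rows)).astype(int), 0, W - 1)
        right = np.clip(np.rint(lr.lane.right.columns_at(rows)).astype(int), 0, W - 1)
        for band in lr.bands:
            m = band.position
            canvas[m, left[m] : right[m]] = 0
    return GelImage(canvas)
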