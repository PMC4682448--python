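"""Synthetic gel images with exact ground truth.

Emulates the artifact classes seen on real PAGE/agarose scans — laterally
curving or slanted lanes, smiling/frowning bands, doublets, uneven
background illumination, speckle contamination and sensor noise — so that
every pipeline stage can be tested against known lane centerlines, band
positions and genotype groupings.  This is a geometric image model, not
an electrophoresis physics simulation: band mobilities are specified
directly in pixels, and band cross-sections are Gaussian.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .image import BANDS_BRIGHT, BANDS_DARK, GelImage, save_image


@dataclass(frozen=True)
class Curvature:
    """Lateral lane drift: none, sinusoid(amplitude, wavelength, phase), or slant."""

    kind: str = "none"            # none | sinusoid | slant
    amplitude: float = 0.0        # px, sinusoid peak deviation
    wavelength: float = 200.0     # px (rows per period)
    phase: float = 0.0            # radians
    slope: float = 0.0            # px per row, slant mode

    def offset(self, rows: np.ndarray) -> np.ndarray:
        if self.kind == "none":
            return np.zeros_like(rows, dtype=float)
        if self.kind == "sinusoid":
            return self.amplitude * np.sin(2 * np.pi * rows / self.wavelength + self.phase)
        if self.kind == "slant":
            return self.slope * (rows - rows.mean())
        raise ValueError(f"unknown curvature kind {self.kind!r}")


@dataclass(frozen=True)
class GelSpec:
    """Full description of one synthetic gel.

    ``band_species`` are mobilities in px below the reference band; the
    reference band itself (present in every lane) sits at
    ``reference_mobility`` px from the top.  ``genotype_patterns`` are
    presence vectors over ``band_species``; ``lane_pattern_assignment``
    maps each lane to a pattern index.
    """

    n_lanes: int = 10
    lane_width: int = 20
    lane_gap: int = 8
    height: int = 220
    width: int | None = None      # None -> computed from lanes + margins
    margin: int = 10
    curvature: Curvature = field(default_factory=Curvature)
    smile: float = 0.0            # parabolic row offset at band edges, px
    band_species: tuple[float, ...] = (40.0, 80.0, 120.0)
    reference_mobility: float = 50.0
    genotype_patterns: tuple[tuple[int, ...], ...] = ((1, 1, 0), (1, 0, 1), (0, 1, 1))
    lane_pattern_assignment: tuple[int, ...] | None = None  # None -> round robin
    doublet_gap: float | None = None  # render species 0 as a doublet with this gap
    band_sigma: float = 2.0       # Gaussian band half-thickness, px
    peak_intensity: float = 180.0
    background: tuple[float, float] = (20.0, 0.02)  # base level, per-row gradient
    noise_sd: float = 3.0
    speckle_count: int = 0
    lane_offset_sd: float = 0.0   # whole-lane vertical jitter (gel-to-gel/lane-to-lane drift)
    band_jitter_sd: float = 0.0   # per-band mobility error, the spread DBSCAN clusters over
    polarity: str = BANDS_DARK
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lanes < 1 or self.lane_width < 2 or self.height < 10:
            raise ValueError("invalid geometry: n_lanes >= 1, lane_width >= 2, height >= 10")
        if self.curvature.kind == "sinusoid" and self.curvature.amplitude >= self.lane_gap + self.lane_width:
            raise ValueError("curvature amplitude must be < lane_gap + lane_width")
        if not (0 <= self.reference_mobility < self.height):
            raise ValueError("reference_mobility outside image height")
        for mob in self.band_species:
            if not (0 <= self.reference_mobility + mob < self.height):
                raise ValueError(f"band_species mobility {mob} falls outside image height")
        for p in self.genotype_patterns:
            if len(p) != len(self.band_species):
                raise ValueError("every genotype pattern must cover all band_species")
        if self.lane_pattern_assignment is not None and len(self.lane_pattern_assignment) != self.n_lanes:
            raise ValueError("lane_pattern_assignment length must equal n_lanes")

    @property
    def pitch(self) -> int:
        return self.lane_width + self.lane_gap

    @property
    def effective_width(self) -> int:
        if self.width is not None:
            return self.width
        return 2 * self.margin + self.n_lanes * self.pitch - self.lane_gap

    def assignment(self) -> tuple[int, ...]:
        if self.lane_pattern_assignment is not None:
            return self.lane_pattern_assignment
        k = len(self.genotype_patterns)
        return tuple(i % k for i in range(self.n_lanes))


@dataclass(frozen=True)
class GroundTruth:
    """Exact generator state: what a perfect pipeline should recover."""

    lane_centerlines: tuple[np.ndarray, ...]      # per lane, column at every row
    band_table: tuple[tuple[int, int, float, bool], ...]  # (lane, species_id, row, is_reference)
    genotype_groups: tuple[int, ...]              # lane -> group id
    lane_offsets: tuple[float, ...]               # whole-lane vertical jitter applied
    spec: GelSpec

    def bands_in_lane(self, lane: int) -> list[tuple[int, float, bool]]:
        return [(sp, row, ref) for ln, sp, row, ref in self.band_table if ln == lane]


def generate_gel(spec: GelSpec) -> tuple[GelImage, GroundTruth]:
    """Render a gel and its ground truth, deterministically from the seed."""
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.effective_width
    rows = np.arange(H, dtype=float)
    base, grad = spec.background
    canvas = np.tile((base + grad * rows)[:, None], (1, W))

    assignment = spec.assignment()
    half = spec.lane_width / 2.0
    centerlines: list[np.ndarray] = []
    band_table: list[tuple[int, int, float, bool]] = []

    for lane in range(spec.n_lanes):
        cx0 = spec.margin + lane * spec.pitch + half
        center = cx0 + spec.curvature.offset(rows)
        centerlines.append(center)

    lane_offsets = tuple(
        float(rng.normal(0.0, spec.lane_offset_sd)) if spec.lane_offset_sd > 0 else 0.0
        for _ in range(spec.n_lanes)
    )

    col_idx = np.arange(W, dtype=float)
    for lane in range(spec.n_lanes):
        center = centerlines[lane]
        pattern = spec.genotype_patterns[assignment[lane]]
        # species_id -1 marks the reference band
        todo: list[tuple[int, float]] = [(-1, spec.reference_mobility)]
        for sp, present in enumerate(pattern):
            if not present:
                continue
            mob = spec.reference_mobility + spec.band_species[sp]
            if sp == 0 and spec.doublet_gap is not None:
                todo.append((sp, mob - spec.doublet_gap / 2.0))
                todo.append((sp, mob + spec.doublet_gap / 2.0))
            else:
                todo.append((sp, mob))
        for sp, row0 in todo:
            jitter = rng.normal(0.0, spec.band_jitter_sd) if spec.band_jitter_sd > 0 else 0.0
            row_c = row0 + lane_offsets[lane] + jitter
            band_table.append((lane, sp, float(row_c), sp == -1))
            _render_band(canvas, center, row_c, half, spec)

    for _ in range(spec.speckle_count):
        r = rng.integers(0, H)
        c = rng.integers(0, W)
        rad = int(rng.integers(1, 3))
        rr, cc = np.ogrid[-rad : rad + 1, -rad : rad + 1]
        disk = rr**2 + cc**2 <= rad**2
        r0, r1 = max(0, r - rad), min(H, r + rad + 1)
        c0, c1 = max(0, c - rad), min(W, c + rad + 1)
        sub = disk[rad - (r - r0) : rad + (r1 - r), rad - (c - c0) : rad + (c1 - c)]
        canvas[r0:r1, c0:c1][sub] = spec.peak_intensity

    if spec.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sd, size=canvas.shape)
    canvas = np.clip(canvas, 0, 255)

    if spec.polarity == BANDS_DARK:
        canvas = 255.0 - canvas
    img = GelImage(np.rint(canvas).astype(np.uint8), polarity=spec.polarity)

    # genotype groups: distinct patterns in order of first appearing lane
    seen: dict[int, int] = {}
    groups = []
    for lane in range(spec.n_lanes):
        p = assignment[lane]
        if p not in seen:
            seen[p] = len(seen)
        groups.append(seen[p])

    truth = GroundTruth(
        lane_centerlines=tuple(centerlines),
        band_table=tuple(band_table),
        genotype_groups=tuple(groups),
        lane_offsets=lane_offsets,
        spec=spec,
    )
    return img, truth


def _render_band(canvas: np.ndarray, center: np.ndarray, row_c: float, half: float, spec: GelSpec) -> None:
    """Additively render one Gaussian-profile band following the lane centerline.

    The smile term bows the band: columns at the lane edges are displaced
    downward by up to ``spec.smile`` px relative to the centre (parabolic).
    """
    H, W = canvas.shape
    sig = spec.band_sigma
    r_lo = max(0, int(row_c - 4 * sig) - 1)
    r_hi = min(H, int(row_c + spec.smile + 4 * sig) + 2)
    for m in range(r_lo, r_hi):
        c = center[m]
        c_lo = max(0, int(np.floor(c - half)))
        c_hi = min(W, int(np.ceil(c + half)))
        if c_hi <= c_lo:
            continue
        cols = np.arange(c_lo, c_hi, dtype=float)
        dx = (cols - c) / half
        local_row = row_c + spec.smile * dx**2
        canvas[m, c_lo:c_hi] += spec.peak_intensity * np.exp(-((m - local_row) ** 2) / (2 * sig**2))


PRESETS: dict[str, GelSpec] = {
    "straight_clean": GelSpec(n_lanes=8, curvature=Curvature(), noise_sd=0.0, seed=11),
    "curved": GelSpec(n_lanes=10, curvature=Curvature("sinusoid", amplitude=10.0, wavelength=250.0), seed=12),
    "smiling": GelSpec(n_lanes=8, smile=5.0, seed=13),
    "doublet": GelSpec(n_lanes=8, doublet_gap=8.0, seed=14),
    "sparse": GelSpec(
        n_lanes=8,
        band_species=(60.0,),
        genotype_patterns=((0,),),
        curvature=Curvature("sinusoid", amplitude=8.0, wavelength=250.0),
        seed=15,
    ),
    "noisy": GelSpec(n_lanes=10, noise_sd=8.0, speckle_count=25, seed=16),
}


def generate_suite(out_dir: str, presets: dict[str, GelSpec] | None = None) -> dict:
    """Write every preset gel as PNG + ground-truth JSON; return the manifest."""
    presets = presets or PRESETS
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"gels": []}
    for name, spec in presets.items():
        img, truth = generate_gel(spec)
        png = out / f"{name}.png"
        save_image(img, str(png))
        truth_path = out / f"{name}.truth.json"
        with open(truth_path, "w") as fh:
            json.dump(truth_to_dict(truth), fh, indent=2)
        manifest["gels"].append({"name": name, "image": png.name, "truth": truth_path.name, "seed": spec.seed})
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def truth_to_dict(truth: GroundTruth) -> dict:
    spec_d = asdict(truth.spec)
    return {
        "spec": spec_d,
        "lane_centerlines": [c.tolist() for c in truth.lane_centerlines],
        "band_table": [list(row) for row in truth.band_table],
        "genotype_groups": list(truth.genotype_groups),
        "lane_offsets": list(truth.lane_offsets),
    }
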