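"""Tunable parameters for every pipeline stage, with YAML round-trip.

Defaults follow the published workflow where it states a value (3-point
smoothing, 15th-percentile band threshold, DBSCAN minPts = 10% of lanes)
and documented package choices elsewhere (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class StripConfig:
    """Dynamic horizontal strip placement from the row-intensity profile."""

    percentile: float = 75.0   # rows above this percentile of smoothed r(m) are high-contrast
    merge_gap: int = 5         # high-contrast rows closer than this merge into one region
    min_height: int = 10       # strips shorter than this merge with a neighbour (px)
    fallback_n: int = 4        # equal strips when banding is too sparse


@dataclass
class BoundaryConfig:
    """Lane-boundary (profile valley) detection within a strip."""

    prominence_frac: float = 0.05  # valley prominence as a fraction of profile range
    min_lane_width: int = 5        # minimum spacing between boundaries / lane width (px)
    noise_sigmas: float = 6.0      # prominence floor in units of estimated profile noise
    max_rel_depth: float = 0.5     # valley value must sit in the lower half of the range


@dataclass
class StitchConfig:
    """Cross-strip boundary matching."""

    max_drift: int | None = None  # max |Δcolumn| for a match; None -> min_lane_width


@dataclass
class BandConfig:
    """Band straightening and peak calling within a lane."""

    percentile: float = 85.0       # background threshold on the summed lane profile
                                   # (bands-bright convention: == bottom 15% of a dark-band scan)
    search_bound: int | None = None  # max |k| for column cross-correlation; None -> H//8
    normalized: bool = False       # normalized cross-correlation instead of raw inner product
    edge_trim_frac: float = 0.25   # fraction of extreme column values trimmed per row of the
                                   # summed profile (robust to boundary bleed and speckles;
                                   # a genuine band spans the full lane width, so the central
                                   # half of the columns carries the same signal)


@dataclass
class GenotypeConfig:
    """Lane alignment, band clustering and genotype calling."""

    search_bound: int | None = None  # inter-lane alignment bound; None -> H//8
    eps_override: float | None = None
    minpts_override: int | None = None
    eps_floor: float = 2.0         # px; guards the degenerate single-gel case
    var_floor: float = 0.25        # px^2; cluster variance floor
    max_z: float = 4.0             # NOVEL gate; inf restores unbounded ML assignment.
                                   # Calibrated so ~50 classified bands per experiment give a
                                   # family-wise false-novelty rate well under 1%; genuine gel
                                   # artifacts sit far beyond it
    pooled_variance: bool = True   # tie the non-reference cluster variances (the mobility
                                   # error mechanism is shared; per-cluster estimates from a
                                   # handful of lanes are too unstable for the z-gate)
    anchor: str = "leftmost"       # or "max_intensity"


@dataclass
class RunConfig:
    """Aggregate configuration for the end-to-end pipeline."""

    strip: StripConfig = field(default_factory=StripConfig)
    boundary: BoundaryConfig = field(default_factory=BoundaryConfig)
    stitch: StitchConfig = field(default_factory=StitchConfig)
    band: BandConfig = field(default_factory=BandConfig)
    genotype: GenotypeConfig = field(default_factory=GenotypeConfig)
    polarity: str = "auto"
    mode: str = "curved"           # or "straight"
    expected_lanes: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        sections = {f.name: f for f in fields(cls)}
        kwargs: dict = {}
        for key, value in data.items():
            if key not in sections:
                raise ValueError(f"unknown config key {key!r}")
            f = sections[key]
            if f.name in ("strip", "boundary", "stitch", "band", "genotype"):
                sub_cls = f.default_factory().__class__  # type: ignore[misc]
                known = {sf.name for sf in fields(sub_cls)}
                bad = set(value) - known
                if bad:
                    raise ValueError(f"unknown config key {key}.{sorted(bad)[0]!r}")
                kwargs[key] = sub_cls(**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
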