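"""Bookkeeping for the ten-image sugarcane ILP PAGE evaluation set.

The curved-lane segmentation method was originally evaluated on ten
silver-stained PAGE scans of sugarcane intron-length-polymorphism
amplicons (433 sample lanes in total).  The images themselves are large
external downloads and are not distributed here; this module carries the
per-image metadata — pixel dimensions, true lane count, and the number of
lanes the automated curved-mode segmentation recovered — and the accuracy
arithmetic over it, so the evaluation bookkeeping is reproducible without
the rasters.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class EvalImage:
    image_id: str
    width: int
    height: int
    n_lanes: int
    n_detected: int


# (image_id, width px, height px, true lanes, lanes recovered in curved mode)
EVALUATION_SET: tuple[EvalImage, ...] = (
    EvalImage("1a", 1884, 524, 72, 39),
    EvalImage("2a", 1955, 524, 60, 37),
    EvalImage("3a", 1871, 524, 72, 19),
    EvalImage("4a", 1911, 546, 60, 45),
    EvalImage("5a", 1810, 718, 56, 46),
    EvalImage("6b", 1810, 718, 34, 34),
    EvalImage("7b", 473, 288, 32, 31),
    EvalImage("8b", 234, 500, 15, 14),
    EvalImage("9b", 276, 574, 15, 15),
    EvalImage("10b", 276, 399, 17, 17),
)


def accuracy_pct(detected: int, total: int) -> float:
    """Lane-detection accuracy: detected / total × 100."""
    if total < 1 or detected < 0 or detected > total:
        raise ValueError(f"invalid counts detected={detected}, total={total}")
    return 100.0 * detected / total


def evaluation_table() -> pd.DataFrame:
    """The evaluation set with accuracy recomputed per image."""
    rows = [
        {
            "image_id": e.image_id,
            "width": e.width,
            "height": e.height,
            "n_lanes": e.n_lanes,
            "n_detected": e.n_detected,
            "accuracy_pct": accuracy_pct(e.n_detected, e.n_lanes),
        }
        for e in EVALUATION_SET
    ]
    return pd.DataFrame(rows)


def total_lanes() -> int:
    """Total sample lanes across the evaluation set."""
    return sum(e.n_lanes for e in EVALUATION_SET)
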