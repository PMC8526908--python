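"""Podocyte foot-process width (FPW) from electron-microscopy tables.

FPW is the standard morphometric index of foot-process effacement:

    FPW = (pi / 4) * (sum of GBM length / sum of foot-process count)

where the sums pool all images in a group before dividing (never a mean of
per-image ratios), and GBM is the glomerular basement membrane contour
along which foot processes are counted.  The pi/4 factor corrects for
random section orientation.  Length units pass through unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = ["EMMeasurement", "foot_process_width", "read_em_table"]


@dataclass
class EMMeasurement:
    """One EM image's pooled measurements."""

    image: str
    glomerulus: str
    animal: str
    gbm_length: float
    foot_process_count: int

    def __post_init__(self) -> None:
        if not self.gbm_length > 0:
            raise ValueError(f"gbm_length must be > 0 (image {self.image})")
        if self.foot_process_count < 1:
            raise ValueError(f"foot_process_count must be >= 1 (image {self.image})")


def _group_key(m: EMMeasurement, level: str) -> str:
    if level == "animal":
        return m.animal
    if level == "glomerulus":
        return f"{m.animal}/{m.glomerulus}"
    if level == "all":
        return "all"
    raise ValueError(f"unknown grouping level {level!r}")


def foot_process_width(
    measurements: Sequence[EMMeasurement],
    group_by: str = "animal",
) -> dict[str, float]:
    """Mean FPW per group using pooled sums.

    ``group_by`` is ``animal``, ``glomerulus`` (nested within animal) or
    ``all``.  FPW scales linearly with the length unit of the input.
    """
    if not measurements:
        raise ValueError("no measurements")
    sums: dict[str, list[float]] = {}
    for m in measurements:
        key = _group_key(m, group_by)
        acc = sums.setdefault(key, [0.0, 0.0])
        acc[0] += m.gbm_length
        acc[1] += m.foot_process_count
    out = {}
    for key, (length, count) in sorted(sums.items()):
        if count <= 0:
            raise ValueError(f"zero summed foot-process count in group {key}")
        out[key] = (math.pi / 4.0) * (length / count)
    return out


def read_em_table(path: str | Path) -> list[EMMeasurement]:
    """TSV with columns animal, glomerulus, image, gbm_length, fp_count."""
    df = pd.read_csv(path, sep="\t")
    need = {"animal", "glomerulus", "image", "gbm_length", "fp_count"}
    missing = need - {c.lower() for c in df.columns}
    if missing:
        raise ValueError(f"missing columns: {', '.join(sorted(missing))}")
    df.columns = [c.lower() for c in df.columns]
    return [
        EMMeasurement(
            image=str(r.image),
            glomerulus=str(r.glomerulus),
            animal=str(r.animal),
            gbm_length=float(r.gbm_length),
            foot_process_count=int(r.fp_count),
        )
        for r in df.itertuples()
    ]
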