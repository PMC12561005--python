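"""ROI placement and per-ROI cell quantification.

Quadrats of 100 × 100 μm² are placed in two strata: SURFACE ROIs anchored
to the bone interface (each must intersect a 20 μm buffer of the
interface polyline — where osteoclasts and CAFs co-occur) and DEEP ROIs
over tumor nests away from the interface (OSCC cells and CAFs). ROI
membership is half-open (``x0 ≤ x < x0+side``, same in y) so a cell on a
shared edge of abutting ROIs is counted exactly once, in the ROI whose
lower corner starts at that edge.

The headline statistic is the *pooled* CAF-per-reference ratio: total
CAFs divided by total reference cells over the pooled ROIs of a stratum
(e.g. 890 CAFs / 78 OSCC cells = 11.4 CAFs per OSCC cell).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box

from .cells import CellTable, CellType
from .errors import ConfigError, IntegrityError, PlacementError, UndefinedRatioError
from .geometry import TissueGeometry

__all__ = [
    "Stratum",
    "ROI",
    "ROISet",
    "ROICounts",
    "place_rois",
    "count_cells",
    "pooled_caf_ratio",
]

INTERFACE_BUFFER_UM = 20.0


class Stratum(str, enum.Enum):
    SURFACE = "SURFACE"
    DEEP = "DEEP"


@dataclass(frozen=True)
class ROI:
    """Axis-aligned square quadrat; (x0, y0) is the lower (min) corner."""

    x0: float
    y0: float
    side: float
    stratum: Stratum

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Half-open membership test, vectorized."""
        return (
            (x >= self.x0)
            & (x < self.x0 + self.side)
            & (y >= self.y0)
            & (y < self.y0 + self.side)
        )

    def to_box(self):
        return box(self.x0, self.y0, self.x0 + self.side, self.y0 + self.side)


@dataclass
class ROISet:
    rois: list[ROI]

    def __len__(self) -> int:
        return len(self.rois)

    def by_stratum(self, stratum: Stratum) -> list[ROI]:
        return [r for r in self.rois if r.stratum == stratum]

    def counts_by_stratum(self) -> dict[str, int]:
        return {s.value: len(self.by_stratum(s)) for s in Stratum}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"x0": r.x0, "y0": r.y0, "side": r.side, "stratum": r.stratum.value}
                for r in self.rois
            ],
            columns=["x0", "y0", "side", "stratum"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ROISet":
        return cls(
            [
                ROI(float(r.x0), float(r.y0), float(r.side), Stratum(r.stratum))
                for r in df.itertuples(index=False)
            ]
        )


@dataclass
class ROICounts:
    """Per-ROI cell counts plus pooled per-stratum totals."""

    per_roi: pd.DataFrame  # columns: stratum, OSCC, CAF, OSTEOCLAST, OTHER

    def pooled(self, stratum: Optional[Stratum] = None) -> dict[str, int]:
        df = self.per_roi
        if stratum is not None:
            df = df[df["stratum"] == stratum.value]
        return {t.value: int(df[t.value].sum()) for t in CellType}


def _overlaps(a: ROI, x0: float, y0: float, side: float) -> bool:
    """Open-interval (interior) rectangle overlap."""
    return (
        x0 < a.x0 + a.side
        and a.x0 < x0 + side
        and y0 < a.y0 + a.side
        and a.y0 < y0 + side
    )


def place_rois(
    geom: TissueGeometry,
    n_surface: int = 15,
    n_deep: int = 15,
    side: float = 100.0,
    seed: int = 0,
) -> ROISet:
    """Place non-overlapping quadrats in the two strata, seeded-random.

    SURFACE ROIs occupy randomly chosen distinct x-slots of width ``side``
    (guaranteeing non-overlap) with the y offset drawn uniformly over the
    window in which the quadrat intersects the 20 μm interface buffer.
    DEEP ROIs are rejection-sampled: each must intersect a tumor nest, miss
    the interface buffer, and not overlap a previously placed DEEP ROI.
    """
    if side <= 0:
        raise ConfigError("ROI side must be > 0")
    if n_surface < 0 or n_deep < 0:
        raise ConfigError("ROI counts must be >= 0")
    rng = np.random.default_rng(seed)
    W, H = geom.frame_width, geom.frame_height
    buffer = geom.interface.buffer(INTERFACE_BUFFER_UM)
    shapely.prepare(buffer)
    rois: list[ROI] = []

    n_slots = int(W // side)
    if n_surface > n_slots:
        raise PlacementError(
            f"frame admits at most {n_slots} non-overlapping surface ROIs "
            f"of side {side}, requested {n_surface}",
        )
    if n_surface:
        slots = rng.choice(n_slots, size=n_surface, replace=False)
        iface = np.asarray(geom.interface.coords)
        for slot in sorted(slots.tolist()):
            x0 = slot * side
            in_slot = (iface[:, 0] >= x0 - 1e-9) & (iface[:, 0] <= x0 + side + 1e-9)
            seg_y = iface[in_slot, 1] if in_slot.any() else iface[:, 1]
            lo = max(0.0, seg_y.min() - INTERFACE_BUFFER_UM - side)
            hi = min(H - side, seg_y.max() + INTERFACE_BUFFER_UM)
            placed = False
            for _ in range(200):
                y0 = rng.uniform(lo, hi)
                if shapely.intersects(buffer, box(x0, y0, x0 + side, y0 + side)):
                    rois.append(ROI(x0, y0, side, Stratum.SURFACE))
                    placed = True
                    break
            if not placed:
                raise PlacementError(
                    "could not anchor a surface ROI to the interface buffer",
                    achieved_surface=len(rois),
                )

    deep: list[ROI] = []
    if n_deep:
        if not geom.tumor_nests:
            raise PlacementError("no tumor nests for deep ROIs", len(rois), 0)
        nb = np.array([n.bounds for n in geom.tumor_nests])
        minx = max(0.0, nb[:, 0].min() - side)
        miny = max(0.0, nb[:, 1].min() - side)
        maxx = min(W - side, nb[:, 2].max())
        maxy = min(H - side, nb[:, 3].max())
        nests = shapely.union_all(geom.tumor_nests)
        shapely.prepare(nests)
        attempts = 0
        max_attempts = 20000
        while len(deep) < n_deep:
            attempts += 1
            if attempts > max_attempts:
                raise PlacementError(
                    "deep ROI placement exhausted retries",
                    achieved_surface=len(rois),
                    achieved_deep=len(deep),
                )
            x0 = rng.uniform(minx, maxx)
            y0 = rng.uniform(miny, maxy)
            rect = box(x0, y0, x0 + side, y0 + side)
            if not shapely.intersects(nests, rect):
                continue
            if shapely.intersects(buffer, rect):
                continue
            if any(_overlaps(r, x0, y0, side) for r in deep):
                continue
            deep.append(ROI(x0, y0, side, Stratum.DEEP))
    return ROISet(rois + deep)


def count_cells(rois: ROISet, table: CellTable) -> ROICounts:
    """Count cells of each type inside every ROI (half-open membership)."""
    if table.units != "um":
        raise IntegrityError("cell table units must be μm")
    xy = table.xy()
    types = table.df["cell_type"].to_numpy()
    rows = []
    for roi in rois.rois:
        inside = (
            roi.contains(xy[:, 0], xy[:, 1]) if len(xy) else np.zeros(0, dtype=bool)
        )
        row = {"stratum": roi.stratum.value}
        for t in CellType:
            row[t.value] = int(np.sum(inside & (types == t.value))) if len(xy) else 0
        rows.append(row)
    cols = ["stratum"] + [t.value for t in CellType]
    per_roi = pd.DataFrame(rows, columns=cols)
    return ROICounts(per_roi=per_roi)


def pooled_caf_ratio(
    counts: ROICounts,
    reference_type: CellType,
    stratum: Optional[Stratum] = None,
) -> float:
    """Pooled CAFs per reference cell over the (optionally filtered) ROIs.

    Returns full precision; reporting layers round to one decimal. A zero
    pooled reference count raises :class:`UndefinedRatioError` rather than
    returning infinity.
    """
    if reference_type == CellType.CAF:
        raise ConfigError("reference_type must differ from CAF")
    pooled = counts.pooled(stratum)
    n_ref = pooled[reference_type.value]
    if n_ref == 0:
        raise UndefinedRatioError(
            f"no {reference_type.value} cells pooled; ratio undefined"
        )
    return pooled[CellType.CAF.value] / n_ref
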