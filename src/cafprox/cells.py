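"""Typed cell records and the cell table container.

A :class:`CellTable` is the in-memory form of a digital-pathology cell
export: one row per detected cell with a position in micrometres (image
convention: origin top-left, y increasing downward) and a cell type
assigned by immunohistochemical marker. Cell types form a closed enum;
OTHER admits untyped stromal cells (e.g. lymphocytes) without giving them
a marker.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError

if TYPE_CHECKING:  # pragma: no cover
    from .geometry import TissueGeometry


class CellType(str, enum.Enum):
    OSCC = "OSCC"
    CAF = "CAF"
    OSTEOCLAST = "OSTEOCLAST"
    OTHER = "OTHER"


class Marker(str, enum.Enum):
    RANKL = "RANKL"
    FAP = "FAP"
    ASMA = "ASMA"
    CATHEPSIN_K = "CATHEPSIN_K"
    NONE = "NONE"


#: Markers admissible for each cell type; NONE is always admissible
#: (simulated or unstained cells), except that OTHER cells may only be NONE.
MARKERS_FOR_TYPE: dict[CellType, frozenset[Marker]] = {
    CellType.OSCC: frozenset({Marker.RANKL, Marker.NONE}),
    CellType.CAF: frozenset({Marker.FAP, Marker.ASMA, Marker.NONE}),
    CellType.OSTEOCLAST: frozenset({Marker.CATHEPSIN_K, Marker.NONE}),
    CellType.OTHER: frozenset({Marker.NONE}),
}

#: Canonical marker used when the simulator assigns one.
DEFAULT_MARKER: dict[CellType, Marker] = {
    CellType.OSCC: Marker.RANKL,
    CellType.CAF: Marker.FAP,
    CellType.OSTEOCLAST: Marker.CATHEPSIN_K,
    CellType.OTHER: Marker.NONE,
}

#: Canonical column order of the tabular form.
CELL_COLUMNS = ["cell_id", "x_um", "y_um", "cell_type", "marker", "parent_id"]


@dataclass(frozen=True)
class CellRecord:
    """One positioned, typed cell. Coordinates in μm, image convention."""

    cell_id: str
    x: float
    y: float
    cell_type: CellType
    marker: Marker = Marker.NONE
    parent_id: Optional[str] = None


@dataclass
class CellTable:
    """Ordered collection of cell records backed by a pandas DataFrame.

    Parameters
    ----------
    df : DataFrame with columns ``cell_id, x_um, y_um, cell_type, marker,
        parent_id`` (the last two optional on input; filled with defaults).
    frame : optional :class:`~cafprox.geometry.TissueGeometry` the
        coordinates refer to; when given, coordinates must lie inside it.
    units : always ``"um"``; kept explicit so unit mismatches are loud.
    """

    df: pd.DataFrame
    frame: Optional["TissueGeometry"] = None
    units: str = "um"

    def __post_init__(self):
        df = self.df.copy()
        if "marker" not in df.columns:
            df["marker"] = Marker.NONE.value
        if "parent_id" not in df.columns:
            df["parent_id"] = pd.NA
        missing = [c for c in CELL_COLUMNS if c not in df.columns]
        if missing:
            raise IntegrityError(f"cell table missing columns: {missing}")
        df = df[CELL_COLUMNS].reset_index(drop=True)
        df["cell_id"] = df["cell_id"].astype(str).astype(object)
        df["x_um"] = df["x_um"].astype(float)
        df["y_um"] = df["y_um"].astype(float)
        df["cell_type"] = df["cell_type"].astype(str).astype(object)
        df["marker"] = df["marker"].astype(str).astype(object)
        # normalize missing parents to pd.NA in a plain object column
        df["parent_id"] = (
            df["parent_id"]
            .astype(object)
            .where(df["parent_id"].notna(), pd.NA)
        )
        self.df = df
        self._validate()

    # -- validation ---------------------------------------------------
    def _validate(self) -> None:
        df = self.df
        if self.units != "um":
            raise IntegrityError(f"units must be 'um', got {self.units!r}")
        if df["cell_id"].duplicated().any():
            dupes = df.loc[df["cell_id"].duplicated(), "cell_id"].unique()[:5]
            raise IntegrityError(f"duplicate cell_id values: {list(dupes)}")
        coords = df[["x_um", "y_um"]].to_numpy()
        if coords.size and not np.isfinite(coords).all():
            raise IntegrityError("non-finite cell coordinates")
        allowed_types = {t.value for t in CellType}
        bad = set(df["cell_type"].unique()) - allowed_types
        if bad:
            raise IntegrityError(
                f"unknown cell_type values {sorted(bad)}; "
                f"allowed: {sorted(allowed_types)}"
            )
        allowed_markers = {m.value for m in Marker}
        badm = set(df["marker"].unique()) - allowed_markers
        if badm:
            raise IntegrityError(
                f"unknown marker values {sorted(badm)}; "
                f"allowed: {sorted(allowed_markers)}"
            )
        for ct, markers in MARKERS_FOR_TYPE.items():
            sub = df.loc[df["cell_type"] == ct.value, "marker"]
            ok = {m.value for m in markers}
            wrong = set(sub.unique()) - ok
            if wrong:
                raise IntegrityError(
                    f"marker(s) {sorted(wrong)} inconsistent with cell_type "
                    f"{ct.value}; allowed: {sorted(ok)}"
                )
        if self.frame is not None and len(df):
            w, h = self.frame.frame_width, self.frame.frame_height
            x, y = coords[:, 0], coords[:, 1]
            tol = 1e-6
            if ((x < -tol) | (x > w + tol) | (y < -tol) | (y > h + tol)).any():
                raise IntegrityError("cell coordinates outside the tissue frame")

    # -- constructors -------------------------------------------------
    @classmethod
    def from_records(
        cls, records: Iterable[CellRecord], frame: Optional["TissueGeometry"] = None
    ) -> "CellTable":
        rows = [
            {
                "cell_id": r.cell_id,
                "x_um": r.x,
                "y_um": r.y,
                "cell_type": r.cell_type.value,
                "marker": r.marker.value,
                "parent_id": r.parent_id if r.parent_id is not None else pd.NA,
            }
            for r in records
        ]
        return cls(pd.DataFrame(rows, columns=CELL_COLUMNS), frame=frame)

    @classmethod
    def from_arrays(
        cls,
        x: Sequence[float],
        y: Sequence[float],
        cell_type: CellType,
        prefix: str,
        parent_id: Optional[Sequence] = None,
        frame: Optional["TissueGeometry"] = None,
    ) -> "CellTable":
        """Build a homogeneous table; ids are ``{prefix}_{i:05d}``."""
        n = len(x)
        df = pd.DataFrame(
            {
                "cell_id": [f"{prefix}_{i:05d}" for i in range(n)],
                "x_um": np.asarray(x, dtype=float),
                "y_um": np.asarray(y, dtype=float),
                "cell_type": cell_type.value,
                "marker": DEFAULT_MARKER[cell_type].value,
                "parent_id": pd.NA if parent_id is None else list(parent_id),
            }
        )
        return cls(df, frame=frame)

    @classmethod
    def empty(cls, frame: Optional["TissueGeometry"] = None) -> "CellTable":
        return cls(pd.DataFrame(columns=CELL_COLUMNS), frame=frame)

    # -- accessors ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def counts_by_type(self) -> dict[str, int]:
        counts = self.df["cell_type"].value_counts().to_dict()
        return {t.value: int(counts.get(t.value, 0)) for t in CellType}

    def select(self, cell_type: CellType) -> "CellTable":
        sub = self.df[self.df["cell_type"] == cell_type.value]
        return CellTable(sub.copy(), frame=self.frame)

    def xy(self, cell_type: Optional[CellType] = None) -> np.ndarray:
        """(n, 2) float array of positions, optionally restricted by type."""
        df = self.df
        if cell_type is not None:
            df = df[df["cell_type"] == cell_type.value]
        return df[["x_um", "y_um"]].to_numpy(dtype=float)

    def to_records(self) -> list[CellRecord]:
        return [
            CellRecord(
                cell_id=row.cell_id,
                x=row.x_um,
                y=row.y_um,
                cell_type=CellType(row.cell_type),
                marker=Marker(row.marker),
                parent_id=None if pd.isna(row.parent_id) else str(row.parent_id),
            )
            for row in self.df.itertuples(index=False)
        ]


def concat_tables(tables: Sequence[CellTable]) -> CellTable:
    """Concatenate tables sharing a frame; ids must stay unique."""
    frames = [t.frame for t in tables if t.frame is not None]
    frame = frames[0] if frames else None
    dfs = [t.df for t in tables if len(t.df)]
    if not dfs:
        return CellTable.empty(frame=frame)
    return CellTable(pd.concat(dfs, ignore_index=True), frame=frame)
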