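"""Canonical data model and CSV I/O for bifurcation measurements.

One row of the canonical table is one measured fork: parent internal-cavity
diameter ``d0`` and the two child diameters ``d1``, ``d2`` (all microns),
optional bifurcation angles (degrees), wing length (mm) and taxonomic
labels.  The canonical header is defined here because no standard layout
exists for this kind of morphometric table; other layouts are mapped on
via registered dialect adapters.

Validation is total: every input row is either accepted or reported with
its row number and the reason, and accepted + rejected equals rows read.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "BifurcationRecord",
    "RowError",
    "MeasurementTable",
    "CANONICAL_COLUMNS",
    "REQUIRED_COLUMNS",
    "register_dialect",
    "read_measurements",
    "write_table",
    "records_to_frame",
    "frame_to_records",
]

CANONICAL_COLUMNS: tuple[str, ...] = (
    "specimen_id",
    "taxon_superfamily",
    "taxon_family",
    "order_label",
    "wing_length",
    "fork_index",
    "d0",
    "d1",
    "d2",
    "angle_children",
    "angle_parent_child1",
    "angle_parent_child2",
)

REQUIRED_COLUMNS: tuple[str, ...] = (
    "specimen_id",
    "taxon_superfamily",
    "order_label",
    "fork_index",
    "d0",
    "d1",
    "d2",
)

_ORDERS = ("Lepidoptera", "Trichoptera")

_ANGLE_FIELDS = ("angle_children", "angle_parent_child1", "angle_parent_child2")


@dataclass(frozen=True)
class BifurcationRecord:
    """One measured fork on a wing.

    Diameters are internal cavity diameters in microns; angles in degrees;
    wing length in mm.  Optional fields are ``None`` when not measured.
    """

    specimen_id: str
    taxon_superfamily: str
    order_label: str
    fork_index: int
    d0: float
    d1: float
    d2: float
    taxon_family: Optional[str] = None
    wing_length: Optional[float] = None
    angle_children: Optional[float] = None
    angle_parent_child1: Optional[float] = None
    angle_parent_child2: Optional[float] = None

    def __post_init__(self):
        for name in ("d0", "d1", "d2"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a positive finite number, got {v!r}")
        if self.fork_index not in (1, 2, 3):
            raise ValueError(f"fork_index must be 1, 2 or 3, got {self.fork_index!r}")
        if self.order_label not in _ORDERS:
            raise ValueError(
                f"order_label must be one of {_ORDERS}, got {self.order_label!r}"
            )
        for name in _ANGLE_FIELDS:
            v = getattr(self, name)
            if v is not None and not (0.0 <= v < 180.0):
                raise ValueError(f"{name} must lie in [0, 180), got {v!r}")
        if self.wing_length is not None and self.wing_length <= 0:
            raise ValueError(f"wing_length must be positive, got {self.wing_length!r}")


@dataclass(frozen=True)
class RowError:
    """A located row-level validation diagnostic (1-based data row number)."""

    row: int
    field: Optional[str]
    reason: str


@dataclass
class MeasurementTable:
    """Validated records plus the rejection report from one read."""

    records: list[BifurcationRecord]
    rejections: list[RowError]

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)

    @property
    def n_read(self) -> int:
        return len(self.records) + len(self.rejections)

    def to_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


# dialect name -> callable mapping a raw DataFrame onto canonical columns
_DIALECTS: dict[str, Callable[[pd.DataFrame], pd.DataFrame]] = {}


def register_dialect(name: str, adapter: Callable[[pd.DataFrame], pd.DataFrame]) -> None:
    """Register a column adapter mapping a foreign CSV layout onto the
    canonical schema (used e.g. for a deposited dataset whose headers
    differ from ours)."""
    _DIALECTS[name] = adapter


def _coerce_float(value, field: str, row: int, optional: bool = False):
    if value is None or (isinstance(value, str) and value.strip() == "") or (
        isinstance(value, float) and math.isnan(value)
    ):
        if optional:
            return None
        raise _RowProblem(field, "missing required value")
    try:
        return float(value)
    except (TypeError, ValueError):
        raise _RowProblem(field, f"unparseable number {value!r}")


class _RowProblem(Exception):
    def __init__(self, field: Optional[str], reason: str):
        self.field = field
        self.reason = reason
        super().__init__(reason)


def _row_to_record(row: pd.Series, row_no: int) -> BifurcationRecord:
    def opt_str(name):
        v = row.get(name)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        s = str(v).strip()
        return s or None

    try:
        fork_raw = row.get("fork_index")
        try:
            fork = int(float(fork_raw))
        except (TypeError, ValueError):
            raise _RowProblem("fork_index", f"unparseable integer {fork_raw!r}")
        return BifurcationRecord(
            specimen_id=str(row.get("specimen_id", "")).strip(),
            taxon_superfamily=str(row.get("taxon_superfamily", "")).strip(),
            taxon_family=opt_str("taxon_family"),
            order_label=str(row.get("order_label", "")).strip(),
            wing_length=_coerce_float(row.get("wing_length"), "wing_length", row_no, optional=True),
            fork_index=fork,
            d0=_coerce_float(row.get("d0"), "d0", row_no),
            d1=_coerce_float(row.get("d1"), "d1", row_no),
            d2=_coerce_float(row.get("d2"), "d2", row_no),
            angle_children=_coerce_float(row.get("angle_children"), "angle_children", row_no, optional=True),
            angle_parent_child1=_coerce_float(row.get("angle_parent_child1"), "angle_parent_child1", row_no, optional=True),
            angle_parent_child2=_coerce_float(row.get("angle_parent_child2"), "angle_parent_child2", row_no, optional=True),
        )
    except _RowProblem:
        raise
    except ValueError as exc:
        # invariant violations raised by BifurcationRecord
        raise _RowProblem(None, str(exc))


def read_measurements(
    path: Union[str, Path],
    dialect: str = "canonical",
) -> MeasurementTable:
    """Read a measurement CSV into validated records, preserving file order.

    Raises a schema error if a required column is absent; rows violating
    the record invariants are rejected individually with row number and
    reason rather than aborting the read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw = raw.replace({"": None})
    if dialect != "canonical":
        if dialect not in _DIALECTS:
            raise ValueError(f"unknown dialect {dialect!r}; registered: {sorted(_DIALECTS)}")
        raw = _DIALECTS[dialect](raw)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"schema error: missing required column(s) {missing}")

    records: list[BifurcationRecord] = []
    rejections: list[RowError] = []
    for i, (_, row) in enumerate(raw.iterrows(), start=1):
        try:
            records.append(_row_to_record(row, i))
        except _RowProblem as p:
            rejections.append(RowError(row=i, field=p.field, reason=p.reason))
    return MeasurementTable(records=records, rejections=rejections)


def records_to_frame(records: Sequence[BifurcationRecord]) -> pd.DataFrame:
    frame = pd.DataFrame([dataclasses.asdict(r) for r in records])
    return frame.reindex(columns=list(CANONICAL_COLUMNS))


def frame_to_records(frame: pd.DataFrame) -> list[BifurcationRecord]:
    table = MeasurementTable([], [])
    for i, (_, row) in enumerate(frame.iterrows(), start=1):
        table.records.append(_row_to_record(row, i))
    return table.records


def write_table(payload, path: Union[str, Path]) -> None:
    """Write records or any result table to CSV.

    Floats are written with ``repr`` round-trip precision so that a
    read-back reproduces every value bit-for-bit.  Empty payloads are an
    error (an empty result table almost always signals an upstream bug).
    """
    if isinstance(payload, MeasurementTable):
        frame = payload.to_frame()
    elif isinstance(payload, pd.DataFrame):
        frame = payload
    elif isinstance(payload, Sequence) and payload and isinstance(payload[0], BifurcationRecord):
        frame = records_to_frame(payload)
    else:
        frame = pd.DataFrame(payload)
    if frame.empty:
        raise ValueError("refusing to write an empty table")
    frame.to_csv(path, index=False, float_format=None)
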