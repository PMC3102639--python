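"""Landmark annotation schema and file I/O.

Coordinate convention (fixed throughout the package): on an axial CT slice,
``x`` increases toward the patient's LEFT and ``y`` toward the patient's
POSTERIOR, both in millimetres. The origin is arbitrary — every downstream
measurement is translation-invariant — but the axis directions define the
sign of all rotation angles, so they are part of the schema.

Two annotation dialects are supported:

* CSV — one landmark per row, header ``subject_id,level,role,x_mm,y_mm``,
  with exactly the six roles ``pedicle_base_left``, ``pedicle_base_right``,
  ``lamina_left_post``, ``lamina_left_ant``, ``lamina_right_post``,
  ``lamina_right_ant`` per (subject, level).
* JSON — a list of per-vertebra objects mirroring :class:`VertebraLandmarks`.

Lamina segments are ORDERED (posterior end first, anterior end second); the
order is data, not a heuristic, and resolves the two-fold ambiguity of the
bisector direction used by Ho's method.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import SchemaError

__all__ = [
    "Point2D",
    "OrientedSegment",
    "VertebraLandmarks",
    "SubjectRecord",
    "MeasurementTable",
    "LANDMARK_ROLES",
    "read_landmarks",
    "write_landmarks",
    "read_measurement_table",
    "write_measurement_table",
    "read_subject_metadata",
    "write_subject_metadata",
]

#: The six landmark roles of one vertebra, in canonical order.
LANDMARK_ROLES = (
    "pedicle_base_left",
    "pedicle_base_right",
    "lamina_left_post",
    "lamina_left_ant",
    "lamina_right_post",
    "lamina_right_ant",
)

_MEASUREMENT_COLUMNS = ("subject_id", "observer", "occasion", "method", "angle_deg")
_METHODS = frozenset({"ho", "new"})


@dataclass(frozen=True)
class Point2D:
    """A landmark position on the axial slice, in millimetres.

    ``x``: along the patient left axis; ``y``: along the patient posterior axis.
    """

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise SchemaError(f"non-finite coordinate ({self.x}, {self.y})")


@dataclass(frozen=True)
class OrientedSegment:
    """One lamina inner-surface line, ordered posterior end -> anterior end."""

    posterior_end: Point2D
    anterior_end: Point2D

    def __post_init__(self) -> None:
        if (
            self.posterior_end.x == self.anterior_end.x
            and self.posterior_end.y == self.anterior_end.y
        ):
            raise SchemaError("degenerate segment: endpoints coincide")

    @property
    def direction(self) -> tuple[float, float]:
        """Unnormalized posterior -> anterior direction vector."""
        return (
            self.anterior_end.x - self.posterior_end.x,
            self.anterior_end.y - self.posterior_end.y,
        )


@dataclass(frozen=True)
class VertebraLandmarks:
    """The six annotated landmarks of one vertebra.

    Two pedicle-base points (posterior vertebral body just beneath each
    pedicle — the anterior-component landmarks) and two oriented lamina
    segments (the posterior-component landmarks of Ho's method).
    """

    subject_id: str
    level: str
    pedicle_base_left: Point2D
    pedicle_base_right: Point2D
    lamina_left: OrientedSegment
    lamina_right: OrientedSegment

    def __post_init__(self) -> None:
        if (
            self.pedicle_base_left.x == self.pedicle_base_right.x
            and self.pedicle_base_left.y == self.pedicle_base_right.y
        ):
            raise SchemaError(
                f"subject {self.subject_id!r}: pedicle-base points coincide"
            )

    def points_by_role(self) -> dict[str, Point2D]:
        return {
            "pedicle_base_left": self.pedicle_base_left,
            "pedicle_base_right": self.pedicle_base_right,
            "lamina_left_post": self.lamina_left.posterior_end,
            "lamina_left_ant": self.lamina_left.anterior_end,
            "lamina_right_post": self.lamina_right.posterior_end,
            "lamina_right_ant": self.lamina_right.anterior_end,
        }

    @classmethod
    def from_points(
        cls, subject_id: str, level: str, points: dict[str, Point2D]
    ) -> "VertebraLandmarks":
        missing = [r for r in LANDMARK_ROLES if r not in points]
        if missing:
            raise SchemaError(
                f"subject {subject_id!r}: missing role(s) {', '.join(missing)}"
            )
        return cls(
            subject_id=subject_id,
            level=level,
            pedicle_base_left=points["pedicle_base_left"],
            pedicle_base_right=points["pedicle_base_right"],
            lamina_left=OrientedSegment(
                points["lamina_left_post"], points["lamina_left_ant"]
            ),
            lamina_right=OrientedSegment(
                points["lamina_right_post"], points["lamina_right_ant"]
            ),
        )


@dataclass(frozen=True)
class SubjectRecord:
    """One study subject: metadata plus the annotated apical vertebra."""

    subject_id: str
    age: float
    cobb_angle_deg: float | None
    apical_level: str
    landmarks: VertebraLandmarks

    def __post_init__(self) -> None:
        if self.cobb_angle_deg is not None and self.cobb_angle_deg < 0:
            raise SchemaError(
                f"subject {self.subject_id!r}: negative Cobb angle "
                f"{self.cobb_angle_deg}"
            )


@dataclass
class MeasurementTable:
    """Long-format repeated measurements: subject x observer x occasion x method.

    ``data`` holds the validated frame with columns
    ``subject_id, observer, occasion, method, angle_deg``; observer and
    occasion labels are preserved exactly as given.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _MEASUREMENT_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"measurement table missing column(s) {missing}")
        bad = set(df["method"].unique()) - _METHODS
        if bad:
            raise SchemaError(
                f"unknown method label(s) {sorted(bad)}; expected one of "
                f"{sorted(_METHODS)}"
            )
        if not pd.api.types.is_numeric_dtype(df["angle_deg"]):
            raise SchemaError("angle_deg column is not numeric")
        if df["angle_deg"].isna().any():
            raise SchemaError("angle_deg contains missing values")
        key = ["subject_id", "observer", "occasion", "method"]
        dup = df.duplicated(subset=key)
        if dup.any():
            first = df.loc[dup, key].iloc[0].tolist()
            raise SchemaError(f"duplicate measurement row for {first}")
        self.data = df.loc[:, list(_MEASUREMENT_COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# landmark file I/O


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "json"):
            raise ValueError(f"unsupported format {fmt!r}; use 'csv' or 'json'")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "json"):
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_landmarks(path: str | Path, format: str | None = None) -> list[VertebraLandmarks]:
    """Read a landmark annotation file (CSV or JSON dialect).

    Returns one :class:`VertebraLandmarks` per (subject_id, level), in file
    order. Raises :class:`SchemaError` on missing/duplicate roles or
    non-numeric coordinates (with the offending line number for CSV).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        return _read_landmarks_csv(path)
    return _read_landmarks_json(path)


def _read_landmarks_csv(path: Path) -> list[VertebraLandmarks]:
    grouped: dict[tuple[str, str], dict[str, Point2D]] = {}
    order: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        expected = {"subject_id", "level", "role", "x_mm", "y_mm"}
        if reader.fieldnames is None or not expected.issubset(reader.fieldnames):
            raise SchemaError(
                f"{path.name}: expected header subject_id,level,role,x_mm,y_mm"
            )
        for lineno, row in enumerate(reader, start=2):
            role = row["role"]
            if role not in LANDMARK_ROLES:
                raise SchemaError(f"{path.name}:{lineno}: unknown role {role!r}")
            try:
                x = float(row["x_mm"])
                y = float(row["y_mm"])
            except (TypeError, ValueError):
                raise SchemaError(
                    f"{path.name}:{lineno}: non-numeric coordinate "
                    f"({row['x_mm']!r}, {row['y_mm']!r})"
                ) from None
            key = (row["subject_id"], row["level"])
            if key not in grouped:
                grouped[key] = {}
                order.append(key)
            if role in grouped[key]:
                raise SchemaError(
                    f"{path.name}:{lineno}: duplicate role {role!r} for "
                    f"subject {key[0]!r}"
                )
            grouped[key][role] = Point2D(x, y)
    return [
        VertebraLandmarks.from_points(sid, level, pts)
        for (sid, level), pts in ((k, grouped[k]) for k in order)
    ]


def _point_from_json(obj: dict, context: str) -> Point2D:
    try:
        return Point2D(float(obj["x_mm"]), float(obj["y_mm"]))
    except (KeyError, TypeError, ValueError):
        raise SchemaError(f"{context}: malformed point {obj!r}") from None


def _read_landmarks_json(path: Path) -> list[VertebraLandmarks]:
    with open(path) as fh:
        payload = json.load(fh)
    if not isinstance(payload, list):
        raise SchemaError(f"{path.name}: expected a JSON list of vertebra objects")
    out = []
    for i, obj in enumerate(payload):
        ctx = f"{path.name}[{i}]"
        try:
            sid = obj["subject_id"]
            level = obj["level"]
        except (TypeError, KeyError):
            raise SchemaError(f"{ctx}: missing subject_id or level") from None
        for fieldname in ("pedicle_base_left", "pedicle_base_right",
                          "lamina_left", "lamina_right"):
            if fieldname not in obj:
                raise SchemaError(f"{ctx}: subject {sid!r} missing {fieldname!r}")
        out.append(
            VertebraLandmarks(
                subject_id=sid,
                level=level,
                pedicle_base_left=_point_from_json(obj["pedicle_base_left"], ctx),
                pedicle_base_right=_point_from_json(obj["pedicle_base_right"], ctx),
                lamina_left=OrientedSegment(
                    _point_from_json(obj["lamina_left"]["posterior_end"], ctx),
                    _point_from_json(obj["lamina_left"]["anterior_end"], ctx),
                ),
                lamina_right=OrientedSegment(
                    _point_from_json(obj["lamina_right"]["posterior_end"], ctx),
                    _point_from_json(obj["lamina_right"]["anterior_end"], ctx),
                ),
            )
        )
    return out


def write_landmarks(
    collection: Sequence[VertebraLandmarks] | Iterable[VertebraLandmarks],
    path: str | Path,
    format: str | None = None,
) -> None:
    """Write landmarks in a dialect readable by :func:`read_landmarks`.

    Coordinates are serialized with 9 decimal digits (sub-nanometre), so a
    round trip reproduces them well beyond the 6-decimal contract.
    """
    collection = list(collection)
    if not collection:
        raise ValueError("refusing to write an empty landmark collection")
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["subject_id", "level", "role", "x_mm", "y_mm"])
            for lm in collection:
                for role, pt in lm.points_by_role().items():
                    writer.writerow(
                        [lm.subject_id, lm.level, role, f"{pt.x:.9f}", f"{pt.y:.9f}"]
                    )
    else:
        payload = []
        for lm in collection:
            payload.append(
                {
                    "subject_id": lm.subject_id,
                    "level": lm.level,
                    "pedicle_base_left": _point_to_json(lm.pedicle_base_left),
                    "pedicle_base_right": _point_to_json(lm.pedicle_base_right),
                    "lamina_left": {
                        "posterior_end": _point_to_json(lm.lamina_left.posterior_end),
                        "anterior_end": _point_to_json(lm.lamina_left.anterior_end),
                    },
                    "lamina_right": {
                        "posterior_end": _point_to_json(lm.lamina_right.posterior_end),
                        "anterior_end": _point_to_json(lm.lamina_right.anterior_end),
                    },
                }
            )
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _point_to_json(pt: Point2D) -> dict[str, float]:
    return {"x_mm": pt.x, "y_mm": pt.y}


# ---------------------------------------------------------------------------
# measurement and metadata tables


def read_measurement_table(path: str | Path) -> MeasurementTable:
    """Read and validate a long-format repeated-measurement CSV."""
    df = pd.read_csv(path)
    return MeasurementTable(df)


def write_measurement_table(table: MeasurementTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def read_subject_metadata(path: str | Path) -> pd.DataFrame:
    """Read the subject metadata CSV (subject_id, age, cobb_angle_deg, apical_level)."""
    df = pd.read_csv(path)
    required = {"subject_id", "age", "cobb_angle_deg", "apical_level"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"metadata missing column(s) {sorted(missing)}")
    if (df["cobb_angle_deg"].dropna() < 0).any():
        raise SchemaError("negative Cobb angle in metadata")
    return df


def write_subject_metadata(records: Sequence[SubjectRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "age": [r.age for r in records],
            "cobb_angle_deg": [r.cobb_angle_deg for r in records],
            "apical_level": [r.apical_level for r in records],
        }
    ).to_csv(path, index=False)
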