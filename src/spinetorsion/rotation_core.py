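"""Vertebral axial rotation and torsion from one vertebra's landmarks.

Two measurements on the same axial slice:

* **Anterior-component rotation (beta)** — the signed angle between the chord
  joining the two pedicle-base points (posterior vertebral body just beneath
  each pedicle) and the horizontal (patient left-right) axis.
* **Posterior-component rotation (alpha, Ho's method)** — the signed angle
  between the bisector of the two lamina inner-surface lines and the
  vertical (anterior-posterior) axis.

Sign convention: rotation of the vertebra's anterior aspect toward the
patient's RIGHT is positive, for both angles. The **torsional deformity
angle** is their discrepancy tau = beta - alpha: positive when the anterior
component (vertebral body) is rotated further toward the convex/right side
than the posterior arch.

All angles are in degrees and live in (-90, 90); values outside that band
signal annotation errors, not wrapped angles — an axial vertebral slice
cannot rotate a quarter turn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .annotations_io import OrientedSegment, Point2D, VertebraLandmarks
from .errors import (
    DegenerateBisectorError,
    DegenerateLandmarkError,
    ImplausibleLandmarkError,
    SpineTorsionError,
)

__all__ = [
    "RotationMeasurement",
    "measure_new_rotation",
    "measure_ho_rotation",
    "torsion_angle",
    "measure_vertebra",
    "measure_collection",
]

_EPS = 1e-12


@dataclass(frozen=True)
class RotationMeasurement:
    """The (alpha, beta, tau) triple for one vertebra, in degrees.

    ``torsion_deg`` is exactly ``beta_deg - alpha_deg`` by construction.
    """

    subject_id: str
    level: str
    alpha_deg: float
    beta_deg: float

    @property
    def torsion_deg(self) -> float:
        return self.beta_deg - self.alpha_deg


def measure_new_rotation(
    pedicle_base_left: Point2D, pedicle_base_right: Point2D
) -> float:
    """Anterior-component rotation beta (degrees) from the pedicle-base chord.

    beta = -atan2(dy, dx) * 180/pi with (dx, dy) = left - right in the
    x-left / y-posterior frame, so a right rotation of the vertebral body
    tilts the chord to a positive angle.
    """
    dx = pedicle_base_left.x - pedicle_base_right.x
    dy = pedicle_base_left.y - pedicle_base_right.y
    if math.hypot(dx, dy) < _EPS:
        raise DegenerateLandmarkError("pedicle-base points coincide")
    beta = -math.degrees(math.atan2(dy, dx))
    if not -90.0 < beta < 90.0:
        raise ImplausibleLandmarkError(
            f"pedicle chord angle {beta:.1f} deg outside (-90, 90); "
            "chord is closer to sagittal than axial orientation"
        )
    return beta


def measure_ho_rotation(
    lamina_left: OrientedSegment, lamina_right: OrientedSegment
) -> float:
    """Posterior-component rotation alpha (degrees) by Ho's lamina bisector.

    The bisector of the two unit lamina directions (posterior end ->
    anterior end) is compared with the vertical axis:
    alpha = atan2(-b_x, -b_y) * 180/pi, positive for right rotation.
    """
    ulx, uly = _unit_direction(lamina_left, "left lamina")
    urx, ury = _unit_direction(lamina_right, "right lamina")
    sx, sy = ulx + urx, uly + ury
    norm = math.hypot(sx, sy)
    if norm < 1e-9:
        raise DegenerateBisectorError(
            "lamina directions are antiparallel; bisector undefined"
        )
    bx, by = sx / norm, sy / norm
    alpha = math.degrees(math.atan2(-bx, -by))
    if not -90.0 < alpha < 90.0:
        raise ImplausibleLandmarkError(
            f"lamina bisector angle {alpha:.1f} deg outside (-90, 90)"
        )
    return alpha


def _unit_direction(segment: OrientedSegment, label: str) -> tuple[float, float]:
    dx, dy = segment.direction
    norm = math.hypot(dx, dy)
    if norm < _EPS:
        raise DegenerateLandmarkError(f"{label} segment is degenerate")
    return dx / norm, dy / norm


def torsion_angle(beta_deg: float, alpha_deg: float) -> float:
    """Torsional deformity angle tau = beta - alpha, in degrees.

    Positive tau: the anterior component is rotated further toward the
    patient's right (the convex side of a right thoracic curve) than the
    posterior component.
    """
    if not (math.isfinite(beta_deg) and math.isfinite(alpha_deg)):
        raise DegenerateLandmarkError("non-finite rotation angle")
    return beta_deg - alpha_deg


def measure_vertebra(landmarks: VertebraLandmarks) -> RotationMeasurement:
    """Apply both methods to the same vertebra and return (alpha, beta, tau).

    Geometry errors are re-raised tagged with the subject and level.
    """
    try:
        beta = measure_new_rotation(
            landmarks.pedicle_base_left, landmarks.pedicle_base_right
        )
        alpha = measure_ho_rotation(landmarks.lamina_left, landmarks.lamina_right)
    except SpineTorsionError as err:
        raise type(err)(
            f"subject {landmarks.subject_id!r} level {landmarks.level!r}: {err}"
        ) from err
    return RotationMeasurement(
        subject_id=landmarks.subject_id,
        level=landmarks.level,
        alpha_deg=alpha,
        beta_deg=beta,
    )


def measure_collection(collection) -> pd.DataFrame:
    """Measure every vertebra and return a per-vertebra angle table.

    Columns: subject_id, level, alpha_deg, beta_deg, torsion_deg (raw
    double precision; round only when formatting reports).
    """
    rows = []
    for lm in collection:
        m = measure_vertebra(lm)
        rows.append(
            {
                "subject_id": m.subject_id,
                "level": m.level,
                "alpha_deg": m.alpha_deg,
                "beta_deg": m.beta_deg,
                "torsion_deg": m.torsion_deg,
            }
        )
    return pd.DataFrame(rows)
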