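"""Digital vertebra phantoms, simulated cohorts, and observer noise.

The phantom is the ground-truth engine of the toolkit: a fixed
mirror-symmetric landmark template (plausible thoracic dimensions, mm) whose
measured rotation is exactly zero, deformed by two rigid sub-rotations about
the spinal-canal centre — the anterior landmark pair (pedicle bases) by
``theta_post + tau`` and the posterior landmark quadruple (lamina endpoints)
by ``theta_post``. That is the minimal landmark-level realization of a
gradual torsion between vertebral body and posterior arch: with zero noise
the measured (alpha, beta, tau) equals (theta_post, theta_post + tau, tau)
to machine precision.

Cohort simulation draws per-subject (theta_post, tau, Cobb) from a
trivariate normal; observer simulation re-perturbs each subject's noiseless
landmarks with independent isotropic Gaussian displacements per (observer,
occasion), so the two methods' reliabilities differ naturally — the lamina
bisector uses four points on shorter segments than the 30 mm pedicle chord.

Random-number contract: every operation takes one integer seed and draws
through a single ``numpy.random.default_rng`` stream in documented order
(phantom: 6 landmark displacements x 2 coordinates, canonical role order;
cohort: the n x 3 trivariate draws, subject order; observers: subjects outer,
observers middle, occasions inner, then the 6 x 2 displacements).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations_io import (
    LANDMARK_ROLES,
    OrientedSegment,
    Point2D,
    SubjectRecord,
    VertebraLandmarks,
    MeasurementTable,
)
from .errors import ParameterError
from .rotation_core import measure_vertebra

__all__ = [
    "CANAL_CENTER",
    "PhantomParams",
    "CohortParams",
    "Cohort",
    "canonical_template",
    "rotate_right",
    "generate_phantom",
    "simulate_cohort",
    "simulate_observers",
]

#: Template spinal-canal centre, the pivot of both sub-rotations (mm).
CANAL_CENTER = Point2D(0.0, 25.0)


def canonical_template(subject_id: str = "template", level: str = "T8") -> VertebraLandmarks:
    """The fixed symmetric landmark layout of an undeformed vertebra.

    Pedicle-base points at (+/-15, 10); lamina segments (+/-3, 42) ->
    (+/-16, 28). Mirror symmetry across the sagittal axis forces
    (alpha, beta, tau) = (0, 0, 0).
    """
    return VertebraLandmarks(
        subject_id=subject_id,
        level=level,
        pedicle_base_left=Point2D(15.0, 10.0),
        pedicle_base_right=Point2D(-15.0, 10.0),
        lamina_left=OrientedSegment(Point2D(3.0, 42.0), Point2D(16.0, 28.0)),
        lamina_right=OrientedSegment(Point2D(-3.0, 42.0), Point2D(-16.0, 28.0)),
    )


def rotate_right(point: Point2D, theta_deg: float, center: Point2D = CANAL_CENTER) -> Point2D:
    """Rotate a point by ``theta_deg`` of RIGHT vertebral rotation about ``center``.

    In the x-left / y-posterior frame a right rotation is the clockwise map
    (x, y) -> (x cos t + y sin t, -x sin t + y cos t) relative to the pivot.
    """
    t = math.radians(theta_deg)
    c, s = math.cos(t), math.sin(t)
    x, y = point.x - center.x, point.y - center.y
    return Point2D(center.x + x * c + y * s, center.y - x * s + y * c)


@dataclass(frozen=True)
class PhantomParams:
    """Ground truth and noise for one phantom vertebra.

    theta_post_deg: posterior-component rotation (true alpha).
    tau_deg: torsional deformity (true tau); the anterior component carries
        theta_post_deg + tau_deg.
    noise_sigma_mm: isotropic Gaussian displacement applied to each landmark.
    """

    theta_post_deg: float = 0.0
    tau_deg: float = 0.0
    noise_sigma_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma_mm < 0:
            raise ParameterError("noise_sigma_mm must be >= 0")
        if abs(self.theta_post_deg) >= 45 or abs(self.theta_post_deg + self.tau_deg) >= 45:
            raise ParameterError(
                "component rotations must stay within +/-45 deg "
                f"(theta_post={self.theta_post_deg}, "
                f"theta_post+tau={self.theta_post_deg + self.tau_deg})"
            )


def generate_phantom(
    params: PhantomParams, subject_id: str = "phantom", level: str = "T8"
) -> VertebraLandmarks:
    """Build one phantom vertebra from the canonical template.

    The pedicle-base pair is rotated rigidly by theta_post + tau and the four
    lamina endpoints by theta_post, both about the canal centre; each of the
    six points then receives an independent N(0, noise_sigma_mm^2)
    displacement per coordinate, in canonical role order.
    """
    template = canonical_template(subject_id, level)
    pts = template.points_by_role()
    theta_ant = params.theta_post_deg + params.tau_deg
    rotated = {}
    for role in LANDMARK_ROLES:
        theta = theta_ant if role.startswith("pedicle") else params.theta_post_deg
        rotated[role] = rotate_right(pts[role], theta)
    if params.noise_sigma_mm > 0:
        rng = np.random.default_rng(params.seed)
        noise = rng.normal(0.0, params.noise_sigma_mm, size=(len(LANDMARK_ROLES), 2))
        rotated = {
            role: Point2D(rotated[role].x + noise[i, 0], rotated[role].y + noise[i, 1])
            for i, role in enumerate(LANDMARK_ROLES)
        }
    return VertebraLandmarks.from_points(subject_id, level, rotated)


@dataclass(frozen=True)
class CohortParams:
    """Population parameters of a simulated scoliosis cohort.

    Defaults reproduce the study conditions: 25 right-thoracic-curve
    subjects with posterior rotation 7.9 +/- 6.3 deg, torsion 6.1 +/- 3.9 deg
    (anterior rotation therefore 14.0 +/- sqrt(6.3^2 + 3.9^2) deg under the
    default independence of torsion and posterior rotation), Cobb angle
    56.5 +/- 11 deg, and a torsion-Cobb correlation of 0.36. The posterior
    rotation-Cobb correlation is fixed at zero.
    """

    n_subjects: int = 25
    theta_post_mean: float = 7.9
    theta_post_sd: float = 6.3
    tau_mean: float = 6.1
    tau_sd: float = 3.9
    cobb_mean: float = 56.5
    cobb_sd: float = 11.0
    rho_tau_cobb: float = 0.36
    rho_tau_theta: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ParameterError("n_subjects must be >= 2")
        for name in ("theta_post_sd", "tau_sd", "cobb_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("rho_tau_cobb", "rho_tau_theta"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise ParameterError(f"{name} must lie in [-1, 1]")

    def covariance(self) -> np.ndarray:
        """Covariance of (theta_post, tau, cobb); raises if not PSD."""
        st, su, sc = self.theta_post_sd, self.tau_sd, self.cobb_sd
        cov = np.array(
            [
                [st**2, self.rho_tau_theta * st * su, 0.0],
                [self.rho_tau_theta * st * su, su**2, self.rho_tau_cobb * su * sc],
                [0.0, self.rho_tau_cobb * su * sc, sc**2],
            ]
        )
        if np.linalg.eigvalsh(cov).min() < -1e-9:
            raise ParameterError(
                "implied covariance is not positive semidefinite for "
                f"rho_tau_theta={self.rho_tau_theta}, rho_tau_cobb={self.rho_tau_cobb}"
            )
        return cov


@dataclass
class Cohort:
    """Simulated subjects plus the ground-truth parameter table."""

    records: list[SubjectRecord]
    truth: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.records)


def simulate_cohort(params: CohortParams) -> Cohort:
    """Draw a cohort and build one noiseless phantom per subject.

    Per-subject (theta_post, tau, Cobb) come from the trivariate normal
    defined by ``params``; each subject's landmarks are the exact
    (noise-free) phantom for their drawn rotations, so downstream
    measurements recover the truth table to machine precision. Ages are
    drawn uniformly on 12-20 years (the adolescent range of the cohort).
    """
    cov = params.covariance()
    mean = np.array([params.theta_post_mean, params.tau_mean, params.cobb_mean])
    rng = np.random.default_rng(params.seed)
    draws = rng.multivariate_normal(mean, cov, size=params.n_subjects,
                                    check_valid="ignore", method="svd")
    ages = rng.uniform(12.0, 20.0, size=params.n_subjects)
    records = []
    rows = []
    width = max(3, len(str(params.n_subjects)))
    for i in range(params.n_subjects):
        theta, tau, cobb = draws[i]
        sid = f"S{i + 1:0{width}d}"
        lm = generate_phantom(
            PhantomParams(theta_post_deg=theta, tau_deg=tau, noise_sigma_mm=0.0),
            subject_id=sid,
            level="T8",
        )
        records.append(
            SubjectRecord(
                subject_id=sid,
                age=float(ages[i]),
                cobb_angle_deg=float(cobb),
                apical_level="T8",
                landmarks=lm,
            )
        )
        rows.append(
            {
                "subject_id": sid,
                "theta_post_deg": float(theta),
                "tau_deg": float(tau),
                "cobb_angle_deg": float(cobb),
            }
        )
    return Cohort(records=records, truth=pd.DataFrame(rows))


def simulate_observers(
    cohort: Cohort | list[SubjectRecord],
    n_observers: int = 3,
    n_occasions: int = 2,
    noise_sigma_mm: float = 0.4,
    seed: int = 0,
) -> MeasurementTable:
    """Simulate repeated annotation: subject x observer x occasion x method.

    For each (subject, observer, occasion) the subject's noiseless landmarks
    are re-perturbed with independent N(0, noise_sigma_mm^2) displacements
    per coordinate and both methods' angles recorded; the default 0.4 mm
    places the simulated reliabilities in the study's observed band.
    With zero noise every repeated angle equals the subject's true angle.
    """
    records = cohort.records if isinstance(cohort, Cohort) else list(cohort)
    if not records:
        raise ParameterError("cohort is empty")
    if n_observers < 1 or n_occasions < 1:
        raise ParameterError("n_observers and n_occasions must be >= 1")
    if noise_sigma_mm < 0:
        raise ParameterError("noise_sigma_mm must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for rec in records:
        base = rec.landmarks.points_by_role()
        for observer in range(1, n_observers + 1):
            for occasion in range(1, n_occasions + 1):
                noise = rng.normal(0.0, noise_sigma_mm, size=(len(LANDMARK_ROLES), 2))
                pts = {
                    role: Point2D(base[role].x + noise[i, 0], base[role].y + noise[i, 1])
                    for i, role in enumerate(LANDMARK_ROLES)
                }
                m = measure_vertebra(
                    VertebraLandmarks.from_points(rec.subject_id, rec.landmarks.level, pts)
                )
                rows.append((rec.subject_id, observer, occasion, "ho", m.alpha_deg))
                rows.append((rec.subject_id, observer, occasion, "new", m.beta_deg))
    df = pd.DataFrame(
        rows, columns=["subject_id", "observer", "occasion", "method", "angle_deg"]
    )
    return MeasurementTable(df)
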