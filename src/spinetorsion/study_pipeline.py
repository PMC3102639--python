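"""The full study analysis: summary statistics, paired comparison, correlations.

Given per-subject angle measurements (and optionally subject metadata and a
repeated-measurement table), this module reproduces the analysis a rotation
study reports: mean +/- sd of the anterior (beta) and posterior (alpha)
component rotations and of the torsional deformity tau = beta - alpha, a
paired comparison of the two methods, Pearson correlations of tau with each
rotation and with the coronal Cobb angle, and the reliability tables.

The paired test is the default reading of the method comparison — both
methods are applied to the same vertebrae, so pairing is the defensible
choice; the unpaired variant is available via ``paired=False``. All tests
are two-sided; p < 0.05 is flagged as significant.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotations_io import MeasurementTable
from .errors import DegenerateDataError, ParameterError
from .reliability_stats import ICCResult, interobserver_icc, intraobserver_icc

__all__ = ["CorrelationResult", "StudyReport", "pearson_r", "paired_t_test",
           "run_study"]

SIGNIFICANCE_LEVEL = 0.05


def _near_constant(v: np.ndarray) -> bool:
    # constant up to floating-point jitter (e.g. an sd-0 simulated quantity
    # measured back through the geometry) carries no usable variance
    return np.ptp(v) <= 1e-9 * max(1.0, float(np.abs(v).max()))


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided p (t-transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ParameterError(f"need >= 3 pairs, got {len(x)}")
    if _near_constant(x) or _near_constant(y):
        raise DegenerateDataError("constant vector: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def paired_t_test(x, y) -> tuple[float, float]:
    """Two-sided paired t-test on x - y.

    Identical vectors return (0.0, 1.0) — no evidence of any difference.
    A nonzero constant difference has zero variance and no finite statistic,
    and raises instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D vectors of equal length")
    if len(x) < 2:
        raise ParameterError(f"need >= 2 pairs, got {len(x)}")
    d = x - y
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        raise DegenerateDataError(
            "differences are a nonzero constant: zero variance, t undefined"
        )
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < SIGNIFICANCE_LEVEL


@dataclass
class StudyReport:
    """Aggregate results of one study run.

    Angles in degrees; ``mean_torsion`` equals ``mean_beta - mean_alpha``
    exactly (linearity of the mean on unrounded values). Correlations that
    could not be computed are absent, with the reason in ``skipped``.
    """

    n: int
    mean_beta: float
    sd_beta: float
    mean_alpha: float
    sd_alpha: float
    mean_torsion: float
    sd_torsion: float
    t_statistic: float
    t_pvalue: float
    paired: bool
    r_torsion_beta: CorrelationResult | None = None
    r_torsion_alpha: CorrelationResult | None = None
    r_torsion_cobb: CorrelationResult | None = None
    icc_tables: dict | None = None
    skipped: dict = field(default_factory=dict)

    @property
    def methods_differ_significantly(self) -> bool:
        return self.t_pvalue < SIGNIFICANCE_LEVEL

    def to_dict(self) -> dict:
        def corr(c):
            return None if c is None else {"r": c.r, "p": c.p}

        def icc(res: ICCResult):
            return {
                "estimate": res.estimate,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "model": res.model_label,
            }

        out = {
            "n": self.n,
            "rotation_new_deg": {"mean": self.mean_beta, "sd": self.sd_beta},
            "rotation_ho_deg": {"mean": self.mean_alpha, "sd": self.sd_alpha},
            "torsion_deg": {"mean": self.mean_torsion, "sd": self.sd_torsion},
            "method_comparison": {
                "test": "paired t" if self.paired else "unpaired t",
                "t": self.t_statistic,
                "p": self.t_pvalue,
            },
            "r_torsion_beta": corr(self.r_torsion_beta),
            "r_torsion_alpha": corr(self.r_torsion_alpha),
            "r_torsion_cobb": corr(self.r_torsion_cobb),
            "skipped": dict(self.skipped),
        }
        if self.icc_tables is not None:
            out["icc"] = {
                method: {
                    "intraobserver": {
                        str(obs): icc(res)
                        for obs, res in tables["intraobserver"].items()
                    },
                    "interobserver": icc(tables["interobserver"]),
                }
                for method, tables in self.icc_tables.items()
            }
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_text(self) -> str:
        """Results-style summary: angles to 0.1 deg, r to 2 dp, p to 3 dp."""
        lines = [
            f"n = {self.n} subjects",
            f"Rotation, new method (anterior component): "
            f"{self.mean_beta:.1f} +/- {self.sd_beta:.1f} deg",
            f"Rotation, Ho's method (posterior component): "
            f"{self.mean_alpha:.1f} +/- {self.sd_alpha:.1f} deg",
            f"Torsional deformity (beta - alpha): "
            f"{self.mean_torsion:.1f} +/- {self.sd_torsion:.1f} deg",
            f"Method comparison ({'paired' if self.paired else 'unpaired'} t): "
            f"t = {self.t_statistic:.2f}, p = {self.t_pvalue:.3f}"
            f"{' *' if self.methods_differ_significantly else ''}",
        ]
        for label, corr in (
            ("torsion vs anterior rotation", self.r_torsion_beta),
            ("torsion vs posterior rotation", self.r_torsion_alpha),
            ("torsion vs Cobb angle", self.r_torsion_cobb),
        ):
            if corr is not None:
                lines.append(
                    f"Correlation {label}: r = {corr.r:.2f}, "
                    f"p = {corr.p:.3f}{' *' if corr.significant else ''}"
                )
        for key, reason in self.skipped.items():
            lines.append(f"Skipped {key}: {reason}")
        if self.icc_tables is not None:
            lines.append("")
            for method, tables in self.icc_tables.items():
                name = "New method" if method == "new" else "Ho's method"
                lines.append(f"ICC, {name}:")
                for obs, res in tables["intraobserver"].items():
                    lines.append(f"  observer {obs}: {res}")
                lines.append(f"  interobserver: {tables['interobserver']}")
        lines.append("(* p < 0.05)")
        return "\n".join(lines)


def run_study(
    measurements: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    measurement_table: MeasurementTable | None = None,
    paired: bool = True,
    occasion_policy: str = "first",
) -> StudyReport:
    """Run the full analysis on per-subject angle measurements.

    ``measurements`` needs columns subject_id, alpha_deg, beta_deg (one row
    per subject; torsion is derived). ``metadata`` may supply cobb_angle_deg
    per subject_id; the Cobb correlation is skipped when absent. A
    ``measurement_table`` attaches the reliability (ICC) tables.

    Degenerate correlation inputs do not abort the run: the affected entry
    is recorded under ``skipped`` and the rest of the report is produced.
    """
    df = measurements
    for col in ("subject_id", "alpha_deg", "beta_deg"):
        if col not in df.columns:
            raise ParameterError(f"measurements missing column {col!r}")
    if len(df) < 3:
        raise ParameterError(f"need >= 3 subjects, got {len(df)}")
    if df["subject_id"].duplicated().any():
        raise ParameterError("duplicate subject_id in measurements")

    alpha = df["alpha_deg"].to_numpy(dtype=float)
    beta = df["beta_deg"].to_numpy(dtype=float)
    tau = beta - alpha
    skipped: dict[str, str] = {}

    t_stat, t_p = (
        paired_t_test(beta, alpha)
        if paired
        else _unpaired(beta, alpha)
    )

    def try_corr(key, x, y):
        try:
            r, p = pearson_r(x, y)
            return CorrelationResult(r, p)
        except DegenerateDataError as err:
            skipped[key] = str(err)
            return None

    r_tb = try_corr("r_torsion_beta", tau, beta)
    r_ta = try_corr("r_torsion_alpha", tau, alpha)

    r_tc = None
    if metadata is not None and "cobb_angle_deg" in metadata.columns:
        merged = df.merge(
            metadata[["subject_id", "cobb_angle_deg"]], on="subject_id", how="left"
        )
        cobb = merged["cobb_angle_deg"].to_numpy(dtype=float)
        if np.isnan(cobb).any():
            skipped["r_torsion_cobb"] = "Cobb angle missing for some subjects"
        else:
            tau_m = (merged["beta_deg"] - merged["alpha_deg"]).to_numpy(dtype=float)
            r_tc = try_corr("r_torsion_cobb", tau_m, cobb)
    else:
        skipped["r_torsion_cobb"] = "no Cobb angles supplied"

    icc_tables = None
    if measurement_table is not None:
        icc_tables = {
            method: {
                "intraobserver": intraobserver_icc(measurement_table, method),
                "interobserver": interobserver_icc(
                    measurement_table, method, occasion_policy
                ),
            }
            for method in ("new", "ho")
        }

    return StudyReport(
        n=len(df),
        mean_beta=float(beta.mean()),
        sd_beta=float(beta.std(ddof=1)),
        mean_alpha=float(alpha.mean()),
        sd_alpha=float(alpha.std(ddof=1)),
        mean_torsion=float(beta.mean()) - float(alpha.mean()),
        sd_torsion=float(tau.std(ddof=1)),
        t_statistic=t_stat,
        t_pvalue=t_p,
        paired=paired,
        r_torsion_beta=r_tb,
        r_torsion_alpha=r_ta,
        r_torsion_cobb=r_tc,
        icc_tables=icc_tables,
        skipped=skipped,
    )


def _unpaired(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise DegenerateDataError("both samples constant: t undefined")
    res = stats.ttest_ind(x, y)
    t, p = float(res.statistic), float(res.pvalue)
    if not (math.isfinite(t) and math.isfinite(p)):
        raise DegenerateDataError("unpaired t undefined for these samples")
    return t, p
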