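"""Intra- and interobserver reliability via the intraclass correlation.

The ICC variant is the two-way random-effects, absolute-agreement,
single-measurement form — ICC(2,1) in Shrout-Fleiss terms, ICC(A,1) in
McGraw-Wong terms — computed from the two-way ANOVA mean squares with rows
as subjects and columns as raters (interobserver) or occasions
(intraobserver):

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

with the standard F-distribution 95% confidence interval. The crossed study
design (every observer rates every subject on every occasion) and the
clinical requirement of absolute agreement motivate the choice; every
result carries a model label so the variant is auditable.

Negative estimates are reported as computed, with a warning, rather than
truncated to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import f as f_dist

from .annotations_io import MeasurementTable
from .errors import DegenerateDataError, IncompleteDesignError, ParameterError

__all__ = ["ICCResult", "icc_single", "intraobserver_icc", "interobserver_icc",
           "format_reliability_tables"]

_MODEL_LABEL = "two-way random, absolute agreement, single measurement"


@dataclass(frozen=True)
class ICCResult:
    """An ICC estimate with its 95% confidence interval and provenance."""

    estimate: float
    ci_low: float
    ci_high: float
    model_label: str
    n_subjects: int
    n_raters_or_occasions: int

    def __str__(self) -> str:
        return f"{self.estimate:.2f} ({self.ci_low:.2f}-{self.ci_high:.2f})"


def icc_single(ratings: np.ndarray) -> ICCResult:
    """ICC(2,1) of an n_subjects x k ratings matrix, with 95% CI.

    Requires n >= 3 subjects, k >= 2 columns, no missing cells, and
    non-degenerate total variance.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ParameterError("ratings must be a 2-D matrix (subjects x columns)")
    n, k = x.shape
    if n < 3:
        raise IncompleteDesignError(f"need >= 3 subjects, got {n}")
    if k < 2:
        raise IncompleteDesignError(f"need >= 2 columns, got {k}")
    if not np.isfinite(x).all():
        raise IncompleteDesignError("ratings contain missing or non-finite cells")

    grand = x.mean()
    sst = float(((x - grand) ** 2).sum())
    if sst <= 1e-12 * max(1.0, grand**2):
        raise DegenerateDataError("zero total variance in ratings")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sse = max(sst - ssr - ssc, 0.0)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if icc < 0:
        warnings.warn(
            f"negative ICC estimate {icc:.3f}; reported as computed",
            stacklevel=2,
        )

    ci_low, ci_high = _icc2_ci(icc, msr, msc, mse, n, k, alpha=0.05)
    # numerical safety only: the interval must bracket the point estimate
    ci_low = min(ci_low, icc)
    ci_high = max(ci_high, icc)
    return ICCResult(
        estimate=float(icc),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        model_label=_MODEL_LABEL,
        n_subjects=n,
        n_raters_or_occasions=k,
    )


def _icc2_ci(icc: float, msr: float, msc: float, mse: float, n: int, k: int,
             alpha: float) -> tuple[float, float]:
    """McGraw-Wong F-based CI for ICC(A,1).

    When MSE = 0 (exact agreement up to a column shift) the Satterthwaite
    degrees of freedom are taken in their fj -> infinity limit,
    v = (n-1)(k-1), which keeps the bounds finite.
    """
    if mse > 0:
        fj = msc / mse
        a = k * icc * fj + n * (1 + (k - 1) * icc) - k * icc
        vn = (k - 1) * (n - 1) * a**2
        vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
        v = vn / vd
    else:
        v = (n - 1) * (k - 1)
    f2u = f_dist.ppf(1 - alpha / 2, n - 1, v)
    f2l = f_dist.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f2u * mse) / (
        f2u * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f2l * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f2l * msr
    )
    return lower, upper


def _pivot(table: MeasurementTable, method: str, index: str, columns: str,
           values_filter: dict | None = None) -> np.ndarray:
    df = table.data
    if method not in ("ho", "new"):
        raise ParameterError(f"unknown method {method!r}")
    df = df[df["method"] == method]
    if values_filter:
        for col, val in values_filter.items():
            df = df[df[col] == val]
    wide = df.pivot_table(index=index, columns=columns, values="angle_deg",
                          aggfunc="mean", dropna=False)
    if wide.isna().any().any():
        raise IncompleteDesignError(
            f"incomplete design: missing ({index}, {columns}) cells for method "
            f"{method!r}"
        )
    return wide.to_numpy()


def intraobserver_icc(table: MeasurementTable, method: str) -> dict:
    """Test-retest ICC per observer: subjects x occasions matrices.

    Returns {observer_label: ICCResult}. Requires every (subject, observer)
    to share the same set of >= 2 occasions.
    """
    df = table.data
    out = {}
    for observer in sorted(df["observer"].unique(), key=str):
        sub = df[(df["observer"] == observer) & (df["method"] == method)]
        occasions = sub["occasion"].unique()
        if len(occasions) < 2:
            raise IncompleteDesignError(
                f"observer {observer!r}: fewer than 2 occasions"
            )
        try:
            matrix = _pivot(table, method, "subject_id", "occasion",
                            {"observer": observer})
            out[observer] = icc_single(matrix)
        except (IncompleteDesignError, DegenerateDataError) as err:
            raise type(err)(f"observer {observer!r}: {err}") from err
    return out


def interobserver_icc(
    table: MeasurementTable, method: str, occasion_policy: str = "first"
) -> ICCResult:
    """Between-observer ICC: subjects x observers matrix.

    ``occasion_policy`` selects what each observer contributes per subject:
    ``"first"`` the first occasion (smallest occasion label), ``"mean"`` the
    average over occasions.
    """
    if occasion_policy not in ("first", "mean"):
        raise ParameterError(
            f"occasion_policy must be 'first' or 'mean', got {occasion_policy!r}"
        )
    df = table.data[table.data["method"] == method]
    if occasion_policy == "first":
        first = sorted(df["occasion"].unique(), key=str)[0]
        matrix = _pivot(table, method, "subject_id", "observer",
                        {"occasion": first})
    else:
        matrix = _pivot(table, method, "subject_id", "observer")
    return icc_single(matrix)


def format_reliability_tables(table: MeasurementTable,
                              occasion_policy: str = "first") -> str:
    """Plain-text reliability tables: per-observer rows then the interobserver row."""
    lines = ["Reliability (ICC, 95% CI)",
             f"model: {_MODEL_LABEL}", ""]
    for method, label in (("new", "New method"), ("ho", "Ho's method")):
        lines.append(f"{label}:")
        intra = intraobserver_icc(table, method)
        for observer, res in intra.items():
            lines.append(
                f"  observer {observer} (N = {res.n_subjects}): {res}"
            )
        inter = interobserver_icc(table, method, occasion_policy)
        lines.append(f"  interobserver (N = {inter.n_subjects}): {inter}")
        lines.append("")
    return "\n".join(lines)
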