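"""Enzyme-inhibition quantification from 96-well plate absorbances.

Percent inhibition is computed from mean absorbances as

    inhibition = (A0 - AI) / A0

where A0 is the mean absorbance of zero-inhibitor wells and AI the mean
absorbance of the sample (standard inhibitor or SPE fraction) wells.
Dose-response curves are fitted with linear, loglinear (linear in log10
dose) or quadratic least squares; fit adequacy is judged by the mean
percent relative error (MRE) between measured and back-calculated
inhibition, and the model with minimal MRE is selected (ties broken toward
the simpler model). IC50 is the dose at which the fitted curve crosses 50%
inhibition, interpolated within the fitted dose range — a curve that never
reaches 50% in range raises a distinct undefined-IC50 error rather than
extrapolating. Relative potency of a fraction against a standard inhibitor
is reported as 100 x IC50(standard) / IC50(fraction), so a fraction
needing more material than the standard scores below 100%.

Inhibition values outside [0, 1] are retained, not clipped: negative
values signal activation or assay problems and must affect the MRE
honestly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PlateMeasurement",
    "DoseResponseFit",
    "UndefinedIC50Error",
    "percent_inhibition",
    "fit_dose_response",
    "select_model",
    "ic50",
    "relative_inhibition",
    "significance_flag",
    "inhibition_curve",
    "analyze_plate",
]

Model = Literal["linear", "loglinear", "quadratic"]

#: Simplicity order used for tie-breaking in model selection.
MODEL_ORDER: tuple[Model, ...] = ("linear", "loglinear", "quadratic")

#: Measured inhibition values below this magnitude are excluded from the
#: relative-error mean (relative error is undefined at zero).
_MRE_EPS = 1e-12


class UndefinedIC50Error(ValueError):
    """The fitted curve does not attain 50% inhibition within the dose range."""


@dataclass(frozen=True)
class PlateMeasurement:
    """One well: enzyme, sample id, dose, absorbance, replicate index."""

    enzyme: str
    sample: str
    dose: float
    absorbance: float
    replicate: int = 0

    def __post_init__(self):
        if self.absorbance < 0:
            raise ValueError("absorbance must be non-negative")
        if self.dose < 0:
            raise ValueError("dose must be non-negative")


@dataclass(frozen=True)
class DoseResponseFit:
    """A fitted dose-response curve and its diagnostics."""

    model: Model
    coefficients: tuple[float, ...]  # highest order first (polyfit convention)
    mre: float  # mean percent relative error, %
    n_points: int
    dose_range: tuple[float, float]

    def predict(self, dose) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        x = np.log10(dose) if self.model == "loglinear" else dose
        return np.polyval(self.coefficients, x)


def percent_inhibition(a0: float, ai: float) -> float:
    """(A0 - AI) / A0; negative values (activation) are returned as-is."""
    if a0 <= 0:
        raise ValueError(f"zero-inhibitor absorbance must be positive, got {a0}")
    return (a0 - ai) / a0


def _mean_percent_relative_error(y: np.ndarray, yhat: np.ndarray) -> float:
    mask = np.abs(y) > _MRE_EPS
    if not mask.any():
        resid = np.max(np.abs(y - yhat))
        return 0.0 if resid < 1e-12 else math.inf
    return float(np.mean(np.abs((y[mask] - yhat[mask]) / y[mask])) * 100.0)


def fit_dose_response(
    points: Sequence[tuple[float, float]], model: Model
) -> DoseResponseFit:
    """Least-squares fit of inhibition on dose under the given model."""
    if len(points) < 3:
        raise ValueError(f"need at least 3 points, got {len(points)}")
    doses = np.array([d for d, _ in points], dtype=float)
    y = np.array([v for _, v in points], dtype=float)
    if model == "linear":
        coeffs = np.polyfit(doses, y, 1)
        x = doses
    elif model == "loglinear":
        if np.any(doses <= 0):
            raise ValueError("loglinear model requires strictly positive doses")
        x = np.log10(doses)
        coeffs = np.polyfit(x, y, 1)
    elif model == "quadratic":
        coeffs = np.polyfit(doses, y, 2)
        x = doses
    else:
        raise ValueError(f"unknown model: {model!r}")
    yhat = np.polyval(coeffs, x)
    return DoseResponseFit(
        model=model,
        coefficients=tuple(float(c) for c in coeffs),
        mre=_mean_percent_relative_error(y, yhat),
        n_points=len(points),
        dose_range=(float(doses.min()), float(doses.max())),
    )


def select_model(points: Sequence[tuple[float, float]]) -> DoseResponseFit:
    """Fit all applicable models and return the one with minimal MRE.

    A more complex model must beat the incumbent by more than a numerical
    epsilon, so exact ties resolve to the simpler model.
    """
    if len(points) < 4:
        raise ValueError(f"model selection needs at least 4 points, got {len(points)}")
    doses = [d for d, _ in points]
    best: DoseResponseFit | None = None
    for model in MODEL_ORDER:
        if model == "loglinear" and min(doses) <= 0:
            continue
        fit = fit_dose_response(points, model)
        if best is None or fit.mre < best.mre - 1e-9:
            best = fit
    assert best is not None
    return best


def ic50(fit: DoseResponseFit, allow_extrapolation: bool = False) -> float:
    """Dose at which the fitted curve predicts 50% inhibition.

    Interpolation only by default; for a quadratic with two in-range roots
    the smaller dose is returned.
    """
    lo, hi = fit.dose_range
    slack = 1e-9 * max(hi - lo, 1.0)

    def in_range(d: float) -> bool:
        return allow_extrapolation or (lo - slack <= d <= hi + slack)

    if fit.model in ("linear", "loglinear"):
        a, b = fit.coefficients
        if a == 0:
            raise UndefinedIC50Error("flat curve never reaches 50% inhibition")
        x = (0.5 - b) / a
        dose = 10.0**x if fit.model == "loglinear" else x
        if dose > 0 and in_range(dose):
            return float(dose)
        raise UndefinedIC50Error(
            f"50% crossing at dose {dose:.4g} lies outside the fitted range {lo:.4g}-{hi:.4g}"
        )
    a2, a1, a0 = fit.coefficients
    roots = np.roots([a2, a1, a0 - 0.5])
    real = [float(r.real) for r in roots if abs(r.imag) < 1e-9]
    candidates = sorted(d for d in real if d > 0 and in_range(d))
    if not candidates:
        raise UndefinedIC50Error(
            f"quadratic curve does not cross 50% inside {lo:.4g}-{hi:.4g}"
        )
    return candidates[0]


def relative_inhibition(
    ic50_fraction: float,
    ic50_standard: float,
    direction: Literal["standard_over_fraction", "fraction_over_standard"] = "standard_over_fraction",
) -> float:
    """Relative potency in percent.

    Default convention: 100 x IC50(standard) / IC50(fraction). The reversed
    convention is available because either reading of a ratio-of-IC50s
    statistic is defensible; output headers state which one is in force.
    """
    if ic50_fraction <= 0 or ic50_standard <= 0:
        raise ValueError("IC50 values must be positive")
    if direction == "standard_over_fraction":
        return 100.0 * ic50_standard / ic50_fraction
    return 100.0 * ic50_fraction / ic50_standard


def significance_flag(
    groups: Mapping[str, Sequence[float]],
) -> dict[str, bool | None]:
    """Flag groups whose mean inhibition is outside the 95% CI of the
    across-group mean (t-based, built from the group means).

    Groups with fewer than two replicate values get None (undefined), as
    does everything when fewer than two valid groups exist (no reference
    distribution).
    """
    means = {
        name: float(np.mean(vals)) if len(vals) >= 2 else None
        for name, vals in groups.items()
    }
    valid = [m for m in means.values() if m is not None]
    if len(valid) < 2:
        return {name: None for name in groups}
    grand = float(np.mean(valid))
    sd = float(np.std(valid, ddof=1))
    half_width = stats.t.ppf(0.975, len(valid) - 1) * sd / math.sqrt(len(valid))
    return {
        name: (None if m is None else bool(abs(m - grand) > half_width))
        for name, m in means.items()
    }


# ---------------------------------------------------------------------------
# Plate-level convenience

ZERO_SAMPLE = "zero_inhibitor"
NEGATIVE_CONTROL = "negative_control"


def inhibition_curve(
    measurements: Iterable[PlateMeasurement], enzyme: str, sample: str
) -> list[tuple[float, float]]:
    """(dose, inhibition) points for one sample, from mean well absorbances."""
    wells = [m for m in measurements if m.enzyme == enzyme]
    zeros = [m.absorbance for m in wells if m.sample == ZERO_SAMPLE]
    if not zeros:
        raise ValueError(f"no zero-inhibitor wells for enzyme {enzyme!r}")
    a0 = float(np.mean(zeros))
    by_dose: dict[float, list[float]] = {}
    for m in wells:
        if m.sample == sample:
            by_dose.setdefault(m.dose, []).append(m.absorbance)
    return [
        (dose, percent_inhibition(a0, float(np.mean(vals))))
        for dose, vals in sorted(by_dose.items())
    ]


def analyze_plate(
    measurements: Sequence[PlateMeasurement],
    standard: str,
    direction: Literal["standard_over_fraction", "fraction_over_standard"] = "standard_over_fraction",
) -> pd.DataFrame:
    """Full plate analysis: per (enzyme, sample) model selection, IC50,
    relative potency against the standard, and the significance flag.

    Returns a table with columns enzyme, sample, model, ic50, mre,
    relative_inhibition_pct, significant. Samples whose curve never
    reaches 50% get NaN IC50 and relative potency.
    """
    rows = []
    enzymes = sorted({m.enzyme for m in measurements})
    for enzyme in enzymes:
        samples = sorted(
            {
                m.sample
                for m in measurements
                if m.enzyme == enzyme and m.sample not in (ZERO_SAMPLE, NEGATIVE_CONTROL)
            }
        )
        groups = {}
        fits: dict[str, DoseResponseFit | None] = {}
        ic50s: dict[str, float] = {}
        for sample in samples:
            curve = inhibition_curve(measurements, enzyme, sample)
            groups[sample] = [v for _, v in curve]
            try:
                fit = select_model(curve)
                fits[sample] = fit
                ic50s[sample] = ic50(fit)
            except (ValueError, UndefinedIC50Error):
                fits[sample] = fits.get(sample)
                ic50s[sample] = float("nan")
        flags = significance_flag(groups)
        std_ic50 = ic50s.get(standard, float("nan"))
        for sample in samples:
            fit = fits.get(sample)
            value = ic50s[sample]
            rel = (
                relative_inhibition(value, std_ic50, direction)
                if sample != standard
                and math.isfinite(value)
                and math.isfinite(std_ic50)
                else float("nan")
            )
            rows.append(
                {
                    "enzyme": enzyme,
                    "sample": sample,
                    "model": fit.model if fit else "",
                    "ic50": value,
                    "mre": fit.mre if fit else float("nan"),
                    f"relative_inhibition_pct_{direction}": rel,
                    "significant": flags.get(sample),
                }
            )
    return pd.DataFrame(rows)
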