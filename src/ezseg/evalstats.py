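"""Agreement statistics between two EZ measurement series.

Implements the evaluation toolkit used to compare automatic and manual
EZ measurements: Sørensen–Dice similarity of binary presence maps, an
analytic fixed-shift model of the Dice coefficient between two
equal-size circles, Pearson correlation with Fisher-z 95% CI, ordinary
least-squares regression with t-based 95% CIs, Bland–Altman statistics
(mean difference, SD, SE, coefficient of repeatability = 1.96*SD,
limits of agreement, mean absolute error) and the ETDRS-derived EZ
size subgroups.

Sign convention: differences are model minus reference, so a positive
mean difference is overestimation by the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats


class DegenerateInputError(ValueError):
    """Raised for inputs on which a statistic is undefined."""


# ---------------------------------------------------------------------------
# Dice similarity
# ---------------------------------------------------------------------------

def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Sørensen–Dice coefficient 2|A∩B| / (|A|+|B|) of two binary maps.

    Both maps empty is undefined and raises; callers must decide how to
    treat absent-EZ scans.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        raise DegenerateInputError("Dice undefined: both maps empty")
    return 2.0 * int((a & b).sum()) / denom


# ---------------------------------------------------------------------------
# fixed-shift two-circle model of the Dice coefficient
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShiftModelParams:
    """Lateral shift d (mm) between two equal circles of area A (mm^2)."""

    shift_mm: float
    area_mm2: float

    def __post_init__(self):
        if self.shift_mm < 0:
            raise ValueError("shift must be >= 0")
        if self.area_mm2 <= 0:
            raise ValueError("area must be > 0")


def fixed_shift_dsc(params: ShiftModelParams) -> float:
    """Dice coefficient of two equal circles at a fixed lateral shift.

    With r = sqrt(A/pi) and centre distance d, the lens-shaped
    intersection area is 2 r^2 arccos(d / 2r) - (d/2) sqrt(4 r^2 - d^2);
    the Dice coefficient is that area divided by one circle's area
    (intersection/area equals 2I/(A+A)).  Returns 1 at d = 0 and 0 once
    d >= 2r (disjoint or tangent circles).
    """
    d, area = params.shift_mm, params.area_mm2
    if d == 0:
        return 1.0
    r = math.sqrt(area / math.pi)
    if d >= 2 * r:
        return 0.0
    lens = 2 * r * r * math.acos(d / (2 * r)) - (d / 2) * math.sqrt(4 * r * r - d * d)
    return lens / (math.pi * r * r)


def fixed_shift_curve(shift_mm: float, areas_mm2: np.ndarray) -> np.ndarray:
    """The model's Dice-vs-area curve at one fixed shift."""
    return np.array([fixed_shift_dsc(ShiftModelParams(shift_mm, a))
                     for a in np.asarray(areas_mm2, dtype=float)])


# ---------------------------------------------------------------------------
# correlation and regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    n: int
    r: float
    r_ci: tuple[float, float]
    r2: float
    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    intercept_ci: tuple[float, float]


def correlation_regression(x, y, alpha: float = 0.05) -> RegressionResult:
    """Pearson r (Fisher-z CI) and OLS y-on-x fit (t-based CIs, df=n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise DegenerateInputError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input series")
    r = float(stats.pearsonr(x, y).statistic)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se_z = 1.0 / math.sqrt(n - 3) if n > 3 else np.inf
    r_ci = (float(np.tanh(z - zcrit * se_z)), float(np.tanh(z + zcrit * se_z)))
    fit = stats.linregress(x, y)
    tcrit = stats.t.ppf(1 - alpha / 2, df=n - 2)
    slope_ci = (fit.slope - tcrit * fit.stderr, fit.slope + tcrit * fit.stderr)
    icept_ci = (fit.intercept - tcrit * fit.intercept_stderr,
                fit.intercept + tcrit * fit.intercept_stderr)
    return RegressionResult(n=n, r=r, r_ci=r_ci, r2=r * r,
                            slope=float(fit.slope),
                            slope_ci=(float(slope_ci[0]), float(slope_ci[1])),
                            intercept=float(fit.intercept),
                            intercept_ci=(float(icept_ci[0]), float(icept_ci[1])))


# ---------------------------------------------------------------------------
# Bland–Altman
# ---------------------------------------------------------------------------

@dataclass
class BlandAltmanResult:
    n: int
    mean_diff: float
    sd_diff: float              # sample SD, n-1 denominator
    se_diff: float              # SD / sqrt(n)
    cor: float                  # coefficient of repeatability = 1.96 * SD
    limits: tuple[float, float]  # mean_diff -+ CoR
    mean_abs_error: float
    sd_abs_error: float


def bland_altman(model, reference) -> BlandAltmanResult:
    """Bland–Altman statistics of differences (model minus reference)."""
    x = np.asarray(model, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D of equal length")
    n = x.size
    if n < 2:
        raise DegenerateInputError("need n >= 2")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    cor = 1.96 * sd
    return BlandAltmanResult(n=n, mean_diff=mean, sd_diff=sd,
                             se_diff=sd / math.sqrt(n), cor=cor,
                             limits=(mean - cor, mean + cor),
                             mean_abs_error=float(np.abs(d).mean()),
                             sd_abs_error=float(np.abs(d).std(ddof=1)))


# ---------------------------------------------------------------------------
# EZ size subgroups (ETDRS-derived cuts)
# ---------------------------------------------------------------------------

SUBGROUP_EDGES = (1.0, 7.0, 30.0)   # mm^2; central subfield / inner / outer ring


def subgroup_label(area_mm2: float) -> str:
    """EZ size subgroup: <1 very_small, [1,7) small, [7,30) medium, >=30 large."""
    if area_mm2 < 0:
        raise ValueError("area must be >= 0")
    if area_mm2 < SUBGROUP_EDGES[0]:
        return "very_small"
    if area_mm2 < SUBGROUP_EDGES[1]:
        return "small"
    if area_mm2 < SUBGROUP_EDGES[2]:
        return "medium"
    return "large"


def macular_circle_area(radius_mm: float) -> float:
    """Area of a macular reference circle (e.g. radius 3 mm -> 28.3 mm^2)."""
    if radius_mm < 0:
        raise ValueError("radius must be >= 0")
    return math.pi * radius_mm ** 2


# ---------------------------------------------------------------------------
# combined report
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    dice_per_scan: list[float]
    regression: RegressionResult
    bland_altman: BlandAltmanResult

    def to_dict(self) -> dict:
        return {"dice_per_scan": self.dice_per_scan,
                "dice_mean": (float(np.mean(self.dice_per_scan))
                              if self.dice_per_scan else None),
                "regression": asdict(self.regression),
                "bland_altman": asdict(self.bland_altman)}


def evaluate(model_areas, reference_areas,
             model_maps: list[np.ndarray] | None = None,
             reference_maps: list[np.ndarray] | None = None) -> EvalReport:
    """Full agreement report between model and reference EZ measurements."""
    dices = []
    if model_maps is not None and reference_maps is not None:
        if len(model_maps) != len(reference_maps):
            raise ValueError("map lists must pair up")
        dices = [dice(a, b) for a, b in zip(model_maps, reference_maps)]
    return EvalReport(dice_per_scan=dices,
                      regression=correlation_regression(model_areas, reference_areas),
                      bland_altman=bland_altman(model_areas, reference_areas))
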