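"""Method-comparison statistics and clinical indices.

Agreement between the automated and manual sizing methods is assessed
with Bland-Altman limits of agreement and paired t-tests; the strength of
each method's association with a common criterion variable is compared
with Meng's Z-test for correlated correlation coefficients.  The clinical
indices used in validation — HOMA-IR and the sex-specific visceral
adiposity index (VAI) — are provided as plain equations.

Differences are oriented automated − manual throughout (method_b −
method_a), so a method that reads systematically low yields negative
mean differences and limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedMeasurements",
    "AgreementResult",
    "ClinicalRecord",
    "bland_altman",
    "bland_altman_plot",
    "meng_z",
    "paired_t",
    "correlations",
    "homa_ir",
    "vai",
]

#: Conventional normal-quantile multiplier for 95% limits of agreement.
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class PairedMeasurements:
    """Per-sample mean diameters from two methods, aligned by sample."""

    sample_ids: tuple[str, ...]
    method_a: np.ndarray  # µm (e.g. manual)
    method_b: np.ndarray  # µm (e.g. automated)

    def __post_init__(self) -> None:
        a = np.asarray(self.method_a, dtype=np.float64)
        b = np.asarray(self.method_b, dtype=np.float64)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("method_a and method_b must be equal-length 1-D arrays")
        if len(self.sample_ids) != a.size:
            raise ValueError("sample_ids length must match the measurement arrays")
        object.__setattr__(self, "method_a", a)
        object.__setattr__(self, "method_b", b)

    @property
    def n(self) -> int:
        return self.method_a.size

    @property
    def differences(self) -> np.ndarray:
        """b − a per sample."""
        return self.method_b - self.method_a


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman mean difference and 95% limits of agreement (µm)."""

    mean_difference: float
    sd_difference: float
    loa_lower: float
    loa_upper: float


def bland_altman(pairs: PairedMeasurements) -> AgreementResult:
    """Bland-Altman agreement analysis of two paired methods.

    Limits of agreement are mean ± 1.96 × sample SD (n−1) of the
    per-sample differences b − a, symmetric about the mean difference by
    construction.
    """
    if pairs.n < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = pairs.differences
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    half = LOA_MULTIPLIER * sd
    return AgreementResult(
        mean_difference=mean, sd_difference=sd, loa_lower=mean - half, loa_upper=mean + half
    )


def bland_altman_plot(pairs: PairedMeasurements, path: str) -> AgreementResult:
    """Write the difference-vs-average plot with mean and limit lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = bland_altman(pairs)
    avg = (pairs.method_a + pairs.method_b) / 2.0
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(avg, pairs.differences, s=18, alpha=0.7, edgecolor="none")
    for y, style, label in (
        (res.mean_difference, "-", f"mean {res.mean_difference:.2f}"),
        (res.loa_upper, "--", f"+1.96 SD {res.loa_upper:.2f}"),
        (res.loa_lower, "--", f"−1.96 SD {res.loa_lower:.2f}"),
    ):
        ax.axhline(y, linestyle=style, color="grey")
        ax.annotate(label, (0.99, y), xycoords=("axes fraction", "data"),
                    ha="right", va="bottom", fontsize=8)
    ax.set_xlabel("average of methods (µm)")
    ax.set_ylabel("difference, automated − manual (µm)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return res


def meng_z(r1: float, r2: float, r12: float, n: int) -> tuple[float, float]:
    """Meng's Z-test for two correlated correlation coefficients.

    ``r1`` and ``r2`` are the correlations of two predictors with one
    common criterion, ``r12`` the correlation between the predictors, and
    ``n`` the sample count.  Both correlations are Fisher z-transformed;
    with r̄² = (r1² + r2²)/2, f = min(1, (1 − r12)/(2(1 − r̄²))) and
    h = (1 − f·r̄²)/(1 − r̄²),

        Z = (z1 − z2) · √((n − 3) / (2(1 − r12)·h)),

    referred to the standard normal for a two-sided p.
    """
    for name, r in (("r1", r1), ("r2", r2), ("r12", r12)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} must lie strictly inside (−1, 1), got {r}")
    if n <= 3:
        raise ValueError(f"Meng's Z needs n > 3, got {n}")
    z1 = math.atanh(r1)
    z2 = math.atanh(r2)
    r_sq_bar = (r1 * r1 + r2 * r2) / 2.0
    f = min(1.0, (1.0 - r12) / (2.0 * (1.0 - r_sq_bar)))
    h = (1.0 - f * r_sq_bar) / (1.0 - r_sq_bar)
    z = (z1 - z2) * math.sqrt((n - 3) / (2.0 * (1.0 - r12) * h))
    p = 2.0 * sps.norm.sf(abs(z))
    return z, float(p)


def paired_t(pairs: PairedMeasurements) -> tuple[float, float, float]:
    """Paired t-test on the per-sample differences (two-sided).

    Returns ``(t, p, mean_difference)``.  Degenerate zero-variance
    differences are handled by convention: all-zero differences give
    t = 0, p = 1; a constant nonzero difference gives a signed infinite
    t with p = 0, flagged in the return value rather than raising.
    """
    if pairs.n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = pairs.differences
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0, 0.0
        return math.copysign(math.inf, mean), 0.0, mean
    t, p = sps.ttest_rel(pairs.method_b, pairs.method_a)
    return float(t), float(p), mean


def correlations(pairs: PairedMeasurements, kind: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation of the two methods, with two-sided p."""
    if pairs.n < 3:
        raise ValueError("correlation needs at least 3 pairs")
    a, b = pairs.method_a, pairs.method_b
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("correlation undefined for constant input")
    if kind == "pearson":
        r, p = sps.pearsonr(a, b)
    elif kind == "spearman":
        r, p = sps.spearmanr(a, b)
    else:
        raise ValueError("kind must be 'pearson' or 'spearman'")
    return float(r), float(p)


def homa_ir(fasting_insulin: float, fasting_glucose: float) -> float:
    """HOMA-IR: fasting insulin (µU/mL) × fasting glucose (mmol/L) / 22.5."""
    if fasting_insulin <= 0 or fasting_glucose <= 0:
        raise ValueError("insulin and glucose must be strictly positive")
    return fasting_insulin * fasting_glucose / 22.5


@dataclass(frozen=True)
class ClinicalRecord:
    """Inputs of the clinical index equations; units noted per field."""

    sex: str  # male | female
    waist_circumference: float  # cm
    bmi: float  # kg/m²
    tg: float  # triglycerides, mmol/L
    hdl: float  # HDL cholesterol, mmol/L
    fasting_insulin: float | None = None  # µU/mL
    fasting_glucose: float | None = None  # mmol/L


def vai(record: ClinicalRecord) -> float:
    """Visceral adiposity index with the validated sex-specific equations.

    male:   (WC / (39.68 + 1.88·BMI)) · (TG / 1.03) · (1.31 / HDL)
    female: (WC / (36.58 + 1.89·BMI)) · (TG / 0.81) · (1.52 / HDL)
    """
    for name, v in (
        ("waist_circumference", record.waist_circumference),
        ("bmi", record.bmi),
        ("tg", record.tg),
        ("hdl", record.hdl),
    ):
        if v is None or v <= 0:
            raise ValueError(f"{name} must be strictly positive")
    if record.sex == "male":
        return (
            record.waist_circumference
            / (39.68 + 1.88 * record.bmi)
            * (record.tg / 1.03)
            * (1.31 / record.hdl)
        )
    if record.sex == "female":
        return (
            record.waist_circumference
            / (36.58 + 1.89 * record.bmi)
            * (record.tg / 0.81)
            * (1.52 / record.hdl)
        )
    raise ValueError(f"sex must be 'male' or 'female', got {record.sex!r}")
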