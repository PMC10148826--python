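"""Single-cell quantitative mass-spectrometry math.

Electro-osmotic extraction from a single cell fills the conical tip of a
nanocapillary. The filled volume is modelled as a cone frustum: the tip
opening has radius ``a``, the cone half-angle (between the cone element and
the axis) is ``alpha``, and the aqueous meniscus sits at height ``h`` along
the axis. Downstream, analyte peak areas are normalized to a stable-isotope
internal standard, back-calculated through an external calibration curve,
corrected for batch effects with parametric empirical-Bayes (ComBat-style)
adjustment, and validated with intra-/inter-day precision metrics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ExtractionGeometry",
    "CalibrationCurve",
    "BatchedMatrix",
    "QuantResult",
    "PrecisionReport",
    "estimate_extraction_volume",
    "fit_calibration",
    "quantify_cell",
    "correct_batches",
    "precision_metrics",
]

#: RSD (%) threshold below which a precision run meets validation criteria.
PRECISION_RSD_LIMIT = 20.0


@dataclass(frozen=True)
class ExtractionGeometry:
    """Conical tip geometry of the extraction nanocapillary.

    Parameters
    ----------
    a : float
        Tip radius at the opening, micrometers.
    alpha : float
        Cone half-angle between the cone element and its axis, radians;
        must lie strictly between 0 and pi/2.
    h : float
        Meniscus height measured along the capillary axis, micrometers.
    """

    a: float
    alpha: float
    h: float

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"tip radius a must be positive, got {self.a}")
        if not 0 < self.alpha < math.pi / 2:
            raise ValueError(
                f"cone half-angle alpha must be in (0, pi/2), got {self.alpha}"
            )
        if self.h < 0:
            raise ValueError(f"meniscus height h must be >= 0, got {self.h}")

    @property
    def L(self) -> float:
        """Dimensionless meniscus height, ``h / a``."""
        return self.h / self.a


def estimate_extraction_volume(geometry: ExtractionGeometry) -> float:
    """Volume of the liquid cone frustum filled up to height ``h``, in fL.

    The frustum volume is

        V = (pi a^3 / (3 tan(alpha))) * ((1 + L tan(alpha))^3 - 1),  L = h/a

    i.e. the integral of the circular cross-section pi (a + x tan(alpha))^2
    from 0 to h. Micrometer inputs give the volume directly in femtoliters
    (1 um^3 == 1 fL). The expansion of (1+x)^3 - 1 is used to stay accurate
    in the slender-cone limit (tan(alpha) -> 0), where V -> pi a^2 h.
    """
    t = math.tan(geometry.alpha)
    x = geometry.L * t
    # (1+x)^3 - 1 == x*(3 + 3x + x^2), exact and cancellation-free
    return math.pi * geometry.a**3 / (3.0 * t) * (x * (3.0 + 3.0 * x + x * x))


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear calibration of analyte/internal-standard response ratio.

    ``lod`` and ``lloq`` follow the ICH blank-based convention
    (3.3 sigma_blank / slope and 10 sigma_blank / slope).
    """

    slope: float
    intercept: float
    r_squared: float
    lod: float
    lloq: float
    linear_range: tuple[float, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared must be in [0,1], got {self.r_squared}")
        if self.lod < 0 or self.lloq < self.lod:
            raise ValueError("require lloq >= lod >= 0")
        if self.linear_range[0] > self.linear_range[1]:
            raise ValueError("linear_range must be (low, high) with low <= high")


def fit_calibration(
    points: Sequence[tuple[float, float]], blank_sd: float = 0.0
) -> CalibrationCurve:
    """Fit an ordinary-least-squares calibration line to (conc, ratio) points.

    Parameters
    ----------
    points : sequence of (concentration, response-ratio) pairs
        Response is the analyte / internal-standard peak-area ratio.
    blank_sd : float
        Standard deviation of the blank response, used for LOD/LLOQ.

    Raises
    ------
    ValueError
        If fewer than 2 distinct concentrations are supplied, or if the
        fitted slope is not positive (non-quantitative assay).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (concentration, response) points")
    if blank_sd < 0:
        raise ValueError("blank_sd must be >= 0")
    conc, resp = pts[:, 0], pts[:, 1]
    if np.unique(conc).size < 2:
        raise ValueError("calibration requires >= 2 distinct concentrations")

    cbar, rbar = conc.mean(), resp.mean()
    sxx = np.sum((conc - cbar) ** 2)
    slope = float(np.sum((conc - cbar) * (resp - rbar)) / sxx)
    intercept = float(rbar - slope * cbar)
    if slope <= 0:
        raise ValueError(f"non-quantitative calibration: slope={slope:.4g} <= 0")

    ss_res = float(np.sum((resp - (slope * conc + intercept)) ** 2))
    ss_tot = float(np.sum((resp - rbar) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    lod = 3.3 * blank_sd / slope
    lloq = 10.0 * blank_sd / slope
    return CalibrationCurve(
        slope=slope,
        intercept=intercept,
        r_squared=max(0.0, min(1.0, r2)),
        lod=lod,
        lloq=lloq,
        linear_range=(lloq, float(conc.max())),
    )


@dataclass(frozen=True)
class QuantResult:
    """Back-calculated single-cell concentration with quality flag."""

    concentration: float  # mM, clamped to >= 0
    below_lloq: bool


def quantify_cell(
    analyte_signal: float,
    is_signal: float,
    is_concentration: float,
    curve: CalibrationCurve,
) -> QuantResult:
    """Back-calculate a cell's metabolite concentration from peak areas.

    The analyte peak area is normalized to the co-extracted internal
    standard, then inverted through the calibration line. Negative
    back-calculated values are clamped to 0 (concentrations are physical
    and downstream factorization requires non-negativity) and flagged.

    Raises
    ------
    ValueError
        If the internal standard was not detected (``is_signal == 0``):
        quantification is refused rather than silently returning zero.
    """
    if is_signal == 0:
        raise ValueError("internal standard signal is zero; quantification refused")
    if is_signal < 0 or analyte_signal < 0:
        raise ValueError("peak areas must be non-negative")
    if curve.slope <= 0:
        raise ValueError("calibration slope must be positive")
    if is_concentration <= 0:
        raise ValueError("internal-standard concentration must be positive")
    ratio = analyte_signal / is_signal
    conc = (ratio - curve.intercept) / curve.slope
    flagged = conc < curve.lloq
    if conc < 0:
        conc, flagged = 0.0, True
    return QuantResult(concentration=float(conc), below_lloq=bool(flagged))


@dataclass
class BatchedMatrix:
    """Positive samples x features matrix with a batch label per sample."""

    values: np.ndarray
    batch_labels: Sequence

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        labels = np.asarray(self.batch_labels)
        if labels.shape[0] != self.values.shape[0]:
            raise ValueError("one batch label required per sample")
        if np.any(~np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("values must be finite and strictly positive")
        self.batch_labels = labels

    @property
    def batches(self) -> list:
        return list(dict.fromkeys(self.batch_labels.tolist()))


def _eb_iterate(z, gamma_hat, delta_hat_sq, gamma_bar, tau_sq, a_prior, b_prior,
                max_iter=200, tol=1e-8):
    """Iterative solution of the ComBat empirical-Bayes posterior modes."""
    n = z.shape[0]
    gamma = gamma_hat.copy()
    delta_sq = delta_hat_sq.copy()
    for _ in range(max_iter):
        gamma_new = (n * tau_sq * gamma_hat + delta_sq * gamma_bar) / (
            n * tau_sq + delta_sq
        )
        ss = np.sum((z - gamma_new[None, :]) ** 2, axis=0)
        delta_new = (0.5 * ss + b_prior) / (n / 2.0 + a_prior - 1.0)
        change = max(
            np.max(np.abs(gamma_new - gamma)),
            np.max(np.abs(delta_new - delta_sq)),
        )
        gamma, delta_sq = gamma_new, delta_new
        if change < tol:
            break
    return gamma, delta_sq


def correct_batches(matrix: BatchedMatrix) -> np.ndarray:
    """Remove batch effects with parametric empirical-Bayes (ComBat) adjustment.

    Values are log-transformed, standardized per feature (grand mean and
    pooled within-batch variance), per-batch location/scale parameters are
    estimated and shrunk toward their across-feature priors, and the
    adjusted data are back-transformed, so output stays strictly positive
    and each feature keeps its grand mean and pooled variance (up to the
    EB shrinkage). A single batch is returned unchanged. Features with zero
    within-batch variance skip the scale step for that batch.
    """
    batches = matrix.batches
    if len(batches) == 1:
        return matrix.values.copy()
    labels = np.asarray(matrix.batch_labels)
    idx = {b: np.flatnonzero(labels == b) for b in batches}
    for b, rows in idx.items():
        if rows.size < 2:
            raise ValueError(f"batch {b!r} has a single sample; cannot correct")

    x = np.log(matrix.values)
    n_total, n_feat = x.shape
    batch_means = {b: x[rows].mean(axis=0) for b, rows in idx.items()}
    # grand mean weighted by batch size; pooled variance around batch means
    alpha = np.zeros(n_feat)
    for b, rows in idx.items():
        alpha += rows.size / n_total * batch_means[b]
    resid = x.copy()
    for b, rows in idx.items():
        resid[rows] -= batch_means[b][None, :]
    pooled_var = np.mean(resid**2, axis=0)
    sd = np.sqrt(pooled_var)
    sd_safe = np.where(sd > 0, sd, 1.0)

    z = (x - alpha[None, :]) / sd_safe[None, :]
    adjusted = z.copy()
    for b, rows in idx.items():
        zb = z[rows]
        gamma_hat = zb.mean(axis=0)
        delta_hat_sq = zb.var(axis=0, ddof=1)
        gamma_bar = gamma_hat.mean()
        tau_sq = gamma_hat.var(ddof=1)
        m, s2 = delta_hat_sq.mean(), delta_hat_sq.var(ddof=1)
        if s2 > 0:
            a_prior = (2 * s2 + m**2) / s2
            b_prior = (m * s2 + m**3) / s2
            gamma_star, delta_star_sq = _eb_iterate(
                zb, gamma_hat, delta_hat_sq, gamma_bar, tau_sq, a_prior, b_prior
            )
        else:
            # degenerate prior (e.g. identical variances): no shrinkage of scale
            if tau_sq > 0:
                gamma_star = gamma_hat  # flat prior limit
            else:
                gamma_star = np.full(n_feat, gamma_bar)
            delta_star_sq = delta_hat_sq.copy()
        # zero within-batch variance: skip the scale step for those features
        scale = np.sqrt(np.where(delta_star_sq > 0, delta_star_sq, 1.0))
        adjusted[rows] = (zb - gamma_star[None, :]) / scale[None, :]

    out = adjusted * sd_safe[None, :] + alpha[None, :]
    return np.exp(out)


@dataclass(frozen=True)
class PrecisionReport:
    """Intra-/inter-day precision of replicate measurements (RSD, %)."""

    intraday_rsd: Mapping[str, float]
    interday_rsd: float
    intraday_pass: Mapping[str, bool]
    interday_pass: bool
    rsd_limit: float = PRECISION_RSD_LIMIT


def _rsd_percent(values: np.ndarray) -> float:
    mean = values.mean()
    if mean == 0:
        raise ValueError("group mean is zero; RSD undefined")
    return 100.0 * values.std(ddof=1) / mean


def precision_metrics(
    replicate_groups: Mapping[str, Sequence[float]],
    rsd_limit: float = PRECISION_RSD_LIMIT,
) -> PrecisionReport:
    """Intra-day RSD per replicate group and inter-day RSD on pooled values.

    RSD = 100 * sample sd / mean. A group (or the pooled set) passes when
    its RSD does not exceed ``rsd_limit`` (default 20%, the usual
    bioanalytical validation criterion).
    """
    if not replicate_groups:
        raise ValueError("no replicate groups supplied")
    intraday: dict[str, float] = {}
    pooled: list[float] = []
    for name, vals in replicate_groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {name!r} needs >= 2 replicates")
        intraday[str(name)] = _rsd_percent(arr)
        pooled.extend(arr.tolist())
    inter = _rsd_percent(np.asarray(pooled))
    return PrecisionReport(
        intraday_rsd=intraday,
        interday_rsd=inter,
        intraday_pass={k: v <= rsd_limit for k, v in intraday.items()},
        interday_pass=inter <= rsd_limit,
        rsd_limit=rsd_limit,
    )
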