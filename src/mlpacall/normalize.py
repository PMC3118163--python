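"""Peak-intensity normalization.

Non-biological variation in MLPA peak intensities comes from per-run global
scale (amount of DNA, PCR efficiency, injection) and from the systematic
decay of intensity with probe size.  Four methods remove it:

``sum_peaks_controls``
    Divide every peak of a run by the sum of that run's *reference-probe*
    peaks.  Corrects the global per-run factor.
``sum_peaks_all``
    Same, but the divisor is the sum over *all* (valid) probes — appropriate
    when the whole profile is expected to be equivalent across groups up to a
    factor.
``slope_correction``
    Fit intensity ~ a + b*size by ordinary least squares on the reference
    probes and divide every peak by the fitted line at its probe size, so a
    reference probe has expected normalized value 1.
``nonlinear``
    Fit an exponential decay A*exp(-lambda*size) to the reference-probe
    replicate means, weighted by the within-subject replicate variance, and
    divide by the fitted curve.  Requires technical replicates.

Fitting units: when the experiment has replicates, divisors and curves are
computed per *subject* from the replicate-mean profile and applied uniformly
to that subject's runs (a subject's normalization factor should not vary
between technical replicates); without replicates each run is its own subject,
so the factor is per run.  Division (rather than subtraction) keeps the
downstream "no change = 1" dosage-ratio scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitError, MethodPreconditionError, ValidationError
from .model import MLPAExperiment, NormalizedExperiment, canonical_normalization_method

logger = logging.getLogger(__name__)

#: Fitted values below this floor abort the division with an error rather
#: than silently clipping.
FITTED_FLOOR = 1e-12


@dataclass(frozen=True)
class SlopeFit:
    """Per-unit linear fit of intensity on probe size (reference probes only)."""

    unit: str
    intercept: float
    slope: float


@dataclass(frozen=True)
class DecayFit:
    """Per-unit exponential decay fit: intensity ~ amplitude * exp(-rate * size)."""

    unit: str
    amplitude: float
    rate: float
    within_subject_sd: float  # NaN when the unit has no replicates

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValidationError("decay rate must be >= 0")


def collapse_replicates(exp: MLPAExperiment) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject replicate means and sample standard deviations.

    Returns ``(means, sds)``, both probe x subject frames; subjects are in
    order of first appearance.  Standard deviations use the n-1 denominator
    and are NaN (flagged undefined) for single-run subjects.
    """
    means = {}
    sds = {}
    for subject, idx in exp.subject_runs.items():
        block = exp.intensities[:, idx]
        means[subject] = block.mean(axis=1)
        sds[subject] = block.std(axis=1, ddof=1) if len(idx) >= 2 else np.full(block.shape[0], np.nan)
    index = list(exp.panel.probe_ids)
    return (
        pd.DataFrame(means, index=index, columns=list(exp.subjects)),
        pd.DataFrame(sds, index=index, columns=list(exp.subjects)),
    )


def _units(exp: MLPAExperiment) -> list[tuple[str, list[int], np.ndarray]]:
    """(unit id, run column indices, replicate-mean profile) per subject."""
    out = []
    for subject, idx in exp.subject_runs.items():
        out.append((subject, idx, exp.intensities[:, idx].mean(axis=1)))
    return out


def normalize_sum_peaks(exp: MLPAExperiment, scope: str = "reference_only") -> NormalizedExperiment:
    """Divide each run by the (reference or total) peak sum of its unit.

    ``scope`` is ``"reference_only"`` (sum-peaks-controls) or ``"all_probes"``
    (sum-peaks-all).  Probes flagged invalid (all-zero) are excluded from the
    all-probes divisor; the exclusion is logged.
    """
    if scope not in ("reference_only", "all_probes"):
        raise ValidationError(f"unknown scope {scope!r}")
    ref_mask = exp.panel.is_reference
    if scope == "reference_only" and ref_mask.sum() < 1:
        raise MethodPreconditionError("sum-peaks-controls requires at least 1 reference probe")
    invalid = set(exp.invalid_probes)
    chosen = np.array(
        [
            (ref_mask[i] if scope == "reference_only" else True) and p not in invalid
            for i, p in enumerate(exp.panel.probe_ids)
        ]
    )
    if invalid and scope == "all_probes":
        logger.info("excluding invalid (all-zero) probe(s) from divisor: %s", sorted(invalid))
    out = np.empty_like(exp.intensities)
    divisors: dict[str, float] = {}
    for unit, idx, profile in _units(exp):
        divisor = float(profile[chosen].sum())
        if divisor <= 0:
            raise FitError(f"zero divisor for unit {unit!r}: chosen probes sum to {divisor}")
        divisors[unit] = divisor
        out[:, idx] = exp.intensities[:, idx] / divisor
    method = "sum_peaks_controls" if scope == "reference_only" else "sum_peaks_all"
    return NormalizedExperiment(
        experiment=exp.with_intensities(out),
        method=method,
        fit_params={"scope": scope, "divisors": divisors},
    )


def normalize_slope(exp: MLPAExperiment) -> NormalizedExperiment:
    """Remove the linear probe-size trend, per unit, via reference-probe OLS."""
    panel = exp.panel
    ref = panel.is_reference
    if ref.sum() < 2:
        raise MethodPreconditionError("slope correction requires >= 2 reference probes")
    sizes = panel.sizes_bp
    if np.ptp(sizes[ref]) == 0:
        raise FitError("degenerate slope fit: all reference probe sizes are equal")
    out = np.empty_like(exp.intensities)
    fits: dict[str, dict[str, float]] = {}
    for unit, idx, profile in _units(exp):
        res = stats.linregress(sizes[ref], profile[ref])
        fitted = res.intercept + res.slope * sizes
        bad = fitted < FITTED_FLOOR
        if np.any(bad):
            first = panel.probe_ids[int(np.argmax(bad))]
            raise FitError(
                f"unit {unit!r}: fitted intensity below {FITTED_FLOOR} at probe {first!r}"
            )
        out[:, idx] = exp.intensities[:, idx] / fitted[:, None]
        fits[unit] = {"intercept": float(res.intercept), "slope": float(res.slope)}
    return NormalizedExperiment(
        experiment=exp.with_intensities(out),
        method="slope_correction",
        fit_params={"per_unit": fits},
    )


def normalize_nonlinear(
    exp: MLPAExperiment,
    max_iter: int = 100,
    tol: float = 1e-12,
) -> NormalizedExperiment:
    """Remove probe-size decay with a per-subject exponential fit.

    Requires technical replicates: the fit is weighted by the within-subject
    replicate variance of each reference probe (inverse-variance weights with
    a floor at the 10th percentile of the positive variances, so zero-variance
    probes do not get infinite weight).  Initialization is a log-linear OLS on
    the positive reference means, refined by bounded nonlinear least squares
    (rate constrained >= 0).
    """
    panel = exp.panel
    if not exp.has_replicates:
        raise MethodPreconditionError("method requires replicates (>= 2 runs for some subject)")
    ref = panel.is_reference
    if ref.sum() < 3:
        raise MethodPreconditionError("nonlinear normalization requires >= 3 reference probes")
    sizes = panel.sizes_bp
    out = np.empty_like(exp.intensities)
    fits: dict[str, dict[str, float]] = {}
    for unit, idx, profile in _units(exp):
        y = profile[ref]
        s = sizes[ref]
        if np.any(y <= 0):
            raise FitError(f"unit {unit!r}: non-positive reference mean; cannot fit decay")
        if len(idx) >= 2:
            var = exp.intensities[np.ix_(ref, idx)].var(axis=1, ddof=1)
            pos = var[var > 0]
            if pos.size:
                weights = 1.0 / np.maximum(var, np.percentile(pos, 10))
            else:
                weights = np.ones_like(var)
            wssd = float(np.sqrt(var.mean()))
        else:
            weights = np.ones_like(y)
            wssd = float("nan")
        amp, rate = _fit_decay(s, y, weights, max_iter=max_iter, tol=tol, unit=unit)
        fitted = amp * np.exp(-rate * sizes)
        if np.any(fitted < FITTED_FLOOR):
            first = panel.probe_ids[int(np.argmax(fitted < FITTED_FLOOR))]
            raise FitError(f"unit {unit!r}: fitted decay below floor at probe {first!r}")
        out[:, idx] = exp.intensities[:, idx] / fitted[:, None]
        fits[unit] = {"amplitude": amp, "rate": rate, "within_subject_sd": wssd}
    return NormalizedExperiment(
        experiment=exp.with_intensities(out),
        method="nonlinear",
        fit_params={"per_unit": fits},
    )


def _fit_decay(s, y, weights, max_iter: int, tol: float, unit: str) -> tuple[float, float]:
    # log-linear initialization: log y = log A - rate * s is exact when the
    # data are noiseless, so the refinement step starts essentially converged.
    init = stats.linregress(s, np.log(y))
    rate0 = max(0.0, -init.slope)
    amp0 = float(np.exp(init.intercept))
    sw = np.sqrt(weights)

    def residuals(params):
        amp, rate = params
        return sw * (y - amp * np.exp(-rate * s))

    result = optimize.least_squares(
        residuals,
        x0=[max(amp0, FITTED_FLOOR), rate0],
        bounds=([FITTED_FLOOR, 0.0], [np.inf, np.inf]),
        xtol=tol,
        ftol=tol,
        gtol=None,
        max_nfev=max_iter * 3,
    )
    if result.status <= 0:
        raise FitError(f"unit {unit!r}: decay fit did not converge within the iteration cap")
    amp, rate = result.x
    return float(amp), float(rate)


def normalize(exp: MLPAExperiment, method: str, **kwargs) -> NormalizedExperiment:
    """Dispatch by method string (dotted or snake_case spellings accepted)."""
    canonical = canonical_normalization_method(method)
    if canonical == "sum_peaks_controls":
        return normalize_sum_peaks(exp, scope="reference_only", **kwargs)
    if canonical == "sum_peaks_all":
        return normalize_sum_peaks(exp, scope="all_probes", **kwargs)
    if canonical == "slope_correction":
        return normalize_slope(exp, **kwargs)
    return normalize_nonlinear(exp, **kwargs)
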