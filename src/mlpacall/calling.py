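"""Copy-number alteration calling between case and control samples.

After normalization each probe is classified per case subject as having a
relative gain (+1), loss (-1) or no change (0) in copy number.  Three methods
with increasing modelling depth:

``threshold``
    The dosage ratio (case / control-mean normalized intensity) is compared
    against fixed cutoffs: ratios below 0.7 are losses, ratios above 1.33 are
    gains.  Comparisons are strict, so a boundary ratio is "no change".

``rex_mlpa`` (REX-MLPA, regression-enhanced)
    Iterative case-on-control regression.  Starting from the reference
    probes, an OLS line of case on control intensities is fitted and a
    prediction band computed; test probes inside the band join the inlier set
    and the line is refitted, until the set stabilizes.  Probes above/below
    the final band are gains/losses.  The inlier set only grows, which
    guarantees termination in at most n_test iterations.

``mixed_model``
    Requires technical replicates.  Works on log normalized intensities,
    where the multiplicative replicate noise is additive: the response is the
    difference between a case subject's replicate-mean profile and the
    control-group mean profile.  The null variance of that difference is
    estimated from leave-one-out differences between control subjects (a
    closed-form moment estimator of the subject-mean variance, pooled across
    probes; normalization shares a divisor across a subject's runs, so this
    estimator absorbs the resulting correlations that a naive
    between/within decomposition would misstate).  The no-change band is
    ``grand_mean +- z(level) * sqrt(v * (1 + 1/n_controls))`` with the grand
    mean taken from the reference probes of the case subjects.  Estimates and
    bands are reported back on the dosage-ratio scale.

No multiple-testing correction is applied by default (per-probe intervals);
an optional Bonferroni adjustment across test probes is available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import FitError, MethodPreconditionError, ValidationError
from .model import (
    CALL_COLUMNS,
    CNACallTable,
    GROUP_CASE,
    GROUP_CONTROL,
    NormalizedExperiment,
    canonical_calling_method,
)
from .normalize import collapse_replicates

logger = logging.getLogger(__name__)

#: Relative floor on band half-widths, absorbing float rounding on perfectly
#: collinear (noiseless) data where the residual variance collapses to zero.
BAND_FLOOR_REL = 1e-8


@dataclass(frozen=True)
class ThresholdConfig:
    """Dosage-ratio cutoffs; defaults 0.7 (deletions) and 1.33 (gains)."""

    lower: float = 0.7
    upper: float = 1.33

    def __post_init__(self) -> None:
        if not (0 < self.lower < 1 < self.upper):
            raise ValidationError(
                f"thresholds must satisfy 0 < lower < 1 < upper, got ({self.lower}, {self.upper})"
            )


@dataclass(frozen=True)
class RexConfig:
    """REX-MLPA settings.

    ``level`` is the coverage of the prediction band (a prediction interval,
    not a confidence-of-mean interval: each probe is classified as an
    individual new observation).  ``pooled_cases`` regresses the mean case
    profile instead of one regression per case subject.
    """

    level: float = 0.95
    max_iter: int = 50
    pooled_cases: bool = False
    bonferroni: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.level < 1):
            raise ValidationError(f"level must be in (0, 1), got {self.level}")
        if self.max_iter < 1:
            raise ValidationError(f"max_iter must be >= 1, got {self.max_iter}")


@dataclass(frozen=True)
class MixedConfig:
    """Mixed-model settings; ``level`` sets the z-quantile no-change band."""

    level: float = 0.95
    bonferroni: bool = False
    min_variance: float = 1e-12

    def __post_init__(self) -> None:
        if not (0 < self.level < 1):
            raise ValidationError(f"level must be in (0, 1), got {self.level}")


@dataclass(frozen=True)
class MixedFit:
    """Fitted null model of the mixed-model caller (log scale).

    ``error_variance`` is the variance of one subject-mean profile value,
    estimated from leave-one-out differences between control subjects; it is
    the variance the no-change band is built from.
    ``within_replicate_variance`` is the pooled replicate-level log variance,
    reported as a diagnostic of assay precision.
    """

    grand_mean: float
    error_variance: float
    within_replicate_variance: float
    level: float
    z: float
    variance_floored: bool = False
    interval: tuple[float, float] = field(default=(np.nan, np.nan))


# --------------------------------------------------------------------------- ratios
def _profiles(norm: NormalizedExperiment):
    """Replicate-mean profiles split into control matrix and case matrix."""
    exp = norm.experiment
    means, sds = collapse_replicates(exp)
    group = exp.subject_group
    controls = [s for s in exp.subjects if group[s] == GROUP_CONTROL]
    cases = [s for s in exp.subjects if group[s] == GROUP_CASE]
    return means, sds, controls, cases


def dosage_ratios(norm: NormalizedExperiment) -> pd.DataFrame:
    """Probe x case-subject matrix of dosage ratios.

    ratio[p, s] = (case subject s's normalized replicate mean at p) /
    (mean over control subjects of their normalized replicate means at p).
    """
    means, _, controls, cases = _profiles(norm)
    if not controls:
        raise MethodPreconditionError("dosage ratios require at least 1 control run")
    ctrl_mean = means[controls].mean(axis=1)
    zero = ctrl_mean[ctrl_mean == 0]
    if len(zero):
        raise FitError(f"zero control mean at probe {zero.index[0]!r}")
    return means[cases].div(ctrl_mean, axis=0)


# ------------------------------------------------------------------------ threshold
def call_threshold(
    norm: NormalizedExperiment, cfg: ThresholdConfig | None = None
) -> CNACallTable:
    """Classify each (probe, case subject) dosage ratio against fixed cutoffs."""
    cfg = cfg or ThresholdConfig()
    ratios = dosage_ratios(norm)
    panel = norm.experiment.panel
    rows = []
    for unit in ratios.columns:
        r = ratios[unit].to_numpy()
        call = np.where(r < cfg.lower, -1, np.where(r > cfg.upper, 1, 0))
        for i, probe in enumerate(panel.probe_ids):
            rows.append(
                (probe, unit, bool(panel.is_reference[i]), int(call[i]), float(r[i]),
                 cfg.lower, cfg.upper, "threshold")
            )
    frame = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return CNACallTable(frame=frame, method="threshold", info={"config": cfg})


# ------------------------------------------------------------------------- REX-MLPA
def call_rex_mlpa(norm: NormalizedExperiment, cfg: RexConfig | None = None) -> CNACallTable:
    """Iterative case-on-control regression with a prediction band.

    Run once per case subject against the pooled control mean profile (or on
    the pooled case mean with ``cfg.pooled_cases``).  Reference probes seed
    the inlier set and, being part of the final null fit, are reported with
    call 0.
    """
    cfg = cfg or RexConfig()
    panel = norm.experiment.panel
    if panel.n_reference < 2:
        raise MethodPreconditionError("REX-MLPA requires >= 2 reference probes")
    means, _, controls, cases = _profiles(norm)
    if not controls:
        raise MethodPreconditionError("REX-MLPA requires at least 1 control run")
    x = means[controls].mean(axis=1).to_numpy()
    ref_mask = panel.is_reference
    n_test = int((~ref_mask).sum())
    alpha = 1.0 - cfg.level
    if cfg.bonferroni and n_test:
        alpha /= n_test

    units = [("case_group", means[cases].mean(axis=1).to_numpy())] if cfg.pooled_cases else [
        (s, means[s].to_numpy()) for s in cases
    ]
    rows = []
    info: dict = {"config": cfg, "per_unit": {}}
    for unit, y in units:
        fit = _rex_single(x, y, ref_mask, alpha, cfg.max_iter, unit)
        info["per_unit"][unit] = {
            "n_iterations": fit["n_iterations"],
            "converged": fit["converged"],
            "inlier_sizes": fit["inlier_sizes"],
            "slope": fit["slope"],
            "intercept": fit["intercept"],
        }
        for i, probe in enumerate(panel.probe_ids):
            is_ref = bool(ref_mask[i])
            call = 0 if is_ref else int(fit["calls"][i])
            rows.append(
                (probe, unit, is_ref, call, float(fit["residual"][i]),
                 float(-fit["half_width"][i]), float(fit["half_width"][i]), "rex_mlpa")
            )
    frame = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return CNACallTable(frame=frame, method="rex_mlpa", info=info)


def _rex_single(x, y, ref_mask, alpha, max_iter, unit):
    n = len(x)
    inliers = ref_mask.copy()
    fitted = np.zeros(n)
    half = np.full(n, np.inf)
    slope = intercept = np.nan
    n_iter = 0
    converged = False
    sizes = [int(inliers.sum())]
    for n_iter in range(1, max_iter + 1):
        xs = x[inliers]
        if np.ptp(xs) == 0:
            raise FitError(
                f"unit {unit!r}: degenerate regression (zero variance in control values among inliers)"
            )
        res = sm.OLS(y[inliers], sm.add_constant(xs)).fit()
        intercept, slope = (float(res.params[0]), float(res.params[1]))
        fitted = intercept + slope * x
        half = _prediction_half_width(res, x, xs, alpha)
        inside = (y >= fitted - half) & (y <= fitted + half)
        new_inliers = inliers | (inside & ~ref_mask)  # growth-only update
        if np.array_equal(new_inliers, inliers):
            converged = True
            break
        inliers = new_inliers
        sizes.append(int(inliers.sum()))
    if not converged:
        warnings.warn(
            f"REX-MLPA did not converge for unit {unit!r} within {max_iter} iterations; "
            "returning the last iteration's calls",
            stacklevel=2,
        )
    residual = y - fitted
    calls = np.where(residual > half, 1, np.where(residual < -half, -1, 0))
    return {
        "calls": calls,
        "residual": residual,
        "half_width": half,
        "fitted": fitted,
        "slope": slope,
        "intercept": intercept,
        "n_iterations": n_iter,
        "converged": converged,
        "inlier_sizes": sizes,
    }


def _prediction_half_width(res, x_all, x_in, alpha) -> np.ndarray:
    """Half-width of the OLS prediction interval at every probe's control value.

    Degenerate fits are handled explicitly: with no residual degrees of
    freedom the band is infinite (every probe is an inlier); a zero residual
    variance (perfect collinearity) gets a relative floor so that float
    rounding cannot produce spurious outliers.
    """
    df = res.df_resid
    scale = res.scale  # residual variance estimate
    if df < 1 or not np.isfinite(scale):
        return np.full(len(x_all), np.inf)
    n = len(x_in)
    mean_x = x_in.mean()
    sxx = float(np.sum((x_in - mean_x) ** 2))
    se_pred = np.sqrt(scale * (1.0 + 1.0 / n + (x_all - mean_x) ** 2 / sxx))
    t = stats.t.ppf(1 - alpha / 2.0, df)
    half = t * se_pred
    floor = BAND_FLOOR_REL * max(1.0, float(np.mean(np.abs(res.model.endog))))
    return np.maximum(half, floor)


# ---------------------------------------------------------------------- mixed model
def call_mixed_model(
    norm: NormalizedExperiment, cfg: MixedConfig | None = None
) -> CNACallTable:
    """Replicate-aware calling with a variance-component null band.

    See the module docstring for the model.  Preconditions: >= 2 reference
    probes, >= 2 control subjects, and technical replicates (>= 2 runs for at
    least 2 subjects).  If every variance estimate collapses to zero
    (noise-free data) the band falls back to a documented minimal-variance
    floor and a warning is emitted.
    """
    cfg = cfg or MixedConfig()
    exp = norm.experiment
    panel = exp.panel
    if not exp.has_replicates:
        raise MethodPreconditionError("method requires replicates")
    n_replicated = sum(1 for runs in exp.subject_runs.values() if len(runs) >= 2)
    if n_replicated < 2:
        raise MethodPreconditionError("mixed model requires >= 2 runs for >= 2 subjects")
    if panel.n_reference < 2:
        raise MethodPreconditionError("mixed model requires >= 2 reference probes")

    vals = exp.intensities
    if np.any(vals < 0) or not np.all(np.isfinite(vals)):
        raise ValidationError("normalized intensities must be finite and non-negative")
    positive = vals[vals > 0]
    if positive.size == 0:
        raise ValidationError("all normalized intensities are zero")
    if np.any(vals <= 0):
        # A genuinely absent peak (e.g. homozygous loss in a case) breaks the
        # log transform; floor it well below the smallest observed signal so
        # it still registers as an extreme loss.
        floor = float(positive.min()) / 10.0
        logger.warning("flooring %d non-positive cell(s) at %.3g before log", int((vals <= 0).sum()), floor)
        vals = np.maximum(vals, floor)
    log_vals = np.log(vals)
    group = exp.subject_group
    subject_runs = exp.subject_runs
    controls = [s for s in exp.subjects if group[s] == GROUP_CONTROL]
    cases = [s for s in exp.subjects if group[s] == GROUP_CASE]
    # subject replicate-mean profiles on the log scale
    log_means = {s: log_vals[:, idx].mean(axis=1) for s, idx in subject_runs.items()}
    if len(controls) < 2:
        raise MethodPreconditionError("mixed model requires >= 2 control subjects")
    if not cases:
        raise MethodPreconditionError("mixed model requires >= 1 case subject")
    n_c = len(controls)
    ref_mask = panel.is_reference

    ctrl_means = np.column_stack([log_means[s] for s in controls])
    ctrl_grand = ctrl_means.mean(axis=1)

    # Leave-one-out control-control differences -> variance of a subject-mean
    # profile value.  Var(dC) = v * n_c / (n_c - 1).
    loo = np.empty_like(ctrl_means)
    for k in range(n_c):
        others = np.delete(ctrl_means, k, axis=1).mean(axis=1)
        loo[:, k] = ctrl_means[:, k] - others
    v_hat = float(np.mean(loo**2)) * (n_c - 1) / n_c

    # Pooled within-subject (replicate) error variance, on the log scale, from
    # control subjects (all probes) and case subjects (reference probes only).
    ss, dof = 0.0, 0
    for subject in controls:
        runs = subject_runs[subject]
        if len(runs) >= 2:
            block = log_vals[:, runs]
            ss += float(((block - block.mean(axis=1, keepdims=True)) ** 2).sum())
            dof += block.shape[0] * (len(runs) - 1)
    for subject in cases:
        runs = subject_runs[subject]
        if len(runs) >= 2 and ref_mask.any():
            block = log_vals[np.ix_(ref_mask, runs)]
            ss += float(((block - block.mean(axis=1, keepdims=True)) ** 2).sum())
            dof += block.shape[0] * (len(runs) - 1)
    sigma2_e = ss / dof if dof > 0 else 0.0

    floored = False
    if v_hat <= cfg.min_variance:
        warnings.warn(
            "mixed model: the control-difference variance estimate is ~0; "
            f"falling back to the minimal-variance floor {cfg.min_variance}",
            stacklevel=2,
        )
        v_hat = cfg.min_variance
        floored = True

    d = np.column_stack([log_means[s] for s in cases]) - ctrl_grand[:, None]
    grand_mean = float(d[ref_mask, :].mean()) if ref_mask.any() else 0.0

    n_test = int((~ref_mask).sum())
    alpha = 1.0 - cfg.level
    if cfg.bonferroni and n_test:
        alpha /= n_test
    z = float(stats.norm.ppf(1 - alpha / 2.0))

    # Var(case subject mean - control grand mean) = v * (1 + 1/n_c), assuming
    # the case replicate structure is comparable to the controls'.
    se = float(np.sqrt(v_hat * (1.0 + 1.0 / n_c)))
    rows = []
    intervals = {}
    for j, unit in enumerate(cases):
        lo, hi = grand_mean - z * se, grand_mean + z * se
        intervals[unit] = (lo, hi)
        for i, probe in enumerate(panel.probe_ids):
            is_ref = bool(ref_mask[i])
            dev = float(d[i, j])
            call = 0 if is_ref else int(np.where(dev > hi, 1, np.where(dev < lo, -1, 0)))
            # report on the dosage-ratio scale (exp is monotone, so the
            # estimate/bound sign rule is preserved)
            rows.append(
                (probe, unit, is_ref, call, float(np.exp(dev)),
                 float(np.exp(lo)), float(np.exp(hi)), "mixed_model")
            )
    fit = MixedFit(
        grand_mean=grand_mean,
        error_variance=v_hat,
        within_replicate_variance=sigma2_e,
        level=cfg.level,
        z=z,
        variance_floored=floored,
        interval=intervals[cases[0]],
    )
    frame = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return CNACallTable(frame=frame, method="mixed_model", info={"config": cfg, "fit": fit, "intervals": intervals})


def call(norm: NormalizedExperiment, method: str, **kwargs) -> CNACallTable:
    """Dispatch by method string ("threshold", "REX-MLPA", "mixed-model")."""
    canonical = canonical_calling_method(method)
    if canonical == "threshold":
        cfg = kwargs.pop("cfg", None) or (ThresholdConfig(**kwargs) if kwargs else None)
        return call_threshold(norm, cfg)
    if canonical == "rex_mlpa":
        cfg = kwargs.pop("cfg", None) or (RexConfig(**kwargs) if kwargs else None)
        return call_rex_mlpa(norm, cfg)
    cfg = kwargs.pop("cfg", None) or (MixedConfig(**kwargs) if kwargs else None)
    return call_mixed_model(norm, cfg)
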