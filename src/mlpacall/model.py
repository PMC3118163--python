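"""Domain types for MLPA peak-intensity experiments.

MLPA (Multiplex Ligation-dependent Probe Amplification) produces one
fluorescent peak per targeted probe and sample run.  Peak intensity is
proportional to the template copy number, the probe's amplification
efficiency, and a per-run global scale; longer probes amplify less
efficiently, so intensity decays with probe size.  These types carry the raw
data through normalization and copy-number calling:

* :class:`ProbePanel` — the probe catalogue (ids, sizes in bp, reference flags).
* :class:`SampleMeta` — one sample run: group (case/control), subject,
  replicate index.
* :class:`MLPAExperiment` — the probe x run intensity matrix plus metadata.
* :class:`NormalizedExperiment` — intensities after one of the normalization
  methods, with the fitted parameters needed to re-apply the transform.
* :class:`CNACallTable` — per (probe, case-unit) gain/loss/no-change calls.

"Intensity" is treated as an abstract non-negative signal: peak height and
peak area both work, provided one convention is used consistently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

GROUP_CONTROL = "control"
GROUP_CASE = "case"

#: Normalization method strings accepted on the CLI / config surface,
#: mapped to canonical names.  The dotted spellings mirror the classic
#: R-style interface; snake_case aliases are canonical.
NORMALIZATION_METHODS: dict[str, str] = {
    "sum.peaks.controls": "sum_peaks_controls",
    "sums.peaks.controls": "sum_peaks_controls",
    "sum_peaks_controls": "sum_peaks_controls",
    "sum.peaks.all": "sum_peaks_all",
    "sums.peaks.all": "sum_peaks_all",
    "sum_peaks_all": "sum_peaks_all",
    "slope.correction": "slope_correction",
    "slope_correction": "slope_correction",
    "non.linear": "nonlinear",
    "non_linear": "nonlinear",
    "nonlinear": "nonlinear",
}

#: Calling method strings accepted verbatim, mapped to canonical names.
CALLING_METHODS: dict[str, str] = {
    "threshold": "threshold",
    "rex-mlpa": "rex_mlpa",
    "rex.mlpa": "rex_mlpa",
    "rex_mlpa": "rex_mlpa",
    "mixed-model": "mixed_model",
    "mixed.model": "mixed_model",
    "mixed_model": "mixed_model",
}


def canonical_normalization_method(name: str) -> str:
    key = str(name).strip().lower()
    if key not in NORMALIZATION_METHODS:
        raise ValidationError(
            f"unknown normalization method {name!r}; valid options: "
            + ", ".join(sorted(set(NORMALIZATION_METHODS)))
        )
    return NORMALIZATION_METHODS[key]


def canonical_calling_method(name: str) -> str:
    key = str(name).strip().lower()
    if key not in CALLING_METHODS:
        raise ValidationError(
            f"unknown calling method {name!r}; valid options: "
            + ", ".join(sorted(set(CALLING_METHODS)))
        )
    return CALLING_METHODS[key]


@dataclass(frozen=True)
class ProbePanel:
    """The probe catalogue of an MLPA kit.

    Parameters
    ----------
    probe_ids
        Unique opaque labels, one per probe.
    sizes_bp
        Amplicon sizes in base pairs; strictly positive.
    is_reference
        Flags the reference (copy-number-neutral) probes used to anchor
        normalization and the null model of the callers.
    """

    probe_ids: tuple[str, ...]
    sizes_bp: np.ndarray
    is_reference: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(str(p) for p in self.probe_ids)
        sizes = np.asarray(self.sizes_bp, dtype=float)
        ref = np.asarray(self.is_reference, dtype=bool)
        object.__setattr__(self, "probe_ids", ids)
        object.__setattr__(self, "sizes_bp", sizes)
        object.__setattr__(self, "is_reference", ref)
        if len(ids) == 0:
            raise ValidationError("probe panel is empty")
        if len(set(ids)) != len(ids):
            dupes = sorted({p for p in ids if ids.count(p) > 1})
            raise ValidationError(f"duplicate probe id(s): {dupes}")
        if sizes.shape != (len(ids),) or ref.shape != (len(ids),):
            raise ValidationError("panel fields must have one entry per probe")
        if not np.all(np.isfinite(sizes)) or np.any(sizes <= 0):
            raise ValidationError("probe sizes must be finite and > 0 bp")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_reference(self) -> int:
        return int(self.is_reference.sum())

    @property
    def reference_ids(self) -> tuple[str, ...]:
        return tuple(p for p, r in zip(self.probe_ids, self.is_reference) if r)

    @property
    def test_ids(self) -> tuple[str, ...]:
        return tuple(p for p, r in zip(self.probe_ids, self.is_reference) if not r)

    def index_of(self, probe_id: str) -> int:
        try:
            return self.probe_ids.index(probe_id)
        except ValueError:
            raise ValidationError(f"unknown probe id {probe_id!r}") from None


@dataclass(frozen=True)
class SampleMeta:
    """Metadata of one sample run (one capillary injection)."""

    run_id: str
    group: str
    subject_id: str
    replicate_index: int = 1

    def __post_init__(self) -> None:
        group = str(self.group).strip().lower()
        if group not in (GROUP_CONTROL, GROUP_CASE):
            raise ValidationError(
                f"run {self.run_id!r}: group must be 'control' or 'case', got {self.group!r}"
            )
        object.__setattr__(self, "group", group)
        object.__setattr__(self, "run_id", str(self.run_id))
        object.__setattr__(self, "subject_id", str(self.subject_id))
        rep = int(self.replicate_index)
        if rep < 1:
            raise ValidationError(
                f"run {self.run_id!r}: replicate_index must be >= 1, got {rep}"
            )
        object.__setattr__(self, "replicate_index", rep)


@dataclass(frozen=True)
class MLPAExperiment:
    """Raw (or normalized) peak intensities with sample metadata.

    ``intensities`` has shape (n_probes, n_runs); column order matches
    ``samples``.  Values must be finite and non-negative.  A probe whose
    intensity is zero across every run is flagged invalid (it carries no
    signal) but does not invalidate the experiment.
    """

    panel: ProbePanel
    samples: tuple[SampleMeta, ...]
    intensities: np.ndarray

    def __post_init__(self) -> None:
        samples = tuple(self.samples)
        vals = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "intensities", vals)
        if len(samples) == 0:
            raise ValidationError("experiment has no sample runs")
        run_ids = [s.run_id for s in samples]
        if len(set(run_ids)) != len(run_ids):
            raise ValidationError("duplicate run ids in sample metadata")
        keys = [(s.subject_id, s.replicate_index) for s in samples]
        if len(set(keys)) != len(keys):
            raise ValidationError("(subject_id, replicate_index) pairs must be unique")
        subj_groups: dict[str, str] = {}
        for s in samples:
            prev = subj_groups.setdefault(s.subject_id, s.group)
            if prev != s.group:
                raise ValidationError(
                    f"subject {s.subject_id!r} appears in both groups"
                )
        groups = {s.group for s in samples}
        if GROUP_CONTROL not in groups or GROUP_CASE not in groups:
            raise ValidationError("experiment needs at least 1 control and 1 case run")
        if vals.shape != (self.panel.n_probes, len(samples)):
            raise ValidationError(
                f"intensity matrix shape {vals.shape} does not match "
                f"({self.panel.n_probes} probes, {len(samples)} runs)"
            )
        if not np.all(np.isfinite(vals)):
            raise ValidationError("intensities must be finite")
        if np.any(vals < 0):
            raise ValidationError("intensities must be non-negative")

    # ------------------------------------------------------------------ views
    @property
    def run_ids(self) -> tuple[str, ...]:
        return tuple(s.run_id for s in self.samples)

    @property
    def n_runs(self) -> int:
        return len(self.samples)

    @property
    def subjects(self) -> tuple[str, ...]:
        """Subject ids in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.subject_id, None)
        return tuple(seen)

    @property
    def subject_runs(self) -> dict[str, list[int]]:
        """Column indices of each subject's runs."""
        out: dict[str, list[int]] = {}
        for j, s in enumerate(self.samples):
            out.setdefault(s.subject_id, []).append(j)
        return out

    @property
    def subject_group(self) -> dict[str, str]:
        return {s.subject_id: s.group for s in self.samples}

    @property
    def has_replicates(self) -> bool:
        """True iff some subject has >= 2 runs."""
        return any(len(v) >= 2 for v in self.subject_runs.values())

    @property
    def control_run_indices(self) -> np.ndarray:
        return np.array([j for j, s in enumerate(self.samples) if s.group == GROUP_CONTROL])

    @property
    def case_run_indices(self) -> np.ndarray:
        return np.array([j for j, s in enumerate(self.samples) if s.group == GROUP_CASE])

    @property
    def invalid_probes(self) -> tuple[str, ...]:
        """Probes with all-zero intensity across every run (no signal)."""
        mask = np.all(self.intensities == 0, axis=1)
        return tuple(p for p, m in zip(self.panel.probe_ids, mask) if m)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.intensities, index=list(self.panel.probe_ids), columns=list(self.run_ids)
        )

    def with_intensities(self, values: np.ndarray) -> "MLPAExperiment":
        return MLPAExperiment(self.panel, self.samples, values)

    def subset_runs(self, run_ids: Sequence[str]) -> "MLPAExperiment":
        """Restrict the experiment to the given runs (order preserved)."""
        wanted = [str(r) for r in run_ids]
        index = {s.run_id: j for j, s in enumerate(self.samples)}
        missing = [r for r in wanted if r not in index]
        if missing:
            raise ValidationError(f"unknown run id(s): {missing}")
        cols = [index[r] for r in wanted]
        return MLPAExperiment(
            self.panel, tuple(self.samples[j] for j in cols), self.intensities[:, cols]
        )

    def first_replicates(self) -> "MLPAExperiment":
        """One run per subject (the lowest replicate index) — the view an
        analysis that ignores technical replicates would see."""
        best: dict[str, SampleMeta] = {}
        for s in self.samples:
            cur = best.get(s.subject_id)
            if cur is None or s.replicate_index < cur.replicate_index:
                best[s.subject_id] = s
        return self.subset_runs([best[subj].run_id for subj in self.subjects])

    def summary(self) -> dict[str, int]:
        groups = [s.group for s in self.samples]
        return {
            "n_probes": self.panel.n_probes,
            "n_reference": self.panel.n_reference,
            "n_runs": self.n_runs,
            "n_control_runs": groups.count(GROUP_CONTROL),
            "n_case_runs": groups.count(GROUP_CASE),
            "n_subjects": len(self.subjects),
            "has_replicates": self.has_replicates,
        }


def setup_experiment(
    control_intensities,
    case_intensities,
    sizes_bp: Sequence[float],
    reference_ids: Sequence[str],
    replicate_map: Mapping[str, tuple[str, int]] | None = None,
    probe_ids: Sequence[str] | None = None,
) -> MLPAExperiment:
    """Assemble and validate an :class:`MLPAExperiment` from matrices.

    ``control_intensities`` and ``case_intensities`` are probe x run tables
    (:class:`pandas.DataFrame` with run-id columns, or plain arrays — run ids
    are then generated as ``control_1 ...`` / ``case_1 ...``).  Both share the
    probe axis, in the order of ``probe_ids`` (or the control frame's index).

    ``replicate_map`` maps run_id -> (subject_id, replicate_index).  When
    absent, every run is its own subject with replicate_index 1 (the
    no-replicates design).
    """
    ctrl = _as_frame(control_intensities, probe_ids, "control")
    case = _as_frame(case_intensities, probe_ids, "case")
    if list(ctrl.index) != list(case.index):
        raise ValidationError("control and case matrices must share the probe axis")
    ids = [str(p) for p in ctrl.index]
    sizes = np.asarray(sizes_bp, dtype=float)
    if sizes.shape != (len(ids),):
        raise ValidationError(
            f"sizes_bp has {sizes.size} entries for {len(ids)} probes"
        )
    ref_set = {str(r) for r in reference_ids}
    unknown = ref_set - set(ids)
    if unknown:
        raise ValidationError(f"unknown reference probe(s): {sorted(unknown)}")
    panel = ProbePanel(
        probe_ids=tuple(ids),
        sizes_bp=sizes,
        is_reference=np.array([p in ref_set for p in ids]),
    )
    samples: list[SampleMeta] = []
    for frame, group in ((ctrl, GROUP_CONTROL), (case, GROUP_CASE)):
        for run_id in frame.columns:
            run_id = str(run_id)
            if replicate_map is not None and run_id in replicate_map:
                subject, rep = replicate_map[run_id]
                samples.append(SampleMeta(run_id, group, str(subject), int(rep)))
            else:
                samples.append(SampleMeta(run_id, group, run_id, 1))
    values = np.column_stack([ctrl.to_numpy(dtype=float), case.to_numpy(dtype=float)])
    return MLPAExperiment(panel=panel, samples=tuple(samples), intensities=values)


def _as_frame(matrix, probe_ids, prefix: str) -> pd.DataFrame:
    if isinstance(matrix, pd.DataFrame):
        frame = matrix.copy()
        if probe_ids is not None:
            frame.index = [str(p) for p in probe_ids]
        return frame
    arr = np.atleast_2d(np.asarray(matrix, dtype=float))
    if probe_ids is None:
        probe_ids = [f"P{i + 1:03d}" for i in range(arr.shape[0])]
    cols = [f"{prefix}_{j + 1}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=[str(p) for p in probe_ids], columns=cols)


@dataclass(frozen=True)
class NormalizedExperiment:
    """An experiment whose intensities have been normalized.

    ``fit_params`` records, per fitting unit (run or subject), everything
    needed to re-apply the transform deterministically: divisors for the
    sum-peaks methods, regression coefficients for the slope correction, or
    decay parameters for the nonlinear method.
    """

    experiment: MLPAExperiment
    method: str
    fit_params: dict = field(default_factory=dict)

    @classmethod
    def pre_normalized(cls, experiment: MLPAExperiment) -> "NormalizedExperiment":
        """Wrap data that is already on a common scale (no transform applied)."""
        return cls(experiment=experiment, method="external", fit_params={})


# Stable column order of a serialized call table; used for diffable output.
CALL_COLUMNS = [
    "probe_id",
    "case_unit",
    "is_reference",
    "call",
    "estimate",
    "lower_bound",
    "upper_bound",
    "method",
]


@dataclass(frozen=True)
class CNACallTable:
    """Per (probe, case-unit) copy-number alteration calls.

    ``call`` is -1 (loss), 0 (no change) or +1 (gain).  ``estimate`` is the
    method's dosage statistic on the "no change = 1" ratio scale wherever the
    method defines one (threshold and mixed model) or the regression residual
    (REX-MLPA); ``lower_bound``/``upper_bound`` delimit the no-change band on
    the same scale.  A non-reference probe is called +1 exactly when its
    estimate exceeds the upper bound and -1 exactly when it falls below the
    lower bound (strict comparisons).  Reference probes anchor the null fit of
    the band methods and are reported with call 0.
    """

    frame: pd.DataFrame
    method: str
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        frame = self.frame.copy()
        missing = [c for c in CALL_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"call table missing column(s): {missing}")
        frame = frame[CALL_COLUMNS].reset_index(drop=True)
        if len(frame):
            frame["call"] = frame["call"].astype(int)
            frame["is_reference"] = frame["is_reference"].astype(bool)
        object.__setattr__(self, "frame", frame)
        self._validate()

    def _validate(self) -> None:
        f = self.frame
        if len(f) == 0:
            return
        if not f["call"].isin([-1, 0, 1]).all():
            raise ValidationError("calls must be in {-1, 0, +1}")
        # The sign rule is checked for every row the band applies to; reference
        # probes in the band methods define the null and carry call 0 by fiat.
        band = f if (f["method"] == "threshold").all() else f[~f["is_reference"]]
        est, lo, hi = (band[c].to_numpy(float) for c in ("estimate", "lower_bound", "upper_bound"))
        call = band["call"].to_numpy(int)
        expected = np.where(est > hi, 1, np.where(est < lo, -1, 0))
        if not np.array_equal(call, expected):
            raise ValidationError("call codes do not match the estimate/bound sign rule")
        ref = f[f["is_reference"]]
        if (f["method"] != "threshold").any() and len(ref) and (ref["call"] != 0).any():
            raise ValidationError("reference probes used in the null fit must not be called altered")

    @property
    def n_calls(self) -> int:
        return int((self.frame["call"] != 0).sum())

    def calls_by_probe(self) -> pd.DataFrame:
        """Pivot to a probe x case-unit grid of call codes."""
        return self.frame.pivot(index="probe_id", columns="case_unit", values="call")
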