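"""Synthetic MLPA experiments with known ground truth.

The generator emulates the physics of an MLPA run: a per-probe baseline that
decays exponentially with amplicon size (longer probes amplify less), a
per-run global scale factor (DNA amount, PCR/injection efficiency), a planted
copy-number multiplier for case subjects (0.5 for a heterozygous loss, 1.5
for a single-copy gain, ...), and multiplicative lognormal measurement noise.
Multiplicative noise keeps intensities positive and makes errors scale with
signal, as peak data do; it also keeps dosage ratios well defined.

    intensity[p, run] = A * exp(-lambda * size_p) * run_factor * mult_p * noise

with ``run_factor ~ Lognormal(0, run_scale_sd)`` per run and
``noise ~ Lognormal(0, sigma)`` per cell, ``sigma = sqrt(log(1 + cv^2))`` so
the cell-level coefficient of variation is ``within_subject_cv``.  The
multiplier applies to case subjects only and is identical across a subject's
replicates (a genotype is a property of the subject, not of the run).

The default shape mirrors a typical candidate-gene panel: 34 probes of which
9 are reference, 10 case and 5 control subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .model import CNACallTable, MLPAExperiment, ProbePanel, SampleMeta

__all__ = [
    "SimConfig",
    "SimTruth",
    "CallScore",
    "simulate_experiment",
    "evaluate_calls",
    "read_truth",
    "write_truth",
]


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults are the package's standard study shape."""

    n_probes: int = 34
    n_reference: int = 9
    n_case_subjects: int = 10
    n_control_subjects: int = 5
    n_replicates: int = 1
    size_range_bp: tuple[float, float] = (90.0, 500.0)
    decay_amplitude: float = 1000.0
    decay_rate: float = 0.004  # per bp; ~5x intensity drop across 90-500 bp
    run_scale_sd: float = 0.15  # lognormal sd of the per-run global factor
    within_subject_cv: float = 0.05
    alteration_map: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_reference < self.n_probes):
            raise ValidationError("need 0 < n_reference < n_probes")
        if self.n_case_subjects < 1 or self.n_control_subjects < 1:
            raise ValidationError("need at least one case and one control subject")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        lo, hi = self.size_range_bp
        if not (0 < lo < hi):
            raise ValidationError("size_range_bp must be an increasing positive pair")
        if self.decay_amplitude <= 0 or self.decay_rate < 0:
            raise ValidationError("decay amplitude must be > 0 and rate >= 0")
        if self.run_scale_sd < 0 or self.within_subject_cv < 0:
            raise ValidationError("noise parameters must be >= 0")
        ids = set(self.probe_ids)
        ref = set(self.reference_ids)
        for probe, mult in self.alteration_map.items():
            if probe not in ids:
                raise ValidationError(f"alteration_map: unknown probe {probe!r}")
            if probe in ref:
                raise ValidationError(f"alteration_map: reference probe {probe!r} cannot be altered")
            if not mult > 0:
                raise ValidationError(f"alteration_map: multiplier for {probe!r} must be > 0")

    @property
    def probe_ids(self) -> tuple[str, ...]:
        return tuple(f"P{i + 1:03d}" for i in range(self.n_probes))

    @property
    def sizes_bp(self) -> np.ndarray:
        return np.linspace(self.size_range_bp[0], self.size_range_bp[1], self.n_probes)

    @property
    def reference_indices(self) -> np.ndarray:
        """Reference probes spread evenly across the size range."""
        idx = np.unique(np.round(np.linspace(0, self.n_probes - 1, self.n_reference)).astype(int))
        k = 0
        extra = []
        while len(idx) + len(extra) < self.n_reference:  # fill collisions on tiny panels
            if k not in idx and k not in extra:
                extra.append(k)
            k += 1
        return np.sort(np.concatenate([idx, np.array(extra, dtype=int)])) if extra else idx

    @property
    def reference_ids(self) -> tuple[str, ...]:
        ids = self.probe_ids
        return tuple(ids[i] for i in self.reference_indices)


@dataclass(frozen=True)
class SimTruth:
    """The planted alteration map and the generating configuration.

    ``config`` is None when a truth table was read back from file rather than
    produced by :func:`simulate_experiment`.
    """

    probe_ids: tuple[str, ...]
    alteration_map: dict[str, float]
    expected_calls: dict[str, int]  # per probe: sign of log multiplier
    config: SimConfig | None = None


def simulate_experiment(cfg: SimConfig, seed: int | None = None) -> tuple[MLPAExperiment, SimTruth]:
    """Generate one experiment; bit-identical for identical (cfg, seed).

    ``seed`` overrides ``cfg.seed`` when given.
    """
    if seed is not None:
        cfg = replace(cfg, seed=int(seed))
    rng = np.random.default_rng(cfg.seed)
    probe_ids = cfg.probe_ids
    sizes = cfg.sizes_bp
    ref_idx = cfg.reference_indices
    is_ref = np.zeros(cfg.n_probes, dtype=bool)
    is_ref[ref_idx] = True
    base = cfg.decay_amplitude * np.exp(-cfg.decay_rate * sizes)

    mult = np.ones(cfg.n_probes)
    for probe, m in cfg.alteration_map.items():
        mult[probe_ids.index(probe)] = m

    sigma_cell = float(np.sqrt(np.log1p(cfg.within_subject_cv**2)))
    samples: list[SampleMeta] = []
    columns: list[np.ndarray] = []
    for group, n_subj, tag in (("control", cfg.n_control_subjects, "C"), ("case", cfg.n_case_subjects, "S")):
        probe_mult = mult if group == "case" else np.ones(cfg.n_probes)
        for s in range(n_subj):
            subject = f"{tag}{s + 1:02d}"
            for r in range(cfg.n_replicates):
                run_factor = float(np.exp(rng.normal(0.0, cfg.run_scale_sd)))
                noise = np.exp(rng.normal(0.0, sigma_cell, size=cfg.n_probes))
                columns.append(base * probe_mult * run_factor * noise)
                samples.append(SampleMeta(f"{subject}_r{r + 1}", group, subject, r + 1))
    panel = ProbePanel(probe_ids=probe_ids, sizes_bp=sizes, is_reference=is_ref)
    exp = MLPAExperiment(panel=panel, samples=tuple(samples), intensities=np.column_stack(columns))
    expected = {p: int(np.sign(np.log(m))) for p, m in cfg.alteration_map.items()}
    truth = SimTruth(
        probe_ids=probe_ids,
        alteration_map=dict(cfg.alteration_map),
        expected_calls=expected,
        config=cfg,
    )
    return exp, truth


def write_truth(truth: SimTruth, path) -> None:
    """Write the planted truth as a probe-level CSV."""
    import pandas as pd

    frame = pd.DataFrame(
        {
            "probe_id": list(truth.probe_ids),
            "multiplier": [truth.alteration_map.get(p, 1.0) for p in truth.probe_ids],
            "expected_call": [truth.expected_calls.get(p, 0) for p in truth.probe_ids],
        }
    )
    frame.to_csv(path, index=False)


def read_truth(path) -> SimTruth:
    """Read a truth CSV written by :func:`write_truth`."""
    import pandas as pd

    from .errors import FormatError

    frame = pd.read_csv(path, dtype={"probe_id": str})
    for col in ("probe_id", "multiplier", "expected_call"):
        if col not in frame.columns:
            raise FormatError(f"truth file missing column {col!r}")
    alteration = {
        str(p): float(m)
        for p, m in zip(frame["probe_id"], frame["multiplier"])
        if float(m) != 1.0
    }
    expected = {
        str(p): int(c) for p, c in zip(frame["probe_id"], frame["expected_call"]) if int(c) != 0
    }
    return SimTruth(
        probe_ids=tuple(str(p) for p in frame["probe_id"]),
        alteration_map=alteration,
        expected_calls=expected,
        config=None,
    )


@dataclass(frozen=True)
class CallScore:
    """Confusion summary of a call table against the planted truth.

    Metrics are computed over test-probe (probe, case-unit) cells: reference
    probes define the null machinery and are excluded.  ``type_i_error`` is
    the fraction of truly-null cells called non-zero; ``power`` is the
    fraction of altered cells called with the correct sign.
    """

    type_i_error: float
    power: float
    n_null_cells: int
    n_altered_cells: int
    confusion: dict[tuple[int, int], int]


def evaluate_calls(calls: CNACallTable, truth: SimTruth) -> CallScore:
    """Score a call table against the simulation truth."""
    frame = calls.frame
    probes = set(frame["probe_id"])
    expected_probes = set(truth.probe_ids)
    if probes != expected_probes:
        raise ValidationError(
            f"probe-set mismatch: calls cover {len(probes)} probes, truth {len(expected_probes)}"
        )
    test = frame[~frame["is_reference"]]
    expected = test["probe_id"].map(lambda p: truth.expected_calls.get(p, 0)).to_numpy(int)
    called = test["call"].to_numpy(int)
    null_mask = expected == 0
    alt_mask = ~null_mask
    n_null = int(null_mask.sum())
    n_alt = int(alt_mask.sum())
    type_i = float((called[null_mask] != 0).mean()) if n_null else float("nan")
    power = float((called[alt_mask] == expected[alt_mask]).mean()) if n_alt else float("nan")
    confusion: dict[tuple[int, int], int] = {}
    for t in (-1, 0, 1):
        for c in (-1, 0, 1):
            confusion[(t, c)] = int(((expected == t) & (called == c)).sum())
    return CallScore(
        type_i_error=type_i,
        power=power,
        n_null_cells=n_null,
        n_altered_cells=n_alt,
        confusion=confusion,
    )
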