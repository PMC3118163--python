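"""Plot exports: case-vs-control scatter and probe x subject call grids."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # file export only; no interactive backend required
import matplotlib.pyplot as plt
import numpy as np

from .model import CNACallTable, NormalizedExperiment
from .normalize import collapse_replicates


def plot_case_control(
    norm: NormalizedExperiment,
    calls: CNACallTable | None = None,
    case_unit: str | None = None,
    path=None,
):
    """Scatter of normalized case vs control intensities for one case unit.

    When a REX-MLPA call table is given, the fitted line and the no-change
    band of that unit are drawn and called probes are highlighted.
    """
    exp = norm.experiment
    means, _ = collapse_replicates(exp)
    group = exp.subject_group
    controls = [s for s in exp.subjects if group[s] == "control"]
    cases = [s for s in exp.subjects if group[s] == "case"]
    if case_unit is None:
        case_unit = cases[0]
    x = means[controls].mean(axis=1).to_numpy()
    y = means[case_unit].to_numpy() if case_unit in means.columns else means[cases].mean(axis=1).to_numpy()

    fig, ax = plt.subplots(figsize=(5, 5))
    ref = exp.panel.is_reference
    ax.scatter(x[ref], y[ref], marker="s", color="tab:gray", label="reference probes")
    ax.scatter(x[~ref], y[~ref], marker="o", color="tab:blue", label="test probes")
    if calls is not None and calls.method == "rex_mlpa":
        unit_info = calls.info.get("per_unit", {}).get(case_unit)
        if unit_info is not None:
            grid = np.linspace(x.min(), x.max(), 50)
            line = unit_info["intercept"] + unit_info["slope"] * grid
            ax.plot(grid, line, color="black", lw=1)
            sub = calls.frame[calls.frame["case_unit"] == case_unit].set_index("probe_id")
            half = sub.loc[list(exp.panel.probe_ids), "upper_bound"].to_numpy(float)
            fitted = unit_info["intercept"] + unit_info["slope"] * x
            order = np.argsort(x)
            ax.fill_between(x[order], (fitted - half)[order], (fitted + half)[order], alpha=0.15, color="black")
            hit = sub["call"] != 0
            if hit.any():
                idx = [exp.panel.index_of(p) for p in sub.index[hit]]
                ax.scatter(x[idx], y[idx], color="tab:red", label="called")
    ax.set_xlabel("control mean normalized intensity")
    ax.set_ylabel(f"case ({case_unit}) normalized intensity")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_call_grid(calls: CNACallTable, path=None):
    """Probe x case-unit grid of calls: red = loss, green = gain."""
    grid = calls.calls_by_probe()
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * len(grid)), max(3, 0.4 * grid.shape[1])))
    from matplotlib.colors import ListedColormap

    cmap = ListedColormap(["tab:red", "white", "tab:green"])
    ax.imshow(grid.to_numpy().T, cmap=cmap, vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(len(grid)), grid.index, rotation=90, fontsize=6)
    ax.set_yticks(range(grid.shape[1]), grid.columns, fontsize=7)
    ax.set_xlabel("probe")
    ax.set_ylabel("case unit")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
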