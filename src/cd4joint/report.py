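"""Report assembly: one markdown document collecting every analysis table."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["build_report", "save_mean_variance_plot", "save_trace_plots"]

_SECTIONS = [
    ("descriptives", "Cohort descriptives"),
    ("mean_variance", "Mean-variance overdispersion profile"),
    ("count_families", "Count-family comparison (quasi-Poisson-log-normal vs negative binomial)"),
    ("survival_comparison", "Survival-model comparison (Weibull vs Cox)"),
    ("variance_models", "Homogeneous vs patient-specific variance"),
    ("mcar", "MCAR missingness diagnostic"),
    ("ladder", "Joint-model DIC ladder"),
    ("joint_summary", "Joint-model posterior summaries"),
    ("hazard_ratios", "Hazard ratios (joint model)"),
]


def _fmt(obj) -> str:
    if isinstance(obj, pd.DataFrame):
        return obj.to_markdown(floatfmt=".4g")
    return str(obj)


def build_report(sections: dict[str, object], title: str = "Joint-model analysis report") -> str:
    """Render a deterministic markdown report.

    ``sections`` maps section keys (see module source) to DataFrames or
    strings; missing sections are rendered as explicit "not run" blocks.
    At least one section must be present.
    """
    present = [k for k, _ in _SECTIONS if k in sections]
    if not present:
        raise ValueError("no analysis outputs to report")
    parts = [f"# {title}", ""]
    for key, heading in _SECTIONS:
        parts.append(f"## {heading}")
        if key in sections:
            parts.append(_fmt(sections[key]))
        else:
            parts.append("_not run_")
        parts.append("")
    return "\n".join(parts)


def save_mean_variance_plot(profile: pd.DataFrame, path: str | Path) -> None:
    """Mean vs SD of the per-visit CD4 change (the overdispersion check)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    import numpy as np

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(profile["mean"], profile["sd"], "o-", label="per-visit profile")
    grid = np.linspace(0, max(profile["mean"].max(), 1.0) * 1.05, 50)
    ax.plot(grid, np.sqrt(grid), "--", color="grey", label="Poisson (SD = sqrt(mean))")
    ax.set_xlabel("mean CD4 change")
    ax.set_ylabel("SD of CD4 change")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def save_trace_plots(result, path: str | Path, params: list[str] | None = None) -> None:
    """Trace plots of selected posterior draws (one panel per parameter)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = params or list(result.draws)[:6]
    fig, axes = plt.subplots(len(names), 1, figsize=(6, 1.8 * len(names)), squeeze=False)
    for ax, name in zip(axes[:, 0], names):
        for c in range(result.draws[name].shape[0]):
            ax.plot(result.draws[name][c], lw=0.6)
        ax.set_ylabel(name, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
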