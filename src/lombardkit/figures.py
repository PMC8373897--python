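"""Static figure export: raw feature distributions and model estimates."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def feature_distribution_figure(table, feature: str, conditions, path: str | Path) -> None:
    """Violin-style distribution of one feature across noise levels."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    data = [table.loc[table["condition"] == c, feature].dropna() for c in conditions]
    data = [d for d in data if len(d)]
    if data:
        ax.violinplot([d.to_numpy() for d in data], vert=False, showmeans=True)
        ax.set_yticks(range(1, len(data) + 1), conditions[: len(data)])
    ax.set_xlabel(feature)
    ax.set_title(f"{feature} by noise level")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def estimate_interval_figure(ladder, path: str | Path) -> None:
    """Marginal condition estimates with +-1 SE bars from a fitted ladder."""
    fit = ladder.full_fit
    levels = fit.factors.get("condition", [])
    if not levels:
        return
    from .inference import _cell_row

    beta = fit.beta
    cov = fit.cov[fit.n_thresholds :, fit.n_thresholds :]
    est, se = [], []
    for lv in levels:
        x = _cell_row(fit, {"condition": lv})
        est.append(float(x @ beta))
        se.append(float(np.sqrt(max(x @ cov @ x, 0))))
    fig, ax = plt.subplots(figsize=(4.2, 3.0))
    ax.errorbar(range(len(levels)), est, yerr=se, fmt="o", capsize=4)
    ax.set_xticks(range(len(levels)), levels)
    ax.set_ylabel(f"estimate ({ladder.response})")
    ax.set_title(f"Model estimates: {ladder.response}")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def export_report_figures(report, out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    conditions = list(report.modality_table.index[:-1])
    for feat, lad in report.ladders.items():
        p1 = out / f"{feat}_distribution.png"
        feature_distribution_figure(report.feature_table, feat, conditions, p1)
        p2 = out / f"{feat}_estimates.png"
        estimate_interval_figure(lad, p2)
        written += [p1, p2]
    return written
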