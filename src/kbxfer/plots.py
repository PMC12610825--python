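"""Standard figures of the transferability experiment."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_ptv_metrics(result, ax=None):
    """Box plots of PTV coverage metrics for both test cohorts."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    metrics = ["V95%", "V105%", "D1%", "D99%"]
    data, labels = [], []
    for m in metrics:
        for arm in ("intra", "external"):
            data.append(result.ptv_metrics[arm][m])
            labels.append(f"{m}\n{arm}")
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("% volume / Gy")
    ax.set_title("PTV planning metrics by test cohort")
    return ax


def plot_volumes(result, ax=None):
    """Box plots of structure volumes for both test cohorts."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    organs = ["PTV"] + list(result.config.organs)
    data, labels = [], []
    for organ in organs:
        for cohort, arm in ((result.bundle.intra_test, "intra"),
                            (result.bundle.external_test, "ext")):
            data.append([p.volumes[organ] for p in cohort.patients])
            labels.append(f"{organ}\n{arm}")
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("volume (cc)")
    ax.tick_params(axis="x", labelsize=7)
    ax.set_title("Structure volumes by test cohort")
    return ax


def plot_delta_panels(report, ax=None, which: str = "delta_mean_dose",
                      band: float = 2.0):
    """Per-model boxes of Δ = clinical − predicted with accuracy-band lines."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    recs = report.records[report.records["category"] != "failed"]
    model_ids = sorted(recs["model_id"].unique())
    data = [recs.loc[recs["model_id"] == m, which].to_numpy()
            for m in model_ids]
    ax.boxplot(data, tick_labels=[m.replace("institution_", "inst ")
                                  for m in model_ids])
    for y in (band, -band):
        ax.axhline(y, linestyle="--", color="gray")
    ax.axhline(0, color="black", linewidth=0.5)
    unit = "Gy" if "mean" in which else "% points"
    ax.set_ylabel(f"Δ ({unit})")
    ax.set_title(f"{which} per model (positive: clinical > predicted)")
    ax.tick_params(axis="x", rotation=45, labelsize=7)
    return ax


def plot_pc1_bars(result, ax=None):
    """Inside/outside PC1 counts per model for both arms."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    insts = sorted(result.intra_report.pc1_outside_by_model)
    import numpy as np
    x = np.arange(len(insts))
    out_i = [result.intra_report.pc1_outside_by_model[i] for i in insts]
    out_e = [result.external_report.pc1_outside_by_model[i] for i in insts]
    ax.bar(x - 0.2, out_i, width=0.4, label="intra")
    ax.bar(x + 0.2, out_e, width=0.4, label="external")
    ax.set_xticks(x)
    ax.set_xticklabels([i.replace("institution_", "inst ") for i in insts],
                       rotation=45, fontsize=7)
    ax.set_ylabel("PC1 outside fraction")
    ax.set_title("Geometry PC1 outside training percentile window")
    ax.legend()
    return ax


def save_standard_figures(result, out_dir) -> list[Path]:
    """Write the four standard figures as PNGs; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    jobs = [
        ("ptv_metrics.png", lambda ax: plot_ptv_metrics(result, ax)),
        ("volumes.png", lambda ax: plot_volumes(result, ax)),
        ("delta_mean_dose.png",
         lambda ax: plot_delta_panels(result.external_report, ax,
                                      "delta_mean_dose", 2.0)),
        ("delta_v20.png",
         lambda ax: plot_delta_panels(result.external_report, ax,
                                      "delta_v20", 5.0)),
        ("pc1_outside.png", lambda ax: plot_pc1_bars(result, ax)),
    ]
    for name, job in jobs:
        fig, ax = plt.subplots(figsize=(8, 4))
        job(ax)
        fig.tight_layout()
        path = out_dir / name
        fig.savefig(path, dpi=110)
        plt.close(fig)
        paths.append(path)
    return paths
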