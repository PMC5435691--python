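"""Agreement figures: concordance scatter and Bland-Altman plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .stats import AgreementReport


def ccc_scatter(report: AgreementReport, path: str | Path) -> None:
    t = report.per_case["tkv_true_ml"]
    a = report.per_case["tkv_auto_ml"]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(t, a, s=25, alpha=0.8)
    lim = [0, max(t.max(), a.max()) * 1.05]
    ax.plot(lim, lim, "k--", lw=1, label="identity")
    ax.set_xlabel("true TKV (mL)")
    ax.set_ylabel("automated TKV (mL)")
    lo, hi = report.ccc_ci95
    ax.set_title(f"CCC = {report.ccc:.3f} [95% CI {lo:.3f}-{hi:.3f}]")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def bland_altman_plot(report: AgreementReport, path: str | Path,
                      mode: str = "percentage") -> None:
    t = report.per_case["tkv_true_ml"].to_numpy()
    a = report.per_case["tkv_auto_ml"].to_numpy()
    means = (t + a) / 2
    if mode == "percentage":
        diffs = 100.0 * (a - t) / means
        m, (lo, hi) = report.ba_mean_pct_diff, report.ba_loa_pct
        ylabel = "difference (% of pairwise mean)"
    else:
        diffs = a - t
        m, (lo, hi) = report.ba_mean_diff_ml, report.ba_loa_ml
        ylabel = "difference (mL)"
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, s=25, alpha=0.8)
    for v, style in ((m, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(v, color="crimson", ls=style, lw=1)
    ax.set_xlabel("pairwise mean TKV (mL)")
    ax.set_ylabel(ylabel)
    ax.set_title(f"Bland-Altman: mean {m:.1f}, LOA [{lo:.1f}, {hi:.1f}]")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def occlusion_heatmap(delta_dsc: np.ndarray, path: str | Path,
                      reference_mask: np.ndarray | None = None) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(delta_dsc, cmap="inferno")
    fig.colorbar(im, ax=ax, label="DSC drop")
    ax.set_title("occlusion importance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
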