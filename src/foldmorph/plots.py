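"""Plotting helpers: violin plots of bootstrapped means and trajectory maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["violin_plot", "trajectory_plot"]


def violin_plot(effects, path, title: str | None = None) -> None:
    """Violin plot of bootstrapped mean z-scores, reference vs comparison.

    One pair of violins per measure; an asterisk marks nominal
    significance (rank-sum p < 0.05).
    """
    fig, ax = plt.subplots(figsize=(1.6 * len(effects) + 2, 4))
    positions_ref = np.arange(len(effects)) * 2.0
    positions_cmp = positions_ref + 0.7
    vr = ax.violinplot([e.boot_ref for e in effects], positions=positions_ref, widths=0.6)
    vc = ax.violinplot([e.boot_cmp for e in effects], positions=positions_cmp, widths=0.6)
    for body in vr["bodies"]:
        body.set_facecolor("tab:gray")
    for body in vc["bodies"]:
        body.set_facecolor("tab:red")
    top = max(max(e.boot_ref.max(), e.boot_cmp.max()) for e in effects)
    for e, x in zip(effects, positions_ref):
        label = f"d={e.d:+.2f}" + ("*" if e.significant else "")
        ax.text(x + 0.35, top + 0.05, label, ha="center", fontsize=9)
    ax.set_xticks(positions_ref + 0.35)
    ax.set_xticklabels([e.measure for e in effects])
    ax.set_ylabel("bootstrapped mean z-score")
    ax.axhline(0, color="k", lw=0.5)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def trajectory_plot(points, path, annotate_I: bool = True) -> None:
    """2D projection (K, S) of trajectory points, reference at the origin.

    Dashed lines link each condition back to the reference; the size
    effect d_I is annotated next to each point since it is projected out.
    """
    fig, ax = plt.subplots(figsize=(5, 5))
    for pt in points:
        ax.plot([0, pt.d_K], [0, pt.d_S], "k--", lw=0.8, zorder=1)
        ax.scatter([pt.d_K], [pt.d_S], s=60, zorder=2)
        label = pt.condition
        if annotate_I and pt.condition != points[0].condition:
            label += f" (d_I={pt.d_I:+.2f})"
        ax.annotate(label, (pt.d_K, pt.d_S), textcoords="offset points", xytext=(6, 6))
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("effect size d in K (tension)")
    ax.set_ylabel("effect size d in S (shape)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
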