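"""Kaplan–Meier and violin figures (SVG output)."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .survival import KMCurve  # noqa: E402
from .tumor_normal import GroupedExpression, expression_summary  # noqa: E402


def _step_xy(curve: KMCurve, horizon: float):
    x = np.concatenate([[0.0], curve.times, [horizon]])
    y = np.concatenate([[1.0], curve.survival, [curve.survival[-1]
                                                if curve.survival.size else 1.0]])
    return x, y


def format_p(p: float) -> str:
    """Scientific notation below 1e-4, else 3 significant figures."""
    if p < 1e-4:
        return f"p = {p:.2g}"
    return f"p = {p:.3g}"


def km_annotation(hr: float, ci_low: float, ci_high: float, p: float,
                  n_high: int, n_low: int) -> str:
    return (f"HR = {hr:.3g}, 95% CI = {ci_low:.3g}–{ci_high:.3g}\n"
            f"{format_p(p)}\nhigh n = {n_high}, low n = {n_low}")


def render_km_plot(high: KMCurve, low: KMCurve, annotation: str = "",
                   title: str = "", path=None):
    """Step-function KM curves for the high/low groups with an annotation box."""
    horizon = max([1.0] + [c.times[-1] for c in (high, low) if c.times.size])
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for curve, label, color in ((high, f"high (n={high.n})", "#c0392b"),
                                (low, f"low (n={low.n})", "#2c3e50")):
        x, y = _step_xy(curve, horizon)
        ax.step(x, y, where="post", label=label, color=color)
    ax.set_xlabel("time")
    ax.set_ylabel("overall survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend(loc="lower left", frameon=False)
    if annotation:
        ax.text(0.98, 0.98, annotation, transform=ax.transAxes,
                ha="right", va="top", fontsize=9,
                bbox=dict(boxstyle="round", fc="white", ec="0.7"))
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, format="svg")
        plt.close(fig)
        return None
    return fig


def render_violin_plot(g: GroupedExpression, annotation: str = "",
                       title: str = "", path=None):
    """Mirror-density (violin) comparison of tumor and normal expression."""
    fig, ax = plt.subplots(figsize=(5, 4.5))
    for pos, (vals, label, color) in enumerate(
            ((g.normal_values, g.labels[1], "#2c3e50"),
             (g.tumor_values, g.labels[0], "#c0392b"))):
        summ = expression_summary(vals)
        if not summ.degenerate:
            dens = summ.density_y / summ.density_y.max() * 0.35
            ax.fill_betweenx(summ.density_x, pos - dens, pos + dens,
                             color=color, alpha=0.6)
        ax.plot([pos - 0.2, pos + 0.2], [summ.median] * 2, color="black")
        ax.plot([pos] * 2, [summ.q1, summ.q3], color="black", lw=3, alpha=0.5)
    ax.set_xticks([0, 1], [f"{g.labels[1]}\n(n={g.normal_values.size})",
                           f"{g.labels[0]}\n(n={g.tumor_values.size})"])
    ax.set_ylabel("expression")
    if annotation:
        ax.set_title(annotation, fontsize=9)
    elif title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, format="svg")
        plt.close(fig)
        return None
    return fig
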