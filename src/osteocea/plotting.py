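"""Plain matplotlib renderings of the decision outputs (optional extra).

Import is lazy so the core package does not require matplotlib.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_tornado(entries, ax=None):
    """Horizontal tornado bars of ICER ranges, widest at the top."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.4 * len(entries) + 1))
    finite = [e for e in entries if np.isfinite(e.width)]
    ys = np.arange(len(finite))[::-1]
    for y, e in zip(ys, finite):
        lo, hi = sorted((e.icer_low, e.icer_high))
        ax.barh(y, hi - lo, left=lo, height=0.6, color="#4878d0")
        ax.plot([e.icer_base], [y], "k|", markersize=10)
    ax.set_yticks(ys)
    ax.set_yticklabels([e.label for e in finite], fontsize=8)
    ax.set_xlabel("ICER (USD/QALY)")
    return ax


def plot_ceac(curves: pd.DataFrame, ax=None):
    """Cost-effectiveness acceptability curves over the WTP grid."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for col in curves.columns:
        if col == "wtp":
            continue
        ax.plot(curves["wtp"], curves[col], label=col)
    ax.set_xlabel("Willingness to pay (USD/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax
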