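"""Small plotting helpers for ancestry distributions."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def plot_sorted_q(curves: dict[str, np.ndarray], path: str | Path,
                  title: str = "Sorted ancestry distributions") -> None:
    """Plot sorted q values against rank, one curve per labelled set.

    A bimodal (parental-dominated) distribution shows a near-step curve; an
    abundance of hybrids flattens it.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, q in curves.items():
        y = np.sort(np.asarray(q, dtype=float))
        ax.plot(np.arange(1, y.size + 1), y, label=label, lw=1.5)
    ax.set_xlabel("individual rank")
    ax.set_ylabel("red wolf ancestry (q)")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
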